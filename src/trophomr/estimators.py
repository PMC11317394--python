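"""Causal estimators and sensitivity analyses for two-sample summary MR.

Notation: per instrument j, ``gamma_j`` (SE ``se_gamma_j``) is the
SNP-exposure effect and ``Gamma_j`` (SE ``se_Gamma_j``) the SNP-outcome
effect, harmonized to a shared allele.  The per-SNP causal estimate is the
Wald ratio ``Gamma_j / gamma_j``; the main estimator is the random-effects
inverse-variance-weighted (IVW) meta-analysis of these ratios, with
multiplicative overdispersion floored at 1 so the fixed-effect result is
recovered under homogeneity.  Sensitivity methods: Cochran's Q, MR-Egger
(free intercept absorbing average directional pleiotropy), the weighted
median (valid if >50% of the weight is on valid instruments), the weighted
mode (valid under the majority/plurality assumption, with a tunable kernel
bandwidth), leave-one-out re-estimation, the MR-PRESSO residual-resampling
outlier test, a first-order sample-overlap bias bound, and reverse-direction
MR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .harmonize import LDTable, clump, harmonize_tables, HarmonizedInstrument
from .sumstats import VariantAssociation

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """One method's causal-effect result (exposure-SD units on the outcome
    scale)."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    nsnp: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(method=self.method, theta=self.theta, se=self.se,
                 ci_low=self.ci_low, ci_high=self.ci_high, pval=self.pval,
                 nsnp=self.nsnp)
        d.update(self.extras)
        return d


@dataclass
class HeterogeneityStats:
    """Cochran-type heterogeneity for IVW (Q) and Egger (Q')."""

    Q: float
    df: int
    pval: float
    Q_prime: float | None = None
    df_prime: int | None = None
    q_diff: float | None = None
    q_diff_p: float | None = None


def _as_arrays(hs):
    """Extract (snp_ids, gamma, se_gamma, Gamma, se_Gamma) arrays.

    Accepts a sequence of HarmonizedInstrument (unusable actions filtered
    out), a DataFrame with the harmonized columns, or a 4/5-tuple of arrays.
    """
    if isinstance(hs, pd.DataFrame):
        df = hs
        if "action" in df.columns:
            df = df[df["action"].isin(["kept", "flipped", "strand_flipped", "proxied"])]
        ids = df["snp_id"].astype(str).to_numpy() if "snp_id" in df.columns \
            else np.array([str(i) for i in range(len(df))])
        return (ids, df["gamma"].to_numpy(float), df["se_gamma"].to_numpy(float),
                df["Gamma"].to_numpy(float), df["se_Gamma"].to_numpy(float))
    if isinstance(hs, tuple):
        if len(hs) == 4:
            g, sg, G, sG = (np.asarray(a, float) for a in hs)
            ids = np.array([str(i) for i in range(len(g))])
        else:
            ids = np.asarray(hs[0], dtype=str)
            g, sg, G, sG = (np.asarray(a, float) for a in hs[1:])
        return ids, g, sg, G, sG
    usable = [h for h in hs if h.usable]
    ids = np.array([h.snp_id for h in usable])
    g = np.array([h.gamma for h in usable], float)
    sg = np.array([h.se_gamma for h in usable], float)
    G = np.array([h.Gamma for h in usable], float)
    sG = np.array([h.se_Gamma for h in usable], float)
    return ids, g, sg, G, sG


def _estimate(method, theta, se, nsnp, pval=None, dist="norm", df=None, **extras):
    if pval is None:
        if dist == "t":
            pval = 2.0 * stats.t.sf(abs(theta / se), df)
        else:
            pval = 2.0 * stats.norm.sf(abs(theta / se))
    return MREstimate(
        method=method, theta=float(theta), se=float(se),
        ci_low=float(theta - Z95 * se), ci_high=float(theta + Z95 * se),
        pval=float(pval), nsnp=int(nsnp), extras=extras,
    )


def wald_ratio(h) -> MREstimate:
    """Single-instrument causal estimate ``Gamma / gamma`` with the
    first-order delta SE ``se_Gamma / |gamma|``."""
    if isinstance(h, HarmonizedInstrument):
        g, sG = h.gamma, h.se_Gamma
        G = h.Gamma
    else:
        _, ga, _, Ga, sGa = _as_arrays(h)
        if len(ga) != 1:
            raise ValueError("wald_ratio takes exactly one instrument")
        g, G, sG = ga[0], Ga[0], sGa[0]
    if g == 0:
        raise ValueError("Wald ratio undefined for gamma = 0")
    theta = G / g
    se = sG / abs(g)
    pval = 1.0 if G == 0 else None
    return _estimate("wald_ratio", theta, se, 1, pval=pval)


def _ivw_core(g, G, w):
    sw_g2 = np.sum(w * g**2)
    theta = np.sum(w * g * G) / sw_g2
    se_fixed = np.sqrt(1.0 / sw_g2)
    Q = float(np.sum(w * (G - theta * g) ** 2))
    return theta, se_fixed, Q


def ivw(hs, model: str = "random_multiplicative") -> MREstimate:
    """Inverse-variance-weighted estimate with Cochran's Q.

    Weights are ``1 / se_Gamma^2``.  Under the default multiplicative
    random-effects model the fixed-effect SE is inflated by
    ``max(1, sqrt(Q / (k - 1)))``; ``model="fixed"`` skips the inflation.
    With a single instrument the Wald ratio is returned instead (logged).
    """
    ids, g, sg, G, sG = _as_arrays(hs)
    k = len(g)
    if k == 0:
        raise ValueError("no usable instruments")
    if k < 2:
        logger.info("ivw: single instrument, falling back to Wald ratio")
        return wald_ratio((g, sg, G, sG))
    w = 1.0 / sG**2
    theta, se_fixed, Q = _ivw_core(g, G, w)
    q_df = k - 1
    q_p = float(stats.chi2.sf(Q, q_df))
    if model == "random_multiplicative":
        se = se_fixed * max(1.0, np.sqrt(Q / q_df))
    elif model == "fixed":
        se = se_fixed
    else:
        raise ValueError(f"unknown IVW model {model!r}")
    return _estimate("ivw" if model == "random_multiplicative" else "ivw_fixed",
                     theta, se, k, Q=Q, Q_df=q_df, Q_pval=q_p)


def cochran_q(hs) -> HeterogeneityStats:
    """Cochran's Q of the IVW fit (df = k - 1)."""
    ids, g, sg, G, sG = _as_arrays(hs)
    w = 1.0 / sG**2
    _, _, Q = _ivw_core(g, G, w)
    df = len(g) - 1
    return HeterogeneityStats(Q=Q, df=df, pval=float(stats.chi2.sf(Q, df)))


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: MREstimate
    heterogeneity: HeterogeneityStats


def mr_egger(hs) -> EggerResult:
    """MR-Egger weighted regression ``Gamma = b0 + theta * gamma``.

    Instruments are first oriented so every ``gamma >= 0`` (required for the
    intercept to be identifiable); weights are ``1 / se_Gamma^2``.  The
    intercept estimates average directional pleiotropy.  Q' is the weighted
    residual sum of squares (df = k - 2); Q - Q' on chi2(1) tests whether the
    free intercept improves on the IVW fit.  SEs carry the same
    multiplicative overdispersion floor as IVW; p-values use t(k - 2).
    """
    ids, g, sg, G, sG = _as_arrays(hs)
    k = len(g)
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    if np.allclose(g, g[0]):
        raise ValueError("degenerate design: no spread in |gamma|")
    w = 1.0 / sG**2
    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=w).fit()
    b0, b1 = fit.params
    Q_prime = float(np.sum(w * fit.resid**2))
    df_prime = k - 2
    scale = max(1.0, np.sqrt(Q_prime / df_prime))
    # statsmodels' bse already include sqrt(MSE); rescale to the floored form
    se0, se1 = fit.bse / np.sqrt(fit.mse_resid) * scale
    Q = cochran_q((g, sg, G, sG)).Q
    q_diff = Q - Q_prime
    het = HeterogeneityStats(
        Q=Q, df=k - 1, pval=float(stats.chi2.sf(Q, k - 1)),
        Q_prime=Q_prime, df_prime=df_prime, q_diff=q_diff,
        q_diff_p=float(stats.chi2.sf(max(q_diff, 0.0), 1)),
    )
    slope = _estimate("mr_egger", b1, se1, k, dist="t", df=df_prime,
                      Q_prime=Q_prime, Q_prime_pval=float(stats.chi2.sf(Q_prime, df_prime)))
    intercept = _estimate("mr_egger_intercept", b0, se0, k, dist="t", df=df_prime)
    return EggerResult(slope=slope, intercept=intercept, heterogeneity=het)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(hs, n_boot: int = 1000, seed=None) -> MREstimate:
    """Weighted median of the Wald ratios.

    Ratios are ordered with inverse-variance weights ``1 / se(ratio)^2``;
    the estimate interpolates the weighted CDF at 0.5 and is consistent when
    more than half the weight comes from valid instruments.  The SE is a
    parametric bootstrap: exposure and outcome effects are resampled from
    normals at their SEs, ratios recomputed (weights held fixed), and the SD
    of the re-estimates taken.
    """
    ids, g, sg, G, sG = _as_arrays(hs)
    if len(g) < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    ratios = G / g
    w = (g / sG) ** 2  # 1 / se(ratio)^2 with the delta-method SE
    theta = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        gb = rng.normal(g, sg)
        Gb = rng.normal(G, sG)
        boot[b] = _weighted_median(Gb / gb, w)
    se = float(np.std(boot, ddof=1))
    return _estimate("weighted_median", theta, se, len(g), n_boot=n_boot)


def silverman_bandwidth(ratios: np.ndarray) -> float:
    """Modified Silverman rule: ``0.9 min(sd, IQR/1.349) k^(-1/5)``."""
    k = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if k > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * k ** (-0.2)


def _kernel_density_argmax(ratios, weights, h, grid_size=2048, refine=25):
    lo = ratios.min() - 3 * h
    hi = ratios.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    i = int(np.argmax(dens))
    # local golden-section refinement within the bracketing grid cells
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_size - 1)]
    f = lambda x: -np.sum(weights * np.exp(-0.5 * ((x - ratios) / h) ** 2))
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(f, bounds=(a, b), method="bounded",
                          options={"xatol": (hi - lo) / grid_size / refine})
    return float(res.x)


def weighted_mode(hs, bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed=None, grid_size: int = 2048) -> MREstimate:
    """Weighted-mode estimate: argmax of a Gaussian-kernel-smoothed density
    over the Wald ratios.

    The base bandwidth is the modified Silverman rule on the ratios, scaled
    by ``bandwidth_factor`` (phi; default 1).  Valid when the largest
    cluster of instruments shares the true ratio (majority/plurality
    assumption); larger phi merges clusters.  SE by parametric bootstrap.
    Degenerate (zero-bandwidth) inputs fall back to the exact weighted mode.
    """
    ids, g, sg, G, sG = _as_arrays(hs)
    if len(g) < 3:
        raise ValueError("weighted mode needs at least 3 instruments")
    ratios = G / g
    w = (g / sG) ** 2
    w = w / w.sum()
    h0 = silverman_bandwidth(ratios)
    h = bandwidth_factor * h0
    if h <= 0:
        logger.warning("weighted_mode: zero bandwidth, using exact mode")
        vals, idx = np.unique(ratios, return_inverse=True)
        theta = float(vals[np.argmax(np.bincount(idx, weights=w))])
    else:
        theta = _kernel_density_argmax(ratios, w, h, grid_size)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        gb = rng.normal(g, sg)
        Gb = rng.normal(G, sG)
        rb = Gb / gb
        hb = bandwidth_factor * silverman_bandwidth(rb)
        if hb <= 0:
            boot[b] = np.median(rb)
            continue
        boot[b] = _kernel_density_argmax(rb, w, hb, grid_size=256)
    se = float(np.std(boot, ddof=1))
    return _estimate("weighted_mode", theta, se, len(g),
                     bandwidth=h, bandwidth_factor=bandwidth_factor,
                     n_boot=n_boot)


def leave_one_out(hs, model: str = "random_multiplicative") -> pd.DataFrame:
    """IVW re-estimated k times, each omitting one instrument.

    Returns a DataFrame keyed by the omitted snp_id.
    """
    ids, g, sg, G, sG = _as_arrays(hs)
    k = len(g)
    if k < 3:
        raise ValueError("leave-one-out needs at least 3 instruments")
    rows = []
    for j in range(k):
        keep = np.arange(k) != j
        est = ivw((g[keep], sg[keep], G[keep], sG[keep]), model=model)
        rows.append(dict(omitted=ids[j], theta=est.theta, se=est.se,
                         ci_low=est.ci_low, ci_high=est.ci_high,
                         pval=est.pval))
    return pd.DataFrame(rows).set_index("omitted")


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_pvals: dict
    outliers: list
    corrected: MREstimate | None
    n_sim: int


def _loo_theta(g, G, w):
    """Leave-one-out IVW point estimates, vectorized over instruments."""
    swgG = np.sum(w * g * G)
    swg2 = np.sum(w * g**2)
    return (swgG - w * g * G) / (swg2 - w * g**2)


def mr_presso(hs, n_sim: int = 1000, outlier_p: float = 0.05,
              seed=None) -> PressoResult:
    """MR-PRESSO global heterogeneity and per-SNP outlier test.

    The observed statistic is the weighted residual sum of squares
    ``RSS = sum_j w_j (Gamma_j - theta_(-j) gamma_j)^2`` with ``theta_(-j)``
    the leave-one-out IVW estimate and ``w_j = 1/se_Gamma_j^2``.  The null
    distribution resamples ``Gamma*_j ~ N(theta_(-j) gamma_j, se_Gamma_j)``
    and recomputes the statistic; the global p is the fraction of resampled
    RSS at or above the observed one.  Per-SNP p-values compare each
    observed weighted squared residual with its own resampled distribution,
    Bonferroni-corrected over k; instruments below ``outlier_p`` are removed
    and IVW rerun ("outlier-corrected" estimate).
    """
    if n_sim < 100:
        logger.warning("mr_presso: n_sim=%d is very small for a resampling p",
                       n_sim)
    ids, g, sg, G, sG = _as_arrays(hs)
    k = len(g)
    if k < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    w = 1.0 / sG**2
    t_loo = _loo_theta(g, G, w)
    resid_obs = w * (G - t_loo * g) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    Gs = rng.normal(t_loo * g, sG, size=(n_sim, k))
    # vectorized LOO theta per simulation
    wG = w * g * Gs
    swgG = wG.sum(axis=1, keepdims=True)
    swg2 = np.sum(w * g**2)
    t_loo_s = (swgG - wG) / (swg2 - w * g**2)
    resid_s = w * (Gs - t_loo_s * g) ** 2
    rss_s = resid_s.sum(axis=1)

    global_p = float(np.mean(rss_s >= rss_obs))
    per_snp = (np.sum(resid_s >= resid_obs, axis=0) + 1) / (n_sim + 1)
    per_snp_adj = np.minimum(per_snp * k, 1.0)
    outliers = [ids[j] for j in range(k) if per_snp_adj[j] < outlier_p]
    corrected = None
    if outliers:
        keep = ~np.isin(ids, outliers)
        if keep.sum() >= 2:
            corrected = ivw((g[keep], sg[keep], G[keep], sG[keep]))
            corrected.method = "mr_presso_corrected"
    return PressoResult(
        global_rss=rss_obs, global_p=global_p,
        outlier_pvals=dict(zip(ids, per_snp_adj)), outliers=outliers,
        corrected=corrected, n_sim=n_sim,
    )


def overlap_bias(overlap_fraction: float, f_bar: float):
    """First-order relative bias of the IVW estimate from exposure/outcome
    sample overlap: ``rho / F_bar``.

    ``overlap_fraction`` is the shared-sample fraction rho; ``f_bar`` a mean
    (or lower-confidence) instrument F.  Verdict is "negligible" below 1%.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap fraction must lie in [0, 1]")
    if f_bar <= 1:
        raise ValueError("mean F must exceed 1")
    bias = overlap_fraction / f_bar
    verdict = "negligible" if bias < 0.01 else "non-negligible"
    return bias, verdict


def bonferroni(pvals: Sequence[float], alpha: float = 0.05):
    """Bonferroni flags with strict inequality: significant iff
    ``p < alpha / m``.  Returns (flags, threshold)."""
    pvals = np.asarray(pvals, dtype=float)
    m = len(pvals)
    if m < 1:
        raise ValueError("need at least one p-value")
    threshold = alpha / m
    return pvals < threshold, threshold


def reverse_mr(
    outcome_as_exposure: Iterable[VariantAssociation],
    birthweight_as_outcome: Iterable[VariantAssociation],
    p_threshold: float = 5e-8,
    ld: LDTable | None = None,
    clump_r2: float = 0.001,
    palindromic_maf_cut: float = 0.4,
) -> MREstimate:
    """Reverse-direction MR: the disorder as exposure, birth weight as
    outcome.

    Genome-wide-significant disorder SNPs are clumped to independence,
    harmonized against the birth-weight table, and passed to IVW (Wald
    ratio when exactly one instrument survives).  With zero instruments a
    ``not_testable`` result is returned.
    """
    gws = [v for v in outcome_as_exposure
           if v.pval is not None and v.pval < p_threshold]
    if ld is not None and len(gws) > 1:
        kept = set(clump(gws, ld, r2_max=clump_r2))
        gws = [v for v in gws if v.snp_id in kept]
    hs = [h for h in harmonize_tables(gws, birthweight_as_outcome,
                                      palindromic_maf_cut)
          if h.usable]
    if not hs:
        return MREstimate(method="not_testable", theta=float("nan"),
                          se=float("nan"), ci_low=float("nan"),
                          ci_high=float("nan"), pval=float("nan"), nsnp=0)
    if len(hs) == 1:
        return wald_ratio(hs[0])
    return ivw(hs)
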