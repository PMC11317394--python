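"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the summary-data regime the estimators consume: per
instrument j a true SNP-exposure effect ``gamma_j`` (scaled so the per-SNP
variance explained matches a realistic profile, ~1e-4 to 4e-4), a true
SNP-outcome effect ``Gamma_j = theta * gamma_j + alpha_j`` with ``alpha_j``
drawn from a configurable pleiotropy model, and noisy estimates with the
standard-error scaling of variance-standardized GWAS
(``se = 1 / sqrt(2 p (1-p) n)``).  Sample overlap between the two studies
is modelled at the summary level as a correlation ``rho`` between the two
estimation errors.  Allele bookkeeping hazards of real data — palindromic
variants, swapped allele order, strand-complemented records — are planted
in the outcome table at configurable rates, and a truth record of
everything planted is always returned so tests never re-infer it.

Annotation fixtures (gene spans, a cell-type mean-expression matrix with
planted specific genes, a block LD table, a chromatin BED) come from
:func:`simulate_annotations`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import LDTable
from .instruments import GeneAnnotation
from .sumstats import CANONICAL_COLUMNS
from .instrument_table import N_EXPOSURE, outcome_iv_ids, packaged_instrument_table

_BASES = ("A", "C", "G", "T")
_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SyntheticScenario:
    """Configuration of one synthetic two-sample dataset.

    ``pleiotropy`` is ``None``/"none", ``("balanced", sd)``,
    ``("directional", mean, sd)`` or ``("outlier", index, magnitude)`` where
    the magnitude is in units of the outcome SE of that SNP.
    ``reverse_theta``, when set, plants ``k_reverse`` additional SNPs that
    are genome-wide significant for the *outcome* trait and act on the
    exposure with that effect, for reverse-direction tests.  Profile arrays
    (``eaf``/``gamma``/``se_gamma``/``se_Gamma``), when given, pin those
    quantities instead of drawing them.
    """

    k: int = 14
    theta: float = 0.0
    pleiotropy: tuple | str | None = None
    n_exp: int = N_EXPOSURE
    n_out: int = 100_000
    overlap_rho: float = 0.0
    ld_blocks: Sequence[tuple[int, float]] | None = None
    frac_palindromic: float = 0.0
    flip_frac: float = 0.0
    reverse_theta: float | None = None
    k_reverse: int = 10
    r2_range: tuple[float, float] = (1e-4, 4e-4)
    eaf: Sequence[float] | None = None
    gamma: Sequence[float] | None = None
    se_gamma: Sequence[float] | None = None
    se_Gamma: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for frac in (self.overlap_rho, self.frac_palindromic, self.flip_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def _pleiotropy_alpha(pleio, k, rng, se_Gamma, gamma_sign):
    if pleio in (None, "none"):
        return np.zeros(k)
    kind = pleio[0]
    if kind == "balanced":
        return rng.normal(0.0, pleio[1], size=k)
    if kind == "directional":
        # directional relative to the exposure-increasing allele: allele
        # orientation is arbitrary, so a mean pleiotropic effect is only
        # well defined (and Egger-detectable) on that oriented scale
        return gamma_sign * rng.normal(pleio[1], pleio[2], size=k)
    if kind == "outlier":
        alpha = np.zeros(k)
        alpha[pleio[1]] = pleio[2] * se_Gamma[pleio[1]]
        return alpha
    raise ValueError(f"unknown pleiotropy model {pleio!r}")


def _draw_alleles(k, frac_palindromic, rng):
    ea, oa = [], []
    for j in range(k):
        if rng.random() < frac_palindromic:
            a, b = _PALINDROMIC[rng.integers(len(_PALINDROMIC))]
        else:
            a, b = _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
        ea.append(a)
        oa.append(b)
    return np.array(ea), np.array(oa)


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def simulate_sumstats(s: SyntheticScenario):
    """Generate (exposure table, outcome table, truth record).

    Tables are canonical summary-statistics DataFrames.  The truth record
    holds theta, the per-SNP true effects and pleiotropy, and the ids of
    every planted perturbation (swapped, strand-complemented, palindromic,
    reverse-instrument SNPs).
    """
    rng = np.random.default_rng(s.seed)
    k = s.k

    eaf = (np.asarray(s.eaf, float) if s.eaf is not None
           else rng.uniform(0.05, 0.5, size=k))
    var_factor = 2.0 * eaf * (1.0 - eaf)
    if s.gamma is not None:
        gamma = np.asarray(s.gamma, float)
    else:
        r2 = rng.uniform(*s.r2_range, size=k)
        gamma = rng.choice([-1.0, 1.0], size=k) * np.sqrt(r2 / var_factor)
    se_g = (np.asarray(s.se_gamma, float) if s.se_gamma is not None
            else 1.0 / np.sqrt(var_factor * s.n_exp))
    se_G = (np.asarray(s.se_Gamma, float) if s.se_Gamma is not None
            else 1.0 / np.sqrt(var_factor * s.n_out))

    alpha = _pleiotropy_alpha(s.pleiotropy, k, rng, se_G,
                              np.where(gamma < 0, -1.0, 1.0))
    Gamma_true = s.theta * gamma + alpha

    # correlated estimation errors model shared samples
    z1 = rng.standard_normal(k)
    z2 = s.overlap_rho * z1 + np.sqrt(1 - s.overlap_rho**2) * rng.standard_normal(k)
    gamma_hat = gamma + se_g * z1
    Gamma_hat = Gamma_true + se_G * z2

    ea, oa = _draw_alleles(k, s.frac_palindromic, rng)
    snp_ids = np.array([f"rs{j + 1:06d}" for j in range(k)])
    chrom = np.full(k, "1")
    pos = np.arange(1, k + 1) * 1_000_000

    exposure = pd.DataFrame(dict(
        snp_id=snp_ids, chrom=chrom, pos=pos, ea=ea, oa=oa, eaf=eaf,
        beta=gamma_hat, se=se_g,
        pval=2 * stats.norm.sf(np.abs(gamma_hat / se_g)),
        z=gamma_hat / se_g, n=float(s.n_exp), fetal_effect=True,
    ))
    outcome = pd.DataFrame(dict(
        snp_id=snp_ids, chrom=chrom, pos=pos, ea=ea.copy(), oa=oa.copy(),
        eaf=eaf.copy(), beta=Gamma_hat.copy(), se=se_G,
        pval=2 * stats.norm.sf(np.abs(Gamma_hat / se_G)),
        z=Gamma_hat / se_G, n=float(s.n_out), fetal_effect=False,
    ))

    # plant allele bookkeeping perturbations in the outcome table
    swapped, strand = [], []
    n_flip = int(round(s.flip_frac * k))
    flip_idx = rng.choice(k, size=n_flip, replace=False) if n_flip else []
    for j in flip_idx:
        if rng.random() < 0.5:
            # swap allele order: effect refers to the other allele
            outcome.loc[j, ["ea", "oa"]] = [oa[j], ea[j]]
            outcome.loc[j, "beta"] *= -1
            outcome.loc[j, "z"] *= -1
            outcome.loc[j, "eaf"] = 1 - outcome.loc[j, "eaf"]
            swapped.append(snp_ids[j])
        else:
            # report the complementary strand; numbers unchanged
            outcome.loc[j, ["ea", "oa"]] = [_COMP[ea[j]], _COMP[oa[j]]]
            strand.append(snp_ids[j])

    reverse_ids = []
    if s.reverse_theta is not None:
        kr = s.k_reverse
        eaf_r = rng.uniform(0.05, 0.5, size=kr)
        vf = 2.0 * eaf_r * (1.0 - eaf_r)
        r2_r = rng.uniform(*s.r2_range, size=kr)
        b_out = rng.choice([-1.0, 1.0], size=kr) * np.sqrt(r2_r / vf)
        se_bo = 1.0 / np.sqrt(vf * s.n_out)
        se_be = 1.0 / np.sqrt(vf * s.n_exp)
        b_exp_true = s.reverse_theta * b_out
        b_out_hat = b_out + rng.normal(0, se_bo)
        b_exp_hat = b_exp_true + rng.normal(0, se_be)
        ids_r = np.array([f"rsR{j + 1:05d}" for j in range(kr)])
        ea_r, oa_r = _draw_alleles(kr, 0.0, rng)
        pos_r = (np.arange(kr) + 1) * 1_000_000
        reverse_ids = list(ids_r)
        out_extra = pd.DataFrame(dict(
            snp_id=ids_r, chrom=np.full(kr, "2"), pos=pos_r, ea=ea_r,
            oa=oa_r, eaf=eaf_r, beta=b_out_hat, se=se_bo,
            pval=2 * stats.norm.sf(np.abs(b_out_hat / se_bo)),
            z=b_out_hat / se_bo, n=float(s.n_out), fetal_effect=False,
        ))
        exp_extra = pd.DataFrame(dict(
            snp_id=ids_r, chrom=np.full(kr, "2"), pos=pos_r, ea=ea_r,
            oa=oa_r, eaf=eaf_r, beta=b_exp_hat, se=se_be,
            pval=2 * stats.norm.sf(np.abs(b_exp_hat / se_be)),
            z=b_exp_hat / se_be, n=float(s.n_exp), fetal_effect=False,
        ))
        outcome = pd.concat([outcome, out_extra], ignore_index=True)
        exposure = pd.concat([exposure, exp_extra], ignore_index=True)

    truth = dict(
        theta=s.theta, gamma=gamma, alpha=alpha, se_gamma=se_g, se_Gamma=se_G,
        eaf=eaf, snp_ids=list(snp_ids), swapped=swapped,
        strand_complemented=strand,
        palindromic=[snp_ids[j] for j in range(k)
                     if _COMP.get(ea[j]) == oa[j]],
        reverse_ids=reverse_ids, reverse_theta=s.reverse_theta,
    )
    exposure.attrs["trait"] = "exposure"
    outcome.attrs["trait"] = "outcome"
    return exposure, outcome, truth


def simulate_ld_table(snp_ids: Sequence[str],
                      ld_blocks: Sequence[tuple[int, float]],
                      fill_r2: float = 0.0) -> LDTable:
    """Block-structured LD: consecutive runs of SNPs share within-block r^2;
    cross-block pairs are omitted (r^2 = 0)."""
    rows = []
    i = 0
    for size, r2 in ld_blocks:
        block = snp_ids[i:i + size]
        for a_i in range(len(block)):
            for b_i in range(a_i + 1, len(block)):
                rows.append((block[a_i], block[b_i], r2, 1))
        i += size
    return LDTable(pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2", "phase"]))


def scenario_from_packaged_profile(theta: float, outcome: str = "depression",
                         n_out: int = 100_000, seed: int = 0,
                         **kwargs) -> SyntheticScenario:
    """Scenario whose instrument-strength profile clones the packaged
    instrument table (effects, SEs and EAFs of the surviving IV set for the
    given outcome label), with outcome-side SEs at sample size ``n_out``."""
    tab, _ = packaged_instrument_table()
    ids = outcome_iv_ids(outcome)
    sub = tab[tab["snp_id"].isin(ids)]
    eaf = sub["eaf"].to_numpy(float)
    eaf = np.minimum(eaf, 1 - eaf)  # frequency folded; sign profile kept in beta
    return SyntheticScenario(
        k=len(sub), theta=theta, n_out=n_out,
        eaf=eaf, gamma=sub["beta"].to_numpy(float),
        se_gamma=sub["se"].to_numpy(float), seed=seed, **kwargs,
    )


def simulate_annotations(
    n_genes: int,
    n_celltypes: int,
    planted_specific: Mapping[str, str],
    seed: int = 0,
    ld_blocks: Sequence[tuple[int, float]] | None = None,
    genes_per_chrom: int = 50,
):
    """Annotation fixtures with planted cell-type-specific genes.

    Returns (gene table, expression matrix, LD table, chromatin BED).
    Planted genes (gene id -> cell type) satisfy the fivefold/threshold
    specificity rule for their cell; all other genes do not.  Chromatin
    intervals tile each chromosome alternating active/inactive states.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    for g in planted_specific:
        if g not in gene_ids:
            raise ValueError(f"planted gene {g!r} not in the gene table")
    cells = [f"CT{c}" for c in range(n_celltypes)]

    genes = []
    for i, g in enumerate(gene_ids):
        chrom = str(i // genes_per_chrom + 1)
        start = (i % genes_per_chrom) * 200_000 + 50_000
        genes.append(GeneAnnotation(g, chrom, start, start + 20_000))

    rows = {}
    for g in gene_ids:
        cell = planted_specific.get(g)
        if cell is not None:
            base = rng.uniform(0.0, 0.8, size=n_celltypes)
            vals = dict(zip(cells, base))
            vals[cell] = rng.uniform(8.0, 12.0)
        else:
            # flat profile: never satisfies any fivefold rule
            vals = dict(zip(cells, rng.uniform(1.0, 2.0, size=n_celltypes)))
        rows[g] = vals
    expr = pd.DataFrame.from_dict(rows, orient="index")[cells]

    snp_ids = [f"rs{i + 1:06d}" for i in range(n_genes)]
    ld = simulate_ld_table(snp_ids, ld_blocks or [])

    bed_rows = []
    chroms = sorted({g.chrom for g in genes}, key=int)
    for chrom in chroms:
        span = max(g.end for g in genes if g.chrom == chrom) + 100_000
        edges = np.arange(0, span + 200_000, 200_000)
        for i in range(len(edges) - 1):
            bed_rows.append(dict(chrom=chrom, start=int(edges[i]),
                                 end=int(edges[i + 1]),
                                 state="TssA" if i % 2 == 0 else "Quies"))
    bed = pd.DataFrame(bed_rows)
    return genes, expr, ld, bed
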