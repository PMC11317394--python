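"""MR estimators: Wald ratio, IVW, Egger, median, mode, PRESSO and friends."""

import numpy as np
import pytest
from scipy import stats

from trophomr.estimators import (bonferroni, cochran_q, ivw, leave_one_out,
                                 mr_egger, mr_presso, overlap_bias,
                                 reverse_mr, wald_ratio, weighted_median,
                                 weighted_mode, silverman_bandwidth)
from trophomr.harmonize import HarmonizedInstrument
from trophomr.simulate import SyntheticScenario, simulate_sumstats
from trophomr.sumstats import to_records

from conftest import make_harmonized, variant


def _h(gamma=0.1, se_gamma=0.01, Gamma=0.02, se_Gamma=0.005, snp="rs1"):
    return HarmonizedInstrument(snp_id=snp, gamma=gamma, se_gamma=se_gamma,
                                Gamma=Gamma, se_Gamma=se_Gamma)


# -- Wald ratio -------------------------------------------------------------

def test_wald_ratio_arithmetic():
    e = wald_ratio(_h())
    assert e.theta == pytest.approx(0.2)
    assert e.se == pytest.approx(0.05)
    assert e.ci_low < e.theta < e.ci_high


def test_wald_ratio_zero_outcome_effect():
    e = wald_ratio(_h(Gamma=0.0))
    assert e.theta == 0.0 and e.pval == 1.0


def test_wald_ratio_sign_invariance_and_domain():
    a = wald_ratio(_h(gamma=0.1, Gamma=0.02))
    b = wald_ratio(_h(gamma=-0.1, Gamma=-0.02))
    assert a.theta == pytest.approx(b.theta)
    with pytest.raises(ValueError):
        wald_ratio(_h(gamma=0.0))


# -- IVW ----------------------------------------------------------------------

def test_ivw_identical_instruments():
    hs = [_h(snp="rs1"), _h(snp="rs2")]
    e = ivw(hs)
    assert e.theta == pytest.approx(0.2)
    assert e.extras["Q"] == pytest.approx(0.0, abs=1e-20)
    # Q = 0 floors the multiplicative scale at 1: fixed SE recovered
    assert e.se == pytest.approx(ivw(hs, model="fixed").se)


def test_ivw_q_hand_example():
    """Two ratio estimates 0.1 and 0.3 with ratio SE 0.1 each give Q = 2."""
    hs = make_harmonized([1.0, 1.0], [1e-6, 1e-6], [0.1, 0.3], [0.1, 0.1])
    e = ivw(hs)
    assert e.theta == pytest.approx(0.2)
    assert e.extras["Q"] == pytest.approx(2.0)
    assert e.extras["Q_pval"] == pytest.approx(stats.chi2.sf(2.0, 1))


def test_ivw_reduces_to_meta_analytic_mean():
    """With gamma = 1 everywhere, IVW is the inverse-variance-weighted mean
    of the outcome effects."""
    G = np.array([0.1, 0.2, 0.4])
    sG = np.array([0.05, 0.1, 0.2])
    hs = make_harmonized(np.ones(3), np.full(3, 1e-6), G, sG)
    w = 1 / sG**2
    assert ivw(hs, model="fixed").theta == pytest.approx(np.sum(w * G) / w.sum())
    assert ivw(hs, model="fixed").se == pytest.approx(np.sqrt(1 / w.sum()))


def test_ivw_random_effects_inflates_only_under_heterogeneity():
    hs = make_harmonized([1.0, 1.0], [1e-6] * 2, [0.1, 0.9], [0.1, 0.1])
    assert ivw(hs).se > ivw(hs, model="fixed").se


def test_ivw_single_instrument_falls_back_to_wald():
    e = ivw([_h()])
    assert e.method == "wald_ratio"
    assert e.theta == pytest.approx(0.2)


def test_ivw_scale_equivariance(simple_instruments):
    c = 3.7
    scaled = [
        HarmonizedInstrument(h.snp_id, h.gamma, h.se_gamma, c * h.Gamma,
                             c * h.se_Gamma)
        for h in simple_instruments
    ]
    for method in (ivw, weighted_median, weighted_mode):
        kw = {} if method is ivw else dict(seed=0, n_boot=50)
        a = method(simple_instruments, **kw)
        b = method(scaled, **kw)
        assert b.theta == pytest.approx(c * a.theta, rel=1e-6)
        assert b.se == pytest.approx(c * a.se, rel=0.05)


def test_q_invariant_to_order(simple_instruments):
    q1 = cochran_q(simple_instruments).Q
    q2 = cochran_q(simple_instruments[::-1]).Q
    assert q1 == pytest.approx(q2)


# -- MR-Egger -----------------------------------------------------------------

def test_egger_noiseless_line():
    gamma = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
    Gamma = 0.02 + 0.3 * gamma
    res = mr_egger(make_harmonized(gamma, [1e-6] * 5, Gamma, [1e-4] * 5))
    assert res.slope.theta == pytest.approx(0.3, abs=1e-6)
    assert res.intercept.theta == pytest.approx(0.02, abs=1e-6)
    assert res.heterogeneity.Q_prime == pytest.approx(0.0, abs=1e-10)


def test_egger_orientation_invariance(simple_instruments):
    base = mr_egger(simple_instruments)
    flipped = list(simple_instruments)
    h = flipped[2]
    flipped[2] = HarmonizedInstrument(h.snp_id, -h.gamma, h.se_gamma,
                                      -h.Gamma, h.se_Gamma)
    alt = mr_egger(flipped)
    assert alt.slope.theta == pytest.approx(base.slope.theta)
    assert alt.intercept.theta == pytest.approx(base.intercept.theta)
    assert alt.heterogeneity.Q_prime == pytest.approx(
        base.heterogeneity.Q_prime)


def test_egger_q_prime_never_exceeds_q():
    rng = np.random.default_rng(11)
    for _ in range(20):
        k = rng.integers(4, 12)
        gamma = rng.uniform(0.01, 0.05, k)
        Gamma = rng.normal(0.2 * gamma, 0.01)
        res = mr_egger(make_harmonized(gamma, np.full(k, 1e-3), Gamma,
                                       rng.uniform(0.005, 0.02, k)))
        het = res.heterogeneity
        assert het.Q_prime <= het.Q + 1e-9
        assert het.q_diff_p == pytest.approx(
            stats.chi2.sf(max(het.q_diff, 0), 1))


def test_egger_degenerate_design():
    with pytest.raises(ValueError):
        mr_egger(make_harmonized([0.02] * 4, [1e-3] * 4, [0.01] * 4,
                                 [0.01] * 4))
    with pytest.raises(ValueError):
        mr_egger([_h(), _h(snp="rs2")])


# -- weighted median ----------------------------------------------------------

def _median_oracle(ratios, weights):
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    s = (np.cumsum(w) - w / 2) / w.sum()
    return float(np.interp(0.5, s, r))


def test_weighted_median_equal_weights():
    hs = make_harmonized([1, 1, 1], [1e-6] * 3, [0.1, 0.2, 0.9], [0.1] * 3)
    assert weighted_median(hs, n_boot=50, seed=0).theta == pytest.approx(0.2)


def test_weighted_median_majority_mass_resists_outliers():
    gamma = np.ones(5)
    Gamma = np.array([0.2, 0.21, 5.0, 5.0, -3.0])
    sG = np.array([0.02, 0.02, 1.0, 1.0, 1.0])  # >50% weight on 0.2/0.21
    e = weighted_median(make_harmonized(gamma, [1e-6] * 5, Gamma, sG),
                        n_boot=50, seed=0)
    assert 0.2 <= e.theta <= 0.21
    assert e.theta == pytest.approx(
        _median_oracle(Gamma / gamma, (gamma / sG) ** 2))


@pytest.mark.parametrize("seed", range(4))
def test_weighted_median_matches_interpolation_oracle(seed):
    rng = np.random.default_rng(seed)
    k = rng.integers(3, 12)
    gamma = rng.uniform(0.01, 0.05, k) * rng.choice([-1, 1], k)
    Gamma = rng.normal(0.2 * gamma, 0.02)
    sG = rng.uniform(0.005, 0.05, k)
    hs = make_harmonized(gamma, np.full(k, 1e-3), Gamma, sG)
    e = weighted_median(hs, n_boot=20, seed=0)
    assert e.theta == pytest.approx(
        _median_oracle(Gamma / gamma, (gamma / sG) ** 2))


def test_weighted_median_bootstrap_reproducible(simple_instruments):
    a = weighted_median(simple_instruments, n_boot=100, seed=42)
    b = weighted_median(simple_instruments, n_boot=100, seed=42)
    assert a.se == b.se


# -- weighted mode ------------------------------------------------------------

def _mode_oracle(ratios, weights, h, n_grid=200_001):
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return grid[np.argmax(dens)]


def test_weighted_mode_majority_cluster():
    hs = make_harmonized([1, 1, 1, 1], [1e-6] * 4, [0.2, 0.2, 0.2, 5.0],
                         [0.1] * 4)
    e = weighted_mode(hs, n_boot=20, seed=0)
    assert e.theta == pytest.approx(0.2, abs=0.02)


@pytest.mark.parametrize("seed", range(4))
def test_weighted_mode_matches_fine_grid_oracle(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(4, 12))
    gamma = rng.uniform(0.01, 0.05, k)
    Gamma = rng.normal(0.1 * gamma, 0.01)
    sG = rng.uniform(0.005, 0.02, k)
    ratios = Gamma / gamma
    w = (gamma / sG) ** 2
    w = w / w.sum()
    hmode = silverman_bandwidth(ratios)
    e = weighted_mode(make_harmonized(gamma, np.full(k, 1e-3), Gamma, sG),
                      n_boot=10, seed=0)
    span = ratios.max() - ratios.min() + 6 * hmode
    assert e.theta == pytest.approx(_mode_oracle(ratios, w, hmode),
                                    abs=span / 100_000)


def test_weighted_mode_bandwidth_merges_clusters():
    """Growing the bandwidth factor moves the mode from the majority
    cluster toward the weighted grand mean on a two-cluster fixture."""
    gamma = np.ones(6)
    Gamma = np.array([0.0, 0.01, -0.01, 1.0, 1.02, 0.98])
    sG = np.array([0.05, 0.05, 0.05, 0.08, 0.08, 0.08])
    hs = make_harmonized(gamma, np.full(6, 1e-6), Gamma, sG)
    w = (gamma / sG) ** 2
    grand = np.sum(w * Gamma) / w.sum()
    thetas = [weighted_mode(hs, bandwidth_factor=phi, n_boot=5, seed=0).theta
              for phi in (1.0, 1.5, 2.0, 2.5)]
    dists = [abs(t - grand) for t in thetas]
    assert dists == sorted(dists, reverse=True)


def test_weighted_mode_zero_bandwidth_fallback():
    hs = make_harmonized([1, 1, 1, 1], [1e-6] * 4, [0.2, 0.2, 0.2, 0.2],
                         [0.1, 0.1, 0.1, 0.2])
    e = weighted_mode(hs, n_boot=5, seed=0)
    assert e.theta == pytest.approx(0.2)


# -- leave-one-out ------------------------------------------------------------

def test_leave_one_out_identical_instruments():
    hs = [_h(snp=f"rs{i}") for i in range(4)]
    loo = leave_one_out(hs)
    assert len(loo) == 4
    assert np.allclose(loo["theta"], 0.2)


def test_leave_one_out_flags_planted_outlier(simple_instruments):
    hs = list(simple_instruments)
    h = hs[3]
    hs[3] = HarmonizedInstrument(h.snp_id, h.gamma, h.se_gamma,
                                 h.Gamma + 0.05, h.se_Gamma)
    full = ivw(hs).theta
    loo = leave_one_out(hs)
    shifts = (loo["theta"] - full).abs()
    assert shifts.idxmax() == h.snp_id


def test_leave_one_out_cardinality():
    hs = [_h(snp=f"rs{i}", Gamma=0.02 + 0.001 * i) for i in range(3)]
    assert len(leave_one_out(hs)) == 3


# -- MR-PRESSO ----------------------------------------------------------------

def test_presso_detects_planted_outlier():
    scen = SyntheticScenario(k=14, theta=0.2, seed=5,
                             pleiotropy=("outlier", 3, 10.0))
    exp, out, truth = simulate_sumstats(scen)
    hs = (exp["snp_id"].to_numpy(), exp["beta"].to_numpy(),
          exp["se"].to_numpy(), out["beta"].to_numpy(),
          out["se"].to_numpy())
    res = mr_presso(hs, n_sim=500, seed=1)
    assert truth["snp_ids"][3] in res.outliers
    assert res.global_p < 0.05
    # outlier-corrected IVW never increases Q
    q_before = ivw(hs).extras["Q"]
    assert res.corrected.extras["Q"] <= q_before + 1e-9


def test_presso_clean_under_null():
    scen = SyntheticScenario(k=14, theta=0.2, seed=6)
    exp, out, _ = simulate_sumstats(scen)
    hs = (exp["snp_id"].to_numpy(), exp["beta"].to_numpy(),
          exp["se"].to_numpy(), out["beta"].to_numpy(), out["se"].to_numpy())
    res = mr_presso(hs, n_sim=500, seed=2)
    assert res.outliers == []
    assert res.corrected is None


def test_presso_needs_four_instruments():
    with pytest.raises(ValueError):
        mr_presso([_h(snp=f"rs{i}") for i in range(3)], n_sim=200, seed=0)


# -- overlap bias, Bonferroni, reverse ---------------------------------------

def test_overlap_bias_values():
    bias, verdict = overlap_bias(0.45, 71.15)
    assert bias == pytest.approx(0.0063, abs=2e-4)
    assert verdict == "negligible"
    assert overlap_bias(0.0, 50.0)[0] == 0.0
    bias2, verdict2 = overlap_bias(1.0, 10.0)
    assert bias2 == pytest.approx(0.1) and verdict2 == "non-negligible"
    with pytest.raises(ValueError):
        overlap_bias(1.5, 50.0)


def test_bonferroni_eight_outcomes():
    flags, thr = bonferroni([0.0059, 0.0063, 0.2, 0.5, 0.9, 0.1, 0.04, 0.7])
    assert thr == pytest.approx(0.00625)
    assert flags[0] and not flags[1]
    # boundary: exactly at the threshold is not significant
    flags2, _ = bonferroni([0.00625] + [1.0] * 7)
    assert not flags2[0]


def test_reverse_mr_branches():
    bw = [variant(snp_id=f"rs{i}", beta=0.01, se=0.02, pval=0.5)
          for i in range(3)]
    # one genome-wide-significant disorder SNP -> Wald ratio branch
    disorder = [variant(snp_id="rs0", beta=0.1, se=0.01, pval=1e-9),
                variant(snp_id="rs1", beta=0.01, se=0.01, pval=0.3)]
    e = reverse_mr(disorder, bw)
    assert e.method == "wald_ratio" and e.nsnp == 1
    # no significant SNPs -> not testable
    none = reverse_mr([variant(pval=0.5)], bw)
    assert none.method == "not_testable" and none.nsnp == 0
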