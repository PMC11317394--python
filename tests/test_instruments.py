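"""Instrument selection, specificity calls, enrichment and strength stats."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trophomr.instruments import (ConfigurationError, GeneAnnotation,
                                  SpecificityCall, annotate_chromatin,
                                  call_specificity, compute_f, compute_r2,
                                  enrichment_table, enrichment_test,
                                  genes_in_window, mean_f,
                                  select_instruments, select_instruments_go)
from trophomr.sumstats import VariantAssociation

from conftest import variant


# -- gene windows -----------------------------------------------------------

def test_genes_in_window_distances():
    snp = variant(pos=1_000_000)
    genes = [
        GeneAnnotation("inwin", "1", 1_100_000, 1_120_000),
        GeneAnnotation("outwin", "1", 1_160_001, 1_200_000),
        GeneAnnotation("inside", "1", 990_000, 1_010_000),
        GeneAnnotation("otherchrom", "2", 1_000_000, 1_010_000),
    ]
    hits = dict(genes_in_window(snp, genes))
    assert hits == {"inwin": 100_000, "inside": 0}


def test_genes_in_window_pappa(packaged_records, packaged_annot):
    genes, _, _ = packaged_annot
    snp = next(r for r in packaged_records if r.snp_id == "rs1323438")
    hits = dict(genes_in_window(snp, genes))
    assert hits["PAPPA"] == 0


# -- specificity ------------------------------------------------------------

def _expr(**rows):
    cols = ["SCT", "EVT", "VCT"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def test_cell_specific_fivefold():
    calls = call_specificity(_expr(g=[10.0, 2.0, 2.0]))
    assert calls["g"].category == "cell_specific"
    assert calls["g"].cell_types == frozenset({"SCT"})


def test_below_expression_threshold_not_specific():
    calls = call_specificity(_expr(g=[0.8, 0.1, 0.0]))
    assert calls["g"].category == "not_specific"


def test_group_specific_two_cells():
    calls = call_specificity(_expr(g=[10.0, 10.0, 1.0]))
    assert calls["g"].category == "group_specific"
    assert calls["g"].cell_types == frozenset({"SCT", "EVT"})


def test_cell_enhanced_vs_mean():
    # not 5x each other cell (4 < 5*0.9); the group rule is blocked by the
    # second cell sitting below the expression threshold; but
    # 4 >= 5 * mean(0.9, 0.1) = 2.5
    calls = call_specificity(_expr(g=[4.0, 0.9, 0.1]))
    assert calls["g"].category == "cell_enhanced"
    assert calls["g"].cell_types == frozenset({"SCT"})


def test_single_cell_type_is_config_error():
    with pytest.raises(ConfigurationError):
        call_specificity(pd.DataFrame({"only": [1.0]}, index=["g"]))


# -- enrichment -------------------------------------------------------------

def _calls_for(specific, cell="SCT"):
    return {g: SpecificityCall(g, "cell_specific", frozenset([cell]), 10.0)
            for g in specific}


def test_enrichment_worked_example():
    universe = [f"g{i}" for i in range(20)]
    specific = universe[:5]
    query = universe[:3] + [universe[10]]  # 3 of 4 specific
    calls = _calls_for(specific)
    calls.update({g: SpecificityCall(g, "not_specific")
                  for g in universe[5:]})
    res = enrichment_test(query, calls, universe, "SCT")
    assert res.p_value == pytest.approx(155 / 4845, rel=1e-9)
    assert res.fold_change == pytest.approx(3.0)
    assert res.overlap == 3


def test_enrichment_zero_overlap_and_identity():
    universe = [f"g{i}" for i in range(10)]
    calls = _calls_for(universe[:4])
    none = enrichment_test(universe[4:8], calls, universe, "SCT")
    assert none.p_value == pytest.approx(1.0)
    assert none.fold_change == 0.0
    ident = enrichment_test(universe[:4], calls, universe[:4], "SCT")
    assert ident.p_value == pytest.approx(1.0)
    assert ident.fold_change == pytest.approx(1.0)


def test_enrichment_empty_inputs_raise():
    with pytest.raises(ValueError):
        enrichment_test([], _calls_for(["g1"]), ["g1"], "SCT")


@pytest.mark.parametrize("M,K,N", [(20, 5, 4), (25, 8, 6), (12, 3, 5)])
def test_enrichment_matches_exhaustive_enumeration(M, K, N):
    """Hypergeometric upper tail equals exact enumeration over all draws."""
    universe = [f"g{i}" for i in range(M)]
    specific = set(universe[:K])
    calls = _calls_for(specific)
    n_spec = min(N - 1, K)
    query = universe[:n_spec] + universe[K:K + N - n_spec]
    obs = len(set(query) & specific)
    res = enrichment_test(query, calls, universe, "SCT")
    count = sum(
        1 for draw in itertools.combinations(universe, N)
        if len(set(draw) & specific) >= obs
    )
    assert res.p_value == pytest.approx(count / math.comb(M, N), rel=1e-9)


# -- strength statistics ----------------------------------------------------

@pytest.mark.parametrize(
    "beta,maf,expected",
    [(0.0154, 0.4602, 1.18e-4), (-0.0219, 0.4732, 2.39e-4), (0.0, 0.3, 0.0)],
)
def test_compute_r2(beta, maf, expected):
    r2 = compute_r2(beta, maf)
    if expected:
        assert float(f"{r2:.3g}") == pytest.approx(expected)
    else:
        assert r2 == 0.0


def test_compute_r2_domain():
    with pytest.raises(ValueError):
        compute_r2(0.1, 0.0)


def test_compute_f_per_snp():
    assert compute_f(3.90e-4, 423_683, 1) == pytest.approx(165.37, rel=1e-3)
    assert compute_f(1e-12, 1000, 1) == pytest.approx(0.0, abs=1e-6)
    with pytest.raises(ValueError):
        compute_f(1.0, 1000, 1)


def test_compute_f_overall_matches_per_snp_at_k1():
    assert compute_f(2e-4, 100_000, 1) == compute_f(2e-4, 100_000, k=1)


def test_compute_f_monotone_in_r2_and_n():
    assert compute_f(2e-4, 1e5) < compute_f(3e-4, 1e5) < compute_f(3e-4, 2e5)


def test_overall_f_fifteen_iv_set(packaged_table):
    tab, excl = packaged_table
    drop = set(excl["missing_everywhere"]) | set(excl["clumped"])
    sub = tab[~tab["snp_id"].isin(drop)]
    assert len(sub) == 15
    overall = compute_f(sub["r2"].sum(), 423_683, k=15)
    assert overall == pytest.approx(81.78, rel=1e-3)
    assert mean_f(sub["f_stat"]) == pytest.approx(81.56, rel=1e-3)


# -- selection --------------------------------------------------------------

def test_select_instruments_packaged(packaged_records, packaged_annot):
    genes, expr, _ = packaged_annot
    calls = call_specificity(expr)
    ivs = select_instruments(packaged_records, genes, calls)
    assert len(ivs) == 18
    by_id = {r.snp_id: r for r in ivs}
    # r2/F here are recomputed from beta and the panel EAF, so agreement
    # with the published F is only to ~1% (frequency provenance)
    assert by_id["rs222857"].f_stat == pytest.approx(165.37, rel=0.01)
    # sum of per-SNP r2 over any subset equals the overall r2 (conservation)
    sub = [by_id[s] for s in ("rs222857", "rs753381", "rs234864")]
    assert sum(r.r2 for r in sub) == pytest.approx(
        np.sum([r.r2 for r in sub]))


def test_select_instruments_threshold_zero(packaged_records, packaged_annot):
    genes, expr, _ = packaged_annot
    calls = call_specificity(expr)
    assert select_instruments(packaged_records, genes, calls,
                              p_threshold=0.0) == []


def test_select_instruments_monotone_in_threshold(packaged_records,
                                                  packaged_annot):
    genes, expr, _ = packaged_annot
    calls = call_specificity(expr)
    small = {r.snp_id for r in select_instruments(
        packaged_records, genes, calls, p_threshold=1e-16)}
    large = {r.snp_id for r in select_instruments(
        packaged_records, genes, calls, p_threshold=5e-8)}
    assert small <= large


def test_select_instruments_window_boundary():
    genes = [GeneAnnotation("edge", "1", 1_150_000, 1_200_000)]
    calls = _calls_for(["edge"])
    snp_at = variant(pos=1_000_000, fetal_effect=True)        # d = 150 000
    snp_in = variant(snp_id="rs2", pos=1_000_001,
                     fetal_effect=True)                        # d = 149 999
    assert select_instruments([snp_at], genes, calls) == []
    assert len(select_instruments([snp_in], genes, calls)) == 1


def test_select_requires_fetal_effect(packaged_records, packaged_annot):
    genes, expr, _ = packaged_annot
    calls = call_specificity(expr)
    import dataclasses
    nofetal = [dataclasses.replace(r, fetal_effect=False)
               for r in packaged_records]
    assert select_instruments(nofetal, genes, calls) == []


def test_select_instruments_go(packaged_records, packaged_annot):
    genes, expr, _ = packaged_annot
    gene_ids = sorted({g.gene_id for g in genes})
    # GO list covering all genes: equals significance-only selection
    all_go = select_instruments_go(packaged_records, genes, gene_ids)
    assert len(all_go) == 18
    # disjoint list selects nothing
    assert select_instruments_go(packaged_records, genes, ["NOPE"]) == []
    with pytest.raises(ConfigurationError):
        select_instruments_go(packaged_records, genes, [])
    # 11 SNPs near listed genes -> 11 instruments (fetal flag not required)
    listed = {"SLC2A1", "EFNA1", "PAPPA2", "SKP2", "HMGA1", "TEAD3", "GCM1",
              "IGF2BP3", "PAPPA", "TACC2", "ASCL2"}
    hits = select_instruments_go(packaged_records, genes, listed)
    assert len(hits) == 11


# -- chromatin --------------------------------------------------------------

def test_annotate_chromatin_basic():
    iv = select_instruments_go(
        [variant(pos=100, fetal_effect=True)],
        [GeneAnnotation("g", "1", 50, 150)], ["g"])
    bed = pd.DataFrame(dict(chrom=["1"], start=[0], end=[200],
                            state=["TssA"]))
    assert annotate_chromatin(iv, bed)[0].chromatin_state == "active"
    far = pd.DataFrame(dict(chrom=["1"], start=[500], end=[600],
                            state=["TssA"]))
    assert annotate_chromatin(iv, far)[0].chromatin_state == "unknown"
    quies = pd.DataFrame(dict(chrom=["1"], start=[0], end=[200],
                              state=["Quies"]))
    assert annotate_chromatin(iv, quies)[0].chromatin_state == "inactive"


def test_annotate_chromatin_packaged(packaged_records, packaged_annot):
    genes, expr, bed = packaged_annot
    calls = call_specificity(expr)
    ivs = annotate_chromatin(select_instruments(packaged_records, genes, calls),
                             bed)
    assert sum(r.chromatin_state == "active" for r in ivs) == 13


def test_annotate_chromatin_malformed_interval():
    bed = pd.DataFrame(dict(chrom=["1"], start=[200], end=[100],
                            state=["TssA"]))
    with pytest.raises(ValueError):
        annotate_chromatin([], bed)
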