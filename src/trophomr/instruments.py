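"""Instrument selection and strength statistics.

Instruments for the birth-weight exposure are genome-wide-significant SNPs
(p < 5e-8) whose effect is exerted through the fetal genome and which lie
within 150 kb of a gene with trophoblast-specific expression (villous
cytotrophoblast, syncytiotrophoblast or extravillous trophoblast) in
single-cell placental expression data.  Specificity of a gene for a cell
type follows a fivefold rule on mean expression with a minimum expression
threshold, in four tiers: specific to one cell, specific to a small group,
enhanced relative to the average of the other cells, or not specific.

Instrument strength per SNP is summarized by the variance explained,
R^2 = 2 beta^2 MAF (1 - MAF), and by the F statistic
F = R^2 (N - k - 1) / (1 - R^2) with k = 1 per SNP or k = #IVs for the
overall instrument (R^2 then being the sum of per-SNP values).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats import VariantAssociation

CATEGORIES = ("cell_specific", "group_specific", "cell_enhanced", "not_specific")


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneAnnotation:
    """A coding gene's span; 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass
class SpecificityCall:
    """Cell-type specificity category for one gene."""

    gene_id: str
    category: str
    cell_types: frozenset = frozenset()
    max_expression: float = 0.0

    @property
    def is_specific(self) -> bool:
        return self.category != "not_specific"


@dataclass
class InstrumentRecord:
    """A selected instrumental variable with annotation and strength stats."""

    variant: VariantAssociation
    genes_in_window: list = field(default_factory=list)
    trophoblast_genes: list = field(default_factory=list)
    chromatin_state: str = "unknown"
    r2: float = float("nan")
    f_stat: float = float("nan")

    @property
    def snp_id(self) -> str:
        return self.variant.snp_id


def genes_in_window(
    snp: VariantAssociation,
    genes: Iterable[GeneAnnotation],
    half_width: int = 150_000,
) -> list[tuple[str, int]]:
    """Genes whose span intersects ``[pos - half_width, pos + half_width]``.

    Distance is 0 when the SNP lies inside the gene body, else the distance
    to the nearest gene edge.  Sorted by distance then gene id.
    """
    hits = []
    for g in genes:
        if g.chrom != snp.chrom:
            continue
        if g.end < snp.pos - half_width or g.start > snp.pos + half_width:
            continue
        if g.start <= snp.pos <= g.end:
            d = 0
        else:
            d = min(abs(snp.pos - g.start), abs(snp.pos - g.end))
        hits.append((g.gene_id, d))
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def call_specificity(
    expr: pd.DataFrame,
    fold: float = 5.0,
    expr_threshold: float = 1.0,
    max_group_size: int = 4,
) -> dict[str, SpecificityCall]:
    """Classify genes by cell-type specificity of mean expression.

    ``expr`` is genes (rows) x cell types (columns), nonnegative mean
    expression.  A gene is ``cell_specific`` for cell ``c`` when
    ``expr >= expr_threshold`` in ``c`` and at least ``fold`` times the
    expression in every other cell; ``group_specific`` when a group of 2 to
    ``max_group_size`` cells jointly beats every cell outside the group by
    the same margin; ``cell_enhanced`` when a cell beats ``fold`` times the
    mean of all other cells.  The most stringent applicable category wins.
    """
    if expr.shape[1] < 2:
        raise ConfigurationError("specificity needs at least two cell types")
    calls: dict[str, SpecificityCall] = {}
    cells = list(expr.columns)
    for gene, row in expr.iterrows():
        v = row.to_numpy(dtype=float)
        maxv = float(v.max())
        order = np.argsort(-v, kind="stable")  # descending
        call = SpecificityCall(gene, "not_specific", frozenset(), maxv)

        # cell_specific: top cell vs every other
        top = order[0]
        others = np.delete(v, top)
        if v[top] >= expr_threshold and np.all(v[top] >= fold * others):
            call = SpecificityCall(gene, "cell_specific",
                                   frozenset([cells[top]]), maxv)
        else:
            # group_specific: expression-descending prefixes of size 2..max
            found = None
            for m in range(2, min(max_group_size, len(cells) - 1) + 1):
                grp = order[:m]
                rest = order[m:]
                if np.all(v[grp] >= expr_threshold) and np.all(
                    v[grp].min() >= fold * v[rest]
                ):
                    found = frozenset(cells[i] for i in grp)
                    break
            if found is not None:
                call = SpecificityCall(gene, "group_specific", found, maxv)
            else:
                mean_others = (v.sum() - v[top]) / (len(v) - 1)
                if v[top] >= expr_threshold and v[top] >= fold * mean_others:
                    call = SpecificityCall(gene, "cell_enhanced",
                                           frozenset([cells[top]]), maxv)
        calls[gene] = call
    return calls


@dataclass
class EnrichmentResult:
    cell_type: str
    p_value: float
    adjusted_p: float
    fold_change: float
    overlap: int


def enrichment_test(
    query_genes: Iterable[str],
    calls: Mapping[str, SpecificityCall],
    universe: Iterable[str],
    cell_type: str,
) -> EnrichmentResult:
    """Hypergeometric enrichment of cell-type-specific genes in a query set.

    The adjusted p is Benjamini-Hochberg across all cell types appearing in
    ``calls`` (the family actually tested); use :func:`enrichment_table` for
    the full per-cell table.
    """
    table = enrichment_table(query_genes, calls, universe)
    row = table[table["cell_type"] == cell_type]
    if row.empty:
        raise ValueError(f"cell type {cell_type!r} not present in calls")
    r = row.iloc[0]
    return EnrichmentResult(cell_type, float(r["p_value"]), float(r["adjusted_p"]),
                            float(r["fold_change"]), int(r["overlap"]))


def enrichment_table(
    query_genes: Iterable[str],
    calls: Mapping[str, SpecificityCall],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Per-cell-type hypergeometric enrichment with BH adjustment."""
    query = set(query_genes)
    uni = set(universe)
    if not query or not uni:
        raise ValueError("query and universe must be nonempty")
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    cell_types = sorted(
        {ct for c in calls.values() if c.is_specific for ct in c.cell_types}
    )
    M, N = len(uni), len(query)
    rows = []
    for ct in cell_types:
        specific = {
            g for g, c in calls.items()
            if c.is_specific and ct in c.cell_types and g in uni
        }
        K = len(specific)
        k = len(specific & query)
        # upper tail: P(X >= k) for X ~ Hypergeom(M, K, N)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if k > 0 else 1.0
        fc = (k / N) / (K / M) if K > 0 else 0.0
        rows.append(dict(cell_type=ct, overlap=k, n_specific=K,
                         p_value=min(p, 1.0), fold_change=fc))
    table = pd.DataFrame(rows)
    if len(table):
        table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["adjusted_p"] = []
    return table


def compute_r2(beta: float, maf: float) -> float:
    """Variance explained by one SNP: ``2 beta^2 maf (1 - maf)``.

    Symmetric in ``maf`` vs ``1 - maf``, so the effect-allele frequency can
    be passed directly.
    """
    beta = np.asarray(beta, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("MAF must lie strictly in (0, 1)")
    out = 2.0 * beta**2 * maf * (1.0 - maf)
    return float(out) if out.ndim == 0 else out


def compute_f(r2: float, n: float, k: int = 1) -> float:
    """Instrument F statistic, ``F = (R2/k) (N - k - 1) / (1 - R2)``.

    With ``k = 1`` this is the per-SNP form ``R2 (N - 2) / (1 - R2)``; for
    the overall instrument pass ``k`` = number of IVs and ``r2`` = sum of
    per-SNP R2 values.
    """
    r2 = float(r2)
    if not 0.0 <= r2 < 1.0:
        raise ValueError("R2 must lie in [0, 1)")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return (r2 / k) * (n - k - 1) / (1.0 - r2)


def mean_f(f_stats: Sequence[float]) -> float:
    """Arithmetic mean of per-SNP F statistics."""
    return float(np.mean(np.asarray(f_stats, dtype=float)))


def _specific_gene_calls(calls: Mapping[str, SpecificityCall]) -> set[str]:
    return {g for g, c in calls.items() if c.is_specific}


def select_instruments(
    exposure: Iterable[VariantAssociation],
    genes: Iterable[GeneAnnotation],
    calls: Mapping[str, SpecificityCall],
    p_threshold: float = 5e-8,
    half_width: int = 150_000,
) -> list[InstrumentRecord]:
    """Main instrument selection: significance + fetal effect + proximity to
    a trophoblast-specific gene.

    Keeps SNPs with ``pval < p_threshold``, ``fetal_effect`` set, and at
    least one specifically-expressed gene within ``half_width``; attaches
    per-SNP R^2 and F.
    """
    genes = list(genes)
    specific = _specific_gene_calls(calls)
    out = []
    for snp in exposure:
        if snp.pval is None or not (snp.pval < p_threshold):
            continue
        if not snp.fetal_effect:
            continue
        window = genes_in_window(snp, genes, half_width)
        troph = [
            (g, sorted(calls[g].cell_types))
            for g, d in window
            if g in specific and d < half_width
        ]
        if not troph:
            continue
        out.append(_make_record(snp, window, troph))
    return out


def select_instruments_go(
    exposure: Iterable[VariantAssociation],
    genes: Iterable[GeneAnnotation],
    go_gene_ids: Iterable[str],
    p_threshold: float = 5e-8,
    half_width: int = 150_000,
) -> list[InstrumentRecord]:
    """Alternative selection by membership of nearby genes in a GO list
    (embryonic placenta development); significance + proximity only, the
    fetal-effect flag is not required."""
    go = set(go_gene_ids)
    if not go:
        raise ConfigurationError("GO gene list is empty")
    genes = list(genes)
    out = []
    for snp in exposure:
        if snp.pval is None or not (snp.pval < p_threshold):
            continue
        window = genes_in_window(snp, genes, half_width)
        hits = [(g, []) for g, d in window if g in go and d < half_width]
        if not hits:
            continue
        out.append(_make_record(snp, window, hits))
    return out


def _make_record(snp, window, troph) -> InstrumentRecord:
    r2 = f = float("nan")
    if snp.beta is not None and snp.eaf is not None:
        r2 = compute_r2(snp.beta, snp.eaf)
        if snp.n:
            f = compute_f(r2, snp.n, k=1)
    return InstrumentRecord(
        variant=snp, genes_in_window=window, trophoblast_genes=troph,
        r2=r2, f_stat=f,
    )


def annotate_chromatin(
    instruments: Iterable[InstrumentRecord],
    intervals: pd.DataFrame,
    active_states: Iterable[str] | None = None,
) -> list[InstrumentRecord]:
    """Assign active/inactive/unknown chromatin state from BED-like intervals.

    ``intervals`` has columns (chrom, start, end, state) with BED convention:
    0-based half-open.  States whose name starts with one of
    ``active_states`` (default: TssA, TssFlnk, Tx, Enh) count as active.
    """
    if active_states is None:
        active_states = ("TssA", "TssFlnk", "Tx", "Enh")
    active_states = tuple(active_states)
    iv = list(instruments)
    bad = intervals[intervals["start"] >= intervals["end"]]
    if len(bad):
        raise ValueError("malformed interval with start >= end")
    for rec in iv:
        pos0 = rec.variant.pos - 1  # 1-based SNP position -> 0-based
        sub = intervals[
            (intervals["chrom"].astype(str) == str(rec.variant.chrom))
            & (intervals["start"] <= pos0)
            & (pos0 < intervals["end"])
        ]
        if sub.empty:
            rec.chromatin_state = "unknown"
        else:
            state = str(sub.iloc[0]["state"])
            rec.chromatin_state = (
                "active" if state.startswith(active_states) else "inactive"
            )
    return iv


def instruments_to_frame(instruments: Iterable[InstrumentRecord]) -> pd.DataFrame:
    """Tabulate instrument records (one row per IV), mirroring the columns a
    reader of the instrument table expects."""
    rows = []
    for rec in instruments:
        v = rec.variant
        rows.append(
            dict(
                snp_id=v.snp_id, chrom=v.chrom, pos=v.pos, ea=v.effect_allele,
                oa=v.other_allele, eaf=v.eaf, beta=v.beta, se=v.se,
                pval=v.pval, n=v.n,
                trophoblast_genes=";".join(
                    f"{g}({','.join(cts)})" if cts else g
                    for g, cts in rec.trophoblast_genes
                ),
                nearest_gene=rec.genes_in_window[0][0] if rec.genes_in_window else "",
                chromatin_state=rec.chromatin_state,
                r2=rec.r2, f_stat=rec.f_stat,
            )
        )
    return pd.DataFrame(rows)
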