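"""Packaged instrument table for the birth-weight exposure.

The 18 instruments selected for the birth-weight -> psychiatric-outcome MR
analysis, with their hg38 positions, alleles (first allele is the effect
allele), European-panel effect-allele frequencies, birth-weight effects,
trophoblast-specific nearby genes with edge distances and cell types
(EVT = extravillous trophoblast, SCT = syncytiotrophoblast, VCT = villous
cytotrophoblast), chromatin activity in trophoblast cultured cells, and the
published per-SNP variance explained (R^2) and F statistics.  The exposure
GWAS sample size is 423,683 and every packaged SNP acts through the fetal
genome.

Alongside the table this module packages the per-outcome instrument
attrition: one SNP (and its proxies) absent from every outcome GWAS, the
outcome-specific absences for depression and ADHD, and the two SNPs removed
by LD clumping in all analyses, together with a small LD table encoding
those clumping relationships and the published proxy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .harmonize import LDTable
from .instruments import GeneAnnotation, InstrumentRecord, SpecificityCall
from .sumstats import VariantAssociation

#: exposure GWAS sample size
N_EXPOSURE = 423_683

# snp_id, chrom, pos, ea, oa, eaf, beta, se, pval,
# [(trophoblast gene, distance, (cell types,))], nearest gene, active, r2, f
_ROWS = [
    ("rs12401656", "1", 42991096, "A", "G", 0.1272, -0.0277, 0.0036, 2.4e-14,
     [("SLC2A1", 32228, ("SCT",))], "SLC2A1", True, 1.78e-4, 75.51),
    ("rs141845046", "1", 155015228, "T", "C", 0.0298, 0.0746, 0.008, 1.6e-20,
     [("EFNA1", 112648, ("EVT", "SCT"))], "ZBTB7B", True, 2.89e-4, 122.67),
    ("rs10913200", "1", 176552519, "A", "G", 0.0229, -0.0552, 0.0078, 1.4e-12,
     [("PAPPA2", 0, ("EVT",))], "PAPPA2", False, 1.48e-4, 62.53),
    ("rs12656216", "5", 36160566, "G", "A", 0.2247, -0.0196, 0.003, 7.4e-11,
     [("SKP2", 0, ("EVT", "VCT"))], "SKP2", True, 1.29e-4, 54.56),
    ("rs75104038", "6", 34222327, "A", "G", 0.0447, 0.0465, 0.0053, 2.9e-18,
     [("HMGA1", 14546, ("VCT",))], "HMGA1", True, 2.20e-4, 93.42),
    ("rs7771453", "6", 35530855, "G", "A", 0.2097, 0.0243, 0.003, 3.9e-16,
     [("TEAD3", 33776, ("SCT",))], "TULP1", True, 2.05e-4, 87.05),
    ("rs577204588", "6", 53156939, "C", "T", 0.0010, -0.1535, 0.0234, 5.8e-11,
     [("GCM1", 8098, ("EVT", "SCT"))], "GCM1", True, 2.48e-4, 105.09),
    ("rs34776209", "7", 23473474, "T", "C", 0.2386, -0.0239, 0.0029, 6.9e-17,
     [("IGF2BP3", 2983, ("VCT",))], "IGF2BP3", True, 2.07e-4, 87.67),
    ("rs1323438", "9", 116353252, "T", "C", 0.2724, -0.0203, 0.0027, 1.3e-13,
     [("PAPPA", 0, ("EVT",))], "PAPPA", True, 1.70e-4, 72.06),
    ("rs2901307", "10", 122368927, "C", "T", 0.5328, -0.0213, 0.0025, 5.6e-18,
     [("TACC2", 114385, ("SCT",))], "PLEKHA1", False, 2.27e-4, 96.04),
    ("rs1011476", "11", 2277805, "T", "G", 0.2465, 0.0179, 0.0027, 4e-11,
     [("ASCL2", 7217, ("EVT",))], "ASCL2", False, 1.30e-4, 55.15),
    ("rs234864", "11", 2836067, "G", "A", 0.4523, -0.0169, 0.0025, 1.2e-11,
     [("CDKN1C", 47146, ("EVT", "SCT")),
      ("PHLDA2", 92206, ("EVT", "SCT", "VCT"))], "KCNQ1", True, 1.42e-4, 60.22),
    ("rs4444073", "11", 10310114, "C", "A", 0.4732, -0.0219, 0.0024, 2.8e-19,
     [("ADM", 2722, ("EVT",))], "ADM", False, 2.39e-4, 101.39),
    ("rs12584892", "13", 73050396, "T", "C", 0.1710, -0.0196, 0.0032, 1.3e-9,
     [("KLF5", 4580, ("VCT",))], "KLF5", False, 1.14e-4, 48.30),
    ("rs222857", "17", 7261244, "C", "T", 0.4205, -0.0282, 0.0025, 2.2e-30,
     [("CLDN7", 0, ("EVT", "SCT", "VCT"))], "CLDN7", True, 3.90e-4, 165.37),
    ("rs41355649", "19", 33299650, "A", "G", 0.0646, -0.0366, 0.0051, 5e-13,
     [("CEBPA", 284, ("SCT",))], "CEBPA", True, 1.63e-4, 69.09),
    ("rs753381", "20", 41168825, "T", "C", 0.4602, 0.0154, 0.0024, 2.8e-10,
     [("TOP1", 44338, ("SCT",))], "PLCG1", True, 1.18e-4, 49.89),
    ("rs220193", "21", 42161198, "A", "G", 0.2346, 0.021, 0.003, 1.5e-12,
     [("ABCG1", 38491, ("SCT",))], "UMODL1", True, 1.53e-4, 64.76),
]

#: per-outcome instrument attrition
EXCLUSIONS = {
    # absent (with all proxies) from every outcome GWAS
    "missing_everywhere": ["rs577204588"],
    # outcome-specific absences
    "missing_by_outcome": {
        "depression": ["rs141845046"],
        "adhd": ["rs10913200", "rs41355649"],
    },
    # removed by LD clumping in all analyses
    "clumped": ["rs7771453", "rs1011476"],
}

#: published proxy relationship: rs73024215 tags rs41355649 at r2 = 0.87
PROXY_R2 = {("rs41355649", "rs73024215"): 0.87}


def packaged_instrument_table() -> tuple[pd.DataFrame, dict]:
    """The packaged instrument table and the per-outcome exclusion lists.

    Columns: snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n,
    fetal_effect, trophoblast genes/distances/cell types, nearest_gene,
    active chromatin flag, and the published r2 and f_stat.
    """
    rows = []
    for (snp, chrom, pos, ea, oa, eaf, beta, se, pval, genes, nearest,
         active, r2, f) in _ROWS:
        rows.append(dict(
            snp_id=snp, chrom=chrom, pos=pos, ea=ea, oa=oa, eaf=eaf,
            beta=beta, se=se, pval=pval, n=N_EXPOSURE, fetal_effect=True,
            trophoblast_genes=";".join(g for g, _, _ in genes),
            gene_distances=";".join(str(d) for _, d, _ in genes),
            cell_types=";".join(",".join(c) for _, _, c in genes),
            nearest_gene=nearest, active_chromatin=bool(active),
            r2=r2, f_stat=f,
        ))
    return pd.DataFrame(rows), {k: (dict(v) if isinstance(v, dict) else list(v))
                                for k, v in EXCLUSIONS.items()}


def outcome_iv_ids(outcome: str | None = None) -> list[str]:
    """Instrument ids surviving attrition for one outcome ("depression",
    "adhd", or any other label for the common 15-IV set)."""
    drop = set(EXCLUSIONS["missing_everywhere"]) | set(EXCLUSIONS["clumped"])
    if outcome in EXCLUSIONS["missing_by_outcome"]:
        drop |= set(EXCLUSIONS["missing_by_outcome"][outcome])
    return [r[0] for r in _ROWS if r[0] not in drop]


def packaged_exposure_records() -> list[VariantAssociation]:
    """The instrument table as exposure summary-statistics records."""
    recs = []
    for (snp, chrom, pos, ea, oa, eaf, beta, se, pval, *_rest) in _ROWS:
        recs.append(VariantAssociation(
            snp_id=snp, chrom=chrom, pos=pos, effect_allele=ea,
            other_allele=oa, eaf=eaf, beta=beta, se=se, pval=pval,
            z=beta / se, n=N_EXPOSURE, fetal_effect=True,
            trait="birth_weight",
        ))
    return recs


def packaged_ld_table() -> LDTable:
    """LD table encoding the packaged clumping and proxy relationships.

    rs7771453 and rs1011476 are each in LD (r^2 > 0.001) with a more
    significant packaged instrument on the same chromosome, so greedy
    clumping removes exactly those two; rs73024215 proxies rs41355649 at
    r^2 = 0.87.  All other pairs are absent (treated as r^2 = 0).
    """
    pairs = pd.DataFrame(
        [
            ("rs75104038", "rs7771453", 0.12, 1),
            ("rs234864", "rs1011476", 0.05, 1),
            ("rs41355649", "rs73024215", 0.87, 1),
        ],
        columns=["snp_a", "snp_b", "r2", "phase"],
    )
    return LDTable(pairs)


def packaged_annotations() -> tuple[list[GeneAnnotation], pd.DataFrame, pd.DataFrame]:
    """Gene spans, a mean-expression matrix and a chromatin-state BED
    consistent with the packaged instrument table.

    Gene spans are synthetic stand-ins placed so that each trophoblast
    gene's edge distance to its SNP matches the packaged distance (genes at
    distance 0 span the SNP); expression values are synthetic, constructed
    so the packaged cell-type calls are exactly reproduced by the fivefold
    specificity rule; the BED tiles a 1 kb window around each SNP with an
    active (TssA) or inactive (Quies) state per the packaged flag.
    """
    genes: list[GeneAnnotation] = []
    expr_rows = {}
    bed_rows = []
    cell_cols = ["EVT", "SCT", "VCT", "Stromal", "Endothelial", "HofbauerCell"]
    for (snp, chrom, pos, _ea, _oa, _eaf, _beta, _se, _pval, gl, nearest,
         active, _r2, _f) in _ROWS:
        for gene, dist, cells in gl:
            if dist == 0:
                start, end = pos - 10_000, pos + 10_000
            else:
                start, end = pos + dist, pos + dist + 50_000
            genes.append(GeneAnnotation(gene, chrom, start, end))
            # specific expression: 10 in the listed cells, 0.5 elsewhere
            expr_rows[gene] = [10.0 if c in cells else 0.5 for c in cell_cols]
        if nearest not in expr_rows:
            genes.append(GeneAnnotation(nearest, chrom, max(pos - 5_000, 1),
                                        pos + 5_000))
            expr_rows[nearest] = [1.5] * len(cell_cols)  # broadly expressed
        state = "TssA" if active else "Quies"
        bed_rows.append(dict(chrom=chrom, start=pos - 500, end=pos + 500,
                             state=state))
    expr = pd.DataFrame.from_dict(expr_rows, orient="index",
                                  columns=cell_cols)
    bed = pd.DataFrame(bed_rows)
    return genes, expr, bed
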