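"""Reading, validation and completion of GWAS summary-statistics tables.

A summary-statistics table carries, per SNP, the marginal association with a
single trait: effect and other allele, effect-allele frequency (EAF), the
per-allele effect ``beta`` with its standard error, the association p-value,
the Z score and the sample size.  Real files disagree wildly on column names
and on which of these fields are present, so reading is column-map driven and
missing fields are reconstructed where the remaining ones determine them:

* ``beta`` from the Z score, ``beta = z / sqrt(2 p (1-p) (n + z^2))`` with
  ``p`` the effect-allele frequency and ``n`` the sample size;
* ``se`` from ``beta / z``;
* ``pval`` from the two-sided standard-normal tail of ``z``;
* ``z`` from ``beta / se``.

Records that carry neither ``(beta, se)`` nor ``(z, eaf, n)`` cannot be
completed and are dropped (with a logged count), as are records failing the
basic validity checks (EAF outside (0,1), non-positive SE, impossible
p-value or position, identical alleles).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order of a normalized summary-statistics table
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "z",
    "n", "fetal_effect",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Raised for unusable summary-statistics input or configuration."""


@dataclass
class VariantAssociation:
    """One SNP's summary-statistics record for one trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    beta: float | None = None
    se: float | None = None
    pval: float | None = None
    z: float | None = None
    n: float | None = None
    fetal_effect: bool = False
    trait: str | None = field(default=None, repr=False)

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G SNPs, whose strand cannot be told from alleles.

        Multi-character (indel) alleles are never palindromic.
        """
        a, b = self.effect_allele, self.other_allele
        if len(a) != 1 or len(b) != 1:
            return False
        return _COMPLEMENT.get(a) == b

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


def beta_from_z(z, p, n):
    """Effect size reconstructed from a Z score.

    ``beta = z / sqrt(2 p (1-p) (n + z^2))`` for effect-allele frequency
    ``p`` and sample size ``n``; the trait is taken as variance-standardized.
    Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("effect-allele frequency must lie strictly in (0, 1)")
    if np.any(n <= 0):
        raise ValueError("sample size must be positive")
    out = z / np.sqrt(2.0 * p * (1.0 - p) * (n + z**2))
    return float(out) if out.ndim == 0 else out


def se_from_beta_z(beta, z):
    """Standard error reconstructed as ``beta / z``; undefined at ``z = 0``."""
    beta = np.asarray(beta, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z == 0):
        raise ValueError("SE from beta/z is undefined at z = 0; drop the record")
    out = beta / z
    return float(out) if out.ndim == 0 else out


def _autodetect_sep(path) -> str | None:
    # let pandas' python engine sniff when not configured
    return None


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into canonical form.

    ``column_map`` maps canonical names (see :data:`CANONICAL_COLUMNS`) to the
    file's column names; canonical names already present in the file need not
    be mapped.  At least ``snp_id``, ``effect allele`` (``ea``) and ``other
    allele`` (``oa``) must resolve, together with one of ``beta+se`` or
    ``z+eaf+n``.  Gzipped input is accepted.  Invalid rows are dropped with a
    logged count; missing derivable fields are completed.
    """
    column_map = dict(column_map or {})
    import csv

    try:
        if delimiter is None:
            raw = pd.read_csv(path, sep=None, engine="python", compression="infer")
        else:
            raw = pd.read_csv(path, sep=delimiter, compression="infer")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise SumstatsError(f"empty or unparseable summary-statistics file: "
                            f"{path}") from exc
    if raw.empty:
        raise SumstatsError(f"no data rows in summary-statistics file: {path}")

    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
    df = raw.rename(columns=rename)
    df = df[[c for c in CANONICAL_COLUMNS if c in df.columns]].copy()

    for required in ("snp_id", "ea", "oa"):
        if required not in df.columns:
            raise SumstatsError(
                f"required column {required!r} not resolvable via column map"
            )
    has_beta = {"beta", "se"}.issubset(df.columns)
    has_z = {"z", "eaf", "n"}.issubset(df.columns)
    if not (has_beta or has_z):
        raise SumstatsError(
            "need either beta+se or z+eaf+n columns to be resolvable"
        )
    return normalize_sumstats(df, trait_label=trait_label)


def normalize_sumstats(df: pd.DataFrame, trait_label: str | None = None) -> pd.DataFrame:
    """Validate, complete and canonicalize an in-memory summary table.

    Returns a new DataFrame with the canonical columns (those present),
    upper-cased alleles, completed ``beta``/``se``/``z``/``pval`` where
    derivable, and invalid rows dropped.
    """
    df = df.copy()
    for col in ("eaf", "beta", "se", "pval", "z", "n", "pos"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("ea", "oa"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    if "fetal_effect" in df.columns:
        df["fetal_effect"] = df["fetal_effect"].astype(bool)

    n0 = len(df)
    ok = pd.Series(True, index=df.index)
    ok &= df["snp_id"].notna() & (df["ea"] != df["oa"])
    if "eaf" in df.columns:
        ok &= df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    if "se" in df.columns:
        ok &= df["se"].isna() | (df["se"] > 0)
    if "pval" in df.columns:
        ok &= df["pval"].isna() | ((df["pval"] > 0) & (df["pval"] <= 1))
    if "pos" in df.columns:
        ok &= df["pos"].isna() | (df["pos"] >= 1)
    if "n" in df.columns:
        ok &= df["n"].isna() | (df["n"] > 0)
    df = df[ok]

    # complete derivable fields
    if "beta" not in df.columns:
        df["beta"] = np.nan
    if "se" not in df.columns:
        df["se"] = np.nan
    if "z" not in df.columns:
        df["z"] = np.nan

    can_beta = df["beta"].isna() & df["z"].notna()
    if {"eaf", "n"}.issubset(df.columns):
        can_beta &= df["eaf"].notna() & df["n"].notna()
        if can_beta.any():
            sub = df.loc[can_beta]
            df.loc[can_beta, "beta"] = beta_from_z(sub["z"], sub["eaf"], sub["n"])
    can_se = df["se"].isna() & df["beta"].notna() & df["z"].notna() & (df["z"] != 0)
    if can_se.any():
        sub = df.loc[can_se]
        df.loc[can_se, "se"] = se_from_beta_z(sub["beta"], sub["z"])
    can_z = df["z"].isna() & df["beta"].notna() & df["se"].notna()
    if can_z.any():
        sub = df.loc[can_z]
        df.loc[can_z, "z"] = sub["beta"] / sub["se"]
    if "pval" not in df.columns:
        df["pval"] = np.nan
    can_p = df["pval"].isna() & df["z"].notna()
    if can_p.any():
        df.loc[can_p, "pval"] = 2.0 * stats.norm.sf(np.abs(df.loc[can_p, "z"]))

    # a usable record has beta and se after completion
    usable = df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    df = df[usable]
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d invalid/incomplete summary-statistics rows", dropped)

    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    df = df[cols].reset_index(drop=True)
    if trait_label is not None:
        df.attrs["trait"] = trait_label
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a normalized table as TSV with canonical column names."""
    df.to_csv(path, sep="\t", index=False)


def to_records(df: pd.DataFrame) -> list[VariantAssociation]:
    """Convert a canonical table to a list of :class:`VariantAssociation`."""
    recs = []
    trait = df.attrs.get("trait")
    for row in df.itertuples(index=False):
        d = row._asdict()
        recs.append(
            VariantAssociation(
                snp_id=str(d["snp_id"]),
                effect_allele=d["ea"],
                other_allele=d["oa"],
                chrom=str(d["chrom"]) if d.get("chrom") is not None else None,
                pos=int(d["pos"]) if d.get("pos") is not None and not _isnan(d.get("pos")) else None,
                eaf=_opt(d.get("eaf")),
                beta=_opt(d.get("beta")),
                se=_opt(d.get("se")),
                pval=_opt(d.get("pval")),
                z=_opt(d.get("z")),
                n=_opt(d.get("n")),
                fetal_effect=bool(d.get("fetal_effect", False)),
                trait=trait,
            )
        )
    return recs


def _isnan(x) -> bool:
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return x is None


def _opt(x) -> float | None:
    if x is None or _isnan(x):
        return None
    return float(x)


def from_records(records: Iterable[VariantAssociation]) -> pd.DataFrame:
    """Inverse of :func:`to_records`."""
    rows = []
    for r in records:
        rows.append(
            dict(
                snp_id=r.snp_id, chrom=r.chrom, pos=r.pos, ea=r.effect_allele,
                oa=r.other_allele, eaf=r.eaf, beta=r.beta, se=r.se,
                pval=r.pval, z=r.z, n=r.n, fetal_effect=r.fetal_effect,
            )
        )
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
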