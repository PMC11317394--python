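"""Allele harmonization, LD proxies and clumping for two-sample MR.

Exposure and outcome summary statistics must refer each SNP's effects to the
same allele before any causal estimate is formed.  Four situations arise:
the outcome record matches the exposure's alleles in order (kept), in
swapped order (outcome effect negated, frequency complemented), only after
strand complementation (A<->T, C<->G), or not at all (dropped).  Palindromic
SNPs (A/T or C/G) carry no strand information in their alleles; they are
dropped outright when the minor-allele frequency exceeds a cutoff (default
0.4, where frequency is uninformative) and otherwise oriented by allele-
frequency concordance between the two studies.

Instruments absent from an outcome GWAS may be replaced by an LD proxy
(maximal r^2 above a floor, default 0.8, within a basepair window), and the
final instrument set is clumped to approximate independence: SNPs are
accepted in order of exposure significance, each required to have
r^2 <= 0.001 (default) with every SNP already accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sumstats import VariantAssociation

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement_allele(a: str) -> str:
    return "".join(_COMPLEMENT.get(b, b) for b in reversed(a)) if len(a) > 1 \
        else _COMPLEMENT.get(a, a)


@dataclass
class HarmonizedInstrument:
    """Exposure/outcome effect pair referenced to a shared effect allele.

    ``gamma``/``se_gamma`` are the SNP-exposure association and its SE,
    ``Gamma``/``se_Gamma`` the SNP-outcome association, after alignment.
    ``action`` records what harmonization did.
    """

    snp_id: str
    gamma: float
    se_gamma: float
    Gamma: float | None
    se_Gamma: float | None
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    action: str = "kept"

    @property
    def usable(self) -> bool:
        return self.action in ("kept", "flipped", "strand_flipped", "proxied")


def harmonize_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    palindromic_maf_cut: float = 0.4,
) -> HarmonizedInstrument:
    """Align one outcome record to the exposure's effect allele.

    Palindromic SNPs are dropped when min(eaf, 1-eaf) exceeds
    ``palindromic_maf_cut`` on either side, else oriented so that the
    effect-allele frequencies agree in direction across studies.
    """
    if exp.snp_id != out.snp_id:
        raise ValueError("harmonize_pair requires matching snp_id")

    base = dict(
        snp_id=exp.snp_id, gamma=exp.beta, se_gamma=exp.se,
        eaf_exposure=exp.eaf,
    )

    def result(action, Gamma=None, se_Gamma=None, eaf_out=None):
        return HarmonizedInstrument(
            Gamma=Gamma, se_Gamma=se_Gamma, eaf_outcome=eaf_out,
            action=action, **base,
        )

    ea, oa = exp.effect_allele, exp.other_allele
    bea, boa = out.effect_allele, out.other_allele

    if exp.is_palindromic:
        if {bea, boa} != {ea, oa}:
            return result("dropped_incompatible")
        for freq in (exp.eaf, out.eaf):
            if freq is not None and min(freq, 1 - freq) > palindromic_maf_cut:
                return result("dropped_palindromic")
        # nominal alignment by allele labels first
        Gamma, eaf_out, flipped = out.beta, out.eaf, False
        if bea == oa:  # written in swapped order
            Gamma = -Gamma if Gamma is not None else None
            eaf_out = 1 - eaf_out if eaf_out is not None else None
            flipped = True
        # frequency concordance decides the strand
        strand = False
        if exp.eaf is not None and eaf_out is not None:
            if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
                Gamma = -Gamma if Gamma is not None else None
                eaf_out = 1 - eaf_out if eaf_out is not None else None
                strand = True
        action = "strand_flipped" if strand else ("flipped" if flipped else "kept")
        return result(action, Gamma, out.se, eaf_out)

    # non-palindromic: try direct, swapped, then strand-complemented forms
    if (bea, boa) == (ea, oa):
        return result("kept", out.beta, out.se, out.eaf)
    if (bea, boa) == (oa, ea):
        return result("flipped", _neg(out.beta), out.se, _comp(out.eaf))
    cea, coa = _complement_allele(bea), _complement_allele(boa)
    if (cea, coa) == (ea, oa):
        return result("strand_flipped", out.beta, out.se, out.eaf)
    if (cea, coa) == (oa, ea):
        return result("strand_flipped", _neg(out.beta), out.se, _comp(out.eaf))
    return result("dropped_incompatible")


def _neg(x):
    return -x if x is not None else None


def _comp(x):
    return 1 - x if x is not None else None


def harmonize_tables(
    exposure: Iterable[VariantAssociation],
    outcome: Iterable[VariantAssociation],
    palindromic_maf_cut: float = 0.4,
) -> list[HarmonizedInstrument]:
    """Harmonize every exposure SNP found in the outcome collection.

    Exposure SNPs absent from the outcome are returned with action
    ``missing`` so callers can attempt proxy substitution.
    """
    out_by_id = {o.snp_id: o for o in outcome}
    res = []
    for e in exposure:
        o = out_by_id.get(e.snp_id)
        if o is None:
            res.append(HarmonizedInstrument(
                snp_id=e.snp_id, gamma=e.beta, se_gamma=e.se, Gamma=None,
                se_Gamma=None, eaf_exposure=e.eaf, action="missing",
            ))
        else:
            res.append(harmonize_pair(e, o, palindromic_maf_cut))
    return res


class LDTable:
    """Symmetric pairwise LD (r^2) lookup backed by a long-format table.

    Rows are (snp_a, snp_b, r2[, phase]); missing pairs are treated as
    r^2 = 0 with a single logged warning, matching the sparse local tables
    this package consumes in place of a reference-panel service.  The
    optional ``phase`` column carries +1/-1: +1 when the listed alleles of
    the two SNPs co-occur on the same haplotype in the same orientation.
    """

    def __init__(self, pairs: pd.DataFrame):
        self._r2: dict[tuple[str, str], float] = {}
        self._phase: dict[tuple[str, str], int] = {}
        has_phase = "phase" in pairs.columns
        for row in pairs.itertuples(index=False):
            a, b, r2 = str(row.snp_a), str(row.snp_b), float(row.r2)
            if not 0.0 <= r2 <= 1.0:
                raise ValueError("r2 must lie in [0, 1]")
            key = (min(a, b), max(a, b))
            self._r2[key] = r2
            if has_phase and not pd.isna(row.phase):
                self._phase[key] = int(row.phase)
        self._warned = False

    @classmethod
    def from_tsv(cls, path) -> "LDTable":
        return cls(pd.read_csv(path, sep="\t"))

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (min(a, b), max(a, b))
        if key not in self._r2:
            if not self._warned:
                logger.warning(
                    "LD pair (%s, %s) missing from table; this and further "
                    "missing pairs are treated as r2 = 0", a, b,
                )
                self._warned = True
            return 0.0
        return self._r2[key]

    def phase(self, a: str, b: str) -> int | None:
        if a == b:
            return 1
        return self._phase.get((min(a, b), max(a, b)))


def find_proxy(
    target: str,
    ld: LDTable,
    candidates: Iterable[VariantAssociation],
    r2_min: float = 0.8,
    window: int = 150_000,
    target_pos: int | None = None,
    target_chrom: str | None = None,
) -> VariantAssociation | None:
    """Best LD proxy for an instrument absent from the outcome data.

    Returns the candidate with maximal r^2 strictly above ``r2_min``
    (within ``window`` bp of ``target_pos`` when positions are known);
    ties break by smaller outcome p-value, then lexical snp_id.
    """
    best = None
    best_key = None
    for c in candidates:
        if c.snp_id == target:
            continue
        if (
            target_pos is not None and c.pos is not None
            and (target_chrom is None or str(c.chrom) == str(target_chrom))
            and abs(c.pos - target_pos) > window
        ):
            continue
        if target_pos is not None and c.pos is None:
            continue
        r2 = ld.r2(target, c.snp_id)
        if r2 <= r2_min:
            continue
        p = c.pval if c.pval is not None else 1.0
        key = (-r2, p, c.snp_id)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return best


def align_proxy(
    exp: VariantAssociation,
    proxy_out: VariantAssociation,
    ld: LDTable,
    palindromic_maf_cut: float = 0.4,
) -> HarmonizedInstrument:
    """Pair the exposure effect of a missing instrument with its proxy's
    outcome effect.

    Orientation uses the LD table's phase when present, else frequency
    concordance between the exposure EAF of the target and the outcome EAF
    of the proxy.  The result is labelled ``proxied``.
    """
    phase = ld.phase(exp.snp_id, proxy_out.snp_id)
    Gamma, eaf_out = proxy_out.beta, proxy_out.eaf
    if phase is not None:
        if phase < 0 and Gamma is not None:
            Gamma = -Gamma
            eaf_out = 1 - eaf_out if eaf_out is not None else None
    elif exp.eaf is not None and eaf_out is not None:
        if (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
            Gamma = -Gamma if Gamma is not None else None
            eaf_out = 1 - eaf_out
    return HarmonizedInstrument(
        snp_id=exp.snp_id, gamma=exp.beta, se_gamma=exp.se,
        Gamma=Gamma, se_Gamma=proxy_out.se, eaf_exposure=exp.eaf,
        eaf_outcome=eaf_out, action="proxied",
    )


def clump(
    snps: pd.DataFrame | Sequence[VariantAssociation],
    ld: LDTable,
    r2_max: float = 0.001,
) -> list[str]:
    """Greedy LD clumping by exposure significance.

    SNPs are visited in ascending exposure p-value (ties broken by lexical
    snp_id); each is retained iff its r^2 with every already-retained SNP is
    at most ``r2_max``.  Returns retained snp_ids in acceptance order.
    """
    if isinstance(snps, pd.DataFrame):
        items = [(str(r.snp_id), float(r.pval)) for r in snps.itertuples(index=False)]
    else:
        items = [(s.snp_id, s.pval if s.pval is not None else 1.0) for s in snps]
    items.sort(key=lambda t: (t[1], t[0]))
    kept: list[str] = []
    for snp_id, _ in items:
        if all(ld.r2(snp_id, k) <= r2_max for k in kept):
            kept.append(snp_id)
    return kept


def harmonized_to_frame(hs: Iterable[HarmonizedInstrument]) -> pd.DataFrame:
    rows = [
        dict(snp_id=h.snp_id, gamma=h.gamma, se_gamma=h.se_gamma,
             Gamma=h.Gamma, se_Gamma=h.se_Gamma, eaf_exposure=h.eaf_exposure,
             eaf_outcome=h.eaf_outcome, action=h.action)
        for h in hs
    ]
    return pd.DataFrame(rows)
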