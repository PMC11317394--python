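"""End-to-end orchestration: select -> harmonize -> estimate -> sensitivity
-> reverse -> report.

``run_forward`` carries an instrument set through per-outcome harmonization
(with proxy substitution and LD clumping), the main random-effects IVW
estimate, Bonferroni correction across outcomes, and — for outcomes passing
the corrected threshold (or always, with ``force_sensitivity``) — the full
sensitivity battery: leave-one-out, MR-Egger, MR-PRESSO, weighted median,
weighted mode at bandwidth factors 1, 2 and 2.5, and the sample-overlap
bias bound.  Every instrument dropped between stages is recorded exactly
once in an attrition log with its reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .harmonize import (LDTable, align_proxy, clump, find_proxy,
                        harmonize_tables, harmonized_to_frame)
from .instruments import compute_f, mean_f
from .model import MRModel
from .sumstats import VariantAssociation, read_sumstats, to_records

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class Thresholds:
    p_gws: float = 5e-8
    window: int = 150_000
    fold: float = 5.0
    expr: float = 1.0
    palindromic_maf: float = 0.4
    proxy_r2: float = 0.8
    clump_r2: float = 0.001
    alpha: float = 0.05


@dataclass
class AnalysisConfig:
    """File-driven configuration of a full analysis run."""

    exposure_path: str
    outcome_paths: Mapping[str, str]
    exposure_column_map: Mapping[str, str] = field(default_factory=dict)
    outcome_column_map: Mapping[str, str] = field(default_factory=dict)
    ld_path: str | None = None
    genes_path: str | None = None
    expression_path: str | None = None
    chromatin_path: str | None = None
    go_list_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    methods: Sequence[str] = ("ivw", "mr_egger", "weighted_median",
                              "weighted_mode")
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        thr = Thresholds(**raw.pop("thresholds", {}))
        missing = [k for k in ("exposure_path", "outcome_paths")
                   if k not in raw]
        if missing:
            raise ConfigurationError(f"config lacks required keys: {missing}")
        return cls(thresholds=thr, **raw)


@dataclass
class OutcomeResult:
    outcome: str
    harmonized: pd.DataFrame
    estimates: pd.DataFrame
    main: est.MREstimate
    attrition: list
    sensitivity: dict = field(default_factory=dict)


def _attrit(log, stage, snp_id, reason):
    log.append(dict(stage=stage, snp_id=snp_id, reason=reason))


def harmonize_outcome(
    instruments: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    ld: LDTable | None,
    thr: Thresholds,
) -> tuple[list, list]:
    """Harmonize one instrument set against one outcome table, with proxy
    substitution for missing SNPs and LD clumping.  Returns (usable
    harmonized instruments, attrition log)."""
    attrition = []
    hs = harmonize_tables(instruments, outcome, thr.palindromic_maf)
    by_id = {v.snp_id: v for v in instruments}
    usable = []
    for h in hs:
        if h.action == "missing":
            proxy = None
            if ld is not None:
                exp = by_id[h.snp_id]
                proxy = find_proxy(h.snp_id, ld, outcome,
                                   r2_min=thr.proxy_r2, window=thr.window,
                                   target_pos=exp.pos, target_chrom=exp.chrom)
            if proxy is None:
                _attrit(attrition, "harmonization", h.snp_id,
                        "absent from outcome GWAS (no proxy)")
                continue
            h = align_proxy(by_id[h.snp_id], proxy, ld, thr.palindromic_maf)
            logger.info("proxied %s by %s", h.snp_id, proxy.snp_id)
        if not h.usable:
            _attrit(attrition, "harmonization", h.snp_id, h.action)
            continue
        usable.append(h)
    if ld is not None and len(usable) > 1:
        pframe = pd.DataFrame(
            dict(snp_id=[h.snp_id for h in usable],
                 pval=[by_id[h.snp_id].pval for h in usable])
        )
        kept = set(clump(pframe, ld, r2_max=thr.clump_r2))
        for h in usable:
            if h.snp_id not in kept:
                _attrit(attrition, "clumping", h.snp_id,
                        f"LD r2 > {thr.clump_r2} with a more significant IV")
        usable = [h for h in usable if h.snp_id in kept]
    return usable, attrition


def sensitivity_battery(
    model: MRModel,
    seed: int = 0,
    overlap_rho: float | None = None,
    mean_f_value: float | None = None,
    mode_bandwidths: Sequence[float] = (1.0, 2.0, 2.5),
    n_boot: int = 1000,
    presso_sims: int = 1000,
) -> dict:
    """The full sensitivity suite for one significant outcome."""
    out: dict = {}
    out["leave_one_out"] = model.leave_one_out()
    egger = model.fit(method="mr_egger")
    out["mr_egger"] = egger
    out["weighted_median"] = model.fit(method="weighted_median",
                                       n_boot=n_boot, seed=seed)
    out["weighted_mode"] = {
        phi: model.fit(method="weighted_mode", bandwidth_factor=phi,
                       n_boot=n_boot, seed=seed)
        for phi in mode_bandwidths
    }
    if model.nsnp >= 4:
        out["mr_presso"] = model.presso(n_sim=presso_sims, seed=seed)
    if overlap_rho is not None and mean_f_value is not None:
        bias, verdict = est.overlap_bias(overlap_rho, mean_f_value)
        out["overlap_bias"] = dict(relative_bias=bias, verdict=verdict)
    return out


def run_forward(
    instruments: Sequence[VariantAssociation],
    outcomes: Mapping[str, Sequence[VariantAssociation]],
    ld: LDTable | None = None,
    thresholds: Thresholds | None = None,
    seed: int = 0,
    force_sensitivity: bool = False,
    run_sensitivity: bool = True,
    overlap_rho: Mapping[str, float] | None = None,
    out_dir=None,
    n_boot: int = 1000,
    presso_sims: int = 1000,
) -> dict:
    """Forward MR of the exposure on every outcome.

    Returns {"outcomes": {label: OutcomeResult}, "bonferroni_threshold",
    "significant": [labels]} and, when ``out_dir`` is given, writes a tidy
    results TSV, a JSON report and the attrition log.
    """
    thr = thresholds or Thresholds()
    results: dict[str, OutcomeResult] = {}
    for label, table in outcomes.items():
        usable, attrition = harmonize_outcome(instruments, table, ld, thr)
        if not usable:
            main = est.MREstimate("not_testable", float("nan"), float("nan"),
                                  float("nan"), float("nan"), float("nan"), 0)
            results[label] = OutcomeResult(label, pd.DataFrame(),
                                           pd.DataFrame([main.to_dict()]),
                                           main, attrition)
            continue
        model = MRModel.from_harmonized(usable)
        main = (model.fit(method="ivw").estimate if model.nsnp >= 2
                else est.wald_ratio(usable[0]))
        results[label] = OutcomeResult(
            label, harmonized_to_frame(usable),
            pd.DataFrame([main.to_dict()]), main, attrition,
        )

    labels = list(results)
    pvals = [results[l].main.pval for l in labels]
    testable = [not np.isnan(p) for p in pvals]
    flags, threshold = est.bonferroni(
        [p if ok else 1.0 for p, ok in zip(pvals, testable)],
        alpha=thr.alpha,
    )
    significant = [l for l, f, ok in zip(labels, flags, testable) if f and ok]

    for label in labels:
        if not run_sensitivity:
            break
        r = results[label]
        if r.main.nsnp < 3:
            continue
        if force_sensitivity or label in significant:
            model = MRModel.from_dataframe(r.harmonized)
            fbar = None
            rho = (overlap_rho or {}).get(label)
            if rho is not None:
                # mean per-SNP F from the harmonized exposure effects
                f = (model.gamma / model.se_gamma) ** 2
                fbar = float(np.mean(f))
            r.sensitivity = sensitivity_battery(
                model, seed=seed, overlap_rho=rho, mean_f_value=fbar,
                n_boot=n_boot, presso_sims=presso_sims,
            )

    bundle = dict(outcomes=results, bonferroni_threshold=threshold,
                  significant=significant)
    if out_dir is not None:
        _write_forward(bundle, out_dir)
    return bundle


def run_reverse(
    outcomes: Mapping[str, Sequence[VariantAssociation]],
    exposure_as_outcome: Sequence[VariantAssociation],
    ld: LDTable | None = None,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Reverse-direction MR for every outcome (disorder as exposure, birth
    weight as outcome); ``not_testable`` rows for outcomes without usable
    instruments."""
    thr = thresholds or Thresholds()
    rows = []
    for label, table in outcomes.items():
        e = est.reverse_mr(table, exposure_as_outcome,
                           p_threshold=thr.p_gws, ld=ld,
                           clump_r2=thr.clump_r2,
                           palindromic_maf_cut=thr.palindromic_maf)
        d = e.to_dict()
        d["outcome"] = label
        rows.append(d)
    return pd.DataFrame(rows).set_index("outcome")


def compute_iv_strength_summary(
    instruments: pd.DataFrame,
    exclusions: Mapping[str, Sequence[str]],
    n_exposure: float,
) -> pd.DataFrame:
    """Per-outcome instrument-strength summary from a packaged instrument
    table carrying per-SNP ``r2`` and ``f_stat``.

    ``exclusions`` maps outcome label -> snp_ids unavailable for that
    outcome (already including globally missing and clumped SNPs).  Overall
    F uses the summed R^2 with k = surviving count; mean F averages the
    per-SNP F statistics.
    """
    rows = []
    for label, dropped in exclusions.items():
        sub = instruments[~instruments["snp_id"].isin(set(dropped))]
        ksurv = len(sub)
        if ksurv == 0:
            rows.append(dict(outcome=label, k=0, overall_f=np.nan,
                             mean_f=np.nan, min_f=np.nan, max_f=np.nan))
            continue
        r2_sum = float(sub["r2"].sum())
        rows.append(dict(
            outcome=label, k=ksurv,
            overall_f=compute_f(r2_sum, n_exposure, k=ksurv),
            mean_f=mean_f(sub["f_stat"]),
            min_f=float(sub["f_stat"].min()),
            max_f=float(sub["f_stat"].max()),
        ))
    return pd.DataFrame(rows).set_index("outcome")


def _estimates_table(bundle) -> pd.DataFrame:
    rows = []
    for label, r in bundle["outcomes"].items():
        d = r.main.to_dict()
        d["outcome"] = label
        rows.append(d)
        for name, s in r.sensitivity.items():
            if name in ("mr_egger", "weighted_median"):
                d2 = s.estimate.to_dict()
            elif name == "weighted_mode":
                for phi, res in s.items():
                    d3 = res.estimate.to_dict()
                    d3["outcome"] = label
                    rows.append(d3)
                continue
            else:
                continue
            d2["outcome"] = label
            rows.append(d2)
            if name == "mr_egger" and s.intercept is not None:
                d4 = s.intercept.to_dict()
                d4["outcome"] = label
                rows.append(d4)
    return pd.DataFrame(rows)


def _write_forward(bundle, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = _estimates_table(bundle)
    table.to_csv(out_dir / "results.tsv", sep="\t", index=False)
    attr = [dict(outcome=label, **row)
            for label, r in bundle["outcomes"].items()
            for row in r.attrition]
    pd.DataFrame(attr, columns=["outcome", "stage", "snp_id", "reason"]) \
        .to_csv(out_dir / "attrition.tsv", sep="\t", index=False)
    report = dict(
        bonferroni_threshold=bundle["bonferroni_threshold"],
        significant=bundle["significant"],
        outcomes={
            label: dict(main=r.main.to_dict(),
                        n_attrition=len(r.attrition))
            for label, r in bundle["outcomes"].items()
        },
    )
    (out_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=float))
    forest = pd.DataFrame([
        dict(outcome=label, method=r.main.method, theta=r.main.theta,
             ci_low=r.main.ci_low, ci_high=r.main.ci_high,
             nsnp=r.main.nsnp)
        for label, r in bundle["outcomes"].items()
    ])
    forest.to_csv(out_dir / "forest.tsv", sep="\t", index=False)


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Effective N of a case-control GWAS, ``4 / (1/cases + 1/controls)``."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)
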