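"""Model/results interface over the MR estimator suite.

``MRModel`` holds a harmonized instrument set (SNP-exposure effects gamma
with SEs, SNP-outcome effects Gamma with SEs); ``fit`` dispatches to an
estimator and returns an ``MRResults`` carrying the estimate, its
uncertainty, heterogeneity diagnostics and a ``summary()`` table.
Sensitivity analyses (leave-one-out, MR-PRESSO, the full battery) hang off
the model.

Example
-------
>>> m = MRModel.from_dataframe(harmonized_df)
>>> res = m.fit()                    # random-effects IVW
>>> res.theta, res.conf_int()
>>> print(res.summary())
>>> m.fit(method="mr_egger").summary()
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import (EggerResult, HeterogeneityStats, MREstimate,
                         PressoResult)

_METHODS = ("ivw", "ivw_fixed", "mr_egger", "weighted_median",
            "weighted_mode", "wald_ratio")


class MRModel:
    """Two-sample summary-data MR model on a harmonized instrument set."""

    def __init__(self, gamma, se_gamma, Gamma, se_Gamma, snp_ids=None):
        self.gamma = np.asarray(gamma, dtype=float)
        self.se_gamma = np.asarray(se_gamma, dtype=float)
        self.Gamma = np.asarray(Gamma, dtype=float)
        self.se_Gamma = np.asarray(se_Gamma, dtype=float)
        k = len(self.gamma)
        if not (len(self.se_gamma) == len(self.Gamma) == len(self.se_Gamma) == k):
            raise ValueError("all effect/SE arrays must share a length")
        if np.any(self.se_gamma <= 0) or np.any(self.se_Gamma <= 0):
            raise ValueError("standard errors must be positive")
        self.snp_ids = (np.asarray(snp_ids, dtype=str) if snp_ids is not None
                        else np.array([f"snp{i}" for i in range(k)]))

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, gamma="gamma",
                       se_gamma="se_gamma", Gamma="Gamma",
                       se_Gamma="se_Gamma", snp_id="snp_id") -> "MRModel":
        if "action" in df.columns:
            df = df[df["action"].isin(
                ["kept", "flipped", "strand_flipped", "proxied"])]
        ids = df[snp_id].astype(str) if snp_id in df.columns else None
        return cls(df[gamma], df[se_gamma], df[Gamma], df[se_Gamma], ids)

    @classmethod
    def from_harmonized(cls, hs) -> "MRModel":
        ids, g, sg, G, sG = est._as_arrays(hs)
        return cls(g, sg, G, sG, ids)

    # -- basic quantities -------------------------------------------------
    @property
    def nsnp(self) -> int:
        return len(self.gamma)

    @property
    def wald_ratios(self) -> np.ndarray:
        return self.Gamma / self.gamma

    @property
    def _tuple(self):
        return (self.snp_ids, self.gamma, self.se_gamma, self.Gamma,
                self.se_Gamma)

    # -- fitting ----------------------------------------------------------
    def fit(self, method: str = "ivw", **kwargs) -> "MRResults":
        """Fit one estimator; ``method`` is one of %s.""" % (_METHODS,)
        if method == "ivw":
            e = est.ivw(self._tuple, **kwargs)
        elif method == "ivw_fixed":
            e = est.ivw(self._tuple, model="fixed", **kwargs)
        elif method == "mr_egger":
            egger = est.mr_egger(self._tuple)
            return MRResults(self, egger.slope, heterogeneity=egger.heterogeneity,
                             intercept=egger.intercept)
        elif method == "weighted_median":
            e = est.weighted_median(self._tuple, **kwargs)
        elif method == "weighted_mode":
            e = est.weighted_mode(self._tuple, **kwargs)
        elif method == "wald_ratio":
            e = est.wald_ratio(self._tuple)
        else:
            raise ValueError(f"unknown method {method!r}")
        het = est.cochran_q(self._tuple) if self.nsnp >= 2 else None
        return MRResults(self, e, heterogeneity=het)

    def fit_all(self, methods: Sequence[str] = ("ivw", "mr_egger",
                                                "weighted_median",
                                                "weighted_mode"),
                seed=None, **kwargs) -> pd.DataFrame:
        """Fit several estimators; returns a tidy one-row-per-method table."""
        rows = []
        for m in methods:
            kw = dict(kwargs)
            if m in ("weighted_median", "weighted_mode"):
                kw.setdefault("seed", seed)
            else:
                kw = {}
            r = self.fit(method=m, **kw)
            rows.append(r.estimate.to_dict())
            if r.intercept is not None:
                rows.append(r.intercept.to_dict())
        return pd.DataFrame(rows)

    # -- sensitivity ------------------------------------------------------
    def leave_one_out(self, **kwargs) -> pd.DataFrame:
        return est.leave_one_out(self._tuple, **kwargs)

    def presso(self, n_sim: int = 1000, outlier_p: float = 0.05,
               seed=None) -> PressoResult:
        return est.mr_presso(self._tuple, n_sim=n_sim, outlier_p=outlier_p,
                             seed=seed)

    def heterogeneity(self) -> HeterogeneityStats:
        return est.cochran_q(self._tuple)


class MRResults:
    """Estimate container with statsmodels-flavoured accessors."""

    def __init__(self, model: MRModel, estimate: MREstimate,
                 heterogeneity: HeterogeneityStats | None = None,
                 intercept: MREstimate | None = None):
        self.model = model
        self.estimate = estimate
        self.het = heterogeneity
        self.intercept = intercept

    # statsmodels-ish accessors
    @property
    def theta(self) -> float:
        return self.estimate.theta

    params = theta

    @property
    def bse(self) -> float:
        return self.estimate.se

    @property
    def pvalue(self) -> float:
        return self.estimate.pval

    @property
    def nobs(self) -> int:
        return self.estimate.nsnp

    @property
    def method(self) -> str:
        return self.estimate.method

    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low, self.estimate.ci_high)

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Two-sample Mendelian randomization",
            "=" * 54,
            f"method:            {e.method}",
            f"instruments (k):   {e.nsnp}",
            f"causal estimate:   {e.theta: .4f}  (SE {e.se:.4f})",
            f"95% CI:            [{e.ci_low: .4f}, {e.ci_high: .4f}]",
            f"p-value:           {e.pval:.4g}",
        ]
        if self.intercept is not None:
            i = self.intercept
            lines += [
                f"Egger intercept:   {i.theta: .4f}  (SE {i.se:.4f}, "
                f"p {i.pval:.3g})",
            ]
        if self.het is not None:
            h = self.het
            lines += [f"Cochran Q:         {h.Q:.3f} on {h.df} df "
                      f"(p {h.pval:.3g})"]
            if h.Q_prime is not None:
                lines += [
                    f"Egger Q':          {h.Q_prime:.3f} on {h.df_prime} df",
                    f"Q - Q':            {h.q_diff:.3f} (chi2(1) p "
                    f"{h.q_diff_p:.3g})",
                ]
        for key, val in e.extras.items():
            lines.append(f"{key + ':':<19}{val}")
        return "\n".join(lines)

    def __repr__(self):
        e = self.estimate
        return (f"<MRResults {e.method}: theta={e.theta:.4f} "
                f"se={e.se:.4f} p={e.pval:.3g} k={e.nsnp}>")
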