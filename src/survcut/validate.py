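"""External validation of locked cutoffs.

Applies a frozen decision rule to an independent cohort and reproduces the
validation surface: one-sided logrank pass/fail at the prespecified adverse
direction, univariate hazard ratios with Kaplan-Meier curves for both
strata, mutation-enrichment 2x2 tables with Fisher's exact p-values, and
multivariate Cox models (optionally refit after excluding a stratum, e.g.
all high-EVI1 cases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .discovery import LockedCutoff
from .errors import DataError, MappingError
from .stats import (
    CoxFit,
    KMCurve,
    SurvivalData,
    cox_ph,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    univariate_hr,
)

__all__ = [
    "ValidationReport",
    "EnrichmentRow",
    "classify_cases",
    "validate_os",
    "validate_efs",
    "mutation_enrichment",
    "multivariate_os",
]


def classify_cases(expr: pd.DataFrame, cutoff: LockedCutoff) -> pd.Series:
    """Label every sample 'low' or 'high' by the locked threshold.

    A score exactly equal to the threshold classifies as 'low' (strict >).
    ``expr`` is a genes x samples table; the cutoff's gene row is used.
    """
    if cutoff.gene not in expr.index:
        raise MappingError(f"gene {cutoff.gene!r} missing from expression table")
    scores = expr.loc[cutoff.gene]
    return pd.Series(
        cutoff.classify(scores.to_numpy(float)), index=expr.columns, name=cutoff.gene
    )


@dataclass(frozen=True)
class ValidationReport:
    """One gene's validation outcome on an independent cohort."""

    gene: str
    endpoint: str                       # "OS" or "EFS"
    threshold: float
    adverse_side: str
    n_low: int
    n_high: int
    hr: float                           # hazard(high) / hazard(low)
    ci_lower: float
    ci_upper: float
    p_one_sided: float
    p_two_sided: float
    passed: bool
    estimable: bool = True
    message: str = ""
    km_low: KMCurve | None = None
    km_high: KMCurve | None = None

    def to_dict(self) -> dict:
        d = {
            "gene": self.gene,
            "endpoint": self.endpoint,
            "threshold": self.threshold,
            "adverse_side": self.adverse_side,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "hr": self.hr,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_one_sided": self.p_one_sided,
            "p_two_sided": self.p_two_sided,
            "passed": self.passed,
            "estimable": self.estimable,
            "message": self.message,
        }
        if self.km_low is not None:
            d["km_low"] = self.km_low.to_frame().to_dict(orient="list")
        if self.km_high is not None:
            d["km_high"] = self.km_high.to_frame().to_dict(orient="list")
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=1, default=float)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _validate_endpoint(
    labels: pd.Series,
    s: SurvivalData,
    adverse_side: str,
    *,
    endpoint: str,
    gene: str = "",
    threshold: float = float("nan"),
    alpha: float = 0.05,
) -> ValidationReport:
    labels = pd.Series(labels)
    if len(labels) != len(s):
        raise DataError("labels and survival data are not aligned")
    if adverse_side not in ("above", "below"):
        raise DataError("adverse_side must be 'above' or 'below'")
    hi = (labels == "high").to_numpy()
    n_high, n_low = int(hi.sum()), int((~hi).sum())
    if n_high == 0 or n_low == 0:
        return ValidationReport(
            gene=gene,
            endpoint=endpoint,
            threshold=threshold,
            adverse_side=adverse_side,
            n_low=n_low,
            n_high=n_high,
            hr=float("nan"),
            ci_lower=float("nan"),
            ci_upper=float("nan"),
            p_one_sided=float("nan"),
            p_two_sided=float("nan"),
            passed=False,
            estimable=False,
            message="empty stratum: test not estimable",
        )
    low_s, high_s = s.subset(~hi), s.subset(hi)
    # one-sided direction: the adverse stratum is expected to fare worse
    adverse_group = "b" if adverse_side == "above" else "a"
    lr = logrank_test(low_s, high_s, adverse_group=adverse_group)
    fit = univariate_hr(low_s, high_s)   # HR = hazard(high) / hazard(low)
    row = fit["group"]
    return ValidationReport(
        gene=gene,
        endpoint=endpoint,
        threshold=threshold,
        adverse_side=adverse_side,
        n_low=n_low,
        n_high=n_high,
        hr=row["HR"],
        ci_lower=row["ci_lower"],
        ci_upper=row["ci_upper"],
        p_one_sided=lr.p_one_sided,
        p_two_sided=lr.p_two_sided,
        passed=bool(lr.p_one_sided <= alpha),
        estimable=fit.estimable,
        message=fit.message,
        km_low=km_estimate(low_s),
        km_high=km_estimate(high_s),
    )


def validate_os(
    labels: pd.Series,
    os: SurvivalData,
    adverse_side: str,
    *,
    gene: str = "",
    threshold: float = float("nan"),
    alpha: float = 0.05,
) -> ValidationReport:
    """One-sided logrank validation for overall survival.

    The rule passes when the one-sided p-value in the prespecified adverse
    direction is <= alpha (0.05); p exactly at alpha passes.
    """
    return _validate_endpoint(
        labels, os, adverse_side, endpoint="OS", gene=gene, threshold=threshold, alpha=alpha
    )


def validate_efs(
    labels: pd.Series,
    efs: SurvivalData,
    adverse_side: str,
    *,
    gene: str = "",
    threshold: float = float("nan"),
    alpha: float = 0.05,
) -> ValidationReport:
    """Event-free-survival analogue of :func:`validate_os`."""
    return _validate_endpoint(
        labels, efs, adverse_side, endpoint="EFS", gene=gene, threshold=threshold, alpha=alpha
    )


@dataclass(frozen=True)
class EnrichmentRow:
    """One mutation's 2x2 stratification against expression strata."""

    mutation: str
    n_total: int
    mutant_low: int
    mutant_high: int
    n_low: int
    n_high: int
    p_two_sided: float

    def table(self) -> list[list[int]]:
        return [
            [self.mutant_low, self.mutant_high],
            [self.n_low - self.mutant_low, self.n_high - self.mutant_high],
        ]


def mutation_enrichment(
    labels: pd.Series, mutations: pd.DataFrame
) -> list[EnrichmentRow]:
    """Fisher's exact enrichment of each mutation across expression strata."""
    labels = pd.Series(labels)
    if len(labels) != len(mutations):
        raise DataError("labels and mutation table are not aligned")
    hi = (labels == "high").to_numpy()
    rows = []
    for col in mutations.columns:
        vals = mutations[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise DataError(f"mutation column {col!r} is not a 0/1 indicator")
        m_low = int(vals[~hi].sum())
        m_high = int(vals[hi].sum())
        n_low, n_high = int((~hi).sum()), int(hi.sum())
        res = fisher_exact_2x2(
            [[m_low, m_high], [n_low - m_low, n_high - m_high]]
        )
        rows.append(
            EnrichmentRow(
                mutation=str(col),
                n_total=int(vals.sum()),
                mutant_low=m_low,
                mutant_high=m_high,
                n_low=n_low,
                n_high=n_high,
                p_two_sided=res.p_two_sided,
            )
        )
    return rows


def multivariate_os(
    covariates: pd.DataFrame,
    s: SurvivalData,
    exclude: np.ndarray | Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> CoxFit:
    """Multivariate Cox model for OS, optionally on a filtered subset.

    ``exclude`` marks samples to drop, either as a boolean mask or as a
    predicate mapping the covariate table to one (e.g. the high-EVI1 cases
    before refitting the model on low-EVI1 cases only). Missing covariate
    values are rejected, not imputed.
    """
    if callable(exclude):
        exclude = np.asarray(exclude(covariates), bool)
    if exclude is not None:
        exclude = np.asarray(exclude, bool)
        if len(exclude) != len(covariates):
            raise DataError("exclusion mask and covariates are not aligned")
        keep = ~exclude
        covariates = covariates.loc[keep]
        s = s.subset(keep)
    return cox_ph(covariates, s)
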