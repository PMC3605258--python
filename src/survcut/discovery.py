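"""Cutoff discovery: cross-validated significance profiling and lockdown.

The central procedure stratifies a cohort at every percentile of a gene's
expression on a fixed grid (10th-90th in steps of 5), and for each of many
random 50/50 splits asks whether the test half shows a significant logrank
difference in overall survival between low and high expressers. The
per-percentile fraction of significant repetitions (the significance
profile) reveals which cutoffs carry reproducible prognostic signal; a peak
supported in an independent verification cohort is translated into an
expression threshold and locked down for external validation.

For genes with extremely right-skewed expression (a small high-expression
spike, as for EVI1) the profile has no power, and the threshold is instead
chosen by maximizing the logrank statistic over candidate cutpoints with a
minimum high-group size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import (
    CohortTooSmallError,
    ConstraintError,
    DataError,
    SpecError,
)
from .standardize import percentile_cutoff_value
from .stats import SurvivalData, logrank_pvalue, _logrank_terms

__all__ = [
    "DEFAULT_GRID",
    "ProfileConfig",
    "SignificanceProfile",
    "LockedCutoff",
    "CutoffSignificanceCV",
    "MaximallySelectedCutoff",
    "PercentileCutoff",
    "cv_significance_profile",
    "find_peaks",
    "select_supported_peak",
    "maximal_logrank_cutoff",
    "lock_cutoff",
]

#: 17-point percentile grid: 10, 15, ..., 90.
DEFAULT_GRID: tuple[int, ...] = tuple(range(10, 95, 5))


@dataclass(frozen=True)
class ProfileConfig:
    """Settings of the cross-validated significance profile."""

    percentile_grid: tuple[float, ...] = DEFAULT_GRID
    n_reps: int = 1000
    alpha: float = 0.05
    split_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(p) for p in self.percentile_grid)
        if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise SpecError("percentile grid must be strictly increasing")
        if grid[0] < 10 or grid[-1] > 90:
            raise SpecError("percentile grid must lie within [10, 90]")
        if self.n_reps < 1:
            raise SpecError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise SpecError("alpha must be in (0, 1)")
        if not 0 < self.split_fraction < 1:
            raise SpecError("split_fraction must be in (0, 1)")
        object.__setattr__(self, "percentile_grid", grid)


@dataclass(frozen=True)
class SignificanceProfile:
    """Per-percentile fraction of CV repetitions with a significant test half.

    ``n_valid`` counts non-degenerate repetitions per percentile; degenerate
    splits (empty or event-free test-half group) count as non-significant in
    ``fraction`` but are tallied here.
    """

    percentiles: tuple[float, ...]
    fraction: np.ndarray
    n_significant: np.ndarray
    n_valid: np.ndarray
    n_reps: int
    alpha: float

    def argmax_percentile(self) -> float:
        """Grid point of the maximal fraction.

        Ties (common when power saturates over a plateau) are broken at the
        median of the tied positions, biased to the lower middle for an even
        tie count — a plateau-robust peak locator.
        """
        best = np.flatnonzero(self.fraction == self.fraction.max())
        mid = best[(len(best) - 1) // 2]
        return self.percentiles[mid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percentile": self.percentiles,
                "fraction": self.fraction,
                "n_significant": self.n_significant,
                "n_valid": self.n_valid,
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, n_reps: int | None = None, alpha: float = 0.05
    ) -> "SignificanceProfile":
        n_sig = (
            df["n_significant"].to_numpy(int)
            if "n_significant" in df
            else np.round(df["fraction"].to_numpy(float) * (n_reps or 1)).astype(int)
        )
        n_valid = (
            df["n_valid"].to_numpy(int)
            if "n_valid" in df
            else np.full(len(df), n_reps or 1)
        )
        return cls(
            percentiles=tuple(df["percentile"].to_numpy(float)),
            fraction=df["fraction"].to_numpy(float),
            n_significant=n_sig,
            n_valid=n_valid,
            n_reps=int(n_reps or n_valid.max()),
            alpha=alpha,
        )


class CutoffSignificanceCV(BaseEstimator):
    """Cross-validated significance profiler (sklearn estimator interface).

    ``fit(X, y)`` takes per-sample expression scores ``X`` (1-D or a single
    column) and survival ``y`` (a :class:`SurvivalData` or an (n, 2) array of
    time/event) and computes the significance profile over the percentile
    grid. Each repetition randomly splits the cohort into train/test halves,
    derives the threshold from the TRAIN half at each grid percentile,
    dichotomizes the TEST half at that threshold and applies a two-sided
    logrank test; the repetition counts as significant when p < alpha.

    Attributes
    ----------
    profile_ : SignificanceProfile
    peaks_ : tuple of percentiles that are strict local maxima
    """

    def __init__(
        self,
        percentile_grid: Sequence[float] = DEFAULT_GRID,
        n_reps: int = 1000,
        alpha: float = 0.05,
        split_fraction: float = 0.5,
        random_state: int = 0,
    ):
        self.percentile_grid = percentile_grid
        self.n_reps = n_reps
        self.alpha = alpha
        self.split_fraction = split_fraction
        self.random_state = random_state

    def _config(self) -> ProfileConfig:
        return ProfileConfig(
            percentile_grid=tuple(self.percentile_grid),
            n_reps=self.n_reps,
            alpha=self.alpha,
            split_fraction=self.split_fraction,
            seed=self.random_state,
        )

    def fit(self, X, y) -> "CutoffSignificanceCV":
        cfg = self._config()
        expr = np.asarray(X, float).reshape(-1)
        s = y if isinstance(y, SurvivalData) else SurvivalData(*np.asarray(y).T[:2])
        if len(expr) != len(s):
            raise DataError("expression and survival are not aligned")
        n = len(expr)
        if n < 20:
            raise CohortTooSmallError(f"cohort of {n} below the minimum of 20")

        # canonical sample order: the profile depends only on the multiset of
        # (expression, time, event) triples, not on input ordering
        canon = np.lexsort((s.event, s.time, expr))
        expr = expr[canon]
        s = SurvivalData(s.time[canon], s.event[canon])

        grid = np.asarray(cfg.percentile_grid, float)
        k = len(grid)
        n_sig = np.zeros(k, int)
        n_valid = np.zeros(k, int)
        rng = np.random.default_rng(cfg.seed)
        n_train = int(round(n * cfg.split_fraction))
        n_train = min(max(n_train, 1), n - 1)

        time, event = s.time, s.event
        for _ in range(cfg.n_reps):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            thresholds = np.percentile(expr[tr], grid)
            t_te, e_te, x_te = time[te], event[te], expr[te]
            for j, thr in enumerate(thresholds):
                hi = x_te > thr
                n_hi = int(hi.sum())
                if n_hi == 0 or n_hi == len(hi):
                    continue  # degenerate: counted non-significant, not valid
                if e_te[hi].sum() == 0 or e_te[~hi].sum() == 0:
                    continue
                n_valid[j] += 1
                if logrank_pvalue(t_te, e_te, hi) < cfg.alpha:
                    n_sig[j] += 1

        self.profile_ = SignificanceProfile(
            percentiles=tuple(grid),
            fraction=n_sig / cfg.n_reps,
            n_significant=n_sig,
            n_valid=n_valid,
            n_reps=cfg.n_reps,
            alpha=cfg.alpha,
        )
        self.peaks_ = tuple(find_peaks(self.profile_))
        return self


def cv_significance_profile(
    expr, s: SurvivalData, cfg: ProfileConfig | None = None, **kwargs
) -> SignificanceProfile:
    """Functional wrapper over :class:`CutoffSignificanceCV`."""
    cfg = cfg or ProfileConfig(**kwargs)
    est = CutoffSignificanceCV(
        percentile_grid=cfg.percentile_grid,
        n_reps=cfg.n_reps,
        alpha=cfg.alpha,
        split_fraction=cfg.split_fraction,
        random_state=cfg.seed,
    )
    est.fit(expr, s)
    return est.profile_


def find_peaks(profile: SignificanceProfile) -> list[float]:
    """Strict local maxima of the profile.

    Interior points must exceed both neighbors strictly; endpoints qualify
    when strictly greater than their single neighbor. Ties never produce a
    peak (a flat profile has none).
    """
    f = np.asarray(profile.fraction, float)
    p = profile.percentiles
    if len(f) == 1:
        return [p[0]]
    peaks = []
    for i in range(len(f)):
        left_ok = i == 0 or f[i] > f[i - 1]
        right_ok = i == len(f) - 1 or f[i] > f[i + 1]
        if left_ok and right_ok:
            peaks.append(p[i])
    return peaks


def select_supported_peak(
    train: SignificanceProfile,
    verify: SignificanceProfile,
    min_support: float = 0.20,
) -> float | None:
    """Choose the training peak best supported by the verification cohort.

    Among strict peaks of the training profile, returns the one whose
    verification-profile fraction is greatest, provided that fraction reaches
    ``min_support``; equal support breaks toward the lower percentile. Returns
    None when no peak qualifies.
    """
    if train.percentiles != verify.percentiles:
        raise ValueError("train and verify profiles use different percentile grids")
    peaks = find_peaks(train)
    if not peaks:
        return None
    vmap = dict(zip(verify.percentiles, verify.fraction))
    best, best_support = None, -1.0
    for pk in sorted(peaks):
        support = float(vmap[pk])
        if support > best_support:
            best, best_support = pk, support
    if best_support >= min_support:
        return best
    return None


@dataclass(frozen=True)
class LockedCutoff:
    """A frozen decision rule: gene, threshold, adverse side, provenance."""

    gene: str
    method: str                      # "percentile-cv" or "maximal-logrank"
    threshold: float
    adverse_side: str                # "above" or "below"
    percentile: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise DataError("threshold must be finite")
        if self.adverse_side not in ("above", "below"):
            raise SpecError("adverse_side must be 'above' or 'below'")
        if self.method not in ("percentile-cv", "maximal-logrank"):
            raise SpecError(f"unknown cutoff method {self.method!r}")

    def classify(self, scores) -> np.ndarray:
        """Label each score 'high' iff strictly above the threshold."""
        vals = np.asarray(scores, float)
        return np.where(vals > self.threshold, "high", "low")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "LockedCutoff":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        return cls(
            gene=d["gene"],
            method=d["method"],
            threshold=float(d["threshold"]),
            adverse_side=d["adverse_side"],
            percentile=d.get("percentile"),
            provenance=d.get("provenance") or {},
        )


class MaximallySelectedCutoff(BaseEstimator):
    """Maximally selected logrank cutpoint (sklearn estimator interface).

    Candidate thresholds are midpoints between consecutive distinct sorted
    expression values that leave between ``min_high`` and floor(n/2) cases in
    the high group; ``fit`` selects the candidate maximizing the logrank
    chi-square statistic, breaking ties toward the larger threshold (smaller
    high group). Intended for extremely skewed markers where percentile
    profiling has no power.

    Attributes
    ----------
    threshold_ : selected expression threshold
    statistic_ : logrank chi-square at the selected threshold
    n_high_ : size of the induced high group
    """

    def __init__(self, min_high: int = 2, adverse_side: str = "above"):
        self.min_high = min_high
        self.adverse_side = adverse_side

    def fit(self, X, y) -> "MaximallySelectedCutoff":
        if self.min_high < 2:
            raise SpecError("min_high must be >= 2")
        expr = np.asarray(X, float).reshape(-1)
        s = y if isinstance(y, SurvivalData) else SurvivalData(*np.asarray(y).T[:2])
        if len(expr) != len(s):
            raise DataError("expression and survival are not aligned")
        n = len(expr)
        sorted_expr = np.sort(expr)
        distinct = np.unique(expr)
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        # high-group size per midpoint: values strictly above it
        n_above = n - np.searchsorted(sorted_expr, mids, side="right")
        ok = (n_above >= self.min_high) & (n_above <= n // 2)
        if not ok.any():
            raise ConstraintError(
                f"no candidate threshold leaves between {self.min_high} "
                f"and {n // 2} high cases"
            )
        best_stat, best_thr, best_high = -np.inf, None, None
        for thr, nh in zip(mids[ok], n_above[ok]):
            hi = expr > thr
            o, e, v, _ = _logrank_terms(s.time, s.event, hi)
            stat = 0.0 if v <= 0 else (o - e) ** 2 / v
            if stat > best_stat or (stat == best_stat and thr > best_thr):
                best_stat, best_thr, best_high = stat, float(thr), int(nh)
        self.threshold_ = best_thr
        self.statistic_ = float(best_stat)
        self.n_high_ = best_high
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise DataError("MaximallySelectedCutoff is not fitted")
        vals = np.asarray(X, float).reshape(-1)
        return np.where(vals > self.threshold_, "high", "low")


class PercentileCutoff(BaseEstimator):
    """Dichotomizer at a fixed expression percentile of the fitted cohort."""

    def __init__(self, percentile: float = 50.0, adverse_side: str = "above"):
        self.percentile = percentile
        self.adverse_side = adverse_side

    def fit(self, X, y=None) -> "PercentileCutoff":
        vals = np.asarray(X, float).reshape(-1)
        self.threshold_ = percentile_cutoff_value(vals, self.percentile)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise DataError("PercentileCutoff is not fitted")
        vals = np.asarray(X, float).reshape(-1)
        return np.where(vals > self.threshold_, "high", "low")


def maximal_logrank_cutoff(
    expr,
    s: SurvivalData,
    min_high: int = 2,
    gene: str = "",
    adverse_side: str = "above",
    provenance: dict | None = None,
) -> LockedCutoff:
    """Lock the threshold that maximizes the logrank statistic.

    See :class:`MaximallySelectedCutoff` for the candidate rule.
    """
    est = MaximallySelectedCutoff(min_high=min_high, adverse_side=adverse_side)
    est.fit(expr, s)
    prov = dict(provenance or {})
    prov.update({"statistic": est.statistic_, "n_high": est.n_high_})
    return LockedCutoff(
        gene=gene,
        method="maximal-logrank",
        threshold=est.threshold_,
        adverse_side=adverse_side,
        percentile=None,
        provenance=prov,
    )


def lock_cutoff(
    expr,
    gene: str,
    percentile: float,
    adverse_side: str,
    provenance: dict | None = None,
) -> LockedCutoff:
    """Translate a chosen percentile into a frozen expression threshold."""
    thr = percentile_cutoff_value(np.asarray(expr, float), percentile)
    return LockedCutoff(
        gene=gene,
        method="percentile-cv",
        threshold=thr,
        adverse_side=adverse_side,
        percentile=float(percentile),
        provenance=dict(provenance or {}),
    )
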