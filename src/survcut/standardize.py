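"""Probe-set matrix standardization and per-gene scoring.

The assay chain accepts a probe-set x sample matrix of positive,
pre-summarized intensities and produces dimensionless, z-like gene scores:

1. chip normalization — rescale every sample column so its 2%-trimmed mean
   hits a common target intensity (500 by default);
2. geometric mean centering — log2 transform and subtract each probe set's
   mean log2 value (division by the geometric mean before the log);
3. mean-variance normalization — z-score each probe-set row (mean 0, SD 1,
   population-SD convention);
4. gene scoring — average the normalized rows mapped to each gene; genes
   with a single probe set pass through.

Fitting the chain on a reference cohort stores the per-probe-set centering
and scale constants, so a single new case can be scored against the frozen
reference (`ExpressionStandardizer.transform` / `apply_reference`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import trim_mean
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DataError, DegenerateProbesetError, MappingError

__all__ = [
    "DEFAULT_PROBESET_MAP",
    "ReferenceModel",
    "ExpressionStandardizer",
    "normalize_chips",
    "geometric_mean_center",
    "mean_variance_normalize",
    "gene_score",
    "fit_reference",
    "apply_reference",
    "subset_probesets",
    "percentile_cutoff_value",
]

#: Marker genes and their probe sets on the 995-probe-set custom array
#: (a subset of the Affymetrix U133Plus2.0 layout).
DEFAULT_PROBESET_MAP: dict[str, tuple[str, ...]] = {
    "BAALC": ("218899_s_at", "222780_s_at"),
    "ERG": ("241926_s_at", "213541_s_at"),
    "EVI1": ("221884_at", "226420_at"),
    "MN1": ("205330_at",),
}

CHIP_TARGET = 500.0
TRIM_FRACTION = 0.02


def _check_matrix(m: pd.DataFrame, positive: bool = False) -> pd.DataFrame:
    if not isinstance(m, pd.DataFrame):
        raise DataError("expected a probe-set x sample DataFrame")
    if m.isna().to_numpy().any():
        raise DataError("matrix contains missing values")
    if positive and (m.to_numpy() <= 0).any():
        raise DataError("intensities must be strictly positive before log transform")
    return m


def normalize_chips(
    raw: pd.DataFrame, target: float = CHIP_TARGET, trim: float = TRIM_FRACTION
) -> pd.DataFrame:
    """Scale each sample column so its trimmed mean equals ``target``.

    Preserves within-sample ordering exactly (a single positive scale factor
    per column).
    """
    _check_matrix(raw, positive=True)
    scaled = {}
    for col in raw.columns:
        tm = trim_mean(raw[col].to_numpy(float), trim)
        scaled[col] = raw[col].to_numpy(float) * (target / tm)
    return pd.DataFrame(scaled, index=raw.index)


def geometric_mean_center(m: pd.DataFrame) -> pd.DataFrame:
    """log2-transform and center each probe-set row at its mean log2 value."""
    _check_matrix(m, positive=True)
    logm = np.log2(m.to_numpy(float))
    centered = logm - logm.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=m.index, columns=m.columns)


def mean_variance_normalize(m: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """z-score each probe-set row to mean 0, SD 1 (population SD by default)."""
    _check_matrix(m)
    vals = m.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = ", ".join(str(m.index[i]) for i in flat[:5])
        raise DegenerateProbesetError(f"zero-variance probe set(s): {names}")
    return pd.DataFrame((vals - mu) / sd, index=m.index, columns=m.columns)


def gene_score(
    m: pd.DataFrame, probeset_map: Mapping[str, Sequence[str]] | None = None
) -> pd.DataFrame:
    """Average each gene's normalized probe-set rows into one score per sample.

    Returns a gene x sample DataFrame. Raises :class:`MappingError` listing
    any mapped probe sets absent from the matrix.
    """
    probeset_map = dict(probeset_map or DEFAULT_PROBESET_MAP)
    missing = [
        ps for sets in probeset_map.values() for ps in sets if ps not in m.index
    ]
    if missing:
        raise MappingError(f"probe set(s) missing from matrix: {', '.join(missing)}")
    rows = {
        gene: m.loc[list(sets)].mean(axis=0) for gene, sets in probeset_map.items()
    }
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class ReferenceModel:
    """Frozen standardization constants enabling single-case analysis."""

    probeset_ids: tuple[str, ...]
    center: np.ndarray        # mean of log2 values per probe set on the reference
    scale: np.ndarray         # SD of centered log2 values per probe set
    chip_target: float
    trim: float
    n_reference: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "probeset_ids": list(self.probeset_ids),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "chip_target": self.chip_target,
            "trim": self.trim,
            "n_reference": self.n_reference,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceModel":
        d = json.loads(Path(path).read_text())
        return cls(
            probeset_ids=tuple(d["probeset_ids"]),
            center=np.asarray(d["center"], float),
            scale=np.asarray(d["scale"], float),
            chip_target=float(d["chip_target"]),
            trim=float(d["trim"]),
            n_reference=int(d["n_reference"]),
        )


class ExpressionStandardizer(TransformerMixin, BaseEstimator):
    """Fit the standardization chain on a reference cohort, score any case.

    Follows the sklearn transformer contract: `fit` expects a samples x
    probe-sets DataFrame (columns = probe-set identifiers), `transform`
    returns a samples x genes DataFrame of standardized scores. Applying the
    fitted transformer to a member of the reference cohort reproduces its
    batch score exactly, because the same frozen centering/scale constants
    are used.

    Parameters
    ----------
    probeset_map : mapping gene -> probe sets, default the four-marker map.
    chip_target : trimmed-mean intensity every chip is scaled to.
    trim : trimmed-mean fraction for chip scaling.
    ddof : degrees of freedom for the probe-set SD (0 = population SD).
    """

    def __init__(
        self,
        probeset_map: Mapping[str, Sequence[str]] | None = None,
        chip_target: float = CHIP_TARGET,
        trim: float = TRIM_FRACTION,
        ddof: int = 0,
    ):
        self.probeset_map = probeset_map
        self.chip_target = chip_target
        self.trim = trim
        self.ddof = ddof

    def _map(self) -> dict[str, tuple[str, ...]]:
        return {k: tuple(v) for k, v in (self.probeset_map or DEFAULT_PROBESET_MAP).items()}

    def fit(self, X: pd.DataFrame, y=None) -> "ExpressionStandardizer":
        m = _check_matrix(X.T, positive=True)  # probe sets x samples internally
        if m.shape[1] < 10:
            raise DataError(
                f"reference cohort has {m.shape[1]} samples; at least 10 required"
            )
        chip = normalize_chips(m, self.chip_target, self.trim)
        logm = np.log2(chip.to_numpy(float))
        center = logm.mean(axis=1)
        sd = (logm - center[:, None]).std(axis=1, ddof=self.ddof)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            names = ", ".join(str(m.index[i]) for i in flat[:5])
            raise DegenerateProbesetError(f"zero-variance probe set(s): {names}")
        self.reference_model_ = ReferenceModel(
            probeset_ids=tuple(str(i) for i in m.index),
            center=center,
            scale=sd,
            chip_target=self.chip_target,
            trim=self.trim,
            n_reference=m.shape[1],
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "reference_model_"):
            raise DataError("ExpressionStandardizer is not fitted")
        ref = self.reference_model_
        m = _check_matrix(X.T, positive=True)
        missing = [p for p in ref.probeset_ids if p not in m.index]
        if missing:
            raise MappingError(
                f"case lacks reference probe set(s): {', '.join(missing[:5])}"
            )
        unknown = [str(p) for p in m.index if str(p) not in ref.probeset_ids]
        if unknown:
            raise MappingError(f"unknown probe set(s): {', '.join(unknown[:5])}")
        m = m.loc[list(ref.probeset_ids)]
        chip = normalize_chips(m, ref.chip_target, ref.trim)
        logm = np.log2(chip.to_numpy(float))
        z = (logm - ref.center[:, None]) / ref.scale[:, None]
        norm = pd.DataFrame(z, index=m.index, columns=m.columns)
        return gene_score(norm, self._map()).T


def fit_reference(
    cohort: pd.DataFrame, probeset_map: Mapping[str, Sequence[str]] | None = None
) -> ReferenceModel:
    """Fit the frozen reference model on a probe-set x sample cohort matrix."""
    est = ExpressionStandardizer(probeset_map=probeset_map)
    est.fit(cohort.T)
    return est.reference_model_


def apply_reference(
    case: pd.DataFrame,
    ref: ReferenceModel,
    probeset_map: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Score one or more cases (probe-set x sample) against a fitted reference."""
    est = ExpressionStandardizer(probeset_map=probeset_map)
    est.reference_model_ = ref
    return est.transform(case.T).T  # genes x samples, matching batch layout


def batch_standardize(
    cohort: pd.DataFrame, probeset_map: Mapping[str, Sequence[str]] | None = None
) -> pd.DataFrame:
    """Full chain on one cohort (fit + apply on itself); genes x samples."""
    chip = normalize_chips(cohort)
    centered = geometric_mean_center(chip)
    norm = mean_variance_normalize(centered)
    return gene_score(norm, probeset_map)


def subset_probesets(
    m: pd.DataFrame, probeset_ids: Sequence[str]
) -> pd.DataFrame:
    """Re-index a larger-platform matrix onto a target probe-set layout.

    Cross-platform import (e.g. a full U133Plus2.0 matrix onto the 995
    probe sets of the custom assay) is a plain row subset by identifier;
    the standardization chain then runs unchanged. Missing identifiers
    raise :class:`MappingError`.
    """
    ids = [str(p) for p in probeset_ids]
    missing = [p for p in ids if p not in m.index]
    if missing:
        raise MappingError(
            f"target layout probe set(s) absent from matrix: {', '.join(missing[:5])}"
        )
    return m.loc[ids]


def percentile_cutoff_value(values: Sequence[float], p: float) -> float:
    """Translate a percentile into an expression threshold.

    Uses linear interpolation between closest ranks over (n - 1) intervals,
    the mainstream numerics default; monotone non-decreasing in ``p``.
    """
    vals = np.asarray(values, float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise DataError("need at least 2 finite values for a percentile cutoff")
    if not 0 <= p <= 100:
        raise ValueError(f"percentile {p} outside [0, 100]")
    return float(np.percentile(vals, p))
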