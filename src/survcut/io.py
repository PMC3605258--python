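"""Readers and writers for the pipeline's plain-text dialects.

Probe-set and gene matrices travel as TSV with the identifier in the first
column (``probeset_id`` or ``gene``); clinical tables as CSV with the
columns produced by :meth:`survcut.simulate.SimulatedCohort.clinical_frame`;
profiles as TSV (percentile, fraction, n_significant, n_valid); cutoffs,
reference models and reports as JSON.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .discovery import SignificanceProfile
from .errors import DataError
from .stats import SurvivalData

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "survival_from_clinical",
    "read_profile",
    "write_profile",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe-set/gene x sample TSV (identifier in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataError(f"empty matrix: {path}")
    df.index = df.index.astype(str)
    return df


def write_matrix(m: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    m.rename_axis(index_label).to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise DataError(f"clinical table {path} lacks a sample_id column")
    return df


def survival_from_clinical(
    clinical: pd.DataFrame, endpoint: str = "os"
) -> SurvivalData:
    """Extract OS or EFS (time in months + event flag) from a clinical table."""
    endpoint = endpoint.lower()
    if endpoint not in ("os", "efs"):
        raise DataError("endpoint must be 'os' or 'efs'")
    return SurvivalData.from_frame(
        clinical, time_col=f"{endpoint}_months", event_col=f"{endpoint}_event"
    )


def write_profile(profile: SignificanceProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_profile(
    path: str | Path, n_reps: int | None = None, alpha: float = 0.05
) -> SignificanceProfile:
    df = pd.read_csv(path, sep="\t")
    return SignificanceProfile.from_frame(df, n_reps=n_reps, alpha=alpha)
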