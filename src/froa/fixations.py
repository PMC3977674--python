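"""Fixation-table I/O, preprocessing, and scanpath metrics.

Fixation tables are CSV files with one row per fixation:

    participant,group,trial,stimulus,fix_index,x_px,y_px,duration_ms

with 0-based pixel coordinates (origin top-left, x rightward, y downward) and
``fix_index`` 1-based and strictly increasing within a trial.

Preprocessing discards the first fixation of every trial (it reflects the
pre-trial central fixation, not stimulus-driven sampling) and removes
fixations that fall outside the stimulus frame.  Scanpath metrics are the
per-participant mean saccade amplitude (Euclidean distance between
consecutive retained fixations within a trial, converted to degrees of
visual angle) and the mean fixation duration (dwell time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, ViewingGeometry

__all__ = [
    "REQUIRED_COLUMNS",
    "FixationTableError",
    "read_fixations",
    "preprocess",
    "PreprocessSummary",
    "saccade_amplitudes",
    "dwell_times",
    "scanpath_metrics",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "participant",
    "group",
    "trial",
    "stimulus",
    "fix_index",
    "x_px",
    "y_px",
    "duration_ms",
]

_TRIAL_KEY = ["participant", "trial"]


class FixationTableError(ValueError):
    """Raised for malformed fixation tables; messages name the offending row."""


def read_fixations(path: str | Path) -> pd.DataFrame:
    """Read and validate a fixation CSV.

    Returns a typed DataFrame with an extra ``row`` column holding the 1-based
    data-row number in the source file (for error reporting downstream).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FixationTableError(f"{path}: missing required columns {missing}")
    df = df[REQUIRED_COLUMNS].copy()
    df["row"] = np.arange(1, len(df) + 1)
    if df.empty:
        logger.warning("%s: fixation table is empty", path)
        return df

    for col in ("trial", "fix_index"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df["row"][vals.isna()]
        if len(bad):
            raise FixationTableError(f"{path}: non-numeric {col} at row {int(bad.iloc[0])}")
        df[col] = vals.astype(int)
    for col in ("x_px", "y_px", "duration_ms"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df["row"][vals.isna()]
        if len(bad):
            raise FixationTableError(f"{path}: non-numeric {col} at row {int(bad.iloc[0])}")
        df[col] = vals.astype(float)

    bad = df["row"][df["duration_ms"] <= 0]
    if len(bad):
        raise FixationTableError(f"{path}: non-positive duration at row {int(bad.iloc[0])}")
    for (_, _), g in df.groupby(_TRIAL_KEY, sort=False):
        diffs = np.diff(g["fix_index"].to_numpy())
        if (diffs <= 0).any():
            row = int(g["row"].iloc[int(np.argmax(diffs <= 0)) + 1])
            raise FixationTableError(f"{path}: fix_index not strictly increasing at row {row}")
    return df


@dataclass
class PreprocessSummary:
    """Bookkeeping of what preprocessing removed."""

    n_first_discarded: int = 0
    n_out_of_frame: int = 0
    empty_trials: list[tuple] = field(default_factory=list)


def preprocess(
    records: pd.DataFrame, geometry: ViewingGeometry = DEFAULT_GEOMETRY
) -> tuple[pd.DataFrame, PreprocessSummary]:
    """Apply the standard fixation preprocessing.

    Per trial the fixation with ``fix_index == 1`` is discarded; fixations
    outside the frame are removed and counted; trials left with no fixations
    are flagged in the summary and contribute nothing downstream.
    """
    summary = PreprocessSummary()
    if records.empty:
        return records.copy(), summary
    df = records.copy()
    first = df["fix_index"] == 1
    summary.n_first_discarded = int(first.sum())
    df = df[~first]
    lim = geometry.frame_px
    inside = (
        (df["x_px"] >= 0) & (df["x_px"] < lim) & (df["y_px"] >= 0) & (df["y_px"] < lim)
    )
    summary.n_out_of_frame = int((~inside).sum())
    df = df[inside]
    kept = set(map(tuple, df[_TRIAL_KEY].drop_duplicates().itertuples(index=False)))
    all_trials = set(map(tuple, records[_TRIAL_KEY].drop_duplicates().itertuples(index=False)))
    summary.empty_trials = sorted(all_trials - kept)
    return df.reset_index(drop=True), summary


def saccade_amplitudes(
    records: pd.DataFrame, geometry: ViewingGeometry = DEFAULT_GEOMETRY
) -> pd.DataFrame:
    """Per-participant mean saccade amplitude in degrees of visual angle.

    Saccades are distances between consecutive retained fixations within a
    trial; they never span trial boundaries.  Participants with no saccades
    are excluded (with a warning).
    """
    rows = []
    for (participant, group), g in records.groupby(["participant", "group"], sort=True):
        amps = []
        for _, t in g.groupby("trial", sort=True):
            t = t.sort_values("fix_index")
            dx = np.diff(t["x_px"].to_numpy())
            dy = np.diff(t["y_px"].to_numpy())
            amps.append(np.hypot(dx, dy))
        amps = np.concatenate(amps) if amps else np.array([])
        if amps.size == 0:
            logger.warning("participant %s has no saccades; excluded", participant)
            continue
        rows.append(
            (participant, group, float(np.mean(amps)) / geometry.px_per_deg, amps.size)
        )
    return pd.DataFrame(
        rows, columns=["participant", "group", "mean_amplitude_deg", "n_saccades"]
    )


def dwell_times(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean fixation duration (ms)."""
    rows = []
    for (participant, group), g in records.groupby(["participant", "group"], sort=True):
        if g.empty:
            continue
        rows.append((participant, group, float(g["duration_ms"].mean()), len(g)))
    return pd.DataFrame(
        rows, columns=["participant", "group", "mean_dwell_ms", "n_fixations"]
    )


def scanpath_metrics(
    records: pd.DataFrame, geometry: ViewingGeometry = DEFAULT_GEOMETRY
) -> pd.DataFrame:
    """Combined per-participant metrics table
    (``participant,group,mean_amplitude_deg,mean_dwell_ms,n_saccades``)."""
    amp = saccade_amplitudes(records, geometry)
    dwell = dwell_times(records)
    out = amp.merge(dwell[["participant", "mean_dwell_ms"]], on="participant", how="outer")
    out["group"] = out["participant"].map(
        dict(zip(dwell["participant"], dwell["group"]))
    )
    return out[["participant", "group", "mean_amplitude_deg", "mean_dwell_ms", "n_saccades"]]
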