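"""Head-motion quality control.

Framewise displacement (FD) follows the Power convention: the sum of
absolute backward differences of the six rigid-body parameters, with
rotations converted to millimetres of arc on a 50 mm sphere. Frames
with FD above threshold are flagged together with their immediate
temporal neighbors; a run is excluded when more than a configurable
fraction (default 40%) of its frames are flagged; a participant is
retained only when all required runs are present and retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "FrameMask",
    "compute_fd",
    "flag_frames",
    "evaluate_run",
    "select_participants",
    "load_motion_file",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_MAX_FLAGGED_FRACTION = 0.40


@dataclass(frozen=True)
class MotionTrace:
    """Rigid-body motion parameters for one run.

    ``values`` is frames x 6: three translations in mm then three
    rotations (radians by default; set ``rotation_unit='degrees'`` for
    the HCP Movement_Regressors dialect, which also puts translations
    first).
    """

    values: np.ndarray
    rotation_unit: str = "radians"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] < 6:
            raise ValueError("motion trace must be frames x >=6")
        if v.shape[0] < 2:
            raise ValueError("motion trace needs at least 2 frames")
        object.__setattr__(self, "values", v)
        if self.rotation_unit not in ("radians", "degrees"):
            raise ValueError(f"unknown rotation unit {self.rotation_unit!r}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FrameMask:
    """Per-frame FD and high-motion flags for one run."""

    fd: np.ndarray
    flagged: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.fd.shape[0]

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def flagged_fraction(self) -> float:
        return self.n_flagged / self.n_frames


def compute_fd(
    trace: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement per frame (Power convention); fd[0] = 0."""
    if head_radius <= 0:
        raise ValueError("head_radius must be positive")
    v = trace.values[:, :6].copy()
    bad = ~np.isfinite(v)
    if bad.any():
        frame = int(np.argwhere(bad)[0, 0])
        raise ValueError(f"non-finite motion parameter at frame {frame}")
    if trace.rotation_unit == "degrees":
        v[:, 3:6] = np.deg2rad(v[:, 3:6])
    d = np.abs(np.diff(v, axis=0))
    fd = np.empty(trace.n_frames)
    fd[0] = 0.0
    fd[1:] = d[:, :3].sum(axis=1) + head_radius * d[:, 3:6].sum(axis=1)
    return fd


def flag_frames(
    fd: Sequence[float] | np.ndarray, threshold: float = DEFAULT_FD_THRESHOLD_MM
) -> FrameMask:
    """Flag frames with fd > threshold plus their immediate temporal
    neighbors (boundary frames expand only inward)."""
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD sequence")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    high = fd > threshold
    flagged = high.copy()
    flagged[:-1] |= high[1:]
    flagged[1:] |= high[:-1]
    return FrameMask(fd=fd, flagged=flagged)


def evaluate_run(
    mask: FrameMask, max_fraction: float = DEFAULT_MAX_FLAGGED_FRACTION
) -> str:
    """'excluded' iff strictly more than ``max_fraction`` of frames are
    flagged, else 'retained'."""
    if not 0.0 < max_fraction < 1.0:
        raise ValueError("max_fraction must be in (0, 1)")
    return "excluded" if mask.flagged_fraction > max_fraction else "retained"


def select_participants(
    run_masks: Mapping[str, Mapping[str, FrameMask]],
    runs_required: int = 4,
    max_fraction: float = DEFAULT_MAX_FLAGGED_FRACTION,
) -> pd.DataFrame:
    """Apply the participant-level inclusion rule.

    ``run_masks`` maps participant id -> {run id -> FrameMask}. A
    participant is retained iff exactly ``runs_required`` runs are
    present and every one of them is individually retained. The mean-FD
    covariate is the grand mean of FD over all frames of all runs
    (flagged frames included).
    """
    rows = []
    for pid, runs in run_masks.items():
        if len(set(runs)) != len(runs):
            raise ValueError(f"duplicate run identifiers for {pid}")
        decisions = {rid: evaluate_run(m, max_fraction) for rid, m in runs.items()}
        complete = len(runs) == runs_required
        all_clean = all(d == "retained" for d in decisions.values())
        fd_all = np.concatenate([m.fd for m in runs.values()]) if runs else np.array([])
        rows.append(
            {
                "participant_id": pid,
                "n_runs": len(runs),
                "n_runs_excluded": sum(d == "excluded" for d in decisions.values()),
                "mean_fd": float(fd_all.mean()) if fd_all.size else math.nan,
                "retained": complete and all_clean,
            }
        )
    return pd.DataFrame(rows)


def qc_report(
    run_masks: Mapping[str, Mapping[str, FrameMask]],
    max_fraction: float = DEFAULT_MAX_FLAGGED_FRACTION,
) -> pd.DataFrame:
    """Per-run QC table (participant, run, n_frames, n_flagged,
    fraction, decision)."""
    rows = []
    for pid, runs in run_masks.items():
        for rid, m in runs.items():
            rows.append(
                {
                    "participant_id": pid,
                    "run": rid,
                    "n_frames": m.n_frames,
                    "n_flagged": m.n_flagged,
                    "flagged_fraction": m.flagged_fraction,
                    "decision": evaluate_run(m, max_fraction),
                }
            )
    return pd.DataFrame(rows)


def load_motion_file(
    path: str | Path, rotation_unit: str = "radians"
) -> MotionTrace:
    """Read a whitespace-delimited motion file (frames x 6, or x 12 with
    derivative columns which are ignored)."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] < 6:
        raise ValueError(f"{path}: expected >= 6 columns, got {arr.shape[1]}")
    return MotionTrace(values=arr[:, :6], rotation_unit=rotation_unit)
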