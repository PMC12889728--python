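"""Weighted connectome construction from parcellated time series.

Each run is de-meaned and variance-normalized per parcel, full Pearson
correlation is computed, Fisher z-transformed, and the retained runs
are averaged element-wise in z space. A weighting scheme then maps the
signed z matrix to nonnegative edge weights: absolute value (default),
positive-only, or negative-only. Weights stay in Fisher-z space; the
diagonal is fixed at zero (no self-loops); the graph is complete and
weighted — no thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "WeightedGraph",
    "standardize_timeseries",
    "correlation_matrix",
    "fisher_z",
    "average_runs",
    "apply_weight_scheme",
    "build_connectome",
    "load_timeseries",
    "save_matrix",
    "load_matrix",
]

WEIGHT_SCHEMES = ("abs", "positive_only", "negative_only")
DEFAULT_CLIP = 1e-7


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric parcels x parcels Fisher-z connectivity, zero diagonal."""

    z: np.ndarray
    parcel_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.isfinite(z).all():
            raise ValueError("connectivity matrix has non-finite entries")
        if np.abs(z - z.T).max() > 1e-12:
            raise ValueError("connectivity matrix not symmetric")
        if np.abs(np.diag(z)).max() > 0:
            raise ValueError("connectivity diagonal must be zero")
        object.__setattr__(self, "z", z)

    @property
    def n_parcels(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class WeightedGraph:
    """Complete weighted graph over parcels: nonnegative symmetric
    weights in Fisher-z units, zero diagonal, provenance scheme."""

    weights: np.ndarray
    scheme: str = "abs"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.abs(np.diag(w)).max() > 0:
            raise ValueError("weight diagonal must be zero")
        if self.scheme not in WEIGHT_SCHEMES:
            raise ValueError(f"unknown weighting scheme {self.scheme!r}")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def standardize_timeseries(ts: np.ndarray) -> np.ndarray:
    """Column-standardize (mean 0, SD 1 with n-1 denominator) a frames x
    parcels matrix."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be frames x parcels")
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 frames")
    sd = ts.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance parcel at column {int(zero[0])}")
    return (ts - ts.mean(axis=0)) / sd


def correlation_matrix(ts: np.ndarray) -> np.ndarray:
    """Full Pearson correlation between parcels of a (standardized)
    frames x parcels matrix."""
    z = standardize_timeseries(ts)
    n = z.shape[0]
    r = (z.T @ z) / (n - 1)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray, clip: float = DEFAULT_CLIP) -> np.ndarray:
    """arctanh with magnitude clipped at 1-clip; diagonal zeroed."""
    r = np.asarray(r, dtype=float)
    if np.abs(r).max() > 1 + 1e-12:
        raise ValueError("correlations outside [-1, 1]")
    z = np.arctanh(np.clip(r, -(1 - clip), 1 - clip))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    return z


def average_runs(z_matrices: Sequence[np.ndarray]) -> ConnectivityMatrix:
    """Element-wise mean of per-run Fisher-z matrices."""
    if len(z_matrices) == 0:
        raise ValueError("no runs to average")
    shapes = {np.asarray(m).shape for m in z_matrices}
    if len(shapes) != 1:
        raise ValueError(f"run matrices have mismatched shapes: {sorted(shapes)}")
    z = np.mean([np.asarray(m, dtype=float) for m in z_matrices], axis=0)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z)


def apply_weight_scheme(cm: ConnectivityMatrix, scheme: str = "abs") -> WeightedGraph:
    """Map signed Fisher-z connectivity to nonnegative edge weights."""
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    z = cm.z
    if scheme == "abs":
        w = np.abs(z)
    elif scheme == "positive_only":
        w = np.maximum(z, 0.0)
    else:
        w = np.abs(np.minimum(z, 0.0))
    return WeightedGraph(weights=w, scheme=scheme)


def build_connectome(
    runs: Iterable[np.ndarray], clip: float = DEFAULT_CLIP
) -> ConnectivityMatrix:
    """Full per-participant path: per run standardize -> correlate ->
    Fisher z; then average across runs.

    Vectorized over runs; numerically identical to applying
    :func:`correlation_matrix` and :func:`fisher_z` run by run and
    averaging with :func:`average_runs`.
    """
    arr = np.stack([np.asarray(r, dtype=float) for r in runs])
    if arr.ndim != 3:
        raise ValueError("runs must be a sequence of frames x parcels matrices")
    n_runs, t, p = arr.shape
    if t < 3:
        raise ValueError("need at least 3 frames")
    arr = arr - arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        parcel = int(np.argwhere(sd[:, 0, :] == 0)[0, 1])
        raise ValueError(f"zero-variance parcel at column {parcel}")
    std = arr / sd
    r = (std.transpose(0, 2, 1) @ std) / (t - 1)
    r = (r + r.transpose(0, 2, 1)) / 2.0
    z = np.arctanh(np.clip(r, -(1 - clip), 1 - clip))
    z = z.mean(axis=0)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z)


# ---------------------------------------------------------------------------
# text I/O


def load_timeseries(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a frames x parcels TSV with a header row of parcel ids."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def save_matrix(
    m: np.ndarray, parcel_ids: Sequence[str], path: str | Path
) -> None:
    """Write a square matrix as TSV with parcel ids as header row and
    first column."""
    pd.DataFrame(m, index=list(parcel_ids), columns=list(parcel_ids)).to_csv(
        path, sep="\t"
    )


def load_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
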