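"""Synthetic multi-site cohort generator with known planted effects.

Emulates the structure of a lifespan resting-state fMRI study: a cohort
aged 36-100 scanned at S sites with four runs per participant, a
loneliness T-score (population mean 50, SD 10) driven by
socio-demographic factors, per-run head-motion traces, and per-run
parcellated BOLD time series drawn from a block-modular multivariate
normal whose correlation structure carries

* an age main effect: within-network correlations weaken linearly with
  standardized age (slope ``gamma_age``), and
* a loneliness-by-age interaction planted on the within-network
  neighborhood of designated nodes: those edges are shifted by
  ``gamma_interaction * z_loneliness * z_age``, so the sign of the
  loneliness association reverses across the age midpoint. This
  directly modulates the local interconnectivity (clustering
  coefficient) of the designated nodes.

Every generator is deterministic given (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .motion import MotionTrace
from .parcellation import Parcellation, default_parcellation

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_motion",
    "generate_timeseries",
    "simulate_cohort_data",
]

#: Default standardized behavioral effects on the loneliness T-score
#: (outcome-SD units): younger, male, unmarried and living-alone
#: participants report more loneliness.
DEFAULT_BEHAVIORAL = {
    "age": -0.24,
    "male": 0.25,
    "unmarried": 0.31,
    "alone": 0.32,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults are the desk-scale stand-in for a 718-parcel multi-site
    lifespan study: 60 parcels over the 12 networks, 4 sites, 4 runs of
    300 frames each, within/between-network base correlations 0.5/0.1.
    """

    n_participants: int = 200
    n_sites: int = 4
    n_parcels: int = 60
    n_networks: int = 12
    n_runs: int = 4
    frames_per_run: int = 300
    age_range: tuple[float, float] = (36.0, 100.0)
    rho_within: float = 0.5
    rho_between: float = 0.1
    #: drop in within-network correlation per SD of age
    gamma_age: float = 0.1
    #: edge shift per unit z_loneliness*z_age on designated neighborhoods
    gamma_interaction: float = 0.0
    #: nodes whose within-network neighborhood carries the interaction
    designated_nodes: tuple[int, ...] = ()
    behavioral_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIORAL)
    )
    #: optional AR(1) coefficient for temporal autocorrelation (off by default)
    ar1: float = 0.0
    #: proportion of injected high-motion spike frames per run
    motion_contamination: float = 0.0
    #: constant correlation of the one anchor edge per network (the
    #: stable extreme tail of real connectomes, e.g. homotopic pairs);
    #: 0 disables anchors
    anchor_rho: float = 0.8
    #: absolute cap for modulated off-diagonal target correlations,
    #: kept below anchor_rho so anchors stay the strongest edges
    correlation_cap: float = 0.7
    #: max allowed per-entry change during PSD repair
    psd_repair_tol: float = 0.25

    def validate(self) -> None:
        if self.n_participants < 2 * self.n_sites:
            raise ValueError(
                f"n_participants={self.n_participants} must be >= "
                f"2*n_sites={2 * self.n_sites} to estimate per-site variance"
            )
        for name in ("rho_within", "rho_between"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (-1, 1)")
        if not 0.0 <= self.anchor_rho < 1.0:
            raise ValueError("anchor_rho outside [0, 1)")
        coeffs = dict(self.behavioral_coefficients)
        coeffs["gamma_age"] = self.gamma_age
        coeffs["gamma_interaction"] = self.gamma_interaction
        for k, v in coeffs.items():
            if not math.isfinite(v):
                raise ValueError(f"coefficient {k!r} is not finite")
        if not 0.0 <= self.motion_contamination <= 1.0:
            raise ValueError("motion_contamination outside [0, 1]")
        for d in self.designated_nodes:
            if not 0 <= d < self.n_parcels:
                raise ValueError(f"designated node {d} outside [0, {self.n_parcels})")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("ar1 outside (-1, 1)")

    def parcellation(self) -> Parcellation:
        return default_parcellation(self.n_parcels, self.n_networks)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load a config from a YAML or JSON file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CohortConfig":
        kwargs = dict(raw)
        kwargs.pop("seed", None)  # seed travels separately
        if "designated_nodes" in kwargs and kwargs["designated_nodes"] is not None:
            kwargs["designated_nodes"] = tuple(kwargs["designated_nodes"])
        if "age_range" in kwargs:
            kwargs["age_range"] = tuple(kwargs["age_range"])
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """The effect structure actually used during generation.

    Together with the config and master seed this fully determines the
    generated cohort; it is what parameter-recovery tests compare
    against.
    """

    gamma_age: float
    gamma_interaction: float
    designated_nodes: tuple[int, ...]
    rho_within: float
    rho_between: float
    behavioral_coefficients: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["designated_nodes"] = tuple(d["designated_nodes"])
        return cls(**d)


def _age_sd(age_range: tuple[float, float]) -> float:
    lo, hi = age_range
    return (hi - lo) / math.sqrt(12.0)  # SD of the uniform draw


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the covariate table for one cohort.

    The loneliness T-score is 50 plus a linear predictor in standardized
    age and the binary factors (coefficients in outcome-SD units, i.e.
    T-score points / 10) plus Gaussian noise scaled so the marginal SD
    is approximately 10.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0C0]))
    n = config.n_participants
    lo, hi = config.age_range

    age = rng.uniform(lo, hi, size=n)
    sex = rng.choice(["male", "female"], size=n)
    marital = rng.choice(["married", "unmarried"], size=n, p=[0.55, 0.45])
    household = rng.choice(["alone", "with_others"], size=n, p=[0.25, 0.75])
    employment = rng.choice(["employed", "unemployed"], size=n, p=[0.7, 0.3])
    education = rng.choice(
        ["hs_or_below", "college", "graduate"], size=n, p=[0.1, 0.55, 0.35]
    )
    # positively skewed family income (thousands of currency units)
    income = np.exp(rng.normal(math.log(70.0), 0.8, size=n))
    moca = np.clip(np.round(rng.normal(26.0, 2.5, size=n)), 0, 30)
    # gray-matter volume declines with age (arbitrary units)
    gmv = 700.0 - 1.2 * age + rng.normal(0.0, 40.0, size=n)
    site = rng.integers(0, config.n_sites, size=n)

    b = dict(config.behavioral_coefficients)
    z_age = (age - (lo + hi) / 2.0) / _age_sd(config.age_range)
    predictor = 10.0 * (
        b.get("age", 0.0) * z_age
        + b.get("male", 0.0) * (sex == "male")
        + b.get("unmarried", 0.0) * (marital == "unmarried")
        + b.get("alone", 0.0) * (household == "alone")
    )
    resid_var = max(100.0 - float(np.var(predictor)), 1.0)
    loneliness = 50.0 + predictor + rng.normal(0.0, math.sqrt(resid_var), size=n)

    cohort = pd.DataFrame(
        {
            "participant_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "marital": marital,
            "household": household,
            "employment": employment,
            "education": education,
            "income": income,
            "loneliness_t": loneliness,
            "moca": moca,
            "gmv": gmv,
            "site": [f"site{s + 1}" for s in site],
        }
    )
    truth = GroundTruth(
        gamma_age=config.gamma_age,
        gamma_interaction=config.gamma_interaction,
        designated_nodes=tuple(config.designated_nodes),
        rho_within=config.rho_within,
        rho_between=config.rho_between,
        behavioral_coefficients={k: float(v) for k, v in b.items()},
        seed=int(seed),
    )
    return cohort, truth


def generate_motion(
    n_frames: int,
    contamination_level: float,
    seed: int,
    step_sd: float = 0.02,
    spike_size: float = 1.0,
) -> MotionTrace:
    """Six-parameter random-walk motion trace for one run.

    ``contamination_level`` is the proportion of frames that receive an
    injected displacement spike of ``spike_size`` mm (applied for a
    single frame on a random translation axis), which produces a
    framewise displacement well above the conventional 0.5 mm flagging
    threshold under the Power convention.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not 0.0 <= contamination_level <= 1.0:
        raise ValueError("contamination_level outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x307]))
    steps = rng.normal(0.0, step_sd, size=(n_frames, 6))
    steps[0] = 0.0
    # rotations move much less than translations in radians
    steps[:, 3:] *= 0.01
    values = np.cumsum(steps, axis=0)

    n_spikes = int(round(contamination_level * n_frames))
    if n_spikes > 0:
        candidates = np.arange(1, n_frames)
        spikes = rng.choice(candidates, size=min(n_spikes, n_frames - 1), replace=False)
        for t in spikes:
            axis = rng.integers(0, 3)
            values[t, axis] += spike_size * rng.choice([-1.0, 1.0])
    return MotionTrace(values=values)


# ---------------------------------------------------------------------------
# time-series generation


def _nearest_psd(r: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to PSD by eigenvalue clipping, then
    re-normalize to unit diagonal."""
    w, v = np.linalg.eigh(r)
    if w[0] >= eps:
        return r
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def target_correlation(
    cohort_row: Mapping,
    parcellation: Parcellation,
    config: CohortConfig,
) -> np.ndarray:
    """Participant-specific target correlation matrix.

    Within-network entries are ``rho_within - gamma_age * z_age``;
    between-network entries are ``rho_between``. For each designated
    node, all edges inside its within-network neighborhood (its own
    within-network edges and the edges among its network peers) are
    additionally shifted by ``gamma_interaction * z_lone * z_age``.
    Modulated entries are capped at ``correlation_cap`` in absolute
    value; one anchor edge per network is then pinned at the constant
    ``anchor_rho`` (the stable extreme tail of real connectomes, which
    keeps the graph's maximum weight — and with it the Onnela
    clustering normalization — decoupled from the planted effects);
    finally the matrix is repaired to positive semi-definite.
    """
    lo, hi = config.age_range
    z_age = (float(cohort_row["age"]) - (lo + hi) / 2.0) / _age_sd(config.age_range)
    z_lone = (float(cohort_row["loneliness_t"]) - 50.0) / 10.0

    labels = parcellation.labels
    same = labels[:, None] == labels[None, :]
    p = parcellation.n_parcels
    r = np.where(same, config.rho_within - config.gamma_age * z_age, config.rho_between)

    if config.gamma_interaction != 0.0 and config.designated_nodes:
        shift = config.gamma_interaction * z_lone * z_age
        for d in config.designated_nodes:
            block = np.flatnonzero(labels == labels[d])
            r[np.ix_(block, block)] += shift

    # within-network entries degrade toward (not below) the
    # between-network background; a whole block of strongly negative
    # pairwise correlations would be geometrically impossible anyway
    floor = min(config.rho_between, config.rho_within)
    r = np.where(
        same,
        np.clip(r, floor, config.correlation_cap),
        np.clip(r, -config.correlation_cap, config.correlation_cap),
    )
    if config.anchor_rho > 0:
        for m in range(parcellation.n_networks):
            block = np.flatnonzero(labels == m)
            if block.size >= 2:
                a, b = block[0], block[1]
                r[a, b] = r[b, a] = config.anchor_rho
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)

    fixed = _nearest_psd(r)
    delta = float(np.max(np.abs(fixed - r)))
    if delta > config.psd_repair_tol:
        raise ValueError(
            f"PSD repair moved an entry by {delta:.3f} "
            f"(> psd_repair_tol={config.psd_repair_tol}); "
            "target correlation structure is not attainable"
        )
    return fixed


def _sample_runs(
    chol: np.ndarray,
    n_runs: int,
    n_frames: int,
    ar1: float,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    p = chol.shape[0]
    e = rng.standard_normal((n_runs, n_frames, p))
    if ar1 != 0.0:
        c = math.sqrt(1.0 - ar1 * ar1)
        for t in range(1, n_frames):
            e[:, t] = ar1 * e[:, t - 1] + c * e[:, t]
    return list(e @ chol.T)


def generate_timeseries(
    cohort_row: Mapping,
    parcellation: Parcellation,
    config: CohortConfig,
    seed: int,
    _chol_cache: dict | None = None,
) -> list[np.ndarray]:
    """Draw the participant's runs (each ``frames_per_run x n_parcels``)
    from the stationary multivariate normal with the participant's
    target correlation matrix."""
    if config.frames_per_run < 3:
        raise ValueError("frames_per_run must be >= 3")
    chol = None
    if _chol_cache is not None:
        # the target matrix depends on the row only through these two
        # scalars, so replicated rows share one Cholesky factor
        lo, hi = config.age_range
        z_age = (float(cohort_row["age"]) - (lo + hi) / 2.0) / _age_sd(config.age_range)
        z_lone = (float(cohort_row["loneliness_t"]) - 50.0) / 10.0
        key = (
            round(config.gamma_age * z_age, 12),
            round(config.gamma_interaction * z_lone * z_age, 12),
        )
        chol = _chol_cache.get(key)
    if chol is None:
        r = target_correlation(cohort_row, parcellation, config)
        try:
            chol = np.linalg.cholesky(r)
        except np.linalg.LinAlgError:
            # PSD but numerically singular: jitter the diagonal
            chol = np.linalg.cholesky(r + 1e-9 * np.eye(r.shape[0]))
        if _chol_cache is not None:
            _chol_cache[key] = chol
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x75]))
    return _sample_runs(chol, config.n_runs, config.frames_per_run, config.ar1, rng)


def simulate_cohort_data(
    config: CohortConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth, dict[str, list[np.ndarray]], dict[str, list[MotionTrace]]]:
    """Generate a full cohort: covariates, per-run time series and
    per-run motion traces, keyed by participant id.

    The master seed fans out to independent per-participant child seeds,
    so individual participants are reproducible in isolation.
    """
    cohort, truth = generate_cohort(config, seed)
    parc = config.parcellation()
    ss = np.random.SeedSequence([int(seed), 0xDA7A])
    child_seeds = ss.generate_state(2 * len(cohort)) % (2**31)
    cache: dict = {}
    timeseries: dict[str, list[np.ndarray]] = {}
    motion: dict[str, list[MotionTrace]] = {}
    for i, row in enumerate(cohort.to_dict("records")):
        pid = row["participant_id"]
        timeseries[pid] = generate_timeseries(
            row, parc, config, int(child_seeds[2 * i]), _chol_cache=cache
        )
        mrng_seed = int(child_seeds[2 * i + 1])
        motion[pid] = [
            generate_motion(
                config.frames_per_run,
                config.motion_contamination,
                mrng_seed + r,
            )
            for r in range(config.n_runs)
        ]
    return cohort, truth, timeseries, motion


def null_config(**overrides) -> CohortConfig:
    """A config with every planted effect switched off (global null)."""
    base = CohortConfig(
        gamma_age=0.0,
        gamma_interaction=0.0,
        designated_nodes=(),
        behavioral_coefficients={"age": 0.0, "male": 0.0, "unmarried": 0.0, "alone": 0.0},
    )
    return replace(base, **overrides)
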