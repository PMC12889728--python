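"""Mass-univariate permutation GLM with site exchangeability blocks.

Each graph metric (participants x nodes) is regressed on loneliness,
age and their interaction plus nuisance covariates. Inference follows
the PALM conventions:

* the test statistic is the Aspin-Welch v: ordinary-least-squares
  contrast estimate divided by a heteroscedasticity-adjusted standard
  error in which each variance group (scanning site) contributes weight
  (its share of residual degrees of freedom) / (its residual sum of
  squares). With a single variance group v reduces exactly to the
  classical t statistic;
* permutation uses the Freedman-Lane scheme — residuals from the
  nuisance-only model are permuted within exchangeability blocks
  (sites) and the full model is refit;
* p-values are two-tailed with the +1 offset, p = (1 + #{|v*| >=
  |v_obs|}) / (1 + n_perm); family-wise error is controlled by the
  distribution of the maximum |v*| across the nodes of each metric;
* the reported z-score is the inverse-normal transform of the
  two-tailed permutation p, signed by the observed statistic.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DesignMatrix",
    "PermutationResult",
    "build_design",
    "aspin_welch_v",
    "permute_within_blocks",
    "run_permutation_glm",
    "fwe_correct",
]

#: predictor columns of interest, in design order
CONTRAST_NAMES = ("loneliness", "age", "interaction")


@dataclass(frozen=True)
class DesignMatrix:
    """Predictor matrix with contrasts, exchangeability blocks and
    variance groups (both = scanning site)."""

    X: np.ndarray
    columns: tuple[str, ...]
    contrasts: dict[str, np.ndarray]
    blocks: np.ndarray
    variance_groups: np.ndarray
    participant_ids: tuple[str, ...]
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(
    cohort: pd.DataFrame,
    model: str = "base",
) -> DesignMatrix:
    """Build the GLM design from a cohort table.

    ``model='base'`` uses loneliness, age, their interaction, and the
    covariates sex, MoCA, mean FD, total GMV and site dummies;
    ``model='adjusted'`` additionally includes marital and household
    status. Rows with missing values in any used column are dropped
    (count recorded). Continuous predictors are mean-centered before
    the interaction term is formed; site enters as K-1 dummies and also
    defines exchangeability blocks and variance groups.
    """
    if model not in ("base", "adjusted"):
        raise ValueError(f"unknown model {model!r}")
    needed = ["participant_id", "loneliness_t", "age", "sex", "moca", "mean_fd", "gmv", "site"]
    if model == "adjusted":
        needed += ["marital", "household"]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {missing_cols}")
    df = cohort[needed].copy()
    complete = df.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    df = df[complete].reset_index(drop=True)

    sites = sorted(df["site"].astype(str).unique())
    counts = df["site"].value_counts()
    small = [s for s in sites if counts[s] < 3]
    if small:
        raise ValueError(f"sites with fewer than 3 members: {small}")

    def centered(col: str) -> np.ndarray:
        v = df[col].to_numpy(dtype=float)
        return v - v.mean()

    lone = centered("loneliness_t")
    age = centered("age")
    cols: list[tuple[str, np.ndarray]] = [
        ("intercept", np.ones(len(df))),
        ("loneliness", lone),
        ("age", age),
        ("interaction", lone * age),
        ("sex_male", (df["sex"].astype(str) == "male").to_numpy(float)),
        ("moca", centered("moca")),
        ("mean_fd", centered("mean_fd")),
        ("gmv", centered("gmv")),
    ]
    if model == "adjusted":
        cols.append(
            ("marital_unmarried", (df["marital"].astype(str) == "unmarried").to_numpy(float))
        )
        cols.append(
            ("household_alone", (df["household"].astype(str) == "alone").to_numpy(float))
        )
    for s in sites[1:]:  # first site is the reference
        cols.append((f"site_{s}", (df["site"].astype(str) == s).to_numpy(float)))

    names = tuple(c[0] for c in cols)
    X = np.column_stack([c[1] for c in cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    site_codes = df["site"].astype(str).map({s: i for i, s in enumerate(sites)}).to_numpy()
    contrasts = {}
    for name in CONTRAST_NAMES:
        c = np.zeros(X.shape[1])
        c[names.index(name)] = 1.0
        contrasts[name] = c
    return DesignMatrix(
        X=X,
        columns=names,
        contrasts=contrasts,
        blocks=site_codes,
        variance_groups=site_codes,
        participant_ids=tuple(df["participant_id"].astype(str)),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Aspin-Welch v statistic


class _VStatEngine:
    """Precomputed pieces for evaluating the Aspin-Welch v statistic of
    one contrast over many response columns."""

    def __init__(self, X: np.ndarray, contrast: np.ndarray, groups: np.ndarray):
        self.X = X
        self.c = np.asarray(contrast, dtype=float)
        self.pinv = np.linalg.pinv(X)
        leverage = np.einsum("ij,ji->i", X, self.pinv)
        dRm = 1.0 - leverage
        codes = np.unique(groups)
        self.masks = [groups == g for g in codes]
        self.dRm_sums = np.array([dRm[m].sum() for m in self.masks])
        self.Gb = np.stack([X[m].T @ X[m] for m in self.masks])

    def v(self, Y: np.ndarray) -> np.ndarray:
        """v statistic per column of Y (n x V)."""
        beta = self.pinv @ Y
        res = Y - self.X @ beta
        rss = np.stack([(res[m] ** 2).sum(axis=0) for m in self.masks])
        yss = np.stack([(Y[m] ** 2).sum(axis=0) for m in self.masks])
        if (rss <= 1e-14 * np.maximum(yss, 1.0)).any():
            raise ValueError("a variance group has zero residual sum of squares")
        w = self.dRm_sums[:, None] / rss  # groups x V
        cte = np.einsum("bv,bij->vij", w, self.Gb)
        rhs = np.broadcast_to(self.c, (Y.shape[1], len(self.c)))[..., None]
        sol = np.linalg.solve(cte, rhs)[..., 0]
        den = sol @ self.c
        num = self.c @ beta
        return num / np.sqrt(den)


def aspin_welch_v(
    y: np.ndarray,
    X: np.ndarray,
    contrast: np.ndarray,
    variance_groups: np.ndarray | None = None,
) -> float | np.ndarray:
    """Aspin-Welch v for one response (or one per column of a 2-D y).

    With a single variance group this equals the classical OLS t
    statistic on the same contrast.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if variance_groups is None:
        variance_groups = np.zeros(X.shape[0], dtype=int)
    engine = _VStatEngine(X, contrast, np.asarray(variance_groups))
    if y.ndim == 1:
        return float(engine.v(y[:, None])[0])
    return engine.v(y)


# ---------------------------------------------------------------------------
# permutations


def permute_within_blocks(
    n: int, blocks: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random permutation of 0..n-1 that maps every block onto
    itself."""
    blocks = np.asarray(blocks)
    if blocks.shape[0] != n:
        raise ValueError("blocks must have length n")
    perm = np.arange(n)
    for g in np.unique(blocks):
        idx = np.flatnonzero(blocks == g)
        perm[idx] = idx[rng.permutation(idx.size)]
    return perm


def _count_block_permutations(blocks: np.ndarray, cap: int) -> int:
    """Number of distinct within-block permutations, saturating at cap+1."""
    total = 1
    for g in np.unique(blocks):
        total *= math.factorial(int((blocks == g).sum()))
        if total > cap:
            return cap + 1
    return total


def _enumerate_block_permutations(blocks: np.ndarray) -> Iterator[np.ndarray]:
    """Yield every distinct within-block permutation (identity first)."""
    groups = [np.flatnonzero(blocks == g) for g in np.unique(blocks)]
    per_group = [list(itertools.permutations(idx)) for idx in groups]
    n = blocks.shape[0]
    for combo in itertools.product(*per_group):
        perm = np.empty(n, dtype=int)
        for idx, arranged in zip(groups, combo):
            perm[idx] = arranged
        yield perm


@dataclass(frozen=True)
class PermutationResult:
    """Per-node, per-contrast permutation inference for one metric."""

    tables: dict[str, pd.DataFrame]
    max_distributions: dict[str, np.ndarray]
    n_perm: int
    seed: int
    exhaustive: bool = False

    def table(self, contrast: str) -> pd.DataFrame:
        return self.tables[contrast]

    def to_tsv(self, path: str | Path, metric_name: str = "metric") -> None:
        frames = []
        for contrast, t in self.tables.items():
            t = t.copy()
            t.insert(0, "contrast", contrast)
            frames.append(t)
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def run_permutation_glm(
    metric_table: pd.DataFrame | np.ndarray,
    design: DesignMatrix,
    n_perm: int = 5000,
    seed: int = 0,
    contrasts: Sequence[str] | None = None,
    node_ids: Sequence[str] | None = None,
) -> PermutationResult:
    """Freedman-Lane permutation GLM for one metric table.

    ``metric_table`` is participants x nodes (a 1-column table for
    global metrics); rows must align with the design (a DataFrame is
    re-indexed by participant id). When the number of distinct
    within-block permutations does not exceed ``n_perm`` the test
    enumerates them exhaustively instead of sampling.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if isinstance(metric_table, pd.DataFrame):
        missing = [p for p in design.participant_ids if p not in metric_table.index]
        if missing:
            raise ValueError(
                f"metric table is missing {len(missing)} design rows "
                f"(first: {missing[0]})"
            )
        if node_ids is None:
            node_ids = [str(c) for c in metric_table.columns]
        Y = metric_table.loc[list(design.participant_ids)].to_numpy(dtype=float)
    else:
        Y = np.asarray(metric_table, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != design.n:
            raise ValueError(
                f"metric table has {Y.shape[0]} rows but design has {design.n}"
            )
    if not np.isfinite(Y).all():
        raise ValueError("metric table has non-finite values")
    if node_ids is None:
        node_ids = [f"node{i}" for i in range(Y.shape[1])]

    if contrasts is None:
        contrasts = list(design.contrasts)
    X = design.X
    n, V = Y.shape

    n_distinct = _count_block_permutations(design.blocks, cap=n_perm)
    exhaustive = n_distinct <= n_perm
    if exhaustive and n_distinct < n_perm:
        warnings.warn(
            f"only {n_distinct} distinct within-block permutations exist; "
            "enumerating exhaustively",
            stacklevel=2,
        )

    tables: dict[str, pd.DataFrame] = {}
    maxdists: dict[str, np.ndarray] = {}
    for ci, cname in enumerate(contrasts):
        c = design.contrasts[cname]
        j = int(np.flatnonzero(c != 0)[0])
        Z = np.delete(X, j, axis=1)
        Hz = Z @ np.linalg.pinv(Z)
        E = Y - Hz @ Y  # nuisance-only residuals
        fitted = Y - E
        engine = _VStatEngine(X, c, design.variance_groups)
        v_obs = engine.v(Y)
        abs_obs = np.abs(v_obs)

        if exhaustive:
            count_ge = np.zeros(V)
            maxstats = []
            for perm in _enumerate_block_permutations(design.blocks):
                v_star = engine.v(E[perm] + fitted)
                a = np.abs(v_star)
                count_ge += a >= abs_obs
                maxstats.append(a.max())
            maxstats = np.asarray(maxstats)
            denom = maxstats.shape[0]
            p_unc = count_ge / denom  # identity permutation included
            p_fwe = (maxstats[:, None] >= abs_obs[None, :]).sum(axis=0) / denom
            n_used = denom
        else:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x61, ci]))
            count_ge = np.zeros(V)
            maxstats = np.empty(n_perm)
            for b in range(n_perm):
                perm = permute_within_blocks(n, design.blocks, rng)
                v_star = engine.v(E[perm] + fitted)
                a = np.abs(v_star)
                count_ge += a >= abs_obs
                maxstats[b] = a.max()
            p_unc = (1.0 + count_ge) / (1.0 + n_perm)
            p_fwe = fwe_correct(v_obs, maxstats)
            n_used = n_perm

        z = np.sign(v_obs) * norm.ppf(1.0 - p_unc / 2.0)
        tables[cname] = pd.DataFrame(
            {
                "node": list(node_ids),
                "v": v_obs,
                "z": z,
                "p_unc": p_unc,
                "p_fwe": p_fwe,
                "direction": np.sign(v_obs).astype(int),
            }
        )
        maxdists[cname] = np.asarray(maxstats)

    return PermutationResult(
        tables=tables,
        max_distributions=maxdists,
        n_perm=n_used,
        seed=int(seed),
        exhaustive=exhaustive,
    )


def fwe_correct(
    observed: np.ndarray, max_stat_distribution: np.ndarray
) -> np.ndarray:
    """Max-statistic FWE-corrected p per node:
    (1 + #{max|v*| >= |v_obs|}) / (1 + n_perm)."""
    dist = np.asarray(max_stat_distribution, dtype=float)
    if dist.size == 0:
        raise ValueError("empty max-statistic distribution")
    abs_obs = np.abs(np.asarray(observed, dtype=float))
    count = (dist[:, None] >= abs_obs[None, :]).sum(axis=0)
    return (1.0 + count) / (1.0 + dist.size)
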