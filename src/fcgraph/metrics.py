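"""Weighted graph measures on complete functional connectomes.

Six nodal measures (normalized strength, closeness, betweenness and
eigenvector centrality, Onnela clustering coefficient, participation
coefficient) and two global measures (average shortest path length and
fixed-partition Newman modularity). Conventions:

* Path length between connected nodes is the minimum sum of reciprocal
  edge weights (Dijkstra); zero-weight edges are treated as absent.
* The clustering coefficient is the Onnela geometric-mean form with
  edge weights normalized by the global maximum weight.
* Participation and modularity use node strengths (weighted degree) and
  a fixed community partition — no community detection.
* Modularity includes the i = j null-model terms with observed
  self-weight zero (standard Newman form).
"""

from __future__ import annotations

import heapq
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectome import WeightedGraph
from .parcellation import Parcellation

__all__ = [
    "normalized_strength",
    "shortest_path_lengths",
    "average_shortest_path_length",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "clustering_coefficient",
    "participation_coefficient",
    "modularity",
    "network_summarize",
    "compute_all_metrics",
    "NODAL_METRICS",
    "GLOBAL_METRICS",
]

NODAL_METRICS = (
    "strength",
    "closeness",
    "betweenness",
    "eigenvector",
    "clustering",
    "participation",
)
GLOBAL_METRICS = ("modularity", "path_length")


def _weights(g: WeightedGraph | np.ndarray) -> np.ndarray:
    if isinstance(g, WeightedGraph):
        return g.weights
    w = np.asarray(g, dtype=float)
    return w


def normalized_strength(g: WeightedGraph | np.ndarray) -> np.ndarray:
    """Node strength averaged over possible connections: s_i/(n-1)."""
    w = _weights(g)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return w.sum(axis=1) / (n - 1)


def shortest_path_lengths(g: WeightedGraph | np.ndarray) -> np.ndarray:
    """All-pairs distance matrix with edge length = 1/weight (Dijkstra);
    unreachable pairs are +inf."""
    w = _weights(g)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    # csgraph treats 0 as "no edge"
    return _csgraph_shortest_path(lengths, method="D", directed=False)


def average_shortest_path_length(g: WeightedGraph | np.ndarray) -> float:
    """Mean distance over all ordered pairs i != j."""
    d = shortest_path_lengths(g)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    if np.isinf(vals).any():
        raise ValueError("graph is disconnected; average path length undefined")
    return float(vals.mean())


def closeness_centrality(g: WeightedGraph | np.ndarray) -> np.ndarray:
    """(n-1) / sum of distances to all other nodes."""
    d = shortest_path_lengths(g)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.isinf(d[off]).any():
        raise ValueError("graph is disconnected; closeness undefined")
    return (n - 1) / d.sum(axis=1)


def betweenness_centrality(g: WeightedGraph | np.ndarray) -> np.ndarray:
    """Brandes betweenness on reciprocal-weight shortest paths.

    Shortest-path ties split proportionally to path multiplicity;
    endpoints excluded; normalized by 2/((n-1)(n-2)) for undirected
    graphs. Returns all zeros for n < 3.
    """
    w = _weights(g)
    n = w.shape[0]
    bc = np.zeros(n)
    if n < 3:
        return bc
    neighbors: list[np.ndarray] = []
    lengths: list[np.ndarray] = []
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        neighbors.append(nb)
        lengths.append(1.0 / w[i, nb])

    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        dist[s] = 0.0
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        done = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            du, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            order.append(u)
            for v, luv in zip(neighbors[u], lengths[u]):
                alt = du + luv
                if alt < dist[v]:
                    dist[v] = alt
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (alt, v))
                elif alt == dist[v] and not done[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for u in reversed(order):
            for p in preds[u]:
                delta[p] += sigma[p] / sigma[u] * (1.0 + delta[u])
            if u != s:
                bc[u] += delta[u]
    # each unordered pair visited from both endpoints; undirected
    # normalization 2/((n-1)(n-2)) folds the halving in:
    return bc / ((n - 1) * (n - 2))


def eigenvector_centrality(
    g: WeightedGraph | np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """Leading eigenvector of the weight matrix by power iteration,
    entries nonnegative, Euclidean norm 1."""
    w = _weights(g)
    n = w.shape[0]
    x = np.full(n, 1.0 / np.sqrt(n))
    for it in range(max_iter):
        y = w @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError("zero weight matrix; eigenvector centrality undefined")
        y /= norm
        if np.abs(y - x).max() < tol:
            return y
        x = y
    raise RuntimeError(
        f"eigenvector centrality did not converge in {max_iter} iterations"
    )


def clustering_coefficient(g: WeightedGraph | np.ndarray) -> np.ndarray:
    """Onnela weighted clustering: geometric mean of triangle weights
    normalized by the global maximum weight; 0 where a node has fewer
    than 2 neighbors."""
    w = _weights(g)
    n = w.shape[0]
    if n == 0:
        return np.zeros(0)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    a = np.cbrt(w / wmax)
    num = np.diagonal(a @ a @ a).copy()  # sum over ordered neighbor pairs
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.zeros(n)
    nz = denom > 0
    c[nz] = num[nz] / denom[nz]
    return c


def participation_coefficient(
    g: WeightedGraph | np.ndarray, parcellation: Parcellation
) -> np.ndarray:
    """P_i = 1 - sum_m (kappa_im / s_i)^2 over all K networks; 0 for
    isolated nodes."""
    w = _weights(g)
    labels = parcellation.labels
    if labels.shape[0] != w.shape[0]:
        raise ValueError("parcellation size does not match graph")
    s = w.sum(axis=1)
    k = parcellation.n_networks
    kappa = np.zeros((w.shape[0], k))
    for m in range(k):
        kappa[:, m] = w[:, labels == m].sum(axis=1)
    p = np.zeros(w.shape[0])
    nz = s > 0
    p[nz] = 1.0 - ((kappa[nz] / s[nz, None]) ** 2).sum(axis=1)
    return p


def modularity(g: WeightedGraph | np.ndarray, parcellation: Parcellation) -> float:
    """Newman modularity Q of a fixed partition:
    Q = (1/2m) sum_ij [w_ij - s_i s_j / 2m] delta(c_i, c_j), including
    the i = j null-model terms (observed self-weight is zero)."""
    w = _weights(g)
    labels = parcellation.labels
    if labels.shape[0] != w.shape[0]:
        raise ValueError("parcellation size does not match graph")
    two_m = w.sum()
    if two_m == 0:
        raise ValueError("graph has zero total weight; modularity undefined")
    s = w.sum(axis=1)
    q = 0.0
    for m in range(parcellation.n_networks):
        idx = labels == m
        q += w[np.ix_(idx, idx)].sum() - (s[idx].sum() ** 2) / two_m
    return float(q / two_m)


def network_summarize(
    metric_values: pd.DataFrame | np.ndarray,
    parcellation: Parcellation,
    significant: np.ndarray | None = None,
    direction: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-network mean of a nodal metric, optionally joined with
    per-node significance flags and association signs to produce signed
    significant-node counts per network."""
    values = np.asarray(metric_values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    if values.shape[1] != parcellation.n_parcels:
        raise ValueError("metric table width does not match parcellation")
    labels = parcellation.labels
    rows = []
    for m, name in enumerate(parcellation.network_names):
        idx = labels == m
        row = {
            "network": name,
            "n_nodes": int(idx.sum()),
            "mean": float(values[:, idx].mean()),
        }
        if significant is not None:
            sig = np.asarray(significant, dtype=bool)[idx]
            if direction is not None:
                sgn = np.asarray(direction)[idx]
                row["n_sig_positive"] = int((sig & (sgn > 0)).sum())
                row["n_sig_negative"] = int((sig & (sgn < 0)).sum())
            else:
                row["n_sig"] = int(sig.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def compute_all_metrics(
    g: WeightedGraph | np.ndarray, parcellation: Parcellation
) -> dict[str, np.ndarray | float]:
    """All six nodal metrics plus modularity and average shortest path
    length for one participant's graph."""
    return {
        "strength": normalized_strength(g),
        "closeness": closeness_centrality(g),
        "betweenness": betweenness_centrality(g),
        "eigenvector": eigenvector_centrality(g),
        "clustering": clustering_coefficient(g),
        "participation": participation_coefficient(g, parcellation),
        "modularity": modularity(g, parcellation),
        "path_length": average_shortest_path_length(g),
    }
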