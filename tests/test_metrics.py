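"""Graph measures: worked examples, oracle equivalence against
networkx and brute-force enumeration, and invariance properties."""

import itertools

import networkx as nx
import numpy as np
import pytest

from fcgraph.metrics import (
    average_shortest_path_length,
    betweenness_centrality,
    closeness_centrality,
    clustering_coefficient,
    compute_all_metrics,
    eigenvector_centrality,
    modularity,
    network_summarize,
    normalized_strength,
    participation_coefficient,
    shortest_path_lengths,
)
from fcgraph.parcellation import Parcellation, default_parcellation

from conftest import random_weight_matrix


def make_parcellation(labels, k):
    return Parcellation(
        tuple(str(i) for i in range(len(labels))),
        tuple(int(x) for x in labels),
        tuple(f"N{i}" for i in range(k)),
    )


class TestWorkedExamples:
    def test_two_clique_modularity_half(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        parc = make_parcellation([0, 0, 1, 1], 2)
        assert modularity(w, parc) == pytest.approx(0.5, abs=1e-12)

    def test_onnela_triangle_half(self):
        w = np.array([[0, 0.8, 0.4], [0.8, 0, 0.2], [0.4, 0.2, 0]])
        assert clustering_coefficient(w) == pytest.approx([0.5] * 3, abs=1e-12)

    def test_triangle_path_length(self):
        w = np.array([[0, 1, 1], [1, 0, 0.1], [1, 0.1, 0]])
        d = shortest_path_lengths(w)
        assert d[1, 2] == pytest.approx(2.0)  # detour via the hub beats 10
        assert average_shortest_path_length(w) == pytest.approx(4 / 3)

    def test_equal_split_participation(self):
        # hub connected once into each of 12 networks
        w = np.zeros((13, 13))
        w[0, 1:] = w[1:, 0] = 1.0
        parc = make_parcellation([0] + list(range(12)), 12)
        p = participation_coefficient(w, parc)
        assert p[0] == pytest.approx(1 - 1 / 12, abs=1e-12)

    def test_all_weight_within_own_network(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.7
        parc = make_parcellation([0, 0, 1, 1], 2)
        assert participation_coefficient(w, parc)[0] == 0.0

    def test_strength_split_two_networks(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.5
        parc = make_parcellation([0, 0, 1], 2)
        assert participation_coefficient(w, parc)[0] == pytest.approx(0.5)

    def test_single_community_modularity_zero(self, rng):
        w = random_weight_matrix(rng, 6)
        parc = make_parcellation([0] * 6, 1)
        assert modularity(w, parc) == pytest.approx(0.0, abs=1e-12)

    def test_three_node_path_betweenness(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        assert betweenness_centrality(w) == pytest.approx([0, 1, 0])

    def test_two_node_closeness_and_distance(self):
        w = np.array([[0, 0.5], [0.5, 0]])
        assert shortest_path_lengths(w)[0, 1] == pytest.approx(2.0)
        assert average_shortest_path_length(w) == pytest.approx(2.0)
        assert closeness_centrality(w) == pytest.approx([0.5, 0.5])

    def test_two_node_eigenvector(self):
        w = np.array([[0, 0.37], [0.37, 0]])
        assert eigenvector_centrality(w) == pytest.approx([2**-0.5] * 2)

    def test_isolated_leaf_clustering_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        assert clustering_coefficient(w)[0] == 0.0


@pytest.fixture(scope="module")
def uniform():
    n, wv = 9, 0.4
    w = np.full((n, n), wv)
    np.fill_diagonal(w, 0.0)
    return w, n, wv


class TestUniformCompleteGraph:
    def test_all_nodal_metrics_constant(self, uniform):
        w, n, wv = uniform
        assert normalized_strength(w) == pytest.approx([wv] * n)
        assert clustering_coefficient(w) == pytest.approx([1.0] * n)
        assert betweenness_centrality(w) == pytest.approx([0.0] * n)
        assert closeness_centrality(w) == pytest.approx([wv] * n)
        assert eigenvector_centrality(w) == pytest.approx([n**-0.5] * n)


class TestOracleEquivalence:
    """Independent reference implementations on random connected graphs."""

    @pytest.mark.parametrize("trial", range(25))
    def test_against_networkx(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 31))
        w = random_weight_matrix(rng, n)
        g = nx.from_numpy_array(w)
        for _, _, d in g.edges(data=True):
            d["dist"] = 1.0 / d["weight"]

        s_ref = np.array([g.degree(i, weight="weight") for i in range(n)]) / (n - 1)
        assert np.abs(normalized_strength(w) - s_ref).max() < 1e-8

        d_ref_dict = dict(nx.all_pairs_dijkstra_path_length(g, weight="dist"))
        d_ref = np.array([[d_ref_dict[i][j] for j in range(n)] for i in range(n)])
        assert np.abs(shortest_path_lengths(w) - d_ref).max() < 1e-8

        c_ref = np.array(
            [nx.closeness_centrality(g, u=i, distance="dist") for i in range(n)]
        )
        assert np.abs(closeness_centrality(w) - c_ref).max() < 1e-8

        b_ref_dict = nx.betweenness_centrality(g, weight="dist", normalized=True)
        b_ref = np.array([b_ref_dict[i] for i in range(n)])
        assert np.abs(betweenness_centrality(w) - b_ref).max() < 1e-8

        evals, evecs = np.linalg.eigh(w)
        e_ref = np.abs(evecs[:, -1])
        assert np.abs(eigenvector_centrality(w) - e_ref).max() < 1e-8

        cl_ref_dict = nx.clustering(g, weight="weight")
        cl_ref = np.array([cl_ref_dict[i] for i in range(n)])
        assert np.abs(clustering_coefficient(w) - cl_ref).max() < 1e-8

        k = int(rng.integers(2, 6))
        labels = rng.integers(0, k, n)
        labels[:k] = np.arange(k)  # every community non-empty
        parc = make_parcellation(labels, k)
        q_ref = nx.community.modularity(
            g, [set(np.flatnonzero(labels == m)) for m in range(k)], weight="weight"
        )
        assert modularity(w, parc) == pytest.approx(q_ref, abs=1e-8)

        s_raw = w.sum(axis=1)
        p_ref = np.array(
            [
                1 - sum((w[i, labels == m].sum() / s_raw[i]) ** 2 for m in range(k))
                for i in range(n)
            ]
        )
        assert np.abs(participation_coefficient(w, parc) - p_ref).max() < 1e-8

    @pytest.mark.parametrize("trial", range(5))
    def test_exhaustive_paths_small_graphs(self, trial):
        """Distances and betweenness against brute-force enumeration of
        every simple path on n <= 6 nodes."""
        rng = np.random.default_rng(2000 + trial)
        n = int(rng.integers(4, 7))
        w = random_weight_matrix(rng, n)
        with np.errstate(divide="ignore"):
            lengths = 1.0 / w  # diagonal inf, never used
        nodes = range(n)
        dist = np.full((n, n), np.inf)
        np.fill_diagonal(dist, 0.0)
        path_counts = {}
        for s, t in itertools.permutations(nodes, 2):
            best, best_paths = np.inf, []
            for k in range(n - 1):
                for mids in itertools.permutations(set(nodes) - {s, t}, k):
                    path = (s, *mids, t)
                    plen = sum(lengths[a, b] for a, b in zip(path, path[1:]))
                    if plen < best - 1e-12:
                        best, best_paths = plen, [path]
                    elif abs(plen - best) <= 1e-12:
                        best_paths.append(path)
            dist[s, t] = best
            path_counts[(s, t)] = best_paths
        assert np.abs(shortest_path_lengths(w) - dist).max() < 1e-8

        bc = np.zeros(n)
        for (s, t), paths in path_counts.items():
            for path in paths:
                for mid in path[1:-1]:
                    bc[mid] += 1.0 / len(paths)
        bc /= 2 * ((n - 1) * (n - 2) / 2)  # ordered pairs, then normalize
        assert np.abs(betweenness_centrality(w) - bc).max() < 1e-8


class TestScaleBehavior:
    def test_scaling_weights(self, rng, parc24):
        w = random_weight_matrix(rng, 24)
        a = 3.7
        assert np.abs(
            clustering_coefficient(a * w) - clustering_coefficient(w)
        ).max() < 1e-12
        assert np.abs(
            participation_coefficient(a * w, parc24)
            - participation_coefficient(w, parc24)
        ).max() < 1e-12
        assert modularity(a * w, parc24) == pytest.approx(modularity(w, parc24))
        assert np.abs(
            eigenvector_centrality(a * w) - eigenvector_centrality(w)
        ).max() < 1e-9
        assert np.abs(
            betweenness_centrality(a * w) - betweenness_centrality(w)
        ).max() < 1e-12
        assert np.abs(
            normalized_strength(a * w) - a * normalized_strength(w)
        ).max() < 1e-12
        assert average_shortest_path_length(a * w) == pytest.approx(
            average_shortest_path_length(w) / a
        )


class TestBoundsAndDegenerate:
    def test_metric_ranges(self, rng, parc24):
        for _ in range(10):
            w = random_weight_matrix(rng, 24)
            c = clustering_coefficient(w)
            assert (c >= 0).all() and (c <= 1).all()
            p = participation_coefficient(w, parc24)
            assert (p >= 0).all() and (p <= 1 - 1 / 12 + 1e-12).all()
            q = modularity(w, parc24)
            assert -1 < q < 1
            assert (normalized_strength(w) >= 0).all()
            assert (closeness_centrality(w) >= 0).all()

    def test_disconnected_pair_is_error(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            average_shortest_path_length(w)

    def test_zero_total_weight_modularity_error(self, parc24):
        with pytest.raises(ValueError):
            modularity(np.zeros((24, 24)), parc24)

    def test_betweenness_small_graph_zeros(self):
        assert np.array_equal(
            betweenness_centrality(np.array([[0, 1.0], [1.0, 0]])), [0, 0]
        )


class TestNetworkSummarize:
    def test_constant_values(self, parc24):
        out = network_summarize(np.full((5, 24), 2.5), parc24)
        assert (out["mean"] == 2.5).all()
        assert out["n_nodes"].sum() == 24

    def test_signed_counts(self, parc24):
        values = np.zeros((1, 24))
        sig = np.zeros(24, dtype=bool)
        sig[[0, 1, 2]] = True
        direction = np.zeros(24)
        direction[[0, 1]] = 1
        direction[2] = -1
        out = network_summarize(values, parc24, significant=sig, direction=direction)
        # parcels 0,1 belong to the first network; parcel 2 to the second
        assert out.loc[0, "n_sig_positive"] == 2
        assert out.loc[1, "n_sig_negative"] == 1
        assert out["n_sig_positive"].sum() == 2
        assert out["n_sig_negative"].sum() == 1

    def test_no_significant_nodes(self, parc24):
        out = network_summarize(
            np.zeros((1, 24)),
            parc24,
            significant=np.zeros(24, dtype=bool),
            direction=np.zeros(24),
        )
        assert out["n_sig_positive"].sum() == 0
        assert out["n_sig_negative"].sum() == 0


def test_compute_all_metrics_keys(rng, parc24):
    w = random_weight_matrix(rng, 24)
    out = compute_all_metrics(w, parc24)
    assert set(out) == {
        "strength",
        "closeness",
        "betweenness",
        "eigenvector",
        "clustering",
        "participation",
        "modularity",
        "path_length",
    }
    assert np.isscalar(out["modularity"]) or out["modularity"].ndim == 0
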