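"""Weighted graph metrics against closed forms and brute-force oracles."""

import itertools

import numpy as np
import pytest

from strokeconn import (betweenness, characteristic_path_length, compute_all,
                        global_efficiency, local_efficiency, node_degree,
                        node_strength, nodal_efficiency)
from strokeconn.metrics import (clustering_onnela, distance_matrix,
                                _local_efficiency_matrix)

from conftest import random_symmetric


# ---------------------------------------------------------------- oracles

def brute_clustering(w):
    """Onnela clustering by explicit enumeration of ordered triples."""
    n = len(w)
    out = np.zeros(n)
    for i in range(n):
        k = np.count_nonzero(w[i])
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                total += (w[i, j] * w[i, h] * w[j, h]) ** (1 / 3)
        out[i] = total / (k * (k - 1))
    return out


def brute_distances(w):
    """All-pairs shortest 1/w distances by exhaustive simple-path enumeration."""
    n = len(w)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    nodes = range(n)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            best = np.inf
            for r in range(n - 1):
                for mids in itertools.permutations(set(nodes) - {s, t}, r):
                    path = (s, *mids, t)
                    if all(w[a, b] > 0 for a, b in zip(path, path[1:])):
                        best = min(best, sum(1 / w[a, b] for a, b in zip(path, path[1:])))
            dist[s, t] = best
    return dist


def brute_betweenness(w):
    """Fractional geodesic counting over exhaustively enumerated paths."""
    n = len(w)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        geodesics = []
        best = np.inf
        for r in range(n - 1):
            for mids in itertools.permutations(set(range(n)) - {s, t}, r):
                path = (s, *mids, t)
                if all(w[a, b] > 0 for a, b in zip(path, path[1:])):
                    length = sum(1 / w[a, b] for a, b in zip(path, path[1:]))
                    if length < best - 1e-12:
                        best, geodesics = length, [path]
                    elif abs(length - best) <= 1e-12:
                        geodesics.append(path)
        for path in geodesics:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(geodesics)
    return bc


def toy(n, seed, density=0.6):
    rng = np.random.default_rng(seed)
    w = random_symmetric(n, rng, density=density)
    return w / w.max()


def path4():
    w = np.zeros((4, 4))
    for i in range(3):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return w


def ring4():
    w = path4()
    w[0, 3] = w[3, 0] = 1.0
    return w


# ------------------------------------------------------------ closed forms

def test_complete_network_unit_metrics():
    for n in (4, 6):
        w = 1.0 - np.eye(n)
        dist = distance_matrix(w)
        assert global_efficiency(dist) == pytest.approx(1.0)
        assert characteristic_path_length(dist) == pytest.approx(1.0)
        assert nodal_efficiency(dist) == pytest.approx(np.ones(n))
        assert _local_efficiency_matrix(w) == pytest.approx(np.ones(n))
        assert clustering_onnela(w) == pytest.approx(np.ones(n))


def test_path_graph_closed_forms():
    dist = distance_matrix(path4())
    assert dist[0, 3] == pytest.approx(3.0)
    assert global_efficiency(dist) == pytest.approx(13 / 18)
    assert nodal_efficiency(dist)[0] == pytest.approx(11 / 18)


def test_ring_characteristic_path_length():
    assert characteristic_path_length(distance_matrix(ring4())) == pytest.approx(4 / 3)


def test_star_has_no_triangles_and_zero_local_efficiency():
    w = np.zeros((4, 4))
    w[0, 1:] = w[1:, 0] = 1.0
    assert clustering_onnela(w) == pytest.approx(np.zeros(4))
    assert _local_efficiency_matrix(w) == pytest.approx(np.zeros(4))


def test_weighted_triangle_onnela_value():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[0, 2] = w[2, 0] = 1.0
    w[1, 2] = w[2, 1] = 0.5
    c = clustering_onnela(w)
    assert c == pytest.approx(np.full(3, 0.5 ** (1 / 3)))
    assert c == pytest.approx(brute_clustering(w))


def test_disconnected_pairs_are_infinite_and_efficiency_handles_them():
    w = np.zeros((5, 5))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    dist = distance_matrix(w)
    assert np.isinf(dist[0, 2]) and np.isinf(dist[1, 4])
    fully_disconnected = np.full((4, 4), np.inf)
    np.fill_diagonal(fully_disconnected, 0.0)
    assert global_efficiency(fully_disconnected) == 0.0
    with pytest.raises(ValueError, match="no finite"):
        characteristic_path_length(distance_matrix(np.zeros((4, 4))))


# ------------------------------------------------------- brute-force toys

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clustering_matches_triple_enumeration(seed):
    w = toy(7, seed)
    assert clustering_onnela(w) == pytest.approx(brute_clustering(w), rel=1e-9)


@pytest.mark.parametrize("seed", [3, 4])
def test_distances_match_exhaustive_path_enumeration(seed):
    w = toy(6, seed, density=0.5)
    assert distance_matrix(w) == pytest.approx(brute_distances(w), rel=1e-9)


def test_local_efficiency_composes_subgraph_and_global_efficiency():
    w = toy(7, 9)
    expected = np.zeros(7)
    for i in range(7):
        nbrs = np.flatnonzero(w[i])
        if len(nbrs) >= 2:
            expected[i] = global_efficiency(brute_distances(w[np.ix_(nbrs, nbrs)]))
    assert _local_efficiency_matrix(w) == pytest.approx(expected, rel=1e-9)


def test_binary_metrics_equal_classical_counterparts():
    rng = np.random.default_rng(21)
    w = (random_symmetric(7, rng, density=0.5) > 0).astype(float)
    dist = brute_distances(w)  # binary: 1/w = 1 per hop
    assert distance_matrix(w) == pytest.approx(dist)
    assert clustering_onnela(w) == pytest.approx(brute_clustering(w))


# -------------------------------------------------- Connectome-level API

def test_degree_strength_and_path_betweenness(embed):
    w = path4()
    c = embed(w)
    deg = node_degree(c)[:4]
    assert deg.tolist() == [1, 2, 2, 1]
    assert node_strength(c)[:4] == pytest.approx([1, 2, 2, 1])
    assert betweenness(c)[:4] == pytest.approx([0, 2, 2, 0])


def test_complete_graph_betweenness_zero(embed):
    w = 1.0 - np.eye(5)
    assert betweenness(embed(w))[:5] == pytest.approx(np.zeros(5))


@pytest.mark.parametrize("seed", [5, 6])
def test_betweenness_matches_exhaustive_oracle(embed, seed):
    w = toy(6, seed, density=0.5)
    assert betweenness(embed(w))[:6] == pytest.approx(brute_betweenness(w), abs=1e-9)


def test_star_degree(embed):
    w = np.zeros((4, 4))
    w[0, 1:] = w[1:, 0] = 1.0
    assert node_degree(embed(w))[:4].tolist() == [3, 1, 1, 1]


def test_compute_all_is_deterministic_and_consistent(normalized_subject):
    gm1, nm1 = compute_all(normalized_subject)
    gm2, nm2 = compute_all(normalized_subject)
    assert gm1 == gm2
    assert np.array_equal(nm1.betweenness, nm2.betweenness)
    # E_glob is the mean of the nodal efficiencies
    assert gm1.eff_global == pytest.approx(nm1.eff_nodal.mean(), abs=1e-12)
    assert gm1.clustering_C == pytest.approx(nm1.clustering.mean(), abs=1e-12)


# ------------------------------------------------------------- properties

def test_relabeling_equivariance():
    rng = np.random.default_rng(30)
    w = toy(7, 31)
    perm = rng.permutation(7)
    wp = w[np.ix_(perm, perm)]
    assert clustering_onnela(wp) == pytest.approx(clustering_onnela(w)[perm])
    assert nodal_efficiency(distance_matrix(wp)) == pytest.approx(
        nodal_efficiency(distance_matrix(w))[perm])
    assert global_efficiency(distance_matrix(wp)) == pytest.approx(
        global_efficiency(distance_matrix(w)))


def test_weight_scaling_behaviour():
    w = toy(7, 33)
    alpha = 0.4
    # distances scale by 1/alpha; clustering of the rescaled-to-max matrix is unchanged
    assert distance_matrix(alpha * w) == pytest.approx(distance_matrix(w) / alpha)
    assert clustering_onnela((alpha * w) / (alpha * w).max()) == pytest.approx(
        clustering_onnela(w / w.max()))


def test_adding_an_edge_never_increases_path_length():
    rng = np.random.default_rng(40)
    for _ in range(5):
        w = toy(7, rng.integers(1e6))
        zeros = np.argwhere(np.triu(w == 0, 1))
        if not len(zeros):
            continue
        i, j = zeros[rng.integers(len(zeros))]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = 0.9
        l1 = characteristic_path_length(distance_matrix(w))
        l2 = characteristic_path_length(distance_matrix(w2))
        assert l2 <= l1 + 1e-12
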