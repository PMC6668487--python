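"""Weighted global and nodal network measures.

Conventions follow the standard weighted definitions of the Brain
Connectivity Toolbox family of measures, on max-normalized weights in
[0, 1]:

* clustering — Onnela's geometric-mean-of-triangles coefficient,
  ``C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w_ij w_ih w_jh)^{1/3}``;
* distances — an edge of weight ``w`` has length ``1/w``, so stronger
  connections are shorter; shortest paths by Dijkstra;
* characteristic path length — mean shortest distance over the finite
  ordered pairs (disconnected pairs are excluded and counted);
* global efficiency — mean of ``1/d_ij`` over ordered pairs with
  ``1/inf = 0``, so disconnection is handled natively;
* local efficiency — for each node, the global efficiency of the
  subnetwork induced by its neighbors (weights retained);
* betweenness — weighted shortest-path betweenness on the same
  ``1/w`` lengths, unnormalized, with equal-length multiplicity split
  fractionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .core import Connectome

log = logging.getLogger(__name__)


@dataclass
class GlobalMetrics:
    """Whole-network summary measures for one subject (dimensionless)."""

    clustering_C: float
    path_length_L: float
    eff_global: float
    eff_local: float
    n_infinite_pairs: int = 0  # ordered pairs excluded from L

    def as_dict(self) -> dict:
        return {
            "clustering_C": self.clustering_C,
            "path_length_L": self.path_length_L,
            "eff_global": self.eff_global,
            "eff_local": self.eff_local,
        }


@dataclass
class NodalMetrics:
    """Per-region measures for one subject (arrays of length 90)."""

    degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray
    eff_nodal: np.ndarray

    def to_frame(self, region_names: list[str]) -> pd.DataFrame:
        return pd.DataFrame({
            "region": region_names,
            "degree": self.degree,
            "strength": self.strength,
            "clustering": self.clustering,
            "betweenness": self.betweenness,
            "eff_nodal": self.eff_nodal,
        })


NODAL_METRIC_NAMES = ["degree", "strength", "clustering", "betweenness", "eff_nodal"]
GLOBAL_METRIC_NAMES = ["clustering_C", "path_length_L", "eff_global", "eff_local"]


def _require_normalized(c: Connectome) -> np.ndarray:
    if c.state != "normalized":
        raise ValueError(f"metrics require a normalized connectome, got state={c.state!r}")
    return c.weights


def node_degree(c: Connectome) -> np.ndarray:
    """Number of suprathreshold edges incident to each node (weight-agnostic)."""
    w = _require_normalized(c)
    return np.count_nonzero(w, axis=1).astype(int)


def node_strength(c: Connectome) -> np.ndarray:
    """Sum of incident edge weights per node."""
    return _require_normalized(c).sum(axis=1)


def clustering_onnela(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering per node for a weight matrix in [0, 1]."""
    k = np.count_nonzero(w, axis=1)
    cube = np.cbrt(w)
    # diag of cube^3 counts each (ordered) triangle (i,j,h) once
    tri = np.einsum("ij,jh,hi->i", cube, cube, cube)
    denom = k * (k - 1)
    out = np.zeros(len(w))
    np.divide(tri, denom, out=out, where=denom > 0)
    return out


def weighted_clustering(c: Connectome) -> np.ndarray:
    """Per-node Onnela clustering coefficients; mean is the network's C."""
    return clustering_onnela(_require_normalized(c))


def distance_matrix(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge lengths 1/w.

    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return _csgraph_shortest_path(csr_matrix(lengths), method="D", directed=False)


def shortest_path_lengths(c: Connectome) -> np.ndarray:
    return distance_matrix(_require_normalized(c))


def characteristic_path_length(dist: np.ndarray) -> float:
    """Mean shortest distance over finite ordered pairs i != j.

    Infinite (disconnected) pairs are excluded; their count is logged.
    Raises if no finite off-diagonal distance exists.
    """
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(dist)
    n_inf = int(off.sum() - finite.sum())
    if finite.sum() == 0:
        raise ValueError("no finite off-diagonal distances: network has no paths")
    if n_inf:
        log.info("characteristic path length: %d infinite ordered pairs excluded", n_inf)
    return float(dist[finite].mean())


def count_infinite_pairs(dist: np.ndarray) -> int:
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    return int(np.isinf(dist[off]).sum())


def global_efficiency(dist: np.ndarray) -> float:
    """Mean inverse distance over ordered pairs, with 1/inf = 0."""
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & off, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def nodal_efficiency(dist: np.ndarray) -> np.ndarray:
    """Per-node mean inverse distance to all other nodes."""
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & off, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
    return inv.sum(axis=1) / (n - 1)


def _local_efficiency_matrix(w: np.ndarray) -> np.ndarray:
    out = np.zeros(len(w))
    for i in range(len(w)):
        nbrs = np.flatnonzero(w[i])
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(distance_matrix(sub))
    return out


def local_efficiency(c: Connectome) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subnetwork.

    Zero for nodes of degree < 2.  The mean over nodes is the network's
    local efficiency.
    """
    return _local_efficiency_matrix(_require_normalized(c))


def betweenness(c: Connectome, weighted: bool = True) -> np.ndarray:
    """Shortest-path betweenness centrality (unnormalized pair counts).

    With ``weighted=True`` (default) geodesics use edge lengths 1/w; with
    ``weighted=False`` all edges count length 1.
    """
    w = _require_normalized(c)
    g = nx.Graph()
    g.add_nodes_from(range(len(w)))
    ii, jj = np.nonzero(np.triu(w, 1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / w[i, j]) for i, j in zip(ii, jj)), weight="length"
    )
    bc = nx.betweenness_centrality(g, normalized=False,
                                   weight="length" if weighted else None)
    return np.array([bc[i] for i in range(len(w))])


def compute_all(c: Connectome) -> tuple[GlobalMetrics, NodalMetrics]:
    """All global and nodal measures for one normalized connectome."""
    w = _require_normalized(c)
    dist = distance_matrix(w)
    clust = clustering_onnela(w)
    eloc = _local_efficiency_matrix(w)
    gm = GlobalMetrics(
        clustering_C=float(clust.mean()),
        path_length_L=characteristic_path_length(dist),
        eff_global=global_efficiency(dist),
        eff_local=float(eloc.mean()),
        n_infinite_pairs=count_infinite_pairs(dist),
    )
    nm = NodalMetrics(
        degree=np.count_nonzero(w, axis=1).astype(int),
        strength=w.sum(axis=1),
        clustering=clust,
        betweenness=betweenness(c),
        eff_nodal=nodal_efficiency(dist),
    )
    return gm, nm
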