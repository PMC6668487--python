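"""Degree-preserving random surrogates and small-world normalization.

A network is compared against an ensemble of randomized surrogates that
keep every node's (binary) degree and the total edge count fixed, produced
by repeated double-edge swaps: two edges (a,b), (c,d) with four distinct
endpoints are replaced by (a,d), (c,b) whenever neither replacement edge
already exists.  Weights travel with the swapped edges, so the topology is
randomized while the multiset of edge weights is preserved exactly.

Small-world normalization reports

* gamma  = C / <C_rand>   (normalized clustering),
* lambda = L / <L_rand>   (normalized characteristic path length),
* sigma  = gamma / lambda (small-worldness),

and the network is called small-world when gamma > 1, lambda is close to 1,
and sigma > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core import Connectome
from .metrics import characteristic_path_length, clustering_onnela, distance_matrix

log = logging.getLogger(__name__)


@dataclass
class SmallWorldResult:
    gamma: float
    lambda_: float
    sigma: float
    n_random: int  # surrogates actually used
    rand_summary: dict  # mean/sd of C_rand and L_rand, exclusion count


def _rewire_matrix(w: np.ndarray, n_swaps_per_edge: int, rng: np.random.Generator,
                   max_attempt_factor: int = 20) -> tuple[np.ndarray, int]:
    """Double-edge-swap randomization of a weight matrix.

    Returns the rewired matrix and the number of successful swaps.
    """
    w = w.copy()
    edges = np.argwhere(np.triu(w, 1) > 0)
    m = len(edges)
    if m < 2:
        return w, 0
    target = n_swaps_per_edge * m
    max_attempts = max_attempt_factor * target
    done = 0
    attempts = 0
    # draw randomness in blocks; the swap loop itself must stay sequential
    block = max(1024, 2 * target)
    picks = rng.integers(0, m, size=(block, 2))
    flips = rng.random(block) < 0.5
    cursor = 0
    while done < target and attempts < max_attempts:
        if cursor >= block:
            picks = rng.integers(0, m, size=(block, 2))
            flips = rng.random(block) < 0.5
            cursor = 0
        e1, e2 = picks[cursor]
        flip = flips[cursor]
        cursor += 1
        attempts += 1
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if w[a, d] != 0 or w[c, b] != 0:
            continue
        w1, w2 = w[a, b], w[c, d]
        w[a, b] = w[b, a] = 0.0
        w[c, d] = w[d, c] = 0.0
        w[a, d] = w[d, a] = w1
        w[c, b] = w[b, c] = w2
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        done += 1
    return w, done


def rewire_preserving_degree(c: Connectome, n_swaps_per_edge: int = 10,
                             seed: int | np.random.Generator = 0) -> Connectome:
    """Randomize topology while preserving degrees, edge count, and weights.

    The binary degree sequence, edge count, and multiset of edge weights of
    the output equal the input's exactly.  If the swap quota cannot be met
    within a bounded number of attempts (e.g. a rigid degree sequence), the
    best effort is returned with a warning.
    """
    if c.state != "normalized":
        raise ValueError("rewiring expects a normalized connectome")
    if c.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, done = _rewire_matrix(c.weights, n_swaps_per_edge, rng)
    target = n_swaps_per_edge * c.n_edges
    if done < target:
        log.warning("%s: only %d/%d swaps achieved", c.subject_id, done, target)
    return replace(c, weights=w)


def small_world_params(c: Connectome, n_random: int = 100,
                       seed: int = 0, n_swaps_per_edge: int = 10,
                       surrogate_fn=None) -> SmallWorldResult:
    """Normalized clustering, path length, and small-worldness of a network.

    ``n_random`` surrogates are generated by degree-preserving rewiring,
    each from a seed derived from ``seed`` and the surrogate index, so the
    ensemble is reproducible.  A surrogate with no finite path is excluded
    and counted.  ``surrogate_fn(c, k) -> Connectome`` overrides surrogate
    generation (testing hook).
    """
    w = c.weights
    c_obs = float(clustering_onnela(w).mean())
    l_obs = characteristic_path_length(distance_matrix(w))
    ss = np.random.SeedSequence([int(seed), 0x5B])
    child_seeds = ss.generate_state(n_random)
    cs, ls = [], []
    n_excluded = 0
    for k in range(n_random):
        if surrogate_fn is not None:
            wr = surrogate_fn(c, k).weights
        else:
            rng = np.random.default_rng(child_seeds[k])
            wr, _ = _rewire_matrix(w, n_swaps_per_edge, rng)
        try:
            lr = characteristic_path_length(distance_matrix(wr))
        except ValueError:
            n_excluded += 1
            continue
        cs.append(float(clustering_onnela(wr).mean()))
        ls.append(lr)
    if not cs:
        raise ValueError("all surrogates excluded: no finite paths")
    cs, ls = np.array(cs), np.array(ls)
    gamma = c_obs / cs.mean()
    lambda_ = l_obs / ls.mean()
    return SmallWorldResult(
        gamma=float(gamma),
        lambda_=float(lambda_),
        sigma=float(gamma / lambda_),
        n_random=len(cs),
        rand_summary={
            "C_rand_mean": float(cs.mean()), "C_rand_sd": float(cs.std(ddof=1)) if len(cs) > 1 else 0.0,
            "L_rand_mean": float(ls.mean()), "L_rand_sd": float(ls.std(ddof=1)) if len(ls) > 1 else 0.0,
            "n_excluded": n_excluded,
        },
    )


def is_small_world(r: SmallWorldResult, lambda_tol: float = 0.25) -> tuple[bool, dict]:
    """Small-world verdict: gamma > 1, |lambda - 1| <= tol, sigma > 1.

    Returns the overall verdict plus the three sub-criteria.
    """
    flags = {
        "gamma_gt_1": r.gamma > 1,
        "lambda_near_1": abs(r.lambda_ - 1) <= lambda_tol,
        "sigma_gt_1": r.sigma > 1,
    }
    return all(flags.values()), flags
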