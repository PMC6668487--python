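import numpy as np
import pytest

from strokeconn import Connectome, RegionTable
from strokeconn.core import N_REGIONS


@pytest.fixture(scope="session")
def regions():
    return RegionTable.aal90()


@pytest.fixture(scope="session")
def embed(regions):
    """Embed a small symmetric toy weight matrix into a 90-node connectome.

    The remaining nodes are isolated.  Per-node metric values on the toy's
    nodes are unaffected by the isolated remainder.
    """

    def _embed(w_small, state="normalized", **kw):
        w_small = np.asarray(w_small, dtype=float)
        n = len(w_small)
        w = np.zeros((N_REGIONS, N_REGIONS))
        w[:n, :n] = w_small
        return Connectome(regions=regions, weights=w, subject_id="toy",
                          lesion_side="left", state=state, **kw)

    return _embed


def random_symmetric(n, rng, density=0.5, integer=False, max_w=40):
    """Random symmetric nonnegative zero-diagonal test matrix."""
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    present = rng.random(len(iu)) < density
    vals = rng.integers(1, max_w, size=len(iu)) if integer else rng.uniform(0.1, 1.0, len(iu))
    w[iu, ju] = np.where(present, vals, 0)
    w += w.T
    return w


@pytest.fixture(scope="session")
def normalized_subject():
    """One preprocessed synthetic subject (thresholded at 10, max-normalized)."""
    from strokeconn import (CohortSpec, apply_threshold, generate_base_connectome,
                            normalize_max)

    spec = CohortSpec(master_seed=42)
    c = generate_base_connectome(spec, 0)
    return normalize_max(apply_threshold(c, 10))
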