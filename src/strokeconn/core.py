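"""Connectome data model, I/O, and matrix preprocessing.

A connectome here is a 90-region undirected weighted network whose raw edge
weights are white-matter streamline (fiber) counts between regions of the
AAL-90 parcellation (cerebellum excluded).  The preprocessing chain mirrors
standard structural-network practice: threshold the raw fiber counts at a
minimum count (default 10) to suppress spurious tractography connections,
then normalize the matrix to its largest entry so that between-subject
differences in overall connectivity strength do not dominate the metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

N_REGIONS = 90

SIDES = ("left", "right", "unknown")
STATES = ("raw", "thresholded", "normalized")

#: Base names of the 45 homotopic region pairs of the AAL-90 parcellation,
#: in atlas order; region 2k is the left member of pair k, region 2k+1 the right.
AAL90_PAIR_NAMES = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]


class RegionTable:
    """The 90-region parcellation table with the left/right homotopic pairing.

    Backed by a DataFrame with columns ``id``, ``name``, ``hemisphere``
    (``left``/``right``/``midline``) and ``homotopic_id`` (the partner
    region's id, needed to flip hemispheres when orienting matrices to the
    lesion side).
    """

    COLUMNS = ("id", "name", "hemisphere", "homotopic_id")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.reset_index(drop=True)
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        if len(frame) != N_REGIONS:
            raise ValueError(f"region table must have {N_REGIONS} rows, got {len(frame)}")
        ids = frame["id"].to_numpy()
        if not np.array_equal(np.sort(ids), np.arange(N_REGIONS)):
            raise ValueError("region ids must be exactly 0..89")
        if frame["name"].duplicated().any():
            dup = frame.loc[frame["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate region name: {dup!r}")
        frame = frame.sort_values("id").reset_index(drop=True)
        partner = frame["homotopic_id"].to_numpy()
        hemi = frame["hemisphere"].to_numpy()
        for i in range(N_REGIONS):
            j = int(partner[i])
            if hemi[i] == "midline":
                if j != i:
                    raise ValueError(f"midline region {i} must be its own partner")
                continue
            if not (0 <= j < N_REGIONS) or int(partner[j]) != i or j == i:
                raise ValueError(f"homotopic pairing broken at region {i}")
            if {hemi[i], hemi[j]} != {"left", "right"}:
                raise ValueError(f"pair ({i}, {j}) must span left and right")
        self.frame = frame

    @classmethod
    def aal90(cls) -> "RegionTable":
        """The default AAL-90 table (45 left/right homotopic pairs)."""
        rows = []
        for k, base in enumerate(AAL90_PAIR_NAMES):
            rows.append((2 * k, f"{base}_L", "left", 2 * k + 1))
            rows.append((2 * k + 1, f"{base}_R", "right", 2 * k))
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path) -> "RegionTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def names(self) -> list[str]:
        return self.frame["name"].tolist()

    def index_of(self, name: str) -> int:
        hit = self.frame.index[self.frame["name"] == name]
        if len(hit) == 0:
            raise KeyError(name)
        return int(hit[0])

    def pair_permutation(self) -> np.ndarray:
        """Permutation mapping each region id to its homotopic partner."""
        return self.frame["homotopic_id"].to_numpy(dtype=int)


@dataclass
class Connectome:
    """One subject's weighted undirected brain network.

    ``weights`` is a symmetric nonnegative 90x90 matrix with zero diagonal.
    ``state`` tracks the preprocessing stage: raw integer fiber counts,
    thresholded counts, or max-normalized weights in [0, 1].
    """

    regions: RegionTable
    weights: np.ndarray
    subject_id: str = ""
    lesion_side: str = "unknown"
    state: str = "raw"
    oriented: bool = False  # True once hemispheres are aligned to lesion side

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.validate()

    def validate(self) -> None:
        w = self.weights
        if w.shape != (N_REGIONS, N_REGIONS):
            raise ValueError(f"weights must be {N_REGIONS}x{N_REGIONS}, got {w.shape}")
        if self.lesion_side not in SIDES:
            raise ValueError(f"lesion_side must be one of {SIDES}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")
        bad = np.argwhere(w < 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(f"negative weight at ({i}, {j}): {w[i, j]}")
        nzd = np.flatnonzero(np.diag(w))
        if nzd.size:
            raise ValueError(f"non-zero diagonal at region {nzd[0]}")
        asym = np.argwhere(w != w.T)
        if asym.size:
            i, j = asym[0]
            raise ValueError(
                f"asymmetric weights at ({i}, {j}): {w[i, j]} vs {w[j, i]}"
            )
        if self.state == "raw" and not np.array_equal(w, np.rint(w)):
            i, j = np.argwhere(w != np.rint(w))[0]
            raise ValueError(f"raw fiber counts must be integers; ({i}, {j}) = {w[i, j]}")
        if self.state == "normalized" and w.any() and not np.isclose(w.max(), 1.0):
            raise ValueError(f"normalized matrix must have max 1, got {w.max()}")

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_weights(self) -> np.ndarray:
        """Nonzero upper-triangle weights (one entry per undirected edge)."""
        triu = np.triu(self.weights, 1)
        return triu[triu > 0]


@dataclass
class SubjectRecord:
    """Clinical/demographic row for one subject.

    HAMD is the 17-item Hamilton Depression Rating Scale; a total score of
    7 or more defines the depressed (PSD) group, below 7 the non-depressed
    (PSND) group.
    """

    subject_id: str
    group: str  # "PSD" | "PSND"
    hamd: int
    age: float
    sex: str  # "male" | "female"
    infarct_size_cm3: float
    lesion_side: str
    covariates: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)  # nihss, mrs, bi, mmse

    def __post_init__(self):
        if self.group not in ("PSD", "PSND"):
            raise ValueError(f"group must be PSD or PSND, got {self.group!r}")
        if self.hamd < 0:
            raise ValueError("HAMD must be nonnegative")
        if self.group == "PSD" and self.hamd < 7:
            raise ValueError(f"PSD requires HAMD >= 7, got {self.hamd}")
        if self.group == "PSND" and self.hamd >= 7:
            raise ValueError(f"PSND requires HAMD < 7, got {self.hamd}")


# Fixed clinical-table dialect shared by the generator and the pipeline.
CLINICAL_COLUMNS = [
    "subject_id", "group", "hamd", "age", "sex", "infarct_size_cm3",
    "lesion_side", "hypertension", "diabetes", "cholesterol",
    "nihss", "mrs", "bi", "mmse",
]


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table and check the group/HAMD consistency rule."""
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    bad = df[(df["group"] == "PSD") & (df["hamd"] < 7)
             | (df["group"] == "PSND") & (df["hamd"] >= 7)]
    if len(bad):
        raise ValueError(
            f"group/HAMD rule violated for subjects: {bad['subject_id'].tolist()}"
        )
    return df


def _load_matrix(path: Path) -> np.ndarray:
    """Load a delimited 90x90 text matrix, sniffing comma vs whitespace/tab."""
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    try:
        mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse as a numeric matrix: {exc}") from exc
    return mat


def read_connectome(matrix_path, regions: RegionTable, subject_id: str = "",
                    lesion_side: str = "unknown") -> Connectome:
    """Read a raw fiber-count matrix from delimited text.

    The file must be a 90x90 numeric matrix (comma- or tab/space-delimited,
    no header).  Asymmetry is an error, not silently repaired: tractography
    count matrices should already be symmetric, and averaging would hide
    upstream bugs.  Errors name the offending row/column coordinates.
    """
    path = Path(matrix_path)
    w = _load_matrix(path)
    if w.shape != (N_REGIONS, N_REGIONS):
        raise ValueError(f"{path}: expected {N_REGIONS}x{N_REGIONS} matrix, got {w.shape}")
    c = Connectome(regions=regions, weights=w,
                   subject_id=subject_id or path.stem,
                   lesion_side=lesion_side, state="raw")
    log.info("read %s: %d edges", c.subject_id, c.n_edges)
    return c


def apply_threshold(c: Connectome, w_min: float = 10) -> Connectome:
    """Zero all fiber counts below the minimum count ``w_min``.

    The boundary is kept: an entry exactly equal to ``w_min`` survives
    (``w_min`` is a *minimum* admissible fiber number).  Operates on raw
    counts only, before normalization.
    """
    if c.state != "raw":
        raise ValueError(f"apply_threshold requires a raw connectome, got state={c.state!r}")
    if w_min <= 0:
        raise ValueError("w_min must be positive")
    w = np.where(c.weights >= w_min, c.weights, 0.0)
    out = replace(c, weights=w, state="thresholded")
    log.info("threshold w_min=%g: %d -> %d edges", w_min, c.n_edges, out.n_edges)
    if out.n_edges == 0:
        log.warning("threshold w_min=%g removed every edge for %s", w_min, c.subject_id)
    return out


def normalize_max(c: Connectome) -> Connectome:
    """Divide all weights by the largest entry, so max weight is exactly 1."""
    if c.state != "thresholded":
        raise ValueError(f"normalize_max requires a thresholded connectome, got state={c.state!r}")
    m = c.weights.max()
    if m == 0:
        raise ValueError(f"{c.subject_id}: no edges to normalize")
    return replace(c, weights=c.weights / m, state="normalized")


def check_connectedness(c: Connectome) -> list[int]:
    """Sizes of connected components (descending), any nonzero weight = edge."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = csr_matrix((c.weights > 0).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = sorted(np.bincount(labels).tolist(), reverse=True)
    if n_comp > 1:
        log.warning("%s: network splits into %d components %s",
                    c.subject_id, n_comp, sizes)
    return sizes


def orient_ipsilesional(c: Connectome) -> Connectome:
    """Align hemispheres so the lesioned side sits on the left-hemisphere ids.

    For a right-sided lesion every homotopic left/right pair is swapped in
    both rows and columns; after this, "ipsilesional" regions are always the
    atlas left-hemisphere ids across all subjects, so lateralized group
    comparisons line up.  The operation is an involution.
    """
    if c.lesion_side == "unknown":
        raise ValueError(
            f"{c.subject_id}: lesion side unknown; skip lateralized analyses "
            "for this subject or record a lesion side"
        )
    if c.lesion_side == "left":
        return replace(c, oriented=True)
    perm = c.regions.pair_permutation()
    w = c.weights[np.ix_(perm, perm)]
    return replace(c, weights=w, oriented=not c.oriented)
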