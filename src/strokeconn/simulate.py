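"""Seeded synthetic two-cohort connectome generator.

Emulates the statistical structure of a two-group (depressed vs.
non-depressed) post-stroke DTI connectome study, so that the whole
analysis pipeline runs end-to-end without any imaging data:

* per-subject 90-region modular small-world networks with integer
  fiber-count weights (log-normal), a strong homotopic (callosal)
  backbone linking hemispheres, and connectivity guaranteed after the
  fiber-count threshold of 10;
* a planted group effect in the depressed-like (PSD) cohort — long-range
  inter-module weights reduced (lower global efficiency) and
  within-module association weights increased (higher local efficiency),
  plus focal weight degradation at designated "lesioned" regions;
* clinical tables whose HAMD scores follow the group-specific moments of
  the study population (8.5 +/- 1.8 in PSD, 3.7 +/- 0.8 in PSND, with
  the >= 7 / < 7 group rule enforced by truncation) and are rank-coupled
  (Gaussian copula) to each PSD subject's local efficiency, so the
  planted metric-symptom association is exactly what a Spearman
  correlation estimates.

The generator plants the *assumptions* of the analysis (small-world
weighted connectomes, effect directions, score distributions); it does not
simulate diffusion physics or tractography.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .core import (CLINICAL_COLUMNS, N_REGIONS, Connectome, RegionTable,
                   apply_threshold, check_connectedness, normalize_max,
                   orient_ipsilesional)
from .metrics import _local_efficiency_matrix

log = logging.getLogger(__name__)

#: Regions with planted focal degradation in the PSD-like group, in the
#: ipsilesional (left-aligned) frame: superior frontal gyrus, posterior
#: cingulate, and contralesional middle temporal gyrus.
DEFAULT_LESIONED_REGIONS = ["Frontal_Sup_L", "Cingulum_Post_L", "Temporal_Mid_R"]


@dataclass
class Topology:
    n_modules: int = 4
    p_intra: float = 0.35
    p_inter: float = 0.06
    p_homotopic: float = 0.9


@dataclass
class WeightModel:
    lognormal_mu: float = 3.5
    lognormal_sigma: float = 0.8
    homotopic_mu_shift: float = 3.0  # callosal edges dominate all others
    homotopic_sigma: float = 0.2  # tight: they anchor the normalization


@dataclass
class Effects:
    global_eff_drop: float = 0.70  # inter-module (long-range) weight reduction
    local_eff_boost: float = 0.35  # intra-module weight increase
    lesioned_regions: list = field(default_factory=lambda: list(DEFAULT_LESIONED_REGIONS))
    lesion_drop: float = 0.30


@dataclass
class HamdModel:
    psd_mean: float = 8.5
    psd_sd: float = 1.8
    psnd_mean: float = 3.7
    psnd_sd: float = 0.8
    coupling: float = 0.8  # rank coupling of HAMD to local efficiency in PSD


@dataclass
class CohortSpec:
    """Full parameterization of the synthetic cohort."""

    n_psd: int = 31
    n_psnd: int = 23
    topology: Topology = field(default_factory=Topology)
    weight_model: WeightModel = field(default_factory=WeightModel)
    effects: Effects = field(default_factory=Effects)
    hamd_model: HamdModel = field(default_factory=HamdModel)
    master_seed: int = 0
    threshold: float = 10.0  # generated networks stay connected above this
    max_retries: int = 20

    def __post_init__(self):
        if self.n_psd < 2 or self.n_psnd < 2:
            raise ValueError("group sizes must be >= 2")
        for name, f in [("global_eff_drop", self.effects.global_eff_drop),
                        ("local_eff_boost", self.effects.local_eff_boost),
                        ("lesion_drop", self.effects.lesion_drop),
                        ("coupling", self.hamd_model.coupling)]:
            if not (0 <= f < 1):
                raise ValueError(f"{name} must be in [0, 1), got {f}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _module_of_pairs(spec: CohortSpec) -> np.ndarray:
    """Module id per region: homotopic pairs assigned to contiguous modules."""
    pair_module = np.concatenate([
        np.full(len(chunk), m)
        for m, chunk in enumerate(np.array_split(np.arange(N_REGIONS // 2),
                                                 spec.topology.n_modules))
    ])
    return pair_module[np.arange(N_REGIONS) // 2]


def _edge_masks(spec: CohortSpec, regions: RegionTable):
    """Boolean masks (upper triangle) for homotopic / intra / inter edges."""
    module = _module_of_pairs(spec)
    partner = regions.pair_permutation()
    iu, ju = np.triu_indices(N_REGIONS, 1)
    homotopic = partner[iu] == ju
    intra = (module[iu] == module[ju]) & ~homotopic
    inter = module[iu] != module[ju]
    return iu, ju, homotopic, intra, inter


def _subject_rng(spec: CohortSpec, index: int, purpose: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.master_seed), int(purpose), int(index)]))


def generate_base_connectome(spec: CohortSpec, subject_seed: int,
                             regions: RegionTable | None = None,
                             subject_id: str = "") -> Connectome:
    """One subject's raw fiber-count connectome before any group effect.

    Modular small-world topology: dense within modules, sparse between,
    with near-certain homotopic edges carrying the heaviest (callosal)
    weights.  Integer weights are log-normal.  Regeneration (bounded
    retries) guarantees the network is fully connected after the default
    fiber-count threshold.
    """
    regions = regions or RegionTable.aal90()
    iu, ju, homotopic, intra, inter = _edge_masks(spec, regions)
    wm, topo = spec.weight_model, spec.topology
    rng = _subject_rng(spec, subject_seed, purpose=1)
    for attempt in range(spec.max_retries):
        p = np.where(homotopic, topo.p_homotopic,
                     np.where(intra, topo.p_intra, topo.p_inter))
        present = rng.random(len(iu)) < p
        mu = np.where(homotopic, wm.lognormal_mu + wm.homotopic_mu_shift, wm.lognormal_mu)
        sigma = np.where(homotopic, wm.homotopic_sigma, wm.lognormal_sigma)
        weights = np.rint(np.exp(rng.normal(mu, sigma))).clip(min=1)
        vals = np.where(present, weights, 0.0)
        w = np.zeros((N_REGIONS, N_REGIONS))
        w[iu, ju] = vals
        w += w.T
        c = Connectome(regions=regions, weights=w, subject_id=subject_id,
                       lesion_side="left", state="raw")
        sizes = check_connectedness(apply_threshold(c, spec.threshold))
        if sizes[0] == N_REGIONS:
            return c
    raise RuntimeError(
        f"could not generate a post-threshold-connected network in "
        f"{spec.max_retries} tries; increase p_intra/p_inter or lower the threshold"
    )


def apply_group_effect(c: Connectome, spec: CohortSpec, group: str) -> Connectome:
    """Plant the depressed-group network effect on a base connectome.

    For PSD-like subjects: inter-module (long-range) weights are reduced by
    ``global_eff_drop``, intra-module association weights increased by
    ``local_eff_boost`` (homotopic backbone untouched, so it keeps anchoring
    the normalization maximum), and the rows/columns of the lesioned
    regions scaled down by ``lesion_drop``.  Weights are re-rounded to
    integer counts.  PSND-like subjects pass through unchanged.
    """
    if group == "PSND":
        return c
    if group != "PSD":
        raise ValueError(f"group must be PSD or PSND, got {group!r}")
    eff = spec.effects
    iu, ju, homotopic, intra, inter = _edge_masks(spec, c.regions)
    w = c.weights.copy()
    vals = w[iu, ju]
    vals = np.where(inter, vals * (1 - eff.global_eff_drop), vals)
    vals = np.where(intra, vals * (1 + eff.local_eff_boost), vals)
    lesioned = np.array([c.regions.index_of(r) for r in eff.lesioned_regions])
    if len(lesioned):
        touch = np.isin(iu, lesioned) | np.isin(ju, lesioned)
        vals = np.where(touch, vals * (1 - eff.lesion_drop), vals)
    vals = np.rint(vals)
    w[:] = 0.0
    w[iu, ju] = vals
    w += w.T
    return dataclasses.replace(c, weights=w)


def _truncnorm_ppf(u, mean, sd, lo=-np.inf, hi=np.inf):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_clinical(spec: CohortSpec, subject_ids: list[str], groups: list[str],
                      lesion_sides: list[str], eff_local: np.ndarray) -> pd.DataFrame:
    """Clinical table with HAMD coupled to local efficiency within PSD.

    HAMD is drawn via a Gaussian copula on ranks: a PSD subject's HAMD
    percentile is correlated (strength ``coupling``) with the rank of its
    network local efficiency, then mapped through the truncated-normal
    HAMD distribution (mean 8.5, SD 1.8, support >= 7).  PSND scores come
    from the complementary truncated normal (mean 3.7, SD 0.8, < 7),
    uncoupled.  Demographics and vascular covariates follow the study
    population's group-wise moments.
    """
    hm = spec.hamd_model
    if not (0 <= hm.coupling < 1):
        raise ValueError("coupling must be in [0, 1)")
    groups = np.asarray(groups)
    eff_local = np.asarray(eff_local, dtype=float)
    rng = _subject_rng(spec, 0, purpose=2)
    n = len(subject_ids)
    hamd = np.zeros(n, dtype=int)

    psd = np.flatnonzero(groups == "PSD")
    psnd = np.flatnonzero(groups == "PSND")
    # copula: latent normal correlated with the E_loc rank score
    z_metric = sps.norm.ppf((sps.rankdata(eff_local[psd]) - 0.5) / len(psd))
    z = hm.coupling * z_metric + np.sqrt(1 - hm.coupling**2) * rng.standard_normal(len(psd))
    u = sps.norm.cdf(z)
    hamd[psd] = np.maximum(7, np.rint(
        _truncnorm_ppf(u, hm.psd_mean, hm.psd_sd, lo=7)).astype(int))
    u2 = rng.uniform(size=len(psnd))
    hamd[psnd] = np.minimum(6, np.rint(
        _truncnorm_ppf(u2, hm.psnd_mean, hm.psnd_sd, lo=0, hi=7)).astype(int))

    is_psd = groups == "PSD"
    age = np.where(is_psd, rng.normal(64, 10, n), rng.normal(67, 12, n))
    sex = np.where(rng.uniform(size=n) < np.where(is_psd, 0.55, 0.65), "male", "female")
    # infarct volume: heavy-tailed; log-normal matched to group mean/SD
    def _ln_params(mean, sd):
        s2 = np.log(1 + (sd / mean) ** 2)
        return np.log(mean) - s2 / 2, np.sqrt(s2)
    mu1, s1 = _ln_params(5.6, 10.1)
    mu2, s2 = _ln_params(4.8, 9.8)
    infarct = np.where(is_psd,
                       rng.lognormal(mu1, s1, n), rng.lognormal(mu2, s2, n))
    htn = rng.uniform(size=n) < np.where(is_psd, 0.52, 0.48)
    dm = rng.uniform(size=n) < np.where(is_psd, 0.16, 0.17)
    chol = np.where(is_psd, rng.normal(4.8, 1.3, n), rng.normal(4.4, 1.5, n)).clip(min=1.5)
    nihss = np.rint(np.where(is_psd, rng.normal(4.5, 2.0, n),
                             rng.normal(3.0, 1.8, n))).clip(0, 20).astype(int)
    mrs = np.rint(np.where(is_psd, rng.normal(2.3, 0.9, n),
                           rng.normal(1.8, 0.9, n))).clip(0, 4).astype(int)
    bi = (5 * np.rint(np.where(is_psd, rng.normal(78, 15, n),
                               rng.normal(86, 12, n)) / 5)).clip(0, 100).astype(int)
    mmse = np.rint(rng.normal(26, 2.5, n)).clip(0, 30).astype(int)

    return pd.DataFrame({
        "subject_id": subject_ids,
        "group": groups,
        "hamd": hamd,
        "age": np.round(age.clip(30, 95)).astype(int),
        "sex": sex,
        "infarct_size_cm3": np.round(infarct, 2),
        "lesion_side": lesion_sides,
        "hypertension": htn.astype(int),
        "diabetes": dm.astype(int),
        "cholesterol": np.round(chol, 2),
        "nihss": nihss,
        "mrs": mrs,
        "bi": bi,
        "mmse": mmse,
    })[CLINICAL_COLUMNS]


def generate_cohort(spec: CohortSpec,
                    regions: RegionTable | None = None
                    ) -> tuple[list[Connectome], pd.DataFrame]:
    """Full synthetic cohort: raw connectomes plus the clinical table.

    Effects are planted in the ipsilesional (left-aligned) frame; subjects
    with a right-sided lesion are then flipped into the anatomical frame,
    so downstream analyses must re-orient with ``orient_ipsilesional`` —
    exactly as they would on real data.
    """
    regions = regions or RegionTable.aal90()
    groups = ["PSD"] * spec.n_psd + ["PSND"] * spec.n_psnd
    ids = [f"sub-PSD{i + 1:03d}" for i in range(spec.n_psd)] + \
          [f"sub-PSND{i + 1:03d}" for i in range(spec.n_psnd)]
    side_rng = _subject_rng(spec, 0, purpose=3)
    p_left = np.where(np.array(groups) == "PSD", 17 / 31, 12 / 23)
    sides = np.where(side_rng.uniform(size=len(ids)) < p_left, "left", "right")

    connectomes = []
    eff_local = np.zeros(len(ids))
    for k, (sid, grp, side) in enumerate(zip(ids, groups, sides)):
        base = generate_base_connectome(spec, k, regions=regions, subject_id=sid)
        c = apply_group_effect(base, spec, grp)
        # local efficiency in the analysis frame, for the HAMD coupling
        eff_local[k] = _local_efficiency_matrix(
            normalize_max(apply_threshold(c, spec.threshold)).weights).mean()
        c = dataclasses.replace(c, lesion_side=side)
        if side == "right":  # flip into the anatomical frame
            c = dataclasses.replace(orient_ipsilesional(c), oriented=False)
        connectomes.append(c)
    clinical = generate_clinical(spec, ids, groups, list(sides), eff_local)
    return connectomes, clinical


def write_cohort(spec: CohortSpec, out_dir) -> Path:
    """Write a cohort to disk: matrices/, regions.csv, clinical.csv, manifest.

    Matrices are integer fiber counts as headerless CSV; re-running with
    the same spec reproduces identical files.
    """
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    regions = RegionTable.aal90()
    connectomes, clinical = generate_cohort(spec, regions)
    for c in connectomes:
        np.savetxt(out / "matrices" / f"{c.subject_id}.csv",
                   c.weights.astype(int), fmt="%d", delimiter=",")
    regions.to_csv(out / "regions.csv")
    clinical.to_csv(out / "clinical.csv", index=False)
    manifest = {"spec": spec.to_dict(), "n_subjects": len(connectomes),
                "package_version": __version__}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("wrote %d subjects to %s", len(connectomes), out)
    return out
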