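"""End-to-end orchestration: cohort -> metrics -> statistics -> report.

The pipeline starts at the connectivity matrices (no imaging steps):
each subject's raw matrix is oriented to the lesion side, thresholded at a
minimum fiber count, max-normalized, and summarized by global/nodal graph
metrics and small-world parameters; group inference and metric-score
correlations then run on the per-subject tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (Connectome, RegionTable, apply_threshold,
                   check_connectedness, normalize_max, orient_ipsilesional,
                   read_clinical, read_connectome)
from .metrics import GLOBAL_METRIC_NAMES, compute_all
from .nullmodels import is_small_world, small_world_params
from .stats import DEFAULT_COVARIATES, run_correlations, run_group_comparison

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis parameters; defaults mirror the study's stated choices."""

    threshold: float = 10.0
    sweep: tuple = tuple(range(5, 16))  # fiber-count robustness sweep
    n_random: int = 100  # surrogates for small-world normalization
    permutations: int = 5000
    alpha: float = 0.05
    lambda_tol: float = 0.25
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    score_cols: list = field(default_factory=lambda: ["hamd", "nihss", "mrs", "bi", "mmse"])
    seed: int = 0
    include_nodal: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_cohort(in_dir) -> tuple[list[Connectome], pd.DataFrame, RegionTable]:
    """Load matrices/, regions.csv, and clinical.csv from a cohort directory."""
    in_dir = Path(in_dir)
    mat_dir = in_dir / "matrices"
    if not mat_dir.is_dir():
        raise FileNotFoundError(f"no matrices/ directory under {in_dir}")
    regions = (RegionTable.from_csv(in_dir / "regions.csv")
               if (in_dir / "regions.csv").exists() else RegionTable.aal90())
    clinical = read_clinical(in_dir / "clinical.csv")
    sides = dict(zip(clinical["subject_id"], clinical["lesion_side"]))
    connectomes = []
    for path in sorted(mat_dir.glob("*.csv")):
        sid = path.stem
        connectomes.append(read_connectome(path, regions, subject_id=sid,
                                           lesion_side=sides.get(sid, "unknown")))
    if not connectomes:
        raise FileNotFoundError(f"no matrix files in {mat_dir}")
    return connectomes, clinical, regions


def preprocess(c: Connectome, threshold: float, orient: bool = True) -> Connectome:
    """Lesion-side orientation, fiber-count threshold, max-normalization."""
    if orient and not c.oriented:
        c = orient_ipsilesional(c)
    t = apply_threshold(c, threshold)
    sizes = check_connectedness(t)
    if sizes[0] < len(t.weights):
        log.warning("%s: largest component %d/%d after threshold %g",
                    c.subject_id, sizes[0], len(t.weights), threshold)
    return normalize_max(t)


def subject_metrics(connectomes: list[Connectome], threshold: float = 10.0,
                    orient: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject global and nodal metric tables (tidy)."""
    g_rows, n_frames = [], []
    for c in connectomes:
        p = preprocess(c, threshold, orient=orient)
        gm, nm = compute_all(p)
        g_rows.append({"subject_id": c.subject_id, **gm.as_dict()})
        nf = nm.to_frame(p.regions.names)
        nf.insert(0, "subject_id", c.subject_id)
        n_frames.append(nf)
    return pd.DataFrame(g_rows), pd.concat(n_frames, ignore_index=True)


def smallworld_table(connectomes: list[Connectome], threshold: float = 10.0,
                     n_random: int = 100, seed: int = 0,
                     lambda_tol: float = 0.25, orient: bool = True) -> pd.DataFrame:
    """Per-subject gamma/lambda/sigma against degree-preserving surrogates."""
    rows = []
    for k, c in enumerate(connectomes):
        p = preprocess(c, threshold, orient=orient)
        r = small_world_params(p, n_random=n_random,
                               seed=int(np.random.SeedSequence(
                                   [int(seed), 7, k]).generate_state(1)[0] % 2**31))
        verdict, flags = is_small_world(r, lambda_tol=lambda_tol)
        rows.append({"subject_id": c.subject_id, "gamma": r.gamma,
                     "lambda": r.lambda_, "sigma": r.sigma,
                     "n_random_effective": r.n_random,
                     "is_small_world": verdict, **flags})
    return pd.DataFrame(rows)


def threshold_sweep(connectomes: list[Connectome], clinical: pd.DataFrame,
                    thresholds=tuple(range(5, 16)), orient: bool = True) -> pd.DataFrame:
    """Group mean differences of the global metrics at each fiber threshold.

    Used to check that the direction of the group effects does not depend
    on the (somewhat arbitrary) fiber-count cutoff.
    """
    groups = dict(zip(clinical["subject_id"], clinical["group"]))
    rows = []
    for w_min in thresholds:
        gdf, _ = subject_metrics(connectomes, threshold=w_min, orient=orient)
        gdf["group"] = gdf["subject_id"].map(groups)
        means = gdf.groupby("group")[GLOBAL_METRIC_NAMES].mean()
        for m in GLOBAL_METRIC_NAMES:
            rows.append({"threshold": w_min, "metric": m,
                         "diff_psd_minus_psnd": means.loc["PSD", m] - means.loc["PSND", m]})
    return pd.DataFrame(rows)


def analyze(global_df: pd.DataFrame, nodal_df: pd.DataFrame | None,
            clinical: pd.DataFrame, config: RunConfig,
            smallworld_df: pd.DataFrame | None = None) -> dict:
    """Group comparisons, correlations, and a JSON-serializable report."""
    comp = run_group_comparison(
        global_df, clinical,
        nodal_df=nodal_df if config.include_nodal else None,
        covariate_cols=config.covariates, B=config.permutations,
        seed=config.seed)
    scores = [s for s in config.score_cols if s in clinical.columns]
    corr = run_correlations(global_df, clinical, score_cols=scores,
                            covariate_cols=config.covariates)
    report = {
        "config": config.to_dict(),
        "package_version": __version__,
        "n_subjects": {g: int(n) for g, n in clinical["group"].value_counts().items()},
        "significant_global": comp["global"].loc[
            comp["global"]["p_perm_adj"] < config.alpha,
            ["metric", "observed_diff", "p_perm_adj"]].to_dict("records"),
        "significant_correlations": corr.loc[
            corr["p_bonferroni"] < config.alpha,
            ["metric_name", "score_name", "rho", "p_bonferroni"]].to_dict("records"),
    }
    if smallworld_df is not None:
        sw = smallworld_df.merge(clinical[["subject_id", "group"]], on="subject_id")
        report["small_world"] = {
            g: {
                "gamma_mean": float(sub["gamma"].mean()),
                "gamma_sd": float(sub["gamma"].std()),
                "lambda_mean": float(sub["lambda"].mean()),
                "lambda_sd": float(sub["lambda"].std()),
                "sigma_mean": float(sub["sigma"].mean()),
                "fraction_small_world": float(sub["is_small_world"].mean()),
            }
            for g, sub in sw.groupby("group")
        }
    if "nodal" in comp:
        hits = comp["nodal"].loc[comp["nodal"]["p_perm_adj"] < config.alpha,
                                 ["metric", "region", "observed_diff", "p_perm_adj"]]
        report["significant_nodal"] = hits.to_dict("records")
    return {"comparison": comp, "correlations": corr, "report": report}


def run_full(in_dir, out_dir, config: RunConfig) -> dict:
    """metrics + small-world + analyze on a cohort directory, with outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    connectomes, clinical, _ = load_cohort(in_dir)
    global_df, nodal_df = subject_metrics(connectomes, config.threshold)
    sw = smallworld_table(connectomes, config.threshold, config.n_random,
                          config.seed, config.lambda_tol)
    global_df.to_csv(out / "global_metrics.csv", index=False)
    nodal_df.to_csv(out / "nodal_metrics.csv", index=False)
    sw.to_csv(out / "smallworld.csv", index=False)
    res = analyze(global_df, nodal_df, clinical, config, smallworld_df=sw)
    res["comparison"]["global"].to_csv(out / "group_comparison_global.csv", index=False)
    if "nodal" in res["comparison"]:
        res["comparison"]["nodal"].to_csv(out / "group_comparison_nodal.csv", index=False)
    res["correlations"].to_csv(out / "correlations.csv", index=False)
    (out / "report.json").write_text(json.dumps(res["report"], indent=2, default=str))
    return res
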