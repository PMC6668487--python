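"""Group inference for connectome metrics.

Implements the study-style statistical battery: Welch t-tests (raw samples
or Table-style summary statistics), Fisher's exact test for proportions, a
label-shuffling permutation test of group mean differences with a
95th-percentile critical value, Spearman rank correlation with optional
covariate adjustment, and Bonferroni correction.

Covariate adjustment is by residualization: metric values are replaced by
the residuals of an ordinary least-squares fit on the covariates plus an
intercept.  For rank statistics (Spearman), both the metric and the score
are rank-transformed before residualizing, so the adjusted correlation is a
partial Spearman coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

#: Covariates adjusted for throughout the analysis: demographics, infarct
#: burden, and vascular risk factors.
DEFAULT_COVARIATES = ["age", "sex", "infarct_size_cm3",
                      "hypertension", "diabetes", "cholesterol"]


@dataclass
class PermutationResult:
    metric_name: str
    observed_diff: float  # group A mean - group B mean (PSD - PSND)
    null_quantile_95: float  # critical value in the tested direction
    p_perm: float
    B: int
    seed: int
    direction: str = "greater"
    significant_at_critical: bool = False


@dataclass
class CorrelationResult:
    metric_name: str
    score_name: str
    rho: float
    p_raw: float
    p_bonferroni: float
    n: int
    covariates: list = field(default_factory=list)


def _design_matrix(covariates: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    return x, names


def adjust_covariates(values, covariates, rank: bool = False) -> np.ndarray:
    """Residualize ``values`` on ``covariates`` plus an intercept.

    With ``rank=True`` the values are rank-transformed (average ties)
    before fitting, for use in rank-based analyses.  Raises on a
    rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(values, dtype=float)
    if rank:
        y = sps.rankdata(y)
    x, names = _design_matrix(covariates)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in covariates or metric; drop subjects first")
    # constant columns carry no information beyond the intercept
    varying = np.ptp(x, axis=0) > 0
    if not varying.all():
        dropped = [n for n, v in zip(names, varying) if not v]
        log.info("adjust_covariates: dropping constant columns %s", dropped)
        x = x[:, varying]
        names = [n for n, v in zip(names, varying) if v]
    design = np.column_stack([np.ones(len(y)), x])
    rank_x = np.linalg.matrix_rank(design)
    if rank_x < design.shape[1]:
        # identify columns that add no rank beyond the preceding ones
        bad = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
                bad.append(names[j - 1])
        raise ValueError(f"collinear covariate columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def ttest_metric(group_a, group_b) -> tuple[float, float, float]:
    """Welch unequal-variance two-sample t-test, two-sided.

    Returns (t, df, p).  If both groups are constant with equal means the
    convention t = 0, p = 1 applies.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, float(len(a) + len(b) - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ttest_from_summary(n1: int, mean1: float, sd1: float,
                       n2: int, mean2: float, sd2: float) -> tuple[float, float, float]:
    """Welch t-test from group summary statistics (n, mean, SD)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]])
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("fisher_exact_2x2: table has an all-zero margin")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def permutation_test(values, labels, B: int = 5000, seed: int = 0,
                     direction: str = "auto",
                     group_a: str = "PSD", group_b: str = "PSND") -> PermutationResult:
    """Label-shuffling permutation test of the group mean difference.

    The observed statistic is mean(A) - mean(B).  ``B`` random label
    assignments preserving the two group sizes build the null distribution
    of that difference.  The empirical p uses the add-one rule
    ``p = (1 + #{null at least as extreme}) / (B + 1)`` so p is never 0.

    ``direction``:
      * ``"greater"`` / ``"less"`` — strict one-tailed test at the
        95th-percentile critical value of the tested tail;
      * ``"auto"`` (default) — tests the observed direction and doubles
        the one-tailed p (capped at 1), since the direction was not fixed
        a priori.
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(y).all():
        raise ValueError("metric values must be finite")
    mask_a = labels == group_a
    mask_b = labels == group_b
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"both groups must be non-empty (got {n_a}, {n_b})")
    if B < 100:
        log.warning("permutation_test: B=%d is very small", B)
    y2 = y[mask_a | mask_b]
    obs = y[mask_a].mean() - y[mask_b].mean()

    rng = np.random.default_rng(seed)
    n = n_a + n_b
    # vectorized label shuffles: argsort of uniforms = random permutations
    order = np.argsort(rng.random((B, n)), axis=1)
    perm_vals = y2[order]
    null = perm_vals[:, :n_a].mean(axis=1) - perm_vals[:, n_a:].mean(axis=1)

    if y2.std() == 0:
        p_one = 1.0
        tested = "greater" if direction in ("auto", "greater") else "less"
    elif direction == "auto":
        tested = "greater" if obs >= 0 else "less"
    elif direction in ("greater", "less"):
        tested = direction
    else:
        raise ValueError(f"direction must be auto/greater/less, got {direction!r}")

    if tested == "greater":
        extreme = int((null >= obs).sum())
        crit = float(np.quantile(null, 0.95))
        signif = obs > crit
    else:
        extreme = int((null <= obs).sum())
        crit = float(np.quantile(null, 0.05))
        signif = obs < crit
    p_one = (1 + extreme) / (B + 1)
    p = min(1.0, 2 * p_one) if direction == "auto" else p_one
    return PermutationResult(
        metric_name="", observed_diff=float(obs), null_quantile_95=crit,
        p_perm=float(p), B=B, seed=seed, direction=tested,
        significant_at_critical=bool(signif),
    )


def spearman(metric_values, scores, covariates=None,
             metric_name: str = "", score_name: str = "",
             family_size: int = 1) -> CorrelationResult:
    """Spearman rank correlation, optionally adjusted for covariates.

    Without covariates this is the ordinary Spearman rho with average-tie
    ranks.  With covariates, both sides are rank-transformed, residualized
    on the covariates (partial Spearman), and Pearson-correlated; the p
    comes from the t approximation with the degrees of freedom reduced by
    the number of covariates.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for constant input")
    cov_names: list[str] = []
    if covariates is None:
        rho, p = sps.spearmanr(x, y)
        rho, p = float(rho), float(p)
    else:
        if isinstance(covariates, pd.DataFrame):
            cov_names = list(covariates.columns)
        rx = adjust_covariates(x, covariates, rank=True)
        ry = adjust_covariates(y, covariates, rank=True)
        rho = float(np.corrcoef(rx, ry)[0, 1])
        k = _design_matrix(covariates)[0].shape[1]
        df = len(x) - 2 - k
        if df <= 0:
            raise ValueError("not enough observations for the covariate set")
        t = rho * np.sqrt(df / max(1e-300, 1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(
        metric_name=metric_name, score_name=score_name, rho=rho, p_raw=p,
        p_bonferroni=min(1.0, family_size * p), n=len(x), covariates=cov_names,
    )


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: m * p capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else family_size
    return np.minimum(1.0, m * p)


def _compare_one(values: np.ndarray, labels: np.ndarray, covariates,
                 B: int, seed: int, name: str) -> dict:
    adj = adjust_covariates(values, covariates) if covariates is not None else np.asarray(values, float)
    a = adj[labels == "PSD"]
    b = adj[labels == "PSND"]
    t, df, p_t = ttest_metric(a, b)
    perm = permutation_test(adj, labels, B=B, seed=seed)
    return {
        "metric": name,
        "observed_diff": perm.observed_diff,
        "t": t, "df": df, "p_t": p_t,
        "p_perm": perm.p_perm,
        "null_q95": perm.null_quantile_95,
        "perm_direction": perm.direction,
        "significant_at_critical": perm.significant_at_critical,
    }


def run_group_comparison(global_df: pd.DataFrame, clinical: pd.DataFrame,
                         nodal_df: pd.DataFrame | None = None,
                         covariate_cols: list[str] | None = None,
                         B: int = 5000, seed: int = 0) -> dict[str, pd.DataFrame]:
    """Covariate-adjusted group comparison of every metric.

    ``global_df`` has one row per subject (columns: subject_id plus global
    metrics); ``nodal_df`` (optional) one row per subject x region with
    nodal metric columns.  Each metric gets a Welch t-test and a
    permutation test on covariate-adjusted residuals; Bonferroni families
    are the global metrics together, and the 90 regions within each nodal
    metric.  Returns tidy DataFrames keyed "global" and "nodal".
    """
    covariate_cols = DEFAULT_COVARIATES if covariate_cols is None else covariate_cols
    merged = global_df.merge(clinical, on="subject_id", validate="one_to_one")
    cov = _encode_covariates(merged, covariate_cols) if covariate_cols else None
    labels = merged["group"].to_numpy()
    metric_cols = [c for c in global_df.columns if c != "subject_id"]
    rows = []
    for i, m in enumerate(metric_cols):
        rows.append(_compare_one(merged[m].to_numpy(float), labels, cov,
                                 B, _child_seed(seed, 0, i), m))
    gdf = pd.DataFrame(rows)
    gdf["p_perm_adj"] = bonferroni(gdf["p_perm"], len(metric_cols))
    gdf["p_t_adj"] = bonferroni(gdf["p_t"], len(metric_cols))
    out = {"global": gdf}

    if nodal_df is not None:
        nrows = []
        regions = nodal_df["region"].unique()
        nodal_metrics = [c for c in nodal_df.columns if c not in ("subject_id", "region")]
        wide = nodal_df.pivot(index="subject_id", columns="region")
        wide = wide.loc[merged["subject_id"]]
        for mi, m in enumerate(nodal_metrics):
            for ri, r in enumerate(regions):
                res = _compare_one(wide[(m, r)].to_numpy(float), labels, cov,
                                   B, _child_seed(seed, mi + 1, ri), m)
                res["region"] = r
                nrows.append(res)
        ndf = pd.DataFrame(nrows)
        # Bonferroni within each metric's 90-region family
        ndf["p_perm_adj"] = ndf.groupby("metric")["p_perm"].transform(
            lambda p: bonferroni(p, len(regions)))
        ndf["p_t_adj"] = ndf.groupby("metric")["p_t"].transform(
            lambda p: bonferroni(p, len(regions)))
        out["nodal"] = ndf
    return out


def run_correlations(global_df: pd.DataFrame, clinical: pd.DataFrame,
                     score_cols: list[str] = ("hamd",),
                     covariate_cols: list[str] | None = None,
                     group: str | None = "PSD") -> pd.DataFrame:
    """Spearman correlations between metrics and clinical scores.

    By default restricted to the PSD group (where depression severity
    varies meaningfully) and adjusted for the standard covariates; the
    Bonferroni family is all metric x score pairs tested.
    """
    covariate_cols = DEFAULT_COVARIATES if covariate_cols is None else covariate_cols
    merged = global_df.merge(clinical, on="subject_id", validate="one_to_one")
    if group is not None:
        merged = merged[merged["group"] == group]
    cov = _encode_covariates(merged, covariate_cols) if covariate_cols else None
    metric_cols = [c for c in global_df.columns if c != "subject_id"]
    family = len(metric_cols) * len(score_cols)
    rows = []
    for m in metric_cols:
        for s in score_cols:
            res = spearman(merged[m].to_numpy(float), merged[s].to_numpy(float),
                           covariates=cov, metric_name=m, score_name=s,
                           family_size=family)
            rows.append(vars(res))
    return pd.DataFrame(rows)


def _encode_covariates(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Numeric covariate design: sex coded 1 = male, 0 = female."""
    out = {}
    for c in cols:
        v = df[c]
        if c == "sex" or v.dtype == object:
            out[c] = (v == "male").astype(float) if c == "sex" else pd.factorize(v)[0].astype(float)
        else:
            out[c] = v.astype(float)
    return pd.DataFrame(out, index=df.index)


def _child_seed(seed: int, block: int, i: int) -> int:
    return int(np.random.SeedSequence([int(seed), block, i]).generate_state(1)[0] % (2**31))
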