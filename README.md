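# strokeconn

Structural brain-connectome group analysis for stroke cohorts — built for
the question of whether post-stroke depression (PSD) leaves a signature
in the white-matter network's topology, and whether that signature tracks
depression severity.

Given per-subject 90×90 fiber-count connectivity matrices (AAL-90
parcellation) and a clinical table, the package:

* preprocesses each matrix (lesion-side orientation by homotopic
  left/right swap, minimum fiber-count threshold `w_min = 10`,
  max-entry normalization);
* computes the weighted graph measures — clustering coefficient *C*,
  characteristic path length *L* (edge length 1/w), global efficiency
  *E*<sub>glob</sub>, local efficiency *E*<sub>loc</sub>, and per-region
  degree, strength, clustering, betweenness, and nodal efficiency;
* normalizes *C* and *L* against 100 degree-preserving random surrogates
  to obtain γ = C/⟨C<sub>rand</sub>⟩, λ = L/⟨L<sub>rand</sub>⟩, and the
  small-worldness σ = γ/λ;
* compares groups with covariate-adjusted Welch t-tests and a
  5,000-shuffle permutation test (95th-percentile critical value,
  add-one empirical p), Bonferroni-corrected;
* correlates network measures with clinical scores (HAMD etc.) by
  covariate-adjusted partial Spearman correlation.

Because datasets of this design are not publicly deposited, the package
ships a seeded synthetic cohort generator that reproduces the statistical
structure the analysis assumes — modular small-world weighted networks
of two groups (n = 31 depressed-like vs n = 23 non-depressed-like) with
planted lower global / higher local efficiency, focal nodal degradation,
and HAMD scores rank-coupled to local efficiency.  Every stage of the
pipeline runs end-to-end with no external data.  See
[docs/methods.md](docs/methods.md) for the model and all conventions.

## Worked example

```python
import strokeconn as sc
from strokeconn.pipeline import subject_metrics
from strokeconn.stats import run_group_comparison, run_correlations

spec = sc.CohortSpec(master_seed=7)          # 31 PSD + 23 PSND subjects
conns, clinical = sc.generate_cohort(spec)

gdf, ndf = subject_metrics(conns, threshold=10)
comp = run_group_comparison(gdf, clinical, B=5000, seed=7)["global"]
print(comp[["metric", "observed_diff", "p_t", "p_perm", "p_perm_adj"]].round(4))

corr = run_correlations(gdf, clinical, score_cols=["hamd"])
print(corr[["metric_name", "rho", "p_bonferroni"]].round(4))
```

Output:

```
       metric  observed_diff  p_t  p_perm  p_perm_adj
 clustering_C         0.0048  0.0  0.0004      0.0016
path_length_L        11.5274  0.0  0.0004      0.0016
   eff_global        -0.0073  0.0  0.0004      0.0016
    eff_local         0.0089  0.0  0.0004      0.0016
  metric_name     rho  p_bonferroni
 clustering_C  0.6506        0.0017
path_length_L -0.5502        0.0175
   eff_global  0.5612        0.0141
    eff_local  0.6642        0.0012
```

Reading it: `observed_diff` is the covariate-adjusted group mean
difference (PSD − PSND).  Global efficiency is lower and local
efficiency higher in the depressed-like group, each with
Bonferroni-corrected permutation p ≈ 0.002 — the planted reorganization
toward a more segregated, lattice-like network is recovered.  The
partial Spearman ρ = 0.66 between local efficiency and HAMD within the
depressed group recovers the planted severity coupling (positive:
higher segregation, worse symptoms).

The same analysis is available from the shell:

```bash
strokeconn simulate --out cohort --seed 7
strokeconn metrics  --in cohort --out results --sweep 5..15
strokeconn analyze  --in cohort --out results --seed 7
strokeconn run      --out study --seed 7       # all three in one go
```

`analyze` writes tidy CSVs (global/nodal comparisons, correlations,
per-subject small-world parameters) plus `report.json` summarizing
small-world verdicts per group, significant metrics after correction,
and significant correlations.

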