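# Methods

## Scope and model

`strokeconn` analyzes structural brain networks of two-group stroke
cohorts.  A subject's network is a 90-node undirected weighted graph on
the AAL-90 parcellation (45 homotopic left/right region pairs, cerebellum
excluded); the raw edge weight `w_ij` is the streamline (fiber) count
between regions `i` and `j` from deterministic tractography.  The
pipeline starts at the connectivity matrix — image processing,
registration, and tractography are out of scope.

Preprocessing per subject:

1. **Lesion-side orientation.** Every homotopic row/column pair is swapped
   for subjects with a right-sided lesion, so "ipsilesional" is always
   the left-hemisphere index across subjects.  The operation is an
   involution and a permutation of node labels, so it changes no
   network-level metric, only the regional correspondence.
2. **Fiber-count threshold** `w_min` (default 10, the minimum admissible
   count; the boundary value survives).  Applied to raw counts — a count
   threshold is meaningless after rescaling.  An 11-point sweep
   (`w_min = 5..15`) quantifies robustness of group differences to this
   choice.
3. **Max-normalization.** The thresholded matrix is divided by its
   largest entry, removing between-subject differences in overall
   connectivity strength.  Asymmetric input is an error, never silently
   averaged: count matrices should arrive symmetric, and silent repair
   hides upstream bugs.

## Graph metrics

All measures use the standard weighted conventions of the Brain
Connectivity Toolbox family, on weights in [0, 1]:

* **Clustering** (Onnela): `C_i = (1/(k_i(k_i-1))) Σ_{j,h} (w_ij w_ih w_jh)^{1/3}`,
  zero for degree < 2; the network's `C` is the node mean.
* **Distances**: edge length `1/w`; Dijkstra all-pairs.  Characteristic
  path length `L` averages finite ordered pairs only and logs the count
  of excluded (disconnected) pairs.
* **Global efficiency**: `E_glob = mean over ordered pairs of 1/d_ij`
  with `1/∞ = 0`, so disconnection needs no special-casing.  Nodal
  efficiency is the per-node row mean; its node average equals `E_glob`
  identically.
* **Local efficiency**: `E_loc(i)` is the global efficiency of the
  subgraph induced by `i`'s neighbors (weights retained), zero for
  degree < 2.
* **Degree** is the binary suprathreshold edge count (strength, the
  weighted row sum, is reported alongside).  **Betweenness** is weighted
  shortest-path betweenness on `1/w` lengths with fractional tie
  splitting, unnormalized; a binary switch exists because the weighted
  choice is a convention, not a law.

Floating comparisons in tests are at 1e-9 relative tolerance;
`E_glob == mean(E_nodal)` is asserted at 1e-12.

## Small-world normalization

Each network is compared to 100 surrogates produced by double-edge swaps
(10 accepted swaps per edge, bounded attempts) that exactly preserve the
binary degree sequence, edge count, and the multiset of edge weights —
weights travel with the swapped edges.  γ = C/⟨C_rand⟩, λ = L/⟨L_rand⟩,
σ = γ/λ (mean aggregation over surrogates; surrogates with no finite
path are excluded and counted).  Surrogate seeds derive from a master
seed plus the surrogate index, so ensembles are reproducible.

A network is called small-world when γ > 1, |λ − 1| ≤ 0.25, and σ > 1.
The λ tolerance is deliberately 0.25: empirical DTI networks in this
regime show λ ≈ 1.2 and are conventionally called small-world; a 0.15
band would reject them.  It is configurable.

## Group inference

* **Covariate adjustment** is residualization: ordinary least squares of
  the metric on age, sex (male=1), infarct volume (cm³), hypertension,
  diabetes, and serum total cholesterol, plus an intercept; analyses use
  the residuals.  Constant covariate columns are dropped (they duplicate
  the intercept); genuinely collinear columns raise an error naming the
  culprits.  For rank analyses both variables are rank-transformed
  before residualization, making the adjusted coefficient a partial
  Spearman correlation (t-approximation p with df reduced by the number
  of covariates).
* **Welch t-tests** (unequal variances — the HAMD group SDs differ more
  than two-fold), from raw samples or from (n, mean, SD) summaries with
  Welch–Satterthwaite df.
* **Permutation test**: observed statistic is the group mean difference
  (PSD − PSND) of adjusted values; 5,000 label shuffles preserving group
  sizes; the 95th percentile of the null is the one-tailed critical
  value; the empirical p uses the add-one rule `(1 + #extreme)/(B + 1)`
  so p is never zero.  Because the tested direction is not fixed a
  priori, the default mode tests the observed direction and doubles the
  one-tailed p (capped at 1); strict one-tailed testing is a switch.
* **Bonferroni families**: the four global metrics together; the 90
  regions within each nodal metric; all metric × score pairs for the
  correlations.  Family sizes are recorded in the outputs.

Correlations with clinical scores (HAMD, NIHSS, mRs, BI, MMSE) are
computed within the depressed group, where symptom severity varies
meaningfully.

## Synthetic cohort generator

No public dataset exists for this design, so the generator produces
cohorts with exactly the statistical structure the analysis assumes.  It
is a model of the *data properties*, not of diffusion physics.

* **Topology**: the 45 homotopic pairs are split into 4 contiguous
  modules (both hemispheres of a pair share a module).  Edges appear
  with probability 0.35 within modules, 0.06 between, 0.9 for homotopic
  pairs.  Weights are rounded log-normals (μ=3.5, σ=0.8 on the log
  scale, i.e. median ≈ 33 streamlines).  Homotopic (callosal) edges are
  drawn with μ shifted by +3.0 and σ=0.2: they are the strongest and
  most stereotyped connections, and they therefore anchor the
  max-normalization denominator stably across subjects.  Generation
  retries (bounded) until the network is fully connected at the default
  threshold of 10.  With these defaults every subject lands in the
  small-world regime (γ ≈ 2–3, σ > 1).
* **Planted group effect** (depressed-like subjects only): inter-module
  weights × (1 − 0.70), intra-module weights × (1 + 0.35), homotopic
  backbone untouched, then re-rounding to integers.  Leaving the
  backbone fixed is essential: if the boost also scaled the matrix
  maximum, max-normalization would cancel it exactly and the planted
  local-efficiency increase would vanish.  Rows/columns of three
  "lesioned" regions (ipsilesional superior frontal gyrus, posterior
  cingulate, contralesional middle temporal gyrus) are scaled by 0.7,
  degrading their degree and nodal efficiency.  The fractions are
  calibrated so the group differences carry study-scale standardized
  effects (|d| ≈ 1.5–2): a study that reports p ≤ 0.001 for both
  efficiency contrasts at n = 31 + 23 must have effects of this size,
  and smaller fractions are invisible at these sample sizes.
* **Clinical table**: HAMD from group-specific truncated normals
  (8.5 ± 1.8 with support ≥ 7; 3.7 ± 0.8 with support [0, 7)), rounded
  and clipped to respect the ≥7/<7 group rule exactly.  Within the
  depressed group the HAMD percentile is tied to the rank of the
  subject's local efficiency through a Gaussian copula with coupling
  0.8, so the planted metric–symptom association is precisely the
  quantity a Spearman correlation estimates (observed adjusted
  ρ ≈ 0.7–0.8 at n = 31).  Truncation at 7 raises the realized PSD mean
  to ≈ 9.2.  Demographics and vascular covariates follow the study
  population's group-wise moments (age 64 ± 10 vs 67 ± 12, male fraction
  0.55/0.65, heavy-tailed log-normal infarct volumes matched to
  5.6 ± 10.1 / 4.8 ± 9.8 cm³, hypertension 0.52/0.48, diabetes
  0.16/0.17, cholesterol 4.8 ± 1.3 / 4.4 ± 1.5 mmol/L); disability
  scores (NIHSS, mRs, BI, MMSE) are plausible group-shifted draws
  included as correlate columns.  Lesion side is drawn per group
  (≈55%/52% left); effects are planted in the ipsilesional frame and
  right-lesion subjects are flipped into the anatomical frame on output,
  so analyses must re-orient — exactly as with real data.
* **Reproducibility**: every random stream derives from
  (master_seed, purpose, subject index) seed sequences; an identical
  spec reproduces byte-identical cohort files.

What passing tests on these cohorts show: the pipeline recovers planted
effect directions and associations of realistic magnitude at the study's
sample sizes, with calibrated type-I error.  What they cannot show:
robustness to tractography artifacts, distance-dependent false
positives, lesion-induced signal dropout, scanner effects, or any other
property of real diffusion data the generator does not model.

## Problem sizes in the shipped checks

The default test suite and the acceptance script scale their simulations
to: 20 replicate cohorts at B = 1,000 permutations for the
parameter-recovery check, B = 5,000 on the single fully analyzed cohort,
100 surrogates per subject for small-world normalization (16 subjects in
the acceptance run), 500 replicates × 1,000 permutations for type-I
calibration, and exhaustive brute-force oracles at n ≤ 7.  These sizes
were chosen so the whole battery completes in a few minutes while
keeping every Monte-Carlo tolerance far above its sampling noise.

## Known limitations

* The generator's modular block topology is a coarse stand-in for real
  cortical geometry; distance, curvature, and tract-length effects are
  absent.
* The permutation and t-test p-values answer slightly different
  questions once covariates are residualized out-of-loop (Freedman–Lane
  style refitting per permutation is not implemented).
* Nodal inference treats regions independently within a Bonferroni
  family; no spatial or cluster-level correction.
* `is_small_world` is a threshold rule on three continuous quantities;
  verdicts near the boundary should be read with the reported γ, λ, σ
  and surrogate spreads, not as a binary fact.
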