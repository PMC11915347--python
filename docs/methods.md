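# Methods

This note documents the models and procedures implemented in `gmconn`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Parcellation and edge bookkeeping

The default atlas has 75 grey-matter ROIs: 31 DKT-style cortical labels
per hemisphere and 13 subcortical parcels (medial brainstem; bilateral
thalamus, caudate, lenticular nucleus, amygdala, hippocampus,
cerebellum). The cerebellum and brainstem are treated as subcortical; the
brainstem, being medial, can never be homotopic. Every symmetric matrix
is vectorized as the row-major upper triangle with 0-based indices
i &lt; j (2775 edges for 75 ROIs); this single convention is used by all
serializations.

Edges are partitioned into five exhaustive, mutually exclusive
categories: cortico-subcortical, subcortico-subcortical,
cortico-cortical intra-hemispheric, inter-hemispheric homotopic (both
ROIs cortical and mutually partnered), and inter-hemispheric
non-homotopic. Boolean flags mark thalamo-cortical edges (a subset of
cortico-subcortical) and edges touching the primary sensorimotor
(precentral, postcentral, paracentral) or visual (pericalcarine, lateral
occipital, cuneus) systems. "Whole-brain" analyses use all 2775 edges;
subcortico-subcortical edges are kept there but are not one of the named
stratified subsets.

The exact cortical label set of the source parcellation is not published
as text, so the default atlas uses the standard 31-label DKT cortical
scheme; any atlas with the same schema can be supplied as CSV.

## Microstructural connectivity

For each group independently, each (ROI, metric) column is replaced by
its residual from one joint OLS on [1, PMA, GA, g_m], where g_m is the
per-subject global median of metric m across ROIs, itself residualized
on [1, PMA, GA]. Joint projection (rather than sequential) makes the
correction order-free; residuals are exactly orthogonal to every
regressor, which is why a planted linear age effect is removed to
machine precision. The global covariate is computed per metric; whether
to pool it across metrics is not determinable from the procedure's
description, and per-metric is the more conservative reading.

Scaling to [0, 1] is per metric over the pooled (subjects × ROIs) values
of the group — never across metrics, whose units are incommensurable
(diffusivities in mm²/s versus unitless fractions). Fingerprints are
concatenated subject-major; Pearson correlation is invariant to any
common ordering and to any positive affine transform per metric, both of
which are asserted by tests.

A deliberate property of the global-median covariate: it absorbs
variance shared across many regions, so between-region correlations
shift downward after correction (block contrasts can *increase*). This
is inherent to the procedure, not an artifact; the confound-free
recovery test therefore compares cohorts under identical treatment.

## Functional connectivity

Preprocessing order is filter → z-score → trim. The filter is a
4th-order Butterworth low-pass at 0.1 Hz applied forward–backward
(zero phase), so no lag-driven decorrelation is introduced. Z-scoring
uses the mean and SD of the retained (post-trim) support, making
retained series exactly zero-mean/unit-SD. At least 50 samples must
remain after trimming; Pearson correlations are unstable below that.
Group FC is the arithmetic mean of subject matrices; a Fisher-z option
exists but is off by default (plain averaging is the documented
procedure). Spatial smoothing is an image-space step upstream of ROI
extraction and is out of scope.

## Developmental change

ΔMC is the plain difference of absolute MC between sessions (the metric
tables are already age-residualized within group, so no further
weighting applies). For ΔFC, each session's edge gets a confidence
interval for the group mean, half-width z·SD/√n with z = 1.96 by
default (an SD-only variant is exposed); the raw mean difference is
multiplied by 1 − overlap, with overlap the Jaccard ratio
intersection/union of the two intervals (an intersection-over-shorter
variant is exposed). Two identical degenerate intervals overlap fully.
The construction is exactly antisymmetric under session swap, and the
weighted change never exceeds the raw difference. A mean-CI (rather than
dispersion interval) makes the shrinkage vanish as n grows, so reliable
differences survive.

## Edge statistics

* **Huber regression.** Iteratively reweighted least squares with
  Huber's weight function (tuning constant 1.345, 95% Gaussian
  efficiency), scale re-estimated each iteration as MAD(residuals)/0.6745
  (zero centre), convergence when coefficients move < 1e-8, at most 100
  iterations. On exactly linear data the scale is zero and the fit
  collapses to OLS. The slope SE uses the standard asymptotic estimator
  with Huber's small-sample correction factor; it agrees with the
  reference robust-regression implementation in statsmodels to ~1%,
  and the coefficients to ~1e-6. The IRLS core is batched over many
  response vectors so that permutation tests refit with the *same*
  estimator as the observed slope at low cost.
* **Permutation p for the slope.** The response is shuffled against the
  predictor N times (shuffling one margin is distributionally equivalent
  to shuffling both); p = (1+k)/(1+N) with k the number of permuted
  |slopes| at least as extreme. The add-one estimator avoids p = 0 and
  recovers the plain proportion as N grows.
* **Wilcoxon.** Smaller-rank-sum convention with zero differences
  dropped; this matters because printed W values depend on the
  convention. Matches a from-first-principles rank enumeration for
  small n.
* **Thresholding.** The top-fraction threshold is the k-th largest
  upper-triangle value with k = ceil(fraction·n_edges), per matrix
  (adapted) or over the pooled values of several matrices (common);
  ties at the threshold are all kept (deterministic, order-independent).
* **FDR.** Benjamini–Hochberg step-up via statsmodels, verified against
  a hand-coded step-up rule.

In MC–FC regressions MC is always the predictor and FC the response;
slopes are not symmetric under exchange. Group comparisons use absolute
MC values, because strongly negative microstructural covariation (e.g.,
fronto-subcortical edges driven by opposing FA/ODI trends) still marks a
related pair.

## Networks and multi-scale mutual information

Correlations map to distances by the cosine theorem, d = √(2(1−ρ)) —
the Euclidean distance between standardized profiles — using |ρ| for MC
and signed ρ for FC (configurable). Ward linkage runs on this distance
via scipy; cuts come from the merge order (`cut_tree`), which guarantees
exactly k non-empty, nested clusters and deterministic tie handling.

Because no single cluster count is privileged in a developing brain, two
dendrograms are compared over every cluster-size pair (k_a, k_b) ∈
2..75. MI is raw (natural log, unadjusted); the permutation null — one
labeling shuffled 100 times, cluster sizes preserved — plays the role
that chance-adjustment would. Significance is MI exceeding the
nearest-rank 95th percentile of the cell's null; significant cells are
summarized by their mean and SD. With no significant cell the summary is
"no significant overlap" (NaN mean), never an error.

Two numerical details matter here. First, observed and null MI are
computed through the identical integer-count code path (a cached
(c/n)·log(c/n) table), so that a shuffle reproducing the observed table
yields a bitwise-identical value. Second, exceedance uses a 1e-9
absolute tie tolerance: at near-singleton cuts all shuffles are
mathematically equivalent to the observed alignment, and without the
tolerance 1-ulp summation-order noise would be read as significance
(measured at ~25% false-positive rate at fine scales; ~5% after, in
agreement with the nominal level).

Raw MI grows with cut entropy, so mean-over-significant-cells summaries
are only comparable between comparisons of the same kind; a cohort-level
between-modality overlap is therefore reported as the mean of the three
groups' summaries, which also suppresses single-comparison chance
patches.

## Synthetic cohorts

The generator emulates the study design: preterm infants scanned twice
(identity and GA preserved across sessions; PMA redrawn independently,
matching the reported lack of session-age correlation) and matched
full-term controls, ages drawn uniformly within each group's reported
range (PMA ses1 28.3–36.9 w; ses2 and FT 38.4–44.9 w; GA 25.6–36.0 w
preterm, 37.4–42.3 w full-term).

Structure is planted through two latent layers shared (or not) across
modalities:

* a **block layer** — ROIs partitioned into `n_blocks` (default 5)
  groups, each with a per-subject factor; loading 0.6 by default;
* a **fine layer** — each ROI carries a unit vector in a 10-dimensional
  latent space (loading 0.35); pairwise dot products modulate edge
  strengths below the block scale, giving the correlation geometry a
  hierarchy rather than flat blocks.

Metric values add per-metric baselines with fixed regional jitter,
linear PMA/GA effects on centred ages (defaults follow perinatal
grey-matter trends: anisotropy and diffusivities falling, neurite
density and dispersion rising), an additive per-subject global offset
(SD 0.3), and residual noise (SD 0.5). All stochastic terms scale with a
per-metric amplitude so diffusivities keep mm²/s magnitudes. The
defaults give within-block MC of roughly 0.5–0.7 — typical of
structural-covariance modules; much smaller noise would saturate
correlations near 1 and hide longitudinal change. BOLD series mix the
same two latent layers with white Gaussian noise so that the mean
within-block temporal correlation equals `fc_block_rho` (0.6); series
default to T = 300 samples at TR 0.392 s (the module's stated default;
the acquisition it emulates would give roughly 2300 frames — tests that
need tighter FC estimates raise T explicitly).

Longitudinal change is planted as per-block shifts of the block
strengths between the preterm sessions (magnitude 0.3, direction drawn
per block). With `modalities_shared` (the default) the block partition,
the fine vectors, and the shift directions are common to MC and FC —
the co-evolution condition; otherwise each modality gets its own
partition, fine geometry, and shifts. One seed feeds named substreams
(covariates, blocks, metrics, time series, deltas), so changing one
stage's draws never perturbs another's, and regeneration is
bit-identical.

What the generator does **not** emulate: spatial autocorrelation and
geometry of real parcels, hemodynamics and motion/physiological noise,
non-linear maturation, heteroscedastic metric noise, subject dropout,
and any genuine biology of the negative MC edges. Passing tests
therefore establish that the *procedures* recover planted statistical
structure under realistic sizes and noise — not that real data carries
that structure.

## Pipeline, determinism, problem sizes

`run_full_analysis` executes: cohort → group MC/FC → paired Wilcoxon and
between-group robust regressions → MC–FC subset regressions per group →
ΔMC/ΔFC → six directionality regressions (co-evolution: ΔFC on ΔMC;
microstructure→function: ΔFC on MC at each session, later FC on ΔMC;
function→microstructure: ΔMC on early FC, later MC on ΔFC), BH-adjusted
as a family → twelve multi-scale MI comparisons (within modality between
groups; between modalities per group; longitudinal networks against each
other and against the opposite modality at both sessions) → thresholded
circos edge lists and a summary JSON. Every protocol number (0.1 Hz,
50-sample trim, 25% threshold, 1000 slope permutations, 100 MI shuffles,
k 2..75, 95th percentile, z 1.96) is a recorded, overridable config
default. The master seed spawns per-stage substreams; identical
(config, seed) runs produce byte-identical summary JSON, permutation
p-values included.

Validation experiments run at the study's scale where the check demands
it (45 subjects/group, 2775 edges, 75 ROIs) and scale only simulation
repetition counts: slope-permutation calibration uses 200 repeats at 200
permutations, MI calibration 500 repeats at 100 shuffles, co-evolution
discrimination 10 seeds at 200 slope permutations — sizes at which each
statistic's sampling error is far below the margins being asserted.

## Known limitations

* Group-wise MC has no subject-level variant, so MC uncertainty cannot
  be propagated; the CI-overlap weighting applies to FC only.
* Raw MI is entropy-scale dependent; comparisons of summaries are
  meaningful only between like-for-like comparisons (normalized
  variants are deliberately not the default, to keep the permutation
  null interpretable).
* Ward clustering is greedy; early merge errors propagate. The
  multi-scale MI comparison mitigates but does not remove this.
* The CI multiplier, overlap formula, and Wilcoxon convention are
  recorded configuration, since the procedures they implement admit
  more than one reading; results are reported alongside the resolved
  options in the run log.
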