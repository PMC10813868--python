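# Methods

This note documents the models implemented in `connqc`, the synthetic-cohort
generator that stands in for study data, the numerical conventions, and the
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Quality metrics

All three metrics are oriented so that lower is better.

**Inverse SNR.** `iSNR = -mean(I1, I2) / (std(I1 - I2) / sqrt(2))`, where
`I1, I2` are two volumes acquired back to back and all statistics run over
brain-masked voxels. The difference image cancels anatomy and leaves noise;
under independent equal-variance noise, `std(I1 - I2) = sqrt(2) * sigma`, so
the denominator estimates the single-volume noise SD. Two conventions are not
forced by the formula and are fixed here as follows:

- the mean is taken over the masked voxels of *both* volumes pooled, making
  the estimator symmetric in the two acquisitions (the alternative — the mean
  of the voxelwise average image — is numerically identical in expectation);
- the SD uses the sample (n−1) denominator, the unbiased choice for a noise
  estimate from a single difference image.

Identical volumes (zero difference variance) raise `UndefinedMetricError`
rather than returning an infinity. The estimator is invariant under uniform
intensity scaling of both volumes.

**Head motion.** The mean volume-to-volume translation
`sum_{i>=2} ||d_i - d_{i-1}|| / (N - 1)` in mm, from the translational
realignment parameters. Rotational parameters are parsed from 6-column
parameter files but do not enter the metric. The file dialect defaults to
the common order rotations (rad) then translations (mm), switchable to
translations-first, since parameter files in the wild use both.

**Atlas mismatch.** `1 - Dice(A, B)` on voxel *counts* in the native grid;
voxel dimensions cancel and are ignored. Both masks empty is an error.

## Synthetic cohort

The generator emulates a population cohort of ~5000 adults aged 40-75 with
oversampled type 2 diabetes, at the level of summary statistics the
downstream analyses consume. It is parameterized by
`connqc.presets`; the defaults are the published reference-cohort values.

**Covariates.** Age is truncated-normal on [40, 75]; because truncation pulls
the realized mean and SD away from the underlying parameters, the generator
solves numerically for the (mu, sigma) whose *truncated* moments equal the
configured mean 59.4 / SD 8.7. Sex is Bernoulli with 0 = male, 1 = female —
chosen so that a positive sex coefficient on connectivity reproduces the
published sign pattern (men have lower overall structural connectivity).
Education is ordinal 1-3 and diabetes status ordinal 0-3 (none, prediabetes,
T2DM, other), matching analyses that report a single coefficient per
variable; the rare "other diabetes" class sits at the top of the ordinal
scale. BMI is normal; relative WMH volume is log-normal with (mu, sigma)
derived in closed form from the configured median and quartiles, and is
always log10-transformed before modelling. Covariates are mutually
independent except a Gaussian-copula age-WMH correlation (default 0.4, a
typical magnitude for lesion burden vs age); R² values of fitted models are
therefore structure-dependent and only coefficient recovery is treated as a
calibration contract. Printed category percentages that sum to 100.1% due to
rounding are renormalized.

**Quality metrics.** Each standardized metric is
`sum_k beta_k z(covariate_k) + residual`, with the residual SD completing the
outcome variance to 1 (configurations implying negative residual variance are
rejected with a diagnostic). Residuals are exactly centered so the rescaled
metrics hit the configured native means exactly; this "exact
standardization" trades a negligible O(1/n) perturbation of refitted
coefficients for deterministic calibration of the means. Residuals across
metrics are correlated: the config specifies target *total* metric-metric
Pearson correlations (defaults: dMRI iSNR-motion 0.298, rs-fMRI iSNR-motion
0.522, dMRI-fMRI motion 0.21) and the generator solves
`rho = (r_target - cov(lp1, lp2)) / (s1 s2)` for the residual correlation,
since the covariate-shared part of the correlation is already substantial
(~0.15 for the rs-fMRI pair). Metrics are rescaled to the configured native
means/SDs (e.g. dMRI motion 0.64 (0.16) mm); motion is clipped at zero with a
logged count (the clipped mass is negligible for dMRI and ~2% for rs-fMRI
motion, whose mean is 1.5 SD above zero).

**Connectomes.** A seeded base template places the 94 regions in a unit box
with two hemisphere blocks (odd labels left, even right); edge strength
decays exponentially with Euclidean distance times a log-normal jitter,
yielding the spatially clustered, intra-hemisphere-dominated topology of real
connectomes. The SC template additionally carries an edge *prevalence* that
increases with strength rank (strongest quintile ~0.93-1.0), so consensus
edges are near-universal but not universal — individual masked node degree
then averages ~17.8 with realistic between-subject variation. The FC template
uses a weaker distance decay, a homotopic (mirror-pair) boost, and weights
mapped into (0, 0.7], which puts the consensus mask's interhemispheric edge
share near 40% (vs ~11% for SC).

Each participant's connectome is the template modulated subject-wise: the
subject's *overall connectivity* target is linear (on the standardized scale)
in the seven covariates and three modality-matched quality metrics per the
configured fully-adjusted coefficient sets, plus unit-variance-completing
noise, rescaled to the configured native mean/SD (SC 5.3e-3 (0.6e-3), FC
0.32 (0.03)). Edge-level noise is multiplicative log-normal for SC (keeps
nonnegativity; Bernoulli edge presence per the template prevalence) and
additive Gaussian clipped at zero for FC (SD 0.15, chosen so a subject's
weakest consensus edges are sometimes absent, as when negative correlations
are clipped in real data). Weights are then rescaled so the realized overall
connectivity equals the subject's target exactly — for FC via a short fixed
point iteration that respects the [0, 1] clip. Setting all coefficients,
noise scales and edge noise to zero (the `null` preset limit) makes every
participant share the base template exactly.

**What the generator does not emulate.** No raw k-space physics, EPI
distortion fields, physiologic noise spectra, tractography biases, or
region-level (nodal) effect heterogeneity: subject effects act through a
global scaling, so edge-level and nodal statistics carry no covariate signal
beyond the overall factor. Passing tests therefore demonstrate the
correctness of the estimators and of the confound arithmetic under the
configured linear structure — not that real tractography or BOLD data meet
that structure. The normalized clustering and efficiency of the synthetic
networks fall in realistic ranges but are emergent properties of the template
geometry, not calibrated targets.

**Randomness.** All randomness flows from one root seed; named substreams
(`cohort`, `quality`, `template`, `overall`, `edges`/participant-index,
per-participant null seeds) are derived via CRC-32-hashed labels fed to
`numpy.random.SeedSequence`, so identical configs give byte-identical outputs
and stages can be re-run independently.

## Connectome construction and consensus

Functional connectivity residualizes each regional series on the 8 nuisance
series plus an intercept before correlating, and clips negatives *after* the
residual correlation — the stated order of operations. Constant residual
series yield undefined correlations; affected edges are zeroed and counted.
Structural edges require at least two tracts between a region pair.

Consensus masks rank edges by the group value (SC: prevalence of the
binarized edge; FC: mean weight) and keep the top `K = round((1 - sparsity)
* 4371)` (round-half-to-even; at sparsity 0.80, K = 874 — reproducing the
published consensus-network edge count exactly, which a literal
"present in ≥80% of participants" cut need not). The literal prevalence cut
is available as `prevalence_threshold` for comparison. Ties break
deterministically: larger group value, then lexicographic region order.
Overall connectivity is the mean over all 4371 pairs, zeros included,
computed before masking; averaging only nonzero entries would change the
scale but not the associations, and the all-pairs reading matches the
"mean of all weights" convention.

## Graph measures and null models

Weighted clustering uses the Onnela geometric-mean triangle intensity on
globally max-normalized weights — the standard toolbox convention, though the
variant is the main comparability knob across studies; for binary weights it
reduces to the classic clustering coefficient. Efficiency uses Dijkstra
shortest paths with edge length 1/weight; disconnected pairs contribute
zero. ν is *binary* degree (not strength), consistent with masked individual
networks retaining most consensus edges.

Null networks are degree-preserving double-edge swaps of the binary topology
with weights carried along with their edges (no weight reshuffling): the
"same size, sparsity and degree" constraint binds the topology only. Default
10 swaps per edge, 100 nulls per network, independent seeded ensembles per
individual (recorded for audit); rigid graphs (e.g. complete) exhaust the
attempt budget and return the identity, logged. Normalization divides the
observed measure by the null-ensemble mean; a zero null mean (e.g. a
triangle-free star) is an error rather than an infinity.

## Confound statistics

All regressions are OLS on z-scored outcome and predictors (standardized
betas), two-sided t-test p-values, alpha 0.05, no multiple-testing correction.
Percent change after quality adjustment is signed and relative to Model 1:
`(b2 - b1)/b1 * 100` — this convention reproduces every published change
cell, including sign flips (−240%) and amplifications (+322%), which
magnitude-based alternatives do not; the same formula applies to the R² rows.
A coefficient is flagged *relevant* when it was significant in Model 1 and
moved by more than the configured threshold (default 10%). The
quality-determinant regressions fit the full seven-covariate model by
default, with an optional p-value-driven forward-selection mode (entry
alpha 0.05) for comparison with stepwise-reported tables.

The motion-aging equivalence converts standardized effects into interpretable
units: a `delta` mm motion increase shifts the standardized outcome by
`beta_motion * delta / sd_motion`, and the age change with the same effect is
`|beta_motion / beta_age| * (delta / sd_motion) * sd_age` years. This
ratio-of-standardized-effects construction is adopted because it reproduces
the published 18.3-year figure from the published inputs; the original
derivation is not spelled out in the source material.

## Problem sizes and numerical choices

Calibration and parameter-recovery checks run at the full cohort size
(n = 5110; Monte-Carlo over 20 seeds for recovery, tolerance 0.03 on
standardized coefficients). The sparsity-sweep trend check uses a consensus
built from 60 synthetic participants with measures on 12 of them and
20-network null ensembles — sizes chosen as the smallest at which the
consensus ranking is stable enough for the monotone trends to be assessed
(with very small consensus samples, prevalence ties near the threshold make
the high-sparsity clustering trend noisy). Graph-measure oracles use
exhaustive enumeration on graphs of at most 8 nodes (tolerance 1e-10);
`networkx` serves as an independent cross-check, never as the implementation.
Fixture iSNR checks use masks of >= 1e4 voxels, where the estimator's
sampling error is well inside the 10% tolerance; motion and mismatch checks
are exact by construction.

## Known limitations

- The generator's subject effects are global scalings; nodal heterogeneity,
  edge-specific covariate effects and distance-dependent motion artifacts are
  out of scope.
- R² values of quality-determinant models depend on the unpublished covariate
  correlation structure and are not calibration targets.
- FC average node degree and normalized clustering of the synthetic networks
  are plausible but not calibrated to the reference cohort's values.
- No B0/distortion modelling, motion estimation, tractography or rs-fMRI
  band-pass filtering: quality metrics consume preprocessed inputs (motion
  traces, masks, volumes) as provided.
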