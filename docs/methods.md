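# Methods

## Data model

The unit of analysis is a per-subject, per-run, per-condition volumetric
z-statistic map on a shared boolean mask with one affine. In memory this is a
`PatternDataset`: an (n_samples × n_mask_voxels) matrix plus a
subject/run/condition attribute row per sample. Inputs are assumed already
standardized (z units), so no per-sphere feature scaling is applied anywhere.
On disk a dataset is one NIfTI-1 volume per map, a mask NIfTI, a
tab-separated trait table (`subject_id  PT  FS  EC  PD`), and a JSON manifest
binding files to attributes; NaN marks out-of-mask voxels in written volumes
and is masked on read. Voxel indices are 0-based; world coordinates appear
only in cluster tables, via the affine.

## Searchlight decoding

For every in-mask voxel the sphere of Euclidean radius r (in voxel units,
membership |Δ|² ≤ r², truncated at mask edges, never padded) defines the
feature set. Defaults are r = 5 for group and pairwise analyses and r = 3 for
within-subject analyses, both configurable.

Classification is a linear SVM. Multiclass problems use the one-vs-one
reduction with majority vote; vote ties are broken by the summed (bounded)
binary decision values. The regularization constant defaults to
C = 1 / mean‖x‖₂ over training rows — a scale-adaptive choice that keeps the
effective regularization comparable across spheres of different size and
signal scale — and can be overridden. Cross-validation folds are
leave-one-subject-out (group: train on every other subject's rows, all runs
and conditions) or leave-one-run-out (within one subject). Fold accuracies
are averaged unweighted, even when folds have unequal test sizes (subjects
with three vs four runs), and written to the sphere's centre voxel. A fold
whose training labels lack a class is excluded with a logged warning.

Two implementation notes that do not change the model:

- each sphere's linear Gram matrix is computed once and the SVM is re-fit per
  fold on kernel slices, which is algebraically identical to fitting on the
  raw features;
- sample rows are put in canonical (subject, run, condition) order before
  fitting, because the SMO solver may break exact ties by sample order; with
  canonicalization the accuracy map is invariant to how the input stack was
  arranged, and this invariance is tested.

Pairwise (two-condition) searchlights restrict the rows to one condition pair
and run the group scheme with chance 0.5; with four conditions there are six
pairs. These serve the diagnostic of whether one uniquely distinguishable
condition drives a four-way result.

## Significance thresholds

Two corrections are computed in parallel; the operating threshold is the more
conservative (larger):

**Permutation null with resel-wise Bonferroni.** Condition labels are
shuffled within each subject × run block — preserving run structure and exact
class balance, the natural exchangeability unit — and the full
cross-validation re-run on one sphere's features; the distribution of mean
accuracies over permutations is the null. The per-test alpha divides 0.05 by
the number of resolution elements: non-overlapping spheres packed greedily
into the mask in lexicographic scan order (deterministic and reproducible; a
user-supplied resel count such as 725 is also accepted). The accuracy
threshold is the smallest observed value matched or exceeded strictly fewer
than ⌊α·n_perms⌋ times; an empirical-quantile alternative
(`method="quantile"`) is exposed. When α·n_perms < 1 the null cannot resolve
the level: a warning is issued and the null maximum plus one resolution step
is returned, so nothing observed passes.

**Exact binomial with voxel-wise Bonferroni.** Under chance p and n test
predictions per voxel, the threshold is k*/n for the smallest k* with exact
upper-tail P(X ≥ k*) ≤ α_per-test, computed by exact tail sums (no normal
approximation). The trial count n is an explicit argument — it is the total
number of test predictions contributing to a voxel's accuracy — and is never
inferred silently. Binary maps mark voxels with accuracy strictly above the
threshold.

**Known limitation (measured here).** Cross-validated predictions are not
independent: folds share most of their training data. At small sample sizes
this inflates the standard deviation of null searchlight accuracy to ~1.2×
the binomial value (measured on 12-subject, 3-run noise datasets), so the
binomial threshold is mildly anticonservative at desk scale: across 200
noise-only pipeline simulations its family-wise false-positive rate was 0.14
rather than ≤ 0.05, and the acceptance test for that property fails and says
so. At study scale (hundreds of stacked maps, dozens of folds, large
spheres) the inflation shrinks and the binomial threshold typically becomes
conservative relative to the permutation null; the permutation route is the
safer of the two at any scale and is the reason both are provided.

## Trait correlation

One sub-scale at a time, the demeaned score (constant regressors are
rejected) is the single regressor of a per-voxel OLS with intercept; the
slope t statistic — a monotone transform of the Pearson correlation in this
design — is the voxel statistic. Zero-variance voxels get t = 0;
zero-residual voxels are capped at ±10⁶. TFCE integrates extent^E · height^H
over height steps (E = 0.5, H = 2, 6-connectivity, 100 equal steps up to the
map maximum by default, or a fixed dh), the published convention for the
algorithm. FWE correction compares the observed TFCE map against the
permutation distribution of the mask-wide maximum TFCE statistic, the
regressor being randomly re-associated with subjects in each of n_perms
permutations (default 5000); p = (1 + #{null ≥ obs})/(1 + n_perms), so p
never reaches zero, and voxels with 1 − p ≥ 0.95 are significant. The test is
one-sided (positive association) by default — the direction of the
theoretical prediction — with a two-sided option that enhances |t|. Each
sub-scale runs in its own model; no correction across the four sub-scales is
applied, which callers should account for. Nuisance covariates and
residual-permutation schemes are out of scope. The conjunction mask is the
voxel-wise AND of the group significance mask (whose source — binomial or
permutation threshold — is an explicit argument, not a default) and the
trait significance mask.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the physiology that produces it. Each spherical signal ROI gets one unit-norm
multivoxel template per condition, drawn once from `pattern_seed` and shared
by all subjects and runs; a sample is amplitude × template plus iid Gaussian
noise at every in-mask voxel, optionally Gaussian-smoothed
(σ = FWHM/(2√(2 ln 2)) / voxel size). The trait linkage acts only through
amplitude: amplitude_i = base + trait_beta · (PT_i − mean PT), clipped at
zero with a logged count — the simplest mechanism by which a trait score
makes patterns more separable. Trait tables draw each IRI sub-scale as the
sum of 7 independent uniform{0..4} items (mean 14, variance 14);
the sub-scales are mutually independent, a stand-in rather than a claim about
any empirical sample, whose inter-correlations are not modelled. Pattern and
noise streams are independently seeded so geometry can be held fixed while
noise varies; generation is bitwise reproducible given config, traits and
seeds.

What the generator does **not** emulate: haemodynamics and temporal
structure, GLM estimation error correlated across conditions, motion and
registration artifacts, spatial noise correlation (unless smoothing is
switched on), inter-subject anatomical variability, and realistic effect
topographies. Passing tests therefore demonstrate the correctness and
calibration of the machinery under the assumed model, not performance on
real scans.

## Default scales and numerical choices

- Fixture scale for tests: 20×20×20 grid (2 mm voxels), 12 subjects, 3 runs,
  4 conditions — small enough for continuous testing, large enough for
  radius-5 spheres.
- Planted-linkage fixture (recovery tests, chosen once from a pilot at this
  scale): 6³ grid, ROI at the grid centre with radius 2 voxels, base
  amplitude 1.5 z, noise SD 0.4 z, trait_beta 0.3 z per PT point, 20 subjects
  × 3 runs, subject searchlight radius 1, TFCE with 50 steps, 300
  permutations.
- Calibration suites run 200 simulated experiments each on 4³–5³ grids, with
  permutation counts (400–600) and TFCE steps (25–50) reduced from the
  defaults; the chance-calibration checks sample sphere centres at random
  (seeded) rather than exhaustively, since the map mean is the estimand.
- Ties and degenerate inputs: empty masks, single subjects, single runs,
  identical condition pairs, constant regressors and constant-accuracy voxels
  all raise or return documented values rather than propagating NaN; the
  affine agreement tolerance on load is 1e-4.

## Acceptance computation

`scripts/acceptance.py` recomputes the null calibration of the four-way group
searchlight: ten pure-noise datasets at the default fixture scale, radius-5
leave-one-subject-out decoding, accuracy sampled at 150 seeded random sphere
centres per dataset, reported as the mean over all 1500 sphere accuracies
together with that count. All seeds derive from the single `--seed` argument.
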