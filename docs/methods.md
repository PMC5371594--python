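# Methods

## The classification model

`mklpet` addresses a two-group problem — idiopathic Parkinson's disease (PD)
versus the pooled atypical syndromes (MSA ∪ PSP) — and its three-group
extension, using volumes of dopaminergic PET/SPECT-like data that are
assumed co-registered to a common grid.

**Soft-margin SVM in the dual.** For labels y_i ∈ {−1, +1} and a positive
semidefinite kernel K, the solver maximizes
`Σ a_i − ½ Σ a_i a_j y_i y_j K_ij` subject to `Σ a_i y_i = 0`,
`0 ≤ a_i ≤ C`. It is a sequential-minimal-optimization loop with
second-order working-set selection; the stopping rule bounds the width of
the feasible bias interval (`max_{I_up}(y_i − f_i) − min_{I_low}(y_j − f_j)
< 1e-8`), which bounds the KKT violations directly. The bias is the mean of
`y_i − f_i` over free support vectors, or the interval midpoint if none are
free. Correctness is contracted by tests, not by the algorithm choice: the
KKT suite at 1e-4, agreement of the dual objective with an independent
SLSQP quadratic-programming solve to 1e-6, an analytic two-point solution,
and decision-value agreement with libsvm (via scikit-learn) on random
problems. The inner loop is JIT-compiled with numba when available; a
pure-Python twin is used otherwise.

**Positive class.** Atypical parkinsonism (MSA ∪ PSP) is +1, so
"sensitivity" reads as the detection rate of the atypical syndromes — the
clinically costly miss. Decision values of exactly zero predict +1, making
predictions deterministic.

**Multiple-kernel combination.** One linear kernel per atlas region,
combined as `k = Σ_m q_m k_m` with q on the simplex. q is chosen by grid
search only (0.1-step lattice with every q_m ≥ 0.1, i.e. 9 candidates for
two kernels, 126 for five), jointly with C ∈ {2^−3 … 2^5}, by
stratified 5-fold cross-validation **within the training partition**; ties
resolve to the smaller C, then the lexicographically smallest q, so results
are independent of enumeration order. Warm starts across the ascending C
values reuse the previous optimum (feasible, since the box only grows).

**Region importance and selection.** A linear SVM on all in-brain voxels
gives the primal weights w = Σ a_i y_i x_i. Region importance is the mean
of |w| over the region's voxels; the absolute value is used because voxels
of opposite sign within one region would otherwise cancel (a signed variant
sits behind a flag). Importances are min–max normalized to [0, 1] for maps;
normalization is monotone, so rankings are unaffected. The top-5 regions by
importance are selected per cross-validation fold from training data only.
The C of this selection SVM is fixed at 1.0 (selection only consumes the
ranking of |w| means, which is insensitive to C over a wide range).

**Evaluation harness.** Outer k = 10 stratified folds (class-stratified
because 24-member classes can otherwise vanish from a fold; an unstratified
fallback with a warning covers classes smaller than k). Per fold:
whole-brain SVM → region ranking → top-5 → nested grid search → final MKL
model → prediction of the held-out fold. Pooled out-of-fold predictions
give accuracy/sensitivity/specificity (binary) or per-class recalls
(one-vs-one multiclass, majority vote, ties broken by the largest summed
|decision value| among the tied class's wins). The multimodal mode appends
a DaTSCAN-striatum kernel to the five selected DMFP region kernels. In the
multiclass mode the per-fold region selection uses the idiopathic-vs-
atypical contrast — the importance map is defined for a binary
discrimination, and this contrast is the study question; per-pair grid
search and training then use only each pair's samples.

**Permutation test.** Significance of the cross-validated accuracy is the
fraction of relabeled runs whose accuracy is ≥ the observed one, where each
of the n_perm runs repeats the complete pipeline — including region
selection — under a random permutation of the labels. The plain fraction is
the default; the (b+1)/(m+1) estimator is available as an option. Because
features and Gram matrices do not depend on labels, they are computed once
and shared across permutation runs; this is an exact optimization, not an
approximation.

**ROC and t-maps.** ROC curves sweep all distinct decision-value
thresholds (scikit-learn's sweep, no intermediate dropping); AUC is the
trapezoid integral and equals the Mann–Whitney statistic with ties counted
one half. The univariate map is a pooled-variance two-sample t per voxel
(df = n₁+n₂−2), converted to z through the one-sided tail (directional
contrast convention), thresholded at p < 0.001 uncorrected per direction,
with suprathreshold voxels grouped into 26-connected clusters reported with
voxel count, volume in mm³, peak t and peak z. Voxels with zero pooled
variance get t = 0 and a flag.

## The phantom

The generator emulates the structure of a three-group dopaminergic-imaging
cohort (default sizes PD 39 / MSA 24 / PSP 24). The default grid is
40×48×34 at 2 mm — a half-scale version of a typical 79×95×68 PET matrix,
chosen to keep full pipelines desk-fast while preserving anatomy-like
layout; a compact 24×28×20 / 3 mm preset (`PhantomSpec.small`) serves the
registration experiments, and any shape is accepted.

Regions are disjoint spheres: bilateral putamen and caudate (baseline 10),
thalamus (2), olfactory region and supplementary motor area (1.5), plus
five filler regions (1.5) that never carry effects and act as negative
controls. Striatal baselines are ~10× extrastriatal ones, reflecting the
concentration of D2/3 ligand signal in the striatum; a diffuse brain
ellipsoid at 0.5 provides extrastriatal background. DaTSCAN-like phantoms
reuse the machinery with extrastriatal baselines scaled by 0.02, mimicking
a tracer with almost purely striatal signal.

Group effects are **multiplicative uptake factors** per (group, region) —
tracer-binding semantics. Defaults: MSA putamen 0.65 / caudate 0.75 /
thalamus 0.85; PSP putamen 0.70 / caudate 0.75 / SMA 0.80 / thalamus 0.90;
PD olfactory 0.70; these magnitudes are in the range of reported striatal
binding losses in atypical parkinsonism and give a discriminable but
non-trivial problem at n ≈ 20–90. `PhantomSpec.strong()` deepens them
(0.40–0.55 with noise 0.3) for discrimination checks; `PhantomSpec.null()`
removes all effects for calibration checks. Noise is i.i.d. Gaussian
(sd 0.4) added before 4 mm FWHM smoothing, yielding spatially correlated
noise as in reconstructed emission images. Per-subject seeds derive from
the master seed via `SeedSequence([seed, subject, modality])`, so cohorts
are bit-reproducible and pure functions of (spec, seed).

What the phantom does **not** model: PET physics (attenuation, scatter,
partial volume, anisotropic scanner PSF), nonlinear anatomical variability,
within-region effect gradients, or realistic intensity units. Passing tests
therefore demonstrate the correctness and statistical calibration of the
pipeline, not clinical-grade performance on real DMFP data.

## Preprocessing

Registration fits the 12-parameter affine (3 translations mm, 3 rotations
rad, 3 zooms, 3 shears; matrix R·Z·S about the grid center, trilinear
resampling, zero fill) by Nelder-Mead on the mean squared intensity
difference at three resolutions (both volumes smoothed 8 / 4 / 0 mm), with
the translation initialized from the center-of-mass offset and parameters
scaled to comparable step sizes. No priors on zooms or shears are imposed:
the contract is "minimizes the similarity cost", which is testable —
recovery of random rigid perturbations within 8 mm / 8° lands at a median
error well under 0.5 voxel. If the search cannot improve on the identity,
the identity is returned with a warning flag (and without one when source
and reference are already identical).

Templates register all inputs to an explicitly indexed reference (callers
wanting the "randomly chosen" behaviour pass a seeded random index), average
the registered volumes with their left-right midplane reflections, smooth
at 8 mm, and symmetrize (`0.5·(T + reflect(T))`), which is bit-exact because
IEEE addition commutes.

Intensity normalization divides by I_max, the mean of the ⌈0.001·N⌉
largest intensities (minimum one voxel) over the brain-mask population —
masked by default so that air cannot enter the top set, whole-volume as an
option, since the original description ("per image") does not specify the
population. The operation is scale-invariant and leaves the mean of the
top set at exactly 1.

The pipeline's whole-brain mask is the union of the atlas support and an
intensity threshold (5% of the cohort-mean maximum by default); the
stand-alone mask op uses a configurable fraction (default 0.1). "All voxels
inside the brain" has no canonical definition for these data, so both knobs
are exposed.

## Numerical choices and degenerate inputs

- SMO tolerance 1e-8 (bias-interval width), max 200k iterations;
  alphas snapped to the box within 1e-14 so index-set tests stay exact.
- Indefinite kernels beyond −1e-8·scale get a diagonal ridge with a
  warning; asymmetry beyond 1e-10 is an error.
- Grid-search validation scores are integer correct-counts; the
  smaller-C-then-lex-q tie rule makes the winner well defined even on
  plateaus (a saturated plateau therefore resolves to the smallest C and
  the lexicographically smallest q — by design, not accident).
- Min–max normalization of a constant weight map returns all zeros.
- Region importance averages over region ∩ feature-mask voxels (N_r is the
  count of voxels that actually carry weights); an empty intersection is an
  error.
- t-map z values are capped by flooring tail probabilities at 1e-300
  before the normal quantile; zero-variance voxels are flagged, not NaN.
- Simplex weights are generated as integer compositions divided by the
  lattice denominator, keeping sums within 1e-12 of 1.
- Files are written float32; all in-memory arithmetic is float64.

## Problem sizes used by the shipped experiments

Chosen once as realistic desk-scale study conditions: discrimination and
ROC on 60 subjects (30 per arm, strong effects, full 9×126 grid, k = 10);
three-group runs on 29 subjects (13/8/8, k = 5); selection recovery on 20
cohorts of 20 subjects each (default effects, 5 outer folds → 100
selection events); full-pipeline permutation test with n_perm = 199 on a
20-subject cohort; permutation type-I calibration with 200 replicates of a
lightweight fixed-C 5-fold pipeline at n_perm = 99; registration recovery
over 10–20 perturbations of the compact phantom. A full 87-subject default
cohort with the complete grid runs in a few seconds on one CPU with numba.

## Known limitations

- The affine registration is intra-modality MSD only; no mutual
  information, so cross-modality registration is out of scope.
- Atlas and volumes must share a grid; there is no resampling between
  mismatched spaces.
- Grid-search weight identification is coarse by construction (integer
  validation counts on small folds); on saturated problems the tie rule,
  not the data, picks q.
- One-vs-one voting can still tie after the magnitude tie-break in
  principle; the final fallback is class-name order.
- The permutation test's runtime scales linearly in n_perm × pipeline
  cost; the label-independent precomputation keeps it tractable but a
  1,000-permutation run at full cohort size remains a minutes-scale job.
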