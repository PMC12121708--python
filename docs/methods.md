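# Methods

This note documents the models implemented in `mvpattern`, the conventions
and numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the design decisions taken where more than one
reasonable reading existed.

## Data model and conventions

The universal container is the `PatternDataset`: one length-V vector per
(run, condition) under a shared binary mask on a `VolumeGrid` (default
3 mm isotropic voxels). Vectors are ordered by ascending flat voxel index
with the x axis varying fastest (Fortran order of the `[x, y, z]` array);
ROI masks, searchlight members, statistic maps and Moran's-I weights all
use this one ordering, so indices are interchangeable across modules.

Contrast patterns are plain per-run differences
`pattern(run, plus) − pattern(run, minus)`, with `minus="rest"` meaning a
zero baseline. No pooled-error t statistic is formed: the pipeline ingests
first-level maps and treats them as opaque pattern vectors, which keeps
the pattern geometry that the similarity, classification and regression
stages operate on. Whether the input maps are t maps or beta maps is
deliberately left to the caller.

## Synthetic data generator

`generate_pattern_dataset` draws

    pattern(r, c) = Σ_k loading[c, k] · s_k + η_r + ε_{r,c}

with `s_k` unit-variance Gaussian fields (optionally smoothed to a chosen
FWHM, standardized within the mask) that are *fixed across runs* — the
participant's stable signal; `η_r` a fresh unit-variance field per run
scaled by `run_noise_sd`, shared by all conditions of that run — the
run-shared physiological noise that motivates excluding within-run RSM
cells; and `ε` i.i.d. `N(0, obs_noise_sd²)`. The implied population
correlation between two condition patterns is an explicit function of the
loading matrix and the noise SDs, which is what the parameter-recovery
tests exploit.

Block schedules use rejection sampling: shuffle each run's multiset of
blocks until no condition occupies two adjacent blocks (retry cap 10,000),
after a closed-form infeasibility check. The default test design is the
study design: 7 conditions × 5 runs × 2 blocks per condition = 14 blocks
per run.

The generator does **not** emulate HRF-convolved time series, motion or
scanner drift, anatomical variability across subjects, or non-Gaussian
noise. Passing tests therefore demonstrate that the *estimators* recover
planted structure under the model's own assumptions — not that those
assumptions hold in any particular scanner dataset.

Smoothing (`smooth_volume`) is separable Gaussian convolution; kernels are
given as mm FWHM (converted per axis, so anisotropic voxels are handled
correctly, never averaged) or directly as an SD in voxel units
(FWHM = SD·√(8·ln 2)·voxel size). Out-of-mask voxels are zero-filled
before convolution and re-masked afterwards; the volume boundary itself is
mirrored, so a constant unmasked volume is a fixed point. Mask-edge
attenuation is therefore visible rather than hidden, and tested.

## RSA

Items are (condition, run) pairs, ordered conditions-first in declared
label order with runs ascending — fixed so neural and model matrices align
by construction. The neural RSM is the Pearson correlation matrix of item
patterns (zero-variance patterns raise an error rather than propagating
NaN). Each binary model RSM keeps only the conditions relevant to its
hypothesis (self=other keeps self/other/semantic; self=introspection and
self=memory keep the self and semantic conditions plus that task's pair),
sets 1 on cross-run self↔partner cells and 0 on every other valid cell.
The validity mask removes the diagonal, same-run pairs and same-condition
pairs. For 5 runs this yields 60 valid cells (20 ones) for the
three-condition model and 120 valid cells (20 ones) for the
four-condition models.

Kendall's tau-a is computed by explicit O(n²) pair enumeration over valid
cells — at most a few hundred cells, so the exact all-pairs-denominator
definition doubles as a transparent reference implementation. Ties add
zero to the numerator and full weight to the denominator, which is why
tau-a (not tau-b) is the right statistic against a binary model.

## Classifier MVPA

`SVC(kernel="linear", C=cost)` with cost 1 by default; folds are runs,
each test fold holding exactly one pattern per class. Labels are +1 for
class a; a decision value of exactly 0 goes to class b, and a fold whose
two training classes are identical falls back to predicting class a and is
flagged — both rules exist purely to make folds bit-reproducible. No
feature scaling is applied beyond optional sphere-mean removal
(subtracting each vector's own mean), since rescaling would change the
margins relative to the procedure being modeled. Sphere-mean removal
defaults to on in the searchlight (local pattern shape, not amplitude) and
off for ROI-level classification, exposed as an explicit flag in both.

One interpretive caveat: the self>semantic vs other>semantic classification
shares the semantic control condition between its two classes. The shared
control correlates the two contrasts, so the measured discriminability of
the self and other conditions is, if anything, an underestimate; the
computation follows the stated design, and the caveat belongs to the
interpretation, not the code.

## Searchlight

Sphere membership uses exact integer arithmetic on squared distances
(d² ≤ r², radius in voxel units; 3 voxels ≡ 9 mm at 3 mm isotropic,
maximum 123 voxels), so no floating-point boundary ambiguity exists; on
anisotropic grids distances are computed in mm per axis. Edge spheres keep
whatever members are in-mask (configurable minimum size, default 1). The
executor accepts any pure per-sphere statistic; a failing center yields
NaN with a warning instead of aborting the map, and results are
independent of traversal order.

## Group inference

Subject maps are centered at their theoretical null value (0 for tau-a,
0.5 for accuracy), optionally smoothed at 4 mm FWHM, and tested with a
one-sample t per voxel. The voxel-forming threshold is the parametric
t quantile at the requested voxel p (df = n−1) — with a dual-threshold
option (lenient inside a hypothesis ROI, stricter outside) — and the
permutation part is reserved for cluster-extent FWE: random per-subject
sign flips generate the null distribution of the maximum suprathreshold
cluster size, and cluster p = (1 + #{perm max ≥ size})/(1 + n_perm). This
plain-t cluster-forming rule is a deliberate simplification of
variance-smoothed pseudo-t approaches. When n_perm reaches 2^n subjects
the null is enumerated exhaustively (with a warning). Connectivity is
6-neighbour by default (18/26 configurable). Overlap maps are voxelwise
conjunctions with a minimum-cluster-size filter.

## Run-pair regression, noise ceiling, variance partitioning

Every regression pairs the dependent contrast from run *a* with predictor
contrasts from run *b* ≠ *a* (ordered pairs; 20 for 5 runs), so run-shared
noise cannot inflate fits. OLS always includes an intercept; patterns are
not voxel-standardized (the choice is surfaced, default raw). Betas, R²
and adjusted R² (n = ROI voxels, p = predictors) are averaged over pairs.
The noise ceiling appends the dependent contrast from the predictor run as
an extra predictor; being a strict superset model, its R² bounds the full
model's on every pair.

Commonality portions come from inclusion–exclusion over the seven
sub-model R² values (each averaged over the same 20 pairs, so they are
commensurable). The algebra requires *raw* R² — adjusted R² is not
additive — so portions use raw R² while adjusted R² is reported alongside
for the full and ceiling models. Negative portions (suppressor structure)
are reported as-is, never clipped. Explainable variance is
100 · (full adjusted R²)/(ceiling adjusted R²) per subject, averaged;
subjects with a nonpositive ceiling are excluded with a warning.

## Smoothness-matched permutation null

Naively shuffling voxels destroys spatial autocorrelation and makes a
permutation null anticonservative. The implemented remedy:

1. **Smoothness estimate.** Moran's I with inverse-Euclidean-distance
   weights over ROI voxel pairs (zero diagonal; full matrix for ROIs up to
   2,000 voxels, a 12 mm distance cutoff beyond that). Under spatial
   independence E[I] = −1/(N−1); I is invariant to affine transforms of
   the values.
2. **Kernel calibration.** For each SD on the grid 0–2.0 (step 0.02, voxel
   units — at 3 mm voxels the typical calibrated values are physically
   sensible sub-voxel kernels), shuffled copies of the observed map are
   smoothed and their Moran's I compared to the observed value; the SD
   minimizing the summed squared difference wins, ties to the smaller SD.
   The same permutation draws are reused across the whole SD grid (common
   random numbers): discrete Gaussian kernels with SD below ~0.25 voxels
   are numerically identical to no smoothing, and reusing draws makes such
   kernel-identical SDs tie exactly instead of being separated by
   simulation noise.
3. **Null generation.** Each of the 1,000 iterations draws one voxel
   permutation and applies it *identically* to the self-condition pattern
   of every run — preserving the cross-run reliability structure the
   shuffle must keep intact — smooths at the calibrated SD, then rescales
   each shuffled pattern to its original mean and SD. The rescale matters:
   smoothing shrinks marginal variance as a side effect, which would make
   null regression statistics systematically smaller than the observed
   ones (measurably inflating type-I error); Moran's I is
   location/scale-invariant, so the smoothness match is untouched.
   Contrasts are then recomputed from the shuffled condition and the
   statistic (betas, adjusted R², variance portions) re-evaluated.
4. **p-values.** Add-one rule, p = (1 + #{null ≥ observed})/(1 + n_perm);
   right-tailed by default (the hypotheses are directional), two-sided by
   flag. p can never be 0; the same seed yields bit-identical nulls. A
   failing iteration is resampled, capped at 1% of n_perm.

## Problem sizes in the shipped test suite

The statistical suites run at sizes chosen to make their Monte-Carlo error
comfortably smaller than the asserted bands: chance-level classification
uses 200 signal-free replicates at 300 voxels; planted-portion recovery
uses 20 synthetic subjects at 10,000 voxels (population portions from the
generator covariance are the oracle, solved so the unique-O portion is
0.10 and the all-common portion 0.15); the permutation-null type-I check
uses 200 no-signal replicates at 216 voxels with 200 permutations each and
a coarsened calibration grid (0–1, step 0.1, 20 repetitions — an i.i.d.
map calibrates to an SD near 0 at any grid resolution); the group-level
type-I check uses 100 null samples of 20 subjects at 100 permutations.

## Known limitations

* First-level GLM, preprocessing and acquisition are out of scope; the
  pipeline starts from per-run condition patterns.
* The cluster test uses plain t for cluster forming (no variance
  smoothing), and inference for regression betas is delegated entirely to
  the permutation null — no spatial-autocorrelation-adjusted parametric
  standard errors are provided.
* Model RSMs are binary only; continuous models, rank-transformed RDMs and
  cross-validated (crossnobis) distances are not implemented.
* The calibrated-shuffle null tracks the *observed* map's Moran's I, a
  single draw; for small ROIs its sampling noise propagates into the
  chosen SD (visible in the calibration tests).
* Multi-ROI analyses emit uncorrected p-values (a Bonferroni helper is the
  caller's responsibility); no FDR machinery is included.
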