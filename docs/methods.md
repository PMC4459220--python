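# Methods

## The measurement

Voxel-mirrored homotopic connectivity (VMHC) quantifies resting-state
cooperation between the cerebral hemispheres: for each voxel *v* on a
left–right symmetric grid, VMHC(*v*) is the Pearson correlation between
the BOLD time series at *v* and at its mirrored counterpart
*mirror(v)*, obtained by reversing the voxel index along the
left–right axis.  The Fisher transform z = atanh(r) (zVMHC) puts the
statistic on an approximately normal scale for group inference.  The
package computes per-subject VMHC/zVMHC maps inside a gray-matter mask
(probability ≥ 0.40), compares them across three groups — schizophrenia
patients with auditory verbal hallucinations (AVH), patients without
(NonAVH), and healthy controls — with a framewise-displacement-covaried
voxelwise ANOVA and Gaussian-random-field (GRF) cluster correction, and
correlates regional sphere means with clinical ratings (PANSS
subscales/total across patients, AHRS within the AVH group).

Mirroring is pure index reversal on the symmetric grid; the left–right
axis length must be even so no voxel is its own mirror.  No per-subject
registration is performed: synthetic cohorts are generated directly on
a common symmetric grid, which stands in for the nonlinear warp to a
symmetric template used with real scans.  The symmetric-template
constructor `(mean + flip(mean))/2` is provided and is exactly
flip-invariant in floating point.

## Preprocessing chain

Fixed order: discard of initial volumes → framewise displacement (FD)
and motion exclusion → nuisance regression → spatial smoothing →
linear detrend → temporal band-pass.

- **Volume discard**: default 10 of 240 volumes (TR = 2 s), leaving
  230 frames.
- **FD**: Power-style scalar, FD(t) = Σ|Δd| + 50 mm · Σ|Δθ(rad)|, with
  FD(1) = 0.  The per-subject mean FD is the covariate carried into
  group models.
- **Exclusion**: a subject is dropped when any per-axis excursion from
  the first retained frame strictly exceeds 2.0 mm (translation) or
  2.0° (rotation).
- **Nuisance regression**: least-squares residualization against an
  intercept, the six rigid-motion parameters, and mean signals from
  ventricle and white-matter masks supplied with the cohort.
  Rank-deficient designs are pruned deterministically (leftmost column
  of a dependent set kept) with a warning.
- **Smoothing**: separable Gaussian, FWHM 4 mm,
  σ = FWHM/(2√(2 ln 2)) scaled by voxel size, reflective boundaries
  (mass-conserving).
- **Detrend**: per-voxel best-fit line removed.
- **Band-pass**: ideal discrete-Fourier mask retaining 0.01–0.08 Hz
  inclusive and zeroing everything else including DC.  This matches the
  legacy frequency-domain toolbox behaviour and is exactly testable
  against an FFT oracle; it is idempotent to machine precision.

Slice timing, rigid realignment, registration, and segmentation are out
of scope; motion influences the pipeline only through the traces, FD,
exclusion, and regression.

## Group statistics

- **First level**: voxelwise one-sample t of zVMHC against zero,
  two-tailed p, Benjamini–Hochberg FDR at q = 0.01 inside the mask,
  then a connected-component extent filter (≥ 20 voxels,
  26-connectivity).
- **ANCOVA**: per voxel, F for the group factor from
  z ~ 1 + 2 group dummies (Control reference) + demeaned mean FD,
  computed as a residual-sum-of-squares comparison between the full and
  the reduced (intercept + FD) model; df = (2, n − 4).  With a constant
  covariate the column is dropped and df adjusts.  The implementation
  agrees with a brute-force per-voxel `lstsq` oracle to < 1e−8 and its
  voxelwise type-I error at p < 0.05 is calibrated (≈ 0.05 over 2000
  null voxels).
- **Two-sample maps**: covariate-adjusted GLM contrast t, df = n − 3.
  With two groups, F = t² exactly.
- **Z conversion**: F and t fields are mapped to standard-normal
  deviates with the same tail probability (F one-sided, t
  sign-preserving), so cluster-forming thresholds are on the Z scale
  (default Z = 2.3).
- **Smoothness**: per-axis FWHM from the variance of spatial first
  differences of voxelwise-standardized (demeaned) residuals, inverted
  through the Gaussian autocorrelation model
  ρ(δ) = exp(−δ²/(4σ²)); resels = mask voxels · ∏(voxel/FWHM).  The
  estimator recovers a known 6 mm kernel within a few percent given
  ~20 residual maps; small map counts bias it mildly low.
- **GRF cluster correction**: expected cluster count
  E[m] = R·ρ₃(z₀) with the 3-D EC density
  ρ₃(z) = (4 ln 2)^{3/2}(2π)^{−2}(z²−1)e^{−z²/2}; extent tail
  P(S ≥ k) = exp(−βk^{2/3}) with β matched to the expected extent
  E[N]/E[m]; familywise cluster p = 1 − exp(−E[m]·P(S ≥ k)); clusters
  kept at corrected p < 0.05.
- **Permutation oracle**: group labels permuted with covariates kept
  per subject; the maximum supra-threshold cluster size per permutation
  yields a nonparametric familywise reference distribution.
- **ROIs and post hocs**: cluster peaks (maximum statistic, ties to the
  smallest linear index) define 5 mm spheres by voxel-center distance —
  19 voxels on a 3 mm grid; pairwise group contrasts on sphere means
  use the pooled within-group variance from the one-way ANOVA
  (df = N − 3) with Bonferroni correction (×3, capped at 1).
- **Three-way classification**: a region is AVH-only when
  Control-vs-AVH is significant but Control-vs-NonAVH is not,
  NonAVH-only for the reverse, shared when both are significant.

### Known accuracy limits of the GRF approximation

Monte-Carlo calibration (this package's own experiments) shows the
standard cluster-extent approximation reproduces the expected cluster
count and mean extent to a few percent, but its exponential extent tail
is too heavy at the low forming threshold Z = 2.3: corrected p-values
are overestimated roughly twofold in the 0.05–0.2 range, independent of
smoothness (tested at 2.7–5.3 voxel FWHM).  Consequently the observed
familywise error at α = 0.05 sits near 0.01–0.03 (conservative), and
agreement with the permutation oracle is close (within ~0.02) for
clusters near or below the decision threshold but degrades for
mid-range p.  Decisions at α = 0.05 are therefore valid but mildly
conservative; the permutation oracle is the arbiter whenever the
approximation is in doubt.

## Correlation analyses

Pearson r between regional zVMHC sphere means and clinical scores, with
the exact two-tailed p from t = r√(n−2)/√(1−r²), df = n − 2.  Cohorts:
all patients (AVH ∪ NonAVH after motion exclusion) for PANSS, AVH only
for AHRS.  Missing scores (AHRS outside AVH) are handled by pairwise
deletion, never imputation.  No multiplicity correction is applied by
default, matching the uncorrected published-style tables; a
Benjamini–Hochberg flag exists.  Rounding to two decimals happens only
at serialization.

## Synthetic cohorts

The generator emulates the study's data structure: TR = 2 s, 240
volumes with the first 10 flagged for discard, 3 mm isotropic grid
(default 20×24×20 — a scaled-down head, so planted regions reuse
anatomical names at scaled-in coordinates rather than published peak
coordinates), group sizes 16/18/20 after exclusion (a `study_cohort`
layout provides 18/18/20 with 2 planted AVH motion outliers, retaining
54), an ellipsoidal flip-symmetric gray-matter probability volume, and
PANSS/AHRS scores with Table-1-plausible means and spreads.

Each mirror pair of voxel series is built as
x = √ρ·c + √(1−ρ)·e₁, y = √ρ·c + √(1−ρ)·e₂ with c, e₁, e₂ independent
unit-variance AR(1) processes (default lag-1 coefficient 0.3), so the
population correlation of the pair is exactly ρ — background gray
matter defaults to ρ = 0.2, planted spherical regions carry
group-specific ρ.  Optional spatial smoothing of the noise field is
applied within each hemisphere separately with variance renormalization
so it cannot leak homotopic correlation across the midline; its default
is 0 mm, keeping the planted ρ the sole source of mirror coupling (the
analysis pipeline applies its own 4 mm smoothing regardless).  No
scanner drift or physiological noise is simulated.

Motion traces are bounded random walks (six axes) rescaled so
non-outlier excursions stay strictly below both exclusion thresholds;
planted outliers exceed 2.5 mm or 2.5° on one axis.  Clinical scores
are drawn as mean + sd·(r·ž + √(1−r²)·ε) with ž the standardized
realized regional zVMHC, giving a known population score–connectivity
correlation.  All randomness flows from one master seed through named
substreams; identical seeds give bit-identical cohorts.

What the generator does *not* emulate — registration error, anatomical
asymmetry, nonstationary and non-Gaussian noise, physiological
confounds — bounds what passing tests show: they validate the
statistical machinery under the stated model, not robustness to real
acquisition artifacts.

## Validation experiment sizes

The calibration/recovery experiments (`vmhcpipe.validation`, also run
by `scripts/acceptance.py`) use desk-scale problem sizes chosen by the
package: correlation recovery on 12×10×10 grids (600 mirror pairs,
230 frames, 50 subjects per ρ); FWER calibration with 500 stationary
null smooth fields on the default grid and mask at 4 and 8 mm FWHM;
permutation agreement with 2000 permutations on 20×20×16 fields
(15 + 15 subjects, 8 mm smoothness); end-to-end classification on
18×18×14 grids at the full 54-subject/230-frame size over 20 cohort
seeds, with planted region centers spaced ≥ 15 mm so distinct effects
produce distinct 26-connected clusters.

## Numerical choices

- Fisher z clips |r| at 1 − 1e−7; zero-variance mirror pairs are
  marked invalid (map value 0) instead of propagating NaN.
- Least squares via QR throughout; residuals orthogonal to regressors
  to ~1e−12 relative.
- 26-connectivity for all cluster labeling.
- Peak ties break to the smallest linear index.
- Sphere membership by voxel-center Euclidean distance, no
  partial-volume weighting.
- Degenerate inputs (single-volume series, empty spheres, rank-deficient
  designs, groups with < 2 subjects, odd mirror axes) raise informative
  errors rather than returning silent defaults.
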