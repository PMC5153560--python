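# Methods

## Image model and conventions

Volumes are 3D NIfTI-1 images; voxel indices are 0-based and the file's
affine maps them to world millimetres. Emission data are interpolated
trilinearly when resampled under a rigid transform (out-of-field voxels
set to 0); region masks are never interpolated and must already sit on
the analysis grid — the pipeline mirrors a workflow in which ROIs are
segmented in subject-native anatomical space and the SPECT volume is
brought to them. Rigid transform estimation, attenuation correction and
reconstruction are out of scope; only transform *application* is
provided.

Gaussian smoothing is parameterized by FWHM in mm
(σ = FWHM / (2√(2 ln 2)), converted per axis to voxel units via the
spacing) and uses a reflective zero-flux boundary, which preserves
constant volumes exactly and conserves total intensity — both
properties are asserted in the test suite. Smoothing is linear to
machine precision.

## Texture quantification

Per-ROI min–max quantization to Q = 32 levels:
level(x) = min(Q, ⌊(v(x) − vmin)/(vmax − vmin)·Q⌋ + 1), with vmin/vmax
the in-mask extremes; a constant ROI maps to level 1 everywhere. This
makes every downstream feature invariant under positive affine
intensity transforms, so global scanner scaling cannot masquerade as
texture. A fixed-range alternative is available via `value_range`.

The co-occurrence matrix uses the 13 unique distance-1 offsets of the
26-neighbourhood (one per central-symmetry pair). For each direction,
ordered pairs with both endpoints in-mask are counted and the count
matrix symmetrized by adding its transpose; the 13 matrices are then
averaged and normalized once (averaging raw counts before normalizing,
rather than averaging per-direction probabilities — the two differ for
ROIs whose pair counts vary by direction). Distance and Q are recorded
alongside every output because inverse variance in particular is
sensitive to them; both are config switches.

Feature variants that differ across the radiomics literature are fixed
as defaults with config switches: homogeneity uses the inverse
difference form 1/(1+|i−j|) (squared-difference form available);
cluster tendency uses exponent 4 (the prominence convention); variance
centres on μₓ; entropy is in bits (the log base is a monotone rescaling
and cannot change a Pearson correlation's magnitude). Degenerate
policies: σₓ = 0 ⇒ correlation 0; Pₑ = 1 ⇒ agreement 1 if P₀ = 1 else
0; a ROI with no valid voxel pair (e.g. a single voxel) produces NaN
features flagged `degenerate` rather than an exception, so one
pathological subject cannot abort a cohort run.

## Conventional quantification

Mean ROI uptake is the arithmetic in-mask mean; normalization is the
plain ratio to the occipital mean (a distribution-volume-ratio-like
quantity; ratio−1 is deliberately not applied). The more affected side
is the one with the *lower* normalized putamen mean (ties to left); the
caudate inherits the putamen's side label. The laterality index
|R−L|/((R+L)/2) is identical for raw and normalized means because the
reference cancels.

## Statistics

Pearson r uses pairwise-complete cases with the two-sided p from the t
distribution on n−2 degrees of freedom; constant input is an error, not
a NaN. The Benjamini–Hochberg step-up procedure is applied per clinical
measure across the m = 14 metric family (conventional + 13 texture):
order p ascending, find the largest k with P(k) ≤ (k/m)·α, declare the
k smallest — including any intermediate P(j) above its own threshold.
Scoping the family per measure (rather than pooling all four measures)
was an open design choice; it is logged in the report output.

Stepwise selection alternates a forward step (add the candidate with
the smallest partial p below 0.10; ties broken by p then name) and a
backward step (drop the retained predictor with the largest partial p
above 0.05), all fits OLS with intercept. Because the entry threshold
exceeds the removal threshold, a candidate with 0.05 < p < 0.10 would
be entered and removed forever; the loop therefore terminates when a
forward-added variable is immediately removed (a net no-op) or when a
selection state repeats, with a hard cap of 50 iterations. Age is
always among the candidates. Collinear or constant candidates raise an
error naming the offending pair. Note that with these thresholds any
noise candidate whose final partial p lands below 0.05 is retained;
with 8 independent noise candidates the probability that none survives
is 0.95⁸ ≈ 0.66, so exact support recovery in the package's
stepwise-recovery simulation plateaus near two-thirds of runs — a
property of the 0.10/0.05 procedure itself, not of the implementation
(the true predictors are recovered in every run).

## The phantom generator

The generator replaces an access-controlled patient cohort, so its goal
is statistical structure, not anatomy: mirrored ellipsoids for caudate
(≈1.4 cm³ each) and putamen (≈4 cm³), an occipital slab, uniform
nonspecific background, on a 64×64×48 grid at 2 mm isotropic spacing.
One deterministic mask set serves all subjects.

A latent severity s ∈ [0, 1] (0 for controls, Uniform(0.1, 1) for PD)
drives everything:

* **Putamen mean loss.** Voxel value base·side·(1 − s_p·g(x)) with
  s_p = min(1, 1.5 s), g the rostrocaudal ramp (slope 0.04/mm from the
  rostral pole, clipped at 1), and side = 1 − 0.3·s on the more
  affected side (fixed left by default; randomizable). Putamen
  severity response exceeds the caudate's, matching the earlier and
  deeper putaminal degeneration.
* **Caudate.** The ramp is mean-centred and only a weak explicit mean
  response (2% at s = 1) remains, so caudate mean uptake is nearly
  severity-flat while its heterogeneity carries severity — the regime
  in which texture adds information beyond mean uptake, which is the
  phenomenon the statistics must detect.
* **Between-subject variability.** Striatal binding varies with CV
  0.15 (biological), and a whole-volume factor with CV 0.10 emulates
  scanner sensitivity; the latter cancels under reference
  normalization. Without such variability every mean-uptake
  correlation saturates at |r| ≈ 1 and the contrast between the
  HC+PD and PD-only analyses cannot exist.
* **Noise and resolution.** Additive Gaussian technical noise
  (SD 6 on a striatal base of 90) precedes a 6 mm FWHM isotropic
  Gaussian filter, the resolution regime of post-reconstruction
  smoothed SPECT.
* **Severity-scaled heterogeneity.** Applied inside each striatal mask
  *after* the filter, in two parts: (i) a nested lesion territory —
  threshold of a smooth 8 mm random field — covering fraction
  0.35·s² of the volume, within which uptake is remapped toward the
  region's intensity floor with fine structure; (ii) a fine-scale
  (1.5 mm) multiplicative jitter with amplitude
  s·min(v − vmin, vmax − v), which tapers to zero at both ends of the
  region's intensity envelope. Both components are re-centred so the
  region mean is bit-for-bit untouched by the texture machinery, and
  the envelope taper pins the in-mask range.

The post-filter application and the convex (s²) onset deserve
explanation, because they were forced by the measurement model rather
than chosen freely. Under per-ROI min–max quantization, the smoothing
rim of a small ROI already traverses the full quantization range at the
kernel-limited maximum slope, so any *pre*-filter severity structure —
necessarily kernel-smooth, and range-stretching through its amplitude —
dilutes the existing pair differences and *lowers* quantized contrast
and dissimilarity as severity grows; additive amplitude of any
distributional shape behaves this way. Only structure that survives at
sub-kernel spatial scales with a pinned range can raise roughness per
range, which is what real patchy denervation contributes and what the
post-filter, envelope-tapered construction represents. Entropy's
response to any perturbation is strongly concave, so a linear onset
would exhaust it below the PD severity floor; the quadratic onset
spreads the response across the severity range. With the default
calibration the more-affected caudate shows, across seeds, r ≈ +0.4
(entropy), +0.78 (contrast), +0.75 (dissimilarity) and −0.3
(homogeneity) against UPDRS within PD, with the caudate mean null —
the qualitative pattern the package's acceptance checks assert.

Clinical scores are noisy linear functions of severity: UPDRS-III =
5 + 45 s + N(0, 6) (clipped ≥ 0), disease duration from diagnosis =
60 s + N(0, 8) months (clipped ≥ 0), duration from symptoms adds
|N(12, 6)| months, MoCA = 28 − 6 s + N(0, 1.5) clipped to [0, 30], age
~ N(61, 9) independent of severity; controls get severity 0, UPDRS
|N(1, 1)| and MoCA 28 + N(0, 1). These coefficients are invented
calibration so that severity explains most score variance at n = 85 —
the generator exists for parameter-recovery testing, not epidemiology.
Disease-duration scales in particular are synthetic.

### What the phantom does *not* emulate

Projection-domain physics (Poisson counting, scatter, attenuation,
reconstruction artifacts), anatomical variability and partial-volume
geometry beyond ellipsoids, registration error, clinical-score floor
and ceiling effects, comorbidity, and any longitudinal structure.
Passing tests therefore demonstrate that the pipeline measures what the
generative model encodes at realistic noise and resolution — not that
identical effect sizes would be observed in patient data.

## Problem sizes and numerical tolerances

The test suite simulates the full 141-subject study once (about half a
minute) and reuses it across the end-to-end checks; unit tests use a
48×48×32 grid with 10 subjects. Brute-force oracles (literal pair
enumeration for the GLCM, double-loop summation for the features)
agree with the vectorized implementations to 1e-10; probability-matrix
normalization is checked to 1e-9 and symmetry to 1e-12; smoothing
linearity and constant preservation to 1e-9; affine-invariance of
texture to 1e-12. The permutation-null and stepwise-recovery checks use
100 seeded replicates. The acceptance script runs the same study end to
end in roughly 30 seconds.

## Known limitations

* The caudate-mean "null" is a statistical property: even with a zero
  systematic response, ~5% of seeds show p < 0.05 by chance.
* Exact stepwise support recovery is bounded near 66% by the
  0.10/0.05 thresholds (see above).
* The noise-free caudate contrast shows a ~1% ripple at very low
  severity before its strong monotone rise; monotonicity is asserted
  as a trend, not per-step.
* Texture features on ROIs this small (≈180 voxels) are dominated by
  the smoothing rim at low severity; absolute feature values are not
  comparable across masks of different size or smoothing kernels, and
  inverse variance is additionally sensitive to Q and distance.
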