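# striatex

Texture and uptake quantification for dopamine-transporter (DAT) SPECT
of the striatum, with a synthetic phantom cohort generator for
end-to-end validation.

## The problem

DAT SPECT with ¹²³I-ioflupane images the density of dopaminergic
terminals in the caudate and putamen, which degenerate in Parkinson's
disease (PD). Routine quantification reduces each region of interest
(ROI) to its mean uptake, normalized to a nonspecific reference region
(occipital cortex):

    DVR-like ratio = mean(ROI) / mean(occipital)

Mean uptake separates patients from controls but tracks symptom
severity poorly within PD, because degeneration is spatially uneven —
rostrocaudal gradients and patchy terminal loss change the *texture* of
uptake before they change its mean. `striatex` measures that texture
with masked 3D gray-level co-occurrence (Haralick) statistics and runs
the full association battery against clinical scores.

## What it computes

**Co-occurrence matrix.** In-mask voxel intensities are min–max
quantized to Q = 32 gray levels. Ordered level pairs (both endpoints
in-mask, offset distance 1) are counted along the 13 unique directions
of the 26-neighbourhood, each count matrix symmetrized with its
transpose, the 13 matrices averaged and normalized to a joint
probability matrix p(i, j).

**13 Haralick features.** With marginals pₓ(i) = Σⱼ p(i,j), μₓ = Σ i·pₓ(i),
σₓ² = Σ (i−μₓ)²·pₓ(i):

| feature | definition |
|---|---|
| energy | Σ p² |
| entropy | −Σ p log₂ p |
| correlation | (Σ ij·p − μₓμᵧ)/(σₓσᵧ) |
| contrast | Σ (i−j)²·p |
| variance | Σ (i−μₓ)²·p |
| sum mean | ½ Σ (i+j)·p |
| agreement (Cohen's κ) | (P₀−Pₑ)/(1−Pₑ), P₀ = Σ p(i,i), Pₑ = Σ pₓpᵧ |
| cluster shade | Σ (i+j−μₓ−μᵧ)³·p |
| cluster tendency | Σ (i+j−μₓ−μᵧ)⁴·p |
| homogeneity | Σ p/(1+\|i−j\|) |
| max probability | max p |
| inverse variance | Σ_{i≠j} p/(i−j)² |
| dissimilarity | Σ \|i−j\|·p |

**Conventional metrics.** Reference-normalized mean uptake per ROI, the
laterality index |R−L|/((R+L)/2), and the imaging-based more/less
affected side split (lower normalized putamen mean = more affected).

**Statistics.** Pearson correlation of each of the 14 metrics
(conventional + 13 texture) against UPDRS-III, disease duration from
diagnosis and from symptom onset, and MoCA; Benjamini–Hochberg step-up
FDR at α = 0.05 across the 14-metric family per measure; stepwise
multivariate linear regression (entry p < 0.10, removal p > 0.05) with
age always among the candidates.

**Phantom generator.** Real DAT SPECT cohorts are access-controlled, so
the package ships a generator of 141-subject synthetic studies (85 PD,
56 HC): ellipsoidal striatal masks, an occipital reference slab,
severity-driven putamen loss with left/right asymmetry, a caudate whose
mean is nearly severity-flat while its within-ROI heterogeneity grows
with severity, additive technical noise, 6 mm FWHM Gaussian smoothing,
and clinical scores linked to the latent severity. See
`docs/methods.md` for the full model and its limitations.

## Worked example

`examples/association_analysis.py` simulates the full synthetic study
and contrasts conventional and texture analysis (about half a minute):

```
putamen (more affected), PD+HC, conventional uptake vs UPDRS-III:
  r = -0.828, p = 1e-36

caudate (more affected), PD only, vs UPDRS-III:
  mean_normalized  r = +0.029  p = 0.79
  entropy          r = +0.388  p = 0.00024 *
  contrast         r = +0.779  p = 1.7e-18 *
  dissimilarity    r = +0.752  p = 1.1e-16 *
  homogeneity      r = -0.229  p = 0.035 *
  (* = significant after Benjamini-Hochberg FDR at alpha = 0.05)
```

Putamen mean uptake correlates with motor severity only because the
healthy controls anchor one end of the range; within PD the caudate
mean carries no signal (p = 0.79) while its texture does, with the
expected directions — heterogeneity metrics (entropy, contrast,
dissimilarity) rise with severity and homogeneity falls.

Other examples: `simulate_phantom_cohort.py` (what a phantom cohort
contains), `texture_features.py` (all 13 features, healthy vs severe),
`full_pipeline.py` (orchestrated run with reports, provenance and a
scatter plot).

A thin CLI wraps the same pipeline:

```
striatex simulate --seed 1 --out cohort/
striatex features --manifest cohort/manifest.yaml --out-csv features.csv
striatex analyze  --features-csv features.csv --clinical-csv cohort/clinical.csv --out-csv report.csv
striatex run-all  --seed 1 --out run/
```

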