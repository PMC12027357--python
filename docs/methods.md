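# Methods

## The problem

During post-harvest storage, an apple's soluble solids content (SSC,
°Brix) and flesh firmness (N) drift with time and temperature: under
refrigeration quality peaks a few weeks in and then declines, while at
room temperature unchecked respiration drives moisture loss and softening
from the start. Both traits leave signatures in 350–1150 nm
diffuse-transmission spectra — water O–H overtones near 720 and 970 nm,
sugar-linked C–H overtones near 840 and 910 nm, skin pigments at
630–675 nm, and bulk scattering that grows with cell-wall content. The
package implements the calibration chain that turns such spectra into
trait predictions and storage-week classifications, together with a
synthetic-data generator standing in for instrument data that is not
publicly available.

## Synthetic data generator

`StudyDesign` fixes the sampling layout: 4 varieties × storage at
{1, 10, 25} °C × 7 weekly batches, 384 samples per variety divided evenly
over that variety's available (temperature, week) cells (remainder to the
earliest weeks), 1044 evenly spaced wavelengths over 350–1150 nm. One
variety (Huangyuanshuai, soft-fleshed) rots early at room temperature and
has no 25 °C group, leaving 11 variety–temperature groups.

`QualityTrendParams` holds per-group trait distributions. Reference values
are drawn as *group mean + mean-centered week profile + N(0, group SD)*;
the week profile is a quadratic peaking at `peak_week` (default 4,
configurable within weeks 3–5) under refrigeration, and is inverted for
SSC — with a monotone linear decline for firmness — at ≥ 20 °C. A
quadratic is the simplest shape with an interior extremum, which is all
the trend data constrain. Values are floored at 10 % of the group mean.

`SpectralForwardModel` renders one spectrum per reference row:

1. **Latents.** The spectral SSC/firmness latents are the reference values
   plus N(0, 0.15 °Brix) / N(0, 0.3 N) — the refractometer or texture
   probe measures a localized sample of what the whole-fruit spectrum
   sees, so spectra and references decouple slightly. A moisture latent
   declines with week at 0.002 · T(°C) per week (faster when warm) with
   per-fruit noise.
2. **Bands.** Gaussian bands on a linear baseline: water 720/35 nm and
   970/45 nm (amplitudes 0.45/0.35 AU, moisture sensitivity +0.12 per
   z-unit; the 970 nm band also carries a +0.12/z firmness term for
   cell-wall absorption), sugar 840/28 and 910/30 nm (0.22/0.26 AU,
   +0.4 per z-unit of SSC), pigment 650/22 nm (0.30 AU, varying with
   variety, declining slowly with week, with 5 % per-fruit color noise).
3. **Scatter.** Per-sample log-normal multiplicative slope
   (`exp(0.2·z_firmness·… + N(0, 0.2))` — firmer flesh scatters more) and
   additive offset N(0, 0.08). This is the dominant nuisance and the
   reason scatter-corrective preprocessing pays off.
4. **Instrument terms.** A per-sample random quadratic baseline drift
   (SD 0.01 AU) and white noise of 0.005 AU inflated 50-fold within
   ~110 nm of the grid edges, where detector sensitivity collapses: the
   350–450 and 1050–1150 nm regions are effectively dead channels, which
   is what gives wavelength selection something real to remove. Optional
   per-batch session effects (smooth spectral deviation,
   wavelength-calibration shift) exist but default to zero.

All randomness flows from one integer seed through `SeedSequence`
children (references, then spectra), so `generate_dataset` is
bit-reproducible.

**What the generator does not emulate.** Absorbance is linear in the
latents (no Beer–Lambert saturation); noise is Gaussian; and — most
importantly — the weekly spectral fingerprint is weak: storage week moves
the spectra only through the slow moisture/pigment drifts and the trait
trends. Configurations with strong week-ordered markers were explored and
rejected because they corrupt the SSC calibration benchmarks the
generator must satisfy. Consequently PLS-DA storage-week discrimination
on default synthetic data is far worse (≈ 50–90 % misclassification)
than instrument studies achieve on real fruit, where respiration leaves
much richer signatures; the discriminant machinery is validated instead
on strongly-marked configurations where weeks are separable. Passing
tests therefore demonstrate correctness of the algorithms, not
expected performance on real spectra.

## Preprocessing

All three transforms are row-wise: SNV (center, scale to unit SD, n−1
denominator), MSC (OLS-regress each spectrum on a reference, invert the
fitted affine scatter; the reference is the *calibration-set* mean, stored
and reused for prediction spectra so no information leaks), and
normalization, read as per-spectrum min–max scaling to [0, 1] (unit-norm
scaling is available as `vector_norm`). Constant rows are errors naming
the offending sample. Kennard–Stone distances are computed on raw
absorbance by default; preprocessing before splitting is available but
not the default, since the stage order is otherwise ambiguous.

## Partitioning

Kennard–Stone is the deterministic greedy maximin rule: seed with the two
mutually farthest spectra (Euclidean), then repeatedly add the sample
farthest from the selected set. Ties break to the lowest index, making
splits platform-independent; a seeded uniform split is available behind a
flag. The calibration size for a ratio r:1 is round-half-up of
n·r/(r+1) — 288/96 at n = 384, r = 3. k-fold CV assignment deals a seeded
permutation round-robin, so fold sizes differ by at most one.

## Wavelength selection

**UVE** appends `n_noise` uniform noise columns (default: as many as real
variables; amplitude 1e−10 of the mean absolute absorbance — too small to
influence the fit, large enough to receive nonzero coefficients), fits
one PLS submodel per leave-one-out deletion (Monte-Carlo subsampling
available for large n), and scores each variable's stability
mean(b)/SD(b) across submodels. Variables whose |stability| does not
exceed `cutoff_factor` × the largest noise-variable |stability| are
eliminated. A zero coefficient SD is flagged (signed infinity, or 0 for
identically-zero coefficients) rather than dropped.

**CARS** runs `n_runs` iterations (default 100). Iteration i records the
10-fold RMSECV of the currently retained subset — with the LV count
re-selected up to `max_lv` by the inner CV minimum — then fits PLS on a
random 80 % Monte-Carlo sample, ranks the retained wavelengths by
|coefficient|, keeps the top r(i+1)·p of them (exponentially decreasing
forced retention with r₁ = 1 and r_N = 2/p), and redraws the set by
weighted sampling with replacement followed by de-duplication (the draw
count is the EDF count, so de-duplication stays mild). The subset with
the minimum recorded RMSECV wins; ties go to the earliest iteration, and
a collapse below 2 variables stops the loop with a truncated trace.
RMSECV inside CARS is averaged over three independent fold assignments
(repeated k-fold): the minimum over ~100 iterations is an extreme
statistic, and a single fold assignment is noisy enough to favor
spuriously small subsets.

## PLS, latent variables, PLS-DA

PLS1 is fitted by NIPALS with mean-centering of X and y and X-deflation
per component; X is not variance-scaled (all channels share absorbance
units) and y is centered but not scaled. For a univariate response each
component is a closed-form step, and regression coefficients compose as
b = W (PᵀW)⁻¹ q, so prediction is the affine map ŷ = ȳ + (x − x̄)·b. A
component whose weight norm falls below 1e−12 stops the fit early with a
warning. Cross-validated LV selection evaluates every truncation of one
`max_lv`-component fit per fold (cheap, exactly equivalent to refitting),
searches 1–20 by default, caps at min(n_train − 1, p) with a log message,
and breaks ties toward fewer components.

PLS-DA encodes storage week 1–7 as a single ordinal response fitted with
the identical machinery (the midpoint decision boundary implies
regression-then-round); continuous predictions round to the nearest class
with half-points up and clamp to the class range. One-hot with argmax was
considered and rejected as inconsistent with a midpoint boundary. The
pipeline's discriminant grid models SNV-corrected spectra, since scatter
carries no week information. Misclassification rates are exact mismatch
fractions, reported to 3 decimals.

Rc/Rp are Pearson correlations between predicted and measured values
(not R²), RMSEC/RMSEP are root-mean-square errors in trait units.

An optional Shapiro–Wilk screen (`outlier_filter`, off by default)
iteratively removes the most studentized-extreme reference value while
normality is rejected at α = 0.05, capped at 5 % of samples — a
conservative reading of an anomaly-filtering step whose procedure is not
otherwise specified.

## Pipeline grids

Regression models are fitted per (trait, temperature) with varieties
pooled; week discrimination per (variety, temperature) group, matching
how comparison tables in this field are laid out. Each cell: one
Kennard–Stone 3:1 split, preprocessing fitted on calibration only,
optional selection on the preprocessed calibration block, CV-selected LV
count, evaluation on the held-out prediction set. Cell failures are
recorded in the report's `error` column without aborting the grid; a
(config, seed) pair determines every output byte (per-cell seeds derive
from CRC32 of the cell key, so grid order is irrelevant).

## Numerical choices and problem sizes

Tolerances: SNV/MSC oracles at 1e−10/1e−12; PLS≡OLS at full rank at
1e−6; score orthogonality at 1e−8 (relative). The test suite runs the
end-to-end recovery on one variety (384 samples × 1044 wavelengths, the
study-sized problem) and the planted-signal experiments on 60-sample
problems over 20 seeds each; the whole suite completes in well under a
minute on one CPU, and `scripts/acceptance.py` in a few seconds.

## Known limitations

- The weekly spectral fingerprint is deliberately weak (see above):
  default-data PLS-DA rates do not represent real-fruit performance.
- Min–max normalization uses the row extremes and therefore inherits
  edge-channel noise; SNV/MSC are the more robust corrections on this
  generator, and the three methods perform similarly after selection.
- The greedy Kennard–Stone split concentrates extreme (high-scatter)
  samples in the calibration set; prediction-set errors on synthetic data
  are accordingly slightly optimistic relative to a random split.
- CARS inherits the known instability of coefficient-magnitude
  resampling: on data whose full spectrum is already near-optimal, its
  minimum-RMSECV subset can be marginally worse than the full spectrum
  for unlucky seeds (observed ~1 in 10 at default settings).
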