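# Methods

## Scope and model

The package operates downstream of peak integration: its inputs are a
feature table (retention time, observed m/z, optional cation
composition, peak area per run) and an injection schedule (run id,
clock time in minutes from batch start, class ∈ {QC, control,
treated}). Raw-file processing (XIC construction, integration) is out
of scope.

Three fitted components follow each other:

1. **Derivatization chemistry.** Every annotated feature is modelled as
   the protonated hydrazone cation RCC + CHH − H2O + H. Monoisotopic
   masses use CODATA/IUPAC atomic masses over {C,H,N,O,P,S} with one
   electron mass subtracted per positive charge; compositions of
   [M+H]+ ions are written with the ionizing proton included in the H
   count, the convention that reproduces the reference cation m/z
   values to four decimals. ppm error is (calculated − observed) /
   calculated × 10⁶, the sign convention consistent with the reference
   table's error column. Composition search enumerates all formulas
   within the ppm window that dominate the scaffold C14H16N3O2⁺ (so
   ≥C15, ≥H16, N ≥ 3, O ≥ 3), with default per-element caps
   C≤45, H≤90, N≤5, O≤10, P≤1, S≤1 — the smallest box containing every
   derivative in the built-in reference set. MS/MS annotation matches
   the diagnostic ions 244.1/262.1 and a fixed neutral-loss table
   (H2O 18.011, NH2 16.019, N2H4 32.037, CO2 43.990, CH2O2 46.005 Da)
   at a 0.3 Da tolerance, appropriate for ion-trap CID spectra printed
   to one decimal. Either diagnostic ion suffices: base-peak 244.1 is
   often omitted from printed lists precisely because it saturates.

2. **Stability model.** Per feature, the QC trajectory is min-max
   scaled to [−2, 2] (constant series map to 0). Scaled trajectories
   are clustered with k-means (k = 5 by default, mirroring the five
   clusters seen in the pea-nodule batch; k = 4 when steady clusters
   are merged) under one of three metrics: Euclidean, DTW (classic
   dynamic program, squared local cost, square root of the accumulated
   optimal-path cost, optional Sakoe–Chiba band) or DBA (DTW-aligned
   barycenter centroid updates). Default metric: DBA. Seeded restarts
   (n_init = 10) keep the lowest within-cluster sum of squared
   distances; results are deterministic for a fixed seed.

   The centroid of each cluster is classified into a model family:
   linear, continuous two-segment (hinge) with the breakpoint searched
   over interior QC times, or steady. The hinge wins over the line if
   it improves the BIC (k = 4 vs 2 parameters) *and* its late slope is
   ≥ 2× the early slope in magnitude. On raw (positive) series a
   fitted-value RSD < 10 % marks the series steady — the same 10 %
   criterion used throughout as the stability threshold. On scaled
   centroids the RSD is undefined (mean ≈ 0), so a cluster is steady
   when its centroid's fitted excursion stays below 1.0 scaled unit
   (a quarter of the full range): coherent drifting clusters span most
   of [−2, 2], whereas averaging incoherent stable members contracts
   the centroid toward zero.

   The cluster decides the family only; parameters are re-fitted per
   analyte on its own raw QC areas, which reconciles cluster-level
   regression with per-analyte correction coefficients. A drifting
   cluster member whose own fitted RSD is < 10 % is demoted to steady
   (no correction) rather than stretched to the cluster shape.
   Correction factors are f(t_ref)/f(t_run) with t_ref = the first QC
   injection (the earliest state is closest to the underivatized
   truth for a degrading derivative), clamped to [0.2, 5] with a
   logged warning; a fitted curve that is non-positive at some run
   leaves that run uncorrected (factor 1) and flags the feature.
   Steady features always get factors of 1. Features with incomplete
   QC series are flagged uncorrectable.

3. **Differential abundance.** Pooled-variance two-sided t-tests on
   corrected intensities (untransformed by default; log2 behind a
   flag), fold change = max(ratio, 1/ratio) with direction, raw
   p ≤ α = 0.05 as the significance gate. No multiple-testing
   correction by default — the reference analysis reports raw t-test
   results — with Benjamini–Hochberg available behind a flag (and the
   caveat that raw-p gates inflate family-wise error). A Shapiro–Wilk
   p-value per feature and density plots are emitted for information
   only; nothing is excluded on normality grounds. Ward linkage on
   per-feature z-scores orders significant features for heatmaps.

## Synthetic batches

The generator emulates a single ~24 h derivatization batch: run slots
every 21.25 min, a QC pool every 12 runs (255-min increments) plus a
closing QC (seven QC points), and biological samples (even
control/treated split, seeded randomization) on randomly chosen
remaining slots; unlisted slots stand for unmonitored acquisitions
such as alternate survey windows. `runs_per_qc ≥ 2` is required — a QC
on every slot would leave no room for samples.

Feature intensities are baseline (log-uniform 10⁵–10⁸ counts) × group
effect × kinetic drift g(t) × noise. Kinetic classes: I, linear
increase, target series RSD ~ U[10, 30] % (a 30 % RSD rising ramp is
already a ~2.2× gain — plausible for solvent evaporation; deeper rises
are not); II, linear decrease, RSD ~ U[10, 55] % (55 % is near the
ceiling a ramp can produce; deeper published RSDs up to 85 % arise
from type III drops); III, loss of 2–10 % by the 1000-min breakpoint
then a linear drop to a final fraction U[0.05, 0.5]; steady, no trend.
Ramp RSD targets are converted to total change by inverting
RSD = (d/√12)/(1 ∓ d/2). Drift is shared between QCs and samples, so
planted fold changes are biased without correction and recoverable
with it. QC intensities use the pooled baseline (mean of both group
baselines).

Noise is multiplicative lognormal with total CV 5 % by default, split
3-4-5 into a **shared per-injection effect** (CV = 0.8 × total) and
independent measurement noise (CV = 0.6 × total). The shared
component is deliberate: with purely independent noise, min-max
scaling turns every steady trajectory into full-range noise and stable
analytes cannot form a coherent cluster — yet in real batches they do,
because all features in one injection share source/volume variation.
The shared effect is exactly the structure that makes steady clusters
recoverable. What the generator does *not* emulate: chromatographic
peak shapes, retention-time drift, missing-value mechanisms (optional
uniform missingness only), ionization suppression that differs between
features, or between-batch effects. Passing tests therefore show the
correction recovers planted within-batch structure, not that it
handles matrix effects or multi-batch studies.

## The corrected-vs-uncorrected demonstration

The qualitative value of the correction is shown on a demonstration
batch in which the randomization happens to be time-imbalanced: seven
controls in the first half of the batch, seven treated samples in the
second. Three up-regulated derivatives (folds 2.1 / 2.7 / 1.7, the
magnitudes of the reference study's three up-regulated analytes) decay
linearly by 75 % across the batch. Degradation then *biases* the
uncorrected treated/control ratios toward or below 1 — at most the
strongest fold survives as significantly up — while the corrected
analysis recovers all three. This is the canonical failure mode
QC-based correction exists to fix; a fully randomized placement shows
the same effect only as a variance inflation whose outcome varies from
batch to batch.

## Numerical choices and edge cases

* Constant series min-max scale to 0 (no direction is defensible).
* RSD of a zero-mean series is reported as NaN, never raised.
* DTW on equal-length QC grids: warping only absorbs small shape
  shifts; distances equal the brute-force path minimum (tested
  exhaustively for lengths ≤ 6).
* DBA iterates until the centroid is stable or 10 iterations; its
  objective is non-increasing per iteration.
* Empty k-means clusters are re-seeded with the worst-fit series.
* Breakpoints are restricted to interior QC times, keeping the hinge
  continuous and identifiable with seven QC points.
* The factor clamp [0.2, 5] bounds the variance a correction can
  inject; decays deeper than 80 % saturate it and are logged.
* The built-in reference table preserves published observed and
  calculated m/z verbatim; for a few entries the published calculated
  value is not reproducible from its composition (up to 1.4 mDa off),
  while the published ppm errors are consistent with the published
  calculated values. `monoisotopic_mass` always reports the
  recomputed value; the reference ppm errors are reproduced from the
  table's own (observed, calculated) pairs.
* Polycarbonyls are treated as mono-derivatized (the reference
  dioxovaleric-acid composition implies a single hydrazone).

## Problem sizes

Default analyses run at the reference scale: 194 features × (14
biological runs + 7 QCs). Validation experiments use 10 seeded batches
for cluster recovery, a single seeded batch for correction efficacy and
the detection contrast, and a 1000-feature null batch for the type-I
error check — sizes at which the full pipeline completes in seconds to
a couple of minutes on one core.

## Known limitations

* Isotope-pattern scoring, in-source-fragment deconvolution and
  isomer/structure elucidation are out of scope; formaldehyde-like
  signals at several retention times are reported as distinct features.
* The correction assumes a single batch; between-batch normalization
  (LOESS/spline QC methods) is not implemented.
* Whether the reference analysis regressed scaled or raw intensities
  is not documented; raw intensities are used here because factors
  must act on raw counts.
* With seven QC points the hinge breakpoint is resolved only to the
  QC spacing (±255 min).
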