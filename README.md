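# carbonylome

Profiling of reactive carbonyl compounds (RCCs) from LC-MS feature
tables of 7-(diethylamino)coumarin-3-carbohydrazide (CHH) derivatives:
annotation by exact mass and diagnostic MS/MS fragments, a
quality-control-based correction for derivative degradation and signal
drift, and control-vs-treated differential abundance. It is aimed at
plant-stress and redox metabolomics groups who quantify carbonyls
(aldehydes, ketones, oxo-acids from lipid peroxidation and sugar
autoxidation) by hydrazide derivatization and need the degradation of
those derivatives over a measurement batch removed before any group
comparison.

## The method

**Annotation.** CHH (C14H17N3O3) traps a carbonyl R1R2C=O as a
hydrazone, losing one water; positive-mode electrospray observes the
protonated cation

    [M + H]+ = RCC + C14H17N3O3 − H2O + H,    m/z = Σ mᵢ − mₑ

computed from monoisotopic atomic masses with the electron mass mₑ
subtracted. Mass errors use ppm = (calc − obs)/calc × 10⁶ with a 3-ppm
annotation gate, and candidate compositions are enumerated only over
formulas containing the coumarin scaffold (≥C15 H16 N3 O3). CID spectra
of all CHH derivatives share diagnostic fragments at m/z 244.1 and
262.1 (loss of the RCC plus N2H4 or NH2), which mark a feature as a
derivative independent of the attached carbonyl.

**Stability correction.** Pooled QC samples injected every 12 runs
(255-min increments) trace each derivative's signal over the batch.
QC series are min-max scaled to [−2, 2] and clustered by k-means under
Euclidean, DTW or DTW-barycenter-averaging metrics; each cluster
centroid is classified as linear increase (type I), linear decrease
(type II), slow decline with a rapid drop after ~1000 min (type III),
or steady. The cluster fixes the model family; parameters are fitted
per analyte on raw QC areas, and every run gets a multiplicative
correction factor f(t_ref)/f(t_run) (clamped to [0.2, 5]) that removes
the degradation/evaporation trend from sample intensities.

**Differential abundance.** Two-sided pooled-variance t-tests
(df = n1+n2−2) on corrected intensities, fold changes reported ≥ 1
with an up/down direction, raw p ≤ α significance (Benjamini–Hochberg
behind a flag), and Ward clustering of significant features for
heatmaps.

A synthetic-batch generator plants the kinetic class structure
(17/95/37/45 features of types I/II/III/steady), group fold changes
and two-component multiplicative noise, so every stage is testable
against known truth.

## Worked example

```python
from carbonylome import (ElementalFormula, derivative_from_rcc,
                         monoisotopic_mass, ppm_error)

glyceraldehyde = ElementalFormula.parse("C3H6O3")
cation = derivative_from_rcc(glyceraldehyde)
print(cation.hill())                       # C17H22N3O5+
print(round(monoisotopic_mass(cation), 4)) # 348.1554
print(round(ppm_error(348.1555, monoisotopic_mass(cation)), 1))  # -0.3
```

The glyceraldehyde hydrazone cation C17H22N3O5+ has a calculated m/z of
348.1554; an observed m/z of 348.1555 is 0.3 ppm high (negative error
under this sign convention), comfortably inside the 3-ppm gate.

Running the full simulated pipeline:

```sh
carbonylome all --seed 5 --workdir out
```

prints, among other things,

```
kinetics types: I: 17, II: 94, III: 38, steady: 45
median QC RSD% before -> after: 32.4 -> 3.9
```

— the planted kinetic classes recovered from the QC series (one planted
type II feature lands in the type III cluster at this seed), and the
median QC relative standard deviation dropping from 32% to 4% once each
analyte's fitted degradation is divided out. `out/` then holds the
feature table, annotation, correction report, corrected intensities and
the differential table, each stamped with the config hash.

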