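# socspec

Prediction of soil organic carbon (SOC, g kg⁻¹) from Vis–NIR reflectance
spectra (400–2500 nm), built for the situation proximal soil sensing keeps
running into: models calibrated on careful laboratory spectra must be used
on field spectra recorded by a different instrument, under varying
moisture, surface and contact conditions. The package provides the whole
chain as a tested library plus CLI:

* **Spectral preparation** — inter-sensor splice correction, range
  trimming, robust multivariate outlier screening of replicate spectra
  (PCA projection + MCD-style robust distances with an adaptively adjusted
  chi-square cutoff), replicate averaging, and nearest-spectra selection
  for georeferenced on-the-go streams.
* **Preprocessing** — the four standard operators: Savitzky–Golay
  derivative (SG), SG smoothing + continuum removal (SGCR), gap-segment
  derivative (gapDer), and multiplicative scatter correction (MSC).
* **PLSR** — a from-scratch NIPALS PLS1 engine exposing weights `w_a`,
  loadings, scores, per-component explained response sums of squares
  `SS_a`, the coefficient path over component counts, and VIP scores

  `VIP_j = sqrt( p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a )`,  with Σ_j VIP_j² = p.

* **Evaluation** — stratified, spatially grouped 5×5-fold nested
  cross-validation (samples closer than 8 m always share a fold; 25 models
  per dataset), with RMSE, R², RPD = SD(obs)/RMSE and Lin's CCC.
* **Calibration transfer** — lab-based correction of field spectra by
  per-wavelength linear transformation (LT), piecewise direct
  standardization (PDS, banded local PLSR maps), and external parameter
  orthogonalization (EPO, projection onto the orthogonal complement of the
  lab−field difference subspace), tuned inside the same nested CV.
* **Wavelength importance** — median regression-coefficient and VIP
  profiles over the CV ensemble, local-peak detection (100 nm span for RC,
  50 nm for VIP), and cross-dataset peak-match tables.
* **Synthetic scenes** — a generator emulating a two-instrument campaign
  (1 nm point spectrometer with splice steps; ~5 nm on-the-go instrument
  with a 1000–1100 nm dead band) over 50 field locations with known SOC,
  moisture and disturbance truth, so every stage is testable end to end.

## Worked example

```python
from socspec import StudyConfig, run_study
from socspec.study import group_median_rmse, correction_improvements

result = run_study(StudyConfig())          # default scene, seed 0
print(group_median_rmse(result.metrics))
```

```
{'highres_lab': 0.629, 'highres_field': 0.931,
 'lowres_lab': 0.772, 'lowres_field': 1.182}
```

These are median held-out RMSEs (g kg⁻¹, over the 25 CV models) of the
best preprocessing variant per device/condition: laboratory spectra beat
field spectra, and the high-resolution instrument beats the on-the-go
instrument, the expected performance ladder. Corrections then narrow the
lab–field gap; `correction_improvements(result.metrics)` reports, e.g.,
`highres_field_gapDer 0.931 → 0.850` for the best of LT/PDS/EPO.

The same run from a shell:

```
socspec run --config config.yaml --out runs/
```

writes `metrics.csv`, `transfer_parameters.csv`,
`correction_improvements.csv`, `peaks.csv` and VIP/RC peak-match tables
into a config-hashed run directory. Stage-wise subcommands (`synth`,
`preprocess`, `cv`, `transfer`, `metrics`) operate on plain CSV files.

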