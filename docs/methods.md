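# Methods

This note documents the models, conventions and design choices behind
`socspec`: what each stage computes, which parameters matter, what the
synthetic scene generator does and does not emulate, and the numerical
decisions a user should know before trusting or extending the results.

## The problem

Soil organic carbon (SOC) leaves broad, overlapping absorption features in
Vis–NIR reflectance. A partial least squares regression (PLSR) calibrated
on laboratory spectra of dried, sieved samples predicts SOC well; the
practical question is how much of that skill survives when spectra come
from the field — a different instrument, moist intact soil, varying
illumination and sensor contact — and how much a lab-based spectral
correction can recover. The package implements the full comparison:
two instruments × lab/field conditions × four preprocessing operators,
evaluated under one shared cross-validation geometry, with three
calibration-transfer methods and a wavelength-importance analysis on top.

## PLSR core

`fit_plsr` implements PLS1 by sequential NIPALS extraction on
mean-centered, unscaled data (variance scaling is deliberately omitted:
reflectance channels share units, and unscaled coefficients are
comparable across wavelengths). Per component: `w = E'f/‖E'f‖`,
`t = Ew`, `p = E't/t't`, `q = f't/t't`, then X-deflation
`E ← E − tp'`. Regression coefficients are `beta = W(P'W)⁻¹q`; the
NIPALS structure makes `beta` available for every component count from
one fit, which the tuning loops exploit.

The per-component explained response sum of squares is defined as
`SS_a = q_a²‖t_a‖²`, the convention under which the VIP normalization
`Σ_j VIP_j² = p` holds exactly; the test suite asserts this identity on
random models and checks equality with ordinary least squares whenever
`A = rank(X)`, plus agreement with an independent reference
implementation at 1e-8.

## Preparation and preprocessing

Fixed order: splice correction → trimming → outlier removal → replicate
averaging → preprocessing operator.

* **Splice correction.** Spectra of the point instrument show additive
  steps at its internal sensor junctions (1000/1800 nm). Segments above
  each junction are shifted so the first point of the following segment
  equals the linear extrapolation from the last two points of the
  preceding one; the shortest-wavelength segment anchors. Recovery of
  injected offsets is exact up to second-order curvature (~1e-5 in
  reflectance on realistic spectra).
* **Trimming.** Models use 400–2200 nm so both instruments are
  comparable; the on-the-go instrument's noisy 1000–1100 nm inter-sensor
  band is dropped as a dead band. Derivative operators never bridge dead
  bands — each contiguous uniform grid segment is processed alone.
* **Outlier screening.** Replicates of one location are projected onto
  principal components keeping ≥99 % variance (capped at n−2); robust
  center/covariance come from a deterministic MCD-style concentration
  (C-steps from a coordinatewise-median start, chi-square consistency
  factor, one reweighting step). A spectrum is dropped when its squared
  robust distance exceeds the chi-square 0.975 quantile *and* the
  empirical tail beyond that cutoff is heavier than the chi-square tail;
  otherwise the cutoff adapts upward and nothing is flagged. Groups
  smaller than three pass through. For the on-the-go stream, records are
  first assigned to their nearest sampling location (≤3 m) and screened
  within those groups — screening the whole stream as one population
  would flag genuine between-location SOC variation.
* **Operators.** SG: 11-point window, polynomial order 2, first
  derivative (the method is used as a spectral derivative; smoothing-only
  is available via `derivative_order=0`). SGCR: SG smoothing then
  division by the upper convex hull (monotone-chain hull, output in
  (0, 1], exactly 1 at hull support points). gapDer: first derivative as
  the difference of 10-point segment means separated by an 11-point gap,
  exact on affine spectra. MSC: OLS of each spectrum on a reference
  (set mean by default, persisted for reuse), corrected to `(x−a)/b`.
  SG/gapDer drop edge points without full support (e.g. 405–2195 and
  415–2185 nm on a 400–2200 nm, 1 nm grid).

## Cross-validation geometry

Samples within 8 m are merged into indivisible groups (single-linkage
connected components), preventing spatially autocorrelated neighbours
from leaking across splits. Stratification: groups are ordered by
group-mean SOC and dealt into 5 folds in consecutive blocks with a seeded
random permutation per block — this keeps fold SOC means within half an
SOC standard deviation of each other while still varying assignments
across the 5 repetitions. The inner loop (5 folds, same grouping) selects
hyperparameters by mean inner RMSE; ties go to the most parsimonious grid
point (fewest components, then smallest window). Fold assignments are a
function of (seed, sample table) only, so all dataset variants of one
scene share byte-identical splits — asserted by hashing fold labels.

## Calibration transfer

All three corrections are fit on paired per-location averages of the
*training fold only* (the leakage-free reading of tuning-inside-CV) and
map field spectra toward the lab domain; the downstream PLSR is trained
on corrected field spectra.

* **LT** — per-wavelength OLS of lab on field; zero-variance channels
  fall back to the lab mean with a warning.
* **PDS** — for each target wavelength a local PLSR maps the field
  window `[i−w, i+w]` (clipped at grid edges, never padded with
  extrapolated reflectance) to the lab value; coefficients assemble into
  a banded matrix. All local fits run as one batched NIPALS; the batched
  path is asserted equal to independent per-window fits.
* **EPO** — `D = lab − field` is column-centered; spectra are projected
  onto the orthogonal complement of its first `c` right singular vectors.
  The projection is applied to lab spectra as well when an EPO-corrected
  model is built (standard EPO usage; the alternative of leaving lab
  spectra unprojected was rejected because train/apply domains must
  match). Column-centering of `D` before the SVD is a convention: the
  mean lab–field offset is an affine effect the PLSR intercept absorbs.

Tuning grids: PDS components 1–10 × window 1–20 and EPO components 1–10
are supported; the default study configuration uses a reduced PDS grid
(ncomp {1,2} × half-width {2,5,10}) and a 1–12 component list for the
downstream PLSR during correction tuning, keeping a full run on one CPU
in minutes. The parameter report lists per-fold selections and their
mode, since a single "the" optimal parameter is not well defined under
resampling.

## Wavelength importance

Regression coefficients (RC) and VIP are evaluated per CV model at its
tuned component count; the analysis uses the per-wavelength median over
the 25 models (median first, peaks second — peaks of the median profile,
not aggregated per-model peaks). Local peaks are strict extrema within a
centered window (span 100 nm for RC maxima+minima, 50 nm for VIP maxima),
windows clipped at segment edges, segment endpoints excluded; ties yield
no peak. Peak matching declares a reference peak matched in a candidate
dataset when some candidate peak lies within a per-dataset tolerance
(10 nm high-resolution, 20 nm low-resolution); totals are column sums and
are monotone in the tolerance. Derivative-preprocessed profiles are
matched on the derivative grid; no back-mapping to absorption centers is
attempted. Match tables are produced for both VIP and RC and labelled.
The reference dataset defaults to the best-performing lab variant.

## Metrics

RMSE; R² as `1 − SSE/SST` about the observed mean (negative values are
possible and meaningful on held-out data); RPD as `SD(obs, n−1)/RMSE`
(the ratio-of-performance-to-deviation reading); Lin's CCC with
n-denominator moments. Metrics are pooled per repetition over the outer
folds — five values per dataset per metric — and summarized by median and
IQR. Pooled-vs-per-fold averaging differs under unequal fold sizes; the
pooled convention is asserted in a constructed test case.

## Synthetic scene generator

The generator emulates the *structure* of a two-instrument lab/field
campaign, not soil physics. Reflectance is a smooth decreasing baseline
minus Gaussian absorption bands whose depths scale with the spectrally
active SOC; everything is synthesized on a 1 nm master grid and
block-averaged to the device grid (so a matched low-resolution dataset is
exactly the block-resampled high-resolution one — a tested invariant).

Default scene (units in parentheses):

* 50 locations, SOC truncated-normal, mean 19.6, range 14–25 (g kg⁻¹);
  the SOC standard deviation (2.5 g kg⁻¹) is a generator choice — only
  mean and range are anchored externally.
* SOC bands at 560, 1330, 1412, 1720, 2008 nm, widths 25–45 nm; gains
  (≈0.002 reflectance per g kg⁻¹) calibrated once so the lab models sit
  in the R² ≈ 0.9 / RPD ≈ 3.4 regime typical of good lab calibrations.
* A per-location *spectrally active SOC* mismatch (sd 0.6 g kg⁻¹)
  represents the gap between measured total SOC and the chromophore pool
  the spectrum responds to; this, not sensor noise, is what bounds lab
  model skill (white replicate noise averages out over 18 replicates and
  would otherwise make models implausibly perfect).
* Device artifact bands: 20 random smooth Gaussian shapes per device
  with per-location coefficients (high-resolution sd 0.002, on-the-go
  sd 0.0045 reflectance) — presentation/optics variability that does not
  average over replicates and separates the two instruments.
* Field disturbance: water absorption at 1400/1900 nm proportional to
  volumetric moisture (15–25 %, 0.005 reflectance per %), a random
  per-spectrum baseline tilt, a per-location field-only structured
  disturbance (12 fresh band shapes, sd 0.012, scaled 1.5× for the
  below-ground on-the-go instrument), extra noise, and a per-location
  field-vs-lab shift of the active SOC (sd 0.65 g kg⁻¹) representing the
  different soil volume actually sensed in situ. The last term is
  deliberately *not* removable by any spectral correction, which is why
  corrected field models approach but do not reach lab performance.
* The on-the-go stream emits ≥10 georeferenced spectra within 2.5 m of
  each location (plus jitter), forcing the nearest-spectra selection
  logic; splice steps (additive per-segment offsets, sd 0.008) are
  injected only for the point instrument, which has splice points.

Randomness: one master seed; per-purpose child streams via
`SeedSequence.spawn` in a fixed order (SOC, coordinates, moisture,
active-SOC mismatch, then lab/field per device). Regeneration is
bit-identical.

What the generator does **not** emulate: nonlinear moisture–reflectance
response, crop residues and stones, sensor temperature drift, spatially
autocorrelated SOC fields, or mineralogy-specific features. Passing tests
therefore demonstrate that the *pipeline* behaves correctly under
realistic low-rank disturbance and noise structure — not that any
particular field dataset will reach these numbers.

## Numerical conventions and degenerate inputs

* PLSR component extraction stops (with a warning) when the residual
  covariance vanishes; requesting more components than `min(n−1, p)`
  truncates. Zero-variance responses are errors.
* The batched PDS NIPALS zeroes components per-wavelength when the local
  residual dies (relative 1e-13), matching the scalar path's early stop.
* EPO component counts are truncated at `rank(D)`; an exactly identical
  lab/field pair yields the identity projection.
* LT treats field variance below 1e-20 (reflectance²) as zero.
* MSC raises when a spectrum's scatter slope is below 1e-12.
* Peak windows use strict inequalities, so plateaus of exactly equal
  values produce no peak.
* Floats are serialized with 9 significant digits; CSV round-trips are
  asserted lossless at that precision.

## Problem sizes

The default study replica — 50 locations, 16 dataset variants, 25 models
each, three corrections on the 8 field variants with the reduced PDS grid
— runs in roughly two to three minutes on one CPU; the test suite adds
unit and property tests and one full replica. Grids and scene size are
configuration, not code: the full paper-scale PDS grid is available by
passing `pds_grid=[(nc, w) for nc in range(1, 11) for w in range(1, 21)]`.

## Known limitations

* The spatial grouping uses single-linkage components; a long chain of
  sub-8 m neighbours can merge into one large group and starve folds.
* The adjusted-quantile outlier rule is a functional re-specification of
  the robust-distance idea, not a port of any particular package; on
  multimodal groups it is conservative by design.
* PDS tuning is the slowest path; the batched implementation is linear in
  the grid size, so the full 200-point grid costs ~30× the default.
* `run_study` holds all variants in memory (~100 MB at default sizes).
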