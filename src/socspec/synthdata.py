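"""Synthetic two-instrument, lab/field Vis-NIR soil scenes.

The generator emulates the data situation of a field-scale soil organic
carbon (SOC) monitoring campaign:

* ~50 sampling locations on an experimental field, SOC truncated-normal
  around 19.6 g kg^-1 inside 14-25 g kg^-1;
* a high-resolution point spectrometer (1 nm output grid, 350-2500 nm,
  internal sensor splices at 1000/1800 nm, 18 lab / 15 field replicate
  spectra per location);
* a low-resolution spectrometer (~5 nm output grid, two sensor segments
  with a dead band at 1000-1100 nm, 18 lab replicates, and a georeferenced
  on-the-go stream of spectra instead of field replicates);
* field disturbance: moisture absorption bands near 1400/1900 nm, a random
  per-spectrum baseline tilt, and extra noise.

The forward model is deliberately simple — a smooth decreasing baseline
minus SOC-scaled Gaussian absorption bands — not a radiative-transfer
model: the downstream pipeline only needs realistic band/scatter/moisture
structure with known ground truth.

All spectra are first synthesized on a 1 nm master grid and then
block-averaged to the device grid, so a low-resolution dataset is exactly
the block-resampled high-resolution dataset when noise is switched off.
Randomness is governed by a single master seed; per-purpose child streams
are derived with ``numpy.random.SeedSequence.spawn`` in a fixed order
(soc, coordinates, moisture, lab per device, field per device).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleTable, SpectrumSet

__all__ = [
    "DeviceProfile",
    "SceneParams",
    "Scene",
    "HIGHRES",
    "LOWRES",
    "generate_soc",
    "generate_coordinates",
    "generate_moisture",
    "generate_lab_spectra",
    "apply_field_disturbance",
    "generate_stream",
    "generate_scene",
    "block_resample",
]


@dataclass(frozen=True)
class DeviceProfile:
    """Output characteristics of one spectrometer."""

    name: str
    wavelength_start: float  # nm
    wavelength_end: float  # nm
    resolution: float  # nm, grid step of the OUTPUT spectra
    dead_bands: tuple = ()  # [(lo, hi)] intervals reported as missing
    splice_points: tuple = ()  # nm where additive inter-sensor offsets occur
    noise_sd: float = 0.0  # reflectance units, added on the output grid
    artifact_sd: float = 0.0  # per-location device artifact amplitude
    field_disturbance_scale: float = 1.0  # multiplier on field-only artifacts
    replicate_counts: dict = field(default_factory=lambda: {"lab": 18, "field": 15})

    def __post_init__(self):
        if not self.wavelength_start < self.wavelength_end:
            raise ValueError("wavelength_start must be < wavelength_end")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for lo, hi in self.dead_bands:
            if not (self.wavelength_start <= lo < hi <= self.wavelength_end):
                raise ValueError(f"dead band ({lo},{hi}) outside device range")
        for sp in self.splice_points:
            if not (self.wavelength_start < sp < self.wavelength_end):
                raise ValueError(f"splice point {sp} outside device range")

    def master_grid(self) -> np.ndarray:
        """1 nm synthesis grid spanning the device range."""
        return np.arange(self.wavelength_start, self.wavelength_end + 0.5, 1.0)


HIGHRES = DeviceProfile(
    name="highres",
    wavelength_start=350.0,
    wavelength_end=2500.0,
    resolution=1.0,
    splice_points=(1000.0, 1800.0),
    noise_sd=0.0020,
    artifact_sd=0.0020,
    replicate_counts={"lab": 18, "field": 15},
)

LOWRES = DeviceProfile(
    name="lowres",
    wavelength_start=350.0,
    wavelength_end=2200.0,
    resolution=5.0,
    dead_bands=((1000.0, 1100.0),),
    noise_sd=0.0045,
    artifact_sd=0.0045,
    field_disturbance_scale=1.5,  # below-ground on-the-go contact is harsher
    replicate_counts={"lab": 18, "field": 12},
)


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth structure of a synthetic scene.

    SOC band gains are in reflectance depth per (g kg^-1); the defaults are
    calibrated so the noiseless SOC signal dominates averaged lab noise
    (lab model R^2 around 0.9) while field moisture/tilt disturbance
    degrades the field models markedly, matching the study regime the
    pipeline is meant for.
    """

    n_locations: int = 50
    soc_mean: float = 19.6  # g kg^-1
    soc_sd: float = 2.5  # g kg^-1 (chosen; only mean and range are given)
    soc_range: tuple = (14.0, 25.0)
    band_centers: tuple = (560.0, 1330.0, 1412.0, 1720.0, 2008.0)
    band_widths: tuple = (45.0, 30.0, 25.0, 30.0, 40.0)
    band_gains: tuple = (0.0016, 0.0018, 0.0022, 0.0020, 0.0024)
    # mismatch between measured SOC and its spectrally active fraction
    soc_spectral_sd: float = 0.6  # g kg^-1, per location
    # device-specific smooth artifact bands (soil presentation / optics)
    artifact_band_count: int = 20
    artifact_width_range: tuple = (30.0, 150.0)
    field_artifact_band_count: int = 12
    moisture_range: tuple = (15.0, 25.0)  # % volumetric
    moisture_band_centers: tuple = (1400.0, 1900.0)
    moisture_band_widths: tuple = (70.0, 90.0)
    moisture_gain: float = 0.0050  # reflectance depth per % volumetric
    # field-only per-location structured disturbance (roughness, contact)
    field_artifact_sd: float = 0.0120
    # per-location mismatch between the SOC of the field-sensed soil volume
    # (moist, intact, at depth) and the processed lab sample (g kg^-1)
    field_soc_mismatch_sd: float = 0.65
    scatter_slope_sd: float = 0.010  # multiplicative, per replicate
    scatter_offset_sd: float = 0.004  # additive, per replicate
    splice_offset_sd: float = 0.008  # additive per sensor segment, per replicate
    field_tilt_sd: float = 0.008  # baseline tilt amplitude per field spectrum
    field_extra_noise_sd: float = 0.003
    field_size_m: tuple = (200.0, 150.0)
    stream_per_location: int = 12
    stream_jitter_m: float = 2.5
    rng_seed: int = 0

    def __post_init__(self):
        if self.soc_range[0] >= self.soc_range[1]:
            raise ValueError("degenerate soc_range (min >= max)")
        if not (len(self.band_centers) == len(self.band_widths) == len(self.band_gains)):
            raise ValueError("band centers/widths/gains must have equal length")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError("band widths must be positive")
        if any(g < 0 for g in self.band_gains):
            raise ValueError("band gains must be non-negative")
        if not (0 <= self.moisture_range[0] <= self.moisture_range[1] <= 100):
            raise ValueError("moisture_range must lie within [0, 100]")


def _child_rngs(seed: int, n: int) -> list:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def generate_soc(params: SceneParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-location SOC (g kg^-1): truncated normal, clipped to soc_range."""
    if params.n_locations < 2:
        raise ValueError("need at least 2 locations")
    lo, hi = params.soc_range
    if rng is None:
        rng = _child_rngs(params.rng_seed, 1)[0]
    if params.soc_sd == 0:
        return np.full(params.n_locations, params.soc_mean)
    a = (lo - params.soc_mean) / params.soc_sd
    b = (hi - params.soc_mean) / params.soc_sd
    soc = stats.truncnorm.rvs(
        a, b, loc=params.soc_mean, scale=params.soc_sd,
        size=params.n_locations, random_state=rng,
    )
    return np.clip(soc, lo, hi)


def generate_coordinates(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform planar coordinates (m) on the field rectangle."""
    w, h = params.field_size_m
    return np.column_stack([rng.uniform(0, w, params.n_locations),
                            rng.uniform(0, h, params.n_locations)])


def generate_moisture(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Per-location volumetric moisture (%), uniform in moisture_range."""
    lo, hi = params.moisture_range
    return rng.uniform(lo, hi, params.n_locations)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _baseline(wl: np.ndarray) -> np.ndarray:
    u = (wl - 350.0) / 2150.0
    return 0.68 - 0.22 * u - 0.06 * u**2


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def ideal_spectrum(soc_value: float, wl: np.ndarray, params: SceneParams) -> np.ndarray:
    """Noiseless reflectance for one SOC value on an arbitrary grid."""
    r = _baseline(wl)
    for c, w, g in zip(params.band_centers, params.band_widths, params.band_gains):
        r = r - g * soc_value * _gauss(wl, c, w)
    return r


def draw_artifacts(n_locations: int, device: DeviceProfile, params: SceneParams,
                   rng: np.random.Generator) -> dict:
    """Device-specific smooth artifact bands with per-location coefficients.

    Emulates soil-presentation and optics variability that does not average
    out over replicates (it is tied to the location/device pair, not to the
    individual scan); shared between lab and field of the same device.
    """
    b = params.artifact_band_count
    if b == 0 or device.artifact_sd == 0:
        return {"centers": np.empty(0), "widths": np.empty(0),
                "coef": np.zeros((n_locations, 0))}
    lo, hi = params.artifact_width_range
    return {
        "centers": rng.uniform(device.wavelength_start + 50,
                               device.wavelength_end - 50, b),
        "widths": rng.uniform(lo, hi, b),
        "coef": rng.normal(0.0, device.artifact_sd, (n_locations, b)),
    }


def _artifact_spectrum(artifacts: dict, loc: int, wl: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wl, dtype=float)
    for c, w, a in zip(artifacts["centers"], artifacts["widths"],
                       artifacts["coef"][loc]):
        out += a * _gauss(wl, c, w)
    return out


def soc_band_shape(wl: np.ndarray, params: SceneParams) -> np.ndarray:
    """Reflectance decrease per g kg^-1 of spectrally active SOC."""
    out = np.zeros_like(wl, dtype=float)
    for c, w, g in zip(params.band_centers, params.band_widths, params.band_gains):
        out += g * _gauss(wl, c, w)
    return out


def _field_soc_shift(n_locations: int, device: DeviceProfile,
                     params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Per-location field-vs-lab shift of the spectrally active SOC."""
    sd = params.field_soc_mismatch_sd * device.field_disturbance_scale
    if sd == 0:
        return np.zeros(n_locations)
    return rng.normal(0.0, sd, n_locations)


def _field_artifacts(n_locations: int, wl: np.ndarray, device: DeviceProfile,
                     params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Per-location field-only disturbance spectra (n_locations x p).

    Fresh smooth band shapes (independent of the device lab artifacts) with
    per-location coefficients of amplitude ``field_artifact_sd``; emulates
    surface roughness / sensor-contact variability.
    """
    b = params.field_artifact_band_count
    if params.field_artifact_sd == 0 or b == 0:
        return np.zeros((n_locations, wl.size))
    lo, hi = params.artifact_width_range
    centers = rng.uniform(wl[0] + 50, wl[-1] - 50, b)
    widths = rng.uniform(lo, hi, b)
    coef = rng.normal(0.0, params.field_artifact_sd * device.field_disturbance_scale,
                      (n_locations, b))
    shapes = np.stack([_gauss(wl, c, w) for c, w in zip(centers, widths)])
    return coef @ shapes


def moisture_disturbance(moisture_pct: float, wl: np.ndarray, params: SceneParams) -> np.ndarray:
    """Reflectance decrease caused by the water absorption bands."""
    d = np.zeros_like(wl, dtype=float)
    for c, w in zip(params.moisture_band_centers, params.moisture_band_widths):
        d += params.moisture_gain * moisture_pct * _gauss(wl, c, w)
    return d


def block_resample(wl: np.ndarray, refl: np.ndarray, resolution: float,
                   dead_bands: Sequence = ()) -> tuple:
    """Block-average a 1 nm grid to ``resolution``; drop dead-band bins.

    The output wavelength of each bin is the mean of its member
    wavelengths.  For resolution 1 this is the identity (minus dead bands).
    """
    step = int(round(resolution))
    p = wl.size - (wl.size % step)
    wl_b = wl[:p].reshape(-1, step).mean(axis=1)
    refl_b = refl[:, :p].reshape(refl.shape[0], -1, step).mean(axis=2)
    keep = np.ones(wl_b.size, dtype=bool)
    for lo, hi in dead_bands:
        keep &= ~((wl_b >= lo) & (wl_b <= hi))
    return wl_b[keep], refl_b[:, keep]


def _segments(wl: np.ndarray, splice_points: Sequence) -> np.ndarray:
    """Integer segment label per master wavelength, split at splice points."""
    seg = np.zeros(wl.size, dtype=int)
    for sp in sorted(splice_points):
        seg += (wl > sp).astype(int)
    return seg


def generate_lab_spectra(
    soc: np.ndarray,
    device: DeviceProfile,
    params: SceneParams,
    rng: np.random.Generator | None = None,
    coords: np.ndarray | None = None,
    sample_ids: Sequence | None = None,
    spectral_soc: np.ndarray | None = None,
    artifacts: dict | None = None,
) -> tuple:
    """Replicated lab spectra for one device plus the generating truth.

    Per replicate: ideal spectrum (driven by the spectrally active SOC and
    the location's device artifacts), multiplicative slope and additive
    offset (scatter), additive per-sensor-segment offsets at the splice
    points, block resampling to the device grid, then device noise;
    clipped to (0, 1).

    ``spectral_soc`` (the SOC fraction the spectrum actually responds to)
    and ``artifacts`` are drawn here when not supplied; pass them in to
    share soil/device truth across datasets.
    """
    soc = np.asarray(soc, dtype=float)
    if rng is None:
        rng = _child_rngs(params.rng_seed, 1)[0]
    wl_m = device.master_grid()
    for c in params.band_centers:
        if not (wl_m[0] <= c <= wl_m[-1]):
            raise ValueError(f"band center {c} nm outside device grid")
    if spectral_soc is None:
        spectral_soc = soc + rng.normal(0.0, params.soc_spectral_sd, soc.size) \
            if params.soc_spectral_sd > 0 else soc
    if artifacts is None:
        artifacts = draw_artifacts(soc.size, device, params, rng)
    seg = _segments(wl_m, device.splice_points)
    n_seg = seg.max() + 1
    n_rep = device.replicate_counts["lab"]
    ids = sample_ids if sample_ids is not None else [f"loc{i:03d}" for i in range(soc.size)]

    rows, meta, truth_scatter = [], [], []
    for i, s in enumerate(spectral_soc):
        base = ideal_spectrum(s, wl_m, params) - _artifact_spectrum(artifacts, i, wl_m)
        for r in range(n_rep):
            slope = 1.0 + rng.normal(0.0, params.scatter_slope_sd)
            offset = rng.normal(0.0, params.scatter_offset_sd)
            spec = slope * base + offset
            if n_seg > 1 and params.splice_offset_sd > 0:
                seg_off = rng.normal(0.0, params.splice_offset_sd, n_seg)
                seg_off[0] = 0.0  # shortest-wavelength segment is the anchor
                spec = spec + seg_off[seg]
            else:
                seg_off = np.zeros(n_seg)
            rows.append(spec)
            truth_scatter.append({"sample": ids[i], "replicate": r,
                                  "slope": slope, "offset": offset,
                                  "segment_offsets": seg_off.tolist()})
            meta.append({
                "sample_id": ids[i], "device": device.name, "condition": "lab",
                "replicate_id": r,
                "x_m": coords[i, 0] if coords is not None else np.nan,
                "y_m": coords[i, 1] if coords is not None else np.nan,
            })
    refl = np.vstack(rows)
    wl_out, refl_out = block_resample(wl_m, refl, device.resolution, device.dead_bands)
    if device.noise_sd > 0:
        refl_out = refl_out + rng.normal(0.0, device.noise_sd, refl_out.shape)
    refl_out = np.clip(refl_out, 1e-6, 1.0 - 1e-6)
    sset = SpectrumSet(wl_out, refl_out, pd.DataFrame(meta))
    truth = {
        "soc": soc, "spectral_soc": spectral_soc, "sample_ids": list(ids),
        "band_centers": list(params.band_centers),
        "band_widths": list(params.band_widths),
        "band_gains": list(params.band_gains),
        "artifacts": artifacts, "scatter": truth_scatter,
    }
    return sset, truth


def apply_field_disturbance(
    lab: SpectrumSet,
    moisture: np.ndarray,
    device: DeviceProfile,
    params: SceneParams,
    rng: np.random.Generator | None = None,
) -> SpectrumSet:
    """Field replicate spectra derived from the per-location lab signal.

    Each location's base spectrum is the mean of its lab replicates; field
    replicates add the moisture absorption, a field-only per-location
    structured disturbance (amplitude ``field_artifact_sd``), a random
    per-spectrum baseline tilt, and extra noise.  With zero moisture and
    all field perturbations off, the field spectra equal the lab means
    exactly.
    """
    moisture = np.asarray(moisture, dtype=float)
    if np.any((moisture < 0) | (moisture > 100)):
        raise ValueError("moisture must lie within [0, 100] %")
    if rng is None:
        rng = _child_rngs(params.rng_seed, 1)[0]
    wl = lab.wavelengths
    tilt_shape = (wl - wl.mean()) / (wl[-1] - wl[0])
    n_rep = device.replicate_counts["field"]
    order = sorted(lab.meta["sample_id"].unique())
    field_art = _field_artifacts(len(order), wl, device, params, rng)
    soc_shift = _field_soc_shift(len(order), device, params, rng)
    band_shape = soc_band_shape(wl, params)
    rows, meta = [], []
    for i, sid in enumerate(order):
        idx = np.flatnonzero(lab.meta["sample_id"].to_numpy() == sid)
        base = lab.reflectance[idx].mean(axis=0)
        dist = (moisture_disturbance(moisture[i], wl, params) + field_art[i]
                + soc_shift[i] * band_shape)
        for r in range(n_rep):
            spec = base - dist
            if params.field_tilt_sd > 0:
                spec = spec + rng.normal(0.0, params.field_tilt_sd) * tilt_shape
            if params.field_extra_noise_sd > 0:
                spec = spec + rng.normal(0.0, params.field_extra_noise_sd, wl.size)
            rows.append(spec)
            m = lab.meta.iloc[idx[0]].to_dict()
            m.update(condition="field", replicate_id=r)
            meta.append(m)
    refl = np.clip(np.vstack(rows), 1e-6, 1.0 - 1e-6)
    return SpectrumSet(wl.copy(), refl, pd.DataFrame(meta)[list(lab.meta.columns)])


def generate_stream(
    soc: np.ndarray,
    coords: np.ndarray,
    moisture: np.ndarray,
    device: DeviceProfile,
    params: SceneParams,
    rng: np.random.Generator | None = None,
    spectral_soc: np.ndarray | None = None,
    artifacts: dict | None = None,
) -> SpectrumSet:
    """Georeferenced on-the-go stream for the low-resolution device.

    Emits ``stream_per_location`` spectra per location with planar jitter
    within ``stream_jitter_m``, each carrying the location's moisture
    disturbance plus per-spectrum tilt and noise.  Records are tagged
    ``sample_id='stream'``: assigning them to locations is the job of the
    nearest-spectra selection downstream.
    """
    if rng is None:
        rng = _child_rngs(params.rng_seed, 1)[0]
    soc = np.asarray(soc, dtype=float)
    if spectral_soc is None:
        spectral_soc = soc
    if artifacts is None:
        artifacts = draw_artifacts(soc.size, device, params, rng)
    wl_m = device.master_grid()
    tilt_shape_m = (wl_m - wl_m.mean()) / (wl_m[-1] - wl_m[0])
    field_art = _field_artifacts(soc.size, wl_m, device, params, rng)
    soc_shift = _field_soc_shift(soc.size, device, params, rng)
    band_shape = soc_band_shape(wl_m, params)
    rows, meta = [], []
    rec = 0
    for i, s in enumerate(spectral_soc):
        base = (ideal_spectrum(s, wl_m, params)
                - _artifact_spectrum(artifacts, i, wl_m)
                - moisture_disturbance(moisture[i], wl_m, params)
                - field_art[i]
                - soc_shift[i] * band_shape)
        for _ in range(params.stream_per_location):
            ang = rng.uniform(0, 2 * np.pi)
            rad = params.stream_jitter_m * np.sqrt(rng.uniform())
            spec = base.copy()
            if params.field_tilt_sd > 0:
                spec = spec + rng.normal(0.0, params.field_tilt_sd) * tilt_shape_m
            rows.append(spec)
            meta.append({
                "sample_id": "stream", "device": device.name, "condition": "field",
                "replicate_id": rec,
                "x_m": coords[i, 0] + rad * np.cos(ang),
                "y_m": coords[i, 1] + rad * np.sin(ang),
            })
            rec += 1
    refl = np.vstack(rows)
    wl_out, refl_out = block_resample(wl_m, refl, device.resolution, device.dead_bands)
    noise_sd = np.hypot(device.noise_sd, params.field_extra_noise_sd)
    if noise_sd > 0:
        refl_out = refl_out + rng.normal(0.0, noise_sd, refl_out.shape)
    refl_out = np.clip(refl_out, 1e-6, 1.0 - 1e-6)
    return SpectrumSet(wl_out, refl_out, pd.DataFrame(meta))


# ---------------------------------------------------------------------------
# whole-scene convenience
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """A full synthetic campaign: truth plus all raw datasets."""

    params: SceneParams
    samples: SampleTable
    moisture: np.ndarray
    lab: dict  # device name -> SpectrumSet (replicates)
    field: dict  # device name -> SpectrumSet (replicates / selected stream)
    stream: dict  # device name -> raw on-the-go SpectrumSet
    truth: dict


def generate_scene(
    params: SceneParams,
    devices: Sequence[DeviceProfile] = (HIGHRES, LOWRES),
    point_field_devices: Sequence[str] = ("highres",),
) -> Scene:
    """Generate the complete two-device lab/field scene from one seed.

    Devices named in ``point_field_devices`` get per-location field
    replicates; the others get an on-the-go stream.
    """
    rngs = _child_rngs(params.rng_seed, 4 + 2 * len(devices))
    soc = generate_soc(params, rngs[0])
    coords = generate_coordinates(params, rngs[1])
    moisture = generate_moisture(params, rngs[2])
    spectral_soc = soc + rngs[3].normal(0.0, params.soc_spectral_sd, soc.size) \
        if params.soc_spectral_sd > 0 else soc
    ids = [f"loc{i:03d}" for i in range(params.n_locations)]
    samples = SampleTable(pd.DataFrame({
        "sample_id": ids, "soc": soc, "x_m": coords[:, 0], "y_m": coords[:, 1],
    }))
    lab, fld, stream = {}, {}, {}
    truth = {"soc": soc, "spectral_soc": spectral_soc, "moisture": moisture,
             "coords": coords, "band_centers": list(params.band_centers),
             "devices": {}}
    for k, dev in enumerate(devices):
        rng_lab, rng_field = rngs[4 + 2 * k], rngs[5 + 2 * k]
        artifacts = draw_artifacts(soc.size, dev, params, rng_lab)
        lab_set, dev_truth = generate_lab_spectra(
            soc, dev, params, rng_lab, coords=coords, sample_ids=ids,
            spectral_soc=spectral_soc, artifacts=artifacts)
        lab[dev.name] = lab_set
        truth["devices"][dev.name] = dev_truth
        if dev.name in point_field_devices:
            fld[dev.name] = apply_field_disturbance(lab_set, moisture, dev, params,
                                                    rng_field)
        else:
            stream[dev.name] = generate_stream(soc, coords, moisture, dev, params,
                                               rng_field, spectral_soc=spectral_soc,
                                               artifacts=artifacts)
    return Scene(params=params, samples=samples, moisture=moisture,
                 lab=lab, field=fld, stream=stream, truth=truth)


def noiseless(params: SceneParams) -> SceneParams:
    """Copy of params with every stochastic perturbation switched off."""
    return replace(
        params,
        scatter_slope_sd=0.0, scatter_offset_sd=0.0, splice_offset_sd=0.0,
        field_tilt_sd=0.0, field_extra_noise_sd=0.0, soc_spectral_sd=0.0,
        field_artifact_sd=0.0, field_soc_mismatch_sd=0.0,
    )


def quiet_device(device: DeviceProfile) -> DeviceProfile:
    """Copy of a device with sensor noise and artifacts switched off."""
    return replace(device, noise_sd=0.0, artifact_sd=0.0)
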