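"""End-to-end study replica on a synthetic scene.

Workflow (one seed drives everything):

1. generate the two-device lab/field scene;
2. per device/condition: splice correction (where the device has splice
   points), 400-2200 nm trimming with dead bands dropped, per-location
   multivariate outlier removal (stream-level for the on-the-go data,
   before nearest-spectra selection), replicate averaging;
3. apply the four preprocessing operators -> 16 dataset variants,
   named ``{device}_{condition}_{method}``;
4. spatially-grouped nested CV (5 folds x 5 repetitions = 25 PLSR models
   per variant) with component-count tuning;
5. tune and evaluate the three corrections (LT, PDS, EPO) on the 8 field
   variants against their lab counterparts;
6. median RC/VIP importance profiles, local peaks, and peak-match tables
   against the best-performing lab variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import importance as imp
from .cv import CVScheme, PLSREstimator, nested_cv
from .io import SampleTable, SpectrumSet, average_replicates, select_nearest_stream
from .metrics import summarize_cv
from .preprocess import (PreprocessSpec, apply_preprocessing, remove_outliers,
                         splice_correct, trim_range)
from .synthdata import HIGHRES, LOWRES, Scene, SceneParams, generate_scene
from .transfer import tune_transfer

PREPROCESS_METHODS = ("SG", "SGCR", "gapDer", "MSC")
TRANSFER_METHODS = ("LT", "PDS", "EPO")


@dataclass
class StudyConfig:
    """Everything a full run needs; defaults give the standard replica."""

    scene: SceneParams = dc_field(default_factory=SceneParams)
    devices: tuple = (HIGHRES, LOWRES)
    trim: tuple = (400.0, 2200.0)
    preprocess_methods: tuple = PREPROCESS_METHODS
    cv: CVScheme = dc_field(default_factory=CVScheme)
    a_max: int = 20
    transfer_methods: tuple = TRANSFER_METHODS
    # correction tuning grids; PDS is (ncomp, half-width) pairs
    epo_grid: tuple = tuple((c,) for c in range(1, 11))
    pds_grid: tuple = ((1, 2), (1, 5), (2, 5), (2, 10))
    transfer_ncomp_grid: tuple = tuple(range(1, 13))
    nearest_k: int = 10
    nearest_radius_m: float = 3.0


def prepare_base_datasets(scene: Scene, config: StudyConfig) -> dict:
    """Averaged per-location spectra per (device, condition), fully prepared.

    Returns {(device, condition): SpectrumSet} with one spectrum per
    location, after splice correction, trimming, outlier removal and
    (for the on-the-go stream) nearest-spectra selection.
    """
    out = {}
    devices = {d.name: d for d in config.devices}
    def prep(s: SpectrumSet, dev) -> SpectrumSet:
        if dev.splice_points:
            s = splice_correct(s, dev.splice_points)
        return trim_range(s, *config.trim, dead_bands=dev.dead_bands)

    for name, dev in devices.items():
        lab = prep(scene.lab[name], dev)
        lab, _ = remove_outliers(lab)
        out[(name, "lab")] = average_replicates(lab)
        if name in scene.field:
            fld = prep(scene.field[name], dev)
            fld, _ = remove_outliers(fld)
            out[(name, "field")] = average_replicates(fld)
        elif name in scene.stream:
            stream = prep(scene.stream[name], dev)
            # screen outliers among the records assigned to each sampling
            # point (nearest location within radius), then select k nearest
            stream = _assign_stream_records(stream, scene.samples,
                                            config.nearest_radius_m)
            stream, _ = remove_outliers(stream)
            nearest = select_nearest_stream(stream, scene.samples,
                                            k=config.nearest_k,
                                            max_radius_m=config.nearest_radius_m)
            out[(name, "field")] = average_replicates(nearest)
        else:
            raise ValueError(f"device {name} has neither field replicates nor stream")
    return out


def _assign_stream_records(stream: SpectrumSet, samples: SampleTable,
                           radius_m: float) -> SpectrumSet:
    """Tag each stream record with its nearest sampling location.

    Records farther than ``radius_m`` from every location keep their
    original tag (they are never candidates downstream).
    """
    xy = stream.meta[["x_m", "y_m"]].to_numpy(dtype=float)
    coords = samples.coords
    meta = stream.meta.copy()
    d = np.hypot(xy[:, 0, None] - coords[None, :, 0],
                 xy[:, 1, None] - coords[None, :, 1])
    nearest = d.argmin(axis=1)
    within = d[np.arange(len(xy)), nearest] <= radius_m
    ids = samples.sample_ids
    meta.loc[within, "sample_id"] = ids[nearest[within]]
    return SpectrumSet(stream.wavelengths.copy(), stream.reflectance.copy(), meta)


def make_variants(base: dict, config: StudyConfig) -> dict:
    """The 16 preprocessed dataset variants, keyed by name."""
    variants = {}
    for (dev, cond), s in base.items():
        for method in config.preprocess_methods:
            variants[f"{dev}_{cond}_{method}"] = apply_preprocessing(
                s, PreprocessSpec(method=method))
    return variants


def _aligned_xy(variant: SpectrumSet, samples: SampleTable) -> np.ndarray:
    """Reflectance matrix row-aligned with the sample table order."""
    order = {sid: i for i, sid in enumerate(variant.meta["sample_id"])}
    idx = np.array([order[sid] for sid in samples.sample_ids])
    return variant.reflectance[idx]


@dataclass
class StudyResult:
    config: StudyConfig
    scene: Scene
    variants: dict  # name -> SpectrumSet
    cv_results: dict  # name -> NestedCVResult
    metrics: pd.DataFrame  # per variant x repetition
    corrected: dict  # (variant, method) -> NestedCVResult
    transfer_reports: dict  # (variant, method) -> parameter report
    profiles: dict  # name or (name, method) -> ImportanceProfile


def run_study(config: StudyConfig | None = None, progress=None) -> StudyResult:
    """Run the full replica; see module docstring for the stages."""
    config = config or StudyConfig()
    log = progress or (lambda msg: None)
    log("generating scene")
    scene = generate_scene(config.scene, config.devices)
    base = prepare_base_datasets(scene, config)
    variants = make_variants(base, config)
    samples = scene.samples

    cv_results, metric_rows = {}, []
    for name, v in variants.items():
        log(f"nested CV: {name}")
        X = _aligned_xy(v, samples)
        res = nested_cv(samples, PLSREstimator(X, samples.soc, config.a_max), config.cv)
        cv_results[name] = res
        per_rep = summarize_cv(res.rows, config.cv.repetitions)
        per_rep.insert(0, "variant", name)
        metric_rows.append(per_rep)

    corrected, reports = {}, {}
    for dev, cond in base:
        if cond != "field":
            continue
        for method in config.preprocess_methods:
            name = f"{dev}_field_{method}"
            lab_v = variants[f"{dev}_lab_{method}"]
            fld_v = variants[name]
            Xl = _aligned_xy(lab_v, samples)
            Xf = _aligned_xy(fld_v, samples)
            for tmethod in config.transfer_methods:
                log(f"correction {tmethod}: {name}")
                grid = {"LT": [()], "PDS": config.pds_grid,
                        "EPO": config.epo_grid}[tmethod]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res, rep = tune_transfer(
                        Xf, Xl, samples, tmethod, config.cv,
                        transfer_grid=grid,
                        ncomp_grid=config.transfer_ncomp_grid)
                corrected[(name, tmethod)] = res
                reports[(name, tmethod)] = rep
                per_rep = summarize_cv(res.rows, config.cv.repetitions)
                per_rep.insert(0, "variant", f"{name}_{tmethod}")
                metric_rows.append(per_rep)

    log("importance profiles")
    profiles = {}
    for name, res in cv_results.items():
        models = [m for (_, _, _, m) in res.models]
        ncomps = [int(gp) for (_, _, gp, _) in res.models]
        prof = imp.median_profiles(models, variants[name].wavelengths, ncomps)
        prof.rc_peaks = imp.find_local_peaks(prof.median_rc, prof.wavelengths,
                                             prof.rc_span_nm, "both")
        prof.vip_peaks = imp.find_local_peaks(prof.median_vip, prof.wavelengths,
                                              prof.vip_span_nm, "maxima")
        profiles[name] = prof

    return StudyResult(
        config=config, scene=scene, variants=variants, cv_results=cv_results,
        metrics=pd.concat(metric_rows, ignore_index=True),
        corrected=corrected, transfer_reports=reports, profiles=profiles,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def group_median_rmse(metrics: pd.DataFrame) -> dict:
    """Median RMSE of the best preprocessing variant per device/condition."""
    out = {}
    for dev in ("highres", "lowres"):
        for cond in ("lab", "field"):
            best = np.inf
            for method in PREPROCESS_METHODS:
                sub = metrics[metrics["variant"] == f"{dev}_{cond}_{method}"]
                if len(sub):
                    best = min(best, float(sub["rmse"].median()))
            out[f"{dev}_{cond}"] = best
    return out


def correction_improvements(metrics: pd.DataFrame,
                            methods=TRANSFER_METHODS) -> pd.DataFrame:
    """Median-RMSE change of each correction vs. the uncorrected variant."""
    rows = []
    for dev in ("highres", "lowres"):
        for pmethod in PREPROCESS_METHODS:
            name = f"{dev}_field_{pmethod}"
            sub0 = metrics[metrics["variant"] == name]
            if not len(sub0):
                continue
            base_rmse = float(sub0["rmse"].median())
            for tm in methods:
                sub = metrics[metrics["variant"] == f"{name}_{tm}"]
                if not len(sub):
                    continue
                rows.append({
                    "variant": name, "correction": tm,
                    "uncorrected_rmse": base_rmse,
                    "corrected_rmse": float(sub["rmse"].median()),
                })
    df = pd.DataFrame(rows)
    if len(df):
        df["improvement"] = df["uncorrected_rmse"] - df["corrected_rmse"]
    return df


def best_lab_variant(metrics: pd.DataFrame) -> str:
    """Lab variant with the lowest median RMSE (the reference model)."""
    lab = metrics[metrics["variant"].str.contains("_lab_")]
    med = lab.groupby("variant")["rmse"].median()
    return med.idxmin()


def peak_match_table(result: StudyResult, reference: str | None = None,
                     index: str = "vip", tolerances: dict | None = None):
    """Match-table of local peaks against the reference variant's peaks.

    The default reference is the best-performing lab variant, mirroring the
    convention of comparing every dataset against the strongest model.
    """
    if reference is None:
        reference = best_lab_variant(result.metrics)
    tol = tolerances or {}
    candidates, tols = {}, {}
    ref_prof = result.profiles[reference]
    ref_peaks = ref_prof.vip_peaks if index == "vip" else ref_prof.rc_peaks
    for name, prof in result.profiles.items():
        if name == reference:
            continue
        candidates[name] = prof.vip_peaks if index == "vip" else prof.rc_peaks
        tols[name] = tol.get(name, 10.0 if name.startswith("highres") else 20.0)
    return imp.match_peaks(ref_peaks, candidates, tols, reference_label=reference)
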