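"""Wavelength-importance analysis across the CV model ensemble.

For each dataset the 25 CV models yield per-wavelength regression
coefficients (RC) and VIP scores; the analysis takes their medians, finds
local peaks (strict extrema within a centered window — 100 nm span for
RC maxima/minima, 50 nm for VIP maxima), and cross-tabulates peak matches
between a reference dataset and candidates within a per-dataset tolerance
(e.g. +-10 nm for the high-resolution device, +-20 nm for the
low-resolution one).  Dead bands are never bridged: windows are clipped
at segment edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsr import PLSRModel, vip
from .preprocess import contiguous_segments

__all__ = [
    "ImportanceProfile", "median_profiles", "find_local_peaks",
    "match_peaks", "vip_selection",
]


@dataclass
class ImportanceProfile:
    wavelengths: np.ndarray
    median_rc: np.ndarray
    median_vip: np.ndarray
    rc_peaks: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    vip_peaks: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    rc_span_nm: float = 100.0
    vip_span_nm: float = 50.0


def median_profiles(models: list, wavelengths: np.ndarray,
                    ncomps: list | None = None) -> ImportanceProfile:
    """Per-wavelength median RC and VIP over an ensemble of fitted models.

    ``ncomps`` optionally gives the tuned component count per model (RC
    and VIP are then evaluated at that count rather than the fit maximum).
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    rcs, vips = [], []
    for k, m in enumerate(models):
        if not isinstance(m, PLSRModel):
            raise TypeError("median_profiles expects PLSRModel instances")
        if m.p != wavelengths.size:
            raise ValueError("model grid size mismatch")
        a = None if ncomps is None else min(int(ncomps[k]), m.A)
        rcs.append(m.coefficients(a))
        vips.append(vip(m, a))
    return ImportanceProfile(
        wavelengths=wavelengths,
        median_rc=np.median(np.vstack(rcs), axis=0),
        median_vip=np.median(np.vstack(vips), axis=0),
    )


def find_local_peaks(values: np.ndarray, wavelengths: np.ndarray,
                     span_nm: float, mode: str = "maxima") -> pd.DataFrame:
    """Strict local extrema within a centered window of width ``span_nm``.

    A point is a peak iff it is interior to its segment and its value is
    strictly more extreme than every other point of the window
    |wl - wl_i| <= span/2, the window being clipped at segment edges (dead
    bands split segments); segment endpoints are never peaks, so monotone
    profiles have none.  Exact-tie plateaus yield no peak; the strictness
    rule keeps peak lists sparse and unambiguous.

    Returns a DataFrame (wavelength_nm, value, kind) sorted by wavelength.
    """
    values = np.asarray(values, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if values.size == 0:
        raise ValueError("empty profile")
    if mode not in {"maxima", "minima", "both"}:
        raise ValueError(f"unknown mode {mode!r}")
    step = np.min(np.diff(wavelengths)) if wavelengths.size > 1 else span_nm
    if span_nm <= step:
        raise ValueError("span must exceed the grid step")
    half = span_nm / 2.0
    rows = []
    for seg in contiguous_segments(wavelengths):
        wl = wavelengths[seg]
        v = values[seg]
        for i in range(1, wl.size - 1):
            lo = np.searchsorted(wl, wl[i] - half, side="left")
            hi = np.searchsorted(wl, wl[i] + half, side="right")
            win = v[lo:hi]
            others = np.delete(win, i - lo)
            if others.size == 0:
                continue
            if mode in ("maxima", "both") and v[i] > others.max():
                rows.append({"wavelength_nm": wl[i], "value": v[i], "kind": "max"})
            elif mode in ("minima", "both") and v[i] < others.min():
                rows.append({"wavelength_nm": wl[i], "value": v[i], "kind": "min"})
    return (pd.DataFrame(rows, columns=["wavelength_nm", "value", "kind"])
            .sort_values("wavelength_nm", ignore_index=True))


@dataclass
class MatchTable:
    reference: str
    table: pd.DataFrame  # rows: reference peak nm; columns: datasets; bool cells
    tolerances: dict

    @property
    def totals(self) -> pd.Series:
        return self.table.sum(axis=0)


def match_peaks(reference_peaks, candidates: dict, tolerances: dict,
                reference_label: str = "reference") -> MatchTable:
    """Cross-dataset peak matching.

    A reference peak matches a candidate dataset iff some candidate peak
    lies within that dataset's tolerance (nm).  Totals are column sums.
    ``reference_peaks``/candidate values may be DataFrames from
    :func:`find_local_peaks` or plain wavelength arrays.
    """
    ref = _peak_wavelengths(reference_peaks)
    cols = {}
    for name, peaks in candidates.items():
        tol = tolerances[name]
        if tol <= 0:
            raise ValueError(f"tolerance for {name!r} must be positive")
        cand = _peak_wavelengths(peaks)
        if cand.size == 0:
            cols[name] = np.zeros(ref.size, dtype=bool)
        else:
            cols[name] = np.array(
                [np.min(np.abs(cand - r)) <= tol for r in ref])
    table = pd.DataFrame(cols, index=pd.Index(ref, name="reference_nm"))
    return MatchTable(reference=reference_label, table=table, tolerances=dict(tolerances))


def _peak_wavelengths(peaks) -> np.ndarray:
    if isinstance(peaks, pd.DataFrame):
        return peaks["wavelength_nm"].to_numpy(dtype=float)
    return np.asarray(peaks, dtype=float).ravel()


def vip_selection(profile: ImportanceProfile, threshold: float = 1.0) -> np.ndarray:
    """Wavelengths whose median VIP strictly exceeds the threshold."""
    return profile.wavelengths[profile.median_vip > threshold]
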