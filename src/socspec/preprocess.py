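"""Spectral data preparation and the four preprocessing operators.

The fixed preparation order is: splice correction -> range trimming ->
per-location multivariate outlier removal -> replicate averaging ->
one of four preprocessing operators:

* ``SG``      Savitzky-Golay derivative (window 11, poly order 2, 1st
              derivative by default);
* ``SGCR``    Savitzky-Golay smoothing followed by continuum removal;
* ``gapDer``  gap-segment first derivative (gap 11 points, segment 10);
* ``MSC``     multiplicative scatter correction against a reference
              spectrum (set mean by default, persisted for reuse).

Derivative operators drop edge points without full window support and
never bridge dead bands: each contiguous uniform segment of the grid is
processed independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_coeffs

from .io import SpectrumSet


# ---------------------------------------------------------------------------
# grid segmentation
# ---------------------------------------------------------------------------

def contiguous_segments(wl: np.ndarray, tol: float = 1e-6) -> list:
    """Index slices of maximal runs with a uniform wavelength step.

    A gap (step larger than the local modal step) starts a new segment, so
    dead bands split the grid.
    """
    if wl.size < 2:
        return [slice(0, wl.size)]
    d = np.diff(wl)
    step = np.median(d)
    # a "break" is any step clearly larger than the modal step (a dead band)
    breaks = np.flatnonzero(d > step * 1.5)
    out, start = [], 0
    for b in breaks:
        out.append(slice(start, b + 1))
        start = b + 1
    out.append(slice(start, wl.size))
    return out


# ---------------------------------------------------------------------------
# splice correction
# ---------------------------------------------------------------------------

def splice_correct(s: SpectrumSet, splice_points) -> SpectrumSet:
    """Remove additive steps at inter-sensor splice wavelengths.

    Segments above each splice point are shifted so that the first point of
    the following segment equals the linear extrapolation from the last two
    points of the preceding segment; the shortest-wavelength segment is the
    fixed anchor.
    """
    wl = s.wavelengths
    for sp in splice_points:
        if not (wl[0] < sp < wl[-1]):
            raise ValueError(f"splice point {sp} nm outside grid [{wl[0]}, {wl[-1]}]")
    refl = s.reflectance.copy()
    bounds = [0] + [int(np.searchsorted(wl, sp, side="right")) for sp in sorted(splice_points)]
    bounds.append(wl.size)
    for k in range(1, len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        prev_end = bounds[k] - 1
        if prev_end < 1:
            raise ValueError("splice segment too short to extrapolate")
        # linear extrapolation from last two points of the preceding segment
        x1, x2 = wl[prev_end - 1], wl[prev_end]
        y1, y2 = refl[:, prev_end - 1], refl[:, prev_end]
        slope = (y2 - y1) / (x2 - x1)
        expected = y2 + slope * (wl[lo] - x2)
        shift = expected - refl[:, lo]
        refl[:, lo:hi] += shift[:, None]
    return SpectrumSet(wl.copy(), refl, s.meta.copy())


def trim_range(s: SpectrumSet, lo: float, hi: float, dead_bands=()) -> SpectrumSet:
    """Keep wavelengths within [lo, hi] and outside the dead bands."""
    if lo >= hi:
        raise ValueError("trim requires lo < hi")
    wl = s.wavelengths
    keep = (wl >= lo) & (wl <= hi)
    for dlo, dhi in dead_bands:
        keep &= ~((wl > dlo) & (wl < dhi))
    if not keep.any():
        raise ValueError(f"trim to [{lo}, {hi}] leaves no wavelengths")
    return s.select_wavelengths(keep)


# ---------------------------------------------------------------------------
# robust multivariate outlier removal
# ---------------------------------------------------------------------------

def _robust_distances(X: np.ndarray) -> np.ndarray:
    """Squared robust Mahalanobis distances in a PCA-reduced space.

    Spectra are projected onto principal components retaining >= 99% of the
    variance (capped at n-2); a deterministic minimum-covariance-determinant
    style concentration (C-steps from a coordinatewise-median start)
    followed by chi-square reweighting yields the robust center and
    covariance.  Returns one squared distance per spectrum.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = sv**2
    if var.sum() <= 0:
        return np.zeros(n), 1
    k_var = int(np.searchsorted(np.cumsum(var) / var.sum(), 0.99) + 1)
    k = max(1, min(k_var, n - 2))
    Z = U[:, :k] * sv[:k]  # scores
    h = (n + k + 1) // 2

    center = np.median(Z, axis=0)
    d2 = ((Z - center) ** 2).sum(axis=1)
    subset = np.argsort(d2, kind="stable")[:h]
    for _ in range(30):
        mu = Z[subset].mean(axis=0)
        cov = np.cov(Z[subset], rowvar=False).reshape(k, k)
        try:
            Li = np.linalg.cholesky(cov)
            y = np.linalg.solve(Li, (Z - mu).T)
            d2 = (y**2).sum(axis=0)
        except np.linalg.LinAlgError:
            warnings.warn("singular covariance in outlier removal; using diagonal",
                          stacklevel=2)
            dvar = np.maximum(np.var(Z[subset], axis=0, ddof=1), 1e-30)
            d2 = (((Z - mu) ** 2) / dvar).sum(axis=1)
        new_subset = np.argsort(d2, kind="stable")[:h]
        if np.array_equal(np.sort(new_subset), np.sort(subset)):
            break
        subset = new_subset
    # consistency: make squared distances chi-square(k) comparable
    med = np.median(d2)
    if med > 0:
        d2 = d2 * (stats.chi2.ppf(0.5, k) / med)
    # one reweighting step
    w = d2 <= stats.chi2.ppf(0.975, k)
    if w.sum() >= k + 2:
        mu = Z[w].mean(axis=0)
        cov = np.cov(Z[w], rowvar=False).reshape(k, k)
        try:
            Li = np.linalg.cholesky(cov)
            y = np.linalg.solve(Li, (Z - mu).T)
            d2 = (y**2).sum(axis=0)
            med = np.median(d2)
            if med > 0:
                d2 = d2 * (stats.chi2.ppf(0.5, k) / med)
        except np.linalg.LinAlgError:
            pass
    return d2, k


def adjusted_outlier_flags(X: np.ndarray, base_quantile: float = 0.975) -> np.ndarray:
    """Boolean mask of outlying spectra by adjusted chi-square cutoff.

    The cutoff starts at the chi-square ``base_quantile`` of the robust
    squared distances; if the empirical tail beyond it is no heavier than
    the chi-square tail, the cutoff is adjusted upward past the maximum
    distance (nothing flagged).
    """
    n = X.shape[0]
    if n < 3:
        return np.zeros(n, dtype=bool)
    d2, k = _robust_distances(X)
    delta = stats.chi2.ppf(base_quantile, k)
    tail = float(np.mean(d2 > delta))
    if tail <= 1.0 - base_quantile:
        return np.zeros(n, dtype=bool)  # tail lighter than chi-square
    return d2 > delta


def remove_outliers(s: SpectrumSet, group_by: str = "sample_id",
                    base_quantile: float = 0.975) -> tuple:
    """Drop outlying replicate spectra per group; returns (set, report).

    Groups with fewer than 3 spectra pass through untouched and are noted
    in the report.
    """
    keep = np.ones(s.n_spectra, dtype=bool)
    report = []
    cols = [group_by, "device", "condition"]
    for key, idx in s.meta.groupby(cols, sort=True).indices.items():
        idx = np.asarray(idx)
        if idx.size < 3:
            report.append({"group": key, "n": int(idx.size), "removed": 0,
                           "note": "too few spectra; passed through"})
            continue
        flags = adjusted_outlier_flags(s.reflectance[idx], base_quantile)
        keep[idx[flags]] = False
        report.append({"group": key, "n": int(idx.size),
                       "removed": int(flags.sum()), "note": ""})
    return s.subset(keep), pd.DataFrame(report)


# ---------------------------------------------------------------------------
# the four preprocessing operators
# ---------------------------------------------------------------------------

def savitzky_golay(s: SpectrumSet, window: int = 11, poly_order: int = 2,
                   derivative_order: int = 1) -> SpectrumSet:
    """Per-segment Savitzky-Golay filtering; edge points are dropped.

    On a 400-2200 nm 1 nm grid with an 11-point window the output spans
    405-2195 nm.  Derivatives are with respect to wavelength (per nm).
    """
    if window % 2 == 0 or window <= poly_order:
        raise ValueError("window must be odd and > poly_order")
    half = window // 2
    wl = s.wavelengths
    out_wl, out_cols = [], []
    for seg in contiguous_segments(wl):
        seg_wl = wl[seg]
        if seg_wl.size < window:
            raise ValueError(
                f"segment {seg_wl[0]}-{seg_wl[-1]} nm shorter than window {window}")
        delta = float(np.mean(np.diff(seg_wl)))
        if np.ptp(np.diff(seg_wl)) > 1e-6 * delta:
            raise ValueError("Savitzky-Golay requires a uniform grid per segment")
        coeffs = savgol_coeffs(window, poly_order, deriv=derivative_order,
                               delta=delta, use="dot")
        block = s.reflectance[:, seg]
        # valid convolution: windows fully inside the segment
        from numpy.lib.stride_tricks import sliding_window_view
        windows = sliding_window_view(block, window, axis=1)
        out_cols.append(windows @ coeffs)
        out_wl.append(seg_wl[half:-half])
    return SpectrumSet(np.concatenate(out_wl), np.hstack(out_cols), s.meta.copy())


def continuum_removal(s: SpectrumSet) -> SpectrumSet:
    """Divide each spectrum by its upper convex hull.

    Output lies in (0, 1] and equals exactly 1 at hull support points,
    including both segment endpoints.  Dead-band segments are hulled
    independently.
    """
    if np.any(s.reflectance <= 0):
        raise ValueError("continuum removal requires strictly positive reflectance")
    wl = s.wavelengths
    out = np.empty_like(s.reflectance)
    for seg in contiguous_segments(wl):
        x = wl[seg]
        block = s.reflectance[:, seg]
        for i in range(block.shape[0]):
            out[i, seg] = block[i] / upper_hull_envelope(x, block[i])
    return SpectrumSet(wl.copy(), np.minimum(out, 1.0), s.meta.copy())


def upper_hull_envelope(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Piecewise-linear upper convex hull of (x, y), evaluated on x.

    Andrew's monotone chain restricted to the upper hull; collinear points
    are kept off the hull (they still evaluate exactly on it).
    """
    n = x.size
    if n < 2:
        return y.copy()
    hull = []  # indices
    for i in range(n):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross >= 0:  # middle point not above the chord -> drop
                hull.pop()
            else:
                break
        hull.append(i)
    hx, hy = x[hull], y[hull]
    return np.interp(x, hx, hy)


def gap_segment_derivative(s: SpectrumSet, w: int = 11, s_seg: int = 10) -> SpectrumSet:
    """Gap-segment first derivative.

    At each point the derivative is (mean of the trailing segment of
    ``s_seg`` points − mean of the leading segment) divided by the
    center-to-center wavelength distance, with a gap of ``w`` points
    (centered on the output point) between the segments.  Edge points
    without full support are dropped: on a 400-2200 nm 1 nm grid with
    w=11, s=10 the output spans 415-2185 nm.  Exact on affine spectra.
    """
    if w < 1 or s_seg < 1:
        raise ValueError("w and s_seg must be >= 1")
    half_gap = w // 2
    support = half_gap + s_seg  # points needed on each side
    wl = s.wavelengths
    out_wl, out_cols = [], []
    for seg in contiguous_segments(wl):
        seg_wl = wl[seg]
        if seg_wl.size < 2 * support + 1:
            raise ValueError("segment too short for gap-segment derivative")
        delta = float(np.mean(np.diff(seg_wl)))
        block = s.reflectance[:, seg]
        csum = np.concatenate(
            [np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1)
        def seg_mean(a, b):  # mean over columns [a, b) for every valid center
            return (csum[:, b] - csum[:, a]) / (b - a)
        centers = np.arange(support, seg_wl.size - support)
        lead = np.stack([seg_mean(c - support, c - half_gap) for c in centers], axis=1)
        trail = np.stack([seg_mean(c + half_gap + 1, c + support + 1) for c in centers], axis=1)
        # center-to-center distance of the two averaging segments
        dist = (2 * half_gap + 1 + s_seg) * delta
        out_cols.append((trail - lead) / dist)
        out_wl.append(seg_wl[centers])
    return SpectrumSet(np.concatenate(out_wl), np.hstack(out_cols), s.meta.copy())


def msc(s: SpectrumSet, reference: np.ndarray | None = None) -> tuple:
    """Multiplicative scatter correction; returns (corrected, reference).

    Each spectrum x is regressed on the reference (OLS, x ~ a + b*ref) and
    corrected to (x − a)/b.  The reference defaults to the set mean and is
    returned so new data can be corrected against the same spectrum.
    """
    ref = s.reflectance.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.size != s.n_wavelengths:
        raise ValueError("MSC reference not on the spectrum grid")
    refc = ref - ref.mean()
    denom = float(refc @ refc)
    if denom <= 0:
        raise ValueError("MSC reference has zero variance")
    out = np.empty_like(s.reflectance)
    for i, x in enumerate(s.reflectance):
        b = float(refc @ (x - x.mean())) / denom
        if abs(b) < 1e-12:
            raise ValueError(f"MSC slope ~0 for spectrum {i} "
                             f"({s.meta.iloc[i]['sample_id']!r})")
        a = x.mean() - b * ref.mean()
        out[i] = (x - a) / b
    return SpectrumSet(s.wavelengths.copy(), out, s.meta.copy()), ref


# ---------------------------------------------------------------------------
# named preprocessing pipelines
# ---------------------------------------------------------------------------

@dataclass
class PreprocessSpec:
    """Configuration of one preprocessing operator.

    ``method`` is one of SG, SGCR, gapDer, MSC.  SG defaults to a first
    derivative (window 11, poly order 2); SGCR smooths (derivative 0)
    before continuum removal; gapDer uses gap 11 / segment 10; MSC uses
    the set mean unless a reference is supplied.
    """

    method: str = "SG"
    window: int = 11
    poly_order: int = 2
    derivative_order: int = 1
    gap_w: int = 11
    segment_s: int = 10
    msc_reference: np.ndarray | None = None

    def __post_init__(self):
        if self.method not in {"SG", "SGCR", "gapDer", "MSC"}:
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.window % 2 == 0 or self.window <= self.poly_order:
            raise ValueError("window must be odd and > poly_order")


def apply_preprocessing(s: SpectrumSet, spec: PreprocessSpec) -> SpectrumSet:
    """Apply one of the four named operators (see :class:`PreprocessSpec`)."""
    if spec.method == "SG":
        return savitzky_golay(s, spec.window, spec.poly_order, spec.derivative_order)
    if spec.method == "SGCR":
        smoothed = savitzky_golay(s, spec.window, spec.poly_order, 0)
        return continuum_removal(smoothed)
    if spec.method == "gapDer":
        return gap_segment_derivative(s, spec.gap_w, spec.segment_s)
    if spec.method == "MSC":
        corrected, _ = msc(s, spec.msc_reference)
        return corrected
    raise ValueError(spec.method)
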