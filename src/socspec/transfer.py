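"""Lab-based correction of field spectra: LT, PDS, and EPO.

All three corrections are fit on paired per-location averages (lab and
field spectra of the same samples on the same grid) and map field spectra
toward the laboratory domain:

* LT  — per-wavelength linear transformation: OLS of lab on field at each
  wavelength, corrected = a + b * field.
* PDS — piecewise direct standardization: for each target wavelength i a
  local PLSR maps the field window [i-w, i+w] to lab_i; the coefficients
  assemble into a banded transform matrix.
* EPO — external parameter orthogonalization: the difference matrix
  D = lab - field (column-centered) is decomposed by SVD and the spectra
  are projected onto the orthogonal complement of its first c right
  singular vectors (P = I - V V^T).  When an EPO-corrected model is
  built, the lab spectra are projected by the same P.

Hyperparameters (PDS window/components, EPO components) are tuned with
the same spatially-grouped nested CV used for model building; transfer
models inside the CV are fit on training-fold samples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cv import CVScheme, NestedCVResult, nested_cv
from .io import SampleTable, SpectrumSet
from .plsr import fit_plsr, predict

__all__ = [
    "TransferModel", "fit_lt", "fit_pds", "fit_epo", "apply_transfer",
    "TransferPLSREstimator", "tune_transfer",
]


@dataclass
class TransferModel:
    """Tagged union of the three correction kinds."""

    kind: str  # LT | PDS | EPO
    # LT
    slope: np.ndarray | None = None  # (p,)
    intercept: np.ndarray | None = None  # (p,) (also PDS intercepts)
    # PDS
    F: np.ndarray | None = None  # (p, p) banded transform
    window: int | None = None
    ncomp: int | None = None
    # EPO
    V: np.ndarray | None = None  # (p, c) orthonormal disturbance directions
    n_components: int | None = None

    @property
    def P_epo(self) -> np.ndarray:
        """Dense EPO projection I - V V^T (built on demand)."""
        if self.kind != "EPO":
            raise AttributeError("P_epo only defined for EPO models")
        return np.eye(self.V.shape[0]) - self.V @ self.V.T


def _check_paired(field_X: np.ndarray, lab_X: np.ndarray) -> None:
    if field_X.shape != lab_X.shape:
        raise ValueError("field and lab matrices must be paired (same shape)")


def fit_lt(field_X: np.ndarray, lab_X: np.ndarray) -> TransferModel:
    """Per-wavelength OLS of lab on field: lab_j ~ a_j + b_j * field_j."""
    field_X = np.asarray(field_X, float)
    lab_X = np.asarray(lab_X, float)
    _check_paired(field_X, lab_X)
    fm = field_X.mean(axis=0)
    lm = lab_X.mean(axis=0)
    fvar = ((field_X - fm) ** 2).sum(axis=0)
    cov = ((field_X - fm) * (lab_X - lm)).sum(axis=0)
    ok = fvar > 1e-20  # numerically zero variance in reflectance^2 units
    b = np.where(ok, cov / np.where(ok, fvar, 1.0), 0.0)
    if not ok.all():
        warnings.warn("zero field variance at some wavelengths; slope set to 0",
                      stacklevel=2)
    a = lm - b * fm
    return TransferModel(kind="LT", slope=b, intercept=a)


def fit_pds(field_X: np.ndarray, lab_X: np.ndarray, w: int, ncomp: int) -> TransferModel:
    """Piecewise direct standardization with window half-width ``w``.

    Each target wavelength i gets a local PLSR (``ncomp`` components,
    clipped to the window size) from the field window [i-w, i+w] to
    lab_i; windows are clipped at the grid edges rather than padded with
    extrapolated reflectance.  All p local NIPALS fits run as one batched
    computation (edge windows are zero-padded, which is exact: constant
    columns carry no weight after centering).
    """
    field_X = np.asarray(field_X, float)
    lab_X = np.asarray(lab_X, float)
    _check_paired(field_X, lab_X)
    if w < 0:
        raise ValueError("window half-width must be >= 0")
    n, p = field_X.shape
    m = 2 * w + 1
    a_eff = min(ncomp, m, n - 1)
    if a_eff < ncomp:
        warnings.warn(f"PDS ncomp clipped to {a_eff} (window {m} points, n={n})",
                      stacklevel=2)
    padded = np.concatenate(
        [np.zeros((n, w)), field_X, np.zeros((n, w))], axis=1)
    # windows[i] is the n x m field window for target wavelength i
    windows = np.lib.stride_tricks.sliding_window_view(padded, m, axis=1)
    windows = np.ascontiguousarray(windows.transpose(1, 0, 2))  # (p, n, m)
    x_mean = windows.mean(axis=1)  # (p, m)
    E = windows - x_mean[:, None, :]
    y_mean = lab_X.mean(axis=0)  # (p,)
    f = (lab_X - y_mean).T.copy()  # (p, n)
    tiny = 1e-300
    Ws, Ps, qs = [], [], []
    scale0 = None
    for _ in range(a_eff):
        wv = np.einsum("pnm,pn->pm", E, f)
        nw = np.linalg.norm(wv, axis=1)
        if scale0 is None:
            scale0 = nw.copy() + tiny
        # dead residual for a window -> zero component (per-problem early stop)
        alive = nw > 1e-13 * scale0
        wv = np.where(alive[:, None], wv / (nw[:, None] + tiny), 0.0)
        t = np.einsum("pnm,pm->pn", E, wv)
        tt = (t * t).sum(axis=1) + tiny
        pl = np.einsum("pnm,pn->pm", E, t) / tt[:, None]
        q = (f * t).sum(axis=1) / tt
        E = E - t[:, :, None] * pl[:, None, :]
        Ws.append(wv)
        Ps.append(pl)
        qs.append(q)
    W = np.stack(Ws, axis=2)  # (p, m, a)
    P = np.stack(Ps, axis=2)
    q = np.stack(qs, axis=1)  # (p, a)
    PtW = np.einsum("pma,pmb->pab", P, W)
    beta = np.einsum("pma,pa->pm", W @ np.linalg.pinv(PtW), q)  # (p, m)
    F = np.zeros((p, p))
    intercept = y_mean - np.einsum("pm,pm->p", x_mean, beta)
    for i in range(p):
        lo, hi = max(0, i - w), min(p, i + w + 1)
        F[lo:hi, i] = beta[i, (lo - (i - w)):(hi - (i - w))]
    return TransferModel(kind="PDS", F=F, intercept=intercept, window=w, ncomp=ncomp)


def fit_epo(field_X: np.ndarray, lab_X: np.ndarray, c: int) -> TransferModel:
    """External parameter orthogonalization with ``c`` components.

    D = lab - field is column-centered; V holds its first c right singular
    vectors; P = I - V V^T is symmetric, idempotent, rank p - c.
    """
    field_X = np.asarray(field_X, float)
    lab_X = np.asarray(lab_X, float)
    _check_paired(field_X, lab_X)
    if c < 1:
        raise ValueError("EPO needs at least 1 component")
    D = lab_X - field_X
    D = D - D.mean(axis=0)
    _, sv, Vt = np.linalg.svd(D, full_matrices=False)
    rank = int((sv > sv[0] * 1e-12).sum()) if sv.size and sv[0] > 0 else 0
    if rank == 0:  # identical domains: nothing to project out
        p = field_X.shape[1]
        return TransferModel(kind="EPO", V=np.zeros((p, 0)), n_components=0)
    if c > rank:
        warnings.warn(f"EPO components truncated from {c} to rank {rank}",
                      stacklevel=2)
        c = rank
    V = Vt[:c].T
    return TransferModel(kind="EPO", V=V, n_components=c)


def apply_transfer(m: TransferModel, X: np.ndarray) -> np.ndarray:
    """Correct spectra (rows) with a fitted transfer model."""
    X = np.atleast_2d(np.asarray(X, float))
    if m.kind == "LT":
        return m.intercept + m.slope * X
    if m.kind == "PDS":
        return X @ m.F + m.intercept
    if m.kind == "EPO":  # X (I - V V^T) without forming the dense projection
        return X - (X @ m.V) @ m.V.T
    raise ValueError(f"unknown transfer kind {m.kind!r}")


def correct_spectrum_set(m: TransferModel, s: SpectrumSet) -> SpectrumSet:
    return SpectrumSet(s.wavelengths.copy(), apply_transfer(m, s.reflectance),
                       s.meta.copy())


# ---------------------------------------------------------------------------
# tuning inside the nested CV
# ---------------------------------------------------------------------------

class TransferPLSREstimator:
    """Joint grid over (transfer parameters, PLSR components).

    The pipeline per grid point: fit the transfer model on the training
    samples' paired lab/field averages, correct the field spectra, and fit
    a PLSR on the corrected field training data (for EPO, the lab target
    is irrelevant at prediction time; the corrected-field model is what is
    evaluated).  Grid points are ordered simplest-first so RMSE ties pick
    the most parsimonious setting.
    """

    def __init__(self, field_X, lab_X, y, method: str,
                 transfer_grid=None, ncomp_grid=None):
        self.field_X = np.asarray(field_X, float)
        self.lab_X = np.asarray(lab_X, float)
        self.y = np.asarray(y, float).ravel()
        _check_paired(self.field_X, self.lab_X)
        self.method = method
        if ncomp_grid is None:
            ncomp_grid = list(range(1, 21))
        self.ncomp_grid = list(ncomp_grid)
        if transfer_grid is None:
            if method == "LT":
                transfer_grid = [()]
            elif method == "PDS":
                transfer_grid = [(nc, w) for nc in range(1, 11) for w in range(1, 21)]
            elif method == "EPO":
                transfer_grid = [(c,) for c in range(1, 11)]
            else:
                raise ValueError(f"unknown transfer method {method!r}")
        self.transfer_grid = list(transfer_grid)
        if not self.transfer_grid or not self.ncomp_grid:
            raise ValueError("empty tuning grid")
        self.grid = [(tp, a) for tp in self.transfer_grid for a in self.ncomp_grid]
        self.grid.sort(key=lambda g: (g[0], g[1]))

    # -- internals ----------------------------------------------------------
    def _fit_transfer(self, train_idx, tp) -> TransferModel:
        Xf, Xl = self.field_X[train_idx], self.lab_X[train_idx]
        if self.method == "LT":
            return fit_lt(Xf, Xl)
        if self.method == "PDS":
            nc, w = tp
            return fit_pds(Xf, Xl, w=w, ncomp=nc)
        nc, = tp
        return fit_epo(Xf, Xl, nc)

    def _cap(self, train_idx) -> int:
        return max(1, min(max(self.ncomp_grid), len(train_idx) - 1,
                          self.field_X.shape[1]))

    def fit(self, train_idx, grid_point):
        tp, a = grid_point
        tm = self._fit_transfer(train_idx, tp)
        Xc = apply_transfer(tm, self.field_X[train_idx])
        pls = fit_plsr(Xc, self.y[train_idx], min(a, self._cap(train_idx)))
        return (tm, pls)

    def predict(self, model, idx, grid_point=None) -> np.ndarray:
        tm, pls = model
        Xc = apply_transfer(tm, self.field_X[idx])
        ncomp = None if grid_point is None else min(grid_point[1], pls.A)
        return predict(pls, Xc, ncomp)

    def eval_grid(self, train_idx, test_idx) -> dict:
        out = {}
        cap = self._cap(train_idx)
        epo_Vt = None
        if self.method == "EPO":  # one SVD serves every component count
            D = self.lab_X[train_idx] - self.field_X[train_idx]
            D = D - D.mean(axis=0)
            _, sv, epo_Vt = np.linalg.svd(D, full_matrices=False)
            epo_rank = int((sv > sv[0] * 1e-12).sum()) if sv.size and sv[0] > 0 else 0
        for tp in self.transfer_grid:
            if epo_Vt is not None:
                c = min(tp[0], epo_rank) if epo_rank else 0
                tm = TransferModel(kind="EPO", V=epo_Vt[:c].T.copy(),
                                   n_components=c)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tm = self._fit_transfer(train_idx, tp)
            Xc_tr = apply_transfer(tm, self.field_X[train_idx])
            Xc_te = apply_transfer(tm, self.field_X[test_idx])
            pls = fit_plsr(Xc_tr, self.y[train_idx], cap)
            for a in self.ncomp_grid:
                yhat = predict(pls, Xc_te, min(a, pls.A))
                out[(tp, a)] = float(np.sqrt(np.mean((self.y[test_idx] - yhat) ** 2)))
        return out


def tune_transfer(
    field_X: np.ndarray,
    lab_X: np.ndarray,
    samples: SampleTable,
    method: str,
    scheme: CVScheme,
    transfer_grid=None,
    ncomp_grid=None,
) -> tuple:
    """Nested-CV tuning + evaluation of one correction method.

    Returns (NestedCVResult, parameter report).  The report lists the
    per-outer-fold selected parameters and their mode, mirroring an
    optimal-parameter table.
    """
    est = TransferPLSREstimator(field_X, lab_X, samples.soc, method,
                                transfer_grid, ncomp_grid)
    res = nested_cv(samples, est, scheme)
    sel = res.selected_params()
    mode = sel["selected"].mode().iloc[0]
    report = {"method": method, "per_fold": sel.to_dict(orient="records"),
              "mode": mode}
    return res, report
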