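"""Partial least squares regression (PLS1) via NIPALS, from scratch.

The model exposes everything the wavelength-importance analysis needs:
per-component weight vectors w_a (unit norm), x-loadings p_a, scores t_a,
y-loadings q_a, the per-component explained sum of squares of the response
SS_a = q_a^2 * ||t_a||^2, and regression coefficients

    beta_A = W_A (P_A^T W_A)^{-1} q_A

on the centered, unscaled reflectance scale, for every component count
A' <= A from a single fit.  Variables are mean-centered but not scaled to
unit variance, the standard convention for spectral data, and the one
under which the VIP normalization sum_j VIP_j^2 = p holds:

    VIP_j = sqrt( p * sum_a SS_a (w_aj / ||w_a||)^2 / sum_a SS_a ).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PLSRModel", "fit_plsr", "predict", "vip", "regression_coefficients"]


@dataclass
class PLSRModel:
    A: int
    x_mean: np.ndarray  # (p,)
    y_mean: float
    W: np.ndarray  # (p, A) unit-norm weight vectors
    P: np.ndarray  # (p, A) x-loadings
    T: np.ndarray  # (n, A) scores
    q: np.ndarray  # (A,) y-loadings
    SS: np.ndarray  # (A,) explained sum of squares of y per component
    beta: np.ndarray  # (p,) coefficients at A components
    wavelengths: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.x_mean.size

    def coefficients(self, ncomp: int | None = None) -> np.ndarray:
        """beta using the first ``ncomp`` components (default: all)."""
        a = self.A if ncomp is None else int(ncomp)
        if not 1 <= a <= self.A:
            raise ValueError(f"ncomp must be in 1..{self.A}")
        if a == self.A:
            return self.beta
        R = self.W[:, :a] @ np.linalg.inv(self.P[:, :a].T @ self.W[:, :a])
        return R @ self.q[:a]

    def to_json(self, path) -> None:
        obj = {
            "A": self.A, "y_mean": self.y_mean,
            "x_mean": self.x_mean.tolist(), "W": self.W.tolist(),
            "P": self.P.tolist(), "T": self.T.tolist(),
            "q": self.q.tolist(), "SS": self.SS.tolist(),
            "beta": self.beta.tolist(),
            "wavelengths": None if self.wavelengths is None else self.wavelengths.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path) -> "PLSRModel":
        o = json.loads(Path(path).read_text())
        return cls(
            A=o["A"], x_mean=np.array(o["x_mean"]), y_mean=o["y_mean"],
            W=np.array(o["W"]), P=np.array(o["P"]), T=np.array(o["T"]),
            q=np.array(o["q"]), SS=np.array(o["SS"]), beta=np.array(o["beta"]),
            wavelengths=None if o["wavelengths"] is None else np.array(o["wavelengths"]),
        )


def fit_plsr(X: np.ndarray, y: np.ndarray, A: int,
             wavelengths: np.ndarray | None = None) -> PLSRModel:
    """Fit PLS1 with ``A`` components by sequential NIPALS extraction.

    X is deflated per component; y is not (equivalent for a single
    response).  If the residual X becomes (numerically) zero before A
    components are extracted, the model is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite entries in X or y")
    if np.var(y) == 0:
        raise ValueError("zero-variance response")
    A_req = int(A)
    if A_req < 1:
        raise ValueError("A must be >= 1")
    A_cap = min(A_req, n - 1, p)
    if A_cap < A_req:
        warnings.warn(f"A={A_req} exceeds min(n-1, p)={A_cap}; truncating",
                      stacklevel=2)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    x_scale = float(np.abs(E).max()) or 1.0

    Ws, Ps, Ts, qs, SSs = [], [], [], [], []
    for _ in range(A_cap):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * x_scale * np.linalg.norm(f):
            warnings.warn("residual covariance vanished; truncating components",
                          stacklevel=2)
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        pl = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pl)
        Ws.append(w)
        Ps.append(pl)
        Ts.append(t)
        qs.append(qa)
        SSs.append(qa**2 * tt)
    if not Ws:
        raise ValueError("no PLS component could be extracted")
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    T = np.column_stack(Ts)
    q = np.array(qs)
    SS = np.array(SSs)
    beta = W @ np.linalg.inv(P.T @ W) @ q
    return PLSRModel(A=len(qs), x_mean=x_mean, y_mean=y_mean, W=W, P=P, T=T,
                     q=q, SS=SS, beta=beta,
                     wavelengths=None if wavelengths is None else np.asarray(wavelengths))


def predict(m: PLSRModel, X: np.ndarray, ncomp: int | None = None) -> np.ndarray:
    """y_hat = y_mean + (X - x_mean) @ beta."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.p:
        raise ValueError(f"X has {X.shape[1]} wavelengths, model expects {m.p}")
    return m.y_mean + (X - m.x_mean) @ m.coefficients(ncomp)


def vip(m: PLSRModel, ncomp: int | None = None) -> np.ndarray:
    """Variable importance in projection per wavelength.

    Weighted sum of squared normalized weights, the weights being the
    explained response sum of squares per component; satisfies
    sum_j VIP_j^2 = p.
    """
    a = m.A if ncomp is None else int(ncomp)
    SS = m.SS[:a]
    tot = SS.sum()
    if tot <= 0:
        raise ValueError("total explained sum of squares is zero")
    Wn = m.W[:, :a] / np.linalg.norm(m.W[:, :a], axis=0)
    return np.sqrt(m.p * (Wn**2 @ SS) / tot)


def regression_coefficients(m: PLSRModel, ncomp: int | None = None) -> np.ndarray:
    """Per-wavelength regression coefficients on the centered data scale."""
    return m.coefficients(ncomp)
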