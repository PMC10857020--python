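"""Stratified, spatially-grouped nested cross-validation.

Samples closer than a minimum separation (default 8 m) are merged into
indivisible groups (single-linkage connected components), so spatially
correlated neighbours never straddle a train/test split.  Groups are
stratified on SOC: sorted by group-mean SOC and dealt into folds in
consecutive blocks with a seeded random permutation per block, which keeps
fold SOC means close while letting repetitions differ.

The outer loop (default 5 folds x 5 repetitions = 25 models per dataset)
evaluates; the inner loop (default 5 folds) tunes a hyperparameter grid by
mean inner RMSE, ties going to the simplest (first-listed) grid point.
Fold subdivisions are a function of (seed, sample table) only, so every
dataset variant of one scene shares identical splits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .io import SampleTable
from .plsr import fit_plsr, predict

__all__ = [
    "CVScheme", "build_spatial_groups", "assign_folds", "nested_cv",
    "NestedCVResult", "PLSREstimator",
]


@dataclass(frozen=True)
class CVScheme:
    k_outer: int = 5
    k_inner: int = 5
    repetitions: int = 5
    min_separation: float = 8.0  # m
    seed: int = 0


def build_spatial_groups(samples: SampleTable, min_separation: float = 8.0) -> np.ndarray:
    """Group label per sample: single-linkage components of the <=8 m graph."""
    coords = samples.coords
    if not np.isfinite(coords).all():
        raise ValueError("sample coordinates required for spatial grouping")
    n = coords.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    adj = squareform(pdist(coords)) <= min_separation
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def assign_folds(groups: np.ndarray, soc: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold label per sample; groups are indivisible and SOC-stratified.

    Groups are ordered by group-mean SOC and dealt into folds in
    consecutive blocks of k, each block permuted by the seeded RNG.
    """
    groups = np.asarray(groups)
    soc = np.asarray(soc, dtype=float)
    uniq = np.unique(groups)
    if uniq.size < k:
        raise ValueError(f"only {uniq.size} spatial groups for {k} folds")
    gmean = np.array([soc[groups == g].mean() for g in uniq])
    order = uniq[np.argsort(gmean, kind="stable")]
    rng = np.random.Generator(np.random.PCG64(seed))
    fold_of_group = {}
    for start in range(0, order.size, k):
        block = order[start:start + k]
        perm = rng.permutation(k)[:block.size]
        for g, f in zip(block, perm):
            fold_of_group[g] = int(f)
    return np.array([fold_of_group[g] for g in groups])


def _fold_seed(master: int, *key: int) -> int:
    """Deterministic sub-seed below 2^31 from the master seed and a key."""
    h = hashlib.sha256(("cv:" + ":".join(str(x) for x in (master, *key))).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


class PLSREstimator:
    """Grid estimator over the PLSR component count.

    The grid is evaluated from a single fit at the largest feasible
    component count (the coefficient path of a NIPALS fit nests all
    smaller counts).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, a_max: int = 20):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        self.a_max = int(a_max)
        self.grid = list(range(1, self.a_max + 1))

    def _cap(self, train_idx) -> int:
        return max(1, min(self.a_max, len(train_idx) - 1, self.X.shape[1]))

    def fit(self, train_idx, grid_point):
        a = min(int(grid_point), self._cap(train_idx))
        return fit_plsr(self.X[train_idx], self.y[train_idx], a)

    def predict(self, model, idx, grid_point=None) -> np.ndarray:
        ncomp = None if grid_point is None else min(int(grid_point), model.A)
        return predict(model, self.X[idx], ncomp)

    def eval_grid(self, train_idx, test_idx) -> dict:
        cap = self._cap(train_idx)
        m = fit_plsr(self.X[train_idx], self.y[train_idx], cap)
        out = {}
        for a in self.grid:
            yhat = predict(m, self.X[test_idx], min(a, m.A))
            out[a] = float(np.sqrt(np.mean((self.y[test_idx] - yhat) ** 2)))
        return out


@dataclass
class NestedCVResult:
    rows: pd.DataFrame  # repetition, fold, sample_id, observed, predicted, selected
    models: list  # (repetition, fold, grid_point, model)
    fold_labels: pd.DataFrame  # repetition x sample fold assignment
    scheme: CVScheme

    def fold_hash(self) -> str:
        """Hash of all fold labels; equal across variants sharing splits."""
        payload = self.fold_labels.to_csv(index=False).encode()
        return hashlib.sha256(payload).hexdigest()

    def selected_params(self) -> pd.DataFrame:
        return self.rows.drop_duplicates(["repetition", "fold"])[
            ["repetition", "fold", "selected"]].reset_index(drop=True)


def nested_cv(samples: SampleTable, estimator, scheme: CVScheme) -> NestedCVResult:
    """Run the nested scheme; returns held-out predictions and all models.

    ``estimator`` provides ``grid`` (ordered simplest-first), ``fit``,
    ``predict`` and ``eval_grid`` (see :class:`PLSREstimator`).
    """
    soc = samples.soc
    groups = build_spatial_groups(samples, scheme.min_separation)
    rows, models, fold_records = [], [], []
    for rep in range(scheme.repetitions):
        outer = assign_folds(groups, soc, scheme.k_outer, _fold_seed(scheme.seed, rep))
        fold_records.append(pd.DataFrame({
            "repetition": rep, "sample_id": samples.sample_ids, "fold": outer}))
        for f in range(scheme.k_outer):
            test_idx = np.flatnonzero(outer == f)
            train_idx = np.flatnonzero(outer != f)
            # inner tuning on the outer-training set
            inner = assign_folds(groups[train_idx], soc[train_idx], scheme.k_inner,
                                 _fold_seed(scheme.seed, rep, f))
            rmse_sum = {gp: 0.0 for gp in estimator.grid}
            for fi in range(scheme.k_inner):
                i_test = train_idx[inner == fi]
                i_train = train_idx[inner != fi]
                if i_test.size < 2 or i_train.size < 2:
                    raise ValueError("inner fold with fewer than 2 samples")
                for gp, rmse in estimator.eval_grid(i_train, i_test).items():
                    rmse_sum[gp] += rmse
            best = min(estimator.grid, key=lambda gp: rmse_sum[gp])  # ties: first listed
            model = estimator.fit(train_idx, best)
            yhat = estimator.predict(model, test_idx, best)
            models.append((rep, f, best, model))
            for j, idx in enumerate(test_idx):
                rows.append({
                    "repetition": rep, "fold": f,
                    "sample_id": samples.sample_ids[idx],
                    "observed": soc[idx], "predicted": float(yhat[j]),
                    "selected": str(best),
                })
    return NestedCVResult(
        rows=pd.DataFrame(rows), models=models,
        fold_labels=pd.concat(fold_records, ignore_index=True), scheme=scheme,
    )
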