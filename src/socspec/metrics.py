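"""Model-performance metrics on held-out predictions.

RMSE (g kg^-1), R^2 as 1 - SSE/SST about the observed mean (so negative
values are possible on held-out data), RPD = SD(observed, n-1)/RMSE, and
Lin's concordance correlation coefficient with n-denominator moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetricsReport", "compute_metrics", "summarize_cv"]


@dataclass
class MetricsReport:
    rmse: float
    r2: float
    rpd: float
    ccc: float
    n: int
    rpd_undefined: bool = False

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "r2": self.r2, "rpd": self.rpd,
                "ccc": self.ccc, "n": self.n}


def compute_metrics(observed, predicted) -> MetricsReport:
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size:
        raise ValueError("observed and predicted lengths differ")
    if o.size < 2:
        raise ValueError("need at least 2 observations")
    sst = float(((o - o.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("zero variance in observed values")
    n = o.size
    rmse = float(np.sqrt(np.mean((o - p) ** 2)))
    r2 = 1.0 - float(((o - p) ** 2).sum()) / sst
    sd_obs = float(np.std(o, ddof=1))
    rpd_undefined = rmse == 0.0
    rpd = np.inf if rpd_undefined else sd_obs / rmse
    # Lin's CCC with population (n-denominator) moments
    cov = float(np.mean((o - o.mean()) * (p - p.mean())))
    var_o = float(np.var(o))
    var_p = float(np.var(p))
    ccc = 2 * cov / (var_o + var_p + (o.mean() - p.mean()) ** 2)
    return MetricsReport(rmse=rmse, r2=r2, rpd=float(rpd), ccc=float(ccc),
                         n=n, rpd_undefined=rpd_undefined)


def summarize_cv(rows: pd.DataFrame, n_repetitions: int = 5) -> pd.DataFrame:
    """Per-repetition pooled metrics over outer-fold held-out predictions.

    ``rows`` must have columns repetition, observed, predicted.  Returns
    one row per repetition (so 5 values per metric at the default scheme),
    which is what performance boxplots and medians are taken over.
    """
    needed = {"repetition", "observed", "predicted"}
    if not needed.issubset(rows.columns):
        raise ValueError(f"CV rows must have columns {sorted(needed)}")
    reps = sorted(rows["repetition"].unique())
    if len(reps) != n_repetitions:
        raise ValueError(f"expected {n_repetitions} repetitions, found {len(reps)}")
    out = []
    for rep in reps:
        sub = rows[rows["repetition"] == rep]
        rec = compute_metrics(sub["observed"], sub["predicted"]).as_dict()
        rec["repetition"] = rep
        out.append(rec)
    return pd.DataFrame(out)[["repetition", "rmse", "r2", "rpd", "ccc", "n"]]


def median_summary(per_rep: pd.DataFrame) -> dict:
    """Median and IQR over the per-repetition metric values."""
    out = {}
    for m in ("rmse", "r2", "rpd", "ccc"):
        v = per_rep[m].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[m] = {"median": float(med), "iqr": float(q3 - q1)}
    return out
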