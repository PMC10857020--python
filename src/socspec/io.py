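"""Spectral containers and tabular I/O.

Two containers travel through the whole pipeline:

``SpectrumSet``
    A wavelength grid (strictly increasing, nm) plus a matrix of spectra
    (rows) and a per-spectrum metadata table (sample id, device, condition,
    replicate id, planar coordinates in m).

``SampleTable``
    Per-location soil organic carbon (SOC, g kg^-1) and planar coordinates.

On-disk formats are plain text only: a *wide* CSV (one row per spectrum,
one column per wavelength, header in nm) and a *long* CSV
(id, x_m, y_m, wavelength_nm, reflectance).  Floats are serialized with
9 significant digits, which is below sensor noise but above round-trip
error, so write -> read is lossless for practical purposes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ["sample_id", "device", "condition", "replicate_id", "x_m", "y_m"]

_FLOAT_FMT = "%.9g"


class SpectraFormatError(ValueError):
    """Raised when an on-disk spectra file violates the format contract."""


@dataclass
class SpectrumSet:
    """A set of spectra sharing one wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm, shape (p,).
    reflectance
        Matrix of shape (n_spectra, p).  Raw reflectance lies in [0, 1];
        derivative/continuum-removed data may leave that range.
    meta
        DataFrame with one row per spectrum and at least the columns in
        ``META_COLUMNS``.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.meta is None:
            self.meta = pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(self.reflectance.shape[0])],
                    "device": "unknown",
                    "condition": "unknown",
                    "replicate_id": np.arange(self.reflectance.shape[0]),
                    "x_m": np.nan,
                    "y_m": np.nan,
                }
            )
        self.meta = self.meta.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        w = self.wavelengths
        if w.ndim != 1:
            raise SpectraFormatError("wavelength grid must be one-dimensional")
        if w.size >= 2 and not np.all(np.diff(w) > 0):
            raise SpectraFormatError("wavelengths must be strictly increasing")
        if self.reflectance.shape[1] != w.size:
            raise SpectraFormatError(
                f"reflectance has {self.reflectance.shape[1]} columns "
                f"but grid has {w.size} wavelengths"
            )
        if len(self.meta) != self.reflectance.shape[0]:
            raise SpectraFormatError("metadata row count != spectra row count")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SpectraFormatError(f"metadata missing columns: {missing}")
        key = self.meta[["sample_id", "device", "condition", "replicate_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].to_dict()
            raise SpectraFormatError(f"duplicate spectrum key: {dup}")

    # -- conveniences -------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.wavelengths.copy(), self.reflectance.copy(), self.meta.copy()
        )

    def subset(self, row_mask_or_idx) -> "SpectrumSet":
        idx = np.asarray(row_mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectrumSet(
            self.wavelengths.copy(),
            self.reflectance[idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )

    def select_wavelengths(self, col_mask) -> "SpectrumSet":
        col_mask = np.asarray(col_mask)
        return SpectrumSet(
            self.wavelengths[col_mask], self.reflectance[:, col_mask], self.meta.copy()
        )

    def nonfinite_rows(self) -> np.ndarray:
        """Indices of spectra containing any non-finite reflectance."""
        return np.flatnonzero(~np.isfinite(self.reflectance).all(axis=1))


@dataclass
class SampleTable:
    """Per-location reference data: SOC (g kg^-1) and planar coordinates (m)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for c in ("sample_id", "soc", "x_m", "y_m"):
            if c not in t.columns:
                raise ValueError(f"sample table missing column {c!r}")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample table")
        if not (t["soc"] > 0).all():
            raise ValueError("SOC must be strictly positive (g kg^-1)")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy()

    @property
    def soc(self) -> np.ndarray:
        return self.table["soc"].to_numpy(dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x_m", "y_m"]].to_numpy(dtype=float)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format=_FLOAT_FMT)

    @classmethod
    def read_csv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_spectra(s: SpectrumSet, path, dialect: str = "wide") -> None:
    """Write a SpectrumSet to CSV; metadata goes to a JSON sidecar (wide) or
    inline columns (long)."""
    path = Path(path)
    if dialect == "wide":
        df = pd.DataFrame(s.reflectance, columns=[_FLOAT_FMT % w for w in s.wavelengths])
        df.insert(0, "spectrum_id", _spectrum_ids(s.meta))
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        s.meta.assign(spectrum_id=_spectrum_ids(s.meta)).to_json(
            path.with_suffix(".meta.json"), orient="records", indent=1
        )
    elif dialect == "long":
        n, p = s.reflectance.shape
        long = pd.DataFrame(
            {
                "spectrum_id": np.repeat(_spectrum_ids(s.meta), p),
                "sample_id": np.repeat(s.meta["sample_id"].to_numpy(), p),
                "device": np.repeat(s.meta["device"].to_numpy(), p),
                "condition": np.repeat(s.meta["condition"].to_numpy(), p),
                "replicate_id": np.repeat(s.meta["replicate_id"].to_numpy(), p),
                "x_m": np.repeat(s.meta["x_m"].to_numpy(), p),
                "y_m": np.repeat(s.meta["y_m"].to_numpy(), p),
                "wavelength_nm": np.tile(s.wavelengths, n),
                "reflectance": s.reflectance.ravel(),
            }
        )
        long.to_csv(path, index=False, float_format=_FLOAT_FMT)
    else:
        raise SpectraFormatError(f"unknown dialect {dialect!r}")


def _spectrum_ids(meta: pd.DataFrame) -> np.ndarray:
    return (
        meta["sample_id"].astype(str)
        + "|" + meta["device"].astype(str)
        + "|" + meta["condition"].astype(str)
        + "|" + meta["replicate_id"].astype(str)
    ).to_numpy()


def read_spectra(path, dialect: str = "wide") -> SpectrumSet:
    """Read a SpectrumSet written by :func:`write_spectra`.

    The wavelength header must parse as numeric nm and be free of
    duplicates; rows are sorted into a canonical order for the long
    dialect so shuffled input yields an identical set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "wide":
        # parse the header from the raw line: pandas mangles duplicates
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")
        try:
            wl = np.array([float(c) for c in header[1:]])
        except ValueError as e:
            raise SpectraFormatError(f"non-numeric wavelength header: {e}") from e
        df = pd.read_csv(path)
        if np.unique(wl).size != wl.size:
            raise SpectraFormatError("duplicated wavelength in header")
        order = np.argsort(wl)
        refl = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
        wl = wl[order]
        if not np.all(np.diff(wl) > 0):
            raise SpectraFormatError("non-monotone wavelength header")
        meta_path = path.with_suffix(".meta.json")
        if meta_path.exists():
            meta = pd.read_json(meta_path, orient="records")
            meta = meta.set_index("spectrum_id").loc[df.iloc[:, 0]].reset_index(drop=True)
            meta = meta[META_COLUMNS]
        else:
            meta = _meta_from_ids(df.iloc[:, 0].to_numpy())
        return SpectrumSet(wl, refl, meta)
    if dialect == "long":
        df = pd.read_csv(path)
        required = {"spectrum_id", "wavelength_nm", "reflectance"}
        if not required.issubset(df.columns):
            raise SpectraFormatError(f"long CSV must have columns {sorted(required)}")
        wl = np.sort(df["wavelength_nm"].unique().astype(float))
        piv = df.pivot_table(
            index="spectrum_id", columns="wavelength_nm", values="reflectance",
            aggfunc="first", sort=True,
        )
        counts = df.groupby("spectrum_id")["wavelength_nm"].count()
        if counts.nunique() != 1 or counts.iloc[0] != wl.size:
            raise SpectraFormatError("ragged long CSV: unequal wavelengths per spectrum")
        meta_cols = [c for c in META_COLUMNS if c in df.columns]
        meta = (
            df.drop_duplicates("spectrum_id").set_index("spectrum_id")[meta_cols]
            if meta_cols
            else None
        )
        piv = piv.sort_index()
        if meta is not None:
            meta = meta.loc[piv.index].reset_index(drop=True)
        else:
            meta = _meta_from_ids(piv.index.to_numpy())
        return SpectrumSet(piv.columns.to_numpy(dtype=float), piv.to_numpy(), meta)
    raise SpectraFormatError(f"unknown dialect {dialect!r}")


def _meta_from_ids(ids: np.ndarray) -> pd.DataFrame:
    rows = []
    for sid in ids:
        parts = str(sid).split("|")
        if len(parts) == 4:
            rows.append(dict(zip(["sample_id", "device", "condition", "replicate_id"], parts)))
        else:
            rows.append({"sample_id": str(sid), "device": "unknown",
                         "condition": "unknown", "replicate_id": 0})
    meta = pd.DataFrame(rows)
    meta["x_m"] = np.nan
    meta["y_m"] = np.nan
    return meta


# ---------------------------------------------------------------------------
# replicate averaging and stream selection
# ---------------------------------------------------------------------------

def average_replicates(s: SpectrumSet) -> SpectrumSet:
    """Arithmetic mean over replicates per (sample, device, condition).

    Returns one spectrum per group; ``n_replicates`` in the output metadata
    records how many spectra contributed.  A group with zero spectra cannot
    occur by construction; an all-NaN spectrum raises.
    """
    groups = s.meta.groupby(["sample_id", "device", "condition"], sort=True)
    rows, meta_rows = [], []
    for (sid, dev, cond), idx in groups.indices.items():
        block = s.reflectance[idx]
        if block.shape[0] == 0:
            raise ValueError(f"no surviving replicates for sample {sid!r}")
        rows.append(block.mean(axis=0))
        sub = s.meta.iloc[idx]
        meta_rows.append(
            {
                "sample_id": sid, "device": dev, "condition": cond,
                "replicate_id": 0,
                "x_m": sub["x_m"].mean(), "y_m": sub["y_m"].mean(),
                "n_replicates": len(idx),
            }
        )
    return SpectrumSet(s.wavelengths.copy(), np.vstack(rows), pd.DataFrame(meta_rows))


def select_nearest_stream(
    stream: SpectrumSet,
    samples: SampleTable,
    k: int = 10,
    max_radius_m: float | None = 3.0,
) -> SpectrumSet:
    """Pick the k stream spectra nearest (planar Euclidean) to each sample.

    Mirrors the on-the-go workflow: the sensor records a georeferenced
    stream, and each sampling location is represented by its k nearest
    records.  Ties are broken by stream record order (stable sort).  If a
    radius is given, only records within it are candidates; when fewer than
    k remain, all are used and a warning is issued (recorded in metadata as
    a smaller ``n_replicates`` downstream).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = stream.meta[["x_m", "y_m"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("stream spectra must carry planar coordinates")
    out_idx, out_meta = [], []
    for _, srow in samples.table.iterrows():
        d = np.hypot(coords[:, 0] - srow["x_m"], coords[:, 1] - srow["y_m"])
        cand = np.arange(len(d)) if max_radius_m is None else np.flatnonzero(d <= max_radius_m)
        if cand.size == 0:
            raise ValueError(f"no stream spectra within radius of sample {srow['sample_id']!r}")
        take = cand[np.argsort(d[cand], kind="stable")][:k]
        if take.size < k:
            warnings.warn(
                f"sample {srow['sample_id']!r}: only {take.size} stream spectra "
                f"available (requested {k})", stacklevel=2,
            )
        for j, t in enumerate(take):
            m = stream.meta.iloc[t].to_dict()
            m.update(sample_id=srow["sample_id"], replicate_id=j)
            out_idx.append(t)
            out_meta.append(m)
    return SpectrumSet(
        stream.wavelengths.copy(),
        stream.reflectance[np.array(out_idx)],
        pd.DataFrame(out_meta)[list(stream.meta.columns)],
    )


def write_truth(truth: dict, path) -> None:
    """JSON sidecar for synthetic ground truth (arrays become lists)."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(truth, indent=1, default=default))
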