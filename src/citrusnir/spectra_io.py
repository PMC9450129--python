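"""Containers and I/O for NIR spectra, reference values and fitted artifacts.

The on-disk dialect is a wide CSV: metadata columns first
(``spectrum_id, fruit_id, population_id, replicate_index, variety``),
then one column per wavelength, named by its nm value.  Absorbance is
stored as read; no unit conversion is ever applied implicitly.
Models and preprocessing states persist as JSON with a format-version
field so an incompatible file fails loudly instead of mis-loading.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    GridError,
    JoinError,
    SerializationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

META_COLUMNS = ["spectrum_id", "fruit_id", "population_id", "replicate_index", "variety"]

FORMAT_VERSION = 1

_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered, uniformly spaced wavelength axis in nm.

    The portable-instrument default spans 650-950 nm at 2 nm spacing,
    giving exactly 151 points; other uniform grids are accepted.
    """

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise GridError("wavelength grid needs at least two points")
        steps = np.diff(vals)
        if np.any(steps <= 0):
            raise GridError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=_GRID_RTOL * max(1.0, abs(steps[0]))):
            raise GridError(
                f"non-uniform wavelength spacing: min step {steps.min():g}, max {steps.max():g}"
            )

    @classmethod
    def default(cls) -> "WavelengthGrid":
        return cls(np.arange(650.0, 950.0 + 1e-9, 2.0))

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid point equal to ``wavelength_nm`` (exact within 1e-6)."""
        idx = int(np.argmin(np.abs(self.values - wavelength_nm)))
        if abs(self.values[idx] - wavelength_nm) > 1e-6:
            raise GridError(f"{wavelength_nm} nm is not on the grid")
        return idx

    def __eq__(self, other) -> bool:  # noqa: D105
        return isinstance(other, WavelengthGrid) and np.array_equal(self.values, other.values)


@dataclass
class SpectraSet:
    """Absorbance matrix on a shared grid plus per-spectrum metadata."""

    grid: WavelengthGrid
    absorbance: np.ndarray  # (n_spectra, n_wavelengths)
    meta: pd.DataFrame  # columns META_COLUMNS

    def __post_init__(self):
        A = np.asarray(self.absorbance, dtype=float)
        if A.ndim != 2:
            A = A.reshape(-1, len(self.grid))
        self.absorbance = A
        if A.shape[1] != len(self.grid):
            raise ValidationError(
                f"absorbance has {A.shape[1]} columns, grid has {len(self.grid)} points"
            )
        self.meta = self.meta.reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if len(self.meta) != A.shape[0]:
            raise ValidationError(
                f"{A.shape[0]} spectra but {len(self.meta)} metadata rows"
            )
        if not np.all(np.isfinite(A)):
            bad = self.meta.loc[~np.isfinite(A).all(axis=1), "spectrum_id"].tolist()
            raise ValidationError(f"non-finite absorbance in spectra: {bad}")
        if self.meta["spectrum_id"].duplicated().any():
            dup = self.meta.loc[self.meta["spectrum_id"].duplicated(), "spectrum_id"].tolist()
            raise ValidationError(f"duplicate spectrum ids: {dup}")

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def spectrum_ids(self) -> pd.Series:
        return self.meta["spectrum_id"]

    def subset(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraSet(self.grid, self.absorbance[idx], self.meta.iloc[idx])

    def by_population(self, populations) -> "SpectraSet":
        pops = {str(p) for p in populations}
        return self.subset(self.meta["population_id"].astype(str).isin(pops).to_numpy())

    def with_absorbance(self, A: np.ndarray, grid: WavelengthGrid | None = None) -> "SpectraSet":
        """Same metadata, new absorbance matrix (optionally a new grid)."""
        return SpectraSet(grid or self.grid, A, self.meta.copy())


@dataclass
class ReferenceTable:
    """Per-spectrum ground truth: SSC in °Brix, TA in g/L (optional)."""

    table: pd.DataFrame  # columns spectrum_id, ssc[, ta]

    def __post_init__(self):
        t = self.table.reset_index(drop=True)
        if "spectrum_id" not in t.columns or "ssc" not in t.columns:
            raise ValidationError("reference table needs spectrum_id and ssc columns")
        if t["spectrum_id"].duplicated().any():
            dup = t.loc[t["spectrum_id"].duplicated(), "spectrum_id"].tolist()
            raise ValidationError(f"duplicate spectrum ids in reference: {dup}")
        present = t["ssc"].notna()
        if (t.loc[present, "ssc"] <= 0).any():
            raise ValidationError("ssc must be > 0 where present")
        if "ta" in t.columns:
            tp = t["ta"].notna()
            if (t.loc[tp, "ta"] < 0).any():
                raise ValidationError("ta must be >= 0 where present")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AnalysisSet:
    """Spectra joined 1:1 with their reference rows, order-stable."""

    spectra: SpectraSet
    reference: ReferenceTable

    def __post_init__(self):
        ids_s = self.spectra.meta["spectrum_id"].to_numpy()
        ids_r = self.reference.table["spectrum_id"].to_numpy()
        if len(ids_s) != len(ids_r) or not (ids_s == ids_r).all():
            raise ValidationError("spectra and reference rows are not aligned 1:1")

    @property
    def X(self) -> np.ndarray:
        return self.spectra.absorbance

    def y(self, attribute: str = "ssc") -> np.ndarray:
        if attribute not in self.reference.table.columns:
            raise ValidationError(f"reference table has no column {attribute!r}")
        return self.reference.table[attribute].to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return self.spectra.n_spectra

    def subset(self, mask) -> "AnalysisSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return AnalysisSet(
            self.spectra.subset(idx),
            ReferenceTable(self.reference.table.iloc[idx]),
        )

    def by_population(self, populations) -> "AnalysisSet":
        pops = {str(p) for p in populations}
        return self.subset(
            self.spectra.meta["population_id"].astype(str).isin(pops).to_numpy()
        )

    def with_absorbance(self, A: np.ndarray, grid=None) -> "AnalysisSet":
        return AnalysisSet(self.spectra.with_absorbance(A, grid), self.reference)


# ---------------------------------------------------------------------------
# spectra CSV I/O


def _parse_wavelength_header(columns) -> WavelengthGrid:
    vals = []
    for c in columns:
        try:
            vals.append(float(c))
        except ValueError as exc:
            raise FormatError(f"wavelength column {c!r} is not numeric") from exc
    return WavelengthGrid(np.array(vals))


def read_spectra(path, fmt: str = "csv") -> SpectraSet:
    """Read a wide-CSV spectra file into a validated :class:`SpectraSet`."""
    if fmt != "csv":
        raise FormatError(f"unsupported format {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"spectrum_id": str, "fruit_id": str,
                                  "population_id": str, "variety": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing metadata columns: {missing}")
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not wl_cols:
        raise FormatError("no wavelength columns found")
    grid = _parse_wavelength_header(wl_cols)
    block = df[wl_cols]
    bad_rows = []
    for i in range(len(block)):
        row = pd.to_numeric(block.iloc[i], errors="coerce")
        if row.isna().any():
            bad_rows.append(df["spectrum_id"].iloc[i])
    if bad_rows:
        raise ValidationError(f"non-numeric or missing absorbance in rows: {bad_rows}")
    A = block.to_numpy(dtype=float)
    meta = df[META_COLUMNS].copy()
    meta["replicate_index"] = meta["replicate_index"].astype(int)
    return SpectraSet(grid, A, meta)


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a :class:`SpectraSet` as wide CSV (round-trips via read_spectra)."""
    path = Path(path)
    wl_names = [format(v, "g") for v in spectra.grid.values]
    block = pd.DataFrame(spectra.absorbance, columns=wl_names)
    out = pd.concat([spectra.meta.reset_index(drop=True), block], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")


def read_reference(path) -> ReferenceTable:
    df = pd.read_csv(path, dtype={"spectrum_id": str})
    return ReferenceTable(df)


def write_reference(ref: ReferenceTable, path) -> None:
    ref.table.to_csv(path, index=False, float_format="%.17g")


def join(spectra: SpectraSet, reference: ReferenceTable, allow_partial: bool = False) -> AnalysisSet:
    """Join spectra with reference rows by spectrum_id, order-stable.

    With ``allow_partial`` the result is the intersection (spectra order
    preserved); otherwise any spectrum lacking a reference row is an error.
    """
    ref = reference.table.set_index("spectrum_id")
    ids = spectra.meta["spectrum_id"]
    have = ids.isin(ref.index).to_numpy()
    if not have.all():
        missing = ids[~have].tolist()
        if not allow_partial:
            raise JoinError(f"spectra without reference rows: {missing}")
        logger.info("join: dropped %d spectra without reference rows", len(missing))
    sub = spectra.subset(have)
    aligned = ref.loc[sub.meta["spectrum_id"]].reset_index()
    return AnalysisSet(sub, ReferenceTable(aligned))


# ---------------------------------------------------------------------------
# model / state serialization


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, WavelengthGrid):
        return {"__grid__": obj.values.tolist()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {"__dataclass__": type(obj).__name__}
        for f in dataclasses.fields(obj):
            d[f.name] = _encode(getattr(obj, f.name))
        return d
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def _decode(obj, registry):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj.get("dtype", "float64"))
        if "__grid__" in obj:
            return WavelengthGrid(np.asarray(obj["__grid__"], dtype=float))
        if "__dataclass__" in obj:
            name = obj["__dataclass__"]
            if name not in registry:
                raise SerializationError(f"unknown serialized type {name!r}")
            cls = registry[name]
            kwargs = {k: _decode(v, registry) for k, v in obj.items() if k != "__dataclass__"}
            return cls(**kwargs)
        return {k: _decode(v, registry) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v, registry) for v in obj]
    return obj


def _registry():
    # late imports: serialization knows every persistable dataclass
    from . import model_update, plsr_core, preprocessing

    classes = [
        plsr_core.PLSRModel,
        preprocessing.PreprocessState,
        preprocessing.SGParams,
        preprocessing.SNVState,
        preprocessing.MSCState,
        preprocessing.VSNState,
        preprocessing.NSRState,
        model_update.UpdateCorrection,
    ]
    return {c.__name__: c for c in classes}


def save_model(obj, path) -> None:
    """Persist a model or preprocessing state as versioned JSON."""
    payload = {"format_version": FORMAT_VERSION, "payload": _encode(obj)}
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    """Load an artifact written by :func:`save_model`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SerializationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise SerializationError(f"{path} is not a citrusnir artifact")
    if payload["format_version"] != FORMAT_VERSION:
        raise SerializationError(
            f"format version {payload['format_version']} not supported "
            f"(expected {FORMAT_VERSION})"
        )
    return _decode(payload["payload"], _registry())
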