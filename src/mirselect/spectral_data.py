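"""Core data model and file I/O for MIR spectra and reference chemistry values.

Spectra are stored as a wide matrix: one row per sample, one column per
wavenumber, with wavenumbers in cm⁻¹ ordered *descending* (the instrument
convention, 4000 → 400 cm⁻¹). All index-based wavelength selections elsewhere
in the package refer to this descending order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "SpectrumSet",
    "ReferenceTable",
    "Dataset",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "read_references",
    "write_references",
    "average_replicates",
    "align",
]

#: significant digits used when writing CSV; chosen so write∘read is lossless
#: to well below any absorbance difference the pipeline can resolve.
CSV_SIGNIFICANT_DIGITS = 12


class SpectraFormatError(ValueError):
    """Raised when a spectra or reference file violates the format contract."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly descending wavenumber axis in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavenumber grid must be 1-D with length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("wavenumber grid contains non-finite values")
        if np.any(values <= 0):
            raise ValueError("wavenumbers must be positive (cm⁻¹)")
        if not np.all(np.diff(values) < 0):
            raise ValueError("wavenumbers must be strictly descending")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        """Mean absolute step between adjacent wavenumbers (cm⁻¹)."""
        return float(np.mean(-np.diff(self.values)))

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        steps = -np.diff(self.values)
        return bool(np.allclose(steps, steps[0], rtol=rtol, atol=0.0))


@dataclass(frozen=True)
class SpectrumSet:
    """n samples × p wavenumbers of absorbance, with unique sample ids."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        A = np.asarray(self.absorbance, dtype=float)
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "absorbance", A)
        object.__setattr__(self, "sample_ids", ids)
        if A.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if A.shape[1] != len(self.grid):
            raise ValueError(
                f"absorbance has {A.shape[1]} columns but grid has {len(self.grid)}"
            )
        if A.shape[0] != len(ids):
            raise ValueError("number of sample ids must match number of rows")
        if len(set(ids)) != len(ids):
            raise SpectraFormatError("sample ids must be unique")
        if not np.all(np.isfinite(A)):
            raise SpectraFormatError("absorbance matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(self, A: np.ndarray) -> "SpectrumSet":
        """Same grid and ids, new absorbance matrix (e.g. after preprocessing)."""
        return SpectrumSet(self.grid, A, self.sample_ids)

    def subset(self, ids: Sequence[str]) -> "SpectrumSet":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return SpectrumSet(self.grid, self.absorbance[rows], tuple(ids))


@dataclass(frozen=True)
class ReferenceTable:
    """Sample id → total polyphenol content (g GAE / 100 g DW)."""

    sample_ids: tuple[str, ...]
    tpc: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        y = np.asarray(self.tpc, dtype=float)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "tpc", y)
        if y.ndim != 1 or y.size != len(ids):
            raise ValueError("tpc must be 1-D and match the id list")
        if len(set(ids)) != len(ids):
            raise SpectraFormatError("reference sample ids must be unique")
        if not np.all(np.isfinite(y)):
            raise SpectraFormatError("reference values contain non-finite entries")
        if np.any(y < 0):
            raise ValueError("TPC values must be non-negative")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids: Sequence[str]) -> "ReferenceTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return ReferenceTable(tuple(ids), self.tpc[rows])


@dataclass(frozen=True)
class Dataset:
    """Row-aligned (X, y) pair: spectra plus their reference TPC values."""

    spectra: SpectrumSet
    references: ReferenceTable
    dropped_spectra_ids: tuple[str, ...] = field(default=())
    dropped_reference_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.spectra.sample_ids != self.references.sample_ids:
            raise ValueError("spectra and references must be aligned on the same ids")

    @property
    def X(self) -> np.ndarray:
        return self.spectra.absorbance

    @property
    def y(self) -> np.ndarray:
        return self.references.tpc

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.spectra.sample_ids

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples

    def subset(self, ids: Sequence[str]) -> "Dataset":
        return Dataset(self.spectra.subset(ids), self.references.subset(ids))

    def with_X(self, A: np.ndarray) -> "Dataset":
        return Dataset(self.spectra.with_absorbance(A), self.references)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a wide spectra CSV: ``sample_id,<wn_1>,<wn_2>,...`` (wn descending).

    Raises
    ------
    SpectraFormatError
        If the header is not strictly descending numeric wavenumbers, ids are
        duplicated, or any cell fails to parse as a finite number.
    """
    df = pd.read_csv(path, header=0, dtype={0: str})
    if df.shape[1] < 3:
        raise SpectraFormatError("spectra file needs an id column and >= 2 wavenumbers")
    try:
        wn = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber in header: {exc}") from exc
    try:
        grid = WavenumberGrid(wn)
    except ValueError as exc:
        raise SpectraFormatError(f"bad wavenumber header: {exc}") from exc
    ids = df.iloc[:, 0].tolist()
    body = df.iloc[:, 1:]
    values = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise SpectraFormatError(
            f"non-numeric or non-finite absorbance at row {r + 1} "
            f"(sample {ids[r]!r}), column {body.columns[c]!r}"
        )
    return SpectrumSet(grid, values, tuple(ids))


def write_spectra(s: SpectrumSet, path: str | Path) -> Path:
    """Write a SpectrumSet as CSV re-readable by :func:`read_spectra`."""
    if s.n_samples == 0:
        raise ValueError("refusing to write a spectra file with no samples")
    path = Path(path)
    header = ["sample_id"] + [_format_number(w) for w in s.grid.values]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for sid, row in zip(s.sample_ids, s.absorbance):
            fh.write(sid + "," + ",".join(_format_number(v) for v in row) + "\n")
    return path


def read_references(path: str | Path) -> ReferenceTable:
    """Read a 2-column reference CSV: ``sample_id,tpc_g_gae_per_100g``."""
    df = pd.read_csv(path, header=0, dtype={0: str})
    if df.shape[1] != 2:
        raise SpectraFormatError("reference file must have exactly 2 columns")
    y = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        row = int(np.argwhere(~np.isfinite(y))[0, 0])
        raise SpectraFormatError(f"non-numeric TPC value at row {row + 1}")
    return ReferenceTable(tuple(df.iloc[:, 0].tolist()), y)


def write_references(r: ReferenceTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id,tpc_g_gae_per_100g\n")
        for sid, v in zip(r.sample_ids, r.tpc):
            fh.write(f"{sid},{_format_number(v)}\n")
    return path


def _format_number(v: float) -> str:
    return f"{v:.{CSV_SIGNIFICANT_DIGITS}g}"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def average_replicates(replicates: Iterable[SpectrumSet]) -> SpectrumSet:
    """Per-cell arithmetic mean of replicate measurements of the same samples.

    All inputs must share the wavenumber grid and the id set; sample order may
    differ between replicates (rows are matched by id). The output uses the
    first replicate's row order. Averaging replicate reloadings is how a single
    representative spectrum per sample is obtained from repeated ATR scans.
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("need at least one replicate set")
    first = reps[0]
    total = np.zeros_like(first.absorbance)
    for rep in reps:
        if not np.array_equal(rep.grid.values, first.grid.values):
            raise ValueError("replicate sets must share the wavenumber grid")
        if set(rep.sample_ids) != set(first.sample_ids):
            raise ValueError("replicate sets must share the sample id set")
        aligned = rep.subset(first.sample_ids)
        total += aligned.absorbance
    return SpectrumSet(first.grid, total / len(reps), first.sample_ids)


def align(s: SpectrumSet, r: ReferenceTable) -> Dataset:
    """Join spectra with reference values on sample id.

    The result is restricted to the id intersection (spectrum row order is
    kept); ids dropped from either side are reported on the Dataset.
    """
    ref_ids = set(r.sample_ids)
    common = [sid for sid in s.sample_ids if sid in ref_ids]
    if not common:
        raise ValueError("spectra and reference ids have an empty intersection")
    dropped_s = tuple(sid for sid in s.sample_ids if sid not in ref_ids)
    spec_ids = set(s.sample_ids)
    dropped_r = tuple(sid for sid in r.sample_ids if sid not in spec_ids)
    return Dataset(
        s.subset(common),
        r.subset(common),
        dropped_spectra_ids=dropped_s,
        dropped_reference_ids=dropped_r,
    )
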