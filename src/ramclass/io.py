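"""Reading and writing spectral matrices, metadata, and report tables.

Interchange format is delimited text (comma by default, tab accepted): a
spectra file holds one wavenumber column (cm^-1) followed by one intensity
column per scan; a companion metadata table maps each scan to its specimen,
individual, class label, and replicate index. Vendor binary formats are out
of scope — convert to CSV/TSV first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("scan_id", "specimen_id", "individual_id", "class_label", "replicate_index")


@dataclass
class Spectrum:
    """A single Raman scan: a wavenumber grid with intensities and provenance.

    Wavenumbers are in cm^-1 and must be strictly increasing; intensities are
    in arbitrary detector units. Provenance labels tie the scan back to the
    specimen and individual it came from.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    scan_id: str = ""
    specimen_id: str = ""
    individual_id: str = ""
    class_label: str = ""
    replicate_index: int = 1

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValueError(
                f"length mismatch: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.wavenumbers) < 2:
            raise ValueError("a spectrum needs at least 2 grid points")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError("non-finite wavenumber")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")

    def replace(self, **kw) -> "Spectrum":
        """Copy of this spectrum with the given fields replaced."""
        out = dict(
            wavenumbers=self.wavenumbers,
            intensities=self.intensities,
            scan_id=self.scan_id,
            specimen_id=self.specimen_id,
            individual_id=self.individual_id,
            class_label=self.class_label,
            replicate_index=self.replicate_index,
        )
        out.update(kw)
        return Spectrum(**out)


@dataclass
class SpectralDataset:
    """A set of scans on a shared wavenumber grid plus per-scan metadata.

    ``matrix`` is n_scans x n_points; ``meta`` has one row per scan, in the
    same order as the matrix rows, with columns scan_id, specimen_id,
    individual_id, class_label, replicate_index.
    """

    grid: np.ndarray
    matrix: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.grid.ndim != 1 or not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be 1-D and strictly increasing")
        if self.matrix.shape[1] != len(self.grid):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but grid has {len(self.grid)} points"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if len(self.meta) != self.matrix.shape[0]:
            raise ValueError(
                f"{self.matrix.shape[0]} matrix rows but {len(self.meta)} metadata rows"
            )
        ids = self.meta["scan_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate scan_id: {dup.iloc[0]!r}")
        if (self.meta["class_label"].astype(str).str.len() == 0).any():
            raise ValueError("every scan needs a non-empty class_label")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return len(self.grid)

    @property
    def classes(self) -> list[str]:
        """Distinct class labels, sorted."""
        return sorted(self.meta["class_label"].astype(str).unique())

    def labels(self) -> np.ndarray:
        return self.meta["class_label"].astype(str).to_numpy()

    def row(self, i: int) -> Spectrum:
        """The i-th scan as a Spectrum."""
        m = self.meta.iloc[i]
        return Spectrum(
            wavenumbers=self.grid,
            intensities=self.matrix[i],
            scan_id=str(m["scan_id"]),
            specimen_id=str(m["specimen_id"]),
            individual_id=str(m["individual_id"]),
            class_label=str(m["class_label"]),
            replicate_index=int(m["replicate_index"]),
        )

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SpectralDataset":
        """Dataset restricted to the given row indices, in that order."""
        idx = np.asarray(idx, dtype=int)
        return SpectralDataset(self.grid, self.matrix[idx], self.meta.iloc[idx])

    def spectra(self) -> Iterable[Spectrum]:
        for i in range(self.n_scans):
            yield self.row(i)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _header_names(path: Path, sep: str) -> list[str]:
    with open(path) as fh:
        first = fh.readline().rstrip("\n\r")
    return [c.strip() for c in first.split(sep)]


def read_dataset(spectra_path, meta_path) -> SpectralDataset:
    """Read a spectra matrix and its metadata table into a SpectralDataset.

    The spectra file must have a header row whose first column is the
    wavenumber axis and whose remaining column names are scan ids; the
    metadata file must have one row per scan id with the columns
    scan_id, specimen_id, individual_id, class_label, replicate_index.
    Output rows follow the metadata row order. A descending wavenumber
    column is sorted ascending (applied uniformly to all scans).
    """
    spectra_path, meta_path = Path(spectra_path), Path(meta_path)
    sep = _sniff_sep(spectra_path)
    names = _header_names(spectra_path, sep)
    if len(names) < 2:
        raise ValueError(f"{spectra_path}: expected a wavenumber column plus scan columns")
    scan_ids = names[1:]
    seen: set[str] = set()
    for sid in scan_ids:
        if sid in seen:
            raise ValueError(f"duplicate scan_id {sid!r} in {spectra_path}")
        seen.add(sid)

    raw = pd.read_csv(spectra_path, sep=sep, dtype=str)
    raw.columns = names
    columns: dict[str, np.ndarray] = {}
    for col in names:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            r = int(bad.idxmax())
            raise ValueError(
                f"{spectra_path}: non-numeric value {raw[col][r]!r} in column {col!r}, data row {r}"
            )
        if converted.isna().any():
            r = int(converted.isna().idxmax())
            raise ValueError(f"{spectra_path}: missing value in column {col!r}, data row {r}")
        columns[col] = raw[col].to_numpy(dtype=float)  # exact round-trip parse
    num = pd.DataFrame(columns)

    msep = _sniff_sep(meta_path)
    meta = pd.read_csv(meta_path, sep=msep, dtype=str)
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"{meta_path}: missing metadata columns {missing_cols}")
    meta = meta[list(META_COLUMNS)].copy()
    meta["replicate_index"] = pd.to_numeric(meta["replicate_index"]).astype(int)
    dup = meta["scan_id"][meta["scan_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{meta_path}: duplicate scan_id {dup.iloc[0]!r}")

    meta_ids = set(meta["scan_id"])
    for sid in scan_ids:
        if sid not in meta_ids:
            raise ValueError(f"scan {sid!r} present in {spectra_path} but missing from metadata")
    for sid in meta["scan_id"]:
        if sid not in seen:
            raise ValueError(f"scan {sid!r} present in metadata but missing from {spectra_path}")

    grid = num[names[0]].to_numpy()
    mat = np.column_stack([num[sid].to_numpy() for sid in meta["scan_id"]]).T
    order = np.argsort(grid, kind="stable")
    grid, mat = grid[order], mat[:, order]
    if not np.all(np.diff(grid) > 0):
        raise ValueError(f"{spectra_path}: wavenumber column has duplicate values")
    return SpectralDataset(grid, mat, meta)


def write_dataset(d: SpectralDataset, spectra_path, meta_path, sep: str = ",") -> None:
    """Write the spectra-matrix / metadata CSV pair (full precision)."""
    cols = {"wavenumber": d.grid}
    for i, sid in enumerate(d.meta["scan_id"].astype(str)):
        cols[sid] = d.matrix[i]
    # %.17g round-trips doubles exactly
    pd.DataFrame(cols).to_csv(spectra_path, sep=sep, index=False, float_format="%.17g")
    d.meta.to_csv(meta_path, sep=sep, index=False)


SWEEP_COLUMNS = (
    "n_pcs",
    "variance_explained_pct",
    "accuracy_pct",
    "sensitivity_pct",
    "specificity_pct",
)


def write_sweep_report(report, path) -> None:
    """Write a PC-count sweep report as CSV.

    Columns are exactly n_pcs, variance_explained_pct, accuracy_pct,
    sensitivity_pct, specificity_pct, one row per retained-PC count in
    ascending order. Percentages are on the 0-100 scale and are written with
    one decimal (full precision is retained in the in-memory report).
    """
    table = report.table if hasattr(report, "table") else report
    if len(table) == 0:
        raise ValueError("refusing to write an empty sweep report")
    out = table[list(SWEEP_COLUMNS)].sort_values("n_pcs")
    out = out.astype({"n_pcs": int})
    out.to_csv(path, index=False, float_format="%.1f")
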