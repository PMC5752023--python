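"""Spectral-map binning: scan-count x m/z compartments, intensities totaled.

Each run is partitioned into fixed half-open bins (default 50 scans x
1 Th over scans [0, 3000) and m/z [200, 1000), i.e. a 60 x 800 grid of
48,000 cells) and every centroid's intensity is added to exactly one
cell.  No noise filtering is applied: all ion signals enter the feature
vector.  Feature identifiers read ``"455-456|1250-1300"`` (m/z bin |
scan bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import MZ_MAX, MZ_MIN, N_SCANS, Run

__all__ = [
    "BinGrid",
    "DEFAULT_GRID",
    "FeatureVector",
    "bin_run",
    "boundary_assignment",
    "OUT_OF_RANGE",
    "FeatureMatrix",
    "export_matrix",
    "read_matrix",
    "build_matrix",
]

#: Sentinel returned for peaks outside the grid.
OUT_OF_RANGE = -1


@dataclass(frozen=True)
class BinGrid:
    """The binning scheme; widths must divide the ranges evenly."""

    scan_width: int = 50
    mz_width: float = 1.0
    scan_range: tuple[int, int] = (0, N_SCANS)
    mz_range: tuple[float, float] = (MZ_MIN, MZ_MAX)

    def __post_init__(self):
        if self.scan_width <= 0 or self.mz_width <= 0:
            raise ValueError("bin widths must be positive")
        s0, s1 = self.scan_range
        if (s1 - s0) % self.scan_width:
            raise ValueError("scan width must divide the scan range evenly")
        n_mz = (self.mz_range[1] - self.mz_range[0]) / self.mz_width
        if abs(n_mz - round(n_mz)) > 1e-9:
            raise ValueError("m/z width must divide the m/z range evenly")

    @property
    def n_scan_bins(self) -> int:
        return (self.scan_range[1] - self.scan_range[0]) // self.scan_width

    @property
    def n_mz_bins(self) -> int:
        return round((self.mz_range[1] - self.mz_range[0]) / self.mz_width)

    @property
    def n_cells(self) -> int:
        return self.n_scan_bins * self.n_mz_bins

    def cell_index(self, mz: np.ndarray, scan: np.ndarray) -> np.ndarray:
        """Vectorized half-open cell assignment; OUT_OF_RANGE outside."""
        mz = np.asarray(mz, dtype=float)
        scan = np.asarray(scan)
        i_mz = np.floor((mz - self.mz_range[0]) / self.mz_width).astype(np.int64)
        i_scan = (np.asarray(scan, dtype=np.int64) - self.scan_range[0]) // self.scan_width
        idx = i_scan * self.n_mz_bins + i_mz
        bad = (
            (mz < self.mz_range[0])
            | (mz >= self.mz_range[1])
            | (scan < self.scan_range[0])
            | (scan >= self.scan_range[1])
        )
        idx[bad] = OUT_OF_RANGE
        return idx

    def feature_ids(self) -> list[str]:
        """Cell labels in storage order (scan-major)."""
        mz0 = self.mz_range[0]
        ids = []
        for i_scan in range(self.n_scan_bins):
            s_lo = self.scan_range[0] + i_scan * self.scan_width
            s_hi = s_lo + self.scan_width
            for i_mz in range(self.n_mz_bins):
                m_lo = mz0 + i_mz * self.mz_width
                m_hi = m_lo + self.mz_width
                ids.append(f"{m_lo:g}-{m_hi:g}|{s_lo}-{s_hi}")
        return ids

    def cell_bounds(self, index: int) -> tuple[float, float, int, int]:
        """(mz_lo, mz_hi, scan_lo, scan_hi) of a cell index."""
        i_scan, i_mz = divmod(index, self.n_mz_bins)
        m_lo = self.mz_range[0] + i_mz * self.mz_width
        s_lo = self.scan_range[0] + i_scan * self.scan_width
        return m_lo, m_lo + self.mz_width, s_lo, s_lo + self.scan_width

    @staticmethod
    def parse_feature_id(fid: str) -> tuple[float, float, int, int]:
        mz_part, scan_part = fid.split("|")
        m_lo, m_hi = (float(x) for x in mz_part.split("-"))
        s_lo, s_hi = (int(x) for x in scan_part.split("-"))
        return m_lo, m_hi, s_lo, s_hi


DEFAULT_GRID = BinGrid()


def boundary_assignment(mz: float, scan: int, grid: BinGrid = DEFAULT_GRID) -> int:
    """Cell index of a single peak (half-open bins on both axes)."""
    return int(grid.cell_index(np.array([mz]), np.array([scan]))[0])


@dataclass
class FeatureVector:
    """Totaled intensities of one run on a grid, plus bookkeeping."""

    grid: BinGrid
    values: np.ndarray
    sample: str
    batch: str = ""
    day: int = 0
    replicate: int = 0
    n_dropped: int = 0
    dropped_intensity: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_cells:
            raise ValueError("feature vector length must equal the cell count")


def bin_run(run: Run, grid: BinGrid = DEFAULT_GRID) -> FeatureVector:
    """Total each peak's intensity into its cell.

    Peaks outside the grid are dropped and counted (never an error);
    everything in range is kept, noise included.
    """
    idx = grid.cell_index(run.mz, run.scan)
    ok = idx != OUT_OF_RANGE
    values = np.bincount(idx[ok], weights=run.intensity[ok], minlength=grid.n_cells)
    return FeatureVector(
        grid,
        values,
        sample=run.label,
        batch=run.batch,
        day=run.day,
        replicate=run.replicate,
        n_dropped=int((~ok).sum()),
        dropped_intensity=float(run.intensity[~ok].sum()),
    )


@dataclass
class FeatureMatrix:
    """features x samples intensity table with per-sample metadata.

    ``values``: DataFrame indexed by feature id, one column per sample.
    ``meta``: DataFrame indexed by sample with batch/day/replicate.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    grid: BinGrid | None = None

    def __post_init__(self):
        if list(self.values.columns) != list(self.meta.index):
            raise ValueError("metadata rows must match sample columns")
        if (self.values.values < 0).any():
            raise ValueError("feature intensities must be non-negative")


def build_matrix(vectors: Sequence[FeatureVector]) -> FeatureMatrix:
    """Assemble binned runs (sharing one grid) into a feature matrix."""
    if not vectors:
        raise ValueError("no feature vectors given")
    grid = vectors[0].grid
    if any(v.grid != grid for v in vectors):
        raise ValueError("all feature vectors must share one grid")
    values = pd.DataFrame(
        {v.sample: v.values for v in vectors}, index=grid.feature_ids()
    )
    meta = pd.DataFrame(
        {
            "batch": [v.batch for v in vectors],
            "day": [v.day for v in vectors],
            "replicate": [v.replicate for v in vectors],
        },
        index=[v.sample for v in vectors],
    )
    return FeatureMatrix(values, meta, grid)


def export_matrix(matrix: FeatureMatrix, path) -> None:
    """Feature-matrix CSV: metadata header rows, then one row per feature."""
    with open(path, "w") as fh:
        cols = ",".join(matrix.values.columns)
        fh.write(f"feature_id,{cols}\n")
        for key in ("batch", "day", "replicate"):
            row = ",".join(str(x) for x in matrix.meta[key])
            fh.write(f"#{key},{row}\n")
        matrix.values.to_csv(fh, header=False)


def read_matrix(path, grid: BinGrid | None = None) -> FeatureMatrix:
    """Read the CSV written by :func:`export_matrix` (lossless)."""
    meta_rows: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        samples = header[1:]
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            parts = line[1:].strip().split(",")
            meta_rows[parts[0]] = parts[1:]
            pos = fh.tell()
        values = pd.read_csv(fh, header=None, index_col=0)
    values.columns = samples
    values.index.name = None
    meta = pd.DataFrame(
        {
            "batch": meta_rows.get("batch", [""] * len(samples)),
            "day": [int(x) for x in meta_rows.get("day", [0] * len(samples))],
            "replicate": [int(x) for x in meta_rows.get("replicate", [0] * len(samples))],
        },
        index=samples,
    )
    return FeatureMatrix(values, meta, grid)
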