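"""Core containers for bucketed NMR data.

A 1H-NMR pseudospectrum is reduced to a feature vector by integrating
fixed-width chemical-shift intervals ("buckets"); solvent and contaminant
regions are excluded, and each sample's bucket vector is normalized to its
total spectral area so that features are relative intensities.

This module owns the bucket-grid arithmetic (:func:`build_bucket_grid`),
spectrum integration, total-area normalization, and CSV/XLSX readers and
writers for sample x bucket tables carrying the two-factor (dose, time)
design metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

logger = logging.getLogger("nmrasca")

#: ppm comparisons are done to this absolute tolerance.
PPM_TOL = 1e-6

#: Reserved metadata column names in bucket tables.
DESIGN_COLUMNS = ("sample_id", "dose", "time", "animal_id")


class GridError(ValueError):
    """Invalid bucket-grid specification."""


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignTable:
    """Per-sample factors of the two-way (dose x time) layout.

    Levels are kept in first-appearance order for plotting but are treated
    as unordered categories by every ANOVA-style computation.  Cell counts
    may be unequal.
    """

    sample_id: tuple[str, ...]
    dose: tuple[str, ...]
    time: tuple[str, ...]
    animal_id: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.sample_id)
        if len(self.dose) != n or len(self.time) != n:
            raise ValueError("sample_id, dose and time must have equal length")
        if self.animal_id and len(self.animal_id) != n:
            raise ValueError("animal_id length mismatch")
        if len(set(self.sample_id)) != n:
            raise ValueError("duplicate sample_id values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DesignTable":
        animal = tuple(df["animal_id"].astype(str)) if "animal_id" in df else ()
        return cls(
            sample_id=tuple(df["sample_id"].astype(str)),
            dose=tuple(df["dose"].astype(str)),
            time=tuple(df["time"].astype(str)),
            animal_id=animal,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "sample_id": self.sample_id,
            "dose": self.dose,
            "time": self.time,
        }
        if self.animal_id:
            data["animal_id"] = self.animal_id
        return pd.DataFrame(data)

    def __len__(self) -> int:
        return len(self.sample_id)

    @property
    def dose_levels(self) -> list[str]:
        return list(dict.fromkeys(self.dose))

    @property
    def time_levels(self) -> list[str]:
        return list(dict.fromkeys(self.time))

    def subset(self, mask: np.ndarray) -> "DesignTable":
        idx = np.flatnonzero(np.asarray(mask))
        return DesignTable(
            sample_id=tuple(self.sample_id[i] for i in idx),
            dose=tuple(self.dose[i] for i in idx),
            time=tuple(self.time[i] for i in idx),
            animal_id=tuple(self.animal_id[i] for i in idx) if self.animal_id else (),
        )

    def cell_counts(self) -> pd.DataFrame:
        """Samples per (time, dose) cell, times as rows."""
        df = self.to_frame()
        return df.pivot_table(index="time", columns="dose", values="sample_id",
                              aggfunc="count", fill_value=0)


# ---------------------------------------------------------------------------
# Bucket grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BucketGrid:
    """Uniform ppm binning scheme with exclusion windows.

    The retained buckets are disjoint width-uniform intervals inside
    ``[region_start_ppm, region_end_ppm]``.  Bucket edges are stored on an
    ascending axis; presentation (labels, IO) follows the descending NMR
    convention.

    Boundary convention: bucket *i* covers
    ``[start + i*width, start + (i+1)*width)``.  An exclusion window
    ``(lo, hi)`` removes the buckets strictly interior to it plus the bucket
    touching its upper edge; the single bucket whose left edge coincides
    with ``lo`` is retained.  Each window of width ``w`` therefore removes
    ``w/width - 1`` buckets.
    """

    region_start_ppm: float
    region_end_ppm: float
    width_ppm: float
    exclusion_windows: tuple[tuple[float, float], ...] = ()
    #: ascending indices of retained buckets on the full grid
    retained_indices: tuple[int, ...] = field(default=(), repr=False)

    @property
    def n_total(self) -> int:
        return int(round((self.region_end_ppm - self.region_start_ppm) / self.width_ppm))

    @property
    def n_buckets(self) -> int:
        return len(self.retained_indices)

    @property
    def bucket_edges(self) -> np.ndarray:
        """(n_buckets, 2) ascending [lo, hi) edges of retained buckets."""
        idx = np.asarray(self.retained_indices, dtype=float)
        lo = self.region_start_ppm + idx * self.width_ppm
        return np.column_stack([lo, lo + self.width_ppm])

    @property
    def bucket_centers(self) -> np.ndarray:
        """Ascending ppm centers of retained buckets."""
        edges = self.bucket_edges
        return edges.mean(axis=1)

    def labels(self) -> list[str]:
        """Bucket labels (center ppm) in descending NMR order."""
        return [f"{c:.3f}" for c in self.bucket_centers[::-1]]


def build_bucket_grid(
    region: tuple[float, float],
    width: float,
    exclusions: Sequence[tuple[float, float]] = (),
) -> BucketGrid:
    """Construct the bucket grid for a spectral region.

    Parameters
    ----------
    region
        (low, high) ppm bounds of the integrated region; order-insensitive.
    width
        Bucket width in ppm (0.01 in routine 1D bucketing).
    exclusions
        (lo, hi) ppm windows (solvent/contaminant resonances) whose buckets
        are dropped; order-insensitive per window and across windows.

    Raises
    ------
    GridError
        If the width does not divide the region, a window lies outside the
        region, or windows overlap.
    """
    lo, hi = sorted(float(v) for v in region)
    width = float(width)
    if width <= 0:
        raise GridError("bucket width must be positive")
    n_total_f = (hi - lo) / width
    n_total = int(round(n_total_f))
    if n_total < 1 or abs(n_total_f - n_total) > PPM_TOL / width:
        raise GridError(
            f"bucket width {width} does not divide region ({lo}, {hi})"
        )

    windows = tuple(tuple(sorted(float(v) for v in w)) for w in exclusions)
    windows = tuple(sorted(windows))
    for (a, b) in windows:
        if a < lo - PPM_TOL or b > hi + PPM_TOL:
            raise GridError(f"exclusion window ({a}, {b}) outside region ({lo}, {hi})")
    for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
        if a2 < b1 - PPM_TOL:
            raise GridError(
                f"exclusion windows ({a1}, {b1}) and ({a2}, {b2}) overlap"
            )

    excluded: set[int] = set()
    for (a, b) in windows:
        i_lo = int(round((a - lo) / width))
        i_hi = int(round((b - lo) / width))
        removed = range(max(i_lo + 1, 0), min(i_hi, n_total))
        excluded.update(removed)
        logger.info(
            "exclusion window %.4g-%.4g ppm: removed %d buckets (boundary bucket at %.4g retained)",
            a, b, len(removed), lo + i_lo * width,
        )

    retained = tuple(i for i in range(n_total) if i not in excluded)
    return BucketGrid(
        region_start_ppm=lo,
        region_end_ppm=hi,
        width_ppm=width,
        exclusion_windows=windows,
        retained_indices=retained,
    )


def integrate_pseudospectrum(
    ppm: np.ndarray, intensity: np.ndarray, grid: BucketGrid
) -> np.ndarray:
    """Integrate a sampled (ppm, intensity) trace over the retained buckets.

    The trace must cover the grid region; trapezoidal quadrature is used
    with exact interpolation at bucket edges.  Excluded regions contribute
    nothing (their buckets simply do not exist on the grid).
    """
    ppm = np.asarray(ppm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if np.any(np.isnan(intensity)):
        raise ValueError("NaN intensities in pseudospectrum")
    order = np.argsort(ppm)
    ppm, intensity = ppm[order], intensity[order]
    if ppm[0] > grid.region_start_ppm + PPM_TOL or ppm[-1] < grid.region_end_ppm - PPM_TOL:
        raise ValueError("pseudospectrum does not cover the grid region")
    # cumulative integral, then difference of interpolants at bucket edges
    cum = np.concatenate([[0.0], cumulative_trapezoid(intensity, ppm)])
    edges = grid.bucket_edges
    cum_lo = np.interp(edges[:, 0], ppm, cum)
    cum_hi = np.interp(edges[:, 1], ppm, cum)
    return cum_hi - cum_lo


# ---------------------------------------------------------------------------
# Bucket matrix
# ---------------------------------------------------------------------------

@dataclass
class BucketMatrix:
    """Samples x buckets intensity matrix with its grid and design.

    ``values[i, j]`` is the integral of sample ``i`` over retained bucket
    ``j`` (ascending ppm order, matching ``grid.bucket_centers``).  Row
    order matches ``design``.  When ``normalized`` each row sums to 1.
    """

    values: np.ndarray
    grid: BucketGrid
    design: DesignTable
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x buckets)")
        if self.values.shape[0] != len(self.design):
            raise ValueError("row count does not match design table")
        if self.grid.n_buckets and self.values.shape[1] != self.grid.n_buckets:
            raise ValueError(
                f"column count {self.values.shape[1]} does not match grid "
                f"bucket count {self.grid.n_buckets}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_buckets(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "BucketMatrix":
        mask = np.asarray(mask, dtype=bool)
        return BucketMatrix(
            values=self.values[mask],
            grid=self.grid,
            design=self.design.subset(mask),
            normalized=self.normalized,
        )


def normalize_total_area(matrix: BucketMatrix) -> BucketMatrix:
    """Divide each row by its total area; idempotent and scale-invariant."""
    sums = matrix.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        names = [matrix.design.sample_id[i] for i in bad[:5]]
        raise ValueError(f"non-positive total area for sample(s): {names}")
    return replace(matrix, values=matrix.values / sums[:, None], normalized=True)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _grid_from_labels(labels: Sequence[str], width: float | None) -> BucketGrid:
    """Reconstruct a (gap-aware) grid from descending ppm center labels."""
    centers = np.array([float(v) for v in labels])
    asc = np.sort(centers)
    if width is None:
        diffs = np.diff(asc)
        width = float(np.min(diffs)) if diffs.size else 0.01
    start = asc[0] - width / 2
    end = asc[-1] + width / 2
    idx = np.round((asc - width / 2 - start) / width).astype(int)
    n_total = int(round((end - start) / width))
    return BucketGrid(
        region_start_ppm=float(start),
        region_end_ppm=float(end),
        width_ppm=float(width),
        exclusion_windows=(),
        retained_indices=tuple(int(i) for i in idx if 0 <= i < n_total),
    )


def read_bucket_table(
    path: str | Path,
    fmt: str | None = None,
    grid: BucketGrid | None = None,
    allow_count_mismatch: bool = False,
) -> BucketMatrix:
    """Read a bucket table (CSV or first XLSX sheet, one header row).

    The header carries design column names followed by per-bucket ppm
    labels in descending NMR order; values are stored internally on the
    ascending axis.  If ``grid`` is given its bucket count is checked
    against the table (override with ``allow_count_mismatch``).
    """
    path = Path(path)
    fmt = fmt or ("xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv")
    if fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=0)
    else:
        df = pd.read_csv(path)

    missing = [c for c in ("sample_id", "dose", "time") if c not in df.columns]
    if missing:
        raise ValueError(f"missing design column(s): {missing}")
    design = DesignTable.from_frame(df)
    bucket_cols = [c for c in df.columns if c not in DESIGN_COLUMNS]

    raw = df[bucket_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise ValueError(
            f"non-numeric value {raw.iloc[r, c]!r} at row {r} column {bucket_cols[c]!r}"
        )

    centers_desc = np.array([float(c) for c in bucket_cols])
    order = np.argsort(centers_desc)  # to ascending
    values = numeric.to_numpy(dtype=float)[:, order]

    if grid is not None and grid.n_buckets != len(bucket_cols):
        msg = (
            f"table has {len(bucket_cols)} buckets but grid defines {grid.n_buckets}"
        )
        if not allow_count_mismatch:
            raise ValueError(msg + " (pass allow_count_mismatch=True to override)")
        logger.warning(msg)
        grid = None
    if grid is None:
        grid = _grid_from_labels(bucket_cols, None)

    rows_sum = values.sum(axis=1)
    normalized = bool(np.allclose(rows_sum, 1.0, atol=1e-9))
    return BucketMatrix(values=values, grid=grid, design=design, normalized=normalized)


def write_bucket_table(matrix: BucketMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write a bucket table; inverse of :func:`read_bucket_table`."""
    path = Path(path)
    fmt = fmt or ("xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv")
    # internal storage ascending; emit descending per NMR convention
    buckets = pd.DataFrame(matrix.values[:, ::-1], columns=matrix.grid.labels())
    df = pd.concat([matrix.design.to_frame(), buckets], axis=1)
    if fmt == "xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Annotation map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationEntry:
    metabolite: str
    ppm_lo: float
    ppm_hi: float
    multiplicity: str = ""


@dataclass(frozen=True)
class AnnotationMap:
    """Metabolite resonance assignments as ppm intervals.

    A bucket may fall in intervals of more than one metabolite (spectral
    overlap); a metabolite may own several intervals (multiplets).
    """

    entries: tuple[AnnotationEntry, ...]

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationMap":
        df = pd.read_csv(path)
        entries = tuple(
            AnnotationEntry(
                metabolite=str(r["metabolite"]),
                ppm_lo=float(min(r["ppm_lo"], r["ppm_hi"])),
                ppm_hi=float(max(r["ppm_lo"], r["ppm_hi"])),
                multiplicity=str(r.get("multiplicity", "") or ""),
            )
            for r in df.to_dict("records")
        )
        return cls(entries=entries)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"metabolite": e.metabolite, "ppm_lo": e.ppm_lo,
                 "ppm_hi": e.ppm_hi, "multiplicity": e.multiplicity}
                for e in self.entries
            ]
        ).to_csv(path, index=False)

    def metabolites_for_bucket(self, grid: BucketGrid, bucket_index: int) -> list[str]:
        """Metabolites whose intervals overlap the given retained bucket."""
        lo, hi = grid.bucket_edges[bucket_index]
        out: list[str] = []
        for e in self.entries:
            if e.ppm_lo < hi - PPM_TOL and e.ppm_hi > lo + PPM_TOL and e.metabolite not in out:
                out.append(e.metabolite)
        return out

    def buckets_for_metabolite(self, grid: BucketGrid, metabolite: str) -> list[int]:
        centers = grid.bucket_centers
        hit: list[int] = []
        for e in self.entries:
            if e.metabolite != metabolite:
                continue
            sel = np.flatnonzero((centers > e.ppm_lo - PPM_TOL) & (centers < e.ppm_hi + PPM_TOL))
            hit.extend(int(i) for i in sel)
        return sorted(set(hit))
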