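"""Occurrence records, grid definition and rasterization to a presence-absence matrix.

Specimen records (taxon, family, x, y) are binned into a rectangular grid of
cells; each cell becomes one row of a binary cell x taxon community matrix,
the training set for the self-organizing map.  The grid is an explicit,
user-supplied geometry: no projection is ever inferred from the data.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel returned by :func:`assign_cell` for points outside the grid.
OUT_OF_GRID = -1

_DEFAULT_COLUMNS = {"taxon": "taxon", "family": "family", "lon": "lon", "lat": "lat"}

#: km per degree of latitude (spherical mean radius).
_KM_PER_DEG = 111.195


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced specimen."""

    taxon: str
    family: str
    lon: float
    lat: float

    def __post_init__(self):
        if not self.taxon:
            raise ValueError("taxon must be nonempty")
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError("coordinates must be finite")


@dataclass(frozen=True)
class GridSpec:
    """Rectangular analysis grid anchored at its south-west corner.

    Cells are indexed row-major with row 0 southernmost:
    ``cell = i * n_cols + j`` for row ``i`` and column ``j``.
    ``cell_area_km2`` may be supplied directly (projected grids); when left
    ``None`` it is approximated for geographic (degree) grids at the grid's
    mean latitude.
    """

    x_min: float
    y_min: float
    cell_w: float
    cell_h: float
    n_cols: int
    n_rows: int
    cell_area_km2: float | None = None

    def __post_init__(self):
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")
        if self.cell_w <= 0 or self.cell_h <= 0:
            raise ValueError("cell dimensions must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_w

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_h

    def cell_area(self) -> float:
        """Cell area in km2; geographic approximation when not supplied."""
        if self.cell_area_km2 is not None:
            return self.cell_area_km2
        mean_lat = 0.5 * (self.y_min + self.y_max)
        return (
            self.cell_h
            * _KM_PER_DEG
            * self.cell_w
            * _KM_PER_DEG
            * math.cos(math.radians(mean_lat))
        )

    def cell_rowcol(self, cell: int) -> tuple[int, int]:
        return divmod(cell, self.n_cols)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GridSpec":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PresenceAbsenceMatrix:
    """Binary cell x taxon matrix with a surveyed-cell mask.

    Rows follow the grid's row-major cell ordering; columns are taxa in
    lexicographic order.  Rows of unsurveyed cells are all-zero.
    """

    values: np.ndarray
    taxa: list[str]
    surveyed: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        self.surveyed = np.asarray(self.surveyed, dtype=bool)
        if self.values.shape != (self.grid.n_cells, len(self.taxa)):
            raise ValueError("matrix shape inconsistent with grid/taxa")
        if self.surveyed.shape != (self.grid.n_cells,):
            raise ValueError("surveyed mask length inconsistent with grid")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def surveyed_values(self) -> np.ndarray:
        """Rows of surveyed cells only, as float64 (SOM input)."""
        return self.values[self.surveyed].astype(np.float64)

    # -- serialization -----------------------------------------------------

    def to_wide_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.taxa)
        df.insert(0, "surveyed", self.surveyed.astype(int))
        df.insert(0, "cell_id", np.arange(self.grid.n_cells))
        df.to_csv(path, index=False)

    def to_triplet_csv(self, path: str | Path) -> None:
        cells, cols = np.nonzero(self.values)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_id", "taxon", "presence"])
            for c, t in zip(cells.tolist(), cols.tolist()):
                w.writerow([c, self.taxa[t], 1])

    @classmethod
    def from_wide_csv(cls, path: str | Path, grid: GridSpec) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path)
        taxa = [c for c in df.columns if c not in ("cell_id", "surveyed")]
        df = df.sort_values("cell_id")
        return cls(
            values=df[taxa].to_numpy(dtype=np.uint8),
            taxa=taxa,
            surveyed=df["surveyed"].to_numpy(dtype=bool),
            grid=grid,
        )


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[OccurrenceRecord]:
    """Read occurrence records from a delimited text file.

    ``column_map`` maps the logical names ``taxon``, ``family``, ``lon``,
    ``lat`` to the file's column names.  The delimiter (comma or tab) is
    auto-detected from the header.  Rows whose coordinates do not parse to
    finite numbers, or whose taxon is empty after whitespace trimming, are
    skipped; the skip count is reported through this module's logger.
    A missing ``family`` column yields empty family strings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(_DEFAULT_COLUMNS, **(column_map or {}))
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = _detect_delimiter(header)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    for logical in ("taxon", "lon", "lat"):
        if cols[logical] not in df.columns:
            raise KeyError(
                f"required column {cols[logical]!r} (for {logical!r}) "
                f"not found in {path}"
            )
    has_family = cols["family"] in df.columns

    def _parse(series: pd.Series) -> pd.Series:
        # float() is correctly rounded, so repr-written coordinates
        # round-trip exactly
        def one(v: str) -> float:
            try:
                return float(v)
            except ValueError:
                return float("nan")

        return series.map(one)

    lon = _parse(df[cols["lon"]])
    lat = _parse(df[cols["lat"]])
    taxa = df[cols["taxon"]].str.strip()
    ok = (
        lon.notna()
        & lat.notna()
        & np.isfinite(lon.fillna(np.nan))
        & np.isfinite(lat.fillna(np.nan))
        & (taxa != "")
    )
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.warning("skipped %d unparseable row(s) in %s", n_skipped, path)

    families = df[cols["family"]].str.strip() if has_family else pd.Series("", index=df.index)
    return [
        OccurrenceRecord(taxon=t, family=f, lon=x, lat=y)
        for t, f, x, y in zip(
            taxa[ok], families[ok], lon[ok].astype(float), lat[ok].astype(float)
        )
    ]


def write_occurrences(records: Sequence[OccurrenceRecord], path: str | Path) -> None:
    """Write records as a standard CSV (taxon,family,lon,lat)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon", "family", "lon", "lat"])
        for r in records:
            w.writerow([r.taxon, r.family, repr(r.lon), repr(r.lat)])


def assign_cell(rec: OccurrenceRecord, grid: GridSpec) -> int:
    """Map a record to its grid-cell index, or :data:`OUT_OF_GRID`.

    Cells are half-open rectangles ``[x0, x0+w) x [y0, y0+h)``; points
    exactly on the grid's maximum x or y edge fold into the last
    column/row, so the grid's outer boundary is fully covered.
    """
    x, y = rec.lon, rec.lat
    if not (grid.x_min <= x <= grid.x_max and grid.y_min <= y <= grid.y_max):
        return OUT_OF_GRID
    j = min(int((x - grid.x_min) // grid.cell_w), grid.n_cols - 1)
    i = min(int((y - grid.y_min) // grid.cell_h), grid.n_rows - 1)
    return i * grid.n_cols + j


def rasterize(
    records: Sequence[OccurrenceRecord], grid: GridSpec
) -> PresenceAbsenceMatrix:
    """Bin records into a presence-absence matrix over the grid.

    A taxon is present in a cell iff at least one of its records falls in
    the cell, so the operation is idempotent under record duplication and
    invariant to record order.  A cell is surveyed iff any record (of any
    taxon) fell in it.
    """
    pairs: set[tuple[int, str]] = set()
    surveyed = np.zeros(grid.n_cells, dtype=bool)
    for rec in records:
        c = assign_cell(rec, grid)
        if c == OUT_OF_GRID:
            continue
        surveyed[c] = True
        pairs.add((c, rec.taxon))
    if not pairs:
        raise ValueError("no records fall inside the grid")
    taxa = sorted({t for _, t in pairs})
    col = {t: k for k, t in enumerate(taxa)}
    values = np.zeros((grid.n_cells, len(taxa)), dtype=np.uint8)
    for c, t in pairs:
        values[c, col[t]] = 1
    return PresenceAbsenceMatrix(values=values, taxa=taxa, surveyed=surveyed, grid=grid)
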