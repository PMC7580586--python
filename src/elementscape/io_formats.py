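"""Standard data containers and on-disk formats.

Grid convention (shared by every module): rasters are regular lon/lat
grids in WGS84 decimal degrees. Cell (0, 0) is the north-west cell;
rows increase southward, columns eastward. Cell centers sit at
``origin + (index + 0.5) * cell_size`` (center convention). The default
cell size is 0.16 degrees, roughly 315 km^2 at mid-latitudes.

On-disk formats are plain text: CSV sample tables (columns
``sample_id, lon, lat, <element>...``), ESRI ASCII grids for rasters,
and GeoJSON polygons for range masks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

logger = logging.getLogger(__name__)

DEFAULT_CELL_SIZE = 0.16


class IngestError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# RasterGrid
# ---------------------------------------------------------------------------

@dataclass
class RasterGrid:
    """A single-band lon/lat raster with NW-origin row indexing.

    Parameters
    ----------
    west, north : float
        Outer edge of the west-most column / north-most row, degrees.
    cell_size : float
        Cell edge length in degrees (square cells).
    values : ndarray of shape (n_rows, n_cols)
        Cell values; NaN marks no-data.
    """

    west: float
    north: float
    cell_size: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.west, other.west)
            and np.isclose(self.north, other.north)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def contains(self, lon: float, lat: float) -> bool:
        return self.west <= lon <= self.east and self.south <= lat <= self.north

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing a point.

        Points exactly on the east/south outer edge map to the last
        cell so that the closed extent is fully covered.
        """
        if not self.contains(lon, lat):
            raise ValueError(
                f"location ({lon}, {lat}) outside raster extent "
                f"[{self.west}, {self.east}] x [{self.south}, {self.north}]"
            )
        col = min(int((lon - self.west) / self.cell_size), self.n_cols - 1)
        row = min(int((self.north - lat) / self.cell_size), self.n_rows - 1)
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        lon = self.west + (col + 0.5) * self.cell_size
        lat = self.north - (row + 0.5) * self.cell_size
        return lon, lat

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of every cell center."""
        lon = self.west + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.north - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def value_at(self, lon: float, lat: float) -> float:
        row, col = self.cell_of(lon, lat)
        return float(self.values[row, col])

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError("replacement values must match grid shape")
        return RasterGrid(self.west, self.north, self.cell_size, values.copy())

    @classmethod
    def blank(cls, west: float, north: float, cell_size: float,
              n_rows: int, n_cols: int, fill: float = np.nan) -> "RasterGrid":
        return cls(west, north, cell_size, np.full((n_rows, n_cols), fill, dtype=float))


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc).

    The header must provide ncols, nrows, xllcorner, yllcorner and
    cellsize; NODATA cells become NaN. Values are stored north row
    first, matching the NW-origin convention.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise IngestError(f"{path}: ASCII grid header missing {sorted(missing)}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    body = " ".join(lines[i:]).split()
    try:
        values = np.array(body, dtype=float)
    except ValueError as exc:
        raise IngestError(f"{path}: non-numeric raster value ({exc})") from None
    if values.size != n_rows * n_cols:
        raise IngestError(
            f"{path}: expected {n_rows * n_cols} values, found {values.size}"
        )
    values = values.reshape(n_rows, n_cols)
    if "nodata_value" in header:
        values[values == header["nodata_value"]] = np.nan
    cell = header["cellsize"]
    west = header["xllcorner"]
    north = header["yllcorner"] + n_rows * cell
    return RasterGrid(west, north, cell, values)


def write_raster(grid: RasterGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid; NaN cells become the nodata sentinel."""
    path = Path(path)
    values = np.where(np.isnan(grid.values), nodata, grid.values)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(grid.west):.17g}\n")
        fh.write(f"yllcorner {float(grid.south):.17g}\n")
        fh.write(f"cellsize {float(grid.cell_size):.17g}\n")
        fh.write(f"NODATA_value {float(nodata):.17g}\n")
        for row in values:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# ElementProfileSet
# ---------------------------------------------------------------------------

@dataclass
class ElementProfileSet:
    """Per-individual element concentration profiles with coordinates.

    ``conc`` is an (n_samples, n_elements) array in ppb; element order
    is fixed by ``elements`` and shared across all records.
    """

    ids: list[str]
    lons: np.ndarray
    lats: np.ndarray
    elements: list[str]
    conc: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(s) for s in self.ids]
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        conc = np.asarray(self.conc, dtype=float)
        if conc.size == 0:
            conc = conc.reshape(len(self.ids), len(self.elements))
        else:
            conc = conc.reshape(len(self.ids), -1)
        self.conc = conc
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("duplicate element names")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({s for s in self.ids if self.ids.count(s) > 1})
            raise IngestError(f"duplicate sample ids: {dupes}")
        n = len(self.ids)
        if not (self.lons.shape == (n,) and self.lats.shape == (n,)):
            raise ValueError("coordinate arrays must match number of ids")
        if self.conc.shape != (n, len(self.elements)):
            raise ValueError("concentration matrix shape mismatch")
        if n and np.isnan(self.conc).any():
            bad = [self.ids[i] for i in np.unique(np.argwhere(np.isnan(self.conc))[:, 0])]
            raise IngestError(f"missing concentrations for samples {bad}")
        if n and (self.conc < 0).any():
            bad = [self.ids[i] for i in np.unique(np.argwhere(self.conc < 0)[:, 0])]
            raise IngestError(f"negative concentrations for samples {bad}")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: Sequence[int]) -> "ElementProfileSet":
        idx = np.asarray(indices, dtype=int)
        return ElementProfileSet(
            [self.ids[i] for i in idx],
            self.lons[idx],
            self.lats[idx],
            list(self.elements),
            self.conc[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.ids, "lon": self.lons, "lat": self.lats})
        for j, e in enumerate(self.elements):
            df[e] = self.conc[:, j] if len(self) else np.array([])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, elements: Sequence[str]) -> "ElementProfileSet":
        return cls(
            list(df["sample_id"].astype(str)),
            df["lon"].to_numpy(float),
            df["lat"].to_numpy(float),
            list(elements),
            df[list(elements)].to_numpy(float) if len(df) else np.empty((0, len(elements))),
        )


def read_profile_table(path: str | Path, elements: Sequence[str]) -> ElementProfileSet:
    """Read a CSV sample table with columns sample_id, lon, lat, elements.

    Extra columns are ignored with a logged warning; a missing required
    column, a non-numeric concentration or a duplicate id is a hard
    ingest error naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    required = ["sample_id", "lon", "lat", *elements]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring extra columns %s", path, extra)
    for col in ["lon", "lat", *elements]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[numeric.isna() & df[col].notna(), "sample_id"]
        if len(bad):
            raise IngestError(
                f"{path}: non-numeric value in column {col!r} for sample(s) "
                f"{list(bad)}"
            )
        if numeric.isna().any():
            rows = list(df.loc[numeric.isna(), "sample_id"])
            raise IngestError(f"{path}: missing {col!r} for sample(s) {rows}")
        df[col] = numeric
    return ElementProfileSet.from_frame(df, elements)


def write_profile_table(profiles: ElementProfileSet, path: str | Path) -> None:
    # %.17g guarantees binary round-trip of doubles through the CSV
    profiles.to_frame().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# SoilGridSet
# ---------------------------------------------------------------------------

@dataclass
class SoilGridSet:
    """Per-element soil concentration rasters on one common grid."""

    grids: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("SoilGridSet needs at least one element grid")
        first = self.template
        for name, g in self.grids.items():
            if not first.same_grid(g):
                raise ValueError(f"grid for {name!r} not aligned with the common grid")

    @property
    def elements(self) -> list[str]:
        return list(self.grids)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.grids.values()))

    def __getitem__(self, element: str) -> RasterGrid:
        return self.grids[element]

    def write_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, g in self.grids.items():
            write_raster(g, directory / f"soil_{name}.asc")

    @classmethod
    def read_dir(cls, directory: str | Path, elements: Iterable[str]) -> "SoilGridSet":
        directory = Path(directory)
        return cls({e: read_raster(directory / f"soil_{e}.asc") for e in elements})


# ---------------------------------------------------------------------------
# RangeMask
# ---------------------------------------------------------------------------

@dataclass
class RangeMask:
    """Boolean raster marking cells inside the species range."""

    grid: RasterGrid  # values are 0/1; exposed as .mask

    @property
    def mask(self) -> np.ndarray:
        return self.grid.values.astype(bool)

    @classmethod
    def from_array(cls, template: RasterGrid, mask: np.ndarray) -> "RangeMask":
        return cls(template.copy_with(np.asarray(mask, dtype=float)))

    @classmethod
    def full(cls, template: RasterGrid) -> "RangeMask":
        return cls.from_array(template, np.ones(template.shape, dtype=bool))


def rasterize_range(polygon_geojson: Mapping | str | Path,
                    template: RasterGrid) -> RangeMask:
    """Rasterize a GeoJSON polygon onto the template grid.

    A cell is inside iff its center lies within any polygon. Accepts a
    GeoJSON mapping (Feature, FeatureCollection or bare geometry) or a
    path to a .geojson file.
    """
    if isinstance(polygon_geojson, (str, Path)):
        with open(polygon_geojson) as fh:
            polygon_geojson = json.load(fh)
    geom = _extract_geometry(polygon_geojson)
    if geom.is_empty:
        raise ValueError("empty range geometry")
    lon, lat = template.centers()
    inside = shapely.contains_xy(geom, lon.ravel(), lat.ravel()).reshape(template.shape)
    return RangeMask.from_array(template, inside)


def _extract_geometry(obj: Mapping):
    gtype = obj.get("type")
    if gtype == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in obj["features"]]
        if not geoms:
            raise ValueError("empty range geometry")
        return shapely.union_all(geoms)
    if gtype == "Feature":
        return shapely_shape(obj["geometry"])
    return shapely_shape(obj)
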