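"""Shared raster geometry, polygon rasterization, and layer-stack algebra.

Every spatial object in the pipeline lives on one regular longitude/latitude
grid (WGS84 degrees).  The grid follows the top-left-origin raster
convention: row 0 touches the northern edge of the extent, column 0 the
western edge.  Cells are half-open, ``[west, east)`` in longitude and
``(south, north]`` in latitude, so every in-extent point maps to exactly one
cell and rasterizing the induced cell-center point set is idempotent.

The default grid is the African study window: latitudes 35S..40N and
longitudes 20W..55E at 0.5 degrees, i.e. a 150 x 150 raster.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .errors import ExtentError, GeometryError, GridMismatchError

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "PresenceLayer",
    "LayerStack",
    "cell_of",
    "rasterize_polygons",
    "richness_map",
    "count_networks",
    "read_geojson_layers",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat raster.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max
        Extent in WGS84 degrees.  Extents crossing the antimeridian are
        rejected.
    resolution
        Cell side in degrees; must divide both extent spans exactly.
    """

    lon_min: float = -20.0
    lon_max: float = 55.0
    lat_min: float = -35.0
    lat_max: float = 40.0
    resolution: float = 0.5

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon_min < self.lon_max <= 180.0):
            raise ExtentError(
                f"longitude extent [{self.lon_min}, {self.lon_max}] is invalid; "
                "antimeridian-crossing extents are unsupported"
            )
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ExtentError(
                f"latitude extent [{self.lat_min}, {self.lat_max}] is invalid"
            )
        if self.resolution <= 0:
            raise ExtentError(f"resolution must be positive, got {self.resolution}")
        for span, name in (
            (self.lon_max - self.lon_min, "longitude"),
            (self.lat_max - self.lat_min, "latitude"),
        ):
            n = span / self.resolution
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ExtentError(
                    f"{name} span {span} is not a positive multiple of "
                    f"resolution {self.resolution}"
                )

    @property
    def n_rows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def n_cols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.lon_min + (col + 0.5) * self.resolution
        lat = self.lat_max - (row + 0.5) * self.resolution
        return lon, lat

    def center_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude of every cell center, each shaped (n_rows, n_cols)."""
        lons = self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution
        lats = self.lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution
        return np.meshgrid(lons, lats)

    def contains(self, lon, lat):
        """Vectorized in-extent test honouring the half-open cell convention."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon < self.lon_max)
            & (lat > self.lat_min)
            & (lat <= self.lat_max)
        )


def cell_of(lon: float, lat: float, spec: GridSpec) -> tuple[int, int]:
    """Map a point to its (row, col) cell index.

    Row 0 is the northern edge, column 0 the western edge.  Cells are
    ``[west, east)`` x ``(south, north]``; points on the eastern or southern
    extent edge are out of extent.
    """
    if not bool(spec.contains(lon, lat)):
        raise ExtentError(
            f"point (lon={lon}, lat={lat}) is outside the grid extent "
            f"lon [{spec.lon_min}, {spec.lon_max}), lat ({spec.lat_min}, {spec.lat_max}]"
        )
    col = math.floor((lon - spec.lon_min) / spec.resolution)
    # (south, north] in latitude: a point on an interior cell boundary belongs
    # to the cell whose *north* edge it touches (the southern one).
    row = math.floor((spec.lat_max - lat) / spec.resolution)
    return min(row, spec.n_rows - 1), min(col, spec.n_cols - 1)


def cells_of(lon: np.ndarray, lat: np.ndarray, spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`cell_of`; callers must pre-filter to in-extent points."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    col = np.floor((lon - spec.lon_min) / spec.resolution).astype(int)
    row = np.floor((spec.lat_max - lat) / spec.resolution).astype(int)
    return np.clip(row, 0, spec.n_rows - 1), np.clip(col, 0, spec.n_cols - 1)


@dataclass
class PresenceLayer:
    """Boolean presence grid for one species, aligned to a GridSpec."""

    species_id: str
    grid: np.ndarray
    spec: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.shape != self.spec.shape:
            raise GridMismatchError(
                f"layer {self.species_id!r}: grid shape {self.grid.shape} "
                f"does not match GridSpec shape {self.spec.shape}"
            )

    @property
    def range_size(self) -> int:
        """Number of presence cells."""
        return int(self.grid.sum())


@dataclass
class LayerStack:
    """Ordered per-species presence layers sharing one GridSpec."""

    spec: GridSpec
    layers: list[PresenceLayer]

    def __post_init__(self) -> None:
        ids = [ly.species_id for ly in self.layers]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GridMismatchError(f"duplicate species ids in stack: {dupes}")
        for ly in self.layers:
            if ly.spec != self.spec:
                raise GridMismatchError(
                    f"layer {ly.species_id!r} uses a different GridSpec"
                )

    @property
    def species_ids(self) -> list[str]:
        return [ly.species_id for ly in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, species_id: str) -> PresenceLayer:
        for ly in self.layers:
            if ly.species_id == species_id:
                return ly
        raise KeyError(species_id)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.species_ids

    def as_array(self) -> np.ndarray:
        """Stack all layers into a (n_species, n_rows, n_cols) boolean array."""
        if not self.layers:
            return np.zeros((0,) + self.spec.shape, dtype=bool)
        return np.stack([ly.grid for ly in self.layers])


def rasterize_polygons(
    geometries: dict[str, BaseGeometry],
    spec: GridSpec,
    touch: bool = False,
) -> LayerStack:
    """Rasterize one (multi)polygon per species onto the grid.

    A cell is marked present iff the geometry covers the cell *center*
    (boundary counts).  With ``touch=True`` a cell is present iff the
    geometry intersects the cell rectangle at all.  Species whose geometry
    covers no cell yield an all-false layer and a warning.
    """
    lon_grid, lat_grid = spec.center_arrays()
    centers = shapely.points(lon_grid.ravel(), lat_grid.ravel())
    if touch:
        half = spec.resolution / 2.0
        boxes = shapely.box(
            lon_grid.ravel() - half,
            lat_grid.ravel() - half,
            lon_grid.ravel() + half,
            lat_grid.ravel() + half,
        )
    layers = []
    for species_id, geom in geometries.items():
        if geom is None:
            raise GeometryError(f"species {species_id!r}: geometry is missing")
        if not isinstance(geom, BaseGeometry):
            raise GeometryError(
                f"species {species_id!r}: expected a shapely geometry, got {type(geom)}"
            )
        if not geom.is_empty and not geom.is_valid:
            raise GeometryError(f"species {species_id!r}: invalid geometry")
        bounds = shapely.bounds(geom)
        if not geom.is_empty and (bounds[0] < -180.0 or bounds[2] > 180.0):
            raise GeometryError(
                f"species {species_id!r}: geometry extends beyond +-180 degrees "
                "longitude (antimeridian-crossing inputs are unsupported)"
            )
        if geom.is_empty:
            mask = np.zeros(lon_grid.size, dtype=bool)
        elif touch:
            mask = shapely.intersects(geom, boxes)
        else:
            mask = shapely.covers(geom, centers)
        grid = mask.reshape(spec.shape)
        if not geom.is_empty and not grid.any():
            logger.warning(
                "species %r: polygon covers no cell %s on this grid; layer is all-false",
                species_id,
                "rectangle" if touch else "center",
            )
        layers.append(PresenceLayer(species_id, grid, spec))
    return LayerStack(spec, layers)


def richness_map(stack: LayerStack) -> np.ndarray:
    """Per-cell count of present species (the stacked-range richness raster)."""
    return stack.as_array().sum(axis=0).astype(int)


def count_networks(stack: LayerStack) -> int:
    """Number of cells holding at least one species.

    This is the denominator of every "local networks" statistic: each
    occupied cell induces one local food web from the metaweb.
    """
    return int((richness_map(stack) > 0).sum())


# ---------------------------------------------------------------------------
# I/O: GeoJSON polygons in, ESRI ASCII grids out (plain-text raster format).
# ---------------------------------------------------------------------------

def read_geojson_layers(
    path: str, species_property: str = "species"
) -> dict[str, BaseGeometry]:
    """Read one (multi)polygon per species from a GeoJSON FeatureCollection.

    Features sharing a species name are unioned.  The species name is taken
    from ``properties[species_property]``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeometryError(f"{path}: expected a GeoJSON FeatureCollection")
    out: dict[str, BaseGeometry] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        name = props.get(species_property)
        if name is None:
            raise GeometryError(
                f"{path}: feature lacks the {species_property!r} property"
            )
        geom = shapely.geometry.shape(feat["geometry"])
        out[name] = geom if name not in out else shapely.union(out[name], geom)
    return out


def write_ascii_grid(path: str, grid: np.ndarray, spec: GridSpec, nodata: int = -9999) -> None:
    """Write a raster as an ESRI ASCII grid georeferenced to the GridSpec."""
    grid = np.asarray(grid)
    if grid.shape != spec.shape:
        raise GridMismatchError(
            f"grid shape {grid.shape} does not match GridSpec shape {spec.shape}"
        )
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.lon_min}\n")
        fh.write(f"yllcorner {spec.lat_min}\n")
        fh.write(f"cellsize {spec.resolution}\n")
        fh.write(f"NODATA_value {nodata}\n")
        fmt = "%d" if np.issubdtype(grid.dtype, np.integer) or grid.dtype == bool else "%.6g"
        np.savetxt(fh, grid.astype(int) if grid.dtype == bool else grid, fmt=fmt)


def read_ascii_grid(path: str) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata values become 0."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].split() and not _is_number(lines[i].split()[0]):
        key, value = lines[i].split()[:2]
        header[key.lower()] = float(value)
        i += 1
    grid = np.loadtxt(lines[i:])
    grid = np.atleast_2d(grid)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if grid.shape != (nrows, ncols):
        raise GridMismatchError(
            f"{path}: data shape {grid.shape} disagrees with header ({nrows}, {ncols})"
        )
    res = header["cellsize"]
    lon_min = header["xllcorner"]
    lat_min = header["yllcorner"]
    spec = GridSpec(lon_min, lon_min + ncols * res, lat_min, lat_min + nrows * res, res)
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, 0, grid)
    return grid, spec


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
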