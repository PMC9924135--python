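"""Point-occurrence cleaning, pixelization, and range validation.

Occurrence records (GBIF-style: species, longitude, latitude, year) are
filtered, binned to presence pixels (a cell with >= 1 record counts once,
removing repeated-sampling effects), and compared against the original and
trophically adjusted ranges of each species.  The "null island" filter
drops records in the +-2 degree box around (0, 0), a common geocoding-error
signature; the temporal filter keeps post-2000 records only.

Distances for the prey-mobility buffer are great-circle (haversine,
spherical Earth of radius 6371 km) from occurrence points to cell centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .gridspace import GridSpec, PresenceLayer, cells_of

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationRecord",
    "load_occurrences",
    "clean_occurrences",
    "pixelize",
    "validate",
    "buffer_recovery",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0

#: accepted column spellings -> canonical name
COLUMN_ALIASES = {
    "species": "species",
    "scientificname": "species",
    "decimallongitude": "lon",
    "longitude": "lon",
    "lon": "lon",
    "decimallatitude": "lat",
    "latitude": "lat",
    "lat": "lat",
    "year": "year",
}

NULL_ISLAND_BOX = (-2.0, 2.0, -2.0, 2.0)  # lon_min, lon_max, lat_min, lat_max


def load_occurrences(path: str) -> pd.DataFrame:
    """Read an occurrence CSV, accepting GBIF simple-download column names.

    Returns a frame with canonical columns ``species, lon, lat, year``.
    """
    df = pd.read_csv(path)
    renames = {}
    for col in df.columns:
        canon = COLUMN_ALIASES.get(col.strip().lower())
        if canon is not None and canon not in renames.values():
            renames[col] = canon
    df = df.rename(columns=renames)
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing occurrence columns {sorted(missing)}")
    if "year" not in df.columns:
        df["year"] = np.nan
    return df[["species", "lon", "lat", "year"]]


def clean_occurrences(
    records: pd.DataFrame,
    spec: GridSpec,
    min_year: int = 2001,
    null_island_box: tuple[float, float, float, float] | None = NULL_ISLAND_BOX,
) -> pd.DataFrame:
    """Apply the coordinate, extent, null-island, and temporal filters.

    Keeps records that (i) have both coordinates, (ii) fall inside the grid
    extent, (iii) are not inside the null-island box (closed interval), and
    (iv) have a year >= ``min_year``.  Per-filter drop counts are logged.
    The operation is idempotent.
    """
    df = records.copy()
    n0 = len(df)
    has_coords = df["lon"].notna() & df["lat"].notna()
    df = df[has_coords]
    n1 = len(df)
    in_extent = spec.contains(df["lon"].to_numpy(), df["lat"].to_numpy())
    df = df[in_extent]
    n2 = len(df)
    if null_island_box is not None:
        lon0, lon1, lat0, lat1 = null_island_box
        in_box = (
            (df["lon"] >= lon0)
            & (df["lon"] <= lon1)
            & (df["lat"] >= lat0)
            & (df["lat"] <= lat1)
        )
        df = df[~in_box]
    n3 = len(df)
    year = pd.to_numeric(df["year"], errors="coerce")
    df = df[year.notna() & (year >= min_year)]
    n4 = len(df)
    logger.info(
        "clean_occurrences: %d records -> dropped %d missing-coords, %d out-of-extent, "
        "%d null-island, %d pre-%d/undated -> %d kept",
        n0, n0 - n1, n1 - n2, n2 - n3, n3 - n4, min_year, n4,
    )
    return df.reset_index(drop=True)


def pixelize(records: pd.DataFrame, spec: GridSpec) -> dict[str, PresenceLayer]:
    """Convert cleaned records to one boolean presence layer per species.

    Multiple records in one cell count once; species with no in-extent
    records get an all-false layer only if present in the input frame.
    """
    layers: dict[str, PresenceLayer] = {}
    for species, group in records.groupby("species", sort=True):
        grid = np.zeros(spec.shape, dtype=bool)
        lon = group["lon"].to_numpy(dtype=float)
        lat = group["lat"].to_numpy(dtype=float)
        ok = spec.contains(lon, lat)
        rows, cols = cells_of(lon[ok], lat[ok], spec)
        grid[rows, cols] = True
        layers[str(species)] = PresenceLayer(str(species), grid, spec)
    return layers


@dataclass(frozen=True)
class ValidationRecord:
    """Agreement of a species' occurrence pixels with its two range versions."""

    species_id: str
    n_gbif_pixels: int
    prop_in_original: float
    prop_in_adjusted: float

    @property
    def delta(self) -> float:
        """Drop in agreement caused by the trophic adjustment (>= 0)."""
        return self.prop_in_original - self.prop_in_adjusted

    def __post_init__(self) -> None:
        if self.prop_in_adjusted > self.prop_in_original + 1e-12:
            raise ValueError(
                f"{self.species_id!r}: proportion in the adjusted range exceeds the "
                "proportion in the original range, which pruning cannot produce"
            )


def validate(
    gbif_layer: PresenceLayer,
    original: PresenceLayer,
    adjusted: PresenceLayer,
) -> ValidationRecord:
    """Proportion of occurrence pixels inside the original and adjusted ranges."""
    n = gbif_layer.range_size
    if n == 0:
        raise UndefinedStatisticError(
            f"{gbif_layer.species_id!r}: no occurrence pixels; proportions undefined"
        )
    prop_orig = int((gbif_layer.grid & original.grid).sum()) / n
    prop_adj = int((gbif_layer.grid & adjusted.grid).sum()) / n
    return ValidationRecord(gbif_layer.species_id, n, prop_orig, prop_adj)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth; broadcasts."""
    lon1, lat1, lon2, lat2 = map(np.radians, map(np.asarray, (lon1, lat1, lon2, lat2)))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def buffer_recovery(
    removed_area: PresenceLayer,
    prey_records: pd.DataFrame,
    radius_km: float,
    spec: GridSpec | None = None,
) -> tuple[float, float]:
    """Prey-mobility analysis of a predator's pruned-away range.

    ``removed_area`` is the predator's original-minus-adjusted layer.
    Returns ``(points_in_removed, area_recovered)``:

    - share of prey occurrence points whose cell lies in the removed area;
    - share of removed-area cells within ``radius_km`` (great-circle, to
      cell centers) of at least one prey point — the part of the mismatch
      that prey mobility could plausibly explain.
    """
    spec = spec or removed_area.spec
    n_removed = removed_area.range_size
    if n_removed == 0:
        raise UndefinedStatisticError(
            "removed area is empty; buffer recovery undefined"
        )
    lon = prey_records["lon"].to_numpy(dtype=float)
    lat = prey_records["lat"].to_numpy(dtype=float)
    ok = spec.contains(lon, lat)
    lon, lat = lon[ok], lat[ok]
    if lon.size == 0:
        return 0.0, 0.0
    rows, cols = cells_of(lon, lat, spec)
    points_in = float(removed_area.grid[rows, cols].mean())

    cell_rows, cell_cols = np.nonzero(removed_area.grid)
    clon = spec.lon_min + (cell_cols + 0.5) * spec.resolution
    clat = spec.lat_max - (cell_rows + 0.5) * spec.resolution
    d = haversine_km(clon[:, None], clat[:, None], lon[None, :], lat[None, :])
    covered = (d <= radius_km).any(axis=1)
    return points_in, float(covered.mean())
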