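"""Georeferenced presence records: CSV I/O and spatial thinning."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import RasterStack

EARTH_RADIUS_KM = 6371.0088


@dataclass
class OccurrenceSet:
    """Presence points with a provenance tag per point.

    Coordinates are WGS84 lon/lat in decimal degrees.
    """

    lons: np.ndarray
    lats: np.ndarray
    species: str = "species"
    source: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.lons = np.atleast_1d(np.asarray(self.lons, dtype=float))
        self.lats = np.atleast_1d(np.asarray(self.lats, dtype=float))
        if self.lons.shape != self.lats.shape:
            raise ValueError("lons and lats must have the same length")
        if not (np.isfinite(self.lons).all() and np.isfinite(self.lats).all()):
            raise ValueError("coordinates must be finite")
        if np.any(np.abs(self.lons) > 180) or np.any(np.abs(self.lats) > 90):
            raise ValueError("coordinates outside lon [-180,180] / lat [-90,90]")
        if not self.source:
            self.source = ["synthetic"] * len(self.lons)

    def __len__(self) -> int:
        return len(self.lons)

    def take(self, idx) -> "OccurrenceSet":
        idx = np.asarray(idx)
        return OccurrenceSet(self.lons[idx], self.lats[idx], self.species,
                             [self.source[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species, "lon": self.lons, "lat": self.lats})

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path, source: str = "portal") -> "OccurrenceSet":
        df = pd.read_csv(path)
        missing = {"species", "lon", "lat"} - set(df.columns)
        if missing:
            raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
        species = str(df["species"].iloc[0]) if len(df) else "species"
        return cls(df["lon"].to_numpy(), df["lat"].to_numpy(), species,
                   [source] * len(df))


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in kilometres."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin_occurrences(occ: OccurrenceSet, stack: RasterStack,
                     min_dist_km: float = 0.0) -> OccurrenceSet:
    """Spatially thin presences: one point per raster cell, then a greedy
    minimum-distance pass.

    Points are visited in input order; a point is kept iff its cell is not
    already taken and it lies at least ``min_dist_km`` (great-circle) from
    every point kept so far.  Deterministic given input order; thinning an
    already-thinned set is the identity.
    """
    if min_dist_km < 0:
        raise ValueError("min_dist_km must be >= 0")
    if len(occ) == 0:
        return occ
    rows, cols = stack.georef.cell_index(occ.lons, occ.lats)
    kept: list[int] = []
    seen_cells: set[tuple[int, int]] = set()
    for i in range(len(occ)):
        cell = (int(rows[i]), int(cols[i]))
        if cell in seen_cells:
            continue
        if min_dist_km > 0 and kept:
            d = great_circle_km(occ.lons[kept], occ.lats[kept],
                                occ.lons[i], occ.lats[i])
            if np.any(d < min_dist_km):
                continue
        kept.append(i)
        seen_cells.add(cell)
    return occ.take(kept)


def clip_to_bounds(occ: OccurrenceSet, lon_min: float, lat_min: float,
                   lon_max: float, lat_max: float) -> OccurrenceSet:
    """Keep points inside a bounding box (inclusive edges)."""
    keep = ((occ.lons >= lon_min) & (occ.lons <= lon_max)
            & (occ.lats >= lat_min) & (occ.lats <= lat_max))
    return occ.take(np.nonzero(keep)[0])
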