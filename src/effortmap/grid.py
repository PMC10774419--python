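"""Half-degree grid with per-cell attribute masks.

Cells are identified by the (lat, lon) coordinates of their centres,
which lie on the lattice of odd multiples of 0.25 degrees (−89.75 …
89.75 latitude, −179.75 … 179.75 longitude at global extent).  A
:class:`Grid` covers a rectangular sub-window of that lattice and holds
boolean per-cell attributes (coastal flag, trawl-ban flag, depth class)
used as constraint masks during effort allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import CELL_SIZE_DEG


def _centres(lo: float, hi: float, cell: float) -> np.ndarray:
    n = (hi - lo) / cell
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"cell size {cell} does not divide extent [{lo}, {hi}] evenly")
    n = int(round(n))
    return lo + cell * (np.arange(n) + 0.5)


@dataclass
class Grid:
    """A regular lat/lon grid of square cells addressed by centre coordinates."""

    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    cell_size: float = CELL_SIZE_DEG
    lats: np.ndarray = field(init=False)
    lons: np.ndarray = field(init=False)
    coastal: np.ndarray = field(init=False)    # (nlat, nlon) bool
    trawl_ban: np.ndarray = field(init=False)  # (nlat, nlon) bool

    def __post_init__(self) -> None:
        self.lats = _centres(self.lat_min, self.lat_max, self.cell_size)
        self.lons = _centres(self.lon_min, self.lon_max, self.cell_size)
        if self.nlat * self.nlon <= 1:
            raise ValueError("degenerate grid: more than one cell is required")
        self.coastal = np.zeros((self.nlat, self.nlon), dtype=bool)
        self.trawl_ban = np.zeros((self.nlat, self.nlon), dtype=bool)

    @property
    def nlat(self) -> int:
        return len(self.lats)

    @property
    def nlon(self) -> int:
        return len(self.lons)

    # ---- coordinate <-> index -------------------------------------------
    def lat_index(self, lat: np.ndarray | float) -> np.ndarray:
        idx = np.round((np.asarray(lat) - self.lat_min) / self.cell_size - 0.5).astype(int)
        return idx

    def lon_index(self, lon: np.ndarray | float) -> np.ndarray:
        idx = np.round((np.asarray(lon) - self.lon_min) / self.cell_size - 0.5).astype(int)
        return idx

    def on_lattice(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """True where (lat, lon) are valid cell centres of this grid."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        ilat = (lat - self.lat_min) / self.cell_size - 0.5
        ilon = (lon - self.lon_min) / self.cell_size - 0.5
        ok_lat = (np.abs(ilat - np.round(ilat)) < 1e-6) & (ilat > -0.5) & (ilat < self.nlat - 0.5)
        ok_lon = (np.abs(ilon - np.round(ilon)) < 1e-6) & (ilon > -0.5) & (ilon < self.nlon - 0.5)
        return ok_lat & ok_lon

    def cell_id(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Flat integer id (row-major) for each (lat, lon) centre pair."""
        return self.lat_index(lat) * self.nlon + self.lon_index(lon)

    def id_to_latlon(self, cell_id: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id)
        return self.lats[cell_id // self.nlon], self.lons[cell_id % self.nlon]
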