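"""Terrain ruggedness: TRI rasters, settlement-level zonal means, quantile groups.

The Terrain Ruggedness Index of a cell is the square root of the summed
squared elevation differences to its eight neighbours (Riley's formulation):

    TRI(c) = sqrt( sum_{n in N8(c)} (z_n - z_c)^2 )        [metres]

Border cells and cells with any missing neighbour get nodata — a partial
neighbourhood would bias TRI low.  Settlement-level ruggedness is the mean of
valid TRI cells within a circular buffer, and settlements are then classified
into k ruggedness quantile groups (group k = most rugged).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .settlements import SettlementTable

log = logging.getLogger(__name__)

ASCII_NODATA = -9999.0


@dataclass
class Raster:
    """A north-up grid: row 0 is the northernmost row, values in metres.

    ``cellsize_m`` is the square cell edge in metres; the origin
    (``xll_km``, ``yll_km``) is the outer corner of the lower-left cell in the
    settlement coordinate frame (planar kilometres).  Missing cells are NaN.
    """

    values: np.ndarray
    cellsize_m: float
    xll_km: float = 0.0
    yll_km: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("raster must be 2-D")
        if self.cellsize_m <= 0:
            raise ValidationError("cellsize_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cellsize_km(self) -> float:
        return self.cellsize_m / 1000.0

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates in km, shaped like the raster."""
        nrows, ncols = self.shape
        cs = self.cellsize_km
        x = self.xll_km + (np.arange(ncols) + 0.5) * cs
        y = self.yll_km + (nrows - np.arange(nrows) - 0.5) * cs
        return np.meshgrid(x, y)


# DEM and TRI rasters share the container; names kept for readability.
DEMGrid = Raster
TRIGrid = Raster


def tri(dem: Raster) -> Raster:
    """Riley's TRI on every interior cell with a complete valid neighbourhood."""
    z = dem.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValidationError("TRI needs a grid of at least 3x3 cells")
    if np.isnan(z).all():
        raise ValidationError("all-nodata grid")
    out = np.full_like(z, np.nan)
    c = z[1:-1, 1:-1]
    acc = np.zeros_like(c)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nb = z[1 + di : z.shape[0] - 1 + di, 1 + dj : z.shape[1] - 1 + dj]
            acc = acc + (nb - c) ** 2  # NaN neighbour poisons the cell
    out[1:-1, 1:-1] = np.sqrt(acc)
    return Raster(out, dem.cellsize_m, dem.xll_km, dem.yll_km)


def settlement_tri(
    tri_grid: Raster, settlements: SettlementTable, radius_km: float = 2.0
) -> pd.DataFrame:
    """Mean TRI of valid cells whose centres lie within ``radius_km`` of each point.

    A settlement whose buffer contains no valid cell falls back to the nearest
    valid cell (logged); a settlement outside the raster extent entirely is an
    error.
    """
    if radius_km <= 0:
        raise ValidationError("radius_km must be positive")
    nrows, ncols = tri_grid.shape
    cs = tri_grid.cellsize_km
    x0, y0 = tri_grid.xll_km, tri_grid.yll_km
    xmax, ymax = x0 + ncols * cs, y0 + nrows * cs
    pts = settlements.coords
    outside = [
        sid
        for sid, (px, py) in zip(settlements.ids, pts)
        if not (x0 <= px <= xmax and y0 <= py <= ymax)
    ]
    if outside:
        raise ValidationError(f"settlements outside raster extent: {outside[:10]}")

    cx, cy = tri_grid.cell_centres()
    valid = np.isfinite(tri_grid.values)
    vx, vy = cx[valid], cy[valid]
    vtri = tri_grid.values[valid]
    if vtri.size == 0:
        raise ValidationError("TRI raster has no valid cells")

    means = np.empty(settlements.n)
    for i, (px, py) in enumerate(pts):
        d2 = (vx - px) ** 2 + (vy - py) ** 2
        mask = d2 <= radius_km**2
        if mask.any():
            means[i] = vtri[mask].mean()
        else:
            j = int(np.argmin(d2))
            means[i] = vtri[j]
            log.info(
                "settlement %s: empty TRI buffer, using nearest valid cell",
                settlements.ids[i],
            )
    return pd.DataFrame({"id": settlements.ids, "mean_tri_m": means})


def quantile_groups(values: pd.Series, k: int = 5) -> pd.Series:
    """Rank-based quantile classification into groups 1..k (k = largest values).

    Settlements are ranked ascending with ties broken by id, and the group of
    rank r out of n is ceil(k * r / n), so group sizes differ by at most one
    when values are distinct.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    n = len(values)
    if n == 0:
        raise ValidationError("no values to classify")
    if n < k:
        raise ValidationError(f"cannot form {k} non-empty groups from {n} values")
    if values.nunique() == 1:
        warnings.warn("all values identical; quantile groups fall back to id order",
                      stacklevel=2)
    order = sorted(values.index, key=lambda sid: (values[sid], str(sid)))
    groups = pd.Series(0, index=values.index, dtype=int)
    for rank, sid in enumerate(order, start=1):
        groups[sid] = math.ceil(k * rank / n)
    return groups


def ruggedness_table(
    tri_grid: Raster,
    settlements: SettlementTable,
    radius_km: float = 2.0,
    k: int = 5,
) -> pd.DataFrame:
    """Convenience: buffer means plus quantile group, columns (id, mean_tri_m, tri_group)."""
    table = settlement_tri(tri_grid, settlements, radius_km)
    vals = table.set_index("id")["mean_tri_m"]
    table["tri_group"] = quantile_groups(vals, k=k).reindex(table["id"]).to_numpy()
    return table


# -- ESRI ASCII grid I/O --------------------------------------------------
# Header coordinates and cellsize are written in kilometres (the settlement
# frame); cell values stay in metres.

def write_ascii_grid(raster: Raster, path) -> None:
    nrows, ncols = raster.shape
    vals = np.where(np.isfinite(raster.values), raster.values, ASCII_NODATA)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xll_km!r}\n")
        fh.write(f"yllcorner {raster.yll_km!r}\n")
        fh.write(f"cellsize {raster.cellsize_km!r}\n")
        fh.write(f"NODATA_value {ASCII_NODATA!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> Raster:
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
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
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValidationError(f"ASCII grid missing header field {key}")
    data = np.loadtxt(lines[i:].__iter__(), dtype=float)
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValidationError(
            f"ASCII grid body {data.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", ASCII_NODATA)
    data = np.where(data == nodata, np.nan, data)
    return Raster(
        data,
        cellsize_m=header["cellsize"] * 1000.0,
        xll_km=header.get("xllcorner", 0.0),
        yll_km=header.get("yllcorner", 0.0),
    )
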