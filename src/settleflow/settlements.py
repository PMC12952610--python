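"""Settlement tables: identifiers, coordinates, region labels and census populations.

A :class:`SettlementTable` wraps a pandas DataFrame with the canonical column
layout ``id, name, x, y, region, pop_<wave>...`` where each ``pop_<wave>``
column holds the population counted at one census wave.  Coordinates are
either planar kilometres (``crs="planar_km"``) or geographic degrees
(``crs="lonlat"``, x = longitude, y = latitude); the convention travels with
the table so distance code never has to guess.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Recognised coordinate conventions.
CRS_PLANAR = "planar_km"
CRS_LONLAT = "lonlat"

_POP_PREFIX = "pop_"


@dataclass
class SettlementTable:
    """Per-settlement attributes plus populations at one or more census waves."""

    data: pd.DataFrame
    crs: str = CRS_PLANAR

    def __post_init__(self) -> None:
        if self.crs not in (CRS_PLANAR, CRS_LONLAT):
            raise ValidationError(f"unknown coordinate convention {self.crs!r}")
        required = ["id", "x", "y"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"settlement table missing columns {missing}")
        if "name" not in self.data.columns:
            self.data = self.data.assign(name=self.data["id"].astype(str))
        if "region" not in self.data.columns:
            self.data = self.data.assign(region="all")
        ids = self.data["id"].astype(str)
        dup = ids[ids.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate settlement ids: {sorted(dup)[:10]}")
        self.data = self.data.reset_index(drop=True)
        self.data["id"] = ids.to_numpy()
        for col in self.wave_columns():
            vals = pd.to_numeric(self.data[col], errors="coerce")
            if vals.isna().any():
                rows = list(self.data.index[vals.isna()][:10])
                raise ValidationError(f"non-numeric populations in {col}, rows {rows}")
            if (vals < 0).any():
                rows = list(self.data.index[vals < 0][:10])
                raise ValidationError(f"negative populations in {col}, rows {rows}")

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> np.ndarray:
        return self.data["id"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        """n x 2 array of (x, y)."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def regions(self) -> pd.Series:
        return self.data.set_index("id")["region"]

    def wave_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(_POP_PREFIX)]

    def waves(self) -> list[str]:
        return [c[len(_POP_PREFIX):] for c in self.wave_columns()]

    def population(self, wave: str) -> pd.Series:
        col = _POP_PREFIX + str(wave)
        if col not in self.data.columns:
            raise ValidationError(
                f"no census wave {wave!r}; available: {self.waves()}"
            )
        return self.data.set_index("id")[col].astype(float)

    def with_population(self, wave: str, values: pd.Series | np.ndarray) -> "SettlementTable":
        df = self.data.copy()
        if isinstance(values, pd.Series):
            values = values.reindex(df["id"]).to_numpy()
        df[_POP_PREFIX + str(wave)] = np.asarray(values)
        return SettlementTable(df, crs=self.crs)


def read_settlements(path, crs: str | None = None) -> SettlementTable:
    """Read a settlement CSV.

    The file may carry its coordinate convention in a leading comment line of
    the form ``# crs: planar_km``; an explicit ``crs`` argument overrides it,
    and the default is planar kilometres.
    """
    file_crs = None
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
        if head.startswith("#"):
            if "crs:" in head:
                file_crs = head.split("crs:", 1)[1].strip()
            body = fh.read()
        else:
            body = head + fh.read()
    df = pd.read_csv(io.StringIO(body), dtype={"id": str})
    table = SettlementTable(df, crs=crs or file_crs or CRS_PLANAR)
    # populations must be whole counts on disk
    for col in table.wave_columns():
        vals = table.data[col].astype(float)
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError(f"non-integer populations in column {col}")
        table.data[col] = vals.astype(np.int64)
    return table


def write_settlements(table: SettlementTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# crs: {table.crs}\n")
        table.data.to_csv(fh, index=False)
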