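"""Grid conventions and the shared quarterly-field container.

The analysis lives on a coarse regular latitude-longitude grid (5 degrees by
default) crossed with the four annual quarters.  Longitudes are kept in the
[0, 360) convention internally so that the Pacific basin -- which straddles
the antimeridian -- is contiguous; readers accept both [-180, 180] and
[0, 360) inputs and remap.

Cells are half-open intervals ``[lat_lo, lat_lo + cell) x [lon_lo, lon_lo +
cell)`` anchored at multiples of the cell size, with latitude 90 folded into
the topmost row so that every valid coordinate belongs to exactly one cell.

A :class:`QuarterlyField` is a sparse mapping ``(cell, quarter) -> value``.
Absent entries are *no data* and are excluded from every sum and
normalization; a stored ``0.0`` is a real zero.  The same container holds
use-intensity surfaces, hooks, relative probabilities and interaction
indices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Iterator, Mapping, NamedTuple

import pandas as pd

__all__ = [
    "GridSpec",
    "CellIndex",
    "QuarterlyField",
    "QUARTERS",
    "bin_position",
    "quarter_of",
    "field_sum",
    "read_field",
    "write_field",
    "field_to_geojson",
]

#: The four annual quarters: Q1 = Jan-Mar, Q2 = Apr-Jun, Q3 = Jul-Sep, Q4 = Oct-Dec.
QUARTERS = (1, 2, 3, 4)


class CellIndex(NamedTuple):
    """Lower-edge coordinates of one grid cell.

    ``lat_lo`` and ``lon_lo`` are the cell's lower edges in degrees;
    ``lon_lo`` is always in [0, 360).  The cell covers the half-open box
    ``[lat_lo, lat_lo + cell_size) x [lon_lo, lon_lo + cell_size)``.
    """

    lat_lo: float
    lon_lo: float


@dataclass(frozen=True)
class GridSpec:
    """Regular lat-lon grid definition.

    Parameters
    ----------
    cell_size_deg:
        Cell edge length in degrees.  Must divide both 360 and 180 evenly.
        The default of 5.0 matches the coarsest resolution at which public
        longline effort statistics are reported basin-wide.
    lon_origin:
        Longitude of the western edge of the first column, in [0, 360).
        0 anchors cells at multiples of the cell size.
    """

    cell_size_deg: float = 5.0
    lon_origin: float = 0.0

    def __post_init__(self) -> None:
        cs = self.cell_size_deg
        if not (math.isfinite(cs) and cs > 0):
            raise ValueError(f"cell_size_deg must be positive, got {cs!r}")
        if not math.isclose(360.0 % cs, 0.0, abs_tol=1e-9) and not math.isclose(
            360.0 % cs, cs, abs_tol=1e-9
        ):
            raise ValueError(f"360 must be divisible by cell_size_deg, got {cs}")
        if not math.isclose(180.0 % cs, 0.0, abs_tol=1e-9) and not math.isclose(
            180.0 % cs, cs, abs_tol=1e-9
        ):
            raise ValueError(f"180 must be divisible by cell_size_deg, got {cs}")
        if not (0.0 <= self.lon_origin < 360.0):
            raise ValueError(f"lon_origin must be in [0, 360), got {self.lon_origin}")


def wrap_lon(lon: float) -> float:
    """Map a longitude from either convention into [0, 360)."""
    out = lon % 360.0
    # guard against floating -1e-16 % 360 -> 360.0
    return 0.0 if out >= 360.0 else out


def bin_position(lat: float, lon: float, spec: GridSpec | None = None) -> CellIndex:
    """Assign a point to its grid cell.

    Longitude may be given in [-180, 180] or [0, 360); it is remapped to
    [0, 360).  ``lat = 90`` is folded into the topmost row so the pole is
    not orphaned by the half-open convention.

    Raises
    ------
    ValueError
        If either coordinate is non-finite or latitude is out of range.
    """
    if spec is None:
        spec = GridSpec()
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise ValueError(f"non-finite coordinates: lat={lat!r}, lon={lon!r}")
    if abs(lat) > 90.0:
        raise ValueError(f"latitude out of range [-90, 90]: {lat!r}")
    cs = spec.cell_size_deg
    lon_w = wrap_lon(lon - spec.lon_origin) + spec.lon_origin
    lat_lo = math.floor(lat / cs) * cs
    lat_lo = min(lat_lo, 90.0 - cs)  # fold lat == 90 into the top row
    lon_lo = math.floor((lon_w - spec.lon_origin) / cs) * cs + spec.lon_origin
    if lon_lo >= 360.0:
        lon_lo -= 360.0
    return CellIndex(lat_lo, lon_lo)


def quarter_of(date: _date) -> int:
    """Annual quarter of a calendar date (Q1 = Jan-Mar ... Q4 = Oct-Dec)."""
    return (date.month - 1) // 3 + 1


@dataclass
class QuarterlyField:
    """Sparse real-valued field over (cell, quarter).

    Entries not present in ``values`` are no-data (masked) and are excluded
    from sums and normalizations.  Values must be finite.
    """

    values: dict[tuple[CellIndex, int], float] = field(default_factory=dict)
    spec: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        for (cell, q), v in self.values.items():
            self._check_key(cell, q)
            if not math.isfinite(v):
                raise ValueError(f"non-finite value {v!r} at {(cell, q)}")

    @staticmethod
    def _check_key(cell: CellIndex, q: int) -> None:
        if q not in QUARTERS:
            raise ValueError(f"quarter must be in {QUARTERS}, got {q!r}")

    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, key: tuple[CellIndex, int]) -> bool:
        return key in self.values

    def __getitem__(self, key: tuple[CellIndex, int]) -> float:
        return self.values[key]

    def get(self, key: tuple[CellIndex, int], default: float | None = None):
        return self.values.get(key, default)

    def items(self) -> Iterator[tuple[tuple[CellIndex, int], float]]:
        return iter(self.values.items())

    def keys(self):
        return self.values.keys()

    def set(self, cell: CellIndex, quarter: int, value: float) -> None:
        self._check_key(cell, quarter)
        if not math.isfinite(value):
            raise ValueError(f"non-finite value {value!r} at {(cell, quarter)}")
        self.values[(cell, quarter)] = float(value)

    def add(self, cell: CellIndex, quarter: int, value: float) -> None:
        """Accumulate ``value`` into a cell-quarter, unmasking it."""
        self._check_key(cell, quarter)
        key = (cell, quarter)
        self.values[key] = self.values.get(key, 0.0) + float(value)

    def copy(self) -> "QuarterlyField":
        return QuarterlyField(dict(self.values), self.spec)

    def scaled(self, factor: float) -> "QuarterlyField":
        return QuarterlyField(
            {k: v * factor for k, v in self.values.items()}, self.spec
        )

    def total(self) -> float:
        """Sum over all non-masked entries (compensated summation)."""
        return math.fsum(self.values.values())

    def merge(self, other: "QuarterlyField") -> "QuarterlyField":
        """Entry-wise sum; a cell-quarter is non-masked if present in either."""
        out = self.copy()
        for (cell, q), v in other.items():
            out.add(cell, q, v)
        return out

    # ---- tabular round trip -------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"lat_lo": c.lat_lo, "lon_lo": c.lon_lo, "quarter": q, "value": v}
            for (c, q), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows, columns=["lat_lo", "lon_lo", "quarter", "value"])

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, spec: GridSpec | None = None
    ) -> "QuarterlyField":
        spec = spec or GridSpec()
        values: dict[tuple[CellIndex, int], float] = {}
        for row in df.itertuples(index=False):
            cell = CellIndex(float(row.lat_lo), wrap_lon(float(row.lon_lo)))
            values[(cell, int(row.quarter))] = float(row.value)
        return cls(values, spec)


def field_sum(f: QuarterlyField) -> float:
    """Sum of a field over all non-masked (cell, quarter) entries."""
    return f.total()


def write_field(f: QuarterlyField, path) -> None:
    """Serialize to delimited text with columns lat_lo, lon_lo, quarter, value."""
    f.to_dataframe().to_csv(path, index=False)


def read_field(path, spec: GridSpec | None = None) -> QuarterlyField:
    # round_trip parsing keeps staged runs bit-identical to in-memory runs
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"lat_lo", "lon_lo", "quarter", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return QuarterlyField.from_dataframe(df, spec)


def field_to_geojson(f: QuarterlyField) -> str:
    """One polygon feature per cell-quarter, for choropleth mapping.

    Longitudes are emitted in the [0, 360) convention used internally;
    mapping tools that want [-180, 180] can shift them downstream.
    """
    cs = f.spec.cell_size_deg
    features = []
    for (cell, q), v in sorted(f.values.items()):
        la, lo = cell.lat_lo, cell.lon_lo
        ring = [
            [lo, la],
            [lo + cs, la],
            [lo + cs, la + cs],
            [lo, la + cs],
            [lo, la],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "lat_lo": la,
                    "lon_lo": lo,
                    "quarter": q,
                    "value": v,
                },
            }
        )
    return json.dumps({"type": "FeatureCollection", "features": features})
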