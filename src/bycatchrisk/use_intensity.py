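"""Inverse-sample-size position weighting and quarterly use-intensity surfaces.

Satellite tracks end at staggered times (battery depletion, tag loss,
mortality), so late relative track days are represented by fewer animals
than early ones.  Left unweighted, pooled positions over-represent the
deployment sites.  The weighting scheme corrects this: the position of
individual *i* of population *j* at relative track day *t* receives

    omega_it = 1 / n_jt

where ``n_jt`` is the number of individuals of population *j* that have a
position estimate at relative day *t*.  Summed over the individuals present
at day *t*, the weights therefore contribute exactly 1 per population per
day -- each tracking day carries equal total evidence regardless of how
many tags were still transmitting.

Unbounded, this rule gives enormous weight to the tail of the single longest
track, so a threshold relative day ``T_j`` (the 85th percentile of the
population's position-day distribution) caps it: positions beyond ``T_j``
receive the same weight as on the threshold day, ``1 / n_{j,T_j}``.

Finally, per-quarter sample sizes of the two populations are balanced: in
each quarter, the population with fewer raw position estimates is inflated
by the ratio x/y of the larger to the smaller count, so that both
populations contribute equal inflated position totals per quarter.

Weighted, thresholded, inflated positions are then summed into 5-degree
cell x quarter bins to give the relative use-intensity surface (one field
per population; all years pooled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .geogrid import CellIndex, GridSpec, QuarterlyField, bin_position, quarter_of
from .tracks import Track

__all__ = [
    "DayCountTable",
    "WeightedPosition",
    "count_individuals_per_day",
    "threshold_day",
    "daily_weight",
    "weight_positions",
    "quarter_inflation",
    "apply_inflation",
    "accumulate_use",
    "use_intensity_fields",
    "diagnostics_table",
]


#: mapping (population, relative day) -> number of individuals with a position
DayCountTable = dict[tuple[str, int], int]


@dataclass
class WeightedPosition:
    """One binned track position carrying its weight and inflation factor.

    ``omega`` is the inverse-sample-size weight after thresholding;
    ``inflation`` is the per-quarter population balancing factor (>= 1).
    The position's final contribution to the use surface is
    ``omega * inflation``.
    """

    turtle_id: str
    population: str
    cell: CellIndex
    quarter: int
    relative_day: int
    omega: float
    inflation: float = 1.0

    @property
    def contribution(self) -> float:
        return self.omega * self.inflation


def count_individuals_per_day(tracks: Iterable[Track]) -> DayCountTable:
    """n_jt: distinct individuals of population j with a day-t position."""
    seen: dict[tuple[str, int], set[str]] = {}
    for tr in tracks:
        for p in tr.points:
            if p.relative_day is None:
                raise ValueError(
                    f"track {tr.turtle_id}: relative days not assigned; "
                    "run assign_relative_days first"
                )
            seen.setdefault((tr.population, p.relative_day), set()).add(tr.turtle_id)
    return {key: len(ids) for key, ids in seen.items()}


def threshold_day(counts: DayCountTable, population: str, q: float = 0.85) -> int:
    """Threshold relative track day T_j for a population.

    T_j is the smallest relative day d such that the cumulative fraction of
    the population's position-days at days <= d reaches q.  Positions past
    T_j are later given the same weight as on day T_j.
    """
    if not 0 < q <= 1:
        raise ValueError(f"q must be in (0, 1], got {q}")
    days = sorted(t for (j, t) in counts if j == population)
    if not days:
        raise ValueError(f"no positions for population {population!r}")
    total = sum(counts[(population, t)] for t in days)
    cum = 0
    for d in days:
        cum += counts[(population, d)]
        if cum / total >= q:
            return d
    return days[-1]  # unreachable for q <= 1, kept for safety


def daily_weight(counts: DayCountTable, population: str, t: int, t_j: int) -> float:
    """omega for a day-t position: 1/n_jt below the threshold, capped above.

    For t <= T_j the weight is ``1 / n_jt``; for t > T_j it is the weight on
    the threshold day, ``1 / n_{j,T_j}``.
    """
    t_eff = min(t, t_j)
    n = counts.get((population, t_eff), 0)
    if n < 1:
        raise ValueError(
            f"inconsistent day-count table: n_({population},{t_eff}) = {n}"
        )
    return 1.0 / n


def weight_positions(
    tracks: Iterable[Track], spec: GridSpec | None = None, q: float = 0.85
) -> tuple[list[WeightedPosition], dict[str, int], DayCountTable]:
    """Bin every track position and attach its thresholded weight.

    Returns the weighted positions, the per-population threshold days T_j,
    and the day-count table (for diagnostics).
    """
    spec = spec or GridSpec()
    tracks = list(tracks)
    counts = count_individuals_per_day(tracks)
    populations = sorted({j for (j, _t) in counts})
    t_j = {j: threshold_day(counts, j, q) for j in populations}
    out: list[WeightedPosition] = []
    for tr in tracks:
        for p in tr.points:
            omega = daily_weight(counts, tr.population, p.relative_day, t_j[tr.population])
            out.append(
                WeightedPosition(
                    turtle_id=tr.turtle_id,
                    population=tr.population,
                    cell=bin_position(p.lat, p.lon, spec),
                    quarter=quarter_of(p.date),
                    relative_day=p.relative_day,
                    omega=omega,
                )
            )
    return out, t_j, counts


def quarter_inflation(
    positions: Iterable[WeightedPosition],
) -> dict[tuple[str, int], float]:
    """Per-quarter population balancing factors.

    In each quarter, the population with fewer *raw* position estimates gets
    the factor x/y (x = larger raw count, y = smaller); the other population
    gets 1.  A quarter where only one population has positions gets 1.
    """
    raw: dict[tuple[str, int], int] = {}
    for wp in positions:
        key = (wp.population, wp.quarter)
        raw[key] = raw.get(key, 0) + 1
    factors: dict[tuple[str, int], float] = {}
    quarters = sorted({q for (_j, q) in raw})
    for q in quarters:
        pops = sorted(j for (j, qq) in raw if qq == q)
        if len(pops) == 1:
            factors[(pops[0], q)] = 1.0
            continue
        counts = {j: raw[(j, q)] for j in pops}
        x = max(counts.values())
        for j in pops:
            y = counts[j]
            factors[(j, q)] = x / y if y < x else 1.0
    return factors


def apply_inflation(
    positions: list[WeightedPosition],
    factors: Mapping[tuple[str, int], float] | None = None,
) -> list[WeightedPosition]:
    """Stamp each position with its quarter's inflation factor (in place)."""
    if factors is None:
        factors = quarter_inflation(positions)
    for wp in positions:
        wp.inflation = factors.get((wp.population, wp.quarter), 1.0)
    return positions


def accumulate_use(
    positions: Iterable[WeightedPosition], spec: GridSpec | None = None
) -> dict[str, QuarterlyField]:
    """Sum position contributions into per-population quarterly fields.

    The value at (cell, quarter) is the sum of ``omega * inflation`` over
    the positions binned there.  Cell-quarters never visited are absent
    (no-data); a visited cell with all weights summing to a positive number
    is the relative use intensity before normalization.
    """
    spec = spec or GridSpec()
    fields: dict[str, QuarterlyField] = {}
    for wp in positions:
        f = fields.setdefault(wp.population, QuarterlyField(spec=spec))
        f.add(wp.cell, wp.quarter, wp.contribution)
    return fields


def use_intensity_fields(
    tracks: Iterable[Track],
    spec: GridSpec | None = None,
    q: float = 0.85,
    inflate: bool = True,
) -> tuple[dict[str, QuarterlyField], pd.DataFrame]:
    """Full weighting pipeline: tracks -> per-population use surfaces.

    Returns the fields plus a diagnostics table (threshold days, per-quarter
    raw counts and inflation factors).
    """
    spec = spec or GridSpec()
    positions, t_j, counts = weight_positions(tracks, spec, q)
    factors = quarter_inflation(positions) if inflate else {}
    apply_inflation(positions, factors)
    fields = accumulate_use(positions, spec)
    diag = diagnostics_table(positions, t_j, factors)
    return fields, diag


def diagnostics_table(
    positions: list[WeightedPosition],
    t_j: Mapping[str, int],
    factors: Mapping[tuple[str, int], float],
) -> pd.DataFrame:
    raw: dict[tuple[str, int], int] = {}
    for wp in positions:
        key = (wp.population, wp.quarter)
        raw[key] = raw.get(key, 0) + 1
    rows = []
    for (j, q), n in sorted(raw.items()):
        rows.append(
            {
                "population": j,
                "quarter": q,
                "n_positions": n,
                "threshold_day": t_j.get(j),
                "inflation": factors.get((j, q), 1.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["population", "quarter", "n_positions", "threshold_day", "inflation"],
    )
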