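"""Track ingest, validation and pre-processing.

Input tracks are daily regularized position series (one estimate per calendar
day per animal), as produced by state-space filtering of raw satellite fixes.
Pre-processing does two things:

* removes daily positions that fall strictly inside long observation gaps
  (more than 20 days by default), where interpolated positions are too
  uncertain to keep;
* assigns each retained point a *relative track day* ``t`` -- calendar days
  since deployment, day 1 being the first position.  Days removed by the gap
  rule remain holes: the numbering is calendar-based, never compacted, so
  that the per-day sample sizes used by the weighting scheme stay indexed by
  true time since deployment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date as _date, timedelta

import pandas as pd

__all__ = [
    "TrackPoint",
    "Track",
    "remove_gap_positions",
    "assign_relative_days",
    "preprocess_tracks",
    "read_tracks",
    "write_tracks",
]

log = logging.getLogger(__name__)

POPULATIONS = ("EP", "WP")


@dataclass(frozen=True)
class TrackPoint:
    date: _date
    lat: float
    lon: float
    relative_day: int | None = None  # days since deployment, day 1 = first fix


@dataclass
class Track:
    """One animal's dated daily positions with a population label."""

    turtle_id: str
    population: str
    points: list[TrackPoint] = field(default_factory=list)
    #: calendar dates with an actual satellite observation; None means the
    #: daily series itself defines the observation dates (pre-thinned input).
    observation_dates: frozenset[_date] | None = None

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(
                f"track {self.turtle_id}: population must be one of "
                f"{POPULATIONS}, got {self.population!r}"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def dates(self) -> list[_date]:
        return [p.date for p in self.points]

    @property
    def duration_days(self) -> int:
        if not self.points:
            return 0
        return (self.points[-1].date - self.points[0].date).days + 1


def remove_gap_positions(
    track: Track,
    observation_dates: frozenset[_date] | None = None,
    max_gap_days: int = 20,
) -> Track | None:
    """Drop daily positions lying strictly inside long observation gaps.

    A *gap* is the run of days strictly between two consecutive observation
    dates; daily positions inside a gap longer than ``max_gap_days`` days
    are removed (the bracketing observed days are kept).  Relative-day
    numbering, if already assigned, is preserved, not compacted.

    If no observation dates are supplied (neither here nor on the track),
    the dates of the daily series itself are taken as the observations, so
    holes in the series are already gaps and nothing is removed.

    Returns the filtered track, or ``None`` if every position fell inside a
    gap (the track is dropped, with a log entry).
    """
    obs = observation_dates if observation_dates is not None else track.observation_dates
    if obs is None:
        obs = frozenset(p.date for p in track.points)
    if not obs:
        log.warning("track %s: no observation dates; dropped", track.turtle_id)
        return None

    ordered = sorted(obs)
    # collect the open intervals (d1, d2) whose interior exceeds the gap limit
    long_gaps: list[tuple[_date, _date]] = []
    for d1, d2 in zip(ordered, ordered[1:]):
        intervening = (d2 - d1).days - 1
        if intervening > max_gap_days:
            long_gaps.append((d1, d2))

    def in_long_gap(d: _date) -> bool:
        return any(d1 < d < d2 for d1, d2 in long_gaps)

    kept = [p for p in track.points if not in_long_gap(p.date)]
    if not kept:
        log.warning("track %s: all positions inside long gaps; dropped", track.turtle_id)
        return None
    return replace_points(track, kept)


def replace_points(track: Track, points: list[TrackPoint]) -> Track:
    return Track(track.turtle_id, track.population, points, track.observation_dates)


def assign_relative_days(track: Track) -> Track:
    """Number points by calendar days since deployment (day 1 = first fix).

    Holes left by gap removal stay holes; e.g. dates {d0, d0+5} get relative
    days {1, 6}.
    """
    pts = sorted(track.points, key=lambda p: p.date)
    seen: set[_date] = set()
    for p in pts:
        if p.date in seen:
            raise ValueError(
                f"track {track.turtle_id}: duplicate position date {p.date}"
            )
        seen.add(p.date)
    if not pts:
        return replace_points(track, [])
    d0 = pts[0].date
    out = [replace(p, relative_day=(p.date - d0).days + 1) for p in pts]
    return replace_points(track, out)


def preprocess_tracks(
    tracks: list[Track], max_gap_days: int = 20
) -> tuple[list[Track], pd.DataFrame]:
    """Gap removal + relative-day assignment over a track collection.

    Returns the retained tracks and a per-track QC table (duration, number
    of positions before/after gap removal, number removed, dropped flag).
    """
    kept: list[Track] = []
    qc_rows = []
    for tr in tracks:
        n_before = len(tr)
        filtered = remove_gap_positions(tr, max_gap_days=max_gap_days)
        dropped = filtered is None
        n_after = 0 if dropped else len(filtered)
        if not dropped:
            kept.append(assign_relative_days(filtered))
        qc_rows.append(
            {
                "turtle_id": tr.turtle_id,
                "population": tr.population,
                "duration_days": tr.duration_days,
                "n_positions": n_before,
                "n_removed": n_before - n_after,
                "dropped": dropped,
            }
        )
    return kept, pd.DataFrame(qc_rows)


# ---- delimited-text I/O -----------------------------------------------------

_COLUMNS = ["turtle_id", "population", "date", "lat", "lon"]


def read_tracks(path) -> list[Track]:
    """Read tracks from delimited text.

    Required columns: turtle_id, population, date (ISO-8601), lat, lon.
    An optional ``observed`` column (0/1) marks which daily positions
    coincide with real satellite observations; when present, the observed
    dates drive gap removal, while unobserved (interpolated) daily positions
    are candidates for removal.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_obs = "observed" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        try:
            float(row.lat), float(row.lon)
            _date.fromisoformat(str(row.date))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: invalid record ({exc})") from exc
        if abs(float(row.lat)) > 90:
            raise ValueError(f"{path}: line {i}: latitude out of range: {row.lat}")

    tracks: list[Track] = []
    for (tid, pop), grp in df.groupby(["turtle_id", "population"], sort=True):
        grp = grp.sort_values("date")
        pts = [
            TrackPoint(_date.fromisoformat(str(r.date)), float(r.lat), float(r.lon))
            for r in grp.itertuples(index=False)
        ]
        obs = None
        if has_obs:
            obs = frozenset(
                _date.fromisoformat(str(r.date))
                for r in grp.itertuples(index=False)
                if int(r.observed)
            )
        tracks.append(Track(str(tid), str(pop), pts, obs))
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    rows = []
    for tr in tracks:
        obs = tr.observation_dates
        for p in tr.points:
            row = {
                "turtle_id": tr.turtle_id,
                "population": tr.population,
                "date": p.date.isoformat(),
                "lat": p.lat,
                "lon": p.lon,
            }
            if obs is not None:
                row["observed"] = int(p.date in obs)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
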