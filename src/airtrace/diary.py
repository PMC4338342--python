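"""Person-day travel diaries: parsing, validation, filtering, 24-h timelines.

The unit of analysis is the *person-day*: one individual's sociodemographic
attributes, residence location, and ordered out-of-home trips over a survey
day.  Time is minutes from midnight on half-open intervals
``[start, start + duration)``; every kept record is normalized to a gapless
partition of ``[0, 1440)`` into at-residence, nonresidential, and in-travel
activity episodes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "AGE_GROUPS",
    "INCOME_CATEGORIES",
    "URBANICITY_CATEGORIES",
    "PURPOSES",
    "AT_RESIDENCE",
    "NONRESIDENTIAL",
    "IN_TRAVEL",
    "PURPOSE_TO_KIND",
    "Trip",
    "PersonDay",
    "ActivityEpisode",
    "Rejection",
    "Exclusion",
    "ConsistencyError",
    "EmptyRecordError",
    "read_diaries",
    "write_diaries",
    "filter_person_days",
    "pare_to_24h",
    "build_timeline",
]

DAY_MINUTES = 1440.0
#: spatial tolerance (m) for "same location" checks between consecutive trips
CHAIN_TOL_M = 1.0
#: temporal tolerance (min) for gap/overlap checks
TIME_TOL = 1e-6

AGE_GROUPS = ("5-18", "19-45", "46-65", ">65")
INCOME_CATEGORIES = ("below_poverty", "middle", "higher")
URBANICITY_CATEGORIES = ("urban", "suburban", "second_city", "rural")
PURPOSES = ("home", "work", "meals", "travel", "other")

AT_RESIDENCE = "at_residence"
NONRESIDENTIAL = "nonresidential"
IN_TRAVEL = "in_travel"

#: Activity-location category for the dwell following a trip, keyed by the
#: trip's purpose: home-purpose dwells are at-residence, travel-purpose
#: activity (e.g. transporting someone) counts as in-travel, and work, meals
#: and all other purposes are nonresidential.
PURPOSE_TO_KIND = {
    "home": AT_RESIDENCE,
    "travel": IN_TRAVEL,
    "work": NONRESIDENTIAL,
    "meals": NONRESIDENTIAL,
    "other": NONRESIDENTIAL,
}


class ConsistencyError(ValueError):
    """A person-day's trips do not form a gapless, ordered timeline."""


class EmptyRecordError(ValueError):
    """A record has no usable overlap with the [0, 1440) survey day."""


@dataclass
class Trip:
    """One out-of-home trip and the dwell at its destination.

    ``travel_window`` is set by :func:`pare_to_24h` when the travel interval
    straddles a day boundary: it gives the retained portion of the travel
    time, in minutes relative to the start of travel.  ``None`` means the
    whole travel time lies inside the day.
    """

    origin: tuple[float, float]
    destination: tuple[float, float]
    start_minute: float
    reported_travel_minutes: float
    dwell_minutes: float
    purpose: str
    travel_window: tuple[float, float] | None = None

    @property
    def travel_minutes_in_day(self) -> float:
        if self.travel_window is None:
            return self.reported_travel_minutes
        return self.travel_window[1] - self.travel_window[0]


@dataclass
class PersonDay:
    person_id: str
    household_id: str
    age_group: str
    black: bool
    hispanic: bool
    white: bool
    asian: bool
    income_category: str
    gender: str
    residence_urbanicity: str
    residence: tuple[float, float]
    trips: list[Trip] = field(default_factory=list)


@dataclass
class ActivityEpisode:
    """A contiguous span of one activity-location category.

    ``location`` is the fixed activity point for dwell episodes and ``None``
    for in-travel episodes, which reference their trip by ``trip_index``.
    """

    kind: str
    start_minute: float
    duration_minutes: float
    location: tuple[float, float] | None = None
    trip_index: int | None = None

    @property
    def end_minute(self) -> float:
        return self.start_minute + self.duration_minutes


@dataclass(frozen=True)
class Rejection:
    """A diary row that could not be parsed into a valid record."""

    line_number: int
    reason: str


@dataclass(frozen=True)
class Exclusion:
    """A parsed person-day removed by filtering, with a reason code."""

    person_day: PersonDay
    reason: str  # one of {"missing", "inconsistent", "out_of_domain"}


# ---------------------------------------------------------------------------
# CSV schema: one "person" row per person-day followed by its "trip" rows.
# ---------------------------------------------------------------------------

_COLUMNS = [
    "record",
    "person_id",
    "household_id",
    "age_group",
    "black",
    "hispanic",
    "white",
    "asian",
    "income_category",
    "gender",
    "urbanicity",
    "res_x",
    "res_y",
    "origin_x",
    "origin_y",
    "dest_x",
    "dest_y",
    "start_min",
    "travel_min",
    "dwell_min",
    "purpose",
]


def _fmt(v: float) -> str:
    """Canonical shortest round-trip text for a float (ints without '.0')."""
    f = float(v)
    if f.is_integer() and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def write_diaries(records: list[PersonDay], path) -> None:
    """Write diaries to CSV; lossless and byte-deterministic for given data."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_COLUMNS)
        for pd_ in records:
            w.writerow(
                [
                    "person",
                    pd_.person_id,
                    pd_.household_id,
                    pd_.age_group,
                    int(pd_.black),
                    int(pd_.hispanic),
                    int(pd_.white),
                    int(pd_.asian),
                    pd_.income_category,
                    pd_.gender,
                    pd_.residence_urbanicity,
                    _fmt(pd_.residence[0]),
                    _fmt(pd_.residence[1]),
                ]
                + [""] * 8
            )
            for t in pd_.trips:
                w.writerow(
                    ["trip", pd_.person_id] + [""] * 11
                    + [
                        _fmt(t.origin[0]),
                        _fmt(t.origin[1]),
                        _fmt(t.destination[0]),
                        _fmt(t.destination[1]),
                        _fmt(t.start_minute),
                        _fmt(t.reported_travel_minutes),
                        _fmt(t.dwell_minutes),
                        t.purpose,
                    ]
                )


def read_diaries(path) -> tuple[list[PersonDay], list[Rejection]]:
    """Parse a diary CSV; every row either yields data or a :class:`Rejection`.

    Records for children under 5 years (age group ``"<5"``) are rejected at
    read time: the survey instrument does not cover them.  Trip rows with
    negative dwell times or non-positive travel times are rejected row-wise;
    their person-day keeps its other trips and will normally then fail the
    consistency filter.
    """
    records: list[PersonDay] = []
    rejections: list[Rejection] = []
    by_id: dict[str, PersonDay] = {}
    skipped_persons: set[str] = set()

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header row")
        if header != _COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_COLUMNS):
                rejections.append(Rejection(lineno, "wrong column count"))
                continue
            vals = dict(zip(_COLUMNS, row))
            kind = vals["record"]
            if kind == "person":
                reason = _parse_person(vals, by_id, records)
                if reason is not None:
                    rejections.append(Rejection(lineno, reason))
                    if vals["person_id"]:
                        skipped_persons.add(vals["person_id"])
            elif kind == "trip":
                pid = vals["person_id"]
                if pid in skipped_persons:
                    rejections.append(Rejection(lineno, "trip for rejected person"))
                    continue
                parent = by_id.get(pid)
                if parent is None:
                    rejections.append(Rejection(lineno, "trip without person row"))
                    continue
                reason = _parse_trip(vals, parent)
                if reason is not None:
                    rejections.append(Rejection(lineno, reason))
            else:
                rejections.append(Rejection(lineno, f"unknown record type {kind!r}"))
    return records, rejections


def _parse_person(vals, by_id, records) -> str | None:
    if vals["age_group"] == "<5":
        return "age under 5: not covered by the survey"
    if vals["age_group"] not in AGE_GROUPS:
        return f"unknown age group {vals['age_group']!r}"
    if vals["income_category"] not in INCOME_CATEGORIES:
        return f"unknown income category {vals['income_category']!r}"
    if vals["urbanicity"] not in URBANICITY_CATEGORIES:
        return f"unknown urbanicity {vals['urbanicity']!r}"
    if vals["person_id"] in by_id:
        return f"duplicate person_id {vals['person_id']!r}"
    try:
        res = (float(vals["res_x"]), float(vals["res_y"]))
        flags = {k: _parse_flag(vals[k]) for k in ("black", "hispanic", "white", "asian")}
    except ValueError as exc:
        return str(exc)
    pd_ = PersonDay(
        person_id=vals["person_id"],
        household_id=vals["household_id"],
        age_group=vals["age_group"],
        income_category=vals["income_category"],
        gender=vals["gender"],
        residence_urbanicity=vals["urbanicity"],
        residence=res,
        **flags,
    )
    by_id[pd_.person_id] = pd_
    records.append(pd_)
    return None


def _parse_flag(text: str) -> bool:
    if text not in ("0", "1"):
        raise ValueError(f"flag must be 0 or 1, got {text!r}")
    return text == "1"


def _parse_trip(vals, parent: PersonDay) -> str | None:
    try:
        origin = (float(vals["origin_x"]), float(vals["origin_y"]))
        dest = (float(vals["dest_x"]), float(vals["dest_y"]))
        start = float(vals["start_min"])
        travel = float(vals["travel_min"])
        dwell = float(vals["dwell_min"])
    except ValueError:
        return "unparsable numeric trip field"
    if travel <= 0:
        return "non-positive travel time"
    if dwell < 0:
        return "negative dwell time"
    if vals["purpose"] not in PURPOSES:
        return f"unknown purpose {vals['purpose']!r}"
    parent.trips.append(
        Trip(
            origin=origin,
            destination=dest,
            start_minute=start,
            reported_travel_minutes=travel,
            dwell_minutes=dwell,
            purpose=vals["purpose"],
        )
    )
    return None


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def _missing_reason(pd_: PersonDay) -> str | None:
    for name, value in [
        ("person_id", pd_.person_id),
        ("household_id", pd_.household_id),
        ("gender", pd_.gender),
    ]:
        if not value:
            return f"missing {name}"
    if pd_.age_group not in AGE_GROUPS:
        return "missing or invalid age group"
    if pd_.income_category not in INCOME_CATEGORIES:
        return "missing or invalid income category"
    if pd_.residence_urbanicity not in URBANICITY_CATEGORIES:
        return "missing or invalid urbanicity"
    coords = [pd_.residence] + [c for t in pd_.trips for c in (t.origin, t.destination)]
    if not all(math.isfinite(v) for xy in coords for v in xy):
        return "non-finite coordinate"
    for t in pd_.trips:
        if not all(
            math.isfinite(v)
            for v in (t.start_minute, t.reported_travel_minutes, t.dwell_minutes)
        ):
            return "non-finite trip time"
    return None


def _inconsistent_reason(pd_: PersonDay) -> str | None:
    trips = pd_.trips
    for k, t in enumerate(trips):
        if t.reported_travel_minutes <= 0:
            return f"trip {k}: non-positive travel time"
        if t.dwell_minutes < 0:
            return f"trip {k}: negative dwell time"
        if t.purpose not in PURPOSES:
            return f"trip {k}: unknown purpose"
    if trips and _dist(trips[0].origin, pd_.residence) > CHAIN_TOL_M:
        return "first trip does not originate at the residence"
    for k in range(1, len(trips)):
        prev, cur = trips[k - 1], trips[k]
        if _dist(cur.origin, prev.destination) > CHAIN_TOL_M:
            return f"trip {k}: origin differs from previous destination"
        arrival = prev.start_minute + prev.travel_minutes_in_day
        expected_start = arrival + prev.dwell_minutes
        if cur.start_minute < arrival - TIME_TOL:
            return f"trip {k}: overlaps previous trip"
        if abs(cur.start_minute - expected_start) > TIME_TOL:
            return f"trip {k}: gap or overlap with previous dwell"
    return None


def _out_of_domain_reason(
    pd_: PersonDay, bbox: tuple[float, float, float, float]
) -> str | None:
    xmin, ymin, xmax, ymax = bbox
    points = [("residence", pd_.residence)]
    for k, t in enumerate(pd_.trips):
        points.append((f"trip {k} origin", t.origin))
        points.append((f"trip {k} destination", t.destination))
    for name, (x, y) in points:
        if not (xmin <= x < xmax and ymin <= y < ymax):
            return f"{name} outside study domain"
    return None


def filter_person_days(
    records: list[PersonDay], domain_bbox: tuple[float, float, float, float]
) -> tuple[list[PersonDay], list[Exclusion]]:
    """Split records into kept and excluded, mirroring survey-sample cleaning.

    Exclusion reason codes: ``missing`` (incomplete attributes), ``inconsistent``
    (overlapping, out-of-order, or spatially broken trip chains), and
    ``out_of_domain`` (residence or any trip endpoint outside ``domain_bbox``
    — the analogue of excluding travel beyond the county boundary).  Filtering
    is total (never raises) and idempotent.
    """
    if not (domain_bbox[0] < domain_bbox[2] and domain_bbox[1] < domain_bbox[3]):
        raise ValueError(f"invalid domain bbox {domain_bbox}")
    kept: list[PersonDay] = []
    excluded: list[Exclusion] = []
    for pd_ in records:
        reason = _missing_reason(pd_)
        code = "missing" if reason else None
        if code is None:
            reason = _inconsistent_reason(pd_)
            code = "inconsistent" if reason else None
        if code is None:
            reason = _out_of_domain_reason(pd_, domain_bbox)
            code = "out_of_domain" if reason else None
        if code is None:
            kept.append(pd_)
        else:
            excluded.append(Exclusion(pd_, code))
    return kept, excluded


# ---------------------------------------------------------------------------
# 24-h paring and timeline construction
# ---------------------------------------------------------------------------

def pare_to_24h(person_day: PersonDay) -> PersonDay:
    """Clip a record to exactly the survey day ``[0, 1440)``.

    Trips lying fully outside the day are dropped; a trip straddling midnight
    keeps only the in-day portion of its travel time (recorded in
    ``Trip.travel_window`` so traces can be clipped proportionally by time)
    and its dwell is truncated at the day boundary.  A record whose trips all
    lie outside the day (so the person's in-day whereabouts are unknown)
    raises :class:`EmptyRecordError`.  Records already inside the day are
    returned unchanged.
    """
    if not person_day.trips:
        return person_day
    if all(
        t.start_minute >= DAY_MINUTES
        or t.start_minute + t.reported_travel_minutes + t.dwell_minutes <= 0
        for t in person_day.trips
    ):
        raise EmptyRecordError(
            f"person-day {person_day.person_id}: no trip overlaps [0, 1440)"
        )
    changed = False
    trips: list[Trip] = []
    for t in person_day.trips:
        end = t.start_minute + t.reported_travel_minutes + t.dwell_minutes
        if t.start_minute >= DAY_MINUTES or end <= 0:
            changed = True
            continue
        new = t
        arrive = t.start_minute + t.reported_travel_minutes
        if t.start_minute < 0:
            # clip travel (and possibly dwell) from the front of the day
            w0 = min(-t.start_minute, t.reported_travel_minutes)
            new = replace(
                new,
                start_minute=0.0,
                travel_window=(w0, t.reported_travel_minutes),
                dwell_minutes=t.dwell_minutes - max(0.0, -arrive),
            )
            changed = True
            arrive = new.travel_minutes_in_day
        if arrive > DAY_MINUTES:
            w = new.travel_window or (0.0, new.reported_travel_minutes)
            new = replace(
                new,
                travel_window=(w[0], w[0] + (DAY_MINUTES - new.start_minute)),
                dwell_minutes=0.0,
            )
            changed = True
        elif arrive + new.dwell_minutes > DAY_MINUTES:
            new = replace(new, dwell_minutes=DAY_MINUTES - arrive)
            changed = True
        trips.append(new)
    if not changed:
        return person_day
    return replace(person_day, trips=trips)


def build_timeline(person_day: PersonDay) -> list[ActivityEpisode]:
    """Partition ``[0, 1440)`` into contiguous activity episodes.

    A zero-trip record yields a single 1440-minute at-residence episode.
    After the last recorded dwell, any remaining time continues at the last
    destination in that dwell's category (for home-anchored diaries this is
    the closing at-residence block).  Gaps or overlaps raise
    :class:`ConsistencyError`; episode durations sum to exactly 1440.
    """
    episodes: list[ActivityEpisode] = []
    cursor = 0.0

    def push(kind, duration, location=None, trip_index=None):
        nonlocal cursor
        if duration <= 0:
            return
        if episodes and episodes[-1].kind == kind and episodes[-1].location == location:
            episodes[-1].duration_minutes += duration
        else:
            episodes.append(
                ActivityEpisode(kind, cursor, duration, location, trip_index)
            )
        cursor += duration

    if not person_day.trips:
        return [ActivityEpisode(AT_RESIDENCE, 0.0, DAY_MINUTES, person_day.residence)]

    last_kind = AT_RESIDENCE
    last_loc = person_day.residence
    for k, t in enumerate(person_day.trips):
        if t.start_minute < cursor - TIME_TOL:
            raise ConsistencyError(
                f"trip {k} starts at {t.start_minute} before {cursor}"
            )
        if t.start_minute > cursor + TIME_TOL:
            if k == 0:
                push(AT_RESIDENCE, t.start_minute, person_day.residence)
            else:
                raise ConsistencyError(
                    f"gap before trip {k}: timeline at {cursor}, "
                    f"trip starts {t.start_minute}"
                )
        push(IN_TRAVEL, t.travel_minutes_in_day, None, k)
        last_kind = PURPOSE_TO_KIND[t.purpose]
        last_loc = t.destination
        push(last_kind, t.dwell_minutes, t.destination, None)
    if cursor > DAY_MINUTES + TIME_TOL:
        raise ConsistencyError(f"timeline overruns the day: {cursor} min")
    push(last_kind, DAY_MINUTES - cursor, last_loc)
    # exact closure: absorb any float residue into the final episode so the
    # left-to-right sum of durations is exactly 1440
    total = 0.0
    for ep in episodes:
        total += ep.duration_minutes
    episodes[-1].duration_minutes += DAY_MINUTES - total
    return episodes
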