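"""Travel-mode assignment and the daily trip limiter.

Mode selection follows a fixed precedence: a reimbursement-recorded mode
always wins; otherwise taxi for patients aged 90+, walking for short
distances (age-dependent threshold), bus when the destination is
bus-accessible with a stop within 250 m for patients under 80, and car in
every remaining case.  Ambulance journeys exist only where a
reimbursement record documents one.

The trip limiter collapses each patient-day's contact combination into at
most two round trips (four one-way legs): contacts during an inpatient
stay generate no travel, the first and last ward days generate one-way
legs, chained outpatient/INR contacts share a single round trip, and only
days spanning primary, INR and specialised care (or INR at two distinct
sites) yield two round trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Mapping, Sequence

from .cohort import Contact, Patient
from .config import WARD_KINDS
from .routing import Geography, RoutingIndex, UnreachableError

log = logging.getLogger(__name__)

TAXI_AGE = 90
WALK_FULL_KM = 1.25  # walkable distance below age 80
WALK_REDUCED_KM = 0.25  # walkable distance at ages 80-89
BUS_STOP_MAX_KM = 0.25
BUS_AGE_LIMIT = 80

MAX_ROUNDTRIPS_PER_DAY = 2
MAX_LEGS_PER_DAY = 2 * MAX_ROUNDTRIPS_PER_DAY


@dataclass(frozen=True)
class ReimbursementRecord:
    """One reimbursed journey with its patient/society cost split."""

    patient_id: str
    date: Date
    mode: str
    patient_cost: float
    society_cost: float
    contact_id: str | None = None

    def __post_init__(self) -> None:
        if self.patient_cost < 0 or self.society_cost < 0:
            raise ValueError("reimbursement costs must be non-negative")


@dataclass(frozen=True)
class TripStub:
    """A planned trip before routing: destination reference and leg count."""

    patient_id: str
    date: Date
    destination: str | None  # facility id; None = route to the closest lab
    legs: str  # 'roundtrip' | 'one_way'
    urgent: bool = False


@dataclass
class Journey:
    patient_id: str
    date: Date
    origin: object
    facility_id: str
    mode: str
    legs: str  # 'roundtrip' | 'one_way'
    distance_km: float  # one-way
    time_h: float  # one-way, excluding parking/service penalties
    from_reimbursement: bool = False
    reimbursement: ReimbursementRecord | None = None

    @property
    def n_legs(self) -> int:
        return 2 if self.legs == "roundtrip" else 1


def assign_travel_mode(
    age: float,
    one_way_distance: float,
    dest_bus_accessible: bool,
    stop_distance: float,
    urgent: bool,
    reimbursement_mode: str | None = None,
) -> str:
    """Rule-based travel mode for one journey (total, deterministic).

    Precedence: recorded mode > taxi (age 90+) > walking (distance/age
    bands) > bus (availability and age) > car.  ``urgent`` alone never
    yields an ambulance: ambulance journeys require a reimbursement record.
    """
    if age < 18:
        raise ValueError(f"age must be >= 18, got {age}")
    if one_way_distance < 0:
        raise ValueError("distance must be non-negative")
    if reimbursement_mode is not None:
        return reimbursement_mode
    if age >= TAXI_AGE:
        return "taxi"
    if (one_way_distance <= WALK_FULL_KM and age < 80) or (
        one_way_distance <= WALK_REDUCED_KM and 80 <= age < TAXI_AGE
    ):
        return "walking"
    if (
        one_way_distance > WALK_FULL_KM
        and dest_bus_accessible
        and stop_distance <= BUS_STOP_MAX_KM
        and age < BUS_AGE_LIMIT
    ):
        return "bus"
    return "car"


def ward_stay_positions(contacts: Iterable[Contact]) -> dict[tuple[str, Date], str]:
    """Position of each in-ward patient-day within its stay.

    A stay is a maximal run of consecutive ward-day dates for one patient.
    Values: ``first``, ``last``, ``first_last`` (single-day stay), ``mid``.
    """
    ward_days: dict[str, set[Date]] = {}
    for c in contacts:
        if c.kind in WARD_KINDS:
            ward_days.setdefault(c.patient_id, set()).add(c.date)
    out: dict[tuple[str, Date], str] = {}
    for pid, days in ward_days.items():
        run: list[Date] = []
        for day in sorted(days) + [None]:  # type: ignore[list-item]
            if run and (day is None or (day - run[-1]).days > 1):
                if len(run) == 1:
                    out[(pid, run[0])] = "first_last"
                else:
                    out[(pid, run[0])] = "first"
                    out[(pid, run[-1])] = "last"
                    for mid in run[1:-1]:
                        out[(pid, mid)] = "mid"
                run = []
            if day is not None:
                run.append(day)
    return out


def _care_groups(day_contacts: Sequence[Contact]) -> dict[str, list[str | None]]:
    """Outpatient destinations of the day, keyed by care level.

    ``inr`` holds the distinct INR facilities (None = closest laboratory),
    ``primary`` / ``specialised`` the facilities of outpatient visits.
    """
    groups: dict[str, list[str | None]] = {"inr": [], "primary": [], "specialised": []}
    for c in day_contacts:
        if c.kind == "inr" and not c.at_home:
            key = c.facility_id  # None routes to the closest lab later
            if key not in groups["inr"]:
                groups["inr"].append(key)
        elif c.kind == "primary_visit":
            if c.facility_id not in groups["primary"]:
                groups["primary"].append(c.facility_id)
        elif c.kind in ("specialised_visit", "emergency_visit"):
            if c.facility_id not in groups["specialised"]:
                groups["specialised"].append(c.facility_id)
    return groups


def daily_trip_plan(
    day_contacts: Sequence[Contact], ward_position: str = "none"
) -> list[TripStub]:
    """Trip stubs for one patient-day, capped at two round trips.

    ``ward_position`` is the day's place within an inpatient stay as given
    by :func:`ward_stay_positions` (``none`` when the patient is not in a
    ward that day).
    """
    if not day_contacts:
        return []
    pids = {c.patient_id for c in day_contacts}
    dates = {c.date for c in day_contacts}
    if len(pids) > 1 or len(dates) > 1:
        raise ValueError("daily_trip_plan expects contacts of one patient on one date")
    pid, day = pids.pop(), dates.pop()
    urgent = any(c.urgent for c in day_contacts)

    if ward_position == "mid":
        return []  # contacts during an inpatient stay generate no travel

    stubs: list[TripStub] = []
    groups = _care_groups(day_contacts)

    if ward_position in ("first", "last", "first_last"):
        ward_contacts = [c for c in day_contacts if c.kind in WARD_KINDS]
        ward_fac = ward_contacts[0].facility_id if ward_contacts else None
        ward_level = (
            "primary"
            if any(c.kind == "primary_ward_day" for c in ward_contacts)
            else "specialised"
        )
        n_ways = 2 if ward_position == "first_last" else 1
        for _ in range(n_ways):
            stubs.append(TripStub(pid, day, ward_fac, "one_way", urgent))
        # an outpatient visit at the other care level still needs its own trip
        other_level = "primary" if ward_level == "specialised" else "specialised"
        if groups[other_level]:
            stubs.append(TripStub(pid, day, groups[other_level][0], "roundtrip", urgent))
    else:
        has = {level: bool(dests) for level, dests in groups.items()}
        if has["primary"] and has["specialised"] and has["inr"]:
            # INR chains with the primary-care trip; specialised is its own
            stubs.append(TripStub(pid, day, groups["primary"][0], "roundtrip", urgent))
            stubs.append(TripStub(pid, day, groups["specialised"][0], "roundtrip", urgent))
        elif len(groups["inr"]) >= 2 and not (has["primary"] or has["specialised"]):
            # monitoring at two distinct sites cannot be chained
            stubs.append(TripStub(pid, day, groups["inr"][0], "roundtrip", urgent))
            stubs.append(TripStub(pid, day, groups["inr"][1], "roundtrip", urgent))
        elif has["specialised"]:
            stubs.append(TripStub(pid, day, groups["specialised"][0], "roundtrip", urgent))
        elif has["primary"]:
            stubs.append(TripStub(pid, day, groups["primary"][0], "roundtrip", urgent))
        elif has["inr"]:
            stubs.append(TripStub(pid, day, groups["inr"][0], "roundtrip", urgent))
        # phone-only days fall through with no stubs

    # hard cap: at most two round trips (four one-way legs) per day
    capped: list[TripStub] = []
    legs = 0
    for stub in stubs:
        cost = 2 if stub.legs == "roundtrip" else 1
        if legs + cost > MAX_LEGS_PER_DAY:
            break
        capped.append(stub)
        legs += cost
    return capped


def plan_trips(contacts: Iterable[Contact]) -> list[TripStub]:
    """Apply the daily trip limiter to a whole contact stream."""
    contacts = list(contacts)
    positions = ward_stay_positions(contacts)
    by_day: dict[tuple[str, Date], list[Contact]] = {}
    for c in contacts:
        by_day.setdefault((c.patient_id, c.date), []).append(c)
    stubs: list[TripStub] = []
    for key in sorted(by_day, key=lambda k: (k[0], k[1])):
        stubs.extend(daily_trip_plan(by_day[key], positions.get(key, "none")))
    return stubs


def resolve_journeys(
    stubs: Iterable[TripStub],
    geo: Geography,
    patient: Patient,
    reimbursements: Iterable[ReimbursementRecord] = (),
    *,
    routing_index: RoutingIndex | None = None,
) -> list[Journey]:
    """Route trip stubs from the patient's home and assign travel modes.

    INR stubs (no facility) go to the closest laboratory; everything else
    to the contact's recorded facility.  Unreachable destinations are
    logged and dropped.  At most one reimbursement record is consumed per
    patient-day; it fixes the mode and later overrides the travel cost.
    """
    index = routing_index or RoutingIndex(geo)
    home = patient.home_node
    records: dict[tuple[str, Date], list[ReimbursementRecord]] = {}
    for rec in reimbursements:
        records.setdefault((rec.patient_id, rec.date), []).append(rec)

    stop_distance = index.bus_stop_distance(home)
    journeys: list[Journey] = []
    for stub in stubs:
        if stub.patient_id != patient.id:
            raise ValueError(f"stub for {stub.patient_id} given patient {patient.id}")
        try:
            if stub.destination is None:
                facility, _, _ = index.nearest_lab(home)
            else:
                facility = geo.facilities[stub.destination]
            selection_distance = index.length_distance(facility.node, home)
        except UnreachableError as exc:
            log.warning("dropping journey for %s on %s: %s", stub.patient_id, stub.date, exc)
            continue
        day_records = records.get((stub.patient_id, stub.date))
        record = day_records.pop(0) if day_records else None
        mode = assign_travel_mode(
            patient.age,
            selection_distance,
            facility.bus_accessible,
            stop_distance,
            stub.urgent,
            record.mode if record else None,
        )
        if mode in ("car", "taxi", "ambulance"):
            distance, time = index.car_route(facility.node, home)
        elif mode == "walking":
            distance = selection_distance
            time = distance / 4.0
        else:  # bus: road network at 30 km/h plus walking to the stop
            distance = selection_distance
            access = stop_distance if stop_distance != float("inf") else 0.0
            time = distance / 30.0 + access / 4.0
        journeys.append(
            Journey(
                patient_id=stub.patient_id,
                date=stub.date,
                origin=home,
                facility_id=facility.id,
                mode=mode,
                legs=stub.legs,
                distance_km=distance,
                time_h=time,
                from_reimbursement=record is not None,
                reimbursement=record,
            )
        )
    return journeys
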