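"""Travel-mode rules and the daily trip limiter."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from afcost.travel_model import (
    MAX_LEGS_PER_DAY,
    ReimbursementRecord,
    assign_travel_mode,
    daily_trip_plan,
    plan_trips,
    resolve_journeys,
    ward_stay_positions,
)

from conftest import WINDOW_START, make_contact, make_patient


class TestAssignTravelMode:
    def test_reimbursement_precedence(self):
        assert assign_travel_mode(30, 0.5, True, 0.1, False, "ambulance") == "ambulance"
        assert assign_travel_mode(95, 100.0, False, math.inf, True, "bus") == "bus"

    def test_taxi_age_90(self):
        assert assign_travel_mode(92, 0.5, False, math.inf, False) == "taxi"
        assert assign_travel_mode(90, 50.0, True, 0.1, False) == "taxi"

    def test_walking_bands(self):
        assert assign_travel_mode(70, 1.0, False, math.inf, False) == "walking"
        assert assign_travel_mode(70, 1.25, False, math.inf, False) == "walking"
        assert assign_travel_mode(85, 0.2, False, math.inf, False) == "walking"
        assert assign_travel_mode(85, 0.5, False, math.inf, False) == "car"

    def test_bus_conditions(self):
        assert assign_travel_mode(70, 5.0, True, 0.2, False) == "bus"
        assert assign_travel_mode(70, 5.0, True, 0.4, False) == "car"  # stop too far
        assert assign_travel_mode(70, 5.0, False, 0.2, False) == "car"  # not accessible
        assert assign_travel_mode(82, 5.0, True, 0.2, False) == "car"  # too old for bus

    def test_car_default(self):
        assert assign_travel_mode(70, 2.0, False, math.inf, False) == "car"

    def test_urgent_without_record_is_not_ambulance(self):
        assert assign_travel_mode(70, 2.0, False, math.inf, True) == "car"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            assign_travel_mode(10, 1.0, False, 0.0, False)
        with pytest.raises(ValueError):
            assign_travel_mode(70, -1.0, False, 0.0, False)

    @given(
        age=st.floats(min_value=18, max_value=110, allow_nan=False),
        d=st.floats(min_value=0, max_value=200, allow_nan=False),
        accessible=st.booleans(),
        stop=st.floats(min_value=0, max_value=10, allow_nan=False),
        urgent=st.booleans(),
    )
    def test_total_and_deterministic(self, age, d, accessible, stop, urgent):
        mode = assign_travel_mode(age, d, accessible, stop, urgent)
        assert mode in ("car", "taxi", "walking", "bus")
        assert mode == assign_travel_mode(age, d, accessible, stop, urgent)


class TestDailyTripPlan:
    def test_inr_during_ward_stay_no_trip(self):
        contacts = [make_contact(day=5, kind="inr"), make_contact(day=5, kind="specialised_ward_day")]
        assert daily_trip_plan(contacts, ward_position="mid") == []

    def test_three_inr_same_location_one_roundtrip(self):
        contacts = [make_contact(day=1, kind="inr", facility_id="lab01") for _ in range(3)]
        stubs = daily_trip_plan(contacts)
        assert len(stubs) == 1 and stubs[0].legs == "roundtrip"

    def test_primary_inr_specialised_two_roundtrips(self):
        contacts = [
            make_contact(day=1, kind="primary_visit", facility_id="hc01"),
            make_contact(day=1, kind="inr", facility_id="lab01"),
            make_contact(day=1, kind="specialised_visit", facility_id="hosp"),
        ]
        stubs = daily_trip_plan(contacts)
        assert [s.legs for s in stubs] == ["roundtrip", "roundtrip"]
        assert {s.destination for s in stubs} == {"hc01", "hosp"}

    def test_inr_two_locations_two_roundtrips(self):
        contacts = [
            make_contact(day=1, kind="inr", facility_id="lab01"),
            make_contact(day=1, kind="inr", facility_id="lab02"),
        ]
        stubs = daily_trip_plan(contacts)
        assert len(stubs) == 2

    def test_phone_only_no_trip(self):
        assert daily_trip_plan([make_contact(day=1, kind="phone")]) == []

    def test_first_ward_day_one_way(self):
        contacts = [make_contact(day=1, kind="specialised_ward_day", facility_id="hosp")]
        stubs = daily_trip_plan(contacts, ward_position="first")
        assert [s.legs for s in stubs] == ["one_way"]

    def test_single_day_stay_two_one_ways(self):
        contacts = [make_contact(day=1, kind="primary_ward_day", facility_id="hc01")]
        stubs = daily_trip_plan(contacts, ward_position="first_last")
        assert [s.legs for s in stubs] == ["one_way", "one_way"]

    def test_visits_plus_first_ward_day(self):
        # primary visit + specialised visit + first specialised ward day:
        # one-way to the ward plus a roundtrip for the other care level
        contacts = [
            make_contact(day=1, kind="primary_visit", facility_id="hc01"),
            make_contact(day=1, kind="specialised_visit", facility_id="hosp"),
            make_contact(day=1, kind="specialised_ward_day", facility_id="hosp"),
        ]
        stubs = daily_trip_plan(contacts, ward_position="first")
        assert sorted(s.legs for s in stubs) == ["one_way", "roundtrip"]

    def test_mixed_patients_rejected(self):
        contacts = [make_contact(pid="A", day=1), make_contact(pid="B", day=1)]
        with pytest.raises(ValueError):
            daily_trip_plan(contacts)

    @settings(max_examples=200, deadline=None)
    @given(
        kinds=st.lists(
            st.sampled_from(
                ["inr", "primary_visit", "specialised_visit", "phone", "emergency_visit"]
            ),
            min_size=0,
            max_size=25,
        ),
        facilities=st.lists(st.sampled_from(["hc01", "hc02", "lab01", "lab02", "hosp", None]), min_size=25, max_size=25),
        ward=st.sampled_from(["none", "first", "last", "first_last", "mid"]),
    )
    def test_trip_cap_under_adversarial_stacking(self, kinds, facilities, ward):
        contacts = [
            make_contact(day=1, kind=k, facility_id=f)
            for k, f in zip(kinds, facilities)
        ]
        if ward != "none":
            contacts.append(make_contact(day=1, kind="primary_ward_day", facility_id="hc01"))
        stubs = daily_trip_plan(contacts, ward_position=ward)
        legs = sum(2 if s.legs == "roundtrip" else 1 for s in stubs)
        assert legs <= MAX_LEGS_PER_DAY


class TestWardStayPositions:
    def test_multi_day_stay(self):
        contacts = [
            make_contact(day=d, kind="specialised_ward_day") for d in (3, 4, 5, 6)
        ]
        pos = ward_stay_positions(contacts)
        pid = contacts[0].patient_id
        days = [c.date for c in contacts]
        assert pos[(pid, days[0])] == "first"
        assert pos[(pid, days[1])] == "mid"
        assert pos[(pid, days[2])] == "mid"
        assert pos[(pid, days[3])] == "last"

    def test_plan_trips_mid_stay_inr_generates_nothing(self):
        pid = "W00001"
        contacts = [make_contact(pid=pid, day=d, kind="primary_ward_day") for d in (3, 4, 5)]
        contacts.append(make_contact(pid=pid, day=4, kind="inr"))
        stubs = plan_trips(contacts)
        mid_day = WINDOW_START.toordinal() + 4
        assert all(s.date.toordinal() != mid_day for s in stubs)
        # first and last day still produce one one-way each
        assert sorted(s.legs for s in stubs) == ["one_way", "one_way"]


class TestResolveJourneys:
    def test_zero_stubs(self, line_geo):
        patient = make_patient(home_node=0)
        assert resolve_journeys([], line_geo, patient) == []

    def test_inr_routes_to_closest_lab(self, line_geo):
        patient = make_patient(home_node=0, age=70)
        stubs = plan_trips([make_contact(day=1, kind="inr")])
        journeys = resolve_journeys(stubs, line_geo, patient)
        assert len(journeys) == 1
        assert journeys[0].facility_id == "lab01"
        assert journeys[0].distance_km == pytest.approx(5.0)

    def test_specialised_routes_to_recorded_facility(self, line_geo):
        patient = make_patient(home_node=0, age=70)
        stubs = plan_trips([make_contact(day=1, kind="specialised_visit", facility_id="hosp")])
        journeys = resolve_journeys(stubs, line_geo, patient)
        assert journeys[0].facility_id == "hosp"
        assert journeys[0].distance_km == pytest.approx(10.0)

    def test_reimbursement_fixes_mode(self, line_geo):
        patient = make_patient(home_node=0, age=70)
        contact = make_contact(day=1, kind="specialised_visit", facility_id="hosp")
        record = ReimbursementRecord(patient.id, contact.date, "taxi", 25.0, 40.0)
        journeys = resolve_journeys(plan_trips([contact]), line_geo, patient, [record])
        assert journeys[0].mode == "taxi"
        assert journeys[0].from_reimbursement
        assert journeys[0].reimbursement is record

    def test_walking_short_distance(self):
        from conftest import build_geography

        geo = build_geography(
            edges=[(0, 1, 1.0, 50.0)],
            facilities=[("hosp", "hospital", 1), ("lab01", "lab", 1)],
        )
        patient = make_patient(home_node=0, age=70)
        journeys = resolve_journeys(plan_trips([make_contact(day=1, kind="inr")]), geo, patient)
        assert journeys[0].mode == "walking"
        assert journeys[0].time_h == pytest.approx(1.0 / 4.0)
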