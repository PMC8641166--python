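"""Cost equations: hand-derived values and conservation properties."""

from __future__ import annotations

import math
from datetime import timedelta

import pytest
from hypothesis import given, strategies as st

from afcost.cost_engine import (
    CeilingState,
    CostModelError,
    CostParameters,
    compose_daily,
    drug_daily_cost,
    drug_only_record,
    patient_fee,
    process_fees,
    time_cost_monitoring,
    time_cost_travel,
    travel_cost,
)
from afcost.travel_model import Journey, ReimbursementRecord

from conftest import WINDOW_START, make_contact, make_patient


def make_journey(patient, day=1, mode="walking", legs="roundtrip", d=1.0, t=0.25, record=None):
    return Journey(
        patient_id=patient.id,
        date=WINDOW_START + timedelta(days=day),
        origin=patient.home_node,
        facility_id="lab01",
        mode=mode,
        legs=legs,
        distance_km=d,
        time_h=t,
        from_reimbursement=record is not None,
        reimbursement=record,
    )


class TestTravelCost:
    def test_walking_free(self, params):
        assert travel_cost("walking", 42.0, None, params) == (0.0, 0.0)

    def test_taxi_hand_arithmetic(self, params):
        pat, soc = travel_cost("taxi", 10.0, None, params)
        assert pat == pytest.approx(5.9 + 1.59 * 10.0)  # 21.8
        assert soc == 0.0

    def test_car_zero_distance(self, params):
        assert travel_cost("car", 0.0, None, params) == (0.0, 0.0)

    def test_car_per_km(self, params):
        assert travel_cost("car", 7.0, None, params)[0] == pytest.approx(0.43 * 7.0)

    def test_bus_fare_bands(self, params):
        assert travel_cost("bus", 10.0, None, params)[0] == 2.00
        assert travel_cost("bus", 20.0, None, params)[0] == 3.80
        assert travel_cost("bus", 99.0, None, params)[0] == 5.00

    def test_ambulance_requires_record(self, params):
        with pytest.raises(CostModelError):
            travel_cost("ambulance", 10.0, None, params)

    def test_reimbursement_override(self, params):
        rec = ReimbursementRecord("W1", WINDOW_START, "taxi", 25.0, 63.5)
        assert travel_cost("taxi", 10.0, rec, params) == (25.0, 63.5)

    @given(d1=st.floats(0, 100, allow_nan=False), d2=st.floats(0, 100, allow_nan=False))
    def test_monotone_in_distance(self, d1, d2):
        params = CostParameters()
        lo, hi = sorted([d1, d2])
        for mode in ("car", "taxi"):
            assert travel_cost(mode, lo, None, params)[0] <= travel_cost(mode, hi, None, params)[0]


class TestTimeCost:
    def test_car_leg_with_parking_penalty(self, params):
        # retired, €12/h, 0.5 h drive: 0.35 * 12 * (0.5 + 0.083)
        assert time_cost_travel("car", 0.5, 0.35, 12.0, params) == pytest.approx(2.4486)

    def test_walking_zero_time(self, params):
        assert time_cost_travel("walking", 0.0, 1.0, 12.0, params) == 0.0

    def test_bus_working_age(self, params):
        assert time_cost_travel("bus", 1.0, 1.0, 12.0, params) == pytest.approx(12.0)

    def test_negative_rejected(self, params):
        with pytest.raises(CostModelError):
            time_cost_travel("car", -0.1, 1.0, 12.0, params)

    def test_monitoring_hand_arithmetic(self, params):
        assert time_cost_monitoring(0, 0.35, 12.0, params) == 0.0
        one = time_cost_monitoring(1, 0.35, 12.0, params)
        assert one == pytest.approx(2.1)  # 1 * 12 * 0.35 * 0.5
        assert time_cost_monitoring(2, 0.35, 12.0, params) == pytest.approx(2 * one)


class TestDrugCost:
    def test_warfarin_split(self, params):
        assert drug_daily_cost("warfarin", params) == (0.08, 0.05)

    def test_doac_split(self, params):
        assert drug_daily_cost("doac", params) == (0.95, 1.76)

    def test_rate_consistency(self, params):
        # patient share 0.08/0.13 = 0.615 vs 1 - 0.40 = 0.60: within 0.02
        pat, soc = drug_daily_cost("warfarin", params)
        assert abs(pat / (pat + soc) - 0.60) <= 0.02

    def test_inconsistent_split_warns(self, params):
        params.warfarin_daily_patient = 0.12
        with pytest.warns(UserWarning, match="inconsistent"):
            drug_daily_cost("warfarin", params)

    def test_unknown_arm(self, params):
        with pytest.raises(CostModelError):
            drug_daily_cost("aspirin", params)

    @given(st.sampled_from(["warfarin", "doac"]))
    def test_payer_conservation(self, arm):
        params = CostParameters()
        pat, soc = drug_daily_cost(arm, params)
        retail = (
            params.warfarin_daily_patient + params.warfarin_daily_society
            if arm == "warfarin"
            else params.doac_daily_patient + params.doac_daily_society
        )
        assert pat + soc == pytest.approx(retail)


class TestPatientFee:
    def test_fee_near_ceiling_splits(self, params):
        state = CeilingState()
        state.cumulative = 680.0
        contact = make_contact(day=1, kind="specialised_visit")
        paid, overflow = patient_fee(contact, state, params)
        assert paid == pytest.approx(3.0)
        assert overflow == pytest.approx(38.2)

    def test_saturated_ceiling_pays_zero(self, params):
        state = CeilingState()
        state.cumulative = 683.0
        paid, overflow = patient_fee(make_contact(day=1, kind="primary_visit"), state, params)
        assert paid == 0.0
        assert overflow == pytest.approx(20.6)

    def test_first_primary_visit_default_fee(self, params):
        paid, overflow = patient_fee(make_contact(day=1, kind="primary_visit"), CeilingState(), params)
        assert paid == pytest.approx(20.6) and overflow == 0.0

    def test_inr_and_phone_free(self, params):
        state = CeilingState()
        assert patient_fee(make_contact(day=1, kind="inr"), state, params) == (0.0, 0.0)
        assert patient_fee(make_contact(day=2, kind="phone"), state, params) == (0.0, 0.0)

    def test_out_of_order_dates_rejected(self, params):
        state = CeilingState()
        patient_fee(make_contact(day=5, kind="primary_visit"), state, params)
        with pytest.raises(CostModelError):
            patient_fee(make_contact(day=1, kind="primary_visit"), state, params)

    def test_ceiling_conservation_property(self, params):
        # 30 ward days: nominal 30*48.9 = 1467; patient pays exactly 683
        contacts = [make_contact(day=d, kind="specialised_ward_day") for d in range(30)]
        fees = process_fees(contacts, params)
        paid = sum(v[0] for v in fees.values())
        overflow = sum(v[1] for v in fees.values())
        assert paid == pytest.approx(683.0)
        assert paid + overflow == pytest.approx(30 * 48.9)
        assert paid <= params.payment_ceiling + 1e-9


class TestComposeDaily:
    def test_no_contacts_only_drug(self, params):
        patient = make_patient(arm="warfarin")
        rec = compose_daily(patient, [], [], params, {})
        assert rec.c_m == rec.c_t == rec.c_d == 0.0
        assert rec.c_a == pytest.approx(0.08)
        assert rec.c_p == pytest.approx(0.08)
        assert rec.healthcare_total == pytest.approx(0.05)

    def test_inr_walking_day_hand_arithmetic(self, params):
        # retired, €12/h: 1 INR visit, walking 1 km each way (0.25 h per leg)
        patient = make_patient(age=70, income=12.0)
        contact = make_contact(pid=patient.id, day=1, kind="inr")
        journey = make_journey(patient, day=1, mode="walking", legs="roundtrip", d=1.0, t=0.25)
        fees = process_fees([contact], params)
        rec = compose_daily(patient, [journey], [contact], params, fees)
        assert rec.c_m == pytest.approx(2.1)
        assert rec.c_t == pytest.approx(0.35 * 12.0 * 0.5)  # 2.1, both legs
        assert rec.c_d == 0.0
        assert rec.inr_cost == pytest.approx(31.0)
        assert rec.c_p == pytest.approx(rec.c_m + rec.c_a + rec.c_t + rec.c_d)

    def test_year_of_drug_only(self, params):
        patient = make_patient(arm="warfarin")
        rec = drug_only_record(patient, 365, params)
        assert rec.healthcare_total == pytest.approx(365 * 0.05)  # 18.25
        assert rec.c_p == pytest.approx(365 * 0.08)  # 29.2

    def test_additivity_exact(self, params):
        patient = make_patient(age=50, income=15.0)
        contacts = [
            make_contact(pid=patient.id, day=3, kind="inr"),
            make_contact(pid=patient.id, day=3, kind="primary_visit", healthcare_unit_cost=65.0),
        ]
        journey = make_journey(patient, day=3, mode="car", legs="roundtrip", d=8.0, t=0.1)
        fees = process_fees(contacts, params)
        rec = compose_daily(patient, [journey], contacts, params, fees)
        assert rec.c_p == rec.c_m + rec.c_a + rec.c_t + rec.c_d  # exact, not approx

    def test_mixed_dates_rejected(self, params):
        patient = make_patient()
        contacts = [make_contact(pid=patient.id, day=1), make_contact(pid=patient.id, day=2)]
        with pytest.raises(CostModelError):
            compose_daily(patient, [], contacts, params, {})

    def test_wrong_patient_rejected(self, params):
        patient = make_patient(pid="W1")
        with pytest.raises(CostModelError):
            compose_daily(patient, [], [make_contact(pid="W2", day=1)], params, {})

    def test_reimbursed_journey_society_cost(self, params):
        patient = make_patient(age=70)
        contact = make_contact(pid=patient.id, day=2, kind="specialised_visit", healthcare_unit_cost=300.0)
        record = ReimbursementRecord(patient.id, contact.date, "taxi", 25.0, 63.5)
        journey = make_journey(patient, day=2, mode="taxi", d=30.0, t=0.5, record=record)
        fees = process_fees([contact], params)
        rec = compose_daily(patient, [journey], [contact], params, fees)
        assert rec.c_d == pytest.approx(25.0)  # record overrides, counted once
        assert rec.k == pytest.approx(63.5)


def test_parameter_validation():
    params = CostParameters(o_c=-1.0)
    with pytest.raises(CostModelError):
        params.validate()
    bad_bands = CostParameters(f_b_bands=((10.0, 2.0), (5.0, 3.8), (math.inf, 5.0)))
    with pytest.raises(CostModelError):
        bad_bands.validate()
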