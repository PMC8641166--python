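"""Per-mode travel costs, time costs, drug payer splits, the patient fee
schedule with the €683 annual payment ceiling, and per-day cost
composition for both payers.

Units: euros, kilometres, hours.  The daily patient cost decomposes
exactly into monitoring time cost + direct therapy cost + travelling time
cost + travel cost; the daily healthcare cost sums visit/ward accounting
costs, the society drug share, reimbursed travel, per-visit INR
monitoring cost and any fee overflow above the ceiling.

Note on the time-cost formula for car and taxi: the parking/service time
penalty is a *time* quantity, so it is valued inside the wage term —
``p_a * c_h * (t_j + t_a)`` per leg — keeping the expression dimensionally
consistent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Iterable, Mapping, Sequence

import yaml

from .cohort import Contact, Patient
from .travel_model import Journey, ReimbursementRecord

ARM_DRUG_KEYS = ("warfarin", "doac")


class CostModelError(ValueError):
    pass


@dataclass
class CostParameters:
    """Fixed price and tariff parameters of the cost model."""

    t_m: float = 0.5  # h spent per INR monitoring visit
    t_a: float = 0.083  # h parking (car) or service (taxi) time per leg
    o_c: float = 0.43  # €/km car operating cost
    o_t: float = 1.59  # €/km taxi operating cost
    f_t: float = 5.9  # € taxi fixed charge
    #: bus fare bands as (max one-way distance km, fare €); last band open-ended
    f_b_bands: tuple[tuple[float, float], ...] = (
        (15.0, 2.00),
        (40.0, 3.80),
        (math.inf, 5.00),
    )
    warfarin_daily_patient: float = 0.08
    warfarin_daily_society: float = 0.05
    doac_daily_patient: float = 0.95
    doac_daily_society: float = 1.76
    v_p_fee: float = 20.6  # € primary-care visit fee (physician; nurse 11.4)
    v_s_fee: float = 41.2  # € specialised-care visit fee
    ward_day_fee: float = 48.9  # € inpatient ward fee per day, both care levels
    i_s: float = 31.0  # € INR monitoring cost to healthcare per visit
    payment_ceiling: float = 683.0  # € annual cap on patient healthcare fees
    reimbursement_rate: dict[str, float] = field(
        default_factory=lambda: {"warfarin": 0.40, "doac": 0.65}
    )
    home_inr_patient_fee: float = 12.0  # € home-care fee per home INR visit
    home_inr_extra_society: float = 40.0  # € home-care visit cost to healthcare
    phone_unit_cost_default: float = 30.0  # € healthcare cost of a phone contact

    def validate(self) -> None:
        numeric = (
            self.t_m, self.t_a, self.o_c, self.o_t, self.f_t,
            self.warfarin_daily_patient, self.warfarin_daily_society,
            self.doac_daily_patient, self.doac_daily_society,
            self.v_p_fee, self.v_s_fee, self.ward_day_fee, self.i_s,
            self.payment_ceiling, self.home_inr_patient_fee,
            self.home_inr_extra_society,
        )
        if any(x < 0 for x in numeric):
            raise CostModelError("all cost parameters must be non-negative")
        prev = 0.0
        for i, (limit, fare) in enumerate(self.f_b_bands):
            if fare < 0:
                raise CostModelError("bus fares must be non-negative")
            if limit <= prev:
                raise CostModelError("bus fare bands must have increasing distance limits")
            prev = limit
        if not math.isinf(self.f_b_bands[-1][0]):
            raise CostModelError("last bus fare band must be open-ended (inf limit)")

    def bus_fare(self, distance_km: float) -> float:
        for limit, fare in self.f_b_bands:
            if distance_km <= limit:
                return fare
        raise CostModelError("no bus fare band matched")  # unreachable: last band is inf

    def drug_daily(self, arm: str) -> tuple[float, float]:
        if arm == "warfarin":
            return self.warfarin_daily_patient, self.warfarin_daily_society
        if arm == "doac":
            return self.doac_daily_patient, self.doac_daily_society
        raise CostModelError(f"unknown therapy arm {arm!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "CostParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "f_b_bands" in data:
            data["f_b_bands"] = tuple(
                (math.inf if str(lim) in ("inf", ".inf") else float(lim), float(fare))
                for lim, fare in data["f_b_bands"]
            )
        params = cls(**data)
        params.validate()
        return params


def travel_cost(
    mode: str,
    distance_km: float,
    reimbursement: ReimbursementRecord | None,
    params: CostParameters,
) -> tuple[float, float]:
    """(patient €, society €) for one journey leg.

    Formula costs: car ``o_c * d``, taxi ``f_t + o_t * d``, walking 0, bus
    the banded fare — all patient-only.  A reimbursement record overrides
    the formula with its recorded split (returned once for the journey, do
    not multiply by legs).  Ambulance journeys are only costed from
    records.
    """
    if distance_km < 0:
        raise CostModelError("distance must be non-negative")
    if reimbursement is not None:
        return reimbursement.patient_cost, reimbursement.society_cost
    if mode == "car":
        return params.o_c * distance_km, 0.0
    if mode == "taxi":
        return params.f_t + params.o_t * distance_km, 0.0
    if mode == "walking":
        return 0.0, 0.0
    if mode == "bus":
        return params.bus_fare(distance_km), 0.0
    if mode == "ambulance":
        raise CostModelError("ambulance journeys require a reimbursement record")
    raise CostModelError(f"unknown travel mode {mode!r}")


def time_cost_travel(
    mode: str, t_j: float, p_a: float, c_h: float, params: CostParameters
) -> float:
    """Time cost (€) of one journey leg.

    Car and taxi legs add the parking/service time ``t_a`` to the travel
    time before valuing it; walking, bus and ambulance legs value the
    travel time alone.
    """
    if t_j < 0 or p_a < 0 or c_h < 0:
        raise CostModelError("time-cost inputs must be non-negative")
    if mode in ("car", "taxi"):
        return p_a * c_h * (t_j + params.t_a)
    if mode in ("walking", "bus", "ambulance"):
        return p_a * c_h * t_j
    raise CostModelError(f"unknown travel mode {mode!r}")


def time_cost_monitoring(m: int, p_a: float, c_h: float, params: CostParameters) -> float:
    """Time cost (€) of ``m`` INR monitoring visits in a day: m·c_h·p_a·t_m."""
    if m < 0:
        raise CostModelError("monitoring count must be non-negative")
    return m * c_h * p_a * params.t_m


def drug_daily_cost(arm: str, params: CostParameters) -> tuple[float, float]:
    """(patient €, society €) daily anticoagulant cost for a therapy arm.

    Warns when the configured split disagrees with the reimbursement rate
    (patient share should be 1 − rate) by more than 0.02.
    """
    patient, society = params.drug_daily(arm)
    total = patient + society
    if total > 0:
        rate = params.reimbursement_rate.get(arm)
        if rate is not None and abs(patient / total - (1.0 - rate)) > 0.02:
            warnings.warn(
                f"{arm}: configured drug split (patient share {patient / total:.3f}) "
                f"is inconsistent with reimbursement rate {rate:.2f}",
                stacklevel=2,
            )
    return patient, society


NOMINAL_FEE_BY_KIND = {
    "inr": "zero",
    "phone": "zero",
    "primary_visit": "v_p_fee",
    "specialised_visit": "v_s_fee",
    "emergency_visit": "v_s_fee",  # billed as a specialised-care visit
    "primary_ward_day": "ward_day_fee",
    "specialised_ward_day": "ward_day_fee",
}


class CeilingState:
    """Running total of one patient's ceiling-eligible fees, date-ordered."""

    def __init__(self) -> None:
        self.cumulative = 0.0
        self.last_date: Date | None = None
        self.reached_on: Date | None = None

    def charge(self, nominal: float, on: Date, ceiling: float) -> tuple[float, float]:
        if self.last_date is not None and on < self.last_date:
            raise CostModelError("fees must be processed in date order (ceiling is order-dependent)")
        self.last_date = on
        headroom = max(ceiling - self.cumulative, 0.0)
        paid = min(nominal, headroom)
        overflow = nominal - paid
        self.cumulative += paid
        if overflow > 0 and self.reached_on is None:
            self.reached_on = on
        return paid, overflow


def nominal_fee(contact: Contact, params: CostParameters) -> float:
    if contact.kind == "inr" and contact.at_home:
        return params.home_inr_patient_fee
    attr = NOMINAL_FEE_BY_KIND[contact.kind]
    return 0.0 if attr == "zero" else getattr(params, attr)


def patient_fee(
    contact: Contact, ceiling_state: CeilingState, params: CostParameters
) -> tuple[float, float]:
    """(fee paid by patient €, overflow absorbed by healthcare €).

    The nominal fee depends on the contact kind; the cumulative part above
    the annual payment ceiling is rerouted to public healthcare
    expenditure.  Contacts must be presented in date order.
    """
    return ceiling_state.charge(nominal_fee(contact, params), contact.date, params.payment_ceiling)


def process_fees(
    contacts: Sequence[Contact], params: CostParameters
) -> dict[str, tuple[float, float]]:
    """Ceiling-process a patient's contacts; contact id -> (paid, overflow)."""
    state = CeilingState()
    out: dict[str, tuple[float, float]] = {}
    for contact in sorted(contacts, key=lambda c: (c.date, c.id)):
        out[contact.id] = patient_fee(contact, state, params)
    return out


@dataclass
class DailyCostRecord:
    """Cost components of one patient-day (or a drug-only stretch of days).

    ``n_days`` is 1 for dated activity records; the pipeline emits a single
    record covering all remaining no-contact days of the window so that
    annual totals stay exactly additive.
    """

    patient_id: str
    date: Date | None
    n_days: int
    # patient side
    c_m: float  # INR-management time cost
    c_a: float  # direct therapy cost: drug + fees
    c_t: float  # travelling time cost
    c_d: float  # travel cost
    c_p: float  # daily patient total (= c_m + c_a + c_t + c_d)
    drug_patient: float
    fees_paid: float
    # healthcare side
    e_p: float  # primary visit + phone accounting costs
    e_s: float  # specialised/emergency visit accounting costs
    w_p: float  # primary ward accounting costs
    w_s: float  # specialised ward accounting costs
    d_h: float  # society drug cost
    k: float  # society travel reimbursement
    inr_cost: float  # m * i_s (+ home-care extras)
    fee_overflow: float
    healthcare_total: float


def journey_costs(
    journey: Journey, patient: Patient, params: CostParameters
) -> tuple[float, float, float]:
    """(patient travel €, society travel €, time cost €) for a journey.

    Formula travel costs and time costs apply per leg; a reimbursement
    record's costs cover the whole journey and are counted once.
    """
    n = journey.n_legs
    time = n * time_cost_travel(
        journey.mode, journey.time_h, patient.wage_coefficient, patient.hourly_income, params
    )
    if journey.reimbursement is not None:
        pat, soc = travel_cost(journey.mode, journey.distance_km, journey.reimbursement, params)
    else:
        leg_pat, leg_soc = travel_cost(journey.mode, journey.distance_km, None, params)
        pat, soc = n * leg_pat, n * leg_soc
    return pat, soc, time


def compose_daily(
    patient: Patient,
    journeys: Sequence[Journey],
    contacts: Sequence[Contact],
    params: CostParameters,
    fees: Mapping[str, tuple[float, float]],
) -> DailyCostRecord:
    """Daily cost record for one patient-day from resolved journeys,
    contacts and ceiling-processed fees."""
    dates = {j.date for j in journeys} | {c.date for c in contacts}
    if len(dates) > 1:
        raise CostModelError("journeys/contacts span more than one date")
    owners = {j.patient_id for j in journeys} | {c.patient_id for c in contacts}
    if owners - {patient.id}:
        raise CostModelError("journeys/contacts belong to a different patient")
    day = dates.pop() if dates else None

    drug_patient, drug_society = drug_daily_cost(patient.arm, params)

    m = sum(1 for c in contacts if c.kind == "inr")
    c_m = time_cost_monitoring(m, patient.wage_coefficient, patient.hourly_income, params)

    fees_paid = fee_overflow = 0.0
    e_p = e_s = w_p = w_s = 0.0
    home_inr_extra = 0.0
    for c in contacts:
        paid, over = fees.get(c.id, (0.0, 0.0))
        fees_paid += paid
        fee_overflow += over
        if c.kind in ("primary_visit", "phone"):
            e_p += c.healthcare_unit_cost
        elif c.kind in ("specialised_visit", "emergency_visit"):
            e_s += c.healthcare_unit_cost
        elif c.kind == "primary_ward_day":
            w_p += c.healthcare_unit_cost
        elif c.kind == "specialised_ward_day":
            w_s += c.healthcare_unit_cost
        if c.kind == "inr" and c.at_home:
            home_inr_extra += params.home_inr_extra_society

    c_t = c_d = k = 0.0
    for j in journeys:
        pat, soc, time = journey_costs(j, patient, params)
        c_d += pat
        k += soc
        c_t += time

    c_a = drug_patient + fees_paid
    c_p = c_m + c_a + c_t + c_d
    inr_cost = m * params.i_s + home_inr_extra
    healthcare_total = e_p + e_s + w_p + w_s + drug_society + k + inr_cost + fee_overflow
    return DailyCostRecord(
        patient_id=patient.id,
        date=day,
        n_days=1,
        c_m=c_m,
        c_a=c_a,
        c_t=c_t,
        c_d=c_d,
        c_p=c_p,
        drug_patient=drug_patient,
        fees_paid=fees_paid,
        e_p=e_p,
        e_s=e_s,
        w_p=w_p,
        w_s=w_s,
        d_h=drug_society,
        k=k,
        inr_cost=inr_cost,
        fee_overflow=fee_overflow,
        healthcare_total=healthcare_total,
    )


def drug_only_record(patient: Patient, n_days: int, params: CostParameters) -> DailyCostRecord:
    """Aggregate record for ``n_days`` without any healthcare contact."""
    if n_days < 0:
        raise CostModelError("n_days must be non-negative")
    drug_patient, drug_society = drug_daily_cost(patient.arm, params)
    return DailyCostRecord(
        patient_id=patient.id,
        date=None,
        n_days=n_days,
        c_m=0.0,
        c_a=n_days * drug_patient,
        c_t=0.0,
        c_d=0.0,
        c_p=n_days * drug_patient,
        drug_patient=n_days * drug_patient,
        fees_paid=0.0,
        e_p=0.0,
        e_s=0.0,
        w_p=0.0,
        w_s=0.0,
        d_h=n_days * drug_society,
        k=0.0,
        inr_cost=0.0,
        fee_overflow=0.0,
        healthcare_total=n_days * drug_society,
    )
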