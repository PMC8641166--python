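"""Cohort selection, contact filtering and the wage coefficient.

Inclusion rules: not in a nursing home, AF diagnosed before the window,
resident in-district, alive at window end, and one continuous anticoagulant
prescription covering the window plus the 60 days before it, with no switch
between drug classes in that span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Sequence

from .config import CONTACT_KINDS, DIAGNOSIS_CLASSES, WARD_KINDS

PRE_WINDOW_DAYS = 60

#: drug name -> therapy class
DRUG_CLASS = {
    "warfarin": "warfarin",
    "dabigatran": "doac",
    "rivaroxaban": "doac",
    "edoxaban": "doac",
    "apixaban": "doac",
}

WORKING_AGE_LIMIT = 65
RETIRED_WAGE_COEFFICIENT = 0.35


class CohortDataError(ValueError):
    """Raised on internally inconsistent registry rows."""


@dataclass(frozen=True)
class Prescription:
    drug: str
    start: date
    end: date

    @property
    def therapy(self) -> str:
        try:
            return DRUG_CLASS[self.drug]
        except KeyError:
            raise CohortDataError(f"unknown anticoagulant drug {self.drug!r}") from None


@dataclass
class Patient:
    id: str
    arm: str  # warfarin | doac
    age: float
    sex: str  # F | M
    home_node: object
    urban: bool
    hourly_income: float  # c_h, €/h
    wage_coefficient: float = 0.0  # p_a; derived from age when left at 0
    alive_at_end: bool = True
    in_district: bool = True
    nursing_home: bool = False
    af_diagnosis_date: date | None = None
    prescriptions: list[Prescription] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age < 18:
            raise CohortDataError(f"patient {self.id}: age {self.age} < 18")
        if self.hourly_income <= 0:
            raise CohortDataError(f"patient {self.id}: hourly income must be > 0")
        if not self.wage_coefficient:
            self.wage_coefficient = wage_coefficient(self.age)


@dataclass
class Contact:
    """One dated AF-related healthcare event."""

    id: str
    patient_id: str
    date: date
    kind: str
    urgent: bool = False
    diagnosis_class: str = "af"
    facility_id: str | None = None
    healthcare_unit_cost: float = 0.0  # accounting cost to the provider, €
    at_home: bool = False  # home-care INR measurement

    def __post_init__(self) -> None:
        if self.kind not in CONTACT_KINDS:
            raise CohortDataError(f"contact {self.id}: unknown kind {self.kind!r}")
        if self.diagnosis_class not in DIAGNOSIS_CLASSES:
            raise CohortDataError(
                f"contact {self.id}: unknown diagnosis class {self.diagnosis_class!r}"
            )
        if self.healthcare_unit_cost < 0:
            raise CohortDataError(f"contact {self.id}: negative unit cost")


def wage_coefficient(age: float, *, retirement_age: float = WORKING_AGE_LIMIT) -> float:
    """Hourly gross-wage weight: 1.0 below retirement age, 0.35 at or above.

    Working time is valued at the full hourly wage; lost leisure time of a
    retired person at 35% of it.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return 1.0 if age < retirement_age else RETIRED_WAGE_COEFFICIENT


def _merge_intervals(
    intervals: Sequence[tuple[date, date]], gap_days: int
) -> list[tuple[date, date]]:
    merged: list[tuple[date, date]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + timedelta(days=gap_days + 1):
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _prescriptions_by_class(patient: Patient) -> dict[str, list[tuple[date, date]]]:
    """Group prescription intervals by therapy class, rejecting contradictions.

    Prescriptions of different classes overlapping in time are a
    data-integrity error (a patient cannot be on both therapies at once).
    """
    by_class: dict[str, list[tuple[date, date]]] = {}
    for rx in patient.prescriptions:
        if rx.end < rx.start:
            raise CohortDataError(f"patient {patient.id}: prescription ends before it starts")
        by_class.setdefault(rx.therapy, []).append((rx.start, rx.end))
    for cls_a in by_class:
        for cls_b in by_class:
            if cls_a >= cls_b:
                continue
            for sa, ea in by_class[cls_a]:
                for sb, eb in by_class[cls_b]:
                    if sa <= eb and sb <= ea:
                        raise CohortDataError(
                            f"patient {patient.id}: overlapping {cls_a}/{cls_b} prescriptions"
                        )
    return by_class


def _continuous_therapy(
    patient: Patient, span: tuple[date, date], gap_days: int
) -> str | None:
    """Therapy class held continuously over ``span``; None if no single one.

    Raises :class:`CohortDataError` when prescriptions of different classes
    overlap in time (contradictory records).
    """
    by_class = _prescriptions_by_class(patient)
    covering = []
    for cls, spans in by_class.items():
        for start, end in _merge_intervals(spans, gap_days):
            if start <= span[0] and end >= span[1]:
                covering.append(cls)
                break
    if len(covering) == 1:
        return covering[0]
    return None


def _switched_therapy(patient: Patient, span: tuple[date, date]) -> bool:
    """True when prescriptions of more than one class touch the span."""
    classes = {
        rx.therapy
        for rx in patient.prescriptions
        if rx.start <= span[1] and rx.end >= span[0]
    }
    return len(classes) > 1


EXCLUSION_RULES = (
    "nursing_home",
    "no_af_diagnosis_before_window",
    "outside_district",
    "not_alive_at_end",
    "no_continuous_prescription",
    "therapy_switch",
)


def select_cohort(
    patients: Iterable[Patient],
    contacts: Iterable[Contact] | None = None,
    window: tuple[date, date] | None = None,
    *,
    prescription_gap_days: int = 0,
) -> tuple[list[Patient], list[Patient], dict[str, int]]:
    """Apply the inclusion/attrition rules and split the cohort into arms.

    Returns ``(warfarin_group, doac_group, attrition_log)``, where the log
    counts exclusions per rule (each patient is charged to the first rule
    that fails, in the documented order).  The retained patient's ``arm`` is
    set to the therapy class of the covering prescription.
    """
    from .config import STUDY_WINDOW

    window = window or STUDY_WINDOW
    span = (window[0] - timedelta(days=PRE_WINDOW_DAYS), window[1])
    log = {rule: 0 for rule in EXCLUSION_RULES}
    warfarin: list[Patient] = []
    doac: list[Patient] = []
    for patient in patients:
        if patient.nursing_home:
            log["nursing_home"] += 1
            continue
        if patient.af_diagnosis_date is None or patient.af_diagnosis_date >= window[0]:
            log["no_af_diagnosis_before_window"] += 1
            continue
        if not patient.in_district:
            log["outside_district"] += 1
            continue
        if not patient.alive_at_end:
            log["not_alive_at_end"] += 1
            continue
        _prescriptions_by_class(patient)  # raises on contradictory overlaps
        if _switched_therapy(patient, span):
            log["therapy_switch"] += 1
            continue
        therapy = _continuous_therapy(patient, span, prescription_gap_days)
        if therapy is None:
            log["no_continuous_prescription"] += 1
            continue
        patient.arm = therapy
        (warfarin if therapy == "warfarin" else doac).append(patient)
    return warfarin, doac, log


#: contacts always retained regardless of diagnosis
_ALWAYS_KEPT_KINDS = frozenset({"inr"})
_ALWAYS_KEPT_CLASSES = frozenset({"af", "gi_bleed"})
_EPISODE_GATED_CLASSES = frozenset({"ischemic_stroke", "intracerebral_haemorrhage"})
EPISODE_GAP_DAYS = 1  # contacts within this many days belong to one episode


def _episodes(contacts: list[Contact]) -> list[list[Contact]]:
    contacts = sorted(contacts, key=lambda c: (c.date, c.id))
    episodes: list[list[Contact]] = []
    for contact in contacts:
        if episodes and (contact.date - episodes[-1][-1].date).days <= EPISODE_GAP_DAYS:
            episodes[-1].append(contact)
        else:
            episodes.append([contact])
    return episodes


def filter_af_contacts(contacts: Iterable[Contact]) -> list[Contact]:
    """Keep the anticoagulation-relevant contact subset.

    INR measurements and AF / gastrointestinal-bleeding contacts are always
    kept.  Stroke and intracerebral-haemorrhage contacts survive only when
    their episode (same patient, dates at most one day apart) contains both
    an urgent visit and at least one inpatient ward day.  Everything else is
    dropped.  The filter is idempotent and order-preserving.
    """
    contacts = list(contacts)
    gated: dict[str, list[Contact]] = {}
    for c in contacts:
        if c.diagnosis_class in _EPISODE_GATED_CLASSES and c.kind not in _ALWAYS_KEPT_KINDS:
            gated.setdefault(c.patient_id, []).append(c)
    kept_gated: set[str] = set()
    for patient_id, pcs in gated.items():
        for episode in _episodes(pcs):
            has_urgent = any(c.urgent or c.kind == "emergency_visit" for c in episode)
            has_ward = any(c.kind in WARD_KINDS for c in episode)
            if has_urgent and has_ward:
                kept_gated.update(c.id for c in episode)
    out: list[Contact] = []
    for c in contacts:
        if c.kind in _ALWAYS_KEPT_KINDS or c.diagnosis_class in _ALWAYS_KEPT_CLASSES:
            out.append(c)
        elif c.diagnosis_class in _EPISODE_GATED_CLASSES and c.id in kept_gated:
            out.append(c)
    return out


#: minimal ICD-10 / ICPC-2 prefix map onto the diagnosis-class enum, for
#: adapting real registry extracts; the synthetic pipeline bypasses it.
ICD_PREFIX_CLASS = {
    "I48": "af",
    "K78": "af",  # ICPC-2
    "I63": "ischemic_stroke",
    "I60": "intracerebral_haemorrhage",
    "I61": "intracerebral_haemorrhage",
    "I62": "intracerebral_haemorrhage",
    "K22": "gi_bleed",
    "K25": "gi_bleed",
    "K26": "gi_bleed",
    "K27": "gi_bleed",
    "K28": "gi_bleed",
    "K63": "gi_bleed",
    "K92": "gi_bleed",
}


def classify_diagnosis(code: str) -> str:
    """Map a raw ICD-10/ICPC-2 code string to the diagnosis-class enum."""
    code = code.strip().upper().replace(".", "")
    for prefix, cls in ICD_PREFIX_CLASS.items():
        if code.startswith(prefix):
            return cls
    return "other"
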