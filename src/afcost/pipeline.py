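"""End-to-end pipeline: synthesis -> selection -> trips -> costs -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import pandas as pd

from . import io as afio
from .cohort import Contact, Patient, filter_af_contacts, select_cohort
from .config import STUDY_DAYS, CohortConfig, GeographyConfig
from .cost_engine import CostParameters, compose_daily, drug_only_record, process_fees
from .reporting import (
    cost_table,
    per_patient_annual,
    records_to_frame,
    render_report,
    utilisation_table,
)
from .routing import Geography, RoutingIndex
from .synthetic_data import (
    generate_cohort,
    generate_contacts,
    generate_geography,
    generate_reimbursements,
)
from .travel_model import Journey, ReimbursementRecord, plan_trips, resolve_journeys

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    geography: Geography
    patients: list[Patient]
    warfarin: list[Patient]
    doac: list[Patient]
    attrition: dict[str, int]
    contacts: list[Contact]
    reimbursements: list[ReimbursementRecord]
    journeys: list[Journey]
    daily: pd.DataFrame
    annual: pd.DataFrame
    table: pd.DataFrame
    utilisation: pd.DataFrame


def compute_costs(
    patients: list[Patient],
    contacts: list[Contact],
    reimbursements: list[ReimbursementRecord],
    geo: Geography,
    params: CostParameters,
    *,
    routing_index: RoutingIndex | None = None,
    window_days: int = STUDY_DAYS,
) -> tuple[pd.DataFrame, list[Journey]]:
    """Daily cost records (as a frame) and resolved journeys for a cohort.

    Every patient accrues daily drug costs over the whole window; days
    without contacts are folded into one drug-only record per patient so
    totals remain exactly additive.
    """
    index = routing_index or RoutingIndex(geo)
    contacts_by_patient: dict[str, list[Contact]] = {}
    for c in contacts:
        contacts_by_patient.setdefault(c.patient_id, []).append(c)
    records_by_patient: dict[str, list[ReimbursementRecord]] = {}
    for r in reimbursements:
        records_by_patient.setdefault(r.patient_id, []).append(r)
    stubs_by_patient: dict[str, list] = {}
    for stub in plan_trips(contacts):
        stubs_by_patient.setdefault(stub.patient_id, []).append(stub)

    all_records = []
    all_journeys: list[Journey] = []
    for patient in patients:
        pcs = contacts_by_patient.get(patient.id, [])
        journeys = resolve_journeys(
            stubs_by_patient.get(patient.id, []),
            geo,
            patient,
            records_by_patient.get(patient.id, []),
            routing_index=index,
        )
        all_journeys.extend(journeys)
        fees = process_fees(pcs, params)
        by_day: dict[Date, tuple[list[Contact], list[Journey]]] = {}
        for c in pcs:
            by_day.setdefault(c.date, ([], []))[0].append(c)
        for j in journeys:
            by_day.setdefault(j.date, ([], []))[1].append(j)
        for day in sorted(by_day):
            day_contacts, day_journeys = by_day[day]
            all_records.append(compose_daily(patient, day_journeys, day_contacts, params, fees))
        rest = window_days - len(by_day)
        if rest > 0:
            all_records.append(drug_only_record(patient, rest, params))
    return records_to_frame(all_records), all_journeys


def run_pipeline(
    cohort_config: CohortConfig | None = None,
    geo_config: GeographyConfig | None = None,
    params: CostParameters | None = None,
) -> PipelineResult:
    """Run the full synthetic study and return every intermediate product."""
    cohort_config = cohort_config or CohortConfig()
    geo_config = geo_config or GeographyConfig(seed=cohort_config.seed)
    params = params or CostParameters()
    params.validate()

    log.info("generating geography (%d nodes)", geo_config.n_nodes)
    geo = generate_geography(geo_config)
    index = RoutingIndex(geo)
    patients = generate_cohort(cohort_config, geo, routing_index=index)
    contacts = generate_contacts(patients, cohort_config)
    reimbursements = generate_reimbursements(contacts, cohort_config)

    warfarin, doac, attrition = select_cohort(patients)
    log.info("cohort selected: %d warfarin, %d doac, attrition=%s", len(warfarin), len(doac), attrition)
    selected = warfarin + doac
    selected_ids = {p.id for p in selected}
    af_contacts = [c for c in filter_af_contacts(contacts) if c.patient_id in selected_ids]

    daily, journeys = compute_costs(
        selected, af_contacts, reimbursements, geo, params, routing_index=index
    )
    annual = per_patient_annual(daily)
    warf_annual = annual.reindex([p.id for p in warfarin]).fillna(0.0)
    doac_annual = annual.reindex([p.id for p in doac]).fillna(0.0)
    table = cost_table(warf_annual, doac_annual)
    utilisation = utilisation_table(selected, af_contacts, journeys, routing_index=index)
    return PipelineResult(
        geography=geo,
        patients=patients,
        warfarin=warfarin,
        doac=doac,
        attrition=attrition,
        contacts=af_contacts,
        reimbursements=reimbursements,
        journeys=journeys,
        daily=daily,
        annual=annual,
        table=table,
        utilisation=utilisation,
    )


def save_result(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    afio.patients_frame(result.patients).to_csv(out / "patients.csv", index=False)
    afio.contacts_frame(result.contacts).to_csv(out / "contacts.csv", index=False)
    afio.reimbursements_frame(result.reimbursements).to_csv(out / "reimbursements.csv", index=False)
    afio.journeys_frame(result.journeys).to_csv(out / "journeys.csv", index=False)
    afio.write_geography(result.geography, out)
    afio.write_attrition(result.attrition, out / "attrition.json")
    cohort = afio.patients_frame(result.warfarin + result.doac)
    cohort.to_csv(out / "cohort.csv", index=False)
    result.daily.to_csv(out / "daily_costs.csv", index=False, float_format="%.4f")
    result.table.to_csv(out / "cost_table.csv", float_format="%.4f")
    result.utilisation.to_csv(out / "utilisation_table.csv", float_format="%.4f")
    (out / "report.md").write_text(render_report(result.table, result.utilisation))
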