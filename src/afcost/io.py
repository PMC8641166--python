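"""CSV/JSON serialisation of the pipeline tables.

All tables are plain CSV: dates ISO-8601, distances km, money €.
Prescription intervals are packed into one column as
``drug:start:end`` items separated by ``;``.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .cohort import Contact, Patient, Prescription
from .routing import Facility, Geography
from .travel_model import Journey, ReimbursementRecord


def _pack_prescriptions(prescriptions: Sequence[Prescription]) -> str:
    return ";".join(f"{rx.drug}:{rx.start.isoformat()}:{rx.end.isoformat()}" for rx in prescriptions)


def _unpack_prescriptions(packed: str) -> list[Prescription]:
    out = []
    for item in str(packed).split(";"):
        if not item:
            continue
        drug, start, end = item.split(":")
        out.append(Prescription(drug, date.fromisoformat(start), date.fromisoformat(end)))
    return out


def patients_frame(patients: Iterable[Patient]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": p.id,
                "arm": p.arm,
                "age": p.age,
                "sex": p.sex,
                "home_node": p.home_node,
                "urban": p.urban,
                "hourly_income": p.hourly_income,
                "wage_coefficient": p.wage_coefficient,
                "alive_at_end": p.alive_at_end,
                "in_district": p.in_district,
                "nursing_home": p.nursing_home,
                "af_diagnosis_date": p.af_diagnosis_date.isoformat() if p.af_diagnosis_date else "",
                "prescriptions": _pack_prescriptions(p.prescriptions),
            }
            for p in patients
        ]
    )


def read_patients(path: str | Path) -> list[Patient]:
    frame = pd.read_csv(path, keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            Patient(
                id=str(row.id),
                arm=str(row.arm),
                age=float(row.age),
                sex=str(row.sex),
                home_node=int(row.home_node),
                urban=bool(row.urban),
                hourly_income=float(row.hourly_income),
                wage_coefficient=float(row.wage_coefficient),
                alive_at_end=bool(row.alive_at_end),
                in_district=bool(row.in_district),
                nursing_home=bool(row.nursing_home),
                af_diagnosis_date=date.fromisoformat(row.af_diagnosis_date)
                if row.af_diagnosis_date
                else None,
                prescriptions=_unpack_prescriptions(row.prescriptions),
            )
        )
    return out


def contacts_frame(contacts: Iterable[Contact]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "patient_id": c.patient_id,
                "date": c.date.isoformat(),
                "kind": c.kind,
                "urgent": c.urgent,
                "diagnosis_class": c.diagnosis_class,
                "facility_id": c.facility_id or "",
                "healthcare_unit_cost": c.healthcare_unit_cost,
                "at_home": c.at_home,
            }
            for c in contacts
        ]
    )


def read_contacts(path: str | Path) -> list[Contact]:
    frame = pd.read_csv(path, keep_default_na=False)
    return [
        Contact(
            id=str(row.id),
            patient_id=str(row.patient_id),
            date=date.fromisoformat(row.date),
            kind=str(row.kind),
            urgent=bool(row.urgent),
            diagnosis_class=str(row.diagnosis_class),
            facility_id=str(row.facility_id) or None,
            healthcare_unit_cost=float(row.healthcare_unit_cost),
            at_home=bool(row.at_home),
        )
        for row in frame.itertuples(index=False)
    ]


def reimbursements_frame(records: Iterable[ReimbursementRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "date": r.date.isoformat(),
                "mode": r.mode,
                "patient_cost": r.patient_cost,
                "society_cost": r.society_cost,
                "contact_id": r.contact_id or "",
            }
            for r in records
        ]
    )


def read_reimbursements(path: str | Path) -> list[ReimbursementRecord]:
    frame = pd.read_csv(path, keep_default_na=False)
    return [
        ReimbursementRecord(
            patient_id=str(row.patient_id),
            date=date.fromisoformat(row.date),
            mode=str(row.mode),
            patient_cost=float(row.patient_cost),
            society_cost=float(row.society_cost),
            contact_id=str(row.contact_id) or None,
        )
        for row in frame.itertuples(index=False)
    ]


def journeys_frame(journeys: Iterable[Journey]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": j.patient_id,
                "date": j.date.isoformat(),
                "origin": j.origin,
                "facility_id": j.facility_id,
                "mode": j.mode,
                "legs": j.legs,
                "distance_km": j.distance_km,
                "time_h": j.time_h,
                "from_reimbursement": j.from_reimbursement,
            }
            for j in journeys
        ]
    )


def write_geography(geo: Geography, out_dir: str | Path) -> None:
    out = Path(out_dir)
    nodes = pd.DataFrame(
        [
            {"id": n, "x_km": data["pos"][0], "y_km": data["pos"][1]}
            for n, data in sorted(geo.graph.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {"u": u, "v": v, "length_km": d["length_km"], "speed_limit": d["speed_limit"]}
            for u, v, d in sorted(geo.graph.edges(data=True))
        ]
    )
    facilities = pd.DataFrame(
        [
            {"id": f.id, "kind": f.kind, "node": f.node, "bus_accessible": f.bus_accessible}
            for f in sorted(geo.facilities.values(), key=lambda f: f.id)
        ]
    )
    stops = pd.DataFrame({"node": list(geo.bus_stops)})
    nodes.to_csv(out / "network_nodes.csv", index=False)
    edges.to_csv(out / "network_edges.csv", index=False)
    facilities.to_csv(out / "facilities.csv", index=False)
    stops.to_csv(out / "bus_stops.csv", index=False)


def read_geography(in_dir: str | Path) -> Geography:
    src = Path(in_dir)
    nodes = pd.read_csv(src / "network_nodes.csv")
    edges = pd.read_csv(src / "network_edges.csv")
    facilities = pd.read_csv(src / "facilities.csv")
    stops = pd.read_csv(src / "bus_stops.csv")
    graph = nx.Graph()
    for row in nodes.itertuples(index=False):
        graph.add_node(int(row.id), pos=(float(row.x_km), float(row.y_km)))
    for row in edges.itertuples(index=False):
        graph.add_edge(
            int(row.u), int(row.v), length_km=float(row.length_km), speed_limit=float(row.speed_limit)
        )
    fac = {
        str(row.id): Facility(str(row.id), str(row.kind), int(row.node), bool(row.bus_accessible))
        for row in facilities.itertuples(index=False)
    }
    geo = Geography(graph=graph, facilities=fac, bus_stops=tuple(int(n) for n in stops["node"]))
    geo.validate()
    return geo


def write_attrition(log: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
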