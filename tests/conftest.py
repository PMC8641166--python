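from __future__ import annotations

from datetime import date, timedelta

import networkx as nx
import pytest

from afcost.cohort import Contact, Patient, Prescription
from afcost.config import STUDY_WINDOW
from afcost.cost_engine import CostParameters
from afcost.routing import Facility, Geography

WINDOW_START, WINDOW_END = STUDY_WINDOW


def build_geography(edges, facilities, bus_stops=()):
    """Explicit test network: edges = [(u, v, length_km, speed_limit), ...],
    facilities = [(id, kind, node, bus_accessible), ...]."""
    graph = nx.Graph()
    for u, v, length, speed in edges:
        graph.add_edge(u, v, length_km=length, speed_limit=speed)
    for node in graph.nodes:
        graph.nodes[node]["pos"] = (0.0, 0.0)
    fac = {f[0]: Facility(f[0], f[1], f[2], f[3] if len(f) > 3 else True) for f in facilities}
    return Geography(graph=graph, facilities=fac, bus_stops=tuple(bus_stops))


def make_patient(pid="W00001", arm="warfarin", age=70.0, home_node=0, income=12.0, **kw):
    defaults = dict(
        sex="F",
        urban=True,
        af_diagnosis_date=WINDOW_START - timedelta(days=365),
        prescriptions=[
            Prescription(
                "warfarin" if arm == "warfarin" else "apixaban",
                WINDOW_START - timedelta(days=120),
                WINDOW_END + timedelta(days=30),
            )
        ],
    )
    defaults.update(kw)
    return Patient(id=pid, arm=arm, age=age, home_node=home_node, hourly_income=income, **defaults)


_counter = iter(range(1, 10_000_000))


def make_contact(pid="W00001", day=0, kind="inr", **kw):
    return Contact(
        id=kw.pop("id", f"{pid}-t{next(_counter):06d}"),
        patient_id=pid,
        date=WINDOW_START + timedelta(days=day),
        kind=kind,
        **kw,
    )


@pytest.fixture
def params():
    p = CostParameters()
    p.validate()
    return p


@pytest.fixture
def line_geo():
    """0 -5km- 1 -5km- 2, hospital at 2, lab+health centre at 1, stop at 1."""
    return build_geography(
        edges=[(0, 1, 5.0, 50.0), (1, 2, 5.0, 80.0)],
        facilities=[
            ("hosp", "hospital", 2, True),
            ("lab01", "lab", 1, True),
            ("hc01", "health_centre", 1, True),
        ],
        bus_stops=(1, 2),
    )
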