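"""Seeded synthetic registry: geography, cohort, contacts, reimbursements.

The generators stand in for restricted registry extracts.  They are
first-class, deterministic components: every draw flows from a single seed
through named child streams, so two runs with the same configuration are
bit-identical and adding a generator does not perturb the others.

Distributional choices (documented, not sourced from any registry):
contact counts are negative binomial (over-dispersed, SD > mean), INR
monitoring dates are evenly spaced with jitter, ages are normal truncated
at 18, incomes normal truncated above zero, and home locations are matched
against a log-normal target for road distance to the nearest laboratory.
"""

from __future__ import annotations

import math
import zlib
from datetime import timedelta

import networkx as nx
import numpy as np

from .cohort import Contact, Patient, Prescription, wage_coefficient
from .config import (
    ARMS,
    STUDY_DAYS,
    STUDY_WINDOW,
    CohortConfig,
    ConfigError,
    GeographyConfig,
)
from .routing import Facility, Geography, RoutingIndex

#: discrete speed limits typical of a rural road network (km/h)
_SPEED_LIMIT_STEPS = np.array([30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 120.0])


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Named, independent child stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())]))


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial counts with the given mean and shape r = dispersion.

    Falls back to Poisson when the dispersion is infinite (no
    over-dispersion requested).
    """
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if not math.isfinite(dispersion):
        return rng.poisson(mean, size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, size: int
) -> np.ndarray:
    """Normal draws re-sampled below ``low`` (rejection; cheap for mild cuts)."""
    out = rng.normal(mean, sd, size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < low
    return out


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def generate_geography(config: GeographyConfig) -> Geography:
    """Random geometric road network with facilities and bus stops.

    Nodes are uniform in a square; each connects to its nearest neighbours
    and components are stitched together, so the result is always connected.
    The hospital sits at the node nearest the centroid; laboratories are
    co-located with health centres where possible.
    """
    config.validate()
    rng = child_rng(config.seed, "geography")
    n = config.n_nodes
    coords = rng.uniform(0.0, config.extent, size=(n, 2))
    graph = nx.Graph()
    for i in range(n):
        graph.add_node(i, pos=(float(coords[i, 0]), float(coords[i, 1])))

    def add_edge(i: int, j: int) -> None:
        if i == j or graph.has_edge(i, j):
            return
        straight = float(np.hypot(*(coords[i] - coords[j])))
        length = max(round(straight * config.road_curvature, 4), 1e-4)
        lo, hi = config.speed_limit_range
        steps = _SPEED_LIMIT_STEPS[(_SPEED_LIMIT_STEPS >= lo) & (_SPEED_LIMIT_STEPS <= hi)]
        if steps.size == 0:
            steps = np.array([lo])
        speed = float(rng.choice(steps))
        graph.add_edge(i, j, length_km=length, speed_limit=speed)

    k = min(config.knn, n - 1)
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    order = np.argsort(dmat, axis=1)
    for i in range(n):
        for j in order[i, 1 : k + 1]:
            add_edge(i, int(j))
    # stitch disconnected components via their closest node pair
    while not nx.is_connected(graph):
        components = sorted(nx.connected_components(graph), key=len, reverse=True)
        main, rest = components[0], components[1]
        best = None
        for i in sorted(rest):
            for j in sorted(main):
                d = dmat[i, j]
                if best is None or d < best[0]:
                    best = (d, i, j)
        add_edge(best[1], best[2])

    centroid = coords.mean(axis=0)
    hospital_node = int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))
    others = [i for i in range(n) if i != hospital_node]
    shuffled = list(rng.permutation(others))
    hc_nodes = shuffled[: config.n_health_centres]
    n_colocated = min(config.n_labs, len(hc_nodes))
    lab_nodes = hc_nodes[:n_colocated] + shuffled[
        len(hc_nodes) : len(hc_nodes) + (config.n_labs - n_colocated)
    ]
    if len(lab_nodes) < config.n_labs:  # tiny networks: allow the hospital node
        lab_nodes.append(hospital_node)

    facilities: dict[str, Facility] = {}
    facilities["hosp"] = Facility("hosp", "hospital", hospital_node, bus_accessible=True)
    for idx, node in enumerate(hc_nodes, start=1):
        fid = f"hc{idx:02d}"
        facilities[fid] = Facility(fid, "health_centre", int(node), bus_accessible=bool(rng.random() < 0.8))
    for idx, node in enumerate(lab_nodes, start=1):
        fid = f"lab{idx:02d}"
        facilities[fid] = Facility(fid, "lab", int(node), bus_accessible=bool(rng.random() < 0.8))

    stop_mask = rng.random(n) < config.bus_stop_density
    stop_mask[hospital_node] = True
    bus_stops = tuple(int(i) for i in np.flatnonzero(stop_mask))

    geo = Geography(graph=graph, facilities=facilities, bus_stops=bus_stops)
    geo.validate()
    return geo


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _clamped_lognormal_mu(mean: float, sd: float, cap: float) -> tuple[float, float]:
    """Log-normal location whose mean *after clamping at cap* equals ``mean``.

    Home distances are matched against network nodes, so draws beyond the
    largest attainable distance collapse onto it; without this correction
    the sample mean is biased low by the clamped tail mass.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    mu0, sigma = _lognormal_params(mean, sd)
    if cap <= mean or not math.isfinite(cap):
        return mu0, sigma

    def clamped_mean(mu: float) -> float:
        z = (math.log(cap) - mu) / sigma
        return math.exp(mu + sigma**2 / 2) * norm.cdf(z - sigma) + cap * norm.sf(z)

    lo, hi = mu0, mu0 + 3.0
    if clamped_mean(hi) < mean:  # cap too tight to ever reach the target
        return mu0, sigma
    mu = brentq(lambda m: clamped_mean(m) - mean, lo, hi, xtol=1e-10)
    return mu, sigma


def generate_cohort(
    config: CohortConfig, geography: Geography, *, routing_index: RoutingIndex | None = None
) -> list[Patient]:
    """Two-arm patient list with ages, incomes and matched home locations.

    Home nodes are chosen by quantile matching: a target road distance to
    the nearest laboratory is drawn from a log-normal with the configured
    moments and the node with the closest achievable distance is selected.
    All generated patients satisfy the downstream inclusion rules.
    """
    config.validate()
    rng = child_rng(config.seed, "cohort")
    index = routing_index or RoutingIndex(geography)

    nodes = sorted(geography.graph.nodes)
    node_lab_dist = np.array([index.nearest_lab(n)[1] for n in nodes])
    dist_order = np.argsort(node_lab_dist, kind="stable")
    sorted_dists = node_lab_dist[dist_order]
    mu, sigma = _clamped_lognormal_mu(
        config.lab_distance_mean, config.lab_distance_sd, float(sorted_dists[-1])
    )

    window_start, window_end = STUDY_WINDOW
    rx_start = window_start - timedelta(days=120)
    rx_end = window_end + timedelta(days=30)
    diagnosis_date = window_start - timedelta(days=365)

    patients: list[Patient] = []
    for arm, count, prefix, drug in (
        ("warfarin", config.n_warfarin, "W", "warfarin"),
        ("doac", config.n_doac, "D", "apixaban"),
    ):
        if count == 0:
            continue
        ages = _truncated_normal(rng, config.age_mean_by_arm[arm], config.age_sd_by_arm[arm], 18.0, count)
        sexes = np.where(rng.random(count) < config.female_share_by_arm[arm], "F", "M")
        incomes = _truncated_normal(rng, config.income_mean, config.income_sd, 0.01, count)
        urban = rng.random(count) < config.urban_share
        targets = rng.lognormal(mu, sigma, count)
        pos = np.searchsorted(sorted_dists, targets)
        for i in range(count):
            j = int(pos[i])
            # nearest achievable node distance to the drawn target
            if j >= len(sorted_dists):
                j = len(sorted_dists) - 1
            elif j > 0 and targets[i] - sorted_dists[j - 1] < sorted_dists[j] - targets[i]:
                j -= 1
            home = nodes[int(dist_order[j])]
            age = float(round(ages[i], 1))
            patients.append(
                Patient(
                    id=f"{prefix}{i + 1:05d}",
                    arm=arm,
                    age=age,
                    sex=str(sexes[i]),
                    home_node=home,
                    urban=bool(urban[i]),
                    hourly_income=float(round(incomes[i], 2)),
                    wage_coefficient=wage_coefficient(age),
                    af_diagnosis_date=diagnosis_date,
                    prescriptions=[Prescription(drug, rx_start, rx_end)],
                )
            )
    return patients


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _inr_days(rng: np.random.Generator, count: int) -> np.ndarray:
    """Evenly spaced monitoring days with jitter, within the study window."""
    base = (np.arange(count) + 0.5) / count * STUDY_DAYS
    jitter = rng.normal(0.0, 3.0, count)
    return np.clip(np.rint(base + jitter), 0, STUDY_DAYS - 1).astype(int)


def generate_contacts(patients: list[Patient], config: CohortConfig) -> list[Contact]:
    """Dated AF-related contact stream over the fixed 365-day window.

    Per patient: INR monitorings on a jittered routine schedule, routine
    visits/phone contacts on uniform days, baseline ward stays as runs of
    consecutive days, and complication episodes that always pair an urgent
    emergency visit with at least one inpatient ward day on consecutive
    dates.
    """
    config.validate()
    rng = child_rng(config.seed, "contacts")
    window_start = STUDY_WINDOW[0]
    unit = config.unit_costs
    contacts: list[Contact] = []
    for patient in patients:
        if patient.arm not in ARMS:
            raise ConfigError(f"patient {patient.id}: unknown arm {patient.arm!r}")
        counter = 0

        def emit(day: int, kind: str, *, urgent: bool = False, diagnosis: str = "af",
                 facility: str | None = None) -> None:
            nonlocal counter
            counter += 1
            contacts.append(
                Contact(
                    id=f"{patient.id}-c{counter:04d}",
                    patient_id=patient.id,
                    date=window_start + timedelta(days=int(day)),
                    kind=kind,
                    urgent=urgent,
                    diagnosis_class=diagnosis,
                    facility_id=facility,
                    healthcare_unit_cost=unit.get(kind, 0.0),
                )
            )

        inr_mean, inr_disp = config.inr_visits_per_year[patient.arm]
        m = int(_draw_counts(rng, inr_mean, inr_disp, 1)[0])
        if m > 0:
            for day in _inr_days(rng, m):
                emit(day, "inr")

        for kind, (mean, disp) in sorted(config.visit_rates[patient.arm].items()):
            count = int(_draw_counts(rng, mean, disp, 1)[0])
            if count == 0:
                continue
            if kind in ("primary_ward_day", "specialised_ward_day"):
                start = int(rng.integers(0, STUDY_DAYS))
                for day in range(start, min(start + count, STUDY_DAYS)):
                    emit(day, kind)
            else:
                for day in sorted(rng.integers(0, STUDY_DAYS, count)):
                    emit(int(day), kind)

        for diagnosis, prob in sorted(config.complication_probs[patient.arm].items()):
            if rng.random() >= prob:
                continue
            start = int(rng.integers(0, STUDY_DAYS - 1))
            stay = 1 + int(rng.poisson(3.0))
            emit(start, "emergency_visit", urgent=True, diagnosis=diagnosis)
            for day in range(start, min(start + stay, STUDY_DAYS)):
                emit(day, "specialised_ward_day", diagnosis=diagnosis)
    return contacts


# ---------------------------------------------------------------------------
# reimbursements
# ---------------------------------------------------------------------------

def generate_reimbursements(contacts: list[Contact], config: CohortConfig):
    """Partial travel-reimbursement records covering ~``kela_coverage`` of
    travel-generating contacts.

    Selected urgent contacts receive an ambulance record; other selected
    contacts are predominantly taxi journeys.  Each record carries the
    patient-paid and society-paid split.
    """
    from .travel_model import ReimbursementRecord

    config.validate()
    if not 0 <= config.kela_coverage <= 1:
        raise ConfigError("kela_coverage: must be in [0, 1]")
    rng = child_rng(config.seed, "reimbursements")
    records: list[ReimbursementRecord] = []
    for contact in contacts:
        if contact.kind == "phone":
            continue  # never generates a journey
        if rng.random() >= config.kela_coverage:
            continue
        if contact.urgent:
            mode = "ambulance"
            total = float(rng.lognormal(math.log(200.0), 0.4))
        else:
            mode = str(rng.choice(["taxi", "taxi", "taxi", "taxi", "car", "bus"]))
            total = float(rng.lognormal(math.log(40.0), 0.6))
        patient_cost = round(min(25.0, total), 2)
        society_cost = round(max(total - patient_cost, 0.0), 2)
        records.append(
            ReimbursementRecord(
                patient_id=contact.patient_id,
                date=contact.date,
                mode=mode,
                patient_cost=patient_cost,
                society_cost=society_cost,
                contact_id=contact.id,
            )
        )
    return records
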