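"""Aggregation of daily cost records into per-patient annual totals and a
two-arm comparison table with normal-theory confidence intervals.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Contact, Patient
from .config import WARD_KINDS
from .cost_engine import DailyCostRecord
from .routing import RoutingIndex
from .travel_model import Journey

#: cost components reported per patient, in table order
COST_COMPONENTS = (
    "total_healthcare",
    "total_patient",
    "total_combined",
    "time_travel",
    "time_cost",
    "travel_cost",
    "fees",
    "drug_patient",
    "inr_monitoring",
    "primary_visit",
    "specialised_visit",
    "primary_ward",
    "specialised_ward",
    "drug_society",
    "society_travel",
)


def records_to_frame(records: Iterable[DailyCostRecord]) -> pd.DataFrame:
    """Daily cost records as a tidy frame with derived component columns."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "date": r.date,
                "n_days": r.n_days,
                "c_m": r.c_m,
                "c_a": r.c_a,
                "c_t": r.c_t,
                "c_d": r.c_d,
                "total_patient": r.c_p,
                "time_cost": r.c_m + r.c_t,
                "travel_cost": r.c_d,
                "time_travel": r.c_m + r.c_t + r.c_d,
                "fees": r.fees_paid,
                "drug_patient": r.drug_patient,
                "inr_monitoring": r.inr_cost,
                "primary_visit": r.e_p,
                "specialised_visit": r.e_s,
                "primary_ward": r.w_p,
                "specialised_ward": r.w_s,
                "drug_society": r.d_h,
                "society_travel": r.k,
                "fee_overflow": r.fee_overflow,
                "total_healthcare": r.healthcare_total,
                "total_combined": r.c_p + r.healthcare_total,
            }
        )
    columns = [
        "patient_id", "date", "n_days", "c_m", "c_a", "c_t", "c_d",
        "total_patient", "time_cost", "travel_cost", "time_travel", "fees",
        "drug_patient", "inr_monitoring", "primary_visit", "specialised_visit",
        "primary_ward", "specialised_ward", "drug_society", "society_travel",
        "fee_overflow", "total_healthcare", "total_combined",
    ]
    return pd.DataFrame(rows, columns=columns)


def per_patient_annual(daily_costs: pd.DataFrame) -> pd.DataFrame:
    """Sum every cost component over days, per patient (exactly additive).

    Raises on duplicate dated (patient, date) rows.
    """
    dated = daily_costs[daily_costs["date"].notna()]
    if dated.duplicated(subset=["patient_id", "date"]).any():
        raise ValueError("duplicate (patient, date) daily cost rows")
    numeric = [c for c in daily_costs.columns if c not in ("patient_id", "date")]
    return daily_costs.groupby("patient_id", sort=True)[numeric].sum()


def group_average(annual: pd.DataFrame, patient_ids: Sequence[str]) -> pd.Series:
    """Arithmetic mean of each component over the listed patients.

    Patients missing from ``annual`` (no records at all) count as zeros in
    the denominator.
    """
    if len(patient_ids) == 0:
        raise ValueError("cannot average an empty arm")
    sub = annual.reindex(patient_ids).fillna(0.0)
    return sub.mean()


def _group_stats(annual_arm: pd.DataFrame) -> pd.DataFrame:
    s = len(annual_arm)
    mean = annual_arm.mean()
    sd = annual_arm.std(ddof=1).fillna(0.0) if s > 1 else mean * 0.0
    half = 1.96 * sd / math.sqrt(s)
    return pd.DataFrame({"mean": mean, "sd": sd, "ci_low": mean - half, "ci_high": mean + half})


def cost_table(
    warfarin_annual: pd.DataFrame,
    doac_annual: pd.DataFrame,
    *,
    use_t: bool = False,
) -> pd.DataFrame:
    """Two-arm comparison: mean ± SD, 95% CI, difference and p-value per row.

    The p-value compares means with an unequal-variance (Welch) statistic;
    ``use_t`` switches from the normal reference to Welch–Satterthwaite t.
    """
    for frame in (warfarin_annual, doac_annual):
        if len(frame) == 0:
            raise ValueError("cannot tabulate an empty arm")
    rows = [c for c in COST_COMPONENTS if c in warfarin_annual.columns]
    w = _group_stats(warfarin_annual[rows])
    d = _group_stats(doac_annual[rows])
    n_w, n_d = len(warfarin_annual), len(doac_annual)
    diff = w["mean"] - d["mean"]
    se = np.sqrt(w["sd"] ** 2 / n_w + d["sd"] ** 2 / n_d)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / se
    z = z.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    if use_t:
        var_w, var_d = w["sd"] ** 2 / n_w, d["sd"] ** 2 / n_d
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (var_w + var_d) ** 2 / (
                var_w**2 / max(n_w - 1, 1) + var_d**2 / max(n_d - 1, 1)
            )
        df = df.replace([np.inf, -np.inf], np.nan).fillna(1.0)
        p = 2.0 * stats.t.sf(np.abs(z), df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "warfarin_mean": w["mean"],
            "warfarin_sd": w["sd"],
            "warfarin_ci_low": w["ci_low"],
            "warfarin_ci_high": w["ci_high"],
            "doac_mean": d["mean"],
            "doac_sd": d["sd"],
            "doac_ci_low": d["ci_low"],
            "doac_ci_high": d["ci_high"],
            "difference": diff,
            "p_value": pd.Series(p, index=diff.index),
        },
        index=pd.Index(rows, name="component"),
    )
    return table


def component_share(component_mean: float, total_mean: float) -> float:
    """Component's percentage share of a total mean, one decimal place."""
    if total_mean == 0:
        raise ValueError("total mean must be non-zero")
    return round(100.0 * component_mean / total_mean, 1)


def utilisation_table(
    patients: Sequence[Patient],
    contacts: Sequence[Contact],
    journeys: Sequence[Journey],
    *,
    routing_index: RoutingIndex | None = None,
) -> pd.DataFrame:
    """Per-arm utilisation and access summary (mean ± SD columns).

    Covers AF-related visit counts, post-limiter travel counts
    (round-trip equivalents), INR counts, ward days, the urban share and —
    when a routing index is supplied — road distances to the nearest
    laboratory, health centre and the hospital.
    """
    by_patient_contacts: dict[str, list[Contact]] = {}
    for c in contacts:
        by_patient_contacts.setdefault(c.patient_id, []).append(c)
    legs_by_patient: dict[str, float] = {}
    for j in journeys:
        legs_by_patient[j.patient_id] = legs_by_patient.get(j.patient_id, 0.0) + j.n_legs

    rows = []
    for p in patients:
        pcs = by_patient_contacts.get(p.id, [])
        row = {
            "arm": p.arm,
            "visits": sum(1 for c in pcs if c.kind != "phone"),
            "travel_count": legs_by_patient.get(p.id, 0.0) / 2.0,
            "inr_count": sum(1 for c in pcs if c.kind == "inr"),
            "ward_days": sum(1 for c in pcs if c.kind in WARD_KINDS),
            "urban": float(p.urban),
        }
        if routing_index is not None:
            row["lab_distance_km"] = routing_index.nearest_lab(p.home_node)[1]
            hc = None
            try:
                hc = routing_index.nearest_facility(p.home_node, "health_centre")
            except Exception:
                pass
            row["health_centre_distance_km"] = (
                routing_index.length_distance(hc.node, p.home_node) if hc else float("nan")
            )
            hosp = routing_index.geo.hospital
            row["hospital_distance_km"] = routing_index.length_distance(hosp.node, p.home_node)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    grouped = frame.groupby("arm")
    out = grouped.mean().add_suffix("_mean").join(grouped.std(ddof=1).add_suffix("_sd"))
    out["n"] = grouped.size()
    return out


def render_report(table: pd.DataFrame, utilisation: pd.DataFrame | None = None) -> str:
    """Markdown report with 1-decimal money columns."""
    show = table.copy()
    for col in show.columns:
        if col != "p_value":
            show[col] = show[col].round(1)
    show["p_value"] = show["p_value"].map(lambda v: f"{v:.3g}")
    parts = ["# Annual cost comparison (€ per patient)", "", show.to_markdown()]
    if utilisation is not None and not utilisation.empty:
        parts += ["", "# Utilisation and access", "", utilisation.round(2).to_markdown()]
    parts.append("")
    return "\n".join(parts)
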