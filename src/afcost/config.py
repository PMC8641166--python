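"""Configuration objects for the synthetic generators and the cost engine.

Every config is a plain dataclass with a ``validate()`` method that raises
:class:`ConfigError` naming the offending field.  All monetary values are
euros, distances kilometres, times hours, rates per year.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Any, Mapping

import yaml

ARMS = ("warfarin", "doac")

#: 12-month observation window used throughout (365 days).
STUDY_WINDOW = (date(2017, 6, 1), date(2018, 5, 31))
STUDY_DAYS = (STUDY_WINDOW[1] - STUDY_WINDOW[0]).days + 1

CONTACT_KINDS = (
    "inr",
    "primary_visit",
    "specialised_visit",
    "primary_ward_day",
    "specialised_ward_day",
    "phone",
    "emergency_visit",
)
WARD_KINDS = ("primary_ward_day", "specialised_ward_day")

DIAGNOSIS_CLASSES = ("af", "ischemic_stroke", "intracerebral_haemorrhage", "gi_bleed", "other")


class ConfigError(ValueError):
    """Raised when a configuration field is invalid."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


def nb_dispersion(mean: float, sd: float) -> float:
    """Negative-binomial shape parameter r reproducing a given mean and SD.

    Var = mu + mu^2 / r  =>  r = mu^2 / (sd^2 - mu).  Requires sd^2 > mean
    (over-dispersion); the generators fall back to Poisson otherwise.
    """
    var = sd * sd
    if var <= mean:
        return math.inf
    return mean * mean / (var - mean)


@dataclass
class CohortConfig:
    """Parameters of the synthetic two-arm cohort generator.

    Defaults are calibrated to the published group characteristics
    (group sizes 3171/829, ages 76.0±9.2 / 72.7±9.8, INR monitoring
    counts 17.5±9.9 / 0.1±0.9, postal-area income ~€12/h, ~5% of
    contacts carrying a travel-reimbursement record).
    """

    n_warfarin: int = 3171
    n_doac: int = 829
    age_mean_by_arm: dict[str, float] = field(
        default_factory=lambda: {"warfarin": 76.0, "doac": 72.7}
    )
    age_sd_by_arm: dict[str, float] = field(
        default_factory=lambda: {"warfarin": 9.2, "doac": 9.8}
    )
    female_share_by_arm: dict[str, float] = field(
        default_factory=lambda: {"warfarin": 0.468, "doac": 0.472}
    )
    #: per arm: (yearly mean count, negative-binomial dispersion r)
    inr_visits_per_year: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "warfarin": (17.5, nb_dispersion(17.5, 9.9)),
            "doac": (0.1, nb_dispersion(0.1, 0.9)),
        }
    )
    #: per arm: contact kind -> (yearly mean count, dispersion r)
    visit_rates: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "warfarin": {
                "primary_visit": (0.2, nb_dispersion(0.2, 0.8)),
                "specialised_visit": (0.2, nb_dispersion(0.2, 0.7)),
                "primary_ward_day": (0.2, nb_dispersion(0.2, 2.7)),
                "specialised_ward_day": (0.1, nb_dispersion(0.1, 1.0)),
                "phone": (0.5, nb_dispersion(0.5, 1.0)),
            },
            "doac": {
                "primary_visit": (0.2, nb_dispersion(0.2, 0.8)),
                "specialised_visit": (0.3, nb_dispersion(0.3, 0.9)),
                "primary_ward_day": (0.2, nb_dispersion(0.2, 2.4)),
                "specialised_ward_day": (0.15, nb_dispersion(0.15, 1.2)),
                "phone": (0.5, nb_dispersion(0.5, 1.0)),
            },
        }
    )
    #: per arm: complication diagnosis class -> yearly probability of one episode
    complication_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "warfarin": {
                "intracerebral_haemorrhage": 0.003,
                "gi_bleed": 0.024,
                "ischemic_stroke": 0.005,
            },
            "doac": {
                "intracerebral_haemorrhage": 0.0,
                "gi_bleed": 0.008,
                "ischemic_stroke": 0.005,
            },
        }
    )
    income_mean: float = 12.0  # €/h, postal-area hourly income
    income_sd: float = 1.0
    urban_share: float = 0.72
    kela_coverage: float = 0.05  # share of travel-generating contacts with a record
    #: targeted road-network distance (km) from home to the nearest laboratory
    lab_distance_mean: float = 5.5
    lab_distance_sd: float = 7.6
    #: healthcare-side accounting unit cost (€) per contact kind
    unit_costs: dict[str, float] = field(
        default_factory=lambda: {
            "inr": 0.0,  # costed separately via the per-visit monitoring price
            "primary_visit": 65.0,
            "specialised_visit": 300.0,
            "primary_ward_day": 150.0,
            "specialised_ward_day": 700.0,
            "emergency_visit": 250.0,
            "phone": 30.0,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_warfarin >= 0, "n_warfarin", "must be >= 0")
        _require(self.n_doac >= 0, "n_doac", "must be >= 0")
        for arm in ARMS:
            _require(arm in self.age_mean_by_arm, "age_mean_by_arm", f"missing arm {arm!r}")
            _require(self.age_sd_by_arm.get(arm, -1) > 0, "age_sd_by_arm", "must be > 0")
            share = self.female_share_by_arm.get(arm)
            _require(share is not None and 0 <= share <= 1, "female_share_by_arm", "must be in [0, 1]")
            mean, disp = self.inr_visits_per_year[arm]
            _require(mean >= 0 and disp > 0, "inr_visits_per_year", "mean >= 0 and dispersion > 0")
            for kind, (m, r) in self.visit_rates[arm].items():
                _require(kind in CONTACT_KINDS, "visit_rates", f"unknown contact kind {kind!r}")
                _require(m >= 0 and r > 0, "visit_rates", f"{kind}: mean >= 0 and dispersion > 0")
            for cls, p in self.complication_probs[arm].items():
                _require(cls in DIAGNOSIS_CLASSES, "complication_probs", f"unknown class {cls!r}")
                _require(0 <= p <= 1, "complication_probs", "must be in [0, 1]")
        _require(self.income_mean > 0, "income_mean", "must be > 0")
        _require(self.income_sd >= 0, "income_sd", "must be >= 0")
        _require(0 <= self.urban_share <= 1, "urban_share", "must be in [0, 1]")
        _require(0 <= self.kela_coverage <= 1, "kela_coverage", "must be in [0, 1]")
        _require(self.lab_distance_mean > 0, "lab_distance_mean", "must be > 0")
        _require(self.lab_distance_sd > 0, "lab_distance_sd", "must be > 0")


@dataclass
class GeographyConfig:
    """Parameters of the synthetic road network and facility placement."""

    n_nodes: int = 800
    n_labs: int = 27
    n_health_centres: int = 23
    bus_stop_density: float = 0.35  # probability a node hosts a bus stop
    speed_limit_range: tuple[float, float] = (40.0, 100.0)
    extent: float = 140.0  # side of the square study area, km
    #: mean number of nearest neighbours each node connects to
    knn: int = 4
    #: detour factor converting straight-line to road distance
    road_curvature: float = 1.3
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_nodes >= 2, "n_nodes", "must be >= 2")
        _require(self.n_labs >= 1, "n_labs", "must be >= 1")
        _require(self.n_health_centres >= 0, "n_health_centres", "must be >= 0")
        needed = 1 + max(self.n_labs, self.n_health_centres)
        _require(
            self.n_nodes >= needed,
            "n_nodes",
            f"too small to place 1 hospital, {self.n_labs} labs and "
            f"{self.n_health_centres} health centres (need >= {needed})",
        )
        _require(0 <= self.bus_stop_density <= 1, "bus_stop_density", "must be in [0, 1]")
        lo, hi = self.speed_limit_range
        _require(0 < lo <= hi, "speed_limit_range", "must satisfy 0 < low <= high")
        _require(self.extent > 0, "extent", "must be > 0")
        _require(self.knn >= 1, "knn", "must be >= 1")
        _require(self.road_curvature >= 1.0, "road_curvature", "must be >= 1")


def _from_mapping(cls, data: Mapping[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown fields for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(data)
    # YAML gives lists where tuples are expected
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    if "inr_visits_per_year" in kwargs:
        kwargs["inr_visits_per_year"] = {
            k: tuple(v) for k, v in kwargs["inr_visits_per_year"].items()
        }
    if "visit_rates" in kwargs:
        kwargs["visit_rates"] = {
            arm: {k: tuple(v) for k, v in rates.items()}
            for arm, rates in kwargs["visit_rates"].items()
        }
    obj = cls(**kwargs)
    obj.validate()
    return obj


def load_cohort_config(path: str) -> CohortConfig:
    with open(path) as fh:
        return _from_mapping(CohortConfig, yaml.safe_load(fh) or {})


def load_geography_config(path: str) -> GeographyConfig:
    with open(path) as fh:
        return _from_mapping(GeographyConfig, yaml.safe_load(fh) or {})
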