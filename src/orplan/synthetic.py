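"""Synthetic waiting lists and arrival streams.

Emulates the statistical structure of one year of elective pediatric
surgical activity in a three-OR operating area shared by nine specialties:
3112 cases with published marginal distributions over specialty, urgency
class and expected operating time, and a standing waiting list of about
630 patients. Specialty, URG class and EOT are drawn independently by
weight (only marginals are published); EOT is uniform within its histogram
bin, with the open-ended top bin capped at the 12-hour block bound.

Anesthesia-type shares, risk prevalences and logistics probabilities have
no published counterpart; the shipped defaults are explicit synthetic
conventions (see the package defaults file).
"""
from __future__ import annotations

from datetime import date, timedelta
from functools import lru_cache
from importlib import resources
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pathway import AnesthesiaCode, CaseProfile, Destination
from .waiting_list import Patient, URGCode, URGTable, WaitingList, default_urg_table


class EOTBin(BaseModel):
    model_config = ConfigDict(frozen=True)

    lower: float = Field(ge=0)
    upper: float
    weight: float = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "EOTBin":
        if self.upper <= self.lower:
            raise ValueError("bin upper bound must exceed lower bound")
        return self


class CaseMixSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    specialty_weights: dict[str, float]
    urg_weights: dict[URGCode, float]
    eot_bins: tuple[EOTBin, ...]
    anesthesia_weights: dict[AnesthesiaCode, float]
    risk_prevalence: dict[str, float]
    p_same_building: float = Field(ge=0, le=1)
    p_prep_room_given_cd: float = Field(ge=0, le=1)
    destination_probs: dict[Destination, float]
    arrival_rate_per_week: float = Field(gt=0)

    @model_validator(mode="after")
    def _check(self) -> "CaseMixSpec":
        for name, weights in (
            ("specialty_weights", self.specialty_weights),
            ("urg_weights", self.urg_weights),
            ("anesthesia_weights", self.anesthesia_weights),
            ("destination_probs", self.destination_probs),
        ):
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name}: negative weight")
            if not any(w > 0 for w in weights.values()):
                raise ValueError(f"{name}: needs at least one positive weight")
        if any(not (0 <= p <= 1) for p in self.risk_prevalence.values()):
            raise ValueError("risk prevalences must be probabilities")
        bins = self.eot_bins
        if not bins:
            raise ValueError("eot_bins must be non-empty")
        for a, b in zip(bins, bins[1:]):
            if b.lower != a.upper:
                raise ValueError("eot_bins must be contiguous and increasing")
        return self

    @classmethod
    def from_yaml(cls, path) -> "CaseMixSpec":
        with open(path) as fh:
            return cls._from_raw(yaml.safe_load(fh))

    @classmethod
    def _from_raw(cls, raw: dict) -> "CaseMixSpec":
        return cls(
            specialty_weights=raw["specialty_weights"],
            urg_weights={URGCode(k): v for k, v in raw["urg_weights"].items()},
            eot_bins=tuple(EOTBin(**b) for b in raw["eot_bins"]),
            anesthesia_weights={
                AnesthesiaCode(k): v for k, v in raw["anesthesia_weights"].items()
            },
            risk_prevalence=raw["risk_prevalence"],
            p_same_building=raw["p_same_building"],
            p_prep_room_given_cd=raw["p_prep_room_given_cd"],
            destination_probs={
                Destination(k): v for k, v in raw["destination_probs"].items()
            },
            arrival_rate_per_week=raw["arrival_rate_per_week"],
        )


@lru_cache(maxsize=1)
def default_casemix() -> CaseMixSpec:
    raw = yaml.safe_load(
        resources.files("orplan.data").joinpath("casemix_default.yaml").read_text()
    )
    return CaseMixSpec._from_raw(raw)


def _weighted_choice(rng: np.random.Generator, weights: dict, size: int) -> list:
    keys = list(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs /= probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def generate_patients(
    n: int,
    spec: CaseMixSpec | None = None,
    seed: int | np.random.Generator = 0,
    *,
    registration_date: date = date(2012, 6, 18),
    id_prefix: str = "P",
    id_start: int = 0,
) -> list[Patient]:
    """Draw ``n`` patients with independent specialty / URG / EOT marginals.

    Registration dates are uniform at ``registration_date``; list and
    arrival generators re-date them. Reproducible for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    spec = spec or default_casemix()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return []
    specialties = _weighted_choice(rng, spec.specialty_weights, n)
    urgs = _weighted_choice(rng, spec.urg_weights, n)
    bin_idx = rng.choice(
        len(spec.eot_bins),
        size=n,
        p=np.array([b.weight for b in spec.eot_bins])
        / sum(b.weight for b in spec.eot_bins),
    )
    anesthesia = _weighted_choice(rng, spec.anesthesia_weights, n)
    destinations = _weighted_choice(rng, spec.destination_probs, n)
    risk_names = sorted(spec.risk_prevalence)
    risk_draws = rng.random((n, len(risk_names)))
    same_building = rng.random(n) < spec.p_same_building
    prep_room = rng.random(n) < spec.p_prep_room_given_cd

    patients = []
    for k in range(n):
        b = spec.eot_bins[bin_idx[k]]
        eot = float(rng.uniform(b.lower, b.upper))
        if eot <= 0:  # EOT must be strictly positive
            eot = min(1.0, b.upper)
        code = anesthesia[k]
        risks = frozenset(
            name
            for m, name in enumerate(risk_names)
            if risk_draws[k, m] < spec.risk_prevalence[name]
        )
        case = CaseProfile(
            eot_min=eot,
            anesthesia=code,
            risks=risks,
            same_building=bool(same_building[k]),
            use_prep_room=bool(prep_room[k])
            and code in (AnesthesiaCode.C, AnesthesiaCode.D),
            destination=destinations[k],
        )
        patients.append(
            Patient(
                id=f"{id_prefix}{id_start + k:06d}",
                specialty=specialties[k],
                urg=urgs[k],
                registration_date=registration_date,
                case=case,
            )
        )
    return patients


def generate_waiting_list(
    size: int,
    reference_date: date = date(2012, 6, 18),
    spec: CaseMixSpec | None = None,
    seed: int = 0,
    *,
    urg_table: URGTable | None = None,
) -> WaitingList:
    """A standing waiting list of ``size`` patients at ``reference_date``.

    Each patient's elapsed wait is uniform over [0, max_wait_days] of their
    URG class, so no generated patient starts beyond their class's maximum
    acceptable wait.
    """
    rng = np.random.default_rng(seed)
    urg_table = urg_table or default_urg_table()
    patients = generate_patients(
        size, spec, rng, registration_date=reference_date, id_prefix="W"
    )
    redated = []
    for p in patients:
        elapsed = int(rng.integers(0, urg_table.max_wait(p.urg) + 1))
        redated.append(
            p.model_copy(update={"registration_date": reference_date - timedelta(days=elapsed)})
        )
    return WaitingList(patients=redated, reference_date=reference_date)


def arrivals(
    rate_per_week: Optional[float] = None,
    n_weeks: int = 4,
    spec: CaseMixSpec | None = None,
    seed: int = 0,
    *,
    start_date: date = date(2012, 6, 18),
) -> list[Patient]:
    """Poisson stream of newly registered patients over ``n_weeks`` weeks.

    Weekly counts are Poisson at ``rate_per_week`` (default: the annual
    case load divided by 52); registration dates are uniform within each
    week, starting at ``start_date``.
    """
    spec = spec or default_casemix()
    if rate_per_week is None:
        rate_per_week = spec.arrival_rate_per_week
    if rate_per_week < 0:
        raise ValueError("rate_per_week must be >= 0")
    rng = np.random.default_rng(seed)
    stream: list[Patient] = []
    serial = 0
    for week in range(n_weeks):
        count = int(rng.poisson(rate_per_week))
        week_patients = generate_patients(
            count, spec, rng, registration_date=start_date, id_prefix="N", id_start=serial
        )
        serial += count
        for p in week_patients:
            offset = int(rng.integers(0, 7))
            stream.append(
                p.model_copy(
                    update={
                        "registration_date": start_date + timedelta(weeks=week, days=offset)
                    }
                )
            )
    stream.sort(key=lambda p: (p.registration_date, p.id))
    return stream
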