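"""Seeded synthetic screening-registry, treatment-record and cost generators.

No patient-level data are distributed with this package, so every pipeline
stage is exercised against synthetic data whose aggregate structure matches
the screening programme the package models: a population of 15,396 diabetes
patients followed 2007-2014, about 35% screened per year, annual incidence
among the screened of roughly 8.4% for any DR, 2.6% for sight-threatening DR
and 2.2% for macular oedema, laser treatment of CSMO up to 2010 and
anti-VEGF thereafter (5.7 / 4.7 / 2.9 injections in treatment years 1-3).

The generator draws independent patient-year events at the configured
incidences (it does not model within-patient progression — that realism
lives in :mod:`drscreen.markov`), and all randomness derives from a single
integer seed, so identical configurations yield identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .registry import CostLineItem, CostSchedule, ScreeningRecord

__all__ = [
    "GeneratorConfig",
    "TreatmentRecord",
    "generate_registry",
    "generate_treatment_records",
    "generate_cost_schedule",
    "generate_cost_ledger",
    "DEFAULT_UNIT_COSTS",
]


#: Default unit-cost schedule (EUR).  Screening, per-patient diagnosis and
#: yearly treatment / follow-up costs by disease category, as reported by the
#: programme this package models; DMO treatment costs are per patient-year
#: (laser era vs anti-VEGF era).
DEFAULT_UNIT_COSTS: Mapping[str, float] = {
    "screening_episode": 40.43,
    "any_dr_diagnosis": 100.51,
    "any_dr_treatment": 184.67,
    "any_dr_follow_up": 288.15,
    "stdr_diagnosis": 167.91,
    "stdr_treatment": 2191.0,
    "stdr_follow_up": 441.37,
    "dmo_diagnosis": 132.24,
    "dmo_laser_treatment": 777.09,
    "dmo_laser_follow_up": 509.42,
    "dmo_anti_vegf_treatment": 7153.62,
    "dmo_anti_vegf_follow_up": 473.56,
}

#: First calendar year in which CSMO is treated with anti-VEGF rather than laser.
ANTI_VEGF_ERA_START = 2011


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic registry.

    Incidences are annual probabilities among screened patients;
    ``incidence_stdr`` and ``incidence_dmo`` are marginal (sight-threatening
    DR includes CSMO by definition, so the generator carves CSMO out of the
    STDR mass).  VA gains are in ETDRS letters, drawn from normal laws
    truncated to each arm's observed range with the location moment-matched
    so the configured mean is recovered in expectation.
    """

    n_patients: int = 15_396
    years: tuple[int, ...] = tuple(range(2007, 2015))
    screen_fraction: float = 0.35
    incidence_any_dr: float = 0.0837
    incidence_stdr: float = 0.0264
    incidence_dmo: float = 0.0219
    csmo_share: float = 0.62  # fraction of DMO that is clinically significant
    injections_by_year: tuple[float, float, float] = (5.7, 4.7, 2.9)
    va_gain_laser: tuple[float, float] = (0.68, 1.78)  # (mean, sd)
    va_range_laser: tuple[float, float] = (-11.0, 6.0)
    va_gain_anti_vegf: tuple[float, float] = (6.84, 3.22)
    va_range_anti_vegf: tuple[float, float] = (0.0, 10.0)
    age_mean: float = 65.66
    age_sd: float = 12.23
    age_mean_dmo: float = 60.67
    age_sd_dmo: float = 10.37
    n_laser_patients: int = 430
    n_anti_vegf_patients: int = 548
    cost_per_injection: float = 1255.02
    laser_cost_per_patient: float = 777.09
    seed: int = 0

    def validate(self) -> None:
        fractions = {
            "screen_fraction": self.screen_fraction,
            "incidence_any_dr": self.incidence_any_dr,
            "incidence_stdr": self.incidence_stdr,
            "incidence_dmo": self.incidence_dmo,
            "csmo_share": self.csmo_share,
        }
        for name, v in fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.incidence_stdr > self.incidence_any_dr:
            raise ValueError("incidence_stdr cannot exceed incidence_any_dr")
        if self.incidence_dmo > self.incidence_any_dr:
            raise ValueError("incidence_dmo cannot exceed incidence_any_dr")
        if self.incidence_any_dr > 0:
            if self.incidence_dmo * self.csmo_share > self.incidence_stdr:
                raise ValueError("CSMO incidence cannot exceed STDR incidence")
        for name in ("va_gain_laser", "va_gain_anti_vegf"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be >= 0")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")


@dataclass(frozen=True)
class TreatmentRecord:
    """One patient-year of DMO treatment."""

    patient_id: str
    year_index: int  # 1..3
    modality: str  # laser | anti_vegf | vitrectomy
    injections: int
    va_gain: float  # ETDRS letters (recorded in year 1)
    cost: float

    def __post_init__(self) -> None:
        if self.modality not in ("laser", "anti_vegf", "vitrectomy"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality != "anti_vegf" and self.injections != 0:
            raise ValueError("injections must be 0 unless modality is anti_vegf")
        if self.cost < 0:
            raise ValueError(f"cost must be >= 0, got {self.cost}")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # One root seed; deterministic sub-streams so the registry and the
    # treatment records can be generated independently yet reproducibly.
    return np.random.default_rng([int(config.seed), stream])


def _truncated_normal(
    mean: float,
    sd: float,
    low: float,
    high: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Truncated-normal draws whose *truncated* mean equals ``mean``.

    The location parameter is solved numerically so that after truncation to
    [low, high] the expectation matches the requested mean; a plain
    truncation would bias the mean toward the interval centre.
    """
    if sd == 0:
        return np.full(size, float(np.clip(mean, low, high)))
    if not low < mean < high:
        raise ValueError(f"target mean {mean} must lie inside ({low}, {high})")

    def truncated_mean(loc: float) -> float:
        a, b = (low - loc) / sd, (high - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    span = 10.0 * sd
    loc = optimize.brentq(lambda m: truncated_mean(m) - mean, low - span, high + span)
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_registry(config: GeneratorConfig = GeneratorConfig()) -> list[ScreeningRecord]:
    """Generate one patient-year record per patient per calendar year.

    Screening attendance is Bernoulli(``screen_fraction``) per patient-year.
    Among screened patient-years the generator draws disease status with the
    configured marginal incidences: any-DR, of which sight-threatening
    (severe/proliferative grade or CSMO) at ``incidence_stdr`` and macular
    oedema at ``incidence_dmo``.  Unscreened patient-years carry no findings
    (the programme observes disease only at screening).
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_patients
    base_year = config.years[0]
    # Stable per-patient baseline ages; ages advance one year per calendar year.
    base_age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 20.0, 95.0)

    inc_any, inc_st, inc_dmo = (
        config.incidence_any_dr,
        config.incidence_stdr,
        config.incidence_dmo,
    )
    # Decompose the marginals: CSMO is a subset of STDR, extrafoveal DMO of
    # non-sight-threatening DR.
    p_st_given_dr = inc_st / inc_any if inc_any else 0.0
    p_csmo_given_st = (inc_dmo * config.csmo_share) / inc_st if inc_st else 0.0
    p_nonst = inc_any - inc_st
    p_extra_given_nonst = (inc_dmo * (1 - config.csmo_share)) / p_nonst if p_nonst else 0.0

    records: list[ScreeningRecord] = []
    for year in config.years:
        offset = year - base_year
        screened = rng.random(n) < config.screen_fraction
        u_dr = rng.random(n)
        u_st = rng.random(n)
        u_dmo = rng.random(n)
        u_grade = rng.random(n)
        ages = base_age + offset
        dmo_age = np.clip(
            rng.normal(config.age_mean_dmo, config.age_sd_dmo, size=n), 20.0, 95.0
        ) + offset
        for i in range(n):
            grade, dmo = "none", "none"
            if screened[i] and u_dr[i] < inc_any:
                if u_st[i] < p_st_given_dr:  # sight-threatening
                    if u_dmo[i] < p_csmo_given_st:
                        dmo = "csmo"
                        grade = "moderate" if u_grade[i] < 0.45 else "mild"
                    else:
                        grade = "proliferative" if u_grade[i] < 0.04 else "severe"
                else:
                    if u_dmo[i] < p_extra_given_nonst:
                        dmo = "extrafoveal"
                    grade = "moderate" if u_grade[i] < 0.09 else "mild"
            age = dmo_age[i] if dmo != "none" else ages[i]
            records.append(
                ScreeningRecord(
                    patient_id=f"P{i:05d}",
                    year=int(year),
                    age=round(float(age), 2),
                    screened=bool(screened[i]),
                    dr_grade=grade,
                    dmo_status=dmo,
                )
            )
    return records


def generate_treatment_records(
    config: GeneratorConfig = GeneratorConfig(),
) -> list[TreatmentRecord]:
    """Generate per-patient DMO treatment records for the two treatment arms.

    Laser patients receive a single treatment year; anti-VEGF patients are
    followed three years with Poisson injection counts at the configured
    yearly means and cost = injections x cost per injection.  VA gains (ETDRS
    letters) are drawn once per patient from the arm's truncated normal law
    and recorded in year 1.
    """
    config.validate()
    rng = _rng(config, 1)
    records: list[TreatmentRecord] = []

    laser_gains = _truncated_normal(
        *config.va_gain_laser, *config.va_range_laser, config.n_laser_patients, rng
    )
    for i in range(config.n_laser_patients):
        records.append(
            TreatmentRecord(
                patient_id=f"L{i:04d}",
                year_index=1,
                modality="laser",
                injections=0,
                va_gain=round(float(laser_gains[i]), 3),
                cost=config.laser_cost_per_patient,
            )
        )

    av_gains = _truncated_normal(
        *config.va_gain_anti_vegf,
        *config.va_range_anti_vegf,
        config.n_anti_vegf_patients,
        rng,
    )
    for i in range(config.n_anti_vegf_patients):
        for y, mean_inj in enumerate(config.injections_by_year, start=1):
            inj = int(rng.poisson(mean_inj))
            records.append(
                TreatmentRecord(
                    patient_id=f"A{i:04d}",
                    year_index=y,
                    modality="anti_vegf",
                    injections=inj,
                    va_gain=round(float(av_gains[i]), 3) if y == 1 else 0.0,
                    cost=round(inj * config.cost_per_injection, 2),
                )
            )
    return records


def generate_cost_schedule(overrides: Mapping[str, float] | None = None) -> CostSchedule:
    """The default unit-cost schedule, with optional overrides.

    Unknown override keys raise ``KeyError``.
    """
    schedule = CostSchedule(DEFAULT_UNIT_COSTS)
    if overrides:
        schedule = schedule.replace(**overrides)
    return schedule


def generate_cost_ledger(
    records: Sequence[ScreeningRecord],
    schedule: CostSchedule | None = None,
) -> list[CostLineItem]:
    """Derive a cost ledger from registry events: deterministic attribution.

    Every screened patient-year incurs one screening line; every new DR
    finding a diagnosis line; CSMO cases a treatment line (laser before
    2011, anti-VEGF from 2011) plus a follow-up line, all at the schedule's
    unit costs.
    """
    if schedule is None:
        schedule = generate_cost_schedule()
    items: list[CostLineItem] = []
    for rec in records:
        if not rec.screened:
            continue
        items.append(CostLineItem(rec.year, "screening", schedule["screening_episode"]))
        if rec.dr_grade == "none" and rec.dmo_status == "none":
            continue
        if rec.dmo_status == "csmo":
            items.append(CostLineItem(rec.year, "diagnosis", schedule["dmo_diagnosis"]))
            if rec.year < ANTI_VEGF_ERA_START:
                items.append(CostLineItem(rec.year, "laser", schedule["dmo_laser_treatment"]))
                items.append(CostLineItem(rec.year, "follow_up", schedule["dmo_laser_follow_up"]))
            else:
                items.append(
                    CostLineItem(rec.year, "anti_vegf", schedule["dmo_anti_vegf_treatment"])
                )
                items.append(
                    CostLineItem(rec.year, "follow_up", schedule["dmo_anti_vegf_follow_up"])
                )
        elif rec.stdr:
            items.append(CostLineItem(rec.year, "diagnosis", schedule["stdr_diagnosis"]))
            items.append(CostLineItem(rec.year, "follow_up", schedule["stdr_follow_up"]))
        else:
            items.append(CostLineItem(rec.year, "diagnosis", schedule["any_dr_diagnosis"]))
            items.append(CostLineItem(rec.year, "follow_up", schedule["any_dr_follow_up"]))
    return items


def treatment_frame(records: Sequence[TreatmentRecord]) -> pd.DataFrame:
    """Treatment records as a tidy DataFrame."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def write_treatment_records(records: Sequence[TreatmentRecord], path) -> None:
    treatment_frame(records).to_csv(path, index=False)


def load_treatment_records(path) -> list[TreatmentRecord]:
    """Load treatment records written by :func:`write_treatment_records`."""
    df = pd.read_csv(path)
    required = {"patient_id", "year_index", "modality", "injections", "va_gain", "cost"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"treatment file {path} is missing columns {sorted(missing)}")
    return [
        TreatmentRecord(
            patient_id=str(r.patient_id),
            year_index=int(r.year_index),
            modality=str(r.modality),
            injections=int(r.injections),
            va_gain=float(r.va_gain),
            cost=float(r.cost),
        )
        for r in df.itertuples(index=False)
    ]
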