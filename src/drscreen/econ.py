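"""Health-economic primitives: discounting, ICER, cost-utility, treatment comparison.

All monetary quantities are in euros, effects in quality-adjusted life-years
(QALYs) unless stated otherwise.  Incremental comparisons follow the usual
cost-effectiveness-plane conventions: the "hi" arm is the candidate strategy
(e.g. annual screening, anti-VEGF), the "lo" arm the comparator (2.5-yearly
screening, laser).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .util import round_half_up

__all__ = [
    "DiscountSpec",
    "HorizonSpec",
    "UtilitySchedule",
    "CEAResult",
    "TreatmentComparison",
    "discount_factor",
    "discounted_sum",
    "icer",
    "remaining_horizon",
    "rescale_qaly_gain",
    "compare_treatments",
    "DEFAULT_WTP_THRESHOLD",
]

#: Willingness-to-pay threshold (EUR per QALY) used as the default decision
#: bound; the conventional NICE figure of GBP 30,000 expressed in euros.
DEFAULT_WTP_THRESHOLD = 38_460.0


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate applied to both future costs and utilities."""

    rate: float = 0.03

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"discount rate must be >= 0, got {self.rate}")


@dataclass(frozen=True)
class HorizonSpec:
    """Remaining-lifetime horizon from a baseline age.

    The default life expectancy of 78 years is the figure for Spanish
    diabetes patients used throughout the analyses in this package.
    """

    age_at_baseline: float
    life_expectancy: float = 78.0

    def __post_init__(self) -> None:
        if not 0 <= self.age_at_baseline <= self.life_expectancy:
            raise ValueError(
                "age_at_baseline must lie in [0, life_expectancy]; got "
                f"age {self.age_at_baseline}, life expectancy {self.life_expectancy}"
            )


#: Illustrative time-trade-off utilities by visual-acuity band.  These are
#: placeholder defaults for demonstrations and tests only — they are not
#: estimates from any study; substantive analyses must supply their own
#: literature-derived utility values.
DEFAULT_UTILITIES: Mapping[str, float] = {
    "va_20_20": 0.92,
    "va_20_40": 0.85,
    "va_20_80": 0.75,
    "va_20_200": 0.62,
    "blind": 0.50,
}


@dataclass(frozen=True)
class UtilitySchedule:
    """Per-year utility weight (0..1) for each health state."""

    values: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_UTILITIES))

    def __post_init__(self) -> None:
        for state, u in self.values.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility for {state!r} must be in [0, 1], got {u}")

    def __getitem__(self, state: str) -> float:
        return self.values[state]


def discount_factor(t: float, spec: DiscountSpec = DiscountSpec()) -> float:
    """Present-value factor ``(1 + rate)^(-t)`` for an amount accruing at year *t*."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return (1.0 + spec.rate) ** (-t)


def discounted_sum(
    stream: Sequence[tuple[float, float]], spec: DiscountSpec = DiscountSpec()
) -> float:
    """Present value of a stream of ``(time_in_years, amount)`` payments."""
    return float(sum(a * discount_factor(t, spec) for t, a in stream))


@dataclass(frozen=True)
class CEAResult:
    """Paired-arm cost-effectiveness comparison.

    ``icer`` is ``None`` when the increment in effect is zero or when one arm
    dominates (cheaper and more effective), in which case a ratio is
    meaningless.  ``quadrant`` locates a defined ICER on the
    cost-effectiveness plane: ``northeast`` (more costly, more effective, the
    usual trade-off) or ``southwest`` (cheaper and less effective — the ratio
    is reported but must be read as a saving per QALY forgone).
    """

    cost_hi: float
    cost_lo: float
    qaly_hi: float
    qaly_lo: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str  # none | hi_dominates | lo_dominates
    quadrant: str | None  # northeast | southwest | None

    def cost_effective(self, wtp: float = DEFAULT_WTP_THRESHOLD) -> bool | None:
        """Whether the hi arm is acceptable at a willingness-to-pay threshold."""
        if self.dominance == "hi_dominates":
            return True
        if self.dominance == "lo_dominates":
            return False
        if self.icer is None or self.quadrant == "southwest":
            return None
        return self.icer <= wtp

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary_line(self) -> str:
        """One-line human-readable summary with dominance/quadrant annotation."""
        if self.dominance == "hi_dominates":
            return (
                f"hi arm dominates (cheaper by EUR {-self.delta_cost:,.2f}, "
                f"gains {self.delta_qaly:.4f} QALY)"
            )
        if self.dominance == "lo_dominates":
            return (
                f"lo arm dominates (hi arm costs EUR {self.delta_cost:,.2f} more, "
                f"loses {-self.delta_qaly:.4f} QALY)"
            )
        if self.icer is None:
            return "ICER undefined (zero QALY increment)"
        note = " [southwest quadrant: saving per QALY forgone]" if self.quadrant == "southwest" else ""
        return f"ICER EUR {self.icer:,.2f} per QALY ({self.delta_cost:+,.2f} EUR / {self.delta_qaly:+.4f} QALY){note}"


def icer(cost_hi: float, qaly_hi: float, cost_lo: float, qaly_lo: float) -> CEAResult:
    """Incremental cost-effectiveness ratio of the hi arm against the lo arm.

    Returns a :class:`CEAResult`; the ratio is ``delta_cost / delta_qaly``
    when both increments share a sign, and dominance is flagged when the hi
    arm is strictly cheaper and more effective (or the reverse).
    """
    for name, v in (("cost_hi", cost_hi), ("qaly_hi", qaly_hi),
                    ("cost_lo", cost_lo), ("qaly_lo", qaly_lo)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    dc = cost_hi - cost_lo
    dq = qaly_hi - qaly_lo
    dominance = "none"
    ratio: float | None = None
    quadrant: str | None = None
    if dc < 0 and dq > 0:
        dominance = "hi_dominates"
    elif dc > 0 and dq < 0:
        dominance = "lo_dominates"
    elif dq != 0:
        ratio = dc / dq
        quadrant = "northeast" if dq > 0 else "southwest"
    return CEAResult(
        cost_hi=cost_hi,
        cost_lo=cost_lo,
        qaly_hi=qaly_hi,
        qaly_lo=qaly_lo,
        delta_cost=dc,
        delta_qaly=dq,
        icer=ratio,
        dominance=dominance,
        quadrant=quadrant,
    )


def remaining_horizon(spec: HorizonSpec) -> float:
    """Years of remaining life expectancy from the baseline age."""
    return spec.life_expectancy - spec.age_at_baseline


def rescale_qaly_gain(gain: float, horizon_from: float, horizon_to: float) -> float:
    """Prorate a QALY gain linearly from one time horizon to another.

    A gain accrued uniformly over ``horizon_from`` years is rescaled to the
    fraction falling within ``horizon_to`` years; no discounting is applied
    inside the rescaling.  The result is rounded half-up to 2 decimals.
    """
    if horizon_from <= 0:
        raise ValueError(f"horizon_from must be > 0, got {horizon_from}")
    if horizon_to < 0:
        raise ValueError(f"horizon_to must be >= 0, got {horizon_to}")
    return round_half_up(gain * horizon_to / horizon_from, 2)


@dataclass(frozen=True)
class TreatmentComparison:
    """Two-arm comparison of visual-acuity gains (ETDRS letters) and cost.

    The t statistic and p value are from Welch's unequal-variance two-sample
    t-test, two-sided.  ``delta_cost_per_patient`` is arm A minus arm B.
    """

    mean_gain_a: float
    mean_gain_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    delta_cost_per_patient: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def compare_treatments(
    gains_a: Sequence[float],
    gains_b: Sequence[float],
    cost_a: float,
    cost_b: float,
) -> TreatmentComparison:
    """Compare per-patient visual-acuity gains of two treatment arms.

    Arm A vs arm B (e.g. anti-VEGF vs laser); Welch's t-test, two-sided.
    Each arm needs at least two observations.
    """
    a = np.asarray(gains_a, dtype=float)
    b = np.asarray(gains_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each arm needs >= 2 observations, got {a.size} and {b.size}"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TreatmentComparison(
        mean_gain_a=float(a.mean()),
        mean_gain_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
        t_statistic=float(t),
        p_value=float(p),
        delta_cost_per_patient=cost_a - cost_b,
    )
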