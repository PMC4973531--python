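"""Deterministic Markov cohort model of DR/DMO progression under screening.

The cohort is tracked as a state-occupancy vector over health states; each
annual cycle applies (optionally) a screening episode and then the row-
stochastic transition matrix, accruing per-state euro costs and utility
weights discounted to present value.  Disease states come in undetected /
detected pairs: screening moves undetected mass to the detected (treated)
counterpart with the test's sensitivity, and healthy mass incurs a
false-positive work-up at rate 1 - specificity.

Transition probabilities and utilities are supplied via configuration; the
bundled demo model ships illustrative values only (see ``data/demo_model.yaml``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import econ
from .econ import DiscountSpec

__all__ = [
    "HealthState",
    "ScreeningStrategy",
    "MarkovModel",
    "CohortTrajectory",
    "validate_model",
    "step",
    "screening_cycles",
    "apply_screening",
    "run_cohort",
    "compare_strategies",
    "model_from_config",
    "strategy_from_config",
    "demo_model_path",
]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class HealthState:
    """One health state with its per-cycle cost (EUR) and utility weight."""

    name: str
    utility: float
    annual_cost: float = 0.0


@dataclass(frozen=True)
class ScreeningStrategy:
    """A screening policy: interval between episodes and test characteristics.

    Defaults are the programme evaluated by this package: 90.2% sensitivity
    and 98.6% specificity for DR, EUR 40.43 per screening episode.
    """

    interval: float
    sensitivity: float = 0.902
    specificity: float = 0.986
    episode_cost: float = 40.43

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError(f"screening interval must be > 0, got {self.interval}")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.episode_cost < 0:
            raise ValueError(f"episode_cost must be >= 0, got {self.episode_cost}")


@dataclass(frozen=True)
class MarkovModel:
    """A validated cohort model.

    ``detection_map`` pairs each undetected disease state index with its
    detected/treated counterpart; ``healthy`` lists state indices whose
    occupants can test false-positive at screening, incurring
    ``fp_workup_cost`` (one diagnostic visit) without changing state.
    """

    states: tuple[HealthState, ...]
    transition: np.ndarray
    initial: np.ndarray
    detection_map: Mapping[int, int] = field(default_factory=dict)
    healthy: tuple[int, ...] = ()
    fp_workup_cost: float = 0.0

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    @property
    def utilities(self) -> np.ndarray:
        return np.array([s.utility for s in self.states])

    @property
    def costs(self) -> np.ndarray:
        return np.array([s.annual_cost for s in self.states])

    @property
    def alive_mask(self) -> np.ndarray:
        return np.array([s.name != "dead" for s in self.states])

    def with_screening_pairs(self, **kwargs) -> "MarkovModel":
        return replace(self, **kwargs)


def validate_model(
    states: Sequence[HealthState],
    matrix: np.ndarray | Sequence[Sequence[float]],
    initial: Sequence[float] | None = None,
    detection_map: Mapping[int, int] | None = None,
    healthy: Sequence[int] = (),
    fp_workup_cost: float = 0.0,
) -> MarkovModel:
    """Check all model invariants and return a :class:`MarkovModel`.

    Raises ``ValueError`` if the matrix is not square and row-stochastic
    (rows sum to 1 within 1e-9, entries in [0, 1]), a utility falls outside
    [0, 1], a cost is negative, or a state named ``dead`` is not absorbing
    with zero cost and utility.
    """
    states = tuple(states)
    P = np.asarray(matrix, dtype=float)
    n = len(states)
    if P.shape != (n, n):
        raise ValueError(f"transition matrix shape {P.shape} does not match {n} states")
    if np.any(P < -_ROW_TOL) or np.any(P > 1 + _ROW_TOL):
        raise ValueError("transition probabilities must lie in [0, 1]")
    row_sums = P.sum(axis=1)
    bad = np.where(np.abs(row_sums - 1.0) > _ROW_TOL)[0]
    if bad.size:
        raise ValueError(
            f"transition rows must sum to 1: row(s) {bad.tolist()} sum to {row_sums[bad].tolist()}"
        )
    for i, s in enumerate(states):
        if not 0.0 <= s.utility <= 1.0:
            raise ValueError(f"utility of state {s.name!r} must be in [0, 1], got {s.utility}")
        if s.annual_cost < 0:
            raise ValueError(f"cost of state {s.name!r} must be >= 0, got {s.annual_cost}")
        if s.name == "dead":
            if s.utility != 0 or s.annual_cost != 0:
                raise ValueError("the dead state must have utility 0 and cost 0")
            if not (P[i, i] == 1.0 and np.all(np.delete(P[i], i) == 0.0)):
                raise ValueError("the dead state must be absorbing")
    if initial is None:
        init = np.zeros(n)
        init[0] = 1.0
    else:
        init = np.asarray(initial, dtype=float)
        if init.shape != (n,):
            raise ValueError(f"initial occupancy has shape {init.shape}, expected ({n},)")
        if np.any(init < 0) or abs(init.sum() - 1.0) > _ROW_TOL:
            raise ValueError("initial occupancy must be nonnegative and sum to 1")
    dmap = dict(detection_map or {})
    for u, d in dmap.items():
        if not (0 <= u < n and 0 <= d < n) or u == d:
            raise ValueError(f"invalid detection pair {u} -> {d}")
    if fp_workup_cost < 0:
        raise ValueError("fp_workup_cost must be >= 0")
    return MarkovModel(
        states=states,
        transition=P,
        initial=init,
        detection_map=dmap,
        healthy=tuple(healthy),
        fp_workup_cost=float(fp_workup_cost),
    )


def step(occupancy: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """One transition of the cohort: ``occupancy @ matrix`` (mass conserved)."""
    occ = np.asarray(occupancy, dtype=float)
    P = np.asarray(matrix, dtype=float)
    if P.shape != (occ.size, occ.size):
        raise ValueError(f"matrix shape {P.shape} does not match occupancy size {occ.size}")
    out = occ @ P
    if abs(out.sum() - occ.sum()) > 1e-12:
        raise ValueError("probability mass not conserved by transition")
    return out


def screening_cycles(interval: float, n_cycles: int) -> set[int]:
    """Integer cycle indices on the screening grid for a given interval.

    Screening episodes fall at the nearest whole cycle (half-up) to each
    multiple of the interval: interval 2.5 screens at cycles 0, 3, 5, 8, ...
    """
    cycles: set[int] = set()
    k = 0
    while True:
        c = math.floor(k * interval + 0.5)
        if c > n_cycles:
            break
        cycles.add(c)
        k += 1
    return cycles


def _on_grid(cycle_time: float, interval: float) -> bool:
    k = round(cycle_time / interval)
    for kk in (k - 1, k, k + 1):
        if kk >= 0 and math.floor(kk * interval + 0.5) == round(cycle_time):
            return True
    return False


def apply_screening(
    occupancy: np.ndarray,
    model: MarkovModel,
    strategy: ScreeningStrategy,
    cycle_time: float,
) -> tuple[np.ndarray, float]:
    """Apply one screening episode to the cohort, if the cycle is on the grid.

    On-grid: every undetected disease state sheds ``sensitivity`` of its mass
    to its detected counterpart; the episode cost accrues for all living
    mass; healthy mass additionally incurs the false-positive work-up cost at
    rate ``1 - specificity`` (those patients return to their state).
    Off-grid cycles return the occupancy unchanged at zero cost.

    Returns ``(new_occupancy, per_capita_cost)``.
    """
    if cycle_time < 0:
        raise ValueError(f"cycle_time must be >= 0, got {cycle_time}")
    occ = np.asarray(occupancy, dtype=float)
    if not _on_grid(cycle_time, strategy.interval):
        return occ.copy(), 0.0
    out = occ.copy()
    for u, d in model.detection_map.items():
        moved = strategy.sensitivity * out[u]
        out[u] -= moved
        out[d] += moved
    alive = float(occ[model.alive_mask].sum())
    cost = alive * strategy.episode_cost
    if model.healthy:
        healthy_mass = float(occ[list(model.healthy)].sum())
        cost += healthy_mass * (1.0 - strategy.specificity) * model.fp_workup_cost
    return out, cost


@dataclass(frozen=True)
class CohortTrajectory:
    """Per-cycle occupancy and discounted cost/QALY accrual of a cohort run."""

    state_names: tuple[str, ...]
    occupancy: np.ndarray  # (n_cycles + 1, n_states); row 0 is the initial cohort
    cycle_costs: np.ndarray  # discounted EUR accrued in each cycle
    cycle_qalys: np.ndarray  # discounted QALYs accrued in each cycle

    @property
    def cumulative_cost(self) -> np.ndarray:
        return np.cumsum(self.cycle_costs)

    @property
    def cumulative_qaly(self) -> np.ndarray:
        return np.cumsum(self.cycle_qalys)

    @property
    def total_cost(self) -> float:
        return float(self.cycle_costs.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.cycle_qalys.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle table: one row per (cycle, state) plus accrual columns."""
        n_cycles = len(self.cycle_costs)
        rows = []
        cum_c, cum_q = self.cumulative_cost, self.cumulative_qaly
        for c in range(n_cycles + 1):
            for j, name in enumerate(self.state_names):
                rows.append(
                    {
                        "cycle": c,
                        "state": name,
                        "occupancy": self.occupancy[c, j],
                        "cumulative_cost": 0.0 if c == 0 else float(cum_c[c - 1]),
                        "cumulative_qaly": 0.0 if c == 0 else float(cum_q[c - 1]),
                    }
                )
        return pd.DataFrame(rows)


def run_cohort(
    model: MarkovModel,
    strategy: ScreeningStrategy | None,
    horizon: float,
    discount: DiscountSpec = DiscountSpec(),
    anchor: str = "end",
) -> CohortTrajectory:
    """Run the cohort for ``round(horizon)`` annual cycles.

    Each cycle applies screening at its start (if the strategy's grid says
    so; ``strategy=None`` disables screening entirely), then one transition;
    state costs and utilities accrue at the end of the cycle with no
    half-cycle correction.  ``anchor`` chooses the discounting origin for the
    accrual: ``"end"`` discounts cycle ``c`` at time ``c`` (from baseline),
    ``"start"`` at ``c - 1`` (from the first screening episode); screening
    costs are always discounted at the episode time.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    if anchor not in ("end", "start"):
        raise ValueError(f"anchor must be 'end' or 'start', got {anchor!r}")
    n_cycles = max(1, int(round(horizon)))
    n = model.n_states
    occupancy = np.empty((n_cycles + 1, n))
    occupancy[0] = model.initial
    cycle_costs = np.zeros(n_cycles)
    cycle_qalys = np.zeros(n_cycles)
    occ = model.initial.copy()
    for c in range(n_cycles):
        if strategy is not None:
            occ, screen_cost = apply_screening(occ, model, strategy, cycle_time=c)
            cycle_costs[c] += screen_cost * econ.discount_factor(c, discount)
        occ = step(occ, model.transition)
        t_accrual = (c + 1) if anchor == "end" else c
        df = econ.discount_factor(t_accrual, discount)
        cycle_costs[c] += float(occ @ model.costs) * df
        cycle_qalys[c] += float(occ @ model.utilities) * df
        occupancy[c + 1] = occ
    return CohortTrajectory(
        state_names=model.state_names,
        occupancy=occupancy,
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
    )


def compare_strategies(
    model: MarkovModel,
    strategy_hi: ScreeningStrategy | None,
    strategy_lo: ScreeningStrategy | None,
    horizon: float,
    discount: DiscountSpec = DiscountSpec(),
    anchor: str = "end",
) -> econ.CEAResult:
    """Run both screening arms on the same model and compare them.

    Increments and the ICER are delegated to :func:`drscreen.econ.icer`, with
    the ``hi`` arm as the candidate strategy.
    """
    hi = run_cohort(model, strategy_hi, horizon, discount, anchor)
    lo = run_cohort(model, strategy_lo, horizon, discount, anchor)
    return econ.icer(hi.total_cost, hi.total_qaly, lo.total_cost, lo.total_qaly)


# ---------------------------------------------------------------------------
# Configuration plumbing


def model_from_config(config: Mapping) -> MarkovModel:
    """Build a validated model from a configuration mapping.

    Expected keys: ``states`` (list of ``{name, utility, cost}``, optionally
    ``detects_to`` naming the detected counterpart and ``healthy: true``),
    ``transitions`` (mapping state -> {state: probability}; omitted mass is
    an error), optional ``initial`` (mapping state -> fraction) and
    ``fp_workup_cost``.
    """
    state_specs = config["states"]
    states = tuple(
        HealthState(
            name=s["name"],
            utility=float(s["utility"]),
            annual_cost=float(s.get("cost", 0.0)),
        )
        for s in state_specs
    )
    index = {s.name: i for i, s in enumerate(states)}
    n = len(states)
    P = np.zeros((n, n))
    for src, targets in config["transitions"].items():
        for dst, p in targets.items():
            P[index[src], index[dst]] = float(p)
    detection_map = {
        index[s["name"]]: index[s["detects_to"]] for s in state_specs if "detects_to" in s
    }
    healthy = tuple(index[s["name"]] for s in state_specs if s.get("healthy"))
    initial = None
    if "initial" in config:
        initial = np.zeros(n)
        for name, frac in config["initial"].items():
            initial[index[name]] = float(frac)
    return validate_model(
        states,
        P,
        initial=initial,
        detection_map=detection_map,
        healthy=healthy,
        fp_workup_cost=float(config.get("fp_workup_cost", 0.0)),
    )


def strategy_from_config(config: Mapping) -> ScreeningStrategy:
    """Build a screening strategy from a ``{interval, sensitivity, ...}`` mapping."""
    return ScreeningStrategy(
        interval=float(config["interval"]),
        sensitivity=float(config.get("sensitivity", 0.902)),
        specificity=float(config.get("specificity", 0.986)),
        episode_cost=float(config.get("episode_cost", 40.43)),
    )


def demo_model_path() -> Path:
    """Path to the bundled illustrative model configuration."""
    return Path(__file__).parent / "data" / "demo_model.yaml"
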