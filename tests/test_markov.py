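"""Cohort engine: validation, stepping, screening and accrual."""

import math

import numpy as np
import pytest

from drscreen import econ, markov
from drscreen.markov import (
    HealthState,
    ScreeningStrategy,
    apply_screening,
    compare_strategies,
    run_cohort,
    screening_cycles,
    step,
    validate_model,
)


def three_state_model(p01=0.2, p12=0.1, cost1=100.0, cost2=500.0):
    """healthy -> sick -> blind chain used across tests."""
    states = (
        HealthState("healthy", utility=0.9),
        HealthState("sick", utility=0.7, annual_cost=cost1),
        HealthState("blind", utility=0.5, annual_cost=cost2),
    )
    P = np.array(
        [
            [1 - p01, p01, 0.0],
            [0.0, 1 - p12, p12],
            [0.0, 0.0, 1.0],
        ]
    )
    return validate_model(states, P)


def detection_model(progress_undetected=0.30, progress_treated=0.05):
    """4-state model in which detection strictly slows progression to blindness."""
    states = (
        HealthState("no_dr", utility=0.9),
        HealthState("dr_undetected", utility=0.7),
        HealthState("dr_treated", utility=0.7, annual_cost=300.0),
        HealthState("blind", utility=0.4, annual_cost=1000.0),
    )
    P = np.array(
        [
            [0.85, 0.15, 0.0, 0.0],
            [0.0, 1 - progress_undetected, 0.0, progress_undetected],
            [0.0, 0.0, 1 - progress_treated, progress_treated],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return validate_model(
        states, P, detection_map={1: 2}, healthy=(0,), fp_workup_cost=100.51
    )


class TestValidateModel:
    def test_identity_accepted(self):
        states = tuple(HealthState(f"s{i}", 0.8) for i in range(3))
        m = validate_model(states, np.eye(3))
        assert m.n_states == 3

    def test_substochastic_row_rejected(self):
        states = tuple(HealthState(f"s{i}", 0.8) for i in range(2))
        with pytest.raises(ValueError, match="sum to 1"):
            validate_model(states, [[0.5, 0.4], [0.0, 1.0]])

    def test_utility_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="utility"):
            validate_model((HealthState("s", 1.2),), [[1.0]])

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError, match="cost"):
            validate_model((HealthState("s", 0.5, annual_cost=-1.0),), [[1.0]])

    def test_dead_must_be_absorbing_and_costless(self):
        states = (HealthState("alive", 0.9), HealthState("dead", 0.0))
        with pytest.raises(ValueError, match="absorbing"):
            validate_model(states, [[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(ValueError, match="dead"):
            validate_model(
                (HealthState("alive", 0.9), HealthState("dead", 0.1)),
                [[0.9, 0.1], [0.0, 1.0]],
            )


class TestStep:
    def test_identity_leaves_occupancy(self):
        occ = np.array([0.3, 0.7])
        assert np.allclose(step(occ, np.eye(2)), occ)

    def test_absorbing_mass_stays(self):
        m = three_state_model()
        occ = np.array([0.0, 0.0, 1.0])
        assert np.allclose(step(occ, m.transition), occ)

    def test_hand_multiplied_product(self):
        P = np.array([[0.6, 0.3, 0.1], [0.2, 0.7, 0.1], [0.0, 0.0, 1.0]])
        occ = np.array([0.5, 0.5, 0.0])
        # by hand: [0.5*0.6+0.5*0.2, 0.5*0.3+0.5*0.7, 0.5*0.1+0.5*0.1]
        assert np.allclose(step(occ, P), [0.4, 0.5, 0.1])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            step(np.array([1.0, 0.0]), np.eye(3))


class TestScreeningSchedule:
    def test_interval_2p5_grid(self):
        assert screening_cycles(2.5, 17) == {0, 3, 5, 8, 10, 13, 15}

    def test_annual_grid(self):
        assert screening_cycles(1.0, 5) == {0, 1, 2, 3, 4, 5}


class TestApplyScreening:
    def test_perfect_test_detects_everything(self):
        m = detection_model()
        occ = np.array([0.5, 0.5, 0.0, 0.0])
        strat = ScreeningStrategy(interval=1.0, sensitivity=1.0, specificity=1.0,
                                  episode_cost=0.0)
        out, cost = apply_screening(occ, m, strat, cycle_time=0)
        assert out[1] == 0.0 and out[2] == 0.5
        assert cost == 0.0  # perfect specificity, free episode

    def test_sensitivity_fraction_detected(self):
        m = detection_model()
        occ = np.array([0.0, 1.0, 0.0, 0.0])
        strat = ScreeningStrategy(interval=1.0, sensitivity=0.902, specificity=1.0)
        out, _ = apply_screening(occ, m, strat, cycle_time=0)
        # 1000 undetected per-capita mass -> 902 detected at 90.2% sensitivity
        assert out[2] * 1000 == pytest.approx(902.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_off_grid_cycle_unchanged_and_free(self):
        m = detection_model()
        occ = np.array([0.25, 0.25, 0.25, 0.25])
        strat = ScreeningStrategy(interval=2.5)
        out, cost = apply_screening(occ, m, strat, cycle_time=2)
        assert np.array_equal(out, occ) and cost == 0.0

    def test_false_positive_workup_charged(self):
        m = detection_model()
        occ = np.array([1.0, 0.0, 0.0, 0.0])
        strat = ScreeningStrategy(interval=1.0, sensitivity=1.0, specificity=0.986,
                                  episode_cost=40.43)
        _, cost = apply_screening(occ, m, strat, cycle_time=0)
        assert cost == pytest.approx(40.43 + 0.014 * 100.51)


def naive_accrual(model, strategy, horizon, rate, anchor="end"):
    """Independent cycle-by-cycle tabulation of the cohort run."""
    occ = [float(x) for x in model.initial]
    n = len(occ)
    n_cycles = int(round(horizon))
    grid = set()
    if strategy is not None:
        k = 0
        while math.floor(k * strategy.interval + 0.5) <= n_cycles:
            grid.add(math.floor(k * strategy.interval + 0.5))
            k += 1
    total_cost = total_qaly = 0.0
    for c in range(n_cycles):
        if strategy is not None and c in grid:
            alive = sum(occ[i] for i, s in enumerate(model.states) if s.name != "dead")
            cost = alive * strategy.episode_cost
            cost += sum(occ[i] for i in model.healthy) * (1 - strategy.specificity) * model.fp_workup_cost
            total_cost += cost / (1 + rate) ** c
            new = list(occ)
            for u, d in model.detection_map.items():
                new[d] += strategy.sensitivity * occ[u]
                new[u] -= strategy.sensitivity * occ[u]
            occ = new
        occ = [
            sum(occ[i] * model.transition[i][j] for i in range(n)) for j in range(n)
        ]
        t = c + 1 if anchor == "end" else c
        total_cost += sum(
            occ[j] * model.states[j].annual_cost for j in range(n)
        ) / (1 + rate) ** t
        total_qaly += sum(occ[j] * model.states[j].utility for j in range(n)) / (
            1 + rate
        ) ** t
    return total_cost, total_qaly


class TestRunCohort:
    def test_zero_costs_and_utilities(self):
        states = (HealthState("a", 0.0), HealthState("b", 0.0))
        m = validate_model(states, np.eye(2))
        traj = run_cohort(m, None, horizon=5)
        assert traj.total_cost == 0.0 and traj.total_qaly == 0.0

    def test_absorbing_state_full_utility(self):
        m = validate_model((HealthState("well", 1.0),), [[1.0]])
        traj = run_cohort(m, None, horizon=3, discount=econ.DiscountSpec(0.0))
        assert traj.total_qaly == pytest.approx(3.0)

    def test_matches_naive_accrual_oracle(self, rng):
        """Engine equals an independently coded accrual loop to 1e-9."""
        for trial in range(8):
            n = int(rng.integers(2, 5))
            P = rng.dirichlet(np.ones(n), size=n)
            states = tuple(
                HealthState(f"s{i}", float(rng.uniform(0, 1)), float(rng.uniform(0, 500)))
                for i in range(n)
            )
            dmap = {0: 1} if n >= 2 and trial % 2 == 0 else {}
            m = validate_model(states, P, detection_map=dmap, healthy=(n - 1,),
                               fp_workup_cost=77.0)
            strat = ScreeningStrategy(
                interval=float(rng.choice([1.0, 2.0, 2.5])),
                sensitivity=float(rng.uniform(0, 1)),
                specificity=float(rng.uniform(0.8, 1)),
                episode_cost=float(rng.uniform(0, 60)),
            )
            horizon = int(rng.integers(1, 7))
            rate = float(rng.choice([0.0, 0.03, 0.05]))
            for anchor in ("end", "start"):
                traj = run_cohort(m, strat, horizon, econ.DiscountSpec(rate), anchor)
                cost, qaly = naive_accrual(m, strat, horizon, rate, anchor)
                assert traj.total_cost == pytest.approx(cost, abs=1e-9)
                assert traj.total_qaly == pytest.approx(qaly, abs=1e-9)

    def test_mass_conserved_every_cycle(self, demo_model):
        traj = run_cohort(demo_model, ScreeningStrategy(2.5), horizon=17)
        assert np.allclose(traj.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(traj.cumulative_cost) >= -1e-12)
        assert np.all(np.diff(traj.cumulative_qaly) >= -1e-12)

    def test_discount_monotonicity(self, demo_model):
        strat = ScreeningStrategy(2.5)
        q_low = run_cohort(demo_model, strat, 17, econ.DiscountSpec(0.01)).total_qaly
        q_high = run_cohort(demo_model, strat, 17, econ.DiscountSpec(0.05)).total_qaly
        assert q_high <= q_low

    @pytest.mark.parametrize("progress", [(0.2, 0.02), (0.3, 0.05), (0.5, 0.1)])
    def test_screening_interval_monotonic_benefit(self, progress):
        """Shorter intervals never lose QALYs when detection slows blindness."""
        m = detection_model(*progress)
        qalys = [
            run_cohort(m, ScreeningStrategy(interval=iv), horizon=15).total_qaly
            for iv in (1.0, 2.0, 2.5, 5.0, 10.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(qalys, qalys[1:]))

    def test_zero_sensitivity_is_cost_only(self, demo_model):
        blind_test = ScreeningStrategy(interval=1.0, sensitivity=0.0)
        screened = run_cohort(demo_model, blind_test, horizon=12)
        unscreened = run_cohort(demo_model, None, horizon=12)
        assert screened.total_qaly == pytest.approx(unscreened.total_qaly, abs=1e-12)
        assert screened.total_cost > unscreened.total_cost

    def test_trajectory_frame_tidy(self, demo_model):
        traj = run_cohort(demo_model, ScreeningStrategy(2.5), horizon=5)
        df = traj.to_frame()
        assert set(df.columns) == {
            "cycle", "state", "occupancy", "cumulative_cost", "cumulative_qaly"
        }
        assert len(df) == 6 * demo_model.n_states


class TestCompareStrategies:
    def test_identical_strategies(self, demo_model):
        s = ScreeningStrategy(2.5)
        r = compare_strategies(demo_model, s, s, horizon=10)
        assert r.delta_cost == 0.0 and r.delta_qaly == 0.0 and r.icer is None

    def test_annual_beats_sparse_in_high_progression_model(self):
        """When blindness is costly and detection prevents it, annual screening
        dominates a 10-year interval outright."""
        states = (
            HealthState("no_dr", utility=0.9),
            HealthState("dr_undetected", utility=0.7),
            HealthState("dr_treated", utility=0.7, annual_cost=50.0),
            HealthState("blind", utility=0.3, annual_cost=20_000.0),
        )
        P = np.array(
            [
                [0.7, 0.3, 0.0, 0.0],
                [0.0, 0.4, 0.0, 0.6],
                [0.0, 0.0, 0.98, 0.02],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        m = validate_model(states, P, detection_map={1: 2}, healthy=(0,))
        r = compare_strategies(
            m, ScreeningStrategy(1.0), ScreeningStrategy(10.0), horizon=15
        )
        assert r.dominance == "hi_dominates"

    def test_delegates_to_econ_icer(self, demo_model):
        hi = run_cohort(demo_model, ScreeningStrategy(1.0), 17)
        lo = run_cohort(demo_model, ScreeningStrategy(2.5), 17)
        expected = econ.icer(hi.total_cost, hi.total_qaly, lo.total_cost, lo.total_qaly)
        got = compare_strategies(demo_model, ScreeningStrategy(1.0), ScreeningStrategy(2.5), 17)
        assert got == expected
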