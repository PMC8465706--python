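import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clrkin import ParameterSet
from clrkin.kinetics import (
    blood_contribution_fraction,
    bolus_initial_condition,
    build_rate_matrix,
    cumulated_activity,
    cumulated_vector,
    organ_activity,
    solve_activities,
)
from clrkin.structures import BLOOD, Edge, ModelStructure, Observable

from conftest import make_random_stable_system


def one_compartment(lam: float) -> tuple[ModelStructure, ParameterSet]:
    s = ModelStructure((BLOOD,), (), {BLOOD: Observable((BLOOD,), None)})
    return s, ParameterSet(lam=lam)


def expm_taylor(m: np.ndarray, t: float) -> np.ndarray:
    """Independent oracle: scaling-and-squaring truncated Taylor series."""
    n_half = max(0, int(math.ceil(math.log2(max(np.abs(m).max() * t, 1e-16)))) + 4)
    a = m * (t / 2**n_half)
    term = np.eye(m.shape[0])
    out = term.copy()
    for k in range(1, 30):
        term = term @ a / k
        out += term
    for _ in range(n_half):
        out = out @ out
    return out


class TestRateMatrix:
    def test_pure_decay_single_compartment(self):
        s, p = one_compartment(lam=0.1)
        m = build_rate_matrix(s, p)
        assert m.shape == (1, 1)
        assert m[0, 0] == pytest.approx(-0.1)

    def test_final_model_dimensions(self, structure, params):
        m = build_rate_matrix(structure, params)
        assert m.shape == (17, 17)

    def test_column_sums_equal_minus_lambda(self, structure, params):
        m = build_rate_matrix(structure, params)
        np.testing.assert_allclose(m.sum(axis=0), -params.lam, atol=1e-15)

    def test_two_compartment_mass_conserving(self):
        s = ModelStructure((BLOOD, "t"), (Edge(BLOOD, "t", "k12"),))
        p = ParameterSet(rates={"k12": 0.3}, lam=0.0)
        m = build_rate_matrix(s, p)
        np.testing.assert_allclose(m.sum(axis=0), 0.0, atol=1e-15)

    def test_missing_rate_named_in_error(self, structure, params):
        incomplete = ParameterSet(
            rates={k: v for k, v in params.rates.items() if k != "blood_to_spleen"},
            blood_fractions=params.blood_fractions,
        )
        with pytest.raises(KeyError, match="blood_to_spleen"):
            build_rate_matrix(structure, incomplete)


class TestSolveActivities:
    def test_pure_decay_closed_form(self):
        s, p = one_compartment(lam=0.1)
        traj = solve_activities(s, p, np.array([10.0]), y0=np.array([100.0]))
        assert traj.activities[-1, 0] == pytest.approx(100 * math.exp(-1.0), rel=1e-10)

    def test_matches_taylor_series_oracle(self, structure, params):
        m = build_rate_matrix(structure, params)
        y0 = bolus_initial_condition(structure)
        for t in (5.0, 72.0, 505.0):
            traj = solve_activities(s := structure, params, np.array([t]))
            expected = expm_taylor(m, t) @ y0
            np.testing.assert_allclose(traj.activities[-1], expected, rtol=1e-8)

    def test_closed_system_conserves_mass(self):
        s = ModelStructure((BLOOD, "t"), (Edge(BLOOD, "t", "k"),))
        p = ParameterSet(rates={"k": 0.5}, lam=0.0)
        traj = solve_activities(s, p, np.linspace(1, 50, 7))
        np.testing.assert_allclose(traj.total(), 100.0, rtol=1e-10)

    def test_initial_condition_reported(self, structure, params):
        traj = solve_activities(structure, params, np.array([2.0, 5.0]))
        assert traj.times[0] == 0.0
        assert traj.compartment(BLOOD)[0] == pytest.approx(100.0)

    def test_nonnegative_trajectories(self, structure, params):
        traj = solve_activities(structure, params, np.linspace(1, 505, 30))
        assert traj.activities.min() >= -1e-9

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mass_balance_invariant(self, seed):
        """Sum_i y_i(t) e^{+lam t} stays at the injected amount."""
        structure, params = make_random_stable_system(seed)
        traj = solve_activities(structure, params, np.linspace(0.5, 300, 12))
        corrected = traj.total() * np.exp(params.lam * traj.times)
        np.testing.assert_allclose(corrected, 100.0, rtol=1e-8)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), factor=st.floats(0.1, 10))
    def test_linearity_in_initial_condition(self, seed, factor):
        structure, params = make_random_stable_system(seed, n_tissues=3)
        times = np.array([1.0, 24.0, 100.0])
        y0 = bolus_initial_condition(structure)
        t1 = solve_activities(structure, params, times, y0)
        t2 = solve_activities(structure, params, times, y0 * factor)
        np.testing.assert_allclose(t2.activities, t1.activities * factor, rtol=1e-10)


class TestOrganActivity:
    def test_empty_observable_is_zero(self, params):
        s = ModelStructure(
            (BLOOD,), (), {"ghost_organ": Observable((), None), BLOOD: Observable((BLOOD,), None)}
        )
        p = ParameterSet(lam=0.01)
        traj = solve_activities(s, p, np.array([1.0, 10.0]))
        np.testing.assert_array_equal(organ_activity(traj, s, p, "ghost_organ"), 0.0)

    def test_tumor_has_no_blood_term(self, structure, params):
        traj = solve_activities(structure, params, np.array([2.0, 24.0]))
        tumor = organ_activity(traj, structure, params, "tumor")
        manual = traj.compartment("tumor_fast") + traj.compartment("tumor_slow")
        np.testing.assert_allclose(tumor, manual, rtol=1e-12)

    def test_heart_at_time_zero_is_blood_fraction(self, structure, params):
        traj = solve_activities(structure, params, np.array([2.0]))
        heart = organ_activity(traj, structure, params, "heart_wall")
        f = params.blood_fractions["f_heart_wall"]
        assert heart[0] == pytest.approx(f * 100.0)

    def test_unknown_organ_raises(self, structure, params):
        traj = solve_activities(structure, params, np.array([2.0]))
        with pytest.raises(KeyError, match="pancreas"):
            organ_activity(traj, structure, params, "pancreas")


class TestCumulatedActivity:
    def test_pure_decay_closed_form(self):
        s, p = one_compartment(lam=0.01)
        assert cumulated_activity(s, p, BLOOD) == pytest.approx(100 / 0.01, rel=1e-12)

    def test_closed_form_matches_quadrature(self):
        """-M^-1 y0 against adaptive quadrature of the solved trajectory."""
        from scipy.integrate import quad
        from scipy.linalg import expm as scipy_expm

        for seed in range(5):
            structure, params = make_random_stable_system(seed, n_tissues=4)
            m = build_rate_matrix(structure, params)
            y0 = bolus_initial_condition(structure)
            horizon = -math.log(1e-14) / params.lam
            integral = cumulated_vector(structure, params)
            for i in range(len(structure.compartments)):
                val, err = quad(
                    lambda t: (scipy_expm(m * t) @ y0)[i], 0, horizon, limit=400
                )
                assert val == pytest.approx(integral[i], rel=1e-6)

    def test_divergent_closed_system_raises(self):
        s = ModelStructure(
            (BLOOD, "t"),
            (Edge(BLOOD, "t", "k"),),
            {BLOOD: Observable((BLOOD,), None)},
        )
        p = ParameterSet(rates={"k": 0.5}, lam=0.0)
        with pytest.raises(ArithmeticError, match="singular|diverg"):
            cumulated_activity(s, p, BLOOD)

    def test_linearity_in_bolus(self, structure, params):
        a1 = cumulated_activity(structure, params, "liver")
        y0 = bolus_initial_condition(structure, 200.0)
        a2 = cumulated_activity(structure, params, "liver", y0)
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_blood_contribution_fraction_bounds(self, structure, params):
        for organ in ("heart_wall", "kidneys", "spleen", "liver"):
            share = blood_contribution_fraction(structure, params, organ)
            assert 0.0 < share < 1.0
        # organs without a blood-fraction term contribute nothing via blood
        assert blood_contribution_fraction(structure, params, "tumor") == 0.0
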