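"""Tests for the closed-form fixed-point solvers, stability and branch sweep."""

import math

import numpy as np
import pytest

from addyn import (
    DegenerateParameterError,
    ModelParams,
    abstinent_equilibrium,
    all_equilibria,
    brute_force_equilibria,
    default_params,
    interior_equilibria,
    jacobian,
    saturated_equilibrium,
    simulate,
    sweep_branches,
)


class TestAbstinent:
    def test_present_and_stable_at_default_E(self, defaults):
        eq = abstinent_equilibrium(defaults, 0.0)
        assert (eq.C_star, eq.S_star) == (0.0, 0.5)
        assert eq.stable
        assert eq.eigen_moduli == pytest.approx((0.8, 0.6))
        assert eq.residual(defaults) < 1e-12

    def test_validity_window_boundary(self, defaults):
        assert abstinent_equilibrium(defaults, -0.5) is not None   # V = 0 exactly
        assert abstinent_equilibrium(defaults, -0.5).boundary
        assert abstinent_equilibrium(defaults, -0.6) is None       # V would be 0.1 > 0


class TestInterior:
    def test_single_unstable_root_at_E0(self, defaults):
        eqs = interior_equilibria(defaults, 0.0)
        assert len(eqs) == 1
        (eq,) = eqs
        assert eq.C_star == pytest.approx(0.5, abs=1e-12)
        assert eq.S_star == pytest.approx(0.0, abs=1e-12)
        assert not eq.stable
        assert eq.eigen_moduli == pytest.approx(
            (0.8 + math.sqrt(0.08), 0.8 - math.sqrt(0.08))
        )
        assert eq.residual(defaults) < 1e-12

    def test_no_roots_beyond_the_fold(self, defaults):
        # discriminant 4E^2 - 10E + 0.25 < 0 at E = 0.3
        assert interior_equilibria(defaults, 0.3) == []

    def test_two_roots_between_zero_and_fold(self, defaults):
        eqs = interior_equilibria(defaults, 0.02)
        assert len(eqs) == 2
        stables = sorted(eq.stable for eq in eqs)
        assert stables == [False, True]  # the addicted branch and the saddle
        for eq in eqs:
            assert eq.residual(defaults) < 1e-10
            assert len(eq.eigen_moduli) == 2

    def test_degenerate_kq_equals_p_signals(self):
        params = ModelParams(d=0.2, b=0.5, q=0.8, p=0.4, S_plus=0.5, h=0.2, k=0.5)
        assert params.k * params.q == params.p
        with pytest.raises(DegenerateParameterError):
            interior_equilibria(params, 0.0)
        # the census falls back to the numeric oracle instead of failing
        eqs = all_equilibria(params, 0.0)
        oracle = brute_force_equilibria(params, 0.0)
        assert len(eqs) == len(oracle)


class TestSaturated:
    def test_coordinates_and_stability_at_E0(self, defaults):
        eq = saturated_equilibrium(defaults, 0.0)
        assert eq.C_star == pytest.approx(2 / 3)
        assert eq.S_star == pytest.approx(-1 / 3)
        assert eq.stable
        assert eq.eigen_moduli == pytest.approx((0.6, 0.4))
        assert eq.residual(defaults) < 1e-12
        assert eq.boundary  # V = 1 exactly at E = 0

    def test_coordinates_independent_of_E_within_regime(self, defaults):
        eq = saturated_equilibrium(defaults, -0.4)
        assert (eq.C_star, eq.S_star) == pytest.approx((2 / 3, -1 / 3))
        assert not eq.boundary

    def test_absent_for_positive_E(self, defaults):
        assert saturated_equilibrium(defaults, 0.1) is None  # 1 - 0.1 = 0.9 < 1


class TestJacobian:
    def test_regime_matrices_at_defaults(self, defaults):
        assert np.allclose(
            jacobian(defaults, 0.0, 0.5, 0.0, "abstinent"),
            [[0.8, 0.0], [-0.2, 0.6]],
        )
        assert np.allclose(
            jacobian(defaults, 0.5, 0.0, 0.0, "interior"),
            [[0.8, -0.2], [-0.4, 0.8]],
        )
        assert np.allclose(
            jacobian(defaults, 2 / 3, -1 / 3, 0.0, "saturated"),
            [[0.4, 0.0], [-0.2, 0.6]],
        )

    def test_boundary_points_report_both_one_sided_linearizations(self, defaults):
        eq = saturated_equilibrium(defaults, 0.0)
        assert eq.boundary
        assert eq.eigen_moduli_interior_side is not None
        assert max(eq.eigen_moduli_interior_side) < 1.0  # stable from either side


class TestCensusAndOracle:
    def test_three_fixed_points_at_E0(self, defaults):
        eqs = all_equilibria(defaults, 0.0)
        assert len(eqs) == 3
        coords = [(round(e.C_star, 9), round(e.S_star, 9)) for e in eqs]
        assert coords == [
            (0.0, 0.5),
            (0.5, 0.0),
            (round(2 / 3, 9), round(-1 / 3, 9)),
        ]
        assert [e.stable for e in eqs] == [True, False, True]
        assert all(e.residual(defaults) < 1e-10 for e in eqs)

    def test_oracle_agrees_at_E0(self, defaults):
        oracle = brute_force_equilibria(defaults, 0.0)
        assert len(oracle) == 3
        closed = sorted((e.C_star, e.S_star) for e in all_equilibria(defaults, 0.0))
        for (Co, So), (Cc, Sc) in zip(oracle, closed):
            assert abs(Co - Cc) < 1e-6 and abs(So - Sc) < 1e-6

    def test_completeness_on_random_parameter_draws(self):
        """Closed-form solvers find exactly the oracle's fixed points."""
        rng = np.random.default_rng(2024)
        n_checked = 0
        while n_checked < 200:
            d = rng.uniform(0.05, 0.8)
            q = rng.uniform(0.2, 2.0)
            b = rng.uniform(0.0, 0.99 / q)
            p = rng.uniform(0.05, 1.2)
            h = rng.uniform(0.0, 0.5)
            k = rng.uniform(0.0, 0.5)
            S_plus = rng.uniform(0.1, 1.0)
            if abs(k * q - p) < 0.05:
                continue
            params = ModelParams(d=d, b=b, q=q, p=p, S_plus=S_plus, h=h, k=k)
            E = rng.uniform(-0.8, 0.5)
            closed = sorted((e.C_star, e.S_star) for e in all_equilibria(params, E))
            oracle = brute_force_equilibria(params, E)
            assert len(closed) == len(oracle), (params, E, closed, oracle)
            for (Cc, Sc), (Co, So) in zip(closed, oracle):
                assert abs(Cc - Co) < 1e-6 and abs(Sc - So) < 1e-6
            n_checked += 1


@pytest.fixture(scope="module")
def diagram(defaults):
    return sweep_branches(defaults, -0.6, 0.35, 0.005)


class TestBranchSweep:

    def test_abstinent_branch_exists_exactly_above_minus_S_plus(self, defaults, diagram):
        for E, eqs in zip(diagram.E_grid, diagram.equilibria):
            has_abstinent = any(e.regime == "abstinent" for e in eqs)
            assert has_abstinent == (E >= -defaults.S_plus - 1e-9)

    def test_counts_in_one_two_three(self, diagram):
        assert set(diagram.counts()) <= {1, 2, 3}

    def test_unstable_branch_lies_between_coexisting_stable_branches(self, diagram):
        saw_bistable = False
        for eqs in diagram.equilibria:
            stable = sorted(e.C_star for e in eqs if e.stable)
            unstable = [e.C_star for e in eqs if not e.stable]
            if len(stable) == 2:
                if any(e.boundary and e.regime == "abstinent" for e in eqs):
                    # at E = -S_plus exactly, the saddle has merged into the
                    # boundary abstinent point; no distinct unstable branch
                    continue
                saw_bistable = True
                assert len(unstable) == 1
                assert stable[0] < unstable[0] < stable[1]
        assert saw_bistable

    def test_fold_location_matches_discriminant_root(self, diagram):
        """Fold of the interior pair at the smaller root of 4E^2 - 10E + 0.25."""
        expected = (10 - math.sqrt(96)) / 8
        assert any(abs(f - expected) < 1e-6 for f in diagram.E_folds)

    def test_branch_endpoint_detected_at_minus_S_plus(self, diagram):
        assert any(abs(f - (-0.5)) < 1e-6 for f in diagram.E_folds)

    def test_export_frame_schema(self, diagram):
        df = diagram.to_frame()
        assert list(df.columns) == ["E", "C_star", "S_star", "regime", "stable", "eig1", "eig2"]
        assert len(df) == diagram.counts().sum()


class TestDynamicsAgreement:
    def test_hysteresis_two_initial_conditions(self, defaults):
        """Where both stable states coexist, history decides the outcome."""
        for E in (-0.3, -0.1, 0.0, 0.02):
            eqs = all_equilibria(defaults, E)
            stable = [e for e in eqs if e.stable]
            assert len(stable) == 2
            lo, hi = sorted(stable, key=lambda e: e.C_star)
            t1 = simulate(defaults, 0.0, defaults.S_plus, E, 0.0, 400)
            t2 = simulate(defaults, hi.C_star, hi.S_star, E, 0.0, 400)
            assert abs(t1.C[-1] - lo.C_star) < 1e-6
            assert abs(t2.C[-1] - hi.C_star) < 1e-6
            assert abs(t1.C[-1] - t2.C[-1]) > 0.1

    def test_stability_classification_matches_simulation(self, defaults):
        """Perturbed trajectories return to stable points and leave unstable ones."""
        for E in (-0.2, 0.0, 0.02):
            for eq in all_equilibria(defaults, E):
                traj = simulate(
                    defaults, min(1.0, eq.C_star + 1e-4), eq.S_star + 1e-4, E, 0.0, 500
                )
                dev = max(abs(traj.C[-1] - eq.C_star), abs(traj.S[-1] - eq.S_star))
                if eq.stable:
                    assert dev < 1e-6
                else:
                    assert max(eq.eigen_moduli) > 1
                    departed = np.maximum(
                        np.abs(traj.C - eq.C_star), np.abs(traj.S - eq.S_star)
                    )
                    assert departed.max() > 1e-2
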