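import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from cryptmech.geometry import Contour, shape_metrics
from cryptmech.junction_mechanics import (
    Cell,
    ForceState,
    Junction,
    Role,
    make_ring,
    relax_ring,
    solve_symmetric_angles,
    straightening_angle,
    total_energy,
    x_balance_residual,
)


class TestForceBalance:
    @pytest.mark.parametrize(
        "F_C, F_R, F_L, th1, th2",
        [
            (1.0, 1.0, 1.0, math.radians(60), math.radians(60)),  # 120-degree state
            (0.0, 1.0, 1.0, math.pi / 2, math.pi / 2),            # side forces orthogonal
            (2.0, 1.0, 1.0, 0.0, 0.0),                            # collinear limit
        ],
    )
    def test_equilibrium_states_have_zero_residual(self, F_C, F_R, F_L, th1, th2):
        state = ForceState(F_C_xz=F_C, F_R_xz=F_R, F_L_xz=F_L, theta1=th1, theta2=th2)
        assert x_balance_residual(state) == pytest.approx(0.0, abs=1e-15)

    def test_equal_forces_give_120_degrees(self):
        th1, th2 = solve_symmetric_angles(1.0, 1.0)
        assert math.degrees(th1 + th2) == pytest.approx(120.0, abs=1e-12)

    @pytest.mark.parametrize(
        "F_C, F_side, expected_deg",
        [(math.sqrt(2.0), 1.0, 45.0), (0.0, 1.0, 90.0), (2.0, 1.0, 0.0)],
    )
    def test_symmetric_angle_closed_form(self, F_C, F_side, expected_deg):
        th1, th2 = solve_symmetric_angles(F_C, F_side)
        assert th1 == th2
        assert math.degrees(th1) == pytest.approx(expected_deg, abs=1e-9)

    def test_overload_has_no_solution(self):
        with pytest.raises(ValueError, match="no solution"):
            solve_symmetric_angles(2.5, 1.0)

    def test_angle_sum_monotone_in_pull(self):
        sums = [sum(solve_symmetric_angles(f, 1.0)) for f in np.linspace(0.0, 2.0, 100)]
        assert all(a >= b for a, b in zip(sums, sums[1:]))

    @given(F_side=st.floats(0.1, 100.0), frac=st.floats(0.0, 1.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_solved_angles_satisfy_balance(self, F_side, frac):
        F_C = 2.0 * F_side * frac
        th1, th2 = solve_symmetric_angles(F_C, F_side)
        state = ForceState(F_C_xz=F_C, F_R_xz=F_side, F_L_xz=F_side,
                           theta1=th1, theta2=th2)
        assert abs(x_balance_residual(state)) < 1e-12


class TestStraighteningAngle:
    @pytest.mark.parametrize(
        "F_R1, F_R2, expected",
        [
            (1.0, 1.0, math.pi),               # equal tensions: straight chain
            (0.0, 1.0, math.pi / 2),           # orthogonal junction
            (0.5, 1.0, 2.0 * math.pi / 3.0),   # pi - arccos(1/2)
        ],
    )
    def test_closed_form(self, F_R1, F_R2, expected):
        assert straightening_angle(F_R1, F_R2) == pytest.approx(expected, abs=1e-12)

    def test_tends_to_pi_as_tensions_equalize(self):
        thetas = [straightening_angle(f, 1.0) for f in np.linspace(0.0, 1.0, 50)]
        assert all(a <= b for a, b in zip(thetas, thetas[1:]))
        assert thetas[-1] == pytest.approx(math.pi)

    def test_overload_rejected(self):
        with pytest.raises(ValueError):
            straightening_angle(1.5, 1.0)


def _oracle_positions(cells, junctions, applied, anchor_stiffness):
    """Independent equilibrium oracle: direct numerical energy minimization."""
    n = len(cells)
    idx = {c.id: i for i, c in enumerate(cells)}
    edges = np.array([[idx[j.cell_a], idx[j.cell_b]] for j in junctions])
    rest = np.array([j.rest_length for j in junctions])
    stiff = np.array([j.stiffness for j in junctions])
    anchor = np.array([c.position for c in cells])
    app = np.zeros((n, 2))
    for cid, f in applied.items():
        app[idx[cid]] = f
    fun = lambda x: total_energy(  # noqa: E731
        x.reshape(n, 2), edges, rest, stiff, app, anchor, anchor_stiffness
    )
    res = minimize(fun, anchor.ravel(), method="L-BFGS-B",
                   options=dict(ftol=1e-18, gtol=1e-13, maxiter=100_000))
    return res.x.reshape(n, 2)


class TestRelaxRing:
    def test_unloaded_ring_does_not_move(self):
        cells, junctions = make_ring(12)
        start = np.array([c.position for c in cells])
        eq = relax_ring(cells, junctions, tol=1e-10)
        assert np.allclose(eq.contour_points, start, atol=1e-12)
        assert eq.iterations == 0

    def test_single_spring_hooke_extension(self):
        cells = [Cell(0, np.array([0.0, 0.0])), Cell(1, np.array([1.0, 0.0]))]
        junctions = [Junction(0, 1, rest_length=1.0, stiffness=1.0)]
        eq = relax_ring(cells, junctions, applied={1: np.array([1.0, 0.0])},
                        fixed={0}, tol=1e-10)
        assert eq.positions[1][0] - 1.0 == pytest.approx(1.0, abs=1e-9)

    def test_unbalanced_force_without_reaction_rejected(self):
        cells, junctions = make_ring(6)
        with pytest.raises(ValueError, match="no equilibrium"):
            relax_ring(cells, junctions, applied={0: np.array([1.0, 0.0])})

    def test_radial_pull_produces_droplet(self):
        cells, junctions = make_ring(24)
        eq = relax_ring(cells, junctions, applied={0: np.array([1.0, 0.0])},
                        tol=1e-9, anchor_stiffness=0.1)
        m = shape_metrics(Contour(eq.contour_points))
        assert m["aspect_ratio"] > 1.0
        assert m["asymmetry"] > 0.02

    @pytest.mark.parametrize("n, pull", [(10, 0.5), (24, 1.0), (30, 2.0)])
    def test_matches_energy_minimization_oracle(self, n, pull):
        cells, junctions = make_ring(n)
        applied = {0: np.array([pull, 0.0])}
        eq = relax_ring(cells, junctions, applied=applied, tol=1e-9,
                        anchor_stiffness=0.1)
        oracle = _oracle_positions(cells, junctions, applied, 0.1)
        pos = np.array([eq.positions[i] for i in range(n)])
        assert np.abs(pos - oracle).max() < 1e-6

    def test_residual_below_tolerance_at_fixed_point(self):
        cells, junctions = make_ring(16)
        eq = relax_ring(cells, junctions, applied={0: np.array([0.7, 0.0])},
                        tol=1e-8, anchor_stiffness=0.1)
        assert eq.residual < 1e-8

    def test_internal_forces_cancel_on_closed_unloaded_ring(self):
        # Newton's third law: junction forces over a closed ring sum to zero
        cells, junctions = make_ring(17, radius=1.3)
        rng = np.random.default_rng(3)
        pos = np.array([c.position for c in cells]) + 0.05 * rng.standard_normal((17, 2))
        idx = {c.id: i for i, c in enumerate(cells)}
        net = np.zeros(2)
        for j in junctions:
            d = pos[idx[j.cell_b]] - pos[idx[j.cell_a]]
            ln = np.hypot(*d)
            f = j.stiffness * (ln - j.rest_length) * d / ln
            net += f + (-f)
        assert np.abs(net).max() < 1e-9

    def test_angle_sum_at_focal_cell_decreases_with_pull(self):
        cells, junctions = make_ring(24)
        sums = []
        warm = None
        for pull in np.linspace(0.2, 2.6, 9):
            eq = relax_ring(cells, junctions, applied={0: np.array([pull, 0.0])},
                            tol=1e-9, anchor_stiffness=0.1, initial_positions=warm)
            warm = eq.contour_points
            sums.append(eq.force_state.theta1 + eq.force_state.theta2)
        assert all(a >= b - 1e-9 for a, b in zip(sums, sums[1:]))

    def test_chain_straightens_under_strong_pull(self):
        cells, junctions = make_ring(24)
        eq = relax_ring(cells, junctions, applied={0: np.array([3.0, 0.0])},
                        tol=1e-9, anchor_stiffness=0.1)
        assert eq.force_state.theta3 > math.radians(180.0 - 10.0)


class TestValidation:
    def test_cell_radius_positive(self):
        with pytest.raises(ValueError):
            Cell(0, np.zeros(2), radius=0.0)

    def test_junction_invariants(self):
        with pytest.raises(ValueError):
            Junction(0, 1, rest_length=0.0, stiffness=1.0)
        with pytest.raises(ValueError):
            Junction(0, 1, rest_length=1.0, stiffness=-1.0)

    def test_junction_pair_unordered(self):
        assert Junction(0, 1, 1.0, 1.0).pair == Junction(1, 0, 1.0, 1.0).pair

    def test_force_state_angle_ranges(self):
        with pytest.raises(ValueError):
            ForceState(theta1=2.0)
        with pytest.raises(ValueError):
            ForceState(theta3=4.0)

    def test_ring_roles_and_geometry(self):
        cells, junctions = make_ring(24, radius=1.0)
        assert len(cells) == 24 and len(junctions) == 24
        for c in cells:
            assert c.role is Role.MCE
            assert np.hypot(*c.position) == pytest.approx(1.0, abs=1e-12)
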