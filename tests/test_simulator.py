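import math

import numpy as np
import pytest

from cryptmech.crypt_simulator import (
    LABEL_ORDER,
    ClassifierThresholds,
    SimConfig,
    SimConfigError,
    SimState,
    classify_opening,
    depth_profile,
    emt_feedback,
    run,
    step,
    with_overrides,
)
from cryptmech.geometry import shape_metrics
from cryptmech.io import make_fixture
from cryptmech.viscoelastic import accumulate

_ORDER = {lab: i for i, lab in enumerate(LABEL_ORDER)}


@pytest.fixture(scope="module")
def short_run():
    return run(SimConfig(n_divisions=30, ring_size=16, relax_tol=1e-6))


class TestConfig:
    def test_defaults_valid_and_delta_f_tracks_euler_load(self):
        cfg = SimConfig()
        assert cfg.F_crit == pytest.approx(math.pi**2 / 48.0)
        assert cfg.delta_F == pytest.approx(0.05 * cfg.F_crit)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ring_size": 2},
            {"K_spring": 0.0},
            {"emt_tolerance_band": 1.5},
            {"F_v": -0.1},
            {"delta_F_per_division": -1.0},
            {"A_L_schedule": (1.0,)},  # length mismatch with n_cross_sections
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(SimConfigError):
            SimConfig(**kwargs)


class TestStep:
    def test_zero_divisions_leaves_opening_round(self):
        res = run(SimConfig(n_divisions=0, ring_size=16))
        assert res.records == []
        assert res.final_label == "round"
        # a regular 16-gon's circularity is (pi/16)/tan(pi/16) ~ 0.987
        m = shape_metrics(res.final_contour)
        assert m["isoperimetric_ratio"] == pytest.approx(1.0, abs=0.02)

    def test_lossless_division_leaves_no_creep(self):
        cfg = SimConfig(n_divisions=1, ring_size=12, F_v=0.0, relax_tol=1e-6)
        state = SimState.initial(cfg)
        step(state)
        assert state.ledger.S_x == 0.0

    def test_trajectory_sx_matches_ledger_recomputation(self, short_run):
        events = [(e.applied_force, e.K_spring, e.F_v) for e in short_run.ledger.events]
        recomputed = accumulate(events).S_x
        assert short_run.records[-1]["S_x"] == recomputed


class TestEMT:
    def test_below_threshold_no_event(self):
        cfg = SimConfig(ring_size=12)
        state = SimState.initial(cfg)
        state.F_C_xz = 0.5 * cfg.F_crit
        assert emt_feedback(state) == []

    def test_overload_fires_and_caps(self):
        cfg = SimConfig(ring_size=12)
        state = SimState.initial(cfg)
        state.F_C_xz = 1.5 * cfg.F_crit
        state.y_p = 0.02
        events = emt_feedback(state)
        assert len(events) >= 1
        assert events[0].force_at_trigger >= cfg.F_crit
        assert events[0].y_p_after < events[0].y_p_before
        assert state.F_C_xz <= cfg.F_crit * (1.0 + cfg.emt_tolerance_band)

    def test_force_ceiling_over_steady_divisions(self):
        cfg = SimConfig(n_divisions=60, ring_size=12, relax_tol=1e-6)
        res = run(cfg)
        burn_in = 20
        for rec in res.records[burn_in:]:
            assert rec["F_C_xz"] <= cfg.F_crit * (1.0 + cfg.emt_tolerance_band) + 1e-12


class TestDepthProfile:
    def test_exponential_attenuation_values(self):
        cfg = SimConfig(n_cross_sections=5, attenuation_lambda=0.5)
        sections = depth_profile(1.0, cfg)
        expected = [math.exp(-0.5 * m) for m in range(5)]
        assert [s.S_x_m for s in sections] == pytest.approx(expected, rel=1e-12)

    def test_huge_attenuation_localizes_to_surface(self):
        cfg = SimConfig(n_cross_sections=4, attenuation_lambda=50.0)
        sections = depth_profile(2.0, cfg)
        assert sections[0].S_x_m == pytest.approx(2.0)
        assert all(s.S_x_m < 1e-20 for s in sections[1:])

    def test_strictly_decreasing_in_depth(self, short_run):
        vals = [s.S_x_m for s in short_run.depth_sections]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_depth_sequence_dl_increasing(self, short_run):
        dls = [s.D_L for s in short_run.depth_sections]
        assert all(a < b for a, b in zip(dls, dls[1:]))

    def test_monotonicity_breaking_schedule_rejected(self):
        cfg = SimConfig(n_cross_sections=3, attenuation_lambda=0.5,
                        A_L_schedule=(0.0, 5.0, 0.0))
        with pytest.raises(SimConfigError, match="monotonicity"):
            depth_profile(1.0, cfg)

    def test_compatible_schedule_accepted(self):
        cfg = SimConfig(n_cross_sections=3, attenuation_lambda=1.0,
                        A_L_schedule=(0.2, 0.1, 0.05))
        vals = [s.S_x_m for s in depth_profile(1.0, cfg)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestClassifier:
    def test_circle_is_round(self, circle720):
        assert classify_opening(shape_metrics(circle720)) == "round"

    def test_teardrop_is_droplet(self):
        contour = make_fixture("teardrop", {"pinch": 3.0})
        assert classify_opening(shape_metrics(contour)) == "droplet"

    def test_elongated_contour_is_linear(self):
        contour = make_fixture("ellipse", {"a": 10.0, "b": 1.0})
        assert classify_opening(shape_metrics(contour)) == "linear"

    def test_groove_requires_linear_neighbours(self):
        contour = make_fixture("ellipse", {"a": 10.0, "b": 1.0})
        m = shape_metrics(contour)
        assert classify_opening(m, n_adjacent_linear=2) == "groove"
        assert classify_opening(m, n_adjacent_linear=0) == "linear"

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ClassifierThresholds(round_aspect=2.0, droplet_aspect=1.5)


class TestRun:
    def test_short_run_reaches_droplet(self, short_run):
        assert short_run.records[-1]["aspect_ratio"] > 1.0
        assert short_run.final_label in ("droplet", "linear")

    def test_shape_metrics_monotone(self, short_run):
        iso = [r["iso_ratio"] for r in short_run.records]
        asp = [r["aspect_ratio"] for r in short_run.records]
        assert all(a >= b - 1e-9 for a, b in zip(iso, iso[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(asp, asp[1:]))

    def test_label_sequence_never_reverses(self, short_run):
        labels = short_run.labels()
        assert all(_ORDER[a] <= _ORDER[b] for a, b in zip(labels, labels[1:]))

    def test_runs_are_deterministic(self):
        cfg = SimConfig(n_divisions=8, ring_size=12, relax_tol=1e-6)
        r1, r2 = run(cfg), run(cfg)
        assert r1.records == r2.records
        assert np.array_equal(r1.final_contour.points, r2.final_contour.points)

    def test_summary_reports_final_class(self, short_run):
        text = short_run.summary()
        assert "final opening class" in text
        assert short_run.final_label in text

    def test_with_overrides_returns_new_config(self):
        cfg = SimConfig()
        cfg2 = with_overrides(cfg, n_divisions=5)
        assert cfg2.n_divisions == 5 and cfg.n_divisions == 200
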