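"""Bending, spine length, coiling, distances, velocity, and go phases."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvatrack.features import (
    FeatureConfig,
    acceleration_series,
    accumulated_distance,
    bending_angle,
    distance_to_origin,
    go_phases,
    is_coiled,
    spine_length,
    sweep_state,
    velocity_series,
)
from larvatrack.model import AnimalModel
from larvatrack.segmentation import Contour

from conftest import straight_model


class TestBendingAngle:
    def test_collinear_is_straight(self):
        assert bending_angle((0, 0), (10, 0), (20, 0)) == pytest.approx(180.0)

    def test_perpendicular_deviation_is_90(self):
        gamma = bending_angle((10, 10), (10, 0), (20, 0))
        assert abs(gamma - 180.0) == pytest.approx(90.0)

    def test_left_bend_exceeds_180_in_image_coords(self):
        # convention: positive cross product of (v2, v1) = left bend (> 180 deg);
        # with y down and the body along +x this is a head deflection toward +y
        assert bending_angle((20, 5), (10, 0), (0, 0)) > 180.0
        assert bending_angle((20, -5), (10, 0), (0, 0)) < 180.0

    def test_magnitude_matches_arccos_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            h, s, t = rng.uniform(-50, 50, (3, 2))
            v1, v2 = h - s, s - t
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 == 0 or n2 == 0:
                continue
            expected = math.degrees(math.acos(np.clip(v1 @ v2 / (n1 * n2), -1, 1)))
            assert abs(bending_angle(h, s, t) - 180.0) == pytest.approx(expected, abs=1e-9)

    def test_antisymmetry_sums_to_360(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            h, s, t = rng.uniform(0, 100, (3, 2))
            g = bending_angle(h, s, t)
            if not np.isnan(g) and abs(g - 180.0) > 1e-9:
                assert g + bending_angle(t, s, h) == pytest.approx(360.0, abs=1e-9)

    def test_degenerate_vectors_are_nan(self):
        assert np.isnan(bending_angle((5, 5), (5, 5), (10, 0)))

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=6, max_size=6))
    def test_bending_always_in_open_interval(self, coords):
        h, s, t = (coords[0], coords[1]), (coords[2], coords[3]), (coords[4], coords[5])
        gamma = bending_angle(h, s, t)
        assert np.isnan(gamma) or 0.0 <= gamma <= 360.0


class TestSweepState:
    def test_examples_and_boundary_semantics(self):
        assert sweep_state(200, 20) == "left"
        assert sweep_state(180, 0) == "left"  # boundary: >= is inclusive
        assert sweep_state(179.9, 0.2) == "straight"
        assert sweep_state(150, 20) == "right"

    def test_matches_inequality_oracle_on_grid(self):
        for gamma in np.linspace(100, 260, 33):
            for tau in (0, 5, 20, 45):
                got = sweep_state(gamma, tau)
                expected = (
                    "left" if gamma >= 180 + tau else "right" if gamma <= 180 - tau else "straight"
                )
                assert got == expected


class TestSpineLength:
    def test_collinear_landmarks(self):
        m = straight_model((0, 0), (30, 0), n_spine=5)
        assert spine_length(m) == pytest.approx(30.0)

    def test_single_interior_point(self):
        m = straight_model((0, 0), (10, 10), n_spine=1)
        assert spine_length(m) == pytest.approx(math.hypot(10, 10))

    def test_matches_polyline_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            m = straight_model((0, 0), (40, 0))
            m.spine = rng.uniform(0, 40, (5, 2))
            chain = [m.head] + list(m.spine) + [m.tail]
            expected = sum(
                math.dist(tuple(chain[i]), tuple(chain[i + 1])) for i in range(len(chain) - 1)
            )
            assert spine_length(m) == pytest.approx(expected)


def _disk_like_model(radius=12.0) -> AnimalModel:
    """Model extracted from a circular blob: spine collapses to a diameter."""
    n = 80
    a = np.linspace(0, 2 * math.pi, n, endpoint=False)
    pts = np.stack([30 + radius * np.cos(a), 30 + radius * np.sin(a)], axis=1)
    contour = Contour.from_points(pts)
    spine = np.stack([np.linspace(30 - radius, 30 + radius, 5), np.full(5, 30.0)], axis=1)
    return AnimalModel(
        head=np.array([30.0 - radius, 30.0]),
        tail=np.array([30.0 + radius, 30.0]),
        spine=spine,
        radii=np.full(5, radius),
        center_of_mass=np.array([30.0, 30.0]),
        area=contour.area,
        perimeter=2 * math.pi * radius,
        contour=contour,
    )


class TestIsCoiled:
    def test_circle_fires_both_ratios(self):
        assert is_coiled(_disk_like_model())

    def test_straight_capsule_does_not_fire(self):
        m = straight_model((10, 20), (60, 20), radius=4.0)
        assert not is_coiled(m)


class TestDistances:
    def test_closed_square_path(self):
        com = np.array([(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)], dtype=float)
        assert accumulated_distance(com)[-1] == pytest.approx(40.0)
        assert distance_to_origin(com)[-1] == pytest.approx(0.0)

    def test_monotone_path_acc_equals_origin(self):
        com = np.array([(t * 3.0, 0) for t in range(20)])
        assert np.allclose(accumulated_distance(com), distance_to_origin(com))

    def test_random_walk_triangle_inequality(self):
        rng = np.random.default_rng(23)
        com = np.cumsum(rng.normal(0, 2, (1000, 2)), axis=0)
        d_acc = accumulated_distance(com)
        d_org = distance_to_origin(com - com[0])
        assert (d_org <= d_acc + 1e-9).all()
        assert (np.diff(d_acc) >= -1e-12).all()


class TestVelocityAcceleration:
    def test_uniform_motion_recovers_speed(self):
        c = 1.7
        com = np.array([(c * t, 0) for t in range(40)], dtype=float)
        v = velocity_series(com, fps=10)
        assert np.allclose(v[5:-5], c)
        assert np.isnan(v[:5]).all() and np.isnan(v[-5:]).all()

    def test_stationary_is_zero(self):
        com = np.zeros((30, 2))
        v = velocity_series(com, fps=10)
        assert np.nanmax(v) == 0

    def test_sinusoidal_path_matches_direct_formula(self):
        t = np.arange(60)
        com = np.stack([t * 1.0, 10 * np.sin(t / 5)], axis=1)
        fps = 10
        v = velocity_series(com, fps)
        half = fps // 2
        for k in range(half, 60 - half):
            expected = np.linalg.norm(com[k - half] - com[k + half]) / fps
            assert v[k] == pytest.approx(expected)

    def test_acceleration_formula(self):
        v = np.array([0.0, 4.0, 4.0, np.nan, 2.0])
        a = acceleration_series(v, divisor=2.0)
        assert a[0] == pytest.approx(2.0)
        assert a[1] == pytest.approx(0.0)
        assert np.isnan(a[2]) and np.isnan(a[3]) and np.isnan(a[4])


class TestGoPhases:
    def _config(self, tau_go=5):
        return FeatureConfig(fps=10, bend_threshold_deg=20, go_velocity_threshold=1.0,
                             go_min_frames=tau_go)

    def test_all_fast_and_straight_one_phase(self):
        v = np.full(20, 3.0)
        g = np.full(20, 180.0)
        flags, phases = go_phases(v, g, self._config())
        assert flags.all()
        assert phases == [(0, 20)]

    def test_runs_below_minimum_are_reorientation(self):
        v = np.array([3.0] * 4 + [0.0] + [3.0] * 4)
        g = np.full(9, 180.0)
        flags, phases = go_phases(v, g, self._config(tau_go=5))
        assert not flags.any()
        assert phases == []

    def test_matches_rle_filter_oracle(self):
        rng = np.random.default_rng(31)
        v = rng.uniform(0, 3, 300)
        g = rng.uniform(120, 240, 300)
        cfg = self._config(tau_go=4)
        flags, _ = go_phases(v, g, cfg)
        raw = (v > 1.0) & (np.abs(g - 180) < 20)
        expected = np.zeros(300, dtype=bool)
        pos = 0
        for val, group in itertools.groupby(raw):
            n = len(list(group))
            if val and n >= 4:
                expected[pos : pos + n] = True
            pos += n
        assert np.array_equal(flags, expected)

    def test_phase_frames_subset_of_raw(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 2, 100)
        g = rng.uniform(150, 210, 100)
        cfg = self._config()
        flags, phases = go_phases(v, g, cfg)
        raw = (v > cfg.go_velocity_threshold) & (np.abs(g - 180) < cfg.bend_threshold_deg)
        assert not (flags & ~raw).any()
        assert len(phases) <= 100 // cfg.go_min_frames
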