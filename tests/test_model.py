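"""Curvature, head/tail location, contour splitting and spine extraction."""

import math

import numpy as np
import pytest

from larvatrack.model import (
    ModelConfig,
    build_model,
    contour_curvature,
    locate_head_tail,
    resample_polyline,
    split_and_resample,
)
from larvatrack.segmentation import Contour, find_contours, extract_foreground
from larvatrack.synthetic import AnimalSpec, SceneSpec, render_scene

from conftest import capsule_contour, capsule_points


def _circle_contour(radius=20, n=120, center=(40, 40)) -> Contour:
    a = np.linspace(0, 2 * math.pi, n, endpoint=False)
    pts = np.stack([center[0] + radius * np.cos(a), center[1] + radius * np.sin(a)], axis=1)
    return Contour.from_points(pts)


class TestCurvature:
    def test_straight_segment_near_180(self):
        contour = capsule_contour(length=80, width=16)
        curv = contour_curvature(contour)
        # points on the long straight sides must be near-collinear
        assert np.median(curv) > 170

    def test_rectangle_corner_near_90(self):
        # rectangle boundary sampled at unit spacing; corner angles ~90 deg
        xs = np.arange(0, 40)
        ys = np.arange(0, 16)
        pts = (
            [(x, 0) for x in xs]
            + [(39, y) for y in ys]
            + [(x, 15) for x in xs[::-1]]
            + [(0, y) for y in ys[::-1]]
        )
        contour = Contour.from_points(np.asarray(pts, dtype=float))
        curv = contour_curvature(contour, ModelConfig())
        assert abs(curv.min() - 90) < 15
        assert curv.max() > 170

    def test_circle_matches_inscribed_angle_formula(self):
        n = 120
        contour = _circle_contour(radius=20, n=n)
        config = ModelConfig()
        curv = contour_curvature(contour, config)
        _, d_max = config.arm_lengths(n)
        expected = 180.0 - 360.0 * d_max / n  # symmetric inscribed angle, widest arms
        assert abs(curv.mean() - expected) < 3.0
        assert curv.std() < 6.0  # uniform up to integer-pixel discretization

    def test_too_short_contour_errors(self):
        tiny = Contour(points=np.array([[0, 0], [1, 0], [1, 1], [0, 1]]), area=4, perimeter=4.0)
        with pytest.raises(ValueError):
            contour_curvature(tiny, ModelConfig())


class TestHeadTail:
    def test_capsule_endpoints_on_opposite_caps(self):
        contour = capsule_contour(length=50, width=10, center=(40, 30))
        curv = contour_curvature(contour)
        h, t = locate_head_tail(contour, curv)
        xs = contour.points[[h, t], 0]
        assert abs(xs.min() - 15) < 4  # one tip near x = 40 - 25
        assert abs(xs.max() - 65) < 4  # other near x = 40 + 25

    def test_rotation_moves_assignment_with_the_shape(self):
        for angle in (0, 90):
            contour = capsule_contour(length=50, width=10, center=(60, 60), angle_deg=angle)
            curv = contour_curvature(contour)
            h, t = locate_head_tail(contour, curv)
            tips = contour.points[[h, t]].astype(float)
            d = np.linalg.norm(tips[0] - tips[1])
            assert d > 0.8 * 50  # endpoints stay near-maximally separated

    def test_ellipse_ends_match_brute_force_window_scan(self):
        a, b, n = 30.0, 10.0, 140
        theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
        pts = np.stack([60 + a * np.cos(theta), 60 + b * np.sin(theta)], axis=1)
        contour = Contour.from_points(pts)
        config = ModelConfig()
        curv = contour_curvature(contour, config)
        h, t = locate_head_tail(contour, curv, config)
        # independent exhaustive scan over circular mean-angle windows
        w = config.curvature_window
        means = np.array(
            [np.mean([curv[(i + k) % n] for k in range(-w, w + 1)]) for i in range(n)]
        )
        brute_head = int(np.argmin(means))
        delta = int(round(config.head_tail_min_separation_frac * n))
        circ = np.minimum(np.abs(np.arange(n) - brute_head), n - np.abs(np.arange(n) - brute_head))
        brute_tail = int(np.argmin(np.where(circ >= delta, means, np.inf)))
        assert {h, t} == {brute_head, brute_tail}
        # both near the major-axis endpoints
        for idx in (h, t):
            assert min(np.linalg.norm(pts[idx] - [90, 60]), np.linalg.norm(pts[idx] - [30, 60])) < 3

    def test_no_candidate_at_separation_errors(self):
        contour = _circle_contour(radius=10, n=40)
        curv = contour_curvature(contour)
        with pytest.raises(ValueError):
            locate_head_tail(contour, curv, ModelConfig(head_tail_min_separation_frac=0.9))


class TestSplitResample:
    def test_symmetric_capsule_pairs_mirror(self):
        contour = capsule_contour(length=50, width=10, center=(40, 30))
        curv = contour_curvature(contour)
        h, t = locate_head_tail(contour, curv)
        half1, half2 = split_and_resample(contour, h, t)
        assert len(half1) == len(half2)
        # paired points mirror about the y=30 symmetry axis
        mirrored = half2.copy()
        mirrored[:, 1] = 60 - mirrored[:, 1]
        assert np.abs(half1 - mirrored).max() < 2.0

    def test_adjacent_head_tail_degenerates_to_endpoints(self):
        contour = capsule_contour(length=40, width=10)
        half1, half2 = split_and_resample(contour, 3, 4)
        assert len(half1) == len(half2) == 2
        assert np.allclose(half1[0], half2[0])
        assert np.allclose(half1[-1], half2[-1])

    def test_resampling_matches_piecewise_linear_oracle(self):
        rng = np.random.default_rng(13)
        pts = np.cumsum(rng.uniform(0.5, 2.0, size=(20, 2)), axis=0)
        m = 9
        out = resample_polyline(pts, m)
        # independent arc-length interpolation, point by point
        seg = [float(np.linalg.norm(pts[i + 1] - pts[i])) for i in range(len(pts) - 1)]
        total = sum(seg)
        for k in range(m):
            target = total * k / (m - 1)
            acc, i = 0.0, 0
            while i < len(seg) - 1 and acc + seg[i] < target - 1e-12:
                acc += seg[i]
                i += 1
            u = (target - acc) / seg[i] if seg[i] else 0.0
            expected = pts[i] + u * (pts[i + 1] - pts[i])
            assert np.allclose(out[k], expected, atol=1e-9)


class TestBuildModel:
    def test_straight_capsule_spine_on_axis(self):
        contour = capsule_contour(length=40, width=10, center=(40, 30))
        model = build_model(contour, ModelConfig(n_spine_points=7))
        assert len(model.spine) == 5
        assert np.abs(model.spine[:, 1] - 30).max() <= 1.0  # on the symmetry axis
        assert 4.0 <= np.median(model.radii) <= 6.0  # half-width of a 10 px body
        assert abs(model.center_of_mass[0] - 40) <= 1 and abs(model.center_of_mass[1] - 30) <= 1

    def test_bent_capsule_spine_follows_analytic_midline(self):
        from larvatrack.segmentation import SegmentationConfig

        spec = SceneSpec(
            shape=(128, 128),
            n_frames=2,
            animals=[AnimalSpec(start=(64, 64), bend_amp_deg=40, bend_period=4)],
            noise_sd=0.0,
            n_artifacts=0,
        )
        frames, truth = render_scene(spec)
        # frame 1 carries the full 40-degree bend
        fg = extract_foreground(frames[1], np.zeros_like(frames[1]),
                                SegmentationConfig(gray_threshold=100, area_min=50, area_max=2000))
        (contour,) = find_contours(fg)
        model = build_model(contour)
        rec = truth.records[truth.records.frame == 1].iloc[0]
        landmarks = np.array(
            [[rec["head_x"], rec["head_y"]]]
            + [[rec[f"spine{j}_x"], rec[f"spine{j}_y"]] for j in range(1, 6)]
            + [[rec["tail_x"], rec["tail_y"]]]
        )
        dense = resample_polyline(landmarks, 300)
        assert abs(rec["bending"] - 180.0) > 15  # genuinely bent posture
        for s in model.spine:
            assert np.linalg.norm(dense - s, axis=1).min() <= 2.0

    def test_translation_equivariance(self):
        base = capsule_contour(length=44, width=10, center=(35, 30))
        shifted = Contour.from_points(np.asarray(base.points, dtype=float) + [17, 23])
        m0 = build_model(base)
        m1 = build_model(shifted)
        for a, b in [(m0.head, m1.head), (m0.tail, m1.tail), (m0.center_of_mass, m1.center_of_mass)]:
            assert np.abs(np.asarray(b) - np.asarray(a) - [17, 23]).max() <= 1.0
        assert np.abs(m1.spine - m0.spine - [17, 23]).max() <= 1.0

    def test_spine_points_inside_contour(self):
        for angle in (0, 37, 90):
            contour = capsule_contour(length=46, width=12, center=(60, 60), angle_deg=angle)
            model = build_model(contour)
            assert contour.contains_points(model.spine).all()

    def test_spine_segments_bounded_by_half_perimeter(self):
        contour = capsule_contour(length=50, width=10)
        model = build_model(contour)
        chain = np.vstack([model.head, model.spine, model.tail])
        total = np.linalg.norm(np.diff(chain, axis=0), axis=1).sum()
        assert total <= model.perimeter / 2 + 5.0
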