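"""Shared fixtures: rendered scenes, hand-built contours and models."""

from __future__ import annotations

import math

import numpy as np
import pytest

from larvatrack.model import AnimalModel
from larvatrack.pipeline import RunConfig, run_pipeline
from larvatrack.segmentation import Contour
from larvatrack.evaluation import match_and_deviate
from larvatrack.synthetic import make_scenario, render_scene, suggested_segmentation


def capsule_points(length: float = 40, width: float = 10, center=(30, 20), angle_deg: float = 0.0):
    """Closed boundary chain of a straight capsule, ~1 px point spacing."""
    r = width / 2.0
    half = (length - width) / 2.0
    pts = []
    n_side = max(2, int(round(2 * half)))
    n_cap = max(3, int(round(math.pi * r)))
    for x in np.linspace(-half, half, n_side, endpoint=False):
        pts.append((x, -r))
    for phi in np.linspace(-math.pi / 2, math.pi / 2, n_cap, endpoint=False):
        pts.append((half + r * math.cos(phi), r * math.sin(phi)))
    for x in np.linspace(half, -half, n_side, endpoint=False):
        pts.append((x, r))
    for phi in np.linspace(math.pi / 2, 3 * math.pi / 2, n_cap, endpoint=False):
        pts.append((-half + r * math.cos(phi), r * math.sin(phi)))
    pts = np.asarray(pts, dtype=float)
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    rot = pts @ np.array([[c, s], [-s, c]])
    return rot + np.asarray(center, dtype=float)


def capsule_contour(length=40, width=10, center=(30, 20), angle_deg=0.0) -> Contour:
    return Contour.from_points(capsule_points(length, width, center, angle_deg))


def straight_model(head, tail, n_spine: int = 5, radius: float = 4.0) -> AnimalModel:
    """Hand-built straight-bodied model with a matching capsule contour."""
    head = np.asarray(head, dtype=float)
    tail = np.asarray(tail, dtype=float)
    spine = np.array([head + (tail - head) * j / (n_spine + 1) for j in range(1, n_spine + 1)])
    length = float(np.linalg.norm(head - tail))
    center = (head + tail) / 2.0
    angle = math.degrees(math.atan2(tail[1] - head[1], tail[0] - head[0]))
    contour = capsule_contour(length + 2 * radius, 2 * radius, center, angle)
    return AnimalModel(
        head=head,
        tail=tail,
        spine=spine,
        radii=np.full(n_spine, radius),
        center_of_mass=np.rint(center),
        area=contour.area,
        perimeter=contour.perimeter,
        contour=contour,
    )


@pytest.fixture(scope="session")
def forward_crawl_run():
    """Full-pipeline run on the 5-animal forward-crawl scene, scored vs truth."""
    spec = make_scenario("forward_crawl")
    frames, truth = render_scene(spec)
    config = RunConfig(segmentation=suggested_segmentation(spec))
    trajectories, table = run_pipeline(frames, config)
    report = match_and_deviate(table, truth.records)
    return {
        "spec": spec,
        "frames": frames,
        "truth": truth,
        "trajectories": trajectories,
        "table": table,
        "report": report,
    }


@pytest.fixture(scope="session")
def headcast_run():
    """Head-cast scene (stationary animal) tracked against a blank background."""
    spec = make_scenario("headcast")
    frames, truth = render_scene(spec)
    config = RunConfig(segmentation=suggested_segmentation(spec))
    background = np.zeros(spec.shape, dtype=np.uint8)
    trajectories, table = run_pipeline(frames, config, background=background)
    report = match_and_deviate(table, truth.records)
    return {"truth": truth, "trajectories": trajectories, "table": table, "report": report}
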