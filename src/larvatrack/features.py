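"""Posture, motion, and phase features derived from tracked animal models.

The main body bending angle gamma is measured at the middle spine point
between the head-side vector ``v1 = h - s_mid`` and the tail-side vector
``v2 = s_mid - t``.  A straight animal has gamma = 180 deg; gamma > 180
means a left bend and gamma < 180 a right bend.  The magnitude of the
deviation from 180 deg is the unsigned angle arccos(<v1, v2>/(|v1||v2|)),
and the side comes from the sign of the 2-D cross product of v2 and v1 in
image coordinates (y axis pointing down): a positive cross product is a
left bend.

Motion features are computed from the center of mass, which is contour
derived and independent of the spine: accumulated path length, distance to
the origin of the trajectory, a velocity over a one-second central window,
and the absolute difference of consecutive velocities as acceleration.
Frames where a feature is undefined (window reaching outside the
trajectory, degenerate geometry, coiled posture) carry NaN, never a silent
zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnimalModel

__all__ = [
    "FeatureConfig",
    "bending_angle",
    "sweep_state",
    "spine_length",
    "is_coiled",
    "accumulated_distance",
    "distance_to_origin",
    "velocity_series",
    "acceleration_series",
    "go_phases",
    "feature_frame",
]


@dataclass
class FeatureConfig:
    """Thresholds and rates for feature extraction.

    fps: recording frame rate (frames/second); the velocity window spans one
    second.  bend_threshold_deg (tau_bend): deviation from 180 deg beyond
    which the posture counts as a left/right sweep.  go_velocity_threshold:
    px/frame above which the animal may be in a go phase.  go_min_frames
    (tau_go): minimal run length of go-classified frames to form a go phase.
    coil_perimeter_tol / coil_radius_tol: relative tolerances of the two
    coil tests (perimeter/spine-length near pi; mid-radius circle
    circumference near the perimeter).
    """

    fps: int = 10
    bend_threshold_deg: float = 20.0
    go_velocity_threshold: float = 1.0
    go_min_frames: int = 5
    coil_perimeter_tol: float = 0.1
    coil_radius_tol: float = 0.15
    acceleration_divisor: float = 2.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.bend_threshold_deg < 0:
            raise ValueError("bend_threshold_deg must be >= 0")
        if self.go_min_frames < 1:
            raise ValueError("go_min_frames must be >= 1")


def bending_angle(head, s_mid, tail) -> float:
    """Signed body bending gamma in degrees (180 = straight, >180 = left).

    NaN if either body vector degenerates to zero length.
    """
    head = np.asarray(head, dtype=float)
    s_mid = np.asarray(s_mid, dtype=float)
    tail = np.asarray(tail, dtype=float)
    v1 = head - s_mid
    v2 = s_mid - tail
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return float("nan")
    magnitude = math.degrees(math.acos(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)))
    cross = v2[0] * v1[1] - v2[1] * v1[0]
    return 180.0 + magnitude if cross > 0 else 180.0 - magnitude


def sweep_state(gamma: float, bend_threshold_deg: float) -> str:
    """Classify a bending angle as 'left', 'right', or 'straight'."""
    if math.isnan(gamma):
        return "straight"
    if gamma >= 180.0 + bend_threshold_deg:
        return "left"
    if gamma <= 180.0 - bend_threshold_deg:
        return "right"
    return "straight"


def spine_length(model: AnimalModel) -> float:
    """Polyline length head -> spine points -> tail, in pixels."""
    chain = np.vstack([model.head, model.spine, model.tail])
    return float(np.linalg.norm(np.diff(chain, axis=0), axis=1).sum())


def is_coiled(model: AnimalModel, config: FeatureConfig | None = None) -> bool:
    """Coil test: the outer contour approaches a circle.

    Fires when the perimeter-to-spine-length ratio reaches pi (it sits near 2
    for a straight body and grows through pi as the body curls and the
    extracted spine collapses, so the test is one-sided), or when the circle
    implied by the middle radius has a circumference close to the perimeter;
    in both cases the spine cannot represent the true midline.
    """
    config = config or FeatureConfig()
    sl = spine_length(model)
    if sl <= 0 or model.perimeter <= 0:
        return True
    perim_ratio = model.perimeter / sl
    circle_ratio = 2.0 * model.mid_radius * math.pi / model.perimeter
    return (
        perim_ratio >= math.pi * (1.0 - config.coil_perimeter_tol)
        or abs(circle_ratio - 1.0) <= config.coil_radius_tol
    )


def accumulated_distance(com_series: np.ndarray) -> np.ndarray:
    """Cumulative path length of the center of mass; 0 at the first frame."""
    com = np.asarray(com_series, dtype=float)
    steps = np.linalg.norm(np.diff(com, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def distance_to_origin(com_series: np.ndarray) -> np.ndarray:
    """Straight-line distance from the first center of mass, per frame."""
    com = np.asarray(com_series, dtype=float)
    return np.linalg.norm(com - com[0], axis=1)


def velocity_series(com_series: np.ndarray, fps: int) -> np.ndarray:
    """Central-window speed: displacement over one second divided by fps.

    ``v(t) = |m_{t-fps/2} - m_{t+fps/2}| / fps`` in px/frame; frames whose
    window reaches outside the series are NaN.
    """
    com = np.asarray(com_series, dtype=float)
    n = len(com)
    half = fps // 2
    v = np.full(n, np.nan)
    if half == 0:
        disp = np.linalg.norm(np.diff(com, axis=0), axis=1)
        v[: n - 1] = disp / max(fps, 1)
        return v
    for t in range(half, n - half):
        v[t] = np.linalg.norm(com[t - half] - com[t + half]) / fps
    return v


def acceleration_series(velocities: np.ndarray, divisor: float = 2.0) -> np.ndarray:
    """``a(t) = |v(t) - v(t+1)| / divisor``; NaN where either velocity is."""
    v = np.asarray(velocities, dtype=float)
    a = np.full(len(v), np.nan)
    if len(v) >= 2:
        a[:-1] = np.abs(v[:-1] - v[1:]) / divisor
    return a


def _runs(flags: np.ndarray):
    """Maximal runs of True as (start, stop_exclusive) intervals."""
    flags = np.asarray(flags, dtype=bool)
    out = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(flags)))
    return out


def go_phases(
    velocities: np.ndarray, gammas: np.ndarray, config: FeatureConfig
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Go-phase classification.

    A frame is raw-go when the velocity exceeds the threshold and the body is
    not strongly bent; a go phase is a run of at least ``go_min_frames``
    raw-go frames.  Returns the per-frame phase flags and the phase
    intervals; non-go frames are reorientation.
    """
    v = np.asarray(velocities, dtype=float)
    g = np.asarray(gammas, dtype=float)
    raw = (v > config.go_velocity_threshold) & (np.abs(g - 180.0) < config.bend_threshold_deg)
    raw &= ~np.isnan(v) & ~np.isnan(g)
    phases = [(s, e) for s, e in _runs(raw) if e - s >= config.go_min_frames]
    flags = np.zeros(len(v), dtype=bool)
    for s, e in phases:
        flags[s:e] = True
    return flags, phases


def feature_frame(models: list[AnimalModel], config: FeatureConfig | None = None) -> pd.DataFrame:
    """Per-frame feature table for one trajectory (frames indexed from 0).

    Columns include landmark positions (head, mid spine point, tail, center
    of mass), the primary features area and perimeter, posture features
    (bending angle, sweep flags, spine length, coiled flag) and motion
    features (accumulated distance, distance to origin, velocity,
    acceleration, go-phase flag).
    """
    config = config or FeatureConfig()
    com = np.array([m.center_of_mass for m in models], dtype=float)
    gammas = np.array([bending_angle(m.head, m.mid_spine, m.tail) for m in models])
    coiled = np.array([is_coiled(m, config) for m in models], dtype=bool)
    gammas = np.where(coiled, np.nan, gammas)  # spine unreliable when coiled
    v = velocity_series(com, config.fps)
    a = acceleration_series(v, config.acceleration_divisor)
    go_flags, _ = go_phases(v, gammas, config)
    sweeps = [sweep_state(g, config.bend_threshold_deg) for g in gammas]
    return pd.DataFrame(
        {
            "head_x": [m.head[0] for m in models],
            "head_y": [m.head[1] for m in models],
            "mid_x": [m.mid_spine[0] for m in models],
            "mid_y": [m.mid_spine[1] for m in models],
            "tail_x": [m.tail[0] for m in models],
            "tail_y": [m.tail[1] for m in models],
            "com_x": com[:, 0],
            "com_y": com[:, 1],
            "area": [m.area for m in models],
            "perimeter": [m.perimeter for m in models],
            "bending": gammas,
            "spine_length": [spine_length(m) for m in models],
            "coiled": coiled,
            "left_bended": [s == "left" for s in sweeps],
            "right_bended": [s == "right" for s in sweeps],
            "dist_accumulated": accumulated_distance(com),
            "dist_to_origin": distance_to_origin(com),
            "velocity": v,
            "acceleration": a,
            "go_phase": go_flags,
        }
    )
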