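"""Synthetic bright-on-dark crawling scenes with exact ground truth.

Each animal is a capsule: a parametric midline (tail at u=0, head at u=1)
swept with a local radius profile that is constant over the mid-body and
tapers with a half-cosine over the terminal quarter at each end.  The head
tip is tapered slightly sharper than the tail tip, so the contour exhibits
exactly two high-curvature regions with the sharper one at the head — the
assumption the curvature-based head/tail detector relies on.

The midline at frame t is built by integrating a tangent direction
``theta(u) = heading(t) + bend(t) * (W(u) - mean(W))`` along the body, where
``W`` distributes the bend uniformly (crawling, snake-like undulation,
coiling) or concentrates it near the head (head casts).  The body is then
anchored either by its width-weighted centroid (the analytic center of
mass) following a crawl path, or by a fixed tail point (head casts).

Rendering paints the union of filled disks along the midline at the body
gray level onto a near-black background with optional static artifact
blobs, then adds clipped Gaussian noise.  Ground truth (head, tail, five
interior spine points with radii, center of mass, bending angle, coiled
flag, phase label, identity) is taken from the analytic midline before
rasterization, so every downstream module can be scored without manual
labels.  Output is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

from .features import bending_angle

__all__ = [
    "AnimalSpec",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "scenario_library",
    "make_scenario",
    "analytic_area",
    "suggested_segmentation",
]

_MIDLINE_SAMPLES = 61
_N_INTERIOR = 5  # ground-truth protocol: head, tail, 5 equidistant spine points


@dataclass
class AnimalSpec:
    """Kinematics and body geometry of one synthetic animal."""

    start: tuple[float, float]
    heading_deg: float = 0.0
    body_length: float = 40.0
    width: float = 9.0
    speed: float = 0.0  # px/frame along the heading
    peristalsis_amp: float = 0.0  # relative speed modulation
    peristalsis_period: float = 12.0
    bend_amp_deg: float = 0.0
    bend_period: float = 40.0
    bend_profile: str = "uniform"  # "uniform" | "head"
    heading_wiggle_deg: float = 0.0
    heading_wiggle_period: float = 50.0
    anchor: str = "com"  # "com" | "tail"
    roll_step: float = 0.0  # lateral jump per frame, perpendicular to heading
    lateral_bump: tuple[float, float, float] | None = None  # (t_center, t_width, amp)
    coil: tuple[int, int, float] | None = None  # (start, stop, max bend deg)
    head_tip_radius: float = 0.9
    tail_tip_radius: float = 1.8
    taper_frac: float = 0.25


@dataclass
class SceneSpec:
    shape: tuple[int, int] = (512, 512)
    n_frames: int = 200
    fps: int = 10
    animals: list[AnimalSpec] = field(default_factory=list)
    background_level: int = 10
    body_level: int = 200
    noise_sd: float = 2.0
    n_artifacts: int = 2
    artifact_level: int = 55
    artifact_radius: float = 6.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-frame per-animal analytic models, tidy one row per (frame, identity)."""

    records: pd.DataFrame
    n_frames: int
    fps: int

    def animal(self, identity: int) -> pd.DataFrame:
        sub = self.records[self.records["identity"] == identity]
        return sub.sort_values("frame").reset_index(drop=True)

    def identities(self) -> list[int]:
        return sorted(self.records["identity"].unique().tolist())


def _radius_profile(u: np.ndarray, spec: AnimalSpec) -> np.ndarray:
    full = spec.width / 2.0
    r = np.full_like(u, full)
    f = spec.taper_frac
    tail_zone = u < f
    r[tail_zone] = spec.tail_tip_radius + (full - spec.tail_tip_radius) * np.sin(
        0.5 * math.pi * u[tail_zone] / f
    )
    head_zone = u > 1 - f
    r[head_zone] = spec.head_tip_radius + (full - spec.head_tip_radius) * np.sin(
        0.5 * math.pi * (1 - u[head_zone]) / f
    )
    return r


def _bend_weight(u: np.ndarray, profile: str) -> np.ndarray:
    if profile == "uniform":
        return u
    if profile == "head":
        return np.clip((u - 0.6) / 0.4, 0.0, 1.0)
    raise ValueError(f"unknown bend profile: {profile!r}")


def _bend_at(spec: AnimalSpec, t: int) -> float:
    if spec.coil is not None:
        c0, c1, amp = spec.coil
        if c0 <= t < c1:
            return amp * math.sin(math.pi * (t - c0) / max(1, c1 - c0))
    if spec.bend_amp_deg == 0:
        return 0.0
    return spec.bend_amp_deg * math.sin(2 * math.pi * t / spec.bend_period)


def _animal_states(spec: AnimalSpec, n_frames: int) -> list[dict]:
    """Analytic per-frame state: midline points, radii, landmarks, labels."""
    u = np.linspace(0.0, 1.0, _MIDLINE_SAMPLES)
    radii = _radius_profile(u, spec)
    weight = _bend_weight(u, spec.bend_profile)
    weight = weight - weight.mean()
    ds = spec.body_length / (_MIDLINE_SAMPLES - 1)

    states = []
    anchor_pos = np.asarray(spec.start, dtype=float)
    for t in range(n_frames):
        heading = spec.heading_deg
        if spec.heading_wiggle_deg:
            heading += spec.heading_wiggle_deg * math.sin(
                2 * math.pi * t / spec.heading_wiggle_period
            )
        h_rad = math.radians(heading)
        bend = _bend_at(spec, t)
        theta = h_rad + math.radians(bend) * weight
        # integrate tail -> head
        dxy = ds * np.stack([np.cos(theta[:-1]), np.sin(theta[:-1])], axis=1)
        pts = np.vstack([[0.0, 0.0], np.cumsum(dxy, axis=0)])

        com_local = (pts * radii[:, None]).sum(axis=0) / radii.sum()
        offset = np.zeros(2)
        if spec.lateral_bump is not None:
            tc, tw, amp = spec.lateral_bump
            perp = np.array([-math.sin(h_rad), math.cos(h_rad)])
            offset = amp * math.exp(-(((t - tc) / tw) ** 2)) * perp
        if spec.anchor == "tail":
            pts = pts - pts[0] + anchor_pos + offset
        else:
            pts = pts - com_local + anchor_pos + offset

        speed_t = spec.speed
        if spec.peristalsis_amp:
            speed_t *= 1.0 + spec.peristalsis_amp * math.sin(
                2 * math.pi * t / spec.peristalsis_period
            )
        speed_t = max(0.0, speed_t)

        coiled = abs(bend) >= 270.0
        phase = "go" if (speed_t > 1.0 and abs(bend) < 20.0) else "stop"

        # landmarks: interior spine points equidistant in arc, head side first
        interior_idx = [
            round((1 - j / (_N_INTERIOR + 1)) * (_MIDLINE_SAMPLES - 1))
            for j in range(1, _N_INTERIOR + 1)
        ]
        states.append(
            {
                "points": pts,
                "radii": radii,
                "head": pts[-1].copy(),
                "tail": pts[0].copy(),
                "spine": pts[interior_idx].copy(),
                "spine_radii": radii[interior_idx].copy(),
                "com": (pts * radii[:, None]).sum(axis=0) / radii.sum(),
                "coiled": coiled,
                "phase": phase,
            }
        )

        # advance the anchor point
        step = speed_t * np.array([math.cos(h_rad), math.sin(h_rad)])
        if spec.roll_step:
            step = step + spec.roll_step * np.array([-math.sin(h_rad), math.cos(h_rad)])
        anchor_pos = anchor_pos + step
    return states


def _draw_animal(canvas: np.ndarray, state: dict, level: int) -> None:
    for (x, y), r in zip(state["points"], state["radii"]):
        rr, cc = _disk((y, x), max(r, 0.6), shape=canvas.shape)
        canvas[rr, cc] = level


def _place_artifacts(spec: SceneSpec, states_per_animal, rng) -> list[tuple[float, float]]:
    h, w = spec.shape
    coms = np.array(
        [st["com"] for states in states_per_animal for st in states]
    ) if states_per_animal else np.empty((0, 2))
    keep_away = max((a.body_length for a in spec.animals), default=40.0) * 1.5
    centers = []
    for _ in range(spec.n_artifacts):
        for _attempt in range(200):
            x = rng.uniform(spec.artifact_radius + 2, w - spec.artifact_radius - 2)
            y = rng.uniform(spec.artifact_radius + 2, h - spec.artifact_radius - 2)
            if coms.size == 0 or np.linalg.norm(coms - [x, y], axis=1).min() > keep_away:
                centers.append((x, y))
                break
    return centers


def render_scene(spec: SceneSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Render a scene to 8-bit frames plus analytic ground truth."""
    rng = np.random.default_rng(spec.seed)
    states_per_animal = [_animal_states(a, spec.n_frames) for a in spec.animals]
    artifacts = _place_artifacts(spec, states_per_animal, rng)

    static = np.full(spec.shape, float(spec.background_level))
    for x, y in artifacts:
        rr, cc = _disk((y, x), spec.artifact_radius, shape=spec.shape)
        static[rr, cc] = spec.artifact_level

    frames: list[np.ndarray] = []
    rows = []
    for t in range(spec.n_frames):
        canvas = static.copy()
        for identity, states in enumerate(states_per_animal):
            _draw_animal(canvas, states[t], spec.body_level)
        if spec.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, spec.noise_sd, spec.shape)
        frames.append(np.clip(canvas, 0, 255).astype(np.uint8))

        for identity, states in enumerate(states_per_animal):
            st = states[t]
            mid = st["spine"][(_N_INTERIOR - 1) // 2]
            row = {
                "frame": t,
                "identity": identity,
                "head_x": st["head"][0],
                "head_y": st["head"][1],
                "tail_x": st["tail"][0],
                "tail_y": st["tail"][1],
                "mid_x": mid[0],
                "mid_y": mid[1],
                "com_x": st["com"][0],
                "com_y": st["com"][1],
                "bending": bending_angle(st["head"], mid, st["tail"]),
                "coiled": st["coiled"],
                "phase": st["phase"],
            }
            for j in range(_N_INTERIOR):
                row[f"spine{j + 1}_x"] = st["spine"][j, 0]
                row[f"spine{j + 1}_y"] = st["spine"][j, 1]
                row[f"radius{j + 1}"] = st["spine_radii"][j]
            rows.append(row)
    truth = GroundTruth(records=pd.DataFrame(rows), n_frames=spec.n_frames, fps=spec.fps)
    return frames, truth


def analytic_area(spec: AnimalSpec) -> float:
    """Area of the swept capsule: integral of the local width plus end caps."""
    u = np.linspace(0.0, 1.0, 2001)
    r = _radius_profile(u, spec)
    ds = spec.body_length / (len(u) - 1)
    body = float(np.trapezoid(2 * r, dx=ds))
    caps = 0.5 * math.pi * (spec.head_tip_radius**2 + spec.tail_tip_radius**2)
    return body + caps


def suggested_segmentation(spec: SceneSpec):
    """Segmentation thresholds matched to a scene's geometry and contrast."""
    from .segmentation import SegmentationConfig

    areas = [analytic_area(a) for a in spec.animals]
    tau = max(20, (spec.body_level - spec.artifact_level) // 2)
    return SegmentationConfig(
        gray_threshold=tau,
        area_min=max(10, int(0.5 * min(areas))),
        area_max=int(1.6 * max(areas)),
    )


def make_scenario(name: str, seed: int = 0, n_frames: int | None = None) -> SceneSpec:
    """Named study conditions covering the qualitatively distinct motion types."""
    if name == "forward_crawl":
        lanes = [70, 160, 250, 340, 430]
        animals = [
            AnimalSpec(
                start=(60.0, float(y)),
                heading_deg=hd,
                speed=1.2,
                peristalsis_amp=0.4,
                peristalsis_period=12,
                bend_amp_deg=12.0,
                bend_period=40 + 6 * k,
                heading_wiggle_deg=6.0,
                heading_wiggle_period=60 + 10 * k,
            )
            for k, (y, hd) in enumerate(zip(lanes, (-4.0, 2.0, 0.0, 3.0, -2.0)))
        ]
        spec = SceneSpec(animals=animals, n_frames=200, seed=seed)
    elif name == "rolling":
        animals = [
            AnimalSpec(start=(80.0, 60.0), heading_deg=0.0, body_length=30.0, roll_step=35.0),
            AnimalSpec(start=(330.0, 60.0), heading_deg=0.0, body_length=30.0, roll_step=35.0),
        ]
        spec = SceneSpec(animals=animals, n_frames=12, seed=seed)
    elif name == "snake":
        animals = [
            AnimalSpec(
                start=(70.0, 256.0),
                heading_deg=0.0,
                body_length=50.0,
                width=6.0,
                speed=1.5,
                bend_amp_deg=60.0,
                bend_period=16,
            )
        ]
        spec = SceneSpec(animals=animals, n_frames=100, seed=seed)
    elif name == "collision":
        animals = [
            AnimalSpec(start=(100.0, 238.0), heading_deg=0.0, speed=1.5,
                       lateral_bump=(50.0, 10.0, 16.0)),
            AnimalSpec(start=(100.0, 274.0), heading_deg=0.0, speed=1.5,
                       lateral_bump=(50.0, 10.0, -16.0)),
        ]
        spec = SceneSpec(animals=animals, n_frames=100, seed=seed)
    elif name == "coiling":
        animals = [
            AnimalSpec(start=(256.0, 256.0), heading_deg=0.0, speed=0.3,
                       coil=(30, 70, 330.0))
        ]
        spec = SceneSpec(animals=animals, n_frames=100, seed=seed)
    elif name == "headcast":
        animals = [
            AnimalSpec(
                start=(220.0, 256.0),
                heading_deg=0.0,
                anchor="tail",
                speed=0.0,
                bend_amp_deg=45.0,
                bend_period=30,
                bend_profile="head",
            )
        ]
        spec = SceneSpec(animals=animals, n_frames=120, seed=seed)
    else:
        raise ValueError(f"unknown scenario: {name!r}")
    if n_frames is not None:
        spec.n_frames = n_frames
    return spec


def scenario_library() -> dict[str, SceneSpec]:
    """All named scenarios at their default sizes (seed 0)."""
    names = ["forward_crawl", "rolling", "snake", "collision", "coiling", "headcast"]
    return {name: make_scenario(name) for name in names}
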