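"""Contour-based posture model: head, tail, discrete spine and local radii.

Each filtered contour is reduced to a landmark chain
``(h, (s_1, r_1), ..., (s_{L-2}, r_{L-2}), t, m)``:

1. per-point curvature angles via the first pass of the IPAN corner detector
   (admissible triangles with arm lengths in ``[d_min, d_max]``, keeping the
   sharpest admissible angle at each point);
2. head and tail as the centres of the two sliding windows with the smallest
   mean angle, at least ``delta`` contour indices apart (head = sharpest;
   this orientation is provisional and owned by the postprocess stage);
3. the contour is split at head and tail into two open halves, the longer
   half resampled by linear interpolation to the shorter one's point count,
   giving paired opposite boundary points ``(p1_j, p2_j)``;
4. spine points are midpoints of L-2 pairs taken at arc-length-equidistant
   positions along the shorter half (endpoints excluded), radii are half the
   pair distances, and the center of mass m is the pixel centroid of the
   enclosed region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d

from .segmentation import Contour

__all__ = [
    "ModelConfig",
    "AnimalModel",
    "contour_curvature",
    "locate_head_tail",
    "split_and_resample",
    "resample_polyline",
    "build_model",
]


@dataclass
class ModelConfig:
    """Spine-extraction parameters.

    ``n_spine_points`` is the total landmark count L including head and tail
    (the default 7 yields 5 interior spine points).  ``curvature_window`` is
    the half-width w of the sliding mean window (window size 2w+1).
    ``head_tail_min_separation_frac`` is the minimal circular index distance
    between head and tail, as a fraction of the contour point count.
    ``curvature_arm_min``/``max`` are the IPAN triangle arm lengths in contour
    points for a 100-point contour; they scale with contour length and are
    clamped to be at least 2.
    """

    n_spine_points: int = 7
    curvature_window: int = 2
    head_tail_min_separation_frac: float = 0.25
    curvature_arm_min: int = 4
    curvature_arm_max: int = 7

    def __post_init__(self) -> None:
        if self.n_spine_points < 3:
            raise ValueError("n_spine_points must be >= 3")
        if self.curvature_window < 1:
            raise ValueError("curvature_window must be >= 1")
        if not 0 < self.head_tail_min_separation_frac < 1:
            raise ValueError("head_tail_min_separation_frac must be in (0, 1)")

    def arm_lengths(self, n_points: int) -> tuple[int, int]:
        scale = n_points / 100.0
        d_min = max(2, int(round(self.curvature_arm_min * scale)))
        d_max = max(d_min + 1, int(round(self.curvature_arm_max * scale)))
        # arms must stay well inside the closed chain
        d_max = min(d_max, max(2, (n_points - 1) // 2))
        d_min = min(d_min, d_max - 1) if d_max > 2 else min(d_min, d_max)
        return max(1, d_min), d_max


@dataclass
class AnimalModel:
    """Landmark representation of one animal in one frame."""

    head: np.ndarray
    tail: np.ndarray
    spine: np.ndarray  # (L-2, 2), ordered head side -> tail side
    radii: np.ndarray  # (L-2,), local half-widths
    center_of_mass: np.ndarray
    area: int
    perimeter: float
    contour: Contour = field(repr=False)

    @property
    def mid_index(self) -> int:
        # 1-based ceil((L-2)/2), ties to the lower index -> 0-based:
        return (len(self.spine) - 1) // 2

    @property
    def mid_spine(self) -> np.ndarray:
        return self.spine[self.mid_index]

    @property
    def mid_radius(self) -> float:
        return float(self.radii[self.mid_index])

    def landmarks(self) -> np.ndarray:
        """All model points: head, spine points, tail, center of mass."""
        return np.vstack([self.head, self.spine, self.tail, self.center_of_mass])

    def flipped(self) -> "AnimalModel":
        """Head/tail swap: spine and radii reverse; contour-derived fields untouched."""
        return replace(
            self,
            head=self.tail.copy(),
            tail=self.head.copy(),
            spine=self.spine[::-1].copy(),
            radii=self.radii[::-1].copy(),
        )


def _normalize_ccw(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    signed = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return pts if signed >= 0 else pts[::-1].copy()


def contour_curvature(contour: Contour, config: ModelConfig | None = None) -> np.ndarray:
    """Sharpest admissible IPAN triangle angle (degrees) at every contour point.

    Small angles mark sharp protrusions; points on straight stretches give
    angles near 180 degrees.
    """
    config = config or ModelConfig()
    pts = np.asarray(contour.points, dtype=float)
    n = len(pts)
    d_min, d_max = config.arm_lengths(n)
    if n < 2 * d_max + 1:
        raise ValueError(f"contour with {n} points too short for arm length {d_max}")
    best = np.full(n, 180.0)
    for a in range(d_min, d_max + 1):
        u = np.roll(pts, a, axis=0) - pts  # towards p_{i-a}
        nu = np.linalg.norm(u, axis=1)
        for b in range(d_min, d_max + 1):
            v = np.roll(pts, -b, axis=0) - pts  # towards p_{i+b}
            nv = np.linalg.norm(v, axis=1)
            denom = np.where(nu * nv > 0, nu * nv, 1.0)
            cosang = np.clip((u * v).sum(axis=1) / denom, -1.0, 1.0)
            ang = np.degrees(np.arccos(cosang))
            ang[nu * nv == 0] = 180.0  # degenerate arm: no curvature evidence
            np.minimum(best, ang, out=best)
    return best


def locate_head_tail(
    contour: Contour, curvatures: np.ndarray, config: ModelConfig | None = None
) -> tuple[int, int]:
    """Indices of the two sharpest curvature windows (head first).

    Window means are taken circularly over 2w+1 points; the head is the
    centre of the globally sharpest window, the tail the sharpest among
    centres at circular distance >= delta from the head.
    """
    config = config or ModelConfig()
    curv = np.asarray(curvatures, dtype=float)
    n = len(curv)
    window = 2 * config.curvature_window + 1
    mean_angle = uniform_filter1d(curv, size=window, mode="wrap")
    head = int(np.argmin(mean_angle))
    delta = max(1, int(round(config.head_tail_min_separation_frac * n)))
    idx = np.arange(n)
    circ = np.minimum(np.abs(idx - head), n - np.abs(idx - head))
    admissible = circ >= delta
    if not admissible.any():
        raise ValueError("no tail candidate at the required separation from the head")
    masked = np.where(admissible, mean_angle, np.inf)
    tail = int(np.argmin(masked))
    return head, tail


def resample_polyline(points, n_out: int) -> np.ndarray:
    """Resample an open polyline to ``n_out`` points, uniform in arc length."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        return np.repeat(pts, n_out, axis=0)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(pts[:1], n_out, axis=0)
    t = np.linspace(0.0, s[-1], n_out)
    return np.stack([np.interp(t, s, pts[:, 0]), np.interp(t, s, pts[:, 1])], axis=1)


def _split_halves(points: np.ndarray, head_index: int, tail_index: int):
    n = len(points)
    if head_index == tail_index:
        raise ValueError("head and tail indices coincide")
    fwd_idx = np.arange(head_index, head_index + (tail_index - head_index) % n + 1) % n
    bwd_idx = np.arange(head_index, head_index - (head_index - tail_index) % n - 1, -1) % n
    return points[fwd_idx], points[bwd_idx]


def split_and_resample(
    contour: Contour, head_index: int, tail_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split the contour at head/tail into two equal-length point chains.

    Both returned chains run from the head point to the tail point; the
    longer chain is linearly resampled to the shorter one's point count so
    that chain points pair off one-to-one across the body.
    """
    pts = np.asarray(contour.points, dtype=float)
    half1, half2 = _split_halves(pts, head_index, tail_index)
    m = min(len(half1), len(half2))
    if len(half1) > m:
        half1 = resample_polyline(half1, m)
    if len(half2) > m:
        half2 = resample_polyline(half2, m)
    return half1, half2


def build_model(contour: Contour, config: ModelConfig | None = None) -> AnimalModel:
    """Full posture extraction for a single contour."""
    config = config or ModelConfig()
    normalized = replace(contour, points=np.rint(_normalize_ccw(contour.points)).astype(np.int64))
    curv = contour_curvature(normalized, config)
    head_idx, tail_idx = locate_head_tail(normalized, curv, config)
    pts = np.asarray(normalized.points, dtype=float)
    half1, half2 = _split_halves(pts, head_idx, tail_idx)
    shorter, longer = (half1, half2) if len(half1) <= len(half2) else (half2, half1)
    m = len(shorter)
    if m < 3:
        raise ValueError("degenerate split: halves too short for interior spine points")
    longer = resample_polyline(longer, m)

    # arc-length-equidistant positions along the shorter half, endpoints excluded
    seg = np.linalg.norm(np.diff(shorter, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    L = config.n_spine_points
    spine = np.empty((L - 2, 2))
    radii = np.empty(L - 2)
    for j in range(1, L - 1):
        target = total * j / (L - 1)
        idx = int(np.searchsorted(s, target, side="right")) - 1  # floor tie-break
        idx = min(max(idx, 1), m - 2)
        p1, p2 = shorter[idx], longer[idx]
        spine[j - 1] = (p1 + p2) / 2.0
        radii[j - 1] = np.linalg.norm(p2 - p1) / 2.0

    return AnimalModel(
        head=pts[head_idx].copy(),
        tail=pts[tail_idx].copy(),
        spine=spine,
        radii=radii,
        center_of_mass=normalized.centroid().astype(float),
        area=contour.area,
        perimeter=contour.perimeter,
        contour=contour,
    )
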