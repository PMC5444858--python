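"""Stimulus-marker geometry: nearest point, distance, bearing, region tests.

Markers live in the image pixel coordinate frame.  Four kinds are
supported: a point, a straight line segment, an axis-aligned rectangle and
an axis-aligned ellipse.  For each animal and frame the derived features
are the Euclidean distance between the animal's center of mass and the
nearest marker point, the bearing angle at the tail between the
tail-to-center vector and the tail-to-marker vector (the tail is used
because it is unaffected by head casts), and a region-membership flag.

The ellipse nearest point is the standard approximation: the line through
the query point and the ellipse centre is intersected with the boundary and
the nearer intersection taken (the exact solution needs a quartic and the
approximation error is negligible at moderate eccentricity).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusMarker",
    "point_marker",
    "line_marker",
    "rectangle_marker",
    "ellipse_marker",
    "nearest_point",
    "stimulus_distance",
    "bearing_angle",
    "in_region",
]

_KINDS = {"point", "line", "rectangle", "ellipse"}


@dataclass
class StimulusMarker:
    kind: str
    params: dict = field(default_factory=dict)
    id: str = "stimulus"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown marker kind: {self.kind!r}")
        if self.kind == "rectangle":
            x0, y0, x1, y1 = self.params["bounds"]
            if not (x0 <= x1 and y0 <= y1):
                raise ValueError("rectangle bounds must be ordered (x_min,y_min,x_max,y_max)")
        if self.kind == "ellipse" and (self.params["a"] <= 0 or self.params["b"] <= 0):
            raise ValueError("ellipse semi-axes must be positive")


def point_marker(x: float, y: float, id: str = "point") -> StimulusMarker:
    return StimulusMarker("point", {"point": (float(x), float(y))}, id)


def line_marker(p0, p1, id: str = "line") -> StimulusMarker:
    return StimulusMarker("line", {"p0": tuple(map(float, p0)), "p1": tuple(map(float, p1))}, id)


def rectangle_marker(x_min, y_min, x_max, y_max, id: str = "rect") -> StimulusMarker:
    return StimulusMarker("rectangle", {"bounds": (float(x_min), float(y_min), float(x_max), float(y_max))}, id)


def ellipse_marker(cx, cy, a, b, id: str = "ellipse") -> StimulusMarker:
    return StimulusMarker("ellipse", {"c": (float(cx), float(cy)), "a": float(a), "b": float(b)}, id)


def _project_to_segment(p0: np.ndarray, p1: np.ndarray, m: np.ndarray) -> np.ndarray:
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        return p0
    u = float((m - p0) @ d) / denom
    proj = p0 + u * d
    if 0 <= u <= 1:
        return proj
    # off-segment: take the endpoint nearer to the projected point
    return p0 if np.linalg.norm(proj - p0) <= np.linalg.norm(proj - p1) else p1


def nearest_point(marker: StimulusMarker, m) -> np.ndarray:
    """Nearest marker point to ``m`` (for the ellipse: centre-line approximation)."""
    m = np.asarray(m, dtype=float)
    if marker.kind == "point":
        return np.asarray(marker.params["point"], dtype=float)
    if marker.kind == "line":
        p0 = np.asarray(marker.params["p0"], dtype=float)
        p1 = np.asarray(marker.params["p1"], dtype=float)
        return _project_to_segment(p0, p1, m)
    if marker.kind == "rectangle":
        x0, y0, x1, y1 = marker.params["bounds"]
        corners = [
            (np.array([x0, y0]), np.array([x1, y0])),
            (np.array([x1, y0]), np.array([x1, y1])),
            (np.array([x1, y1]), np.array([x0, y1])),
            (np.array([x0, y1]), np.array([x0, y0])),
        ]
        candidates = [_project_to_segment(a, b, m) for a, b in corners]
        dists = [np.linalg.norm(m - c) for c in candidates]
        return candidates[int(np.argmin(dists))]
    # ellipse
    c = np.asarray(marker.params["c"], dtype=float)
    a, b = marker.params["a"], marker.params["b"]
    d = m - c
    if np.linalg.norm(d) == 0:
        warnings.warn("query point at ellipse centre; returning the +x boundary point")
        return c + np.array([a, 0.0])
    # scale so the ellipse becomes the unit circle, intersect the ray, scale back
    scale = np.array([a, b])
    u = d / scale
    candidates = [c + (s * u / np.linalg.norm(u)) * scale for s in (1.0, -1.0)]
    dists = [np.linalg.norm(m - p) for p in candidates]
    return candidates[int(np.argmin(dists))]


def stimulus_distance(marker: StimulusMarker, m) -> float:
    """Euclidean distance from ``m`` to the nearest marker point."""
    return float(np.linalg.norm(np.asarray(m, dtype=float) - nearest_point(marker, m)))


def bearing_angle(m, tail, p) -> float:
    """Unsigned angle (degrees, [0, 180]) at the tail between body and marker.

    ``v1 = m - tail`` and ``v2 = p - tail``; NaN on degenerate vectors.
    """
    m = np.asarray(m, dtype=float)
    tail = np.asarray(tail, dtype=float)
    p = np.asarray(p, dtype=float)
    v1 = m - tail
    v2 = p - tail
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return float("nan")
    return math.degrees(math.acos(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)))


def in_region(marker: StimulusMarker, m, line_tol: float = 0.5) -> bool:
    """Closed-region membership of ``m``."""
    m = np.asarray(m, dtype=float)
    if marker.kind == "point":
        return bool(np.allclose(m, marker.params["point"]))
    if marker.kind == "line":
        return stimulus_distance(marker, m) <= line_tol
    if marker.kind == "rectangle":
        x0, y0, x1, y1 = marker.params["bounds"]
        return bool(x0 <= m[0] <= x1 and y0 <= m[1] <= y1)
    c = np.asarray(marker.params["c"], dtype=float)
    a, b = marker.params["a"], marker.params["b"]
    d = (m - c) / np.array([a, b])
    return bool(d @ d <= 1.0)
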