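"""Frame-to-frame association of animal models into trajectories.

Association between the animals of consecutive frames is a bipartite
matching on an ``N_t x N_{t+1}`` cost matrix.  Three cost measurements are
supported: Euclidean distance between centers of mass (smooth, contour
derived), Euclidean distance between middle spine points (inside the body,
more jitter), and the contour overlap in pixels (a similarity: higher is
better).  Two solvers are supported: the optimal Hungarian assignment, with
a subsequent inside-contour plausibility check that terminates implausible
matches, and a sequential greedy matcher gated by a threshold ``tau_greedy``
(maximal distance, or minimal overlap for the overlap cost).

Animals that lose their match terminate; unmatched detections spawn new
identities from a monotone counter (identities are never recycled, and
collisions are not resolved — merged contours exceed the area band, the
participating trajectories end, and the animals re-appear under new ids).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import AnimalModel, ModelConfig, build_model
from .segmentation import (
    SegmentationConfig,
    compute_background,
    extract_foreground,
    filter_contours,
    find_contours,
)

__all__ = [
    "CostMethod",
    "Solver",
    "TrackingConfig",
    "Trajectory",
    "pairwise_cost",
    "cost_matrix",
    "solve_hungarian",
    "solve_greedy",
    "validate_assignment",
    "extract_models",
    "track_sequence",
]

logger = logging.getLogger(__name__)


class CostMethod(str, Enum):
    CENTER_OF_MASS = "com"
    MID_SPINE = "mid"
    CONTOUR_OVERLAP = "overlap"


class Solver(str, Enum):
    HUNGARIAN = "hungarian"
    GREEDY = "greedy"


@dataclass
class TrackingConfig:
    cost_method: CostMethod = CostMethod.CONTOUR_OVERLAP
    solver: Solver = Solver.HUNGARIAN
    greedy_threshold: float = 50.0  # px for distance costs, px^2 for overlap

    def __post_init__(self) -> None:
        self.cost_method = CostMethod(self.cost_method)
        self.solver = Solver(self.solver)
        if self.solver is Solver.GREEDY and self.greedy_threshold <= 0:
            raise ValueError("greedy_threshold must be > 0 for the greedy solver")


@dataclass
class Trajectory:
    """Gap-free sequence of models for one identity, frames ``start`` .. ``start+len-1``."""

    id: int
    start_frame: int
    models: list[AnimalModel] = field(default_factory=list)
    active: bool = True

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.models) - 1

    def frames(self) -> range:
        return range(self.start_frame, self.end_frame + 1)

    def model_at(self, frame: int) -> AnimalModel:
        return self.models[frame - self.start_frame]


def pairwise_cost(a: AnimalModel, b: AnimalModel, method: CostMethod) -> float:
    method = CostMethod(method)
    if method is CostMethod.CENTER_OF_MASS:
        return float(np.linalg.norm(a.center_of_mass - b.center_of_mass))
    if method is CostMethod.MID_SPINE:
        return float(np.linalg.norm(a.mid_spine - b.mid_spine))
    if method is CostMethod.CONTOUR_OVERLAP:
        return float(
            np.intersect1d(a.contour.pixel_keys(), b.contour.pixel_keys()).size
        )
    raise ValueError(f"unknown cost method: {method}")


def cost_matrix(models_t, models_next, method: CostMethod) -> np.ndarray:
    values = np.empty((len(models_t), len(models_next)))
    for i, a in enumerate(models_t):
        for j, b in enumerate(models_next):
            values[i, j] = pairwise_cost(a, b, method)
    return values


def solve_hungarian(costs: np.ndarray, maximize: bool = False) -> list[tuple[int, int]]:
    """Optimal bipartite assignment of ``min(N_t, N_{t+1})`` pairs."""
    costs = np.asarray(costs, dtype=float)
    if costs.size == 0:
        return []
    rows, cols = linear_sum_assignment(costs, maximize=maximize)
    return list(zip(rows.tolist(), cols.tolist()))


def solve_greedy(
    costs: np.ndarray, config: TrackingConfig, maximize: bool | None = None
) -> list[tuple[int, int]]:
    """Sequential best-first matching gated by ``tau_greedy``.

    Rows are visited in ascending index order; each takes its best unclaimed
    column (ties to the lower column index).  Distance pairs are accepted only
    below the threshold, overlap pairs only above it.
    """
    costs = np.asarray(costs, dtype=float)
    if maximize is None:
        maximize = CostMethod(config.cost_method) is CostMethod.CONTOUR_OVERLAP
    pairs: list[tuple[int, int]] = []
    taken: set[int] = set()
    for i in range(costs.shape[0]):
        best_j, best_c = -1, None
        for j in range(costs.shape[1]):
            if j in taken:
                continue
            c = costs[i, j]
            if best_c is None or (c > best_c if maximize else c < best_c):
                best_j, best_c = j, c
        if best_j < 0:
            continue
        ok = best_c >= config.greedy_threshold if maximize else best_c <= config.greedy_threshold
        if ok:
            pairs.append((i, best_j))
            taken.add(best_j)
    return pairs


def validate_assignment(a: AnimalModel, b: AnimalModel) -> bool:
    """True iff at least one landmark of ``a`` lies inside or on ``b``'s contour."""
    return bool(b.contour.contains_points(a.landmarks()).any())


def extract_models(
    frame: np.ndarray,
    background: np.ndarray,
    seg_config: SegmentationConfig,
    model_config: ModelConfig,
) -> list[AnimalModel]:
    """Segment one frame and build a model per filtered contour.

    Contours whose posture extraction degenerates (too few boundary points
    for the curvature triangles) are dropped with a debug log entry.
    """
    foreground = extract_foreground(frame, background, seg_config)
    contours = filter_contours(find_contours(foreground), seg_config)
    models = []
    for contour in contours:
        try:
            models.append(build_model(contour, model_config))
        except ValueError as exc:
            logger.debug("dropping contour (area %d): %s", contour.area, exc)
    return models


def _assign(models_t, models_next, config: TrackingConfig) -> list[tuple[int, int]]:
    maximize = CostMethod(config.cost_method) is CostMethod.CONTOUR_OVERLAP
    costs = cost_matrix(models_t, models_next, config.cost_method)
    if Solver(config.solver) is Solver.HUNGARIAN:
        pairs = solve_hungarian(costs, maximize=maximize)
        accepted = []
        for i, j in pairs:
            if maximize and costs[i, j] <= 0:
                continue  # zero overlap: implausible outright
            if validate_assignment(models_t[i], models_next[j]):
                accepted.append((i, j))
        return accepted
    return solve_greedy(costs, config, maximize=maximize)


def track_sequence(
    frames,
    seg_config: SegmentationConfig | None = None,
    model_config: ModelConfig | None = None,
    tracking_config: TrackingConfig | None = None,
    background: np.ndarray | None = None,
) -> list[Trajectory]:
    """Run segmentation, model extraction and association over a sequence.

    Returns all trajectories ever spawned (active and terminated); every
    model of every frame belongs to exactly one trajectory and identities
    never merge.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    seg_config = seg_config or SegmentationConfig()
    model_config = model_config or ModelConfig()
    tracking_config = tracking_config or TrackingConfig()
    if background is None:
        background = compute_background(frames, stride=seg_config.background_stride)

    trajectories: list[Trajectory] = []
    active: list[Trajectory] = []
    next_id = 0
    for t, frame in enumerate(frames):
        models = extract_models(frame, background, seg_config, model_config)
        if not active:
            matches: list[tuple[int, int]] = []
        else:
            prev_models = [traj.models[-1] for traj in active]
            matches = _assign(prev_models, models, tracking_config)
        matched_rows = {i for i, _ in matches}
        matched_cols = {j for _, j in matches}
        for i, j in matches:
            active[i].models.append(models[j])
        terminated = [traj for i, traj in enumerate(active) if i not in matched_rows]
        for traj in terminated:
            traj.active = False
        active = [traj for i, traj in enumerate(active) if i in matched_rows]
        spawned = 0
        for j, model in enumerate(models):
            if j not in matched_cols:
                traj = Trajectory(id=next_id, start_frame=t, models=[model])
                next_id += 1
                trajectories.append(traj)
                active.append(traj)
                spawned += 1
        if terminated or spawned:
            logger.info(
                "frame %d: %d animals, %d matched, %d terminated, %d spawned",
                t, len(models), len(matches), len(terminated), spawned,
            )
    return trajectories
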