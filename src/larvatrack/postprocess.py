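"""Trajectory-level head/tail correction.

The per-frame head/tail assignment rests on curvature sharpness alone and
can alternate between frames.  Over a whole trajectory two behavioural
regularities disambiguate the orientation:

* locomotion conformity — during forward crawling the vector from the body
  midpoint to the head points along the direction of travel;
* bending conformity — during reorientation (low speed) the head end moves
  while the tail end stays put.

Both are turned into per-segment vote fractions on maximal coil-free runs
of frames; their mean is the probability that the current head label is
correct, and a segment is flipped (head/tail swapped, spine and radii
reversed) when it falls below the flip threshold.  Within each segment the
labels are first made temporally consistent by assigning each frame's head
to the endpoint nearest the previous frame's head, so the vote judges one
coherent labelling rather than a per-frame mixture.  Contour-derived
quantities (center of mass, area, perimeter) are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureConfig, velocity_series
from .tracking import Trajectory

__all__ = [
    "OrientationVote",
    "PostprocessConfig",
    "uncoiled_segments",
    "orientation_probability",
    "apply_orientation",
    "anchor_landmarks",
    "postprocess_trajectory",
]


@dataclass
class OrientationVote:
    locomotion_score: float
    bending_score: float
    combined: float


@dataclass
class PostprocessConfig:
    orientation_min_segment: int = 2
    orientation_flip_threshold: float = 0.5
    locomotion_weight: float = 1.0
    bending_weight: float = 1.0


def uncoiled_segments(n_frames: int, coiled_flags) -> list[tuple[int, int]]:
    """Maximal (start, stop_exclusive) runs of coil-free frames."""
    flags = np.asarray(coiled_flags, dtype=bool)
    if len(flags) != n_frames:
        raise ValueError("coiled flags not aligned with trajectory")
    out = []
    start = None
    for i, coiled in enumerate(flags):
        if not coiled and start is None:
            start = i
        elif coiled and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, n_frames))
    return out


def orientation_probability(
    models: list,
    feature_config: FeatureConfig | None = None,
    config: PostprocessConfig | None = None,
) -> OrientationVote:
    """Probability that the current head label of a segment is correct.

    Segments shorter than two frames get a neutral 0.5 vote.  The bending
    score only counts low-velocity frames (speed below the go threshold,
    i.e. reorientations); when no such frames exist only the locomotion
    score contributes.
    """
    feature_config = feature_config or FeatureConfig()
    config = config or PostprocessConfig()
    if len(models) < 2:
        return OrientationVote(0.5, 0.5, 0.5)
    com = np.array([m.center_of_mass for m in models], dtype=float)
    heads = np.array([m.head for m in models], dtype=float)
    tails = np.array([m.tail for m in models], dtype=float)
    mids = np.array([m.mid_spine for m in models], dtype=float)

    disp = np.diff(com, axis=0)
    moving = np.linalg.norm(disp, axis=1) > 0
    loco_votes = ((heads[:-1] - mids[:-1]) * disp).sum(axis=1)[moving] > 0
    loco = float(loco_votes.mean()) if loco_votes.size else None

    v = velocity_series(com, feature_config.fps)
    slow = np.zeros(len(models) - 1, dtype=bool)
    defined = ~np.isnan(v[:-1])
    slow[defined] = v[:-1][defined] < feature_config.go_velocity_threshold
    head_step = np.linalg.norm(np.diff(heads, axis=0), axis=1)
    tail_step = np.linalg.norm(np.diff(tails, axis=0), axis=1)
    informative = slow & (head_step != tail_step)  # ties carry no orientation signal
    bend_votes = (head_step > tail_step)[informative]
    bend = float(bend_votes.mean()) if bend_votes.size else None

    scores, weights = [], []
    if loco is not None:
        scores.append(loco)
        weights.append(config.locomotion_weight)
    if bend is not None:
        scores.append(bend)
        weights.append(config.bending_weight)
    combined = float(np.average(scores, weights=weights)) if scores else 0.5
    return OrientationVote(
        locomotion_score=loco if loco is not None else 0.5,
        bending_score=bend if bend is not None else 0.5,
        combined=combined,
    )


def apply_orientation(traj: Trajectory, flip_intervals) -> Trajectory:
    """Swap head/tail (reversing spine and radii) inside the given intervals.

    Intervals are (start, stop_exclusive) in trajectory-local frame offsets.
    Involutive: applying the same intervals twice restores the input.
    """
    for start, stop in flip_intervals:
        if not (0 <= start <= stop <= len(traj.models)):
            raise ValueError(f"flip interval ({start}, {stop}) outside trajectory")
        for k in range(start, stop):
            traj.models[k] = traj.models[k].flipped()
    return traj


def anchor_landmarks(traj: Trajectory, start: int = 0, stop: int | None = None) -> Trajectory:
    """Propagate head identity by nearest-predecessor matching.

    From ``start`` onwards each frame's head label goes to whichever current
    endpoint lies closer to the previous frame's head, suppressing isolated
    curvature-driven switches.
    """
    stop = len(traj.models) if stop is None else stop
    for k in range(start + 1, stop):
        prev_head = traj.models[k - 1].head
        m = traj.models[k]
        if np.linalg.norm(m.head - prev_head) > np.linalg.norm(m.tail - prev_head):
            traj.models[k] = m.flipped()
    return traj


def postprocess_trajectory(
    traj: Trajectory,
    coiled_flags,
    feature_config: FeatureConfig | None = None,
    config: PostprocessConfig | None = None,
) -> Trajectory:
    """Full orientation correction for one trajectory.

    Per coil-free segment: stabilise labels by anchoring, vote, flip the
    whole segment if the vote falls below the threshold.  Coiled frames
    between segments inherit the orientation of the preceding segment (the
    spine is unreliable there anyway).  Idempotent.
    """
    feature_config = feature_config or FeatureConfig()
    config = config or PostprocessConfig()
    segments = uncoiled_segments(len(traj.models), coiled_flags)
    for start, stop in segments:
        anchor_landmarks(traj, start, stop)
        if stop - start < config.orientation_min_segment:
            continue
        vote = orientation_probability(traj.models[start:stop], feature_config, config)
        if vote.combined < config.orientation_flip_threshold:
            apply_orientation(traj, [(start, stop)])
    # coiled gaps follow the preceding oriented frame
    for start, stop in segments:
        for k in range(stop, len(traj.models)):
            if not coiled_flags[k]:
                break
            m = traj.models[k]
            prev_head = traj.models[k - 1].head
            if np.linalg.norm(m.head - prev_head) > np.linalg.norm(m.tail - prev_head):
                traj.models[k] = m.flipped()
    return traj
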