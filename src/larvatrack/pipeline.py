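"""End-to-end convenience layer: frames in, trajectories and feature tables out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureConfig, feature_frame, is_coiled
from .model import ModelConfig
from .postprocess import PostprocessConfig, postprocess_trajectory
from .segmentation import SegmentationConfig
from .stimulus import StimulusMarker, bearing_angle, in_region, nearest_point, stimulus_distance
from .tracking import TrackingConfig, Trajectory, track_sequence

__all__ = ["RunConfig", "run_pipeline", "trajectories_to_table"]


@dataclass
class RunConfig:
    """Union of all stage configurations plus stimulus markers."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    markers: list[StimulusMarker] = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build from a flat key/value mapping (e.g. a parsed YAML file)."""
        data = dict(data)
        markers = [
            _marker_from_dict(m) for m in data.pop("markers", [])
        ]

        def pick(config_cls):
            names = set(config_cls.__dataclass_fields__)
            return config_cls(**{k: v for k, v in data.items() if k in names})

        return cls(
            segmentation=pick(SegmentationConfig),
            model=pick(ModelConfig),
            tracking=pick(TrackingConfig),
            features=pick(FeatureConfig),
            postprocess=pick(PostprocessConfig),
            markers=markers,
        )


def _marker_from_dict(m: dict) -> StimulusMarker:
    m = dict(m)
    kind = m.pop("kind")
    mid = m.pop("id", kind)
    if kind == "point":
        params = {"point": (m["x"], m["y"])}
    elif kind == "line":
        params = {"p0": tuple(m["p0"]), "p1": tuple(m["p1"])}
    elif kind == "rectangle":
        params = {"bounds": (m["x_min"], m["y_min"], m["x_max"], m["y_max"])}
    elif kind == "ellipse":
        params = {"c": (m["cx"], m["cy"]), "a": m["a"], "b": m["b"]}
    else:
        raise ValueError(f"unknown marker kind: {kind!r}")
    return StimulusMarker(kind, params, mid)


def _stimulus_columns(df: pd.DataFrame, markers: list[StimulusMarker]) -> pd.DataFrame:
    for marker in markers:
        dists, bearings, inside = [], [], []
        for _, row in df.iterrows():
            com = np.array([row["com_x"], row["com_y"]])
            tail = np.array([row["tail_x"], row["tail_y"]])
            p = nearest_point(marker, com)
            dists.append(stimulus_distance(marker, com))
            bearings.append(bearing_angle(com, tail, p))
            inside.append(in_region(marker, com))
        df[f"dist_to_{marker.id}"] = dists
        df[f"bearing_{marker.id}"] = bearings
        df[f"in_{marker.id}"] = inside
    return df


def trajectories_to_table(
    trajectories: list[Trajectory],
    config: FeatureConfig | None = None,
    markers: list[StimulusMarker] | None = None,
) -> pd.DataFrame:
    """Tidy per-(animal, frame) feature table; frames are 0-based here."""
    config = config or FeatureConfig()
    parts = []
    for traj in trajectories:
        df = feature_frame(traj.models, config)
        df.insert(0, "animal_id", traj.id)
        df.insert(1, "frame", np.arange(traj.start_frame, traj.start_frame + len(traj.models)))
        parts.append(_stimulus_columns(df, markers or []))
    if not parts:
        return pd.DataFrame(columns=["animal_id", "frame"])
    return pd.concat(parts, ignore_index=True)


def run_pipeline(frames, config: RunConfig | None = None, background=None):
    """Track, orientation-correct, and featurize an image sequence.

    Returns ``(trajectories, table)`` where the table is the tidy feature
    table over all trajectories (post head/tail correction).  ``background``
    overrides the minimum-intensity background estimate; supply a blank
    background when animals stay put for the whole recording (the minimum
    projection assumes each pixel is animal-free at some point in time).
    """
    config = config or RunConfig()
    trajectories = track_sequence(
        frames,
        seg_config=config.segmentation,
        model_config=config.model,
        tracking_config=config.tracking,
        background=background,
    )
    for traj in trajectories:
        coiled = [is_coiled(m, config.features) for m in traj.models]
        postprocess_trajectory(traj, coiled, config.features, config.postprocess)
    table = trajectories_to_table(trajectories, config.features, config.markers)
    return trajectories, table
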