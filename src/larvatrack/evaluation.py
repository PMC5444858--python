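"""Deviation scoring of tracking results against ground truth.

Tracked trajectories are matched to ground-truth identities by majority
nearest-center-of-mass vote over their common frames.  Per matched frame
three deviations are recorded: the Euclidean distance between the centers
of mass, the distance between the central spine points, and the absolute
body-bending difference.  Bending differences are taken circularly (the
smaller of d and 360-d) except on frames where the tracked head sits nearer
the true tail than the true head — a head/tail swap — where the raw
difference is kept so that swaps surface as large outliers rather than
being folded away.

Summaries follow the classical robust table layout: mean, standard
deviation, median, min and max over the non-outlier values, the maximum
including outliers (Max*), and the outlier count/fraction, with outliers
defined by Tukey fences (1.5 IQR beyond the quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricSummary",
    "DeviationReport",
    "summarize_deviations",
    "match_identities",
    "match_and_deviate",
]

_LANDMARK_COLS = [
    "com_x", "com_y", "mid_x", "mid_y", "head_x", "head_y", "tail_x", "tail_y", "bending",
]


@dataclass
class MetricSummary:
    mean: float
    std: float
    median: float
    min: float
    max: float  # excluding outliers
    max_star: float  # including outliers
    n_outliers: int
    outlier_fraction: float


@dataclass
class DeviationReport:
    summaries: dict[str, MetricSummary]
    deviations: pd.DataFrame  # per (tracked_id, frame): com, mid, bending, head_swapped
    matching: dict[int, int]  # tracked id -> truth identity
    lost_truth_ids: list[int] = field(default_factory=list)
    n_identity_switches: int = 0
    head_match_fraction: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped summary: one row per deviation metric."""
        rows = []
        for name, s in self.summaries.items():
            rows.append(
                {
                    "deviation": name,
                    "mean": s.mean,
                    "std": s.std,
                    "median": s.median,
                    "min": s.min,
                    "max": s.max,
                    "max_star": s.max_star,
                    "n_outliers": s.n_outliers,
                    "outlier_fraction": s.outlier_fraction,
                }
            )
        return pd.DataFrame(rows)


def _tukey_outliers(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def summarize_deviations(values, outlier_k: float = 1.5) -> MetricSummary:
    """Robust summary of one deviation series (NaNs dropped)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        nan = float("nan")
        return MetricSummary(nan, nan, nan, nan, nan, nan, 0, 0.0)
    out = _tukey_outliers(v, outlier_k)
    kept = v[~out] if (~out).any() else v
    return MetricSummary(
        mean=float(kept.mean()),
        std=float(kept.std(ddof=1)) if kept.size > 1 else 0.0,
        median=float(np.median(kept)),
        min=float(kept.min()),
        max=float(kept.max()),
        max_star=float(v.max()),
        n_outliers=int(out.sum()),
        outlier_fraction=float(out.mean()),
    )


def _per_animal_tables(df: pd.DataFrame, id_col: str) -> dict[int, pd.DataFrame]:
    return {
        int(ident): sub.set_index("frame").sort_index()
        for ident, sub in df.groupby(id_col)
    }


def match_identities(tracked: pd.DataFrame, truth: pd.DataFrame):
    """Majority nearest-center-of-mass matching of tracked ids to truth ids.

    Returns (matching, per-id switch counts): a tracked id maps to the truth
    identity that is its nearest neighbour in the most frames; frames voting
    for a different identity count as switches.
    """
    tracked_by = _per_animal_tables(tracked, "animal_id")
    truth_by = _per_animal_tables(truth, "identity")
    matching: dict[int, int] = {}
    switches: dict[int, int] = {}
    for tid, tdf in tracked_by.items():
        votes: list[int] = []
        for frame, row in tdf.iterrows():
            best, best_d = None, np.inf
            for gid, gdf in truth_by.items():
                if frame not in gdf.index:
                    continue
                g = gdf.loc[frame]
                d = float(np.hypot(row["com_x"] - g["com_x"], row["com_y"] - g["com_y"]))
                if d < best_d:
                    best, best_d = gid, d
            if best is not None:
                votes.append(best)
        if votes:
            counts = pd.Series(votes).value_counts()
            matching[tid] = int(counts.idxmax())
            switches[tid] = int(len(votes) - counts.max())
    return matching, switches


def match_and_deviate(
    tracked: pd.DataFrame,
    truth: pd.DataFrame,
    outlier_k: float = 1.5,
    full_span_only: bool = False,
) -> DeviationReport:
    """Score tracked landmark tables against ground-truth tables.

    Both inputs are tidy frames with one row per (animal, frame) carrying
    the landmark columns (com/mid/head/tail positions and the bending
    angle); the tracked table uses ``animal_id``, the truth table
    ``identity``.  With ``full_span_only`` trajectories not covering every
    truth frame are excluded from the deviation statistics (they still count
    towards identity bookkeeping).
    """
    matching, switches = match_identities(tracked, truth)
    tracked_by = _per_animal_tables(tracked, "animal_id")
    truth_by = _per_animal_tables(truth, "identity")
    all_frames = truth["frame"].nunique()

    rows = []
    head_hits = 0
    head_total = 0
    for tid, gid in matching.items():
        tdf, gdf = tracked_by[tid], truth_by[gid]
        if full_span_only and len(tdf) < all_frames:
            continue
        common = tdf.index.intersection(gdf.index)
        for frame in common:
            trow, grow = tdf.loc[frame], gdf.loc[frame]
            com_dev = float(np.hypot(trow["com_x"] - grow["com_x"], trow["com_y"] - grow["com_y"]))
            mid_dev = float(np.hypot(trow["mid_x"] - grow["mid_x"], trow["mid_y"] - grow["mid_y"]))
            d_head = np.hypot(trow["head_x"] - grow["head_x"], trow["head_y"] - grow["head_y"])
            d_tail = np.hypot(trow["head_x"] - grow["tail_x"], trow["head_y"] - grow["tail_y"])
            swapped = bool(d_head > d_tail)
            raw = abs(float(trow["bending"]) - float(grow["bending"]))
            bend_dev = raw if swapped else min(raw, 360.0 - raw)
            coiled = bool(grow["coiled"]) if "coiled" in grow else False
            if not coiled:
                head_total += 1
                head_hits += int(not swapped)
            rows.append(
                {
                    "tracked_id": tid,
                    "truth_id": gid,
                    "frame": frame,
                    "com": com_dev,
                    "mid": mid_dev,
                    "bending": bend_dev,
                    "head_swapped": swapped,
                    "coiled": coiled,
                }
            )
    dev = pd.DataFrame(
        rows,
        columns=[
            "tracked_id", "truth_id", "frame", "com", "mid", "bending",
            "head_swapped", "coiled",
        ],
    )
    summaries = {
        name: summarize_deviations(dev[name].to_numpy(), outlier_k)
        for name in ("com", "mid", "bending")
    }
    lost = [gid for gid in truth_by if gid not in set(matching.values())]
    return DeviationReport(
        summaries=summaries,
        deviations=dev,
        matching=matching,
        lost_truth_ids=lost,
        n_identity_switches=int(sum(switches.values())),
        head_match_fraction=(head_hits / head_total) if head_total else float("nan"),
    )
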