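"""Reading image sequences and writing results.

Input is a directory of TIFF or PNG frames, one file per frame, ordered
lexicographically.  Output after tracking is (a) a long-format CSV with one
row per (animal, frame, feature) — the robust interchange surface, (b) a
wide per-animal CSV mirroring the classical table view with animals in
columns and (feature, frame) rows, and (c) a trajectory overlay image
drawing each identity's center-of-mass path in a deterministic per-id
colour over the last frame.  Frame indices are 1-based in all files
(0-based internally); undefined features are written as empty fields.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_sequence",
    "write_frames",
    "write_long_csv",
    "read_long_csv",
    "write_wide_csv",
    "write_overlay",
    "write_results",
    "ground_truth_to_table",
]

_EXTENSIONS = (".png", ".tif", ".tiff")
_ID_COLS = ("animal_id", "frame")


def read_sequence(path, invert: bool = False) -> list[np.ndarray]:
    """Load a directory of grayscale frames in lexicographic order."""
    directory = Path(path)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in _EXTENSIONS)
    if not files:
        raise FileNotFoundError(f"no TIFF/PNG frames found in {directory}")
    frames = []
    shape = None
    for f in files:
        try:
            arr = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - rewrap with the file name
            raise OSError(f"cannot read frame {f}: {exc}") from exc
        if arr.ndim == 3:
            arr = arr[..., :3].mean(axis=-1)
        if arr.dtype != np.uint8:
            warnings.warn(f"{f.name}: rescaling {arr.dtype} frame to 8-bit")
            arr = arr.astype(float)
            peak = arr.max() or 1.0
            arr = arr / peak * 255.0
        arr = arr.astype(np.uint8)
        if invert:
            arr = 255 - arr
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"{f.name}: frame shape {arr.shape} != {shape}")
        frames.append(arr)
    return frames


def write_frames(frames, directory, fmt: str = "png") -> list[Path]:
    """Write frames as zero-padded numbered images."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(frames):
        p = directory / f"frame_{t:05d}.{fmt}"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def _to_long(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["frame"] = out["frame"] + 1  # 1-based in files
    long = out.melt(id_vars=list(_ID_COLS), var_name="feature", value_name="value")
    return long.sort_values(["animal_id", "frame", "feature"], kind="stable").reset_index(drop=True)


def write_long_csv(table: pd.DataFrame, path) -> None:
    """Long-format CSV: (animal_id, frame, feature, value); NaN -> empty field."""
    _to_long(table).to_csv(path, index=False, lineterminator="\n")


def read_long_csv(path) -> pd.DataFrame:
    """Inverse of :func:`write_long_csv`: back to the tidy wide table, 0-based frames."""
    long = pd.read_csv(path)
    if long.empty:
        return pd.DataFrame(columns=list(_ID_COLS))
    wide = long.pivot_table(
        index=list(_ID_COLS), columns="feature", values="value", aggfunc="first", dropna=False
    ).reset_index()
    wide.columns.name = None
    wide["frame"] = wide["frame"].astype(int) - 1
    wide["animal_id"] = wide["animal_id"].astype(int)
    for col in wide.columns:
        if col in ("coiled", "left_bended", "right_bended", "go_phase") or col.startswith("in_"):
            wide[col] = wide[col].astype(float).fillna(0).astype(bool)
    return wide


def write_wide_csv(table: pd.DataFrame, path) -> None:
    """Per-animal table view: animals in columns, (feature, frame) rows."""
    long = _to_long(table)
    wide = long.pivot_table(
        index=["feature", "frame"], columns="animal_id", values="value", aggfunc="first"
    )
    wide.columns = [f"animal_{c}" for c in wide.columns]
    wide.to_csv(path, lineterminator="\n")


def write_overlay(trajectories, last_frame: np.ndarray, path) -> None:
    """Color-coded center-of-mass paths over the final frame, one colour per id."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    ax.imshow(last_frame, cmap="gray", vmin=0, vmax=255)
    cmap = plt.get_cmap("tab20")
    for traj in trajectories:
        com = np.array([m.center_of_mass for m in traj.models])
        ax.plot(com[:, 0], com[:, 1], color=cmap(traj.id % 20), linewidth=1.2,
                label=f"id {traj.id}")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def write_results(trajectories, table: pd.DataFrame, out_dir, last_frame=None) -> dict[str, Path]:
    """Write the standard result bundle into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "long": out / "features.csv",
        "wide": out / "features_wide.csv",
    }
    write_long_csv(table, paths["long"])
    write_wide_csv(table, paths["wide"])
    if last_frame is not None:
        paths["overlay"] = out / "trajectories.png"
        write_overlay(trajectories, last_frame, paths["overlay"])
    return paths


def ground_truth_to_table(truth) -> pd.DataFrame:
    """Ground-truth records as a tracker-schema table (identity as animal_id)."""
    df = truth.records.copy()
    df.insert(0, "animal_id", df["identity"])
    return df
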