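"""Background subtraction and contour extraction for bright-on-dark recordings.

FTIR-based imaging produces a near-black background with bright animals, so a
static background image is simply the per-pixel minimum over time (every pixel
is animal-free in at least one frame once the animals have crawled past).
Foreground pixels keep their original intensity; everything within a gray-value
threshold of the background is zeroed.  Connected bright components are then
traced into closed boundary chains and filtered by area to isolate single
animals: components larger than ``area_max`` are presumed collisions,
smaller than ``area_min`` presumed artifacts, and both are discarded.

Coordinate convention: ``x`` = column, ``y`` = row, origin at the top-left,
0-based, integer pixel centers.  No sub-pixel accuracy is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import draw as _draw
from skimage import measure as _measure

__all__ = [
    "SegmentationConfig",
    "Contour",
    "compute_background",
    "extract_foreground",
    "find_contours",
    "filter_contours",
]


@dataclass
class SegmentationConfig:
    """Thresholds controlling segmentation.

    Parameters
    ----------
    gray_threshold
        Intensity offset above the background required for a pixel to count
        as foreground (the user-set gray value threshold tau).
    area_min, area_max
        Inclusive area band (pixel counts) a contour must fall in to be kept.
    background_stride
        Use every ``stride``-th frame when building the background image; the
        minimum over a subsample is an upper bound of the true minimum
        background, which is adequate when animals move slowly.
    """

    gray_threshold: int = 50
    area_min: int = 60
    area_max: int = 1200
    background_stride: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.gray_threshold <= 255:
            raise ValueError("gray_threshold must be in [0, 255]")
        if not 0 < self.area_min < self.area_max:
            raise ValueError("need 0 < area_min < area_max")
        if self.background_stride < 1:
            raise ValueError("background_stride must be >= 1")


@dataclass
class Contour:
    """A closed, ordered chain of integer boundary pixels.

    ``points`` is an (N, 2) integer array of (x, y) positions; the chain is
    implicitly closed (last point connects back to the first).  ``area`` is
    the number of pixels enclosed by (and including) the boundary, and
    ``perimeter`` the length of the closed polygonal boundary.  ``pixels``
    caches the filled region as an (K, 2) array of (x, y) coordinates; it is
    rasterized on demand for contours built directly from point lists.
    """

    points: np.ndarray
    area: int
    perimeter: float
    pixels: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_points(cls, points) -> "Contour":
        """Build a contour from a closed (x, y) chain, rasterizing its interior."""
        pts = np.asarray(points)
        pixels = _fill_polygon(pts)
        return cls(
            points=np.rint(pts).astype(np.int64),
            area=int(len(pixels)),
            perimeter=_chain_length(pts),
            pixels=pixels,
        )

    def filled_pixels(self) -> np.ndarray:
        if self.pixels is None:
            self.pixels = _fill_polygon(self.points)
        return self.pixels

    def pixel_keys(self) -> np.ndarray:
        return _keys(self.filled_pixels())

    def contains_points(self, points) -> np.ndarray:
        """Per-point membership (boundary inclusive) at pixel resolution."""
        pts = np.rint(np.atleast_2d(np.asarray(points, dtype=float))).astype(np.int64)
        return np.isin(_keys(pts), self.pixel_keys())

    def centroid(self) -> np.ndarray:
        """Center of mass: mean of enclosed pixel coordinates, rounded to int."""
        return np.rint(self.filled_pixels().mean(axis=0)).astype(np.int64)


_KEY_STRIDE = 1 << 20  # supports images up to ~1e6 pixels per side


def _keys(pixels: np.ndarray) -> np.ndarray:
    p = np.asarray(pixels, dtype=np.int64)
    return p[:, 0] * _KEY_STRIDE + p[:, 1]


def _chain_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def _fill_polygon(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    rr, cc = _draw.polygon(pts[:, 1], pts[:, 0])
    interior = np.stack([cc, rr], axis=1).astype(np.int64)
    boundary = np.rint(pts).astype(np.int64)
    allpix = np.vstack([interior, boundary])
    _, idx = np.unique(_keys(allpix), return_index=True)
    return allpix[np.sort(idx)]


def compute_background(frames, stride: int = 1) -> np.ndarray:
    """Per-pixel minimum intensity over time.

    Raises on an empty sequence or inconsistent frame shapes.
    """
    it = list(frames)[:: max(1, int(stride))]
    if not it:
        raise ValueError("cannot compute a background from an empty sequence")
    first = np.asarray(it[0])
    background = first.copy()
    for frame in it[1:]:
        arr = np.asarray(frame)
        if arr.shape != first.shape:
            raise ValueError(f"frame shape {arr.shape} != {first.shape}")
        np.minimum(background, arr, out=background)
    return background


def extract_foreground(frame, background, config: SegmentationConfig) -> np.ndarray:
    """Keep original intensities where ``|I - B| >= tau``, zero elsewhere."""
    image = np.asarray(frame)
    bg = np.asarray(background)
    if image.shape != bg.shape:
        raise ValueError(f"frame shape {image.shape} != background {bg.shape}")
    diff = np.abs(image.astype(np.int32) - bg.astype(np.int32))
    out = np.where(diff >= config.gray_threshold, image, 0)
    return out.astype(image.dtype)


# Moore neighbourhood, clockwise in image coordinates (row down), starting north.
_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbour border following on a binary mask.

    Returns the ordered closed chain of outer-boundary pixels as (row, col)
    pairs, clockwise in image coordinates.  Jacob's stopping criterion: stop
    on re-entering the start pixel from the original direction.
    """
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # topmost-leftmost foreground pixel
    h, w = mask.shape

    def is_fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(mask[r, c])

    chain: list[tuple[int, int]] = []
    current = start
    backtrack = (start[0], start[1] - 1)
    first_move = None  # direction of the first departure from the start pixel
    for _ in range(4 * mask.size + 8):
        d0 = _MOORE.index((backtrack[0] - current[0], backtrack[1] - current[1]))
        cand = None
        for k in range(1, 9):
            off = _MOORE[(d0 + k) % 8]
            cand = (current[0] + off[0], current[1] + off[1])
            if is_fg(*cand):
                break
        else:
            return np.asarray([start], dtype=np.int64)  # isolated pixel
        if current == start:
            if first_move is None:
                first_move = off
            elif off == first_move:
                break
        chain.append(current)
        prev_off = _MOORE[(d0 + k - 1) % 8]
        backtrack = (current[0] + prev_off[0], current[1] + prev_off[1])
        current = cand
    return np.asarray(chain or [start], dtype=np.int64)


def find_contours(foreground: np.ndarray) -> list[Contour]:
    """Trace one outer contour per 8-connected foreground component.

    The component's pixel count is the contour area and its pixel coordinates
    are cached on the contour; holes inside components are ignored.
    """
    mask = np.asarray(foreground) > 0
    labels = _measure.label(mask, connectivity=2)
    contours: list[Contour] = []
    for region in _measure.regionprops(labels):
        r0, c0, _, _ = region.bbox
        chain_rc = _trace_boundary(region.image)
        chain_rc[:, 0] += r0
        chain_rc[:, 1] += c0
        points = chain_rc[:, ::-1].copy()  # (row, col) -> (x, y)
        pixels = region.coords[:, ::-1].astype(np.int64).copy()
        contours.append(
            Contour(
                points=points,
                area=int(region.area),
                perimeter=_chain_length(points),
                pixels=pixels,
            )
        )
    return contours


def filter_contours(contours, config: SegmentationConfig) -> list[Contour]:
    """Keep contours whose area lies in ``[area_min, area_max]``."""
    return [c for c in contours if config.area_min <= c.area <= config.area_max]
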