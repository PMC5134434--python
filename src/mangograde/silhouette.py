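"""Fruit silhouette segmentation and boundary extraction.

Segments a single fruit from a white-tray image, view by view. The top view
is high-contrast: the tray has high blue (B) values while the fruit skin has
low B, so a pair of global thresholds on the B band isolates the fruit and
drops the dark stem. The side view is a low-contrast mirror reflection with
a shadow band, handled by three repeated channel thresholds (B, G, B) with a
median filter between passes. The cleaned mask's outer border is traced as a
closed, clockwise, 8-connected pixel contour.

Conventions: images are H×W×3 uint8 RGB, origin top-left, x to the right and
y down; pixel centres sit at integer coordinates; masks are boolean with
True = fruit. All functions are pure (inputs are never modified).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "ViewLayout",
    "BoundaryTrace",
    "MaskMeasures",
    "split_views",
    "to_gray_b",
    "threshold_top",
    "remove_small_particles",
    "fill_holes",
    "threshold_side",
    "extract_boundary",
    "measure_mask",
    "default_min_area",
]

#: min_area reference: 500 px for a 1600x850 (1.36 MP) frame, scaled by area.
_REFERENCE_MIN_AREA = 500
_REFERENCE_FRAME_PX = 1600 * 850


@dataclass(frozen=True)
class ViewLayout:
    """Crop rectangles locating the two views inside one camera frame.

    Each rectangle is (x0, y0, width, height) in pixels, 0-based. The camera
    sees the fruit from above and, through a tilted mirror, from the side, so
    one frame holds both silhouettes.
    """

    top: tuple[int, int, int, int]
    side: tuple[int, int, int, int]

    @classmethod
    def halves(cls, width: int, height: int, split_x: int | None = None) -> "ViewLayout":
        """Layout with the top view left and the side view right of ``split_x``."""
        if split_x is None:
            split_x = width // 2
        return cls(top=(0, 0, split_x, height), side=(split_x, 0, width - split_x, height))


@dataclass(frozen=True)
class BoundaryTrace:
    """Closed, clockwise, 8-connected pixel contour of a single blob.

    ``points`` is an (N, 2) integer array of (x, y) coordinates; the last
    point is 8-adjacent to the first. Clockwise is defined in image
    coordinates (x right, y down), i.e. the shoelace signed area is negative.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
            raise ValueError("boundary needs at least 4 (x, y) points")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def signed_area(self) -> float:
        """Shoelace signed area; negative for clockwise in image coordinates."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class MaskMeasures:
    """Pixel-domain geometry of a single-component mask."""

    area_px: float
    perimeter_px: float
    max_diameter_px: float
    min_diameter_px: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), exclusive stop


def _as_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H×W×3 RGB image, got shape {arr.shape}")
    return arr


def split_views(image: np.ndarray, layout: ViewLayout) -> tuple[np.ndarray, np.ndarray]:
    """Crop the top-view and side-view sub-images out of a composite frame."""
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    crops = []
    for name, (x0, y0, cw, ch) in (("top", layout.top), ("side", layout.side)):
        if cw <= 0 or ch <= 0:
            raise ValueError(f"{name} view rectangle is empty")
        if x0 < 0 or y0 < 0 or x0 + cw > w or y0 + ch > h:
            raise ValueError(f"{name} view rectangle {layout.top if name == 'top' else layout.side} exceeds image bounds {w}×{h}")
        crops.append(arr[y0 : y0 + ch, x0 : x0 + cw].copy())
    return crops[0], crops[1]


def to_gray_b(image: np.ndarray) -> np.ndarray:
    """Return the blue band as a grayscale image.

    The white tray has a high B value and mango skin a low one, so the B band
    alone carries the fruit/background contrast.
    """
    return _as_rgb(image)[:, :, 2].copy()


def threshold_top(
    gray: np.ndarray,
    bg_thresh: int = 90,
    stem_range: tuple[int, int] = (0, 20),
) -> np.ndarray:
    """Segment the top view with two global thresholds on the B band.

    Fruit pixels are those with B strictly inside ``(stem_range[1],
    bg_thresh)``: values at or above ``bg_thresh`` are bright background, and
    values inside ``stem_range`` (default 0–20) are the near-black stem,
    excluded so the stalk does not distort the shape outline.
    """
    lo, hi = stem_range
    if lo > hi:
        raise ValueError(f"stem_range is inverted: {stem_range}")
    if hi >= bg_thresh:
        raise ValueError(f"stem_range upper bound {hi} must be below bg_thresh {bg_thresh}")
    g = np.asarray(gray)
    return (g > hi) & (g < bg_thresh)


def remove_small_particles(mask: np.ndarray, min_area: int | None = None) -> np.ndarray:
    """Drop connected components smaller than ``min_area`` pixels.

    The largest component is always retained even if it falls below
    ``min_area``, so a valid (small) fruit is never deleted. Default
    ``min_area`` scales with the frame size (500 px at 1600×850).
    """
    m = np.asarray(mask, dtype=bool)
    if min_area is None:
        min_area = default_min_area(m.shape)
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return m.copy()
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero((areas >= min_area)) + 1
    largest = int(np.argmax(areas)) + 1
    if largest not in keep:
        keep = np.append(keep, largest)
    return np.isin(labels, keep)


def default_min_area(shape: Sequence[int]) -> int:
    """Speck-removal threshold scaled to the frame area."""
    frame_px = int(shape[0]) * int(shape[1])
    return max(1, round(_REFERENCE_MIN_AREA * frame_px / _REFERENCE_FRAME_PX))


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background holes fully enclosed by fruit (dark spots, dirt)."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


def threshold_side(
    image: np.ndarray,
    params: Sequence[tuple[str, int]] = (("B", 120), ("G", 110), ("B", 100)),
    median_size: int = 7,
) -> np.ndarray:
    """Segment the low-contrast side view with three repeated thresholds.

    Each pass keeps pixels whose stated channel is strictly below the stated
    intensity, restricted to the region surviving the previous pass; a
    ``median_size`` × ``median_size`` median filter between passes erases the
    thin boundary of the shadow band the fruit casts in the mirror view. The
    default B→G→B ordering tolerates a shadow that is darker than the tray in
    all bands but lighter than the fruit in B.
    """
    if median_size % 2 == 0 or median_size < 3:
        raise ValueError("median_size must be odd and >= 3")
    arr = _as_rgb(image)
    channel_index = {"R": 0, "G": 1, "B": 2}
    mask = np.ones(arr.shape[:2], dtype=bool)
    for i, (channel, thresh) in enumerate(params):
        if channel not in channel_index:
            raise ValueError(f"unknown channel {channel!r}")
        band = arr[:, :, channel_index[channel]]
        mask = mask & (band < thresh)
        if i < len(params) - 1:
            mask = ndimage.median_filter(mask, size=median_size)
    return mask


def _single_component(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    _, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("mask is empty")
    if n > 1:
        raise ValueError(f"mask has {n} connected components; expected exactly 1")
    return m


# Moore neighbourhood in clockwise order under image coordinates (y down),
# starting east: E, SE, S, SW, W, NW, N, NE as (dx, dy).
_MOORE = np.array([(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)])


def extract_boundary(mask: np.ndarray) -> BoundaryTrace:
    """Trace the outer border of the mask as a closed clockwise contour.

    Moore-neighbour tracing with Jacob's stopping criterion. The start point
    is the topmost, then leftmost, foreground pixel, and the walk proceeds
    clockwise in image coordinates, so repeated runs give identical traces.
    """
    m = _single_component(mask)
    if int(m.sum()) < 4:
        raise ValueError("component too small to trace (area < 4)")
    rows, cols = np.nonzero(m)
    start = (int(cols[0]), int(rows[0]))  # topmost then leftmost (row-major nonzero order)

    h, w = m.shape

    def is_fg(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and bool(m[y, x])

    # The start pixel is the leftmost pixel of the blob's topmost row, so its
    # west neighbour is guaranteed background; tracing "enters" from the west.
    dir_index = {(int(dx), int(dy)): k for k, (dx, dy) in enumerate(_MOORE)}
    points: list[tuple[int, int]] = []
    cur = start
    prev_bg = (start[0] - 1, start[1])
    # The walk is a deterministic map on states (current pixel, previous
    # background cell), so it is periodic; the contour is the cycle through
    # the start state.
    seen: dict[tuple[tuple[int, int], tuple[int, int]], int] = {}
    max_steps = 4 * h * w  # safety, unreachable for valid masks
    for _ in range(max_steps):
        state = (cur, prev_bg)
        if state in seen:
            points = points[seen[state] :]
            break
        seen[state] = len(points)
        points.append(cur)
        # scan the Moore neighbourhood clockwise starting at the previous
        # background pixel; the first foreground pixel hit is the next
        # boundary pixel, and the cell checked just before it the new prev_bg
        d0 = dir_index[(prev_bg[0] - cur[0], prev_bg[1] - cur[1])]
        nxt = None
        for k in range(1, 9):
            d = (d0 + k) % 8
            nx, ny = cur[0] + int(_MOORE[d][0]), cur[1] + int(_MOORE[d][1])
            if is_fg(nx, ny):
                nxt = (nx, ny)
                break
            prev_bg = (nx, ny)
        if nxt is None:
            break  # isolated pixel; cannot happen for area >= 4 single component
        cur = nxt
    else:
        raise RuntimeError("boundary tracing failed to terminate")

    pts = np.array(points, dtype=int)
    # rotate so the trace starts at the topmost-then-leftmost boundary pixel
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    pts = np.roll(pts, -int(order[0]), axis=0)
    if len(pts) < 4:
        raise ValueError("traced contour degenerate (fewer than 4 points)")
    trace = BoundaryTrace(pts)
    if trace.signed_area() > 0:  # enforce clockwise in image coordinates
        pts = np.vstack([pts[:1], pts[1:][::-1]])
        trace = BoundaryTrace(pts)
    return trace


def measure_mask(mask: np.ndarray) -> MaskMeasures:
    """Area, perimeter, Feret diameters and bounding box of the fruit blob.

    ``max_diameter_px`` is the maximum Feret diameter (largest caliper
    distance across the convex hull); ``min_diameter_px`` is the extent
    measured perpendicular to that axis.
    """
    m = _single_component(mask)
    props = measure.regionprops(m.astype(np.uint8))[0]
    coords = props.coords  # (row, col)
    pts = coords[:, ::-1].astype(float)  # (x, y)
    max_d, min_d = _feret_diameters(pts)
    return MaskMeasures(
        area_px=float(props.area),
        perimeter_px=float(props.perimeter),
        max_diameter_px=max_d,
        min_diameter_px=min_d,
        bbox=tuple(int(v) for v in props.bbox),
    )


def _feret_diameters(points: np.ndarray) -> tuple[float, float]:
    """Max Feret diameter and the perpendicular extent, on pixel centres +-0.5.

    Pixel centres are at integers; each pixel spans ±0.5, so the hull of the
    centre points is dilated by half a pixel along the measured direction.
    """
    from scipy.spatial import ConvexHull

    if len(points) >= 4:
        try:
            hull = ConvexHull(points)
            pts = points[hull.vertices]
        except Exception:
            pts = points
    else:
        pts = points
    # max Feret: brute force over hull vertex pairs (hulls here are small)
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    max_d = float(np.sqrt(d2[i, j])) + 1.0  # +0.5 px at each end
    axis = pts[j] - pts[i]
    norm = np.linalg.norm(axis)
    if norm == 0:
        return max_d, max_d
    perp = np.array([-axis[1], axis[0]]) / norm
    proj = pts @ perp
    min_d = float(proj.max() - proj.min()) + 1.0
    return max_d, min_d


def rasterize_boundary(trace: BoundaryTrace, shape: tuple[int, int]) -> np.ndarray:
    """Paint a boundary trace back into a filled mask (round-trip helper)."""
    m = np.zeros(shape, dtype=bool)
    m[trace.y, trace.x] = True
    return ndimage.binary_fill_holes(m)
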