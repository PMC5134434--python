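"""Disk-method volume, mass estimation and commercial grading.

The fruit is treated as a stack of thin elliptical disks along its length:
the top view gives each disk's width Δy, the side view its height Δz, and
a disk of thickness Δx contributes V = π·(Δy/2)·(Δz/2)·Δx. Summing over
the length gives the volume, mass follows from a linear density model, and
the mass maps to the commercial grade bands (A ≥ 400 g, B 350–400 g,
C < 350 g; misshapen fruit are rejected regardless of mass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .silhouette import _single_component

__all__ = [
    "SliceProfilePair",
    "GradeReport",
    "slice_profiles",
    "disk_volume",
    "estimate_mass",
    "fit_mass_model",
    "assign_grade",
    "MASS_SLOPE",
    "MASS_INTERCEPT",
]

#: Published linear volume→mass model for Harumanis (g = slope·mL + intercept).
MASS_SLOPE = 0.9973
MASS_INTERCEPT = 6.778


@dataclass(frozen=True)
class SliceProfilePair:
    """Per-slice widths (top view) and heights (side view) along the length.

    ``dx`` is the slice thickness; the widths/heights and dx share one unit
    (mm throughout the pipeline).
    """

    dx: float
    widths: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        if len(w) != len(h):
            raise ValueError("width and height profiles must have equal length")
        if np.any(w < 0) or np.any(h < 0):
            raise ValueError("slice extents must be non-negative")
        if self.dx <= 0:
            raise ValueError("slice thickness must be positive")
        object.__setattr__(self, "widths", w)
        object.__setattr__(self, "heights", h)

    @property
    def n_slices(self) -> int:
        return len(self.widths)


@dataclass(frozen=True)
class GradeReport:
    """One fruit's grading outcome."""

    id: str
    shape_class: str
    volume_ml: float | None
    mass_g: float | None
    grade: str


def _column_extents(mask: np.ndarray) -> np.ndarray:
    """Foreground extent (max−min+1 rows) per occupied column, left to right.

    The +1 counts full pixel spans: with pixel centres on the integer grid, a
    physical extent of d pixels covers on average d centres, so the count is
    an unbiased pixel-domain estimate of the silhouette's extent.
    """
    rows, cols = np.nonzero(mask)
    order = np.argsort(cols, kind="stable")
    cols_s, rows_s = cols[order], rows[order]
    uniq, starts = np.unique(cols_s, return_index=True)
    extents = []
    boundaries = list(starts) + [len(cols_s)]
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        seg = rows_s[a:b]
        extents.append(seg.max() - seg.min() + 1)
    return np.asarray(extents, dtype=float)


def _horizontalize(mask: np.ndarray) -> np.ndarray:
    """Rotate the mask so the blob's major axis lies along the columns."""
    from skimage import measure, transform

    props = measure.regionprops(mask.astype(np.uint8))[0]
    # regionprops orientation: angle between major axis and the row (vertical)
    # axis; convert to the rotation that lays the major axis horizontally.
    angle_deg = 90.0 - np.degrees(props.orientation)
    angle_deg = (angle_deg + 90.0) % 180.0 - 90.0
    if abs(angle_deg) < 0.5:
        return mask
    rot = transform.rotate(
        mask.astype(float), angle_deg, resize=True, order=0, center=props.centroid[::-1]
    )
    return rot > 0.5


def slice_profiles(
    top_mask: np.ndarray,
    side_mask: np.ndarray,
    mm_per_px_top: float,
    mm_per_px_side: float,
) -> SliceProfilePair:
    """Build the per-slice width/height profiles from the two silhouettes.

    Both masks are rotated major-axis-horizontal; per-column extents are
    read off, the side profile is linearly resampled to the top profile's
    slice count, and everything is converted to millimetres. The slice
    thickness is one top-view pixel.
    """
    top = _horizontalize(_single_component(top_mask))
    side = _horizontalize(_single_component(side_mask))
    widths_px = _column_extents(top)
    heights_px = _column_extents(side)
    widths = widths_px * mm_per_px_top
    heights = heights_px * mm_per_px_side
    n = len(widths)
    if len(heights) != n:
        src = np.linspace(0.0, 1.0, len(heights))
        tgt = np.linspace(0.0, 1.0, n)
        heights = np.interp(tgt, src, heights)
    return SliceProfilePair(dx=mm_per_px_top, widths=widths, heights=heights)


def disk_volume(profiles: SliceProfilePair) -> float:
    """Total volume in mL: Σ π·(Δy/2)·(Δz/2)·Δx, mm³ → mL."""
    v_mm3 = float(
        np.sum(np.pi * (profiles.widths / 2.0) * (profiles.heights / 2.0) * profiles.dx)
    )
    return v_mm3 / 1000.0


def estimate_mass(
    volume_ml: float, slope: float = MASS_SLOPE, intercept: float = MASS_INTERCEPT
) -> float:
    """Mass in grams from volume in mL via the linear density model."""
    if volume_ml < 0:
        raise ValueError("volume must be >= 0")
    return slope * volume_ml + intercept


def fit_mass_model(volumes, masses) -> tuple[float, float, float]:
    """OLS fit mass = slope·volume + intercept; returns (slope, intercept, R²)."""
    v = np.asarray(volumes, dtype=float)
    m = np.asarray(masses, dtype=float)
    if len(v) != len(m):
        raise ValueError("volumes and masses lengths differ")
    if len(v) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(v) == 0:
        raise np.linalg.LinAlgError("volumes are constant; slope is unidentifiable")
    res = stats.linregress(v, m)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def assign_grade(mass_g: float, shape_class: str) -> str:
    """Commercial grade: A ≥ 400 g, B in [350, 400) g, C < 350 g, or Rejected.

    Misshapen fruit are rejected regardless of mass. The published bands
    leave (350, 351) and (399, 400) g unassigned; half-open intervals close
    those gaps.
    """
    if shape_class == "misshapen":
        return "Rejected"
    if mass_g < 0:
        raise ValueError("mass must be >= 0")
    if mass_g >= 400.0:
        return "A"
    if mass_g >= 350.0:
        return "B"
    return "C"
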