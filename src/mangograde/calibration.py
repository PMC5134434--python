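"""Pixel-to-millimetre calibration from pinhole camera geometry.

Uses the aerial-photograph scale model: for a thin lens, an object of size
``s`` at distance ``D`` images onto ``s · f / D`` of sensor, so

    object size = image size (px) × pixel pitch (mm/px) × D (mm) / f (mm).

The side view is seen through a plane mirror at a fixed optical path
``h3 + h4``, so its scale is constant. The top view's distance depends on
how tall the fruit is: the camera sits ``h2`` above the platform and the
widest horizontal section of the fruit lies partway up its height, so the
per-image distance is ``h1 = h2 − plane_fraction × fruit height``, with the
fruit height measured first from the side view.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CameraGeometry",
    "CalibratedDimensions",
    "object_size",
    "side_view_size",
    "derive_h1",
    "top_view_size",
    "mm_per_pixel",
]


@dataclass(frozen=True)
class CameraGeometry:
    """Optical geometry of the two-view capture platform.

    Parameters
    ----------
    focal_length : mm lens focal length.
    pixel_size : mm sensor pixel pitch (square pixels).
    h2 : mm, camera to platform (tray surface).
    h3 : mm, camera to mirror.
    h4 : mm, mirror to object.
    h1 : mm, camera to the top-view object plane; derived per image from the
        side-view fruit height, ``None`` until :func:`derive_h1` runs.
    plane_fraction : where the object plane sits as a fraction of fruit
        height (0 = tray, 1 = top of fruit). The widest section of an ovoid
        fruit typically lies near mid-height, hence the 0.5 default.
    """

    focal_length: float = 8.0
    pixel_size: float = 0.0045
    h2: float = 450.0
    h3: float = 300.0
    h4: float = 200.0
    plane_fraction: float = 0.5
    h1: float | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("focal_length", "pixel_size", "h2", "h3", "h4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.plane_fraction <= 1.0:
            raise ValueError("plane_fraction must lie in [0, 1]")
        if not 0.0 < self.pixel_size < 0.1:
            raise ValueError("pixel_size (mm) out of plausible sensor range")
        if self.focal_length >= min(self.h2, self.h3 + self.h4):
            raise ValueError("focal length must be well below working distances")

    def with_h1(self, h1: float) -> "CameraGeometry":
        return replace(self, h1=h1)


@dataclass(frozen=True)
class CalibratedDimensions:
    """Calibrated fruit dimensions in millimetres."""

    length: float
    width: float
    height: float
    mm_per_px_top: float
    mm_per_px_side: float

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("dimensions must be positive")
        if self.length < self.width:
            raise ValueError("length must be the major extent (length >= width)")


def object_size(image_size: float, geometry: CameraGeometry, distance: float) -> float:
    """Object size in mm for a pixel extent at a given object distance."""
    if image_size < 0:
        raise ValueError("image_size must be >= 0")
    if distance <= 0:
        raise ValueError("distance must be positive")
    return image_size * geometry.pixel_size * distance / geometry.focal_length


def side_view_size(image_size: float, geometry: CameraGeometry) -> float:
    """Object size in mm in the mirror (side) view, distance = h3 + h4."""
    return object_size(image_size, geometry, geometry.h3 + geometry.h4)


def derive_h1(
    side_height: float, geometry: CameraGeometry, plane_fraction: float | None = None
) -> CameraGeometry:
    """Recalibrate the top view for this fruit's height.

    ``side_height`` is the fruit height in mm measured from the side view;
    the returned geometry carries ``h1 = h2 − plane_fraction × side_height``.
    """
    frac = geometry.plane_fraction if plane_fraction is None else plane_fraction
    if not 0.0 <= frac <= 1.0:
        raise ValueError("plane_fraction must lie in [0, 1]")
    if side_height < 0:
        raise ValueError("side_height must be >= 0")
    if side_height >= geometry.h2:
        raise ValueError("fruit height cannot reach the camera (side_height >= h2)")
    return geometry.with_h1(geometry.h2 - frac * side_height)


def top_view_size(image_size: float, geometry: CameraGeometry) -> float:
    """Object size in mm in the top view, using the per-image plane h1."""
    if geometry.h1 is None:
        raise RuntimeError("h1 not derived; call derive_h1 with the side-view height first")
    return object_size(image_size, geometry, geometry.h1)


def mm_per_pixel(geometry: CameraGeometry, view: str) -> float:
    """Millimetres per pixel for a view ('top' needs h1 derived; 'side' is fixed)."""
    if view == "side":
        distance = geometry.h3 + geometry.h4
    elif view == "top":
        if geometry.h1 is None:
            raise RuntimeError("h1 not derived; call derive_h1 first")
        distance = geometry.h1
    else:
        raise ValueError("view must be 'top' or 'side'")
    return geometry.pixel_size * distance / geometry.focal_length
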