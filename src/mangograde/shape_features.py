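"""Size-shape parameters and Fourier-descriptor shape features.

The shape of a fruit silhouette is summarised two ways:

* **Size-shape parameters** from the mask geometry: aspect ratio
  (max/min Feret diameter), area ratio (area / aspect ratio) and roundness
  (4·area / (π·max diameter²); 1 for a circle).

* **Fourier descriptors** of the boundary: the centroid-distance signature
  R(k) of the closed clockwise contour is resampled to 512 points, rescaled
  so its maximum is 100, and Fourier-transformed. The magnitude spectrum
  |F(m)| is start-point and (after normalisation) scale invariant. The
  harmonic sums S_p = Σ_m |F(m)|·m^p over the first 10 harmonics weight the
  higher frequencies progressively — S1 behaves like the mean slope of the
  signature, S3 amplifies the short, sharp irregularities that mark a
  misshapen fruit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .silhouette import BoundaryTrace, MaskMeasures

__all__ = [
    "DistanceSignature",
    "NormalizedSignature",
    "FourierSpectrum",
    "ShapeFeatureVector",
    "centroid",
    "distance_signature",
    "normalize_signature",
    "fourier_magnitudes",
    "s_features",
    "size_shape",
    "features_from_boundary",
    "features_from_mask",
]

FEATURE_NAMES = ("aspect_ratio", "area_ratio", "roundness", "S1", "S2", "S3")


@dataclass(frozen=True)
class DistanceSignature:
    """Radial distances R(k) from the centroid to each boundary point."""

    values: np.ndarray
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("empty distance signature")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class NormalizedSignature:
    """Signature resampled to a fixed length and rescaled to max = 100."""

    values: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class FourierSpectrum:
    """Magnitudes |F(m)|, m = 0..M, of the normalised signature."""

    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        mags = np.asarray(self.magnitudes, dtype=float)
        if np.any(mags < 0):
            raise ValueError("magnitudes must be non-negative")
        object.__setattr__(self, "magnitudes", mags)


@dataclass(frozen=True)
class ShapeFeatureVector:
    """The six shape features used for regular/misshapen discrimination."""

    aspect_ratio: float
    area_ratio: float
    roundness: float
    S1: float
    S2: float
    S3: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def centroid(boundary: BoundaryTrace) -> tuple[float, float]:
    """Area-weighted centroid of the polygon enclosed by the boundary.

    Green's-theorem form: with signed area A = ½Σ(x_k·y_{k+1} − x_{k+1}·y_k),
    x_c = (1/6A)·Σ(x_k + x_{k+1})(x_k·y_{k+1} − x_{k+1}·y_k), and the y form
    symmetrically. Works for clockwise or counter-clockwise input.
    """
    x = boundary.x.astype(float)
    y = boundary.y.astype(float)
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * float(np.sum(cross))
    if abs(area) < 1e-12:
        raise ValueError("degenerate boundary: enclosed area is zero")
    cx = float(np.sum((x + x1) * cross)) / (6.0 * area)
    cy = float(np.sum((y + y1) * cross)) / (6.0 * area)
    return cx, cy


def distance_signature(
    boundary: BoundaryTrace, center: tuple[float, float] | None = None
) -> DistanceSignature:
    """Euclidean distance of each boundary point to the centroid, in order."""
    if center is None:
        center = centroid(boundary)
    cx, cy = center
    r = np.hypot(boundary.x - cx, boundary.y - cy)
    return DistanceSignature(values=r, centroid=(float(cx), float(cy)))


def normalize_signature(
    sig: DistanceSignature, n: int = 512, scale_to: float = 100.0
) -> NormalizedSignature:
    """Resample the signature to ``n`` points and rescale its max to ``scale_to``.

    Resampling is linear interpolation on the (periodic) boundary index, so
    fruit of different boundary lengths become comparable; the max-100
    rescaling removes overall size, leaving pure shape.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    v = sig.values
    m = len(v)
    # periodic linear interpolation over the closed boundary index
    src = np.arange(m + 1, dtype=float)
    vv = np.append(v, v[0])
    tgt = np.linspace(0.0, m, n, endpoint=False)
    res = np.interp(tgt, src, vv)
    peak = float(res.max())
    if peak <= 0:
        raise ValueError("signature is identically zero")
    scale = scale_to / peak
    return NormalizedSignature(values=res * scale, scale=scale)


def fourier_magnitudes(sig: NormalizedSignature, m_max: int | None = None) -> FourierSpectrum:
    """Magnitude spectrum |F(m)| of the normalised signature.

    |F(m)| = (1/N)·√[(Σ_k R(k)cos(2πmk/N))² + (Σ_k R(k)sin(2πmk/N))²],
    the DFT magnitude with the 1/N factor outside the square root, so a
    constant signature c has |F(0)| = c and a unit cosine has |F(1)| = ½.
    """
    v = sig.values
    n = len(v)
    if m_max is None:
        m_max = n // 2
    if m_max >= n:
        raise ValueError(f"m_max must be below the signature length {n}")
    spec = np.abs(np.fft.fft(v)) / n
    return FourierSpectrum(magnitudes=spec[: m_max + 1])


def s_features(spec: FourierSpectrum, h_max: int = 10) -> tuple[float, float, float]:
    """Harmonic sums S_p = Σ_{m=0}^{h_max} |F(m)|·m^p for p = 1, 2, 3.

    The m=0 (size) term vanishes; increasing p emphasises higher harmonics,
    so S3 reacts strongest to localised boundary irregularity.
    """
    mags = spec.magnitudes
    if len(mags) < h_max + 1:
        raise ValueError(f"spectrum covers m <= {len(mags) - 1}; need m <= {h_max}")
    m = np.arange(h_max + 1, dtype=float)
    f = mags[: h_max + 1]
    return tuple(float(np.sum(f * m**p)) for p in (1, 2, 3))


def size_shape(measures: MaskMeasures | dict) -> tuple[float, float, float]:
    """Aspect ratio, area ratio and roundness from mask measurements."""
    if isinstance(measures, MaskMeasures):
        area = measures.area_px
        max_d = measures.max_diameter_px
        min_d = measures.min_diameter_px
    else:
        area, max_d, min_d = measures["area"], measures["max_diameter"], measures["min_diameter"]
    if min_d <= 0 or max_d <= 0:
        raise ValueError("diameters must be positive")
    if area <= 0:
        raise ValueError("area must be positive")
    aspect = max_d / min_d
    area_ratio = area / aspect
    roundness = 4.0 * area / (np.pi * max_d**2)
    return aspect, area_ratio, roundness


def features_from_boundary(
    boundary: BoundaryTrace,
    measures: MaskMeasures,
    n_samples: int = 512,
    h_max: int = 10,
) -> ShapeFeatureVector:
    """Full shape feature vector for one silhouette."""
    aspect, area_ratio, roundness = size_shape(measures)
    sig = distance_signature(boundary)
    norm = normalize_signature(sig, n=n_samples)
    spec = fourier_magnitudes(norm, m_max=h_max)
    s1, s2, s3 = s_features(spec, h_max=h_max)
    return ShapeFeatureVector(
        aspect_ratio=aspect, area_ratio=area_ratio, roundness=roundness, S1=s1, S2=s2, S3=s3
    )


def features_from_mask(mask) -> ShapeFeatureVector:
    """Shape features straight from a single-component binary mask."""
    from .silhouette import extract_boundary, measure_mask

    return features_from_boundary(extract_boundary(mask), measure_mask(mask))
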