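"""Synthetic two-view fruit scenes with exact ground truth.

Real graded fruit are not shipped with the package, so every pipeline stage
is exercised against generated scenes instead. A fruit is modelled as a
solid with elliptical cross-sections along its length axis: the radius
profile is a tapered ovoid, r(t) ∝ √(1−t²)·(1+τ·t) on t ∈ [−1, 1], and
"misshapen" fruit add localised Gaussian lobes (bumps or dents) to the
top-view outline. The solid's top and side silhouettes are projected into
pixels through the same pinhole-scale model the calibration module inverts,
so segmentation → calibration → volume can be checked end to end. True
volume comes from fine numerical integration of the generative solid and
true mass from a linear density model, both exact by construction.

Rendered frames emulate the capture platform's composite image: white tray,
green fruit (low blue values), optional dark stem at the fruit tip, dark
specks (dirt), and a shadow band beside the side view, each with labelled
ground-truth pixels so the preprocessing steps can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CameraGeometry
from .volume_grading import MASS_INTERCEPT, MASS_SLOPE, assign_grade

__all__ = [
    "Lobe",
    "FruitSpec",
    "SceneTruth",
    "RenderedScene",
    "SyntheticDataset",
    "generate_fruit",
    "render_scene",
    "generate_dataset",
    "DEFAULT_VIEW_SHAPE",
]

#: (height, width) of each view; the composite frame is two views side by side.
DEFAULT_VIEW_SHAPE = (850, 800)

#: |lobe amplitude| above which a fruit counts as misshapen (mm).
MISSHAPEN_AMPLITUDE_MM = 2.0

# render colours (R, G, B); chosen so the segmentation thresholds in
# silhouette.py separate them: tray B high, fruit B in (20, 90) top / < 100
# side, stem B <= 20, shadow B in [100, 120).
_TRAY = (250, 249, 247)
_FRUIT_TOP = (150, 170, 60)
_FRUIT_SIDE = (110, 90, 70)
_STEM = (45, 40, 15)
_SPECK = (30, 25, 12)
_SHADOW = (120, 80, 110)
_SHADOW_RIM = (113, 88, 105)


@dataclass(frozen=True)
class Lobe:
    """Gaussian outline deformation: position t0 ∈ (−1, 1) along the length,
    signed amplitude in mm (+bump/−dent), width as a sigma on the t axis,
    applied to the upper (+y) or lower (−y) side of the top outline."""

    position: float
    amplitude_mm: float
    width: float
    side: int = 1  # +1 upper, -1 lower

    def __post_init__(self) -> None:
        if not -1.0 < self.position < 1.0:
            raise ValueError("lobe position must lie strictly inside (-1, 1)")
        if self.width <= 0:
            raise ValueError("lobe width must be positive")
        if self.side not in (-1, 1):
            raise ValueError("lobe side must be +1 or -1")


@dataclass(frozen=True)
class FruitSpec:
    """Geometric and density parameters of one generated fruit."""

    length: float = 130.0  # mm, major axis
    max_width: float = 81.0  # mm, top-view minor axis
    max_height: float = 65.0  # mm, side-view extent
    taper: float = 0.12  # ovoid asymmetry exponent tau
    lobes: tuple[Lobe, ...] = ()
    density_model: tuple[float, float] = (MASS_SLOPE, MASS_INTERCEPT)  # g/mL, g

    def __post_init__(self) -> None:
        if min(self.length, self.max_width, self.max_height) <= 0:
            raise ValueError("fruit dimensions must be positive")
        if self.max_width > self.length:
            raise ValueError("length must be the major axis (length >= max_width)")

    @property
    def is_misshapen(self) -> bool:
        return any(abs(l.amplitude_mm) > MISSHAPEN_AMPLITUDE_MM for l in self.lobes)

    @property
    def label(self) -> str:
        return "misshapen" if self.is_misshapen else "regular"


@dataclass
class SceneTruth:
    """Ground truth for one fruit: silhouettes, volume, mass and grade."""

    spec: FruitSpec
    geometry: CameraGeometry
    top_mask: np.ndarray
    side_mask: np.ndarray
    true_volume_ml: float
    true_mass_g: float
    mm_per_px_top: float
    mm_per_px_side: float

    @property
    def label(self) -> str:
        return self.spec.label

    @property
    def true_grade(self) -> str:
        return assign_grade(self.true_mass_g, self.label)


@dataclass
class RenderedScene:
    """A rendered composite frame plus per-artefact pixel labels."""

    image: np.ndarray  # H×W×3 uint8
    stem_mask: np.ndarray
    speck_mask: np.ndarray
    shadow_mask: np.ndarray
    top_region: tuple[int, int, int, int]  # (x0, y0, w, h)
    side_region: tuple[int, int, int, int]


def _profile(spec: FruitSpec, t: np.ndarray) -> np.ndarray:
    """Normalised tapered-ovoid radius profile, max value 1."""
    tt = np.clip(t, -1.0, 1.0)
    s = np.sqrt(np.clip(1.0 - tt**2, 0.0, None)) * (1.0 + spec.taper * tt)
    # normalise by the analytic maximum of sqrt(1-t^2)(1+tau t)
    tau = spec.taper
    if abs(tau) < 1e-12:
        smax = 1.0
    else:
        # stationary point of log s: -t/(1-t^2) + tau/(1+tau t) = 0
        roots = np.roots([2 * tau, 1.0, -tau])
        cand = [r.real for r in roots if abs(r.imag) < 1e-9 and -1 < r.real < 1]
        tstar = cand[0] if cand else 0.0
        smax = float(np.sqrt(1 - tstar**2) * (1 + tau * tstar))
    return s / smax


def _outline_halves(spec: FruitSpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower half-widths (mm) of the top outline at positions t."""
    prof = _profile(spec, t)
    base = 0.5 * spec.max_width * prof
    upper = base.copy()
    lower = base.copy()
    for lobe in spec.lobes:
        # lobes scale with the local profile so they vanish at the fruit tips
        bump = lobe.amplitude_mm * prof * np.exp(
            -0.5 * ((t - lobe.position) / lobe.width) ** 2
        )
        if lobe.side > 0:
            upper += bump
        else:
            lower += bump
    if np.any(upper < 0) or np.any(lower < 0):
        raise ValueError("lobe amplitude makes the outline radius negative")
    return upper, lower


def _side_half_height(spec: FruitSpec, t: np.ndarray) -> np.ndarray:
    return 0.5 * spec.max_height * _profile(spec, t)


def generate_fruit(
    spec: FruitSpec,
    seed: int | None = None,
    geometry: CameraGeometry | None = None,
    view_shape: tuple[int, int] = DEFAULT_VIEW_SHAPE,
    n_integration: int = 10_000,
) -> SceneTruth:
    """Build the ground-truth solid and project its two silhouettes.

    The top view is projected at the per-fruit object plane
    ``h1 = h2 − plane_fraction × fruit height`` and the side view at
    ``h3 + h4`` — the same scale model the calibration module applies in
    reverse, so a correct pipeline recovers millimetre dimensions exactly up
    to pixel quantisation. ``seed`` is accepted for interface symmetry; the
    projection itself is deterministic.
    """
    if geometry is None:
        geometry = CameraGeometry()
    h1 = geometry.h2 - geometry.plane_fraction * spec.max_height
    if h1 <= geometry.focal_length:
        raise ValueError("fruit too tall for the camera geometry")
    px_per_mm_top = geometry.focal_length / (geometry.pixel_size * h1)
    px_per_mm_side = geometry.focal_length / (geometry.pixel_size * (geometry.h3 + geometry.h4))

    # true volume: elliptical cross-sections, semi-axes = half of the
    # top-view column extent and the side half-height
    t = np.linspace(-1.0, 1.0, n_integration)
    upper, lower = _outline_halves(spec, t)
    hh = _side_half_height(spec, t)
    dx = spec.length / (n_integration - 1)
    semi_y = 0.5 * (upper + lower)
    v_mm3 = float(np.trapezoid(np.pi * semi_y * hh, dx=dx))
    true_volume_ml = v_mm3 / 1000.0
    slope, intercept = spec.density_model
    true_mass_g = slope * true_volume_ml + intercept

    vh, vw = view_shape
    cx, cy = vw / 2.0, vh / 2.0

    def rasterize(upper_mm, lower_mm, scale):
        xs = (np.arange(vw) - cx) / scale  # mm, per column
        ys = (np.arange(vh) - cy) / scale  # mm, per row (y down)
        tt = 2.0 * xs / spec.length
        inside_x = np.abs(tt) <= 1.0
        up = np.where(inside_x, np.interp(tt, t, upper_mm), -1.0)
        lo = np.where(inside_x, np.interp(tt, t, lower_mm), -1.0)
        return (ys[:, None] <= up[None, :]) & (ys[:, None] >= -lo[None, :])

    top_mask = rasterize(upper, lower, px_per_mm_top)
    side_mask = rasterize(hh, hh, px_per_mm_side)
    return SceneTruth(
        spec=spec,
        geometry=geometry,
        top_mask=top_mask,
        side_mask=side_mask,
        true_volume_ml=true_volume_ml,
        true_mass_g=true_mass_g,
        mm_per_px_top=1.0 / px_per_mm_top,
        mm_per_px_side=1.0 / px_per_mm_side,
    )


def render_scene(
    truth: SceneTruth,
    noise: dict | None = None,
    seed: int | None = None,
) -> RenderedScene:
    """Compose the two views into one white-tray frame with optional artefacts.

    ``noise`` keys: ``stem`` (bool), ``specks`` (int count), ``shadow``
    (bool). Stem pixels get near-black colour (B ≤ 20), specks are small
    dark components inside and outside the fruit, and the shadow is a band
    hugging one side of the side-view silhouette, darker than the tray but
    lighter than the fruit in the blue channel.
    """
    noise = dict(noise or {})
    rng = np.random.default_rng(seed)
    vh, vw = truth.top_mask.shape
    frame = np.empty((vh, 2 * vw, 3), dtype=np.uint8)
    frame[:, :] = _TRAY
    stem_mask = np.zeros(frame.shape[:2], dtype=bool)
    speck_mask = np.zeros_like(stem_mask)
    shadow_mask = np.zeros_like(stem_mask)

    top = truth.top_mask
    side = truth.side_mask
    frame[:, :vw][top] = _FRUIT_TOP
    frame[:, vw:][side] = _FRUIT_SIDE

    if noise.get("shadow", False):
        # band extending a few mm to the right of the side silhouette
        width_px = max(3, int(round(6.0 / truth.mm_per_px_side)))
        sh = np.zeros_like(side)
        for k in range(1, width_px + 1):
            sh[:, k:] |= side[:, :-k]
        sh &= ~side
        rim = np.zeros_like(sh)
        for k in range(1, 3):
            rim[:, k:] |= sh[:, :-k]
        rim &= ~sh & ~side
        frame[:, vw:][sh] = _SHADOW
        frame[:, vw:][rim] = _SHADOW_RIM
        shadow_mask[:, vw:] = sh | rim

    if noise.get("stem", False):
        # short dark stalk protruding from the fruit tip in the top view
        cols = np.flatnonzero(top.any(axis=0))
        tip = cols[-1]
        rows = np.flatnonzero(top[:, tip])
        r0 = int(rows.mean())
        stem_len = max(4, int(round(10.0 / truth.mm_per_px_top)))
        stem_w = max(2, int(round(3.0 / truth.mm_per_px_top)))
        r_lo, r_hi = r0 - stem_w // 2, r0 + (stem_w + 1) // 2
        c_hi = min(vw, tip + 1 + stem_len)
        stem = np.zeros_like(top)
        stem[r_lo:r_hi, tip + 1 : c_hi] = True
        stem &= ~top
        frame[:, :vw][stem] = _STEM
        stem_mask[:, :vw] = stem

    n_specks = int(noise.get("specks", 0))
    if n_specks:
        h, w = frame.shape[:2]
        for _ in range(n_specks):
            r = int(rng.integers(5, h - 5))
            c = int(rng.integers(5, w - 5))
            rad = int(rng.integers(1, 4))
            yy, xx = np.ogrid[-rad : rad + 1, -rad : rad + 1]
            disc = yy**2 + xx**2 <= rad**2
            sl = (slice(r - rad, r + rad + 1), slice(c - rad, c + rad + 1))
            speck_mask[sl] |= disc
        speck_mask &= ~stem_mask
        frame[speck_mask] = _SPECK

    return RenderedScene(
        image=frame,
        stem_mask=stem_mask,
        speck_mask=speck_mask,
        shadow_mask=shadow_mask,
        top_region=(0, 0, vw, vh),
        side_region=(vw, 0, vw, vh),
    )


@dataclass
class SyntheticDataset:
    """A reproducible batch of fruit specs with an eager truth table.

    Scenes are regenerated on demand from the stored specs and per-fruit
    seeds rather than held in memory (a rendered frame is ~4 MB).
    """

    specs: list[FruitSpec]
    seeds: list[int]
    geometry: CameraGeometry
    noise: dict
    truth_table: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.specs)

    def truth(self, i: int) -> SceneTruth:
        return generate_fruit(self.specs[i], seed=self.seeds[i], geometry=self.geometry)

    def scene(self, i: int) -> RenderedScene:
        return render_scene(self.truth(i), noise=self.noise, seed=self.seeds[i])


def _draw_spec(rng: np.random.Generator, misshapen: bool, effect_profile: dict) -> FruitSpec:
    # redraw until the lobes leave the outline non-negative (a deep dent near
    # the tapered tip can otherwise push the half-width below zero)
    for _ in range(100):
        spec = _draw_spec_once(rng, misshapen, effect_profile)
        try:
            _outline_halves(spec, np.linspace(-1.0, 1.0, 512))
        except ValueError:
            continue
        return spec
    raise RuntimeError("could not draw a valid fruit spec")


def _draw_spec_once(rng: np.random.Generator, misshapen: bool, effect_profile: dict) -> FruitSpec:
    # elongated ovoid population: aspect ratio ~1.6, masses ~280-470 g so all
    # three commercial grades occur
    length = float(np.clip(rng.normal(132.0, 10.0), 105.0, 150.0))
    width = float(np.clip(rng.normal(0.62, 0.03), 0.52, 0.72)) * length
    height = float(np.clip(rng.normal(0.80, 0.04), 0.68, 0.92)) * width
    taper = float(np.clip(rng.normal(0.12, 0.04), 0.0, 0.25))
    lobes: list[Lobe] = []
    if misshapen:
        amp_lo, amp_hi = effect_profile.get("amplitude_mm", (4.0, 9.0))
        for _ in range(int(rng.integers(1, 4))):
            amp = float(rng.uniform(amp_lo, amp_hi)) * (1 if rng.random() < 0.7 else -1)
            lobes.append(
                Lobe(
                    position=float(rng.uniform(-0.7, 0.7)),
                    amplitude_mm=amp,
                    width=float(rng.uniform(0.08, 0.2)),
                    side=int(rng.choice([-1, 1])),
                )
            )
    return FruitSpec(
        length=length, max_width=width, max_height=height, taper=taper, lobes=tuple(lobes)
    )


def generate_dataset(
    n_regular: int = 159,
    n_misshapen: int = 21,
    effect_profile: dict | None = None,
    seed: int = 0,
    geometry: CameraGeometry | None = None,
    noise: dict | None = None,
    ref_volume_sigma: float = 5.0,
) -> SyntheticDataset:
    """Draw a labelled fruit population and its truth table.

    Defaults mirror the study population: 159 regular and 21 misshapen
    fruit, with dimensions spanning masses of roughly 280–470 g so all
    three commercial grades occur. Misshapen fruit draw 1–3 lobes of
    4–9 mm, which raises S1–S3 well above the regular cohort.

    Besides the exact ``true_volume_ml``, the truth table carries
    ``measured_volume_ml``: the exact volume plus Gaussian reading noise of
    ``ref_volume_sigma`` mL, emulating a water-displacement reference read
    off a laboratory beaker — the reference a method-agreement study
    compares an image-based estimate against.
    """
    if n_regular < 0 or n_misshapen < 0:
        raise ValueError("counts must be >= 0")
    if geometry is None:
        geometry = CameraGeometry()
    effect_profile = dict(effect_profile or {})
    rng = np.random.default_rng(seed)
    flags = [False] * n_regular + [True] * n_misshapen
    rng.shuffle(flags)
    specs = [_draw_spec(rng, f, effect_profile) for f in flags]
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=len(specs))]
    rows = []
    for i, spec in enumerate(specs):
        truth = generate_fruit(spec, seed=seeds[i], geometry=geometry)
        rows.append(
            {
                "id": f"fruit{i:04d}",
                "class": spec.label,
                "length_mm": spec.length,
                "max_width_mm": spec.max_width,
                "max_height_mm": spec.max_height,
                "true_volume_ml": truth.true_volume_ml,
                "measured_volume_ml": truth.true_volume_ml
                + float(rng.normal(0.0, ref_volume_sigma)),
                "true_mass_g": truth.true_mass_g,
                "grade": truth.true_grade,
            }
        )
    table = pd.DataFrame(rows, columns=[
        "id", "class", "length_mm", "max_width_mm", "max_height_mm",
        "true_volume_ml", "measured_volume_ml", "true_mass_g", "grade",
    ])
    return SyntheticDataset(
        specs=specs, seeds=seeds, geometry=geometry, noise=dict(noise or {}), truth_table=table
    )
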