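"""End-to-end grading runs: segment → calibrate → classify → volume → grade.

One :class:`RunConfig` carries everything a run needs (camera geometry,
thresholds, the discriminant model, grade boundaries), and
:func:`grade_batch` applies the full stage order to each composite frame:
split the two views, segment each, calibrate pixels to millimetres from the
side-view height, compute shape features from the top-view boundary,
classify regular vs misshapen, and for regular fruit estimate volume by the
disk method, convert to mass and assign the grade. Misshapen fruit are
rejected immediately and get no volume or mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import shape_classifier as sc
from . import shape_features as sf
from . import silhouette as sil
from . import volume_grading as vg

__all__ = ["RunConfig", "FruitResult", "process_frame", "grade_batch", "train"]


@dataclass
class RunConfig:
    """Parameters of a grading run; round-trips through YAML unchanged."""

    geometry: cal.CameraGeometry = field(default_factory=cal.CameraGeometry)
    split_x: int | None = None  # view boundary column; None = frame midpoint
    bg_thresh: int = 90
    stem_range: tuple[int, int] = (0, 20)
    side_params: tuple[tuple[str, int], ...] = (("B", 120), ("G", 110), ("B", 100))
    median_size: int = 7
    min_area: int | None = None  # None = scale with frame area
    model_path: str | None = None  # None = builtin published coefficients
    classify_shapes: bool = True  # False grades every fruit as regular
    f_enter: float = 3.84
    f_remove: float = 2.71
    seed: int = 0

    def model(self) -> sc.DiscriminantModel:
        if self.model_path is None:
            return sc.default_model()
        return sc.DiscriminantModel.from_json(self.model_path)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["geometry"] = {k: v for k, v in asdict(self.geometry).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        geom = d.pop("geometry", {})
        if isinstance(geom, dict):
            geom.pop("h1", None)
            # accept *_mm suffixed keys from hand-written configs
            geom = {k.removesuffix("_mm"): v for k, v in geom.items()}
            d["geometry"] = cal.CameraGeometry(**geom)
        if "stem_range" in d:
            d["stem_range"] = tuple(d["stem_range"])
        if "side_params" in d:
            d["side_params"] = tuple((str(c), int(t)) for c, t in d["side_params"])
        return cls(**d)


@dataclass
class FruitResult:
    """Per-fruit outcome row of a grading run."""

    id: str
    shape_class: str
    volume_ml: float | None
    mass_g: float | None
    grade: str
    length_mm: float | None = None
    width_mm: float | None = None
    height_mm: float | None = None
    error: str | None = None

    def as_row(self) -> dict:
        return asdict(self)


def _segment_view(mask: np.ndarray, min_area: int | None) -> np.ndarray:
    cleaned = sil.remove_small_particles(mask, min_area)
    return sil.fill_holes(cleaned)


def process_frame(image: np.ndarray, config: RunConfig, fruit_id: str = "fruit") -> FruitResult:
    """Run the full grading pipeline on one composite two-view frame."""
    h, w = np.asarray(image).shape[:2]
    layout = sil.ViewLayout.halves(w, h, config.split_x)
    top_img, side_img = sil.split_views(image, layout)

    min_area = config.min_area or sil.default_min_area((h, w))
    top_mask = _segment_view(
        sil.threshold_top(sil.to_gray_b(top_img), config.bg_thresh, config.stem_range), min_area
    )
    side_mask = _segment_view(
        sil.threshold_side(side_img, config.side_params, config.median_size), min_area
    )

    # calibrate: fruit height from the fixed-scale side view, then the
    # per-fruit top-view plane
    side_meas = sil.measure_mask(side_mask)
    # fruit height = vertical bounding-box extent of the side silhouette
    # (the caliper-style maximum height of a fruit resting on the tray)
    height_px = side_meas.bbox[2] - side_meas.bbox[0]
    height_mm = cal.side_view_size(height_px, config.geometry)
    geom = cal.derive_h1(height_mm, config.geometry)
    mm_top = cal.mm_per_pixel(geom, "top")
    mm_side = cal.mm_per_pixel(geom, "side")

    top_meas = sil.measure_mask(top_mask)
    length_mm = top_meas.max_diameter_px * mm_top
    width_mm = top_meas.min_diameter_px * mm_top

    boundary = sil.extract_boundary(top_mask)
    features = sf.features_from_boundary(boundary, top_meas)

    if config.classify_shapes:
        shape_class = sc.classify(features, config.model())
    else:
        shape_class = "regular"

    if shape_class == "misshapen":
        return FruitResult(
            id=fruit_id, shape_class=shape_class, volume_ml=None, mass_g=None,
            grade="Rejected", length_mm=length_mm, width_mm=width_mm, height_mm=height_mm,
        )
    profiles = vg.slice_profiles(top_mask, side_mask, mm_top, mm_side)
    volume = vg.disk_volume(profiles)
    mass = vg.estimate_mass(volume)
    grade = vg.assign_grade(mass, shape_class)
    return FruitResult(
        id=fruit_id, shape_class=shape_class, volume_ml=volume, mass_g=mass,
        grade=grade, length_mm=length_mm, width_mm=width_mm, height_mm=height_mm,
    )


def grade_batch(
    images: Sequence,
    config: RunConfig | None = None,
    ids: Sequence[str] | None = None,
    out_csv: str | Path | None = None,
    out_json: str | Path | None = None,
) -> pd.DataFrame:
    """Grade a batch of frames (paths or arrays); one row per input.

    A frame that fails to process contributes an error row instead of
    aborting the run, so every input yields exactly one report row.
    """
    if config is None:
        config = RunConfig()
    rows = []
    for i, item in enumerate(images):
        fruit_id = ids[i] if ids is not None else (
            Path(item).stem if isinstance(item, (str, Path)) else f"fruit{i:04d}"
        )
        try:
            if isinstance(item, (str, Path)):
                import imageio.v3 as iio

                arr = iio.imread(item)
                if arr.ndim == 3 and arr.shape[2] == 4:
                    arr = arr[:, :, :3]
            else:
                arr = np.asarray(item)
            rows.append(process_frame(arr, config, fruit_id).as_row())
        except Exception as exc:  # per-item failure: record and continue
            rows.append(
                FruitResult(
                    id=fruit_id, shape_class="error", volume_ml=None, mass_g=None,
                    grade="error", error=str(exc),
                ).as_row()
            )
    report = pd.DataFrame(rows)
    if out_csv is not None:
        report.to_csv(out_csv, index=False, float_format="%.2f")
    if out_json is not None:
        summary = {
            "n": len(report),
            "n_errors": int((report["shape_class"] == "error").sum()),
            "grades": report["grade"].value_counts().to_dict(),
            "results": report.to_dict(orient="records"),
        }
        Path(out_json).write_text(json.dumps(summary, indent=2, default=float))
    return report


def train(
    features: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    model_out: str | Path | None = None,
) -> tuple[sc.DiscriminantModel, sc.StepwiseTrace]:
    """Stepwise-select features then fit classification functions.

    ``features`` is a table (or CSV path) with the six shape-feature columns
    and a ``label`` column of ``regular``/``misshapen``.
    """
    if config is None:
        config = RunConfig()
    if isinstance(features, (str, Path)):
        features = pd.read_csv(features)
    if "label" not in features.columns:
        raise ValueError("training table needs a 'label' column")
    y = features["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    feat_cols = [c for c in sf.FEATURE_NAMES if c in features.columns]
    if len(feat_cols) < 2:
        raise ValueError("training table needs at least two shape-feature columns")
    X = features[feat_cols]
    selected, trace = sc.stepwise_select(
        X, y, f_enter=config.f_enter, f_remove=config.f_remove
    )
    if not selected:
        raise ValueError("stepwise selection retained no features; cannot fit a model")
    model = sc.fit_classification_functions(features[selected], y)
    if model_out is not None:
        model.to_json(model_out)
    return model, trace
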