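"""Fisher linear classification of fruit shape (regular vs misshapen).

Each class c gets a linear classification function

    score_c(x) = const_c + Σ_f coeff_{c,f} · x_f

and the fruit is assigned to the class with the larger score. The shipped
default model carries the published Harumanis coefficients over
(S1, S2, S3, area_ratio), so classification works out of the box; the module
can also refit the functions from labelled feature tables and run stepwise
feature selection driven by Wilks' Lambda, the det(within)/det(total)
scatter ratio that shrinks as group separation grows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .shape_features import ShapeFeatureVector

__all__ = [
    "DiscriminantModel",
    "StepwiseStep",
    "StepwiseTrace",
    "default_model",
    "discriminant_scores",
    "classify",
    "fit_classification_functions",
    "wilks_lambda",
    "stepwise_select",
    "confusion_report",
    "ConfusionReport",
]


@dataclass(frozen=True)
class DiscriminantModel:
    """Per-class linear classification functions.

    ``coefficients[c]`` maps feature name → weight; ``constants[c]`` is the
    intercept. Class order matters: ties break to the first listed class.
    """

    classes: tuple[str, ...]
    coefficients: Mapping[str, Mapping[str, float]]
    constants: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least two classes")
        feats = [tuple(sorted(self.coefficients[c])) for c in self.classes]
        if len(set(feats)) != 1:
            raise ValueError("all classes must share one feature set")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.coefficients[self.classes[0]].keys())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "coefficients": {c: dict(self.coefficients[c]) for c in self.classes},
            "constants": dict(self.constants),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscriminantModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(payload["classes"]),
            coefficients=payload["coefficients"],
            constants=payload["constants"],
        )


def default_model() -> DiscriminantModel:
    """The published Harumanis classification functions (S-features + area ratio)."""
    return DiscriminantModel(
        classes=("regular", "misshapen"),
        coefficients={
            "regular": {"S1": 24.96, "S2": -8.95, "S3": 0.78, "area_ratio": 0.34},
            "misshapen": {"S1": 22.05, "S2": -6.97, "S3": 0.59, "area_ratio": 0.37},
        },
        constants={"regular": -198.85, "misshapen": -228.38},
    )


def _feature_value(features, name: str) -> float:
    if isinstance(features, ShapeFeatureVector):
        features = features.as_dict()
    if name not in features:
        raise KeyError(f"feature {name!r} missing from input")
    return float(features[name])


def discriminant_scores(features, model: DiscriminantModel) -> dict[str, float]:
    """Evaluate every class's classification function at the feature vector."""
    scores = {}
    for c in model.classes:
        s = float(model.constants[c])
        for name, coef in model.coefficients[c].items():
            s += float(coef) * _feature_value(features, name)
        scores[c] = s
    return scores


def classify(features, model: DiscriminantModel | None = None) -> str:
    """Assign the class with the highest score; ties go to the first class."""
    if model is None:
        model = default_model()
    scores = discriminant_scores(features, model)
    best = model.classes[0]
    for c in model.classes[1:]:
        if scores[c] > scores[best]:
            best = c
    return best


def _as_matrix(X, feature_names: Sequence[str] | None):
    if isinstance(X, pd.DataFrame):
        names = list(feature_names) if feature_names is not None else list(X.columns)
        return X[names].to_numpy(dtype=float), names
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D")
    if feature_names is None:
        names = [f"x{i}" for i in range(arr.shape[1])]
    else:
        names = list(feature_names)
    return arr, names


def fit_classification_functions(
    X,
    y: Sequence[str],
    feature_names: Sequence[str] | None = None,
    priors: Mapping[str, float] | None = None,
) -> DiscriminantModel:
    """Fit Fisher classification functions from a labelled feature table.

    With pooled within-class covariance W and class means μ_c, the function
    for class c has coefficients W⁻¹μ_c and constant −½μ_cᵀW⁻¹μ_c + log π_c
    (equal priors π_c by default). Classes are ordered with "regular" first
    when present, otherwise by first appearance.
    """
    arr, names = _as_matrix(X, feature_names)
    y = np.asarray(y)
    if len(y) != len(arr):
        raise ValueError("X and y lengths differ")
    labels = list(dict.fromkeys(y.tolist()))
    if "regular" in labels:
        labels = ["regular"] + [c for c in labels if c != "regular"]
    if len(labels) < 2:
        raise ValueError("need at least two classes to fit")
    n, p = arr.shape
    g = len(labels)
    means = {}
    W = np.zeros((p, p))
    for c in labels:
        sub = arr[y == c]
        if len(sub) < 2:
            raise ValueError(f"class {c!r} needs at least 2 samples")
        mu = sub.mean(axis=0)
        means[c] = mu
        W += (sub - mu).T @ (sub - mu)
    W /= n - g  # pooled within-class covariance
    try:
        Winv = np.linalg.inv(W)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular; drop collinear features"
        ) from exc
    if priors is None:
        priors = {c: 1.0 / g for c in labels}
    coefficients = {}
    constants = {}
    for c in labels:
        b = Winv @ means[c]
        coefficients[c] = {name: float(v) for name, v in zip(names, b)}
        constants[c] = float(-0.5 * means[c] @ b + np.log(priors[c]))
    return DiscriminantModel(
        classes=tuple(labels), coefficients=coefficients, constants=constants
    )


def wilks_lambda(X, y, features: Sequence[str] | Sequence[int] | None = None) -> float:
    """Wilks' Λ = det(W)/det(T) for a feature subset.

    W is the within-group and T the total scatter matrix; Λ near 1 means the
    groups are indistinguishable on this subset, Λ near 0 means separation.
    """
    if isinstance(X, pd.DataFrame) and features is not None:
        arr = X[list(features)].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if features is not None:
            arr = arr[:, list(features)]
    if arr.shape[1] == 0:
        raise ValueError("feature subset is empty")
    y = np.asarray(y)
    grand = arr.mean(axis=0)
    T = (arr - grand).T @ (arr - grand)
    W = np.zeros_like(T)
    for c in np.unique(y):
        sub = arr[y == c]
        mu = sub.mean(axis=0)
        W += (sub - mu).T @ (sub - mu)
    detT = np.linalg.det(T)
    if abs(detT) < 1e-300:
        raise np.linalg.LinAlgError("total scatter matrix is singular")
    return float(np.linalg.det(W) / detT)


@dataclass(frozen=True)
class StepwiseStep:
    action: str  # "enter" | "remove"
    feature: str
    wilks: float
    f_statistic: float


@dataclass(frozen=True)
class StepwiseTrace:
    steps: tuple[StepwiseStep, ...] = field(default_factory=tuple)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": i + 1,
                    "action": s.action,
                    "feature": s.feature,
                    "wilks_lambda": s.wilks,
                    "F": s.f_statistic,
                }
                for i, s in enumerate(self.steps)
            ]
        )


def _partial_f(lam_without: float, lam_with: float, n: int, g: int, p_with: int) -> float:
    """Partial F for the variable whose presence changes Λ_without → Λ_with."""
    if lam_with <= 0:
        return np.inf
    ratio = lam_without / lam_with
    return (ratio - 1.0) * (n - g - p_with + 1) / (g - 1)


def stepwise_select(
    X,
    y,
    feature_names: Sequence[str] | None = None,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_steps: int = 100,
) -> tuple[list[str], StepwiseTrace]:
    """Stepwise feature selection by minimising Wilks' Λ.

    At each step the candidate whose entry most reduces Λ enters if its
    partial F exceeds ``f_enter``; then any in-model feature whose partial F
    has fallen below ``f_remove`` leaves. Stops when no change occurs.
    """
    arr, names = _as_matrix(X, feature_names)
    y = np.asarray(y)
    n = len(arr)
    g = len(np.unique(y))
    if arr.shape[1] < 2:
        raise ValueError("need at least two candidate features")
    df = pd.DataFrame(arr, columns=names)
    selected: list[str] = []
    steps: list[StepwiseStep] = []
    for _ in range(max_steps):
        changed = False
        # --- entry ---
        lam_cur = wilks_lambda(df, y, selected) if selected else 1.0
        best = None
        for cand in names:
            if cand in selected:
                continue
            lam_new = wilks_lambda(df, y, selected + [cand])
            f_stat = _partial_f(lam_cur, lam_new, n, g, len(selected) + 1)
            if f_stat >= f_enter and (best is None or lam_new < best[1]):
                best = (cand, lam_new, f_stat)
        if best is not None:
            selected.append(best[0])
            steps.append(StepwiseStep("enter", best[0], best[1], best[2]))
            changed = True
        # --- removal ---
        while len(selected) > 1:
            lam_full = wilks_lambda(df, y, selected)
            worst = None
            for feat in selected:
                rest = [f for f in selected if f != feat]
                lam_rest = wilks_lambda(df, y, rest)
                f_stat = _partial_f(lam_rest, lam_full, n, g, len(selected))
                if f_stat < f_remove and (worst is None or f_stat < worst[1]):
                    worst = (feat, f_stat)
            if worst is None:
                break
            selected.remove(worst[0])
            lam_after = wilks_lambda(df, y, selected) if selected else 1.0
            steps.append(StepwiseStep("remove", worst[0], lam_after, worst[1]))
            changed = True
        if not changed:
            break
    return selected, StepwiseTrace(tuple(steps))


@dataclass(frozen=True)
class ConfusionReport:
    """Confusion matrix with per-class and overall percent correct."""

    matrix: pd.DataFrame  # rows = actual, columns = predicted (counts)
    per_class_pct: dict[str, float]
    overall_pct: float

    def __str__(self) -> str:
        lines = ["From/To\t" + "\t".join(str(c) for c in self.matrix.columns) + "\tTotal\tPercentage"]
        for label, row in self.matrix.iterrows():
            total = int(row.sum())
            lines.append(
                f"{label}\t" + "\t".join(str(int(v)) for v in row) + f"\t{total}\t{self.per_class_pct[label]:.1f}%"
            )
        lines.append(f"Overall\t\t\t{int(self.matrix.to_numpy().sum())}\t{self.overall_pct:.1f}%")
        return "\n".join(lines)


def confusion_report(y_true: Sequence, y_pred: Sequence) -> ConfusionReport:
    """Counts plus per-class and overall percent correct, one decimal."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    labels = list(dict.fromkeys(list(y_true) + list(y_pred)))
    mat = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    per_class = {}
    for c in labels:
        row_total = int(mat.loc[c].sum())
        per_class[c] = round(100.0 * mat.loc[c, c] / row_total, 1) if row_total else float("nan")
    total = int(mat.to_numpy().sum())
    correct = int(np.trace(mat.to_numpy()))
    overall = round(100.0 * correct / total, 1) if total else float("nan")
    return ConfusionReport(matrix=mat, per_class_pct=per_class, overall_pct=overall)
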