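"""The SVM/KNN classifier zoo over superpixel color features.

Twelve classifier variants — six support-vector machines (linear, quadratic,
cubic, and three Gaussian-kernel scales) and six K-nearest-neighbor variants
(k = 1/10/100, cosine and Minkowski-3 metrics, distance weighting) — are
scored by stratified cross-validation on labeled superpixel records, and the
most accurate one is used to predict a binary spike mask.  A pixel-wise
Otsu-threshold baseline on the Eg and Dgr planes is provided as the
non-superpixel control.

Features are standardized to zero mean / unit SD inside each training fold;
the Gaussian kernel scales are expressed in units of sqrt(P), P being the
number of predictors, so standardization is what makes them meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from skimage.filters import threshold_otsu

from .features import FeatureMaps
from .superpixels import SuperpixelMap, SuperpixelRecord

__all__ = [
    "ClassifierSpec",
    "CVReport",
    "TrainedModel",
    "build_zoo",
    "train_and_score",
    "select_best",
    "fit_model",
    "predict_mask",
    "baseline_threshold_segment",
]

DEFAULT_FEATURES = ("mean_Eg", "mean_Dgr")


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier variant.

    ``kernel_scale_factor`` multiplies sqrt(P) at fit time for Gaussian
    SVMs (P = number of predictors); it is None for every other family
    member.
    """

    code: str
    family: str  # "SVM" | "KNN"
    kernel_or_metric: str
    kernel_scale_factor: float | None = None
    n_neighbors: int | None = None
    weighting: str = "uniform"

    def make_estimator(self, n_features: int):
        """Instantiate the sklearn estimator (standardized-feature space)."""
        if self.family == "SVM":
            if self.kernel_or_metric == "linear":
                return SVC(kernel="linear", C=1.0)
            if self.kernel_or_metric == "poly-2":
                return SVC(kernel="poly", degree=2, gamma=1.0, coef0=1.0, C=1.0)
            if self.kernel_or_metric == "poly-3":
                return SVC(kernel="poly", degree=3, gamma=1.0, coef0=1.0, C=1.0)
            if self.kernel_or_metric == "gaussian":
                scale = self.kernel_scale_factor * np.sqrt(n_features)
                return SVC(kernel="rbf", gamma=1.0 / scale**2, C=1.0)
            raise ValueError(f"unknown SVM kernel {self.kernel_or_metric!r}")
        if self.family == "KNN":
            metric_kwargs = {
                "euclidean": dict(metric="euclidean"),
                "cosine": dict(metric="cosine"),
                "minkowski-3": dict(metric="minkowski", p=3),
            }[self.kernel_or_metric]
            return KNeighborsClassifier(
                n_neighbors=self.n_neighbors, weights=self.weighting, **metric_kwargs
            )
        raise ValueError(f"unknown family {self.family!r}")


def build_zoo() -> list[ClassifierSpec]:
    """The twelve classifier variants, in canonical listing order."""
    return [
        ClassifierSpec("linSVM", "SVM", "linear"),
        ClassifierSpec("quaSVM", "SVM", "poly-2"),
        ClassifierSpec("cubSVM", "SVM", "poly-3"),
        ClassifierSpec("finGSVM", "SVM", "gaussian", kernel_scale_factor=0.25),
        ClassifierSpec("medGSVM", "SVM", "gaussian", kernel_scale_factor=1.0),
        ClassifierSpec("coaGSVM", "SVM", "gaussian", kernel_scale_factor=4.0),
        ClassifierSpec("finKNN", "KNN", "euclidean", n_neighbors=1),
        ClassifierSpec("medKNN", "KNN", "euclidean", n_neighbors=10),
        ClassifierSpec("coaKNN", "KNN", "euclidean", n_neighbors=100),
        ClassifierSpec("cosKNN", "KNN", "cosine", n_neighbors=10),
        ClassifierSpec("cubKNN", "KNN", "minkowski-3", n_neighbors=10),
        ClassifierSpec(
            "weiKNN", "KNN", "euclidean", n_neighbors=10, weighting="distance"
        ),
    ]


ZOO_ORDER = tuple(s.code for s in build_zoo())


@dataclass(frozen=True)
class CVReport:
    """Cross-validation accuracies for one classifier spec."""

    spec_code: str
    fold_accuracies: tuple[float, ...]
    n_samples: int
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class TrainedModel:
    """A fitted classifier together with its standardization state."""

    spec_code: str
    pipeline: Pipeline  # StandardScaler + estimator, fitted
    feature_names: tuple[str, ...] = DEFAULT_FEATURES

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(X)


def _design_matrix(
    records: list[SuperpixelRecord], feature_names: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[getattr(r, f) for f in feature_names] for r in records])
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise ValueError("all records must carry labels; run assign_labels first")
    return X, np.asarray(labels, dtype=int)


def _make_pipeline(spec: ClassifierSpec, n_features: int) -> Pipeline:
    return Pipeline(
        [("scale", StandardScaler()), ("clf", spec.make_estimator(n_features))]
    )


def train_and_score(
    records: list[SuperpixelRecord],
    spec: ClassifierSpec,
    n_folds: int = 5,
    seed: int = 0,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
) -> CVReport:
    """Stratified k-fold cross-validation accuracy of one spec.

    Standardization is fitted inside each training fold (no leakage into the
    held-out fold).  Deterministic for a fixed seed.
    """
    X, y = _design_matrix(records, feature_names)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(
            f"training set contains a single class ({classes[0]}); "
            "both spike and background superpixels are required"
        )
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; "
            f"need at least n_folds = {n_folds} per class"
        )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pipe = _make_pipeline(spec, X.shape[1])
    accs = []
    for train_idx, test_idx in cv.split(X, y):
        fold = clone(pipe)
        fold.fit(X[train_idx], y[train_idx])
        accs.append(float(fold.score(X[test_idx], y[test_idx])))
    return CVReport(
        spec_code=spec.code,
        fold_accuracies=tuple(accs),
        n_samples=len(y),
        seed=seed,
    )


def resubstitution_accuracy(
    records: list[SuperpixelRecord],
    spec: ClassifierSpec,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
) -> float:
    """Apparent (training-set) accuracy; diagnostic only."""
    X, y = _design_matrix(records, feature_names)
    pipe = _make_pipeline(spec, X.shape[1])
    pipe.fit(X, y)
    return float(pipe.score(X, y))


def select_best(reports: list[CVReport]) -> str:
    """Spec code with maximal mean accuracy; ties go to the earlier zoo entry."""
    if not reports:
        raise ValueError("no reports to select from")
    order = {code: i for i, code in enumerate(ZOO_ORDER)}
    best = max(
        reports,
        key=lambda r: (r.mean_accuracy, -order.get(r.spec_code, len(order))),
    )
    return best.spec_code


def fit_model(
    records: list[SuperpixelRecord],
    spec: ClassifierSpec,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
) -> TrainedModel:
    """Fit a spec on the full labeled record set."""
    X, y = _design_matrix(records, feature_names)
    if len(np.unique(y)) < 2:
        raise ValueError("cannot fit on a single-class training set")
    pipe = _make_pipeline(spec, X.shape[1])
    pipe.fit(X, y)
    return TrainedModel(spec_code=spec.code, pipeline=pipe, feature_names=feature_names)


def predict_mask(
    model: TrainedModel,
    records: list[SuperpixelRecord],
    spmap: SuperpixelMap,
) -> np.ndarray:
    """Predict per-superpixel labels and paint them back to a pixel mask."""
    missing = [f for f in model.feature_names if not hasattr(records[0], f)]
    if missing:
        raise ValueError(f"records lack features required by the model: {missing}")
    X = np.array([[getattr(r, f) for f in model.feature_names] for r in records])
    pred = model.predict(X).astype(bool)
    lut = np.zeros(spmap.n_segments, dtype=bool)
    for r, p in zip(records, pred):
        lut[r.segment_id] = p
    return lut[spmap.segment_ids]


def baseline_threshold_segment(
    features: FeatureMaps, combine: str = "intersection"
) -> np.ndarray:
    """Pixel-wise control: automatic (Otsu) thresholds on Eg and Dgr.

    Each plane is thresholded independently at its Otsu value; the two
    binary masks are superimposed — by default intersected, since Eg alone
    cannot reject leaf pixels.  A constant plane has no threshold and yields
    an all-background mask with a warning.
    """
    if combine not in ("intersection", "union"):
        raise ValueError("combine must be 'intersection' or 'union'")
    masks = []
    for name in ("Eg", "Dgr"):
        plane = features.plane(name)
        if np.ptp(plane) == 0:
            warnings.warn(
                f"{name} plane is constant; threshold undefined, mask empty",
                stacklevel=2,
            )
            masks.append(np.zeros(plane.shape, dtype=bool))
            continue
        masks.append(plane > threshold_otsu(plane))
    if combine == "intersection":
        return masks[0] & masks[1]
    return masks[0] | masks[1]
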