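"""Kernel Bayes classifier with class-conditional KDE densities.

Pipeline: per-feature transform (natural log for wear-rate features, then
z-score standardization fitted on the pooled training set), frequency or
fixed class priors, one fixed-bandwidth KDE per class on the standardized
scale, and posteriors via Bayes' theorem

    P(C_i | x) = p(x | C_i) P(C_i) / sum_j p(x | C_j) P(C_j)

with MAP classification (ties resolved to the first class, i.e. control).
Standardization is fitted on both classes pooled so that a single shared
bandwidth is meaningful for every class density.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from osteorisk.cohort import SubjectRecord
from osteorisk.kde import KdeModel, kde_log_evaluate_grid

__all__ = [
    "FEATURES",
    "LOG_FEATURES",
    "FeatureSpec",
    "StandardizationParams",
    "ClassifierModel",
    "SurfaceResult",
    "fit_transform",
    "apply_transform",
    "inverse_transform",
    "estimate_priors",
    "fit",
    "posterior",
    "posterior_batch",
    "posterior_with_support",
    "classify",
    "posterior_curve",
    "posterior_surface",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

FEATURES = ("annual_wear", "age_at_surgery", "bmi", "height")
LOG_FEATURES = frozenset({"annual_wear"})
TRANSFORMS = ("standardize", "log_then_standardize")

# exp(_LOG_TINY) is the smallest positive normal double; below this the
# class-conditional densities are treated as having no support at x.
_LOG_TINY = math.log(np.finfo(float).tiny)


@dataclass(frozen=True)
class FeatureSpec:
    """Ordered feature names with their per-feature transforms."""

    names: tuple[str, ...]
    transforms: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        if not names:
            raise ValueError("feature list must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate feature names in {names}")
        unknown = [n for n in names if n not in FEATURES]
        if unknown:
            raise ValueError(f"unknown feature(s) {unknown}; allowed: {FEATURES}")
        transforms = tuple(self.transforms)
        if len(transforms) != len(names):
            raise ValueError("need one transform per feature")
        for name, tr in zip(names, transforms):
            if tr not in TRANSFORMS:
                raise ValueError(f"unknown transform {tr!r}; allowed: {TRANSFORMS}")
            if name in LOG_FEATURES and tr != "log_then_standardize":
                raise ValueError(f"feature {name!r} requires log_then_standardize")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "transforms", transforms)

    @classmethod
    def of(cls, *names: str) -> "FeatureSpec":
        """Spec with the default transform for each feature."""
        return cls(
            names=tuple(names),
            transforms=tuple(
                "log_then_standardize" if n in LOG_FEATURES else "standardize"
                for n in names
            ),
        )

    @property
    def d(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature location/scale on the (possibly log) scale, from training data."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != sd.shape or mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D arrays of equal length")
        if np.any(sd <= 0):
            raise ValueError("every feature sd must be positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)


def extract_matrix(records: Sequence[SubjectRecord], spec: FeatureSpec) -> np.ndarray:
    """Raw (untransformed) feature matrix, one row per record."""
    return np.array(
        [[getattr(r, name) for name in spec.names] for r in records], dtype=float
    )


def _log_columns(X: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    X = np.array(X, dtype=float, copy=True)
    for j, tr in enumerate(spec.transforms):
        if tr == "log_then_standardize":
            col = X[:, j]
            if np.any(col <= 0):
                raise ValueError(
                    f"feature {spec.names[j]!r} must be positive for log transform"
                )
            X[:, j] = np.log(col)
    return X


def fit_transform(
    records: Sequence[SubjectRecord], spec: FeatureSpec
) -> tuple[np.ndarray, StandardizationParams]:
    """Fit the per-feature transform on ``records`` and return the design
    matrix plus the parameters for out-of-sample use.

    The fitted columns have mean 0 and sample s.d. (ddof=1) 1.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to fit a standardization")
    L = _log_columns(extract_matrix(records, spec), spec)
    mean = L.mean(axis=0)
    sd = L.std(axis=0, ddof=1)
    zero = [spec.names[j] for j in np.flatnonzero(sd == 0)]
    if zero:
        raise ValueError(f"zero-variance feature(s) {zero} in training data")
    params = StandardizationParams(mean=mean, sd=sd)
    return (L - mean) / sd, params


def apply_transform(
    params: StandardizationParams, spec: FeatureSpec, X_raw: np.ndarray
) -> np.ndarray:
    """Map raw-unit rows to the standardized model scale using training params."""
    X = np.atleast_2d(np.asarray(X_raw, dtype=float))
    if X.shape[1] != spec.d:
        raise ValueError(f"expected {spec.d} feature column(s), got {X.shape[1]}")
    return (_log_columns(X, spec) - params.mean) / params.sd


def inverse_transform(
    params: StandardizationParams, spec: FeatureSpec, Z: np.ndarray
) -> np.ndarray:
    """Back-transform model-scale rows to raw units (exponentiating log features)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = Z * params.sd + params.mean
    for j, tr in enumerate(spec.transforms):
        if tr == "log_then_standardize":
            X[:, j] = np.exp(X[:, j])
    return X


def estimate_priors(labels: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    """Relative class frequencies in ``labels``, ordered as ``classes``."""
    labels = list(labels)
    counts = np.array([labels.count(c) for c in classes], dtype=float)
    if np.any(counts == 0):
        empty = [c for c, n in zip(classes, counts) if n == 0]
        raise ValueError(f"empty class(es) {empty} in labels")
    return counts / counts.sum()


@dataclass(frozen=True)
class ClassifierModel:
    """Fitted kernel Bayes classifier.

    ``feature_spec``/``standardization`` may both be None for a model built
    directly from model-scale matrices (:meth:`from_arrays`); queries are then
    interpreted on that scale with no preprocessing.
    """

    classes: tuple[str, ...]
    priors: np.ndarray
    densities: tuple[KdeModel, ...]
    h: float
    feature_spec: FeatureSpec | None
    standardization: StandardizationParams | None

    def __post_init__(self) -> None:
        priors = np.asarray(self.priors, dtype=float)
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if priors.shape != (len(self.classes),):
            raise ValueError("need one prior per class")
        if np.any(priors <= 0) or np.any(priors >= 1):
            raise ValueError("each prior must lie in (0, 1)")
        if abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        if len(self.densities) != len(self.classes):
            raise ValueError("need one density per class")
        dims = {m.d for m in self.densities}
        if len(dims) != 1:
            raise ValueError("all class densities must share one dimension")
        for m in self.densities:
            if m.h != self.h:
                raise ValueError("all class densities must share the bandwidth h")
        object.__setattr__(self, "priors", priors / priors.sum())
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "densities", tuple(self.densities))

    @property
    def d(self) -> int:
        return self.densities[0].d

    @classmethod
    def from_arrays(
        cls,
        points_by_class: Sequence[np.ndarray],
        classes: Sequence[str],
        h: float,
        priors: Sequence[float] | None = None,
    ) -> "ClassifierModel":
        """Build a model from per-class model-scale point sets (no preprocessing)."""
        densities = tuple(KdeModel(points=np.atleast_2d(np.asarray(p, dtype=float)
                                                        .reshape(len(p), -1)), h=h)
                          for p in points_by_class)
        if priors is None:
            n = np.array([m.n for m in densities], dtype=float)
            priors = n / n.sum()
        return cls(
            classes=tuple(classes),
            priors=np.asarray(priors, dtype=float),
            densities=densities,
            h=h,
            feature_spec=None,
            standardization=None,
        )


def fit(
    records: Sequence[SubjectRecord],
    feature_spec: FeatureSpec,
    h: float,
    priors: Sequence[float] | None = None,
    classes: tuple[str, ...] = ("control", "osteolysis"),
) -> ClassifierModel:
    """Fit transforms (pooled), priors (empirical unless fixed) and one KDE
    per class; fully deterministic given the records."""
    if not h > 0:
        raise ValueError(f"bandwidth h must be positive, got {h}")
    labels = [r.label for r in records]
    for c in classes:
        if c not in labels:
            raise ValueError(f"class {c!r} absent from training records")
    Z, params = fit_transform(records, feature_spec)
    y = np.array(labels)
    densities = tuple(KdeModel(points=Z[y == c], h=h) for c in classes)
    p = estimate_priors(labels, classes) if priors is None else np.asarray(priors, float)
    return ClassifierModel(
        classes=classes,
        priors=p,
        densities=densities,
        h=h,
        feature_spec=feature_spec,
        standardization=params,
    )


def _to_model_scale(model: ClassifierModel, X_raw: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X_raw, dtype=float))
    if model.standardization is None:
        if X.shape[1] != model.d:
            raise ValueError(f"expected {model.d} feature column(s), got {X.shape[1]}")
        return X
    return apply_transform(model.standardization, model.feature_spec, X)


def posterior_batch(
    model: ClassifierModel, X_raw: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior probabilities for each row of ``X_raw`` (raw units).

    Returns ``(probs, supported)`` where ``probs`` is (m, M) with rows summing
    to 1 and ``supported`` flags rows where at least one class density is
    positive; unsupported rows fall back to the priors.
    """
    Z = _to_model_scale(model, X_raw)
    logp = np.column_stack(
        [kde_log_evaluate_grid(m, Z) for m in model.densities]
    ) + np.log(model.priors)
    supported = np.max(logp - np.log(model.priors), axis=1) > _LOG_TINY
    shifted = logp - logp.max(axis=1, keepdims=True)
    w = np.exp(shifted)
    probs = w / w.sum(axis=1, keepdims=True)
    probs[~supported] = model.priors
    return probs, supported


def posterior_with_support(model: ClassifierModel, x) -> tuple[np.ndarray, bool]:
    """Posterior at one raw-unit point, plus a density-support flag."""
    probs, supported = posterior_batch(model, np.atleast_1d(x)[None, :])
    return probs[0], bool(supported[0])


def posterior(model: ClassifierModel, x) -> np.ndarray:
    """Posterior class probabilities at one raw-unit point (sums to 1)."""
    return posterior_with_support(model, x)[0]


def classify(model: ClassifierModel, x) -> str:
    """MAP class label; exact posterior ties resolve to the first class."""
    return model.classes[int(np.argmax(posterior(model, x)))]


def _pooled_density(model: ClassifierModel, Z: np.ndarray) -> np.ndarray:
    """Prior-weighted mixture of the class densities on the model scale."""
    comp = np.column_stack(
        [np.exp(kde_log_evaluate_grid(m, Z)) for m in model.densities]
    )
    return comp @ model.priors


def _axis_grid(model: ClassifierModel, dim: int, n_points: int, padding: float):
    pts = np.vstack([m.points for m in model.densities])[:, dim]
    return np.linspace(pts.min() - padding, pts.max() + padding, n_points)


def posterior_curve(
    model: ClassifierModel, n_points: int = 256, padding: float = 2.0
) -> pd.DataFrame:
    """Posterior-vs-feature table for a univariate model.

    The grid spans the training range +/- ``padding`` on the standardized
    scale; the feature column is reported back-transformed to raw units.
    Columns: ``z``, the raw feature, one ``posterior_<class>`` per class, and
    the pooled training ``density`` (standardized scale).
    """
    if model.d != 1:
        raise ValueError(f"posterior_curve needs a 1-feature model, got d={model.d}")
    z = _axis_grid(model, 0, n_points, padding)
    Z = z[:, None]
    if model.standardization is None:
        raw = Z.copy()
        name = "x"
    else:
        raw = inverse_transform(model.standardization, model.feature_spec, Z)
        name = model.feature_spec.names[0]
    probs, _ = posterior_batch(model, raw)
    out = pd.DataFrame({"z": z, name: raw[:, 0]})
    for i, c in enumerate(model.classes):
        out[f"posterior_{c}"] = probs[:, i]
    out["density"] = _pooled_density(model, Z)
    return out


@dataclass(frozen=True)
class SurfaceResult:
    """Posterior and pooled-density grids for a bivariate model.

    ``posteriors`` has shape (M, r, r) indexed as [class, axis-1 cell,
    axis-2 cell]; ``density`` is the prior-weighted training density on the
    standardized grid.
    """

    feature_names: tuple[str, str]
    z1: np.ndarray
    z2: np.ndarray
    raw1: np.ndarray
    raw2: np.ndarray
    posteriors: np.ndarray
    density: np.ndarray
    classes: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        n1, n2 = self.z1.size, self.z2.size
        i, j = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
        data = {
            self.feature_names[0]: self.raw1[i.ravel()],
            self.feature_names[1]: self.raw2[j.ravel()],
        }
        for ci, c in enumerate(self.classes):
            data[f"posterior_{c}"] = self.posteriors[ci].ravel()
        data["density"] = self.density.ravel()
        return pd.DataFrame(data)


def posterior_surface(
    model: ClassifierModel, resolution: int = 100, padding: float = 2.0
) -> SurfaceResult:
    """Posterior surface plus companion training-density grid for a
    two-feature model, on a ``resolution x resolution`` raw-unit grid."""
    if model.d != 2:
        raise ValueError(f"posterior_surface needs a 2-feature model, got d={model.d}")
    z1 = _axis_grid(model, 0, resolution, padding)
    z2 = _axis_grid(model, 1, resolution, padding)
    G1, G2 = np.meshgrid(z1, z2, indexing="ij")
    Z = np.column_stack([G1.ravel(), G2.ravel()])
    if model.standardization is None:
        raw = Z
        names = ("x1", "x2")
        raw1, raw2 = z1, z2
    else:
        raw = inverse_transform(model.standardization, model.feature_spec, Z)
        names = tuple(model.feature_spec.names)
        axes = inverse_transform(
            model.standardization, model.feature_spec,
            np.column_stack([z1, z2]),
        )
        raw1, raw2 = axes[:, 0], axes[:, 1]
    probs, _ = posterior_batch(model, raw)
    M = len(model.classes)
    posts = probs.T.reshape(M, resolution, resolution)
    dens = _pooled_density(model, Z).reshape(resolution, resolution)
    return SurfaceResult(
        feature_names=names, z1=z1, z2=z2, raw1=raw1, raw2=raw2,
        posteriors=posts, density=dens, classes=model.classes,
    )


def model_to_dict(model: ClassifierModel) -> dict:
    doc = {
        "classes": list(model.classes),
        "priors": model.priors.tolist(),
        "h": model.h,
        "points": [m.points.tolist() for m in model.densities],
        "feature_spec": None,
        "standardization": None,
    }
    if model.feature_spec is not None:
        doc["feature_spec"] = {
            "names": list(model.feature_spec.names),
            "transforms": list(model.feature_spec.transforms),
        }
    if model.standardization is not None:
        doc["standardization"] = {
            "mean": model.standardization.mean.tolist(),
            "sd": model.standardization.sd.tolist(),
        }
    return doc


def model_from_dict(doc: dict) -> ClassifierModel:
    spec = None
    if doc.get("feature_spec") is not None:
        spec = FeatureSpec(
            names=tuple(doc["feature_spec"]["names"]),
            transforms=tuple(doc["feature_spec"]["transforms"]),
        )
    std = None
    if doc.get("standardization") is not None:
        std = StandardizationParams(
            mean=np.asarray(doc["standardization"]["mean"], dtype=float),
            sd=np.asarray(doc["standardization"]["sd"], dtype=float),
        )
    h = float(doc["h"])
    return ClassifierModel(
        classes=tuple(doc["classes"]),
        priors=np.asarray(doc["priors"], dtype=float),
        densities=tuple(
            KdeModel(points=np.asarray(p, dtype=float), h=h) for p in doc["points"]
        ),
        h=h,
        feature_spec=spec,
        standardization=std,
    )


def save_model(model: ClassifierModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> ClassifierModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
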