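"""Model evaluation: stratified k-fold CV, repeated permutations, sex-specific
subgroup analyses and the bandwidth sensitivity sweep.

All preprocessing (standardization), priors and class densities are re-fitted
on the training folds only — held-out subjects never influence the model they
are scored with.  Permutation seeds are derived deterministically from a
single master seed, and within a permutation the same fold assignment is
reused across the whole bandwidth grid so sensitivity curves isolate the
effect of h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from osteorisk import classifier as clf
from osteorisk.cohort import SubjectRecord, subset

__all__ = [
    "FoldAssignment",
    "CvResult",
    "RepeatedCvSummary",
    "SweepResult",
    "stratified_kfold",
    "cross_validate",
    "repeated_cv",
    "sex_stratified_cv",
    "bandwidth_sweep",
    "default_h_grid",
    "permutation_seed",
]

SUBGROUPS = ("all", "male", "female")


@dataclass(frozen=True)
class FoldAssignment:
    """A stratified partition into k folds (fold index per position)."""

    k: int
    folds: np.ndarray
    seed: int | None
    ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "folds", np.asarray(self.folds, dtype=int))

    @property
    def fold_of(self) -> dict:
        keys = self.ids if self.ids is not None else range(self.folds.size)
        return dict(zip(keys, self.folds.tolist()))

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds != fold)


def stratified_kfold(
    labels: Sequence[str],
    k: int,
    seed: int,
    ids: Sequence[str] | None = None,
) -> FoldAssignment:
    """Random stratified k-fold assignment: within every class, fold sizes
    differ by at most one.  Deterministic given (labels, k, seed)."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    folds = np.full(labels.size, -1, dtype=int)
    # iterate classes in order of first appearance for determinism
    _, first = np.unique(labels, return_index=True)
    for cls in labels[np.sort(first)]:
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has {idx.size} member(s), fewer than k={k}"
            )
        perm = rng.permutation(idx)
        fold_order = rng.permutation(k)  # randomize which folds get extras
        folds[perm] = fold_order[np.arange(idx.size) % k]
    return FoldAssignment(
        k=k, folds=folds, seed=seed, ids=tuple(ids) if ids is not None else None
    )


@dataclass(frozen=True)
class CvResult:
    """Per-fold and pooled misclassification for one CV pass."""

    per_fold_error: tuple[float, ...]
    per_fold_n: tuple[int, ...]
    pooled_error: float
    mean_fold_error: float
    h: float
    k: int
    seed: int | None
    subgroup: str = "all"

    @property
    def n(self) -> int:
        return int(sum(self.per_fold_n))


def cross_validate(
    records: Sequence[SubjectRecord],
    feature_spec: clf.FeatureSpec,
    h: float,
    k: int = 5,
    seed: int | None = None,
    folds: FoldAssignment | None = None,
    subgroup: str = "all",
) -> CvResult:
    """Stratified k-fold CV of the kernel Bayes classifier.

    Either a seed (folds are drawn here) or a precomputed ``folds`` assignment
    must be given.  Transforms, priors and densities are fitted per training
    fold; the held-out fold is scored with MAP classification.
    """
    records = list(records)
    labels = [r.label for r in records]
    if folds is None:
        if seed is None:
            raise ValueError("either seed or folds must be provided")
        folds = stratified_kfold(labels, k, seed, ids=[r.id for r in records])
    elif folds.folds.size != len(records):
        raise ValueError("fold assignment size does not match record count")

    y = np.array(labels)
    per_fold_error: list[float] = []
    per_fold_n: list[int] = []
    n_wrong_total = 0
    for fold in range(folds.k):
        test_idx = folds.test_indices(fold)
        train_idx = folds.train_indices(fold)
        train = [records[i] for i in train_idx]
        try:
            model = clf.fit(train, feature_spec, h)
        except ValueError as exc:
            raise ValueError(f"fold {fold}: {exc}") from exc
        X_test = clf.extract_matrix([records[i] for i in test_idx], feature_spec)
        probs, _ = clf.posterior_batch(model, X_test)
        pred = np.asarray(model.classes)[np.argmax(probs, axis=1)]
        n_wrong = int(np.sum(pred != y[test_idx]))
        per_fold_error.append(n_wrong / test_idx.size)
        per_fold_n.append(int(test_idx.size))
        n_wrong_total += n_wrong
    return CvResult(
        per_fold_error=tuple(per_fold_error),
        per_fold_n=tuple(per_fold_n),
        pooled_error=n_wrong_total / len(records),
        mean_fold_error=float(np.mean(per_fold_error)),
        h=h,
        k=folds.k,
        seed=folds.seed,
        subgroup=subgroup,
    )


def permutation_seed(master_seed: int, permutation: int) -> int:
    """Deterministic per-permutation seed derived from the master seed."""
    return int(np.random.SeedSequence((master_seed, permutation)).generate_state(1)[0])


@dataclass(frozen=True)
class RepeatedCvSummary:
    """Pooled-error distribution over repeated CV permutations."""

    errors: tuple[float, ...]
    mean: float
    sd: float
    min: float
    max: float
    h: float
    k: int
    master_seed: int
    subgroup: str = "all"
    results: tuple[CvResult, ...] = field(default_factory=tuple, repr=False)

    @property
    def n_permutations(self) -> int:
        return len(self.errors)


def _summarize(
    results: Sequence[CvResult], h: float, k: int, master_seed: int, subgroup: str
) -> RepeatedCvSummary:
    errors = np.array([r.pooled_error for r in results])
    return RepeatedCvSummary(
        errors=tuple(errors.tolist()),
        mean=float(errors.mean()),
        sd=float(errors.std(ddof=1)) if errors.size > 1 else 0.0,
        min=float(errors.min()),
        max=float(errors.max()),
        h=h,
        k=k,
        master_seed=master_seed,
        subgroup=subgroup,
        results=tuple(results),
    )


def repeated_cv(
    records: Sequence[SubjectRecord],
    feature_spec: clf.FeatureSpec,
    h: float,
    k: int = 5,
    n_permutations: int = 100,
    master_seed: int = 0,
    subgroup: str = "all",
) -> RepeatedCvSummary:
    """CV repeated over random fold permutations; returns the error
    distribution (mean, s.d., range and the full vector)."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    results = [
        cross_validate(
            records, feature_spec, h, k,
            seed=permutation_seed(master_seed, p), subgroup=subgroup,
        )
        for p in range(n_permutations)
    ]
    return _summarize(results, h, k, master_seed, subgroup)


def _subgroup_records(
    records: Sequence[SubjectRecord], subgroup: str
) -> list[SubjectRecord]:
    if subgroup == "all":
        return list(records)
    return subset(records, sex=subgroup)


def sex_stratified_cv(
    records: Sequence[SubjectRecord],
    feature_spec: clf.FeatureSpec,
    h: float,
    k: int = 5,
    n_permutations: int = 100,
    master_seed: int = 0,
    subgroups: Sequence[str] = SUBGROUPS,
) -> dict[str, RepeatedCvSummary]:
    """Repeated CV on the whole cohort and on each sex separately; every
    subgroup re-estimates priors, transforms and densities internally."""
    out: dict[str, RepeatedCvSummary] = {}
    for sub in subgroups:
        if sub not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {sub!r}; allowed: {SUBGROUPS}")
        recs = _subgroup_records(records, sub)
        for cls in ("control", "osteolysis"):
            if not any(r.label == cls for r in recs):
                raise ValueError(f"subgroup {sub!r} has no {cls!r} subjects")
        out[sub] = repeated_cv(
            recs, feature_spec, h, k, n_permutations, master_seed, subgroup=sub
        )
    return out


def default_h_grid() -> np.ndarray:
    """The default bandwidth grid 0.1, 0.2, ..., 10.0 (100 values)."""
    return np.round(np.arange(1, 101) * 0.1, 10)


@dataclass(frozen=True)
class SweepResult:
    """Misclassification as a function of bandwidth across permutations."""

    h_grid: np.ndarray
    per_permutation_error: np.ndarray  # (n_permutations, n_h)
    mean_error: np.ndarray
    n_permutations: int
    master_seed: int
    subgroup: str = "all"

    def __post_init__(self) -> None:
        h = np.asarray(self.h_grid, dtype=float)
        err = np.asarray(self.per_permutation_error, dtype=float)
        if np.any(np.diff(h) <= 0):
            raise ValueError("h_grid must be strictly increasing")
        if err.shape != (self.n_permutations, h.size):
            raise ValueError("error matrix shape must be (n_permutations, n_h)")
        object.__setattr__(self, "h_grid", h)
        object.__setattr__(self, "per_permutation_error", err)
        object.__setattr__(self, "mean_error", err.mean(axis=0))


def bandwidth_sweep(
    records: Sequence[SubjectRecord],
    feature_spec: clf.FeatureSpec,
    h_grid: Sequence[float] | None = None,
    k: int = 5,
    n_permutations: int = 100,
    master_seed: int = 0,
    subgroup: str = "all",
) -> SweepResult:
    """Mean misclassification over a bandwidth grid, averaged across repeated
    fold permutations; folds are shared across the grid within a permutation."""
    recs = _subgroup_records(records, subgroup)
    h_grid = default_h_grid() if h_grid is None else np.asarray(h_grid, dtype=float)
    if h_grid.size == 0 or np.any(h_grid <= 0):
        raise ValueError("h_grid must be non-empty and positive")
    labels = [r.id for r in recs]
    errors = np.empty((n_permutations, h_grid.size))
    for p in range(n_permutations):
        folds = stratified_kfold(
            [r.label for r in recs], k, permutation_seed(master_seed, p), ids=labels
        )
        for j, h in enumerate(h_grid):
            errors[p, j] = cross_validate(
                recs, feature_spec, float(h), k, folds=folds, subgroup=subgroup
            ).pooled_error
    return SweepResult(
        h_grid=h_grid,
        per_permutation_error=errors,
        mean_error=errors.mean(axis=0),
        n_permutations=n_permutations,
        master_seed=master_seed,
        subgroup=subgroup,
    )
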