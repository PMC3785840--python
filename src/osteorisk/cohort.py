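"""Synthetic subject cohorts calibrated to published group-level statistics.

The generator draws, per outcome class, total linear wear from a moment-matched
log-normal and age, height, BMI and implant survival time from moment-matched
truncated normals.  Weight is derived from BMI and height so the
``bmi = weight / height**2`` identity holds exactly, and annual wear is the
quotient of total wear and survival time.  Variables are drawn independently
within class; within-class correlations are not published and are therefore
not modelled (a documented fidelity limitation).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SubjectRecord",
    "GroupSpec",
    "CohortConfig",
    "CohortError",
    "lognormal_params_from_moments",
    "truncnorm_params_from_moments",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "default_config",
    "COHORT_COLUMNS",
]

SEXES = ("male", "female")
LABELS = ("control", "osteolysis")

COHORT_COLUMNS = (
    "id",
    "sex",
    "age_at_surgery",
    "height",
    "weight",
    "bmi",
    "total_wear",
    "survival_time",
    "annual_wear",
    "label",
)

# plausibility bounds used to truncate the normal draws
AGE_BOUNDS = (30.0, 95.0)
HEIGHT_BOUNDS = (1.30, 2.10)
SURVIVAL_BOUNDS = (1.0, 30.0)
BMI_BOUNDS = (12.0, 60.0)


class CohortError(ValueError):
    """Raised for invalid generator parameters or malformed cohort files."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: demographics, wear, survival time and outcome label."""

    id: str
    sex: str
    age_at_surgery: float
    height: float
    weight: float
    bmi: float
    total_wear: float
    survival_time: float
    annual_wear: float
    label: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.label not in LABELS:
            raise CohortError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if not self.total_wear > 0:
            raise CohortError(f"total_wear must be positive, got {self.total_wear}")
        if not self.survival_time > 0:
            raise CohortError(
                f"survival_time must be positive, got {self.survival_time}"
            )


@dataclass(frozen=True)
class GroupSpec:
    """Target moments for one outcome class (means and s.d. per variable)."""

    n: int
    n_male: int
    wear_mean: float
    wear_sd: float
    age_mean: float
    age_sd: float
    height_mean: float
    height_sd: float
    bmi_mean: float
    bmi_sd: float
    survival_mean: float
    survival_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CohortError("group size n must be >= 1")
        if not 0 <= self.n_male <= self.n:
            raise CohortError("n_male must satisfy 0 <= n_male <= n")
        for name in ("wear", "age", "height", "bmi", "survival"):
            mean = getattr(self, f"{name}_mean")
            sd = getattr(self, f"{name}_sd")
            if not mean > 0:
                raise CohortError(f"{name}_mean must be positive, got {mean}")
            if sd < 0:
                raise CohortError(f"{name}_sd must be non-negative, got {sd}")


@dataclass(frozen=True)
class CohortConfig:
    """Full generator configuration: one spec per class plus a master seed.

    ``sex_height_gap`` is the male-minus-female mean height difference (m);
    it is split between the sexes so the class mean and s.d. are preserved.
    """

    control: GroupSpec
    osteolysis: GroupSpec
    seed: int = 0
    sex_height_gap: float = 0.05

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def default_config(seed: int = 0) -> CohortConfig:
    """Configuration replicating the published cohort (463 subjects)."""
    return CohortConfig(
        control=GroupSpec(
            n=283, n_male=132,
            wear_mean=1.022, wear_sd=0.957,
            age_mean=64.1, age_sd=8.2,
            height_mean=1.63, height_sd=0.09,
            bmi_mean=28.4, bmi_sd=5.0,
            survival_mean=11.9, survival_sd=4.2,
        ),
        osteolysis=GroupSpec(
            n=180, n_male=106,
            wear_mean=1.411, wear_sd=0.955,
            age_mean=59.5, age_sd=8.8,
            height_mean=1.67, height_sd=0.09,
            bmi_mean=28.4, bmi_sd=4.6,
            survival_mean=10.2, survival_sd=4.7,
        ),
        seed=seed,
    )


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of the log-normal with the given mean and s.d.

    Closed form: ``sigma**2 = ln(1 + sd**2/mean**2)`` and
    ``mu = ln(mean) - sigma**2 / 2``.
    """
    if not mean > 0:
        raise CohortError(f"mean must be positive, got {mean}")
    if not sd > 0:
        raise CohortError(f"sd must be positive, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def truncnorm_params_from_moments(
    mean: float, sd: float, bounds: tuple[float, float]
) -> tuple[float, float]:
    """Parent (loc, scale) so the normal truncated to ``bounds`` has the
    requested mean and s.d.

    Truncation shifts the moments of a plain normal (materially so when a
    bound sits within ~2 s.d. of the mean), so the parent parameters are
    solved for numerically rather than used as-is.
    """
    lo, hi = bounds
    if not lo < mean < hi:
        raise CohortError(f"target mean {mean} outside truncation bounds {bounds}")
    if not sd > 0:
        raise CohortError(f"sd must be positive, got {sd}")

    def residual(params: np.ndarray) -> np.ndarray:
        loc, log_scale = params
        scale = math.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        dist = stats.truncnorm(a, b, loc=loc, scale=scale)
        return np.array([dist.mean() - mean, dist.std() - sd])

    sol = optimize.root(residual, np.array([mean, math.log(sd)]), tol=1e-12)
    if not sol.success:  # pragma: no cover - well-behaved for plausible inputs
        raise CohortError(f"truncated-normal moment matching failed: {sol.message}")
    loc, log_scale = sol.x
    return float(loc), float(math.exp(log_scale))


def _draw_truncnorm(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    loc, scale = truncnorm_params_from_moments(mean, sd, bounds)
    a, b = (bounds[0] - loc) / scale, (bounds[1] - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def _sex_height_targets(
    spec: GroupSpec, gap: float
) -> dict[str, tuple[float, float]]:
    """Per-sex height (mean, sd) preserving the class mean and variance.

    Male mean sits ``gap * p_female`` above the class mean and female mean
    ``gap * p_male`` below it; the within-sex s.d. is shrunk so the pooled
    class variance still equals ``height_sd**2``.
    """
    p_male = spec.n_male / spec.n
    p_female = 1.0 - p_male
    between_var = p_male * p_female * gap * gap
    within_var = spec.height_sd**2 - between_var
    if within_var <= 0:
        raise CohortError(
            f"sex_height_gap={gap} incompatible with height_sd={spec.height_sd}"
        )
    sd = math.sqrt(within_var)
    return {
        "male": (spec.height_mean + gap * p_female, sd),
        "female": (spec.height_mean - gap * p_male, sd),
    }


def _generate_group(
    spec: GroupSpec,
    label: str,
    gap: float,
    streams: dict[str, np.random.Generator],
) -> list[SubjectRecord]:
    n = spec.n
    mu, sigma = lognormal_params_from_moments(spec.wear_mean, spec.wear_sd)
    wear = np.exp(streams["wear"].normal(mu, sigma, size=n))
    age = _draw_truncnorm(streams["age"], n, spec.age_mean, spec.age_sd, AGE_BOUNDS)
    bmi = _draw_truncnorm(streams["bmi"], n, spec.bmi_mean, spec.bmi_sd, BMI_BOUNDS)
    survival = _draw_truncnorm(
        streams["survival"], n, spec.survival_mean, spec.survival_sd, SURVIVAL_BOUNDS
    )

    sexes = ["male"] * spec.n_male + ["female"] * (n - spec.n_male)
    targets = _sex_height_targets(spec, gap)
    height = np.empty(n)
    for sex in SEXES:
        idx = np.flatnonzero(np.array(sexes) == sex)
        if idx.size:
            m, s = targets[sex]
            height[idx] = _draw_truncnorm(streams[f"height_{sex}"], idx.size, m, s,
                                          HEIGHT_BOUNDS)

    prefix = label[0].upper()
    records = []
    for i in range(n):
        h = float(height[i])
        b = float(bmi[i])
        records.append(
            SubjectRecord(
                id=f"{prefix}{i + 1:04d}",
                sex=sexes[i],
                age_at_surgery=float(age[i]),
                height=h,
                weight=b * h * h,
                bmi=b,
                total_wear=float(wear[i]),
                survival_time=float(survival[i]),
                annual_wear=float(wear[i] / survival[i]),
                label=label,
            )
        )
    return records


_STREAM_NAMES = ("wear", "age", "bmi", "survival", "height_male", "height_female")


def seed_streams(seed: int) -> dict[str, dict[str, np.random.Generator]]:
    """Independent per-class, per-variable generator substreams.

    Children are spawned from one master :class:`numpy.random.SeedSequence`
    in a fixed documented order, so a given master seed always yields the
    same draws regardless of call context.
    """
    children = np.random.SeedSequence(seed).spawn(len(LABELS) * len(_STREAM_NAMES))
    it = iter(children)
    return {
        label: {name: np.random.default_rng(next(it)) for name in _STREAM_NAMES}
        for label in LABELS
    }


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate a full synthetic cohort; identical config => identical cohort."""
    streams = seed_streams(config.seed)
    records = _generate_group(
        config.control, "control", config.sex_height_gap, streams["control"]
    )
    records += _generate_group(
        config.osteolysis, "osteolysis", config.sex_height_gap, streams["osteolysis"]
    )
    return records


def write_cohort(records: Iterable[SubjectRecord], path) -> None:
    """Write records as CSV with full-precision (round-trippable) floats."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.sex,
                    repr(r.age_at_surgery),
                    repr(r.height),
                    repr(r.weight),
                    repr(r.bmi),
                    repr(r.total_wear),
                    repr(r.survival_time),
                    repr(r.annual_wear),
                    r.label,
                ]
            )


def read_cohort(path) -> list[SubjectRecord]:
    """Read a cohort CSV (header-keyed; column order is irrelevant).

    Rejects files with missing columns and rows with non-positive wear or
    survival time or unknown sex/label, naming the offending row.
    """
    records: list[SubjectRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise CohortError(f"missing column(s) {missing} in {path}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    SubjectRecord(
                        id=row["id"],
                        sex=row["sex"],
                        age_at_surgery=float(row["age_at_surgery"]),
                        height=float(row["height"]),
                        weight=float(row["weight"]),
                        bmi=float(row["bmi"]),
                        total_wear=float(row["total_wear"]),
                        survival_time=float(row["survival_time"]),
                        annual_wear=float(row["annual_wear"]),
                        label=row["label"],
                    )
                )
            except (CohortError, ValueError) as exc:
                raise CohortError(f"row {lineno} of {path}: {exc}") from exc
    return records


def subset(records: Sequence[SubjectRecord], sex: str | None = None) -> list[SubjectRecord]:
    """Records restricted to one sex (or all records when sex is None)."""
    if sex is None:
        return list(records)
    if sex not in SEXES:
        raise CohortError(f"unknown sex {sex!r}; expected one of {SEXES}")
    return [r for r in records if r.sex == sex]
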