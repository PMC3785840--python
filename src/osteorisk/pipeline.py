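"""Config-driven pipeline: simulate -> fit -> curves/surfaces -> CV -> sweep.

A run is described by a JSON config (see :func:`validate_config`), writes all
artifacts into one output directory and records a manifest with the config
hash, master seed and a SHA-256 checksum per artifact.  Re-running an
identical config reproduces every artifact bit-identically (floats are
written with 12 significant digits; checksum equality assumes identical
floating-point arithmetic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from osteorisk import classifier as clf
from osteorisk import cohort as coh
from osteorisk import evaluation as ev

__all__ = [
    "RunConfig",
    "ConfigError",
    "validate_config",
    "load_config",
    "default_run_config",
    "run_pipeline",
]

log = logging.getLogger("osteorisk")

FLOAT_FMT = "%.12g"


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration."""

    cohort_config: coh.CohortConfig | None
    cohort_path: str | None
    features: tuple[str, ...]
    h: float
    k: int
    n_permutations: int
    subgroups: tuple[str, ...]
    sweep_grid: tuple[float, ...] | None
    sweep_permutations: int
    out_dir: str
    master_seed: int

    def __post_init__(self) -> None:
        if (self.cohort_config is None) == (self.cohort_path is None):
            raise ConfigError(
                ["exactly one of cohort simulation config and cohort path required"]
            )


def _group_spec_from(doc: dict, path: str, errors: list[str]) -> coh.GroupSpec | None:
    required = [f.name for f in dataclasses.fields(coh.GroupSpec)]
    missing = [k for k in required if k not in doc]
    unknown = [k for k in doc if k not in required]
    if missing:
        errors.append(f"{path}: missing field(s) {missing}")
    if unknown:
        errors.append(f"{path}: unknown field(s) {unknown}")
    if missing or unknown:
        return None
    try:
        return coh.GroupSpec(**{k: (int(doc[k]) if k in ("n", "n_male") else float(doc[k]))
                                for k in required})
    except (coh.CohortError, TypeError, ValueError) as exc:
        errors.append(f"{path}: {exc}")
        return None


def validate_config(doc: dict) -> RunConfig:
    """Validate a config document, reporting every error at once."""
    errors: list[str] = []

    cohort_config = None
    cohort_path = None
    cohort = doc.get("cohort")
    if not isinstance(cohort, dict) or ("simulate" in cohort) == ("path" in cohort):
        errors.append(
            "cohort: must be an object with exactly one of 'simulate' and 'path'"
        )
    elif "path" in cohort:
        cohort_path = str(cohort["path"])
    else:
        sim = cohort["simulate"]
        seed = int(doc.get("master_seed", 0))
        if sim == "default":
            cohort_config = coh.default_config(seed=seed)
        elif isinstance(sim, dict):
            control = _group_spec_from(
                sim.get("control", {}), "cohort.simulate.control", errors
            )
            osteolysis = _group_spec_from(
                sim.get("osteolysis", {}), "cohort.simulate.osteolysis", errors
            )
            if control is not None and osteolysis is not None:
                try:
                    cohort_config = coh.CohortConfig(
                        control=control,
                        osteolysis=osteolysis,
                        seed=seed,
                        sex_height_gap=float(sim.get("sex_height_gap", 0.05)),
                    )
                except (coh.CohortError, ValueError) as exc:
                    errors.append(f"cohort.simulate: {exc}")
        else:
            errors.append("cohort.simulate: must be 'default' or a config object")

    features = tuple(doc.get("features", ["annual_wear", "age_at_surgery"]))
    try:
        clf.FeatureSpec.of(*features)
    except ValueError as exc:
        errors.append(f"features: {exc}")

    h = doc.get("h", 0.7)
    if not isinstance(h, (int, float)) or not h > 0:
        errors.append(f"h: must be a positive number, got {h!r}")
    k = doc.get("k", 5)
    if not isinstance(k, int) or k < 2:
        errors.append(f"k: must be an integer >= 2, got {k!r}")
    n_perm = doc.get("n_permutations", 100)
    if not isinstance(n_perm, int) or n_perm < 1:
        errors.append(f"n_permutations: must be an integer >= 1, got {n_perm!r}")

    subgroups = tuple(doc.get("subgroups", list(ev.SUBGROUPS)))
    bad = [s for s in subgroups if s not in ev.SUBGROUPS]
    if bad:
        errors.append(f"subgroups: unknown {bad}; allowed: {list(ev.SUBGROUPS)}")

    sweep_grid = None
    sweep_perm = 0
    sweep = doc.get("sweep")
    if sweep is not None:
        try:
            h_min = float(sweep.get("h_min", 0.1))
            h_max = float(sweep.get("h_max", 10.0))
            h_step = float(sweep.get("h_step", 0.1))
            sweep_perm = int(sweep.get("n_permutations", n_perm))
            if not (0 < h_min <= h_max) or h_step <= 0 or sweep_perm < 1:
                raise ValueError(
                    f"need 0 < h_min <= h_max, h_step > 0, n_permutations >= 1"
                )
            n_steps = int(round((h_max - h_min) / h_step)) + 1
            sweep_grid = tuple(
                np.round(h_min + h_step * np.arange(n_steps), 10).tolist()
            )
        except (TypeError, ValueError, AttributeError) as exc:
            errors.append(f"sweep: {exc}")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        cohort_config=cohort_config,
        cohort_path=cohort_path,
        features=features,
        h=float(h),
        k=k,
        n_permutations=n_perm,
        subgroups=subgroups,
        sweep_grid=sweep_grid,
        sweep_permutations=sweep_perm,
        out_dir=str(doc.get("out_dir", "results")),
        master_seed=int(doc.get("master_seed", 0)),
    )


def load_config(path) -> RunConfig:
    """Parse and validate a JSON config file."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ConfigError([f"{path}: malformed JSON at line {exc.lineno}, "
                           f"column {exc.colno}: {exc.msg}"]) from exc
    if not isinstance(doc, dict):
        raise ConfigError([f"{path}: top-level JSON value must be an object"])
    return validate_config(doc)


def default_run_config(out_dir: str = "results", master_seed: int = 0,
                       n_permutations: int = 100,
                       sweep: bool = True) -> dict:
    """A config document for the headline analysis (wear + age, h = 0.7)."""
    doc: dict[str, Any] = {
        "cohort": {"simulate": "default"},
        "features": ["annual_wear", "age_at_surgery"],
        "h": 0.7,
        "k": 5,
        "n_permutations": n_permutations,
        "subgroups": ["all", "male", "female"],
        "out_dir": out_dir,
        "master_seed": master_seed,
    }
    if sweep:
        doc["sweep"] = {"h_min": 0.1, "h_max": 10.0, "h_step": 0.1,
                        "n_permutations": n_permutations}
    return doc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, doc: Any) -> None:
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _cv_rows(summaries: dict[str, ev.RepeatedCvSummary]) -> pd.DataFrame:
    rows = []
    for sub, s in summaries.items():
        for p, err in enumerate(s.errors):
            rows.append({"subgroup": sub, "permutation": p, "error": err})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    out = Path(config.out_dir)
    if not out.exists():
        out.mkdir(parents=True)
        log.info("created output directory %s", out)
    artifacts: dict[str, str] = {}

    def record(name: str, path: Path) -> None:
        artifacts[name] = _sha256(path)
        log.info("artifact=%s sha256=%s", name, artifacts[name])

    # --- cohort ------------------------------------------------------------
    if config.cohort_config is not None:
        log.info("stage=simulate seed=%d", config.cohort_config.seed)
        records = coh.generate_cohort(config.cohort_config)
        cohort_path = out / "cohort.csv"
        coh.write_cohort(records, cohort_path)
        record("cohort.csv", cohort_path)
    else:
        log.info("stage=load path=%s", config.cohort_path)
        records = coh.read_cohort(config.cohort_path)

    # --- fit ---------------------------------------------------------------
    spec = clf.FeatureSpec.of(*config.features)
    log.info("stage=fit features=%s h=%g", ",".join(spec.names), config.h)
    model = clf.fit(records, spec, config.h)
    model_path = out / "model.json"
    clf.save_model(model, model_path)
    record("model.json", model_path)

    # --- posterior grids ---------------------------------------------------
    if model.d == 1:
        curve = clf.posterior_curve(model)
        path = out / "posterior_curve.csv"
        curve.to_csv(path, index=False, float_format=FLOAT_FMT)
        record("posterior_curve.csv", path)
    elif model.d == 2:
        surface = clf.posterior_surface(model)
        path = out / "posterior_surface.csv"
        surface.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)
        record("posterior_surface.csv", path)

    # --- cross-validation --------------------------------------------------
    log.info("stage=crossval k=%d permutations=%d seed=%d",
             config.k, config.n_permutations, config.master_seed)
    summaries = ev.sex_stratified_cv(
        records, spec, config.h, config.k, config.n_permutations,
        config.master_seed, subgroups=config.subgroups,
    )
    cv_path = out / "cv_errors.csv"
    _cv_rows(summaries).to_csv(cv_path, index=False, float_format=FLOAT_FMT)
    record("cv_errors.csv", cv_path)
    summary_doc = {
        sub: {"mean": s.mean, "sd": s.sd, "min": s.min, "max": s.max,
              "n_permutations": s.n_permutations, "h": s.h, "k": s.k}
        for sub, s in summaries.items()
    }
    cv_sum_path = out / "cv_summary.json"
    _write_json(cv_sum_path, summary_doc)
    record("cv_summary.json", cv_sum_path)

    # --- bandwidth sweep ---------------------------------------------------
    if config.sweep_grid is not None:
        log.info("stage=sweep n_h=%d permutations=%d",
                 len(config.sweep_grid), config.sweep_permutations)
        sweep_rows = []
        sweep_doc = {}
        for sub in config.subgroups:
            res = ev.bandwidth_sweep(
                records, spec, config.sweep_grid, config.k,
                config.sweep_permutations, config.master_seed, subgroup=sub,
            )
            for p in range(res.n_permutations):
                for j, h in enumerate(res.h_grid):
                    sweep_rows.append(
                        {"subgroup": sub, "permutation": p, "h": h,
                         "error": res.per_permutation_error[p, j]}
                    )
            sweep_doc[sub] = {
                "h_grid": res.h_grid.tolist(),
                "mean_error": res.mean_error.tolist(),
                "n_permutations": res.n_permutations,
            }
        sweep_path = out / "sweep_errors.csv"
        pd.DataFrame(sweep_rows).to_csv(sweep_path, index=False,
                                        float_format=FLOAT_FMT)
        record("sweep_errors.csv", sweep_path)
        sweep_sum_path = out / "sweep_summary.json"
        _write_json(sweep_sum_path, sweep_doc)
        record("sweep_summary.json", sweep_sum_path)

    # --- manifest ----------------------------------------------------------
    config_doc = _config_to_doc(config)
    manifest = {
        "config": config_doc,
        "config_sha256": hashlib.sha256(
            json.dumps(config_doc, sort_keys=True).encode()
        ).hexdigest(),
        "master_seed": config.master_seed,
        "artifacts": artifacts,
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


def _config_to_doc(config: RunConfig) -> dict:
    doc: dict[str, Any] = {
        "features": list(config.features),
        "h": config.h,
        "k": config.k,
        "n_permutations": config.n_permutations,
        "subgroups": list(config.subgroups),
        "out_dir": config.out_dir,
        "master_seed": config.master_seed,
    }
    if config.cohort_path is not None:
        doc["cohort"] = {"path": config.cohort_path}
    else:
        cc = config.cohort_config
        doc["cohort"] = {
            "simulate": {
                "control": dataclasses.asdict(cc.control),
                "osteolysis": dataclasses.asdict(cc.osteolysis),
                "sex_height_gap": cc.sex_height_gap,
            }
        }
    if config.sweep_grid is not None:
        doc["sweep"] = {
            "h_min": config.sweep_grid[0],
            "h_max": config.sweep_grid[-1],
            "h_step": (config.sweep_grid[1] - config.sweep_grid[0]
                       if len(config.sweep_grid) > 1 else 0.1),
            "n_permutations": config.sweep_permutations,
        }
    return doc
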