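"""End-to-end orchestration: simulate -> prepare -> fit -> interpret -> advise -> score.

A single structured config (YAML on disk, plain dicts in memory) drives the
six-stage chain and every artifact lands under one output directory with a
run manifest recording the config hash, per-stage row counts and wall times.
Reruns with the same config produce identical CSV/JSON artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .advisor import AdvisorConstraints, SolverOptions, advise_testset
from .evaluate import EfsaBaseline, compare_to_guidelines
from .interpret import ale, largest_drop_interval, pdp_ice
from .preprocess import EligibilityCriteria, apply_eligibility_filters, split_by_participant
from .surrogate import (
    FeaturePolicy,
    fit_surrogate,
    mae,
    prune_features,
    rank_features,
    save_model,
)
from .synthetic_cohort import (
    COHORT_COLUMNS,
    CohortSpec,
    PhysiologyParams,
    generate_cohort,
    write_cohort,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger(__name__)


def _build(cls, data: dict | None, **overrides):
    data = dict(data or {})
    data.update(overrides)
    # tolerate lists where tuples are expected (YAML has no tuples)
    for k, v in data.items():
        if isinstance(v, list):
            data[k] = tuple(v)
    return cls(**data)


@dataclass
class RunConfig:
    """Validated configuration of one full pipeline run."""

    seed: int
    output_dir: str
    cohort: CohortSpec
    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    eligibility: EligibilityCriteria = field(default_factory=EligibilityCriteria)
    feature_policy: FeaturePolicy = field(default_factory=FeaturePolicy)
    learner_kind: str = "gbt"
    split_ratio: float = 0.75
    cv_folds: int = 5
    n_search: int = 20
    constraints: AdvisorConstraints = field(default_factory=AdvisorConstraints)
    solver: SolverOptions = field(default_factory=SolverOptions)
    baseline: EfsaBaseline = field(default_factory=EfsaBaseline)
    interpret_feature: str = "plain_water"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        for req in ("seed", "output_dir", "cohort"):
            if req not in raw:
                raise ValueError(f"run config is missing required field {req!r}")
        cohort = _build(CohortSpec, raw["cohort"], seed=raw["cohort"].get("seed", raw["seed"]))
        return cls(
            seed=int(raw["seed"]),
            output_dir=str(raw["output_dir"]),
            cohort=cohort,
            physiology=_build(PhysiologyParams, raw.get("physiology")),
            eligibility=_build(EligibilityCriteria, raw.get("eligibility")),
            feature_policy=_build(FeaturePolicy, raw.get("feature_policy")),
            learner_kind=raw.get("learner_kind", "gbt"),
            split_ratio=float(raw.get("split_ratio", 0.75)),
            cv_folds=int(raw.get("cv_folds", 5)),
            n_search=int(raw.get("n_search", 20)),
            constraints=_build(AdvisorConstraints, raw.get("constraints")),
            solver=_build(SolverOptions, raw.get("solver")),
            baseline=_build(EfsaBaseline, raw.get("baseline")),
            interpret_feature=raw.get("interpret_feature", "plain_water"),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        def plain(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: plain(getattr(obj, k)) for k in obj.__dataclass_fields__}
            if isinstance(obj, (tuple, list)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        return plain(self)

    def config_hash(self) -> str:
        """Stable across key-order permutations of semantically equal configs."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    artifacts: dict[str, str]
    row_counts: dict[str, int]
    wall_times_s: dict[str, float]
    version: str

    def as_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "artifacts": self.artifacts,
            "row_counts": self.row_counts,
            "wall_times_s": {k: round(v, 3) for k, v in self.wall_times_s.items()},
            "version": self.version,
        }


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full chain and write every stage artifact.

    Stages: cohort simulation, eligibility filtering + participant split,
    feature ranking + surrogate fit, water PDP/ALE curves, test-set advice,
    contingency scoring against the EFSA baseline.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}
    times: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    t = stage("simulate")
    cohort = generate_cohort(config.cohort, config.physiology)
    write_cohort(cohort, str(out / "cohort.csv"))
    artifacts["cohort"] = str(out / "cohort.csv")
    counts["cohort_rows"] = len(cohort)
    times["simulate"] = time.perf_counter() - t

    t = stage("prepare")
    filtered, report = apply_eligibility_filters(cohort, config.eligibility)
    split = split_by_participant(filtered, config.split_ratio, config.seed)
    split.train_rows.to_csv(out / "train.csv", index=False)
    split.test_rows.to_csv(out / "test.csv", index=False)
    (out / "filters.json").write_text(json.dumps(report.as_dict(), indent=2))
    artifacts.update(
        train=str(out / "train.csv"), test=str(out / "test.csv"),
        filters=str(out / "filters.json"),
    )
    counts["train_rows"] = len(split.train_rows)
    counts["test_rows"] = len(split.test_rows)
    times["prepare"] = time.perf_counter() - t

    t = stage("fit")
    candidates = [
        c for c in COHORT_COLUMNS
        if c not in ("participant_id", "visit_index", "urine_osm")
    ]
    importances = rank_features(split.train_rows, candidates, seed=config.seed)
    importances.table.to_csv(out / "importance.csv", index=False)
    features = prune_features(importances, config.feature_policy)
    model = fit_surrogate(
        split.train_rows, features, config.learner_kind,
        cv_folds=config.cv_folds, n_search=config.n_search, seed=config.seed,
    )
    save_model(model, str(out / "model"))
    eligible_test = split.test_rows[split.test_rows["urine_osm"].notna()]
    test_mae = mae(eligible_test["urine_osm"].to_numpy(float), model.predict(eligible_test))
    artifacts.update(importance=str(out / "importance.csv"), model=str(out / "model"))
    counts["n_features"] = len(features)
    times["fit"] = time.perf_counter() - t

    t = stage("interpret")
    train_known = split.train_rows[split.train_rows[config.interpret_feature].notna()]
    pdp = pdp_ice(model, train_known, config.interpret_feature)
    pdp.to_frame().to_csv(out / "pdp.csv", index=False)
    ale_res = ale(model, train_known, config.interpret_feature)
    ale_res.to_frame().to_csv(out / "ale.csv", index=False)
    drop = largest_drop_interval(pdp, window_mL=300.0)
    artifacts.update(pdp=str(out / "pdp.csv"), ale=str(out / "ale.csv"))
    times["interpret"] = time.perf_counter() - t

    t = stage("advise")
    advice = advise_testset(model, split.test_rows, config.constraints, config.solver)
    advice.to_csv(out / "advice.csv", index=False)
    artifacts["advice"] = str(out / "advice.csv")
    counts["advised_rows"] = len(advice)
    counts["skipped_rows"] = advice.attrs["skipped"]
    times["advise"] = time.perf_counter() - t

    t = stage("score")
    reports = compare_to_guidelines(
        split.test_rows, advice, config.constraints.target_uosm, config.baseline
    )
    score = {
        name: rep.as_dict() for name, rep in reports.items()
    }
    score["test_mae"] = round(test_mae, 2)
    score["largest_drop_interval_mL"] = list(drop) if drop else None
    (out / "report.json").write_text(json.dumps(score, indent=2))
    artifacts["report"] = str(out / "report.json")
    counts["scored_rows"] = reports["algorithm"].table.total
    times["score"] = time.perf_counter() - t

    manifest = RunManifest(
        config_hash=config.config_hash(),
        artifacts=artifacts,
        row_counts=counts,
        wall_times_s=times,
        version=__version__,
    )
    (out / "manifest.json").write_text(json.dumps(manifest.as_dict(), indent=2))
    return manifest
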