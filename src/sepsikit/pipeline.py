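"""End-to-end pipeline orchestration with content-hash stage caching.

Stages run in order generate -> label -> featurize -> evaluate (training and
evaluation share one stage because models are fitted per grid cell). Each
stage writes its artifacts plus a ``manifest.json`` recording the hash of
its configuration and of its upstream inputs; a rerun with an identical
configuration finds matching manifests and skips the stage, while deleting
an intermediate invalidates exactly the downstream stages. All randomness
derives from the single ``seed`` via fixed per-stage offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .errors import ConfigError
from .experiment import ExperimentGrid, ExperimentResult, run_experiment
from .features import FeatureSpec
from .onset import ExclusionConfig, exclusion_flow
from .sofa import SofaWindow
from .synthetic import CohortConfig, CohortTables, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("generate", "label", "featurize", "evaluate")


@dataclass
class RunConfig:
    """Single structured configuration for a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    definitions: tuple[str, ...] = ("H1", "H2", "H3")
    models: tuple[str, ...] = ("gbm", "lstm", "coxphm")
    windows: tuple[SofaWindow, ...] = (SofaWindow(24, 12),)
    horizons: tuple[int, ...] = (6,)
    variants: tuple[str, ...] = ("main",)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    train_fraction: float = 0.85
    n_boot: int = 100
    tune: bool = False
    seed: int = 0
    output_dir: str = "sepsikit_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.pop("cohort").items()})
        if "exclusion" in raw:
            excl = raw.pop("exclusion")
            if "excluded_units" in excl:
                excl["excluded_units"] = frozenset(excl["excluded_units"])
            kwargs["exclusion"] = ExclusionConfig(**excl)
        if "windows" in raw:
            kwargs["windows"] = tuple(SofaWindow(*w) for w in raw.pop("windows"))
        for key in ("definitions", "models", "horizons", "variants"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        kwargs.update(raw)
        return cls(**kwargs)

    def grid(self) -> ExperimentGrid:
        return ExperimentGrid(definitions=self.definitions, models=self.models,
                              windows=self.windows, horizons=self.horizons,
                              variants=self.variants)

    def config_hash(self, stage: str) -> str:
        relevant = {
            "generate": {"cohort": dataclasses.asdict(self.cohort), "seed": self.seed},
            "label": {"definitions": self.definitions,
                      "windows": [(w.x, w.y) for w in self.windows],
                      "variants": self.variants,
                      "exclusion": dataclasses.asdict(self.exclusion) | {
                          "excluded_units": sorted(self.exclusion.excluded_units)},
                      "seed": self.seed, "train_fraction": self.train_fraction},
            "featurize": {},
            "evaluate": {"models": self.models, "horizons": self.horizons,
                         "n_boot": self.n_boot, "tune": self.tune, "seed": self.seed},
        }[stage]
        payload = json.dumps(relevant, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _stage_dir(out: Path, stage: str) -> Path:
    d = out / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _manifest_path(out: Path, stage: str) -> Path:
    return out / stage / "manifest.json"


def _write_manifest(out: Path, stage: str, config_hash: str, input_hash: str,
                    outputs: list[str], elapsed: float) -> None:
    _manifest_path(out, stage).write_text(json.dumps({
        "stage": stage, "config_hash": config_hash, "input_hash": input_hash,
        "outputs": outputs, "elapsed_seconds": round(elapsed, 3),
    }, indent=2))


def _stage_fresh(out: Path, stage: str, config_hash: str, input_hash: str) -> bool:
    path = _manifest_path(out, stage)
    if not path.exists():
        return False
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError:
        return False
    if manifest.get("config_hash") != config_hash or manifest.get("input_hash") != input_hash:
        return False
    return all((out / stage / f).exists() for f in manifest.get("outputs", []))


def _manifest_hash(out: Path, stage: str) -> str:
    path = _manifest_path(out, stage)
    if not path.exists():
        return "missing"
    manifest = json.loads(path.read_text())
    return hashlib.sha256(json.dumps(manifest, sort_keys=True).encode()).hexdigest()


def run_all(config: RunConfig, force: bool = False,
            through: str = "evaluate") -> Path:
    """Execute (or resume) the pipeline up to and including ``through``.

    Returns the artifact directory. Stages already satisfied by cached
    manifests are skipped unless ``force`` is set.
    """
    from .features import build_feature_matrix

    if through not in STAGES:
        raise ConfigError(f"through must be one of {STAGES}, got {through!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(
        {"seed": config.seed, "definitions": config.definitions,
         "models": config.models, "horizons": config.horizons,
         "variants": config.variants,
         "windows": [(w.x, w.y) for w in config.windows]}, indent=2, default=str))

    # -- generate ---------------------------------------------------------
    stage, t0 = "generate", time.time()
    chash = config.config_hash(stage)
    if force or not _stage_fresh(out, stage, chash, "root"):
        logger.info("stage generate: running")
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        tables = generate_cohort(cohort_cfg)
        tables.save(_stage_dir(out, stage), fmt="csv")
        _write_manifest(out, stage, chash, "root",
                        ["stays.csv", "observations.csv", "doses.csv",
                         "cultures.csv", "ground_truth.csv"], time.time() - t0)
    else:
        logger.info("stage generate: cached, skipping")
    if through == "generate":
        return out
    tables = CohortTables.load(out / "generate", fmt="csv")

    # -- label ------------------------------------------------------------
    from .onset import apply_exclusions, compute_onsets, split_train_test
    from .sofa import SOFA_VARIABLES, build_hourly_grid, compute_sofa
    from .suspicion import compute_suspicion

    stage, t0 = "label", time.time()
    chash = config.config_hash(stage)
    ihash = _manifest_hash(out, "generate")
    if force or not _stage_fresh(out, stage, chash, ihash):
        logger.info("stage label: running")
        sdir = _stage_dir(out, stage)
        split = split_train_test(tables.stays, config.train_fraction, config.seed)
        grid = build_hourly_grid(tables.observations, tables.stays, variables=SOFA_VARIABLES)
        trace = compute_sofa(grid)
        trace.to_csv(sdir / "sofa_trace.csv", index=False)
        outputs = ["sofa_trace.csv"]
        flow_report: dict[str, list] = {}
        for variant in config.variants:
            include_other = variant == "other_cultures"
            susp = compute_suspicion(tables.doses, tables.cultures, tables.stays,
                                     include_other)
            excl = dataclasses.replace(config.exclusion,
                                       strict_h3_grace=(variant == "strict"))
            for window in config.windows:
                onsets = compute_onsets(susp, trace, window)
                tag = f"{variant}_x{window.x:g}_y{window.y:g}"
                onsets.to_csv(sdir / f"onsets_{tag}.csv", index=False)
                outputs.append(f"onsets_{tag}.csv")
                for definition in config.definitions:
                    assembly = apply_exclusions(tables.stays, onsets, excl, definition,
                                                split=split,
                                                observations=tables.observations)
                    name = f"cohort_{definition}_{tag}.csv"
                    assembly.to_csv(sdir / name, index=False)
                    outputs.append(name)
                    flow_report[f"{definition}_{tag}"] = exclusion_flow(assembly).to_dict("records")
        (sdir / "flow_report.json").write_text(json.dumps(flow_report, indent=2))
        outputs.append("flow_report.json")
        _write_manifest(out, stage, chash, ihash, outputs, time.time() - t0)
    else:
        logger.info("stage label: cached, skipping")
    if through == "label":
        return out

    # -- featurize --------------------------------------------------------
    stage, t0 = "featurize", time.time()
    chash = config.config_hash(stage)
    ihash = _manifest_hash(out, "generate")
    if force or not _stage_fresh(out, stage, chash, ihash):
        logger.info("stage featurize: running")
        features = build_feature_matrix(tables.observations, tables.stays)
        features.reset_index().to_parquet(_stage_dir(out, stage) / "features.parquet")
        _write_manifest(out, stage, chash, ihash, ["features.parquet"], time.time() - t0)
    else:
        logger.info("stage featurize: cached, skipping")
    if through == "featurize":
        return out
    features = pd.read_parquet(out / "featurize" / "features.parquet")
    features = features.set_index(["stay_id", "hour"])

    # -- evaluate (train + evaluate per grid cell) ------------------------
    stage, t0 = "evaluate", time.time()
    chash = config.config_hash(stage)
    ihash = _manifest_hash(out, "label") + _manifest_hash(out, "featurize")
    if force or not _stage_fresh(out, stage, chash, ihash):
        logger.info("stage evaluate: running")
        result = run_experiment(tables, config.grid(), seed=config.seed,
                                exclusion=config.exclusion,
                                train_fraction=config.train_fraction,
                                n_boot=config.n_boot, tune=config.tune,
                                features=features)
        sdir = _stage_dir(out, stage)
        result.reports_frame().to_csv(sdir / "reports.csv", index=False)
        result.reports_frame().to_json(sdir / "reports.json", orient="records", indent=2)
        result.table1.to_csv(sdir / "table1.csv", index=False)
        result.table2.to_csv(sdir / "table2.csv")
        result.roc_points.to_csv(sdir / "roc_points.csv", index=False)
        (sdir / "comparison_note.txt").write_text(result.comparison_note + "\n")
        (sdir / "skipped.json").write_text(json.dumps(result.skipped, indent=2))
        _write_manifest(out, stage, chash, ihash,
                        ["reports.csv", "reports.json", "table1.csv", "table2.csv",
                         "roc_points.csv", "comparison_note.txt", "skipped.json"],
                        time.time() - t0)
    else:
        logger.info("stage evaluate: cached, skipping")
    return out
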