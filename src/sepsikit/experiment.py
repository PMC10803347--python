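"""Definition-sensitivity experiment runner.

Evaluates every cell of a {definition} x {model} x {SOFA window} x {horizon}
x {exclusion variant} grid on one cohort: label the cohort under the cell's
definition, fit the cell's scorer on the training split, calibrate the alert
threshold to the target training sensitivity, then report pooled
patient-hour AUROC with a patient-level bootstrap CI plus thresholded
sensitivity/specificity/accuracy on the test split.

Exclusion variants:

* ``main`` — the standard exclusion chain, blood cultures only;
* ``strict`` — the early-onset grace exclusion uses the H3 onset for every
  definition (the strictest cohort; on H3 itself this equals ``main``);
* ``other_cultures`` — non-blood specimens also count toward suspicion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .features import FeatureSpec, build_feature_matrix
from .metrics import auroc, bootstrap_ci, confusion_metrics
from .models import DEFAULT_GRIDS, ModelSpec, calibrate_threshold, make_model, tune_cv
from .onset import (DEFINITIONS, ExclusionConfig, apply_exclusions, compute_onsets,
                    make_hourly_labels, split_train_test)
from .sofa import SOFA_VARIABLES, SofaWindow, build_hourly_grid, compute_sofa
from .suspicion import compute_suspicion
from .synthetic import CohortTables

logger = logging.getLogger(__name__)

VARIANTS = ("main", "strict", "other_cultures")
MODEL_KINDS = ("gbm", "lstm", "coxphm")


@dataclass(frozen=True)
class ExperimentGrid:
    definitions: tuple[str, ...] = DEFINITIONS
    models: tuple[str, ...] = MODEL_KINDS
    windows: tuple[SofaWindow, ...] = (SofaWindow(24, 12),)
    horizons: tuple[int, ...] = (6,)
    variants: tuple[str, ...] = ("main",)

    def __post_init__(self) -> None:
        for name, values, allowed in (
            ("definitions", self.definitions, DEFINITIONS),
            ("models", self.models, MODEL_KINDS),
            ("variants", self.variants, VARIANTS),
        ):
            if not values:
                raise ConfigError(f"grid axis {name} must be non-empty")
            bad = set(values) - set(allowed)
            if bad:
                raise ConfigError(f"grid axis {name} has unknown values {sorted(bad)}")
        if not self.windows or not self.horizons:
            raise ConfigError("grid axes windows and horizons must be non-empty")


@dataclass
class EvalReport:
    definition: str
    model: str
    window_x: float
    window_y: float
    horizon: int
    variant: str
    auroc: float
    ci_lower: float
    ci_upper: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float
    n_train: int
    n_test: int
    n_train_hours: int
    n_test_hours: int
    seed: int


@dataclass
class ExperimentResult:
    reports: list[EvalReport]
    skipped: list[dict]
    table1: pd.DataFrame
    table2: pd.DataFrame
    roc_points: pd.DataFrame
    comparison_note: str

    def reports_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.reports])


def _join_features(features: pd.DataFrame, labels: pd.DataFrame):
    idx = pd.MultiIndex.from_arrays([labels["stay_id"], labels["hour"]],
                                    names=features.index.names)
    X = features.loc[idx]
    y = labels["label"].to_numpy()
    groups = labels["stay_id"].to_numpy()
    return X, y, groups


def run_experiment(tables: CohortTables, grid: ExperimentGrid, *,
                   seed: int = 0, feature_spec: FeatureSpec | None = None,
                   exclusion: ExclusionConfig | None = None,
                   train_fraction: float = 0.85, n_boot: int = 100,
                   tune: bool = False, cv_folds: int = 5,
                   target_sensitivity: float = 0.85,
                   model_params: dict[str, dict] | None = None,
                   features: pd.DataFrame | None = None) -> ExperimentResult:
    """Run every grid cell on one cohort and collect evaluation reports.

    With ``tune=True`` each scorer's hyperparameters are selected by
    patient-grouped ``cv_folds``-fold CV on the training split (the small
    default grids in ``models.DEFAULT_GRIDS``) and refitted on the full
    training data; otherwise fixed defaults (or ``model_params``) are used.
    """
    grid.__post_init__()
    base_exclusion = exclusion or ExclusionConfig()
    model_params = model_params or {}
    stays, observations = tables.stays, tables.observations

    split = split_train_test(stays, train_fraction, seed)
    if features is None:
        logger.info("computing feature matrix")
        features = build_feature_matrix(observations, stays, feature_spec)
    sofa_grid = build_hourly_grid(observations, stays, variables=SOFA_VARIABLES)
    trace = compute_sofa(sofa_grid)

    susp_cache: dict[bool, pd.DataFrame] = {}
    reports: list[EvalReport] = []
    skipped: list[dict] = []
    roc_rows: list[pd.DataFrame] = []

    for variant in grid.variants:
        include_other = variant == "other_cultures"
        if include_other not in susp_cache:
            susp_cache[include_other] = compute_suspicion(
                tables.doses, tables.cultures, stays, include_other)
        suspicion = susp_cache[include_other]
        excl = replace(base_exclusion, strict_h3_grace=(variant == "strict"))
        for window in grid.windows:
            onsets = compute_onsets(suspicion, trace, window)
            for definition in grid.definitions:
                assembly = apply_exclusions(stays, onsets, excl, definition,
                                            split=split, observations=observations)
                for horizon in grid.horizons:
                    labels = make_hourly_labels(stays, assembly, horizon)
                    cell_id = {"definition": definition, "variant": variant,
                               "window_x": window.x, "window_y": window.y,
                               "horizon": horizon}
                    lab = labels.merge(assembly[["stay_id", "split"]], on="stay_id")
                    train_lab = lab[lab["split"] == "train"]
                    test_lab = lab[lab["split"] == "test"]
                    if len(train_lab) == 0 or train_lab["label"].nunique() < 2:
                        skipped.append({**cell_id, "reason": "training split has a single class"})
                        continue
                    if len(test_lab) == 0:
                        skipped.append({**cell_id, "reason": "test split is empty"})
                        continue
                    test_has_both = test_lab["label"].nunique() == 2
                    Xtr, ytr, gtr = _join_features(features, train_lab)
                    Xte, yte, gte = _join_features(features, test_lab)
                    n_train = train_lab["stay_id"].nunique()
                    n_test = test_lab["stay_id"].nunique()
                    for kind in grid.models:
                        spec = ModelSpec(kind=kind, seed=seed, horizon=horizon,
                                         grid=DEFAULT_GRIDS[kind] if tune else {})
                        logger.info("fitting %s / %s / %s", definition, variant, kind)
                        if tune and spec.grid:
                            _best, _cv, scorer = tune_cv(
                                lambda p, s=spec: make_model(s, p), spec,
                                Xtr, ytr, gtr, k=cv_folds)
                        else:
                            scorer = make_model(spec, model_params.get(kind))
                            scorer.fit(Xtr, ytr, gtr)
                        cal = calibrate_threshold(scorer.score(Xtr), ytr,
                                                  target=target_sensitivity)
                        test_scores = scorer.score(Xte)
                        if test_has_both:
                            point = auroc(test_scores, yte)
                            lo, hi = bootstrap_ci(auroc, test_scores, yte, gte,
                                                  n_resamples=n_boot, seed=seed)
                        else:
                            # AUROC undefined on a single-class test split;
                            # the cell still reports its confusion metrics
                            point, lo, hi = float("nan"), float("nan"), float("nan")
                        conf = confusion_metrics(test_scores >= cal.threshold, yte)
                        reports.append(EvalReport(
                            definition=definition, model=kind,
                            window_x=window.x, window_y=window.y,
                            horizon=horizon, variant=variant,
                            auroc=point, ci_lower=lo, ci_upper=hi,
                            sensitivity=conf["sensitivity"],
                            specificity=conf["specificity"],
                            accuracy=conf["accuracy"],
                            threshold=cal.threshold,
                            n_train=n_train, n_test=n_test,
                            n_train_hours=len(train_lab), n_test_hours=len(test_lab),
                            seed=seed))
                        if test_has_both:
                            roc_rows.append(_roc_points(test_scores, yte, definition,
                                                        kind, window, variant))

    table1 = _table1(reports)
    table2 = _table2(reports)
    note = _comparison_note(reports)
    roc_points = (pd.concat(roc_rows, ignore_index=True)
                  if roc_rows else pd.DataFrame(columns=["definition", "model", "window",
                                                         "variant", "fpr", "tpr"]))
    return ExperimentResult(reports=reports, skipped=skipped, table1=table1,
                            table2=table2, roc_points=roc_points, comparison_note=note)


def _roc_points(scores: np.ndarray, labels: np.ndarray, definition: str,
                model: str, window: SofaWindow, variant: str,
                max_points: int = 200) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    if len(fpr) > max_points:
        keep = np.linspace(0, len(fpr) - 1, max_points).astype(int)
        fpr, tpr = fpr[keep], tpr[keep]
    return pd.DataFrame({"definition": definition, "model": model,
                         "window": f"{{{window.x:g},{window.y:g}}}",
                         "variant": variant, "fpr": fpr, "tpr": tpr})


def _table1(reports: list[EvalReport]) -> pd.DataFrame:
    rows = [asdict(r) for r in reports if r.variant == "main"]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    df["auroc_ci"] = df.apply(
        lambda r: f"{r.auroc:.3f} [{r.ci_lower:.3f},{r.ci_upper:.3f}]", axis=1)
    return df[["definition", "model", "window_x", "window_y", "horizon",
               "auroc_ci", "specificity", "sensitivity", "accuracy"]]


def _table2(reports: list[EvalReport]) -> pd.DataFrame:
    if not reports:
        return pd.DataFrame()
    df = pd.DataFrame([asdict(r) for r in reports])
    out = df.pivot_table(index="variant", columns=["definition", "model"],
                         values="auroc", aggfunc="first")
    return out


def _comparison_note(reports: list[EvalReport]) -> str:
    main = [r for r in reports if r.variant == "main" and np.isfinite(r.auroc)]
    if not main:
        return "no main-variant cells were evaluated"
    by_def: dict[str, list[EvalReport]] = {}
    for r in main:
        by_def.setdefault(r.definition, []).append(r)
    def_mean = {d: float(np.mean([r.auroc for r in rs])) for d, rs in by_def.items()}
    worst_def = min(def_mean, key=def_mean.get)
    best_def = max(def_mean, key=def_mean.get)
    best_on_worst = max(by_def[worst_def], key=lambda r: r.auroc)
    worst_on_best = min(by_def[best_def], key=lambda r: r.auroc)
    if best_def == worst_def:
        return "single definition evaluated; no cross-definition comparison"
    note = (f"best model on worst definition: {best_on_worst.model} on {worst_def} "
            f"(AUROC {best_on_worst.auroc:.3f}); worst model on best definition: "
            f"{worst_on_best.model} on {best_def} (AUROC {worst_on_best.auroc:.3f}).")
    if best_on_worst.auroc < worst_on_best.auroc:
        note += (" Cross-definition inversion: the best model under the worst "
                 "definition underperforms the worst model under the best "
                 "definition — model rankings are not comparable across "
                 "onset definitions.")
    return note
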