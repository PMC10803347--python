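"""Patient-hour risk scorers and their tuning/calibration utilities.

Three interchangeable scorers share a common contract — ``fit(X, y, groups)``
then ``score(X)`` returning one risk value per patient-hour row, higher
meaning more likely to develop sepsis within the prediction horizon:

* :class:`GBMScorer` — a light gradient boosting machine classifier on
  independent patient-hour rows (lightgbm behind the interface);
* :class:`~sepsikit.lstm.LSTMScorer` — a small recurrent network over each
  stay's hourly sequence (own NumPy implementation, see ``lstm.py``);
* :class:`CoxHorizonScorer` — a proportional-hazards model with time-varying
  covariates scored as the T-hour event risk
  ``r(t) = 1 - exp(-[H0(t+T) - H0(t)] * exp(beta . x_t))`` with a
  Breslow-type baseline cumulative hazard (lifelines behind the interface).

Scores never read labels; all scorers are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Optional, Protocol

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractViolation
from .metrics import auroc

logger = logging.getLogger(__name__)


class RiskScorer(Protocol):
    def fit(self, X: pd.DataFrame, y: np.ndarray, groups: np.ndarray) -> "RiskScorer": ...
    def score(self, X: pd.DataFrame) -> np.ndarray: ...


@dataclass
class ModelSpec:
    """Model kind, hyperparameter grid, and seed for one training run."""

    kind: str = "gbm"
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0
    horizon: int = 6

    def __post_init__(self) -> None:
        if self.kind not in ("gbm", "lstm", "coxphm"):
            raise ConfigError(f"model kind must be gbm, lstm or coxphm, got {self.kind!r}")

    def configurations(self) -> list[dict]:
        if not self.grid:
            return [{}]
        keys = sorted(self.grid)
        return [dict(zip(keys, vals)) for vals in product(*(self.grid[k] for k in keys))]


DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gbm": {"num_leaves": [15, 31], "learning_rate": [0.05, 0.1], "n_estimators": [100, 200]},
    "lstm": {"hidden": [24], "epochs": [8]},
    "coxphm": {"penalizer": [0.1, 1.0]},
}


class GBMScorer:
    """Gradient-boosted tree classifier on patient-hour rows."""

    def __init__(self, num_leaves: int = 31, learning_rate: float = 0.1,
                 n_estimators: int = 100, min_child_samples: int = 60,
                 colsample_bytree: float = 0.8, seed: int = 0):
        self.num_leaves = num_leaves
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.min_child_samples = min_child_samples
        self.colsample_bytree = colsample_bytree
        self.seed = seed
        self._model = None
        self._constant: Optional[float] = None

    def fit(self, X: pd.DataFrame, y: np.ndarray, groups: np.ndarray) -> "GBMScorer":
        import lightgbm as lgb

        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            # degenerate target: score constant
            self._constant = float(y[0]) if len(y) else 0.0
            self._model = None
            return self
        self._constant = None
        self._model = lgb.LGBMClassifier(
            num_leaves=self.num_leaves,
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            min_child_samples=self.min_child_samples,
            colsample_bytree=self.colsample_bytree,
            random_state=self.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
        )
        self._model.fit(X.to_numpy(dtype=float), y)
        return self

    def score(self, X: pd.DataFrame) -> np.ndarray:
        if self._model is None:
            if self._constant is None:
                raise ContractViolation("score() called before fit()")
            return np.full(len(X), self._constant)
        import warnings

        with warnings.catch_warnings():
            # lightgbm names numpy columns internally; sklearn then warns on
            # every predict that the query matrix has no names
            warnings.filterwarnings("ignore", message="X does not have valid feature names")
            return self._model.predict_proba(X.to_numpy(dtype=float))[:, 1]


class CoxHorizonScorer:
    """Time-varying-covariate proportional hazards scored as T-hour risk.

    The event table is reconstructed from the hourly label table: a stay with
    any positive label is an event at one hour past its last labeled row
    (the grid onset hour); controls are censored at their last hour. Near-
    constant covariates are dropped and the rest standardized before the fit.
    """

    def __init__(self, horizon: int = 6, penalizer: float = 0.1, seed: int = 0):
        self.horizon = horizon
        self.penalizer = penalizer
        self.seed = seed
        self._fitter = None
        self._cols: list[str] = []
        self._mean: Optional[np.ndarray] = None
        self._scale: Optional[np.ndarray] = None
        self._baseline_times: Optional[np.ndarray] = None
        self._baseline_h0: Optional[np.ndarray] = None

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self._cols].to_numpy(dtype=float)
        return (Z - self._mean) / self._scale

    def fit(self, X: pd.DataFrame, y: np.ndarray, groups: np.ndarray) -> "CoxHorizonScorer":
        from lifelines import CoxTimeVaryingFitter

        y = np.asarray(y)
        groups = np.asarray(groups)
        hours = X.index.get_level_values("hour").to_numpy()

        vals = X.to_numpy(dtype=float)
        std = vals.std(axis=0)
        keep = std > 1e-8
        self._cols = [c for c, k in zip(X.columns, keep) if k]
        self._mean = vals[:, keep].mean(axis=0)
        self._scale = vals[:, keep].std(axis=0)
        Z = self._design(X)

        long = pd.DataFrame(Z, columns=self._cols)
        long["id"] = groups
        long["start"] = hours.astype(float)
        long["stop"] = hours.astype(float) + 1.0
        long["event"] = False
        df = pd.DataFrame({"g": groups, "h": hours, "y": y})
        last_hour = df.groupby("g")["h"].transform("max")
        septic = df.groupby("g")["y"].transform("max") > 0
        long.loc[(septic & (df["h"] == last_hour)).to_numpy(), "event"] = True

        self._fitter = CoxTimeVaryingFitter(penalizer=self.penalizer)
        self._fitter.fit(long, id_col="id", start_col="start", stop_col="stop",
                         event_col="event", show_progress=False)
        bch = self._fitter.baseline_cumulative_hazard_
        self._baseline_times = bch.index.to_numpy(dtype=float)
        self._baseline_h0 = bch.iloc[:, 0].to_numpy(dtype=float)
        return self

    def _h0(self, t: np.ndarray) -> np.ndarray:
        """Linearly interpolated Breslow baseline cumulative hazard.

        The raw Breslow estimate is a step function over ~n_events jump
        times, so a short horizon (t, t+T] frequently contains no jump and
        the step estimate would zero the risk irrespective of covariates.
        Linear interpolation spreads each increment over the preceding
        inter-event gap, giving a strictly informative T-hour risk.
        """
        return np.interp(t, self._baseline_times, self._baseline_h0,
                         left=0.0, right=float(self._baseline_h0[-1]))

    def score(self, X: pd.DataFrame) -> np.ndarray:
        if self._fitter is None:
            raise ContractViolation("score() called before fit()")
        hours = X.index.get_level_values("hour").to_numpy(dtype=float)
        lp = self._design(X) @ self._fitter.params_.to_numpy()
        delta = self._h0(hours + 1.0 + self.horizon) - self._h0(hours + 1.0)
        return 1.0 - np.exp(-np.clip(delta * np.exp(lp), 0.0, 700.0))


@dataclass(frozen=True)
class ThresholdCalibration:
    threshold: float
    achieved_sensitivity: float
    target_sensitivity: float = 0.85


def calibrate_threshold(scores: np.ndarray, labels: np.ndarray,
                        target: float = 0.85) -> ThresholdCalibration:
    """Largest threshold whose training patient-hour sensitivity >= target.

    With P positives that is the ceil(target * P)-th highest positive score;
    tied scores can only push the achieved sensitivity above the target.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    if len(pos) == 0:
        raise ContractViolation("threshold calibration requires at least one positive label")
    k = int(np.ceil(target * len(pos)))
    k = max(k, 1)
    threshold = float(np.sort(pos)[::-1][k - 1])
    achieved = float(np.mean(pos >= threshold))
    return ThresholdCalibration(threshold=threshold, achieved_sensitivity=achieved,
                                target_sensitivity=target)


def binarize(scores: np.ndarray, threshold: float,
             hours: Optional[np.ndarray] = None) -> tuple[np.ndarray, Optional[float]]:
    """Binary alert trace (score >= threshold) and the first alert hour."""
    if not np.isfinite(threshold):
        raise ContractViolation(f"threshold must be finite, got {threshold}")
    scores = np.asarray(scores, dtype=float)
    flags = scores >= threshold
    if hours is None:
        hours = np.arange(len(scores))
    hours = np.asarray(hours, dtype=float)
    first_alert = float(hours[flags].min()) if flags.any() else None
    return flags, first_alert


def tune_cv(make_scorer: Callable[[dict], RiskScorer], spec: ModelSpec,
            X: pd.DataFrame, y: np.ndarray, groups: np.ndarray,
            k: int = 5) -> tuple[dict, pd.DataFrame, RiskScorer]:
    """Patient-grouped k-fold hyperparameter selection, then refit on all data.

    Folds partition patients (no patient appears in two folds); the selection
    metric is the mean patient-hour AUROC across folds. Returns the winning
    configuration, the CV table (one row per configuration x fold), and the
    winner refitted on the full training data.
    """
    from sklearn.model_selection import GroupKFold

    y = np.asarray(y)
    groups = np.asarray(groups)
    n_patients = len(np.unique(groups))
    if n_patients < k:
        raise ContractViolation(f"{n_patients} patients < {k} folds")

    rows = []
    means: list[tuple[float, dict]] = []
    folds = list(GroupKFold(n_splits=k).split(X, y, groups))
    for params in spec.configurations():
        fold_scores = []
        for fold_idx, (tr, va) in enumerate(folds):
            scorer = make_scorer(params)
            scorer.fit(X.iloc[tr], y[tr], groups[tr])
            val_auc = auroc(scorer.score(X.iloc[va]), y[va])
            fold_scores.append(val_auc if val_auc is not None else np.nan)
            rows.append({"params": str(params), "fold": fold_idx, "auroc": fold_scores[-1]})
        means.append((float(np.nanmean(fold_scores)), params))
    best_mean, best_params = max(means, key=lambda t: t[0])
    logger.info("tune_cv selected %s (mean AUROC %.4f)", best_params, best_mean)
    best = make_scorer(best_params)
    best.fit(X, y, groups)
    return best_params, pd.DataFrame(rows), best


def make_model(spec: ModelSpec, params: dict | None = None) -> RiskScorer:
    """Instantiate a scorer of the spec's kind with the given hyperparameters."""
    from .lstm import LSTMScorer

    params = dict(params or {})
    if spec.kind == "gbm":
        return GBMScorer(seed=spec.seed, **params)
    if spec.kind == "lstm":
        return LSTMScorer(seed=spec.seed, **params)
    return CoxHorizonScorer(horizon=spec.horizon, seed=spec.seed, **params)
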