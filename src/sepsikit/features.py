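"""Patient-hour design matrix: raw forward-filled variables, rolling derived
features, and truncated path-signature features.

The default specification mirrors the modelling setup of the prediction
task: 38 raw columns (observed clinical variables plus demographics and
admission information) and 75 derived columns (8-hour rolling max/min/mean,
raw-measurement counts, 8-hour deltas, and depth-2 time-augmented signature
coefficients of selected vital pairs), 113 in total. The exact derived set
is configurable; the default is a documented, non-authoritative choice of
the same shape and style as published sepsis early-warning pipelines.

Every feature at hour ``h`` is a function of data at or before ``h``:
forward-fill only looks back, every rolling window is ``[h - L + 1, h]``
truncated at the stay start, and signature windows are backward-looking with
constant extrapolation before admission. Hours before a variable's first
observation are filled with a fixed per-variable reference value so that
scorers receive finite inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractViolation
from .signatures import batch_signature_depth2, signature_dim, signature_transform
from .synthetic import VARIABLE_TABLE

TRANSFORMS = ("rolling_max", "rolling_min", "rolling_mean", "measurement_count", "delta")

#: fill value used for hours before a variable's first observation
REFERENCE_VALUES: dict[str, float] = {
    **{name: spec[0] for name, spec in VARIABLE_TABLE.items()},
    "vent_flag": 0.0,
    "norepinephrine_dose": 0.0,
    "epinephrine_dose": 0.0,
    "dopamine_dose": 0.0,
    "dobutamine_dose": 0.0,
}

_OBSERVED_RAW = (
    "heart_rate", "sbp", "dbp", "map", "resp_rate", "temp", "spo2", "fio2",
    "pao2", "pf_ratio", "gcs", "platelets", "bilirubin", "creatinine", "bun",
    "lactate", "ph", "bicarbonate", "wbc", "hemoglobin", "glucose",
    "potassium", "sodium", "chloride", "magnesium", "calcium", "albumin",
    "alt", "ast", "urine_output", "vent_flag", "norepinephrine_dose",
    "dopamine_dose", "dobutamine_dose",
)
_STATIC_RAW = ("age", "sex_female", "icu_hour", "hosp_to_icu_hours")

_ROLL_STAT_VARS = (
    "heart_rate", "map", "sbp", "resp_rate", "temp", "spo2", "pf_ratio",
    "gcs", "platelets", "bilirubin", "creatinine", "lactate", "wbc", "bun", "ph",
)
_COUNT_VARS = (
    "heart_rate", "map", "resp_rate", "spo2", "temp", "platelets",
    "creatinine", "lactate", "wbc", "bilirubin",
)
_DELTA_VARS = (
    "heart_rate", "map", "resp_rate", "temp", "spo2", "lactate",
    "creatinine", "platelets",
)


def _default_derived() -> list[tuple[str, str, str, int]]:
    derived = []
    for var in _ROLL_STAT_VARS:
        for stat in ("rolling_max", "rolling_min", "rolling_mean"):
            derived.append((f"{var}_{stat[8:]}8h", var, stat, 8))
    for var in _COUNT_VARS:
        derived.append((f"{var}_count8h", var, "measurement_count", 8))
    for var in _DELTA_VARS:
        derived.append((f"{var}_delta8h", var, "delta", 8))
    return derived


@dataclass
class FeatureSpec:
    """Configuration of the design matrix columns.

    ``derived_definitions`` entries are (name, source variable, transform,
    lookback hours); transforms are rolling_max / rolling_min / rolling_mean
    / measurement_count / delta. ``signature_channels`` lists variable groups
    each expanded to a depth-``signature_depth`` signature over a
    ``signature_lookback``-hour window, time-augmented when ``time_augment``.
    """

    raw_variables: tuple[str, ...] = _OBSERVED_RAW + _STATIC_RAW
    derived_definitions: list[tuple[str, str, str, int]] = field(default_factory=_default_derived)
    signature_channels: list[tuple[str, ...]] = field(default_factory=lambda: [("heart_rate", "map")])
    signature_depth: int = 2
    signature_lookback: int = 8
    time_augment: bool = True
    add_count_channel: bool = False

    def validate(self) -> None:
        names = [d[0] for d in self.derived_definitions]
        if len(set(names)) != len(names):
            raise ConfigError("derived_definitions names must be unique")
        if len(set(self.raw_variables)) != len(self.raw_variables):
            raise ConfigError("raw_variables must be unique")
        for name, _src, transform, lookback in self.derived_definitions:
            if transform not in TRANSFORMS:
                raise ConfigError(f"unknown transform {transform!r} in derived feature {name!r}")
            if lookback < 1:
                raise ConfigError(f"lookback must be >= 1 in derived feature {name!r}")
        if self.signature_depth < 1:
            raise ConfigError(f"signature_depth must be >= 1, got {self.signature_depth}")
        if self.signature_lookback < 2:
            raise ConfigError(f"signature_lookback must be >= 2, got {self.signature_lookback}")

    @property
    def observed_variables(self) -> list[str]:
        return [v for v in self.raw_variables if v not in _STATIC_RAW]

    def signature_feature_names(self) -> list[str]:
        names = []
        for group in self.signature_channels:
            d = len(group) + (1 if self.time_augment else 0) + (1 if self.add_count_channel else 0)
            tag = "_".join(group)
            for i in range(signature_dim(d, self.signature_depth)):
                names.append(f"sig_{tag}_{i}")
        return names

    def feature_names(self) -> list[str]:
        return (list(self.raw_variables)
                + [d[0] for d in self.derived_definitions]
                + self.signature_feature_names())


def filled_grid(grid: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Replace pre-first-observation NaNs with per-variable reference values."""
    out = grid.copy()
    for var in variables:
        ref = REFERENCE_VALUES.get(var, 0.0)
        out[var] = out[var].fillna(ref)
    return out


def rolling_features(grid: pd.DataFrame, observations: pd.DataFrame,
                     spec: FeatureSpec) -> pd.DataFrame:
    """Derived columns on the (reference-filled) hourly grid.

    Rolling statistics and deltas read the filled grid; measurement_count
    counts raw (pre-fill) observations whose hour falls in the lookback.
    """
    out = grid[["stay_id", "hour"]].copy()
    g = grid.groupby("stay_id", sort=False)

    count_cache: dict[str, pd.Series] = {}

    def obs_counts(var: str) -> pd.Series:
        if var not in count_cache:
            sub = observations[observations["variable"] == var].copy()
            if len(sub) == 0:
                count_cache[var] = pd.Series(0.0, index=out.index)
            else:
                sub["hour"] = np.floor(sub["time"].to_numpy(dtype=float)).astype(np.int64)
                per_hour = sub.groupby(["stay_id", "hour"]).size().rename("n").reset_index()
                merged = out.merge(per_hour, on=["stay_id", "hour"], how="left")["n"].fillna(0.0)
                count_cache[var] = merged
        return count_cache[var]

    for name, src, transform, lookback in spec.derived_definitions:
        if src not in grid.columns and transform != "measurement_count":
            raise ConfigError(f"derived feature {name!r} reads missing variable {src!r}")
        if transform == "rolling_max":
            col = g[src].rolling(lookback, min_periods=1).max().reset_index(drop=True)
        elif transform == "rolling_min":
            col = g[src].rolling(lookback, min_periods=1).min().reset_index(drop=True)
        elif transform == "rolling_mean":
            col = g[src].rolling(lookback, min_periods=1).mean().reset_index(drop=True)
        elif transform == "measurement_count":
            counts = obs_counts(src)
            col = (counts.groupby(grid["stay_id"], sort=False)
                   .rolling(lookback, min_periods=1).sum().reset_index(drop=True))
        else:  # delta: value now minus value at the window start
            shifted = g[src].shift(lookback - 1)
            first = g[src].transform("first")
            col = grid[src] - shifted.fillna(first)
        out[name] = np.asarray(col)
    return out


def _stay_signature_block(values: np.ndarray, lookback: int, depth: int,
                          time_augment: bool, add_count: bool) -> np.ndarray:
    """Signatures of backward windows at every hour of one stay.

    ``values`` has shape (n_hours, n_channels). Windows are the last
    ``lookback`` hours, edge-padded with the hour-0 value (time keeps
    stepping, so the padded prefix is a constant segment of the path).
    """
    n, c = values.shape
    pad = np.repeat(values[:1], lookback - 1, axis=0)
    padded = np.concatenate([pad, values], axis=0)
    windows = np.lib.stride_tricks.sliding_window_view(padded, lookback, axis=0)
    windows = np.ascontiguousarray(np.moveaxis(windows, -1, 1))  # (n, lookback, c)
    chans = [windows]
    if time_augment:
        t = np.broadcast_to(np.arange(lookback, dtype=float)[None, :, None], (n, lookback, 1))
        chans.insert(0, t)
    if add_count:
        cum = np.broadcast_to(np.arange(lookback, dtype=float)[None, :, None], (n, lookback, 1))
        chans.append(cum)
    paths = np.concatenate(chans, axis=2)
    if depth == 2:
        return batch_signature_depth2(paths)
    return np.stack([signature_transform(p, depth) for p in paths])


def signature_features(grid: pd.DataFrame, spec: FeatureSpec) -> pd.DataFrame:
    """Signature coefficient columns for every configured channel group."""
    out = grid[["stay_id", "hour"]].copy()
    names = spec.signature_feature_names()
    if not names:
        return out
    blocks = []
    for _sid, stay_grid in grid.groupby("stay_id", sort=False):
        group_feats = []
        for group in spec.signature_channels:
            vals = stay_grid[list(group)].to_numpy(dtype=float)
            group_feats.append(_stay_signature_block(
                vals, spec.signature_lookback, spec.signature_depth,
                spec.time_augment, spec.add_count_channel))
        blocks.append(np.concatenate(group_feats, axis=1))
    out[names] = np.concatenate(blocks, axis=0)
    return out


def assemble_matrix(grid: pd.DataFrame, derived: pd.DataFrame,
                    signatures: pd.DataFrame, stays: pd.DataFrame,
                    spec: FeatureSpec) -> pd.DataFrame:
    """Join raw, derived, signature and static columns into the design matrix.

    Returns a DataFrame indexed by (stay_id, hour) with exactly
    ``spec.feature_names()`` columns in fixed order.
    """
    for name, part in (("derived", derived), ("signatures", signatures)):
        if len(part) != len(grid) or not (
            part[["stay_id", "hour"]].to_numpy() == grid[["stay_id", "hour"]].to_numpy()
        ).all():
            raise ContractViolation(f"{name} rows are not aligned with the grid rows")
    static = stays.set_index("stay_id")
    mat = grid.copy()
    for name, part in (("derived", derived), ("signatures", signatures)):
        extra = [c for c in part.columns if c not in ("stay_id", "hour")]
        mat[extra] = part[extra].to_numpy()
    mat["age"] = static.loc[mat["stay_id"], "age"].to_numpy()
    mat["sex_female"] = (static.loc[mat["stay_id"], "sex"] == "F").to_numpy().astype(float)
    mat["icu_hour"] = mat["hour"].astype(float)
    mat["hosp_to_icu_hours"] = static.loc[mat["stay_id"], "hosp_to_icu_hours"].to_numpy()
    missing = [c for c in spec.feature_names() if c not in mat.columns]
    if missing:
        raise ContractViolation(f"assembled matrix is missing columns {missing[:10]}")
    mat = mat.set_index(["stay_id", "hour"])
    return mat[spec.feature_names()]


def build_feature_matrix(observations: pd.DataFrame, stays: pd.DataFrame,
                         spec: FeatureSpec | None = None) -> pd.DataFrame:
    """Full design matrix for every in-stay hour of every stay."""
    from .sofa import build_hourly_grid

    spec = spec or FeatureSpec()
    spec.validate()
    grid = build_hourly_grid(observations, stays, variables=spec.observed_variables)
    grid = filled_grid(grid, spec.observed_variables)
    derived = rolling_features(grid, observations, spec)
    sigs = signature_features(grid, spec)
    return assemble_matrix(grid, derived, sigs, stays, spec)
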