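"""Hourly SOFA computation and in-window deterioration detection.

The grid is hourly, hours ``0 .. ceil(los) - 1``, forward-filled with no
staleness limit (the only imputation used anywhere in the package). A cell at
hour ``h`` is the last observation at or before the end of hour ``h``; ties
within an hour resolve to the latest observation. Cells before a variable's
first observation are absent (NaN) and contribute 0 to the subscore for that
organ — an unmeasured organ cannot be scored.

``detect_tsofa`` implements the deterioration rule: within the SOFA window
``[t_suspicion - x, t_suspicion + y]`` (intersected with the stay), the first
hour at which the total score is at least two points above its value at the
first hour of the restricted window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractViolation, ValidationError

SOFA_VARIABLES = (
    "pf_ratio", "vent_flag", "platelets", "bilirubin", "map",
    "norepinephrine_dose", "epinephrine_dose", "dopamine_dose",
    "dobutamine_dose", "gcs", "creatinine", "urine_output",
)

NONNEGATIVE_VARIABLES = (
    "pf_ratio", "platelets", "bilirubin", "creatinine", "urine_output",
    "norepinephrine_dose", "epinephrine_dose", "dopamine_dose", "dobutamine_dose",
)


@dataclass(frozen=True)
class SofaWindow:
    """Hours before (``x``) and after (``y``) t_suspicion searched for the SOFA rise."""

    x: float = 24.0
    y: float = 12.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ConfigError(f"SofaWindow requires x >= 0 and y >= 0, got {{{self.x}, {self.y}}}")


def n_grid_hours(los_hours: float) -> int:
    """Number of hourly grid rows for a stay: hours 0 .. ceil(los) - 1."""
    return max(int(np.ceil(los_hours)), 1)


def build_hourly_grid(observations: pd.DataFrame, stays: pd.DataFrame,
                      variables: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Forward-filled hourly wide grid for every stay.

    Parameters
    ----------
    observations : long table with columns stay_id, variable, time, value.
    stays : table with stay_id and los_hours (grid length per stay).
    variables : columns to materialise; defaults to every variable present.

    Returns a DataFrame with columns ``stay_id``, ``hour`` and one column per
    variable; NaN marks hours before the first observation of a variable.
    """
    if len(observations) and (observations["time"].to_numpy() < 0).any():
        raise ContractViolation("observation times must be >= 0 (hours since ICU admission)")
    if variables is None:
        variables = sorted(observations["variable"].unique()) if len(observations) else []
    variables = list(variables)

    frames = []
    for stay_id, los in zip(stays["stay_id"].to_numpy(), stays["los_hours"].to_numpy(dtype=float)):
        n_hours = n_grid_hours(los)
        frames.append(pd.DataFrame({
            "stay_id": stay_id,
            "hour": np.arange(n_hours, dtype=np.int64),
        }))
    base = pd.concat(frames, ignore_index=True)

    if len(observations) == 0 or not variables:
        for var in variables:
            base[var] = np.nan
        return base

    obs = observations[observations["variable"].isin(variables)].copy()
    obs["hour"] = np.floor(obs["time"].to_numpy(dtype=float)).astype(np.int64)
    # latest observation within each (stay, variable, hour) wins
    obs = obs.sort_values(["stay_id", "variable", "hour", "time"], kind="mergesort")
    cell = obs.groupby(["stay_id", "variable", "hour"], sort=False)["value"].last().reset_index()
    wide = cell.pivot_table(index=["stay_id", "hour"], columns="variable",
                            values="value", aggfunc="last")
    grid = base.merge(wide.reset_index(), on=["stay_id", "hour"], how="left")
    value_cols = [c for c in grid.columns if c not in ("stay_id", "hour")]
    grid[value_cols] = grid.groupby("stay_id", sort=False)[value_cols].ffill()
    for var in variables:
        if var not in grid.columns:
            grid[var] = np.nan
    return grid[["stay_id", "hour"] + variables]


def _col(grid: pd.DataFrame, name: str) -> np.ndarray:
    if name in grid.columns:
        return grid[name].to_numpy(dtype=float)
    return np.full(len(grid), np.nan)


def _respiration(pf: np.ndarray, vent: np.ndarray) -> np.ndarray:
    score = np.zeros(len(pf), dtype=np.int64)
    on_vent = vent >= 0.5
    with np.errstate(invalid="ignore"):
        score = np.where(pf < 400, 1, score)
        score = np.where(pf < 300, 2, score)
        score = np.where((pf < 200) & on_vent, 3, score)
        score = np.where((pf < 100) & on_vent, 4, score)
    return np.where(np.isnan(pf), 0, score)


def _coagulation(platelets: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        score = np.select(
            [platelets < 20, platelets < 50, platelets < 100, platelets < 150],
            [4, 3, 2, 1], default=0)
    return np.where(np.isnan(platelets), 0, score)


def _liver(bilirubin: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        score = np.select(
            [bilirubin >= 12.0, bilirubin >= 6.0, bilirubin >= 2.0, bilirubin >= 1.2],
            [4, 3, 2, 1], default=0)
    return np.where(np.isnan(bilirubin), 0, score)


def _cardiovascular(mapress: np.ndarray, norepi: np.ndarray, epi: np.ndarray,
                    dopa: np.ndarray, dobu: np.ndarray) -> np.ndarray:
    norepi = np.nan_to_num(norepi)
    epi = np.nan_to_num(epi)
    dopa = np.nan_to_num(dopa)
    dobu = np.nan_to_num(dobu)
    score = np.zeros(len(mapress), dtype=np.int64)
    with np.errstate(invalid="ignore"):
        score = np.where(mapress < 70, 1, score)
    score = np.where((dopa > 0) | (dobu > 0), np.maximum(score, 2), score)
    score = np.where((dopa > 5) | ((norepi > 0) & (norepi <= 0.1))
                     | ((epi > 0) & (epi <= 0.1)), np.maximum(score, 3), score)
    score = np.where((dopa > 15) | (norepi > 0.1) | (epi > 0.1), 4, score)
    return score


def _cns(gcs: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        score = np.select([gcs < 6, gcs <= 9, gcs <= 12, gcs <= 14], [4, 3, 2, 1], default=0)
    return np.where(np.isnan(gcs), 0, score)


def _renal(creatinine: np.ndarray, urine_24h: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        cr = np.select(
            [creatinine >= 5.0, creatinine >= 3.5, creatinine >= 2.0, creatinine >= 1.2],
            [4, 3, 2, 1], default=0)
        cr = np.where(np.isnan(creatinine), 0, cr)
        uo = np.select([urine_24h < 200, urine_24h < 500], [4, 3], default=0)
        uo = np.where(np.isnan(urine_24h), 0, uo)
    return np.maximum(cr, uo)


def compute_sofa(grid: pd.DataFrame) -> pd.DataFrame:
    """Six SOFA subscores and the total at every grid hour.

    Standard thresholds: respiration from the PaO2/FiO2 ratio (scores 3-4
    require ventilation), coagulation from platelets (x10^3/uL), liver from
    bilirubin (mg/dL), cardiovascular from MAP and vasopressor dose bands
    (norepinephrine/epinephrine in ug/kg/min, dopamine/dobutamine in
    ug/kg/min), CNS from GCS, renal from the worse of the creatinine band and
    the rolling-24h urine output band (the urine band needs a full 24 h of
    data before it contributes).
    """
    for var in NONNEGATIVE_VARIABLES:
        if var in grid.columns:
            vals = grid[var].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                bad = vals < 0
            if bad.any():
                rows = np.flatnonzero(bad)[:20].tolist()
                raise ValidationError(f"negative values for {var!r} at grid rows {rows}")

    urine = grid["urine_output"] if "urine_output" in grid.columns else pd.Series(np.nan, index=grid.index)
    urine_24h = (
        urine.groupby(grid["stay_id"], sort=False)
        .rolling(window=24, min_periods=24).sum()
        .reset_index(level=0, drop=True)
        .to_numpy(dtype=float)
    )

    out = grid[["stay_id", "hour"]].copy()
    out["respiration"] = _respiration(_col(grid, "pf_ratio"), np.nan_to_num(_col(grid, "vent_flag")))
    out["coagulation"] = _coagulation(_col(grid, "platelets"))
    out["liver"] = _liver(_col(grid, "bilirubin"))
    out["cardiovascular"] = _cardiovascular(
        _col(grid, "map"), _col(grid, "norepinephrine_dose"), _col(grid, "epinephrine_dose"),
        _col(grid, "dopamine_dose"), _col(grid, "dobutamine_dose"))
    out["cns"] = _cns(_col(grid, "gcs"))
    out["renal"] = _renal(_col(grid, "creatinine"), urine_24h)
    subs = ["respiration", "coagulation", "liver", "cardiovascular", "cns", "renal"]
    out[subs] = out[subs].astype(np.int64)
    out["total"] = out[subs].sum(axis=1)
    return out


def detect_tsofa(totals: np.ndarray | pd.Series, t_suspicion: float,
                 window: SofaWindow) -> Optional[int]:
    """First in-window hour with total SOFA >= (window-initial value + 2).

    ``totals`` is one stay's hourly total score, index = hour. The window is
    the integer hours ``h`` with ``max(0, t_suspicion - x) <= h`` and
    ``h <= min(last_hour, t_suspicion + y)``; the initial value is the total
    at the first such hour. Returns None when the restricted window is empty
    or no rise occurs.
    """
    totals = np.asarray(totals)
    n = len(totals)
    if n == 0:
        return None
    h_lo = max(0, int(np.ceil(t_suspicion - window.x)))
    h_hi = min(n - 1, int(np.floor(t_suspicion + window.y)))
    if h_lo > h_hi:
        return None
    initial = totals[h_lo]
    for h in range(h_lo, h_hi + 1):
        if totals[h] >= initial + 2:
            return h
    return None


def detect_tsofa_all(trace: pd.DataFrame, suspicion: pd.DataFrame,
                     window: SofaWindow) -> pd.DataFrame:
    """Per-stay t_sofa for every stay with a t_suspicion.

    ``trace`` is a compute_sofa output covering all stays; ``suspicion`` has
    columns stay_id and t_suspicion (NaN rows yield NaN t_sofa).
    """
    by_stay = {sid: g["total"].to_numpy() for sid, g in trace.groupby("stay_id", sort=False)}
    rows = []
    for sid, t_susp in zip(suspicion["stay_id"].to_numpy(), suspicion["t_suspicion"].to_numpy(dtype=float)):
        t_sofa = np.nan
        if np.isfinite(t_susp) and sid in by_stay:
            hit = detect_tsofa(by_stay[sid], float(t_susp), window)
            if hit is not None:
                t_sofa = float(hit)
        rows.append((sid, t_sofa))
    return pd.DataFrame(rows, columns=["stay_id", "t_sofa"])
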