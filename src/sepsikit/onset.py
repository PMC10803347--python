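"""Sepsis onset assignment (H1/H2/H3), cohort exclusions, splitting, and
hourly prediction labels.

The three competing onset definitions read the same pair of event times:

* **H1** — onset at the organ-dysfunction time, ``t_sepsis = t_sofa``;
* **H2** — onset at suspicion of infection, ``t_sepsis = t_suspicion``;
* **H3** — onset at the earlier of the two.

Sepsis requires *both* events, so a stay with only one of them is a control
under every definition. Exclusions are applied in a fixed, documented order
so that flow-diagram counts are reproducible; the train/test split is drawn
*before* exclusions, stratified on sex, age quartile, length-of-stay
quartile, and ever-ventilated status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractViolation
from .sofa import SofaWindow, compute_sofa, detect_tsofa_all, n_grid_hours

logger = logging.getLogger(__name__)

DEFINITIONS = ("H1", "H2", "H3")

EXCLUSION_ORDER = (
    "pre_icu_antibiotics",
    "excluded_care_unit",
    "elective_surgical",
    "los_out_of_bounds",
    "no_vital_signs",
    "early_onset",
    "duplicate_patient",
)


@dataclass(frozen=True)
class ExclusionConfig:
    """Cohort exclusion rules; defaults follow the study inclusion band.

    ``strict_h3_grace`` applies the early-onset grace rule using the H3
    onset (the earliest of the three) regardless of the definition under
    analysis — the strictest cohort, used to isolate definition effects from
    cohort effects.
    """

    min_los: float = 4.0
    max_los: float = 480.0
    onset_grace: float = 4.0
    exclude_pre_icu_abx: bool = True
    excluded_units: frozenset[str] = frozenset({"CSRU"})
    exclude_elective_surgical: bool = True
    require_any_vitals: bool = True
    strict_h3_grace: bool = False

    def __post_init__(self) -> None:
        if not self.min_los < self.max_los:
            raise ConfigError(f"min_los must be < max_los, got {self.min_los} >= {self.max_los}")
        if self.onset_grace < 0:
            raise ConfigError(f"onset_grace must be >= 0, got {self.onset_grace}")


def assign_onset(t_suspicion: float, t_sofa: float, definition: str) -> float:
    """t_sepsis under one definition; NaN unless both inputs are present."""
    if definition not in DEFINITIONS:
        raise ConfigError(f"definition must be one of {DEFINITIONS}, got {definition!r}")
    if not (np.isfinite(t_suspicion) and np.isfinite(t_sofa)):
        return float("nan")
    if definition == "H1":
        return float(t_sofa)
    if definition == "H2":
        return float(t_suspicion)
    return float(min(t_sofa, t_suspicion))


def compute_onsets(suspicion: pd.DataFrame, sofa_trace: pd.DataFrame,
                   window: SofaWindow) -> pd.DataFrame:
    """Per-stay onset record: t_suspicion, in-window t_sofa, and H1/H2/H3 onsets."""
    tsofa = detect_tsofa_all(sofa_trace, suspicion, window)
    onsets = suspicion.merge(tsofa, on="stay_id", how="left")
    ts = onsets["t_suspicion"].to_numpy(dtype=float)
    tf = onsets["t_sofa"].to_numpy(dtype=float)
    both = np.isfinite(ts) & np.isfinite(tf)
    onsets["t_sepsis_h1"] = np.where(both, tf, np.nan)
    onsets["t_sepsis_h2"] = np.where(both, ts, np.nan)
    onsets["t_sepsis_h3"] = np.where(both, np.minimum(tf, ts), np.nan)
    onsets["window_x"] = window.x
    onsets["window_y"] = window.y
    return onsets


def label_from_sofa_and_suspicion(observations: pd.DataFrame, stays: pd.DataFrame,
                                  doses: pd.DataFrame, cultures: pd.DataFrame,
                                  window: SofaWindow,
                                  include_other_specimens: bool = False) -> pd.DataFrame:
    """Convenience: run grid -> SOFA -> suspicion -> onsets in one call."""
    from .sofa import SOFA_VARIABLES, build_hourly_grid
    from .suspicion import compute_suspicion

    grid = build_hourly_grid(observations, stays, variables=SOFA_VARIABLES)
    trace = compute_sofa(grid)
    susp = compute_suspicion(doses, cultures, stays, include_other_specimens)
    return compute_onsets(susp, trace, window)


def split_train_test(stays: pd.DataFrame, train_fraction: float = 0.85,
                     seed: int = 0) -> pd.Series:
    """Stratified train/test assignment, one label per stay.

    Strata are sex x age quartile x LOS quartile x ever_ventilated, with
    quartiles computed on the cohort being split. Train counts use
    largest-remainder allocation: each stratum contributes
    floor(train_fraction * n) and the strata with the largest fractional
    remainders absorb the slots needed to reach the global
    round(train_fraction * N), so every stratum is within one patient of the
    target fraction and small cohorts still receive a test set. Singleton
    strata go to train (logged). Deterministic given the seed.
    """
    if len(stays) == 0:
        raise ContractViolation("cannot split an empty stays table")
    rng = np.random.default_rng(seed)
    age_q = pd.qcut(stays["age"], 4, labels=False, duplicates="drop")
    los_q = pd.qcut(stays["los_hours"], 4, labels=False, duplicates="drop")
    strata = (
        stays["sex"].astype(str) + "|" + age_q.astype(str) + "|"
        + los_q.astype(str) + "|" + stays["ever_ventilated"].astype(str)
    )
    groups = [(key, np.asarray(idx)) for key, idx in strata.groupby(strata).groups.items()]
    quotas = []
    for key, idx in groups:
        n = len(idx)
        exact = train_fraction * n
        base = 1 if n == 1 else int(np.floor(exact))
        quotas.append([key, idx, base, exact - base])
        if n == 1:
            logger.warning("stratum of size 1 assigned to train")
    target_train = int(round(train_fraction * len(stays)))
    short = target_train - sum(q[2] for q in quotas)
    if short > 0:
        # hand the remaining train slots to the largest remainders
        eligible = sorted((q for q in quotas if q[2] < len(q[1])),
                          key=lambda q: -q[3])
        for q in eligible[:short]:
            q[2] += 1
    assignment = pd.Series("train", index=stays.index, name="split")
    for _key, idx, n_train, _rem in quotas:
        order = rng.permutation(len(idx))
        assignment.loc[idx[order[n_train:]]] = "test"
    return assignment


def apply_exclusions(stays: pd.DataFrame, onsets: pd.DataFrame,
                     config: ExclusionConfig, definition: str,
                     split: pd.Series | None = None,
                     observations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort assembly: inclusion flag, first-fired exclusion reason, split.

    The exclusion order is fixed: (1) pre-ICU antibiotics, (2) excluded care
    unit, (3) elective surgical, (4) LOS out of bounds, (5) all vital signs
    missing, (6) onset within the grace period of admission (H3's onset when
    ``strict_h3_grace``), (7) duplicate patient (earliest stay kept). Each
    excluded stay carries exactly the first reason that fired.
    """
    if definition not in DEFINITIONS:
        raise ConfigError(f"definition must be one of {DEFINITIONS}, got {definition!r}")
    if set(stays["stay_id"]) - set(onsets["stay_id"]):
        raise ContractViolation("onsets table does not cover every stay")

    df = stays.merge(onsets, on="stay_id", how="left", validate="one_to_one")
    onset_col = "t_sepsis_h3" if config.strict_h3_grace else f"t_sepsis_{definition.lower()}"
    t_onset = df[onset_col].to_numpy(dtype=float)

    has_vitals = pd.Series(True, index=df.index)
    if config.require_any_vitals and observations is not None:
        vital_names = {"heart_rate", "sbp", "dbp", "map", "resp_rate", "temp", "spo2"}
        vit = observations[observations["variable"].isin(vital_names)]
        stays_with_vitals = set(vit["stay_id"].unique())
        has_vitals = df["stay_id"].isin(stays_with_vitals)

    reason = pd.Series(pd.NA, index=df.index, dtype="object")

    def mark(mask: pd.Series | np.ndarray, name: str) -> None:
        new = pd.Series(np.asarray(mask, dtype=bool), index=df.index) & reason.isna()
        reason[new] = name

    if config.exclude_pre_icu_abx:
        mark(df["pre_icu_antibiotics"].to_numpy(dtype=bool), "pre_icu_antibiotics")
    mark(df["care_unit"].isin(config.excluded_units), "excluded_care_unit")
    if config.exclude_elective_surgical:
        mark(df["elective_surgical"].to_numpy(dtype=bool), "elective_surgical")
    los = df["los_hours"].to_numpy(dtype=float)
    mark((los < config.min_los) | (los > config.max_los), "los_out_of_bounds")
    if config.require_any_vitals and observations is not None:
        mark(~has_vitals, "no_vital_signs")
    with np.errstate(invalid="ignore"):
        early = np.isfinite(t_onset) & (t_onset <= config.onset_grace)
    mark(early, "early_onset")
    # one stay per patient: keep the earliest stay_id among still-candidate rows
    candidate = reason.isna()
    first_stay = df[candidate].groupby("patient_id")["stay_id"].transform("min")
    dup = pd.Series(False, index=df.index)
    dup.loc[candidate] = (df.loc[candidate, "stay_id"] != first_stay).to_numpy()
    mark(dup, "duplicate_patient")

    out = df[["stay_id", "patient_id"]].copy()
    out["included"] = reason.isna()
    out["exclusion_reason"] = reason
    out["t_sepsis"] = df[f"t_sepsis_{definition.lower()}"]
    out["definition"] = definition
    if split is not None:
        out["split"] = split.to_numpy()
    return out


def exclusion_flow(assembly: pd.DataFrame) -> pd.DataFrame:
    """Flow-diagram counts: stays removed per reason, in application order."""
    counts = assembly["exclusion_reason"].value_counts()
    rows = [{"step": "assessed", "n": len(assembly)}]
    for reason in EXCLUSION_ORDER:
        if reason in counts:
            rows.append({"step": f"excluded: {reason}", "n": int(counts[reason])})
    rows.append({"step": "included", "n": int(assembly["included"].sum())})
    return pd.DataFrame(rows)


def make_hourly_labels(stays: pd.DataFrame, assembly: pd.DataFrame,
                       horizon: int) -> pd.DataFrame:
    """Hourly 0/1 labels for the real-time prediction task.

    Septic stays contribute hours strictly before the (grid-floored) onset,
    labeled 1 when the onset falls within the next ``horizon`` hours
    (half-open lookahead ``(h, h + T]``); controls contribute every in-stay
    hour labeled 0. Positive labels per septic stay therefore number exactly
    ``min(T, floor(t_sepsis))``.
    """
    if horizon < 1:
        raise ConfigError(f"horizon must be >= 1, got {horizon}")
    sub = stays.merge(assembly[["stay_id", "included", "t_sepsis"]], on="stay_id")
    sub = sub[sub["included"]]
    frames = []
    for sid, los, t_sepsis in zip(sub["stay_id"].to_numpy(),
                                  sub["los_hours"].to_numpy(dtype=float),
                                  sub["t_sepsis"].to_numpy(dtype=float)):
        n_hours = n_grid_hours(los)
        if np.isfinite(t_sepsis):
            onset_grid = int(np.floor(t_sepsis))
            if onset_grid <= 0:
                raise ContractViolation(
                    f"stay {sid}: onset at grid hour {onset_grid} should have been excluded")
            hours = np.arange(min(onset_grid, n_hours), dtype=np.int64)
            label = ((onset_grid - hours) <= horizon).astype(np.int8)
        else:
            hours = np.arange(n_hours, dtype=np.int64)
            label = np.zeros(n_hours, dtype=np.int8)
        frames.append(pd.DataFrame({"stay_id": sid, "hour": hours, "label": label}))
    if not frames:
        return pd.DataFrame(columns=["stay_id", "hour", "label"])
    out = pd.concat(frames, ignore_index=True)
    out.attrs["horizon"] = horizon
    return out
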