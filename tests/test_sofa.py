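"""Hourly grid, SOFA subscores, and deterioration detection."""

import numpy as np
import pandas as pd
import pytest

from sepsikit import SofaWindow, ValidationError, build_hourly_grid, compute_sofa, detect_tsofa
from sepsikit.errors import ContractViolation

ONE_STAY = pd.DataFrame({"stay_id": [1], "los_hours": [24.0]})


def _obs(rows):
    return pd.DataFrame(rows, columns=["stay_id", "variable", "time", "value"])


# ---------------------------------------------------------------- grid ----

def test_forward_fill_between_observations():
    obs = _obs([(1, "platelets", 2.0, 100.0), (1, "platelets", 10.0, 40.0)])
    grid = build_hourly_grid(obs, ONE_STAY)
    vals = grid.set_index("hour")["platelets"]
    assert vals.loc[:1].isna().all()
    assert (vals.loc[2:9] == 100.0).all()
    assert (vals.loc[10:] == 40.0).all()


def test_never_observed_variable_absent_everywhere():
    grid = build_hourly_grid(_obs([(1, "platelets", 1.0, 90.0)]), ONE_STAY,
                             variables=["platelets", "bilirubin"])
    assert grid["bilirubin"].isna().all()


def test_empty_observation_table_gives_all_absent_grid():
    grid = build_hourly_grid(_obs([]), ONE_STAY, variables=["map"])
    assert len(grid) == 24
    assert grid["map"].isna().all()


def test_ties_in_same_hour_take_latest_observation():
    obs = _obs([(1, "map", 3.2, 80.0), (1, "map", 3.9, 60.0)])
    grid = build_hourly_grid(obs, ONE_STAY)
    assert grid.set_index("hour")["map"].loc[3] == 60.0


def test_negative_times_rejected():
    with pytest.raises(ContractViolation):
        build_hourly_grid(_obs([(1, "map", -1.0, 80.0)]), ONE_STAY)


def test_grid_matches_bruteforce_last_value_scan(rng):
    stays = pd.DataFrame({"stay_id": [1, 2], "los_hours": [30.0, 17.5]})
    rows = []
    for sid, los in zip(stays["stay_id"], stays["los_hours"]):
        for var in ("map", "platelets"):
            for t in np.sort(rng.uniform(0, los, rng.integers(0, 25))):
                rows.append((sid, var, float(t), float(rng.normal(100, 10))))
    obs = _obs(rows)
    grid = build_hourly_grid(obs, stays, variables=["map", "platelets"])
    for _, row in grid.iterrows():
        for var in ("map", "platelets"):
            prior = obs[(obs["stay_id"] == row["stay_id"]) & (obs["variable"] == var)
                        & (obs["time"] < row["hour"] + 1)]
            expected = prior.sort_values("time")["value"].iloc[-1] if len(prior) else np.nan
            actual = row[var]
            assert (np.isnan(expected) and np.isnan(actual)) or expected == actual


def test_grid_causality_under_truncation(small_cohort):
    stays = small_cohort.stays.head(5)
    obs = small_cohort.observations[small_cohort.observations["stay_id"].isin(stays["stay_id"])]
    full = build_hourly_grid(obs, stays, variables=["heart_rate", "platelets"])
    h = 12
    truncated = build_hourly_grid(obs[obs["time"] < h + 1], stays,
                                  variables=["heart_rate", "platelets"])
    pd.testing.assert_frame_equal(full[full["hour"] <= h].reset_index(drop=True),
                                  truncated[truncated["hour"] <= h].reset_index(drop=True))


# ---------------------------------------------------------------- sofa ----

def _grid_with(**cols):
    n = 4
    base = {"stay_id": [1] * n, "hour": list(range(n))}
    base.update({k: [v] * n for k, v in cols.items()})
    return pd.DataFrame(base)


def test_all_normal_scores_zero():
    grid = _grid_with(pf_ratio=450.0, vent_flag=0.0, platelets=250.0, bilirubin=0.7,
                      map=85.0, gcs=15.0, creatinine=0.9)
    trace = compute_sofa(grid)
    assert (trace["total"] == 0).all()


def test_platelets_90_scores_coagulation_two():
    trace = compute_sofa(_grid_with(platelets=90.0, map=85.0, gcs=15.0))
    assert (trace["coagulation"] == 2).all()
    assert (trace["total"] == 2).all()


def test_respiration_three_requires_ventilation():
    vent = compute_sofa(_grid_with(pf_ratio=150.0, vent_flag=1.0))
    no_vent = compute_sofa(_grid_with(pf_ratio=150.0, vent_flag=0.0))
    assert (vent["respiration"] == 3).all()
    assert (no_vent["respiration"] == 2).all()


def test_absent_variables_contribute_zero():
    trace = compute_sofa(_grid_with(platelets=np.nan))
    assert (trace["total"] == 0).all()


def test_negative_platelets_raise_listing_rows():
    with pytest.raises(ValidationError, match="platelets"):
        compute_sofa(_grid_with(platelets=-5.0))


def _oracle_sofa(pf, vent, plt, bili, mapv, norepi, gcs, creat):
    """Independent transcription of the published SOFA threshold table."""
    resp = 0
    if not np.isnan(pf):
        if pf < 100 and vent:
            resp = 4
        elif pf < 200 and vent:
            resp = 3
        elif pf < 300:
            resp = 2
        elif pf < 400:
            resp = 1
    coag = 0
    if not np.isnan(plt):
        coag = 4 if plt < 20 else 3 if plt < 50 else 2 if plt < 100 else 1 if plt < 150 else 0
    liver = 0
    if not np.isnan(bili):
        liver = 4 if bili >= 12 else 3 if bili >= 6 else 2 if bili >= 2 else 1 if bili >= 1.2 else 0
    cardio = 0
    if norepi > 0.1:
        cardio = 4
    elif norepi > 0:
        cardio = 3
    elif not np.isnan(mapv) and mapv < 70:
        cardio = 1
    cns = 0
    if not np.isnan(gcs):
        cns = 4 if gcs < 6 else 3 if gcs <= 9 else 2 if gcs <= 12 else 1 if gcs <= 14 else 0
    renal = 0
    if not np.isnan(creat):
        renal = (4 if creat >= 5 else 3 if creat >= 3.5 else 2 if creat >= 2
                 else 1 if creat >= 1.2 else 0)
    return resp, coag, liver, cardio, cns, renal


def test_subscores_match_transcribed_threshold_table(rng):
    n = 500
    grid = pd.DataFrame({
        "stay_id": np.arange(n), "hour": np.zeros(n, dtype=int),
        "pf_ratio": rng.uniform(40, 550, n),
        "vent_flag": rng.integers(0, 2, n).astype(float),
        "platelets": rng.uniform(1, 400, n),
        "bilirubin": rng.uniform(0.1, 15, n),
        "map": rng.uniform(40, 110, n),
        "norepinephrine_dose": np.where(rng.uniform(size=n) < 0.3,
                                        rng.uniform(0.01, 0.3, n), 0.0),
        "gcs": rng.integers(3, 16, n).astype(float),
        "creatinine": rng.uniform(0.3, 6.0, n),
    })
    # sprinkle missing values
    for col in ("pf_ratio", "platelets", "bilirubin", "map", "gcs", "creatinine"):
        grid.loc[rng.uniform(size=n) < 0.1, col] = np.nan
    trace = compute_sofa(grid)
    for i in range(n):
        row = grid.iloc[i]
        expected = _oracle_sofa(row["pf_ratio"], row["vent_flag"] >= 0.5,
                                row["platelets"], row["bilirubin"], row["map"],
                                row["norepinephrine_dose"], row["gcs"], row["creatinine"])
        got = tuple(trace.iloc[i][["respiration", "coagulation", "liver",
                                   "cardiovascular", "cns", "renal"]])
        assert got == expected, f"row {i}: {got} != {expected}"


def test_urine_band_needs_full_day_of_data():
    n = 40
    grid = pd.DataFrame({"stay_id": [1] * n, "hour": range(n),
                         "urine_output": [10.0] * n})  # 240 mL/day: band 3
    trace = compute_sofa(grid)
    assert (trace.loc[trace["hour"] < 23, "renal"] == 0).all()
    assert (trace.loc[trace["hour"] >= 23, "renal"] == 3).all()


def test_compute_sofa_is_pointwise_in_patient_order(small_cohort):
    obs, stays = small_cohort.observations, small_cohort.stays.head(6)
    obs = obs[obs["stay_id"].isin(stays["stay_id"])]
    from sepsikit.sofa import SOFA_VARIABLES

    grid = build_hourly_grid(obs, stays, variables=SOFA_VARIABLES)
    trace = compute_sofa(grid)
    perm = stays.iloc[::-1].reset_index(drop=True)
    trace_perm = compute_sofa(build_hourly_grid(obs, perm, variables=SOFA_VARIABLES))
    merged = trace.merge(trace_perm, on=["stay_id", "hour"], suffixes=("", "_p"))
    assert (merged["total"] == merged["total_p"]).all()


# ---------------------------------------------------------- detect_tsofa ----

def test_constant_totals_no_detection():
    assert detect_tsofa(np.full(20, 3), 10.0, SofaWindow(5, 5)) is None


def test_first_hour_reaching_initial_plus_two():
    totals = np.array([2, 2, 3, 4])
    assert detect_tsofa(totals, 1.0, SofaWindow(24, 12)) == 3


def test_empty_restricted_window_absent():
    assert detect_tsofa(np.array([0, 0, 1]), 50.0, SofaWindow(2, 2)) is None


def _brute_tsofa(totals, t_susp, window):
    hours = [h for h in range(len(totals))
             if h >= t_susp - window.x and h <= t_susp + window.y]
    if not hours:
        return None
    initial = totals[hours[0]]
    for h in hours:
        if totals[h] >= initial + 2:
            return h
    return None


def test_detection_matches_bruteforce_scan(rng):
    for _ in range(1000):
        totals = rng.integers(0, 10, rng.integers(1, 60))
        t_susp = float(rng.uniform(-5, len(totals) + 5))
        window = SofaWindow(float(rng.uniform(0, 30)), float(rng.uniform(0, 15)))
        assert detect_tsofa(totals, t_susp, window) == _brute_tsofa(totals, t_susp, window)


def test_enlarging_y_never_removes_or_delays_detection(rng):
    for _ in range(300):
        totals = rng.integers(0, 8, 48)
        t_susp = float(rng.uniform(0, 47))
        x = float(rng.uniform(0, 24))
        y = float(rng.uniform(0, 12))
        small = detect_tsofa(totals, t_susp, SofaWindow(x, y))
        big = detect_tsofa(totals, t_susp, SofaWindow(x, y + rng.uniform(0, 24)))
        if small is not None:
            assert big is not None and big <= small
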