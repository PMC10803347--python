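"""Onset definitions, exclusions, splitting, and hourly labels."""

import numpy as np
import pandas as pd
import pytest

from sepsikit import ConfigError, ExclusionConfig, assign_onset, apply_exclusions, \
    make_hourly_labels, split_train_test
from sepsikit.onset import exclusion_flow
from conftest import make_stays


def _onsets_frame(stays, t_susp=None, t_sofa=None):
    n = len(stays)
    t_susp = [np.nan] * n if t_susp is None else t_susp
    t_sofa = [np.nan] * n if t_sofa is None else t_sofa
    ts, tf = np.asarray(t_susp, float), np.asarray(t_sofa, float)
    both = np.isfinite(ts) & np.isfinite(tf)
    return pd.DataFrame({
        "stay_id": stays["stay_id"],
        "t_suspicion": ts, "t_sofa": tf,
        "t_sepsis_h1": np.where(both, tf, np.nan),
        "t_sepsis_h2": np.where(both, ts, np.nan),
        "t_sepsis_h3": np.where(both, np.minimum(ts, tf), np.nan),
    })


# ------------------------------------------------------------- onsets ----

def test_direct_definition_rules():
    assert assign_onset(20.0, 15.0, "H1") == 15.0
    assert assign_onset(20.0, 15.0, "H2") == 20.0
    assert assign_onset(20.0, 15.0, "H3") == 15.0


def test_both_events_required():
    for d in ("H1", "H2", "H3"):
        assert np.isnan(assign_onset(20.0, np.nan, d))
        assert np.isnan(assign_onset(np.nan, 15.0, d))


def test_unknown_definition_rejected():
    with pytest.raises(ConfigError):
        assign_onset(1.0, 2.0, "H4")


def test_h3_is_elementwise_minimum_of_h1_h2(rng):
    for _ in range(500):
        ts = float(rng.uniform(0, 100)) if rng.uniform() < 0.8 else np.nan
        tf = float(rng.uniform(0, 100)) if rng.uniform() < 0.8 else np.nan
        h1, h2, h3 = (assign_onset(ts, tf, d) for d in ("H1", "H2", "H3"))
        if np.isnan(h1) or np.isnan(h2):
            assert np.isnan(h3)
        else:
            assert h3 == min(h1, h2)


# --------------------------------------------------------- exclusions ----

def test_toy_cohort_exclusion_chain():
    # 8 stays: pre-ICU abx, LOS 2 h, LOS 30 d, cardiothoracic unit,
    # all-vitals-missing, three clean -> 3 included
    stays = make_stays([50.0, 2.0, 720.0, 50.0, 50.0, 50.0, 50.0, 50.0])
    stays.loc[0, "pre_icu_antibiotics"] = True
    stays.loc[3, "care_unit"] = "CSRU"
    obs_rows = [(sid, "heart_rate", 1.0, 80.0) for sid in stays["stay_id"] if sid != 5]
    observations = pd.DataFrame(obs_rows, columns=["stay_id", "variable", "time", "value"])
    onsets = _onsets_frame(stays)
    asm = apply_exclusions(stays, onsets, ExclusionConfig(), "H1",
                           observations=observations)
    assert asm["included"].sum() == 3
    reasons = asm.set_index("stay_id")["exclusion_reason"]
    assert reasons.loc[1] == "pre_icu_antibiotics"
    assert reasons.loc[2] == "los_out_of_bounds"
    assert reasons.loc[3] == "los_out_of_bounds"
    assert reasons.loc[4] == "excluded_care_unit"
    assert reasons.loc[5] == "no_vital_signs"


def test_onset_within_grace_excluded():
    stays = make_stays([50.0, 50.0])
    onsets = _onsets_frame(stays, t_susp=[3.0, 10.0], t_sofa=[3.0, 10.0])
    asm = apply_exclusions(stays, onsets, ExclusionConfig(), "H1")
    assert asm.set_index("stay_id")["exclusion_reason"].loc[1] == "early_onset"
    assert asm.set_index("stay_id")["included"].loc[2]


def test_strict_h3_grace_applies_h3_onset_to_h2_cohort():
    stays = make_stays([50.0])
    # H2 onset 10 h but H3 onset 3 h (t_sofa = 3)
    onsets = _onsets_frame(stays, t_susp=[10.0], t_sofa=[3.0])
    lax = apply_exclusions(stays, onsets, ExclusionConfig(), "H2")
    strict = apply_exclusions(stays, onsets,
                              ExclusionConfig(strict_h3_grace=True), "H2")
    assert lax["included"].iloc[0]
    assert not strict["included"].iloc[0]
    assert strict["exclusion_reason"].iloc[0] == "early_onset"


def test_exclusion_reasons_partition_excluded_set(small_cohort):
    from sepsikit.onset import compute_onsets
    from sepsikit.sofa import SOFA_VARIABLES, SofaWindow, build_hourly_grid, compute_sofa
    from sepsikit.suspicion import compute_suspicion

    t = small_cohort
    grid = build_hourly_grid(t.observations, t.stays, variables=SOFA_VARIABLES)
    onsets = compute_onsets(compute_suspicion(t.doses, t.cultures, t.stays),
                            compute_sofa(grid), SofaWindow(24, 12))
    asm = apply_exclusions(t.stays, onsets, ExclusionConfig(), "H3",
                           observations=t.observations)
    excluded = asm[~asm["included"]]
    assert excluded["exclusion_reason"].notna().all()
    assert asm[asm["included"]]["exclusion_reason"].isna().all()
    flow = exclusion_flow(asm)
    n_excluded = flow[flow["step"].str.startswith("excluded")]["n"].sum()
    assert n_excluded + asm["included"].sum() == len(asm)


def test_h3_grace_exclusion_is_superset_of_h1_h2(small_cohort):
    from sepsikit.onset import compute_onsets
    from sepsikit.sofa import SOFA_VARIABLES, SofaWindow, build_hourly_grid, compute_sofa
    from sepsikit.suspicion import compute_suspicion

    t = small_cohort
    grid = build_hourly_grid(t.observations, t.stays, variables=SOFA_VARIABLES)
    onsets = compute_onsets(compute_suspicion(t.doses, t.cultures, t.stays),
                            compute_sofa(grid), SofaWindow(24, 12))
    grace = ExclusionConfig()
    def early(definition):
        asm = apply_exclusions(t.stays, onsets, grace, definition,
                               observations=t.observations)
        return set(asm.loc[asm["exclusion_reason"] == "early_onset", "stay_id"])
    assert early("H1") <= early("H3")
    assert early("H2") <= early("H3")


# -------------------------------------------------------------- split ----

def test_split_arithmetic_on_balanced_cohort(rng):
    n = 1000
    stays = make_stays([48.0 + i % 96 for i in range(n)],
                       sex=[("F" if i % 2 else "M") for i in range(n)],
                       age=[30.0 + (i % 50) for i in range(n)],
                       ever_ventilated=[bool(i % 4 == 0) for i in range(n)])
    split = split_train_test(stays, 0.85, seed=3)
    assert abs((split == "train").sum() - 850) <= 16  # +-1 per stratum
    assert (split == "test").sum() + (split == "train").sum() == n


def test_split_deterministic():
    stays = make_stays([40.0 + i for i in range(60)],
                       age=[40.0 + i % 30 for i in range(60)])
    a = split_train_test(stays, 0.85, seed=5)
    b = split_train_test(stays, 0.85, seed=5)
    assert (a == b).all()


def test_per_stratum_train_fraction_within_one_patient(rng):
    n = 400
    stays = make_stays(list(rng.uniform(10, 400, n)),
                       sex=list(rng.choice(["F", "M"], n)),
                       age=list(rng.uniform(20, 90, n)),
                       ever_ventilated=list(rng.uniform(size=n) < 0.3))
    split = split_train_test(stays, 0.85, seed=9)
    age_q = pd.qcut(stays["age"], 4, labels=False, duplicates="drop")
    los_q = pd.qcut(stays["los_hours"], 4, labels=False, duplicates="drop")
    strata = (stays["sex"].astype(str) + "|" + age_q.astype(str) + "|"
              + los_q.astype(str) + "|" + stays["ever_ventilated"].astype(str))
    for _, idx in strata.groupby(strata).groups.items():
        n_s = len(idx)
        n_train = (split.loc[idx] == "train").sum()
        if n_s == 1:
            assert n_train == 1
        else:
            assert abs(n_train - 0.85 * n_s) <= 1


# ------------------------------------------------------------- labels ----

def test_fig3_style_labels_onset_21_horizon_6():
    stays = make_stays([40.0])
    asm = pd.DataFrame({"stay_id": [1], "included": [True], "t_sepsis": [21.0]})
    labels = make_hourly_labels(stays, asm, horizon=6)
    lab = labels.set_index("hour")["label"]
    assert labels["hour"].max() == 20  # no row at or after onset
    assert (lab.loc[15:20] == 1).all()
    assert (lab.loc[:14] == 0).all()


def test_control_stay_contributes_all_hours_zero():
    stays = make_stays([30.0])
    asm = pd.DataFrame({"stay_id": [1], "included": [True], "t_sepsis": [np.nan]})
    labels = make_hourly_labels(stays, asm, horizon=6)
    assert len(labels) == 30
    assert (labels["label"] == 0).all()


def test_positive_count_closed_form(rng):
    for _ in range(200):
        los = float(rng.uniform(6, 120))
        t_sepsis = float(rng.uniform(4.5, los - 0.01))
        horizon = int(rng.integers(1, 13))
        stays = make_stays([los])
        asm = pd.DataFrame({"stay_id": [1], "included": [True], "t_sepsis": [t_sepsis]})
        labels = make_hourly_labels(stays, asm, horizon)
        onset_grid = int(np.floor(t_sepsis))
        assert labels["label"].sum() == min(horizon, onset_grid)
        assert labels["hour"].max() == onset_grid - 1


def test_horizon_must_be_positive():
    with pytest.raises(ConfigError):
        make_hourly_labels(make_stays([10.0]),
                           pd.DataFrame({"stay_id": [1], "included": [True],
                                         "t_sepsis": [np.nan]}), horizon=0)
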