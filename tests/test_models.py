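"""Risk scorers: contracts, calibration, binarization, CV tuning."""

import numpy as np
import pandas as pd
import pytest

from sepsikit import (
    CoxHorizonScorer,
    GBMScorer,
    LSTMScorer,
    binarize,
    calibrate_threshold,
    tune_cv,
)
from sepsikit.errors import ContractViolation
from sepsikit.models import ModelSpec, make_model


def _panel(n_stays=20, hours=15, d=6, seed=0, signal=True):
    """Small patient-hour panel with an optional monotone pre-onset signal."""
    rng = np.random.default_rng(seed)
    idx, rows, y = [], [], []
    for sid in range(1, n_stays + 1):
        septic = sid % 2 == 0
        onset = hours if not septic else int(rng.integers(8, hours))
        for h in range(onset):
            x = rng.standard_normal(d)
            label = int(septic and onset - h <= 4)
            if signal and label:
                x[0] += 2.5
            idx.append((sid, h))
            rows.append(x)
            y.append(label)
    X = pd.DataFrame(rows, columns=[f"f{i}" for i in range(d)],
                     index=pd.MultiIndex.from_tuples(idx, names=["stay_id", "hour"]))
    return X, np.array(y), np.array([i[0] for i in idx])


# ----------------------------------------------------------- scorers ----

def test_gbm_degenerate_labels_score_constant():
    X, y, g = _panel()
    m = GBMScorer().fit(X, np.zeros_like(y), g)
    scores = m.score(X)
    assert len(np.unique(scores)) == 1
    from sepsikit import auroc
    assert auroc(scores, np.zeros_like(y)) is None


def test_gbm_deterministic_given_seed():
    X, y, g = _panel()
    a = GBMScorer(seed=3).fit(X, y, g).score(X)
    b = GBMScorer(seed=3).fit(X, y, g).score(X)
    np.testing.assert_array_equal(a, b)


def test_lstm_deterministic_given_seed():
    X, y, g = _panel()
    a = LSTMScorer(hidden=8, epochs=2, seed=3).fit(X, y, g).score(X)
    b = LSTMScorer(hidden=8, epochs=2, seed=3).fit(X, y, g).score(X)
    np.testing.assert_array_equal(a, b)


def test_lstm_learns_separable_signal():
    from sepsikit import auroc

    X, y, g = _panel(n_stays=40, seed=1)
    m = LSTMScorer(hidden=8, epochs=60, batch_size=8, seed=0).fit(X, y, g)
    assert auroc(m.score(X), y) > 0.85


def test_lstm_score_before_fit_rejected():
    X, y, g = _panel()
    with pytest.raises(ContractViolation):
        LSTMScorer().score(X)


def test_lstm_gradients_match_finite_differences():
    from sepsikit.lstm import LSTMParams, _forward, _backward

    rng = np.random.default_rng(0)
    B, T, D, H = 3, 5, 4, 6
    params = LSTMParams(D, H, rng)
    X = rng.standard_normal((B, T, D))
    y = rng.integers(0, 2, (B, T)).astype(float)
    mask = np.ones((B, T))
    mask[1, 3:] = 0
    logits, caches = _forward(params, X)
    _loss, grads = _backward(params, X, logits, caches, y, mask)

    def loss_at():
        l, c = _forward(params, X)
        return _backward(params, X, l, c, y, mask)[0]

    eps = 1e-6
    flat = params.as_list()
    for p, grad in zip(flat, grads):
        for k in range(0, p.size, max(1, p.size // 3)):
            idx = np.unravel_index(k, p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            params.b_out = float(flat[4][0])
            up = loss_at()
            p[idx] = orig - eps
            params.b_out = float(flat[4][0])
            down = loss_at()
            p[idx] = orig
            params.b_out = float(flat[4][0])
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(grad[idx], rel=1e-4, abs=1e-8)


def test_cox_risk_is_increasing_in_linear_predictor():
    # r(t) = 1 - exp(-dH0 * exp(lp)) is monotone in lp for fixed dH0 > 0
    lp = np.linspace(-3, 3, 50)
    risk = 1.0 - np.exp(-0.2 * np.exp(lp))
    assert (np.diff(risk) > 0).all()


def test_cox_null_coefficients_score_by_hour_only():
    X, y, g = _panel(n_stays=30, seed=2)
    m = CoxHorizonScorer(horizon=4).fit(X, y, g)
    m._fitter.params_[:] = 0.0
    scores = pd.Series(m.score(X), index=X.index)
    by_hour = scores.groupby(level="hour").nunique()
    assert (by_hour == 1).all()


def test_cox_fit_and_scores_in_unit_interval():
    X, y, g = _panel(n_stays=30, seed=2)
    m = CoxHorizonScorer(horizon=4).fit(X, y, g)
    s = m.score(X)
    assert ((s >= 0) & (s <= 1)).all()


# ------------------------------------------------------- calibration ----

def test_perfect_scorer_threshold_is_one():
    labels = np.array([0, 1, 0, 1, 1])
    cal = calibrate_threshold(labels.astype(float), labels)
    assert cal.threshold == 1.0
    assert cal.achieved_sensitivity == 1.0


def test_threshold_is_order_statistic_of_positive_scores(rng):
    scores = rng.uniform(size=200)
    labels = np.zeros(200, dtype=int)
    pos_rows = rng.choice(200, size=20, replace=False)
    labels[pos_rows] = 1
    cal = calibrate_threshold(scores, labels, target=0.85)
    pos_sorted = np.sort(scores[labels == 1])[::-1]
    assert cal.threshold == pos_sorted[16]  # ceil(0.85 * 20) = 17 captured
    assert cal.achieved_sensitivity >= 0.85


def test_lowering_target_never_raises_threshold(rng):
    for _ in range(100):
        n = int(rng.integers(10, 80))
        scores = rng.uniform(size=n)
        labels = (rng.uniform(size=n) < 0.4).astype(int)
        if labels.sum() == 0:
            labels[0] = 1
        t_high = calibrate_threshold(scores, labels, target=0.9).threshold
        t_low = calibrate_threshold(scores, labels, target=0.6).threshold
        assert t_low >= t_high


def test_calibration_requires_positives():
    with pytest.raises(ContractViolation):
        calibrate_threshold(np.array([0.5]), np.array([0]))


# --------------------------------------------------------- binarize ----

def test_first_alert_one_hour_before_onset():
    # risk trace crosses the threshold first at hour 20; with onset at 21 h
    # and a 6 h horizon the alert precedes onset within the horizon
    hours = np.arange(25)
    scores = np.where(hours >= 20, 0.9, 0.2)
    flags, first_alert = binarize(scores, 0.5, hours)
    assert first_alert == 20
    onset, horizon = 21, 6
    assert 0 < onset - first_alert <= horizon


def test_no_alert_when_all_below_threshold():
    flags, first = binarize(np.full(10, 0.2), 0.5)
    assert not flags.any() and first is None


def test_first_alert_matches_full_scan(rng):
    for _ in range(200):
        scores = rng.uniform(size=30)
        thr = float(rng.uniform())
        flags, first = binarize(scores, thr)
        flagged = [h for h in range(30) if scores[h] >= thr]
        assert first == (min(flagged) if flagged else None)


# ----------------------------------------------------------- tuning ----

def test_single_configuration_grid_selected_with_k_fold_table():
    X, y, g = _panel(n_stays=25)
    spec = ModelSpec(kind="gbm", grid={"num_leaves": [7]}, seed=0)
    best, cv, scorer = tune_cv(lambda p: make_model(spec, p), spec, X, y, g, k=5)
    assert best == {"num_leaves": 7}
    assert len(cv) == 5


def test_folds_partition_patients():
    from sklearn.model_selection import GroupKFold

    X, y, g = _panel(n_stays=25)
    seen: dict[int, int] = {}
    for fold, (_tr, va) in enumerate(GroupKFold(n_splits=5).split(X, y, g)):
        for sid in np.unique(g[va]):
            assert sid not in seen
            seen[sid] = fold
    assert len(seen) == 25


def test_too_few_patients_rejected():
    X, y, g = _panel(n_stays=3)
    spec = ModelSpec(kind="gbm", grid={}, seed=0)
    with pytest.raises(ContractViolation):
        tune_cv(lambda p: make_model(spec, p), spec, X, y, g, k=5)


def test_cv_prefers_adequate_depth_on_interaction_signal():
    """Stumps cannot represent an XOR interaction; CV should pick depth."""
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n_stays, hours = 40, 10
        idx, rows, y = [], [], []
        for sid in range(n_stays):
            a, b = rng.integers(0, 2, 2)
            for h in range(hours):
                x = rng.standard_normal(4) * 0.3
                x[0] += a
                x[1] += b
                idx.append((sid, h))
                rows.append(x)
                y.append(int(a ^ b))
        X = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(idx, names=["stay_id", "hour"]))
        X.columns = [f"f{i}" for i in range(4)]
        y = np.array(y)
        g = np.array([i[0] for i in idx])
        spec = ModelSpec(kind="gbm", grid={"num_leaves": [2, 8]}, seed=seed)
        best, _cv, _m = tune_cv(
            lambda p: GBMScorer(n_estimators=50, min_child_samples=5, seed=0, **p),
            spec, X, y, g, k=5)
        wins += best["num_leaves"] == 8
    assert wins >= 9
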