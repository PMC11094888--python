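import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynrad.evaluation import (auc_delong, calibration_brier, decision_curve,
                               delong_test, likelihood_ratio_test,
                               shap_linear, subgroup_association,
                               youden_metrics, youden_threshold)


def _brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


# ------------------------------------------------------------------ AUC

def test_auc_perfect():
    auc, _, ci = auc_delong([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert auc == 1.0
    assert ci[0] <= auc <= ci[1]


def test_auc_all_ties():
    auc, _, _ = auc_delong([0.5] * 6, [1, 0, 1, 0, 1, 0])
    assert auc == 0.5


def test_auc_equals_bruteforce_pairwise():
    rng = np.random.default_rng(0)
    for n in (10, 57, 500):
        s = np.round(rng.random(n), 2)  # rounding forces ties
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        auc, var, ci = auc_delong(s, y)
        assert auc == pytest.approx(_brute_force_auc(s, y), abs=1e-12)
        assert ci[0] <= auc <= ci[1]
        assert var >= 0


def test_auc_variance_matches_bootstrap():
    rng = np.random.default_rng(1)
    n = 30
    s = rng.random(n)
    y = np.array([1] * 12 + [0] * 18)
    _, var, _ = auc_delong(s, y)
    reps = []
    for _ in range(10_000):
        idx1 = rng.integers(0, 12, 12)
        idx0 = 12 + rng.integers(0, 18, 18)
        idx = np.concatenate([idx1, idx0])  # stratified bootstrap
        reps.append(_brute_force_auc(s[idx], y[idx]))
    boot = np.var(reps)
    assert var == pytest.approx(boot, rel=0.2)


def test_auc_single_class_raises():
    with pytest.raises(ValueError):
        auc_delong([0.1, 0.2], [1, 1])


# ------------------------------------------------------------------ DeLong test

def test_delong_identical_models_p_one():
    rng = np.random.default_rng(0)
    s = rng.random(40)
    y = rng.integers(0, 2, 40)
    assert delong_test(s, s.copy(), y) == 1.0


def test_delong_perfect_vs_random():
    rng = np.random.default_rng(2)
    n = 200
    y = rng.integers(0, 2, n)
    perfect = y + rng.normal(0, 0.05, n)
    random_s = rng.random(n)
    assert delong_test(perfect, random_s, y) < 0.001


def test_delong_type_one_error():
    rng = np.random.default_rng(3)
    n, reps = 60, 2000
    rejections = 0
    for _ in range(reps):
        y = np.array([1] * 25 + [0] * 35)
        a = rng.random(n)
        b = rng.random(n)
        if delong_test(a, b, y) < 0.05:
            rejections += 1
    assert 0.03 <= rejections / reps <= 0.07


# ------------------------------------------------------------------ LRT

def _design(n, rng, k=1):
    return pd.DataFrame(rng.normal(size=(n, k)),
                        columns=[f"x{i}" for i in range(k)])


def test_lrt_identical_models_p_one():
    rng = np.random.default_rng(0)
    X = _design(100, rng)
    y = rng.integers(0, 2, 100)
    assert likelihood_ratio_test(X, X, y) == 1.0


def test_lrt_null_uniform():
    rng = np.random.default_rng(1)
    n, reps = 120, 2000
    pvals = []
    for _ in range(reps):
        X1 = _design(n, rng)
        X2 = X1.copy()
        X2["null_extra"] = rng.normal(size=n)
        y = rng.integers(0, 2, n)
        pvals.append(likelihood_ratio_test(X1, X2, y))
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_lrt_strong_covariate():
    rng = np.random.default_rng(2)
    n = 200
    y = rng.integers(0, 2, n)
    X1 = _design(n, rng)
    X2 = X1.copy()
    X2["outcome_like"] = y + rng.normal(0, 0.1, n)
    assert likelihood_ratio_test(X1, X2, y) < 1e-6


def test_lrt_non_nested_raises():
    rng = np.random.default_rng(3)
    A = pd.DataFrame({"a": rng.normal(size=10)})
    B = pd.DataFrame({"b": rng.normal(size=10)})
    with pytest.raises(ValueError):
        likelihood_ratio_test(A, B, rng.integers(0, 2, 10))


# ------------------------------------------------------------------ Youden

def test_youden_perfect_separation():
    tr_s = [0.1, 0.2, 0.8, 0.9]
    tr_y = [0, 0, 1, 1]
    m = youden_metrics(tr_s, tr_y, tr_s, tr_y)
    assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0


def test_youden_threshold_near_analytic_optimum():
    rng = np.random.default_rng(4)
    n = 5000
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(2 * x)))  # true model; Youden optimum at p = 0.5
    y = (rng.random(n) < p).astype(int)
    t = youden_threshold(p, y)
    assert abs(t - 0.5) < 0.1


def test_youden_degenerate_all_above():
    m = youden_metrics([0.2, 0.8], [0, 1], [0.9, 0.95, 0.99], [0, 1, 1])
    assert m["specificity"] == 0.0
    assert m["accuracy"] == pytest.approx(2 / 3)  # prevalence


# ------------------------------------------------------------------ calibration

def test_brier_perfect_and_constant():
    _, b0 = calibration_brier([1.0, 0.0, 1.0], [1, 0, 1])
    assert b0 == 0.0
    _, b1 = calibration_brier([0.5] * 10, [1, 0] * 5)
    assert b1 == pytest.approx(0.25)


def test_calibration_slope_well_calibrated():
    rng = np.random.default_rng(5)
    n = 5000
    p = rng.uniform(0.05, 0.95, n)
    y = (rng.random(n) < p).astype(int)
    table, _ = calibration_brier(p, y)
    slope = np.polyfit(table["mean_predicted"], table["observed_rate"], 1)[0]
    assert 0.9 <= slope <= 1.1


def test_calibration_rejects_non_probabilities():
    with pytest.raises(ValueError):
        calibration_brier([1.5, 0.2], [1, 0])


# ------------------------------------------------------------------ decision curves

def test_decision_curve_treat_none_zero():
    dc = decision_curve([0.4, 0.6], [0, 1])
    assert (dc["treat_none"] == 0).all()


def test_decision_curve_treat_all_closed_form():
    rng = np.random.default_rng(6)
    y = (rng.random(500) < 0.3).astype(int)
    dc = decision_curve(rng.random(500), y)
    prev = y.mean()
    expect = prev - (1 - prev) * dc["threshold"] / (1 - dc["threshold"])
    np.testing.assert_allclose(dc["treat_all"], expect, atol=1e-12)
    # spec spot value at prevalence .3, pt .2 (exact prevalence fixture)
    y30 = np.array([1] * 3 + [0] * 7)
    dc30 = decision_curve(np.linspace(0, 1, 10), y30, thresholds=[0.2])
    assert dc30["treat_all"].iloc[0] == pytest.approx(0.3 - 0.7 * 0.25)


def test_decision_curve_perfect_model():
    y = np.array([1] * 4 + [0] * 6)
    dc = decision_curve(y.astype(float), y)
    np.testing.assert_allclose(dc["net_benefit"], y.mean(), atol=1e-12)


def test_decision_curve_excludes_pt_one():
    dc = decision_curve([0.5], [1], thresholds=[0.2, 1.0])
    assert (dc["threshold"] < 1).all()


# ------------------------------------------------------------------ subgroups

def test_subgroup_or_crossproduct():
    # table [[20,10],[10,20]] -> OR 4
    y = np.array([1] * 30 + [0] * 30)
    pred = np.concatenate([np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)])
    out = subgroup_association(pred, y, ["g"] * 60, threshold=0.5)
    assert out.loc[0, "or"] == pytest.approx(4.0)


def test_subgroup_or_equal_odds():
    y = np.array([1] * 30 + [0] * 30)
    pred = np.concatenate([np.ones(15), np.zeros(15), np.ones(15), np.zeros(15)])
    out = subgroup_association(pred, y, ["g"] * 60, threshold=0.5)
    assert out.loc[0, "or"] == pytest.approx(1.0)


def test_subgroup_zero_cell_correction():
    y = np.array([1] * 10 + [0] * 10)
    pred = np.concatenate([np.ones(10), np.ones(5), np.zeros(5)])
    out = subgroup_association(pred, y, ["g"] * 20, threshold=0.5)
    assert np.isfinite(out.loc[0, "or"])
    assert bool(out.loc[0, "corrected"])


def test_subgroup_insufficient_flagged():
    y = np.array([1, 0, 0, 0])
    out = subgroup_association([0.9, 0.1, 0.2, 0.3], y, ["g"] * 4, 0.5)
    assert out.loc[0, "note"] == "insufficient"
    assert np.isnan(out.loc[0, "or"])


# ------------------------------------------------------------------ SHAP

def test_shap_zero_at_background_mean():
    rng = np.random.default_rng(7)
    bg = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
    x = pd.DataFrame([bg.mean()], columns=list("abc"))
    phi = shap_linear(np.array([1.0, -2.0, 0.5]), x, bg)
    np.testing.assert_allclose(phi.to_numpy(), 0.0, atol=1e-12)


def test_shap_additivity_identity():
    rng = np.random.default_rng(8)
    coef = np.array([0.7, -1.2, 2.0])
    bg = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
    X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
    phi = shap_linear(coef, X, bg)
    logit = X.to_numpy() @ coef
    base = bg.mean().to_numpy() @ coef
    np.testing.assert_allclose(phi.sum(axis=1) + base, logit, atol=1e-10)


def test_shap_symmetric_importance():
    rng = np.random.default_rng(9)
    n = 1000
    bg = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    phi = shap_linear(np.array([1.5, 1.5]), bg, bg)
    imp = phi.abs().mean()
    assert imp["a"] == pytest.approx(imp["b"], rel=0.02)
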