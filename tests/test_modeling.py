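import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynrad.modeling import (build_combined_models, fit_logistic_cv,
                             lasso_select, mrmr_rank, mwu_filter,
                             variance_filter)


# ------------------------------------------------------------------ variance

def test_variance_filter_drops_constant():
    t = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
    surv, reasons = variance_filter(t)
    assert surv == ["b"]
    assert reasons["a"] == "low_variance"


def test_variance_filter_drops_missing():
    t = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 3.0]})
    surv, reasons = variance_filter(t)
    assert surv == ["b"]
    assert reasons["a"] == "missing"


def test_variance_filter_keeps_duplicates():
    t = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    surv, _ = variance_filter(t)
    assert surv == ["a", "b"]


# ------------------------------------------------------------------ MWU

def test_mwu_exact_small_groups():
    """{1,2,3} vs {4,5,6}: exact two-sided p = 0.1 (enumeration oracle)."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([0, 0, 0, 1, 1, 1])
    # enumeration: U statistic for every assignment of 3 labels to 6 values
    u_obs = stats.mannwhitneyu(x[y == 1], x[y == 0],
                               alternative="two-sided").statistic
    extremes = 0
    total = 0
    for pos in itertools.combinations(range(6), 3):
        lab = np.zeros(6, dtype=int)
        lab[list(pos)] = 1
        u = stats.mannwhitneyu(x[lab == 1], x[lab == 0],
                               alternative="two-sided").statistic
        total += 1
        if abs(u - 4.5) >= abs(u_obs - 4.5):  # distance from the null mean
            extremes += 1
    assert extremes / total == pytest.approx(0.1)
    t = pd.DataFrame({"f": x})
    surv, pvals = mwu_filter(t, y)
    assert pvals["f"] == pytest.approx(0.1)
    assert surv == []  # 0.1 is NOT < 0.05


def test_mwu_null_pass_rate():
    rng = np.random.default_rng(0)
    n, m = 200, 100
    t = pd.DataFrame(rng.normal(size=(n, m)),
                     columns=[f"f{i}" for i in range(m)])
    y = rng.integers(0, 2, n)
    surv, _ = mwu_filter(t, y)
    expected = m * 0.05
    slack = 3 * np.sqrt(m * 0.05 * 0.95)
    assert abs(len(surv) - expected) <= slack


def test_mwu_perfect_feature_retained_at_n16():
    y = np.array([0] * 8 + [1] * 8)
    t = pd.DataFrame({"f": y.astype(float)})
    surv, pvals = mwu_filter(t, y)
    assert surv == ["f"] and pvals["f"] < 0.05


def test_mwu_single_class_raises():
    t = pd.DataFrame({"f": [1.0, 2.0]})
    with pytest.raises(ValueError):
        mwu_filter(t, [1, 1])


# ------------------------------------------------------------------ LASSO

def _signal_noise_table(n=200, noise=20, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    cols = {"signal": y + rng.normal(0, 0.3, n)}
    for i in range(noise):
        cols[f"noise{i}"] = rng.normal(size=n)
    return pd.DataFrame(cols), y


def test_lasso_recovers_predictive_feature():
    t, y = _signal_noise_table()
    surv, _, _ = lasso_select(t, y, seed=0)
    assert "signal" in surv


def test_lasso_sparsity_on_duplicates():
    hits = 0
    for seed in range(10):
        t, y = _signal_noise_table(seed=seed, noise=5)
        t["signal_dup"] = t["signal"]
        surv, _, _ = lasso_select(t, y, seed=seed)
        if not {"signal", "signal_dup"} <= set(surv):
            hits += 1
    assert hits >= 9  # L1 keeps at most one of an exact duplicate pair


def test_lasso_fallback_on_infinite_penalty():
    t, y = _signal_noise_table(n=80, noise=5)
    with pytest.warns(UserWarning, match="falling back"):
        surv, _, _ = lasso_select(t, y, Cs=[1e-8])
    assert len(surv) == 1


# ------------------------------------------------------------------ mRMR

def test_mrmr_duplicate_ranked_last():
    rng = np.random.default_rng(0)
    n = 400
    y = rng.integers(0, 2, n)
    a = y + rng.normal(0, 0.5, n)
    b = rng.normal(size=n) + 0.8 * y  # independent informative
    t = pd.DataFrame({"a1": a, "a2": a, "b": b})
    ranked = mrmr_rank(t, y)
    assert ranked[0] in ("a1", "a2")
    assert ranked[1] == "b"
    assert ranked[2] in ("a1", "a2")


def test_mrmr_single_feature():
    t = pd.DataFrame({"only": [1.0, 2.0, 3.0, 4.0]})
    assert mrmr_rank(t, [0, 0, 1, 1]) == ["only"]


def test_mrmr_k_zero():
    t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
    assert mrmr_rank(t, [0, 0, 1, 1], k=0) == []


def test_mrmr_deterministic_tie_break():
    t = pd.DataFrame({"z": [1.0, 2.0, 3.0, 4.0], "a": [1.0, 2.0, 3.0, 4.0]})
    ranked = mrmr_rank(t, [0, 0, 1, 1])
    assert ranked[0] == "z"  # column order, not alphabetical


# ------------------------------------------------------------------ logistic CV

def test_separable_feature_train_auc_one():
    y = np.array([0] * 20 + [1] * 20)
    t = pd.DataFrame({"f": np.concatenate([np.zeros(20), np.ones(20)])})
    bundle = fit_logistic_cv(t, y, ["f"], folds=5)
    from sklearn.metrics import roc_auc_score
    assert roc_auc_score(y, bundle.predict(t)) == 1.0


def test_null_features_oof_auc_near_half():
    rng = np.random.default_rng(1)
    n = 400
    y = rng.integers(0, 2, n)
    t = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
    bundle = fit_logistic_cv(t, y, list("abcde"), folds=10)
    from sklearn.metrics import roc_auc_score
    auc = roc_auc_score(y, bundle.train_oof_scores)
    assert 0.4 <= auc <= 0.6


def test_prefix_selection_prefers_single_strong_feature():
    rng = np.random.default_rng(0)
    n = 300
    y = rng.integers(0, 2, n)
    t = pd.DataFrame({
        "strong": y + rng.normal(0, 0.2, n),
        "noise1": rng.normal(size=n),
        "noise2": rng.normal(size=n),
    })
    bundle = fit_logistic_cv(t, y, ["strong", "noise1", "noise2"], folds=10)
    assert bundle.features == ["strong"]


# ------------------------------------------------------------------ combined

def _clinical_frame(n, rng):
    return pd.DataFrame({
        "hr_status": rng.integers(0, 2, n),
        "her2_status": rng.integers(0, 2, n),
    }, index=[f"P{i}" for i in range(n)])


def test_combined_collinearity_warning():
    rng = np.random.default_rng(0)
    n = 100
    clin = _clinical_frame(n, rng)
    y = rng.integers(0, 2, n)
    score = pd.Series(rng.random(n), index=clin.index)
    with pytest.warns(UserWarning, match="collinear"):
        build_combined_models(clin, score, score.copy(), y)


def test_combined_null_component_wald_p():
    rng = np.random.default_rng(3)
    n = 2000
    clin = _clinical_frame(n, rng)
    logit = -0.5 + 0.8 * clin["hr_status"].to_numpy()
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    rad = pd.Series(rng.random(n), index=clin.index)  # pure noise component
    dyn = pd.Series(rng.random(n), index=clin.index)
    models = build_combined_models(clin, rad, dyn, y)
    assert models["CRD"].component_pvalues["radiomic_score"] > 0.05


def test_crd_not_worse_than_components():
    rng = np.random.default_rng(4)
    n = 600
    clin = _clinical_frame(n, rng)
    latent = rng.normal(size=n)
    logit = 0.7 * clin["hr_status"].to_numpy() + latent
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    rad = pd.Series(1 / (1 + np.exp(-(latent + rng.normal(0, 1, n)))),
                    index=clin.index)
    dyn = pd.Series(1 / (1 + np.exp(-(latent + rng.normal(0, 1, n)))),
                    index=clin.index)
    models = build_combined_models(clin, rad, dyn, y)
    from sklearn.metrics import roc_auc_score
    aucs = {m: roc_auc_score(y, models[m].train_scores)
            for m in ("C", "R", "D", "CRD")}
    assert aucs["CRD"] >= max(aucs["C"], aucs["R"], aucs["D"]) - 0.02


def test_selection_cascade_monotonicity():
    """Survivors shrink at every stage on a noisy table."""
    from dynrad.modeling import SelectionTrace
    rng = np.random.default_rng(5)
    n = 150
    y = rng.integers(0, 2, n)
    t = pd.DataFrame(rng.normal(size=(n, 30)),
                     columns=[f"f{i}" for i in range(30)])
    t["sig"] = y + rng.normal(0, 0.5, n)
    trace = SelectionTrace()
    surv1, _ = variance_filter(t)
    trace.record("variance", surv1)
    surv2, _ = mwu_filter(t[surv1], y)
    trace.record("mwu", surv2)
    surv3, _, _ = lasso_select(t[surv2], y) if surv2 else (surv2, {}, 0)
    trace.record("lasso", surv3)
    assert set(surv3) <= set(surv2) <= set(surv1)
    with pytest.raises(ValueError):
        trace.record("bogus", surv3 + ["f0_new"])
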