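"""Performance statistics: DeLong AUC inference, model comparisons,
threshold metrics, calibration, decision curves, subgroup odds ratios and
exact linear SHAP attributions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "auc_delong", "delong_test", "likelihood_ratio_test", "youden_metrics",
    "calibration_brier", "decision_curve", "subgroup_association", "shap_linear",
]


# ------------------------------------------------------------------ DeLong

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


def auc_delong(scores: Sequence[float], labels: Sequence[int]
               ) -> Tuple[float, float, Tuple[float, float]]:
    """AUC (tie value 1/2), its DeLong variance, and a Wald 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return auc, float(var), ci


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> float:
    """Two-sided p for the paired (correlated-ROC) DeLong comparison."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if a.shape != b.shape:
        raise ValueError("score vectors must be paired")
    auc_a, v10a, v01a = _delong_components(a, labels)
    auc_b, v10b, v01b = _delong_components(b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# ------------------------------------------------------------------ LRT

def _loglik(X: np.ndarray, y: np.ndarray) -> float:
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
        try:
            fit = model.fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # quasi-separation: Newton's Hessian is singular, lbfgs is not
            fit = model.fit(disp=0, maxiter=500, method="lbfgs")
    return float(fit.llf)


def likelihood_ratio_test(nested_X: pd.DataFrame, full_X: pd.DataFrame,
                          labels: Sequence[int]) -> float:
    """Chi-square p-value comparing nested logistic model fits."""
    if not set(nested_X.columns) <= set(full_X.columns):
        raise ValueError("models are not nested")
    y = np.asarray(labels).astype(int)
    df = full_X.shape[1] - nested_X.shape[1]
    if df == 0:
        return 1.0
    ll0 = _loglik(nested_X.to_numpy(dtype=float), y)
    ll1 = _loglik(full_X.to_numpy(dtype=float), y)
    stat = max(0.0, 2.0 * (ll1 - ll0))
    return float(stats.chi2.sf(stat, df))


# ------------------------------------------------------------------ thresholds

def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Score maximizing sensitivity + specificity - 1; ties -> lower score."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    cand = np.unique(s)
    best_t, best_j = cand[0], -np.inf
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    for t in cand:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def youden_metrics(train_scores, train_labels, test_scores, test_labels
                   ) -> Dict[str, float]:
    """Metrics on TEST at the train-frozen Youden threshold."""
    t = youden_threshold(train_scores, train_labels)
    s = np.asarray(test_scores, dtype=float)
    y = np.asarray(test_labels).astype(int)
    pred = (s >= t).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return {
        "threshold": t,
        "accuracy": (tp + tn) / y.size,
        "sensitivity": sens,
        "specificity": spec,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


# ------------------------------------------------------------------ calibration

def calibration_brier(scores, labels, n_bins: int = 10
                      ) -> Tuple[pd.DataFrame, float]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must be probabilities in [0,1]")
    brier = float(((s - y) ** 2).mean())
    edges = np.linspace(0, 1, n_bins + 1)
    idx = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        in_bin = idx == b
        if not in_bin.any():
            continue
        rows.append({
            "bin": b,
            "mean_predicted": float(s[in_bin].mean()),
            "observed_rate": float(y[in_bin].mean()),
            "count": int(in_bin.sum()),
        })
    return pd.DataFrame(rows), brier


# ------------------------------------------------------------------ decision curve

def decision_curve(scores, labels, thresholds: Optional[Sequence[float]] = None
                   ) -> pd.DataFrame:
    """Net benefit NB(pt) = TP/n - FP/n * pt/(1-pt), with treat-all and
    treat-none reference curves."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray([t for t in thresholds if 0 < t < 1], dtype=float)
    n = y.size
    prev = y.mean()
    rows = []
    for pt in thresholds:
        pred = s >= pt
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        odds = pt / (1 - pt)
        rows.append({
            "threshold": pt,
            "net_benefit": tp - fp * odds,
            "treat_all": prev - (1 - prev) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ subgroups

def subgroup_association(scores, labels, strata, threshold: float
                         ) -> pd.DataFrame:
    """Per-stratum odds ratio (Youden-dichotomized 2x2, Haldane-Anscombe
    correction for zero cells) and a two-sample t test of the predicted
    probabilities by outcome."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    strata = np.asarray(strata)
    rows = []
    for g in pd.unique(strata):
        sel = strata == g
        ys, ss = y[sel], s[sel]
        if min((ys == 1).sum(), (ys == 0).sum()) < 2:
            rows.append({"stratum": g, "n": int(sel.sum()), "or": np.nan,
                         "t_p": np.nan, "corrected": False,
                         "note": "insufficient"})
            continue
        pred = (ss >= threshold).astype(int)
        a = ((pred == 1) & (ys == 1)).sum()
        b = ((pred == 1) & (ys == 0)).sum()
        c = ((pred == 0) & (ys == 1)).sum()
        d = ((pred == 0) & (ys == 0)).sum()
        corrected = 0 in (a, b, c, d)
        if corrected:
            a, b, c, d = (v + 0.5 for v in (a, b, c, d))
        or_ = (a * d) / (b * c)
        t_p = float(stats.ttest_ind(ss[ys == 1], ss[ys == 0]).pvalue)
        rows.append({"stratum": g, "n": int(sel.sum()), "or": float(or_),
                     "t_p": t_p, "corrected": corrected, "note": ""})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ SHAP

def shap_linear(coef: np.ndarray, data: pd.DataFrame,
                background: pd.DataFrame) -> pd.DataFrame:
    """Exact SHAP attributions on the logit scale for a linear model with
    independent features: phi_j(x) = coef_j * (x_j - mean background_j)."""
    mu = background.mean(axis=0).to_numpy(dtype=float)
    X = data.to_numpy(dtype=float)
    phi = (X - mu) * np.asarray(coef, dtype=float)
    return pd.DataFrame(phi, index=data.index, columns=data.columns)
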