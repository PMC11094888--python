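"""Feature selection cascade (variance -> Mann-Whitney -> LASSO -> mRMR) and
logistic model building with 10-fold cross-validation.

Combined models stack the component model SCORES (out-of-fold on train to
avoid optimistic stacking) together with the clinical factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score, mutual_info_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

log = logging.getLogger(__name__)

__all__ = [
    "SelectionTrace", "ModelBundle",
    "variance_filter", "mwu_filter", "lasso_select", "mrmr_rank",
    "fit_logistic_cv", "build_combined_models",
]


@dataclass
class SelectionTrace:
    stages: Dict[str, List[str]] = field(default_factory=dict)
    mwu_pvalues: Dict[str, float] = field(default_factory=dict)
    lasso_coefs: Dict[str, float] = field(default_factory=dict)
    lasso_penalty: float = np.nan
    mrmr_ranking: List[str] = field(default_factory=list)

    def record(self, stage: str, survivors: Sequence[str]) -> None:
        if self.stages:
            prev = list(self.stages.values())[-1]
            extra = set(survivors) - set(prev)
            if extra:
                raise ValueError(f"stage {stage} added features: {sorted(extra)}")
        self.stages[stage] = list(survivors)


@dataclass
class ModelBundle:
    name: str
    features: List[str]
    coef: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    train_oof_scores: Optional[pd.Series] = None
    train_scores: Optional[pd.Series] = None
    component_pvalues: Dict[str, float] = field(default_factory=dict)
    cv_auc_by_size: Dict[int, float] = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> pd.Series:
        X = (table[self.features].to_numpy(dtype=float) - self.scaler_mean) / self.scaler_scale
        z = X @ self.coef + self.intercept
        return pd.Series(1.0 / (1.0 + np.exp(-z)), index=table.index,
                         name=self.name)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "features": self.features,
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "component_pvalues": self.component_pvalues,
            "cv_auc_by_size": {str(k): v for k, v in self.cv_auc_by_size.items()},
        }


# ----------------------------------------------------------------- selection

def variance_filter(table: pd.DataFrame, min_variance: float = 1e-8
                    ) -> Tuple[List[str], Dict[str, str]]:
    """Drop features with any missing value or variance below threshold."""
    survivors, reasons = [], {}
    for col in table.columns:
        x = table[col]
        if x.isna().any():
            reasons[col] = "missing"
        elif float(np.var(x.to_numpy(dtype=float))) < min_variance:
            reasons[col] = "low_variance"
        else:
            survivors.append(col)
    return survivors, reasons


def mwu_filter(table: pd.DataFrame, labels: Sequence[int], alpha: float = 0.05
               ) -> Tuple[List[str], Dict[str, float]]:
    """Two-sided Mann-Whitney U per feature; keep p < alpha (strict)."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    survivors, pvals = [], {}
    g1 = y == 1
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        method = "exact" if min(g1.sum(), (~g1).sum()) < 8 else "asymptotic"
        res = stats.mannwhitneyu(x[g1], x[~g1], alternative="two-sided",
                                 method=method)
        pvals[col] = float(res.pvalue)
        if res.pvalue < alpha:
            survivors.append(col)
    return survivors, pvals


def lasso_select(table: pd.DataFrame, labels: Sequence[int], cv_folds: int = 5,
                 seed: int = 0, Cs=None) -> Tuple[List[str], Dict[str, float], float]:
    """L1 logistic regression with cross-validated penalty.

    Returns (survivors, coefficients, chosen C). Falls back to the single
    largest-coefficient feature at the weakest penalty if everything is
    zeroed out.
    """
    y = np.asarray(labels).astype(int)
    # collapse exact-duplicate columns (L1 splits weight across duplicates,
    # so dedup is what makes "select one of the pair" well defined)
    seen: Dict[bytes, str] = {}
    unique_cols = []
    for c in table.columns:
        key = table[c].to_numpy(dtype=float).tobytes()
        if key not in seen:
            seen[key] = c
            unique_cols.append(c)
    table = table[unique_cols]
    X = StandardScaler().fit_transform(table.to_numpy(dtype=float))
    n_splits = min(cv_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True,
                         random_state=seed)
    model = LogisticRegressionCV(
        Cs=np.logspace(-2, 1, 10) if Cs is None else np.asarray(Cs, dtype=float),
        cv=cv, penalty="l1", solver="liblinear",
        scoring="neg_log_loss", max_iter=1000, tol=1e-3, random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coef = model.coef_.ravel()
    chosen_c = float(model.C_[0])
    survivors = [c for c, w in zip(table.columns, coef) if w != 0.0]
    if not survivors:
        warnings.warn("LASSO zeroed all features; falling back to the "
                      "largest-|coefficient| feature at the weakest penalty")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            weak = LogisticRegression(penalty="l1", C=100.0, solver="liblinear",
                                      max_iter=2000, random_state=seed).fit(X, y)
        idx = int(np.argmax(np.abs(weak.coef_.ravel())))
        survivors = [table.columns[idx]]
        coef = weak.coef_.ravel()
    coefs = {c: float(w) for c, w in zip(table.columns, coef)}
    return survivors, coefs, chosen_c


def _quantile_bins(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(x, np.unique(qs))


def mrmr_rank(table: pd.DataFrame, labels: Sequence[int], k: Optional[int] = None,
              n_bins: int = 4) -> List[str]:
    """Greedy minimum-redundancy-maximum-relevance ranking.

    Difference criterion (relevance minus mean redundancy) with mutual
    information on quantile-discretized values; deterministic ties broken by
    column order.
    """
    y = np.asarray(labels).astype(int)
    cols = list(table.columns)
    if k is None:
        k = len(cols)
    k = min(k, len(cols))
    if k == 0:
        return []
    disc = {c: _quantile_bins(table[c].to_numpy(dtype=float), n_bins) for c in cols}
    relevance = {c: mutual_info_score(disc[c], y) for c in cols}
    selected: List[str] = []
    remaining = list(cols)
    mi_cache: Dict[Tuple[str, str], float] = {}

    def mi(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = mutual_info_score(disc[a], disc[b])
        return mi_cache[key]

    while remaining and len(selected) < k:
        best_col, best_score = None, -np.inf
        for c in remaining:
            red = np.mean([mi(c, s) for s in selected]) if selected else 0.0
            score = relevance[c] - red
            if score > best_score + 1e-15:
                best_col, best_score = c, score
        selected.append(best_col)
        remaining.remove(best_col)
    return selected


# ----------------------------------------------------------------- modelling

def _oof_scores(X: np.ndarray, y: np.ndarray, folds: int, seed: int
                ) -> np.ndarray:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(y.size, np.nan)
    for tr, te in cv.split(X, y):
        if len(np.unique(y[tr])) < 2:  # pragma: no cover - stratified
            raise ValueError("single-class fold")
        m = LogisticRegression(max_iter=2000).fit(X[tr], y[tr])
        oof[te] = m.predict_proba(X[te])[:, 1]
    return oof


def fit_logistic_cv(table: pd.DataFrame, labels: Sequence[int],
                    ranked_features: Sequence[str], folds: int = 10,
                    k_max: int = 15, seed: int = 0, name: str = "model"
                    ) -> ModelBundle:
    """Choose the ranked-prefix size maximizing mean out-of-fold AUC, then
    refit on the full training set."""
    y = np.asarray(labels).astype(int)
    ranked = list(ranked_features)[:k_max]
    if not ranked:
        raise ValueError("no ranked features supplied")
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("too few samples per class for stratified folds")
    scaler = StandardScaler().fit(table[ranked].to_numpy(dtype=float))
    Xall = scaler.transform(table[ranked].to_numpy(dtype=float))
    cv_auc: Dict[int, float] = {}
    oof_by_size: Dict[int, np.ndarray] = {}
    for size in range(1, len(ranked) + 1):
        oof = _oof_scores(Xall[:, :size], y, folds, seed)
        cv_auc[size] = float(roc_auc_score(y, oof))
        oof_by_size[size] = oof
    best_size = max(cv_auc, key=lambda s: (cv_auc[s], -s))
    feats = ranked[:best_size]
    final = LogisticRegression(max_iter=2000).fit(Xall[:, :best_size], y)
    bundle = ModelBundle(
        name=name,
        features=feats,
        coef=final.coef_.ravel(),
        intercept=float(final.intercept_[0]),
        scaler_mean=scaler.mean_[:best_size],
        scaler_scale=scaler.scale_[:best_size],
        cv_auc_by_size=cv_auc,
    )
    bundle.train_oof_scores = pd.Series(oof_by_size[best_size],
                                        index=table.index, name=name)
    bundle.train_scores = bundle.predict(table)
    return bundle


_COMBOS = {
    "C": ["hr_status", "her2_status"],
    "R": ["radiomic_score"],
    "D": ["dynamic_score"],
    "CR": ["hr_status", "her2_status", "radiomic_score"],
    "CD": ["hr_status", "her2_status", "dynamic_score"],
    "RD": ["radiomic_score", "dynamic_score"],
    "CRD": ["hr_status", "her2_status", "radiomic_score", "dynamic_score"],
}


def build_combined_models(clinical: pd.DataFrame, radiomic_score: pd.Series,
                          dynamic_score: pd.Series, labels: Sequence[int],
                          folds: int = 10, seed: int = 0
                          ) -> Dict[str, ModelBundle]:
    """Logistic models for C and every score combination (CR, CD, RD, CRD).

    Component Wald p-values are reported for each fit; collinear inputs
    trigger a warning but the fit is kept.
    """
    y = np.asarray(labels).astype(int)
    base = clinical[["hr_status", "her2_status"]].astype(float).copy()
    base["radiomic_score"] = radiomic_score.reindex(base.index).astype(float)
    base["dynamic_score"] = dynamic_score.reindex(base.index).astype(float)

    corr = base.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    if np.nanmax(corr.to_numpy()) > 0.98:
        warnings.warn("near-collinear inputs in combined models")

    out: Dict[str, ModelBundle] = {}
    for name, cols in _COMBOS.items():
        X = base[cols].to_numpy(dtype=float)
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        model = LogisticRegression(max_iter=2000).fit(Xs, y)
        # Wald p-values from an unpenalized statsmodels refit
        pvals: Dict[str, float] = {}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm_fit = sm.Logit(y, sm.add_constant(Xs)).fit(disp=0)
            pvals = {c: float(p) for c, p in zip(cols, sm_fit.pvalues[1:])}
        except Exception as exc:  # perfect separation etc.
            log.warning("Wald p-values unavailable for %s: %s", name, exc)
        bundle = ModelBundle(
            name=name, features=cols,
            coef=model.coef_.ravel(), intercept=float(model.intercept_[0]),
            scaler_mean=scaler.mean_, scaler_scale=scaler.scale_,
            component_pvalues=pvals,
        )
        n_folds = min(folds, int(np.bincount(y).min()))
        bundle.train_oof_scores = pd.Series(
            _oof_scores(Xs, y, max(2, n_folds), seed), index=base.index, name=name)
        bundle.train_scores = bundle.predict(base)
        out[name] = bundle
    return out
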