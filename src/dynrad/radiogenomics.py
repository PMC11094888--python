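"""Radiogenomic stratification: DYN+/- groups, differential expression and
gene set enrichment analysis (weighted running-sum GSEA with phenotype
permutation)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ExpressionMatrix

__all__ = [
    "stratify_dyn", "differential_expression", "gsea", "overlap_analysis",
    "read_gmt",
]


def stratify_dyn(scores: pd.Series, threshold: float) -> pd.Series:
    """DYN+ if predicted probability >= threshold (inclusive boundary)."""
    labels = (scores >= threshold).astype(int)
    if labels.nunique() < 2:
        raise ValueError("degenerate stratification: all patients in one group")
    return labels.rename("dyn_group")


def _gene_t_and_fc(values: np.ndarray, grp: np.ndarray, welch: bool):
    a = values[:, grp == 1]
    b = values[:, grp == 0]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    log2fc = a.mean(axis=1) - b.mean(axis=1)  # log-scale difference
    # zero-variance genes with equal means: undefined t -> p = 1
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    return t, p, log2fc


def differential_expression(expr: ExpressionMatrix, groups: pd.Series,
                            fc_cutoff: float = 0.25, alpha: float = 0.05,
                            welch: bool = True) -> pd.DataFrame:
    """Per-gene t test between DYN+ and DYN- patients.

    Retains genes with |log2FC| > fc_cutoff AND p < alpha (both strict).
    log2FC is the difference of group means on log2-scale expression.
    """
    values = expr.values
    common = [p for p in values.columns if p in groups.index]
    grp = groups.loc[common].to_numpy()
    if min((grp == 1).sum(), (grp == 0).sum()) < 2:
        raise ValueError("need >= 2 patients per group")
    mat = values[common].to_numpy(dtype=float)
    t, p, log2fc = _gene_t_and_fc(mat, grp, welch)
    table = pd.DataFrame({
        "gene_id": values.index,
        "log2fc": log2fc,
        "t": t,
        "p": p,
    })
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    kept = table[(table["p"] < alpha) & (table["log2fc"].abs() > fc_cutoff)]
    return kept.reset_index(drop=True)


# ------------------------------------------------------------------ GSEA

def read_gmt(path) -> Dict[str, List[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def _enrichment_score(ranked_genes: List[str], metric: np.ndarray,
                      gene_set: set, weight: float = 1.0) -> float:
    hits = np.fromiter((g in gene_set for g in ranked_genes), bool,
                       count=len(ranked_genes))
    if not hits.any():
        return np.nan
    w = np.abs(metric) ** weight
    w_hit = np.where(hits, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:
        return 0.0
    p_hit = np.cumsum(w_hit) / denom
    n_miss = (~hits).sum()
    if n_miss == 0:
        return 0.0  # running sum returns to zero with no misses
    p_miss = np.cumsum(~hits) / n_miss
    running = p_hit - p_miss
    return float(running[np.argmax(np.abs(running))])


def _rank_metric(mat: np.ndarray, grp: np.ndarray, welch: bool) -> np.ndarray:
    t, _, _ = _gene_t_and_fc(mat, grp, welch)
    return t


@dataclass
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05 and self.fdr < 0.25


def gsea(expr: ExpressionMatrix, groups: pd.Series,
         gene_sets: Dict[str, Sequence[str]], n_permutations: int = 1000,
         seed: int = 0, welch: bool = True) -> List[EnrichmentResult]:
    """Phenotype-permutation GSEA on all genes ranked by signed t-statistic.

    Enrichment uses the weighted (p=1) Kolmogorov-Smirnov running sum; NES
    and FDR follow the sign-matched normalization procedure.
    """
    values = expr.values
    common = [p for p in values.columns if p in groups.index]
    grp = groups.loc[common].to_numpy()
    mat = values[common].to_numpy(dtype=float)
    genes = list(values.index)
    measured = set(genes)

    usable = {}
    for name, members in gene_sets.items():
        inter = set(members) & measured
        if not inter:
            warnings.warn(f"gene set {name!r} has no measured genes; skipped")
            continue
        usable[name] = inter

    metric = _rank_metric(mat, grp, welch)
    order = np.argsort(-metric, kind="stable")
    ranked = [genes[i] for i in order]
    metric_sorted = metric[order]

    es_obs = {name: _enrichment_score(ranked, metric_sorted, s)
              for name, s in usable.items()}

    rng = np.random.default_rng(seed)
    null_es = {name: np.empty(n_permutations) for name in usable}
    for b in range(n_permutations):
        perm = rng.permutation(grp)
        m = _rank_metric(mat, perm, welch)
        o = np.argsort(-m, kind="stable")
        rk = [genes[i] for i in o]
        ms = m[o]
        for name, s in usable.items():
            null_es[name][b] = _enrichment_score(rk, ms, s)

    # sign-matched normalization
    results = []
    all_nes_null: List[np.ndarray] = []
    nes_obs = {}
    for name in usable:
        null = null_es[name]
        obs = es_obs[name]
        same_sign = null[np.sign(null) == np.sign(obs)] if obs != 0 else null
        mean_abs = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes_obs[name] = obs / mean_abs if mean_abs and np.isfinite(mean_abs) else np.nan
        pos_m = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_m = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        nes_null = np.where(null >= 0,
                            null / pos_m if pos_m else np.nan,
                            null / neg_m if neg_m else np.nan)
        all_nes_null.append(nes_null[np.isfinite(nes_null)])
    pooled_null = np.concatenate(all_nes_null) if all_nes_null else np.array([])
    nes_obs_arr = np.array([nes_obs[n] for n in usable])

    for name in usable:
        null = null_es[name]
        obs = es_obs[name]
        if obs >= 0:
            same = null[null >= 0]
            p = (same >= obs).mean() if same.size else 1.0
        else:
            same = null[null < 0]
            p = (same <= obs).mean() if same.size else 1.0
        nes = nes_obs[name]
        if np.isfinite(nes) and pooled_null.size:
            if nes >= 0:
                frac_null = (pooled_null >= nes).mean() / max(
                    (pooled_null >= 0).mean(), 1e-12)
                frac_obs = (nes_obs_arr >= nes).mean() / max(
                    (nes_obs_arr >= 0).mean(), 1e-12)
            else:
                frac_null = (pooled_null <= nes).mean() / max(
                    (pooled_null < 0).mean(), 1e-12)
                frac_obs = (nes_obs_arr <= nes).mean() / max(
                    (nes_obs_arr < 0).mean(), 1e-12)
            fdr = min(1.0, frac_null / max(frac_obs, 1e-12))
        else:
            fdr = np.nan
        results.append(EnrichmentResult(
            gene_set=name, es=float(obs),
            nes=float(nes) if np.isfinite(nes) else np.nan,
            p=float(p), fdr=float(fdr), size=len(usable[name]),
        ))
    return results


def overlap_analysis(deg_tables: Dict[str, pd.DataFrame]) -> Dict[str, Dict]:
    """Per-direction intersections of DEG lists across stratifications."""
    if len(deg_tables) < 2:
        raise ValueError("need at least two DEG tables")
    out = {}
    for direction in ("up", "down"):
        sets = {name: set(t.loc[t["direction"] == direction, "gene_id"])
                for name, t in deg_tables.items()}
        common = set.intersection(*sets.values()) if sets else set()
        out[direction] = {
            "per_table_counts": {k: len(v) for k, v in sets.items()},
            "common": sorted(common),
            "n_common": len(common),
        }
    return out
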