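"""End-to-end orchestration: cohort -> preprocessing -> features ->
reliability screening -> dynamic features -> models -> evaluation ->
radiogenomics."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import PerturbationParams, PreprocessParams, SimulationConfig
from .dynamics import build_feature_series, extract_dynamic_features
from .evaluation import (auc_delong, delong_test, likelihood_ratio_test,
                         calibration_brier, decision_curve,
                         subgroup_association, youden_metrics, youden_threshold,
                         shap_linear)
from .modeling import (ModelBundle, SelectionTrace, build_combined_models,
                       fit_logistic_cv, lasso_select, mrmr_rank, mwu_filter,
                       variance_filter)
from .preprocess import joint_normalize, resample_isotropic
from .radiomics import extract_feature_table, column_metadata
from .reliability import (perturb_mask, phase_variation_test,
                          reliability_report)
from .synthetic import generate_cohort, split_train_test
from .radiogenomics import differential_expression, gsea, stratify_dyn

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    clinical: pd.DataFrame
    feature_table: pd.DataFrame
    eligible_series_features: List[str]
    dynamic_table: pd.DataFrame
    models: Dict[str, ModelBundle]
    traces: Dict[str, SelectionTrace]
    evaluation: Dict[str, dict]
    deg_table: Optional[pd.DataFrame] = None
    dyn_groups: Optional[pd.Series] = None
    expression: Optional[object] = None
    reliability: Optional[pd.DataFrame] = None


def preprocess_stack(stack, params: PreprocessParams):
    out = resample_isotropic(stack, params)
    out = joint_normalize(out, scale=params.normalization_scale)
    out.image = out.image.astype(np.float32)  # halves cohort-scale memory
    return out


def screen_features(stacks, params: PreprocessParams,
                    perturb: PerturbationParams, feature_table: pd.DataFrame,
                    n_phases: int, reliability_subset: int = 24,
                    icc_threshold: float = 0.9):
    """ICC screening on a patient subset plus the phase-variation test.

    Returns base names of first-order/texture features that are repeatable in
    every phase and vary across phases.
    """
    subset = list(feature_table.index[:reliability_subset])
    tables = {0: feature_table.loc[subset]}
    for k in range(1, perturb.n_perturbations + 1):
        rows = []
        for pid, stack in zip(feature_table.index, stacks):
            if pid not in subset:
                continue
            pstack = perturb_mask(stack, perturb, k)
            rows.append(extract_feature_table([pstack], [pid], params).iloc[0])
        tables[k] = pd.DataFrame(rows)
    rep = reliability_report(tables, n_phases, icc_threshold)

    # collapse per-column ICCs to per-feature all-phase repeatability
    base_names = {}
    for col in feature_table.columns:
        if col.startswith("shape_"):
            continue
        base, _, phase = col.rpartition("_phase")
        base_names.setdefault(base, []).append(col)
    eligible = []
    variation_p = {}
    for base, cols in base_names.items():
        iccs = rep.loc[cols, "icc"]
        if not (iccs >= icc_threshold).all():
            continue
        vals = feature_table[sorted(cols, key=lambda c: int(c.rpartition("_phase")[2]))]
        p, varying = phase_variation_test(vals.to_numpy(dtype=float))
        variation_p[base] = p
        if varying:
            eligible.append(base)
    return sorted(eligible), rep, variation_p


def _select_and_fit(table: pd.DataFrame, labels, name: str, seed: int,
                    folds: int = 10, k_max: int = 15):
    trace = SelectionTrace()
    surv, _ = variance_filter(table)
    trace.record("variance", surv)
    surv2, pvals = mwu_filter(table[surv], labels)
    trace.record("mwu", surv2)
    trace.mwu_pvalues = pvals
    if not surv2:
        raise ValueError(f"no {name} features survive the MWU filter")
    surv3, coefs, penalty = lasso_select(table[surv2], labels, seed=seed)
    trace.record("lasso", surv3)
    trace.lasso_coefs = coefs
    trace.lasso_penalty = penalty
    ranked = mrmr_rank(table[surv3], labels)
    trace.mrmr_ranking = ranked
    bundle = fit_logistic_cv(table, labels, ranked, folds=folds, k_max=k_max,
                             seed=seed, name=name)
    return bundle, trace


def evaluate_model(name: str, train_scores: pd.Series, test_scores: pd.Series,
                   y_train: pd.Series, y_test: pd.Series) -> dict:
    auc_tr, _, ci_tr = auc_delong(train_scores, y_train)
    auc_te, _, ci_te = auc_delong(test_scores, y_test)
    metrics = youden_metrics(train_scores, y_train, test_scores, y_test)
    _, brier_te = calibration_brier(test_scores, y_test)
    return {
        "train_auc": auc_tr, "train_ci": ci_tr,
        "test_auc": auc_te, "test_ci": ci_te,
        "brier_test": brier_te, **metrics,
    }


def run_pipeline(config: SimulationConfig,
                 preprocess_params: Optional[PreprocessParams] = None,
                 perturb_params: Optional[PerturbationParams] = None,
                 split_ratio: float = 3.0, seed: int = 0,
                 reliability_subset: int = 24,
                 run_radiogenomics: bool = True,
                 gsea_gene_sets: Optional[dict] = None,
                 gsea_permutations: int = 200) -> PipelineResult:
    pp = preprocess_params or PreprocessParams()
    pb = perturb_params or PerturbationParams(n_perturbations=8, seed=seed)

    log.info("generating cohort (n=%d)", config.n_patients)
    stacks, clinical, expression = generate_cohort(config)
    clinical = split_train_test(clinical, ratio=split_ratio, seed=seed)
    clinical = clinical.set_index("patient_id")

    log.info("preprocessing and extracting features")
    pre = [preprocess_stack(s, pp) for s in stacks]
    stacks = None  # release the raw-resolution cohort
    feature_table = extract_feature_table(pre, clinical.index, pp)

    train_ids = clinical.index[clinical["split"] == "train"]
    test_ids = clinical.index[clinical["split"] == "test"]
    y_train = clinical.loc[train_ids, "pcr"]
    y_test = clinical.loc[test_ids, "pcr"]

    log.info("reliability screening")
    eligible, rel_report, variation_p = screen_features(
        pre, pp, pb, feature_table, config.n_phases,
        reliability_subset=reliability_subset)
    log.info("%d eligible feature series", len(eligible))

    series = build_feature_series(feature_table, eligible)
    dynamic_table = extract_dynamic_features(series)
    dynamic_table = dynamic_table.reindex(feature_table.index)

    log.info("fitting radiomic and dynamic models")
    rad_bundle, rad_trace = _select_and_fit(
        feature_table.loc[train_ids], y_train, "R", seed)
    dyn_bundle, dyn_trace = _select_and_fit(
        dynamic_table.loc[train_ids], y_train, "D", seed)

    combos = build_combined_models(
        clinical.loc[train_ids],
        rad_bundle.train_oof_scores,
        dyn_bundle.train_oof_scores,
        y_train, seed=seed)

    models = {"R": rad_bundle, "D": dyn_bundle, **combos}
    traces = {"R": rad_trace, "D": dyn_trace}

    # test-set component scores feed the combined models
    rad_test = rad_bundle.predict(feature_table.loc[test_ids])
    dyn_test = dyn_bundle.predict(dynamic_table.loc[test_ids])
    test_design = clinical.loc[test_ids, ["hr_status", "her2_status"]].astype(float)
    test_design["radiomic_score"] = rad_test
    test_design["dynamic_score"] = dyn_test

    evaluation: Dict[str, dict] = {}
    test_scores_by_model: Dict[str, pd.Series] = {}
    for name, bundle in models.items():
        if name == "R":
            te = rad_test
        elif name == "D":
            te = dyn_test
        else:
            te = bundle.predict(test_design)
        test_scores_by_model[name] = te
        evaluation[name] = evaluate_model(
            name, bundle.train_oof_scores, te, y_train, y_test)

    # model comparisons against CRD
    for name in models:
        if name == "CRD":
            continue
        evaluation[name]["delong_p_vs_CRD_test"] = delong_test(
            test_scores_by_model["CRD"], test_scores_by_model[name], y_test)

    # likelihood-ratio tests of nested combined models against CRD
    train_design = clinical.loc[train_ids, ["hr_status", "her2_status"]].astype(float)
    train_design["radiomic_score"] = rad_bundle.train_oof_scores
    train_design["dynamic_score"] = dyn_bundle.train_oof_scores
    for name in ("C", "CR", "CD", "RD"):
        evaluation[name]["lrt_p_vs_CRD_train"] = likelihood_ratio_test(
            train_design[models[name].features],
            train_design[models["CRD"].features], y_train)

    # optimal-model extras: decision curve, subgroup ORs, linear SHAP
    crd = models["CRD"]
    evaluation["CRD"]["decision_curve_test"] = decision_curve(
        test_scores_by_model["CRD"], y_test).to_dict(orient="list")
    subtype = (clinical.loc[test_ids, "hr_status"].map({1: "HR+", 0: "HR-"})
               + clinical.loc[test_ids, "her2_status"].map({1: "HER2+", 0: "HER2-"}))
    evaluation["CRD"]["subgroups_test"] = subgroup_association(
        test_scores_by_model["CRD"], y_test, subtype,
        threshold=evaluation["CRD"]["threshold"]).to_dict(orient="list")
    crd_std = (train_design[crd.features] - crd.scaler_mean) / crd.scaler_scale
    shap = shap_linear(crd.coef, crd_std, crd_std)
    evaluation["CRD"]["shap_mean_abs"] = shap.abs().mean().to_dict()

    result = PipelineResult(
        clinical=clinical, feature_table=feature_table,
        eligible_series_features=eligible, dynamic_table=dynamic_table,
        models=models, traces=traces, evaluation=evaluation,
        expression=expression, reliability=rel_report,
    )

    if run_radiogenomics:
        thr = youden_threshold(dyn_bundle.train_oof_scores, y_train)
        all_scores = pd.concat([dyn_bundle.train_oof_scores, dyn_test])
        groups = stratify_dyn(all_scores, thr)
        result.dyn_groups = groups
        result.deg_table = differential_expression(expression, groups)
        if gsea_gene_sets:
            result.evaluation["gsea"] = [
                r.__dict__ for r in gsea(expression, groups, gsea_gene_sets,
                                         n_permutations=gsea_permutations,
                                         seed=seed)
            ]
    return result
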