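import numpy as np
import pandas as pd
import pytest

from dynrad.radiogenomics import (differential_expression, gsea,
                                  overlap_analysis, read_gmt, stratify_dyn)
from dynrad.synthetic import ExpressionMatrix


def _expr(n_genes=500, n_per_group=50, n_planted=20, log2fc=1.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    grp = np.array([1] * n_per_group + [0] * n_per_group)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    vals = rng.normal(8.0, 1.0, size=(n_genes, n))
    planted = genes[:n_planted]
    vals[:n_planted] += log2fc * grp[None, :]
    df = pd.DataFrame(vals, index=genes,
                      columns=[f"P{i}" for i in range(n)])
    em = ExpressionMatrix(values=df, planted_deg_ids=planted)
    groups = pd.Series(grp, index=df.columns, name="dyn_group")
    return em, groups


# ------------------------------------------------------------------ stratify

def test_stratify_basic():
    s = pd.Series([0.4, 0.6], index=["a", "b"])
    out = stratify_dyn(s, 0.5)
    assert out.tolist() == [0, 1]


def test_stratify_boundary_inclusive():
    s = pd.Series([0.5, 0.1], index=["a", "b"])
    assert stratify_dyn(s, 0.5).tolist() == [1, 0]


def test_stratify_degenerate_raises():
    with pytest.raises(ValueError):
        stratify_dyn(pd.Series([0.9, 0.8]), 0.5)


# ------------------------------------------------------------------ DEGs

def test_deg_identical_gene_excluded():
    em, groups = _expr(n_genes=10, n_planted=0)
    em.values.iloc[0] = 5.0  # constant everywhere
    out = differential_expression(em, groups)
    assert "G0000" not in set(out["gene_id"])


def test_deg_planted_recall_and_null_rate():
    em, groups = _expr(n_genes=2020, n_per_group=100, n_planted=20,
                       log2fc=1.0, seed=1)
    out = differential_expression(em, groups)
    found = set(out["gene_id"])
    recall = len(found & set(em.planted_deg_ids)) / 20
    assert recall >= 0.95
    null_pass = len(found - set(em.planted_deg_ids)) / 2000
    assert null_pass <= 0.06


def test_deg_boundary_strictness():
    # log2fc exactly at the cutoff must be excluded even with tiny p
    rng = np.random.default_rng(2)
    n = 400
    grp = np.array([1] * 200 + [0] * 200)
    base = rng.normal(0, 0.001, n)
    vals = np.vstack([base + 0.25 * grp])  # log2fc == 0.25 exactly (approx)
    vals[0, grp == 1] = 0.25
    vals[0, grp == 0] = 0.0
    df = pd.DataFrame(vals, index=["G0"], columns=[f"P{i}" for i in range(n)])
    em = ExpressionMatrix(values=df, planted_deg_ids=[])
    groups = pd.Series(grp, index=df.columns)
    out = differential_expression(em, groups)
    assert out.empty


def test_deg_direction_labels():
    em, groups = _expr(n_genes=30, n_planted=5, log2fc=2.0)
    out = differential_expression(em, groups)
    planted_rows = out[out["gene_id"].isin(em.planted_deg_ids)]
    assert (planted_rows["direction"] == "up").all()


def test_deg_type_one_control_null():
    em, groups = _expr(n_genes=2000, n_per_group=60, n_planted=0, seed=3)
    out = differential_expression(em, groups)
    rate = len(out) / 2000
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 2000)


def test_deg_small_group_raises():
    em, _ = _expr(n_genes=5)
    groups = pd.Series([1] + [0] * 99, index=em.values.columns)
    with pytest.raises(ValueError):
        differential_expression(em, groups)


# ------------------------------------------------------------------ GSEA

def test_gsea_planted_set_enriched():
    em, groups = _expr(n_genes=500, n_per_group=40, n_planted=25,
                       log2fc=1.2, seed=4)
    sets = {"planted": em.planted_deg_ids,
            "random": [f"G{i:04d}" for i in range(400, 430)]}
    res = {r.gene_set: r for r in gsea(em, groups, sets,
                                       n_permutations=200, seed=0)}
    assert res["planted"].es > 0
    assert res["planted"].p < 0.05
    assert res["planted"].fdr < 0.25


def test_gsea_null_set_rarely_significant():
    em, groups = _expr(n_genes=300, n_per_group=20, n_planted=0, seed=5)
    rng = np.random.default_rng(0)
    hits = 0
    runs = 50
    for i in range(runs):
        members = [f"G{g:04d}" for g in rng.choice(300, 20, replace=False)]
        res = gsea(em, groups, {"s": members}, n_permutations=100, seed=i)[0]
        if res.p < 0.05 and res.fdr < 0.25:
            hits += 1
    assert hits / runs <= 0.10


def test_gsea_all_genes_set_es_near_zero():
    em, groups = _expr(n_genes=200, n_per_group=30, n_planted=10, seed=6)
    res = gsea(em, groups, {"all": list(em.values.index)},
               n_permutations=10, seed=0)[0]
    assert res.es == pytest.approx(0.0, abs=1e-12)


def test_gsea_unmeasured_set_skipped():
    em, groups = _expr(n_genes=50, n_planted=0)
    with pytest.warns(UserWarning, match="skipped"):
        res = gsea(em, groups, {"alien": ["ZZZ1", "ZZZ2"]},
                   n_permutations=10, seed=0)
    assert res == []


def test_gsea_rank_order_invariance():
    """ES depends on the ranking order, not the metric's scale."""
    from dynrad.radiogenomics import _enrichment_score
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(100)]
    metric = np.sort(rng.normal(size=100))[::-1]
    gene_set = set(rng.choice(genes, 15, replace=False))
    es1 = _enrichment_score(genes, metric, gene_set, weight=0.0)
    es2 = _enrichment_score(genes, metric * 7.0, gene_set, weight=0.0)
    assert es1 == pytest.approx(es2, abs=1e-12)


# ------------------------------------------------------------------ overlap

def _deg_frame(up, down):
    return pd.DataFrame({
        "gene_id": up + down,
        "direction": ["up"] * len(up) + ["down"] * len(down),
    })


def test_overlap_identical_tables():
    t = _deg_frame(["a", "b"], ["c"])
    out = overlap_analysis({"x": t, "y": t.copy()})
    assert set(out["up"]["common"]) == {"a", "b"}
    assert out["down"]["n_common"] == 1


def test_overlap_disjoint_tables():
    out = overlap_analysis({"x": _deg_frame(["a"], []),
                            "y": _deg_frame(["b"], [])})
    assert out["up"]["common"] == []


def test_overlap_requires_two():
    with pytest.raises(ValueError):
        overlap_analysis({"x": _deg_frame(["a"], [])})


def test_overlap_recovers_planted_intersection():
    em1, g1 = _expr(n_genes=520, n_per_group=100, n_planted=20, seed=8)
    em2, g2 = _expr(n_genes=520, n_per_group=100, n_planted=20, seed=9)
    # same planted genes in both cohorts by construction (first 20)
    t1 = differential_expression(em1, g1)
    t2 = differential_expression(em2, g2)
    out = overlap_analysis({"a": t1, "b": t2})
    common = set(out["up"]["common"])
    assert len(common & set(em1.planted_deg_ids)) >= 18  # >= 0.9 * 20


def test_read_gmt(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg9\n")
    sets = read_gmt(p)
    assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g9"]}
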