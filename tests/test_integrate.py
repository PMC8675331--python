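import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methylink as ml
from _oracles import quadrant_truth_table, spearman_midrank_oracle
from methylink.genome import derive_all_regions


# -------------------------------------------------------------- nine quadrant


def test_quadrant_grid_matches_truth_table():
    """Exhaustive grid including the strict boundaries at |log2FC|=1 and
    |meth.diff|=25."""
    fcs = [-5.0, -1.5, -1.0 - 1e-12, -1.0, -0.5, 0.0, 0.5, 1.0, 1.0 + 1e-12, 1.5, 5.0]
    mds = [-90.0, -26.0, -25.0 - 1e-9, -25.0, -10.0, 0.0, 10.0, 25.0, 25.0 + 1e-9, 26.0, 90.0]
    seen = set()
    for fc in fcs:
        for md in mds:
            q = ml.nine_quadrant(fc, md)
            assert q == quadrant_truth_table(fc, md)
            seen.add(q)
    assert seen == set(range(1, 10))


def test_quadrant_anchor_examples():
    assert ml.nine_quadrant(2.0, -30.0) == 1   # upregulated + upstream hypomethylated
    assert ml.nine_quadrant(-2.0, -30.0) == 7  # downregulated + hypomethylated
    assert ml.nine_quadrant(0.5, 10.0) == 5    # centre cell
    assert ml.nine_quadrant(1.0, 25.0) == 5    # boundaries are no-change


def test_quadrant_point_negation_symmetry(rng):
    for _ in range(200):
        fc = float(rng.uniform(-4, 4))
        md = float(rng.uniform(-80, 80))
        q, qn = ml.nine_quadrant(fc, md), ml.nine_quadrant(-fc, -md)
        assert {q, qn} in ({1, 9}, {3, 7}, {2, 8}, {4, 6}, {5},
                           ) or (q, qn) in ((5, 5),)


def test_quadrant_rejects_non_finite():
    with pytest.raises(ValueError):
        ml.nine_quadrant(float("nan"), 10.0)
    with pytest.raises(ValueError):
        ml.nine_quadrant(0.0, float("inf"))


def test_quadrant_table_merges_de_and_methylation():
    de = pd.DataFrame({"gene_id": ["a", "b", "c"], "log2fc": [2.0, -2.0, 0.0],
                       "p": [1e-5] * 3, "q": [1e-4] * 3, "is_deg": [True, True, False]})
    md = pd.DataFrame({"gene_id": ["a", "b", "c", "z"],
                       "region_kind": ["upstream2k"] * 4,
                       "meth_diff": [-30.0, -30.0, 0.0, 50.0]})
    out = ml.quadrant_table(de, md)
    got = out.set_index("gene_id")["quadrant"]
    assert got.to_dict() == {"a": 1, "b": 7, "c": 5}


# ------------------------------------------------------------------ spearman


def _levels(kinds_vals):
    return pd.DataFrame(
        [(g, k, v, 5) for k, pairs in kinds_vals.items() for g, v in pairs],
        columns=["gene_id", "region_kind", "level", "n_covered"],
    )


def test_perfect_anticorrelation_gives_minus_one():
    levels = _levels({"body": [(f"g{i}", 1.0 - i * 0.1) for i in range(5)]})
    expr = pd.Series({f"g{i}": float(i) for i in range(5)})
    out = ml.spearman_linkage(levels, expr)
    assert out.iloc[0]["rho"] == pytest.approx(-1.0)


def test_tied_ranks_match_midrank_oracle(rng):
    vals = rng.integers(0, 4, size=30).astype(float) / 4.0
    expr_vals = rng.integers(0, 5, size=30).astype(float)
    levels = _levels({"body": [(f"g{i}", vals[i]) for i in range(30)]})
    expr = pd.Series({f"g{i}": expr_vals[i] for i in range(30)})
    out = ml.spearman_linkage(levels, expr)
    assert out.iloc[0]["rho"] == pytest.approx(spearman_midrank_oracle(vals, expr_vals), rel=1e-12)


def test_independent_pairing_is_non_significant(rng):
    n = 1000
    levels = _levels({"body": [(f"g{i}", float(rng.random())) for i in range(n)]})
    expr = pd.Series({f"g{i}": float(rng.random()) for i in range(n)})
    out = ml.spearman_linkage(levels, expr)
    assert abs(out.iloc[0]["rho"]) < 0.08
    assert out.iloc[0]["p"] > 0.01


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 10**6), min_size=4, max_size=25, unique=True), st.data())
def test_monotone_transform_invariance(ints, data):
    """rho is invariant under strictly monotone transforms of either side."""
    n = len(ints)
    vals = [v / 10**6 for v in ints]
    expr_ints = data.draw(st.lists(st.integers(1, 10**6), min_size=n, max_size=n,
                                   unique=True))
    expr_vals = [v / 2000.0 for v in expr_ints]
    levels = _levels({"body": [(f"g{i}", vals[i]) for i in range(n)]})
    expr = pd.Series({f"g{i}": expr_vals[i] for i in range(n)})
    base = ml.spearman_linkage(levels, expr).iloc[0]["rho"]
    warped = ml.spearman_linkage(
        _levels({"body": [(f"g{i}", np.exp(3 * vals[i])) for i in range(n)]}),
        np.log(expr),
    ).iloc[0]["rho"]
    assert warped == pytest.approx(base, abs=1e-9)


def test_constant_vector_flagged_undefined():
    levels = _levels({"body": [("a", 0.5), ("b", 0.5), ("c", 0.5)]})
    expr = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
    out = ml.spearman_linkage(levels, expr)
    assert np.isnan(out.iloc[0]["rho"])


# ------------------------------------------------------------ class profiles


def _uniform_records(level_num, level_den, span=12_000):
    rows = [("chr1", p, "+", "CG", level_num, level_den) for p in range(0, span, 30)]
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "count_methylated", "count_total"])


def test_single_class_reduces_to_plain_profile():
    genes = [ml.GeneModel("gA", "chr1", 4000, 6000, "+")]
    rec = _uniform_records(5, 10)
    fpkm = pd.Series({"gA": 50.0})
    combined = ml.linkage_by_class(rec, genes, fpkm, 5, 5)
    plain = ml.metagene_profile(rec, genes, 5, 5)
    assert (combined["expression_class"] == "middle").all()
    assert np.allclose(combined["mean_level"], plain["mean_level"], equal_nan=True)


def test_uniform_methylation_is_class_independent():
    genes = [ml.GeneModel("gA", "chr1", 4000, 6000, "+"),
             ml.GeneModel("gB", "chr1", 14_000, 16_000, "+")]
    rec = _uniform_records(7, 10, span=20_000)
    fpkm = pd.Series({"gA": 0.5, "gB": 500.0})
    out = ml.linkage_by_class(rec, genes, fpkm, 5, 5)
    for _, grp in out.groupby("expression_class"):
        assert np.allclose(grp["mean_level"].dropna(), 0.7)


def test_planted_linkage_signs_recovered(small_config, small_annotation):
    cfg = small_config
    expr = ml.simulate_expression(cfg, small_annotation)
    fpkm_mean = expr.fpkm.mean(axis=1)
    link = ml.simulate_linkage(cfg, small_annotation, fpkm_mean)
    rec = ml.simulate_methylome(cfg, small_annotation, "F", linkage=link)
    regions = derive_all_regions(small_annotation, 2000, cfg.chromosomes)
    rho = ml.spearman_linkage(ml.gene_region_levels(rec, regions), fpkm_mean)
    rho = rho.set_index("region_kind")["rho"]
    assert rho["upstream2k"] < 0 and rho["downstream2k"] < 0
    assert rho["body"] > 0


# ----------------------------------------------------------------- DEG x DMG


def test_overlap_bookkeeping():
    de = pd.DataFrame({"gene_id": ["a", "b", "c", "d"], "is_deg": [True, True, True, False]})
    dmg = pd.DataFrame({"gene_id": ["b", "c", "z"]})
    s = ml.overlap_deg_dmg(de, dmg)
    assert s.n_deg == 3 and s.n_dmg == 3 and s.n_common == 2
    assert s.pct_of_degs == pytest.approx(100 * 2 / 3)
    assert s.common_genes == frozenset({"b", "c"})


def test_overlap_disjoint_and_subset_cases():
    de = pd.DataFrame({"gene_id": ["a", "b"], "is_deg": [True, True]})
    assert ml.overlap_deg_dmg(de, pd.DataFrame({"gene_id": ["x"]})).n_common == 0
    s = ml.overlap_deg_dmg(de, pd.DataFrame({"gene_id": ["a", "b", "c"]}))
    assert s.pct_of_degs == 100.0
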