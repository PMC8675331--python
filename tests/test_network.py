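import numpy as np
import pandas as pd
import pytest

import methylink as ml
from _oracles import tom_bruteforce
from methylink.network import (
    HubCriteria,
    NetworkParams,
    UNASSIGNED,
    eigengene_matrix,
    flag_extreme_modules,
    gene_significance,
    module_membership,
)


def _expr(x, genes=None, samples=None):
    x = np.asarray(x, dtype=float)
    genes = genes or [f"g{i}" for i in range(x.shape[0])]
    samples = samples or [f"s{i}" for i in range(x.shape[1])]
    return pd.DataFrame(x, index=genes, columns=samples)


# ---------------------------------------------------------------- adjacency


def test_adjacency_power_and_unsigned_symmetry(rng):
    t = rng.normal(size=20)
    x = _expr([t, 0.9 * t + np.sqrt(1 - 0.81) * rng.normal(size=20), -t])
    a = ml.adjacency(x, NetworkParams(power=8))
    r01 = np.corrcoef(x.iloc[0], x.iloc[1])[0, 1]
    assert a.iloc[0, 1] == pytest.approx(abs(r01) ** 8)
    assert a.iloc[0, 2] == pytest.approx(1.0)  # |cor(t, -t)| = 1
    assert a.iloc[0, 0] == 1.0


def test_adjacency_requires_three_samples_and_drops_constants(caplog):
    x = _expr([[1, 2, 3, 4], [5, 5, 5, 5], [0, 1, 0, 1]])
    with pytest.raises(ValueError):
        ml.adjacency(x.iloc[:, :2])
    with caplog.at_level("WARNING"):
        a = ml.adjacency(x)
    assert list(a.index) == ["g0", "g2"]


# ---------------------------------------------------------------------- TOM


def test_tom_two_gene_closed_form():
    for w in (0.0, 0.3, 0.7, 1.0):
        a = pd.DataFrame([[1.0, w], [w, 1.0]], index=["a", "b"], columns=["a", "b"])
        tom = ml.topological_overlap(a)
        assert tom.iloc[0, 1] == pytest.approx(w)  # (0 + w) / (w + 1 - w)


def test_tom_three_node_instances_match_bruteforce():
    a = np.array([[1.0, 0.5, 0.8], [0.5, 1.0, 0.8], [0.8, 0.8, 1.0]])
    tom = ml.topological_overlap(_adj(a))
    assert tom.iloc[0, 1] == pytest.approx(tom_bruteforce(a)[0, 1])
    # a fully connected unit-weight triangle saturates the overlap
    full = np.ones((3, 3))
    assert ml.topological_overlap(_adj(full)).iloc[0, 1] == pytest.approx(1.0)


def _adj(a):
    n = a.shape[0]
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)


def test_tom_zero_adjacency_stays_zero():
    a = np.eye(4)
    tom = ml.topological_overlap(_adj(a))
    off = tom.to_numpy()[~np.eye(4, dtype=bool)]
    assert np.allclose(off, 0.0)


def test_tom_matches_bruteforce_on_random_networks(rng):
    for n in (3, 4, 5, 6):
        for _ in range(5):
            r = rng.uniform(0, 1, size=(n, n))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = ml.topological_overlap(_adj(a)).to_numpy()
            assert np.allclose(tom, tom_bruteforce(a), atol=1e-12)


def test_tom_rejects_asymmetric_or_out_of_range():
    bad = np.array([[1.0, 0.2], [0.4, 1.0]])
    with pytest.raises(ValueError):
        ml.topological_overlap(_adj(bad))
    with pytest.raises(ValueError):
        ml.topological_overlap(_adj(np.array([[1.0, 1.5], [1.5, 1.0]])))


# ------------------------------------------------------------ module detection


def _planted_matrix(rng, sizes=(100, 100), n_noise=0, n_samples=30, r=0.8):
    rows, labels = [], []
    for mi, size in enumerate(sizes):
        f = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(np.sqrt(r) * f + np.sqrt(1 - r) * rng.normal(size=n_samples))
            labels.append(f"planted{mi + 1}")
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        labels.append(UNASSIGNED)
    x = _expr(np.array(rows))
    return x, pd.Series(labels, index=x.index)


def test_two_planted_blocks_recovered(rng):
    from sklearn.metrics import adjusted_rand_score

    x, truth = _planted_matrix(rng)
    res = ml.build_network(x, params=NetworkParams(min_module_size=50))
    assert adjusted_rand_score(truth, res.labels) >= 0.9
    assert len(res.modules) == 2


def test_small_cluster_relabelled_unassigned(rng):
    x, _ = _planted_matrix(rng, sizes=(60, 10))
    res = ml.build_network(x, params=NetworkParams(min_module_size=50))
    counts = res.labels.value_counts()
    assert counts.get("M1", 0) >= 50
    assert counts.get(UNASSIGNED, 0) >= 10
    assert len(res.modules) == 1


def test_fewer_genes_than_min_module_size_all_unassigned(rng):
    x, _ = _planted_matrix(rng, sizes=(20,))
    labels = ml.detect_modules(ml.topological_overlap(ml.adjacency(x)),
                               NetworkParams(min_module_size=50))
    assert set(labels) == {UNASSIGNED}


def test_labels_invariant_under_gene_permutation(rng):
    x, _ = _planted_matrix(rng, sizes=(60, 60), n_noise=5)
    res = ml.build_network(x, params=NetworkParams(min_module_size=50))
    perm = x.sample(frac=1.0, random_state=7)
    res_p = ml.build_network(perm, params=NetworkParams(min_module_size=50))
    joined = pd.concat([res.labels, res_p.labels.reindex(res.labels.index)], axis=1)
    # same partition (names may swap): check pairwise agreement
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(joined.iloc[:, 0], joined.iloc[:, 1]) == 1.0


# ----------------------------------------------------------------- eigengenes


def test_identical_genes_share_the_eigengene_and_unit_mm():
    profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    x = _expr([profile, profile, profile])
    eig = ml.module_eigengene(x, list(x.index))
    z = (profile - profile.mean()) / profile.std(ddof=1)
    assert np.allclose(np.abs(eig), np.abs(z / np.linalg.norm(z)))
    assert np.corrcoef(eig, profile)[0, 1] > 0.999
    labels = pd.Series(["M1"] * 3, index=x.index)
    mm = module_membership(x, labels, eigengene_matrix(x, labels))
    assert np.allclose(mm, 1.0)


def test_sign_flip_of_all_genes_does_not_flip_orientation():
    rng = np.random.default_rng(0)
    x = _expr(rng.normal(size=(5, 12)))
    eig = ml.module_eigengene(x, list(x.index))
    eig_neg = ml.module_eigengene(-x, list(x.index))
    assert np.corrcoef(eig, -eig_neg)[0, 1] > 0.999 or np.corrcoef(eig, eig_neg)[0, 1] > 0.999
    # orientation: non-negative correlation with module mean
    assert np.corrcoef(eig, x.mean(axis=0))[0, 1] >= 0


def test_two_gene_variance_share_closed_form(rng):
    """PC1 of a 2x2 correlation structure explains (1 + |rho|) / 2."""
    n = 20_000
    f = rng.normal(size=n)
    rho = 0.6
    x = _expr([f, rho * f + np.sqrt(1 - rho**2) * rng.normal(size=n)])
    z = ((x.T - x.mean(axis=1)) / x.std(axis=1, ddof=1)).T.to_numpy()
    s = np.linalg.svd(z, compute_uv=False)
    share = s[0] ** 2 / (s**2).sum()
    emp_rho = np.corrcoef(x.iloc[0], x.iloc[1])[0, 1]
    assert share == pytest.approx((1 + abs(emp_rho)) / 2, abs=1e-9)


def test_constant_module_is_an_error():
    x = _expr([[2.0, 2.0, 2.0], [7.0, 7.0, 7.0]])
    with pytest.raises(ValueError):
        ml.module_eigengene(x, list(x.index))


# ---------------------------------------------------- trait correlation & hubs


def test_module_trait_correlation_extremes(rng):
    t = rng.normal(size=10)
    eig = pd.DataFrame([t, -t, rng.normal(size=10)], index=["M1", "M2", "M3"],
                       columns=[f"s{i}" for i in range(10)])
    traits = pd.DataFrame({"length": t}, index=eig.columns)
    r, p = ml.module_trait_correlation(eig, traits)
    assert r.loc["M1", "length"] == pytest.approx(1.0)
    assert r.loc["M2", "length"] == pytest.approx(-1.0)
    assert flag_extreme_modules(r, "length") == ("M1", "M2")
    # trait orthogonalized against the (centred) eigengene ~ zero correlation
    tc = t - t.mean()
    resid = rng.normal(size=10)
    resid = resid - resid.mean()
    resid = resid - np.dot(resid, tc) / np.dot(tc, tc) * tc
    r2, _ = ml.module_trait_correlation(eig.loc[["M1"]], pd.DataFrame({"o": resid}, index=eig.columns))
    assert abs(r2.loc["M1", "o"]) < 1e-9


def test_constant_trait_flagged_undefined(rng):
    eig = pd.DataFrame([rng.normal(size=6)], index=["M1"], columns=[f"s{i}" for i in range(6)])
    traits = pd.DataFrame({"flat": np.ones(6)}, index=eig.columns)
    r, p = ml.module_trait_correlation(eig, traits)
    assert np.isnan(r.loc["M1", "flat"]) and np.isnan(p.loc["M1", "flat"])


def _toy_result():
    genes = ["a", "b", "c", "d"]
    labels = pd.Series(["M1"] * 4, index=genes)
    tom = pd.DataFrame(
        [[1.0, 0.65, 0.59, 0.70],
         [0.65, 1.0, 0.10, 0.62],
         [0.59, 0.10, 1.0, 0.20],
         [0.70, 0.62, 0.20, 1.0]],
        index=genes, columns=genes,
    )
    gs = pd.DataFrame({"length": [0.6, 0.55, 0.7, 0.52], "weight": [0.55, 0.6, 0.51, 0.53]},
                      index=genes)
    mm = pd.Series([0.95, 0.92, 0.85, 0.91], index=genes)
    res = ml.ModuleResult(labels=labels, eigengenes=pd.DataFrame(index=["M1"]), tom=tom)
    res.gene_significance = gs
    res.module_membership = mm
    return res


def test_hub_selection_joint_thresholds():
    res = _toy_result()
    crit = HubCriteria(0.50, "above", 0.90, 0.60)
    selected, edges, top = ml.select_hub_genes(res, "M1", crit)
    # c rejected on MM despite the best GS
    assert selected == ["a", "b", "d"]
    got = {tuple(sorted((r.source, r.target))) for r in edges.itertuples()}
    assert got == {("a", "b"), ("a", "d"), ("b", "d")}
    assert top == "a"  # degree ties broken by count ordering; a has max weight edges


def test_hub_edge_floor_is_strict():
    res = _toy_result()
    res.tom.loc["a", "b"] = res.tom.loc["b", "a"] = 0.60  # exactly the floor
    _, edges, _ = ml.select_hub_genes(res, "M1", HubCriteria(0.50, "above", 0.90, 0.60))
    assert ("a", "b") not in {tuple(sorted((r.source, r.target))) for r in edges.itertuples()}


def test_hub_selection_below_direction_and_empty_result():
    res = _toy_result()
    res.gene_significance = -res.gene_significance
    sel, edges, top = ml.select_hub_genes(res, "M1", HubCriteria(-0.35, "below", 0.90, 0.48))
    assert sel == ["a", "b", "d"]
    sel2, edges2, top2 = ml.select_hub_genes(res, "M1", HubCriteria(0.50, "above", 0.90, 0.60))
    assert sel2 == [] and edges2.empty and top2 is None


def test_gene_significance_is_signed(rng):
    t = rng.normal(size=15)
    x = _expr([t, -t])
    gs = gene_significance(x, pd.DataFrame({"tr": t}, index=x.columns))
    assert gs.loc["g0", "tr"] == pytest.approx(1.0)
    assert gs.loc["g1", "tr"] == pytest.approx(-1.0)
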