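"""Filtering, clustering, PSI, normalization, batch adjustment, PCs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from spliceqtl.phenotype_quant import (ClusterMap, JunctionTable,
                                       PhenotypeMatrix, batch_adjust,
                                       build_covariates, cluster_junctions,
                                       compute_psi, cpm_log2,
                                       expression_phenotypes, filter_genes,
                                       filter_junctions, phenotype_pcs,
                                       rank_inverse_normal, standardize)


def make_jt(records, counts, samples=None):
    meta = pd.DataFrame(records).set_index("junction")
    samples = samples or [f"s{i}" for i in range(np.shape(counts)[1])]
    cdf = pd.DataFrame(counts, index=meta.index, columns=samples)
    return JunctionTable(meta, cdf)


# ---------------------------------------------------------------------------
# gene filter / CPM
# ---------------------------------------------------------------------------

def test_filter_genes_boundary_and_brute_force(rng):
    n = 20
    counts = pd.DataFrame(rng.integers(0, 20, size=(30, n)),
                          index=[f"g{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(n)])
    groups = ["c1"] * 10 + ["c2"] * 10
    kept = filter_genes(counts, min_reads=5, min_frac=0.10, groups=groups)
    # brute-force double loop oracle
    expect = []
    for gname in counts.index:
        ok = True
        for grp in ("c1", "c2"):
            cols = [s for s, gr in zip(counts.columns, groups) if gr == grp]
            n_ok = sum(counts.loc[gname, s] >= 5 for s in cols)
            if n_ok / len(cols) < 0.10:
                ok = False
        if ok:
            expect.append(gname)
    assert list(kept.index) == expect


def test_filter_genes_exact_boundary():
    # 5 reads in exactly 10% of each 10-sample cohort -> kept
    counts = pd.DataFrame(np.zeros((2, 20), dtype=int),
                          index=["keep", "drop"],
                          columns=[f"s{i}" for i in range(20)])
    counts.loc["keep", ["s0", "s10"]] = 5
    counts.loc["drop", :] = 4
    kept = filter_genes(counts, groups=["a"] * 10 + ["b"] * 10)
    assert list(kept.index) == ["keep"]


def test_filter_genes_empty_group_raises():
    counts = pd.DataFrame(np.ones((2, 2), dtype=int))
    with pytest.raises(ValueError):
        filter_genes(counts, groups=["a", "a", "b"])


def test_cpm_log2_hand_oracle():
    counts = pd.DataFrame([[100, 50], [999_900, 150]], columns=["a", "b"])
    out = cpm_log2(counts, pseudocount=1.0)
    assert out.loc[0, "a"] == pytest.approx(np.log2(100 + 1))
    # doubling all counts of a sample leaves CPM unchanged
    out2 = cpm_log2(counts * 2, pseudocount=1.0)
    pd.testing.assert_frame_equal(out, out2)
    # 3x3 hand-computed oracle
    c3 = pd.DataFrame(np.arange(1, 10).reshape(3, 3))
    lib = c3.sum(axis=0)
    want = np.log2(c3 / lib * 1e6 + 1.0)
    np.testing.assert_allclose(cpm_log2(c3).to_numpy(), want.to_numpy(),
                               atol=1e-12)


# ---------------------------------------------------------------------------
# junction filter / clustering
# ---------------------------------------------------------------------------

def test_filter_junctions_boundary(rng):
    n = 20  # ceil(0.1 * 20) = 2 samples needed
    recs = [{"junction": f"j{i}", "chrom": "chr1", "intron_start": 100 + i,
             "intron_end": 200 + i, "strand": "+"} for i in range(3)]
    counts = np.zeros((3, n), dtype=int)
    counts[0, :2] = 5     # boundary: kept
    counts[1, :1] = 50    # only 1 sample: dropped
    kept = filter_junctions(make_jt(recs, counts))
    assert list(kept.counts.index) == ["j0"]


def test_cluster_shared_donor_and_long_intron():
    recs = [
        {"junction": "A", "chrom": "chr1", "intron_start": 100,
         "intron_end": 200, "strand": "+"},
        {"junction": "B", "chrom": "chr1", "intron_start": 100,
         "intron_end": 300, "strand": "+"},
        {"junction": "C", "chrom": "chr1", "intron_start": 1_000,
         "intron_end": 700_000, "strand": "+"},  # 600 kb: excluded
        {"junction": "D", "chrom": "chr1", "intron_start": 1_000,
         "intron_end": 2_000, "strand": "+"},
    ]
    counts = np.full((4, 10), 10, dtype=int)
    cm = cluster_junctions(make_jt(recs, counts))
    assert len(cm.clusters) == 1
    assert sorted(cm.clusters["cluster_0"]) == ["A", "B"]


def test_cluster_min_reads_and_singletons():
    recs = [
        {"junction": "A", "chrom": "chr1", "intron_start": 100,
         "intron_end": 200, "strand": "+"},
        {"junction": "B", "chrom": "chr1", "intron_start": 100,
         "intron_end": 300, "strand": "+"},
    ]
    cm = cluster_junctions(make_jt(recs, np.full((2, 10), 1)),
                           min_cluster_reads=30)
    assert len(cm.clusters) == 0  # total 20 < 30


def test_cluster_components_match_union_find_oracle(rng):
    """Random shared-site graph: components equal a networkx oracle."""
    import networkx as nx

    recs = []
    sites = list(range(10))
    for i in range(25):
        a, b = sorted(rng.choice(sites, 2, replace=False))
        recs.append({"junction": f"j{i}", "chrom": "chr1",
                     "intron_start": 1_000 + a * 100,
                     "intron_end": 1_000 + b * 100 + 50, "strand": "+"})
    counts = np.full((25, 5), 20, dtype=int)
    cm = cluster_junctions(make_jt(recs, counts), min_cluster_reads=0)
    G = nx.Graph()
    for r in recs:
        G.add_node(r["junction"])
    for i, r in enumerate(recs):
        for s in recs[i + 1:]:
            if (r["intron_start"] == s["intron_start"]
                    or r["intron_end"] == s["intron_end"]
                    or r["intron_start"] == s["intron_end"]
                    or r["intron_end"] == s["intron_start"]):
                G.add_edge(r["junction"], s["junction"])
    want = sorted(sorted(c) for c in nx.connected_components(G) if len(c) >= 2)
    got = sorted(sorted(js) for js in cm.clusters.values())
    assert got == want


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def _psi_fixture(counts):
    recs = [{"junction": f"j{i}", "chrom": "chr1",
             "intron_start": 100, "intron_end": 200 + i * 100, "strand": "+"}
            for i in range(np.shape(counts)[0])]
    jt = make_jt(recs, counts)
    cm = cluster_junctions(jt, min_cluster_reads=0)
    return jt, cm


def test_psi_simple_ratio_and_zero_total():
    counts = np.array([[30, 0, 8], [10, 0, 2]])
    jt, cm = _psi_fixture(counts)
    psi = compute_psi(jt, cm, max_missing_frac=0.5)
    assert psi.values.loc["j0", "s0"] == pytest.approx(0.75)
    assert psi.values.loc["j1", "s0"] == pytest.approx(0.25)
    assert np.isnan(psi.values.loc["j0", "s1"])  # total 0 -> missing, not 0


def test_psi_sums_to_one_and_scale_invariance(rng):
    counts = rng.integers(1, 50, size=(4, 12))
    jt, cm = _psi_fixture(counts)
    psi = compute_psi(jt, cm)
    sums = psi.values.sum(axis=0)
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)
    # multiplying one sample's counts by a constant leaves PSI unchanged
    scaled = counts.copy()
    scaled[:, 0] *= 7
    jt2, cm2 = _psi_fixture(scaled)
    psi2 = compute_psi(jt2, cm2)
    np.testing.assert_allclose(psi2.values.to_numpy(), psi.values.to_numpy(),
                               atol=1e-12)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_rank_int_closed_form_n5():
    x = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
    out = rank_inverse_normal(x)
    want = norm.ppf((np.array([3, 1, 2, 5, 4]) - 0.5) / 5)
    np.testing.assert_allclose(out, want, atol=1e-12)


def test_standardize_moments_and_rank_invariance(rng):
    vals = rng.normal(size=(3, 200))
    pm = PhenotypeMatrix(
        pd.DataFrame(vals, index=list("abc"),
                     columns=[f"s{i}" for i in range(200)]),
        pd.DataFrame({"chrom": "chr1", "start": 1, "end": 2, "cluster": ""},
                     index=list("abc")), "splicing")
    out = standardize(pm)
    assert np.allclose(out.values.mean(axis=1), 0, atol=1e-6)
    assert np.allclose(out.values.std(axis=1), 1, atol=0.02)
    # monotone transform of input -> identical output
    pm2 = PhenotypeMatrix(np.exp(pm.values * 0.5), pm.anchors, "splicing")
    out2 = standardize(pm2)
    np.testing.assert_allclose(out2.values.to_numpy(),
                               out.values.to_numpy(), atol=1e-12)


# ---------------------------------------------------------------------------
# batch adjustment
# ---------------------------------------------------------------------------

def test_batch_adjust_removes_offsets(rng):
    n = 100
    base = rng.normal(size=(5, 2 * n))
    base[:, n:] += 1.0
    batches = ["A"] * n + ["B"] * n
    pm = PhenotypeMatrix(
        pd.DataFrame(base, columns=[f"s{i}" for i in range(2 * n)]),
        pd.DataFrame({"chrom": "chr1", "start": 1, "end": 2, "cluster": ""},
                     index=range(5)), "splicing")
    out = batch_adjust(pm, batches)
    diff = (out.values.iloc[:, :n].mean(axis=1)
            - out.values.iloc[:, n:].mean(axis=1))
    assert np.abs(diff).max() < 1e-10
    # residual batch R^2 below 1% (ANOVA oracle)
    for row in out.values.to_numpy():
        grand = row.mean()
        ss_b = n * ((row[:n].mean() - grand) ** 2
                    + (row[n:].mean() - grand) ** 2)
        ss_t = ((row - grand) ** 2).sum()
        assert ss_b / ss_t < 0.01


def test_batch_adjust_single_batch_is_centering_only(rng):
    vals = rng.normal(size=(2, 50))
    pm = PhenotypeMatrix(
        pd.DataFrame(vals, columns=[f"s{i}" for i in range(50)]),
        pd.DataFrame({"chrom": "chr1", "start": 1, "end": 2, "cluster": ""},
                     index=range(2)), "splicing")
    out = batch_adjust(pm, ["A"] * 50)
    np.testing.assert_allclose(out.values.to_numpy(), vals, atol=1e-10)


# ---------------------------------------------------------------------------
# phenotype PCs / covariates
# ---------------------------------------------------------------------------

def _pm(vals):
    return PhenotypeMatrix(
        pd.DataFrame(vals, columns=[f"s{i}" for i in range(vals.shape[1])]),
        pd.DataFrame({"chrom": "chr1", "start": 1, "end": 2, "cluster": ""},
                     index=range(vals.shape[0])), "expression")


def test_pcs_rank_one_matrix(rng):
    u = rng.normal(size=20)
    v = rng.normal(size=50)
    vals = np.outer(u, v) + rng.normal(scale=1e-6, size=(20, 50))
    pcs = phenotype_pcs(_pm(vals), 2)
    var = pcs.var(axis=0)
    assert var["PC1"] / var.sum() > 0.999


def test_pcs_match_eigendecomposition_oracle(rng):
    vals = rng.normal(size=(10, 40))
    pcs = phenotype_pcs(_pm(vals), 3).to_numpy()
    Z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1,
                                                            keepdims=True)
    evals, evecs = np.linalg.eigh(Z @ Z.T)
    order = np.argsort(evals)[::-1][:3]
    scores = Z.T @ evecs[:, order]
    for c in range(3):
        got, want = pcs[:, c], scores[:, c]
        if np.dot(got, want) < 0:
            want = -want
        np.testing.assert_allclose(got, want, atol=1e-8)


def test_pcs_k_exceeding_rank_raises(rng):
    vals = np.vstack([rng.normal(size=30)] * 3)  # rank 1 after scaling
    with pytest.raises(ValueError):
        phenotype_pcs(_pm(vals), 3)


def test_build_covariates_drops_collinear_and_expands_batch():
    pcs = pd.DataFrame({"PC1": [1.0, 2, 3, 4]}, index=list("abcd"))
    dup = pd.DataFrame({"PC1_copy": [2.0, 4, 6, 8]}, index=list("abcd"))
    batch = pd.Series(["x", "x", "y", "y"], index=list("abcd"), name="batch")
    cov = build_covariates(pcs, dup, batch)
    assert "PC1" in cov.columns and "PC1_copy" not in cov.columns
    assert any(c.startswith("batch_") for c in cov.columns)
    assert np.linalg.matrix_rank(np.column_stack(
        [np.ones(4), cov.to_numpy()])) == cov.shape[1] + 1
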