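"""Generators: LD structure, planted-effect recovery, determinism, annotations."""

import numpy as np
import pandas as pd
import pytest

from spliceqtl.core_io import pearson_r2
from spliceqtl.synthetic_data import (SimConfig, simulate_annotations,
                                      simulate_expression, simulate_genotypes,
                                      simulate_gwas, simulate_gwas_locus,
                                      simulate_junction_counts)


def cfg(**kw) -> SimConfig:
    base = dict(n_samples=500, n_chrom=1, n_blocks_per_chrom=5, block_size=10,
                within_block_rho=0.9, variant_spacing=1_000,
                block_spacing=100_000, chrom_len=1_000_000, seed=1)
    base.update(kw)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def test_genotypes_deterministic():
    g1 = simulate_genotypes(cfg())
    g2 = simulate_genotypes(cfg())
    np.testing.assert_array_equal(g1.dosage, g2.dosage)
    assert [v.id for v in g1.variants] == [v.id for v in g2.variants]


def test_rho_zero_gives_independence():
    g = simulate_genotypes(cfg(within_block_rho=0.0, n_blocks_per_chrom=10))
    rng = np.random.default_rng(0)
    r2s = []
    for _ in range(100):
        i, j = rng.choice(g.n_variants, 2, replace=False)
        r2s.append(pearson_r2(g.dosage[:, i], g.dosage[:, j]))
    assert np.nanmean(r2s) < 0.05


def test_adjacent_pair_r2_tracks_rho_squared():
    """Adjacent dosage correlation equals the haplotype copy rate rho."""
    g = simulate_genotypes(cfg(within_block_rho=0.95))
    r2s = [pearson_r2(g.dosage[:, j], g.dosage[:, j + 1])
           for j in range(9)]  # first block's adjacent pairs
    assert np.mean(r2s) > 0.5
    assert np.mean(r2s) == pytest.approx(0.95 ** 2, abs=0.1)


def test_realized_mafs_within_range():
    g = simulate_genotypes(cfg(maf_range=(0.2, 0.4)))
    mafs = np.array([v.maf for v in g.variants])
    assert (mafs > 0.1).all() and (mafs <= 0.5).all()


# ---------------------------------------------------------------------------
# junction counts
# ---------------------------------------------------------------------------

def test_junction_counts_deterministic_and_null_slope():
    c = cfg(n_clusters=10, junctions_per_cluster=3, cluster_depth=200)
    g = simulate_genotypes(c)
    t1, _ = simulate_junction_counts(g, c, batch_logit_offset=0.0)
    t2, _ = simulate_junction_counts(g, c, batch_logit_offset=0.0)
    pd.testing.assert_frame_equal(t1, t2)
    # null: genotype-PSI slope centered at 0 across clusters
    slopes = []
    for cl in range(10):
        rows = t1[t1["junction"].str.startswith(f"clu{cl}_")]
        counts = rows[g.samples].to_numpy(dtype=float)
        psi = counts[0] / np.maximum(counts.sum(axis=0), 1)
        dos = g.dosage[:, 0]
        slopes.append(np.polyfit(dos, psi, 1)[0])
    assert abs(np.mean(slopes)) < 0.02


def test_junction_effect_matches_softmax_prediction():
    """Planted logit effect shifts PSI by the closed-form softmax amount."""
    c = cfg(n_samples=400, n_clusters=2, junctions_per_cluster=2,
            cluster_depth=500)
    g = simulate_genotypes(c)
    vid = g.variants[5].id
    eff = pd.DataFrame([{"cluster": 0, "junction": 0, "variant": vid,
                         "beta": 1.0}])
    table, truth = simulate_junction_counts(g, c, eff, batch_logit_offset=0.0)
    assert len(truth.sqtl) == 1
    rows = table[table["junction"].str.startswith("clu0_")]
    counts = rows[g.samples].to_numpy(dtype=float)
    psi0 = counts[0] / counts.sum(axis=0)
    dos = g.column(vid)
    # closed-form oracle: E PSI(d) = sigmoid(logit_gap + beta d)
    rng = np.random.default_rng(c.seed + 1)
    base = rng.normal(0.0, 1.0, size=2)  # same stream position as generator
    gap = base[0] - base[1]
    for d in (0, 2):
        sel = dos == d
        if sel.sum() < 10:
            continue
        pred = 1.0 / (1.0 + np.exp(-(gap + 1.0 * d)))
        assert np.mean(psi0[sel]) == pytest.approx(pred, abs=0.05)


def test_junction_effect_on_missing_target_raises():
    c = cfg(n_clusters=2, junctions_per_cluster=2)
    g = simulate_genotypes(c)
    bad = pd.DataFrame([{"cluster": 5, "junction": 0,
                         "variant": g.variants[0].id, "beta": 1.0}])
    with pytest.raises(ValueError):
        simulate_junction_counts(g, c, bad)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def test_expression_recovers_planted_slope():
    c = cfg(n_samples=300, n_genes=3, maf_range=(0.3, 0.4))
    g = simulate_genotypes(c)
    vid = g.variants[10].id
    eff = pd.DataFrame([{"gene": 0, "variant": vid, "beta": 0.8}])
    counts, genes, truth = simulate_expression(g, c, eff,
                                               batch_log2_offset=0.0)
    assert list(truth.eqtl["feature"]) == ["gene0"]
    y = np.log2(counts.loc["gene0"].to_numpy(dtype=float) + 1)
    dos = g.column(vid)
    slope = np.polyfit(dos, y, 1)[0]
    assert slope == pytest.approx(0.8, abs=0.15)
    # null gene slope centered at zero
    y1 = np.log2(counts.loc["gene1"].to_numpy(dtype=float) + 1)
    assert abs(np.polyfit(dos, y1, 1)[0]) < 0.2


def test_expression_batch_offset_visible_then_removable():
    from spliceqtl.phenotype_quant import (PhenotypeMatrix, batch_adjust,
                                           expression_phenotypes)
    c = cfg(n_samples=400, n_genes=5)
    g = simulate_genotypes(c)
    counts, genes, truth = simulate_expression(g, c, batch_log2_offset=1.0)
    batches = np.array(c.batches())
    y = np.log2(counts.to_numpy(dtype=float) + 1)
    diff = y[:, batches == "A"].mean() - y[:, batches == "B"].mean()
    assert abs(abs(diff) - 1.0) < 0.2
    pm = expression_phenotypes(pd.DataFrame(y, index=counts.index,
                                            columns=counts.columns), genes)
    adj = batch_adjust(pm, batches)
    resid = (adj.values.loc[:, batches == "A"].mean(axis=1)
             - adj.values.loc[:, batches == "B"].mean(axis=1))
    assert np.abs(resid).max() < 0.05


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def test_gwas_null_locus_max_z_modest(small_panel):
    rng = np.random.default_rng(3)
    vids = [v.id for v in small_panel.variants]
    n_big = 0
    for _ in range(20):
        gw = simulate_gwas_locus(small_panel, vids, None, 0.0, 10_000, rng)
        if np.abs(gw.table["z"]).max() >= 4:
            n_big += 1
    assert n_big <= 1


def test_gwas_perfect_proxy_shares_mean(small_panel):
    """A variant in near-perfect LD inherits the causal mean via R @ lam."""
    rng = np.random.default_rng(4)
    vids = [v.id for v in small_panel.variants[:10]]  # one block
    causal = vids[5]
    n, beta = 40_000, 8.0 / np.sqrt(40_000)
    zs = []
    for _ in range(200):
        gw = simulate_gwas_locus(small_panel, vids, causal, beta, n, rng)
        zs.append(gw.table.set_index("id").loc[causal, "z"])
    # lead z distribution matches N(lambda_c, 1)
    assert np.mean(zs) == pytest.approx(8.0, abs=0.3)
    assert np.std(zs) == pytest.approx(1.0, abs=0.25)


def test_gwas_z_beta_se_consistency(small_panel):
    rng = np.random.default_rng(5)
    vids = [v.id for v in small_panel.variants[:10]]
    gw = simulate_gwas_locus(small_panel, vids, vids[0], 0.03, 10_000, rng)
    t = gw.table
    np.testing.assert_allclose(t["z"], t["beta"] / t["se"], rtol=1e-9)


def test_simulate_gwas_truth_labels(small_panel):
    locus_spec = pd.DataFrame([
        {"locus": "L1", "causal": small_panel.variants[3].id, "beta": 0.03,
         "n": 10_000, "sharing": "shared"},
        {"locus": "L0", "causal": "", "beta": 0.0, "n": 10_000,
         "sharing": "null"},
    ])
    tables, truth = simulate_gwas(small_panel, locus_spec, seed=9)
    assert set(tables) == {"L1", "L0"}
    assert truth.gwas.set_index("locus").loc["L1", "sharing"] == "shared"
    assert (truth.to_frame()["kind"] == "gwas").all()


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _toy_junctions():
    return pd.DataFrame([
        {"junction": "j1", "chrom": "chr1", "intron_start": 3_000,
         "intron_end": 5_000, "strand": "+"},
        {"junction": "j2", "chrom": "chr1", "intron_start": 3_000,
         "intron_end": 7_000, "strand": "+"},
    ])


def test_annotation_classes_mutually_exclusive():
    c = cfg(n_chrom=1)
    tracks = simulate_annotations(c, _toy_junctions())
    genic = ["splice_site", "exon", "intron", "promoter"]
    for i, a in enumerate(genic):
        for b in genic[i + 1:]:
            for iv in tracks[a]:
                assert not tracks[b].overlapping(iv), (a, b, iv)


def test_splice_sites_cover_junction_boundaries():
    c = cfg(n_chrom=1)
    jt = _toy_junctions()
    tracks = simulate_annotations(c, jt)
    for _, r in jt.iterrows():
        for pos in (r["intron_start"], r["intron_end"]):
            assert tracks["splice_site"].covers_pos(r["chrom"], int(pos))


def test_annotation_intervals_match_per_base_labelling():
    """Interval arithmetic agrees with brute-force per-base labels on 10 kb."""
    c = cfg(n_chrom=1)
    tracks = simulate_annotations(c, _toy_junctions())
    genic = ["splice_site", "exon", "intron", "promoter"]
    for pos in range(1, 10_001):
        labels = [name for name in genic
                  if tracks[name].covers_pos("chr1", pos)]
        assert len(labels) <= 1, (pos, labels)
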