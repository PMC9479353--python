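"""Nominal scan, permutation pass, beta approximation, Storey q, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from spliceqtl import cis_qtl
from spliceqtl.cis_qtl import (add_qvalues_and_thresholds, call_significant,
                               cis_window, compare_sqtl_eqtl, delta_psi,
                               fit_beta_mle, genomewide_threshold_pt,
                               nominal_scan, nominal_threshold_per_feature,
                               permutation_pass, permutation_pass_all,
                               storey_qvalues)
from spliceqtl.core_io import GenotypeMatrix, Variant
from spliceqtl.phenotype_quant import PhenotypeMatrix


def make_pm(values, anchors, kind="expression"):
    return PhenotypeMatrix(values, anchors, kind)


def panel_and_pheno(rng, n=200, m=15, beta=0.0, causal=None):
    causal = min(m - 1, 5) if causal is None else causal
    variants = [Variant(f"v{j}", "chr1", 1_000 + j * 100, "A", "G")
                for j in range(m)]
    dosage = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    g = GenotypeMatrix(variants, [f"s{i}" for i in range(n)], dosage)
    y = beta * dosage[:, causal] + rng.normal(size=n)
    pm = make_pm(pd.DataFrame([y], index=["f"], columns=g.samples),
                 pd.DataFrame({"chrom": ["chr1"], "start": [1_500],
                               "end": [1_500], "cluster": [""]}, index=["f"]))
    return g, pm


# ---------------------------------------------------------------------------
# cis windows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("args, want", [
    (("chr1", 1_000_000, 1_000_000, "expression"),
     ("chr1", 500_000, 1_500_000)),
    (("chr1", 100_000, 101_000, "splicing"), ("chr1", 50_000, 151_000)),
    (("chr1", 10_000, 10_000, "expression"), ("chr1", 1, 510_000)),
])
def test_cis_window(args, want):
    assert cis_window(*args) == want


# ---------------------------------------------------------------------------
# nominal scan
# ---------------------------------------------------------------------------

def test_nominal_identity_phenotype(rng):
    g, pm = panel_and_pheno(rng)
    pm.values.loc["f"] = g.dosage[:, 3]  # phenotype == dosage
    out = nominal_scan(pm, g, None, "f").set_index("variant")
    assert out.loc["v3", "slope"] == pytest.approx(1.0, abs=1e-10)
    assert out.loc["v3", "p"] < 1e-100


def test_nominal_matches_full_multiple_regression(rng):
    """Frisch-Waugh: residual-on-residual equals the full OLS fit."""
    import statsmodels.api as sm

    n = 20
    g, pm = panel_and_pheno(rng, n=n, m=4, beta=0.5, causal=1)
    cov = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)},
                       index=g.samples)
    out = nominal_scan(pm, g, cov, "f").set_index("variant")
    y = pm.values.loc["f"].to_numpy()
    for j in range(4):
        X = sm.add_constant(np.column_stack([g.dosage[:, j],
                                             cov.to_numpy()]))
        fit = sm.OLS(y, X).fit()
        vid = f"v{j}"
        assert out.loc[vid, "slope"] == pytest.approx(fit.params[1], abs=1e-8)
        assert out.loc[vid, "t"] == pytest.approx(fit.tvalues[1], abs=1e-8)
        assert out.loc[vid, "p"] == pytest.approx(fit.pvalues[1], abs=1e-8)


def test_nominal_null_p_uniform(rng):
    """Permuted phenotypes give approximately uniform nominal p-values."""
    ps = []
    for _ in range(60):
        g, pm = panel_and_pheno(rng, n=100, m=1)
        ps.extend(nominal_scan(pm, g, None, "f")["p"])
    stat, p = stats.kstest(ps, "uniform")
    assert p > 0.01


def test_nominal_skips_monomorphic(rng):
    g, pm = panel_and_pheno(rng, m=3)
    g.dosage[:, 0] = 2.0
    out = nominal_scan(pm, g, None, "f")
    assert "v0" not in set(out["variant"])


# ---------------------------------------------------------------------------
# beta fit / permutation pass
# ---------------------------------------------------------------------------

def test_beta_fit_best_of_m_uniform(rng):
    """Best of M independent uniforms ~ Beta(1, M): b recovered within 25%."""
    M = 40
    x = rng.random((1_000, M)).min(axis=1)
    a, b, conv = fit_beta_mle(x)
    assert conv
    assert a == pytest.approx(1.0, abs=0.25)
    assert b == pytest.approx(M, rel=0.25)


def test_permutation_empirical_p_formula(rng):
    g, pm = panel_and_pheno(rng, n=300, m=10, beta=1.0)
    rec = permutation_pass(pm, g, None, "f", B=500, seed=1)
    # strong effect: observed best p below every permutation minimum
    assert rec["p_empirical"] == pytest.approx(1 / 501)
    assert rec["lead"] == "v5"
    assert 0 < rec["p_beta"] < 1


def test_permutation_beta_b_tracks_window_size(rng):
    """Independent null variants: fitted beta_b ~ M (a ~ 1)."""
    bs = []
    for k in range(8):
        g, pm = panel_and_pheno(rng, n=250, m=20)
        rec = permutation_pass(pm, g, None, "f", B=1000, seed=k)
        bs.append(rec["beta_b"])
    assert np.mean(bs) == pytest.approx(20, rel=0.25)


def test_permutation_p_beta_rank_agrees_with_empirical(rng):
    """p_beta and p_empirical agree in rank over many simulated features."""
    recs = []
    for k in range(100):
        beta = 0.35 if k < 30 else 0.0
        g, pm = panel_and_pheno(rng, n=120, m=8, beta=beta)
        recs.append(permutation_pass(pm, g, None, "f", B=150, seed=k))
    df = pd.DataFrame(recs)
    rho = stats.spearmanr(df["p_beta"], df["p_empirical"]).statistic
    assert rho > 0.95
    assert (df["p_beta"] > 0).all()


def test_permutation_deterministic_per_feature_seed(rng):
    g, pm = panel_and_pheno(rng, n=100, m=5, beta=0.4)
    r1 = permutation_pass(pm, g, None, "f", B=200, seed=3)
    r2 = permutation_pass(pm, g, None, "f", B=200, seed=3)
    assert r1 == r2


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def test_storey_all_ones():
    q, pi0 = storey_qvalues(np.ones(10))
    np.testing.assert_allclose(q, 1.0)


def test_storey_pi0_one_equals_bh():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(11)
    p = rng.random(200)  # null-ish: pi0 estimate near 1 but clip at 1
    q, pi0 = storey_qvalues(p)
    bh = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(q, bh * pi0, atol=1e-12)


def test_storey_brute_force_oracle(rng):
    p = rng.random(50) ** 2
    q, pi0 = storey_qvalues(p, lam=0.5)
    m = len(p)
    pi0_want = min(max(np.sum(p > 0.5) / (0.5 * m), 1 / m), 1.0)
    assert pi0 == pytest.approx(pi0_want, abs=1e-12)
    order = np.argsort(p)
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    for i in range(m):
        cand = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i] - 1e-15]
        want = min(1.0, pi0_want * min(cand))
        assert q[i] == pytest.approx(want, abs=1e-12)


def test_storey_monotone_in_p(rng):
    p = rng.random(100)
    q, _ = storey_qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def test_pt_closest_to_fdr():
    perm = pd.DataFrame({"q": [0.005, 0.009, 0.012],
                         "p_beta": [1e-5, 2e-5, 3e-5]})
    assert genomewide_threshold_pt(perm, 0.01) == 2e-5
    perm2 = pd.DataFrame({"q": [0.02], "p_beta": [5e-4]})
    assert genomewide_threshold_pt(perm2, 0.01) == 5e-4


def test_pt_brute_force(rng):
    q = rng.random(30) * 0.05
    perm = pd.DataFrame({"q": q, "p_beta": rng.random(30) * 1e-3})
    got = genomewide_threshold_pt(perm, 0.01)
    best = min(range(30), key=lambda i: (abs(q[i] - 0.01),
                                         perm["p_beta"][i]))
    assert got == perm["p_beta"][best]


def test_nominal_threshold_closed_forms():
    assert nominal_threshold_per_feature(0.01, 1.0, 1.0) == pytest.approx(0.01)
    b = 25.0
    want = 1 - (1 - 0.01) ** (1 / b)
    assert nominal_threshold_per_feature(0.01, 1.0, b) == pytest.approx(
        want, rel=1e-10)
    # round trip through the CDF
    thr = nominal_threshold_per_feature(0.01, 1.3, 17.0)
    assert special.betainc(1.3, 17.0, thr) == pytest.approx(0.01, abs=1e-10)


# ---------------------------------------------------------------------------
# calls / delta-PSI / sharing
# ---------------------------------------------------------------------------

def test_call_significant_threshold_and_pairs(rng):
    g, pm = panel_and_pheno(rng, n=300, m=10, beta=1.0)
    pm2 = PhenotypeMatrix(
        pd.concat([pm.values,
                   pd.DataFrame([rng.normal(size=300)], index=["null"],
                                columns=g.samples)]),
        pd.concat([pm.anchors,
                   pm.anchors.rename(index={"f": "null"})]), "expression")
    perm = permutation_pass_all(pm2, g, None, B=300, seed=5)
    perm = add_qvalues_and_thresholds(perm, fdr=0.05)
    nominal = {f: nominal_scan(pm2, g, None, f) for f in pm2.features}
    calls = call_significant(perm, nominal, fdr=0.05)
    assert "f" in calls.features
    # every nominal pair sits below its feature threshold (brute force)
    thr = dict(zip(perm["feature"], perm["nominal_threshold"]))
    for _, row in calls.nominal_pairs.iterrows():
        assert row["p"] <= thr[row["feature"]]
    # non-significant features contribute no pairs
    assert set(calls.nominal_pairs["feature"]) <= set(calls.features)


def test_degenerate_feature_reported_not_dropped(rng):
    g, pm = panel_and_pheno(rng, m=3)
    far = pm.anchors.copy()
    far["chrom"] = "chrX"  # no cis variants at all
    pm_far = PhenotypeMatrix(pm.values, far, "expression")
    perm = permutation_pass_all(pm_far, g, None, B=100, seed=0)
    perm = add_qvalues_and_thresholds(perm)
    assert len(perm) == 1 and perm["n_variants"][0] == 0
    assert perm["q"][0] == pytest.approx(1.0, abs=1e-6)


def test_delta_psi_hand_arithmetic():
    psi = pd.Series([0.1, 0.2, 0.5, 0.6, 0.35, 0.45])
    dos = np.array([0, 0, 2, 2, 1, 1])
    assert delta_psi(psi, dos) == pytest.approx(0.55 - 0.15)
    # without hom-alt samples, heterozygotes substitute
    dos2 = np.array([0, 0, 1, 1, 1, 1])
    assert delta_psi(psi, dos2) == pytest.approx(np.median([0.5, 0.6, 0.35,
                                                            0.45]) - 0.15)
    assert delta_psi(pd.Series([0.3, 0.3]), np.array([0, 2])) == 0.0


def test_compare_sqtl_eqtl_classification(small_panel):
    """Same lead -> shared; leads in different LD blocks -> independent."""
    perm_cols = ["feature", "lead", "q", "p_beta", "nominal_threshold"]
    lead_a = small_panel.variants[3].id   # block 0
    lead_b = small_panel.variants[45].id  # block 4
    sqtl = cis_qtl.QtlCallSet(
        pd.DataFrame([["j1", lead_a, 0.001, 1e-5, 1e-3],
                      ["j2", lead_a, 0.001, 1e-5, 1e-3]], columns=perm_cols),
        pd.DataFrame(columns=["feature", "variant", "pos", "slope", "se",
                              "t", "p"]))
    eqtl = cis_qtl.QtlCallSet(
        pd.DataFrame([["g1", lead_a, 0.001, 1e-5, 1e-3],
                      ["g2", lead_b, 0.001, 1e-5, 1e-3]], columns=perm_cols),
        pd.DataFrame(columns=["feature", "variant", "pos", "slope", "se",
                              "t", "p"]))
    mapping = {"j1": "g1", "j2": "g2"}
    out = compare_sqtl_eqtl(sqtl, eqtl, small_panel, mapping).set_index("gene")
    assert out.loc["g1", "r2"] == pytest.approx(1.0)
    assert not out.loc["g1", "independent"]
    assert out.loc["g2", "r2"] < 0.2 and out.loc["g2", "independent"]


def test_type_one_error_on_null_features(rng):
    """Fully null panel: essentially nothing called at q <= 0.01."""
    n_feat = 60
    vals, anchors = [], []
    g, _ = panel_and_pheno(rng, n=150, m=10)
    for i in range(n_feat):
        vals.append(rng.normal(size=150))
    pm = PhenotypeMatrix(
        pd.DataFrame(vals, index=[f"f{i}" for i in range(n_feat)],
                     columns=g.samples),
        pd.DataFrame({"chrom": "chr1", "start": 1_500, "end": 1_500,
                      "cluster": ""}, index=[f"f{i}" for i in range(n_feat)]),
        "expression")
    perm = permutation_pass_all(pm, g, None, B=200, seed=2)
    perm = add_qvalues_and_thresholds(perm, fdr=0.01)
    assert (perm["q"] <= 0.01).sum() <= 1
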