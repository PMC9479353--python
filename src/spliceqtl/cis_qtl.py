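"""cis-QTL mapping: nominal scan, permutation pass with beta approximation,
Storey q-values, hierarchical nominal thresholds, and effect summaries.

The association model regresses a (standardized) phenotype on a dosage
column with covariates. Both phenotype and dosages are residualized on the
covariates (with intercept) first; by Frisch-Waugh the slope, t and p of
the residual-on-residual simple regression equal those of the full
multiple regression, with df = n - n_cov - 2.

The permutation pass permutes the covariate-residualized phenotype B times
(genotypes and covariates fixed), records the best nominal p per
permutation, and fits a Beta(a, b) distribution to those minima by maximum
likelihood; the beta-approximated empirical p-value
``p_beta = BetaCDF(p_best; a, b)`` interpolates below the 1/(B+1)
resolution of the raw empirical p-value ``(r + 1)/(B + 1)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_io import GenotypeMatrix, pearson_r2
from .phenotype_quant import PhenotypeMatrix

PERM_COLUMNS = ["feature", "n_variants", "lead", "slope", "p_nominal_best",
                "p_empirical", "beta_a", "beta_b", "p_beta", "mle_converged"]


# ---------------------------------------------------------------------------
# windows and residualization
# ---------------------------------------------------------------------------

def cis_window(anchor_chrom: str, anchor_start: int, anchor_end: int,
               kind: str, window_e: int = 500_000, window_s: int = 50_000,
               ) -> tuple[str, int, int]:
    """cis-window around a feature anchor (1-based inclusive bounds).

    Expression: TSS +/- 500 kb. Splicing: junction interval +/- 50 kb.
    The start is clipped at position 1.
    """
    w = window_e if kind == "expression" else window_s
    return anchor_chrom, max(1, anchor_start - w), anchor_end + w


def _design(cov: pd.DataFrame | None, n: int) -> np.ndarray:
    if cov is None or cov.shape[1] == 0:
        return np.ones((n, 1))
    X = np.column_stack([np.ones(n), cov.to_numpy(dtype=float)])
    return X


def residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on the design X (least squares)."""
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


@dataclass
class _Prepared:
    y_res: np.ndarray       # residualized phenotype, n
    G_res: np.ndarray       # residualized dosages, n x M
    variant_ids: list[str]
    positions: np.ndarray
    df: int
    n_cov: int


def _prepare(pm: PhenotypeMatrix, g: GenotypeMatrix,
             cov: pd.DataFrame | None, feature: str,
             window_e: int = 500_000, window_s: int = 50_000,
             ) -> _Prepared | None:
    """Residualize phenotype and cis-window dosages; None if no variant."""
    anc = pm.anchors.loc[feature]
    chrom, lo, hi = cis_window(anc["chrom"], int(anc["start"]),
                               int(anc["end"]), pm.kind, window_e, window_s)
    idx = g.window_indices(chrom, lo, hi)
    y = pm.values.loc[feature].reindex(g.samples).to_numpy(dtype=float)
    if np.isnan(y).any():
        y = np.where(np.isnan(y), np.nanmean(y), y)
    n = len(y)
    X = _design(cov, n)
    n_cov = X.shape[1] - 1
    if n < n_cov + 10 + 2:
        raise ValueError("too few samples for the covariate model")
    G = g.dosage[:, idx].copy()
    col_mean = np.nanmean(G, axis=0) if G.size else np.empty(0)
    if G.size:
        miss = np.where(np.isnan(G))
        G[miss] = np.take(col_mean, miss[1])
    keep = [k for k in range(G.shape[1]) if np.std(G[:, k]) > 0]
    if not keep:
        return None
    G = G[:, keep]
    vids = [g.variants[idx[k]].id for k in keep]
    pos = np.array([g.variants[idx[k]].pos for k in keep])
    return _Prepared(residualize(y[:, None], X)[:, 0], residualize(G, X),
                     vids, pos, df=n - n_cov - 2, n_cov=n_cov)


def _corr_to_t_p(r: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, np.clip(p, 5e-324, 1.0)


# ---------------------------------------------------------------------------
# nominal scan
# ---------------------------------------------------------------------------

def nominal_scan(pm: PhenotypeMatrix, g: GenotypeMatrix,
                 cov: pd.DataFrame | None, feature: str,
                 window_e: int = 500_000, window_s: int = 50_000,
                 ) -> pd.DataFrame:
    """Nominal associations of one feature against all cis-window variants.

    Returns columns feature, variant, pos, slope, se, t, p. Zero-variance
    dosage columns are skipped.
    """
    prep = _prepare(pm, g, cov, feature, window_e, window_s)
    if prep is None:
        return pd.DataFrame(columns=["feature", "variant", "pos", "slope",
                                     "se", "t", "p"])
    y, G = prep.y_res, prep.G_res
    sy = np.sqrt((y ** 2).sum())
    sg = np.sqrt((G ** 2).sum(axis=0))
    r = (G.T @ y) / (sg * sy)
    t, p = _corr_to_t_p(r, prep.df)
    slope = r * sy / sg
    with np.errstate(divide="ignore", invalid="ignore"):
        se = slope / t
        se = np.where(t == 0, np.nan, se)
    return pd.DataFrame({"feature": feature, "variant": prep.variant_ids,
                         "pos": prep.positions, "slope": slope, "se": se,
                         "t": t, "p": p})


# ---------------------------------------------------------------------------
# beta fit
# ---------------------------------------------------------------------------

def fit_beta_mle(x: np.ndarray, tol: float = 1e-8, max_iter: int = 200,
                 ) -> tuple[float, float, bool]:
    """Fit Beta(a, b) to values in (0, 1) by maximum likelihood.

    Optimizes the negative log-likelihood over (log a, log b) from a
    method-of-moments start; on failure the method-of-moments estimate is
    returned with ``converged=False``.
    """
    x = np.clip(np.asarray(x, dtype=float), 1e-300, 1 - 1e-16)
    m, v = x.mean(), x.var()
    v = max(v, 1e-12)
    common = m * (1 - m) / v - 1
    a0 = max(m * common, 1e-3)
    b0 = max((1 - m) * common, 1e-3)
    slog = np.log(x).mean()
    slog1 = np.log1p(-x).mean()

    def nll(params: np.ndarray) -> float:
        a, b = np.exp(params)
        return -(a - 1) * slog - (b - 1) * slog1 + special.betaln(a, b)

    res = optimize.minimize(nll, np.log([a0, b0]), method="Nelder-Mead",
                            options={"xatol": tol, "fatol": tol,
                                     "maxiter": max_iter * 10})
    if res.success and np.all(np.isfinite(res.x)):
        a, b = np.exp(res.x)
        return float(a), float(b), True
    return float(a0), float(b0), False


# ---------------------------------------------------------------------------
# permutation pass
# ---------------------------------------------------------------------------

def feature_seed(master_seed: int, feature: str) -> int:
    """Per-feature RNG seed derived by hashing the feature id.

    Stable under feature subsetting and ordering.
    """
    return (int(master_seed) * 1_000_003 + zlib.crc32(feature.encode())) % (2 ** 31)


def permutation_pass(pm: PhenotypeMatrix, g: GenotypeMatrix,
                     cov: pd.DataFrame | None, feature: str,
                     B: int = 1000, seed: int = 0,
                     window_e: int = 500_000, window_s: int = 50_000,
                     ) -> dict | None:
    """Permutation pass for one feature.

    Returns a dict with the PERM_COLUMNS fields, or None when the
    cis-window holds no polymorphic variant (callers report such features
    with q = 1 rather than dropping them silently).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    prep = _prepare(pm, g, cov, feature, window_e, window_s)
    if prep is None:
        return None
    y, G = prep.y_res, prep.G_res
    n = len(y)
    Gn = G / np.sqrt((G ** 2).sum(axis=0))
    yn = y / np.sqrt((y ** 2).sum())
    r_obs = Gn.T @ yn
    t_obs, p_obs = _corr_to_t_p(r_obs, prep.df)
    best = int(np.argmax(np.abs(r_obs)))
    # lead tie-break: min p, then min position, then id
    tie = np.isclose(np.abs(r_obs), np.abs(r_obs[best]), rtol=0, atol=1e-15)
    if tie.sum() > 1:
        cand = sorted(np.nonzero(tie)[0],
                      key=lambda k: (prep.positions[k], prep.variant_ids[k]))
        best = cand[0]
    p_best = float(p_obs[best])

    rng = np.random.default_rng(feature_seed(seed, feature))
    perm_idx = np.argsort(rng.random((B, n)), axis=1)
    Yp = yn[perm_idx].T                      # n x B
    max_abs_r = np.abs(Gn.T @ Yp).max(axis=0)
    _, p_perm = _corr_to_t_p(max_abs_r, prep.df)

    r_count = int(np.sum(p_perm <= p_best))
    p_empirical = (r_count + 1) / (B + 1)
    a, b, converged = fit_beta_mle(p_perm)
    p_beta = float(special.betainc(a, b, min(max(p_best, 5e-324), 1.0)))
    p_beta = float(np.clip(p_beta, 1e-300, 1 - 1e-16))
    return {"feature": feature, "n_variants": G.shape[1],
            "lead": prep.variant_ids[best], "slope": float(
                r_obs[best] * np.sqrt((y ** 2).sum())
                / np.sqrt((G[:, best] ** 2).sum())),
            "p_nominal_best": p_best, "p_empirical": p_empirical,
            "beta_a": a, "beta_b": b, "p_beta": p_beta,
            "mle_converged": converged}


def permutation_pass_all(pm: PhenotypeMatrix, g: GenotypeMatrix,
                         cov: pd.DataFrame | None, B: int = 1000,
                         seed: int = 0, window_e: int = 500_000,
                         window_s: int = 50_000) -> pd.DataFrame:
    """Permutation pass over every feature; degenerate features get q = 1
    later (p_beta = 1, n_variants = 0)."""
    rows = []
    for feature in pm.features:
        rec = permutation_pass(pm, g, cov, feature, B=B, seed=seed,
                               window_e=window_e, window_s=window_s)
        if rec is None:
            rec = {"feature": feature, "n_variants": 0, "lead": "",
                   "slope": np.nan, "p_nominal_best": np.nan,
                   "p_empirical": 1.0, "beta_a": np.nan, "beta_b": np.nan,
                   "p_beta": 1.0 - 1e-16, "mle_converged": False}
        rows.append(rec)
    return pd.DataFrame(rows, columns=PERM_COLUMNS)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def storey_qvalues(p: np.ndarray, lam: float = 0.5,
                   ) -> tuple[np.ndarray, float]:
    """Storey q-values with a single fixed lambda.

    ``pi0 = #{p > lam} / ((1 - lam) m)`` clipped to (0, 1];
    ``q_i = pi0 * min_{p_j >= p_i} (m p_j / rank_j)``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1] and be non-missing")
    m = len(p)
    pi0 = np.sum(p > lam) / ((1.0 - lam) * m)
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_ord = pi0 * m * ranked / np.arange(1, m + 1)
    q_ord = np.minimum.accumulate(q_ord[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_ord, 1.0)
    return q, float(pi0)


def genomewide_threshold_pt(perm: pd.DataFrame, fdr: float = 0.01) -> float:
    """Genome-wide empirical p threshold: p_beta of the feature whose
    q-value is closest to the FDR target (ties -> smaller p_beta)."""
    if "q" not in perm.columns:
        raise ValueError("perm table needs a q column (run storey first)")
    if len(perm) == 0:
        raise ValueError("empty permutation table")
    d = np.abs(perm["q"].to_numpy() - fdr)
    best = np.lexsort((perm["p_beta"].to_numpy(), d))[0]
    return float(perm["p_beta"].iloc[best])


def nominal_threshold_per_feature(pt: float, beta_a: float, beta_b: float,
                                  ) -> float:
    """Back-transform the genome-wide threshold through a feature's beta fit."""
    return float(special.betaincinv(beta_a, beta_b, pt))


def add_qvalues_and_thresholds(perm: pd.DataFrame, fdr: float = 0.01,
                               lam: float = 0.5) -> pd.DataFrame:
    """Attach Storey q, pi0, genome-wide pt, and per-feature nominal
    thresholds to a permutation table."""
    perm = perm.copy()
    q, pi0 = storey_qvalues(perm["p_beta"].to_numpy(), lam=lam)
    perm["q"] = q
    perm.attrs["pi0"] = pi0
    pt = genomewide_threshold_pt(perm, fdr=fdr)
    perm.attrs["pt"] = pt
    thr = np.full(len(perm), np.nan)
    ok = perm["beta_a"].notna() & perm["beta_b"].notna()
    thr[ok.to_numpy()] = [
        nominal_threshold_per_feature(pt, a, b)
        for a, b in zip(perm.loc[ok, "beta_a"], perm.loc[ok, "beta_b"])]
    perm["nominal_threshold"] = thr
    return perm


# ---------------------------------------------------------------------------
# significance calls
# ---------------------------------------------------------------------------

@dataclass
class QtlCallSet:
    """Significant features with leads, plus all nominal variant pairs."""

    significant: pd.DataFrame   # perm-table rows with q <= fdr
    nominal_pairs: pd.DataFrame  # feature, variant, pos, slope, se, t, p

    @property
    def features(self) -> list[str]:
        return list(self.significant["feature"])

    def lead_of(self, feature: str) -> str:
        row = self.significant[self.significant["feature"] == feature]
        return str(row["lead"].iloc[0])


def call_significant(perm: pd.DataFrame,
                     nominal: dict[str, pd.DataFrame] | None = None,
                     fdr: float = 0.01) -> QtlCallSet:
    """FDR call: features with q <= fdr; nominal pairs are that feature's
    cis variants with p <= its beta-derived nominal threshold."""
    if "nominal_threshold" not in perm.columns:
        raise ValueError("run add_qvalues_and_thresholds first")
    sig = perm[perm["q"] <= fdr].reset_index(drop=True)
    pairs = []
    if nominal:
        thr = dict(zip(sig["feature"], sig["nominal_threshold"]))
        for feat, tab in nominal.items():
            if feat not in thr or np.isnan(thr[feat]):
                continue
            pairs.append(tab[tab["p"] <= thr[feat]])
    nominal_pairs = (pd.concat(pairs, ignore_index=True) if pairs
                     else pd.DataFrame(columns=["feature", "variant", "pos",
                                                "slope", "se", "t", "p"]))
    return QtlCallSet(sig, nominal_pairs)


# ---------------------------------------------------------------------------
# effect-size and sharing summaries
# ---------------------------------------------------------------------------

def delta_psi(psi_raw: pd.Series, dosage: np.ndarray) -> float:
    """Difference in median raw PSI between homozygous groups.

    ``median PSI(hom-alt) - median PSI(hom-ref)``; heterozygotes stand in
    for hom-alt when no hom-alt samples exist. Computed on raw (not
    standardized) PSI.
    """
    y = psi_raw.to_numpy(dtype=float)
    d = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(d))
    y, d = y[ok], d[ok]
    ref = y[d == 0]
    alt = y[d == 2]
    if len(alt) == 0:
        alt = y[d == 1]
    if len(ref) == 0 or len(alt) == 0:
        return float("nan")
    return float(np.median(alt) - np.median(ref))


def delta_psi_table(psi_raw: PhenotypeMatrix, g: GenotypeMatrix,
                    perm: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """Per-cluster delta-PSI at the best-q junction of each cluster.

    Only significant clusters (q <= fdr) are reported; each row carries
    |delta PSI| and whether the shift exceeds 10% of usage.
    """
    sig = perm[perm["q"] <= fdr]
    rows = []
    for cluster, grp in sig.groupby(
            psi_raw.anchors.reindex(sig["feature"])["cluster"].to_numpy()):
        best = grp.sort_values(["q", "p_beta"]).iloc[0]
        feat, lead = best["feature"], best["lead"]
        if not lead:
            continue
        dpsi = delta_psi(psi_raw.values.loc[feat], g.column(lead))
        rows.append({"cluster": cluster, "feature": feat, "lead": lead,
                     "q": best["q"], "delta_psi": dpsi,
                     "abs_shift_gt_10pct": bool(abs(dpsi) > 0.10)})
    return pd.DataFrame(rows, columns=["cluster", "feature", "lead", "q",
                                       "delta_psi", "abs_shift_gt_10pct"])


def compare_sqtl_eqtl(sqtl_calls: QtlCallSet, eqtl_calls: QtlCallSet,
                      g: GenotypeMatrix, feature_gene: dict[str, str],
                      r2_independent: float = 0.6,
                      ld_window_bp: int = 1_000_000) -> pd.DataFrame:
    """Lead-lead LD between sQTL and eQTL signals of the same gene.

    ``feature_gene`` maps splicing feature ids to gene ids (eQTL features
    map to themselves). A gene is classified ``independent`` when the
    lead-lead r^2 is below ``r2_independent``; the fraction of nominally
    significant variants shared between the two signals is also reported.
    """
    egenes = {feature_gene.get(f, f): f for f in eqtl_calls.features}
    rows = []
    for sfeat in sqtl_calls.features:
        gene = feature_gene.get(sfeat, sfeat)
        if gene not in egenes:
            continue
        efeat = egenes[gene]
        slead = sqtl_calls.lead_of(sfeat)
        elead = eqtl_calls.lead_of(efeat)
        vs, ve = g.variants[g.index_of(slead)], g.variants[g.index_of(elead)]
        if vs.chrom == ve.chrom and abs(vs.pos - ve.pos) <= ld_window_bp:
            r2 = pearson_r2(g.column(slead), g.column(elead))
        else:
            r2 = 0.0
        s_vars = set(sqtl_calls.nominal_pairs.query("feature == @sfeat")["variant"])
        e_vars = set(eqtl_calls.nominal_pairs.query("feature == @efeat")["variant"])
        shared = (len(s_vars & e_vars) / len(s_vars | e_vars)
                  if (s_vars | e_vars) else float("nan"))
        rows.append({"gene": gene, "sqtl_feature": sfeat, "eqtl_feature": efeat,
                     "lead_sqtl": slead, "lead_eqtl": elead, "r2": r2,
                     "independent": bool(not np.isnan(r2) and r2 < r2_independent),
                     "frac_nominal_shared": shared})
    return pd.DataFrame(rows, columns=["gene", "sqtl_feature", "eqtl_feature",
                                       "lead_sqtl", "lead_eqtl", "r2",
                                       "independent", "frac_nominal_shared"])
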