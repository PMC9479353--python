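"""Summary-statistics TWAS: cis prediction weights, association, gating.

A feature's cis-genetic component is learned from the QTL panel
(covariate-residualized phenotype on cis dosages) with one of three
models — top1 (all weight on the best marginal variant), ridge (penalty by
generalized cross-validation) or lasso (CV-min on the penalty path) — and
the winner is chosen by k-fold cross-validated R^2. Features whose best
model explains essentially nothing (cv R^2 <= 0.01) are not carried to
association.

Association against GWAS summary statistics uses the standard weighted
z-score with an LD reference from the same panel:

    z_twas = w' z / sqrt(w' R w)

Significant results are Bonferroni-flagged and gated on colocalization
(shared-variant PP >= 0.6 by default) to suppress signals driven by
linkage rather than a shared causal variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV, RidgeCV
from sklearn.model_selection import KFold

from .core_io import GenotypeMatrix, GwasSummary, ld_corr
from .cis_qtl import _prepare
from .phenotype_quant import PhenotypeMatrix

CV_R2_MIN = 0.01


@dataclass
class TwasWeights:
    feature: str
    variant_ids: list[str]
    weights: np.ndarray
    model: str          # top1 | ridge | lasso
    cv_r2: float        # recorded even when negative
    n_train: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.any(self.weights != 0):
            raise ValueError("weights must have at least one nonzero entry")


@dataclass
class TwasResult:
    feature: str
    z: float
    p: float
    best_gwas_variant: str
    coloc_pp: float = float("nan")
    pass_coloc_gate: bool = False
    gate_reason: str = ""
    significant: bool = False
    locus_class: str = ""


# ---------------------------------------------------------------------------
# weight training
# ---------------------------------------------------------------------------

def _cv_r2(model_fit, X: np.ndarray, y: np.ndarray, k: int,
           seed: int) -> float:
    """Out-of-fold R^2 of a fit-callable over k folds."""
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.zeros_like(y)
    for tr, te in kf.split(X):
        pred[te] = model_fit(X[tr], y[tr], X[te])
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("-inf")


def fit_weights_cv(pm: PhenotypeMatrix, g: GenotypeMatrix,
                   cov: pd.DataFrame | None, feature: str,
                   k_folds: int = 5, seed: int = 0,
                   window_e: int = 500_000, window_s: int = 50_000,
                   cv_r2_min: float = CV_R2_MIN) -> TwasWeights | None:
    """Train cis prediction weights for one feature; None if non-heritable.

    Candidate models are compared by k-fold cross-validated R^2 on the
    covariate-residualized phenotype; the winner's weights are refit on
    the full data.
    """
    prep = _prepare(pm, g, cov, feature, window_e, window_s)
    if prep is None:
        return None
    y, X = prep.y_res, prep.G_res
    n = len(y)

    def top1_fit(Xtr, ytr, Xte):
        sg = np.sqrt((Xtr ** 2).sum(axis=0))
        sg[sg == 0] = np.nan
        r = np.abs(Xtr.T @ ytr) / (sg * np.sqrt((ytr ** 2).sum()))
        j = int(np.nanargmax(r))
        denom = (Xtr[:, j] ** 2).sum()
        slope = (Xtr[:, j] @ ytr) / denom if denom > 0 else 0.0
        return Xte[:, j] * slope

    def ridge_fit(Xtr, ytr, Xte):
        m = RidgeCV(alphas=np.logspace(-2, 4, 20), gcv_mode="auto")
        m.fit(Xtr, ytr)
        return m.predict(Xte)

    def lasso_fit(Xtr, ytr, Xte):
        m = LassoCV(alphas=30, cv=3, random_state=seed, max_iter=5000)
        with warnings.catch_warnings():
            # near-duplicate LD columns stall the coordinate descent at
            # penalties the CV discards anyway
            warnings.simplefilter("ignore", ConvergenceWarning)
            m.fit(Xtr, ytr)
        return m.predict(Xte)

    candidates = {"top1": top1_fit, "ridge": ridge_fit, "lasso": lasso_fit}
    scores = {name: _cv_r2(fit, X, y, k_folds, seed)
              for name, fit in candidates.items()}
    best = max(scores, key=lambda k_: scores[k_])
    if scores[best] <= cv_r2_min:
        return None

    if best == "top1":
        sg = np.sqrt((X ** 2).sum(axis=0))
        r = np.abs(X.T @ y) / (sg * np.sqrt((y ** 2).sum()))
        j = int(np.nanargmax(r))
        w = np.zeros(X.shape[1])
        w[j] = (X[:, j] @ y) / (X[:, j] ** 2).sum()
    elif best == "ridge":
        m = RidgeCV(alphas=np.logspace(-2, 4, 20), gcv_mode="auto")
        m.fit(X, y)
        w = m.coef_
    else:
        m = LassoCV(alphas=30, cv=3, random_state=seed, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            m.fit(X, y)
        w = m.coef_
        if not np.any(w != 0):  # lasso zeroed everything despite good CV
            return None
    return TwasWeights(feature, prep.variant_ids, w, best,
                       float(scores[best]), n)


def ridge_closed_form(X: np.ndarray, y: np.ndarray, alpha: float,
                      ) -> np.ndarray:
    """(X'X + alpha I)^-1 X'y — reference solution for the ridge model."""
    k = X.shape[1]
    return np.linalg.solve(X.T @ X + alpha * np.eye(k), X.T @ y)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def twas_association(wts: TwasWeights, gwas: GwasSummary,
                     g: GenotypeMatrix, ridge_eps: float = 1e-6,
                     ) -> TwasResult:
    """Weighted z-score association of a feature with a GWAS trait.

    GWAS variants are intersected with the panel; weights on variants
    absent from the GWAS are dropped (FUSION-style intersection rule).
    """
    gt = gwas.table.set_index("id")
    keep = [(vid, w) for vid, w in zip(wts.variant_ids, wts.weights)
            if w != 0 and vid in gt.index and vid in g]
    if not keep:
        raise ValueError(f"{wts.feature}: no weighted variant overlaps the GWAS")
    vids = [v for v, _ in keep]
    w = np.array([x for _, x in keep])
    z = gt.loc[vids, "z"].to_numpy(dtype=float)
    R = ld_corr(g, vids)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    denom = float(w @ R @ w)
    if denom <= 0:
        R = R + ridge_eps * np.eye(len(R))
        denom = float(w @ R @ w)
        if denom <= 0:
            raise ValueError(f"{wts.feature}: non-positive weighted LD variance")
    z_twas = float(w @ z) / np.sqrt(denom)
    p = float(2.0 * stats.norm.sf(abs(z_twas)))
    best = vids[int(np.argmax(np.abs(z)))]
    return TwasResult(wts.feature, z_twas, max(p, 5e-324), best)


def twas_significance(results: list[TwasResult], m_tests: int,
                      alpha: float = 0.05) -> list[TwasResult]:
    """Bonferroni flag: significant iff p <= alpha / m_tests."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    thr = bonferroni_threshold(m_tests, alpha)
    for r in results:
        r.significant = r.p <= thr
    return results


def bonferroni_threshold(m_tests: int, alpha: float = 0.05) -> float:
    return alpha / m_tests


def coloc_gate(results: list[TwasResult], coloc: pd.DataFrame,
               min_pp: float = 0.6) -> list[TwasResult]:
    """Flag results whose locus lacks a shared-variant coloc PP >= min_pp.

    ``coloc`` is the table from colocalize_all (columns feature, pp4).
    Gated-out results are retained with ``pass_coloc_gate=False``.
    """
    best_pp = coloc.groupby("feature")["pp4"].max() if len(coloc) else pd.Series(dtype=float)
    for r in results:
        if r.feature not in best_pp.index:
            r.pass_coloc_gate = False
            r.gate_reason = "no_coloc"
            r.coloc_pp = float("nan")
        else:
            r.coloc_pp = float(best_pp[r.feature])
            r.pass_coloc_gate = r.coloc_pp >= min_pp
            r.gate_reason = "" if r.pass_coloc_gate else "low_pp"
    return results


def classify_locus(result: TwasResult, known_leads: list[str],
                   g: GenotypeMatrix, r2_min: float = 0.1,
                   dist_bp: int = 500_000) -> str:
    """known if the best GWAS variant is in LD with, or near, a known lead."""
    from .core_io import pearson_r2

    if result.best_gwas_variant not in g:
        result.locus_class = "novel"
        return "novel"
    v = g.variants[g.index_of(result.best_gwas_variant)]
    dos = g.column(result.best_gwas_variant)
    for lead in known_leads:
        if lead not in g:
            continue
        u = g.variants[g.index_of(lead)]
        if u.chrom == v.chrom and abs(u.pos - v.pos) < dist_bp:
            result.locus_class = "known"
            return "known"
        r2 = pearson_r2(dos, g.column(lead))
        if not np.isnan(r2) and r2 >= r2_min:
            result.locus_class = "known"
            return "known"
    result.locus_class = "novel"
    return "novel"


def results_table(results: list[TwasResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature": r.feature, "z": r.z, "p": r.p,
        "best_gwas_variant": r.best_gwas_variant, "coloc_pp": r.coloc_pp,
        "pass_coloc_gate": r.pass_coloc_gate, "gate_reason": r.gate_reason,
        "significant": r.significant, "locus_class": r.locus_class,
    } for r in results])
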