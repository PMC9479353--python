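"""Single-causal-variant Bayesian fine-mapping and summary-stat conditioning.

Under the restriction of one causal variant per locus, the posterior over
which variant is causal reduces to per-variant Wakefield approximate Bayes
factors with a uniform prior:

    log ABF_j = 0.5 log(1 - r_j) + 0.5 r_j z_j^2,   r_j = W / (W + se_j^2)

    CPP_j = ABF_j / sum_k ABF_k

where W is the prior variance of the causal effect. The 95% credible set
is the smallest prefix of variants, in descending CPP order, whose
cumulative posterior reaches 0.95.

``conditional_z`` implements summary-statistic conditioning a la COJO:
z-scores are adjusted for a conditioning set C through the LD (signed
correlation) matrix,

    z_cond_j = (z_j - R_jC R_CC^-1 z_C) / sqrt(1 - R_jC R_CC^-1 R_Cj).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_PRIOR_VARIANCE = 0.04  # effect SD 0.2 on a standardized trait / log-odds


def wakefield_abf(beta: np.ndarray, se: np.ndarray,
                  prior_variance: float = DEFAULT_PRIOR_VARIANCE,
                  ) -> np.ndarray:
    """log approximate Bayes factor per variant (alternative vs null).

    ``prior_variance`` (W) is the variance of the causal effect prior;
    W = 0 collapses to the point null (log ABF = 0).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_variance < 0:
        raise ValueError("prior variance must be non-negative")
    z = beta / se
    r = prior_variance / (prior_variance + se ** 2)
    return 0.5 * np.log1p(-r) + 0.5 * r * z * z


def single_causal_posteriors(beta: np.ndarray, se: np.ndarray,
                             prior_variance: float = DEFAULT_PRIOR_VARIANCE,
                             ) -> np.ndarray:
    """Per-variant causal posterior probabilities (CPP), uniform prior."""
    log_abf = wakefield_abf(beta, se, prior_variance)
    log_abf = log_abf - log_abf.max()
    w = np.exp(log_abf)
    return w / w.sum()


@dataclass
class CredibleSet:
    """Fine-mapping result for one signal."""

    signal: str
    table: pd.DataFrame  # variant, pos, z, log_abf, cpp, in_credible_set
    level: float

    @property
    def members(self) -> list[str]:
        return list(self.table.loc[self.table["in_credible_set"], "variant"])

    @property
    def lead(self) -> str:
        return str(self.table.loc[self.table["cpp"].idxmax(), "variant"])

    def cpp_of(self, variant: str) -> float:
        rows = self.table[self.table["variant"] == variant]
        return float(rows["cpp"].iloc[0]) if len(rows) else 0.0

    @property
    def size(self) -> int:
        return int(self.table["in_credible_set"].sum())


def credible_set_95(cpp: np.ndarray, variant_ids: list[str],
                    positions: np.ndarray | None = None,
                    level: float = 0.95) -> np.ndarray:
    """Boolean membership of the minimal cumulative >= level credible set.

    Variants are sorted by descending CPP (ties broken by genomic
    position, then id); the variant crossing the level is included.
    """
    cpp = np.asarray(cpp, dtype=float)
    if not np.isclose(cpp.sum(), 1.0, atol=1e-8):
        raise ValueError("CPPs must sum to 1")
    if positions is None:
        positions = np.arange(len(cpp))
    order = np.lexsort((list(variant_ids), positions, -cpp))
    member = np.zeros(len(cpp), dtype=bool)
    cum = 0.0
    for j in order:
        member[j] = True
        cum += cpp[j]
        if cum >= level - 1e-12:
            break
    return member


def finemap_signal(signal: str, stats: pd.DataFrame,
                   prior_variance: float = DEFAULT_PRIOR_VARIANCE,
                   level: float = 0.95) -> CredibleSet:
    """Fine-map one locus given summary stats (columns id, pos, beta, se)."""
    beta = stats["beta"].to_numpy(dtype=float)
    se = stats["se"].to_numpy(dtype=float)
    log_abf = wakefield_abf(beta, se, prior_variance)
    cpp = single_causal_posteriors(beta, se, prior_variance)
    member = credible_set_95(cpp, list(stats["id"]),
                             stats["pos"].to_numpy(), level)
    table = pd.DataFrame({"variant": stats["id"].to_numpy(),
                          "pos": stats["pos"].to_numpy(),
                          "z": beta / se, "log_abf": log_abf, "cpp": cpp,
                          "in_credible_set": member})
    return CredibleSet(signal, table, level)


def conditional_z(z: np.ndarray, corr: np.ndarray, cond_idx: list[int],
                  collinear_tol: float = 0.05, ridge_eps: float = 1e-6,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Condition locus z-scores on a set of variants via the LD matrix.

    Returns (z_cond, collinear_flag). Conditioned-on variants and variants
    whose conditional variance falls below ``collinear_tol`` are flagged
    collinear and get nan. A singular conditioning block is
    ridge-regularized with ``ridge_eps`` on the diagonal.
    """
    z = np.asarray(z, dtype=float)
    R = np.asarray(corr, dtype=float)
    C = list(cond_idx)
    Rcc = R[np.ix_(C, C)]
    try:
        Rcc_inv = np.linalg.inv(Rcc)
    except np.linalg.LinAlgError:
        Rcc_inv = np.linalg.inv(Rcc + ridge_eps * np.eye(len(C)))
    Rjc = R[:, C]
    adj = Rjc @ Rcc_inv
    num = z - adj @ z[C]
    var = 1.0 - np.einsum("jk,jk->j", adj, Rjc)
    collinear = var < collinear_tol
    collinear[C] = True
    out = np.full_like(z, np.nan)
    ok = ~collinear
    out[ok] = num[ok] / np.sqrt(var[ok])
    return out, collinear
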