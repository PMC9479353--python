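"""Bayesian colocalization of a QTL signal with a GWAS signal.

For each variant the Wakefield log ABF is computed per trait; the five
hypotheses over a locus (H0 no association; H1/H2 one trait only; H3 two
distinct causal variants; H4 one shared variant) are scored by summing
ABFs in log space:

    H1 ~ p1  * sum_j ABF1_j
    H2 ~ p2  * sum_j ABF2_j
    H3 ~ p1 p2 * (sum_j ABF1_j * sum_k ABF2_k - sum_j ABF1_j ABF2_j)
    H4 ~ p12 * sum_j ABF1_j ABF2_j

normalized against H0 = 1. A locus is declared colocalized when the
shared-variant posterior PP4 reaches the decision threshold (0.8 by
default). Eligibility gating mirrors the credible-set / LD rule used to
decide which GWAS signals are worth testing against a QTL lead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core_io import GenotypeMatrix, GwasSummary, pearson_r2
from .fine_mapping import CredibleSet, wakefield_abf

PRIOR_P1 = 1e-4
PRIOR_P2 = 1e-4
PRIOR_P12 = 1e-5
QTL_PRIOR_SD = 0.15     # quantitative-trait ABF prior SD
GWAS_PRIOR_SD = 0.2     # case-control (log-odds) ABF prior SD


@dataclass
class ColocResult:
    """Posterior over the five colocalization hypotheses for one locus."""

    locus: str
    n_variants: int
    pp: np.ndarray  # PP0..PP4
    eligible: bool = True
    colocalized: bool = False
    prior_mode: str = "fixed"

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,) or not np.isclose(self.pp.sum(), 1.0, atol=1e-8):
            raise ValueError("PP vector must have 5 entries summing to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    @property
    def pp3(self) -> float:
        return float(self.pp[3])


def _log_sum(log_abf: np.ndarray) -> float:
    return float(logsumexp(log_abf))


def coloc_posteriors(log_abf1: np.ndarray, log_abf2: np.ndarray,
                     p1: float = PRIOR_P1, p2: float = PRIOR_P2,
                     p12: float = PRIOR_P12, locus: str = "locus",
                     prior_mode: str = "fixed") -> ColocResult:
    """Hypothesis posteriors from per-variant log ABFs of two traits."""
    log_abf1 = np.asarray(log_abf1, dtype=float)
    log_abf2 = np.asarray(log_abf2, dtype=float)
    if log_abf1.shape != log_abf2.shape:
        raise ValueError("trait ABF vectors must align on the same variants")
    m = len(log_abf1)
    if m < 2:
        raise ValueError("need at least 2 shared variants")
    if m < 25:
        warnings.warn(f"{locus}: only {m} shared variants; posteriors may be "
                      "unstable", stacklevel=2)
    ls1 = _log_sum(log_abf1)
    ls2 = _log_sum(log_abf2)
    ls12 = _log_sum(log_abf1 + log_abf2)
    # log of (sum_j sum_{k != j} ABF1_j ABF2_k) = log(e^{ls1+ls2} - e^{ls12})
    both = ls1 + ls2
    if both > ls12:
        l_h3 = both + np.log1p(-np.exp(ls12 - both))
    else:  # degenerate single-variant-dominated locus
        l_h3 = -np.inf
    logs = np.array([
        0.0,
        np.log(p1) + ls1,
        np.log(p2) + ls2,
        np.log(p1) + np.log(p2) + l_h3,
        np.log(p12) + ls12,
    ])
    pp = np.exp(logs - logsumexp(logs))
    return ColocResult(locus, m, pp / pp.sum(), prior_mode=prior_mode)


def trait_log_abf(table: pd.DataFrame, prior_sd: float) -> np.ndarray:
    """Per-variant log ABFs for one trait (columns beta, se)."""
    return wakefield_abf(table["beta"].to_numpy(dtype=float),
                         table["se"].to_numpy(dtype=float),
                         prior_sd ** 2)


def eligible_signals(gwas_credsets: dict[str, CredibleSet],
                     qtl_leads: dict[str, str], g: GenotypeMatrix,
                     gwas_tables: dict[str, GwasSummary] | None = None,
                     cpp_min: float = 0.01, r2_min: float = 0.6,
                     p_fallback: float = 5e-5) -> pd.DataFrame:
    """Which GWAS signals are eligible for colocalization against which QTL.

    A signal qualifies if any of its credible-set variants with CPP >=
    ``cpp_min`` has r^2 >= ``r2_min`` with a QTL lead. When a signal has no
    credible set, the fallback takes any variant with GWAS p <=
    ``p_fallback`` in ``r2_min`` LD with the lead (requires
    ``gwas_tables``).
    """
    rows = []
    for locus, lead_map in ((lo, qtl_leads) for lo in
                            set(gwas_credsets) | set(gwas_tables or {})):
        cs = gwas_credsets.get(locus)
        for feature, lead in lead_map.items():
            if lead not in g:
                continue
            lead_dos = g.column(lead)
            ok = False
            best_r2 = 0.0
            if cs is not None:
                cand = cs.table[cs.table["cpp"] >= cpp_min]
                for vid in cand["variant"]:
                    if vid not in g:
                        continue
                    r2 = pearson_r2(lead_dos, g.column(vid))
                    if not np.isnan(r2):
                        best_r2 = max(best_r2, r2)
                if best_r2 >= r2_min:
                    ok = True
            elif gwas_tables and locus in gwas_tables:
                tab = gwas_tables[locus].table
                for vid in tab.loc[tab["p"] <= p_fallback, "id"]:
                    if vid not in g:
                        continue
                    r2 = pearson_r2(lead_dos, g.column(vid))
                    if not np.isnan(r2):
                        best_r2 = max(best_r2, r2)
                if best_r2 >= r2_min:
                    ok = True
            if ok:
                rows.append({"locus": locus, "feature": feature,
                             "qtl_lead": lead, "best_r2": best_r2})
    return pd.DataFrame(rows, columns=["locus", "feature", "qtl_lead",
                                       "best_r2"])


def colocalize_locus(qtl_stats: pd.DataFrame, gwas: GwasSummary,
                     lead_pos: int, lead_chrom: str,
                     window_bp: int = 1_000_000, p_incl: float = 5e-5,
                     pp_threshold: float = 0.8, locus: str = "locus",
                     qtl_prior_sd: float = QTL_PRIOR_SD,
                     gwas_prior_sd: float = GWAS_PRIOR_SD,
                     require_signal: bool = True,
                     hard_filter: bool = False) -> ColocResult:
    """Colocalize one GWAS signal with a QTL across a centered window.

    The window spans ``lead_pos +/- window_bp / 2``. With
    ``require_signal`` the region must contain at least one variant with
    GWAS p <= ``p_incl`` (all region variants then enter the computation);
    ``hard_filter`` instead restricts the computation to those variants.
    ``qtl_stats`` needs columns id, pos, beta, se.
    """
    half = window_bp // 2
    lo, hi = max(1, lead_pos - half), lead_pos + half
    gt = gwas.table
    region = gt[(gt["chrom"] == lead_chrom) & (gt["pos"] >= lo)
                & (gt["pos"] <= hi)]
    if require_signal and not (region["p"] <= p_incl).any():
        raise ValueError(f"{locus}: no variant with GWAS p <= {p_incl} in window")
    if hard_filter:
        region = region[region["p"] <= p_incl]
    shared = sorted(set(region["id"]) & set(qtl_stats["id"]))
    if len(shared) < 2:
        raise ValueError(f"{locus}: fewer than 2 shared variants")
    q = qtl_stats.set_index("id").loc[shared]
    w = region.set_index("id").loc[shared]
    res = coloc_posteriors(trait_log_abf(q.reset_index(), qtl_prior_sd),
                           trait_log_abf(w.reset_index(), gwas_prior_sd),
                           locus=locus)
    res.colocalized = res.pp4 >= pp_threshold
    return res


def colocalize_all(signals: pd.DataFrame, qtl_stats: dict[str, pd.DataFrame],
                   gwas_tables: dict[str, GwasSummary], g: GenotypeMatrix,
                   window_bp: int = 1_000_000, p_incl: float = 5e-5,
                   pp_threshold: float = 0.8) -> pd.DataFrame:
    """Run colocalization over an eligibility table.

    ``signals`` comes from :func:`eligible_signals` plus columns
    ``gwas_lead`` naming each locus's lead variant. Returns one row per
    (locus, feature) with PP0..PP4 and the colocalized flag.
    """
    rows = []
    for _, sig in signals.iterrows():
        locus, feature = sig["locus"], sig["feature"]
        gwas = gwas_tables[locus]
        lead_id = sig.get("gwas_lead") or gwas.table.loc[
            gwas.table["p"].idxmin(), "id"]
        lead_row = gwas.lookup(lead_id)
        try:
            res = colocalize_locus(qtl_stats[feature], gwas,
                                   int(lead_row["pos"]), str(lead_row["chrom"]),
                                   window_bp=window_bp, p_incl=p_incl,
                                   pp_threshold=pp_threshold,
                                   locus=f"{locus}:{feature}")
        except ValueError:
            continue
        rows.append({"locus": locus, "feature": feature,
                     "n_variants": res.n_variants,
                     **{f"pp{i}": res.pp[i] for i in range(5)},
                     "eligible": True, "colocalized": res.colocalized,
                     "prior_mode": res.prior_mode})
    return pd.DataFrame(rows, columns=["locus", "feature", "n_variants",
                                       "pp0", "pp1", "pp2", "pp3", "pp4",
                                       "eligible", "colocalized",
                                       "prior_mode"])
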