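"""Headline calibration measurements on synthetic data with planted truth.

Two study-condition experiments used by the calibration suite and the
acceptance script:

* :func:`fdr_calibration` — realized false discovery proportion of the
  permutation + beta-approximation + Storey-q discovery procedure at
  q <= 0.01, on a cohort of features with known nulls;
* :func:`credible_set_coverage` — empirical coverage of single-causal
  95% credible sets over simulated GWAS loci with one planted causal
  variant and correctly specified LD.

The experiment sizes default to the study conditions (1000 features with
200 planted effects of 0.8 SD per allele at n = 300 and B = 1000
permutations; 1000 loci of 100 variants in rho = 0.9 block LD with lead
non-centrality 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cis_qtl import add_qvalues_and_thresholds, permutation_pass_all
from .fine_mapping import finemap_signal
from .phenotype_quant import cpm_log2, expression_phenotypes, filter_genes
from .synthetic_data import (SimConfig, simulate_expression,
                             simulate_genotypes, simulate_gwas_locus)


@dataclass
class FdrRun:
    fdp: float           # realized false discovery proportion
    n_called: int
    n_false: int
    n_features: int
    pi0: float


def fdr_calibration(seed: int, n_features: int = 1000, n_effect: int = 200,
                    n_samples: int = 300, B: int = 1000, beta: float = 0.8,
                    fdr: float = 0.01, block_size: int = 20) -> FdrRun:
    """One seeded FDR-calibration run of the full discovery procedure.

    Each feature owns one LD block (so nulls are genuinely unassociated);
    planted effects act on the central variant at MAF >= 0.2. The
    phenotype route is the expression pipeline: counts -> gene filter ->
    log2 CPM -> permutation pass -> Storey q.
    """
    n_chrom = 20
    per_chrom = int(np.ceil(n_features / n_chrom))
    cfg = SimConfig(
        n_samples=n_samples, n_chrom=n_chrom, n_blocks_per_chrom=per_chrom,
        block_size=block_size, within_block_rho=0.9, variant_spacing=1_000,
        # block spacing > the 1 Mb expression window so cis-windows are 1:1
        block_spacing=1_100_000, chrom_len=per_chrom * 1_100_000 + 100_000,
        maf_range=(0.2, 0.5), n_genes=n_features, gene_noise_sd=1.0,
        seed=seed)
    g = simulate_genotypes(cfg)
    mid = block_size // 2
    blocks = [f"chr{c + 1}_b{b}" for c in range(n_chrom)
              for b in range(per_chrom)][:n_features]
    eff_rows = [{"gene": i, "variant": f"{blocks[i]}_v{mid}",
                 "beta": beta if i < n_effect else 0.0}
                for i in range(n_features)]
    counts, genes, truth = simulate_expression(
        g, cfg, pd.DataFrame(eff_rows), batch_log2_offset=0.0)
    counts = filter_genes(counts)
    pm = expression_phenotypes(cpm_log2(counts), genes)
    perm = permutation_pass_all(pm, g, None, B=B, seed=seed)
    perm = add_qvalues_and_thresholds(perm, fdr=fdr)
    true_set = set(truth.eqtl["feature"])
    called = perm.loc[perm["q"] <= fdr, "feature"]
    n_false = int(sum(f not in true_set for f in called))
    return FdrRun(fdp=(n_false / len(called)) if len(called) else 0.0,
                  n_called=int(len(called)), n_false=n_false,
                  n_features=len(perm), pi0=float(perm.attrs["pi0"]))


def fdr_calibration_mean(seed: int, n_seeds: int = 10, **kw) -> dict:
    """Mean realized FDP over seeds derived from ``seed``."""
    runs = [fdr_calibration((seed * 1_000_003 + k) % (2 ** 31), **kw)
            for k in range(n_seeds)]
    return {"mean_fdp": float(np.mean([r.fdp for r in runs])),
            "max_fdp": float(np.max([r.fdp for r in runs])),
            "mean_called": float(np.mean([r.n_called for r in runs])),
            "runs": runs}


def credible_set_coverage(seed: int, n_loci: int = 1000, n_variants: int = 100,
                          rho: float = 0.9, ncp: float = 6.0,
                          n_gwas: int = 50_000, n_panel: int = 400,
                          level: float = 0.95) -> dict:
    """Empirical credible-set coverage over simulated single-causal loci.

    Returns coverage (fraction of loci whose true causal is inside the
    cumulative >= ``level`` set), the Monte-Carlo SE, and the mean set
    size.
    """
    cfg = SimConfig(n_samples=n_panel, n_chrom=1, n_blocks_per_chrom=1,
                    block_size=n_variants, within_block_rho=rho,
                    variant_spacing=1_000, block_spacing=100_000,
                    chrom_len=n_variants * 1_000 + 20_000, seed=seed)
    g = simulate_genotypes(cfg)
    vids = [v.id for v in g.variants]
    rng = np.random.default_rng(seed + 1)
    beta_gwas = ncp / np.sqrt(n_gwas)
    hits = 0
    sizes = []
    for _ in range(n_loci):
        causal = vids[int(rng.integers(len(vids)))]
        gw = simulate_gwas_locus(g, vids, causal, beta_gwas, n_gwas, rng)
        cs = finemap_signal("locus", gw.table[["id", "pos", "beta", "se"]],
                            level=level)
        hits += causal in cs.members
        sizes.append(cs.size)
    cov = hits / n_loci
    return {"coverage": cov,
            "mc_se": float(np.sqrt(cov * (1 - cov) / n_loci)),
            "mean_set_size": float(np.mean(sizes)), "n_loci": n_loci}
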