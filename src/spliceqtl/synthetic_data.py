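"""Synthetic genotype / phenotype / GWAS generators with recorded truth.

Every generator is seed-deterministic and writes its planted effects into a
:class:`SimTruth` table, so downstream recovery tests never peek at the
generating code. The models are deliberately simple but structurally
faithful to the data the pipeline consumes:

* genotypes — block-LD diploid dosages built from two haplotypes, each a
  first-order Markov chain (allele copied from the previous marker with
  probability ``within_block_rho``, refreshed from the block allele
  frequency otherwise), so adjacent-marker haplotype correlation is
  ``rho`` and dosage r^2 decays as ``rho^(2*lag)``;
* splicing — per splice cluster, sample totals are negative binomial and
  junction counts multinomial with proportions
  ``softmax(base_logits + beta * dosage + batch_offset)``, a planted sQTL
  acting on one junction's logit;
* expression — Poisson counts around a log-normal mean with an additive
  per-allele effect on the log2 scale, per-batch offsets, and 2-fold
  library-size variation;
* GWAS — locus z-scores drawn from MVN(R @ lam, R) with a single nonzero
  non-centrality ``sqrt(n) * beta`` at the causal variant, the standard
  summary-statistic model under which fine-mapping and colocalization are
  derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (GenotypeMatrix, GwasSummary, Interval, IntervalSet,
                      Variant, ld_corr)

GENERATOR_VERSION = "1"


# ---------------------------------------------------------------------------
# configuration / truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Knobs for the synthetic cohort.

    Defaults describe a desk-scale cohort of a few hundred donors with
    common variants in moderately strong LD blocks, matching the regime
    the mapping pipeline targets.
    """

    n_samples: int = 300
    n_chrom: int = 2
    chrom_len: int = 10_000_000
    n_blocks_per_chrom: int = 10
    block_size: int = 20
    within_block_rho: float = 0.9
    variant_spacing: int = 1_000
    block_spacing: int = 500_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_clusters: int = 20
    junctions_per_cluster: int = 3
    cluster_depth: float = 100.0
    nb_dispersion: float = 10.0
    n_genes: int = 20
    gene_base_log2: float = 6.0
    gene_noise_sd: float = 1.0
    batch_labels: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_chrom", "n_blocks_per_chrom", "block_size",
                     "n_clusters", "junctions_per_cluster", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")

    def batches(self) -> list[str]:
        if self.batch_labels is not None:
            if len(self.batch_labels) != self.n_samples:
                raise ValueError("batch_labels length != n_samples")
            return list(self.batch_labels)
        half = self.n_samples // 2
        return ["A"] * half + ["B"] * (self.n_samples - half)


@dataclass
class SimTruth:
    """Planted ground truth, one row per effect."""

    sqtl: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["feature", "variant", "beta"]))
    eqtl: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["feature", "variant", "beta"]))
    gwas: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["locus", "variant", "beta", "n", "sharing"]))
    batch_offsets: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, df in (("sqtl", self.sqtl), ("eqtl", self.eqtl)):
            for _, r in df.iterrows():
                rows.append({"kind": kind, "feature": r["feature"],
                             "variant": r["variant"], "beta": r["beta"],
                             "sharing": ""})
        for _, r in self.gwas.iterrows():
            rows.append({"kind": "gwas", "feature": r["locus"],
                         "variant": r["variant"], "beta": r["beta"],
                         "sharing": r["sharing"]})
        return pd.DataFrame(rows, columns=["kind", "feature", "variant", "beta",
                                           "sharing"])

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _markov_haplotypes(rng: np.random.Generator, n_hap: int, n_var: int,
                       freq: float, rho: float) -> np.ndarray:
    """Haplotype block: allele copied from the left neighbour w.p. rho."""
    hap = np.empty((n_hap, n_var), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < freq
    if n_var > 1:
        copy = rng.random((n_hap, n_var - 1)) < rho
        fresh = (rng.random((n_hap, n_var - 1)) < freq).astype(np.int8)
        for j in range(1, n_var):
            hap[:, j] = np.where(copy[:, j - 1], hap[:, j - 1], fresh[:, j - 1])
    return hap


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Block-LD diploid dosage matrix; blocks independent of each other."""
    rng = np.random.default_rng(cfg.seed)
    variants: list[Variant] = []
    cols: list[np.ndarray] = []
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        for b in range(cfg.n_blocks_per_chrom):
            freq = rng.uniform(*cfg.maf_range)
            h1 = _markov_haplotypes(rng, cfg.n_samples, cfg.block_size, freq,
                                    cfg.within_block_rho)
            h2 = _markov_haplotypes(rng, cfg.n_samples, cfg.block_size, freq,
                                    cfg.within_block_rho)
            dos = (h1 + h2).astype(float)
            start = b * cfg.block_spacing + 10_000
            for k in range(cfg.block_size):
                pos = start + k * cfg.variant_spacing
                if pos > cfg.chrom_len:
                    warnings.warn("block extends past chrom_len; clipping",
                                  stacklevel=2)
                    break
                vid = f"{chrom}_b{b}_v{k}"
                alt = float(dos[:, k].sum()) / (2 * cfg.n_samples)
                variants.append(Variant(vid, chrom, pos, "A", "G",
                                        maf=min(alt, 1 - alt)))
                cols.append(dos[:, k])
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(variants, samples, np.column_stack(cols))


# ---------------------------------------------------------------------------
# splicing
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def simulate_junction_counts(
        g: GenotypeMatrix, cfg: SimConfig,
        effects: pd.DataFrame | None = None,
        batch_logit_offset: float = 0.5,
) -> tuple[pd.DataFrame, SimTruth]:
    """Junction count table with planted genotype effects on junction usage.

    ``effects`` rows are (cluster: int, junction_in_cluster: int,
    variant: id, beta: logit effect per alt allele). Each cluster is
    anchored at a genomic position near its causal (or a random) variant
    so the sQTL lies inside the junction cis-window.

    Returns a BED-like table ``chrom intron_start intron_end strand`` plus
    one count column per sample, and the truth record.
    """
    if cfg.junctions_per_cluster < 2:
        raise ValueError("clusters need >= 2 junctions")
    rng = np.random.default_rng(cfg.seed + 1)
    effects = effects if effects is not None else pd.DataFrame(
        columns=["cluster", "junction", "variant", "beta"])
    for _, r in effects.iterrows():
        if r["cluster"] >= cfg.n_clusters:
            raise ValueError(f"effect on non-existent cluster {r['cluster']}")
        if r["junction"] >= cfg.junctions_per_cluster:
            raise ValueError(f"effect on non-existent junction {r['junction']}")
        if r["variant"] not in g:
            raise ValueError(f"effect on unknown variant {r['variant']}")

    batches = np.array(cfg.batches())
    batch_names = sorted(set(batches))
    batch_off = {b: (i - (len(batch_names) - 1) / 2) * batch_logit_offset
                 for i, b in enumerate(batch_names)}

    eff_by_cluster: dict[int, list[tuple[int, str, float]]] = {}
    for _, r in effects.iterrows():
        eff_by_cluster.setdefault(int(r["cluster"]), []).append(
            (int(r["junction"]), str(r["variant"]), float(r["beta"])))

    rows = []
    counts = []
    truth_rows = []
    n = g.n_samples
    J = cfg.junctions_per_cluster
    for cl in range(cfg.n_clusters):
        cl_effects = eff_by_cluster.get(cl, [])
        if cl_effects:
            anchor = g.variants[g.index_of(cl_effects[0][1])]
        else:
            anchor = g.variants[rng.integers(g.n_variants)]
        chrom, base = anchor.chrom, anchor.pos
        # junctions share a donor site -> one leafcutter cluster
        donor = base + 500
        base_logits = rng.normal(0.0, 1.0, size=J)
        logits = np.tile(base_logits, (n, 1))
        for j_idx, vid, beta in cl_effects:
            dos = np.nan_to_num(g.column(vid), nan=float(np.nanmean(g.column(vid))))
            logits[:, j_idx] = logits[:, j_idx] + beta * dos
            truth_rows.append({"feature": f"clu{cl}_j{j_idx}", "variant": vid,
                               "beta": beta})
        for i, b in enumerate(batches):
            logits[i, 0] += batch_off[b]  # batch shifts usage of junction 0
        props = _softmax(logits)
        # NB total: gamma-poisson mixture around cluster_depth
        lam = rng.gamma(cfg.nb_dispersion,
                        cfg.cluster_depth / cfg.nb_dispersion, size=n)
        totals = rng.poisson(lam)
        cnt = np.empty((J, n), dtype=int)
        for i in range(n):
            cnt[:, i] = rng.multinomial(totals[i], props[i])
        for j_idx in range(J):
            intron_end = donor + 1000 * (j_idx + 1)
            rows.append({"junction": f"clu{cl}_j{j_idx}", "chrom": chrom,
                         "intron_start": donor, "intron_end": intron_end,
                         "strand": "+", "cluster_hint": cl})
            counts.append(cnt[j_idx])
    table = pd.DataFrame(rows)
    cmat = pd.DataFrame(np.vstack(counts), columns=g.samples,
                        index=table["junction"])
    out = pd.concat([table.set_index("junction"), cmat], axis=1).reset_index()
    truth = SimTruth(sqtl=pd.DataFrame(truth_rows,
                                       columns=["feature", "variant", "beta"]),
                     batch_offsets=batch_off)
    return out, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
        g: GenotypeMatrix, cfg: SimConfig,
        effects: pd.DataFrame | None = None,
        batch_log2_offset: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Gene count table with planted additive eQTLs on the log2 scale.

    ``effects`` rows are (gene: int, variant: id, beta: log2-units per alt
    allele, i.e. units of the residual SD when ``gene_noise_sd == 1``).
    Genes without a listed effect are null; a row with ``beta == 0`` only
    anchors the gene's TSS at that variant (no effect is planted and none
    is recorded in the truth table). Each effect gene's TSS is placed at
    its causal variant so the effect is in cis.

    Returns (counts genes x samples, gene annotation with TSS, truth).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    effects = effects if effects is not None else pd.DataFrame(
        columns=["gene", "variant", "beta"])
    for _, r in effects.iterrows():
        if r["gene"] >= cfg.n_genes:
            raise ValueError(f"effect on non-existent gene {r['gene']}")
        if r["variant"] not in g:
            raise ValueError(f"effect on unknown variant {r['variant']}")
    eff_by_gene: dict[int, tuple[str, float]] = {
        int(r["gene"]): (str(r["variant"]), float(r["beta"]))
        for _, r in effects.iterrows()}

    batches = np.array(cfg.batches())
    batch_names = sorted(set(batches))
    batch_off = {b: (i - (len(batch_names) - 1) / 2) * batch_log2_offset
                 for i, b in enumerate(batch_names)}
    boff = np.array([batch_off[b] for b in batches])

    n = g.n_samples
    lib = rng.uniform(0.5, 1.0, size=n) * 2  # 2-fold library-size spread
    rows = []
    counts = np.empty((cfg.n_genes, n), dtype=int)
    truth_rows = []
    for gi in range(cfg.n_genes):
        if gi in eff_by_gene:
            vid, beta = eff_by_gene[gi]
            anchor = g.variants[g.index_of(vid)]
            if beta == 0.0:  # anchor-only row: a genuinely null gene
                genetic = 0.0
            else:
                dos = np.nan_to_num(g.column(vid),
                                    nan=float(np.nanmean(g.column(vid))))
                genetic = beta * dos
                truth_rows.append({"feature": f"gene{gi}", "variant": vid,
                                   "beta": beta})
        else:
            anchor = g.variants[rng.integers(g.n_variants)]
            genetic = 0.0
        log2_expr = (cfg.gene_base_log2 + genetic + boff
                     + rng.normal(0.0, cfg.gene_noise_sd, size=n))
        mean = lib * (2.0 ** log2_expr)
        counts[gi] = rng.poisson(mean)
        rows.append({"gene": f"gene{gi}", "chrom": anchor.chrom,
                     "tss": anchor.pos})
    genes = pd.DataFrame(rows)
    cdf = pd.DataFrame(counts, index=genes["gene"], columns=g.samples)
    truth = SimTruth(eqtl=pd.DataFrame(truth_rows,
                                       columns=["feature", "variant", "beta"]),
                     batch_offsets=batch_off)
    return cdf, genes, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas_locus(g: GenotypeMatrix, variant_ids: Sequence[str],
                        causal: str | None, beta_gwas: float, n_gwas: int,
                        rng: np.random.Generator,
                        ridge_eps: float = 1e-4) -> GwasSummary:
    """One locus of GWAS summary statistics from the MVN z-score model.

    ``z ~ MVN(R @ lam, R)`` where R is the locus dosage correlation matrix
    and lam is zero except ``sqrt(n_gwas) * beta_gwas`` at the causal
    variant (``causal=None`` for a null locus). beta/se are back-filled
    from z using the effect-allele frequency and n.
    """
    variant_ids = list(variant_ids)
    R = ld_corr(g, variant_ids)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    lam = np.zeros(len(variant_ids))
    if causal is not None:
        if causal not in variant_ids:
            raise ValueError("causal variant not inside the locus")
        lam[variant_ids.index(causal)] = np.sqrt(n_gwas) * beta_gwas
    # ridge keeps the Cholesky stable when the panel LD is near-singular
    Rr = R + ridge_eps * np.eye(len(R))
    Rr /= 1.0 + ridge_eps
    L = np.linalg.cholesky(Rr)
    z = R @ lam + L @ rng.standard_normal(len(R))
    from scipy.stats import norm

    rows = []
    for vid, zj in zip(variant_ids, z):
        v = g.variants[g.index_of(vid)]
        dos = g.column(vid)
        f = float(np.nansum(dos) / (2 * np.sum(~np.isnan(dos))))
        f = min(max(f, 1e-3), 1 - 1e-3)
        se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_gwas)
        p = 2.0 * norm.sf(abs(zj))
        rows.append({"id": vid, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                     "alt": v.alt, "beta": zj * se, "se": se, "z": zj,
                     "p": max(p, 5e-324), "n": n_gwas, "freq": f})
    return GwasSummary(pd.DataFrame(rows))


def simulate_gwas(g: GenotypeMatrix, locus_spec: pd.DataFrame,
                  qtl_truth: SimTruth | None = None,
                  seed: int = 0, window_bp: int = 500_000,
                  ) -> tuple[dict[str, GwasSummary], SimTruth]:
    """GWAS summary statistics for a set of loci.

    ``locus_spec`` rows: (locus: id, causal: variant id or '', beta: float,
    n: int, sharing: shared|linked|distinct|null). The ``sharing`` label is
    bookkeeping copied into the truth record; the caller is responsible
    for choosing a causal variant that realizes the label relative to the
    planted QTLs.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, GwasSummary] = {}
    truth_rows = []
    for _, r in locus_spec.iterrows():
        causal = r["causal"] or None
        if causal is not None:
            v = g.variants[g.index_of(causal)]
            idx = g.window_indices(v.chrom, max(1, v.pos - window_bp),
                                   v.pos + window_bp)
        else:
            anchor = g.variants[rng.integers(g.n_variants)]
            idx = g.window_indices(anchor.chrom,
                                   max(1, anchor.pos - window_bp),
                                   anchor.pos + window_bp)
        vids = [g.variants[j].id for j in idx]
        out[r["locus"]] = simulate_gwas_locus(
            g, vids, causal, float(r["beta"]), int(r["n"]), rng)
        truth_rows.append({"locus": r["locus"], "variant": causal or "",
                           "beta": float(r["beta"]), "n": int(r["n"]),
                           "sharing": r["sharing"]})
    truth = SimTruth(gwas=pd.DataFrame(
        truth_rows, columns=["locus", "variant", "beta", "n", "sharing"]))
    return out, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(cfg: SimConfig,
                         junction_table: pd.DataFrame | None = None,
                         splice_pad: int = 8,
                         ) -> dict[str, IntervalSet]:
    """Genomic annotation tracks for enrichment tests.

    Produces mutually exclusive genic classes (splice_site, exon, intron,
    promoter), an intergenic enhancer track, plus one blacklist and one
    MHC-analog interval per genome to exercise exclusion logic. Splice
    sites take +/- ``splice_pad`` bp around every junction boundary and
    win ties over exon/intron space.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    splice: list[Interval] = []
    exon: list[Interval] = []
    intron: list[Interval] = []
    promoter: list[Interval] = []
    enhancer: list[Interval] = []

    if junction_table is not None:
        for _, r in junction_table.iterrows():
            c = r["chrom"]
            for pos in (int(r["intron_start"]), int(r["intron_end"])):
                splice.append(Interval(c, max(0, pos - 1 - splice_pad),
                                       pos + splice_pad, "splice_site"))
            intron.append(Interval(c, int(r["intron_start"]) - 1 + splice_pad,
                                   int(r["intron_end"]) - splice_pad, "intron"))
            exon.append(Interval(c, max(0, int(r["intron_start"]) - 1 - 200),
                                 max(1, int(r["intron_start"]) - 1 - splice_pad),
                                 "exon"))
            promoter.append(Interval(c, max(0, int(r["intron_start"]) - 2000),
                                     max(1, int(r["intron_start"]) - 1000),
                                     "promoter"))
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        for _ in range(5):
            s = int(rng.integers(0, max(1, cfg.chrom_len - 2000)))
            enhancer.append(Interval(chrom, s, s + 1500, "enhancer"))
    black_start = cfg.chrom_len - 200_000
    tracks = {
        "splice_site": IntervalSet(_clip_away(splice, [])),
        "exon": IntervalSet(_clip_away(exon, splice)),
        "intron": IntervalSet(_clip_away(intron, splice)),
        "promoter": promoter,
        "enhancer": IntervalSet(enhancer),
        "blacklist": IntervalSet([Interval("chr1", black_start,
                                           black_start + 100_000, "blacklist")]),
        "mhc": IntervalSet([Interval("chr1", black_start + 100_000,
                                     black_start + 200_000, "mhc_analog")]),
    }
    # promoters must not leak into splice/exon/intron space
    genic = list(tracks["splice_site"]) + list(tracks["exon"]) + list(tracks["intron"])
    tracks["promoter"] = IntervalSet(_clip_away(promoter, genic))
    return tracks


def _clip_away(intervals: list[Interval], blockers: list[Interval],
               ) -> list[Interval]:
    """Subtract blocker space from each interval (keeps leftover pieces)."""
    out: list[Interval] = []
    for iv in intervals:
        pieces = [(iv.start, iv.end)]
        for b in blockers:
            if b.chrom != iv.chrom:
                continue
            nxt = []
            for s, e in pieces:
                if b.end <= s or e <= b.start:
                    nxt.append((s, e))
                    continue
                if s < b.start:
                    nxt.append((s, b.start))
                if b.end < e:
                    nxt.append((b.end, e))
            pieces = nxt
        for s, e in pieces:
            if s < e:
                out.append(Interval(iv.chrom, s, e, iv.name))
    return _merge_same_name(out)


def _merge_same_name(ivs: list[Interval]) -> list[Interval]:
    ivs = sorted(ivs, key=lambda x: (x.chrom, x.start, x.end))
    out: list[Interval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and out[-1].name == iv.name \
                and iv.start <= out[-1].end:
            out[-1] = Interval(iv.chrom, out[-1].start,
                               max(out[-1].end, iv.end), iv.name)
        else:
            out.append(iv)
    return out
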