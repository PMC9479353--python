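"""From count tables to analysis-ready phenotype matrices.

Pipelines (order is fixed and logged by the pipeline driver):

* splicing: filter junctions -> cluster by shared splice sites -> PSI ->
  rank-inverse-normal standardization -> batch adjustment -> phenotype PCs
* expression: filter genes -> log2 CPM -> batch adjustment -> phenotype PCs

PSI (percent spliced in) is a junction's read count divided by the total
reads of its splice cluster in that sample; clusters are connected
components of the graph joining junctions that share a donor or acceptor
coordinate, mirroring intron-excision-ratio quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class JunctionTable:
    """Junction coordinates plus a junctions x samples count matrix.

    ``intron_start`` / ``intron_end`` are the 1-based first and last
    intronic bases (donor / acceptor anchors for clustering).
    """

    meta: pd.DataFrame      # index: junction id; chrom, intron_start, intron_end, strand
    counts: pd.DataFrame    # index: junction id; columns: samples

    def __post_init__(self) -> None:
        if not (self.meta.index == self.counts.index).all():
            raise ValueError("meta and counts must share the junction index")
        if (self.meta["intron_start"] >= self.meta["intron_end"]).any():
            raise ValueError("intron_start must be < intron_end")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_table(cls, table: pd.DataFrame, id_col: str = "junction",
                   ) -> "JunctionTable":
        meta_cols = ["chrom", "intron_start", "intron_end", "strand"]
        t = table.set_index(id_col)
        sample_cols = [c for c in t.columns
                       if c not in meta_cols + ["cluster_hint"]]
        return cls(t[meta_cols], t[sample_cols].astype(int))

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, junction_ids: Sequence[str]) -> "JunctionTable":
        ids = list(junction_ids)
        return JunctionTable(self.meta.loc[ids], self.counts.loc[ids])


@dataclass
class ClusterMap:
    """cluster id -> ordered junction ids, with per-sample cluster totals."""

    clusters: dict[str, list[str]]
    totals: pd.DataFrame  # index: cluster id; columns: samples

    def cluster_of(self) -> dict[str, str]:
        return {j: cid for cid, js in self.clusters.items() for j in js}


@dataclass
class PhenotypeMatrix:
    """features x samples phenotype values with per-feature cis anchors.

    ``anchors`` carries chrom plus either a TSS (expression) or a junction
    interval (splicing), and optionally the cluster id for splicing
    features.
    """

    values: pd.DataFrame   # index: feature id; columns: samples
    anchors: pd.DataFrame  # index: feature id; chrom, start, end, cluster
    kind: str              # "expression" | "splicing"

    def __post_init__(self) -> None:
        if self.kind not in ("expression", "splicing"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if not (self.values.index == self.anchors.index).all():
            raise ValueError("values and anchors must share the feature index")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def subset(self, feature_ids: Sequence[str]) -> "PhenotypeMatrix":
        ids = list(feature_ids)
        return PhenotypeMatrix(self.values.loc[ids], self.anchors.loc[ids],
                               self.kind)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_genes(counts: pd.DataFrame, min_reads: int = 5,
                 min_frac: float = 0.10,
                 groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Keep genes with >= min_reads in >= min_frac of samples in every group.

    ``groups`` assigns each sample (column) to a cohort; with None all
    samples form one group.
    """
    if groups is None:
        groups = ["all"] * counts.shape[1]
    groups = np.asarray(list(groups))
    if len(groups) != counts.shape[1]:
        raise ValueError("groups length != number of samples")
    keep = np.ones(len(counts), dtype=bool)
    for gname in pd.unique(groups):
        cols = counts.columns[groups == gname]
        if len(cols) == 0:
            raise ValueError(f"empty group {gname!r}")
        frac = (counts[cols] >= min_reads).sum(axis=1) / len(cols)
        keep &= (frac >= min_frac).values
    return counts.loc[keep]


def cpm_log2(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(counts-per-million + pseudocount), per-sample library size."""
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    return np.log2(counts.div(lib, axis=1) * 1e6 + pseudocount)


def filter_junctions(jt: JunctionTable, min_reads: int = 5,
                     min_frac: float = 0.10) -> JunctionTable:
    """Keep junctions supported by >= min_reads in >= min_frac of samples."""
    need = int(np.ceil(min_frac * jt.counts.shape[1]))
    n_ok = (jt.counts >= min_reads).sum(axis=1)
    return jt.subset(jt.counts.index[n_ok >= need])


def cluster_junctions(jt: JunctionTable, min_cluster_reads: int = 30,
                      max_intron_bp: int = 500_000,
                      per_sample_reads: bool = False) -> ClusterMap:
    """Group junctions sharing a donor or acceptor into splice clusters.

    Junctions longer than ``max_intron_bp`` are removed first. Clusters
    are connected components over shared (chrom, strand, coordinate)
    anchors; single-junction clusters and clusters whose reads total less
    than ``min_cluster_reads`` (summed over samples by default, or
    required in every sample when ``per_sample_reads``) are dropped.
    """
    meta = jt.meta
    length = meta["intron_end"] - meta["intron_start"] + 1
    ids = [j for j in meta.index if length[j] <= max_intron_bp]

    parent = {j: j for j in ids}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    anchor_owner: dict[tuple, str] = {}
    for j in ids:
        r = meta.loc[j]
        for coord in (int(r["intron_start"]), int(r["intron_end"])):
            key = (r["chrom"], r["strand"], coord)
            if key in anchor_owner:
                union(anchor_owner[key], j)
            else:
                anchor_owner[key] = j

    comps: dict[str, list[str]] = {}
    for j in ids:
        comps.setdefault(find(j), []).append(j)

    clusters: dict[str, list[str]] = {}
    totals_rows = []
    # deterministic cluster numbering by genomic order of the first junction
    ordered = sorted(comps.values(),
                     key=lambda js: (meta.loc[js[0], "chrom"],
                                     int(meta.loc[js[0], "intron_start"])))
    k = 0
    for js in ordered:
        if len(js) < 2:
            continue
        sub = jt.counts.loc[js]
        if per_sample_reads:
            if (sub.sum(axis=0) < min_cluster_reads).any():
                continue
        elif sub.values.sum() < min_cluster_reads:
            continue
        cid = f"cluster_{k}"
        k += 1
        clusters[cid] = sorted(js, key=lambda j: (int(meta.loc[j, "intron_start"]),
                                                  int(meta.loc[j, "intron_end"])))
        totals_rows.append(pd.Series(sub.sum(axis=0), name=cid))
    totals = (pd.DataFrame(totals_rows) if totals_rows
              else pd.DataFrame(columns=jt.samples))
    return ClusterMap(clusters, totals)


def compute_psi(jt: JunctionTable, cm: ClusterMap,
                max_missing_frac: float = 0.5) -> PhenotypeMatrix:
    """Junction usage ratios: count / per-sample cluster total.

    Samples where the cluster total is 0 get missing values (nan), not 0.
    Features missing in more than ``max_missing_frac`` of samples are
    dropped, as are features constant across samples.
    """
    rows = []
    anchor_rows = []
    for cid, js in cm.clusters.items():
        tot = jt.counts.loc[js].sum(axis=0).astype(float)
        tot[tot == 0] = np.nan
        for j in js:
            psi = jt.counts.loc[j] / tot
            if psi.isna().mean() > max_missing_frac:
                continue
            non_na = psi.dropna()
            if len(non_na) == 0 or non_na.nunique() == 1:
                continue
            rows.append(pd.Series(psi, name=j))
            m = jt.meta.loc[j]
            anchor_rows.append({"feature": j, "chrom": m["chrom"],
                                "start": int(m["intron_start"]),
                                "end": int(m["intron_end"]), "cluster": cid})
    values = pd.DataFrame(rows) if rows else pd.DataFrame(columns=jt.samples)
    anchors = (pd.DataFrame(anchor_rows).set_index("feature")
               if anchor_rows else
               pd.DataFrame(columns=["chrom", "start", "end", "cluster"]))
    return PhenotypeMatrix(values, anchors, "splicing")


def expression_phenotypes(log_expr: pd.DataFrame,
                          gene_anno: pd.DataFrame) -> PhenotypeMatrix:
    """Wrap a normalized expression matrix with TSS anchors.

    ``gene_anno`` needs columns gene, chrom, tss.
    """
    anno = gene_anno.set_index("gene").loc[log_expr.index]
    anchors = pd.DataFrame({"chrom": anno["chrom"],
                            "start": anno["tss"].astype(int),
                            "end": anno["tss"].astype(int),
                            "cluster": ""})
    return PhenotypeMatrix(log_expr.copy(), anchors, "expression")


# ---------------------------------------------------------------------------
# standardization / batch adjustment / PCs
# ---------------------------------------------------------------------------

def rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """Phi^-1((rank - 0.5) / n) with average ranks for ties.

    Missing values are imputed at the median before ranking (so they land
    near zero after the transform).
    """
    x = np.asarray(x, dtype=float)
    out = x.copy()
    miss = np.isnan(out)
    if miss.all():
        raise ValueError("all-missing feature")
    if miss.any():
        out[miss] = np.nanmedian(out)
    ranks = pd.Series(out).rank(method="average").to_numpy()
    return norm.ppf((ranks - 0.5) / len(out))


def standardize(pm: PhenotypeMatrix) -> PhenotypeMatrix:
    """Per-feature rank-based inverse-normal transform."""
    vals = np.vstack([rank_inverse_normal(row)
                      for row in pm.values.to_numpy()])
    return PhenotypeMatrix(pd.DataFrame(vals, index=pm.values.index,
                                        columns=pm.values.columns),
                           pm.anchors, pm.kind)


def batch_adjust(pm: PhenotypeMatrix, batches: Sequence[str],
                 ) -> PhenotypeMatrix:
    """Location-scale batch adjustment per feature.

    Each batch is centered at the overall feature mean and rescaled so its
    SD matches the pooled (residual) SD. A simpler surrogate for
    empirical-Bayes batch correction that removes additive and scale batch
    structure exactly.
    """
    batches = np.asarray(list(batches))
    if len(batches) != pm.values.shape[1]:
        raise ValueError("batches length != number of samples")
    X = pm.values.to_numpy(dtype=float).copy()
    grand = np.nanmean(X, axis=1, keepdims=True)
    resid_sd = np.zeros(X.shape[0])
    masks = [batches == b for b in pd.unique(batches)]
    # pooled within-batch SD
    ss, nn = np.zeros(X.shape[0]), np.zeros(X.shape[0])
    for m in masks:
        sub = X[:, m]
        mu = np.nanmean(sub, axis=1, keepdims=True)
        ss += np.nansum((sub - mu) ** 2, axis=1)
        nn += np.sum(~np.isnan(sub), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid_sd = np.sqrt(ss / np.maximum(nn - len(masks), 1))
    for m in masks:
        sub = X[:, m]
        mu = np.nanmean(sub, axis=1, keepdims=True)
        sd = np.nanstd(sub, axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X[:, m] = (sub - mu) / sd * resid_sd[:, None] + grand
    return PhenotypeMatrix(pd.DataFrame(X, index=pm.values.index,
                                        columns=pm.values.columns),
                           pm.anchors, pm.kind)


def phenotype_pcs(pm: PhenotypeMatrix, k: int) -> pd.DataFrame:
    """Top-k principal component sample scores of the phenotype matrix.

    Features are standardized first; missing values are imputed at the
    feature mean. Sign convention: the largest-|loading| element of each
    component is positive. Returns samples x k DataFrame (PC1..PCk).
    """
    X = pm.values.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    Z = np.where(np.isnan(Z), 0.0, Z)
    rank = np.linalg.matrix_rank(Z)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    # samples are observations: svd of Z.T (n_samples x n_features)
    U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for c in range(k):
        load = Vt[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1
    return pd.DataFrame(scores, index=pm.values.columns,
                        columns=[f"PC{i + 1}" for i in range(k)])


def build_covariates(*parts: pd.DataFrame | pd.Series,
                     drop_collinear: bool = True) -> pd.DataFrame:
    """Column-bind covariate blocks on the shared sample index.

    Categorical columns are expanded to indicator columns (first level
    dropped); collinear columns are removed to keep full column rank.
    """
    frames = []
    for p in parts:
        if isinstance(p, pd.Series):
            p = p.to_frame()
        expanded = []
        for col in p.columns:
            s = p[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                d = pd.get_dummies(s, prefix=col, drop_first=True).astype(float)
                expanded.append(d)
            else:
                expanded.append(s.astype(float).to_frame())
        frames.append(pd.concat(expanded, axis=1))
    cov = pd.concat(frames, axis=1)
    if cov.isna().any().any():
        raise ValueError("covariates contain missing values")
    if drop_collinear:
        keep: list[str] = []
        X = np.ones((len(cov), 1))
        for col in cov.columns:
            cand = np.column_stack([X, cov[col].to_numpy()])
            if np.linalg.matrix_rank(cand) > X.shape[1]:
                keep.append(col)
                X = cand
        cov = cov[keep]
    return cov
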