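"""LD-matched control-variant permutation null for inflation and enrichment.

QTL variants cluster in LD blocks, so naive QQ comparisons against all
genome variants overstate GWAS-signal inflation. The null built here
mimics a query set's regional footprint: the genome is tiled into
approximately independent LD blocks; the per-block spans occupied by the
query variants are re-placed uniformly at random outside excluded regions
(query-bearing blocks, blacklist, MHC-analog), and an equal number of
candidate variants is sampled from the placed intervals. Repeating B
times yields a per-rank envelope for QQ plots and a matched expectation
for annotation fold enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (GenotypeMatrix, GwasSummary, Interval, IntervalSet,
                      pearson_r2)


# ---------------------------------------------------------------------------
# LD blocks
# ---------------------------------------------------------------------------

def infer_ld_blocks(g: GenotypeMatrix, r2_break: float = 0.1,
                    lookback: int = 50) -> IntervalSet:
    """Greedy left-to-right partition of each chromosome into LD blocks.

    A new block opens when the maximum r^2 between a variant and the
    previous ``lookback`` variants falls below ``r2_break``. Blocks tile
    each chromosome end to end (0-based half-open intervals).
    """
    X = g.dosage.copy()
    mean = np.nanmean(X, axis=0)
    miss = np.where(np.isnan(X))
    X[miss] = np.take(mean, miss[1])
    sd = X.std(axis=0)
    sd[sd == 0] = np.nan
    Z = (X - X.mean(axis=0)) / sd

    intervals: list[Interval] = []
    by_chrom: dict[str, list[int]] = {}
    for j, v in enumerate(g.variants):
        by_chrom.setdefault(v.chrom, []).append(j)
    for chrom, idx in by_chrom.items():
        idx = sorted(idx, key=lambda j: g.variants[j].pos)
        starts = [0]  # index into idx where each block starts
        for k in range(1, len(idx)):
            lo = max(0, k - lookback)
            zk = Z[:, idx[k]]
            prev = Z[:, [idx[m] for m in range(lo, k)]]
            with np.errstate(invalid="ignore"):
                r = (prev.T @ zk) / len(zk)
            max_r2 = np.nanmax(r ** 2) if len(r) else 0.0
            if np.isnan(max_r2):
                max_r2 = 0.0
            if max_r2 < r2_break:
                starts.append(k)
        bounds = starts + [len(idx)]
        chrom_end = g.variants[idx[-1]].pos
        for bi in range(len(starts)):
            first = g.variants[idx[bounds[bi]]].pos
            last = (g.variants[idx[bounds[bi + 1] - 1]].pos
                    if bi + 1 < len(bounds) else chrom_end)
            # tile: block runs to the start of the next block
            start0 = 0 if bi == 0 else intervals_end
            if bi + 1 < len(starts):
                nxt = g.variants[idx[bounds[bi + 1]]].pos
                end0 = (last + nxt) // 2
            else:
                end0 = last
            intervals_end = end0
            intervals.append(Interval(chrom, start0, max(end0, start0 + 1),
                                      f"{chrom}_block{bi}"))
    return IntervalSet(intervals)


# ---------------------------------------------------------------------------
# control sets
# ---------------------------------------------------------------------------

@dataclass
class ControlSets:
    """B variant-id sets matched to a query's size and regional footprint."""

    sets: list[list[str]]
    seed: int
    span_sizes: list[int]

    def __len__(self) -> int:
        return len(self.sets)


def _query_spans(query_ids: list[str], g: GenotypeMatrix,
                 blocks: IntervalSet,
                 ) -> tuple[list[tuple[int, int]], list[Interval]]:
    """Per-block (span bp, variant count) of the query, and its blocks."""
    pos_by_block: dict[Interval, list[int]] = {}
    for vid in query_ids:
        v = g.variants[g.index_of(vid)]
        hits = blocks.overlapping(Interval(v.chrom, v.pos - 1, v.pos, vid))
        for b in hits:
            pos_by_block.setdefault(b, []).append(v.pos)
    spans = [(max(ps) - min(ps) + 1, len(ps))
             for ps in pos_by_block.values()]
    return spans, list(pos_by_block.keys())


def build_control_sets(query_ids: list[str], g: GenotypeMatrix,
                       blocks: IntervalSet, exclude: IntervalSet,
                       B: int = 1000, seed: int = 0,
                       chrom_len: dict[str, int] | None = None,
                       max_retries: int = 100) -> ControlSets:
    """B control sets of |query| variants drawn from shuffled regions.

    Per permutation: the query's per-block spans are placed uniformly at
    random (non-overlapping, outside query-bearing blocks, blacklist and
    MHC-analog exclusions); candidate variants inside the placed intervals
    are pooled and |query| of them sampled without replacement.
    """
    rng = np.random.default_rng(seed)
    query = set(query_ids)
    spans, query_blocks = _query_spans(query_ids, g, blocks)
    excl = exclude.union(IntervalSet(query_blocks))
    if chrom_len is None:
        chrom_len = {}
        for v in g.variants:
            chrom_len[v.chrom] = max(chrom_len.get(v.chrom, 0), v.pos)
    chroms = sorted(chrom_len)
    # candidate pool: variants outside excluded space and outside the query
    pool = [(v.id, v.chrom, v.pos) for v in g.variants
            if v.id not in query and not excl.covers_pos(v.chrom, v.pos)]
    pool_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for c in chroms:
        ps = np.array([p for _, cc, p in pool if cc == c])
        ids = [i for i, cc, _ in pool if cc == c]
        order = np.argsort(ps)
        pool_by_chrom[c] = (ps[order], [ids[k] for k in order])

    k = len(query_ids)
    if sum(len(ids) for _, ids in pool_by_chrom.values()) < k:
        raise RuntimeError(
            "candidate pool smaller than the query; the simulated genome "
            "is too small for the requested query footprint")
    # flat candidate list for anchoring placements on variant-bearing space
    anchors = [(c, p) for c in chroms
               for p in pool_by_chrom[c][0]]

    def block_candidates(iv: Interval) -> list[str]:
        cand: list[str] = []
        for blk in blocks.overlapping(iv):
            ps, ids = pool_by_chrom.get(blk.chrom, (np.empty(0), []))
            lo = np.searchsorted(ps, blk.start + 1)
            hi = np.searchsorted(ps, blk.end, side="right")
            cand.extend(ids[lo:hi])
        return sorted(set(cand))

    sets: list[list[str]] = []
    for _ in range(B):
        for attempt in range(max_retries):
            placed: list[Interval] = []
            used_blocks: list[Interval] = []
            chosen: list[str] = []
            ok = True
            for span, n_in_span in spans:
                placed_one = False
                for _try in range(50):
                    # anchor the shuffled region on a random pool variant so
                    # it is guaranteed to contain candidates
                    c, pos = anchors[rng.integers(len(anchors))]
                    offset = int(rng.integers(0, span))
                    s = max(0, int(pos) - 1 - offset)
                    iv = Interval(c, s, s + span, "ctrl")
                    if excl.overlapping(iv):
                        continue
                    if any(iv.overlaps(p) for p in placed):
                        continue
                    # distinct independent LD regions per shuffled span,
                    # so the control set matches the query's block count
                    landed = blocks.overlapping(iv)
                    if any(b in used_blocks for b in landed):
                        continue
                    # sampling pool: candidates in the LD blocks the
                    # region landed in (blocks carry the variants)
                    cand = [v for v in block_candidates(iv)
                            if v not in chosen]
                    if len(cand) < n_in_span:
                        continue
                    pick = rng.choice(len(cand), size=n_in_span,
                                      replace=False)
                    chosen.extend(cand[i] for i in sorted(pick))
                    placed.append(iv)
                    used_blocks.extend(landed)
                    placed_one = True
                    break
                if not placed_one:
                    ok = False
                    break
            if ok and len(chosen) == k:
                sets.append(chosen)
                break
        else:
            raise RuntimeError(
                "control-set placement failed repeatedly; the simulated "
                "genome is too small for the requested query footprint")
    return ControlSets(sets, seed, [s for s, _ in spans])


# ---------------------------------------------------------------------------
# QQ inflation
# ---------------------------------------------------------------------------

@dataclass
class QqResult:
    """Observed vs expected -log10 p quantiles with a control envelope."""

    observed: np.ndarray
    expected: np.ndarray
    env_lo: np.ndarray
    env_hi: np.ndarray
    enriched: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rank": np.arange(1, len(self.observed) + 1),
                             "expected": self.expected,
                             "observed": self.observed,
                             "env_lo": self.env_lo, "env_hi": self.env_hi})


def _neglog_sorted(p: np.ndarray, n_out: int) -> np.ndarray:
    """Descending -log10 p, linearly interpolated onto n_out ranks."""
    obs = -np.log10(np.sort(np.asarray(p, dtype=float)))
    if len(obs) == n_out:
        return obs
    src = (np.arange(len(obs)) + 0.5) / len(obs)
    dst = (np.arange(n_out) + 0.5) / n_out
    return np.interp(dst, src, obs)


def qq_inflation(query_ids: list[str], gwas: GwasSummary,
                 controls: ControlSets, g: GenotypeMatrix,
                 maf_min: float = 0.05, top_decile_frac: float = 0.10,
                 ) -> QqResult:
    """QQ comparison of a query variant set's GWAS p-values vs matched controls.

    Variants are restricted to MAF >= ``maf_min``. The enrichment flag is
    true when at least ``top_decile_frac`` of the top-decile ranks exceed
    the 97.5th-percentile control envelope.
    """
    maf = {v.id: v.maf for v in g.variants}
    pmap = dict(zip(gwas.table["id"], gwas.table["p"]))

    def pvals(ids: list[str]) -> np.ndarray:
        return np.array([pmap[i] for i in ids
                         if i in pmap and maf.get(i, 0) >= maf_min])

    p_obs = pvals(query_ids)
    if len(p_obs) == 0:
        raise ValueError("no query variant passes the MAF filter / GWAS overlap")
    n = len(p_obs)
    observed = _neglog_sorted(p_obs, n)  # descending, like expected
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    ctrl = []
    for s in controls.sets:
        pc = pvals(s)
        if len(pc):
            ctrl.append(_neglog_sorted(pc, n))
    ctrl_arr = np.vstack(ctrl)
    env_lo = np.percentile(ctrl_arr, 2.5, axis=0)
    env_hi = np.percentile(ctrl_arr, 97.5, axis=0)
    top = max(1, int(np.ceil(n * 0.10)))
    exceed = np.mean(observed[:top] > env_hi[:top])
    return QqResult(observed, expected, env_lo, env_hi,
                    bool(exceed >= top_decile_frac))


# ---------------------------------------------------------------------------
# annotation fold enrichment
# ---------------------------------------------------------------------------

def _hits(ids: list[str], annotation: IntervalSet, g: GenotypeMatrix,
          r2_proxy: float, ld_window_bp: int) -> int:
    """Count variants hitting the annotation directly or via an LD proxy."""
    count = 0
    for vid in ids:
        v = g.variants[g.index_of(vid)]
        if annotation.covers_pos(v.chrom, v.pos):
            count += 1
            continue
        idx = g.window_indices(v.chrom, max(1, v.pos - ld_window_bp),
                               v.pos + ld_window_bp)
        dos = g.column(vid)
        hit = False
        for j in idx:
            u = g.variants[j]
            if u.id == vid or not annotation.covers_pos(u.chrom, u.pos):
                continue
            r2 = pearson_r2(dos, g.dosage[:, j])
            if not np.isnan(r2) and r2 >= r2_proxy:
                hit = True
                break
        count += hit
    return count


def annotation_fold_enrichment(query_ids: list[str], annotation: IntervalSet,
                               g: GenotypeMatrix, controls: ControlSets,
                               r2_proxy: float = 0.7,
                               ld_window_bp: int = 50_000,
                               ) -> dict[str, float]:
    """Fold enrichment of a lead set in an annotation vs matched controls.

    A lead hits the annotation if it, or any variant with r^2 >=
    ``r2_proxy`` within ``ld_window_bp``, overlaps an interval. Returns
    fold = observed / mean(control hits) and the one-sided empirical p
    ``(#controls >= observed + 1) / (B + 1)``.
    """
    obs = _hits(query_ids, annotation, g, r2_proxy, ld_window_bp)
    ctrl = np.array([_hits(s, annotation, g, r2_proxy, ld_window_bp)
                     for s in controls.sets], dtype=float)
    mean_ctrl = ctrl.mean() if len(ctrl) else float("nan")
    fold = obs / mean_ctrl if mean_ctrl > 0 else float("inf")
    p_emp = (np.sum(ctrl >= obs) + 1) / (len(ctrl) + 1)
    return {"observed": float(obs), "expected": float(mean_ctrl),
            "fold": float(fold), "p_empirical": float(p_emp)}
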