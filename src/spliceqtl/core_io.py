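"""Core data containers and file IO shared by every analysis stage.

Conventions
-----------
Variant positions are 1-based (VCF native). Genomic intervals are stored
0-based half-open (BED native); :func:`interval_to_1based` /
:func:`interval_from_1based` centralize the conversion. Dosages live in
``{0, 1, 2, nan}``; missing dosages are mean-imputed *inside* regression
and LD computations only, never in the stored matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with QC metadata.

    ``maf`` is the minor-allele frequency (min of alt frequency and its
    complement) over non-missing genotypes; ``missing_rate`` the fraction
    of samples with no genotype call.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float = float("nan")
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id}: ref == alt ({self.ref})")
        if not math.isnan(self.maf) and not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")


class GenotypeMatrix:
    """samples x variants dosage matrix with variant metadata.

    ``dosage[i, j]`` is the alt-allele count of sample ``i`` at variant
    ``j`` (0, 1, 2 or nan for missing).
    """

    def __init__(self, variants: Sequence[Variant], samples: Sequence[str],
                 dosage: np.ndarray):
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} != (n_samples={len(samples)}, "
                f"n_variants={len(variants)})")
        self.variants = list(variants)
        self.samples = list(samples)
        self.dosage = dosage
        self._index = {v.id: j for j, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            seen: set[str] = set()
            for v in self.variants:
                if v.id in seen:
                    raise ValueError(f"duplicate variant id: {v.id}")
                seen.add(v.id)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self._index[variant_id]]

    def index_of(self, variant_id: str) -> int:
        return self._index[variant_id]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix([self.variants[j] for j in keep], self.samples,
                              self.dosage[:, keep])

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        g = GenotypeMatrix.__new__(GenotypeMatrix)
        g.samples = [self.samples[i] for i in keep]
        g.dosage = self.dosage[keep, :]
        stats = variant_stats_array(g.dosage)
        g.variants = [
            Variant(v.id, v.chrom, v.pos, v.ref, v.alt,
                    maf=stats["maf"][j], missing_rate=stats["missing_rate"][j])
            for j, v in enumerate(self.variants)]
        g._index = dict(self._index)
        return g

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=int)

    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    def window_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of variants with 1-based pos in [start, end] on chrom."""
        pos = self.positions()
        on = np.array([v.chrom == chrom for v in self.variants])
        return np.nonzero(on & (pos >= start) & (pos <= end))[0]


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval {self.name}: start {self.start} >= end {self.end}")

    def contains_pos(self, chrom: str, pos_1based: int) -> bool:
        return self.chrom == chrom and self.start < pos_1based <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return (self.chrom == other.chrom and self.start < other.end
                and other.start < self.end)


class IntervalSet:
    """Sorted collection of half-open intervals supporting overlap queries."""

    def __init__(self, intervals: Iterable[Interval] = ()):  # noqa: D401
        self.intervals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[Interval]]] = {}
        for iv in self.intervals:
            self._by_chrom.setdefault(iv.chrom, ([], [], []))  # type: ignore[arg-type]
        tmp: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            tmp.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in tmp.items():
            starts = np.array([iv.start for iv in ivs], dtype=int)
            ends = np.array([iv.end for iv in ivs], dtype=int)
            self._by_chrom[chrom] = (starts, ends, ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def covers_pos(self, chrom: str, pos_1based: int) -> bool:
        """True if the 1-based position falls inside any interval."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends, _ = entry
        # half-open: base pos (1-based) is covered iff start < pos <= end
        return bool(np.any((starts < pos_1based) & (pos_1based <= ends)))

    def overlapping(self, query: Interval) -> list[Interval]:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return []
        starts, ends, ivs = entry
        hit = (starts < query.end) & (query.start < ends)
        return [ivs[i] for i in np.nonzero(hit)[0]]

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self.intervals) + list(other.intervals))


def interval_to_1based(iv: Interval) -> tuple[str, int, int]:
    """Half-open 0-based interval -> inclusive 1-based (chrom, first, last)."""
    return iv.chrom, iv.start + 1, iv.end


def interval_from_1based(chrom: str, first: int, last: int, name: str = ".") -> Interval:
    """Inclusive 1-based coordinates -> half-open 0-based interval."""
    return Interval(chrom, first - 1, last, name)


GWAS_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "beta", "se", "z", "p", "n", "freq"]


class GwasSummary:
    """Per-variant GWAS summary statistics table.

    Wraps a DataFrame with columns ``id chrom pos ref alt beta se z p n
    freq``; ``z`` is filled from ``beta/se`` when absent.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        missing = [c for c in ("id", "chrom", "pos", "p") if c not in table.columns]
        if missing:
            raise ValueError(f"GWAS summary missing required column(s): {missing}")
        if "z" not in table.columns or table["z"].isna().all():
            if "beta" not in table.columns or "se" not in table.columns:
                raise ValueError("GWAS summary needs z, or beta and se to derive it")
            table["z"] = table["beta"] / table["se"]
        if "se" in table.columns and (table["se"].dropna() < 0).any():
            raise ValueError("negative se in GWAS summary")
        for col in GWAS_COLUMNS:
            if col not in table.columns:
                table[col] = np.nan
        bad_p = table["p"].dropna()
        if ((bad_p <= 0) | (bad_p > 1)).any():
            raise ValueError("GWAS p-values must lie in (0, 1]")
        both = table.dropna(subset=["beta", "se", "z"])
        if len(both):
            dev = np.abs(both["z"] - both["beta"] / both["se"])
            if (dev > 1e-6 * np.maximum(1.0, np.abs(both["z"]))).any():
                raise ValueError("z inconsistent with beta/se")
        self.table = table[GWAS_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def subset_ids(self, ids: Sequence[str]) -> "GwasSummary":
        keep = self.table[self.table["id"].isin(set(ids))]
        return GwasSummary(keep.reset_index(drop=True))

    def lookup(self, variant_id: str) -> pd.Series:
        rows = self.table[self.table["id"] == variant_id]
        if rows.empty:
            raise KeyError(variant_id)
        return rows.iloc[0]


@dataclass
class LdMatrix:
    """Squared-correlation (r^2) matrix over a set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 shape does not match variant count")

    def value(self, a: str, b: str) -> float:
        i = self.variant_ids.index(a)
        j = self.variant_ids.index(b)
        return float(self.r2[i, j])


# ---------------------------------------------------------------------------
# per-variant statistics and QC
# ---------------------------------------------------------------------------

def variant_stats_array(dosage: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized per-variant maf / missing-rate / genotype counts.

    ``maf`` is nan for all-missing variants.
    """
    dosage = np.asarray(dosage, dtype=float)
    n = dosage.shape[0]
    miss = np.isnan(dosage)
    n_obs = n - miss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.nansum(dosage, axis=0) / (2.0 * n_obs)
    alt_freq = np.where(n_obs == 0, np.nan, alt_freq)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    counts = {
        "n_homref": np.nansum(dosage == 0, axis=0).astype(int),
        "n_het": np.nansum(dosage == 1, axis=0).astype(int),
        "n_homalt": np.nansum(dosage == 2, axis=0).astype(int),
    }
    return {
        "maf": maf,
        "alt_freq": alt_freq,
        "missing_rate": miss.sum(axis=0) / float(n),
        **counts,
    }


def variant_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant QC statistics table (maf, missing rate, genotype counts)."""
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    stats = variant_stats_array(g.dosage)
    return pd.DataFrame({
        "id": [v.id for v in g.variants],
        "chrom": [v.chrom for v in g.variants],
        "pos": [v.pos for v in g.variants],
        "maf": stats["maf"],
        "alt_freq": stats["alt_freq"],
        "missing_rate": stats["missing_rate"],
        "n_homref": stats["n_homref"],
        "n_het": stats["n_het"],
        "n_homalt": stats["n_homalt"],
    })


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed table (two-sided by probability mass). Monomorphic
    sites return 1.0.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_homref, n_homalt) + n_het
    if n_rare == 0:
        return 1.0

    # log P(het = h | allele counts) up to a shared constant, h stepping by 2
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (hets * math.log(2.0)
            - _lgamma_arr(hets + 1) - _lgamma_arr(rare_hom + 1)
            - _lgamma_arr(common_hom + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = np.nonzero(hets == n_het)[0]
    if len(obs) == 0:  # parity mismatch cannot happen with valid counts
        raise ValueError("observed het count incompatible with allele counts")
    p_obs = prob[obs[0]]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln
    return gammaln(np.asarray(x, dtype=float))


def qc_filter_variants(g: GenotypeMatrix, maf_min: float = 0.01,
                       miss_max: float = 0.05, hwe_min: float = 1e-6,
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants failing MAF / missingness / HWE thresholds.

    Kept variants satisfy ``maf >= maf_min``, ``missing_rate < miss_max``
    and HWE exact p ``> hwe_min``. The removal report lists each dropped
    variant with the first failing rule in the order MAF, missingness, HWE.
    """
    for thr in (maf_min, miss_max, hwe_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    stats = variant_stats(g)
    removed: list[tuple[str, str]] = []
    keep: list[int] = []
    for j, row in stats.iterrows():
        maf = row["maf"]
        if np.isnan(maf) or maf < maf_min:
            removed.append((row["id"], "maf"))
            continue
        if row["missing_rate"] >= miss_max:
            removed.append((row["id"], "missingness"))
            continue
        p_hwe = hwe_exact_test(int(row["n_homref"]), int(row["n_het"]),
                               int(row["n_homalt"]))
        if p_hwe <= hwe_min:
            removed.append((row["id"], "hwe"))
            continue
        keep.append(int(j))
    if not keep:
        warnings.warn("QC removed every variant", stacklevel=2)
    report = pd.DataFrame(removed, columns=["id", "reason"])
    return g.subset_variants(keep), report


def drop_duplicate_samples(g: GenotypeMatrix, r_max: float = 0.95,
                           ) -> tuple[GenotypeMatrix, list[str]]:
    """Remove the later member of any sample pair with dosage correlation > r_max.

    A lightweight stand-in for relatedness QC appropriate to simulated
    panels without pedigree structure.
    """
    x = np.array(g.dosage, dtype=float)
    col_mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(col_mean, idx[1])
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((x ** 2).sum(axis=1))
    norm[norm == 0] = 1.0
    xn = x / norm[:, None]
    corr = xn @ xn.T
    dropped: list[str] = []
    keep: list[int] = []
    for i in range(g.n_samples):
        if any(corr[i, k] > r_max for k in keep):
            dropped.append(g.samples[i])
        else:
            keep.append(i)
    if not dropped:
        return g, []
    return g.subset_samples(keep), dropped


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def _impute_mean(cols: np.ndarray) -> np.ndarray:
    cols = np.array(cols, dtype=float)
    if cols.ndim == 1:
        cols = cols[:, None]
    mean = np.nanmean(cols, axis=0)
    idx = np.where(np.isnan(cols))
    cols[idx] = np.take(mean, idx[1])
    return cols


def pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation over samples non-missing in both columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_r2(g: GenotypeMatrix, focal: str, window_bp: int = 1_000_000,
          ) -> dict[str, float]:
    """r^2 between a focal variant and all variants within +/- window_bp.

    Zero-variance columns yield nan. The focal variant itself is included
    (r^2 = 1 unless it has zero variance).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if focal not in g:
        raise KeyError(f"focal variant {focal} not in genotype matrix")
    jf = g.index_of(focal)
    vf = g.variants[jf]
    idx = g.window_indices(vf.chrom, max(1, vf.pos - window_bp), vf.pos + window_bp)
    out: dict[str, float] = {}
    a = g.dosage[:, jf]
    for j in idx:
        out[g.variants[j].id] = pearson_r2(a, g.dosage[:, j])
    return out


def ld_matrix(g: GenotypeMatrix, variant_ids: Sequence[str]) -> LdMatrix:
    """Pairwise r^2 over a variant list (mean-imputed missing dosages)."""
    cols = _impute_mean(np.column_stack([g.column(v) for v in variant_ids]))
    sd = cols.std(axis=0)
    sd[sd == 0] = np.nan
    z = (cols - cols.mean(axis=0)) / sd
    r = (z.T @ z) / len(cols)
    return LdMatrix(list(variant_ids), r ** 2)


def ld_corr(g: GenotypeMatrix, variant_ids: Sequence[str]) -> np.ndarray:
    """Signed dosage correlation matrix (for conditional analysis / simulation)."""
    cols = _impute_mean(np.column_stack([g.column(v) for v in variant_ids]))
    sd = cols.std(axis=0)
    sd[sd == 0] = np.nan
    z = (cols - cols.mean(axis=0)) / sd
    return (z.T @ z) / len(cols)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def load_genotypes(path: str) -> tuple[GenotypeMatrix, int]:
    """Read a VCF into a GenotypeMatrix; returns (matrix, n_skipped).

    Accepts GT or DS fields (GT preferred); multiallelic records are
    skipped and counted. Duplicate variant ids raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    variants: list[Variant] = []
    columns: list[np.ndarray] = []
    skipped = 0
    seen: set[str] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        if vid in seen:
            raise ValueError(f"duplicate variant id: {vid}")
        seen.add(vid)
        gts = rec.genotype.array()  # alleles + phase flag
        alleles = gts[:, :-1].astype(float)
        alleles[alleles < 0] = np.nan
        dos = alleles.sum(axis=1)
        columns.append(dos)
        st = variant_stats_array(dos[:, None])
        variants.append(Variant(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
                                maf=float(st["maf"][0]),
                                missing_rate=float(st["missing_rate"][0])))
    if skipped:
        warnings.warn(f"skipped {skipped} multiallelic record(s)", stacklevel=2)
    dosage = (np.column_stack(columns) if columns
              else np.empty((len(samples), 0)))
    return GenotypeMatrix(variants, samples, dosage), skipped


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT genotypes, sorted by (chrom, pos)."""
    order = sorted(range(g.n_variants),
                   key=lambda j: (g.variants[j].chrom, g.variants[j].pos,
                                  g.variants[j].id))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({v.chrom for v in g.variants})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in order:
            v = g.variants[j]
            gts = [code.get(d, "./.") if not np.isnan(d) else "./."
                   for d in g.dosage[:, j]]
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def load_intervals(path: str) -> IntervalSet:
    """Read BED3+ (0-based half-open); column 4 is the interval name."""
    ivs: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            name = parts[3] if len(parts) > 3 else "."
            ivs.append(Interval(parts[0], int(parts[1]), int(parts[2]), name))
    return IntervalSet(ivs)


def write_intervals(ivs: IntervalSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def load_gwas_summary(path: str) -> GwasSummary:
    """Read a TSV of GWAS summary statistics (header contract: GWAS_COLUMNS)."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GwasSummary(table)


def write_gwas_summary(gwas: GwasSummary, path: str) -> None:
    out = gwas.table.sort_values(["chrom", "pos", "id"]).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
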