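"""End-to-end synthetic demonstration pipeline with caching and a manifest.

Stages (fixed order): simulate -> phenotypes -> qtl -> finemap -> coloc ->
twas -> integrate -> report. Each stage writes plain TSV/VCF/BED outputs
into the run directory; the manifest records parameters, seeds, package
version and a content hash per stage, and unchanged stages are skipped on
rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cis_qtl, colocalization, fine_mapping, integration, twas
from .core_io import GenotypeMatrix, GwasSummary, write_intervals, write_vcf
from .phenotype_quant import (JunctionTable, batch_adjust, build_covariates,
                              cluster_junctions, compute_psi, cpm_log2,
                              expression_phenotypes, filter_genes,
                              filter_junctions, phenotype_pcs, standardize)
from .synthetic_data import (SimConfig, simulate_annotations,
                             simulate_expression, simulate_genotypes,
                             simulate_gwas, simulate_junction_counts)

log = logging.getLogger("spliceqtl.pipeline")

STAGES = ["simulate", "phenotypes", "qtl", "finemap", "coloc", "twas",
          "integrate", "report"]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, named after their defaults."""

    out_dir: str = "run"
    seed: int = 0
    fdr: float = 0.01
    cis_window_e: int = 500_000
    cis_window_s: int = 50_000
    perms: int = 1000
    coloc_pp: float = 0.8
    twas_gate: float = 0.6
    credible_level: float = 0.95
    maf_min: float = 0.01
    qq_maf: float = 0.05
    pcs_expression: int = 5
    pcs_splicing: int = 3
    n_samples: int = 250
    n_planted_sqtl: int = 6
    n_planted_eqtl: int = 6
    qtl_beta: float = 1.0
    gwas_n: int = 50_000
    gwas_z: float = 8.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True,
                                     default=str).encode()).hexdigest()[:16]


class Runner:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.dir = Path(cfg.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        self.manifest = (json.loads(self.manifest_path.read_text())
                         if self.manifest_path.exists() else
                         {"version": __version__, "stages": {}})
        self.state: dict = {}

    def _stage_hash(self, stage: str) -> str:
        upstream = STAGES[:STAGES.index(stage) + 1]
        return _hash({"cfg": asdict(self.cfg), "stages": upstream,
                      "version": __version__})

    def run(self) -> Path:
        for stage in STAGES:
            h = self._stage_hash(stage)
            rec = self.manifest["stages"].get(stage)
            cached = rec is not None and rec.get("hash") == h and all(
                (self.dir / f).exists() for f in rec.get("outputs", []))
            # stages feeding in-memory state downstream must recompute
            getattr(self, f"stage_{stage}")()
            self.manifest["stages"][stage] = {
                "hash": h, "cached": cached,
                "outputs": self.state.get(f"{stage}_outputs", [])}
            log.info("stage %s %s", stage, "cache-hit" if cached else "ran")
        self.manifest["version"] = __version__
        self.manifest["seed"] = self.cfg.seed
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))
        return self.dir

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.cfg
        sim = SimConfig(n_samples=cfg.n_samples, n_chrom=2,
                        n_blocks_per_chrom=12, block_size=15,
                        within_block_rho=0.9, variant_spacing=2_000,
                        block_spacing=400_000, chrom_len=5_000_000,
                        n_clusters=cfg.n_planted_sqtl + 8,
                        junctions_per_cluster=3,
                        n_genes=cfg.n_planted_eqtl + 24,
                        cluster_depth=150.0, seed=cfg.seed)
        g = simulate_genotypes(sim)
        rng = np.random.default_rng(cfg.seed + 17)
        # one QTL block per planted effect; GWAS loci reuse / link / avoid them
        blocks = [f"chr{c}_b{b}" for c in (1, 2) for b in range(12)]
        chosen = rng.permutation(len(blocks))
        sqtl_effects, eqtl_effects = [], []
        for i in range(cfg.n_planted_sqtl):
            blk = blocks[chosen[i]]
            sqtl_effects.append({"cluster": i, "junction": 0,
                                 "variant": f"{blk}_v7", "beta": cfg.qtl_beta})
        for i in range(cfg.n_planted_eqtl):
            blk = blocks[chosen[cfg.n_planted_sqtl + i]]
            eqtl_effects.append({"gene": i, "variant": f"{blk}_v7",
                                 "beta": 0.8})
        jt_table, struth = simulate_junction_counts(
            g, sim, pd.DataFrame(sqtl_effects))
        counts, genes, etruth = simulate_expression(
            g, sim, pd.DataFrame(eqtl_effects))
        beta_gwas = cfg.gwas_z / np.sqrt(cfg.gwas_n)
        locus_rows = []
        # shared: GWAS causal == planted QTL causal
        locus_rows.append({"locus": "L_shared_s", "sharing": "shared",
                           "causal": sqtl_effects[0]["variant"],
                           "beta": beta_gwas, "n": cfg.gwas_n})
        locus_rows.append({"locus": "L_shared_e", "sharing": "shared",
                           "causal": eqtl_effects[0]["variant"],
                           "beta": beta_gwas, "n": cfg.gwas_n})
        # linked: causal in the same LD block but a different variant
        blk = sqtl_effects[1]["variant"].rsplit("_v", 1)[0]
        locus_rows.append({"locus": "L_linked_s", "sharing": "linked",
                           "causal": f"{blk}_v0", "beta": beta_gwas,
                           "n": cfg.gwas_n})
        # distinct: causal in a QTL-free block on the same chromosome arm
        free = blocks[chosen[cfg.n_planted_sqtl + cfg.n_planted_eqtl]]
        locus_rows.append({"locus": "L_distinct", "sharing": "distinct",
                           "causal": f"{free}_v7", "beta": beta_gwas,
                           "n": cfg.gwas_n})
        gwas_tables, gtruth = simulate_gwas(
            g, pd.DataFrame(locus_rows), seed=cfg.seed + 29,
            window_bp=cfg.cis_window_s)
        annotations = simulate_annotations(sim, jt_table)

        self.state.update(g=g, sim=sim, jt_table=jt_table, counts=counts,
                          genes=genes, struth=struth, etruth=etruth,
                          gwas_tables=gwas_tables, gtruth=gtruth,
                          annotations=annotations)
        write_vcf(g, str(self.dir / "genotypes.vcf"))
        jt_table.to_csv(self.dir / "junctions.tsv", sep="\t", index=False)
        counts.to_csv(self.dir / "gene_counts.tsv", sep="\t")
        genes.to_csv(self.dir / "genes.tsv", sep="\t", index=False)
        truth = pd.concat([struth.to_frame(), etruth.to_frame(),
                           gtruth.to_frame()], ignore_index=True)
        truth.to_csv(self.dir / "truth.tsv", sep="\t", index=False)
        for name, ivs in annotations.items():
            write_intervals(ivs, str(self.dir / f"anno_{name}.bed"))
        self.state["simulate_outputs"] = ["genotypes.vcf", "junctions.tsv",
                                          "gene_counts.tsv", "truth.tsv"]

    def stage_phenotypes(self) -> None:
        cfg, st = self.cfg, self.state
        batches = st["sim"].batches()
        jt = JunctionTable.from_table(st["jt_table"])
        jt = filter_junctions(jt)
        cm = cluster_junctions(jt)
        psi_raw = compute_psi(jt, cm)
        psi = standardize(psi_raw)
        psi = batch_adjust(psi, batches)
        k_s = min(cfg.pcs_splicing, max(1, len(psi.features) - 1))
        spc = phenotype_pcs(psi, k_s)
        s_cov = build_covariates(spc, pd.Series(batches, index=psi.samples,
                                                name="batch"))

        gcounts = filter_genes(st["counts"])
        expr = cpm_log2(gcounts)
        epm = expression_phenotypes(expr, st["genes"])
        epm = batch_adjust(epm, batches)
        k_e = min(cfg.pcs_expression, max(1, len(epm.features) - 1))
        epc = phenotype_pcs(epm, k_e)
        e_cov = build_covariates(epc, pd.Series(batches, index=epm.samples,
                                                name="batch"))
        st.update(psi_raw=psi_raw, psi=psi, s_cov=s_cov, epm=epm, e_cov=e_cov)
        psi.values.to_csv(self.dir / "psi_std.tsv", sep="\t")
        epm.values.to_csv(self.dir / "expr_norm.tsv", sep="\t")
        st["phenotypes_outputs"] = ["psi_std.tsv", "expr_norm.tsv"]

    def stage_qtl(self) -> None:
        cfg, st = self.cfg, self.state
        g = st["g"]
        results = {}
        for kind, pm, cov in (("sqtl", st["psi"], st["s_cov"]),
                              ("eqtl", st["epm"], st["e_cov"])):
            perm = cis_qtl.permutation_pass_all(
                pm, g, cov, B=cfg.perms, seed=cfg.seed,
                window_e=cfg.cis_window_e, window_s=cfg.cis_window_s)
            perm = cis_qtl.add_qvalues_and_thresholds(perm, fdr=cfg.fdr)
            nominal = {f: cis_qtl.nominal_scan(pm, g, cov, f,
                                               cfg.cis_window_e,
                                               cfg.cis_window_s)
                       for f in pm.features}
            calls = cis_qtl.call_significant(perm, nominal, fdr=cfg.fdr)
            results[kind] = {"perm": perm, "nominal": nominal, "calls": calls}
            perm.to_csv(self.dir / f"{kind}_perm.tsv", sep="\t", index=False)
            calls.nominal_pairs.to_csv(self.dir / f"{kind}_pairs.tsv",
                                       sep="\t", index=False)
        dpsi = cis_qtl.delta_psi_table(st["psi_raw"], g,
                                       results["sqtl"]["perm"], fdr=cfg.fdr)
        dpsi.to_csv(self.dir / "delta_psi.tsv", sep="\t", index=False)
        st.update(qtl=results, dpsi=dpsi)
        st["qtl_outputs"] = ["sqtl_perm.tsv", "eqtl_perm.tsv",
                             "sqtl_pairs.tsv", "eqtl_pairs.tsv",
                             "delta_psi.tsv"]

    def stage_finemap(self) -> None:
        cfg, st = self.cfg, self.state
        qtl_credsets: dict[str, fine_mapping.CredibleSet] = {}
        qtl_stats: dict[str, pd.DataFrame] = {}
        for kind in ("sqtl", "eqtl"):
            res = st["qtl"][kind]
            for feat in res["calls"].features:
                nom = res["nominal"][feat].rename(columns={"variant": "id",
                                                           "slope": "beta"})
                nom = nom.dropna(subset=["beta", "se"])
                if nom.empty:
                    continue
                qtl_stats[feat] = nom[["id", "pos", "beta", "se"]]
                qtl_credsets[feat] = fine_mapping.finemap_signal(
                    feat, qtl_stats[feat], level=cfg.credible_level)
        gwas_credsets = {}
        for locus, gw in st["gwas_tables"].items():
            t = gw.table.rename(columns={})
            gwas_credsets[locus] = fine_mapping.finemap_signal(
                locus, t[["id", "pos", "beta", "se"]],
                level=cfg.credible_level)
        st.update(qtl_credsets=qtl_credsets, qtl_stats=qtl_stats,
                  gwas_credsets=gwas_credsets)
        rows = []
        for feat, cs in qtl_credsets.items():
            t = cs.table.copy()
            t.insert(0, "signal", feat)
            rows.append(t)
        if rows:
            pd.concat(rows).to_csv(self.dir / "qtl_credible_sets.tsv",
                                   sep="\t", index=False)
        st["finemap_outputs"] = ["qtl_credible_sets.tsv"] if rows else []

    def stage_coloc(self) -> None:
        cfg, st = self.cfg, self.state
        g = st["g"]
        leads = {}
        for kind in ("sqtl", "eqtl"):
            calls = st["qtl"][kind]["calls"]
            for feat in calls.features:
                leads[feat] = calls.lead_of(feat)
        elig = colocalization.eligible_signals(
            st["gwas_credsets"], leads, g, gwas_tables=st["gwas_tables"],
            r2_min=0.6)
        coloc = colocalization.colocalize_all(
            elig, st["qtl_stats"], st["gwas_tables"], g,
            window_bp=1_000_000, pp_threshold=cfg.coloc_pp)
        coloc.to_csv(self.dir / "coloc.tsv", sep="\t", index=False)
        st["coloc"] = coloc
        st["coloc_outputs"] = ["coloc.tsv"]

    def stage_twas(self) -> None:
        cfg, st = self.cfg, self.state
        g = st["g"]
        merged = pd.concat([gw.table for gw in st["gwas_tables"].values()]
                           ).drop_duplicates("id").reset_index(drop=True)
        gwas_all = GwasSummary(merged)
        results = []
        tested = 0
        for kind, pm, cov in (("sqtl", st["psi"], st["s_cov"]),
                              ("eqtl", st["epm"], st["e_cov"])):
            for feat in pm.features:
                wts = twas.fit_weights_cv(pm, g, cov, feat, seed=cfg.seed,
                                          window_e=cfg.cis_window_e,
                                          window_s=cfg.cis_window_s)
                if wts is None:
                    continue
                try:
                    res = twas.twas_association(wts, gwas_all, g)
                except ValueError:
                    continue
                tested += 1
                results.append(res)
        if tested:
            twas.twas_significance(results, tested)
            twas.coloc_gate(results, st["coloc"], min_pp=cfg.twas_gate)
            known = [st["gwas_tables"][lo].table.loc[
                st["gwas_tables"][lo].table["p"].idxmin(), "id"]
                for lo in st["gwas_tables"]]
            for r in results:
                twas.classify_locus(r, known, g)
        table = twas.results_table(results)
        # attach the GWAS locus whose window holds each best variant
        locus_of = {}
        for lo, gw in st["gwas_tables"].items():
            for vid in gw.table["id"]:
                locus_of.setdefault(vid, lo)
        if len(table):
            table["locus"] = [locus_of.get(v, "") for v in
                              table["best_gwas_variant"]]
        table.to_csv(self.dir / "twas.tsv", sep="\t", index=False)
        st["twas"] = table
        st["twas_outputs"] = ["twas.tsv"]

    def stage_integrate(self) -> None:
        cfg, st = self.cfg, self.state
        coloc = st["coloc"]
        coloc_pp: dict[str, float] = {}
        qtl_sets: dict[str, list] = {}
        if len(coloc):
            for _, r in coloc.iterrows():
                coloc_pp[r["locus"]] = max(coloc_pp.get(r["locus"], 0.0),
                                           r["pp4"])
                if r["colocalized"] and r["feature"] in st["qtl_credsets"]:
                    qtl_sets.setdefault(r["locus"], []).append(
                        st["qtl_credsets"][r["feature"]])
        records = integration.intersect_credible_sets(
            st["gwas_credsets"], qtl_sets, coloc_pp,
            pp_threshold=cfg.coloc_pp)
        ranks = integration.cpp_rank_comparison(records)
        resol = integration.resolution_counts(records)
        eff = integration.effector_table(coloc, st["twas"])
        eff.to_csv(self.dir / "effectors.tsv", sep="\t", index=False)
        summary = {"rank_comparison": ranks, "resolution": resol,
                   "n_colocalized_loci": len(records)}
        (self.dir / "integration.json").write_text(
            json.dumps(summary, indent=1, default=float))
        st.update(records=records, effectors=eff, integration=summary)
        st["integrate_outputs"] = ["effectors.tsv", "integration.json"]

    def stage_report(self) -> None:
        st = self.state
        truth = pd.read_csv(self.dir / "truth.tsv", sep="\t")
        shared = truth[(truth["kind"] == "gwas")
                       & (truth["sharing"] == "shared")]
        planted_shared_vars = set(shared["variant"])
        eff = st["effectors"]
        nominated_feats = set(eff["feature"]) if len(eff) else set()

        def unit(f: str) -> str:
            return f.split("_j")[0] if "_j" in f else f

        nominated_units = {unit(f) for f in nominated_feats}
        planted_feats = set()
        for _, r in truth[truth["kind"].isin(["sqtl", "eqtl"])].iterrows():
            if r["variant"] in planted_shared_vars:
                planted_feats.add(r["feature"])
        recovered = {f for f in planted_feats if unit(f) in nominated_units}
        # a planted splicing effect moves every junction of its cluster
        # (compositional coupling), so siblings are not false nominations
        planted_units = set()
        for f in truth.loc[truth["kind"].isin(["sqtl", "eqtl"]), "feature"]:
            planted_units.add(f.split("_j")[0] if "_j" in f else f)
        false_nom = {f for f in nominated_feats
                     if (f.split("_j")[0] if "_j" in f else f)
                     not in planted_units}
        summary = {
            "n_sqtl_significant": int(len(st["qtl"]["sqtl"]["calls"].features)),
            "n_eqtl_significant": int(len(st["qtl"]["eqtl"]["calls"].features)),
            "n_colocalized": int(st["coloc"]["colocalized"].sum())
            if len(st["coloc"]) else 0,
            "n_twas_significant": int(st["twas"]["significant"].sum())
            if len(st["twas"]) else 0,
            "planted_shared_features": sorted(planted_feats),
            "recovered_shared_features": sorted(recovered),
            "n_false_nominations": len(false_nom),
        }
        (self.dir / "report.json").write_text(json.dumps(summary, indent=1))
        st["report"] = summary
        st["report_outputs"] = ["report.json"]


def run_pipeline(cfg: PipelineConfig) -> tuple[Path, dict]:
    """Run every stage; returns (run directory, report summary)."""
    runner = Runner(cfg)
    out = runner.run()
    return out, runner.state.get("report", {})
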