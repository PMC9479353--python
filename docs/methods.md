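# Methods

This note documents the models, parameter choices and numerical decisions
behind `spliceqtl`, and what the synthetic-data experiments do and do not
establish.

## Data model and conventions

Variant positions are 1-based (VCF convention); intervals are 0-based
half-open (BED convention), with conversions centralized in
`core_io.interval_to_1based` / `interval_from_1based`. Dosages are alt
allele counts in {0, 1, 2} with `nan` for missing calls; missing values
are mean-imputed only inside regression and LD computations and never
written back to the stored matrix. Variant QC keeps sites with MAF ≥ 0.01,
missingness < 5% and Hardy–Weinberg exact p > 1e-6, applied in that order
so each removal carries a single reason. The HWE test is the exact
conditional test (two-sided by probability mass over heterozygote counts
given the allele counts) rather than a chi-square, avoiding small-count
artifacts; it is checked exhaustively against full enumeration for all
tables up to n = 50. Sample-level relatedness QC is reduced to dropping
near-duplicate samples (dosage correlation > 0.95) — pedigree inference is
out of scope and the synthetic cohorts contain no relatives.

## Synthetic data generator

The generator provides planted, recorded truth for every downstream stage;
all recovery tests read the truth table only.

* **Genotypes.** Each LD block draws one allele frequency from
  `maf_range` (default 0.05–0.5); haplotypes follow a first-order Markov
  chain in which each marker copies its left neighbour with probability ρ
  (`within_block_rho`, default 0.9) and refreshes from the block frequency
  otherwise. Adjacent-marker haplotype correlation is therefore exactly ρ
  and dosage r² decays as ρ^(2·lag); blocks are mutually independent.
  Frequencies are block-constant by construction (a consequence of the
  copy chain preserving its marginal), which the tests account for when
  comparing frequency distributions.
* **Splicing.** Per cluster and sample, a negative-binomial total (mean
  `cluster_depth`, shape `nb_dispersion`) is split multinomially with
  proportions softmax(base logits + β·dosage + batch offset); a planted
  sQTL is a logit effect β on one junction. Because cluster proportions
  are compositional, an effect on one junction necessarily moves its
  siblings — evaluation therefore credits recovery at the cluster level.
* **Expression.** log₂ expression = baseline + β·dosage + batch offset +
  N(0, 1); counts are Poisson around 2^log2expr times a library factor
  varying 2-fold. β is thus in units of the residual SD.
* **GWAS.** Locus z-scores follow the standard summary-statistic model
  z ~ MVN(Rλ, R) with R the panel dosage correlation matrix and λ zero
  except √n·β at the causal variant; beta/se are back-filled from the
  effect-allele frequency and n. This is the model under which the
  fine-mapping and colocalization machinery is derived, so these
  experiments isolate method correctness from model misspecification.
* **Annotations.** Mutually exclusive genic classes (splice-site ±8 bp
  winning over exon/intron/promoter space), an enhancer track, and one
  blacklist plus one MHC-analog interval per genome so exclusion logic is
  always exercised.

What the generator does **not** emulate: read-level alignment noise,
imputation uncertainty, population structure or relatedness, polygenic
GWAS background, and junction-annotation error. Passing tests demonstrate
the statistical machinery is correct under its own assumptions, not that
those assumptions hold in any particular real cohort.

## Phenotype quantification

Junctions need ≥ 5 reads in ≥ 10% of samples; genes need ≥ 5 reads in
≥ 10% of samples within every cohort. Clusters are connected components of
the shared-donor/acceptor graph after removing junctions longer than
500 kb; clusters keep ≥ 2 junctions and ≥ 30 reads in total (the total is
interpreted as summed over all samples; a per-sample variant is available
via `per_sample_reads`). PSI uses per-sample cluster totals, with a zero
total yielding a missing value and features over 50% missing dropped.
Standardization is a rank-based inverse-normal transform,
Φ⁻¹((rank−0.5)/n) with average ranks for ties and median imputation before
ranking; it is applied before batch adjustment (the reverse order is a
defensible alternative; this one is fixed and logged). Batch adjustment is
a per-feature location–scale correction (each batch recentred to the grand
mean and rescaled to the pooled within-batch SD). This removes additive
and scale batch structure exactly in simulation; it deliberately omits the
empirical-Bayes shrinkage of ComBat-style correctors, which matters only
when batches are small relative to feature noise. Phenotype PCs come from
an SVD of the feature-standardized matrix with a deterministic sign
convention (largest-|loading| element positive).

A practical caveat surfaced by the simulations: with very few features,
phenotype PCs partially absorb strong planted genetic effects and leak
them into other features' residuals. The demonstration pipeline therefore
simulates a few dozen genes rather than a handful; real cohorts, with
thousands of features, are in the safe regime.

## cis-QTL mapping

The association engine residualizes both phenotype and dosages on the
covariates (with intercept) and computes slope, t and two-sided p from the
residual correlation with df = n − n_cov − 2; this equals the full
multiple regression by Frisch–Waugh and is verified against one in tests.
The permutation pass permutes the residualized phenotype (covariates and
genotypes fixed), collects the best p per permutation, and reports:
p_empirical = (r+1)/(B+1); a Beta(a, b) fit to the permutation minima; and
p_beta = F_Beta(p_best). The beta MLE optimizes the exact likelihood over
(log a, log b) by Nelder–Mead from a method-of-moments start (the simplex
is more robust than Newton steps at near-degenerate fits; the objective,
parameterization and initialization are the conventional ones) and falls
back to method-of-moments with a recorded flag on non-convergence.
Permutation streams are derived per feature by hashing the feature id with
the master seed, so results are reproducible under feature subsetting.

Storey q-values use a single fixed λ = 0.5 — π₀ = #{p > λ}/((1−λ)m)
clipped to (0, 1] — rather than the spline smoother, for determinism; at
the π₀ levels of these designs the difference is negligible. The
genome-wide threshold p_t is the p_beta of the feature whose q is closest
to the FDR target (ties to the smaller p_beta), and per-feature nominal
cutoffs are F_Beta⁻¹(p_t; a, b). Features with no polymorphic cis variant
are reported with q = 1 rather than dropped. Lead ties break by smaller
p, then genomic position, then id. ΔPSI is computed on raw (never
standardized) PSI as median(hom-alt) − median(hom-ref), heterozygotes
substituting when hom-alt is absent, reported for the best-q junction per
cluster.

**Calibration (computed by `scripts/acceptance.py` and the acceptance
tests).** On cohorts of 1000 features (200 planted 0.8-SD effects at
MAF ≥ 0.2, 800 nulls; n = 300, B = 1000) the realized false discovery
proportion among q ≤ 0.01 calls is measured per seed and averaged over ten
seeds; on fully null cohorts essentially nothing is called.

## LD-matched permutation null

QTL variants cluster in LD blocks, so inflation and enrichment must be
judged against controls with the same regional footprint. LD blocks are
inferred by a greedy scan (new block when max r² against the previous 50
variants drops below 0.1), tiling each chromosome. Control sets re-place
the query's per-block spans uniformly at random — each shuffled span must
land in a distinct, previously unused LD block outside the exclusion
space (query-bearing blocks, blacklist, MHC-analog) — and sample exactly
the query's per-block variant count from the candidate variants of the
blocks the span landed in. This matches the query's block-count structure,
which the envelope's exchangeability argument requires. QQ plots use
expected quantiles −log₁₀((i−0.5)/n) and a rank-wise 2.5/97.5-percentile
envelope over control sets; the enrichment flag fires when ≥ 10% of the
top-decile ranks exceed the upper envelope. Annotation fold enrichment
counts a lead as hitting an annotation when it or an LD proxy (r² ≥ 0.7
within 50 kb) overlaps, with fold = observed / mean control hits and an
empirical p of (#{controls ≥ observed}+1)/(B+1).

A structural limitation quantified during calibration: the control null
is only exchangeable when the genome holds many more LD blocks than the
query occupies. On toy genomes where the query spans a large fraction of
all blocks, the envelope collapses onto a handful of fixed block z-scores
and the flag is uncalibrated by construction; the calibration suite
therefore uses 60-block genomes with 8-block queries.

## Fine-mapping and conditioning

Single-causal fine-mapping uses per-variant Wakefield log ABFs with a
uniform causal prior; under the one-causal restriction this is equivalent
to joint-likelihood single-causal methods while needing only per-variant
summary statistics. The default prior variance is W = 0.04 (effect SD 0.2
on a standardized phenotype, also used on the log-odds scale for
case–control traits); CPPs are normalized per locus and credible sets take
the minimal CPP-descending prefix reaching the level, ties broken by
genomic position for determinism. Summary-statistic conditioning follows
the standard formula z_cond = (z − R_jC R_CC⁻¹ z_C)/√(1 − R_jC R_CC⁻¹ R_Cj)
with variants below 5% conditional variance flagged collinear and a 1e-6
ridge on a singular conditioning block.

Coverage (computed, not asserted a priori): over 1000 simulated loci of
100 variants in ρ = 0.9 block LD with lead non-centrality 6 and correctly
specified LD, the planted causal falls inside the 95% credible set in ≈
98% of loci — mildly conservative, as expected when the fixed
non-centrality exceeds what the effect-size prior would typically draw.

## Colocalization and TWAS

Colocalization sums per-variant log ABFs (prior SD 0.15 for quantitative
QTL traits, 0.2 for case–control GWAS) into the five-hypothesis
posteriors with fixed priors p1 = p2 = 1e-4, p12 = 1e-5, computed in log
space via logsumexp. Signals are tested only when eligible — a GWAS
credible-set variant with CPP ≥ 0.01 in r² ≥ 0.6 with a QTL lead, or,
without credible sets, any variant at GWAS p ≤ 5e-5 in r² ≥ 0.6 — across
a 1 Mb window centered on the GWAS lead that must contain at least one
variant at p ≤ 5e-5 (all window variants then enter the computation; a
hard filter is available by flag). The decision bar is PP4 ≥ 0.8.

TWAS weights come from top1, ridge (GCV-selected penalty) or lasso
(CV-min path), the winner chosen by 5-fold cross-validated R² on the
covariate-residualized phenotype; features with best cv R² ≤ 0.01 are
declared non-heritable and excluded, which plays the role of a
heritability gate. BLUP is statistically close to ridge and is not
duplicated; MCMC-based sparse Bayesian models are omitted. Association is
z_TWAS = wᵀz/√(wᵀRw) with R from the training panel, Bonferroni
correction over tested features, a colocalization gate at PP4 ≥ 0.6
(missing colocalization records gate out with reason `no_coloc`), and
known/novel locus classification by r² ≥ 0.1 or distance < 500 kb to a
known lead.

## Integration

At loci with colocalization PP > 0.8, GWAS credible-set variants are
split into those also in the colocalizing QTL credible set and those not;
a variant in several QTL credible sets contributes its maximum CPP. The
two CPP distributions are compared by a two-sided rank-sum test (normal
approximation with tie correction, pooled over loci; per-locus testing is
available), and fine-mapping resolution is summarized as the number of
loci with ≤ 5 candidate variants before vs after intersecting. The
candidate-effector table is the union of colocalized QTL features and
significant, coloc-gated TWAS features with per-route evidence flags.

## Pipeline and problem sizes

The demonstration pipeline runs simulate → phenotypes → qtl → finemap →
coloc → twas → integrate → report with a JSON manifest recording
parameters, seeds, package version and per-stage content hashes;
unchanged stages are cache-flagged on rerun and full runs are
byte-deterministic under a fixed seed. Default demonstration sizes — 220–
250 samples, 24 LD blocks of 15 variants, ~12 splice clusters, ~30 genes,
4 GWAS loci, B = 300–1000 permutations — complete in well under a minute;
the calibration experiments (1000 features × B = 1000 × 10 seeds, and
1000 fine-mapping loci) complete in about two minutes. These sizes were
chosen as the smallest at which the measured quantities have useful
Monte-Carlo precision.

## Known limitations

* Single-causal fine-mapping and colocalization assume at most one causal
  variant per trait per locus; multi-signal loci need conditioning first.
* The location–scale batch adjustment does not shrink across features;
  with tiny batches it can overfit batch SDs.
* The QTLtools-style rule "feature closest to the FDR threshold" can
  differ by one feature from other implementations at the boundary.
* The control-variant null requires a genome with many more LD blocks
  than the query footprint (see above).
* GWAS simulation draws exact MVN z-scores; fine-mapping with a
  mismatched LD reference (a real-data hazard) is not modeled.
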