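# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `methclime`. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All genomic coordinates are 1-based inclusive inside the package. BED
output is converted to 0-based half-open at the file boundary and
converted back on read; GFF3 stays 1-based. Genotypes are biallelic and
coded 0/1 for inbred homozygotes (−1 = missing); heterozygotes occur
only in the F2 cross simulator.

## Methylation quantification

A site's level is `meth/total`, missing below a minimum coverage
(default 1 read — the choice is exposed because published pipelines
differ). Region-level aggregation is always count-weighted
(`Σmeth/Σtotal`), which makes aggregate levels exact ratios of read
counts. Genome-wide context averages are **unweighted** means of site
levels by default, with a coverage-weighted variant behind a flag: the
two differ when coverage correlates with methylation, and the
unweighted form treats every covered cytosine equally. Sites are kept
per-cytosine; symmetric-CpG strand merging is deliberately not done.

Bisulfite conversion efficiency is `1 − Σmeth/Σtotal` on the
chloroplast contig, which is biologically unmethylated, so any apparent
methylation there is unconverted-read error.

Sliding windows are 200 bp at 100 bp steps (half-overlapping; the
window size must be a multiple of the step). A window with no covered
site is missing. Variable-window selection drops windows with a missing
fraction above a cutoff (default: any missing sample disqualifies),
ranks the rest by across-accession variance, and breaks ties toward the
earlier genomic coordinate so the selection is deterministic. Smoothing
is a no-op hook: the windows operate on raw counts, since windowed
count aggregation dominates downstream behavior and keeps the oracle
tests exact.

GBM classification: a gene is gene-body methylated iff its
across-sample mean CG level is ≥ 0.05 while CHG (and, by default, CHH)
stay below 0.05; high-CG/high-CHG genes are transposon-like and
excluded; genes missing a context are excluded with a reason. The
procedure is idempotent and invariant to accession order.

## DMR calling

Two samples are compared per non-overlapping 100 bp tile by Fisher's
exact test on the summed (methylated, unmethylated) counts, with
Benjamini–Hochberg control across tested windows. Windows with zero
coverage in either sample are untested and excluded from the FDR
denominator. A call requires q ≤ 0.05 **and** an absolute level
difference ≥ 0.3; the "minimum change of 0.3" is interpreted as an
absolute difference in methylation fractions (the semantics of the
standard count-based callers), with a log-ratio variant behind a flag.
Fisher's exact test is the natural per-window test for two samples
without replicates; dispersion-aware models are out of scope.

Temperature DMRs are per-accession pairwise calls between the two
growth temperatures, oriented 16°C − 10°C; the consensus set is the
union of windows called in ≥ k accessions (k configurable, default 1 —
the merging rule behind published per-accession counts is not uniquely
determined, so it is exposed). Mutant-dependent DMRs are pairwise calls
of wild type vs knockout restricted to windows that lose methylation in
the mutant.

TE-family enrichment permutes the "variable" label over all TEs;
`expected = |variable|·|family|/|all|`, a family is flagged
over-represented when observed exceeds both its expectation and the
95th permutation quantile, and the empirical p uses (r+1)/(n+1).

## Mixed-model GWAS

The scan is the standard one-random-effect LMM with an
identity-by-state kinship (fraction of identical alleles,
pairwise-complete over missing calls, unit diagonal). The variance
ratio δ = σe²/σg² is estimated once on the null model and reused for
every SNP. Estimation is by REML (profile ML is available by flag):
in calibration simulations under a structured null the ML plug-in
showed mild test-statistic inflation, while REML keeps the per-SNP Wald
t test calibrated — the calibration check is part of the test suite.
Per-SNP tests are Wald t with the null-design degrees of freedom;
Bonferroni 0.05 over tested SNPs defines significance. SNPs below a 5%
minor-allele-frequency cutoff (configurable) are not tested; missing
genotypes are mean-imputed per SNP; cofactor SNPs are never
self-tested, and SNPs collinear with the design are skipped.

The stepwise scan adds the most significant SNP as a fixed cofactor and
repeats until nothing passes Bonferroni or a cofactor cap is reached.
This is what resolves a repulsion-phase pair: the first locus masks the
second until it is conditioned on.

cis/trans labels use a 100 kb window around each phenotype's genomic
anchor (distinct from the 50 kb cis window of the variance components —
both are kept as separately configurable values). Effect-direction
summaries count the sign of the non-reference-allele effect and test
the split with an exact binomial test.

BLUP correction fits y = μ + u + e by the same machinery and subtracts
û = E[u|y]; with no genetic variance the phenotype returns unchanged.

## F2 interval mapping

The cross simulator draws two independent gametes per F2 individual as
Markov chains along each chromosome with Haldane recombination
fractions, giving {0,1,2} genotypes with the expected 1:2:1
segregation. Haley–Knott regression walks a 4 cM grid; at each position
the 3-state genotype distribution given the flanking markers is
computed from F2 transition matrices (no interference), the phenotype
is regressed on the expected additive and dominance dosages, and
LOD = (n/2)·log10(RSS₀/RSS₁). The genome-wide 0.05 threshold is the
95th percentile of the max-LOD over phenotype permutations (default
1000), evaluated for all permutations simultaneously by projecting the
permuted phenotype matrix once per grid position. The reported support
interval is the 1.5-LOD drop around the peak.

## Two-environment variance components

The model for an N×2 phenotype is a sum of matrix-normal random effects
with Kronecker-structured covariance Σₖ C_k ⊗ R_k + Σ ⊗ I_N
(environment index slow, accession fast), with relatedness matrices
built from standardized genotypes of the relevant SNP sets: cis =
within 50 kb of the phenotype's anchor, trans = all other SNPs, CMT2 =
the major-locus region. Each matrix is rescaled to unit mean diagonal.

Every 2×2 environment covariance (including the noise Σ) is
parameterized as C = a²J + diag(b₁², b₂²). This makes C positive
semidefinite by construction and makes the shared / environment-
specific split identifiable as a² vs mean(b₁², b₂²) without a post-hoc
decomposition; a free-form PSD parameterization with post-hoc splitting
would fit the same likelihoods but leave the split convention implicit.
Environment means are profiled out by GLS inside the likelihood;
estimation is maximum likelihood (not REML). Restarts initialize each
standard-deviation parameter log-uniformly on [10⁻³, 1] (after
rescaling the data to unit variance, which also makes the fractions
exactly scale-invariant); optimization is L-BFGS-B with numerical
gradients (finite-difference step 10⁻⁶ — smaller steps sit below the
Cholesky noise floor and break the line search), capped at 500
iterations, stopping on gradient norm or relative likelihood change.
Fitting stops at the first converged restart, and non-converged fits
refuse to be partitioned.

The E fraction is the sample-size-weighted variance of the fitted
environment means around their weighted grand mean; each random
effect contributes a shared and a ×E fraction; everything is normalized
to sum to one. Missing cells are handled by fitting on observed cells
only; an environment with fewer than two observations is an error.

**A known identifiability limit**: when a relatedness matrix is close
to the identity away from the population blocks, the environment-
specific genetic term b²·R is nearly aliased with the noise term, and
maximum likelihood may split pure noise between them. The shared
(cross-environment) genetic fractions and E remain identifiable; tests
of null behavior therefore assert those, plus the combined unstructured
remainder.

## Population genetics

Hudson's Fst uses the sample-size-corrected per-site estimator
(numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), denominator
p₁(1−p₂) + p₂(1−p₁)); the genome value is the ratio of summed
numerators to summed denominators, with the mean of per-site ratios
also reported for comparison. Sites with zero denominator are excluded.

Haseman–Elston regression regresses the phenotype cross-products y_i y_j
(i<j, phenotype centered within the analysis group) on the matching IBS
kinship entries, with an intercept (the IBS matrix has an arbitrary
affine offset relative to a centered genetic covariance, which the
intercept absorbs); the slope, floored at zero, is σ²_A. Qst recomputes
kinship on each population subsample (slicing the global matrix would
carry the global normalization into the within-population regression),
weights the within-population variances by n_k − 1, and is
σ²_B/(σ²_B + 2σ²_W) with σ²_B = overall − within floored at zero.

SNP-set overlap enrichment draws frequency-matched null sets (MAF bins
of width 0.02, uniform fallback with a warning when a bin is empty);
fold = observed/mean(null) and p = (#null ≥ obs + 1)/(n_perm + 1).
Expression contrasts use median-of-genes effective library sizes, then
Wilcoxon rank-sum tests of per-accession class means between regions,
per-gene |Δ expression| between temperatures, and the per-accession
GBM-mean normalized by the non-GBM mean as a within-sample library-size
control. Note that median normalization partially redistributes a
genuine class-wide shift onto the other class when the shifted class is
a large fraction of all genes; the test suite demonstrates both the
benefit (removing a planted library confounder) and this side effect.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analysis is exercised under.

* **Genotypes**: 150 inbred accessions, half from each region, 10,000
  biallelic SNPs. Regional allele frequencies follow the
  Balding–Nichols model with divergence parameter 0.187, so the
  realized Hudson Fst tracks that target (slightly above it, ~0.20,
  because of the nested demes below). Within each region, accessions
  belong to 4 nested demes with deme-level divergence 0.05: fully
  exchangeable within-region genotypes would make within-population
  kinship nearly constant and the Haseman–Elston slope unidentified.
  Latitudes are drawn north (62.8–68.4°N) and south (55.4–59.9°N) of a
  60°N split.
* **Major locus**: two designated SNPs ("CMT2a"/"CMT2b") on the middle
  chromosome, drawn in complete repulsion at region-specific
  non-reference frequencies (south 22.6%/30.6%, north 9.5%/7.9%); the
  a-allele raises and the b-allele lowers TE CHH methylation on the
  logit scale (±0.9). A rare "CMT2-null" accession flag silences the
  CMT2-dependent pathway (−4 logits).
* **Methylomes**: effects act on the logit of the per-site methylation
  probability — the simplest link that keeps probabilities in (0,1)
  with unbounded effects; no generative model is implied by real data.
  Baselines depend on context and feature (TE CHH ~0.12, TE CHG ~0.3,
  TE CG ~0.45, GBM-gene CG ~0.3, unmethylated-gene CG ~0.01, plus
  site-level jitter). Cis effects (±1.4 logits via one SNP within 50 kb)
  cover 45% of TEs; a polygenic trans effect acts on all TE CHH.
  The temperature effect applies to CHH only: planted gain-DMR hosts
  (the 2.7% "variable" TEs) get +2 logits at 16°C, loss hosts (2%,
  given a high 10C baseline so the drop is callable at the 0.3
  difference threshold) get −2.5, and a global CHH shift is then
  calibrated by root finding so the genome-wide mean CHH at 16°C is
  exactly 1.14× the 10°C mean *on the observed scale* (conversion error
  included). GBM liability = 15 north-enriched trans SNPs (frequencies
  0.85 north / 0.05 south, effect 0.12 each) + a polygenic term
  (within-region sd 0.25) + non-genetic noise (sd 0.49); these scales
  were calibrated once so the planted CG–latitude correlation is ~0.70
  and then left alone.
* **Observation model**: depth ~ Poisson(12.6); methylated reads ~
  Binomial(depth, p(1−ε) + (1−p)ε) with ε = 0.0041 applied
  symmetrically; the chloroplast contig is simulated at p = 0 as the
  conversion-efficiency control. Cytosines sit on a fixed grid (default
  every 40 bp, configurable) with random contexts (CG/CHG/CHH =
  0.25/0.25/0.5) and strands — real cytosine spacing, local context
  clustering, and linkage disequilibrium decay are *not* emulated.
* **Expression**: log-normal, with GBM genes coupled to the GBM
  liability (coupling 0.25 by default) and an optional per-sample
  library-size multiplier for confounder tests.

What passing tests show, and do not show: the pipeline recovers planted
cis/trans/major-locus/temperature signals under binomial sampling at
realistic depth and under Balding–Nichols-style structure. They do not
show robustness to alignment artifacts, context miscalls, LD between
causal and tagging variants, TE-density covariation, or non-logistic
methylation distributions, none of which the generator emulates.

On this architecture the measured Qst of the GBM-like trait runs higher
(~0.9) than would be seen with richer within-population structure: the
IBS-based Haseman–Elston estimator recovers little within-population
additive variance from two nearly homogeneous regions, pushing Qst
toward 1. The Qst ≫ Fst contrast — the scientifically meaningful
output — is stable across seeds, and the acceptance script reports the
measured value as-is.

## Problem sizes

The default test and demo sizes (60–150 accessions, 2 Mb genome across
5 chromosomes, 2,000–10,000 SNPs, 300 genes + 300 TEs, sites every
40–120 bp) were chosen as the smallest panels at which every planted
signal is comfortably detectable by the corresponding stage; parameter-
recovery checks use N = 300 accessions for the variance components and
n = 113 F2s for interval mapping. All sizes are configurable.
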