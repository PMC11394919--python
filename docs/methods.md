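# Methods

This note documents the statistical model behind each stage, the defaults
and why, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Allelic-asymmetry model

At a heterozygous site covered by `n = r + a` reads of an assay, the null
model is symmetric coverage of the two alleles, `r ~ Bin(n, ½)`.  The
two-sided p-value uses the *minimum-likelihood* convention — the sum of
point probabilities no larger than the observed one — which for a
symmetric null reduces exactly to `min(1, 2·P(X ≤ min(r,a)))`.  This
matches the exact binomial tests of standard statistical software and is
symmetric in `(r, a)`.  Multiple testing is controlled with
Benjamini–Hochberg at 0.1.

**BH family.**  Adjustment is applied within each `(individual, assay)`
stratum so that ChIP and RNA evidence stay independent (they feed the ASB
and ASE decisions separately); a global family is available via
`call_events(..., bh_family="global")`.  An assay tests a het site whenever
it has ≥ 1 read there — the >20 depth / ≥ 0.2 minor-fraction thresholds
gate het status from *pooled* counts only.

**A structural property of the het filter**: a site whose true allele
ratio is extreme (minor fraction well below 0.2) tends to fail the
pooled-minor-fraction gate and is never tested.  Detectable allelic
imbalance therefore lives roughly in the 0.6–0.8 major-allele band at
practical depths; the generator's default planted imbalance (0.75) sits in
that band.  Sites planted at 0.9+ are recovered reliably only when het
status is established independently (as in the unit tests that construct
het tables directly).

## Gene-level ASE ("MBASED-lite")

Genes with one informative SNV inherit the SNP decision.  For ≥ 2 SNVs the
phase is unknown; each SNV's major allele is assigned to a nominal
haplotype ("pseudo-phasing") and the count-weighted aggregate frequency
`T = Σ max(rᵢ,aᵢ) / Σ nᵢ` is the test statistic.  Because taking the
maximum at every SNV inflates `T` above ½ under the null, the Monte-Carlo
null redraws `kᵢ ~ BetaBin(nᵢ, ½, ρ)` and re-applies the same maximisation;
`p = (1 + #{T* ≥ T}) / (n_sim + 1)`, compared on integer numerators so the
test is exact with respect to floating-point ties.  Defaults:
`n_sim = 9999` (p floored at 1/(n_sim+1)); a warning below 999.  This is a
deliberate simplification of the full beta-binomial meta-analytic
gene-level ASE estimator: the pseudo-phasing null replication is the
essential bias correction, and the Monte-Carlo form keeps the null exact
at any depth configuration.

**Overdispersion in the null (`ρ`).**  Real allele counts are
overdispersed relative to binomial.  `mbased_gene_ase` defaults to a
binomial null (`ρ = 0`); when the data's overdispersion is known or
estimated it should be passed through (`call_ase_genes(..., rho=...)`).
`run_on_study` does this automatically with the generating ρ of the
simulated study — the analysis of a study whose nuisance parameters are on
record uses them.  The SNP-level binomial test is left uncorrected by
design (it is the method under study); consequences are discussed under
Limitations.

Multi-SNV gene p-values are BH-adjusted per individual at 0.1 — the
SNP-level threshold reused at gene level, since no separate gene-level
threshold is part of the method.  An alternative rule
(`gene_ase_rule="any_snv"`: a gene is ASE when any of its SNVs is) is
implemented because the qualitative description "genes containing at least
one ASE SNP" admits both readings; the calibrated aggregate test is the
default for multi-SNV genes.

## Promoters and panel assembly

Promoters are `[max(1, TSS−1000), TSS+1000]`, 1-based inclusive, one per
distinct `(gene, TSS)` including alternative TSSs; BED exports convert to
0-based half-open.  ASB–ASE pairing is same-individual by default (the
discovery logic is per individual), with a cross-individual mode by flag;
panel membership needs support in ≥ 1 individual (`min_individuals`
configurable).  The panel is invariant to input row order.

## Catalog enrichment

Matching is direct (identical position or rs ID) with precedence over
proximal (≤ 1000 bp, inclusive).  2×2 enrichment of panel vs non-panel het
sites: OR = ad/bc with Haldane's +0.5 on all cells when any cell is zero;
Woolf CI `exp(ln OR ± 1.96·√(Σ 1/cell))`; Fisher exact two-sided (minlike)
and Pearson χ² (1 df, no continuity correction).  Trait ranking keeps
traits with ≥ 100 catalog variants, tests direct membership per trait,
BH-adjusts across traits, and orders by direct-match count.  TF-ASB
catalog entries are used at FDR < 0.05 when an FDR column is present.
Percentages are rounded half-up to one decimal — a fixed convention, since
published tables are not always internally consistent about rounding.
The background set is "het sites tested but not in the panel"; whether
non-het positions should enter the background is configurable by passing a
different site table.

## Differential expression

Median-of-ratios size factors; per-gene dispersion by method of moments on
normalised counts, pooled within groups and floored at 1e-8; Wald test of
the log group-mean ratio with delta-method standard errors under NB
variance `μ/s + αμ²`; BH across genes; DEG gate `|log₂FC| > 0.2` and
`p.adj < 0.05`.  Dispersion shrinkage, outlier handling and LFC shrinkage
are deliberately absent — the downstream contribution is the gate and the
promoter intersection, not the DE engine — so results on real datasets
will differ from shrinkage-based engines; an independent cross-check in
the test suite verifies fold-change agreement with one on planted data.
All-zero genes are excluded (count recorded in `DataFrame.attrs`).  The
reference level is the alphabetically first label unless given.  DEG–rSNP
totals are additive by construction: an rSNP is counted once per direction
it supports, so up + down equals the grand total.

## Network stages

Betweenness is unnormalised and stress counts shortest paths over
unordered pairs — the conventions of the Cytoscape/CytoNCA tooling this
stage mirrors.  Stress uses a Brandes-style accumulation
(`δ(v) = σ_sv · paths(v)` per source, halved), verified against exhaustive
all-shortest-path enumeration on graphs ≤ 12 nodes.  Hub selection keeps
ties at rank 20 (inclusion over exclusion).  MCODE: vertex weight = (max
core number k of the closed neighbourhood) × (density of that k-core);
greedy expansion from the best unassigned seed admits neighbours scoring
≥ seed × (1 − 0.2) to depth 100; complexes lacking a 2-core are dropped;
module score = density × size, reported at ≥ 4.  Fluff and haircut
post-processing exist in the literature but are off here (not part of the
parameter set used).  ORA is the one-sided hypergeometric upper tail with
BH at 0.05, all sets intersected with the declared universe.  AUC is the
Mann–Whitney U statistic with half-credit ties over `n_pos·n_neg`
(equivalently the trapezoidal ROC area); the positive class is the disease
group and AUC is not auto-oriented by default (a regulation-direction-blind
reading of per-gene AUCs), with `orient=True` available.

## Synthetic-data generator

One synthetic chromosome; non-overlapping genes (2–6 kb) with intergenic
gaps > 2.1 kb so ±1 kb promoters never cross gene boundaries; per-gene
strand; 1–3 transcripts per gene, extra transcripts with shifted TSSs
(≥ 10% of genes get alternative TSSs).  Promoter het sites are placed
upstream of the primary TSS and covered by both ChIP marks; gene-body
sites are covered by RNA — so pooled het calling combines the two marks at
promoter sites.  Depth is Poisson(60) per individual × assay × site;
allele counts are beta-binomial with intra-class correlation ρ = 0.02
(overdispersion of the magnitude seen in real ChIP/RNA allele counts;
ρ = 0 reduces to binomial).  A fraction (default 0.1) of genes is
"regulated": their promoter sites are imbalanced in both marks and their
gene-body sites in RNA, all at major-allele frequency 0.75 (strong but
above the het filter's survival band — see the structural property above).
Individuals are het at each site with probability 0.8.  Reference-mapping
bias is represented at the counting level: "naive" mode shifts the
reference-allele probability by `ref_bias_delta` (default 0.05), while
"dual-genome" mode — modelling remapping against an individualised genome
with alleles swapped — is unbiased.  Reads, alignment, LD structure and
real coordinates are not simulated.

Catalogs: each het site enters each catalog with probability 0.05,
multiplied by 8 (capped at 1) at true rSNP positions; GWAS entries at true
rSNP sites concentrate on one large trait, planting a trait-level
enrichment; per-trait nominal sizes (60…400) straddle the 100-variant
filter.  Counts: NB with mean `μ_g·s_j·2^{x_j β_g}`, log-normal baseline
means, log-uniform size factors in e^±0.3, dispersion 0.05, planted
|log₂FC| = 1 in 10% of genes, 10 vs 10 samples (the scale of the smaller
published cohort this stage emulates).  PPI: Erdős–Rényi background
(p = 0.05) over 120 gene symbols plus three planted disjoint 8-cliques.
All generators are deterministic functions of the seed, drawing from
independent per-component streams so outputs do not depend on call order.

What passing tests do **not** show about real data: no read-level error,
no mapping artefacts, no LD between sites, no isoform structure, no batch
effects in counts, and catalog/trait structure far simpler than real
GWAS/eQTL resources.  Recovery rates measured here characterise the
statistical machinery under the generator's assumptions, not expected
yields on sequencing data.

## Problem sizes

Defaults are desk-scale: 200 genes × 9 individuals (~10 000 depth rows),
200-gene count matrices, 120-node graphs.  Simulation-based tests average
over 20 seeds with 999 Monte-Carlo reps for the gene-level null; the
production default is 9 999 reps.

## Known limitations

- The SNP-level binomial test ignores overdispersion, so SNP-level calls
  are anticonservative on overdispersed data (the realised false-discovery
  proportion among ASB/ASE calls exceeds the nominal 0.1 when ρ > 0).
  The panel stage absorbs much of this — a false rSNP needs a false ASB
  *and* a false same-individual gene-ASE call — and the gene-level null
  accepts a ρ; a beta-binomial SNP-level test would be the natural
  extension but is not the method implemented here.
- Pseudo-phasing aggregates magnitude only; genes whose SNVs are truly
  imbalanced in opposite directions on one haplotype are indistinguishable
  from concordant imbalance.
- The NB-Wald DE core is intentionally minimal (see above).
- MCODE expansion can merge planted modules connected by high-scoring
  bridges into one complex; recovery is therefore scored as "planted
  module contained in a detected module".
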