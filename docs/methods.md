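# Methods

This note documents the statistical models implemented in `gutlink`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Summary statistics and harmonization

All stages consume per-SNP marginal association statistics (`beta`, `se`,
`pval`, `eaf`, `n`, alleles, position) for one trait at one locus, from
tab-separated tables. Positions are 1-based; chromosome labels are opaque
strings with any `chr` prefix stripped. Records violating basic invariants
(`se ≤ 0`, `p ∉ (0,1]`, identical alleles, …) are rejected row-wise with a
logged report rather than failing the table.

Two-sample analyses require the outcome's effects to be expressed on the
exposure's effect allele. `harmonize_pair` keeps SNPs whose allele pairs
match, negates the outcome beta (and reflects its frequency) when the pair
is swapped, and drops everything else as a mismatch. Strand-ambiguous
palindromic SNPs (A/T, C/G) are dropped when either study's effect-allele
frequency lies within 0.08 of 0.5, or when the frequency is missing — the
0.08 half-width is common two-sample MR practice; harmonization is
idempotent and invariant to a global allele-orientation flip of the outcome
table. Case-control studies lacking a pooled MAF use the sample-size-
weighted average of case and control frequencies.

## Instruments

Instruments are exposure SNPs below the significance threshold (5×10⁻⁸ for
expression-QTL exposures; 1×10⁻⁵ for microbiome-QTL exposures, whose
cohorts are far less powered per taxon), pruned by greedy clumping:
repeatedly take the smallest-p remaining candidate and remove candidates
with panel r² ≥ 0.01 within ±100 kb of it. "Within a 100 kb window" is
interpreted as ±100 kb around each index SNP, matching standard clumping
tools; SNPs farther apart are never pruned against each other. Ties in p
break by position then SNP id, making clumping deterministic. Clumping runs
on the exposure table before harmonization (declared order; both operations
commute for matched-allele tables).

## Two-sample MR

Per instrument j the Wald ratio is βⱼ = β_out,j/β_exp,j with first-order
(delta-method) SE σⱼ = se_out,j/|β_exp,j| — the standard two-sample
simplification that ignores exposure uncertainty, adequate because
instruments are strongly associated with the exposure by construction.
The IVW estimate is the σ⁻²-weighted mean; the default *multiplicative
random effects* mode scales the fixed-effect SE by max(1, √(Q/(J−1)))
(Cochran's Q), coinciding with the fixed-effect estimate when
underdispersed. Pairs with fewer than two usable instruments are refused
with an explicit reason code.

QC follows standard practice: MR-Egger (outcome beta regressed on exposure
beta with a free intercept, weights se_out⁻², instruments oriented so all
exposure betas are positive) screens directional pleiotropy, excluding
pairs with intercept p < 0.05 (t-test, J−2 df); with fewer than three
instruments the screen is not evaluable and the pair passes with a logged
caveat. Leave-one-out flags pairs where dropping a single instrument flips
the estimate's sign or moves its p across 0.05. Nominal IVW p-values are
adjusted by Benjamini–Hochberg FDR pooled study-wise — by default across
all gene×genus tests of a run (per-tissue pooling available), with
significance at q < 0.05. Two-step MR chains a gene→genus estimate with a
genus→trait estimate when the first passes full QC (FDR ∧ Egger ∧ HEIDI)
and the second is nominally significant (p < 0.05, a declared choice);
the chained effect β₁β₂ carries the first-order SE
√(β₂²se₁² + β₁²se₂²).

## SMR and HEIDI

At the top cis SNP, T_SMR = z_x²z_y²/(z_x²+z_y²) is referred to χ²₁. HEIDI
asks whether SNPs in LD with the top SNP give the same SMR effect
b = β_out/β_exp: under a single shared causal variant all b's estimate one
quantity. Up to 20 SNPs (strongest exposure z first) with panel r² to the
top SNP in (0.05, 0.9) form dᵢ = bᵢ − b_top; the covariance of d is
propagated by the delta method from the per-trait marginal covariances
(cov(βᵢ,βⱼ) = r_ij·seᵢ·seⱼ within a trait; traits independent across
cohorts). T_HEIDI = Σ z_d,i², with the tail of this dependent quadratic
form evaluated by Satterthwaite moment matching (g·χ²_h with g, h fitted to
the covariance's first two spectral moments) — simple and dependency-free;
a Monte-Carlo empirical null is retained in the tests as the validating
oracle. The eligibility band, cap of 20 and minimum of 3 SNPs follow the
conventions of the original SMR tool. Fewer than 3 eligible SNPs makes the
test non-evaluable: the pair then *passes* the filter with a caveat, so the
HEIDI screen is conservative only when it can actually be computed.
Pairs with p_HEIDI < 0.01 are interpreted as linkage and filtered. SMR p is
reported but not used as a filter.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor
log ABF = ½log(V/(V+W)) + z²W/(2(V+W)), with V the squared SE and prior
effect variance W = 0.15² for quantitative traits (0.2² for case-control
log-odds); the beta/SE parameterization is primary, with a sample-size+MAF
fallback when SEs are missing. Hypothesis evidences accumulate in log space
(no underflow up to ≥10⁵ SNPs). Priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ are the
conventional single-causal-variant defaults. PP4 > 0.5 is labelled
colocalized and PP4 > 0.9 tier-1. PP3 is exactly zero for single-SNP loci.

The three-trait extension enumerates all 15 association configurations
(all-null, plus every partition of every non-empty trait subset into
shared-causal-variant groups). Configuration evidence sums over assignments
of *distinct* SNPs to groups (inclusion–exclusion over coincidence
patterns, exact and validated against exhaustive enumeration), with
per-SNP priors by group size p1 = 10⁻⁴, p2 = 10⁻⁶, p3 = 10⁻⁷. PP_abc is
the posterior of the single all-shared configuration (not a sum over
partial-sharing configurations), flagged at > 0.1. Raw posteriors are
reported without multiplicity adjustment.

## Classification and enrichment

Significant (gene, genus) keys across the three intestinal tissues are
partitioned into the seven non-empty tissue subsets. A tissue-specific pair
is *eQTL-specific* when its gene is an eGene in that tissue only and
*regulation-specific* when the gene is an eGene elsewhere too (genes absent
from every eGene set are reported as unclassifiable). Sharing is keyed by
(gene, genus), not by lead SNP. Cross-tissue agreement is summarized by the
fraction of sign-consistent shared pairs and by weighted Pearson
correlation/WLS slope with weights 1/(se₁²+se₂²) (inverse total variance —
the weighting scheme is a declared choice). Genes regulating more than 10
distinct genera are "broadly regulating"; exactly 10 falls in the
"specifically regulating" class (the boundary is undefined by the >10/<10
phrasing; strict >10 is the declared rule). Gene similarity uses Jaccard
distance (defined 0 for two empty sets) with average-linkage agglomerative
clustering; rows are canonicalized to sorted gene-id order before linkage,
which makes memberships deterministic and invariant to input row order;
the cluster count k is caller-chosen configuration, not inferred.

Taxon enrichment of a genus in a category uses
OR = [n/(n_s−n)]/[(N−n)/(N_s−N−(n_s−n))], which is algebraically the 2×2
cross-product ratio since N_s−N−(n_s−n) = (N_s−n_s)−(N−n); significance is
the right tail of the hypergeometric distribution. Zero-cell ORs are
reported as exact 0/∞ with a +0.5 Haldane-corrected companion column for
plotting; the left (depletion) tail is also reported, clearly labelled as
supplementary. The gene-set engine applies the same right-sided Fisher test
per GMT set against a caller-supplied background (all genes tested in MR),
BH-adjusted across the collection.

## Synthetic data generator

Haplotypes follow a Gaussian copula: latent AR(1) normals (parameter
`ld_rho`) thresholded at Φ⁻¹(maf); genotypes are sums of two independent
haplotypes. Thresholding attenuates correlation, so the LD panel shipped
with each study is the *implied genotype correlation* of the copula,
computed by Gauss–Legendre quadrature of the bivariate-normal orthant
probability — that panel, not the latent ρ^|i−j|, is what clumping, HEIDI
and colocalization consume, and the empirical LD of simulated genotypes
converges to it (mean absolute deviation < 0.05 at n = 20,000).

Every trait gets an independent genotype cohort; the exposure phenotype is
regenerated in downstream cohorts from the same causal SNPs with fresh
noise, so only genetic effects transmit — the two-sample contract. Marginal
per-SNP statistics are exact simple-regression OLS (no approximation).
Scenarios: `causal` (outcome = α·exposure, default α = 0.3, 10
heterogeneous cis effects), `null` (α = 0), `pleiotropy` (direct SNP→
outcome effects γ = 0.05 at the instruments), `shared2`/`linkage`/
`distinct2` (one shared causal variant vs two distinct variants at
moderate/negligible LD, for HEIDI and coloc), and `shared3` (a causal chain
x→y→z with α = (0.4, 0.5) through one dominant and two minor causal SNPs —
dominated by a single variant so the single-causal-variant colocalization
regime applies, while still providing multiple instruments for two-step
MR). Defaults mirror the motivating cohorts: exposure panels of 368/318/174
(intestinal eQTL scale), outcome cohorts of 18,340 with 116-genus-style
continuous abundance traits; an optional rank-inverse-normal transform of
the outcome emulates transformed genus abundances and is flagged as a
stand-in in the truth manifest. The generator does **not** model
compositional 16S noise, zero inflation, sample overlap (unless
deliberately configured), population structure, or genome-wide polygenic
background — passing tests demonstrate correctness of the statistical
machinery under its stated assumptions, not robustness to those real-data
complications.

## Numerical and design notes

- All hypothesis-evidence arithmetic is in log space via log-sum-exp;
  the distinct-assignment inclusion–exclusion clamps non-positive residuals
  (possible only when a locus has fewer SNPs than sharing groups) to zero
  evidence.
- BH FDR is delegated to `statsmodels.multipletests` within scopes; Egger
  to `statsmodels` WLS; Fisher tails to `scipy.stats.hypergeom`; each is
  cross-checked in the tests against an independent brute-force oracle.
- The filter cascade order (multi-IV → Egger → HEIDI → study-wise FDR) is
  explicit configuration; every filtered unit is logged with its reason
  code, and result rows carry a hash of the full configuration so reruns
  with different thresholds never collide (manifests are content-addressed
  by that hash).
- Test and acceptance simulations use locus sizes of 24–60 SNPs and
  cohorts of 3,000–20,000 (per-scenario settings stated in the tests);
  these are the package's own validation scales, chosen so each check
  isolates one statistical property with adequate Monte-Carlo precision.
  Seed counts follow the stated validation design (500 for estimator
  recovery, 1,000 for type-I error, 200 for posterior behaviour).
- Degenerate inputs: empty SNP intersections yield empty harmonized tables
  (not exceptions) for MR, but are errors for colocalization (which cannot
  proceed); zero exposure betas drop the instrument; both-zero z-scores
  give T_SMR = 0, p = 1.

## Known limitations

Single-causal-variant assumptions in SMR/HEIDI and (m)oloc are violated at
multi-signal loci; the simulator's `shared3` chain deliberately keeps one
dominant variant. The delta-method ratio SE ignores exposure uncertainty
and slightly under-covers with weak instruments. Study-wise FDR pooling
scope is ambiguous in the motivating design; both global and per-tissue
pooling are implemented. No liftover, VCF parsing, reference-panel LD
estimation, S-LDSC heritability partitioning, or ontology content is
included.
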