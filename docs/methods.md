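# Methods

## Scope and data model

`colocmr` screens candidate drug-target genes against a disease GWAS
using only summary statistics: per-variant effect estimates (or
z-scores), standard errors, allele frequencies and sample sizes for one
binary outcome trait and one or more quantitative exposure traits
(eQTL/pQTL). Exposure effects are per SD of the expression/protein
trait; outcome effects are log-odds. Coordinates are 1-based closed
intervals on hg38, and a built-in table carries the regions of the
seven type 1 diabetes candidate genes (plus IL23A, which lacks
protein-level data and is reported as an explicit no-data row).

## Harmonisation

The two traits are intersected on variant id (rsID by default; a
chrom:pos:alleles key is equally valid and both are plain strings to
the code). Outcome records whose alleles are swapped relative to the
exposure are re-signed (β → −β, z → −z, eaf → 1−eaf); records matching
neither directly nor swapped are dropped and counted. Palindromic (A/T,
C/G) variants are dropped by default because strand cannot be resolved
from summary data; a flag retains them for sources known to share
strand. Duplicate ids within one file keep the smallest p-value
(logged); duplicates surviving to harmonisation are an error.
Harmonisation is idempotent, and the whole pipeline is invariant under
relabelling any variant's alleles together with the implied sign flips
(this gauge invariance is asserted bitwise in the tests).

## z → (β, se) conversion

eQTL consortia often release z-scores only. For a standardised
phenotype, β = z·(2p(1−p)(n+z²))^(−1/2) and se = (2p(1−p)(n+z²))^(−1/2),
where p is the minor allele frequency (frequencies above 0.5 are
folded) and n the sample size; the exposure study's own frequency is
used. The defining property is β/se = z, so the instrument F statistic
(β/se)² equals z². We enforce the quotient *bitwise*: naive rounding of
z·se leaves β/se one ulp off z for ~10% of inputs, so se is perturbed
by a few ulps (relative changes ≤ ~1e-10, far below any statistical
resolution) until a representable β divides back to z exactly; when z
lies just under a power of two the required offset is solved in exact
rational arithmetic rather than scanned. F is computed as an explicit
product (ratio·ratio) because libm `pow` can differ from the product by
an ulp.

## Colocalisation

Per-variant evidence is the Wakefield approximate Bayes factor,
log ABF = ½(log(1−r) + r z²) with r = W/(W+V), V = se². The prior
effect SD √W defaults to 0.15 for the quantitative exposure and 0.2 for
the binary outcome — the conventional defaults for expression and
disease GWAS — and both are configurable. Under at-most-one causal
variant per trait, hypothesis weights are

    H0: 1          H1: p1·S1       H2: p2·S2
    H3: p1·p2·(S1·S2 − S12)        H4: p12·S12

with S1 = Σe^{l1_j}, S2 = Σe^{l2_j}, S12 = Σe^{l1_j+l2_j} and priors
(p1, p2, p12) = (1e-4, 1e-4, 1e-5). Every sum is a log-sum-exp;
the H3 difference uses log1p(−exp(·)) and is clamped to −∞ when the
argument is non-negative, which happens exactly for single-variant
regions (every product term of S12 appears in S1·S2, so the difference
is mathematically non-negative and zero iff one variant). The tests
check the log-space path against a 50-digit direct-summation oracle to
1e-10 absolute on random regions of up to 50 variants.

The per-variant H4 posterior is softmax(l1+l2); the lead shared causal
variant is its argmax, with ties broken by smaller exposure p-value and
then lexicographic id so results are order-independent. Outcome records
must carry β/se on the log-odds scale; z-only binary-trait records are
deliberately not converted (the quantitative-trait formula does not
apply to case-control designs).

MR proceeds only when P(H4) strictly exceeds the gate (default 0.8).
Multiple exposure traits for one gene (eQTL and pQTL) are separate
rows; no multiplicity adjustment is applied to the posteriors.
Tissue- or cell-type-specific exposures are just additional targets in
the config — the operation is identical, only the exposure file
differs.

## Mendelian randomisation

Single-instrument Wald ratio at the lead variant, unweighted:
θ = β_out/β_exp, se(θ) = se_out/|β_exp| (first-order delta method, the
two-sample MR convention; a second-order option adds the exposure-SE
term, and with the F ≈ 150–330 instruments this screen produces the two
differ by under ~5%). ORs per SD use exp(θ) with 95% CI at the exact
normal quantile 1.959964, and two-sided normal p-values. F < 10 raises
a weak-instrument warning but is not an exclusion rule. Under the null
(β_out ≈ 0) the first-order SE is exact in distribution, which is why
nominal coverage is checked there; with a nonzero θ and very strong
instruments the neglected term is O(θ²·se_exp²/β_exp²) and immaterial
at the screen's instrument strengths.

## Missense-variant arm

Candidates are coding missense variants inside the gene body (not the
flanked cis-window), associated with the exposure at p < 1e-5 — a
Bonferroni-style threshold for a cis-region's worth of independent
tests rather than the genome-wide 5e-8. They are pruned greedily in
ascending p-value order, accepting a variant iff r² < 0.2 against every
already-accepted one, with r² the squared Pearson correlation of
reference-panel dosages; ties in p fall back to lexicographic id so the
selection is deterministic. Each selected variant yields its own Wald
estimate; estimates are never combined. MAF < 0.01 is annotated, not
filtered. The tests verify the greedy rule against an independent
subset-enumeration oracle on all candidate sets up to size 8.

## Synthetic data generator

The generator emulates the screen's study conditions: exposure
n = 31,684 (eQTL-scale), outcome 18,942 cases / 501,638 controls with
effective n = 4/(1/n_cases + 1/n_controls) ≈ 73,011. Haplotypes arise
by thresholding an AR(1) latent Gaussian (adjacent correlation
`ld_decay`, default 0.9) at each variant's MAF quantile (MAF uniform on
(0.1, 0.5) by default, 80 variants spaced 2 kb apart, 1000 haplotypes →
500 diploid reference individuals, 1000-Genomes-EUR scale). Summary
statistics are drawn directly as z ~ MVN(Rλ, R) on the panel's
empirical dosage correlation R, with the non-centrality
λ_c = effect·sqrt(2p(1−p)·n) at the causal variant(s) — zero, one
shared, or two distinct according to the architecture H0–H4. H3
scenarios assert panel r² < 0.3 between the two causal variants at
generation. Allele pairs are sampled from the non-palindromic set so
default harmonisation keeps every variant.

Simulating at the summary level (rather than regressing phenotypes on
genotypes) is orders of magnitude faster and matches the statistical
contract of everything downstream, which consumes summary statistics
only; a user-supplied R is accepted for realistic LD. What the
generator does *not* emulate: coalescent-realistic haplotype structure,
recombination hotspots, population stratification, imputation error,
and meta-analytic heterogeneity — so passing tests demonstrate
correctness of the machinery under the stated model, not robustness to
real-data pathologies such as LD-reference mismatch.

Preset effect sizes are chosen to mirror the motivating screen's
qualitative findings: `il2ra_like` (shared causal variant, true
OR 0.22 per SD, instrument z ≈ 15), `il6r_like` (shared, OR 1.98),
`jak2_like` (distinct causal variants 30 variants apart, latent
correlation 0.9³⁰ → panel r² ≈ 0.01, so MR must be vetoed), and
`tyk2_missense` (shared causal *missense* variant, OR 0.61, shipped
with a four-row candidate table exercising the p-filter, the LD prune
and the gene-region restriction). Per-SD effects at the causal variant
are per-allele effects in trait-SD units; the per-SD causal log-OR is
outcome_effect/exposure_effect.

## Numerical and design choices

- All Bayes-factor work in natural logs; no naive exponentials
  anywhere (z up to ~40 ⇒ ABFs ~e⁸⁰⁰).
- Monomorphic panel columns (possible in tiny panels) are repaired by
  flipping one haplotype; the empirical R is then full-rank for
  n_individuals > n_variants, and MVN draws jitter the diagonal
  (1e-8, then 1e-6) before failing if a user-supplied R is not PSD.
- Posterior percentages are reported to one decimal, ORs to two
  decimals with 95% CI, p-values to two significant figures.
- The config hash covers exactly the semantic fields (targets, priors,
  gate, functional settings, seed), so cosmetic changes (log level,
  output paths) do not perturb provenance.
- Problem sizes in the acceptance studies — 200 replicates for the
  architecture-recovery rates, 500/1000 for Wald recovery/coverage,
  80-variant regions — give Monte-Carlo error comfortably inside the
  asserted bands while keeping the whole run in seconds.

## Known limitations

- One causal variant per trait: with multiple causal variants
  colocalisation can dilute toward H3 even when one variant is shared;
  the missense arm exists precisely for that failure mode, but the
  generator's architecture enum cannot express the mixed case.
- Binary-outcome ABFs take the published log-odds β/se at face value;
  no case-fraction-adjusted effective-n correction is applied on the
  outcome side.
- No liftover, no multi-allelic decomposition, no imputation of missing
  summary statistics, no multi-instrument estimators (IVW/Egger) — the
  design is single-variant cis-MR throughout.
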