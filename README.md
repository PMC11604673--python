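# colocmr

Colocalisation-gated cis-Mendelian randomisation for drug-target
validation from GWAS summary statistics.

## The problem

Drug targets with supporting human genetics succeed more often in
clinical development. Given a disease GWAS (here the motivating use case
is type 1 diabetes, a case-control GWAS of ~19k cases and ~500k
controls) and quantitative trait loci for a candidate target's
expression (whole-blood eQTL, n ≈ 32k) or circulating protein level
(serum pQTL, n ≈ 36k), two questions arise for each target gene:

1. **Is the disease signal near the gene the *same* signal that drives
   the target's level?** Nearby but distinct causal variants produce
   spurious support through linkage disequilibrium (LD).
2. **If so, in which direction and how strongly does the target's level
   move disease risk?**

`colocmr` answers the first with single-causal-variant Bayesian
colocalisation and the second with single-instrument Wald-ratio
Mendelian randomisation (MR), run only when colocalisation supports a
shared causal variant. A parallel arm instruments the target with
coding missense variants, which remains informative when the
one-causal-variant assumption fails.

## The model

For each variant *j* in a cis-region (gene ± 1 Mb), the evidence of
association with a trait is the Wakefield approximate Bayes factor
against the null; with V = se², prior effect variance W and z = β/se,

```
log ABF_j = ½ [ log(1 − r) + r z² ],   r = W / (W + V).
```

Assuming at most one causal variant per trait, the five hypotheses
H0 (no association), H1 (exposure only), H2 (outcome only), H3 (two
distinct causal variants), H4 (one shared causal variant) get
unnormalised weights

```
1,  p1·S1,  p2·S2,  p1·p2·(S1·S2 − S12),  p12·S12
```

where S1 = Σ_j ABF1_j, S2 = Σ_j ABF2_j, S12 = Σ_j ABF1_j·ABF2_j and
(p1, p2, p12) = (1e-4, 1e-4, 1e-5) are the per-variant prior causal
probabilities. All accumulation is done in log space (regional eQTL
z-scores reach |z| ≈ 40).

If P(H4) > 0.8, the lead shared causal variant (argmax of the
per-variant H4 posterior) becomes the MR instrument:

```
θ = β_out / β_exp,   se(θ) = se_out / |β_exp|,   OR per SD = exp(θ),
```

with instrument strength F = (β_exp/se_exp)². Exposure studies that
publish only z-scores are converted with
β = z·(2p(1−p)(n+z²))^(−1/2), se = (2p(1−p)(n+z²))^(−1/2), so β/se = z.

Missense-arm instruments are gene-region missense variants associated
with the exposure at p < 1e-5, greedily LD-pruned to pairwise r² < 0.2
(reference-panel dosage correlations), each used individually.

Because the real GWAS inputs are large external downloads, the package
ships a summary-statistic simulator: haplotypes from a thresholded
AR(1) latent Gaussian give a reference panel and its LD matrix R, and
marginal z-scores are drawn from MVN(Rλ, R) under a chosen causal
architecture H0–H4, with the binary outcome scaled by the effective
sample size 4/(1/n_cases + 1/n_controls).

## Worked example

```bash
colocmr simulate --preset il2ra_like --out-dir sim/
```

writes `exposure.tsv`, `outcome.tsv`, `panel.vcf` and `truth.json` for a
synthetic region with a strongly protective shared causal variant
(true OR 0.22 per SD of expression). Then

```python
import colocmr

sim = colocmr.make_study_fixture("il2ra_like")
harm = colocmr.harmonise(sim.exposure_sumstats, sim.outcome_sumstats)
res = colocmr.coloc_abf(harm)
print({h: round(p, 3) for h, p in res.as_dict().items()})
# {'H0': 0.0, 'H1': 0.0, 'H2': 0.0, 'H3': 0.0, 'H4': 1.0}
est = colocmr.mr_from_coloc(harm, res)
print(est.instrument)         # rs100040  (the true causal variant)
print(est.format_or())        # 0.23 (0.22, 0.25)
print(round(est.f_stat, 1))   # 329.1
```

P(H4) ≈ 1.0 passes the 0.8 gate, the lead variant is the true simulated
causal variant, and the Wald OR per SD (0.23 here) recovers the
generating OR of 0.22 with a strong instrument (F ≈ 329). Under the
`jak2_like` preset (distinct causal variants) the same pipeline returns
P(H3) ≈ 1.0 and skips MR.

The full screen over several targets runs from a YAML config:

```bash
colocmr screen --config screen.yaml --out-dir results/
```

producing `coloc.tsv` (posterior percentages per gene/trait with the
lead variant), `mr.tsv` (OR with 95% CI, p, F per instrument and arm)
and `report.json` (full precision plus run metadata).

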