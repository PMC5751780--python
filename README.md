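# multidcox

Differential co-expression analysis under multiple co-factors: an untargeted,
set-scoring greedy search for gene sets whose *degree of co-expression*
changes across sample groups defined by several covariates at once, with a
linear model that deconvolves and quantifies each factor's influence.

## The problem

Differential co-expression (DCX) — a gene set tightly co-regulated in one
biological condition but not another — signals changed regulatory control:
a transcription factor losing its grip, a mutated pathway, a latent driver.
Most DCX methods compare exactly two groups. Real cohorts are stratified by
*many* co-factors simultaneously (genotype, mutation status, grade,
treatment, sex), and running separate two-group analyses per factor
multiplies tests and confounds interpretation. `multidcox` addresses the
multi-factor case directly: it searches de novo for gene sets and fits one
model per set that attributes co-expression to individual factors with
signed significance calls.

It is aimed at transcriptomics analysts working with processed (log-scale,
normalized) expression matrices and per-sample covariate tables.

## The model

Let `E_im` be expression of gene *i* in sample *m*, and let each sample
carry a factor vector `B_m = (B_m1, …, B_mz)` of binary (−1/+1) or ordinal
codes. Samples with identical factor vectors form a *stratum*. For a gene
set *I* and two samples of the same stratum (`B_mn = B_m = B_n`), the
pairwise co-expression statistic is the squared mean expression change

    A_mn(I) = ( (1/|I|) Σ_{i∈I} (E_im − E_in) )²

— large when the set shifts coherently between the samples (shared signal,
i.e. co-expression), near zero when changes are incoherent. Factor
influence is estimated by ordinary least squares over all within-stratum
sample pairs,

    A(I) ~ 1 + B F,

whose factor coefficient vector `F(I)` is the set's *differential
co-expression profile*; per-factor partial F-tests give nominal p-values.
The intercept absorbs co-expression common to all strata, so a set
co-expressed everywhere is not called differential.

The search proceeds per factor and direction: (1) calibrate a global
coefficient threshold `C_T` from randomly sampled gene pairs (half the
10th-largest pooled |coefficient|); (2) collect significant seed gene
pairs; (3) expand the top seed into a conservative set *J* (accept genes
that strictly improve the target coefficient), augment to *L* by admitting
genes whose centroid-pair profile matches *J*'s under relaxed thresholds
`T_ni`, and filter weak contributors back out leave-one-out; (4) gate each
set's factor calls by an effect-size threshold taken at the valleys of the
pooled coefficient density and by a column-permutation test. Sets with ≥ 6
genes and ≥ 1 surviving factor are reported.

A seedable simulation benchmark reproduces the package's study design —
50,000-probe-style matrices (desk-scale defaults are smaller), three
factors spanning 12 strata, planted 20-gene DCX sets with N(0,1) shared
signal and N(0,σ²) noise — and scores any result for FDR, FNR, profile
failures and false sets.

## Worked example

```python
from multidcox import (RunConfig, SimulationConfig, run_search,
                       score_result, simulate_dataset)

sim = SimulationConfig(n_genes=2000, samples_per_stratum=10, sigma=0.2, rng_seed=2)
expr, factors, truth = simulate_dataset(sim)

result = run_search(expr, factors, RunConfig(rng_seed=22, variance_quantile=0.5))
print(f"C_T = {result.thresholds.C_T:.4f}; {len(result.reported)} DCX gene sets reported")
for s in result.reported:
    print(f"  {s.size:2d} genes  profile [{s.profile}]  "
          f"coefficients {[round(float(c), 3) for c in s.fit.coefficients]}")
metrics = score_result(result.reported, truth)
print(f"set1 Jaccard {metrics['set1_jaccard']:.2f}, "
      f"set2 Jaccard {metrics['set2_jaccard']:.2f}, gene FDR {metrics['fdr']:.2f}")
```

prints

```
C_T = 0.3206; 2 DCX gene sets reported
  20 genes  profile [B1:+1,B2:+1,B3:0]  coefficients [0.641, 0.641, 0.066]
  17 genes  profile [B1:-1,B2:0,B3:0]  coefficients [-1.172, 0.003, 0.441]
set1 Jaccard 0.85, set2 Jaccard 1.00, gene FDR 0.00
```

The 20-gene set is the planted "co-expressed when B1 = +1 and B2 = +1" set,
recovered exactly with both factors called positive; the 17-gene set
recovers the "co-expressed at B1 = −1" set with a negative B1 call and the
null factors correctly zeroed. No spurious sets are reported; the
always-co-expressed control set is absent because its signal loads on the
intercept.

The same pipeline runs from the shell on tab-delimited inputs:

```sh
multidcox simulate --out sim --n-genes 2000 --seed 2
multidcox run --expr sim/expression.tsv --factors sim/factors.tsv \
              --out results --variance-quantile 0.5 --rng-seed 22
multidcox benchmark --out bench --sigmas 0.2 0.8 --replicates 3 --n-genes 2000
```

`run` writes `dcx_sets.tsv` (one row per set: genes, per-factor
coefficient, p-value and signed call) and `run_metadata.json` (thresholds,
seeds, config echo — sufficient to reproduce the run exactly).

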