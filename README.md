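# eqtlsim

Simulation workbench for studying how linkage disequilibrium (LD) among
multiple causal regulatory variants biases cis-eQTL discovery, localization,
and effect-size estimation.

Most eQTL pipelines find a primary association by single-marker regression
and then hunt for secondary signals by *sequential conditional analysis*:
the residual of each discovered SNP becomes the dependent variable of the
next scan. This implicitly assumes causal variants are sparse and weakly
linked. When a gene is instead regulated by several sites in strong LD, the
procedure can merge, split, displace, and misestimate signals. `eqtlsim`
provides a tested pipeline for quantifying those failure modes on synthetic
genotype panels with controlled allele frequencies and LD — no access to a
real genotyped cohort required — plus readers for VCF/dosage-TSV data when a
real panel is available.

## Model

A quantitative expression trait for individual *j* is simulated as

    y_j = sum_i s_i * beta_i * g_ij + e_j,     e_j ~ N(0, 1)

where `g_ij` in {0, 1, 2} is the minor-allele dosage at causal site *i*,
`s_i` in {+1, -1} its direction, and the allelic effect (in trait SD units,
sdu) is parameterized by variance explained relative to unit environmental
noise:

    beta = sqrt(VE / (2 p (1 - p))),   VE = 2 p (1 - p) beta^2

for minor allele frequency *p*. Pairs of variants with an exact LD target
are built from the two-locus haplotype frequencies `p11 = p1 p2 + D`,
`D = r sqrt(p1 q1 p2 q2)`; whole 400-kb cis-windows come from a
latent-Gaussian block model with serial correlation inside LD blocks.

Two closed forms anchor the analysis:

* omitted-variable bias of a univariate estimate when a second linked
  causal site is unmodeled:
  `E[b1_hat] - b1 = r * b2 * sqrt(p2 q2 / (p1 q1))`;
* power of the 1-df association test via the noncentral chi-square with
  noncentrality `n * VE / (1 + VE)`.

Detection follows standard practice: univariate scan, stepwise conditional
discovery at `P < 1e-5`, joint multivariable refit of all peaks. Scoring
includes tagging efficiency and causal capture at the `r^2 > 0.8` credible
cutoff, the Regulatory Trait Concordance score
`RTC = (N_SNPs - rank_causal) / N_SNPs`, a four-way variance decomposition,
and bias surfaces over (true |beta|, mean co-causal LD). A dedicated
masking experiment deletes a simulated causal variant and its close proxies
(an "unimputed" variant) and measures how often the orphaned signal splits
into spurious primary + secondary associations across the minor-allele
frequency spectrum.

## Worked example

```python
import eqtlsim as es

# power to detect a 5%-of-variance effect in 1839 samples at P < 1e-5
print(es.univariate_power(ve=0.05, n=1839, alpha=1e-5))   # 0.9999996

# bias of a univariate estimate when an equally common linked causal
# site (r = 0.7, beta = 0.5 sdu) is omitted from the model
print(es.expected_univariate_bias(0.7, 0.5, 0.25, 0.25))  # 0.35 sdu

# 200 replicates: four same-direction causal sites (VE ~ U(0.02, 0.10))
# in a block-LD cis-window, cohort of 1839
res = es.run_experiment(scenario="4:0", reps=200, seed=0)
print(res.table_detected)
```

prints a detection-count table of the form

```
detected  percent  tagging_proportion
       2      1.5               0.833
       3     25.5               0.993
       4     72.5               0.984
      >4      0.5               0.800
```

i.e. all four sites are recovered in ~73% of replicates, at least one site
is missed in ~27%, and 0.5% of replicates produce a fifth, spurious,
independent peak; bracketed proportions give the fraction of discovered
peaks whose `r^2 > 0.8` credible set contains a true causal site.

The same pipeline is scriptable from the shell:

```
eqtlsim run-scenario --scenario 2:2 --reps 2000 --out runs/s22
eqtlsim mask-experiment --n-trials 800 --mask-cutoff 0.5 --out runs/mask
eqtlsim bias-tools samplesize --r2 0.9 --ve-each 0.1 --tol 0.1
eqtlsim report --scenario-dir runs/s22 --out runs/s22/figs
```

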