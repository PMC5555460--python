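# Methods

## Scope and model

`eqtlsim` studies the behaviour of standard cis-eQTL mapping — univariate
scanning, sequential conditional (stepwise) discovery, and joint
multivariable refitting — when several causal regulatory variants act on one
transcript under realistic linkage disequilibrium. Every quantity is
computed on synthetic diploid dosage genotypes, so the pipeline is fully
self-contained; VCF and dosage-TSV readers provide an entry point for real
panels.

Traits are additive on dosage with unit environmental noise:
`y = sum_i s_i beta_i g_i + N(0,1)`. Variance explained (VE) is defined
*relative to the unit noise*, not to total trait variance; the fraction of
total variance contributed by one independent site is therefore
`VE / (1 + VE)`. Effects are parameterized as `beta = sqrt(VE / (2p(1-p)))`
(sdu per minor allele), so rarer alleles carry larger effects at equal VE.
The trait is not re-standardized after genetic effects are added; all
reported effect estimates are on the simulation's sdu scale.

## Genotype generators

**Two-locus pairs.** For an exact pairwise LD target, haplotypes are drawn
from the four-cell table `p11 = p1 p2 + D`, `D = r sqrt(p1 q1 p2 q2)`, and
paired at random into diploids (random mating), so the expected dosage
correlation equals the haplotype `r`. Feasibility is enforced exactly: the
positive-coupling bound is `sqrt(pmin(1-pmax)/(pmax(1-pmin)))` (perfect LD
requires equal frequencies), while negative coupling is bounded by the
minor/minor cell, which is far tighter for rare alleles; infeasible targets
raise an error naming the attainable range. Columns whose *empirical*
frequency drifts above 0.5 are flipped so dosages always count the minor
allele.

**Cis-window panels.** `simulate_locus` draws 2n haplotypes from a latent
Gaussian with AR(1) serial correlation `rho` inside each LD block
(independent across blocks) and thresholds each variant's latents at its
maf quantile. Within a block, mafs follow a reflected random walk (step SD
0.02) from a fresh spectrum draw at the block start: neighboring variants
on a shared haplotype background have similar frequencies, without which
high dosage r^2 between neighbors is unattainable regardless of the latent
correlation. The default locus alternates high-LD blocks (40 variants,
rho = 0.99) with low-LD blocks (25 variants, rho = 0.4); the high-rho value
was calibrated once so the median adjacent-pair dosage r^2 in high blocks
is about 0.8, giving a mix of strong haplotype blocks and poorly structured
regions in every 400-kb window. Positions are uniform over 400 kb; there is
no mutation/recombination model, no phasing, and no population structure.

**Maf spectra.** `uniform_range` (default U(0.05, 0.5)) represents a
common-variant panel; `rare_shifted` is a scaled Beta(1.3, 15.4) on
[0.01, 0.5] with its mode near maf 0.02, representing the frequency
spectrum of variants missing from an imputation panel. The maf floor is
0.01 throughout.

## Association machinery

Scans are vectorized simple regressions with intercept; p-values come from
the exact t distribution (not a normal approximation) and are clipped at
the smallest subnormal double so exact fits never report p = 0. Stepwise
discovery forwards residuals: scan the current dependent variable, record
the argmin-p variant (ties to the lowest index) with its conditional
estimate if p < alpha (default 1e-5), replace the dependent variable by the
regression residual, and repeat up to `max_steps` (default 10).
Already-selected variants are excluded from later scans, since the residual
is orthogonal only to the most recent pick. Residual forwarding — rather
than refitting all prior peaks as covariates at each scan — is the default
because it is the convention the workbench is built to study; the joint
refit of all peaks afterwards is the "multisite model". Each step records
its incremental share of the original trait variance; the sum telescopes to
`1 - Var(final residual)/Var(y)`.

Joint fits are ordinary least squares with intercept. Variants pairwise
collinear at r^2 >= 1 - 1e-12 with an earlier-listed variant are pruned
(and reported) before fitting; remaining rank deficiency or
n <= #parameters is a hard error — no silent pseudo-inverse.

**Omitted-variable bias.** With two standardized causal genotypes at
correlation r and only the focal one modeled, the univariate slope
converges to `b1 + b2 Cov(g1,g2)/Var(g1)`, i.e. a bias of
`r * b2 * sqrt(p2 q2 / (p1 q1))` with p1 the focal and p2 the omitted maf.
The orientation of the frequency ratio is deliberately pinned by a
simulation oracle in the test suite (the two orientations coincide at
p1 = p2, where the bias is simply `r * b2`, and differ sharply otherwise);
the implemented form is the one the large-n simulations reproduce.

**Power.** The 1-df association statistic is treated as noncentral
chi-square with noncentrality `n * VE / (1 + VE)`; at VE = 0 the power
equals alpha exactly. The closed form is cross-checked against simulation
in the test suite.

**Sample-size search.** `required_sample_size` measures, for each n on a
grid, the mean |beta_hat - beta| over both sites of a jointly fitted
two-SNP pair (equal mafs solving 2p(1-p) = 0.4 by default, so VE = 0.1
means beta = 0.5 sdu) across Monte-Carlo replicates, and returns the
smallest n meeting the tolerance. Mean absolute error is the default
criterion because the accuracy statement it operationalizes does not name
its metric; RMSE and the estimator SD are reported alongside on the same
curve. Replicates whose pair is perfectly collinear in-sample (possible at
small n under tight LD) carry no two-site information and are excluded,
with the count reported. For orientation: the estimator SD under joint
fitting is `sqrt(1/(n * 2p(1-p) * (1-r^2)))`, so the mean absolute error is
about `sqrt(2/pi) * 5/sqrt(n)` at r^2 = 0.9, putting the 0.1-sdu crossing
near n = 1600 on a 100-step grid — comfortably above the 900-sample
threshold quoted for this design.

## Scoring conventions

* **Tagging (peak -> causal).** A peak matches the causal with r^2 above
  the credible cutoff (default 0.8) having the largest true |beta|; a
  causal claimed by an earlier-step peak is unavailable to later peaks.
  The dedup rule keeps tagging proportions bounded by 1. Unmatched peaks
  are spurious.
* **Capture (causal -> peak).** A causal is captured iff any peak exceeds
  the cutoff with it; no dedup, so one peak can capture two causals and
  capture counts can exceed match counts.
* **RTC.** Computed within the replicate's variant panel:
  `(N - rank)/N` with the 0-based rank of the causal variant in the
  ascending-p ordering, ties sharing the minimal rank. Replicate-level
  summaries use the primary scan's ranking and the largest-effect causal.
* **Variance decomposition.** Four coefficients of determination on the
  same replicate: true sites jointly ("Simu"), discovered peaks jointly
  ("Multi"), summed sequential contributions ("Uni"), first peak alone
  ("Single"). Empty peak sets score zero for the discovered quantities.
* **Bias surfaces.** Scored pairs are restricted to peaks matched at the
  credible cutoff; the deviation target is the true signed beta oriented by
  the sign of the peak-causal dosage correlation. Cells are 0.1-sdu by
  0.05-r^2 bins (configurable); empty cells are reported as missing, never
  zero. The tagging-proportion entries of ">k" detection rows average over
  all peaks, including those beyond the k-th (flagged in the run metadata,
  since the convention is ambiguous).

The scenario runner draws a fresh panel per replicate, samples k causal
sites uniformly (optionally under a pairwise-r^2 clique constraint),
assigns VE ~ U(0.02, 0.10) under the sign scenario ("4:0", "3:1", "2:2",
...), and scores everything above. Desk-scale defaults are n = 1839
samples (the cohort scale the study conditions assume) and m = 200 variants
per window — real cis-windows carry many more variants, so per-window
multiple-testing burden is understated; the detection threshold 1e-5 is
kept as the condition of interest. Default replicate count in the CLI is
2000 (the `--paper-scale` flag documents the full-scale settings).

## Masking (pseudo-unimputed variant) experiment

One causal variant is simulated, then deleted from the panel together with
every variant above the mask cutoff in r^2 with it, and stepwise analysis
runs on the remainder. The default cutoff is 0.8, consistent with the
credible-set convention; the splitting illustration the experiment
reproduces uses 0.5, and the cutoff is a first-class knob recorded in every
output (both values appear in the test suite).

The locus model places the causal *between* two proxy branches. Each
branch anchor (same maf as the causal) is generated conditionally on the
causal haplotype at target `r^2 = U(0.7, 1) * r2_best(maf)`; each branch
extends from its anchor as a chain with neighbor r^2 = 0.9. The geometry is
deliberate: branches are conditionally independent given the causal, so
deleting the causal leaves two imperfectly coupled signal paths —
conditioning on the best proxy of one branch leaves residual causal signal
on the other, which is precisely the mechanism that splits one effect into
a spurious "independent" secondary association. Within a branch, strong
mutual LD keeps the number of spurious signals bounded. Independent common
background variants (maf U(0.05, 0.5)) complete the panel.

The tagging-efficiency curve `r2_best(maf)` is a declared parametric
stand-in for the (unrecoverable) empirical maf -> best-tag relationship of
a real imputation panel: logistic in log10(maf) with r2_max = 0.85,
midpoint 10^-1.58, scale 0.18, giving ~0.08 at maf 0.01, ~0.70 at 0.05 and
~0.84 for common variants. The steep collapse at rarity encodes the
defining feature of unimputed variants — rare ones are usually so poorly
proxied that they yield no association signal at all, while common ones are
almost always strongly tagged. Curve parameters and the maf spectrum are
serialized into every summary.

Trials are aggregated into maf bins (default edges 0.01, 0.02, 0.05, 0.1,
0.2, 0.5) with Clopper-Pearson 95% intervals; the cumulative spurious
proportion is the secondary-signal rate per bin weighted by the analytic
spectrum mass of the bin (renormalized over observed bins). A pure-function
calculator extrapolates a genome-wide count from user-supplied cohort
constants (number of unobserved variants, genic fraction, functional
fraction); it asserts nothing about any particular cohort.

## Seeding and reproducibility

Every generator takes a seed or `numpy` Generator. Replicated experiments
spawn replicate k's stream as `SeedSequence([master_seed, k])`, so a
replicate's results are invariant to the total replicate count and any run
is regenerable from its manifest (config echo, package version, output
checksums) alone.

## What the synthetic panels do and do not show

The latent-Gaussian block model reproduces the features the analyses are
sensitive to — block-structured dosage LD with realistic decay, maf-similar
neighbors, a maf floor, controllable pairwise targets — but not allele-age
/ frequency-dependent LD, recombination hotspots, population structure, or
the long-range tail of real haplotype sharing. Consequently, detection-count
and tagging tables produced here reproduce the *qualitative* patterns of
multisite interference (missed antagonistic pairs, spurious extra peaks in
reinforcing configurations, RTC degradation with multisite regulation, the
conditional-vs-joint bias ordering), not the numeric percentages any
particular cohort would give. Closed-form quantities (VE arithmetic, the
bias formula, power, the two-SNP sample-size curve) are exact properties of
the model and transfer directly.

Other known limitations: effects are strictly additive (no dominance,
epistasis, or GxE); noise is Gaussian with no measurement-error model;
trans effects and covariates are out of scope; multi-allelic variants and
indels are not represented; and the masking experiment's LD geometry is a
two-branch idealization of a real block neighborhood.
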