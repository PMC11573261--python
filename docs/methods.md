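# Methods

## Model and procedure

The scan treats one quantitative phenotype and a panel of biallelic SNPs
over the same cohort. Per SNP, genotypes are encoded as microstates
x ∈ {+1, 0, −1} (base-pair rule AA = TT = +1, GG = CC = −1, otherwise 0;
numeric dosages 2/1/0 map to +1/0/−1). Phenotypes are first adjusted for
fixed effects with an ordinary least-squares model on a treatment-coded
design (optionally after a natural-log transform); the residuals are
ranked ascending, and the genetic path θ(i) is the cumulative microstate
sum along that ranking. The endpoint θ(N) = N₊ − N₋ is conserved under
any ordering, so all information sits in the shape of
Δθ(i) = θ(i) − (N₊ − N₋)·i/N.

The test statistic is the combinatorial path probability p^GIFT: the
global maximum and minimum of Δθ split the ordering into three regions,
and p^GIFT is the probability that a uniformly random arrangement of the
same microstate multiset reproduces the observed per-region microstate
composition — a product of three per-region multinomial coefficients over
the total multinomial coefficient. Exactness of this identity is verified
in the test suite by exhaustive enumeration over every composition with
N ≤ 10.

Because p^GIFT is the probability of a particular arrangement class, it
is *not* uniform under the null: at N = 565 a typical null path already
has p^GIFT ≈ 10⁻⁵. Significance therefore uses permutation calibration:
K random arrangements per reference composition are scored, and the
(1 − α) quantiles of the pooled −log10 p^GIFT provide the 95%/99%
genome-wide lines. Benjamini–Hochberg adjustment across the scan
(p_GIFT) is applied and reported as well, but with this statistic a BH
cut at conventional FDR levels flags essentially every SNP in large
cohorts; the calibrated lines are the operative decision rule, and the
Manhattan plot draws them.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `calibration_k` | 1000 | permutation replicates per composition; threshold Monte-Carlo error ≈ a few percent at the 95% quantile |
| `alphas` | (0.05, 0.01) | significance levels; threshold(α) = (1 − α) pooled null quantile of −log10 p^GIFT |
| `maf_min` | 0.05 | minor-allele-frequency filter |
| `call_rate_max_missing` | 0.10 | per-SNP missingness ceiling ("call rate 10%" read as max 10% missing; configurable) |
| `hwe_p_min` | 1e−6 | 1-df chi-square Hardy–Weinberg filter |
| `r2_max` (LD pruning) | 0.1 | squared-correlation ceiling for the independent-SNP count feeding −log10(α/N_independent) Bonferroni lines for the GWAS baseline |
| `tie_policy` | stable | residual ties: keep input order (warning; the method assumes unique phenotypic values), or seeded random |
| `extremum_on` | delta | regions delimited on Δθ; a `theta` switch exists but Δθ is strongly preferred (see below) |

## Synthetic data

`fisher_sim` draws genotypes from Hardy–Weinberg proportions and adds
a·x + d·(1 − |x|) to a Normal(mean, variance) phenotype — the classical
additive/dominance parameterization in which d shifts heterozygotes only.
Its defaults are the reference study conditions: n = 1000, phenotype mean
68 and variance 4 (sd 2), allele frequency 0.8 (genotype frequencies
64/32/4%), gene effect a = 2 (one phenotype sd), no dominance.
`theoretic_snp` produces exact-count microstate multisets; the six
reference compositions at N = 565 (N₊ = 25 throughout, 100 microstates
shifted from the −1 to the 0 class between entries) are exported as
`REFERENCE_NULL_COMPOSITIONS`. `null_scan_dataset` builds all-null panels
with per-SNP allele frequencies drawn uniformly on [0.1, 0.9] — chosen so
panels pass the default MAF filter and span the common-variant range.
For the all-null type-I check the cohort size is 565 individuals, the
reference-composition sample size.

The generator emulates a single unlinked causal variant with independent
SNPs and i.i.d. Gaussian noise. It does not produce linkage
disequilibrium between markers, pedigree/relatedness structure,
non-Gaussian phenotypes, or a mechanistic model of scale-dependent
(sigmoid-path) associations — `two_subpopulation_mixture` draws
sigmoid-like paths purely as a demonstration construction. Passing tests
therefore show correctness of the statistics under these idealized
conditions, not robustness to stratification or LD in real cohorts.

## Numerical choices

* All p-value arithmetic is in natural-log space via `scipy.special.gammaln`;
  log₁₀ N⁰path agrees with exact integer factorials to 12 significant
  digits for N ≤ 20 and stays finite at N = 10,000. BH adjustment is also
  performed in log space (a step-up on log p + log(m/rank) with a reverse
  cumulative minimum), since p^GIFT underflows double precision near
  N ≈ 1000; the log-space variant is cross-checked against statsmodels'
  `fdr_bh` in the ordinary range. Reported `p_raw`/`p_adj` columns may
  underflow to 0.0; the −log10 columns carry the information.
* Extrema are located with first-occurrence tie-breaking; boundaries are
  sorted so regions always read left-to-right. A flat Δθ (including
  single-microstate-type SNPs) degenerates to boundaries (argmax, N) and
  scores p^GIFT = 1, never an error.
* Regions are delimited on Δθ, not θ: the subtraction cancels the
  composition-dependent slope, and empirically the null quantiles of
  −log10 p^GIFT are nearly composition-independent on Δθ (relative spread
  ≈ 0.2 across the reference compositions) but vary by a factor ≈ 3 on θ.
* Null ensembles shuffle the explicit multiset (never position-wise
  independent draws), so every replicate conserves the endpoint; a single
  root seed makes ensembles, calibrations and scans reproducible.
* Missing genotypes drop the individual for that SNP only; counts, the
  ordering and the null line are recomputed per SNP. Missing residuals
  drop the individual from the scan.
* Fixed-effect residuals come from `numpy.linalg.lstsq` on a full-rank
  treatment-coded design; single-level covariates are dropped with a
  warning. The HWE filter is a 1-df chi-square (no mid-p exact test); LD
  pruning is greedy left-to-right within chromosome against all
  previously kept SNPs (mean-imputed dosages for the correlation).
* Scan-level calibration defaults to up to six compositions spread evenly
  over the scanned SNPs' heterozygote fractions — sufficient because of
  the near composition-independence above; the reference panel can be
  passed explicitly.

## Design decisions taken where the design was open

* **Type-I control.** Because p^GIFT is not uniform, "rejection at level
  α" means exceeding the calibrated (1 − α) null quantile, not
  p^GIFT < α. With matched calibration the measured rejection rate on a
  500-SNP all-null scan is 5.0% at the 95% line.
* **Threshold stability.** The across-composition relative spread
  (max − min)/mean of the 95%/99% null quantiles over the six reference
  compositions measures ≈ 0.17–0.22 at K = 1000. The middle four
  compositions agree within ≈ 2%; the two extreme compositions are capped
  by their smaller log₁₀ N⁰path (an arrangement probability cannot be
  smaller than 1/N⁰path), which pulls their quantiles down. Pooled
  thresholds are used for decisions; the per-composition table quantifies
  the spread rather than hiding it.
* **Effect sign convention.** a = (μ₊ − μ₋)/2 is signed; negating the
  encoding negates a and the regression slope while leaving d, |t| and
  p-values unchanged (property-tested). The two-group comparison uses
  Student's pooled-variance t-test, the classical default.
* **Phenotype ties.** The method assumes phenotypic residuals are unique;
  ties warn and default to stable input-order breaking so results are
  deterministic, with a seeded random policy available.

## Problem sizes

Default test and reproduction runs use K = 1000 permutation replicates
per composition (K = 2000 for variance-law checks), 500-SNP null panels,
and 10 replicates of the causal-power simulation; the full suite and the
reproduction script each complete in well under a minute on one CPU.

## Known limitations

* No mixed-model / kinship correction: confounding by relatedness or
  stratification is not addressed (the GWAS baseline is plain OLS, not a
  GEMMA-style mixed model).
* Strand handling follows the literal base-pair rule; an A/T or G/C SNP
  collapses both homozygote classes onto one microstate value, which the
  rule inherits by construction.
* Multi-allelic sites, imputation and phasing are out of scope; the
  shape classification of paths (paraboloid vs sigmoid) is visual, not
  algorithmic.
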