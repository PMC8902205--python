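# Methods

`candgene` re-implements the statistical core of a small candidate-gene
association study: a few hundred animals genotyped at a handful of SNPs
in one gene, summarized by locus diversity statistics, phased into
haplotypes by EM, screened for linkage disequilibrium, and tested for
association with continuous body-conformation traits under a
fixed-effects linear model. This note records the models, the defaults,
and the choices made where the design was genuinely open.

## Locus statistics

Allele frequencies come from gene counting:
`p = (2·n_refhom + n_het) / (2n)`. The diversity indices follow the
Nei/Chakraborty conventions used in livestock diversity reports:
expected homozygosity `Ho = Σ p_i²` ("gene homozygosity"), gene
diversity `He = 1 − Ho`, effective allele number `Ne = 1/Ho`, and the
Botstein polymorphism information content
`PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²` (biallelic form
`He − 2p²q²`). `Ho` here is the *expected* homozygosity, not the
observed homozygote proportion; the observed heterozygote fraction is
reported separately as `het_obs`.

The Hardy-Weinberg test is the plain chi-square
`Σ (obs − exp)²/exp` against `n·(p², 2pq, q²)` with allele frequencies
estimated from the same sample, no continuity correction and no exact
test. Degrees of freedom are configurable: `legacy` mode (default) uses
2 df, matching the convention of older population-genetics packages
(POPGENE-era) whose output many diversity tables in the cattle
literature reproduce; `standard` mode uses the textbook 1 df (three
genotype classes minus one estimated allele frequency). The statistic
is identical in both modes; only the tail changes. Monomorphic loci are
reported as flagged rows, not errors, when summarized over a panel.

## EM haplotype phasing

Haplotype frequencies are estimated by the classical EM over phase
configurations. For an individual with `h` heterozygous loci there are
`max(1, 2^(h−1))` unordered compatible haplotype pairs; the E-step
weights each pair by `2 f_h f_k` (or `f_h²` for a homozygous pair)
under random union of gametes and normalizes within the individual, and
the M-step sets each frequency to its expected gamete share. The
log-likelihood is non-decreasing by construction and the implementation
records the full trajectory so tests can assert it.

Numerical choices:

* Identical multi-locus genotype patterns are collapsed into weighted
  groups before iteration — an exact reformulation that makes the cost
  depend on the number of distinct genotype patterns, not on herd size.
* Initialization is the linkage-equilibrium product of observed allele
  frequencies. The all-double-heterozygote configuration makes that
  point a stationary saddle, so each of the default 5 restarts applies
  a small seed-driven multiplicative jitter and the restart with the
  best final log-likelihood wins. Results are reproducible for a fixed
  seed.
* Convergence: absolute log-likelihood change below 1e-8, cap of 1000
  iterations; hitting the cap returns `converged=False` rather than
  failing silently.
* Multi-locus estimation uses listwise-complete cases; pairwise LD uses
  pairwise-complete cases — what a genotype-table tool can do without
  imputation, which is out of scope.

Haplotype filtering drops estimates below 5% (configurable) and, as in
the field's reporting convention, does **not** renormalize the retained
frequencies; the discarded count and mass are reported.

## Linkage disequilibrium

For each locus pair the two-locus EM frequencies give
`D = f_AB − p_A p_B`, `D′ = |D| / D_max` with
`D_max = min(p_A p_b, p_a p_B)` for `D > 0` and
`min(p_A p_B, p_a p_b)` otherwise, and
`r² = D² / (p_A p_a p_B p_b)`. `D′` at exactly `D = 0` is defined as 0
(linkage equilibrium). Pairs with `r² > 0.33` are flagged as strong LD —
the conventional threshold for LD being useful in mapping. Matrix
summaries report the means of `D′` and `r²` over all `L(L−1)/2` pairs.
Both statistics are invariant to which allele is labelled reference,
which is property-tested.

## Diplotype assignment

Each complete-case individual is assigned its maximum-posterior
compatible haplotype pair under the EM frequencies (hard assignment,
deterministic lexicographic tie-break), mirroring the hard
"combined haplotype" classes such studies report. Individuals
incompatible with every retained pair fall back to the unfiltered
estimate and are flagged. Diplotype classes are labelled by their
concatenated per-locus genotype strings (e.g. `GGGGCCTTAA`), which is
unambiguous where haplotype-numbering schemes are not, and classes
below 5% population frequency are excluded from association.

## Association model

Each trait is analyzed with OLS on
`y = mu + class + age + sire + e`, reference-level dummy coding, one
classification at a time (a SNP's genotypes or the diplotype classes).
Age is categorical. Sire is described in this literature as a random
effect but is fitted here as a fixed blocking factor: the original
analyses used general-linear-model software, a fixed-factor GLM is the
reproducible reading, and REML variance components are explicitly out
of scope. This is a documented deviation, not an oversight.

Least-squares means are the class predictions averaged over covariate
levels with equal weight, with standard errors from the coefficient
covariance; raw class means ± SE are reported alongside since published
tables rarely say which they print. The overall class effect is a
partial F-test on the class dummies. All `k(k−1)/2` pairwise class
contrasts within one trait × classification family are t-tested and
Bonferroni-adjusted (`min(1, m·p)`); the family never spans traits or
markers, matching per-column superscript letters. Grouping letters come
from a greedy clique cover of the non-significant-pair graph in
descending LS-mean order. Rank-deficient designs (e.g. a class
confounded with sire) raise an error naming the aliased columns.

## Synthetic herd generator

The generator emulates the study population so the pipeline is testable
without any real data. Gametes are drawn independently from a fixed
haplotype pool — by default the five common 5-locus GDF8 haplotypes at
31.5/23.8/23.5/5.8/5.2% with the residual 10.2% spread uniformly over 7
rare filler haplotypes (12 distinct haplotypes in total), so the <5%
filter retains exactly the five common ones in expectation. Default
herd size is 380. Random mating means Hardy-Weinberg and the pool's LD
structure hold at population level; an optional `inbreeding` parameter
(probability the second gamete copies the first) induces controlled
heterozygote deficits for HWE-violation scenarios.

Traits are additive: baseline + diplotype-class effect + age-class
effect + sire effect + Gaussian residual, with age and sire assigned
uniformly (3 age classes, 10 sires by default) and per-level effects
drawn once per run at SD 1.5 cm. Baselines (BL 126, WH 110, HH 110,
HG 149, AGR 168, HW 31.5, PBW 17.5 cm) and residual SDs (7, 4.5, 4.5,
8, 6, 3, 1.8 cm) are invented: true residual variances are never
published for such tables, so SDs were chosen once to put class-mean
standard errors in the 0.5–1.5 cm range typical of these reports. The
default effect map gives the most-common-haplotype homozygote
(`CACTA/CACTA`) modest advantages on WH, HH, HG, AGR and PBW, the
qualitative pattern such studies describe.

What the generator does *not* emulate: genotyping error, pedigree
structure beyond one sire level, selection, linked new mutations, or
non-Gaussian trait errors. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
real-data artifacts.

## Verification strategy and problem sizes

Every estimator is checked against an independent route: allele
frequencies against literal allele enumeration; the HWE statistic
against a scipy-based recomputation on 1000 random count triples; EM
against a multi-start SLSQP maximization of the phase-mixture
likelihood over the frequency simplex on instances small enough
(≤3 loci, ≤12 individuals) for that oracle to be trustworthy, at 1e-4;
LD closed forms against hand-computed cases; the fixed-effects model
against one-way ANOVA in the balanced no-covariate case. End-to-end,
phasing a simulated 380-head herd recovers the generating frequency of
the most common haplotype within 3 binomial SEs per seed and within 2
percentage points on a 10-seed average; the overall F-test's type-I
error under a null with 2000 replicate trait draws (conditioning on one
genotype draw, for runtime) must land in the 99% Monte-Carlo band
[3.7%, 6.3%] around 5%. The full default pipeline runs in seconds and
is byte-identical across reruns with one seed, because all rounding
(frequencies 2 d.p., indices and LD 3 d.p., trait means 2 d.p.,
haplotype percentages 2 d.p.) happens only at render time.

## Known limitations

* No mixed model / REML for sire; no additive-dominance decomposition.
* No imputation of missing genotypes or traits; complete-case only.
* Multi-allelic generalizations of the diversity formulas are computed
  but only biallelic loci are exercised by the panel.
* EM phasing enumerates `2^(h−1)` pairs per individual, fine for
  candidate-gene panels (here L=5), not for genome-scale phasing; no
  partition-ligation.
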