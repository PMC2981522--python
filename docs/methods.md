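# Methods

## Data model and conventions

A family is a complete trio — father, mother, affected child — genotyped
at biallelic SNPs with 1-based physical coordinates; region selection is
inclusive on both ends and a region's printed "width" is the difference of
its end coordinates.  Genotypes are unordered allele pairs; an allele
coded `0` in PED input marks the whole genotype missing.  Families whose
parents cannot be resolved are dropped, never imputed: every downstream
method conditions on parental genotypes, so incomplete families carry no
usable transmission information.

## Quality control

Order: (1) Mendelian masking — any (family, SNP) triple inconsistent with
Mendelian inheritance is set to missing for all three members; (2) per-SNP
call rate over all individuals (default threshold 0.95); (3) minor allele
frequency (default 0.01) and a two-sided exact Hardy-Weinberg test
(default α = 0.001), both in parents only, because affected-child
ascertainment distorts child genotype proportions.  Masking precedes the
call-rate computation, which changes results marginally relative to the
opposite order; the order is fixed for reproducibility and the report
records every action and all failure reasons.  The HWE test conditions on
the minor-allele count and sums the probabilities of all heterozygote
counts no more probable than the observed one.

## Single-marker TDT

For effect allele *e*, every heterozygous parental meiosis with complete
family genotypes is informative; `T` counts transmissions of *e* and `U`
non-transmissions.  When both parents are heterozygous and the child is
heterozygous the per-allele bookkeeping still credits exactly one T and
one U.  Inference:

* exact two-sided p: binomial test of `T` in `T+U` trials at ½, two-sided
  by the minimum-likelihood convention (sum of outcome probabilities not
  exceeding the observed outcome's);
* relative risk: under a multiplicative model the conditional-ML estimate
  is `T/U`, with Wald 95% CI `exp(ln(T/U) ± 1.96·√(1/T+1/U))`.  A zero
  cell gets +0.5 added to both counts and the result flagged;
* permutation p: label-flipping of meioses, which for a single SNP *is*
  the exact binomial null; an optional adaptive mode stops early once the
  Wilson 99% interval of the estimate lies above α (off by default —
  fixed replicate counts reproduce exactly).

## Haplotype phasing

All Mendelian-consistent assignments of ordered parental haplotype pairs
and transmissions are enumerated per family (missing genotypes are summed
over; the enumeration is bounded at 10 SNPs, and pairs are analysed in
practice).  An EM algorithm estimates founder haplotype frequencies: the
E-step weights each configuration by the product of its four
founder-haplotype frequencies, the M-step re-estimates frequencies from
the weighted counts.  Defaults: uniform start, tolerance 1e-8 on the
log-likelihood, max 1000 iterations, haplotypes below 1e-10 pruned.
Families are grouped by genotype pattern so the enumeration runs once per
distinct pattern.  The likelihood surface can hold local optima and the
uniform start can sit on a symmetric saddle; `n_restarts` adds seeded
Dirichlet restarts and keeps the best likelihood (used by the tests that
compare EM against exhaustive maximisation).  Phase posteriors become the
fractional weights used everywhere downstream — this is why haplotype
tables show decimal transmitted counts.

## Haplotype TDT and its Monte-Carlo null

Fractional counts `T_h`, `U_h` accumulate posterior weights over parental
meioses; the global statistic is `Σ_h (T_h−U_h)²/(T_h+U_h)` over
haplotypes with any transmissions.  The null is *not* generated by
flipping transmitted/untransmitted labels with the posterior weights held
fixed: that construction is measurably anti-conservative, because
re-randomising a transmission changes the child genotype and with it the
phase-ambiguity structure the weights came from.  Instead the null is
sampled at the data level: per meiosis a gamete is redrawn given the
parental genotypes (haplotype pairs weighted by the EM frequency
estimates, either member transmitted with probability ½), the
pseudo-child genotype is re-masked with the family's observed
missingness, and the expected fractional counts are recomputed by the
same E-step.  Founder genotypes are preserved, retaining the TDT's
robustness to stratification.  Distinct family patterns are precomputed,
so each of the `n_perm` draws is a set of multinomial samples.  Empirical
size at α = 0.05 over two independent 1000-replicate null batches:
0.050 and 0.062 (hap-TDT), 0.061 and 0.048 (conditional scan).

The conditional screen for secondary signals restricts to meioses whose
transmitted and untransmitted haplotypes share the index-SNP allele but
differ at the candidate — meioses where the index hypothesis makes no
prediction — and tests candidate transmissions against ½ within
index-allele strata, with the same Monte-Carlo null additionally
conditioned on the child's observed index genotype.  A candidate in
perfect LD with the index has no informative meioses and is never
selected.  The two-marker scan tests all pairs of selected SNPs, ranks by
permutation p with coordinate tie-breaks, and reports Bonferroni-adjusted
p alongside.

## Conditional logistic regression

Each phase configuration of a trio defines a matched set: the case is the
transmitted haplotype pair, the three pseudo-controls are the other
combinations of the four parental haplotypes; covariates are per-copy
dosages (alleles, haplotypes, or collapsed coding-variant classes), so
`exp(β)` is a per-copy relative risk.  With ambiguous phase the family
likelihood is a mixture over its distinct parental phase assignments with
prior weights proportional to founder-frequency products (numerator: all
consistent configurations; denominator: each phase's four equally likely
offspring).  The alternative of raising each configuration's term to its
posterior weight — a geometric mean — is retained as `method="weighted"`
but attenuates coefficients of phase-uncertain covariates and is not the
default.  Newton-Raphson from β = 0 with step halving; convergence at
|Δlog-lik| < 1e-10 or 100 iterations; separation is flagged rather than
reported as converged; singular designs raise an error naming the
collinear covariates.  Wald intervals match the reporting style of the
field; a likelihood-ratio p against β = 0 is available.  For a single SNP
the fit reproduces `T/U` to numerical precision (asserted in tests).

## Synthetic-association assessment

Coding variants are observed as per-individual carrier statuses, not
phased haplotypes.  Each collapsed class (carrier of ≥ 1 variant — the
Li–Leal burden indicator; missing status counts as non-carrier, logged)
becomes one extra biallelic pseudo-locus: carriers are heterozygous
wild-type/variant, and the trio EM assigns the variant allele to a
parental haplotype probabilistically.  On the extended phasing the
package computes: (1) the stratified transmission table — fractional T/U
per (two-marker haplotype × background) cell, with
expected-under-independence frequencies as products of the marginals;
cell sums over backgrounds reproduce the unstratified table exactly;
(2) carrier-removal analysis — TDT and haplotype TDT before/after
dropping trios whose index child (configurably: any member) carries a
class variant; (3) three hierarchical models — SNP dosages only,
collapsed coding covariates only, and all jointly.  For protective
polymorphisms the risk-direction covariate is the wild-type (major)
allele dosage; for functional mutations the mutated-allele dosage.  With
zero carriers the coding-only model reports its failure and the joint
model degrades to the SNP model, with a note.

## Power

Under multiplicative per-allele risk *r* and rare-disease ascertainment,
a transmitted founder allele is the risk allele with probability
`p·r/(p·r+q)`, untransmitted alleles stay at the population frequency,
and transmissions from heterozygous parents are Bernoulli(`r/(1+r)`).
The analytic power fixes the informative-meiosis count at its expectation
and applies a normal approximation; the simulation twin draws parental
genotypes from HWE, ascertains by rejection sampling proportional to
`r^(child risk-allele count)`, and applies the exact binomial TDT.  The
simulation is authoritative (the analytic form ignores discreteness,
overstating power by under a point at the default design); both are
monotone in sample size and effect size.

## Synthetic data

Founder haplotypes are drawn i.i.d. from a pool; coding variants are
placed on designated host haplotypes with a within-host carrier
frequency; each parent transmits one haplotype; the family is accepted
with probability proportional to the child's multiplicative risk
(per-copy haplotype effect, optionally a wildcard pattern so a per-allele
SNP effect is expressible, times per-carried-variant effects), normalised
by the maximum possible product.  Missingness and Mendelian-error
injection (one random allele flipped in one member) come last; the
`SimTruth` sidecar records all latent state first, enabling bias and
coverage measurement against known truth.

Defaults emulate the motivating study: two SNPs 201,708 bp apart; risk
haplotype [A; G] with per-copy hRR 1.61; published *parental* haplotype
frequencies (0.646/0.157/0.134/0.063) de-tilted to population scale so
that ascertained parents reproduce them — each parent carries one
risk-enriched and one population-frequency haplotype, `t_h = p_h(1 +
r_h/E)/2` with `E = Σ p_h r_h`, inverted by fixed point — which also puts
the index SNP's parental effect-allele frequency near 0.29; two
protective polymorphisms on the [G; G] background (within-host
frequencies 0.086 and 0.023, per-copy RR 0.60, chosen once to land near
carrier counts of ~85 and ~23 per 787 children); and two
functional-mutation clusters on [G; G] and [A; G] with collapsed RR 2.6
and a collapsed carrier rate of 2–3%.

What the generator does *not* emulate: within-region recombination (the
modelled region lies between recombination hotspots, so pool haplotypes
are transmitted intact), population stratification, genotyping-batch
structure, and linkage between the region and other loci.  Passing tests
therefore demonstrate correctness of the estimators and calibration of
the tests under the stated sampling model, not robustness to those
real-data complications — though the TDT family of tests is insensitive
to stratification by construction.

## Problem sizes in the test suite

Null calibrations use 1000 replicates of 400 trios with 199 Monte-Carlo
null draws each (the 0.05 rejection threshold is exactly attainable at
that resolution); parameter-recovery runs use 200 replicates at the
study's sample sizes (787 trios for the haplotype effect, 525 for the
collapsed-variant effect); the power target uses at least 5000
replicates.  These sizes keep Monte-Carlo error comfortably inside the
asserted bands.

## Known limitations

* Carrier statuses are individual-level, so the variant-to-haplotype
  assignment is probabilistic; coefficients of collapsed covariates carry
  a small residual attenuation (measured ≈1–3% on the default designs)
  that full haplotype-resolved data would remove.
* EM frequency estimates from ascertained founders are mildly tilted by
  true risk effects; the Monte-Carlo nulls and mixture priors use these
  estimates, which is standard practice but not exact.
* The exact HWE test and exact TDT are conservative at small counts, as
  all discrete exact tests are.
* Multi-allelic sites, X-linked inheritance, parent-of-origin effects and
  extended pedigrees are out of scope.
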