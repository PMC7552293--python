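# Methods

## Two-stage pooled screen and its expectation

The screen genotypes a cohort of `N` diploid individuals at one biallelic
indel. Samples are randomly permuted and chunked into consecutive pools of
size `a`; the remainder, if any, forms one smaller final pool. Each pool
costs one PCR reaction. A pool whose members all share one genotype is called
wholesale; a pool showing **mixed genotypes** sends every member to an
individual retest (one reaction each). Note the trigger is "genotypes
differ", not "contains a carrier": a hypothetical all-heterozygote pool would
not be retested. At the allele frequencies this design targets (MAF ≲ 0.05)
the two events coincide for all practical purposes.

With detection-positive frequency `p`, the probability a pool of `a` is
uniform-negative is `(1−p)^a`, and the expected reaction count is

```
n(a) = N · ( 1/a · (1−p)^a + (1 + 1/a) · (1 − (1−p)^a) )
     = N · ( 1/a + 1 − (1−p)^a )        (identical algebraically)
```

The design module evaluates this as a continuous expectation, ignoring the
remainder pool (the simulator handles the remainder explicitly; at
`N = 2350, a = 11` the difference is under half a reaction). Ties in the
integer argmin are broken toward smaller `a`, which puts fewer samples at
risk per retest batch. Reported reaction counts are rounded to one decimal.
The continuous optimum sits near `a* ≈ 1/√p`; for `p = 0.01` the integer
optimum over [3, 20] is 11 with `n = 459.6` for `N = 2350`, 19.6% of the
one-by-one budget.

**MAF versus carrier frequency.** Following the field's practice, the pilot
MAF estimate is plugged directly into the formula as `p`. Under
Hardy–Weinberg the probability an *individual* triggers pool positivity is
the carrier frequency `2p(1−p) + p² ≈ 2p`, roughly double the MAF, so the
formula under-predicts the realized reaction count when the two notions are
conflated. The simulator exposes the per-individual positivity probability
as its own parameter (`carrier_prob`), and a test documents that simulating
at `2p(1−p)` exceeds the MAF-based prediction. The acceptance computation
uses positivity probability = `p` = 0.01, matching the design convention.

**Assay model.** Error-free by default: pool calls and retest calls always
equal the true genotypes, so the simulator's genotype output is a round-trip
identity and only the reaction accounting is stochastic. A per-pool
false-negative rate flag exists for sensitivity exploration but defaults
to 0. One integer seed drives both the pooling permutation and any assay
noise.

## Pilot MAF

From pilot genotype counts `(n_II, n_ID, n_DD)`,
`maf = (n_ID + 2 n_DD) / (2 n)`, folded to the minor side (≤ 0.5). A pilot
of 50 with one heterozygote gives 0.01.

## Population parameters

Per breed: genotype frequencies, allele frequencies
`q = (n_ID + 2 n_DD)/(2n)`, MAF = min(p, q), and the Nei panel computed from
allele frequencies: homozygosity `Ho = p² + q²`, heterozygosity
`He = 1 − Ho`, effective allele number `Ne = 1/Ho`. The expected
(allele-frequency-based) definitions were chosen over observed genotype
shares; for rare variants the two agree at the three-decimal precision used
in tables (`He = 2pq` vs observed heterozygote share differ only in the
`p²`-order terms). Monomorphic breeds are legal inputs (`He = 0, Ne = 1`).
Table output rounds half-up to three decimals; full precision is retained
internally. An exact Hardy–Weinberg test (conditional on allele counts) is
available as an optional diagnostic but is not part of the standard table.

## Linkage disequilibrium

Unphased genotypes at two biallelic loci are coded 0/1/2 copies of the
variant allele. Under random union of gametes the only phase-ambiguous class
is the double heterozygote; EM iterates between phasing those individuals
(E-step weight `h_AB·h_ab / (h_AB·h_ab + h_Ab·h_aB)`) and re-estimating the
four haplotype frequencies by counting (M-step). Initialization is at
linkage equilibrium `p_AB = p_A p_B`; convergence is declared when the
log-likelihood changes by less than 1e-8 (default), capped at 1000
iterations with an explicit `converged` flag rather than silent return. The
log-likelihood trace is retained on the result so monotonicity is
assertable. EM preserves the observed allele-frequency margins exactly.

From the converged frequencies: `D = p_AB − p_A p_B`;
`D_max = min(p_A(1−p_B), (1−p_A)p_B)` for `D > 0` and
`min(p_A p_B, (1−p_A)(1−p_B))` for `D < 0` (Lewontin normalization);
`D′ = |D|/D_max` reported as a magnitude; `r² = D²/(p_A q_A p_B q_B)`.
Strength classes: complete iff `D′ = 1` and `r² = 1` (within 1e-9); strong
iff `r² > 0.33`; weak iff `r² ≤ 0.33` — the boundary value is assigned to
weak since the conventional inequalities are strict on both sides. Note a
rare allele perfectly coupled to a common one has `D′ = 1` but small `r²`
and is classed weak, which is the epidemiologically meaningful call.
Monomorphic loci raise an error naming the locus; `pairwise_ld` reports such
pairs as undefined instead of dropping them.

## Association testing

Each trait arm can be screened for normality with a one-sample KS test
against a normal with sample-estimated mean and SD. The default p-value is
the asymptotic Kolmogorov distribution (the common statistical-package
behavior); because estimating parameters shrinks the null distribution of
the statistic, that default is conservative, and a seeded Monte-Carlo
Lilliefors p-value (10⁴ draws by default) is available behind a flag.

The genotype comparison is the two-sided Mann–Whitney U test of wild-type
homozygotes versus deletion carriers (dominant coding; at these frequencies
carriers are effectively all heterozygotes). Mode "auto" uses the exact
permutation null when the smaller arm has ≤ 10 observations and the pooled
data are tie-free — which covers deletion arms of size 9 and 4 at cohort
scale — and otherwise the tie-corrected normal approximation with continuity
correction. Summaries report arithmetic mean ± SE per arm (with no
covariates, least-squares means reduce to arithmetic means), U, p, and a
significance flag at α = 0.05. No multiple-testing correction is applied by
default, matching single-locus candidate-gene practice; Bonferroni and
Benjamini–Hochberg flags exist.

## Synthetic data generator

* **Populations**: per-breed genotypes drawn iid from Hardy–Weinberg
  proportions `((1−p)², 2p(1−p), p²)`. The bundled seven-breed frame uses
  the published cohort sizes (907/629/190/49/201/48/326) and deletion
  frequencies (0.007/0.011/0.008/0.010/0/0/0), with the Tan-sheep sex split
  fixed at 458 rams / 449 ewes; elsewhere sex is Bernoulli(0.5). No
  pedigree, relatedness, or population structure is modeled — passing tests
  say nothing about screens on inbred or family-structured cohorts.
* **Traits**: value = baseline location + dominant carrier shift +
  scale × standardized noise. Noise families: *skewed* — shifted lognormal
  with σ = 0.5 (skewness ≈ 1.75, the default, since growth data in this
  setting fail normality screens); *heavy-tailed* — t(3)/√3; *normal* —
  Gaussian. All are standardized to mean 0, variance 1 so `scale` is the
  per-animal SD in trait units. The bundled Tan-sheep panel (BW, BH, BL,
  HHC, PG, CD, CW, CC; kg/cm) sets locations to the published wild-type arm
  means, scales to the published arm SEs rescaled by √n_arm, and carrier
  effects to the published arm-mean differences (e.g. −3.63 cm on ram body
  length). These are stand-ins chosen to match first and second moments, not
  inferences about the unavailable per-animal distributions; trait–trait
  correlations are not modeled.
* **Two-locus genotypes**: haplotype frequencies constructed from
  `(p_A, p_B, D′)` via `p_AB = p_A p_B + D′·D_max`, individuals formed by
  pairing two independent haplotype draws. Infeasible combinations are
  rejected with the feasible bound in the message.

All generators are byte-deterministic given their seed.

## Problem sizes and numerical choices

Monte-Carlo checks use: 2000 replicates for the cohort-scale screen mean
(MC standard error ≈ 1.1 reactions against a 1% band of ±4.6); 10⁵
replicates for the tiny brute-force-oracle instance (N = 12, a = 3); 1000
replicates for type-I-error calibration at arm sizes (449, 9); 10⁴
individuals for D′ recovery within 0.05; a 10⁻⁴ grid for the LD
likelihood oracle. EM tolerance 1e-8 on the log-likelihood; panel identities
(Ho + He = 1, Ne·Ho = 1) hold to 1e-12; classification boundaries use 1e-9.

## Known limitations

* The analytic design formula ignores pool-dilution sensitivity limits,
  genotyping error, and cost differences between pool and individual
  reactions; it optimizes reaction count only.
* The expected-reaction formula treats `p` as the pool-positivity driver;
  see the MAF-versus-carrier-frequency note above.
* LD analysis is strictly two-locus: no haplotype blocks, no multi-locus
  haplotypes, no significance testing of D′.
* The association module offers no covariate adjustment; with only two
  observed genotype classes, additive/dominant model contrasts are not
  distinguishable.
* The trait generator draws traits independently given genotype and sex;
  real body measurements are strongly mutually correlated.
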