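# Methods

This note documents the statistical models, the synthetic-data
generator, defaults, numerical choices, and known limitations of
`pedigwas`.

## Kinship and the association model

The pedigree kinship coefficient `k_ij` (probability that one allele
sampled from each of i and j is identical by descent) is computed by
the standard recursion over a topological order: founders are
unrelated to non-descendants, and for a non-founder i with parents
(f, m) and any non-descendant j, `k_ij = (k_fj + k_mj)/2`.  The matrix
`Φ` stores `k_ij` off the diagonal and fixes the diagonal at 1/2, so
`2Φ` is the additive (numerator) relationship matrix A: expected
allele sharing of 1/2 for parent–child and full siblings, 1/4 for
half siblings and avuncular pairs, 1/16 for half first cousins.  Some
publications print the off-diagonal as `2k_ij` while keeping the
diagonal at 1/2; that matrix is not positive semidefinite for any
family with two or more first-degree relatives (a father–mother–child
trio already gives a negative leading minor), so it cannot serve as a
covariance and the kinship-coefficient convention is used throughout.

Fixing the diagonal at 1/2 ignores inbreeding (the exact diagonal is
`(1+F)/2`); the synthetic pedigrees are non-inbred by construction, so
the truncation is exact there.  For externally supplied inbred
pedigrees it can cost positive semidefiniteness; a ridge of up to
1e-8 is tried before the Cholesky factorization fails loudly.

The quantitative-trait model is `y ~ N(α + βg, 2σ²Φ)`.  Fitting
decorrelates y, the intercept and the dosage by the Cholesky factor of
`2Φ` and solves ordinary least squares in the whitened coordinates;
`σ²` is the maximum-likelihood estimate (not REML — the model is fit
exactly as written).  The headline test is the 1-df likelihood-ratio
χ², `n·log(RSS₀/RSS₁)`; the Wald standard error from the whitened
design supplies the 95% CI (`β ± 1.96·SE`).  Monomorphic or collinear
dosages produce a flagged degenerate result with p = 1 rather than an
exception, so genome scans never die on a single variant.  Binary
traits use logistic regression with a likelihood-ratio test; complete
separation falls back to a Jeffreys-prior (Firth) penalized fit,
flagged in the result status.

The genome scan applies the imputation-info (> 0.8) and MAF (> 0.01%)
filters *before* testing and returns a ledger naming the rule that
removed each filtered variant; results plus ledger always partition
the input panel exactly.

## Genotype probabilities for untyped relatives

For an untyped target the posterior over its genotype given all typed
genotypes in its family component is computed exactly: factors are
Hardy–Weinberg founder priors at the supplied MAF and 3×3×3 Mendelian
transmission tables; untyped childless members (other than the target)
are pruned first, since they marginalize out of a single-locus
likelihood; the remainder is eliminated variable-by-variable with a
min-degree ordering.  Families whose pruned untyped count exceeds 20
fall back to conditioned gene-dropping Monte Carlo (100,000 seeded
drops, rejection on the typed genotypes).  Typed configurations with
zero likelihood raise an error identifying the violating trio when one
is fully typed.

In the pipeline, dosages are inferred only for untyped individuals
with at least one typed first- or second-degree relative, and the
inference conditions on the target's first/second-degree neighbourhood
(parents, offspring, siblings, grandparents, grandchildren, avuncular
links through full siblings, plus the parents linking them); more
distant typed genotypes carry little single-locus information and are
ignored for tractability.

The imputation-info statistic is the dosage-variance ratio
`Var(d) / (2·p̂·(1−p̂))` (the MACH/IMPUTE r̂² convention), clipped to
[0, 1.05] and defined as 1 at degenerate allele frequencies.

## Phenotype preparation

Repeated measurements are averaged per individual on the raw scale
before anything else, so one row per individual matches the
kinship-indexed model.  Covariate correction (sex, year of birth,
linear) is by OLS; in the composed discovery pipeline it is applied to
log-transformed values.  The log scale matters: the trait is generated
(and EPO-like assays behave) multiplicatively, and an additive fit on
the raw scale perturbs the ranks that the subsequent inverse-normal
transform consumes — in simulations this attenuates a planted 1.47 SD
effect by roughly 8%, while log-scale correction removes the
covariates without disturbing the latent ranks.  The generic
`residualize` operation itself is scale-agnostic; `prepare_phenotype`
accepts `covariate_scale="linear"` for the raw-scale variant.

The inverse-normal transform maps value i to
`Probit((rank_i − 0.5)/n)` with average ranks for ties; Blom's
offset ((rank − 3/8)/(n + 1/4)) is available by argument.  The
transform is invariant under strictly monotone input transformations
and yields mean ~0 and variance ~1.

Stratified standardization (for a haemoglobin-like trait measured in
several laboratories) inverse-normal transforms within each
sex × laboratory stratum, subtracts a penalized cubic smoothing-spline
age trend (smoothing chosen by generalized cross-validation, as a
stand-in for a generalized additive model), re-standardizes, and pools.
Strata under 30 individuals are merged into the largest stratum with a
warning.

## Significance thresholds and calibration

Weighted Bonferroni: given per-class variant counts `N_c` and relative
weights `w_c`, the thresholds are `α_c = w_c · FWER / Σ N_d w_d`, so
the ratios of thresholds equal the ratios of weights and
`Σ N_c α_c = FWER` exactly.  The packaged default scheme uses the five
published class counts (8,464 high; 149,983 moderate; 2,283,889 low;
3,913,058 DHS; 26,108,038 other) with weight ratios back-derived from
the published thresholds (≈ 329 : 64.6 : 5.8 : 2.9 : 1); the weights
themselves were not published, only the resulting thresholds.  The
corrected p-value is `min(1, p · FWER / α_class)`, monotone within a
class and exactly equivalent to the threshold rule.

LD scores are windowed (variant-count windows — the synthetic panel
has no genetic map): `score_j = 1 + Σ r²_adj` over neighbours within
the window, with the small-sample bias adjustment
`r²_adj = r² − (1−r²)/(n−2)` floored at zero per pair.  The LDSC fit
is unweighted OLS of per-variant χ² on LD score (the reference
method's χ²-dependent weights and block jackknife are out of scope —
only the intercept is used), and the applied correction factor is
`max(intercept, 1)`: a deflated scan (intercept < 1) is left alone
rather than inflated into significance.  Desk-scale caveat: with a
uniform-block synthetic panel all LD scores are similar, so the
extrapolated intercept is noisy; the clamp at 1 makes the applied
factor robust, but intercept values from small homogeneous panels
should not be over-interpreted.

A simulation check of the whole scheme draws null p-values from their
exact uniform law across the five classes (running millions of full
regressions per replicate scan would add nothing to that check) and
confirms the family-wise rejection rate stays within budget.

## Replication and power

Matching is greedy and deterministic: carriers sorted by id each take
the remaining control of the same sex with minimal year-of-birth
distance among those within ±1 sample-collection year, ties broken by
smaller control id; unmatched carriers are reported, never dropped
silently.  Optimal bipartite matching would minimize total distance
but sacrifices the reproducibility of a simple deterministic rule.

The Wilcoxon signed-rank test drops zero differences, average-ranks
ties, enumerates the exact null distribution by dynamic programming
for up to 25 informative pairs (half-ranks doubled to stay integral),
and above that uses the normal approximation with tie-corrected
variance and a 0.5 continuity correction; both the switch point and
the correction are arguments.  The paired t-test runs on log values
(df = n−1).  Fold change is reported under both conventions — ratio of
group medians and median of per-pair ratios — because they genuinely
differ and published fold figures are ambiguous between them.
Fisher's method is `X = −2Σ ln p_i ~ χ²(2k)`.

Power uses the standard GWAS normal approximation for an additive
dosage with variance `2·maf·(1−maf)` against a unit-variance trait:
minimal detectable effect `(z_{1−α/2} + z_{power}) / √(N·2·maf·(1−maf))`,
with the negligible wrong-sign tail dropped in `power_at` (so a zero
effect gives power α/2, the retained tail).  A two-sided α of 0.05
reproduces the published 0.127 SD at N = 273,160 and MAF 0.09%; the α
behind that published figure was not stated and 0.05 is adopted.

## Expression module

RNA libraries are excluded when mapped reads < 10⁷, mapped pairs
< 10⁶, or the lower read-end mapping rate falls below 80% of the
higher; each exclusion carries its triggering rules.  Expression
association reuses the rank inverse-normal transform, regresses on
dosage plus nuisance covariates (OLS, or the kinship GLS when a Φ is
supplied), and reports effects in SD units.  Allele balance in
heterozygous carriers is an exact two-sided binomial test against 1:1
read origin (the minimal test; no published choice to follow).
Alignment, counting and TMM normalization are out of scope — the
module consumes normalized counts.

## The synthetic generator

What it emulates: a multi-generation non-inbred pedigree built by
random monogamous pairing within generations (couples sharing any
ancestor are disallowed), Poisson family sizes (mean 2.5, truncated at
8); a rare biallelic variant gene-dropped from Hardy–Weinberg founders
at MAF 0.09%; a panel of common variants (MAF ~ U(0.05, 0.5)) in LD
blocks built by founder-haplotype copying (copy probability 0.9,
blocks transmitted without internal recombination) with the five
annotation classes assigned at the published proportions; an EPO-like
trait with latent value

```
sex·0.2 + 0.01·(birth year − mean) + effect·g + family + noise
```

where `family + noise` has unit variance and the family part has
covariance `0.3·2Φ` (the polygenic component that makes the Φ-aware
model necessary), reported as `exp(0.5·latent + log 13.3)` so the raw
median sits at ~13.3 IU/L, with 1–2 repeats per individual (mean 1.4);
and a chip-typed fraction of 71.5%, matching the study's 2994 typed of
4187 measured.  Defaults put the pedigree at ~4200 members
(730 founders, 3 offspring generations) so a default cohort matches
the discovery cohort's scale.  Every generator is a pure function of
(config, seed).

What it does not emulate: hospital-based ascertainment of who gets
measured (individuals are phenotyped uniformly — the study's
ascertainment was not described), sequence-level data, phasing,
genotyping error, or assay-specific artefacts.  Passing tests
therefore demonstrate the statistical machinery under the stated
generative model, not robustness to those real-data features.

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen to make Monte-Carlo error
small relative to the tolerances while keeping the suite quick on one
CPU: effect recovery uses 200 replicate ~4200-member cohorts sharing
one pedigree and kinship factorization (the estimator's mean is
unaffected by reusing the pedigree); null-scan calibration uses a
~1800-member cohort and 2000 independent variants; kinship/gene-drop
agreement uses 100,000 drops per pedigree; FWER control uses 200
replicate 100,000-variant scans with p-values drawn from their exact
null law.

## Known limitations

- Exact dosage inference conditions on the local first/second-degree
  family, not the full connected component; distant typed relatives
  are ignored.
- The Monte-Carlo fallback for very large untyped families uses
  rejection sampling, which is inefficient at very low MAF when typed
  carriers are observed.
- The LDSC intercept from small homogeneous panels is noisy (see
  above); only the clamped factor is used downstream.
- The diagonal-1/2 convention makes Φ exact only for non-inbred
  pedigrees.
- Matching is greedy, not globally optimal.
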