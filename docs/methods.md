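# Methods

## The model

For a vector **y** of phenotypes pre-adjusted for fixed effects, the full
model is

    y = 1 mu + (L b) + A a + D d + I i + e

with per-SNP random regressions **a** ~ N(0, I sig2_a), **d** ~ N(0, I sig2_d),
**i** ~ N(0, I sig2_i), optional common-litter intercepts **b** ~ N(0, I sig2_L)
and residuals **e** ~ N(0, I sig2_e). Three nested variants are fitted:
MA (additive only), MAD (additive + dominance) and MADI (all three). The
regressor matrices are derived from phased parental-origin probabilities —
P1 (counted allele inherited from the father) and P2 (from the mother):

    A = P1 + P2 - 1        D = |P1 - P2|        I = P1 - P2

With certain phase the ordered genotypes map to A in {-1,0,0,+1},
D in {0,1,1,0} and I in {0,+1,-1,0}; D = |I| holds identically. I is the
parent-of-origin contrast: reciprocal heterozygotes differ only in its sign,
which is what separates imprinting variance from dominance variance. Under
HWE at counted-allele frequency p the three columns of one SNP are mutually
uncorrelated, so the three variances are structurally separable.

The coding is used verbatim (columns are not mean-centred); the intercept
absorbs column means, and the explained-variance statistic below subtracts
the mean of each genotypic-value vector, so no estimate depends on the
location of the coding. Flipping which allele is counted negates A and I and
fixes D; all variance estimates are invariant under the flip.

## Estimation

Priors on all location parameters are flat, and priors on all variance
parameters are unbounded uniform, making the joint posterior proportional to
the likelihood. The chain starts with every location parameter at 0 and
every variance at 1. Updates are single-site Gibbs with maintained
residuals: each SNP effect is drawn from its normal full conditional

    a_j | .  ~  N( x_j' r_j / (x_j'x_j + sig2_e/sig2_a),
                   sig2_e / (x_j'x_j + sig2_e/sig2_a) )

where r_j is the residual with SNP j's contribution restored; the residual
vector is updated incrementally so a full sweep costs O(n m). (Any blocking
of these updates changes only mixing speed, not the stationary
distribution; a residual-maintenance guard in the tests checks that the
incrementally maintained residual agrees with a from-scratch recomputation
to < 1e-6.) Variance parameters get scaled inverse-chi-square draws
sig2 = SS / chisq(count - 2), the exact full conditional under the flat
prior on the variance (count = number of effects, or n for the residual).
Other samplers differ by +-1 in this df convention; the difference is
immaterial at count >= 1000. Variances are
floored at 1e-12 to avoid an absorbing state at zero; hits are logged.

Default chain settings are 100,000 iterations, 50,000 burn-in, thinning 100.
The validation and test runs use 10,000 / 5,000 / 10, which the diagnostics
(trace stability across blocks) show is ample at the cohort sizes used.

### Explained variance

SNP-regression models do not directly report total explained variance. At
every saved iteration the sampler records the population variance
(denominator n) of each genotypic-value vector — var(**Aa**), var(**Dd**),
var(**Ii**) and var(**Lb**) — giving posterior means *and SDs* of the
totals, and per-iteration phenotypic variance sig2_P as their sum plus
sig2_e. Heritabilities are per-iteration ratios averaged over draws
(narrow-sense h2 = var(Aa)/sig2_P); the ratio of posterior means is reported
alongside, since the two summaries differ slightly and the original
convention is unstated. The Gram-diagonal route
mean(diag(AA')) * sig2_a is provided as an independent cross-check; the two
agree asymptotically on HWE genotypes with centred columns.

Per-chromosome variance applies the same statistic to the columns of one
chromosome at a time (effect draws are stored when requested). The genome
total and the sum over chromosomes differ by cross-chromosome covariance
terms; under linkage equilibrium they agree closely. Chromosome length is
the distance in bp between the first and last retained (post-QC) SNP. The
variance-versus-length relationship is summarized by the r2 of an OLS
regression (scipy linregress); it needs >= 3 chromosomes with positive,
non-degenerate lengths.

### Breeding-model transformation

The genotypic-model components are re-expressed on the classical
parameterization through allele substitution effects alpha = a + d(q - p):
V_A = sum 2pq alpha^2 and V_D = sum (2pq d)^2, applied per saved iteration.
The linkage-equilibrium form is used; inter-SNP covariance (LD) corrections
are omitted, a documented limitation. With d = 0 the transformation reduces
exactly to the genotypic decomposition.

### Model comparison

DIC = D_bar + p_D with D_bar the mean saved deviance,
D = n log(2 pi sig2_e) + SSE/sig2_e, and p_D = D_bar - D_hat, where D_hat
plugs in posterior means of the location parameters and of sig2_e
(conditional DIC with location parameters in focus). A marginal DIC —
integrating over SNP effects — would differ; the convention of the original
software is unknown, so absolute DIC values are comparable only within this
package. A negative p_D triggers a warning, not an error.

## Quality control

SNPs are removed in a fixed order so each removal is charged to exactly one
rule: unmapped / sex chromosome, call rate < 0.95, MAF < 0.05 (monomorphic
SNPs are charged here: zero-variance columns make Gibbs updates degenerate),
HWE chi-square > 600 (1-df goodness-of-fit with p estimated from the
counts); then individuals with > 0.05 missing calls are dropped. HWE counts
use only hard calls (P1, P2 within 1e-6 of {0,1}); partially uncertain
entries are excluded from the test, a choice the source data format forces
on us. The sampler requires complete data; a mean-imputation fallback
exists but is off by default — pedigree-based imputation upstream is the
intended path.

## The synthetic cohort

The generator emulates the validation design: n individuals with m biallelic
SNPs on 18 autosomes, paternal and maternal alleles drawn independently
Bernoulli(p) per SNP — so HWE holds, parental origin is known exactly, and
SNPs are in linkage equilibrium. Panel frequencies are uniform on
(0.05, 0.95) (a post-QC spectrum); chromosome SNP counts decline ~2.5-fold
from largest to smallest, as in livestock genomes, and SNPs sit on a 1-Mb
grid. 15 QTL are drawn from SNPs with MAF 0.45-0.50 on 15 distinct
chromosomes: 5 purely additive, 5 purely dominant, 5 purely imprinted. Each
effect is calibrated at the QTL's realized frequency by inverting the
single-locus variance formulas

    Va = 2pq [a + d(p-q)]^2      Vd = (2pq d)^2      Vi = 2pq i^2

so the own-type contribution is exactly 2% of phenotypic variance
(a = i = sqrt(0.02/2pq), d = sqrt(0.02)/2pq). Dominance QTL additionally
leak v(p-q)^2/2pq <= 4.05e-4 of additive variance in this MAF window —
tracked, not zeroed. Phenotype = sum of regressor-weighted effects + iid
Normal(0, 0.70) residual; genetic variance 0.30, phenotypic variance 1,
10% per component. Replicates default to fresh cohorts under distinct
seeds; a shared-panel mode keeps one genotype matrix and draws disjoint QTL
sets across replicates.

What the generator does *not* emulate: linkage disequilibrium, family
structure (all individuals are unrelated), selection, genotyping error and
phasing uncertainty (P1, P2 are exact). Two consequences matter for
interpreting validation results. First, with unrelated individuals the
genomic-relationship structure that helps separate genetic from residual
variance is absent, so at desk scale (m ~ n ~ 1000) the components are more
weakly identified than in a real half-sib livestock cohort: the positivity
of variance components then inflates the genetic fractions slightly and
deflates the residual (by roughly 0.01-0.04 at the default sizes). Passing
recovery tests here therefore demonstrates correctness of the machinery
under the stated design, not estimator performance on related, LD-rich
data. Second, the sampling correlations between component variances depend
on the real-data LD structure and are only qualitatively reproduced
(strongest negative correlations involve the residual).

## Problem sizes and numerical choices

Validation replicates use n = 1500 individuals and m = 1000 SNPs (from the
design's stated ranges n 800-1500, m 1000-2000), the corner with the best
n/m ratio and hence the strongest identification of the variance
components; chains are 10,000 iterations / 5,000 burn-in / thin 10, and 5
replicates are averaged. The DIC ranking study uses 10 replicates at
n = 500, m = 540 with 3,000-iteration chains — model ranking needs far less
chain than variance estimation. The fixed-variance oracle check runs the
sampler in "ridge mode" (variance updates disabled) on n = 30, m = 8 and
compares posterior means against the closed-form mixed-model-equation
solution within 3 Monte-Carlo SEs (batch-means).

Ties and degenerate inputs: monomorphic SNPs are dropped in QC; an
all-missing column is an error; select_qtl raises when fewer than 15
chromosomes carry an eligible SNP; chromosomes with < 2 SNPs get length 0
and are excluded from the length regression; sample_variance requires
count > 2 (the flat-prior conditional is improper otherwise).

## Known limitations

- Absolute DIC values depend on the conditional-DIC focus choice and are
  not comparable to other software's DIC output.
- The under-parameterized-model contrasts (e.g. MAD dominance vs MADI
  dominance) are small relative to across-replicate noise at desk scale;
  only the MA-vs-MADI additive inflation is a robust direction.
- The breeding-model transformation ignores LD terms.
- No convergence gating: effective-sample-size and trace diagnostics are
  available but the fits do not fail on poor mixing.
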