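# Methods

## Model and estimation

For one gene and one biallelic SNP, log2 expression of sample k with genotype
j (minor-allele count 0/1/2) in population i ∈ {0, 1} is modelled as

    y_ijk = mu_i0 + tau_j + e_ijk,    e_ijk ~ N(0, sigma^2) i.i.d.

The genotype offsets tau_j are shared across populations (the "constrained"
part: no population × genotype interaction), while the baselines mu_i0 are
free. The design has one indicator column per population and one per
non-baseline genotype class observed anywhere in the data; classes unobserved
in both populations are dropped. A class observed in only one population
keeps its shared tau column — that borrowing of strength is the point of the
model — and identifiability is guarded by an explicit design-rank check.
Estimation is ordinary least squares on this design; the decomposition
identities and the invariance of every estimable quantity to the choice of
baseline genotype are asserted by tests rather than relying on a cell-mean
closed form.

Linear hypotheses B·beta = 0 are tested with the partial F-statistic
F = (Bb)'[B(X'X)⁻¹B']⁻¹(Bb) / q / (SSE/v), q = rank(B), v = n − rank(X),
with exact F(q, v) upper-tail p-values and no continuity corrections. The
association test takes B selecting all retained tau rows; the
baseline-difference (BD) test uses B = (1, −1, 0, 0); the genetic-score (GS)
test uses B = (0, 0, P̂_01 − P̂_11, P̂_02 − P̂_12) with the estimated genotype
proportion differences treated as constants. BD + GS equals the difference of
model-implied population means evaluated at the observed genotype
proportions; the identity is checked to 1e-10 on every fit.

Degenerate inputs are signalled, not guessed at: all-missing genotypes ("no
data"), one empty population, rank-deficient designs ("not identifiable"),
zero residual df ("saturated"), monomorphic SNPs ("not testable"), and a
zero GS contrast ("untestable contrast", returned as GS = 0 with no test).
Missing genotypes are removed by listwise deletion per SNP. A numerator of
exactly zero in any F-test yields F = 0, p = 1; noise-free data with a
nonzero contrast yield an infinite statistic with p reported as 0.

## Comparator methods

* **IG** — one-way ANOVA per population; a *common eQTL* requires both tests
  to reject (union-null rule); the intersection-null variant (either rejects)
  is also provided. The common genotype c = argmax_j Π_i P_ij breaks ties
  toward the smallest class.
* **QT** — within each population the gene's values are mapped to standard
  normal quantiles, rank r of n going to Φ⁻¹((r − 0.5)/n) with average ranks
  for ties (a standard convention, fixed here and documented; tests of QT
  rely on calibration properties, not the third decimal of a quantile). The transformed values
  are pooled and a single one-way ANOVA on genotype is run.
* **Two-way ANOVA with interaction** — the saturated cell-means model,
  testing all genotype-related terms jointly; a simulation comparator.

## Assumption checks

Nested-model F-tests compare (a) the saturated cell-means model against the
constrained model (interaction test), (b) the constrained model against a
shared baseline (equivalent to the 1-df BD test), and (c) the co-dominant
model against the additive constraint tau_2 = 2·tau_1, coded as a single
slope on minor-allele count. Multiplicity is handled with Benjamini-Hochberg
step-up adjustment; q-value estimation of the null proportion is out of
scope.

## Permutation null for GS

Because the proportion differences inside B are estimated, the GS F-test's
null distribution is not exactly F when the SNP effect is large but the true
frequency difference is zero. `permutation_null_gs` permutes population
labels without restriction (the simplest label-exchangeable null),
recomputes the GS statistic, and
reports the add-one estimator (1 + #exceeding)/(n_perm + 1), so p is never
zero. Untestable permuted replicates are redrawn up to a retry cap, then
counted as non-exceeding.

## Simulation design

One scenario draws Hardy-Weinberg genotypes at MAF p0 (population 0, n0
samples) and p0 + d (population 1, n1 samples) and generates expression as
D·1[i=0] + j·E + N(0, sigma²). The effect is additive (true tau_1 = E,
tau_2 = 2E), so the heterozygote offset recovered by the fit should equal E.
Defaults: n0 = 60, n1 = 90 (mirroring the CEU and CHB+JPT cohort sizes of
the HapMap expression panels), sigma = 1, D applied to population 0,
alpha = 0.05, and 10,000 replicates (the publication-scale default for
estimator-recovery summaries). The test suite and acceptance script run
2000 replicates per grid point — a deliberate problem size that keeps a
full frequency grid under a minute per study while leaving exact-binomial
99% bounds of about ±0.013 around a 5% rate. Replicate RNG streams are spawned
from the scenario seed so all methods see identical data within a replicate
(paired comparisons). Untestable replicates are counted and excluded from
rate denominators, and flagged when they exceed half of all replicates.

What the generator emulates: HWE genotypes, additive SNP effects, Gaussian
noise, population-level location shifts. What it does not: linkage
disequilibrium between SNPs, multi-SNP architectures, non-normal expression
noise, batch effects, relatedness, covariates. Passing calibration tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data features.

A known and deliberate finding reproduced by the engine: at d = 0 with a
real effect (E = 0.5) the GS F-test is anticonservative. Conditional on the
genotypes, its noncentrality is (Δ·tau)/sqrt(sigma²·B(X'X)⁻¹B'), which is
invariant to the magnitude of the sampled frequency drift Δ (numerator and
standard error both scale linearly in |Δ|) and grows like sqrt(n)·E/sigma.
At n0 = 60, n1 = 90, sigma = 1 the maximum rejection over the frequency grid
is ≈ 0.68; smaller cohorts or noisier expression give proportionally smaller
inflation. The practical advice is unchanged: a significant GS alone does
not certify a frequency difference; the permutation null or an explicit
frequency test should accompany it.

## Scan pipeline

Every SNP is paired with every gene on the same chromosome (trans-genome
pairs are excluded by design); *local* means the SNP lies within 100 kb of
the gene body, boundaries inclusive. Coordinates are 1-based inclusive
internally; BED input is converted on read. Significance uses a conservative
p < 1e-6 default, BH adjustment is computed across all tested pairs, and per
gene the significant SNP with the smallest association p-value is the
putative eQT locus, ties broken by smaller position then SNP id. eSNP filtering keeps
|GS| ≥ 0.5 (inclusive) with a significant GS test. For clustering-style
displays, genotypes are re-oriented so 2 means homozygous for the
up-regulated allele, using the fitted homozygote contrast (tau_2, or
2·tau_1 when the minor homozygote class is absent); a zero contrast keeps
the minor-allele orientation with a warning. The minor allele itself is
defined on the pooled sample, frequency ties resolving to ALT (VCF) or the
second listed allele (TSV).

## Limitations

Two populations only; no kinship, covariates or mixed models; no genotype
imputation; no LD-aware multiple testing. The scan's FDR is computed on the
primary method's p-values only. The GS F-test's anticonservatism at d ≈ 0
with strong effects is inherent to treating estimated proportion differences
as constants and is documented rather than patched; use the permutation null
when d is small.
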