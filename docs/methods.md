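# Methods

`agevar` quantifies how inter-individual *variability* of gene expression —
not just its mean level — changes across adulthood in bulk transcriptome
cohorts. This note describes the models, the statistics, the synthetic-data
generator used for validation, the numerical conventions, and the known
limitations.

## Expression model and differential expression

For gene *i* and sample *j* with age *a_j* (years), expression on the log2
scale is modelled as

    Y_ij = β_i0 + β_i1 · a_j^0.25 + covariates + ε_ij .

The fourth-root age transform compresses the fast expression dynamics of
young adulthood relative to the slow changes at older ages and reduces the
leverage of unevenly sampled age ranges; the exponent is configurable
(`age_transform_exponent`, default 0.25). Slope estimates under `age` and
`age^0.25` are in practice strongly rank-concordant (the acceptance script
measures this on simulated data). Covariates — technical batch, sex, race,
post-mortem interval (hours), RNA integrity number, tissue pH — are
dummy-coded against the first sorted level and fitted jointly by ordinary
least squares, vectorized across genes with a shared design matrix. The age
coefficient β_i1 is the differential-expression measure; its two-sided
t-test p-value (residual degrees of freedom, no empirical-Bayes moderation)
is adjusted across genes by Benjamini–Hochberg, and genes are called at
q ≤ 0.05 (inclusive).

## Differential variability

Two complementary statistics target changes in the residual spread.

**Continuous, Δvar(ρ).** The absolute residuals |ε_ij| of the expression
model serve as a per-sample variability signal; Δvar(ρ) is their Spearman
correlation with age. Positive values mean variability rises with age. The
statistic sees the entire adult range and is best powered for monotonic
trends. p-values use the t approximation on n − 2 degrees of freedom and
are BH-adjusted. Genes fit exactly (all residuals ≈ 0 within 1e-10) are
degenerate: Δvar(ρ) = 0, p = 1.

**Grouped, Δvar(IQR).** On a covariate-corrected matrix (age deliberately
*not* removed), the old group's interquartile range IQR_old is compared
with a null distribution built by drawing B = 10,000 without-replacement
subsamples of the young group, each of the old group's size, and recording
their IQRs. With m the mean of the null IQRs,

    Δvar(IQR) = (IQR_old − m) / m ,

a fractional change that is ≥ −1 by construction and right-skewed under
symmetric alternatives. The empirical p-value is the doubled one-sided tail
with add-one correction,

    p = min(1, 2 · min((1 + #{null ≥ IQR_old}), (1 + #{null ≤ IQR_old})) / (B + 1)) ,

never exactly zero. Middle-aged samples (between the young and old windows)
are ignored by construction. Genes whose mean null IQR is zero are excluded
from the BH correction and reported separately. When C(n_young, n_old) is
below `exhaustive_limit` (default 50,000) all subsets are enumerated and
the p-value is exact.

Implementation detail: one B × n_old subsample-index matrix, derived from
the run seed, is shared by all genes. This keeps runtime linear in genes
and makes per-gene location/scale invariance exact — adding a constant to a
gene, or multiplying it by c > 0, changes neither Δvar nor the p-value.

### Known limitation: the grouped null is anti-conservative

The resampled null captures only the *within-young-sample* spread of
subsample IQRs, with variance ≈ v·(1/n_old − 1/n_young) for an
asymptotically linear statistic with influence variance v. An independent
old-group IQR under the null instead varies with ≈ v·(1/n_old + 1/n_young)
around the population value, because (i) an independent sample of size
n_old has no finite-population shrinkage and (ii) the young sample's own
IQR is itself an estimate. At the study's group sizes (53 young, 22 old)
the implied z-inflation is √((1/22 + 1/53)/(1/22 − 1/53)) ≈ 1.56, which
predicts a type-I error of roughly 0.18–0.21 at nominal 0.05; seeded null
simulations in the test suite measure ≈ 0.16–0.17. A control experiment in
which the "old" group is drawn as a subset of the same young values (making
old and null subsamples exchangeable) restores exact calibration (≈ 0.05),
confirming the implementation is faithful and the inflation is intrinsic to
the test's design. Consequences: raw empirical p-values from the grouped
approach overstate significance, and BH-adjusted calls do not control the
false discovery rate at the nominal level (a seeded 10%-signal mixture
shows an observed false-discovery proportion ≈ 0.3–0.4 at q ≤ 0.05). The
corresponding calibration checks in `tests/test_acceptance.py` assert
nominal behaviour and therefore fail; they are kept failing deliberately,
as an executable record of this property. Δvar(IQR) as an *effect size*
is unaffected (its expectation approaches k − 1 when the old-group SD is
k times the young); rankings and cross-method comparisons remain
meaningful, and the continuous approach is exactly nominal in the same
simulations.

## Preprocessing

* **Age filter**: samples with 20 ≤ age ≤ 80 kept, bounds inclusive.
* **Probe summarization**: probes mapping to more than one gene are
  dropped; a gene's value is the arithmetic mean of its remaining probes.
* **Quantile normalization**: every sample is forced to the common
  reference (row means of column-sorted values); within-column ties receive
  the mean of the reference values their tied ranks span. QN is idempotent
  and preserves the matrix total.
* **Covariate correction**: gene-wise OLS residuals of expression on
  intercept + covariates (never age). By default the fitted intercept is
  added back so values stay on the log2 scale; both Δvar statistics are
  shift-invariant, so this choice cannot alter any result. Unsupervised
  corrections (surrogate-variable analysis, empirical-Bayes batch
  adjustment) are not implemented; externally corrected matrices enter
  through the ordinary TSV reader.

## Pathway analyses

Per-gene Δvar scores are summarized over a gene-set collection in two ways.
The *distribution study* reports each set's Δvar quartiles (type-7
quantiles), the fraction of sets whose median is strictly positive, and the
mean of the per-set medians; sets are first intersected with the scored
universe and then size-filtered (defaults 5–500). *Preranked GSEA* ranks
genes by decreasing score (ties broken by gene id), accumulates hit
increments |score|^w (w = 1, normalized to sum 1 within the set) against
miss decrements 1/(N − set size), and takes the running sum's maximum
deviation as ES. The null permutes gene labels (n_perm = 1000 by default);
NES divides ES by the mean magnitude of same-sign permutation scores; the
empirical p uses the add-one correction; sets are filtered at 10–500 genes
by default. The permutation count, weight and NES convention are package
defaults, configurable, since no single external convention is canonical.

## Association checks

* **Mean–variability coupling**: per gene, Δmean = mean_old − mean of
  young-subsample means and ΔIQR = IQR_old − mean of young-subsample IQRs
  (same subsampling scheme as the grouped test); the 2×2 sign table (exact
  zeros counted as non-positive, deterministically) is tested with Fisher's
  exact test. Independence of level and variability change gives an odds
  ratio near 1.
* **Gene-list overlap**: Jaccard similarity plus Fisher's exact test of the
  2×2 membership table against a stated universe.
* **External score correlation**: Spearman correlation of Δvar (or |Δvar|)
  with any per-gene score over the shared genes.
* **Cell-type-specific genes**: expression z-standardized per gene; a cell
  type's effect size is the mean z over its samples; genes with effect
  size > 2 (configurable) are assigned to that type. "Effect size" is
  defined here as this mean z — with the default threshold the per-type
  lists are disjoint in practice (checked, warned otherwise).

## Synthetic data

The generator emulates an adult post-mortem brain cohort: 147 samples with
exact per-bin quotas 53/72/22 over ages [20,40], (40,60), [60,80] (uniform
within bins; largest-remainder apportionment, multinomial optional),
19 technical batches with additive per-(gene, batch) effects ~N(0, 0.3²),
sex/race categories and standardized PMI/RIN/pH entering linearly with
coefficients ~N(0, 0.1²), per-gene baselines β0 ~ N(8, 2²) and residual
scales σ0 log2-normal with median 0.5 — magnitudes typical of log2
microarray data. Planted signals: a configurable fraction of genes gets a
nonzero age slope β1 ~ N(0, 1²); a configurable fraction gets an
age-dependent residual scale, either linear in age,
σ(a) = σ0·(1 + γ(a−20)/60), or a step at age 50, σ = σ0 before and
σ0·(1+γ) after — the two shapes the two statistics are respectively suited
to. Decrease-genes use γ = −g/(1+g) for a drawn magnitude g, so increases
and decreases are reciprocal and σ stays positive. One root seed governs
everything; sample-level draws and per-gene noise use separate seed-sequence
spawns, so a gene's noise stream does not depend on how many genes are
simulated.

What the generator does **not** emulate: probe-level artifacts, cell-type
composition shifts, count noise (data are Gaussian on the log2 scale),
age-correlated batch assignment, or missing annotations. Passing recovery
tests therefore demonstrates correctness of the statistics under the
modelled design, not robustness to every artifact of real cohorts.

## Numerical conventions and degenerate inputs

Quantiles everywhere use linear interpolation of order statistics at
h = (n−1)q ("type 7") — Δvar(IQR) values depend on this convention, so it
is fixed and tested against an independent interpolation oracle. Spearman
uses average ranks with the t-approximation p (group sizes here are ≥ 22;
no exact permutation p). Fisher's test reports the sample odds ratio ad/bc
(flagged when infinite or zero) with the standard two-sided conditional
p-value. Skewness is the plain moment coefficient g1 = m3/m2^{3/2}.
Normality of score distributions is assessed by Shapiro–Wilk on repeated
5,000-value subsamples (the statistic's reference implementation caps n at
5,000); shorter inputs clip the subsample size. Constant vectors yield
flagged degenerate results (estimate 0, p 1) rather than NaNs; rank-deficient
designs and single-level categorical covariates are hard errors.

## Problem sizes used in validation

Seeded simulations in the test suite and acceptance script use 2,000 genes
for null calibration and FDR experiments, 500 genes for effect-size and
slope recovery, B = 1,000 resamples, and the cohort's 147-sample age
design — sizes at which every Monte-Carlo band asserted in the tests is
stable across seeds while the whole suite runs in well under a minute.
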