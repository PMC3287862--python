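# Methods

## Problem setting

Rare variants (minor allele frequency, MAF, at or below 5% here; the more
common 1% cutoff is available through configuration) carry too little
information individually for single-marker association tests. Collapsing
methods summarize all rare variants inside a genomic block — here, a gene —
into one per-individual burden score, enriching the signal and reducing the
degrees of freedom. This package implements three collapsing schemes inside
a multimarker penalized-regression framework, evaluates their stability and
predictive value across phenotype replicates, and scores their ability to
recover a known causal truth set on synthetic data.

## Collapsing scores

Variants are partitioned at the MAF threshold with the boundary inclusive on
the rare side (MAF ≤ threshold is rare). For a gene *g* with rare sites
*j = 1..m* and dosage *g_ij* ∈ {0, 1, 2} for individual *i*:

* **PROP (proportion coding)** — the carrier proportion
  `s_i = #{j : g_ij ≥ 1} / m`, bounded in [0, 1]. The indicator form (not
  allele counts) is used, so a homozygote at a single-site gene scores 1.
* **DAS (data-adaptive sum)** — `s_i = Σ_j g̃_ij` where `g̃_ij = 2 − g_ij`
  for any site whose *marginal* single-variant regression on the trait has a
  negative slope with p < α₀ (default α₀ = 0.1), and `g̃ = g` otherwise.
  Flips are re-estimated from each phenotype replicate. Marginal tests: the
  exact OLS slope t-test for quantitative traits; the logistic score test
  (`U = Σ g(y − ȳ)`, `V = ȳ(1 − ȳ) Σ (g − ḡ)²`, `z = U/√V`) for the binary
  trait. Monomorphic sites have no defined marginal fit and keep their
  original orientation.
* **WS (weighted sum)** — `s_i = Σ_j g_ij / w_j` over **all** the gene's
  variants (rare and common pooled; a WS design therefore has no separate
  common-variant columns), with `w_j = √(n q_j (1 − q_j))` and
  `q_j = (m_j + 1)/(2 n_u + 2)`, where `m_j` is the minor-allele count and
  `n_u` the size of the frequency-reference group — unaffected individuals
  for the disease trait, all individuals for quantitative traits (which have
  no control group) — and `n` the total number of genotyped individuals.

Genes with no rare variants contribute no collapsed column (their common
variants still enter individually, except under WS, which drops a gene only
if it has no variants at all).

## Penalized multimarker model

With covariates `E_i` (Age, Sex, Smoke, one-hot population), common-variant
dosages `CV_iv` and collapsed gene scores `S_il`,

    g(μ_i) = β₀ + E_i'β_E + Σ_v β_v CV_iv + Σ_l β_l S_il

with the identity link for quantitative traits and the logit link for the
binary disease trait. Estimation minimizes

    (1/n)·NLL(β) + Σ_j λ_j |β_j|

by cyclical coordinate descent with soft-thresholding; covariates are never
penalized (λ_j = 0) and inactive coefficients are exact zeros, so feature
"selection" needs no epsilon. Logistic fits use proximal Newton (IRLS) with
a weighted inner coordinate descent. Convergence is declared when the
largest coefficient change in a sweep falls below 1e-7 (1e-5 inside
cross-validation folds, which only score the grid; final refits always use
the tight tolerance). Features are standardized to unit variance before
penalization — collapsed scores, dosages and covariates live on
heterogeneous scales — and coefficients are mapped back to the original
scale; the penalty therefore acts on standardized coefficients.

λ is chosen per replicate by k = 5-fold cross-validation at the
error-minimizing value (not the 1-SE rule) on a 50-point log-spaced grid
from λ_max (the smallest λ giving the all-zero penalized solution, computed
from the gradient at the covariates-only optimum) down to 0.001·λ_max.

### Annotation-aware differential penalties

When nonsynonymous and synonymous rare variants are collapsed separately,
the penalty splits by class:

    (1/n)·NLL(β) + λ_ns Σ_{a_j = ns} |β_j| + λ_s Σ_{a_j = s} |β_j|

The pair (λ_ns, λ_s) is tuned by within-replicate cross-validation over a
full 2-D grid (10 × 10 log-spaced by default). Common-variant columns are
penalized at min(λ_ns, λ_s); the class-indexed penalty does not dictate a
level for them, so this is a documented, configurable choice (`"ns"` and
`"s"` rules are also available). Since deleterious mutations tend to be
nonsynonymous, cross-validation typically settles on λ_s ≥ λ_ns, shrinking
the decoy synonymous terms harder.

## Evaluation

* **Consistency** — with `s_ij = 1` iff feature *j* has a nonzero
  coefficient in replicate *i*, and *F* the features selected in at least
  one of the *R* replicates, the instability score is
  `C = Σ_{j∈F} n_j (R − n_j) / R`, `n_j = Σ_i s_ij`. C = 0 iff every
  replicate selects the identical set; lower is more consistent. The score
  is a pluggable strategy (an |F|-normalized variant is provided) because
  the raw-sum form is one of several formulations preserving the
  "lower = more stable" semantics. Covariates are excluded by default:
  being unpenalized they are always selected and contribute zero
  instability.
* **Cross-replicate prediction** — each replicate's fitted model predicts
  the trait in every other replicate (genotypes and covariates are fixed,
  so each model yields one prediction vector). The improvement over a
  covariates-only baseline (OLS / unpenalized logistic, refit per
  replicate) is `mean baseline MSE − mean full MSE` for quantitative traits
  and `mean full AUC − mean baseline AUC` for disease; positive means the
  genetic features help.
* **ROC against the truth set** — features are ranked by the number of
  replicates giving them a nonzero coefficient; sweeping a count threshold
  t ∈ {0..R+1} traces sensitivity/specificity against the causal set, and
  the AUC is the trapezoid-rule area (equal to the tie-corrected
  Mann–Whitney statistic of the count ranking; verified against brute-force
  pairwise concordance). At gene granularity every feature maps to its gene
  (entity count = max over its columns) and truth = causal genes; at
  variant+gene granularity common variants are scored as themselves against
  the causal-variant list.

## Synthetic mini-exome generator

The generator emulates the structure of a workshop-style simulated exome
study: one fixed genotype matrix, fixed covariates, and many phenotype
replicates with a known answer sheet. Defaults (all configurable):

* n = 1000 individuals, 100 genes, 1 + Poisson(7) variants per gene.
* MAF spectrum: a mixture of 0.05·Beta(0.5, 6) (rare-skewed) with a 10%
  uniform-on-(0.05, 0.5] common component; dosages drawn per variant under
  Hardy–Weinberg, columns oriented to the sample minor allele.
* Half of the variants nonsynonymous; every causal variant is drawn from
  the nonsynonymous **rare** polymorphic sites, clustered 3 per causal gene,
  with relative per-allele effects Uniform(0.5, 1.5).
* R = 200 phenotype replicates; genotypes and covariates fixed, phenotypes
  resampled.
* Trait models: Q1 = Age + Smoke + genes + noise; Q2 = genes + noise (no
  covariate effects); Q4 = Age + Sex + Smoke + noise (no genetic effects,
  covariates explaining 30% of variance); disease = indicator that a
  liability — 0.4·z(Q1) + 0.4·z(Q2) + 0.2·z(Q4) plus its own causal-variant
  component and unit noise — exceeds the per-replicate empirical quantile
  at prevalence 0.3. Q1/Q2 causal variants are therefore causal for disease
  too, and the truth set records the union.
* Heritability: the genetic component is rescaled (noise variance fixed at
  1) so var(G)/var(Y) equals the target h² (default 0.3); this is feasible
  for any target and the truth set stores the rescaled per-allele effects.

What the generator does **not** emulate: linkage disequilibrium and
pedigree/relatedness structure of real sequence data, sequencing error, and
population-stratified allele frequencies (a population covariate label
exists but does not stratify MAF by default). Tests passing on this
generator therefore demonstrate the methods' behavior under independent
Hardy–Weinberg genotypes, not robustness to LD or confounding.

## Numerical choices and degenerate inputs

* Exact zeros come from soft-thresholding; KKT (subgradient) conditions are
  verified to 1e-6 in the test suite against an exhaustive sign-enumeration
  oracle.
* Constant (zero-variance) columns are excluded from updates and receive
  coefficient 0.
* Logistic fits clip the linear predictor at ±30 and floor IRLS weights at
  1e-5; complete separation therefore terminates at the regularized
  optimum rather than diverging.
* Grid/CV ties break toward the first (largest-λ) grid point; fold splits
  are seeded, and every stage's randomness derives from the single run
  seed.
* Missing genotypes on read are imputed to the rounded per-variant mean
  dosage (logged; a warning above 10% missingness); missing covariates are
  an error.

## Problem sizes in the shipped analyses

The packaged acceptance analyses run the full pipeline at moderate sizes —
n = 500 with 100 genes and 50 replicates for gene recovery, and batches of
10–20 smaller studies (n = 300, 20–30 genes, 6 replicates) for the
annotation-penalty and prediction-sign comparisons — chosen so the whole
battery completes in minutes on one core while leaving the Monte-Carlo
margins comfortably clear of the acceptance thresholds.

## Known limitations

* The consistency score can reward methods that are consistently wrong; it
  is reported alongside prediction improvement and truth-set AUC for that
  reason.
* Gene–environment interactions, Bayesian annotation priors, using the
  quantitative traits as disease predictors, and additive models are out of
  scope, as are kernel/variance-component (SKAT-style) tests and
  pathway-level collapsing.
* The disease model omits the quantitative traits as predictors, so — as on
  the real workshop data — its truth-set recovery is intrinsically weaker
  than the quantitative traits'.
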