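# Methods

## Problem setting

Family-based (trio) sequencing identifies de novo variants directly, and
gene-level association frameworks in the TADA family convert per-gene de
novo and transmitted counts into Bayes factors that multiply across data
types. Case-only cohorts lack parental genotypes, so the de novo /
inherited split of their variants is hidden, and their contribution to
association evidence is traditionally modest. This package infers that
split probabilistically and propagates the inference — including its
error rates — into the gene-level Bayes factor.

Throughout, analysis is restricted to ultra-rare protein-truncating
variants (population allele frequency < 0.1%; a variant absent from the
population reference is treated as frequency 0, the strongest rarity
evidence).

## ClassDn: inheritance-class inference

Six covariates separate de novo from inherited PTVs: allele frequency
(de novo variants are rarer), the gene constraint score LOEUF (lower =
more constrained; de novo hits concentrate in constrained genes), the
constrained coding region percentile CCR (0–100, higher for de novo), a
prior DD/NDD gene-risk FDR (lower for de novo), and the observed and
expected loss-of-function counts of the gene (obs_lof lower, exp_lof
higher for de novo — together they carry constraint and absolute
mutational-target information beyond their ratio).

Because inherited variants outnumber de novo roughly 30:1, plain
learners neglect the minority class. Two resampling ensembles are
implemented over shallow decision trees (default depth 3, 100
estimators):

* **RUSBoost** — AdaBoost.M1 where each round undersamples the majority
  class to a 1:1 ratio (sampling probability proportional to the current
  boosting weight) before fitting; weights are updated on the full set;
  rounds with weighted error ≥ 0.5 are discarded. The de novo score is
  the α-weighted fraction of rounds voting de novo.
* **UnderBagging** — independent balanced undersamples, one tree each;
  the score is the plain vote fraction.

The base-learner depth, ensemble size and sampling ratio are exposed in
configuration; the published ensembles' hyperparameters are not known,
and no claim of equivalence is made. Missing covariates are imputed by
training-set medians stored on the model. Classification is *strictly
greater than* the threshold c (a score equal to c is likely inherited),
which makes sensitivity w₁ nonincreasing and specificity w₂ nondecreasing
in c exactly. Train/test discipline is caller-controlled: the intended
use is training on one family cohort and estimating (w₁, w₂) on a
disjoint one.

## The Random Draw model

For a gene with x_d likely-de-novo and x_h likely-inherited case
variants, each variant is modeled as an independent draw from a mixed
pool. Let I indicate true de novo status, X the thresholded classifier
call, D gene risk status, and

    p1 = P(I=1 | D=1),   p0 = P(I=1 | D=0),   p1 > p0,

because a risk gene's baseline mutation rate μ is multiplied by a
relative risk γ > 1. Classification error enters through the corrected
draw probability q = w₁·p + (1−w₂)·(1−p), and

    P(x_d, x_h | D=d) = C(x_d+x_h, x_d) · q_d^{x_d} (1−q_d)^{x_h}.

The Bayes factor BF_RD = P(x_d,x_h|D=1)/P(x_d,x_h|D=0) is computed in
natural-log space (the binomial coefficients cancel), so counts of order
10⁴ are exact to floating point. Structural identities: BF ≡ 1 when
p1 = p0, when x_d = x_h = 0, or when w₁ + w₂ = 1 (an uninformative
classifier makes q independent of p); with w₁ = w₂ = 1 the BF reduces to
the pure binomial Bayes factor. When w₁ + w₂ < 1 the evidence direction
flips and a warning is emitted. Fixing the total x_d + x_h induces the
negative correlation between de novo and inherited counts seen in real
gene-level results.

Three prior forms for (p1, p0) are supported:

1. **Point values** — default (0.603, 0.026), the de novo fractions of
   case variants in risk and non-risk genes used throughout the power
   simulations; in pipeline runs they are re-estimated from the labeled
   family cohort by risk-stratified de novo fractions (falling back to
   the defaults, with a warning, if the stratified estimate is
   degenerate).
2. **Beta priors** — Beta(a₁,b₁), Beta(a₀,b₀) on the draw probability;
   with a perfect classifier the marginal is the closed-form
   beta-binomial; with an imperfect one the prior is pushed through the
   misclassification map by Gauss–Jacobi quadrature with the Beta
   density's endpoint weights folded into the rule (120 nodes; exact for
   hyperparameters below 1, which Gauss–Legendre handles poorly).
3. **Competing rates from μ** — de novo variants arrive at rate μ
   (non-risk) or γμ (risk) and inherited variants at a per-gene rate ν,
   so p = rate_dn/(rate_dn + ν). The mapping is scale-invariant in
   (μ, ν) jointly and guarantees p1 > p0 for γ > 1. This is the
   package's own documented construction; the published per-gene prior
   derivation is not available and no equivalence is claimed.

Degenerate corrected parameters (q ∈ {0,1}) with incompatible counts
yield an explicit 0/∞ Bayes factor with a warning, never an exception.

## Gene discovery

Per gene, BF_final = max(1, BF_RD) × max(1, BF_family): flooring at 1
means a data source can add evidence but never subtract it. With prior
risk-gene proportion π₁ (default 0.06 ≈ the accepted fraction of genes
with strong effects on ASD), the posterior null probability is
(1−π₁)/((1−π₁) + π₁·BF). Genes are ranked by BF descending (gene
identifier as tie-break; tied BFs share the q-value of the last tied
rank) and the q-value at rank k is the mean posterior null probability of
the top k — the expected FDR of declaring the top k. Selection is
q < 0.05, or a Bonferroni rule on p-values recovered from q-values by
inverting the Benjamini–Hochberg step-up map (p₍k₎ = q₍k₎·k/m with an
enforced running maximum). BH is not injective, so this inverse is a
canonical pseudo-inverse; it is isolated in one function
(`qvalues_to_pvalues`) so an alternative convention can be swapped in.

## Synthetic data

Real SPARK/ASC cohorts cannot be redistributed, so generators provide
statistically matched stand-ins; all draws go through
`numpy.random.default_rng` with explicit seeds.

* **Covariates**: class-conditional families chosen for
  support-correctness — AF: point mass at 0 plus log-uniform on
  [10⁻⁶, 10⁻³); LOEUF: normal truncated to [0,2]; CCR: point mass at 0
  plus uniform (0,100]; FDR: Beta; obs_lof: Poisson; exp_lof: gamma.
  Default parameters give moderate class overlap with the de novo class
  lower in AF, LOEUF, FDR and obs_lof and higher in CCR and exp_lof; a
  deliberately separable variant exists for classifier sanity tests.
  Only the direction of separation is biologically constrained; the
  parametric forms and overlap level are this package's choices, so
  classifier *performance numbers* on synthetic data say nothing about
  performance on real cohorts — only the relative behavior of the
  algorithms does.
* **Family cohorts**: de novo variants are assigned to genes with weight
  μ × (γ_risk for risk genes, default 20), emulating the concentration of
  de novo hits in risk genes in affected cohorts; inherited variants
  uniformly. Default imbalance 30:1.
* **Case-only cohorts**: labels are generated then hidden (returned
  separately for evaluation). Global mode fixes the de novo count to
  round(n × fraction); risk-stratified mode applies per-gene fractions
  (0.603 risk / 0.026 non-risk).
* **Gene tables**: log-normal mutation rates centred on a typical
  per-gene PTV rate (2×10⁻⁶), log-normal family Bayes factors with a
  much larger location for risk genes, Poisson case variant counts
  (mean 0.75/gene ≈ a 13.5k-variant cohort over 18k genes).
* **Scores**: Gaussian, mean 0.6 / variance 0.1 for de novo and mean
  0.2 / variance 0.1 for inherited; draws are kept unclamped and
  thresholded raw.

Rounding of fractional counts is half-away-from-zero, lower-bounded at
zero, fixed as a convention for reproducibility.

## Simulation studies

Since the score distributions are known, (w₁, w₂) at threshold c follow
analytically from the normal tails: w₁ = 1 − Φ((c−0.6)/√0.1),
w₂ = Φ((c−0.2)/√0.1), giving (0.829, 0.624), (0.624, 0.829),
(0.376, 0.943), (0.171, 0.987) at c = 0.3, 0.5, 0.7, 0.9.

* **Null study**: case variants carry no signal (every gene's variants
  de novo at the non-risk fraction, independent of risk status); family
  BFs keep their signal. The per-family error rate (PFER) is the mean
  number of selected genes outside the risk-gene truth set, under both
  selection rules. Forcing BF_RD = 1 recovers the family-only benchmark
  exactly, replicate by replicate.
* **Power study**: each gene's de novo count is its case variant count
  times the risk-dependent fraction (rounded); the mean number of
  q < 0.05 discoveries over replicates is compared with the family-only
  count.

Default scale is 18,000 genes, 6% risk, 100 replicates per threshold —
genome-scale and fast (seconds per study) because replicates are fully
vectorized (per-variant Gaussian scores tallied per gene with bincount;
the per-gene log-BF evaluated array-wise). The published error/power
table depends on real family-based Bayes factors and gene lists, so only
the analytic operating points and the qualitative orderings (power
peaking near c = 0.7 and exceeding family-only; stricter thresholds not
increasing Bonferroni PFER) are reproduced here; the absolute PFER and
discovery counts depend on the synthetic gene table's BF distribution.

## Numerical and design notes

* All Bayes factors are stored as natural logs and reported linear.
* `bayesian_fdr` restores input order after ranking; ties share the last
  tied rank's q-value.
* The pipeline manifest records config hash, seed, package version and
  inputs but no timestamps, so identical runs are byte-identical.
* Classifier model files are pickles with a format-version tag.
* Multi-gene/transcript variants are out of scope: one gene_id per
  record, resolution owned by the caller. No VCF/BAM parsing — inputs
  are pre-annotated TSVs.
* Known limitations: point priors (p1, p0) estimated from genes with
  prior evidence of association are biased toward known biology; the
  synthetic covariate model does not emulate sequencing error, read
  depth, or parental genotype dropout; γ is never estimated from data.
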