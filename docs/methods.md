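# Methods

This note records the models, parameter choices, numerical conventions
and known limitations of `autoscore`. It documents what the code does
and why the open design points were settled the way they were; every
empirical statement here is one the test suite or `scripts/acceptance.py`
computes.

## Single-sample enrichment scoring

The autophagy score is the ssGSEA statistic: per sample, genes are
ranked 1..N (highest expression = N, ties receive average ranks) and the
score is the integrated difference between a rank-weighted ECDF over set
members and an unweighted ECDF over non-members, walking genes from
highest to lowest rank.

* **α = 0.25, range normalization on** — the published defaults of the
  ssGSEA formulation; both are exposed (`SsgseaParams`). Normalization
  divides every score in a scoring run by the global max − min of the
  unnormalized score table; a zero range leaves scores untouched with a
  warning. Normalization is per scoring run; whether to score a
  multi-cancer cohort jointly or per cancer is the caller's choice (the
  pipeline scores the whole cohort in one run, then classifies per
  cancer, which is tertile-invariant to any monotone rescaling anyway).
* **Tie handling** — average ranks enter the weights; the walk order
  breaks rank ties lexicographically by gene identifier, making the
  statistic fully deterministic. With average ranks both ECDFs reach
  exactly 1 at position N.
* **Set/matrix mismatch** — genes of a set absent from the matrix are
  dropped with a logged count; an empty effective set is an error, as is
  a set covering every gene (the non-member ECDF would be undefined).
* Correctness is anchored to a literal positional-walk oracle (max
  |Δ| < 1e-10 on random instances) and to exact hand-walk values ±2.0
  on a 4-gene example; rank invariance under monotone transforms is
  asserted bit-exactly.

## Signature validation and consensus

A candidate list validates on a labeled dataset when a **two-sided Welch
t-test** of its scores (known autophagy-high vs -low samples) gives
p < 0.05 **and** the high-group mean exceeds the low-group mean. The
direction constraint matters: a two-sided p alone would validate a list
whose scores move the wrong way. Welch rather than pooled-variance was
chosen for robustness; at the group sizes involved the difference is
negligible. Lists passing in ≥ 4 datasets are retained and their exact
set intersection (ordered lexicographically) is the consensus signature.
Under the null (labels carrying no signal) the pass rate per dataset is
≈ α/2, which the suite verifies by simulation.

## Tertile classification

Cuts are the empirical 1/3 and 2/3 quantiles with linear interpolation
between order statistics (the common quantile default; the choice is
immaterial for distinct scores beyond ±1 sample per group). Boundaries
are closed on both cuts with "low" taking precedence, so the degenerate
all-equal case collapses to all-low with a warning rather than an
arbitrary split. Tertiles are computed per cancer type: pooling would
confound cancer-level expression baselines with autophagy status.
Cancers enter downstream analysis only with ≥ 30 samples in **both**
extreme groups.

## Propensity balancing

Group membership (high = 1) is modeled by logistic regression on the
clinical confounders (default list: age, gender, purity, race,
histological type, stage — whichever are present; the covariate set is
config-driven). Categorical covariates are expanded to indicators with
the first level as reference; single-level covariates are dropped with a
warning; samples with missing covariates are dropped complete-case with
a logged count (no imputation rule is assumed). Fitted probabilities are
clipped to [1e-6, 1 − 1e-6] to bound weights; perfect separation is
detected and reported as an error naming the remedy (remove the
separating covariate).

Matching weights emulate 1:1 pair matching: `min(e, 1−e)/e` for high
samples, `min(e, 1−e)/(1−e)` for low, so every sample whose group is on
the minority side of its propensity has weight exactly 1 and all weights
lie in (0, 1]. Downstream tests consume the weights directly — MW is a
weighting method; resampling a matched subset would inject unstated
randomness. Balance is the weighted standardized difference
`d = (x̄_h − x̄_l)/√((s²_h + s²_l)/2)` (weighted moments use the
reliability-weights unbiased variance; categorical covariates report the
max |d| over levels), declared adequate when every |d| < 0.1.

## Differential feature calling

Continuous layers use a Welch-type t statistic on MW-weighted means and
variances with **Kish effective sample sizes** `(Σw)²/Σw²` in place of
counts, and Welch–Satterthwaite degrees of freedom on the same ess. The
test statistic is closed-form (no named weighted test is prescribed for
this design); the permutation layer below guards its approximations.
Binary layers use a two-proportion z statistic on weighted proportions,
replaced by the exact two-sided conditional (hypergeometric) test when
weights are uniform and any expected cell of the 2×2 table is below 5.

* **Effects.** Fold changes are computed on linear-scale weighted means
  and reported sign-magnitude (+r for high ≥ low, −(low/high) otherwise,
  so ±1 is "no change" and a halving is −2.0). Log-scale inputs must be
  de-logged by the caller. Protein/methylation report the weighted mean
  difference; binary layers the weighted proportion difference. A zero
  denominator mean yields signed infinity with a flag; a feature constant
  across samples is uninformative (effect 0, p 1).
* **Multiplicity.** BH step-up per cancer type per layer, implemented
  directly (q = min-over-suffix of p·m/rank) and cross-checked against
  statsmodels and a brute-force oracle to 1e-12.
* **Permutation stabilization.** Group labels are permuted freely across
  samples 100 times (weights stay attached to their samples; strata are
  not defined for this design, and weights are not refit per
  permutation); `perm_p = (1 + #{|T_perm| ≥ |T_obs|}) / (n_perm + 1)`,
  so the attainable minimum is 1/101 and the p is deterministic given
  the seed.
* **Call criterion.** significant ⇔ layer effect threshold (mRNA
  |FC| > 2, miRNA |FC| > 1.5, protein and methylation |diff| > 0.2;
  mutation/SCNA have no effect gate) AND FDR < 0.05 AND perm p ≤ 0.05.
* **Protein pathway scores.** For a signed pathway (activating/
  inhibitory members), the per-sample score is (Σ+ − Σ−)/n_members;
  group differences use the continuous machinery with BH across
  pathways.

## Networks and enrichment

Recurrence thresholds (TF ≥ 9 cancers, miRNA ≥ 4, targets ≥ 3) are
config-exposed defaults; the target filter is applied to both network
kinds. Edges are exactly the reference regulator→target pairs induced by
the selected nodes — the builder can never invent regulation, and
removing a regulator never adds edges. Over-representation is the
one-sided hypergeometric tail with BH across sets; the enrichment
universe defaults to the genes tested in the corresponding differential
step, not the whole annotation.

## Drug response

Spearman correlations use average ranks, pairwise-complete missing-data
handling, a minimum of 10 paired observations, and the t-approximation
p with n − 2 degrees of freedom. Under the GDSC convention higher AUC
means more viable (more resistant), so rs > +0.3 with FDR < 0.05 labels
a cell-line pair resistant and rs < −0.3 sensitive; the cohort analysis
uses ±0.2 against imputed drug response. BH families: per drug across
genes for cell lines, per cancer across drugs for cohorts (the FDR
family is not otherwise pinned down; both choices are config-exposed).
Negating a response vector provably swaps the two labels.

## Synthetic data: what it emulates, and what it does not

The generators produce the three study substrates with planted truth
(`SimConfig` holds every knob):

* **Labeled validation sets** — per-gene i.i.d. standard-normal
  expression; a planted 37-gene core shifted by 2 SD in the labeled-high
  samples of each of 6 datasets (20/group); 4 signal lists = core plus
  private padding, 2 noise lists drawn from non-core genes (keeping the
  planted ground truth crisp).
* **Confounded cohort** — three confounders (age, sex, purity) with
  logit coefficient 0.8 each drive group membership; a 20% fraction of
  features receives a small confounder-driven mean shift (log-scale
  slope 0.1) that MW weighting must remove; planted features shift
  between groups independently of the confounders (default 600 samples;
  continuous expression is linear-scale normal noise with a constant
  coefficient of variation 0.5, floored at 0.01; binary layers are
  Bernoulli with planted odds ratios). The signature can be embedded
  into the mRNA layer so scoring + tertiles recover the latent groups;
  benchmark runs of the feature caller disable the embedding so planted
  truth and called features are commensurable.
* **Drug panel** — planted gene–drug pairs achieve rank correlation ±0.6
  through a Gaussian copula (Pearson r = 2 sin(πρ/6)); all other pairs
  independent; 200 cell lines.

All generators draw from per-stage substreams of `default_rng([seed,
stage])`; identical config + seed reproduces bit-identical outputs.

What the simulations do **not** model: gene–gene correlation structure,
batch effects, realistic copy-number segment geometry, mutation
signatures, heavy-tailed expression noise, or probe-level artifacts.
Passing tests therefore demonstrate correctness of the statistics and
calibration under the stated generative assumptions, not performance on
real cohorts — in particular the near-perfect spike recovery reflects
the independence of features in the generator.

## Pipeline and determinism

Stages communicate only via TSV/GMT files; each stage is independently
invokable from the CLI. A JSON manifest records config, seed, per-output
SHA-256 digests (paths relative to the run directory) and record counts;
floats are always written with `%.10g`, so identical config + seed gives
byte-identical runs. Config validation rejects out-of-domain thresholds
before any computation. The simulated single-cancer study uses
recurrence thresholds of 1 (one cancer cannot recur in nine); the
multi-cancer defaults remain the thresholds quoted above.

Problem sizes in the shipped benchmarks (2000 features per layer,
600-sample cohorts, 200 cell lines, 10–50 seed replicates) were chosen
as the smallest at which the calibration quantities stabilize; all are
config knobs.

## Known limitations

* The weighted Welch/z statistics are asymptotic; at very small
  effective sample sizes only the permutation p is trustworthy.
* Gene identifiers are matched case-sensitively with no alias
  resolution; harmonization across sources is the caller's burden.
* The propensity model is a main-effects logistic; interactions or
  non-linear confounding require a custom covariate expansion.
* Drug-response imputation is consumed as an input table, never
  computed; survival analysis and count-model differential expression
  are out of scope.
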