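# Methods

This note documents the statistical model behind `irlncpair`, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Pair features and why they are rank-based

The unit of modelling is the unordered lncRNA pair {A, B} with the binary
per-sample feature x = 1[expr(A) > expr(B)] (strict inequality; ties give
0).  Because only the within-sample ordering of two genes enters, the
feature — and hence the fitted signature and every downstream risk score —
is invariant under any strictly increasing per-sample transformation of the
expression values.  This is the property that makes pair signatures
portable across platforms, and it is asserted bit-for-bit in the test
suite.  Pairs are stored in canonical lexicographic order (A < B); the
ordered duplicate {B, A} is redundant because, on tie-free data, its column
is exactly one minus the canonical one.

The **valid-match filter** keeps a pair only when its ones-fraction over
the modelling cohort lies in [0.20, 0.80], read inclusively.  A comparison
that resolves the same way in (almost) every patient carries no prognostic
contrast.  The fractions are computed on the tumor samples with survival
data — the population the filter is meant to make the model informative
for — rather than on the merged cohort.

## Screens

*Immune-related lncRNAs.*  A lncRNA is retained when at least one curated
immune gene satisfies Pearson r > 0.4 and p < 0.001, both strict, with p
from the exact t transform t = r·sqrt((n−2)/(1−r²)) on n−2 df.  The screen
is **signed** by default ("more than 0.4" read literally); a flag switches
to |r| because many published variants screen on absolute correlation.  No
multiplicity correction is applied at this step — the 0.001 threshold is
used raw, as is conventional for this screen — and the correlation is
computed on the merged normal+tumor samples (configurable to tumor-only).
Constant genes are excluded with a logged count rather than raising.

*Differential expression.*  Group difference is the mean difference of the
already-log2 values (log2FC); significance is the Wilcoxon rank-sum test —
exact enumeration when both groups have n ≤ 12 and the pooled values are
tie-free, otherwise the normal approximation with tie and continuity
correction — with Benjamini–Hochberg adjustment across the screened
irlncRNA family.  A rank test was chosen over moderated-t statistics to
keep the stage assumption-light and self-contained; variance shrinkage is
explicitly out of scope.  The default thresholds are |log2FC| > 2 and
**FDR < 0.05**.  The filter is two-sided (down-regulated genes pass), and
both thresholds are exposed in the configuration.

## Survival modelling

*Univariate screen.*  Each valid pair is fit in a univariate Cox
proportional-hazards model; pairs with Wald p < 0.05 survive.  Degenerate
fits (constant column, < 2 events) and non-converging fits (monotone
likelihood) are dropped with a warning rather than halting the run.

*Penalized fit.*  Survivors enter an L1-penalized Cox model
(coordinate-descent path over a descending λ sequence).  λ is chosen to
minimize the k-fold cross-validated held-out deviance, computed as −2×
the Breslow partial log-likelihood of the held-out fold under the
train-fold coefficients; folds are stratified by event status and seeded
from the run seed.  A one-standard-error rule is available by flag
(`lambda_rule="1se"`), with the minimum-deviance rule as default since no
fold count or selection rule is canonical for this design.  10 folds by
default.

*Tie handling.*  The unpenalized fits (univariate and multivariate)
delegate to lifelines, which uses Efron's approximation for tied event
times; the penalized path and the cross-validation deviance use the Breslow
convention.  Survival times in the synthetic cohort are continuous, so ties
occur with probability zero and the two conventions coincide there; on real
data with heavy ties the conventions may differ slightly in the third
decimal of β.  Newton convergence is tightened to 1e−9 so that fits agree
with a brute-force partial-likelihood maximizer to 1e−4.

*Risk score.*  riskScore_i = Σ β_n x_ni over the selected pairs, with x the
binary pair values.  Scores are therefore piecewise-constant with at most
2^m distinct values for an m-pair signature.

## Stratification

Time-dependent ROC curves use the cumulative-case / dynamic-control
definition: at horizon t, cases are subjects with an event by t and
controls are subjects event-free past t.  Censoring is handled with the
product-limit (Kaplan–Meier) weighting of the classic estimator:
for threshold c,

    sens(c, t) = (1 − S_c(t)) · P(score > c) / (1 − S(t))
    spec(c, t) = 1 − S_c(t) · P(score > c) / S(t)

with S the overall and S_c the above-threshold KM survival at t.  This
estimator is not guaranteed monotone under censoring, so the curves are
isotonized (running maximum on sensitivity, running minimum on specificity,
along descending thresholds) before the trapezoidal AUC; without censoring
it reduces exactly to empirical fractions and the AUC equals the
Mann–Whitney statistic of the binary status indicator, which the tests
assert to machine precision.

Horizons default to 365/1095/1825 days; the horizon with the largest AUC is
selected, ties breaking toward the longest.  The cutoff maximizes the
Youden index J = sensitivity + specificity − 1, ties breaking toward the
lower threshold (the larger high-risk group); a flat curve (J = 0
everywhere) falls back to the median score with a warning.  Samples with
score strictly above the cutoff are high risk; a cutoff that empties either
group is an error.

## Evaluation

Kaplan–Meier estimation, the two-group log-rank test and the multivariate
Cox model stand on lifelines.  Clinical covariates enter the independence
model with a fixed coding: age continuous in years; grade G1–G4 → 1–4 and
stage I–IV → 1–4 as ordinal integers; residual disease binary (R0 → 0,
anything else → 1).  Rows with any missing covariate are deleted listwise,
and a rank-deficient design raises with the names of the collinear columns.

Group contrasts (clinical factors, drug IC50-like scores, enrichment
scores) use the same Wilcoxon machinery as the DE stage and attach the
conventional stars: p < 0.001 "***", p < 0.01 "**", p < 0.05 "*", all
strict.  Drug sensitivity is consumed as a precomputed per-sample score
table (lower = more sensitive); training expression-to-IC50 models is out
of scope by design.

Immune infiltration is summarized with a single-sample rank-based
enrichment score: per sample, genes are ranked by expression descending
(rank values n..1, ties broken by gene order); walking down the ranking the
running sum gains rank^α/Σ_set rank^α at in-set genes and loses
1/(n − |set|) elsewhere, and the score is the sum of the running sum over
all positions, optionally min–max normalized per set across samples.
α = 0.25 by default.  This is a documented contract rather than a
deconvolution method: it orders samples by the joint expression salience of
a gene set and supports group contrasts, nothing more.

## Synthetic cohort

The generator plants exactly the structure the pipeline is designed to
find, at desk scale:

| parameter | default | meaning |
|---|---|---|
| n_normal / n_tumor | 60 / 300 | cohort sizes |
| n_mrna (n_immune) | 500 (100) | mRNAs, first 100 are the immune panel |
| n_lnc / n_irlnc / n_de | 300 / 40 / 20 | lncRNAs, planted immune-related, planted DE |
| de_shift | 3.0 log2 | tumor-only additive shift on DE genes |
| n_planted_pairs, pair_betas | 5, 0.8 each | hazard-driving pairs (log-HR per pair) |
| baseline_hazard | 2e-4 /day | exponential baseline |
| censor_max | 3650 days | uniform administrative censoring |
| noise_sd | 0.5 log2 | residual expression noise |
| batch_shifts | {A: 0, B: 1} | additive offsets, batches balanced across cohorts |

A single standard-normal latent factor f (per-sample immune activity)
drives co-expression: immune genes and planted irlncRNAs both load on f
with weight 1.0, giving a population correlation of 0.8 between an immune
gene and a planted irlncRNA before the tumor shift (≈ 0.57 on the merged
cohort after the DE shift inflates lncRNA variance) — comfortably above
the 0.4 screen while non-planted lncRNAs are independent noise.  The two
genes of a planted pair share their mean expression, so the pair indicator
is approximately Bernoulli(1/2) and survives the 20–80% filter.  Survival
is exponential with rate h0·exp(Σ β_k x_ik) and uniform censoring — the
simplest generative model consistent with proportional hazards.  Clinical
covariates are drawn from fixed frequency tables and carry no hazard;
vital status mirrors the event indicator.  Synthetic IC50-like drug scores
are a drug-specific baseline plus an effect proportional to the latent
linear predictor plus noise, so high-risk patients score higher (less
sensitive).  The immune-cell GMT partitions the immune panel into seven
disjoint synthetic signatures.

What the generator does **not** emulate: RNA-seq count overdispersion
(values are Gaussian on the log2 scale), correlated blocks of immune
programs (one global factor), non-proportional hazards, informative
censoring, and batch effects beyond additive location shifts.  Passing
tests therefore demonstrate correctness of the machinery and calibration
under the stated model, not robustness to those real-data features.

All randomness derives from the config seed through independent
`SeedSequence` streams per stage, making every output — including the
written files — byte-identical across runs with the same seed.

## Problem sizes used in the checks

The automated checks run the full pipeline at the default scale above
(~4 s end to end) and use 20-seed replicates for the calibration
properties: 1000-gene null DE matrices, 100 null pairs per seed for the
univariate screen, and 50 null drug contrasts per seed after
stratification, with acceptance bands of ±2 percentage points around the
nominal 5% (about four binomial standard errors at those replicate
counts).

## Known limitations

- The location–scale batch adjustment removes additive/multiplicative
  per-batch effects only; it performs no empirical-Bayes shrinkage and
  protects no covariates.  Batches confounded with cohort (> 95% one
  label) are flagged, not corrected for.
- Univariate screening refits lifelines per pair; for signatures built
  from hundreds of genes (10^4+ pairs) this stage dominates runtime.
- The KM-weighted ROC estimator can exceed [0, 1] before clipping in very
  small strata; isotonization makes the reported curves monotone but the
  raw estimator's variance at extreme thresholds remains high.
- Risk scores from a small signature take few distinct values, so the
  Youden cutoff is a coarse grid; reported cutoffs are observed score
  values by construction.
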