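# irlncpair

Prognostic survival signatures built from **rank-based pairs of
immune-related lncRNAs**, for transcriptomic cohorts with tumor/normal
contrasts and follow-up data (the motivating setting is bulk RNA-seq of
ovarian cancer, but nothing in the code is tissue-specific).

Classical expression signatures depend on the measured level of each gene,
which makes them fragile across platforms and normalizations.  This package
instead builds **binary pair features**: for two lncRNAs *A* and *B*, the
feature is 1 in a sample when expr(*A*) > expr(*B*) and 0 otherwise.  Only
the within-sample ordering enters, so the signature is invariant to any
strictly increasing per-sample transform of the data.

## The method

Given a log2-scale expression matrix over normal and tumor cohorts, a gene
annotation (GTF), a curated immune gene list and a clinical table:

1. **Immune-related lncRNAs (irlncRNAs)** — a lncRNA is retained when some
   immune gene correlates with it at Pearson *r* > 0.4 and *p* < 0.001.
2. **Differential expression** — irlncRNAs with |log2FC| > 2 and
   Benjamini–Hochberg FDR < 0.05 between tumor and normal (Wilcoxon
   rank-sum) become DEirlncRNAs.
3. **Pair features** — all C(k,2) unordered DEirlncRNA pairs are binarized
   per sample; pairs whose ones-fraction lies in [20%, 80%] are *valid
   matches* (a comparison constant across patients cannot be prognostic).
4. **Signature** — pairs passing a univariate Cox screen (Wald *p* < 0.05)
   enter an L1-penalized Cox model; the penalty λ minimizes the 10-fold
   cross-validated partial-likelihood deviance.  The risk score of sample
   *i* is

   riskScore_i = Σ_n β_n · x_ni

   with β_n the lasso-Cox coefficients and x_ni ∈ {0, 1} the pair values.
5. **Stratification** — time-dependent ROC curves (cumulative cases /
   dynamic controls, Kaplan–Meier weighting) at 1/3/5 years; the horizon
   with maximal AUC supplies the Youden-optimal cutoff
   (max sensitivity + specificity − 1); scores above it are high risk.
6. **Evaluation** — Kaplan–Meier curves and log-rank test between groups,
   multivariate Cox for prognostic independence from age / grade / stage /
   residual disease, Wilcoxon contrasts of clinical factors and
   IC50-like drug-sensitivity scores (with ∗/∗∗/∗∗∗ significance stars),
   and a single-sample rank-based enrichment score for immune-cell gene
   sets.

A fully synthetic cohort generator (`irlncpair.synthetic`) plants all of
this structure — a latent immune-activity factor, tumor-only expression
shifts, and pair features that drive an exponential proportional-hazards
model — so the whole chain is testable without any external downloads.

## Worked example

The scripts in `examples/` walk through the pipeline on a generated cohort
(60 normal + 300 tumor samples, 500 mRNAs, 300 lncRNAs).  After
`python examples/01_generate_cohort.py` and `02`/`03`:

```
correlation screen: 40 irlncRNAs (4000 passing gene-lncRNA correlations)
  recall of planted irlncRNAs: 40/40
differential expression: 20 DEirlncRNAs (20 up, 0 down)
candidate pairs: 190 from 20 genes
valid pairs (20-80% ones-fraction): 40
signature: 10 pairs at lambda=0.009743
  LNC0001|LNC0002: beta=+0.328  <- planted
  ...
  LNC0009|LNC0010: beta=+0.703  <- planted
```

All five planted hazard pairs appear in the fitted signature.
`04_stratify_and_evaluate.py` then prints:

```
horizon 1825 days, AUC 0.950, cutoff 0.946
groups: 211 high risk, 89 low risk
log-rank: chi2=67.6, p=2.04e-16 ***
  median survival: high 291 d, low 1838 d
multivariate Cox (HR [95% CI], p):
  risk_score  3.147 [2.559-3.869] p=1.48e-27
drug IC50 contrasts (high vs low risk):
  cisplatin    median 3.26 vs 2.58, p=2.35e-13 ***
```

High-risk patients die sooner, the score is prognostic independently of
the clinical covariates (HR per score unit with a CI excluding 1), and the
planted drug-sensitivity differences are detected.

The same run is available as one command:

```sh
irlncpair run-all --seed 42 --out my_run        # or: irlncpair simulate/extract/de/pairs/fit/stratify/evaluate
```

which persists every stage's table plus a `manifest.json` whose contents
are byte-identical across runs with the same config and seed.

## Layout

- `src/irlncpair/io.py` — readers/writers and domain containers (expression
  TSV, Ensembl GTF, GMT, clinical and drug-score tables)
- `src/irlncpair/synthetic.py` — the planted-structure cohort generator
- `src/irlncpair/preprocess.py` — merging, location–scale batch adjustment,
  biotype partition
- `src/irlncpair/coexpression.py`, `diffexpr.py`, `pairs.py` — screens and
  pair features
- `src/irlncpair/signature.py`, `stratify.py`, `evaluate.py` — modelling,
  ROC stratification, verification
- `src/irlncpair/pipeline.py`, `cli.py` — orchestration and the thin CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
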