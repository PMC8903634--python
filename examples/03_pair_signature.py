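"""Build the 0/1 pair features and fit the lasso-Cox signature.

Every unordered pair of DE immune-related lncRNAs becomes a binary feature
(1 when the first gene's expression exceeds the second within the sample);
pairs informative in 20-80% of patients are kept, screened by univariate
Cox, and the penalty of the final L1 Cox model is chosen by 10-fold
cross-validated deviance.  The printed coefficients are the per-pair
log-hazard weights of the risk score sum(beta_n * x_n).
"""
from irlncpair import io, coexpression, diffexpr, pairs, preprocess, signature
from irlncpair.synthetic import GroundTruth

expr = io.read_expression_matrix("example_cohort/expression.tsv",
                                 labels_path="example_cohort/sample_labels.tsv")
ann = io.read_gtf_annotation("example_cohort/annotation.gtf")
immune = io.read_gene_list("example_cohort/immune_genes.txt")
surv = io.read_clinical_table("example_cohort/clinical.tsv")
truth = GroundTruth.from_json("example_cohort/ground_truth.json")

expr = preprocess.batch_adjust(expr)
mrna, lnc = preprocess.partition_by_biotype(expr, ann)
irlnc, _ = coexpression.extract_irlncrnas(mrna.values.loc[immune], lnc.values)
de_ids = diffexpr.select_deirlncrnas(diffexpr.de_table(lnc, genes=sorted(irlnc)))

tumor = [s for s in lnc.tumor_samples() if s in set(surv.sample_ids)]
pm = pairs.build_pair_matrix(lnc.values.loc[de_ids], tumor)
print(f"candidate pairs: {pm.n_pairs} from {len(de_ids)} genes")
pm = pairs.filter_valid_pairs(pm)
print(f"valid pairs (20-80% ones-fraction): {pm.n_pairs}")

pm_screened, _ = signature.screen_pairs(pm, surv)
model = signature.fit_lasso_cox(pm_screened, surv, seed=42)
scores = signature.compute_risk_score(model, pm)

planted = {"|".join(p) for p in truth.planted_pairs}
print(f"signature: {len(model.pair_names)} pairs at lambda={model.lambda_:.4g}")
for name, beta in zip(model.pair_names, model.betas):
    tag = "  <- planted" if name in planted else ""
    print(f"  {name}: beta={beta:+.3f}{tag}")
print(f"risk scores: n={len(scores)}, range [{scores.min():.2f}, {scores.max():.2f}]")
scores.to_frame().to_csv("example_cohort/risk_scores.tsv", sep="\t")
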