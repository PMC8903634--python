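"""Screen for immune-related lncRNAs and test their differential expression.

Reads the bundle written by 01_generate_cohort.py, applies the correlation
screen (a lncRNA is immune-related when some immune gene correlates with it
at r > 0.4 and p < 0.001) and then the tumor-vs-normal filter
(|log2FC| > 2, BH-FDR < 0.05).  The printed recall shows how much of the
planted structure the two screens recover.
"""
from irlncpair import io, coexpression, diffexpr, preprocess
from irlncpair.synthetic import GroundTruth

expr = io.read_expression_matrix("example_cohort/expression.tsv",
                                 labels_path="example_cohort/sample_labels.tsv")
ann = io.read_gtf_annotation("example_cohort/annotation.gtf")
immune = io.read_gene_list("example_cohort/immune_genes.txt")
truth = GroundTruth.from_json("example_cohort/ground_truth.json")

expr = preprocess.batch_adjust(expr)
mrna, lnc = preprocess.partition_by_biotype(expr, ann)

irlnc, records = coexpression.extract_irlncrnas(mrna.values.loc[immune], lnc.values)
print(f"correlation screen: {len(irlnc)} irlncRNAs "
      f"({len(records)} passing gene-lncRNA correlations)")
print(f"  recall of planted irlncRNAs: "
      f"{len(irlnc & set(truth.irlnc_ids))}/{len(truth.irlnc_ids)}")

res = diffexpr.de_table(lnc, genes=sorted(irlnc))
de_ids = diffexpr.select_deirlncrnas(res)
n_up = (res.loc[de_ids, "direction"] == "up").sum()
print(f"differential expression: {len(de_ids)} DEirlncRNAs "
      f"({n_up} up, {len(de_ids) - n_up} down)")
print(f"  recall of planted DE genes: "
      f"{len(set(de_ids) & set(truth.de_ids))}/{len(truth.de_ids)}")
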