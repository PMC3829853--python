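"""Generate the standard synthetic cohort and inspect its ground truth.

Builds a three-dataset expression cohort with planted co-expression
modules and three transcriptional subtypes, plus a scale-free signaling
network with planted driver genes, and writes everything to disk in the
plain-text formats the pipeline reads.
"""

from pathlib import Path

from crcnet import io
from crcnet.synthetic import (SyntheticCohortSpec, gen_alteration_data,
                              gen_expression_cohort,
                              gen_ontology_and_annotations,
                              gen_signaling_network, gen_survival,
                              plant_driver_genes)

out = Path("example_output")
out.mkdir(exist_ok=True)

spec = SyntheticCohortSpec(seed=1)
expr, truth = gen_expression_cohort(spec)
print(f"expression: {expr.values.shape[0]} genes x "
      f"{expr.values.shape[1]} samples in {len(expr.datasets)} datasets")
print(f"planted modules: {len(truth.module_members)} "
      f"(sizes {sorted(len(m) for m in truth.module_members.values())})")
print(f"subtype sizes: {truth.sample_subtype.value_counts().to_dict()}")

net = gen_signaling_network(300, 3, seed=2, genes=list(expr.genes))
truth = plant_driver_genes(net, truth, 12, seed=3)
mut, cnv = gen_alteration_data(net, truth, background_rate=0.01,
                               driver_rate=0.6, seed=4)
surv = gen_survival(truth, censor_rate=0.3, seed=5)
onto, ann = gen_ontology_and_annotations(60, list(expr.genes), truth, seed=6)

io.write_expression(expr, out / "expression.tsv", out / "samples.tsv",
                    extra_annotations=truth.sample_subtype.rename(
                        "true_subtype").to_frame())
io.write_edge_list(net, out / "signaling_network.tsv", weight=None)
io.write_matrix(mut, out / "mutations.tsv")
io.write_matrix(cnv, out / "cnv_calls.tsv")
io.write_survival(surv, out / "survival.tsv")
io.write_obo(onto, out / "ontology.obo")
io.write_annotations(ann, out / "annotations.tsv")

print(f"network: {net.number_of_nodes()} genes, "
      f"{net.number_of_edges()} edges; "
      f"{sum(len(d) for d in truth.driver_genes.values())} planted drivers")
print(f"alterations: {int(mut.to_numpy().sum())} mutation calls, "
      f"{int(cnv.to_numpy().sum())} CNV calls "
      f"({(surv['event'] == 1).mean():.0%} of samples with observed death)")
print(f"files written under {out}/")
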