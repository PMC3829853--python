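# crcnet

Transcriptional subtype discovery and driver-subnetwork inference for
colorectal cancer (CRC) expression cohorts.

Bulk CRC cohorts assembled from several microarray datasets show
reproducible transcriptional subtypes, and the heterogeneous somatic
alterations of each subtype tend to converge on a small number of
signaling-network regions. `crcnet` implements that analysis as a tested,
reusable Python library:

1. **Cross-dataset normalization** — probe-to-gene collapse (multi-gene
   probes dropped, per-sample median over probes), per-dataset mean
   centering, common-gene merging, optional centering against normal
   reference samples.
2. **Co-expression modules** — all-pairs Pearson correlations; a
   knowledge-guided correlation threshold chosen where the mean Resnik
   semantic similarity of gene pairs (from an ontology) rises sharply on
   both the positive and negative side; iterative clique enumeration
   (ICE) merges heavily overlapping maximal cliques into modules of at
   least 20 genes.
3. **Subtype discovery** — consensus average-linkage hierarchical
   clustering of samples over module genes (resampled subsets,
   1 − Pearson distance), cluster number read off the consensus-CDF
   area curve, SigClust-style pairwise cluster significance, and core
   samples defined by positive silhouette width
   s(i) = (b(i) − a(i)) / max(a(i), b(i)).
4. **Subtype classifier** — nearest shrunken centroids (PAM):
   standardized class differences d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0))
   soft-thresholded by Δ, repeated stratified 10-fold cross-validation,
   posterior class probabilities; per-subtype signature genes by
   one-tailed Student t-tests and a permutation test of signature
   functional coherence.
5. **Driver subnetworks** — binary mutation (non-silent calls) and CNV
   (ratio ≥ 1.2 or ≤ 0.8) matrices are column-normalized and row-summed
   into a start-probability vector p0; a random walk with restart
   p_{t+1} = (1 − r) Wᵀ p_t + r p0 (r = 0.5, column-normalized adjacency
   W, L1 convergence) scores every gene of the signaling network's
   largest component; permuted-seed walks give local (same-gene) and
   global (all-genes) empirical p-values, and the largest connected
   component of genes with local p < 0.05 and global p < 0.05 is the
   subtype's driver subnetwork. Hypergeometric/BH gene-set enrichment
   summarizes the result.
6. **Characterization** — contingency-table association with
   per-cell hypergeometric enrichment, developmental-timecourse
   correlation of subtype centroids (Fisher-z CIs), mean-expression
   signature scoring (e.g. EMT), Kaplan–Meier curves with the k-group
   log-rank test.

A fully seeded synthetic-cohort generator (`crcnet.synthetic`) plants
modules, subtypes, driver subnetworks, survival differences and a small
ontology with known ground truth, so the entire pipeline is validated
end to end without any external data.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from crcnet.synthetic import (SyntheticCohortSpec, gen_expression_cohort,
                              gen_ontology_and_annotations)
from crcnet.pipeline import run_discovery

spec = SyntheticCohortSpec(seed=1)           # 1200 genes, 180 samples,
expr, truth = gen_expression_cohort(spec)    # 3 datasets, 3 subtypes
onto, ann = gen_ontology_and_annotations(60, list(expr.genes), truth, seed=6)

res = run_discovery(expr, onto, ann, n_resamples=200, seed=7)
core = res.assignment.core_sample_ids
print(res.k, len(res.modules), len(core))
print(adjusted_rand_score(truth.sample_subtype.loc[core],
                          res.assignment.table.loc[core, "label"]))
```

prints

```
3 13 179
0.9664...
```

three consensus clusters were found, 13 co-expression modules survived
the 20-gene floor, 179 of 180 samples have positive silhouette width,
and the core-sample labels agree with the planted subtypes almost
perfectly (adjusted Rand index 0.97). The `examples/` directory holds
one short narrative script per capability (cohort generation, module
discovery, subtyping, classification, driver inference, survival and
characterization); each prints the numbers it computes and a line on
what they mean.

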