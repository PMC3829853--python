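# Methods

This note documents the models and procedures `crcnet` implements, the
parameters that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Cross-dataset normalization

Multi-dataset expression compendia carry additive platform/site offsets.
The pipeline removes them by mean-centering every gene within each
dataset; merging then takes the intersection of gene universes. Probe
collapse drops probes mapped to more than one gene and represents a
gene measured by several probes with the per-sample median (ties among
an even number of probes resolve to the arithmetic mean of the central
pair — the standard median). Missing values are rejected rather than
imputed: silent imputation would distort the correlation structure that
module discovery and clustering depend on. Per-dataset centering is
idempotent and commutes with merging when datasets are disjoint.

## Knowledge-guided correlation threshold

All unordered gene pairs are binned by Pearson correlation (bin width
0.05 over [−1, 1] — fine enough to localize a similarity jump while
keeping bins populated). Each bin's mean Resnik semantic similarity is
computed from ontology annotations: IC(t) = −ln(fraction of annotated
genes annotated to t or its descendants), and a gene pair scores the
maximum IC over the most informative common ancestors of their
annotation-term pairs (the max convention; it is monotone under
annotation refinement). The threshold is the smallest bin edge ≥ 0.3
whose bin mean exceeds the pooled mean of the |r| < 0.3 bins by at
least two pooled standard errors on **both** the positive and negative
side; empty bins are flagged and excluded, and a flat curve raises an
error instructing a manual choice. A user-supplied threshold always
wins. On cohorts where functional similarity rises gradually with |r|,
the rule fires at the first qualifying edge rather than at the visually
sharpest jump; the binned curve is returned so the user can inspect it
and override.

## Iterative clique enumeration (ICE)

Maximal cliques of the thresholded network (|r| ≥ threshold, signed
edges kept) with at least `min_clique` = 5 members are processed in
decreasing size, ties broken by lexicographically smallest member list
for determinism. A clique is merged into the existing module with which
it shares the largest fraction of its own nodes when that fraction
reaches `merge_overlap` = 0.5 (measured as |clique ∩ module|/|clique|);
otherwise it seeds a new module. Modules below `min_module` = 20 unique
genes are discarded. The overlap criterion and minimum clique size are
reimplementation choices exposed in the API, not values asserted by the
original description, which defers to earlier work.

## Consensus clustering and core samples

Each of `n_resamples` (default 1000; end-to-end tests and the
acceptance script use 200 as their problem-size choice) draws 80% of
samples without replacement and clusters them by average-linkage
hierarchical clustering under 1 − Pearson distance over the module
genes, cutting at each k. Consensus entry (i, j) is the co-clustering
count over the co-sampling count; never co-sampled pairs are flagged
and excluded from the CDF. The cluster number is the largest k whose
relative gain in consensus-CDF area over k − 1 exceeds 0.1 — an
automated reading of the usual CDF plot that never overrides an
explicit user k. Final labels come from average-linkage clustering of
1 − consensus at the chosen k.

SigClust-style pair significance simulates the null of a single
Gaussian with diagonal covariance whose eigenvalues are the pooled
sample-covariance eigenvalues floored at a background variance
estimated from the median absolute deviation of all entries (the
background soft-thresholding step reduces algebraically to this
elementwise floor); each simulated dataset is split by 2-means and
p = (1 + #{simulated index ≤ observed})/(1 + n_sim).

Silhouette widths use the cluster-mean-distance definition with
1 − Pearson distance over the selected module genes (all selected
genes, not module summaries). Samples in singleton clusters get
s(i) = 0 — neither core nor anti-core — with a loud log message. Core
samples are exactly those with s(i) > 0.

## Nearest shrunken centroids

d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s0)) with m_k = sqrt(1/n_k − 1/n),
pooled within-class SD s_i, fudge s0 = median(s_i); soft-thresholding
d'_ik = sign(d_ik) max(|d_ik| − Δ, 0) zeroes genes out of the
classifier as Δ grows (active-gene count is non-increasing in Δ).
Prediction minimizes the standardized squared distance to the shrunken
centroids minus 2 ln(prior); priors are empirical class frequencies;
posteriors are softmax(−δ/2). With no active genes the prior term
alone decides. Cross-validation is stratified k-fold (default 10)
repeated (default 100) with fresh fold seeds per repeat.

Signature assignment: a gene is "up in k" when one-tailed
pooled-variance Student t-tests give p < 0.05 against **each** other
subtype separately (the stricter reading of "compared to all other
subtypes"; a pooled-others mode is available); down-regulation is the
mirrored rule applied to the remainder. No multiple-testing correction
is applied — deliberate fidelity to the raw p < 0.05 rule. Functional
coherence of a signature is tested by comparing its mean pairwise
Resnik similarity against same-size random draws from the background,
with the add-one permutation p.

## Random walk with restart

The walk runs on the largest connected component of the signaling
network; start mass on genes outside it is dropped (logged) and the
vector renormalized. W is the column-normalized adjacency of the
unweighted, undirected network. Start probabilities: each binary
alteration matrix is column-normalized (a sample's alterations sum
to 1, so alterations in quiet genomes weigh more; all-zero samples
contribute 0), row-summed, the mutation and CNV vectors added with
equal weight, and the sum normalized to 1. The iteration
p ← (1 − r) Wᵀ p + r p0 with r = 0.5 stops when the L1 change drops
below 1e-6 (max 10⁴ iterations, error on non-convergence). Scores stay
a probability distribution at every step.

Significance: permutations shuffle the p0 values across all network
genes — zeros included, matching "randomly permuted start
probabilities" read literally, so a permutation can fix a gene's own
value and tie its observed score. All permutation walks advance
simultaneously as columns of one matrix iteration, which is
mathematically identical to running them one at a time. Local
p_i = (1 + #{perm score of i ≥ observed_i})/(1 + n_perm); global p
pools permutation scores over all genes and permutations
(denominator 1 + n_perm·n_genes; a per-permutation averaging mode is
available). Add-one estimators keep p > 0. The driver subnetwork is
the largest connected component of genes with local p < 0.05 **and**
global p < 0.05, ties broken by node count, edge count, then smallest
member. Activating and deactivating alterations are not distinguished
— the walk is direction-blind by design; expression-level consistency
checks live in the characterization module.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not the biology that produces it:

* **Expression.** Each planted module m has one latent factor per
  sample, f_ms ~ N(μ_mk, factor_sd), where μ_mk = `subtype_effect` for
  the module's associated subtype (modules are assigned to subtypes
  round-robin) and 0 otherwise. Member genes are
  x = ±`module_correlation`·f + ε, ε ~ N(0, `noise_sd`); a
  `module_neg_fraction` minority of members load negatively, giving
  modules the anti-correlated arm real co-expression modules show and
  populating the negative side of the threshold curve. Non-module
  genes are pure noise. Every gene receives an additive per-dataset
  offset ~ N(0, `batch_sd`), which per-dataset centering removes.
* **Defaults.** 1200 genes; three datasets of 60 samples; three
  subtypes balanced within datasets; 15 modules of 25–40 genes (a
  cohort rich enough that per-module factor noise averages out in
  sample correlations); loading 0.9; factor_sd 0.6; noise_sd 0.5;
  subtype_effect 1.0 (= 2 × noise_sd); batch_sd 0.3. factor_sd is the
  within-subtype heterogeneity knob — the one quantity the underlying
  study never characterizes — and was fixed once to keep both
  within-module gene correlation (≈ 0.54 at these settings) and
  between-subtype separation at realistic levels.
* **Network and alterations.** A connected preferential-attachment
  graph (heavy-tailed degrees) over cohort gene names; per subtype a
  connected driver gene set grown by breadth-first expansion, disjoint
  across subtypes. Mutation and CNV calls are independent Bernoulli
  draws: `driver_rate` (default 0.6) on a sample's own subtype drivers,
  `background_rate` (default 0.01) elsewhere. Independence of the two
  matrices is the neutral case for the equal-weight combination.
* **Survival.** Exponential event times with subtype hazards (defaults
  0.04/0.01/0.02 per month — poor, good and intermediate outcome);
  independent exponential censoring calibrated so the expected censored
  fraction equals `censor_rate`.
* **Ontology.** A random rooted DAG grown child→parent with occasional
  extra parents; each module gets a dedicated deep term annotated to
  its members, every gene is annotated to the root plus one random
  generic term. Within-module Resnik similarity therefore exceeds
  cross-module similarity by construction.

What the generator does **not** emulate: probe-level noise,
non-additive batch effects, correlated mutation/CNV processes,
hypermutator phenotypes, microsatellite instability, or ontology
annotation bias. Passing end-to-end tests therefore demonstrates that
the pipeline recovers the structure it is designed for when that
structure is present — not that real cohorts contain it.

## Numerical choices and degenerate inputs

Zero-variance genes are skipped (logged) in the correlation stream.
Pearson correlations of constant vectors are undefined and excluded
rather than coerced. The silhouette of a singleton cluster is 0. The
walk errors on all-zero start vectors and on non-convergence. CNV
ratios must be positive; both binarization cutoffs are inclusive.
Stage-correlation CIs collapse to a point at |r| = 1 where the Fisher
transform diverges. Contingency reports emit both row and column
percentages, labeled, because published tables mix the two conventions;
fold enrichment is always observed/(row·col/grand), the explicit
independence formula.

## Problem sizes

Unit tests run on toy instances with frozen hand-computed or
brute-force oracle values. End-to-end validations (and the acceptance
script) use the default 1200-gene/180-sample cohort, a 300-node
signaling network with 12 planted drivers per subtype, 200 consensus
resamples and 200–500 walk permutations — sizes chosen so the full
suite completes in minutes on one CPU while keeping every statistical
check well-powered.

## Known limitations

The ICE overlap criterion and SigClust covariance details follow the
cited conventions rather than a published reference implementation of
this exact pipeline. The knowledge-guided threshold rule formalizes a
visual judgement and can fire below the visually sharpest jump on
smoothly rising curves. Cox regression, soft-threshold (weighted)
co-expression analysis, NMF clustering and directed signaling semantics
are out of scope.
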