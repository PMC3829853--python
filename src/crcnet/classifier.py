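"""Nearest shrunken centroid (PAM-style) subtype classifier.

Class centroids are standardized against the overall centroid with the
pooled within-class SD plus a fudge s0 (median of the SDs), then
soft-thresholded by the shrinkage Delta: genes whose standardized
difference shrinks to zero for all classes drop out of the classifier.
Prediction minimizes the standardized squared distance to the shrunken
centroids with a class-prior term; posteriors come from a softmax of
the discriminant scores.

Also provides the subtype signature-gene assignment (one-tailed t-tests
of one subtype against each other subtype) and the permutation test for
functional coherence of a signature under Resnik similarity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "NSCModel",
    "train_nsc",
    "predict",
    "cv_error_curve",
    "SignatureSet",
    "assign_signatures",
    "coherence_test",
]


@dataclass
class NSCModel:
    """Shrunken-centroid model at a single shrinkage Delta."""

    genes: pd.Index
    classes: np.ndarray
    overall_centroid: np.ndarray       # x_bar_i
    class_centroids: np.ndarray        # genes x classes, x_bar_ik
    pooled_sd: np.ndarray              # s_i
    s0: float
    m_k: np.ndarray
    priors: np.ndarray
    delta: float
    dprime: np.ndarray                 # genes x classes, shrunken differences

    @property
    def active_genes(self) -> pd.Index:
        return self.genes[(self.dprime != 0).any(axis=1)]

    @property
    def shrunken_centroids(self) -> np.ndarray:
        return (self.overall_centroid[:, None]
                + self.dprime * self.m_k[None, :]
                * (self.pooled_sd + self.s0)[:, None])


def _fit_components(X: np.ndarray, y: np.ndarray):
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    n = len(y)
    overall = X.mean(axis=1)
    cents = np.column_stack([X[:, y == c].mean(axis=1) for c in classes])
    ss = np.zeros(X.shape[0])
    for j, c in enumerate(classes):
        block = X[:, y == c]
        ss += ((block - cents[:, j][:, None]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ss / (n - len(classes)))
    if np.all(pooled_sd == 0):
        raise ValueError("zero pooled within-class SD for every gene")
    s0 = float(np.median(pooled_sd))
    m_k = np.sqrt(1.0 / counts - 1.0 / n)
    priors = counts / n
    return classes, overall, cents, pooled_sd, s0, m_k, priors


def train_nsc(expr, labels, delta_grid=(0.0,)) -> dict[float, NSCModel]:
    """Fit a shrunken-centroid model at each Delta in ``delta_grid``.

    ``expr`` is an ExpressionMatrix (or genes x samples DataFrame);
    ``labels`` maps sample -> class. Returns {Delta: NSCModel}.
    """
    values = expr.values if hasattr(expr, "values") and hasattr(expr, "genes") \
        else expr
    if isinstance(values, pd.DataFrame):
        X = values.to_numpy()
        genes = values.index
        labels = pd.Series(labels).loc[values.columns].to_numpy()
    else:
        raise TypeError("expr must be an ExpressionMatrix or DataFrame")

    classes, overall, cents, pooled_sd, s0, m_k, priors = _fit_components(X, labels)
    denom = m_k[None, :] * (pooled_sd + s0)[:, None]
    d = (cents - overall[:, None]) / denom

    models = {}
    for delta in delta_grid:
        if delta < 0:
            raise ValueError("Delta must be nonnegative")
        dprime = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
        models[float(delta)] = NSCModel(
            genes=genes, classes=classes, overall_centroid=overall,
            class_centroids=cents, pooled_sd=pooled_sd, s0=s0, m_k=m_k,
            priors=priors, delta=float(delta), dprime=dprime)
    return models


def predict(model: NSCModel, expr, return_posteriors: bool = True):
    """Classify samples with the shrunken-centroid discriminant.

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 ln prior_k,
    minimized over classes; posteriors are softmax(-delta_k / 2).
    Returns (labels Series, posteriors DataFrame).
    """
    values = expr.values if hasattr(expr, "genes") else expr
    missing = model.genes.difference(values.index)
    if len(missing):
        raise ValueError(f"model genes absent from expression: {list(missing)[:5]}")
    X = values.loc[model.genes].to_numpy()
    denom = (model.pooled_sd + model.s0)[:, None]
    shrunken = model.shrunken_centroids
    disc = np.empty((X.shape[1], len(model.classes)))
    for j in range(len(model.classes)):
        z = (X - shrunken[:, j][:, None]) / denom
        disc[:, j] = (z ** 2).sum(axis=0) - 2.0 * np.log(model.priors[j])
    labels = pd.Series(model.classes[np.argmin(disc, axis=1)],
                       index=values.columns, name="label")
    if not return_posteriors:
        return labels
    logp = -disc / 2.0
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    posteriors = pd.DataFrame(post, index=values.columns, columns=model.classes)
    return labels, posteriors


def cv_error_curve(expr, labels, delta_grid, folds: int = 10,
                   repeats: int = 100, seed: int = 0) -> pd.Series:
    """Mean misclassification rate per Delta over repeated stratified CV.

    Runs ``folds``-fold stratified cross-validation ``repeats`` times
    with fresh fold assignments each repeat; the classic protocol is
    10-fold repeated 100 times.
    """
    from sklearn.model_selection import StratifiedKFold

    values = expr.values if hasattr(expr, "genes") else expr
    y = pd.Series(labels).loc[values.columns]
    counts = y.value_counts()
    if (counts < folds).any():
        raise ValueError("every class needs at least `folds` samples")

    delta_grid = [float(d) for d in delta_grid]
    errors = np.zeros(len(delta_grid))
    total = 0
    rng = np.random.default_rng(seed)
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for train_idx, test_idx in skf.split(values.T, y):
            tr_cols = values.columns[train_idx]
            te_cols = values.columns[test_idx]
            models = train_nsc(values[tr_cols], y.loc[tr_cols], delta_grid)
            for g, delta in enumerate(delta_grid):
                pred = predict(models[delta], values[te_cols],
                               return_posteriors=False)
                errors[g] += (pred.to_numpy() != y.loc[te_cols].to_numpy()).sum()
            total += len(te_cols)
    return pd.Series(errors / total, index=delta_grid, name="cv_error")


@dataclass
class SignatureSet:
    """Per-subtype up/down signature genes plus the unassigned remainder."""

    up: dict[object, list]
    down: dict[object, list]
    unassigned: list

    def signature(self, subtype) -> list:
        return sorted(set(self.up.get(subtype, [])) | set(self.down.get(subtype, [])))

    def sizes(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.up):
            rows.append((k, len(self.up[k]), len(self.down[k]),
                         len(self.up[k]) + len(self.down[k])))
        return pd.DataFrame(rows, columns=["subtype", "up", "down", "total"])


def assign_signatures(expr, labels, alpha: float = 0.05,
                      mode: str = "each") -> SignatureSet:
    """Assign classifier genes to subtype signatures by one-tailed t-tests.

    Stage 1: a gene is "up in k" iff a one-tailed pooled-variance
    Student t-test gives p < alpha for k versus each other subtype
    (``mode='each'``; ``mode='pooled'`` tests k against all other
    samples pooled). Stage 2 applies the mirrored rule for
    down-regulation to the genes stage 1 left unassigned. Genes failing
    both remain unassigned; each gene lands in at most one subtype.
    """
    if mode not in {"each", "pooled"}:
        raise ValueError("mode must be 'each' or 'pooled'")
    values = expr.values if hasattr(expr, "genes") else expr
    y = pd.Series(labels).loc[values.columns]
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 subtypes")
    if (y.value_counts() < 2).any():
        raise ValueError("every subtype needs at least 2 samples")
    X = values.to_numpy()
    masks = {k: (y == k).to_numpy() for k in classes}

    def one_sided_p(k, alternative):
        """p-values of gene-wise tests of k against the others."""
        ps = np.ones((X.shape[0], len(classes) - 1)) \
            if mode == "each" else np.ones((X.shape[0], 1))
        if mode == "each":
            for j, other in enumerate(c for c in classes if c != k):
                res = stats.ttest_ind(X[:, masks[k]].T, X[:, masks[other]].T,
                                      equal_var=True, alternative=alternative)
                ps[:, j] = res.pvalue
        else:
            rest = ~masks[k]
            res = stats.ttest_ind(X[:, masks[k]].T, X[:, rest].T,
                                  equal_var=True, alternative=alternative)
            ps[:, 0] = res.pvalue
        return ps.max(axis=1)

    up: dict = {k: [] for k in classes}
    down: dict = {k: [] for k in classes}
    assigned = np.zeros(X.shape[0], dtype=bool)
    for k in classes:
        p = one_sided_p(k, "greater")
        hit = (p < alpha) & ~assigned
        up[k] = list(values.index[hit])
        assigned |= hit
    for k in classes:
        p = one_sided_p(k, "less")
        hit = (p < alpha) & ~assigned
        down[k] = list(values.index[hit])
        assigned |= hit
    unassigned = list(values.index[~assigned])
    return SignatureSet(up, down, unassigned)


def coherence_test(signature, background, ontology, annotations,
                   n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation test for functional coherence of a signature.

    Observed statistic: mean pairwise Resnik similarity over the
    signature genes. Null: the same statistic on ``n_perm`` random
    draws of the same size from ``background``.
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    from .coexpr import ResnikSimilarity

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    signature = sorted(set(signature))
    background = sorted(set(background))
    if len(signature) < 2:
        raise ValueError("signature needs at least 2 genes")
    if not set(signature) <= set(background):
        raise ValueError("signature must be a subset of the background")
    if len(background) < len(signature):
        raise ValueError("background smaller than the signature")

    sim = ResnikSimilarity(ontology, annotations)

    def mean_pairwise(genes):
        scores = [sim.gene_similarity(a, b)
                  for a, b in itertools.combinations(genes, 2)]
        return float(np.mean(scores))

    observed = mean_pairwise(signature)
    rng = np.random.default_rng(seed)
    count = 0
    bg = np.array(background)
    for _ in range(n_perm):
        draw = rng.choice(bg, size=len(signature), replace=False)
        if mean_pairwise(draw) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)
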