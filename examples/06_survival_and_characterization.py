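"""Characterize subtypes: survival, signature scores, cross-tabulation.

Kaplan-Meier / log-rank comparison of subtype survival, a mean-
expression signature score per sample (the EMT-signature pattern), and
the contingency-table enrichment report used to compare two labelings.
"""

import numpy as np
import pandas as pd

from crcnet.stats import crosstab_association, km_logrank, signature_score
from crcnet.synthetic import (SyntheticCohortSpec, gen_expression_cohort,
                              gen_survival)

spec = SyntheticCohortSpec(seed=1)
expr, truth = gen_expression_cohort(spec)

# subtype-dependent exponential survival (hazards per month by subtype)
surv = gen_survival(truth, censor_rate=0.3, seed=5)
res = km_logrank(surv)
print(f"log-rank test across {len(res.curves)} subtypes: "
      f"chi2 = {res.statistic:.2f} (df={res.df}), p = {res.p:.2e}")
for k, curve in sorted(res.curves.items()):
    t5 = curve[curve["timeline"] <= 60]["survival"].min()
    print(f"  subtype {k}: KM survival at 5 years = {t5:.2f}")
print("distinct hazards translate into separated KM curves and a small p")

# signature scoring: average centered expression of one planted module
module = sorted(truth.module_members)[0]
genes = sorted(truth.module_members[module])
score = signature_score(expr, genes)
by_subtype = score.groupby(truth.sample_subtype).mean()
print(f"\nmean {module} activity score by subtype:")
print(by_subtype.round(2).to_string())
print("the module's associated subtype scores highest")

# cross-tabulation of two labelings with per-cell enrichment
rng = np.random.default_rng(0)
noisy = truth.sample_subtype.copy()
flip = rng.random(len(noisy)) < 0.2
noisy[flip] = rng.integers(1, 4, size=int(flip.sum()))
out = crosstab_association(truth.sample_subtype, noisy)
diag = out[out["row"] == out["col"]]
print("\nagreement cells of truth vs a 20%-noisy relabeling:")
print(diag[["row", "col", "count", "row_pct", "fold", "fdr"]]
      .round(3).to_string(index=False))
print("diagonal cells show strong fold enrichment at small FDR")
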