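"""Build ecotypes from signature scores and test their prognostic value.

Generates a 200-sample bulk cohort whose 12 signature scores form 4
correlated blocks and whose hazard depends on the first block's score
(HR = 2 per SD).  Ecotypes are recovered by consensus partition clustering
of Z-scored, capped signature columns; their scores are then tested with
median-split Kaplan-Meier, Cox regression and a nested-model comparison
against a stage-only baseline.
"""

import numpy as np
import pandas as pd

from snatlas.ecotypes import consensus_partition, ecotype_scores, zscore_cap
from snatlas.simulate import (SimulationConfig, generate_bulk_cohort,
                              random_signature_matrix)
from snatlas.survival import compare_nested, cox_univariate, km_logrank_median

rng = np.random.default_rng(0)
sig = random_signature_matrix(200, [f"S{i}" for i in range(12)], rng)
cfg = SimulationConfig(cohort_n=200,
                       planted_log_hazard=[np.log(2), 0, 0, 0], seed=1)
cohort, truth = generate_bulk_cohort(cfg, sig)
print(f"cohort: {cohort.n_samples} samples, "
      f"{int(cohort.clinical.event_os.sum())} OS events")

z = zscore_cap(truth.signature_activity, cohort.clinical["dataset_id"])
model = consensus_partition(z, max_k=10, seed=0)
print(f"consensus partition chose k={model.k}; assignment:")
print(model.assignment.groupby(model.assignment).groups)

eco = ecotype_scores(z, model)
res = cox_univariate(cohort, eco, "os")
print("\nunivariate Cox (per SD), BH-adjusted:")
print(res.table.round(3).to_string())

prognostic = res.table.p_adj.idxmin()
km = km_logrank_median(cohort, eco[prognostic], "os")
print(f"\nmedian-split log-rank for {prognostic}: p = {km['p']:.2e} "
      f"(n high/low = {km['n']['high']}/{km['n']['low']})")

stage = pd.get_dummies(cohort.clinical["stage"], drop_first=True).astype(float)
nested = compare_nested(cohort, stage, eco[[prognostic]], "os")
print(f"stage-only C-index {nested['c_index_base']:.3f} -> "
      f"with ecotype {nested['c_index_full']:.3f}; "
      f"LRT p = {nested['lrt_p']:.2e}")
# The ecotype containing the hazard-driving block should emerge as the
# prognostic one and add concordance over the stage-only model.
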