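"""Score gene sets in bulk samples and deconvolve cell-type fractions.

Builds a single-cell reference of four microenvironment populations, forms
a pseudobulk with known composition from held-out cells (the split-
validation protocol: 1000 training cells if a population has >2000 cells,
otherwise 50%), and compares deconvolved to true fractions.  Also scores a
gene set in a bulk profile with ssGSEA.
"""

import pandas as pd

from snatlas.signatures import split_validate, ssgsea
from snatlas.simulate import SimulationConfig, generate_multi_tumor_dataset

cfg = SimulationConfig(n_tumors=2, cells_per_tumor=0, n_genes=400,
                       microenv_cells_per_tumor=1200, n_celltypes=4, seed=3)
cm, _ = generate_multi_tumor_dataset(cfg)
print("population sizes:", cm.celltype_of.value_counts().to_dict())

report = split_validate(cm, cm.celltype_of.to_numpy(), seed=0)
print("training draws per population:", report["train_sizes"])
table = pd.DataFrame({"true": report["true_proportions"],
                      "estimated": report["estimated_proportions"]})
print(table.round(3).to_string())
print(f"Pearson r(true, estimated) = {report['pearson_r']:.3f}")
# Well-separated populations deconvolve nearly perfectly (r > 0.9); the
# paper-style protocol draws exactly 1000 training cells for populations
# above 2000 cells and half otherwise.

expr = pd.Series(range(1, 21), index=[f"G{i:05d}" for i in range(20)],
                 dtype=float)
top_set = list(expr.nlargest(5).index)
bottom_set = list(expr.nsmallest(5).index)
print(f"\nssGSEA: top-ranked set {ssgsea(expr, top_set):.3f} vs "
      f"bottom-ranked set {ssgsea(expr, bottom_set):.3f}")
# A set concentrated at the top of the expression ranking scores high;
# the same-size set at the bottom scores negative.
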