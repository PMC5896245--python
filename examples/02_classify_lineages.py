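"""Classify variants into germline / potentially-somatic / tumor-unique
categories and estimate tumor purity from germline heterozygote VAFs."""

import numpy as np

from devilseq.classify import (SampleRoles, classify_table,
                               estimate_tumor_purity, summarize_categories)
from devilseq.simulate import CohortConfig, simulate_cohort

cfg = CohortConfig(n_germline=400, n_trunk=200, n_unique=200,
                   purity=0.92, seed=3)
table, truth = simulate_cohort(cfg)
roles = SampleRoles.from_config(cfg)
assignments = classify_table(table, roles)

print(summarize_categories(assignments, table["vclass"]))
# The table partitions all variants: germline sites are supported in the
# normal panel, lineage rows need >= 5 reads in both tumors of one lineage
# and no normal support, tumor-unique rows in exactly one tumor.

# purity of the first tumor from founder-heterozygous germline sites whose
# residual host cells are homozygous reference (expected VAF = purity / 2)
tumor = roles.lineage1[0]
het = truth[(truth["category"] == "germline")
            & np.isclose(truth[f"vaf:{tumor}"], cfg.purity * 0.5)]
vafs = (table.loc[het.index, f"{tumor}:fwd"]
        + table.loc[het.index, f"{tumor}:rev"]) / table.loc[het.index, f"{tumor}:depth"]
est = estimate_tumor_purity(np.asarray(vafs), min_loci=30)
print(f"\n{tumor}: estimated host fraction {est['host_fraction']:.3f} "
      f"(simulated {1 - cfg.purity:.2f}), purity {est['purity']:.3f}")
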