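"""Label structural-variant calls by read support and screen candidate
presence/absence-variation (PAV) contigs by relative coverage."""

import pandas as pd

from devilseq.classify import SampleRoles
from devilseq.screens import filter_pav_contigs, filter_sv_calls

roles = SampleRoles(lineage1=("L1T1", "L1T2"), lineage2=("L2T1", "L2T2"),
                    highcov_normals=("H1", "H2", "H3"),
                    panel_normals=("P1",))

calls = pd.DataFrame([
    {"sv_id": "sv1", **{f"support:{s}": 0 for s in roles.all_samples},
     "support:L1T1": 18, "support:L1T2": 15},                 # lineage shared
    {"sv_id": "sv2", **{f"support:{s}": 0 for s in roles.all_samples},
     "support:L2T2": 14},                                  # tumor somatic
    {"sv_id": "sv3", **{f"support:{s}": 3 for s in roles.all_samples}},
    {"sv_id": "sv4", **{f"support:{s}": 0 for s in roles.all_samples},
     "support:L1T1": 6},                                     # too few reads
])
labeled = filter_sv_calls(calls, roles)
print(labeled[["sv_id", "label"]].to_string(index=False))
# Retention needs > 10 supporting reads in total; > 2 combined normal reads
# marks a likely germline polymorphism.

pav = pd.DataFrame({
    "contig": ["candidate1", "candidate2"],
    "depth:L1T1": [40.0, 10.0], "depth:L1T2": [35.0, 8.0],
    "depth:H1": [0.5, 0.4], "depth:H2": [0.2, 0.1],
})
kept = filter_pav_contigs(pav, ["L1T1", "L1T2"], ["H1", "H2"],
                          genome_means={"L1T1": 86.0, "L1T2": 67.0,
                                        "H1": 65.0, "H2": 49.0})
print("\nPAV contigs kept:", list(kept["contig"]))
# candidate1 reaches 40% of tumor genome-wide depth while staying under 20%
# in every host - the coverage signature of tumor-exclusive DNA.
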