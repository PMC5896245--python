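"""Filter candidate CNV segments: minimum-size rule for tumor-unique
events, paired t-test between the lineage's two tumors, and posterior
pooling for shared segments."""

import pandas as pd

from devilseq.cnv import filter_cnv_segments
from devilseq.simulate import simulate_cnv_bins

spec = pd.DataFrame([
    {"start_bin": 100, "end_bin": 108, "cn": 4, "samples": ["T1"]},   # 8 bins
    {"start_bin": 300, "end_bin": 320, "cn": 4, "samples": ["T1"]},   # 20 bins
    {"start_bin": 500, "end_bin": 530, "cn": 3, "samples": ["T1", "T2"]},
])
bins = simulate_cnv_bins(spec, n_bins=800, depth=70, samples=["T1", "T2"],
                         seed=13)
segments = pd.DataFrame({
    "scaffold": "scf1",
    "start": [100 * 500, 300 * 500, 500 * 500],
    "end": [108 * 500, 320 * 500, 530 * 500],
    "tumor": "T1",
    "cn": [4, 4, 3],
})
out = filter_cnv_segments(segments, bins, tumor_pair=("T1", "T2"))
print(out[["start", "end", "cn", "status", "p_value", "pooled_cn"]]
      .to_string(index=False))
# 4 kb < the 5 kb minimum -> rejected; the 10 kb CN4 event differs between
# tumors (p << 0.01) -> retained tumor-unique; the segment present in both
# tumors is not significantly different -> pooled posterior assigns CN 3
# to both.
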