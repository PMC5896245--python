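"""Place a tumor founder genotype within population structure: impute the
SNP panel, cluster individuals, and list the tumor's nearest neighbors."""

from devilseq.popstruct import (cluster_samples, impute_missing,
                                nearest_neighbors, top_split)
from devilseq.simulate import simulate_population_panel

panel, labels = simulate_population_panel(n_individuals=60, n_snps=320,
                                          fst_like_divergence=0.8,
                                          missing_rate=0.05, seed=9)
complete = impute_missing(panel)
dendro = cluster_samples(complete, linkage="complete", metric="euclidean")
side1, side2 = top_split(dendro)
print(f"top dendrogram split: {len(side1)} vs {len(side2)} individuals")
print("tumor clusters with:", "side 1" if "tumor" in side1 else "side 2")

nn = nearest_neighbors(complete, "tumor", k=5)
nn["population"] = [labels[n] for n in nn["neighbor"]]
print(nn.round(2).to_string(index=False))
# The tumor genotype was copied from a pop0 founder, so its nearest
# neighbor sits at distance ~0 and all close neighbors are pop0 animals.
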