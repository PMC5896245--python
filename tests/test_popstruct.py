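"""SNP panel filtering, genotype coding, imputation and clustering."""

import numpy as np
import pandas as pd
import pytest

from devilseq.filters import RegionAnnotation
from devilseq.popstruct import (PanelFilterInputs, cluster_samples,
                                code_genotypes, filter_snp_panel,
                                impute_missing, nearest_neighbors, top_split)
from devilseq.simulate import simulate_population_panel


def _panel_inputs():
    ann = RegionAnnotation(
        scaffold_lengths={"s1": 100_000, "sX": 100_000, "unp": 100_000},
        chromosome_of={"s1": "1", "sX": "X"},
        repeats={"s1": np.array([[50_000, 50_100]])},
    )
    cand = pd.DataFrame([
        # snp_id, fragment, scaffold, pos, vclass, mismatches, gap_len
        ("a", "f1", "s1", 10_000, "SNP", 0, 0),    # survives
        ("b", "f1", "s1", 10_040, "SNP", 0, 0),    # same fragment, 3'
        ("c", "f2", "s1", 20_000, "indel", 0, 0),  # (i) indel
        ("d", "f3", "s1", 30_000, "SNP", 3, 0),    # (ii) ambiguous
        ("e", "f4", "sX", 40_000, "SNP", 0, 0),    # (iii) X chromosome
        ("f", "f5", "s1", 50_050, "SNP", 0, 0),    # (iii) in repeat
        ("g", "f6", "s1", 60_000, "SNP", 0, 0),    # (iv) non-diploid
        ("h", "f7", "s1", 70_000, "SNP", 0, 0),    # (v) invariant
    ], columns=["snp_id", "fragment", "scaffold", "pos", "vclass",
                "mismatches", "gap_len"])
    rng = np.random.default_rng(0)
    geno = pd.DataFrame(
        rng.choice([0.0, 0.5, 1.0], size=(40, len(cand))),
        columns=cand["snp_id"])
    geno["h"] = 0.5  # every individual identical -> variability 0
    nondip = {"s1": np.array([[59_000, 61_000]])}
    return PanelFilterInputs(cand, geno, ann, nondip)


def test_filter_cascade_counts_and_survivor():
    inputs = _panel_inputs()
    panel, excl = filter_snp_panel(inputs, keep_top_frac=0.6)
    assert excl["indel"] == 1
    assert excl["ambiguous_fragment"] == 1
    assert excl["region_or_x"] == 2
    assert excl["nondiploid"] == 1
    assert excl["low_variation"] == 1        # 'h' is the least varying
    assert excl["fragment_duplicate"] == 1   # 'b' loses to 'a' (5'-most)
    assert excl.sum() + len(panel) == len(inputs.candidates)
    assert list(panel["snp_id"]) == ["a"]


def test_filter_requires_mapping_stats():
    inputs = _panel_inputs()
    inputs.candidates.loc[0, "mismatches"] = np.nan
    with pytest.raises(ValueError):
        filter_snp_panel(inputs)


def test_genotype_coding_boundaries():
    a1 = pd.DataFrame({"s1": [4, 8, 5, 7, 0]})
    a2 = pd.DataFrame({"s1": [2, 2, 5, 3, 10]})
    codes = code_genotypes(a1, a2)["s1"]
    assert np.isnan(codes[0])                 # 6 reads < 7 -> missing
    assert codes[1] == 0.0                    # 80% allele 1 -> hom 1/1
    assert codes[2] == 0.5                    # 50% -> het
    assert codes[3] == 0.5                    # exactly 70% -> het (strict rule)
    assert codes[4] == 1.0                    # 0% allele 1 -> hom 2/2
    with pytest.raises(ValueError):
        code_genotypes(a1 - 5, a2)


def test_imputation_hand_cases():
    panel = pd.DataFrame({
        "s1": [0.0, 0.5, 1.0, 0.0],
        "s2": [0.0, 0.5, 1.0, np.nan],   # duplicate of s1 with a hole
        "s3": [1.0, 0.0, 0.5, 1.0],
    }, index=list("abcd"))
    out = impute_missing(panel)
    assert out.loc["d", "s2"] == 0.0          # adopted from s1 (distance 0)
    # observed cells untouched
    mask = panel.notna()
    changed = (out != panel) & mask
    assert not changed.any().any()
    complete = impute_missing(out)
    pd.testing.assert_frame_equal(complete, out)  # idempotent when complete
    with pytest.raises(ValueError):
        impute_missing(panel[["s1"]])


def test_imputation_picks_nearest_by_euclidean():
    panel = pd.DataFrame({
        "q": [0.0, 0.0, 1.0, np.nan],
        "near": [0.0, 0.0, 1.0, 0.5],     # distance 0 on shared rows
        "far": [1.0, 1.0, 0.0, 1.0],      # distance sqrt(3)
    })
    out = impute_missing(panel)
    assert out.loc[3, "q"] == 0.5


def test_clustering_recovers_populations_and_newick():
    panel, labels = simulate_population_panel(40, 120, fst_like_divergence=0.8,
                                              missing_rate=0.0, seed=1)
    dg = cluster_samples(panel)
    side1, side2 = top_split(dg)
    pops = {name: lab.replace("tumor(", "").rstrip(")") for name, lab in labels.items()}
    purity = max(
        np.mean([pops[n] == "pop0" for n in side1]),
        np.mean([pops[n] == "pop0" for n in side2]),
    )
    assert purity == 1.0
    nwk = dg.to_newick()
    assert nwk.endswith(";") and "tumor" in nwk
    # identical rows merge at height zero
    dup = pd.DataFrame([[0.0, 1.0], [0.0, 1.0], [1.0, 0.0]], index=list("xyz"))
    Z = cluster_samples(dup).linkage
    assert Z[0, 2] == 0.0
    with pytest.raises(ValueError):
        cluster_samples(dup.iloc[:1])


def test_clustering_invariant_to_feature_permutation():
    panel, _ = simulate_population_panel(20, 60, seed=2)
    rng = np.random.default_rng(3)
    shuffled = panel[rng.permutation(panel.columns)]
    Z1 = cluster_samples(panel).linkage
    Z2 = cluster_samples(shuffled).linkage
    assert np.allclose(Z1[:, 2], Z2[:, 2])
    assert np.all(np.diff(Z1[:, 2]) >= -1e-12)  # merge heights non-decreasing


def test_nearest_neighbors_contract():
    panel, labels = simulate_population_panel(30, 80, seed=4)
    nn = nearest_neighbors(panel, "tumor", 3)
    assert nn.loc[0, "neighbor"] == "ind1" and nn.loc[0, "distance"] == 0.0
    src = [labels[n] for n in nn["neighbor"]]
    assert all(s == "pop0" for s in src)
    full = nearest_neighbors(panel, "tumor", len(panel) - 1)
    assert len(full) == len(panel) - 1
    with pytest.raises(ValueError):
        nearest_neighbors(panel, "tumor", len(panel))
    with pytest.raises(KeyError):
        nearest_neighbors(panel, "nope", 2)
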