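"""Variant post-filters: boundary conventions, planted-artifact removal,
idempotence and order independence."""

import numpy as np
import pandas as pd
import pytest

from devilseq.filters import (RegionAnnotation, apply_all_filters, compute_vaf,
                              filter_noise, filter_reference_artifacts,
                              filter_regions, filter_strand_bias,
                              read_support_table, write_support_table)
from devilseq.simulate import CohortConfig, simulate_cohort, simulate_regions


def make_table(rows):
    """rows: list of dicts sample -> (fwd, rev, depth)."""
    recs = []
    for i, r in enumerate(rows):
        rec = {"scaffold": "scf1", "chromosome": "1", "pos": 5000 + i,
               "ref": "C", "alt": "T", "vclass": "SNV"}
        for s, (f, v, d) in r.items():
            rec[f"{s}:fwd"], rec[f"{s}:rev"], rec[f"{s}:depth"] = f, v, d
        recs.append(rec)
    return pd.DataFrame(recs)


def test_vaf_definition_and_errors():
    t = make_table([{"A": (3, 2, 10), "B": (0, 0, 20)},
                    {"A": (0, 0, 0), "B": (1, 1, 4)}])
    vaf = compute_vaf(t)
    assert vaf.loc[0, "A"] == 0.5 and vaf.loc[0, "B"] == 0.0
    assert np.isnan(vaf.loc[1, "A"]) and vaf.loc[1, "B"] == 0.5
    bad = make_table([{"A": (5, 3, 4)}])
    with pytest.raises(ValueError):
        compute_vaf(bad)


def test_reference_artifact_threshold_is_strict():
    t = make_table([
        {"R": (19, 0, 20)},   # VAF 0.95 -> dropped
        {"R": (9, 9, 20)},    # VAF 0.90 exactly -> kept
        {"R": (0, 0, 20)},    # VAF 0 -> kept
    ])
    out = filter_reference_artifacts(t, "R")
    assert list(out.index) == [1, 2]
    with pytest.raises(KeyError):
        filter_reference_artifacts(t, "nope")


def test_strand_bias_pooled_rules():
    t = make_table([
        {"A": (10, 10, 100)},          # balanced, high coverage -> kept
        {"A": (19, 1, 50)},            # 5% reverse -> dropped
        {"A": (1, 3, 8)},              # low coverage, 1 fwd < 2 -> dropped
        {"A": (2, 2, 8)},              # low coverage, 2 on each -> kept
        {"A": (2, 8, 100)},            # exactly 20% forward: tie kept
        {"A": (0, 0, 100)},            # no support anywhere -> kept
    ])
    out = filter_strand_bias(t)
    assert list(out.index) == [0, 3, 4, 5]


def test_strand_bias_pools_across_samples():
    # individually skewed but balanced in the pool -> kept
    t = make_table([{"A": (10, 0, 60), "B": (0, 10, 60)}])
    assert len(filter_strand_bias(t)) == 1


def test_noise_rule_requires_host_support():
    t = make_table([
        {"T": (5, 5, 20), "H": (1, 0, 20)},   # tumor VAF 0.5 -> kept
        {"T": (1, 0, 20), "H": (1, 0, 20)},   # all supported < 0.2, host hit -> dropped
        {"T": (1, 0, 20), "H": (0, 0, 20)},   # no host support -> kept
    ])
    out = filter_noise(t, host_samples=["H"])
    assert list(out.index) == [0, 2]
    with pytest.raises(ValueError):
        filter_noise(t, host_samples=[])


def test_region_windows_and_unassigned_scaffolds():
    ann = RegionAnnotation(
        scaffold_lengths={"scf1": 100_000, "unp": 100_000},
        chromosome_of={"scf1": "1"},
        repeats={"scf1": np.array([[10_000, 10_050]])},
        contig_bounds={"scf1": np.array([50_000])},
    )
    t = make_table([{"A": (5, 5, 20)} for _ in range(6)])
    t["pos"] = [9_998, 10_060, 50_400, 50_501, 500, 99_500]
    t.loc[5, "scaffold"] = "unp"
    out = filter_regions(t, ann)
    # 9998 within 5 bp of the repeat (1-based 10001..10050) -> dropped
    # 10060 is 10 bp past the repeat end -> kept
    # 50400 within 500 of a contig bound -> dropped; 50501 (501 away) kept
    # 500 within 1000 of scaffold start -> dropped
    # 99500 within 1000 of scaffold end -> dropped; unplaced scaffold -> dropped
    assert list(out.index) == [1, 3]
    t.loc[0, "pos"] = 200_000
    with pytest.raises(ValueError):
        filter_regions(t, ann)


def test_each_filter_removes_exactly_its_planted_class():
    cfg = CohortConfig(n_germline=0, n_trunk=60, n_unique=0, n_lowcov_normals=5,
                       n_ref_artifacts=15, n_strand_artifacts=15,
                       n_noise_artifacts=15, n_repeat_artifacts=15, seed=21)
    table, truth = simulate_cohort(cfg)
    ann = simulate_regions(cfg)
    clean = truth["category"] != "artifact"

    # a planted site whose *sampled* reads no longer satisfy a filter's
    # predicate (e.g. a low-coverage normal drawing 2/10 noise reads, VAF
    # 0.2) is correctly kept, so removal of the planted class is near- but
    # not necessarily fully complete; clean variants must never be touched.
    for fn, planted, min_removed in [
        (lambda t: filter_reference_artifacts(t, cfg.reference_sample),
         "ref_artifact", 15),
        (filter_strand_bias, "strand_artifact", 15),
        (lambda t: filter_noise(t, list(cfg.highcov_normals)),
         "noise_artifact", 9),
    ]:
        out = fn(table)
        removed = truth.loc[table.index.difference(out.index), "tumor"]
        assert (removed == planted).all(), f"{planted}: removed {set(removed)}"
        assert (removed == planted).sum() >= min_removed
        assert clean[out.index].sum() == clean.sum()

    out = filter_regions(table, ann)
    removed = truth.loc[table.index.difference(out.index), "tumor"]
    assert (removed == "repeat_artifact").all() and len(removed) == 15


def test_filters_idempotent_and_order_independent():
    cfg = CohortConfig(n_germline=40, n_trunk=30, n_unique=30, n_lowcov_normals=5,
                       n_ref_artifacts=8, n_strand_artifacts=8,
                       n_noise_artifacts=8, seed=22)
    table, _ = simulate_cohort(cfg)
    hosts = list(cfg.highcov_normals)
    f1 = lambda t: filter_reference_artifacts(t, cfg.reference_sample)
    f2 = filter_strand_bias
    f3 = lambda t: filter_noise(t, hosts)
    for f in (f1, f2, f3):
        once = f(table)
        pd.testing.assert_frame_equal(f(once), once)
    ab = f2(f1(table))
    ba = f1(f2(table))
    assert list(ab.index) == list(ba.index)


def test_apply_all_filters_logs_removals():
    cfg = CohortConfig(n_germline=20, n_trunk=20, n_unique=0, n_lowcov_normals=3,
                       n_noise_artifacts=5, seed=23)
    table, _ = simulate_cohort(cfg)
    log = []
    out = apply_all_filters(table, cfg.reference_sample,
                            list(cfg.highcov_normals),
                            annotation=simulate_regions(cfg), log=log)
    assert len(out) + len(log) == len(table)
    assert all(name in {"reference_artifact", "strand_bias", "noise", "regions"}
               for _, name in log)


def test_tsv_roundtrip(tmp_path, small_cohort):
    _, table, _, _ = small_cohort
    p = tmp_path / "t.tsv"
    write_support_table(table, str(p))
    back = read_support_table(str(p))
    pd.testing.assert_frame_equal(back, table.reset_index(drop=True))
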