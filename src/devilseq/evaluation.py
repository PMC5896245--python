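"""End-to-end recovery studies on synthetic cohorts.

Each function here runs one pipeline stage on freshly simulated data with
known truth and measures how well the truth is recovered: signature-weight
recovery and credible-interval coverage, MCMC-versus-grid agreement,
stepwise-selection specificity, variant-classification accuracy, validation
calibration and power, junction-classifier agreement with a brute-force
oracle, purity recovery, population-split purity, and CNV filtering
behavior. They are the package's own benchmark suite; the study sizes are
chosen to be decisive yet quick (seconds to a couple of minutes each).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, cnv, popstruct, screens, signatures, simulate, validation

__all__ = [
    "signature_recovery",
    "gibbs_vs_grid",
    "delta_selection_specificity",
    "classification_recovery",
    "validation_calibration",
    "junction_oracle_agreement",
    "purity_recovery",
    "population_recovery",
    "cnv_filtering_study",
]


def _subseeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

def signature_recovery(seed: int = 0, n_seeds: int = 20, n_mutations: int = 10_000,
                       weights=(0.7, 0.3), ids=(1, 5),
                       n_samples: int = 10_000) -> dict:
    """Simulate spectra from a two-signature mixture and refit.

    Returns the worst absolute error of the posterior-mean weights across
    replicates and the fraction of replicates whose 95% credible interval
    covers the true weights.
    """
    S = signatures.synthetic_signature_matrix().loc[list(ids)]
    truth = np.asarray(weights, dtype=float)
    errors, covered = [], []
    for s in _subseeds(seed, n_seeds):
        M = simulate.simulate_mutation_spectrum(truth, S, n_mutations, seed=int(s))
        fit = signatures.fit_mixture(M, S, n_samples=n_samples, seed=int(s))
        errors.append(np.abs(fit.mean - truth).max())
        covered.append(bool(np.all((fit.ci_low <= truth) & (truth <= fit.ci_high))))
    return {"max_abs_error": float(np.max(errors)),
            "coverage_fraction": float(np.mean(covered)),
            "n_seeds": n_seeds, "n_mutations": n_mutations}


def gibbs_vs_grid(seed: int = 0, n_mutations: int = 500,
                  n_samples: int = 10_000) -> dict:
    """Posterior mean from the Gibbs sampler versus direct grid summation."""
    S = signatures.synthetic_signature_matrix().loc[[1, 5]]
    s1, s2 = _subseeds(seed, 2)
    M = simulate.simulate_mutation_spectrum([0.7, 0.3], S, n_mutations, seed=int(s1))
    fit = signatures.fit_mixture(M, S, n_samples=n_samples, seed=int(s2))
    grid = signatures.grid_posterior_mean_k2(M, S)
    return {"max_abs_diff": float(np.abs(fit.mean - grid).max()),
            "n_mutations": n_mutations}


def delta_selection_specificity(seed: int = 0, n_seeds: int = 20,
                                n_mutations: int = 600,
                                n_samples: int = 5_000) -> dict:
    """False-positive behavior of stepwise signature selection.

    Spectra are simulated from the base pair of signatures alone at the
    scale of a small tumor-unique mutation set; a well-calibrated selection
    should accept no extra candidate in the majority of replicates.
    """
    S_all = signatures.synthetic_signature_matrix()
    base = [1, 5]
    any_accepted = []
    for s in _subseeds(seed, n_seeds):
        M = simulate.simulate_mutation_spectrum([0.7, 0.3], S_all.loc[base],
                                                n_mutations, seed=int(s))
        report = signatures.select_signatures(M, S_all, base_ids=base,
                                              n_samples=n_samples, seed=int(s))
        any_accepted.append(bool(report["accepted"].any()))
    return {"seed_fraction_with_false_accept": float(np.mean(any_accepted)),
            "n_seeds": n_seeds, "n_mutations": n_mutations}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

_EXPECTED = {
    "germline": lambda r: "germline",
    "trunk_somatic": lambda r: f"lin{r['lineage']}_potentially_somatic",
    "unique_somatic": lambda r: f"tumor_unique:{r['tumor']}",
}


def classification_recovery(seed: int = 0, n_germline: int = 800,
                            n_trunk: int = 500, n_unique: int = 500) -> dict:
    """Classify a full synthetic cohort against its truth table.

    Accuracy is measured over threshold-satisfying variants: those whose
    sampled read support meets their own category's defining thresholds
    (e.g. a trunk variant that happened to draw < 5 reads in one tumor
    cannot be recovered by any threshold rule and is excluded).
    """
    cfg = simulate.CohortConfig(n_germline=n_germline, n_trunk=n_trunk,
                                n_unique=n_unique, mean_depth=70.0,
                                purity=1.0, seed=seed)
    table, truth = simulate.simulate_cohort(cfg)
    roles = classify.SampleRoles.from_config(cfg)
    assigned = classify.classify_table(table, roles)
    reads = {s: classify.variant_reads(table, s).to_numpy()
             for s in roles.all_samples}

    def eligible(i, r):
        if r["category"] == "germline":
            return (any(reads[s][i] >= 5 for s in roles.highcov_normals)
                    or any(reads[s][i] >= 1 for s in roles.panel_normals))
        if r["category"] == "trunk_somatic":
            tums = roles.lineage1 if r["lineage"] == 1 else roles.lineage2
            return all(reads[t][i] >= 5 for t in tums)
        if r["category"] == "unique_somatic":
            return reads[r["tumor"]][i] >= 5
        return False

    mask = np.array([eligible(i, r) for i, r in truth.iterrows()])
    expect = np.array([_EXPECTED[r["category"]](r) for _, r in truth.iterrows()])
    acc = float((assigned.to_numpy()[mask] == expect[mask]).mean())
    summary = classify.summarize_categories(assigned, table["vclass"])
    return {"accuracy": acc, "n_eligible": int(mask.sum()),
            "n_variants": len(table),
            "partition_exact": bool(summary["total"].sum() == len(table))}


def purity_recovery(seed: int = 0, host_fractions=(0.0, 0.05, 0.10, 0.20),
                    n_loci: int = 1000, depth: float = 70.0) -> dict:
    """Recover planted host-DNA fractions from founder-het germline VAFs."""
    rng = np.random.default_rng(seed)
    errors = {}
    for h in host_fractions:
        depths = rng.poisson(depth, size=n_loci)
        depths = np.maximum(depths, 1)
        reads = rng.binomial(depths, (1 - h) / 2)
        est = classify.estimate_tumor_purity(reads / depths)
        errors[h] = abs(est["host_fraction"] - h)
    return {"max_abs_error": float(max(errors.values())),
            "per_fraction": {str(k): float(v) for k, v in errors.items()},
            "n_loci": n_loci}


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validation_calibration(seed: int = 0, n_null: int = 1000,
                           n_true: int = 200, depth: int = 70_000) -> dict:
    """Type-I error on null loci and power at the expected minimum VAF."""
    s1, s2 = _subseeds(seed, 2)
    null = simulate.simulate_amplicon_experiment(n_null, depth=depth,
                                                 true_vaf=0.0, seed=int(s1))
    model = validation.fit_background_model(null)
    null_rate = float(validation.validate_alleles(null, model)["validated"].mean())
    true = simulate.simulate_amplicon_experiment(n_true, depth=depth,
                                                 true_vaf=0.25, seed=int(s2))
    tmodel = validation.fit_background_model(true)
    power = float(validation.validate_alleles(true, tmodel)["validated"].mean())
    return {"null_rate": null_rate, "power": power,
            "n_null": n_null, "n_true": n_true}


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------

def _oracle_junction(contig: str, refA: str, refB: str) -> tuple[str, int]:
    """Linear-scan brute force over every prefix/suffix split."""
    e_a = max(x for x in range(len(contig) + 1) if contig[:x] in refA)
    s_b = min(y for y in range(len(contig) + 1) if contig[y:] in refB)
    k = e_a - s_b
    if k > 0:
        return "microhomology", k
    if k < 0:
        return "insertion", -k
    return "blunt", 0


def junction_oracle_agreement(seed: int = 0, n: int = 1000,
                              max_len: int = 20) -> dict:
    """Classifier versus brute-force oracle on simulated junctions spanning
    homology and insertion lengths 0..``max_len``."""
    jx = simulate.simulate_junctions(n, (0, max_len), (0, max_len), seed=seed)
    res = screens.classify_junction_table(jx)
    agree_oracle = agree_truth = 0
    for _, row in res.iterrows():
        okind, olen = _oracle_junction(row["contig"], row["refA"], row["refB"])
        agree_oracle += (row["kind"], row["length"]) == (okind, olen)
        agree_truth += (row["kind"], row["length"]) == (row["true_class"],
                                                        row["true_length"])
    return {"oracle_agreement": agree_oracle / n,
            "truth_agreement": agree_truth / n, "n": n}


# ---------------------------------------------------------------------------
# population structure
# ---------------------------------------------------------------------------

def population_recovery(seed: int = 0, n_individuals: int = 60,
                        n_snps: int = 320, divergence: float = 0.8,
                        missing_rate: float = 0.05, k: int = 5) -> dict:
    """Two-population panel: impute, cluster, and place the tumor genotype."""
    panel, labels = simulate.simulate_population_panel(
        n_individuals, n_snps, fst_like_divergence=divergence,
        missing_rate=missing_rate, seed=seed)
    complete = popstruct.impute_missing(panel) if panel.isna().any().any() else panel
    dg = popstruct.cluster_samples(complete)
    side1, side2 = popstruct.top_split(dg)
    pop_of = {n: ("pop0" if lab in ("pop0", "tumor(pop0)") else "pop1")
              for n, lab in labels.items()}
    purity = max(
        min(np.mean([pop_of[n] == "pop0" for n in side]),
            np.mean([pop_of[n] == "pop1" for n in other]))
        for side, other in [(side1, side2), (side2, side1)]
    )
    nn = popstruct.nearest_neighbors(complete, "tumor", k)
    neighbor_frac = float(np.mean([labels[n] == "pop0" for n in nn["neighbor"]]))
    return {"split_purity": float(purity),
            "tumor_neighbor_source_fraction": neighbor_frac,
            "n_individuals": n_individuals}


# ---------------------------------------------------------------------------
# CNV
# ---------------------------------------------------------------------------

def cnv_filtering_study(seed: int = 0, n_reps: int = 30, depth: float = 70.0,
                        shared_cn: int = 3) -> dict:
    """Replicated CNV filtering: an 8-bin tumor-unique candidate (must be
    size-rejected), a 20-bin CN4 tumor-unique event (should be retained by
    the paired t-test), and a shared segment with identical counts in both
    tumors (must pool to the true copy number)."""
    small_rejected, unique_retained, shared_ok = [], [], []
    for s in _subseeds(seed, n_reps):
        spec = pd.DataFrame([
            {"start_bin": 100, "end_bin": 108, "cn": 4, "samples": ["T1"]},
            {"start_bin": 300, "end_bin": 320, "cn": 4, "samples": ["T1"]},
            {"start_bin": 500, "end_bin": 525, "cn": shared_cn, "samples": ["T1"]},
        ])
        bins = simulate.simulate_cnv_bins(spec, n_bins=700, depth=depth,
                                          samples=["T1", "T2"], seed=int(s))
        sel = (bins["start"] >= 500 * 500) & (bins["end"] <= 525 * 500)
        bins.loc[sel, "T2"] = bins.loc[sel, "T1"]
        segments = pd.DataFrame({
            "scaffold": "scf1",
            "start": [100 * 500, 300 * 500, 500 * 500],
            "end": [108 * 500, 320 * 500, 525 * 500],
            "tumor": "T1", "cn": [4, 4, shared_cn],
        })
        out = cnv.filter_cnv_segments(segments, bins, ("T1", "T2"))
        small_rejected.append(out["status"].iloc[0] == "rejected_min_size")
        unique_retained.append(out["status"].iloc[1] == "tumor_unique")
        shared_ok.append(out["status"].iloc[2] == "shared"
                         and out["pooled_cn"].iloc[2] == shared_cn)
    return {"small_rejected_fraction": float(np.mean(small_rejected)),
            "unique_retained_fraction": float(np.mean(unique_retained)),
            "shared_pooled_correct_fraction": float(np.mean(shared_ok)),
            "n_reps": n_reps}
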