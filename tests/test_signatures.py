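"""Spectrum construction, triplet normalization, mixture posterior, and
stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from devilseq.signatures import (CHANNELS_96, TRIPLETS_32, build_spectrum,
                                 cosine_similarity, fit_mixture,
                                 grid_posterior_mean_k2, normalize_by_triplets,
                                 read_signature_matrix, read_spectrum,
                                 reconstruct_spectrum, select_signatures,
                                 synthetic_signature_matrix, write_signature_matrix,
                                 write_spectrum)
from devilseq.simulate import simulate_mutation_spectrum


def test_channel_order_convention():
    assert len(CHANNELS_96) == 96 and len(set(CHANNELS_96)) == 96
    assert CHANNELS_96[0] == "A[C>A]A"
    assert CHANNELS_96[16] == "A[C>G]A"
    assert CHANNELS_96[-1] == "T[T>G]T"
    assert len(TRIPLETS_32) == 32


def test_build_spectrum_reverse_complements_purines():
    snvs = pd.DataFrame([
        {"ref": "G", "alt": "T", "context": "AGC"},  # -> G[C>A]T
        {"ref": "C", "alt": "T", "context": "ACG"},  # stays A[C>T]G
        {"ref": "C", "alt": "T", "context": "NCG"},  # ambiguous -> excluded
    ])
    s = build_spectrum(snvs)
    assert s["G[C>A]T"] == 1 and s["A[C>T]G"] == 1
    assert s.sum() == 2 and s.attrs["n_excluded"] == 1
    empty = build_spectrum(snvs.iloc[:0])
    assert empty.sum() == 0


def test_triplet_normalization_toy_arithmetic():
    uniform = {t: 10.0 for t in TRIPLETS_32}
    spec = pd.Series(np.arange(96, dtype=float), index=CHANNELS_96)
    out = normalize_by_triplets(spec, uniform)
    assert np.allclose(out, 100 * spec / spec.sum())
    assert out.sum() == pytest.approx(100.0)
    # doubling one triplet's frequency halves its channels pre-rescale
    skew = dict(uniform)
    skew["ACA"] = 20.0
    spec1 = pd.Series(1.0, index=CHANNELS_96)
    out2 = normalize_by_triplets(spec1, skew)
    aca = [c for c in CHANNELS_96 if c[0] == "A" and c[2] == "C" and c[6] == "A"]
    rest = [c for c in CHANNELS_96 if c not in aca]
    assert np.allclose(out2[aca].to_numpy() * 2, out2[rest[0]])
    with pytest.raises(ValueError):
        normalize_by_triplets(spec, {t: 0.0 for t in TRIPLETS_32})


def test_normalization_round_trip():
    rng = np.random.default_rng(0)
    freqs = pd.Series(rng.uniform(1, 5, 32), index=TRIPLETS_32)
    spec = pd.Series(rng.integers(1, 50, 96).astype(float), index=CHANNELS_96)
    once = normalize_by_triplets(spec, freqs)
    back = normalize_by_triplets(once, 1 / freqs)
    assert np.allclose(back, 100 * spec / spec.sum())


def test_single_signature_posterior_is_degenerate(sigmatrix):
    M = simulate_mutation_spectrum([1.0], sigmatrix.iloc[[0]], 500, seed=0)
    fit = fit_mixture(M, sigmatrix.iloc[[0]], n_samples=100)
    assert fit.mean[0] == 1.0 and fit.ci_low[0] == fit.ci_high[0] == 1.0


def test_fit_requires_integer_counts(sigmatrix):
    with pytest.raises(ValueError):
        fit_mixture(np.full(96, 0.5), sigmatrix.iloc[:2])


def test_posterior_matches_grid_oracle(sigmatrix):
    S = sigmatrix.loc[[1, 5]]
    M = simulate_mutation_spectrum([0.6, 0.4], S, 500, seed=10)
    fit = fit_mixture(M, S, n_samples=10_000, seed=1)
    grid = grid_posterior_mean_k2(M, S)
    assert np.abs(fit.mean - grid).max() < 0.005


def test_identical_signatures_not_identified_but_sum_recovered(sigmatrix):
    row = sigmatrix.iloc[[0]]
    S = pd.concat([row, row]).set_index(pd.Index([1, 2]))
    M = simulate_mutation_spectrum([1.0], row, 1000, seed=2)
    fit = fit_mixture(M, S, n_samples=8000, seed=3)
    diff = fit.samples[:, 0] - fit.samples[:, 1]
    assert abs(diff.mean()) < 0.1          # centered at 0 by symmetry
    assert np.allclose(fit.samples.sum(axis=1), 1)


def test_weight_samples_stay_on_simplex(sigmatrix):
    M = simulate_mutation_spectrum([0.5, 0.3, 0.2], sigmatrix.iloc[:3], 800, seed=4)
    fit = fit_mixture(M, sigmatrix.iloc[:3], n_samples=2000, seed=5)
    assert np.all(fit.samples >= 0)
    assert np.allclose(fit.samples.sum(axis=1), 1)
    assert fit.theta.sum() == pytest.approx(1.0)


def test_reconstruction_and_cosine_closed_forms(sigmatrix):
    S = sigmatrix.iloc[:2]
    assert np.allclose(reconstruct_spectrum([1, 0], S), S.iloc[0])
    a = np.zeros(96); a[0] = a[1] = 1
    b = np.zeros(96); b[0] = 1
    assert cosine_similarity(a, a) == pytest.approx(1.0)
    assert cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2))
    disjoint = np.zeros(96); disjoint[5] = 1
    assert cosine_similarity(b, disjoint) == 0.0
    with pytest.raises(ValueError):
        cosine_similarity(np.zeros(96), b)
    with pytest.raises(ValueError):
        reconstruct_spectrum([0.6, 0.6], S)


def test_nested_fit_cosine_monotone(sigmatrix):
    M = simulate_mutation_spectrum([0.7, 0.3], sigmatrix.loc[[1, 5]], 2000, seed=6)
    target = M / M.sum()
    f2 = fit_mixture(M, sigmatrix.loc[[1, 5]], n_samples=4000, seed=7)
    f3 = fit_mixture(M, sigmatrix.loc[[1, 5, 2]], n_samples=4000, seed=7)
    assert cosine_similarity(target, f3.theta) >= \
        cosine_similarity(target, f2.theta) - 0.01


def test_selection_accepts_true_extra_and_respects_delta(sigmatrix):
    M = simulate_mutation_spectrum([0.45, 0.25, 0.3], sigmatrix.loc[[1, 5, 7]],
                                   10_000, seed=8)
    report = select_signatures(M, sigmatrix, base_ids=[1, 5],
                               n_samples=3000, seed=9)
    row7 = report.set_index("candidate").loc[7]
    assert row7["accepted"] and row7["delta"] >= 0.02
    inf_report = select_signatures(M, sigmatrix, base_ids=[1, 5],
                                   delta_min=np.inf, n_samples=500, seed=9)
    assert not inf_report["accepted"].any()
    with pytest.raises(ValueError):
        select_signatures(M, sigmatrix, base_ids=[])


def test_signature_io_roundtrip(tmp_path, sigmatrix):
    p = tmp_path / "sigs.tsv"
    write_signature_matrix(sigmatrix, str(p))
    back = read_signature_matrix(str(p))
    assert np.allclose(back.to_numpy(), sigmatrix.to_numpy())
    # catalog-style layout
    cat = pd.DataFrame({
        "Substitution Type": [c[2:5] for c in CHANNELS_96],
        "Trinucleotide": [c[0] + c[2] + c[6] for c in CHANNELS_96],
        "Signature 1": sigmatrix.iloc[0].to_numpy(),
    })
    p2 = tmp_path / "catalog.tsv"
    cat.to_csv(p2, sep="\t", index=False)
    back2 = read_signature_matrix(str(p2))
    assert np.allclose(back2.loc["Signature 1"].to_numpy(),
                       sigmatrix.iloc[0].to_numpy())
    spec = pd.Series(np.arange(96.0), index=CHANNELS_96)
    p3 = tmp_path / "spec.tsv"
    write_spectrum(spec, str(p3))
    assert np.allclose(read_spectrum(str(p3)), spec)


def test_synthetic_matrix_is_deterministic_and_stochastic_rows():
    A = synthetic_signature_matrix()
    B = synthetic_signature_matrix()
    assert np.allclose(A, B)
    assert np.allclose(A.sum(axis=1), 1)
    assert (A.to_numpy() >= 0).all()
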