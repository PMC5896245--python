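"""Mutational-spectrum construction and Bayesian signature refitting.

A mutational spectrum is the vector of single-nucleotide variant counts over
96 categories: the six pyrimidine-context substitution types (C>A, C>G, C>T,
T>A, T>C, T>G) crossed with the 16 combinations of immediate 5' and 3'
flanking bases, in the standard catalog ordering. Refitting estimates how a
fixed set of reference signatures mixes to reconstruct an observed spectrum:

    W ~ Dirichlet(1)        prior on mixture weights (uniform on the simplex)
    theta = W S             mixture multinomial probabilities
    M ~ Multinomial(theta)  likelihood of the 96 observed counts

where S is the K x 96 signature matrix. Posterior sampling uses a
data-augmentation Gibbs sampler that is exact for this model: given W, the
latent per-category signature attributions are multinomial; given the
attributions, W is Dirichlet. Spectra and signatures can be normalized by
genome trinucleotide frequencies so that spectra from genomes with different
base composition (or different species) are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS_96",
    "TRIPLETS_32",
    "channel_to_mutation",
    "build_spectrum",
    "normalize_by_triplets",
    "MixtureFit",
    "fit_mixture",
    "reconstruct_spectrum",
    "cosine_similarity",
    "select_signatures",
    "grid_posterior_mean_k2",
    "synthetic_signature_matrix",
    "read_signature_matrix",
    "write_spectrum",
    "read_spectrum",
]

_COMP = str.maketrans("ACGT", "TGCA")
_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

#: The 96 mutation categories in catalog order: substitution type major,
#: then 5' base, then 3' base (A, C, G, T).
CHANNELS_96: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in _SUBS
    for five in "ACGT"
    for three in "ACGT"
]

#: The 32 pyrimidine-centered trinucleotides, in the order induced by the
#: channel list (C-centered first).
TRIPLETS_32: list[str] = sorted(
    {f"{c[0]}{c[2]}{c[6]}" for c in CHANNELS_96},
    key=lambda t: (t[1], t[0], t[2]),
)

_CHANNEL_TRIPLET = np.array([f"{c[0]}{c[2]}{c[6]}" for c in CHANNELS_96])


def channel_to_mutation(channel: str) -> tuple[str, str, str]:
    """Decompose ``"A[C>T]G"`` into (ref, alt, trinucleotide context)."""
    return channel[2], channel[4], channel[0] + channel[2] + channel[6]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# spectrum construction
# ---------------------------------------------------------------------------

def build_spectrum(snvs: pd.DataFrame, genome=None) -> pd.Series:
    """Count SNVs into the 96 channels.

    ``snvs`` needs columns ``ref`` and ``alt`` plus either a ``context``
    column (trinucleotide with the mutated base in the middle) or ``scaffold``
    and ``pos`` with ``genome`` a mapping of scaffold -> sequence (e.g. a
    :class:`pyfaidx.Fasta`). Purine-reference mutations are reverse-
    complemented into pyrimidine context. Mutations whose context contains an
    ambiguous base are excluded; their number is attached as
    ``spectrum.attrs["n_excluded"]``.
    """
    counts = pd.Series(0, index=pd.Index(CHANNELS_96, name="channel"), name="count")
    excluded = 0
    for _, row in snvs.iterrows():
        ref, alt = str(row["ref"]).upper(), str(row["alt"]).upper()
        if "context" in snvs.columns:
            ctx = str(row["context"]).upper()
        else:
            seq = genome[row["scaffold"]]
            pos = int(row["pos"])  # 1-based
            ctx = str(seq[pos - 2:pos + 1]).upper()
        if len(ctx) != 3 or ctx[1] != ref or any(b not in "ACGT" for b in ctx + alt):
            excluded += 1
            continue
        if ref in "AG":  # purine reference: flip to pyrimidine strand
            ctx, ref, alt = _revcomp(ctx), _revcomp(ref), _revcomp(alt)
        counts[f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"] += 1
    counts.attrs["n_excluded"] = excluded
    return counts


def normalize_by_triplets(spectrum, triplet_freqs) -> pd.Series | pd.DataFrame:
    """Divide each channel by its trinucleotide's genome frequency, then
    rescale to sum to 100%.

    ``triplet_freqs`` maps each of the 32 pyrimidine-context triplets to a
    positive count or frequency. Accepts a 96-vector (Series) or a K x 96
    signature matrix (DataFrame, normalized row-wise). Dividing an
    observed spectrum by the frequencies of its own genome — or a reference
    signature by those of the genome it was derived from — yields a
    composition-agnostic spectrum.
    """
    tf = pd.Series(triplet_freqs)
    if len(tf) != 32 or (tf <= 0).any():
        raise ValueError("need positive frequencies for all 32 triplets")
    divisor = tf.reindex(_CHANNEL_TRIPLET).to_numpy(dtype=float)
    if np.isnan(divisor).any():
        raise ValueError("triplet frequencies missing some contexts")
    if isinstance(spectrum, pd.DataFrame):
        vals = spectrum.to_numpy(dtype=float) / divisor
        vals = 100.0 * vals / vals.sum(axis=1, keepdims=True)
        return pd.DataFrame(vals, index=spectrum.index, columns=spectrum.columns)
    vals = np.asarray(spectrum, dtype=float) / divisor
    out = pd.Series(100.0 * vals / vals.sum(), index=CHANNELS_96)
    return out


# ---------------------------------------------------------------------------
# mixture model
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Posterior summary of a signature-mixture refit."""

    signature_ids: list
    samples: np.ndarray          # n_samples x K posterior draws of W
    mean: np.ndarray             # posterior-mean weights
    ci_low: np.ndarray           # 2.5% equal-tailed bound
    ci_high: np.ndarray          # 97.5% equal-tailed bound
    theta: np.ndarray            # reconstruction mean(W) @ S
    n_samples: int
    seed: int | None

    @property
    def weights(self) -> pd.Series:
        return pd.Series(self.mean, index=self.signature_ids, name="weight")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "weight": self.mean, "ci_low": self.ci_low, "ci_high": self.ci_high,
        }, index=pd.Index(self.signature_ids, name="signature"))


def _as_counts(M) -> np.ndarray:
    m = np.asarray(M if not isinstance(M, pd.Series) else M.to_numpy())
    if m.shape != (96,):
        raise ValueError("spectrum must have 96 entries")
    if np.any(m < 0) or not np.allclose(m, np.round(m)):
        raise ValueError("multinomial likelihood requires non-negative integer counts")
    return np.round(m).astype(np.int64)


def _as_signature_array(S) -> tuple[list, np.ndarray]:
    if isinstance(S, pd.DataFrame):
        ids, arr = list(S.index), S.to_numpy(dtype=float)
    else:
        arr = np.asarray(S, dtype=float)
        ids = list(range(1, arr.shape[0] + 1))
    if arr.ndim != 2 or arr.shape[1] != 96:
        raise ValueError("signature matrix must be K x 96")
    if np.any(arr < 0):
        raise ValueError("signature entries must be non-negative")
    arr = arr / arr.sum(axis=1, keepdims=True)
    return ids, arr


def fit_mixture(M, S, n_samples: int = 10_000, burn_in: int | None = None,
                alpha: float = 1.0, seed: int | None = None) -> MixtureFit:
    """Sample the posterior of the mixture weights W.

    Gibbs data augmentation: per sweep, the counts in each of the 96
    categories are attributed to signatures with probabilities proportional
    to ``W_k S_k,c``; W is then redrawn from Dirichlet(alpha + attributed
    totals). The point estimate is the posterior mean; 95% equal-tailed
    credible intervals come from the sample quantiles. K = 1 returns the
    degenerate exact posterior W = [1].
    """
    m = _as_counts(M)
    ids, Sarr = _as_signature_array(S)
    K = Sarr.shape[0]
    if K == 0:
        raise ValueError("need at least one signature")
    if K == 1:
        ones = np.ones((n_samples, 1))
        return MixtureFit(ids, ones, np.array([1.0]), np.array([1.0]),
                          np.array([1.0]), Sarr[0], n_samples, seed)
    if burn_in is None:
        burn_in = max(200, n_samples // 10)
    active = m > 0
    Ssub = np.ascontiguousarray(Sarr[:, active].T)  # C x K
    if np.any(Ssub.sum(axis=1) == 0):
        raise ValueError("observed counts in a category with zero probability "
                         "under every signature")
    mm = m[active]
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(np.full(K, alpha))
    draws = np.empty((n_samples, K))
    for t in range(burn_in + n_samples):
        P = Ssub * W
        P /= P.sum(axis=1, keepdims=True)
        counts = rng.multinomial(mm, P)
        W = rng.dirichlet(alpha + counts.sum(axis=0))
        if t >= burn_in:
            draws[t - burn_in] = W
    mean = draws.mean(axis=0)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return MixtureFit(ids, draws, mean, lo, hi, mean @ Sarr, n_samples, seed)


def reconstruct_spectrum(W, S) -> pd.Series:
    """theta = W S, the mixture's 96-channel probability vector."""
    w = np.asarray(W, dtype=float)
    _, Sarr = _as_signature_array(S)
    if w.shape != (Sarr.shape[0],):
        raise ValueError("weight vector length must match signature count")
    if np.any(w < 0) or not np.isclose(w.sum(), 1):
        raise ValueError("weights must lie on the simplex")
    return pd.Series(w @ Sarr, index=CHANNELS_96, name="theta")


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two spectra, in [0, 1] for non-negative
    vectors."""
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(av @ bv / (na * nb))


def grid_posterior_mean_k2(M, S, n_grid: int = 4001, alpha: float = 1.0) -> np.ndarray:
    """Posterior mean of W for K = 2 by direct summation on a fine grid.

    Independent of the Gibbs sampler: the multinomial likelihood times the
    Dirichlet(alpha) prior density is evaluated on a regular grid over
    w1 in (0, 1) and normalized numerically. Used as a correctness oracle
    for the MCMC.
    """
    m = _as_counts(M)
    _, Sarr = _as_signature_array(S)
    if Sarr.shape[0] != 2:
        raise ValueError("grid oracle is for exactly two signatures")
    w1 = np.linspace(0.0, 1.0, n_grid)[1:-1]
    theta = np.outer(w1, Sarr[0]) + np.outer(1 - w1, Sarr[1])
    active = m > 0
    with np.errstate(divide="ignore"):
        loglik = np.log(theta[:, active]) @ m[active]
    logpost = loglik + (alpha - 1) * (np.log(w1) + np.log(1 - w1))
    post = np.exp(logpost - logpost.max())
    post /= post.sum()
    mw1 = float(post @ w1)
    return np.array([mw1, 1 - mw1])


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def select_signatures(M, S_all: pd.DataFrame, base_ids=(1, 5),
                      delta_min: float = 0.02, n_samples: int = 10_000,
                      seed: int | None = 0) -> pd.DataFrame:
    """Stepwise candidate screening against a base signature set.

    Fits the base set, then each base + {candidate} expansion with the same
    sampler settings and seed policy, and reports the gain in cosine
    similarity between the observed spectrum (as proportions) and the
    reconstruction. Candidates with a gain of at least ``delta_min`` are
    flagged accepted. Returns a frame (one row per candidate) with the base
    cosine attached as ``result.attrs["base_cosine"]``.
    """
    base_ids = list(base_ids)
    if not base_ids:
        raise ValueError("base set must be non-empty")
    missing = [i for i in base_ids if i not in S_all.index]
    if missing:
        raise KeyError(f"base signatures not in matrix: {missing}")
    m = _as_counts(M)
    target = m / m.sum()

    def fitted_cosine(ids):
        fit = fit_mixture(m, S_all.loc[ids], n_samples=n_samples, seed=seed)
        return cosine_similarity(target, fit.theta), fit

    base_cos, _ = fitted_cosine(base_ids)
    rows = []
    for cand in S_all.index:
        if cand in base_ids:
            continue
        cos_c, _ = fitted_cosine(base_ids + [cand])
        delta = cos_c - base_cos
        rows.append({"candidate": cand, "cosine": cos_c, "delta": delta,
                     "accepted": bool(delta >= delta_min)})
    report = pd.DataFrame(rows)
    report.attrs["base_cosine"] = base_cos
    report.attrs["base_ids"] = base_ids
    return report


# ---------------------------------------------------------------------------
# reference-style synthetic signatures
# ---------------------------------------------------------------------------

def synthetic_signature_matrix(n_signatures: int = 10, seed: int = 2017,
                               concentration: float = 0.08,
                               n_peaks: int = 8) -> pd.DataFrame:
    """A deterministic synthetic stand-in for a reference signature catalog.

    Each row is a sparse 96-channel probability vector with ``n_peaks``
    prominent channels (drawn without replacement per signature) on a low
    Dirichlet-noise floor, giving mutually distinguishable signatures with
    realistic peakiness. This is a synthetic construction — it does not
    reproduce any published catalog — intended for simulation studies and
    recovery tests where only the mixture structure matters.
    """
    rng = np.random.default_rng(seed)
    rows = np.empty((n_signatures, 96))
    for k in range(n_signatures):
        floor = rng.dirichlet(np.full(96, concentration))
        peaks = rng.choice(96, size=n_peaks, replace=False)
        weights = rng.dirichlet(np.full(n_peaks, 1.0))
        row = 0.15 * floor
        row[peaks] += 0.85 * weights
        rows[k] = row / row.sum()
    return pd.DataFrame(rows, index=pd.Index(range(1, n_signatures + 1),
                                             name="signature"),
                        columns=CHANNELS_96)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_signature_matrix(path: str) -> pd.DataFrame:
    """Read a signature matrix TSV.

    Accepts either the catalog layout (rows = 96 mutation types with
    ``Substitution Type`` and ``Trinucleotide`` columns, one column per
    signature) or the transposed wide layout written by
    :func:`write_signature_matrix` (rows = signatures, 96 channel columns).
    """
    df = pd.read_csv(path, sep="\t")
    if "Substitution Type" in df.columns and "Trinucleotide" in df.columns:
        channels = [f"{t[0]}[{s}]{t[2]}" for s, t in
                    zip(df["Substitution Type"], df["Trinucleotide"])]
        sig_cols = [c for c in df.columns
                    if c not in ("Substitution Type", "Trinucleotide",
                                 "Somatic Mutation Type")]
        out = df[sig_cols].T
        out.columns = channels
        return out[CHANNELS_96]
    df = df.set_index(df.columns[0])
    return df[CHANNELS_96]


def write_signature_matrix(S: pd.DataFrame, path: str) -> None:
    S.to_csv(path, sep="\t")


def write_spectrum(spectrum: pd.Series, path: str) -> None:
    spectrum.rename_axis("channel").to_frame("count").to_csv(path, sep="\t")


def read_spectrum(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].reindex(CHANNELS_96)
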