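"""Copy-number segment filtering and gene-level copy-number calling.

Downstream of read-depth segmentation: per-sample bin counts (500 bp bins by
default) are normalized to each sample's modal coverage so diploid bins sit
at 1.0. Candidate tumor-unique CNV segments must span a minimum genomic size
(5 kb, i.e. 10 bins of 500 bp); their per-bin counts are then compared
between the two tumors of the lineage with a paired two-sided t-test — if the
difference is not significant the segment is relabeled lineage-shared and a
single copy number is assigned from the pooled per-bin copy-number
posteriors (the state with the highest median posterior). A separate
gene-level caller tests per-gene bin coverage across sample groups with
one-way ANOVA followed by Tukey's range test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "normalize_bin_counts",
    "cn_posteriors",
    "filter_cnv_segments",
    "call_gene_copy_number",
    "panel_window_profile",
]

CN_STATES = np.arange(7)  # copy numbers 0..6
_CN0_RATE = 0.05          # residual coverage fraction modeled for CN 0


def _mode_of_counts(counts: np.ndarray) -> int:
    """Mode of an integer count histogram; ties go to the smaller count."""
    counts = np.asarray(counts)
    if counts.max() == 0:
        raise ValueError("sample has no coverage")
    return int(np.bincount(counts.astype(np.int64)).argmax())


def normalize_bin_counts(bins: pd.DataFrame, samples: list[str] | None = None,
                         method: str = "mode") -> pd.DataFrame:
    """Normalize per-bin read counts per sample.

    ``method="mode"`` divides by the sample's modal bin count (the diploid
    peak), so copy-neutral bins sit near 1.0 and a CN4 bin near 2.0;
    ``method="mean"`` divides by the sample's mean bin count (used for
    normal-panel window profiles).
    """
    samples = samples or [c for c in bins.columns
                          if c not in ("scaffold", "start", "end")]
    out = bins.copy()
    for s in samples:
        counts = bins[s].to_numpy()
        denom = _mode_of_counts(counts) if method == "mode" else counts.mean()
        if denom == 0:
            raise ValueError(f"zero normalization denominator for sample {s}")
        out[s] = counts / denom
    return out


def cn_posteriors(counts: np.ndarray, depth_per_copy2: float) -> np.ndarray:
    """Per-bin posterior over copy-number states 0..6.

    Poisson read-count model: a bin at copy number s has expected count
    ``depth_per_copy2 * s / 2`` (CN0 keeps a small residual rate). Uniform
    prior over states. Returns a bins x 7 row-stochastic matrix.
    """
    counts = np.asarray(counts, dtype=np.int64)
    rates = np.maximum(CN_STATES / 2.0, _CN0_RATE) * depth_per_copy2
    loglik = counts[:, None] * np.log(rates[None, :]) - rates[None, :]
    loglik -= loglik.max(axis=1, keepdims=True)
    post = np.exp(loglik)
    return post / post.sum(axis=1, keepdims=True)


def pooled_copy_number(post_a: np.ndarray, post_b: np.ndarray) -> int:
    """Shared copy number from two tumors' per-bin posteriors: average the
    posteriors bin-wise, take the median over bins per state, and return the
    arg-max state (ties -> lower state)."""
    pooled = (post_a + post_b) / 2.0
    med = np.median(pooled, axis=0)
    return int(np.argmax(med))  # argmax takes the first (lowest) on ties


def filter_cnv_segments(segments: pd.DataFrame, bins: pd.DataFrame,
                        tumor_pair: tuple[str, str],
                        min_unique_bp: int = 5000, p_cut: float = 0.01,
                        depth_per_copy2: float | None = None) -> pd.DataFrame:
    """Filter and label candidate tumor-unique CNV segments.

    ``segments`` needs ``scaffold``, ``start``, ``end`` (bp, half-open),
    ``tumor`` (the candidate carrier, one of ``tumor_pair``) and ``cn`` (the
    segmented copy number). ``bins`` is the raw bin-count frame covering the
    segments. Cascade per segment:

    1. span < ``min_unique_bp`` -> status ``rejected_min_size``;
    2. paired two-sided t-test on the segment's per-bin normalized counts
       between the two tumors; p < ``p_cut`` -> ``tumor_unique`` retained;
    3. otherwise ``shared``: copy-number posteriors of both tumors are
       pooled and the highest-median state is assigned to both
       (``pooled_cn`` column).

    Output is the input segments with ``status``, ``p_value`` and
    ``pooled_cn`` columns; no segment is ever invented or dropped silently.
    """
    t1, t2 = tumor_pair
    # the paired t-test needs a low-variance scale estimate per sample: the
    # genome-wide mean. The integer histogram mode (used for copy-ratio
    # display) can shift by one count between samples, which a paired test
    # reads as a systematic difference and rejects spuriously.
    norm = normalize_bin_counts(bins, [t1, t2], method="mean")
    if depth_per_copy2 is None:
        depth_per_copy2 = float(np.mean(
            [_mode_of_counts(bins[t].to_numpy()) for t in (t1, t2)]))
    out = segments.copy()
    status, pvals, pooled = [], [], []
    for _, seg in segments.iterrows():
        sel = ((bins["scaffold"] == seg["scaffold"])
               & (bins["start"] >= seg["start"]) & (bins["end"] <= seg["end"]))
        n_bins = int(sel.sum())
        if seg["end"] - seg["start"] < min_unique_bp:
            status.append("rejected_min_size")
            pvals.append(np.nan)
            pooled.append(np.nan)
            continue
        if n_bins < 2:
            raise ValueError("segment covers fewer than two bins; t-test undefined")
        raw_a, raw_b = bins.loc[sel, t1].to_numpy(), bins.loc[sel, t2].to_numpy()
        a, b = norm.loc[sel, t1].to_numpy(), norm.loc[sel, t2].to_numpy()
        if np.array_equal(raw_a, raw_b):
            p = 1.0  # identical read-count vectors: no dispersion difference
        else:
            p = float(stats.ttest_rel(a, b).pvalue)
        pvals.append(p)
        if p < p_cut:
            status.append("tumor_unique")
            pooled.append(np.nan)
        else:
            status.append("shared")
            pa = cn_posteriors(bins.loc[sel, t1].to_numpy(), depth_per_copy2)
            pb = cn_posteriors(bins.loc[sel, t2].to_numpy(), depth_per_copy2)
            pooled.append(pooled_copy_number(pa, pb))
    out["status"] = status
    out["p_value"] = pvals
    out["pooled_cn"] = pooled
    return out


def call_gene_copy_number(gene_bins: dict[str, pd.DataFrame],
                          groups: dict[str, list[str]],
                          alpha: float = 0.0001,
                          diff_cut: float = 0.25) -> pd.DataFrame:
    """Gene-level copy-number status per sample group.

    ``gene_bins`` maps gene -> frame of normalized per-bin coverage with one
    column per sample; ``groups`` maps group name (e.g. lineage-1 tumors,
    lineage-2 tumors, hosts) -> its samples. Per gene: one-way ANOVA across
    groups on the pooled bin x sample normalized coverages; if significant at
    ``alpha``, Tukey's range test identifies which group(s) deviate; a group
    significantly different from both others with a mean coverage difference
    of magnitude > ``diff_cut`` versus the rest is called a gain or loss.
    """
    rows = []
    for gene, bins in gene_bins.items():
        if not len(bins):
            raise ValueError(f"gene {gene} has zero bins")
        obs = {g: bins[list(ss)].to_numpy(dtype=float).ravel()
               for g, ss in groups.items()}
        fstat, p = stats.f_oneway(*obs.values())
        calls = {g: "neutral" for g in groups}
        diffs = {g: np.nan for g in groups}
        if np.isfinite(p) and p < alpha:
            values = np.concatenate(list(obs.values()))
            labels = np.concatenate([[g] * len(v) for g, v in obs.items()])
            tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
            sig = {}
            res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
            for _, r in res.iterrows():
                sig[frozenset((r["group1"], r["group2"]))] = bool(r["reject"])
            for g in groups:
                others = [o for o in groups if o != g]
                if all(sig.get(frozenset((g, o)), False) for o in others):
                    rest = np.concatenate([obs[o] for o in others])
                    diff = obs[g].mean() - rest.mean()
                    diffs[g] = diff
                    if diff > diff_cut:
                        calls[g] = "gain"
                    elif diff < -diff_cut:
                        calls[g] = "loss"
        for g in groups:
            rows.append({"gene": gene, "group": g, "status": calls[g],
                         "mean_difference": diffs[g], "anova_p": p})
    return pd.DataFrame(rows)


def panel_window_profile(window_counts: pd.DataFrame,
                         samples: list[str] | None = None) -> pd.DataFrame:
    """Normalized coverage profile over large windows for a normal panel.

    Each sample's window counts are divided by that sample's mean window
    count (proportional to its genome-wide sequencing depth), so single-copy
    regions sit near 1.0 and a segregating hemizygous deletion near 0.5,
    regardless of how deeply each animal was sequenced.
    """
    return normalize_bin_counts(window_counts, samples, method="mean")
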