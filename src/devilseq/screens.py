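"""Structural-variant filtering, breakpoint-junction classification, and
presence/absence-variation (PAV) screening.

Structural-variant calls (discordant-read support per sample) are filtered
and labeled germline-like / somatic / lineage-shared by support-count rules.
Assembled contigs spanning a rearrangement are resolved to base-pair
precision and classified as microhomology (the two reference sides share k
identical bases at the join), non-templated insertion (k contig bases match
neither side), or blunt. Junction-class compositions of two lineages are
compared with Pearson's chi-square. PAV screening retains assembly contigs
well covered in at least one tumor but essentially absent from every host —
the signature of tumor-exclusive DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_sv_calls",
    "JunctionCall",
    "classify_junction",
    "classify_junction_table",
    "compare_junction_classes",
    "filter_pav_contigs",
]


# ---------------------------------------------------------------------------
# SV support filtering
# ---------------------------------------------------------------------------

def filter_sv_calls(calls: pd.DataFrame, roles, min_total: int = 11,
                    max_normal: int = 2, min_somatic: int = 11,
                    max_other: int = 2) -> pd.DataFrame:
    """Label SV calls by per-sample discordant-read support.

    ``calls`` carries one ``support:<sample>`` column per cohort sample
    (roles as in :class:`devilseq.classify.SampleRoles`). Cascade:

    * total support across all samples < ``min_total`` (i.e. not > 10)
      -> ``rejected_low_support``;
    * combined support across the normals > ``max_normal``
      -> ``rejected_germline``;
    * support >= ``min_somatic`` in one tumor (or in both tumors of a
      lineage) with combined support across all other samples <= ``max_other``
      -> ``somatic:<tumor>`` / ``lineage_shared:<1|2>``;
    * anything else -> ``unresolved``.

    Labels partition the input; rejected calls are retained with reason
    codes.
    """
    def sup(sample):
        col = f"support:{sample}"
        if col not in calls.columns:
            raise KeyError(f"missing support column for sample {sample!r}")
        return calls[col].to_numpy()

    samples = list(roles.all_samples)
    normals = list(roles.highcov_normals) + list(roles.panel_normals)
    total = sum(sup(s) for s in samples)
    normal_total = sum(sup(s) for s in normals) if normals else np.zeros(len(calls))
    labels = np.full(len(calls), "unresolved", dtype=object)

    lineages = {1: list(roles.lineage1), 2: list(roles.lineage2)}
    for lin, tumors in lineages.items():
        lin_sup = sum(sup(t) for t in tumors)
        others = sum(sup(s) for s in samples if s not in tumors)
        ok = (np.all([sup(t) >= min_somatic for t in tumors], axis=0)
              & (others <= max_other))
        labels[ok] = f"lineage_shared:{lin}"
    for t in roles.tumors:
        others = sum(sup(s) for s in samples if s != t)
        ok = (sup(t) >= min_somatic) & (others <= max_other)
        labels[ok] = f"somatic:{t}"
    labels[normal_total > max_normal] = "rejected_germline"
    labels[total < min_total] = "rejected_low_support"
    out = calls.copy()
    out["label"] = labels
    return out


# ---------------------------------------------------------------------------
# junction classification
# ---------------------------------------------------------------------------

@dataclass
class JunctionCall:
    """A breakpoint junction resolved to base-pair precision.

    ``kind`` is ``microhomology``, ``insertion`` or ``blunt``; ``length`` is
    the homology/insertion length (0 iff blunt); ``sequence`` the homologous
    or inserted bases; ``breakpoint`` the left-aligned 0-based contig offset
    where the B side begins.
    """

    kind: str
    length: int
    sequence: str
    breakpoint: int
    a_end: int      # contig offset where the A-side match ends
    b_start: int    # contig offset where the B-side match starts


def _max_prefix_in(contig: str, ref: str) -> int:
    """Largest x with contig[:x] a substring of ref (monotone -> bisection)."""
    lo, hi = 0, min(len(contig), len(ref))
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if contig[:mid] in ref:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _min_suffix_start_in(contig: str, ref: str) -> int:
    """Smallest y with contig[y:] a substring of ref."""
    n = len(contig)
    lo, hi = max(0, n - len(ref)), n
    while lo < hi:
        mid = (lo + hi) // 2
        if contig[mid:] in ref:
            hi = mid
        else:
            lo = mid + 1
    return lo


def classify_junction(contig: str, refA: str, refB: str,
                      min_anchor: int = 20) -> JunctionCall:
    """Classify a breakpoint junction by maximal exact overlap.

    The contig is anchored to the A-side reference from its start and to the
    B-side reference from its end; matches are extended maximally. If the
    two extents overlap by k bases the junction is a microhomology of length
    k; if they leave a gap of k unmatched contig bases it is a non-templated
    insertion of those bases; exact abutment is blunt. Breakpoints are
    left-aligned (the reported coordinate is the leftmost consistent
    placement). A side failing to match at least ``min_anchor`` bases raises.
    """
    contig, refA, refB = contig.upper(), refA.upper(), refB.upper()
    a_end = _max_prefix_in(contig, refA)
    b_start = _min_suffix_start_in(contig, refB)
    if a_end < min_anchor:
        raise ValueError("contig fails to align to the A-side reference")
    if len(contig) - b_start < min_anchor:
        raise ValueError("contig fails to align to the B-side reference")
    k = a_end - b_start
    if k > 0:
        return JunctionCall("microhomology", k, contig[b_start:a_end],
                            b_start, a_end, b_start)
    if k < 0:
        return JunctionCall("insertion", -k, contig[a_end:b_start],
                            a_end, a_end, b_start)
    return JunctionCall("blunt", 0, "", a_end, a_end, b_start)


def classify_junction_table(junctions: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a junction frame (columns ``contig``, ``refA``,
    ``refB``); returns the frame with ``kind``, ``length``, ``sequence`` and
    ``breakpoint`` columns appended."""
    calls = [classify_junction(r["contig"], r["refA"], r["refB"])
             for _, r in junctions.iterrows()]
    out = junctions.copy()
    out["kind"] = [c.kind for c in calls]
    out["length"] = [c.length for c in calls]
    out["sequence"] = [c.sequence for c in calls]
    out["breakpoint"] = [c.breakpoint for c in calls]
    return out


def compare_junction_classes(counts_a, counts_b) -> tuple[float, float]:
    """Pearson chi-square comparison of two junction-class compositions.

    Inputs are 3-vectors (microhomology, insertion, blunt) for the two
    lineages. All-zero classes are dropped (degrees of freedom reduce
    accordingly); identical compositions give statistic 0, p = 1.
    """
    table = np.asarray([counts_a, counts_b], dtype=float)
    if np.any(table < 0):
        raise ValueError("negative class counts")
    if table.sum() == 0 or np.any(table.sum(axis=1) == 0):
        raise ValueError("each lineage needs at least one junction")
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# PAV screening
# ---------------------------------------------------------------------------

def filter_pav_contigs(table: pd.DataFrame, tumor_samples: list[str],
                       host_samples: list[str], genome_means: dict[str, float],
                       tumor_frac: float = 0.40, host_frac: float = 0.20
                       ) -> pd.DataFrame:
    """Retain candidate PAV contigs by relative read depth.

    A contig is kept iff its depth reaches ``tumor_frac`` x the genome-wide
    mean depth in at least one tumor (plausibly a single-copy integration)
    and stays below ``host_frac`` x the genome-wide mean in every host.
    ``table`` needs a ``depth:<sample>`` column per sample.
    """
    for s in tumor_samples + host_samples:
        if genome_means.get(s, 0) <= 0:
            raise ValueError(f"non-positive genome-wide mean depth for {s!r}")
    keep = np.zeros(len(table), dtype=bool)
    for t in tumor_samples:
        keep |= table[f"depth:{t}"].to_numpy() >= tumor_frac * genome_means[t]
    for h in host_samples:
        keep &= table[f"depth:{h}"].to_numpy() < host_frac * genome_means[h]
    return table.loc[keep]
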