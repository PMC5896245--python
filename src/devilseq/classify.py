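"""Clonal-lineage classification of filtered variants and tumor purity.

In a transmissible cancer each tumor lineage carries the germline of its
founder animal in addition to its somatic mutations, so variants are sorted
with read-support thresholds against a panel of normal genomes rather than a
single matched normal:

* germline — supported in the normal population (>= 5 reads in any
  high-coverage normal, or >= 1 read anywhere in the low-coverage panel);
* potentially somatic — >= 5 reads in both tumors of one lineage (or all
  tumors), absent from every normal; a mix of founder germline not captured
  by the panel and true trunk somatic mutations;
* tumor-unique — >= 5 reads in exactly one tumor; the best proxy for recent
  somatic mutation;
* remainder — everything else (e.g. support split across lineages without
  being shared by all tumors).

Tumor purity (host-DNA contamination) is estimated from the VAF of
founder-heterozygous germline variants: at purity 1 these sit at VAF 0.5, and
host DNA carrying the reference allele dilutes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import compute_vaf, sample_names, variant_reads

__all__ = [
    "SampleRoles",
    "CATEGORIES",
    "classify_variant",
    "classify_table",
    "summarize_categories",
    "estimate_tumor_purity",
    "informative_germline_vafs",
]

CATEGORIES = [
    "germline",
    "lin1_potentially_somatic",
    "lin2_potentially_somatic",
    "shared_potentially_somatic",
    "tumor_unique",
    "remainder",
]


@dataclass
class SampleRoles:
    """Cohort roles: which samples are tumors of each lineage, which are
    high-coverage normals, and which form the low-coverage normal panel
    (including the ascertainment normal)."""

    lineage1: tuple[str, ...]
    lineage2: tuple[str, ...]
    highcov_normals: tuple[str, ...]
    panel_normals: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        groups = [tuple(self.lineage1), tuple(self.lineage2),
                  tuple(self.highcov_normals), tuple(self.panel_normals)]
        self.lineage1, self.lineage2, self.highcov_normals, self.panel_normals = groups
        flat = [s for g in groups for s in g]
        if len(set(flat)) != len(flat):
            raise ValueError("sample role sets must be disjoint")
        if not self.lineage1 or not self.lineage2:
            raise ValueError("both lineages need at least one tumor")

    @property
    def tumors(self) -> tuple[str, ...]:
        return self.lineage1 + self.lineage2

    @property
    def all_samples(self) -> tuple[str, ...]:
        return self.tumors + self.highcov_normals + self.panel_normals

    @classmethod
    def from_config(cls, config) -> "SampleRoles":
        """Roles for a :class:`~devilseq.simulate.CohortConfig` cohort."""
        return cls(lineage1=tuple(config.tumor_names(1)),
                   lineage2=tuple(config.tumor_names(2)),
                   highcov_normals=tuple(config.highcov_normals),
                   panel_normals=tuple(config.lowcov_normals))


def classify_variant(support: dict[str, int], roles: SampleRoles,
                     tumor_min: int = 5, normal_max: int = 5) -> str:
    """Assign one variant to a category from per-sample variant read counts.

    The cascade is evaluated in order germline -> shared -> lineage ->
    tumor-unique -> remainder; exclusion thresholds are strict
    (``< normal_max`` reads in high-coverage normals, 0 reads in the panel,
    ``< tumor_min`` reads in non-carrier tumors).

    Returns the category; tumor-unique results are returned as
    ``"tumor_unique:<sample>"``.
    """
    missing = [s for s in roles.all_samples if s not in support]
    if missing:
        raise KeyError(f"no read support recorded for samples: {missing}")
    if any(support[s] >= normal_max for s in roles.highcov_normals) or \
       any(support[s] >= 1 for s in roles.panel_normals):
        return "germline"
    # beyond here every normal has < normal_max (high-cov) and 0 (panel) reads
    lin1_hit = [support[s] >= tumor_min for s in roles.lineage1]
    lin2_hit = [support[s] >= tumor_min for s in roles.lineage2]
    if all(lin1_hit) and all(lin2_hit):
        return "shared_potentially_somatic"
    if all(lin1_hit) and not any(lin2_hit):
        return "lin1_potentially_somatic"
    if all(lin2_hit) and not any(lin1_hit):
        return "lin2_potentially_somatic"
    hits = [s for s in roles.tumors if support[s] >= tumor_min]
    if len(hits) == 1:
        return f"tumor_unique:{hits[0]}"
    return "remainder"


def classify_table(table: pd.DataFrame, roles: SampleRoles,
                   tumor_min: int = 5, normal_max: int = 5) -> pd.Series:
    """Vectorized classification of an allele-support table.

    Returns a Series of category labels aligned with the table's index.
    """
    reads = {s: variant_reads(table, s).to_numpy() for s in roles.all_samples}
    n = len(table)
    germ = np.zeros(n, dtype=bool)
    for s in roles.highcov_normals:
        germ |= reads[s] >= normal_max
    for s in roles.panel_normals:
        germ |= reads[s] >= 1
    lin1 = np.array([reads[s] >= tumor_min for s in roles.lineage1])
    lin2 = np.array([reads[s] >= tumor_min for s in roles.lineage2])
    all1, any1 = lin1.all(axis=0), lin1.any(axis=0)
    all2, any2 = lin2.all(axis=0), lin2.any(axis=0)
    hits = np.array([reads[s] >= tumor_min for s in roles.tumors])
    n_hits = hits.sum(axis=0)
    labels = np.full(n, "remainder", dtype=object)
    unique_mask = (n_hits == 1) & ~germ
    if unique_mask.any():
        which = hits.argmax(axis=0)
        for i in np.flatnonzero(unique_mask):
            labels[i] = f"tumor_unique:{roles.tumors[which[i]]}"
    labels[(all2 & ~any1)] = "lin2_potentially_somatic"
    labels[(all1 & ~any2)] = "lin1_potentially_somatic"
    labels[(all1 & all2)] = "shared_potentially_somatic"
    labels[germ] = "germline"
    return pd.Series(labels, index=table.index, name="category")


def summarize_categories(assignments: pd.Series,
                         vclass: pd.Series | None = None) -> pd.DataFrame:
    """Counts by category x variant class (SNV / indel).

    Tumor-unique assignments are kept per tumor. The summary partitions the
    input: the grand total equals the number of assignments.
    """
    cat = assignments.astype(str)
    if vclass is None:
        vclass = pd.Series("SNV", index=assignments.index)
    order = (CATEGORIES[:-2]
             + sorted({c for c in cat.unique() if c.startswith("tumor_unique")})
             + ["remainder"])
    tab = (pd.crosstab(cat, vclass.rename("vclass"))
           .reindex(order, fill_value=0)
           .rename_axis("category"))
    for col in ("SNV", "indel"):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[["SNV", "indel"]]
    tab["total"] = tab.sum(axis=1)
    assert tab["total"].sum() == len(assignments)
    return tab


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------

def estimate_tumor_purity(germline_het_vafs, min_loci: int = 100) -> dict:
    """Estimate the host-DNA fraction of a tumor sample.

    Input: VAFs in the tumor at loci where the founder is heterozygous and
    the host is homozygous reference. With host fraction h the expected VAF
    is (1 - h)/2, so h = 1 - 2 * median(VAF), clipped to [0, 1]. The
    interquartile range of per-locus implied h values is reported alongside.
    """
    v = np.asarray(germline_het_vafs, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < min_loci:
        raise ValueError(f"need >= {min_loci} informative loci, got {len(v)}")
    h = float(np.clip(1 - 2 * np.median(v), 0, 1))
    per_locus = np.clip(1 - 2 * v, 0, 1)
    q1, q3 = np.percentile(per_locus, [25, 75])
    return {"host_fraction": h, "purity": 1 - h,
            "iqr": (float(q1), float(q3)), "n_loci": len(v)}


def informative_germline_vafs(table: pd.DataFrame, assignments: pd.Series,
                              roles: SampleRoles, tumor: str,
                              het_band: tuple[float, float] = (0.2, 0.8),
                              min_reads: int = 5) -> np.ndarray:
    """Extract purity-informative VAFs for one tumor.

    Selects variants classified germline whose VAF in the tumor is
    heterozygous-like (within ``het_band``, with >= ``min_reads`` supporting
    reads) while no high-coverage normal shows variant support — the pattern
    of founder-heterozygous / host-homozygous-reference sites.
    """
    germ = assignments == "germline"
    vaf = compute_vaf(table)
    t = vaf[tumor]
    sel = germ & (t >= het_band[0]) & (t <= het_band[1]) & \
        (variant_reads(table, tumor) >= min_reads)
    for h in roles.highcov_normals:
        sel &= variant_reads(table, h) == 0
    return vaf.loc[sel, tumor].to_numpy()
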