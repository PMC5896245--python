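"""Population placement of tumor founder genotypes from a SNP panel.

A reduced-representation (RAD-style) SNP panel genotyped across wild
individuals plus the tumors lets the founder animal of each clonal lineage be
placed within population structure. The pipeline: filter the candidate SNP
list, code genotypes numerically (hom 1/1 -> 0, het -> 0.5, hom 2/2 -> 1),
impute missing genotypes from the most similar SNP, cluster individuals by
complete-linkage on Euclidean distance, and report each tumor's nearest
neighbors. The clustering step is generic and is reused for e.g. drug-screen
log-IC50 matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .filters import RegionAnnotation

__all__ = [
    "PanelFilterInputs",
    "filter_snp_panel",
    "code_genotypes",
    "impute_missing",
    "Dendrogram",
    "cluster_samples",
    "nearest_neighbors",
    "top_split",
]


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------

@dataclass
class PanelFilterInputs:
    """Everything the SNP-panel filter cascade consults.

    ``candidates``: frame with columns ``snp_id``, ``fragment``, ``scaffold``,
    ``pos``, ``vclass`` (``SNP``/``indel``), ``mismatches`` (fragment mapping
    mismatches), ``gap_len`` (total alignment gap length in bp).
    ``genotypes``: individuals x candidate-SNP matrix of published genotype
    codes used for the variation ranking. ``annotation``: repeat and
    contig/scaffold-boundary windows plus the scaffold -> chromosome map.
    ``nondiploid``: scaffold -> array of (start, end) 1-based inclusive
    intervals that are non-diploid in any tumor.
    """

    candidates: pd.DataFrame
    genotypes: pd.DataFrame
    annotation: RegionAnnotation
    nondiploid: dict[str, np.ndarray] = field(default_factory=dict)
    x_chromosome: str = "X"


def filter_snp_panel(inputs: PanelFilterInputs, keep_top_frac: float = 0.40
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the ordered SNP-panel exclusion cascade.

    Steps: (i) drop indels; (ii) drop SNPs on ambiguously mapping fragments
    (> 2 mismatches or total gap length > 2 bp); (iii) drop SNPs in repeat /
    contig-end / scaffold-end windows or on the X chromosome or on scaffolds
    without a chromosome; (iv) drop SNPs in tumor non-diploid regions;
    (v) rank SNPs by variability — 1 minus the modal genotype's share across
    individuals — and keep the most-varying ``keep_top_frac``; (vi) keep only
    the SNP closest to the fragment's 5' end when several share a fragment.

    Missing mapping stats raise. Returns the surviving candidate frame and a
    per-step exclusion-count Series (which, with the survivors, sums to the
    candidate total).
    """
    cand = inputs.candidates.copy()
    if cand[["mismatches", "gap_len"]].isna().any().any():
        raise ValueError("candidates with missing fragment mapping stats")
    counts = {}
    total = len(cand)

    keep = cand["vclass"].str.upper() != "INDEL"
    counts["indel"] = int((~keep).sum())
    cand = cand[keep]

    keep = ~((cand["mismatches"] > 2) | (cand["gap_len"] > 2))
    counts["ambiguous_fragment"] = int((~keep).sum())
    cand = cand[keep]

    ann = inputs.annotation

    def region_bad(row):
        scf = row["scaffold"]
        if ann.chromosome_of.get(scf) == inputs.x_chromosome:
            return True
        if scf not in ann.chromosome_of:
            return True
        return ann.is_excluded(scf, int(row["pos"]))

    keep = ~cand.apply(region_bad, axis=1)
    counts["region_or_x"] = int((~keep).sum())
    cand = cand[keep]

    def in_nondiploid(row):
        iv = inputs.nondiploid.get(row["scaffold"])
        if iv is None or not len(iv):
            return False
        iv = np.asarray(iv).reshape(-1, 2)
        return bool(np.any((iv[:, 0] <= row["pos"]) & (row["pos"] <= iv[:, 1])))

    keep = ~cand.apply(in_nondiploid, axis=1)
    counts["nondiploid"] = int((~keep).sum())
    cand = cand[keep]

    # variability = 1 - modal genotype share across individuals
    geno = inputs.genotypes[cand["snp_id"]]
    modal_share = geno.apply(
        lambda col: col.value_counts(dropna=True).max() / col.notna().sum())
    variability = 1.0 - modal_share
    n_keep = int(np.ceil(keep_top_frac * len(cand)))
    order = variability.rank(method="first", ascending=False)
    keep = cand["snp_id"].map(order) <= n_keep
    counts["low_variation"] = int((~keep).sum())
    cand = cand[keep.to_numpy()]

    # one SNP per fragment: the 5'-most on the reference
    before = len(cand)
    cand = (cand.sort_values(["fragment", "pos"], kind="stable")
            .drop_duplicates("fragment", keep="first"))
    counts["fragment_duplicate"] = before - len(cand)

    excl = pd.Series(counts, name="excluded")
    assert excl.sum() + len(cand) == total
    return cand.reset_index(drop=True), excl


def code_genotypes(allele1_counts: pd.DataFrame, allele2_counts: pd.DataFrame,
                   min_depth: int = 7, hom_frac: float = 0.70) -> pd.DataFrame:
    """Numeric genotype codes from per-allele read counts.

    Sites with total coverage below ``min_depth`` become missing (NaN);
    otherwise allele-1 read fraction > ``hom_frac`` codes 0 (hom 1/1),
    < 1 - ``hom_frac`` codes 1 (hom 2/2), and anything between — boundaries
    included — codes 0.5 (het).
    """
    a1 = allele1_counts.to_numpy(dtype=float)
    a2 = allele2_counts.to_numpy(dtype=float)
    if np.any(a1 < 0) or np.any(a2 < 0):
        raise ValueError("negative allele counts")
    depth = a1 + a2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, a1 / np.where(depth > 0, depth, 1), np.nan)
    code = np.full(a1.shape, 0.5)
    code[frac > hom_frac] = 0.0
    code[frac < 1 - hom_frac] = 1.0
    code[depth < min_depth] = np.nan
    return pd.DataFrame(code, index=allele1_counts.index,
                        columns=allele1_counts.columns)


def impute_missing(panel: pd.DataFrame) -> pd.DataFrame:
    """Fill missing genotypes from the most similar SNP column.

    For each SNP with missing entries, other SNP columns are ranked by
    Euclidean distance computed over individuals where both SNPs are
    observed (pre-imputation values only, so column order does not matter);
    each missing cell adopts the value of the nearest column that is
    observed for that individual. Observed genotypes are never altered;
    complete panels return unchanged.
    """
    if panel.shape[1] < 2:
        raise ValueError("need at least two SNPs to impute from")
    if panel.isna().all(axis=0).any():
        raise ValueError("a SNP with no observed genotypes cannot be imputed")
    X = panel.to_numpy(dtype=float)
    out = X.copy()
    obs = ~np.isnan(X)
    n_snps = X.shape[1]
    for j in range(n_snps):
        holes = np.flatnonzero(~obs[:, j])
        if not len(holes):
            continue
        dists = np.full(n_snps, np.inf)
        for k in range(n_snps):
            if k == j:
                continue
            both = obs[:, j] & obs[:, k]
            if not both.any():
                continue
            d = X[both, j] - X[both, k]
            dists[k] = float(np.sqrt(np.sum(d * d)))
        if not np.isfinite(dists).any():
            raise ValueError(f"SNP {panel.columns[j]!r} shares no observed "
                             "individuals with any other SNP")
        order = np.argsort(dists, kind="stable")
        for i in holes:
            for k in order:
                if np.isfinite(dists[k]) and obs[i, k]:
                    out[i, j] = X[i, k]
                    break
    return pd.DataFrame(out, index=panel.index, columns=panel.columns)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative clustering result with labeled leaves."""

    linkage: np.ndarray
    labels: list[str]

    def cut(self, n_clusters: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                    f":{length:.6g}")

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def cluster_samples(matrix: pd.DataFrame, linkage: str = "complete",
                    metric: str = "euclidean") -> Dendrogram:
    """Hierarchical clustering of rows (individuals/samples) on their feature
    vectors. No missing values allowed — impute first."""
    if len(matrix) < 2:
        raise ValueError("need at least two samples to cluster")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    Z = hierarchy.linkage(matrix.to_numpy(dtype=float), method=linkage,
                          metric=metric)
    return Dendrogram(Z, [str(x) for x in matrix.index])


def top_split(dendrogram: Dendrogram) -> tuple[set[str], set[str]]:
    """The two leaf sets created by the dendrogram's final merge."""
    groups = dendrogram.cut(2)
    return (set(groups.index[groups == 1]), set(groups.index[groups == 2]))


def nearest_neighbors(matrix: pd.DataFrame, query: str, k: int,
                      metric: str = "euclidean") -> pd.DataFrame:
    """The ``k`` nearest rows to ``query`` under ``metric``; ties broken by
    input order."""
    if query not in matrix.index:
        raise KeyError(f"query sample {query!r} not in matrix")
    if k >= len(matrix):
        raise ValueError("k must be smaller than the number of samples")
    D = squareform(pdist(matrix.to_numpy(dtype=float), metric=metric))
    qi = list(matrix.index).index(query)
    d = pd.Series(D[qi], index=matrix.index).drop(query)
    order = np.argsort(d.to_numpy(), kind="stable")[:k]
    return pd.DataFrame({"neighbor": d.index[order], "distance": d.to_numpy()[order]})
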