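"""Synthetic cohorts and datasets with known ground truth.

Every downstream stage of the pipeline (variant filtering, lineage
classification, signature refitting, amplicon validation, population
clustering, CNV filtering, junction classification) can be exercised on the
outputs of this module alone. The generators model two clonally transmissible
tumor lineages sampled as two tumors each, plus a panel of normal host
genomes, at toy scale:

* read depth per sample per site ~ Poisson(mean depth);
* variant-supporting reads ~ Binomial(depth, expected VAF), where the
  expected VAF combines the carried genotype with tumor purity;
* forward-strand variant reads ~ Binomial(variant reads, strand split).

All generators are deterministic for a fixed seed: a single master seed is
expanded into independent per-component substreams via
:class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .filters import META_COLUMNS, RegionAnnotation
from .signatures import CHANNELS_96, channel_to_mutation

__all__ = [
    "CohortConfig",
    "simulate_cohort",
    "simulate_regions",
    "simulate_mutation_spectrum",
    "simulate_population_panel",
    "simulate_amplicon_experiment",
    "simulate_cnv_bins",
    "simulate_junctions",
    "write_vcf",
]

_BASES = np.array(list("ACGT"))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Design of a synthetic two-lineage tumor cohort.

    Defaults mirror the sequencing design of the study system: two tumors per
    lineage at ~70x, three high-coverage normal hosts, a larger low-coverage
    normal panel, tumors grown as near-pure cell lines.
    """

    n_lineages: int = 2
    tumors_per_lineage: int = 2
    n_highcov_normals: int = 3
    n_lowcov_normals: int = 43
    mean_depth: float = 70.0
    lowcov_mean_depth: float = 10.0
    purity: float = 1.0
    n_germline: int = 200
    n_trunk: int = 100
    n_unique: int = 100
    indel_fraction: float = 0.0
    strand_split: float = 0.5
    noise_rate: float = 0.0
    n_ref_artifacts: int = 0
    n_strand_artifacts: int = 0
    n_noise_artifacts: int = 0
    n_repeat_artifacts: int = 0
    avoid_ref_hom: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_lineages, self.tumors_per_lineage, self.n_highcov_normals,
                  self.n_lowcov_normals, self.n_germline, self.n_trunk, self.n_unique,
                  self.n_ref_artifacts, self.n_strand_artifacts,
                  self.n_noise_artifacts, self.n_repeat_artifacts)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_lineages * self.tumors_per_lineage == 0:
            raise ValueError("cohort must contain at least one tumor")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        if not 0 <= self.strand_split <= 1:
            raise ValueError("strand_split must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    # sample naming -------------------------------------------------------
    def tumor_names(self, lineage: int) -> list[str]:
        return [f"L{lineage}T{i + 1}" for i in range(self.tumors_per_lineage)]

    @property
    def tumors(self) -> list[str]:
        return [t for lin in range(1, self.n_lineages + 1) for t in self.tumor_names(lin)]

    @property
    def highcov_normals(self) -> list[str]:
        return [f"H{i + 1}" for i in range(self.n_highcov_normals)]

    @property
    def lowcov_normals(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_lowcov_normals)]

    @property
    def samples(self) -> list[str]:
        return self.tumors + self.highcov_normals + self.lowcov_normals

    @property
    def reference_sample(self) -> str:
        """The normal whose genome stands in for the reference assembly."""
        if not self.n_highcov_normals:
            raise ValueError("no high-coverage normals configured")
        return self.highcov_normals[0]


def simulate_regions(config: CohortConfig, n_scaffolds: int = 5,
                     scaffold_length: int = 1_000_000) -> RegionAnnotation:
    """Toy scaffold-level reference annotation: ``n_scaffolds`` chromosome-
    assigned scaffolds plus one unplaced, contig joins every 100 kb, and a
    sprinkling of short simple repeats."""
    rng = _rng(config.seed, 1)
    lengths = {f"scf{i + 1}": scaffold_length for i in range(n_scaffolds + 1)}
    chrom = {f"scf{i + 1}": str(i % 5 + 1) for i in range(n_scaffolds)}
    repeats = {}
    bounds = {}
    for scf in lengths:
        starts = rng.integers(2000, scaffold_length - 2000, size=20)
        repeats[scf] = np.sort(starts)[:, None] + np.array([[0, 50]])
        bounds[scf] = np.arange(100_000, scaffold_length, 100_000)
    return RegionAnnotation(scaffold_lengths=lengths, chromosome_of=chrom,
                            repeats=repeats, contig_bounds=bounds)


def _safe_positions(rng, ann: RegionAnnotation, n: int, scaffolds: list[str]) -> list[tuple[str, int]]:
    out = []
    while len(out) < n:
        scf = scaffolds[rng.integers(len(scaffolds))]
        pos = int(rng.integers(1, ann.scaffold_lengths[scf] + 1))
        if not ann.is_excluded(scf, pos):
            out.append((scf, pos))
    return out


def simulate_cohort(
    config: CohortConfig,
    signature_matrix: pd.DataFrame | None = None,
    signature_weights: np.ndarray | None = None,
    annotation: RegionAnnotation | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an allele-support table plus a truth table.

    Variant categories planted: population germline variants (population
    allele frequency ~ U(0.2, 0.8)); trunk somatic variants heterozygous in
    both tumors of one lineage; tumor-unique somatic variants; and optional
    artifact classes that the post-genotyping filters are designed to remove.

    If a signature matrix (rows = signatures, columns = the 96 trinucleotide
    channels) is given, each somatic SNV draws a generating signature from
    ``signature_weights`` and its ref/alt/context from that signature's
    channel distribution; the truth table records the generating signature
    (1-based row index).

    Returns ``(table, truth)``. ``truth`` has one row per variant: category
    (``germline`` / ``trunk_somatic`` / ``unique_somatic`` / ``artifact``),
    lineage, tumor, generating ``signature``, and ``vaf:<sample>`` columns of
    expected VAFs.
    """
    ann = annotation or simulate_regions(config)
    placed = sorted(ann.chromosome_of)
    rng = _rng(config.seed, 2)

    tumors_by_lin = {lin: config.tumor_names(lin) for lin in range(1, config.n_lineages + 1)}
    samples = config.samples
    lowcov = set(config.lowcov_normals)
    normals = config.highcov_normals + config.lowcov_normals

    if signature_matrix is not None:
        S = signature_matrix.to_numpy(dtype=float)
        Wsig = (np.asarray(signature_weights, dtype=float)
                if signature_weights is not None else np.full(len(S), 1 / len(S)))
        if Wsig.shape != (len(S),) or not np.isclose(Wsig.sum(), 1):
            raise ValueError("signature weights must sum to 1, one per signature")
    else:
        S, Wsig = None, None

    rows: list[dict] = []
    truth_rows: list[dict] = []

    def draw_context():
        if S is None:
            ch = CHANNELS_96[rng.integers(96)]
            return ch, 1
        k = int(rng.choice(len(S), p=Wsig))
        ch = CHANNELS_96[int(rng.choice(96, p=S[k] / S[k].sum()))]
        return ch, k + 1

    def add_variant(category, vafs, *, lineage=None, tumor=None, vclass=None,
                    strand_split=None, in_repeat=False):
        if vclass is None:
            vclass = "indel" if rng.random() < config.indel_fraction else "SNV"
        if vclass == "SNV":
            channel, sig = draw_context()
            ref, alt, _ = channel_to_mutation(channel)
        else:
            ref, alt, sig = "A", "AT", 0
        if in_repeat:
            scf = placed[rng.integers(len(placed))]
            iv = ann.repeats[scf][rng.integers(len(ann.repeats[scf]))]
            pos = int(iv[0]) + 1 + int(rng.integers(50))
        else:
            (scf, pos), = _safe_positions(rng, ann, 1, placed)
        row = {"scaffold": scf, "chromosome": ann.chromosome_of.get(scf, ""),
               "pos": pos, "ref": ref, "alt": alt, "vclass": vclass}
        trow = {"category": category, "lineage": lineage or 0, "tumor": tumor or "",
                "signature": sig}
        split = config.strand_split if strand_split is None else strand_split
        for s in samples:
            mean_d = config.lowcov_mean_depth if s in lowcov else config.mean_depth
            depth = int(rng.poisson(mean_d))
            v = float(np.clip(vafs.get(s, 0.0) + config.noise_rate, 0, 1))
            var = int(rng.binomial(depth, v)) if depth else 0
            fwd = int(rng.binomial(var, split)) if var else 0
            row[f"{s}:fwd"], row[f"{s}:rev"], row[f"{s}:depth"] = fwd, var - fwd, depth
            trow[f"vaf:{s}"] = v
        rows.append(row)
        truth_rows.append(trow)

    # germline: population variants at frequency f; tumors carry founder genotype
    for _ in range(config.n_germline):
        f = rng.uniform(0.2, 0.8)
        vafs = {}
        for s in normals:
            g = int(rng.binomial(2, f))
            if config.avoid_ref_hom and s == config.reference_sample and g == 2:
                g = 1  # hom-alt sites in the reference animal are unascertainable
            vafs[s] = g / 2
        for lin, tums in tumors_by_lin.items():
            gf = int(rng.binomial(2, f))       # founder genotype
            gh = int(rng.binomial(2, f))       # residual host cells
            for t in tums:
                vafs[t] = config.purity * gf / 2 + (1 - config.purity) * gh / 2
        add_variant("germline", vafs)

    # trunk somatic: heterozygous in both tumors of one lineage
    lins = list(tumors_by_lin)
    for i in range(config.n_trunk):
        lin = lins[i % len(lins)]
        vafs = {t: config.purity * 0.5 for t in tumors_by_lin[lin]}
        add_variant("trunk_somatic", vafs, lineage=lin)

    # tumor-unique somatic
    all_tumors = config.tumors
    for i in range(config.n_unique):
        t = all_tumors[i % len(all_tumors)]
        lin = int(t[1])
        add_variant("unique_somatic", {t: config.purity * 0.5}, lineage=lin, tumor=t)

    # artifact classes (planted targets for each filter)
    ref = config.reference_sample if config.n_highcov_normals else None
    for _ in range(config.n_ref_artifacts):
        vafs = {s: 0.5 for s in samples}
        vafs[ref] = 1.0
        add_variant("artifact", vafs, tumor="ref_artifact", vclass="SNV")
    for _ in range(config.n_strand_artifacts):
        vafs = {t: 0.5 for t in all_tumors}
        add_variant("artifact", vafs, tumor="strand_artifact", vclass="SNV",
                    strand_split=0.02)
    for _ in range(config.n_noise_artifacts):
        vafs = {s: 0.05 for s in samples}
        add_variant("artifact", vafs, tumor="noise_artifact", vclass="SNV")
    for _ in range(config.n_repeat_artifacts):
        vafs = {t: 0.5 for t in all_tumors}
        add_variant("artifact", vafs, tumor="repeat_artifact", vclass="SNV",
                    in_repeat=True)

    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    table.index.name = truth.index.name = "variant_id"
    return table, truth


# ---------------------------------------------------------------------------
# mutation spectra
# ---------------------------------------------------------------------------

def simulate_mutation_spectrum(weights, signature_matrix: pd.DataFrame, n: int,
                               seed: int = 0) -> pd.Series:
    """Draw ``n`` mutations from a mixture of signatures.

    ``weights`` (length K, summing to 1) mixes the rows of
    ``signature_matrix`` (K x 96, rows summing to 1); counts are a single
    multinomial draw from the mixture distribution.
    """
    w = np.asarray(weights, dtype=float)
    S = signature_matrix.to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.isclose(w.sum(), 1):
        raise ValueError("weights must sum to 1")
    if S.shape != (len(w), 96):
        raise ValueError("signature matrix must be K x 96")
    theta = w @ S
    theta = theta / theta.sum()
    counts = _rng(seed, 3).multinomial(n, theta)
    return pd.Series(counts, index=CHANNELS_96, name="count")


# ---------------------------------------------------------------------------
# population panel
# ---------------------------------------------------------------------------

def simulate_population_panel(
    n_individuals: int = 60,
    n_snps: int = 320,
    n_pops: int = 2,
    fst_like_divergence: float = 0.8,
    missing_rate: float = 0.0,
    tumor_from_pop: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genotype panel (individuals x SNPs, codes {0, 0.5, 1, NaN}) from
    ``n_pops`` subpopulations whose allele frequencies diverge by
    ``fst_like_divergence`` (0 = panmictic; 0.8 gives 0.1-vs-0.9 at two
    populations), plus a ``tumor`` row copied from the first individual
    (the founder) of population ``tumor_from_pop``.

    Returns ``(panel, labels)`` where labels give each row's population
    (the tumor row is labeled ``tumor(<pop>)``).
    """
    if n_pops < 2:
        raise ValueError("need at least two populations")
    if missing_rate >= 1:
        raise ValueError("missing_rate must be < 1")
    rng = _rng(seed, 4)
    # population allele frequencies spread around 0.5
    offsets = np.linspace(-0.5, 0.5, n_pops) * fst_like_divergence
    freqs = np.clip(0.5 + offsets[:, None] + rng.normal(0, 0.02, size=(n_pops, n_snps)),
                    0.02, 0.98)
    per_pop = np.array_split(np.arange(n_individuals), n_pops)
    geno = np.empty((n_individuals, n_snps))
    labels = np.empty(n_individuals, dtype=object)
    for p, idx in enumerate(per_pop):
        geno[idx] = rng.binomial(2, freqs[p], size=(len(idx), n_snps)) / 2
        labels[idx] = f"pop{p}"
    founder = per_pop[tumor_from_pop][0]
    tumor_row = geno[founder].copy()
    geno = np.vstack([geno, tumor_row])
    labels = np.append(labels, f"tumor(pop{tumor_from_pop})")
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno = np.where(mask, np.nan, geno)
    names = [f"ind{i + 1}" for i in range(n_individuals)] + ["tumor"]
    panel = pd.DataFrame(geno, index=names,
                         columns=[f"snp{j + 1}" for j in range(n_snps)])
    return panel, pd.Series(labels, index=names, name="population")


# ---------------------------------------------------------------------------
# amplicon validation experiment
# ---------------------------------------------------------------------------

def simulate_amplicon_experiment(
    n_loci: int = 96,
    depth: int = 70_000,
    background_shape: float = 2.0,
    background_scale: float = 5e-4,
    true_vaf: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus base counts from deep amplicon sequencing.

    Each of the three non-reference bases accrues error reads at a rate drawn
    from Gamma(shape, scale); at loci carrying a real variant
    (``true_vaf > 0``) the declared alternative base additionally receives
    reads at ``true_vaf``. Null experiments (``true_vaf = 0``) leave the
    alternative base behaving exactly like background — the regime for
    checking the validation test's false-positive rate.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(seed, 5)
    rows = []
    for i in range(n_loci):
        ref, alt, bg1, bg2 = rng.permutation(_BASES)
        counts = {b: 0 for b in "ACGT"}
        for b in (alt, bg1, bg2):
            rate = rng.gamma(background_shape, background_scale)
            if b == alt:
                rate += true_vaf
            counts[b] = int(rng.binomial(depth, min(rate, 1.0)))
        counts[ref] = depth - sum(counts.values())
        rows.append({"locus": f"locus{i + 1}", "ref": ref, "alt": alt,
                     "depth": depth, **{f"count_{b}": counts[b] for b in "ACGT"}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CNV bins
# ---------------------------------------------------------------------------

def simulate_cnv_bins(
    segments: pd.DataFrame,
    n_bins: int = 2000,
    bin_size: int = 500,
    depth: float = 70.0,
    samples: list[str] | None = None,
    scaffold: str = "scf1",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin read counts with planted copy-number segments.

    ``segments`` needs columns ``start_bin``, ``end_bin`` (half-open, in
    bins), ``cn``, and ``samples`` (iterable of affected sample names).
    Background copy number is 2 everywhere; bin counts are
    Poisson(depth x CN / 2). Segments must not overlap for the same sample.
    """
    samples = samples or ["L1T1", "L1T2", "H1"]
    rng = _rng(seed, 6)
    cn = {s: np.full(n_bins, 2.0) for s in samples}
    for _, seg in segments.iterrows():
        b0, b1 = int(seg["start_bin"]), int(seg["end_bin"])
        if not 0 <= b0 < b1 <= n_bins:
            raise ValueError("segment outside binned region")
        for s in seg["samples"]:
            if np.any(cn[s][b0:b1] != 2.0):
                raise ValueError("overlapping segments for sample " + s)
            cn[s][b0:b1] = seg["cn"]
    out = pd.DataFrame({
        "scaffold": scaffold,
        "start": np.arange(n_bins) * bin_size,
        "end": (np.arange(n_bins) + 1) * bin_size,
    })
    for s in samples:
        out[s] = rng.poisson(depth * cn[s] / 2)
    return out


# ---------------------------------------------------------------------------
# breakpoint junctions
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(4, size=n)])


def simulate_junctions(
    n: int = 100,
    homology_len_range: tuple[int, int] = (1, 10),
    insertion_len_range: tuple[int, int] = (1, 10),
    flank: int = 150,
    ext: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Assembled breakpoint contigs with known junction classes.

    Each record carries a contig spanning a rearrangement junction, the two
    local reference segments (A side extending past the breakpoint, B side
    preceding it), and the true class: ``blunt``, ``microhomology`` of length
    k, or ``insertion`` of length k. Flanking sequence is random but
    construction enforces that the first non-matching base on each side
    breaks the match, so the class is exactly recoverable by maximal-overlap
    search.
    """
    rng = _rng(seed, 7)
    classes = ["blunt", "microhomology", "insertion"]
    rows = []
    for i in range(n):
        cls = classes[int(rng.integers(3))]
        if cls == "microhomology":
            k = int(rng.integers(homology_len_range[0], homology_len_range[1] + 1))
        elif cls == "insertion":
            k = int(rng.integers(insertion_len_range[0], insertion_len_range[1] + 1))
        else:
            k = 0
        if k == 0:
            cls = "blunt"
        while True:
            L, R = _random_seq(rng, flank), _random_seq(rng, flank)
            X, Y = _random_seq(rng, ext), _random_seq(rng, ext)
            if cls == "microhomology":
                H = _random_seq(rng, k)
                contig, refA, refB = L + H + R, L + H + X, Y + H + R
                ok = X[0] != R[0] and Y[-1] != L[-1]
            elif cls == "insertion":
                ins = _random_seq(rng, k)
                contig, refA, refB = L + ins + R, L + X, Y + R
                ok = ins[0] != X[0] and ins[-1] != Y[-1]
            else:
                contig, refA, refB = L + R, L + X, Y + R
                ok = X[0] != R[0] and Y[-1] != L[-1]
            if ok:
                break
        rows.append({"junction_id": f"jx{i + 1}", "contig": contig,
                     "refA": refA, "refB": refB, "true_class": cls,
                     "true_length": k})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

def write_vcf(table: pd.DataFrame, path: str) -> None:
    """Write the allele-support table as a minimal multi-sample VCF v4.2.

    FORMAT fields: ``DP`` (total depth), ``ADF``/``ADR`` (forward/reverse
    variant-allele depth).
    """
    from .filters import sample_names
    samples = sample_names(table)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for scf in pd.unique(table["scaffold"]):
            fh.write(f"##contig=<ID={scf}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=ADF,Number=1,Type=Integer,Description="Forward-strand variant allele depth">\n')
        fh.write('##FORMAT=<ID=ADR,Number=1,Type=Integer,Description="Reverse-strand variant allele depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for idx, row in table.iterrows():
            fields = [str(row["scaffold"]), str(row["pos"]), f"var{idx}",
                      row["ref"], row["alt"], ".", ".", ".", "DP:ADF:ADR"]
            for s in samples:
                fields.append(f"{row[f'{s}:depth']}:{row[f'{s}:fwd']}:{row[f'{s}:rev']}")
            fh.write("\t".join(fields) + "\n")
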