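"""Post-genotyping variant filters for multi-sample tumor/host cohorts.

The allele-support table is a plain :class:`pandas.DataFrame` with one row per
variant and the metadata columns ``scaffold``, ``chromosome``, ``pos``
(1-based), ``ref``, ``alt``, ``vclass`` (``SNV`` or ``indel``), followed by
three columns per sample named ``<sample>:fwd``, ``<sample>:rev`` and
``<sample>:depth`` holding forward/reverse variant-supporting read counts and
total read depth.

Filters implemented here remove, in any order (each is a pure row predicate):

* reference-assembly artifacts — sites where the animal used to build the
  reference assembly shows a near-homozygous variant allele fraction;
* strand-biased calls — pooled variant support heavily skewed to one strand;
* recurrent low-VAF sequencing noise shared with host samples;
* calls in unreliable regions — near simple repeats, near contig/scaffold
  boundaries, or on scaffolds not assigned to a chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["scaffold", "chromosome", "pos", "ref", "alt", "vclass"]

__all__ = [
    "META_COLUMNS",
    "RegionAnnotation",
    "sample_names",
    "variant_reads",
    "compute_vaf",
    "filter_reference_artifacts",
    "filter_strand_bias",
    "filter_noise",
    "filter_regions",
    "apply_all_filters",
    "read_support_table",
    "write_support_table",
    "read_vcf",
]


# ---------------------------------------------------------------------------
# table helpers
# ---------------------------------------------------------------------------

def sample_names(table: pd.DataFrame) -> list[str]:
    """Sample identifiers inferred from ``<sample>:depth`` columns, in order."""
    return [c[:-6] for c in table.columns if c.endswith(":depth")]


def variant_reads(table: pd.DataFrame, sample: str) -> pd.Series:
    """Total (forward + reverse) variant-supporting reads for one sample."""
    return table[f"{sample}:fwd"] + table[f"{sample}:rev"]


def compute_vaf(table: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Return a variants x samples frame of variant allele fractions.

    VAF is the proportion of reads at the site supporting the variant allele.
    Sites with zero depth get ``NaN`` (undefined rather than zero). Variant
    reads exceeding depth raise ``ValueError``.
    """
    samples = samples or sample_names(table)
    out = {}
    for s in samples:
        reads = variant_reads(table, s).to_numpy(dtype=float)
        depth = table[f"{s}:depth"].to_numpy(dtype=float)
        if np.any(reads > depth):
            raise ValueError(f"variant reads exceed depth for sample {s!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            vaf = np.where(depth > 0, reads / np.where(depth > 0, depth, 1), np.nan)
        out[s] = vaf
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# region annotation
# ---------------------------------------------------------------------------

@dataclass
class RegionAnnotation:
    """Reference annotations used by the region filter.

    ``repeats`` and ``contig_bounds`` map scaffold -> arrays of 0-based
    half-open intervals / boundary positions; ``scaffold_lengths`` maps
    scaffold -> length; ``chromosome_of`` maps scaffold -> chromosome name
    (scaffolds absent from the map are treated as unassigned).
    """

    scaffold_lengths: dict[str, int]
    chromosome_of: dict[str, str] = field(default_factory=dict)
    repeats: dict[str, np.ndarray] = field(default_factory=dict)
    contig_bounds: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scf, iv in list(self.repeats.items()):
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            if np.any(iv[:, 0] < 0) or np.any(iv[:, 1] < iv[:, 0]):
                raise ValueError(f"malformed repeat intervals on {scf}")
            order = np.argsort(iv[:, 0], kind="stable")
            self.repeats[scf] = iv[order]
        for scf, b in list(self.contig_bounds.items()):
            self.contig_bounds[scf] = np.sort(np.asarray(b, dtype=np.int64))

    @classmethod
    def from_bed(
        cls,
        scaffold_lengths: dict[str, int],
        chromosome_of: dict[str, str],
        repeats_bed: str | None = None,
        contig_bounds_bed: str | None = None,
    ) -> "RegionAnnotation":
        """Build from BED files (0-based half-open, as emitted by e.g. TRF)."""
        repeats: dict[str, list] = {}
        bounds: dict[str, list] = {}
        if repeats_bed is not None:
            bed = pd.read_csv(repeats_bed, sep="\t", header=None, comment="#",
                              usecols=[0, 1, 2], names=["scf", "start", "end"])
            for scf, grp in bed.groupby("scf"):
                repeats[str(scf)] = grp[["start", "end"]].to_numpy()
        if contig_bounds_bed is not None:
            bed = pd.read_csv(contig_bounds_bed, sep="\t", header=None, comment="#",
                              usecols=[0, 1, 2], names=["scf", "start", "end"])
            for scf, grp in bed.groupby("scf"):
                # contig intervals: both edges are boundaries
                bounds[str(scf)] = np.unique(grp[["start", "end"]].to_numpy().ravel())
        return cls(scaffold_lengths=dict(scaffold_lengths),
                   chromosome_of=dict(chromosome_of),
                   repeats={k: np.asarray(v) for k, v in repeats.items()},
                   contig_bounds={k: np.asarray(v) for k, v in bounds.items()})

    def is_excluded(self, scaffold: str, pos: int, repeat_pad: int = 5,
                    contig_pad: int = 500, scaffold_pad: int = 1000) -> bool:
        """True if the 1-based position falls in any excluded window.

        Windows are inclusive on both sides. Positions outside the scaffold
        raise ``ValueError``.
        """
        length = self.scaffold_lengths.get(scaffold)
        if length is None:
            raise ValueError(f"unknown scaffold {scaffold!r}")
        if not (1 <= pos <= length):
            raise ValueError(f"position {pos} outside scaffold {scaffold!r} (len {length})")
        if scaffold not in self.chromosome_of:
            return True
        if pos <= scaffold_pad or pos > length - scaffold_pad:
            return True
        for b in self.contig_bounds.get(scaffold, ()):  # b is a 0-based edge
            if abs(pos - b) <= contig_pad:
                return True
        iv = self.repeats.get(scaffold)
        if iv is not None and len(iv):
            # repeat [s, e) 0-based -> 1-based inclusive [s+1, e]; pad both sides
            lo = iv[:, 0] + 1 - repeat_pad
            hi = iv[:, 1] + repeat_pad
            i = np.searchsorted(lo, pos, side="right")
            if np.any(hi[:i] >= pos):
                return True
        return False


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_reference_artifacts(table: pd.DataFrame, reference_sample: str,
                               threshold: float = 0.9) -> pd.DataFrame:
    """Drop variants with VAF strictly above ``threshold`` in the sample used
    to assemble the reference genome (such calls flag assembly errors, not
    real variation). Ties at the threshold are kept."""
    if f"{reference_sample}:depth" not in table.columns:
        raise KeyError(f"unknown sample {reference_sample!r}")
    vaf = compute_vaf(table, [reference_sample])[reference_sample]
    keep = ~(vaf > threshold)  # NaN (zero depth) is kept
    return table.loc[keep.fillna(True)]


def filter_strand_bias(table: pd.DataFrame, high_cov: int = 11,
                       frac: float = 0.2, min_reads: int = 2) -> pd.DataFrame:
    """Strand-bias filter on variant support pooled across all samples.

    At sites with total coverage (summed depth over samples) >= ``high_cov``,
    pooled variant support must have at least ``frac`` of reads on each
    strand; ties at the fraction are kept. At lower-coverage sites, at least
    ``min_reads`` supporting reads are required on each strand. Rows with no
    variant support anywhere are kept (nothing to assess).
    """
    samples = sample_names(table)
    fwd = sum(table[f"{s}:fwd"] for s in samples)
    rev = sum(table[f"{s}:rev"] for s in samples)
    depth = sum(table[f"{s}:depth"] for s in samples)
    total = fwd + rev
    with np.errstate(divide="ignore", invalid="ignore"):
        f_frac = np.where(total > 0, fwd / np.where(total > 0, total, 1), 0.5)
    high = depth >= high_cov
    ok_high = (f_frac >= frac) & (f_frac <= 1 - frac)
    ok_low = (fwd >= min_reads) & (rev >= min_reads)
    keep = np.where(total > 0, np.where(high, ok_high, ok_low), True)
    return table.loc[np.asarray(keep, dtype=bool)]


def filter_noise(table: pd.DataFrame, host_samples: list[str],
                 vaf_cut: float = 0.2) -> pd.DataFrame:
    """Recurrent sequencing-noise filter.

    A variant is dropped iff every sample with >= 1 supporting read has
    VAF < ``vaf_cut`` and at least one host sample has >= 1 supporting read.
    Such low-fraction support shared with hosts marks systematic noise or
    alignment artifacts rather than clonal variation.
    """
    if not host_samples:
        raise ValueError("host sample set must be non-empty")
    samples = sample_names(table)
    missing = set(host_samples) - set(samples)
    if missing:
        raise KeyError(f"host samples not in table: {sorted(missing)}")
    vaf = compute_vaf(table)
    supported = pd.DataFrame(
        {s: variant_reads(table, s) >= 1 for s in samples}, index=table.index)
    low = vaf < vaf_cut
    # all supported samples low-VAF (vacuously true if no support anywhere)
    all_low = (~supported | low).all(axis=1)
    host_support = supported[list(host_samples)].any(axis=1)
    drop = all_low & host_support & supported.any(axis=1)
    return table.loc[~drop]


def filter_regions(table: pd.DataFrame, annotation: RegionAnnotation,
                   repeat_pad: int = 5, contig_pad: int = 500,
                   scaffold_pad: int = 1000) -> pd.DataFrame:
    """Drop variants near simple repeats (±``repeat_pad`` bp), near contig
    edges (±``contig_pad``) or scaffold ends (±``scaffold_pad``), and any
    variant on a scaffold not assigned to a chromosome."""
    keep = [
        not annotation.is_excluded(scf, int(pos), repeat_pad, contig_pad, scaffold_pad)
        for scf, pos in zip(table["scaffold"], table["pos"])
    ]
    return table.loc[keep]


def apply_all_filters(table: pd.DataFrame, reference_sample: str,
                      host_samples: list[str],
                      annotation: RegionAnnotation | None = None,
                      log: list | None = None) -> pd.DataFrame:
    """Run the full filter cascade; optionally collect a removal log.

    ``log``, if given, is extended with ``(variant_index, filter_name)``
    pairs, one per removed row.
    """
    steps: list[tuple[str, pd.DataFrame]] = []
    out = table
    for name, fn in [
        ("reference_artifact", lambda t: filter_reference_artifacts(t, reference_sample)),
        ("strand_bias", filter_strand_bias),
        ("noise", lambda t: filter_noise(t, host_samples)),
    ]:
        nxt = fn(out)
        steps.append((name, out.index.difference(nxt.index)))
        out = nxt
    if annotation is not None:
        nxt = filter_regions(out, annotation)
        steps.append(("regions", out.index.difference(nxt.index)))
        out = nxt
    if log is not None:
        for name, removed in steps:
            log.extend((idx, name) for idx in removed)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_support_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_vcf(path: str) -> pd.DataFrame:
    """Read a multi-sample VCF into an allele-support table.

    Per-sample read support comes from the FORMAT fields ``DP`` (total
    depth) and ``ADF``/``ADR`` (forward/reverse variant-allele depth, the
    dialect written by :func:`devilseq.simulate.write_vcf`). Records
    lacking strand-resolved allele depths get ``fwd = rev = 0`` with a
    warning — the strand-bias filter then treats them as unassessable.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    missing_strand = 0
    for rec in vcf:
        row = {"scaffold": rec.CHROM, "chromosome": rec.CHROM,
               "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0],
               "vclass": "SNV" if len(rec.REF) == 1 and len(rec.ALT[0]) == 1
               else "indel"}
        try:
            adf = rec.format("ADF")[:, 0]
            adr = rec.format("ADR")[:, 0]
        except (KeyError, TypeError):
            adf = adr = np.zeros(len(samples), dtype=int)
            missing_strand += 1
        dp = rec.format("DP")[:, 0]
        for i, s in enumerate(samples):
            row[f"{s}:fwd"] = int(max(adf[i], 0))
            row[f"{s}:rev"] = int(max(adr[i], 0))
            row[f"{s}:depth"] = int(max(dp[i], 0))
        rows.append(row)
    if missing_strand:
        warnings.warn(f"{missing_strand} records lack strand-resolved allele "
                      "depths; strand-bias filtering is skipped for them")
    return pd.DataFrame(rows)


def read_support_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t",
                        dtype={"scaffold": str, "chromosome": str, "ref": str,
                               "alt": str})
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        warnings.warn(f"support table missing metadata columns: {missing}")
    return table
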