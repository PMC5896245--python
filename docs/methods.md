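# Methods

This note records the models behind each module, the parameter choices and
their defaults, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one reasonable reading existed.

## Cohort model and synthetic data

A transmissible-cancer cohort is modeled as `n_lineages` clonal tumor
lineages (default 2) sampled as `tumors_per_lineage` tumors each (default
2), three high-coverage normal hosts and a low-coverage normal panel
(default 43 animals, emulating an ascertainment genome plus additional
population genomes). Read counts follow the simplest model consistent with
the count-based thresholds the pipeline uses:

* per-site depth ~ Poisson(`mean_depth`, default 70; `lowcov_mean_depth`,
  default 10, for the panel);
* variant reads ~ Binomial(depth, expected VAF), where expected VAF combines
  the carried genotype with tumor purity:
  `purity·g_founder/2 + (1 − purity)·g_host/2` for tumors, `g/2` for
  normals;
* forward-strand variant reads ~ Binomial(variant reads, `strand_split`,
  default 0.5).

Germline variants get a population allele frequency ~ U(0.2, 0.8) and
independent genotypes per animal; trunk somatic variants are heterozygous in
both tumors of one lineage; tumor-unique variants in exactly one tumor.
Optional artifact classes plant one target per filter: reference-sample
VAF-1.0 sites, strand-skewed calls (forward fraction 0.02), low-VAF
(0.05) support shared with hosts, and repeat-adjacent calls. By default the
reference animal's germline genotypes avoid homozygous-alternative states,
since such sites would be absorbed into the reference assembly and are not
ascertainable as variants.

All generators derive deterministic substreams from one master seed via
`numpy.random.SeedSequence`, so identical configurations give byte-identical
outputs.

The generators emulate *genotyped tables*, not reads: no sequencing-error
base substitution model, no mapping ambiguity, no real genome sequence, no
linkage between SNP-panel loci, and no overdispersion beyond
Poisson/binomial sampling. Passing recovery tests therefore demonstrates
correctness of the decision rules and estimators under their stated
sampling assumptions, not robustness to alignment artifacts in real data.

## Variant filters

Thresholds follow the strict/non-strict boundaries as used throughout:
reference-sample VAF **> 0.9** discards (0.9 exactly is kept); strand
fraction ties at 20% are kept; noise filter drops a row iff every sample
with ≥ 1 supporting read has VAF **< 0.2** and at least one host has ≥ 1
read. Strand support is pooled across all samples (the rule is a per-region
statement about the whole cohort); per-sample application is a possible
alternative reading and can be emulated by filtering single-sample tables.
Window exclusions are inclusive on both sides; positions are 1-based;
BED-style annotations (0-based half-open) are converted internally. Rows
lacking strand-resolved allele depths (some VCF dialects) skip the
strand-bias filter with a warning rather than being dropped.

Each filter is a pure row predicate, hence idempotent and order-independent;
`apply_all_filters` fixes a canonical order only for the removal log.

## Lineage classification

The category cascade is germline → shared → lineage-specific → tumor-unique
→ remainder, with germline defined as ≥ 5 reads in any high-coverage normal
or ≥ 1 read in any panel normal, and all somatic categories requiring ≥ 5
reads per carrier tumor, < 5 in non-carrier tumors, < 5 in high-coverage
normals and 0 in the panel. Where source descriptions oscillate between
"< 5" and "≤ 5" for the exclusion side, "< 5" is used uniformly (the
complement of the ≥ 5 carrier rule); both thresholds are arguments.
The "≥ 1 read in the panel" germline clause is interpreted as *any* panel
member, the complement of the somatic "0 reads in all of them" requirement.

Purity: for founder-heterozygous, host-homozygous-reference sites the
expected VAF is (1 − h)/2, so the host fraction is estimated as
h = 1 − 2·median(VAF), clipped to [0, 1], with the interquartile range of
per-locus implied values as a spread measure. The estimator is deliberately
median-based: copy-number-altered regions bias individual loci but not the
bulk of the distribution. At 1,000 informative loci and depth 70 the
recovery error stays below 0.01 for host fractions up to 0.2.

## Signature refitting

Spectra use the standard 96-category convention (six pyrimidine-context
substitution types × 16 flank combinations, catalog ordering);
purine-reference mutations are reverse-complemented. Triplet normalization
divides each channel by its trinucleotide's frequency (32 pyrimidine-context
triplets) and rescales to 100%; applying it with a genome's own frequencies
makes spectra composition-agnostic and hence comparable across genomes.

The mixture model is W ∼ Dirichlet(1), θ = W·S, M ∼ Multinomial(θ).
Sampling uses data augmentation, which is exact for this model: given W the
latent attribution of each category's counts to signatures is multinomial
with probabilities ∝ W_k·S_kc; given attributions, W is
Dirichlet(1 + totals). Each sweep is a joint blocked update, mixing fast
(lag-1 autocorrelation ≈ 0.18 at K = 2); the default 10,000 retained sweeps
follow a burn-in of max(200, 10%). Correctness is verified against direct
fine-grid summation of the posterior for K = 2 (agreement of the posterior
mean within 5·10⁻⁴ in practice, asserted at 0.005) and interval calibration
against the exact grid quantiles. The point estimate is the posterior mean;
intervals are 95% equal-tailed. K = 1 short-circuits to the degenerate
exact posterior. Duplicate signature rows are non-identifiable by design;
only their weight sum is recovered, which the symmetry test asserts.

Stepwise selection fits the base set, then each base ∪ {candidate} with the
same sampler settings and seed, and accepts candidates whose reconstruction
cosine (against the observed proportions) gains ≥ 0.02. At the scale of a
few hundred mutations this threshold is deliberately conservative: in
replicated null studies (data from the base pair alone, n ≈ 600) no
candidate is accepted in the majority of runs.

`synthetic_signature_matrix` provides a deterministic synthetic stand-in
for a reference catalog — ten sparse, mutually distinguishable 96-channel
profiles — used by the simulation studies; it reproduces no published
catalog, and any catalog in the supported TSV layouts can be supplied
instead.

## Amplicon validation

Background error is measured by the two bases at each locus that are
neither reference nor predicted alternative (two observations per locus,
pooled). The gamma fit is maximum likelihood with location fixed at 0;
zero fractions are replaced by the half-read pseudo-fraction 1/(2·depth) to
keep the MLE finite (the fitting method and zero handling are this
package's choices; method-of-moments is the fallback, and numerically
constant backgrounds degrade to a fixed threshold). Validation requires
the alternative VAF to exceed the fitted distribution's q-quantile
(default 0.95). On null loci the flag rate is ≈ 1 − q when the gamma family
holds; at the design minimum VAF of 0.25 and ~70,000× depth, power is 1.

## Population structure

Panel filtering order: indels; ambiguous fragments (> 2 mismatches or total
gap length > 2 bp); repeat/contig-end/scaffold-end windows (5/500/1000 bp),
X-chromosome and unassigned scaffolds; tumor non-diploid regions; variation
ranking; one SNP per fragment (5′-most). "Limited variation" is formalized
as the modal genotype's share across individuals: SNPs are ranked by
1 − modal share and the top 40% most variable are kept (ceil on ties by
stable rank). Genotype coding from allele counts: < 7 reads → missing;
allele-1 fraction > 0.70 → 0; < 0.30 → 1; otherwise 0.5 (boundaries are
heterozygous, per the strict published inequalities).

Imputation adopts genotypes from the nearest SNP column by Euclidean
distance over pairwise-complete individuals, computed on pre-imputation
values only (single pass, so column order has no effect); a missing cell
takes the nearest column that is observed for that individual. Observed
genotypes are never altered and the operation is idempotent on complete
panels. Clustering is complete-linkage on Euclidean distances, exported as
Newick if needed; the same routine serves any samples × features matrix
(e.g. log-IC50 drug-response profiles).

## Copy number

Bin counts (500-bp bins) are normalized to each sample's modal count for
copy-ratio interpretation (diploid ≈ 1.0). Candidate tumor-unique segments
shorter than 5,000 bp (10 bins) are rejected outright. The
lineage-consistency check is a paired two-sided t-test on per-bin counts
between the two tumors of the lineage; for this test counts are scaled by
each sample's *genome-wide mean* rather than the integer mode — the mode
can differ by one count between samples, a systematic offset that a paired
test misreads as a copy-number difference (empirically 23% false
tumor-unique calls mode-normalized versus the nominal 1% mean-normalized).
Identical count vectors short-circuit to p = 1. Non-significant segments
(p ≥ 0.01) are relabeled shared: per-bin copy-number posteriors
(Poisson read-count likelihood over states 0–6, uniform prior, CN 0 kept at
a small residual rate of 0.05 haploid units) are averaged between tumors,
the median over bins taken per state, and the arg-max state assigned to
both tumors, ties resolved to the lower state.

The gene-level caller pools normalized bin coverages per sample group
(lineage 1 / lineage 2 / hosts), tests heterogeneity by one-way ANOVA at
α = 10⁻⁴, identifies the deviating group by Tukey's range test (a group
must differ from both others), and calls gain/loss only when the group's
mean differs from the rest by more than 0.25 on the normalized scale.
Normal-panel window profiles (10-kb windows) are normalized by each
sample's mean so profiles are comparable across sequencing depths.

## SV, junctions and PAV

SV labeling: > 10 supporting reads in total to retain; > 2 combined reads
across normals marks a likely germline polymorphism; somatic (one tumor) or
lineage-shared (both tumors) labels require > 10 reads per carrier and < 3
combined elsewhere. Rejected calls keep reason codes so labels partition
the input.

Junction classification finds the maximal contig prefix matching the
A-side reference and the maximal contig suffix matching the B-side; because
both predicates are monotone in length, binary search gives the exact
maximal extents. Overlap k > 0 → microhomology(k); gap k > 0 →
insertion(k, sequence); abutment → blunt; breakpoints are reported
left-aligned (the indel convention). The test suite checks exact agreement
with a brute-force enumeration of every split. The simulator constructs
junctions whose first off-junction base breaks the match on each side, so
truth is recoverable by maximal-overlap search; homology and insertion
lengths default to 0–20 bp with 150-bp flanks.

PAV screening keeps a contig iff its depth reaches 40% of the genome-wide
mean in at least one tumor and stays under 20% in every host — single-copy
presence in tumors, absence in normals.

## Study sizes and determinism

The bundled recovery studies (`devilseq.evaluation`, driven by the test
suite and `scripts/acceptance.py`) use: 20 replicates × 10,000 mutations
for weight recovery; 500 mutations for the grid-oracle comparison; 20
replicates × 600 mutations for selection specificity; a 1,800-variant
cohort at depth 70 for classification; 1,000 null + 200 true amplicon loci;
1,000 junctions; 1,000 purity loci per host fraction; a 60-animal × 320-SNP
panel; and 30 CNV replicates. These sizes make each check decisive (the
binomial/posterior noise is well below the asserted tolerances) while the
whole suite runs in about a minute. Credible-interval coverage over 20
replicates is itself binomial (sd ≈ 5% at nominal 95%), so values in the
high-80s can occur for a correct sampler; the calibration test against
exact grid quantiles pins the intervals directly.

## Known limitations

* The simulators draw independent sites; linkage, mapping artifacts and
  overdispersed coverage are out of scope.
* The imputation distance is unnormalized over pairwise-complete entries,
  which slightly favors low-overlap columns at high missingness; at the
  panel's ~5% missingness this is negligible.
* The junction classifier assumes the assembled contig matches the
  references exactly near the breakpoint (assembly errors would need an
  alignment-based front end).
* Signature refitting assumes the supplied matrix and the observed spectrum
  are on the same normalization scale; mixing a normalized matrix with raw
  counts is the caller's error to avoid.
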