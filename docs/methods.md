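# Methods

This note documents the models, conventions and design choices behind
`gcsig`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what each procedure assumes, which parameters
matter, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and strand conventions

All in-memory coordinates are 0-based half-open; VCF and GFF3 emission
converts to 1-based on write and back on read. Every SNV is collapsed onto
the strand carrying the pyrimidine reference base, giving the six classes
C>A, C>G, C>T, T>A, T>C, T>G; contexts (up to ±2 bp) are reverse-
complemented together with the alleles. Collapse is an involution: an SNV
and its reverse-complement presentation classify identically (property-
tested). Motifs use XpCpY notation for pure ±1 motifs (5′ flank, mutated
pyrimidine, 3′ flank) and an explicit offset notation for extensions.

## Somatic filtering

SNV rule: a tumor call is *germline* when an identical call (same alleles,
same genotype allele-set) exists in the normal; *somatic* when the variant
is absent from the normal calls, the normal genotype (allele set; phase is
ignored because caller output carries no reliable phase) differs from the
tumor's, and the normal sample shows fewer than two reads of the variant
allele; otherwise *rejected* with a machine-readable reason. "Fewer than
two" is a strict integer `< 2`, so exactly one supporting read still
passes. A missing normal support row for a tumor-unique site raises an
error rather than guessing — silent absence would be indistinguishable
from zero contamination. A normal sample with no call at a site is treated
as homozygous reference for the genotype comparison.

Indel rule: variant reads / total ≥ 0.20 on the exact rational (no
rounding, so 2/10 passes), at least one variant read on each strand, at
least 10 reads overlapping the site, and no indel call in the normal at
the same left-aligned site. Indels in both samples are normalised with the
standard left-alignment algorithm (trim shared trailing base, extend left;
trim shared leading base) before comparison, because positional dialects
between call sets otherwise create false somatic calls. Left alignment is
idempotent (property-tested). Multi-allelic records are decomposed into
biallelic records at VCF read time.

Every input call ends in exactly one of {somatic, germline, rejected}; the
audit TSV preserves the partition.

## Spectra, bias and region tests

Spectra are proportions of classified SNVs (not per-Mb rates); since the
bias statistic bᵢ = (sᵢ − gᵢ)/gᵢ divides two frequencies measured under
the same convention, the choice cancels. Per-class significance uses the
2×2 Pearson χ² (class vs rest × somatic vs germline) without Yates
correction by default — the counts in realistic runs are large — with a
continuity-correction flag for small tables. gᵢ = 0 with sᵢ > 0 is
reported as an undefined-bias error, never silently dropped.

The coding-excess test is a 2×2 (somatic vs germline) × (in-region vs
out) table; germline variants serve as the reference set rather than the
genomic footprint, so composition artefacts shared by both call sets
cancel. Region membership is half-open on the 0-based position. The
transcribed-strand test compares, per class, events whose pyrimidine lies
on the transcribed (template) strand versus the untranscribed strand
against a 50/50 χ²; SNVs overlapping genes on opposite strands are
ambiguous and are excluded but tallied.

## Context enrichment

For one mutation class the 2×2 table (somatic vs germline) × (motif vs no
motif) yields OR = (a/b)/(c/d) and a Pearson χ² p-value. Zero cells get
the Haldane–Anscombe +0.5 correction for the OR (flagged; the χ² uses the
raw table). The scan tests the eight single-base motifs at offsets −1/+1,
then extends Bonferroni-significant seeds by one further fixed position in
{−2, −1, +1, +2}; the correction family is everything tested for the
class. Windows are stored at up to ±2 bp (truncated and flagged at contig
ends, padded with N for matching, so a motif position outside a truncated
window never matches).

## MSI homopolymer analysis

Homopolymer tracts are maximal single-base runs (N breaks runs; runs at
contig ends count as maximal), scanned by a linear pass and verified in
tests against a regular-expression oracle. The MSI signature class is a
left-aligned single-base T deletion whose position falls inside a poly-T
tract. The background rate for tract length L pools (tract, sample) pairs
across the MSI-positive cohort: p = mutated pairs / (n_tracts ×
n_samples), with multiple deletions in one tract/sample counted once.
Pooling (rather than averaging per-sample rates) is the documented choice;
rates are estimated separately per tract length and base because the
deletion propensity grows steeply with tract length.

The recurrence test for a tract mutated in k of n MSI-positive samples is
the one-sided exact binomial tail P(X ≥ k), X ~ Binomial(n, p), computed
via the regularised incomplete beta function (scipy) and verified against
exact rational-arithmetic summation to relative error < 1e-12 for n ≤ 100.
The Bonferroni family defaults to the number of tracts of the tested
length in the evaluation region — each such tract is an implicit
hypothesis — and is configurable and recorded in the output. MSI status of
a sample is an input label; the package does not call MSI status from
markers.

## DNA-PET SV cluster QC

Superclusters are connected components under anchor overlap, where two
clusters are adjacent when *either* anchor of one intersects either anchor
of the other on the same chromosome (the either-anchor reading of
overlap); union-find over interval trees makes the result independent of
input order. The four retention criteria are size ≥ 6, both anchors
≥ 1000 bp, supercluster size ≤ 100 or own size ≥ 10 (strict > 100, rescue
at ≥ 10), and fused-region similarity score absent or ≤ 2000. The
similarity score is consumed as a precomputed column rather than running
an aligner, keeping the rule bit-exact and the package dependency-light.
Rejections are labelled with the first failing criterion in order.
Tumor/normal comparison matches clusters of the same SV type whose anchor
midpoints lie within a window (default 10 kbp, the long-insert library
scale) of each other; unmatched retained tumor clusters are somatic.

## Microbial screening

Reads are discarded when any 5-mer occurs more than three times, counted
with overlaps (the strictest deterministic reading); reads shorter than
5 bp carry no evidence and are kept but flagged. Species evidence pools
strains, counts distinct fixed 1-kbp windows ([i·1000, (i+1)·1000) tiles,
not sliding), and requires > 4 distinct windows, at least one uniquely
mapping read, and absence from the matched blood control.

The concentration estimate assumes clonal populations and uniform
coverage. The default reading treats the sequence yield of a population as
proportional to cell count × genome size, giving cells_s/cells_h =
(cov_s/size_s)/(cov_h/size_h); an alternative reading treating per-base
depth as directly proportional to cell count (ratio = cov_s/cov_h) is
available behind a flag because the underlying relation can be read either
way. The reading used is recorded in the result.

## Synthetic-data generator

The generator emulates the structure of a paired tumor/normal whole-genome
experiment at desk scale (default two 250-kbp chromosomes rather than a
3-Gbp genome; all analyses are per-site or per-tract, so problem size
scales counts, not logic):

* **Reference.** i.i.d. bases from a configurable composition. Planted
  homopolymer tracts are flank-protected (neighbouring bases forced to
  differ from the tract base) and background runs of the planted base are
  broken below the shortest planted length, so planted counts equal
  scanned counts exactly and count assertions can be exact. Genes with 1–3
  exons are placed uniformly without overlap to cover approximately the
  requested exon fraction (default 5%, a round figure near the human
  coding+UTR footprint).
* **Variants.** Somatic SNVs are drawn per class from a six-class mixture
  and placed by weighted sampling without replacement (Gumbel top-k) over
  sites whose collapsed reference base matches the class; context motifs
  multiply site weights (an infinite multiplier restricts the class to
  matching sites, used by forced-context tests), and exome-restricted
  classes are confined to exons. A class with no eligible site raises an
  error rather than silently undershooting, because silent undershoot
  corrupts recovery tests. Germline SNVs use their own mixture without
  context weighting. The default somatic mixture is C>A/T>A-heavy with
  multipliers CpCpT ×3.2, TpCpA ×1.7 for C>A and CpG ×1.2, GpC ×1.4 for
  the exome-restricted C>T class — the odds-ratio scale observed in
  gastric tumors; the default germline mixture is a transition-heavy
  polymorphism spectrum (C>T 0.31, T>C 0.33), a free parameter of the
  generator chosen to resemble human germline variation, since no
  numerical germline spectrum was available to copy.
* **MSI indels.** One Bernoulli trial per eligible poly-T tract at the
  per-tract rate (default 0.045, the 8T exome background measured in
  MSI-positive tumors), emitting a left-aligned single-T deletion.
* **Read support.** Depth is fixed at the mean when dispersion is 0,
  otherwise gamma-Poisson with variance mean + dispersion·mean²; variant
  reads are Binomial(depth, VAF) split 50/50 across strands. Normal
  samples see germline variants at the tumor VAF and somatic variants at a
  configurable contamination VAF (default 0), which exercises the "< 2
  reads in normal" boundary.
* **Auxiliary tables.** Tumor SV clusters are the union of the germline
  set (shared with the normal) and somatic-only clusters; microbial reads
  hit a requested number of distinct 1-kbp windows, with low-complexity
  reads built from repeated 5-mers on demand.

What passing synthetic tests shows — and does not. The generator plants
known signatures in i.i.d. sequence; recovery tests demonstrate that the
estimators are unbiased and correctly calibrated under the stated
sampling models. Real genomes add mappability artefacts, GC isochores,
repeat families beyond planted tracts, caller-specific error modes and
subclonal VAF structure, none of which are emulated; passing here does not
certify performance on those.

## Numerical choices and degenerate inputs

χ² tests fall back to (χ²=0, p=1) when a table margin is zero. Odds ratios
apply +0.5 only when a cell is zero, and flag it. Probability-vector
validation uses a 1e-9 tolerance on the sum. The binomial tail uses the
survival function directly (no log-space tricks needed at cohort sizes
n ≤ a few hundred). Empty indel sets yield an empty MSI summary with a
warning rather than an error. Ties in recurrence tables are broken by a
stable sort on the raw p-value.

## Pipeline determinism and problem sizes

Every stage derives its randomness from the single config seed (stage
offsets seed+1, seed+2, ... keep streams independent); reports contain no
timestamps, so identical config + seed gives byte-identical reports. The
default test-suite and acceptance problem sizes (20,000 SNVs for mixture
recovery, 5,000 for motif power, 12-sample MSI cohorts over ~80–120
tracts, 10,000 sites for filter-oracle agreement, 200 null replicates for
error-rate calibration) were chosen so that binomial sampling error is
several times smaller than the assertion tolerances they face.

## Known limitations

* No read-level simulation, mapping, CNV calling or breakpoint assembly;
  read support is consumed as a table and similarity scores as a column.
* The enrichment scan covers the fixed ±2 positional alphabet only; it is
  not a de-novo motif finder.
* The published odds ratios for context motifs were measured against an
  unavailable germline call set; the package supports germline-referenced
  enrichment (default) and recovers planted motifs, but printed OR values
  from the original data are treated as qualitative patterns, not
  regression targets.
* Gene placement in the generator is uniform; there is no synteny, no
  overlapping isoforms, and no expression stratification.
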