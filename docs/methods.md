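# Methods

## Scope and data model

`mik` analyzes the interactome formed by miRNAs and their mRNA targets as
measured by two families of experiments: chimera-producing AGO-CLIP variants
(CLASH, CLEAR-CLIP), which report one miRNA paired with one target fragment
per chimeric read, and conventional CLIP, which reports binding intervals
without miRNA identity.  All coordinates are held 0-based half-open on a
single assembly.  VCF positions (1-based) and BED intervals are converted at
the I/O boundary; cross-assembly liftover is out of scope and inputs are
assumed pre-lifted, with the assembly name declared per dataset and checked
for consistency where two datasets meet.

A chimera footprint may be split across exons (about one in five in the data
this package is modeled on); it is represented as 1–3 genomic blocks that
must share a seqid and strand.  Transcript-to-genome projection walks exons
in transcription order (position 0 of a minus-strand transcript is the
rightmost base of its exon union); the inverse projection requires each
block to sit inside a single exon and the blocks to be contiguous in
transcript space, and is the exact inverse on every valid interval.

## Annotation

Each interval receives exactly one part label with fixed, configurable
precedence `CDS > 3'UTR > 5'UTR > ncRNA_exonic > intronic > intergenic`,
evaluated across all overlapping transcripts (the transcript yielding the
highest-precedence part wins).  The precedence is a design choice: published
percentages of parts are single-label tallies, and the upstream annotator's
tie-breaking is not documented, so a deterministic order is fixed here.

## Cross-dataset overlap and its null

Two chimera sets are compared in genome space.  A pair is *common* when any
block of one record overlaps any block of the other on the same seqid and
strand by at least `min_overlap` nt (default 1); counts are many-to-many.
Matching miRNA identity is optional and off by default, because the
significance null randomizes coordinates without miRNA labels and the
observed statistic should match its null.  Overlap length of multi-block
pairs is the summed per-block overlap (a `max` mode exists).

The null re-places `nA` and `nB` fragments uniformly within a shared
transcript set — transcripts chosen with probability proportional to
length, each fragment wholly inside one transcript — projects them to the
genome and re-scores.  Fragments may overlap each other within a set; no
exclusion rule is applied, which keeps the closed-form check valid: for a
single transcript of length `T` and fixed fragment length `l`, the expected
pair count is approximately `nA*nB*(2l-1)/T` (exact up to edge effects of
order `l/T`).  The empirical p-value uses the add-one estimator
`(1 + #{replicate >= observed}) / (1 + replicates)`; with the conventional
five replicates its floor is 1/6, so a one-sample z-score against the
replicate distribution is reported alongside and labeled as such.  A single
master seed derives per-replicate seeds.

## Expression integration

*Genes.*  Transcript tpm are summed per gene within each replicate, then
averaged across replicates.  A gene counts as expressed when its mean is
>= 1 tpm and at least one replicate reaches 1 tpm.  A separate >= 10 tpm
threshold governs cross-cell-line comparisons.  Genes are then partitioned
by their chimera record count: non-expressed but interacting (candidate
mapping artifacts or AGO-protected fragments), expressed with 0 or 1–8
records, high-interacting (>= 9) and sponge-like (>= 50) — transcripts
binding many miRNAs with no partner preference.  Counts are record-level
(each chimera counts), with distinct-partner tallies reported alongside.

*miRNAs.*  Raw counts are normalized with median-of-ratios size factors
(per sample, the median over entities with a nonzero geometric mean of
count / geometric mean), written in-package; `pydeseq2`'s implementation of
the same estimator serves as an independent oracle in the test suite, never
as the implementation.  Note the estimator is equivariant only up to its
global geometric-mean reference: scaling one of `m` samples by `c` rescales
every normalized value by `c^(1/m)` while leaving all relative values
unchanged.  A miRNA is expressed at >= 3 normalized mean counts.  For each
expressed, interacting miRNA the ratio `R = expression / interaction count`
is formed (normalized counts by default; raw available).  Type 1 miRNAs
(abundant, few targets) require expression and `R` strictly above the
cohort's 90th percentiles; type 2 (promiscuous, low `R`) require `R`
strictly below the 10th and interactions strictly above the 90th.
Percentiles are nearest-rank on the filtered cohort — deterministic, no
interpolation — and the strict inequalities mean exact ties never qualify.
Cohort-dependent published cutoff values are not reproduced here.

*Conservation and profiles.*  Per-miRNA conservation is the mean per-base
phyloP over the mature span (missing bases skipped and counted); group
values are means of per-miRNA means.  Positional interaction profiles bin a
representative transcript (the longest expressed one) into 50-nt segments;
an interaction increments every bin it overlaps and the trailing partial
bin is kept.

## Consensus binding regions (Exp-MiBRs)

Evidence is accumulated per genomic position: one unit per non-chimeric
dataset covering the position (duplicate peaks of one dataset never double
count) and one unit per individual chimera (two chimeras of one dataset are
two units; a chimera does not additionally activate its parent dataset).
Unstranded peaks contribute to both strands and are flagged.  Storage is
sparse per covered position.

An Exp-MiBR is a maximal run of >= L consecutive positions each holding
>= n units (defaults L=10, n=2).  The emitted region is the qualifying run
itself, trimmed to supported positions; the published definition is
ambiguous between this and the merged coverage footprint containing the
run, so the footprint variant is available via a flag (with footprint
dedup when several runs share one).  The parameter grid over L=1..25,
n=1..10 counts merged footprints harboring a qualifying run by default:
those counts are non-increasing in both L and n, whereas counts of trimmed
runs are provably not monotone in n (raising n can split one long run into
several shorter ones), which is why the merged convention is the grid
default while extraction keeps the trimmed default.

Regions carry aggregated dataset, cell-line and miRNA lists (miRNAs from
chimeras only, so peak-only regions have none) plus gene/part annotation.
Tissue summaries partition regions into cell-line-exclusive and shared,
flagging as ubiquitous those seen in >= 7 cell lines (of a 9-line
vocabulary).  Sequence coverage reports the fraction of a contig covered by
the region union and the genes touched exonically, as used for
mitochondrial-genome summaries.

## Variant queries

A point query (1-based) returns every region whose half-open interval
contains it.  VCF annotation adds `MIBR_*` INFO fields to variants inside
regions, preserves record order and untouched records byte-for-byte, and is
exactly invertible (stripping the added fields restores the input body,
including a restored `.` INFO).  Indels match by anchor position by
default; REF-span matching is a flag, since the reference web tool's indel
behavior is unspecified.  Files above 20 MB are refused, mirroring the
original service limit, and query/table assembly declarations must agree.

## Synthetic data and what it does (not) show

The generators produce a complete, downloads-free test bed: a packed gene
model (~1 Mb over two nuclear contigs plus a compact chrM-like contig, 200
genes, 1–5 exons, both strands, CDS/UTR partitions), chimera sets, CLIP
peak replicates, expression tables, mature-miRNA coordinates with a
conservation track, and a query VCF — all deterministic per master seed,
with every planted fact in `truth.json`.

Interaction footprints draw from a truncated normal bounded to [8, 200] nt
whose location is calibrated so the *truncated* mean is the target 37.2 nt
(plain truncation would inflate it to ~40); about 19% of placements
straddle an exon junction where the host transcript allows.  Per-gene
placement weights are lognormal, giving the heavy-tailed interaction-load
distribution seen in real tallies; random fill is capped below the sponge
threshold so planted sponge genes (60 records each) are the only
sponge-like calls, and fill is restricted to genes passing the 1-tpm call
so the non-expressed-interacting set is exactly the planted one.

The miRNA cohort (200 by default) is laid out in four background strata —
mid-ratio bulk, high-expression (20–30 records), high-ratio (1–2 records)
and low-ratio (3–8 records) — arranged so that no background miRNA can sit
strictly outside both percentile cutoffs of either type rule: strata that
own one extreme are bounded away from the other.  Planted type-1
(expression 5e4, one record) and type-2 (expression 60, 60 records) are
therefore the only strict exceedances, with multiplicative margin rather
than exact ties, so recovery does not hinge on floating-point tie-breaking.
The two count-matrix samples differ by an exact factor of two, exercising
non-trivial size factors while keeping planted expression targets intact
after normalization.

CLIP peak replicates cover each true region with probability `p`
(default 1), optionally jittered, plus per-dataset false-positive peaks;
the manifest's expected consensus set is computed by direct per-position
counting over the emitted peaks, independent of the caller.  Scale defaults
keep a full simulation plus pipeline run under a few seconds.

What passing these tests shows: the algorithms implement their definitions
exactly and recover planted structure under the stated conditions.  What
they do not show: robustness to real-data pathologies absent from the
generator — multi-mapping artifacts, paralog cross-alignment, coverage
biases, overlapping gene models, assembly mismatches — nor the published
cohort-dependent numbers, which require the original full-scale datasets.

## Numerical choices and limitations

- Nearest-rank percentiles and strict inequalities make typing
  deterministic; cohorts under 10 miRNAs yield no type calls, with a
  warning.
- Median-of-ratios falls back to unit factors (with a warning) when every
  entity contains a zero count.
- Fragment placement in the null resamples lengths up to 1,000 times when
  no transcript can host a sampled length, then errors.
- Degenerate inputs: inverted intervals are rejected row-wise with line
  numbers at I/O; empty VCF bodies, empty peak sets and empty groups behave
  as documented (empty outputs or explicit errors).
- The per-position profile is a dict-of-sets per (seqid, strand); it meets
  the covered-positions scale of the published merge (millions) but is not
  optimized beyond sparsity.
- Problem sizes used by the test suite and the reproduction script (200
  random profiles up to 5 kb, 1,000 round-trip intervals, 200 null
  replicates, the default simulation scale) were chosen as the smallest
  sizes at which the checks are statistically meaningful.
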