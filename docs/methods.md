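# Methods

## Splice graphs

Each gene's protein-coding transcript isoforms (GTF `exon` + `CDS`
features; transcripts without CDS are dropped by default) are merged
into a directed acyclic splice graph. Exon intervals from all isoforms
are fragmented at *every* distinct transcript boundary — donors,
acceptors, and transcript starts/ends — not only at splice sites. This
is what guarantees the defining invariant: every genomic base covered by
any exon lies in exactly one exon part, so a read never has an ambiguous
placement. Fragmenting only at donor/acceptor sites would break the
invariant for alternate first/last exons with staggered ends.

Parts in a maximal genomically contiguous run form one *exon region* and
share an ordinal; regions are numbered 1, 2, … in transcription order
(reverse genomic order on the minus strand) and multi-part regions get
sub-labels `N.1, N.2, …`. A part is flagged coding when any transcript's
CDS overlaps it; CDS boundaries do not fragment parts. Internally all
coordinates are 0-based half-open; GTF and the exon reference table are
read/written 1-based inclusive.

Degenerate inputs: an empty transcript set, mixed strands or mixed
chromosomes within a gene are errors; a transcript with inconsistent
strand or chromosome across its own features is rejected with a warning
(covers trans-spliced or multi-chromosome annotations, which the model
deliberately does not represent). Single-transcript genes still get a
graph — they simply yield no events — so downstream handling is uniform.

## Event catalog

Detectors operate purely in transcription order on two edge classes:
*splices* (junctions) and *adjacencies* (read-through between contiguous
parts on some path). This makes the code strand-agnostic and gives the
symmetry property tested in the suite: flipping a gene's strand label
without moving coordinates swaps AD↔AA and AT↔AL while preserving
ES/RI/ME.

* **ES** — a splice A→C with a transcript-supported path A→…→C whose
  first and last steps are splices. Include: the intermediate parts, the
  entry and exit junctions and any internal junctions; exclude: the
  bridging splice. Paths that begin or end with an adjacency are
  deliberately not ES — they are the AD/AA/RI topologies.
* **AD / AA** — ≥ 2 splices leaving (entering) sub-part boundaries of
  one exon region toward (from) a shared part. Include: the extension
  sub-parts and the long-form junction; exclude: the short-form
  junction. With more than two alternatives, events are emitted pairwise
  against the longest (most-included) form, since inclusion is only
  well defined against a reference form.
* **RI** — a splice whose intron is exactly tiled by parts contiguous
  with both flanks (some isoform reads straight through). Include: the
  intronic part(s); exclude: the splice. Exon-body reads on the
  retained segment therefore count toward include, by analogy with ES.
* **ME** — two internal parts in different exon regions sharing a
  splice-predecessor and a splice-successor that never co-occur on any
  transcript path. Include: the transcription-order-first alternative
  and its junctions; exclude: the other and its junctions. The
  orientation is a convention; the two PSI values are complementary.
* **AT / AL** — ≥ 2 distinct first (last) exon regions across transcript
  paths, each tied to the gene body by a terminal splice. One event per
  alternative, so each promoter/terminator gets its own PSI; the exclude
  set is the competitors' terminal splices. Single-exon transcripts
  contribute no alternative (there is no countable junction).

Nested or overlapping patterns are all emitted independently — the
catalog enumerates every potential elementary event, with no compound
classification and no de-duplication. Event IDs are
`SYMBOL_TYPE_LABELS`; duplicate IDs within a gene (possible for ME pairs
with identical labels) get a numeric suffix, and the catalog order is
deterministic (type, anchor position, ID).

## Counting and PSI

A primary mapped record (secondary/supplementary alignments are
ignored) contributes:

* +1 to each exon part its aligned blocks overlap by ≥ `min_anchor`
  bases (blocks are CIGAR runs merged over M/D/=/X and split at N);
* +1 to a splice when consecutive blocks match the splice's intron
  exactly and both anchoring blocks are ≥ `min_anchor` long.

`min_anchor` defaults to 4 bases for both rules — small enough not to
discard evidence on error-free data, large enough to reject 1–3-base
overhangs that alignment ambiguity could misplace. `total_aligned_reads`
counts every primary mapped record in the file, including those on
chromosomes without a graph.

PSI is `include / (include + exclude)` on **raw** counts, reported only
when `include + exclude ≥ min_coverage` (default 8; below that the
value is missing, not zero — low coverage is absence of evidence).
Normalized observations (reads per 1000 exonic bases per million
aligned reads for parts; reads per million for junctions, which have no
length) are computed for export and expression shading. A
`use_normalized` switch makes the PSI ratio use them instead, but the
coverage gate always applies to raw reads; raw is the default because
the canonical worked example (8 include reads vs 2 exclude reads →
PSI = 0.8) is raw-count arithmetic.

**Estimator bias.** A junction-spanning read also overlaps the flanked
exon part by its anchor, so for an ES event the include evidence pools
body and junction windows while the exclude evidence is a single
junction window. With uniform coverage the raw-count PSI therefore
over-weights inclusion for asymmetric events (ES, AD, AA, RI, AT, AL):
it is a monotone, reproducible index of inclusion rather than an
unbiased estimate of the isoform fraction. The ME geometry is the
symmetric case — include and exclude windows are congruent when the two
exons have equal length — so there `E[PSI] = p` exactly, and the
parameter-recovery test uses it. This is a property of the method being
implemented, not an implementation artifact.

## Novel junctions

Split-read junctions absent from the graph are accepted when the donor
boundary satisfies `part.start < pos ≤ part.end` and the acceptor
boundary `part.start ≤ pos < part.end` for some existing part — i.e.
both ends are on part boundaries or strictly inside parts. Junctions
with an end in intronic or intergenic space are discarded: novel exons
are never inferred. Discovery re-fragments the gene by rebuilding the
graph from its source transcripts with the new boundaries added (the
graph retains its transcripts precisely to make this rebuild exact),
re-numbers parts and re-attaches all novel splices; the in-place
alternative would have to rewrite labels, paths and splices by hand.
Discovery from the provided spliced alignments replaces a literal
second-pass re-alignment of unaligned reads, which would require an
external aligner; the contract is identical (find unannotated splices,
never exons).

At cohort level, an event containing a novel splice is reported only
when each of its novel splices carries ≥ `min_fraction` (default 1%) of
the event's covering reads in ≥ `min_samples` (default 10) samples.
"Share of the event's covering reads" is the operational reading of
"expressed in ≥ 1% of transcripts": within one event, covering reads
are the transcript-level denominator PSI itself uses.

## Cohort summaries

Group means are unweighted over non-missing samples, computed separately
for tumor and normal strata; no minimum group size is imposed but *n*
is always reported. The tissue-difference ranking sorts by the
population variance (ddof = 0) of per-group **tumor** mean PSI across
the selected groups — variance of group means, not of per-sample
values, because the question is variation *between* tumor types. The
tumor−normal ranking scores each event by the maximum |mean tumor −
mean normal| over selected groups with both strata (`mean` is available
as an alternative aggregation). Ties break lexicographically by event
ID; events lacking enough informative groups sort last. All summary
statistics are reproduced in the test suite by independent two-pass
loops to 1e-12 relative tolerance.

The download format is one row per event, one column per sample headed
`group:tissue_class:sample_id`, `NA` for missing, floats at 17
significant digits so export → import round-trips bit-exactly.

## The simulator

`FixtureSpec` describes one synthetic gene as a list of the seven
pattern codes plus geometry: exon length 150 bp, intron 120 bp,
donor/acceptor extension 60 bp, read length 75 bp, anchor 4 bp by
default — intron-containing multi-exon genes at desk scale, with every
exon long enough to hold a read. Two isoforms suffice for any pattern
combination: T1 carries the include form of every pattern, T2 the
exclude form, separated by shared anchor exons so patterns never
interact. The mixture fraction of T1 (`inclusion`, default 0.5) is the
ground-truth inclusion for every include-form event.

Reads are error-free, uniform along each isoform, with deterministic
per-isoform counts `round(fraction × depth × n_start_positions /
n_junction_positions)` — so `depth` reads as "expected junction-spanning
reads per splice at fraction 1". Randomness (a seeded NumPy generator)
enters only through start positions; the same seed reproduces
byte-identical SAM. The truth table is tallied in isoform coordinate
space, an arithmetic path that shares nothing with the genome-space
CIGAR counting it validates, and the two agree exactly on every
fixture.

What the simulator does *not* emulate — sequencing error, indels,
coverage bias, multi-mapping, unspliced pre-mRNA background, partially
degraded libraries — bounds what green tests show: they verify the
graph/event/PSI machinery, not robustness to alignment noise. Cohort
matrices for ranking tests are synthesized directly (per-group true
means, truncated-Gaussian sample noise, random missingness) because the
ranking layer consumes PSI values, not reads.

## Problem sizes and defaults

The test suite and acceptance script run whole pipelines on single-gene
fixtures (≤ 20 exon parts), cohorts of 12–60 samples and a few hundred
to a few thousand reads per sample; parameter-recovery simulations use
depth 120 (≈ 600 covering reads per event), comfortably above the
≥ 200-read floor the recovery property is stated at. These sizes
exercise every code path; nothing in the implementation is specific to
them, and the single-pass counter streams arbitrarily large
coordinate-sorted BAMs.

## Known limitations

* PSI from raw counts is biased toward inclusion for asymmetric events
  (see above); cross-sample comparisons of the same event are unaffected
  since the bias is a property of the event geometry.
* ME detection considers single-part alternatives; a mutually exclusive
  *pair of multi-part regions* would be reported as multiple pairwise
  events rather than one.
* AT/AL alternatives whose first/last exon region also occurs mid-path
  in another isoform are skipped with a warning rather than modelled.
* Overlapping genes are processed independently per gene_id; a read
  overlapping two genes counts in both.
* Non-coding transcripts are excluded by default, matching the
  protein-coding scope of the gene models; `coding_only=False` lifts
  this but coding flags are then meaningless for UTR-only isoforms.
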