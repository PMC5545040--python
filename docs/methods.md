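# Methods

This note documents the models, conventions and numerical choices behind
`scafeval`, what the simulator does and does not emulate, and the known
limitations.

## Coordinates and rounding

All reported coordinates are 1-based inclusive, so an interval's length is
`end − start + 1`; a breakpoint pinned between flanks ending at 39,021,787
and resuming at 39,021,892 is the 104 bp interval 39,021,788–39,021,891.
PAF input/output uses the standard 0-based half-open convention and is
converted at the boundary. Percentages are rounded to two decimals with ties
going away from zero; mean gap sizes are reported as integer nucleotides.

## Gap and contig accounting

Maximal runs of `N` of at least `min_gap` (default 1) seed captured gaps.
Optical-map scaffolders emit short restriction-site fragments inside the
gaps they introduce; following the GAEMR basic-stats convention, any non-N
island shorter than `min_contig` (default 200 nt) that lies between two gap
seeds is merged with its neighbours into a single gap, so one join
contributes one gap to the statistics. Terminal islands are kept as contigs:
the island rule targets fragments *inside* gaps, and a scaffold edge borders
no second gap. Free-standing scaffolds shorter than `min_contig` are kept by
default (`drop_short_scaffolds` exposes the alternative). Softmasked
(lowercase) bases count as ordinary sequence and are retained for repeat
analysis. The default `min_gap` of 1 is safe for the two gap dialects
modelled here (fixed 100 N; sized with a floor of several hundred nt) and is
configurable for others.

`nxx(lengths, x, genome_size)` returns the smallest length L such that
sequences of length ≥ L sum to at least x% of `genome_size` (the assembly
total by default). The adjusted variant fixes `genome_size` (default
400 Mb) so that assemblies of different total size are comparable; it
returns 0 when the assembly never reaches the threshold.

Gap filling is assessed by lifting each gap of the *before* assembly onto
the *after* assembly via its flanking 32 bp of contig sequence (searched
left to right, so lifting is monotone and O(n) in practice); a gap counts
as filled when no gap of the after assembly overlaps the lifted interval.
This is robust to fills whose inserted length differs from the estimated
gap size.

## Join/break lineage by anchor placement

Scaffolding reorders, joins, breaks and reverse-complements input scaffolds
but never edits sequence within a contig, so placement does not need an
aligner. Every input contig is seeded with up to 16 evenly spaced 64-mers;
each anchor that occurs exactly once in the output assembly fixes a
diagonal, which is extended to the maximal exact match (clamped to one
output scaffold). Uncovered stretches are re-anchored for up to four
rounds, so a contig broken across output scaffolds (a resolved chimera)
yields one exact placement per piece and the inferred break position is the
exact junction coordinate. Anchors hitting multiple loci are discarded;
contigs whose placements overlap on the input (true multi-mapping, i.e.
repeats) are flagged ambiguous and excluded from event calling but
reported. With 64-mer anchors and the divergence the simulator applies
between repeat copies (5–15%), exact cross-copy matches are rare, so
ambiguity is the exception even at 25% repeat content; on repeat-free
genomes placement is exact and join/break precision and recall are 1.0,
which the test suite asserts at 50 Mb.

Join events are output scaffolds containing ≥ 2 distinct input scaffolds,
members ordered by output coordinate; break events are input scaffolds
placed on ≥ 2 outputs, with one break per transition (interleaved
placements are reported as-is, with no minimisation). Shared joins between
two technologies are unordered *directly adjacent* member pairs present in
both join sets — transitive co-membership in a super-scaffold is
deliberately not counted, since the quantity of interest is which
adjacencies two technologies independently support. The "scaffolds per
join" summary is emitted both as joined-inputs-per-event and
members-per-event, since the two denominators differ once a scaffold
participates in several adjacent pairs.

## Synteny blocks, join validation, breakpoints

Alignment records are chained per (query, target chromosome, strand) by
dynamic programming on aligned bases; a record may follow another when both
query and target gaps are at most `max_join_gap` (default 100 kb) and the
target advances in strand order. Chains are peeled off best-first; query
coverage is then resolved to a single block per position by removing member
records more than half covered by better chains and re-chaining the
survivors, and blocks spanning under `min_block` (default 1 kb) on the
query are dropped. A small exhaustive oracle over random record sets
verifies that the top chain is optimal. The chaining thresholds are exposed
as parameters rather than hard-coded, as the appropriate values depend on
the divergence of the genomes being compared.

A join member's chromosome is the one holding strictly more than
`majority_fraction` (default 0.5) of its synteny-aligned bases, else
"unassigned"; reference chromosome "U" propagates as "U". The verdict is
*same* if all members are assigned and agree, *unknown* if any member is
"U"/unassigned, else *different*. Note that a genuine translocation
spanning join is scored *different* against a reference that lacks the
rearrangement — chromosome agreement is a proxy for correctness, not a gold
standard. Same-chromosome rates are reported overall and within
supported/unsupported strata (a join is supported when any of its adjacent
pairs is shared with the other technology), at both event and member-pair
granularity, because the two denominators genuinely differ.

A rearrangement transition is a pair of blocks adjacent on a query that map
to different chromosomes, different strands, or jump more than
`non_collinear_gap` (default 1 Mb) on the same chromosome. Each side of the
transition contributes the reference interval between the flank's
transition-facing end and the nearest block beyond it on that chromosome
(from any query); identical intervals discovered from both sides of a
reciprocal event are reported once.

## Novel sequence

Aligned query intervals are merged and subtracted from contig (gap-removed)
space. Raw complement segments are reclassified — not counted as novel —
when shorter than `min_segment` (default 100 nt), tandem-repetitive, or
low-complexity; the remainder is novel sequence. The partition
aligned + novel + reclassified + gaps = total holds exactly by
construction and is asserted on every simulation. The low-complexity filter
is a DUST-style triplet-coincidence score over 64 nt windows (random
sequence scores ≈ 0.5, homopolymers ≈ 31, dinucleotide runs ≈ 15,
trinucleotide runs ≈ 10; threshold 4, flagged when half the windows
exceed it). The tandem filter detects a period p ≤ 500 allowing ≥ 5 copies
at ≥ 80% self-identity under shift; tandem is tested before low complexity
so a dinucleotide array is attributed to the tandem class. Both are
calibrated on constructed strings in the test suite. Contaminant screening
is supported as an optional exclusion interval set (treated as aligned)
rather than by querying an external database, keeping the pipeline
deterministic and offline. Genes qualify as accession-specific when
strictly more than 50% of their total CDS length overlaps novel segments.

## Flank repeat enrichment

The observed statistic is the pooled repeat fraction (repeat bases over
non-N bases) in the `flank` = 10 kb windows each side of the supplied
events, truncated at scaffold ends. Repeats may come from a BED track, from
softmask, or their union. The null redraws the same number of event
positions uniformly over contig (non-N) space, keeping event lengths, and
the one-sided p-value is (1 + #{null ≥ observed}) / (1 + n_perm) — never
zero, reproducible bit-exactly for a fixed seed. The pooled fraction is the
headline statistic; a per-event fraction table accompanies it. Under the
null the test is calibrated (type-I error within binomial bounds over 200
simulated datasets, asserted in the suite).

## The simulator

The generator emulates the statistical structure the analysis assumes:

* **Reference** — equal-length chromosomes of uniform random sequence with
  three repeat families (interspersed 5 kb units at 10% per-copy
  divergence, interspersed 800 nt units at 15%, and tandem satellite arrays
  of 156 nt units), placed without overlap to a target repeat fraction
  (default 25%) and softmasked; toy gene models (1–5 CDS, uniform spacing)
  sufficient for the CDS-overlap rule, with no splicing realism.
* **Accession** — a reciprocal arm exchange between two chromosomes with a
  small deletion (`slop`, default 2 kb) at each junction — real
  translocations are not base-perfect reciprocal — whose deleted reference
  intervals are exactly the truth breakpoints (4 side-records, 2 unique
  intervals); one large novel insertion at each junction (0.23% and 0.086%
  of genome size, mirroring the clustering of novel sequence at real
  rearrangement junctions) plus dispersed smaller novel insertions
  (defaults chosen so total novel content is ≈ 5% of the genome); SNPs
  (0.5%) and short indels (0.02%) on reference-derived segments.
* **Fragmentation** — contig lengths follow a log-normal renewal process
  (mean 300 kb, σ = 1.0); each break is snapped into a softmasked position
  within 25 kb with probability 1 − 1/w (w = `repeat_break_weight`),
  emulating assemblers stalling in repeats, and w = 1 reduces to uniform
  break positions. A configurable number of chimeric scaffolds (default 8)
  concatenate distant contigs, with recorded junctions.
* **Scaffolding** — candidate joins are pairs of non-chimeric scaffolds
  adjacent on the accession, both ≥ `min_joinable`, separated by at most
  `max_span` of sequence held only in smaller scaffolds; each candidate
  succeeds with probability `join_success_rate` (0.8), standing in for
  evidence coverage. Gaps follow the profile's dialect: sized with 10%
  multiplicative error and a 500 nt floor plus sub-200 nt restriction-site
  islands for the optical-map-like profile, or exactly 100 N for the
  proximity-like profile. The proximity-like profile splits chimeric
  scaffolds before joining (and may re-join the pieces to their true
  neighbours); the optical-map-like profile only logs them, and logged
  chimeras are excluded as join members — joining through an unresolved
  chimera would plant joins that are wrong by construction, which belongs
  to the `join_error_rate` knob instead. Whole super-scaffolds are
  reverse-complemented at rate 0.3 to exercise orientation handling.
  Second rounds carry first-round gaps through with their origin labels.
* **Alignments** — PAF records derive from contig provenance intersected
  with the accession's reference-segment map. Coordinates are exact at
  segment boundaries (hence at translocation junctions); within a segment
  they interpolate linearly, so indel drift is bounded by the indel load
  and does not affect breakpoint recovery. Matches are estimated from the
  SNP rate. Novel segments produce no records.
* **Gap filling** — gaps whose true span is at most `max_fill_span` are
  replaced by the true accession sequence with probability `fill_prob`,
  reproducing the preferential filling of small gaps.

What the simulator does not emulate: read-level data and error models,
optical-map molecule physics, segmental duplication and polyploidy, gene
structure realism, and assembly base errors beyond SNPs/indels. Passing
tests therefore demonstrate the correctness of the accounting, lineage,
validation and statistics machinery under the stated generative model —
not the behaviour of any real scaffolding product on real data.

## Problem sizes and determinism

The shared test simulation is an 8 Mb, 4-chromosome genome (runs in
seconds); lineage precision/recall is additionally asserted on a 50 Mb
repeat-free genome, and the acceptance script uses 12 Mb studies — sizes at
which every code path (multi-member chains, chimera splitting, carried
gaps, translocation, novel extraction) is exercised while a full run stays
in the minutes range on one CPU. Every source of randomness flows through
an explicit `numpy` Generator seeded from the configuration or CLI
`--seed`; reruns are byte-identical, which the suite asserts end to end.

## Known limitations

* Placement requires exact contig sequence preservation; scaffolders that
  polish or trim contig ends would need alignment-based placement (the
  `Placement` type accommodates it, the anchor engine does not produce it).
* Shared-join comparison counts direct adjacencies only; order-preserving
  rearrangements within a super-scaffold are not scored.
* Breakpoint intervals depend on the chaining parameters; highly diverged
  genomes may need larger `max_join_gap` before flanks abut the true
  transition.
* The DUST and tandem thresholds are calibrated on constructed strings, not
  against external masking tools; borderline segments may classify
  differently than Dustmasker/TRF would.
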