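# Methods

`csvarc` re-implements, as a tested library, the bespoke computational steps of
assembly-based human genome studies: variant discovery from haplotype-to-
reference alignments, complex structural variant (CSV) resolution by a
shortest path over a variant-scored DAG, non-redundant population merging,
Phred-scaled haplotype quality evaluation, and centromere analytics.  All of
it is exercisable on fully seeded synthetic diploid genomes with an exact
truth ledger, so every operation can be checked against an independent oracle.

## Coordinates and records

All coordinates are 0-based half-open.  Alignment records follow PAF
semantics: minus-strand query intervals are stored in original (unreversed)
query space, and the CIGAR (ops `=XID` only) is in target order, describing
the reverse complement of the query slice.  Variants of 50 bp or more are
structural variants (SVs), 1–49-bp insertions/deletions are indels, and
single-base substitutions are SNVs.

## Synthetic genomes (simdata)

The generator derives everything from one event ledger: `make_reference`
builds seeded chromosomes with telomere motif runs (fixed 6-mer tandem,
default 5 kb per end) and an optional centromere — a centred alpha-satellite
array tiled by higher-order-repeat (HOR) rows of `monomers x 171 bp`, each
marked live (`L`) with the requested probability, annotated both as
`alpha_satellite` and as a CenSat-style `censat_exclude` track.
`implant_simple_variants` places SNV/INS/DEL events by rejection sampling
(largest first, default retry cap 1000, 2-bp padding), avoiding excluded
annotation labels and caller-supplied intervals; genotypes are homozygous
with probability 0.4, otherwise assigned to one haplotype.

CSV templates are token signatures over `{DEL, INV, INVDUP}` with exactly one
contiguous inverted run and INVDUP permitted only at the template edges —
this covers the catalogued signatures (`DEL-INV-DEL`, `INVDUP-INV-DEL`,
`INVDUP-INV-INVDUP`).  An INVDUP flank keeps its direct copy and also appears
inside the inverted copy, i.e. one copy in each orientation.  Single-token
templates are rejected: a complex event spans more than one repair junction.
`INS`/`DUP` tokens are recognised by the grammar but not realised by the
generator.  Optional inverted repeat pairs flanking a locus
(`install_inverted_repeats`) emulate the segmental duplications that mediate
template switches; the emitted alignments remain idealized split records
(real aligners fragment ambiguously inside such repeats — a documented
simplification).

Haplotype sequence and alignment records come from the *same* ledger walk, so
the record set tiles the query without overlap, concatenating per-record
query slices reconstructs the haplotype exactly, and inverted segments appear
as single minus-strand records.  `simulate_alignments` re-derives the
sequence and fails loudly if the supplied haplotype does not match the
ledger.

Methylation tracks are 5-kb bins at a configurable baseline (default 0.9)
with hypomethylated dips (`baseline - depth`, edge bins lowered by their
overlap fraction).  The bounded symmetric perturbation (default ±0.05) is a
seeded *track-level* offset.  Per-bin jitter exists (`bin_noise`) but
defaults to 0, deliberately: dip selection is rank-based (strictly below the
region median), so with any continuous independent per-bin noise roughly half
of the non-dip bins fall below the median regardless of noise amplitude, and
dip boundaries get extended by geometric-length runs of such bins.  A
track-level offset still exercises the median-relative logic (calls are
invariant to uniform baseline shifts) while keeping dip boundaries
bin-exact.  Passing recovery tests therefore demonstrates the threshold
logic, not robustness to bin-level measurement noise in real data.

## Variant discovery (align_variants)

Within a record, `X` runs become per-base SNVs, `I` runs insertions
(left-aligned to the target position of the left flank; no repeat-aware
shifting — a documented gap), `D` runs deletions, with sequences extracted
from query and reference.  Between query-consecutive records: a target gap is
a deletion, a query gap an insertion, a target overlap between
opposite-orientation records a duplicated inversion (INVDUP), and the
non-duplicated part of an inverted record an inversion.  When a junction has
both a query and a target gap, a paired INS+DEL is emitted (keeps the type
system closed).

Query-overlap trimming resolves each pairwise overlap by trimming whichever
record loses fewer `=` bases (ties: the record with the larger target
coordinate), splitting `=`/`X` runs at the boundary and removing `I`/`D` ops
whole so records never start or end in a gap op.  Trimming is idempotent and
never increases total matched bases.

Region exclusion removes a variant when its target interval overlaps any
exclusion interval by at least one base (half-open: abutting variants are
kept; point-like insertions count as the single anchor base).  Callers
pre-filter the track, e.g. dropping monomeric rows from a CenSat-style file.

`apply_variants_to_reference` replays calls: adjacent INV/INVDUP runs are
grouped, the union span is reverse-complemented, and INVDUP flanks retain the
direct copy on their outer side; on exact alignments this reconstructs the
query byte-identically.

## Complex-SV resolution (csv_resolver)

Records of one query (and target) are graph nodes; an edge `a -> b` exists
when `b` starts at or after `a`'s query end within a 50-bp slack and carries
the junction's variants.  Costs: `junction_open = 1.0` per edge; per-variant
cost `0.1 + log10(1 + length)/10`; each traversed node credits
`-match_weight x matched bases` (plus its own variant costs, and an inversion
cost for minus-strand records).  `match_weight` defaults to `1e-3` per base.
The weight matters: it must make a path that *aligns* a segment cheaper than
a path that hides the same segment inside an INS+DEL pair.  Skipping a
b-bp inverted middle record saves one junction (1.0) and the INV/DEL costs
(~1.0 at 10-kb scale) but forfeits `match_weight x b` of credit, so with the
default the through-path wins for segments above roughly 2 kb; far smaller
weights make the solver collapse every multi-junction event into indels.
Events at sub-kilobase scale may still be reported as indel pairs — at that
scale the two representations are genuinely ambiguous from split alignments.

The graph is acyclic by construction (edges advance in query coordinate), so
the minimum-cost source-to-sink path is found by one relaxation pass in
topological order, O(N+E) in nodes and edges; a literal Bellman–Ford mode
(|V|-1 relaxation rounds) is available and equals it, as does exhaustive path
enumeration on small random DAGs.  Ties break toward fewer edges, then the
lexicographically smallest node path — deterministic output.

Anchors are records with ≥ 1 kb aligned length and ≥ 90% `=` identity
(configurable); the source feeds anchors and anchors feed the sink.  The
accepted path is cut at plus-strand anchor nodes; each between-anchor piece
is one candidate event.  Its junction (inter-alignment) variants, ordered by
target coordinate, name the signature (SV-class variants only, hyphen-
joined); intra-record variants are ordinary calls.  A repair junction is a
path edge carrying at least one SV-class variant, so a lone clean inversion
(flip with no gaps or duplications) has zero junctions and passes through as
a simple variant, while `DEL-INV-DEL`-style events have two.  Events with at
most one junction are simple; complex calls whose span intersects the
exclusion track (e.g. centromeric repeats) are eliminated.

## Population merging (merge_popgen)

Two calls merge when they share a type and chromosome and satisfy 50%
reciprocal overlap (interval classes) and 80% sequence identity
(sequence-bearing classes).  Insertions are point-like on the reference, so
reciprocal overlap is replaced by a breakpoint window of
`max(50 bp, 0.5 x max(length))` plus the identity test.  Identity is
Levenshtein-normalised, `1 - d/max(|a|, |b|)` (edit distance from edlib),
preceded by a `min/max length >= 0.8` prefilter; this definition is unique
across co-optimal alignments, which keeps the merge deterministic and lets a
pure-Python dynamic-programming oracle reproduce it exactly.  Merging is
greedy and seed-based — variants sorted by descending carrier count, then
leftmost coordinate (further keys only to break exact ties) — and each
variant joins the first qualifying seed.  This is deliberately not transitive
closure; the ordering is the determinism contract, making the result
independent of input file order and idempotent under re-merging.

Allele frequency is carriers over genotyped haplotypes; haplotypes marked
missing (`.`, indicating misassembly at the locus) leave the denominator, and
trio children can be excluded.  Discovery curves count variants by the rank
of their first carrier in a given (or permuted, seeded) haplotype order;
the final point is the merged total regardless of order.  Caller support
marks a lead variant supported when any other caller's variant qualifies
under the same merge predicate.

## Quality evaluation (qv_eval)

*Windowed variant QV.*  Per 1-Mb reference window,
`QV = -10 log10(bp_changes / (2 x window_size))`, where `bp_changes` sums the
changed bases over both consensus haplotypes at conflicting positions;
erroneous variants longer than 20 bp are tallied separately and the median
window QV is reported.  Whether multi-base errors count as affected bases or
as variants is ambiguous in the field's usage, so both modes exist; bases is
the default.  Zero-error windows report a capped QV of 99 with an explicit
flag.

*k-mer QV.*  Canonical 21-mers, 2-bit encoded; every k-mer position of the
assembly is tested against the error-free source's k-mer set;
`error_rate = 1 - (1 - asm_only/total)^(1/k)`, QV its Phred scale,
completeness the fraction of source k-mers present in the assembly.  On
synthetic sequence this recovers implanted substitution rates of 1e-3 to
1e-5 within one Phred unit at 10 Mb.

*Availability QV.*  For a target haplotype against a reference panel,
divergence to each member is the global-alignment edit fraction
(edits / alignment columns, edlib); the reported QV is the maximum over
members, capped when the target occurs verbatim.

*Parental support.*  Parent contigs are aligned onto child contigs; a child
base is supported when covered by an `=` op from at least one parent, contigs
under 100 kb are excluded, and per-contig plus overall supported fractions
are returned.

*T2T status.*  A chromosome is a `T2T contig` when a single gapless sequence
covers it end to end with at least 1 kb of telomere annotation within 10 kb
of each end (thresholds configurable); with internal N-gaps it is a
`T2T scaffold`; with no aligned sequence `missing`; otherwise `not T2T`.

## Centromere analytics (centromere)

Live (`L`) HOR rows are grouped into arrays by adjacency (join distance
50 kb — synthetic rows carry no array names, so adjacency stands in for the
per-array grouping; configurable), and each array's length is max end minus
min start.  CDR detection computes the median methylation over bins
overlapping the alpha-satellite annotation by at least half a bin, selects
bins strictly below it (ties at the median excluded), merges consecutive
bins, and keeps runs strictly longer than 50 kb, reporting mean methylation.
The region over which the median is taken is whatever alpha-satellite
annotation the caller supplies (whole-contig vs active-array scoping is left
to the caller).  A centromere is di-CDR when at least two CDRs lie more than
80 kb apart, measured edge to edge.  Mobile element insertions are placed
relative to the CDRs (`inside_cdr` / `between_cdrs` / `outside_cdr`) with the
distance from the element midpoint to the nearest array edge; elements
outside the array are flagged, not rejected.

## Problem sizes and determinism

Synthetic checks use 120–300-kb chromosomes for calling and resolution (50
replicates per CSV template), a 1-Mb chromosome with a 400-kb array for
centromere analytics, and 10 Mb for k-mer rate recovery — sizes at which
every property is exact or within its stated tolerance while the whole suite
runs in well under a minute per module.  All randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
sequences, tracks and ledgers.

## Known limitations

- Insertion breakpoints are left-aligned without repeat normalization.
- The generator emits idealized split alignments; real alignments fragment
  unpredictably inside segmental duplications, so end-to-end recovery rates
  on real data will be lower than on these tests.
- Sub-kilobase complex events can be represented as indel clusters rather
  than named signatures (scoring ambiguity inherent to split alignments).
- The per-bin-noise-free methylation model tests threshold logic, not
  noise robustness (see above).
- `DUP` calls (same-orientation target overlap) are emitted but have no
  generator support and no replay rule beyond tandem duplication.
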