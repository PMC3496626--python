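# Methods

## Setting

A de novo 454 transcriptome assembly of a species without a reference
genome produces, per Newbler run, contigs (contiguous assembled
segments, roughly exon-scale), isotigs (ordered contig paths, one per
putative isoform) and isogroups (isotigs sharing contigs, one per
putative gene), plus unassembled singleton reads. All downstream
questions must be answered from these structures together with
similarity searches against a related species' reference gene set,
repeat-library annotations, and the per-tissue origin of each read.
This package implements that post-assembly layer; the assembler itself
and live BLAST/RepeatMasker execution are out of scope — the pipeline
consumes their tabular outputs.

## Annotation and coverage

Queries are split into *clustered* (≥ 1 hit with E ≤ `e_threshold`,
default 1e-20, inclusive) and *unclustered*. Each clustered query is
assigned the subject of its minimum-E-value hit; ties break by higher
bit score, then lexicographically smallest subject id — the tie rule is
this package's choice (any fixed rule works; determinism under row
permutation is the requirement). Reference coverage counts a reference
gene as covered when ≥ 1 annotated query hits it; a single match
suffices. Reference totals are always caller-supplied — the package
never guesses the size of an external gene universe.

Percent reporting: fractional percentages are **truncated** (not
rounded) to two decimals, so 1,935/2,579 reports as 75.02 rather than
75.03; this matches how such coverage figures are conventionally
printed. Percentages reported as whole numbers (small pathway lists,
the AS-isogroup fraction) round to nearest. Both are computed in integer
arithmetic (`_util.truncate_ratio_percent` et al.) to avoid binary
floating-point edge cases at the truncation boundary.

CDS completeness scans the three forward frames (assembled isotigs are
orientation-resolved; a `six_frame` flag exists) for the longest
ATG-to-in-frame-stop ORF. *intact_full_length* requires such an ORF of
length ≥ `min_fraction` (default 0.9) × the reference CDS length; the
0.9 quantifies a judgment that is inherently manual at study time.
A complete-but-shorter ORF, or an ATG-initiated open run of ≥ 60 nt
ending at the sequence edge (a truncated transcript), gives
*truncated_or_utr*; otherwise *absent*. The scanner is property-tested
against brute-force enumeration of all ATG/stop pairs.

## Tissue-exclusive DEG filter

One library per tissue and no replicates rule out statistical DE
testing; the filter is exact: a contig passes iff (max tissue count /
row total) ≥ `exclusivity` and row total ≥ `min_reads`. Defaults are the
strict study conditions: exclusivity 1.0 (every other tissue exactly
zero) and 100 reads. Contigs lift to genes through the annotation
table; a gene counts once per tissue, a gene passing in two tissues is
excluded and reported as a conflict (the package's rule — the situation
does not arise in the generator or, apparently, in practice), and
unannotated passing contigs are reported in a separate contig-level
section. Tissue pooling sums columns before filtering; a gene whose
reads split across two pooled libraries (the cerebrum/cerebellum case)
can only gain candidacy from pooling, never lose it, which the tests
verify on a planted split-gene fixture.

## Alternative-splicing events

Only the isotig↔contig membership relation of the layout file is used.
For each isogroup a **global contig order** is built: a topological sort
of all pairwise precedence constraints contributed by the isotigs, with
ties broken by discovery rank (contigs enumerated longest-isotig-first).
When the longest isotig contains every contig — always true for
generated layouts — the global order is exactly its member order.
Contradictory constraints (two isotigs ordering a pair oppositely, or a
precedence cycle) raise an order-conflict error naming a pair; in
aggregate (pipeline) mode such groups are skipped with a warning, in
strict mode they abort.

An **AS event** is a maximal run of consecutive contigs in the global
order sharing one inclusion vector (membership across isotigs) that is
not all-ones. This is the reproducible surrogate for manually curated
exon-creation/loss units: it is deterministic, oracle-checkable by
exhaustive span enumeration, and each event is exactly one variable exon
block. Events are disjoint and cover precisely the variable contigs.
Position classes: a block containing the 5′-most contig of the global
order is `five_prime`; containing the 3′-most (and not the 5′-most)
is `three_prime`; otherwise `internal`. A block spanning both termini
(two-contig groups) classifies `five_prime`. Orientation is ignored for
detection. The summary's mean events per AS isogroup is truncated to
two decimals and the AS-isogroup fraction rounds to a whole percent,
matching the reporting conventions above.

## TE-related AS and exonization

A repeat overlapping the *margin window* of an event block — the first
`margin_bp` bases of the block's first contig or the last `margin_bp`
bases of its last contig, 0-based half-open intersection — marks the
event TE-related. Exonized TE fragments donate their own splice sites,
so the diagnostic repeat sits at the block boundary; a repeat deep in
the block interior does not count. `margin_bp` defaults to 30 nt: the
margin is schematic in the source material and no number is given, so
the package exposes it as a config knob and echoes it in every output
header. Flagging is monotone in the margin and anti-monotone in
repeat-class restriction (both property-tested). The TE fraction of
events reports numerator and denominator explicitly alongside the
percent (truncated to one decimal), because a percentage alone is
ambiguous when several denominators (events, AS isogroups, isogroups)
are in play.

The exonization rate over a transcript set counts a gene as TE-exonized
when any exon interval of any of its transcripts overlaps any repeat on
that transcript, and reports 100·count/genes truncated to two decimals.
Interval indexing uses an interval tree; the test oracle is the naive
double loop.

## Synthetic studies

The generator emulates the study design, not the sequencing chemistry:
16 tissue libraries (the study's tissue list is the packaged default),
genes as isogroups built from 3–8 constitutive contigs of 100–500 nt
with 1–2-contig variable blocks planted in distinct inter-contig slots,
a complete first isotig plus leave-one-block-out (and random further)
inclusion patterns, per-contig read counts, BLAST-style hits and
repeat annotations. Defaults are the study conditions where stated:
17% of isogroups multi-isoform (the reported AS-isogroup fraction),
10.4% of variable blocks TE-inserted (the reported TE-related AS
fraction), 20% of genes without a reference ortholog (the unclustered
read fraction), DEG planting weighted by the published per-tissue
candidate proportions (zero for cerebrum, ovary and spleen). Desk-scale
choices not stated anywhere: 200 genes, negative-binomial counts with
mean 50 reads/contig and dispersion 0.5 (overdispersed counts are the
field's default assumption; the study states no count model), DEG
probability 0.10 so that a default study plants a two-digit number of
DEG genes.

Construction makes recovery exact rather than probabilistic: planted
DEG contigs get all reads in one tissue with ≥ 100 per contig, every
other expressed contig gets ≥ 2 tissues with non-zero counts; variable
blocks are separated by constitutive contigs so maximal-run detection
returns exactly the planted blocks; TE insertions overlap a margin
window while decoy repeats are placed strictly outside every window.
Per-gene RNG streams are derived from (seed, gene index), so enlarging
a study leaves earlier genes byte-identical. What the generator does
*not* emulate — sequencing error, chimeras, fragmented or partially
assembled transcripts, annotation error, ambiguous contig orders,
genes whose exclusivity is approximate rather than exact — means that
exact-recovery tests certify the detectors' logic, not their robustness
to real-data noise; on real layouts the manual-curation step the
detectors replace would still be advisable.

## Numerical and degenerate-input choices

Internal coordinates are 0-based half-open everywhere; 1-based inclusive
coordinates exist only in the file dialects (hit tables, repeat files)
and are converted exactly once at the read/write boundary. Readers
reject malformed input with the line number rather than repairing it.
Empty inputs are legal where a sensible empty answer exists (no hits →
everything unclustered; empty count matrix → no candidates; single
isotig → no events); they error where a ratio would be undefined (empty
reference set or gene list, zero events for the TE fraction). A summary
over zero AS isogroups reports mean 0.00 with an explicit flag rather
than NaN.

## Scale

The default test suite and the acceptance script run a 200-gene study
and a few thousand randomized oracle instances; the whole suite
completes in seconds. These sizes were chosen as the smallest at which
every code path (multi-isoform groups, all three position classes, TE
and decoy repeats, unclustered genes, DEG planting in weighted tissues)
is exercised with comfortable margins.

## Known limitations

- The genuine pictorial `454IsotigsLayout.txt` is not parsed; the
  simplified layout dialect encodes the membership relation that the
  analysis actually uses. Supporting the native format would need a
  corpus of real files to pin its variants down.
- Gene-level DEG counting assumes the annotation maps contigs of one
  gene consistently; chimeric annotations would surface as conflicts.
- The AS event unit is a surrogate for manual curation; counts on real
  data will differ from a curator's (who may merge or split blocks on
  sequence evidence the layout does not carry).
- TE calls depend on repeat annotations being in contig coordinates;
  isotig-space repeats are not projected and are rejected.
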