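"""Transposable-element (TE) relatedness of splice events and TE
exonization rates.

A variable exon block created or lost between isoforms is called
*TE-related* when a repeat annotation (RepeatMasker-style) overlaps the
marginal region of the block: the first ``margin_bp`` bases of the
block's first contig or the last ``margin_bp`` bases of its last contig.
TE fragments recruited as exons donate their own splice sites, so the
diagnostic repeat sits at the exon boundary rather than deep inside it.
The margin width is a tunable (default 30 nt) reported in all outputs.

The exonization rate over a transcript set is the percentage of genes
with at least one exon interval of at least one transcript overlapping
at least one repeat — the comparative statistic computed per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from ._util import ValidationError, truncate_ratio_percent
from .formats import RepeatFeature
from .splice import ASEvent

DEFAULT_MARGIN_BP = 30


@dataclass(frozen=True)
class TeCallConfig:
    """Margin width and repeat-class filter for TE-related AS calls.

    ``allowed_classes=None`` admits every repeat class; otherwise a
    repeat counts only when its class/family string starts with one of
    the allowed prefixes (so ``{"SINE/Alu"}`` and ``{"SINE"}`` both admit
    ``SINE/Alu`` repeats).
    """

    margin_bp: int = DEFAULT_MARGIN_BP
    allowed_classes: frozenset[str] | None = None

    def __post_init__(self):
        if self.margin_bp < 1:
            raise ValidationError("margin_bp must be >= 1")

    def admits(self, repeat_class: str) -> bool:
        if self.allowed_classes is None:
            return True
        return any(
            repeat_class == c or repeat_class.startswith(c.rstrip("/") + "/")
            for c in self.allowed_classes
        )


@dataclass(frozen=True)
class TeExonizationReport:
    label: str
    n_genes: int
    n_genes_with_te_exon: int
    rate: float  # percent, truncated to two decimals


def _margin_windows(
    event: ASEvent, contig_lengths: Mapping[str, int], margin_bp: int
) -> list[tuple[str, int, int]]:
    """The two margin windows of an event block, clipped to contig
    length, as (contig, start, end) in 0-based half-open space."""
    first, last = event.block[0], event.block[-1]
    for cid in (first, last):
        if cid not in contig_lengths:
            raise ValidationError(f"event block contig {cid!r} has no known length")
    windows = [(first, 0, min(margin_bp, contig_lengths[first]))]
    llen = contig_lengths[last]
    windows.append((last, max(0, llen - margin_bp), llen))
    return windows


def flag_te_events(
    events: Sequence[ASEvent],
    repeats: Iterable[RepeatFeature],
    contig_lengths: Mapping[str, int],
    cfg: TeCallConfig = TeCallConfig(),
) -> list[ASEvent]:
    """Return the events with ``te_related`` set.

    True iff a repeat of an admitted class overlaps (non-empty interval
    intersection) either margin window of the block.  Repeats on targets
    absent from ``contig_lengths`` are rejected as unresolvable.
    """
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        if rep.target_id not in contig_lengths:
            raise ValidationError(
                f"repeat {rep.name!r} on unknown target {rep.target_id!r}"
            )
        if not cfg.admits(rep.repeat_class):
            continue
        trees.setdefault(rep.target_id, IntervalTree()).addi(rep.start, rep.end)
    flagged: list[ASEvent] = []
    for ev in events:
        hit = False
        for cid, w_start, w_end in _margin_windows(ev, contig_lengths, cfg.margin_bp):
            if w_end <= w_start:
                continue
            tree = trees.get(cid)
            if tree is not None and tree.overlap(w_start, w_end):
                hit = True
                break
        flagged.append(replace(ev, te_related=hit))
    return flagged


def te_event_fraction(events: Sequence[ASEvent]) -> tuple[int, int, float]:
    """(n_te_related, n_events, percent truncated to one decimal)."""
    if not events:
        raise ValidationError("no events to summarise")
    n_te = sum(1 for e in events if e.te_related)
    return n_te, len(events), truncate_ratio_percent(n_te, len(events), digits=1)


def exonization_rate(
    gene_exons: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]],
    repeats: Iterable[RepeatFeature],
    label: str,
) -> TeExonizationReport:
    """TE exonization rate for a transcript set.

    ``gene_exons`` maps gene -> transcript -> exon intervals (0-based
    half-open, in transcript coordinates); repeats are annotated on the
    transcripts.  A gene is TE-exonized when any exon of any of its
    transcripts overlaps any repeat on that transcript.
    """
    if not gene_exons:
        raise ValidationError("empty gene set")
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        trees.setdefault(rep.target_id, IntervalTree()).addi(rep.start, rep.end)
    n_hit = 0
    for gene, transcripts in gene_exons.items():
        hit = False
        for tx, exons in transcripts.items():
            tree = trees.get(tx)
            for start, end in exons:
                if end <= start or start < 0:
                    raise ValidationError(
                        f"gene {gene} transcript {tx}: bad exon [{start},{end})"
                    )
                if not hit and tree is not None and tree.overlap(start, end):
                    hit = True
        if hit:
            n_hit += 1
    return TeExonizationReport(
        label=label,
        n_genes=len(gene_exons),
        n_genes_with_te_exon=n_hit,
        rate=truncate_ratio_percent(n_hit, len(gene_exons)),
    )
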