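"""Alternative-splicing event detection from isotig layouts.

Without a genome to align to, alternative splicing in a de novo 454
assembly is visible only through the isogroup structure: each isotig is
an ordered path of contigs, and a contig present in some isotigs of an
isogroup but absent in others marks a variable (created or lost) exon
unit.  An *event* is a maximal run of consecutive contigs — in a global
contig order consistent with every isotig — that share one inclusion
vector across the isotigs and are not in all of them.  Events are
classified positionally: a block containing the first contig of the
global order is five_prime, one containing the last (and not the first)
is three_prime, anything else is internal.

Orientation is ignored for detection (only membership and order matter);
isotigs whose member orders contradict each other raise
:class:`OrderConflictError` (or are skipped with a warning in
non-strict aggregation, since real layouts are not expected to contain
them).
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import ValidationError, round_ratio_percent, truncate_ratio
from .annotation import AnnotationTable
from .formats import Isogroup

logger = logging.getLogger(__name__)

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
INTERNAL = "internal"


class OrderConflictError(ValueError):
    """Two isotigs order a pair of contigs inconsistently."""

    def __init__(self, group_id: str, pair: tuple[str, str]):
        self.group_id = group_id
        self.pair = pair
        super().__init__(
            f"isogroup {group_id}: contigs {pair[0]!r} and {pair[1]!r} appear "
            f"in contradictory order in different isotigs"
        )


@dataclass(frozen=True)
class InclusionMatrix:
    """Binary contig x isotig membership for one isogroup, rows in global
    contig order."""

    isogroup_id: str
    contig_order: tuple[str, ...]
    isotig_ids: tuple[str, ...]
    matrix: tuple[tuple[int, ...], ...]  # rows = contigs, columns = isotigs


@dataclass(frozen=True)
class ASEvent:
    """A maximal variable contig block within an isogroup."""

    isogroup_id: str
    block: tuple[str, ...]
    inclusion: tuple[int, ...]  # one flag per isotig, file order
    position_class: str
    te_related: bool = False


@dataclass(frozen=True)
class ASSummary:
    """Aggregate AS statistics over a set of isogroups.

    ``mean_events_per_as_isogroup`` is truncated to two decimals and
    ``percent_as_isogroups`` rounded to the nearest integer, the
    conventions used for reporting these quantities.
    """

    n_isogroups_examined: int
    n_as_isogroups: int
    n_events: int
    counts_by_class: dict[str, int]
    max_events: tuple[str, int]  # (gene or isogroup id, event count)
    n_te_related: int = 0
    no_as_isogroups: bool = False

    @property
    def mean_events_per_as_isogroup(self) -> float:
        if self.n_as_isogroups == 0:
            return 0.0
        return truncate_ratio(self.n_events, self.n_as_isogroups)

    @property
    def percent_as_isogroups(self) -> int:
        if self.n_isogroups_examined == 0:
            return 0
        return round_ratio_percent(self.n_as_isogroups, self.n_isogroups_examined)


def global_contig_order(group: Isogroup) -> tuple[str, ...]:
    """A total contig order consistent with every isotig's member order.

    The order is a topological sort of the precedence constraints
    contributed by every isotig (a before b whenever a precedes b in some
    isotig); among unconstrained contigs, ties break by discovery rank —
    the order contigs first appear when isotigs are visited longest-first
    (then by isotig id) — so the result is deterministic and, whenever
    the longest isotig contains every contig, equal to its member order.
    A contig pair ordered differently by two isotigs raises
    :class:`OrderConflictError`.
    """
    isotigs = sorted(group.isotigs, key=lambda t: (-len(t.members), t.id))
    rank: dict[str, int] = {}
    for tig in isotigs:
        for c in tig.contig_ids:
            rank.setdefault(c, len(rank))

    successors: dict[str, set[str]] = {c: set() for c in rank}
    indegree: dict[str, int] = {c: 0 for c in rank}
    pair_seen: set[tuple[str, str]] = set()
    for tig in group.isotigs:
        ids = tig.contig_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if (b, a) in pair_seen:
                    raise OrderConflictError(group.id, (a, b))
                if (a, b) not in pair_seen:
                    pair_seen.add((a, b))
                    successors[a].add(b)
                    indegree[b] += 1

    ready = [(rank[c], c) for c in rank if indegree[c] == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        _, c = heapq.heappop(ready)
        order.append(c)
        for d in successors[c]:
            indegree[d] -= 1
            if indegree[d] == 0:
                heapq.heappush(ready, (rank[d], d))
    if len(order) != len(rank):
        # a precedence cycle spanning >=3 isotigs with no directly
        # contradicted pair; report two cycle members sharing an isotig
        remaining = [c for c in rank if indegree[c] > 0]
        pair = (remaining[0], remaining[1] if len(remaining) > 1 else remaining[0])
        for tig in group.isotigs:
            inside = [c for c in tig.contig_ids if c in set(remaining)]
            if len(inside) >= 2:
                pair = (inside[0], inside[1])
                break
        raise OrderConflictError(group.id, pair)
    return tuple(order)


def inclusion_matrix(group: Isogroup) -> InclusionMatrix:
    order = global_contig_order(group)
    membership = [set(t.contig_ids) for t in group.isotigs]
    matrix = tuple(
        tuple(1 if c in m else 0 for m in membership) for c in order
    )
    return InclusionMatrix(
        group.id, order, tuple(t.id for t in group.isotigs), matrix
    )


def classify_position(
    block: Sequence[str], order: Sequence[str]
) -> str:
    """Positional class of a block: five_prime if it holds the 5'-most
    contig of the global order (this wins when a block spans both
    termini), three_prime if the 3'-most, internal otherwise."""
    blockset = set(block)
    if order[0] in blockset:
        return FIVE_PRIME
    if order[-1] in blockset:
        return THREE_PRIME
    return INTERNAL


def detect_events(group: Isogroup) -> list[ASEvent]:
    """Maximal runs of consecutive contigs with identical, non-all-ones
    inclusion vectors, 5'->3'. Single-isotig groups have no events."""
    if len(group.isotigs) < 2:
        return []
    im = inclusion_matrix(group)
    n_isotigs = len(im.isotig_ids)
    all_ones = tuple([1] * n_isotigs)
    events: list[ASEvent] = []
    i = 0
    n = len(im.contig_order)
    while i < n:
        vec = im.matrix[i]
        if vec == all_ones:
            i += 1
            continue
        j = i
        while j + 1 < n and im.matrix[j + 1] == vec:
            j += 1
        block = im.contig_order[i : j + 1]
        events.append(
            ASEvent(
                isogroup_id=group.id,
                block=block,
                inclusion=vec,
                position_class=classify_position(block, im.contig_order),
            )
        )
        i = j + 1
    return events


def summarize(
    groups: Iterable[Isogroup],
    annotations: AnnotationTable | None = None,
    strict: bool = False,
    precomputed_events: dict[str, list[ASEvent]] | None = None,
) -> ASSummary:
    """Aggregate AS statistics over isogroups.

    Mean events are computed over AS isogroups (>=2 isotigs) only; the
    isogroup with the most events is reported by its annotated gene when
    an annotation table is given (looked up through any member isotig;
    ties broken by lexicographically smallest label).  Groups with
    contradictory contig orders are skipped with a warning, or raise in
    strict mode.
    """
    n_examined = 0
    n_as = 0
    n_events = 0
    n_te = 0
    by_class = {FIVE_PRIME: 0, THREE_PRIME: 0, INTERNAL: 0}
    best: tuple[int, str] | None = None  # (-count, label) for min-compare
    for g in groups:
        n_examined += 1
        try:
            events = (
                precomputed_events[g.id]
                if precomputed_events is not None
                else detect_events(g)
            )
        except OrderConflictError:
            if strict:
                raise
            logger.warning("skipping isogroup %s: contradictory contig order", g.id)
            continue
        if len(g.isotigs) >= 2:
            n_as += 1
        n_events += len(events)
        for ev in events:
            by_class[ev.position_class] += 1
            if ev.te_related:
                n_te += 1
        label = g.id
        if annotations is not None:
            for t in g.isotigs:
                gene = annotations.gene_of(t.id)
                if gene is not None:
                    label = gene
                    break
        if events and (best is None or (-len(events), label) < best):
            best = (-len(events), label)
    return ASSummary(
        n_isogroups_examined=n_examined,
        n_as_isogroups=n_as,
        n_events=n_events,
        counts_by_class=by_class,
        max_events=(best[1], -best[0]) if best else ("", 0),
        n_te_related=n_te,
        no_as_isogroups=(n_as == 0),
    )
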