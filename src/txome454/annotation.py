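"""Query partitioning, best-hit annotation, coverage and CDS completeness.

A de novo transcriptome with no genome of its own is annotated by
similarity to a reference gene set: queries (reads, contigs or isotigs)
with at least one hit at or below an E-value threshold (default 1e-20)
form the *clustered* group and inherit the reference gene of their best
hit; the rest are *unclustered*.  Coverage is then the fraction of
reference genes recovered by at least one annotated query, and gene-list
coverage applies the same count to disease- or pathway-gene lists.
CDS completeness asks whether an assembled transcript carries an intact
open reading frame spanning most of the reference coding sequence.

Percent conventions: fractional percentages are *truncated* to two
decimals (1,935/2,579 -> 75.02); integer percentages round to nearest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._util import ValidationError, round_ratio_percent, truncate_ratio_percent
from .formats import HitRecord

DEFAULT_E_THRESHOLD = 1e-20

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class AnnotationTable:
    """Best-hit gene assignment per annotated query plus the set of
    unannotated queries; the two collections partition the query set."""

    assignments: dict[str, tuple[str, float, float]]  # query -> (gene, E, bit)
    unannotated: frozenset[str]

    def __post_init__(self):
        overlap = set(self.assignments) & self.unannotated
        if overlap:
            raise ValidationError(
                f"queries both annotated and unannotated: {sorted(overlap)[:3]}"
            )

    @property
    def n_queries(self) -> int:
        return len(self.assignments) + len(self.unannotated)

    def gene_of(self, query_id: str) -> str | None:
        rec = self.assignments.get(query_id)
        return rec[0] if rec else None


@dataclass(frozen=True)
class CoverageReport:
    n_reference_genes: int
    n_covered_genes: int
    percent_covered: float
    n_queries: int
    n_matched_queries: int
    percent_matched_queries: float


@dataclass(frozen=True)
class AssemblyGroupSummary:
    """Newbler per-group output sizes (clustered or unclustered read group)."""

    label: str
    n_contigs: int
    n_isotigs: int
    n_isogroups: int
    n_singletons: int
    n_discarded: int
    n_input_reads: int

    def __post_init__(self):
        for f in (
            "n_contigs",
            "n_isotigs",
            "n_isogroups",
            "n_singletons",
            "n_discarded",
            "n_input_reads",
        ):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} negative")


@dataclass(frozen=True)
class CdsAssessment:
    gene_id: str
    status: str  # intact_full_length | truncated_or_utr | absent
    orf_start: int | None = None
    orf_end: int | None = None
    orf_fraction_of_reference: float | None = None


def partition_queries(
    hits: Iterable[HitRecord],
    all_query_ids: Iterable[str],
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> tuple[set[str], set[str]]:
    """Split queries into (clustered, unclustered) by whether any hit has
    E-value <= ``e_threshold`` (inclusive)."""
    if e_threshold <= 0:
        raise ValidationError("e_threshold must be positive")
    universe = set(all_query_ids)
    clustered: set[str] = set()
    for h in hits:
        if h.query_id not in universe:
            raise ValidationError(f"hit references unknown query {h.query_id!r}")
        if h.e_value <= e_threshold:
            clustered.add(h.query_id)
    return clustered, universe - clustered


def annotate(
    hits: Iterable[HitRecord], e_threshold: float = DEFAULT_E_THRESHOLD
) -> AnnotationTable:
    """Assign each query the subject of its best hit at or below the
    threshold.

    Best = minimum E-value; ties broken by higher bit score, then by
    lexicographically smallest subject id, so the assignment is invariant
    under permutation of the hit table.
    """
    if e_threshold <= 0:
        raise ValidationError("e_threshold must be positive")
    best: dict[str, tuple[float, float, str]] = {}
    seen: set[str] = set()
    for h in hits:
        seen.add(h.query_id)
        if h.e_value > e_threshold:
            continue
        key = (h.e_value, -h.bit_score, h.subject_id)
        cur = best.get(h.query_id)
        if cur is None or key < cur:
            best[h.query_id] = key
    assignments = {q: (subj, e, -negbit) for q, (e, negbit, subj) in best.items()}
    return AnnotationTable(assignments, frozenset(seen - set(assignments)))


def reference_coverage(
    annotations: AnnotationTable, reference_gene_ids: Iterable[str]
) -> CoverageReport:
    """Fraction of reference genes hit by >=1 annotated query, and the
    matched-query fraction; one match suffices for a gene to count as
    covered."""
    reference = set(reference_gene_ids)
    if not reference:
        raise ValidationError("empty reference gene set")
    covered = {g for g, _, _ in annotations.assignments.values() if g in reference}
    n_q = annotations.n_queries
    n_m = len(annotations.assignments)
    return CoverageReport(
        n_reference_genes=len(reference),
        n_covered_genes=len(covered),
        percent_covered=truncate_ratio_percent(len(covered), len(reference)),
        n_queries=n_q,
        n_matched_queries=n_m,
        percent_matched_queries=truncate_ratio_percent(n_m, n_q) if n_q else 0.0,
    )


def list_coverage(
    annotations: AnnotationTable, gene_list: Iterable[str]
) -> tuple[int, int, float]:
    """Coverage of an arbitrary gene list (OMIM/KEGG-style): returns
    (n_list, n_covered, percent truncated to two decimals)."""
    genes = set(gene_list)
    if not genes:
        raise ValidationError("empty gene list")
    hit_genes = {g for g, _, _ in annotations.assignments.values()}
    n_cov = len(genes & hit_genes)
    return len(genes), n_cov, truncate_ratio_percent(n_cov, len(genes))


def list_coverage_int_percent(n_covered: int, n_list: int) -> int:
    """Integer-percent report used for small gene lists (rounds to
    nearest, e.g. 115/129 -> 89)."""
    return round_ratio_percent(n_covered, n_list)


def merge_summaries(
    a: AssemblyGroupSummary, b: AssemblyGroupSummary
) -> AssemblyGroupSummary:
    """Combine the clustered and unclustered per-group assembly summaries
    by component-wise sum."""
    if a.label == b.label:
        raise ValidationError(f"cannot merge two {a.label!r} summaries")
    return AssemblyGroupSummary(
        label="combined",
        n_contigs=a.n_contigs + b.n_contigs,
        n_isotigs=a.n_isotigs + b.n_isotigs,
        n_isogroups=a.n_isogroups + b.n_isogroups,
        n_singletons=a.n_singletons + b.n_singletons,
        n_discarded=a.n_discarded + b.n_discarded,
        n_input_reads=a.n_input_reads + b.n_input_reads,
    )


def _orfs_in_frame(seq: str, frame: int) -> Iterable[tuple[int, int, bool]]:
    """Yield (start, end, complete) ORFs in one forward frame; end is
    exclusive and includes the stop codon when complete."""
    start = None
    i = frame
    n = len(seq)
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in _STOPS:
            yield start, i + 3, True
            start = None
        i += 3
    if start is not None:
        yield start, n - (n - start) % 3, False


def assess_cds(
    sequence: str,
    reference_cds_length: int,
    min_fraction: float = 0.9,
    gene_id: str = "",
    six_frame: bool = False,
    min_open_orf: int = 60,
) -> CdsAssessment:
    """Judge CDS completeness of an assembled transcript.

    Scans the three forward frames (six with ``six_frame``) for the
    longest ATG-to-stop ORF.  ``intact_full_length`` requires a complete
    ORF (start and in-frame stop) of length >= ``min_fraction`` x
    ``reference_cds_length``; a shorter complete ORF, or an ATG-initiated
    open run of >= ``min_open_orf`` nt reaching the sequence end, yields
    ``truncated_or_utr``; otherwise ``absent``.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    if reference_cds_length <= 0:
        raise ValidationError("reference_cds_length must be positive")
    seq = sequence.upper()
    strands = [seq]
    if six_frame:
        comp = str.maketrans("ACGTN", "TGCAN")
        strands.append(seq.translate(comp)[::-1])
    best_complete: tuple[int, int] | None = None
    has_open = False
    for s in strands:
        for frame in range(3):
            for start, end, complete in _orfs_in_frame(s, frame):
                if complete:
                    if best_complete is None or end - start > (
                        best_complete[1] - best_complete[0]
                    ):
                        best_complete = (start, end)
                elif end - start >= min_open_orf:
                    has_open = True
    if best_complete is not None:
        start, end = best_complete
        frac = (end - start) / reference_cds_length
        if frac >= min_fraction:
            return CdsAssessment(gene_id, "intact_full_length", start, end, frac)
        return CdsAssessment(gene_id, "truncated_or_utr", start, end, frac)
    if has_open:
        return CdsAssessment(gene_id, "truncated_or_utr")
    return CdsAssessment(gene_id, "absent")
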