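"""Tissue-exclusive differentially-expressed-gene (DEG) filtering.

The study design has one library per tissue and no replicates, so no
statistical DE test is possible; instead a strict exclusivity filter is
applied to the per-contig read counts: a contig is a DEG candidate when
100% of its reads come from a single tissue and the total is at least
100 reads.  Candidate contigs are lifted to genes through the best-hit
annotation table; a gene whose passing contigs disagree on tissue is a
conflict and is excluded from the per-tissue counts.  Tissue pooling
(e.g. cerebrum + cerebellum -> brain) is supported because genes whose
reads split across closely related libraries only pass after pooling.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._util import ValidationError
from .annotation import AnnotationTable
from .formats import TissueCountMatrix

DEFAULT_MIN_READS = 100
DEFAULT_EXCLUSIVITY = 1.0


@dataclass(frozen=True)
class DegRecord:
    """One passing contig: its exclusive tissue, read total, and the gene
    it annotates to (None when unannotated)."""

    contig_id: str
    tissue: str
    total_reads: int
    gene_id: str | None = None


@dataclass
class DegSummary:
    """Gene-level DEG table: per-tissue candidate gene counts and names,
    conflicted genes, and unannotated passing contigs (reported
    separately because the gene table is gene-level only)."""

    per_tissue_counts: dict[str, int]
    per_tissue_genes: dict[str, list[str]]
    conflicts: list[tuple[str, tuple[str, ...]]]  # (gene, tissues it passed in)
    unannotated_contigs: list[DegRecord]
    selected_for_validation: dict[str, int] = field(default_factory=dict)

    @property
    def total_candidates(self) -> int:
        return sum(self.per_tissue_counts.values())

    @property
    def total_selected(self) -> int:
        return sum(self.selected_for_validation.values())


def pool_tissues(
    matrix: TissueCountMatrix, pooling: Mapping[str, str]
) -> TissueCountMatrix:
    """Sum columns mapped to the same new label; untouched columns keep
    their label. Total read mass is conserved."""
    for old in pooling:
        if old not in matrix.counts.columns:
            raise ValidationError(f"unknown tissue label {old!r} in pooling map")
    renamed = matrix.counts.rename(columns=dict(pooling))
    pooled = renamed.T.groupby(level=0, sort=False).sum().T
    return TissueCountMatrix(pooled)


def find_deg_contigs(
    matrix: TissueCountMatrix,
    min_reads: int = DEFAULT_MIN_READS,
    exclusivity: float = DEFAULT_EXCLUSIVITY,
    annotations: AnnotationTable | None = None,
) -> list[DegRecord]:
    """Select contigs whose reads are tissue-exclusive.

    A contig passes when ``max tissue count / row total >= exclusivity``
    and ``row total >= min_reads``; with the default exclusivity of 1.0
    every other tissue must be exactly zero.  The selected tissue is the
    argmax, unique whenever exclusivity > 0.5.
    """
    if min_reads < 1:
        raise ValidationError("min_reads must be >= 1")
    if not 0 < exclusivity <= 1:
        raise ValidationError("exclusivity must be in (0, 1]")
    records: list[DegRecord] = []
    df = matrix.counts
    if df.empty:
        return records
    tissues = list(df.columns)
    for cid, row in df.iterrows():
        vals = row.to_numpy()
        total = int(vals.sum())
        if total < min_reads:
            continue
        top = int(vals.max())
        if top < exclusivity * total:
            continue
        tissue = tissues[int(vals.argmax())]
        gene = annotations.gene_of(str(cid)) if annotations else None
        records.append(DegRecord(str(cid), tissue, total, gene))
    return records


def deg_genes(
    records: Sequence[DegRecord],
    annotations: AnnotationTable,
    selected_for_validation: Mapping[str, int] | None = None,
) -> DegSummary:
    """Lift passing contigs to gene level.

    A gene counts once per tissue regardless of how many of its contigs
    pass; a gene passing in two different tissues is excluded as a
    conflict.  Unannotated passing contigs are carried in a separate
    contig-level section.
    """
    gene_tissues: dict[str, set[str]] = defaultdict(set)
    unannotated: list[DegRecord] = []
    for rec in records:
        gene = rec.gene_id or annotations.gene_of(rec.contig_id)
        if gene is None:
            unannotated.append(rec)
        else:
            gene_tissues[gene].add(rec.tissue)
    per_tissue: dict[str, list[str]] = defaultdict(list)
    conflicts: list[tuple[str, tuple[str, ...]]] = []
    for gene in sorted(gene_tissues):
        tissues = gene_tissues[gene]
        if len(tissues) > 1:
            conflicts.append((gene, tuple(sorted(tissues))))
        else:
            per_tissue[next(iter(tissues))].append(gene)
    return DegSummary(
        per_tissue_counts={t: len(gs) for t, gs in per_tissue.items()},
        per_tissue_genes=dict(per_tissue),
        conflicts=conflicts,
        unannotated_contigs=unannotated,
        selected_for_validation=dict(selected_for_validation or {}),
    )
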