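"""End-to-end orchestration: partition -> annotate -> coverage -> DEG ->
AS -> TE -> report.

Each stage reads the prior stage's files and writes its own before the
next begins, so any stage can also be invoked standalone on intermediate
files with identical results.  All outputs are TSV plus a plain-text
summary; a run-metadata file records every threshold and the seed, and a
rerun with identical inputs and config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

from ._util import ValidationError
from . import __version__
from .annotation import (
    AnnotationTable,
    annotate,
    partition_queries,
    reference_coverage,
)
from .deg import deg_genes, find_deg_contigs, pool_tissues
from .formats import (
    read_counts,
    read_gene_list,
    read_hits,
    read_layout,
    read_repeats,
)
from .splice import detect_events, summarize, OrderConflictError
from .te import TeCallConfig, flag_te_events, te_event_fraction

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    layout_path: str | Path
    hits_path: str | Path
    counts_path: str | Path
    repeats_path: str | Path
    reference_genes_path: str | Path
    output_dir: str | Path
    gene_list_paths: dict[str, str | Path] = field(default_factory=dict)
    contigs_fasta_path: str | Path | None = None
    e_threshold: float = 1e-20
    min_reads: int = 100
    exclusivity: float = 1.0
    pooling: dict[str, str] = field(default_factory=dict)
    margin_bp: int = 30
    repeats_dialect: str = "tsv"
    annotated_only_as: bool = True
    strict: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "layout_path",
            "hits_path",
            "counts_path",
            "repeats_path",
            "reference_genes_path",
        ):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: no such file {p}")
        if self.e_threshold <= 0:
            raise ValidationError("e_threshold must be positive")
        if self.min_reads < 1:
            raise ValidationError("min_reads must be >= 1")
        if not 0 < self.exclusivity <= 1:
            raise ValidationError("exclusivity must be in (0, 1]")
        if self.margin_bp < 1:
            raise ValidationError("margin_bp must be >= 1")


def _write(path: Path, text: str) -> Path:
    path.write_text(text)
    return path


def run(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns a manifest of written reports."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    # --- load inputs -------------------------------------------------
    with open(config.layout_path) as fh:
        groups = read_layout(fh)
    with open(config.hits_path) as fh:
        hits = read_hits(fh)
    with open(config.counts_path) as fh:
        counts = read_counts(fh)
    with open(config.repeats_path) as fh:
        repeats = read_repeats(fh, dialect=config.repeats_dialect)
    with open(config.reference_genes_path) as fh:
        reference = read_gene_list(fh)

    contig_lengths: dict[str, int] = {}
    if config.contigs_fasta_path:
        from .formats import read_fasta

        contig_lengths = {
            cid: len(s) for cid, s in read_fasta(str(config.contigs_fasta_path)).items()
        }

    # --- partition + annotate ---------------------------------------
    all_queries = {h.query_id for h in hits}
    for g in groups:
        all_queries.update(t.id for t in g.isotigs)
        all_queries.update(g.contig_ids)
    all_queries.update(counts.contig_ids)
    clustered, unclustered = partition_queries(hits, all_queries, config.e_threshold)
    logger.info(
        "partition: %d clustered / %d unclustered at E<=%g",
        len(clustered),
        len(unclustered),
        config.e_threshold,
    )
    manifest["partition.tsv"] = _write(
        out / "partition.tsv",
        "query\tgroup\n"
        + "".join(
            f"{q}\t{'clustered' if q in clustered else 'unclustered'}\n"
            for q in sorted(all_queries)
        ),
    )
    annotations = annotate(hits, config.e_threshold)
    manifest["annotations.tsv"] = _write(
        out / "annotations.tsv",
        "query\tgene\te_value\tbit_score\n"
        + "".join(
            f"{q}\t{g}\t{e:.3e}\t{b:.1f}\n"
            for q, (g, e, b) in sorted(annotations.assignments.items())
        ),
    )

    # --- coverage ----------------------------------------------------
    cov = reference_coverage(annotations, reference)
    manifest["coverage.tsv"] = _write(
        out / "coverage.tsv",
        "n_reference_genes\tn_covered_genes\tpercent_covered\t"
        "n_queries\tn_matched_queries\tpercent_matched_queries\n"
        f"{cov.n_reference_genes}\t{cov.n_covered_genes}\t{cov.percent_covered:.2f}\t"
        f"{cov.n_queries}\t{cov.n_matched_queries}\t{cov.percent_matched_queries:.2f}\n",
    )

    # --- DEG ---------------------------------------------------------
    matrix = pool_tissues(counts, config.pooling) if config.pooling else counts
    records = find_deg_contigs(
        matrix, config.min_reads, config.exclusivity, annotations
    )
    summary = deg_genes(records, annotations)
    deg_lines = ["tissue\tn_candidates\tgenes"]
    for tissue in matrix.tissues:
        genes = summary.per_tissue_genes.get(tissue, [])
        deg_lines.append(f"{tissue}\t{len(genes)}\t{','.join(genes)}")
    deg_lines.append(f"total\t{summary.total_candidates}\t")
    manifest["deg_candidates.tsv"] = _write(
        out / "deg_candidates.tsv", "\n".join(deg_lines) + "\n"
    )
    manifest["deg_conflicts.tsv"] = _write(
        out / "deg_conflicts.tsv",
        "gene\ttissues\n"
        + "".join(f"{g}\t{','.join(ts)}\n" for g, ts in summary.conflicts),
    )
    manifest["deg_unannotated.tsv"] = _write(
        out / "deg_unannotated.tsv",
        "contig\ttissue\ttotal_reads\n"
        + "".join(
            f"{r.contig_id}\t{r.tissue}\t{r.total_reads}\n"
            for r in summary.unannotated_contigs
        ),
    )

    # --- AS ----------------------------------------------------------
    def group_annotated(g) -> bool:
        return any(annotations.gene_of(t.id) for t in g.isotigs) or any(
            annotations.gene_of(c) for c in g.contig_ids
        )

    as_groups = [
        g for g in groups if not config.annotated_only_as or group_annotated(g)
    ]
    events = []
    events_by_group = {}
    for g in as_groups:
        try:
            evs = detect_events(g)
        except OrderConflictError:
            if config.strict:
                raise
            logger.warning("skipping isogroup %s: order conflict", g.id)
            evs = []
        events_by_group[g.id] = evs
        events.extend(evs)

    # --- TE ----------------------------------------------------------
    if (events or repeats) and not contig_lengths:
        raise ValidationError(
            "contigs_fasta_path is required to anchor repeat margin windows"
        )
    te_cfg = TeCallConfig(margin_bp=config.margin_bp)
    flagged = flag_te_events(events, repeats, contig_lengths, te_cfg)
    events_by_group = {
        gid: [e for e in flagged if e.isogroup_id == gid] for gid in events_by_group
    }
    as_summary = summarize(
        as_groups,
        annotations,
        strict=config.strict,
        precomputed_events=events_by_group,
    )
    ev_lines = ["isogroup\tgene\tblock\tinclusion\tclass\tte_related"]
    gene_by_group = {}
    for g in as_groups:
        gene = ""
        for t in g.isotigs:
            gg = annotations.gene_of(t.id)
            if gg:
                gene = gg
                break
        gene_by_group[g.id] = gene
    for ev in flagged:
        ev_lines.append(
            f"{ev.isogroup_id}\t{gene_by_group.get(ev.isogroup_id, '')}\t"
            f"{','.join(ev.block)}\t{''.join(map(str, ev.inclusion))}\t"
            f"{ev.position_class}\t{int(ev.te_related)}"
        )
    manifest["as_events.tsv"] = _write(out / "as_events.tsv", "\n".join(ev_lines) + "\n")
    s = as_summary
    manifest["as_summary.tsv"] = _write(
        out / "as_summary.tsv",
        "n_isogroups_examined\tn_as_isogroups\tn_events\tmean_events_per_as_isogroup\t"
        "percent_as_isogroups\tn_five_prime\tn_three_prime\tn_internal\t"
        "max_events_gene\tmax_events\tn_te_related\tmargin_bp\n"
        f"{s.n_isogroups_examined}\t{s.n_as_isogroups}\t{s.n_events}\t"
        f"{s.mean_events_per_as_isogroup:.2f}\t{s.percent_as_isogroups}\t"
        f"{s.counts_by_class['five_prime']}\t{s.counts_by_class['three_prime']}\t"
        f"{s.counts_by_class['internal']}\t{s.max_events[0]}\t{s.max_events[1]}\t"
        f"{s.n_te_related}\t{config.margin_bp}\n",
    )
    if flagged:
        n_te, n_ev, pct = te_event_fraction(flagged)
    else:
        n_te, n_ev, pct = 0, 0, 0.0
    manifest["te_fraction.tsv"] = _write(
        out / "te_fraction.tsv",
        f"n_te_related\tn_events\tpercent\tmargin_bp\n{n_te}\t{n_ev}\t{pct:.1f}\t{config.margin_bp}\n",
    )

    # --- report + metadata ------------------------------------------
    report_lines = [
        "pipeline report",
        "===============",
        f"queries: {len(all_queries)} ({len(clustered)} clustered, {len(unclustered)} unclustered at E<={config.e_threshold:g})",
        f"reference coverage: {cov.n_covered_genes}/{cov.n_reference_genes} genes ({cov.percent_covered:.2f}%)",
        f"matched queries: {cov.n_matched_queries}/{cov.n_queries} ({cov.percent_matched_queries:.2f}%)",
        f"DEG candidates: {summary.total_candidates} genes "
        f"(min_reads={config.min_reads}, exclusivity={config.exclusivity:g}); "
        f"{len(summary.conflicts)} conflicts; {len(summary.unannotated_contigs)} unannotated passing contigs",
        f"AS: {s.n_events} events in {s.n_as_isogroups}/{s.n_isogroups_examined} isogroups "
        f"(mean {s.mean_events_per_as_isogroup:.2f}/AS-isogroup, {s.percent_as_isogroups}% AS); "
        f"5'={s.counts_by_class['five_prime']} 3'={s.counts_by_class['three_prime']} "
        f"internal={s.counts_by_class['internal']}",
        f"TE-related AS: {n_te}/{n_ev} events ({pct:.1f}%, margin {config.margin_bp} bp)",
    ]
    manifest["report.txt"] = _write(out / "report.txt", "\n".join(report_lines) + "\n")
    meta = [f"txome454_version\t{__version__}"]
    for f in fields(config):
        meta.append(f"{f.name}\t{getattr(config, f.name)}")
    manifest["run_metadata.tsv"] = _write(out / "run_metadata.tsv", "\n".join(meta) + "\n")
    return manifest
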