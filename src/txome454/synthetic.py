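"""Synthetic study generator with planted ground truth.

Emulates the data structure of a 16-tissue 454 transcriptome study at
desk scale: a reference gene set with orthologous transcripts, isogroups
whose isotigs are built from shared (constitutive) contigs plus variable
exon blocks, per-contig per-tissue read counts, BLAST-style hit tables,
and repeat annotations with TE insertions at variable-block margins.
Every planted feature — tissue-exclusive DEG genes, AS events with their
positional class, TE-related events, and the ortholog map — is recorded
in :class:`TruthTables` so downstream detectors can be scored exactly.

Construction guarantees that make recovery exact rather than
probabilistic at the defaults:

* planted DEG contigs have reads in exactly one tissue with a per-contig
  total of at least the downstream threshold (100); every other
  expressed contig has non-zero counts in at least two tissues;
* each variable block is a contiguous run of 1-2 contigs separated from
  other blocks by constitutive contigs, with an inclusion pattern that
  leaves it out of at least one isotig, so exhaustive pairwise isotig
  comparison exhibits exactly the planted blocks;
* a TE-related block carries a repeat overlapping a margin window of its
  boundary contig; decoy repeats are placed only outside every margin
  window.

Genes draw from per-gene random streams derived from (seed, gene index),
so enlarging ``n_genes`` does not reshuffle earlier genes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ConfigError
from .formats import (
    DEFAULT_TISSUES,
    HitRecord,
    Isogroup,
    Isotig,
    RepeatFeature,
    TissueCountMatrix,
    read_counts,
    read_fasta,
    read_gene_list,
    read_hits,
    read_layout,
    read_repeats,
    write_counts,
    write_fasta,
    write_gene_list,
    write_hits,
    write_layout,
    write_repeats,
)

# Table-1 per-tissue DEG candidate proportions of the study (sum 175),
# in DEFAULT_TISSUES order; used as the default tissue weights for
# planting tissue-exclusive genes.
_TABLE1_CANDIDATES = (4, 1, 3, 11, 42, 5, 0, 22, 3, 19, 11, 2, 0, 7, 45, 0)
DEFAULT_DEG_TISSUE_WEIGHTS = tuple(c / 175 for c in _TABLE1_CANDIDATES)


@dataclass(frozen=True)
class GenConfig:
    """Study-generator parameters; defaults are the study conditions at
    desk scale (16 tissues, ~17% multi-isoform isogroups, ~10.4% of
    variable blocks TE-inserted, ~20% unclustered genes)."""

    n_genes: int = 200
    n_tissues: int = 16
    tissue_names: tuple[str, ...] = DEFAULT_TISSUES
    p_multi_isoform: float = 0.17
    max_isotigs_per_isogroup: int = 5
    contigs_per_isotig_range: tuple[int, int] = (3, 8)
    contig_length_range: tuple[int, int] = (100, 500)
    p_deg: float = 0.10
    deg_tissue_weights: tuple[float, ...] = DEFAULT_DEG_TISSUE_WEIGHTS
    read_depth_mean: float = 50.0
    read_depth_dispersion: float = 0.5
    p_te_insertion: float = 0.104
    te_margin_bp: int = 30
    p_unclustered: float = 0.20
    seed: int = 42

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigError("n_genes must be a positive integer")
        if self.n_tissues < 1:
            raise ConfigError("n_tissues must be a positive integer")
        if len(self.tissue_names) != self.n_tissues:
            raise ConfigError("tissue_names length must equal n_tissues")
        if len(set(self.tissue_names)) != self.n_tissues:
            raise ConfigError("tissue_names must be distinct")
        for f in ("p_multi_isoform", "p_deg", "p_te_insertion", "p_unclustered"):
            v = getattr(self, f)
            if not 0 <= v <= 1:
                raise ConfigError(f"{f} must be in [0, 1]")
        if self.max_isotigs_per_isogroup < 1:
            raise ConfigError("max_isotigs_per_isogroup must be positive")
        for f in ("contigs_per_isotig_range", "contig_length_range"):
            lo, hi = getattr(self, f)
            if lo < 1 or lo > hi:
                raise ConfigError(f"{f} must be a non-empty positive range")
        if len(self.deg_tissue_weights) != self.n_tissues:
            raise ConfigError("deg_tissue_weights length must equal n_tissues")
        if any(w < 0 for w in self.deg_tissue_weights):
            raise ConfigError("deg_tissue_weights must be non-negative")
        if abs(sum(self.deg_tissue_weights) - 1.0) > 1e-9:
            raise ConfigError("deg_tissue_weights must sum to 1")
        if self.read_depth_mean <= 0:
            raise ConfigError("read_depth_mean must be positive")
        if self.read_depth_dispersion <= 0:
            raise ConfigError("read_depth_dispersion must be positive")
        if self.te_margin_bp < 1:
            raise ConfigError("te_margin_bp must be positive")


@dataclass(frozen=True)
class TruthTables:
    """Planted ground truth of one generated study."""

    deg_genes: dict[str, str]  # gene -> exclusive tissue
    as_events: tuple[tuple[str, tuple[str, ...], str], ...]  # (isogroup, block, class)
    te_related_events: tuple[tuple[str, tuple[str, ...], str], ...]
    ortholog_map: dict[str, str]  # gene -> reference gene or "none"

    def __post_init__(self):
        if not set(self.te_related_events) <= set(self.as_events):
            raise ConfigError("te_related_events must be a subset of as_events")


@dataclass
class StudyBundle:
    """All artifacts of one generated study, in memory."""

    config: GenConfig
    reference_genes: list[str]
    contig_sequences: dict[str, str]
    isogroups: list[Isogroup]
    hits: list[HitRecord]
    counts: TissueCountMatrix
    repeats: list[RepeatFeature]
    truth: TruthTables

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(s) for cid, s in self.contig_sequences.items()}


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    """Negative-binomial draws parameterised by mean and dispersion
    (variance = mean + dispersion * mean^2)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def generate_study(config: GenConfig) -> StudyBundle:
    """Generate a complete synthetic study; deterministic given the
    config (including its seed)."""
    tissues = list(config.tissue_names)
    reference_genes: list[str] = []
    contig_sequences: dict[str, str] = {}
    isogroups: list[Isogroup] = []
    hits: list[HitRecord] = []
    repeats: list[RepeatFeature] = []
    deg_truth: dict[str, str] = {}
    as_truth: list[tuple[str, tuple[str, ...], str]] = []
    te_truth: list[tuple[str, tuple[str, ...], str]] = []
    ortholog_map: dict[str, str] = {}
    count_rows: dict[str, np.ndarray] = {}

    weights = np.asarray(config.deg_tissue_weights, dtype=float)
    weights = weights / weights.sum()

    contig_counter = 0
    for gi in range(config.n_genes):
        rng = np.random.default_rng([config.seed % (2**63), gi])
        gene = f"MFGENE{gi + 1:05d}"
        ref_gene = f"HREF{gi + 1:05d}"
        reference_genes.append(ref_gene)
        group_id = f"isogroup{gi + 1:05d}"

        unclustered = rng.random() < config.p_unclustered
        multi = rng.random() < config.p_multi_isoform
        if multi and config.max_isotigs_per_isogroup >= 2:
            n_isotigs = int(rng.integers(2, config.max_isotigs_per_isogroup + 1))
        else:
            n_isotigs = 1

        lo, hi = config.contigs_per_isotig_range
        n_const = max(2, int(rng.integers(lo, hi + 1)))

        # variable blocks: contiguous 1-2 contig runs in slots between
        # (and flanking) the constitutive contigs; at most n_isotigs - 1
        # blocks so each can be left out of a dedicated isotig.
        n_blocks = 0
        if n_isotigs >= 2:
            n_blocks = int(rng.integers(1, min(3, n_isotigs - 1, n_const) + 1))
        # slots: 0 = before const[0] (5'), k in 1..n_const-1 = internal,
        # n_const = after the last constitutive contig (3')
        slot_ids = rng.choice(n_const + 1, size=n_blocks, replace=False) if n_blocks else []

        def new_contig() -> str:
            nonlocal contig_counter
            contig_counter += 1
            cid = f"contig{contig_counter:06d}"
            length = int(
                rng.integers(config.contig_length_range[0], config.contig_length_range[1] + 1)
            )
            contig_sequences[cid] = _random_seq(rng, length)
            return cid

        const_contigs = [new_contig() for _ in range(n_const)]
        blocks: list[tuple[int, tuple[str, ...]]] = []
        for slot in sorted(int(s) for s in slot_ids):
            run = tuple(new_contig() for _ in range(int(rng.integers(1, 3))))
            blocks.append((slot, run))

        # global layout: blocks interleaved with constitutive contigs
        layout: list[str] = []
        block_at = dict(blocks)
        for slot in range(n_const + 1):
            if slot in block_at:
                layout.extend(block_at[slot])
            if slot < n_const:
                layout.append(const_contigs[slot])

        # isotig inclusion patterns over blocks: isotig 0 includes all;
        # isotig j (1..n_blocks) excludes exactly block j-1; any further
        # isotigs exclude a random non-empty block subset not yet used.
        patterns: list[tuple[int, ...]] = [tuple([1] * n_blocks)]
        for j in range(n_blocks):
            pat = [1] * n_blocks
            pat[j] = 0
            patterns.append(tuple(pat))
        while len(patterns) < n_isotigs:
            pat = tuple(int(b) for b in rng.integers(0, 2, size=n_blocks))
            if pat not in patterns:
                patterns.append(pat)
            elif len(patterns) >= 2**n_blocks:
                break
        n_isotigs = len(patterns)

        isotigs = []
        slot_index = {s: k for k, (s, _) in enumerate(blocks)}
        for ti, pat in enumerate(patterns):
            members: list[str] = []
            for slot in range(n_const + 1):
                if slot in block_at:
                    if pat[slot_index[slot]]:
                        members.extend(block_at[slot])
                if slot < n_const:
                    members.append(const_contigs[slot])
            isotigs.append(
                Isotig(
                    f"isotig{gi + 1:05d}_{ti:02d}",
                    tuple((c, "+") for c in members),
                )
            )
        isogroups.append(Isogroup(group_id, tuple(isotigs)))

        # truth AS events, 5'->3'
        for slot, run in blocks:
            if slot == 0:
                cls = "five_prime"
            elif slot == n_const:
                cls = "three_prime"
            else:
                cls = "internal"
            as_truth.append((group_id, run, cls))

        # TE insertions at variable-block margins, plus decoy repeats
        # strictly outside every margin window.
        margin = config.te_margin_bp
        for slot, run in blocks:
            if rng.random() < config.p_te_insertion:
                five_side = bool(rng.random() < 0.5)
                cid = run[0] if five_side else run[-1]
                clen = len(contig_sequences[cid])
                rep_len = int(rng.integers(60, 301))
                if five_side:
                    start = int(rng.integers(0, min(margin, clen)))
                    end = min(clen, start + rep_len)
                else:
                    end = clen - int(rng.integers(0, min(margin, clen)))
                    start = max(0, end - rep_len)
                repeats.append(
                    RepeatFeature(cid, start, end, "+", "AluY", "SINE/Alu")
                )
                te_truth.append((group_id, run, _class_of(slot, n_const)))
            else:
                # decoy repeat in the block interior, beyond both margins
                cid = run[0]
                clen = len(contig_sequences[cid])
                interior = clen - 2 * margin - 20
                if interior > 0 and rng.random() < 0.5:
                    start = margin + 10 + int(rng.integers(0, interior))
                    end = min(clen - margin - 1, start + 150)
                    if end > start:
                        repeats.append(
                            RepeatFeature(cid, start, end, "+", "L1MA4", "LINE/L1")
                        )
        # decoys on constitutive contigs (never part of an event block)
        if n_const and rng.random() < 0.3:
            cid = const_contigs[int(rng.integers(0, n_const))]
            clen = len(contig_sequences[cid])
            start = int(rng.integers(0, max(1, clen - 80)))
            repeats.append(
                RepeatFeature(cid, start, min(clen, start + 80), "-", "MIR", "SINE/MIR")
            )

        # hits: clustered genes get strong hits for every isotig and
        # contig; unclustered genes get at most a weak (above-threshold)
        # hit, so they never cluster at the 1e-20 cutoff.
        ortholog_map[gene] = "none" if unclustered else ref_gene
        queries = [t.id for t in isotigs] + [
            c for t in isotigs for c in t.contig_ids
        ]
        queries = list(dict.fromkeys(queries))
        for q in queries:
            qlen = len(contig_sequences.get(q, "")) or 500
            if not unclustered:
                exponent = int(rng.integers(25, 120))
                hits.append(
                    HitRecord(
                        query_id=q,
                        subject_id=ref_gene,
                        percent_identity=float(np.round(90 + 9 * rng.random(), 2)),
                        alignment_length=qlen,
                        mismatches=int(rng.integers(0, 10)),
                        gap_opens=0,
                        query_start=1,
                        query_end=qlen,
                        subject_start=1,
                        subject_end=qlen,
                        e_value=10.0 ** (-exponent),
                        bit_score=float(200 + int(rng.integers(0, 800))),
                    )
                )
            elif rng.random() < 0.5:
                hits.append(
                    HitRecord(
                        query_id=q,
                        subject_id=f"HREF{int(rng.integers(1, config.n_genes + 1)):05d}",
                        percent_identity=float(np.round(60 + 15 * rng.random(), 2)),
                        alignment_length=min(80, qlen),
                        mismatches=int(rng.integers(10, 30)),
                        gap_opens=int(rng.integers(0, 5)),
                        query_start=1,
                        query_end=min(80, qlen),
                        subject_start=1,
                        subject_end=min(80, qlen),
                        e_value=10.0 ** (-float(rng.integers(1, 10))),
                        bit_score=float(30 + int(rng.integers(0, 40))),
                    )
                )

        # read counts per contig
        gene_contigs = sorted(
            {c for t in isotigs for c in t.contig_ids},
            key=layout.index,
        )
        is_deg = (not unclustered) and rng.random() < config.p_deg
        if is_deg:
            tissue_idx = int(rng.choice(config.n_tissues, p=weights))
            deg_truth[gene] = tissues[tissue_idx]
            for cid in gene_contigs:
                row = np.zeros(config.n_tissues, dtype=int)
                row[tissue_idx] = 100 + int(
                    _nb_counts(rng, config.read_depth_mean, config.read_depth_dispersion, 1)[0]
                )
                count_rows[cid] = row
        else:
            for cid in gene_contigs:
                row = _nb_counts(
                    rng,
                    config.read_depth_mean / config.n_tissues,
                    config.read_depth_dispersion,
                    config.n_tissues,
                ).astype(int)
                # guarantee >=2 tissues with non-zero counts so no
                # non-planted contig can be 100% tissue-exclusive
                nz = np.flatnonzero(row)
                if len(nz) < 2:
                    need = 2 - len(nz)
                    zeros = [i for i in range(config.n_tissues) if row[i] == 0]
                    for i in zeros[:need]:
                        row[i] = 1
                count_rows[cid] = row

    counts = TissueCountMatrix(
        pd.DataFrame(
            {t: [int(count_rows[c][i]) for c in count_rows] for i, t in enumerate(tissues)},
            index=list(count_rows),
        )
    )
    return StudyBundle(
        config=config,
        reference_genes=reference_genes,
        contig_sequences=contig_sequences,
        isogroups=isogroups,
        hits=hits,
        counts=counts,
        repeats=sorted(repeats, key=lambda r: (r.target_id, r.start, r.end, r.name)),
        truth=TruthTables(
            deg_genes=deg_truth,
            as_events=tuple(as_truth),
            te_related_events=tuple(te_truth),
            ortholog_map=ortholog_map,
        ),
    )


def _class_of(slot: int, n_const: int) -> str:
    if slot == 0:
        return "five_prime"
    if slot == n_const:
        return "three_prime"
    return "internal"


MANIFEST_FILES = (
    "contigs.fasta",
    "layout.txt",
    "hits.tsv",
    "counts.tsv",
    "repeats.tsv",
    "reference_genes.txt",
    "deg_truth.tsv",
    "as_truth.tsv",
    "ortholog_truth.tsv",
)


def write_bundle(bundle: StudyBundle, directory: str | Path) -> dict[str, Path]:
    """Write every bundle artifact to ``directory`` in the formats module
    dialects; returns a manifest of written files.  Re-reading with
    :func:`read_bundle` reproduces the bundle exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def put(name: str, text: str) -> None:
        path = directory / name
        path.write_text(text)
        manifest[name] = path

    with io.StringIO() as buf:
        write_fasta(bundle.contig_sequences, buf)
        put("contigs.fasta", buf.getvalue())
    put("layout.txt", write_layout(bundle.isogroups))
    put("hits.tsv", write_hits(bundle.hits))
    put("counts.tsv", write_counts(bundle.counts))
    put("repeats.tsv", write_repeats(bundle.repeats))
    put("reference_genes.txt", write_gene_list(bundle.reference_genes))
    deg_rows = ["gene\ttissue"] + [
        f"{g}\t{t}" for g, t in sorted(bundle.truth.deg_genes.items())
    ]
    put("deg_truth.tsv", "\n".join(deg_rows) + "\n")
    as_rows = ["isogroup\tblock\tclass\tte_related"]
    te_set = set(bundle.truth.te_related_events)
    for ev in bundle.truth.as_events:
        gid, block, cls = ev
        as_rows.append(f"{gid}\t{','.join(block)}\t{cls}\t{int(ev in te_set)}")
    put("as_truth.tsv", "\n".join(as_rows) + "\n")
    ortho_rows = ["gene\treference_gene"] + [
        f"{g}\t{r}" for g, r in sorted(bundle.truth.ortholog_map.items())
    ]
    put("ortholog_truth.tsv", "\n".join(ortho_rows) + "\n")
    return manifest


def read_bundle(directory: str | Path, config: GenConfig) -> StudyBundle:
    """Read a written bundle back into memory (inverse of
    :func:`write_bundle`; the config is carried, not re-derived)."""
    directory = Path(directory)
    contig_sequences = read_fasta(str(directory / "contigs.fasta"))
    with open(directory / "layout.txt") as fh:
        isogroups = read_layout(fh)
    with open(directory / "hits.tsv") as fh:
        hits = read_hits(fh)
    with open(directory / "counts.tsv") as fh:
        counts = read_counts(fh)
    with open(directory / "repeats.tsv") as fh:
        repeats = read_repeats(fh, dialect="tsv")
    with open(directory / "reference_genes.txt") as fh:
        reference_genes = read_gene_list(fh)
    deg_genes: dict[str, str] = {}
    for line in (directory / "deg_truth.tsv").read_text().splitlines()[1:]:
        g, t = line.split("\t")
        deg_genes[g] = t
    as_events: list[tuple[str, tuple[str, ...], str]] = []
    te_events: list[tuple[str, tuple[str, ...], str]] = []
    for line in (directory / "as_truth.tsv").read_text().splitlines()[1:]:
        gid, block, cls, te = line.split("\t")
        ev = (gid, tuple(block.split(",")), cls)
        as_events.append(ev)
        if te == "1":
            te_events.append(ev)
    ortholog_map: dict[str, str] = {}
    for line in (directory / "ortholog_truth.tsv").read_text().splitlines()[1:]:
        g, r = line.split("\t")
        ortholog_map[g] = r
    return StudyBundle(
        config=config,
        reference_genes=reference_genes,
        contig_sequences=contig_sequences,
        isogroups=isogroups,
        hits=hits,
        counts=counts,
        repeats=repeats,
        truth=TruthTables(
            deg_genes=deg_genes,
            as_events=tuple(as_events),
            te_related_events=tuple(te_events),
            ortholog_map=ortholog_map,
        ),
    )
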