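"""Readers and writers for every file dialect the pipeline touches.

All coordinates are 0-based half-open **in memory**; 1-based inclusive
coordinates exist only inside the file dialects that use them
(RepeatMasker ``.out``, the repeats TSV and BLAST tabular hits), and are
converted exactly once, at read/write time.  Readers reject malformed
input with a :class:`~txome454._util.ParseError` carrying the offending
line number; they never silently repair.

Dialects
--------
layout
    A simplified isotig-layout file standing in for Newbler's pictorial
    ``454IsotigsLayout.txt``.  ``#`` comments; per isogroup a header line
    ``>`` id TAB ``numIsotigs=`` n TAB ``numContigs=`` m followed by n
    lines ``isotig-id`` TAB ``contig(+),contig(-),...`` listing members
    5'->3'.  Only the isotig<->contig membership relation is encoded,
    which is all the alternative-splicing analysis consumes.
hits
    BLAST tabular ``outfmt 6``: 12 tab-separated columns.
repeats
    RepeatMasker ``.out`` (3 header lines, whitespace-separated, 1-based
    inclusive query coordinates, strand ``C`` meaning complement) or a
    simplified 6-column TSV (target, start, end, strand, name,
    class/family; 1-based inclusive in the file).
counts
    TSV with a header row: first column contig id, remaining columns
    tissue labels, integer cells.
FASTA
    Standard, via Biopython; wrapped at 70 columns on write.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import IO, Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from ._util import ParseError, ValidationError

# The 16 tissue libraries of the study design, in library order.
DEFAULT_TISSUES: tuple[str, ...] = (
    "cecum",
    "cerebellum",
    "heart",
    "kidney",
    "liver",
    "lung",
    "ovary",
    "pancreas",
    "prostate",
    "salivary_gland",
    "skeletal_muscle",
    "small_intestine",
    "spleen",
    "stomach",
    "testis",
    "cerebrum",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """An assembled sequence segment (roughly exon-scale in transcript
    assemblies). ``sequence`` is optional; when present its length must
    equal ``length``."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValidationError(f"contig {self.id}: non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"contig {self.id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass(frozen=True)
class Isotig:
    """One putative transcript isoform: an ordered 5'->3' path of
    (contig id, orientation) members."""

    id: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"isotig {self.id}: no members")
        ids = [c for c, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"isotig {self.id}: duplicate member contig")
        for c, o in self.members:
            if o not in ("+", "-"):
                raise ValidationError(f"isotig {self.id}: bad orientation {o!r}")

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.members)


@dataclass(frozen=True)
class Isogroup:
    """The set of isotigs sharing contigs — one gene's transcript variants."""

    id: str
    isotigs: tuple[Isotig, ...]

    def __post_init__(self):
        if not self.isotigs:
            raise ValidationError(f"isogroup {self.id}: no isotigs")
        tids = [t.id for t in self.isotigs]
        if len(set(tids)) != len(tids):
            raise ValidationError(f"isogroup {self.id}: duplicate isotig id")

    @property
    def contig_ids(self) -> set[str]:
        out: set[str] = set()
        for t in self.isotigs:
            out.update(t.contig_ids)
        return out


@dataclass(frozen=True)
class HitRecord:
    """One similarity alignment between a query transcript and a
    reference gene (BLAST tabular row)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValidationError(f"hit {self.query_id}: negative E-value")
        if not 0 <= self.percent_identity <= 100:
            raise ValidationError(f"hit {self.query_id}: identity out of [0,100]")


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat-library match on a contig or isotig.

    ``start``/``end`` are 0-based half-open on the target; file dialects
    are 1-based inclusive and converted on read.
    """

    target_id: str
    start: int
    end: int
    strand: str
    name: str
    repeat_class: str

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"repeat {self.name} on {self.target_id}: bad interval "
                f"[{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"repeat {self.name}: bad strand {self.strand!r}")


@dataclass
class TissueCountMatrix:
    """Per-contig, per-tissue read counts backed by an integer DataFrame
    (rows = contig ids, columns = tissue labels)."""

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts
        if df.index.has_duplicates:
            raise ValidationError("duplicate contig ids in count matrix")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate tissue labels in count matrix")
        if df.size and (df.to_numpy() < 0).any():
            raise ValidationError("negative read count in count matrix")
        df = df.astype(int)
        df.index.name = "contig"
        df.columns.name = None
        self.counts = df

    @property
    def contig_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other) -> bool:
        return isinstance(other, TissueCountMatrix) and self.counts.equals(
            other.counts
        )


# ---------------------------------------------------------------------------
# layout dialect
# ---------------------------------------------------------------------------

_MEMBER_RE = re.compile(r"^(?P<cid>[^(),\s]+)\((?P<ori>[+-])\)$")


def read_layout(stream: IO[str] | Iterable[str]) -> list[Isogroup]:
    """Parse the simplified isotig-layout dialect into isogroups.

    Declared ``numIsotigs``/``numContigs`` must match the parsed content;
    any mismatch, duplicate id or malformed member raises
    :class:`ParseError` with the line number.
    """
    groups: list[Isogroup] = []
    lines = list(stream)
    i = 0
    n = len(lines)
    while i < n:
        raw = lines[i]
        line = raw.strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith(">"):
            raise ParseError(f"expected isogroup header, got {line!r}", i)
        header_line = i
        fields = line[1:].split("\t")
        if len(fields) != 3:
            raise ParseError("header needs id, numIsotigs=, numContigs=", i)
        gid = fields[0].strip()
        try:
            if not fields[1].startswith("numIsotigs=") or not fields[2].startswith(
                "numContigs="
            ):
                raise ValueError
            n_isotigs = int(fields[1].split("=", 1)[1])
            n_contigs = int(fields[2].split("=", 1)[1])
        except ValueError:
            raise ParseError("malformed numIsotigs/numContigs", header_line) from None
        isotigs: list[Isotig] = []
        for _ in range(n_isotigs):
            # skip comments/blank between records
            while i < n and (not lines[i].strip() or lines[i].strip().startswith("#")):
                i += 1
            if i >= n or lines[i].strip().startswith(">"):
                raise ParseError(
                    f"isogroup {gid}: declared numIsotigs={n_isotigs} but record "
                    f"has {len(isotigs)} isotig line(s)",
                    header_line,
                )
            row = lines[i].strip()
            i += 1
            parts = row.split("\t")
            if len(parts) != 2:
                raise ParseError("isotig line needs id TAB members", i)
            tid, member_str = parts
            members = []
            for tok in member_str.split(","):
                m = _MEMBER_RE.match(tok.strip())
                if not m:
                    raise ParseError(f"malformed member token {tok!r}", i)
                members.append((m.group("cid"), m.group("ori")))
            try:
                isotigs.append(Isotig(tid, tuple(members)))
            except ValidationError as exc:
                raise ParseError(str(exc), i) from None
        group_contigs = set()
        for t in isotigs:
            group_contigs.update(t.contig_ids)
        if len(group_contigs) != n_contigs:
            raise ParseError(
                f"isogroup {gid}: declared numContigs={n_contigs} but members "
                f"reference {len(group_contigs)} distinct contigs",
                header_line,
            )
        try:
            groups.append(Isogroup(gid, tuple(isotigs)))
        except ValidationError as exc:
            raise ParseError(str(exc), header_line) from None
    if len({g.id for g in groups}) != len(groups):
        raise ParseError("duplicate isogroup id", 1)
    return groups


def write_layout(groups: Iterable[Isogroup]) -> str:
    """Serialise isogroups to the layout dialect; inverse of
    :func:`read_layout`."""
    out = ["# isotig layout: >id\tnumIsotigs=n\tnumContigs=m; then n member lines"]
    for g in groups:
        out.append(f">{g.id}\tnumIsotigs={len(g.isotigs)}\tnumContigs={len(g.contig_ids)}")
        for t in g.isotigs:
            members = ",".join(f"{c}({o})" for c, o in t.members)
            out.append(f"{t.id}\t{members}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# BLAST tabular hits
# ---------------------------------------------------------------------------


def read_hits(stream: IO[str] | Iterable[str]) -> list[HitRecord]:
    """Parse a 12-column BLAST ``outfmt 6`` table."""
    hits: list[HitRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise ParseError(f"expected 12 columns, got {len(cols)}", lineno)
        try:
            hit = HitRecord(
                query_id=cols[0],
                subject_id=cols[1],
                percent_identity=float(cols[2]),
                alignment_length=int(cols[3]),
                mismatches=int(cols[4]),
                gap_opens=int(cols[5]),
                query_start=int(cols[6]),
                query_end=int(cols[7]),
                subject_start=int(cols[8]),
                subject_end=int(cols[9]),
                e_value=float(cols[10]),
                bit_score=float(cols[11]),
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"unparsable hit row: {exc}", lineno) from None
        hits.append(hit)
    return hits


def write_hits(hits: Iterable[HitRecord]) -> str:
    rows = []
    for h in hits:
        rows.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.percent_identity:.2f}",
                    str(h.alignment_length),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.query_start),
                    str(h.query_end),
                    str(h.subject_start),
                    str(h.subject_end),
                    f"{h.e_value:.2e}" if h.e_value else "0.0",
                    f"{h.bit_score:.1f}",
                ]
            )
        )
    return "\n".join(rows) + ("\n" if rows else "")


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------


def read_repeats(
    stream: IO[str] | Iterable[str],
    dialect: Literal["rm_out", "tsv"] = "tsv",
    target_lengths: dict[str, int] | None = None,
) -> list[RepeatFeature]:
    """Parse repeat annotations from RepeatMasker ``.out`` or the 6-column
    TSV dialect, converting 1-based inclusive file coordinates to the
    0-based half-open in-memory convention in this single step."""
    if dialect not in ("rm_out", "tsv"):
        raise ValidationError(f"unknown repeats dialect {dialect!r}")
    feats: list[RepeatFeature] = []
    lines = list(stream)
    start_at = 0
    if dialect == "rm_out":
        # standard .out: two header lines + one blank
        start_at = 3
        for lineno in range(min(2, len(lines))):
            head = lines[lineno]
            if "score" not in head and "SW" not in head and head.strip():
                raise ParseError("not a RepeatMasker .out header", lineno + 1)
    for lineno, raw in enumerate(lines[start_at:], start=start_at + 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if dialect == "rm_out":
            cols = line.split()
            if len(cols) < 14:
                raise ParseError(f"expected >=14 .out columns, got {len(cols)}", lineno)
            target, b, e, strand, name, rclass = (
                cols[4],
                cols[5],
                cols[6],
                cols[8],
                cols[9],
                cols[10],
            )
            strand = "-" if strand == "C" else strand
        else:
            cols = line.split("\t")
            if len(cols) != 6:
                raise ParseError(f"expected 6 TSV columns, got {len(cols)}", lineno)
            target, b, e, strand, name, rclass = cols
        try:
            begin1, end1 = int(b), int(e)
        except ValueError:
            raise ParseError(f"unparsable repeat coordinates {b!r}/{e!r}", lineno) from None
        start, end = begin1 - 1, end1  # 1-based inclusive -> 0-based half-open
        if start < 0 or end <= start:
            raise ParseError(f"bad repeat interval {begin1}..{end1}", lineno)
        if target_lengths is not None:
            tlen = target_lengths.get(target)
            if tlen is not None and end > tlen:
                raise ParseError(
                    f"repeat end {end1} beyond {target} length {tlen}", lineno
                )
        try:
            feats.append(RepeatFeature(target, start, end, strand, name, rclass))
        except ValidationError as exc:
            raise ParseError(str(exc), lineno) from None
    return feats


def write_repeats(feats: Iterable[RepeatFeature]) -> str:
    """Write the 6-column TSV repeats dialect (1-based inclusive)."""
    rows = [
        "\t".join(
            [f.target_id, str(f.start + 1), str(f.end), f.strand, f.name, f.repeat_class]
        )
        for f in feats
    ]
    return "\n".join(rows) + ("\n" if rows else "")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


def read_counts(stream: IO[str]) -> TissueCountMatrix:
    df = pd.read_csv(stream, sep="\t", index_col=0, dtype=str)
    try:
        numeric = df.apply(pd.to_numeric)
    except ValueError as exc:
        raise ParseError(f"non-integer count cell: {exc}", 2) from None
    if numeric.size and not (numeric.to_numpy() == numeric.to_numpy().astype(int)).all():
        raise ParseError("non-integer count cell", 2)
    return TissueCountMatrix(numeric.astype(int))


def write_counts(matrix: TissueCountMatrix) -> str:
    df = matrix.counts
    header = "contig\t" + "\t".join(map(str, df.columns))
    rows = [header]
    for cid, row in df.iterrows():
        rows.append(str(cid) + "\t" + "\t".join(str(int(v)) for v in row))
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# FASTA and gene lists
# ---------------------------------------------------------------------------


def read_fasta(path_or_handle) -> dict[str, str]:
    """Read FASTA into an id -> sequence mapping (order-preserving)."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(path_or_handle, "fasta")
    }


def write_fasta(sequences: dict[str, str], handle) -> None:
    """Write sequences as FASTA wrapped at 70 columns."""
    writer = FastaWriter(handle, wrap=70)
    writer.write_file(
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()
    )


def read_gene_list(stream: IO[str] | Iterable[str]) -> list[str]:
    """One gene id per line; ``#`` comments and blanks skipped; duplicates
    rejected."""
    ids: list[str] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line in seen:
            raise ParseError(f"duplicate gene id {line!r}", lineno)
        seen.add(line)
        ids.append(line)
    return ids


def write_gene_list(ids: Iterable[str]) -> str:
    rows = list(ids)
    return "\n".join(rows) + ("\n" if rows else "")
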