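"""Annotation, sequence and expression-table I/O.

All genomic coordinates in this package are 1-based and inclusive on both
ends (the GFF3 convention); an interval ``start..end`` therefore spans
``end - start + 1`` bases.  Any half-open arithmetic is internal to a
function and never serialized.

Both GTF and GFF3 are accepted on input (dialect auto-detected per line by
gffutils); output is always GFF3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSet",
    "GffParseError",
    "read_gff",
    "write_gff",
    "read_bed",
    "read_fasta",
    "write_fasta",
    "read_expression",
    "write_expression",
    "parse_conditions",
    "DEFAULT_CONDITION_MAP",
]

STRANDS = ("+", "-")

#: sample-name prefix -> condition, after the control (PC1-PC3) vs heat
#: (PH1-PH3) library design this pipeline was built around.
DEFAULT_CONDITION_MAP: Mapping[str, str] = {"PC": "control", "PH": "heat"}


class GffParseError(ValueError):
    """Raised for malformed GTF/GFF3 input; message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded, 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap(self, other: "GenomicInterval") -> int | None:
        """Bases strictly between the intervals; 0 on overlap.

        Returns None for intervals on different chromosomes.  Symmetric in
        its arguments: ``gap = later.start - earlier.end - 1``.
        """
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        earlier, later = (self, other) if self.start <= other.start else (other, self)
        return later.start - earlier.end - 1


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered non-overlapping exons on one chromosome/strand.

    ``length`` is the spliced length (sum of exon lengths), the quantity the
    200-nt lncRNA size filter and FPKM use.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "candidate"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        prev_end = 0
        for e in self.exons:
            if e.start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = e.end

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom,
            self.exons[0].start,
            self.exons[-1].end,
            self.exons[0].strand,
        )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start - a.end > 1:
                out.append(
                    GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand)
                )
        return tuple(out)


@dataclass
class AnnotationSet:
    """A keyed collection of transcripts with derived gene spans."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "AnnotationSet":
        d: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.transcript_id in d:
                raise ValueError(f"duplicate transcript id {t.transcript_id}")
            d[t.transcript_id] = t
        return cls(d)

    @property
    def genes(self) -> dict[str, GenomicInterval]:
        """gene_id -> union span of the gene's transcripts."""
        spans: dict[str, GenomicInterval] = {}
        for t in self.transcripts.values():
            iv = t.interval
            cur = spans.get(t.gene_id)
            if cur is None:
                spans[t.gene_id] = iv
            else:
                spans[t.gene_id] = GenomicInterval(
                    cur.chrom, min(cur.start, iv.start), max(cur.end, iv.end), cur.strand
                )
        return spans

    def subset(self, biotype: str) -> "AnnotationSet":
        return AnnotationSet(
            {k: t for k, t in self.transcripts.items() if t.biotype == biotype}
        )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]


# ---------------------------------------------------------------------------
# GFF3 / GTF

_EXON_TYPES = frozenset({"exon"})
_TRANSCRIPT_TYPES = frozenset(
    {"transcript", "mRNA", "lnc_RNA", "lncRNA", "ncRNA", "primary_transcript"}
)


def _first(attrs, *keys) -> str | None:
    for k in keys:
        v = attrs.get(k)
        if v:
            return v[0]
    return None


def read_gff(path: str | Path, feature_policy: Mapping | None = None) -> AnnotationSet:
    """Read a GTF or GFF3 annotation into an :class:`AnnotationSet`.

    Transcript spans are computed from exons; exons must carry a transcript
    attribute (``transcript_id`` in GTF, ``Parent`` in GFF3) and an explicit
    strand.  Malformed lines raise :class:`GffParseError` naming the line.
    """
    policy = dict(feature_policy or {})
    exon_types = frozenset(policy.get("exon_types", _EXON_TYPES))
    tx_types = frozenset(policy.get("transcript_types", _TRANSCRIPT_TYPES))
    biotype_attrs = tuple(
        policy.get("biotype_attrs", ("biotype", "transcript_biotype", "gene_biotype"))
    )

    exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise GffParseError(
                    f"{path}: line {lineno}: non-numeric start/end "
                    f"({fields[3]!r}, {fields[4]!r})"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # pragma: no cover - defensive
                raise GffParseError(f"{path}: line {lineno}: {exc}") from exc

            ftype = feat.featuretype
            if ftype in tx_types:
                tid = _first(feat.attributes, "ID", "transcript_id")
                gid = _first(feat.attributes, "Parent", "gene_id") or tid
                if tid:
                    tx_gene[tid] = gid
                    bt = _first(feat.attributes, *biotype_attrs)
                    if bt:
                        tx_biotype[tid] = bt
            elif ftype in exon_types:
                tid = _first(feat.attributes, "transcript_id", "Parent")
                if tid is None:
                    raise GffParseError(
                        f"{path}: line {lineno}: exon without a transcript "
                        "attribute (transcript_id/Parent)"
                    )
                if feat.strand not in STRANDS:
                    raise GffParseError(
                        f"{path}: line {lineno}: exon of {tid} has strand "
                        f"{feat.strand!r}; explicit +/- required"
                    )
                gid = _first(feat.attributes, "gene_id")
                if gid:
                    tx_gene.setdefault(tid, gid)
                bt = _first(feat.attributes, *biotype_attrs)
                if bt:
                    tx_biotype.setdefault(tid, bt)
                exons.setdefault(tid, []).append(
                    GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
                )

    transcripts = []
    for tid, exs in exons.items():
        exs.sort(key=lambda e: e.start)
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=tx_gene.get(tid, tid),
                exons=tuple(exs),
                biotype=tx_biotype.get(tid, "candidate"),
            )
        )
    return AnnotationSet.from_transcripts(transcripts)


def write_gff(annotation: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as GFF3, sorted by (chrom, start, transcript_id)."""
    order = sorted(
        annotation,
        key=lambda t: (t.chrom, t.interval.start, t.transcript_id),
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in order:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\tstresslnc\ttranscript\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={t.transcript_id};Parent={t.gene_id};"
                f"biotype={t.biotype}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{e.chrom}\tstresslnc\texon\t{e.start}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tParent={t.transcript_id}\n"
                )


def read_bed(path: str | Path, biotype: str = "known_lncRNA") -> AnnotationSet:
    """Read a BED6 track (e.g. a known-lncRNA annotation) as single-exon models.

    BED is 0-based half-open; coordinates are converted to 1-based inclusive.
    """
    transcripts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise GffParseError(
                    f"{path}: line {lineno}: BED6 requires 6 columns"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            transcripts.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=name,
                    exons=(GenomicInterval(chrom, int(start) + 1, int(end), strand),),
                    biotype=biotype,
                )
            )
    return AnnotationSet.from_transcripts(transcripts)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Expression tables

_SAMPLE_RE = re.compile(r"^([A-Za-z_]+?)(\d+)$")


def parse_conditions(
    sample_ids: Iterable[str],
    condition_map: Mapping[str, str] | None = None,
) -> pd.Series:
    """Map sample names like PC1..PC3/PH1..PH3 to condition labels.

    The trailing integer is the replicate index; the leading prefix is looked
    up in ``condition_map`` (default: PC -> control, PH -> heat).  Unmapped
    prefixes become their own condition label.
    """
    cmap = dict(condition_map or DEFAULT_CONDITION_MAP)
    out = {}
    for s in sample_ids:
        m = _SAMPLE_RE.match(s)
        prefix = m.group(1) if m else s
        out[s] = cmap.get(prefix, prefix)
    return pd.Series(out, name="condition")


def read_expression(
    path: str | Path,
    condition_map: Mapping[str, str] | None = None,
    integer: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Read a features x samples TSV of counts (or FPKM with integer=False).

    Returns (matrix, condition labels).  Raises on duplicated feature ids,
    missing cells and (for counts) negative or non-integer values, naming the
    offending row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated feature ids: {dups}")
    if df.isna().any().any():
        r, c = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
        )
        raise ValueError(f"{path}: missing value at feature {r!r}, sample {c!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric value at feature {bad!r}, sample {col!r}"
            )
    if (df.values < 0).any():
        r, c = next(
            (r, c) for r in df.index for c in df.columns if df.at[r, c] < 0
        )
        raise ValueError(f"{path}: negative value at feature {r!r}, sample {c!r}")
    if integer:
        df = df.round().astype(int)
    conditions = parse_conditions(df.columns, condition_map)
    return df, conditions


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")
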