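"""lncRNA discovery: filter cascade, coding-potential consensus, classification.

The cascade screens assembled transcripts with ordered rules —

1. ``min_length``       spliced length >= 200 nt (single-exon transcripts are
                        retained by default);
2. ``coding_overlap``   same-strand exonic overlap with a protein-coding gene
                        rejects the transcript; overlap with a known-lncRNA
                        track instead marks it as a known lncRNA (opposite-
                        strand overlap is never a rejection, otherwise the
                        antisense class could not exist);
3. ``min_fpkm``         max FPKM over all samples >= 0.5;
4. ``coding_potential`` a transcript is a novel lncRNA only if all three
                        coding-potential predictors (longest ORF, hexamer
                        log-likelihood, protein-motif scan) call it
                        non-coding; known lncRNAs skip this step.

Each transcript receives exactly one outcome and, if rejected, the first
failed rule, making every decision auditable.

Surviving lncRNAs are positionally classified with precedence
antisense > intronic > lincRNA: antisense on exon-level opposite-strand
overlap, intronic on full containment within a single intron of a
same-strand gene transcript, lincRNA otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io_formats import AnnotationSet, TranscriptModel

__all__ = [
    "CodingCall",
    "FilterTrace",
    "RULES",
    "LNC_CLASSES",
    "hexamer_frequencies",
    "hexamer_score",
    "longest_orf_codons",
    "coding_potential",
    "classify_lncRNA",
    "filter_cascade",
    "summarize_structure",
    "traces_to_frame",
    "DEFAULT_THRESHOLDS",
]

RULES = ("min_length", "single_exon", "coding_overlap", "min_fpkm", "coding_potential")
LNC_CLASSES = ("lincRNA", "intronic", "antisense")
OUTCOMES = ("known_lncRNA", "novel_lncRNA", "rejected")

DEFAULT_THRESHOLDS: Mapping[str, object] = {
    "min_length": 200,
    "min_fpkm": 0.5,
    "keep_single_exon": True,
    "orf_min_codons": 100,
}

_NTS = "ACGT"
_STOPS = frozenset({"TAA", "TAG", "TGA"})
ALL_HEXAMERS = ["".join(p) for p in itertools.product(_NTS, repeat=6)]


@dataclass(frozen=True)
class CodingCall:
    """Verdicts of the three coding-potential predictors for one transcript."""

    transcript_id: str
    orf_call: str
    orf_codons: int
    hexamer_call: str
    hexamer_score: float
    domain_call: str
    domain_motif: str | None

    @property
    def consensus(self) -> str:
        """'noncoding' iff all three predictors agree on noncoding."""
        calls = (self.orf_call, self.hexamer_call, self.domain_call)
        return "noncoding" if all(c == "noncoding" for c in calls) else "coding"


@dataclass(frozen=True)
class FilterTrace:
    transcript_id: str
    outcome: str
    rejected_at: str | None = None
    lnc_class: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if (self.outcome == "rejected") != (self.rejected_at is not None):
            raise ValueError("rejected_at must be set iff outcome is 'rejected'")
        if self.lnc_class is not None and self.outcome == "rejected":
            raise ValueError("rejected transcripts carry no lncRNA class")


def traces_to_frame(traces: Iterable[FilterTrace]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "outcome": t.outcome,
                "rejected_at": t.rejected_at or "",
                "class": t.lnc_class or "",
            }
            for t in traces
        ]
    ).set_index("transcript_id")


# ---------------------------------------------------------------------------
# Coding potential

def _validate_sequence(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(bad)}")
    return seq


def hexamer_frequencies(
    sequences: Iterable[str], pseudocount: float = 1.0
) -> dict[str, float]:
    """Relative frequencies of all 4096 hexamers over a sequence set.

    Overlapping hexamers are counted; windows containing N are skipped.
    Pseudocounts keep every frequency positive so log-ratios stay finite.
    """
    counts = dict.fromkeys(ALL_HEXAMERS, pseudocount)
    for seq in sequences:
        seq = _validate_sequence(seq)
        for i in range(len(seq) - 5):
            h = seq[i : i + 6]
            if "N" not in h:
                counts[h] += 1
    total = sum(counts.values())
    return {h: c / total for h, c in counts.items()}


def hexamer_score(
    seq: str, coding_freqs: Mapping[str, float], noncoding_freqs: Mapping[str, float]
) -> float:
    """Mean log2(f_coding/f_noncoding) over all overlapping hexamers."""
    seq = _validate_sequence(seq)
    scores = []
    for i in range(len(seq) - 5):
        h = seq[i : i + 6]
        if "N" in h:
            continue
        scores.append(math.log2(coding_freqs[h] / noncoding_freqs[h]))
    return float(np.mean(scores)) if scores else 0.0


def longest_orf_codons(seq: str) -> int:
    """Longest forward-frame ORF (ATG..stop) in codons, stop excluded.

    Only ORFs terminated by an in-frame stop count; codons containing N
    break an open reading.
    """
    seq = _validate_sequence(seq)
    best = 0
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                start = None
                continue
            if codon in _STOPS:
                if start is not None:
                    best = max(best, (i - start) // 3)
                start = None
            elif start is None and codon == "ATG":
                start = i
    return best


def _translations(seq: str) -> list[str]:
    out = []
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()) if sub else "")
    return out


def coding_potential(
    sequence: str,
    hexamer_tables: tuple[Mapping[str, float], Mapping[str, float]],
    motif_list: Sequence[str] = (),
    orf_min_codons: int = 100,
    transcript_id: str = "",
) -> CodingCall:
    """Consensus coding-potential call from three independent predictors.

    ORF predictor: coding iff the longest forward-frame ORF reaches
    ``orf_min_codons``.  Hexamer predictor: coding iff the mean hexamer
    log-likelihood ratio is strictly positive.  Domain predictor: coding iff
    any peptide motif occurs in one of the three forward-frame translations.
    """
    seq = _validate_sequence(sequence)
    coding_freqs, noncoding_freqs = hexamer_tables

    orf = longest_orf_codons(seq)
    hex_score = hexamer_score(seq, coding_freqs, noncoding_freqs)
    motif_hit = None
    if motif_list:
        prots = _translations(seq)
        for motif in motif_list:
            if any(motif in p for p in prots):
                motif_hit = motif
                break
    return CodingCall(
        transcript_id=transcript_id,
        orf_call="coding" if orf >= orf_min_codons else "noncoding",
        orf_codons=orf,
        hexamer_call="coding" if hex_score > 0 else "noncoding",
        hexamer_score=hex_score,
        domain_call="coding" if motif_hit else "noncoding",
        domain_motif=motif_hit,
    )


# ---------------------------------------------------------------------------
# Interval indexes

def _exon_tree(
    transcripts: Iterable[TranscriptModel],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in transcripts:
        for e in t.exons:
            trees.setdefault((e.chrom, e.strand), IntervalTree()).addi(
                e.start, e.end + 1, t.gene_id
            )
    return trees


def _intron_tree(
    transcripts: Iterable[TranscriptModel],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in transcripts:
        for iv in t.introns():
            trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(
                iv.start, iv.end + 1, t.gene_id
            )
    return trees


def _other_strand(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _exon_overlap(
    t: TranscriptModel,
    trees: Mapping[tuple[str, str], IntervalTree],
    strand: str,
    exclude_gene: str | None = None,
) -> bool:
    tree = trees.get((t.chrom, strand))
    if tree is None:
        return False
    for e in t.exons:
        for hit in tree.overlap(e.start, e.end + 1):
            if exclude_gene is None or hit.data != exclude_gene:
                return True
    return False


class _GeneIndex:
    """Exon and intron interval trees over a set of coding gene models."""

    def __init__(self, coding_transcripts: Iterable[TranscriptModel]):
        txs = list(coding_transcripts)
        self.exons = _exon_tree(txs)
        self.introns = _intron_tree(txs)


def classify_lncRNA(
    lnc: TranscriptModel,
    genes: AnnotationSet | Iterable[TranscriptModel],
    _index: _GeneIndex | None = None,
) -> str:
    """Positional class of a surviving lncRNA: antisense, intronic or lincRNA.

    Precedence is exactly antisense > intronic > lincRNA.  Opposite-strand
    containment in an intron without exon overlap is lincRNA by convention.
    """
    if _index is None:
        txs = genes if not isinstance(genes, AnnotationSet) else list(genes)
        txs = [t for t in txs if t.biotype == "coding"] or list(txs)
        _index = _GeneIndex(txs)
    if _exon_overlap(lnc, _index.exons, _other_strand(lnc.strand)):
        return "antisense"
    span = lnc.interval
    tree = _index.introns.get((lnc.chrom, lnc.strand))
    if tree is not None:
        for hit in tree.overlap(span.start, span.end + 1):
            if hit.begin <= span.start and span.end < hit.end:
                return "intronic"
    return "lincRNA"


# ---------------------------------------------------------------------------
# Filter cascade

def filter_cascade(
    annotation: AnnotationSet,
    known_lnc: AnnotationSet,
    fpkm: pd.DataFrame,
    sequences: Mapping[str, str],
    thresholds: Mapping[str, object] | None = None,
    hexamer_tables: tuple[Mapping[str, float], Mapping[str, float]] | None = None,
    motif_list: Sequence[str] = (),
) -> list[FilterTrace]:
    """Run the ordered lncRNA filter cascade over every transcript.

    ``annotation`` holds the assembled transcripts; those with biotype
    ``coding`` double as the reference protein-coding gene models for the
    overlap rule and the positional classification.  ``known_lnc`` is the
    known-lncRNA track (matched by same-strand exon overlap).  When no
    hexamer tables are given, the coding table is trained on the coding-gene
    sequences and the non-coding table is uniform.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    missing_seq = [t.transcript_id for t in annotation if t.transcript_id not in sequences]
    missing_fpkm = [t.transcript_id for t in annotation if t.transcript_id not in fpkm.index]
    if missing_seq or missing_fpkm:
        raise ValueError(
            f"transcripts missing sequence: {missing_seq[:5]}... "
            f"missing FPKM: {missing_fpkm[:5]}..."
            if len(missing_seq) > 5 or len(missing_fpkm) > 5
            else f"transcripts missing sequence: {missing_seq}; missing FPKM: {missing_fpkm}"
        )

    coding_txs = [t for t in annotation if t.biotype == "coding"]
    coding_trees = _exon_tree(coding_txs)
    known_trees = _exon_tree(known_lnc)
    gene_index = _GeneIndex(coding_txs)

    if hexamer_tables is None:
        coding_seqs = [sequences[t.transcript_id] for t in coding_txs]
        coding_tab = (
            hexamer_frequencies(coding_seqs)
            if coding_seqs
            else dict.fromkeys(ALL_HEXAMERS, 1 / 4096)
        )
        hexamer_tables = (coding_tab, dict.fromkeys(ALL_HEXAMERS, 1 / 4096))

    max_fpkm = fpkm.max(axis=1)
    traces: list[FilterTrace] = []
    for t in annotation:
        tid = t.transcript_id
        if t.length < int(th["min_length"]):
            traces.append(FilterTrace(tid, "rejected", "min_length"))
            continue
        if not th["keep_single_exon"] and t.n_exons == 1:
            traces.append(FilterTrace(tid, "rejected", "single_exon"))
            continue
        if _exon_overlap(t, coding_trees, t.strand):
            traces.append(FilterTrace(tid, "rejected", "coding_overlap"))
            continue
        is_known = _exon_overlap(t, known_trees, t.strand)
        if float(max_fpkm[tid]) < float(th["min_fpkm"]):
            traces.append(FilterTrace(tid, "rejected", "min_fpkm"))
            continue
        if not is_known:
            call = coding_potential(
                sequences[tid],
                hexamer_tables,
                motif_list,
                orf_min_codons=int(th["orf_min_codons"]),
                transcript_id=tid,
            )
            if call.consensus == "coding":
                traces.append(FilterTrace(tid, "rejected", "coding_potential"))
                continue
        lnc_class = classify_lncRNA(t, coding_txs, _index=gene_index)
        traces.append(
            FilterTrace(
                tid,
                "known_lncRNA" if is_known else "novel_lncRNA",
                lnc_class=lnc_class,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# Structural summaries

def summarize_structure(
    lncs: Sequence[TranscriptModel],
    mrnas: Sequence[TranscriptModel],
    length_edges: Sequence[int] = (500, 1200),
    max_exon_bin: int = 10,
) -> dict[str, pd.DataFrame]:
    """Exon-count, length and chromosome distributions for two cohorts.

    Fractions sum to 1 per cohort; the last exon bin is open-ended
    (``>= max_exon_bin``), length bins follow ``length_edges``.
    """
    if not lncs or not mrnas:
        raise ValueError("both cohorts must be non-empty")

    edges = sorted(length_edges)
    len_labels = (
        [f"<{edges[0]}"]
        + [f"{a}-{b}" for a, b in zip(edges, edges[1:])]
        + [f">{edges[-1]}"]
    )
    exon_labels = [str(i) for i in range(1, max_exon_bin)] + [f">={max_exon_bin}"]

    def exon_frac(cohort: Sequence[TranscriptModel]) -> pd.Series:
        n = np.array([min(t.n_exons, max_exon_bin) for t in cohort])
        fracs = [(n == i).mean() for i in range(1, max_exon_bin)]
        fracs.append((n == max_exon_bin).mean())
        return pd.Series(fracs, index=exon_labels)

    def len_frac(cohort: Sequence[TranscriptModel]) -> pd.Series:
        lens = np.array([t.length for t in cohort])
        bins = np.searchsorted(edges, lens, side="right")
        return pd.Series(
            [(bins == i).mean() for i in range(len(len_labels))], index=len_labels
        )

    def chrom_counts(cohort: Sequence[TranscriptModel]) -> pd.Series:
        return pd.Series([t.chrom for t in cohort]).value_counts().sort_index()

    return {
        "exon_fractions": pd.DataFrame(
            {"lncRNA": exon_frac(lncs), "mRNA": exon_frac(mrnas)}
        ),
        "length_fractions": pd.DataFrame(
            {"lncRNA": len_frac(lncs), "mRNA": len_frac(mrnas)}
        ),
        "chrom_counts": pd.DataFrame(
            {"lncRNA": chrom_counts(lncs), "mRNA": chrom_counts(mrnas)}
        ).fillna(0).astype(int),
    }
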