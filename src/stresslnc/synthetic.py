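"""Synthetic multi-chromosome dataset with planted ground truth.

Everything downstream of read alignment/assembly is exercised on data
generated here: a toy genome with protein-coding gene models carrying real
ORFs, planted lncRNAs of each positional class (lincRNA / intronic /
antisense), decoy transcripts each violating exactly one cascade rule,
negative-binomial fragment counts with planted condition effects, exact
shared-profile trans pairs, embedded miRNA complementary sites and a
planted over-represented annotation term.

Planted lncRNAs pass every filter threshold by construction (length >= 200
nt, expressed, non-coding composition); every decoy records the single rule
it violates so cascade attributions can be audited.  All outputs are pure
functions of the :class:`SimulationConfig` (seed included): the same
configuration reproduces byte-identical files.

Coding sequences are drawn from a skewed codon-usage table (GC-ending
codons strongly preferred) so the hexamer predictor has signal; all other
sequence is i.i.d. uniform.  Planted trans pairs use deterministic integer
shared-profile counts so their noise-free FPKM vectors are exactly
proportional (Pearson r = 1); negative-binomial noise would destroy the
planted correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, compute_fpkm
from .io_formats import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    parse_conditions,
    write_fasta,
    write_gff,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_genome",
    "simulate_counts",
    "plant_mirna_sites",
    "simulate_term_map",
    "simulate_count_matrix",
    "simulate_all",
    "SimulationOutputs",
]

_NT = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS]
# skewed codon usage: GC-ending codons are strongly preferred, giving coding
# sequence a hexamer signature distinct from the uniform background
_CODON_W = np.array([6.0 if c[2] in "GC" else 1.0 for c in _CODONS])
_CODON_P = _CODON_W / _CODON_W.sum()

_AA2CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}

DECOY_KINDS = ("decoy_short", "decoy_coding_orf", "decoy_low_fpkm", "decoy_cds_overlap")
DECOY_RULE = {
    "decoy_short": "min_length",
    "decoy_coding_orf": "coding_potential",
    "decoy_low_fpkm": "min_fpkm",
    "decoy_cds_overlap": "coding_overlap",
}
SITE_KINDS = ("exact", "gu", "mismatch")
SITE_EXPECTATION = {"exact": 0.0, "gu": 0.5, "mismatch": 2.0}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic dataset; defaults define the study design
    the pipeline is tested under (2 conditions x 3 replicates)."""

    seed: int = 1
    n_chroms: int = 10
    chrom_length: int = 600_000
    n_coding_genes: int = 100
    n_lnc_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"lincRNA": 200, "intronic": 5, "antisense": 5}
    )
    n_decoys: int = 200
    frac_known: float = 0.1
    n_replicates: int = 3
    nb_dispersion: float = 0.1
    frac_de: float = 0.25
    planted_log2fc: float = 2.0
    n_cis_pairs: int = 30
    n_trans_pairs: int = 20
    n_mirna_sites: int = 9
    mirna_length: int = 21
    mean_low: float = 20.0
    mean_high: float = 500.0
    library_size_jitter: float = 0.2
    motif_peptide: str = "HSPDNAKWQE"

    def __post_init__(self) -> None:
        counts = [
            self.n_chroms, self.chrom_length, self.n_coding_genes, self.n_decoys,
            self.n_replicates, self.n_cis_pairs, self.n_trans_pairs,
            self.n_mirna_sites, self.mirna_length,
        ] + list(self.n_lnc_per_class.values())
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must lie in [0, 1]")
        object.__setattr__(self, "n_lnc_per_class", dict(self.n_lnc_per_class))


@dataclass
class TruthTable:
    """Planted ground truth keyed by emitted feature ids."""

    transcripts: pd.DataFrame  # kind, true_class, is_known, violated_rule, de...
    pairs: pd.DataFrame  # lnc_id, gene_id, relation, distance
    mirnas: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["mirna_id", "sequence", "direction"])
    )
    mirna_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["mirna_id", "lnc_id", "site_start", "kind", "expectation"]
        )
    )
    planted_terms: dict = field(default_factory=dict)
    chromosomes: dict = field(default_factory=dict)  # toy genome sequences

    @property
    def planted_lnc_ids(self) -> list[str]:
        t = self.transcripts
        return t.index[t["kind"].isin(["lincRNA", "intronic", "antisense"])].tolist()

    @property
    def decoy_ids(self) -> list[str]:
        return self.transcripts.index[
            self.transcripts["kind"].str.startswith("decoy")
        ].tolist()

    @property
    def common_target_genes(self) -> list[str]:
        p = self.pairs
        cis = set(p.loc[p["relation"] == "cis", "gene_id"])
        trans = set(p.loc[p["relation"] == "trans", "gene_id"])
        return sorted(cis & trans)


# ---------------------------------------------------------------------------
# genome simulation helpers

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, n)])


def _noncoding_seq(rng: np.random.Generator, n: int, max_orf: int = 60) -> str:
    """Uniform-random sequence rejection-sampled to be ORF-poor.

    A uniform sequence of a few hundred nt occasionally contains an ORF long
    enough to trip the ORF predictor; planted lncRNAs must pass the cascade
    by construction, so such draws are discarded.
    """
    from .discovery import longest_orf_codons

    for _ in range(100):
        seq = _random_seq(rng, n)
        if longest_orf_codons(seq) < max_orf:
            return seq
    raise RuntimeError("could not draw an ORF-poor sequence")  # pragma: no cover


def _coding_orf(rng: np.random.Generator, n_codons: int, motif: str) -> str:
    """ATG + biased codons (motif embedded mid-ORF) + stop; n_codons counts
    ATG through the last sense codon."""
    codons = ["ATG"]
    codons += [_CODONS[i] for i in rng.choice(len(_CODONS), n_codons - 1, p=_CODON_P)]
    if motif:
        pos = 1 + (n_codons - 1 - len(motif)) // 2
        for j, aa in enumerate(motif):
            codons[pos + j] = _AA2CODON[aa]
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    return "".join(codons) + stop


def _split_lengths(rng: np.random.Generator, total: int, parts: int, min_part: int = 60) -> list[int]:
    if parts == 1 or total < parts * min_part:
        return [total]
    extra = rng.multinomial(total - parts * min_part, np.full(parts, 1 / parts))
    return [min_part + int(e) for e in extra]


def _make_exons(
    chrom: str, strand: str, start: int, piece_lens: list[int], intron_lens: list[int]
) -> tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i, plen in enumerate(piece_lens):
        exons.append(GenomicInterval(chrom, pos, pos + plen - 1, strand))
        pos += plen
        if i < len(intron_lens):
            pos += intron_lens[i]
    return tuple(exons)


def _splice(chrom_seq: np.ndarray, exons, strand: str) -> str:
    s = "".join("".join(chrom_seq[e.start - 1 : e.end]) for e in exons)
    return s if strand == "+" else _revcomp(s)


def _write_spliced(chrom_seq: np.ndarray, exons, strand: str, seq: str) -> None:
    if strand == "-":
        seq = _revcomp(seq)
    pos = 0
    for e in exons:
        n = e.end - e.start + 1
        chrom_seq[e.start - 1 : e.end] = list(seq[pos : pos + n])
        pos += n


def simulate_genome(config: SimulationConfig) -> tuple[AnnotationSet, dict[str, str], TruthTable]:
    """Generate the toy genome, annotation, transcript sequences and truth.

    Raises if the configured chromosome length cannot accommodate the
    requested features (the error suggests a larger genome).
    """
    rng = np.random.default_rng([config.seed, 0])
    chroms = [f"chr{i + 1:02d}" for i in range(config.n_chroms)]
    chrom_seqs = {c: _NT[rng.integers(0, 4, config.chrom_length)].copy() for c in chroms}

    n_linc = config.n_lnc_per_class.get("lincRNA", 0)
    n_intronic = config.n_lnc_per_class.get("intronic", 0)
    n_antisense = config.n_lnc_per_class.get("antisense", 0)

    # ---- element specs placed by the left-to-right chromosome walk
    placed: list[dict] = []
    for i in range(config.n_coding_genes):
        placed.append({"id": f"G{i:04d}.T1", "gene": f"G{i:04d}", "kind": "coding"})
    for i in range(n_linc):
        placed.append({"id": f"LINC{i:04d}", "gene": f"LINC{i:04d}", "kind": "lincRNA"})
    decoy_kinds = [DECOY_KINDS[i % len(DECOY_KINDS)] for i in range(config.n_decoys)]
    n_tail_decoys = decoy_kinds.count("decoy_cds_overlap")
    for i, kind in enumerate(decoy_kinds):
        if kind != "decoy_cds_overlap":
            placed.append({"id": f"DECOY{i:04d}", "gene": f"DECOY{i:04d}", "kind": kind})
    # interleave types along chromosomes deterministically
    placed = [placed[i] for i in rng.permutation(len(placed))]

    cursors = {c: 1000 for c in chroms}
    transcripts: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    rows: list[dict] = []
    gene_info: dict[str, dict] = {}  # per gene: exons, strand, utr3, chrom

    for k, spec in enumerate(placed):
        chrom = chroms[k % len(chroms)]
        gap = int(rng.integers(1000, 8001))
        start = cursors[chrom] + gap
        strand = "+" if rng.random() < 0.5 else "-"
        kind = spec["kind"]

        if kind == "coding":
            n_codons = int(rng.integers(160, 301))
            utr5 = int(rng.integers(20, 101))
            utr3 = int(rng.integers(70, 201))
            orf = _coding_orf(rng, n_codons, config.motif_peptide)
            mrna = _random_seq(rng, utr5) + orf + _random_seq(rng, utr3)
            n_exons = int(rng.integers(3, 7))
            pieces = _split_lengths(rng, len(mrna), n_exons)
            introns = [int(rng.integers(1200, 2601))] + [
                int(rng.integers(150, 2501)) for _ in range(len(pieces) - 2)
            ]
            exons = _make_exons(chrom, strand, start, pieces, introns[: len(pieces) - 1])
            seq = mrna
            gene_info[spec["gene"]] = {
                "exons": exons, "strand": strand, "utr3": utr3, "chrom": chrom,
            }
        elif kind == "lincRNA":
            length = 210 + min(int(rng.exponential(250)), 1300)
            two_exon = rng.random() > 0.92
            if two_exon:
                pieces = _split_lengths(rng, length, 2)
                introns = [int(rng.integers(80, 301))]
            else:
                pieces, introns = [length], []
            exons = _make_exons(chrom, strand, start, pieces, introns)
            seq = _noncoding_seq(rng, length)
        elif kind == "decoy_short":
            length = int(rng.integers(120, 200))
            exons = _make_exons(chrom, strand, start, [length], [])
            seq = _random_seq(rng, length)
        elif kind == "decoy_coding_orf":
            n_codons = int(rng.integers(150, 221))
            codons = ["ATG"] + [
                _CODONS[i] for i in rng.integers(0, len(_CODONS), n_codons - 1)
            ]
            orf = "".join(codons) + "TAA"
            seq = _random_seq(rng, int(rng.integers(30, 81))) + orf + _random_seq(
                rng, int(rng.integers(30, 81))
            )
            exons = _make_exons(chrom, strand, start, [len(seq)], [])
        elif kind == "decoy_low_fpkm":
            length = int(rng.integers(300, 601))
            exons = _make_exons(chrom, strand, start, [length], [])
            seq = _random_seq(rng, length)
        else:  # pragma: no cover
            raise AssertionError(kind)

        end = exons[-1].end
        if end > config.chrom_length - 2000:
            raise ValueError(
                f"cannot place {spec['id']} on {chrom} (would end at {end}); "
                "increase chrom_length or reduce feature counts"
            )
        cursors[chrom] = end
        tm = TranscriptModel(
            spec["id"], spec["gene"], exons,
            biotype="coding" if kind == "coding" else "candidate",
        )
        transcripts.append(tm)
        _write_spliced(chrom_seqs[chrom], exons, strand, seq)
        sequences[spec["id"]] = seq
        rows.append(
            {
                "transcript_id": spec["id"],
                "kind": kind,
                "true_class": kind if kind in ("lincRNA",) else "",
                "violated_rule": DECOY_RULE.get(kind, "coding_overlap" if kind == "coding" else ""),
                "n_exons": len(exons),
            }
        )

    gene_ids = sorted(gene_info)

    # ---- intronic lncRNAs: fully inside the (large) first intron of a host
    host_cycle = itertools.cycle(gene_ids)
    for i in range(n_intronic):
        for _ in range(len(gene_ids) + 1):
            gid = next(host_cycle)
            info = gene_info[gid]
            exs = info["exons"]
            if len(exs) < 2:
                continue
            intron_lo, intron_hi = exs[0].end + 1, exs[1].start - 1
            room = intron_hi - intron_lo + 1
            if room >= 260:
                break
        else:
            raise ValueError("no host intron large enough; increase gene intron sizes")
        length = int(rng.integers(210, min(600, room - 40) + 1))
        offset = int(rng.integers(10, room - length - 10 + 1))
        lnc_start = intron_lo + offset
        exons = (GenomicInterval(info["chrom"], lnc_start, lnc_start + length - 1, info["strand"]),)
        tid = f"LNCI{i:04d}"
        tm = TranscriptModel(tid, tid, exons, biotype="candidate")
        transcripts.append(tm)
        seq = _noncoding_seq(rng, length)
        _write_spliced(chrom_seqs[info["chrom"]], exons, info["strand"], seq)
        sequences[tid] = seq
        rows.append(
            {"transcript_id": tid, "kind": "intronic", "true_class": "intronic",
             "violated_rule": "", "n_exons": 1}
        )

    # ---- antisense lncRNAs and same-strand CDS-overlap decoys: both hang off
    # a gene's 3'-terminal exon (the 3'UTR tail keeps their sequence neutral),
    # extending into the downstream placement gap
    used_tails: set[str] = set()

    def _tail_element(i: int, tid: str, opposite: bool) -> tuple[TranscriptModel, str]:
        for gid in gene_ids:
            if gid not in used_tails:
                break
        else:
            raise ValueError("ran out of gene tails for overlap elements")
        used_tails.add(gid)
        info = gene_info[gid]
        exs = info["exons"]
        ov = int(rng.integers(20, 61))
        length = int(rng.integers(250, 501))
        if info["strand"] == "+":
            term = exs[-1]
            lnc_start = term.end - ov + 1
            lnc_end = lnc_start + length - 1
        else:
            term = exs[0]  # genomic-leftmost exon is the 3' end on minus strand
            lnc_end = term.start + ov - 1
            lnc_start = lnc_end - length + 1
        strand = (
            ("-" if info["strand"] == "+" else "+") if opposite else info["strand"]
        )
        iv = GenomicInterval(info["chrom"], lnc_start, lnc_end, strand)
        tm = TranscriptModel(tid, tid, (iv,), biotype="candidate")
        return tm, info["chrom"]

    for i in range(n_antisense):
        tid = f"LNCA{i:04d}"
        tm, chrom = _tail_element(i, tid, opposite=True)
        transcripts.append(tm)
        sequences[tid] = _splice(chrom_seqs[chrom], tm.exons, tm.strand)
        rows.append(
            {"transcript_id": tid, "kind": "antisense", "true_class": "antisense",
             "violated_rule": "", "n_exons": 1}
        )
    for i, kind in enumerate(decoy_kinds):
        if kind != "decoy_cds_overlap":
            continue
        tid = f"DECOY{i:04d}"
        tm, chrom = _tail_element(i, tid, opposite=False)
        transcripts.append(tm)
        sequences[tid] = _splice(chrom_seqs[chrom], tm.exons, tm.strand)
        rows.append(
            {"transcript_id": tid, "kind": kind, "true_class": "",
             "violated_rule": DECOY_RULE[kind], "n_exons": 1}
        )

    truth_df = pd.DataFrame(rows).set_index("transcript_id")

    # ---- known lncRNAs
    lnc_ids = truth_df.index[
        truth_df["kind"].isin(["lincRNA", "intronic", "antisense"])
    ].tolist()
    n_known = int(round(config.frac_known * len(lnc_ids)))
    known_ids = sorted(
        np.array(lnc_ids)[rng.choice(len(lnc_ids), n_known, replace=False)].tolist()
    ) if n_known else []
    truth_df["is_known"] = truth_df.index.isin(known_ids)

    # ---- planted DE and cis/trans pairs
    annotation = AnnotationSet.from_transcripts(transcripts)
    truth_df["de_planted"] = False
    truth_df["de_direction"] = ""
    eligible_de = truth_df["kind"].isin(["coding", "lincRNA", "intronic", "antisense"])
    draw = rng.random(len(truth_df))
    truth_df.loc[eligible_de & (draw < config.frac_de), "de_planted"] = True
    dirs = np.where(rng.random(len(truth_df)) < 0.5, "up", "down")
    truth_df.loc[truth_df["de_planted"], "de_direction"] = dirs[truth_df["de_planted"].values]

    pair_rows: list[dict] = []
    gene_spans = {g: _span_of(gene_info[g]["exons"]) for g in gene_ids}
    linc_models = [annotation[t] for t in truth_df.index if truth_df.at[t, "kind"] == "lincRNA"]
    used_genes: set[str] = set()
    cis_pairs: list[tuple[str, str, int]] = []
    for lnc in linc_models:
        if len(cis_pairs) >= config.n_cis_pairs:
            break
        span = lnc.interval
        best: tuple[int, str] | None = None
        for gid in gene_ids:
            if gid in used_genes:
                continue
            giv = gene_spans[gid]
            if giv.chrom != span.chrom:
                continue
            gap = span.gap(GenomicInterval(giv.chrom, giv.start, giv.end))
            if gap is not None and gap <= 100_000 and (best is None or gap < best[0]):
                best = (gap, gid)
        if best is not None:
            used_genes.add(best[1])
            cis_pairs.append((lnc.transcript_id, best[1], best[0]))
    if len(cis_pairs) < config.n_cis_pairs:
        raise ValueError(
            "could not plant the requested number of cis pairs; "
            "increase lincRNA count or gene density"
        )
    for lnc_id, gid, gap in cis_pairs:
        pair_rows.append({"lnc_id": lnc_id, "gene_id": gid, "relation": "cis", "distance": gap})
        truth_df.loc[lnc_id, ["de_planted", "de_direction"]] = [True, "up"]

    n_trans = min(config.n_trans_pairs, len(cis_pairs))
    truth_df["trans_pair"] = -1
    for p, (lnc_id, gid, _gap) in enumerate(cis_pairs[:n_trans]):
        pair_rows.append({"lnc_id": lnc_id, "gene_id": gid, "relation": "trans", "distance": -1})
        gene_tid = f"{gid}.T1"
        truth_df.loc[lnc_id, "trans_pair"] = p
        truth_df.loc[gene_tid, "trans_pair"] = p
        truth_df.loc[gene_tid, ["de_planted", "de_direction"]] = [True, "up"]
        truth_df.loc[lnc_id, ["de_planted", "de_direction"]] = [True, "up"]

    truth = TruthTable(
        transcripts=truth_df,
        pairs=pd.DataFrame(pair_rows, columns=["lnc_id", "gene_id", "relation", "distance"]),
        chromosomes={c: "".join(s) for c, s in chrom_seqs.items()},
    )
    return annotation, sequences, truth


def _span_of(exons) -> GenomicInterval:
    return GenomicInterval(exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand)


# ---------------------------------------------------------------------------
# counts

def simulate_counts(
    annotation: AnnotationSet,
    truth: TruthTable,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Negative-binomial fragment counts with planted condition effects.

    Baseline means are log-uniform over [mean_low, mean_high]; planted-DE
    features have their heat-condition mean multiplied (up) or divided
    (down) by 2**planted_log2fc; per-sample depth factors are uniform within
    +/- library_size_jitter.  Features in a planted trans pair instead get
    deterministic integer shared-profile counts (see module docstring).
    Records the drawn baseline mean in ``truth.transcripts['base_mean']``.
    """
    rng = np.random.default_rng([config.seed, 1])
    t = truth.transcripts
    features = [tm.transcript_id for tm in annotation]
    n_rep = config.n_replicates
    samples = [f"PC{i + 1}" for i in range(n_rep)] + [f"PH{i + 1}" for i in range(n_rep)]
    is_heat = np.array([s.startswith("PH") for s in samples])

    base = 10 ** rng.uniform(
        math.log10(config.mean_low), math.log10(config.mean_high), len(features)
    )
    kinds = t.loc[features, "kind"].values
    base[kinds == "decoy_low_fpkm"] = 0.0
    lib_factor = rng.uniform(
        1 - config.library_size_jitter, 1 + config.library_size_jitter, len(samples)
    )

    fold = np.ones((len(features), len(samples)))
    de = t.loc[features, "de_planted"].values
    direction = t.loc[features, "de_direction"].values
    eff = 2.0 ** config.planted_log2fc
    fold[np.ix_(de & (direction == "up"), is_heat)] = eff
    fold[np.ix_(de & (direction == "down"), is_heat)] = 1.0 / eff

    mean = base[:, None] * fold * lib_factor[None, :]
    if config.nb_dispersion <= 0:
        counts = rng.poisson(mean)
    else:
        size = 1.0 / config.nb_dispersion
        prob = size / (size + mean)
        counts = np.where(mean > 0, rng.negative_binomial(size, np.maximum(prob, 1e-12)), 0)

    # deterministic shared-profile counts for planted trans pairs
    pair_ids = t.loc[features, "trans_pair"].values if "trans_pair" in t else np.full(len(features), -1)
    effect_int = max(2, int(round(2.0 ** abs(config.planted_log2fc))))
    for p in sorted({int(x) for x in pair_ids if x >= 0}):
        # constant within condition: keeps the pair's FPKM vectors exactly
        # proportional without adding within-condition variance
        base_profile = int(rng.integers(4, 13))
        profile = base_profile * np.where(is_heat, effect_int, 1)
        members = np.flatnonzero(pair_ids == p)
        for m in members:
            k = int(rng.integers(5, 31))
            counts[m] = k * profile

    counts_df = pd.DataFrame(counts.astype(np.int64), index=features, columns=samples)
    truth.transcripts.loc[features, "base_mean"] = base
    lengths = pd.Series({tm.transcript_id: tm.length for tm in annotation})
    return ExpressionMatrix(
        counts=counts_df,
        conditions=parse_conditions(samples),
        feature_lengths=lengths.reindex(features),
    )


def simulate_count_matrix(
    n_features: int,
    n_replicates: int = 3,
    mean_low: float = 10.0,
    mean_high: float = 1000.0,
    dispersion: float = 0.1,
    frac_de: float = 0.0,
    log2fc: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Bare count matrix for DE calibration studies (no genome around it).

    Returns (counts, conditions, truth) where truth has per-feature
    ``de_planted`` and ``direction``.  Planted effects multiply the heat
    mean by 2**log2fc.
    """
    rng = np.random.default_rng([seed, 7])
    samples = [f"PC{i + 1}" for i in range(n_replicates)] + [
        f"PH{i + 1}" for i in range(n_replicates)
    ]
    is_heat = np.array([s.startswith("PH") for s in samples])
    base = 10 ** rng.uniform(math.log10(mean_low), math.log10(mean_high), n_features)
    de = rng.random(n_features) < frac_de
    fold = np.ones((n_features, len(samples)))
    fold[np.ix_(de, is_heat)] = 2.0 ** log2fc
    mean = base[:, None] * fold
    if dispersion <= 0:
        counts = rng.poisson(mean)
    else:
        size = 1.0 / dispersion
        counts = rng.negative_binomial(size, size / (size + mean))
    ids = [f"F{i:05d}" for i in range(n_features)]
    truth = pd.DataFrame(
        {"de_planted": de, "direction": np.where(de, "up" if log2fc >= 0 else "down", "")},
        index=ids,
    )
    return (
        pd.DataFrame(counts.astype(np.int64), index=ids, columns=samples),
        parse_conditions(samples),
        truth,
    )


# ---------------------------------------------------------------------------
# miRNA sites

def plant_mirna_sites(
    sequences: Mapping[str, str],
    truth: TruthTable,
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str]]:
    """Embed miRNA complementary sites into DE lincRNA sequences.

    Sites cycle through three kinds: an exact reverse-complement site
    (expectation 0), a single non-seed G:U wobble (0.5) and a single seed
    mismatch (2.0 under the doubled-seed scheme).  Each site gets its own
    freshly drawn miRNA; site positions, kinds and forced expectations are
    recorded in ``truth.mirna_sites``; miRNA DE directions in
    ``truth.mirnas``.  Returns (updated sequences, miRNA sequences as RNA).
    """
    rng = np.random.default_rng([config.seed, 2])
    t = truth.transcripts
    L = config.mirna_length
    gu_pos = min(16, L)  # outside the 2-13 seed
    seed_pos = 3

    eligible = [
        tid for tid in t.index
        if t.at[tid, "kind"] == "lincRNA" and t.at[tid, "de_planted"]
        and t.at[tid, "n_exons"] == 1
    ]
    # prefer trans-pair lincRNAs so miRNA->lncRNA->gene chains exist
    if "trans_pair" in t:
        eligible.sort(key=lambda tid: (t.at[tid, "trans_pair"] < 0, tid))
    if config.n_mirna_sites > len(eligible):
        raise ValueError("not enough eligible DE lincRNAs to host miRNA sites")

    new_seqs = dict(sequences)
    mirnas: dict[str, str] = {}
    mirna_rows, site_rows = [], []
    for i in range(config.n_mirna_sites):
        kind = SITE_KINDS[i % len(SITE_KINDS)]
        lnc_id = eligible[i]
        lnc_seq = new_seqs[lnc_id]
        if len(lnc_seq) <= L:
            raise ValueError(f"lncRNA {lnc_id} shorter than the miRNA")
        m = "".join(_NT[rng.integers(0, 4, L)])
        if kind == "gu":
            m = m[: gu_pos - 1] + "G" + m[gu_pos:]
        site = _revcomp(m)  # window position L - i + 1 faces miRNA position i
        if kind == "gu":
            j = L - gu_pos  # 0-based window index facing miRNA position gu_pos
            site = site[:j] + "T" + site[j + 1 :]
        elif kind == "mismatch":
            j = L - seed_pos
            mb = m[seed_pos - 1]
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[mb]
            bad = [b for b in "ACGT" if b != comp and (mb, b) not in {("G", "T"), ("T", "G")}]
            site = site[:j] + bad[int(rng.integers(0, len(bad)))] + site[j + 1 :]
        start = int(rng.integers(0, len(lnc_seq) - L + 1))
        new_seqs[lnc_id] = lnc_seq[:start] + site + lnc_seq[start + L :]
        mid = f"miR{i + 1:03d}"
        mirnas[mid] = m.replace("T", "U")
        mirna_rows.append(
            {"mirna_id": mid, "sequence": mirnas[mid],
             "direction": "up" if rng.random() < 0.5 else "down"}
        )
        site_rows.append(
            {"mirna_id": mid, "lnc_id": lnc_id, "site_start": start + 1,
             "kind": kind, "expectation": SITE_EXPECTATION[kind]}
        )
    truth.mirnas = pd.DataFrame(mirna_rows, columns=["mirna_id", "sequence", "direction"])
    truth.mirna_sites = pd.DataFrame(
        site_rows, columns=["mirna_id", "lnc_id", "site_start", "kind", "expectation"]
    )
    return new_seqs, mirnas


# ---------------------------------------------------------------------------
# term map

def simulate_term_map(
    annotation: AnnotationSet,
    truth: TruthTable,
    config: SimulationConfig,
    background_rate: float = 0.08,
    planted_fg_rate: float = 0.8,
    planted_bg_rate: float = 0.03,
) -> pd.DataFrame:
    """Gene->term annotation with one planted over-represented GO term and
    one planted pathway, both concentrated on the planted common targets."""
    rng = np.random.default_rng([config.seed, 3])
    genes = sorted({tm.gene_id for tm in annotation if tm.biotype == "coding"})
    common = set(truth.common_target_genes)

    terms = (
        [(f"GO:70000{i:02d}", "BP", f"background process {i}") for i in range(8)]
        + [(f"GO:71000{i:02d}", "CC", f"background component {i}") for i in range(8)]
        + [(f"GO:72000{i:02d}", "MF", f"background function {i}") for i in range(8)]
        + [(f"ko990{i:02d}", "pathway", f"background pathway {i}") for i in range(10)]
    )
    rows = []
    for term_id, ns, name in terms:
        mask = rng.random(len(genes)) < background_rate
        for g in np.array(genes)[mask]:
            rows.append({"gene_id": g, "term_id": term_id, "namespace": ns, "name": name})

    for term_id, ns, name in (
        ("GO:9999001", "BP", "planted heat stress response"),
        ("ko99990", "pathway", "planted heat pathway"),
    ):
        hit = []
        for g in genes:
            rate = planted_fg_rate if g in common else planted_bg_rate
            if rng.random() < rate:
                hit.append(g)
        if common and not set(hit) & common:
            hit.append(sorted(common)[0])
        for g in hit:
            rows.append({"gene_id": g, "term_id": term_id, "namespace": ns, "name": name})
    truth.planted_terms = {"GO": "GO:9999001", "pathway": "ko99990"}
    df = pd.DataFrame(rows, columns=["gene_id", "term_id", "namespace", "name"])
    return df.sort_values(["term_id", "gene_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# driver

@dataclass
class SimulationOutputs:
    config: SimulationConfig
    annotation: AnnotationSet
    known_lnc: AnnotationSet
    sequences: dict[str, str]
    expression: ExpressionMatrix
    mirnas: dict[str, str]
    term_map: pd.DataFrame
    truth: TruthTable
    paths: dict[str, Path]


def simulate_all(config: SimulationConfig, outdir: str | Path) -> SimulationOutputs:
    """Run the full generator and write every artifact under ``outdir``.

    Emits genome.fa, annotation.gff3, known_lnc.gff3, transcripts.fa,
    counts.tsv, fpkm.tsv, mirna.fa, dems.tsv, terms.tsv, motifs.txt and the
    truth/ tables.  Deterministic: same config -> byte-identical files.
    """
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)

    annotation, sequences, truth = simulate_genome(config)
    sequences, mirnas = plant_mirna_sites(sequences, truth, config)

    # keep the toy genome consistent with the planted sites
    for tid in truth.mirna_sites["lnc_id"].unique():
        tm = annotation[tid]
        chrom = list(truth.chromosomes[tm.chrom])
        arr = np.array(chrom)
        _write_spliced(arr, tm.exons, tm.strand, sequences[tid])
        truth.chromosomes[tm.chrom] = "".join(arr)

    expr = simulate_counts(annotation, truth, config)
    term_map = simulate_term_map(annotation, truth, config)

    known = AnnotationSet.from_transcripts(
        TranscriptModel(f"KN_{tid}", f"KN_{tid}", annotation[tid].exons, "known_lncRNA")
        for tid in truth.transcripts.index[truth.transcripts["is_known"]]
    )

    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "known_lnc": outdir / "known_lnc.gff3",
        "transcripts": outdir / "transcripts.fa",
        "counts": outdir / "counts.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "mirna": outdir / "mirna.fa",
        "dems": outdir / "dems.tsv",
        "terms": outdir / "terms.tsv",
        "motifs": outdir / "motifs.txt",
        "truth_transcripts": outdir / "truth" / "transcripts.tsv",
        "truth_pairs": outdir / "truth" / "pairs.tsv",
        "truth_mirnas": outdir / "truth" / "mirnas.tsv",
        "truth_mirna_sites": outdir / "truth" / "mirna_sites.tsv",
        "truth_terms": outdir / "truth" / "planted_terms.tsv",
    }
    write_fasta(truth.chromosomes, paths["genome"])
    write_gff(annotation, paths["annotation"])
    write_gff(known, paths["known_lnc"])
    write_fasta(sequences, paths["transcripts"])
    expr.counts.to_csv(paths["counts"], sep="\t", index_label="feature_id")
    fpkm = compute_fpkm(expr.counts, expr.library_sizes, expr.feature_lengths)
    fpkm.to_csv(paths["fpkm"], sep="\t", index_label="feature_id", float_format="%.10g")
    write_fasta(mirnas, paths["mirna"])
    truth.mirnas[["mirna_id", "direction"]].to_csv(paths["dems"], sep="\t", index=False)
    term_map.to_csv(paths["terms"], sep="\t", index=False)
    paths["motifs"].write_text(config.motif_peptide + "\n")
    truth.transcripts.to_csv(paths["truth_transcripts"], sep="\t")
    truth.pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    truth.mirnas.to_csv(paths["truth_mirnas"], sep="\t", index=False)
    truth.mirna_sites.to_csv(paths["truth_mirna_sites"], sep="\t", index=False)
    pd.DataFrame(
        [{"namespace": k, "term_id": v} for k, v in sorted(truth.planted_terms.items())]
    ).to_csv(paths["truth_terms"], sep="\t", index=False)

    return SimulationOutputs(
        config=config,
        annotation=annotation,
        known_lnc=known,
        sequences=sequences,
        expression=expr,
        mirnas=mirnas,
        term_map=term_map,
        truth=truth,
        paths=paths,
    )
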