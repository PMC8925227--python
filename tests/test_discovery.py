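"""Filter cascade, coding-potential consensus and positional classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stresslnc.discovery import (
    ALL_HEXAMERS,
    CodingCall,
    classify_lncRNA,
    coding_potential,
    filter_cascade,
    hexamer_frequencies,
    longest_orf_codons,
    summarize_structure,
    traces_to_frame,
)
from stresslnc.io_formats import AnnotationSet, GenomicInterval, TranscriptModel

UNIFORM = dict.fromkeys(ALL_HEXAMERS, 1 / 4096)


def _tx(tid, chrom, start, end, strand="+", gene=None, biotype="candidate", exons=None):
    exons = exons or [(start, end)]
    return TranscriptModel(
        tid, gene or tid,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        biotype=biotype,
    )


class TestCodingPotential:
    def test_long_orf_forces_coding_consensus(self):
        rng = np.random.default_rng(0)
        orf = "ATG" + "".join(
            rng.choice([c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
                        if c not in ("TAA", "TAG", "TGA")], 199)
        ) + "TAA"
        seq = "ACGT" * 20 + orf + "ACGT" * 20
        call = coding_potential(seq, (UNIFORM, UNIFORM))
        assert call.orf_call == "coding"
        assert call.orf_codons >= 200
        assert call.consensus == "coding"

    def test_random_sequence_is_noncoding(self):
        rng = np.random.default_rng(1)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        while longest_orf_codons(seq) >= 100:  # pragma: no cover
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        call = coding_potential(seq, (UNIFORM, UNIFORM))
        assert call.hexamer_score == pytest.approx(0.0)  # identical tables
        assert call.hexamer_call == "noncoding"  # strict > 0
        assert call.consensus == "noncoding"

    def test_motif_scan_fires_on_translated_peptide(self):
        # MKW -> ATG AAA TGG in frame 1
        seq = "ATGAAATGG" + "A" * 191
        call = coding_potential(seq, (UNIFORM, UNIFORM), motif_list=["MKW"])
        assert call.domain_call == "coding"
        assert call.domain_motif == "MKW"

    def test_orf_requires_terminating_stop(self):
        assert longest_orf_codons("ATG" + "AAA" * 50) == 0
        assert longest_orf_codons("ATG" + "AAA" * 50 + "TAA") == 51

    def test_n_breaks_orfs_and_is_skipped_in_hexamers(self):
        assert longest_orf_codons("ATG" + "AAA" * 11 + "TAA") == 12
        # an N codon interrupts the reading; no later ATG, so no ORF at all
        assert longest_orf_codons("ATG" + "AAA" * 5 + "ANA" + "AAA" * 5 + "TAA") == 0
        # reading can restart at an ATG after the N
        assert longest_orf_codons("ATG" + "AAA" * 5 + "ANA" + "ATG" + "AAA" * 4 + "TAA") == 5
        freqs = hexamer_frequencies(["AAAAAANAAAAAA"], pseudocount=0.0)
        assert sum(v > 0 for v in freqs.values()) == 1  # only AAAAAA counted

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            coding_potential("ACGTX" * 50, (UNIFORM, UNIFORM))

    def test_consensus_is_unanimity_over_all_combinations(self):
        for orf, hexa, dom in itertools.product(["coding", "noncoding"], repeat=3):
            call = CodingCall("t", orf, 0, hexa, 0.0, dom, None)
            expected = "noncoding" if (orf, hexa, dom) == ("noncoding",) * 3 else "coding"
            assert call.consensus == expected

    def test_hexamer_training_separates_biased_from_uniform(self, small_sim):
        t = small_sim.truth.transcripts
        coding_seqs = [small_sim.sequences[i] for i in t.index[t["kind"] == "coding"]]
        linc_seqs = [small_sim.sequences[i] for i in t.index[t["kind"] == "lincRNA"]]
        table = hexamer_frequencies(coding_seqs)
        from stresslnc.discovery import hexamer_score

        coding_scores = [hexamer_score(s, table, UNIFORM) for s in coding_seqs[:20]]
        linc_scores = [hexamer_score(s, table, UNIFORM) for s in linc_seqs[:20]]
        assert min(coding_scores) > 0
        assert np.mean([s < 0 for s in linc_scores]) >= 0.9


class TestFilterCascade:
    def _run(self, transcripts, fpkm_rows, known=(), sequences=None, **kw):
        ann = AnnotationSet.from_transcripts(transcripts)
        known_ann = AnnotationSet.from_transcripts(known)
        fpkm = pd.DataFrame(fpkm_rows, index=[t.transcript_id for t in transcripts],
                            columns=[f"S{i}" for i in range(6)])
        seqs = sequences or {
            t.transcript_id: "ACGTTGCATT" * (t.length // 10 + 1) for t in transcripts
        }
        seqs = {k: v[: len(v)] for k, v in seqs.items()}
        return traces_to_frame(
            filter_cascade(ann, known_ann, fpkm, seqs,
                           hexamer_tables=(UNIFORM, UNIFORM), **kw)
        )

    def test_short_transcript_rejected_at_min_length(self):
        df = self._run([_tx("t1", "chr1", 100, 298)], [[5] * 6])
        assert df.loc["t1", "outcome"] == "rejected"
        assert df.loc["t1", "rejected_at"] == "min_length"

    def test_low_fpkm_rejected_with_max_below_half(self):
        df = self._run([_tx("t1", "chr1", 100, 400)], [[0.1, 0.2, 0.3, 0.4, 0.2, 0.1]])
        assert df.loc["t1", "rejected_at"] == "min_fpkm"

    def test_boundary_fpkm_of_half_is_kept(self):
        df = self._run([_tx("t1", "chr1", 100, 400)], [[0.5, 0, 0, 0, 0, 0]])
        assert df.loc["t1", "outcome"] == "novel_lncRNA"

    def test_same_strand_exon_overlap_rejected_opposite_kept(self):
        gene = _tx("g1.T1", "chr1", 1000, 2000, "+", gene="g1", biotype="coding")
        same = _tx("t_same", "chr1", 1900, 2300, "+")
        anti = _tx("t_anti", "chr1", 1900, 2300, "-")
        df = self._run([gene, same, anti], [[5] * 6] * 3)
        assert df.loc["t_same", "rejected_at"] == "coding_overlap"
        assert df.loc["t_anti", "outcome"] == "novel_lncRNA"
        assert df.loc["t_anti", "class"] == "antisense"
        # the coding model itself overlaps itself and is screened out
        assert df.loc["g1.T1", "rejected_at"] == "coding_overlap"

    def test_known_overlap_skips_coding_potential(self):
        # coding-looking sequence would be rejected as novel, but the
        # known-lncRNA overlap shortcuts the coding-potential step
        orf = "ATG" + "AAA" * 120 + "TAA"
        t = _tx("t1", "chr1", 100, 100 + len(orf) - 1)
        known = _tx("kn1", "chr1", 150, 300)
        df = self._run([t], [[5] * 6], known=[known], sequences={"t1": orf})
        assert df.loc["t1", "outcome"] == "known_lncRNA"

    def test_single_exon_drop_switch(self):
        t = _tx("t1", "chr1", 100, 400)
        df = self._run([t], [[5] * 6], thresholds={"keep_single_exon": False})
        assert df.loc["t1", "rejected_at"] == "single_exon"

    def test_missing_fpkm_row_is_an_error(self):
        ann = AnnotationSet.from_transcripts([_tx("t1", "chr1", 100, 400)])
        fpkm = pd.DataFrame([[1.0]], index=["other"], columns=["S1"])
        with pytest.raises(ValueError, match="t1"):
            filter_cascade(ann, AnnotationSet(), fpkm, {"t1": "ACGT" * 100},
                           hexamer_tables=(UNIFORM, UNIFORM))

    def test_every_transcript_gets_exactly_one_outcome(self, small_sim):
        fpkm = small_sim.expression.fpkm()
        traces = filter_cascade(
            small_sim.annotation, small_sim.known_lnc, fpkm, small_sim.sequences,
            motif_list=[small_sim.config.motif_peptide],
        )
        ids = [t.transcript_id for t in traces]
        assert sorted(ids) == sorted(small_sim.annotation.transcripts)
        assert len(set(ids)) == len(ids)

    def test_planted_truth_recovery_small_scale(self, small_sim):
        fpkm = small_sim.expression.fpkm()
        df = traces_to_frame(
            filter_cascade(
                small_sim.annotation, small_sim.known_lnc, fpkm, small_sim.sequences,
                motif_list=[small_sim.config.motif_peptide],
            )
        ).join(small_sim.truth.transcripts)
        lnc = df[df["kind"].isin(["lincRNA", "intronic", "antisense"])]
        assert (lnc["outcome"] != "rejected").mean() >= 0.95
        rest = df[df["kind"].str.startswith("decoy") | (df["kind"] == "coding")]
        assert (rest["outcome"] == "rejected").mean() >= 0.95
        rejected = rest[rest["outcome"] == "rejected"]
        assert (rejected["rejected_at"] == rejected["violated_rule"]).all()


def _brute_force_class(lnc, genes):
    """Exhaustive O(n*m) interval-pair oracle for the positional classes."""
    for g in genes:
        for ge in g.exons:
            for le in lnc.exons:
                if ge.strand != le.strand and ge.overlaps(le):
                    return "antisense"
    span = lnc.interval
    for g in genes:
        for intron in g.introns():
            if (intron.chrom == span.chrom and intron.strand == span.strand
                    and intron.start <= span.start and span.end <= intron.end):
                return "intronic"
    return "lincRNA"


class TestClassification:
    def test_one_bp_antisense_overlap(self):
        gene = _tx("g.T1", "chr1", 1000, 1500, "+", biotype="coding")
        lnc = _tx("l", "chr1", 1500, 1900, "-")
        assert classify_lncRNA(lnc, [gene]) == "antisense"

    def test_intronic_containment_same_strand_only(self):
        gene = _tx("g.T1", "chr1", 100, 1000, "+", biotype="coding",
                   exons=[(100, 300), (801, 1000)])
        inside_same = _tx("l1", "chr1", 400, 700, "+")
        inside_opp = _tx("l2", "chr1", 400, 700, "-")
        assert classify_lncRNA(inside_same, [gene]) == "intronic"
        assert classify_lncRNA(inside_opp, [gene]) == "lincRNA"

    def test_distant_transcript_is_lincRNA(self):
        gene = _tx("g.T1", "chr1", 1000, 2000, "+", biotype="coding")
        lnc = _tx("l", "chr1", 52_000, 52_400, "+")
        assert classify_lncRNA(lnc, [gene]) == "lincRNA"

    def test_agrees_with_brute_force_oracle_on_random_configs(self):
        rng = np.random.default_rng(42)
        agree = 0
        n = 300
        for i in range(n):
            genes = []
            for j in range(rng.integers(1, 5)):
                s = int(rng.integers(1, 50_000))
                n_ex = int(rng.integers(1, 4))
                exons, pos = [], s
                for _ in range(n_ex):
                    ln = int(rng.integers(100, 500))
                    exons.append((pos, pos + ln - 1))
                    pos += ln + int(rng.integers(50, 2000))
                genes.append(
                    _tx(f"g{j}.T1", "chr1", 0, 0, "+" if rng.random() < 0.5 else "-",
                        biotype="coding", exons=exons)
                )
            ls = int(rng.integers(1, 55_000))
            lnc = _tx("l", "chr1", ls, ls + int(rng.integers(200, 1500)),
                      "+" if rng.random() < 0.5 else "-")
            if classify_lncRNA(lnc, genes) == _brute_force_class(lnc, genes):
                agree += 1
        assert agree == n


class TestSummarizeStructure:
    def test_single_exon_cohort(self):
        lncs = [_tx(f"l{i}", "chr1", 100, 400) for i in range(10)]
        mrnas = [_tx("m", "chr1", 100, 4000, biotype="coding",
                     exons=[(100, 2000), (2101, 4000)])]
        s = summarize_structure(lncs, mrnas)
        assert s["exon_fractions"].loc["1", "lncRNA"] == 1.0
        assert s["exon_fractions"]["lncRNA"].sum() == pytest.approx(1.0)

    def test_length_binning(self):
        cohort = [
            _tx("a", "chr1", 1, 250), _tx("b", "chr1", 1, 450), _tx("c", "chr1", 1, 1300)
        ]
        s = summarize_structure(cohort, cohort, length_edges=(500, 1200))
        frac = s["length_fractions"]["lncRNA"]
        assert frac["<500"] == pytest.approx(2 / 3)
        assert frac["500-1200"] == 0.0
        assert frac[">1200"] == pytest.approx(1 / 3)

    def test_fractions_sum_to_one_on_random_cohorts(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            cohort = [
                _tx(f"t{i}", "chr1", 1, int(rng.integers(200, 5000)))
                for i in range(int(rng.integers(1, 30)))
            ]
            s = summarize_structure(cohort, cohort)
            for col in ("lncRNA", "mRNA"):
                assert s["exon_fractions"][col].sum() == pytest.approx(1.0, abs=1e-12)
                assert s["length_fractions"][col].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            summarize_structure([], [_tx("m", "chr1", 1, 300)])
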