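"""cis/trans target prediction and the common-target intersection."""

import numpy as np
import pandas as pd
import pytest

from stresslnc.io_formats import GenomicInterval, TranscriptModel
from stresslnc.targeting import (
    TargetLink,
    cis_targets,
    common_targets,
    trans_targets,
)


def _lnc(tid, chrom, start, end, strand="+"):
    return TranscriptModel(tid, tid, (GenomicInterval(chrom, start, end, strand),))


def _genes(*spans):
    return {gid: GenomicInterval(chrom, s, e) for gid, chrom, s, e in spans}


class TestCisTargets:
    def test_gap_below_window_is_a_target(self):
        links = cis_targets(
            [_lnc("l1", "chr1", 200_000, 201_000)],
            _genes(("g1", "chr1", 150_000, 160_000)),
        )
        assert len(links) == 1
        assert links[0].distance == 39_999

    def test_boundary_gap_of_window_is_included(self):
        links = cis_targets(
            [_lnc("l1", "chr1", 200_000, 201_000)],
            _genes(("g1", "chr1", 301_001, 310_000)),
        )
        assert len(links) == 1
        assert links[0].distance == 100_000
        # one bp further: excluded
        links = cis_targets(
            [_lnc("l1", "chr1", 200_000, 201_000)],
            _genes(("g1", "chr1", 301_002, 310_000)),
        )
        assert links == []

    def test_overlap_counts_as_distance_zero_and_strand_ignored(self):
        links = cis_targets(
            [_lnc("l1", "chr1", 1000, 2000, "-")],
            _genes(("g1", "chr1", 1500, 3000)),
        )
        assert links[0].distance == 0

    def test_other_chromosome_never_a_target(self):
        links = cis_targets(
            [_lnc("l1", "chr1", 1000, 2000)], _genes(("g1", "chr2", 1000, 2000))
        )
        assert links == []

    def test_agrees_with_brute_force_all_pairs_scan(self):
        rng = np.random.default_rng(17)
        window = 100_000
        for _ in range(40):
            lncs = [
                _lnc(f"l{i}", f"chr{rng.integers(1, 4)}",
                     *sorted(rng.integers(1, 1_000_000, 2) + [0, 1]))
                for i in range(25)
            ]
            genes = _genes(*[
                (f"g{j}", f"chr{rng.integers(1, 4)}",
                 *sorted(rng.integers(1, 1_000_000, 2) + [0, 1]))
                for j in range(25)
            ])
            got = {(l.lnc_id, l.gene_id, l.distance) for l in cis_targets(lncs, genes, window)}
            expected = set()
            for lnc in lncs:
                for gid, giv in genes.items():
                    gap = lnc.interval.gap(giv)
                    if gap is not None and gap <= window:
                        expected.add((lnc.transcript_id, gid, gap))
            assert got == expected

    def test_window_monotonicity(self):
        rng = np.random.default_rng(3)
        lncs = [_lnc(f"l{i}", "chr1", *sorted(rng.integers(1, 500_000, 2) + [0, 1]))
                for i in range(20)]
        genes = _genes(*[(f"g{j}", "chr1", *sorted(rng.integers(1, 500_000, 2) + [0, 1]))
                         for j in range(20)])
        small = {(l.lnc_id, l.gene_id) for l in cis_targets(lncs, genes, 50_000)}
        big = {(l.lnc_id, l.gene_id) for l in cis_targets(lncs, genes, 150_000)}
        assert small <= big


class TestTransTargets:
    def _fpkm(self, rows: dict) -> pd.DataFrame:
        return pd.DataFrame(rows, index=[f"S{i}" for i in range(6)]).T

    def test_proportional_vectors_are_targets(self):
        f = self._fpkm({"l": [1, 2, 3, 4, 5, 6], "g": [2, 4, 6, 8, 10, 12]})
        links = trans_targets(["l"], ["g"], f)
        assert len(links) == 1
        assert links[0].r == pytest.approx(1.0)

    def test_derived_example_r_0982(self):
        f = pd.DataFrame({"l": [1, 2, 3], "g": [1, 2, 4]},
                         index=["S0", "S1", "S2"]).T
        links = trans_targets(["l"], ["g"], f)
        r_oracle = 3 / np.sqrt(2 * 14 / 3)
        assert links[0].r == pytest.approx(r_oracle, abs=1e-12)
        assert abs(links[0].r) >= 0.95

    def test_anticorrelation_accepted_via_absolute_r(self):
        f = self._fpkm({"l": [1, 2, 3, 4, 5, 6], "g": [6, 5, 4, 3, 2, 1]})
        links = trans_targets(["l"], ["g"], f)
        assert links[0].r == pytest.approx(-1.0)

    def test_constant_profile_skipped_with_warning(self):
        f = self._fpkm({"l": [1, 2, 3, 4, 5, 6], "g": [5, 5, 5, 5, 5, 5]})
        with pytest.warns(UserWarning, match="zero-variance"):
            links = trans_targets(["l"], ["g"], f)
        assert links == []

    def test_r_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(23)
        X = rng.gamma(2, 10, size=(30, 6))
        f = pd.DataFrame(X, index=[f"f{i}" for i in range(30)],
                         columns=[f"S{i}" for i in range(6)])
        links = trans_targets([f"f{i}" for i in range(15)],
                              [f"f{i}" for i in range(15, 30)], f, r_min=0.0)
        by_pair = {(l.lnc_id, l.gene_id): l.r for l in links}
        for (a, b), r in by_pair.items():
            x, y = f.loc[a].values, f.loc[b].values
            n = len(x)
            num = n * (x * y).sum() - x.sum() * y.sum()
            den = np.sqrt((n * (x**2).sum() - x.sum() ** 2)
                          * (n * (y**2).sum() - y.sum() ** 2))
            assert r == pytest.approx(num / den, abs=1e-12)
            # symmetry of the correlation itself
            assert r == pytest.approx(np.corrcoef(y, x)[0, 1], abs=1e-12)

    def test_too_few_samples_rejected(self):
        f = pd.DataFrame({"l": [1, 2], "g": [2, 4]}, index=["S0", "S1"]).T
        with pytest.raises(ValueError, match=">= 3 samples"):
            trans_targets(["l"], ["g"], f)

    def test_rmin_monotonicity(self):
        rng = np.random.default_rng(5)
        f = pd.DataFrame(rng.gamma(2, 10, size=(20, 6)),
                         index=[f"f{i}" for i in range(20)])
        lncs, genes = [f"f{i}" for i in range(10)], [f"f{i}" for i in range(10, 20)]
        strict = {(l.lnc_id, l.gene_id) for l in trans_targets(lncs, genes, f, r_min=0.9)}
        loose = {(l.lnc_id, l.gene_id) for l in trans_targets(lncs, genes, f, r_min=0.5)}
        assert strict <= loose


class TestCommonTargets:
    CIS = [TargetLink("lncA", "g1", "cis", distance=500)]
    TRANS_B = [TargetLink("lncB", "g1", "trans", r=0.99)]
    TRANS_A = [TargetLink("lncA", "g1", "trans", r=0.97)]

    def test_any_lnc_vs_same_lnc_modes(self):
        flags = {"g1": "up"}
        assert "g1" in common_targets(self.CIS, self.TRANS_B, flags, mode="any_lnc")
        assert "g1" not in common_targets(self.CIS, self.TRANS_B, flags, mode="same_lnc")
        assert "g1" in common_targets(self.CIS, self.TRANS_A, flags, mode="same_lnc")

    def test_non_de_gene_excluded(self):
        assert len(common_targets(self.CIS, self.TRANS_A, {"g1": "ns"})) == 0
        assert len(common_targets(self.CIS, self.TRANS_A, {})) == 0

    def test_same_lnc_subset_of_any_lnc(self):
        rng = np.random.default_rng(8)
        cis, trans = [], []
        flags = {}
        for g in range(30):
            gid = f"g{g}"
            flags[gid] = "up" if rng.random() < 0.7 else "ns"
            for l in range(3):
                if rng.random() < 0.5:
                    cis.append(TargetLink(f"l{l}", gid, "cis", distance=10))
                if rng.random() < 0.5:
                    trans.append(TargetLink(f"l{l}", gid, "trans", r=0.99))
        any_set = set(common_targets(cis, trans, flags, "any_lnc").gene_ids)
        same_set = set(common_targets(cis, trans, flags, "same_lnc").gene_ids)
        assert same_set <= any_set

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            common_targets([], [], {}, mode="both")

    def test_planted_pairs_recovered_from_synthetic_truth(self, small_sim):
        fpkm = small_sim.expression.fpkm()
        truth = small_sim.truth
        pairs = truth.pairs
        trans_pairs = pairs[pairs["relation"] == "trans"]
        lnc_ids = trans_pairs["lnc_id"].tolist()
        gene_tids = [f"{g}.T1" for g in trans_pairs["gene_id"]]
        links = trans_targets(lnc_ids, gene_tids, fpkm)
        found = {(l.lnc_id, l.gene_id) for l in links}
        for lnc, gtid in zip(lnc_ids, gene_tids):
            assert (lnc, gtid) in found
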