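"""Hypergeometric enrichment, IUPAC scanning, GC control, pioneer calls."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_set
from tfhot.enrichment import (
    IUPAC,
    MotifPattern,
    factor_hotspot_occupancy,
    gc_content,
    gc_group_comparison,
    gene_set_enrichment,
    motif_group_enrichment,
    region_overlap_enrichment,
    reverse_complement,
    scan_motif,
)
from tfhot.intervals import GenomicInterval
from tfhot.occupancy import OccupancyRegion
from tfhot.stats import hypergeom_tails


def region(start, end, group="singleton", chrom="chr1"):
    return OccupancyRegion(GenomicInterval(chrom, start, end), {"A"}, group=group)


def enumerate_tail(k, n, K, N):
    """Exhaustive draw enumeration: upper and lower tail of the overlap."""
    universe = range(N)
    marked = set(range(K))
    total = ge = le = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        hits = len(marked & set(draw))
        ge += hits >= k
        le += hits <= k
    return ge / total, le / total


class TestHypergeometricTails:
    def test_worked_example(self):
        """N=10, K=4, n=5, k=4: 6 favourable draws of C(10,5)=252."""
        upper, _ = hypergeom_tails(4, 5, 4, 10)
        assert upper == pytest.approx(6 / 252)

    def test_matches_enumeration_small_universes(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        upper, lower = hypergeom_tails(k, n, K, N)
                        e_up, e_low = enumerate_tail(k, n, K, N)
                        assert upper == pytest.approx(e_up, abs=1e-12)
                        assert lower == pytest.approx(e_low, abs=1e-12)

    def test_tails_share_point_mass(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            N = int(rng.integers(2, 100))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            upper, lower = hypergeom_tails(k, n, K, N)
            assert upper + lower >= 1.0 - 1e-12

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tails(5, 4, 10, 20)


class TestRegionOverlapEnrichment:
    def test_annotation_equals_universe(self):
        universe = [region(i * 1000, i * 1000 + 100,
                           "hotspot" if i < 3 else "singleton")
                    for i in range(10)]
        anno = [r.interval for r in universe]
        results = region_overlap_enrichment(
            {"hotspot": universe[:3], "singleton": universe[3:]}, anno, universe
        )
        for r in results:
            assert r.fraction == 1.0
            assert r.p_enrichment == pytest.approx(1.0)

    def test_counts_any_one_bp_overlap(self):
        universe = [region(0, 100), region(1000, 1100)]
        anno = [GenomicInterval("chr1", 99, 500)]
        (res,) = region_overlap_enrichment({"g": universe[:1]}, anno, universe)
        assert res.overlap == 1 and res.annotation_size == 1

    def test_group_larger_than_universe_rejected(self):
        universe = [region(0, 100)]
        with pytest.raises(ValueError):
            region_overlap_enrichment(
                {"g": universe * 2}, [GenomicInterval("chr1", 0, 10)], universe
            )

    def test_planted_overlap_contrast_detected(self):
        rng = np.random.default_rng(21)
        hot, single, anno = [], [], []
        for i in range(500):
            s = i * 4000
            hot.append(region(s, s + 200, "hotspot"))
            if rng.random() < 0.30:
                anno.append(GenomicInterval("chr1", s + 50, s + 150))
        for i in range(500):
            s = 3_000_000 + i * 4000
            single.append(region(s, s + 200, "singleton"))
            if rng.random() < 0.02:
                anno.append(GenomicInterval("chr1", s + 50, s + 150))
        universe = hot + single
        results = {
            r.group: r
            for r in region_overlap_enrichment(
                {"hotspot": hot, "singleton": single}, anno, universe
            )
        }
        assert results["hotspot"].p_enrichment < 1e-6
        assert results["hotspot"].fraction == pytest.approx(0.30, abs=0.05)
        assert results["singleton"].fraction == pytest.approx(0.02, abs=0.05)
        assert results["singleton"].direction == "depleted"


class TestGeneSetEnrichment:
    def test_exact_small_universe(self):
        """N=4, K=1, n=2, k=1 -> p = C(1,1)C(3,1)/C(4,2) = 0.5."""
        (res,) = gene_set_enrichment(
            {"hotspot": ["g1", "g2"]}, ["g1"], ["g1", "g2", "g3", "g4"]
        )
        assert res.p_enrichment == pytest.approx(0.5)

    def test_disjoint_query_p_one(self):
        (res,) = gene_set_enrichment(
            {"g": ["a", "b"]}, ["c"], ["a", "b", "c", "d"]
        )
        assert res.overlap == 0
        assert res.p_enrichment == pytest.approx(1.0)

    def test_case_insensitive_matching_and_warning(self, caplog):
        with caplog.at_level("WARNING"):
            (res,) = gene_set_enrichment(
                {"g": ["Gata1"]}, ["GATA1", "nope"], ["gata1", "tal1"]
            )
        assert res.overlap == 1
        assert any("not in universe" in m for m in caplog.messages)

    def test_empty_query_after_matching_rejected(self):
        with pytest.raises(ValueError):
            gene_set_enrichment({"g": ["a"]}, ["zz"], ["a", "b"])

    def test_planted_biased_de_list_detected(self):
        rng = np.random.default_rng(33)
        universe = [f"gene{i}" for i in range(2000)]
        hot_genes = universe[:400]
        other = universe[400:]
        query = [g for g in hot_genes if rng.random() < 0.25] + [
            g for g in other if rng.random() < 0.05
        ]
        (res,) = gene_set_enrichment({"hotspot": hot_genes}, query, universe)
        assert res.p_enrichment < 0.01


def brute_force_scan(seq, consensus, both_strands=True):
    def matches(window):
        for s_ch, m_ch in zip(window, consensus.upper()):
            if s_ch == "N":
                if m_ch != "N":
                    return False
            elif s_ch not in IUPAC[m_ch]:
                return False
        return True

    def count(s):
        m = len(consensus)
        return sum(matches(s[i : i + m]) for i in range(len(s) - m + 1))

    total = count(seq.upper())
    if both_strands:
        total += count(reverse_complement(seq))
    return total


class TestScanMotif:
    def test_overlapping_matches_counted(self):
        # 'A' matches at all 4 positions forward; reverse complement TTTT
        # contributes none
        assert scan_motif("AAAA", "A", both_strands=False) == 4

    def test_gata_consensus_worked_example(self):
        assert scan_motif("CTGATAAG", "WGATAR") == 1

    def test_empty_sequence(self):
        assert scan_motif("", "WGATAR") == 0

    def test_sequence_n_matches_only_motif_n(self):
        assert scan_motif("ANA", "AAA", both_strands=False) == 0
        assert scan_motif("ANA", "ANA", both_strands=False) == 1

    def test_invalid_motif_alphabet_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern("bad", "AXG")

    def test_strand_symmetry_property(self):
        rng = np.random.default_rng(17)
        letters = np.array(list("ACGT"))
        motif_letters = np.array(list(IUPAC))
        for _ in range(50):
            seq = "".join(rng.choice(letters, size=rng.integers(10, 80)))
            motif = "".join(rng.choice(motif_letters, size=rng.integers(2, 8)))
            assert scan_motif(seq, motif) == scan_motif(
                reverse_complement(seq), motif
            )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(18)
        letters = np.array(list("ACGTN"), dtype=object)
        motif_letters = np.array(list(IUPAC), dtype=object)
        for _ in range(200):
            seq = "".join(rng.choice(letters, size=rng.integers(5, 200),
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            motif = "".join(rng.choice(motif_letters, size=rng.integers(1, 12)))
            assert scan_motif(seq, motif) == brute_force_scan(seq, motif)


class TestMotifGroupEnrichment:
    def test_identical_sets_p_one(self):
        seqs = ["ACGTGATAAGCT", "TTTTGATAAGGG"]
        _f, tests = motif_group_enrichment(
            {"a": seqs, "b": list(seqs)}, MotifPattern("gata", "WGATAR")
        )
        assert tests.p_value.iloc[0] == pytest.approx(1.0)

    def test_absent_motif_skips_tests(self):
        _f, tests = motif_group_enrichment(
            {"a": ["CCCC"], "b": ["GGGG"]}, MotifPattern("gata", "TGATAA")
        )
        assert tests.empty

    def test_planted_contrast_significant(self):
        rng = np.random.default_rng(19)
        letters = np.array(list("ACGT"))

        def windows(n, rate):
            out = []
            for _ in range(n):
                s = list("".join(rng.choice(letters, size=120)))
                if rng.random() < rate:
                    s[40:47] = list("TGACTCA")
                out.append("".join(s))
            return out

        _f, tests = motif_group_enrichment(
            {"hotspot": windows(300, 0.6), "singleton": windows(300, 0.05)},
            MotifPattern("ap1", "TGASTCA"),
        )
        assert tests.p_value.iloc[0] < 1e-10


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("AATT", 0.0), ("GANTC", 0.5)]
    )
    def test_counting_rule(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_sequence_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            means, _tests = gc_group_comparison(
                {"a": ["NNNN", "GGCC"], "b": ["ATAT", "GCGC"]}
            )
        assert means.set_index("group").loc["a", "n"] == 1
        assert math.isnan(gc_content("NNN"))


class TestPioneerFactors:
    def make_hotspots(self, n):
        return [
            OccupancyRegion(
                GenomicInterval("chr1", i * 1000, i * 1000 + 200),
                {f"F{j}" for j in range(6)},
                group="hotspot",
            )
            for i in range(n)
        ]

    def test_fraction_and_strict_threshold(self):
        hotspots = self.make_hotspots(100)
        spans95 = [(i * 1000, i * 1000 + 200) for i in range(95)]
        spans90 = [(i * 1000, i * 1000 + 200) for i in range(90)]
        table = factor_hotspot_occupancy(
            [make_set("P", "ES", spans95), make_set("Q", "ES", spans90)],
            hotspots,
        ).set_index("factor")
        assert table.loc["P", "fraction"] == pytest.approx(0.95)
        assert bool(table.loc["P", "pioneer"]) is True
        assert table.loc["Q", "fraction"] == pytest.approx(0.90)
        assert bool(table.loc["Q", "pioneer"]) is False  # strictly > 0.90

    def test_factor_without_peaks(self):
        table = factor_hotspot_occupancy(
            [make_set("Z", "ES", [(10**7, 10**7 + 10)])], self.make_hotspots(10)
        )
        assert table.fraction.iloc[0] == 0.0
        assert not table.pioneer.iloc[0]

    def test_invariant_to_peak_fragmentation(self):
        hotspots = self.make_hotspots(50)
        whole = [(i * 1000, i * 1000 + 200) for i in range(40)]
        frags = []
        for s, e in whole:
            frags += [(s, s + 120), (s + 80, e)]
        t1 = factor_hotspot_occupancy([make_set("P", "ES", whole)], hotspots)
        t2 = factor_hotspot_occupancy([make_set("P", "ES", frags)], hotspots)
        assert t1.fraction.iloc[0] == t2.fraction.iloc[0]

    def test_zero_hotspots_rejected(self):
        with pytest.raises(ValueError):
            factor_hotspot_occupancy([make_set("P", "ES", [(0, 10)])], [])
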