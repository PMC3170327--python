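"""Per-gene and windowed selection statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_pileup, uniform_pileup
from metapnps import codons
from metapnps.dnds import (
    GeneModel,
    PolyCounts,
    SiteCounts,
    WindowSpec,
    gene_dnds,
    gene_polymorphism_counts,
    gene_site_counts,
    gene_stats,
    mean_dnds,
    sliding_window_dnds,
)


class TestGeneSiteCounts:
    def test_three_codon_gene(self, gene_factory):
        # TTT GGG ATG, all positions covered >= 5x
        seq = "TTTGGGATG"
        p = uniform_pileup(seq, 6)
        s = gene_site_counts(seq, p, gene_factory(0, 9))
        assert s.ns_sites == pytest.approx(8 / 3 + 2 + 3)
        assert s.s_sites == pytest.approx(1 / 3 + 1 + 0)
        assert s.positions_counted == 9
        assert s.ns_sites + s.s_sites == pytest.approx(s.positions_counted)

    def test_all_below_depth(self, gene_factory):
        seq = "TTTGGGATG"
        p = uniform_pileup(seq, 4)
        s = gene_site_counts(seq, p, gene_factory(0, 9))
        assert (s.ns_sites, s.s_sites, s.positions_counted) == (0, 0, 0)

    def test_codon_with_n_skipped(self, gene_factory):
        seq = "TTTGNGATG"
        p = uniform_pileup(seq, 6)
        s = gene_site_counts(seq, p, gene_factory(0, 9))
        assert s.positions_counted == 6  # middle codon's 3 positions skipped

    def test_minus_strand(self, gene_factory):
        # reverse complement of TTT GGG ATG
        seq = codons.revcomp_str("TTTGGGATG")
        p = uniform_pileup(seq, 6)
        s = gene_site_counts(seq, p, gene_factory(0, 9, strand="-"))
        assert s.ns_sites == pytest.approx(8 / 3 + 2 + 3)

    def test_internal_stop_skipped_and_flagged(self, gene_factory):
        seq = "TTTTAAGGG"  # TAA mid-gene
        p = uniform_pileup(seq, 6)
        stats = gene_stats(seq, p, gene_factory(0, 9))
        assert stats.has_internal_stop
        assert stats.site_counts.positions_counted == 6

    def test_length_trimmed_to_codon_boundary(self, gene_factory):
        seq = "TTTGGGAT"
        p = uniform_pileup(seq, 6)
        stats = gene_stats(seq, p, gene_factory(0, 8))
        assert stats.trimmed
        assert stats.site_counts.positions_counted == 6

    def test_gene_outside_bounds(self, gene_factory):
        p = uniform_pileup("TTTGGG", 6)
        with pytest.raises(ValueError):
            gene_site_counts("TTTGGG", p, gene_factory(0, 9))


class TestPolymorphisms:
    def test_synonymous_variant_per_read(self, gene_factory):
        # GGG with {G:5, A:1} at third position -> GGA, synonymous
        counts = {0: {"G": 6}, 1: {"G": 6}, 2: {"G": 5, "A": 1}}
        p = make_pileup(counts, 3)
        polys = gene_polymorphism_counts("GGG", p, gene_factory(0, 3))
        assert (polys.ns_polys, polys.s_polys) == (0, 1)

    def test_multiplicity_modes(self, gene_factory):
        counts = {0: {"G": 6}, 1: {"G": 6}, 2: {"G": 4, "A": 2}}
        p = make_pileup(counts, 3)
        per_read = gene_polymorphism_counts("GGG", p, gene_factory(0, 3), poly_mode="per-read")
        per_allele = gene_polymorphism_counts("GGG", p, gene_factory(0, 3), poly_mode="per-allele")
        assert per_read.s_polys == 2
        assert per_allele.s_polys == 1

    def test_below_depth_ignored(self, gene_factory):
        counts = {0: {"G": 4}, 1: {"G": 4}, 2: {"G": 3, "A": 1}}
        p = make_pileup(counts, 3)
        polys = gene_polymorphism_counts("GGG", p, gene_factory(0, 3))
        assert (polys.ns_polys, polys.s_polys) == (0, 0)

    def test_nonsynonymous_variant(self, gene_factory):
        counts = {0: {"G": 5, "T": 1}, 1: {"G": 6}, 2: {"G": 6}}
        p = make_pileup(counts, 3)
        polys = gene_polymorphism_counts("GGG", p, gene_factory(0, 3))
        assert (polys.ns_polys, polys.s_polys) == (1, 0)  # TGG = Trp

    def test_minus_strand_complemented(self, gene_factory):
        # gene GGG on minus strand occupies CCC on the genome;
        # a genome-strand T variant at genome pos 0 is gene-strand A at codon pos 2
        counts = {0: {"C": 5, "T": 1}, 1: {"C": 6}, 2: {"C": 6}}
        p = make_pileup(counts, 3)
        polys = gene_polymorphism_counts("CCC", p, gene_factory(0, 3, strand="-"))
        assert (polys.ns_polys, polys.s_polys) == (0, 1)  # GGG -> GGA


class TestGeneDnds:
    def test_arithmetic(self):
        dn, ds, ratio, diff = gene_dnds(SiteCounts(2, 1, 3), PolyCounts(1, 1))
        assert (dn, ds, ratio, diff) == (0.5, 1.0, 0.5, -0.5)

    def test_nan_on_no_polys(self):
        *_, ratio, diff = gene_dnds(SiteCounts(2, 1, 3), PolyCounts(0, 0))
        assert math.isnan(ratio)
        assert diff == 0.0

    def test_inf_on_ns_only(self):
        *_, ratio, _ = gene_dnds(SiteCounts(2, 1, 3), PolyCounts(3, 0))
        assert math.isinf(ratio)

    def test_zero_on_s_only(self):
        *_, ratio, _ = gene_dnds(SiteCounts(2, 1, 3), PolyCounts(0, 2))
        assert ratio == 0.0

    def test_diff_zero_when_ratio_one(self):
        dn, ds, ratio, diff = gene_dnds(SiteCounts(2, 1, 3), PolyCounts(2, 1))
        assert ratio == pytest.approx(1.0)
        assert diff == pytest.approx(0.0)

    @given(st.floats(0.1, 10.0))
    def test_ratio_invariant_to_site_scaling(self, factor):
        # multiplying both site counts by a constant leaves the ratio unchanged
        base = gene_dnds(SiteCounts(2.0, 1.0, 3), PolyCounts(5, 3))[2]
        scaled = gene_dnds(SiteCounts(2.0 * factor, 1.0 * factor, 3), PolyCounts(5, 3))[2]
        assert scaled == pytest.approx(base)

    def test_uncomputable_flag(self, gene_factory):
        p = make_pileup({}, 9)
        stats = gene_stats("TTTGGGATG", p, gene_factory(0, 9))
        assert stats.uncomputable
        assert math.isnan(stats.dnds)


class TestVsReference:
    def test_reads_identical_to_reference(self, gene_factory):
        seq = "TTTGGGATG"
        p = uniform_pileup(seq, 6)
        stats = gene_stats(seq, p, gene_factory(0, 9))
        assert math.isnan(stats.dnds)

    def test_consensus_vs_reference_differ(self, gene_factory):
        # all reads carry GGA at the third codon position; reference says GGG
        counts = {0: {"G": 6}, 1: {"G": 6}, 2: {"A": 6}}
        p = make_pileup(counts, 3)
        gene = gene_factory(0, 3)
        vs_consensus = gene_stats("GGA", p, gene)  # consensus basis
        vs_reference = gene_stats("GGG", p, gene)  # reference basis
        assert vs_consensus.poly_counts == PolyCounts(0, 0)
        assert vs_reference.poly_counts == PolyCounts(0, 6)

    def test_opposite_calls_representable(self, gene_factory):
        # consensus-based ratio < 1 while reference-based > 1
        cons = "GGGTAT"
        ref = "GGGTAC"
        counts = {
            0: {"G": 6}, 1: {"G": 6}, 2: {"G": 5, "A": 1},  # GGA: S vs both bases
            3: {"T": 6}, 4: {"A": 5, "G": 1}, 5: {"T": 6},  # TGT: NS vs consensus TAT
        }
        p = make_pileup(counts, 6)
        gene = gene_factory(0, 6)
        c = gene_stats(cons, p, gene)
        r = gene_stats(ref, p, gene)
        assert c.dnds < 1
        # reference basis additionally sees the fixed T at pos 5 (6 reads) as a change
        assert r.poly_counts != c.poly_counts


class TestWindows:
    def test_single_window_equals_gene(self, gene_factory):
        rng = np.random.default_rng(3)
        seq = "ATG" + "".join(
            np.random.default_rng(0).choice(["GGT", "ACT", "TTA", "CCA"], 66).tolist()
        )
        assert len(seq) == 201
        counts = {
            i: {seq[i]: 8} if rng.random() > 0.1 else {seq[i]: 5, "ACGT"[rng.integers(4)]: 3}
            for i in range(201)
        }
        p = make_pileup(counts, 201)
        gene = gene_factory(0, 201)
        wins = sliding_window_dnds(seq, p, gene, WindowSpec())
        assert len(wins) == 1
        whole = gene_stats(seq, p, gene)
        assert wins[0].site_counts == whole.site_counts
        assert wins[0].poly_counts == whole.poly_counts
        assert (wins[0].window_start, wins[0].window_end) == (0, 201)

    def test_offsets_for_450bp_gene(self, gene_factory):
        seq = "GGT" * 150
        p = uniform_pileup(seq, 6)
        wins = sliding_window_dnds(seq, p, gene_factory(0, 450), WindowSpec())
        starts = [w.window_start for w in wins]
        assert starts == [0, 48, 96, 144, 192, 240, 288]
        assert [w.truncated_window for w in wins] == [False] * 6 + [True]
        assert wins[-1].window_end == 450

    def test_minus_strand_genome_coordinates(self, gene_factory):
        seq = codons.revcomp_str("GGT" * 150)
        p = uniform_pileup(seq, 6)
        wins = sliding_window_dnds(seq, p, gene_factory(0, 450, strand="-"), WindowSpec())
        # first window covers the gene's 5' end = genome end
        assert (wins[0].window_start, wins[0].window_end) == (249, 450)
        assert wins[-1].truncated_window

    def test_short_gene_single_truncated_window(self, gene_factory):
        seq = "GGT" * 20
        p = uniform_pileup(seq, 6)
        wins = sliding_window_dnds(seq, p, gene_factory(0, 60), WindowSpec())
        assert len(wins) == 1
        assert wins[0].truncated_window

    def test_no_covered_positions_is_nan(self, gene_factory):
        seq = "GGT" * 67
        p = make_pileup({}, 201)
        wins = sliding_window_dnds(seq, p, gene_factory(0, 201), WindowSpec())
        assert math.isnan(wins[0].dnds)

    def test_tiling_windows_reproduce_gene_counts(self, gene_factory):
        # windows with step == length partition the gene exactly
        rng = np.random.default_rng(9)
        seq = "GGT" * 100
        counts = {}
        for i in range(300):
            counts[i] = {seq[i]: 7}
            if rng.random() < 0.2:
                alt = "ACGT"[rng.integers(4)]
                if alt != seq[i]:
                    counts[i][alt] = 2
        p = make_pileup(counts, 300)
        gene = gene_factory(0, 300)
        wins = sliding_window_dnds(seq, p, gene, WindowSpec(60, 60))
        whole = gene_stats(seq, p, gene)
        assert sum(w.poly_counts.ns_polys for w in wins) == whole.poly_counts.ns_polys
        assert sum(w.poly_counts.s_polys for w in wins) == whole.poly_counts.s_polys
        assert sum(w.site_counts.positions_counted for w in wins) == whole.site_counts.positions_counted
        assert sum(w.site_counts.ns_sites for w in wins) == pytest.approx(whole.site_counts.ns_sites)


class TestMeanDnds:
    def test_excludes_nan_and_inf(self):
        class S:
            def __init__(self, v):
                self.dnds = v

        vals = [S(0.5), S(1.5), S(math.nan), S(math.inf)]
        assert mean_dnds(vals) == pytest.approx(1.0)

    def test_all_excluded_is_nan(self):
        class S:
            def __init__(self, v):
                self.dnds = v

        assert math.isnan(mean_dnds([S(math.nan)]))


def test_window_spec_validation():
    with pytest.raises(ValueError):
        WindowSpec(window_length=200)
    with pytest.raises(ValueError):
        WindowSpec(step=0)


def test_gene_model_validation():
    with pytest.raises(ValueError):
        GeneModel("g", "ref", 10, 5)
    with pytest.raises(ValueError):
        GeneModel("g", "ref", 0, 9, strand="x")
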