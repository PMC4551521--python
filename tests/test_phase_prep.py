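"""Locus selection, allele calling, artifact filters and frag/allvars output."""

import numpy as np
import pytest

from cellhap import phase_prep as pp
from cellhap.phase_prep import ALT, HET, MISSING, REF, ScaffoldCall, SnpLocus
from cellhap.scaffolding import Scaffold


def make_call(indices, alleles, library="lib", start=0):
    return ScaffoldCall(Scaffold("c", start, start + 10_000, library),
                        library, np.array(indices), np.array(alleles))


class TestSelectInformativeLoci:
    RECORDS = [
        ("c", 100, "A", ["C"], "hom_ref", 30.0),
        ("c", 200, "A", ["C"], "het", 30.0),   # alt never seen -> excluded
        ("c", 300, "A", ["C"], "het", 30.0),   # ref lib1, alt lib2 -> included
        ("c", 400, "A", ["C", "G"], "het", 30.0),  # multi-allelic -> skipped
        ("c", 500, "A", ["C"], "het", 30.0),   # both alleles in one library
    ]
    PILEUPS = {
        "lib1": {("c", 200): (5, 0), ("c", 300): (4, 0), ("c", 500): (3, 3)},
        "lib2": {("c", 300): (0, 6)},
    }

    def test_selection_rules(self):
        loci = pp.select_informative_loci(self.RECORDS, self.PILEUPS)
        assert [l.pos for l in loci] == [300, 500]

    def test_multiallelic_warns(self, caplog):
        with caplog.at_level("WARNING"):
            pp.select_informative_loci(self.RECORDS, self.PILEUPS)
        assert any("multi-allelic" in r.message for r in caplog.records)


class TestCallScaffoldAlleles:
    LOCI = [SnpLocus("c", p, "A", "C") for p in (50, 150, 250, 950)]

    def call(self, pileup):
        scaffold = Scaffold("c", 0, 1000, "lib")
        return pp.call_scaffold_alleles(scaffold, pileup, self.LOCI, "lib")

    def test_clear_ref(self):
        c = self.call({("c", 50): (5, 0)})
        assert c.alleles[0] == REF

    def test_het_call(self):
        c = self.call({("c", 150): (3, 3)})
        assert c.alleles[1] == HET

    def test_insufficient_reads_missing(self):
        c = self.call({("c", 250): (1, 0)})
        assert c.alleles[2] == MISSING

    def test_alt_with_one_stray_ref(self):
        c = self.call({("c", 50): (1, 6)})
        assert c.alleles[0] == ALT

    def test_loci_outside_span_excluded(self):
        scaffold = Scaffold("c", 100, 200, "lib")
        c = pp.call_scaffold_alleles(scaffold, {}, self.LOCI, "lib")
        assert list(c.locus_indices) == [1]  # only pos 150 inside [100, 200)


class TestHetScaffoldFilter:
    def test_four_hets_removed(self):
        call = make_call(range(30), [HET] * 4 + [REF] * 26)
        retained, removed = pp.filter_het_scaffolds([call])
        assert len(removed) == 1 and retained == []

    def test_three_hets_retained_and_masked(self):
        call = make_call(range(30), [HET] * 3 + [REF] * 27)
        retained, removed = pp.filter_het_scaffolds([call])
        assert removed == [] and len(retained) == 1
        assert np.sum(retained[0].alleles == HET) == 0
        assert np.sum(retained[0].alleles == MISSING) == 3

    def test_fraction_exactly_point_two_retained(self):
        call = make_call(range(5), [HET, REF, REF, ALT, REF])
        retained, removed = pp.filter_het_scaffolds([call])
        assert removed == []  # strict >

    def test_fraction_above_point_two_removed(self):
        call = make_call(range(4), [HET, REF, REF, ALT])
        retained, removed = pp.filter_het_scaffolds([call])
        assert len(removed) == 1

    def test_strict_mode_drops_any_het(self):
        call = make_call(range(30), [HET] + [REF] * 29)
        retained, removed = pp.filter_het_scaffolds([call], max_het_count=0)
        assert len(removed) == 1


class TestTwoSnpFilter:
    def test_three_combinations_removes_both(self):
        calls = [
            make_call([0, 1], [REF, REF], "a"),
            make_call([0, 1], [ALT, ALT], "b"),
            make_call([0, 1], [REF, ALT], "c"),
        ]
        removed, table = pp.two_snp_haplotype_filter(calls, 2)
        assert removed == {0, 1}
        assert table[0].allele_count == 3

    def test_two_combinations_kept(self):
        calls = [make_call([0, 1], [REF, REF], "a"), make_call([0, 1], [ALT, ALT], "b")]
        removed, _ = pp.two_snp_haplotype_filter(calls, 2)
        assert removed == set()

    def test_single_combination_kept(self):
        removed, table = pp.two_snp_haplotype_filter([make_call([0, 1], [REF, REF])], 2)
        assert removed == set() and table[0].allele_count == 1

    def test_single_pass_on_original_adjacency(self):
        # removing loci 1,2 makes 0 and 3 adjacent, but the filter must not
        # re-test the new pair
        calls = [
            make_call([1, 2], [REF, REF], "a"),
            make_call([1, 2], [ALT, ALT], "b"),
            make_call([1, 2], [REF, ALT], "c"),
            # conflicting combinations at the *new* pair (0,3)
            make_call([0, 3], [REF, REF], "d"),
            make_call([0, 3], [ALT, ALT], "e"),
            make_call([0, 3], [REF, ALT], "f"),
        ]
        removed, _ = pp.two_snp_haplotype_filter(calls, 4)
        assert removed == {1, 2}  # (0,3) not adjacent originally

    def test_masked_and_missing_ignored(self):
        calls = [
            make_call([0, 1], [REF, REF], "a"),
            make_call([0, 1], [ALT, ALT], "b"),
            make_call([0, 1], [HET, ALT], "c"),  # het does not contribute
            make_call([0, 1], [MISSING, REF], "d"),
        ]
        removed, _ = pp.two_snp_haplotype_filter(calls, 2)
        assert removed == set()

    def test_efficacy_on_cnv_data(self, cnv_result):
        # after filtering, re-counting combinations over retained loci leaves
        # at most two for the vast majority of newly adjacent pairs
        retained = cnv_result.retained_calls
        removed = cnv_result.removed_loci
        kept = sorted(
            {int(i) for c in retained for i, a in zip(c.locus_indices, c.alleles)
             if a in (REF, ALT)} - removed
        )
        rank = {k: r for r, k in enumerate(kept)}
        pair_sets: dict[int, set] = {}
        for c in retained:
            prev = None
            for i, a in zip(c.locus_indices, c.alleles):
                i = int(i)
                if a in (REF, ALT) and i in rank:
                    if prev is not None and rank[i] == rank[prev[0]] + 1:
                        pair_sets.setdefault(prev[0], set()).add((prev[1], int(a)))
                    prev = (i, int(a))
        ok = sum(1 for s in pair_sets.values() if len(s) <= 2)
        assert ok / len(pair_sets) >= 0.90


class TestExpectations:
    def test_exact_sixth(self):
        assert pp.expected_diploid_fraction(1 / 6, "exact") == pytest.approx(1 / 11)

    def test_fosmid_estimator(self):
        assert pp.expected_diploid_fraction(0.24, "paper_approx") == pytest.approx(0.06)

    def test_whole_genome_limit(self):
        assert pp.expected_diploid_fraction(1.0, "exact") == pytest.approx(1.0)

    def test_het_genome_fraction_one_sixth(self):
        # f^2 of the genome is heterozygous in a 1/6 aliquot
        assert (1 / 6) ** 2 == pytest.approx(0.0278, abs=1e-4)

    def test_screen_positive_loci(self):
        assert pp.expected_screen_positive_loci(24, 1 / 6) == pytest.approx(8.0)
        assert pp.expected_screen_positive_loci(24, 1 / 6, "exact") == pytest.approx(24 * 11 / 36)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            pp.expected_diploid_fraction(0.0)


class TestHetCoverageDiagnostics:
    def test_exact_linear(self):
        x = np.array([1, 2, 3, 4, 5])
        y = 1.5 * x + 2
        d = pp.het_coverage_diagnostics(y, x)
        assert d["slope"] == pytest.approx(1.5)
        assert d["r2"] == pytest.approx(1.0)

    def test_constant_response(self):
        d = pp.het_coverage_diagnostics(np.full(5, 7.0), np.arange(5))
        assert d["slope"] == pytest.approx(0.0)

    def test_degenerate_predictor_flagged(self):
        d = pp.het_coverage_diagnostics(np.array([1.0, 2, 3]), np.full(3, 4))
        assert d["degenerate"] and d["r2"] is None

    def test_noisy_linear_recovers_slope(self, rng):
        x = rng.integers(1, 14, size=400).astype(float)
        y = 1.5 * x + 20 + rng.normal(0, 2, size=400)
        d = pp.het_coverage_diagnostics(y, x)
        se = 2 / (np.std(x) * np.sqrt(400))
        assert abs(d["slope"] - 1.5) < 2 * se


class TestWriteSihInput:
    LOCI = [SnpLocus("c", 10 * (i + 1), "A", "C") for i in range(10)]

    def test_contiguous_block(self):
        call = make_call([4, 5, 6], [REF, ALT, REF], "s1")
        frag, allvars = pp.write_sih_input([call], self.LOCI)
        assert frag == ["1 s1:0 5 010"]
        assert len(allvars) == 10

    def test_split_blocks(self):
        call = make_call([4, 8], [REF, ALT], "s2")
        frag, _ = pp.write_sih_input([call], self.LOCI)
        assert frag == ["2 s2:0 5 0 9 1"]

    def test_single_locus_omitted(self):
        call = make_call([4], [REF], "s3")
        frag, _ = pp.write_sih_input([call], self.LOCI)
        assert frag == []

    def test_removed_locus_dropped_then_reindexed(self):
        call = make_call([4, 5, 6], [REF, ALT, REF], "s4")
        frag, allvars = pp.write_sih_input([call], self.LOCI, removed_loci={5})
        # locus 5 removed: indices 4 and 6 map to retained positions 5 and 6,
        # which are now adjacent in allvars order -> one block "00"... no:
        # alleles at original 4 and 6 are REF, REF
        assert frag == ["1 s4:0 5 00"]
        assert len(allvars) == 9

    def test_below_two_after_removal_omitted(self):
        call = make_call([4, 5], [REF, ALT], "s5")
        frag, _ = pp.write_sih_input([call], self.LOCI, removed_loci={5})
        assert frag == []
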