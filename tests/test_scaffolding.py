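"""Contig merging, scaffold joining, gap statistics and length summaries."""

import numpy as np
import pytest
from scipy import stats

from cellhap import scaffolding as sc
from cellhap.intervals import contains_point


def occupancy_contigs(intervals, length):
    """Independent oracle: per-base occupancy scan."""
    occ = np.zeros(length, dtype=bool)
    for s, e in intervals:
        occ[s:e] = True
    edges = np.flatnonzero(np.diff(np.concatenate([[0], occ.view(np.int8), [0]])))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


class TestBuildContigs:
    def test_overlap_merge(self):
        contigs = sc.build_contigs([(0, 75), (50, 125)])
        assert [(c.start, c.end) for c in contigs] == [(0, 125)]
        assert contigs[0].read_count == 2

    def test_gap_preserved(self):
        contigs = sc.build_contigs([(0, 75), (80, 155)])
        assert [(c.start, c.end) for c in contigs] == [(0, 75), (80, 155)]

    def test_abutting_reads_merge(self):
        contigs = sc.build_contigs([(0, 75), (75, 150)])
        assert [(c.start, c.end) for c in contigs] == [(0, 150)]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            sc.build_contigs([(50, 60), (0, 10)])
        with pytest.raises(ValueError):
            sc.build_contigs([(10, 10)])

    def test_matches_occupancy_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 80))
            starts = rng.integers(0, 1900, size=n)
            lens = rng.integers(1, 120, size=n)
            ivs = sorted((int(s), int(min(s + l, 2000))) for s, l in zip(starts, lens))
            got = [(c.start, c.end) for c in sc.build_contigs(ivs)]
            assert got == occupancy_contigs(ivs, 2000)


class TestJoinContigs:
    def make(self, spans):
        return [sc.Contig("c", s, e) for s, e in spans]

    def test_join_below_threshold_only(self):
        scaffolds = sc.join_contigs(self.make([(0, 100), (600, 700), (2000, 2100)]), 1000)
        assert [(s.start, s.end) for s in scaffolds] == [(0, 700), (2000, 2100)]
        assert scaffolds[0].internal_gaps == [500]

    def test_threshold_is_strict(self):
        scaffolds = sc.join_contigs(self.make([(0, 100), (1100, 1200)]), 1000)
        assert len(scaffolds) == 2  # gap exactly 1000 is NOT joined

    def test_zero_gap_identity(self):
        contigs = self.make([(0, 100), (200, 300), (400, 500)])
        scaffolds = sc.join_contigs(contigs, 0)
        assert len(scaffolds) == len(contigs)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            sc.join_contigs(self.make([(0, 10)]), -1)

    def test_count_conservation(self, rng):
        # scaffold count + join count = contig count; span conservation
        starts = np.cumsum(rng.integers(50, 2000, size=100))
        contigs = self.make([(int(s), int(s + 40)) for s in starts])
        scaffolds = sc.join_contigs(contigs, 700)
        joins = sum(len(s.internal_gaps) for s in scaffolds)
        assert len(scaffolds) + joins == len(contigs)
        total_contig = sum(c.length for c in contigs)
        total_span = sum(s.length for s in scaffolds)
        total_gaps = sum(sum(s.internal_gaps) for s in scaffolds)
        assert total_span == total_contig + total_gaps

    def test_monotone_in_max_gap(self, rng):
        starts = np.cumsum(rng.integers(110, 3000, size=200))  # gaps >= 10
        contigs = self.make([(int(s), int(s + 100)) for s in starts])
        prev_n50, prev_total, prev_count = 0.0, 0.0, len(contigs) + 1
        for gap in range(0, 3200, 200):
            scaffolds = sc.join_contigs(contigs, gap)
            summ = sc.length_summary([s.length for s in scaffolds])
            assert summ["N50"] >= prev_n50
            assert summ["total"] >= prev_total
            assert summ["count"] <= prev_count
            prev_n50, prev_total, prev_count = summ["N50"], summ["total"], summ["count"]

    def test_recovers_amplicon_spans(self, clean_truth):
        # deep, unskewed libraries: within-amplicon gaps are rare, so joining
        # at 1 kb should recover nearly all amplicon segments whole
        from cellhap import synthetic_data as sd

        libs = sd.simulate_subcell_libraries(
            clean_truth, n_cells=2, aliquots_per_cell=3, aliquot_fraction=1 / 6,
            amplicon_mean_len=30_000, coverage_skew=0.0, mean_depth=30, seed=44,
        )
        recovered = total = 0
        for lib in libs:
            contigs = sc.build_contigs(sorted(lib.read_intervals), chrom="c")
            scaffolds = sc.join_contigs(contigs, 1000)
            spans = [(s.start, s.end) for s in scaffolds]
            segs = [
                seg for h in (0, 1) for seg in lib.covered_segments[h]
                if seg[1] - seg[0] >= 1000
            ]
            for a, b in segs:
                total += 1
                # one scaffold covers (almost) the whole segment: allow the
                # sub-read-length fringe at each end
                mid_ok = any(s <= a + 300 and e >= b - 300 for s, e in spans)
                recovered += mid_ok
        assert total > 50
        assert recovered / total >= 0.95


class TestGapStatistics:
    def test_global_mean(self):
        gs = sc.gap_statistics(np.array([100, 200, 300]), bin_width=1000)
        assert gs.global_mean == pytest.approx(200)

    def test_exponential_expectation_closed_form(self):
        gaps = np.full(100, 50)
        gs = sc.gap_statistics(gaps, bin_width=100, exponential_mean=584)
        assert gs.expected_exponential_counts[0] == pytest.approx(
            100 * (1 - np.exp(-100 / 584)), rel=1e-9
        )
        assert gs.expected_exponential_counts[0] == pytest.approx(15.7, abs=0.05)

    def test_single_gap(self):
        gs = sc.gap_statistics(np.array([42]), bin_width=10)
        assert gs.bin_counts.sum() == 1
        assert gs.bin_counts[4] == 1

    def test_counts_partition_gaps(self, rng):
        gaps = rng.integers(1, 5000, size=500)
        gs = sc.gap_statistics(gaps, bin_width=250)
        assert gs.bin_counts.sum() == len(gaps)


class TestAdaptiveThreshold:
    def test_zero_sd(self):
        assert sc.adaptive_gap_threshold(np.full(10, 100), k=3) == pytest.approx(100)

    def test_closed_form_mean_sd(self):
        expected = 200 + np.std([100, 200, 300], ddof=1)
        assert sc.adaptive_gap_threshold(np.array([100, 200, 300]), k=1) == pytest.approx(expected)

    def test_k_zero_is_mean(self):
        assert sc.adaptive_gap_threshold(np.array([10, 20, 60]), k=0) == pytest.approx(30)

    def test_ceiling_restricts_population(self):
        gaps = np.array([100, 200, 5000])
        assert sc.adaptive_gap_threshold(gaps, k=0, ceiling=1000) == pytest.approx(150)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.adaptive_gap_threshold(np.array([]), k=3)


class TestCoverageHistogram:
    def test_constant_depth(self):
        h = sc.coverage_histogram(np.full(1000, 5), max_depth=10)
        assert h["counts"][5] == 1000
        assert h["counts"].sum() == 1000
        assert h["expected"][5] == pytest.approx(stats.poisson.pmf(5, 5) * 1000)

    def test_poisson_zero_class(self):
        h = sc.coverage_histogram(np.array([0, 1, 1, 2]), max_depth=5)
        assert h["expected"][0] / h["n"] == pytest.approx(np.exp(-h["mean"]))

    def test_simulated_poisson_fits(self, rng):
        depths = rng.poisson(4.0, size=20_000)
        h = sc.coverage_histogram(depths, max_depth=15)
        obs = np.concatenate([h["counts"], [h["overflow"]]])
        exp = np.concatenate([h["expected"], [h["expected_overflow"]]])
        keep = exp >= 5
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 2)
        assert pval > 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.coverage_histogram(np.array([]))


class TestWindowedRuns:
    def test_solid_run(self):
        depths = [0.0] * 10 + [5.0] * 30 + [0.0] * 10
        runs = sc.windowed_run_scaffolds(depths, background=1.0)
        assert [(r.start, r.end) for r in runs] == [(10_000, 40_000)]
        assert runs[0].flags == ()

    def test_short_run_dropped(self):
        depths = [0.0] * 5 + [5.0] * 10 + [0.0] * 5
        assert sc.windowed_run_scaffolds(depths, background=1.0) == []

    def test_exact_two_thirds_retained(self):
        # 30 windows, 20 above background, interleaved to keep every prefix
        # at >= 2/3: retained at the boundary (>=, not >)
        pattern = ([5.0, 5.0, 0.0] * 10)
        runs = sc.windowed_run_scaffolds(pattern, background=1.0, run_min=25_000)
        assert len(runs) == 1
        n_windows = (runs[0].end - runs[0].start) // 1000
        above = sum(1 for d in pattern[runs[0].start // 1000: runs[0].end // 1000] if d > 1.0)
        assert above / n_windows >= 2 / 3

    def test_long_run_flagged(self):
        depths = [5.0] * 60
        runs = sc.windowed_run_scaffolds(depths, background=1.0)
        assert runs[0].flags == ("over_run_max",)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            sc.windowed_run_scaffolds([1.0], background=0.5, window_fraction=0.0)


class TestLengthSummary:
    @pytest.mark.parametrize(
        "lengths,n50",
        [([8, 2, 2], 8), ([5, 5], 5), ([3, 3, 2, 2, 2], 3), ([7], 7)],
    )
    def test_n50(self, lengths, n50):
        assert sc.length_summary(lengths)["N50"] == n50

    def test_other_fields(self):
        s = sc.length_summary([8, 2, 2])
        assert s["mean"] == 4 and s["max"] == 8 and s["total"] == 12 and s["count"] == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.length_summary([])
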