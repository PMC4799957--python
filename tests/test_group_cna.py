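import numpy as np
import pandas as pd
import pytest

from crosscna.types import CrossCnaError, Segment
from crosscna.group_cna import (
    frequency_track,
    gene_copy_matrix,
    gene_group_test,
    group_specific_segments,
)


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])


class TestGeneCopyMatrix:
    def test_gene_inside_single_segment_takes_its_mean(self):
        genes = _genes([("g1", "chr1", 100, 200, "+")])
        segs = [Segment("s1", "chr1", 0, 1000, 10, 0.4)]
        m = gene_copy_matrix(segs, genes)
        assert m.values.at["g1", "s1"] == pytest.approx(0.4)
        assert m.calls.at["g1", "s1"] == "gain"

    def test_gene_split_by_breakpoint_weighted_mean(self):
        genes = _genes([("g1", "chr1", 100, 300, "+")])
        segs = [Segment("s1", "chr1", 0, 200, 5, 0.4),
                Segment("s1", "chr1", 200, 1000, 5, 0.0)]
        m = gene_copy_matrix(segs, genes)
        assert m.values.at["g1", "s1"] == pytest.approx(0.2)

    def test_uncovered_gene_is_missing_not_zero(self):
        genes = _genes([("g1", "chr2", 100, 200, "+")])
        segs = [Segment("s1", "chr1", 0, 1000, 10, 0.4)]
        m = gene_copy_matrix(segs, genes)
        assert np.isnan(m.values.at["g1", "s1"])
        assert pd.isna(m.calls.at["g1", "s1"])

    def test_matches_brute_force_per_bp_average(self):
        """30 random genes against a random segment partition, vs a naive
        per-basepair averaging oracle."""
        rng = np.random.default_rng(6)
        bounds = np.sort(rng.choice(np.arange(100, 10_000), 7, replace=False))
        bounds = [0, *bounds, 10_000]
        segs = [Segment("s1", "chr1", a, b, 2, float(rng.normal(0, 0.5)))
                for a, b in zip(bounds, bounds[1:])]
        per_bp = np.zeros(10_000)
        for s in segs:
            per_bp[s.start:s.end] = s.mean_log2
        rows = []
        for k in range(30):
            start = int(rng.integers(0, 9_900))
            end = start + int(rng.integers(10, 1500))
            rows.append((f"g{k}", "chr1", start, min(end, 10_000), "+"))
        genes = _genes(rows)
        m = gene_copy_matrix(segs, genes)
        for gid, start, end in zip(genes["gene_id"], genes["start"], genes["end"]):
            assert m.values.at[gid, "s1"] == pytest.approx(
                per_bp[start:end].mean(), abs=1e-9)


class TestFrequencyTrack:
    @pytest.fixture()
    def matrix(self):
        genes = _genes([("g1", "chr1", 0, 100, "+")])
        segs = []
        for k in range(18):
            mean = 0.8 if k < 3 else 0.0
            segs.append(Segment(f"t_{k:02d}", "chr1", 0, 1000, 5, mean))
        return gene_copy_matrix(segs, genes)

    def test_three_of_eighteen_gained(self, matrix):
        track = frequency_track(matrix, matrix.samples, "tumor")
        assert track.table.at["g1", "freq_gain"] == pytest.approx(3 / 18)
        assert track.table.at["g1", "freq_loss"] == 0.0

    def test_missing_calls_count_in_denominator(self):
        genes = _genes([("g1", "chr1", 0, 100, "+")])
        segs = [Segment("s0", "chr1", 0, 1000, 5, 0.8),
                Segment("s1", "chr2", 0, 1000, 5, 0.8)]  # s1 misses the gene
        m = gene_copy_matrix(segs, genes)
        track = frequency_track(m, ["s0", "s1"], "g")
        assert track.table.at["g1", "freq_gain"] == pytest.approx(0.5)

    def test_empty_group_rejected(self, matrix):
        with pytest.raises(CrossCnaError, match="empty"):
            frequency_track(matrix, [], "g")

    def test_invariant_to_sample_order(self, matrix):
        fwd = frequency_track(matrix, matrix.samples, "g")
        rev = frequency_track(matrix, matrix.samples[::-1], "g")
        pd.testing.assert_frame_equal(fwd.table, rev.table)


class TestGeneGroupTest:
    def _matrix_from_values(self, values_a, values_b):
        genes = _genes([("g1", "chr1", 0, 100, "+")])
        segs = []
        for k, v in enumerate(values_a):
            segs.append(Segment(f"a_{k:02d}", "chr1", 0, 1000, 5, float(v)))
        for k, v in enumerate(values_b):
            segs.append(Segment(f"b_{k:02d}", "chr1", 0, 1000, 5, float(v)))
        m = gene_copy_matrix(segs, genes)
        a = [f"a_{k:02d}" for k in range(len(values_a))]
        b = [f"b_{k:02d}" for k in range(len(values_b))]
        return m, a, b

    def test_identical_groups_with_variance_give_p_one(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        m, a, b = self._matrix_from_values(vals, vals)
        assert gene_group_test(m, a, b, "g1") == pytest.approx(1.0, abs=1e-9)

    def test_strong_separation_gives_tiny_p(self):
        rng = np.random.default_rng(0)
        m, a, b = self._matrix_from_values(1.0 + rng.normal(0, 0.05, 18),
                                           rng.normal(0, 0.05, 18))
        assert gene_group_test(m, a, b, "g1") < 1e-10

    def test_single_usable_value_gives_missing_p(self):
        m, a, b = self._matrix_from_values([0.5], [0.1, 0.2, 0.3])
        assert np.isnan(gene_group_test(m, a, b, "g1"))


class TestGroupSpecificSegments:
    def _cohort(self, freq_a=0.5, freq_b=0.0, n=18, n_genes=5, effect=0.8, sd=0.05,
                seed=0):
        """n_genes adjacent genes gained in a fraction of each group."""
        rng = np.random.default_rng(seed)
        genes = _genes([(f"g{k}", "chr1", k * 1000, k * 1000 + 800, "+")
                        for k in range(n_genes)])
        segs = []
        for grp, freq in (("a", freq_a), ("b", freq_b)):
            carriers = int(round(freq * n))
            for k in range(n):
                mean = effect if k < carriers else 0.0
                mean += float(rng.normal(0, sd))
                segs.append(Segment(f"{grp}_{k:02d}", "chr1", 0, n_genes * 1000,
                                    n_genes, mean))
        m = gene_copy_matrix(segs, genes)
        a = [f"a_{k:02d}" for k in range(n)]
        b = [f"b_{k:02d}" for k in range(n)]
        track = frequency_track(m, a, "focal")
        return track, m, a, b

    def test_planted_group_specific_gain_reported(self):
        track, m, a, b = self._cohort(freq_a=0.5, freq_b=0.0)
        regions = group_specific_segments(track, m, a, b)
        assert len(regions) == 1
        assert regions[0].direction == "gain"
        assert regions[0].frequency == pytest.approx(0.5)
        assert regions[0].min_gene_p < 0.05

    def test_low_frequency_region_excluded_by_15pct_rule(self):
        track, m, a, b = self._cohort(freq_a=2 / 18, freq_b=0.0)
        assert group_specific_segments(track, m, a, b) == []

    def test_equal_frequency_region_excluded_by_gene_p_rule(self):
        track, m, a, b = self._cohort(freq_a=0.5, freq_b=0.5, seed=1)
        assert group_specific_segments(track, m, a, b) == []

    def test_filtering_is_monotone(self):
        track, m, a, b = self._cohort(freq_a=0.5, freq_b=0.0)
        base = group_specific_segments(track, m, a, b, 0.15, 0.05)
        stricter_freq = group_specific_segments(track, m, a, b, 0.6, 0.05)
        stricter_p = group_specific_segments(track, m, a, b, 0.15, 1e-30)
        assert len(stricter_freq) <= len(base)
        assert len(stricter_p) <= len(base)
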