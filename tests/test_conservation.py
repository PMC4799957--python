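import numpy as np
import pandas as pd
import pytest

from crosscna.types import FrequencyTrack, GroupSpecificSegment
from crosscna.conservation import (
    conserved_cna_genes,
    cross_species_segment_stats,
    remap_orthologs,
)


def _track(gene_rows, group="tumor", n=18):
    """gene_rows: (gene_id, chrom, start, end, freq_gain, freq_loss)."""
    df = pd.DataFrame(gene_rows, columns=["gene_id", "chromosome", "start", "end",
                                          "freq_gain", "freq_loss"])
    return FrequencyTrack(group, n, df.set_index("gene_id"))


class TestRemapOrthologs:
    def test_identity_map_preserves_track(self):
        rows = [(f"g{k}", "chr1", k * 100, k * 100 + 50, 0.1 * k, 0.0)
                for k in range(5)]
        track = _track(rows)
        genes = pd.DataFrame({
            "gene_id": [f"g{k}" for k in range(5)], "chromosome": "chr1",
            "start": [k * 100 for k in range(5)],
            "end": [k * 100 + 50 for k in range(5)], "strand": "+",
        })
        omap = pd.DataFrame({"gene_a": genes["gene_id"], "gene_b": genes["gene_id"]})
        remapped = remap_orthologs(track, omap, genes)
        assert remapped.table["mapped"].all()
        assert np.allclose(remapped.table["source_freq_gain"],
                           track.table["freq_gain"])

    def test_unmapped_target_gene_flagged_without_frequencies(self):
        track = _track([("a1", "chr1", 0, 50, 0.5, 0.0)])
        genes = pd.DataFrame({"gene_id": ["b1", "b2"], "chromosome": "chr1",
                              "start": [0, 100], "end": [50, 150], "strand": "+"})
        omap = pd.DataFrame({"gene_a": ["a1"], "gene_b": ["b1"]})
        remapped = remap_orthologs(track, omap, genes)
        assert not remapped.table.at["b2", "mapped"]
        assert np.isnan(remapped.table.at["b2", "source_freq_gain"])

    def test_shuffled_order_matches_brute_force_join(self):
        rng = np.random.default_rng(4)
        n = 20
        src_rows = [(f"a{k}", "chr1", k * 100, k * 100 + 50,
                     float(rng.uniform(0, 0.6)), 0.0) for k in range(n)]
        track = _track(src_rows)
        order = rng.permutation(n)
        genes = pd.DataFrame({
            "gene_id": [f"b{k}" for k in range(n)], "chromosome": "chr1",
            "start": [int(order[k]) * 100 for k in range(n)],
            "end": [int(order[k]) * 100 + 50 for k in range(n)], "strand": "+",
        })
        omap = pd.DataFrame({"gene_a": [f"a{k}" for k in range(n)],
                             "gene_b": [f"b{k}" for k in range(n)]})
        remapped = remap_orthologs(track, omap, genes)
        # order follows target coordinates
        assert list(remapped.table["start"]) == sorted(remapped.table["start"])
        # values follow the map (brute-force dict join)
        lookup = {f"b{k}": track.table.at[f"a{k}", "freq_gain"] for k in range(n)}
        for gid in remapped.table.index:
            assert remapped.table.at[gid, "source_freq_gain"] == lookup[gid]


class TestConservedGenes:
    def _pairframes(self, src_freqs, tgt_freqs):
        """Single shared target gene set b0..bn with direct orthologs."""
        n = len(src_freqs)
        track_a = _track([(f"a{k}", "chr1", k * 100, k * 100 + 50, *src_freqs[k])
                          for k in range(n)])
        track_b = _track([(f"b{k}", "chr1", k * 100, k * 100 + 50, *tgt_freqs[k])
                          for k in range(n)])
        genes_b = pd.DataFrame({
            "gene_id": [f"b{k}" for k in range(n)], "chromosome": "chr1",
            "start": [k * 100 for k in range(n)],
            "end": [k * 100 + 50 for k in range(n)], "strand": "+",
        })
        omap = pd.DataFrame({"gene_a": [f"a{k}" for k in range(n)],
                             "gene_b": [f"b{k}" for k in range(n)]})
        remapped = remap_orthologs(track_a, omap, genes_b)
        return remapped, track_b

    def test_direction_and_threshold_rules(self):
        remapped, track_b = self._pairframes(
            src_freqs=[(0.5, 0.0), (0.5, 0.0), (0.5, 0.0), (0.2, 0.2)],
            tgt_freqs=[(0.5, 0.0), (0.0, 0.5), (0.10, 0.0), (0.3, 0.0)],
        )
        conserved = conserved_cna_genes(remapped, track_b, 0.15)
        # b0 conserved gain; b1 direction mismatch; b2 below 15%; b3 source tie
        assert conserved["gene_id"].tolist() == ["b0"]
        assert conserved["direction"].tolist() == ["gain"]

    def test_symmetric_in_species(self):
        rng = np.random.default_rng(9)
        n = 30
        freqs = lambda: [(float(rng.choice([0, 0.1, 0.3, 0.5])),
                          float(rng.choice([0, 0.1, 0.3]))) for _ in range(n)]
        fa, fb = freqs(), freqs()
        fa = [(g, l) if g + l <= 1 else (g, 0.0) for g, l in fa]
        fb = [(g, l) if g + l <= 1 else (g, 0.0) for g, l in fb]
        remap_ab, track_b = self._pairframes(fa, fb)
        conserved_ab = conserved_cna_genes(remap_ab, track_b, 0.15)
        remap_ba, track_a = self._pairframes(fb, fa)
        conserved_ba = conserved_cna_genes(remap_ba, track_a, 0.15)
        # same pairs conserved regardless of which species is the source
        idx = lambda df: sorted(int(g[1:]) for g in df["gene_id"])
        assert idx(conserved_ab) == idx(conserved_ba)

    def test_removing_ortholog_pairs_never_adds_conserved_genes(self):
        remapped, track_b = self._pairframes(
            src_freqs=[(0.5, 0.0)] * 6, tgt_freqs=[(0.5, 0.0)] * 6)
        full = conserved_cna_genes(remapped, track_b, 0.15)
        reduced_table = remapped.table.copy()
        reduced_table.loc["b0", "mapped"] = False
        from crosscna.types import RemappedTrack
        reduced = conserved_cna_genes(RemappedTrack("tumor", reduced_table),
                                      track_b, 0.15)
        assert len(reduced) <= len(full)
        assert set(reduced["gene_id"]) <= set(full["gene_id"])


class TestSegmentStats:
    def _conserved(self, src_ids):
        return pd.DataFrame({
            "gene_id": [f"b_{g}" for g in src_ids], "source_gene": src_ids,
            "direction": "gain", "source_freq": 0.5, "target_freq": 0.5,
        })

    def _segments(self, gene_lists):
        return [GroupSpecificSegment("chr1", 100 * k, 100 * k + 50, "gain", 0.5,
                                     genes, {genes[0]: 0.01})
                for k, genes in enumerate(gene_lists)]

    def test_half_of_segments_shared(self):
        segs = self._segments([["a1", "a2"], ["a3"], ["a4"], ["a5", "a6"]])
        stats = cross_species_segment_stats(segs, self._conserved(["a1", "a5"]))
        assert stats.pct_segments_shared == pytest.approx(50.0)

    def test_all_genes_conserved_gives_100pct(self):
        segs = self._segments([["a1", "a2"]])
        stats = cross_species_segment_stats(segs, self._conserved(["a1", "a2"]))
        assert stats.pct_genes_shared == pytest.approx(100.0)

    def test_zero_segments_undefined_not_zero(self):
        stats = cross_species_segment_stats([], self._conserved(["a1"]))
        assert stats.pct_segments_shared is None
        assert stats.pct_genes_shared is None

    def test_counts_match_exhaustive_set_intersection(self):
        rng = np.random.default_rng(12)
        gene_lists = [[f"a{k}_{j}" for j in range(4)] for k in range(5)]
        all_genes = [g for genes in gene_lists for g in genes]
        conserved_src = list(rng.choice(all_genes, 7, replace=False))
        stats = cross_species_segment_stats(self._segments(gene_lists),
                                            self._conserved(conserved_src))
        hit = sum(1 for genes in gene_lists if set(genes) & set(conserved_src))
        assert stats.pct_segments_shared == pytest.approx(100.0 * hit / 5)
        assert stats.pct_genes_shared == pytest.approx(
            100.0 * len(set(all_genes) & set(conserved_src)) / len(all_genes))
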