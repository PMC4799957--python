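"""Cross-species remapping of CNA frequency tracks and conservation statistics.

The source species' gene-level alteration frequencies are carried through a
one-to-one ortholog map into the target species' genomic order.  A gene is
a conserved CNA when both species alter it in the same dominant direction
(gain or loss) at or above the frequency threshold (15% by default); a
frequency tie at a gene leaves it unclassified and never conserved.  The
conserved gene set is symmetric in the two species; the segment-level
percentage is computed from the designated source side's segments.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ConservationStats,
    CrossCnaError,
    FrequencyTrack,
    GroupSpecificSegment,
    RemappedTrack,
)


def remap_orthologs(source_track: FrequencyTrack, ortholog_map: pd.DataFrame,
                    target_genes: pd.DataFrame,
                    source_side: str = "gene_a") -> RemappedTrack:
    """Carry source-species frequencies onto target genes in target order.

    ``ortholog_map`` must be one-to-one with columns gene_a/gene_b;
    ``source_side`` names the column holding source-species ids (the other
    column holds target ids).  Target genes without an ortholog, or whose
    ortholog is absent from the source track, are flagged unmapped and
    carry no frequencies.
    """
    if source_side not in ("gene_a", "gene_b"):
        raise CrossCnaError("source_side must be 'gene_a' or 'gene_b'")
    target_side = "gene_b" if source_side == "gene_a" else "gene_a"
    if ortholog_map[source_side].duplicated().any() or \
            ortholog_map[target_side].duplicated().any():
        raise CrossCnaError("ortholog map is not one-to-one")
    to_source = dict(zip(ortholog_map[target_side], ortholog_map[source_side]))

    tg = target_genes.sort_values(["chromosome", "start"], kind="mergesort")
    table = tg.set_index("gene_id")[["chromosome", "start", "end"]].copy()
    src = table.index.map(lambda g: to_source.get(g))
    table["source_gene"] = src
    in_track = pd.Index(src).isin(source_track.table.index) & pd.notna(src)
    table["mapped"] = in_track
    table["source_freq_gain"] = np.nan
    table["source_freq_loss"] = np.nan
    mapped_src = [s for s, ok in zip(src, in_track) if ok]
    table.loc[in_track, "source_freq_gain"] = \
        source_track.table.loc[mapped_src, "freq_gain"].to_numpy()
    table.loc[in_track, "source_freq_loss"] = \
        source_track.table.loc[mapped_src, "freq_loss"].to_numpy()
    return RemappedTrack(source_group=source_track.group, table=table)


def _dominant(freq_gain, freq_loss) -> str | None:
    """Dominant alteration direction; None on ties (unclassifiable)."""
    if freq_gain > freq_loss:
        return "gain"
    if freq_loss > freq_gain:
        return "loss"
    return None


def conserved_cna_genes(remapped: RemappedTrack, target_track: FrequencyTrack,
                        freq_threshold: float = 0.15) -> pd.DataFrame:
    """Genes altered in the same dominant direction at >= threshold in both
    species.

    Returns one row per conserved target gene: gene_id (target),
    source_gene, direction, source_freq, target_freq.
    """
    rows = []
    rt = remapped.table
    tt = target_track.table
    for gid in rt.index[rt["mapped"]]:
        if gid not in tt.index:
            continue
        sg, sl = rt.at[gid, "source_freq_gain"], rt.at[gid, "source_freq_loss"]
        tg, tl = tt.at[gid, "freq_gain"], tt.at[gid, "freq_loss"]
        d_src, d_tgt = _dominant(sg, sl), _dominant(tg, tl)
        if d_src is None or d_src != d_tgt:
            continue
        s_freq = sg if d_src == "gain" else sl
        t_freq = tg if d_src == "gain" else tl
        if s_freq >= freq_threshold and t_freq >= freq_threshold:
            rows.append({
                "gene_id": gid,
                "source_gene": rt.at[gid, "source_gene"],
                "direction": d_src,
                "source_freq": float(s_freq),
                "target_freq": float(t_freq),
            })
    return pd.DataFrame(rows, columns=["gene_id", "source_gene", "direction",
                                       "source_freq", "target_freq"])


def cross_species_segment_stats(source_segments: Sequence[GroupSpecificSegment],
                                conserved_genes: pd.DataFrame,
                                ) -> ConservationStats:
    """Summarize conservation at segment and gene level.

    ``pct_segments_shared``: percent of source altered segments containing
    at least one conserved gene (source-species ids).
    ``pct_genes_shared``: percent of the distinct genes inside source
    altered segments that are conserved.  Both are None (undefined) when
    there are no source segments.
    """
    conserved_src = set(conserved_genes["source_gene"]) if len(conserved_genes) else set()
    n_segments = len(source_segments)
    seg_genes: set[str] = set()
    n_hit = 0
    for seg in source_segments:
        seg_genes.update(seg.genes)
        if any(g in conserved_src for g in seg.genes):
            n_hit += 1
    if n_segments == 0:
        return ConservationStats(None, None, [], 0, 0)
    pct_segments = 100.0 * n_hit / n_segments
    n_conserved_in_segments = len(seg_genes & conserved_src)
    pct_genes = 100.0 * n_conserved_in_segments / len(seg_genes) if seg_genes else None
    return ConservationStats(
        pct_segments_shared=pct_segments,
        pct_genes_shared=pct_genes,
        conserved_genes=sorted(seg_genes & conserved_src),
        n_source_segments=n_segments,
        n_source_segment_genes=len(seg_genes),
    )


def write_conserved_genes(conserved: pd.DataFrame, path) -> None:
    conserved.to_csv(path, sep="\t", index=False, na_rep=".")


def write_conservation_stats(stats: ConservationStats, path,
                             freq_threshold: float = 0.15,
                             source_group: str = "", target_group: str = "") -> None:
    payload = {
        "pct_segments_shared": stats.pct_segments_shared,
        "pct_genes_shared": stats.pct_genes_shared,
        "n_source_segments": stats.n_source_segments,
        "n_source_segment_genes": stats.n_source_segment_genes,
        "n_conserved_genes_in_segments": len(stats.conserved_genes),
        "freq_threshold": freq_threshold,
        "source_group": source_group,
        "target_group": target_group,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
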