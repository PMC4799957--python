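"""Gene-level copy matrices, within-group CNA frequencies, and detection of
group-specific segments.

A "group-specific segment" follows a two-part rule: a maximal run of
adjacent genes (in genomic order) altered in one direction at a frequency
of at least ``freq_threshold`` (default 15%) within the focal group, which
additionally contains at least one gene whose copy values differ between
the two groups at ``p < p_threshold`` (default 0.05, Welch two-sample t,
uncorrected by design — the published rule is a plain per-gene p cutoff).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CrossCnaError,
    FrequencyTrack,
    GeneCopyMatrix,
    GroupSpecificSegment,
    Segment,
)

logger = logging.getLogger(__name__)


def gene_copy_matrix(segments: Sequence[Segment], genes: pd.DataFrame,
                     gain_threshold: float = 0.2,
                     loss_threshold: float = -0.2) -> GeneCopyMatrix:
    """Project per-sample segments onto genes.

    A gene's value in a sample is the bp-overlap-weighted mean of the means
    of the segments overlapping it; the gene call applies the same
    inclusive thresholds used for segments.  A gene overlapped by no
    segment (including genes on chromosomes absent from the segmentation)
    is missing (NaN), never zero.
    """
    if not (gain_threshold > 0 > loss_threshold):
        raise CrossCnaError("need gain_threshold > 0 > loss_threshold")
    genes = genes.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
    samples = sorted({s.sample_id for s in segments})
    seg_chroms = {s.chromosome for s in segments}
    missing_chroms = sorted(set(genes["chromosome"]) - seg_chroms)
    if missing_chroms:
        logger.warning("genes on %d chromosome(s) absent from segmentation: %s",
                       len(missing_chroms), ",".join(missing_chroms))

    by_sample_chrom: dict[tuple[str, str], list[Segment]] = {}
    for s in segments:
        by_sample_chrom.setdefault((s.sample_id, s.chromosome), []).append(s)

    values = pd.DataFrame(np.nan, index=genes["gene_id"], columns=samples, dtype=float)
    for (sample, chrom), segs in by_sample_chrom.items():
        segs.sort(key=lambda s: s.start)
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        means = np.array([s.mean_log2 for s in segs])
        sub = genes[genes["chromosome"] == chrom]
        for gid, gstart, gend in zip(sub["gene_id"], sub["start"], sub["end"]):
            lo = int(np.searchsorted(ends, gstart, side="right"))
            hi = int(np.searchsorted(starts, gend, side="left"))
            if hi <= lo:
                continue
            ov = np.minimum(ends[lo:hi], gend) - np.maximum(starts[lo:hi], gstart)
            ov = np.clip(ov, 0, None)
            w = ov.sum()
            if w > 0:
                values.at[gid, sample] = float((ov * means[lo:hi]).sum() / w)

    calls = pd.DataFrame("neutral", index=values.index, columns=samples, dtype=object)
    calls = calls.mask(values >= gain_threshold, "gain")
    calls = calls.mask(values <= loss_threshold, "loss")
    calls = calls.mask(values.isna(), np.nan)
    return GeneCopyMatrix(genes=genes, values=values, calls=calls)


def frequency_track(matrix: GeneCopyMatrix, group_samples: Sequence[str],
                    group: str = "group") -> FrequencyTrack:
    """Per-gene fraction of group samples called gain/loss.

    Missing calls count in the denominator (the full group size), never in
    the numerator.
    """
    group_samples = list(group_samples)
    if not group_samples:
        raise CrossCnaError("empty group")
    unknown = set(group_samples) - set(matrix.samples)
    if unknown:
        raise CrossCnaError(f"group samples not in matrix: {sorted(unknown)}")
    calls = matrix.calls[group_samples]
    n = len(group_samples)
    table = matrix.genes.set_index("gene_id")[["chromosome", "start", "end"]].copy()
    table["freq_gain"] = (calls == "gain").sum(axis=1) / n
    table["freq_loss"] = (calls == "loss").sum(axis=1) / n
    track = FrequencyTrack(group=group, n_samples=n, table=table)
    track.validate()
    return track


def gene_group_test(matrix: GeneCopyMatrix, group_a: Sequence[str],
                    group_b: Sequence[str], gene_id: str) -> float:
    """Two-sided Welch t-test p-value comparing a gene's copy values between
    groups; NaN when either group has fewer than 2 non-missing values."""
    a = matrix.values.loc[gene_id, list(group_a)].to_numpy(dtype=float)
    b = matrix.values.loc[gene_id, list(group_b)].to_numpy(dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def group_specific_segments(freq_track_a: FrequencyTrack, matrix: GeneCopyMatrix,
                            group_a: Sequence[str], group_b: Sequence[str],
                            freq_threshold: float = 0.15,
                            p_threshold: float = 0.05,
                            ) -> list[GroupSpecificSegment]:
    """Detect segments specific to the focal group ``group_a``.

    Candidate regions are maximal runs of adjacent genes (same chromosome,
    genomic order) whose focal-group frequency in one direction is at least
    ``freq_threshold``; a candidate is reported iff at least one contained
    gene's between-group Welch p-value is below ``p_threshold``.  The
    region frequency is the max gene frequency in the run.
    """
    if not 0.0 < freq_threshold <= 1.0:
        raise CrossCnaError("freq_threshold must be in (0, 1]")
    table = freq_track_a.table
    genes = matrix.genes  # genomic order
    out: list[GroupSpecificSegment] = []
    for direction in ("gain", "loss"):
        col = f"freq_{direction}"
        eligible = table.loc[genes["gene_id"], col].to_numpy() >= freq_threshold
        run: list[int] = []
        prev_chrom = None
        for idx, (ok, chrom) in enumerate(zip(eligible, genes["chromosome"])):
            if ok and chrom == prev_chrom:
                run.append(idx)
            else:
                if run:
                    out.extend(_finish_run(run, direction, genes, table, matrix,
                                           group_a, group_b, p_threshold))
                run = [idx] if ok else []
            prev_chrom = chrom
        if run:
            out.extend(_finish_run(run, direction, genes, table, matrix,
                                   group_a, group_b, p_threshold))
    out.sort(key=lambda r: (r.chromosome, r.start, r.direction))
    return out


def _finish_run(run: list[int], direction: str, genes: pd.DataFrame,
                table: pd.DataFrame, matrix: GeneCopyMatrix,
                group_a: Sequence[str], group_b: Sequence[str],
                p_threshold: float) -> list[GroupSpecificSegment]:
    sub = genes.iloc[run]
    gene_ids = list(sub["gene_id"])
    pvals = {g: gene_group_test(matrix, group_a, group_b, g) for g in gene_ids}
    finite = [p for p in pvals.values() if np.isfinite(p)]
    if not finite or min(finite) >= p_threshold:
        return []
    return [GroupSpecificSegment(
        chromosome=str(sub["chromosome"].iloc[0]),
        start=int(sub["start"].min()),
        end=int(sub["end"].max()),
        direction=direction,
        frequency=float(table.loc[gene_ids, f"freq_{direction}"].max()),
        genes=gene_ids,
        gene_p=pvals,
    )]


def read_group_specific(path) -> list[GroupSpecificSegment]:
    """Read a group-specific-regions TSV back (gene p-values are reduced to
    the stored minimum; full per-gene p-values live only in-session)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, na_values=["."])
    out = []
    for _, row in df.iterrows():
        genes = str(row["genes"]).split(",") if pd.notna(row["genes"]) else []
        min_p = float(row["min_gene_p"]) if pd.notna(row["min_gene_p"]) else float("nan")
        out.append(GroupSpecificSegment(
            chromosome=str(row["chromosome"]), start=int(row["start"]),
            end=int(row["end"]), direction=str(row["direction"]),
            frequency=float(row["frequency"]), genes=genes,
            gene_p={genes[0]: min_p} if genes else {},
        ))
    return out


def write_group_specific(regions: list[GroupSpecificSegment], path) -> None:
    rows = [{
        "chromosome": r.chromosome, "start": r.start, "end": r.end,
        "direction": r.direction, "frequency": r.frequency,
        "min_gene_p": r.min_gene_p, "genes": ",".join(r.genes),
    } for r in regions]
    pd.DataFrame(rows, columns=["chromosome", "start", "end", "direction",
                                "frequency", "min_gene_p", "genes"]
                 ).to_csv(path, sep="\t", index=False, na_rep=".")
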