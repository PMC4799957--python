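"""Readers and writers for the tab-delimited formats the pipeline touches.

All files are UTF-8 TSV with "." for missing values.  Internal coordinates
are 0-based half-open everywhere; BED is native, SEG is converted at the
boundary (written 1-based inclusive).  Chromosome names are compared by
exact string match.  Malformed rows are reported with 1-based file line
numbers (header = line 1).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import CrossCnaError, FrequencyTrack, ProbeProfile, Segment

logger = logging.getLogger(__name__)

NA = "."
_SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False, **kw)


def _line(df_index: int, header: bool = True) -> int:
    """1-based file line for a DataFrame row index."""
    return int(df_index) + (2 if header else 1)


def _numeric(df: pd.DataFrame, column: str, path: str | Path,
             kind=float) -> np.ndarray:
    raw = df[column]
    try:
        # astype uses the correctly-rounded parser (exact round-trips),
        # unlike the fast pd.to_numeric path
        out = raw.astype(float)
    except (ValueError, TypeError):
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna()
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CrossCnaError(
            f"{path}: non-numeric value {raw.iloc[i]!r} in column {column!r} "
            f"at line {_line(df.index[i])}"
        ) from None
    if kind is int:
        frac = out.dropna() % 1
        if (frac != 0).any():
            raise CrossCnaError(f"{path}: non-integer value in column {column!r}")
        return out.astype("Int64").to_numpy(dtype=object)
    return out.to_numpy(dtype=float)


def _require(df: pd.DataFrame, columns: Iterable[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CrossCnaError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# probe tables (wide: one log2-ratio column per sample)
# ---------------------------------------------------------------------------

def read_probe_table(path: str | Path) -> list[ProbeProfile]:
    """Read a wide probe table into one ProbeProfile per sample column.

    Required columns: probe_id, chromosome, position; every remaining
    column is a sample's log2 ratios, except columns named
    ``intensity_<sample>`` which attach mean intensities to that sample.
    Rows are re-sorted by (chromosome, position).
    """
    df = _read_tsv(path)
    _require(df, ["probe_id", "chromosome", "position"], path)
    df = df.copy()
    df["position"] = pd.to_numeric(df["position"], errors="coerce")
    if df["position"].isna().any():
        i = int(np.flatnonzero(df["position"].isna().to_numpy())[0])
        raise CrossCnaError(f"{path}: bad position at line {_line(df.index[i])}")
    dup = df.duplicated(subset=["chromosome", "position"], keep=False)
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[1])
        raise CrossCnaError(
            f"{path}: duplicate (chromosome, position) at line {_line(df.index[i])}"
        )
    sample_cols = [c for c in df.columns
                   if c not in ("probe_id", "chromosome", "position")
                   and not c.startswith("intensity_")]
    if not sample_cols:
        raise CrossCnaError(f"{path}: no sample columns found")
    ratios = {c: _numeric(df, c, path) for c in sample_cols}
    intensities = {c[len("intensity_"):]: _numeric(df, c, path)
                   for c in df.columns if c.startswith("intensity_")}
    base = pd.DataFrame({
        "probe_id": df["probe_id"].to_numpy(),
        "chromosome": df["chromosome"].to_numpy(),
        "position": df["position"].astype(int).to_numpy(),
    })
    profiles = []
    for sample in sample_cols:
        probes = base.copy()
        probes["log2_ratio"] = ratios[sample]
        if sample in intensities:
            probes["mean_intensity"] = intensities[sample]
        probes = probes.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
        prof = ProbeProfile(sample, probes)
        prof.validate()
        profiles.append(prof)
    return profiles


def write_probe_table(profiles: Sequence[ProbeProfile], path: str | Path) -> None:
    """Write profiles as one wide TSV; all profiles must share the probe grid."""
    if not profiles:
        raise CrossCnaError("no profiles to write")
    base = profiles[0].probes[["probe_id", "chromosome", "position"]].reset_index(drop=True)
    out = base.copy()
    for prof in profiles:
        key = prof.probes[["probe_id", "chromosome", "position"]].reset_index(drop=True)
        if not key.equals(base):
            raise CrossCnaError("profiles do not share one probe grid")
        out[prof.sample_id] = prof.probes["log2_ratio"].to_numpy()
    for prof in profiles:
        if "mean_intensity" in prof.probes.columns:
            out[f"intensity_{prof.sample_id}"] = prof.probes["mean_intensity"].to_numpy()
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


# ---------------------------------------------------------------------------
# SEG (segmented copy number exchange format)
# ---------------------------------------------------------------------------

def write_seg(segments: Sequence[Segment], path: str | Path) -> None:
    """Write segments in SEG dialect: 1-based inclusive, means to 6 decimals.

    An extra ``Call`` column is appended when any segment carries a
    non-neutral call.  Overlapping segments within one sample/chromosome
    are rejected.
    """
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chromosome), []).append(s)
    for (sample, chrom), group in by_key.items():
        group.sort(key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise CrossCnaError(
                    f"overlapping segments in sample {sample!r} on {chrom!r}"
                )
    with_calls = any(s.call != "neutral" for s in segments)
    rows = []
    for s in segments:
        row = {
            "Sample": s.sample_id,
            "Chromosome": s.chromosome,
            "Start": s.start + 1,  # 0-based half-open -> 1-based inclusive
            "End": s.end,
            "Num_Probes": s.n_probes,
            "Segment_Mean": f"{s.mean_log2:.6f}",
        }
        if with_calls:
            row["Call"] = s.call
        rows.append(row)
    cols = _SEG_COLUMNS + (["Call"] if with_calls else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, na_rep=NA)


def read_seg(path: str | Path) -> list[Segment]:
    df = _read_tsv(path)
    _require(df, _SEG_COLUMNS, path)
    starts = _numeric(df, "Start", path, int)
    ends = _numeric(df, "End", path, int)
    n_probes = _numeric(df, "Num_Probes", path, int)
    means = _numeric(df, "Segment_Mean", path)
    calls = df["Call"] if "Call" in df.columns else pd.Series(["neutral"] * len(df))
    segments = []
    for i in range(len(df)):
        segments.append(Segment(
            sample_id=str(df["Sample"].iloc[i]),
            chromosome=str(df["Chromosome"].iloc[i]),
            start=int(starts[i]) - 1,  # back to 0-based half-open
            end=int(ends[i]),
            n_probes=int(n_probes[i]),
            mean_log2=float(means[i]),
            call=str(calls.iloc[i]) if pd.notna(calls.iloc[i]) else "neutral",
        ))
    return segments


# ---------------------------------------------------------------------------
# BED6 gene annotations
# ---------------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 gene annotations (0-based half-open, kept unchanged)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                     na_values=[NA], keep_default_na=False)
    if df.shape[1] < 6:
        raise CrossCnaError(f"{path}: BED6 requires 6 columns, found {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = ["chromosome", "start", "end", "gene_id", "score", "strand"]
    starts = _numeric(df, "start", path, int)
    ends = _numeric(df, "end", path, int)
    out = pd.DataFrame({
        "gene_id": df["gene_id"].to_numpy(),
        "chromosome": df["chromosome"].to_numpy(),
        "start": [int(x) for x in starts],
        "end": [int(x) for x in ends],
        "strand": df["strand"].to_numpy(),
    })
    bad = out["start"] >= out["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CrossCnaError(f"{path}: start >= end at line {_line(df.index[i], header=False)}")
    return out.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({
        0: genes["chromosome"], 1: genes["start"], 2: genes["end"],
        3: genes["gene_id"], 4: 0, 5: genes.get("strand", "+"),
    })
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# ortholog map
# ---------------------------------------------------------------------------

def read_ortholog_map(path: str | Path,
                      valid_a: Iterable[str] | None = None,
                      valid_b: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a two-column ortholog TSV and enforce one-to-one pairing.

    Pairs referencing genes outside ``valid_a``/``valid_b`` (when given)
    are dropped, as are all pairs involving an id that appears more than
    once (one-to-many orthology carries no gene-to-gene signal here).
    Dropped counts are logged and stored in ``result.attrs`` under
    ``n_dropped_unknown`` and ``n_dropped_multi``.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise CrossCnaError(f"{path}: ortholog map needs two id columns")
    df = df.iloc[:, :2].copy()
    df.columns = ["gene_a", "gene_b"]
    if df.isna().any().any():
        i = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0])
        raise CrossCnaError(f"{path}: missing id at line {_line(df.index[i])}")
    n0 = len(df)
    if valid_a is not None:
        df = df[df["gene_a"].isin(set(valid_a))]
    if valid_b is not None:
        df = df[df["gene_b"].isin(set(valid_b))]
    n_unknown = n0 - len(df)
    multi = df["gene_a"].duplicated(keep=False) | df["gene_b"].duplicated(keep=False)
    n_multi = int(multi.sum())
    df = df[~multi].reset_index(drop=True)
    if n_unknown:
        logger.warning("%s: dropped %d ortholog pairs with unknown gene ids", path, n_unknown)
    if n_multi:
        logger.warning("%s: dropped %d one-to-many ortholog pairs", path, n_multi)
    df.attrs["n_dropped_unknown"] = n_unknown
    df.attrs["n_dropped_multi"] = n_multi
    return df


def write_ortholog_map(omap: pd.DataFrame, path: str | Path) -> None:
    omap[["gene_a", "gene_b"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------

DE_Q_THRESHOLD = 0.1  # FDR-corrected q below which a gene counts as DE


def read_de_table(path: str | Path, q_threshold: float = DE_Q_THRESHOLD) -> pd.DataFrame:
    """Read a differential-expression table.

    Required columns: gene_id, log2_fold_change, p_value, fdr_q.  The
    ``direction`` (up/down/ns) is derived from the fold-change sign and
    ``q_threshold``; an existing direction column must agree with the rule.
    """
    df = _read_tsv(path)
    _require(df, ["gene_id", "log2_fold_change", "p_value", "fdr_q"], path)
    lfc = _numeric(df, "log2_fold_change", path)
    p = _numeric(df, "p_value", path)
    q = _numeric(df, "fdr_q", path)
    direction = np.where(
        (q < q_threshold) & (lfc > 0), "up",
        np.where((q < q_threshold) & (lfc < 0), "down", "ns"),
    )
    if "direction" in df.columns:
        mismatch = df["direction"].to_numpy() != direction
        if mismatch.any():
            i = int(np.flatnonzero(mismatch)[0])
            raise CrossCnaError(
                f"{path}: direction {df['direction'].iloc[i]!r} inconsistent with "
                f"fold change/q at line {_line(df.index[i])}"
            )
    return pd.DataFrame({
        "gene_id": df["gene_id"].to_numpy(),
        "log2_fold_change": lfc,
        "p_value": p,
        "fdr_q": q,
        "direction": direction,
    })


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, na_rep=NA)


# ---------------------------------------------------------------------------
# Ct table
# ---------------------------------------------------------------------------

def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table (sample_id, group, gene_id, ct_target,
    ct_housekeeping).  Ct values must be positive when present; missing
    values ('.') are allowed and handled downstream."""
    df = _read_tsv(path)
    _require(df, ["sample_id", "group", "gene_id", "ct_target", "ct_housekeeping"], path)
    ct_t = _numeric(df, "ct_target", path)
    ct_h = _numeric(df, "ct_housekeeping", path)
    for name, arr in (("ct_target", ct_t), ("ct_housekeeping", ct_h)):
        bad = np.isfinite(arr) & (arr <= 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CrossCnaError(
                f"{path}: non-positive {name} at line {_line(df.index[i])}"
            )
    return pd.DataFrame({
        "sample_id": df["sample_id"].to_numpy(),
        "group": df["group"].to_numpy(),
        "gene_id": df["gene_id"].to_numpy(),
        "ct_target": ct_t,
        "ct_housekeeping": ct_h,
    })


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, sep="\t", index=False, na_rep=NA)


# ---------------------------------------------------------------------------
# frequency tracks and truth files (pipeline exchange formats)
# ---------------------------------------------------------------------------

def write_frequency_track(track: FrequencyTrack, path: str | Path) -> None:
    out = track.table.reset_index()
    out.insert(0, "group", track.group)
    out.insert(1, "n_samples", track.n_samples)
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_frequency_track(path: str | Path) -> FrequencyTrack:
    df = _read_tsv(path)
    _require(df, ["group", "n_samples", "gene_id", "chromosome", "start", "end",
                  "freq_gain", "freq_loss"], path)
    table = pd.DataFrame({
        "gene_id": df["gene_id"].to_numpy(),
        "chromosome": df["chromosome"].to_numpy(),
        "start": [int(x) for x in _numeric(df, "start", path, int)],
        "end": [int(x) for x in _numeric(df, "end", path, int)],
        "freq_gain": _numeric(df, "freq_gain", path),
        "freq_loss": _numeric(df, "freq_loss", path),
    }).set_index("gene_id")
    track = FrequencyTrack(
        group=str(df["group"].iloc[0]),
        n_samples=int(df["n_samples"].iloc[0]),
        table=table,
    )
    track.validate()
    return track


def write_truth_table(truth, path: str | Path) -> None:
    """Write planted-CNA ground truth: one row per spec with its carriers."""
    rows = []
    for s in truth.specs:
        rows.append({
            "spec_id": s.spec_id,
            "chromosome": s.chromosome,
            "start": s.start,
            "end": s.end,
            "direction": s.direction,
            "effect": s.effect,
            "penetrance": s.penetrance,
            "group": s.group,
            "carriers": ",".join(truth.carriers[s.spec_id]),
        })
    pd.DataFrame(rows, columns=["spec_id", "chromosome", "start", "end", "direction",
                                "effect", "penetrance", "group", "carriers"]
                 ).to_csv(path, sep="\t", index=False, na_rep=NA)
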