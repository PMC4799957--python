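"""CNA-expression concordance and its permutation null.

Differentially expressed genes are cross-tabulated against cohort-level
CNA labels (a gene is "gain" when gained in at least 15% of samples and
gains outnumber losses; symmetrically for "loss"; ties are neutral).  The
observed percentage of DE genes inside direction-matched CNA labels is
assessed against a null built by drawing equally sized gene sets uniformly
without replacement from the expressed universe, summarized as a z-score
(sample sd, n-1 denominator) plus a two-sided add-one empirical p-value
p = (1 + #{|null - mean| >= |obs - mean|}) / (n_perm + 1), which never
returns zero.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .types import (
    ConcordanceSummary,
    CrossCnaError,
    FrequencyTrack,
    PermutationResult,
)
import logging

logger = logging.getLogger(__name__)


def classify_genes_by_cna(freq_track: FrequencyTrack,
                          freq_threshold: float = 0.15) -> pd.Series:
    """Cohort-level per-gene CNA label in {gain, loss, neutral}."""
    t = freq_track.table
    gain = (t["freq_gain"] >= freq_threshold) & (t["freq_gain"] > t["freq_loss"])
    loss = (t["freq_loss"] >= freq_threshold) & (t["freq_loss"] > t["freq_gain"])
    labels = pd.Series("neutral", index=t.index, dtype=object)
    labels[gain] = "gain"
    labels[loss] = "loss"
    labels.name = "cna_label"
    return labels


def concordance_table(de: pd.DataFrame, cna_labels: pd.Series,
                      conserved_genes: set | None = None) -> ConcordanceSummary:
    """Percent of DE genes (by direction) carrying each CNA label.

    ``de`` needs columns gene_id and direction (up/down/ns).  DE genes
    absent from the label universe are counted and excluded with a warning.
    When ``conserved_genes`` is given, conserved_gain/conserved_loss rows
    restrict each label to genes in that set.  A direction with no genes
    yields NaN percentages (missing, not 0).
    """
    universe = set(cna_labels.index)
    n_unknown = 0
    sets: dict[str, list[str]] = {}
    for direction in ("up", "down"):
        genes = list(de.loc[de["direction"] == direction, "gene_id"])
        known = [g for g in genes if g in universe]
        n_unknown += len(genes) - len(known)
        sets[direction] = known
    if n_unknown:
        logger.warning("%d DE genes absent from the CNA label universe; excluded",
                       n_unknown)

    row_labels = ["gain", "loss", "neutral"]
    if conserved_genes is not None:
        row_labels += ["conserved_gain", "conserved_loss"]
    counts = pd.DataFrame(0, index=row_labels, columns=["up", "down"], dtype=int)
    pcts = pd.DataFrame(np.nan, index=row_labels, columns=["up_pct", "down_pct"])
    for direction in ("up", "down"):
        genes = sets[direction]
        n = len(genes)
        labels = cna_labels.loc[genes]
        counts.loc["gain", direction] = int((labels == "gain").sum())
        counts.loc["loss", direction] = int((labels == "loss").sum())
        counts.loc["neutral", direction] = int((labels == "neutral").sum())
        if conserved_genes is not None:
            in_cons = labels.index.isin(conserved_genes)
            counts.loc["conserved_gain", direction] = int(((labels == "gain") & in_cons).sum())
            counts.loc["conserved_loss", direction] = int(((labels == "loss") & in_cons).sum())
        if n > 0:
            pcts[f"{direction}_pct"] = 100.0 * counts[direction] / n
    return ConcordanceSummary(
        table=pcts,
        counts=counts,
        n_up=len(sets["up"]),
        n_down=len(sets["down"]),
        n_universe=len(universe),
        n_unknown=n_unknown,
    )


def permutation_test(cna_labels: pd.Series, set_size: int, target_label: str,
                     observed_pct: float, n_perm: int = 1000,
                     seed: int = 0) -> PermutationResult:
    """Null distribution of the percent of a random gene set carrying
    ``target_label``.

    Each permutation draws ``set_size`` genes uniformly without replacement
    from the full label universe.  The z-score uses the sample sd of the
    null percentages; when the null sd is zero the z-score is NaN while
    the empirical p-value remains valid.
    """
    n_universe = len(cna_labels)
    if not 1 <= set_size <= n_universe:
        raise CrossCnaError("set_size must be in [1, universe size]")
    if n_perm < 1:
        raise CrossCnaError("n_perm must be >= 1")
    flags = (cna_labels == target_label).to_numpy()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n_universe, size=set_size, replace=False)
        null[i] = 100.0 * flags[idx].mean()
    mean = null.mean()
    sd = null.std(ddof=1) if n_perm > 1 else 0.0
    z = float((observed_pct - mean) / sd) if sd > 0 else float("nan")
    exceed = int((np.abs(null - mean) >= abs(observed_pct - mean) - 1e-12).sum())
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        observed_pct=float(observed_pct),
        null_pcts=null,
        z_score=z,
        empirical_p=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def write_concordance(summary: ConcordanceSummary, path) -> None:
    out = summary.table.copy()
    out.index.name = "cna_type"
    out.to_csv(path, sep="\t", na_rep=".")


def write_permutation(results: dict[str, PermutationResult], path) -> None:
    payload = {}
    for name, r in results.items():
        payload[name] = {
            "observed_pct": r.observed_pct,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
            "z_score": None if np.isnan(r.z_score) else r.z_score,
            "empirical_p": r.empirical_p,
            "n_perm": r.n_perm,
            "seed": r.seed,
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def plot_null_histogram(result: PermutationResult, path, title: str = "") -> None:
    """Histogram of the permutation null with the observed value arrowed."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.null_pcts, bins=30, color="steelblue", edgecolor="white")
    ax.axvline(result.observed_pct, color="crimson")
    ax.annotate("observed", xy=(result.observed_pct, ax.get_ylim()[1] * 0.9),
                color="crimson", rotation=90, va="top")
    ax.set_xlabel("% of gene set in CNA label")
    ax.set_ylabel("permutations")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
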