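"""Synthetic genomes, aCGH-style cohorts, expression tables and qPCR plates.

Everything downstream of the wet lab is exercised on data produced here:
two genomes linked by a one-to-one ortholog map, per-sample probe log-ratio
profiles with planted gain/loss segments at controlled within-group
frequencies, a differential-expression table with controlled fractions of
up/down genes inside gain/loss-called genes, and Ct tables with planted
fold changes.  Every operation takes one explicit integer seed and is fully
deterministic; planted truth is returned alongside the data.

The noise model is deliberately simple: i.i.d. Gaussian probe noise on the
log2 scale, additive effects where planted regions overlap, no intensity
waves, purity or subclonality.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    Chromosome,
    CohortTruth,
    CrossCnaError,
    Genome,
    GenomePair,
    PlantedCnaSpec,
    ProbeProfile,
)

_MIN_GENE_GAP = 5_000  # bp between adjacent genes
_GENE_LEN_RANGE = (10_000, 80_000)  # bp
_CHROM_LEN_RANGE = (40_000_000, 60_000_000)  # bp


def _make_genome(rng: np.random.Generator, label: str, n_chrom: int,
                 genes_per_chrom: int) -> Genome:
    chroms: list[Chromosome] = []
    rows = []
    for ci in range(1, n_chrom + 1):
        name = f"chr{label}{ci}"
        length = int(rng.integers(*_CHROM_LEN_RANGE))
        lens = rng.integers(*_GENE_LEN_RANGE, size=genes_per_chrom)
        occupied = int(lens.sum()) + (genes_per_chrom + 1) * _MIN_GENE_GAP
        if occupied > length:
            raise CrossCnaError(
                f"cannot fit {genes_per_chrom} genes on {name} ({length} bp)"
            )
        # distribute the leftover space over the gaps, proportionally to
        # uniform weights, so gene placement is uniform with a minimum gap
        slack = length - occupied
        w = rng.random(genes_per_chrom + 1)
        extra = np.floor(w / w.sum() * slack).astype(int)
        pos = 0
        for gi in range(genes_per_chrom):
            pos += _MIN_GENE_GAP + int(extra[gi])
            start = pos
            end = start + int(lens[gi])
            rows.append(
                {
                    "gene_id": f"g{label}_{ci}_{gi:04d}",
                    "chromosome": name,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            pos = end
        chroms.append(Chromosome(name, length))
    genes = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    genes = genes.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
    return Genome(chroms, genes)


def make_genome_pair(seed: int, n_chrom: int, genes_per_chrom: int,
                     ortholog_rate: float) -> GenomePair:
    """Build two synthetic genomes plus a one-to-one ortholog map.

    Parameters
    ----------
    seed : int
        Seed for all randomness in this call.
    n_chrom : int
        Chromosomes per genome (>= 1).
    genes_per_chrom : int
        Non-overlapping genes per chromosome (>= 1).
    ortholog_rate : float
        Fraction of genes (of the smaller gene set) paired one-to-one.
        Pairs are drawn uniformly without replacement on both sides and
        shuffled, so genomic order differs between the two species.
    """
    if n_chrom < 1 or genes_per_chrom < 1:
        raise CrossCnaError("n_chrom and genes_per_chrom must be >= 1")
    if not 0.0 <= ortholog_rate <= 1.0:
        raise CrossCnaError("ortholog_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genome_a = _make_genome(rng, "A", n_chrom, genes_per_chrom)
    genome_b = _make_genome(rng, "B", n_chrom, genes_per_chrom)
    n_pairs = int(round(ortholog_rate * min(len(genome_a.genes), len(genome_b.genes))))
    ids_a = rng.choice(genome_a.genes["gene_id"].to_numpy(), size=n_pairs, replace=False)
    ids_b = rng.choice(genome_b.genes["gene_id"].to_numpy(), size=n_pairs, replace=False)
    omap = pd.DataFrame({"gene_a": ids_a, "gene_b": ids_b})
    pair = GenomePair(genome_a, genome_b, omap)
    pair.validate()
    return pair


def _resolve_groups(specs: Sequence[PlantedCnaSpec],
                    n_samples: int | Mapping[str, int]) -> dict[str, int]:
    if isinstance(n_samples, Mapping):
        sizes = {str(g): int(n) for g, n in n_samples.items()}
    else:
        groups = sorted({s.group for s in specs}) or ["all"]
        sizes = {g: int(n_samples) for g in groups}
    for g, n in sizes.items():
        if n < 1:
            raise CrossCnaError(f"group {g!r} needs at least one sample")
    missing = {s.group for s in specs} - set(sizes)
    if missing:
        raise CrossCnaError(f"specs reference groups without samples: {sorted(missing)}")
    return sizes


def simulate_cohort(genome: Genome, specs: Sequence[PlantedCnaSpec],
                    n_samples: int | Mapping[str, int], probe_spacing: int,
                    noise_sd: float, seed: int
                    ) -> tuple[list[ProbeProfile], CohortTruth]:
    """Simulate per-sample probe profiles with planted CNAs.

    Each sample's probe value is the sum of the effects of the planted CNAs
    it carries that cover the probe, plus Gaussian(0, noise_sd).  Carriers
    of each spec are Bernoulli(penetrance) draws per sample of the spec's
    group (or an exact random subset when the spec fixes ``n_carriers``).
    Overlapping planted regions add their effects.

    ``n_samples`` is the per-group cohort size: either one integer applied
    to every group named by the specs, or a mapping group -> size (which may
    include alteration-free groups).

    Returns the profiles (sample ids ``<group>_<k>``) and the exact truth.
    """
    if probe_spacing <= 0:
        raise CrossCnaError("probe_spacing must be > 0")
    if noise_sd < 0:
        raise CrossCnaError("noise_sd must be >= 0")
    lengths = {c.name: c.length for c in genome.chromosomes}
    for s in specs:
        if s.chromosome not in lengths:
            raise CrossCnaError(f"spec {s.spec_id}: unknown chromosome {s.chromosome!r}")
        if s.start < 0 or s.end > lengths[s.chromosome]:
            raise CrossCnaError(f"spec {s.spec_id}: region outside chromosome")
    ids = [s.spec_id for s in specs]
    if len(set(ids)) != len(ids):
        raise CrossCnaError("duplicate spec_id among planted specs")

    rng = np.random.default_rng(seed)
    sizes = _resolve_groups(specs, n_samples)
    sample_groups: dict[str, str] = {}
    for g in sorted(sizes):
        for k in range(sizes[g]):
            sample_groups[f"{g}_{k:02d}"] = g
    samples = list(sample_groups)

    # carrier draws, one pass per spec over its group's samples
    carriers: dict[str, list[str]] = {}
    for s in specs:
        members = [x for x in samples if sample_groups[x] == s.group]
        if s.n_carriers is not None:
            if not 0 <= s.n_carriers <= len(members):
                raise CrossCnaError(f"spec {s.spec_id}: n_carriers out of range")
            chosen = sorted(rng.choice(members, size=s.n_carriers, replace=False))
        else:
            draws = rng.random(len(members)) < s.penetrance
            chosen = [m for m, d in zip(members, draws) if d]
        carriers[s.spec_id] = chosen

    # probe grid, shared by all samples
    grid = []
    for c in sorted(genome.chromosomes, key=lambda c: c.name):
        pos = np.arange(probe_spacing // 2 + 1, c.length + 1, probe_spacing)
        grid.append(pd.DataFrame({
            "probe_id": [f"p_{c.name}_{k}" for k in range(len(pos))],
            "chromosome": c.name,
            "position": pos,
        }))
    grid = pd.concat(grid, ignore_index=True)
    pos0 = grid["position"].to_numpy() - 1  # internal 0-based coordinate
    chrom_arr = grid["chromosome"].to_numpy()

    profiles = []
    for sample in samples:
        values = np.zeros(len(grid))
        for s in specs:
            if sample in carriers[s.spec_id]:
                mask = (chrom_arr == s.chromosome) & (pos0 >= s.start) & (pos0 < s.end)
                values[mask] += s.effect
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=len(grid))
        probes = grid.copy()
        probes["log2_ratio"] = values
        prof = ProbeProfile(sample, probes)
        prof.validate()
        profiles.append(prof)

    truth = CohortTruth(
        specs=list(specs),
        carriers=carriers,
        gene_truth=_gene_truth(genome.genes, specs, carriers, sizes),
        group_sizes=sizes,
    )
    return profiles, truth


def _gene_truth(genes: pd.DataFrame, specs: Sequence[PlantedCnaSpec],
                carriers: dict[str, list[str]], sizes: dict[str, int]) -> pd.DataFrame:
    rows = []
    for group in sorted(sizes):
        n = sizes[group]
        for _, g in genes.iterrows():
            hit: dict[str, set[str]] = {"gain": set(), "loss": set()}
            for s in specs:
                if s.group != group or s.chromosome != g["chromosome"]:
                    continue
                if s.start < g["end"] and s.end > g["start"]:
                    hit[s.direction].update(carriers[s.spec_id])
            rows.append({
                "gene_id": g["gene_id"],
                "group": group,
                "freq_gain": len(hit["gain"]) / n,
                "freq_loss": len(hit["loss"]) / n,
            })
    return pd.DataFrame(rows, columns=["gene_id", "group", "freq_gain", "freq_loss"])


def simulate_expression(gene_calls: Mapping[str, str] | pd.Series,
                        n_up: int, n_down: int, frac_up_in_gain: float,
                        frac_down_in_loss: float, seed: int) -> pd.DataFrame:
    """Build a DE table with controlled CNA concordance.

    ``gene_calls`` maps every expressed gene to its cohort-level CNA label
    (gain/loss/neutral).  ``round(frac_up_in_gain * n_up)`` up-regulated
    genes are drawn from gain-labeled genes (nearest-integer rounding); the
    remaining up genes come from neutral genes, and symmetrically for
    down/loss.  All other genes are emitted as not significant, so the
    returned table is the full expressed universe.

    Columns: gene_id, log2_fold_change, p_value, fdr_q, direction.
    """
    calls = pd.Series(dict(gene_calls)) if not isinstance(gene_calls, pd.Series) else gene_calls
    if n_up < 0 or n_down < 0:
        raise CrossCnaError("n_up and n_down must be >= 0")
    for frac, name in ((frac_up_in_gain, "frac_up_in_gain"), (frac_down_in_loss, "frac_down_in_loss")):
        if not 0.0 <= frac <= 1.0:
            raise CrossCnaError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pools = {lab: sorted(calls.index[calls == lab]) for lab in ("gain", "loss", "neutral")}

    k_up = int(round(frac_up_in_gain * n_up))
    k_down = int(round(frac_down_in_loss * n_down))
    need = [("gain", k_up), ("loss", k_down), ("neutral", (n_up - k_up) + (n_down - k_down))]
    for stratum, k in need:
        if k > len(pools[stratum]):
            raise CrossCnaError(
                f"not enough {stratum}-labeled genes: need {k}, have {len(pools[stratum])}"
            )

    up = list(rng.choice(pools["gain"], size=k_up, replace=False)) if k_up else []
    down = list(rng.choice(pools["loss"], size=k_down, replace=False)) if k_down else []
    rest = rng.choice(pools["neutral"], size=(n_up - k_up) + (n_down - k_down), replace=False)
    up += list(rest[: n_up - k_up])
    down += list(rest[n_up - k_up:])

    up_set, down_set = set(up), set(down)
    rows = []
    for gene in calls.index:
        if gene in up_set:
            lfc = float(rng.uniform(0.5, 3.0))
            q = float(rng.uniform(0.0, 0.09))
            direction = "up"
        elif gene in down_set:
            lfc = -float(rng.uniform(0.5, 3.0))
            q = float(rng.uniform(0.0, 0.09))
            direction = "down"
        else:
            lfc = float(rng.normal(0.0, 0.2))
            q = float(rng.uniform(0.1, 1.0))
            direction = "ns"
        rows.append({
            "gene_id": gene,
            "log2_fold_change": lfc,
            "p_value": q / 2.0,
            "fdr_q": q,
            "direction": direction,
        })
    return pd.DataFrame(rows, columns=["gene_id", "log2_fold_change", "p_value", "fdr_q", "direction"])


def simulate_qpcr(n_control: int, n_treated: int,
                  fold_changes: Mapping[str, float], ct_noise_sd: float,
                  seed: int) -> pd.DataFrame:
    """Simulate a qPCR Ct table with planted fold changes.

    The housekeeping gene has constant expected Ct in both groups; each
    target gene's treated-group Ct is shifted by ``-log2(fold_change)``
    relative to its control baseline.  Gaussian(0, ct_noise_sd) cycle noise
    is added to every measured Ct.

    Columns: sample_id, group, gene_id, ct_target, ct_housekeeping.
    """
    if n_control < 1 or n_treated < 1:
        raise CrossCnaError("both groups need at least one sample")
    if ct_noise_sd < 0:
        raise CrossCnaError("ct_noise_sd must be >= 0")
    for gene, fc in fold_changes.items():
        if not fc > 0:
            raise CrossCnaError(f"fold change for {gene!r} must be > 0")
    rng = np.random.default_rng(seed)
    hk_base = 20.0
    genes = sorted(fold_changes)
    target_base = {g: 25.0 + float(rng.uniform(-3.0, 3.0)) for g in genes}
    samples = [(f"ctrl_{k:02d}", "control") for k in range(n_control)]
    samples += [(f"trt_{k:02d}", "treated") for k in range(n_treated)]
    rows = []
    for sample, group in samples:
        for g in genes:
            shift = -np.log2(fold_changes[g]) if group == "treated" else 0.0
            ct_t = target_base[g] + shift
            ct_h = hk_base
            if ct_noise_sd > 0:
                ct_t += float(rng.normal(0.0, ct_noise_sd))
                ct_h += float(rng.normal(0.0, ct_noise_sd))
            rows.append({
                "sample_id": sample, "group": group, "gene_id": g,
                "ct_target": ct_t, "ct_housekeeping": ct_h,
            })
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "ct_target", "ct_housekeeping"])
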