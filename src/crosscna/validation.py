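"""Planted-truth validation experiments for the whole pipeline.

Each function here builds synthetic inputs with known ground truth, runs
the corresponding pipeline stage(s), and measures recovery against an
independent oracle (exhaustive scans, closed forms, brute-force set
logic).  They back both the acceptance test suite and
``scripts/acceptance.py``; problem sizes are chosen to finish in minutes
on one CPU while keeping every planted signal well inside the detectable
regime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .concordance import classify_genes_by_cna, concordance_table, permutation_test
from .conservation import (
    conserved_cna_genes,
    cross_species_segment_stats,
    remap_orthologs,
)
from .group_cna import frequency_track, gene_copy_matrix, group_specific_segments
from .qpcr import bh_qvalues, ddct_fold_change, ttest_fdr
from .segmentation import SegmentationConfig, cbs_segment, call_segments
from .synthetic_data import (
    make_genome_pair,
    simulate_cohort,
    simulate_expression,
    simulate_qpcr,
)
from .types import (
    Chromosome,
    FrequencyTrack,
    Genome,
    GroupSpecificSegment,
    PlantedCnaSpec,
    ProbeProfile,
)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def dense_genome(n_chrom: int = 2, genes_per_chrom: int = 50,
                 gene_len: int = 150_000, gap: int = 50_000,
                 label: str = "V") -> Genome:
    """A genome with genes on a regular grid, so planted regions can be
    aligned to cover whole gene blocks (used by the round-trip checks)."""
    chroms, rows = [], []
    length = genes_per_chrom * (gene_len + gap) + gap
    for ci in range(1, n_chrom + 1):
        name = f"chr{label}{ci}"
        chroms.append(Chromosome(name, length))
        for gi in range(genes_per_chrom):
            start = gap + gi * (gene_len + gap)
            rows.append({"gene_id": f"g{label}_{ci}_{gi:04d}", "chromosome": name,
                         "start": start, "end": start + gene_len, "strand": "+"})
    return Genome(chroms, pd.DataFrame(rows))


def gene_block_region(genome: Genome, chrom: str, first: int, last: int,
                      ) -> tuple[int, int]:
    """(start, end) spanning genes [first, last] of a chromosome, inclusive."""
    sub = genome.genes[genome.genes["chromosome"] == chrom].reset_index(drop=True)
    return int(sub["start"].iloc[first]), int(sub["end"].iloc[last])


def exhaustive_t_argmax(x: np.ndarray) -> int:
    """Split index b maximizing the pooled two-sample |t| of x[:b] vs x[b:].

    Brute-force single-change-point oracle (closed form via prefix sums);
    b ranges over [2, n-2] so both sides have at least two points.
    """
    n = len(x)
    s = np.cumsum(x)
    s2 = np.cumsum(x ** 2)
    best_b, best_t = -1, -np.inf
    for b in range(2, n - 1):
        n1, n2 = b, n - b
        m1 = s[b - 1] / n1
        m2 = (s[-1] - s[b - 1]) / n2
        ss1 = s2[b - 1] - n1 * m1 ** 2
        ss2 = (s2[-1] - s2[b - 1]) - n2 * m2 ** 2
        sp2 = (ss1 + ss2) / (n - 2)
        if sp2 <= 0:
            continue
        t = abs(m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        if t > best_t:
            best_t, best_b = t, b
    return best_b


def _probe_profile(x: np.ndarray, chrom: str = "chr1", spacing: int = 1000,
                   sample: str = "s") -> ProbeProfile:
    pos = np.arange(1, len(x) + 1) * spacing
    return ProbeProfile(sample, pd.DataFrame({
        "probe_id": [f"p{k}" for k in range(len(x))],
        "chromosome": chrom, "position": pos, "log2_ratio": x,
    }))


def _breakpoints(segments) -> list[int]:
    """Probe-index breakpoints of a single-chromosome segmentation."""
    cuts, total = [], 0
    for seg in segments[:-1]:
        total += seg.n_probes
        cuts.append(total)
    return cuts


# ---------------------------------------------------------------------------
# 1. CBS vs exhaustive single-change-point scan
# ---------------------------------------------------------------------------

def breakpoint_recovery_experiment(seed: int, n_chrom: int = 100,
                                   n_probes: int = 200, shift: float = 1.0,
                                   noise_sd: float = 0.25) -> dict:
    """Plant one change point per chromosome and score CBS against the
    exhaustive max-t scan and against the truth (+-3 probes)."""
    rng = np.random.default_rng(seed)
    cfg = SegmentationConfig(alpha=0.01, n_perm_ref=1000, min_probes=2,
                             seed=int(rng.integers(2 ** 31)))
    n_match, n_close = 0, 0
    for _ in range(n_chrom):
        cp = int(rng.integers(50, 151))
        x = rng.normal(0.0, noise_sd, n_probes)
        x[cp:] += shift
        segs = cbs_segment(_probe_profile(x), cfg)
        cuts = _breakpoints(segs)
        oracle = exhaustive_t_argmax(x)
        if cuts:
            nearest = min(cuts, key=lambda c: abs(c - cp))
            if nearest == oracle:
                n_match += 1
            if abs(nearest - cp) <= 3:
                n_close += 1
    return {
        "match_exhaustive_pct": 100.0 * n_match / n_chrom,
        "within3_pct": 100.0 * n_close / n_chrom,
        "n": n_chrom,
    }


# ---------------------------------------------------------------------------
# 2. noiseless simulate -> segment -> call -> frequency round trip
# ---------------------------------------------------------------------------

def noiseless_roundtrip_experiment(seed: int) -> dict:
    """On a noiseless cohort, every planted region must come back with exact
    probe-resolution boundaries, exact means, and exact frequencies."""
    genome = dense_genome()
    r_gain = gene_block_region(genome, "chrV1", 10, 24)
    r_loss = gene_block_region(genome, "chrV2", 30, 44)
    specs = [
        PlantedCnaSpec("chrV1", *r_gain, "gain", 0.8, 0.5, "tumor",
                       n_carriers=9, spec_id="gain1"),
        PlantedCnaSpec("chrV2", *r_loss, "loss", -0.7, 0.5, "tumor",
                       n_carriers=7, spec_id="loss1"),
    ]
    spacing = 50_000
    profiles, truth = simulate_cohort(genome, specs, {"tumor": 18}, spacing,
                                      noise_sd=0.0, seed=seed)
    cfg = SegmentationConfig(alpha=0.01, n_perm_ref=500, seed=seed)
    all_segments = []
    n_regions = n_exact = 0
    for prof in profiles:
        segs = call_segments(cbs_segment(prof, cfg), 0.2, -0.2)
        all_segments.extend(segs)
        for spec in specs:
            if prof.sample_id not in truth.carriers[spec.spec_id]:
                continue
            n_regions += 1
            pos = prof.probes.loc[prof.probes["chromosome"] == spec.chromosome,
                                  "position"].to_numpy()
            in_region = (pos - 1 >= spec.start) & (pos - 1 < spec.end)
            first, last = pos[in_region][0], pos[in_region][-1]
            hits = [s for s in segs if s.chromosome == spec.chromosome
                    and s.start == first - 1 and s.end == last
                    and abs(s.mean_log2 - spec.effect) < 1e-9
                    and s.call == spec.direction]
            n_exact += bool(hits)
    matrix = gene_copy_matrix(all_segments, genome.genes)
    track = frequency_track(matrix, [p.sample_id for p in profiles], "tumor")
    truth_t = truth.gene_truth.set_index("gene_id")
    max_err = 0.0
    for spec in specs:
        sub = genome.genes[(genome.genes["chromosome"] == spec.chromosome)
                           & (genome.genes["start"] >= spec.start)
                           & (genome.genes["end"] <= spec.end)]
        col = f"freq_{spec.direction}"
        for gid in sub["gene_id"]:
            err = abs(track.table.at[gid, col] - truth_t.at[gid, col])
            max_err = max(max_err, float(err))
    return {
        "boundary_exact_pct": 100.0 * n_exact / n_regions,
        "frequency_max_abs_error": max_err,
        "n": n_regions,
    }


# ---------------------------------------------------------------------------
# 3. group-specific detection under the two-part rule
# ---------------------------------------------------------------------------

def group_detection_experiment(seed: int) -> dict:
    """Three planted regions probe the detection rule: a true tumor-specific
    gain (9/18 vs 0), the same gain at 2/18 (fails the 15% rule), and a
    gain at equal frequency in both groups (fails the gene-p rule)."""
    genome = dense_genome()
    r_true = gene_block_region(genome, "chrV1", 5, 18)
    r_rare = gene_block_region(genome, "chrV2", 2, 12)
    r_shared = gene_block_region(genome, "chrV2", 30, 42)
    specs = [
        PlantedCnaSpec("chrV1", *r_true, "gain", 0.8, 0.5, "tumor",
                       n_carriers=9, spec_id="true"),
        PlantedCnaSpec("chrV2", *r_rare, "gain", 0.8, 2 / 18, "tumor",
                       n_carriers=2, spec_id="rare"),
        PlantedCnaSpec("chrV2", *r_shared, "gain", 0.8, 0.5, "tumor",
                       n_carriers=9, spec_id="shared_t"),
        PlantedCnaSpec("chrV2", *r_shared, "gain", 0.8, 0.5, "nontumor",
                       n_carriers=9, spec_id="shared_n"),
    ]
    profiles, _ = simulate_cohort(genome, specs, {"tumor": 18, "nontumor": 18},
                                  probe_spacing=50_000, noise_sd=0.2, seed=seed)
    cfg = SegmentationConfig(alpha=0.01, n_perm_ref=1000, seed=seed)
    segments = []
    for prof in profiles:
        segments.extend(call_segments(cbs_segment(prof, cfg), 0.2, -0.2))
    matrix = gene_copy_matrix(segments, genome.genes)
    tumors = [p.sample_id for p in profiles if p.sample_id.startswith("tumor")]
    nontumors = [p.sample_id for p in profiles if p.sample_id.startswith("nontumor")]
    track = frequency_track(matrix, tumors, "tumor")
    regions = group_specific_segments(track, matrix, tumors, nontumors,
                                      freq_threshold=0.15, p_threshold=0.05)

    def detected(region: tuple[int, int], chrom: str) -> bool:
        return any(r.chromosome == chrom and r.direction == "gain"
                   and r.start < region[1] and r.end > region[0]
                   for r in regions)

    return {
        "true_region_detected": float(detected(r_true, "chrV1")),
        "rare_region_detected": float(detected(r_rare, "chrV2")),
        "shared_region_detected": float(detected(r_shared, "chrV2")),
        "n": len(regions),
    }


# ---------------------------------------------------------------------------
# 4. permutation-null calibration
# ---------------------------------------------------------------------------

def permutation_calibration_experiment(seed: int, n_universe: int = 17_000,
                                       n_label: int = 3000, set_size: int = 3063,
                                       n_perm: int = 10_000) -> dict:
    """Null mean vs the hypergeometric closed form, and uniformity of the
    empirical p-value under a random observed set."""
    labels = pd.Series(["gain"] * n_label + ["neutral"] * (n_universe - n_label),
                       index=[f"g{k}" for k in range(n_universe)])
    res = permutation_test(labels, set_size, "gain",
                           observed_pct=100.0 * n_label / n_universe,
                           n_perm=n_perm, seed=seed)
    hyper_mean = 100.0 * n_label / n_universe
    # variance of the sample count is hypergeometric; scale to a percentage
    var_count = (set_size * (n_label / n_universe) * (1 - n_label / n_universe)
                 * (n_universe - set_size) / (n_universe - 1))
    hyper_sd = 100.0 * np.sqrt(var_count) / set_size
    mc_se = res.null_sd / np.sqrt(n_perm)

    # calibration: p uniform when the observed set is itself a null draw
    rng = np.random.default_rng(seed + 1)
    # the universe must be large enough that the overlap percentage is not
    # too discrete for a continuous-uniform comparison
    n_small, k_small, m_small, runs, perms = 3000, 600, 300, 500, 400
    small = pd.Series(["gain"] * k_small + ["neutral"] * (n_small - k_small),
                      index=[f"s{k}" for k in range(n_small)])
    flags = (small == "gain").to_numpy()
    pvals = np.empty(runs)
    for r in range(runs):
        idx = rng.choice(n_small, size=m_small, replace=False)
        obs = 100.0 * flags[idx].mean()
        pvals[r] = permutation_test(small, m_small, "gain", obs, perms,
                                    seed=int(rng.integers(2 ** 31))).empirical_p
    ks = float(sps.kstest(pvals, "uniform").statistic)
    return {
        "null_mean_pct": res.null_mean,
        "hypergeometric_mean_pct": hyper_mean,
        "null_sd_pct": res.null_sd,
        "hypergeometric_sd_pct": float(hyper_sd),
        "mean_abs_deviation_in_mc_se": float(abs(res.null_mean - hyper_mean) / mc_se),
        "p_uniformity_ks": ks,
        "n": n_perm,
    }


# ---------------------------------------------------------------------------
# 5. concordance recovery at the published design point
# ---------------------------------------------------------------------------

def concordance_recovery_experiment(seed: int, n_universe: int = 17_000,
                                    n_gain: int = 3000, n_loss: int = 3000,
                                    n_up: int = 3000, n_down: int = 2400,
                                    frac: float = 0.52, n_perm: int = 1000) -> dict:
    """Plant DE/CNA concordance at 52% and recover it from the table plus
    the permutation z-score."""
    ids = [f"g{k}" for k in range(n_universe)]
    labels = pd.Series(["gain"] * n_gain + ["loss"] * n_loss
                       + ["neutral"] * (n_universe - n_gain - n_loss), index=ids)
    de = simulate_expression(labels, n_up=n_up, n_down=n_down,
                             frac_up_in_gain=frac, frac_down_in_loss=frac,
                             seed=seed)
    summary = concordance_table(de, labels)
    up_gain = float(summary.table.at["gain", "up_pct"])
    down_loss = float(summary.table.at["loss", "down_pct"])
    res = permutation_test(labels, summary.n_up, "gain", up_gain,
                           n_perm=n_perm, seed=seed + 1)
    return {
        "up_in_gain_pct": up_gain,
        "down_in_loss_pct": down_loss,
        "planted_pct": 100.0 * frac,
        "z_up_in_gain": res.z_score,
        "empirical_p": res.empirical_p,
        "n": n_universe,
    }


# ---------------------------------------------------------------------------
# 6. conservation vs brute-force set intersection
# ---------------------------------------------------------------------------

def conservation_oracle_experiment(seed: int) -> dict:
    """Random two-genome frequency tracks: the package's remap + conserve +
    segment statistics must equal a brute-force set-intersection oracle."""
    pair = make_genome_pair(seed, n_chrom=2, genes_per_chrom=40, ortholog_rate=0.9)
    rng = np.random.default_rng(seed + 1)
    freq_choices = np.array([0.0, 0.05, 0.1, 0.2, 0.3, 0.5])

    def random_track(genes: pd.DataFrame, group: str) -> FrequencyTrack:
        n = len(genes)
        fg = rng.choice(freq_choices, n)
        fl = rng.choice(freq_choices, n)
        both = fg + fl > 1
        fl[both] = 0.0
        table = genes.set_index("gene_id")[["chromosome", "start", "end"]].copy()
        table["freq_gain"], table["freq_loss"] = fg, fl
        return FrequencyTrack(group, 18, table)

    track_a = random_track(pair.genome_a.genes, "tumor")
    track_b = random_track(pair.genome_b.genes, "tumor")

    # package path
    remapped = remap_orthologs(track_a, pair.ortholog_map, pair.genome_b.genes)
    conserved = conserved_cna_genes(remapped, track_b, 0.15)
    order_a = list(pair.genome_a.genes["gene_id"])
    seg_genes = [order_a[i:i + 10] for i in range(0, len(order_a), 10)]
    segments = [GroupSpecificSegment("chr", 0, 1, "gain", 0.5, genes, {genes[0]: 0.01})
                for genes in seg_genes]
    stats = cross_species_segment_stats(segments, conserved)

    # brute-force oracle: plain dict/set logic over the ortholog pairs
    ta, tb = track_a.table, track_b.table
    oracle_pairs = set()
    for ga, gb in zip(pair.ortholog_map["gene_a"], pair.ortholog_map["gene_b"]):
        for direction in ("gain", "loss"):
            other = "loss" if direction == "gain" else "gain"
            if (ta.at[ga, f"freq_{direction}"] > ta.at[ga, f"freq_{other}"]
                    and tb.at[gb, f"freq_{direction}"] > tb.at[gb, f"freq_{other}"]
                    and ta.at[ga, f"freq_{direction}"] >= 0.15
                    and tb.at[gb, f"freq_{direction}"] >= 0.15):
                oracle_pairs.add((ga, gb))
    oracle_src = {ga for ga, _ in oracle_pairs}
    oracle_hit = sum(1 for genes in seg_genes if any(g in oracle_src for g in genes))
    oracle_pct_seg = 100.0 * oracle_hit / len(seg_genes)
    all_seg_genes = {g for genes in seg_genes for g in genes}
    oracle_pct_gene = 100.0 * len(all_seg_genes & oracle_src) / len(all_seg_genes)

    package_pairs = set(zip(conserved["source_gene"], conserved["gene_id"]))
    return {
        "pct_segments_shared": stats.pct_segments_shared,
        "oracle_pct_segments_shared": oracle_pct_seg,
        "pct_genes_shared": stats.pct_genes_shared,
        "oracle_pct_genes_shared": oracle_pct_gene,
        "conserved_sets_equal": float(package_pairs == oracle_pairs),
        "n": len(pair.ortholog_map),
    }


# ---------------------------------------------------------------------------
# 7. qPCR identities
# ---------------------------------------------------------------------------

def qpcr_identity_experiment(seed: int) -> dict:
    """Noiseless planted folds recovered exactly; BH q-values match the
    hand-applied step-up formula."""
    ct = simulate_qpcr(n_control=5, n_treated=18,
                       fold_changes={"gA": 3.5, "gB": 1.0, "gC": 0.5},
                       ct_noise_sd=0.0, seed=seed)
    rel = ddct_fold_change(ct, "control")
    results = ttest_fdr(rel, "control").set_index("gene_id")
    q = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.5]))
    q_expected = np.array([0.04, 0.04, 0.04, 0.5])
    ctrl = rel[rel["group"] == "control"]
    return {
        "recovered_fold_3p5": float(results.at["gA", "treated_mean"]),
        "recovered_fold_1": float(results.at["gB", "treated_mean"]),
        "recovered_fold_0p5": float(results.at["gC", "treated_mean"]),
        "control_mean_rel_quantity": float(ctrl["rel_quantity"].mean()),
        "bh_max_abs_error": float(np.max(np.abs(q - q_expected))),
        "n": len(results),
    }
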