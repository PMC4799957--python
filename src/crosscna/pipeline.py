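"""End-to-end orchestration of the CNA analysis stages.

Stages (dependency order): simulate -> segment -> groupcna -> conserve ->
concord -> qpcr.  Each stage reads its inputs either from the in-session
context, from standard filenames in the output directory (written by an
earlier run), or from paths in the config's ``inputs`` section; a missing
requirement is a validation error naming the field.  Stage seeds derive
from the master seed by fixed offsets, so a config + seed pair pins every
output byte.  Every output file is recorded in ``manifest.json`` with its
sha256 (paths relative to the output directory).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from . import concordance as conc
from . import conservation as cons
from . import group_cna as gc
from . import io_formats as io
from . import qpcr as qp
from . import synthetic_data as synth
from .segmentation import SegmentationConfig, segment_cohort
from .types import CrossCnaError, PlantedCnaSpec

logger = logging.getLogger(__name__)

STAGES = ["simulate", "segment", "groupcna", "conserve", "concord", "qpcr"]
STAGE_SEED_OFFSETS = {s: i + 1 for i, s in enumerate(STAGES)}


class ValidationError(CrossCnaError):
    """Configuration or missing-input error (CLI exit code 1)."""


def _check_keys(section: dict, allowed: set[str], prefix: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        name = sorted(unknown)[0]
        raise ValidationError(f"unknown config key: {prefix}{name}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see examples/synthetic.yaml)."""

    seed: int = 17
    outdir: Path = Path("crosscna_out")
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    freq_threshold: float = 0.15
    gene_p_threshold: float = 0.05
    q_threshold: float = 0.1
    n_perm: int = 1000
    focal_group: str = "tumor"
    comparator_group: str = "nontumor"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys(raw, {"schema_version", "seed", "outdir", "simulate", "inputs",
                          "segmentation", "thresholds", "n_perm", "groups"}, "")
        if raw.get("schema_version", 1) != 1:
            raise ValidationError("schema_version: only version 1 is supported")
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "outdir" in raw:
            cfg.outdir = Path(raw["outdir"])
        if "simulate" in raw and raw["simulate"] is not None:
            cfg.simulate = _validate_simulate(raw["simulate"])
        if "inputs" in raw and raw["inputs"] is not None:
            _check_keys(raw["inputs"], {"probe_table_a", "probe_table_b", "genes_a",
                                        "genes_b", "orthologs", "de_table", "ct_table",
                                        "sample_groups_a", "sample_groups_b"},
                        "inputs.")
            cfg.inputs = {k: str(v) for k, v in raw["inputs"].items()}
        if "segmentation" in raw and raw["segmentation"] is not None:
            seg = raw["segmentation"]
            _check_keys(seg, {"alpha", "n_perm_ref", "min_probes", "lowess_span",
                              "gain_threshold", "loss_threshold"}, "segmentation.")
            try:
                cfg.segmentation = SegmentationConfig(**seg)
            except (TypeError, CrossCnaError) as exc:
                raise ValidationError(f"segmentation: {exc}") from exc
        if "thresholds" in raw and raw["thresholds"] is not None:
            thr = raw["thresholds"]
            _check_keys(thr, {"freq_threshold", "gene_p_threshold", "q_threshold"},
                        "thresholds.")
            cfg.freq_threshold = float(thr.get("freq_threshold", cfg.freq_threshold))
            cfg.gene_p_threshold = float(thr.get("gene_p_threshold", cfg.gene_p_threshold))
            cfg.q_threshold = float(thr.get("q_threshold", cfg.q_threshold))
        if "n_perm" in raw:
            cfg.n_perm = int(raw["n_perm"])
        if "groups" in raw and raw["groups"] is not None:
            _check_keys(raw["groups"], {"focal", "comparator"}, "groups.")
            cfg.focal_group = str(raw["groups"].get("focal", cfg.focal_group))
            cfg.comparator_group = str(raw["groups"].get("comparator", cfg.comparator_group))
        if not 0.0 < cfg.freq_threshold <= 1.0:
            raise ValidationError("thresholds.freq_threshold must be in (0, 1]")
        if not 0.0 < cfg.gene_p_threshold < 1.0:
            raise ValidationError("thresholds.gene_p_threshold must be in (0, 1)")
        if not 0.0 < cfg.q_threshold < 1.0:
            raise ValidationError("thresholds.q_threshold must be in (0, 1)")
        if cfg.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if cfg.focal_group == cfg.comparator_group:
            raise ValidationError("groups.focal must differ from groups.comparator")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config root must be a mapping")
        return cls.from_dict(raw)


_SIMULATE_KEYS = {"n_chrom", "genes_per_chrom", "ortholog_rate", "probe_spacing",
                  "noise_sd", "group_sizes_a", "group_sizes_b", "specs_a", "specs_b",
                  "expression", "qpcr"}
_SPEC_KEYS = {"chromosome", "start", "end", "direction", "effect", "penetrance",
              "group", "n_carriers", "spec_id"}


def _validate_simulate(sim: dict) -> dict:
    _check_keys(sim, _SIMULATE_KEYS, "simulate.")
    for side in ("specs_a", "specs_b"):
        for k, spec in enumerate(sim.get(side, [])):
            _check_keys(spec, _SPEC_KEYS, f"simulate.{side}[{k}].")
    if "expression" in sim:
        _check_keys(sim["expression"], {"n_up", "n_down", "frac_up_in_gain",
                                        "frac_down_in_loss"}, "simulate.expression.")
    if "qpcr" in sim:
        _check_keys(sim["qpcr"], {"n_control", "n_treated", "fold_changes",
                                  "ct_noise_sd"}, "simulate.qpcr.")
    return sim


def default_synthetic_config(outdir: str | Path = "crosscna_out",
                             seed: int = 17) -> PipelineConfig:
    """A complete synthetic study emulating the two-species design.

    Species A carries the mouse-like roles (18 tumors vs 18 matched
    nontumor samples, planted recurrent gains/losses in the tumors);
    species B is the human-like comparator cohort whose CNA labels also
    drive the planted DE concordance.  Sizes are kept small enough for a
    desk-scale run while leaving every planted signal detectable.
    """
    raw = {
        "seed": seed,
        "outdir": str(outdir),
        "simulate": {
            "n_chrom": 2,
            "genes_per_chrom": 60,
            "ortholog_rate": 0.8,
            "probe_spacing": 300_000,
            "noise_sd": 0.2,
            "group_sizes_a": {"tumor": 18, "nontumor": 18},
            "group_sizes_b": {"tumor": 18, "nontumor": 18},
            "specs_a": [
                {"chromosome": "chrA1", "start": 2_000_000, "end": 12_000_000,
                 "direction": "gain", "effect": 0.8, "penetrance": 0.5, "group": "tumor"},
                {"chromosome": "chrA2", "start": 20_000_000, "end": 30_000_000,
                 "direction": "loss", "effect": -0.8, "penetrance": 0.4, "group": "tumor"},
            ],
            "specs_b": [
                {"chromosome": "chrB1", "start": 5_000_000, "end": 18_000_000,
                 "direction": "gain", "effect": 0.8, "penetrance": 0.5, "group": "tumor"},
                {"chromosome": "chrB2", "start": 8_000_000, "end": 20_000_000,
                 "direction": "loss", "effect": -0.8, "penetrance": 0.4, "group": "tumor"},
            ],
            "expression": {"n_up": 30, "n_down": 25,
                           "frac_up_in_gain": 0.5, "frac_down_in_loss": 0.5},
            "qpcr": {"n_control": 5, "n_treated": 18,
                     "fold_changes": {"geneX": 3.5, "geneY": 1.0, "geneZ": 0.5},
                     "ct_noise_sd": 0.15},
        },
        "n_perm": 1000,
        "groups": {"focal": "tumor", "comparator": "nontumor"},
    }
    return PipelineConfig.from_dict(raw)


# ---------------------------------------------------------------------------
# stage runner
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Context:
    """In-session artifacts plus fallbacks to outdir files / config inputs."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.mem: dict[str, Any] = {}

    def path_for(self, name: str) -> Path:
        return self.outdir / name

    def resolve(self, filename: str, input_key: str | None, field_name: str) -> Path:
        p = self.outdir / filename
        if p.exists():
            return p
        if input_key and self.config.inputs.get(input_key):
            q = Path(self.config.inputs[input_key])
            if not q.exists():
                raise ValidationError(f"inputs.{input_key}: file not found: {q}")
            return q
        raise ValidationError(f"missing required input: {field_name} "
                              f"(no {filename} in outdir and no inputs.{input_key})")


def _groups_from_samples(samples: Sequence[str]) -> dict[str, str]:
    """Sample -> group, from the ``<group>_<k>`` naming convention."""
    return {s: s.rsplit("_", 1)[0] for s in samples}


def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None,
                 ) -> dict:
    """Run the requested stages in dependency order; returns the manifest."""
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    ctx = _Context(config)
    ctx.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"version": __version__, "seed": config.seed,
                                "stages": {}}
    runner = {"simulate": _stage_simulate, "segment": _stage_segment,
              "groupcna": _stage_groupcna, "conserve": _stage_conserve,
              "concord": _stage_concord, "qpcr": _stage_qpcr}
    for stage in stages:
        seed = config.seed + STAGE_SEED_OFFSETS[stage]
        logger.info("stage %s (seed %d)", stage, seed)
        outputs = runner[stage](ctx, seed)
        manifest["stages"][stage] = {
            "seed": seed,
            "outputs": {name: {"path": name, "sha256": _sha256(ctx.path_for(name))}
                        for name in outputs},
        }
    manifest_path = ctx.path_for("manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _specs_from_config(raw_specs: list[dict]) -> list[PlantedCnaSpec]:
    return [PlantedCnaSpec(**spec) for spec in raw_specs]


def _stage_simulate(ctx: _Context, seed: int) -> list[str]:
    sim = ctx.config.simulate
    if sim is None:
        raise ValidationError("simulate: section required to run the simulate stage")
    pair = synth.make_genome_pair(
        seed=seed, n_chrom=int(sim.get("n_chrom", 2)),
        genes_per_chrom=int(sim.get("genes_per_chrom", 60)),
        ortholog_rate=float(sim.get("ortholog_rate", 0.8)))
    spacing = int(sim.get("probe_spacing", 300_000))
    noise_sd = float(sim.get("noise_sd", 0.2))
    profiles_a, truth_a = synth.simulate_cohort(
        pair.genome_a, _specs_from_config(sim.get("specs_a", [])),
        sim.get("group_sizes_a", 18), spacing, noise_sd, seed + 1)
    profiles_b, truth_b = synth.simulate_cohort(
        pair.genome_b, _specs_from_config(sim.get("specs_b", [])),
        sim.get("group_sizes_b", 18), spacing, noise_sd, seed + 2)

    # DE table planted against species B's true focal-group CNA labels
    focal = ctx.config.focal_group
    gt = truth_b.gene_truth
    gt = gt[gt["group"] == focal].set_index("gene_id")
    thr = ctx.config.freq_threshold
    calls = pd.Series("neutral", index=gt.index, dtype=object)
    calls[(gt["freq_gain"] >= thr) & (gt["freq_gain"] > gt["freq_loss"])] = "gain"
    calls[(gt["freq_loss"] >= thr) & (gt["freq_loss"] > gt["freq_gain"])] = "loss"
    expr = sim.get("expression", {})
    de = synth.simulate_expression(
        calls, n_up=int(expr.get("n_up", 30)), n_down=int(expr.get("n_down", 25)),
        frac_up_in_gain=float(expr.get("frac_up_in_gain", 0.5)),
        frac_down_in_loss=float(expr.get("frac_down_in_loss", 0.5)),
        seed=seed + 3)

    q = sim.get("qpcr", {})
    ct = synth.simulate_qpcr(
        n_control=int(q.get("n_control", 5)), n_treated=int(q.get("n_treated", 18)),
        fold_changes=q.get("fold_changes", {"geneX": 3.5}),
        ct_noise_sd=float(q.get("ct_noise_sd", 0.15)), seed=seed + 4)

    io.write_gene_bed(pair.genome_a.genes, ctx.path_for("genes_a.bed"))
    io.write_gene_bed(pair.genome_b.genes, ctx.path_for("genes_b.bed"))
    io.write_ortholog_map(pair.ortholog_map, ctx.path_for("orthologs.tsv"))
    io.write_probe_table(profiles_a, ctx.path_for("probes_a.tsv"))
    io.write_probe_table(profiles_b, ctx.path_for("probes_b.tsv"))
    io.write_truth_table(truth_a, ctx.path_for("truth_a.tsv"))
    io.write_truth_table(truth_b, ctx.path_for("truth_b.tsv"))
    io.write_de_table(de, ctx.path_for("de_table.tsv"))
    io.write_ct_table(ct, ctx.path_for("ct_table.tsv"))
    ctx.mem.update(profiles_a=profiles_a, profiles_b=profiles_b, pair=pair, de=de, ct=ct)
    return ["genes_a.bed", "genes_b.bed", "orthologs.tsv", "probes_a.tsv",
            "probes_b.tsv", "truth_a.tsv", "truth_b.tsv", "de_table.tsv",
            "ct_table.tsv"]


def _load_profiles(ctx: _Context, side: str):
    key = f"profiles_{side}"
    if key not in ctx.mem:
        path = ctx.resolve(f"probes_{side}.tsv", f"probe_table_{side}",
                           f"probe table ({side})")
        ctx.mem[key] = io.read_probe_table(path)
    return ctx.mem[key]


def _load_genes(ctx: _Context, side: str) -> pd.DataFrame:
    key = f"genes_{side}"
    if key not in ctx.mem:
        if "pair" in ctx.mem:
            genome = ctx.mem["pair"].genome_a if side == "a" else ctx.mem["pair"].genome_b
            ctx.mem[key] = genome.genes
        else:
            path = ctx.resolve(f"genes_{side}.bed", f"genes_{side}",
                               f"gene annotations ({side})")
            ctx.mem[key] = io.read_gene_bed(path)
    return ctx.mem[key]


def _stage_segment(ctx: _Context, seed: int) -> list[str]:
    cfg = ctx.config
    outputs = []
    for side in ("a", "b"):
        profiles = _load_profiles(ctx, side)
        seg_cfg = SegmentationConfig(
            alpha=cfg.segmentation.alpha, n_perm_ref=cfg.segmentation.n_perm_ref,
            min_probes=cfg.segmentation.min_probes,
            lowess_span=cfg.segmentation.lowess_span,
            gain_threshold=cfg.segmentation.gain_threshold,
            loss_threshold=cfg.segmentation.loss_threshold, seed=seed)
        segments, log = segment_cohort(profiles, seg_cfg)
        ctx.mem[f"segments_{side}"] = segments
        io.write_seg(segments, ctx.path_for(f"segments_{side}.seg"))
        log.to_csv(ctx.path_for(f"segment_log_{side}.tsv"), sep="\t", index=False)
        outputs += [f"segments_{side}.seg", f"segment_log_{side}.tsv"]
    return outputs


def _load_segments(ctx: _Context, side: str):
    key = f"segments_{side}"
    if key not in ctx.mem:
        path = ctx.resolve(f"segments_{side}.seg", None, f"segments ({side})")
        ctx.mem[key] = io.read_seg(path)
    return ctx.mem[key]


def _stage_groupcna(ctx: _Context, seed: int) -> list[str]:
    cfg = ctx.config
    outputs = []
    for side in ("a", "b"):
        segments = _load_segments(ctx, side)
        genes = _load_genes(ctx, side)
        matrix = gc.gene_copy_matrix(segments, genes,
                                     cfg.segmentation.gain_threshold,
                                     cfg.segmentation.loss_threshold)
        ctx.mem[f"matrix_{side}"] = matrix
        groups = _groups_from_samples(matrix.samples)
        for group in (cfg.focal_group, cfg.comparator_group):
            members = [s for s, g in groups.items() if g == group]
            if not members:
                continue
            track = gc.frequency_track(matrix, members, group)
            ctx.mem[f"track_{side}_{group}"] = track
            fname = f"freq_{group}_{side}.tsv"
            io.write_frequency_track(track, ctx.path_for(fname))
            outputs.append(fname)
        focal_members = [s for s, g in groups.items() if g == cfg.focal_group]
        comp_members = [s for s, g in groups.items() if g == cfg.comparator_group]
        if focal_members and comp_members:
            regions = gc.group_specific_segments(
                ctx.mem[f"track_{side}_{cfg.focal_group}"], matrix,
                focal_members, comp_members,
                cfg.freq_threshold, cfg.gene_p_threshold)
            ctx.mem[f"regions_{side}"] = regions
            fname = f"group_specific_{side}.tsv"
            gc.write_group_specific(regions, ctx.path_for(fname))
            outputs.append(fname)
    return outputs


def _load_track(ctx: _Context, side: str, group: str):
    key = f"track_{side}_{group}"
    if key not in ctx.mem:
        path = ctx.resolve(f"freq_{group}_{side}.tsv", None,
                           f"frequency track ({group}, {side})")
        ctx.mem[key] = io.read_frequency_track(path)
    return ctx.mem[key]


def _stage_conserve(ctx: _Context, seed: int) -> list[str]:
    cfg = ctx.config
    track_a = _load_track(ctx, "a", cfg.focal_group)
    track_b = _load_track(ctx, "b", cfg.focal_group)
    genes_b = _load_genes(ctx, "b")
    if "pair" in ctx.mem:
        omap = ctx.mem["pair"].ortholog_map
    else:
        path = ctx.resolve("orthologs.tsv", "orthologs", "ortholog map")
        omap = io.read_ortholog_map(path, valid_a=track_a.table.index,
                                    valid_b=genes_b["gene_id"])
    remapped = cons.remap_orthologs(track_a, omap, genes_b, source_side="gene_a")
    conserved = cons.conserved_cna_genes(remapped, track_b, cfg.freq_threshold)
    if "regions_a" not in ctx.mem:
        path = ctx.resolve("group_specific_a.tsv", None,
                           "group-specific regions (run the groupcna stage first)")
        ctx.mem["regions_a"] = gc.read_group_specific(path)
    stats = cons.cross_species_segment_stats(ctx.mem["regions_a"], conserved)
    ctx.mem["conserved"] = conserved
    cons.write_conserved_genes(conserved, ctx.path_for("conserved_genes.tsv"))
    cons.write_conservation_stats(stats, ctx.path_for("conservation_stats.json"),
                                  cfg.freq_threshold, track_a.group, track_b.group)
    return ["conserved_genes.tsv", "conservation_stats.json"]


def _stage_concord(ctx: _Context, seed: int) -> list[str]:
    cfg = ctx.config
    if "de" not in ctx.mem:
        path = ctx.resolve("de_table.tsv", "de_table", "DE table")
        ctx.mem["de"] = io.read_de_table(path, cfg.q_threshold)
    de = ctx.mem["de"]
    track_b = _load_track(ctx, "b", cfg.focal_group)
    labels = conc.classify_genes_by_cna(track_b, cfg.freq_threshold)
    conserved = None
    if "conserved" in ctx.mem and len(ctx.mem["conserved"]):
        conserved = set(ctx.mem["conserved"]["gene_id"])
    summary = conc.concordance_table(de, labels, conserved)
    results = {}
    for direction, label in (("up", "gain"), ("down", "loss")):
        n_set = summary.n_up if direction == "up" else summary.n_down
        if n_set == 0:
            continue
        observed = float(summary.table.at[label, f"{direction}_pct"])
        results[f"{direction}_in_{label}"] = conc.permutation_test(
            labels, n_set, label, observed, cfg.n_perm, seed)
    conc.write_concordance(summary, ctx.path_for("concordance_table.tsv"))
    conc.write_permutation(results, ctx.path_for("permutation.json"))
    return ["concordance_table.tsv", "permutation.json"]


def _stage_qpcr(ctx: _Context, seed: int) -> list[str]:
    cfg = ctx.config
    if "ct" not in ctx.mem:
        path = ctx.resolve("ct_table.tsv", "ct_table", "Ct table")
        ctx.mem["ct"] = io.read_ct_table(path)
    rel = qp.ddct_fold_change(ctx.mem["ct"], control_group="control")
    results = qp.ttest_fdr(rel, control_group="control", q_threshold=cfg.q_threshold)
    qp.write_qpcr_results(results, ctx.path_for("qpcr_results.tsv"))
    return ["qpcr_results.tsv"]
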