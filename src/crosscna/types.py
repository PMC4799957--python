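"""Core data containers shared across the pipeline.

Coordinate convention
---------------------
All genomic intervals are **0-based, half-open** ``[start, end)`` internally.
Probe ``position`` is a 1-based basepair coordinate (the probe at position
``p`` occupies internal coordinate ``p - 1``).  File readers/writers convert
at the boundary (BED is native; SEG is written 1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd


class CrossCnaError(Exception):
    """Base class for validation errors raised by this package."""


class Chromosome(NamedTuple):
    name: str
    length: int  # bp


@dataclass
class Genome:
    """One species' chromosomes plus its gene annotation table.

    ``genes`` columns: gene_id, chromosome, start, end, strand
    (0-based half-open intervals, sorted by chromosome then start).
    """

    chromosomes: list[Chromosome]
    genes: pd.DataFrame

    def chrom_length(self, name: str) -> int:
        for c in self.chromosomes:
            if c.name == name:
                return c.length
        raise CrossCnaError(f"unknown chromosome {name!r}")

    def validate(self) -> None:
        lengths = {c.name: c.length for c in self.chromosomes}
        g = self.genes
        required = {"gene_id", "chromosome", "start", "end", "strand"}
        missing = required - set(g.columns)
        if missing:
            raise CrossCnaError(f"gene table missing columns {sorted(missing)}")
        if (g["start"] >= g["end"]).any():
            raise CrossCnaError("gene with start >= end")
        for chrom, sub in g.groupby("chromosome", sort=False):
            if chrom not in lengths:
                raise CrossCnaError(f"gene on unknown chromosome {chrom!r}")
            if (sub["end"] > lengths[chrom]).any() or (sub["start"] < 0).any():
                raise CrossCnaError(f"gene interval outside chromosome {chrom!r}")
            s = sub.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise CrossCnaError(f"overlapping genes on {chrom!r}")


@dataclass
class GenomePair:
    """Two genomes linked by a one-to-one ortholog map.

    ``ortholog_map`` columns: gene_a, gene_b; each id occurs in at most one
    pair and exists in the corresponding gene table.
    """

    genome_a: Genome
    genome_b: Genome
    ortholog_map: pd.DataFrame

    def validate(self) -> None:
        self.genome_a.validate()
        self.genome_b.validate()
        m = self.ortholog_map
        if not {"gene_a", "gene_b"} <= set(m.columns):
            raise CrossCnaError("ortholog map needs columns gene_a, gene_b")
        if m["gene_a"].duplicated().any() or m["gene_b"].duplicated().any():
            raise CrossCnaError("ortholog map is not one-to-one")
        if not set(m["gene_a"]) <= set(self.genome_a.genes["gene_id"]):
            raise CrossCnaError("ortholog map references unknown genome-A gene")
        if not set(m["gene_b"]) <= set(self.genome_b.genes["gene_id"]):
            raise CrossCnaError("ortholog map references unknown genome-B gene")


@dataclass
class ProbeProfile:
    """One sample's ordered probe-level log2-ratio measurements.

    ``probes`` columns: probe_id, chromosome, position (1-based bp),
    log2_ratio, and optionally mean_intensity.  Rows sorted by
    (chromosome, position); no duplicate (chromosome, position).
    """

    sample_id: str
    probes: pd.DataFrame

    def validate(self) -> None:
        p = self.probes
        required = {"probe_id", "chromosome", "position", "log2_ratio"}
        missing = required - set(p.columns)
        if missing:
            raise CrossCnaError(
                f"profile {self.sample_id}: missing columns {sorted(missing)}"
            )
        if (p["position"] < 1).any():
            raise CrossCnaError(f"profile {self.sample_id}: position < 1")
        key = p[["chromosome", "position"]]
        if key.duplicated().any():
            raise CrossCnaError(
                f"profile {self.sample_id}: duplicate (chromosome, position)"
            )
        sorted_key = key.sort_values(["chromosome", "position"])
        if not np.array_equal(sorted_key.index.values, key.index.values):
            raise CrossCnaError(
                f"profile {self.sample_id}: probes not sorted by (chromosome, position)"
            )

    @property
    def has_intensity(self) -> bool:
        return (
            "mean_intensity" in self.probes.columns
            and self.probes["mean_intensity"].notna().all()
        )


@dataclass
class Segment:
    """A constant-copy genomic interval of one sample.

    Internal 0-based half-open coordinates; ``call`` is gain/loss/neutral.
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    n_probes: int
    mean_log2: float
    call: str = "neutral"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CrossCnaError("segment start > end")
        if self.n_probes < 1:
            raise CrossCnaError("segment with no probes")


@dataclass
class PlantedCnaSpec:
    """A ground-truth CNA to plant into simulated cohorts.

    ``penetrance`` is the Bernoulli carrier probability per sample of
    ``group``; if ``n_carriers`` is given, exactly that many carriers are
    drawn instead (a hypergeometric-style planting that fixes the realized
    frequency).  ``effect`` is the mean log2-ratio shift of carriers.
    """

    chromosome: str
    start: int
    end: int
    direction: str  # gain | loss
    effect: float
    penetrance: float
    group: str
    n_carriers: int | None = None
    spec_id: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise CrossCnaError(f"direction must be gain|loss, got {self.direction!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise CrossCnaError("penetrance must be in [0, 1]")
        if self.direction == "gain" and self.effect <= 0:
            raise CrossCnaError("gain spec requires effect > 0")
        if self.direction == "loss" and self.effect >= 0:
            raise CrossCnaError("loss spec requires effect < 0")
        if self.start >= self.end:
            raise CrossCnaError("spec region start >= end")
        if not self.spec_id:
            self.spec_id = (
                f"{self.group}_{self.direction}_{self.chromosome}"
                f"_{self.start}_{self.end}"
            )


@dataclass
class CohortTruth:
    """Exact ground truth of a simulated cohort.

    ``carriers`` maps spec_id -> sorted list of carrier sample ids.
    ``gene_truth`` has one row per (gene, group): freq_gain / freq_loss are
    carried-sample counts over group size for specs overlapping the gene.
    """

    specs: list[PlantedCnaSpec]
    carriers: dict[str, list[str]]
    gene_truth: pd.DataFrame
    group_sizes: dict[str, int]

    def carrier_fraction(self, spec_id: str) -> float:
        spec = next(s for s in self.specs if s.spec_id == spec_id)
        return len(self.carriers[spec_id]) / self.group_sizes[spec.group]


@dataclass
class FrequencyTrack:
    """Per-gene fraction of group samples altered in each direction.

    ``table`` is indexed by gene_id with columns chromosome, start, end,
    freq_gain, freq_loss.  Denominator is always the full group size; genes
    with a missing call in a sample count in the denominator only.
    """

    group: str
    n_samples: int
    table: pd.DataFrame

    def validate(self) -> None:
        t = self.table
        if ((t["freq_gain"] < 0) | (t["freq_gain"] > 1)).any():
            raise CrossCnaError("freq_gain outside [0, 1]")
        if ((t["freq_loss"] < 0) | (t["freq_loss"] > 1)).any():
            raise CrossCnaError("freq_loss outside [0, 1]")
        if ((t["freq_gain"] + t["freq_loss"]) > 1 + 1e-12).any():
            raise CrossCnaError("freq_gain + freq_loss > 1")


@dataclass
class GeneCopyMatrix:
    """Gene-level copy values and calls across samples.

    ``values``/``calls`` are genes x samples DataFrames indexed by gene_id;
    a gene overlapped by no segment in a sample is NaN (missing), not 0.
    """

    genes: pd.DataFrame
    values: pd.DataFrame
    calls: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GroupSpecificSegment:
    """A run of adjacent same-direction high-frequency genes that passes the
    two-part group-specificity rule (frequency and at least one gene p)."""

    chromosome: str
    start: int
    end: int
    direction: str
    frequency: float  # max gene frequency in the focal group
    genes: list[str]
    gene_p: dict[str, float]

    @property
    def min_gene_p(self) -> float:
        finite = [p for p in self.gene_p.values() if np.isfinite(p)]
        return min(finite) if finite else float("nan")


@dataclass
class RemappedTrack:
    """A source-species frequency track carried into target genomic order.

    ``table`` indexed by target gene_id, sorted by target coordinates, with
    columns chromosome, start, end, source_gene, source_freq_gain,
    source_freq_loss, mapped (bool).
    """

    source_group: str
    table: pd.DataFrame


@dataclass
class ConservationStats:
    """Cross-species sharing summary.

    Percentages are on the 0-100 scale; None when there are no altered
    source segments (undefined, not zero).
    """

    pct_segments_shared: float | None
    pct_genes_shared: float | None
    conserved_genes: list[str]
    n_source_segments: int
    n_source_segment_genes: int


@dataclass
class ConcordanceSummary:
    """Percentages of DE genes lying inside direction-matched CNA calls.

    ``table``: rows are CNA labels (gain/loss and, when a conserved gene
    list was supplied, conserved_gain/conserved_loss), columns up_pct and
    down_pct.  ``counts`` holds the corresponding integer counts.
    """

    table: pd.DataFrame
    counts: pd.DataFrame
    n_up: int
    n_down: int
    n_universe: int
    n_unknown: int = 0


@dataclass
class PermutationResult:
    """Null distribution of the in-label percentage for random gene sets."""

    observed_pct: float
    null_pcts: np.ndarray
    z_score: float
    empirical_p: float
    n_perm: int
    seed: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_pcts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_pcts, ddof=1))


@dataclass
class SegmentationLog:
    sample_id: str
    n_probes: int
    n_probes_dropped: int
    n_segments: int
    short_chromosomes: list[str] = field(default_factory=list)
    seed: int = 0
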