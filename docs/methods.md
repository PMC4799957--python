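# Methods

This note documents the models, defaults, numerical choices and known
limitations of `crosscna`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All genomic intervals are 0-based half-open internally. BED6 is read
natively; SEG is converted at the boundary (written 1-based inclusive,
segment means to 6 decimals). Probe tables are wide TSVs (one log2-ratio
column per sample, optional `intensity_<sample>` columns); all files are
UTF-8, tab-delimited, `.` for missing. Chromosome names are compared by
exact string match — no `chr` stripping — so mismatched naming surfaces as
an explicit "missing chromosome" warning rather than silent non-overlap.
Strand is read and carried but ignored by all copy-number computations
(copy number is strand-agnostic).

## Normalization

Two-color aCGH log2(R/G) ratios carry intensity-dependent dye bias. When
probe mean intensities are available, a lowess regression of log2-ratio on
intensity (span 0.3 by default) is fitted per sample and subtracted. When
they are not — as for all synthetic profiles — the profile is
median-centered, which is idempotent and preserves every downstream
breakpoint. Normalization never reorders or drops probes.

## Circular binary segmentation

Each chromosome's ordered probes are treated as a circle. For an arc
`[i, j)` of length `k` out of `n` probes, with prefix sums `S`, the
mean-shift likelihood-ratio statistic is

    Z(i, j) = |S_j − S_i − (k/n) S_n| / sqrt(k (n − k) / n)

and the split candidate is the arc maximizing `|Z|` (ties broken toward
the leftmost `i`, then `j`). Because significance is judged against a
permutation distribution of the same probe values, the unknown noise
variance cancels, so the global-variance form is used rather than a
pooled-variance t; on single-change-point inputs the two statistics select
the same split, which the acceptance suite verifies against an exhaustive
two-sample-t scan.

A split is accepted when its permutation p-value (default 1000
permutations) is below `alpha` (default 0.01) and every resulting piece
has at least `min_probes` probes (default 2); accepted arcs contribute up
to two breakpoints and the recursion continues on each piece.
Permutations stop early only once the exceedance count already forces
`p >= alpha`, so decisions are identical to a full run; accepted splits
are always backed by the full permutation count. Chromosomes with fewer
than `2 * min_probes` probes are emitted as a single segment and flagged
in the per-sample log, as are probes dropped for missing values. There is
no post-hoc merge/undo pass; that is a deliberate extension point.

Gain/loss calls use inclusive thresholds at ±0.2 log2 units by default — a
conventional aCGH operating point, surfaced in `SegmentationConfig`
because the appropriate value depends on tumor purity and platform.

## Group-specific CNAs

Frequencies are computed at gene resolution: a gene's copy value in a
sample is the bp-overlap-weighted mean of overlapping segment means, its
call uses the same thresholds as segments, and a gene covered by no
segment is missing (it still counts in the frequency denominator, never
the numerator). A region is group-specific when a maximal run of adjacent
same-direction genes reaches frequency ≥ `freq_threshold` (default 0.15)
in the focal group **and** contains at least one gene whose copy values
differ between the groups at `p < p_threshold` (default 0.05, two-sided
Welch t — chosen as a robust default for unequal variances; the published
rule names no test). The gene-level p criterion is deliberately
uncorrected, mirroring the stated rule; the region frequency reported is
the maximum gene frequency in the run. Raising the frequency threshold or
lowering the p threshold can only remove regions (tested as a monotonicity
property).

## Cross-species conservation

Only one-to-one ortholog pairs carry information; pairs involving a
duplicated id are dropped at I/O (one-to-many orthology cannot be remapped
gene-to-gene without double counting). The source species' per-gene
frequencies are joined onto target genes and sorted by target coordinates.
A gene is a conserved CNA when both species have the same *dominant*
direction (the direction with the strictly higher frequency; a tie is
unclassifiable and never conserved) at frequency ≥ 0.15 in both. The
conserved set is symmetric in the species; the segment-level summary —
percent of source altered segments containing ≥ 1 conserved gene, and
percent of source-segment genes conserved — is source-specific by
construction. With zero source segments the percentages are undefined
(reported as missing, not 0). The gene-sharing denominator is the set of
distinct genes in the source segments; a target-side or union denominator
would be equally defensible, and callers can compute them from the emitted
conserved-gene table.

## Expression–CNA concordance

Cohort-level gene labels reuse the only stated recurrence criterion:
gain if `freq_gain ≥ 0.15` and gains outnumber losses, symmetrically for
loss, ties neutral. The concordance table reports, per DE direction
(q < 0.1), the percentage of genes carrying each label, plus
conserved-only rows when a conserved gene set is supplied; a direction
with no genes yields missing percentages. The permutation null draws
`set_size` gene identities uniformly without replacement from the full
expressed universe (preserving label counts) and records the in-label
percentage; the z-score uses the sample standard deviation (n−1) of the
null, and the two-sided empirical p-value uses an add-one correction,
`p = (1 + #{|null − mean| ≥ |obs − mean|}) / (n_perm + 1)`, so it is never
zero even when the z-score implies vanishing likelihood. The null mean and
sd converge to the hypergeometric closed form (mean `100·K/N`), which the
acceptance suite checks at 10,000 permutations. The calibration check that
the empirical p is uniform under the null uses a universe large enough
(3,000 genes) that the discrete overlap percentage approximates a
continuous statistic; on very small universes the discreteness itself
dominates a Kolmogorov–Smirnov comparison.

The differential-expression model fit itself is out of scope: DE tables
are inputs (gene, log2 fold change, p, q), with direction derived from the
fold-change sign at q < 0.1.

## qPCR quantification

Per sample, `ΔCt = Ct_target − Ct_housekeeping`; `ΔΔCt` subtracts the
control-group mean ΔCt (the Livak baseline, matching normalization to a
vehicle-control group); the relative quantity is `2^−ΔΔCt`. Under this
baseline the control group's *geometric* mean relative quantity is exactly
1; its arithmetic mean equals 1 exactly only in noiseless data (Jensen's
inequality). Group differences are tested on the relative quantities with
a two-sided unpaired Student's t-test (equal variance, Welch available via
a flag), followed by Benjamini–Hochberg step-up q-values across the gene
panel, significant at q < 0.1. Whether to test ΔCt values or relative
quantities is not dictated by the published description; this package
tests relative quantities. Samples missing either Ct are excluded with a
warning; genes with no usable control measurement (e.g. undetected in
controls) are excluded from quantification entirely — they have no defined
fold change and are reported descriptively by the caller.

## Synthetic-data generator

The generator emulates the study design, not array physics. Genomes are
a few tens-of-Mb chromosomes with uniformly placed non-overlapping genes
(minimum 5 kb gap); ortholog pairs are drawn uniformly without replacement
on both sides and shuffled so genomic order differs between species. Probe
grids are regular (default 300 kb in the example study, mimicking a
180K-probe-scale array's genome-wide density at reduced total size).
Planted CNAs are rectangular mean shifts: each sample of the spec's group
carries the CNA with probability `penetrance` (or an exact carrier count
when `n_carriers` is set, which pins the realized frequency — used where a
check is *about* a specific frequency), carried effects add where regions
overlap, and i.i.d. Gaussian noise (default sd 0.2, a mid-range value for
tumor aCGH after normalization) is added on the log2 scale. Cohort sizes
default to 18 tumor + 18 matched nontumor samples, and the qPCR design to
5 control + 18 treated samples, matching the emulated study. The DE
generator places `round(frac · n)` of the up (down) genes in gain- (loss-)
labeled genes, the remainder in neutral genes, and emits the full universe
with ns rows.

Not modeled: intensity waves and GC bias, tumor purity and ploidy,
subclonality, segmental noise correlation, ortholog families, and
amplification-efficiency variation in qPCR. Passing tests therefore show
the *inference machinery* is correct under its stated model, not that the
thresholds are optimal for any particular real platform.

## Pipeline and reproducibility

Stage seeds derive from the master seed by fixed offsets (+1 simulate, +2
segment, ..., +6 qpcr; the simulate stage further offsets its four
generator calls), so one config + seed pins every output byte — manifests
record relative paths and sha256 hashes, and an identical rerun is
byte-identical. The config schema is strict: unknown keys are errors, and
validation failures name the first offending field. CLI exit codes: 0
success, 1 validation error, 2 runtime error.

## Validation problem sizes

The acceptance experiments use: 100 simulated chromosomes of 200 probes
(shift 1.0, sd 0.25) for breakpoint recovery; a dense 2×50-gene genome at
50 kb spacing for the noiseless round trip and the group-detection check
(18+18 samples, sd 0.2); 17,000-gene universes for the permutation-null
and concordance checks (10,000 and 1,000 permutations respectively, with a
3,000-gene universe and 500×400 permutations for p-uniformity); and a
2×40-gene genome pair at 90% orthology for the conservation oracle. These
sizes keep the full validation run to a few minutes on one CPU while
holding every planted signal far from the detection boundary.

## Known limitations

- CBS here has no segment-merging ("undo") pass, so very long chromosomes
  with drift can over-segment relative to reference implementations.
- The per-gene Welch test treats gene-level copy values as independent
  observations; adjacent genes sharing a segment are correlated, which is
  why significance gates *regions*, not genes.
- The permutation null permutes gene identities only; it does not preserve
  genomic adjacency of DE genes, matching the stated null but ignoring
  co-expression clustering.
- Real-data comparators (SNP-array cohorts) are expected to arrive
  pre-segmented in SEG form; the package does not genotype or estimate
  purity/ploidy.
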