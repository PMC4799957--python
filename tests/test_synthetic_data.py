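import numpy as np
import pandas as pd
import pytest

from crosscna.types import Chromosome, CrossCnaError, Genome, PlantedCnaSpec
from crosscna.synthetic_data import (
    make_genome_pair,
    simulate_cohort,
    simulate_expression,
    simulate_qpcr,
)


class TestMakeGenomePair:
    def test_full_ortholog_rate_pairs_every_gene(self, genome_pair):
        assert len(genome_pair.genome_a.genes) == 100
        assert len(genome_pair.genome_b.genes) == 100
        assert len(genome_pair.ortholog_map) == 100
        genome_pair.validate()

    def test_zero_rate_gives_empty_map(self):
        pair = make_genome_pair(seed=2, n_chrom=1, genes_per_chrom=10, ortholog_rate=0.0)
        assert len(pair.ortholog_map) == 0

    def test_deterministic_for_fixed_seed(self):
        a = make_genome_pair(seed=5, n_chrom=2, genes_per_chrom=20, ortholog_rate=0.5)
        b = make_genome_pair(seed=5, n_chrom=2, genes_per_chrom=20, ortholog_rate=0.5)
        pd.testing.assert_frame_equal(a.genome_a.genes, b.genome_a.genes)
        pd.testing.assert_frame_equal(a.ortholog_map, b.ortholog_map)
        assert a.genome_a.chromosomes == b.genome_a.chromosomes

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_genes_sorted_nonoverlapping_within_bounds(self, seed):
        pair = make_genome_pair(seed=seed, n_chrom=3, genes_per_chrom=30,
                                ortholog_rate=0.7)
        pair.validate()  # checks bounds, order, overlap, one-to-one map

    @pytest.mark.parametrize("kwargs", [
        {"n_chrom": 0, "genes_per_chrom": 5, "ortholog_rate": 0.5},
        {"n_chrom": 1, "genes_per_chrom": 0, "ortholog_rate": 0.5},
        {"n_chrom": 1, "genes_per_chrom": 5, "ortholog_rate": 1.5},
    ])
    def test_invalid_sizes_rejected(self, kwargs):
        with pytest.raises(CrossCnaError):
            make_genome_pair(seed=1, **kwargs)


class TestSimulateCohort:
    def test_noiseless_values_exactly_effect_inside_region(self, noiseless_cohort):
        profiles, truth, spec = noiseless_cohort
        assert truth.carriers["g1"] == [p.sample_id for p in profiles]
        for prof in profiles:
            pos0 = prof.probes["position"].to_numpy() - 1
            inside = (pos0 >= spec.start) & (pos0 < spec.end)
            vals = prof.probes["log2_ratio"].to_numpy()
            assert np.all(vals[inside] == 0.8)
            assert np.all(vals[~inside] == 0.0)

    def test_truth_records_realized_carriers(self, tiny_genome):
        spec = PlantedCnaSpec("chr1", 0, 300_000, "gain", 0.5, 0.5, "tumor")
        profiles, truth = simulate_cohort(tiny_genome, [spec], 18, 50_000, 0.0, 11)
        carriers = set(truth.carriers[spec.spec_id])
        for prof in profiles:
            carries = prof.probes["log2_ratio"].iloc[0] != 0.0
            assert carries == (prof.sample_id in carriers)

    def test_exact_carrier_count_option(self, tiny_genome):
        spec = PlantedCnaSpec("chr1", 0, 300_000, "gain", 0.5, 2 / 18, "tumor",
                              n_carriers=2)
        _, truth = simulate_cohort(tiny_genome, [spec], 18, 50_000, 0.0, 1)
        assert len(truth.carriers[spec.spec_id]) == 2

    def test_region_outside_genome_rejected(self, tiny_genome):
        spec = PlantedCnaSpec("chr1", 0, 2_000_000, "gain", 0.5, 0.5, "tumor")
        with pytest.raises(CrossCnaError, match="outside"):
            simulate_cohort(tiny_genome, [spec], 4, 50_000, 0.0, 1)

    def test_overlapping_specs_add_effects(self, tiny_genome):
        specs = [
            PlantedCnaSpec("chr1", 0, 400_000, "gain", 0.5, 1.0, "tumor", spec_id="a"),
            PlantedCnaSpec("chr1", 200_000, 600_000, "gain", 0.3, 1.0, "tumor", spec_id="b"),
        ]
        profiles, _ = simulate_cohort(tiny_genome, specs, 2, 50_000, 0.0, 1)
        pos0 = profiles[0].probes["position"].to_numpy() - 1
        vals = profiles[0].probes["log2_ratio"].to_numpy()
        both = (pos0 >= 200_000) & (pos0 < 400_000)
        assert np.allclose(vals[both], 0.8)

    def test_carrier_fraction_unbiased_over_many_cohorts(self):
        """Mean realized carrier fraction ~ Binomial(n, p)/n: within 3 SE of p."""
        genome = Genome([Chromosome("chr1", 200_000)], pd.DataFrame({
            "gene_id": ["g"], "chromosome": ["chr1"], "start": [0],
            "end": [100_000], "strand": ["+"]}))
        spec = PlantedCnaSpec("chr1", 0, 100_000, "gain", 0.5, 0.5, "tumor")
        n, reps = 18, 200
        fracs = []
        for r in range(reps):
            _, truth = simulate_cohort(genome, [spec], n, 100_000, 0.0, seed=r)
            fracs.append(len(truth.carriers[spec.spec_id]) / n)
        se = np.sqrt(0.5 * 0.5 / (n * reps))
        assert abs(np.mean(fracs) - 0.5) < 3 * se

    def test_deterministic_for_fixed_seed(self, tiny_genome):
        spec = PlantedCnaSpec("chr1", 0, 300_000, "gain", 0.5, 0.5, "tumor")
        p1, t1 = simulate_cohort(tiny_genome, [spec], 6, 50_000, 0.3, 42)
        p2, t2 = simulate_cohort(tiny_genome, [spec], 6, 50_000, 0.3, 42)
        assert t1.carriers == t2.carriers
        for a, b in zip(p1, p2):
            pd.testing.assert_frame_equal(a.probes, b.probes)


class TestSimulateExpression:
    @pytest.fixture()
    def labels(self):
        return pd.Series(["gain"] * 50 + ["loss"] * 40 + ["neutral"] * 200,
                         index=[f"g{k}" for k in range(290)])

    def test_full_fraction_puts_every_up_gene_in_gain(self, labels):
        de = simulate_expression(labels, n_up=20, n_down=0,
                                 frac_up_in_gain=1.0, frac_down_in_loss=0.0, seed=1)
        up = de[de["direction"] == "up"]
        assert len(up) == 20
        assert (labels.loc[up["gene_id"]] == "gain").all()

    def test_realized_count_is_rounded_target(self, labels):
        de = simulate_expression(labels, n_up=25, n_down=0,
                                 frac_up_in_gain=0.52, frac_down_in_loss=0.0, seed=2)
        up = de[de["direction"] == "up"]
        n_in_gain = int((labels.loc[up["gene_id"]] == "gain").sum())
        assert n_in_gain == round(0.52 * 25)

    def test_zero_sets_give_no_de_rows(self, labels):
        de = simulate_expression(labels, 0, 0, 0.5, 0.5, seed=1)
        assert (de["direction"] == "ns").all()
        assert len(de) == len(labels)

    def test_infeasible_fraction_names_stratum(self, labels):
        with pytest.raises(CrossCnaError, match="gain"):
            simulate_expression(labels, n_up=200, n_down=0,
                                frac_up_in_gain=1.0, frac_down_in_loss=0.0, seed=1)

    def test_direction_consistent_with_q_and_sign(self, labels):
        de = simulate_expression(labels, 10, 10, 0.5, 0.5, seed=3)
        sig = de["fdr_q"] < 0.1
        assert ((de.loc[sig & (de["log2_fold_change"] > 0), "direction"]) == "up").all()
        assert ((de.loc[~sig, "direction"]) == "ns").all()


class TestSimulateQpcr:
    def test_noiseless_fold_two_shifts_one_cycle(self):
        ct = simulate_qpcr(3, 3, {"g": 2.0}, 0.0, seed=1)
        ctrl = ct[ct["group"] == "control"]["ct_target"].mean()
        trt = ct[ct["group"] == "treated"]["ct_target"].mean()
        assert trt == pytest.approx(ctrl - 1.0, abs=1e-12)

    def test_fold_one_means_equal_ct(self):
        ct = simulate_qpcr(3, 3, {"g": 1.0}, 0.0, seed=1)
        assert ct["ct_target"].nunique() == 1

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(CrossCnaError):
            simulate_qpcr(3, 3, {"g": 0.0}, 0.0, seed=1)

    def test_housekeeping_constant_in_expectation(self):
        ct = simulate_qpcr(20, 20, {"g": 4.0}, 0.5, seed=5)
        ctrl = ct[ct["group"] == "control"]["ct_housekeeping"]
        trt = ct[ct["group"] == "treated"]["ct_housekeeping"]
        assert abs(ctrl.mean() - trt.mean()) < 0.5
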