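import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosscna.types import CrossCnaError, ProbeProfile
from crosscna.segmentation import (
    SegmentationConfig,
    call_segments,
    cbs_segment,
    lowess_normalize,
)
from crosscna.validation import exhaustive_t_argmax, _breakpoints
from tests.conftest import step_profile


def _flat_profile(value=0.3, n=50, intensities=None):
    df = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)],
        "chromosome": "chr1",
        "position": np.arange(1, n + 1) * 1000,
        "log2_ratio": np.full(n, value, dtype=float),
    })
    if intensities is not None:
        df["mean_intensity"] = intensities
    return ProbeProfile("s1", df)


class TestLowessNormalize:
    def test_constant_profile_centered_to_zero(self):
        out = lowess_normalize(_flat_profile(0.3))
        assert np.allclose(out.probes["log2_ratio"], 0.0)

    def test_median_centering_idempotent(self):
        rng = np.random.default_rng(1)
        prof = _flat_profile(0.0)
        prof.probes["log2_ratio"] = rng.normal(0.2, 0.5, len(prof.probes))
        once = lowess_normalize(prof)
        twice = lowess_normalize(once)
        assert np.max(np.abs(twice.probes["log2_ratio"]
                             - once.probes["log2_ratio"])) < 1e-8

    def test_intensity_bias_removed(self):
        rng = np.random.default_rng(2)
        n = 500
        intensity = rng.uniform(0, 100, n)
        ratio = 0.01 * intensity + rng.normal(0, 0.05, n)
        prof = _flat_profile(0.0, n=n, intensities=intensity)
        prof.probes["log2_ratio"] = ratio
        out = lowess_normalize(prof, span=0.3)
        corr = np.corrcoef(out.probes["log2_ratio"], intensity)[0, 1]
        assert abs(corr) < 0.05

    def test_bad_span_rejected(self):
        with pytest.raises(CrossCnaError):
            lowess_normalize(_flat_profile(), span=1.5)


class TestCbsSegment:
    def test_flat_noiseless_profile_single_segment(self):
        prof = _flat_profile(0.0, n=100)
        segs = cbs_segment(prof, SegmentationConfig(seed=1))
        assert len(segs) == 1
        assert segs[0].n_probes == 100
        assert segs[0].mean_log2 == 0.0

    def test_single_step_boundary_recovered(self):
        prof = step_profile(n=100, cp=50, shift=1.0, sd=0.1, seed=3)
        segs = cbs_segment(prof, SegmentationConfig(alpha=0.01, seed=3))
        cuts = _breakpoints(segs)
        assert len(cuts) == 1
        assert abs(cuts[0] - 50) <= 2
        # the accepted breakpoint maximizes the two-sample t over all splits
        x = prof.probes["log2_ratio"].to_numpy()
        assert cuts[0] == exhaustive_t_argmax(x)

    def test_short_chromosome_kept_whole(self):
        prof = _flat_profile(0.5, n=3)
        segs = cbs_segment(prof, SegmentationConfig(min_probes=2, seed=1))
        assert len(segs) == 1
        assert segs[0].n_probes == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_property(self, seed):
        """Every probe falls in exactly one segment per chromosome."""
        rng = np.random.default_rng(seed)
        n = 120
        x = rng.normal(0, 0.3, n)
        x[40:80] += rng.choice([-1.0, 1.0])
        prof = step_profile(n=n, cp=0, shift=0.0, sd=0.0, seed=0)
        prof.probes["log2_ratio"] = x
        segs = cbs_segment(prof, SegmentationConfig(seed=seed))
        assert sum(s.n_probes for s in segs) == n
        bounds = [(s.start, s.end) for s in segs]
        assert bounds == sorted(bounds)
        for (a, b), (c, d) in zip(bounds, bounds[1:]):
            assert b <= c

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), cp=st.integers(10, 50),
           shift=st.floats(-2, 2))
    def test_partition_holds_for_arbitrary_step_profiles(self, seed, cp, shift):
        prof = step_profile(n=60, cp=cp, shift=shift, sd=0.2, seed=seed)
        segs = cbs_segment(prof, SegmentationConfig(n_perm_ref=100, seed=seed))
        assert sum(s.n_probes for s in segs) == 60
        assert all(s.start < s.end for s in segs)

    def test_alpha_monotonicity(self):
        prof = step_profile(n=100, cp=50, shift=0.8, sd=0.25, seed=5)
        counts = []
        for alpha in (0.2, 0.05, 0.01, 0.001):
            segs = cbs_segment(prof, SegmentationConfig(alpha=alpha, seed=9))
            counts.append(len(segs))
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_for_fixed_seed(self):
        prof = step_profile(n=100, cp=30, shift=0.6, sd=0.3, seed=8)
        a = cbs_segment(prof, SegmentationConfig(seed=4))
        b = cbs_segment(prof, SegmentationConfig(seed=4))
        assert a == b

    def test_missing_probes_dropped_and_counted(self):
        prof = _flat_profile(0.0, n=50)
        prof.probes.loc[3, "log2_ratio"] = np.nan
        from crosscna.segmentation import segment_with_log
        segs, log = segment_with_log(prof, SegmentationConfig(seed=1))
        assert log.n_probes_dropped == 1
        assert sum(s.n_probes for s in segs) == 49


class TestCallSegments:
    @pytest.mark.parametrize("mean,expected", [
        (0.5, "gain"), (-0.5, "loss"), (0.0, "neutral"),
        (0.2, "gain"), (-0.2, "loss"),  # thresholds are inclusive
        (0.1999, "neutral"),
    ])
    def test_threshold_rule(self, mean, expected):
        from crosscna.types import Segment
        seg = Segment("s", "chr1", 0, 10, 2, mean)
        out = call_segments([seg], 0.2, -0.2)
        assert out[0].call == expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(CrossCnaError):
            call_segments([], -0.1, -0.2)
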