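"""Mean estimators: definitions, reductions, inequalities, robustness."""

import numpy as np
import pytest
from helpers import random_mode
from hypothesis import given, settings
from hypothesis import strategies as st

from mcetseg.estimators import (
    EstimatorSpec,
    alpha_trimmed_mean,
    classical_mean,
    contraharmonic_mean,
    estimate_means,
    geometric_mean,
    harmonic_mean,
    mode_mean,
)
from mcetseg.exceptions import (
    EmptyClassError,
    TrimExceedsClassSizeError,
    UnsupportedEstimatorError,
)
from mcetseg.histogram import compute_histogram

modes = st.lists(st.integers(min_value=1, max_value=256), min_size=1, max_size=80)


class TestDirectValues:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([2, 2, 4, 4], 3.0),
            ([7], 7.0),
            ([1, 2, 3, 4, 5, 100], 115 / 6),
        ],
    )
    def test_classical(self, values, expected):
        assert classical_mean(values) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "values, d2, expected",
        [
            ([1, 2, 3, 4, 5, 100], 1, 3.5),
            ([10, 10, 10], 1, 10.0),
        ],
    )
    def test_alpha_trim(self, values, d2, expected):
        assert alpha_trimmed_mean(values, d2) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 4], 12 / 7),
            ([5, 5, 5], 5.0),
            ([2, 8], 3.2),
        ],
    )
    def test_harmonic(self, values, expected):
        assert harmonic_mean(values) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "values, q, expected",
        [
            ([1, 2, 3], 1.0, 14 / 6),
            ([2, 8], 0.0, 5.0),
        ],
    )
    def test_contraharmonic(self, values, q, expected):
        assert contraharmonic_mean(values, q) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([2, 8], 4.0),
            ([3, 3, 3, 3], 3.0),
            ([1, 1, 8], 2.0),
        ],
    )
    def test_geometric(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected)

    def test_empty_mode_rejected(self):
        for fn in (classical_mean, harmonic_mean, geometric_mean):
            with pytest.raises(EmptyClassError):
                fn([])

    def test_trim_exceeding_class_size(self):
        with pytest.raises(TrimExceedsClassSizeError):
            alpha_trimmed_mean([1, 2, 3, 4], 2)

    def test_positional_trim_ignores_duplicate_values(self):
        # exactly one entry removed per end even when values repeat
        assert alpha_trimmed_mean([1, 1, 1, 9, 9, 9], 1) == pytest.approx(5.0)


class TestReductionIdentities:
    """The zero-parameter filters must reproduce the classical mean."""

    def test_on_random_modes(self, rng):
        for _ in range(100):
            mode = random_mode(rng)
            base = classical_mean(mode)
            assert contraharmonic_mean(mode, 0.0) == pytest.approx(base, rel=1e-9)
            assert alpha_trimmed_mean(mode, 0) == pytest.approx(base, rel=1e-9)
            assert contraharmonic_mean(mode, -1.0) == pytest.approx(
                harmonic_mean(mode), rel=1e-9
            )


class TestMeanInequalities:
    @settings(max_examples=200, deadline=None)
    @given(modes)
    def test_am_gm_hm_chain(self, values):
        hm = harmonic_mean(values)
        gm = geometric_mean(values)
        am = classical_mean(values)
        if len(set(values)) == 1:
            assert hm == pytest.approx(am) and gm == pytest.approx(am)
        else:
            assert hm < gm < am

    @settings(max_examples=100, deadline=None)
    @given(modes)
    def test_contraharmonic_monotone_in_q(self, values):
        if len(set(values)) == 1:
            return
        grid = [-3.0, -1.0, -0.5, 0.0, 0.1, 1.0]
        means = [contraharmonic_mean(values, q) for q in grid]
        assert all(a < b for a, b in zip(means, means[1:]))

    @settings(max_examples=100, deadline=None)
    @given(modes)
    def test_location_bounds(self, values):
        lo, hi = min(values), max(values)
        for mean in (
            classical_mean(values),
            harmonic_mean(values),
            geometric_mean(values),
            alpha_trimmed_mean(values, max((len(values) - 1) // 2 - 1, 0)),
        ):
            assert lo - 1e-12 <= mean <= hi + 1e-12


class TestTrimRobustness:
    def test_trim_shields_mean_from_high_outliers(self, rng):
        for _ in range(30):
            mode = np.sort(rng.integers(20, 120, size=100))
            clean = classical_mean(mode)
            k = int(rng.integers(1, 6))
            outliers = np.full(k, 256)
            enlarged = np.sort(np.concatenate([mode, outliers]))
            trimmed = alpha_trimmed_mean(enlarged, k)
            plain = classical_mean(enlarged)
            assert abs(trimmed - clean) < abs(plain - clean)


class TestEstimateMeans:
    def test_degenerate_classes_hit_spike_values(self, two_spike_histogram):
        assert estimate_means(
            two_spike_histogram, 100, EstimatorSpec("classical")
        ) == (10.0, 200.0)

    @pytest.mark.parametrize(
        "spec",
        [
            EstimatorSpec("contraharmonic", order=0.0),
            EstimatorSpec("alpha_trim", half_trim=0),
        ],
    )
    def test_reductions_match_classical(self, two_spike_histogram, spec):
        classical = estimate_means(two_spike_histogram, 100, EstimatorSpec("classical"))
        assert estimate_means(two_spike_histogram, 100, spec) == classical

    def test_weighted_path_matches_multiset_path(self, rng):
        """The count-weighted sweep form agrees with the per-pixel API."""
        from helpers import random_histogram
        from mcetseg.histogram import split_modes

        specs = [
            EstimatorSpec("classical"),
            EstimatorSpec("harmonic"),
            EstimatorSpec("geometric"),
            EstimatorSpec("contraharmonic", order=-0.5),
            EstimatorSpec("alpha_trim", half_trim=7),
        ]
        for _ in range(10):
            hist = random_histogram(rng, total=600)
            t = int(rng.integers(1, 256))
            try:
                mode1, mode2 = split_modes(hist, t)
            except EmptyClassError:
                continue
            for spec in specs:
                try:
                    expected = (mode_mean(mode1, spec), mode_mean(mode2, spec))
                except TrimExceedsClassSizeError:
                    continue
                mu1, mu2 = estimate_means(hist, t, spec)
                assert mu1 == pytest.approx(expected[0], rel=1e-12)
                assert mu2 == pytest.approx(expected[1], rel=1e-12)

    def test_empty_class_propagates(self, two_spike_histogram):
        with pytest.raises(EmptyClassError):
            estimate_means(two_spike_histogram, 250, EstimatorSpec("classical"))

    def test_lognormal_is_flagged_unsupported(self, two_spike_histogram):
        with pytest.raises(UnsupportedEstimatorError):
            estimate_means(two_spike_histogram, 100, EstimatorSpec("lognormal"))


class TestEstimatorSpec:
    @pytest.mark.parametrize(
        "text, method, param",
        [
            ("classical", "classical", None),
            ("harmonic", "harmonic", None),
            ("alpha_trim:50", "alpha_trim", 50),
            ("contraharmonic:-0.5", "contraharmonic", -0.5),
        ],
    )
    def test_parse_and_format_round_trip(self, text, method, param):
        spec = EstimatorSpec.parse(text)
        assert spec.method == method and spec.param == param
        assert EstimatorSpec.parse(str(spec)) == spec

    @pytest.mark.parametrize(
        "text",
        ["alpha_trim:-3", "alpha_trim:2.5", "alpha_trim", "contraharmonic",
         "classical:1", "median", "contraharmonic:inf"],
    )
    def test_invalid_specs_rejected(self, text):
        with pytest.raises(ValueError):
            EstimatorSpec.parse(text)
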