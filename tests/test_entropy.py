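"""Entropy core: oracle equivalence, identities, and examples."""

import numpy as np
import pytest

from expmse_decode.entropy import (EntropyParams, TemplateIndex,
                                   align_to_ml_rate, apen,
                                   build_template_index, coarse_grain,
                                   exp_sampen, feature_columns,
                                   interpolate_undefined, lsampen,
                                   match_counts, sampen, ExpSampEnSeries)
from expmse_decode.errors import ConfigError, UndefinedEntropyError

from oracles import (brute_apen, brute_exp_sampen, brute_lsampen,
                     brute_match_counts, brute_sampen)

P = EntropyParams(m=2, r=0.2)


class TestCoarseGrain:
    def test_tau_1_is_identity(self):
        x = np.arange(7.0)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_pairwise_means(self):
        np.testing.assert_array_equal(
            coarse_grain(np.array([1., 2, 3, 4, 5, 6]), 2),
            [1.5, 3.5, 5.5])

    def test_length_is_floor_n_over_tau(self):
        assert coarse_grain(np.zeros(480_000), 128).size == 3750

    def test_tau_exceeding_length_rejected(self):
        with pytest.raises(ConfigError):
            coarse_grain(np.zeros(5), 6)


class TestTemplateIndex:
    def test_concatenated_length_and_standardization(self):
        rng = np.random.default_rng(0)
        series = [rng.normal(size=10_000) for _ in range(68)]
        idx = build_template_index(series, tsf=2)
        assert idx.n == 68 * 5000 == 340_000
        assert abs(idx.values.mean()) <= 1e-9
        assert abs(idx.values.std() - 1.0) <= 1e-9

    def test_capping_stride_subsamples_templates_only(self):
        rng = np.random.default_rng(1)
        series = [rng.normal(size=3000) for _ in range(4)]
        idx = build_template_index(series, tsf=1, cap=5000)
        pos = idx.admissible_positions(2)
        assert pos.size <= 5000
        assert pos.size >= 2500  # within a factor 2 of the cap
        assert idx.n == 12_000   # query pool untouched

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedEntropyError):
            build_template_index([np.ones(100)], tsf=1)

    def test_mismatched_region_lengths_rejected(self):
        with pytest.raises(ConfigError):
            build_template_index([np.zeros(10), np.zeros(12)], tsf=1)


def _unstandardized_index(values, boundaries=None):
    values = np.asarray(values, dtype=float)
    if boundaries is None:
        boundaries = np.array([0, values.size], dtype=np.int64)
    return TemplateIndex(values=values.copy(),
                         boundaries=np.asarray(boundaries, dtype=np.int64))


class TestMatchCounts:
    def test_constant_index_matches_everything(self):
        idx = _unstandardized_index(np.zeros(50))
        A, B = match_counts(idx, np.zeros(2), 0.0, P)
        assert A == B == 48  # all admissible positions

    def test_alternating_pattern_is_deterministic(self):
        x = np.tile([0.0, 10.0], 30)
        idx = _unstandardized_index(x)
        A, B = match_counts(idx, np.array([0.0, 10.0]), 0.0, P)
        assert A > 0 and B == A  # the continuation is fully determined

    def test_matches_brute_force_on_seeded_noise(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=500)
        bounds = np.array([0, 250, 500])
        idx = _unstandardized_index(x, bounds)
        for _ in range(20):
            n = int(rng.integers(2, 500))
            if n < 2 or (250 <= n < 252):
                continue
            A, B = match_counts(idx, x[n - 2: n], x[n], P, self_position=n)
            A2, B2 = brute_match_counts(x, bounds, 2, 0.2, x[n - 2: n],
                                        x[n], self_position=n)
            assert (A, B) == (A2, B2)

    def test_b_never_exceeds_a(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        idx = _unstandardized_index(x)
        for n in range(2, 300, 7):
            A, B = match_counts(idx, x[n - 2: n], x[n], P, self_position=n)
            assert 0 <= B <= A


class TestExpSampEn:
    def test_equals_brute_force_everywhere(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=200)
        bounds = np.array([0, 100, 200])
        idx = _unstandardized_index(x, bounds)
        oracle = brute_exp_sampen(x, bounds, 2, 0.2)
        for b in range(2):
            block = x[bounds[b]: bounds[b + 1]]
            res = exp_sampen(block, idx, P, index_offset=int(bounds[b]))
            for i in range(block.size):
                o = oracle[bounds[b] + i]
                if np.isnan(o):
                    assert res.undefined_mask[i]
                else:
                    assert not res.undefined_mask[i]
                    assert abs(res.values[i] - o) <= 1e-12

    def test_defined_values_nonnegative(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        idx = _unstandardized_index(x)
        res = exp_sampen(x, idx, P, index_offset=0)
        assert (res.values[~res.undefined_mask] >= 0).all()

    def test_perfect_continuation_gives_zero(self):
        x = np.tile([0.0, 10.0], 40)
        idx = _unstandardized_index(x)
        res = exp_sampen(x, idx, P, index_offset=0)
        defined = ~res.undefined_mask
        assert defined.any()
        np.testing.assert_allclose(res.values[defined], 0.0, atol=1e-14)


class TestScalarStatistics:
    def test_all_match_brute_force(self):
        rng = np.random.default_rng(33)
        x = rng.normal(size=300)
        x = (x - x.mean()) / x.std()
        assert abs(apen(x, P) - brute_apen(x, 2, 0.2)) <= 1e-12
        assert abs(sampen(x, P) - brute_sampen(x, 2, 0.2)) <= 1e-12
        assert abs(lsampen(x, P) - brute_lsampen(x, 2, 0.2)) <= 1e-12

    def test_mean_exp_sampen_equals_apen_exactly(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=350)
        idx = _unstandardized_index(x)
        res = exp_sampen(x, idx, P, index_offset=0)
        defined = ~res.undefined_mask
        assert res.values[defined].mean() == pytest.approx(
            apen(x, P), abs=1e-14)

    def test_constant_series_has_zero_entropy(self):
        # zero-variance guard bypassed: counts on the raw series
        x = np.zeros(50)
        assert apen(x, P) == 0.0
        assert sampen(x, P) == 0.0
        assert lsampen(x, P) == 0.0

    def test_alternating_series_sampen_zero(self):
        x = np.tile([-1.0, 1.0], 40)
        assert sampen(x, P) == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ConfigError):
            sampen(np.zeros(3), P)


class TestInterpolation:
    def _series(self, values, mask):
        values = np.asarray(values, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        return ExpSampEnSeries(values=values, undefined_mask=mask,
                               A=np.zeros(values.size, dtype=np.int64),
                               B=np.zeros(values.size, dtype=np.int64))

    def test_no_gaps_is_identity(self):
        s = self._series([1.0, 2.0, 3.0], [False, False, False])
        np.testing.assert_array_equal(interpolate_undefined(s), [1, 2, 3])

    def test_interior_gap_linear(self):
        s = self._series([0.0, 99.0, 2.0], [False, True, False])
        np.testing.assert_allclose(interpolate_undefined(s), [0, 1, 2])

    def test_edge_gap_nearest_value(self):
        s = self._series([99.0, 1.0, 3.0], [True, False, False])
        np.testing.assert_allclose(interpolate_undefined(s), [1, 1, 3])

    def test_fully_undefined_rejected(self):
        s = self._series([0.0, 0.0], [True, True])
        with pytest.raises(UndefinedEntropyError):
            interpolate_undefined(s)


class TestMLAlignment:
    def test_six_seconds_give_nine_points(self):
        # 6 s at fs 400, tau 1: 2400 samples -> 9 bins of 256
        out = align_to_ml_rate(np.ones(2400), tsf=1, fs=400.0)
        assert out.size == 9

    def test_constant_input_constant_output(self):
        out = align_to_ml_rate(np.full(1000, 3.14), tsf=8, fs=400.0)
        np.testing.assert_allclose(out, 3.14)

    def test_tau_128_bins_average_two_coarse_samples(self):
        x = np.arange(100.0)
        out = align_to_ml_rate(x, tsf=128, fs=400.0)
        # 0.64 s = 256 raw samples = 2 coarse samples per bin
        np.testing.assert_allclose(out, (x[0::2] + x[1::2])[:out.size] / 2)

    def test_bin_shorter_than_coarse_sample_rejected(self):
        with pytest.raises(ConfigError):
            align_to_ml_rate(np.ones(100), tsf=512, fs=400.0)


class TestFeatureColumns:
    def test_thirty_columns_in_documented_order(self):
        cols = feature_columns()
        assert len(cols) == 30
        assert cols[0] == "gamma-Amp-A"
        assert cols[5] == "gamma-Phase-A"
        assert cols[10] == "beta-Amp-A"
        assert cols[-1] == "alpha-Phase-E"
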