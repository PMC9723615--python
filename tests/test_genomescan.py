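"""Windowed density scan: smoothing, binomial null, region calls, KS, groups."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mpradesign as m
from mpradesign.errors import ConfigError


def binomial_quantile_enumeration(n, p, q):
    """Smallest k with CDF >= q, by direct pmf summation (independent oracle)."""
    cdf = 0.0
    for k in range(n + 1):
        cdf += math.comb(n, k) * p**k * (1 - p) ** (n - k)
        if cdf >= q:
            return k
    return n


class TestSmoothTrack:
    def test_width_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0])
        assert np.array_equal(m.smooth_track(x, 1), x)

    def test_constant_track_fixed_point(self):
        x = np.full(50, 2.5)
        assert np.allclose(m.smooth_track(x, 9), x)

    def test_hand_computed_average(self):
        out = m.smooth_track([0, 0, 3, 0, 0], 3)
        assert np.allclose(out, [0, 1, 1, 1, 0])

    def test_edge_truncation_shrinks_window(self):
        out = m.smooth_track([6.0, 0.0, 0.0, 0.0], 3)
        assert out[0] == 3.0  # mean of first two only

    @pytest.mark.parametrize("width", [0, 2, 4])
    def test_even_or_nonpositive_width_rejected(self, width):
        with pytest.raises(ConfigError):
            m.smooth_track([1.0, 2.0], width)


class TestWindowProportions:
    def test_all_above_threshold(self):
        out = m.window_positive_proportion(np.ones(5000), 0.5, window=1000)
        assert (out["proportion"] == 1.0).all()

    def test_ten_megabase_track_gives_ten_thousand_windows(self):
        rng = np.random.default_rng(0)
        out = m.window_positive_proportion(rng.uniform(size=10_000_000), 0.95)
        assert len(out) == 10_000
        assert out["proportion"].mean() == pytest.approx(0.05, abs=0.001)

    def test_trailing_remainder_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="trailing"):
            out = m.window_positive_proportion(np.ones(2500), 0.5, window=1000)
        assert len(out) == 2

    def test_window_coordinates_half_open(self):
        out = m.window_positive_proportion(np.zeros(4000), 0.5, window=1000)
        assert out.loc[3, "start"] == 3000 and out.loc[3, "end"] == 4000

    def test_empty_track_rejected(self):
        with pytest.raises(ConfigError):
            m.window_positive_proportion(np.array([]), 0.5)


class TestUniformNullInterval:
    def test_published_defaults(self):
        iv = m.uniform_null_interval(1000, 0.05, 0.95)
        assert (iv.lower, iv.upper) == (0.037, 0.064)

    def test_zero_rate_degenerates(self):
        iv = m.uniform_null_interval(1000, 0.0, 0.95)
        assert (iv.lower, iv.upper) == (0.0, 0.0)

    def test_small_window_enumeration(self):
        iv = m.uniform_null_interval(10, 0.5, 0.95)
        assert (iv.lower, iv.upper) == (0.2, 0.8)

    @pytest.mark.parametrize("window,rate", [(1000, 0.05), (100, 0.1), (500, 0.02), (37, 0.3)])
    def test_agrees_with_exhaustive_cdf_enumeration(self, window, rate):
        iv = m.uniform_null_interval(window, rate, 0.95)
        assert iv.lower * window == binomial_quantile_enumeration(window, rate, 0.025)
        assert iv.upper * window == binomial_quantile_enumeration(window, rate, 0.975)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigError):
            m.uniform_null_interval(1000, 1.5, 0.95)


class TestClassifyRegions:
    def _summaries(self, proportions):
        return pd.DataFrame({"proportion": proportions})

    def test_at_rate_all_neutral(self):
        iv = m.uniform_null_interval(1000, 0.05, 0.95)
        _, fr = m.classify_regions(self._summaries([0.05] * 10), iv)
        assert fr == {"active": 0.0, "inactive": 0.0, "neutral": 1.0}

    def test_three_way_calls(self):
        iv = m.NullInterval(lower=0.037, upper=0.064)
        called, _ = m.classify_regions(self._summaries([0.0, 0.05, 1.0]), iv)
        assert called["call"].tolist() == ["inactive", "neutral", "active"]

    def test_fractions_sum_to_one_and_permutation_invariant(self):
        rng = np.random.default_rng(1)
        props = rng.uniform(size=300)
        iv = m.NullInterval(lower=0.3, upper=0.7)
        _, fr1 = m.classify_regions(self._summaries(props), iv)
        _, fr2 = m.classify_regions(self._summaries(rng.permutation(props)), iv)
        assert fr1 == fr2
        assert sum(fr1.values()) == pytest.approx(1.0)

    def test_null_calibration_on_uniform_tracks(self):
        """Uniform tracks: non-neutral fraction stays near 1 - coverage."""
        iv = m.uniform_null_interval(1000, 0.05, 0.95)
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            counts = rng.binomial(1000, 0.05, size=10_000)
            _, fr = m.classify_regions(self._summaries(counts / 1000), iv)
            rates.append(fr["active"] + fr["inactive"])
        assert np.mean(rates) <= 0.05 + 0.01

    def test_bimodal_track_called_non_neutral(self):
        cfg = m.SynthConfig(clump_rate_active=0.5, clump_rate_inactive=0.005, seed=3)
        track = m.generate_genome_track(2_000_000, cfg)
        summaries = m.window_positive_proportion(track.scores, track.threshold)
        _, fr = m.classify_regions(summaries, m.uniform_null_interval())
        assert fr["active"] + fr["inactive"] > 0.9


class TestKolmogorovSmirnov:
    def test_null_sample_not_rejected(self):
        rng = np.random.default_rng(2)
        props = rng.binomial(1000, 0.05, size=10_000) / 1000
        _, p = m.ks_goodness_of_fit(props, 1000, 0.05)
        assert p > 0.01

    def test_all_zero_statistic_closed_form(self):
        stat, p = m.ks_goodness_of_fit(np.zeros(100), 1000, 0.05)
        assert stat == pytest.approx(1 - 0.95**1000, abs=1e-12)
        assert p < 1e-10

    def test_degenerate_null_statistic_zero(self):
        stat, _ = m.ks_goodness_of_fit(np.zeros(100), 1000, 0.0)
        assert stat == 0.0

    def test_too_few_windows_rejected(self):
        with pytest.raises(ConfigError):
            m.ks_goodness_of_fit(np.zeros(5), 1000, 0.05)


class TestCompareGroups:
    def test_identical_groups_null_results(self):
        x = pd.DataFrame({"Q": [1.0, 2.0, 3.0] * 2})
        res = m.compare_groups(x, [0, 0, 0, 1, 1, 1], kinds={"Q": "quantitative"})
        assert res.loc[0, "statistic"] == 0.0
        assert res.loc[0, "p"] == 1.0

    def test_balanced_contingency_statistic_zero(self):
        x = pd.DataFrame({"B": [0] * 10 + [1] * 10 + [0] * 10 + [1] * 10})
        g = [0] * 20 + [1] * 20
        res = m.compare_groups(x, g, kinds={"B": "qualitative"})
        assert res.loc[0, "statistic"] == 0.0

    def test_planted_shift_survives_bonferroni(self):
        """Shift d=1 at n=200/group: significant at the family-corrected level."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200)])
            g = np.repeat([0, 1], 200)
            tab = pd.DataFrame({"Q": vals})
            res = m.compare_groups(tab, g, kinds={"Q": "quantitative"}, alpha=0.05)
            hits += res.loc[0, "p"] < 0.05 / 20
        assert hits >= 9

    def test_family_size_sets_threshold(self):
        rng = np.random.default_rng(9)
        tab = pd.DataFrame({f"Q{i}": rng.normal(size=100) for i in range(10)})
        tab["Q0"] += np.repeat([0.0, 0.6], 50)
        g = np.repeat([0, 1], 50)
        res = m.compare_groups(tab, g)
        row = res.set_index("annotation").loc["Q0"]
        assert row["significant"] == (row["p"] < 0.05 / 10)

    def test_small_group_rejected(self):
        tab = pd.DataFrame({"Q": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigError):
            m.compare_groups(tab, [0, 1, 1], kinds={"Q": "quantitative"})

    def test_three_groups_rejected(self):
        tab = pd.DataFrame({"Q": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigError):
            m.compare_groups(tab, [0, 1, 2])
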