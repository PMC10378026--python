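"""Channel maps, group statistics and the synthetic multichannel generator."""

import numpy as np
import pytest
from scipy import stats

from petd.group_stats import (
    ChannelMap,
    average_maps,
    bootstrap_corr_difference,
    channel_maps,
    fisher_z_test,
    map_correlation,
    ranksum_groups,
    synth_multichannel,
)
from petd.io import MultichannelSeries

from conftest import tiled_sine


def sine_record(periods, n_periods_of_longest=50, fs=250.0):
    longest = max(periods)
    n = longest * n_periods_of_longest
    data = []
    for p in periods:
        one = np.sin(2 * np.pi * np.arange(p) / p)
        data.append(np.tile(one, n // p)[:n])
    return MultichannelSeries(
        np.asarray(data), fs, tuple(f"ch{i}_{p}" for i, p in enumerate(periods))
    )


def make_map(values, labels=None):
    labels = labels or tuple(f"c{i}" for i in range(len(values)))
    return ChannelMap(labels, np.asarray(values, float), "test")


class TestChannelMaps:
    def test_identical_channels_identical_values(self):
        mc = sine_record([40, 40, 40])
        m = channel_maps(mc, "pe-td", tau_max=80)
        assert np.all(m.values == m.values[0])

    def test_pe_td_to_acw0_ratio_4_on_sinusoids(self):
        mc = sine_record([20, 40, 60])
        pe = channel_maps(mc, "pe-td", tau_max=100)
        aw = channel_maps(mc, "acw-0", window_s=1e9)  # force whole-trace
        ratios = pe.values / aw.values
        # integer-lag zero crossing can overshoot the ideal quarter period
        # by one sample under the biased (divide-by-N) ACF estimator
        assert np.allclose(ratios, 4.0, rtol=0.25)

    def test_average_maps_requires_matched_labels(self):
        a = make_map([1, 2, 3])
        b = ChannelMap(("x", "y", "z"), np.ones(3), "test")
        with pytest.raises(ValueError, match="labels"):
            average_maps([a, b])
        avg = average_maps([a, make_map([3, 4, 5])])
        assert np.allclose(avg.values, [2, 3, 4])


class TestMapCorrelation:
    def test_monotone_transform_gives_unit_spearman(self):
        a = make_map([0.1, 0.3, 0.2, 0.5, 0.4])
        b = make_map(2 * a.values)
        r, p = map_correlation(a, b)
        assert r == pytest.approx(1.0, abs=1e-9)
        b = make_map(np.exp(a.values))  # any strictly monotone transform
        assert map_correlation(a, b)[0] == pytest.approx(1.0, abs=1e-9)

    def test_negated_map(self):
        a = make_map([0.1, 0.3, 0.2, 0.5, 0.4])
        r, _ = map_correlation(a, make_map(-a.values))
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_independent_maps_small_r(self, rng):
        a = make_map(rng.standard_normal(200))
        b = make_map(rng.standard_normal(200))
        r, p = map_correlation(a, b)
        assert abs(r) < 0.2
        assert p > 0.001

    def test_errors(self):
        a = make_map([1, 2, 3])
        with pytest.raises(ValueError, match="labels"):
            map_correlation(a, ChannelMap(("a", "b", "c"), np.ones(3), "t"))
        with pytest.raises(ValueError, match="constant"):
            map_correlation(a, make_map([1, 1, 1]))
        with pytest.raises(ValueError, match="at least 3"):
            map_correlation(make_map([1, 2]), make_map([2, 1]))


class TestFisherZ:
    def test_equal_correlations(self):
        z, p = fisher_z_test(0.7, 100, 0.7, 50)
        assert z == 0.0
        assert p == 1.0

    def test_closed_form_large_contrast(self):
        # the healthy-vs-unresponsive style contrast: 0.90 vs 0.55 at n=244
        z, p = fisher_z_test(0.90, 244, 0.55, 244)
        manual = (np.arctanh(0.90) - np.arctanh(0.55)) / np.sqrt(2 / 241)
        assert z == pytest.approx(manual)
        assert p < 0.001

    def test_antisymmetry(self):
        z1, p1 = fisher_z_test(0.8, 50, 0.3, 60)
        z2, p2 = fisher_z_test(0.3, 60, 0.8, 50)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fisher_z_test(1.0, 50, 0.5, 50)
        with pytest.raises(ValueError):
            fisher_z_test(0.5, 3, 0.5, 50)


class TestRanksum:
    def test_identical_groups(self):
        stat, p = ranksum_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)

    def test_shifted_groups_significant(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 3.0
        _, p = ranksum_groups(a, b)
        assert p < 0.001

    def test_monotone_invariance(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 1.0
        _, p1 = ranksum_groups(a, b)
        _, p2 = ranksum_groups(np.exp(a), np.exp(b))
        assert p1 == p2

    def test_all_tied_warns(self):
        with pytest.warns(RuntimeWarning, match="tied"):
            ranksum_groups([2.0, 2.0], [2.0, 2.0])


class TestBootstrapCorrDifference:
    def test_identical_groups_p_near_one(self, rng):
        x = rng.standard_normal(50)
        y = x + 0.5 * rng.standard_normal(50)
        comp = bootstrap_corr_difference(x, y, x, y, n_boot=2000, seed=1)
        assert comp.p_boot > 0.5
        assert comp.r_group1 == comp.r_group2

    def test_strong_contrast_detected_and_agrees_with_fisher(self, rng):
        n = 200
        x1 = rng.standard_normal(n)
        y1 = 0.9 * x1 + 0.45 * rng.standard_normal(n)  # r ~ 0.9
        x2 = rng.standard_normal(n)
        y2 = rng.standard_normal(n)  # r ~ 0
        comp = bootstrap_corr_difference(x1, y1, x2, y2, n_boot=4000, seed=2)
        assert comp.p_boot < 0.01
        assert comp.p_fisher < 0.001
        assert abs(comp.p_boot - comp.p_fisher) < 0.05

    def test_seed_reproducible_bitwise(self, rng):
        x1, y1 = rng.standard_normal(30), rng.standard_normal(30)
        x2, y2 = rng.standard_normal(30), rng.standard_normal(30)
        a = bootstrap_corr_difference(x1, y1, x2, y2, n_boot=500, seed=9)
        b = bootstrap_corr_difference(x1, y1, x2, y2, n_boot=500, seed=9)
        assert a == b

    def test_seed_only_perturbs_p_within_mc_error(self, rng):
        n = 80
        x1 = rng.standard_normal(n)
        y1 = 0.5 * x1 + rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y2 = 0.4 * x2 + rng.standard_normal(n)
        ps = [
            bootstrap_corr_difference(x1, y1, x2, y2, n_boot=4000, seed=s).p_boot
            for s in (1, 2)
        ]
        se = np.sqrt(ps[0] * (1 - ps[0]) / 4000)
        assert abs(ps[0] - ps[1]) < max(3 * se, 0.02)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="matching"):
            bootstrap_corr_difference([1, 2, 3], [1, 2], [1, 2, 3], [1, 2, 3])


class TestSyntheticMultichannel:
    def test_gradient_recovered_by_pe_td_map(self):
        subs = synth_multichannel(2, 16, regime="conscious-like", seed=4)
        maps = [channel_maps(s, "pe-td") for s in subs]
        avg = average_maps(maps)
        rho = stats.spearmanr(avg.values, np.arange(16)).statistic
        assert rho > 0.9

    def test_conscious_regime_high_map_agreement(self):
        subs = synth_multichannel(2, 16, regime="conscious-like", seed=4)
        pe = average_maps([channel_maps(s, "pe-td") for s in subs])
        aw = average_maps([channel_maps(s, "acw-0") for s in subs])
        r, p = map_correlation(pe, aw)
        assert r > 0.8
        assert p < 0.001

    def test_deterministic_and_distinct_subjects(self):
        a = synth_multichannel(2, 4, seed=11)
        b = synth_multichannel(2, 4, seed=11)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))
        assert not np.array_equal(a[0].data, a[1].data)

    def test_regime_validation(self):
        with pytest.raises(ValueError, match="regime"):
            synth_multichannel(1, 4, regime="asleep")
        with pytest.raises(ValueError, match="channels"):
            synth_multichannel(1, 1)
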