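"""Distribution statistics, top-N selection and calibration fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shellproxy as sp
from shellproxy.proxystats import TemperatureGroup


def brute_force_ks(a, b):
    """Independent oracle: sup of |F_a - F_b| over every observed point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        d = abs((a <= x).mean() - (b <= x).mean())
        best = max(best, d)
    return best


def _group(areas, temperature=1.0, kind="BMU"):
    recs = [
        sp.ParticleRecord(i, kind, 10, float(a), 1.0, (0, 0), f"s{i % 3}", temperature)
        for i, a in enumerate(areas)
    ]
    return TemperatureGroup(temperature, recs)


class TestECDF:
    def test_step_values(self):
        f = sp.ecdf([1.0, 2.0, 3.0])
        assert f(2.0) == pytest.approx(2 / 3)
        assert f(0.5) == 0.0 and f(3.0) == 1.0

    def test_all_equal_single_jump(self):
        f = sp.ecdf([2.0, 2.0, 2.0])
        assert f(1.9999) == 0.0 and f(2.0) == 1.0

    def test_quantile_matches_sort_and_index_oracle(self, rng):
        values = rng.lognormal(0, 1, size=503)
        f = sp.ecdf(values)
        srt = np.sort(values)
        for p in (0.5, 0.9, 0.999):
            assert f.quantile(p) == srt[math.ceil(p * len(values)) - 1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sp.ecdf([])


class TestKolmogorovSmirnov:
    def test_identical_samples_zero(self):
        assert sp.ks_two_sample([1, 2, 3], [1, 2, 3])[0] == 0.0

    def test_disjoint_samples_one(self):
        assert sp.ks_two_sample([0, 0, 0], [1, 1, 1])[0] == 1.0

    def test_interleaved_thirds(self):
        d, _ = sp.ks_two_sample([1, 2, 3], [1.5, 2.5, 3.5])
        assert d == pytest.approx(1 / 3)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 20), min_size=2, max_size=50),
        b=st.lists(st.integers(0, 20), min_size=2, max_size=50),
    )
    def test_matches_brute_force_oracle(self, a, b):
        d, _ = sp.ks_two_sample(a, b)
        assert d == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            sp.ks_two_sample([1.0], [1, 2, 3])


class TestTopN:
    def test_three_largest_of_six(self):
        g = _group([5, 1, 4, 2, 6, 3])
        assert [r.area for r in sp.top_n(g, n=3)] == [6, 5, 4]

    def test_n_exceeding_group_warns_and_returns_all(self):
        g = _group([1, 2])
        with pytest.warns(UserWarning, match="only 2"):
            assert len(sp.top_n(g, n=15)) == 2

    def test_boundary_ties_resolved_deterministically(self):
        areas = [3.0, 2.0, 2.0, 2.0, 1.0]
        g = _group(areas)
        first = [(r.specimen_id, r.entity_id) for r in sp.top_n(g, n=3)]
        for _ in range(5):
            assert [(r.specimen_id, r.entity_id) for r in sp.top_n(_group(areas), n=3)] == first

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            sp.top_n(_group([1.0]), n=0)

    def test_pairs_pooled_vs_group_means(self):
        groups = [_group([1, 2, 3, 4], temperature=1.0), _group([5, 6, 7, 8], temperature=15.0)]
        areas, temps = sp.top_n_pairs(groups, n=2)
        assert areas == [4, 3, 8, 7] and temps == [1.0, 1.0, 15.0, 15.0]
        areas, temps = sp.top_n_pairs(groups, n=2, aggregate="group_means")
        assert areas == [3.5, 7.5] and temps == [1.0, 15.0]


class TestSpearman:
    def test_perfect_monotone(self):
        assert sp.spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
        assert sp.spearman([1, 2, 3, 4], [8, 6, 4, 2])[0] == -1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.1, 100), min_size=4, max_size=30, unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        ys = list(range(len(xs)))
        r1, _ = sp.spearman(xs, ys)
        r2, _ = sp.spearman(np.log(xs), ys)  # strictly monotone transform
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = sp.spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert math.isnan(r)


class TestThresholdSensitivity:
    def _sampling_groups(self, tail_fraction, seed=77):
        groups = []
        for ti, temp in enumerate((1.0, 3.0, 6.0, 9.0, 12.0, 15.0)):
            recs = []
            for s in range(3):
                cfg = sp.SyntheticConfig(
                    seed=seed + 1000 * ti + s, temperature=temp, tail_fraction=tail_fraction
                )
                for j, x in enumerate(sp.sample_bmu_population(cfg)):
                    recs.append(
                        sp.ParticleRecord(j, "BMU", 10, x.size_um2, 1.0, (0, 0), f"s{s}", temp)
                    )
            groups.append(TemperatureGroup(temp, recs))
        return groups

    def test_correlation_decays_into_the_bulk(self):
        # only the upper tail scales with temperature, so r falls as the
        # subset grows into the invariant bulk
        curve = dict(
            (n, r) for n, r, _ in sp.threshold_sensitivity(self._sampling_groups(0.012), [15, 500])
        )
        assert curve[15] > curve[500]

    def test_no_tail_no_signal(self):
        curve = sp.threshold_sensitivity(self._sampling_groups(0.0), [15])
        assert abs(curve[0][1]) < 0.3

    def test_single_point_curve(self):
        curve = sp.threshold_sensitivity(self._sampling_groups(0.012), [15])
        assert len(curve) == 1 and curve[0][0] == 15


class TestCalibrationFits:
    def test_exact_exponential_recovery(self):
        t = np.array([1.0, 3.0, 6.0, 9.0, 12.0, 15.0])
        s = 2.0 * np.exp(0.15 * t)
        m = sp.fit_exponential(t, s)
        assert m.params["a"] == pytest.approx(2.0, rel=1e-6)
        assert m.params["b"] == pytest.approx(0.15, rel=1e-6)
        assert m.r_squared == pytest.approx(1.0)

    def test_exact_linear_recovery(self):
        t = np.array([1.0, 3.0, 6.0, 9.0, 12.0, 15.0])
        m = sp.fit_linear(t, 1.5 + 0.6 * t)
        assert m.params["alpha"] == pytest.approx(1.5)
        assert m.params["beta"] == pytest.approx(0.6)

    def test_constant_areas_give_flat_models(self):
        t = [1.0, 6.0, 15.0, 9.0]
        with pytest.warns(UserWarning):
            lin = sp.fit_linear(t, [2.0] * 4)
            expm = sp.fit_exponential(t, [2.0] * 4)
        assert lin.params["beta"] == pytest.approx(0.0, abs=1e-12)
        assert expm.params["b"] == pytest.approx(0.0, abs=1e-8)

    def test_two_point_endpoint_rate(self):
        # exponential through the endpoint group means 0.68 μm² @ 1 °C and
        # 10.13 μm² @ 15 °C: b = ln(10.13/0.68)/14 by the closed form
        b_expected = math.log(10.13 / 0.68) / 14
        t = np.array([1.0, 8.0, 15.0])
        a0 = 0.68 / math.exp(b_expected)
        s = a0 * np.exp(b_expected * t)
        m = sp.fit_exponential(t, s)
        assert m.params["b"] == pytest.approx(b_expected, rel=1e-6)
        assert m.params["b"] == pytest.approx(0.1929, abs=2e-4)

    def test_nonpositive_areas_fall_back_to_two_point_init(self):
        t = np.array([1.0, 1.0, 8.0, 15.0, 15.0])
        s = np.array([0.0, 0.6, 2.0, 9.0, 11.0])  # zero blocks the log step
        m = sp.fit_exponential(t, s)
        assert m.params["b"] > 0

    def test_linear_negativity_diagnostic(self):
        # a steep positive slope with small intercept predicts negative sizes
        # near 0 °C — the documented failure mode for pores
        t = np.array([1.0, 3.0, 6.0, 9.0, 12.0, 15.0])
        m = sp.fit_linear(t, -1.0 + 0.7 * t)
        assert m.diagnostics["predicts_negative_on_0_16C"]

    def test_needs_three_distinct_temperatures(self):
        with pytest.raises(ValueError, match="distinct"):
            sp.fit_linear([1.0, 1.0, 2.0], [1, 2, 3])


class TestPredictTemperature:
    def test_forward_inverse_consistency(self):
        t = np.array([1.0, 3.0, 6.0, 9.0, 12.0, 15.0])
        m = sp.fit_exponential(t, 0.6 * np.exp(0.19 * t))
        for T in (2.0, 9.0, 14.0):
            pred = sp.predict_temperature(m, m.predict(T))
            assert pred.temperature == pytest.approx(T, abs=1e-6)
            assert not pred.extrapolated

    def test_extrapolation_flag_below_range(self):
        t = np.array([1.0, 3.0, 6.0, 9.0, 12.0, 15.0])
        m = sp.fit_exponential(t, 0.6 * np.exp(0.19 * t))
        pred = sp.predict_temperature(m, 0.5 * m.predict(1.0))
        assert pred.extrapolated

    def test_leave_one_temperature_out_recovery(self):
        # sampling-level cross-validation on the default generator ladder
        temps = (1.0, 3.0, 6.0, 9.0, 12.0, 15.0)
        tops = {}
        for ti, temp in enumerate(temps):
            areas = []
            for s in range(3):
                cfg = sp.SyntheticConfig(seed=11 + 1000 * ti + s, temperature=temp)
                areas += [x.size_um2 for x in sp.sample_bmu_population(cfg)]
            tops[temp] = sorted(areas, reverse=True)[:15]
        for held in (3.0, 6.0, 9.0, 12.0):
            pairs = [(a, T) for T, v in tops.items() if T != held for a in v]
            m = sp.fit_linear([t for _, t in pairs], [a for a, _ in pairs])
            pred = sp.predict_temperature(m, float(np.mean(tops[held])))
            assert pred.temperature == pytest.approx(held, abs=2.0)

    def test_invalid_inversions_rejected(self):
        t = np.array([1.0, 3.0, 6.0, 9.0, 12.0, 15.0])
        m = sp.fit_exponential(t, 0.6 * np.exp(0.19 * t))
        with pytest.raises(ValueError):
            sp.predict_temperature(m, -1.0)
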