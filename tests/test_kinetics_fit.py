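"""Exponential and gamma-survival fitting, bootstrap CIs, ratio decay."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optokinetics.core_model import CascadeParams, gamma_survival, survival_quantile
from optokinetics.kinetics_fit import (
    DecayTrace,
    bootstrap_ci,
    fit_exponential,
    fit_gamma_survival,
    normalize_trace,
    ratio_decay_halflife,
    time_to_fraction,
    time_to_half_max,
)
from optokinetics.synthetic_data import gen_lovtrap_traces


def make_trace(times, values, t_zero=0.0):
    return DecayTrace(np.asarray(times, float), np.asarray(values, float), t_zero=t_zero)


class TestNormalizeTrace:
    def test_linear_rescale_example(self):
        # pre-mean 2.0, min 0.5 => value 1.25 maps to 0.5
        times = np.arange(-3.0, 4.0)
        values = np.array([2.0, 2.0, 2.0, 1.25, 0.5, 1.25, 2.0])
        out = normalize_trace(make_trace(times, values))
        assert out.values[3] == pytest.approx(0.5)
        assert out.values[:3] == pytest.approx(1.0)
        assert out.values.min() == pytest.approx(0.0)

    def test_constant_trace_flagged_degenerate(self):
        out = normalize_trace(make_trace(np.arange(-3.0, 5.0), np.full(8, 2.0)))
        assert out.meta["degenerate"]
        assert np.all(out.values == 0.0)

    def test_requires_baseline_points(self):
        with pytest.raises(ValueError):
            normalize_trace(make_trace(np.arange(5.0), np.ones(5), t_zero=0.0))

    def test_baseline_subtract_mode_max_is_one(self):
        times = np.arange(-5.0, 20.0)
        values = 1.0 + np.exp(-0.3 * np.clip(times, 0, None)) * (times >= 0) * 2.0
        out = normalize_trace(make_trace(times, values), mode="baseline_subtract_scale_max")
        assert out.values.max() == pytest.approx(1.0)


class TestFitExponential:
    def test_noiseless_dissociation_rate(self):
        t = np.arange(0.0, 26.0)
        trace = make_trace(t, np.exp(-0.88 * t))
        fit = fit_exponential(trace, "decay")
        assert fit.rate == pytest.approx(0.88, rel=1e-3)

    def test_noiseless_association_rate(self):
        t = np.arange(0.0, 101.0)
        trace = make_trace(t, 1.0 - np.exp(-0.04 * t))
        fit = fit_exponential(trace, "rise")
        assert fit.rate == pytest.approx(0.04, rel=1e-3)

    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_equivariance(self, scale):
        t = np.arange(0.0, 30.0)
        rng = np.random.default_rng(7)
        base = 0.1 + np.exp(-0.5 * t) + rng.normal(0, 0.01, t.size)
        f1 = fit_exponential(make_trace(t, base), "decay")
        f2 = fit_exponential(make_trace(t, scale * base), "decay")
        assert f2.rate == pytest.approx(f1.rate, rel=1e-6)
        assert f2.amplitude == pytest.approx(scale * f1.amplitude, rel=1e-6)

    def test_noisy_replicate_recovery(self):
        traces, truth = gen_lovtrap_traces(n=12, seed=11)
        rates = []
        for tr in traces:
            norm = normalize_trace(tr)
            rates.append(fit_exponential(norm.window(25.0, 50.0), "decay").rate)
        assert np.mean(rates) == pytest.approx(truth["k_off"], rel=0.10)


class TestTimeToFraction:
    def _fit(self, rate, direction="decay"):
        t = np.arange(0.0, 200.0)
        y = np.exp(-rate * t) if direction == "decay" else 1 - np.exp(-rate * t)
        return fit_exponential(make_trace(t, y), direction)

    def test_association_near_completion_time(self):
        fit = self._fit(0.04, "rise")
        assert time_to_fraction(fit, 0.05) == pytest.approx(np.log(20) / 0.04, rel=1e-3)
        assert time_to_fraction(fit, 0.05) == pytest.approx(74.9, abs=0.5)

    def test_dissociation_near_completion_time(self):
        fit = self._fit(0.88, "decay")
        t95 = time_to_fraction(fit, 0.05)
        assert t95 == pytest.approx(3.40, abs=0.05)
        assert t95 <= 3.5

    def test_unit_rate_identity(self):
        fit = self._fit(1.0)
        assert time_to_fraction(fit, np.exp(-1)) == pytest.approx(1.0, rel=1e-3)


class TestFitGammaSurvival:
    def test_noiseless_calcium_default_recovery(self):
        params = CascadeParams(5, 6.21)
        t = np.arange(0.0, 160.0, 2.0)
        fit = fit_gamma_survival(make_trace(t, gamma_survival(t, params)))
        assert fit.shape == 5
        assert fit.half_life == pytest.approx(29.0, abs=0.1)
        assert fit.onset_time == pytest.approx(7.94, abs=0.1)
        assert fit.half_life > fit.onset_time > 0

    def test_exponential_data_selects_shape_one(self):
        t = np.arange(0.0, 100.0, 2.0)
        fit = fit_gamma_survival(make_trace(t, np.exp(-t / 20.0)))
        assert fit.shape == 1
        assert fit.scale == pytest.approx(20.0, rel=1e-4)

    def test_shape_one_grid_matches_exponential_rate(self):
        t = np.arange(0.0, 100.0, 2.0)
        y = np.exp(-t / 15.0)
        gfit = fit_gamma_survival(make_trace(t, y), shape_grid=[1])
        efit = fit_exponential(make_trace(t, y), "decay")
        assert 1.0 / gfit.scale == pytest.approx(efit.rate, rel=1e-3)

    def test_half_life_increases_with_shape_at_fixed_mean_delay(self):
        halves = [survival_quantile(CascadeParams(k, 30.0 / k), 0.5) for k in range(1, 9)]
        assert np.all(np.diff(halves) > 0)

    def test_noisy_onset_recovery(self):
        rng = np.random.default_rng(5)
        params = CascadeParams(5, 6.21)
        t = np.arange(0.0, 160.0, 2.0)
        onsets = []
        for _ in range(8):
            y = gamma_survival(t, params) + rng.normal(0, 0.03, t.size)
            onsets.append(fit_gamma_survival(make_trace(t, y)).onset_time)
        assert np.mean(onsets) == pytest.approx(7.94, rel=0.25)


class TestBootstrapCI:
    @staticmethod
    def _half_life_op(trace):
        return fit_gamma_survival(trace).half_life

    def _replicates(self, noise, seed=3, n=4):
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 160.0, 2.0)
        clean = gamma_survival(t, CascadeParams(5, 6.21))
        return [make_trace(t, clean + rng.normal(0, noise, t.size)) for _ in range(n)]

    def test_identical_replicates_zero_width(self):
        traces = self._replicates(0.0)
        lo, hi = bootstrap_ci(traces, self._half_life_op, n_boot=100, seed=0)
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_seeded_determinism(self):
        traces = self._replicates(0.05)
        a = bootstrap_ci(traces, self._half_life_op, n_boot=150, seed=42)
        b = bootstrap_ci(traces, self._half_life_op, n_boot=150, seed=42)
        assert a == b

    def test_width_shrinks_with_noise(self):
        wide = bootstrap_ci(self._replicates(0.08), self._half_life_op, n_boot=120, seed=1)
        narrow = bootstrap_ci(self._replicates(0.01), self._half_life_op, n_boot=120, seed=1)
        assert (narrow[1] - narrow[0]) < (wide[1] - wide[0])

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning):
            bootstrap_ci(self._replicates(0.01), self._half_life_op, n_boot=50, seed=0)


class TestRatioDecay:
    def test_known_mrna_half_life(self):
        t = np.arange(0.0, 65.0, 5.0)
        light = pd.Series(np.exp(-np.log(2) / 25.0 * t), index=t)
        dark = pd.Series(np.ones_like(t), index=t)
        out = ratio_decay_halflife(light, dark)
        assert out.half_life == pytest.approx(25.0, rel=1e-3)
        assert out.half_crossing == pytest.approx(25.0, abs=1.5)

    def test_identical_arms_flagged_infinite(self):
        t = np.arange(0.0, 65.0, 5.0)
        arm = pd.Series(np.ones_like(t), index=t)
        out = ratio_decay_halflife(arm, arm)
        assert not out.finite
        assert np.isinf(out.half_life)

    def test_nonpositive_dark_rejected(self):
        t = np.arange(0.0, 65.0, 5.0)
        with pytest.raises(ValueError):
            ratio_decay_halflife(pd.Series(1.0, index=t), pd.Series(0.0, index=t))


class TestTimeToHalfMax:
    def test_linear_interpolation_crossing(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        v = np.array([1.0, 1.0, 0.6, 0.2])
        # target 0.5 crossed between t=2 (0.6) and t=3 (0.2)
        assert time_to_half_max(t, v, t_start=1.0) == pytest.approx(1.25)
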