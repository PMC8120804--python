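"""Generator contracts: documented kinetics, determinism, ground-truth sidecars."""

import json

import numpy as np
import pandas as pd
import pytest

from optokinetics.core_model import StimulusProfile
from optokinetics.synthetic_data import (
    gen_calcium_events,
    gen_ct_table,
    gen_endpoint_population,
    gen_lovtrap_traces,
    gen_membrane_stack,
    gen_pperk_samples,
    gen_plate_measurements,
    gen_western_lanes,
    generate_study,
)

HOUR = 3600.0


class TestLovtrapTraces:
    def test_noiseless_dissociation_depth(self):
        traces, _ = gen_lovtrap_traces(n=1, seed=0, noise_sd=0.0)
        tr = traces[0]
        # bound fraction at end of the 25-s illumination is e^(-0.88*25) of start
        v0 = tr.values[tr.times == 24.0][0]
        v1 = tr.values[tr.times == 50.0][0]
        baseline = tr.values.min()
        assert (v1 - baseline) / (v0 - baseline) == pytest.approx(np.exp(-0.88 * 25), abs=1e-6)

    def test_default_sample_size_matches_experiment(self):
        traces, truth = gen_lovtrap_traces()
        assert len(traces) == truth["n"] == 12

    def test_seed_determinism(self):
        a, _ = gen_lovtrap_traces(seed=5)
        b, _ = gen_lovtrap_traces(seed=5)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.values, tb.values)


class TestCalciumEvents:
    def test_pre_dimerizer_ratio_flat_at_baseline(self):
        events, truth = gen_calcium_events(seed=3)
        conj = events[events["is_conjugate"]]
        pre = conj[conj["acquisition_time"] < truth["t_dimerizer"]]
        ratio = (pre["indo_405"] - 50.0) / (pre["indo_485"] - 50.0)
        # lognormal measurement noise inflates the mean by exp(sd^2/2)
        assert ratio.mean() == pytest.approx(1.0 * np.exp(0.12**2 / 2), rel=0.05)

    def test_flux_saturates_before_illumination(self):
        events, truth = gen_calcium_events(seed=3)
        conj = events[events["is_conjugate"]]
        sel = (conj["acquisition_time"] > truth["t_illumination"] - 30) & (
            conj["acquisition_time"] < truth["t_illumination"]
        )
        plateau = conj[sel]
        ratio = (plateau["indo_405"] - 50.0) / (plateau["indo_485"] - 50.0)
        # plateau = baseline + full amplitude (rise saturated within ~2 min)
        assert ratio.mean() == pytest.approx(2.5 * np.exp(0.12**2 / 2), rel=0.05)

    def test_mean_ratio_halves_29s_after_illumination(self):
        events, truth = gen_calcium_events(seed=3, duration=400.0)
        conj = events[events["is_conjugate"]]
        t = conj["acquisition_time"].to_numpy()
        ratio = ((conj["indo_405"] - 50.0) / (conj["indo_485"] - 50.0)).to_numpy()
        t0 = truth["t_illumination"]
        at = lambda lo, hi: ratio[(t >= lo) & (t < hi)].mean()
        plateau = at(t0 - 30, t0) - 1.0 * np.exp(0.12**2 / 2)
        half_after = at(t0 + 27, t0 + 31) - 1.0 * np.exp(0.12**2 / 2)
        assert half_after / plateau == pytest.approx(0.5, abs=0.06)

    def test_seed_determinism(self):
        a, _ = gen_calcium_events(seed=9, duration=50.0)
        b, _ = gen_calcium_events(seed=9, duration=50.0)
        pd.testing.assert_frame_equal(a, b)


class TestPperkSamples:
    def test_time_zero_single_background_mode(self):
        samples, truth = gen_pperk_samples(seed=1)
        t0 = samples[0.0]["pperk"]
        assert t0.median() == pytest.approx(truth["background_median"], rel=0.1)
        assert (t0 > 1000).mean() < 0.02

    def test_detectable_within_one_minute(self):
        samples, truth = gen_pperk_samples(seed=1)
        med1 = samples[1.0]["pperk"].median()
        assert med1 > 3 * truth["background_median"]

    def test_seed_determinism(self):
        a, _ = gen_pperk_samples(seed=2)
        b, _ = gen_pperk_samples(seed=2)
        for tp in a:
            pd.testing.assert_frame_equal(a[tp], b[tp])


class TestWesternLanes:
    def test_zero_jitter_lanes_share_band_positions(self):
        lanes, truth = gen_western_lanes(seed=1, shift_jitter_sd=0.0, noise_sd=0.0)
        peaks = [lane.coordinate[np.argmax(lane.tpn_intensity)] for lane in lanes]
        assert np.ptp(peaks) == pytest.approx(0.0, abs=1e-9)

    def test_start_active_fraction_configured(self):
        from optokinetics.westernquant import active_fraction, integrate_lane

        lanes, truth = gen_western_lanes(seed=1, shift_jitter_sd=0.0, noise_sd=0.0)
        _, profile = integrate_lane(lanes[0].coordinate, lanes[0].fos_intensity)
        frac = active_fraction(lanes[0].coordinate, profile, cutoff=truth["cutoff"])
        assert frac == pytest.approx(truth["start_fraction"], abs=0.03)

    def test_fifteen_minute_fraction_consistent_with_half_life(self):
        from optokinetics.westernquant import active_fraction, integrate_lane

        lanes, truth = gen_western_lanes(seed=1, shift_jitter_sd=0.0, noise_sd=0.0)
        last = [ln for ln in lanes if ln.timepoint == 15.0][0]
        _, profile = integrate_lane(last.coordinate, last.fos_intensity)
        frac = active_fraction(last.coordinate, profile, cutoff=truth["cutoff"])
        expected = truth["start_fraction"] * 0.5 ** (15.0 / truth["active_half_life_min"])
        assert frac == pytest.approx(expected, abs=0.03)


class TestCtTable:
    def test_housekeeping_constant_and_schema(self):
        table, _ = gen_ct_table(seed=4)
        assert set(table.columns) == {"time_min", "condition", "gene", "replicate", "ct"}
        hk = table[table["gene"] == "GAPDH"]["ct"]
        assert hk.std() < 0.5  # loading + technical noise only

    def test_seed_determinism(self):
        a, _ = gen_ct_table(seed=8)
        b, _ = gen_ct_table(seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestEndpointPopulation:
    def test_constant_light_gives_background_only(self):
        dark_free = StimulusProfile(segments=(), horizon=24 * HOUR)
        cells, truth = gen_endpoint_population(dark_free, seed=0, n_cells=200)
        assert truth["activated_fraction"] == 0.0
        assert cells["intensity"].median() < 200.0

    def test_continuous_dark_activates_nearly_all(self):
        continuous = StimulusProfile.constant(24 * HOUR)
        _, truth = gen_endpoint_population(continuous, seed=0, n_cells=200)
        assert truth["activated_fraction"] > 0.9

    def test_activated_fraction_monotone_in_signal_duration(self):
        fractions = []
        for hours in (1.0, 6.0, 24.0):
            stim = StimulusProfile.constant(hours * HOUR, horizon=24 * HOUR)
            _, truth = gen_endpoint_population(stim, seed=0, n_cells=300)
            fractions.append(truth["activated_fraction"])
        assert fractions == sorted(fractions)
        assert fractions[-1] > fractions[0]


class TestPlateAndStack:
    def test_zero_spread_uniform_plate(self):
        table, _ = gen_plate_measurements(seed=0, slope_spread=0.0, noise_sd=0.0)
        top = table[table["pwm"] == 255.0]["intensity"]
        assert top.std() == pytest.approx(0.0, abs=1e-9)

    def test_stack_determinism_and_truth_mask(self):
        a, ta = gen_membrane_stack(seed=6, n_frames=10)
        b, _ = gen_membrane_stack(seed=6, n_frames=10)
        assert np.array_equal(a.reporter, b.reporter)
        assert ta["mask"].any()


class TestStudyDirectory:
    def test_emits_tables_truths_and_manifest(self, tmp_path):
        manifest = generate_study(tmp_path / "study", seed=3)
        root = tmp_path / "study"
        listed = json.loads((root / "manifest.json").read_text())
        assert listed["artifacts"] == manifest["artifacts"]
        for name in manifest["artifacts"]:
            assert (root / f"{name}.csv").exists()
            assert (root / f"{name}_truth.json").exists()
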