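"""Core forward model: gamma survival, cascade ODE, pathway stages."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chi2
from scipy.stats import gamma as gamma_dist

from optokinetics.core_model import (
    CascadeParams,
    GeneParams,
    OutputParams,
    ReadoutParams,
    StimulusProfile,
    gamma_survival,
    simulate_cascade,
    simulate_pathway,
    survival_quantile,
)

DEFAULT = CascadeParams(5, 6.21)


class TestGammaSurvival:
    @pytest.mark.parametrize("k,theta", [(1, 1.0), (2, 10.0), (5, 6.21), (7, 0.5)])
    def test_survival_at_origin_is_one(self, k, theta):
        assert gamma_survival(0.0, CascadeParams(k, theta)) == pytest.approx(1.0)

    def test_exponential_median(self):
        assert gamma_survival(np.log(2), CascadeParams(1, 1.0)) == pytest.approx(0.5)

    def test_two_step_chain_against_density_integral(self):
        # oracle: survival = 1 - integral of the gamma(2, 10) density
        oracle = 1.0 - quad(lambda x: gamma_dist.pdf(x, 2, scale=10.0), 0, 10.0)[0]
        value = gamma_survival(10.0, CascadeParams(2, 10.0))
        assert oracle == pytest.approx(2 * np.exp(-1), abs=1e-9)
        assert value == pytest.approx(oracle, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gamma_survival(-1.0, DEFAULT)

    @pytest.mark.parametrize("k", range(1, 11))
    def test_monotone_decreasing_to_zero(self, k):
        params = CascadeParams(k, 6.21)
        grid = np.linspace(0, 60 * k, 400)
        s = gamma_survival(grid, params)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 0)
        assert gamma_survival(1e4 * k, params) < 1e-10


class TestSurvivalQuantile:
    def test_exponential_half_life(self):
        assert survival_quantile(CascadeParams(1, 1.0), 0.5) == pytest.approx(np.log(2), rel=1e-8)

    def test_calcium_default_quantiles_vs_chi_square(self):
        # oracle: 2 * gamma(k, theta) / theta ~ chi-square with 2k dof
        half = chi2.isf(0.5, 10) * 6.21 / 2.0
        onset = chi2.isf(0.99, 10) * 6.21 / 2.0
        assert survival_quantile(DEFAULT, 0.5) == pytest.approx(half, rel=1e-8)
        assert survival_quantile(DEFAULT, 0.5) == pytest.approx(29.0, abs=0.05)
        assert survival_quantile(DEFAULT, 0.99) == pytest.approx(onset, rel=1e-8)
        assert survival_quantile(DEFAULT, 0.99) == pytest.approx(7.9, abs=0.1)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_level_rejected(self, level):
        with pytest.raises(ValueError):
            survival_quantile(DEFAULT, level)

    def test_round_trip_with_survival(self):
        for level in (0.99, 0.5, 0.1):
            t = survival_quantile(DEFAULT, level)
            assert gamma_survival(t, DEFAULT) == pytest.approx(level, rel=1e-7)


class TestSimulateCascade:
    def test_sustained_input_reaches_steady_state(self):
        stim = StimulusProfile.constant(400.0)
        traj = simulate_cascade(DEFAULT, stim, np.arange(0.0, 400.0, 2.0))
        assert traj.node_activities[-1] == pytest.approx(np.ones(5), abs=1e-6)

    @pytest.mark.parametrize("k", [1, 3, 5, 10])
    def test_step_off_matches_gamma_survival(self, k):
        params = CascadeParams(k, 6.21)
        t_off = 200.0
        stim = StimulusProfile(((0.0, t_off, 1.0),), 500.0)
        grid = np.arange(0.0, 500.0, 2.0)
        traj = simulate_cascade(params, stim, grid)
        post = grid >= t_off
        expected = gamma_survival(grid[post] - t_off, params)
        assert np.max(np.abs(traj.terminal[post] - expected)) < 1e-3

    def test_step_on_single_step_is_exponential_rise(self):
        params = CascadeParams(1, 6.21)
        stim = StimulusProfile.constant(60.0)
        grid = np.arange(0.0, 60.0, 1.0)
        traj = simulate_cascade(params, stim, grid)
        expected = 1.0 - np.exp(-grid / 6.21)
        assert np.max(np.abs(traj.terminal - expected)) < 1e-6

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_cascade(DEFAULT, StimulusProfile.constant(10.0), np.array([]))


class TestSimulatePathway:
    fast_gene = GeneParams(transcription_rate=np.log(2) / 60, mrna_decay=np.log(2) / 60, shutoff_delay=0.0)
    fast_out = OutputParams(production=np.log(2) / 120, degradation=np.log(2) / 120)

    def test_no_stimulus_no_protein(self):
        stim = StimulusProfile(segments=(), horizon=600.0)
        traj = simulate_pathway(stimulus=stim, gene=self.fast_gene, output=self.fast_out)
        assert np.all(traj.protein == 0.0)
        assert np.all(traj.mrna == 0.0)

    def test_saturated_fixed_point(self):
        # sustained input: M -> beta*a/gamma, P -> alpha*beta*a/(gamma*delta)
        stim = StimulusProfile.constant(4 * 3600.0)
        traj = simulate_pathway(stimulus=stim, gene=self.fast_gene, output=self.fast_out, dt=1.0)
        a_sat = ReadoutParams().activity(1.0)
        assert traj.mrna[-1] == pytest.approx(a_sat, rel=1e-3)
        assert traj.protein[-1] == pytest.approx(a_sat, rel=1e-2)

    def test_mrna_first_order_decay_after_shutoff(self):
        stim = StimulusProfile(((0.0, 1800.0, 1.0),), 7200.0)
        traj = simulate_pathway(stimulus=stim, gene=self.fast_gene, output=self.fast_out, dt=1.0)
        # transcription is zero after shutoff; fit log-slope over a late window
        sel = (traj.times >= 3600.0) & (traj.times <= 5400.0)
        slope = np.polyfit(traj.times[sel], np.log(traj.mrna[sel]), 1)[0]
        assert -slope == pytest.approx(self.fast_gene.mrna_decay, rel=1e-3)

    def test_linear_readout_superposition(self):
        # LTI limit: transcription integral depends on total signal only
        from optokinetics.protocols import build_pulse_train

        totals = []
        for interval in (0.0, 15.0, 45.0):
            profile, _ = build_pulse_train(15.0, interval)
            traj = simulate_pathway(stimulus=profile, readout=None, dt=1.0)
            totals.append(np.trapezoid(traj.transcription, traj.times))
        assert max(totals) - min(totals) < 1e-3 * max(totals)

    def test_maturation_delay_shifts_production(self):
        out_delayed = OutputParams(production=np.log(2) / 120, degradation=np.log(2) / 120, maturation_delay=600.0)
        stim = StimulusProfile.constant(3600.0)
        plain = simulate_pathway(stimulus=stim, gene=self.fast_gene, output=self.fast_out, dt=1.0)
        delayed = simulate_pathway(stimulus=stim, gene=self.fast_gene, output=out_delayed, dt=1.0)
        assert np.all(delayed.protein[plain.times < 600.0] == pytest.approx(0.0, abs=1e-12))
        assert delayed.protein[-1] < plain.protein[-1]


class TestStimulusProfile:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            StimulusProfile(((0.0, 10.0, 1.0), (5.0, 15.0, 1.0)), 20.0)

    def test_gaps_are_level_zero(self):
        stim = StimulusProfile(((0.0, 10.0, 1.0), (20.0, 30.0, 0.5)), 40.0)
        assert stim.level(15.0) == 0.0
        assert stim.level(25.0) == 0.5
        assert stim.total_on_time() == pytest.approx(15.0)
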