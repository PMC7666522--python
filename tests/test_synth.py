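"""Synthetic session generator: population draws, bursts, staircase, sessions."""

import numpy as np
import pytest

import blinkpk as b
from blinkpk.synth import (
    DEFAULT_POPULATION,
    PopulationConfig,
    ReflexComponent,
    component_scale,
)


class TestDrawPatient:
    def test_sd_zero_yields_exact_cohort_means(self, sd0_population):
        profile = b.draw_patient(b.session_rng(0, 0), sd0_population)
        assert (profile.ce_lor2, profile.ce_lor1, profile.ce_lorp) == (1.45, 2.99, 4.22)

    def test_unorderable_means_raise_after_redraw_cap(self):
        pop = PopulationConfig(ce_lor2_mean=4.22, ce_lorp_mean=1.45,
                               ce_lor2_sd=0.0, ce_lor1_sd=0.0, ce_lorp_sd=0.0,
                               max_redraws=50)
        with pytest.raises(ValueError, match="ordered"):
            b.draw_patient(b.session_rng(0, 0), pop)

    def test_thresholds_always_ordered_and_floored(self):
        rng = b.session_rng(5, 0)
        for _ in range(200):
            p = b.draw_patient(rng)
            assert 0.1 <= p.ce_lor2 < p.ce_lor1 < p.ce_lorp

    def test_correlated_marginals_match_cohort_calibration(self):
        # the shared-factor copula must leave the truncated-normal marginal
        # means at their configured values (the point of the design)
        rng = b.session_rng(123, 0)
        draws = np.array([
            (p.ce_lor2, p.ce_lor1, p.ce_lorp)
            for p in (b.draw_patient(rng) for _ in range(4000))
        ])
        # truncated-normal analytic means (floor 0.1)
        from scipy import stats
        expected = []
        for mean, sd in ((1.45, 0.85), (2.99, 1.19), (4.22, 1.24)):
            a = (0.1 - mean) / sd
            expected.append(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd))
        assert np.allclose(draws.mean(axis=0), expected, atol=0.08)

    def test_independent_mode_violation_fraction_matches_mc_oracle(self):
        # fraction of raw independent triples violating the ordering,
        # compared against a direct Monte-Carlo oracle on the same normals
        pop = DEFAULT_POPULATION
        oracle_rng = np.random.default_rng(99)
        n = 200_000
        a = oracle_rng.normal(pop.ce_lor2_mean, pop.ce_lor2_sd, n)
        bb = oracle_rng.normal(pop.ce_lor1_mean, pop.ce_lor1_sd, n)
        c = oracle_rng.normal(pop.ce_lorp_mean, pop.ce_lorp_sd, n)
        keep = (a >= 0.1) & (bb >= 0.1) & (c >= 0.1)
        oracle_frac = 1.0 - ((a < bb) & (bb < c))[keep].mean()

        rng = b.session_rng(77, 0)
        viol = 0
        n_draws = 10_000
        for _ in range(n_draws):
            lor2 = b.synth._truncated_normal(rng, pop.ce_lor2_mean, pop.ce_lor2_sd, 0.1)
            lor1 = b.synth._truncated_normal(rng, pop.ce_lor1_mean, pop.ce_lor1_sd, 0.1)
            lorp = b.synth._truncated_normal(rng, pop.ce_lorp_mean, pop.ce_lorp_sd, 0.1)
            viol += not (lor2 < lor1 < lorp)
        assert viol / n_draws == pytest.approx(oracle_frac, abs=0.01)


class TestComponentScale:
    @pytest.mark.parametrize("ce,expected", [(0.0, 1.0), (2.0, 0.0), (5.0, 0.0),
                                             (1.0, 0.5)])
    def test_linear_fade(self, ce, expected):
        comp = ReflexComponent(name="R1", latency_ms=10.5, duration_ms=6,
                               center_freq_hz=150, env_width_ms=1.5,
                               baseline_amp_uv=80, abolition_ce=2.0, gamma=1.0)
        assert component_scale(comp, ce) == pytest.approx(expected)

    def test_monotone_nonincreasing_in_ce(self, mean_profile):
        for comp in mean_profile.components:
            scales = [component_scale(comp, ce) for ce in np.linspace(0, 6, 200)]
            assert all(s0 >= s1 for s0, s1 in zip(scales, scales[1:]))


class TestSynthSweep:
    def test_fully_suppressed_noise_free_sweep_is_zero(self, mean_profile):
        sweep = b.synth_sweep(mean_profile, ce=5.0, rng=b.session_rng(0, 1))
        assert np.all(sweep.samples == 0.0)

    def test_burst_energy_confined_to_analysis_windows(self, mean_profile):
        sweep = b.synth_sweep(mean_profile, ce=0.0, rng=b.session_rng(0, 1))
        t_ms = np.arange(len(sweep.samples)) / sweep.fs_hz * 1e3
        # R1 alone (suppress R2 via a profile where R2 is abolished at ~0)
        r1, r2 = mean_profile.components
        from blinkpk.synth import _burst
        for comp, lo, hi in ((r1, 10.0, 25.0), (r2, 25.0, 200.0)):
            burst = _burst(t_ms, comp, scale=1.0, jitter_ms=0.0)
            energy = burst ** 2
            inside = energy[(t_ms >= lo) & (t_ms < hi)].sum()
            assert inside / energy.sum() > 0.99

    def test_t2_window_mean_frequency_near_r2_carrier(self, mean_profile):
        # independent FFT check on the pure burst, no Welch machinery
        sweep = b.synth_sweep(mean_profile, ce=0.0, rng=b.session_rng(0, 1))
        seg = sweep.samples[250:]
        spec = np.abs(np.fft.rfft(seg)) ** 2
        freqs = np.fft.rfftfreq(len(seg), d=1.0 / sweep.fs_hz)
        f_mean = (freqs * spec).sum() / spec.sum()
        assert abs(f_mean - 60.0) < 10.0

    def test_noise_is_highpassed(self, mean_demographics):
        profile = b.PatientProfile(
            demographics=mean_demographics, ce_lor2=1.45, ce_lor1=2.99,
            ce_lorp=4.22, noise_sd_uv=2.0)
        sweep = b.synth_sweep(profile, ce=5.0, rng=b.session_rng(0, 2))
        spec = np.abs(np.fft.rfft(sweep.samples)) ** 2
        freqs = np.fft.rfftfreq(len(sweep.samples), d=1e-4)
        low = spec[freqs < 10].mean()
        mid = spec[(freqs > 100) & (freqs < 2000)].mean()
        assert low < 0.05 * mid


class TestArassStaircase:
    def test_awake_at_zero_and_unresponsive_at_lorp(self, mean_profile):
        assert b.arass_at(mean_profile, 0.0) == 0
        assert b.arass_at(mean_profile, mean_profile.ce_lorp) == -5
        assert b.arass_at(mean_profile, 10.0) == -5

    def test_cohort_calibration_reproduces_endpoint_scores(self, mean_profile):
        # at the cohort mean thresholds the score is 0 when R2 vanishes
        # (34% of the LORP Ce) and −2 when R1 vanishes (71%)
        assert b.arass_at(mean_profile, mean_profile.ce_lor2) == 0
        assert b.arass_at(mean_profile, mean_profile.ce_lor1) == -2

    def test_monotone_nonincreasing_in_ce(self, mean_profile):
        scores = [b.arass_at(mean_profile, ce) for ce in np.linspace(0, 5, 500)]
        assert all(s0 >= s1 for s0, s1 in zip(scores, scores[1:]))


class TestSimulateSession:
    def test_truth_endpoints_ordered_and_match_profile(self, noisefree_session):
        t = noisefree_session.truth
        assert t.lor2_time < t.lor1_time < t.lorp_time
        assert t.lorp_ce == noisefree_session.profile.ce_lorp

    def test_lorp_time_consistent_with_cohort_mean(self, noisefree_session):
        # emergent cross-check of the PK model against the cohort summary
        assert noisefree_session.truth.lorp_time == pytest.approx(147.84, rel=0.25)

    def test_six_second_cadence_with_baseline(self, noisefree_session):
        times = [s.stim_time_s for s in noisefree_session.sweeps]
        assert times[0] == -24.0
        assert np.allclose(np.diff(times), 6.0)
        assert len(noisefree_session.sedation) == len(noisefree_session.sweeps)

    def test_sedation_monotone_and_stops_at_first_minus5(self, noisefree_session):
        scores = [r.arass for r in noisefree_session.sedation]
        assert all(s0 >= s1 for s0, s1 in zip(scores, scores[1:]))
        assert scores[-1] == -5
        assert scores.count(-5) == 1

    def test_same_seed_bit_identical(self, mean_demographics):
        profile = b.PatientProfile(
            demographics=mean_demographics, ce_lor2=1.45, ce_lor1=2.99,
            ce_lorp=4.22)
        s1 = b.simulate_session(profile, b.session_rng(9, 4))
        s2 = b.simulate_session(profile, b.session_rng(9, 4))
        assert all(np.array_equal(a.samples, c.samples)
                   for a, c in zip(s1.sweeps, s2.sweeps))

    def test_unreachable_threshold_raises(self, mean_demographics):
        profile = b.PatientProfile(
            demographics=mean_demographics, ce_lor2=1.0, ce_lor1=2.0,
            ce_lorp=50.0, noise_sd_uv=0.0)
        with pytest.raises(RuntimeError, match="never reached"):
            b.simulate_session(profile, b.session_rng(0, 0), horizon_s=300.0)

    def test_r2_vanishes_before_r1_before_lorp(self, noisefree_session):
        # abolition ordering is structural: thresholds are the LOR2/LOR1 Ce
        r1, r2 = noisefree_session.profile.components
        assert r2.abolition_ce < r1.abolition_ce < noisefree_session.profile.ce_lorp
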