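"""Synthetic LFP generator: background statistics, response structure,
trial assembly and the experiment schedule."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, ttest_1samp

from stimscape.simulate import (
    SimConfig,
    TRIALS_BY_DIMENSION,
    _trial_parts,
    background_spectrum,
    effective_frequency,
    entrain_gain,
    plan_experiment,
    simulate_background,
    simulate_experiment,
    simulate_response,
    simulate_trial,
)
from stimscape.spectral import GAMMA_BAND, THETA_BAND, bandpower, multitaper_psd
from stimscape.waveforms import WaveformSpec, gen_waveform

FS = 2000.0
STIM_35 = WaveformSpec(kind="standard", amplitude=50, freq=35, pulse_width=0.005)
STIM_7 = WaveformSpec(kind="standard", amplitude=50, freq=7, pulse_width=0.005)


def expected_band_power(band, condition, cfg, n=10_000):
    """Closed-form expected background bandpower from the target spectrum."""
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.fs)
    s = background_spectrum(freqs, condition, cfg)
    df = freqs[1] - freqs[0]
    return float(s[(freqs >= band[0]) & (freqs < band[1])].sum() * df)


class TestBackground:
    def test_exploration_elevates_theta_by_configured_gain(self, cfg, rng):
        def theta_bp(condition):
            trace = simulate_background(condition, 60.0, cfg, rng)
            return bandpower(multitaper_psd(trace, cfg.fs, 100.0), THETA_BAND)

        ratio = theta_bp("exploration") / theta_bp("quiescence")
        assert ratio == pytest.approx(cfg.theta_exploration_gain, rel=0.2)

    def test_all_sources_off_gives_zero_trace(self, rng):
        cfg = SimConfig(noise_sd=0.0, theta_power=0.0)
        trace = simulate_background("quiescence", 5.0, cfg, rng)
        assert not np.any(trace)

    def test_zero_exponent_gives_flat_spectrum(self, rng):
        cfg = SimConfig(background_exponent=0.0, theta_power=0.0)
        trace = simulate_background("quiescence", 60.0, cfg, rng)
        psd = multitaper_psd(trace, cfg.fs, 100.0)
        sel = (psd.freqs >= 4) & (psd.freqs <= 50)
        power = psd.power[sel]
        # average in ~2 Hz bins to beat estimator variance, then check flatness
        width = 120
        binned = power[: power.size // width * width].reshape(-1, width).mean(axis=1)
        assert binned.max() / binned.min() < 1.5


class TestResponse:
    def test_zero_amplitude_waveform_gives_zero_response(self, cfg):
        spec = WaveformSpec(kind="standard", amplitude=0, freq=35, pulse_width=0.005)
        wf = gen_waveform(spec, 5.0, FS, validate=False)
        assert not np.any(simulate_response(wf, 1.0, cfg))

    def test_gamma_percent_change_matches_generator_target(self, cfg, rng):
        """Monte-Carlo mean gamma change agrees with the generator's own
        closed-form target (response bandpower over expected baseline)."""
        resp = simulate_response(gen_waveform(STIM_35, 5.0, FS), 1.0, cfg)
        p_resp = bandpower(multitaper_psd(resp, FS, 100.0), GAMMA_BAND)
        p_bg = expected_band_power(GAMMA_BAND, "quiescence", cfg)
        target = 100.0 * p_resp / p_bg
        changes = []
        for _ in range(200):
            pre, bg, r = _trial_parts(STIM_35, "quiescence", cfg, rng, 1.0)
            p_stim = bandpower(multitaper_psd(bg + r, FS, 100.0), GAMMA_BAND)
            changes.append(100.0 * (p_stim - p_bg) / p_bg)
        changes = np.asarray(changes)
        se = changes.std(ddof=1) / np.sqrt(changes.size)
        assert changes.mean() > 0
        assert abs(changes.mean() - target) <= 3 * se

    def test_theta_stimulation_does_not_raise_theta(self, cfg, rng):
        """Below the roll-off knee the response is negligible: mean theta
        change across trials is not significantly greater than zero."""
        p_bg = expected_band_power(THETA_BAND, "quiescence", cfg)
        changes = []
        for _ in range(200):
            pre, bg, r = _trial_parts(STIM_7, "quiescence", cfg, rng, 1.0)
            p_stim = bandpower(multitaper_psd(bg + r, FS, 100.0), THETA_BAND)
            changes.append(100.0 * (p_stim - p_bg) / p_bg)
        t, p_two = ttest_1samp(changes, 0.0)
        p_one = p_two / 2 if t > 0 else 1 - p_two / 2
        assert p_one > 0.01

    def test_quadratic_nonlinearity_seeds_harmonic_at_70(self, cfg):
        resp = simulate_response(gen_waveform(STIM_35, 5.0, FS), 1.0, cfg)
        psd = multitaper_psd(resp, FS, 100.0)
        i = np.argmin(np.abs(psd.freqs - 70.0))
        window = psd.power[i - 10 : i + 11]
        assert np.argmax(window) == 10

    def test_sampling_rate_mismatch_rejected(self, cfg):
        wf = gen_waveform(STIM_35, 5.0, 4000.0)
        with pytest.raises(ValueError, match="fs"):
            simulate_response(wf, 1.0, cfg)

    def test_gain_curve_monotone_and_effective_frequency(self, cfg):
        freqs = np.linspace(2, 50, 100)
        gains = [entrain_gain(f, cfg) for f in freqs]
        assert np.all(np.diff(gains) >= 0)
        ds = WaveformSpec(
            kind="double_sine", amplitude=20, freq1=10, freq2=40, ratio=0.25
        )
        assert effective_frequency(ds) == pytest.approx(0.25 * 10 + 0.75 * 40)


class TestTrialAssembly:
    def test_segment_lengths(self, cfg, rng):
        trial = simulate_trial(None, "quiescence", "s0", "s0_0", cfg, rng)
        assert trial.pre_signal.size == 10_000
        assert trial.stim_signal.size == 10_000

    def test_additivity_of_response(self, cfg):
        """Same-seed trial equals background plus response, bit for bit."""
        pre, bg, resp = _trial_parts(
            STIM_35, "quiescence", cfg, np.random.default_rng(42), 1.0
        )
        trial = simulate_trial(
            STIM_35, "quiescence", "s0", "s0_0", cfg, np.random.default_rng(42)
        )
        np.testing.assert_array_equal(trial.stim_signal, bg + resp)
        np.testing.assert_array_equal(trial.pre_signal, pre)

    def test_behavior_trials_are_exchangeable(self, cfg, rng):
        pre_theta, stim_theta = [], []
        for _ in range(100):
            trial = simulate_trial(None, "exploration", "s0", "s0_0", cfg, rng)
            pre_theta.append(
                bandpower(multitaper_psd(trial.pre_signal, FS, 100.0), THETA_BAND)
            )
            stim_theta.append(
                bandpower(multitaper_psd(trial.stim_signal, FS, 100.0), THETA_BAND)
            )
        p = mannwhitneyu(pre_theta, stim_theta).pvalue
        assert p > 0.01

    def test_gamma_stimulation_raises_gamma_in_most_trials(self, cfg, rng):
        wins = 0
        for _ in range(100):
            trial = simulate_trial(STIM_35, "quiescence", "s0", "s0_0", cfg, rng)
            g_pre = bandpower(multitaper_psd(trial.pre_signal, FS, 100.0), GAMMA_BAND)
            g_stim = bandpower(multitaper_psd(trial.stim_signal, FS, 100.0), GAMMA_BAND)
            wins += g_stim > g_pre
        assert wins >= 90

    def test_seeded_determinism(self, cfg):
        a = simulate_trial(
            STIM_35, "quiescence", "s0", "s0_0", cfg, np.random.default_rng(99)
        )
        b = simulate_trial(
            STIM_35, "quiescence", "s0", "s0_0", cfg, np.random.default_rng(99)
        )
        np.testing.assert_array_equal(a.pre_signal, b.pre_signal)
        np.testing.assert_array_equal(a.stim_signal, b.stim_signal)


class TestExperimentSchedule:
    @pytest.mark.parametrize(
        "space, expected",
        [("sine", 600), ("standard", 750), ("poisson", 750),
         ("double_sine", 1750), ("nested", 1750)],
    )
    def test_trial_counts_follow_dimensionality(self, space, expected, rng):
        cfg = SimConfig(n_subjects=1)
        table = plan_experiment([space], cfg, rng)
        assert int((table["kind"] == space).sum()) == expected

    def test_full_design_totals(self, rng):
        cfg = SimConfig(n_subjects=4)
        spaces = ["sine", "standard", "poisson", "double_sine", "nested"]
        table = plan_experiment(spaces, cfg, rng)
        stim = table[table["kind"] != "behavior"]
        per_subject = stim.groupby("subject_id").size()
        assert (per_subject == 600 + 750 + 750 + 1750 + 1750).all()
        assert sum(TRIALS_BY_DIMENSION[k] for k in (2, 3, 3, 4, 5)) == 5600

    def test_sessions_alternate_conditions_and_behavior_present(self, rng):
        cfg = SimConfig(n_subjects=1)
        table = plan_experiment(["sine"], cfg, rng)
        cond_by_session = table.groupby("session_id")["condition"].unique()
        assert all(len(c) == 1 for c in cond_by_session)
        conds = [c[0] for c in cond_by_session]
        assert conds[: 2] == ["exploration", "quiescence"]
        beh = table[table["kind"] == "behavior"]
        assert set(beh["condition"]) == {"exploration", "quiescence"}

    def test_simulate_experiment_signals_align_with_table(self, rng):
        cfg = SimConfig(n_subjects=1, n_behavior_per_condition=5, session_size=10)
        table, signals = simulate_experiment(
            ["sine"], cfg, rng, trials_scale=0.02
        )
        assert set(signals) == set(table["trial_id"])
        first = signals[table["trial_id"].iloc[0]]
        assert first["pre"].size == 10_000 and first["stim"].size == 10_000
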