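"""Tests for the preprocessing chain against closed-form and hand oracles."""

import numpy as np
import pytest

from nirscog.preprocess import (
    baseline_correct,
    block_average,
    detrend,
    lowpass,
    preprocess_recording,
    short_separation_regress,
)
from nirscog.synthetic import silent_noise, simulate_recording
from nirscog.types import BlockSchedule, NeuralSeries, RecordingNoise


def _tone_amplitude(x, fs, freq, trim_s=100.0):
    """Steady-state amplitude at ``freq``, away from filter edge transients."""
    k = int(trim_s * fs)
    t = np.arange(len(x))[k:-k] / fs
    c = x[k:-k]
    return 2.0 * np.abs(np.sum(c * np.exp(-2j * np.pi * freq * t))) / len(c)


# --------------------------------------------------------------------------
# detrend
# --------------------------------------------------------------------------

class TestDetrend:
    def test_exact_line_maps_to_zero(self):
        t = np.arange(100, dtype=float)
        assert np.allclose(detrend(2.0 + 0.01 * t), 0.0, atol=1e-12)
        assert np.allclose(detrend(np.full(50, 7.3)), 0.0, atol=1e-12)

    def test_matches_normal_equations_residual(self):
        t = np.arange(500) / 10.0
        x = np.sin(2 * np.pi * 0.05 * t) + 0.02 * t
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ x)
        np.testing.assert_allclose(detrend(x), x - X @ beta, atol=1e-10)

    def test_idempotent(self, rng):
        x = rng.normal(size=300)
        once = detrend(x)
        np.testing.assert_allclose(detrend(once), once, atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend(np.array([1.0]))


# --------------------------------------------------------------------------
# low-pass filter
# --------------------------------------------------------------------------

class TestLowpass:
    def test_dc_gain_unity(self):
        out = lowpass(np.full(2000, 5.0), fs=10.0)
        assert np.allclose(out, 5.0, atol=1e-6)

    def test_stopband_tone_attenuated(self):
        """0.5 Hz at fs 10: 4th-order Butterworth two-pass leaves < 5%."""
        fs, t = 10.0, np.arange(6000) / 10.0
        out = lowpass(np.sin(2 * np.pi * 0.5 * t), fs)
        # closed-form: |H|^2 = (1 + (f/fc)^(2*order))^(-1), squared for two passes
        gain = (1.0 / (1.0 + (0.5 / 0.1) ** 8))
        measured = _tone_amplitude(out, fs, 0.5)
        assert measured < 0.05
        assert measured == pytest.approx(gain, rel=0.2)

    def test_passband_tone_preserved(self):
        fs, t = 10.0, np.arange(40000) / 10.0
        out = lowpass(np.sin(2 * np.pi * 0.01 * t), fs)
        gain = 1.0 / (1.0 + (0.01 / 0.1) ** 8)
        assert _tone_amplitude(out, fs, 0.01, trim_s=400) > 0.95
        assert gain > 0.95  # the closed form agrees the tone is in-band

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.zeros(100), fs=0.2, cutoff=0.1)


# --------------------------------------------------------------------------
# short-separation regression
# --------------------------------------------------------------------------

class TestShortSeparation:
    def test_constant_shallow_falls_back_to_centering(self):
        deep = np.array([1.0, 2.0, 3.0, 4.0])
        out = short_separation_regress(deep, np.zeros(4))
        assert out.fallback
        np.testing.assert_allclose(out.values, deep - deep.mean())

    def test_perfect_linear_dependence_removed(self):
        shallow = np.linspace(-1, 1, 50)
        out = short_separation_regress(2 * shallow + 3, shallow)
        assert np.allclose(out.values, 0.0, atol=1e-10)
        assert out.coef == pytest.approx((3.0, 2.0))

    def test_matches_normal_equations_oracle(self, rng):
        deep = rng.normal(size=50)
        shallow = rng.normal(size=50)
        X = np.column_stack([np.ones(50), shallow])
        beta = np.linalg.solve(X.T @ X, X.T @ deep)
        out = short_separation_regress(deep, shallow)
        np.testing.assert_allclose(out.values, deep - X @ beta, atol=1e-10)
        # residual properties
        assert abs(out.values.mean()) < 1e-10
        assert abs(np.corrcoef(out.values, shallow)[0, 1]) < 1e-8

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            short_separation_regress(np.zeros(5), np.zeros(4))


# --------------------------------------------------------------------------
# baseline correction and block averaging
# --------------------------------------------------------------------------

def _series_from_block_values(schedule, fs, values_per_block):
    x = np.empty(schedule.n_samples(fs))
    for block, v in zip(schedule.blocks, values_per_block):
        x[schedule.sample_slice(block, fs)] = v
    return NeuralSeries(x, fs, schedule)


class TestBaselineCorrect:
    def test_game_equal_to_rest_mean_gives_zero(self, default_schedule):
        ns = _series_from_block_values(default_schedule, 10.0, [1, 1, 2, 2, 3])
        out = baseline_correct(ns)
        for b in default_schedule.game_blocks():
            assert np.allclose(out.values[default_schedule.sample_slice(b, 10.0)], 0.0)

    def test_simple_offset(self):
        sched = BlockSchedule.alternating(30.0, 1)
        ns = _series_from_block_values(sched, 10.0, [1.0, 1.5, 1.0])
        out = baseline_correct(ns)
        game = sched.game_blocks()[0]
        assert np.allclose(out.values[sched.sample_slice(game, 10.0)], 0.5)

    def test_each_game_block_uses_own_preceding_rest(self, default_schedule):
        """Hand oracle: R/V means (10, 12, 20, 25, 30) -> corrections 2 and 5."""
        ns = _series_from_block_values(default_schedule, 10.0, [10, 12, 20, 25, 30])
        out = baseline_correct(ns)
        v1, v2 = default_schedule.game_blocks()
        assert np.allclose(out.values[default_schedule.sample_slice(v1, 10.0)], 2.0)
        assert np.allclose(out.values[default_schedule.sample_slice(v2, 10.0)], 5.0)
        # rest blocks are centered on their own means
        for b in default_schedule.rest_blocks():
            assert np.allclose(out.values[default_schedule.sample_slice(b, 10.0)], 0.0)


class TestBlockAverage:
    def test_zero_corrected_signal(self, default_schedule):
        ns = _series_from_block_values(default_schedule, 10.0, [5, 0, 5, 0, 5])
        est = block_average(ns)
        assert est.activity == 0.0

    def test_equal_length_blocks_average(self, default_schedule):
        ns = _series_from_block_values(default_schedule, 10.0, [0, 0.4, 0, 0.6, 0])
        est = block_average(ns)
        assert est.activity == pytest.approx(0.5)
        assert est.block_means == pytest.approx((0.4, 0.6))

    def test_unequal_blocks_match_direct_summation(self, rng):
        from nirscog.types import Block
        sched = BlockSchedule((Block("rest", 0, 30), Block("game", 30, 60),
                               Block("rest", 60, 90), Block("game", 90, 140),
                               Block("rest", 140, 170)))
        x = rng.normal(size=sched.n_samples(10.0))
        ns = NeuralSeries(x, 10.0, sched)
        est = block_average(ns)
        samples = np.concatenate([x[sched.sample_slice(b, 10.0)]
                                  for b in sched.game_blocks()])
        assert est.activity == pytest.approx(samples.mean(), abs=1e-12)
        # invariant: scalar equals count-weighted mean of per-block means
        w = np.array(est.block_sizes)
        assert est.activity == pytest.approx(
            float(np.average(est.block_means, weights=w)), abs=1e-12)

    def test_no_game_blocks_rejected(self):
        from nirscog.types import Block
        sched = BlockSchedule((Block("rest", 0, 30),))
        ns = NeuralSeries(np.zeros(300), 10.0, sched)
        with pytest.raises(ValueError, match="game"):
            block_average(ns)


# --------------------------------------------------------------------------
# full chain
# --------------------------------------------------------------------------

class TestFullChain:
    def test_activity_increases_with_amplitude(self, default_schedule):
        acts = [preprocess_recording(simulate_recording(
            a, schedule=default_schedule, noise=silent_noise(), seed=0)).activity
            for a in (0.0, 0.5, 1.0)]
        assert acts[0] < acts[1] < acts[2]

    def test_regression_suppresses_systemic_only_signal(self, default_schedule):
        """With no neural signal, the short-separation step shrinks |activity|."""
        noise = RecordingNoise(deep_noise_sd=0.0, shallow_noise_sd=0.0,
                               drift_slope_sd=0.0)
        wins = 0
        for seed in range(100):
            rec = simulate_recording(0.0, schedule=default_schedule,
                                     noise=noise, seed=seed)
            with_reg = preprocess_recording(rec).activity
            without = preprocess_recording(rec, short_separation=False).activity
            wins += abs(with_reg) < abs(without)
        assert wins > 50

    def test_scale_equivariance(self, default_schedule):
        rec = simulate_recording(1.0, schedule=default_schedule, seed=5)
        base = preprocess_recording(rec).activity
        from nirscog.types import Recording
        scaled = Recording(rec.participant_id, rec.side, rec.fs,
                           3.0 * rec.shallow, 3.0 * rec.deep, rec.schedule)
        assert preprocess_recording(scaled).activity == pytest.approx(3.0 * base,
                                                                      rel=1e-9)

    def test_stage_order_matters(self, default_schedule):
        """Baseline-correcting before the regression changes the answer;
        the shipped order regresses first."""
        rec = simulate_recording(1.0, schedule=default_schedule, seed=8)
        from nirscog.preprocess import detrend, lowpass
        fs = rec.fs
        deep = lowpass(detrend(rec.deep), fs)
        shallow = lowpass(detrend(rec.shallow), fs)
        shipped = block_average(baseline_correct(
            short_separation_regress(deep, shallow, fs=fs,
                                     schedule=default_schedule))).activity
        swapped_neural = baseline_correct(NeuralSeries(deep, fs, default_schedule))
        swapped_shallow = baseline_correct(NeuralSeries(shallow, fs, default_schedule))
        swapped = block_average(baseline_correct(short_separation_regress(
            swapped_neural.values, swapped_shallow.values, fs=fs,
            schedule=default_schedule))).activity
        assert shipped != pytest.approx(swapped, rel=1e-6)

    def test_amplitude_recovery_from_cohort(self, small_cohort):
        """Preprocessed activity tracks the latent amplitude (r > 0.8, n=24)."""
        from nirscog.preprocess import preprocess_recordings
        from nirscog.synthetic import simulate_cohort_recordings
        participants, amps = small_cohort
        recs = simulate_cohort_recordings(participants, amps, seed=99)
        table = preprocess_recordings(recs)
        truth = np.array([amps[i][s] for i, s in zip(table["id"], table["side"])])
        assert np.corrcoef(table["activity"], truth)[0, 1] > 0.8
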