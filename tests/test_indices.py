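"""Acoustic indices against closed forms and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from helpers import (aci_oracle, adi_oracle, bi_oracle, entropy_oracle,
                     gini_oracle, saturation_oracle)
from sonoscape import indices as idx
from sonoscape.audio import Waveform

RATE = 22_050


def make_spec(values, rate=RATE, frame_len=512, profile=None):
    """Wrap a constructed matrix as an AmplitudeSpectrogram."""
    values = np.asarray(values, dtype=float)
    return idx.AmplitudeSpectrogram(
        values=values, frame_len=frame_len, frame_hop=frame_len,
        freq_resolution=rate / frame_len, rate=rate,
        noise_profile=None if profile is None else np.asarray(profile, float))


class TestSpectrogram:
    def test_full_scale_sine_hits_unit_amplitude_in_its_bin(self, sine):
        w, freq = sine
        spec = idx.amplitude_spectrogram(w, frame_len=512)
        k = int(np.argmax(spec.values.mean(axis=0)))
        assert k == round(freq / spec.freq_resolution)
        assert spec.values[:, k].mean() == pytest.approx(1.0, rel=0.05)

    def test_zero_input_gives_zero_matrix(self, silence):
        spec = idx.amplitude_spectrogram(silence)
        assert np.all(spec.values == 0)

    def test_white_noise_is_spectrally_flat(self):
        rng = np.random.default_rng(1)
        w = Waveform(0.3 * rng.standard_normal(RATE * 120), RATE)
        spec = idx.amplitude_spectrogram(w)
        means = spec.values.mean(axis=0)[1:]  # DC bin excluded
        assert means.std() / means.mean() < 0.1

    def test_too_short_waveform_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            idx.amplitude_spectrogram(Waveform(np.zeros(100), RATE))


class TestNoiseRemoval:
    def test_steady_tone_is_treated_as_background(self, sine):
        w, freq = sine
        spec = idx.amplitude_spectrogram(w)
        cleaned = idx.remove_background_noise(spec)
        k = round(freq / spec.freq_resolution)
        assert cleaned.values[:, k].mean() < 0.05 * spec.values[:, k].mean()

    def test_impulsive_call_survives_removal(self):
        rng = np.random.default_rng(2)
        x = 0.01 * rng.standard_normal(RATE * 10)
        freq = 46 * RATE / 512
        t = np.arange(int(0.3 * RATE)) / RATE
        call = 0.8 * np.sin(2 * np.pi * freq * t)
        x[3 * RATE: 3 * RATE + len(call)] += call
        spec = idx.amplitude_spectrogram(Waveform(x, RATE))
        cleaned = idx.remove_background_noise(spec)
        k = 46
        pre = spec.values[:, k].max()
        post = cleaned.values[:, k].max()
        assert post >= 0.9 * pre

    def test_removal_is_idempotent(self, rendered):
        spec = idx.amplitude_spectrogram(rendered)
        once = idx.remove_background_noise(spec)
        twice = idx.remove_background_noise(once)
        # residual background of an already-cleaned spectrogram is ~0
        assert np.abs(twice.noise_profile).max() < 0.05 * spec.values.max()
        assert np.allclose(twice.values, once.values,
                           atol=0.05 * spec.values.max())


class TestTemporalEntropy:
    def test_white_noise_has_flat_envelope(self, white_noise):
        assert idx.temporal_entropy(white_noise) > 0.97

    def test_single_click_concentrates_envelope(self):
        x = np.zeros(RATE * 5)
        x[RATE] = 1.0
        assert idx.temporal_entropy(Waveform(x, RATE)) < 0.2

    def test_two_level_envelope_matches_hand_computation(self):
        # square-modulated constant signal: half frames at 0.5, half at 0.05
        n_frames = 100
        amps = np.repeat([0.5, 0.05], n_frames // 2)
        x = np.concatenate([
            a * np.where(np.arange(512) % 2 == 0, 1.0, -1.0) for a in amps])
        got = idx.temporal_entropy(Waveform(x, RATE), frame_len=512)
        assert got == pytest.approx(entropy_oracle(amps), abs=1e-9)

    def test_silence_is_flagged_and_maximal(self, silence):
        with pytest.warns(idx.SilentRecordingWarning):
            assert idx.temporal_entropy(silence) == 1.0


class TestAcousticComplexity:
    def test_constant_tone_has_zero_complexity(self):
        spec = make_spec(np.tile([0, 0.8, 0], (50, 1)))
        assert idx.acoustic_complexity(spec, window_s=2.0) == 0.0

    def test_alternating_amplitude_closed_form(self):
        n = 200
        col = np.where(np.arange(n) % 2 == 0, 1.0, 2.0)
        spec = make_spec(col[:, None])
        frames_per_win = int(round(60.0 / spec.frame_duration))
        want = (n - 1) * 1.0 / (1.5 * n)  # -> 2/3 as n grows
        assert idx.acoustic_complexity(spec, 60.0) == pytest.approx(want)
        assert want == pytest.approx(2 / 3, abs=0.01)

    def test_noise_beats_tone_of_equal_power(self, sine):
        w, _ = sine
        rng = np.random.default_rng(3)
        noise = rng.standard_normal(len(w.samples))
        noise *= np.sqrt(np.mean(w.samples ** 2) / np.mean(noise ** 2))
        aci_noise = idx.acoustic_complexity(
            idx.amplitude_spectrogram(Waveform(noise, RATE)))
        aci_tone = idx.acoustic_complexity(idx.amplitude_spectrogram(w))
        assert aci_noise > aci_tone

    def test_all_zero_window_contributes_zero_not_nan(self):
        spec = make_spec(np.zeros((50, 4)))
        assert idx.acoustic_complexity(spec, 2.0) == 0.0


class TestSpectralEntropy:
    def test_pure_tone_is_concentrated(self, sine):
        w, _ = sine
        assert idx.spectral_entropy(idx.amplitude_spectrogram(w)) < 0.25

    def test_white_noise_is_maximal(self, white_noise):
        assert idx.spectral_entropy(idx.amplitude_spectrogram(white_noise)) > 0.95

    def test_two_equal_tones_closed_form(self):
        K = 64
        mean_spec = np.zeros(K)
        mean_spec[[10, 40]] = 1.0
        spec = make_spec(np.tile(mean_spec, (5, 1)))
        assert idx.spectral_entropy(spec) == pytest.approx(
            math.log(2) / math.log(K))


class TestSaturation:
    def test_silence_saturates_nothing(self, silence):
        spec = idx.amplitude_spectrogram(silence)
        cleaned = idx.remove_background_noise(spec)
        assert idx.soundscape_saturation(cleaned) == 0.0

    def test_known_active_mask_recovers_its_fraction(self):
        rng = np.random.default_rng(4)
        values = np.zeros((40, 40))
        mask = rng.permutation(40 * 40)[: 40 * 10]  # exactly 25 % of cells
        values.flat[mask] = 1.0
        spec = make_spec(values, profile=np.full(40, 0.01))
        assert idx.soundscape_saturation(spec, 3.0) == pytest.approx(25.0,
                                                                     abs=2.0)

    def test_saturation_grows_with_community_size(self, pool, plots):
        from sonoscape import simulate as sim
        # only species whose diel window covers the rendered hour can add
        # energy, so grow the community from those
        audible = [sp.species_id for sp in pool
                   if sp.guild != "insect_nocturnal"]
        sats = []
        for k in (0, 3, 12):
            row = pd.Series({sp.species_id: 1 if sp.species_id in audible[:k]
                             else 0 for sp in pool})
            w = sim.render_recording(plots[5], row, pool, 6 * 3600, 20.0,
                                     noise_db=-45.0, seed=21)
            cleaned = idx.remove_background_noise(idx.amplitude_spectrogram(w))
            sats.append(idx.soundscape_saturation(cleaned))
        assert sats[0] <= sats[1] <= sats[2]


class TestEvents:
    def test_silence_has_no_events(self, silence):
        assert idx.events_per_second(silence) == 0.0

    def test_five_clicks_in_ten_seconds(self):
        rng = np.random.default_rng(5)
        x = 0.001 * rng.standard_normal(RATE * 10)
        for s in (1.0, 3.0, 5.0, 7.0, 9.0):
            i = int(s * RATE)
            x[i: i + RATE // 10] += 0.8 * np.sin(
                2 * np.pi * 2000 * np.arange(RATE // 10) / RATE)
        assert idx.events_per_second(Waveform(x, RATE)) == pytest.approx(0.5)

    def test_poisson_call_train_rate_recovered(self):
        lam = 0.4
        rng = np.random.default_rng(6)
        dur = 120
        x = 0.001 * rng.standard_normal(RATE * dur)
        t = 0.0
        n = 0
        while True:
            t += rng.exponential(1 / lam)
            if t > dur - 0.5:
                break
            i = int(t * RATE)
            burst = 0.7 * np.sin(2 * np.pi * 3000 * np.arange(RATE // 8) / RATE)
            burst *= np.hanning(len(burst))
            x[i: i + len(burst)] += burst
            n += 1
        got = idx.events_per_second(Waveform(x, RATE))
        assert got == pytest.approx(n / dur, rel=0.15)


class TestBandIndices:
    def test_equal_activity_maximises_diversity(self):
        nyq_bands = 11  # 22.05 kHz / 2 / 1000
        values = np.full((30, 256), 1.0)
        spec = make_spec(values, profile=np.full(256, 0.01))
        adi, aei, _ = idx.adi_aei_bi(spec, bi_band=(2000, 8000))
        assert adi == pytest.approx(math.log(nyq_bands))
        assert aei == 0.0

    def test_single_band_activity_is_least_even(self):
        values = np.zeros((30, 256))
        values[:, 10:20] = 1.0  # inside band 0 (0-1 kHz)
        spec = make_spec(values, profile=np.full(256, 0.01))
        adi, aei, _ = idx.adi_aei_bi(spec)
        assert adi == pytest.approx(0.0)
        assert aei == pytest.approx(10 / 11)  # (n-1)/n for 11 bands

    def test_hand_built_proportions_match_formulas(self):
        props = [0.6, 0.3, 0.1]
        assert adi_oracle(props) == pytest.approx(
            -sum(p / 1.0 * math.log(p) for p in props))
        assert gini_oracle(props) == pytest.approx(
            sum(abs(a - b) for a in props for b in props) / (2 * 3 * 1.0))

    def test_silence_yields_zero_triplet_with_warning(self, silence):
        cleaned = idx.remove_background_noise(idx.amplitude_spectrogram(silence))
        with pytest.warns(idx.SilentRecordingWarning):
            assert idx.adi_aei_bi(cleaned) == (0.0, 0.0, 0.0)


class TestOracleEquivalence:
    """Every index equals a direct brute-force evaluation on small
    constructed matrices."""

    def test_indices_match_bruteforce_on_small_matrix(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 1, (10, 10)) ** 2
        profile = np.full(10, 0.05)
        spec = make_spec(values, rate=20_000, frame_len=20, profile=profile)
        # 20-sample frames @20 kHz -> 1000 Hz/bin, 10 bands up to 10 kHz
        fpw = int(round(60.0 / spec.frame_duration))
        assert idx.acoustic_complexity(spec, 60.0) == pytest.approx(
            aci_oracle(values, fpw), abs=1e-12)
        assert idx.spectral_entropy(spec) == pytest.approx(
            entropy_oracle(values.mean(axis=0)), abs=1e-12)
        assert idx.soundscape_saturation(spec, 3.0) == pytest.approx(
            saturation_oracle(values, profile, 3.0), abs=1e-12)
        adi, aei, bi = idx.adi_aei_bi(spec, band_width=1000.0,
                                      bi_band=(2000, 8000),
                                      activity_threshold_db=3.0)
        gain = 10 ** (3 / 20) - 1
        props = [(values[:, k] > gain * 0.05).mean() for k in range(10)]
        assert adi == pytest.approx(adi_oracle(props), abs=1e-12)
        assert aei == pytest.approx(gini_oracle(props), abs=1e-12)
        assert bi == pytest.approx(
            bi_oracle(values, spec.bin_freqs(), (2000, 8000)), abs=1e-9)


class TestScaleInvariance:
    def test_ratio_indices_ignore_amplitude_scale(self, rendered):
        half = Waveform(rendered.samples * 0.5, rendered.rate)
        for w_a, w_b in [(rendered, half)]:
            sa = idx.amplitude_spectrogram(w_a)
            sb = idx.amplitude_spectrogram(w_b)
            assert abs(idx.temporal_entropy(w_a) - idx.temporal_entropy(w_b)) < 1e-6
            assert abs(idx.spectral_entropy(sa) - idx.spectral_entropy(sb)) < 1e-6
            assert abs(idx.acoustic_complexity(sa) - idx.acoustic_complexity(sb)) < 1e-6


class TestPlotSummary:
    def _frame(self, rows):
        cols = ["plot_id", "start_time"] + idx.INDEX_COLUMNS
        return pd.DataFrame(rows, columns=cols)

    def test_single_recording_summary_is_itself(self):
        df = self._frame([["p1", 0.0, .4, 1, .5, 10, .1, 1, .2, 5]])
        out = idx.summarize_plot_indices(df)
        assert out.loc["p1", "H_t"] == 0.4
        assert out.loc["p1", "n_recordings"] == 1

    def test_mean_of_two_recordings(self):
        df = self._frame([["p1", 0.0, .4, 1, .5, 10, .1, 1, .2, 5],
                          ["p1", 1.0, .6, 3, .7, 20, .3, 2, .4, 7]])
        out = idx.summarize_plot_indices(df)
        assert out.loc["p1", "H_t"] == pytest.approx(0.5)
        assert out.loc["p1", "ACI"] == pytest.approx(2.0)

    def test_order_invariance(self):
        rows = [["p1", 0.0, .4, 1, .5, 10, .1, 1, .2, 5],
                ["p2", 0.0, .2, 2, .6, 30, .2, 1, .3, 6],
                ["p1", 1.0, .6, 3, .7, 20, .3, 2, .4, 7]]
        a = idx.summarize_plot_indices(self._frame(rows))
        b = idx.summarize_plot_indices(self._frame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no recordings"):
            idx.summarize_plot_indices(pd.DataFrame())


class TestRangesOnSimulatorOutput:
    def test_all_indices_within_stated_ranges(self, rendered):
        s = idx.compute_indices(rendered, aci_window_s=10.0)
        assert 0 <= s.H_t <= 1 and 0 <= s.H_f <= 1
        assert 0 <= s.saturation <= 100
        assert s.ACI >= 0 and s.events_per_second >= 0
        assert s.ADI >= 0 and 0 <= s.AEI <= 1 and s.BI >= 0
        assert not any(np.isnan(v) for v in s.as_dict().values())
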