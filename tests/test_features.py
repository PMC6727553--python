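"""Segmentation, periodogram, band powers, ratios and EMG energy."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import signal as sps

from ratsleep import features, io, synthetic
from ratsleep.features import BANDS, DB_FLOOR

RATE = 200.0


def tone(f, rate=RATE, dur=2.0, amp=1.0, phase=0.0):
    t = np.arange(int(rate * dur)) / rate
    return amp * np.sin(2 * np.pi * f * t + phase)


def recording(eeg_s, emg_s=None, eeg_rate=RATE, emg_rate=500.0):
    if emg_s is None:
        emg_s = np.zeros(int(emg_rate * len(eeg_s) / eeg_rate))
    return io.Recording(eeg=eeg_s, eeg_rate=eeg_rate, emg=emg_s, emg_rate=emg_rate)


class TestSegmentation:
    @pytest.mark.parametrize("dur,n_epochs", [(60, 6), (67, 6), (10, 1)])
    def test_epoch_and_segment_counts(self, dur, n_epochs):
        rec = recording(np.zeros(int(RATE * dur)))
        groups = features.segment_epochs(rec)
        assert len(groups) == n_epochs
        assert all(len(g) == 5 for g in groups)

    def test_day_long_session_epoch_count(self):
        # a 26-h session at 10-s epochs
        assert features.epoch_count(26 * 3600.0) == 9360

    def test_sub_epoch_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter than one"):
            features.segment_epochs(recording(np.zeros(int(RATE * 7))))

    def test_epoch_must_be_multiple_of_segment(self):
        rec = recording(np.zeros(int(RATE * 60)))
        with pytest.raises(ValueError, match="integer multiple"):
            features.segment_epochs(rec, epoch_s=10.0, segment_s=3.0)


class TestPeriodogram:
    def test_pure_tone_concentrates_in_its_bin(self):
        freqs, power = features.periodogram(tone(4.0), RATE)
        i = np.argmin(np.abs(freqs - 4.0))
        assert power[i] == pytest.approx(0.5, rel=1e-9)
        assert np.sum(power) == pytest.approx(0.5, rel=1e-9)
        off = np.delete(power, i)
        assert np.max(off) < 1e-20

    def test_constant_signal_is_pure_dc(self):
        c = 3.7
        freqs, power = features.periodogram(np.full(400, c), RATE)
        assert power[0] == pytest.approx(c**2, rel=1e-12)
        assert np.sum(power[1:]) < 1e-20

    def test_wrong_segment_length_rejected(self):
        with pytest.raises(ValueError, match="2-s segment"):
            features.periodogram(np.zeros(399), RATE)

    @given(st.integers(0, 2**32 - 1))
    def test_parseval_on_white_noise(self, seed):
        x = np.random.default_rng(seed).standard_normal(400)
        _, power = features.periodogram(x, RATE)
        # oracle: direct time-domain mean square
        assert np.sum(power) == pytest.approx(np.mean(x**2), rel=1e-9)

    def test_grid_is_half_hz_at_any_rate(self):
        for rate in (200.0, 500.0, 250.0):
            freqs, _ = features.periodogram(np.zeros(int(2 * rate)), rate)
            assert np.allclose(np.diff(freqs), 0.5)


class TestBandPower:
    def test_zero_segment_sits_at_the_floor(self):
        freqs, power = features.periodogram(np.zeros(400), RATE)
        for band in ("eeg_lo", "delta", "theta", "alpha", "beta", "gamma"):
            assert features.band_power_db(power, freqs, BANDS[band]) == \
                pytest.approx(-120.0, abs=1e-9)

    def test_tone_band_dominates_other_bands(self):
        freqs, power = features.periodogram(tone(4.0), RATE)
        sp_delta = features.band_power_db(power, freqs, BANDS["delta"])
        sp_theta = features.band_power_db(power, freqs, BANDS["theta"])
        # the tone lifts one of delta's nine bins ~117 dB above the floor,
        # i.e. ~13 dB on the band mean; theta stays at the floor
        assert sp_delta > sp_theta + 10.0

    def test_seven_hz_tone_matches_bin_enumeration(self):
        freqs, power = features.periodogram(tone(7.0), RATE)
        got = features.band_power_db(power, freqs, BANDS["theta"])
        # oracle: enumerate the six bins at 6.0-8.5 Hz by hand
        bins = [np.argmin(np.abs(freqs - f)) for f in (6.0, 6.5, 7.0, 7.5, 8.0, 8.5)]
        expected = np.mean([10 * np.log10(power[b] + DB_FLOOR) for b in bins])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_band_off_grid_is_a_configuration_error(self):
        freqs, power = features.periodogram(np.zeros(400), RATE)
        with pytest.raises(ValueError, match="no\\s+bins"):
            features.band_power_db(power, freqs,
                                   features.BandDefinition("tiny", 7.1, 7.3))


class TestPowerRatio:
    def test_in_band_tone_takes_the_whole_ratio(self):
        freqs, power = features.periodogram(tone(4.0), RATE)
        assert features.power_ratio(power, freqs, BANDS["delta"]) >= 0.999

    def test_dc_signal_fills_the_low_band(self):
        freqs, power = features.periodogram(np.full(400, 2.0), RATE)
        assert features.power_ratio(power, freqs, BANDS["eeg_lo"]) == \
            pytest.approx(1.0, rel=1e-12)

    def test_equal_tones_split_evenly(self):
        freqs, power = features.periodogram(tone(2.0) + tone(12.0, phase=1.0), RATE)
        assert features.power_ratio(power, freqs, BANDS["delta"]) == \
            pytest.approx(0.5, rel=1e-9)
        assert features.power_ratio(power, freqs, BANDS["alpha"]) == \
            pytest.approx(0.5, rel=1e-9)

    def test_zero_total_power_gives_zero(self):
        freqs, power = features.periodogram(np.zeros(400), RATE)
        assert features.power_ratio(power, freqs, BANDS["delta"]) == 0.0

    @given(st.integers(0, 2**32 - 1))
    def test_disjoint_band_ratios_sum_below_one(self, seed):
        x = np.random.default_rng(seed).standard_normal(400)
        freqs, power = features.periodogram(x, RATE)
        total = sum(
            features.power_ratio(power, freqs, BANDS[b])
            for b in ("eeg_lo", "delta", "alpha")
        )
        assert total <= 1.0 + 1e-12


class TestEmg:
    def test_dc_killed_by_highpass(self):
        x = np.full(5000, 10.0)
        y = features.emg_bandpass(x, 500.0)
        assert np.sqrt(np.mean(y**2)) < 10.0 * 10 ** (-40 / 20)

    def test_passband_center_preserved(self):
        t = np.arange(10 * 500) / 500.0
        x = np.sin(2 * np.pi * 50 * t)
        y = features.emg_bandpass(x, 500.0)
        mid = y[1000:-1000]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation_matches_filter_response(self):
        t = np.arange(10 * 500) / 500.0
        x = np.sin(2 * np.pi * 200 * t)
        y = features.emg_bandpass(x, 500.0)
        measured_db = 20 * np.log10(
            np.sqrt(np.mean(y[1000:-1000] ** 2)) / np.sqrt(0.5)
        )
        assert measured_db <= -20.0
        # oracle: squared magnitude response (forward-backward) at 200 Hz
        sos = sps.butter(4, [10, 100], btype="bandpass", fs=500.0, output="sos")
        _, h = sps.sosfreqz(sos, worN=[200.0], fs=500.0)
        expected_db = 40 * np.log10(np.abs(h[0]))
        assert measured_db == pytest.approx(expected_db, abs=2.0)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            features.emg_bandpass(np.zeros(1000), 200.0)

    def test_energy_of_zero_segment(self):
        assert features.emg_energy(np.zeros(1000)) == 0.0

    def test_energy_of_rectified_sine_close_to_2A_over_pi(self):
        amp = 7.0
        t = np.arange(2 * 500) / 500.0
        x = amp * np.sin(2 * np.pi * 50 * t)  # whole cycles
        assert features.emg_energy(x) == pytest.approx(2 * amp / np.pi, rel=0.05)

    @given(st.integers(0, 2**32 - 1))
    def test_energy_equals_direct_summation(self, seed):
        x = np.random.default_rng(seed).standard_normal(500)
        expected = sum(abs(v) for v in x) / len(x)
        assert features.emg_energy(x) == pytest.approx(expected, rel=1e-12)


class TestExtractFeatures:
    def test_shape_one_epoch(self):
        fm = features.extract_features(recording(np.zeros(int(RATE * 10))))
        assert len(fm.data) == 5
        assert list(fm.data.columns) == ["epoch", "segment"] + features.FEATURE_NAMES

    def test_pure_delta_eeg_and_silent_emg(self):
        eeg = np.concatenate([tone(2.0, dur=2.0)] * 5)
        fm = features.extract_features(recording(eeg))
        assert (fm.data["pr_delta"] >= 0.999).all()
        assert (fm.data["emg_energy"] == 0.0).all()

    def test_deterministic(self):
        rec, _ = synthetic.generate_study(n_epochs=6, seed=3)
        a = features.extract_features(rec)
        b = features.extract_features(rec)
        assert a.data.equals(b.data)

    def test_nrem2_epoch_has_majority_delta_segments(self):
        eeg, emg = synthetic.synthesize_epoch("N2", seed=5)
        fm = features.extract_features(
            io.Recording(eeg=eeg, eeg_rate=200.0, emg=emg, emg_rate=500.0)
        )
        assert (fm.data["pr_delta"] > 0.5).sum() >= 3

    def test_emg_segments_align_with_eeg_windows(self):
        # an EMG burst confined to [4, 6) s shows up in segment 2 only
        emg = np.zeros(10 * 500)
        t = np.arange(4 * 500, 6 * 500) / 500.0
        emg[4 * 500:6 * 500] = 50 * np.sin(2 * np.pi * 50 * t)
        fm = features.extract_features(recording(np.zeros(int(RATE * 10)), emg))
        energies = fm.data["emg_energy"].to_numpy()
        assert np.argmax(energies) == 2
        assert energies[2] > 10 * max(energies[0], energies[4])
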