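"""Connectivity chain: preprocessing, windowed Fourier phase, PLI,
band averaging, trimming and global aggregation."""

import numpy as np
import pytest

from avconn import (
    band_average,
    band_pli,
    global_connectivity,
    pli,
    pli_matrix,
    preprocess,
    trim_epochs,
    wft_phase,
)
from avconn.connectivity import (
    ANALYSIS_CHANNELS_28,
    RAW_CHANNELS_32,
    EpochArray,
    SpectralPhase,
    wft_coefficients,
)


def make_phase(phase_array, freqs=None, fs=250.0):
    """Wrap a raw (ch, samples, freqs, trials) phase array."""
    phase_array = np.asarray(phase_array, float)
    if freqs is None:
        freqs = np.arange(1, phase_array.shape[2] + 1, dtype=float)
    return SpectralPhase(
        phase=phase_array,
        freqs=np.asarray(freqs, float),
        fs=fs,
        times_ms=-800.0 + np.arange(phase_array.shape[1]) * 1000.0 / fs,
    )


class TestPreprocess:
    def _raw32(self, rng, n_trials=3):
        return EpochArray(
            data=rng.normal(size=(32, 700, n_trials)),
            channel_names=RAW_CHANNELS_32,
        )

    def test_32_to_28_channels(self):
        out = preprocess(self._raw32(np.random.default_rng(0)))
        assert out.n_channels == 28
        assert out.channel_names == ANALYSIS_CHANNELS_28

    def test_missing_mastoids_error(self):
        raw = EpochArray(
            data=np.zeros((3, 700, 1)), channel_names=("a", "b", "c")
        )
        with pytest.raises(KeyError):
            preprocess(raw)

    def test_zero_mastoids_equivalent_to_filtering_only(self):
        # synthetic data already referenced: zero mastoid channels mean the
        # re-referencing step is a no-op, so output equals band-pass +
        # baseline alone
        rng = np.random.default_rng(1)
        raw = self._raw32(rng)
        idx = [RAW_CHANNELS_32.index(m) for m in ("TP9", "TP10")]
        raw.data[idx] = 0.0
        with_reref = preprocess(raw)
        without = preprocess(raw, mastoids=None, eog=("HEOG", "VEOG", "TP9", "TP10"))
        assert np.allclose(with_reref.data, without.data)

    def test_out_of_band_tone_attenuated(self):
        # 60-Hz line-frequency tone must lose >= 20 dB through the 1-50 Hz
        # zero-phase band-pass
        fs = 250.0
        t = np.arange(700) / fs
        tone = np.cos(2 * np.pi * 60.0 * t)
        raw = EpochArray(
            data=np.tile(tone, (32, 1))[:, :, None],
            channel_names=RAW_CHANNELS_32,
        )
        out = preprocess(raw, baseline=False)
        # compare mid-epoch RMS to avoid filtfilt edge transients
        ratio = np.sqrt(np.mean(out.data[0, 200:500, 0] ** 2)) / np.sqrt(
            np.mean(tone[200:500] ** 2)
        )
        assert ratio < 10 ** (-20 / 20)  # >= 20 dB attenuation

    def test_baseline_removes_prestimulus_mean(self):
        rng = np.random.default_rng(2)
        raw = self._raw32(rng)
        out = preprocess(raw)
        pre = out.times_ms < 0
        assert np.allclose(out.data[:, pre, :].mean(axis=1), 0.0, atol=1e-10)


class TestWFTPhase:
    def test_matches_bruteforce_windowed_sum(self):
        # independent oracle: direct double loop over (t, f) computing the
        # windowed complex inner product
        rng = np.random.default_rng(4)
        fs = 250.0
        x = rng.normal(size=120)
        freqs = [3.0, 10.0, 27.0]
        got = wft_coefficients(x, fs, freqs)
        w = 50
        window = np.hamming(w)
        c = w // 2
        for fi, f in enumerate(freqs):
            for t in (0, 25, 60, 119):
                acc = 0.0j
                for k in range(w):
                    idx = t + k - c
                    if 0 <= idx < len(x):
                        acc += x[idx] * window[k] * np.exp(-2j * np.pi * f * (k - c) / fs)
                assert got[t, fi] == pytest.approx(acc, rel=1e-9, abs=1e-12)

    def test_phase_tracks_analytic_phase(self):
        # noiseless cosine: extracted phase equals theta + 2 pi f t within
        # 0.05 rad at the probe frequency, mid-epoch
        fs, f0, theta = 250.0, 10.0, 0.7
        times = (-800.0 + np.arange(700) * 1000.0 / fs) / 1000.0
        x = np.cos(2 * np.pi * f0 * times + theta)
        ep = EpochArray(data=x[None, :, None], channel_names=("c0",))
        phase = wft_phase(ep, freqs=[f0])
        for t in (250, 350, 450):
            expected = np.angle(np.exp(1j * (2 * np.pi * f0 * times[t] + theta)))
            err = np.angle(np.exp(1j * (phase.phase[0, t, 0, 0] - expected)))
            assert abs(err) < 0.05

    def test_identical_channels_zero_phase_difference(self, random_epochs):
        ep = EpochArray(
            data=np.vstack([random_epochs.data[:1], random_epochs.data[:1]]),
            channel_names=("a", "b"),
        )
        phase = wft_phase(ep, freqs=[5.0, 20.0])
        assert np.allclose(phase.phase[0], phase.phase[1])

    def test_phase_wrapped(self, random_epochs):
        phase = wft_phase(random_epochs, freqs=[7.0])
        assert (np.abs(phase.phase) <= np.pi).all()

    def test_out_of_range_frequency_rejected(self, random_epochs):
        with pytest.raises(ValueError):
            wft_phase(random_epochs, freqs=[0.5])
        with pytest.raises(ValueError):
            wft_phase(random_epochs, freqs=[51.0])


class TestPLI:
    def test_constant_lag_gives_one(self):
        ph = np.zeros((2, 10, 1, 8))
        ph[0] += np.pi / 4
        assert np.allclose(pli(make_phase(ph), 0, 1), 1.0)

    def test_balanced_lags_cancel(self):
        ph = np.zeros((2, 5, 1, 8))
        ph[0, :, :, :4] += np.pi / 4
        ph[0, :, :, 4:] -= np.pi / 4
        assert np.allclose(pli(make_phase(ph), 0, 1), 0.0)

    def test_zero_lag_contributes_nothing(self):
        ph = np.tile(np.random.default_rng(0).uniform(-np.pi, np.pi, (1, 6, 2, 9)), (2, 1, 1, 1))
        assert np.allclose(pli(make_phase(ph), 0, 1), 0.0)

    def test_diagonal_is_zero(self):
        ph = np.random.default_rng(1).uniform(-np.pi, np.pi, (3, 4, 2, 5))
        assert np.allclose(pli(make_phase(ph), 1, 1), 0.0)

    def test_uniform_phases_bounded(self):
        # |mean of N=100 random signs| <= 0.3 in >= 99% of draws
        rng = np.random.default_rng(12)
        exceed = 0
        n_draws = 300
        for _ in range(n_draws):
            ph = rng.uniform(-np.pi, np.pi, (2, 1, 1, 100))
            exceed += pli(make_phase(ph), 0, 1)[0, 0] > 0.3
        assert exceed / n_draws <= 0.01 + 0.02  # 0.997 expected under the null

    def test_matrix_symmetric_with_zero_diagonal(self):
        ph = np.random.default_rng(2).uniform(-np.pi, np.pi, (4, 6, 3, 7))
        mat = pli_matrix(make_phase(ph))
        assert np.allclose(mat, mat.transpose(1, 0, 2, 3))
        assert np.allclose(mat[np.arange(4), np.arange(4)], 0.0)

    def test_amplitude_invariance(self, random_epochs):
        scaled = EpochArray(
            data=random_epochs.data * np.array([1.0, 10.0, 0.1, 3.0])[:, None, None],
            channel_names=random_epochs.channel_names,
        )
        a = band_pli(random_epochs, "alpha")
        b = band_pli(scaled, "alpha")
        assert np.allclose(a.pli, b.pli)


class TestBandAverage:
    def test_constant_band(self):
        freqs = np.arange(1, 51, dtype=float)
        vals = np.full((3, 50), 0.42)
        assert np.allclose(band_average(vals, freqs, (4, 7)), 0.42)

    def test_theta_uses_exactly_four_bins(self):
        freqs = np.arange(1, 51, dtype=float)
        vals = np.zeros((1, 50))
        vals[0, 3:7] = [0.1, 0.2, 0.3, 0.4]  # 4,5,6,7 Hz
        assert band_average(vals, freqs, (4, 7))[0] == pytest.approx(0.25)

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(5)
        freqs = np.arange(1, 51, dtype=float)
        vals = rng.random((2, 50))
        got = band_average(vals, freqs, (14, 30))
        expected = np.array([
            sum(vals[i, f - 1] for f in range(14, 31)) / 17 for i in range(2)
        ])
        assert np.allclose(got, expected)

    def test_empty_band_errors(self):
        with pytest.raises(ValueError):
            band_average(np.zeros((1, 3)), np.array([1.0, 2.0, 3.0]), (10, 12))


class TestTrim:
    def test_700_to_200_samples(self, random_epochs):
        tensor = band_pli(random_epochs, "theta")
        trimmed = trim_epochs(tensor)
        assert trimmed.pli.shape[-1] == 200
        assert trimmed.times_ms[0] == -200.0
        assert trimmed.times_ms[-1] == 596.0

    def test_partition_arithmetic(self, random_epochs):
        tensor = band_pli(random_epochs, "theta")
        trimmed = trim_epochs(tensor)
        assert tensor.pli.shape[-1] == 150 + trimmed.pli.shape[-1] + 350

    def test_double_trim_errors(self, random_epochs):
        trimmed = trim_epochs(band_pli(random_epochs, "theta"))
        with pytest.raises(ValueError):
            trim_epochs(trimmed)


class TestGlobalConnectivity:
    def test_constant_network(self, random_epochs):
        tensor = band_pli(random_epochs, "theta")
        n = tensor.n_channels
        tensor.pli = np.full_like(tensor.pli, 0.5)
        tensor.pli[np.arange(n), np.arange(n)] = 0.0
        series = global_connectivity(tensor)
        assert np.allclose(series.mean_pli, 0.5)

    def test_single_pair_counting(self):
        n, s = 28, 4
        mat = np.zeros((n, n, s))
        mat[0, 1] = mat[1, 0] = 1.0
        from avconn.connectivity import PLITensor
        tensor = PLITensor(
            pli=mat, band="theta", band_hz=(4, 7),
            times_ms=np.arange(s, dtype=float),
            channel_names=tuple(f"c{i}" for i in range(n)),
        )
        series = global_connectivity(tensor)
        assert np.allclose(series.mean_pli, 1.0 / 378.0)

    def test_matches_bruteforce_double_loop(self, random_epochs):
        tensor = band_pli(random_epochs, "alpha")
        series = global_connectivity(tensor)
        n = tensor.n_channels
        expected = np.zeros(tensor.pli.shape[-1])
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                expected += tensor.pli[i, j]
                count += 1
        assert np.allclose(series.mean_pli, expected / count)


class TestStreamingEquivalence:
    def test_band_pli_equals_composed_steps(self, random_epochs):
        # streaming path == wft_phase -> pli_matrix -> band_average
        tensor = band_pli(random_epochs, "theta")
        phase = wft_phase(random_epochs, freqs=np.arange(4, 8, dtype=float))
        composed = band_average(pli_matrix(phase), phase.freqs, (4, 7))
        assert np.allclose(tensor.pli, composed)


class TestVolumeConduction:
    def test_common_signal_does_not_disturb_lagged_pli(self):
        from avconn.synthetic import EEGGenSpec, OscillatorSource, generate_eeg_dataset

        src = OscillatorSource(
            freq_hz=10.0, channel_lags={0: 0.0, 1: np.pi / 2}, kappa=1e6
        )
        base = EEGGenSpec(n_channels=2, n_trials=50, sources=(src,), noise_sd=0.2, seed=33)
        with_common = EEGGenSpec(
            n_channels=2, n_trials=50, sources=(src,), noise_sd=0.2,
            common_zero_lag_amplitude=0.3, seed=33,
        )
        (ep0,) = generate_eeg_dataset(base, 1)
        (ep1,) = generate_eeg_dataset(with_common, 1)
        p0 = trim_epochs(band_pli(ep0, "alpha")).pli[0, 1]
        p1 = trim_epochs(band_pli(ep1, "alpha")).pli[0, 1]
        assert np.abs(p0 - p1).mean() < 0.05
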