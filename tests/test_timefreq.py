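"""Morlet bank geometry, ITPC algebra, induced power, matrix binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirpeeg import preprocess as pp
from chirpeeg import synthgen as sg
from chirpeeg import timefreq as tf


def _epochs_from(trials, fs=625.0, t0_offset=0.5):
    trials = np.asarray(trials, dtype=float)
    return pp.EpochArray(
        epochs=trials[:, None, :], t0_offset=t0_offset,
        rejected=np.zeros(trials.shape[0], dtype=bool), fs=fs,
        channel_labels=["ch00"], region_assignment={"ch00": "LF"},
    )


def _coeffs(F):
    F = np.asarray(F, dtype=np.complex128)
    return tf.TrialCoefficients(
        F=F, freqs=np.arange(1.0, 1.0 + F.shape[1]), fs=625.0,
        validity=np.ones(F.shape[1:], dtype=bool),
    )


class TestWaveletBank:
    def test_spectral_bandwidth(self):
        bank = tf.build_wavelet_bank(fs=625.0)
        i40 = int(np.where(bank.center_freqs == 40.0)[0][0])
        assert bank.sigma_f[i40] == pytest.approx(4.0)

    def test_unit_energy_and_odd_length(self):
        bank = tf.build_wavelet_bank(fs=625.0)
        for ker in bank.kernels:
            assert np.linalg.norm(ker) == pytest.approx(1.0)
            assert len(ker) % 2 == 1

    def test_gaussian_frequency_selectivity(self):
        """40-Hz kernel responds more to 40 Hz than 48 Hz, in the ratio of
        the Gaussian spectral profile exp(-df^2/(2 sigma_f^2))."""
        fs = 625.0
        bank = tf.build_wavelet_bank(freqs=[40.0], fs=fs)
        ker = bank.kernels[0]
        t = np.arange(len(ker)) / fs
        resp = {f: abs(np.vdot(ker, np.exp(2j * np.pi * f * t))) for f in (40.0, 48.0)}
        assert resp[40.0] > resp[48.0]
        expected = np.exp(-(8.0**2) / (2 * 4.0**2))
        assert resp[48.0] / resp[40.0] == pytest.approx(expected, rel=0.05)

    def test_admissibility_guard(self):
        with pytest.raises(sg.ValidationError):
            tf.build_wavelet_bank(c=3.0, fs=625.0)
        with pytest.raises(sg.ValidationError):
            tf.build_wavelet_bank(freqs=[400.0], fs=625.0)


class TestTransform:
    def test_sinusoid_constant_magnitude(self):
        fs = 625.0
        t = np.arange(1875) / fs
        ep = _epochs_from([np.sin(2 * np.pi * 40 * t)])
        bank = tf.build_wavelet_bank(freqs=[40.0], fs=fs)
        tc = tf.transform_epochs(ep, bank, "LF")
        mag = np.abs(tc.F[0, 0])[tc.validity[0]]
        assert mag.std() / mag.mean() < 0.02

    def test_zero_trial_zero_coefficients(self):
        ep = _epochs_from([np.zeros(1875)])
        bank = tf.build_wavelet_bank(freqs=[10.0, 40.0], fs=625.0)
        tc = tf.transform_epochs(ep, bank, "LF")
        np.testing.assert_allclose(np.abs(tc.F), 0.0)

    def test_rejected_trials_excluded(self):
        rng = np.random.default_rng(0)
        ep = _epochs_from(rng.standard_normal((5, 1875)))
        ep.rejected[1] = True
        bank = tf.build_wavelet_bank(freqs=[20.0], fs=625.0)
        assert tf.transform_epochs(ep, bank, "LF").n == 4

    def test_unknown_selector_errors(self):
        ep = _epochs_from(np.zeros((1, 1875)))
        bank = tf.build_wavelet_bank(freqs=[20.0], fs=625.0)
        with pytest.raises(sg.ValidationError):
            tf.transform_epochs(ep, bank, "XX")


class TestItpc:
    def test_identical_trials_unity(self):
        rng = np.random.default_rng(1)
        one = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        F = np.tile(one, (8, 3, 1))
        itpc = tf.compute_itpc(_coeffs(F))
        np.testing.assert_allclose(itpc.values, 1.0, atol=1e-7)

    def test_antipodal_pair_cancels(self):
        one = np.full((1, 1, 4), 1.0 + 1.0j)
        F = np.concatenate([one, -one])
        itpc = tf.compute_itpc(_coeffs(F))
        np.testing.assert_allclose(itpc.values, 0.0, atol=1e-12)

    def test_four_phasor_worked_case(self):
        """Phases {0, 90, 90, 90} deg -> |1 + 3i|/4 = sqrt(10)/4."""
        F = np.exp(1j * np.deg2rad([0.0, 90.0, 90.0, 90.0]))[:, None, None]
        itpc = tf.compute_itpc(_coeffs(F))
        assert itpc.values[0, 0] == pytest.approx(np.sqrt(10.0) / 4.0)

    def test_uniform_phase_null_level(self):
        """E[ITPC^2] = 1/n for uniform phases; checked at n=300 over many
        (f, t) points against the exact phasor-sum expectation."""
        rng = np.random.default_rng(2)
        n = 300
        F = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(n, 40, 200)))
        itpc = tf.compute_itpc(_coeffs(F))
        stat = n * itpc.values**2
        se = stat.std() / np.sqrt(stat.size)
        assert abs(stat.mean() - 1.0) < 3 * se + 0.02

    def test_scaling_invariance(self):
        rng = np.random.default_rng(3)
        F = rng.standard_normal((6, 2, 9)) + 1j * rng.standard_normal((6, 2, 9))
        gains = rng.uniform(0.1, 10.0, size=(6, 1, 1))
        a = tf.compute_itpc(_coeffs(F)).values
        b = tf.compute_itpc(_coeffs(F * gains)).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_zero_magnitude_points_excluded(self):
        F = np.ones((4, 1, 2), dtype=complex)
        F[0, 0, 0] = 0.0        # carries no phase at that point
        itpc = tf.compute_itpc(_coeffs(F))
        np.testing.assert_allclose(itpc.values, 1.0)

    def test_single_trial_rejected(self):
        with pytest.raises(sg.ValidationError):
            tf.compute_itpc(_coeffs(np.ones((1, 1, 1), dtype=complex)))

    @given(st.integers(2, 12))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, n):
        rng = np.random.default_rng(n)
        F = rng.standard_normal((n, 3, 5)) + 1j * rng.standard_normal((n, 3, 5))
        v = tf.compute_itpc(_coeffs(F)).values
        assert np.all(v >= 0.0) and np.all(v <= 1.0 + 1e-12)


class TestInducedPower:
    def test_identical_trials_no_induced(self):
        fs = 625.0
        t = np.arange(1875) / fs
        sig = np.sin(2 * np.pi * 40 * t) * (t > 0.5)
        ep = _epochs_from(np.tile(sig, (6, 1)))
        bank = tf.build_wavelet_bank(freqs=[40.0], fs=fs)
        with pytest.raises(sg.ValidationError, match="baseline"):
            # all power is evoked; removing it leaves a zero baseline
            tf.induced_power(ep, bank, "LF")

    def test_noise_only_equals_total(self):
        rng = np.random.default_rng(4)
        fs = 625.0
        x = rng.standard_normal((40, 1875))
        ep = _epochs_from(x)
        bank = tf.build_wavelet_bank(freqs=[30.0], fs=fs)
        ind = tf.induced_power(ep, bank, "LF")
        tc = tf.transform_epochs(ep, bank, "LF")
        total = (np.abs(tc.F) ** 2).mean(axis=0)
        base = total[:, (ep.times >= -0.5) & (ep.times < 0)].mean(axis=1)
        total_pct = 100.0 * (total - base[:, None]) / base[:, None]
        # evoked average ~ 0 for independent noise -> induced ~ total
        diff = np.abs(ind.values - total_pct)[ind.validity]
        assert np.percentile(diff, 95) < 15.0

    def test_nonlocked_burst_detected(self):
        """A 40-Hz burst at 1-1.5 s with random phase per trial appears as
        positive induced power there and nowhere in the baseline."""
        rng = np.random.default_rng(5)
        fs = 625.0
        t = np.arange(1875) / fs - 0.5
        window = (t >= 1.0) & (t < 1.5)
        trials = 0.5 * rng.standard_normal((30, 1875))
        for k in range(30):
            trials[k] += 3.0 * np.sin(2 * np.pi * 40 * (t + rng.uniform(0, 1))) * window
        ep = _epochs_from(trials)
        bank = tf.build_wavelet_bank(freqs=[40.0], fs=fs)
        ind = tf.induced_power(ep, bank, "LF")
        in_burst = ind.values[0, window].mean()
        pre = ind.values[0, (t >= -0.4) & (t < 0)].mean()
        assert in_burst > 100.0
        assert abs(pre) < 30.0


class TestBinning:
    def _map(self, values):
        values = np.asarray(values, dtype=float)
        return tf.TimeFrequencyMap(
            values=values, kind="total_power", n_trials=10,
            epoch_span=3.0, freqs=np.arange(1.0, 1.0 + values.shape[0]),
        )

    def test_output_shape_100x625(self):
        binned = tf.bin_to_matrix(self._map(np.zeros((100, 1875))))
        assert binned.values.shape == (100, 625)

    def test_constant_map_preserved(self):
        binned = tf.bin_to_matrix(self._map(np.full((3, 1875), 2.5)))
        np.testing.assert_allclose(binned.values, 2.5)

    def test_ramp_block_means(self):
        ramp = np.linspace(0.0, 1.0, 1875)
        binned = tf.bin_to_matrix(self._map(ramp[None, :]))
        expected = ramp.reshape(625, 3).mean(axis=1)
        np.testing.assert_allclose(binned.values[0], expected)

    def test_remainder_folds_into_last_bin(self):
        vals = np.arange(627.0)[None, :]
        binned = tf.bin_to_matrix(self._map(vals))
        assert binned.values.shape == (1, 625)
        np.testing.assert_allclose(binned.values[0, :-1], vals[0, :624])
        assert binned.values[0, -1] == pytest.approx(vals[0, 624:].mean())

    def test_too_short_rejected(self):
        with pytest.raises(sg.ValidationError):
            tf.bin_to_matrix(self._map(np.zeros((1, 100))))
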