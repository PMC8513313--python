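"""Preprocessing contracts: decimation, notch, segmentation, epoching,
artifact rejection, exclusion and outlier rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirpeeg import preprocess as pp
from chirpeeg import synthgen as sg
from chirpeeg import workflows as wf
from conftest import single_channel_recording


def _sine_amplitude(x, f, fs):
    t = np.arange(len(x)) / fs
    X = np.c_[np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)]
    return np.hypot(*np.linalg.lstsq(X, x, rcond=None)[0])


class TestDownsample:
    def test_rate_length_and_events(self):
        scn = sg.SimScenario(n_channels=2, seed=30, n_trials=3)
        rec = sg.simulate_chirp_session(scn)
        out = pp.downsample(rec, 625.0)
        assert out.fs == 625.0
        assert out.n_samples == -(-rec.n_samples // 2)
        np.testing.assert_array_equal(out.events.onsets,
                                      np.round(rec.events.onsets / 2))

    def test_passband_amplitude_preserved(self):
        fs = 1250.0
        t = np.arange(int(20 * fs)) / fs
        rec = single_channel_recording(np.sin(2 * np.pi * 40 * t), fs)
        out = pp.downsample(rec, 625.0)
        assert _sine_amplitude(out.samples[0], 40.0, 625.0) == pytest.approx(1.0, rel=0.01)

    def test_non_integer_factor_rejected(self):
        rec = single_channel_recording(np.zeros(1000), fs=1000.0)
        with pytest.raises(sg.ValidationError, match="resample"):
            pp.downsample(rec, 625.0)


class TestNotch:
    def test_line_attenuation_and_passband(self):
        fs = 625.0
        t = np.arange(int(20 * fs)) / fs
        rec60 = single_channel_recording(np.sin(2 * np.pi * 60 * t), fs)
        resid = _sine_amplitude(pp.notch_filter(rec60).samples[0], 60.0, fs)
        assert resid <= 0.1                     # >= 20 dB at 60 Hz
        rec40 = single_channel_recording(np.sin(2 * np.pi * 40 * t), fs)
        amp = _sine_amplitude(pp.notch_filter(rec40).samples[0], 40.0, fs)
        assert abs(amp - 1.0) <= 0.03
        # +/- 5 Hz attenuation stays under 3 dB
        for f in (55.0, 65.0):
            recf = single_channel_recording(np.sin(2 * np.pi * f * t), fs)
            a = _sine_amplitude(pp.notch_filter(recf).samples[0], f, fs)
            assert a >= 10 ** (-3 / 20)

    def test_zero_input(self):
        rec = single_channel_recording(np.zeros(5000))
        np.testing.assert_allclose(pp.notch_filter(rec).samples, 0.0)

    def test_above_nyquist_rejected(self):
        rec = single_channel_recording(np.zeros(5000), fs=100.0)
        with pytest.raises(sg.ValidationError):
            pp.notch_filter(rec, freq=60.0)


class TestSegmentation:
    def test_counts_and_remainder(self):
        rec = single_channel_recording(np.random.default_rng(0).standard_normal(
            int(300.7 * 625)))
        segs = pp.segment_resting(rec)
        assert segs.segments.shape == (300, 1, 625)
        np.testing.assert_array_equal(segs.segment_onsets[:3], [0, 625, 1250])
        assert not segs.rejected.any()

    def test_degenerate_input_warns(self, caplog):
        rec = single_channel_recording(np.zeros(312))
        with caplog.at_level("WARNING"):
            segs = pp.segment_resting(rec)
        assert segs.segments.shape[0] == 0


class TestEpoching:
    def test_epoch_geometry(self):
        scn = sg.SimScenario(n_channels=2, seed=31, n_trials=10)
        rec = wf.preprocess_recording(sg.simulate_chirp_session(scn))
        ep = pp.epoch_chirp(rec)
        assert ep.epochs.shape == (10, 2, 1875)   # 3 s at 625 Hz
        assert ep.t0_offset == 0.5

    def test_truncated_trial_dropped(self, caplog):
        scn = sg.SimScenario(n_channels=1, seed=32, n_trials=5)
        rec = sg.simulate_chirp_session(scn)
        cut = sg.Recording(
            fs=rec.fs,
            samples=rec.samples[:, :rec.events.onsets[-1] + round(1.2 * rec.fs)],
            channel_labels=rec.channel_labels,
            region_assignment=rec.region_assignment,
            events=rec.events,
        )
        with caplog.at_level("WARNING"):
            ep = pp.epoch_chirp(cut)
        assert ep.epochs.shape[0] == 4

    def test_no_events_rejected(self):
        rec = single_channel_recording(np.zeros(5000))
        with pytest.raises(sg.ValidationError):
            pp.epoch_chirp(rec)

    def test_delta_alignment_through_pipeline(self):
        """A delta at the modulation onset lands at sample round(pre*fs)
        after decimation, notch and epoching (zero-phase contract)."""
        fs = 1250.0
        n = int(30 * fs)
        onset = 10000                       # ramp start, even for exact /2
        stim = sg.ChirpStimulus()
        x = np.zeros(n)
        x[onset + round(stim.ramp_duration * fs)] = 100.0
        rec = sg.Recording(
            fs=fs, samples=x[None, :], channel_labels=["ch00"],
            region_assignment={"ch00": "LF"},
            events=sg.EventTable(onsets=np.array([onset]), kinds=["chirp_up"],
                                 stimuli=[stim]),
        )
        ep = pp.epoch_chirp(wf.preprocess_recording(rec))
        peak = int(np.argmax(np.abs(ep.epochs[0, 0])))
        assert peak == round(0.5 * 625)

    def test_linearity_of_filter_chain(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(10 * 1250))
        rec = single_channel_recording(x, fs=1250.0)
        rec5 = single_channel_recording(5.0 * x, fs=1250.0)
        a = wf.preprocess_recording(rec).samples
        b = wf.preprocess_recording(rec5).samples
        np.testing.assert_allclose(b, 5.0 * a, rtol=1e-9, atol=1e-9)


class TestArtifactRejection:
    def test_infinite_limits_reject_nothing(self, background_recording):
        segs = pp.segment_resting(wf.preprocess_recording(background_recording))
        big = pp.ArtifactCriteria(amplitude_limit=1e12, gradient_limit=1e12,
                                  maxmin_limit=1e12)
        assert not pp.detect_artifacts(segs, big).rejected.any()

    def test_clean_background_rejection_low(self, background_recording):
        segs = pp.segment_resting(wf.preprocess_recording(background_recording))
        out = pp.detect_artifacts(segs)
        assert out.rejected.mean() < 0.05

    def test_injected_artifacts_are_rejected(self, background_recording,
                                             small_scenario):
        from dataclasses import replace

        scn = replace(small_scenario, artifact_rate=6.0, artifact_amp=900.0)
        dirty, truth = sg.inject_artifacts(background_recording, scn)
        assert truth
        segs = pp.detect_artifacts(
            pp.segment_resting(wf.preprocess_recording(dirty)))
        L = 625
        for art in truth:
            # the segment holding the bump peak must always trip max-min
            peak = ((art.start + art.stop) // 2) // 2 // L
            if peak < len(segs.rejected):
                assert segs.rejected[peak]

    @given(st.floats(1.0, 3.0), st.floats(1.0, 3.0), st.floats(1.0, 3.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_rejection_monotone_in_limits(self, fa, fg, fm):
        """Loosening every limit never rejects more segments."""
        rng = np.random.default_rng(40)
        data = 80.0 * rng.standard_normal((2, 30 * 625))
        rec = sg.Recording(fs=625.0, samples=data,
                           channel_labels=["ch00", "ch01"],
                           region_assignment={"ch00": "LF", "ch01": "RF"})
        segs = pp.segment_resting(rec)
        tight = pp.ArtifactCriteria(150.0, 60.0, 200.0)
        loose = pp.ArtifactCriteria(150.0 * fa, 60.0 * fg, 200.0 * fm)
        r_tight = pp.detect_artifacts(segs, tight).rejected
        r_loose = pp.detect_artifacts(segs, loose).rejected
        assert not np.any(r_loose & ~r_tight)


class TestExclusionAndOutliers:
    @pytest.mark.parametrize("n_bad,expected", [
        (89, "keep"),      # 29.7%
        (90, "keep"),      # exactly 30.0% -> "more than 30%" not met
        (91, "exclude"),   # 30.3%
    ])
    def test_exclusion_rule_strictly_above_30pct(self, n_bad, expected):
        mask = np.zeros(300, dtype=bool)
        mask[:n_bad] = True
        decision, frac = pp.exclusion_decision(mask)
        assert decision == expected
        assert frac == pytest.approx(n_bad / 300)

    def test_grubbs_worked_example(self):
        """G = (8.0 - mean)/sd = 1.788 exceeds the n=5 critical 1.715."""
        assert pp.grubbs_outlier([1.0, 1.1, 0.9, 1.05, 8.0]) == [4]

    def test_grubbs_identical_values(self):
        assert pp.grubbs_outlier([2.0] * 6) == []

    def test_grubbs_small_sample_rejected(self):
        with pytest.raises(sg.ValidationError):
            pp.grubbs_outlier([1.0, 2.0])

    def test_grubbs_null_flag_rate(self):
        """On standard normal samples (n=20) the flag rate tracks alpha."""
        rng = np.random.default_rng(50)
        flags = sum(
            bool(pp.grubbs_outlier(rng.standard_normal(20), alpha=0.05))
            for _ in range(400)
        )
        rate = flags / 400
        assert 0.01 < rate < 0.12
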