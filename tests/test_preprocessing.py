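import numpy as np
import pytest
from scipy import signal as sps

from eeghotspot import (
    EEGRecording,
    bandpass,
    build_input,
    common_average_reference,
    compute_psd,
    downsample,
    epoch,
    remove_artifact_components,
    select_channel_set,
)
from eeghotspot.preprocessing import EpochArray


def _tone(freq, fs, seconds, n_ch=2):
    t = np.arange(int(seconds * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return EEGRecording(np.tile(x, (n_ch, 1)), fs, tuple(f"ch{i}" for i in range(n_ch)))


class TestDownsample:
    def test_length_and_event_rescale(self):
        rec = EEGRecording(np.zeros((2, 10_000)), 1000.0, ("a", "b"),
                           events=[(1000, "keypress")])
        out = downsample(rec, 200.0)
        assert out.n_samples == 2000
        assert out.fs == 200.0
        assert out.events[0][0] == 200

    def test_noninteger_ratio_500_to_200(self):
        rec = EEGRecording(np.zeros((1, 5000)), 500.0, ("a",))
        out = downsample(rec, 200.0)
        assert out.n_samples == 2000

    def test_sinusoid_amplitude_preserved(self):
        """FFT oracle: a 10 Hz tone survives resampling within 1 %."""
        rec = _tone(10.0, 1000.0, 4.0)
        out = downsample(rec, 200.0)
        spec = np.abs(np.fft.rfft(out.signal[0])) / out.n_samples * 2
        freqs = np.fft.rfftfreq(out.n_samples, 1 / out.fs)
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(10.0, abs=freqs[1])
        assert spec.max() == pytest.approx(1.0, rel=0.01)

    def test_upsampling_rejected(self):
        rec = EEGRecording(np.zeros((1, 100)), 100.0, ("a",))
        with pytest.raises(ValueError):
            downsample(rec, 200.0)


class TestCommonAverageReference:
    def test_closed_form_two_channels(self):
        rec = EEGRecording(np.array([[1.0, 1.0], [3.0, 3.0]]), 10.0, ("a", "b"))
        out = common_average_reference(rec)
        assert np.allclose(out.signal, [[-1.0, -1.0], [1.0, 1.0]])

    def test_column_sums_zero(self):
        rng = np.random.default_rng(0)
        rec = EEGRecording(rng.standard_normal((8, 500)) * 50, 100.0,
                           tuple(f"c{i}" for i in range(8)))
        out = common_average_reference(rec)
        assert np.allclose(out.signal.sum(axis=0), 0.0, atol=1e-9 * 50)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        rec = EEGRecording(rng.standard_normal((5, 100)), 100.0,
                           tuple(f"c{i}" for i in range(5)))
        once = common_average_reference(rec)
        twice = common_average_reference(once)
        assert np.allclose(once.signal, twice.signal)

    def test_single_channel_rejected(self):
        rec = EEGRecording(np.zeros((1, 100)), 100.0, ("a",))
        with pytest.raises(ValueError):
            common_average_reference(rec)


class TestBandpass:
    def test_dc_removed(self):
        rec = EEGRecording(np.full((2, 2000), 7.0), 200.0, ("a", "b"))
        out = bandpass(rec)
        assert abs(out.signal[0, 500:1500].mean()) < 0.05

    def test_squared_butterworth_response_at_28hz(self):
        """Forward-backward filtering realizes the squared magnitude response;
        oracle: the analog 3rd-order Butterworth band-pass prototype."""
        rec = _tone(28.0, 200.0, 10.0)
        out = bandpass(rec)
        mid = out.signal[0, 400:-400]  # avoid edge transients
        measured = np.sqrt(2) * mid.std()
        b, a = sps.butter(3, [2 * np.pi * 1, 2 * np.pi * 55], btype="bandpass",
                          analog=True)
        _, h = sps.freqs(b, a, worN=[2 * np.pi * 28.0])
        expected = np.abs(h[0]) ** 2
        assert measured == pytest.approx(expected, rel=0.02)

    def test_zero_phase_no_lag(self):
        rng = np.random.default_rng(2)
        carrier = np.sin(2 * np.pi * 40 * np.arange(4000) / 200.0)
        rec = EEGRecording(carrier[None, :], 200.0, ("a",))
        out = bandpass(rec)
        xc = np.correlate(out.signal[0, 200:-200], carrier[200:-200], "full")
        lag = np.argmax(xc) - (len(carrier) - 401)
        assert lag == 0

    def test_time_reversal_commutes(self):
        rng = np.random.default_rng(3)
        rec = EEGRecording(rng.standard_normal((3, 3000)), 200.0, ("a", "b", "c"))
        fwd = bandpass(rec).signal[:, ::-1]
        rev = bandpass(rec.copy_with(signal=rec.signal[:, ::-1])).signal
        assert np.allclose(fwd, rev, atol=1e-6)

    def test_cutoff_above_nyquist_rejected(self):
        rec = EEGRecording(np.zeros((1, 100)), 100.0, ("a",))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, high=55.0)


@pytest.fixture(scope="module")
def cleaned(stroke_subject):
    rec = stroke_subject.recording("left")
    r = bandpass(common_average_reference(downsample(rec)))
    out, report = remove_artifact_components(r, seed=0)
    return r, out, report


class TestICA:
    def test_blink_variance_drops(self, cleaned):
        before, after, report = cleaned
        i = before.labels.index("Fp1")
        assert report.flagged, "expected at least one flagged component"
        assert after.signal[i].var() < 0.2 * before.signal[i].var()

    def test_output_shape_unchanged(self, cleaned):
        before, after, _ = cleaned
        assert after.signal.shape == before.signal.shape

    def test_artifact_free_recording_nearly_untouched(self, stroke_montage):
        from eeghotspot import SyntheticConfig, generate_subject

        cfg = SyntheticConfig(cohort="stroke", n_trials=5, snr=0.5,
                              artifact_rate=0.0, seed=13)
        subj = generate_subject(stroke_montage, cfg, np.random.default_rng(13),
                                hands=("right",))
        r = bandpass(common_average_reference(downsample(subj.recording("right"))))
        out, report = remove_artifact_components(r, seed=0)
        assert len(report.flagged) <= 1
        rms_in = np.sqrt(np.mean(r.signal**2))
        err = np.sqrt(np.mean((out.signal - r.signal) ** 2))
        assert err < 0.05 * rms_in

    def test_too_few_samples_rejected(self):
        rec = EEGRecording(np.random.default_rng(0).standard_normal((10, 9)),
                           100.0, tuple(f"c{i}" for i in range(10)))
        with pytest.raises(ValueError, match="more samples"):
            remove_artifact_components(rec)


class TestEpoching:
    def test_healthy_window(self, healthy_subject):
        ds = downsample(healthy_subject.recording("right"))
        ep = epoch(ds, "healthy")
        assert ep.data.shape == (12, 63, 200)
        assert ep.window == (-0.5, 0.5)

    def test_stroke_window(self, stroke_subject):
        ds = downsample(stroke_subject.recording("left"))
        ep = epoch(ds, "stroke")
        assert ep.data.shape[2] == 300
        assert ep.window == (-0.5, 1.0)

    def test_out_of_bounds_trial_dropped(self):
        rec = EEGRecording(
            np.zeros((2, 1000)), 200.0, ("a", "b"),
            events=[(50, "keypress"), (500, "keypress")], cohort="healthy",
        )
        ep = epoch(rec, "healthy")
        assert ep.data.shape[0] == 1

    def test_no_usable_trials_raises(self):
        rec = EEGRecording(np.zeros((1, 300)), 200.0, ("a",),
                           events=[(10, "keypress")])
        with pytest.raises(ValueError, match="no usable trials"):
            epoch(rec, "healthy")


class TestPSD:
    def _epochs(self, freq, fs=200.0, n=3, seconds=1.0, amp=1.0):
        t = np.arange(int(seconds * fs)) / fs
        x = amp * np.sin(2 * np.pi * freq * t)
        data = np.tile(x, (n, 2, 1))
        return EpochArray(data, fs, (-0.5, seconds - 0.5), ("a", "b"))

    def test_pure_tone_argmax(self):
        mi = compute_psd(self._epochs(40.0))
        assert mi.freq_bins[np.argmax(mi.tensor[0, 0])] == 40.0

    def test_bin_count_21(self):
        mi = compute_psd(self._epochs(35.0))
        assert mi.tensor.shape[2] == 21
        assert mi.freq_bins == tuple(float(f) for f in range(30, 51))

    def test_quadratic_amplitude_scaling(self):
        a = compute_psd(self._epochs(40.0, amp=1.0)).tensor
        b = compute_psd(self._epochs(40.0, amp=2.0)).tensor
        assert np.allclose(b, 4.0 * a, rtol=1e-10, atol=1e-12)

    def test_parseval_full_band(self):
        """Total magnitude-squared spectrum equals epoch energy (rect window,
        zero-padding); full-spectrum oracle via numpy fft."""
        rng = np.random.default_rng(4)
        data = rng.standard_normal((2, 3, 300))
        ep = EpochArray(data, 200.0, (-0.5, 1.0), ("a", "b", "c"))
        n_fft = 400  # next multiple of fs/resolution
        spec = np.fft.fft(ep.data, n=n_fft, axis=2)
        total = (np.abs(spec) ** 2).sum(axis=2) / n_fft
        energy = (ep.data**2).sum(axis=2)
        assert np.allclose(total, energy, rtol=1e-6)

    def test_stroke_epoch_padding_hits_integer_bins(self):
        # 1.5 s at 200 Hz -> padded to 400 samples, 0.5 Hz grid
        mi = compute_psd(self._epochs(40.0, seconds=1.5))
        assert mi.tensor.shape[2] == 21
        assert mi.freq_bins[np.argmax(mi.tensor[0, 0])] == 40.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            compute_psd(self._epochs(10.0, fs=80.0), band=(30, 50))


class TestLadder:
    def test_level1_shape(self, healthy_subject):
        mi = build_input(healthy_subject.recording("right"), 1)
        assert mi.shape == (12, 63, 200)
        assert mi.width_kind == "time"

    def test_level5_shape(self, healthy_subject):
        mi = build_input(healthy_subject.recording("right"), 5)
        assert mi.shape == (12, 63, 21)
        assert mi.width_kind == "psd"

    def test_level2_is_level1_minus_channel_mean(self, healthy_subject):
        t1 = build_input(healthy_subject.recording("right"), 1).tensor
        t2 = build_input(healthy_subject.recording("right"), 2).tensor
        assert np.allclose(t2, t1 - t1.mean(axis=1, keepdims=True), atol=1e-9)

    def test_level3_equals_bandpass_of_level2_intermediate(self, healthy_subject):
        """Ladder consistency: stage composition equals the cumulative build."""
        rec = healthy_subject.recording("right")
        manual = epoch(bandpass(common_average_reference(downsample(rec))),
                       "healthy").data
        t3 = build_input(rec, 3).tensor
        assert np.allclose(t3, manual, atol=1e-9)

    def test_channel_set_restriction(self, healthy_subject, healthy_montage):
        cs = select_channel_set(healthy_montage, "Set5", "right")
        mi = build_input(healthy_subject.recording("right"), 1, channel_set=cs)
        assert mi.shape[1] == 9
        assert mi.labels == cs.labels

    def test_provenance_stages(self, healthy_subject):
        mi = build_input(healthy_subject.recording("right"), 3)
        assert mi.stages[0].startswith("downsample")
        assert "CAR" in mi.stages[1]
        assert any(s.startswith("bandpass") for s in mi.stages)

    def test_invalid_level(self, healthy_subject):
        with pytest.raises(ValueError):
            build_input(healthy_subject.recording("right"), 6)
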