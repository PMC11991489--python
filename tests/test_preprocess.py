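"""Filtering, resampling, re-referencing, epoching, and epoch rejection."""

import numpy as np
import pytest

from myocortex import Recording, bandpass, epoch, notch, preprocess_eeg, reject_epochs, rereference, resample
from myocortex import mpf, welch_psd
from myocortex.preprocess import ParameterError, PipelineError


def sine_rec(freq, rate=1000.0, duration=10.0, amp=10.0, label="C3"):
    t = np.arange(int(rate * duration)) / rate
    return Recording(amp * np.sin(2 * np.pi * freq * t)[None, :], rate, [label], ["EEG"])


def rms_of(rec):
    return float(np.sqrt(np.mean(rec.data**2)))


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = sine_rec(10.0)
        out = bandpass(rec, 1.0, 100.0)
        assert rms_of(out) / rms_of(rec) >= 0.95

    def test_drift_removed(self):
        rec = sine_rec(0.1, duration=30.0)
        out = bandpass(rec, 1.0, 100.0)
        assert rms_of(out) / rms_of(rec) <= 0.1

    def test_zero_in_zero_out(self):
        rec = Recording(np.zeros((2, 1000)), 500.0, ["C3", "C4"], ["EEG", "EEG"])
        assert np.allclose(bandpass(rec, 1.0, 100.0).data, 0.0)

    def test_edge_above_nyquist_refused(self):
        with pytest.raises(ParameterError):
            bandpass(sine_rec(10.0, rate=400.0), 1.0, 250.0)

    def test_zero_phase_preserves_pulse_peak(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        rec = Recording(x[None, :], 500.0, ["C3"], ["EEG"])
        out = bandpass(rec, 1.0, 100.0)
        assert int(np.argmax(np.abs(out.data[0]))) == 1000


class TestNotch:
    def test_in_notch_attenuation_at_least_20db(self):
        rec = sine_rec(50.0)
        out = notch(rec, 48.0, 52.0)
        atten_db = 20 * np.log10(rms_of(rec) / rms_of(out))
        assert atten_db >= 20.0

    def test_out_of_notch_tone_untouched(self):
        rec = sine_rec(30.0)
        out = notch(rec, 48.0, 52.0)
        atten_db = 20 * np.log10(rms_of(rec) / rms_of(out))
        assert atten_db <= 1.0

    def test_zero_in_zero_out(self):
        rec = Recording(np.zeros((1, 2000)), 500.0, ["C3"], ["EEG"])
        assert np.allclose(notch(rec, 48.0, 52.0).data, 0.0)


class TestResample:
    def test_sample_count_halved(self):
        rec = sine_rec(40.0, rate=1000.0, duration=1.0)
        out = resample(rec, 500.0)
        assert out.n_samples == 500 and out.rate == 500.0

    def test_spectrum_preserved_below_new_nyquist(self):
        rec = sine_rec(40.0, rate=1000.0, duration=10.0)
        out = resample(rec, 500.0)
        spec = welch_psd(out.data[0], out.rate)
        assert mpf(spec, (20.0, 100.0)) == pytest.approx(40.0, abs=1.0)

    def test_identity_when_rate_unchanged(self):
        rec = sine_rec(40.0, rate=500.0)
        out = resample(rec, 500.0)
        assert np.array_equal(out.data, rec.data)

    def test_upsampling_refused(self):
        with pytest.raises(ParameterError, match="upsampling"):
            resample(sine_rec(10.0, rate=500.0), 1000.0)


class TestRereference:
    def make(self, rng):
        data = np.vstack([
            rng.standard_normal(1000),        # C3 (EEG)
            np.full(1000, 3.0),               # M1 (REF)
            np.full(1000, 3.0),               # M2 (REF)
            rng.standard_normal(1000),        # EMG
        ])
        return Recording(data, 500.0, ["C3", "M1", "M2", "EMG_L"],
                         ["EEG", "REF", "REF", "EMG"])

    def test_constant_reference_subtracted(self, rng):
        rec = self.make(rng)
        out = rereference(rec)
        assert np.allclose(out.get("C3"), rec.get("C3") - 3.0)

    def test_channel_equal_to_reference_becomes_zero(self, rng):
        rec = self.make(rng)
        rec.data[0] = 3.0
        assert np.allclose(rereference(rec).get("C3"), 0.0)

    def test_emg_untouched(self, rng):
        rec = self.make(rng)
        assert np.array_equal(rereference(rec).get("EMG_L"), rec.get("EMG_L"))

    def test_missing_reference_errors(self, rng):
        rec = self.make(rng).pick(["C3", "M1", "EMG_L"])
        with pytest.raises(KeyError, match="M2"):
            rereference(rec)


class TestEpoch:
    @pytest.mark.parametrize("duration, expected", [(10.0, 5), (11.0, 5)])
    def test_epoch_counts(self, duration, expected):
        rec = sine_rec(10.0, rate=500.0, duration=duration)
        ep = epoch(rec, 2.0)
        assert ep.n_epochs == expected
        assert ep.data.shape[2] == 1000

    def test_too_short_errors(self):
        with pytest.raises(PipelineError):
            epoch(sine_rec(10.0, rate=500.0, duration=1.5), 2.0)

    def test_samples_preserved(self):
        rec = sine_rec(10.0, rate=500.0, duration=4.0)
        ep = epoch(rec, 2.0)
        assert np.array_equal(ep.data[1, 0], rec.data[0, 1000:2000])


class TestRejectEpochs:
    def test_clean_epochs_all_kept(self, rng):
        rec = Recording(rng.standard_normal((2, 5000)) * 20, 500.0,
                        ["C3", "C4"], ["EEG", "EEG"])
        ep = reject_epochs(epoch(rec, 2.0))
        assert ep.n_epochs == 5
        assert list(ep.kept_indices) == [0, 1, 2, 3, 4]

    def test_spike_epoch_dropped(self, rng):
        data = rng.standard_normal((2, 5000)) * 20
        data[0, 1500] = 500.0  # spike inside epoch 1
        ep = reject_epochs(epoch(Recording(data, 500.0, ["C3", "C4"], ["EEG", "EEG"]), 2.0))
        assert 1 not in ep.kept_indices
        assert ep.n_epochs == 4

    def test_infinite_thresholds_identity(self, rng):
        data = rng.standard_normal((1, 5000)) * 20
        data[0, 100] = 400.0
        ep = epoch(Recording(data, 500.0, ["C3"], ["EEG"]), 2.0)
        kept = reject_epochs(ep, abs_uv=np.inf, z_max=np.inf)
        assert kept.n_epochs == ep.n_epochs

    def test_all_rejected_is_pipeline_error(self, rng):
        data = rng.standard_normal((1, 5000)) * 500
        ep = epoch(Recording(data, 500.0, ["C3"], ["EEG"]), 2.0)
        with pytest.raises(PipelineError, match="rejected"):
            reject_epochs(ep, abs_uv=1.0)

    def test_kept_plus_rejected_conserved(self, rng):
        data = rng.standard_normal((1, 10000)) * 20
        data[0, 200] = 300.0
        data[0, 7000] = 300.0
        ep = epoch(Recording(data, 500.0, ["C3"], ["EEG"]), 2.0)
        kept = reject_epochs(ep)
        assert kept.n_epochs + kept.meta["n_rejected"] == ep.n_epochs


def test_eeg_chain_records_provenance(rng):
    data = rng.standard_normal((3, 8000)) * 20
    rec = Recording(data, 1000.0, ["C3", "M1", "M2"], ["EEG", "REF", "REF"])
    ep = preprocess_eeg(rec, epoch_length=2.0)
    ops = [step["op"] for step in ep.meta["chain"]]
    assert ops == ["bandpass", "notch", "notch", "resample", "rereference", "epoch"]
    assert ep.rate == 500.0
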