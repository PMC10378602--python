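"""Filtering, phase extraction, synthetic LFP generation and I/O."""

import numpy as np
import pytest
from scipy import signal as sps

from phasete import (
    SyntheticLFPConfig,
    TrialEnsemble,
    bandpass_filter,
    extract_phase,
    generate_synthetic_lfp,
    read_ensemble,
    write_ensemble,
)
from phasete.exceptions import (
    InsufficientSamplesError,
    InvalidBandError,
    MetadataError,
    ShapeError,
)
from phasete.signal_core import design_fir, fir_order_for_band


def _sinusoid(freq, fs=100.0, duration=4.0, n_trials=2):
    t = np.arange(int(duration * fs)) / fs
    return TrialEnsemble(np.tile(np.cos(2 * np.pi * freq * t), (n_trials, 1)), fs)


class TestBandpassFilter:
    def test_passband_sinusoid_preserved(self):
        ens = _sinusoid(25.0)
        out = bandpass_filter(ens, (15, 35), order=30)
        mid = slice(100, 300)
        ratio = out.data[0, mid].std() / ens.data[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_attenuation_matches_designed_response(self):
        # oracle: evaluate the designed transfer function at 5 Hz directly
        ens = _sinusoid(5.0, duration=8.0)
        order = 40
        out = bandpass_filter(ens, (15, 35), order=order, zero_phase=True)
        taps = design_fir((15, 35), 100.0, order)
        _, h = sps.freqz(taps, worN=[5.0], fs=100.0)
        expected = np.abs(h[0]) ** 2  # forward-backward squares the response
        mid = slice(150, 650)
        ratio = out.data[0, mid].std() / ens.data[0, mid].std()
        assert ratio == pytest.approx(expected, rel=0.15, abs=1e-4)

    def test_linearity(self, rng):
        x = TrialEnsemble(rng.standard_normal((3, 300)), 100.0)
        y = TrialEnsemble(rng.standard_normal((3, 300)), 100.0)
        combo = TrialEnsemble(2.0 * x.data - 3.0 * y.data, 100.0)
        f = lambda e: bandpass_filter(e, (15, 35), 20).data
        assert np.allclose(f(combo), 2.0 * f(x) - 3.0 * f(y), atol=1e-10)

    def test_zero_phase_has_no_group_delay(self):
        ens = _sinusoid(25.0, duration=6.0, n_trials=1)
        out = bandpass_filter(ens, (15, 35), order=30)
        a = ens.data[0, 100:-100]
        b = out.data[0, 100:-100]
        lags = np.arange(-2, 3)  # within one oscillation period (4 samples)
        cc = [np.corrcoef(a, np.roll(b, l))[0, 1] for l in lags]
        assert lags[int(np.argmax(cc))] == 0

    def test_band_outside_nyquist_rejected(self):
        ens = _sinusoid(10.0)
        with pytest.raises(InvalidBandError):
            bandpass_filter(ens, (15, 60), 20)
        with pytest.raises(InvalidBandError):
            bandpass_filter(ens, (35, 15), 20)

    def test_order_exceeding_length_rejected(self):
        ens = TrialEnsemble(np.random.default_rng(0).standard_normal((1, 50)), 100.0)
        with pytest.raises(InsufficientSamplesError):
            bandpass_filter(ens, (15, 35), order=60)

    def test_lfp_order_rule(self):
        assert fir_order_for_band(2000.0, 4.0) == 3 * 500
        assert fir_order_for_band(100.0, 15.0) == 3 * 6


class TestExtractPhase:
    def test_cosine_phase_slope(self):
        ens = _sinusoid(10.0, duration=6.0)
        ph = extract_phase(ens, (4, 12), order=40)
        mid = slice(100, 500)
        slope = np.diff(np.unwrap(ph.phase[0]))[mid].mean() * ens.fs
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=0.01)

    def test_identical_trials_identical_phase(self):
        ens = _sinusoid(25.0, n_trials=3)
        ph = extract_phase(ens, (15, 35), order=20)
        assert np.array_equal(ph.phase[0], ph.phase[1])
        assert np.all(ph.phase >= -np.pi) and np.all(ph.phase < np.pi)

    def test_against_spectral_hilbert_oracle(self, rng):
        # oracle: FFT-based analytic signal of the identically filtered trial
        data = rng.standard_normal((2, 400))
        ens = TrialEnsemble(data, 100.0)
        ph = extract_phase(ens, (15, 35), order=30)
        filt = bandpass_filter(ens, (15, 35), 30).data[0]
        n = filt.size
        spec = np.fft.fft(filt)
        h = np.zeros(n)
        h[0] = 1
        h[1:n // 2] = 2
        h[n // 2] = 1
        analytic = np.fft.ifft(spec * h)
        expected = np.angle(analytic)
        d = np.angle(np.exp(1j * (ph.phase[0, 50:-50] - expected[50:-50])))
        assert np.max(np.abs(d)) < 1e-8

    def test_dc_offset_leaves_phase_unchanged(self, rng):
        data = rng.standard_normal((1, 300))
        p1 = extract_phase(TrialEnsemble(data, 100.0), (15, 35), order=30)
        p2 = extract_phase(TrialEnsemble(data + 5.0, 100.0), (15, 35), order=30)
        assert np.allclose(p1.phase, p2.phase, atol=1e-9)


class TestSyntheticLFP:
    def test_seeded_runs_identical(self):
        cfg = SyntheticLFPConfig(fs=500.0, n_trials=6, epoch_length=2.0, seed=3)
        x1, y1, t1 = generate_synthetic_lfp(cfg)
        x2, y2, t2 = generate_synthetic_lfp(cfg)
        assert np.array_equal(x1.data, x2.data)
        assert np.array_equal(y1.data, y2.data)
        assert t1 == t2

    def test_uncoupled_band_components_uncorrelated(self):
        # narrowband processes of finite length carry sizable per-trial
        # spurious correlation; only the across-trial mean must vanish
        cfg = SyntheticLFPConfig(fs=500.0, n_trials=20, epoch_length=4.0,
                                 coupling_strength=0.0, seed=4)
        x, y, _ = generate_synthetic_lfp(cfg)
        xb = bandpass_filter(x, cfg.coupled_band, 150).data
        yb = bandpass_filter(y, cfg.coupled_band, 150).data
        cc = [np.corrcoef(xb[i], yb[i])[0, 1] for i in range(cfg.n_trials)]
        assert np.abs(np.mean(cc)) < 0.15

    def test_coupled_band_crosscorrelation_peaks_at_lag(self):
        # oracle: cross-correlogram of the band-passed channels
        cfg = SyntheticLFPConfig(fs=500.0, n_trials=10, epoch_length=3.0,
                                 coupling_direction="xy", coupling_lag_ms=20.0,
                                 coupling_strength=0.9, pink_noise_level=0.3,
                                 seed=5)
        x, y, _ = generate_synthetic_lfp(cfg)
        xb = bandpass_filter(x, cfg.coupled_band, 150).data
        yb = bandpass_filter(y, cfg.coupled_band, 150).data
        lag_samp = int(cfg.coupling_lag_ms / 1000 * cfg.fs)
        lags = np.arange(-30, 31)
        cc = np.array([
            np.mean([np.corrcoef(xb[i, 50:-50],
                                 np.roll(yb[i], -l)[50:-50])[0, 1]
                     for i in range(cfg.n_trials)])
            for l in lags])
        # roll(y, -l)[t] = y[t+l]: the peak sits at +lag (Y lags X)
        assert abs(lags[int(np.argmax(cc))] - lag_samp) <= 2

    def test_flagged_trial_counts(self):
        cfg = SyntheticLFPConfig(fs=500.0, n_trials=30, epoch_length=2.0,
                                 delta_dominant_fraction=0.2,
                                 artifact_trial_fraction=0.1, seed=6)
        _, _, truth = generate_synthetic_lfp(cfg)
        assert len(truth["delta_dominant_trials"]) == 6
        assert len(truth["artifact_trials"]) == 3


class TestEnsembleIO:
    def test_csv_round_trip(self, tmp_path, rng):
        ens = TrialEnsemble(rng.standard_normal((3, 100)), 250.0, "hp01")
        path = tmp_path / "ens.csv"
        write_ensemble(ens, path, format="csv")
        back = read_ensemble(path, format="csv")
        assert np.allclose(back.data, ens.data)
        assert back.fs == ens.fs and back.channel_id == "hp01"

    def test_hdf5_round_trip(self, tmp_path, rng):
        ens = TrialEnsemble(rng.standard_normal((4, 64)), 1000.0, "ncl07")
        path = tmp_path / "ens.h5"
        write_ensemble(ens, path, format="hdf5")
        back = read_ensemble(path, format="hdf5")
        assert np.array_equal(back.data, ens.data)
        assert back.fs == 1000.0

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("1.0,2.0,3.0\n4.0,5.0\n")
        with pytest.raises(ShapeError):
            read_ensemble(path, format="csv", fs=100.0)

    def test_missing_fs_rejected(self, tmp_path):
        path = tmp_path / "nofs.csv"
        path.write_text("1.0,2.0,3.0\n4.0,5.0,6.0\n")
        with pytest.raises(MetadataError):
            read_ensemble(path, format="csv")

    def test_hdf5_missing_fs_attribute_rejected(self, tmp_path):
        import h5py

        path = tmp_path / "nofs.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=np.zeros((2, 10)))
        with pytest.raises(MetadataError):
            read_ensemble(path, format="hdf5")

    def test_nonfinite_data_rejected(self):
        with pytest.raises(ShapeError):
            TrialEnsemble(np.array([[1.0, np.nan]]), 100.0)
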