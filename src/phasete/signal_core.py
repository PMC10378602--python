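"""Trial-ensemble containers, band-pass filtering, Hilbert phase extraction and I/O.

The unit of data exchange throughout the package is the :class:`TrialEnsemble`:
a real matrix of ``n_trials x n_samples`` holding independent repetitions of the
same experimental condition, recorded at a common sampling rate.  Directed
coupling is always estimated on the instantaneous phase of one frequency band
(:class:`PhaseEnsemble`), obtained by zero-phase FIR band-pass filtering
followed by the Hilbert transform.

The module also contains a synthetic local-field-potential generator that
emulates trial-based two-region recordings (theta/beta/gamma content, pink
background noise, movement artifacts, delta-dominated epochs) with a known,
imposed directed phase coupling.  It provides ground truth for pipeline tests
where real recordings are not distributable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .exceptions import (
    InsufficientSamplesError,
    InvalidBandError,
    MetadataError,
    ShapeError,
)

__all__ = [
    "TrialEnsemble",
    "PhaseEnsemble",
    "SyntheticLFPConfig",
    "bandpass_filter",
    "extract_phase",
    "fir_order_for_band",
    "generate_synthetic_lfp",
    "read_ensemble",
    "write_ensemble",
    "wrap_phase",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialEnsemble:
    """Multi-trial single-channel time series.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_samples)``; every trial has the same
        length.  Values are in acquisition units (e.g. mV).
    fs
        Sampling rate in Hz, strictly positive.
    channel_id
        Free-form channel label.
    """

    data: np.ndarray
    fs: float
    channel_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 1:
            data = data[None, :]
        if data.ndim != 2:
            raise ShapeError(f"trial data must be 2-D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ShapeError("trial data contains non-finite values")
        if not (self.fs > 0):
            raise InvalidBandError(f"sampling rate must be > 0, got {self.fs}")
        object.__setattr__(self, "data", data)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def subset(self, trial_idx: Sequence[int]) -> "TrialEnsemble":
        """Return a new ensemble restricted to the given trial indices."""
        return TrialEnsemble(self.data[np.asarray(trial_idx)], self.fs, self.channel_id)


@dataclass(frozen=True)
class PhaseEnsemble:
    """Wrapped instantaneous phase of one frequency band, per trial.

    ``phase`` has the same shape as the source :class:`TrialEnsemble` and every
    value lies in ``[-pi, pi)``.
    """

    phase: np.ndarray
    band: tuple[float, float]
    fs: float

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=float)
        if phase.ndim != 2:
            raise ShapeError(f"phase must be 2-D, got shape {phase.shape}")
        object.__setattr__(self, "phase", phase)

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phase.shape[1]

    def subset(self, trial_idx: Sequence[int]) -> "PhaseEnsemble":
        return PhaseEnsemble(self.phase[np.asarray(trial_idx)], self.band, self.fs)


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to the half-open interval ``[-pi, pi)``."""
    return np.mod(np.asarray(x) + np.pi, 2.0 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# filtering and phase extraction
# ---------------------------------------------------------------------------

def _validate_band(band: tuple[float, float], fs: float) -> tuple[float, float]:
    low, high = float(band[0]), float(band[1])
    if not (0.0 < low < high < fs / 2.0):
        raise InvalidBandError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({fs / 2:g} Hz)"
        )
    return low, high


def fir_order_for_band(fs: float, low: float) -> int:
    """Filter-order rule for LFP bands: ``3 * floor(fs / low)``.

    ``fs / low`` is the number of samples per cycle of the low cut-off; three
    cycles of impulse response give adequate stop-band behaviour for narrow
    physiological bands.
    """
    if low <= 0:
        raise InvalidBandError("low cut-off must be positive")
    return 3 * int(np.floor(fs / low))


def design_fir(band: tuple[float, float], fs: float, order: int) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase band-pass FIR of the given order.

    Returns the ``order + 1`` filter taps.  ``order`` is forced even so the
    linear-phase delay is an integer number of samples.
    """
    low, high = _validate_band(band, fs)
    if order < 2:
        raise InsufficientSamplesError(f"filter order must be >= 2, got {order}")
    numtaps = order + 1
    if numtaps % 2 == 0:  # even-order (odd-tap) type-I FIR for a band-pass
        numtaps += 1
    return sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs, window="hamming")


def bandpass_filter(
    ensemble: TrialEnsemble,
    band: tuple[float, float],
    order: int,
    zero_phase: bool = True,
) -> TrialEnsemble:
    """Band-pass filter every trial with a linear-phase FIR filter.

    With ``zero_phase=True`` the filter is applied forward and backward
    (two-way), which squares the magnitude response and cancels the group
    delay.  Edge transients are handled by even (reflecting) padding of
    ``3 * order`` samples, trimmed after filtering.
    """
    taps = design_fir(band, ensemble.fs, order)
    if order >= ensemble.n_samples:
        raise InsufficientSamplesError(
            f"filter order {order} >= trial length {ensemble.n_samples}"
        )
    if zero_phase:
        padlen = min(3 * order, ensemble.n_samples - 1)
        out = sps.filtfilt(taps, [1.0], ensemble.data, axis=1,
                           padtype="even", padlen=padlen)
    else:
        out = sps.lfilter(taps, [1.0], ensemble.data, axis=1)
    return TrialEnsemble(out, ensemble.fs, ensemble.channel_id)


def extract_phase(
    ensemble: TrialEnsemble,
    band: tuple[float, float],
    order: Optional[int] = None,
) -> PhaseEnsemble:
    """Instantaneous phase of one frequency band.

    The band-passed signal is turned into its analytic signal by the Hilbert
    transform; the returned phase is the analytic-signal angle wrapped to
    ``[-pi, pi)``.  If ``order`` is omitted, the LFP rule
    ``3 * floor(fs / low)`` is used.
    """
    if order is None:
        order = fir_order_for_band(ensemble.fs, band[0])
    filtered = bandpass_filter(ensemble, band, order, zero_phase=True)
    analytic = sps.hilbert(filtered.data, axis=1)
    return PhaseEnsemble(wrap_phase(np.angle(analytic)), tuple(band), ensemble.fs)


# ---------------------------------------------------------------------------
# synthetic LFP generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLFPConfig:
    """Configuration of the synthetic two-region LFP generator.

    Defaults emulate a trial-based avian recording session: 2000 Hz sampling,
    ~30 repeated 7 s epochs, theta/beta/gamma oscillatory content on a pink
    (1/f) background, with a directed phase coupling imposed in one band.
    ``coupling_interval`` optionally confines the coupling to a time window
    within the epoch (seconds from epoch start); ``None`` couples the whole
    epoch.
    """

    fs: float = 2000.0
    n_trials: int = 30
    epoch_length: float = 7.0
    coupled_band: tuple[float, float] = (4.0, 12.0)
    coupling_direction: str = "xy"  # "xy", "yx" or "none"
    coupling_lag_ms: float = 20.0
    coupling_strength: float = 0.8
    pink_noise_level: float = 1.0
    artifact_trial_fraction: float = 0.0
    delta_dominant_fraction: float = 0.0
    coupling_interval: Optional[tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_lag_ms < 0:
            raise ValueError("coupling_lag_ms must be >= 0")
        for name in ("coupling_strength", "artifact_trial_fraction",
                     "delta_dominant_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.coupling_direction not in ("xy", "yx", "none"):
            raise ValueError("coupling_direction must be 'xy', 'yx' or 'none'")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """Approximate 1/f noise by shaping white noise in the frequency domain."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # 1/f above 4 Hz, flat below: keeps the background from dominating the
    # delta band, which is reserved for the designated delta-dominant trials
    scale = 1.0 / np.sqrt(np.maximum(freqs, 4.0))
    scale[0] = 0.0  # no DC
    out = np.fft.irfft(spec * scale[None, :], n=n, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _narrowband(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-variance stochastic narrow-band oscillation (filtered white noise)."""
    order = min(fir_order_for_band(fs, band[0]), shape[1] // 4)
    taps = sps.firwin(order + 1, list(band), pass_zero=False, fs=fs, window="hamming")
    x = sps.filtfilt(taps, [1.0], rng.standard_normal(shape), axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_synthetic_lfp(
    config: SyntheticLFPConfig,
) -> tuple[TrialEnsemble, TrialEnsemble, dict]:
    """Generate a coupled pair of synthetic LFP trial ensembles.

    The receiver's coupled-band component is a lag-shifted, strength-weighted
    copy of the driver's plus independent narrow-band noise; both channels
    additionally carry independent beta and gamma oscillations and pink
    background noise.  Designated trials receive large-amplitude artifact
    transients and/or a dominant 0.5-4 Hz component.

    Returns ``(X, Y, ground_truth)`` where ``ground_truth`` records direction,
    lag, and the artifact / delta-dominant trial masks.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.epoch_length * cfg.fs))
    shape = (cfg.n_trials, n)
    lag = int(round(cfg.coupling_lag_ms / 1000.0 * cfg.fs))

    # driver band component and receiver's independent band component
    drv = _narrowband(rng, shape, cfg.fs, cfg.coupled_band)
    indep = _narrowband(rng, shape, cfg.fs, cfg.coupled_band)
    lagged = np.roll(drv, lag, axis=1)  # receiver sees the driver's past
    s = cfg.coupling_strength
    mix = s * lagged + np.sqrt(max(1.0 - s * s, 0.0)) * indep
    if cfg.coupling_interval is not None:
        t0, t1 = cfg.coupling_interval
        tmask = np.zeros(n)
        tmask[int(t0 * cfg.fs):int(t1 * cfg.fs)] = 1.0
        # smooth 100 ms ramps avoid spectral splatter at the window edges
        ramp = int(0.1 * cfg.fs)
        if ramp > 1:
            tmask = np.convolve(tmask, np.ones(ramp) / ramp, mode="same")
        mix = tmask[None, :] * mix + (1.0 - tmask[None, :]) * indep

    if cfg.coupling_direction == "xy":
        x_band, y_band = drv, mix
    elif cfg.coupling_direction == "yx":
        x_band, y_band = mix, drv
    else:
        x_band, y_band = drv, indep

    def _background() -> np.ndarray:
        bg = cfg.pink_noise_level * _pink_noise(rng, shape, cfg.fs)
        bg += 0.5 * _narrowband(rng, shape, cfg.fs, (12.0, 30.0))
        bg += 0.3 * _narrowband(rng, shape, cfg.fs, (30.0, 45.0))
        bg += 0.2 * _narrowband(rng, shape, cfg.fs, (55.0, 80.0))
        return bg

    x = x_band + _background()
    y = y_band + _background()

    n_art = int(round(cfg.artifact_trial_fraction * cfg.n_trials))
    n_delta = int(round(cfg.delta_dominant_fraction * cfg.n_trials))
    order = rng.permutation(cfg.n_trials)
    art_idx = np.sort(order[:n_art])
    delta_idx = np.sort(order[n_art:n_art + n_delta])

    amp = 10.0 * max(x.std(), y.std())
    for i in art_idx:  # boxcar artifact transient on both channels
        t0 = rng.integers(0, max(n - int(0.2 * cfg.fs), 1))
        w = int(0.2 * cfg.fs)
        x[i, t0:t0 + w] += amp
        y[i, t0:t0 + w] += amp
    if n_delta:
        t = np.arange(n) / cfg.fs
        for i in delta_idx:
            f0 = rng.uniform(0.8, 2.5)
            ph = rng.uniform(0, 2 * np.pi)
            slow = 6.0 * np.sin(2 * np.pi * f0 * t + ph)
            x[i] += slow
            y[i] += slow

    truth = {
        "direction": cfg.coupling_direction,
        "lag_ms": cfg.coupling_lag_ms,
        "coupled_band": tuple(cfg.coupled_band),
        "coupling_interval": cfg.coupling_interval,
        "artifact_trials": art_idx.tolist(),
        "delta_dominant_trials": delta_idx.tolist(),
        "coupled_trials": [i for i in range(cfg.n_trials) if i not in set(art_idx)],
    }
    X = TrialEnsemble(x, cfg.fs, "X")
    Y = TrialEnsemble(y, cfg.fs, "Y")
    return X, Y, truth


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: TrialEnsemble, path, format: str = "csv",
                   dataset: str = "data") -> None:
    """Write a trial ensemble to delimited text (one trial per row) or HDF5."""
    if format == "csv":
        header = json.dumps({"fs": ensemble.fs, "channel_id": ensemble.channel_id})
        np.savetxt(path, ensemble.data, delimiter=",", header=header)
    elif format == "hdf5":
        import h5py

        with h5py.File(path, "a") as f:
            if dataset in f:
                del f[dataset]
            ds = f.create_dataset(dataset, data=ensemble.data)
            ds.attrs["fs"] = ensemble.fs
            ds.attrs["trial_length"] = ensemble.n_samples
            ds.attrs["channel_id"] = ensemble.channel_id
    else:
        raise ValueError(f"unknown format {format!r}")


def read_ensemble(path, format: str = "csv", dataset: str = "data",
                  fs: Optional[float] = None) -> TrialEnsemble:
    """Read a trial ensemble written by :func:`write_ensemble`.

    For delimited text the sampling rate is taken from the JSON header comment
    or the ``fs`` argument; ragged rows raise :class:`ShapeError` and a missing
    sampling rate raises :class:`MetadataError`.
    """
    if format == "csv":
        meta: dict = {}
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first[1:].strip())
            except json.JSONDecodeError:
                meta = {}
        try:
            data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        except ValueError as exc:
            raise ShapeError(f"ragged or non-numeric rows in {path}: {exc}") from exc
        fs_val = meta.get("fs", fs)
        if fs_val is None:
            raise MetadataError(f"no sampling rate in {path} and none supplied")
        return TrialEnsemble(data, float(fs_val), str(meta.get("channel_id", "")))
    elif format == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise MetadataError(f"dataset {dataset!r} not found in {path}")
            ds = f[dataset]
            if "fs" not in ds.attrs:
                raise MetadataError(f"dataset {dataset!r} in {path} has no 'fs' attribute")
            return TrialEnsemble(
                np.asarray(ds[()]), float(ds.attrs["fs"]),
                str(ds.attrs.get("channel_id", "")),
            )
    raise ValueError(f"unknown format {format!r}")


def run_metadata(seed: int, config: object | None = None) -> dict:
    """JSON-serializable run-metadata record (seed, config, version)."""
    from . import __version__

    rec = {"seed": int(seed), "phasete_version": __version__}
    if config is not None:
        if dataclasses.is_dataclass(config):
            rec["config"] = dataclasses.asdict(config)
        else:
            rec["config"] = dict(config)  # type: ignore[arg-type]
    return rec
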