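"""Time-frequency transformation of epoched EEG.

Short-time Fourier transform with Hann-tapered, heavily overlapping windows;
removal of the evoked (phase-locked) signal in the complex domain; intertrial
phase coherence for verifying that removal; condition averaging of
single-trial power; and percent-change baseline correction.

Under the defaults (500-ms / 125-sample windows, 80% overlap, zero-padding to
1-Hz spacing) epochs spanning −750 to +1250 ms yield frames centered at −500
to +1000 ms in 100-ms steps and frequencies 1–30 Hz in 1-Hz steps. Frames
whose window would extend past the epoch are never produced, so half a window
is trimmed from each side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .synthgen import EpochSet

__all__ = [
    "TFDecomposition",
    "PowerSurface",
    "reject_trials",
    "stft_tfr",
    "subtract_evoked",
    "intertrial_coherence",
    "condition_average",
    "baseline_percent_change",
    "bandpass_filter",
]

logger = logging.getLogger(__name__)


@dataclass
class TFDecomposition:
    """Complex STFT coefficients, trials × channels × frequencies × frames.

    Coefficient magnitude estimates the peak amplitude (µV) of an on-bin
    sinusoid, independent of window length (``2/sum(window)`` scaling), so
    power is in µV² under a fixed, documented convention.
    """

    coefficients: np.ndarray
    frequencies: np.ndarray
    frame_times: np.ndarray  # ms, frame centers
    window_ms: float
    overlap_fraction: float
    condition_labels: np.ndarray | None = None
    subject_id: str = ""

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    @property
    def n_trials(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class PowerSurface:
    """Power per channel × frequency × frame for one condition and subject."""

    values: np.ndarray
    frequencies: np.ndarray
    frame_times: np.ndarray
    units: str  # "linear" (µV²), "log10", or "percent"
    condition: str = ""
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.units == "linear" and np.any(self.values < 0):
            raise ValueError("linear power must be non-negative")


def reject_trials(epochs: EpochSet, threshold: float) -> EpochSet:
    """Drop trials whose absolute voltage exceeds ``threshold`` µV anywhere.

    Survivor order is preserved. Raises if no trial survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = np.abs(epochs.data).max(axis=(1, 2)) <= threshold
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("reject_trials: dropped %d of %d trials at %.0f uV",
                    n_drop, epochs.n_trials, threshold)
    if not keep.any():
        raise ValueError(f"all {epochs.n_trials} trials exceed {threshold} uV")
    return EpochSet(
        data=epochs.data[keep], sampling_rate=epochs.sampling_rate,
        times=epochs.times, condition_labels=epochs.condition_labels[keep],
        subject_id=epochs.subject_id)


def stft_tfr(epochs: EpochSet, window_ms: float = 500.0, overlap: float = 0.8,
             pad_to_resolution: float = 1.0,
             band: tuple[float, float] = (1.0, 30.0)) -> TFDecomposition:
    """Hann-windowed STFT of every trial and channel.

    Frames advance by ``window_ms * (1 - overlap)`` and only fully supported
    windows are kept. The FFT is zero-padded so the frequency spacing equals
    ``pad_to_resolution`` Hz, and the output is restricted to ``band``
    (inclusive). Frame centers are ``epoch_start + window/2 + k*hop``.
    """
    fs = epochs.sampling_rate
    nyq = fs / 2.0
    if band[1] > nyq:
        raise ValueError(f"band upper edge {band[1]} Hz exceeds Nyquist {nyq} Hz")
    n_win_f = window_ms / 1000.0 * fs
    n_win = int(round(n_win_f))
    if abs(n_win_f - n_win) > 1e-9:
        raise ValueError("window_ms must correspond to an integer sample count")
    if n_win > epochs.times.size:
        raise ValueError("epoch shorter than the analysis window")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    hop = int(round(n_win * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large: hop below one sample")
    n_fft = int(round(fs / pad_to_resolution))
    if n_fft < n_win:
        raise ValueError("pad_to_resolution finer than the window allows requires n_fft >= window")

    window = sp_signal.windows.hann(n_win, sym=False)
    scale = 2.0 / window.sum()

    segments = np.lib.stride_tricks.sliding_window_view(epochs.data, n_win, axis=-1)
    segments = segments[..., ::hop, :]  # trials x channels x frames x n_win
    coefs = np.fft.rfft(segments * window, n=n_fft, axis=-1) * scale

    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fmask = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    coefs = np.moveaxis(coefs[..., fmask], -1, 2)  # ... x freqs x frames

    n_frames = segments.shape[2]
    frame_times = epochs.times[0] + window_ms / 2.0 + (hop * 1000.0 / fs) * np.arange(n_frames)
    return TFDecomposition(
        coefficients=coefs, frequencies=freqs[fmask], frame_times=frame_times,
        window_ms=window_ms, overlap_fraction=overlap,
        condition_labels=epochs.condition_labels, subject_id=epochs.subject_id)


def subtract_evoked(tfd: TFDecomposition) -> TFDecomposition:
    """Remove the phase-locked (evoked) part in the complex domain.

    The across-trial mean complex coefficient is subtracted from every trial
    at each (channel, frequency, frame); the output's across-trial mean is
    zero to numerical precision.
    """
    if tfd.n_trials < 2:
        raise ValueError("evoked subtraction requires at least 2 trials")
    evoked = tfd.coefficients.mean(axis=0, keepdims=True)
    return TFDecomposition(
        coefficients=tfd.coefficients - evoked, frequencies=tfd.frequencies,
        frame_times=tfd.frame_times, window_ms=tfd.window_ms,
        overlap_fraction=tfd.overlap_fraction,
        condition_labels=tfd.condition_labels, subject_id=tfd.subject_id)


def intertrial_coherence(tfd: TFDecomposition) -> np.ndarray:
    """Magnitude of the across-trial mean unit phasor, per (ch, freq, frame).

    Zero-magnitude coefficients have undefined phase; they are excluded from
    the mean (with a logged count). Values lie in [0, 1]; 1 means perfect
    phase locking, the chance floor for n independent trials is
    ``sqrt(pi / (4 n))``.
    """
    if tfd.n_trials < 2:
        raise ValueError("ITC requires at least 2 trials")
    mag = np.abs(tfd.coefficients)
    valid = mag > 0
    n_invalid = int(valid.size - valid.sum())
    if n_invalid:
        logger.info("intertrial_coherence: excluded %d zero-magnitude coefficients", n_invalid)
    unit = np.where(valid, tfd.coefficients / np.where(valid, mag, 1.0), 0.0)
    counts = valid.sum(axis=0)
    resultant = np.abs(unit.sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        itc = np.where(counts > 0, resultant / np.maximum(counts, 1), 0.0)
    return itc


def condition_average(tfd: TFDecomposition, labels=None) -> dict[str, PowerSurface]:
    """Mean single-trial power per condition, in linear (µV²) units."""
    if labels is None:
        labels = tfd.condition_labels
    if labels is None:
        raise ValueError("condition labels required")
    labels = np.asarray(labels)
    if labels.size != tfd.n_trials:
        raise ValueError("one label per trial required")
    power = tfd.power
    out = {}
    for cond in np.unique(labels):
        mask = labels == cond
        out[str(cond)] = PowerSurface(
            values=power[mask].mean(axis=0), frequencies=tfd.frequencies,
            frame_times=tfd.frame_times, units="linear", condition=str(cond),
            subject_id=tfd.subject_id)
    return out


def baseline_percent_change(surface: PowerSurface,
                            baseline_window: tuple[float, float] = (-400.0, -200.0)) -> PowerSurface:
    """Percent change from the mean power in ``baseline_window`` (ms).

    ``100 * (P - P_base) / P_base`` per channel and frequency, where
    ``P_base`` is the mean over baseline frames.
    """
    if surface.units != "linear":
        raise ValueError("baseline correction operates on linear power")
    bmask = (surface.frame_times >= baseline_window[0]) & (surface.frame_times <= baseline_window[1])
    if not bmask.any():
        raise ValueError("baseline window covers no frame")
    base = surface.values[..., bmask].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("degenerate baseline: zero power in the baseline window")
    return PowerSurface(
        values=100.0 * (surface.values - base) / base,
        frequencies=surface.frequencies, frame_times=surface.frame_times,
        units="percent", condition=surface.condition, subject_id=surface.subject_id)


def bandpass_filter(epochs: EpochSet, low_hz: float = 1.0, high_hz: float = 30.0,
                    order: int = 2) -> EpochSet:
    """Zero-phase second-order-sections Butterworth bandpass (for real data).

    Synthetic cohorts are band-limited by construction and do not need this.
    """
    sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass",
                           fs=epochs.sampling_rate, output="sos")
    data = sp_signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return EpochSet(data=data, sampling_rate=epochs.sampling_rate, times=epochs.times,
                    condition_labels=epochs.condition_labels, subject_id=epochs.subject_id)
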