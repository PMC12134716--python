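"""Spectral parameterization: aperiodic fit plus iterative Gaussian peaks.

Each power spectrum is decomposed in log10-power space into

* an aperiodic component ``b - chi * log10(f)`` (fixed mode, no knee), where
  ``b`` is the offset and ``chi`` the aperiodic exponent, and
* a sum of Gaussian peaks ``a * exp(-(f - c)^2 / (2 sigma^2))`` describing
  oscillations above the aperiodic background.

The fitting sequence follows the published parameterization algorithm:
a robust aperiodic fit, iterative peak seeding on the flattened spectrum,
joint bounded least-squares refinement of all peaks, and a final aperiodic
refit on the peak-removed spectrum. Applying the procedure independently to
every frame of a spectrogram (no temporal smoothing or clustering) yields
time-resolved oscillatory and aperiodic power surfaces.

Reported peak widths follow the reference-tool bandwidth convention
``width = 2 * sigma`` so the default width bounds are (0.5, 12) Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .tfr import PowerSurface

__all__ = [
    "SpecparamSettings",
    "Peak",
    "SpectralFit",
    "ParameterizedTFR",
    "fit_aperiodic",
    "fit_peaks",
    "parameterize_spectrum",
    "parameterize_tfr",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpecparamSettings:
    """Parameterization settings (defaults follow the reference tool).

    peak_width_bounds
        Bounds on the reported peak width ``2 * sigma``, Hz.
    peak_threshold_sd
        Stop seeding peaks once the tallest flattened point falls below this
        many SDs of the flattened spectrum.
    max_peaks
        Optional cap on the number of peaks (None = unlimited).
    min_peak_height
        Optional absolute height floor, log10 power (None = none).
    robust_percentile
        Percentile of positive residuals above which points are masked in the
        robust aperiodic refit.
    band
        Frequency range fitted, Hz (inclusive).
    """

    peak_width_bounds: tuple[float, float] = (0.5, 12.0)
    peak_threshold_sd: float = 2.0
    max_peaks: int | None = None
    min_peak_height: float | None = None
    robust_percentile: float = 2.5
    band: tuple[float, float] = (1.0, 30.0)

    @property
    def sigma_bounds(self) -> tuple[float, float]:
        return (self.peak_width_bounds[0] / 2.0, self.peak_width_bounds[1] / 2.0)


@dataclass(frozen=True)
class Peak:
    center_hz: float
    amplitude: float  # log10 power above the aperiodic component
    width_hz: float   # 2 * Gaussian SD

    @property
    def sigma(self) -> float:
        return self.width_hz / 2.0


@dataclass
class SpectralFit:
    """One spectrum's decomposition: aperiodic line + Gaussian peaks + R²."""

    offset: float
    exponent: float
    peaks: tuple[Peak, ...]
    r_squared: float
    frequencies: np.ndarray | None = None

    def aperiodic_log10(self, frequencies) -> np.ndarray:
        f = np.asarray(frequencies, dtype=float)
        return self.offset - self.exponent * np.log10(f)

    def oscillatory_log10(self, frequencies) -> np.ndarray:
        f = np.asarray(frequencies, dtype=float)
        out = np.zeros_like(f)
        for p in self.peaks:
            out += p.amplitude * np.exp(-0.5 * ((f - p.center_hz) / p.sigma) ** 2)
        return out

    def model_log10(self, frequencies) -> np.ndarray:
        return self.aperiodic_log10(frequencies) + self.oscillatory_log10(frequencies)


@dataclass
class ParameterizedTFR:
    """Parameterized spectrogram surfaces, channels × frequencies × frames.

    ``total`` is observed log10 power; ``aperiodic`` the fitted line
    evaluated on the grid; ``oscillatory`` the fitted Gaussian sum;
    ``fit_quality`` the per-(channel, frame) R². Frames that failed to fit
    are NaN in all surfaces.
    """

    total: np.ndarray
    aperiodic: np.ndarray
    oscillatory: np.ndarray
    fit_quality: np.ndarray
    frequencies: np.ndarray
    frame_times: np.ndarray
    settings: SpecparamSettings
    condition: str = ""
    subject_id: str = ""
    n_failed: int = 0

    def surface(self, kind: str) -> PowerSurface:
        """Expose one component as a :class:`PowerSurface` (log10 units)."""
        values = {"total": self.total, "aperiodic": self.aperiodic,
                  "oscillatory": self.oscillatory}[kind]
        return PowerSurface(values=values, frequencies=self.frequencies,
                            frame_times=self.frame_times, units="log10",
                            condition=self.condition, subject_id=self.subject_id)


# ---------------------------------------------------------------------------
# aperiodic component
# ---------------------------------------------------------------------------

def _line_fit(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    # least squares line, closed form
    x = log_f - log_f.mean()
    slope = (x * (log_p - log_p.mean())).sum() / (x * x).sum()
    intercept = log_p.mean() - slope * log_f.mean()
    return intercept, slope


def fit_aperiodic(frequencies, log_power, robust: bool = True,
                  percentile: float = 2.5) -> tuple[float, float]:
    """Fit ``log10 P = offset - exponent * log10 f``; return (offset, exponent).

    In robust mode the line is refit after masking points whose positive
    residual exceeds the given percentile of the positive residuals — large
    positive excursions are peaks, and discarding them keeps the aperiodic
    estimate anchored to the spectrum's lower envelope.
    """
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(log_power, dtype=float)
    if f.size < 3:
        raise ValueError("aperiodic fit requires at least 3 frequency points")
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    if not np.all(np.isfinite(p)):
        raise ValueError("log power must be finite")
    log_f = np.log10(f)
    intercept, slope = _line_fit(log_f, p)
    if robust:
        resid = p - (intercept + slope * log_f)
        pos = np.clip(resid, 0.0, None)
        thresh = np.percentile(pos, percentile)
        keep = resid <= thresh
        if keep.sum() >= 3:
            intercept, slope = _line_fit(log_f[keep], p[keep])
    return float(intercept), float(-slope)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def _gaussian(f, c, a, sigma):
    return a * np.exp(-0.5 * ((f - c) / sigma) ** 2)


def _multi_gaussian(params, f):
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        out += _gaussian(f, params[i], params[i + 1], params[i + 2])
    return out


def _refine_peaks(f: np.ndarray, flat: np.ndarray, guesses: list[tuple],
                  sigma_bounds: tuple[float, float]) -> list[tuple]:
    """Jointly refine Gaussians by bounded least squares (analytic Jacobian)."""
    x0, lo, hi = [], [], []
    f_lo, f_hi = f[0], f[-1]
    for c, a, s in guesses:
        x0 += [c, a, s]
        lo += [max(f_lo - s, c - 2.0 * s), 0.0, sigma_bounds[0]]
        hi += [min(f_hi + s, c + 2.0 * s), 1.5 * max(a, 1e-6) + 0.5, sigma_bounds[1]]
    x0 = np.clip(x0, lo, hi)

    def resid(params):
        return _multi_gaussian(params, f) - flat

    def jac(params):
        j = np.empty((f.size, params.size))
        for i in range(0, params.size, 3):
            c, a, s = params[i], params[i + 1], params[i + 2]
            e = np.exp(-0.5 * ((f - c) / s) ** 2)
            j[:, i] = a * e * (f - c) / s ** 2
            j[:, i + 1] = e
            j[:, i + 2] = a * e * (f - c) ** 2 / s ** 3
        return j

    try:
        res = optimize.least_squares(resid, x0, jac=jac, bounds=(lo, hi),
                                     method="trf", xtol=1e-8, ftol=1e-8, max_nfev=200)
        params = res.x
    except Exception:  # pragma: no cover - optimizer pathologies
        logger.warning("peak refinement failed; keeping seeded guesses")
        params = np.asarray(x0)
    return [(params[i], params[i + 1], params[i + 2]) for i in range(0, params.size, 3)]


def fit_peaks(frequencies, flattened, width_bounds: tuple[float, float] = (0.5, 12.0),
              threshold_sd: float = 2.0, max_peaks: int | None = None,
              min_height: float | None = None) -> tuple[Peak, ...]:
    """Iteratively seed and jointly refine Gaussian peaks on a flattened spectrum.

    Seeding: take the global maximum (ties broken toward the lower
    frequency); stop when its height drops below ``threshold_sd`` SDs of the
    current flattened spectrum (or below ``min_height``, or when ``max_peaks``
    is reached); otherwise seed a Gaussian there with width from the
    half-height extent clipped to ``width_bounds``, subtract it, and repeat.
    Guesses centered within one seeded SD of the band edge are discarded.
    After joint refinement, peaks whose center left the band are dropped.
    """
    f = np.asarray(frequencies, dtype=float)
    flat = np.asarray(flattened, dtype=float).copy()
    sigma_lo, sigma_hi = width_bounds[0] / 2.0, width_bounds[1] / 2.0
    guesses: list[tuple] = []
    work = flat.copy()
    while max_peaks is None or len(guesses) < max_peaks:
        i_max = int(np.argmax(work))  # argmax returns the first (lowest-f) tie
        height = work[i_max]
        if height <= 0:
            break
        if height < threshold_sd * work.std():
            break
        if min_height is not None and height < min_height:
            break
        # sub-bin center from a parabola through the three points at the max;
        # keeps the subtracted seed from leaving flank residue at off-grid peaks
        c = f[i_max]
        if 0 < i_max < f.size - 1:
            y0, y1, y2 = work[i_max - 1], work[i_max], work[i_max + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                shift = np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)
                c = f[i_max] + shift * (f[min(i_max + 1, f.size - 1)] - f[i_max])
        # width from the half-height extent; the shorter available side sets
        # it so overlapping peaks are not merged into one broad seed
        half = height / 2.0
        sides = []
        left = i_max
        while left > 0 and work[left] > half:
            left -= 1
        if work[left] <= half:
            sides.append(f[i_max] - f[left])
        right = i_max
        while right < f.size - 1 and work[right] > half:
            right += 1
        if work[right] <= half:
            sides.append(f[right] - f[i_max])
        half_width = min(sides) if sides else (f[-1] - f[0]) / 2.0
        sigma = np.clip(2.0 * half_width / 2.355, sigma_lo, sigma_hi)
        work = work - _gaussian(f, c, height, sigma)
        # edge guard: unconstrained Gaussians hanging off the band are dropped
        if c - f[0] >= sigma and f[-1] - c >= sigma:
            guesses.append((c, height, sigma))
    if not guesses:
        return ()
    refined = _refine_peaks(f, flat, guesses, (sigma_lo, sigma_hi))
    peaks = tuple(Peak(center_hz=float(c), amplitude=float(a), width_hz=float(2.0 * s))
                  for c, a, s in refined
                  if f[0] <= c <= f[-1] and a > 0)
    return tuple(sorted(peaks, key=lambda p: p.center_hz))


# ---------------------------------------------------------------------------
# full spectrum and spectrogram
# ---------------------------------------------------------------------------

def parameterize_spectrum(frequencies, power, settings: SpecparamSettings | None = None) -> SpectralFit:
    """Decompose one linear-power spectrum into aperiodic + peaks.

    Pipeline: robust aperiodic fit → flatten → iterative peak fit → remove
    the peak model from the log spectrum → final aperiodic refit on the
    peak-removed spectrum → assemble the model. ``r_squared`` is the squared
    Pearson correlation between modeled and observed log10 power.
    """
    settings = settings or SpecparamSettings()
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(power, dtype=float)
    bmask = (f >= settings.band[0] - 1e-9) & (f <= settings.band[1] + 1e-9)
    f, p = f[bmask], p[bmask]
    if np.any(p <= 0):
        bad = f[np.nonzero(p <= 0)[0][0]]
        raise ValueError(f"non-positive power at {bad:g} Hz cannot be log-transformed")
    log_p = np.log10(p)

    offset0, exponent0 = fit_aperiodic(f, log_p, robust=True,
                                       percentile=settings.robust_percentile)
    flat = log_p - (offset0 - exponent0 * np.log10(f))
    peaks = fit_peaks(f, flat, width_bounds=settings.peak_width_bounds,
                      threshold_sd=settings.peak_threshold_sd,
                      max_peaks=settings.max_peaks,
                      min_height=settings.min_peak_height)
    peak_model = np.zeros_like(f)
    for pk in peaks:
        peak_model += _gaussian(f, pk.center_hz, pk.amplitude, pk.sigma)
    offset, exponent = fit_aperiodic(f, log_p - peak_model, robust=False)
    model = (offset - exponent * np.log10(f)) + peak_model
    obs_var = log_p.var()
    if obs_var > 0:
        r = np.corrcoef(model, log_p)[0, 1]
        r2 = float(r * r) if np.isfinite(r) else 1.0
    else:
        r2 = 1.0
    return SpectralFit(offset=float(offset), exponent=float(exponent),
                       peaks=peaks, r_squared=r2, frequencies=f)


def parameterize_tfr(surface: PowerSurface, settings: SpecparamSettings | None = None) -> ParameterizedTFR:
    """Parameterize every (channel, frame) spectrum of a linear power surface.

    No smoothing or clustering couples neighboring frames; each frame is fit
    independently. Frames that fail to fit are recorded as NaN with a logged
    diagnostic rather than raising.
    """
    settings = settings or SpecparamSettings()
    if surface.units != "linear":
        raise ValueError("parameterization operates on linear power "
                         "(never baseline-corrected surfaces)")
    f = surface.frequencies
    bmask = (f >= settings.band[0] - 1e-9) & (f <= settings.band[1] + 1e-9)
    f_fit = f[bmask]
    n_ch, _, n_frames = surface.values.shape
    shape = (n_ch, f_fit.size, n_frames)
    total = np.full(shape, np.nan)
    aperiodic = np.full(shape, np.nan)
    oscillatory = np.full(shape, np.nan)
    fit_quality = np.full((n_ch, n_frames), np.nan)
    n_failed = 0
    log_f = np.log10(f_fit)
    for ch in range(n_ch):
        for fr in range(n_frames):
            spec = surface.values[ch, bmask, fr]
            try:
                fit = parameterize_spectrum(f_fit, spec, settings)
            except Exception as exc:
                n_failed += 1
                logger.warning("fit failed at channel %d frame %d: %s", ch, fr, exc)
                continue
            total[ch, :, fr] = np.log10(spec)
            aperiodic[ch, :, fr] = fit.offset - fit.exponent * log_f
            oscillatory[ch, :, fr] = fit.oscillatory_log10(f_fit)
            fit_quality[ch, fr] = fit.r_squared
    if n_failed:
        logger.warning("parameterize_tfr: %d of %d fits failed", n_failed, n_ch * n_frames)
    return ParameterizedTFR(total=total, aperiodic=aperiodic, oscillatory=oscillatory,
                            fit_quality=fit_quality, frequencies=f_fit,
                            frame_times=surface.frame_times, settings=settings,
                            condition=surface.condition, subject_id=surface.subject_id,
                            n_failed=n_failed)
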