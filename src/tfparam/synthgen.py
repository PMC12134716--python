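"""Synthetic event-related EEG cohorts with known ground truth.

Every downstream stage of the package (time-frequency transform, spectral
parameterization, TFCE statistics) is exercised on cohorts produced here, so
each trial is built from fully documented components:

* an aperiodic 1/f background (frequency-domain shaped Gaussian noise) whose
  one-sided PSD is ``10**offset * f**(-exponent)``,
* an event-locked broadband power shift, realized as a smooth multiplicative
  gain on the background so the spectral exponent is untouched,
* oscillatory bursts (Gaussian-enveloped sinusoids) with uniform random phase
  per trial, so their power is induced rather than evoked,
* sustained oscillations with a post-stimulus suppression (alpha/beta
  desynchronization),
* a deterministic phase-locked evoked waveform added identically to every
  trial, and
* a subject-level behavioral score linearly coupled to the subject's realized
  aperiodic offset.

Identical ``(design, seed)`` reproduce a cohort bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EpochSet",
    "BurstSpec",
    "SustainedSpec",
    "AperiodicShift",
    "EvokedSpec",
    "BehaviorCoupling",
    "SyntheticDesign",
    "GroundTruth",
    "default_channel_positions",
    "spatial_profile",
    "simulate_aperiodic_signal",
    "simulate_oscillatory_burst",
    "simulate_subject",
    "simulate_cohort",
    "default_design",
]

#: 32-channel subset of the international 10-20 layout used as default montage.
DEFAULT_CHANNEL_NAMES = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "O2",
)


def default_channel_positions(names=DEFAULT_CHANNEL_NAMES) -> np.ndarray:
    """Unit-sphere 3-D positions for ``names`` from the standard 10-20 montage.

    Positions are taken from mne's standard montage, recentered on the
    best-fit sphere and normalized to unit radius, so Euclidean chord
    distances are comparable across the scalp.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    ch_pos = montage.get_positions()["ch_pos"]
    pos = np.array([ch_pos[n] for n in names], dtype=float)
    # best-fit sphere center: solve |p - c|^2 = r^2 linearly
    a = np.c_[2.0 * pos, np.ones(len(pos))]
    b = (pos ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    centered = pos - sol[:3]
    return centered / np.linalg.norm(centered, axis=1, keepdims=True)


def spatial_profile(positions: np.ndarray, center: np.ndarray, width: float = 0.6) -> np.ndarray:
    """Per-channel gains: Gaussian in chord distance from ``center`` (peak 1)."""
    center = np.asarray(center, dtype=float)
    center = center / np.linalg.norm(center)
    d = np.linalg.norm(positions - center, axis=1)
    return np.exp(-0.5 * (d / width) ** 2)


# ---------------------------------------------------------------------------
# design dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurstSpec:
    """Gaussian-enveloped sinusoid with uniform random phase per trial."""

    frequency_hz: float
    amplitude_uv: float
    center_ms: float
    envelope_sd_ms: float
    condition: str
    topography: np.ndarray | None = None  # per-channel gain, peak 1


@dataclass(frozen=True)
class SustainedSpec:
    """Ongoing oscillation with smooth post-stimulus suppression."""

    frequency_hz: float
    amplitude_uv: float
    suppression: float  # fraction of amplitude removed post-stimulus, in [0, 1]
    condition: str
    suppression_onset_ms: float = 0.0
    suppression_duration_ms: float = 700.0
    topography: np.ndarray | None = None


@dataclass(frozen=True)
class AperiodicShift:
    """Event-locked additive change of the aperiodic offset (log10 power)."""

    magnitude: float
    onset_ms: float
    duration_ms: float
    condition: str
    topography: np.ndarray | None = None


@dataclass(frozen=True)
class EvokedSpec:
    """Deterministic phase-locked waveform added to every trial.

    A Gaussian-windowed sinusoid with fixed phase; ``amplitude_uv = 0``
    disables it.
    """

    amplitude_uv: float = 4.0
    frequency_hz: float = 3.0
    center_ms: float = 150.0
    envelope_sd_ms: float = 70.0
    topography: np.ndarray | None = None


@dataclass(frozen=True)
class BehaviorCoupling:
    """score = intercept + slope * subject_aperiodic_offset + N(0, noise_sd)."""

    intercept: float = 0.9
    slope: float = 0.4
    noise_sd: float = 0.1732
    clip_unit_interval: bool = True


@dataclass
class SyntheticDesign:
    """Full description of a simulated two-condition event-related study."""

    n_subjects: int = 20
    n_trials_per_condition: int = 100
    sampling_rate: float = 250.0
    epoch_window_ms: tuple[float, float] = (-750.0, 1250.0)
    conditions: tuple[str, ...] = ("congruent", "incongruent")
    channel_positions: np.ndarray = field(default_factory=default_channel_positions)
    # aperiodic background, per condition (log10 power at 1 Hz, exponent)
    aperiodic_offset: dict[str, float] = field(
        default_factory=lambda: {"congruent": -1.0, "incongruent": -1.0})
    aperiodic_exponent: dict[str, float] = field(
        default_factory=lambda: {"congruent": 1.0, "incongruent": 1.0})
    subject_offset_sd: float = 0.25
    aperiodic_shifts: tuple[AperiodicShift, ...] = ()
    bursts: tuple[BurstSpec, ...] = ()
    sustained: tuple[SustainedSpec, ...] = ()
    evoked: EvokedSpec = field(default_factory=EvokedSpec)
    behavior: BehaviorCoupling = field(default_factory=BehaviorCoupling)
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.channel_positions)

    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sampling_rate
        start, stop = self.epoch_window_ms
        n = int(round((stop - start) / dt))
        return start + dt * np.arange(n)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.epoch_window_ms[1] <= self.epoch_window_ms[0]:
            raise ValueError("epoch_window_ms must be increasing")
        nyq = self.sampling_rate / 2.0
        for b in self.bursts:
            if b.amplitude_uv < 0:
                raise ValueError("burst amplitude must be >= 0")
            if b.frequency_hz >= nyq:
                raise ValueError(f"burst frequency {b.frequency_hz} Hz >= Nyquist")
            if b.envelope_sd_ms <= 0:
                raise ValueError("burst envelope SD must be positive")
            if b.condition not in self.conditions:
                raise ValueError(f"unknown burst condition {b.condition!r}")
        for s in self.sustained:
            if s.amplitude_uv < 0:
                raise ValueError("sustained amplitude must be >= 0")
            if not 0.0 <= s.suppression <= 1.0:
                raise ValueError("suppression fraction must lie in [0, 1]")
            if s.frequency_hz >= nyq:
                raise ValueError(f"sustained frequency {s.frequency_hz} Hz >= Nyquist")
        for cond in self.conditions:
            if cond not in self.aperiodic_offset or cond not in self.aperiodic_exponent:
                raise ValueError(f"missing aperiodic parameters for {cond!r}")
            if self.aperiodic_exponent[cond] < 0:
                raise ValueError("aperiodic exponent must be >= 0")


@dataclass
class EpochSet:
    """Epoched voltages for one subject and condition.

    data
        µV array, trials × channels × samples.
    times
        ms relative to the event, uniform grid.
    """

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray
    condition_labels: np.ndarray
    subject_id: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.condition_labels = np.asarray(self.condition_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length must match sample count")
        if self.data.shape[0] != self.condition_labels.size:
            raise ValueError("one condition label per trial required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contain non-finite values")
        dt = 1000.0 / self.sampling_rate
        if self.times.size > 1 and not np.allclose(np.diff(self.times), dt):
            raise ValueError("times grid spacing must equal 1000/sampling_rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class GroundTruth:
    """Realized simulation parameters, one record per subject-condition."""

    records: dict = field(default_factory=dict)

    def record(self, subject: int, condition: str, **kwargs) -> None:
        self.records[(subject, condition)] = dict(kwargs)

    def __getitem__(self, key):
        return self.records[key]


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def simulate_aperiodic_signal(exponent: float, offset: float, duration: float,
                              sampling_rate: float, seed=None) -> np.ndarray:
    """Zero-mean voltage series with one-sided PSD ``10**offset * f**(-exponent)``.

    Frequency-domain synthesis: complex Gaussian spectrum shaped by
    ``sqrt(S(f))``, inverse-transformed. The DC bin is zeroed, so the output
    has exactly zero mean; the expected Welch PSD matches the target at every
    positive frequency.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    psd = np.zeros_like(freqs)
    psd[1:] = 10.0 ** offset * freqs[1:] ** (-exponent)
    # E|X_k|^2 = S(f_k) * fs * n / 2 makes the one-sided periodogram unbiased
    sigma = np.sqrt(psd * sampling_rate * n / 2.0)
    spec = sigma * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real * np.sqrt(2.0)
    return np.fft.irfft(spec, n=n)


def simulate_oscillatory_burst(frequency: float, amplitude: float, center_time: float,
                               envelope_sd: float, times: np.ndarray,
                               phase: float = 0.0, sampling_rate: float | None = None) -> np.ndarray:
    """Gaussian-enveloped sinusoid on the ``times`` grid (ms).

    The envelope peaks at ``amplitude`` at ``center_time``; ``phase`` is the
    sinusoid phase at the envelope center.
    """
    times = np.asarray(times, dtype=float)
    if envelope_sd <= 0:
        raise ValueError("envelope_sd must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if sampling_rate is None and times.size > 1:
        sampling_rate = 1000.0 / (times[1] - times[0])
    if sampling_rate is not None and frequency >= sampling_rate / 2.0:
        raise ValueError(f"frequency {frequency} Hz is at or above Nyquist")
    envelope = amplitude * np.exp(-0.5 * ((times - center_time) / envelope_sd) ** 2)
    return envelope * np.sin(2.0 * np.pi * frequency * (times - center_time) / 1000.0 + phase)


def _smooth_gate(times: np.ndarray, onset_ms: float, duration_ms: float,
                 ramp_ms: float = 100.0) -> np.ndarray:
    """0→1→0 gate over [onset, onset+duration] with raised-cosine ramps."""
    t = np.asarray(times, dtype=float)
    ramp = min(ramp_ms, duration_ms / 2.0)
    up = np.clip((t - onset_ms) / ramp, 0.0, 1.0)
    down = np.clip((onset_ms + duration_ms - t) / ramp, 0.0, 1.0)
    smooth = lambda x: 0.5 - 0.5 * np.cos(np.pi * x)  # noqa: E731
    return smooth(up) * smooth(down)


def _component_gain(topography, n_channels: int) -> np.ndarray:
    if topography is None:
        return np.ones(n_channels)
    gain = np.asarray(topography, dtype=float)
    if gain.shape != (n_channels,):
        raise ValueError("topography must have one gain per channel")
    return gain


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

def _subject_rng(design: SyntheticDesign, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([design.seed, subject_index]))


def simulate_subject(design: SyntheticDesign, subject_index: int,
                     return_components: bool = False):
    """Simulate all conditions for one subject.

    Returns ``(epochs_by_condition, truth_record)`` where the first element
    maps condition label → :class:`EpochSet`. With ``return_components=True``
    a third element maps condition → dict of the additive trial components
    (``background``, ``bursts``, ``sustained``, ``evoked``), whose sum equals
    the generated data exactly.
    """
    design.validate()
    if not 0 <= subject_index < design.n_subjects:
        raise ValueError("subject_index out of range")
    rng = _subject_rng(design, subject_index)
    times = design.times_ms()
    n_samp = times.size
    n_ch = design.n_channels
    n_tr = design.n_trials_per_condition
    duration = n_samp / design.sampling_rate

    # one subject-level offset deviation shared across conditions
    offset_dev = design.subject_offset_sd * rng.standard_normal()

    epochs: dict[str, EpochSet] = {}
    components: dict[str, dict[str, np.ndarray]] = {}
    truth: dict[str, dict] = {}
    for cond in design.conditions:
        offset = design.aperiodic_offset[cond] + offset_dev
        exponent = design.aperiodic_exponent[cond]

        # event-locked offset time course (log10 power) per channel
        shift_tc = np.zeros((n_ch, n_samp))
        for sh in design.aperiodic_shifts:
            if sh.condition != cond:
                continue
            gain = _component_gain(sh.topography, n_ch)
            shift_tc += sh.magnitude * gain[:, None] * _smooth_gate(times, sh.onset_ms, sh.duration_ms)
        amp_gain = 10.0 ** (shift_tc / 2.0)  # power gain 10**shift

        background = np.empty((n_tr, n_ch, n_samp))
        for tr in range(n_tr):
            for ch in range(n_ch):
                background[tr, ch] = simulate_aperiodic_signal(
                    exponent, offset, duration, design.sampling_rate, seed=rng)
        background *= amp_gain[None, :, :]

        burst_part = np.zeros_like(background)
        cond_bursts = [b for b in design.bursts if b.condition == cond]
        burst_phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_tr, len(cond_bursts)))
        for bi, b in enumerate(cond_bursts):
            gain = _component_gain(b.topography, n_ch)
            for tr in range(n_tr):
                wave = simulate_oscillatory_burst(
                    b.frequency_hz, b.amplitude_uv, b.center_ms, b.envelope_sd_ms,
                    times, phase=burst_phases[tr, bi], sampling_rate=design.sampling_rate)
                burst_part[tr] += gain[:, None] * wave[None, :]

        sustained_part = np.zeros_like(background)
        cond_sustained = [s for s in design.sustained if s.condition == cond]
        sus_phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_tr, len(cond_sustained)))
        for si, s in enumerate(cond_sustained):
            gain = _component_gain(s.topography, n_ch)
            envelope = s.amplitude_uv * (1.0 - s.suppression * _smooth_gate(
                times, s.suppression_onset_ms, s.suppression_duration_ms))
            for tr in range(n_tr):
                wave = envelope * np.sin(
                    2.0 * np.pi * s.frequency_hz * times / 1000.0 + sus_phases[tr, si])
                sustained_part[tr] += gain[:, None] * wave[None, :]

        ev = design.evoked
        evoked_wave = simulate_oscillatory_burst(
            ev.frequency_hz, ev.amplitude_uv, ev.center_ms, ev.envelope_sd_ms,
            times, phase=np.pi / 2.0, sampling_rate=design.sampling_rate)
        evoked_part = np.broadcast_to(
            _component_gain(ev.topography, n_ch)[:, None] * evoked_wave[None, :],
            background.shape).copy()

        data = background + burst_part + sustained_part + evoked_part
        epochs[cond] = EpochSet(
            data=data, sampling_rate=design.sampling_rate, times=times.copy(),
            condition_labels=np.array([cond] * n_tr), subject_id=f"S{subject_index:03d}")
        components[cond] = {
            "background": background, "bursts": burst_part,
            "sustained": sustained_part, "evoked": evoked_part,
        }
        truth[cond] = {
            "aperiodic_offset": offset,
            "aperiodic_exponent": exponent,
            "offset_time_course_log10": shift_tc + offset,
            "burst_phases": burst_phases,
            "bursts": cond_bursts,
            "sustained": cond_sustained,
            "evoked_waveform": evoked_wave,
        }

    if return_components:
        return epochs, truth, components
    return epochs, truth


def simulate_cohort(design: SyntheticDesign):
    """Simulate all subjects plus the behavioral covariate.

    Returns ``(subjects, behavior, ground_truth)`` where ``subjects`` is a
    list of condition → :class:`EpochSet` dicts and ``behavior`` a per-subject
    score coupled to the realized aperiodic offset.
    """
    design.validate()
    if design.n_subjects < 4:
        raise ValueError("a cohort needs n_subjects >= 4")
    truth = GroundTruth()
    subjects = []
    offsets = np.empty(design.n_subjects)
    for s in range(design.n_subjects):
        epochs, rec = simulate_subject(design, s)
        subjects.append(epochs)
        for cond, r in rec.items():
            truth.record(s, cond, **r)
        offsets[s] = np.mean([rec[c]["aperiodic_offset"] for c in design.conditions])

    beh = design.behavior
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x5EED]))
    scores = beh.intercept + beh.slope * offsets + beh.noise_sd * rng.standard_normal(design.n_subjects)
    if beh.clip_unit_interval:
        scores = np.clip(scores, 0.0, 1.0)
    truth.records["behavior"] = {
        "scores": scores, "noiseless_predictor": beh.intercept + beh.slope * offsets,
        "subject_offsets": offsets,
    }
    return subjects, scores, truth


def default_design(n_subjects: int = 20, n_trials_per_condition: int = 100,
                   seed: int = 0, positions: np.ndarray | None = None) -> SyntheticDesign:
    """Study-like two-condition design with known effects.

    Emulates a flanker-style recording: stimulus-locked mediofrontal theta
    bursts (stronger for the incongruent condition), sustained posterior alpha
    and central beta with post-stimulus desynchronization, a phase-locked
    evoked waveform, and a broadband event-locked aperiodic power increase
    that differs between conditions over central sensors.
    """
    if positions is None:
        positions = default_channel_positions()
    frontal = spatial_profile(positions, np.array([0.0, 0.7, 0.7]))
    posterior = spatial_profile(positions, np.array([0.0, -0.8, 0.6]))
    central = spatial_profile(positions, np.array([0.0, 0.0, 1.0]))
    return SyntheticDesign(
        n_subjects=n_subjects,
        n_trials_per_condition=n_trials_per_condition,
        channel_positions=positions,
        bursts=(
            BurstSpec(6.0, 1.0, 400.0, 150.0, "congruent", topography=frontal),
            BurstSpec(6.0, 2.0, 400.0, 150.0, "incongruent", topography=frontal),
        ),
        sustained=(
            SustainedSpec(10.0, 2.0, 0.4, "congruent", topography=posterior),
            SustainedSpec(10.0, 2.0, 0.4, "incongruent", topography=posterior),
            SustainedSpec(20.0, 1.0, 0.3, "congruent", topography=central),
            SustainedSpec(20.0, 1.0, 0.3, "incongruent", topography=central),
        ),
        aperiodic_shifts=(
            AperiodicShift(0.15, 0.0, 600.0, "congruent", topography=central),
            AperiodicShift(0.35, 0.0, 600.0, "incongruent", topography=central),
        ),
        evoked=EvokedSpec(amplitude_uv=4.0, frequency_hz=3.0, center_ms=150.0,
                          envelope_sd_ms=70.0, topography=central),
        seed=seed,
    )


def design_to_dict(design: SyntheticDesign) -> dict:
    """Plain-data representation of a design (for YAML round-trips)."""
    def conv(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        return obj

    out = {f.name: conv(getattr(design, f.name)) for f in dataclasses.fields(design)}
    return out


def design_from_dict(d: dict) -> SyntheticDesign:
    d = dict(d)
    arr = lambda x: None if x is None else np.asarray(x, dtype=float)  # noqa: E731
    d["channel_positions"] = arr(d["channel_positions"])
    d["epoch_window_ms"] = tuple(d["epoch_window_ms"])
    d["conditions"] = tuple(d["conditions"])
    d["bursts"] = tuple(BurstSpec(**{**b, "topography": arr(b.get("topography"))})
                        for b in d.get("bursts", ()))
    d["sustained"] = tuple(SustainedSpec(**{**s, "topography": arr(s.get("topography"))})
                           for s in d.get("sustained", ()))
    d["aperiodic_shifts"] = tuple(AperiodicShift(**{**s, "topography": arr(s.get("topography"))})
                                  for s in d.get("aperiodic_shifts", ()))
    ev = d.get("evoked")
    if isinstance(ev, dict):
        d["evoked"] = EvokedSpec(**{**ev, "topography": arr(ev.get("topography"))})
    bh = d.get("behavior")
    if isinstance(bh, dict):
        d["behavior"] = BehaviorCoupling(**bh)
    return SyntheticDesign(**d)
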