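"""Single-cycle flow waveforms: the arteriovenous (AV) driving flow and synthetic cohorts.

The pulsatile load on the craniospinal system is the arteriovenous flow --
arterial inflow to the cranium minus the (delayed, flattened) venous outflow.
Because the venous return is measured less reliably than the arterial inflow,
the venous curve is shifted and volume-matched to the arterial one before
subtraction, so the AV flow carries exactly zero net volume per cardiac cycle
(Monro-Kellie: the rigid cranium cannot accumulate volume over a cycle).

All flows are in ml/min, sampled uniformly on the closed-open grid
``[0, period)``; the caudally directed flow (cranium -> spine) is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GridMismatchError, InvalidParameterError

#: Minimum samples per cycle (cardiac-gated PC-MRI resolves 32 frames per cycle).
MIN_SAMPLES = 32

#: Default sampling density (power of two, comfortably above 32 frames).
DEFAULT_SAMPLES = 256

#: Default heart rate of the bench protocol, beats/min.
DEFAULT_HEART_RATE = 70.0

#: Default AV stroke volume, ml per cardiac cycle.
DEFAULT_STROKE_VOLUME = 0.8

# Parametric defaults of the AV generator (seconds / ml/min).  The arterial
# systolic lobe is a narrow Gaussian riding on the mean cerebral inflow; the
# venous return is the same volume delayed and flattened by the venous
# compliance.  Values are chosen to reproduce the canonical AV morphology:
# a sharp systolic surge followed by a shallower, roughly twice-as-wide
# negative lobe roughly an eighth of a cycle later.
ARTERIAL_PEAK = 350.0
ARTERIAL_BASELINE = 650.0
SYSTOLIC_TIME = 0.20
ARTERIAL_WIDTH = 0.06
VENOUS_DELAY = 0.12
VENOUS_SMOOTHING = 0.10

# Cervical CSF cohort template statistics (ml/min, ml, fraction of cycle):
# bidirectional flow maxima, spinal stroke volume and the late cranial-directed
# maximum typical of healthy young adults.
TEMPLATE_CAUDAL_MAX = 122.82
TEMPLATE_CRANIAL_MAX = -77.86
TEMPLATE_STROKE_VOLUME = 0.385
TEMPLATE_CRANIAL_PHASE = 0.63


@dataclass(frozen=True)
class SampledWaveform:
    """One cardiac cycle of flow, uniformly sampled on ``[0, period)``.

    Parameters
    ----------
    period:
        Cycle duration in seconds (60 / heart rate).
    values:
        Flow samples in ml/min, caudal / into-cranium positive.
    sign_convention:
        Documentation tag; ``"caudal_positive"`` is the only convention used.
    """

    period: float
    values: np.ndarray
    sign_convention: str = "caudal_positive"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.isfinite(self.period) or self.period <= 0:
            raise InvalidParameterError(f"period must be positive, got {self.period}")
        if vals.ndim != 1 or vals.size < MIN_SAMPLES:
            raise InvalidParameterError(
                f"waveform needs >= {MIN_SAMPLES} samples in one cycle, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise InvalidParameterError("waveform samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return self.period / self.n_samples

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    # -- cycle integrals -------------------------------------------------
    def cycle_volume(self) -> float:
        """Net volume per cycle in ml (periodic trapezoid = mean * period)."""
        return float(np.mean(self.values)) * self.period / 60.0

    def positive_lobe_volume(self) -> float:
        """Volume of the caudally directed lobe, ml per cycle."""
        return _wrap_trapz(np.clip(self.values, 0.0, None), self.dt) / 60.0

    def negative_lobe_volume(self) -> float:
        """Magnitude of the cranially directed lobe volume, ml per cycle."""
        return _wrap_trapz(np.clip(-self.values, 0.0, None), self.dt) / 60.0

    def tile(self, n_cycles: int) -> tuple[np.ndarray, np.ndarray]:
        """Time grid and samples of this cycle repeated ``n_cycles`` times."""
        if n_cycles < 1:
            raise InvalidParameterError("n_cycles must be >= 1")
        t = np.arange(self.n_samples * n_cycles) * self.dt
        return t, np.tile(self.values, n_cycles)

    def same_grid(self, other: "SampledWaveform", tol: float = 1e-9) -> bool:
        return (
            self.n_samples == other.n_samples
            and abs(self.period - other.period) <= tol * max(1.0, self.period)
        )


def _wrap_trapz(vals: np.ndarray, dt: float) -> float:
    """Trapezoidal integral over one period treating the grid as circular."""
    closed = np.append(vals, vals[0])
    return float(np.trapezoid(closed, dx=dt))


def _wrapped_gaussian(t: np.ndarray, mu: float, sigma: float, period: float) -> np.ndarray:
    """Periodically wrapped unit-peak Gaussian (3 image terms suffice here)."""
    out = np.zeros_like(t)
    for k in (-2, -1, 0, 1, 2):
        out += np.exp(-0.5 * ((t - mu - k * period) / sigma) ** 2)
    return out


def generate_arterial(
    peak_flow: float = ARTERIAL_PEAK,
    systolic_time: float = SYSTOLIC_TIME,
    width: float = ARTERIAL_WIDTH,
    baseline: float = ARTERIAL_BASELINE,
    period: float = 60.0 / DEFAULT_HEART_RATE,
    n_samples: int = DEFAULT_SAMPLES,
) -> SampledWaveform:
    """Parametric arterial inflow: baseline plus a Gaussian systolic lobe.

    ``peak_flow`` is the lobe height above baseline (ml/min), ``width`` its
    Gaussian sigma in seconds, ``systolic_time`` the lobe centre.
    """
    if period <= 0 or width <= 0:
        raise InvalidParameterError("period and width must be positive")
    if not 0 <= systolic_time < period:
        raise InvalidParameterError("systolic_time must lie in [0, period)")
    t = np.arange(n_samples) * period / n_samples
    vals = baseline + peak_flow * _wrapped_gaussian(t, systolic_time, width, period)
    return SampledWaveform(period=period, values=vals)


def derive_venous(
    arterial: SampledWaveform,
    delay: float = VENOUS_DELAY,
    smoothing_width: float = VENOUS_SMOOTHING,
) -> SampledWaveform:
    """Venous outflow model: the arterial curve delayed and low-pass flattened.

    The circular time shift and Gaussian smoothing are applied spectrally, so
    the cycle volume is preserved exactly (the DC coefficient is untouched).
    """
    if not 0 <= delay < arterial.period:
        raise InvalidParameterError("delay must lie in [0, period)")
    if smoothing_width < 0 or smoothing_width >= arterial.period:
        raise InvalidParameterError("smoothing width must lie in [0, period)")
    spec = np.fft.rfft(arterial.values)
    freqs = np.fft.rfftfreq(arterial.n_samples, arterial.dt)
    spec = spec * np.exp(-2j * np.pi * freqs * delay)
    if smoothing_width > 0:
        spec = spec * np.exp(-0.5 * (2 * np.pi * freqs * smoothing_width) ** 2)
    vals = np.fft.irfft(spec, arterial.n_samples)
    return SampledWaveform(period=arterial.period, values=vals)


def match_venous_volume(
    arterial: SampledWaveform,
    venous: SampledWaveform,
    extra_shift: float = 0.0,
) -> SampledWaveform:
    """Scale (optionally after a further circular shift) the venous curve so
    its cycle volume equals the arterial one.

    Exact volume equality is required downstream: the AV difference must carry
    zero net volume or the cam profile would not close and the simulated
    pressures would drift cycle over cycle.
    """
    if not arterial.same_grid(venous):
        raise GridMismatchError("arterial and venous waveforms must share one grid")
    vals = venous.values
    if extra_shift:
        spec = np.fft.rfft(vals)
        freqs = np.fft.rfftfreq(venous.n_samples, venous.dt)
        vals = np.fft.irfft(spec * np.exp(-2j * np.pi * freqs * extra_shift), venous.n_samples)
    v_ven = float(np.mean(vals)) * venous.period / 60.0
    v_art = arterial.cycle_volume()
    if v_ven <= 0:
        raise InvalidParameterError("venous cycle volume must be positive to match")
    return SampledWaveform(period=venous.period, values=vals * (v_art / v_ven))


def av_flow(arterial: SampledWaveform, venous: SampledWaveform) -> SampledWaveform:
    """Pointwise arterial minus venous flow (the net pulsatile volume load)."""
    if not arterial.same_grid(venous):
        raise GridMismatchError("arterial and venous waveforms must share one grid")
    return SampledWaveform(period=arterial.period, values=arterial.values - venous.values)


def scale_to_stroke_volume(wf: SampledWaveform, target_sv: float) -> SampledWaveform:
    """Scale a waveform so its caudal (positive) lobe volume equals ``target_sv`` ml."""
    if target_sv < 0:
        raise InvalidParameterError("target stroke volume must be non-negative")
    sv = wf.positive_lobe_volume()
    if sv <= 0:
        raise InvalidParameterError("waveform has no positive lobe to scale")
    return replace(wf, values=wf.values * (target_sv / sv))


def default_av_waveform(
    heart_rate_bpm: float = DEFAULT_HEART_RATE,
    n_samples: int = DEFAULT_SAMPLES,
    stroke_volume: float = DEFAULT_STROKE_VOLUME,
) -> SampledWaveform:
    """The default AV driving waveform: generated arterial and venous curves,
    volume matching, subtraction, and scaling to the target stroke volume
    (default 0.8 ml per cycle)."""
    period = 60.0 / heart_rate_bpm
    art = generate_arterial(period=period, n_samples=n_samples)
    ven = derive_venous(art)
    ven = match_venous_volume(art, ven)
    av = av_flow(art, ven)
    return scale_to_stroke_volume(av, stroke_volume)


def cervical_template(
    heart_rate_bpm: float = DEFAULT_HEART_RATE,
    n_samples: int = DEFAULT_SAMPLES,
) -> SampledWaveform:
    """Template cervical (C2-C3) CSF flow of a healthy young adult.

    Two opposed Gaussian lobes with equal volumes: caudal maximum 122.82
    ml/min at cycle start, cranial maximum -77.86 ml/min at 63% of the cycle,
    each lobe carrying the 0.385 ml spinal stroke volume.
    """
    period = 60.0 / heart_rate_bpm
    t = np.arange(n_samples) * period / n_samples
    root2pi = np.sqrt(2 * np.pi)
    sig_caudal = TEMPLATE_STROKE_VOLUME * 60.0 / (TEMPLATE_CAUDAL_MAX * root2pi)
    sig_cranial = TEMPLATE_STROKE_VOLUME * 60.0 / (-TEMPLATE_CRANIAL_MAX * root2pi)
    lobe_caudal = _wrapped_gaussian(t, 0.0, sig_caudal, period)
    lobe_cranial = _wrapped_gaussian(t, TEMPLATE_CRANIAL_PHASE * period, sig_cranial, period)
    # the opposing lobe's wrapped tail shaves ~2% off each extremum; a short
    # fixed-point correction of the amplitudes restores the target statistics
    a_caudal, a_cranial = TEMPLATE_CAUDAL_MAX, TEMPLATE_CRANIAL_MAX
    for _ in range(8):
        vals = a_caudal * lobe_caudal + a_cranial * lobe_cranial
        a_caudal *= TEMPLATE_CAUDAL_MAX / vals.max()
        a_cranial *= TEMPLATE_CRANIAL_MAX / vals.min()
    return SampledWaveform(period=period, values=a_caudal * lobe_caudal + a_cranial * lobe_cranial)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cervical-flow cohort.

    ``amplitude_jitter`` is the relative (1-sigma) spread of the caudal and
    cranial lobe amplitudes across subjects; ``phase_jitter`` the 1-sigma
    timing spread as a fraction of the cycle.  Defaults emulate the
    subject-to-subject spread of a nine-volunteer cohort whose bidirectional
    extrema deviate by roughly a quarter of their mean and whose cranial-max
    timing varies by about 10% of the cycle.
    """

    n_subjects: int = 9
    template: SampledWaveform = field(default_factory=cervical_template)
    amplitude_jitter: float = 0.15
    phase_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if self.amplitude_jitter < 0 or self.phase_jitter < 0:
            raise InvalidParameterError("jitter parameters must be non-negative")


def synth_cohort(spec: CohortSpec) -> list[SampledWaveform]:
    """Draw a reproducible synthetic cohort around the template waveform.

    Each subject scales the caudal and cranial lobes independently
    (multiplicative Gaussian jitter, clipped at 0.1 to preserve lobe signs)
    and circularly shifts the cycle by a Gaussian timing offset.
    """
    rng = np.random.default_rng(spec.seed)
    wf = spec.template
    out: list[SampledWaveform] = []
    for _ in range(spec.n_subjects):
        f_caudal = max(0.1, 1.0 + spec.amplitude_jitter * rng.standard_normal())
        f_cranial = max(0.1, 1.0 + spec.amplitude_jitter * rng.standard_normal())
        shift = int(round(spec.phase_jitter * rng.standard_normal() * wf.n_samples))
        vals = np.where(wf.values >= 0, f_caudal * wf.values, f_cranial * wf.values)
        vals = np.roll(vals, shift)
        out.append(SampledWaveform(period=wf.period, values=vals))
    return out


def add_sensor_noise(
    wf: SampledWaveform, accuracy: float = 6.0, seed: int = 0
) -> SampledWaveform:
    """Add ultrasound-flow-meter noise to a waveform.

    The manufacturer ``accuracy`` (ml/min) is read as a +/- bound of about two
    standard deviations, i.e. additive zero-mean Gaussian noise with
    sigma = accuracy / 2.
    """
    if accuracy < 0:
        raise InvalidParameterError("accuracy must be non-negative")
    if accuracy == 0:
        return wf
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, accuracy / 2.0, wf.n_samples)
    return replace(wf, values=wf.values + noise)
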