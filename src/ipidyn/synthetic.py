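"""Synthetic three-state EEG-like traces with controlled IPI predictability.

The generator produces what the analysis consumes, nothing more: a
peak-structured waveform whose inter-peak intervals follow an AR(2)
process with positively skewed innovations.  Each behavioural state is a
:class:`StateProfile`; predictability is controlled by the innovation
noise of the interval process, so REM (smallest innovation SD) yields the
most predictable intervals and slow-wave sleep (largest, with larger peak
amplitudes in analogy to slow waves) the least — the generative analogue
of the empirical state ordering this pipeline measures.

Intervals are drawn as

    x_t = phi1 x_{t-1} + phi2 x_{t-2} + eta_t,
    interval_t = round(ipi_mean + x_t) clipped to >= 2,

with eta_t a standardized shifted lognormal scaled to ``innovation_sd``,
so the interval distribution is positively skewed like real interval data.
The waveform places a peak at each cumulative interval position and renders
a raised-cosine arc down to baseline and back between consecutive peaks, so
every cycle contributes exactly one strict local maximum before measurement
noise is added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .signal_io import SignalTrace, SleepState

__all__ = [
    "StateProfile",
    "SyntheticRun",
    "default_profiles",
    "generate_ipi_sequence",
    "synthesize_signal",
    "generate_run",
]


@dataclass(frozen=True)
class StateProfile:
    """Generative parameters for one behavioural state.

    ipi_mean: mean interval in samples (12 samples = 120 ms at 100 Hz,
    inside the ~100-150 ms scale of slow cortical peak dynamics).
    ar_coeffs: AR(2) coefficients on the mean-centered interval process.
    innovation_sd: interval process noise in samples — the predictability dial.
    amplitude_mean/amplitude_sd: peak heights in microvolts.
    noise_sd: additive white measurement noise in microvolts.
    ipi_skew: lognormal shape parameter of the innovations (0 = symmetric).
    slow_amp/slow_freq: amplitude (microvolts) and frequency (Hz) of an
    additive slow-oscillation baseline (0 = none).  Slow-wave sleep EEG is
    dominated by a high-amplitude sub-hertz oscillation with the faster
    peak structure riding on top; the default SWS profile uses this so its
    spectral mass sits at the low-frequency end like real deep-sleep EEG.
    The amplitude/frequency product is kept small enough that the baseline
    slope never exceeds the arc curvature at a peak, so peak *positions*
    are unaffected.
    """

    name: SleepState
    ipi_mean: float = 12.0
    ar_coeffs: tuple[float, float] = (0.5, 0.2)
    innovation_sd: float = 1.0
    amplitude_mean: float = 40.0
    amplitude_sd: float = 4.0
    noise_sd: float = 2.0
    ipi_skew: float = 0.6
    slow_amp: float = 0.0
    slow_freq: float = 0.2

    def __post_init__(self) -> None:
        if self.ipi_mean < 4:
            raise ValueError(f"ipi_mean must be >= 4 samples, got {self.ipi_mean}")
        if self.innovation_sd < 0:
            raise ValueError("innovation_sd must be nonnegative")
        p1, p2 = self.ar_coeffs
        # stationarity triangle for AR(2)
        if not (abs(p2) < 1 and p2 + p1 < 1 and p2 - p1 < 1):
            raise ValueError(f"AR coefficients {self.ar_coeffs} are not stationary")
        if not self.amplitude_mean > 3 * self.noise_sd:
            raise ValueError(
                "amplitude_mean must exceed 3x noise_sd for peaks to survive smoothing"
            )
        if self.ipi_skew < 0:
            raise ValueError("ipi_skew must be nonnegative")
        if self.slow_amp < 0 or self.slow_freq <= 0:
            raise ValueError("slow_amp must be >= 0 and slow_freq > 0")


@dataclass(frozen=True)
class SyntheticRun:
    """A generated trace together with its ground-truth interval sequence."""

    profile: StateProfile
    n_ipi: int
    seed: int
    true_ipi: np.ndarray
    trace: SignalTrace


def default_profiles() -> dict[SleepState, StateProfile]:
    """The three default state profiles.

    Innovation SDs are ordered REM (0.6) < AWAKE (1.0) < SWS (2.5) samples,
    encoding more predictable interval dynamics in conscious states; SWS
    additionally gets larger peak amplitudes (the slow-wave analogy).
    """
    base = dict(ipi_mean=12.0, ar_coeffs=(0.5, 0.2), ipi_skew=0.6,
                amplitude_sd=4.0, noise_sd=2.0)
    return {
        SleepState.REM: StateProfile(SleepState.REM, innovation_sd=0.6,
                                     amplitude_mean=40.0, **base),
        SleepState.AWAKE: StateProfile(SleepState.AWAKE, innovation_sd=1.0,
                                       amplitude_mean=40.0, **base),
        SleepState.SWS: StateProfile(SleepState.SWS, innovation_sd=2.5,
                                     amplitude_mean=75.0, slow_amp=150.0,
                                     slow_freq=0.05, **base),
    }


def _standardized_skewed_innovations(
    n: int, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-SD positively skewed innovations (shifted lognormal)."""
    if shape == 0.0:
        return rng.standard_normal(n)
    ln_mean = math.exp(shape**2 / 2.0)
    ln_sd = math.sqrt((math.exp(shape**2) - 1.0) * math.exp(shape**2))
    return (rng.lognormal(0.0, shape, size=n) - ln_mean) / ln_sd


def generate_ipi_sequence(
    profile: StateProfile, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Generate n integer intervals from the profile's AR(2) process.

    A 200-step burn-in removes the influence of the zero initial state.
    Intervals are rounded to integers and clipped to [2, round(3 * ipi_mean)]
    samples; the upper clip (hit with probability ~1e-4 under the default
    profiles) keeps extreme outliers from flattening the rendered arcs so
    far that a peak stops being a resolvable local maximum.
    """
    if n < 10:
        raise ValueError(f"need n >= 10 intervals, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p1, p2 = profile.ar_coeffs
    burn = 200
    eta = profile.innovation_sd * _standardized_skewed_innovations(
        n + burn, profile.ipi_skew, rng
    )
    x = np.zeros(n + burn)
    for t in range(2, n + burn):
        x[t] = p1 * x[t - 1] + p2 * x[t - 2] + eta[t]
    intervals = np.round(profile.ipi_mean + x[burn:]).astype(np.int64)
    return np.clip(intervals, 2, int(round(3 * profile.ipi_mean)))


def synthesize_signal(
    intervals: np.ndarray,
    profile: StateProfile,
    seed: int | np.random.Generator = 0,
) -> SignalTrace:
    """Render a peak-structured waveform realizing the given intervals.

    Peaks sit at cumulative interval positions, offset by a leading pad of
    ``ceil(ipi_mean)`` samples (mirrored at the end) so the first and last
    peaks are interior.  Between consecutive peaks the signal follows a
    raised-cosine arc from the left peak down to baseline and up to the
    right peak; the pads ramp from/to baseline with the matching half-arc.
    Peak heights are drawn from N(amplitude_mean, amplitude_sd^2) truncated
    below at 1 microvolt, and white measurement noise N(0, noise_sd^2) is
    added last.  Trace length = sum(intervals) + 1 + 2 * pad.
    """
    intervals = np.asarray(intervals, dtype=np.int64)
    if intervals.size == 0:
        raise ValueError("need at least one interval")
    if intervals.min() < 2:
        raise ValueError("intervals must be >= 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pad = int(math.ceil(profile.ipi_mean))
    peaks = pad + np.concatenate([[0], np.cumsum(intervals)])
    n_samples = int(peaks[-1]) + pad + 1
    amps = rng.normal(profile.amplitude_mean, profile.amplitude_sd, size=peaks.size)
    amps = np.maximum(amps, 1.0)

    x = np.zeros(n_samples)

    def arc(tau: np.ndarray) -> np.ndarray:
        # raised cosine: 1 at tau=0 and tau=1 (peaks), 0 at tau=0.5 (trough)
        return 0.5 * (1.0 + np.cos(2.0 * np.pi * tau))

    # leading ramp up to the first peak (second half of an arc)
    t = np.arange(0, pad + 1)
    x[: pad + 1] = amps[0] * arc(0.5 + 0.5 * t / pad)
    # interior arcs
    for i in range(peaks.size - 1):
        left, right = int(peaks[i]), int(peaks[i + 1])
        span = right - left
        t = np.arange(span + 1)
        tau = t / span
        heights = np.where(tau <= 0.5, amps[i], amps[i + 1])
        x[left : right + 1] = heights * arc(tau)
    # trailing ramp down from the last peak (first half of an arc)
    t = np.arange(0, pad + 1)
    x[int(peaks[-1]) :] = amps[-1] * arc(0.5 * t / pad)

    if profile.slow_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        tgrid = np.arange(n_samples) / 100.0
        x = x + profile.slow_amp * np.sin(2.0 * np.pi * profile.slow_freq * tgrid + phase)
    if profile.noise_sd > 0:
        x = x + rng.normal(0.0, profile.noise_sd, size=n_samples)
    return SignalTrace(x, fs=100.0, channel="synthetic", state=profile.name)


def generate_run(
    profile: StateProfile, n_ipi: int, seed: int = 0
) -> SyntheticRun:
    """Generate intervals and the corresponding trace from one seeded stream."""
    rng = np.random.default_rng(seed)
    intervals = generate_ipi_sequence(profile, n_ipi, rng)
    trace = synthesize_signal(intervals, profile, rng)
    return SyntheticRun(profile, n_ipi, seed, intervals, trace)
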