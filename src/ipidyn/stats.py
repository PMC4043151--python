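"""Error summaries, effect sizes, and spectral checks.

Prediction errors are compared across states on the natural log of the
absolute error (the absolute-error distributions are positively skewed, and
the log transform brings them close enough to normality for a t-test).
The two-sample test is Welch's (unequal variances); the effect size is
Cohen's d with the pooled standard deviation, signed as first group minus
second.  The spectral utilities estimate a Welch-averaged periodogram of
the *raw* trace, used to check where spectral mass sits (the slow 1-2 Hz
peak regime) and that the alpha band (7.5-12.5 Hz) is not driving results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .predictor import ErrorRecord
from .signal_io import SignalTrace

__all__ = [
    "ErrorSummary",
    "EffectSize",
    "SpectrumResult",
    "sample_skewness",
    "summarize_errors",
    "log_transform",
    "compare_states",
    "power_spectrum",
    "band_power_fraction",
    "alpha_band_power",
]

LOG_EPSILON = 1e-8
ALPHA_BAND = (7.5, 12.5)


@dataclass(frozen=True)
class ErrorSummary:
    """Moments and histogram of one condition's prediction errors.

    mean_abs/sd_abs are over absolute errors in sample units;
    skewness_signed is the moment skewness g1 of the signed errors.
    The histogram uses integer-width bins in sample units.
    """

    n: int
    mean_abs: float
    sd_abs: float
    mean_signed: float
    skewness_signed: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray


@dataclass(frozen=True)
class EffectSize:
    """Welch t-test and pooled-SD Cohen's d between two groups.

    Sign convention: positive d/t means the first group's mean is larger.
    """

    d: float
    t_stat: float
    p_value: float
    df: float
    group_labels: tuple[str, str]


@dataclass(frozen=True)
class SpectrumResult:
    """One-sided Welch power spectral density on a frequency grid in Hz."""

    freqs: np.ndarray
    power: np.ndarray
    fs: float


def sample_skewness(x: np.ndarray) -> float:
    """Moment skewness g1 = m3 / m2^1.5 (no small-sample correction)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("skewness needs at least 2 values")
    c = x - x.mean()
    m2 = np.mean(c * c)
    if m2 == 0:
        return 0.0
    return float(np.mean(c ** 3) / m2 ** 1.5)


def summarize_errors(errors: ErrorRecord) -> ErrorSummary:
    """Summary statistics of a test-set error record."""
    e = errors.signed_errors
    if e.size < 2:
        raise ValueError(f"need at least 2 errors to summarize, got {e.size}")
    a = np.abs(e)
    lo = np.floor(e.min())
    hi = np.ceil(e.max())
    edges = np.arange(lo, hi + 2.0)  # integer-width bins covering all errors
    counts, _ = np.histogram(e, bins=edges)
    return ErrorSummary(
        n=int(e.size),
        mean_abs=float(a.mean()),
        sd_abs=float(a.std(ddof=1)),
        mean_signed=float(e.mean()),
        skewness_signed=sample_skewness(e),
        hist_edges=edges,
        hist_counts=counts,
    )


def log_transform(abs_errors: np.ndarray) -> np.ndarray:
    """Natural log of |error| + epsilon (epsilon = 1e-8 guards exact zeros)."""
    a = np.asarray(abs_errors, dtype=float)
    if np.any(a < 0):
        raise ValueError("log_transform expects nonnegative (absolute) errors")
    return np.log(a + LOG_EPSILON)


def compare_states(
    a: np.ndarray,
    b: np.ndarray,
    labels: tuple[str, str] = ("a", "b"),
) -> EffectSize:
    """Welch two-sample t-test plus pooled-SD Cohen's d on transformed errors.

    d = (mean_a - mean_b) / s_pooled with
    s_pooled = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # identical constants: no effect by definition
            return EffectSize(0.0, 0.0, 1.0, float(a.size + b.size - 2), labels)
        raise ValueError("zero variance in both groups with unequal means")
    res = sp_stats.ttest_ind(a, b, equal_var=False)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    d = float((a.mean() - b.mean()) / pooled)
    return EffectSize(d, float(res.statistic), float(res.pvalue), float(res.df), labels)


def power_spectrum(trace: SignalTrace, *, max_nperseg: int = 4096) -> SpectrumResult:
    """Welch-averaged periodogram (Hann window, 50% overlap) of the raw trace.

    Segment length is min(max_nperseg, N).  Operates on the unsmoothed
    signal: smoothing is part of the peak measurement, not the spectrum.
    """
    x = trace.samples
    if x.size < 64:
        raise ValueError(f"spectrum needs at least 64 samples, got {x.size}")
    nperseg = min(max_nperseg, x.size)
    freqs, power = sp_signal.welch(
        x, fs=trace.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    return SpectrumResult(freqs, power, trace.fs)


def band_power_fraction(spectrum: SpectrumResult, lo: float, hi: float) -> float:
    """Fraction of total spectral power inside [lo, hi] Hz."""
    if not 0 <= lo < hi:
        raise ValueError(f"need 0 <= lo < hi, got [{lo}, {hi}]")
    if hi > spectrum.fs / 2:
        raise ValueError(
            f"band [{lo}, {hi}] Hz exceeds the Nyquist frequency {spectrum.fs / 2} Hz"
        )
    total = float(np.sum(spectrum.power))
    if total == 0:
        return 0.0
    # half-open [lo, hi) so adjacent bands partition the axis; Nyquist closes the top
    in_band = (spectrum.freqs >= lo) & (spectrum.freqs < hi)
    if hi == spectrum.fs / 2:
        in_band |= spectrum.freqs == hi
    return float(np.sum(spectrum.power[in_band]) / total)


def alpha_band_power(spectrum: SpectrumResult) -> float:
    """Fraction of total power in the alpha band (7.5-12.5 Hz)."""
    return band_power_fraction(spectrum, *ALPHA_BAND)
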