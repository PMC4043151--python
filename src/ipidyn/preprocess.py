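"""Smoothing, peak detection, and inter-peak-interval construction.

The measurement chain is: convolve the raw trace with a unit-sum Gaussian
kernel (sigma in samples) to suppress sharp high-frequency peaks, mark every
interior sample that is strictly greater than both immediate neighbours as a
local peak, and difference consecutive peak indices to obtain the inter-peak
interval (IPI) sequence in sample units (10 ms per sample at 100 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .signal_io import SignalTrace

__all__ = [
    "SmoothingConfig",
    "PeakSeries",
    "IPISeries",
    "gaussian_kernel",
    "gaussian_smooth",
    "detect_peaks",
    "compute_ipi",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Gaussian smoothing parameters.

    sigma is the kernel standard deviation in *samples* (default 1.0, i.e.
    a 10 ms scale at 100 Hz); truncation is the kernel half-width in
    multiples of sigma (default 4.0).
    """

    sigma: float = 1.0
    truncation: float = 4.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.truncation >= 1:
            raise ValueError(f"truncation must be >= 1, got {self.truncation}")

    @property
    def radius(self) -> int:
        """Kernel half-width in samples."""
        return int(math.ceil(self.truncation * self.sigma))


@dataclass(frozen=True)
class PeakSeries:
    """Strictly increasing sample indices of detected local maxima."""

    indices: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if idx.size and (idx[0] < 1 or idx[-1] > self.source_length - 2):
            raise ValueError("peak indices must be interior to the signal")
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class IPISeries:
    """Ordered inter-peak intervals in integer sample units.

    ``unit_ms`` converts samples to milliseconds at reporting time
    (10.0 ms per sample at 100 Hz); intervals themselves stay integral.
    """

    intervals: np.ndarray
    unit_ms: float = 10.0

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64)
        if iv.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if iv.size and iv.min() < 1:
            raise ValueError("every interval must be >= 1 sample")
        object.__setattr__(self, "intervals", iv)

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def intervals_ms(self) -> np.ndarray:
        return self.intervals * self.unit_ms


def gaussian_kernel(config: SmoothingConfig) -> np.ndarray:
    """The discrete unit-sum Gaussian kernel on offsets [-radius, radius]."""
    r = config.radius
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * (x / config.sigma) ** 2)
    return k / k.sum()


def gaussian_smooth(trace: SignalTrace, config: SmoothingConfig | None = None) -> SignalTrace:
    """Convolve a trace with a unit-sum Gaussian kernel (reflect padding).

    Returns a trace of the same length.  Reflect padding avoids the edge
    attenuation that zero padding would cause, which would otherwise create
    spurious boundary peaks.
    """
    config = config or SmoothingConfig()
    kernel_len = 2 * config.radius + 1
    if len(trace) <= kernel_len:
        raise ValueError(
            f"trace of length {len(trace)} is too short for a kernel of length {kernel_len}"
        )
    smoothed = gaussian_filter1d(
        trace.samples, sigma=config.sigma, mode="reflect", radius=config.radius
    )
    return trace.with_samples(smoothed)


def detect_peaks(trace: SignalTrace) -> PeakSeries:
    """Indices where the signal strictly exceeds both immediate neighbours.

    Endpoints are never peaks and plateau samples (equal to a neighbour)
    are not counted: a flat-topped peak yields no index rather than an
    arbitrary one.
    """
    x = trace.samples
    if x.size < 3:
        raise ValueError(f"peak detection needs at least 3 samples, got {x.size}")
    interior = (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])
    return PeakSeries(np.flatnonzero(interior) + 1, source_length=x.size)


def compute_ipi(peaks: PeakSeries, fs: float = 100.0) -> IPISeries:
    """Difference consecutive peak indices into an interval sequence.

    Needs at least two peaks; ``unit_ms = 1000 / fs``.
    """
    if len(peaks) < 2:
        raise ValueError(
            f"need at least 2 peaks to form intervals, got {len(peaks)}"
        )
    return IPISeries(np.diff(peaks.indices), unit_ms=1000.0 / fs)
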