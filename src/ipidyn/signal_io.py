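"""Reading and writing single-channel signal traces.

Two interchange formats are supported:

* **EDF** (European Data Format), the standard container for polysomnography
  recordings.  Reading goes through :mod:`mne` (an optional dependency);
  a minimal 16-bit EDF *writer* is provided so that traces can be exported
  to, and round-tripped through, the same format the source recordings use.
* **Plain one-column text**, one amplitude per line, ``#`` comments allowed.
  This is the lowest-common-denominator format the rest of the pipeline is
  guaranteed to run on.

Amplitudes are carried in microvolts throughout.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SleepState",
    "SignalTrace",
    "SignalIOError",
    "ChannelNotFoundError",
    "read_edf",
    "write_edf",
    "read_text",
    "write_text",
]


class SignalIOError(ValueError):
    """Raised for malformed, unreadable, or non-conforming signal files."""


class ChannelNotFoundError(SignalIOError):
    """Requested channel label is absent from the recording."""


class SleepState(str, Enum):
    """Behavioural state label attached to a trace.

    AWAKE and REM are treated as conscious states, SWS (slow-wave sleep)
    as the unconscious/less-conscious contrast condition.
    """

    AWAKE = "AWAKE"
    REM = "REM"
    SWS = "SWS"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples
        Signal amplitudes in microvolts. Must be finite and at least 2 long.
    fs
        Sampling rate in Hz (default 100, the rate of the sleep recordings
        this pipeline targets; one sample = 10 ms).
    channel
        Free-text channel label, e.g. ``"Fpz-Cz"``.
    state
        Sleep/wake state label.
    subject_id
        Free-text subject identifier.
    """

    samples: np.ndarray
    fs: float = 100.0
    channel: str = ""
    state: SleepState = SleepState.UNKNOWN
    subject_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if arr.size < 2:
            raise ValueError(f"a trace needs at least 2 samples, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValueError(f"non-finite sample at index {bad}; traces must be clean")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", arr)
        if isinstance(self.state, str) and not isinstance(self.state, SleepState):
            object.__setattr__(self, "state", SleepState(self.state))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "SignalTrace":
        return replace(self, samples=samples)


# ---------------------------------------------------------------------------
# plain text
# ---------------------------------------------------------------------------

def read_text(
    path: str | os.PathLike,
    fs: float = 100.0,
    *,
    channel: str = "",
    state: SleepState = SleepState.UNKNOWN,
    subject_id: str = "",
) -> SignalTrace:
    """Read a one-column text file of amplitudes into a :class:`SignalTrace`.

    Blank lines and lines starting with ``#`` are skipped.  The sampling
    rate is not stored in the file and must be supplied by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"no such file: {path}")
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise SignalIOError(
                    f"{path}: cannot parse {stripped!r} as a number at line {lineno}"
                ) from None
    if len(values) < 2:
        raise SignalIOError(f"{path}: needs at least 2 numeric samples, found {len(values)}")
    return SignalTrace(np.array(values), fs=fs, channel=channel, state=state,
                       subject_id=subject_id)


def write_text(trace: SignalTrace, path: str | os.PathLike) -> None:
    """Write a trace as one value per line, with a small ``#`` metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# channel={trace.channel} fs={trace.fs:g} state={trace.state.value}"
                 f" subject={trace.subject_id}\n")
        for v in trace.samples:
            fh.write(f"{v:.12g}\n")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    """Fixed-width ASCII field, left-justified, as the EDF header requires."""
    s = str(value)
    if len(s) > width:
        raise SignalIOError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(
    traces: Sequence[SignalTrace],
    path: str | os.PathLike,
    *,
    physical_dim: str = "uV",
) -> None:
    """Write one or more equal-length, equal-rate traces as a minimal EDF file.

    All samples are stored in a single data record of the full trace
    duration, quantized to 16-bit integers over each channel's physical
    range — the quantization step is ``(phys_max - phys_min) / 65535``.
    Channel labels come from ``trace.channel``.
    """
    if not traces:
        raise SignalIOError("write_edf needs at least one trace")
    n = len(traces[0])
    fs = traces[0].fs
    for t in traces:
        if len(t) != n or t.fs != fs:
            raise SignalIOError("all channels must share length and sampling rate")
    ns = len(traces)
    duration = n / fs

    header = bytearray()
    header += _edf_field("0", 8)                      # version
    header += _edf_field("X X X X", 80)               # patient id
    header += _edf_field("Startdate X", 80)           # recording id
    header += _edf_field("01.01.00", 8)               # start date
    header += _edf_field("00.00.00", 8)               # start time
    header += _edf_field(str(256 * (1 + ns)), 8)      # header bytes
    header += _edf_field("", 44)                      # reserved
    header += _edf_field("1", 8)                      # number of data records
    header += _edf_field(f"{duration:.6g}", 8)        # record duration (s)
    header += _edf_field(str(ns), 4)                  # number of signals

    digitized: list[np.ndarray] = []
    phys: list[tuple[float, float]] = []
    for t in traces:
        lo = float(np.min(t.samples))
        hi = float(np.max(t.samples))
        if hi == lo:                                   # constant channel: widen range
            hi = lo + 1.0
        phys.append((lo, hi))
        scale = (hi - lo) / 65535.0
        dig = np.round((t.samples - lo) / scale).astype(np.int64) - 32768
        digitized.append(np.clip(dig, -32768, 32767).astype("<i2"))

    for t in traces:
        header += _edf_field(t.channel or "chan", 16)
    for _ in traces:
        header += _edf_field("", 80)                  # transducer
    for _ in traces:
        header += _edf_field(physical_dim, 8)
    for lo, hi in phys:
        header += _edf_field(f"{lo:.6g}", 8)
    for lo, hi in phys:
        header += _edf_field(f"{hi:.6g}", 8)
    for _ in traces:
        header += _edf_field("-32768", 8)
    for _ in traces:
        header += _edf_field("32767", 8)
    for _ in traces:
        header += _edf_field("", 80)                  # prefiltering
    for _ in traces:
        header += _edf_field(str(n), 8)               # samples per record
    for _ in traces:
        header += _edf_field("", 32)                  # reserved

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for dig in digitized:
            fh.write(dig.tobytes())


def read_edf(
    path: str | os.PathLike,
    channel: str,
    *,
    state: SleepState = SleepState.UNKNOWN,
    subject_id: str = "",
) -> SignalTrace:
    """Read one channel of an EDF recording into a :class:`SignalTrace`.

    The sampling rate is taken from the EDF header. Amplitudes are returned
    in microvolts. Requires :mod:`mne` (install the ``edf`` extra).

    Raises
    ------
    ChannelNotFoundError
        If ``channel`` is absent; the message lists the available channels.
    SignalIOError
        For missing or malformed files, or non-finite samples.
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"no such file: {path}")
    try:
        import mne  # noqa: deferred, optional dependency
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "EDF reading requires mne; install with `pip install ipidyn[edf]`"
        ) from exc
    try:
        raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    except Exception as exc:
        raise SignalIOError(f"{path}: not a readable EDF file ({exc})") from exc
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in {path.name}; available: "
            + ", ".join(repr(c) for c in raw.ch_names)
        )
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    try:
        data = raw.get_data(picks=[channel], units="uV")[0]
    except (ValueError, TypeError):
        # channels without a voltage unit (e.g. annotations misc): take raw values
        data = raw.get_data(picks=[channel])[0]
    fs = float(raw.info["sfreq"])
    if not np.all(np.isfinite(data)):
        raise SignalIOError(f"{path}: channel {channel!r} contains non-finite samples")
    return SignalTrace(np.asarray(data, dtype=float), fs=fs, channel=channel,
                       state=state, subject_id=subject_id)
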