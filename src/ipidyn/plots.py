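"""Optional figure rendering for run results.

Four standard panels per run: per-state error bars (mean +/- SD of the
absolute test error), error distributions on a log frequency axis,
raw-trace power spectra, and interval distributions.  All functions take
computed objects and write a PNG; nothing here recomputes statistics.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import RunResult
from .signal_io import SignalTrace
from .stats import SpectrumResult

STATE_COLORS = {"AWAKE": "tab:red", "REM": "tab:blue", "SWS": "tab:green",
                "UNKNOWN": "tab:gray"}


def plot_error_bars(result: RunResult, path: str | Path) -> None:
    """Mean +/- SD of absolute test error per (subject, state), in 10 ms units."""
    fig, ax = plt.subplots(figsize=(6, 4))
    labels, means, sds, colors = [], [], [], []
    for r in result.per_input:
        labels.append(f"{r.subject_id}\n{r.state.value}")
        means.append(r.summary.mean_abs)
        sds.append(r.summary.sd_abs)
        colors.append(STATE_COLORS[r.state.value])
    ax.bar(range(len(labels)), means, yerr=sds, color=colors, capsize=3)
    ax.set_xticks(range(len(labels)), labels, fontsize=8)
    ax.set_ylabel("IPI prediction error (unit: 10 ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_error_distributions(result: RunResult, path: str | Path) -> None:
    """Signed-error histograms, log-scaled y to expose the tails."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for r in result.per_input:
        centers = (r.summary.hist_edges[:-1] + r.summary.hist_edges[1:]) / 2
        ax.plot(centers, np.maximum(r.summary.hist_counts, 0.5),
                color=STATE_COLORS[r.state.value],
                label=f"{r.subject_id}/{r.state.value}")
    ax.set_yscale("log")
    ax.set_xlabel("signed error (unit: 10 ms)")
    ax.set_ylabel("count")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectrum(spectra: dict[str, SpectrumResult], path: str | Path) -> None:
    """Welch power spectra of raw traces, one line per label."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, spec in spectra.items():
        state = label.split("/")[-1]
        ax.plot(spec.freqs, spec.power, label=label,
                color=STATE_COLORS.get(state, None))
    ax.set_xlim(0, 20)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power spectral density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ipi_distributions(result: RunResult, path: str | Path) -> None:
    """Interval histograms per input (positively skewed in real data)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for r in result.per_input:
        iv = r.ipi.intervals
        edges = np.arange(iv.min() - 0.5, iv.max() + 1.5)
        counts, _ = np.histogram(iv, bins=edges)
        ax.plot((edges[:-1] + edges[1:]) / 2, counts,
                color=STATE_COLORS[r.state.value],
                label=f"{r.subject_id}/{r.state.value}")
    ax.set_xlabel("inter-peak interval (unit: 10 ms)")
    ax.set_ylabel("count")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
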