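"""End-to-end orchestration: load/generate -> smooth -> peaks -> IPI ->
split -> train -> evaluate -> statistics -> report.

A run processes a grid of (subject, state) inputs — each either a file on
disk or a synthetic state profile — trains one network per input, and
compares states pairwise within each subject on log-transformed absolute
test errors.  Everything is deterministic given the run seed; per-input
seeds are derived from it with :class:`numpy.random.SeedSequence` so adding
or reordering inputs does not perturb other inputs' streams.

Reports are plain tab-separated tables written with fixed float formatting,
so identical configurations and seeds produce byte-identical files.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import yaml

from . import __version__
from .preprocess import (IPISeries, SmoothingConfig, compute_ipi, detect_peaks,
                         gaussian_smooth)
from .predictor import (ErrorRecord, MLPModel, Split, TrainingConfig, WindowConfig,
                        evaluate, make_windowed, save_model, split_series, train_lm)
from .signal_io import SignalTrace, SleepState, read_edf, read_text
from .stats import (EffectSize, ErrorSummary, compare_states, log_transform,
                    summarize_errors)
from .synthetic import StateProfile, default_profiles, generate_run

__all__ = [
    "InputSpec",
    "RunConfig",
    "RunResult",
    "ConfigError",
    "run",
    "validate_config",
    "load_config",
    "write_report",
]

logger = logging.getLogger("ipidyn")

PredictionMode = ("IPI", "RAW")


class ConfigError(ValueError):
    """Invalid run configuration; message lists every violation found."""


@dataclass(frozen=True)
class InputSpec:
    """One (subject, state) input: a file path or a synthetic profile name."""

    subject_id: str
    state: SleepState
    path: str | None = None          # EDF or text file; None => synthetic
    channel: str = "Fpz-Cz"          # EDF channel (ignored for text/synthetic)
    fs: float = 100.0                # sampling rate for text files
    n_ipi: int = 3000                # synthetic interval count


@dataclass
class RunConfig:
    """Full configuration of a pipeline run."""

    inputs: list[InputSpec]
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    output_dir: str | None = None
    seed: int = 0
    mode: str = "IPI"

    def __post_init__(self) -> None:
        problems = []
        if self.mode not in PredictionMode:
            problems.append(f"mode must be one of {PredictionMode}, got {self.mode!r}")
        states = {i.state for i in self.inputs}
        if len(states) < 2:
            problems.append(
                "need inputs from at least 2 states for a comparison, got "
                + (", ".join(s.value for s in states) or "none")
            )
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class SubjectStateResult:
    """Everything computed for one (subject, state) input."""

    subject_id: str
    state: SleepState
    n_peaks: int
    ipi: IPISeries
    summary: ErrorSummary
    errors: ErrorRecord
    model: MLPModel
    stop_reason: str
    epochs: int


@dataclass
class RunResult:
    """Per-input summaries plus pairwise within-subject effect sizes."""

    per_input: list[SubjectStateResult]
    pairwise: list[tuple[str, EffectSize]]   # (subject_id, effect)
    failures: list[tuple[str, str, str]]     # (subject, stage, message)
    provenance: dict[str, Any]


# ---------------------------------------------------------------------------
# configuration parsing
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, set[str]] = {
    "": {"inputs", "smoothing", "window", "training", "output_dir", "seed", "mode"},
    "smoothing": {"sigma", "truncation"},
    "window": {"k", "normalize"},
    "training": {"lambda0", "lambda_decrease", "lambda_increase", "max_epochs",
                 "patience", "lambda_max", "hidden_units", "seed"},
    "inputs[]": {"subject_id", "state", "path", "channel", "fs", "n_ipi"},
}


def _check_keys(mapping: dict, section: str, errors: list[str]) -> None:
    allowed = _SCHEMA[section]
    for key in mapping:
        if key not in allowed:
            hint = ""
            dotted = [f"{sec.rstrip('[]')}.{k}" for sec, keys in _SCHEMA.items()
                      if sec for k in keys]
            # prefer a fully qualified suggestion (e.g. "smoothing.sigma")
            close = (difflib.get_close_matches(key, dotted, n=1)
                     or difflib.get_close_matches(key, list(allowed), n=1))
            if close:
                hint = f" (did you mean {close[0]!r}?)"
            where = section or "top level"
            errors.append(f"unknown key {key!r} in {where}{hint}")


def validate_config(raw: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed mapping, or raise with every
    violation found (unknown keys are rejected for typo safety)."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration must be a mapping, got {type(raw).__name__}")
    _check_keys(raw, "", errors)
    for section in ("smoothing", "window", "training"):
        sub = raw.get(section, {})
        if isinstance(sub, dict):
            _check_keys(sub, section, errors)
        else:
            errors.append(f"{section} must be a mapping")

    inputs: list[InputSpec] = []
    for i, item in enumerate(raw.get("inputs", []) or []):
        if not isinstance(item, dict):
            errors.append(f"inputs[{i}] must be a mapping")
            continue
        _check_keys(item, "inputs[]", errors)
        try:
            state = SleepState(str(item.get("state", "UNKNOWN")).upper())
        except ValueError:
            errors.append(
                f"inputs[{i}].state must be one of AWAKE/REM/SWS/UNKNOWN, "
                f"got {item.get('state')!r}"
            )
            continue
        inputs.append(InputSpec(
            subject_id=str(item.get("subject_id", f"s{i}")),
            state=state,
            path=item.get("path"),
            channel=str(item.get("channel", "Fpz-Cz")),
            fs=float(item.get("fs", 100.0)),
            n_ipi=int(item.get("n_ipi", 3000)),
        ))
    if not inputs:
        errors.append("inputs: at least two (subject, state) entries are required")

    def build(cls, section):
        try:
            return cls(**raw.get(section, {}))
        except (TypeError, ValueError) as exc:
            errors.append(f"{section}: {exc} (in {cls.__name__})")
            return cls()

    smoothing = build(SmoothingConfig, "smoothing")
    window = build(WindowConfig, "window")
    training = build(TrainingConfig, "training")
    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(
        inputs=inputs,
        smoothing=smoothing,
        window=window,
        training=training,
        output_dir=raw.get("output_dir"),
        seed=int(raw.get("seed", 0)),
        mode=str(raw.get("mode", "IPI")).upper(),
    )


def load_config(path: str | os.PathLike) -> RunConfig:
    """Parse a YAML configuration file into a validated :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw or {})


# ---------------------------------------------------------------------------
# the run itself
# ---------------------------------------------------------------------------

def _load_trace(spec: InputSpec, seed: int) -> tuple[SignalTrace, np.ndarray | None]:
    """Load an input trace from disk or synthesize one; returns (trace, truth)."""
    if spec.path is None:
        profile = default_profiles()[spec.state]
        run_ = generate_run(profile, spec.n_ipi, seed=seed)
        return run_.trace, run_.true_ipi
    p = Path(spec.path)
    if p.suffix.lower() == ".edf":
        return read_edf(p, spec.channel, state=spec.state,
                        subject_id=spec.subject_id), None
    return read_text(p, fs=spec.fs, state=spec.state,
                     subject_id=spec.subject_id), None


def _process_input(
    spec: InputSpec, config: RunConfig, seed: int
) -> SubjectStateResult:
    trace, _truth = _load_trace(spec, seed)
    logger.info("[%s/%s] loaded %d samples at %g Hz",
                spec.subject_id, spec.state.value, len(trace), trace.fs)
    smoothed = gaussian_smooth(trace, config.smoothing)
    if config.mode == "IPI":
        peaks = detect_peaks(smoothed)
        ipi = compute_ipi(peaks, fs=trace.fs)
        series = ipi.intervals.astype(float)
        n_peaks = len(peaks)
        logger.info("[%s/%s] %d peaks -> %d intervals",
                    spec.subject_id, spec.state.value, n_peaks, len(ipi))
    else:  # RAW: exploratory direct prediction of the smoothed waveform
        series = smoothed.samples
        ipi = IPISeries(np.ones(2, dtype=np.int64), unit_ms=1000.0 / trace.fs)
        n_peaks = 0
    data = make_windowed(series, config.window)
    counts = data.counts()
    logger.info("[%s/%s] pairs: %s", spec.subject_id, spec.state.value, counts)
    tcfg = TrainingConfig(**{**_training_kwargs(config.training), "seed": seed})
    model, trace_ = train_lm(data, tcfg)
    logger.info("[%s/%s] trained %d epochs (stop: %s)",
                spec.subject_id, spec.state.value, trace_.epochs, trace_.stop_reason)
    errors = evaluate(model, data, Split.TEST)
    return SubjectStateResult(
        subject_id=spec.subject_id,
        state=spec.state,
        n_peaks=n_peaks,
        ipi=ipi,
        summary=summarize_errors(errors),
        errors=errors,
        model=model,
        stop_reason=trace_.stop_reason,
        epochs=trace_.epochs,
    )


def _training_kwargs(t: TrainingConfig) -> dict:
    return {f: getattr(t, f) for f in t.__dataclass_fields__}


def _config_digest(config: RunConfig) -> str:
    payload = {
        "inputs": [asdict(i) for i in config.inputs],
        "smoothing": asdict(config.smoothing),
        "window": asdict(config.window),
        "training": _training_kwargs(config.training),
        "seed": config.seed,
        "mode": config.mode,
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline over every configured input.

    One network is trained per (subject, state) input.  A failing input is
    recorded with its stage and message; remaining inputs still run.
    States are compared pairwise within each subject on log|test error|.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.inputs))
    per_input: list[SubjectStateResult] = []
    failures: list[tuple[str, str, str]] = []
    for spec, seq in zip(config.inputs, seeds):
        child_seed = int(seq.generate_state(1)[0] % (2**31))
        try:
            per_input.append(_process_input(spec, config, child_seed))
        except Exception as exc:  # collected, not fatal
            stage = type(exc).__name__
            failures.append((f"{spec.subject_id}/{spec.state.value}", stage, str(exc)))
            logger.error("[%s/%s] failed: %s", spec.subject_id, spec.state.value, exc)

    pairwise: list[tuple[str, EffectSize]] = []
    by_subject: dict[str, list[SubjectStateResult]] = {}
    for res in per_input:
        by_subject.setdefault(res.subject_id, []).append(res)
    order = {SleepState.REM: 0, SleepState.AWAKE: 1, SleepState.SWS: 2,
             SleepState.UNKNOWN: 3}
    for subject, results in by_subject.items():
        results = sorted(results, key=lambda r: order[r.state])
        for i in range(len(results)):
            for j in range(i + 1, len(results)):
                a, b = results[i], results[j]
                eff = compare_states(
                    log_transform(a.errors.abs_errors),
                    log_transform(b.errors.abs_errors),
                    labels=(a.state.value, b.state.value),
                )
                pairwise.append((subject, eff))

    provenance = {
        "config_digest": _config_digest(config),
        "seed": config.seed,
        "version": __version__,
        "mode": config.mode,
    }
    result = RunResult(per_input, pairwise, failures, provenance)
    if config.output_dir is not None:
        write_report(result, config, Path(config.output_dir))
    return result


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def write_report(result: RunResult, config: RunConfig, outdir: Path) -> None:
    """Write summary/effects tables, per-input models and provenance.

    All numbers use fixed formats so identical runs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lines = ["subject\tstate\tn_peaks\tn_errors\tmean_abs\tsd_abs\tmean_signed"
             "\tskewness_signed\tepochs\tstop_reason"]
    for r in result.per_input:
        s = r.summary
        lines.append(
            f"{r.subject_id}\t{r.state.value}\t{r.n_peaks}\t{s.n}"
            f"\t{s.mean_abs:.6f}\t{s.sd_abs:.6f}\t{s.mean_signed:.6f}"
            f"\t{s.skewness_signed:.6f}\t{r.epochs}\t{r.stop_reason}"
        )
    (outdir / "state_summaries.tsv").write_text("\n".join(lines) + "\n")

    lines = ["# pairwise Welch t-tests on log|error|; d = Cohen's d (pooled SD),",
             "# sign: first state minus second; p-values are NOT corrected for",
             "# multiple comparisons across state pairs",
             "subject\tstate_a\tstate_b\td\tt_stat\tp_value\tdf"]
    for subject, eff in result.pairwise:
        lines.append(
            f"{subject}\t{eff.group_labels[0]}\t{eff.group_labels[1]}"
            f"\t{eff.d:.6f}\t{eff.t_stat:.6f}\t{eff.p_value:.6e}\t{eff.df:.2f}"
        )
    if config.mode == "RAW":
        lines.insert(0, "# RAW mode is exploratory: direct waveform prediction "
                        "carries no claims here")
    (outdir / "effect_sizes.tsv").write_text("\n".join(lines) + "\n")

    for r in result.per_input:
        save_model(r.model, outdir / f"model_{r.subject_id}_{r.state.value}.json")

    if result.failures:
        flines = ["input\tstage\tmessage"]
        flines += [f"{a}\t{b}\t{c}" for a, b, c in result.failures]
        (outdir / "failures.tsv").write_text("\n".join(flines) + "\n")

    (outdir / "provenance.json").write_text(
        json.dumps(result.provenance, indent=1, sort_keys=True) + "\n"
    )
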