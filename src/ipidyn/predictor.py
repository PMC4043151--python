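"""One-step-ahead interval prediction with a small LM-trained MLP.

An interval series is traversed with a sliding window of k past values
(k = 10 by default); the value immediately after each window is the target.
Pairs are tagged chronologically into training (60%), validation (15%) and
test (25%) splits — chronological rather than shuffled, because adjacent
windows share k-1 of their k values and a random split would leak test
information into training.

The predictor is a feed-forward network with k inputs, H tanh hidden units
(H = 10) and one linear output, trained by full-batch Levenberg–Marquardt
on the training sum of squared errors.  The damping parameter lambda
interpolates between Gauss–Newton (small lambda) and small-step gradient
descent (large lambda): a step that reduces the training SSE is accepted
and lambda shrinks by the decrease factor; a rejected step grows lambda by
the increase factor and the step is retried within the same epoch.
Early stopping monitors the validation error with a patience counter and
the returned weights are those with the best validation error seen.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .preprocess import IPISeries

__all__ = [
    "Split",
    "WindowConfig",
    "WindowedDataset",
    "MLPModel",
    "TrainingConfig",
    "TrainingTrace",
    "ErrorRecord",
    "split_series",
    "window_pairs",
    "make_windowed",
    "train_lm",
    "evaluate",
    "save_model",
    "load_model",
]


class Split(str, Enum):
    TRAIN = "TRAIN"
    VAL = "VAL"
    TEST = "TEST"


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window parameters: k past values predict the next one.

    With ``normalize`` (default), inputs and targets are z-scored with the
    mean/SD of the *training* portion only; raw interval magnitudes
    (~10-15 samples) are otherwise ill-conditioned for tanh hidden units.
    """

    k: int = 10
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"window length k must be >= 1, got {self.k}")


@dataclass(frozen=True)
class WindowedDataset:
    """(k-lag input, next value) pairs with chronological split tags.

    ``inputs``/``targets`` hold the raw (unnormalized) series values;
    ``norm_stats`` is the (mean, sd) computed from TRAIN pairs, applied at
    training/prediction time when normalization is on.
    """

    inputs: np.ndarray          # (n_pairs, k)
    targets: np.ndarray         # (n_pairs,)
    split: np.ndarray           # (n_pairs,) of split-tag strings "TRAIN"/"VAL"/"TEST"
    norm_stats: tuple[float, float]
    normalize: bool = True

    def mask(self, which: Split) -> np.ndarray:
        return self.split == which.value

    def pairs(self, which: Split) -> tuple[np.ndarray, np.ndarray]:
        m = self.mask(which)
        return self.inputs[m], self.targets[m]

    def counts(self) -> dict[str, int]:
        return {s.value: int(np.sum(self.split == s.value)) for s in Split}


@dataclass
class MLPModel:
    """k-H-1 feed-forward network: tanh hidden layer, linear output."""

    weights_ih: np.ndarray      # (k, H)
    bias_h: np.ndarray          # (H,)
    weights_ho: np.ndarray      # (H,)
    bias_o: float

    def __post_init__(self) -> None:
        for arr in (self.weights_ih, self.bias_h, self.weights_ho):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model weights must be finite")
        if not np.isfinite(self.bias_o):
            raise ValueError("model weights must be finite")

    @property
    def k(self) -> int:
        return self.weights_ih.shape[0]

    @property
    def hidden_units(self) -> int:
        return self.weights_ih.shape[1]

    @property
    def n_params(self) -> int:
        return self.k * self.hidden_units + 2 * self.hidden_units + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Predict one value per row of the (n, k) input matrix."""
        h = np.tanh(x @ self.weights_ih + self.bias_h)
        return h @ self.weights_ho + self.bias_o

    # -- flat parameter vector <-> structured weights ----------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.weights_ih.ravel(), self.bias_h, self.weights_ho, [self.bias_o]]
        )

    @classmethod
    def from_vector(cls, theta: np.ndarray, k: int, hidden: int) -> "MLPModel":
        ih = theta[: k * hidden].reshape(k, hidden)
        bh = theta[k * hidden : k * hidden + hidden]
        ho = theta[k * hidden + hidden : k * hidden + 2 * hidden]
        bo = float(theta[-1])
        return cls(ih.copy(), bh.copy(), ho.copy(), bo)

    @classmethod
    def init_random(cls, k: int, hidden: int, rng: np.random.Generator) -> "MLPModel":
        # uniform in [-0.5, 0.5] scaled by 1/sqrt(fan-in)
        ih = rng.uniform(-0.5, 0.5, size=(k, hidden)) / np.sqrt(k)
        bh = rng.uniform(-0.5, 0.5, size=hidden) / np.sqrt(k)
        ho = rng.uniform(-0.5, 0.5, size=hidden) / np.sqrt(hidden)
        bo = float(rng.uniform(-0.5, 0.5)) / np.sqrt(hidden)
        return cls(ih, bh, ho, bo)


@dataclass(frozen=True)
class TrainingConfig:
    """Levenberg–Marquardt schedule and stopping rules.

    lambda0 = 0.001 with decrease factor 0.1 on an accepted step and
    increase factor 10 on a rejected one.  Training stops after ``patience``
    consecutive epochs without validation improvement, at ``max_epochs``,
    or when lambda exceeds ``lambda_max`` without finding a downhill step.
    """

    lambda0: float = 1e-3
    lambda_decrease: float = 0.1
    lambda_increase: float = 10.0
    max_epochs: int = 1000
    patience: int = 6
    lambda_max: float = 1e10
    hidden_units: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lambda_decrease < 1 < self.lambda_increase):
            raise ValueError("need 0 < lambda_decrease < 1 < lambda_increase")
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be positive")
        if self.hidden_units < 1:
            raise ValueError("need at least one hidden unit")


@dataclass
class TrainingTrace:
    """Per-epoch diagnostics of an LM run."""

    train_sse: list[float] = field(default_factory=list)     # accepted steps only
    val_sse: list[float] = field(default_factory=list)
    lambdas: list[float] = field(default_factory=list)        # lambda after each epoch
    attempted_lambdas: list[list[float]] = field(default_factory=list)
    epochs: int = 0
    stop_reason: str = ""


@dataclass(frozen=True)
class ErrorRecord:
    """Signed test-set prediction errors (true - predicted) in sample units."""

    signed_errors: np.ndarray

    @property
    def abs_errors(self) -> np.ndarray:
        return np.abs(self.signed_errors)

    def __len__(self) -> int:
        return self.signed_errors.size


# ---------------------------------------------------------------------------
# windowing and splits
# ---------------------------------------------------------------------------

def window_pairs(series: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Slide a window of length k over the series.

    Returns (inputs, targets): inputs[i] holds the k values preceding
    targets[i]; the pair count is ``len(series) - k``.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= k:
        raise ValueError(f"series of length {x.size} yields no pairs for k={k}")
    idx = np.arange(x.size - k)[:, None] + np.arange(k)[None, :]
    return x[idx], x[k:]


def make_windowed(series: np.ndarray, config: WindowConfig | None = None) -> WindowedDataset:
    """Build a windowed dataset from any 1-D numeric series.

    Pairs are formed over the whole series (pair count = len(series) - k),
    then tagged chronologically: the first 60% TRAIN, the next 15% VAL and
    the remainder (~25%) TEST, with TRAIN/VAL counts rounded down.
    """
    config = config or WindowConfig()
    x = np.asarray(series, dtype=float)
    k = config.k
    n_pairs = x.size - k
    if n_pairs < 4:
        raise ValueError(
            f"series of length {x.size} is too short: need at least {k + 4} values "
            f"for k={k} (one pair per split)"
        )
    inputs, targets = window_pairs(x, k)

    n_train = int(n_pairs * 0.60)
    n_val = int(n_pairs * 0.15)
    n_train = max(n_train, 1)
    n_val = max(n_val, 1)
    if n_train + n_val >= n_pairs:
        raise ValueError(f"series too short to leave a test split ({n_pairs} pairs)")
    split = np.empty(n_pairs, dtype="<U5")
    split[:n_train] = Split.TRAIN.value
    split[n_train : n_train + n_val] = Split.VAL.value
    split[n_train + n_val :] = Split.TEST.value

    train_vals = np.concatenate([inputs[:n_train].ravel(), targets[:n_train]])
    mean = float(np.mean(train_vals))
    sd = float(np.std(train_vals))
    if sd == 0.0:
        sd = 1.0  # constant training series: normalization becomes centering
    return WindowedDataset(inputs, targets, split, (mean, sd), normalize=config.normalize)


def split_series(ipi: IPISeries, config: WindowConfig | None = None) -> WindowedDataset:
    """Windowed one-step-prediction dataset from an interval series."""
    return make_windowed(ipi.intervals.astype(float), config)


# ---------------------------------------------------------------------------
# Levenberg–Marquardt training
# ---------------------------------------------------------------------------

def _jacobian(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Jacobian of the network output w.r.t. the flat parameter vector.

    Rows are samples; column order matches :meth:`MLPModel.to_vector`.
    """
    n, k = x.shape
    hpre = x @ model.weights_ih + model.bias_h
    h = np.tanh(hpre)
    dh = (1.0 - h * h) * model.weights_ho          # (n, H): dy/dhpre
    j_ih = x[:, :, None] * dh[:, None, :]          # (n, k, H)
    return np.concatenate(
        [j_ih.reshape(n, k * model.hidden_units), dh, h, np.ones((n, 1))], axis=1
    )


def _norm(dataset: WindowedDataset, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if not dataset.normalize:
        return x, y
    mean, sd = dataset.norm_stats
    return (x - mean) / sd, (y - mean) / sd


def train_lm(
    data: WindowedDataset,
    tconfig: TrainingConfig | None = None,
) -> tuple[MLPModel, TrainingTrace]:
    """Train the MLP by full-batch Levenberg–Marquardt on the TRAIN split.

    Each epoch linearizes the residuals r = y - yhat around the current
    weights and solves (J'J + lambda I) delta = J'r.  A step that lowers
    the training SSE is accepted (lambda *= lambda_decrease); otherwise
    lambda *= lambda_increase and the step is re-solved, up to lambda_max.
    Returns the weights with the best validation SSE and a diagnostics trace.
    """
    tconfig = tconfig or TrainingConfig()
    x_tr, y_tr = data.pairs(Split.TRAIN)
    x_va, y_va = data.pairs(Split.VAL)
    if x_tr.shape[0] < 10:
        raise ValueError(f"need at least 10 training pairs, got {x_tr.shape[0]}")
    if x_va.shape[0] < 1:
        raise ValueError("validation split is empty")
    x_tr, y_tr = _norm(data, x_tr, y_tr)
    x_va, y_va = _norm(data, x_va, y_va)

    rng = np.random.default_rng(tconfig.seed)
    k = x_tr.shape[1]
    model = MLPModel.init_random(k, tconfig.hidden_units, rng)
    theta = model.to_vector()
    n_params = theta.size
    eye = np.eye(n_params)

    def sse(th: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
        m = MLPModel.from_vector(th, k, tconfig.hidden_units)
        r = y - m.forward(x)
        return float(r @ r)

    lam = tconfig.lambda0
    current_sse = sse(theta, x_tr, y_tr)
    if not np.isfinite(current_sse):
        raise FloatingPointError("non-finite training loss at initialization")

    trace = TrainingTrace()
    best_val = sse(theta, x_va, y_va)
    best_theta = theta.copy()
    fails = 0
    stop = ""

    for epoch in range(tconfig.max_epochs):
        m = MLPModel.from_vector(theta, k, tconfig.hidden_units)
        r = y_tr - m.forward(x_tr)
        jac = _jacobian(m, x_tr)
        jtj = jac.T @ jac
        jtr = jac.T @ r

        attempted: list[float] = []
        accepted = False
        while lam <= tconfig.lambda_max:
            attempted.append(lam)
            try:
                delta = np.linalg.solve(jtj + lam * eye, jtr)
            except np.linalg.LinAlgError:
                lam *= tconfig.lambda_increase
                continue
            cand = theta + delta
            cand_sse = sse(cand, x_tr, y_tr)
            if not np.isfinite(cand_sse):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (lambda={lam:g})"
                )
            if cand_sse < current_sse:
                theta = cand
                current_sse = cand_sse
                lam *= tconfig.lambda_decrease
                accepted = True
                break
            lam *= tconfig.lambda_increase
        trace.attempted_lambdas.append(attempted)

        if not accepted:
            stop = "lambda_max"
            break

        val_sse = sse(theta, x_va, y_va)
        trace.train_sse.append(current_sse)
        trace.val_sse.append(val_sse)
        trace.lambdas.append(lam)
        trace.epochs = epoch + 1
        if val_sse < best_val:
            best_val = val_sse
            best_theta = theta.copy()
            fails = 0
        else:
            fails += 1
            if fails >= tconfig.patience:
                stop = "patience"
                break
    else:
        stop = "max_epochs"

    trace.stop_reason = stop or "max_epochs"
    return MLPModel.from_vector(best_theta, k, tconfig.hidden_units), trace


def evaluate(model: MLPModel, data: WindowedDataset, which: Split = Split.TEST) -> ErrorRecord:
    """Signed errors (true - predicted) on held-out pairs, in sample units.

    Predictions are de-normalized back to raw series units before the
    error is taken, so errors are directly interpretable as interval
    samples (10 ms each at 100 Hz).
    """
    x, y = data.pairs(which)
    if x.shape[0] == 0:
        raise ValueError(f"no {which.value} pairs to evaluate")
    if data.normalize:
        mean, sd = data.norm_stats
        yhat = model.forward((x - mean) / sd) * sd + mean
    else:
        yhat = model.forward(x)
    return ErrorRecord(y - yhat)


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def save_model(model: MLPModel, path: str | os.PathLike) -> None:
    """Serialize weights to a plain JSON file (shapes + flat lists)."""
    payload = {
        "k": model.k,
        "hidden_units": model.hidden_units,
        "weights_ih": model.weights_ih.ravel().tolist(),
        "bias_h": model.bias_h.tolist(),
        "weights_ho": model.weights_ho.tolist(),
        "bias_o": model.bias_o,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_model(path: str | os.PathLike) -> MLPModel:
    payload = json.loads(Path(path).read_text())
    k, hidden = payload["k"], payload["hidden_units"]
    return MLPModel(
        np.array(payload["weights_ih"], dtype=float).reshape(k, hidden),
        np.array(payload["bias_h"], dtype=float),
        np.array(payload["weights_ho"], dtype=float),
        float(payload["bias_o"]),
    )
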