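"""Reversible nonlinear dimension reduction of activation trajectories.

An auto-associative (bottleneck) network with architecture
``n -> c -> y -> c -> n`` — n the flattened trajectory length, c the
codification-layer width and y the bottleneck width — is trained to reproduce
its own input. The y bottleneck activations of each molecule are its learned
molecular descriptors (X1..Xy). Training runs in cycles of weight updates and
stops on a target reconstruction RMS, on stagnation ("cycles past best"), or
on a cycle budget; the weights returned are those of the best-RMS cycle.

Two trainers are provided: a reproducible minibatch gradient-descent trainer
(default) and a Monte Carlo trainer (greedy Gaussian weight perturbation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemio import DescriptorTable, MolecularGraph
from .codes_encoder import EncoderConfig, encode_dataset

__all__ = [
    "ReductionConfig",
    "BottleneckReducer",
    "TrainingLog",
    "train_reducer",
    "project_codes",
    "reduce_dataset",
]


@dataclass(frozen=True)
class ReductionConfig:
    """Training regime of the bottleneck network.

    ``cycles_past_best`` is the number of cycles allowed without improving the
    best RMS before training stops; the production default is 1000, but small
    runs converge (or stagnate) far earlier.
    """

    y: int = 3
    c: Optional[int] = None          # default max(10, 2y)
    iterations_per_cycle: int = 3000
    cycles_past_best: int = 1000
    target_rms: float = 0.005
    max_cycles: int = 5000
    learning_rate: float = 0.05
    batch_size: int = 16
    trainer: str = "gradient"        # {"gradient", "monte-carlo"}
    mc_sigma: float = 0.02
    hidden_activation: str = "sigmoid"  # {"sigmoid", "linear"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.y < 1:
            raise ValueError("bottleneck width y must be >= 1")
        if self.target_rms <= 0:
            raise ValueError("target RMS must be positive")
        if self.trainer not in ("gradient", "monte-carlo"):
            raise ValueError(f"unknown trainer {self.trainer!r}")
        if self.hidden_activation not in ("sigmoid", "linear"):
            raise ValueError(f"unknown activation {self.hidden_activation!r}")

    def resolved_c(self) -> int:
        return self.c if self.c is not None else max(10, 2 * self.y)


@dataclass
class TrainingLog:
    rms_per_cycle: list[float]
    best_cycle: int
    best_rms: float
    stop_reason: str  # {"target_rms", "cycles_past_best", "max_cycles"}
    best_codes: Optional[np.ndarray] = None  # training-set codes at the best cycle


class BottleneckReducer:
    """Trained n-c-y-c-n auto-associative network (sigmoid hidden, linear output)."""

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray],
                 config: ReductionConfig, input_length: int):
        self.weights = weights
        self.biases = biases
        self.config = config
        self.input_length = input_length

    def _act(self, x: np.ndarray) -> np.ndarray:
        if self.config.hidden_activation == "linear":
            return x
        return 1.0 / (1.0 + np.exp(-x))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return (reconstruction, layer activations [h1, code, h2])."""
        h1 = self._act(x @ self.weights[0] + self.biases[0])
        code = self._act(h1 @ self.weights[1] + self.biases[1])
        h2 = self._act(code @ self.weights[2] + self.biases[2])
        out = h2 @ self.weights[3] + self.biases[3]
        return out, [h1, code, h2]

    def codes(self, x: np.ndarray) -> np.ndarray:
        _, acts = self.forward(np.atleast_2d(x))
        return acts[1]

    def reconstruction_rms(self, x: np.ndarray) -> float:
        out, _ = self.forward(x)
        return float(np.sqrt(np.mean((out - x) ** 2)))


def _init_parameters(n: int, c: int, y: int, rng: np.random.Generator):
    # uniform(-0.5, 0.5) scaled by 1/sqrt(fan-in): keeps sigmoid units out of
    # saturation at large input lengths
    dims = [(n, c), (c, y), (y, c), (c, n)]
    weights = [rng.uniform(-0.5, 0.5, size=d) / np.sqrt(d[0]) for d in dims]
    biases = [rng.uniform(-0.5, 0.5, size=d[1]) for d in dims]
    return weights, biases


def train_reducer(
    tensor: np.ndarray,
    config: Optional[ReductionConfig] = None,
) -> tuple[BottleneckReducer, TrainingLog]:
    """Train the bottleneck network on a padded trajectory tensor.

    ``tensor`` is either (n_mol, A, R) or already-flattened (n_mol, n_in),
    with values in [0,1] (activation trajectories are). Fully reproducible
    from ``config.seed``.
    """
    config = config or ReductionConfig()
    x = np.asarray(tensor, dtype=float)
    if x.ndim == 3:
        x = x.reshape(x.shape[0], -1)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 molecules to train the reducer")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in training tensor")
    n_mol, n_in = x.shape
    c = config.resolved_c()
    # c may exceed the input length (over-complete codification layer); the
    # bottleneck itself must stay strictly below c and no wider than the input
    if not (config.y < c) or config.y > n_in:
        raise ValueError(
            f"architecture requires y < c and y <= input length "
            f"(y={config.y}, c={c}, n={n_in})")

    rng = np.random.default_rng(config.seed)
    weights, biases = _init_parameters(n_in, c, config.y, rng)
    model = BottleneckReducer(weights, biases, config, n_in)

    best_rms = model.reconstruction_rms(x)
    best_state = _copy_state(model)
    best_codes = model.codes(x)
    best_cycle = -1
    log_rms: list[float] = []
    stop_reason = "max_cycles"
    batch = min(config.batch_size, n_mol)
    lr = config.learning_rate
    sigmoid_hidden = config.hidden_activation == "sigmoid"

    for cycle in range(config.max_cycles):
        if config.trainer == "gradient":
            _gradient_cycle(model, x, rng, batch, lr, config.iterations_per_cycle,
                            sigmoid_hidden)
        else:
            _monte_carlo_cycle(model, x, rng, batch, config.mc_sigma,
                               config.iterations_per_cycle)
        rms = model.reconstruction_rms(x)
        log_rms.append(rms)
        if rms < best_rms:
            best_rms = rms
            best_state = _copy_state(model)
            best_cycle = cycle
            best_codes = model.codes(x)
        if best_rms <= config.target_rms:
            stop_reason = "target_rms"
            break
        if cycle - best_cycle >= config.cycles_past_best:
            stop_reason = "cycles_past_best"
            break

    model.weights, model.biases = best_state
    return model, TrainingLog(log_rms, best_cycle, best_rms, stop_reason, best_codes)


def _copy_state(model: BottleneckReducer):
    return ([w.copy() for w in model.weights], [b.copy() for b in model.biases])


def _gradient_cycle(model, x, rng, batch, lr, n_updates, sigmoid_hidden) -> None:
    w, b = model.weights, model.biases
    n = x.shape[0]
    for _ in range(n_updates):
        idx = rng.integers(0, n, size=batch)
        xb = x[idx]
        # forward
        z1 = xb @ w[0] + b[0]
        h1 = 1 / (1 + np.exp(-z1)) if sigmoid_hidden else z1
        z2 = h1 @ w[1] + b[1]
        h2 = 1 / (1 + np.exp(-z2)) if sigmoid_hidden else z2
        z3 = h2 @ w[2] + b[2]
        h3 = 1 / (1 + np.exp(-z3)) if sigmoid_hidden else z3
        out = h3 @ w[3] + b[3]
        # backward (squared reconstruction error summed over features,
        # averaged over the minibatch)
        d_out = 2.0 * (out - xb) / batch
        d_h3 = d_out @ w[3].T
        if sigmoid_hidden:
            d_h3 *= h3 * (1 - h3)
        d_h2 = d_h3 @ w[2].T
        if sigmoid_hidden:
            d_h2 *= h2 * (1 - h2)
        d_h1 = d_h2 @ w[1].T
        if sigmoid_hidden:
            d_h1 *= h1 * (1 - h1)
        w[3] -= lr * (h3.T @ d_out)
        b[3] -= lr * d_out.sum(axis=0)
        w[2] -= lr * (h2.T @ d_h3)
        b[2] -= lr * d_h3.sum(axis=0)
        w[1] -= lr * (h1.T @ d_h2)
        b[1] -= lr * d_h2.sum(axis=0)
        w[0] -= lr * (xb.T @ d_h1)
        b[0] -= lr * d_h1.sum(axis=0)


def _monte_carlo_cycle(model, x, rng, batch, sigma, n_updates) -> None:
    n = x.shape[0]
    for _ in range(n_updates):
        idx = rng.integers(0, n, size=batch)
        xb = x[idx]
        out, _ = model.forward(xb)
        current = float(np.mean((out - xb) ** 2))
        perturb_w = [rng.normal(0, sigma, size=w.shape) for w in model.weights]
        perturb_b = [rng.normal(0, sigma, size=b.shape) for b in model.biases]
        for w, dw in zip(model.weights, perturb_w):
            w += dw
        for b, db in zip(model.biases, perturb_b):
            b += db
        out, _ = model.forward(xb)
        proposed = float(np.mean((out - xb) ** 2))
        if proposed >= current:  # greedy: revert
            for w, dw in zip(model.weights, perturb_w):
                w -= dw
            for b, db in zip(model.biases, perturb_b):
                b -= db


def project_codes(
    reducer: BottleneckReducer,
    tensor: np.ndarray,
    ids: Optional[Sequence[str]] = None,
    prefix: str = "X",
) -> pd.DataFrame:
    """Bottleneck activations per molecule, as a DataFrame with columns X1..Xy."""
    x = np.asarray(tensor, dtype=float)
    if x.ndim == 3:
        x = x.reshape(x.shape[0], -1)
    elif x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != reducer.input_length:
        raise ValueError(
            f"input length mismatch: reducer expects {reducer.input_length}, got {x.shape[1]}")
    codes = reducer.codes(x)
    cols = [f"{prefix}{k + 1}" for k in range(codes.shape[1])]
    index = list(ids) if ids is not None else [str(i) for i in range(len(codes))]
    return pd.DataFrame(codes, columns=cols, index=index)


def reduce_dataset(
    graphs: Sequence[MolecularGraph],
    ids: Optional[Sequence[str]] = None,
    encoder_config: Optional[EncoderConfig] = None,
    reduction_config: Optional[ReductionConfig] = None,
    prefix: str = "X",
) -> tuple[DescriptorTable, BottleneckReducer, TrainingLog]:
    """Full feature-learning pipeline: encode -> pad -> train -> project.

    The training-set presentation order is fixed by sorted ids, so permuting
    the input molecule order only permutes the output rows (same seed).
    """
    if ids is None:
        ids = [g.smiles or f"mol{i}" for i, g in enumerate(graphs)]
    if len(set(ids)) != len(ids):
        raise ValueError("molecule ids must be unique")
    order = np.argsort(np.asarray(ids, dtype=object))
    sorted_graphs = [graphs[i] for i in order]
    sorted_ids = [ids[i] for i in order]
    tensor, _records = encode_dataset(sorted_graphs, encoder_config, ids=sorted_ids)
    reducer, log = train_reducer(tensor, reduction_config)
    codes = project_codes(reducer, tensor, ids=sorted_ids, prefix=prefix)
    codes = codes.loc[list(ids)]  # restore input order
    return DescriptorTable(codes), reducer, log
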