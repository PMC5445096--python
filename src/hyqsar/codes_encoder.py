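"""Neural encoding of molecular graphs.

Each atom of the molecular graph is a neuron of an interactive activation and
competition (IAC) style network: bonded atoms excite each other with a weight
set by bond order, non-bonded atom pairs inhibit each other, and every atom
type starts from its own initial activation. Iterating the network to
equilibrium and recording every intermediate state yields the dynamic A x R
activation matrix (A atoms, R recorded iterations) that downstream
dimensionality reduction compresses into learned molecular descriptors.

R/S stereocenters perturb the initial activation of the tagged atom, so
enantiomers encode differently; formal charge shifts it as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chemio import MolecularGraph

__all__ = [
    "EncoderConfig",
    "ActivationTrajectory",
    "connection_weights",
    "initial_activations",
    "iterate_to_equilibrium",
    "encode_dataset",
    "unpad_trajectories",
    "NonConvergenceWarning",
]

#: Per-element initial activations (electronegativity / 4, bounded in (0,1));
#: distinct per atom type so "atom nature" is encoded in the starting state.
DEFAULT_INITIAL_VALUES: dict[str, float] = {
    "C": 0.636,
    "N": 0.761,
    "O": 0.860,
    "S": 0.645,
    "P": 0.549,
    "F": 0.995,
    "Cl": 0.790,
    "Br": 0.740,
    "I": 0.665,
    "B": 0.510,
    "Si": 0.475,
    "H": 0.550,
}

DEFAULT_BOND_WEIGHTS: dict[str, float] = {
    "single": 0.10,
    "double": 0.20,
    "triple": 0.30,
    "aromatic": 0.15,
}


class NonConvergenceWarning(UserWarning):
    """A molecule did not reach equilibrium within the iteration budget."""


@dataclass(frozen=True)
class EncoderConfig:
    """Parameters of the atom-level activation network.

    Excitatory weights (bond weights) must be positive and the inhibition
    weight negative; initial activations live strictly inside (0,1).
    """

    initial_values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_VALUES))
    default_initial: float = 0.5
    bond_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BOND_WEIGHTS))
    inhibition: float = -0.01
    self_feedback: float = 1.0        # beta; keeps edgeless inputs off the flat 0.5 fixed point
    gain: float = 1.0                 # sigmoid gain g
    stereo_delta: float = 0.05        # R: x(1+delta), S: x(1-delta)
    charge_shift: float = 0.05        # per unit of formal charge
    epsilon: float = 1e-6             # max-norm equilibrium tolerance
    max_iterations: int = 1000
    update_rule: str = "sigmoid"      # {"sigmoid", "iac"}
    iac_decay: float = 0.1
    iac_rest: float = 0.1

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.bond_weights.values()):
            raise ValueError("bond (excitatory) weights must be positive")
        if self.inhibition >= 0:
            raise ValueError("inhibition weight must be negative")
        if self.epsilon <= 0:
            raise ValueError("equilibrium tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0 <= self.stereo_delta < 0.5):
            raise ValueError("stereo delta must be in [0, 0.5)")
        if self.gain <= 0:
            raise ValueError("sigmoid gain must be positive")
        for sym, v in self.initial_values.items():
            if not (0 < v < 1):
                raise ValueError(f"initial value for {sym} must be in (0,1), got {v}")
        if self.update_rule not in ("sigmoid", "iac"):
            raise ValueError(f"unknown update rule {self.update_rule!r}")


@dataclass
class ActivationTrajectory:
    """The A x R dynamic matrix: one row per atom, one column per recorded state."""

    matrix: np.ndarray            # shape (A, R), column 0 = initial state
    converged: bool
    molecule_id: Optional[str] = None

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.matrix.shape[1]

    def flatten(self) -> np.ndarray:
        return self.matrix.reshape(-1)


def connection_weights(graph: MolecularGraph, config: EncoderConfig) -> np.ndarray:
    """Symmetric A x A connection matrix: bond weight where bonded, inhibition
    where not, zero diagonal."""
    a = graph.n_atoms
    w = np.full((a, a), config.inhibition, dtype=float)
    np.fill_diagonal(w, 0.0)
    for i, j, order in graph.bonds:
        try:
            bw = config.bond_weights[order]
        except KeyError:
            raise ValueError(f"no weight configured for bond order {order!r}") from None
        w[i, j] = bw
        w[j, i] = bw
    return w


def initial_activations(graph: MolecularGraph, config: EncoderConfig) -> np.ndarray:
    """Per-atom initial state: element table value, stereo-corrected and
    charge-shifted, clipped strictly inside (0,1)."""
    a0 = np.empty(graph.n_atoms, dtype=float)
    for idx, atom in enumerate(graph.atoms):
        v = config.initial_values.get(atom.element, config.default_initial)
        if atom.stereo == "R":
            v *= 1.0 + config.stereo_delta
        elif atom.stereo == "S":
            v *= 1.0 - config.stereo_delta
        v += config.charge_shift * atom.formal_charge
        a0[idx] = v
    return np.clip(a0, 1e-6, 1.0 - 1e-6)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def iterate_to_equilibrium(
    graph: MolecularGraph,
    config: Optional[EncoderConfig] = None,
    molecule_id: Optional[str] = None,
) -> ActivationTrajectory:
    """Run the network synchronously until the state change falls below epsilon.

    Under the sigmoid rule each step applies
    ``a_i(t+1) = sigma(g * (beta * a_i(t) + sum_j w_ij a_j(t)))`` and the
    trajectory records every state visited, starting with the initial state in
    column 0. Non-convergence within the iteration budget is flagged, not
    raised.
    """
    config = config or EncoderConfig()
    w = connection_weights(graph, config)
    state = initial_activations(graph, config)
    states = [state]
    converged = False
    for _ in range(config.max_iterations):
        if config.update_rule == "sigmoid":
            net = config.self_feedback * state + w @ state
            new = _sigmoid(config.gain * net)
        else:  # classical IAC increment, clipped to the unit interval
            net = w @ state
            delta = np.where(net > 0, (1.0 - state) * net, state * net)
            new = state + delta - config.iac_decay * (state - config.iac_rest)
            new = np.clip(new, 1e-6, 1.0 - 1e-6)
        states.append(new)
        if np.max(np.abs(new - state)) < config.epsilon:
            converged = True
            state = new
            break
        state = new
    matrix = np.column_stack(states)
    return ActivationTrajectory(matrix=matrix, converged=converged,
                                molecule_id=molecule_id)


def encode_dataset(
    graphs: Sequence[MolecularGraph],
    config: Optional[EncoderConfig] = None,
    ids: Optional[Sequence[str]] = None,
    strict: bool = False,
) -> tuple[np.ndarray, list[dict]]:
    """Encode every molecule and pad trajectories to a common (A_max, R_max).

    Padding columns repeat each molecule's final (equilibrium) column; padding
    rows are zero, so the flattened length ``A_max * R_max`` is identical for
    all molecules. Returns the padded tensor of shape (n, A_max, R_max) and
    per-molecule records ``{"id", "A", "R", "converged"}``.
    """
    if len(graphs) == 0:
        raise ValueError("no molecules to encode")
    config = config or EncoderConfig()
    if ids is None:
        ids = [g.smiles or f"mol{i}" for i, g in enumerate(graphs)]
    trajectories = [
        iterate_to_equilibrium(g, config, molecule_id=mid)
        for g, mid in zip(graphs, ids)
    ]
    bad = [t.molecule_id for t in trajectories if not t.converged]
    if bad:
        msg = f"molecules did not converge: {bad}"
        if strict:
            raise RuntimeError(msg)
        warnings.warn(msg, NonConvergenceWarning)

    a_max = max(t.n_atoms for t in trajectories)
    r_max = max(t.n_iterations for t in trajectories)
    tensor = np.zeros((len(trajectories), a_max, r_max), dtype=float)
    records = []
    for k, t in enumerate(trajectories):
        a, r = t.matrix.shape
        tensor[k, :a, :r] = t.matrix
        if r < r_max:  # repeat the equilibrium column
            tensor[k, :a, r:] = t.matrix[:, -1][:, None]
        records.append({"id": t.molecule_id, "A": a, "R": r, "converged": t.converged})
    return tensor, records


def unpad_trajectories(tensor: np.ndarray, records: Sequence[dict]) -> list[np.ndarray]:
    """Invert the padding of :func:`encode_dataset` exactly."""
    return [tensor[k, : rec["A"], : rec["R"]].copy() for k, rec in enumerate(records)]
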