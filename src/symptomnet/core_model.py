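"""Stochastic binary symptom-network dynamics.

A symptom network is a set of ``J`` binary nodes ("symptoms") coupled by a
symmetric weight matrix ``W`` with zero diagonal, plus per-node thresholds
``tau``. At each time step every symptom receives *total activation*

    A_i(t) = c * sum_j W_ij X_j(t-1) + S_i(t)

where ``c`` is a global connectivity multiplier and ``S`` an external
stress input, and then switches on with logistic probability

    P(X_i(t) = 1) = 1 / (1 + exp(b_i - A_i(t)))

with ``b_i`` derived from the threshold (by default its absolute value).
The scalar readout is the symptom count ``D(t) = sum_i X_i(t)``, ranging
from 0 (fully healthy) to ``J`` (all symptoms active).

The update is synchronous by default: all symptoms are resampled each
step from the previous state. An asynchronous mode (one randomly chosen
node per step) is available for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit


class DimensionMismatchError(ValueError):
    """A vector or matrix has the wrong length/shape for the network."""


class NetworkValidationError(ValueError):
    """The supplied weights/thresholds violate a network invariant."""


_B_MODES = ("abs", "identity")


@dataclass(frozen=True)
class SymptomNetwork:
    """Static model parameters: labels, pairwise weights, thresholds.

    Parameters
    ----------
    labels
        ``J`` symptom identifiers.
    weights
        ``J x J`` symmetric real matrix with zero diagonal; entry
        ``w_ij`` is the pairwise coupling between symptoms ``i`` and
        ``j`` (positive values make the pair prefer the same state).
    thresholds
        ``J`` real values ``tau_i``; negative values favour 'off'.
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        tau = np.asarray(self.thresholds, dtype=float)
        labels = tuple(str(x) for x in self.labels)
        J = len(labels)
        if J < 2:
            raise NetworkValidationError(f"a network needs at least 2 symptoms, got {J}")
        if W.shape != (J, J):
            raise DimensionMismatchError(
                f"weights must be {J}x{J} to match {J} labels, got shape {W.shape}"
            )
        if tau.shape != (J,):
            raise DimensionMismatchError(
                f"thresholds must have length {J}, got {tau.shape[0] if tau.ndim == 1 else tau.shape}"
            )
        if not np.allclose(W, W.T, atol=1e-10):
            raise NetworkValidationError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0.0):
            raise NetworkValidationError(
                "weight matrix has nonzero diagonal entries; self-loops are not modelled"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "thresholds", tau)

    @property
    def J(self) -> int:
        return len(self.labels)

    def b(self, mode: str = "abs") -> np.ndarray:
        """Probability-function parameter ``b_i`` derived from thresholds.

        ``"abs"`` gives ``b_i = |tau_i|`` (the simulator's default
        convention); ``"identity"`` gives ``b_i = -tau_i``, which makes
        the logistic probability the full conditional of the Ising
        distribution whose parameters the estimator targets.
        """
        if mode == "abs":
            return np.abs(self.thresholds)
        if mode == "identity":
            return -self.thresholds
        raise ValueError(f"unknown b_mode {mode!r}; expected one of {_B_MODES}")


@dataclass(frozen=True)
class SystemState:
    """Binary activation vector at one time step."""

    X: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.int8)
        if X.ndim != 1:
            raise DimensionMismatchError(f"state must be a vector, got shape {X.shape}")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("state entries must be 0 or 1")
        if self.t < 0:
            raise ValueError("time index must be non-negative")
        object.__setattr__(self, "X", X)

    @property
    def D(self) -> int:
        """Number of active symptoms."""
        return int(self.X.sum())


@dataclass(frozen=True)
class ModelConfig:
    """Run parameters for a simulation.

    ``connectivity`` multiplies the whole weight matrix and is the
    model's vulnerability dial; reference values are 0.80 (weak),
    1.10 (medium) and 2.00 (strong).
    """

    connectivity: float = 1.0
    b_mode: str = "abs"
    seed: int | None = None
    n_steps: int = 10_000
    initial_state: np.ndarray | None = None
    update: str = "synchronous"

    def __post_init__(self) -> None:
        if self.connectivity <= 0:
            raise ValueError(f"connectivity must be positive, got {self.connectivity}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.b_mode not in _B_MODES:
            raise ValueError(f"unknown b_mode {self.b_mode!r}; expected one of {_B_MODES}")
        if self.update not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown update scheme {self.update!r}")


@dataclass(frozen=True)
class SimulationTrace:
    """Time-indexed record of a simulation run."""

    states: np.ndarray  # (n_steps, J) int8
    D: np.ndarray  # (n_steps,) int
    stress: np.ndarray  # (n_steps,) float, zeros when unstressed
    config_echo: ModelConfig
    stress_direction: np.ndarray | None = None  # +1 ascending / -1 descending, if ramped

    def __post_init__(self) -> None:
        n = self.states.shape[0]
        if not (len(self.D) == len(self.stress) == n):
            raise DimensionMismatchError(
                f"inconsistent trace lengths: states {n}, D {len(self.D)}, stress {len(self.stress)}"
            )
        if not np.array_equal(self.D, self.states.sum(axis=1)):
            raise ValueError("D must equal the row sums of states")

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def J(self) -> int:
        return self.states.shape[1]

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        """Tabular view: columns t, stress, D, X_<label>."""
        if labels is None:
            labels = [f"X{i + 1}" for i in range(self.J)]
        frame = pd.DataFrame(
            {"t": np.arange(self.n_steps), "stress": self.stress, "D": self.D}
        )
        for j, lab in enumerate(labels):
            frame[f"X_{lab}"] = self.states[:, j]
        return frame


def total_activation(
    net: SymptomNetwork,
    X_prev: np.ndarray,
    c: float,
    S: np.ndarray | float | None = None,
) -> np.ndarray:
    """Per-symptom input ``A_i = c * sum_j w_ij X_prev_j + S_i``.

    ``S`` may be a scalar (applied to every symptom, the default stress
    protocol), a length-``J`` vector, or ``None`` (no stress).
    """
    X_prev = np.asarray(X_prev)
    if X_prev.shape != (net.J,):
        raise DimensionMismatchError(
            f"previous state has length {X_prev.shape[0] if X_prev.ndim == 1 else X_prev.shape}, "
            f"expected {net.J}"
        )
    if c <= 0:
        raise ValueError(f"connectivity must be positive, got {c}")
    A = c * (net.weights @ X_prev.astype(float))
    if S is not None:
        S_arr = np.asarray(S, dtype=float)
        if S_arr.ndim == 0:
            A = A + float(S_arr)
        elif S_arr.shape == (net.J,):
            A = A + S_arr
        else:
            raise DimensionMismatchError(
                f"stress vector has length {S_arr.shape[0] if S_arr.ndim == 1 else S_arr.shape}, "
                f"expected scalar or {net.J}"
            )
    return A


def activation_probability(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Logistic switching probability ``P_i = 1 / (1 + exp(b_i - A_i))``.

    Computed as ``expit(A - b)``, which is numerically stable for
    arbitrarily large ``|b - A|`` (saturates to exactly 0.0 or 1.0
    rather than overflowing).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.shape != b.shape:
        raise DimensionMismatchError(f"A has shape {A.shape} but b has shape {b.shape}")
    return expit(A - b)


def step(
    net: SymptomNetwork,
    state: SystemState,
    cfg: ModelConfig,
    S: np.ndarray | float | None = None,
    rng: np.random.Generator | None = None,
) -> SystemState:
    """Advance the system one time step.

    Synchronous mode resamples every symptom from Bernoulli(P_i) with
    P computed from the time-``t`` state; asynchronous mode resamples a
    single uniformly chosen symptom. Bernoulli draws are consumed in
    fixed node order, so a seeded generator reproduces traces exactly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    A = total_activation(net, state.X, cfg.connectivity, S)
    P = activation_probability(A, net.b(cfg.b_mode))
    if cfg.update == "synchronous":
        X_next = (rng.random(net.J) < P).astype(np.int8)
    else:
        X_next = state.X.copy()
        i = int(rng.integers(net.J))
        X_next[i] = np.int8(rng.random() < P[i])
    return SystemState(X=X_next, t=state.t + 1)


def _resolve_stress(stress_schedule, n_steps: int, J: int) -> np.ndarray:
    """Normalise a stress input to an (n_steps, J) array."""
    if stress_schedule is None:
        return np.zeros((n_steps, J))
    values = getattr(stress_schedule, "values", stress_schedule)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        if len(values) != n_steps:
            raise DimensionMismatchError(
                f"stress schedule has length {len(values)}, expected n_steps={n_steps}"
            )
        return np.broadcast_to(values[:, None], (n_steps, J)).copy()
    if values.shape == (n_steps, J):
        return values
    raise DimensionMismatchError(
        f"stress schedule has shape {values.shape}, expected ({n_steps},) or ({n_steps}, {J})"
    )


def simulate(
    net: SymptomNetwork,
    cfg: ModelConfig,
    stress_schedule=None,
) -> SimulationTrace:
    """Run the dynamics for ``cfg.n_steps`` steps and record the trace.

    The run starts from ``cfg.initial_state`` (all symptoms off when
    not given). ``stress_schedule`` may be ``None``, a length-``n_steps``
    vector (broadcast to all symptoms), an ``(n_steps, J)`` array, or a
    :class:`~symptomnet.stress_protocol.StressSchedule`.
    """
    J = net.J
    stress = _resolve_stress(stress_schedule, cfg.n_steps, J)
    direction = getattr(stress_schedule, "direction", None)
    if direction is not None:
        direction = np.asarray(direction)

    if cfg.initial_state is None:
        X = np.zeros(J, dtype=np.int8)
    else:
        X = np.asarray(cfg.initial_state, dtype=np.int8)
        if X.shape != (J,):
            raise DimensionMismatchError(
                f"initial state has length {X.shape[0] if X.ndim == 1 else X.shape}, expected {J}"
            )
    rng = np.random.default_rng(cfg.seed)
    b = net.b(cfg.b_mode)
    cW = cfg.connectivity * net.weights

    states = np.empty((cfg.n_steps, J), dtype=np.int8)
    state = SystemState(X=X, t=0)
    for t in range(cfg.n_steps):
        A = cW @ state.X.astype(float) + stress[t]
        P = expit(A - b)
        if cfg.update == "synchronous":
            X_next = (rng.random(J) < P).astype(np.int8)
        else:
            X_next = state.X.copy()
            i = int(rng.integers(J))
            X_next[i] = np.int8(rng.random() < P[i])
        state = SystemState(X=X_next, t=t + 1)
        states[t] = X_next

    scalar_stress = stress[:, 0] if np.all(stress == stress[:, [0]]) else stress.mean(axis=1)
    return SimulationTrace(
        states=states,
        D=states.sum(axis=1).astype(int),
        stress=scalar_stress,
        config_echo=cfg,
        stress_direction=direction,
    )


# ---------------------------------------------------------------------------
# Exact analysis of the synchronous chain (small J)


def enumerate_states(J: int) -> np.ndarray:
    """All 2^J binary configurations, in binary-counting order."""
    idx = np.arange(2**J)
    return ((idx[:, None] >> np.arange(J)) & 1).astype(np.int8)


def transition_matrix(
    net: SymptomNetwork, cfg: ModelConfig, S: float = 0.0, max_J: int = 12
) -> np.ndarray:
    """Exact 2^J x 2^J transition matrix of the synchronous chain.

    Entry (x, y) is ``prod_i P_i(x)^{y_i} (1 - P_i(x))^{1 - y_i}`` where
    ``P_i(x)`` is the activation probability given previous state x.
    """
    if net.J > max_J:
        raise ValueError(f"exact enumeration limited to J <= {max_J}, got J={net.J}")
    states = enumerate_states(net.J)
    b = net.b(cfg.b_mode)
    n = states.shape[0]
    T = np.empty((n, n))
    for xi in range(n):
        A = total_activation(net, states[xi], cfg.connectivity, S)
        P = activation_probability(A, b)
        # product over nodes of P or 1-P according to the target state
        T[xi] = np.prod(np.where(states == 1, P, 1.0 - P), axis=1)
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def with_seed(cfg: ModelConfig, seed: int) -> ModelConfig:
    """Copy a config with a different seed."""
    return replace(cfg, seed=seed)
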