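"""Synthetic networks and exact Ising-distributed binary data.

Real symptom-network studies estimate parameters from large binary
questionnaire datasets that are rarely public. This module replaces
that input: :func:`random_network` draws a network whose qualitative
structure echoes published depression networks (mostly positive
pairwise weights, negative per-symptom thresholds so symptoms prefer
'off' and marginal prevalences stay low), and :func:`sample_ising_exact`
draws i.i.d. respondents from the exact Ising distribution

    P(x) ∝ exp( sum_i tau_i x_i + sum_{i<j} w_ij x_i x_j ),   x in {0,1}^J

by full 2^J enumeration, so estimator-recovery experiments have a
known ground truth. :func:`sample_ising_gibbs` is the scalable
single-site Gibbs alternative for J > 20.

Note the sampler uses the conventional Ising parameterisation with
``tau`` itself (not ``|tau|``); the absolute-value convention belongs
to the simulator's probability function only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from symptomnet.core_model import SymptomNetwork, enumerate_states

_EXACT_MAX_J = 20


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a random symptom network and dataset.

    Defaults mimic a 14-symptom depression network: roughly half of the
    91 possible pairs connected, positive weights of modest size, and
    clearly negative thresholds so that symptom prevalence is low in
    the unstressed population. At these values the simulated dynamics
    reproduce the reference phenomenology: spontaneous brief symptom
    excursions under weak connectivity (c = 0.80), larger but still
    transient episodes at medium connectivity (c = 1.10), and a
    self-sustaining fully-depressed state at strong connectivity
    (c = 2.00).
    """

    J: int = 14
    edge_density: float = 0.5
    weight_range: tuple[float, float] = (0.3, 1.2)
    threshold_range: tuple[float, float] = (-4.0, -2.0)
    N: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.J < 2:
            raise ValueError(f"J must be >= 2, got {self.J}")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError(f"edge_density must be in [0, 1], got {self.edge_density}")
        for name, (lo, hi) in (
            ("weight_range", self.weight_range),
            ("threshold_range", self.threshold_range),
        ):
            if lo > hi:
                raise ValueError(f"{name} must be ordered (low, high), got ({lo}, {hi})")
        if self.weight_range[0] <= 0:
            raise ValueError("weights must be positive")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")


def random_network(spec: GeneratorSpec) -> SymptomNetwork:
    """Draw a random symmetric zero-diagonal network from a spec.

    Each unordered pair receives an edge with probability
    ``edge_density``; edge weights are uniform in ``weight_range`` and
    thresholds uniform in ``threshold_range``. Seeded and reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    J = spec.J
    W = np.zeros((J, J))
    iu, ju = np.triu_indices(J, k=1)
    present = rng.random(len(iu)) < spec.edge_density
    w = rng.uniform(*spec.weight_range, size=len(iu)) * present
    W[iu, ju] = w
    W[ju, iu] = w
    tau = rng.uniform(*spec.threshold_range, size=J)
    labels = tuple(f"S{i + 1}" for i in range(J))
    return SymptomNetwork(labels=labels, weights=W, thresholds=tau)


def ising_state_probabilities(net: SymptomNetwork) -> tuple[np.ndarray, np.ndarray]:
    """All 2^J configurations and their exact Ising probabilities."""
    if net.J > _EXACT_MAX_J:
        raise ValueError(
            f"exact enumeration infeasible for J={net.J} > {_EXACT_MAX_J}; "
            "use sample_ising_gibbs instead"
        )
    states = enumerate_states(net.J).astype(float)
    # energy: tau.x + sum_{i<j} w_ij x_i x_j ; the quadratic form double-counts pairs
    energy = states @ net.thresholds + 0.5 * np.einsum("si,ij,sj->s", states, net.weights, states)
    energy -= energy.max()  # guard exp overflow; cancels in normalisation
    p = np.exp(energy)
    return states.astype(np.int8), p / p.sum()


def sample_ising_exact(net: SymptomNetwork, N: int, seed: int | None = None):
    """Draw N i.i.d. respondents from the exact Ising distribution.

    Enumerates all 2^J configurations, normalises, and samples from the
    resulting categorical distribution. Limited to J <= 20.
    """
    from symptomnet.ising_estimation import BinaryDataset

    states, p = ising_state_probabilities(net)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(p), size=N, p=p)
    return BinaryDataset(data=states[idx].copy(), labels=list(net.labels))


def sample_ising_gibbs(
    net: SymptomNetwork,
    N: int,
    burn_in: int = 1000,
    thin: int = 10,
    seed: int | None = None,
):
    """Draw N thinned configurations by single-site Gibbs sampling.

    Each sweep updates every node from its full conditional
    ``P(x_i = 1 | x_-i) = logistic(tau_i + sum_j w_ij x_j)``. The first
    ``burn_in`` sweeps are discarded and one draw is kept every
    ``thin`` sweeps. Suitable for networks too large for enumeration.
    """
    from scipy.special import expit

    from symptomnet.ising_estimation import BinaryDataset

    if burn_in < 1 or thin < 1:
        raise ValueError("burn_in and thin must be >= 1")
    rng = np.random.default_rng(seed)
    J = net.J
    x = (rng.random(J) < 0.5).astype(np.int8)
    out = np.empty((N, J), dtype=np.int8)
    n_sweeps = burn_in + N * thin
    # pre-draw uniforms in fixed (sweep, node) order for reproducibility
    kept = 0
    for sweep in range(n_sweeps):
        for i in range(J):
            field = net.thresholds[i] + net.weights[i] @ x
            x[i] = np.int8(rng.random() < expit(field))
        if sweep >= burn_in and (sweep - burn_in) % thin == 0 and kept < N:
            out[kept] = x
            kept += 1
    return BinaryDataset(data=out, labels=list(net.labels))
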