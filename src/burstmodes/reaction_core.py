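"""Elementary reaction networks with dual stochastic/deterministic semantics.

A well-mixed system of ``M`` species undergoing ``R`` irreversible elementary
reactions is described by educt and product stoichiometric coefficient
matrices.  The same network yields

* deterministic mass-action kinetics on concentrations ``c = n/V``, with rate
  constants ``k_j``;
* a continuous-time Markov chain on copy numbers ``n``, whose propensities use
  the stochastic constants ``kappa_j = k_j * V * prod_i beta_ij! / V**beta_ij``
  and combinatorial educt-encounter counts.

:func:`simulate_ssa` provides the exact direct-method Gillespie sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ReactionNetwork",
    "SystemState",
    "Trajectory",
    "stochastic_constant",
    "propensity",
    "mass_action_rhs",
    "simulate_ssa",
]

_EXACT_BINOM_LIMIT = 10**6  # integer arithmetic below this, log-gamma above


@dataclass(frozen=True)
class ReactionNetwork:
    """Elementary reaction system: species, stoichiometry, rates, volume.

    ``educt_coeffs`` and ``product_coeffs`` are M x R matrices of nonnegative
    integers (species by reaction); the stoichiometric matrix is their
    difference.  ``det_rate_constants`` are the deterministic (mass-action)
    constants ``k_j``; the stochastic constants ``kappa_j`` are derived, never
    stored.
    """

    species_labels: tuple
    educt_coeffs: np.ndarray
    product_coeffs: np.ndarray
    det_rate_constants: np.ndarray
    volume: float = 1.0

    def __post_init__(self) -> None:
        beta = np.asarray(self.educt_coeffs, dtype=np.int64)
        gamma = np.asarray(self.product_coeffs, dtype=np.int64)
        k = np.asarray(self.det_rate_constants, dtype=float)
        object.__setattr__(self, "species_labels", tuple(self.species_labels))
        object.__setattr__(self, "educt_coeffs", beta)
        object.__setattr__(self, "product_coeffs", gamma)
        object.__setattr__(self, "det_rate_constants", k)
        M = len(self.species_labels)
        if beta.shape != gamma.shape or beta.ndim != 2 or beta.shape[0] != M:
            raise ValueError("stoichiometric matrices must be M x R and agree")
        if beta.shape[1] != k.size:
            raise ValueError("need one rate constant per reaction")
        if np.any(beta < 0) or np.any(gamma < 0):
            raise ValueError("stoichiometric coefficients must be nonnegative")
        if np.any(k <= 0):
            raise ValueError("rate constants must be positive")
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    @property
    def n_species(self) -> int:
        return self.educt_coeffs.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.educt_coeffs.shape[1]

    @property
    def stoich_matrix(self) -> np.ndarray:
        """Net stoichiometry ``A = product_coeffs - educt_coeffs``."""
        return self.product_coeffs - self.educt_coeffs

    @classmethod
    def from_config(cls, cfg: dict) -> "ReactionNetwork":
        """Build from ``{species: [...], reactions: [{educts, products, k}], volume}``.

        ``educts``/``products`` map species label to coefficient.
        """
        species = list(cfg["species"])
        idx = {s: i for i, s in enumerate(species)}
        R = len(cfg["reactions"])
        beta = np.zeros((len(species), R), dtype=np.int64)
        gamma = np.zeros_like(beta)
        k = np.empty(R)
        for j, rxn in enumerate(cfg["reactions"]):
            for s, c in (rxn.get("educts") or {}).items():
                beta[idx[s], j] = c
            for s, c in (rxn.get("products") or {}).items():
                gamma[idx[s], j] = c
            k[j] = rxn["k"]
        return cls(tuple(species), beta, gamma, k, float(cfg.get("volume", 1.0)))


@dataclass
class SystemState:
    """Copy-number vector plus simulation time."""

    copy_numbers: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.copy_numbers = np.asarray(self.copy_numbers, dtype=np.int64)
        if np.any(self.copy_numbers < 0):
            raise ValueError("copy numbers must be nonnegative")
        if self.time < 0:
            raise ValueError("time must be nonnegative")


@dataclass
class Trajectory:
    """Piecewise-constant sample path: state ``states[:, i]`` holds on
    ``[times[i], times[i+1])``."""

    times: np.ndarray
    states: np.ndarray  # M x (n_events + 1)
    species_labels: tuple = field(default_factory=tuple)

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.states[:, max(i, 0)]

    def time_average(self, t_start: float = 0.0) -> np.ndarray:
        """Time-weighted average copy numbers over ``[t_start, times[-1]]``."""
        t = np.clip(self.times, t_start, None)
        dt = np.diff(t)
        total = t[-1] - t_start
        if total <= 0:
            return self.states[:, -1].astype(float)
        return (self.states[:, :-1] * dt).sum(axis=1) / total


def stochastic_constant(network: ReactionNetwork, j: int) -> float:
    """Stochastic rate constant ``kappa_j = k_j * V * prod_i beta_ij! / V**beta_ij``."""
    beta_j = network.educt_coeffs[:, j]
    k = float(network.det_rate_constants[j])
    V = network.volume
    fact = 1.0
    for b in beta_j:
        fact *= math.factorial(int(b))
    return k * V * fact / V ** int(beta_j.sum())


def _binom(n: int, b: int) -> float:
    if n < b:
        return 0.0
    if n < _EXACT_BINOM_LIMIT:
        return float(math.comb(int(n), int(b)))
    return float(
        np.exp(gammaln(n + 1) - gammaln(b + 1) - gammaln(n - b + 1))
    )


def propensity(network: ReactionNetwork, state: SystemState, j: int) -> float:
    """Propensity ``w_j(n) = kappa_j * prod_i C(n_i, beta_ij)``.

    Zero whenever any educt count falls short of its coefficient.
    """
    n = state.copy_numbers
    beta_j = network.educt_coeffs[:, j]
    w = stochastic_constant(network, j)
    for ni, b in zip(n, beta_j):
        if b:
            w *= _binom(int(ni), int(b))
            if w == 0.0:
                return 0.0
    return w


def propensity_volume_form(network: ReactionNetwork, state: SystemState, j: int) -> float:
    """Equivalent falling-factorial/volume form of the propensity,
    ``k_j * V**(1 - sum_i beta_ij) * prod_i n_i!/(n_i - beta_ij)!``.

    Used as an internal consistency check against :func:`propensity`.
    """
    n = state.copy_numbers
    beta_j = network.educt_coeffs[:, j]
    k = float(network.det_rate_constants[j])
    V = network.volume
    w = k * V ** (1 - int(beta_j.sum()))
    for ni, b in zip(n, beta_j):
        b = int(b)
        if ni < b:
            return 0.0
        for m in range(b):
            w *= ni - m
    return w


def mass_action_rhs(network: ReactionNetwork, c: np.ndarray) -> np.ndarray:
    """Mass-action concentration dynamics ``dc_i/dt = sum_j a_ij k_j prod_l c_l**beta_lj``."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    rates = network.det_rate_constants * np.prod(
        c[:, None] ** network.educt_coeffs, axis=0
    )
    return network.stoich_matrix @ rates


def simulate_ssa(
    network: ReactionNetwork,
    n0: SystemState,
    t_end: float,
    rng: np.random.Generator | int,
) -> Trajectory:
    """Exact direct-method Gillespie simulation over ``[n0.time, t_end]``.

    Waiting times are exponential with the total propensity; the firing
    channel is chosen proportionally to its propensity; the state jumps by the
    corresponding stoichiometric column.  When all propensities vanish the
    state is frozen until ``t_end``.
    """
    if t_end <= n0.time:
        raise ValueError("t_end must exceed the initial time")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    A = network.stoich_matrix
    kappas = np.array(
        [stochastic_constant(network, j) for j in range(network.n_reactions)]
    )
    beta = network.educt_coeffs
    n = n0.copy_numbers.copy()
    t = float(n0.time)
    times = [t]
    states = [n.copy()]
    while True:
        w = kappas.copy()
        for j in range(network.n_reactions):
            for i in range(network.n_species):
                if beta[i, j]:
                    w[j] *= _binom(int(n[i]), int(beta[i, j]))
        total = w.sum()
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        u = rng.random() * total
        acc = 0.0
        j = network.n_reactions - 1
        for jj in range(network.n_reactions):
            acc += w[jj]
            if u < acc:
                j = jj
                break
        n += A[:, j]
        times.append(t)
        states.append(n.copy())
    times.append(t_end)
    states.append(n.copy())
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states).T,
        species_labels=network.species_labels,
    )
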