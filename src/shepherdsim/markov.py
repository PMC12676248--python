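"""Absorbing Markov chain of SMC/SV+ cell fate during early development.

A proliferating abnormal cell can, at each developmental step, undergo
apoptosis (CLEARED), be allocated to the trophectoderm (TE), be retained in
the inner cell mass (ICM), or keep proliferating.  CLEARED, TE and ICM are
absorbing.  With per-step probabilities (p_clear, p_te, p_icm, p_stay), the
mass still proliferating after k steps is p_stay**k and each absorbing state
ultimately receives p_a / (1 - p_stay) of the mass (geometric series).

The chain uses mass-vector semantics (a distribution over states), not
per-cell sampling; a per-cell Monte-Carlo version exists only as a test
oracle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "State",
    "TransitionSpec",
    "ChainDistribution",
    "step",
    "iterate",
    "absorbing_distribution",
    "expected_absorption_time",
]

_SUM_TOL = 1e-12


class State(enum.IntEnum):
    PROLIFERATING = 0
    CLEARED = 1
    TE = 2
    ICM = 3


@dataclass(frozen=True)
class TransitionSpec:
    """Per-step fate probabilities of a proliferating SMC/SV+ cell.

    Defaults (0.2, 0.2, 0.2, 0.4) are the simplest symmetric choice; they
    send one third of the clone to each terminal fate, i.e. ~33% ICM
    retention.
    """

    p_clear: float = 0.2
    p_te: float = 0.2
    p_icm: float = 0.2
    p_stay: float = 0.4

    def __post_init__(self) -> None:
        probs = (self.p_clear, self.p_te, self.p_icm, self.p_stay)
        if any(p < 0 for p in probs):
            raise ValueError("transition probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > _SUM_TOL:
            raise ValueError("transition probabilities must sum to 1")
        if self.p_stay >= 1.0:
            raise ValueError("p_stay must be < 1 (the chain must absorb)")

    @property
    def matrix(self) -> np.ndarray:
        """Row-stochastic transition matrix over (PROLIFERATING, CLEARED, TE, ICM)."""
        P = np.eye(4)
        P[State.PROLIFERATING] = [self.p_stay, self.p_clear, self.p_te, self.p_icm]
        return P


@dataclass(frozen=True)
class ChainDistribution:
    """Probability mass over states after `iteration` steps."""

    mass: np.ndarray
    iteration: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "mass", m)
        if m.shape != (4,):
            raise ValueError("mass must be a length-4 vector")
        if np.any(m < -_SUM_TOL) or abs(m.sum() - 1.0) > _SUM_TOL:
            raise ValueError("mass must be a probability vector")

    def __getitem__(self, state: State) -> float:
        return float(self.mass[state])


def initial_distribution() -> ChainDistribution:
    """All mass proliferating — a fresh SMC/SV+ clone."""
    return ChainDistribution(np.array([1.0, 0.0, 0.0, 0.0]), 0)


def step(dist: ChainDistribution, spec: TransitionSpec) -> ChainDistribution:
    """Apply one transition: absorbed mass only grows, proliferating decays."""
    return ChainDistribution(dist.mass @ spec.matrix, dist.iteration + 1)


def iterate(spec: TransitionSpec, n_steps: int) -> list[ChainDistribution]:
    """Trajectory from the all-proliferating start over n_steps transitions.

    Returns n_steps + 1 distributions (including the start).  The
    proliferating mass after k steps equals p_stay**k.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    traj = [initial_distribution()]
    for _ in range(n_steps):
        traj.append(step(traj[-1], spec))
    return traj


def absorbing_distribution(spec: TransitionSpec) -> np.ndarray:
    """Limiting mass over (CLEARED, TE, ICM): p_a / (1 - p_stay) each."""
    denom = 1.0 - spec.p_stay
    if denom <= 0.0:
        raise ValueError("p_stay = 1 admits no absorption")
    return np.array([spec.p_clear, spec.p_te, spec.p_icm]) / denom


def expected_absorption_time(spec: TransitionSpec) -> float:
    """Mean number of steps before leaving PROLIFERATING: 1 / (1 - p_stay)."""
    return 1.0 / (1.0 - spec.p_stay)


def trajectory_to_tsv(traj: list[ChainDistribution]) -> str:
    lines = ["iteration\tproliferating\tcleared\tte\ticm"]
    for d in traj:
        lines.append(
            f"{d.iteration}\t" + "\t".join(f"{v:.12f}" for v in d.mass)
        )
    return "\n".join(lines) + "\n"
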