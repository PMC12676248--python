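"""Agent-based simulation of mosaic cell selection during blastocyst formation.

SMC/SV+ and SMC/SV− cells proliferate from a small founder population.  Each
division cycle every surviving cell produces two daughters; SMC/SV+ daughters
die with per-cycle probability ``s`` (mild selection against the abnormal
clone) while SMC/SV− daughters always survive.  After the final cycle each
surviving cell is assigned to the inner cell mass (ICM) with probability ``q``
for normal cells and ``q·(1−a)`` for abnormal ones (allocation bias ``a``),
otherwise to the trophectoderm (TE).  The quantity of interest is the final
SMC/SV+ fraction in the ICM, i.e. the mosaic level the embryo proper retains.

``expected_icm_fraction`` is the deterministic mean of this process under
independent survival and allocation:

    E[ICM+ fraction] = p0·(1−s)^c·(1−a) / (p0·(1−s)^c·(1−a) + (1−p0))

which the Monte-Carlo simulator must reproduce (and tests check) whenever the
initial positive fraction p0 is exactly representable by the founder count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ABMParams",
    "ABMResult",
    "SweepMatrix",
    "simulate_embryo",
    "expected_icm_fraction",
    "run_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ABMParams:
    """Simulator configuration.

    Defaults approximate a human blastocyst: 8 founders undergoing 5 division
    cycles (≈256 cells) with a baseline ICM allocation probability of 0.25.
    """

    p0: float
    n_founders: int = 8
    n_cycles: int = 5
    selection_bias: float = 0.0
    allocation_bias: float = 0.0
    icm_base_prob: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0.0 <= self.selection_bias <= 1.0:
            raise ValueError("selection_bias must lie in [0, 1]")
        if not 0.0 <= self.allocation_bias <= 1.0:
            raise ValueError("allocation_bias must lie in [0, 1]")
        if not 0.0 < self.icm_base_prob < 1.0:
            raise ValueError("icm_base_prob must lie in (0, 1)")

    @property
    def n_positive_founders(self) -> int:
        # Deterministic half-up rounding so p0 is exactly representable at
        # small founder counts (a Bernoulli draw would add founder noise).
        return int(math.floor(self.p0 * self.n_founders + 0.5))


@dataclass(frozen=True)
class ABMResult:
    """Outcome of one simulated embryo."""

    icm_positive_fraction: float | None
    te_positive_fraction: float | None
    trajectory: tuple[tuple[int, int], ...]  # (positive, negative) per cycle
    seed: int
    icm_counts: tuple[int, int] = (0, 0)
    te_counts: tuple[int, int] = (0, 0)


def simulate_embryo(params: ABMParams, seed: int) -> ABMResult:
    """Run one embryo to allocation; identical seeds give identical results.

    If every cell dies before allocation the result carries absent fractions
    and a warning is logged rather than raising.
    """
    rng = np.random.default_rng(seed)
    s = params.selection_bias
    q = params.icm_base_prob
    a = params.allocation_bias

    pos = params.n_positive_founders
    neg = params.n_founders - pos
    trajectory = [(pos, neg)]
    for _ in range(params.n_cycles):
        # Every surviving cell divides; each positive daughter independently
        # dies with probability s, negative daughters always survive.
        pos = int(rng.binomial(2 * pos, 1.0 - s)) if pos > 0 else 0
        neg = 2 * neg
        trajectory.append((pos, neg))

    if pos + neg == 0:
        logger.warning("all cells dead before allocation (seed=%d)", seed)
        return ABMResult(None, None, tuple(trajectory), seed)

    icm_pos = int(rng.binomial(pos, q * (1.0 - a))) if pos > 0 else 0
    icm_neg = int(rng.binomial(neg, q)) if neg > 0 else 0
    te_pos = pos - icm_pos
    te_neg = neg - icm_neg

    icm_total = icm_pos + icm_neg
    te_total = te_pos + te_neg
    return ABMResult(
        icm_positive_fraction=icm_pos / icm_total if icm_total else None,
        te_positive_fraction=te_pos / te_total if te_total else None,
        trajectory=tuple(trajectory),
        seed=seed,
        icm_counts=(icm_pos, icm_neg),
        te_counts=(te_pos, te_neg),
    )


def expected_icm_fraction(params: ABMParams) -> float:
    """Closed-form expected ICM SMC/SV+ fraction.

    Derivation: positives grow in expectation by a factor 2(1−s) per cycle
    and negatives by 2, so after c cycles the positive share is
    p0(1−s)^c / (p0(1−s)^c + (1−p0)); ICM allocation further thins positives
    by (1−a).  Raises when no cells survive in expectation.
    """
    p0, s, a, c = (
        params.p0,
        params.selection_bias,
        params.allocation_bias,
        params.n_cycles,
    )
    num = p0 * (1.0 - s) ** c * (1.0 - a)
    den = num + (1.0 - p0)
    if den == 0.0:
        raise ValueError("no surviving ICM cells in expectation")
    return num / den


@dataclass(frozen=True)
class SweepMatrix:
    """Mean ICM SMC/SV+ fraction over a (p0 × selection bias) grid."""

    p0_grid: tuple[float, ...]
    s_grid: tuple[float, ...]
    mean_icm_fraction: np.ndarray  # shape (len(p0_grid), len(s_grid)); NaN = missing
    n_reps: int
    n_empty: np.ndarray = field(default=None)  # runs with an empty ICM per cell

    def to_tsv(self) -> str:
        lines = ["p0\\s\t" + "\t".join(f"{s:g}" for s in self.s_grid)]
        for i, p0 in enumerate(self.p0_grid):
            row = "\t".join(
                "NA" if np.isnan(v) else f"{v:.6f}"
                for v in self.mean_icm_fraction[i]
            )
            lines.append(f"{p0:g}\t{row}")
        return "\n".join(lines) + "\n"


def _replicate_seed(base_seed: int, i: int, j: int, r: int) -> int:
    ss = np.random.SeedSequence([base_seed, i, j, r])
    return int(ss.generate_state(1, np.uint64)[0])


def run_sweep(
    p0_grid: Sequence[float],
    s_grid: Sequence[float],
    reps: int,
    base_seed: int,
    params: ABMParams | None = None,
) -> SweepMatrix:
    """Replicate the simulator over a grid of initial fractions and biases.

    Per-cell replicate seeds derive deterministically from ``base_seed`` and
    the grid/replicate indices, so sweeps are reproducible.  Replicates with
    an empty ICM are excluded from the mean and counted; a cell where every
    replicate is empty is marked missing (NaN).
    """
    if len(p0_grid) == 0 or len(s_grid) == 0:
        raise ValueError("grids must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    template = params or ABMParams(p0=0.5)

    means = np.full((len(p0_grid), len(s_grid)), np.nan)
    empties = np.zeros((len(p0_grid), len(s_grid)), dtype=int)
    for i, p0 in enumerate(p0_grid):
        for j, s in enumerate(s_grid):
            cell_params = ABMParams(
                p0=p0,
                n_founders=template.n_founders,
                n_cycles=template.n_cycles,
                selection_bias=s,
                allocation_bias=template.allocation_bias,
                icm_base_prob=template.icm_base_prob,
            )
            vals = []
            for r in range(reps):
                res = simulate_embryo(
                    cell_params, _replicate_seed(base_seed, i, j, r)
                )
                if res.icm_positive_fraction is None:
                    empties[i, j] += 1
                else:
                    vals.append(res.icm_positive_fraction)
            if vals:
                means[i, j] = float(np.mean(vals))
    return SweepMatrix(
        p0_grid=tuple(p0_grid),
        s_grid=tuple(s_grid),
        mean_icm_fraction=means,
        n_reps=reps,
        n_empty=empties,
    )
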