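"""Synthetic parent–offspring transmission tables with known ground truth.

The generator emulates the statistical structure of the literature case
table: parents are either constitutional (100%) carriers or mosaic with a
beta-distributed ratio; offspring ratios are shrunk toward lower values by a
selection process with effective per-cycle strength ``s_eff`` acting over
``c`` cycles (the same closed form as the agent-based model with no
allocation bias); and the observed offspring ratio is a binomial draw over a
realistic number of scored metaphases.  Because the truth (s_eff, c, each
case's latent mean) is recorded, generated tables support end-to-end
parameter-recovery and null-calibration testing of the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cases import Origin, RatioValue, TransmissionCase

__all__ = ["GenParams", "shepherd_expected_ratio", "generate_case_table"]


@dataclass(frozen=True)
class GenParams:
    """Generator configuration.

    Defaults mirror the reference table: about half the parents are
    constitutional carriers (prob_constitutional = 0.5), mosaic parents have
    symmetric mid-range ratios (Beta(2, 2)), selection is mild
    (s_eff = 0.05 over c = 5 cycles), and metaphase denominators span the
    20–100 cells typically scored clinically.
    """

    n_cases: int = 500
    prob_constitutional: float = 0.5
    parent_beta_params: tuple[float, float] = (2.0, 2.0)
    s_eff: float = 0.05
    c: int = 5
    metaphase_range: tuple[int, int] = (20, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not 0.0 <= self.prob_constitutional <= 1.0:
            raise ValueError("prob_constitutional must lie in [0, 1]")
        if any(p <= 0 for p in self.parent_beta_params):
            raise ValueError("parent beta parameters must be positive")
        if not 0.0 <= self.s_eff <= 1.0:
            raise ValueError("s_eff must lie in [0, 1]")
        if self.c < 0:
            raise ValueError("c must be non-negative")
        lo, hi = self.metaphase_range
        if lo < 10 or hi < lo:
            raise ValueError("metaphase_range must satisfy 10 <= min <= max")


def shepherd_expected_ratio(x: float, s_eff: float, c: int) -> float:
    """Expected offspring ratio after selection: x(1-s)^c / (x(1-s)^c + 1 - x).

    Identical to the agent-based model's expected ICM fraction with no
    allocation bias.  Fixed points at x = 0 and x = 1 (no competing clone);
    strictly below x elsewhere whenever s_eff > 0.
    """
    num = x * (1.0 - s_eff) ** c
    return num / (num + (1.0 - x))


def generate_case_table(
    gp: GenParams,
) -> tuple[list[TransmissionCase], dict]:
    """Draw a synthetic case table plus a ground-truth record.

    Per case: the parent is constitutional (ratio 1.0) with probability
    ``prob_constitutional``, else mosaic with a Beta draw; the latent
    offspring mean comes from :func:`shepherd_expected_ratio`; the observed
    offspring ratio is Binomial(m, mean)/m with m uniform over
    ``metaphase_range``.  A fixed seed yields an identical table.
    """
    rng = np.random.default_rng(gp.seed)
    a, b = gp.parent_beta_params
    lo, hi = gp.metaphase_range

    cases: list[TransmissionCase] = []
    truth_cases = []
    for i in range(gp.n_cases):
        constitutional = bool(rng.random() < gp.prob_constitutional)
        parent = 1.0 if constitutional else float(rng.beta(a, b))
        mu = shepherd_expected_ratio(parent, gp.s_eff, gp.c)
        m = int(rng.integers(lo, hi + 1))
        observed = int(rng.binomial(m, mu)) / m
        origin = Origin.MATERNAL if rng.random() < 0.5 else Origin.PATERNAL
        cases.append(
            TransmissionCase(
                case_id=f"S{i + 1:04d}",
                smc_type="synthetic SMC",
                offspring_ratio=RatioValue.point(observed),
                parent_ratio=RatioValue.point(parent),
                origin=origin,
                offspring_phenotype="Phenotypically normal",
                parent_phenotype="Phenotypically normal",
                mechanism="synthetic",
                source="synthetic",
            )
        )
        truth_cases.append(
            {
                "case_id": f"S{i + 1:04d}",
                "constitutional": constitutional,
                "parent_ratio": parent,
                "expected_offspring_ratio": mu,
                "metaphases": m,
                "observed_offspring_ratio": observed,
            }
        )
    truth = {
        "s_eff": gp.s_eff,
        "c": gp.c,
        "seed": gp.seed,
        "cases": truth_cases,
    }
    return cases, truth
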