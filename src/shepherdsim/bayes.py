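"""Beta-binomial test of systematic mosaic reduction across generations.

Each usable parent–offspring pair is a Bernoulli trial: a "success" is a
transmission in which the offspring mosaic ratio fell (strictly lower, or
lower-or-comparable under a tolerance band).  With a Beta(alpha, beta) prior
on the per-transmission reduction rate theta, the posterior after s successes
in n trials is Beta(alpha + s, beta + n - s) by conjugacy, and

    P(theta > 1/2 | data)

measures how strongly the data reject random inheritance (under which the
offspring ratio is as likely to rise as to fall, theta = 1/2).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import beta as beta_dist

from .cases import TransmissionCase, TransmissionClass, classify_transmission

__all__ = [
    "BetaPosterior",
    "ReductionRule",
    "HypothesisResult",
    "count_reduction_events",
    "posterior_update",
    "prob_reduction",
    "credible_interval",
    "reduction_test",
]


@dataclass(frozen=True)
class BetaPosterior:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


UNIFORM_PRIOR = BetaPosterior(1.0, 1.0)


class ReductionRule(enum.Enum):
    STRICT_LOWER = "strict_lower"
    LOWER_OR_COMPARABLE = "lower_or_comparable"


def count_reduction_events(
    cases: Sequence[TransmissionCase],
    rule: ReductionRule = ReductionRule.STRICT_LOWER,
    tolerance: float = 0.10,
) -> tuple[int, int]:
    """Count reduction successes and usable trials over the case table."""
    successes = 0
    trials = 0
    for case in cases:
        cls = classify_transmission(case, tolerance)
        if cls is TransmissionClass.UNDETERMINED:
            continue
        trials += 1
        if cls is TransmissionClass.LOWER:
            successes += 1
        elif (
            cls is TransmissionClass.COMPARABLE
            and rule is ReductionRule.LOWER_OR_COMPARABLE
        ):
            successes += 1
    if trials == 0:
        raise ValueError("no usable parent–offspring pairs")
    return successes, trials


def posterior_update(
    prior: BetaPosterior, successes: int, trials: int
) -> BetaPosterior:
    """Conjugate update: Beta(a, b) + (s, n) -> Beta(a + s, b + n - s)."""
    if successes < 0 or trials < 0 or successes > trials:
        raise ValueError("require 0 <= successes <= trials")
    return BetaPosterior(prior.alpha + successes, prior.beta + trials - successes)


def prob_reduction(post: BetaPosterior, threshold: float = 0.5) -> float:
    """P(theta > threshold) under the posterior (regularized incomplete beta)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return float(beta_dist.sf(threshold, post.alpha, post.beta))


def credible_interval(
    post: BetaPosterior, level: float = 0.95
) -> tuple[float, float]:
    """Central credible interval from beta quantiles."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo = float(beta_dist.ppf(alpha, post.alpha, post.beta))
    hi = float(beta_dist.ppf(1.0 - alpha, post.alpha, post.beta))
    return lo, hi


@dataclass(frozen=True)
class HypothesisResult:
    prob_reduction: float
    credible_interval: tuple[float, float]
    successes: int
    trials: int
    posterior: BetaPosterior

    def to_dict(self) -> dict:
        return {
            "prob_reduction": self.prob_reduction,
            "credible_interval": list(self.credible_interval),
            "successes": self.successes,
            "trials": self.trials,
            "posterior": {"alpha": self.posterior.alpha, "beta": self.posterior.beta},
        }


def reduction_test(
    cases: Sequence[TransmissionCase],
    prior: BetaPosterior = UNIFORM_PRIOR,
    rule: ReductionRule = ReductionRule.STRICT_LOWER,
    tolerance: float = 0.10,
    threshold: float = 0.5,
    level: float = 0.95,
) -> HypothesisResult:
    """Full pipeline: count events, update the prior, summarize the posterior."""
    successes, trials = count_reduction_events(cases, rule, tolerance)
    post = posterior_update(prior, successes, trials)
    return HypothesisResult(
        prob_reduction=prob_reduction(post, threshold),
        credible_interval=credible_interval(post, level),
        successes=successes,
        trials=trials,
        posterior=post,
    )
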