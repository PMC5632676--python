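"""Net diversification rate estimators from species counts and clade ages.

The method-of-moments estimators of Magallón & Sanderson (2001): given an
extant species count ``n``, a clade age ``t`` (crown or stem, in My), and a
relative extinction fraction ``epsilon`` = mu/lambda, the net
diversification rate r = lambda - mu (species per My) is

    stem,  eps = 0:   r = ln(n) / t
    crown, eps = 0:   r = ln(n/2) / t
    stem,  eps > 0:   r = ln(n (1 - eps) + eps) / t
    crown, eps > 0:   r = (1/t) * [ ln( n (1 - eps^2) / 2 + 2 eps
                        + (1 - eps) / 2 * sqrt( n (n eps^2 + 2 n eps
                        - 8 eps + n) ) ) - ln 2 ]

The eps > 0 forms reduce continuously to the eps = 0 closed forms.  For a
crown age the count must be >= 2 (a crown group has two daughter lineages
by definition); higher extinction always lowers the estimated rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DiversificationInput", "net_diversification"]


@dataclass(frozen=True)
class DiversificationInput:
    """Inputs to the rate estimator.

    n_species: extant species count (>= 2 for crown ages, >= 1 for stem).
    age: clade age in My (> 0).
    age_type: "crown" or "stem".
    epsilon: relative extinction fraction mu/lambda in [0, 1).
    """

    n_species: int
    age: float
    age_type: str = "crown"
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.age_type not in ("crown", "stem"):
            raise ValueError("age_type must be 'crown' or 'stem'")
        if self.age <= 0:
            raise ValueError("age must be > 0")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")
        floor = 2 if self.age_type == "crown" else 1
        if self.n_species < floor:
            raise ValueError(
                f"n_species must be >= {floor} for a {self.age_type} age"
            )


def net_diversification(inp: DiversificationInput) -> float:
    """Net diversification rate (species/My) for the given clade."""
    n, t, eps = inp.n_species, inp.age, inp.epsilon
    if inp.age_type == "stem":
        if eps == 0.0:
            return math.log(n) / t
        return math.log(n * (1.0 - eps) + eps) / t
    if eps == 0.0:
        return math.log(n / 2.0) / t
    inner = (
        n * (1.0 - eps * eps) / 2.0
        + 2.0 * eps
        + (1.0 - eps) / 2.0 * math.sqrt(n * (n * eps * eps + 2.0 * n * eps - 8.0 * eps + n))
    )
    return (math.log(inner) - math.log(2.0)) / t
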