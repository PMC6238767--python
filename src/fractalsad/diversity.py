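"""Hill numbers and Renyi entropy.

The Hill number of order ``a`` over relative abundances ``w_i`` is

    N_a = (sum_i w_i**a) ** (1/(1-a)),

an "effective number of species": the richness of a perfectly even community
with the same diversity.  Special orders are taken analytically — richness at
a = 0, the exponential of Shannon entropy at a = 1 (the continuity limit),
inverse Simpson concentration at a = 2, and the dominance ratio at a = inf:

    N_inf = 1 / max(w_i) = A_T / A_1,

which is exactly the partial generalized harmonic sum of the fractal SAD
model.  The Renyi entropy of order ``a`` is ``ln(N_a)``.

Infinity is passed as the ordinary float ``math.inf`` and handled as an
explicit sentinel, never approximated by a large finite order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import RankAbundance
from .errors import InvalidArgumentError

__all__ = ["DiversityProfile", "hill_number", "renyi_entropy", "diversity_profile"]


@dataclass(frozen=True)
class DiversityProfile:
    """Hill numbers evaluated on a grid of orders for one sample.

    ``orders`` may include ``math.inf``.  Hill numbers lie in [1, S] and are
    non-increasing in the order: raising ``a`` weights dominant species more
    heavily, so the effective richness can only shrink.
    """

    sample_id: str
    orders: tuple[float, ...]
    hill_numbers: tuple[float, ...]


def hill_number(sample: RankAbundance, a: float) -> float:
    """Effective number of species of order ``a`` for one sample.

    Parameters
    ----------
    sample : RankAbundance
    a : float
        Non-negative order; ``math.inf`` selects the dominance limit
        ``A_T / A_1`` (computed exactly from the sample totals, not through
        the normalised weights).

    Raises
    ------
    InvalidArgumentError
        If ``a`` is negative or NaN.
    """
    if math.isnan(a) or a < 0:
        raise InvalidArgumentError(f"order must be >= 0, got {a!r}")
    if math.isinf(a):
        return sample.A_T / sample.abundances[0]
    if a == 0:
        return float(sample.S)
    w = sample.relative()
    if a == 1:
        # Shannon limit: exp(-sum w ln w); w > 0 always holds here
        return float(np.exp(-np.sum(w * np.log(w))))
    return float(np.sum(w ** a) ** (1.0 / (1.0 - a)))


def renyi_entropy(sample: RankAbundance, a: float) -> float:
    """Renyi entropy of order ``a`` in nats: ``ln(hill_number(sample, a))``.

    Order 1 is Shannon entropy; order 0 is ``ln(S)``.
    """
    return math.log(hill_number(sample, a))


def diversity_profile(sample: RankAbundance, orders: Sequence[float]) -> DiversityProfile:
    """Evaluate Hill numbers on a grid of orders (a diversity profile)."""
    vals = tuple(hill_number(sample, a) for a in orders)
    return DiversityProfile(
        sample_id=sample.sample_id, orders=tuple(float(a) for a in orders), hill_numbers=vals
    )
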