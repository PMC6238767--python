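"""Seeded generators for communities with known rank-abundance structure.

Three models, selected by :class:`SyntheticSpec.model`:

``exact_power_law``
    The noise-free forward model ``A_r = r**(-p_true)``; the estimator must
    recover ``p_true`` to machine precision on this output.

``multinomial_power_law``
    N individuals drawn multinomially from S species whose expected relative
    abundances follow ``r**(-p_true)``.  Species with zero draws are removed
    and the result re-ranked, mirroring real surveys where only detected
    species are recorded.  This is the sampling-noise layer used for
    parameter-recovery experiments.

``fractal_accumulation``
    The stepwise fractal process behind the power law: the community starts
    with one species of abundance 1, and at every step K = k**d new species
    appear, each k times less abundant than those added the step before.
    After step j the community holds ceil(K**j) species and the newcomers
    have abundance k**(-j).  The resulting staircase approximates
    ``A_r ~ r**(-1/d)``, so the estimator should recover p ~ 1/d.

All generators are deterministic given the spec (including its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import RankAbundance, predict_sad
from .errors import InvalidSpecError

__all__ = [
    "SyntheticSpec",
    "generate",
    "generate_exact",
    "generate_multinomial",
    "generate_accumulation",
]

MODELS = ("exact_power_law", "multinomial_power_law", "fractal_accumulation")


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration for one synthetic community.

    Defaults correspond to the standard recovery experiment: a Zipf community
    (p_true = 1) of 100 species sampled at 10^5 individuals, and the doubling
    accumulation process (d = 1, k = 2) run for 10 steps.
    """

    model: str
    p_true: float = 1.0
    S: int = 100
    N: int = 100_000
    d: float = 1.0
    k: float = 2.0
    n_steps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise InvalidSpecError(
                f"unknown model {self.model!r}; expected one of {MODELS}"
            )


def _require(spec: SyntheticSpec, model: str) -> None:
    if spec.model != model:
        raise InvalidSpecError(f"spec has model {spec.model!r}, expected {model!r}")


def generate(spec: SyntheticSpec) -> RankAbundance:
    """Dispatch to the generator named by ``spec.model``."""
    if spec.model == "exact_power_law":
        return generate_exact(spec)
    if spec.model == "multinomial_power_law":
        return generate_multinomial(spec)
    return generate_accumulation(spec)


def generate_exact(spec: SyntheticSpec) -> RankAbundance:
    """Noise-free power-law SAD: ``predict_sad(p_true, S)``.  Seed ignored."""
    _require(spec, "exact_power_law")
    if spec.S < 1:
        raise InvalidSpecError(f"S must be >= 1, got {spec.S}")
    sad = predict_sad(spec.p_true, spec.S, sample_id=f"exact_p{spec.p_true:g}_S{spec.S}")
    return replace(sad, group="synthetic")


def generate_multinomial(spec: SyntheticSpec) -> RankAbundance:
    """Multinomial sample of N individuals from a power-law community.

    Expected relative abundance of the r-th species is proportional to
    ``r**(-p_true)``.  Unobserved species are dropped and the observed counts
    re-ranked non-increasing (ties keep the expected-rank order, so output is
    reproducible).  A single integer seed fully determines the draw.
    """
    _require(spec, "multinomial_power_law")
    if spec.N < 1:
        raise InvalidSpecError(f"N must be >= 1, got {spec.N}")
    if spec.S < 2:
        raise InvalidSpecError(f"S must be >= 2, got {spec.S}")
    r = np.arange(1, spec.S + 1, dtype=float)
    w = r ** (-spec.p_true)
    w /= w.sum()
    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.N, w)
    labels = [f"sp{j + 1}" for j in range(spec.S)]
    return RankAbundance.from_counts(
        f"multinomial_p{spec.p_true:g}_S{spec.S}_N{spec.N}_seed{spec.seed}",
        counts,
        species=labels,
        group="synthetic",
    )


def generate_accumulation(spec: SyntheticSpec) -> RankAbundance:
    """Deterministic stepwise fractal accumulation.

    Step 0 holds one species of abundance 1.  After step j >= 1 the community
    holds ``ceil(K**j)`` species (K = k**d); the species added at step j each
    have abundance ``k**(-j)``.  Non-integer K**j is ceiled, and the number
    of newcomers at step j is ``ceil(K**j) - ceil(K**(j-1))``, so richness is
    exactly reproducible for fractal (non-integer) dimensions too.
    """
    _require(spec, "fractal_accumulation")
    if not (spec.d > 0):
        raise InvalidSpecError(f"d must be > 0, got {spec.d}")
    if not (spec.k > 1):
        raise InvalidSpecError(f"k must be > 1, got {spec.k}")
    if spec.n_steps < 0:
        raise InvalidSpecError(f"n_steps must be >= 0, got {spec.n_steps}")
    K = spec.k ** spec.d
    parts = [np.ones(1)]
    prev_total = 1
    for j in range(1, spec.n_steps + 1):
        total = math.ceil(K ** j)
        new = total - prev_total
        if new > 0:
            parts.append(np.full(new, spec.k ** (-j)))
        prev_total = max(prev_total, total)
    ab = np.concatenate(parts)
    return RankAbundance(
        sample_id=f"accum_d{spec.d:g}_k{spec.k:g}_steps{spec.n_steps}",
        abundances=ab,
        group="synthetic",
    )
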