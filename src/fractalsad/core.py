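"""The fractal rank-abundance model and its closed-form exponent estimator.

A community's species abundance distribution (SAD) is modelled as a power law
over abundance ranks,

    A_r / A_1 = r**(-p),    r = 1, 2, ..., S,

where ``A_r`` is the abundance of the r-th most abundant species, ``S`` the
species richness, and ``p`` the fractal parameter (the reciprocal of the
fractal dimension ``d`` of the stepwise accumulation hypothesis; ``p = 1`` is
Zipf's law).  With ``F_r = ln(A_r/A_1)`` and ``D_r = ln(r)`` the model is a
line through the origin in log-log space, and minimising the sum of squared
errors ``sum((-p*D_r - F_r)**2)`` gives the closed form

    p = -sum(D_r * F_r) / sum(D_r**2).

This module houses that estimator, the model's forward prediction, the
log-scale goodness of fit, and the harmonic-series machinery connecting the
dominance ratio ``A_T/A_1`` to effective species numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DivergentSeriesError,
    InsufficientRanksError,
    InvalidArgumentError,
    InvalidSampleError,
)

__all__ = [
    "RankAbundance",
    "FractalFit",
    "predict_sad",
    "estimate_p",
    "r_squared_log",
    "effective_species_finite",
    "effective_species_infinite",
    "harmonic_gap",
]

# Summation chunk for very large richness values; keeps peak memory flat.
_CHUNK = 1_000_000


@dataclass(frozen=True)
class RankAbundance:
    """One community sample: abundances sorted non-increasing.

    Parameters
    ----------
    sample_id : str
        Label identifying the sample.
    abundances : numpy.ndarray
        Strictly positive values sorted non-increasing.  Counts, densities or
        relative abundances are all acceptable; the model is scale invariant.
    group : str, optional
        Label of the source dataset (used by the survey layer).
    ranked : bool
        When True (default) the ordering invariant is enforced.  Model-
        generated vectors with a negative exponent are increasing in the rank
        index by construction; :func:`predict_sad` builds those with
        ``ranked=False`` so that the exponent remains recoverable.  Empirical
        data always go through :meth:`from_counts`, which sorts.

    Raises
    ------
    InvalidSampleError
        If any abundance is non-positive or the ordering is violated.  Use
        :meth:`from_counts` to build a sample from raw, unsorted records.
    """

    sample_id: str
    abundances: np.ndarray
    group: str | None = None
    ranked: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.abundances, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InvalidSampleError(
                f"sample {self.sample_id!r}: abundances must be a non-empty 1-d sequence"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidSampleError(f"sample {self.sample_id!r}: non-finite abundance")
        if np.any(arr <= 0):
            raise InvalidSampleError(
                f"sample {self.sample_id!r}: abundances must be strictly positive"
            )
        if self.ranked and np.any(arr[:-1] < arr[1:]):
            raise InvalidSampleError(
                f"sample {self.sample_id!r}: abundances must be sorted non-increasing"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "abundances", arr)

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        values: Sequence[float],
        *,
        species: Sequence[str] | None = None,
        group: str | None = None,
    ) -> "RankAbundance":
        """Build a sample from raw records: drop zeros, rank non-increasing.

        Zero abundances are removed (only detected species enter the ranking);
        negative values are an error.  Ties are broken stably by the order of
        ``species`` labels (or input order when labels are absent), so ranks
        are reproducible.
        """
        arr = np.asarray(values, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            raise InvalidSampleError(
                f"sample {sample_id!r}: abundances must be finite and non-negative"
            )
        keep = arr > 0
        arr = arr[keep]
        if arr.size == 0:
            raise InvalidSampleError(f"sample {sample_id!r}: no positive abundances")
        if species is not None:
            labels = np.asarray(species, dtype=object)[keep]
            order = np.lexsort((labels, -arr))
        else:
            # mergesort is stable: equal abundances keep input order
            order = np.argsort(-arr, kind="mergesort")
        return cls(sample_id=sample_id, abundances=arr[order], group=group)

    @property
    def S(self) -> int:
        """Species richness (number of ranked species)."""
        return int(self.abundances.size)

    @property
    def A_T(self) -> float:
        """Total abundance (sum over species)."""
        return float(self.abundances.sum())

    @property
    def A_1(self) -> float:
        """Abundance of the dominant (rank-1) species."""
        return float(self.abundances[0])

    def relative(self) -> np.ndarray:
        """Relative abundances w_i = A_i / A_T (sum to 1)."""
        return self.abundances / self.abundances.sum()


@dataclass(frozen=True)
class FractalFit:
    """Result of fitting the rank-abundance power law to one sample.

    ``p`` is the estimated exponent, ``r_squared`` the goodness of fit on the
    log-transformed variables (log rank vs. log relative abundance), ``S`` the
    richness, and ``n_used`` the number of ranks entering the estimator's sums
    (all S ranks; the r = 1 term contributes zero to both).  ``A_T`` and
    ``group`` are copied from the sample for downstream reporting.
    """

    sample_id: str
    p: float
    r_squared: float
    S: int
    n_used: int
    A_T: float = float("nan")
    group: str | None = None


def _log_terms(sample: RankAbundance) -> tuple[np.ndarray, np.ndarray]:
    a = sample.abundances
    F = np.log(a / a[0])
    D = np.log(np.arange(1, a.size + 1, dtype=float))
    return F, D


def predict_sad(p: float, S: int, A1: float = 1.0, *, sample_id: str = "predicted") -> RankAbundance:
    """Forward model: abundances ``A1 * r**(-p)`` for ranks r = 1..S.

    Parameters
    ----------
    p : float
        Rank-abundance exponent.  ``p = 0`` gives a perfectly even (flat) SAD,
        ``p = 1`` Zipf's law; any real value is accepted.
    S : int
        Species richness, at least 1.
    A1 : float
        Abundance of the dominant species (default 1, i.e. relative scale).

    Returns
    -------
    RankAbundance

    Examples
    --------
    >>> predict_sad(1, 6).abundances.tolist()
    [1.0, 0.5, 0.3333333333333333, 0.25, 0.2, 0.16666666666666666]
    """
    if S < 1 or int(S) != S:
        raise InvalidArgumentError(f"S must be a positive integer, got {S!r}")
    if not (A1 > 0):
        raise InvalidArgumentError(f"A1 must be positive, got {A1!r}")
    if not math.isfinite(p):
        raise InvalidArgumentError(f"p must be finite, got {p!r}")
    r = np.arange(1, int(S) + 1, dtype=float)
    ab = A1 * r ** (-float(p))
    return RankAbundance(sample_id=sample_id, abundances=ab, ranked=p >= 0)


def estimate_p(sample: RankAbundance) -> FractalFit:
    """Closed-form least-squares estimate of the rank-abundance exponent.

    Minimises ``sum((-p*D_r - F_r)**2)`` over p, a line through the origin in
    log-log space, giving ``p = -sum(D_r*F_r) / sum(D_r**2)``.  The fit
    quality is the centered R-squared of :func:`r_squared_log`.

    The sign of p is reported as computed: inverted or unusually even
    communities can yield p <= 0 and surveys keep whatever the estimator
    returns.

    Raises
    ------
    InsufficientRanksError
        If the sample has fewer than two species (the denominator
        ``sum(D_r**2)`` would be zero).
    """
    if sample.S < 2:
        raise InsufficientRanksError(
            f"sample {sample.sample_id!r}: need S >= 2 to estimate p (got S={sample.S})"
        )
    F, D = _log_terms(sample)
    p = float(-(D @ F) / (D @ D))
    r2 = r_squared_log(sample, p)
    return FractalFit(
        sample_id=sample.sample_id,
        p=p,
        r_squared=r2,
        S=sample.S,
        n_used=sample.S,
        A_T=sample.A_T,
        group=sample.group,
    )


def r_squared_log(sample: RankAbundance, p: float, *, centered: bool = True) -> float:
    """Goodness of fit of the power law on the log-transformed variables.

    ``R^2 = 1 - SS_res / SS_tot`` with ``SS_res = sum((F_r + p*D_r)**2)``.
    With ``centered=True`` (default) the total sum of squares is taken about
    the mean of ``F_r``; the uncentered variant uses ``sum(F_r**2)``.  The
    centered form is bounded above by 1 and can be negative when the
    through-origin power law fits worse than a flat line.  A flat SAD fitted
    with p = 0 has ``SS_tot = SS_res = 0`` and returns 1 by convention
    (zero residuals are a perfect fit).
    """
    if sample.S < 2:
        raise InsufficientRanksError(
            f"sample {sample.sample_id!r}: need S >= 2 for R^2 (got S={sample.S})"
        )
    if not math.isfinite(p):
        raise InvalidArgumentError(f"p must be finite, got {p!r}")
    F, D = _log_terms(sample)
    resid = F + p * D
    ss_res = float(resid @ resid)
    if centered:
        dev = F - F.mean()
        ss_tot = float(dev @ dev)
    else:
        ss_tot = float(F @ F)
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


def _power_sum(p: float, S: int) -> float:
    """sum of r**(-p) for r = 1..S, chunked so S ~ 1e8 stays in memory."""
    total = 0.0
    start = 1
    while start <= S:
        stop = min(S, start + _CHUNK - 1)
        r = np.arange(start, stop + 1, dtype=float)
        total += float(np.sum(r ** (-p)))
        start = stop + 1
    return total


def effective_species_finite(p: float, S: int) -> float:
    """Partial generalized harmonic sum ``A_T/A_1 = sum_{r=1}^{S} r**(-p)``.

    Under the power-law SAD this equals the dominance ratio A_T/A_1, which is
    the effective number of species of order infinity.  Equals S at p = 0 and
    the S-th harmonic number at p = 1.
    """
    if S < 1 or int(S) != S:
        raise InvalidArgumentError(f"S must be a positive integer, got {S!r}")
    if not math.isfinite(p):
        raise InvalidArgumentError(f"p must be finite, got {p!r}")
    return _power_sum(float(p), int(S))


def effective_species_infinite(p: float, tol: float = 1e-10) -> float:
    """Infinite-richness limit ``sum_{r>=1} r**(-p)`` (the zeta value).

    The series converges exactly when p > 1; for p <= 1 it diverges (p = 1 is
    Zipf's law, the boundary case) and a :class:`DivergentSeriesError` is
    raised — that is the contract, not a failure.

    The value is computed as a partial sum to N plus the integral tail
    ``N**(1-p)/(p-1)`` refined by two Euler–Maclaurin correction terms
    (``-N**(-p)/2 + p*N**(-p-1)/12``); N is grown until the magnitude of the
    first neglected term, ``p(p+1)(p+2)/720 * N**(-p-3)``, is below ``tol``.
    """
    if not (tol > 0):
        raise InvalidArgumentError(f"tol must be positive, got {tol!r}")
    if not math.isfinite(p):
        raise InvalidArgumentError(f"p must be finite, got {p!r}")
    if p <= 1:
        raise DivergentSeriesError(
            f"sum of r**(-p) diverges for p <= 1 (got p={p}); "
            "the effective number of species is unbounded"
        )
    N = 10
    while p * (p + 1) * (p + 2) / 720.0 * N ** (-p - 3) >= tol:
        N *= 2
    partial = _power_sum(p, N)
    tail = N ** (1 - p) / (p - 1) - 0.5 * N ** (-p) + p / 12.0 * N ** (-p - 1.0)
    return partial + tail


def harmonic_gap(S: int) -> float:
    """``H_S - ln(S)``: the harmonic number minus the log of its index.

    Non-increasing in S and converging to the Euler–Mascheroni constant
    (gamma ~ 0.5772156649) — the Zipf-law (p = 1) community's dominance ratio
    exceeds ``ln(S)`` by an amount shrinking to gamma.
    """
    if S < 1 or int(S) != S:
        raise InvalidArgumentError(f"S must be a positive integer, got {S!r}")
    return _power_sum(1.0, int(S)) - math.log(S)
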