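"""Batch fitting and summary statistics over collections of samples.

This is the empirical pipeline: fit the rank-abundance exponent to every
sample in one or more datasets, then reduce the fitted exponents (and their
goodness-of-fit values) to per-group summary rows — maximum, minimum, median,
mean with standard error, sample count — and to binned frequency
distributions of p.  Bins are right-open thirds anchored at zero
([0, 1/3), [1/3, 2/3), ...) by default, matching the intervals in which the
exponent's mode is conventionally reported (0.67–1, 1–1.33, 1.33–1.67).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .core import FractalFit, RankAbundance, estimate_p, r_squared_log
from .errors import EmptyInputError, InsufficientRanksError, InvalidArgumentError

__all__ = [
    "ExclusionRecord",
    "FitCollection",
    "GroupSummary",
    "PHistogram",
    "fit_collection",
    "summarize_group",
    "summarize_by_group",
    "p_histogram",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 1.0 / 3.0


@dataclass(frozen=True)
class ExclusionRecord:
    """One sample dropped from a batch fit, with the reason."""

    sample_id: str
    group: str | None
    reason: str


@dataclass
class FitCollection:
    """Fits from a batch run plus the audit trail of excluded samples.

    Iterating yields the :class:`FractalFit` values in input order.
    """

    fits: list[FractalFit]
    excluded: list[ExclusionRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[FractalFit]:
        return iter(self.fits)

    def __len__(self) -> int:
        return len(self.fits)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass(frozen=True)
class GroupSummary:
    """Summary row for one group and one statistic (p or R^2).

    ``standard_error`` is the sample standard deviation (n-1 denominator)
    divided by sqrt(n); it is 0 for a single fit.  The median uses the
    midpoint convention for even n.
    """

    group: str
    statistic: str
    maximum: float
    minimum: float
    median: float
    mean: float
    standard_error: float
    n_samples: int


@dataclass(frozen=True)
class PHistogram:
    """Binned frequency distribution of fitted exponents for one group.

    ``bin_edges`` ascend from 0 in uniform steps; bin j counts values in the
    right-open interval [edges[j], edges[j+1]).  Negative exponents fall in
    the explicit ``underflow`` count, so ``sum(counts) + underflow`` equals
    the number of fits.
    """

    group: str
    bin_edges: np.ndarray
    counts: np.ndarray
    underflow: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.underflow


def fit_collection(samples: Iterable[RankAbundance]) -> FitCollection:
    """Fit every sample with at least two species; log and count the rest.

    Output order matches input order.  Raises :class:`EmptyInputError` for an
    empty collection.
    """
    fits: list[FractalFit] = []
    excluded: list[ExclusionRecord] = []
    n_in = 0
    for sample in samples:
        n_in += 1
        try:
            fits.append(estimate_p(sample))
        except InsufficientRanksError as err:
            rec = ExclusionRecord(sample.sample_id, sample.group, str(err))
            excluded.append(rec)
            logger.info("excluded %s: %s", sample.sample_id, rec.reason)
    if n_in == 0:
        raise EmptyInputError("no samples to fit")
    return FitCollection(fits=fits, excluded=excluded)


def _extract(fits: Iterable[FractalFit], which: str) -> np.ndarray:
    if which not in ("p", "r_squared"):
        raise InvalidArgumentError(f"statistic must be 'p' or 'r_squared', got {which!r}")
    return np.array([getattr(f, which) for f in fits], dtype=float)


def summarize_group(
    fits: Iterable[FractalFit], which: str = "p", *, group: str = "all"
) -> GroupSummary:
    """Reduce one group's fits to a summary row (max, min, median, mean ± SE)."""
    values = _extract(fits, which)
    if values.size == 0:
        raise EmptyInputError("no fits to summarize")
    n = int(values.size)
    se = 0.0 if n == 1 else float(values.std(ddof=1) / math.sqrt(n))
    return GroupSummary(
        group=group,
        statistic=which,
        maximum=float(values.max()),
        minimum=float(values.min()),
        median=float(np.median(values)),
        mean=float(values.mean()),
        standard_error=se,
        n_samples=n,
    )


def summarize_by_group(
    fits: Iterable[FractalFit], which: str = "p"
) -> list[GroupSummary]:
    """Per-group summary rows plus a final "Total" row over all fits.

    Groups appear in first-seen order; fits with no group label fall under
    ``"ungrouped"``.
    """
    fits = list(fits)
    if not fits:
        raise EmptyInputError("no fits to summarize")
    by_group: dict[str, list[FractalFit]] = {}
    for f in fits:
        by_group.setdefault(f.group or "ungrouped", []).append(f)
    rows = [summarize_group(v, which, group=g) for g, v in by_group.items()]
    if len(rows) > 1:
        rows.append(summarize_group(fits, which, group="Total"))
    return rows


def p_histogram(
    fits: Iterable[FractalFit],
    bin_width: float = DEFAULT_BIN_WIDTH,
    *,
    group: str = "all",
) -> PHistogram:
    """Bin fitted exponents into right-open intervals anchored at zero.

    Edges run from 0 to the smallest multiple of ``bin_width`` strictly
    exceeding the largest exponent; negative exponents are counted in the
    explicit underflow bin.
    """
    if not (bin_width > 0):
        raise InvalidArgumentError(f"bin_width must be positive, got {bin_width!r}")
    values = _extract(fits, "p")
    if values.size == 0:
        raise EmptyInputError("no fits to bin")
    underflow = int((values < 0).sum())
    nonneg = values[values >= 0]
    if nonneg.size == 0:
        edges = np.array([0.0, bin_width])
        counts = np.zeros(1, dtype=int)
    else:
        idx = np.floor(nonneg / bin_width).astype(int)
        n_bins = int(idx.max()) + 1
        counts = np.bincount(idx, minlength=n_bins)
        edges = np.arange(n_bins + 1, dtype=float) * bin_width
    return PHistogram(group=group, bin_edges=edges, counts=counts, underflow=underflow)


def uncentered_r_squared(samples: Iterable[RankAbundance], fits: Iterable[FractalFit]) -> list[float]:
    """Uncentered R^2 (total sum of squares about zero) for fitted samples.

    Companion column for resolving which convention a published table used;
    pairs samples and fits positionally.
    """
    return [
        r_squared_log(s, f.p, centered=False) for s, f in zip(samples, fits)
    ]
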