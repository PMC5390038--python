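"""Kendall tau-b, partial tau-b, and bootstrap confidence intervals.

Tau-b is the tie-corrected rank correlation

    tau_b = (P - Q) / sqrt((P + Q + X0) (P + Q + Y0))

where, over all n(n-1)/2 index pairs, P counts concordant pairs, Q
discordant pairs, X0 pairs tied only in x and Y0 pairs tied only in y;
pairs tied in both rankings enter no term.  The implementation computes
the full P/Q/X0/Y0 decomposition in O(n log n) (lexicographic sort plus
merge-based inversion counting) so the counts stay inspectable while the
bootstrap remains fast.

The partial coefficient removes the rank association shared with a
control ranking f:

    tau_b(x, y | f) = (tau_xy - tau_fx * tau_fy)
                      / sqrt((1 - tau_fx^2) (1 - tau_fy^2))

Confidence intervals are percentile bootstrap (resample word indices
with replacement, sample size n, 1000 replicates by default).  For
comparing two coefficients, the *paired* bootstrap draws one index
resample per replicate and evaluates both statistics on it, so the
interval for the (absolute) difference respects the statistics' shared
data.  Inference is by interval-exclusion-of-zero; no p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TauResult",
    "IntervalEstimate",
    "DegenerateRankingError",
    "kendall_tau_b",
    "partial_tau_b",
    "partial_tau_from_taus",
    "bootstrap_ci",
    "bootstrap_difference_ci",
]


class DegenerateRankingError(ValueError):
    """Raised when tau-b (or partial tau-b) is undefined for the given data."""


@dataclass(frozen=True)
class TauResult:
    """Tau-b with its concordance decomposition."""

    tau: float
    concordant: int
    discordant: int
    ties_x_only: int
    ties_y_only: int
    n: int


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with a percentile-bootstrap confidence interval."""

    point: float
    lower: float
    upper: float
    level: float
    reps: int
    seed: int

    def excludes_zero(self) -> bool:
        return self.lower > 0.0 or self.upper < 0.0


def _count_inversions(a: np.ndarray) -> int:
    """Pairs i < j with a[i] > a[j], by divide and conquer on sorted halves."""

    def rec(seg: np.ndarray) -> tuple[int, np.ndarray]:
        n = seg.size
        if n <= 64:
            return int(np.triu(seg[:, None] > seg[None, :], 1).sum()), np.sort(seg)
        mid = n // 2
        cl, left = rec(seg[:mid])
        cr, right = rec(seg[mid:])
        # each right element is inverted with the left elements strictly above it
        cross = int((left.size - np.searchsorted(left, right, side="right")).sum())
        return cl + cr + cross, np.sort(np.concatenate((left, right)))

    return rec(a)[0]


def _tie_pairs(keys: np.ndarray) -> int:
    """Number of index pairs sharing a key; keys must be sorted."""
    if keys.ndim == 1:
        boundaries = np.flatnonzero(np.diff(keys) != 0)
    else:  # rows
        boundaries = np.flatnonzero(np.any(np.diff(keys, axis=0) != 0, axis=1))
    run_ends = np.concatenate((boundaries + 1, [keys.shape[0]]))
    run_starts = np.concatenate(([0], boundaries + 1))
    runs = run_ends - run_starts
    return int((runs * (runs - 1) // 2).sum())


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> TauResult:
    """Tau-b of two aligned rankings, with the P/Q/X0/Y0 counts.

    Raises :class:`DegenerateRankingError` when either ranking is
    constant (zero denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d sequences")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")

    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]
    n0 = n * (n - 1) // 2
    ties_x = _tie_pairs(xs)                      # tied in x (incl. both)
    ties_y = _tie_pairs(np.sort(y))              # tied in y (incl. both)
    ties_xy = _tie_pairs(np.column_stack((xs, ys)))  # tied in both
    # within equal-x runs ys is ascending, so strict inversions in ys count
    # exactly the discordant pairs
    q = _count_inversions(ys)
    p = n0 - ties_x - ties_y + ties_xy - q
    x0 = ties_x - ties_xy
    y0 = ties_y - ties_xy

    denom = (p + q + x0) * (p + q + y0)
    if denom == 0:
        raise DegenerateRankingError(
            "tau-b undefined: a ranking is constant (all pairs tied)"
        )
    tau = (p - q) / np.sqrt(denom)
    return TauResult(
        tau=float(tau), concordant=p, discordant=q,
        ties_x_only=x0, ties_y_only=y0, n=n,
    )


def partial_tau_from_taus(tau_xy: float, tau_fx: float, tau_fy: float) -> float:
    """Partial tau-b from three precomputed coefficients."""
    if abs(tau_fx) >= 1.0 or abs(tau_fy) >= 1.0:
        raise DegenerateRankingError(
            "partial tau-b undefined: control is perfectly rank-correlated "
            "with a primary variable"
        )
    return (tau_xy - tau_fx * tau_fy) / np.sqrt(
        (1.0 - tau_fx**2) * (1.0 - tau_fy**2)
    )


def partial_tau_b(
    x: Sequence[float], y: Sequence[float], f: Sequence[float]
) -> float:
    """Tau-b of x and y controlling for the ranking by f."""
    tau_xy = kendall_tau_b(x, y).tau
    tau_fx = kendall_tau_b(f, x).tau
    tau_fy = kendall_tau_b(f, y).tau
    return float(partial_tau_from_taus(tau_xy, tau_fx, tau_fy))


Stat = Callable[..., float]


def _resample_stats(
    stats: Sequence[Stat],
    columns: Sequence[np.ndarray],
    reps: int,
    rng: np.random.Generator,
    max_redraw_factor: int = 10,
) -> np.ndarray:
    """(reps, len(stats)) matrix of statistics over shared index resamples.

    A resample on which any statistic is undefined (degenerate ranking)
    is redrawn; total draws are capped at ``max_redraw_factor * reps``.
    """
    n = columns[0].shape[0]
    out = np.empty((reps, len(stats)))
    draws = 0
    filled = 0
    while filled < reps:
        if draws >= max_redraw_factor * reps:
            raise DegenerateRankingError(
                f"bootstrap failed: statistic undefined on too many resamples "
                f"({draws} draws for {reps} replicates)"
            )
        idx = rng.integers(0, n, size=n)
        draws += 1
        cols = [c[idx] for c in columns]
        try:
            for k, stat in enumerate(stats):
                out[filled, k] = stat(*cols)
        except DegenerateRankingError:
            continue
        filled += 1
    return out


def _percentile_interval(values: np.ndarray, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def bootstrap_ci(
    stat: Stat,
    data: Sequence[Sequence[float]],
    reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> IntervalEstimate:
    """Percentile-bootstrap CI for ``stat`` over aligned data columns.

    ``stat`` is called as ``stat(*columns)`` on both the full data (for
    the point estimate) and each index resample.
    """
    columns = [np.asarray(c, dtype=float) for c in data]
    point = float(stat(*columns))
    rng = np.random.default_rng(seed)
    values = _resample_stats([stat], columns, reps, rng)[:, 0]
    lower, upper = _percentile_interval(values, level)
    return IntervalEstimate(
        point=point, lower=lower, upper=upper, level=level, reps=reps, seed=seed
    )


def bootstrap_difference_ci(
    stat_a: Stat,
    stat_b: Stat,
    data: Sequence[Sequence[float]],
    reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    absolute: bool = False,
) -> IntervalEstimate:
    """Paired-bootstrap CI for the difference between two coefficients.

    Each replicate draws one index resample and evaluates both
    statistics on it.  With ``absolute=True`` the replicate value is
    ``|A| - |B|`` (difference of coefficient magnitudes, the natural
    comparison for two negative correlations); otherwise ``A - B``.
    Zero excluded from the interval means the coefficients differ at
    the given level.
    """
    columns = [np.asarray(c, dtype=float) for c in data]
    a0, b0 = float(stat_a(*columns)), float(stat_b(*columns))
    point = abs(a0) - abs(b0) if absolute else a0 - b0
    rng = np.random.default_rng(seed)
    pairs = _resample_stats([stat_a, stat_b], columns, reps, rng)
    if absolute:
        values = np.abs(pairs[:, 0]) - np.abs(pairs[:, 1])
    else:
        values = pairs[:, 0] - pairs[:, 1]
    lower, upper = _percentile_interval(values, level)
    return IntervalEstimate(
        point=point, lower=lower, upper=upper, level=level, reps=reps, seed=seed
    )
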