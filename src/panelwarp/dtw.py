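"""Dynamic time warping for very short time series.

The series handled here are standardized questionnaire-item scores measured
at 4 or 5 assessment waves. Distances use the ``symmetric2`` step pattern —
diagonal steps weigh the local cost twice, horizontal/vertical steps once,
and the first matched cell counts as a diagonal entry — restricted to a
Sakoe-Chiba band so the warping path never strays more than ``window``
assessments from the diagonal. The cumulative cost divided by the sum of
the two series lengths gives a normalized distance that is comparable
between participants with 4 and with 5 complete assessments.

Two implementations are provided: a scalar one that also returns the cost
matrices and the optimal warping path (useful for inspection and plotting),
and a batch one vectorized over many pairs at once, which the distance
pipeline and the simulation studies rely on. ``brute_force_dtw`` enumerates
every admissible path and exists as an independent oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "local_cost",
    "dtw_distance",
    "dtw_distance_batch",
    "brute_force_dtw",
    "WarpingResult",
    "STEP_PATTERNS",
    "METRICS",
]

STEP_PATTERNS = ("symmetric2",)
METRICS = ("absolute", "squared")


@dataclass
class WarpingResult:
    """Outcome of a DTW alignment of two equal-length series."""

    path: list[tuple[int, int]]
    cumulative_cost: float
    normalized_distance: float
    lcm: np.ndarray = field(default=None, repr=False)
    acm: np.ndarray = field(default=None, repr=False)


def _check_series(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if a.size != b.size:
        raise ValueError(
            f"series lengths differ ({a.size} vs {b.size}); within a "
            "participant both items share the same complete waves"
        )
    if a.size < 2:
        raise ValueError("series must have at least 2 time points")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series contain NaN or infinite values")
    return a, b


def local_cost(series_a, series_b, metric: str = "absolute") -> np.ndarray:
    """Local cost matrix between all time points of two series.

    ``lcm[i, j]`` is the dissimilarity between ``series_a[i]`` and
    ``series_b[j]``; the absolute difference by default, the squared
    difference when ``metric="squared"``.
    """
    a, b = _check_series(series_a, series_b)
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    diff = a[:, None] - b[None, :]
    return np.abs(diff) if metric == "absolute" else diff**2


def _validate_params(window: int, step_pattern: str) -> None:
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    if step_pattern not in STEP_PATTERNS:
        raise ValueError(
            f"unknown step pattern {step_pattern!r}; choose from {STEP_PATTERNS}"
        )


def dtw_distance(
    series_a,
    series_b,
    window: int = 1,
    step_pattern: str = "symmetric2",
    metric: str = "absolute",
) -> WarpingResult:
    """DTW distance under the symmetric2 step pattern and a Sakoe-Chiba band.

    The accumulated cost follows the recursion

        D(i, j) = min( D(i-1, j)   +     c(i, j),
                       D(i-1, j-1) + 2 * c(i, j),
                       D(i,   j-1) +     c(i, j) )

    with ``D(0, 0) = 2 * c(0, 0)`` and cells with ``|i - j| > window``
    unreachable. The normalized distance divides the cumulative cost by
    ``len(a) + len(b)``.

    Ties between equal-cost predecessors are broken deterministically,
    preferring diagonal, then vertical, then horizontal; the distance is
    unaffected, only the reported path.
    """
    _validate_params(window, step_pattern)
    lcm = local_cost(series_a, series_b, metric=metric)
    t = lcm.shape[0]

    acm = np.full((t, t), np.inf)
    acm[0, 0] = 2.0 * lcm[0, 0]
    for i in range(t):
        for j in range(max(0, i - window), min(t, i + window + 1)):
            if i == 0 and j == 0:
                continue
            c = lcm[i, j]
            best = np.inf
            if i > 0 and j > 0:
                best = acm[i - 1, j - 1] + 2.0 * c
            if i > 0:
                best = min(best, acm[i - 1, j] + c)
            if j > 0:
                best = min(best, acm[i, j - 1] + c)
            acm[i, j] = best

    # Backtrack; preference order diagonal > vertical > horizontal.
    path = [(t - 1, t - 1)]
    i, j = t - 1, t - 1
    while (i, j) != (0, 0):
        c = lcm[i, j]
        here = acm[i, j]
        if i > 0 and j > 0 and np.isclose(acm[i - 1, j - 1] + 2.0 * c, here):
            i, j = i - 1, j - 1
        elif i > 0 and np.isfinite(acm[i - 1, j]) and np.isclose(acm[i - 1, j] + c, here):
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()

    cost = float(acm[t - 1, t - 1])
    return WarpingResult(
        path=path,
        cumulative_cost=cost,
        normalized_distance=cost / (2.0 * t),
        lcm=lcm,
        acm=acm,
    )


def dtw_distance_batch(
    series_a: np.ndarray,
    series_b: np.ndarray,
    window: int = 1,
    step_pattern: str = "symmetric2",
    metric: str = "absolute",
) -> np.ndarray:
    """Normalized symmetric2 DTW distances for many pairs at once.

    ``series_a`` and ``series_b`` are ``(n_pairs, T)`` arrays; row ``k`` of
    each holds the two series of pair ``k``. Returns an ``(n_pairs,)``
    vector of normalized distances identical (to float precision) to
    calling :func:`dtw_distance` row by row. The dynamic program keeps only
    two rows of the accumulated cost matrix, so memory stays at
    ``O(n_pairs * T)`` regardless of the pair count.
    """
    _validate_params(window, step_pattern)
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("series_a and series_b must be 2-D arrays of equal shape")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series contain NaN or infinite values")
    n, t = a.shape

    def cost(i: int, j: int) -> np.ndarray:
        d = a[:, i] - b[:, j]
        return np.abs(d) if metric == "absolute" else d * d

    prev = np.full((n, t), np.inf)
    prev[:, 0] = 2.0 * cost(0, 0)
    for j in range(1, min(t, window + 1)):
        prev[:, j] = prev[:, j - 1] + cost(0, j)

    for i in range(1, t):
        cur = np.full((n, t), np.inf)
        lo, hi = max(0, i - window), min(t - 1, i + window)
        for j in range(lo, hi + 1):
            c = cost(i, j)
            best = prev[:, j] + c  # vertical
            if j > 0:
                np.minimum(best, prev[:, j - 1] + 2.0 * c, out=best)  # diagonal
                np.minimum(best, cur[:, j - 1] + c, out=best)  # horizontal
            cur[:, j] = best
        prev = cur

    return prev[:, t - 1] / (2.0 * t)


def brute_force_dtw(
    series_a,
    series_b,
    window: int = 1,
    step_pattern: str = "symmetric2",
    metric: str = "absolute",
) -> WarpingResult:
    """Exhaustive enumeration of every band-admissible warping path.

    Test oracle only: walks all monotone paths from (0, 0) to (T-1, T-1)
    with steps down/right/diagonal, applying the symmetric2 weights
    (first cell and diagonal steps cost twice the local cost), and returns
    the minimum. Limited to ``T <= 6`` where the path count is small.
    """
    _validate_params(window, step_pattern)
    lcm = local_cost(series_a, series_b, metric=metric)
    t = lcm.shape[0]
    if t > 6:
        raise ValueError("brute force restricted to series of length <= 6")

    best_cost = np.inf
    best_path: list[tuple[int, int]] | None = None
    # stack of (i, j, cost so far, path so far)
    stack: list[tuple[int, int, float, list[tuple[int, int]]]] = [
        (0, 0, 2.0 * lcm[0, 0], [(0, 0)])
    ]
    while stack:
        i, j, cost, path = stack.pop()
        if (i, j) == (t - 1, t - 1):
            if cost < best_cost:
                best_cost, best_path = cost, path
            continue
        for di, dj, w in ((1, 1, 2.0), (1, 0, 1.0), (0, 1, 1.0)):
            ni, nj = i + di, j + dj
            if ni >= t or nj >= t or abs(ni - nj) > window:
                continue
            stack.append(
                (ni, nj, cost + w * lcm[ni, nj], path + [(ni, nj)])
            )

    assert best_path is not None  # (t-1,t-1) reachable for window >= 0
    return WarpingResult(
        path=best_path,
        cumulative_cost=float(best_cost),
        normalized_distance=float(best_cost) / (2.0 * t),
        lcm=lcm,
        acm=None,
    )
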