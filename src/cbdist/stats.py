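"""Statistical companions to the distance matrix.

Provides the Mantel test (Pearson correlation between two distance
matrices with a joint row/column permutation null), a between-versus-
within group permutation test, classical (Torgerson) metric
multidimensional scaling, and the exponential convergence-curve fit used
to summarize how the metric stabilizes with sequencing depth.

All permutation procedures take an explicit integer seed, record it in
their results, and are exactly reproducible for a fixed seed.  P-values
use the add-one estimator (count + 1) / (replicates + 1) so they are
never zero, with weak inequality for ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import DistanceMatrix

__all__ = [
    "PermutationResult",
    "MantelResult",
    "Embedding",
    "ConvergenceFit",
    "mantel_test",
    "group_permutation_test",
    "classical_mds",
    "fit_convergence_curve",
]

logger = logging.getLogger(__name__)

DEFAULT_REPLICATES = 1000
DEFAULT_SEED = 0


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, its permutation null, and the one-sided p."""

    statistic: float
    null_values: np.ndarray
    replicates: int
    p_value: float
    seed: int


@dataclass(frozen=True)
class MantelResult:
    """Mantel correlation between two distance matrices."""

    r: float
    permutation: PermutationResult


@dataclass(frozen=True)
class Embedding:
    """Classical-scaling coordinates and the full eigenvalue spectrum."""

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray


@dataclass(frozen=True)
class ConvergenceFit:
    """Parameters of value(n) = asymptote + amplitude * exp(-rate * n)."""

    asymptote: float
    amplitude: float
    rate: float
    sse: float


def _add_one_p(null: np.ndarray, observed: float) -> float:
    # weak inequality: ties count toward the p-value
    return (int(np.sum(null >= observed)) + 1) / (len(null) + 1)


def _lower_triangle(values: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(values.shape[0], k=-1)
    return values[i, j]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("undefined correlation: constant distance vector")
    return float((xc @ yc) / denom)


def mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = DEFAULT_SEED,
) -> MantelResult:
    """Mantel test between two labeled distance matrices.

    The statistic is the Pearson product-moment correlation of the
    strictly-lower-triangle distance vectors after aligning ``b`` to
    ``a``'s label order.  The null is built by jointly permuting the rows
    and columns of ``b`` per replicate; the one-sided p-value is for the
    alternative that the matrices are positively correlated.
    """
    if sorted(a.labels) != sorted(b.labels):
        raise ValueError("matrices do not share the same label set")
    n = len(a)
    if n < 4:
        raise ValueError("Mantel test requires at least 4 samples")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    b = b.reorder(a.labels)
    a_vec = _lower_triangle(a.values)
    r_obs = _pearson(a_vec, _lower_triangle(b.values))
    rng = np.random.default_rng(seed)
    null = np.empty(replicates)
    for k in range(replicates):
        idx = rng.permutation(n)
        null[k] = _pearson(a_vec, _lower_triangle(b.values[np.ix_(idx, idx)]))
    p = _add_one_p(null, r_obs)
    return MantelResult(
        r=r_obs,
        permutation=PermutationResult(
            statistic=r_obs, null_values=null, replicates=replicates,
            p_value=p, seed=seed,
        ),
    )


def mantel_exhaustive_p(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Exact Mantel p over all n! relabelings (small n only).

    Counts relabelings whose correlation is >= the observed one; the
    identity permutation is part of the enumeration, so p is never zero.
    """
    from itertools import permutations

    b = b.reorder(a.labels)
    n = len(a)
    if n > 8:
        raise ValueError("exhaustive enumeration is limited to n <= 8")
    a_vec = _lower_triangle(a.values)
    r_obs = _pearson(a_vec, _lower_triangle(b.values))
    count = 0
    total = 0
    for perm in permutations(range(n)):
        idx = np.array(perm)
        r = _pearson(a_vec, _lower_triangle(b.values[np.ix_(idx, idx)]))
        count += r >= r_obs - 1e-12
        total += 1
    return count / total


def _between_minus_within(values: np.ndarray, group_ids: np.ndarray) -> float:
    same = group_ids[:, None] == group_ids[None, :]
    tri = np.tril(np.ones_like(same, dtype=bool), k=-1)
    within = values[same & tri]
    between = values[~same & tri]
    if within.size == 0 or between.size == 0:
        raise ValueError("need at least one within-group and one between-group pair")
    return float(between.mean() - within.mean())


def group_permutation_test(
    d: DistanceMatrix,
    groups: Mapping[str, str],
    replicates: int = DEFAULT_REPLICATES,
    seed: int = DEFAULT_SEED,
) -> PermutationResult:
    """Permutation test for group structure in a distance matrix.

    The statistic is mean(between-group distance) - mean(within-group
    distance).  The null is built by permuting the group labels across
    samples (equivalently, jointly permuting rows and columns of the
    matrix) per replicate; the one-sided p-value is for the alternative
    that samples are more similar within groups than between them.
    """
    missing = [l for l in d.labels if l not in groups]
    if missing:
        raise ValueError(f"no group assignment for labels: {missing}")
    names = sorted({groups[l] for l in d.labels})
    if len(names) < 2:
        raise ValueError("need at least two groups")
    group_ids = np.array([names.index(groups[l]) for l in d.labels])
    for g, name in enumerate(names):
        if not np.any(group_ids == g):
            raise ValueError(f"group {name!r} has no members among matrix labels")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    obs = _between_minus_within(d.values, group_ids)
    rng = np.random.default_rng(seed)
    null = np.empty(replicates)
    for k in range(replicates):
        null[k] = _between_minus_within(d.values, rng.permutation(group_ids))
    return PermutationResult(
        statistic=obs, null_values=null, replicates=replicates,
        p_value=_add_one_p(null, obs), seed=seed,
    )


def group_exhaustive_p(d: DistanceMatrix, groups: Mapping[str, str]) -> float:
    """Exact group-test p over all label permutations (small n only)."""
    from itertools import permutations

    names = sorted({groups[l] for l in d.labels})
    group_ids = np.array([names.index(groups[l]) for l in d.labels])
    n = len(d)
    if n > 8:
        raise ValueError("exhaustive enumeration is limited to n <= 8")
    obs = _between_minus_within(d.values, group_ids)
    count = 0
    total = 0
    for perm in permutations(group_ids):
        count += _between_minus_within(d.values, np.array(perm)) >= obs - 1e-12
        total += 1
    return count / total


def classical_mds(d: DistanceMatrix, k: int = 2) -> Embedding:
    """Classical (Torgerson) metric multidimensional scaling.

    Double-centers the squared-distance matrix, eigendecomposes, and
    returns the top-``k`` coordinates scaled by the square roots of the
    positive eigenvalues.  Dimensions whose eigenvalues are not positive
    (which arise when the distances are not Euclidean) are zero-filled
    with a warning; no additive-constant correction is applied.
    """
    n = len(d)
    if n < 3:
        raise ValueError("classical MDS requires at least 3 samples")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    sq = d.values ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * centering @ sq @ centering
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, k))
    dropped = 0
    for dim in range(k):
        if eigval[dim] > 1e-12:
            coords[:, dim] = eigvec[:, dim] * np.sqrt(eigval[dim])
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{dropped} of {k} requested dimensions have non-positive "
            "eigenvalues (non-Euclidean distances); coordinates zero-filled",
            stacklevel=2,
        )
    return Embedding(labels=list(d.labels), coordinates=coords, eigenvalues=eigval)


def fit_convergence_curve(
    depths: Sequence[int], cbd_values: Sequence[float]
) -> ConvergenceFit:
    """Least-squares fit of value(n) = asymptote + amplitude * exp(-rate*n).

    Summarizes how the distance between a fixed reference and growing
    subsamples of a second dataset approaches its plateau; ``rate`` is
    constrained non-negative.
    """
    n = np.asarray(depths, dtype=float)
    y = np.asarray(cbd_values, dtype=float)
    if n.size < 4:
        raise ValueError("need at least 4 points to fit the decay model")
    if np.any(n <= 0) or np.any(np.diff(n) <= 0):
        raise ValueError("depths must be positive and strictly increasing")

    def model(x, asymptote, amplitude, rate):
        return asymptote + amplitude * np.exp(-rate * x)

    p0 = (y[-1], y[0] - y[-1], 1.0 / float(np.median(n)))
    try:
        popt, _ = curve_fit(
            model, n, y, p0=p0,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"convergence-curve fit failed: {exc}") from exc
    residuals = y - model(n, *popt)
    return ConvergenceFit(
        asymptote=float(popt[0]), amplitude=float(popt[1]),
        rate=float(popt[2]), sse=float(residuals @ residuals),
    )
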