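"""Rank-based two-sample statistics for domain-set enrichment.

This module houses the statistical core of the package:

* :func:`mann_whitney` — a two-sided Mann-Whitney U-test of a domain-associated
  value set against the remaining values.  For small, tie-free groups the exact
  null distribution of U is computed by a dynamic-programming count over rank
  assignments; otherwise a normal approximation with tie-corrected variance and
  a continuity correction of 0.5 is used.  A seeded Monte-Carlo permutation
  mode is available for small tied sets.
* :func:`rho_statistic` — the overlap statistic rho = P(X > Y) + 0.5 P(X = Y),
  the probability that a random domain value exceeds a random background value
  (ties counted half).  rho is 0.5 for completely overlapping distributions and
  0 or 1 for completely separated ones; its distance from 0.5 measures how far
  the domain set is displaced from the background.
* :func:`bh_adjust` — Benjamini-Hochberg step-up FDR adjustment.
* :func:`storey_qvalues` — Storey q-values with spline-smoothed pi0 estimation.

Domain-family sets are frequently small (fewer than 10 proteins), where the
normal approximation to U is poor; the exact path exists for precisely this
regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import interpolate, stats

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "MultipleTestingResult",
    "mann_whitney",
    "rho_statistic",
    "bh_adjust",
    "storey_qvalues",
    "multiple_testing",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_EXACT_THRESHOLD",
]

#: Storey's recommended lambda grid: 0.05, 0.10, ..., 0.95.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(
    round(0.05 * i, 2) for i in range(1, 20)
)

#: Largest min(n1, n2) for which the exact U null distribution is used.
DEFAULT_EXACT_THRESHOLD: int = 25

# p-values are never reported as exactly zero; floor at the smallest positive
# normal double.
_P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one Mann-Whitney comparison of a domain set vs the rest.

    ``u_statistic`` is U for the domain group (cross-pairs won, ties counted
    half), so ``rho == u_statistic / (n_domain * n_rest)``.
    """

    u_statistic: float
    n_domain: int
    n_rest: int
    p_value: float
    rho: float
    method: str  # "exact", "normal_approx" or "permutation"


@dataclass(frozen=True)
class MultipleTestingResult:
    """Raw p-values with their BH-adjusted values and Storey q-values."""

    p_values: np.ndarray
    bh_adjusted: np.ndarray
    q_values: np.ndarray
    pi0_estimate: float


def _as_group(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InputError(f"{name} group must be a non-empty 1-d sequence of values")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} group contains non-finite values")
    return arr


@lru_cache(maxsize=256)
def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments attaining each value of U, for U = 0..n1*n2.

    Counts partitions of U into at most ``m`` parts each at most ``n`` via the
    recurrence f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u): the largest rank of
    the combined sample either belongs to the domain group (beating all ``n``
    background values) or it does not.  Counts are float64; they stay well
    inside the double range for every min(n1, n2) the exact path accepts.
    """
    m, n = (n1, n2) if n1 <= n2 else (n2, n1)
    f = np.zeros((m + 1, m * n + 1))
    f[:, 0] = 1.0
    for j in range(1, n + 1):
        for i in range(1, m + 1):
            f[i, j:] += f[i - 1, : f.shape[1] - j]
    return f[m]


def _exact_p(u: int, n1: int, n2: int) -> float:
    counts = _exact_u_counts(n1, n2)
    total = counts.sum()
    lower = counts[: u + 1].sum() / total
    upper = counts[u:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def _normal_p(u1: float, n1: int, n2: int, combined: np.ndarray) -> float:
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0.0:  # every value identical
        return 1.0
    mu = n1 * n2 / 2.0
    z = max(abs(u1 - mu) - 0.5, 0.0) / math.sqrt(var)
    return min(1.0, 2.0 * float(stats.norm.sf(z)))


def _permutation_p(
    u1: float,
    n1: int,
    ranks: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> float:
    mu = n1 * (ranks.size - n1) / 2.0
    observed = abs(u1 - mu)
    offset = n1 * (n1 + 1) / 2.0
    hits = 0
    remaining = int(n_permutations)
    chunk = max(1, min(remaining, 5_000_000 // max(ranks.size, 1)))
    while remaining > 0:
        b = min(chunk, remaining)
        idx = np.argsort(rng.random((b, ranks.size)), axis=1)[:, :n1]
        u_perm = ranks[idx].sum(axis=1) - offset
        hits += int(np.count_nonzero(np.abs(u_perm - mu) >= observed - 1e-9))
        remaining -= b
    return (1 + hits) / (n_permutations + 1)


def mann_whitney(
    domain_values: Sequence[float],
    rest_values: Sequence[float],
    *,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    method: str = "auto",
    n_permutations: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> TestResult:
    """Two-sided Mann-Whitney U-test of ``domain_values`` against ``rest_values``.

    Parameters
    ----------
    domain_values, rest_values
        The value set linked to one domain feature and the remaining values of
        the uploaded population.  Both must be non-empty, with at least three
        values combined.
    exact_threshold
        Use the exact null distribution of U when ``min(n1, n2)`` does not
        exceed this and the combined sample is tie-free.
    method
        ``"auto"`` (default rule above), or force ``"exact"``,
        ``"normal_approx"`` or ``"permutation"``.
    n_permutations, rng
        Replicates and seed/generator for the permutation mode.

    Returns
    -------
    TestResult
        U for the domain group (ties counted half), group sizes, the two-sided
        p-value, rho, and which method produced the p-value.
    """
    x = _as_group(domain_values, "domain")
    y = _as_group(rest_values, "rest")
    n1, n2 = x.size, y.size
    if n1 + n2 < 3:
        raise InputError("need at least 3 values in the two groups combined")

    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    rho = u1 / (n1 * n2)
    has_ties = np.unique(combined).size < combined.size

    if method == "auto":
        method = (
            "exact"
            if (not has_ties and min(n1, n2) <= exact_threshold)
            else "normal_approx"
        )

    if method == "exact":
        if has_ties:
            raise InputError(
                "exact method requires a tie-free combined sample; "
                "use normal_approx or permutation"
            )
        p = _exact_p(int(round(u1)), n1, n2)
    elif method == "normal_approx":
        if np.all(combined == combined[0]):
            logger.info(
                "all %d values identical across both groups; p = 1, rho = 0.5",
                n1 + n2,
            )
        p = _normal_p(u1, n1, n2, combined)
    elif method == "permutation":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        p = _permutation_p(u1, n1, ranks, n_permutations, rng)
    else:
        raise InputError(f"unknown test method: {method!r}")

    return TestResult(
        u_statistic=u1,
        n_domain=n1,
        n_rest=n2,
        p_value=max(p, _P_FLOOR),
        rho=rho,
        method=method,
    )


def rho_statistic(
    domain_values: Sequence[float], rest_values: Sequence[float]
) -> float:
    """Overlap statistic: probability a random domain value exceeds a random
    background value, ties counted half.

    rho = (#{(x, y): x > y} + 0.5 #{(x, y): x = y}) / (n1 * n2) over all cross
    pairs.  0.5 means the two distributions overlap completely; 0 and 1 mean
    complete separation (domain entirely below, resp. above, the background).
    """
    x = _as_group(domain_values, "domain")
    y = _as_group(rest_values, "rest")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    return u1 / (x.size * y.size)


def _validated_p(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputError("p_values must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise InputError("p-values must lie in (0, 1]")
    return p


def _step_up(p: np.ndarray, pi0: float) -> np.ndarray:
    """Step-up adjustment q(p_(i)) = min_{j>=i} pi0 * m * p_(j) / j, in input order."""
    m = p.size
    order = np.argsort(p, kind="mergesort")  # stable under ties
    adj = pi0 * m * p[order] / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(adj[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    if pi0 >= 1.0:
        # m*p/i can round one ulp below p; the adjusted value dominates raw p
        out = np.maximum(out, p)
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted p-values, in input order."""
    return _step_up(_validated_p(p_values), 1.0)


def estimate_pi0(
    p_values: Sequence[float],
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> float:
    """Estimate the proportion pi0 of true null hypotheses by Storey's lambda
    method: pi0(lambda) = #{p > lambda} / (m (1 - lambda)) smoothed with a
    cubic spline across the grid and evaluated at the largest lambda.
    """
    p = _validated_p(p_values)
    lam = np.unique(np.asarray(lambda_grid, dtype=float))
    if lam.size < 4:
        raise InputError("lambda_grid needs at least 4 distinct values for the spline")
    if np.any(lam < 0.0) or np.any(lam >= 1.0):
        raise InputError("lambda_grid values must lie in [0, 1)")
    pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    spline = interpolate.UnivariateSpline(lam, pi0_lam, k=3)
    pi0 = float(spline(lam.max()))
    if pi0 <= 0.0:
        logger.warning(
            "pi0 spline estimate %.3g is non-positive; falling back to pi0 = 1", pi0
        )
        return 1.0
    return min(pi0, 1.0)


def storey_qvalues(
    p_values: Sequence[float],
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    *,
    pi0_min_tests: int = 100,
    pi0: float | None = None,
) -> tuple[np.ndarray, float]:
    """Storey q-values for ``p_values``; returns ``(q_values, pi0)``.

    pi0 is estimated by :func:`estimate_pi0` unless supplied.  With fewer than
    ``pi0_min_tests`` p-values the spline fit is unstable and pi0 falls back to
    1, in which case the q-values equal :func:`bh_adjust` exactly.
    """
    p = _validated_p(p_values)
    if pi0 is None:
        if p.size < pi0_min_tests:
            logger.info(
                "only %d tests (< %d): using pi0 = 1, q-values reduce to BH",
                p.size,
                pi0_min_tests,
            )
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p, lambda_grid)
    if not 0.0 < pi0 <= 1.0:
        raise InputError("pi0 must lie in (0, 1]")
    return _step_up(p, pi0), pi0


def multiple_testing(
    p_values: Sequence[float],
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    *,
    pi0_min_tests: int = 100,
    pi0: float | None = None,
) -> MultipleTestingResult:
    """Bundle BH-adjusted p-values and Storey q-values for one test family."""
    p = _validated_p(p_values)
    q, pi0_hat = storey_qvalues(
        p, lambda_grid, pi0_min_tests=pi0_min_tests, pi0=pi0
    )
    return MultipleTestingResult(
        p_values=p,
        bh_adjusted=bh_adjust(p),
        q_values=q,
        pi0_estimate=pi0_hat,
    )
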