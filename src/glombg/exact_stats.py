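"""Exact sign and binomial tests on counts, plus the t tests and Pearson r
used throughout the analyses.

The headline inferential statistics of the glomerular-imaging analyses are
counts of paired decreases (sign tests) and counts of suppressed odor
mixtures (binomial tests).  These are computed exactly: tail probabilities
are sums of binomial terms evaluated in integer / rational arithmetic, so
the p-values are exact for any practical n (the contract covers n <= 1e4).

Conventions
-----------
``two_sided_doubled_tail``
    p = min(1, 2 * min(P(X <= k), P(X >= k))), X ~ Binomial(n, p0).
    This is the classical sign-test convention and reproduces the printed
    values for 51/64, 26/32 and 24/32 at p0 = 1/2.
``one_sided_smaller_tail``
    p = min(P(X <= k), P(X >= k)): the tail in the direction of the
    observed deviation.  Reproduces 29/31 (upper tail) and 7/16 (lower
    tail) at p0 = 1/2.
``one_sided_upper`` / ``one_sided_lower``
    The named tail, P(X >= k) or P(X <= k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "sign_test_exact",
    "binomial_test_exact",
    "paired_t",
    "two_sample_t",
    "pearson_r",
]

_SIDES = {
    "two_sided_doubled_tail",
    "one_sided_smaller_tail",
    "one_sided_upper",
    "one_sided_lower",
}


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` is k for count tests, t for t tests, r for correlations.
    """

    test_name: str
    n: int
    statistic: float
    sidedness: str
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")


def _validate_kn(k: int, n: int) -> tuple[int, int]:
    # coerce numpy integers: native ints keep the tail sums in exact
    # arbitrary-precision arithmetic (fixed-width ints would overflow)
    k, n = int(k), int(n)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0 <= k <= n):
        raise ValueError(f"k must be in [0, n={n}], got {k}")
    return k, n


def _tail_probs(k: int, n: int, p0: Fraction) -> tuple[Fraction, Fraction]:
    """Exact (P(X <= k), P(X >= k)) for X ~ Binomial(n, p0)."""
    a, b = p0.numerator, p0.denominator
    # term_i = C(n, i) * a^i * (b-a)^(n-i); P = sum / b^n. All integers.
    c = b - a
    lower = sum(math.comb(n, i) * a**i * c ** (n - i) for i in range(0, k + 1))
    upper = sum(math.comb(n, i) * a**i * c ** (n - i) for i in range(k, n + 1))
    denom = b**n
    return Fraction(lower, denom), Fraction(upper, denom)


def sign_test_exact(k: int, n: int, sided: str = "two_sided_doubled_tail") -> TestResult:
    """Exact sign test: k successes (e.g. paired decreases) out of n pairs.

    Ties must already be removed from n.  Under H0 each pair decreases
    with probability 1/2.
    """
    k, n = _validate_kn(k, n)
    if sided not in _SIDES:
        raise ValueError(f"unknown sidedness: {sided}")
    lo, hi = _tail_probs(k, n, Fraction(1, 2))
    if sided == "two_sided_doubled_tail":
        p = min(Fraction(1), 2 * min(lo, hi))
    elif sided == "one_sided_smaller_tail":
        p = min(lo, hi)
    elif sided == "one_sided_upper":
        p = hi
    else:
        p = lo
    return TestResult("sign_test_exact", n, float(k), sided, float(p))


def binomial_test_exact(
    k: int,
    n: int,
    p0: float | Fraction = Fraction(1, 2),
    sided: str = "one_sided_smaller_tail",
) -> TestResult:
    """Exact binomial test of k successes in n trials against rate p0."""
    k, n = _validate_kn(k, n)
    if sided not in _SIDES:
        raise ValueError(f"unknown sidedness: {sided}")
    p0 = Fraction(p0).limit_denominator(10**9) if not isinstance(p0, Fraction) else p0
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    lo, hi = _tail_probs(k, n, p0)
    if sided == "two_sided_doubled_tail":
        p = min(Fraction(1), 2 * min(lo, hi))
    elif sided == "one_sided_smaller_tail":
        p = min(lo, hi)
    elif sided == "one_sided_upper":
        p = hi
    else:
        p = lo
    return TestResult("binomial_test_exact", n, float(k), sided, float(p))


def _check_finite(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def paired_t(x, y) -> TestResult:
    """Two-sided paired t test (the 'double-tailed t test' of the analyses)."""
    x = _check_finite(x, "x")
    y = _check_finite(y, "y")
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t needs two equal-length vectors with n >= 2")
    d = x - y
    if np.allclose(d, d[0]) and math.isclose(d[0], 0.0, abs_tol=0.0):
        # identical inputs: t = 0 by convention, p = 1
        return TestResult("paired_t", x.size, 0.0, "two_sided_doubled_tail", 1.0)
    res = _sps.ttest_rel(x, y)
    return TestResult("paired_t", x.size, float(res.statistic), "two_sided_doubled_tail", float(res.pvalue))


def two_sample_t(x, y) -> TestResult:
    """Two-sided unpaired t test (equal-variance, classical)."""
    x = _check_finite(x, "x")
    y = _check_finite(y, "y")
    if x.size < 2 or y.size < 2:
        raise ValueError("two_sample_t needs n >= 2 per group")
    res = _sps.ttest_ind(x, y)
    return TestResult("two_sample_t", x.size + y.size, float(res.statistic), "two_sided_doubled_tail", float(res.pvalue))


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with two-sided p from the t distribution."""
    x = _check_finite(x, "x")
    y = _check_finite(y, "y")
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson_r needs two equal-length vectors with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    res = _sps.pearsonr(x, y)
    return TestResult("pearson_r", x.size, float(res.statistic), "two_sided_doubled_tail", float(res.pvalue))
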