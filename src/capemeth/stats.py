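"""Exact small-sample statistics shared by every stage of the pipeline.

All exact tests (binomial upper tail, Fisher's exact) are computed by direct
summation of probability terms in log space, so they stay numerically stable
for read depths far beyond anything a bisulfite experiment produces.  The
chi-square statistics are computed from first principles; only the chi-square
survival function comes from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "TestResult",
    "binomial_tail",
    "bh_adjust",
    "pearson_chi2_2x2",
    "gof_chi2_equal",
    "fisher_exact_2x2",
    "DegenerateTableError",
]


class DegenerateTableError(ValueError):
    """A contingency table with a zero marginal (or zero total)."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a chi-square style test.

    ``statistic`` is None for exact tests that report only a p-value.
    """

    statistic: Optional[float]
    df: Optional[int]
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")
        if self.statistic is not None:
            if self.statistic < 0:
                raise ValueError("statistic must be non-negative")
            if self.df is None or self.df < 1:
                raise ValueError("df must be >= 1 when a statistic is reported")


def _log_binom_coeff(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def binomial_tail(k, n, p0: float):
    """Upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0).

    This is the methylation-calling statistic: ``k`` non-converted reads out
    of ``n`` total at a cytosine, tested against the null that every read is
    an unconverted artefact occurring with probability ``p0`` (one minus the
    spike-in conversion rate).

    Accepts scalars or equally-shaped integer arrays for ``k`` and ``n`` and
    returns a float or float array accordingly.  Computed by exact summation
    of log-pmf terms (logsumexp), never by a normal approximation.
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0 must lie in [0,1], got {p0}")
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    n_arr = np.atleast_1d(np.asarray(n, dtype=np.int64))
    if k_arr.shape != n_arr.shape:
        k_arr, n_arr = np.broadcast_arrays(k_arr, n_arr)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1")
    if np.any(k_arr < 0) or np.any(k_arr > n_arr):
        raise ValueError("require 0 <= k <= n")

    scalar = np.isscalar(k) and np.isscalar(n)
    if p0 == 0.0:
        out = np.where(k_arr == 0, 1.0, 0.0)
        return float(out[0]) if scalar else out
    if p0 == 1.0:
        out = np.ones_like(k_arr, dtype=float)
        return float(out[0]) if scalar else out

    logp, log1mp = np.log(p0), np.log1p(-p0)
    nmax = int(n_arr.max())
    out = np.empty(k_arr.shape, dtype=float)
    # grid evaluation when depths are small (the usual case); row-wise
    # logsumexp otherwise, still exact.
    if k_arr.size * (nmax + 1) <= 50_000_000:
        i = np.arange(nmax + 1)
        terms = (
            _log_binom_coeff(n_arr[..., None], i)
            + i * logp
            + (n_arr[..., None] - i) * log1mp
        )
        valid = (i >= k_arr[..., None]) & (i <= n_arr[..., None])
        terms = np.where(valid, terms, -np.inf)
        out = np.exp(logsumexp(terms, axis=-1))
    else:
        flat_k, flat_n = k_arr.ravel(), n_arr.ravel()
        flat = np.empty(flat_k.size)
        for j in range(flat_k.size):
            i = np.arange(flat_k[j], flat_n[j] + 1)
            t = _log_binom_coeff(float(flat_n[j]), i) + i * logp + (flat_n[j] - i) * log1mp
            flat[j] = np.exp(logsumexp(t))
        out = flat.reshape(k_arr.shape)
    out = np.clip(out, 0.0, 1.0)
    # exact endpoints
    out = np.where(k_arr == 0, 1.0, out)
    return float(out[0]) if scalar else out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (``q``-values).

    Returns adjusted values in the input order.  Each output is >= its input,
    bounded by 1, and monotone in the ranking of the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _check_counts(*counts: float) -> None:
    for c in counts:
        if c < 0 or c != int(c):
            raise ValueError(f"counts must be non-negative integers, got {c}")


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df = 1.

    No continuity correction (the convention throughout this package).
    Statistic via the closed form N(ad - bc)^2 / (r1 r2 c1 c2).
    """
    _check_counts(a, b, c, d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError("2x2 table has a zero marginal")
    n = r1 + r2
    # float arithmetic overflows silently at genome scale; use Python ints
    num = n * (a * d - b * c) ** 2
    stat = num / (r1 * r2 * c1 * c2)
    p = float(_chi2_dist.sf(stat, 1))
    return TestResult(statistic=float(stat), df=1, p_value=p)


def gof_chi2_equal(counts: Sequence[int]) -> TestResult:
    """Goodness-of-fit chi-square against equal expected counts.

    ``df = k - 1`` for ``k`` categories.  Used for the directional-bias test
    on hypermethylated-site (and gene) counts between the two embryo pools.
    """
    obs = list(counts)
    _check_counts(*obs)
    if len(obs) < 2:
        raise ValueError("need at least 2 categories")
    total = sum(obs)
    if total == 0:
        raise DegenerateTableError("all counts are zero")
    k = len(obs)
    expected = total / k
    stat = sum((o - expected) ** 2 / expected for o in obs)
    p = float(_chi2_dist.sf(stat, k - 1))
    return TestResult(statistic=float(stat), df=k - 1, p_value=p)


def _log_hypergeom_pmf(x: np.ndarray, row1: int, col1: int, n: int) -> np.ndarray:
    return (
        _log_binom_coeff(np.float64(col1), x)
        + _log_binom_coeff(np.float64(n - col1), row1 - x)
        - _log_binom_coeff(np.float64(n), np.float64(row1))
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities (margins fixed) of every table whose
    probability does not exceed that of the observed table, with a relative
    tolerance of 1e-7 for ties.  Serves as the per-site two-sample test for
    differential methylation between two pooled, unreplicated samples.
    """
    _check_counts(a, b, c, d)
    row1, col1 = a + b, a + c
    n = a + b + c + d
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    x = np.arange(lo, hi + 1, dtype=np.float64)
    logpmf = _log_hypergeom_pmf(x, row1, col1, n)
    log_obs = logpmf[int(a) - lo]
    keep = logpmf <= log_obs + np.log1p(1e-7)
    p = float(np.exp(logsumexp(logpmf[keep])))
    return min(1.0, p)
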