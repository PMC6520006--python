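"""Statistical primitives shared across the pipeline.

All quantile-based quantities use linear interpolation of order statistics
("type 7", the R default), because the grouped differential-variability
statistic is defined in terms of IQRs and its value depends on the quantile
convention. Spearman p-values use the t approximation on n-2 degrees of
freedom; Fisher's exact test reports the sample odds ratio ad/bc with the
standard two-sided conditional p; skewness is the plain moment coefficient
g1 = m3 / m2^{3/2} without small-sample bias correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "quantile",
    "iqr",
    "spearman",
    "bh_fdr",
    "fisher_2x2",
    "skewness",
    "normality_subsample_test",
]


@dataclass(frozen=True)
class TestResult:
    """Estimate + p-value pair with sample size and degeneracy flag.

    ``degenerate`` marks inputs on which the statistic is undefined (e.g. a
    constant vector for a correlation); degenerate results carry the
    documented fallback values (estimate 0, p 1).
    """

    estimate: float
    p_value: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def quantile(values, q: float) -> float:
    """Type-7 quantile: linear interpolation at h = (n-1)q + 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("quantile of empty vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("quantile requires finite values")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    return float(np.quantile(v, q, method="linear"))


def iqr(values) -> float:
    """Interquartile range, 75th minus 25th type-7 percentile (>= 0)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"iqr requires n >= 2, got n={v.size}")
    return quantile(v, 0.75) - quantile(v, 0.25)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with t-approximation p-value.

    Constant input in either argument yields the degenerate fallback
    (estimate 0, p 1) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError(f"spearman requires n >= 3, got n={n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(estimate=0.0, p_value=1.0, n=n, degenerate=True)
    rho, p = sps.spearmanr(x, y)
    if np.isnan(rho):  # pragma: no cover - guarded by ptp check above
        return TestResult(estimate=0.0, p_value=1.0, n=n, degenerate=True)
    return TestResult(estimate=float(rho), p_value=float(p), n=n)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q(i) = min_{j >= i, sorted order} p(j) * m / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_2x2(table) -> TestResult:
    """Fisher's exact test on a 2x2 count table.

    Returns the sample odds ratio ad/bc (inf when bc == 0 with ad > 0,
    flagged degenerate) and the standard two-sided conditional p-value: the
    sum of hypergeometric probabilities of tables, with the observed margins,
    no more probable than the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(int)
    a, b, c, d = t.ravel()
    n = t.sum()
    if min(a + b, c + d, a + c, b + d) == 0:
        # a zero margin fixes the table: no association is testable
        return TestResult(estimate=1.0, p_value=1.0, n=int(n), degenerate=True)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    degenerate = False
    if b * c == 0:
        odds = np.inf if a * d > 0 else 0.0
        degenerate = True
    else:
        odds = a * d / (b * c)
    return TestResult(estimate=float(odds), p_value=float(min(p, 1.0)),
                      n=int(n), degenerate=degenerate)


def skewness(values) -> float:
    """Moment skewness g1 = m3 / m2^(3/2) (no bias correction)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError(f"skewness requires n >= 3, got n={v.size}")
    if np.ptp(v) == 0:
        raise ValueError("skewness undefined for constant input")
    return float(sps.skew(v, bias=True))


def normality_subsample_test(values, subsample_size: int = 5000,
                             n_repeats: int = 20,
                             seed: int | None = None) -> list[TestResult]:
    """Shapiro-Wilk normality on repeated without-replacement subsamples.

    Large score distributions (one value per gene) are tested on subsamples
    of ``subsample_size`` measures because the Shapiro-Wilk statistic is only
    defined for n <= 5000 in the reference implementation. If the input is
    shorter than ``subsample_size`` the size is clipped (logged).
    """
    v = np.asarray(values, dtype=float)
    if subsample_size > v.size:
        log.info("normality test: subsample size clipped from %d to %d",
                 subsample_size, v.size)
        subsample_size = v.size
    if subsample_size < 3:
        raise ValueError("need at least 3 values for the Shapiro-Wilk test")
    rng = np.random.default_rng(seed)
    out: list[TestResult] = []
    for _ in range(n_repeats):
        sub = rng.choice(v, size=subsample_size, replace=False)
        if np.ptp(sub) == 0:
            out.append(TestResult(0.0, 1.0, subsample_size, degenerate=True))
            continue
        w, p = sps.shapiro(sub)
        out.append(TestResult(float(w), float(p), subsample_size))
    return out
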