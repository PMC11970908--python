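"""Self-contained statistical primitives.

Every routine here is written against an explicit definition so it can be
checked against brute-force enumeration at desk scale: the Wilcoxon
rank-sum test enumerates the exact null for small samples and otherwise
uses the tie-corrected normal approximation with continuity correction;
the two-sample Kolmogorov–Smirnov test computes the exact D with the
asymptotic Kolmogorov p; the hypergeometric enrichment test sums the
upper tail in log space.  All p-values are two-sided except the
hypergeometric one, which is the one-sided upper (enrichment) tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
from scipy.special import gammaln, kolmogorov, logsumexp, stdtr

from .errors import ValidationError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")
        if self.n1 < 1 or self.n2 < 1:
            raise ValidationError("sample sizes must be >= 1")


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with midranks for ties."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def wilcoxon_rank_sum(x, y, exact_threshold: int = 12) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the rank sum of ``x`` using midranks.  When
    ``n1 + n2 <= exact_threshold`` the p-value is exact, by full
    enumeration of the C(n, n1) equally likely rank assignments;
    otherwise the normal approximation with tie-corrected variance and a
    0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = _midranks(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    if n <= exact_threshold:
        dev = abs(w - mu)
        total = comb(n, n1)
        hits = 0
        for subset in combinations(range(n), n1):
            ws = ranks[list(subset)].sum()
            if abs(ws - mu) >= dev - 1e-9:
                hits += 1
        return TestResult(w, hits / total, "wilcoxon-exact", n1, n2)

    tie = _tie_term(np.concatenate([x, y]))
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:  # every value identical
        return TestResult(w, 1.0, "wilcoxon-normal", n1, n2)
    dev = abs(w - mu)
    z = max(dev - 0.5, 0.0) / sqrt(var)
    p = min(1.0, erfc(z / sqrt(2.0)))
    return TestResult(w, p, "wilcoxon-normal", n1, n2)


def rank_sum_matrix(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Row-wise Wilcoxon rank-sum p-values (normal approximation).

    ``xa``/``xb`` are genes × cells blocks of the two groups.  Shares the
    tie-corrected variance and continuity correction of
    :func:`wilcoxon_rank_sum`; used by the all-pairs differential
    expression stage where per-gene Python loops would be prohibitive.
    """
    from scipy.stats import rankdata

    n1, n2 = xa.shape[1], xb.shape[1]
    n = n1 + n2
    combined = np.concatenate([xa, xb], axis=1)
    ranks = rankdata(combined, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    mu = n1 * (n + 1) / 2.0

    # per-row sum(t^3 - t): run lengths along each sorted row
    s = np.sort(combined, axis=1)
    tie = np.zeros(combined.shape[0])
    for i in range(combined.shape[0]):
        _, counts = np.unique(s[i], return_counts=True)
        c = counts.astype(float)
        tie[i] = np.sum(c**3 - c)

    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    dev = np.abs(w - mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.maximum(dev - 0.5, 0.0) / np.sqrt(var)
    from scipy.special import erfc as _erfc

    p = np.where(var > 0, np.minimum(1.0, _erfc(z / np.sqrt(2.0))), 1.0)
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p-value).

    D = sup |ECDF_x − ECDF_y|; p from the asymptotic Kolmogorov
    distribution evaluated at sqrt(n1·n2/(n1+n2))·D.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    xs = np.sort(x)
    ys = np.sort(y)
    grid = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, grid, side="right") / n1
    cdf_y = np.searchsorted(ys, grid, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = sqrt(n1 * n2 / (n1 + n2))
    p = float(np.clip(kolmogorov(en * d), 0.0, 1.0))
    return TestResult(d, p, "ks-asymptotic", n1, n2)


def _log_hypergeom_pmf(i: np.ndarray, big_n: int, big_k: int, n: int) -> np.ndarray:
    return (
        gammaln(big_k + 1) - gammaln(i + 1) - gammaln(big_k - i + 1)
        + gammaln(big_n - big_k + 1) - gammaln(n - i + 1)
        - gammaln(big_n - big_k - n + i + 1)
        - (gammaln(big_n + 1) - gammaln(n + 1) - gammaln(big_n - n + 1))
    )


def hypergeom_test(k: int, big_k: int, n: int, big_n: int) -> TestResult:
    """One-sided (upper tail) hypergeometric enrichment test.

    p = P(X ≥ k) for X ~ Hypergeom(N=big_n, K=big_k, n), evaluated in log
    space; ``k`` successes among ``n`` draws, ``big_k`` marked items in a
    universe of ``big_n``.
    """
    if not (0 <= k <= min(big_k, n) <= big_n) or n > big_n:
        raise ValidationError(
            f"inconsistent counts k={k}, K={big_k}, n={n}, N={big_n}"
        )
    lo = max(k, max(0, n + big_k - big_n))
    hi = min(big_k, n)
    if k <= max(0, n + big_k - big_n):
        return TestResult(float(k), 1.0, "hypergeom-upper", n, big_n)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, big_n, big_k, n)
    p = float(np.clip(np.exp(logsumexp(logp)), 0.0, 1.0))
    return TestResult(float(k), p, "hypergeom-upper", n, big_n)


def t_test_unpaired(x, y, welch: bool = False) -> TestResult:
    """Unpaired two-sided t-test (pooled variance; Welch behind a flag).

    Degenerate samples with zero variance on both sides and equal means
    yield p = 1 by convention; with distinct means, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("each sample needs at least 2 observations")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if m1 == m2:
            return TestResult(0.0, 1.0, "t-degenerate", n1, n2)
        return TestResult(np.inf if m1 > m2 else -np.inf, 0.0, "t-degenerate", n1, n2)
    if welch:
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        method = "t-welch"
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (m1 - m2) / sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        method = "t-pooled"
    p = float(np.clip(2.0 * stdtr(df, -abs(t)), 0.0, 1.0))
    return TestResult(float(t), p, method, n1, n2)
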