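"""Statistical kernels for signature derivation and evaluation.

Thin, contract-checked wrappers around scipy/statsmodels where an
established implementation exists (two-sample KS, Mann-Whitney U, Spearman,
BH step-up), plus the tie-corrected Kendall coefficient of concordance and
directional empirical p-values, which are written here.  Every kernel is
verifiable against a brute-force oracle at small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ks_two_sample",
    "bh_adjust",
    "mann_whitney_u",
    "spearman_rho",
    "kendalls_w",
    "empirical_pvalue",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_sample(name: str, x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def ks_two_sample(x: Sequence[float], y: Sequence[float], method: str = "asymp") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    The statistic is the supremum over thresholds of the absolute gap
    between the two empirical CDFs.  The p-value comes from the asymptotic
    two-sample null by default; pass ``method="exact"`` for small samples
    (practical up to roughly n*m <= 1e4).  Ties need no special handling:
    the ECDF-sup definition is well defined with ties and no jitter is added.
    """
    xa = _check_sample("x", x)
    ya = _check_sample("y", y)
    res = sps.ks_2samp(xa, ya, method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):
        # the asymptotic form degenerates for very small samples
        p = float(sps.ks_2samp(xa, ya, method="exact").pvalue)
    return TestResult(float(res.statistic), min(p, 1.0))


def bh_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(adjusted, reject)`` in the input order.  Adjusted values are
    the standard monotone BH q-values, ``q_(i) = min_{j>=i} m * p_(j) / j``
    capped at 1.  Rejection is strict: ``adjusted < alpha``, i.e. a feature
    is called significant only when its corrected p-value falls below the
    threshold.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    adjusted = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    return adjusted, adjusted < alpha


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U rank-sum test with tie correction.

    The statistic is U for ``x`` relative to ``y``: the number of pairs
    ``(xi, yj)`` with ``xi > yj`` plus half the tied pairs.
    """
    xa = _check_sample("x", x)
    ya = _check_sample("y", y)
    res = sps.mannwhitneyu(xa, ya, alternative="two-sided")
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation: Pearson correlation of midranks, two-sided p.

    Constant input makes the correlation undefined and raises rather than
    silently returning 0 or NaN.
    """
    xa = _check_sample("x", x)
    ya = _check_sample("y", y)
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input: Spearman correlation is undefined")
    rho, p = sps.spearmanr(xa, ya)
    return TestResult(float(rho), float(min(p, 1.0)))


def kendalls_w(ranks, tie_correction: bool = True) -> float:
    """Kendall's coefficient of concordance W for m rankings of n items.

    ``ranks`` is an m x n matrix, one row per judge, each row a (possibly
    midrank-resolved) ranking of the same n items.  With S the sum of
    squared deviations of per-item rank sums from their mean,

        W = 12 S / (m^2 (n^3 - n) - m * T)

    where T is the tie correction ``sum over judges of sum over tied groups
    of (t^3 - t)`` (zero when ``tie_correction`` is off or no ties exist).
    W = 1 for identical rankings; W = 0 when rank sums are constant.
    """
    R = np.asarray(ranks, dtype=float)
    if R.ndim != 2:
        raise ValueError("ranks must be a 2-D matrix (judges x items)")
    m, n = R.shape
    if m < 2:
        raise ValueError("need at least 2 judges")
    if n < 2:
        raise ValueError("need at least 2 items")
    expected_row_sum = n * (n + 1) / 2.0
    if not np.allclose(R.sum(axis=1), expected_row_sum):
        raise ValueError("each row must be a ranking of 1..n (midranks allowed)")
    col_sums = R.sum(axis=0)
    S = float(np.sum((col_sums - col_sums.mean()) ** 2))
    T = 0.0
    if tie_correction:
        for row in R:
            _, counts = np.unique(row, return_counts=True)
            T += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * T
    if denom <= 0:
        raise ValueError("degenerate ranking matrix: all items tied in every row")
    return 12.0 * S / denom


def empirical_pvalue(
    observed: float,
    null_samples: Sequence[float],
    direction: str = "ge",
    add_one: bool = False,
) -> float:
    """Directional permutation p-value: proportion of null samples at least
    (``direction="ge"``) or at most (``"le"``) as extreme as the observed
    value, ties counting as extreme.

    ``add_one`` applies the (1 + count) / (1 + N) small-sample correction,
    which guards against reporting exactly zero; off by default so the value
    is the plain proportion.
    """
    null = _check_sample("null_samples", null_samples)
    if direction == "ge":
        count = int(np.sum(null >= observed))
    elif direction == "le":
        count = int(np.sum(null <= observed))
    else:
        raise ValueError("direction must be 'ge' or 'le'")
    if add_one:
        return (1 + count) / (1 + null.size)
    return count / null.size
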