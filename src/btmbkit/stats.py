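"""Nonparametric, contingency and correlation tests for group comparisons.

Thin, policy-carrying wrappers around :mod:`scipy.stats`: each operation fixes
the conventions used throughout the analysis (two-sided p-values, midrank tie
handling, exact small-sample paths) and returns a uniform :class:`TestResult`
record that serializes into the analysis report.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import EmptyInputError, ValidationError

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "spearman_corr",
    "chi_square_test",
    "fisher_exact_2x2",
]

# exact Mann-Whitney enumeration is used up to this product of sample sizes
_MW_EXACT_LIMIT = 400
# exact Spearman permutation p-value up to this n
_SPEARMAN_EXACT_N = 9


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (U, H, rho, or chi-square depending on ``method``).
    p_value : float
        Two-sided p-value in [0, 1].
    method : str
        One of ``mann_whitney``, ``kruskal_wallis``, ``spearman``,
        ``chi_square``, ``fisher_exact``.
    n : tuple of int
        Per-group sample sizes (row sums for contingency tables).
    notes : str
        Free-text notes on ties / exactness of the p-value.
    """

    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...] = field(default=())
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "method": self.method,
            "n": list(self.n),
            "notes": self.notes,
        }


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise EmptyInputError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses full exact enumeration when ``len(x) * len(y) <= 400`` and the pooled
    sample has no ties; otherwise the normal approximation with midrank tie
    correction and continuity correction. The reported U is the statistic of
    the first sample.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (xa.size * ya.size) <= _MW_EXACT_LIMIT and not has_ties
    res = sps.mannwhitneyu(
        xa, ya, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    notes = "exact enumeration" if exact else (
        "normal approximation, tie and continuity corrected"
        if has_ties else "normal approximation, continuity corrected"
    )
    return TestResult(float(res.statistic), float(res.pvalue), "mann_whitney",
                      (xa.size, ya.size), notes)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across two or more groups (tie-corrected)."""
    arrays = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValidationError("kruskal_wallis requires at least two groups")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        # all observations identical: H = 0 by convention, no evidence
        return TestResult(0.0, 1.0, "kruskal_wallis",
                          tuple(a.size for a in arrays), "degenerate: all values tied")
    res = sps.kruskal(*arrays)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal_wallis",
                      tuple(a.size for a in arrays), "tie-corrected chi-square approximation")


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ValidationError("undefined correlation: zero variance in a variable")
    return float(rx @ ry) / denom


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation with two-sided p-value.

    p comes from the t approximation with n - 2 df, except for n <= 9 where the
    exact permutation distribution of rho is enumerated (all n! relabelings).
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValidationError("x and y must be paired (equal length)")
    n = xa.size
    if n < 3:
        raise ValidationError("spearman_corr requires n >= 3")
    rho = _spearman_rho(xa, ya)
    if n <= _SPEARMAN_EXACT_N:
        ry = sps.rankdata(ya)
        target = abs(rho) - 1e-12
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(xa, ry[list(perm)])
            hits += abs(r) >= target
            total += 1
        p = hits / total
        notes = "exact permutation p"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
        notes = "t approximation, n-2 df"
    return TestResult(rho, float(p), "spearman", (n,), notes)


def _table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValidationError("contingency table must be 2-dimensional")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        arrf = np.asarray(table, dtype=float)
        if np.any(arrf < 0) or np.any(arrf != np.round(arrf)):
            raise ValidationError("contingency table needs nonnegative integer cells")
        arr = arrf.astype(int)
    return arr


def chi_square_test(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction by default)."""
    arr = _table(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("chi-square undefined: table has a zero marginal")
    res = sps.chi2_contingency(arr, correction=yates)
    return TestResult(float(res.statistic), float(res.pvalue), "chi_square",
                      tuple(int(s) for s in arr.sum(axis=1)),
                      "Yates corrected" if yates else "uncorrected")


def fisher_exact_2x2(table, rule: str = "point_probability") -> TestResult:
    """Fisher's exact test on a 2x2 table, two-sided.

    ``point_probability`` (default) sums hypergeometric point probabilities no
    larger than the observed table's; ``doubling`` doubles the smaller one-sided
    tail (capped at 1).
    """
    arr = _table(table)
    if arr.shape != (2, 2):
        raise ValidationError("fisher_exact_2x2 requires a 2x2 table")
    sizes = tuple(int(s) for s in arr.sum(axis=1))
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return TestResult(math.nan, 1.0, "fisher_exact", sizes,
                          "degenerate: zero marginal, conditional distribution is a point mass")
    if rule == "point_probability":
        _, p = sps.fisher_exact(arr, alternative="two-sided")
        notes = "exact, point-probability rule"
    elif rule == "doubling":
        _, p_less = sps.fisher_exact(arr, alternative="less")
        _, p_greater = sps.fisher_exact(arr, alternative="greater")
        p = min(1.0, 2.0 * min(p_less, p_greater))
        notes = "exact, doubled one-sided tail"
    else:
        raise ValidationError(f"unknown two-sided rule: {rule!r}")
    odds = sps.fisher_exact(arr)[0]
    return TestResult(float(odds), float(p), "fisher_exact", sizes, notes)
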