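"""Shared statistical primitives.

Thin, contract-enforcing wrappers around scipy/statsmodels: two-sided
Wilcoxon rank-sum with exact small-sample enumeration, two-sided and
one-sided Fisher's exact test, Pearson chi-square, and Benjamini-Hochberg
adjustment.  Every test returns a :class:`TestResult` that records which
computational route (exact vs. normal approximation) produced the p-value
and whether the input was degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: largest combined sample size for which the Wilcoxon null is enumerated
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (rank-sum U, odds ratio's table, or chi-square,
        depending on the method).
    p_value : float
        Two-sided (or stated one-sided) p-value in [0, 1].
    method : str
        ``"exact"`` or ``"normal-approximation"`` (``"chi-square"`` for the
        Pearson test).
    effect : float
        Effect descriptor: rank-sum for Wilcoxon, odds ratio for Fisher,
        Cramer-like statistic for chi-square.
    degenerate : bool
        True when the input carried no information (all values tied, a zero
        margin, ...); the p-value is then 1 by convention.
    extra : dict
        Method-specific extras (degrees of freedom, continuity-corrected
        odds ratio, ...).
    """

    statistic: float
    p_value: float
    method: str
    effect: float
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def wilcoxon_rank_sum(
    x,
    y,
    *,
    exact_max_n: int = EXACT_WILCOXON_MAX_N,
    continuity: bool = True,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Mid-ranks are used for ties.  The null distribution is enumerated
    exactly when ``len(x) + len(y) <= exact_max_n`` and there are no ties;
    otherwise the normal approximation with tie-corrected variance (and a
    continuity correction unless ``continuity=False``) is used.

    Parameters
    ----------
    x, y : array-like
        The two non-empty samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=float(x.size * y.size / 2.0),
            p_value=1.0,
            method="degenerate",
            effect=float(sps.rankdata(pooled)[: x.size].sum()),
            degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (x.size + y.size) <= exact_max_n and not has_ties
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=continuity,
    )
    rank_sum = float(sps.rankdata(pooled)[: x.size].sum())
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        method="exact" if use_exact else "normal-approximation",
        effect=rank_sum,
    )


def fisher_exact(table, *, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table of non-negative integer counts.

    Two-sided p-values sum hypergeometric probabilities no greater than the
    observed table's.  The reported odds ratio is the sample (conditional
    MLE-free) cross-product ratio; a Haldane 0.5-continuity version is
    carried in ``extra["odds_ratio_continuity"]`` for display when a cell
    is zero — it never affects the p-value.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(np.int64)
    a, b = t[0]
    c, d = t[1]
    row_margins = t.sum(axis=1)
    col_margins = t.sum(axis=0)
    or_cc = float(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
    if np.any(row_margins == 0) or np.any(col_margins == 0):
        return TestResult(
            statistic=float("nan"),
            p_value=1.0,
            method="exact",
            effect=float("nan"),
            degenerate=True,
            extra={"odds_ratio_continuity": or_cc},
        )
    odds, p = sps.fisher_exact(t, alternative=alternative)
    return TestResult(
        statistic=float(odds),
        p_value=min(float(p), 1.0),
        method="exact",
        effect=float(odds),
        extra={"odds_ratio_continuity": or_cc},
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone in sorted order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square_test(observed) -> TestResult:
    """Pearson chi-square test of independence on an r x c contingency table.

    Uses df = (r-1)(c-1) and the upper-tail p, without Yates correction.
    A zero expected cell is an error: use :func:`fisher_exact` instead.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("observed must be an r x c table with r, c >= 2")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = row @ col / total
    if np.any(expected == 0):
        raise ValueError(
            "zero expected cell count; use fisher_exact for sparse 2x2 tables"
        )
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return TestResult(
        statistic=float(stat),
        p_value=min(float(p), 1.0),
        method="chi-square",
        effect=float(np.sqrt(stat / total)),
        extra={"df": int(dof)},
    )
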