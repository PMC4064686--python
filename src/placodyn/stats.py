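"""Statistical tests used for placode comparisons.

Two-sample Kolmogorov-Smirnov (apical-area cumulative distributions),
G test of independence (fluctuation contingency tables) and the two-tailed
Student's t test (fluorescence-intensity comparisons).  All return a common
:class:`TestResult`.  The G statistic is computed directly as
G = 2·Σ O·ln(O/E) with expected counts from the table margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "ks_two_sample",
    "g_test",
    "t_test_two_sample",
]


@dataclass
class TestResult:
    """Named test outcome: statistic, degrees of freedom (if any), two-sided p."""

    name: str
    statistic: float
    pvalue: float
    df: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class ContingencyTable2x2:
    """2×2 contingency table of non-negative integer counts."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("row0", "row1")
    col_labels: tuple = ("col0", "col1")

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def ks_two_sample(x, y) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_x − ECDF_y| with the asymptotic two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return TestResult("ks_two_sample", float(res.statistic), float(res.pvalue))


def g_test(table) -> TestResult:
    """G test of independence: G = 2·Σ O·ln(O/E), df = (r−1)(c−1).

    Expected counts come from the row/column margins; zero margins are
    rejected (expected counts must all be positive).  The p-value is the
    chi-square upper tail at the table's degrees of freedom.
    """
    if isinstance(table, ContingencyTable2x2):
        obs = table.to_array()
    else:
        obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row/column margin: expected counts must be > 0")
    expected = np.outer(rows, cols) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * float(terms.sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(g, df))
    return TestResult("g_test", g, p, df=df)


def t_test_two_sample(x, y, mode: str = "student") -> TestResult:
    """Two-tailed two-sample t test.

    ``student`` (default) pools variances; ``welch`` does not.  If both
    samples are degenerate (zero variance): equal means give statistic 0 and
    p = 1, unequal means give an infinite statistic and p = 0 (the
    separation is perfect at any sample size; documented convention).
    """
    if mode not in ("student", "welch"):
        raise ValueError("mode must be 'student' or 'welch'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            df = len(x) + len(y) - 2 if mode == "student" else float("nan")
            return TestResult("t_test_two_sample", 0.0, 1.0, df=df)
        return TestResult(
            "t_test_two_sample",
            float(np.sign(x.mean() - y.mean()) * np.inf),
            0.0,
            df=len(x) + len(y) - 2,
        )
    res = sps.ttest_ind(x, y, equal_var=(mode == "student"))
    df = len(x) + len(y) - 2 if mode == "student" else float(res.df)
    return TestResult(
        "t_test_two_sample", float(res.statistic), float(res.pvalue), df=df
    )
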