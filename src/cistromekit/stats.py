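"""Statistical primitives shared by every pipeline stage.

Thin, explicitly-typed wrappers over scipy.stats for the handful of tests
the analysis uses: two-sample and one-sample-normal Kolmogorov-Smirnov,
Kruskal-Wallis, the cumulative hypergeometric tail, Fisher's exact test,
Welch's t, Pearson R² and ordinary least squares.  Each returns a
:class:`TestResult` so downstream report code stays uniform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ks_two_sample",
    "ks_one_sample_normal",
    "kruskal_wallis",
    "hypergeom_tail",
    "fisher_exact_2x2",
    "welch_t",
    "pearson_r2",
    "ols",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.pvalue}")


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample KS: D = sup|ECDF_a - ECDF_b|.

    The p-value is exact for small samples and asymptotic (Kolmogorov
    distribution with effective n) otherwise, so it tracks the
    permutation null at the sample sizes where the asymptotic form is
    visibly biased.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("ks_two_sample requires >=2 values per sample")
    method = "exact" if max(len(a), len(b)) <= 100 else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      len(a), len(b), "ks_two_sample")


def ks_one_sample_normal(a: Sequence[float]) -> TestResult:
    """One-sample KS normality screen against Normal(mean(a), sd(a)).

    Because the normal parameters are estimated from the same sample,
    the plain Kolmogorov p-value is badly conservative (a uniform sample
    of n=500 sits almost exactly on the uncorrected 5% critical value);
    the Lilliefors-corrected p-value is used instead, with the D
    statistic reported as the ordinary ECDF-vs-CDF sup gap.
    """
    a = np.asarray(a, float)
    if len(a) < 8:
        raise ValueError("ks_one_sample_normal requires >=8 values")
    sd = float(np.std(a, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate sample: zero standard deviation")
    from statsmodels.stats.diagnostic import lilliefors

    d, p = lilliefors(a, dist="norm", pvalmethod="table")
    return TestResult(float(d), float(min(max(p, 0.0), 1.0)),
                      len(a), 0, "ks_one_sample_normal")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("kruskal_wallis requires >=2 groups of >=2 values")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # scipy raises on all-identical input
        return TestResult(0.0, 1.0, len(groups[0]), len(groups[1]), "kruskal_wallis")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), len(groups[0]), len(groups[1]),
                      "kruskal_wallis")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) drawing n from N containing K successes.

    Evaluated in log space by scipy's hypergeometric survival function;
    exact to ~1e-12 relative for the population sizes used here.
    """
    if not (0 <= k <= min(K, n)) or n > N or K > N:
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_2x2(table, alternative: str = "greater") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    ``alternative='greater'`` is the one-sided enrichment p, identical to
    :func:`hypergeom_tail` on the table's margins; ``'two-sided'`` sums
    tables whose pmf is <= the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 integer table")
    _, p = sps.fisher_exact(t, alternative=alternative)
    odds = sps.contingency.odds_ratio(t, kind="sample").statistic if t.sum() else 1.0
    return TestResult(float(odds), float(p), int(t[0].sum()), int(t[1].sum()),
                      f"fisher_exact_{alternative}")


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Unpaired two-sample t-test with Welch-Satterthwaite df, two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("welch_t requires >=3 values per group")
    if np.std(a) == 0 and np.std(b) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        return TestResult(0.0 if p == 1.0 else np.inf, p, len(a), len(b), "welch_t")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(t), float(p), len(a), len(b), "welch_t")


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    r, _ = sps.pearsonr(x, y)
    return float(r * r)


def ols(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R²).

    Constant x yields an undefined slope, returned as NaN.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("ols requires matched samples of >=3 points")
    if np.all(x == x[0]):
        return float("nan"), float("nan"), float("nan")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
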