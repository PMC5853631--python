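"""Shared statistical primitives.

Small, dependency-light implementations of the tests used throughout the
analyses: exact binomial tails, t tests (p computed through the regularized
incomplete beta function), Spearman rank correlation with an exact
permutation p-value at small n, and the balanced two-way ANOVA interaction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "TestResult",
    "BONFERRONI_PER_TIMEPOINT",
    "binomial_tail",
    "binomial_tail_lower",
    "p_from_t",
    "paired_t",
    "one_sample_t",
    "spearman_corr",
    "two_way_interaction",
]

#: Per-timepoint Bonferroni threshold used for decoding time courses
#: (.05 over 8 comparisons).
BONFERRONI_PER_TIMEPOINT = 0.05 / 8


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    statistic: float
    p: float
    df: float | tuple[float, float] | None = None
    sided: str = "two-sided"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value out of range: {self.p}")


def binomial_tail(k: int, n: int, q: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, q), by exact summation.

    This is the group-level test used to ask how many of n subjects can show
    an effect (e.g. picking the trained boundary out of 4 candidates, q=1/4)
    by chance: binomial_tail(9, 12, 0.25) = 3.92e-4.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= q <= 1.0:
        raise ValueError("success probability must be in [0, 1]")
    if k == 0:
        return 1.0
    total = sum(
        math.comb(n, i) * q**i * (1.0 - q) ** (n - i) for i in range(k, n + 1)
    )
    return float(min(1.0, max(0.0, total)))


def binomial_tail_lower(k: int, n: int, q: float) -> float:
    """Lower-tail P(X <= k); complements :func:`binomial_tail` at k+1."""
    if k < 0:
        return 0.0
    return float(
        sum(math.comb(n, i) * q**i * (1.0 - q) ** (n - i) for i in range(0, min(k, n) + 1))
    )


def p_from_t(t: float, df: float, sided: str = "two-sided") -> float:
    """p-value of a t statistic via the regularized incomplete beta function.

    ``P(|T| >= t) = I_{df/(df+t^2)}(df/2, 1/2)`` for the two-sided case.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    x = df / (df + t * t)
    two = float(special.betainc(df / 2.0, 0.5, x))
    if sided == "two-sided":
        return two
    if sided in ("greater", "less"):
        one = two / 2.0
        tail_matches = (t >= 0) == (sided == "greater")
        return one if tail_matches else 1.0 - one
    raise ValueError(f"unknown sidedness {sided!r}")


def _t_stat(diffs: np.ndarray, mu0: float = 0.0) -> tuple[float, int]:
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t statistic undefined")
    t = (d.mean() - mu0) / (sd / math.sqrt(n))
    return float(t), n - 1


def paired_t(x, y, sided: str = "two-sided") -> TestResult:
    """Paired t test on matched samples (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    t, df = _t_stat(x - y)
    return TestResult(t, p_from_t(t, df, sided), df=df, sided=sided)


def one_sample_t(x, mu0: float = 0.0, sided: str = "two-sided") -> TestResult:
    """One-sample t test of mean(x) against mu0."""
    t, df = _t_stat(np.asarray(x, dtype=float), mu0)
    return TestResult(t, p_from_t(t, df, sided), df=df, sided=sided)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("constant input: rank correlation undefined")
    return float(rx @ ry) / denom


def spearman_corr(x, y, exact_max_n: int = 10) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value is exact (full permutation enumeration of one margin) for
    n <= ``exact_max_n``, and uses the t approximation with n-2 df above
    that.  Two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)

    if n <= exact_max_n:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        obs = abs(float(rxc @ ryc))
        total = 0
        extreme = 0
        chunk: list[tuple] = []

        def flush(chunk):
            perm = np.asarray(chunk)  # (m, n) permutations of ry
            stat = np.abs((perm - ry.mean()) @ rxc)
            return int(np.sum(stat >= obs - 1e-12))

        for p in itertools.permutations(ry):
            chunk.append(p)
            total += 1
            if len(chunk) == 50000:
                extreme += flush(chunk)
                chunk = []
        if chunk:
            extreme += flush(chunk)
        p_val = extreme / total
        return TestResult(rho, p_val, df=None, sided="two-sided")

    if abs(rho) >= 1.0:
        return TestResult(rho, 0.0, df=n - 2)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return TestResult(rho, p_from_t(t, n - 2), df=n - 2)


def two_way_interaction(values, factor_a, factor_b) -> TestResult:
    """Interaction F test from a two-way ANOVA with replicates.

    Intended for the balanced 2x2 design used to ask whether pattern
    similarity depends jointly on retinotopic position group and the learned
    category rule; the fit is delegated to statsmodels OLS + anova_lm.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "v": np.asarray(values, dtype=float),
            "a": pd.Categorical(factor_a),
            "b": pd.Categorical(factor_b),
        }
    )
    counts = df.groupby(["a", "b"], observed=True).size()
    if counts.min() < 2:
        raise ValueError("each cell needs at least 2 replicates")
    if counts.nunique() != 1:
        raise ValueError("design must be balanced")
    fit = smf.ols("v ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(a):C(b)"]
    df_resid = float(table.loc["Residual", "df"])
    return TestResult(
        float(row["F"]), float(row["PR(>F)"]), df=(float(row["df"]), df_resid)
    )
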