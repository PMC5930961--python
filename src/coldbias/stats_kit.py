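"""Statistical tests used across the pipeline, with explicit tail contracts.

Thin, contract-preserving wrappers over :mod:`scipy.stats`: one-sample /
paired / two-sample t-tests (the one-sample default null is a bias ratio of
1), the equal-split chi-square goodness-of-fit used to compare the two
substitution directions, Pearson/Spearman correlation, and ordinary
least-squares regression. Degenerate inputs (zero variance, constant
vectors) return a flagged missing result instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

TAILS = ("two_sided", "greater", "less")
_SCIPY_TAIL = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    df: float | None
    p_value: float | None
    tail: str
    method: str
    missing: bool = False
    missing_reason: str | None = None

    @property
    def stars(self) -> str:
        """Significance stars: ``*`` p<0.05, ``**`` p<0.01."""
        if self.p_value is None:
            return ""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _missing(method: str, tail: str, reason: str) -> TestResult:
    return TestResult(None, None, None, tail, method, missing=True, missing_reason=reason)


def t_test(
    values_a: Sequence[float],
    values_b: Sequence[float] | None = None,
    mode: str = "one_sample_mu1",
    tail: str = "two_sided",
    mu: float = 1.0,
    equal_var: bool = False,
) -> TestResult:
    """t-test in the pipeline's three modes.

    ``one_sample_mu1`` tests the mean of ``values_a`` against ``mu``
    (default 1, the unbiased-ratio null); ``paired`` and ``two_sample``
    compare two groups. The two-sample form is Welch's by default
    (``equal_var=True`` selects the pooled-variance form, with df adjusted
    accordingly). ``tail='greater'`` tests mean(a) > mu (or > mean(b)).
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    a = np.asarray(values_a, dtype=float)
    alt = _SCIPY_TAIL[tail]
    if mode == "one_sample_mu1":
        if a.size < 2:
            return _missing("one-sample t-test", tail, "need n >= 2")
        if np.ptp(a) == 0:
            return _missing("one-sample t-test", tail, "zero variance")
        res = sps.ttest_1samp(a, popmean=mu, alternative=alt)
        return TestResult(float(res.statistic), float(a.size - 1), float(res.pvalue), tail, "one-sample t-test")
    if values_b is None:
        raise ValueError(f"mode {mode!r} needs a second sample")
    b = np.asarray(values_b, dtype=float)
    if mode == "paired":
        if a.size != b.size:
            raise ValueError("paired t-test needs equal-length samples")
        if a.size < 2:
            return _missing("paired t-test", tail, "need n >= 2")
        if np.ptp(a - b) == 0:
            if np.allclose(a, b):
                # identical vectors: statistic 0 by convention
                p = 1.0 if tail == "two_sided" else 0.5
                return TestResult(0.0, float(a.size - 1), p, tail, "paired t-test")
            return _missing("paired t-test", tail, "zero variance of differences")
        res = sps.ttest_rel(a, b, alternative=alt)
        return TestResult(float(res.statistic), float(a.size - 1), float(res.pvalue), tail, "paired t-test")
    if mode == "two_sample":
        if a.size < 2 or b.size < 2:
            return _missing("two-sample t-test", tail, "need n >= 2 in both groups")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return _missing("two-sample t-test", tail, "zero variance")
        res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alt)
        if equal_var:
            df = float(a.size + b.size - 2)
            method = "two-sample t-test (pooled)"
        else:
            df = float(res.df)
            method = "two-sample t-test (Welch)"
        return TestResult(float(res.statistic), df, float(res.pvalue), tail, method)
    raise ValueError(f"unknown t-test mode {mode!r}")


def chisq_gof(observed: Sequence[int]) -> TestResult:
    """Chi-square goodness-of-fit of two counts against an equal split.

    Used to test directional substitution counts (s1 vs s2) against the
    symmetric null; df = 1, no continuity correction.
    """
    if len(observed) != 2:
        raise ValueError("chisq_gof expects exactly two counts")
    a, b = observed
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0:
        return _missing("chi-square goodness-of-fit", "two_sided", "zero total count")
    res = sps.chisquare([a, b])
    return TestResult(float(res.statistic), 1.0, float(res.pvalue), "two_sided", "chi-square goodness-of-fit")


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson", tail: str = "two_sided"
) -> TestResult:
    """Pearson or Spearman correlation with its p-value.

    Spearman uses mid-rank averaging for ties. The returned ``statistic`` is
    r (or rho); df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    name = f"{method} correlation"
    if x.size < 3:
        return _missing(name, tail, "need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _missing(name, tail, "constant input")
    alt = _SCIPY_TAIL[tail]
    if method == "pearson":
        res = sps.pearsonr(x, y, alternative=alt)
    elif method == "spearman":
        res = sps.spearmanr(x, y, alternative=alt)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return TestResult(float(res.statistic), float(x.size - 2), float(res.pvalue), tail, name)


@dataclass(frozen=True)
class RegressionResult:
    slope: float | None
    intercept: float | None
    r_squared: float | None
    test: TestResult


def linregress(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x; R^2 is the squared Pearson r, df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        return RegressionResult(None, None, None, _missing("linear regression", "two_sided", "need n >= 3"))
    if np.ptp(x) == 0:
        return RegressionResult(None, None, None, _missing("linear regression", "two_sided", "constant x"))
    res = sps.linregress(x, y)
    test = TestResult(
        float(res.slope / res.stderr) if res.stderr > 0 else float("inf"),
        float(x.size - 2),
        float(res.pvalue),
        "two_sided",
        "linear regression",
    )
    return RegressionResult(float(res.slope), float(res.intercept), float(res.rvalue**2), test)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional report column)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adjusted = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adjusted[idx] = running
    return adjusted.tolist()
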