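"""Inferential toolbox: exact sign test, Pearson r, Levene's test, Welch t.

Each test is written out from its defining formulas (so results can be
checked against independent implementations); only the t and F
distribution functions come from scipy.  No multiple-testing correction
is applied anywhere, matching how such field studies report collections
of exploratory tests; this is deliberate and documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    n_used: int = 0
    tail: str = "two"
    note: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")

    def __str__(self) -> str:
        df = "" if self.df is None else f", df = {self.df}"
        return f"{self.name}: statistic = {self.statistic:.4g}{df}, p = {self.p_value:.4g}"


def sign_test(n_positive: int, n_negative: int, tail: str = "two") -> TestResult:
    """Exact sign test on the counts of positive and negative differences.

    Ties must be dropped before counting (the caller logs them).  The
    two-sided p is twice the smaller binomial(n, 1/2) tail, capped at 1;
    twelve concordant moves out of twelve give p = 2 * 0.5**12 = 0.000488,
    printing as 0.0005 at four decimals.
    """
    k, m = int(n_positive), int(n_negative)
    n = k + m
    if n < 1:
        raise ValueError("sign test needs at least one informative pair")
    # exact binomial tails at p = 1/2
    pmf = [math.comb(n, i) * 0.5 ** n for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    if tail == "two":
        p = min(1.0, 2.0 * min(lower, upper))
    elif tail == "greater":
        p = upper
    elif tail == "less":
        p = lower
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return TestResult("sign test", float(k), p, df=None, n_used=n, tail=tail)


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with the t-based two-sided p-value.

    p comes from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of
    freedom.  |r| = 1 gives p = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("Pearson r needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined for constant input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return TestResult("Pearson r", r, p, df=n - 2, n_used=n)


def levene_test(*groups, center: str = "mean") -> TestResult:
    """Levene's test for equality of variances across k groups.

    Classic (mean-centred) Levene by default -- the variant plainly called
    "Levene's test"; ``center='median'`` gives the Brown-Forsythe flavour.
    F is the one-way ANOVA statistic on the absolute deviations, with
    (k - 1, N - k) degrees of freedom.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    gs = [g[np.isfinite(g)] for g in gs]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("Levene's test needs >= 2 groups with >= 2 values each")
    loc = np.mean if center == "mean" else np.median
    z = [np.abs(g - loc(g)) for g in gs]
    n = np.array([zi.size for zi in z])
    N, k = int(n.sum()), len(z)
    zbar_i = np.array([zi.mean() for zi in z])
    zbar = float(np.concatenate(z).mean())
    between = float(np.sum(n * (zbar_i - zbar) ** 2))
    within = float(sum(np.sum((zi - zb) ** 2) for zi, zb in zip(z, zbar_i)))
    if within == 0:
        raise ValueError("all groups constant; Levene statistic undefined")
    F = (N - k) / (k - 1) * between / within
    p = float(sps.f.sf(F, k - 1, N - k))
    return TestResult("Levene's test", F, p, df=(k - 1, N - k), n_used=N)


def welch_t(x, y) -> TestResult:
    """Welch's two-sample t-test (unequal variances, Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("Welch t needs >= 2 values per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return TestResult("Welch t", 0.0, 1.0, df=nx + ny - 2, n_used=nx + ny)
    t = float((x.mean() - y.mean()) / math.sqrt(se2))
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult("Welch t", t, p, df=float(df), n_used=nx + ny)
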