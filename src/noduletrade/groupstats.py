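"""Group-difference and trait-association tests.

One-way ANOVA (built from the classical sum-of-squares decomposition)
tests whether head width differs among termite genera and whether
nodule diameter and density differ among cultivar clades. Pearson
correlation on log(n+1)-transformed data tests whether farmer size
tracks cultivar nodule size (expected positive) and nodule density
(expected negative).

Both statistics are computed from first principles here; the test
suite cross-checks them against scipy's reference implementations.
No multiple-testing correction is applied: the analysis reports three
separate ANOVAs and two correlations, each at its nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: Mapping[str, float]
    ss_between: float
    ss_within: float
    ss_total: float

    def summary(self) -> str:
        lines = [
            "One-way ANOVA",
            "=" * 44,
            f"{'F':<16}{self.f_stat:>12.4g}"
            f"  df = ({self.df_between}, {self.df_within})",
            f"{'p':<16}{self.p_value:>12.4g}",
            f"{'SS between':<16}{self.ss_between:>12.6g}",
            f"{'SS within':<16}{self.ss_within:>12.6g}",
        ]
        for g, m in self.group_means.items():
            lines.append(f"  mean[{g}] = {m:.6g}")
        return "\n".join(lines)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with the OLS line on (transformed) pairs."""

    r: float
    slope: float
    intercept: float
    p_value: float
    n: int
    transform: str

    def summary(self) -> str:
        return (
            f"Pearson correlation (transform={self.transform}): "
            f"r = {self.r:.4f}, slope = {self.slope:.4g}, "
            f"p = {self.p_value:.4g}, n = {self.n}"
        )


def anova_oneway(
    values: Sequence[float],
    groups: Sequence,
    welch: bool = False,
) -> AnovaResult:
    """One-way ANOVA from the sum-of-squares decomposition.

    F = (SSB / (k-1)) / (SSW / (N-k)) with p from the F distribution.
    ``welch=True`` applies Welch's unequal-variance correction instead
    (Welch-Satterthwaite degrees of freedom); the classical test is the
    default.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("values and groups must be equal-length 1-D")
    labels = list(dict.fromkeys(g.tolist()))  # first-appearance order
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    samples = [y[g == lab] for lab in labels]
    sizes = np.array([s.size for s in samples])
    if sizes.min() < 1:
        raise ValueError("every group needs at least one value")
    N = int(sizes.sum())
    k = len(labels)
    if N - k < 1:
        raise ValueError("all groups are singletons (zero within-group df)")
    means = np.array([s.mean() for s in samples])
    grand = y.mean()
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((s - m) ** 2) for s, m in zip(samples, means)))
    ss_total = float(np.sum((y - grand) ** 2))
    group_means = {lab: float(m) for lab, m in zip(labels, means)}

    if not welch:
        df_b, df_w = k - 1, N - k
        msb = ss_between / df_b
        msw = ss_within / df_w
        f = msb / msw if msw > 0 else (0.0 if msb == 0 else float("inf"))
        p = float(stats.f.sf(f, df_b, df_w))
        return AnovaResult(
            float(f), df_b, df_w, p, group_means,
            ss_between, ss_within, ss_total,
        )

    # Welch: weight by n_j / s_j^2; needs >= 2 values per group
    if sizes.min() < 2:
        raise ValueError("Welch ANOVA needs >= 2 values in every group")
    var = np.array([s.var(ddof=1) for s in samples])
    if np.any(var == 0):
        raise ValueError("Welch ANOVA undefined for zero-variance groups")
    w = sizes / var
    grand_w = float(np.sum(w * means) / np.sum(w))
    f_num = float(np.sum(w * (means - grand_w) ** 2) / (k - 1))
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (sizes - 1))
    f_den = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    df_w_welch = float((k**2 - 1) / (3.0 * lam))
    f = f_num / f_den
    p = float(stats.f.sf(f, k - 1, df_w_welch))
    return AnovaResult(
        float(f), k - 1, int(round(df_w_welch)), p, group_means,
        ss_between, ss_within, ss_total,
    )


def log1p_standardize(values: Sequence[float]) -> np.ndarray:
    """Elementwise natural log of (value + 1); rejects negative input.

    The transform standardizes count-like, right-skewed measurements
    before correlation while keeping zeros at zero; it is strictly
    monotone, so orderings are preserved.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("log1p standardization requires values >= 0")
    return np.log1p(x)


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    transform: str = "log1p",
) -> CorrelationResult:
    """Pearson correlation and OLS line, optionally on log1p scales.

    Returns r, the fitted slope/intercept on the (transformed) scale and
    a two-sided p-value from the t distribution with n-2 degrees of
    freedom. Requires at least 3 pairs and nonzero variance in both
    variables after the transform.
    """
    if transform not in ("log1p", "none"):
        raise ValueError("transform must be 'log1p' or 'none'")
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = xv.size
    if n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if transform == "log1p":
        xv = log1p_standardize(xv)
        yv = log1p_standardize(yv)
    sxx = float(np.sum((xv - xv.mean()) ** 2))
    syy = float(np.sum((yv - yv.mean()) ** 2))
    if sxx == 0 or syy == 0:
        raise ValueError("correlation undefined for a constant vector")
    sxy = float(np.sum((xv - xv.mean()) * (yv - yv.mean())))
    r = sxy / np.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    slope = sxy / sxx
    intercept = float(yv.mean() - slope * xv.mean())
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(
        r=float(r),
        slope=float(slope),
        intercept=intercept,
        p_value=p,
        n=n,
        transform=transform,
    )
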