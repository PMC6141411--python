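"""Agreement and comparison statistics for paired measurement series.

Implements the metrics conventionally used to compare two measurements of
the same quantity (rest vs. stress replicates, or two modalities): Pearson
correlation, Lin's concordance correlation coefficient, Bland-Altman bias
and 95% limits of agreement, a paired Student t test, and a normality check
of the differences.

Conventions
-----------
* Differences are always ``y - x`` (second argument minus first).
* Lin's ccc uses population (1/n) moments, per Lin's original definition;
  1/(n-1) variants differ noticeably at small n.
* The normality check is a Lilliefors-corrected Kolmogorov-Smirnov test
  (mean and SD estimated from the data); a naive KS p-value would be
  anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

__all__ = [
    "AgreementReport",
    "pearson",
    "lin_ccc",
    "bland_altman",
    "paired_ttest",
    "ks_normality",
    "agreement_report",
    "bland_altman_plot",
    "scatter_plot",
]


def _paired(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    return x, y


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x, y = _paired(x, y)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y).statistic)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ``ccc = 2 s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2)`` with population
    (1/n) moments.  Penalizes location and scale shifts as well as
    dispersion, hence ``|ccc| <= |r|``; equals ``r`` iff the two series have
    equal means and variances.  Two identical constant series concord
    perfectly (ccc = 1).
    """
    x, y = _paired(x, y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    sx2 = np.mean((x - x.mean()) ** 2)
    sy2 = np.mean((y - y.mean()) ** 2)
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:  # both constant and equal
        return 1.0
    return float(2.0 * sxy / denom)


def bland_altman(x, y):
    """Bland-Altman bias, its 95% CI and the 95% limits of agreement.

    Differences are ``d = y - x``; bias = mean d; the CI uses the t
    distribution (``bias +- t_{0.975, n-1} SD / sqrt(n)``); the limits of
    agreement are ``bias +- 1.96 SD`` with the sample (n-1) SD.

    Returns
    -------
    (bias, (ci_lo, ci_hi), (loa_lo, loa_hi))
    """
    x, y = _paired(x, y)
    d = y - x
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = float(sps.t.ppf(0.975, n - 1))
    half_ci = tcrit * sd / np.sqrt(n)
    return (
        bias,
        (bias - half_ci, bias + half_ci),
        (bias - 1.96 * sd, bias + 1.96 * sd),
    )


def paired_ttest(x, y):
    """Two-sided paired Student t test on ``y - x``.

    Returns ``(t, p)``; both are NaN when the differences have zero variance
    (the statistic is undefined — e.g. x == y), which callers should treat
    as a flag rather than a significance result.
    """
    x, y = _paired(x, y)
    d = y - x
    if np.var(d, ddof=1) == 0:
        return float("nan"), float("nan")
    res = sps.ttest_rel(y, x)
    return float(res.statistic), float(res.pvalue)


def ks_normality(d) -> float:
    """Lilliefors-corrected Kolmogorov-Smirnov normality p-value.

    Tests the differences against a normal distribution with mean and SD
    estimated from the sample; p-values come from simulated small-sample
    tables.
    """
    d = np.asarray(d, dtype=float)
    if d.size < 4:
        raise ValueError("need at least 4 values for the normality test")
    if np.var(d) == 0:
        return 0.0
    return float(_lilliefors(d, dist="norm", pvalmethod="table")[1])


@dataclass
class AgreementReport:
    """Agreement statistics for one paired series."""

    n: int
    pearson_r: float
    lin_ccc: float
    bias: float
    bias_ci95: tuple
    loa95: tuple
    t_stat: float
    t_p: float
    ks_p: float
    labels: tuple = ("x", "y")
    unit: str = ""

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "lin_ccc": self.lin_ccc,
            "bias": self.bias,
            "bias_ci95": list(self.bias_ci95),
            "loa95": list(self.loa95),
            "t_stat": self.t_stat,
            "t_p": self.t_p,
            "ks_p": self.ks_p,
            "labels": list(self.labels),
            "unit": self.unit,
        }


def agreement_report(x, y, labels=("x", "y"), unit: str = "") -> AgreementReport:
    """Full agreement panel (r, ccc, Bland-Altman, paired t, KS normality)."""
    x, y = _paired(x, y)
    bias, ci, loa = bland_altman(x, y)
    t, p = paired_ttest(x, y)
    return AgreementReport(
        n=int(x.size),
        pearson_r=pearson(x, y),
        lin_ccc=lin_ccc(x, y),
        bias=bias,
        bias_ci95=ci,
        loa95=loa,
        t_stat=t,
        t_p=p,
        ks_p=ks_normality(y - x),
        labels=tuple(labels),
        unit=unit,
    )


def bland_altman_plot(x, y, ax=None, labels=("x", "y"), unit: str = ""):
    """Bland-Altman diagram: differences vs. means, bias and 95% LoA lines."""
    import matplotlib.pyplot as plt

    x, y = _paired(x, y)
    bias, ci, loa = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    mean = (x + y) / 2.0
    ax.scatter(mean, y - x, color="tab:orange", edgecolor="k", zorder=3)
    ax.axhspan(ci[0], ci[1], color="0.85", zorder=1)
    ax.axhline(bias, linestyle="--", color="k")
    for lim in loa:
        ax.axhline(lim, color="k")
    ax.set_xlabel(f"mean of {labels[0]} and {labels[1]} {unit}".strip())
    ax.set_ylabel(f"{labels[1]} - {labels[0]} {unit}".strip())
    return ax


def scatter_plot(x, y, ax=None, labels=("x", "y"), unit: str = ""):
    """Scatter of y vs. x with the identity line, annotated with r and ccc."""
    import matplotlib.pyplot as plt

    x, y = _paired(x, y)
    if ax is None:
        _, ax = plt.subplots()
    lims = (min(x.min(), y.min()), max(x.max(), y.max()))
    ax.plot(lims, lims, color="0.6", zorder=1)
    ax.scatter(x, y, color="tab:orange", edgecolor="k", zorder=3)
    ax.set_xlabel(f"{labels[0]} {unit}".strip())
    ax.set_ylabel(f"{labels[1]} {unit}".strip())
    ax.set_title(f"R = {pearson(x, y):.2f}, ccc = {lin_ccc(x, y):.2f}")
    return ax
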