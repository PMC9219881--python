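"""Group comparisons and concentration-response regression summaries.

Normal-vs-tumor (or depletion/control/enrichment) comparisons use a
two-sided Welch t-test by default — the safe choice for small groups with
unequal variances — with Student and Mann-Whitney alternatives exposed.
Significance stars follow the * p < 0.05 / ** p < 0.001 convention.

The concentration regression is ordinary least squares of band AUC
(% s^-1 ppm) on cholesterol concentration (mM); with three conditions it
is fitted on per-condition means by default, with a per-sample option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError

TEST_METHODS = ("welch", "student", "mannwhitney")


@dataclass
class GroupSamples:
    """Measurements for one experimental group (optionally one study day)."""

    group_label: str
    values: np.ndarray
    day: int | None = None
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("group values must be finite")


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    stars: str
    method: str


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(a: GroupSamples, b: GroupSamples,
                   method: str = "welch") -> ComparisonResult:
    """Two-sided comparison of two groups with significance stars."""
    if method not in TEST_METHODS:
        raise InvalidInputError(f"method must be one of {TEST_METHODS}")
    xa, xb = a.values, b.values
    if xa.size < 2 or xb.size < 2:
        raise InvalidInputError("need n >= 2 per group")
    if np.ptp(xa) == 0 and np.ptp(xb) == 0:
        # no variance anywhere: identical means are indistinguishable
        if xa[0] == xb[0]:
            return ComparisonResult(statistic=0.0, p_value=1.0, stars="",
                                    method=method)
    if method == "mannwhitney":
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
    else:
        res = sps.ttest_ind(xa, xb, equal_var=(method == "student"))
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return ComparisonResult(statistic=float(res.statistic), p_value=p,
                            stars=significance_stars(p), method=method)


def fit_regression(x, y) -> RegressionFit:
    """OLS of y on x with R^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise InvalidInputError("need matched x/y with n >= 2")
    if np.ptp(x) == 0:
        raise InvalidInputError("x values must not all be equal")
    res = sps.linregress(x, y)
    pred = res.intercept + res.slope * x
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(np.clip(r2, 0.0, 1.0)))


def regression_table(measurements: dict, concentrations: dict,
                     on_means: bool = True) -> dict:
    """Concentration-response regression per band.

    ``measurements`` maps band label -> {condition: list of AUC values};
    ``concentrations`` maps condition -> list of concentrations (mM).
    With ``on_means`` (default) each condition contributes one point
    (mean AUC vs mean concentration); otherwise samples are paired in
    order within each condition.
    """
    table = {}
    for band, by_condition in measurements.items():
        xs, ys = [], []
        for condition, values in by_condition.items():
            conc = np.asarray(concentrations[condition], float)
            vals = np.asarray(values, float)
            if on_means:
                xs.append(conc.mean())
                ys.append(vals.mean())
            else:
                if conc.size != vals.size:
                    raise InvalidInputError(
                        f"per-sample fit needs paired values in {condition!r}")
                xs.extend(conc)
                ys.extend(vals)
        fit = fit_regression(np.asarray(xs), np.asarray(ys))
        table[band] = fit
    return table
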