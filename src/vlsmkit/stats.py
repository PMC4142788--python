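"""Behavioral association statistics.

Two analyses operate at the whole-patient level, before any voxelwise
mapping: a Pearson chi-square test of association between two binary
phenotypes (2x2 table), and an ANCOVA comparing digit span between AOS
groups with functional lesion volume as covariate. The ANCOVA is an
ordinary least-squares fit ``y ~ 1 + group + covariate``; the group term is
tested on (1, n - 3) denominator degrees of freedom, and adjusted means are
the fitted group means evaluated at the grand covariate mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table.

    Rows index factor 1 (present/absent), columns factor 2 (present/absent):
    ``a`` = both present, ``b`` = factor 1 only, ``c`` = factor 2 only,
    ``d`` = neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if any(x < 0 for x in (self.a, self.b, self.c, self.d)):
            raise ValueError("cell counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def chi_square(t: TwoByTwo, continuity_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test on a 2x2 table (1 df).

    Uses the closed form ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``; with the
    Yates correction, ``|ad - bc|`` is reduced by ``n/2`` (floored at 0).
    Raises ``ValueError`` when any margin is zero (statistic undefined).
    """
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: zero margin in the 2x2 table")
    det = abs(t.a * t.d - t.b * t.c)
    if continuity_correction:
        det = max(0.0, det - t.n / 2)
    statistic = t.n * det**2 / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(statistic, df=1))
    return float(statistic), p


@dataclass(frozen=True)
class AncovaResult:
    """Covariate-adjusted two-group comparison.

    ``adjusted_means`` maps group label (0, 1) to the fitted mean at the
    grand covariate mean; ``df`` is (numerator, denominator) = (1, n - 3).
    """

    adjusted_means: dict[int, float]
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    slope: float
    group_effect: float
    group_effect_se: float

    @property
    def adjusted_mean_difference(self) -> float:
        return self.adjusted_means[1] - self.adjusted_means[0]


def ancova_group_comparison(
    y: np.ndarray, group: np.ndarray, covariate: np.ndarray
) -> AncovaResult:
    """ANCOVA: ``y ~ intercept + group + covariate`` with an F test on group.

    ``group`` is binary (0/1). Missing outcomes (NaN) are dropped pairwise.
    With a constant covariate the slope is reported as 0 and the model
    reduces to a one-way comparison, still on (1, n - 3) df. Perfect
    collinearity between group and covariate raises ``ValueError``.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    covariate = np.asarray(covariate, dtype=float)
    keep = np.isfinite(y) & np.isfinite(covariate)
    y, group, covariate = y[keep], group[keep], covariate[keep]
    n = y.size
    groups = np.unique(group)
    if groups.size != 2:
        raise ValueError(f"need exactly 2 groups, got {groups.size}")
    g = (group == groups.max()).astype(float)
    if min(g.sum(), n - g.sum()) < 2:
        raise ValueError("need at least 2 patients per group")

    const_cov = np.ptp(covariate) == 0
    if not const_cov:
        # collinearity check: covariate fully determined by group membership
        within_ptp = max(np.ptp(covariate[g == 0]), np.ptp(covariate[g == 1]))
        between = abs(covariate[g == 1].mean() - covariate[g == 0].mean())
        if within_ptp == 0 and between > 0:
            raise ValueError("covariate is perfectly collinear with group")

    if const_cov:
        # one-way comparison; the df convention keeps the covariate's cost
        X = sm.add_constant(g)
        fit = sm.OLS(y, X).fit()
        coef, se = float(fit.params[1]), float(fit.bse[1])
        slope = 0.0
        df_den = n - 3
        f_stat = (coef / se) ** 2
        p = float(sps.f.sf(f_stat, 1, df_den))
        adj = {0: float(fit.params[0]), 1: float(fit.params[0] + coef)}
        return AncovaResult(adj, float(f_stat), (1, df_den), p, slope, coef, se)

    X = np.column_stack([np.ones(n), g, covariate])
    fit = sm.OLS(y, X).fit()
    coef, se = float(fit.params[1]), float(fit.bse[1])
    slope = float(fit.params[2])
    f_stat = (coef / se) ** 2
    df_den = int(fit.df_resid)  # n - 3
    p = float(sps.f.sf(f_stat, 1, df_den))
    cbar = covariate.mean()
    adj = {
        0: float(fit.params[0] + slope * cbar),
        1: float(fit.params[0] + coef + slope * cbar),
    }
    return AncovaResult(adj, float(f_stat), (1, df_den), p, slope, coef, se)
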