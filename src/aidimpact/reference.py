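"""Published reference values from the original sustained-funding evaluation.

These numbers are inputs, not outputs, of this package: the assembled
real-world country panel behind them is not publicly deposited, so they
serve as worked-example material and as arithmetic cross-checks (e.g. the
post-treatment average must equal the mean of the printed yearly effect
estimates, and the lives-saved adjustment must reproduce the printed
adjusted counts).
"""

from __future__ import annotations

#: Yearly synthetic-control effect estimates (deaths per 1,000 WRA) for the
#: 2005-2019 post-treatment period, with placebo p-values (raw and
#: standardised by pre-period RMSPE).
SCM_EFFECT_ESTIMATES: dict[int, float] = {
    2005: -0.1302,
    2006: -0.2259,
    2007: -0.2526,
    2008: -0.3026,
    2009: -0.5077,
    2010: -0.4981,
    2011: -0.8717,
    2012: -0.8661,
    2013: -1.0007,
    2014: -1.0565,
    2015: -0.8516,
    2016: -0.8020,
    2017: -0.7989,
    2018: -0.7794,
    2019: -0.7321,
}

SCM_P_VALUES: dict[int, float] = {
    2005: 0.579, 2006: 0.526, 2007: 0.526, 2008: 0.474, 2009: 0.368,
    2010: 0.421, 2011: 0.263, 2012: 0.263, 2013: 0.263, 2014: 0.211,
    2015: 0.316, 2016: 0.316, 2017: 0.316, 2018: 0.316, 2019: 0.368,
}

#: Printed post-treatment average of the yearly effect estimates.
SCM_POST_AVERAGE: float = -0.6451

#: Years in which the standardised placebo p-value fell below 0.001.
SIGNIFICANT_YEARS: list[int] = list(range(2009, 2020))

#: Effect over the significant years, as printed (magnitude, 2 d.p.).
SCM_SIGNIFICANT_AVERAGE: float = -0.80

#: Number of donor-pool countries (denominator of every placebo p-value).
N_DONORS: int = 19

#: Donor-pool attrition: candidates surviving the income/funding screens,
#: the population screen, the ascending-trend screen, and the
#: existence/HIV-data screens.
COHORT_STAGE_COUNTS: tuple[int, int, int, int] = (77, 59, 23, 19)

#: Funding medians used to pick the treated unit (opaque units, current USD).
MEDIAN_TOTAL_FUNDING: float = 45_557.0
MEDIAN_PC_FUNDING: float = 2.73

#: Latent-factor-model post-average effects (limited / expanded predictor
#: sets) with 90% credible intervals.
BM_POST_AVERAGE_LIMITED: tuple[float, float, float] = (-1.29, -0.18, -2.40)
BM_POST_AVERAGE_EXPANDED: tuple[float, float, float] = (-0.96, -0.18, -1.73)

#: Residual-ATE / baseline-ATE ratios.
RESIDUAL_RATIO_SCM: float = 1.04
RESIDUAL_RATIO_BM: float = 1.35

#: Lives-saved accounting: unadjusted annual range, the non-USG adjustment
#: share, and the published adjusted annual range.
ANNUAL_LIVES_SAVED_RANGE: tuple[float, float] = (138_573.0, 183_708.0)
NONUSG_ADJUSTMENT_SHARE: float = 0.28
ANNUAL_LIVES_SAVED_ADJUSTED_RANGE: tuple[int, int] = (99_773, 132_270)
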