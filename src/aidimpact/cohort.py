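"""Cohort construction: treated-unit selection and donor-pool filtering.

Treated countries are those with sustained (every year of a funding window),
broad (multiple health programme areas) and above-median donor health
funding, where medians are taken over the reference set of substantially
funded countries, separately for mean annual total funding and mean annual
per-capita funding.  The donor pool is then drawn from the remaining low-
and middle-income countries by a sequence of eligibility filters, each of
which is logged with per-unit exclusion reasons so the attrition from the
initial candidate list down to the final pool is fully auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CountryYearPanel, StudyDesign

__all__ = [
    "FundingThresholds",
    "CohortReport",
    "compute_funding_medians",
    "select_treatment_unit",
    "ascending_trend",
    "filter_donor_pool",
]


@dataclass
class FundingThresholds:
    """Median funding cut-offs over a reference set of funded countries."""

    median_total: float
    median_pc: float
    reference_units: tuple[str, ...]
    window: tuple[int, int]


@dataclass
class CohortReport:
    """Stage-by-stage attrition record for donor-pool filtering."""

    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)

    def log_stage(self, name: str, remaining) -> None:
        self.stage_counts.append((name, len(remaining)))

    def exclude(self, unit: str, reason: str) -> None:
        self.excluded.setdefault(unit, reason)

    def counts(self) -> list[int]:
        return [n for _, n in self.stage_counts]

    def to_json(self, path) -> None:
        payload = {
            "stages": [{"stage": s, "remaining": n} for s, n in self.stage_counts],
            "excluded": self.excluded,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _unit_means(panel: CountryYearPanel, units, column: str,
                window: tuple[int, int]) -> pd.Series:
    lo, hi = window
    sub = panel.data[
        panel.data["unit_id"].isin(set(units))
        & panel.data["year"].between(lo, hi)
    ]
    return sub.groupby("unit_id")[column].mean()


def compute_funding_medians(panel: CountryYearPanel, window: tuple[int, int],
                            reference_units) -> FundingThresholds:
    """Median of per-unit mean annual total and per-capita funding.

    Each reference unit contributes its mean annual funding over the window;
    the thresholds are the medians of those per-unit means (midpoint of the
    two central values for an even count).
    """
    reference_units = tuple(sorted(set(reference_units)))
    if not reference_units:
        raise ValueError("empty reference set for funding medians")
    totals = _unit_means(panel, reference_units, "usg_funding_total", window)
    pcs = _unit_means(panel, reference_units, "usg_funding_pc", window)
    missing = [u for u in reference_units if u not in totals.index]
    if missing:
        raise ValueError(f"reference units without funding data in window: {missing}")
    return FundingThresholds(
        median_total=float(np.median(totals.loc[list(reference_units)])),
        median_pc=float(np.median(pcs.loc[list(reference_units)])),
        reference_units=reference_units,
        window=tuple(window),
    )


def select_treatment_unit(panel: CountryYearPanel, thresholds: FundingThresholds,
                          window: tuple[int, int] | None = None,
                          breadth_flags: dict[str, bool] | None = None,
                          strict: bool = True) -> set[str]:
    """Units with sustained, broad, above-median funding.

    A unit qualifies if it (a) has positive funding every year of the
    window, (b) is flagged as funded across a broad range of health areas,
    and (c) exceeds both the total and the per-capita funding median.
    ``strict`` controls whether "above median" is strict (>, the default)
    or weak (>=); strictness matters for borderline units sitting exactly
    at a median.
    """
    if window is None:
        window = thresholds.window
    lo, hi = window
    n_years = hi - lo + 1
    selected = set()
    means_total = _unit_means(panel, panel.units, "usg_funding_total", window)
    means_pc = _unit_means(panel, panel.units, "usg_funding_pc", window)
    for unit in panel.units:
        sub = panel.data[
            (panel.data["unit_id"] == unit) & panel.data["year"].between(lo, hi)
        ]
        funded_years = int((sub["usg_funding_total"] > 0).sum())
        if funded_years < n_years:
            continue
        if breadth_flags is not None and not breadth_flags.get(unit, False):
            continue
        if breadth_flags is None and "funding_breadth" in panel.data.columns:
            if not bool(sub["funding_breadth"].iloc[0]):
                continue
        mt, mp = means_total.get(unit, 0.0), means_pc.get(unit, 0.0)
        if strict:
            ok = mt > thresholds.median_total and mp > thresholds.median_pc
        else:
            ok = mt >= thresholds.median_total and mp >= thresholds.median_pc
        if ok:
            selected.add(unit)
    return selected


def ascending_trend(series) -> bool:
    """True iff the OLS slope of value on year is strictly positive.

    ``series`` is an iterable of (year, value) pairs or a pandas Series
    indexed by year; at least three points are required.
    """
    if isinstance(series, pd.Series):
        years = np.asarray(series.index, dtype=float)
        values = series.to_numpy(dtype=float)
    else:
        pairs = list(series)
        years = np.array([p[0] for p in pairs], dtype=float)
        values = np.array([p[1] for p in pairs], dtype=float)
    if len(years) < 3:
        raise ValueError("ascending_trend needs at least 3 points")
    slope = np.polyfit(years, values, 1)[0]
    # a flat series must not register as ascending through float noise
    tol = 1e-12 * max(1.0, float(np.abs(values).max()))
    return bool(slope > tol)


def filter_donor_pool(panel: CountryYearPanel, thresholds: FundingThresholds,
                      design: StudyDesign,
                      treated_units=(),
                      min_population: float = 500_000,
                      strict: bool = True) -> tuple[set[str], CohortReport]:
    """Sequential donor-pool eligibility filters with full attrition logging.

    Stages, in order:

    1. low- or lower/upper-middle-income classification at baseline;
    2. not treated: not in the treated set and not above both funding
       medians (low or sporadic funding is allowed -- exposure to *some*
       funding does not disqualify a donor);
    3. population at least ``min_population`` in the year before treatment;
    4. ascending pre-period trend in the share of WRA deaths among total
       deaths (matching the treated unit's rising pre-period mortality);
    5. unit existed (has data) for the full pre-period;
    6. HIV-prevalence predictor observed throughout the pre-period.
    """
    report = CohortReport()
    treated_units = set(treated_units)
    candidates = [u for u in panel.units if u not in treated_units]
    report.log_stage("candidates", candidates)

    df = panel.data
    baseline_class = (
        df.dropna(subset=["income_class_baseline"])
        .groupby("unit_id")["income_class_baseline"]
        .first()
        if "income_class_baseline" in df.columns
        else pd.Series(dtype=object)
    )

    stage1 = []
    for u in candidates:
        cls = baseline_class.get(u, "low")
        if cls in ("low", "lower-middle", "upper-middle"):
            stage1.append(u)
        else:
            report.exclude(u, "high-income at baseline")
    report.log_stage("income_class", stage1)

    lo, hi = thresholds.window
    means_total = _unit_means(panel, stage1, "usg_funding_total", (lo, hi))
    means_pc = _unit_means(panel, stage1, "usg_funding_pc", (lo, hi))
    stage2 = []
    for u in stage1:
        mt, mp = means_total.get(u, 0.0), means_pc.get(u, 0.0)
        if np.isnan(mt):
            mt = 0.0
        if np.isnan(mp):
            mp = 0.0
        if strict:
            above_both = mt > thresholds.median_total and mp > thresholds.median_pc
        else:
            above_both = mt >= thresholds.median_total and mp >= thresholds.median_pc
        if above_both:
            report.exclude(u, "above-median funding (treated-like exposure)")
        else:
            stage2.append(u)
    report.log_stage("funding_exposure", stage2)

    ref_year = design.treatment_year - 1
    pop = df[df["year"] == ref_year].set_index("unit_id")["wra_pop"] \
        if "population_total" not in df.columns \
        else df[df["year"] == ref_year].set_index("unit_id")["population_total"]
    stage3 = []
    for u in stage2:
        p = pop.get(u, np.nan)
        if pd.notna(p) and p >= min_population:
            stage3.append(u)
        else:
            report.exclude(u, f"population below {min_population:,.0f} in {ref_year}")
    report.log_stage("population", stage3)

    stage4 = []
    for u in stage3:
        sub = df[(df["unit_id"] == u) & df["year"].isin(design.pre_years)]
        share = (sub["wra_deaths"] / sub["total_deaths"]).to_numpy(dtype=float)
        years = sub["year"].to_numpy()
        finite = np.isfinite(share)
        if finite.sum() < 3:
            # trend undefined on < 3 points; deferred to the existence stage
            stage4.append(u)
        elif ascending_trend(pd.Series(share[finite], index=years[finite])):
            stage4.append(u)
        else:
            report.exclude(u, "no ascending pre-period trend in WRA share of deaths")
    report.log_stage("ascending_trend", stage4)

    stage5 = []
    for u in stage4:
        sub = df[(df["unit_id"] == u) & df["year"].isin(design.pre_years)]
        years_present = set(sub.loc[sub["outcome"].notna(), "year"])
        if set(design.pre_years) <= years_present:
            stage5.append(u)
        else:
            report.exclude(u, "established after study start / not present for full pre-period")
    report.log_stage("existence", stage5)

    stage6 = []
    for u in stage5:
        sub = df[(df["unit_id"] == u) & df["year"].isin(design.pre_years)]
        if "hiv_prev" in sub.columns and sub["hiv_prev"].notna().all():
            stage6.append(u)
        else:
            report.exclude(u, "HIV data unavailable in pre-period")
    report.log_stage("hiv_data", stage6)

    return set(stage6), report
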