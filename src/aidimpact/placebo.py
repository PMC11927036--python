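"""In-space placebo inference for the synthetic control.

Each donor country is re-analysed as if it had been treated: the synthetic-
control machinery is refitted with that donor as a singleton treated unit
and the remaining donors as its pool.  The resulting ensemble of placebo
gap paths is the permutation null distribution for the treated unit's gaps.
The p-value for a year is the share of placebo units whose gap is at least
as extreme (in absolute value) as the treated gap, so every p-value lies on
the grid {k/J : k = 0..J} for J placebo units.  Standardised p-values apply
the same rank rule after dividing each unit's gaps by its own pre-period
RMSPE, discounting placebos whose large post-period gaps merely reflect a
poor pre-period fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CountryYearPanel, StudyDesign
from .scm import OptimizationError, ScmOptions, ScmSolution, fit_scm

__all__ = [
    "PlaceboEnsemble",
    "PvalueTable",
    "run_placebos",
    "placebo_pvalue",
    "standardized_pvalue",
    "post_average_pvalue",
    "pvalue_table",
]


@dataclass
class PlaceboEnsemble:
    """Treated and placebo gap paths on a common year axis."""

    years: list[int]
    pre_years: list[int]
    treated_gaps: np.ndarray
    treated_rmspe_pre: float
    placebo_gaps: dict[str, np.ndarray]
    placebo_rmspe_pre: dict[str, float]
    failed: list[str] = field(default_factory=list)

    @property
    def post_years(self) -> list[int]:
        return self.years[len(self.pre_years):]

    @property
    def n_placebos(self) -> int:
        return len(self.placebo_gaps)

    def _year_index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise ValueError(f"year {year} outside ensemble range") from None


@dataclass
class PvalueTable:
    """Raw and standardised placebo p-values per year plus the post-average."""

    years: list[int]
    raw: dict[int, float]
    standardized: dict[int, float]
    post_average_raw: float
    post_average_standardized: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "p_value": [self.raw[y] for y in self.years],
                "standardized_p_value": [self.standardized[y] for y in self.years],
            },
            index=pd.Index(self.years, name="year"),
        )
        return df

    def to_dict(self) -> dict:
        return {
            "per_year": {
                int(y): {
                    "p_value": self.raw[y],
                    "standardized_p_value": self.standardized[y],
                }
                for y in self.years
            },
            "post_average": {
                "p_value": self.post_average_raw,
                "standardized_p_value": self.post_average_standardized,
            },
        }

    @staticmethod
    def render_p(p: float) -> str:
        """Human-readable p: zero (more extreme than every placebo) prints
        as '<0.001'."""
        return "<0.001" if p == 0.0 else f"{p:.3f}"


def run_placebos(panel: CountryYearPanel, design: StudyDesign,
                 options: ScmOptions | None = None,
                 treated_solution: ScmSolution | None = None) -> PlaceboEnsemble:
    """Refit the synthetic control with each donor as pseudo-treated.

    A placebo refit that fails to converge is dropped with a warning and the
    effective placebo count shrinks accordingly.
    """
    if treated_solution is None:
        treated_solution = fit_scm(panel, design, options)
    placebo_gaps: dict[str, np.ndarray] = {}
    placebo_rmspe: dict[str, float] = {}
    failed: list[str] = []
    donors = sorted(design.donor_units)
    for d in donors:
        pool = tuple(u for u in donors if u != d)
        pseudo = design.replace(treated_units=(d,), donor_units=pool)
        try:
            sol = fit_scm(panel, pseudo, options)
        except (OptimizationError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            warnings.warn(f"placebo refit failed for {d}: {exc}")
            failed.append(d)
            continue
        placebo_gaps[d] = sol.gaps
        placebo_rmspe[d] = sol.rmspe_pre
    return PlaceboEnsemble(
        years=list(treated_solution.years),
        pre_years=list(treated_solution.pre_years),
        treated_gaps=treated_solution.gaps,
        treated_rmspe_pre=treated_solution.rmspe_pre,
        placebo_gaps=placebo_gaps,
        placebo_rmspe_pre=placebo_rmspe,
        failed=failed,
    )


def _rank_p(treated_stat: float, placebo_stats: np.ndarray) -> float:
    # ties count against the treated unit (>=), the conservative convention
    return float(np.sum(np.abs(placebo_stats) >= abs(treated_stat)) / placebo_stats.size)


def placebo_pvalue(ensemble: PlaceboEnsemble, year: int) -> float:
    """Share of placebo units with an absolute gap at least as large as the
    treated unit's in the given year."""
    i = ensemble._year_index(year)
    stats = np.array([g[i] for g in ensemble.placebo_gaps.values()])
    return _rank_p(ensemble.treated_gaps[i], stats)


def standardized_pvalue(ensemble: PlaceboEnsemble, year: int) -> float:
    """Rank rule on gaps scaled by each unit's own pre-period RMSPE.

    Placebos with a zero pre-period RMSPE (exact pre-period fit) have no
    meaningful scale and are excluded with a warning.
    """
    i = ensemble._year_index(year)
    if ensemble.treated_rmspe_pre <= 0:
        raise ValueError("treated pre-period RMSPE is zero; cannot standardise")
    stats, dropped = [], []
    for u, g in ensemble.placebo_gaps.items():
        r = ensemble.placebo_rmspe_pre[u]
        if r <= 0:
            dropped.append(u)
            continue
        stats.append(g[i] / r)
    if dropped:
        warnings.warn(f"placebos with zero pre-RMSPE excluded: {dropped}")
    return _rank_p(ensemble.treated_gaps[i] / ensemble.treated_rmspe_pre,
                   np.array(stats))


def post_average_pvalue(ensemble: PlaceboEnsemble, post_years=None,
                        standardized: bool = False) -> float:
    """Rank rule applied to each unit's mean post-period gap."""
    if post_years is None:
        post_years = ensemble.post_years
    idx = [ensemble._year_index(y) for y in post_years]
    t_stat = float(np.mean(ensemble.treated_gaps[idx]))
    stats = []
    if standardized:
        if ensemble.treated_rmspe_pre <= 0:
            raise ValueError("treated pre-period RMSPE is zero; cannot standardise")
        t_stat /= ensemble.treated_rmspe_pre
        for u, g in ensemble.placebo_gaps.items():
            r = ensemble.placebo_rmspe_pre[u]
            if r > 0:
                stats.append(np.mean(g[idx]) / r)
    else:
        stats = [np.mean(g[idx]) for g in ensemble.placebo_gaps.values()]
    return _rank_p(t_stat, np.array(stats))


def pvalue_table(ensemble: PlaceboEnsemble, post_years=None) -> PvalueTable:
    """Per-post-year raw and standardised p-values plus the post-average."""
    if post_years is None:
        post_years = ensemble.post_years
    raw = {y: placebo_pvalue(ensemble, y) for y in post_years}
    std = {y: standardized_pvalue(ensemble, y) for y in post_years}
    return PvalueTable(
        years=list(post_years),
        raw=raw,
        standardized=std,
        post_average_raw=post_average_pvalue(ensemble, post_years, standardized=False),
        post_average_standardized=post_average_pvalue(
            ensemble, post_years, standardized=True
        ),
    )
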