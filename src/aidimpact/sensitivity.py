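"""Robustness battery for the funding-effect estimates.

Four checks travel together here: leave-unit-out treatment scenarios
(re-running the full pipeline with named countries dropped from the treated
aggregate); a two-step residual-regression control for the competing,
non-USG funding stream, summarised by the ratio of the residual-outcome ATE
to the baseline ATE; a scan over candidate treatment years; and an in-time
placebo for the Bayesian model in which the pre-period is split in half and
the second half is predicted from the first (a well-specified model should
find no "effect" where no treatment occurred).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .bayes import AttSummary, BmConfig, att_summary, fit_bm
from .panel import CountryYearPanel, StudyDesign
from .placebo import post_average_pvalue, pvalue_table, run_placebos
from .scm import ScmOptions, fit_scm

__all__ = [
    "ScenarioSpec",
    "ResidualAteResult",
    "run_scenario",
    "residualize_outcome",
    "residual_ate_ratio",
    "treatment_year_scan",
    "bm_split_placebo",
]


@dataclass
class ScenarioSpec:
    name: str
    dropped_units: tuple[str, ...] = ()
    treatment_year_override: int | None = None
    method: str = "scm"  # {"scm", "bm", "both"}

    def __post_init__(self) -> None:
        if self.method not in ("scm", "bm", "both"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ResidualAteResult:
    """Residual-outcome vs. baseline treatment effects and their ratio.

    Interpretation of the ratio: near 0 means the competing funding stream
    drives the estimated effect; near 1 means it does not bias the baseline
    estimate; between 0 and 1, partial influence; above 1, the baseline is
    biased towards zero by it.
    """

    base_ate: float
    residual_ate: float
    first_stage_slope: float
    first_stage_intercept: float
    method: str = "scm"

    @property
    def ratio(self) -> float:
        if self.base_ate == 0:
            raise ZeroDivisionError("base ATE is zero; ratio undefined")
        return self.residual_ate / self.base_ate

    def interpretation(self) -> str:
        r = self.ratio
        if r > 1.0:
            return "baseline possibly biased downward by the competing stream"
        if r >= 0.9:
            return "competing funding stream does not bias the baseline"
        if r > 0.1:
            return "partial influence of the competing funding stream"
        return "effect primarily driven by the competing funding stream"


def run_scenario(panel: CountryYearPanel, design: StudyDesign, spec: ScenarioSpec,
                 scm_options: ScmOptions | None = None,
                 bm_config: BmConfig | None = None,
                 with_placebos: bool = True) -> dict:
    """Re-run the pipeline with units dropped from the treated aggregate."""
    unknown = set(spec.dropped_units) - set(design.treated_units)
    if unknown:
        raise ValueError(f"dropped units not in treated set: {sorted(unknown)}")
    remaining = tuple(u for u in design.treated_units if u not in set(spec.dropped_units))
    if not remaining:
        raise ValueError("scenario drops every treated unit")
    d = design.replace(treated_units=remaining)
    if spec.treatment_year_override is not None:
        d = d.replace(treatment_year=spec.treatment_year_override)
    out: dict = {"name": spec.name, "design": d}
    if spec.method in ("scm", "both"):
        sol = fit_scm(panel, d, scm_options)
        out["scm"] = sol
        if with_placebos:
            ens = run_placebos(panel, d, scm_options, treated_solution=sol)
            out["pvalues"] = pvalue_table(ens)
    if spec.method in ("bm", "both"):
        post = fit_bm(panel, d, bm_config)
        out["bm"] = att_summary(post, (bm_config or BmConfig()).ci_level)
    return out


def residualize_outcome(panel: CountryYearPanel, covariate: str = "nonusg_oda_pc"
                        ) -> tuple[CountryYearPanel, float, float]:
    """First stage of the residual-ATE procedure.

    A pooled OLS of the outcome on the named per-capita funding covariate
    (plus intercept) over all units and years; the residual replaces the
    outcome, so the second-stage estimators see mortality net of that
    funding stream.  Returns (panel, slope, intercept).
    """
    if covariate not in panel.data.columns:
        raise KeyError(f"covariate {covariate!r} not in panel")
    x = panel.data[covariate].to_numpy(dtype=float)
    y = panel.data["outcome"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if np.nanstd(x[ok]) == 0:
        raise ValueError(f"covariate {covariate!r} has zero variance")
    model = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
    intercept, slope = model.params
    resid = np.where(ok, y - (intercept + slope * x), y)
    out = panel.with_outcome(resid)
    return out, float(slope), float(intercept)


def residual_ate_ratio(panel: CountryYearPanel, design: StudyDesign,
                       covariate: str = "nonusg_oda_pc",
                       method: str = "scm",
                       scm_options: ScmOptions | None = None,
                       bm_config: BmConfig | None = None) -> ResidualAteResult:
    """Baseline vs residual-outcome ATE on the same design."""
    resid_panel, slope, intercept = residualize_outcome(panel, covariate)
    if method == "scm":
        base = fit_scm(panel, design, scm_options).ate_post
        resid = fit_scm(resid_panel, design, scm_options).ate_post
    elif method == "bm":
        base = att_summary(fit_bm(panel, design, bm_config)).post_average
        resid = att_summary(fit_bm(resid_panel, design, bm_config)).post_average
    else:
        raise ValueError(f"unknown method {method!r}")
    return ResidualAteResult(
        base_ate=float(base), residual_ate=float(resid),
        first_stage_slope=slope, first_stage_intercept=intercept, method=method,
    )


def treatment_year_scan(panel: CountryYearPanel, design: StudyDesign,
                        years, scm_options: ScmOptions | None = None,
                        min_pre_years: int = 5,
                        with_placebos: bool = True) -> dict[int, dict]:
    """Re-run the synthetic-control pipeline for each candidate treatment year.

    Candidates leaving fewer than ``min_pre_years`` pre-treatment years are
    skipped with a warning.  Returns, per year, the post-average effect and
    (optionally) its placebo p-value.
    """
    results: dict[int, dict] = {}
    for y in years:
        if y - design.start_year < min_pre_years:
            warnings.warn(f"candidate year {y} leaves a pre-period shorter than "
                          f"{min_pre_years} years; skipped")
            continue
        if y > design.end_year:
            warnings.warn(f"candidate year {y} beyond the panel; skipped")
            continue
        d = design.replace(treatment_year=y)
        sol = fit_scm(panel, d, scm_options)
        entry = {"ate_post": sol.ate_post, "rmspe_pre": sol.rmspe_pre}
        if with_placebos:
            ens = run_placebos(panel, d, scm_options, treated_solution=sol)
            entry["p_post_average"] = post_average_pvalue(ens, standardized=True)
        results[y] = entry
    return results


def bm_split_placebo(panel: CountryYearPanel, design: StudyDesign,
                     config: BmConfig | None = None) -> AttSummary:
    """In-time placebo for the latent-factor model.

    The panel is truncated to the pre-treatment period; the model is
    trained on the first half (split at floor(T0/2)) and predicts the
    second half, where treated observations are held out exactly as the
    post-period is in the real analysis.  Since no treatment occurred, a
    well-specified model should estimate an effect near zero with a
    credible interval covering zero.
    """
    pre = design.pre_years
    if len(pre) < 6:
        raise ValueError("split placebo needs at least 6 pre-treatment years")
    split = pre[0] + len(pre) // 2
    d = design.replace(end_year=pre[-1], treatment_year=split)
    sub = panel.data[panel.data["year"] <= pre[-1]].copy()
    cfg = config or BmConfig()
    post = fit_bm(CountryYearPanel(sub, predictor_names=panel.predictor_names),
                  d, cfg)
    return att_summary(post, cfg.ci_level)
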