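"""Synthetic country-year panel generator.

Every analysis stage in this package is exercised on simulated panels whose
statistical structure matches what the estimators assume: untreated
mortality follows a latent-factor panel model

    y_it(0) = mu + alpha_i + xi_t + gamma_i' f_t + beta' x_it + eps_it

with a shared hump-shaped year effect xi_t (mortality rising through the
1990s, peaking near 2003, then declining -- the qualitative shape of WRA
mortality in heavily aid-funded countries over 1990-2019), unit-level
autocorrelated covariates, and an additive treatment effect delta(t)
injected into treated units from the treatment year onward (zero before,
ramping to -1.0 deaths per 1,000 WRA by 2014 and then flat, by default).
Funding series give treated units sustained, broad, above-median support
with a sharp post-2004 jump, while donors receive low or sporadic funding.

Populations are log-uniform; death counts are derived from rates and
optionally integer-rounded, in which case the rate/count identity holds to
rounding error.  Every generator returns a ground-truth record (effect
path, coefficients, factor structure, untreated outcome matrix) sufficient
to verify any downstream estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PREDICTOR_NAMES, CountryYearPanel, StudyDesign

__all__ = [
    "DgpConfig",
    "generate_panel",
    "generate_funding",
    "generate_mixture_panel",
    "make_cohort_fixture",
    "default_effect_path",
]

# plausible level ranges for each standard predictor
_PREDICTOR_RANGES = {
    "hiv_prev": (0.1, 8.0),
    "tb_cdr": (30.0, 90.0),
    "cpr_any": (5.0, 60.0),
    "measles_imm": (40.0, 95.0),
    "f_schooling": (1.0, 10.0),
    "pct_urban": (10.0, 70.0),
    "tfr": (2.0, 7.0),
    "f_lfp": (30.0, 90.0),
    "gdp_pc": (300.0, 8000.0),
    "polity5": (-10.0, 10.0),
}

_DEFAULT_EFFECTS = {"hiv_prev": 0.08, "tfr": 0.05, "gdp_pc": -5e-5}


def default_effect_path(treatment_year: int = 2005, end_year: int = 2019,
                        plateau: float = -1.0,
                        ramp_end: int = 2014) -> dict[int, float]:
    """Zero before treatment; linear ramp to ``plateau`` by ``ramp_end``,
    flat thereafter."""
    path = {}
    for y in range(treatment_year, end_year + 1):
        frac = min(1.0, (y - treatment_year + 1) / (ramp_end - treatment_year + 1))
        path[y] = plateau * frac
    return path


@dataclass
class DgpConfig:
    """Data-generating-process settings; ``seed`` is mandatory."""

    seed: int
    n_treated: int = 16
    n_donor_pool: int = 19
    n_extra_units: int = 0
    start_year: int = 1990
    end_year: int = 2019
    treatment_year: int = 2005
    effect_path: dict[int, float] | None = None   # None -> default ramp
    n_factors: int = 2
    factor_scale: float = 0.3
    loading_sd: float = 0.5
    loading_treated_shift: float = 0.0            # factor confounding knob
    noise_sd: float = 0.15
    predictor_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    base_rate: float = 6.0
    unit_sd: float = 0.7
    hump_amplitude: float = 1.3                   # xi rise to the 2003 peak
    peak_year: int = 2003
    pop_range: tuple[float, float] = (2e6, 1.5e8)  # total population
    wra_fraction: float = 0.24
    round_deaths: bool = True
    misspecify: bool = False   # omitted accelerating trend (for failure-mode tests)
    nonusg_correlation: float = 0.0
    funding_window: tuple[int, int] = (2007, 2019)

    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))

    def resolved_effect_path(self) -> dict[int, float]:
        if self.effect_path is not None:
            return {int(y): float(v) for y, v in self.effect_path.items()}
        return default_effect_path(self.treatment_year, self.end_year)


def _xi_path(cfg: DgpConfig) -> np.ndarray:
    """Hump-shaped common year effect: rise to the peak year, then decline."""
    years = np.array(cfg.years(), dtype=float)
    peak = float(cfg.peak_year)
    up = (years - cfg.start_year) / max(peak - cfg.start_year, 1.0)
    down = (years - peak) / max(cfg.end_year - peak, 1.0)
    xi = np.where(
        years <= peak,
        cfg.hump_amplitude * up,
        cfg.hump_amplitude * (1.0 - 1.6 * down),
    )
    return xi - xi.mean()


def _ar1(rng, n, sd, rho=0.8):
    x = np.zeros(n)
    innov_sd = sd * np.sqrt(1 - rho ** 2)
    x[0] = rng.normal(0, sd)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + rng.normal(0, innov_sd)
    return x


def _predictor_series(rng, cfg: DgpConfig, name: str, n_years: int) -> np.ndarray:
    lo, hi = _PREDICTOR_RANGES[name]
    base = rng.uniform(lo, hi)
    trend = rng.normal(0, (hi - lo) / (4 * n_years))
    noise = _ar1(rng, n_years, (hi - lo) * 0.02)
    series = base + trend * np.arange(n_years) + noise
    return np.clip(series, lo * 0.5 if lo > 0 else lo * 1.5, hi * 1.2)


def generate_funding(cfg: DgpConfig, treated: list[str], donors: list[str],
                     extras: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Funding columns for every unit-year.

    Treated units: positive funding every year, a sharp post-2004 level
    jump, breadth flag on, and per-unit mean total/per-capita funding that
    sits strictly above the medians of the funded reference set by
    construction.  Donor units: low, sporadic funding (funded in fewer than
    six years of the window), with total and per-capita levels anti-ranked
    so that no donor exceeds both medians.  Non-USG ODA per capita is drawn
    with a configurable correlation to USG per-capita funding.
    """
    years = cfg.years()
    rows = []
    jump_year = 2005
    for u in treated:
        level_total = rng.uniform(80.0, 200.0)
        level_pc = rng.uniform(3.5, 8.0)
        for y in years:
            scale = 1.0 if y >= jump_year else 0.35
            total = level_total * scale * rng.uniform(0.9, 1.1)
            pc = level_pc * scale * rng.uniform(0.9, 1.1)
            rows.append((u, y, total, pc, True))
    pool = donors + extras
    lo_w, hi_w = cfg.funding_window
    window_years = [y for y in years if lo_w <= y <= hi_w] or years
    n_w = len(window_years)
    ranks = rng.permutation(max(len(pool), 1))
    for j, u in enumerate(pool):
        # anti-ranked window means: donors high in total funding are low per
        # capita, so no donor sits above both medians
        q = (ranks[j] + 0.5) / len(pool)
        target_total = 2.0 + 26.0 * q
        target_pc = 0.05 + 0.75 * (1.0 - q)
        n_funded = int(rng.integers(1, min(4, n_w + 1)))
        funded = set(rng.choice(window_years, size=n_funded, replace=False).tolist())
        per_year_total = target_total * n_w / n_funded
        per_year_pc = target_pc * n_w / n_funded
        outside = [y for y in years if y not in window_years]
        sporadic = set(rng.choice(outside, size=min(2, len(outside)),
                                  replace=False).tolist())
        for y in years:
            if y in funded:
                rows.append((u, y, per_year_total, per_year_pc, False))
            elif y in sporadic:
                rows.append((u, y, target_total * 0.5, target_pc * 0.5, False))
            else:
                rows.append((u, y, 0.0, 0.0, False))
    df = pd.DataFrame(
        rows,
        columns=["unit_id", "year", "usg_funding_total", "usg_funding_pc",
                 "funding_breadth"],
    )
    base_oda = rng.uniform(5.0, 60.0, size=len(df))
    rho = cfg.nonusg_correlation
    pc = df["usg_funding_pc"].to_numpy()
    pc_sd = pc.std() or 1.0
    df["nonusg_oda_pc"] = np.clip(
        base_oda + rho * 10.0 * (pc - pc.mean()) / pc_sd
        + rng.normal(0, 3.0, size=len(df)),
        0.0, None,
    )
    return df


def generate_panel(cfg: DgpConfig) -> tuple[CountryYearPanel, dict]:
    """Draw a full panel and its ground truth.

    Returns ``(panel, truth)`` where ``truth`` records the untreated outcome
    matrix ``y0`` (pre-rounding rates), the injected effect path, all
    structural parameters, and the generated study design.
    """
    rng = np.random.default_rng(cfg.seed)
    years = cfg.years()
    n_years = len(years)
    treated = [f"T{i:02d}" for i in range(cfg.n_treated)]
    donors = [f"D{i:02d}" for i in range(cfg.n_donor_pool)]
    extras = [f"X{i:02d}" for i in range(cfg.n_extra_units)]
    units = treated + donors + extras
    n_units = len(units)
    is_treated = np.array([u in set(treated) for u in units])

    alpha = rng.normal(0.0, cfg.unit_sd, size=n_units)
    xi = _xi_path(cfg)
    r = cfg.n_factors
    if r:
        F = np.column_stack([_ar1(rng, n_years, cfg.factor_scale) for _ in range(r)])
        gamma = rng.normal(0.0, cfg.loading_sd, size=(n_units, r))
        gamma[is_treated] += cfg.loading_treated_shift
        factor_term = gamma @ F.T
    else:
        F = np.zeros((n_years, 0))
        gamma = np.zeros((n_units, 0))
        factor_term = np.zeros((n_units, n_years))

    predictors = {
        name: np.vstack([_predictor_series(rng, cfg, name, n_years)
                         for _ in range(n_units)])
        for name in _PREDICTOR_RANGES
    }
    funding = generate_funding(cfg, treated, donors, extras, rng)
    oda_wide = funding.pivot(index="unit_id", columns="year",
                             values="nonusg_oda_pc").loc[units, years].to_numpy()
    predictors["nonusg_oda_pc"] = oda_wide

    pop_total = np.exp(
        rng.uniform(np.log(cfg.pop_range[0]), np.log(cfg.pop_range[1]), size=n_units)
    )
    pop_growth = rng.uniform(0.005, 0.03, size=n_units)
    pop_matrix = pop_total[:, None] * np.exp(
        np.outer(pop_growth, np.arange(n_years))
    )
    wra_frac = rng.uniform(cfg.wra_fraction * 0.9, cfg.wra_fraction * 1.1,
                           size=n_units)
    wra_pop = pop_matrix * wra_frac[:, None]
    predictors["log_pop"] = np.log(pop_matrix)

    beta_term = np.zeros((n_units, n_years))
    for name, coef in cfg.predictor_effects.items():
        beta_term += coef * predictors[name]
    beta_term -= beta_term.mean()

    eps = rng.normal(0.0, cfg.noise_sd, size=(n_units, n_years))
    y0 = cfg.base_rate + alpha[:, None] + xi[None, :] + factor_term + beta_term + eps
    if cfg.misspecify:
        # omitted treated-specific accelerating trend: no observed covariate
        # or common year effect can absorb it, so models fitted without it
        # mispredict treated units increasingly over time
        t_frac = (np.arange(n_years) / max(n_years - 1, 1)) ** 2
        trend_coef = np.where(is_treated, rng.uniform(0.8, 1.6, size=n_units), 0.0)
        y0 = y0 + trend_coef[:, None] * t_frac[None, :]

    delta_path = cfg.resolved_effect_path()
    delta = np.array([delta_path.get(y, 0.0) for y in years])
    y_obs = y0 + np.where(is_treated[:, None], delta[None, :], 0.0)
    n_clipped = int((y_obs < 0).sum())
    y_obs = np.clip(y_obs, 0.0, None)

    wra_deaths = y_obs * wra_pop / 1000.0
    if cfg.round_deaths:
        wra_deaths = np.round(wra_deaths)
    rate = wra_deaths / wra_pop * 1000.0

    # WRA share of total deaths: ascending through the pre-period by default
    share0 = rng.uniform(0.08, 0.12, size=n_units)
    share_slope = rng.uniform(0.002, 0.004, size=n_units)
    share = share0[:, None] + share_slope[:, None] * (
        np.array(years)[None, :] - cfg.start_year
    )
    total_deaths = wra_deaths / share
    if cfg.round_deaths:
        total_deaths = np.maximum(np.round(total_deaths), wra_deaths)

    records = []
    for i, u in enumerate(units):
        for t, y in enumerate(years):
            rec = {
                "unit_id": u, "year": y,
                "wra_deaths": wra_deaths[i, t],
                "wra_pop": wra_pop[i, t],
                "total_deaths": total_deaths[i, t],
                "population_total": pop_matrix[i, t],
                "outcome": rate[i, t],
                "income_class_baseline": "low" if alpha[i] > 0 else "lower-middle",
            }
            for name in PREDICTOR_NAMES:
                rec[name] = predictors[name][i, t]
            records.append(rec)
    df = pd.DataFrame.from_records(records)
    df = df.merge(
        funding[["unit_id", "year", "usg_funding_total", "usg_funding_pc",
                 "funding_breadth"]],
        on=["unit_id", "year"], how="left",
    )
    panel = CountryYearPanel(df)
    design = StudyDesign(
        treatment_year=cfg.treatment_year,
        start_year=cfg.start_year,
        end_year=cfg.end_year,
        treated_units=tuple(treated),
        donor_units=tuple(donors),
    )
    truth = {
        "design": design,
        "treated": treated,
        "donors": donors,
        "extras": extras,
        "delta": {y: delta_path.get(y, 0.0) for y in years},
        "alpha": dict(zip(units, alpha)),
        "xi": dict(zip(years, xi)),
        "gamma": gamma,
        "factors": F,
        "predictor_effects": dict(cfg.predictor_effects),
        "y0": pd.DataFrame(y0, index=units, columns=years),
        "y_obs": pd.DataFrame(y_obs, index=units, columns=years),
        "n_clipped": n_clipped,
        "noise_sd": cfg.noise_sd,
    }
    return panel, truth


def generate_mixture_panel(cfg: DgpConfig, weights=None
                           ) -> tuple[CountryYearPanel, dict, StudyDesign]:
    """Panel whose single treated unit is a known convex mix of donors.

    The treated outcome and predictors are exact weighted combinations of
    realised donor paths (plus the injected effect after the treatment
    year), so the generating donor weights are the ground truth a synthetic
    control should recover.  Death counts are kept unrounded to preserve
    the convex representation exactly.
    """
    base = DgpConfig(**{**cfg.__dict__, "n_treated": 0, "round_deaths": False})
    panel, truth = generate_panel(base)
    rng = np.random.default_rng(cfg.seed + 1)
    donors = truth["donors"]
    J = len(donors)
    if weights is None:
        w = rng.dirichlet(np.full(J, 0.8))
        # concentrate on a few donors, as fitted weights typically are
        w = np.where(w < 0.05, 0.0, w)
        if w.sum() == 0:
            w = np.full(J, 1.0 / J)
        w = w / w.sum()
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    years = cfg.years()
    delta_path = cfg.resolved_effect_path()

    wide_out = panel.wide("outcome").loc[years, donors].to_numpy()
    mix_out = wide_out @ w
    delta = np.array([delta_path.get(y, 0.0) for y in years])
    treated_out = mix_out + delta

    pop_wide = panel.wide("wra_pop").loc[years, donors].to_numpy()
    mix_pop = pop_wide @ w
    rows = []
    for t, y in enumerate(years):
        rec = {
            "unit_id": "TRT", "year": y,
            "wra_pop": mix_pop[t],
            "wra_deaths": treated_out[t] * mix_pop[t] / 1000.0,
            "total_deaths": treated_out[t] * mix_pop[t] / 1000.0 / 0.1,
            "population_total": mix_pop[t] / cfg.wra_fraction,
            "outcome": treated_out[t],
            "income_class_baseline": "low",
            "usg_funding_total": 100.0, "usg_funding_pc": 5.0,
            "funding_breadth": True,
        }
        for name in PREDICTOR_NAMES:
            rec[name] = float(panel.wide(name).loc[y, donors].to_numpy() @ w)
        rows.append(rec)
    df = pd.concat([panel.data, pd.DataFrame(rows)], ignore_index=True)
    mixed_panel = CountryYearPanel(df)
    design = StudyDesign(
        treatment_year=cfg.treatment_year,
        start_year=cfg.start_year, end_year=cfg.end_year,
        treated_units=("TRT",), donor_units=tuple(donors),
    )
    truth = {**truth, "mixture_weights": dict(zip(donors, w)),
             "delta": {y: delta_path.get(y, 0.0) for y in years}}
    return mixed_panel, truth, design


def make_cohort_fixture(seed: int,
                        n_treated: int = 16,
                        n_final_donors: int = 19,
                        n_hiv_missing: int = 3,
                        n_late_established: int = 1,
                        n_non_ascending: int = 36,
                        n_small_pop: int = 18,
                        n_above_both: int = 2,
                        n_high_income: int = 5
                        ) -> tuple[CountryYearPanel, StudyDesign, dict]:
    """Panel engineered so donor-pool filtering reproduces target attrition.

    With the defaults the candidate list thins as 77 (after income and
    funding-exposure screens) -> 59 (population) -> 23 (ascending trend)
    -> 19 (existence and HIV-data screens), the attrition pattern of a
    sixteen-treated / nineteen-donor study cohort.  Raises if the quotas
    are inconsistent.
    """
    n_ascending_pass = n_final_donors + n_hiv_missing + n_late_established
    n_pop_pass = n_ascending_pass + n_non_ascending
    n_funding_pass = n_pop_pass + n_small_pop
    if min(n_final_donors, n_hiv_missing, n_late_established, n_non_ascending,
           n_small_pop, n_above_both, n_high_income) < 0:
        raise ValueError("quotas must be non-negative")

    n_extra = (n_funding_pass - n_final_donors) + n_above_both + n_high_income
    cfg = DgpConfig(
        seed=seed, n_treated=n_treated, n_donor_pool=n_final_donors,
        n_extra_units=n_extra, effect_path={},
    )
    panel, truth = generate_panel(cfg)
    df = panel.data
    extras = truth["extras"]
    rng = np.random.default_rng(seed + 7)

    pos = 0

    def take(n):
        nonlocal pos
        out = extras[pos:pos + n]
        if len(out) < n:
            raise ValueError("quota combination exceeds generated extra units")
        pos += n
        return out

    hiv_missing = take(n_hiv_missing)
    late = take(n_late_established)
    non_ascending = take(n_non_ascending)
    small_pop = take(n_small_pop)
    above_both = take(n_above_both)
    high_income = take(n_high_income)

    df.loc[df["unit_id"].isin(hiv_missing), "hiv_prev"] = np.nan

    for u in late:
        sel = (df["unit_id"] == u) & (df["year"] < 2006)
        df.loc[sel, ["outcome", "wra_deaths", "total_deaths"]] = np.nan

    for u in non_ascending:
        sel = df["unit_id"] == u
        years = df.loc[sel, "year"].to_numpy()
        wra = df.loc[sel, "wra_deaths"].to_numpy()
        share = 0.16 - 0.003 * (years - cfg.start_year)  # descending share
        df.loc[sel, "total_deaths"] = np.maximum(np.round(wra / share), wra)

    for u in small_pop:
        sel = df["unit_id"] == u
        df.loc[sel, "population_total"] = rng.uniform(120_000, 480_000)

    window = cfg.funding_window
    for u in above_both:
        sel = df["unit_id"] == u
        on = sel & df["year"].between(*window)
        df.loc[on, "usg_funding_total"] = rng.uniform(150.0, 250.0)
        df.loc[on, "usg_funding_pc"] = rng.uniform(4.0, 9.0)
        # sporadic outside the window and no breadth: never a treated unit
        df.loc[sel, "funding_breadth"] = False
        df.loc[sel & (df["year"] == window[0]), "usg_funding_total"] = 0.0

    df.loc[df["unit_id"].isin(high_income), "income_class_baseline"] = "high"

    fixture_panel = CountryYearPanel(df)
    design = truth["design"]
    meta = {
        "treated": truth["treated"],
        "intended_donors": truth["donors"],
        "hiv_missing": hiv_missing,
        "late_established": late,
        "non_ascending": non_ascending,
        "small_pop": small_pop,
        "above_both": above_both,
        "high_income": high_income,
        "expected_counts": {
            "funding_exposure": n_funding_pass,
            "population": n_pop_pass,
            "ascending_trend": n_ascending_pass,
            "hiv_data": n_final_donors,
        },
    }
    return fixture_panel, design, meta
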