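"""Bayesian dynamic multilevel latent factor counterfactual model.

The outcome model is

    y_it = mu + beta' x_it + alpha_i + xi_t + gamma_i' f_t + eps_it,
    eps_it ~ Normal(0, sigma^2),

with unit effects alpha_i, year effects xi_t, and r latent factors f_t with
unit-specific loadings gamma_i capturing unobserved common shocks that hit
countries with different intensities.  The model is fitted by a Gibbs
sampler on all donor observations plus the treated units' pre-treatment
observations; treated post-treatment cells are excluded from the likelihood
and imputed from the posterior predictive, giving counterfactual draws of
what mortality would have been without the sustained funding.  Per-year
treatment effects are observed-minus-counterfactual draws aggregated over
treated units with population weights, summarised by posterior means and
equal-tailed credible intervals (90% by default).

Priors are conjugate: Normal(0, 10^2) on the intercept, the (standardised-
scale) regression coefficients and the factor loadings; hierarchical
Normal(0, tau^2) on unit and year effects with InverseGamma(2, 1) priors on
tau^2; InverseGamma(2, 1) on sigma^2.  Latent factors have a Normal(0, 1)
prior per coordinate.  For interpretability every stored draw is put in a
canonical form: factors centred over fitted years (the shift absorbed into
unit effects), orthonormalised columns, sign fixed by the first unit's
loading.  Counterfactual draws are computed before this rotation and are
invariant to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CountryYearPanel, StudyDesign

__all__ = [
    "BmConfig",
    "BmPosterior",
    "AttSummary",
    "fit_bm",
    "att_summary",
    "per_country_effects",
]


@dataclass
class BmConfig:
    n_factors: int = 2
    n_iter: int = 4000
    burn_in: int = 2000
    thin: int = 2
    seed: int = 0
    ci_level: float = 0.90
    predictor_names: list[str] | None = None  # defaults to the design's list
    prior_scale: float = 10.0                 # sd of N(0, scale^2) priors
    ig_shape: float = 2.0
    ig_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class BmPosterior:
    """Stored Gibbs draws and held-out counterfactual predictions."""

    unit_ids: list[str]
    treated_ids: list[str]
    years: list[int]
    post_years: list[int]
    predictor_names: list[str]
    beta: np.ndarray            # (D, k) on the original predictor scale
    mu: np.ndarray              # (D,)
    alpha: np.ndarray           # (D, N)
    xi: np.ndarray              # (D, T)
    gamma: np.ndarray           # (D, N, r)
    factors: np.ndarray         # (D, T, r)
    sigma2: np.ndarray          # (D,)
    counterfactual: np.ndarray  # (D, n_treated, n_post) predictive draws
    observed_treated: np.ndarray  # (n_treated, n_post) observed outcomes
    treated_pop: np.ndarray       # (n_treated, n_post) WRA populations

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]


@dataclass
class AttSummary:
    """Per-year aggregate treatment effects with credible intervals."""

    years: list[int]
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    post_average: float
    post_average_ci: tuple[float, float]
    ci_level: float
    per_unit: pd.DataFrame | None = None  # unit x (year, mean, lower, upper)

    @property
    def significant(self) -> bool:
        lo, hi = self.post_average_ci
        return not (lo <= 0.0 <= hi)

    def significant_years(self) -> list[int]:
        return [
            y for y, lo, hi in zip(self.years, self.lower, self.upper)
            if not (lo <= 0.0 <= hi)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"effect": self.mean, "lower": self.lower, "upper": self.upper},
            index=pd.Index(self.years, name="year"),
        )

    def to_dict(self) -> dict:
        return {
            "per_year": {
                int(y): {"effect": float(m), "lower": float(lo), "upper": float(hi)}
                for y, m, lo, hi in zip(self.years, self.mean, self.lower, self.upper)
            },
            "post_average": {
                "effect": float(self.post_average),
                "lower": float(self.post_average_ci[0]),
                "upper": float(self.post_average_ci[1]),
            },
            "ci_level": self.ci_level,
        }


def _build_arrays(panel: CountryYearPanel, design: StudyDesign,
                  predictor_names: list[str]):
    units = sorted(set(design.treated_units) | set(design.donor_units))
    years = design.all_years
    Y = panel.wide("outcome").reindex(index=years, columns=units).to_numpy(float).T
    pop = panel.wide("wra_pop").reindex(index=years, columns=units).to_numpy(float).T
    X = np.stack(
        [
            panel.wide(p).reindex(index=years, columns=units).to_numpy(float).T
            for p in predictor_names
        ],
        axis=-1,
    ) if predictor_names else np.zeros((len(units), len(years), 0))
    return units, years, Y, pop, X


def fit_bm(panel: CountryYearPanel, design: StudyDesign,
           config: BmConfig | None = None) -> BmPosterior:
    """Gibbs sampler for the latent-factor counterfactual model.

    Treated units' post-treatment observations never enter the likelihood;
    the returned posterior contains predictive draws of those cells.
    Deterministic for a fixed (data, config, seed) triple.
    """
    config = config or BmConfig()
    predictor_names = (
        config.predictor_names
        if config.predictor_names is not None
        else [p for p in design.predictor_names if p in panel.data.columns]
    )
    units, years, Y, pop, X = _build_arrays(panel, design, predictor_names)
    N, T = Y.shape
    k = X.shape[-1]
    r = config.n_factors
    treated_idx = np.array([units.index(u) for u in sorted(design.treated_units)])
    post_idx = np.array([years.index(y) for y in design.post_years])
    pre_len = len(design.pre_years)

    if pre_len < 10:
        warnings.warn(
            f"only {pre_len} pre-treatment years; the latent-factor model "
            "prefers a long pre-period"
        )
    if len(design.donor_units) <= len(design.treated_units):
        warnings.warn("donor pool not larger than the treated set")
    if pre_len < 2:
        raise ValueError("need at least 2 pre-treatment years")

    # observation mask: everything observed except treated x post cells
    M = np.isfinite(Y)
    for i in treated_idx:
        M[i, post_idx] = False
    if not np.isfinite(Y[M]).all():
        raise ValueError("panel has missing outcomes outside treated post cells")
    if k and not np.isfinite(X).all():
        raise ValueError("panel has missing predictor values")

    # standardise predictors for sampling; coefficients mapped back on storage
    if k:
        x_mean = X.reshape(-1, k).mean(axis=0)
        x_sd = X.reshape(-1, k).std(axis=0)
        x_sd[x_sd == 0] = 1.0
        Xs = (X - x_mean) / x_sd
    else:
        x_mean = x_sd = np.zeros(0)
        Xs = X

    rng = np.random.default_rng(config.seed)
    iu, it = np.nonzero(M)
    n_obs = iu.size
    Xo = Xs[iu, it]                       # (n_obs, k)
    XtX = Xo.T @ Xo if k else np.zeros((0, 0))
    prior_prec = 1.0 / config.prior_scale ** 2

    # state
    beta = np.zeros(k)
    mu = float(np.nanmean(Y[M]))
    alpha = np.zeros(N)
    xi = np.zeros(T)
    gamma = np.zeros((N, r))
    F = rng.standard_normal((T, r)) * 0.1 if r else np.zeros((T, 0))
    sigma2 = float(np.nanvar(Y[M])) or 1.0
    tau_a2 = 1.0
    tau_x2 = 1.0

    Mf = M.astype(float)
    Yz = np.where(M, Y, 0.0)

    def xb():
        return Xs @ beta if k else np.zeros((N, T))

    n_treated, n_post = treated_idx.size, post_idx.size
    cf_draws, beta_draws, mu_draws = [], [], []
    alpha_draws, xi_draws, gamma_draws, f_draws, sig_draws = [], [], [], [], []

    XB = xb()
    for it_no in range(config.n_iter):
        FG = gamma @ F.T if r else 0.0   # (N, T)

        # beta | rest
        if k:
            R = Yz - (mu + alpha[:, None] + xi[None, :] + FG) * Mf
            resid = R[iu, it]
            prec = XtX / sigma2 + prior_prec * np.eye(k)
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, Xo.T @ resid / sigma2)
            beta = mean + np.linalg.solve(chol.T, rng.standard_normal(k))
            XB = Xs @ beta

        # mu | rest
        R = Y - XB - alpha[:, None] - xi[None, :] - FG
        s = R[M].sum()
        prec_mu = n_obs / sigma2 + prior_prec
        mu = s / sigma2 / prec_mu + rng.standard_normal() / np.sqrt(prec_mu)

        # alpha_i | rest
        R = Y - XB - mu - xi[None, :] - FG
        n_i = Mf.sum(axis=1)
        prec_a = n_i / sigma2 + 1.0 / tau_a2
        mean_a = np.where(M, R, 0.0).sum(axis=1) / sigma2 / prec_a
        alpha = mean_a + rng.standard_normal(N) / np.sqrt(prec_a)

        # xi_t | rest
        R = Y - XB - mu - alpha[:, None] - FG
        n_t = Mf.sum(axis=0)
        prec_x = n_t / sigma2 + 1.0 / tau_x2
        mean_x = np.where(M, R, 0.0).sum(axis=0) / sigma2 / prec_x
        xi = mean_x + rng.standard_normal(T) / np.sqrt(prec_x)

        if r:
            # gamma_i | rest
            R = np.where(M, Y - XB - mu - alpha[:, None] - xi[None, :], 0.0)
            A = np.einsum("tr,ts,it->irs", F, F, Mf)        # (N, r, r)
            b = np.einsum("it,tr->ir", R, F)
            eye_r = np.eye(r)
            for i in range(N):
                prec_g = A[i] / sigma2 + prior_prec * eye_r
                cg = np.linalg.cholesky(prec_g)
                mg = np.linalg.solve(prec_g, b[i] / sigma2)
                gamma[i] = mg + np.linalg.solve(cg.T, rng.standard_normal(r))

            # f_t | rest
            A = np.einsum("ir,is,it->trs", gamma, gamma, Mf)  # (T, r, r)
            b = np.einsum("it,ir->tr", R, gamma)
            for t in range(T):
                prec_f = A[t] / sigma2 + eye_r
                cf_ = np.linalg.cholesky(prec_f)
                mf = np.linalg.solve(prec_f, b[t] / sigma2)
                F[t] = mf + np.linalg.solve(cf_.T, rng.standard_normal(r))
            FG = gamma @ F.T

        # variances
        E = Y - XB - mu - alpha[:, None] - xi[None, :] - (FG if r else 0.0)
        ssr = float((E[M] ** 2).sum())
        if not np.isfinite(ssr):
            raise FloatingPointError(f"non-finite likelihood at iteration {it_no}")
        sigma2 = 1.0 / rng.gamma(config.ig_shape + n_obs / 2.0,
                                 1.0 / (config.ig_rate + ssr / 2.0))
        tau_a2 = 1.0 / rng.gamma(config.ig_shape + N / 2.0,
                                 1.0 / (config.ig_rate + (alpha ** 2).sum() / 2.0))
        tau_x2 = 1.0 / rng.gamma(config.ig_shape + T / 2.0,
                                 1.0 / (config.ig_rate + (xi ** 2).sum() / 2.0))

        if it_no >= config.burn_in and (it_no - config.burn_in) % config.thin == 0:
            # counterfactual predictive draws for treated x post cells
            pred = (
                mu
                + (XB if k else 0.0)
                + alpha[:, None]
                + xi[None, :]
                + (gamma @ F.T if r else 0.0)
            )
            cf = (
                pred[np.ix_(treated_idx, post_idx)]
                + rng.standard_normal((n_treated, n_post)) * np.sqrt(sigma2)
            )
            cf_draws.append(cf)

            # canonical form for stored structural draws
            a_st, xi_st = alpha.copy(), xi.copy()
            g_st, f_st = gamma.copy(), F.copy()
            if r:
                shift = f_st.mean(axis=0)
                f_st = f_st - shift
                a_st = a_st + g_st @ shift
                Q, Rm = np.linalg.qr(f_st)
                f_st, g_st = Q, g_st @ Rm.T
                for j in range(r):
                    if g_st[0, j] < 0:
                        g_st[:, j] *= -1.0
                        f_st[:, j] *= -1.0
            if k:
                beta_orig = beta / x_sd
                mu_orig = mu - float((beta / x_sd) @ x_mean)
            else:
                beta_orig, mu_orig = beta.copy(), mu
            beta_draws.append(beta_orig)
            mu_draws.append(mu_orig)
            alpha_draws.append(a_st)
            xi_draws.append(xi_st)
            gamma_draws.append(g_st)
            f_draws.append(f_st)
            sig_draws.append(sigma2)

    return BmPosterior(
        unit_ids=list(units),
        treated_ids=sorted(design.treated_units),
        years=list(years),
        post_years=list(design.post_years),
        predictor_names=list(predictor_names),
        beta=np.array(beta_draws),
        mu=np.array(mu_draws),
        alpha=np.array(alpha_draws),
        xi=np.array(xi_draws),
        gamma=np.array(gamma_draws),
        factors=np.array(f_draws),
        sigma2=np.array(sig_draws),
        counterfactual=np.array(cf_draws),
        observed_treated=Y[np.ix_(treated_idx, post_idx)],
        treated_pop=pop[np.ix_(treated_idx, post_idx)],
    )


def _ci(draws: np.ndarray, level: float, axis=0):
    lo = (1.0 - level) / 2.0
    return (
        np.quantile(draws, lo, axis=axis),
        np.quantile(draws, 1.0 - lo, axis=axis),
    )


def att_summary(posterior: BmPosterior, ci_level: float = 0.90) -> AttSummary:
    """Aggregate per-year treatment effects across treated units.

    Effect draws are observed minus counterfactual, combined across treated
    units with per-year WRA-population weights (matching the construction
    of the aggregated treated unit).  The post-period average is a posterior
    functional: the post-year mean is taken within each draw, then
    summarised across draws.
    """
    w = posterior.treated_pop / posterior.treated_pop.sum(axis=0, keepdims=True)
    eff = posterior.observed_treated[None] - posterior.counterfactual  # (D, m, P)
    agg = np.einsum("dmp,mp->dp", eff, w)                              # (D, P)
    mean = agg.mean(axis=0)
    lower, upper = _ci(agg, ci_level)
    post_draws = agg.mean(axis=1)
    pa_lo, pa_hi = _ci(post_draws, ci_level)
    return AttSummary(
        years=list(posterior.post_years),
        mean=mean, lower=lower, upper=upper,
        post_average=float(post_draws.mean()),
        post_average_ci=(float(pa_lo), float(pa_hi)),
        ci_level=ci_level,
    )


def per_country_effects(posterior: BmPosterior, ci_level: float = 0.90) -> AttSummary:
    """Per-treated-unit effect summaries (no cross-unit averaging).

    Units whose post-average credible interval overlaps zero are flagged as
    indistinguishable from their counterfactual.
    """
    eff = posterior.observed_treated[None] - posterior.counterfactual  # (D, m, P)
    rows = []
    for j, unit in enumerate(posterior.treated_ids):
        unit_draws = eff[:, j, :]
        lo, hi = _ci(unit_draws, ci_level)
        pa_draws = unit_draws.mean(axis=1)
        pa_lo, pa_hi = _ci(pa_draws, ci_level)
        for p, y in enumerate(posterior.post_years):
            rows.append({
                "unit_id": unit, "year": y,
                "effect": float(unit_draws[:, p].mean()),
                "lower": float(lo[p]), "upper": float(hi[p]),
            })
        rows.append({
            "unit_id": unit, "year": "post_average",
            "effect": float(pa_draws.mean()),
            "lower": float(pa_lo), "upper": float(pa_hi),
        })
    per_unit = pd.DataFrame(rows)
    per_unit["overlaps_zero"] = (per_unit["lower"] <= 0) & (per_unit["upper"] >= 0)
    agg = att_summary(posterior, ci_level)
    agg.per_unit = per_unit
    return agg
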