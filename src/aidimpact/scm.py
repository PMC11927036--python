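"""Synthetic control estimation.

The synthetic control for an aggregated treated unit is a convex combination
of donor countries.  Donor weights W live on the probability simplex and are
chosen, for a given diagonal predictor-importance matrix diag(V), to minimise
the weighted predictor discrepancy

    (X1 - X0 W)' diag(V) (X1 - X0 W),

the classic inner problem of the nested synthetic-control program.  The
predictor weights V (non-negative, summing to one) are chosen in an outer
loop to minimise the pre-treatment root mean squared prediction error
(RMSPE) of the resulting outcome path, so that the data decide which
predictors matter for reproducing the treated unit's pre-period mortality
trajectory.  Post-treatment gaps (treated minus synthetic) are the per-year
effect estimates; their unweighted mean over the post-period is the average
treatment effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize as sopt

from .panel import (
    CountryYearPanel,
    StudyDesign,
    aggregate_predictor,
    aggregate_treated,
)

__all__ = [
    "ScmDesignMatrices",
    "ScmSolution",
    "ScmOptions",
    "OptimizationError",
    "prepare_design",
    "solve_w",
    "optimize_v",
    "rmspe",
    "effect_series",
    "fit_scm",
]


class OptimizationError(RuntimeError):
    pass


@dataclass
class ScmOptions:
    """Tuning knobs for the nested optimisation.

    ``n_random_starts`` extra Dirichlet-drawn V starts are added to the two
    deterministic ones (uniform V and the regression-based V of the
    synthetic-control literature); the start list is fixed by ``seed`` so a
    fit is reproducible.  ``zero_tol`` is the reporting threshold below
    which donor weights are truncated to zero and renormalised.
    """

    n_random_starts: int = 4
    seed: int = 20_050_101
    maxiter: int | None = None
    zero_tol: float = 1e-4
    polish: bool = True        # SLSQP polish of the final inner QP solution
    vertex_starts: bool = True  # add one start per single-predictor vertex


@dataclass
class ScmDesignMatrices:
    """Aligned treated/donor predictor and outcome arrays.

    Predictor rows are scaled to unit standard deviation across units so V
    weights are comparable across differently-scaled covariates; the scale
    factors are retained.
    """

    X1: np.ndarray          # (k,)   treated predictor means, scaled
    X0: np.ndarray          # (k, J) donor predictor means, scaled
    Z1: np.ndarray          # (T0,)  treated pre-period outcome path
    Z0: np.ndarray          # (T0, J)
    donor_ids: list[str]
    predictor_names: list[str]
    pre_years: list[int]
    scale: np.ndarray       # (k,) per-predictor std used for scaling
    Y1_all: np.ndarray = field(default=None)   # treated outcome, all years
    Y0_all: np.ndarray = field(default=None)   # (T, J) donor outcomes, all years
    all_years: list[int] = field(default_factory=list)


def rmspe(actual, synthetic, years=None, all_years=None) -> float:
    """Root mean squared prediction error over a year subset.

    If ``years``/``all_years`` are given, both series are first restricted
    to the named years; otherwise they are compared elementwise.
    """
    a = np.asarray(actual, dtype=float)
    s = np.asarray(synthetic, dtype=float)
    if years is not None:
        idx = [all_years.index(y) for y in years]
        a, s = a[idx], s[idx]
    if a.size == 0:
        raise ValueError("empty year set for RMSPE")
    if a.shape != s.shape:
        raise ValueError("series length mismatch")
    return float(np.sqrt(np.mean((a - s) ** 2)))


def prepare_design(panel: CountryYearPanel, design: StudyDesign) -> ScmDesignMatrices:
    """Build the treated/donor matching matrices.

    Predictor entries are per-unit means over the pre-period (population-
    weighted aggregates for the treated unit); outcome paths are the raw
    yearly mortality rates.
    """
    donors = sorted(design.donor_units)
    if not donors:
        raise ValueError("design has no donor units")
    pre = design.pre_years
    all_years = design.all_years
    k_names = [p for p in design.predictor_names if p in panel.data.columns]

    wide = panel.wide("outcome")
    for u in donors:
        missing = [y for y in all_years if y not in wide.index or pd.isna(wide.loc[y, u])]
        if missing:
            raise ValueError(f"donor {u} missing outcome for years {missing[:5]}")
    Z0 = wide.loc[pre, donors].to_numpy(dtype=float)
    Y0_all = wide.loc[all_years, donors].to_numpy(dtype=float)

    treated = sorted(design.treated_units)
    agg = aggregate_treated(panel, treated, years=all_years)
    Y1_all = agg.values
    Z1 = Y1_all[: len(pre)]

    X1 = np.empty(len(k_names))
    X0 = np.empty((len(k_names), len(donors)))
    pred_wide = {p: panel.wide(p) for p in k_names}
    for i, p in enumerate(k_names):
        X1[i] = aggregate_predictor(panel, treated, p, pre).mean()
        X0[i] = pred_wide[p].loc[pre, donors].mean(axis=0).to_numpy(dtype=float)
    if not (np.isfinite(X0).all() and np.isfinite(X1).all()):
        bad = [k_names[i] for i in range(len(k_names)) if not np.isfinite(X0[i]).all()]
        raise ValueError(f"missing predictor values for donors in: {bad}")

    # scale each predictor row by its std across treated + donors
    stacked = np.column_stack([X1, X0])
    scale = stacked.std(axis=1, ddof=0)
    scale[scale == 0] = 1.0
    return ScmDesignMatrices(
        X1=X1 / scale, X0=X0 / scale[:, None], Z1=Z1, Z0=Z0,
        donor_ids=donors, predictor_names=k_names, pre_years=list(pre),
        scale=scale, Y1_all=Y1_all, Y0_all=Y0_all, all_years=list(all_years),
    )


def solve_w(X0: np.ndarray, X1: np.ndarray, V: np.ndarray,
            polish: bool = False) -> tuple[np.ndarray, float]:
    """Inner QP: simplex-constrained weighted least squares for donor weights.

    Solved as a penalised non-negative least-squares problem (the adding-up
    constraint enters as a heavily weighted extra row, a standard exact-in-
    the-limit reformulation), with an optional SLSQP polish for the final
    reported solution.  Returns (W, objective value).
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    k, J = X0.shape
    sv = np.sqrt(V)
    A = sv[:, None] * X0
    b = sv * X1
    scale = max(1.0, float(np.abs(A).max()), float(np.abs(b).max()))
    lam = 1e5 * scale
    # tiny ridge keeps the solution unique (and continuous in V) when the
    # weighted predictor system is rank-deficient, e.g. at vertex V
    ridge = 1e-4 * scale
    A_aug = np.vstack([A, lam * np.ones((1, J)), ridge * np.eye(J)])
    b_aug = np.concatenate([b, [lam], np.zeros(J)])
    W, _ = sopt.nnls(A_aug, b_aug)
    total = W.sum()
    if total <= 0:
        W = np.full(J, 1.0 / J)
    else:
        W = W / total

    def objective(w):
        r = X1 - X0 @ w
        return float(r @ (V * r))

    def objective_reg(w):
        return objective(w) + ridge ** 2 * float(w @ w)

    if polish and J >= 2:
        res = sopt.minimize(
            objective_reg, W, method="SLSQP",
            bounds=[(0.0, 1.0)] * J,
            constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
            options={"ftol": 1e-14, "maxiter": 300},
        )
        if res.success and objective_reg(res.x) < objective_reg(W):
            W = np.clip(res.x, 0.0, None)
            W = W / W.sum()
    return W, objective(W)


def _regression_v(m: ScmDesignMatrices) -> np.ndarray:
    """Regression-based predictor importances: each predictor's share of the
    squared coefficients from regressing pre-period outcomes on predictors
    across all units (treated + donors)."""
    X = np.column_stack([m.X1, m.X0]).T           # (J+1, k)
    Z = np.column_stack([m.Z1[:, None], m.Z0]).T  # (J+1, T0)
    Xc = np.column_stack([np.ones(X.shape[0]), X])
    beta, *_ = np.linalg.lstsq(Xc, Z, rcond=None)
    imp = np.sum(beta[1:] ** 2, axis=1)
    if imp.sum() <= 0:
        return np.full(X.shape[1], 1.0 / X.shape[1])
    return imp / imp.sum()


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def optimize_v(matrices: ScmDesignMatrices,
               options: ScmOptions | None = None) -> "ScmSolution":
    """Outer loop: pick predictor weights V minimising pre-period RMSPE.

    V is parameterised through a softmax so the search is unconstrained;
    Nelder-Mead runs from a fixed multi-start list (uniform V, the
    regression-based V, and seeded Dirichlet draws).  The best start wins;
    ties go to the earlier start, making the fit deterministic.
    """
    options = options or ScmOptions()
    m = matrices
    k, J = m.X0.shape
    if J < 2 or len(m.pre_years) < 2:
        raise ValueError("need at least 2 donors and 2 pre-period years")

    def outer_loss(z):
        V = _softmax(z)
        W, _ = solve_w(m.X0, m.X1, V)
        return rmspe(m.Z1, m.Z0 @ W)

    starts = [np.zeros(k)]
    v_reg = _regression_v(m)
    starts.append(np.log(v_reg + 1e-8))
    if options.vertex_starts:
        for j in range(k):
            v = np.full(k, 1e-6)
            v[j] = 1.0
            starts.append(np.log(v))
    rng = np.random.default_rng(options.seed)
    for _ in range(options.n_random_starts):
        starts.append(np.log(rng.dirichlet(np.ones(k)) + 1e-8))

    best_z, best_loss = None, np.inf
    maxiter = options.maxiter or 200 * k
    for z0 in starts:
        res = sopt.minimize(outer_loss, z0, method="Nelder-Mead",
                            options={"maxiter": maxiter, "xatol": 1e-6,
                                     "fatol": 1e-10})
        if res.fun < best_loss - 1e-15:
            best_loss, best_z = res.fun, res.x
    if best_z is None:
        raise OptimizationError("all outer starts failed")
    # one restart from the incumbent to escape a stalled simplex
    res = sopt.minimize(outer_loss, best_z, method="Nelder-Mead",
                        options={"maxiter": maxiter, "xatol": 1e-8,
                                 "fatol": 1e-12})
    if res.fun < best_loss - 1e-15:
        best_loss, best_z = res.fun, res.x

    V = _softmax(best_z)
    W, _ = solve_w(m.X0, m.X1, V, polish=options.polish)
    # truncate negligible weights for reporting, then renormalise
    W = np.where(W < options.zero_tol, 0.0, W)
    W = W / W.sum()
    return _build_solution(m, W, V)


def _build_solution(m: ScmDesignMatrices, W: np.ndarray, V: np.ndarray) -> "ScmSolution":
    synthetic = m.Y0_all @ W
    gaps = m.Y1_all - synthetic
    pre_n = len(m.pre_years)
    pre_rmspe = rmspe(m.Y1_all[:pre_n], synthetic[:pre_n])
    post_gaps = gaps[pre_n:]
    return ScmSolution(
        W=W, V=V, donor_ids=list(m.donor_ids),
        predictor_names=list(m.predictor_names),
        years=list(m.all_years), pre_years=list(m.pre_years),
        treated_path=m.Y1_all, synthetic_path=synthetic, gaps=gaps,
        rmspe_pre=pre_rmspe,
        ate_post=float(post_gaps.mean()) if post_gaps.size else np.nan,
    )


@dataclass
class ScmSolution:
    """Fitted synthetic control: weights, paths, fit, and effect series."""

    W: np.ndarray
    V: np.ndarray
    donor_ids: list[str]
    predictor_names: list[str]
    years: list[int]
    pre_years: list[int]
    treated_path: np.ndarray
    synthetic_path: np.ndarray
    gaps: np.ndarray
    rmspe_pre: float
    ate_post: float

    @property
    def post_years(self) -> list[int]:
        return self.years[len(self.pre_years):]

    def gap_series(self) -> pd.Series:
        return pd.Series(self.gaps, index=self.years, name="gap")

    def weights_table(self) -> pd.Series:
        return pd.Series(self.W, index=self.donor_ids, name="weight")

    def to_dict(self) -> dict:
        return {
            "weights": {u: float(w) for u, w in zip(self.donor_ids, self.W)},
            "predictor_weights": {
                p: float(v) for p, v in zip(self.predictor_names, self.V)
            },
            "rmspe_pre": float(self.rmspe_pre),
            "gaps": {int(y): float(g) for y, g in zip(self.years, self.gaps)},
            "synthetic_path": {
                int(y): float(s) for y, s in zip(self.years, self.synthetic_path)
            },
            "ate_post": float(self.ate_post),
        }


def effect_series(solution: ScmSolution, post_years=None,
                  significant_years=None) -> tuple[pd.Series, float, float | None]:
    """Per-year gaps with post-period effect summaries.

    Returns (gap series over all years, post-period average effect, and --
    when ``significant_years`` is supplied -- the average over that subset,
    e.g. the years where placebo inference flags significance).
    """
    gaps = solution.gap_series()
    if post_years is None:
        post_years = solution.post_years
    ate_post = float(gaps.loc[list(post_years)].mean())
    ate_sig = None
    if significant_years is not None:
        ate_sig = float(gaps.loc[list(significant_years)].mean())
    return gaps, ate_post, ate_sig


def fit_scm(panel: CountryYearPanel, design: StudyDesign,
            options: ScmOptions | None = None) -> ScmSolution:
    """Convenience wrapper: build design matrices, then run the nested fit."""
    return optimize_v(prepare_design(panel, design), options)
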