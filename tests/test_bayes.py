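import numpy as np
import pandas as pd
import pytest

from aidimpact import BmConfig, att_summary, fit_bm, per_country_effects
from aidimpact.simulate import generate_panel

from conftest import small_config

BM_FAST = dict(n_factors=1, n_iter=1500, burn_in=750, thin=2)
PREDS = ["hiv_prev", "tfr"]


@pytest.fixture(scope="module")
def fitted():
    cfg = small_config(55, n_treated=4, n_donor_pool=10, n_factors=1, noise_sd=0.2)
    panel, truth = generate_panel(cfg)
    design = truth["design"].replace(predictor_names=PREDS)
    post = fit_bm(panel, design,
                  BmConfig(seed=9, predictor_names=PREDS, **BM_FAST))
    return panel, truth, design, post


class TestFitBm:
    def test_parameter_recovery_single_replicate(self, fitted):
        _, truth, _, post = fitted
        true_beta = np.array([truth["predictor_effects"]["hiv_prev"],
                              truth["predictor_effects"]["tfr"]])
        mean, sd = post.beta.mean(axis=0), post.beta.std(axis=0)
        assert np.all(np.abs(mean - true_beta) <= 3 * sd)
        assert abs(post.sigma2.mean() - truth["noise_sd"] ** 2) < 0.05

    def test_att_tracks_injected_effect(self, fitted):
        _, truth, design, post = fitted
        s = att_summary(post)
        delta = np.array([truth["delta"][y] for y in design.post_years])
        half_width = (s.upper - s.lower) / 2
        assert np.all(np.abs(s.mean - delta) <= np.maximum(half_width, 0.3))

    def test_draws_reproducible_for_fixed_seed(self, fitted):
        panel, _, design, post = fitted
        again = fit_bm(panel, design,
                       BmConfig(seed=9, predictor_names=PREDS, **BM_FAST))
        np.testing.assert_array_equal(post.beta, again.beta)
        np.testing.assert_array_equal(post.counterfactual, again.counterfactual)

    def test_different_seeds_agree_within_monte_carlo_error(self, fitted):
        panel, _, design, post = fitted
        other = fit_bm(panel, design,
                       BmConfig(seed=10, predictor_names=PREDS, **BM_FAST))
        a, b = att_summary(post), att_summary(other)
        draws_a = np.einsum(
            "dmp,mp->dp",
            post.observed_treated[None] - post.counterfactual,
            post.treated_pop / post.treated_pop.sum(axis=0, keepdims=True),
        ).mean(axis=1)
        mcse = draws_a.std() / np.sqrt(max(_ess_guess(draws_a), 4))
        assert abs(a.post_average - b.post_average) <= 6 * mcse + 0.05

    def test_burn_in_must_be_smaller_than_iterations(self):
        with pytest.raises(ValueError):
            BmConfig(n_iter=100, burn_in=100)

    def test_loadings_sign_convention_in_every_draw(self, fitted):
        _, _, _, post = fitted
        assert np.all(post.gamma[:, 0, :] >= 0)

    def test_factor_columns_orthonormal_in_every_stored_draw(self, fitted):
        _, _, _, post = fitted
        for d in range(0, post.n_draws, 100):
            F = post.factors[d]
            np.testing.assert_allclose(F.T @ F, np.eye(F.shape[1]), atol=1e-8)


def _ess_guess(x):
    """Crude effective sample size from lag-1 autocorrelation."""
    x = x - x.mean()
    if x.std() == 0:
        return len(x)
    rho = np.corrcoef(x[:-1], x[1:])[0, 1]
    rho = min(max(rho, 0.0), 0.99)
    return len(x) * (1 - rho) / (1 + rho)


class TestNoiselessLimits:
    def _noiseless_panel(self):
        cfg = small_config(66, n_treated=2, n_donor_pool=8, n_factors=0,
                           noise_sd=0.0, predictor_effects={},
                           round_deaths=False)
        return generate_panel(cfg)

    def test_counterfactual_matches_additive_truth(self):
        # zero noise, no factors, no covariates: y = mu + alpha_i + xi_t and
        # the posterior predictive mean must sit on the truth up to the
        # residual posterior spread implied by the proper variance prior
        panel, truth = self._noiseless_panel()
        design = truth["design"].replace(predictor_names=[])
        post = fit_bm(panel, design,
                      BmConfig(n_factors=0, n_iter=1500, burn_in=750, thin=2,
                               seed=3, predictor_names=[]))
        cf_mean = post.counterfactual.mean(axis=0)
        y0 = truth["y0"].loc[post.treated_ids, post.post_years].to_numpy()
        assert np.abs(cf_mean - y0).max() < 0.05
        assert post.sigma2.mean() < 0.02

    def test_matches_two_way_least_squares_in_noiseless_limit(self):
        panel, truth = self._noiseless_panel()
        design = truth["design"].replace(predictor_names=[])
        post = fit_bm(panel, design,
                      BmConfig(n_factors=0, n_iter=1500, burn_in=750, thin=2,
                               seed=4, predictor_names=[]))
        # closed-form oracle: two-way fixed-effects least squares on the
        # observed cells, predicted onto the held-out treated cells
        df = panel.data
        obs = df[~(df["unit_id"].isin(design.treated_units)
                   & (df["year"] >= design.treatment_year))]
        X = pd.get_dummies(obs[["unit_id"]], drop_first=False).astype(float)
        Xy = pd.get_dummies(obs["year"].astype(str), drop_first=True).astype(float)
        A = np.column_stack([X.to_numpy(), Xy.to_numpy()])
        coef, *_ = np.linalg.lstsq(A, obs["outcome"].to_numpy(), rcond=None)
        units_cols = list(X.columns)
        year_cols = list(Xy.columns)
        for j, unit in enumerate(post.treated_ids):
            for p, year in enumerate(post.post_years):
                pred = coef[units_cols.index(f"unit_id_{unit}")]
                pred += coef[len(units_cols) + year_cols.index(str(year))]
                assert post.counterfactual[:, j, p].mean() == pytest.approx(
                    pred, abs=0.05
                )


class TestAttSummaries:
    def test_zero_effect_draws_give_degenerate_summary(self, fitted):
        _, _, _, post = fitted
        clone = _clone_with_counterfactual(post, np.broadcast_to(
            post.observed_treated, post.counterfactual.shape
        ).copy())
        s = att_summary(clone)
        np.testing.assert_allclose(s.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(s.lower, 0.0, atol=1e-12)
        np.testing.assert_allclose(s.upper, 0.0, atol=1e-12)

    def test_interval_endpoints_are_draw_quantiles(self, fitted):
        _, _, _, post = fitted
        s = att_summary(post, ci_level=0.90)
        w = post.treated_pop / post.treated_pop.sum(axis=0, keepdims=True)
        agg = np.einsum("dmp,mp->dp",
                        post.observed_treated[None] - post.counterfactual, w)
        np.testing.assert_allclose(s.lower, np.quantile(agg, 0.05, axis=0))
        np.testing.assert_allclose(s.upper, np.quantile(agg, 0.95, axis=0))
        assert np.all(s.lower <= s.mean) and np.all(s.mean <= s.upper)

    def test_single_treated_per_country_equals_aggregate(self):
        cfg = small_config(71, n_treated=1, n_donor_pool=8, n_factors=1)
        panel, truth = generate_panel(cfg)
        design = truth["design"].replace(predictor_names=PREDS)
        post = fit_bm(panel, design,
                      BmConfig(seed=5, predictor_names=PREDS, **BM_FAST))
        agg = att_summary(post)
        per = per_country_effects(post)
        unit_rows = per.per_unit[per.per_unit["year"] != "post_average"]
        np.testing.assert_allclose(unit_rows["effect"].to_numpy(), agg.mean,
                                   atol=1e-10)

    def test_post_disaster_shock_yields_harmful_effect(self):
        # one treated unit suffers a persistent post-period level increase
        cfg = small_config(72, n_treated=3, n_donor_pool=9, n_factors=1,
                           effect_path={})
        panel, truth = generate_panel(cfg)
        design = truth["design"].replace(predictor_names=PREDS)
        df = panel.data.copy()
        shocked = truth["treated"][0]
        sel = (df["unit_id"] == shocked) & (df["year"] >= design.treatment_year)
        df.loc[sel, "outcome"] += 2.0
        from aidimpact import CountryYearPanel
        post = fit_bm(CountryYearPanel(df), design,
                      BmConfig(seed=6, predictor_names=PREDS, **BM_FAST))
        per = per_country_effects(post).per_unit
        row = per[(per["unit_id"] == shocked) & (per["year"] == "post_average")]
        assert row["effect"].iloc[0] > 1.0


def _clone_with_counterfactual(post, cf):
    import copy
    clone = copy.copy(post)
    clone.counterfactual = cf
    return clone
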