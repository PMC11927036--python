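import itertools

import numpy as np
import pytest

from aidimpact import fit_scm, optimize_v, prepare_design, rmspe, solve_w
from aidimpact.reference import (
    SCM_EFFECT_ESTIMATES,
    SCM_POST_AVERAGE,
    SCM_SIGNIFICANT_AVERAGE,
    SIGNIFICANT_YEARS,
)
from aidimpact.scm import ScmOptions, _build_solution, effect_series
from aidimpact.simulate import generate_mixture_panel, generate_panel

from conftest import FAST_SCM, SMALL_PREDICTORS, small_config


def simplex_grid(J, step=0.01):
    """All weight vectors on the simplex with coordinates k*step."""
    n = round(1 / step)
    for cuts in itertools.combinations(range(n + J - 1), J - 1):
        prev, w = -1, []
        for c in cuts:
            w.append(c - prev - 1)
            prev = c
        w.append(n + J - 2 - prev)
        yield np.array(w) / n


class TestRmspe:
    def test_identical_series_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert rmspe(a, a) == 0.0

    def test_constant_gap_closed_form(self):
        a = np.array([5.0, 6.0, 7.0])
        assert rmspe(a, a - 0.3) == pytest.approx(0.3)

    def test_random_pair_matches_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert rmspe(a, b) == pytest.approx(np.sqrt(np.mean((a - b) ** 2)))

    def test_empty_year_set_rejected(self):
        with pytest.raises(ValueError):
            rmspe([], [])


class TestSolveW:
    def test_exact_donor_match_is_vertex(self):
        rng = np.random.default_rng(2)
        X0 = rng.normal(size=(3, 4))
        X1 = X0[:, 2].copy()
        W, obj = solve_w(X0, X1, np.ones(3) / 3)
        expected = np.zeros(4)
        expected[2] = 1.0
        np.testing.assert_allclose(W, expected, atol=1e-6)
        assert obj < 1e-10

    def test_midpoint_splits_evenly(self):
        X0 = np.array([[0.0, 2.0], [1.0, 3.0], [5.0, 1.0]])
        X1 = X0.mean(axis=1)
        W, obj = solve_w(X0, X1, np.ones(3) / 3)
        np.testing.assert_allclose(W, [0.5, 0.5], atol=1e-6)
        assert obj < 1e-10

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            X0 = rng.normal(size=(3, 3))
            X1 = rng.normal(size=3)
            V = rng.dirichlet(np.ones(3))
            W, obj = solve_w(X0, X1, V, polish=True)
            grid_obj = min(
                float((X1 - X0 @ w) @ (V * (X1 - X0 @ w)))
                for w in simplex_grid(3, 0.01)
            )
            assert obj <= grid_obj + 1e-4

    def test_never_worse_than_best_vertex(self):
        rng = np.random.default_rng(4)
        X0 = rng.normal(size=(4, 6))
        X1 = rng.normal(size=4)
        V = rng.dirichlet(np.ones(4))
        _, obj = solve_w(X0, X1, V)
        vertex_objs = [
            float((X1 - X0[:, j]) @ (V * (X1 - X0[:, j])))
            for j in range(6)
        ]
        assert obj <= min(vertex_objs) + 1e-9

    def test_common_predictor_scaling_leaves_w_unchanged(self):
        rng = np.random.default_rng(5)
        X0 = rng.normal(size=(3, 5))
        X1 = rng.normal(size=3)
        V = rng.dirichlet(np.ones(3))
        W1, _ = solve_w(X0, X1, V)
        W2, _ = solve_w(7.3 * X0, 7.3 * X1, V)
        np.testing.assert_allclose(W1, W2, atol=1e-6)

    def test_donor_permutation_permutes_w(self):
        rng = np.random.default_rng(6)
        X0 = rng.normal(size=(3, 5))
        X1 = rng.normal(size=3)
        V = rng.dirichlet(np.ones(3))
        perm = rng.permutation(5)
        W, _ = solve_w(X0, X1, V, polish=True)
        Wp, _ = solve_w(X0[:, perm], X1, V, polish=True)
        np.testing.assert_allclose(Wp, W[perm], atol=1e-5)


class TestOptimizeV:
    def test_treated_identical_to_donor(self, small_study):
        # a twin of one donor is the treated unit: the fit must land on that
        # donor's vertex with a perfect pre-period fit
        panel, truth, design = small_study
        donor = truth["donors"][0]
        df = panel.data[panel.data["unit_id"] == donor].copy()
        df["unit_id"] = "TWIN"
        import pandas as pd
        from aidimpact import CountryYearPanel
        panel2 = CountryYearPanel(pd.concat([panel.data, df], ignore_index=True))
        d2 = design.replace(treated_units=("TWIN",),
                            donor_units=tuple(truth["donors"]))
        sol = fit_scm(panel2, d2)
        assert sol.rmspe_pre < 1e-6
        assert sol.weights_table().loc[donor] == pytest.approx(1.0, abs=1e-4)

    def test_informative_predictor_gets_weight(self):
        # one predictor perfectly predicts the outcome path, another is noise
        rng = np.random.default_rng(8)
        J, T0 = 6, 8
        Z0 = rng.normal(5, 1, size=(T0, J))
        w_true = np.array([0.5, 0.5, 0, 0, 0, 0.0])
        Z1 = Z0 @ w_true
        informative = Z0.mean(axis=0)
        noise = rng.normal(size=J)
        X0 = np.vstack([informative, noise])
        X1 = np.array([Z1.mean(), rng.normal()])
        from aidimpact.scm import ScmDesignMatrices
        m = ScmDesignMatrices(
            X1=X1, X0=X0, Z1=Z1, Z0=Z0, donor_ids=[f"D{j}" for j in range(J)],
            predictor_names=["good", "noise"], pre_years=list(range(T0)),
            scale=np.ones(2), Y1_all=Z1, Y0_all=Z0, all_years=list(range(T0)),
        )
        sol = optimize_v(m)
        assert sol.V[0] >= 0.9

    def test_outer_loss_close_to_dirichlet_grid(self):
        rng = np.random.default_rng(9)
        J, T0, k = 4, 8, 3
        X0 = rng.normal(size=(k, J))
        X1 = rng.normal(size=k)
        Z0 = rng.normal(size=(T0, J))
        Z1 = Z0 @ rng.dirichlet(np.ones(J))
        from aidimpact.scm import ScmDesignMatrices
        m = ScmDesignMatrices(
            X1=X1, X0=X0, Z1=Z1, Z0=Z0, donor_ids=[f"D{j}" for j in range(J)],
            predictor_names=list("abc"), pre_years=list(range(T0)),
            scale=np.ones(k), Y1_all=Z1, Y0_all=Z0, all_years=list(range(T0)),
        )
        sol = optimize_v(m)
        # exhaustive seeded Dirichlet grid over predictor weights
        v_grid = np.random.default_rng(99).dirichlet(np.ones(k), size=2000)
        grid_best = min(
            rmspe(Z1, Z0 @ solve_w(X0, X1, v)[0]) for v in v_grid
        )
        assert sol.rmspe_pre <= grid_best + 1e-3

    def test_beats_uniform_weights(self, small_study):
        panel, _, design = small_study
        m = prepare_design(panel, design)
        sol = optimize_v(m, FAST_SCM)
        uniform = rmspe(m.Z1, m.Z0 @ np.full(len(m.donor_ids), 1 / len(m.donor_ids)))
        assert sol.rmspe_pre <= uniform + 1e-12


class TestPrepareDesign:
    def test_predictor_means_match_direct_recomputation(self, small_study):
        panel, _, design = small_study
        m = prepare_design(panel, design)
        for j, donor in enumerate(m.donor_ids):
            sub = panel.data[(panel.data["unit_id"] == donor)
                             & panel.data["year"].isin(design.pre_years)]
            for i, p in enumerate(m.predictor_names):
                assert m.X0[i, j] * m.scale[i] == pytest.approx(sub[p].mean())

    def test_missing_donor_year_reported(self, small_study):
        panel, truth, design = small_study
        import pandas as pd
        from aidimpact import CountryYearPanel
        donor = truth["donors"][0]
        df = panel.data.copy()
        df.loc[(df["unit_id"] == donor) & (df["year"] == 2001), "outcome"] = np.nan
        with pytest.raises(ValueError, match=donor):
            prepare_design(CountryYearPanel(df), design)


class TestEffectSeries:
    def test_published_yearly_estimates_average(self):
        years = sorted(SCM_EFFECT_ESTIMATES)
        gaps = np.array([SCM_EFFECT_ESTIMATES[y] for y in years])
        sol = _build_solution_from_gaps(years, gaps)
        _, ate_post, ate_sig = effect_series(
            sol, post_years=years, significant_years=SIGNIFICANT_YEARS
        )
        assert round(ate_post, 4) == SCM_POST_AVERAGE
        assert round(ate_sig, 2) == SCM_SIGNIFICANT_AVERAGE

    def test_all_zero_gaps(self):
        years = list(range(2005, 2010))
        sol = _build_solution_from_gaps(years, np.zeros(5))
        _, ate_post, _ = effect_series(sol, post_years=years)
        assert ate_post == 0.0


def _build_solution_from_gaps(years, gaps):
    from aidimpact.scm import ScmSolution
    return ScmSolution(
        W=np.array([1.0]), V=np.array([1.0]), donor_ids=["D"],
        predictor_names=["p"], years=list(years), pre_years=[],
        treated_path=gaps, synthetic_path=np.zeros(len(years)), gaps=np.asarray(gaps),
        rmspe_pre=1.0, ate_post=float(np.mean(gaps)),
    )


class TestMixtureRecovery:
    def test_recovers_generating_weights_under_null(self):
        cfg = small_config(31, n_treated=0, effect_path={}, round_deaths=False)
        panel, truth, design = generate_mixture_panel(cfg)
        sol = fit_scm(panel, design)
        w_true = np.array([truth["mixture_weights"][d] for d in sol.donor_ids])
        assert np.abs(sol.W - w_true).sum() < 0.1
        post_gaps = sol.gaps[len(sol.pre_years):]
        assert np.abs(post_gaps).mean() < 0.1
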