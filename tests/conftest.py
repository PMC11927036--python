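import numpy as np
import pandas as pd
import pytest

from aidimpact import CountryYearPanel, StudyDesign
from aidimpact.scm import ScmOptions
from aidimpact.simulate import DgpConfig, generate_panel

#: Reduced-cost optimiser settings used by simulation-heavy tests.
FAST_SCM = ScmOptions(n_random_starts=1, maxiter=120, polish=False,
                      vertex_starts=False)

#: Small predictor subsets keep the outer optimisation cheap in simulations.
SMALL_PREDICTORS = ["hiv_prev", "tfr", "gdp_pc"]


def small_config(seed: int, **overrides) -> DgpConfig:
    """Desk-scale study: 3 treated, 8 donors, 20 years, 1 factor."""
    base = dict(
        seed=seed, n_treated=3, n_donor_pool=8,
        start_year=1995, end_year=2014, treatment_year=2005,
        n_factors=1, noise_sd=0.15,
        predictor_effects={"hiv_prev": 0.08, "tfr": 0.05},
    )
    base.update(overrides)
    return DgpConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    """One shared small panel with its ground truth and design."""
    panel, truth = generate_panel(small_config(421))
    design = truth["design"].replace(predictor_names=SMALL_PREDICTORS)
    return panel, truth, design


@pytest.fixture()
def tiny_panel():
    """Hand-built 2-unit, 3-year panel with exact counts."""
    rows = []
    for unit, base_deaths, pop in [("AAA", 4000, 1_000_000), ("BBB", 9000, 2_000_000)]:
        for i, year in enumerate([2000, 2001, 2002]):
            deaths = base_deaths + 100 * i
            rows.append({
                "unit_id": unit, "year": year,
                "wra_deaths": deaths, "wra_pop": pop,
                "total_deaths": deaths * 8,
                "outcome": deaths / pop * 1000,
                "income_class_baseline": "low",
            })
    return CountryYearPanel(pd.DataFrame(rows), predictor_names=[])
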