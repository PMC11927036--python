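# aidimpact

Quasi-experimental evaluation of sustained donor health funding effects on
mortality among women of reproductive age (WRA, ages 15–49), for
epidemiologists and impact-evaluation analysts working with country-year
panels.

Large, multi-country health-funding programmes cannot be randomised, so
their mortality impact has to be inferred from comparative case-study
methods. `aidimpact` implements the full pipeline for one such evaluation
design:

* **Cohort construction** — select the treated countries (sustained,
  broad, above-median funding) and filter a donor pool of comparison
  countries through auditable eligibility screens, aggregating the treated
  countries into one population-weighted unit.
* **Synthetic control** — find donor weights `W` on the probability
  simplex and predictor-importance weights `V` by the nested program

  ```
  W(V) = argmin_{W≥0, ΣW=1} (X1 − X0 W)' diag(V) (X1 − X0 W)
  V*   = argmin_V  RMSPE_pre( Z1 − Z0 W(V) )
  ```

  so the synthetic control reproduces the treated unit's pre-treatment WRA
  mortality path; post-treatment gaps are the per-year effect estimates.
* **Placebo inference** — refit every donor as pseudo-treated and rank the
  treated gap against the placebo gaps, raw and standardised by each
  unit's pre-period RMSPE; p-values live on {k/J}.
* **Bayesian latent-factor counterfactual** — a Gibbs-sampled panel model
  `y_it = μ + β'x_it + α_i + ξ_t + γ_i'f_t + ε_it` fitted with treated
  post-period cells held out, giving counterfactual draws and per-year
  treatment effects with 90% credible intervals, overall and per country.
* **Sensitivity battery** — leave-country-out scenarios, a two-step
  residual regression netting out the competing (non-USG) funding stream
  with the residual/base ATE ratio, a treatment-year scan, and an in-time
  split placebo for the Bayesian model.
* **Deaths-averted accounting** — convert effects (deaths per 1,000 WRA)
  into lives saved via the WRA population, with an adjustment share for
  other funding streams.
* **Synthetic data** — a ground-truthed panel generator matching the
  latent-factor model class, with hump-shaped common mortality trends, a
  post-2004 funding jump for treated units, an injected effect path, and
  an engineered cohort fixture whose donor-pool attrition reproduces the
  77 → 59 → 23 → 19 selection path.

## Worked example

```python
from aidimpact import (BmConfig, DgpConfig, att_summary, fit_bm, fit_scm,
                       generate_panel)
from aidimpact.placebo import pvalue_table, run_placebos

# a synthetic study at the default conditions: 16 treated countries,
# 19 donors, 1990-2019, treatment in 2005, true effect ramping to
# -1.0 deaths per 1,000 WRA by 2014
panel, truth = generate_panel(DgpConfig(seed=1))
design = truth["design"]

sol = fit_scm(panel, design)
print(f"pre-period RMSPE: {sol.rmspe_pre:.4f}")
print(f"post-period average effect: {sol.ate_post:.4f}")

table = pvalue_table(run_placebos(panel, design, treated_solution=sol))
print(f"post-average standardised p: {table.post_average_standardized:.3f}")

summary = att_summary(fit_bm(panel, design, BmConfig(seed=1)))
lo, hi = summary.post_average_ci
print(f"Bayesian post-average effect: {summary.post_average:.2f} "
      f"(90% CI {lo:.2f}, {hi:.2f})")
```

Output (seed 1):

```
pre-period RMSPE: 0.0746
post-period average effect: -0.6855
post-average standardised p: 0.000
Bayesian post-average effect: -0.76 (90% CI -0.85, -0.69)
```

The true post-period average of the injected effect path is −0.70 deaths
per 1,000 WRA: the synthetic control recovers it to 0.015, the placebo test
ranks the treated unit above every donor (p stored as 0, rendered
"<0.001"), and the Bayesian interval brackets the truth. Applying the
fitted gaps to the treated WRA population turns the rate reduction into
annual lives-saved counts — `scripts/acceptance.py` reports about 135,000
per year for this study, or 97,000 after a 28% adjustment for other
funding streams.

An `aidimpact` command-line group mirrors the stages (`simulate-panel`,
`select-cohort`, `fit-scm`, `placebo`, `fit-bayes`, `sensitivity`,
`lives-saved`); each subcommand is a thin wrapper over the functions above.

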