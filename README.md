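# intertemporal

Delay-discounting behavioral modeling for neuroeconomic studies: simulate
the monetary smaller-sooner / larger-later choice task, fit discounted
subjective-value models per participant by maximum likelihood, select
among them by BIC and balanced accuracy, export the subjective-value
parametric regressors an fMRI GLM consumes, and run the group-level
standardized-regression stage that relates PET receptor-availability
measures to fMRI value signals.

It is written for researchers who analyze intertemporal-choice data — with
or without imaging — and want a tested, scriptable pipeline whose every
stage can be exercised offline against synthetic cohorts with known ground
truth.

## The model

On each trial a participant chooses between an early amount `A_SS` at
delay `D_SS` and a larger late amount `A_LL` at delay `D_LL` (days). The
core model discounts hyperbolically,

    SV = A / (1 + kD),

with discount rate `k` (per day, analyzed as Ln(k)), and maps values to
choice probabilities through a softmax with inverse temperature β:

    p(SS) = exp(β·SV_SS) / (exp(β·SV_SS) + exp(β·SV_LL)).

Alternatives fit alongside it — exponential `A·e^(−kD)`, a two-exponential
beta-delta form, a concave discounted-utility form, an
exponentiated-delay hyperbolic `A/(1+kD^s)`, and a fixed-p random
baseline — and are compared by BIC (`p·ln n − 2·LL`, paired t-tests
across participants) and by balanced accuracy (mean per-class recall of
deterministic SS/LL predictions). Group-level associations between
per-subject scalars are standardized regressions (slope ≡ Pearson r) with
Fisher-z confidence intervals, a Bonferroni-corrected 3×4 ROI grid, and
Cook's-distance/studentized-residual influence triage. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from intertemporal import (
    simulate_cohort, fit_model, compare_models, standardized_regression,
)

# 12 softmax agents with hyperbolic discounting at the cohort parameters
cohort = simulate_cohort(12, seed=42, lnk_mean=-4.68, lnk_sd=1.27,
                         beta_temp=3.74)

fits = []
for subject_id, agent, records in cohort:
    for model in ("hyperbolic", "exponential", "random"):
        fits.append(fit_model(records, model, subject_id=subject_id))

hyp = [f for f in fits if f.model_name == "hyperbolic"]
true_lnk = [np.log(agent.params.k) for _, agent, _ in cohort]
recovered = [f.ln_k for f in hyp]
print("recovery r =", round(np.corrcoef(true_lnk, recovered)[0, 1], 3))

table = compare_models(fits, reference="hyperbolic")
print(table.per_model.round(2).to_string(index=False))

assoc = standardized_regression(recovered, [f.prop_sooner for f in hyp],
                                with_diagnostics=False)
print("Ln(k) vs prop(sooner): beta =", round(assoc.std_beta, 3),
      "CI", (round(assoc.ci_low, 3), round(assoc.ci_high, 3)))
```

Output:

```
recovery r = 0.992
 model_name  mean_bic  sd_bic  mean_balanced_accuracy
exponential     41.19   11.47                    0.89
 hyperbolic     35.30   10.50                    0.91
     random    116.45    0.00                    0.50
Ln(k) vs prop(sooner): beta = 0.939 CI (0.793, 0.983)
```

The recovery correlation says the fitted Ln(k) track the generating
discount rates almost perfectly at this session length (84 trials). The
hyperbolic family — the generating model — carries the lowest mean BIC and
the highest balanced accuracy, and the random baseline sits at its exact
closed form `2·84·ln 2 ≈ 116.45` with chance-level predictions. Steeper
discounters (higher Ln(k)) choose the sooner option more often, the
strongly positive standardized slope with its asymmetric Fisher-z
interval.

A command-line interface mirrors the library
(`intertemporal simulate | fit | compare | evs | assoc`); events tables
are BIDS-style `*_events.tsv`, fits travel as CSV, and regressors are
written as FSL 3-column EV files.

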