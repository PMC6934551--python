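# Methods

## The task and its synthetic counterpart

The monetary delay-discounting task offers, on each trial, a smaller-sooner
(SS) amount against a larger-later (LL) amount. The generator reproduces
the task's stated design: the sooner delay is drawn uniformly from
{today, 2 weeks, 1 month} and the later reward arrives a uniform
{2 weeks, 1 month, 6 weeks} after it, with months counted as 30 days (the
task description never gives day counts; {0, 14, 30} and offsets
{14, 30, 42} are the natural reading). The later amount is drawn from
Normal($15, $10) truncated to [$5, $30] by rejection; the sooner amount is
the later amount reduced by a Uniform[1%, 50%] fraction. The Gaussian is
read as governing the *late* amount — its grammatical antecedent — so the
[$5, $30] bounds are enforced on the late amount only and the early amount
may fall below $5. Amounts are rounded to cents, with the early amount
nudged by at most one cent so the 1–50% reduction survives rounding.
Whether the reduction fraction was itself uniform or Gaussian is ambiguous
in the task description; uniform was chosen. Delay and amount menus are
sampled independently per trial and runs are filled sequentially (no
counterbalancing is described). A session is 84 trials in two 42-trial
runs, one choice screen every 12 s; responses land within a 7.95 s window.

Synthetic participants are softmax agents over one of the value models
below. Their reaction times are truncated-lognormal (median 1.5 s, log-SD
0.4, support (0.3, 7.95] s) — pure plumbing for regressor timing; nothing
ever fits RTs. Misses are drawn independently at a configurable rate
(default 0).

What the generator does *not* emulate: human lapses of attention tied to
trial content, RT–difficulty coupling, session effects, or any violation
of the softmax assumption. Passing recovery tests therefore show that the
estimator is correct and well-conditioned *under the model*, not that real
choices obey a hyperbolic softmax.

## Value models and the choice rule

Six candidate families, all with delay `D` in days and amount `A` in USD:

| family | SV | free parameters |
|---|---|---|
| hyperbolic | A / (1 + kD) | k, β |
| exponential | A·e^(−kD) | k, β |
| beta-delta (two-exponential) | A·(e^(−β_dd·D) + e^(−δD)) | β_dd, δ, β |
| discounted utility | e^(−rA) / (r(1 + kD)) | r, k, β |
| exponentiated-delay hyperbolic | A / (1 + kD^s) | k, s, β |
| random | — (p = 0.5 fixed) | none |

The softmax inverse temperature is called `beta_temp` throughout and the
beta-delta immediate rate `beta_dd`, keeping the two conventional uses of
β apart. Choice probabilities are computed through the logistic of
β·(SV_a − SV_b), so no exponential can overflow, and are clipped into
[1e−12, 1 − 1e−12] so logs stay finite.

Two deliberate oddities, kept because the model comparison is defined over
these exact forms: the two-exponential beta-delta sum gives SV(0) = 2A
(a standard β–δ parameterisation would not), and the discounted-utility
numerator e^(−rA) makes value *decrease* with amount. The second makes the
family fit simulated hyperbolic choosers very badly (balanced accuracy at
chance); that is the honest behavior of the printed form, not a bug. A
maintainer wanting the literature-standard variants should treat them as
new model families rather than silently editing these.

## Fitting

Per participant, the negative log-likelihood of the responded choices is
minimised. Missed trials are excluded everywhere; `n` is the count of
valid trials (default floor: 10). All free parameters are strictly
positive and are optimised as their logarithms, making the search
unconstrained; log-parameters beyond ±50 are rejected with a large penalty
before exponentiation can overflow. The optimiser is Nelder-Mead
(objective tolerance 1e−6, at most 2000 iterations per start) from a fixed
multi-start grid: k ∈ {1e−4, 1e−3, 1e−2, 0.1, 1} × β ∈ {0.1, 1, 10} for
two-parameter families, and 3-point grids per parameter (27 starts) for
three-parameter families — β_dd, δ ∈ {1e−3, 1e−2, 0.1}, r ∈ {0.01, 0.1, 1},
s ∈ {0.5, 1, 2}, k ∈ {1e−3, 1e−2, 0.1}. The best converged start wins;
ties break by lower objective then lexicographic parameters. A fitted
inverse temperature above 1e3 raises a `beta_temp_at_edge` flag
(near-deterministic data make β unidentifiable from above); a fit below
1e−6 is floored there. The random baseline is closed-form: LL = −n·ln 2,
zero parameters.

Model comparison uses BIC = p·ln(n) − 2·LL (natural log, n = valid
trials; p = 2 for the two-parameter families, 3 for the others, 0 for
random) with paired two-sided t-tests of the reference model's per-subject
BIC against each alternative (df = N − 1). Prediction accuracy is balanced
accuracy — the mean of per-class recall over actual SS and actual LL
choices — from deterministic predictions: predict SS iff SV_SS > SV_LL,
ties to LL. If a participant never made one of the two choices, the
present class's recall is reported alone and the fit is flagged
`degenerate_balanced_accuracy`. The random model's predictions are seeded
coin flips.

Validation establishes three things on synthetic cohorts: (i) the
multi-start simplex optimum is never worse than an exhaustive 60×60
log-spaced (k, β) grid plus 1e−4 nats; (ii) across 50 simulated subjects
at the cohort parameters (Ln(k) ~ N(−4.68, 1.27²), β = 3.74, 84 trials)
the true/recovered Ln(k) correlation exceeds 0.95 and the recovered cohort
mean sits within 0.4 of the generating mean; (iii) BIC ranks the
generating (hyperbolic) family above beta-delta and random.

## Event regressors

From fitted parameters, two FSL FEAT 3-column EV regressors per run: an
un-modulated choice-period regressor (onset = choice screen, duration =
RT, weight 1; misses get the full 7.95 s window) and a subjective-value
parametric modulator — zero-duration events at the moment of response
(onset + RT; "at the choice reaction time" is read as the response moment,
with a stimulus-locked duration-RT variant available as an option),
weighted by the chosen option's SV under the subject's fitted parameters,
mean-centered within each run (the FEAT demeaning convention; per-session
demeaning was the plausible alternative and per-run was chosen). Weights
before centering equal the value-model outputs exactly. Misses contribute
no modulated event. A group-average variant substitutes the cohort
geometric-mean discount rate, k = exp(mean Ln(k)); the rank agreement
between subject-specific and group-average trial weights is a measurable
Spearman correlation, not an assumption.

## Group-level associations

Per-subject scalars (PET BP_ND in ventral striatum, midbrain, vmPFC; fMRI
SV parameter estimates in those plus posterior cingulate; Ln(k);
proportion sooner; age; sex) enter simple standardized regressions: both
variables z-scored, so the standardized slope is exactly Pearson's r; p
two-sided from t with n − 2 df; 95% CI from the Fisher z-transform
tanh(atanh(r) ± z*/√(n − 3)), which reproduces asymmetric printed
intervals from (r, n) alone. The 3×4 PET-by-fMRI grid is one Bonferroni
family (α/12 ≈ 0.004167); behavior correlations default to uncorrected
with their family size recorded, since their correction status in the
original analysis is unclear.

Influence triage per regression: Cook's distance flagged above 4× its
mean; externally studentized residuals tested two-sided against t with
n − 3 df at 0.05; Breusch–Pagan (chosen as the conventional
heteroskedasticity test; the original analysis does not name one)
supplies a model-level p. A point is *influential* only when the Cook's
rule and the studentized-residual test agree; flagged points are reported,
never auto-excluded — exclusion is an explicit re-run. Cook's distances
are verified against brute-force leave-one-out refits to 1e−10.

Covariate-adjusted follow-ups regress z-scored outcome on z-scored
predictor plus age (z-scored) and sex (binary indicator); the reported
coefficient is the standardized partial slope with a t-based Wald CI
(a partial coefficient is not a correlation, so Fisher-z does not apply).

The synthetic subject table draws each scalar independently from Gaussians
at the cohort descriptives (binding potentials truncated positive), and
can plant exact sample correlations between named column pairs by
constructing the second column from the residualized first; planted pairs
are recovered exactly by the regression stage, and a 12-test null grid
holds its family-wise error at ~5%.

## Problem sizes and numerical choices

Recovery, oracle-equivalence, and model-selection checks use 50-, 20-, and
50-subject cohorts of 84 trials — the study's session length at its fitted
cohort parameters. Probability floor 1e−12; optimizer tolerances above;
KS design checks at n = 10,000 and α = 0.001. The acceptance script
(`scripts/acceptance.py`) re-runs the 50-subject pipeline end-to-end with
all six families and a 22-subject association grid.

## Known limitations

- Synthetic choices obey the softmax generative model exactly, so
  balanced accuracies run higher (~88%) than typically observed in humans
  (~78%); the comparison between models, not the absolute accuracy, is the
  transportable result.
- The cohort-mean proportion of sooner choices emerging from this design
  at Ln(k) = −4.68 is ≈ 0.36–0.46 depending on the seed, somewhat below
  the 0.55 a human cohort produced; the generator's independent uniform
  menus are the stated design, and no parameter was adjusted to close the
  gap.
- The group-average regressor is defined for single-rate families
  (hyperbolic, exponential) and the exponentiated/concave extensions via
  parameter means; it has no meaning for the random baseline.
- GLM estimation, HRF convolution, and voxelwise inference are out of
  scope: the regressor stage ends at FEAT-ready EV files.
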