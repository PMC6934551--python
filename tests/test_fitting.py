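"""Likelihoods, maximum-likelihood fitting, BIC, and prediction accuracy."""

import math

import numpy as np
import pytest

from intertemporal import (
    AgentSpec,
    Choice,
    ChoiceRecord,
    ConfusionCounts,
    FitConfig,
    ModelParams,
    TrialSpec,
    balanced_accuracy,
    bic_score,
    compare_models,
    confusion_counts,
    fit_model,
    generate_trials,
    negative_log_likelihood,
    predict_choices,
    proportion_sooner,
    simulate_choices,
    summarize_cohort,
)
from intertemporal.fitting import FitResult, NoDataError


def make_trial(early, late, early_delay=0, offset=14, index=0):
    return TrialSpec(
        trial_index=index, run_index=0, onset_s=12.0 * index,
        early_amount_usd=early, late_amount_usd=late,
        early_delay_days=early_delay, late_delay_days=early_delay + offset,
    )


def record(trial, choice, rt=1.5):
    return ChoiceRecord(trial=trial, choice=choice,
                        rt_s=None if choice is Choice.MISS else rt)


class TestNegativeLogLikelihood:
    def test_zero_temperature_gives_chance_likelihood(self, design84,
                                                      hyperbolic_records):
        params = ModelParams(model_name="hyperbolic", k=0.01, beta_temp=0.0)
        nll = negative_log_likelihood(hyperbolic_records, params)
        assert nll == pytest.approx(len(hyperbolic_records) * math.log(2))

    def test_unit_logit_trials(self):
        # k = 3/98 puts SV_LL = 20 / (10/7) = 14, one dollar below SV_SS,
        # so with beta 1 the chosen probability is e/(e+1)
        trial = make_trial(15.0, 20.0)
        params = ModelParams(model_name="hyperbolic", k=3 / 98, beta_temp=1.0)
        recs = [record(trial, Choice.SS),
                record(make_trial(15.0, 20.0, index=1), Choice.SS)]
        expected = -2 * math.log(math.e / (math.e + 1))
        assert negative_log_likelihood(recs, params) == pytest.approx(
            expected, abs=1e-9)
        assert expected == pytest.approx(0.6265, abs=5e-5)

    def test_random_model_closed_form(self, hyperbolic_records):
        params = ModelParams(model_name="random")
        nll = negative_log_likelihood(hyperbolic_records, params)
        assert nll == pytest.approx(84 * math.log(2))
        assert nll == pytest.approx(58.2244, abs=5e-5)

    def test_all_misses_rejected(self, design84):
        recs = [record(t, Choice.MISS) for t in design84]
        with pytest.raises(NoDataError):
            negative_log_likelihood(
                recs, ModelParams(model_name="random"))

    def test_miss_trials_excluded(self, design84):
        params = ModelParams(model_name="hyperbolic", k=0.01, beta_temp=0.0)
        recs = [record(t, Choice.SS) for t in design84[:10]]
        recs += [record(t, Choice.MISS) for t in design84[10:20]]
        assert negative_log_likelihood(recs, params) == pytest.approx(
            10 * math.log(2))


class TestBicScore:
    def test_random_on_full_session(self):
        assert bic_score(-84 * math.log(2), 0, 84) == pytest.approx(
            2 * 84 * math.log(2))
        assert bic_score(-84 * math.log(2), 0, 84) == pytest.approx(
            116.4487, abs=5e-5)

    def test_two_parameter_model(self):
        assert bic_score(-20.0, 2, 84) == pytest.approx(
            2 * math.log(84) + 40, abs=1e-9)
        assert bic_score(-20.0, 2, 84) == pytest.approx(48.8616, abs=5e-5)

    def test_degenerate(self):
        assert bic_score(0.0, 0, 1) == 0.0
        with pytest.raises(ValueError):
            bic_score(0.0, 0, 0)


class TestPredictChoices:
    def test_patient_model_predicts_waiting(self, hyperbolic_records):
        params = ModelParams(model_name="hyperbolic", k=1e-12, beta_temp=1.0)
        assert all(c is Choice.LL
                   for c in predict_choices(hyperbolic_records, params))

    def test_steep_discounting_predicts_sooner(self):
        recs = [record(make_trial(15.0, 20.0), Choice.LL)]
        params = ModelParams(model_name="hyperbolic", k=1.0, beta_temp=1.0)
        assert predict_choices(recs, params) == [Choice.SS]

    def test_exact_tie_goes_to_later_option(self):
        # k = 1/16 over 14 days scales 30 down to exactly 16
        recs = [record(make_trial(16.0, 30.0), Choice.SS)]
        params = ModelParams(model_name="hyperbolic", k=0.0625, beta_temp=1.0)
        from intertemporal.models import sv_hyperbolic
        assert sv_hyperbolic(30.0, 0.0625, 14) == 16.0
        assert predict_choices(recs, params) == [Choice.LL]


class TestBalancedAccuracy:
    def test_hand_example(self):
        counts = ConfusionCounts(t_ss=3, f_ss=1, t_ll=4, f_ll=2)
        assert balanced_accuracy(counts) == pytest.approx(
            0.5 * (3 / 4 + 4 / 6))

    def test_perfect_predictions(self):
        assert balanced_accuracy(
            ConfusionCounts(t_ss=10, f_ss=0, t_ll=30, f_ll=0)) == 1.0

    def test_degenerate_single_class(self):
        counts = ConfusionCounts(t_ss=0, f_ss=0, t_ll=8, f_ll=2)
        assert counts.degenerate
        assert balanced_accuracy(counts) == pytest.approx(0.8)

    def test_empty_rejected(self):
        with pytest.raises(NoDataError):
            balanced_accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_coin_flip_is_at_chance(self):
        rng = np.random.default_rng(0)
        n = 10_000
        actual = rng.random(n) < 0.5
        predicted = rng.random(n) < 0.5
        t_ss = int(np.sum(actual & predicted))
        f_ss = int(np.sum(actual & ~predicted))
        t_ll = int(np.sum(~actual & ~predicted))
        f_ll = int(np.sum(~actual & predicted))
        acc = balanced_accuracy(ConfusionCounts(t_ss, f_ss, t_ll, f_ll))
        assert acc == pytest.approx(0.5, abs=0.02)


class TestFitModel:
    def test_recovers_generating_discount_rate(self, hyperbolic_records):
        fit = fit_model(hyperbolic_records, "hyperbolic")
        assert fit.ln_k == pytest.approx(-4.6, abs=0.75)
        assert fit.n_valid == 84
        assert fit.n_params == 2
        assert fit.bic == pytest.approx(
            2 * math.log(84) - 2 * fit.ll_max)
        assert fit.n_starts_converged > 0

    def test_beats_dense_grid_oracle(self, hyperbolic_records):
        """Multi-start simplex must reach at least the best point of an
        exhaustive 60 x 60 log-spaced (k, beta) grid, for both
        two-parameter discount families."""
        valid = [r for r in hyperbolic_records if r.choice is not Choice.MISS]
        a_ss = np.array([r.trial.early_amount_usd for r in valid])
        d_ss = np.array([r.trial.early_delay_days for r in valid], float)
        a_ll = np.array([r.trial.late_amount_usd for r in valid])
        d_ll = np.array([r.trial.late_delay_days for r in valid], float)
        chose_ss = np.array([r.choice is Choice.SS for r in valid])
        for family in ("hyperbolic", "exponential"):
            if family == "hyperbolic":
                def sv(a, d, k):
                    return a / (1 + k * d)
            else:
                def sv(a, d, k):
                    return a * np.exp(-k * d)
            best = np.inf
            for k in np.logspace(-5, 1, 60):
                diff = sv(a_ss, d_ss, k) - sv(a_ll, d_ll, k)
                signed = np.where(chose_ss, diff, -diff)
                for beta in np.logspace(-3, 2, 60):
                    with np.errstate(over="ignore"):
                        p = 1.0 / (1.0 + np.exp(-beta * signed))
                    nll = -np.sum(np.log(np.clip(p, 1e-12, 1)))
                    best = min(best, nll)
            fit = fit_model(hyperbolic_records, family)
            assert -fit.ll_max <= best + 1e-4

    def test_random_model_is_closed_form(self, hyperbolic_records):
        fit = fit_model(hyperbolic_records, "random")
        assert fit.ll_max == pytest.approx(-84 * math.log(2))
        assert fit.n_params == 0
        assert fit.bic == pytest.approx(2 * 84 * math.log(2))
        assert fit.n_starts_converged == 0

    def test_minimum_trial_floor(self, design84):
        recs = [record(t, Choice.SS) for t in design84[:5]]
        with pytest.raises(NoDataError):
            fit_model(recs, "hyperbolic")

    def test_unknown_model(self, hyperbolic_records):
        with pytest.raises(ValueError):
            fit_model(hyperbolic_records, "magic")

    def test_three_parameter_families_fit(self, hyperbolic_records):
        for family in ("beta_delta", "quasi_hyperbolic_s",
                       "discounted_utility"):
            fit = fit_model(hyperbolic_records, family)
            assert fit.n_params == 3
            assert np.isfinite(fit.bic)


class TestProportionSooner:
    def test_all_sooner(self, design84):
        recs = [record(t, Choice.SS) for t in design84[:10]]
        assert proportion_sooner(recs) == 1.0

    def test_miss_exclusion(self, design84):
        recs = [record(t, Choice.SS) for t in design84[:5]]
        recs += [record(t, Choice.LL) for t in design84[5:10]]
        recs += [record(t, Choice.MISS) for t in design84[10:12]]
        assert proportion_sooner(recs) == 0.5

    def test_no_valid_trials(self, design84):
        with pytest.raises(NoDataError):
            proportion_sooner([record(design84[0], Choice.MISS)])


def _toy_fit(subject, model, bic, ln_k=None, beta=None, acc=0.75):
    params = None
    if model == "hyperbolic":
        params = ModelParams(model_name="hyperbolic",
                             k=math.exp(ln_k if ln_k is not None else -4),
                             beta_temp=beta if beta is not None else 2.0)
    elif model == "random":
        params = ModelParams(model_name="random")
    return FitResult(
        subject_id=subject, model_name=model, mle_params=params,
        ll_max=-bic / 2, n_valid=84, n_params=0, bic=bic,
        balanced_accuracy=acc, ln_k=ln_k, prop_sooner=0.5,
        n_starts_converged=1,
    )


class TestCompareModels:
    def test_paired_t_hand_example(self):
        fits = [
            _toy_fit(s, "hyperbolic", b, ln_k=-4.0, beta=2.0)
            for s, b in zip("abc", [1.0, 2.0, 3.0])
        ] + [_toy_fit(s, "random", b) for s, b in zip("abc", [2.0, 3.0, 5.0])]
        table = compare_models(fits, reference="hyperbolic")
        row = table.vs_reference.iloc[0]
        assert row["t"] == pytest.approx(-4.0)
        assert row["df"] == 2

    def test_identical_bics_flagged(self):
        fits = [
            _toy_fit(s, "hyperbolic", b, ln_k=-4.0, beta=2.0)
            for s, b in zip("abc", [1.0, 2.0, 3.0])
        ] + [_toy_fit(s, "random", b) for s, b in zip("abc", [1.0, 2.0, 3.0])]
        table = compare_models(fits, reference="hyperbolic")
        row = table.vs_reference.iloc[0]
        assert row["t"] == 0.0
        assert row["zero_variance"]

    def test_unequal_subject_sets_rejected(self):
        fits = [
            _toy_fit("a", "hyperbolic", 1.0, ln_k=-4.0, beta=2.0),
            _toy_fit("b", "hyperbolic", 2.0, ln_k=-4.0, beta=2.0),
            _toy_fit("a", "random", 2.0),
        ]
        with pytest.raises(ValueError):
            compare_models(fits, reference="hyperbolic")


class TestSummarizeCohort:
    def test_mean_and_sd(self):
        fits = [
            _toy_fit("a", "hyperbolic", 30.0, ln_k=-4.0, beta=2.0),
            _toy_fit("b", "hyperbolic", 32.0, ln_k=-5.0, beta=4.0),
        ]
        table = summarize_cohort(fits)
        row = table[table.variable == "ln_k[hyperbolic]"].iloc[0]
        assert row["mean"] == pytest.approx(-4.5)
        assert row["sd"] == pytest.approx(math.sqrt(0.5), abs=1e-6)
        assert set(table.variable) == {
            "prop_sooner", "ln_k[hyperbolic]", "beta_temp[hyperbolic]",
            "bic[hyperbolic]",
        }

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort(
                [_toy_fit("a", "hyperbolic", 30.0, ln_k=-4.0, beta=2.0)])
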