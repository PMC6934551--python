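"""Per-participant maximum-likelihood fitting and model comparison.

Each candidate model's parameters are fit per participant by minimising the
negative log-likelihood of the observed smaller-sooner / larger-later
choices under a softmax decision rule. Positive parameters are optimised on
the log scale with a deterministic multi-start Nelder-Mead simplex; models
are then compared across participants by BIC (paired t-tests against a
reference model) and by balanced accuracy of their deterministic choice
predictions.

Missed trials carry no choice and are excluded everywhere; ``n`` in the BIC
penalty is the number of valid (responded) trials.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .models import (
    MODEL_FAMILIES,
    N_FREE_PARAMS,
    ModelParams,
    UnsupportedModelError,
    ln_k,
    subjective_value,
)
from .task import Choice, ChoiceRecord

__all__ = [
    "FitConfig",
    "FitResult",
    "ConfusionCounts",
    "ModelComparisonTable",
    "NoDataError",
    "FitFailureError",
    "negative_log_likelihood",
    "fit_model",
    "bic_score",
    "predict_choices",
    "confusion_counts",
    "balanced_accuracy",
    "compare_models",
    "proportion_sooner",
    "summarize_cohort",
]


class NoDataError(ValueError):
    """Raised when an operation receives no valid (responded) trials."""


class FitFailureError(RuntimeError):
    """Raised when no optimizer start converges; carries diagnostics."""


# -- configuration ----------------------------------------------------------

#: deterministic multi-start grids, on the natural parameter scale
DEFAULT_START_GRIDS: dict[str, tuple[float, ...]] = {
    "k": (1e-4, 1e-3, 1e-2, 1e-1, 1.0),
    "k3": (1e-3, 1e-2, 1e-1),  # coarser k grid for three-parameter models
    "beta_temp": (0.1, 1.0, 10.0),
    "beta_dd": (1e-3, 1e-2, 1e-1),
    "delta": (1e-3, 1e-2, 1e-1),
    "r": (1e-2, 1e-1, 1.0),
    "s": (0.5, 1.0, 2.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and likelihood settings.

    ``prob_floor`` guards the log-likelihood against zero probabilities at
    extreme inverse temperatures; ``beta_temp_edge`` is the value above
    which a fitted inverse temperature is flagged as effectively unbounded
    (near-deterministic data).
    """

    prob_floor: float = 1e-12
    min_valid_trials: int = 10
    fatol: float = 1e-6
    xatol: float = 1e-6
    maxiter: int = 2000
    beta_temp_floor: float = 1e-6
    beta_temp_edge: float = 1e3
    seed: int = 0
    start_grids: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_START_GRIDS)
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Prediction counts split by the participant's actual choice.

    ``t_ss``/``f_ss`` partition the actual smaller-sooner trials into
    correctly and incorrectly predicted; ``t_ll``/``f_ll`` do the same for
    actual larger-later trials.
    """

    t_ss: int
    f_ss: int
    t_ll: int
    f_ll: int

    @property
    def total(self) -> int:
        return self.t_ss + self.f_ss + self.t_ll + self.f_ll

    @property
    def degenerate(self) -> bool:
        """True when one of the two choice classes never occurred."""
        return (self.t_ss + self.f_ss == 0) or (self.t_ll + self.f_ll == 0)


@dataclass(frozen=True)
class FitResult:
    subject_id: str
    model_name: str
    mle_params: Optional[ModelParams]
    ll_max: float
    n_valid: int
    n_params: int
    bic: float
    balanced_accuracy: float
    ln_k: Optional[float]
    prop_sooner: float
    n_starts_converged: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ModelComparisonTable:
    """Cohort-level model comparison.

    ``per_model``: mean/SD BIC and mean balanced accuracy per model.
    ``vs_reference``: paired t-test of the reference model's BIC against
    each other model (df = number of subjects - 1).
    """

    reference: str
    per_model: pd.DataFrame
    vs_reference: pd.DataFrame


# -- likelihood -------------------------------------------------------------

def _valid_arrays(records: Sequence[ChoiceRecord]):
    """Option amounts/delays and the choice indicator for responded trials."""
    valid = [r for r in records if r.choice is not Choice.MISS]
    if not valid:
        raise NoDataError("all trials are misses; nothing to fit")
    a_ss = np.array([r.trial.early_amount_usd for r in valid])
    d_ss = np.array([r.trial.early_delay_days for r in valid], dtype=float)
    a_ll = np.array([r.trial.late_amount_usd for r in valid])
    d_ll = np.array([r.trial.late_delay_days for r in valid], dtype=float)
    chose_ss = np.array([r.choice is Choice.SS for r in valid])
    return a_ss, d_ss, a_ll, d_ll, chose_ss


def _nll_arrays(params: ModelParams, a_ss, d_ss, a_ll, d_ll, chose_ss,
                prob_floor: float) -> float:
    n = chose_ss.size
    if params.model_name == "random":
        return n * math.log(2.0)
    sv_ss = subjective_value(params, a_ss, d_ss)
    sv_ll = subjective_value(params, a_ll, d_ll)
    # p(chosen) through the logistic of the signed SV difference
    diff = np.where(chose_ss, sv_ss - sv_ll, sv_ll - sv_ss)
    p = expit(params.beta_temp * diff)
    p = np.clip(p, prob_floor, 1.0)
    return float(-np.sum(np.log(p)))


def negative_log_likelihood(
    records: Sequence[ChoiceRecord],
    params: ModelParams,
    prob_floor: float = 1e-12,
) -> float:
    """Negative log-likelihood (nats) of the responded choices.

    Each responded trial contributes ``-ln p(chosen option)`` under the
    softmax rule; probabilities are floored at ``prob_floor`` before the
    log so the objective stays finite. The random baseline contributes
    ``ln 2`` per trial. Missed trials are excluded.
    """
    return _nll_arrays(params, *_valid_arrays(records), prob_floor)


# -- optimisation -----------------------------------------------------------

def _free_param_names(model_name: str) -> list[str]:
    names = list(MODEL_FAMILIES[model_name])
    if model_name != "random":
        names.append("beta_temp")
    return names


def _start_grid(model_name: str, grids: dict[str, tuple[float, ...]]):
    names = _free_param_names(model_name)
    three_param = len(names) == 3
    axes = []
    for name in names:
        if name == "k" and three_param and "k3" in grids:
            axes.append(grids["k3"])
        else:
            axes.append(grids[name])
    return names, list(itertools.product(*axes))


def _params_from_theta(model_name: str, names: list[str],
                       theta: np.ndarray) -> ModelParams:
    values = {n: float(np.exp(t)) for n, t in zip(names, theta)}
    return ModelParams(model_name=model_name, **values)


def fit_model(
    records: Sequence[ChoiceRecord],
    model_name: str,
    config: FitConfig | None = None,
    subject_id: str = "sub-00",
) -> FitResult:
    """Fit one model to one participant's choices by multi-start Nelder-Mead.

    All free parameters are strictly positive and are optimised as their
    logs, which makes the search unconstrained. Starts come from a fixed
    grid; the best converged start wins, ties broken by lower negative
    log-likelihood then lexicographic parameter order. The random baseline
    is not optimised: its likelihood is closed-form with zero parameters.
    """
    cfg = config or FitConfig()
    if model_name not in MODEL_FAMILIES:
        raise UnsupportedModelError(f"unknown model family {model_name!r}")
    arrays = _valid_arrays(records)
    chose_ss = arrays[4]
    n_valid = int(chose_ss.size)
    if n_valid < cfg.min_valid_trials:
        raise NoDataError(
            f"{n_valid} valid trials < minimum {cfg.min_valid_trials}"
        )
    prop_ss = float(chose_ss.mean())
    flags: list[str] = []

    if model_name == "random":
        ll = -n_valid * math.log(2.0)
        counts = _random_confusion(records, seed=cfg.seed)
        acc = balanced_accuracy(counts)
        if counts.degenerate:
            flags.append("degenerate_balanced_accuracy")
        return FitResult(
            subject_id=subject_id,
            model_name="random",
            mle_params=ModelParams(model_name="random"),
            ll_max=ll,
            n_valid=n_valid,
            n_params=0,
            bic=bic_score(ll, 0, n_valid),
            balanced_accuracy=acc,
            ln_k=None,
            prop_sooner=prop_ss,
            n_starts_converged=0,
            flags=tuple(flags),
        )

    names, starts = _start_grid(model_name, cfg.start_grids)

    def objective(theta: np.ndarray) -> float:
        # reject log-parameters far outside any plausible scale before exp
        # can overflow or underflow to an invalid zero
        if np.any(np.abs(theta) > 50.0):
            return 1e10 + float(np.sum(np.abs(theta)))
        params = _params_from_theta(model_name, names, theta)
        return _nll_arrays(params, *arrays, cfg.prob_floor)

    best: tuple[float, tuple[float, ...]] | None = None
    n_converged = 0
    for start in starts:
        theta0 = np.log(np.asarray(start, dtype=float))
        res = optimize.minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            options={
                "fatol": cfg.fatol,
                "xatol": cfg.xatol,
                "maxiter": cfg.maxiter,
            },
        )
        if not np.isfinite(res.fun):
            continue
        if res.success:
            n_converged += 1
        candidate = (float(res.fun), tuple(float(t) for t in res.x))
        if best is None or candidate < best:
            best = candidate
    if n_converged == 0 or best is None:
        raise FitFailureError(
            f"no Nelder-Mead start converged for {model_name} "
            f"({len(starts)} starts, n_valid={n_valid})"
        )
    nll_min, theta_best = best
    params = _params_from_theta(model_name, names, np.asarray(theta_best))
    if params.beta_temp is not None:
        if params.beta_temp < cfg.beta_temp_floor:
            params = params.with_values(beta_temp=cfg.beta_temp_floor)
            nll_min = _nll_arrays(params, *arrays, cfg.prob_floor)
        if params.beta_temp >= cfg.beta_temp_edge:
            flags.append("beta_temp_at_edge")

    predicted = predict_choices(records, params)
    counts = confusion_counts(records, predicted)
    if counts.degenerate:
        flags.append("degenerate_balanced_accuracy")
    ll = -nll_min
    n_params = N_FREE_PARAMS[model_name]
    return FitResult(
        subject_id=subject_id,
        model_name=model_name,
        mle_params=params,
        ll_max=ll,
        n_valid=n_valid,
        n_params=n_params,
        bic=bic_score(ll, n_params, n_valid),
        balanced_accuracy=balanced_accuracy(counts),
        ln_k=ln_k(params.k) if params.k is not None else None,
        prop_sooner=prop_ss,
        n_starts_converged=n_converged,
        flags=tuple(flags),
    )


def bic_score(ll_max: float, n_params: int, n_valid: int) -> float:
    """Bayesian Information Criterion, ``n_params * ln(n) - 2 * ll_max``."""
    if n_valid < 1:
        raise ValueError(f"n_valid must be >= 1, got {n_valid}")
    return n_params * math.log(n_valid) - 2.0 * ll_max


# -- prediction and accuracy -------------------------------------------------

def predict_choices(
    records: Sequence[ChoiceRecord],
    params: ModelParams,
    seed: int = 0,
) -> list[Choice]:
    """Deterministic choice predictions on responded trials.

    Predict smaller-sooner exactly when its subjective value is strictly
    greater; ties go to larger-later. The random baseline has no values and
    predicts by a seeded coin flip.
    """
    valid = [r for r in records if r.choice is not Choice.MISS]
    if params.model_name == "random":
        rng = np.random.default_rng(seed)
        return [Choice.SS if rng.random() < 0.5 else Choice.LL for _ in valid]
    out: list[Choice] = []
    for rec in valid:
        t = rec.trial
        sv_ss = subjective_value(params, t.early_amount_usd, t.early_delay_days)
        sv_ll = subjective_value(params, t.late_amount_usd, t.late_delay_days)
        out.append(Choice.SS if sv_ss > sv_ll else Choice.LL)
    return out


def confusion_counts(
    records: Sequence[ChoiceRecord], predicted: Sequence[Choice]
) -> ConfusionCounts:
    valid = [r for r in records if r.choice is not Choice.MISS]
    if len(valid) != len(predicted):
        raise ValueError(
            f"{len(predicted)} predictions for {len(valid)} valid trials"
        )
    t_ss = f_ss = t_ll = f_ll = 0
    for rec, pred in zip(valid, predicted):
        if rec.choice is Choice.SS:
            if pred is Choice.SS:
                t_ss += 1
            else:
                f_ss += 1
        else:
            if pred is Choice.LL:
                t_ll += 1
            else:
                f_ll += 1
    return ConfusionCounts(t_ss=t_ss, f_ss=f_ss, t_ll=t_ll, f_ll=f_ll)


def _random_confusion(records: Sequence[ChoiceRecord], seed: int
                      ) -> ConfusionCounts:
    random_params = ModelParams(model_name="random")
    return confusion_counts(
        records, predict_choices(records, random_params, seed=seed)
    )


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """Mean per-class recall over smaller-sooner and larger-later choices.

    Insensitive to unequal class sizes. If one class never occurred the
    other class's recall is returned on its own (see
    :attr:`ConfusionCounts.degenerate`).
    """
    if counts.total == 0:
        raise NoDataError("no trials to score")
    recalls = []
    if counts.t_ss + counts.f_ss > 0:
        recalls.append(counts.t_ss / (counts.t_ss + counts.f_ss))
    if counts.t_ll + counts.f_ll > 0:
        recalls.append(counts.t_ll / (counts.t_ll + counts.f_ll))
    return float(np.mean(recalls))


def proportion_sooner(records: Sequence[ChoiceRecord]) -> float:
    """Proportion of responded trials where the sooner option was chosen."""
    valid = [r for r in records if r.choice is not Choice.MISS]
    if not valid:
        raise NoDataError("no valid trials")
    return sum(r.choice is Choice.SS for r in valid) / len(valid)


# -- cohort tables -----------------------------------------------------------

def _fits_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [f.subject_id for f in fits],
            "model_name": [f.model_name for f in fits],
            "bic": [f.bic for f in fits],
            "balanced_accuracy": [f.balanced_accuracy for f in fits],
            "ln_k": [f.ln_k for f in fits],
            "beta_temp": [
                None if f.mle_params is None else f.mle_params.beta_temp
                for f in fits
            ],
            "prop_sooner": [f.prop_sooner for f in fits],
        }
    )


def compare_models(
    fits: Sequence[FitResult], reference: str = "hyperbolic"
) -> ModelComparisonTable:
    """Cohort model comparison against a reference model.

    For each non-reference model, a paired two-sided t-test of the
    reference model's per-subject BIC against that model's (df = N - 1).
    Subjects must be identical across models.
    """
    frame = _fits_frame(fits)
    models = sorted(frame["model_name"].unique())
    if reference not in models:
        raise ValueError(f"no fits for reference model {reference!r}")
    subject_sets = {
        m: tuple(sorted(frame.loc[frame.model_name == m, "subject_id"]))
        for m in models
    }
    if len(set(subject_sets.values())) != 1:
        raise ValueError("subject sets differ across models")

    per_model = (
        frame.groupby("model_name")
        .agg(
            mean_bic=("bic", "mean"),
            sd_bic=("bic", "std"),
            mean_balanced_accuracy=("balanced_accuracy", "mean"),
        )
        .reset_index()
    )

    wide = frame.pivot(index="subject_id", columns="model_name", values="bic")
    rows = []
    for other in models:
        if other == reference:
            continue
        diff = wide[reference] - wide[other]
        if np.allclose(diff, diff.iloc[0]) and np.isclose(diff.std(ddof=1), 0):
            t_stat, p = (0.0, 1.0) if np.isclose(diff.iloc[0], 0) else (
                np.inf * np.sign(diff.iloc[0]), 0.0)
            zero_var = True
        else:
            t_stat, p = stats.ttest_rel(wide[reference], wide[other])
            zero_var = False
        rows.append(
            {
                "model_name": other,
                "t": float(t_stat),
                "df": len(wide) - 1,
                "p": float(p),
                "zero_variance": zero_var,
            }
        )
    return ModelComparisonTable(
        reference=reference,
        per_model=per_model,
        vs_reference=pd.DataFrame(rows),
    )


def summarize_cohort(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Cohort descriptives: mean and SD per variable, per model.

    Rows mirror a study-characteristics table: proportion of sooner choices,
    then per model the fitted Ln(k), inverse temperature, and BIC.
    """
    frame = _fits_frame(fits)
    if frame["subject_id"].nunique() < 2:
        raise ValueError("cohort summary needs at least 2 subjects")
    rows = []

    def add(variable: str, values: pd.Series) -> None:
        values = values.dropna().astype(float)
        if len(values):
            rows.append(
                {
                    "variable": variable,
                    "mean": values.mean(),
                    "sd": values.std(ddof=1),
                    "n": len(values),
                }
            )

    first_model = frame["model_name"].iloc[0]
    add("prop_sooner",
        frame.loc[frame.model_name == first_model, "prop_sooner"])
    for model in sorted(frame["model_name"].unique()):
        sub = frame[frame.model_name == model]
        add(f"ln_k[{model}]", sub["ln_k"])
        add(f"beta_temp[{model}]", sub["beta_temp"])
        add(f"bic[{model}]", sub["bic"])
    return pd.DataFrame(rows)
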