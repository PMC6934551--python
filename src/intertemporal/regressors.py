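"""GLM event regressors from fitted value models.

Two regressors per run, in the FSL FEAT 3-column EV convention:

* an un-modulated choice-period regressor — one event per trial, onset at
  the choice screen, duration equal to the reaction time (the full 7.95 s
  response window on missed trials), weight 1;
* a subjective-value parametric modulator — a zero-duration event at the
  moment of response (stimulus onset + reaction time) on each responded
  trial, weighted by the subjective value of the chosen option under the
  participant's fitted discount parameters, mean-centered within each run.

A group-average variant replaces each participant's discount rate with the
geometric-mean cohort rate (the arithmetic mean of Ln(k), exponentiated),
for testing whether associations depend on subject-specific valuation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .fitting import FitResult, NoDataError
from .models import ModelParams, subjective_value
from .task import Choice, ChoiceRecord, RESPONSE_WINDOW_S

__all__ = [
    "RegressorKind",
    "EventRegressor",
    "chosen_sv_series",
    "group_average_params",
    "group_average_sv_series",
    "build_regressors",
    "export_ev3",
]


class RegressorKind(str, enum.Enum):
    UNMODULATED = "unmodulated"
    SV_MODULATED = "sv_modulated"


@dataclass(frozen=True)
class EventRegressor:
    """Rows of (onset, duration, weight) for one run and one regressor."""

    kind: RegressorKind
    onsets_s: tuple[float, ...]
    durations_s: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.onsets_s)
        if not (len(self.durations_s) == n and len(self.weights) == n):
            raise ValueError("onsets, durations and weights must align")
        if any(b <= a for a, b in zip(self.onsets_s, self.onsets_s[1:])):
            raise ValueError("onsets must be strictly increasing")
        if self.kind is RegressorKind.SV_MODULATED:
            if abs(sum(self.weights)) > 1e-9:
                raise ValueError("modulated weights must be mean-centered")

    def __len__(self) -> int:
        return len(self.onsets_s)


def chosen_sv_series(
    records: Sequence[ChoiceRecord], params: ModelParams
) -> list[float]:
    """Subjective value of the chosen option on each responded trial.

    Values come straight from the value model at the participant's fitted
    parameters — no rescaling. Missed trials contribute nothing.
    """
    out: list[float] = []
    for rec in records:
        if rec.choice is Choice.MISS:
            continue
        t = rec.trial
        if rec.choice is Choice.SS:
            sv = subjective_value(params, t.early_amount_usd, t.early_delay_days)
        else:
            sv = subjective_value(params, t.late_amount_usd, t.late_delay_days)
        out.append(float(sv))
    return out


def group_average_params(cohort_fits: Sequence[FitResult]) -> ModelParams:
    """Hyperbolic parameters at the cohort's geometric-mean discount rate.

    ``k = exp(mean(Ln(k)))`` over subjects; the inverse temperature is
    irrelevant for building value series and is carried as the mean fitted
    value.
    """
    if not cohort_fits:
        raise NoDataError("empty cohort")
    lnks = [f.ln_k for f in cohort_fits if f.ln_k is not None]
    if not lnks:
        raise NoDataError("no fits with a discount rate in cohort")
    betas = [
        f.mle_params.beta_temp
        for f in cohort_fits
        if f.mle_params is not None and f.mle_params.beta_temp is not None
    ]
    model = cohort_fits[0].model_name
    base = {"model_name": model, "k": math.exp(float(np.mean(lnks))),
            "beta_temp": float(np.mean(betas)) if betas else 1.0}
    extra = {}
    if model == "quasi_hyperbolic_s":
        extra["s"] = float(np.mean([f.mle_params.s for f in cohort_fits]))
    elif model == "discounted_utility":
        extra["r"] = float(np.mean([f.mle_params.r for f in cohort_fits]))
    elif model not in ("hyperbolic", "exponential"):
        raise ValueError(f"group averaging not defined for {model!r}")
    return ModelParams(**base, **extra)


def group_average_sv_series(
    records: Sequence[ChoiceRecord], cohort_fits: Sequence[FitResult]
) -> list[float]:
    """Chosen-option SV series using the group-averaged discount rate."""
    return chosen_sv_series(records, group_average_params(cohort_fits))


def build_regressors(
    records: Sequence[ChoiceRecord],
    sv_series: Sequence[float],
    modulated_at_response: bool = True,
) -> tuple[list[EventRegressor], list[EventRegressor]]:
    """Build per-run (unmodulated, sv-modulated) regressor pairs.

    ``sv_series`` must hold one value per responded trial, in trial order
    (the output of :func:`chosen_sv_series`). With
    ``modulated_at_response`` (the default) the modulator is a stick at
    stimulus onset + RT; otherwise it sits at stimulus onset with the RT as
    duration. SV weights are mean-centered within each run.

    Returns two lists indexed by run: unmodulated regressors and modulated
    regressors.
    """
    n_responded = sum(r.choice is not Choice.MISS for r in records)
    if n_responded != len(sv_series):
        raise ValueError(
            f"sv_series has {len(sv_series)} values for "
            f"{n_responded} responded trials"
        )
    runs = sorted({r.trial.run_index for r in records})
    sv_iter = iter(sv_series)
    per_run: dict[int, dict[str, list]] = {
        run: {"u_on": [], "u_dur": [], "m_on": [], "m_dur": [], "m_w": []}
        for run in runs
    }
    for rec in records:
        t = rec.trial
        bucket = per_run[t.run_index]
        if rec.choice is Choice.MISS:
            bucket["u_on"].append(t.onset_s)
            bucket["u_dur"].append(RESPONSE_WINDOW_S)
            continue
        sv = next(sv_iter)
        bucket["u_on"].append(t.onset_s)
        bucket["u_dur"].append(rec.rt_s)
        if modulated_at_response:
            bucket["m_on"].append(t.onset_s + rec.rt_s)
            bucket["m_dur"].append(0.0)
        else:
            bucket["m_on"].append(t.onset_s)
            bucket["m_dur"].append(rec.rt_s)
        bucket["m_w"].append(sv)

    unmodulated: list[EventRegressor] = []
    modulated: list[EventRegressor] = []
    for run in runs:
        b = per_run[run]
        unmodulated.append(
            EventRegressor(
                kind=RegressorKind.UNMODULATED,
                onsets_s=tuple(b["u_on"]),
                durations_s=tuple(b["u_dur"]),
                weights=tuple(1.0 for _ in b["u_on"]),
            )
        )
        weights = np.asarray(b["m_w"], dtype=float)
        centered = weights - weights.mean() if weights.size else weights
        modulated.append(
            EventRegressor(
                kind=RegressorKind.SV_MODULATED,
                onsets_s=tuple(b["m_on"]),
                durations_s=tuple(b["m_dur"]),
                weights=tuple(float(w) for w in centered),
            )
        )
    return unmodulated, modulated


def export_ev3(regressor: EventRegressor, path) -> None:
    """Write an FSL 3-column EV file: onset, duration, weight.

    Six-decimal fixed format, whitespace separated, one event per line.
    Refuses to write an empty regressor (FEAT rejects empty EVs).
    """
    if len(regressor) == 0:
        raise ValueError("refusing to write an empty EV file")
    lines = [
        f"{on:.6f}\t{dur:.6f}\t{w:.6f}"
        for on, dur, w in zip(
            regressor.onsets_s, regressor.durations_s, regressor.weights
        )
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
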