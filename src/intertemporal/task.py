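"""Monetary delay-discounting task: design generation, agent simulation, I/O.

The task pits a smaller-sooner (SS) reward against a larger-later (LL)
reward on every trial. The sooner delay is drawn from {today, 2 weeks,
1 month} and the later reward arrives {2 weeks, 1 month, 6 weeks} after the
sooner one (1 month = 30 days). The later amount is Gaussian (mean $15,
SD $10) truncated to [$5, $30]; the sooner amount is 1-50% smaller. A
session is 84 trials in two runs of 42, one choice screen every 12 s.

Synthetic participants are softmax agents over a discounted-value model
(:mod:`intertemporal.models`); they exist so that every downstream fitting
and regressor-building stage can be exercised, and recovery-tested, without
scanner data.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import ModelParams, choice_probability, subjective_value

__all__ = [
    "EARLY_DELAYS_DAYS",
    "DELAY_OFFSETS_DAYS",
    "TRIAL_PERIOD_S",
    "RESPONSE_WINDOW_S",
    "Choice",
    "TrialSpec",
    "ChoiceRecord",
    "AgentSpec",
    "InvalidDesignError",
    "EventsParseError",
    "generate_trials",
    "simulate_choices",
    "write_events",
    "read_events",
]

EARLY_DELAYS_DAYS = (0, 14, 30)
DELAY_OFFSETS_DAYS = (14, 30, 42)
TRIAL_PERIOD_S = 12.0
RESPONSE_WINDOW_S = 7.95

LATE_AMOUNT_MEAN = 15.0
LATE_AMOUNT_SD = 10.0
LATE_AMOUNT_MIN = 5.0
LATE_AMOUNT_MAX = 30.0
FRACTION_SMALLER_MIN = 0.01
FRACTION_SMALLER_MAX = 0.50


class InvalidDesignError(ValueError):
    """Raised when requested design parameters are inconsistent."""


class EventsParseError(ValueError):
    """Raised when an events table is malformed; names the row and column."""


class Choice(str, enum.Enum):
    SS = "SS"
    LL = "LL"
    MISS = "MISS"


@dataclass(frozen=True)
class TrialSpec:
    """One choice trial: option amounts/delays and its timing in the run."""

    trial_index: int
    run_index: int
    onset_s: float
    early_amount_usd: float
    late_amount_usd: float
    early_delay_days: int
    late_delay_days: int

    def __post_init__(self) -> None:
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")
        if not self.early_amount_usd < self.late_amount_usd:
            raise ValueError("early amount must be smaller than late amount")
        ratio = self.early_amount_usd / self.late_amount_usd
        if not (0.50 <= ratio <= 0.99):
            raise ValueError(
                f"early/late amount ratio {ratio:.4f} outside [0.50, 0.99]"
            )
        if not (LATE_AMOUNT_MIN <= self.late_amount_usd <= LATE_AMOUNT_MAX):
            raise ValueError("late amount outside [$5, $30]")
        if self.early_delay_days not in EARLY_DELAYS_DAYS:
            raise ValueError(f"early delay {self.early_delay_days} not in menu")
        if (self.late_delay_days - self.early_delay_days) not in DELAY_OFFSETS_DAYS:
            raise ValueError("late-minus-early delay offset not in menu")


@dataclass(frozen=True)
class ChoiceRecord:
    """A trial plus the simulated or observed response."""

    trial: TrialSpec
    choice: Choice
    rt_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.choice is Choice.MISS:
            if self.rt_s is not None:
                raise ValueError("MISS trials carry no reaction time")
        else:
            if self.rt_s is None:
                raise ValueError("responded trials require a reaction time")
            if not (0 < self.rt_s <= RESPONSE_WINDOW_S):
                raise ValueError(
                    f"rt_s must be in (0, {RESPONSE_WINDOW_S}], got {self.rt_s}"
                )


@dataclass(frozen=True)
class AgentSpec:
    """Ground-truth generator for one synthetic participant."""

    model_name: str
    params: ModelParams
    miss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.miss_rate < 1):
            raise ValueError("miss_rate must be in [0, 1)")
        if self.params.model_name != self.model_name:
            raise ValueError("params do not match the agent's model family")


def _round_cents(x: float) -> float:
    return round(x, 2)


def generate_trials(n_trials: int, n_runs: int, seed: int) -> list[TrialSpec]:
    """Draw a task design of ``n_trials`` split evenly over ``n_runs`` runs.

    Late amounts are sampled from Normal(15, 10) truncated to [5, 30] by
    rejection; the early amount is the late amount reduced by a
    Uniform[0.01, 0.50] fraction; both are rounded to cents (the early
    amount is nudged by at most one cent so the 1-50% reduction survives
    rounding). Delay menus are sampled uniformly and independently per
    trial. Onsets advance by 12 s within each run. Deterministic given
    ``seed``.
    """
    if n_runs < 1 or n_trials < 1:
        raise InvalidDesignError("need at least one run and one trial")
    if n_trials % n_runs != 0:
        raise InvalidDesignError(
            f"n_trials={n_trials} not divisible by n_runs={n_runs}"
        )
    rng = np.random.default_rng(seed)
    per_run = n_trials // n_runs
    trials: list[TrialSpec] = []
    for i in range(n_trials):
        late = rng.normal(LATE_AMOUNT_MEAN, LATE_AMOUNT_SD)
        while not (LATE_AMOUNT_MIN <= late <= LATE_AMOUNT_MAX):
            late = rng.normal(LATE_AMOUNT_MEAN, LATE_AMOUNT_SD)
        late = _round_cents(late)
        frac = rng.uniform(FRACTION_SMALLER_MIN, FRACTION_SMALLER_MAX)
        early = _round_cents(late * (1.0 - frac))
        # rounding may push the reduction just past 1% or 50%; pull it back
        lo = math.ceil(late * 0.50 * 100) / 100
        hi = math.floor(late * 0.99 * 100) / 100
        early = min(max(early, lo), hi)
        early_delay = int(rng.choice(EARLY_DELAYS_DAYS))
        offset = int(rng.choice(DELAY_OFFSETS_DAYS))
        trials.append(
            TrialSpec(
                trial_index=i,
                run_index=i // per_run,
                onset_s=(i % per_run) * TRIAL_PERIOD_S,
                early_amount_usd=early,
                late_amount_usd=late,
                early_delay_days=early_delay,
                late_delay_days=early_delay + offset,
            )
        )
    return trials


def _draw_rt(rng: np.random.Generator, median_s: float, sigma: float) -> float:
    """Lognormal RT truncated to (0.3, 7.95] s by rejection."""
    while True:
        rt = float(rng.lognormal(mean=math.log(median_s), sigma=sigma))
        if 0.3 < rt <= RESPONSE_WINDOW_S:
            return rt


def simulate_choices(
    trials: Sequence[TrialSpec],
    agent: AgentSpec,
    rt_median_s: float = 1.5,
    rt_sigma: float = 0.4,
) -> list[ChoiceRecord]:
    """Simulate one agent's responses on a task design.

    The smaller-sooner option is chosen with its softmax probability under
    the agent's value model (the random family is a fair coin). Misses are
    drawn independently at ``agent.miss_rate`` and carry no reaction time;
    reaction times are truncated-lognormal plumbing, never fit.
    """
    rng = np.random.default_rng(agent.seed)
    records: list[ChoiceRecord] = []
    for trial in trials:
        if agent.model_name == "random":
            p_ss = 0.5
        else:
            sv_ss = subjective_value(
                agent.params, trial.early_amount_usd, trial.early_delay_days
            )
            sv_ll = subjective_value(
                agent.params, trial.late_amount_usd, trial.late_delay_days
            )
            p_ss = float(
                choice_probability(sv_ss, sv_ll, agent.params.beta_temp)
            )
        chose_ss = rng.random() < p_ss
        missed = rng.random() < agent.miss_rate
        if missed:
            records.append(ChoiceRecord(trial=trial, choice=Choice.MISS))
        else:
            records.append(
                ChoiceRecord(
                    trial=trial,
                    choice=Choice.SS if chose_ss else Choice.LL,
                    rt_s=_draw_rt(rng, rt_median_s, rt_sigma),
                )
            )
    return records


def simulate_cohort(
    n_subjects: int,
    seed: int,
    model_name: str = "hyperbolic",
    lnk_mean: float = -4.68,
    lnk_sd: float = 1.27,
    beta_temp: float = 3.74,
    n_trials: int = 84,
    n_runs: int = 2,
    miss_rate: float = 0.0,
) -> list[tuple[str, AgentSpec, list[ChoiceRecord]]]:
    """Simulate a cohort of hyperbolic (or exponential) softmax agents.

    Each subject gets a fresh task design and a discount rate drawn as
    ``Ln(k) ~ Normal(lnk_mean, lnk_sd)`` with a shared inverse temperature;
    the defaults are the study cohort's fitted values. Returns
    ``(subject_id, agent, records)`` triples.
    """
    if model_name not in ("hyperbolic", "exponential"):
        raise ValueError(
            "cohort simulation draws a single discount rate; use "
            "'hyperbolic' or 'exponential'"
        )
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        k = float(np.exp(rng.normal(lnk_mean, lnk_sd)))
        params = ModelParams(model_name=model_name, k=k, beta_temp=beta_temp)
        design_seed = int(rng.integers(0, 2**31 - 1))
        agent_seed = int(rng.integers(0, 2**31 - 1))
        agent = AgentSpec(
            model_name=model_name,
            params=params,
            miss_rate=miss_rate,
            seed=agent_seed,
        )
        trials = generate_trials(n_trials, n_runs, seed=design_seed)
        records = simulate_choices(trials, agent)
        cohort.append((f"sub-{i + 1:02d}", agent, records))
    return cohort


_EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_index",
    "run",
    "early_amount",
    "late_amount",
    "early_delay",
    "late_delay",
    "choice",
    "response_time",
]
_NUMERIC_COLUMNS = [
    "onset", "duration", "trial_index", "run",
    "early_amount", "late_amount", "early_delay", "late_delay",
]


def write_events(records: Sequence[ChoiceRecord], path) -> None:
    """Write records as a BIDS-style tab-separated events file.

    ``onset``/``duration`` are in seconds; the duration is the reaction
    time, or the full 7.95 s response window on missed trials. Missing
    values (the reaction time of a miss) are written as ``n/a``.
    """
    rows = []
    for rec in records:
        t = rec.trial
        missed = rec.choice is Choice.MISS
        rows.append(
            {
                "onset": t.onset_s,
                "duration": RESPONSE_WINDOW_S if missed else rec.rt_s,
                "trial_index": t.trial_index,
                "run": t.run_index,
                "early_amount": t.early_amount_usd,
                "late_amount": t.late_amount_usd,
                "early_delay": t.early_delay_days,
                "late_delay": t.late_delay_days,
                "choice": rec.choice.value,
                "response_time": np.nan if missed else rec.rt_s,
            }
        )
    frame = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events(path) -> list[ChoiceRecord]:
    """Read an events file written by :func:`write_events`.

    Raises :class:`EventsParseError` naming the offending row and column on
    a missing column, a non-numeric amount, or an invariant violation such
    as a negative amount.
    """
    frame = pd.read_csv(
        Path(path), sep="\t", na_values=["n/a"],
        float_precision="round_trip",
    )
    for col in _EVENT_COLUMNS:
        if col not in frame.columns:
            raise EventsParseError(f"missing column {col!r}")
    records: list[ChoiceRecord] = []
    for i, row in frame.iterrows():
        for col in _NUMERIC_COLUMNS:
            value = row[col]
            try:
                if math.isnan(float(value)):
                    raise ValueError
            except (TypeError, ValueError):
                raise EventsParseError(
                    f"row {i}: column {col!r} is not numeric: {value!r}"
                ) from None
        try:
            trial = TrialSpec(
                trial_index=int(row["trial_index"]),
                run_index=int(row["run"]),
                onset_s=float(row["onset"]),
                early_amount_usd=float(row["early_amount"]),
                late_amount_usd=float(row["late_amount"]),
                early_delay_days=int(row["early_delay"]),
                late_delay_days=int(row["late_delay"]),
            )
            choice = Choice(str(row["choice"]))
            rt = row["response_time"]
            rt = None if (isinstance(rt, float) and math.isnan(rt)) else float(rt)
            records.append(ChoiceRecord(trial=trial, choice=choice, rt_s=rt))
        except ValueError as exc:
            raise EventsParseError(f"row {i}: {exc}") from exc
    return records
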