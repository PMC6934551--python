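"""Candidate choice models for intertemporal decisions.

Five discounted-subjective-value functions plus a random-choice baseline,
together with the softmax decision rule that maps subjective values to
choice probabilities.

Every value function maps a monetary amount ``A`` (USD) and a delay ``D``
(days) to a subjective value. The discount-rate parameter ``k`` is in units
of 1/day, so ``k * D`` is dimensionless. Choice stochasticity is governed by
a softmax inverse temperature ``beta_temp`` (0 = coin flip, large = strict
value maximisation). The inverse temperature is named ``beta_temp`` and the
beta-delta model's immediate-discount rate ``beta_dd`` to keep the two
conventional uses of the symbol beta apart.

Two of the functional forms are implemented in their published two-parameter
shapes even where those shapes have surprising limits:

* ``sv_beta_delta`` is the two-exponential sum ``A * (exp(-beta_dd*D) +
  exp(-delta*D))``, which equals ``2A`` at zero delay rather than ``A``.
* ``sv_discounted_utility`` is ``exp(-r*A) / (r * (1 + k*D))``, which is
  decreasing in the amount.

Both are deliberate: the model comparison is between these exact forms, and
a silent "correction" would change every downstream likelihood. See
``docs/methods.md`` for discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "MODEL_FAMILIES",
    "N_FREE_PARAMS",
    "ModelParams",
    "SVPair",
    "sv_hyperbolic",
    "sv_exponential",
    "sv_beta_delta",
    "sv_discounted_utility",
    "sv_quasi_hyperbolic_s",
    "subjective_value",
    "sv_pair",
    "choice_probability",
    "ln_k",
]

#: value-function parameters belonging to each model family (softmax
#: ``beta_temp`` is additionally required by every family except random).
MODEL_FAMILIES: dict[str, tuple[str, ...]] = {
    "hyperbolic": ("k",),
    "exponential": ("k",),
    "beta_delta": ("beta_dd", "delta"),
    "discounted_utility": ("r", "k"),
    "quasi_hyperbolic_s": ("k", "s"),
    "random": (),
}

#: free parameters counted in the BIC complexity penalty (value-function
#: parameters plus one softmax inverse temperature; random has none).
N_FREE_PARAMS: dict[str, int] = {
    name: (len(fields) + 1 if name != "random" else 0)
    for name, fields in MODEL_FAMILIES.items()
}

# parameters that must be strictly positive vs merely non-negative
_STRICTLY_POSITIVE = {"k", "r", "s"}
_NON_NEGATIVE = {"beta_dd", "delta", "beta_temp"}


class UnsupportedModelError(ValueError):
    """Raised for a model family name outside :data:`MODEL_FAMILIES`."""


@dataclass(frozen=True)
class ModelParams:
    """Named parameters for one model family.

    Only the fields belonging to ``model_name`` may be set; the softmax
    inverse temperature ``beta_temp`` is required for every family except
    ``random``, which has no parameters at all.
    """

    model_name: str
    k: Optional[float] = None
    beta_dd: Optional[float] = None
    delta: Optional[float] = None
    r: Optional[float] = None
    s: Optional[float] = None
    beta_temp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_FAMILIES:
            raise UnsupportedModelError(
                f"unknown model family {self.model_name!r}; "
                f"expected one of {sorted(MODEL_FAMILIES)}"
            )
        allowed = set(MODEL_FAMILIES[self.model_name])
        if self.model_name != "random":
            allowed.add("beta_temp")
        for name in ("k", "beta_dd", "delta", "r", "s", "beta_temp"):
            value = getattr(self, name)
            if name in allowed:
                if value is None:
                    raise ValueError(
                        f"{self.model_name} requires parameter {name!r}"
                    )
                if name in _STRICTLY_POSITIVE and not value > 0:
                    raise ValueError(f"{name} must be > 0, got {value}")
                if name in _NON_NEGATIVE and not value >= 0:
                    raise ValueError(f"{name} must be >= 0, got {value}")
                if not np.isfinite(value):
                    raise ValueError(f"{name} must be finite, got {value}")
            elif value is not None:
                raise ValueError(
                    f"parameter {name!r} does not belong to model "
                    f"{self.model_name!r}"
                )

    def free_values(self) -> dict[str, float]:
        """Value-function parameters plus ``beta_temp`` as a dict."""
        out = {n: getattr(self, n) for n in MODEL_FAMILIES[self.model_name]}
        if self.model_name != "random":
            out["beta_temp"] = self.beta_temp
        return out

    def with_values(self, **updates: float) -> "ModelParams":
        return replace(self, **updates)


@dataclass(frozen=True)
class SVPair:
    """Subjective values of the two options on one trial."""

    sv_ss: float
    sv_ll: float


def _check_amount_delay(A, D) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(A < 0):
        raise ValueError("amount A must be >= 0")
    if np.any(D < 0):
        raise ValueError("delay D must be >= 0")
    return A, D


def sv_hyperbolic(A, k: float, D):
    """Hyperbolic discounting, ``SV = A / (1 + k*D)``."""
    A, D = _check_amount_delay(A, D)
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    return A / (1.0 + k * D)


def sv_exponential(A, k: float, D):
    """Exponential discounting, ``SV = A * exp(-k*D)``."""
    A, D = _check_amount_delay(A, D)
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    return A * np.exp(-k * D)


def sv_beta_delta(A, beta_dd: float, delta: float, D):
    """Double-exponential beta-delta, ``SV = A * (exp(-beta_dd*D) + exp(-delta*D))``.

    Note the sum of the two exponentials is used as-is, so ``SV(D=0) = 2A``.
    """
    A, D = _check_amount_delay(A, D)
    if beta_dd < 0 or delta < 0:
        raise ValueError("beta_dd and delta must be >= 0")
    return A * (np.exp(-beta_dd * D) + np.exp(-delta * D))


def sv_discounted_utility(A, r: float, k: float, D):
    """Discounted utility with concave amount weighting, ``SV = exp(-r*A) / (r*(1+k*D))``.

    ``r`` is a concavity/risk-aversion weight. The numerator is the bare
    ``exp(-r*A)``, making SV decreasing in the amount; this is the form the
    model comparison uses.
    """
    A, D = _check_amount_delay(A, D)
    if not r > 0:
        raise ValueError(f"r must be > 0, got {r}")
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    return np.exp(-r * A) / (r * (1.0 + k * D))


def sv_quasi_hyperbolic_s(A, k: float, s: float, D):
    """Hyperbolic discounting with exponentiated delay, ``SV = A / (1 + k*D**s)``.

    Reduces to plain hyperbolic at ``s = 1``.
    """
    A, D = _check_amount_delay(A, D)
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    if not s > 0:
        raise ValueError(f"s must be > 0, got {s}")
    # k * D**s may overflow for extreme search points; the limit SV -> 0 is
    # exactly what the division then returns
    with np.errstate(over="ignore"):
        return A / (1.0 + k * np.power(D, s))


def subjective_value(params: ModelParams, A, D):
    """Evaluate ``params``' value function at amount ``A`` and delay ``D``.

    Vectorised over ``A`` and ``D``. Not defined for the random model,
    which assigns no values to options.
    """
    name = params.model_name
    if name == "hyperbolic":
        return sv_hyperbolic(A, params.k, D)
    if name == "exponential":
        return sv_exponential(A, params.k, D)
    if name == "beta_delta":
        return sv_beta_delta(A, params.beta_dd, params.delta, D)
    if name == "discounted_utility":
        return sv_discounted_utility(A, params.r, params.k, D)
    if name == "quasi_hyperbolic_s":
        return sv_quasi_hyperbolic_s(A, params.k, params.s, D)
    raise UnsupportedModelError(
        f"model {name!r} has no subjective-value function"
    )


def sv_pair(params: ModelParams, early_amount, early_delay,
            late_amount, late_delay) -> SVPair:
    """Subjective values of the smaller-sooner and larger-later options."""
    return SVPair(
        sv_ss=float(subjective_value(params, early_amount, early_delay)),
        sv_ll=float(subjective_value(params, late_amount, late_delay)),
    )


def choice_probability(sv_chosen, sv_other, beta_temp: float):
    """Softmax probability of the option valued ``sv_chosen``.

    ``p = exp(b*sv_a) / (exp(b*sv_a) + exp(b*sv_b))``, evaluated through the
    logistic function of ``b * (sv_a - sv_b)`` so no exponential can
    overflow. The result is clipped into ``[1e-12, 1 - 1e-12]`` so its log
    is always finite.
    """
    if beta_temp < 0:
        raise ValueError(f"beta_temp must be >= 0, got {beta_temp}")
    sv_chosen = np.asarray(sv_chosen, dtype=float)
    sv_other = np.asarray(sv_other, dtype=float)
    if not (np.all(np.isfinite(sv_chosen)) and np.all(np.isfinite(sv_other))):
        raise ValueError("subjective values must be finite")
    p = expit(beta_temp * (sv_chosen - sv_other))
    return np.clip(p, 1e-12, 1.0 - 1e-12)


def ln_k(k: float) -> float:
    """Natural log of the discount rate (the scale used for correlations,
    since raw ``k`` is heavily right-skewed)."""
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    return float(np.log(k))
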