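"""Group-level associations between receptor availability and value signals.

The analysis stage relates per-subject scalars — PET dopamine-D2-like
receptor binding potential (BP_ND) in ventral striatum, midbrain and vmPFC;
fMRI subjective-value parameter estimates in those regions plus posterior
cingulate; and discounting behavior (Ln(k), proportion sooner) — through
simple standardized regressions.

Conventions:

* both variables are z-scored, so the standardized coefficient of a simple
  regression is exactly the Pearson correlation;
* 95% confidence intervals come from the Fisher z-transform,
  ``tanh(atanh(r) +/- z* / sqrt(n - 3))``, which produces the familiar
  asymmetric intervals;
* the PET-by-fMRI grid (3 x 4 = 12 tests) is Bonferroni-corrected;
* influence triage per regression combines Cook's distance (> 4x the mean),
  a two-sided test of the externally studentized residual, and a
  Breusch-Pagan heteroskedasticity check; a point is called influential
  only when both per-point criteria fire. Flagged points are reported,
  never silently dropped — exclusion is an explicit re-run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "PET_ROIS",
    "FMRI_ROIS",
    "BEHAVIOR_COLS",
    "OutlierPoint",
    "OutlierDiagnostics",
    "AssociationResult",
    "fisher_ci",
    "bonferroni_alpha",
    "standardized_regression",
    "outlier_diagnostics",
    "adjusted_regression",
    "run_association_grid",
    "simulate_subject_table",
]

PET_ROIS = ("vs", "midbrain", "vmpfc")
FMRI_ROIS = ("vs", "midbrain", "vmpfc", "pcc")
BEHAVIOR_COLS = ("ln_k", "prop_sooner")


class DegenerateInputError(ValueError):
    """Raised for zero-variance or rank-deficient regression inputs."""


@dataclass(frozen=True)
class OutlierPoint:
    subject_id: str
    cooks_d: float
    cooks_flag: bool
    studentized: float
    studentized_p: float
    influential: bool


@dataclass(frozen=True)
class OutlierDiagnostics:
    points: tuple[OutlierPoint, ...]
    het_p: float

    @property
    def influential_ids(self) -> tuple[str, ...]:
        return tuple(p.subject_id for p in self.points if p.influential)


@dataclass(frozen=True)
class AssociationResult:
    predictor: str
    outcome: str
    n: int
    std_beta: float
    ci_low: float
    ci_high: float
    p: float
    alpha_bonferroni: float
    significant: bool
    diagnostics: Optional[OutlierDiagnostics] = None


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a correlation via the Fisher z-transform."""
    if not abs(r) < 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test threshold controlling the family-wise error over ``m`` tests."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def _as_clean_array(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite values")
    return arr


def _zscore(arr: np.ndarray, name: str) -> np.ndarray:
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError(f"{name} has zero variance")
    return (arr - arr.mean()) / sd


def standardized_regression(
    x,
    y,
    predictor: str = "x",
    outcome: str = "y",
    alpha: float = 0.05,
    m_tests: int = 1,
    subject_ids: Optional[Sequence[str]] = None,
    with_diagnostics: bool = True,
) -> AssociationResult:
    """Simple regression of z-scored ``y`` on z-scored ``x``.

    The standardized slope equals the Pearson correlation; the two-sided p
    comes from the t distribution with n - 2 df and the 95% CI from the
    Fisher z-transform. ``m_tests`` sets the Bonferroni family used for the
    significance flag.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = int(x.size)
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    xz, yz = _zscore(x, "x"), _zscore(y, "y")
    r = float(np.dot(xz, yz) / (n - 1))
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        p = 0.0
        ci = (r, r)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        ci = fisher_ci(r, n)
    threshold = bonferroni_alpha(alpha, m_tests)
    diagnostics = None
    if with_diagnostics and n >= 5 and abs(r) < 1.0:
        diagnostics = outlier_diagnostics(x, y, subject_ids=subject_ids)
    return AssociationResult(
        predictor=predictor,
        outcome=outcome,
        n=n,
        std_beta=r,
        ci_low=ci[0],
        ci_high=ci[1],
        p=p,
        alpha_bonferroni=threshold,
        significant=p < threshold,
        diagnostics=diagnostics,
    )


def outlier_diagnostics(
    x, y, subject_ids: Optional[Sequence[str]] = None
) -> OutlierDiagnostics:
    """Per-point influence triage for a simple regression of y on x.

    Cook's distance is flagged above 4x its mean; the externally
    studentized residual is tested two-sided against t with n - 3 df at
    0.05; Breusch-Pagan supplies a model-level heteroskedasticity p. A
    point is influential when the Cook's flag and the studentized-residual
    test agree.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    n = int(x.size)
    if n < 5:
        raise ValueError(f"need n >= 5 for influence diagnostics, got {n}")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise DegenerateInputError("zero variance input")
    ids = (
        [str(s) for s in subject_ids]
        if subject_ids is not None
        else [f"sub-{i:02d}" for i in range(n)]
    )
    if len(ids) != n:
        raise ValueError("subject_ids length mismatch")
    exog = sm.add_constant(x)
    fit = sm.OLS(y, exog).fit()
    influence = OLSInfluence(fit)
    cooks = influence.cooks_distance[0]
    cook_threshold = 4.0 * float(np.mean(cooks))
    studentized = influence.resid_studentized_external
    stud_p = 2.0 * stats.t.sf(np.abs(studentized), df=n - 3)
    _, het_p, _, _ = het_breuschpagan(fit.resid, exog)
    points = tuple(
        OutlierPoint(
            subject_id=ids[i],
            cooks_d=float(cooks[i]),
            cooks_flag=bool(cooks[i] > cook_threshold),
            studentized=float(studentized[i]),
            studentized_p=float(stud_p[i]),
            influential=bool(cooks[i] > cook_threshold and stud_p[i] < 0.05),
        )
        for i in range(n)
    )
    return OutlierDiagnostics(points=points, het_p=float(het_p))


def adjusted_regression(
    x,
    y,
    covariates: pd.DataFrame,
    predictor: str = "x",
    outcome: str = "y",
    alpha: float = 0.05,
    m_tests: int = 1,
) -> AssociationResult:
    """Standardized partial coefficient of ``x`` controlling for covariates.

    Continuous variables (x, y, and any non-binary covariate such as age)
    are z-scored; binary covariates such as sex enter as 0/1 indicators.
    The CI and p are Wald/t-based since the partial coefficient is no
    longer a plain correlation.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    n = int(x.size)
    if len(covariates) != n or x.size != y.size:
        raise ValueError("x, y and covariates must align")
    if n <= covariates.shape[1] + 2:
        raise ValueError("too few observations for the requested model")
    cols = [_zscore(x, "x")]
    names = [predictor]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            if len(levels) > 2:
                raise ValueError(
                    f"covariate {name!r} has more than two levels"
                )
            arr = (col.astype(str) == levels[-1]).to_numpy(dtype=float)
        else:
            arr = _as_clean_array(col.to_numpy(dtype=float), name)
            if set(np.unique(arr)) - {0.0, 1.0}:
                arr = _zscore(arr, name)
        cols.append(arr)
        names.append(name)
    design = np.column_stack(cols)
    exog = sm.add_constant(design)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise DegenerateInputError("rank-deficient design matrix")
    fit = sm.OLS(_zscore(y, "y"), exog).fit()
    beta = float(fit.params[1])
    ci = fit.conf_int(alpha=alpha)
    threshold = bonferroni_alpha(alpha, m_tests)
    p = float(fit.pvalues[1])
    return AssociationResult(
        predictor=predictor,
        outcome=outcome,
        n=n,
        std_beta=beta,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p=p,
        alpha_bonferroni=threshold,
        significant=p < threshold,
        diagnostics=None,
    )


def run_association_grid(
    rows: pd.DataFrame,
    pet_rois: Sequence[str] = PET_ROIS,
    fmri_rois: Sequence[str] = FMRI_ROIS,
    behavior_cols: Sequence[str] = BEHAVIOR_COLS,
    alpha: float = 0.05,
    correct_behavior: bool = False,
) -> list[AssociationResult]:
    """All pairwise standardized regressions of the analysis stage.

    One result per PET x fMRI ROI pair, Bonferroni-corrected as one family
    (3 x 4 = 12 tests at the defaults); PET-by-behavior and
    fMRI-by-behavior regressions are appended, by default uncorrected
    (``m_tests = 1``) but with the family size applied when
    ``correct_behavior`` is set.

    PET columns are ``bp_<roi>``; fMRI columns are ``sv_<roi>``.
    """
    pet_cols = [f"bp_{r}" for r in pet_rois]
    fmri_cols = [f"sv_{r}" for r in fmri_rois]
    needed = pet_cols + fmri_cols + list(behavior_cols) + ["subject_id"]
    missing = [c for c in needed if c not in rows.columns]
    if missing:
        raise KeyError(f"subject table is missing columns: {missing}")
    if rows["subject_id"].duplicated().any():
        raise ValueError("duplicated subject_id in subject table")
    ids = rows["subject_id"].tolist()
    results: list[AssociationResult] = []
    m_grid = len(pet_cols) * len(fmri_cols)
    for pet in pet_cols:
        for fmri in fmri_cols:
            results.append(
                standardized_regression(
                    rows[pet], rows[fmri],
                    predictor=pet, outcome=fmri,
                    alpha=alpha, m_tests=m_grid, subject_ids=ids,
                )
            )
    m_behavior_pet = len(pet_cols) * len(behavior_cols)
    m_behavior_fmri = len(fmri_cols) * len(behavior_cols)
    for cols, m_family in ((pet_cols, m_behavior_pet),
                           (fmri_cols, m_behavior_fmri)):
        for col in cols:
            for beh in behavior_cols:
                results.append(
                    standardized_regression(
                        rows[col], rows[beh],
                        predictor=col, outcome=beh,
                        alpha=alpha,
                        m_tests=m_family if correct_behavior else 1,
                        subject_ids=ids,
                    )
                )
    return results


# -- synthetic subject tables ------------------------------------------------

#: per-column (mean, SD) of the synthetic cohort's scalar measures; binding
#: potentials and behavior match the study cohort's descriptives, fMRI
#: percent-signal-change effects are centered near zero with spread typical
#: of ROI-mean parametric-modulation estimates.
COHORT_SCALARS: dict[str, tuple[float, float]] = {
    "bp_vs": (17.3, 2.90),
    "bp_midbrain": (1.50, 0.236),
    "bp_vmpfc": (0.762, 0.139),
    "sv_vs": (0.05, 0.15),
    "sv_midbrain": (0.05, 0.15),
    "sv_vmpfc": (0.10, 0.20),
    "sv_pcc": (0.10, 0.20),
    "ln_k": (-4.68, 1.27),
    "prop_sooner": (0.550, 0.212),
    "age": (20.9, 1.95),
}


def simulate_subject_table(
    n_subjects: int,
    seed: int,
    planted: Optional[Mapping[tuple[str, str], float]] = None,
) -> pd.DataFrame:
    """Synthetic per-subject scalar table for the association stage.

    Columns are drawn independently from Gaussians at the cohort means and
    SDs in :data:`COHORT_SCALARS` (binding potentials truncated positive,
    proportions clipped to [0, 1]), plus a balanced binary sex column.
    ``planted`` maps column pairs to target correlations: the second column
    is rebuilt as ``r * z(first) + sqrt(1 - r^2) * noise`` on its original
    scale, so the planted population correlation is exact.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for col, (mean, sd) in COHORT_SCALARS.items():
        draws = rng.normal(mean, sd, size=n_subjects)
        if col.startswith("bp_"):
            while np.any(draws <= 0):
                bad = draws <= 0
                draws[bad] = rng.normal(mean, sd, size=bad.sum())
        if col == "prop_sooner":
            draws = np.clip(draws, 0.0, 1.0)
        data[col] = draws
    for (first, second), r in (planted or {}).items():
        if not (-1 < r < 1):
            raise ValueError(f"planted correlation must be in (-1, 1), got {r}")
        mean, sd = COHORT_SCALARS[second]
        z1 = (data[first] - data[first].mean()) / data[first].std(ddof=1)
        noise = rng.normal(size=n_subjects)
        noise = (noise - noise.mean()) / noise.std(ddof=1)
        # residualize the noise against z1 so the sample correlation is exact
        noise = noise - z1 * float(np.dot(noise, z1) / np.dot(z1, z1))
        noise = noise / noise.std(ddof=1)
        data[second] = mean + sd * (r * z1 + np.sqrt(1 - r * r) * noise)
    table = pd.DataFrame(data)
    table.insert(0, "subject_id",
                 [f"sub-{i + 1:02d}" for i in range(n_subjects)])
    sexes = np.array(["F", "M"])[np.arange(n_subjects) % 2]
    table["sex"] = rng.permutation(sexes)
    return table
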