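"""Estimating condition-specific health decrements and the implied multipliers.

Patients surviving a severe acute illness (the motivating case is
meningitis) can be left with lasting after-effects — behavioral problems,
learning disability, amputations — each of which depresses not only the
patient's own health-status index but, through caring strain and worry, the
index of linked family carers. Two ordinary least squares models, one per
role, regress the utility index on non-exclusive condition indicators while
adjusting for age, sex and years since illness onset. The coefficient on a
condition indicator is its marginal utility decrement for that role.

A condition's patient and carer decrements convert to an intervention
multiplier under additivity across network members:

    m = (|patient decrement| + n·|carer decrement|) / |patient decrement|

for ``n`` affected members — the ratio of total annual health benefit from
treating or preventing the condition to the patient-only benefit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import check_finite, round_half_away
from .errors import SingularDesignError, UndefinedMultiplierError

__all__ = [
    "ConditionEffectEstimate",
    "estimate_decrements",
    "multipliers_from_decrements",
    "rank_conditions",
    "COHORT_COLUMNS",
    "CONDITION_PREFIX",
]

#: Required columns of a cohort table, ahead of any ``cond_*`` indicators.
COHORT_COLUMNS = (
    "person_id",
    "dyad_id",
    "role",
    "utility",
    "age",
    "sex",
    "years_since_onset",
)

CONDITION_PREFIX = "cond_"

DEFAULT_COVARIATES = ("age", "sex", "years_since_onset")


@dataclass(frozen=True)
class ConditionEffectEstimate:
    """Estimated marginal utility impact of one condition for one role."""

    condition: str
    role: str
    decrement: float
    se: float
    n_obs: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "decrement", check_finite("decrement", self.decrement))
        se = check_finite("se", self.se)
        if se < 0:
            raise ValueError("standard error must be non-negative")
        object.__setattr__(self, "se", se)


def _condition_columns(records: pd.DataFrame, conditions: Sequence[str] | None) -> list[str]:
    if conditions is None:
        cols = [c for c in records.columns if c.startswith(CONDITION_PREFIX)]
        if not cols:
            raise ValueError(f"no '{CONDITION_PREFIX}*' condition columns found")
        return cols
    cols = []
    for cond in conditions:
        col = cond if cond in records.columns else CONDITION_PREFIX + cond
        if col not in records.columns:
            raise KeyError(f"condition column {cond!r} not in records")
        cols.append(col)
    return cols


def _encode_sex(series: pd.Series) -> np.ndarray:
    """Map a sex column to a numeric indicator (alphabetically first level = 0)."""
    if pd.api.types.is_numeric_dtype(series):
        return series.to_numpy(dtype=float)
    levels = sorted(series.dropna().unique())
    if len(levels) > 2:
        raise ValueError(f"sex column has {len(levels)} levels; expected at most 2")
    mapping = {lev: float(i) for i, lev in enumerate(levels)}
    return series.map(mapping).to_numpy(dtype=float)


def _check_full_rank(design: pd.DataFrame) -> None:
    """Raise SingularDesignError naming the columns that add no rank."""
    mat = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) == mat.shape[1]:
        return
    offenders = []
    kept = np.ones((len(design), 1))
    for name in design.columns:
        candidate = np.column_stack([kept, design[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(candidate) > kept.shape[1]:
            kept = candidate
        else:
            offenders.append(name)
    raise SingularDesignError(
        "design matrix is rank deficient; collinear or constant columns: "
        + ", ".join(offenders),
        columns=tuple(offenders),
    )


def estimate_decrements(
    records: pd.DataFrame,
    role: str,
    conditions: Sequence[str] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> list[ConditionEffectEstimate]:
    """Fit one OLS model for ``role`` and return per-condition utility decrements.

    The utility index is regressed on all condition indicators jointly plus
    the adjustment covariates (by default age, sex and years since onset);
    each condition coefficient is therefore its marginal impact holding the
    other conditions and the covariates fixed. Pass ``covariates=()`` for an
    unadjusted model.

    Raises
    ------
    SingularDesignError
        If the design matrix is rank deficient; the error names the
        collinear columns.
    ValueError
        If fewer than (number of parameters + 2) records carry the role.
    """
    subset = records[records["role"] == role]
    if subset.empty:
        raise ValueError(f"no records with role {role!r}")
    cond_cols = _condition_columns(records, conditions)

    design = pd.DataFrame(index=subset.index)
    for col in cond_cols:
        design[col] = pd.to_numeric(subset[col])
    for cov in covariates:
        if cov == "sex":
            design[cov] = _encode_sex(subset[cov])
        else:
            design[cov] = pd.to_numeric(subset[cov])

    n_params = design.shape[1] + 1  # + intercept
    if len(subset) < n_params + 2:
        raise ValueError(
            f"need at least {n_params + 2} records for {n_params} parameters, "
            f"got {len(subset)}"
        )
    _check_full_rank(design)

    y = pd.to_numeric(subset["utility"]).to_numpy(dtype=float)
    X = sm.add_constant(design.to_numpy(dtype=float))
    fit = sm.OLS(y, X).fit()

    estimates = []
    for i, col in enumerate(cond_cols, start=1):
        name = col[len(CONDITION_PREFIX):] if col.startswith(CONDITION_PREFIX) else col
        estimates.append(
            ConditionEffectEstimate(
                condition=name,
                role=role,
                decrement=float(fit.params[i]),
                se=float(fit.bse[i]),
                n_obs=int(fit.nobs),
            )
        )
    return estimates


def multipliers_from_decrements(
    patient_dec: float,
    carer_dec: float,
    n_members: int,
    precision: int | None = None,
) -> float:
    """Intervention multiplier from a condition's patient and carer decrements.

    Computes ``(|patient| + n·|carer|) / |patient|`` = ``1 + n·r`` with the
    per-member spillover ratio ``r = |carer|/|patient|``. With ``precision``
    set, ``r`` is rounded to that many decimals before the multiplier is
    formed and the result rounded likewise — the reporting policy that keeps
    published multiplier tables internally additive (the n-member entry is
    exactly 1 + n·(single-member entry − 1)). Leave ``precision`` as None
    for raw double precision.
    """
    patient_dec = check_finite("patient_dec", patient_dec)
    carer_dec = check_finite("carer_dec", carer_dec)
    if n_members < 0:
        raise ValueError("n_members must be non-negative")
    if patient_dec == 0:
        raise UndefinedMultiplierError(
            "multiplier undefined for a zero patient decrement"
        )
    ratio = abs(carer_dec) / abs(patient_dec)
    if precision is not None:
        ratio = round_half_away(ratio, precision)
    m = 1.0 + n_members * ratio
    if precision is not None:
        m = round_half_away(m, precision)
    return m


def rank_conditions(
    estimates: Iterable[ConditionEffectEstimate] | Mapping[str, float],
    role: str | None = None,
) -> list[str]:
    """Conditions ordered by decreasing magnitude of decrement.

    Accepts estimates (optionally filtered to ``role``) or a plain mapping
    of condition name to decrement. Patient and carer orderings can differ:
    a condition that dominates patient health loss may impose only a small
    carer burden, and vice versa. Ties break alphabetically.
    """
    if isinstance(estimates, Mapping):
        items = list(estimates.items())
    else:
        items = [
            (e.condition, e.decrement)
            for e in estimates
            if role is None or e.role == role
        ]
    if not items:
        raise ValueError("no estimates to rank")
    return [name for name, dec in sorted(items, key=lambda kv: (-abs(kv[1]), kv[0]))]
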