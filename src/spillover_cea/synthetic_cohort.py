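"""Synthetic patient–carer cohorts with known spillover structure.

No individual-level meningitis after-effects dataset is publicly deposited,
so every estimation stage here is exercised on cohorts generated with a
known data-generating process that mirrors the study design: dyads of one
patient and a fixed number of carers, non-exclusive condition indicators
drawn per dyad, carers inheriting the patient's condition flags as
exposures, and a linear utility model

    utility = intercept(role) + Σ_c flag_c · decrement_c(role)
              + β_age·age + β_sex·female + β_years·years_since_onset
              + N(0, σ²)

Because the generator's truth is known, ordinary least squares recovery of
the decrements can be checked exactly (zero noise) and statistically
(Monte-Carlo coverage).

Randomness uses one spawned substream per dyad, so enlarging a cohort
leaves all earlier dyads bit-identical and the same seed always reproduces
the same table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import check_finite
from .portfolio import CarePackage, ScenarioSpec
from .spillover_estimation import CONDITION_PREFIX, multipliers_from_decrements

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_intervention_table",
    "MENINGITIS_DECREMENTS",
    "reference_cohort_spec",
    "reference_care_packages",
    "reference_scenario",
    "REFERENCE_PATIENT_BENEFITS",
    "REFERENCE_PACKAGE_COST",
]

#: Mean utility decrements (patient, carer) per after-effect on the
#: EQ-5D-5L index scale, from the meningitis family-impact regressions.
MENINGITIS_DECREMENTS: dict[str, tuple[float, float]] = {
    "behavioral_problems": (-0.109, -0.030),
    "learning_disability": (-0.041, -0.023),
    "amputation": (-0.226, -0.005),
}

#: After-effect prevalences for the generator. Not estimated quantities:
#: chosen to give each indicator enough positive cases for stable OLS at
#: moderate cohort sizes while keeping most dyads unaffected.
DEFAULT_PREVALENCES: dict[str, float] = {
    "behavioral_problems": 0.25,
    "learning_disability": 0.20,
    "amputation": 0.05,
}

#: Covariate sampling ranges: patients skew young (meningitis is largely a
#: childhood disease), carers are working-age adults; onset 1–25 years ago.
PATIENT_AGE_RANGE = (1.0, 40.0)
CARER_AGE_RANGE = (25.0, 60.0)
YEARS_SINCE_ONSET_RANGE = (1.0, 25.0)

#: Stylized funding menu: per-condition patient benefits (health units) of
#: a relatively more (A) and less (B) cost-effective package.
REFERENCE_PATIENT_BENEFITS: dict[str, dict[str, float]] = {
    "behavioral_problems": {"A": 120.0, "B": 80.0},
    "learning_disability": {"A": 80.0, "B": 70.0},
    "amputation": {"A": 120.0, "B": 110.0},
}
REFERENCE_PACKAGE_COST = 2_000_000.0
REFERENCE_DISPLACED_PATIENT_UNITS = 100.0
REFERENCE_DISPLACED_MEMBER_UNITS = 16.0


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Decrements are negative utility shifts per condition; ``sex_effect``
    applies to the female indicator. ``cap_at_one`` clips utilities at 1
    (off by default: censoring would bias the OLS recovery checks, and the
    default intercepts keep the linear predictor below 1 anyway).
    """

    n_dyads: int
    seed: int
    carers_per_patient: int = 1
    prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    patient_decrements: Mapping[str, float] = field(
        default_factory=lambda: {c: p for c, (p, _) in MENINGITIS_DECREMENTS.items()}
    )
    carer_decrements: Mapping[str, float] = field(
        default_factory=lambda: {c: k for c, (_, k) in MENINGITIS_DECREMENTS.items()}
    )
    patient_intercept: float = 0.90
    carer_intercept: float = 0.92
    age_effect: float = -0.002
    sex_effect: float = -0.010
    years_effect: float = 0.001
    noise_sd: float = 0.1
    cap_at_one: bool = False

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError(f"n_dyads must be >= 1, got {self.n_dyads}")
        if self.carers_per_patient < 0:
            raise ValueError("carers_per_patient must be non-negative")
        if check_finite("noise_sd", self.noise_sd) < 0:
            raise ValueError("noise_sd must be non-negative")
        for cond, prev in self.prevalences.items():
            if not 0.0 <= prev <= 1.0:
                raise ValueError(f"prevalence for {cond!r} must lie in [0, 1], got {prev}")
            if cond not in self.patient_decrements or cond not in self.carer_decrements:
                raise ValueError(f"missing decrement for condition {cond!r}")

    @property
    def conditions(self) -> tuple[str, ...]:
        """Condition names in deterministic (sorted) draw order."""
        return tuple(sorted(self.prevalences))


def _linear_predictor(
    spec: CohortSpec,
    decrements: Mapping[str, float],
    intercept: float,
    flags: Mapping[str, int],
    age: float,
    female: int,
    years: float,
) -> float:
    return (
        intercept
        + sum(flags[c] * decrements[c] for c in spec.conditions)
        + spec.age_effect * age
        + spec.sex_effect * female
        + spec.years_effect * years
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort as a tidy table, one row per person.

    Columns: ``person_id, dyad_id, role, utility, age, sex,
    years_since_onset`` plus one ``cond_*`` indicator per condition. Carers
    carry their linked patient's condition flags and onset time, with their
    own age and sex. Each dyad consumes exactly one spawned RNG substream.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_dyads)
    conds = spec.conditions
    rows: list[dict] = []

    for d, child in enumerate(children):
        rng = np.random.default_rng(child)
        flags = {c: int(rng.random() < spec.prevalences[c]) for c in conds}
        years = rng.uniform(*YEARS_SINCE_ONSET_RANGE)

        age = rng.uniform(*PATIENT_AGE_RANGE)
        female = int(rng.random() < 0.5)
        utility = _linear_predictor(
            spec, spec.patient_decrements, spec.patient_intercept, flags, age, female, years
        ) + rng.normal(0.0, spec.noise_sd)
        rows.append(
            _row(f"d{d:05d}p", d, "patient", utility, age, female, years, flags, spec)
        )

        for j in range(spec.carers_per_patient):
            age = rng.uniform(*CARER_AGE_RANGE)
            female = int(rng.random() < 0.5)
            utility = _linear_predictor(
                spec, spec.carer_decrements, spec.carer_intercept, flags, age, female, years
            ) + rng.normal(0.0, spec.noise_sd)
            rows.append(
                _row(f"d{d:05d}c{j}", d, "carer", utility, age, female, years, flags, spec)
            )

    return pd.DataFrame(rows)


def _row(
    person_id: str,
    dyad: int,
    role: str,
    utility: float,
    age: float,
    female: int,
    years: float,
    flags: Mapping[str, int],
    spec: CohortSpec,
) -> dict:
    if spec.cap_at_one:
        utility = min(utility, 1.0)
    row = {
        "person_id": person_id,
        "dyad_id": dyad,
        "role": role,
        "utility": utility,
        "age": age,
        "sex": "F" if female else "M",
        "years_since_onset": years,
    }
    for c in spec.conditions:
        row[CONDITION_PREFIX + c] = flags[c]
    return row


def generate_intervention_table(
    spec: CohortSpec,
    patient_benefits: Mapping[str, Mapping[str, float]],
    cost: float,
    n_members: Sequence[int] = (1, 2),
    precision: int | None = 2,
) -> list[CarePackage]:
    """Build a funding menu whose multipliers follow the spec's true decrements.

    ``patient_benefits`` maps condition -> arm -> health units; every
    package gets the same ``cost``. Multipliers at each network size in
    ``n_members`` come from :func:`multipliers_from_decrements` at the
    given reporting precision.
    """
    packages = []
    for condition, arms in patient_benefits.items():
        p_dec = spec.patient_decrements[condition]
        c_dec = spec.carer_decrements[condition]
        mults = {
            n: multipliers_from_decrements(p_dec, c_dec, n, precision) for n in n_members
        }
        for arm, benefit in arms.items():
            packages.append(
                CarePackage(
                    condition=condition,
                    arm=arm,
                    cost=cost,
                    patient_benefit=benefit,
                    multipliers=mults,
                )
            )
    return packages


# ---------------------------------------------------------------------------
# Reference parameterization (the published worked example)
# ---------------------------------------------------------------------------


def reference_cohort_spec(n_dyads: int = 2000, seed: int = 1, **overrides) -> CohortSpec:
    """Cohort spec carrying the published after-effect decrements."""
    return CohortSpec(n_dyads=n_dyads, seed=seed, **overrides)


def reference_care_packages() -> list[CarePackage]:
    """The six-package menu of the worked funding example.

    Equal costs of £2 million, the published patient benefits, and
    2-decimal multipliers derived from the after-effect decrements.
    """
    spec = reference_cohort_spec(n_dyads=1, seed=0)
    return generate_intervention_table(
        spec, REFERENCE_PATIENT_BENEFITS, REFERENCE_PACKAGE_COST
    )


def reference_scenario(n_members_recognized: int) -> ScenarioSpec:
    """Worked-example scenario: 100 patient and 16 per-carer units displaced per package."""
    return ScenarioSpec(
        n_members_recognized=n_members_recognized,
        displaced_patient_units=REFERENCE_DISPLACED_PATIENT_UNITS,
        displaced_member_units=REFERENCE_DISPLACED_MEMBER_UNITS,
    )
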