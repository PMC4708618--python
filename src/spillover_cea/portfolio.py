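"""Portfolio funding under graded spillover information.

A decision maker faces a menu of equally priced care packages, each
generating patient health plus spillovers to a fixed number of carers, and
must decide which to fund out of a budget whose spending displaces both
patient and carer health elsewhere. Three information scenarios are
compared: the decision maker recognizes spillovers to 0, 1 or 2 network
members. Recognizing more members scales each package's perceived benefit
by its condition multiplier at that network size — and simultaneously
raises the effective threshold, because the displaced stream carries
spillovers too.

Realized (as opposed to perceived) net health benefit is always scored
under full information: the benefit each funded package actually generates
for patient plus all carers, minus the health its funding actually
displaces. Patient-only decision making both funds packages whose true
benefit falls short of true displacement and passes over packages whose
spillovers would have justified them; ignoring the displaced-side
spillovers alone (a threshold left unadjusted, i.e. m_d treated as 1)
over-funds across the board.

Perceived benefits are reported as integers (half away from zero) computed
from 2-decimal condition multipliers, matching the convention of published
scenario tables; pass ``rounded=False`` for the raw values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._utils import check_finite, round_half_away
from .errors import ConfigurationError

__all__ = [
    "CarePackage",
    "ScenarioSpec",
    "FundingOutcome",
    "perceived_benefit",
    "scenario_threshold",
    "select_funding",
    "realized_net_benefit",
    "displaced_spillover_penalty",
    "evaluate_scenario",
]


@dataclass(frozen=True)
class CarePackage:
    """One candidate package of care.

    ``multipliers`` maps network size n (≥1) to the condition's generated
    multiplier at that size, conventionally at 2 decimals; n = 0 implicitly
    maps to 1 (no spillover recognized). Multipliers below 1 represent
    adverse spillovers and are allowed.
    """

    condition: str
    arm: str
    cost: float
    patient_benefit: float
    multipliers: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cost = check_finite("cost", self.cost)
        if cost <= 0:
            raise ValueError(f"package cost must be positive, got {cost}")
        benefit = check_finite("patient_benefit", self.patient_benefit)
        if benefit <= 0:
            raise ValueError(f"patient benefit must be positive, got {benefit}")
        mults = {int(n): check_finite(f"multiplier[{n}]", m) for n, m in self.multipliers.items()}
        object.__setattr__(self, "cost", cost)
        object.__setattr__(self, "patient_benefit", benefit)
        object.__setattr__(self, "multipliers", mults)

    @property
    def id(self) -> str:
        return f"{self.condition}:{self.arm}"

    def multiplier_for(self, n_members: int) -> float:
        if n_members == 0:
            return 1.0
        try:
            return self.multipliers[n_members]
        except KeyError:
            raise ConfigurationError(
                f"package {self.id!r} has no multiplier for {n_members} network "
                f"members (available: {sorted(self.multipliers)})"
            ) from None


@dataclass(frozen=True)
class ScenarioSpec:
    """An information scenario: how many network members the decision maker sees.

    ``displaced_patient_units`` and ``displaced_member_units`` are the
    health units displaced per package funded — the patient-side opportunity
    cost and the per-carer opportunity cost of the same spending.
    """

    n_members_recognized: int
    displaced_patient_units: float
    displaced_member_units: float = 0.0

    def __post_init__(self) -> None:
        if self.n_members_recognized < 0:
            raise ValueError("n_members_recognized must be non-negative")
        dp = check_finite("displaced_patient_units", self.displaced_patient_units)
        if dp <= 0:
            raise ValueError("displaced patient units must be positive")
        dm = check_finite("displaced_member_units", self.displaced_member_units)
        if dm < 0:
            raise ValueError("displaced member units must be non-negative")
        object.__setattr__(self, "displaced_patient_units", dp)
        object.__setattr__(self, "displaced_member_units", dm)

    def displacement_multiplier(self) -> float:
        """m_d implied by this scenario's recognized displacement."""
        return (
            1.0
            + self.n_members_recognized
            * self.displaced_member_units
            / self.displaced_patient_units
        )


@dataclass(frozen=True)
class FundingOutcome:
    """Result of applying one information scenario to a package menu."""

    scenario: ScenarioSpec
    perceived: dict[str, float]
    threshold: float
    funded: tuple[str, ...]
    realized_net_benefit: float


def perceived_benefit(
    package: CarePackage, scenario: ScenarioSpec, rounded: bool = True
) -> float:
    """Health benefit the decision maker perceives for ``package``.

    Patient benefit times the package's multiplier at the recognized
    network size; reported rounded to the nearest integer (half away from
    zero) unless ``rounded=False``.
    """
    value = package.patient_benefit * package.multiplier_for(scenario.n_members_recognized)
    return round_half_away(value) if rounded else value


def scenario_threshold(scenario: ScenarioSpec) -> float:
    """Health a funded package must beat: total units it displaces.

    Patient units plus the recognized members' units; with nothing
    recognized this is the conventional patient-only threshold.
    """
    return (
        scenario.displaced_patient_units
        + scenario.n_members_recognized * scenario.displaced_member_units
    )


def select_funding(
    packages: Sequence[CarePackage], scenario: ScenarioSpec, rounded: bool = True
) -> tuple[str, ...]:
    """Ids of packages whose perceived benefit strictly exceeds the threshold."""
    threshold = scenario_threshold(scenario)
    return tuple(
        p.id for p in packages if perceived_benefit(p, scenario, rounded) > threshold
    )


def realized_net_benefit(
    funded: Sequence[str],
    packages: Sequence[CarePackage],
    full_info_scenario: ScenarioSpec,
    rounded: bool = True,
) -> float:
    """Net health the funded set actually delivers, scored under full information.

    Sum over funded packages of (full-information perceived benefit minus
    full-information threshold). Empty set gives zero.
    """
    by_id = {p.id: p for p in packages}
    unknown = [pid for pid in funded if pid not in by_id]
    if unknown:
        raise KeyError(f"funded ids not in package list: {unknown}")
    threshold = scenario_threshold(full_info_scenario)
    return math.fsum(
        perceived_benefit(by_id[pid], full_info_scenario, rounded) - threshold
        for pid in funded
    )


def displaced_spillover_penalty(
    packages: Sequence[CarePackage],
    full_info_scenario: ScenarioSpec,
    rounded: bool = True,
) -> float:
    """Health lost by leaving the threshold unadjusted for displaced spillovers.

    Compares the optimal full-information funding set against the set
    chosen when generated spillovers are recognized but the displaced
    stream's multiplier is treated as 1 (threshold kept at patient units
    only) — the over-funding trap of counting spillovers on only one side
    of the ledger. Returns optimal minus naive realized net benefit (≥ 0).
    """
    optimal = select_funding(packages, full_info_scenario, rounded)
    naive_threshold = full_info_scenario.displaced_patient_units
    naive = tuple(
        p.id
        for p in packages
        if perceived_benefit(p, full_info_scenario, rounded) > naive_threshold
    )
    return realized_net_benefit(
        optimal, packages, full_info_scenario, rounded
    ) - realized_net_benefit(naive, packages, full_info_scenario, rounded)


def evaluate_scenario(
    packages: Sequence[CarePackage],
    scenario: ScenarioSpec,
    full_info_scenario: ScenarioSpec | None = None,
    rounded: bool = True,
) -> FundingOutcome:
    """Apply one scenario to the menu and score its choices under full information.

    ``full_info_scenario`` defaults to the scenario itself (appropriate when
    it already recognizes the whole network).
    """
    full = full_info_scenario if full_info_scenario is not None else scenario
    perceived = {p.id: perceived_benefit(p, scenario, rounded) for p in packages}
    funded = select_funding(packages, scenario, rounded)
    rnb = realized_net_benefit(funded, packages, full, rounded)
    return FundingOutcome(
        scenario=scenario,
        perceived=perceived,
        threshold=scenario_threshold(scenario),
        funded=funded,
        realized_net_benefit=rnb,
    )
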