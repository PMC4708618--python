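"""Core decision rules for cost-effectiveness analysis with health spillovers.

Extra-welfarist economic evaluation asks whether the health a new
intervention generates exceeds the health its funding displaces elsewhere in
a fixed budget. Conventionally only *patient* health enters on both sides:

    fund  iff  Δc / Δh_p < k_p

where ``Δc`` is the incremental cost, ``Δh_p`` the incremental patient
health benefit and ``k_p`` the threshold expressed as cost per unit of
patient health displaced. When treatment effects spill over onto family
members and informal carers, both the generated and the displaced stream
carry a network component. Two multiplier effects internalize this:

    m_i = (Δh_p + Δh_n) / Δh_p        (generated stream)
    m_d = (Δh_dp + Δh_dn) / Δh_dp     (displaced stream)

and the adjusted rule becomes

    fund  iff  (Δc / Δh_p) · (m_d / m_i) < k_p

which reduces to the conventional rule exactly when the two multipliers are
equal. When both streams are measured outright, the direct comparison

    fund  iff  Δc / (Δh_p + Δh_n) < Δc_d / (Δh_dp + Δh_dn)

applies without forming any multiplier. All rules use strict inequality at
the threshold: a tie is a rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Union

from ._utils import check_finite
from .errors import ConfigurationError, UndefinedMultiplierError, ZeroDisplacedHealthError

__all__ = [
    "HealthEffect",
    "CostDelta",
    "ThresholdSpec",
    "MultiplierPair",
    "Verdict",
    "Decision",
    "generated_multiplier",
    "displaced_multiplier",
    "conventional_decision",
    "spillover_decision",
    "direct_spillover_decision",
    "net_health_benefit",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HealthEffect:
    """Incremental health changes to a patient and their family network.

    Parameters
    ----------
    patient_delta
        Incremental health change for the patient (QALY-like units).
    network_deltas
        Per-member incremental health changes for the patient's network;
        may be empty. The aggregate network effect is their sum
        (spillovers are treated as additive across members).
    """

    patient_delta: float
    network_deltas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "patient_delta", check_finite("patient_delta", self.patient_delta))
        deltas = tuple(check_finite("network delta", d) for d in self.network_deltas)
        object.__setattr__(self, "network_deltas", deltas)

    @property
    def network_delta(self) -> float:
        """Aggregate network effect: the sum of the per-member components."""
        return math.fsum(self.network_deltas)

    @property
    def total_delta(self) -> float:
        """Total incremental health: patient plus aggregate network effect."""
        return self.patient_delta + self.network_delta


@dataclass(frozen=True)
class CostDelta:
    """Incremental cost of an intervention, in unspecified currency units."""

    value: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", check_finite("cost", self.value))


CostLike = Union[CostDelta, float, int]


def _cost_value(cost: CostLike) -> float:
    return cost.value if isinstance(cost, CostDelta) else check_finite("cost", cost)


@dataclass(frozen=True)
class ThresholdSpec:
    """Cost-effectiveness threshold and the displacement it encodes.

    ``k_p`` is the cost per unit of *patient* health displaced elsewhere in
    the budget. Its reciprocal is the patient health displaced per currency
    unit; supplying both triggers a consistency check. A per-member network
    displacement rate allows the displacement multiplier ``m_d`` to be
    derived for any assumed network size.
    """

    k_p: float
    displaced_patient_per_budget: float | None = None
    displaced_network_per_member_per_budget: float = 0.0

    def __post_init__(self) -> None:
        k_p = check_finite("k_p", self.k_p)
        if k_p <= 0:
            raise ConfigurationError(f"k_p must be positive, got {k_p}")
        object.__setattr__(self, "k_p", k_p)
        dppb = self.displaced_patient_per_budget
        if dppb is None:
            dppb = 1.0 / k_p
        else:
            dppb = check_finite("displaced_patient_per_budget", dppb)
            if dppb <= 0:
                raise ConfigurationError("displaced_patient_per_budget must be positive")
            if abs(k_p * dppb - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"inconsistent threshold: k_p={k_p} implies "
                    f"{1.0 / k_p:g} displaced patient units per currency unit, "
                    f"got {dppb:g}"
                )
        object.__setattr__(self, "displaced_patient_per_budget", dppb)
        dn = check_finite(
            "displaced_network_per_member_per_budget",
            self.displaced_network_per_member_per_budget,
        )
        if dn < 0:
            raise ConfigurationError("displaced network rate must be non-negative")
        object.__setattr__(self, "displaced_network_per_member_per_budget", dn)

    def displaced_patient_units(self, budget: float) -> float:
        """Patient health displaced by spending ``budget``."""
        return self.displaced_patient_per_budget * budget

    def displaced_network_units(self, budget: float, n_members: int) -> float:
        """Network health displaced by spending ``budget`` across ``n_members``."""
        return n_members * self.displaced_network_per_member_per_budget * budget

    def displacement_multiplier(self, n_members: int) -> float:
        """m_d implied by the per-member displacement rate for ``n_members``."""
        if n_members < 0:
            raise ValueError("n_members must be non-negative")
        return 1.0 + n_members * (
            self.displaced_network_per_member_per_budget / self.displaced_patient_per_budget
        )


@dataclass(frozen=True)
class MultiplierPair:
    """The two multiplier effects: generated (``m_i``) and displaced (``m_d``)."""

    m_i: float
    m_d: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "m_i", check_finite("m_i", self.m_i))
        object.__setattr__(self, "m_d", check_finite("m_d", self.m_d))

    @classmethod
    def from_effects(cls, generated: HealthEffect, displaced: HealthEffect) -> "MultiplierPair":
        return cls(generated_multiplier(generated), displaced_multiplier(displaced))


class Verdict(Enum):
    """Outcome of a funding test."""

    FUND = "fund"
    REJECT = "reject"
    DOMINATED = "dominated"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Decision:
    """A funding verdict with the ratio(s) that produced it.

    ``icer`` is the unadjusted cost per unit of patient health;
    ``adjusted_icer`` carries the multiplier correction where one applies.
    ``code`` explains non-FUND/REJECT verdicts (e.g. a dominated
    intervention whose patient benefit is negative).
    """

    verdict: Verdict
    rule: str
    icer: float | None = None
    adjusted_icer: float | None = None
    code: str | None = None

    @property
    def fund(self) -> bool:
        return self.verdict is Verdict.FUND


# ---------------------------------------------------------------------------
# Multipliers
# ---------------------------------------------------------------------------


def _stream_multiplier(effect: HealthEffect, stream: str) -> float:
    if effect.patient_delta == 0:
        raise UndefinedMultiplierError(
            f"{stream} multiplier is undefined when the patient health change is "
            "zero; compare the streams with direct_spillover_decision instead"
        )
    return effect.total_delta / effect.patient_delta


def generated_multiplier(effect: HealthEffect) -> float:
    """Multiplier on the generated stream: (Δh_p + Δh_n) / Δh_p.

    For a network of ``n`` identical members with per-member effect ``c``
    and patient effect ``p`` this is ``1 + n·(c/p)``. Same-signed patient
    and member effects (the usual case — both are losses averted) give a
    multiplier above one; an empty network gives exactly one.
    """
    return _stream_multiplier(effect, "generated")


def displaced_multiplier(displaced_effect: HealthEffect) -> float:
    """Multiplier on the displaced stream: (Δh_dp + Δh_dn) / Δh_dp."""
    return _stream_multiplier(displaced_effect, "displaced")


# ---------------------------------------------------------------------------
# Decision rules
# ---------------------------------------------------------------------------


def _nonpositive_benefit_decision(patient_benefit: float, rule: str) -> Decision:
    if patient_benefit < 0:
        return Decision(Verdict.DOMINATED, rule, code="negative-patient-benefit")
    return Decision(Verdict.INDETERMINATE, rule, code="zero-patient-benefit")


def conventional_decision(
    cost: CostLike, patient_benefit: float, threshold: ThresholdSpec
) -> Decision:
    """Conventional patient-only test: fund iff Δc/Δh_p < k_p (strict).

    A non-positive patient benefit yields a DOMINATED (negative) or
    INDETERMINATE (zero) verdict rather than an exception, since the ICER
    is meaningless there.
    """
    c = _cost_value(cost)
    patient_benefit = check_finite("patient_benefit", patient_benefit)
    if patient_benefit <= 0:
        return _nonpositive_benefit_decision(patient_benefit, "conventional")
    icer = c / patient_benefit
    verdict = Verdict.FUND if icer < threshold.k_p else Verdict.REJECT
    return Decision(verdict, "conventional", icer=icer, adjusted_icer=icer)


def spillover_decision(
    cost: CostLike,
    patient_benefit: float,
    multipliers: MultiplierPair,
    threshold: ThresholdSpec,
) -> Decision:
    """Multiplier-adjusted test: fund iff (Δc/Δh_p)·(m_d/m_i) < k_p (strict).

    Identical to :func:`conventional_decision` whenever ``m_i == m_d``.
    The ratio form is invalid when ``m_i <= 0`` (total generated health is
    non-positive while patient health is positive); callers must then use
    :func:`direct_spillover_decision`.
    """
    c = _cost_value(cost)
    patient_benefit = check_finite("patient_benefit", patient_benefit)
    if patient_benefit <= 0:
        return _nonpositive_benefit_decision(patient_benefit, "multiplier")
    if multipliers.m_i <= 0:
        raise UndefinedMultiplierError(
            f"m_i={multipliers.m_i} is non-positive: total generated health does "
            "not exceed zero, so the ratio-form rule is invalid; use "
            "direct_spillover_decision on the measured streams"
        )
    icer = c / patient_benefit
    adjusted = icer * (multipliers.m_d / multipliers.m_i)
    verdict = Verdict.FUND if adjusted < threshold.k_p else Verdict.REJECT
    return Decision(verdict, "multiplier", icer=icer, adjusted_icer=adjusted)


def direct_spillover_decision(
    cost: CostLike,
    generated: HealthEffect,
    displaced_cost: CostLike,
    displaced: HealthEffect,
) -> Decision:
    """Direct two-stream test: fund iff Δc/(Δh_p+Δh_n) < Δc_d/(Δh_dp+Δh_dn).

    Implemented as the cross-multiplied comparison
    ``Δc·(Δh_dp+Δh_dn) < Δc_d·(Δh_p+Δh_n)``, which is equivalent for
    positive totals and rejects cleanly when the generated total is
    non-positive. Agrees with :func:`spillover_decision` whenever the ratio
    form is applicable.
    """
    c = _cost_value(cost)
    c_d = _cost_value(displaced_cost)
    total_displaced = displaced.total_delta
    if total_displaced <= 0:
        raise ZeroDisplacedHealthError(
            "total displaced health must be positive to define the implicit "
            f"threshold, got {total_displaced}"
        )
    if c_d <= 0:
        raise ConfigurationError("displaced cost must be positive")
    total_generated = generated.total_delta
    fund = c * total_displaced < c_d * total_generated
    icer = c / total_generated if total_generated > 0 else None
    return Decision(Verdict.FUND if fund else Verdict.REJECT, "direct", icer=icer)


def net_health_benefit(total_generated: float, total_displaced: float) -> float:
    """Net health benefit of a funding decision: generated minus displaced."""
    return check_finite("total_generated", total_generated) - check_finite(
        "total_displaced", total_displaced
    )


def total_net_health_benefit(pairs: Iterable[tuple[float, float]]) -> float:
    """Sum of net health benefits over (generated, displaced) pairs."""
    return math.fsum(net_health_benefit(g, d) for g, d in pairs)
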