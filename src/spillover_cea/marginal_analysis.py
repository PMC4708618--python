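"""Marginal-benefit equilibrium analysis of spillover-adjusted funding levels.

A national funding decision for a divisible intervention can be pictured
with a declining marginal health benefit schedule for patients (MHB_P) and
a constant marginal health loss schedule (MHL_P) — constant because the
intervention's budget share is small, so the opportunity cost per unit does
not vary. Patient-health maximization funds up to the quantity Q1 where the
two schedules cross.

Spillovers proportional to patient health scale the schedules: the societal
benefit schedule is MHB_S(q) = m_i·MHB_P(q) and the societal loss schedule
MHL_S = m_d·MHL_P. Three regimes follow:

* equal multipliers — both schedules scale alike and the equilibrium stays
  at Q1: patient-only decision making already maximizes societal health;
* m_i > m_d — the societal equilibrium moves beyond Q1; the welfare
  triangle between the schedules over [Q1, Q*] is the health forgone by
  stopping at Q1;
* m_i < m_d — the societal equilibrium falls short of Q1, and if the loss
  triangle from overprovision (B) exceeds the gain triangle near the origin
  (C), not funding at all beats funding to Q1.

Schedules are linear here: the minimal concrete form of the generic
declining curves, sufficient for all of the comparative statics above.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from ._utils import check_finite
from .decision_core import MultiplierPair
from .errors import UnboundedDemandError

__all__ = [
    "LinearSchedule",
    "EquilibriumVerdict",
    "EquilibriumResult",
    "societal_schedules",
    "equilibrium_quantity",
    "welfare_triangle",
    "corner_solution_check",
    "analyze",
    "plot_schedules",
]


@dataclass(frozen=True)
class LinearSchedule:
    """A declining linear marginal schedule: value(q) = intercept − slope·q.

    ``slope`` is the decline per quantity unit and must be non-negative; a
    zero slope models the constant loss schedule.
    """

    intercept: float
    slope: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "intercept", check_finite("intercept", self.intercept))
        slope = check_finite("slope", self.slope)
        if slope < 0:
            raise ValueError(f"slope must be non-negative, got {slope}")
        object.__setattr__(self, "slope", slope)

    def __call__(self, q: float) -> float:
        return self.intercept - self.slope * q

    def scaled(self, factor: float) -> "LinearSchedule":
        """Schedule with both intercept and slope multiplied by ``factor``."""
        return LinearSchedule(self.intercept * factor, self.slope * factor)


class EquilibriumVerdict(Enum):
    FUND_TO_EQUILIBRIUM = "fund-to-equilibrium"
    NO_FUNDING = "no-funding"


@dataclass(frozen=True)
class EquilibriumResult:
    """Outcome of the societal equilibrium analysis.

    ``q_patient`` is the patient-only equilibrium; ``q_societal`` the
    spillover-adjusted one; ``triangle_area`` the health gained (or saved)
    by moving between them; ``verdict`` whether partial funding beats no
    funding at all.
    """

    q_patient: float
    q_societal: float
    triangle_area: float
    verdict: EquilibriumVerdict


def societal_schedules(
    mhb_p: LinearSchedule, mhl_p: float, multipliers: MultiplierPair
) -> tuple[LinearSchedule, float]:
    """Scale patient schedules to societal ones: MHB_S = m_i·MHB_P, MHL_S = m_d·MHL_P.

    Valid for positive multipliers; spillovers are assumed proportional to
    patient health within the intervention.
    """
    if multipliers.m_i <= 0 or multipliers.m_d <= 0:
        raise ValueError("societal schedules require positive multipliers")
    mhl_p = check_finite("mhl_p", mhl_p)
    return mhb_p.scaled(multipliers.m_i), multipliers.m_d * mhl_p


def equilibrium_quantity(mhb: LinearSchedule, mhl: float) -> float:
    """Quantity equating marginal health benefit and marginal health loss.

    Closed form ``(intercept − mhl)/slope``, clipped at zero when the
    benefit schedule starts below the loss line.
    """
    mhl = check_finite("mhl", mhl)
    if mhb.slope == 0:
        if mhb.intercept > mhl:
            raise UnboundedDemandError(
                "flat benefit schedule above the loss schedule: demand is unbounded"
            )
        return 0.0
    return max((mhb.intercept - mhl) / mhb.slope, 0.0)


def welfare_triangle(
    q_from: float, q_to: float, mhb_s: LinearSchedule, mhl_s: float
) -> float:
    """Health area between MHB_S and the constant MHL_S over [q_from, q_to].

    The gap g(q) = MHB_S(q) − MHL_S is linear, so the integral is exact:
    |∫ g dq| over the ordered interval. When one endpoint is the crossing
    point this is the textbook triangle ½·|Δq|·|g(other endpoint)|.
    """
    a, b = sorted((check_finite("q_from", q_from), check_finite("q_to", q_to)))
    mhl_s = check_finite("mhl_s", mhl_s)
    gap0 = mhb_s.intercept - mhl_s
    integral = gap0 * (b - a) - mhb_s.slope * (b * b - a * a) / 2.0
    return abs(integral)


def corner_solution_check(
    mhb_s: LinearSchedule, mhl_s: float, q1: float
) -> EquilibriumVerdict:
    """Is funding up to the patient-only equilibrium better than not funding?

    Signs the net societal health of funding to ``q1``,
    ∫₀^{q1} (MHB_S − MHL_S) dq. Geometrically this compares the gain
    triangle near the origin (C) with the overprovision loss triangle (B):
    C ≥ B means partial funding (to the societal equilibrium) is worthwhile;
    C < B means net health is higher with the intervention not funded at
    all than funded to q1. When MHB_S stays above MHL_S the loss triangle
    is empty and the verdict is trivially to fund.
    """
    q1 = check_finite("q1", q1)
    if q1 < 0:
        raise ValueError("q1 must be non-negative")
    mhl_s = check_finite("mhl_s", mhl_s)
    net = (mhb_s.intercept - mhl_s) * q1 - mhb_s.slope * q1 * q1 / 2.0
    if net >= 0:
        return EquilibriumVerdict.FUND_TO_EQUILIBRIUM
    return EquilibriumVerdict.NO_FUNDING


def analyze(
    mhb_p: LinearSchedule, mhl_p: float, multipliers: MultiplierPair
) -> EquilibriumResult:
    """Full analysis: equilibria, welfare triangle between them, corner verdict."""
    q1 = equilibrium_quantity(mhb_p, mhl_p)
    mhb_s, mhl_s = societal_schedules(mhb_p, mhl_p, multipliers)
    q_star = equilibrium_quantity(mhb_s, mhl_s)
    area = welfare_triangle(q1, q_star, mhb_s, mhl_s)
    verdict = corner_solution_check(mhb_s, mhl_s, q1)
    return EquilibriumResult(q1, q_star, area, verdict)


def plot_schedules(
    mhb_p: LinearSchedule,
    mhl_p: float,
    multipliers: MultiplierPair,
    path: str,
) -> None:
    """Plot patient and societal schedules with both equilibria marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    result = analyze(mhb_p, mhl_p, multipliers)
    mhb_s, mhl_s = societal_schedules(mhb_p, mhl_p, multipliers)
    q_max = max(result.q_patient, result.q_societal, 1.0) * 1.3
    q = np.linspace(0.0, q_max, 200)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(q, mhb_p.intercept - mhb_p.slope * q, label="MHB$_P$")
    ax.plot(q, mhb_s.intercept - mhb_s.slope * q, label="MHB$_S$")
    ax.axhline(mhl_p, linestyle="--", label="MHL$_P$")
    ax.axhline(mhl_s, linestyle=":", label="MHL$_S$")
    for qq, lab in ((result.q_patient, "$Q_1$"), (result.q_societal, "$Q^*$")):
        ax.axvline(qq, color="grey", linewidth=0.8)
        ax.annotate(lab, (qq, 0), textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel("quantity of intervention")
    ax.set_ylabel("marginal health per unit")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
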