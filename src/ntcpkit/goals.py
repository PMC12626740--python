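"""Clinical planning goals and per-plan pass/fail evaluation.

Encodes the whole-brain IMRT objective set (target coverage, hippocampal
avoidance, lacrimal and parotid sparing) and evaluates each goal against a
supplied cumulative DVH.  A plan is clinically acceptable when at least 90%
of the PTV receives the prescription dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .dvh import CumulativeDVH, DVHError, dose_at_volume, volume_at_dose

__all__ = [
    "ClinicalGoal",
    "GoalResult",
    "PlanReport",
    "PRESCRIPTION_DOSE_GY",
    "default_goals",
    "evaluate_goal",
    "evaluate_plan",
]

logger = logging.getLogger(__name__)

#: Prescription dose (Gy) the acceptability rule binds on.
PRESCRIPTION_DOSE_GY = 30.0

#: Minimum PTV volume fraction at prescription dose for acceptability.
PTV_COVERAGE_FRACTION = 0.90

_METRICS = {"D_percent", "V_gray", "D_max", "D_min"}
_COMPARATORS = {"<=", ">="}


@dataclass(frozen=True)
class ClinicalGoal:
    """One dosimetric objective for one structure.

    ``metric`` is one of ``D_percent`` (dose to the hottest fraction ``x``
    of the volume, x stored as a fraction), ``V_gray`` (volume fraction at
    >= ``x`` Gy), ``D_max``, or ``D_min`` (dose to 100% of the volume).
    Dose thresholds are in Gy; volume thresholds are fractions.
    """

    structure_label: str
    metric: str
    comparator: str
    threshold: float
    x: Optional[float] = None
    priority: str = "primary"

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"comparator must be '<=' or '>='")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.metric in ("D_percent", "V_gray") and self.x is None:
            raise ValueError(f"metric {self.metric} requires a parameter x")
        if self.metric == "D_percent" and not 0 < self.x <= 1:
            raise ValueError("D_percent fraction must lie in (0, 1]")
        if self.metric == "V_gray" and not 0 < self.threshold <= 1:
            raise ValueError("V_gray threshold must be a volume fraction")
        if self.priority not in ("primary", "secondary"):
            raise ValueError("priority must be 'primary' or 'secondary'")

    def describe(self) -> str:
        if self.metric == "D_percent":
            name = f"D_{self.x * 100:g}%"
        elif self.metric == "V_gray":
            name = f"V_{self.x:g}Gy"
        else:
            name = self.metric
        unit = "%" if self.metric == "V_gray" else "Gy"
        thr = self.threshold * 100 if self.metric == "V_gray" else self.threshold
        return f"{self.structure_label} {name} {self.comparator} {thr:g} {unit}"


@dataclass(frozen=True)
class GoalResult:
    goal: ClinicalGoal
    achieved: Optional[float]  # None when the DVH was missing
    passed: Optional[bool]


@dataclass(frozen=True)
class PlanReport:
    """Per-goal outcomes plus the overall acceptability flag.

    ``overall_acceptable`` is True iff PTV V_30Gy >= 0.90, False when the
    PTV DVH shows less coverage, and None (indeterminate) when no PTV DVH
    was supplied.
    """

    results: tuple[GoalResult, ...]
    overall_acceptable: Optional[bool]
    ptv_coverage: Optional[float] = None


def default_goals() -> list[ClinicalGoal]:
    """The ten shipped whole-brain planning objectives.

    PTV: D_2% <= 37.5 Gy, D_98% >= 25 Gy, V_30Gy >= 90% (>= 95% secondary);
    hippocampi: D_min <= 9 Gy, D_max <= 16 Gy; lacrimal glands:
    V_15Gy <= 80%, D_max <= 15 Gy (secondary); parotid glands:
    V_20Gy <= 50%, D_max <= 20 Gy (secondary).
    """
    return [
        ClinicalGoal("ptv", "D_percent", "<=", 37.5, x=0.02),
        ClinicalGoal("ptv", "D_percent", ">=", 25.0, x=0.98),
        ClinicalGoal("ptv", "V_gray", ">=", 0.90, x=30.0),
        ClinicalGoal("ptv", "V_gray", ">=", 0.95, x=30.0, priority="secondary"),
        ClinicalGoal("hippocampi", "D_min", "<=", 9.0),
        ClinicalGoal("hippocampi", "D_max", "<=", 16.0),
        ClinicalGoal("lacrimal", "V_gray", "<=", 0.80, x=15.0),
        ClinicalGoal("lacrimal", "D_max", "<=", 15.0, priority="secondary"),
        ClinicalGoal("parotid", "V_gray", "<=", 0.50, x=20.0),
        ClinicalGoal("parotid", "D_max", "<=", 20.0, priority="secondary"),
    ]


def _cumulative_d_max(c: CumulativeDVH) -> float:
    """Dose at which the cumulative volume reaches zero (support supremum)."""
    v = c.volume_fraction
    if v[-1] > 1e-12:
        return float(c.dose_grid[-1])
    j = int(np.argmax(v <= 1e-12))
    return float(c.dose_grid[j])


def _metric_value(c: CumulativeDVH, g: ClinicalGoal) -> float:
    if g.metric == "D_percent":
        return dose_at_volume(c, g.x)
    if g.metric == "V_gray":
        return volume_at_dose(c, g.x)
    if g.metric == "D_max":
        return _cumulative_d_max(c)
    if g.metric == "D_min":
        return dose_at_volume(c, 1.0)
    raise AssertionError(g.metric)


def evaluate_goal(dvh: CumulativeDVH, g: ClinicalGoal) -> GoalResult:
    """Evaluate one goal against one cumulative DVH."""
    if dvh.structure_label and dvh.structure_label != g.structure_label:
        raise DVHError(
            f"goal is for {g.structure_label!r} but DVH is labeled "
            f"{dvh.structure_label!r}"
        )
    achieved = _metric_value(dvh, g)
    passed = achieved <= g.threshold if g.comparator == "<=" else achieved >= g.threshold
    return GoalResult(goal=g, achieved=achieved, passed=passed)


def evaluate_plan(
    dvhs: Mapping[str, CumulativeDVH],
    goals: Optional[Sequence[ClinicalGoal]] = None,
    prescription: float = PRESCRIPTION_DOSE_GY,
) -> PlanReport:
    """Evaluate every goal with an available DVH and set plan acceptability.

    Structures without a DVH produce a logged warning and a result with
    ``achieved``/``passed`` of None.  Without a PTV DVH the acceptability
    flag is indeterminate (None), never False.
    """
    goals = list(default_goals() if goals is None else goals)
    results = []
    for g in goals:
        dvh = dvhs.get(g.structure_label)
        if dvh is None:
            logger.warning("no DVH for structure %r; goal skipped: %s",
                           g.structure_label, g.describe())
            results.append(GoalResult(goal=g, achieved=None, passed=None))
        else:
            results.append(evaluate_goal(dvh, g))

    ptv = dvhs.get("ptv")
    if ptv is None:
        coverage = None
        acceptable = None
    else:
        coverage = volume_at_dose(ptv, prescription)
        acceptable = coverage >= PTV_COVERAGE_FRACTION
    return PlanReport(
        results=tuple(results),
        overall_acceptable=acceptable,
        ptv_coverage=coverage,
    )
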