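"""Two-arm decision tree: standard of care vs dedicated pediatric ORs.

Each demand case faces a chance node: with probability ``p_no_or`` it goes
untreated in the given scenario and experiences the natural course of the
disease; otherwise it is operated and follows the treated branch
(perioperative death / success / failure). The arm's expected annual DALYs
are the sum of these per-case expectations over the annual demand; the
intervention arm has ``p_no_or = 0``.

Three treated-subset semantics are offered. The default, ``"expected"``,
takes the exact expectation over the chance node (every record treated with
probability volume/demand), which is the tree's own semantics and is
deterministic. ``"random"`` (seeded draw) and ``"by_order"`` select an
explicit treated subset instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .burden import (
    BurdenError,
    DiscountSpec,
    DiseaseCatalog,
    TreatmentParams,
    daly_treated,
    daly_untreated,
)
from .costing import CostLedger
from .registry import PatientRecord

SELECTIONS = ("expected", "random", "by_order")

__all__ = [
    "TreeError",
    "ScenarioSpec",
    "ArmResult",
    "CEResult",
    "evaluate_arm",
    "icer",
    "classify_threshold",
]


class TreeError(ValueError):
    """Invalid scenario specification."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One decision-tree arm: volume treated, untreated fraction, costs."""

    label: str
    annual_volume: float
    cost_ledger: CostLedger
    treatment: TreatmentParams
    p_no_or: float | None = None   # derived from volume/demand when None

    def __post_init__(self) -> None:
        if self.annual_volume < 0:
            raise TreeError(f"annual_volume must be >= 0, got {self.annual_volume}")
        if self.p_no_or is not None and not 0.0 <= self.p_no_or <= 1.0:
            raise TreeError(f"p_no_or must be in [0, 1], got {self.p_no_or}")


@dataclass(frozen=True)
class ArmResult:
    """Expected annual cost, accrued DALYs and lives saved for one arm."""

    label: str
    expected_cost: float
    expected_dalys: float
    lives_saved: float


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of the intervention arm against the comparator."""

    delta_cost: float
    delta_dalys_averted: float
    icer: float
    delta_lives_saved: float
    cost_per_life_saved: float
    classification: str | None = None

    def with_classification(self, label: str) -> "CEResult":
        return replace(self, classification=label)


def evaluate_arm(
    spec: ScenarioSpec,
    demand_registry: Sequence[PatientRecord],
    catalog: DiseaseCatalog,
    disc: DiscountSpec,
    selection: str = "expected",
    seed: int | None = None,
    demand_size: float | None = None,
) -> ArmResult:
    """Expected annual cost and DALYs for one arm over the annual demand.

    ``demand_registry`` carries the case mix and ages of the annual demand.
    In ``"expected"`` mode it may be a representative sample and
    ``demand_size`` (default: its length) sets the demanded caseload; in the
    subset modes the registry *is* the demand and the volume may not exceed
    its size.
    """
    if not demand_registry:
        raise TreeError("demand registry must not be empty")
    if selection not in SELECTIONS:
        raise TreeError(f"selection must be one of {SELECTIONS}, got {selection!r}")

    n_records = len(demand_registry)
    demand = float(demand_size) if demand_size is not None else float(n_records)
    volume = float(spec.annual_volume)
    if spec.p_no_or is not None and spec.p_no_or < 1.0:
        demand = volume / (1.0 - spec.p_no_or)
    if volume - demand > 1e-9:
        raise TreeError(
            f"{spec.label}: annual_volume ({volume}) exceeds demand ({demand})"
        )
    p_no_or = 1.0 - volume / demand if demand > 0 else 0.0

    tp = spec.treatment
    treated = np.array(
        [
            daly_treated(r, catalog.entry(r.diagnosis), tp, catalog, disc)
            for r in demand_registry
        ]
    )
    untreated = np.array([daly_untreated(r, catalog, disc) for r in demand_registry])
    p_death_u = np.array(
        [catalog.entry(r.diagnosis).p_death_untreated for r in demand_registry]
    )

    if selection == "expected":
        expected_dalys = demand * (
            (1.0 - p_no_or) * treated.mean() + p_no_or * untreated.mean()
        )
        lives = volume * float((p_death_u - tp.p_dbd).mean())
    else:
        if volume > n_records + 1e-9:
            raise TreeError(
                f"{spec.label}: annual_volume ({volume}) exceeds the registry "
                f"size ({n_records}) required for subset selection"
            )
        k = int(round(volume))
        if selection == "random":
            rng = np.random.default_rng(seed)
            idx = rng.choice(n_records, size=k, replace=False)
        else:  # by_order
            idx = np.arange(k)
        mask = np.zeros(n_records, dtype=bool)
        mask[idx] = True
        expected_dalys = float(treated[mask].sum() + untreated[~mask].sum())
        lives = float((p_death_u[mask] - tp.p_dbd).sum())

    return ArmResult(
        label=spec.label,
        expected_cost=float(spec.cost_ledger.total),
        expected_dalys=float(expected_dalys),
        lives_saved=max(0.0, lives),
    )


def icer(soc: ArmResult, orr: ArmResult) -> CEResult:
    """Incremental cost per DALY averted of the intervention arm vs comparator.

    Dominance conventions: negative ICERs are never reported — an arm that
    is cheaper and averts DALYs is ``dominant`` (ICER is NaN), one that costs
    more and averts nothing is ``dominated``.
    """
    delta_cost = orr.expected_cost - soc.expected_cost
    averted = soc.expected_dalys - orr.expected_dalys
    delta_lives = orr.lives_saved - soc.lives_saved

    classification: str | None = None
    if averted > 0 and delta_cost <= 0:
        classification = "dominant"
        ratio = float("nan")
    elif averted <= 0 and delta_cost >= 0 and (averted < 0 or delta_cost > 0):
        classification = "dominated"
        ratio = float("nan")
    elif averted == 0 and delta_cost == 0:
        ratio = float("nan")
    else:
        ratio = delta_cost / averted

    cost_per_life = delta_cost / delta_lives if delta_lives > 0 else float("nan")
    return CEResult(
        delta_cost=float(delta_cost),
        delta_dalys_averted=float(averted),
        icer=float(ratio),
        delta_lives_saved=float(delta_lives),
        cost_per_life_saved=float(cost_per_life),
        classification=classification,
    )


def classify_threshold(ce: CEResult, threshold: float) -> str:
    """Cost-effective iff dominant or ICER strictly below the willingness-to-pay
    threshold (USD per DALY averted)."""
    if threshold <= 0:
        raise TreeError(f"threshold must be positive, got {threshold}")
    if ce.classification == "dominant":
        return "cost_effective"
    if ce.classification == "dominated" or math.isnan(ce.icer):
        return "not_cost_effective"
    return "cost_effective" if ce.icer < threshold else "not_cost_effective"
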