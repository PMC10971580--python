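"""Annualized, payor-attributed incremental costing.

The intervention's annual incremental cost is assembled from fixed
components — straight-line annualized durable equipment, freight and
installation, charity administrative overhead, and presence-weighted
incremental personnel salaries — plus per-case variable components
(disposables, perioperative medications, utilities, inpatient bed-days,
family out-of-pocket spend) scaled by the incremental caseload. Every
component is tagged with its payor (charity / MoH / patient) and fixity, and
the ledger partitions its total exactly across payors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import defaults

PAYORS = ("charity", "MoH", "patient")
FIXITIES = ("fixed", "per_case")

__all__ = [
    "CostingError",
    "DurableItem",
    "StaffRole",
    "VariableRates",
    "CostComponent",
    "CostLedger",
    "annualize",
    "personnel_cost",
    "variable_costs",
    "build_ledger",
    "default_durables",
    "default_staff",
    "default_variable_rates",
    "default_incremental_ledger",
    "write_ledger",
]


class CostingError(ValueError):
    """Invalid costing input."""


@dataclass(frozen=True)
class DurableItem:
    """A durable asset annualized over its useful lifespan (2021 USD)."""

    name: str
    unit_cost: float
    quantity: int = 1
    lifespan_years: float = 1.0

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise CostingError(f"{self.name}: unit_cost must be >= 0")
        if self.quantity <= 0:
            raise CostingError(f"{self.name}: quantity must be positive")
        if self.lifespan_years <= 0:
            raise CostingError(f"{self.name}: lifespan_years must be positive")


@dataclass(frozen=True)
class StaffRole:
    """A perioperative role with presence weight and incremental share."""

    role: str
    annual_salary: float
    presence_weight: float = 1.0
    incremental_share: float = 1.0

    def __post_init__(self) -> None:
        if self.annual_salary < 0:
            raise CostingError(f"{self.role}: annual_salary must be >= 0")
        for name in ("presence_weight", "incremental_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CostingError(f"{self.role}: {name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class VariableRates:
    """Per-case variable rates (2021 USD)."""

    disposables_per_case: float = defaults.DISPOSABLES_PER_CASE_USD
    meds_per_case: float = defaults.MEDS_PER_CASE_USD
    utilities_per_case: float = defaults.UTILITIES_PER_CASE_USD
    hospital_day_cost: float = defaults.HOSPITAL_DAY_COST_USD
    mean_los_days: float = defaults.MEAN_LOS_DAYS
    oop_per_case: float = defaults.OOP_PER_CASE_USD

    def __post_init__(self) -> None:
        for name in (
            "disposables_per_case",
            "meds_per_case",
            "utilities_per_case",
            "hospital_day_cost",
            "mean_los_days",
            "oop_per_case",
        ):
            if getattr(self, name) < 0:
                raise CostingError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def perioperative_per_case(self) -> float:
        """MoH-borne variable cost per case (everything except OOP)."""
        return (
            self.disposables_per_case
            + self.meds_per_case
            + self.utilities_per_case
            + self.hospital_day_cost * self.mean_los_days
        )


@dataclass(frozen=True)
class CostComponent:
    label: str
    payor: str
    fixity: str
    annual_amount: float

    def __post_init__(self) -> None:
        if self.payor not in PAYORS:
            raise CostingError(
                f"{self.label}: unknown payor {self.payor!r}; expected one of {PAYORS}"
            )
        if self.fixity not in FIXITIES:
            raise CostingError(
                f"{self.label}: unknown fixity {self.fixity!r}; expected one of {FIXITIES}"
            )


@dataclass(frozen=True)
class CostLedger:
    """Component list with total and an exact payor partition."""

    components: tuple[CostComponent, ...]

    @property
    def total(self) -> float:
        return sum(c.annual_amount for c in self.components)

    @property
    def by_payor(self) -> dict[str, float]:
        out = {p: 0.0 for p in PAYORS}
        for c in self.components:
            out[c.payor] += c.annual_amount
        # re-balance float drift so the partition sums to the total exactly
        drift = self.total - sum(out.values())
        out["MoH"] += drift
        return out

    @property
    def installation_capital(self) -> float:
        """Charity equipment + shipping, excluding administrative overhead."""
        return sum(
            c.annual_amount
            for c in self.components
            if c.payor == "charity" and "overhead" not in c.label
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": c.label,
                    "payor": c.payor,
                    "fixity": c.fixity,
                    "annual_usd": c.annual_amount,
                }
                for c in self.components
            ]
        )


def annualize(item: DurableItem) -> float:
    """Straight-line annual cost: unit cost x quantity / lifespan."""
    return item.unit_cost * item.quantity / item.lifespan_years


def personnel_cost(roles: Sequence[StaffRole]) -> float:
    """Presence-weighted incremental salary total per year."""
    return sum(r.annual_salary * r.presence_weight * r.incremental_share for r in roles)


def variable_costs(rates: VariableRates, n_incremental_cases: int) -> list[CostComponent]:
    """Per-case components scaled by the incremental caseload."""
    if n_incremental_cases < 0:
        raise CostingError(
            f"n_incremental_cases must be >= 0, got {n_incremental_cases}"
        )
    n = n_incremental_cases
    return [
        CostComponent("disposable supplies", "MoH", "per_case", rates.disposables_per_case * n),
        CostComponent("perioperative medications", "MoH", "per_case", rates.meds_per_case * n),
        CostComponent("perioperative utilities", "MoH", "per_case", rates.utilities_per_case * n),
        CostComponent(
            "inpatient hospitalization",
            "MoH",
            "per_case",
            rates.hospital_day_cost * rates.mean_los_days * n,
        ),
        CostComponent("out-of-pocket", "patient", "per_case", rates.oop_per_case * n),
    ]


def build_ledger(
    fixed_components: Iterable[CostComponent],
    personnel_annual: float,
    variable_components: Iterable[CostComponent],
) -> CostLedger:
    """Assemble the annual ledger: charity fixed capital, MoH personnel and
    variable costs, patient out-of-pocket."""
    components = (
        tuple(fixed_components)
        + (CostComponent("personnel salaries", "MoH", "fixed", personnel_annual),)
        + tuple(variable_components)
    )
    return CostLedger(components=components)


# --- shipped defaults -------------------------------------------------------

def default_durables() -> list[DurableItem]:
    """The charity equipment bundle, carried at its published annualized cost."""
    return [
        DurableItem(
            "durable OR equipment bundle (annualized)",
            unit_cost=defaults.EQUIPMENT_ANNUAL_USD,
            quantity=1,
            lifespan_years=1.0,
        )
    ]


def default_staff() -> list[StaffRole]:
    share = defaults.PERSONNEL_INCREMENTAL_SHARE
    return [
        StaffRole(role, salary, presence, share)
        for role, salary, presence in defaults.DEFAULT_STAFF
    ]


def default_variable_rates() -> VariableRates:
    return VariableRates()


def default_fixed_components() -> list[CostComponent]:
    return [
        CostComponent(
            "durable equipment (annualized)",
            "charity",
            "fixed",
            sum(annualize(d) for d in default_durables()),
        ),
        CostComponent(
            "shipping and installation", "charity", "fixed",
            defaults.SHIPPING_INSTALL_ANNUAL_USD,
        ),
        CostComponent(
            "charity administrative overhead", "charity", "fixed",
            defaults.OVERHEAD_ANNUAL_USD,
        ),
    ]


def default_incremental_ledger(
    n_incremental_cases: int = defaults.N_INCREMENTAL_CASES,
) -> CostLedger:
    """The intervention's annual incremental cost ledger at default inputs."""
    return build_ledger(
        default_fixed_components(),
        personnel_cost(default_staff()),
        variable_costs(default_variable_rates(), n_incremental_cases),
    )


def write_ledger(ledger: CostLedger, path, header_lines: Sequence[str] = ()) -> None:
    """Export the ledger as CSV, optionally prefixed with '#' metadata lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        ledger.to_frame().to_csv(fh, index=False)
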