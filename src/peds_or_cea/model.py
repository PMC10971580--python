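"""Assembled base-case model with named, overridable parameters.

``CEAModel`` binds together a demand registry (the annual case mix), a
calibrated disease catalog, treatment parameters and the cost inputs, and
evaluates both decision-tree arms for any combination of parameter
overrides. The override mechanism is what the one-way (tornado) and
probabilistic sensitivity analyses drive.

Cost structure (all 2021 USD/year). The comparator arm carries only the
per-case variable costs of its own caseload; the intervention arm carries
the same per-case rates at the full caseload plus the fixed components
(annualized equipment, shipping/installation, charity overhead, incremental
personnel). With the shipped defaults this reproduces the printed annual
totals of both arms to within a dollar.

In probabilistic batches the drawn yearly caseload rescales the fixed
components proportionally at the base volume (``caseload_mode="per_case"``,
the per-patient decision-tree view in which fixed annual costs are amortized
per case); ``"fixed_annual"`` keeps them constant instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import costing, defaults
from .burden import (
    CalibrationInfo,
    DiscountSpec,
    DiseaseCatalog,
    DiseaseEntry,
    TreatmentParams,
    calibrate_catalog,
    default_catalog,
)
from .costing import CostComponent, CostLedger, VariableRates
from .registry import (
    PatientRecord,
    RegistryParams,
    default_registry_params,
    generate_registry,
)
from .tree import ArmResult, CEResult, ScenarioSpec, classify_threshold, evaluate_arm, icer

__all__ = ["ModelParams", "EvalResult", "CEAModel", "ModelError"]


class ModelError(ValueError):
    """Invalid model parameter or override."""


@dataclass(frozen=True)
class ModelParams:
    """Scalar model knobs; every field is overridable by name."""

    discount_rate: float = defaults.DISCOUNT_RATE
    life_expectancy: float = defaults.LIFE_EXPECTANCY_YEARS
    annual_volume: float = float(defaults.OR_ANNUAL_VOLUME)
    soc_volume_fraction: float = defaults.SOC_VOLUME_FRACTION
    p_dbd: float = defaults.P_DEATH_BEFORE_DISCHARGE
    p_st: float = defaults.P_SUCCESSFUL_TREATMENT
    equipment_annual: float = defaults.EQUIPMENT_ANNUAL_USD
    shipping_annual: float = defaults.SHIPPING_INSTALL_ANNUAL_USD
    overhead_annual: float = defaults.OVERHEAD_ANNUAL_USD
    personnel_annual: float = defaults.PERSONNEL_ANNUAL_USD
    disposables_per_case: float = defaults.DISPOSABLES_PER_CASE_USD
    meds_per_case: float = defaults.MEDS_PER_CASE_USD
    utilities_per_case: float = defaults.UTILITIES_PER_CASE_USD
    hospital_day_cost: float = defaults.HOSPITAL_DAY_COST_USD
    mean_los_days: float = defaults.MEAN_LOS_DAYS
    oop_per_case: float = defaults.OOP_PER_CASE_USD
    dw_scale: float = 1.0


@dataclass(frozen=True)
class EvalResult:
    soc: ArmResult
    orr: ArmResult
    ce: CEResult
    threshold: float

    @property
    def classification(self) -> str:
        return classify_threshold(self.ce, self.threshold)


class CEAModel:
    """Both decision-tree arms over an annual demand registry."""

    def __init__(
        self,
        demand_registry: Sequence[PatientRecord],
        catalog: DiseaseCatalog,
        treatment: TreatmentParams,
        params: ModelParams | None = None,
        threshold: float = defaults.THRESHOLD_USD_PER_DALY,
        calibration: CalibrationInfo | None = None,
    ) -> None:
        if not demand_registry:
            raise ModelError("demand registry must not be empty")
        self.registry = list(demand_registry)
        self.catalog = catalog
        self.treatment = treatment
        self.params = params or ModelParams(
            p_dbd=treatment.p_dbd, p_st=treatment.p_st
        )
        self.threshold = threshold
        self.calibration = calibration

    # -- construction -------------------------------------------------------

    @classmethod
    def default(
        cls,
        seed: int = 0,
        registry_params: RegistryParams | None = None,
        catalog: DiseaseCatalog | None = None,
        calibrate: bool = True,
        threshold: float = defaults.THRESHOLD_USD_PER_DALY,
    ) -> "CEAModel":
        """The shipped study conditions: a synthetic annual demand registry of
        343 cases and a catalog calibrated to the two arms' annual DALY totals."""
        ss = np.random.SeedSequence(seed)
        reg_seed = int(ss.generate_state(1)[0] % (2**31))
        if registry_params is None:
            registry_params = replace(
                default_registry_params(seed=reg_seed),
                n_cases=defaults.OR_ANNUAL_VOLUME,
                months_span=12.0,
            )
        registry = generate_registry(registry_params)
        cat = catalog or default_catalog()
        tp = TreatmentParams()
        info = None
        if calibrate:
            cat, tp, info = calibrate_catalog(
                cat,
                registry,
                tp,
                DiscountSpec(defaults.DISCOUNT_RATE),
                defaults.SOC_ANNUAL_DALYS,
                defaults.OR_ANNUAL_DALYS,
                (defaults.SOC_ANNUAL_VOLUME, defaults.OR_ANNUAL_VOLUME),
            )
        params = ModelParams(p_dbd=tp.p_dbd, p_st=tp.p_st)
        return cls(registry, cat, tp, params, threshold, info)

    # -- override machinery --------------------------------------------------

    def _apply_overrides(self, overrides: Mapping[str, float]) -> tuple[ModelParams, DiseaseCatalog]:
        scalar = {}
        entry_overrides: dict[str, dict[str, float]] = {}
        valid_fields = set(ModelParams.__dataclass_fields__)
        for name, value in overrides.items():
            if ":" in name:
                fieldname, dx = name.split(":", 1)
                if fieldname not in ("dw_untreated", "dw_residual"):
                    raise ModelError(f"unknown per-diagnosis override {name!r}")
                if dx not in self.catalog.entries:
                    raise ModelError(f"override {name!r}: unknown diagnosis {dx!r}")
                entry_overrides.setdefault(dx, {})[fieldname] = float(value)
            elif name in valid_fields:
                scalar[name] = float(value)
            else:
                raise ModelError(f"unknown model parameter {name!r}")
        params = replace(self.params, **scalar)

        entries: dict[str, DiseaseEntry] = {}
        for dx, e in self.catalog.entries.items():
            ov = entry_overrides.get(dx, {})
            dw_u = ov.get("dw_untreated", e.dw_untreated) * params.dw_scale
            dw_r = ov.get("dw_residual", e.dw_residual) * params.dw_scale
            dw_u = min(1.0, max(0.0, dw_u))
            dw_r = min(dw_u, max(0.0, dw_r))   # residual never above untreated
            entries[dx] = replace(e, dw_untreated=dw_u, dw_residual=dw_r)
        catalog = DiseaseCatalog(entries=entries, life_expectancy=params.life_expectancy)
        return params, catalog

    def _ledgers(
        self, params: ModelParams, n_soc: float, n_or: float, fixed_scale: float
    ) -> tuple[CostLedger, CostLedger]:
        rates = VariableRates(
            disposables_per_case=params.disposables_per_case,
            meds_per_case=params.meds_per_case,
            utilities_per_case=params.utilities_per_case,
            hospital_day_cost=params.hospital_day_cost,
            mean_los_days=params.mean_los_days,
            oop_per_case=params.oop_per_case,
        )
        fixed = [
            CostComponent(
                "durable equipment (annualized)", "charity", "fixed",
                params.equipment_annual * fixed_scale,
            ),
            CostComponent(
                "shipping and installation", "charity", "fixed",
                params.shipping_annual * fixed_scale,
            ),
            CostComponent(
                "charity administrative overhead", "charity", "fixed",
                params.overhead_annual * fixed_scale,
            ),
        ]
        soc = costing.build_ledger([], 0.0, costing.variable_costs(rates, n_soc))
        orr = costing.build_ledger(
            fixed,
            params.personnel_annual * fixed_scale,
            costing.variable_costs(rates, n_or),
        )
        return soc, orr

    # -- evaluation -----------------------------------------------------------

    def evaluate(
        self,
        caseload: float | None = None,
        caseload_mode: str = "per_case",
        selection: str = "expected",
        selection_seed: int | None = None,
        **overrides: float,
    ) -> EvalResult:
        """Evaluate both arms and their incremental comparison.

        ``caseload`` replaces the annual demand volume (for probabilistic
        batches); under ``caseload_mode="per_case"`` the fixed components are
        rescaled by caseload / base volume.
        """
        if caseload_mode not in ("per_case", "fixed_annual"):
            raise ModelError(f"unknown caseload_mode {caseload_mode!r}")
        params, catalog = self._apply_overrides(overrides)
        disc = DiscountSpec(params.discount_rate)
        tp = TreatmentParams(p_dbd=params.p_dbd, p_st=params.p_st)

        n_or = float(caseload) if caseload is not None else params.annual_volume
        if n_or <= 0:
            raise ModelError(f"annual caseload must be positive, got {n_or}")
        n_soc = params.soc_volume_fraction * n_or
        fixed_scale = (
            n_or / params.annual_volume
            if (caseload is not None and caseload_mode == "per_case")
            else 1.0
        )

        soc_ledger, or_ledger = self._ledgers(params, n_soc, n_or, fixed_scale)
        soc_spec = ScenarioSpec("standard_of_care", n_soc, soc_ledger, tp)
        or_spec = ScenarioSpec("pediatric_or", n_or, or_ledger, tp, p_no_or=0.0)

        soc = evaluate_arm(
            soc_spec, self.registry, catalog, disc,
            selection=selection, seed=selection_seed, demand_size=n_or,
        )
        orr = evaluate_arm(
            or_spec, self.registry, catalog, disc,
            selection=selection, seed=selection_seed, demand_size=n_or,
        )
        return EvalResult(soc=soc, orr=orr, ce=icer(soc, orr), threshold=self.threshold)

    def base_case(self) -> EvalResult:
        return self.evaluate()

    def icer_at(self, **overrides: float) -> float:
        """The ICER with the given named overrides (tornado entry point)."""
        return self.evaluate(**overrides).ce.icer
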