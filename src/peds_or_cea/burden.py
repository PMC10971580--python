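"""Disease burden: discounted YLL/YLD and per-case DALYs.

The decision-tree outcome model: an untreated child experiences the natural
course of the disease (death with probability ``p_death_untreated``, else
life with the untreated disability weight). A treated child may die before
discharge (pDBD), otherwise treatment succeeds with probability pST —
leaving either no sequelae or, with probability ``p_residual_after_success``,
a residual burden — or fails, in which case the natural course applies.

Future healthy life-years are discounted continuously at annual rate r:
a stream of L years counts as (1 - exp(-r L)) / r, which tends to L as
r -> 0. No age weighting is applied and disability is constant over time,
so both YLL and YLD streams reduce to disability-weight multiples of the
same discounted-years term.

``calibrate_catalog`` rescales the catalog's (non-public) natural-history
parameters so that the two scenario arms reproduce externally printed annual
DALY totals; the implied per-case burdens d_t (treated) and d_u (untreated)
are solved in closed form and reported alongside the fitted scale factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import defaults
from .registry import PatientRecord

RESIDUAL_CONVENTIONS = ("death_within_year", "lifelong_disability")

__all__ = [
    "BurdenError",
    "CalibrationError",
    "DiscountSpec",
    "DiseaseEntry",
    "DiseaseCatalog",
    "TreatmentParams",
    "CalibrationInfo",
    "remaining_life",
    "discounted_years",
    "daly_untreated",
    "daly_treated",
    "dalys_averted",
    "calibrate_catalog",
    "default_catalog",
    "read_catalog",
    "write_catalog",
]


class BurdenError(ValueError):
    """Invalid burden-model input."""


class CalibrationError(BurdenError):
    """Calibration targets are infeasible for the catalog family."""


@dataclass(frozen=True)
class DiscountSpec:
    """Annual time discount on future health (dimensionless rate)."""

    rate: float = defaults.DISCOUNT_RATE

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 0.10:
            raise BurdenError(f"discount rate must be in [0, 0.10], got {self.rate}")


@dataclass(frozen=True)
class DiseaseEntry:
    """Natural-history and treatment parameters for one diagnosis group."""

    diagnosis: str
    p_death_untreated: float
    dw_untreated: float
    dw_residual: float
    p_residual_after_success: float
    residual_convention: str = "lifelong_disability"

    def __post_init__(self) -> None:
        for name in (
            "p_death_untreated",
            "dw_untreated",
            "dw_residual",
            "p_residual_after_success",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise BurdenError(f"{self.diagnosis}: {name} must be in [0, 1], got {v}")
        if self.dw_residual > self.dw_untreated + 1e-12:
            raise BurdenError(
                f"{self.diagnosis}: dw_residual ({self.dw_residual}) must not exceed "
                f"dw_untreated ({self.dw_untreated})"
            )
        if self.residual_convention not in RESIDUAL_CONVENTIONS:
            raise BurdenError(
                f"{self.diagnosis}: residual_convention must be one of "
                f"{RESIDUAL_CONVENTIONS}, got {self.residual_convention!r}"
            )


@dataclass(frozen=True)
class DiseaseCatalog:
    """Per-diagnosis entries plus the national life expectancy (years)."""

    entries: Mapping[str, DiseaseEntry]
    life_expectancy: float = defaults.LIFE_EXPECTANCY_YEARS

    def __post_init__(self) -> None:
        if self.life_expectancy <= 0:
            raise BurdenError(
                f"life_expectancy must be positive, got {self.life_expectancy}"
            )

    def entry(self, diagnosis: str) -> DiseaseEntry:
        try:
            return self.entries[diagnosis]
        except KeyError:
            raise BurdenError(f"unknown diagnosis {diagnosis!r}") from None


@dataclass(frozen=True)
class TreatmentParams:
    """Perioperative mortality (pDBD) and treatment success (pST)."""

    p_dbd: float = defaults.P_DEATH_BEFORE_DISCHARGE
    p_st: float = defaults.P_SUCCESSFUL_TREATMENT

    def __post_init__(self) -> None:
        for name in ("p_dbd", "p_st"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise BurdenError(f"{name} must be in [0, 1], got {v}")


def default_catalog(life_expectancy: float = defaults.LIFE_EXPECTANCY_YEARS) -> DiseaseCatalog:
    entries = {
        row[0]: DiseaseEntry(*row) for row in defaults.DEFAULT_CATALOG_ROWS
    }
    return DiseaseCatalog(entries=entries, life_expectancy=life_expectancy)


# --- core quantities --------------------------------------------------------

def remaining_life(age_years: float, catalog: DiseaseCatalog) -> float:
    """Remaining life expectancy at surgery: life expectancy minus age."""
    if age_years < 0:
        raise BurdenError(f"age must be non-negative, got {age_years}")
    if age_years >= catalog.life_expectancy:
        raise BurdenError(
            f"age {age_years} is not below life expectancy {catalog.life_expectancy}"
        )
    return catalog.life_expectancy - age_years


def discounted_years(L: float, disc: DiscountSpec) -> float:
    """Present value of a stream of L healthy years at continuous rate r."""
    if L < 0:
        raise BurdenError(f"years must be non-negative, got {L}")
    r = disc.rate
    if r == 0.0:
        return L
    return -math.expm1(-r * L) / r


def _yll(record: PatientRecord, catalog: DiseaseCatalog, disc: DiscountSpec) -> float:
    return discounted_years(remaining_life(record.age_years, catalog), disc)


def daly_untreated(
    record: PatientRecord, catalog: DiseaseCatalog, disc: DiscountSpec
) -> float:
    """Expected DALYs under the natural course of the disease."""
    e = catalog.entry(record.diagnosis)
    Y = _yll(record, catalog, disc)
    return (e.p_death_untreated + (1.0 - e.p_death_untreated) * e.dw_untreated) * Y


def _residual_burden(entry: DiseaseEntry, Y: float) -> float:
    if entry.residual_convention == "death_within_year":
        return Y
    return entry.dw_residual * Y


def daly_treated(
    record: PatientRecord,
    entry: DiseaseEntry,
    tp: TreatmentParams,
    catalog: DiseaseCatalog,
    disc: DiscountSpec,
) -> float:
    """Expected DALYs when operated: perioperative death, success (with or
    without residual burden) or failure back to the natural course."""
    if entry.diagnosis not in catalog.entries:
        raise BurdenError(f"unknown diagnosis {entry.diagnosis!r}")
    Y = _yll(record, catalog, disc)
    untreated_equiv = (
        entry.p_death_untreated + (1.0 - entry.p_death_untreated) * entry.dw_untreated
    ) * Y
    success = entry.p_residual_after_success * _residual_burden(entry, Y)
    return tp.p_dbd * Y + (1.0 - tp.p_dbd) * (
        tp.p_st * success + (1.0 - tp.p_st) * untreated_equiv
    )


def dalys_averted(
    record: PatientRecord,
    entry: DiseaseEntry,
    tp: TreatmentParams,
    catalog: DiseaseCatalog,
    disc: DiscountSpec,
) -> float:
    """Untreated minus treated expected DALYs for one case."""
    return daly_untreated(record, catalog, disc) - daly_treated(
        record, entry, tp, catalog, disc
    )


# --- calibration ------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationInfo:
    """Solved per-case burdens and the applied scale factors."""

    d_treated: float
    d_untreated: float
    untreated_scale: float
    treatment_scale: float
    target_soc_dalys: float
    target_or_dalys: float
    n_soc: int
    n_or: int


def solve_per_case_burdens(
    target_soc_dalys: float,
    target_or_dalys: float,
    n_soc: float,
    n_or: float,
) -> tuple[float, float]:
    """Closed-form per-case treated/untreated burdens implied by two arm totals.

    The intervention arm treats all n_or demand cases (total = n_or * d_t);
    the comparator treats n_soc and leaves n_or - n_soc untreated
    (total = n_soc * d_t + (n_or - n_soc) * d_u).
    """
    if n_soc >= n_or:
        raise CalibrationError(f"n_soc ({n_soc}) must be below n_or ({n_or})")
    if target_soc_dalys <= 0 or target_or_dalys <= 0:
        raise CalibrationError("calibration targets must be positive")
    d_t = target_or_dalys / n_or
    d_u = (target_soc_dalys - n_soc * d_t) / (n_or - n_soc)
    if d_u <= d_t:
        raise CalibrationError(
            f"targets imply untreated burden d_u={d_u:.4g} <= treated d_t={d_t:.4g}; "
            "the comparator arm must accrue more burden per untreated case"
        )
    return d_t, d_u


def _scaled_entries(
    catalog: DiseaseCatalog, f_untreated: float, g_treatment: float
) -> dict[str, DiseaseEntry]:
    out = {}
    for dx, e in catalog.entries.items():
        out[dx] = replace(
            e,
            p_death_untreated=min(1.0, f_untreated * e.p_death_untreated),
            dw_untreated=min(1.0, f_untreated * e.dw_untreated),
            dw_residual=min(1.0, f_untreated * e.dw_residual),
            p_residual_after_success=min(1.0, g_treatment * e.p_residual_after_success),
        )
    return out


def _scaled_tp(tp: TreatmentParams, g_treatment: float) -> TreatmentParams:
    return replace(tp, p_st=1.0 - min(1.0, g_treatment * (1.0 - tp.p_st)))


def _mean_burdens(
    catalog: DiseaseCatalog,
    registry: Sequence[PatientRecord],
    tp: TreatmentParams,
    disc: DiscountSpec,
) -> tuple[float, float]:
    t = np.mean(
        [daly_treated(r, catalog.entry(r.diagnosis), tp, catalog, disc) for r in registry]
    )
    u = np.mean([daly_untreated(r, catalog, disc) for r in registry])
    return float(t), float(u)


def _max_scale(values: Iterable[float]) -> float:
    vals = [v for v in values if v > 0]
    return min((1.0 / v for v in vals), default=float("inf"))


def calibrate_catalog(
    catalog: DiseaseCatalog,
    registry: Sequence[PatientRecord],
    tp: TreatmentParams,
    disc: DiscountSpec,
    target_soc_dalys: float = defaults.SOC_ANNUAL_DALYS,
    target_or_dalys: float = defaults.OR_ANNUAL_DALYS,
    volumes: tuple[int, int] = (defaults.SOC_ANNUAL_VOLUME, defaults.OR_ANNUAL_VOLUME),
) -> tuple[DiseaseCatalog, TreatmentParams, CalibrationInfo]:
    """Rescale catalog parameters so both arms reproduce the target DALY totals.

    Two scalar factors are fitted against the registry's case mix and ages:
    ``untreated_scale`` multiplies every entry's natural-course parameters so
    the mean untreated burden equals d_u, and ``treatment_scale`` multiplies
    the treatment-failure and residual-disability probabilities so the mean
    treated burden equals d_t. Returns the calibrated catalog, the adjusted
    treatment parameters, and the solved per-case burdens.
    """
    if not registry:
        raise CalibrationError("calibration requires a non-empty registry")
    n_soc, n_or = volumes
    d_t, d_u = solve_per_case_burdens(target_soc_dalys, target_or_dalys, n_soc, n_or)

    mean_Y = float(np.mean([_yll(r, catalog, disc) for r in registry]))
    if d_u >= mean_Y or d_t >= mean_Y:
        raise CalibrationError(
            f"targets imply per-case burden above the registry's mean discounted "
            f"remaining life ({mean_Y:.3f} DALYs/case)"
        )

    # 1) untreated scale: mean untreated burden -> d_u (monotone in f).
    f_hi = _max_scale(
        v
        for e in catalog.entries.values()
        for v in (e.p_death_untreated, e.dw_untreated)
    )
    f_hi = min(f_hi, 1e6)

    def untreated_gap(f: float) -> float:
        cat = DiseaseCatalog(_scaled_entries(catalog, f, 1.0), catalog.life_expectancy)
        return _mean_burdens(cat, registry, tp, disc)[1] - d_u

    if untreated_gap(f_hi) < 0:
        raise CalibrationError(
            "untreated-burden target is infeasible: would require probabilities "
            "or disability weights above 1"
        )
    f = optimize.brentq(untreated_gap, 0.0, f_hi, xtol=1e-12, rtol=1e-14)

    # 2) treatment scale: mean treated burden -> d_t given the untreated fit.
    g_hi = min(
        _max_scale([1.0 - tp.p_st]),
        _max_scale(e.p_residual_after_success for e in catalog.entries.values()),
        1e6,
    )

    def treated_gap(g: float) -> float:
        cat = DiseaseCatalog(_scaled_entries(catalog, f, g), catalog.life_expectancy)
        return _mean_burdens(cat, registry, _scaled_tp(tp, g), disc)[0] - d_t

    lo, hi = treated_gap(0.0), treated_gap(g_hi)
    if lo > 0:
        raise CalibrationError(
            f"treated-burden target d_t={d_t:.4g} is below the perioperative-death "
            "floor; it is infeasible for the given pDBD"
        )
    if hi < 0:
        raise CalibrationError(
            "treated-burden target is infeasible: residual/failure probabilities "
            "would need to exceed 1"
        )
    g = optimize.brentq(treated_gap, 0.0, g_hi, xtol=1e-12, rtol=1e-14)

    calibrated = DiseaseCatalog(_scaled_entries(catalog, f, g), catalog.life_expectancy)
    info = CalibrationInfo(
        d_treated=d_t,
        d_untreated=d_u,
        untreated_scale=f,
        treatment_scale=g,
        target_soc_dalys=target_soc_dalys,
        target_or_dalys=target_or_dalys,
        n_soc=n_soc,
        n_or=n_or,
    )
    return calibrated, _scaled_tp(tp, g), info


# --- catalog CSV I/O --------------------------------------------------------

_CATALOG_COLUMNS = [
    "diagnosis",
    "p_death_untreated",
    "dw_untreated",
    "dw_residual",
    "p_residual_after_success",
    "residual_convention",
]


def write_catalog(catalog: DiseaseCatalog, path) -> None:
    rows = [
        {
            "diagnosis": e.diagnosis,
            "p_death_untreated": e.p_death_untreated,
            "dw_untreated": e.dw_untreated,
            "dw_residual": e.dw_residual,
            "p_residual_after_success": e.p_residual_after_success,
            "residual_convention": e.residual_convention,
        }
        for e in catalog.entries.values()
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, index=False)


def read_catalog(
    path, life_expectancy: float = defaults.LIFE_EXPECTANCY_YEARS
) -> DiseaseCatalog:
    df = pd.read_csv(path)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise BurdenError(f"catalog file {path} is missing column(s): {missing}")
    entries = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            e = DiseaseEntry(
                diagnosis=str(row.diagnosis),
                p_death_untreated=float(row.p_death_untreated),
                dw_untreated=float(row.dw_untreated),
                dw_residual=float(row.dw_residual),
                p_residual_after_success=float(row.p_residual_after_success),
                residual_convention=str(row.residual_convention),
            )
        except (BurdenError, ValueError) as exc:
            raise BurdenError(f"catalog file {path}, row {i}: {exc}") from exc
        entries[e.diagnosis] = e
    return DiseaseCatalog(entries=entries, life_expectancy=life_expectancy)
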