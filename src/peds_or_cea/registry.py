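"""Synthetic perioperative patient registry.

Generates, reads, writes and summarizes patient-level registries with the
statistical structure of the hospital's perioperative database: one row per
operated child with age, sex, diagnosis group, urgency, in-hospital outcome
and out-of-pocket spend. Ages are drawn from a gamma law moment-matched
*after* truncation to [0, 18), since the observed SD (4.61 y) exceeds the
mean (3.84 y) and a symmetric nonnegative distribution cannot reproduce
those moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import defaults

MAX_AGE_YEARS = 18.0
SEXES = ("male", "female")
URGENCIES = ("elective", "emergency")

__all__ = [
    "PatientRecord",
    "RegistryParams",
    "RegistrySummary",
    "RegistryError",
    "generate_registry",
    "summarize_registry",
    "read_registry",
    "write_registry",
    "annualized_params",
    "default_registry_params",
]


class RegistryError(ValueError):
    """Invalid registry parameters or malformed registry file."""


@dataclass(frozen=True)
class PatientRecord:
    """One operated child."""

    age_years: float
    sex: str
    diagnosis: str
    urgency: str
    died_before_discharge: bool
    oop_cost: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.age_years < MAX_AGE_YEARS:
            raise RegistryError(
                f"age_years must be in [0, {MAX_AGE_YEARS}), got {self.age_years}"
            )
        if self.sex not in SEXES:
            raise RegistryError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.urgency not in URGENCIES:
            raise RegistryError(
                f"urgency must be one of {URGENCIES}, got {self.urgency!r}"
            )
        if self.oop_cost < 0:
            raise RegistryError(f"oop_cost must be >= 0, got {self.oop_cost}")


@dataclass(frozen=True)
class RegistryParams:
    """Generator parameters for a synthetic registry."""

    n_cases: int = defaults.REGISTRY_N_CASES
    months_span: float = defaults.REGISTRY_MONTHS_SPAN
    age_mean: float = defaults.REGISTRY_AGE_MEAN
    age_sd: float = defaults.REGISTRY_AGE_SD
    p_male: float = defaults.REGISTRY_P_MALE
    p_elective: float = defaults.REGISTRY_P_ELECTIVE
    mortality_elective: float = defaults.MORTALITY_ELECTIVE
    mortality_emergency: float = defaults.MORTALITY_EMERGENCY
    case_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(defaults.DEFAULT_CASE_MIX)
    )
    oop_mean: float = defaults.OOP_PER_CASE_USD
    oop_shape: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise RegistryError(f"n_cases must be positive, got {self.n_cases}")
        if self.months_span <= 0:
            raise RegistryError(f"months_span must be positive, got {self.months_span}")
        if self.age_sd <= 0:
            raise RegistryError(f"age_sd must be positive, got {self.age_sd}")
        if not 0.0 < self.age_mean < MAX_AGE_YEARS:
            raise RegistryError(
                f"age_mean must lie in (0, {MAX_AGE_YEARS}), got {self.age_mean}"
            )
        for name in ("p_male", "p_elective", "mortality_elective", "mortality_emergency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise RegistryError(f"{name} must be a probability in [0, 1], got {v}")
        if not self.case_mix:
            raise RegistryError("case_mix must not be empty")
        for dx, p in self.case_mix.items():
            if not 0.0 <= p <= 1.0:
                raise RegistryError(f"case_mix[{dx!r}] must be in [0, 1], got {p}")
        total = float(sum(self.case_mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise RegistryError(f"case_mix probabilities must sum to 1, got {total}")
        if self.oop_mean <= 0:
            raise RegistryError(f"oop_mean must be positive, got {self.oop_mean}")
        if self.oop_shape <= 0:
            raise RegistryError(f"oop_shape must be positive, got {self.oop_shape}")


@dataclass(frozen=True)
class RegistrySummary:
    """Direct tabulation of a registry (percent scale where named pct/mortality)."""

    n_cases: int
    mean_age: float
    sd_age: float
    pct_male: float
    pct_elective: float
    mortality_overall: float
    mortality_by_urgency: dict[str, float]
    cases_per_month: float
    case_mix_observed: dict[str, float]


def default_registry_params(seed: int = 0) -> RegistryParams:
    """The shipped study conditions (1,068 cases over 3.2 years)."""
    return RegistryParams(seed=seed)


def annualized_params(params: RegistryParams) -> RegistryParams:
    """A 12-month variant with the same monthly throughput and structure."""
    years = params.months_span / 12.0
    return replace(
        params,
        n_cases=int(round(params.n_cases / years)),
        months_span=12.0,
    )


# --- truncated-gamma age sampler -------------------------------------------

def _trunc_gamma_raw_moment(k: float, theta: float, upper: float, order: int) -> float:
    """E[X^order | X < upper] for X ~ Gamma(k, theta), via incomplete gammas."""
    x = upper / theta
    log_ratio = special.gammaln(k + order) - special.gammaln(k)
    p_num = special.gammainc(k + order, x)
    p_den = special.gammainc(k, x)
    if p_den <= 0.0:
        return float("nan")
    return theta**order * math.exp(log_ratio) * p_num / p_den


@lru_cache(maxsize=64)
def _fit_truncated_gamma(mean: float, sd: float, upper: float) -> tuple[float, float]:
    """Gamma (shape, scale) whose truncation to [0, upper) has the target moments."""

    def residual(log_params: np.ndarray) -> np.ndarray:
        k, theta = np.exp(log_params)
        m1 = _trunc_gamma_raw_moment(k, theta, upper, 1)
        m2 = _trunc_gamma_raw_moment(k, theta, upper, 2)
        return np.array([m1 - mean, (m2 - m1**2) - sd**2])

    x0 = np.log([(mean / sd) ** 2, sd**2 / mean])
    sol, info, ier, msg = optimize.fsolve(residual, x0, full_output=True)
    if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-8:
        raise RegistryError(
            f"cannot moment-match a truncated gamma to mean={mean}, sd={sd} "
            f"on [0, {upper}): {msg}"
        )
    k, theta = np.exp(sol)
    return float(k), float(theta)


def _sample_ages(params: RegistryParams, rng: np.random.Generator, n: int) -> np.ndarray:
    k, theta = _fit_truncated_gamma(params.age_mean, params.age_sd, MAX_AGE_YEARS)
    dist = stats.gamma(k, scale=theta)
    cap = dist.cdf(MAX_AGE_YEARS)
    u = rng.uniform(0.0, 1.0, size=n)
    ages = dist.ppf(u * cap)
    # guard against ppf landing exactly on the open upper bound
    return np.clip(ages, 0.0, np.nextafter(MAX_AGE_YEARS, 0.0))


# --- generation ------------------------------------------------------------

def generate_registry(params: RegistryParams) -> list[PatientRecord]:
    """Draw a synthetic registry; a pure function of ``params`` (incl. seed)."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_cases

    ages = _sample_ages(params, rng, n)
    sexes = np.where(rng.uniform(size=n) < params.p_male, "male", "female")
    diagnoses = list(params.case_mix)
    probs = np.array([params.case_mix[d] for d in diagnoses], dtype=float)
    dx = rng.choice(len(diagnoses), size=n, p=probs / probs.sum())
    elective = rng.uniform(size=n) < params.p_elective
    p_death = np.where(elective, params.mortality_elective, params.mortality_emergency)
    died = rng.uniform(size=n) < p_death
    oop = rng.gamma(params.oop_shape, params.oop_mean / params.oop_shape, size=n)

    return [
        PatientRecord(
            age_years=float(ages[i]),
            sex=str(sexes[i]),
            diagnosis=diagnoses[dx[i]],
            urgency="elective" if elective[i] else "emergency",
            died_before_discharge=bool(died[i]),
            oop_cost=float(oop[i]),
        )
        for i in range(n)
    ]


# --- summarization ----------------------------------------------------------

def summarize_registry(
    records: Sequence[PatientRecord], months_span: float
) -> RegistrySummary:
    """Tabulate marginals; percentages are on the 0-100 scale."""
    if not records:
        raise RegistryError("cannot summarize an empty registry")
    if months_span <= 0:
        raise RegistryError(f"months_span must be positive, got {months_span}")
    n = len(records)
    ages = np.array([r.age_years for r in records])
    died = np.array([r.died_before_discharge for r in records])

    by_urgency: dict[str, float] = {}
    for urgency in URGENCIES:
        mask = np.array([r.urgency == urgency for r in records])
        if mask.any():
            by_urgency[urgency] = 100.0 * died[mask].mean()

    mix: dict[str, float] = {}
    for r in records:
        mix[r.diagnosis] = mix.get(r.diagnosis, 0.0) + 1.0
    mix = {dx: 100.0 * c / n for dx, c in sorted(mix.items())}

    return RegistrySummary(
        n_cases=n,
        mean_age=float(ages.mean()),
        sd_age=float(ages.std(ddof=1)) if n > 1 else 0.0,
        pct_male=100.0 * sum(r.sex == "male" for r in records) / n,
        pct_elective=100.0 * sum(r.urgency == "elective" for r in records) / n,
        mortality_overall=100.0 * float(died.mean()),
        mortality_by_urgency=by_urgency,
        cases_per_month=n / months_span,
        case_mix_observed=mix,
    )


# --- CSV I/O ----------------------------------------------------------------

_COLUMNS = ["age_years", "sex", "diagnosis", "urgency", "died_before_discharge", "oop_cost"]


def write_registry(records: Sequence[PatientRecord], path) -> None:
    """Write a registry as UTF-8 comma-separated values with a header row."""
    df = pd.DataFrame(
        {
            "age_years": [r.age_years for r in records],
            "sex": [r.sex for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "urgency": [r.urgency for r in records],
            "died_before_discharge": [r.died_before_discharge for r in records],
            "oop_cost": [r.oop_cost for r in records],
        }
    )
    # %.17g keeps write->read an exact identity for float fields
    df.to_csv(path, index=False, float_format="%.17g")


def read_registry(path, known_diagnoses: Sequence[str] | None = None) -> list[PatientRecord]:
    """Read a registry CSV; reports the offending column or 1-based data row."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"registry file {path} is missing column(s): {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        died = row.died_before_discharge
        if isinstance(died, str):
            died = died.strip().lower() in ("true", "1", "yes")
        try:
            rec = PatientRecord(
                age_years=float(row.age_years),
                sex=str(row.sex),
                diagnosis=str(row.diagnosis),
                urgency=str(row.urgency),
                died_before_discharge=bool(died),
                oop_cost=float(row.oop_cost),
            )
        except (RegistryError, ValueError) as exc:
            raise RegistryError(f"registry file {path}, row {i}: {exc}") from exc
        if known_diagnoses is not None and rec.diagnosis not in known_diagnoses:
            raise RegistryError(
                f"registry file {path}, row {i}: unknown diagnosis {rec.diagnosis!r}"
            )
        records.append(rec)
    return records
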