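"""Run configuration: YAML loading, validation, hashing.

A run is fully reproducible from one configuration: every stochastic stage
(registry generation, Monte Carlo draws, bootstrap) derives its stream from
the single ``seed`` through independent seed-sequence children, and every
output file embeds the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import defaults

__all__ = ["ConfigError", "PsaConfig", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class PsaConfig:
    n_batches: int = defaults.PSA_N_BATCHES
    caseload_low: float = defaults.PSA_CASELOAD_RANGE[0]
    caseload_high: float = defaults.PSA_CASELOAD_RANGE[1]
    n_boot: int = defaults.PSA_N_BOOTSTRAP
    caseload_mode: str = "per_case"


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    discount_rate: float = defaults.DISCOUNT_RATE
    life_expectancy: float = defaults.LIFE_EXPECTANCY_YEARS
    threshold_usd_per_daly: float = defaults.THRESHOLD_USD_PER_DALY
    soc_annual_volume: int = defaults.SOC_ANNUAL_VOLUME
    or_annual_volume: int = defaults.OR_ANNUAL_VOLUME
    target_soc_dalys: float = defaults.SOC_ANNUAL_DALYS
    target_or_dalys: float = defaults.OR_ANNUAL_DALYS
    registry_path: str | None = None
    catalog_path: str | None = None
    psa: PsaConfig = field(default_factory=PsaConfig)

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")
        if self.life_expectancy <= 0:
            raise ConfigError("life_expectancy must be positive")
        if self.threshold_usd_per_daly <= 0:
            raise ConfigError("threshold_usd_per_daly must be positive")
        if not 0 < self.soc_annual_volume < self.or_annual_volume:
            raise ConfigError(
                "need 0 < soc_annual_volume < or_annual_volume, got "
                f"{self.soc_annual_volume} / {self.or_annual_volume}"
            )
        if self.psa.n_batches < 1 or self.psa.n_boot < 2:
            raise ConfigError("psa.n_batches must be >= 1 and psa.n_boot >= 2")
        if not self.psa.caseload_low <= self.psa.caseload_high:
            raise ConfigError("psa caseload range is inverted")
        for name in ("registry_path", "catalog_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a YAML config; unknown keys are rejected to catch typos."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    psa_raw = raw.pop("psa", {})
    known = set(RunConfig.__dataclass_fields__) - {"psa"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    unknown_psa = set(psa_raw) - set(PsaConfig.__dataclass_fields__)
    if unknown_psa:
        raise ConfigError(f"unknown psa config key(s): {sorted(unknown_psa)}")
    cfg = RunConfig(psa=PsaConfig(**psa_raw), **raw)
    cfg.validate()
    return cfg
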