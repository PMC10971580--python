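"""One-way (tornado) and probabilistic sensitivity analysis.

Tornado: each parameter is moved alone to the ends of its plausible range
and the full ICER re-evaluated; the span ranks influence.

PSA: each Monte Carlo batch draws a yearly caseload (uniform) and every
uncertain parameter from its assigned family — beta for probabilities and
disability weights, gamma for costs, an empirical resampler for the
perioperative medication rate — re-evaluates both arms, and records the
incremental (cost, DALYs averted, ICER) triple. Distributions are fitted by
method of moments with mean equal to the base value and the variance mapped
from the plausible range as ((high - low) / 3.92)^2, i.e. the range read as
a 95% interval. The headline PSA ICER is the ratio of means (mean
incremental cost over mean DALYs averted); the mean of per-batch ratios is
also reported. Uncertainty intervals are percentile bootstrap over the
batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .model import CEAModel

DISTRIBUTIONS = ("uniform", "beta", "gamma", "empirical", "degenerate")

__all__ = [
    "SensitivityError",
    "ParamSpec",
    "TornadoEntry",
    "PsaSample",
    "PsaResult",
    "one_way",
    "tornado",
    "build_distribution",
    "run_psa",
    "bootstrap_ui",
    "ce_plane",
    "default_tornado_specs",
    "default_psa_specs",
]


class SensitivityError(ValueError):
    """Invalid sensitivity-analysis specification."""


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, plausible range, family."""

    name: str
    base_value: float
    low: float
    high: float
    distribution: str = "uniform"
    dist_params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.low <= self.base_value <= self.high:
            raise SensitivityError(
                f"{self.name}: need low <= base <= high, got "
                f"({self.low}, {self.base_value}, {self.high})"
            )
        if self.distribution not in DISTRIBUTIONS:
            raise SensitivityError(
                f"{self.name}: unknown distribution {self.distribution!r}"
            )


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PsaSample:
    delta_cost: float
    dalys_averted: float
    icer: float

    @property
    def flagged(self) -> bool:
        """Extreme draw with non-positive health benefit."""
        return self.dalys_averted <= 0


@dataclass(frozen=True)
class PsaResult:
    samples: tuple[PsaSample, ...]
    mean_icer: float               # ratio of means (headline)
    mean_of_sample_icers: float
    ui95: tuple[float, float]
    mean_dalys_averted: float
    mean_delta_cost: float
    prob_cost_effective: float
    threshold: float
    n_failed: int = 0


# --- one-way ---------------------------------------------------------------

def one_way(param: ParamSpec, model: CEAModel, rel_tol: float = 1e-6) -> TornadoEntry:
    """Re-evaluate the ICER with one parameter at each end of its range."""
    base = model.icer_at()
    at_base = model.icer_at(**{param.name: param.base_value})
    if not math.isclose(at_base, base, rel_tol=1e-9, abs_tol=1e-9):
        raise SensitivityError(
            f"{param.name}: model does not reproduce the base-case ICER at "
            f"base_value ({at_base:.6g} vs {base:.6g})"
        )
    try:
        lo = model.icer_at(**{param.name: param.low})
    except Exception as exc:
        raise SensitivityError(f"{param.name} at low={param.low}: {exc}") from exc
    try:
        hi = model.icer_at(**{param.name: param.high})
    except Exception as exc:
        raise SensitivityError(f"{param.name} at high={param.high}: {exc}") from exc
    return TornadoEntry(name=param.name, icer_at_low=lo, icer_at_high=hi)


def tornado(params: Sequence[ParamSpec], model: CEAModel) -> list[TornadoEntry]:
    """One-way entries for every parameter, sorted by decreasing span."""
    entries = [one_way(p, model) for p in params]
    return sorted(entries, key=lambda e: e.span, reverse=True)


def tornado_frame(entries: Sequence[TornadoEntry], params: Sequence[ParamSpec]) -> pd.DataFrame:
    ranges = {p.name: (p.low, p.high) for p in params}
    return pd.DataFrame(
        [
            {
                "param": e.name,
                "low": ranges[e.name][0],
                "high": ranges[e.name][1],
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "span": e.span,
            }
            for e in entries
        ]
    )


# --- distributions ---------------------------------------------------------

def _range_variance(low: float, high: float) -> float:
    # plausible range read as a central 95% interval
    return ((high - low) / (2.0 * 1.96)) ** 2


class _Sampler:
    def __init__(self, fn: Callable[[np.random.Generator], float], mean: float):
        self._fn = fn
        self.mean = mean

    def sample(self, rng: np.random.Generator) -> float:
        return float(self._fn(rng))


def build_distribution(p: ParamSpec) -> _Sampler:
    """A seedable method-of-moments sampler with mean equal to the base value."""
    if p.distribution == "degenerate":
        return _Sampler(lambda rng: p.base_value, p.base_value)
    if p.distribution == "uniform":
        return _Sampler(lambda rng: rng.uniform(p.low, p.high), (p.low + p.high) / 2.0)
    if p.distribution == "empirical":
        values = np.asarray(p.dist_params.get("values", ()), dtype=float)
        if values.size == 0:
            raise SensitivityError(f"{p.name}: empirical distribution needs 'values'")
        return _Sampler(lambda rng: rng.choice(values), float(values.mean()))

    m = p.base_value
    v = _range_variance(p.low, p.high)
    if v <= 0:
        return _Sampler(lambda rng: m, m)
    if p.distribution == "beta":
        if not (0.0 <= p.low and p.high <= 1.0):
            raise SensitivityError(f"{p.name}: beta range must lie within [0, 1]")
        if v >= m * (1.0 - m):
            raise SensitivityError(
                f"{p.name}: variance {v:.4g} infeasible for a beta with mean {m}"
            )
        common = m * (1.0 - m) / v - 1.0
        a, b = m * common, (1.0 - m) * common
        return _Sampler(lambda rng: rng.beta(a, b), m)
    if p.distribution == "gamma":
        if m <= 0:
            raise SensitivityError(f"{p.name}: gamma requires a positive mean")
        shape = m**2 / v
        scale = v / m
        return _Sampler(lambda rng: rng.gamma(shape, scale), m)
    raise SensitivityError(f"{p.name}: unknown distribution {p.distribution!r}")


# --- default uncertain-parameter sets --------------------------------------

def _cost_range(base: float) -> tuple[float, float]:
    d = defaults.RELATIVE_COST_RANGE
    return base * (1.0 - d), base * (1.0 + d)


def _prob_range(base: float) -> tuple[float, float]:
    d = defaults.ABSOLUTE_PROB_RANGE
    return max(0.0, base - d), min(1.0, base + d)


def default_tornado_specs(model: CEAModel) -> list[ParamSpec]:
    """The one-way ranges: service volume fraction, discounting, life
    expectancy, perioperative mortality, and the major cost components."""
    p = model.params
    specs = [
        ParamSpec("soc_volume_fraction", p.soc_volume_fraction, 0.0, 0.90),
        ParamSpec("discount_rate", p.discount_rate, *defaults.DISCOUNT_RATE_RANGE),
        ParamSpec("life_expectancy", p.life_expectancy, *_cost_range(p.life_expectancy)),
        ParamSpec("p_dbd", p.p_dbd, defaults.P_DBD_RANGE[0], defaults.P_DBD_RANGE[1]),
        ParamSpec("equipment_annual", p.equipment_annual, *_cost_range(p.equipment_annual)),
        ParamSpec("shipping_annual", p.shipping_annual, *_cost_range(p.shipping_annual)),
        ParamSpec("overhead_annual", p.overhead_annual, *_cost_range(p.overhead_annual)),
        ParamSpec("personnel_annual", p.personnel_annual, *_cost_range(p.personnel_annual)),
        ParamSpec("hospital_day_cost", p.hospital_day_cost, *_cost_range(p.hospital_day_cost)),
        ParamSpec("oop_per_case", p.oop_per_case, *_cost_range(p.oop_per_case)),
    ]
    return specs


def default_psa_specs(model: CEAModel) -> list[ParamSpec]:
    """The uncertain-parameter table: caseload uniform; probabilities and
    disability weights beta; costs gamma; medication rate empirical."""
    p = model.params
    lo, hi = defaults.PSA_CASELOAD_RANGE
    specs = [
        ParamSpec("annual_caseload", (lo + hi) / 2.0, lo, hi, "uniform"),
        ParamSpec("p_dbd", p.p_dbd, *defaults.P_DBD_RANGE, "beta"),
        ParamSpec("p_st", p.p_st, *_prob_range(p.p_st), "beta"),
        ParamSpec("equipment_annual", p.equipment_annual, *_cost_range(p.equipment_annual), "gamma"),
        ParamSpec("shipping_annual", p.shipping_annual, *_cost_range(p.shipping_annual), "gamma"),
        ParamSpec("personnel_annual", p.personnel_annual, *_cost_range(p.personnel_annual), "gamma"),
        ParamSpec("disposables_per_case", p.disposables_per_case, *_cost_range(p.disposables_per_case), "gamma"),
        ParamSpec(
            "meds_per_case",
            p.meds_per_case,
            *_cost_range(p.meds_per_case),
            "empirical",
            # mean-preserving empirical grid over the plausible range
            {"values": tuple(p.meds_per_case * f for f in (0.8, 0.9, 1.0, 1.1, 1.2))},
        ),
        ParamSpec("hospital_day_cost", p.hospital_day_cost, *_cost_range(p.hospital_day_cost), "gamma"),
        ParamSpec("oop_per_case", p.oop_per_case, *_cost_range(p.oop_per_case), "gamma"),
    ]
    for dx, entry in model.catalog.entries.items():
        if entry.dw_untreated > 0:
            specs.append(
                ParamSpec(
                    f"dw_untreated:{dx}", entry.dw_untreated,
                    *_prob_range(entry.dw_untreated), "beta",
                )
            )
        if entry.dw_residual > 0:
            specs.append(
                ParamSpec(
                    f"dw_residual:{dx}", entry.dw_residual,
                    *_prob_range(entry.dw_residual), "beta",
                )
            )
    return specs


# --- PSA --------------------------------------------------------------------

def run_psa(
    model: CEAModel,
    specs: Sequence[ParamSpec] | None = None,
    n_batches: int = defaults.PSA_N_BATCHES,
    seed: int = 0,
    threshold: float | None = None,
    caseload_mode: str = "per_case",
    n_boot: int = defaults.PSA_N_BOOTSTRAP,
) -> PsaResult:
    """Monte Carlo over yearly caseloads and the uncertain-parameter table.

    Fully reproducible from ``seed``: parameter draws and the bootstrap use
    independent child streams of one seed sequence. Batches whose evaluation
    fails are excluded and counted in ``n_failed``.
    """
    if n_batches < 1:
        raise SensitivityError(f"n_batches must be >= 1, got {n_batches}")
    if specs is None:
        specs = default_psa_specs(model)
    threshold = model.threshold if threshold is None else threshold

    ss = np.random.SeedSequence(seed)
    draw_ss, boot_ss = ss.spawn(2)
    rng = np.random.default_rng(draw_ss)

    samplers = {s.name: build_distribution(s) for s in specs}
    samples: list[PsaSample] = []
    n_failed = 0
    for _ in range(n_batches):
        draws = {name: smp.sample(rng) for name, smp in samplers.items()}
        caseload = draws.pop("annual_caseload", None)
        try:
            res = model.evaluate(
                caseload=caseload, caseload_mode=caseload_mode, **draws
            )
        except Exception:
            n_failed += 1
            continue
        ce = res.ce
        ratio = ce.delta_cost / ce.delta_dalys_averted if ce.delta_dalys_averted != 0 else float("nan")
        samples.append(
            PsaSample(
                delta_cost=ce.delta_cost,
                dalys_averted=ce.delta_dalys_averted,
                icer=ratio,
            )
        )
    if not samples:
        raise SensitivityError("every PSA batch failed")

    dc = np.array([s.delta_cost for s in samples])
    de = np.array([s.dalys_averted for s in samples])
    ratio_of_means = float(dc.mean() / de.mean()) if de.mean() != 0 else float("nan")
    ui = bootstrap_ui(samples, n_boot=n_boot, seed=int(boot_ss.generate_state(1)[0] % (2**31)))
    nmb = threshold * de - dc
    return PsaResult(
        samples=tuple(samples),
        mean_icer=ratio_of_means,
        mean_of_sample_icers=float(np.mean([s.icer for s in samples])),
        ui95=ui,
        mean_dalys_averted=float(de.mean()),
        mean_delta_cost=float(dc.mean()),
        prob_cost_effective=float((nmb > 0).mean()),
        threshold=threshold,
        n_failed=n_failed,
    )


def _ratio_of_means(samples: Sequence[PsaSample]) -> float:
    dc = np.mean([s.delta_cost for s in samples])
    de = np.mean([s.dalys_averted for s in samples])
    return float(dc / de) if de != 0 else float("nan")


def bootstrap_ui(
    samples: Sequence[PsaSample] | Sequence[float],
    n_boot: int = defaults.PSA_N_BOOTSTRAP,
    level: float = 0.95,
    seed: int = 0,
    statistic: Callable[[Sequence[PsaSample]], float] | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap of the summary ICER over PSA batches.

    Resamples batches with replacement and recomputes the summary statistic
    (default: ratio of means for PsaSamples, plain mean for numbers).
    """
    if len(samples) < 2:
        raise SensitivityError("bootstrap requires at least 2 samples")
    if n_boot < 2:
        raise SensitivityError(f"n_boot must be >= 2, got {n_boot}")
    if not 0.0 < level < 1.0:
        raise SensitivityError(f"level must be in (0, 1), got {level}")

    items = list(samples)
    if statistic is None:
        if isinstance(items[0], PsaSample):
            statistic = _ratio_of_means
        else:
            statistic = lambda xs: float(np.mean(xs))

    rng = np.random.default_rng(seed)
    n = len(items)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        stats[b] = statistic([items[i] for i in idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# --- cost-effectiveness plane -----------------------------------------------

def ce_plane(
    samples: Sequence[PsaSample], threshold: float = defaults.THRESHOLD_USD_PER_DALY
) -> dict:
    """Plot-ready scatter of (DALYs averted, incremental cost) with the ICER
    and threshold ray slopes and the fraction of draws under the threshold."""
    if not samples:
        raise SensitivityError("ce_plane requires at least one sample")
    df = pd.DataFrame(
        {
            "dalys_averted": [s.dalys_averted for s in samples],
            "delta_cost": [s.delta_cost for s in samples],
        }
    )
    df["below_threshold"] = threshold * df["dalys_averted"] - df["delta_cost"] > 0
    return {
        "points": df,
        "icer_slope": _ratio_of_means(samples),
        "threshold_slope": float(threshold),
        "prob_cost_effective": float(df["below_threshold"].mean()),
    }


# --- plotting ---------------------------------------------------------------

def plot_tornado(entries: Sequence[TornadoEntry], base_icer: float, path) -> None:
    """Horizontal-bar tornado diagram (widest span on top), written to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = sorted(entries, key=lambda e: e.span)
    names = [e.name for e in entries]
    lows = np.array([min(e.icer_at_low, e.icer_at_high) for e in entries])
    highs = np.array([max(e.icer_at_low, e.icer_at_high) for e in entries])
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
    ax.barh(names, highs - lows, left=lows, color="#4878a8")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label=f"base case ({base_icer:.0f})")
    ax.set_xlabel("ICER ($ per DALY averted)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(plane: dict, path) -> None:
    """Scatter of PSA draws with ICER and willingness-to-pay rays."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = plane["points"]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(pts["dalys_averted"], pts["delta_cost"], s=12, alpha=0.6)
    xmax = max(float(pts["dalys_averted"].max()), 0.0) * 1.05 + 1e-9
    xs = np.linspace(0.0, xmax, 50)
    ax.plot(xs, plane["icer_slope"] * xs, color="grey", lw=1.5,
            label=f"ICER ({plane['icer_slope']:.0f} $/DALY)")
    ax.plot(xs, plane["threshold_slope"] * xs, color="grey", lw=1.5, ls=":",
            label=f"threshold ({plane['threshold_slope']:.0f} $/DALY)")
    ax.set_xlabel("DALYs averted")
    ax.set_ylabel("incremental cost ($)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
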