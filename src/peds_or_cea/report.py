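"""End-to-end run: registry -> burden -> costing -> tree -> sensitivity.

``run_all`` executes the whole pipeline under one configuration and writes a
report bundle: base-case JSON, cost ledger CSV, tornado CSV (+diagram), PSA
samples CSV, cost-effectiveness-plane CSV (+figure) and a Markdown summary.
Every output embeds the configuration hash and the seed.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import costing, defaults, sensitivity
from .burden import DiscountSpec, TreatmentParams, calibrate_catalog, default_catalog, read_catalog, write_catalog
from .config import RunConfig
from .model import CEAModel, ModelParams
from .registry import default_registry_params, generate_registry, read_registry, write_registry
from .tree import classify_threshold

__all__ = ["ReportError", "build_model", "run_all"]


class ReportError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ReportError:
                raise
            except Exception as exc:
                raise ReportError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@_stage("build_model")
def build_model(cfg: RunConfig) -> CEAModel:
    """Assemble (and calibrate) the model described by a run configuration."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    reg_seed = int(ss.generate_state(1)[0] % (2**31))

    if cfg.registry_path:
        registry = read_registry(cfg.registry_path)
    else:
        params = replace(
            default_registry_params(seed=reg_seed),
            n_cases=cfg.or_annual_volume,
            months_span=12.0,
        )
        registry = generate_registry(params)

    if cfg.catalog_path:
        catalog = read_catalog(cfg.catalog_path, life_expectancy=cfg.life_expectancy)
    else:
        catalog = default_catalog(life_expectancy=cfg.life_expectancy)

    catalog, tp, info = calibrate_catalog(
        catalog,
        registry,
        TreatmentParams(),
        DiscountSpec(cfg.discount_rate),
        cfg.target_soc_dalys,
        cfg.target_or_dalys,
        (cfg.soc_annual_volume, cfg.or_annual_volume),
    )
    params = ModelParams(
        discount_rate=cfg.discount_rate,
        life_expectancy=cfg.life_expectancy,
        annual_volume=float(cfg.or_annual_volume),
        soc_volume_fraction=cfg.soc_annual_volume / cfg.or_annual_volume,
        p_dbd=tp.p_dbd,
        p_st=tp.p_st,
    )
    return CEAModel(registry, catalog, tp, params, cfg.threshold_usd_per_daly, info)


def _write_csv(df: pd.DataFrame, path: Path, meta: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in meta:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def run_all(cfg: RunConfig, out_dir) -> dict:
    """Run the full analysis and write the report bundle into ``out_dir``.

    Returns the base-case/PSA summary dictionary that is also written to
    ``base_case.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = [f"config_sha256={cfg.config_hash}", f"seed={cfg.seed}"]

    model = build_model(cfg)
    write_registry(model.registry, out / "registry.csv")
    write_catalog(model.catalog, out / "catalog_calibrated.csv")

    # base case ------------------------------------------------------------
    try:
        base = model.base_case()
    except Exception as exc:
        raise ReportError(f"stage 'base_case' failed: {exc}") from exc
    classification = classify_threshold(base.ce, cfg.threshold_usd_per_daly)

    # incremental cost ledger ----------------------------------------------
    try:
        n_inc = cfg.or_annual_volume - cfg.soc_annual_volume
        ledger = costing.default_incremental_ledger(n_inc)
        costing.write_ledger(ledger, out / "ledger.csv", meta)
    except Exception as exc:
        raise ReportError(f"stage 'costing' failed: {exc}") from exc

    # tornado ----------------------------------------------------------------
    try:
        specs = sensitivity.default_tornado_specs(model)
        entries = sensitivity.tornado(specs, model)
        _write_csv(sensitivity.tornado_frame(entries, specs), out / "tornado.csv", meta)
        sensitivity.plot_tornado(entries, base.ce.icer, out / "tornado.png")
    except Exception as exc:
        raise ReportError(f"stage 'tornado' failed: {exc}") from exc

    # PSA ---------------------------------------------------------------------
    try:
        psa_ss = np.random.SeedSequence([cfg.seed, 1])
        psa_seed = int(psa_ss.generate_state(1)[0] % (2**31))
        psa = sensitivity.run_psa(
            model,
            n_batches=cfg.psa.n_batches,
            seed=psa_seed,
            threshold=cfg.threshold_usd_per_daly,
            caseload_mode=cfg.psa.caseload_mode,
            n_boot=cfg.psa.n_boot,
        )
        samples_df = pd.DataFrame(
            {
                "batch": np.arange(1, len(psa.samples) + 1),
                "delta_cost": [s.delta_cost for s in psa.samples],
                "dalys_averted": [s.dalys_averted for s in psa.samples],
                "icer": [s.icer for s in psa.samples],
            }
        )
        _write_csv(samples_df, out / "psa_samples.csv", meta)
        plane = sensitivity.ce_plane(psa.samples, cfg.threshold_usd_per_daly)
        _write_csv(plane["points"], out / "ce_plane.csv", meta)
        sensitivity.plot_ce_plane(plane, out / "ce_plane.png")
    except ReportError:
        raise
    except Exception as exc:
        raise ReportError(f"stage 'psa' failed: {exc}") from exc

    summary = {
        "config_sha256": cfg.config_hash,
        "seed": cfg.seed,
        "base_case": {
            "soc": {
                "cost_usd": base.soc.expected_cost,
                "dalys": base.soc.expected_dalys,
                "lives_saved": base.soc.lives_saved,
            },
            "pediatric_or": {
                "cost_usd": base.orr.expected_cost,
                "dalys": base.orr.expected_dalys,
                "lives_saved": base.orr.lives_saved,
            },
            "delta_cost_usd": base.ce.delta_cost,
            "dalys_averted": base.ce.delta_dalys_averted,
            "icer_usd_per_daly": base.ce.icer,
            "cost_per_life_saved_usd": base.ce.cost_per_life_saved,
            "threshold_usd_per_daly": cfg.threshold_usd_per_daly,
            "classification": classification,
        },
        "calibration": {
            "d_treated": model.calibration.d_treated,
            "d_untreated": model.calibration.d_untreated,
        }
        if model.calibration
        else None,
        "psa": {
            "n_batches": cfg.psa.n_batches,
            "mean_icer_usd_per_daly": psa.mean_icer,
            "mean_of_sample_icers": psa.mean_of_sample_icers,
            "ui95": list(psa.ui95),
            "mean_dalys_averted": psa.mean_dalys_averted,
            "mean_delta_cost_usd": psa.mean_delta_cost,
            "prob_cost_effective": psa.prob_cost_effective,
            "n_failed": psa.n_failed,
        },
    }
    with open(out / "base_case.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)

    _write_summary_md(out / "summary.md", cfg, summary)
    return summary


def _write_summary_md(path: Path, cfg: RunConfig, s: dict) -> None:
    b = s["base_case"]
    p = s["psa"]
    lines = [
        "# Cost-effectiveness summary: dedicated pediatric OR installation",
        "",
        f"config `{s['config_sha256']}`, seed {s['seed']}",
        "",
        "| Annually | Standard of care | Pediatric OR | Incremental |",
        "|---|---|---|---|",
        f"| DALYs | {b['soc']['dalys']:.0f} | {b['pediatric_or']['dalys']:.0f} "
        f"| -{b['dalys_averted']:.0f} |",
        f"| Total cost | ${b['soc']['cost_usd']:,.0f} | ${b['pediatric_or']['cost_usd']:,.0f} "
        f"| ${b['delta_cost_usd']:,.0f} |",
        f"| ICER | | | ${b['icer_usd_per_daly']:,.0f} per DALY averted |",
        "",
        f"Willingness-to-pay threshold: ${b['threshold_usd_per_daly']:,.0f} per DALY "
        f"averted; classification: **{b['classification']}**.",
        f"Cost per life saved: ${b['cost_per_life_saved_usd']:,.0f}.",
        "",
        f"PSA ({p['n_batches']} batches): mean ICER ${p['mean_icer_usd_per_daly']:,.0f} "
        f"per DALY averted (95% UI {p['ui95'][0]:,.0f}-{p['ui95'][1]:,.0f}); "
        f"P(cost-effective) = {p['prob_cost_effective']:.2f}.",
        "",
    ]
    path.write_text("\n".join(lines), encoding="utf-8")
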