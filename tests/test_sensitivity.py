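"""Tornado analysis, distribution fitting, PSA and bootstrap."""

import numpy as np
import pytest

from peds_or_cea.sensitivity import (
    ParamSpec,
    PsaSample,
    SensitivityError,
    bootstrap_ui,
    build_distribution,
    ce_plane,
    default_psa_specs,
    default_tornado_specs,
    one_way,
    run_psa,
    tornado,
)


# --- one-way ----------------------------------------------------------------

def test_one_way_reevaluates_both_endpoints(default_model):
    entry = one_way(
        ParamSpec("discount_rate", 0.03, 0.0, 0.06), default_model
    )
    base = default_model.icer_at()
    assert entry.icer_at_low < base < entry.icer_at_high
    assert entry.span == pytest.approx(entry.icer_at_high - entry.icer_at_low)


def test_one_way_degenerate_range_has_zero_span(default_model):
    entry = one_way(ParamSpec("overhead_annual", 7018.0, 7018.0, 7018.0), default_model)
    assert entry.span == 0.0


def test_one_way_rejects_wrong_base_value(default_model):
    with pytest.raises(SensitivityError, match="base-case"):
        one_way(ParamSpec("discount_rate", 0.05, 0.0, 0.06), default_model)


def test_one_way_names_failing_endpoint(default_model):
    with pytest.raises(SensitivityError, match="discount_rate.*high"):
        one_way(ParamSpec("discount_rate", 0.03, 0.0, 0.5), default_model)


def test_tornado_sorted_by_span_and_directions(default_model):
    entries = tornado(default_tornado_specs(default_model), default_model)
    spans = [e.span for e in entries]
    assert spans == sorted(spans, reverse=True)
    by_name = {e.name: e for e in entries}
    # the comparator volume share and discounting dominate the diagram
    assert by_name["soc_volume_fraction"].span == max(spans)
    assert by_name["discount_rate"].icer_at_low < by_name["discount_rate"].icer_at_high


# --- distributions -----------------------------------------------------------

@pytest.mark.parametrize(
    "spec,expected_mean",
    [
        (ParamSpec("u", 325.0, 250.0, 400.0, "uniform"), 325.0),
        (ParamSpec("b", 0.017, 0.0, 0.217, "beta"), 0.017),
        (ParamSpec("g", 57_435.0, 45_948.0, 68_922.0, "gamma"), 57_435.0),
        (
            ParamSpec("e", 90.0, 72.0, 108.0, "empirical",
                      {"values": (72.0, 81.0, 90.0, 99.0, 108.0)}),
            90.0,
        ),
    ],
)
def test_samplers_recover_target_means(spec, expected_mean):
    sampler = build_distribution(spec)
    rng = np.random.default_rng(12345)
    draws = np.array([sampler.sample(rng) for _ in range(10_000)])
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - expected_mean) < 3 * se
    if spec.distribution == "beta":
        assert ((draws >= 0) & (draws <= 1)).all()


def test_beta_infeasible_variance_raises():
    # mean 0.5 with a range so wide the implied variance exceeds m(1-m)
    spec = ParamSpec("b", 0.999, 0.0, 1.0, "beta")
    with pytest.raises(SensitivityError, match="infeasible"):
        build_distribution(spec)


def test_beta_requires_unit_interval():
    with pytest.raises(SensitivityError, match="0, 1"):
        build_distribution(ParamSpec("b", 2.0, 1.0, 3.0, "beta"))


def test_empirical_requires_values():
    with pytest.raises(SensitivityError, match="values"):
        build_distribution(ParamSpec("e", 1.0, 0.0, 2.0, "empirical"))


# --- PSA ----------------------------------------------------------------------

def degenerate_specs(model):
    p = model.params
    return [
        ParamSpec("annual_caseload", p.annual_volume, p.annual_volume, p.annual_volume, "degenerate"),
        ParamSpec("p_dbd", p.p_dbd, p.p_dbd, p.p_dbd, "degenerate"),
        ParamSpec("equipment_annual", p.equipment_annual, p.equipment_annual, p.equipment_annual, "degenerate"),
    ]


def test_zero_variance_psa_collapses_to_base_case(default_model):
    base = default_model.base_case().ce
    res = run_psa(default_model, specs=degenerate_specs(default_model), n_batches=10, seed=4)
    for s in res.samples:
        assert s.icer == base.icer
        assert s.delta_cost == base.delta_cost
        assert s.dalys_averted == base.delta_dalys_averted
    assert res.mean_icer == pytest.approx(base.icer, abs=1e-12)


def test_caseload_scaling_preserves_icer_in_per_case_mode(default_model):
    """In the per-patient tree view the drawn caseload scales costs and
    effects together, leaving each batch's ICER at the base value."""
    specs = [ParamSpec("annual_caseload", 325.0, 250.0, 400.0, "uniform")]
    res = run_psa(default_model, specs=specs, n_batches=20, seed=9)
    base = default_model.base_case().ce.icer
    for s in res.samples:
        assert s.icer == pytest.approx(base, rel=1e-12)
    averted = np.array([s.dalys_averted for s in res.samples])
    assert averted.std() > 0  # the caseload itself does vary


def test_psa_seed_determinism(default_model):
    r1 = run_psa(default_model, n_batches=30, seed=17)
    r2 = run_psa(default_model, n_batches=30, seed=17)
    assert r1 == r2
    r3 = run_psa(default_model, n_batches=30, seed=18)
    assert r3.mean_icer != r1.mean_icer


def test_psa_summary_fields(default_model):
    res = run_psa(default_model, n_batches=60, seed=2)
    assert res.n_failed == 0
    assert len(res.samples) == 60
    assert 0.0 <= res.prob_cost_effective <= 1.0
    assert res.ui95[0] <= res.ui95[1]
    # uncertainty of the 100-batch mean is on the scale of the published
    # interval (width ~21 $/DALY), far smaller than the ICER itself
    assert 0.0 < res.ui95[1] - res.ui95[0] < 100.0
    assert res.mean_delta_cost == pytest.approx(
        np.mean([s.delta_cost for s in res.samples])
    )


# --- bootstrap ----------------------------------------------------------------

def test_bootstrap_constant_samples_degenerate_interval():
    samples = [PsaSample(100.0, 10.0, 10.0)] * 20
    assert bootstrap_ui(samples, n_boot=50, seed=1) == (10.0, 10.0)


def test_bootstrap_plain_numbers_mean():
    rng = np.random.default_rng(0)
    xs = rng.normal(100.0, 10.0, size=200)
    lo, hi = bootstrap_ui(list(xs), n_boot=200, seed=2)
    assert lo < xs.mean() < hi
    assert hi - lo < 10.0  # interval of the mean, not of the draws


@pytest.mark.parametrize("bad", [0, 1])
def test_bootstrap_rejects_too_few_resamples(bad):
    samples = [PsaSample(1.0, 1.0, 1.0)] * 5
    with pytest.raises(SensitivityError):
        bootstrap_ui(samples, n_boot=bad, seed=1)


def test_bootstrap_rejects_too_few_samples():
    with pytest.raises(SensitivityError, match="2 samples"):
        bootstrap_ui([PsaSample(1.0, 1.0, 1.0)], seed=1)


# --- CE plane -------------------------------------------------------------------

def test_ce_plane_fraction_below_threshold(default_model):
    res = run_psa(default_model, n_batches=50, seed=6)
    plane = ce_plane(res.samples, threshold=1043.0)
    assert plane["threshold_slope"] == 1043.0
    # the simulated cloud sits well under the willingness-to-pay ray
    assert plane["prob_cost_effective"] > 0.9
    assert plane["prob_cost_effective"] == res.prob_cost_effective


def test_ce_plane_all_below_and_empty():
    samples = [PsaSample(10.0, 1.0, 10.0), PsaSample(20.0, 1.0, 20.0)]
    assert ce_plane(samples, threshold=100.0)["prob_cost_effective"] == 1.0
    with pytest.raises(SensitivityError):
        ce_plane([], threshold=100.0)


def test_plots_write_files(default_model, tmp_path):
    from peds_or_cea.sensitivity import plot_ce_plane, plot_tornado

    res = run_psa(default_model, n_batches=20, seed=3)
    plane = ce_plane(res.samples, 1043.0)
    plot_ce_plane(plane, tmp_path / "plane.png")
    entries = tornado(default_tornado_specs(default_model), default_model)
    plot_tornado(entries, default_model.icer_at(), tmp_path / "tornado.png")
    assert (tmp_path / "plane.png").stat().st_size > 0
    assert (tmp_path / "tornado.png").stat().st_size > 0
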