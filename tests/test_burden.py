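"""DALY computation: discounting, tree-leaf oracle, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peds_or_cea.burden import (
    BurdenError,
    CalibrationError,
    DiscountSpec,
    DiseaseCatalog,
    DiseaseEntry,
    TreatmentParams,
    calibrate_catalog,
    daly_treated,
    daly_untreated,
    dalys_averted,
    default_catalog,
    discounted_years,
    read_catalog,
    remaining_life,
    solve_per_case_burdens,
    write_catalog,
)
from peds_or_cea.model import CEAModel
from peds_or_cea.registry import PatientRecord


def record(age=3.84, dx="general_pediatric"):
    return PatientRecord(age, "male", dx, "elective", False, 0.0)


def entry(dx="general_pediatric", p_u=0.5, dw_u=0.5, dw_r=0.1, p_res=0.0,
          convention="lifelong_disability"):
    return DiseaseEntry(dx, p_u, dw_u, dw_r, p_res, convention)


def catalog_of(e, life=54.0):
    return DiseaseCatalog({e.diagnosis: e}, life_expectancy=life)


# --- leaf-enumeration oracle (independent of the implementation) -----------

def leaf_sum_untreated(p_u, dw_u, Y):
    """Exhaustive path enumeration of the natural-course subtree."""
    return p_u * Y + (1 - p_u) * dw_u * Y


def leaf_sum_treated(p_dbd, p_st, p_res, residual, p_u, dw_u, Y):
    """Exhaustive path enumeration of the treated subtree: perioperative
    death / success (with or without residual) / failure to natural course."""
    leaves = [
        (p_dbd, Y),
        ((1 - p_dbd) * p_st * p_res, residual),
        ((1 - p_dbd) * p_st * (1 - p_res), 0.0),
        ((1 - p_dbd) * (1 - p_st) * p_u, Y),
        ((1 - p_dbd) * (1 - p_st) * (1 - p_u), dw_u * Y),
    ]
    assert math.isclose(sum(p for p, _ in leaves), 1.0)
    return sum(p * burden for p, burden in leaves)


# --- remaining life & discounting ------------------------------------------

def test_remaining_life(catalog):
    assert remaining_life(3.84, catalog) == pytest.approx(50.16)
    assert remaining_life(0.0, catalog) == 54.0
    with pytest.raises(BurdenError):
        remaining_life(54.0, catalog)
    with pytest.raises(BurdenError):
        remaining_life(-1.0, catalog)


def test_discounted_years_values():
    assert discounted_years(10.0, DiscountSpec(0.0)) == 10.0
    assert discounted_years(0.0, DiscountSpec(0.05)) == 0.0
    # direct evaluation of (1 - exp(-0.03 * 50.16)) / 0.03
    expected = (1.0 - math.exp(-0.03 * 50.16)) / 0.03
    assert expected == pytest.approx(25.93, abs=0.01)
    assert discounted_years(50.16, DiscountSpec(0.03)) == pytest.approx(expected)
    with pytest.raises(BurdenError):
        discounted_years(-1.0, DiscountSpec(0.03))


def test_discount_zero_rate_limit_is_continuous():
    for L in (1.0, 25.0, 40.0):
        assert discounted_years(L, DiscountSpec(1e-9)) == pytest.approx(
            discounted_years(L, DiscountSpec(0.0)), abs=1e-6
        )


@given(
    L=st.floats(0.1, 54.0),
    r1=st.floats(0.0, 0.099),
    dr=st.floats(1e-4, 0.001),
)
def test_discounted_years_decreasing_in_rate(L, r1, dr):
    assert discounted_years(L, DiscountSpec(r1 + dr)) < discounted_years(
        L, DiscountSpec(r1)
    )


# --- per-case DALYs vs the leaf oracle --------------------------------------

def test_daly_untreated_examples():
    disc = DiscountSpec(0.03)
    Y = discounted_years(50.16, disc)
    cat = catalog_of(entry(p_u=1.0))
    assert daly_untreated(record(), cat, disc) == pytest.approx(Y)
    cat0 = catalog_of(entry(p_u=0.0, dw_u=0.0, dw_r=0.0))
    assert daly_untreated(record(), cat0, disc) == 0.0
    cat5 = catalog_of(entry(p_u=0.5, dw_u=0.5))
    assert daly_untreated(record(), cat5, disc) == pytest.approx(0.75 * Y)
    with pytest.raises(BurdenError, match="unknown diagnosis"):
        daly_untreated(record(dx="nope"), cat, disc)


def test_daly_treated_examples():
    disc = DiscountSpec(0.03)
    Y = discounted_years(50.16, disc)
    e = entry(p_res=0.0)
    cat = catalog_of(e)
    assert daly_treated(record(), e, TreatmentParams(0.0, 1.0), cat, disc) == 0.0
    assert daly_treated(record(), e, TreatmentParams(1.0, 1.0), cat, disc) == pytest.approx(Y)
    got = daly_treated(record(), e, TreatmentParams(0.017, 1.0), cat, disc)
    assert got == pytest.approx(0.017 * Y)


@given(
    age=st.floats(0.0, 17.99),
    p_u=st.floats(0.0, 1.0),
    dw_u=st.floats(0.0, 1.0),
    dw_r_frac=st.floats(0.0, 1.0),
    p_res=st.floats(0.0, 1.0),
    p_dbd=st.floats(0.0, 1.0),
    p_st=st.floats(0.0, 1.0),
    rate=st.floats(0.0, 0.10),
    convention=st.sampled_from(["lifelong_disability", "death_within_year"]),
)
def test_daly_matches_leaf_enumeration_oracle(
    age, p_u, dw_u, dw_r_frac, p_res, p_dbd, p_st, rate, convention
):
    disc = DiscountSpec(rate)
    dw_r = dw_u * dw_r_frac
    e = entry(p_u=p_u, dw_u=dw_u, dw_r=dw_r, p_res=p_res, convention=convention)
    cat = catalog_of(e)
    rec = record(age=age)
    Y = discounted_years(54.0 - age, disc)
    residual = Y if convention == "death_within_year" else dw_r * Y
    assert daly_untreated(rec, cat, disc) == pytest.approx(
        leaf_sum_untreated(p_u, dw_u, Y), abs=1e-12
    )
    tp = TreatmentParams(p_dbd, p_st)
    assert daly_treated(rec, e, tp, cat, disc) == pytest.approx(
        leaf_sum_treated(p_dbd, p_st, p_res, residual, p_u, dw_u, Y), abs=1e-12
    )


@given(p1=st.floats(0.0, 0.99), dp=st.floats(1e-6, 0.01))
def test_daly_treated_nondecreasing_in_perioperative_mortality(p1, dp):
    disc = DiscountSpec(0.03)
    e = entry(p_u=0.3, dw_u=0.4, p_res=0.1, dw_r=0.1)
    cat = catalog_of(e)
    lo = daly_treated(record(), e, TreatmentParams(p1, 0.9), cat, disc)
    hi = daly_treated(record(), e, TreatmentParams(min(1.0, p1 + dp), 0.9), cat, disc)
    assert hi >= lo
    # and the benefit of surgery shrinks accordingly
    assert dalys_averted(record(), e, TreatmentParams(min(1.0, p1 + dp), 0.9), cat, disc) <= (
        dalys_averted(record(), e, TreatmentParams(p1, 0.9), cat, disc)
    )


def test_dalys_averted_examples():
    disc = DiscountSpec(0.03)
    Y = discounted_years(50.16, disc)
    e = entry(p_u=1.0, p_res=0.0)
    cat = catalog_of(e)
    assert dalys_averted(record(), e, TreatmentParams(0.0, 1.0), cat, disc) == pytest.approx(Y)
    # a "treatment" that replicates the natural course averts nothing
    e2 = entry(p_u=0.0, dw_u=0.4, dw_r=0.4, p_res=1.0)
    cat2 = catalog_of(e2)
    assert dalys_averted(record(), e2, TreatmentParams(0.0, 1.0), cat2, disc) == pytest.approx(0.0)


@given(
    p_u=st.floats(0.0, 1.0),
    frac_dbd=st.floats(0.0, 1.0),
    dw_u=st.floats(0.0, 1.0),
    dw_r_frac=st.floats(0.0, 1.0),
    p_res=st.floats(0.0, 1.0),
)
def test_surgery_never_harms_under_certain_success(p_u, frac_dbd, dw_u, dw_r_frac, p_res):
    """With certain treatment success, residual disability no worse than the
    untreated state, and perioperative mortality no higher than untreated
    mortality, surgery cannot increase expected burden."""
    disc = DiscountSpec(0.03)
    e = entry(p_u=p_u, dw_u=dw_u, dw_r=dw_u * dw_r_frac, p_res=p_res)
    cat = catalog_of(e)
    tp = TreatmentParams(p_dbd=p_u * frac_dbd, p_st=1.0)
    assert dalys_averted(record(), e, tp, cat, disc) >= -1e-12


# --- calibration -------------------------------------------------------------

def test_per_case_burdens_match_linear_system():
    """Closed-form solution agrees with solving the 2x2 linear system."""
    A = np.array([[343.0, 0.0], [226.0, 117.0]])
    d_t_expected, d_u_expected = np.linalg.solve(A, [302.0, 840.0])
    d_t, d_u = solve_per_case_burdens(840.0, 302.0, 226, 343)
    assert d_t == pytest.approx(d_t_expected)
    assert d_u == pytest.approx(d_u_expected)
    assert d_t == pytest.approx(0.880, abs=5e-4)
    assert d_u == pytest.approx(5.48, abs=5e-3)


def test_calibration_recovers_targets(annual_registry, disc):
    cat, tp, info = calibrate_catalog(
        default_catalog(), annual_registry, TreatmentParams(), disc, 840.0, 302.0, (226, 343)
    )
    model = CEAModel(annual_registry, cat, tp, calibration=info)
    res = model.base_case()
    assert res.orr.expected_dalys == pytest.approx(302.0, rel=5e-3)
    assert res.soc.expected_dalys == pytest.approx(840.0, rel=5e-3)
    # scaled parameters stay valid probabilities/weights
    for e in cat.entries.values():
        assert 0.0 <= e.p_death_untreated <= 1.0
        assert 0.0 <= e.dw_residual <= e.dw_untreated <= 1.0


def test_calibration_identity_when_targets_equal_current_output(annual_registry, disc):
    cat, tp, info = calibrate_catalog(
        default_catalog(), annual_registry, TreatmentParams(), disc, 840.0, 302.0, (226, 343)
    )
    model = CEAModel(annual_registry, cat, tp)
    base = model.base_case()
    cat2, tp2, info2 = calibrate_catalog(
        cat, annual_registry, tp, disc,
        base.soc.expected_dalys, base.orr.expected_dalys, (226, 343),
    )
    assert info2.untreated_scale == pytest.approx(1.0, abs=1e-6)
    assert info2.treatment_scale == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize(
    "targets",
    [
        (840.0, 343 * 60.0),      # treated burden above any remaining life-years
        (226 * 0.9 + 117 * 30.0, 343 * 0.9),  # untreated burden infeasible
        (300.0, 840.0),           # comparator accruing less than intervention
    ],
)
def test_calibration_infeasible_targets_raise(annual_registry, disc, targets):
    soc, orr = targets
    with pytest.raises(CalibrationError):
        calibrate_catalog(
            default_catalog(), annual_registry, TreatmentParams(), disc, soc, orr, (226, 343)
        )


# --- catalog validation & I/O -----------------------------------------------

def test_entry_rejects_residual_worse_than_untreated():
    with pytest.raises(BurdenError, match="dw_residual"):
        entry(dw_u=0.2, dw_r=0.5)


def test_catalog_csv_roundtrip(tmp_path):
    cat = default_catalog()
    path = tmp_path / "catalog.csv"
    write_catalog(cat, path)
    back = read_catalog(path)
    assert back.entries == cat.entries


def test_catalog_csv_bad_row(tmp_path):
    path = tmp_path / "catalog.csv"
    path.write_text(
        "diagnosis,p_death_untreated,dw_untreated,dw_residual,"
        "p_residual_after_success,residual_convention\n"
        "x,1.5,0.2,0.1,0.0,lifelong_disability\n"
    )
    with pytest.raises(BurdenError, match="row 1"):
        read_catalog(path)
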