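"""Rate fitting, conversions, budget closure and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2otracer.analysis import (
    anova_tukey,
    ara_to_fixation,
    close_budget,
    cumulative_retardation,
    fit_consumption_rate,
    fixation_fraction,
    mean_biomass,
    per_cell_to_specific,
    percent_slowdown,
)
from n2otracer.equilibrium import henry_constant_n2o, n2o_capacity
from n2otracer.isotopes import IsotopePool
from n2otracer.species import NATURAL_ABUNDANCE_15N as NAT
from n2otracer.timeseries import TimeSeries
from n2otracer.vial_gas import VialConfig, headspace_capacity

VIAL = VialConfig(total_volume_ml=100, liquid_volume_ml=30)
K0 = henry_constant_n2o(VIAL.temperature_k)
CAP46_UG = n2o_capacity(VIAL, K0) * VIAL.pressure_atm * 2 * 14  # ug-N per unit x
HEAD_UG = headspace_capacity(VIAL) * VIAL.pressure_atm * 2 * 14


def _ts_from_amounts(n2o_ug_by_day, n30_ug_by_day=None, biomass_g=1e-3):
    """Long-format series whose two-phase N2O amount follows the given ug-N values."""
    rows = []
    for day, ug in n2o_ug_by_day.items():
        rows.append(("v1", "toy", 1, day, "N2O_46", ug / CAP46_UG))
        rows.append(("v1", "toy", 1, day, "biomass_dry_g", biomass_g))
        if n30_ug_by_day is not None:
            rows.append(("v1", "toy", 1, day, "N2_30", n30_ug_by_day[day] / HEAD_UG))
    return TimeSeries.from_records(rows)


def test_fit_recovers_an_exact_line():
    ts = _ts_from_amounts({float(t): 10.0 - 2.0 * t for t in range(5)})
    est = fit_consumption_rate(ts, "N2O_46", (0.0, 4.0), 1e-3, VIAL, k0=K0)
    assert est.slope == pytest.approx(-2.0, rel=1e-9)
    assert est.intercept == pytest.approx(10.0, rel=1e-9)
    assert est.r_squared == pytest.approx(1.0, abs=1e-12)
    assert est.specific_rate == pytest.approx(2000.0, rel=1e-9)
    assert est.n_points == 5


def test_fit_preconditions():
    ts = _ts_from_amounts({0.0: 10.0, 1.0: 8.0})
    with pytest.raises(ValueError):
        fit_consumption_rate(ts, "N2O_46", (0.0, 0.5), 1e-3, VIAL)  # single point
    with pytest.raises(ValueError):
        fit_consumption_rate(ts, "N2O_46", (0.0, 1.0), 0.0, VIAL)  # no biomass


@pytest.mark.parametrize(
    "rate_a, rate_b, expected",
    [(48.7, 127.0, 61.65), (5.0, 5.0, 0.0), (0.0, 3.0, 100.0)],
)
def test_percent_slowdown(rate_a, rate_b, expected):
    assert percent_slowdown(rate_a, rate_b) == pytest.approx(expected, abs=0.01)


def test_percent_slowdown_rejects_zero_reference():
    with pytest.raises(ValueError):
        percent_slowdown(1.0, 0.0)


def test_cumulative_retardation_toy_cases():
    ts_b = _ts_from_amounts({0.0: 10.0, 17.0: 5.0})
    assert cumulative_retardation(ts_b, ts_b, "N2O_46", 17.0, VIAL, K0) == pytest.approx(0.0)
    flat = _ts_from_amounts({0.0: 10.0, 17.0: 10.0})
    assert cumulative_retardation(flat, ts_b, "N2O_46", 17.0, VIAL, K0) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        cumulative_retardation(ts_b, flat, "N2O_46", 17.0, VIAL, K0)


def test_ara_conversion():
    assert ara_to_fixation(3.0) == pytest.approx(28.0)
    assert ara_to_fixation(0.0) == 0.0
    # 2.46e4 ug-N/g/day corresponds to 2.46e4/28*3 umol ethylene
    assert ara_to_fixation(2.46e4 / 28 * 3) == pytest.approx(2.46e4, rel=1e-12)
    assert ara_to_fixation(2636.0) == pytest.approx(2.46e4, rel=2e-3)
    with pytest.raises(ValueError):
        ara_to_fixation(-1.0)


def test_fixation_fraction_printed_values():
    assert fixation_fraction(48.7, 2.46e4) == pytest.approx(0.198, abs=0.001)
    assert fixation_fraction(127.0, 2.46e4) == pytest.approx(0.516, abs=0.001)
    assert fixation_fraction(0.0, 10.0) == 0.0
    with pytest.raises(ValueError):
        fixation_fraction(1.0, 0.0)


def test_per_cell_conversion():
    # 1 fg-N/cell/day at 0.28 pg/cell = 3.57e3 ug-N/g/day
    assert per_cell_to_specific(1e-15) == pytest.approx(3.571e3, rel=1e-3)
    assert per_cell_to_specific(0.0) == 0.0
    assert per_cell_to_specific(1e-15, 0.56) == pytest.approx(per_cell_to_specific(1e-15) / 2)
    with pytest.raises(ValueError):
        per_cell_to_specific(1.0, 0.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6), st.floats(1e-3, 1e3))
def test_rate_comparisons_are_scale_invariant(a, b, c):
    assert percent_slowdown(a * c, b * c) == pytest.approx(
        percent_slowdown(a, b), rel=1e-9, abs=1e-6
    )
    assert fixation_fraction(a * c, b * c) == pytest.approx(fixation_fraction(a, b), rel=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(0.0, 1e5), st.floats(0.1, 10.0))
def test_ara_conversion_is_linear_and_invertible(rate, ratio):
    forward = ara_to_fixation(rate, ratio)
    assert forward == pytest.approx(rate / ratio * 28, rel=1e-12)
    assert forward / 28 * ratio == pytest.approx(rate, rel=1e-12, abs=1e-12)


def test_budget_exact_partition():
    """consumed 10, emitted 6, fixed 4 -> closure 100%, missing 0%."""
    ts = _ts_from_amounts({0.0: 12.0, 17.0: 2.0}, n30_ug_by_day={0.0: 0.0, 17.0: 6.0})
    pool = IsotopePool(1000.0, NAT + 4.0 / 1000.0 * (1 - NAT))  # 4 ug tracer-derived
    report = close_budget(ts, VIAL, biomass_pool=pool, k0=K0)
    assert report.consumed_n2o_ug == pytest.approx(10.0, rel=1e-9)
    assert report.emitted_30n2_ug == pytest.approx(6.0, rel=1e-9)
    assert report.fixed_15n_ug == pytest.approx(4.0, rel=1e-9)
    assert report.closure_percent == pytest.approx(100.0, rel=1e-9)
    assert report.missing_percent == pytest.approx(0.0, abs=1e-9)


def test_budget_flags_no_net_consumption():
    ts = _ts_from_amounts({0.0: 10.0, 17.0: 10.0}, n30_ug_by_day={0.0: 0.0, 17.0: 0.0})
    report = close_budget(ts, VIAL, biomass_pool=IsotopePool(100.0, NAT), k0=K0)
    assert report.no_net_consumption
    assert report.closure_percent is None


def test_mean_biomass_window():
    ts = _ts_from_amounts({0.0: 10.0, 1.0: 9.0, 2.0: 8.0})
    assert mean_biomass(ts, (0.0, 2.0)) == pytest.approx(1e-3)
    with pytest.raises(ValueError):
        mean_biomass(ts, (5.0, 6.0))


# ---------------------------------------------------------------------------
# ANOVA + Tukey


def test_anova_hand_computed_table():
    """3x3 table with textbook arithmetic: SSB=42, SSW=6 -> F = 21."""
    groups = {"A": [1, 2, 3], "B": [2, 3, 4], "C": [6, 7, 8]}
    res = anova_tukey(groups)
    assert res.f_statistic == pytest.approx(21.0, rel=1e-9)
    assert res.p_value < 0.05
    # A vs B: q = 1/sqrt(MSW/n) = 1.73 < q_crit(3, 6) -> shared letter
    assert set(res.letters["A"]) & set(res.letters["B"])
    assert not set(res.letters["C"]) & set(res.letters["A"])
    assert not set(res.letters["C"]) & set(res.letters["B"])


def test_anova_matches_statsmodels_tukey():
    """Independent cross-check of the pairwise p-values."""
    import pandas as pd
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = {"A": [1.0, 2.1, 2.9], "B": [2.2, 3.0, 4.1], "C": [6.1, 7.0, 7.8]}
    res = anova_tukey(groups)
    data = [(k, v) for k, vals in groups.items() for v in vals]
    df = pd.DataFrame(data, columns=["group", "value"])
    sm = pairwise_tukeyhsd(df["value"], df["group"])
    # statsmodels lists pairs of sorted group names in lexicographic order:
    # (A,B), (A,C), (B,C) for three groups
    sm_pairs = [("A", "B"), ("A", "C"), ("B", "C")]
    sm_p = dict(zip(sm_pairs, sm.pvalues))
    for pair, p in res.tukey_p.items():
        assert p == pytest.approx(sm_p[pair], abs=1e-6)


def test_anova_degenerate_groups():
    res = anova_tukey({"A": [2.0, 2.0], "B": [2.0, 2.0], "C": [2.0, 2.0]})
    assert res.p_value == 1.0
    assert set(res.letters.values()) == {"a"}


def test_anova_widely_separated_groups_get_distinct_letters():
    res = anova_tukey(
        {"A": [0.0, 0.1, -0.1], "B": [10.0, 10.1, 9.9], "C": [20.0, 20.1, 19.9]}
    )
    letters = list(res.letters.values())
    assert len(set(letters)) == 3
    assert all(len(v) == 1 for v in letters)


def test_anova_input_validation():
    with pytest.raises(ValueError):
        anova_tukey({"A": [1.0, 2.0]})
    with pytest.raises(ValueError):
        anova_tukey({"A": [1.0], "B": [2.0, 3.0]})
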