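"""Regional aggregation, expected-value totals, period statistics."""

import numpy as np
import pandas as pd
import pytest

from wbcm.model import GridGeometry, LulccRaster, initialize_state, step
from wbcm.report import (
    add_rollups,
    aggregate,
    annual_per_ha,
    area_accounting,
    diff_map,
    expected_totals,
    period_change_tests,
    period_stats,
)

from conftest import uniform_raster


def _areas(rows):
    return pd.DataFrame(rows, columns=["year", "class", "area_mha"])


def test_single_pixel_contribution(param_table, mapping, legend):
    r = uniform_raster(legend["FOR"], shape=(1, 1))
    st = initialize_state(r, param_table, mapping, mode="expected")
    out = aggregate(st, r, mapping)
    scs = out[(out["class"] == "FOR") & (out.reservoir == "SCS100")]["total_tg"].iloc[0]
    assert scs == pytest.approx(0.09 * 82.5 * 1e-6)  # 30 m pixel = 0.09 ha


def test_zero_state_zero_totals(param_table, mapping, legend):
    r = uniform_raster(legend["WATER"], shape=(4, 4))
    st = initialize_state(r, param_table, mapping, mode="expected")
    assert aggregate(st, r, mapping)["total_tg"].abs().sum() == 0


@pytest.mark.parametrize(
    "year,cls,res,area,expect",
    [
        (1990, "FOR", "SCS100", 3.34, 276),
        (2018, "SF", "SCS100", 4.49, 315),
        (2018, "RAG", "SCS100", 3.08, 177),
        (1990, "SF", "AGB", 4.27, 28.9),
        (1990, "FOR", "BGB", 3.34, 28.9),
        (1990, "GF", "BGB", 3.77, 30.6),
    ],
)
def test_expected_totals_reference_cells(param_table, mapping, year, cls, res, area, expect):
    # area (Mha) x class mean (Mg-C/ha) = total (Tg-C)
    out = expected_totals(_areas([(year, cls, area)]), param_table, mapping)
    got = out[out.reservoir == res]["total_tg"].iloc[0]
    assert got == pytest.approx(expect, rel=0.01)


def test_expected_totals_zero_area(param_table, mapping):
    out = expected_totals(_areas([(1990, "FOR", 0.0)]), param_table, mapping)
    assert (out["total_tg"] == 0).all()


def test_area_accounting_and_rollup(legend):
    g = np.full((10, 10), legend["FOR"], dtype=np.uint8)
    g[:, :3] = legend["RAG"]
    g[0, 0] = 0  # nodata
    r = LulccRaster(1990, g, GridGeometry.square((10, 10)))
    areas = area_accounting([r], legend)
    total = areas["area_mha"].sum()
    assert total == pytest.approx(99 * 0.09 / 1e6)
    as_map = areas.set_index("class")["area_mha"]
    assert as_map["RAG"] == pytest.approx(29 * 0.09 / 1e6)


def test_rollups_sum_and_tcs(param_table, mapping):
    areas = _areas([(1990, c, a) for c, a in
                    [("FOR", 3.34), ("SF", 4.27), ("GF", 3.77), ("RAG", 0.84),
                     ("IRR", 0.02), ("PAST", 1.08), ("RAG_PAST", 0.08)]])
    rolled = add_rollups(expected_totals(areas, param_table, mapping))
    nat = rolled[(rolled["class"] == "natural") & (rolled.reservoir == "SCS100")]["total_tg"].iloc[0]
    per = rolled.set_index(["class", "reservoir"])["total_tg"]
    assert nat == pytest.approx(per[("FOR", "SCS100")] + per[("SF", "SCS100")] + per[("GF", "SCS100")])
    tot_tcs = per[("total", "TCS")]
    assert tot_tcs == pytest.approx(
        per[("total", "AGB")] + per[("total", "BGB")] + per[("total", "SCS100")]
    )
    # reference rollup: natural 1990 biomass ~ 82.3 Tg-C
    assert per[("natural", "AGB")] == pytest.approx(82.3, rel=0.01)


def test_period_stats_constant_years(param_table, mapping):
    areas = pd.concat([_areas([(y, "FOR", 2.0)]) for y in range(1990, 1997)])
    totals = expected_totals(areas, param_table, mapping)
    stats_df = period_stats(totals, region_area_mha=2.0, periods=[("P1", 1990, 1996)])
    scs = stats_df[stats_df.reservoir == "SCS100"].iloc[0]
    assert scs["std"] == pytest.approx(0.0)
    assert scs["mean"] == pytest.approx(82.5)
    shares = stats_df[stats_df.reservoir.isin(["AGB", "BGB", "SCS100"])]["pct_share"].sum()
    assert shares == pytest.approx(100.0, abs=0.1)


def test_period_stats_missing_year_raises(param_table, mapping):
    totals = expected_totals(_areas([(1990, "FOR", 1.0)]), param_table, mapping)
    with pytest.raises(ValueError, match="missing years"):
        period_stats(totals, 1.0, periods=[("P1", 1990, 1991)])


def test_period_change_identical_periods(param_table, mapping):
    areas = pd.concat([_areas([(y, "FOR", 2.0)]) for y in range(1990, 2004)])
    totals = expected_totals(areas, param_table, mapping)
    out = period_change_tests(totals, 2.0, ("P1", 1990, 1996), ("P2", 1997, 2003))
    assert (out["pct_change"] == 0).all()
    assert (out["p_value"] == 1.0).all()


def test_pooled_df_7v7_and_7v8():
    rng = np.random.default_rng(0)
    rows = []
    for y in range(1990, 2019):
        for cls, area in [("FOR", 2.0 + 0.01 * rng.normal()), ("RAG", 1.0 + 0.01 * rng.normal())]:
            rows.append((y, cls, area))
    totals_rows = []
    for y, cls, area in rows:
        totals_rows.append((y, cls, "AGB", area * 5))
        totals_rows.append((y, cls, "BGB", area * 3))
        totals_rows.append((y, cls, "SCS100", area * 60))
    totals = pd.DataFrame(totals_rows, columns=["year", "class", "reservoir", "total_tg"])
    out12 = period_change_tests(totals, 3.0, ("P1", 1990, 1996), ("P2", 1997, 2003))
    assert (out12["df"] == 12).all()  # pooled Student: 7 + 7 - 2
    out14 = period_change_tests(totals, 3.0, ("P1", 1990, 1996), ("P4", 2011, 2018))
    assert (out14["df"] == 13).all()  # 7 + 8 - 2


def test_diff_map_examples(param_table, mapping, legend):
    r0 = uniform_raster(legend["FOR"], year=1990, shape=(3, 3))
    r1 = uniform_raster(legend["PAST"], year=1991, shape=(3, 3))
    s0 = initialize_state(r0, param_table, mapping, mode="expected")
    s1 = step(s0, r0, r1, param_table, mapping, mode="expected")
    d = diff_map(s0, s1)
    expect = (1.315 + 2.622 + 51.7) - (12.06 + 8.638 + 82.5)
    assert np.allclose(d, expect)
    assert np.allclose(diff_map(s0, s0), 0.0)
    # diff-map sum times pixel area equals the difference of aggregated totals
    area_ha = s0.geometry.pixel_area_ha
    t0 = aggregate(s0, r0, mapping)["total_tg"].sum()
    t1 = aggregate(s1, r1, mapping)["total_tg"].sum()
    assert np.nansum(d) * area_ha * 1e-6 == pytest.approx(t1 - t0)


def test_diff_map_nodata_propagates(param_table, mapping, legend):
    g = np.full((3, 3), legend["FOR"], dtype=np.uint8)
    g[0, 0] = 0
    r = LulccRaster(1990, g, GridGeometry.square((3, 3)))
    s = initialize_state(r, param_table, mapping, mode="expected")
    d = diff_map(s, s)
    assert np.isnan(d[0, 0]) and np.allclose(d.ravel()[1:], 0.0)


def test_annual_per_ha_units(param_table, mapping):
    totals = expected_totals(_areas([(1990, "FOR", 13.4)]), param_table, mapping)
    per_ha = annual_per_ha(totals, region_area_mha=13.4)
    scs = per_ha[per_ha.reservoir == "SCS100"]["value"].iloc[0]
    assert scs == pytest.approx(82.5)
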