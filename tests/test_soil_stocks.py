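"""Soil stock computation: layer arithmetic, depth truncation,
equivalent-mass correction, and the class summary statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wbcm.soil import (
    SoilLayer,
    SoilProfile,
    compute_stocks,
    cumulative_mass,
    equivalent_mass_stock,
    fixed_depth_stock,
    layer_stock,
    pairwise_ttests,
    pct_difference,
    profiles_from_frame,
    profiles_to_frame,
    reference_mass_for_depth,
    summarize_by_class,
)

from conftest import make_profile


def slab_oracle(profile, reference_mass, slab_cm=0.1):
    """Independent fine-slab integration of the equivalent-mass stock.

    Walks 1 mm slabs from the surface, accumulating soil mass and carbon
    (properties constant within a layer), and linearly interpolates the
    final partial slab.
    """
    import math

    mass = 0.0
    carbon = 0.0
    for lyr in profile.layers:
        n = max(1, math.ceil(lyr.thickness / slab_cm))
        h = lyr.thickness / n  # even slabs no thicker than slab_cm
        dm = lyr.bulk_density * h * 100.0
        dc = lyr.bulk_density * lyr.oc_conc * h * 0.1
        for _ in range(n):
            if mass + dm >= reference_mass:
                frac = (reference_mass - mass) / dm
                return carbon + frac * dc
            mass += dm
            carbon += dc
    return carbon


class TestLayerStock:
    @pytest.mark.parametrize(
        "top,bottom,bd,oc,expected",
        [(0, 30, 1.5, 10, 45.0), (0, 5, 1.2, 20, 12.0), (10, 15, 1.4, 0, 0.0)],
    )
    def test_unit_arithmetic(self, top, bottom, bd, oc, expected):
        assert layer_stock(SoilLayer(top, bottom, bd, oc)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(depth_top=10, depth_bottom=5, bulk_density=1.2, oc_conc=5),
            dict(depth_top=0, depth_bottom=5, bulk_density=-1.0, oc_conc=5),
            dict(depth_top=0, depth_bottom=5, bulk_density=1.2, oc_conc=-1),
        ],
    )
    def test_invalid_layer_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SoilLayer(**kwargs)


class TestFixedDepth:
    def test_boundary_additivity(self):
        p = make_profile(layers=((0, 10), (10, 20)), bd=1.0, oc=10.0)
        # each layer holds 1.0*10*10*0.1 = 10 Mg-C/ha
        assert fixed_depth_stock(p, 10) == pytest.approx(10.0)
        assert fixed_depth_stock(p, 20) == pytest.approx(20.0)

    def test_zero_depth(self):
        assert fixed_depth_stock(make_profile(), 0) == 0.0

    def test_uniform_closed_form(self):
        p = make_profile(bd=1.3, oc=8.0)
        assert fixed_depth_stock(p, 30) == pytest.approx(1.3 * 8.0 * 30 * 0.1)
        assert fixed_depth_stock(p, 100) == pytest.approx(1.3 * 8.0 * 100 * 0.1)

    def test_prorates_inside_layer(self):
        p = make_profile(layers=((0, 40),), bd=1.0, oc=10.0)
        assert fixed_depth_stock(p, 25) == pytest.approx(25.0)

    def test_depth_beyond_profile_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            fixed_depth_stock(make_profile(), 150)


class TestEquivalentMass:
    def test_identity_with_fixed_depth(self):
        p = make_profile(bd=1.0, oc=10.0)
        m = cumulative_mass(p, 30)  # 3000 Mg/ha for BD 1.0
        assert m == pytest.approx(3000.0)
        res = equivalent_mass_stock(p, m)
        assert res.stock == pytest.approx(fixed_depth_stock(p, 30))
        assert not res.extrapolated

    def test_uniform_profile_value(self):
        p = make_profile(bd=1.0, oc=10.0)
        assert equivalent_mass_stock(p, 3000.0).stock == pytest.approx(30.0)

    def test_compacted_profile_matches_slab_oracle(self):
        # compacted topsoil: same reference mass reaches less depth
        p = make_profile(layers=((0, 20), (20, 100)), bd=[1.6, 1.3], oc=[15.0, 5.0])
        ref = 2000.0
        res = equivalent_mass_stock(p, ref)
        assert res.stock == pytest.approx(slab_oracle(p, ref), rel=1e-3)
        assert res.depth_reached < 20

    def test_extrapolation_flagged(self):
        p = make_profile(bd=1.0, oc=10.0)  # total mass 10000 Mg/ha
        res = equivalent_mass_stock(p, 20000.0)
        assert res.extrapolated
        assert res.stock == pytest.approx(fixed_depth_stock(p, 100))

    def test_nonpositive_reference_mass_rejected(self):
        with pytest.raises(ValueError):
            equivalent_mass_stock(make_profile(), 0.0)


class TestReferenceMass:
    def test_single_uniform_profile(self):
        assert reference_mass_for_depth([make_profile(bd=1.0)], 100) == pytest.approx(10000.0)

    def test_mean_of_profiles(self):
        p1, p2 = make_profile(bd=1.0), make_profile(bd=1.4)
        ref = reference_mass_for_depth([p1, p2], 30)
        assert ref == pytest.approx((3000.0 + 4200.0) / 2)
        assert reference_mass_for_depth([p1, p1], 30) == reference_mass_for_depth([p1], 30)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            reference_mass_for_depth([], 30)


class TestSummaries:
    def test_hand_computed_group(self):
        df = pd.DataFrame(
            {"site_id": list("abcd"), "class": "FOR", "depth_cm": 100.0,
             "stock": [1.0, 2.0, 3.0, 4.0]}
        )
        out = summarize_by_class(df)
        row = out.iloc[0]
        assert row["avg"] == pytest.approx(2.5)
        assert row["std"] == pytest.approx(1.2909944)
        assert row["ci"] == pytest.approx(stats.t.ppf(0.975, 3) * 1.2909944 / 2)

    def test_reference_campaign_ci(self):
        # n=19, sd 43.6 -> t-based half width 21.0 (published FOR value)
        ci = stats.t.ppf(0.975, 18) * 43.6 / np.sqrt(19)
        assert ci == pytest.approx(21.0, abs=0.05)

    def test_identical_values_zero_ci(self):
        df = pd.DataFrame(
            {"site_id": ["a", "b", "c"], "class": "X", "depth_cm": 30.0, "stock": 5.0}
        )
        row = summarize_by_class(df).iloc[0]
        assert row["std"] == 0 and row["ci"] == 0

    def test_singleton_group_flagged(self):
        df = pd.DataFrame(
            {"site_id": ["a"], "class": "X", "depth_cm": 30.0, "stock": [5.0]}
        )
        row = summarize_by_class(df).iloc[0]
        assert row["flagged"] and np.isnan(row["std"])


class TestPctDifference:
    def test_native_baseline_headline(self):
        # pasture vs forest full-profile stocks from the field campaign
        assert pct_difference(51.7, 82.5, "baseline_native") == pytest.approx(-37.3, abs=0.05)

    def test_increase_relative_to_pasture(self):
        assert pct_difference(45.5, 28.0, "baseline_native") == pytest.approx(62.5, abs=0.05)

    def test_equal_means_zero(self):
        for conv in ("baseline_native", "baseline_agricultural"):
            assert pct_difference(50.0, 50.0, conv) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            pct_difference(10.0, 0.0, "baseline_native")


class TestPairwiseTTests:
    @staticmethod
    def _frame(groups):
        rows = [
            (f"{c}{i}", c, 100.0, v)
            for c, vals in groups.items()
            for i, v in enumerate(vals)
        ]
        return pd.DataFrame(rows, columns=["site_id", "class", "depth_cm", "stock"])

    def test_identical_groups(self):
        vals = [1.0, 2.0, 3.0]
        out = pairwise_ttests(self._frame({"A": vals, "B": vals}), 100.0)
        assert out.iloc[0]["t_stat"] == pytest.approx(0.0)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_large_separation_significant(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)  # 10 sigma apart
        out = pairwise_ttests(self._frame({"A": a, "B": b}), 100.0)
        assert out.iloc[0]["p_value"] < 1e-6

    def test_all_pairs_present(self):
        rng = np.random.default_rng(4)
        groups = {c: rng.normal(0, 1, 5) for c in "ABCD"}
        out = pairwise_ttests(self._frame(groups), 100.0)
        assert len(out) == 6
        assert set(map(tuple, out[["class_a", "class_b"]].values)) == {
            ("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")
        }

    def test_degenerate_group_flagged_not_dropped(self):
        out = pairwise_ttests(self._frame({"A": [1.0], "B": [1.0, 2.0, 3.0]}), 100.0)
        assert len(out) == 1 and bool(out.iloc[0]["flagged"])

    @pytest.mark.parametrize("variant,df", [("pooled", 8.0)])
    def test_pooled_df(self, variant, df):
        rng = np.random.default_rng(7)
        out = pairwise_ttests(
            self._frame({"A": rng.normal(0, 1, 5), "B": rng.normal(0, 1, 5)}),
            100.0, variant=variant,
        )
        assert out.iloc[0]["df"] == pytest.approx(df)


class TestTabularRoundTrip:
    def test_frame_round_trip(self):
        profs = [make_profile(site_id=f"s{i}", bd=1.2 + 0.1 * i) for i in range(3)]
        back = profiles_from_frame(profiles_to_frame(profs))
        assert [p.site_id for p in back] == [p.site_id for p in profs]
        assert back[1].layers == profs[1].layers

    def test_missing_bulk_density_rejected_with_warning(self):
        frame = profiles_to_frame([make_profile(site_id="ok"), make_profile(site_id="bad")])
        frame.loc[
            (frame["site_id"] == "bad") & (frame["depth_top_cm"] == 0),
            "bulk_density_g_cm3",
        ] = np.nan
        with pytest.warns(UserWarning, match="bad"):
            profs = profiles_from_frame(frame)
        assert [p.site_id for p in profs] == ["ok"]

    def test_compute_stocks_flags_method(self):
        profs = [make_profile(site_id=f"s{i}", lulcc_class="FOR") for i in range(2)]
        out = compute_stocks(profs, method="equivalent_mass")
        assert out.attrs["method"] == "equivalent_mass"
        assert set(out["depth_cm"]) == {30.0, 60.0, 100.0}
        # reference = the profiles themselves -> equivalent mass == fixed depth
        fd = compute_stocks(profs, method="fixed_depth")
        assert np.allclose(out["stock"], fd["stock"])
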