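"""Regional aggregation and summary statistics of carbon states.

Turns per-pixel carbon maps into the study-level products: per-class,
per-reservoir regional totals in Tg-C; per-hectare period statistics
with pooled-variance t-tests between periods; pixelwise total-carbon
difference maps; and class-area accounting. A raster-free expected-value
calculator reproduces the same totals directly from a class-area table
(area in Mha x class mean in Mg-C ha^-1 = total in Tg-C), which serves
as the closed-form oracle for expected-mode runs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CarbonState, ClassMapping, GeometryError, LulccRaster
from .params import RESERVOIRS, CarbonParamTable

__all__ = [
    "NATURAL_CLASSES",
    "AGRICULTURAL_CLASSES",
    "aggregate",
    "expected_totals",
    "area_accounting",
    "add_rollups",
    "period_stats",
    "period_change_tests",
    "diff_map",
    "annual_per_ha",
    "plot_timeseries",
    "DEFAULT_PERIODS",
]

NATURAL_CLASSES = ("FOR", "SF", "GF")
AGRICULTURAL_CLASSES = ("RAG", "IRR", "PAST", "RAG_PAST")

#: Period definitions of the historical analysis (label, first, last year).
DEFAULT_PERIODS = (
    ("P1", 1990, 1996),
    ("P2", 1997, 2003),
    ("P3", 2004, 2010),
    ("P4", 2011, 2018),
)


def aggregate(
    state: CarbonState, lulcc: LulccRaster, mapping: ClassMapping
) -> pd.DataFrame:
    """Per-class regional totals for one year.

    total(class, reservoir) = sum over the class's pixels of
    value (Mg-C ha^-1) x pixel area (ha), converted to Tg-C (1e-6).

    Returns a tidy frame: year, class, reservoir, total_tg.
    """
    if state.geometry != lulcc.geometry:
        raise GeometryError("state and land-cover raster are not co-registered")
    area_ha = state.geometry.pixel_area_ha
    codes = lulcc.grid.ravel()
    name_of = mapping.code_to_name
    rows = []
    for res in RESERVOIRS:
        vals = state.reservoir(res).ravel()
        ok = ~np.isnan(vals)
        sums = np.bincount(codes[ok], weights=vals[ok], minlength=256)
        for code, name in name_of.items():
            if name == "nodata":
                continue
            rows.append((state.year, name, res, sums[code] * area_ha * 1e-6))
    return pd.DataFrame(rows, columns=["year", "class", "reservoir", "total_tg"])


def expected_totals(areas: pd.DataFrame, table: CarbonParamTable,
                    mapping: ClassMapping) -> pd.DataFrame:
    """Raster-free expected totals from a class-area table.

    `areas` is tidy with columns year, class, area_mha. Since
    1 Mha x 1 Mg-C ha^-1 = 1 Tg-C, total = area_mha x class mean.
    Zero-carbon classes contribute zero.
    """
    rows = []
    for year, name, area_mha in areas[["year", "class", "area_mha"]].itertuples(
        index=False, name=None
    ):
        for res in RESERVOIRS:
            if name in mapping.zero_carbon:
                avg = 0.0
            else:
                avg = table.get(mapping.param_class(name, res), res).avg
            rows.append((year, name, res, area_mha * avg))
    return pd.DataFrame(rows, columns=["year", "class", "reservoir", "total_tg"])


def area_accounting(
    series: Sequence[LulccRaster], legend: dict[str, int]
) -> pd.DataFrame:
    """Per-year per-class areas in Mha from a raster series.

    Tidy frame: year, class, area_mha. Nodata is excluded; zero-carbon
    classes are included (they occupy area). The per-year total is
    constant for a closed region.
    """
    rows = []
    for r in series:
        r.validate_codes(legend)
        counts = np.bincount(r.grid.ravel(), minlength=256)
        for name, code in legend.items():
            if name == "nodata":
                continue
            rows.append((r.year, name, counts[code] * r.geometry.pixel_area_ha / 1e6))
    return pd.DataFrame(rows, columns=["year", "class", "area_mha"])


def add_rollups(totals: pd.DataFrame) -> pd.DataFrame:
    """Append natural/agricultural/total rollup rows and a TCS reservoir.

    Input/output are tidy (year, class, reservoir, total_tg); rollup
    rows use the pseudo-classes ``natural``, ``agricultural`` and
    ``total``, and every class additionally gets a ``TCS`` pseudo-
    reservoir equal to AGB + BGB + SCS100.
    """
    base = totals[~totals["class"].isin(["natural", "agricultural", "total"])]
    base = base[base["reservoir"] != "TCS"]
    out = [base]
    for label, members in (
        ("natural", NATURAL_CLASSES),
        ("agricultural", AGRICULTURAL_CLASSES),
        ("total", None),
    ):
        sub = base if members is None else base[base["class"].isin(members)]
        g = sub.groupby(["year", "reservoir"], as_index=False)["total_tg"].sum()
        g.insert(1, "class", label)
        out.append(g)
    stacked = pd.concat(out, ignore_index=True)
    tcs = stacked.groupby(["year", "class"], as_index=False)["total_tg"].sum()
    tcs["reservoir"] = "TCS"
    return pd.concat([stacked, tcs[["year", "class", "reservoir", "total_tg"]]],
                     ignore_index=True)


def annual_per_ha(totals: pd.DataFrame, region_area_mha: float) -> pd.DataFrame:
    """Region-wide annual per-hectare values, Mg-C ha^-1.

    Divides each reservoir's regional total (Tg) by the full region area
    (Mha), including zero-carbon classes in the denominator
    (Tg / Mha = Mg ha^-1). Returns year, reservoir (incl. TCS), value.
    """
    if region_area_mha <= 0:
        raise ValueError("region area must be positive")
    rolled = add_rollups(totals)
    tot = rolled[rolled["class"] == "total"].copy()
    tot["value"] = tot["total_tg"] / region_area_mha
    return tot[["year", "reservoir", "value"]].reset_index(drop=True)


def period_stats(
    totals: pd.DataFrame,
    region_area_mha: float,
    periods: Sequence[tuple[str, int, int]] = DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Mean/sd of annual per-ha values per period and reservoir.

    Also reports each reservoir's percent share of the period's mean
    total carbon stock; shares sum to 100 across AGB/BGB/SCS100.
    Raises if a period year is missing from `totals`.
    """
    per_ha = annual_per_ha(totals, region_area_mha)
    years_present = set(per_ha["year"])
    rows = []
    for label, y0, y1 in periods:
        wanted = set(range(y0, y1 + 1))
        missing = sorted(wanted - years_present)
        if missing:
            raise ValueError(f"period {label}: missing years {missing}")
        sub = per_ha[per_ha["year"].isin(wanted)]
        tcs_mean = sub.loc[sub["reservoir"] == "TCS", "value"].mean()
        for res, grp in sub.groupby("reservoir"):
            vals = grp["value"].to_numpy(float)
            rows.append(
                (label, y0, y1, res, len(vals), float(np.mean(vals)),
                 float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                 100.0 * float(np.mean(vals)) / tcs_mean)
            )
    return pd.DataFrame(
        rows,
        columns=["period", "year_start", "year_end", "reservoir", "n", "mean", "std", "pct_share"],
    )


def period_change_tests(
    totals: pd.DataFrame,
    region_area_mha: float,
    period_a: tuple[str, int, int],
    period_b: tuple[str, int, int],
    variant: str = "pooled",
) -> pd.DataFrame:
    """Percent change of per-ha means between two periods with a
    two-sided two-sample t-test on the annual values.

    The pooled-variance Student variant is the default (df = n_a + n_b -
    2, e.g. 12 for 7 vs 7 years and 13 for 7 vs 8); Welch is available.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    per_ha = annual_per_ha(totals, region_area_mha)
    rows = []
    for res, grp in per_ha.groupby("reservoir"):
        a = grp.loc[grp["year"].between(period_a[1], period_a[2]), "value"].to_numpy(float)
        b = grp.loc[grp["year"].between(period_b[1], period_b[2]), "value"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"period t-test needs >= 2 annual values, reservoir {res}")
        pct = 100.0 * (np.mean(b) - np.mean(a)) / np.mean(a)
        if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
            t, df, p, flagged = 0.0, float(len(a) + len(b) - 2), 1.0, True
        else:
            res_t = stats.ttest_ind(b, a, equal_var=(variant == "pooled"))
            t, df, p, flagged = float(res_t.statistic), float(res_t.df), float(res_t.pvalue), False
        rows.append((f"{period_b[0]}-{period_a[0]}", res, float(pct), t, df, p, flagged))
    return pd.DataFrame(
        rows, columns=["comparison", "reservoir", "pct_change", "t_stat", "df", "p_value", "flagged"]
    )


def diff_map(state_a: CarbonState, state_b: CarbonState) -> np.ndarray:
    """Pixelwise total-carbon difference TCS_b - TCS_a, Mg-C ha^-1.

    NaN wherever either input is nodata.
    """
    if state_a.geometry != state_b.geometry:
        raise GeometryError("difference map inputs are not co-registered")
    return state_b.tcs - state_a.tcs


def plot_timeseries(totals: pd.DataFrame, path=None):
    """Total carbon stock per class per year (one line per class).

    Returns the matplotlib figure; saves to `path` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rolled = add_rollups(totals)
    tcs = rolled[(rolled["reservoir"] == "TCS")
                 & ~rolled["class"].isin(["natural", "agricultural"])]
    fig, ax = plt.subplots(figsize=(8, 5))
    for cls, grp in tcs.groupby("class"):
        grp = grp.sort_values("year")
        ax.plot(grp["year"], grp["total_tg"], label=cls,
                lw=2.5 if cls == "total" else 1.2)
    ax.set_xlabel("year")
    ax.set_ylabel("total carbon stock (Tg-C)")
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
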