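"""Soil carbon stocks from layered profiles.

Computes depth-interval soil carbon stocks from field profiles of bulk
density and organic-carbon concentration, by two conventions:

* **fixed depth** — integrate carbon from the surface down to a nominal
  depth (30, 60 or 100 cm);
* **equivalent soil mass** — integrate carbon down to a fixed *mass* of
  soil taken from native-cover reference profiles, which removes apparent
  stock changes caused purely by compaction-driven bulk-density
  differences in agricultural soils.

Also provides the group summaries (mean, sd, t-based confidence
interval), percentage-difference tables and pairwise two-sample t-tests
used to compare land-use classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "EquivalentMassResult",
    "STANDARD_LAYERS",
    "SOIL_CLASSES",
    "layer_stock",
    "layer_mass",
    "fixed_depth_stock",
    "cumulative_mass",
    "equivalent_mass_stock",
    "reference_mass_for_depth",
    "profiles_from_frame",
    "profiles_to_frame",
    "compute_stocks",
    "summarize_by_class",
    "pct_difference",
    "difference_table",
    "pairwise_ttests",
]

#: Field-campaign sampling design: seven contiguous layers down to 1 m.
STANDARD_LAYERS: tuple[tuple[float, float], ...] = (
    (0, 5), (5, 10), (10, 15), (15, 20), (20, 40), (40, 60), (60, 100),
)

#: Land-use/land-cover classes of the soil sampling campaign. CDO pools
#: savanna and grassland formations of the Cerrado.
SOIL_CLASSES = ("FOR", "CDO", "RAG", "IRR", "PAST")


@dataclass(frozen=True)
class SoilLayer:
    """One sampled depth layer of a soil profile.

    Parameters
    ----------
    depth_top, depth_bottom : float
        Layer bounds in cm below the surface.
    bulk_density : float
        Dry bulk density, g cm^-3.
    oc_conc : float
        Organic-carbon concentration, g C per kg soil.
    """

    depth_top: float
    depth_bottom: float
    bulk_density: float
    oc_conc: float

    def __post_init__(self) -> None:
        if not (self.depth_bottom > self.depth_top >= 0):
            raise ValueError(
                f"invalid layer bounds [{self.depth_top}, {self.depth_bottom}] cm"
            )
        if not self.bulk_density > 0:
            raise ValueError(f"bulk density must be positive, got {self.bulk_density}")
        if self.oc_conc < 0:
            raise ValueError(f"organic C concentration must be >= 0, got {self.oc_conc}")

    @property
    def thickness(self) -> float:
        return self.depth_bottom - self.depth_top


@dataclass(frozen=True)
class SoilProfile:
    """Layered profile of one sampling site.

    Layers must be contiguous and non-overlapping starting at 0 cm. The
    three deep field layers (20-40, 40-60, 60-100 cm) were sampled at
    their mid-points and are treated as homogeneous: each measurement
    applies to its whole layer.
    """

    site_id: str
    lulcc_class: str
    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError(f"profile {self.site_id}: no layers")
        expected_top = 0.0
        for lyr in self.layers:
            if not np.isclose(lyr.depth_top, expected_top):
                raise ValueError(
                    f"profile {self.site_id}: layers not contiguous from 0 cm "
                    f"(expected top {expected_top}, got {lyr.depth_top})"
                )
            expected_top = lyr.depth_bottom

    @property
    def max_depth(self) -> float:
        return self.layers[-1].depth_bottom


def layer_stock(layer: SoilLayer) -> float:
    """Carbon stock of a single layer in Mg-C ha^-1.

    BD (g cm^-3) x OC (g kg^-1) x thickness (cm) x 0.1 gives Mg-C ha^-1.
    """
    return layer.bulk_density * layer.oc_conc * layer.thickness * 0.1


def layer_mass(layer: SoilLayer) -> float:
    """Dry soil mass of a layer in Mg ha^-1 (BD x thickness_cm x 100)."""
    return layer.bulk_density * layer.thickness * 100.0


def fixed_depth_stock(profile: SoilProfile, depth: float) -> float:
    """Carbon stock from the surface to `depth` cm, Mg-C ha^-1.

    A depth falling inside a layer pro-rates that layer's carbon linearly
    by thickness (constant-within-layer assumption).
    """
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    if depth > profile.max_depth + 1e-9:
        raise ValueError(
            f"depth {depth} cm exceeds profile {profile.site_id} "
            f"bottom at {profile.max_depth} cm"
        )
    total = 0.0
    for lyr in profile.layers:
        if depth >= lyr.depth_bottom:
            total += layer_stock(lyr)
        elif depth > lyr.depth_top:
            total += layer_stock(lyr) * (depth - lyr.depth_top) / lyr.thickness
            break
        else:
            break
    return total


def cumulative_mass(profile: SoilProfile, depth: float) -> float:
    """Dry soil mass from the surface to `depth` cm, Mg ha^-1."""
    if depth < 0 or depth > profile.max_depth + 1e-9:
        raise ValueError(f"depth {depth} cm outside profile {profile.site_id}")
    total = 0.0
    for lyr in profile.layers:
        if depth >= lyr.depth_bottom:
            total += layer_mass(lyr)
        elif depth > lyr.depth_top:
            total += layer_mass(lyr) * (depth - lyr.depth_top) / lyr.thickness
            break
        else:
            break
    return total


@dataclass(frozen=True)
class EquivalentMassResult:
    """Equivalent-soil-mass stock with provenance.

    `extrapolated` is set when the requested reference mass exceeds the
    profile's total mass; the stock then covers only the available mass
    and should not be compared against complete profiles.
    """

    stock: float
    reference_mass: float
    depth_reached: float
    extrapolated: bool

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.stock


def equivalent_mass_stock(
    profile: SoilProfile, reference_mass: float
) -> EquivalentMassResult:
    """Carbon contained in the topmost `reference_mass` Mg ha^-1 of soil.

    Whole layers are summed while the cumulative mass stays below the
    reference mass; the layer that straddles it contributes the fraction
    (remaining mass / layer mass) of its carbon. When the profile's
    cumulative mass to a depth equals the reference mass exactly, the
    result equals ``fixed_depth_stock`` at that depth.
    """
    if reference_mass <= 0:
        raise ValueError(f"reference mass must be positive, got {reference_mass}")
    remaining = reference_mass
    total = 0.0
    depth = 0.0
    for lyr in profile.layers:
        m = layer_mass(lyr)
        if m <= remaining:
            total += layer_stock(lyr)
            remaining -= m
            depth = lyr.depth_bottom
        else:
            frac = remaining / m
            total += layer_stock(lyr) * frac
            depth = lyr.depth_top + frac * lyr.thickness
            remaining = 0.0
            break
    return EquivalentMassResult(
        stock=total,
        reference_mass=reference_mass,
        depth_reached=depth,
        extrapolated=remaining > 1e-9,
    )


def reference_mass_for_depth(
    reference_profiles: Sequence[SoilProfile], depth: float
) -> float:
    """Mean cumulative soil mass to `depth` over native-cover profiles."""
    if not reference_profiles:
        raise ValueError("at least one reference profile is required")
    return float(np.mean([cumulative_mass(p, depth) for p in reference_profiles]))


# ---------------------------------------------------------------------------
# Tabular interface

_PROFILE_COLUMNS = [
    "site_id",
    "class",
    "depth_top_cm",
    "depth_bottom_cm",
    "bulk_density_g_cm3",
    "oc_g_kg",
]


def profiles_from_frame(frame: pd.DataFrame) -> list[SoilProfile]:
    """Build profiles from a long table (one row per layer).

    Rows with missing bulk density invalidate the whole profile: such
    profiles are rejected with a warning rather than imputed.
    """
    missing = [c for c in _PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"profile table missing columns: {missing}")
    profiles: list[SoilProfile] = []
    for (site, cls), grp in frame.groupby(["site_id", "class"], sort=True):
        grp = grp.sort_values("depth_top_cm")
        if grp["bulk_density_g_cm3"].isna().any():
            import warnings

            warnings.warn(
                f"profile {site}: missing bulk density, profile rejected",
                stacklevel=2,
            )
            continue
        layers = tuple(
            SoilLayer(
                depth_top=row.depth_top_cm,
                depth_bottom=row.depth_bottom_cm,
                bulk_density=row.bulk_density_g_cm3,
                oc_conc=row.oc_g_kg,
            )
            for row in grp.itertuples()
        )
        profiles.append(SoilProfile(site_id=str(site), lulcc_class=str(cls), layers=layers))
    return profiles


def profiles_to_frame(profiles: Iterable[SoilProfile]) -> pd.DataFrame:
    """Inverse of :func:`profiles_from_frame` (long layer table)."""
    rows = [
        (p.site_id, p.lulcc_class, l.depth_top, l.depth_bottom, l.bulk_density, l.oc_conc)
        for p in profiles
        for l in p.layers
    ]
    return pd.DataFrame(rows, columns=_PROFILE_COLUMNS)


def compute_stocks(
    profiles: Sequence[SoilProfile],
    depths: Sequence[float] = (30.0, 60.0, 100.0),
    method: str = "equivalent_mass",
    reference_classes: Sequence[str] = ("FOR", "CDO"),
) -> pd.DataFrame:
    """Per-site stocks at each depth interval, tidy format.

    With ``method='equivalent_mass'`` the reference mass for each depth
    is the mean cumulative mass of the `reference_classes` (native cover)
    profiles at that depth; an `extrapolated` column flags sites whose
    profile holds less soil mass than the reference.

    Returns columns: site_id, class, depth_cm, stock, extrapolated.
    """
    if method not in ("fixed_depth", "equivalent_mass"):
        raise ValueError(f"unknown method {method!r}")
    ref_masses: dict[float, float] = {}
    if method == "equivalent_mass":
        refs = [p for p in profiles if p.lulcc_class in reference_classes]
        if not refs:
            raise ValueError(
                f"no reference profiles among classes {tuple(reference_classes)}"
            )
        ref_masses = {d: reference_mass_for_depth(refs, d) for d in depths}
    rows = []
    for p in profiles:
        for d in depths:
            if method == "fixed_depth":
                rows.append((p.site_id, p.lulcc_class, d, fixed_depth_stock(p, d), False))
            else:
                res = equivalent_mass_stock(p, ref_masses[d])
                rows.append((p.site_id, p.lulcc_class, d, res.stock, res.extrapolated))
    out = pd.DataFrame(
        rows, columns=["site_id", "class", "depth_cm", "stock", "extrapolated"]
    )
    out.attrs["method"] = method
    out.attrs["reference_mass"] = ref_masses
    return out


def summarize_by_class(stocks: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per class x depth summaries: n, mean, sample sd, t-based CI half-width.

    ci = t_{1-alpha/2, n-1} * sd / sqrt(n). Groups with n < 2 are kept but
    flagged with NaN sd/ci.
    """
    rows = []
    for (cls, d), grp in stocks.groupby(["class", "depth_cm"], sort=True):
        vals = grp["stock"].to_numpy(float)
        n = len(vals)
        avg = float(np.mean(vals))
        if n >= 2:
            sd = float(np.std(vals, ddof=1))
            ci = float(stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n))
            flagged = False
        else:
            sd = ci = float("nan")
            flagged = True
        rows.append((cls, d, n, avg, sd, ci, flagged))
    out = pd.DataFrame(
        rows, columns=["class", "depth_cm", "n", "avg", "std", "ci", "flagged"]
    )
    out.attrs["alpha"] = alpha
    return out


def pct_difference(avg_lu: float, avg_lc: float, convention: str) -> float:
    """Percentage difference between a land-use and a land-cover mean.

    ``baseline_native``       100 * (avg_lu - avg_lc) / avg_lc
    ``baseline_agricultural`` 100 * (avg_lu - avg_lc) / avg_lu

    The two conventions are reciprocal: (1 + p_nat/100)(1 - p_agr/100) = 1.
    """
    if convention == "baseline_native":
        denom = avg_lc
    elif convention == "baseline_agricultural":
        denom = avg_lu
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if denom == 0:
        raise ZeroDivisionError("zero denominator in pct_difference")
    return 100.0 * (avg_lu - avg_lc) / denom


def difference_table(
    summaries: pd.DataFrame,
    lu_classes: Sequence[str] = ("IRR", "RAG", "PAST"),
    lc_classes: Sequence[str] = ("FOR", "CDO"),
    conventions: dict[float, str] | None = None,
) -> pd.DataFrame:
    """Percentage differences of agricultural classes vs native covers.

    By convention of the reference study, the 0-30 cm column is expressed
    relative to the agricultural mean and the 0-100 cm column relative to
    the native mean; override per-depth via `conventions`.
    """
    if conventions is None:
        conventions = {30.0: "baseline_agricultural", 100.0: "baseline_native"}
    idx = summaries.set_index(["class", "depth_cm"])["avg"]
    rows = []
    for d, conv in conventions.items():
        for lu in lu_classes:
            for lc in lc_classes:
                p = pct_difference(idx[(lu, d)], idx[(lc, d)], conv)
                rows.append((lu, lc, d, conv, p))
    return pd.DataFrame(
        rows,
        columns=["class_lu", "class_lc", "depth_cm", "denominator_convention", "pct_difference"],
    )


def pairwise_ttests(
    stocks: pd.DataFrame, depth_cm: float, variant: str = "welch"
) -> pd.DataFrame:
    """Two-sided two-sample t-tests between all class pairs at one depth.

    `variant` is ``'welch'`` (unequal variances, default) or ``'pooled'``
    (classic Student). Degenerate groups (n < 2 or zero variance in both)
    are flagged rather than dropped.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    sub = stocks[stocks["depth_cm"] == depth_cm]
    groups = {cls: g["stock"].to_numpy(float) for cls, g in sub.groupby("class", sort=True)}
    if len(groups) < 2:
        raise ValueError("need at least two classes for pairwise tests")
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa, xb = groups[a], groups[b]
            flagged = len(xa) < 2 or len(xb) < 2
            if not flagged and np.var(xa, ddof=1) + np.var(xb, ddof=1) == 0:
                if np.mean(xa) == np.mean(xb):
                    t, p = 0.0, 1.0
                    df = len(xa) + len(xb) - 2
                    rows.append((a, b, depth_cm, variant, t, float(df), p, False))
                    continue
                flagged = True
            if flagged:
                rows.append((a, b, depth_cm, variant, np.nan, np.nan, np.nan, True))
                continue
            res = stats.ttest_ind(xa, xb, equal_var=(variant == "pooled"))
            rows.append(
                (a, b, depth_cm, variant, float(res.statistic), float(res.df), float(res.pvalue), False)
            )
    return pd.DataFrame(
        rows,
        columns=["class_a", "class_b", "depth_cm", "variant", "t_stat", "df", "p_value", "flagged"],
    )
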