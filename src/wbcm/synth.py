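"""Synthetic inputs: land-cover raster series and soil profile sets.

The land-cover generator produces an annual class-raster series whose
per-class pixel counts follow a prescribed area trajectory (anchor
years, linear interpolation) exactly, with spatially contiguous
patch conversions: growing classes expand by seeded region growing into
the classes that are losing area, emulating the patchy frontier
expansion of agricultural conversion rather than salt-and-pepper noise.

The soil generator emits seven-layer profiles (0-5, 5-10, 10-15, 15-20,
20-40, 40-60, 60-100 cm) whose organic carbon decays exponentially with
depth and whose bulk density increases with depth (optionally inflated
for agricultural compaction). Each profile's fixed-depth 0-100 cm stock
is drawn from a moment-matched lognormal, so class sample means and
standard deviations converge to the prescribed targets while stocks
stay positive and right-skewed, as field soil-stock distributions are.

Both generators are fully determined by their seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .model import GridGeometry, LulccRaster, default_legend
from .soil import STANDARD_LAYERS, SoilLayer, SoilProfile

__all__ = [
    "TrajectorySpec",
    "SoilSynthSpec",
    "TABLE_AREA_ANCHORS_MHA",
    "REGION_TOTAL_MHA",
    "table_trajectory",
    "gen_lulcc_series",
    "gen_soil_profiles",
]

#: Reference class-area trajectory (Mha) at the five anchor years of the
#: 1990-2018 study region (13.40 Mha total).
REGION_TOTAL_MHA = 13.40
_ANCHOR_YEARS = (1990, 1997, 2004, 2011, 2018)
TABLE_AREA_ANCHORS_MHA: dict[str, tuple[float, ...]] = {
    "FOR": (3.34, 3.29, 3.06, 2.81, 2.07),
    "SF": (4.27, 4.24, 4.07, 3.77, 4.49),
    "GF": (3.77, 3.36, 3.43, 3.14, 1.69),
    "RAG_PAST": (0.08, 0.06, 0.05, 0.05, 0.36),
    "RAG": (0.84, 1.15, 1.43, 2.14, 3.08),
    "IRR": (0.02, 0.05, 0.06, 0.08, 0.20),
    "PAST": (1.08, 1.24, 1.30, 1.39, 1.51),
}

#: Reference per-class 0-100 cm soil-stock targets (mean, sd), Mg-C ha^-1.
SOIL_TARGETS: dict[str, tuple[float, float]] = {
    "FOR": (82.5, 43.6),
    "CDO": (70.3, 41.6),
    "RAG": (57.4, 33.3),
    "IRR": (78.1, 25.5),
    "PAST": (51.7, 25.5),
}

_NEIGH = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class TrajectorySpec:
    """Target class-area fractions per year for the raster generator.

    `anchors` maps class name -> {year: fraction of valid pixels};
    fractions are interpolated linearly between anchor years. Per-year
    fractions must sum to <= 1; the remainder becomes WATER.
    """

    years: tuple[int, ...]
    anchors: dict[str, dict[int, float]]
    grid_shape: tuple[int, int] = (300, 300)
    pixel_size: float = 30.0
    seed: int = 0

    def fractions(self, year: int) -> dict[str, float]:
        out = {}
        for cls, anch in self.anchors.items():
            ys = sorted(anch)
            out[cls] = float(np.interp(year, ys, [anch[y] for y in ys]))
        return out


def table_trajectory(
    grid_shape: tuple[int, int] = (300, 300),
    years: tuple[int, ...] | None = None,
    pixel_size: float = 30.0,
    seed: int = 0,
) -> TrajectorySpec:
    """Trajectory proportional to the reference 1990-2018 class areas."""
    if years is None:
        years = tuple(range(1990, 2019))
    anchors = {
        cls: {y: a / REGION_TOTAL_MHA for y, a in zip(_ANCHOR_YEARS, areas)}
        for cls, areas in TABLE_AREA_ANCHORS_MHA.items()
    }
    return TrajectorySpec(
        years=tuple(years), anchors=anchors, grid_shape=tuple(grid_shape),
        pixel_size=pixel_size, seed=seed,
    )


def _largest_remainder(fracs: dict[str, float], n: int, year: int) -> dict[str, int]:
    """Integer pixel targets summing exactly to n (largest-remainder)."""
    total = sum(fracs.values())
    if total > 1 + 1e-9 or any(f < 0 for f in fracs.values()):
        raise ValueError(f"year {year}: class fractions invalid (sum {total:.4f})")
    fr = dict(fracs)
    fr["WATER"] = fr.get("WATER", 0.0) + (1.0 - total)
    raw = {c: f * n for c, f in fr.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(fr, key=lambda c: (-(raw[c] - counts[c]), c))[:short]:
        counts[c] += 1
    return {c: k for c, k in counts.items() if k > 0}


def _grow_initial(shape, targets: dict[str, int], codes: dict[str, int],
                  rng: np.random.Generator) -> np.ndarray:
    """Competitive multi-seed region growing filling the whole grid with
    exactly `targets` pixels per class."""
    nr, nc = shape
    n = nr * nc
    grid = np.zeros(n, dtype=np.int64) - 1
    order = rng.permutation(n)  # scan order for fresh seeds
    scan = 0
    demand = {c: k for c, k in targets.items()}
    frontier: dict[str, list[int]] = {c: [] for c in demand}
    classes = sorted(demand)
    while classes:
        weights = np.array([demand[c] for c in classes], float)
        c = classes[rng.choice(len(classes), p=weights / weights.sum())]
        pix = -1
        fr = frontier[c]
        while fr:
            i = int(rng.integers(len(fr)))
            fr[i], fr[-1] = fr[-1], fr[i]
            cand = fr.pop()
            if grid[cand] < 0:
                pix = cand
                break
        if pix < 0:  # plant a new seed at a random unassigned pixel
            while grid[order[scan]] >= 0:
                scan += 1
            pix = int(order[scan])
        grid[pix] = codes[c]
        demand[c] -= 1
        if demand[c] == 0:
            classes.remove(c)
        r, q = divmod(pix, nc)
        for dr, dq in _NEIGH:
            rr, qq = r + dr, q + dq
            if 0 <= rr < nr and 0 <= qq < nc and grid[rr * nc + qq] < 0:
                fr.append(rr * nc + qq)
    return grid.reshape(shape)


def _transition(grid: np.ndarray, targets: dict[str, int], codes: dict[str, int],
                rng: np.random.Generator, year: int) -> np.ndarray:
    """Patch-convert pixels so counts reach `targets`; conversions grow
    from the expanding class's boundary into surplus (donor) classes."""
    nr, nc = grid.shape
    flat = grid.ravel().copy()
    counts = np.bincount(flat, minlength=256)
    delta = {c: targets.get(c, 0) - int(counts[code]) for c, code in codes.items()}
    for c, k in targets.items():
        if c not in codes:
            raise ValueError(f"year {year}: class {c} missing from legend")
    surplus = {codes[c]: -d for c, d in delta.items() if d < 0}
    growers = {c: d for c, d in delta.items() if d > 0}
    if not growers:
        return flat.reshape(nr, nc)
    donor_codes = set(surplus)
    # initial frontiers: donor pixels adjacent to each grower's region
    frontier: dict[str, list[int]] = {}
    for g in growers:
        mask = flat.reshape(nr, nc) == codes[g]
        adj = np.zeros((nr, nc), bool)
        adj[:-1, :] |= mask[1:, :]
        adj[1:, :] |= mask[:-1, :]
        adj[:, :-1] |= mask[:, 1:]
        adj[:, 1:] |= mask[:, :-1]
        cand = adj & np.isin(flat.reshape(nr, nc), list(donor_codes))
        frontier[g] = list(np.flatnonzero(cand.ravel()))
    donor_pixels = {
        code: list(np.flatnonzero(flat == code)) for code in donor_codes
    }
    classes = sorted(growers)
    while classes:
        weights = np.array([growers[c] for c in classes], float)
        g = classes[rng.choice(len(classes), p=weights / weights.sum())]
        pix = -1
        fr = frontier[g]
        while fr:
            i = int(rng.integers(len(fr)))
            fr[i], fr[-1] = fr[-1], fr[i]
            cand = fr.pop()
            if surplus.get(int(flat[cand]), 0) > 0:
                pix = cand
                break
        if pix < 0:  # seed a new patch inside a donor with surplus
            live = [code for code, s in surplus.items() if s > 0]
            w = np.array([surplus[code] for code in live], float)
            code = live[rng.choice(len(live), p=w / w.sum())]
            pool = donor_pixels[code]
            while True:
                i = int(rng.integers(len(pool)))
                pool[i], pool[-1] = pool[-1], pool[i]
                cand = pool.pop()
                if flat[cand] == code:
                    pix = cand
                    break
        donor = int(flat[pix])
        flat[pix] = codes[g]
        surplus[donor] -= 1
        growers[g] -= 1
        if growers[g] == 0:
            classes.remove(g)
        r, q = divmod(pix, nc)
        for dr, dq in _NEIGH:
            rr, qq = r + dr, q + dq
            if 0 <= rr < nr and 0 <= qq < nc:
                j = rr * nc + qq
                if int(flat[j]) in donor_codes:
                    fr.append(j)
    return flat.reshape(nr, nc)


def gen_lulcc_series(
    spec: TrajectorySpec, legend: dict[str, int] | None = None
) -> list[LulccRaster]:
    """Generate one land-cover raster per year following `spec`.

    Per-year per-class pixel counts hit the interpolated targets exactly
    (largest-remainder rounding); transitions are contiguous patch
    conversions from area-losing donor classes. Bit-reproducible under
    `spec.seed`.
    """
    if legend is None:
        legend = default_legend()
    codes = {k: v for k, v in legend.items() if k != "nodata"}
    unknown = set(spec.anchors) - set(codes)
    if unknown:
        raise ValueError(f"trajectory classes not in legend: {sorted(unknown)}")
    geom = GridGeometry.square(spec.grid_shape, spec.pixel_size)
    n = spec.grid_shape[0] * spec.grid_shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x4C55]))
    out: list[LulccRaster] = []
    grid: np.ndarray | None = None
    for year in spec.years:
        targets = _largest_remainder(spec.fractions(year), n, year)
        if grid is None:
            grid = _grow_initial(spec.grid_shape, targets, codes, rng)
        else:
            grid = _transition(grid, targets, codes, rng, year)
        out.append(LulccRaster(year=year, grid=grid.astype(np.uint8), geometry=geom,
                               nodata=legend.get("nodata", 0)))
    return out


# ---------------------------------------------------------------------------
# Soil profiles


@dataclass(frozen=True)
class SoilSynthSpec:
    """Targets and shape parameters for synthetic soil profiles.

    targets : class -> (mean, sd) of the fixed-depth 0-100 cm stock in
        Mg-C ha^-1 (defaults: the reference field campaign's values).
    oc_decay_rate : exponential decay of organic C with depth, cm^-1.
    bd_surface : class -> surface bulk density, g cm^-3.
    bd_gradient : bulk-density increase per metre of depth, g cm^-3.
    bd_inflation : class -> multiplicative factor on bulk density
        (compaction scenarios, e.g. 1.15 for trafficked agricultural soil).
    """

    targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SOIL_TARGETS)
    )
    n_per_class: int = 20
    oc_decay_rate: float = 0.02
    bd_surface: dict[str, float] = field(
        default_factory=lambda: {"FOR": 1.25, "CDO": 1.30, "RAG": 1.45,
                                 "IRR": 1.40, "PAST": 1.50}
    )
    bd_gradient: float = 0.25
    bd_jitter: float = 0.05
    bd_inflation: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def gen_soil_profiles(spec: SoilSynthSpec) -> list[SoilProfile]:
    """Generate `n_per_class` seven-layer profiles per class.

    Organic carbon decreases exponentially with depth; bulk density is
    non-decreasing with depth. The surface concentration of each profile
    is calibrated so that its fixed-depth 0-100 cm stock equals the
    profile's lognormal stock draw exactly; hence class sample moments
    converge to the spec targets.
    """
    if spec.n_per_class < 2:
        raise ValueError("need at least 2 profiles per class")
    mids = np.array([(a + b) / 2 for a, b in STANDARD_LAYERS])
    ths = np.array([b - a for a, b in STANDARD_LAYERS])
    profiles: list[SoilProfile] = []
    for cls in sorted(spec.targets):
        mean, sd = spec.targets[cls]
        if mean <= 0:
            raise ValueError(f"class {cls}: target mean must be positive")
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), zlib.crc32(cls.encode())])
        )
        bd0 = spec.bd_surface.get(cls, 1.35) * spec.bd_inflation.get(cls, 1.0)
        decay = np.exp(-spec.oc_decay_rate * mids)
        for i in range(spec.n_per_class):
            jitter = rng.normal(0.0, spec.bd_jitter)
            bd = np.maximum(bd0 + jitter + spec.bd_gradient * mids / 100.0, 0.5)
            if sd == 0:
                stock = mean
            else:
                s2 = np.log1p((sd / mean) ** 2)
                stock = rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2))
            surface_oc = stock / float(np.sum(bd * decay * ths * 0.1))
            layers = tuple(
                SoilLayer(a, b, float(bd[j]), float(surface_oc * decay[j]))
                for j, (a, b) in enumerate(STANDARD_LAYERS)
            )
            profiles.append(
                SoilProfile(site_id=f"{cls}-{i:03d}", lulcc_class=cls, layers=layers)
            )
    return profiles
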