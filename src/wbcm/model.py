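"""Bookkeeping reconstruction of carbon stocks over a land-cover series.

The model assigns every pixel of the first year's land-cover raster a
value for each carbon reservoir (AGB, BGB, SCS100) drawn from its
class's value pool, then walks the raster series year by year: pixels
whose class did not change keep their values bit-identically, pixels
whose class changed receive fresh, independent draws from the new
class's pools. No biological process is simulated — classes are assumed
at equilibrium, and a transition moves the pixel instantaneously to the
new class's stock distribution.

Randomness is organised so results are independent of traversal order:
for every (year, reservoir) a full grid of pool indices is generated
from a Philox counter-based stream keyed on (root seed, year,
reservoir); a pixel's redraw depends only on its position, the year and
its new class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Sequence

import numpy as np

from .params import RESERVOIRS, CarbonParamTable

__all__ = [
    "GridGeometry",
    "LulccRaster",
    "CarbonState",
    "ClassMapping",
    "default_legend",
    "default_mapping",
    "initialize_state",
    "step",
    "run_reconstruction",
]

NODATA_FLOAT = -9999.0

#: Classes that carry zero carbon in every reservoir but still occupy area.
ZERO_CARBON_CLASSES = ("WATER", "URBAN")


class GeometryError(ValueError):
    """Rasters in one series must share shape, pixel size and transform."""


@dataclass(frozen=True)
class GridGeometry:
    """Minimal georeferencing: shape, affine transform and a CRS tag.

    `transform` follows the usual (a, b, c, d, e, f) convention: x =
    a*col + b*row + c, y = d*col + e*row + f, origin at the upper-left
    corner; `a` is the pixel width and `-e` the pixel height in metres.
    """

    shape: tuple[int, int]
    transform: tuple[float, float, float, float, float, float]
    crs: str = "EPSG:32723"

    @classmethod
    def square(cls, shape: tuple[int, int], pixel_size: float = 30.0,
               origin: tuple[float, float] = (0.0, 0.0), crs: str = "EPSG:32723") -> "GridGeometry":
        x0, y0 = origin
        return cls(shape=tuple(shape), transform=(pixel_size, 0.0, x0, 0.0, -pixel_size, y0), crs=crs)

    @property
    def pixel_area_ha(self) -> float:
        a, b, _, d, e, _ = self.transform
        return abs(a * e - b * d) / 1e4

    @property
    def pixel_size(self) -> float:
        return abs(self.transform[0])

    def __eq__(self, other: object) -> bool:  # tolerant float comparison
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.transform, other.transform)
            and self.crs == other.crs
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.crs))


@dataclass(frozen=True)
class LulccRaster:
    """One year's land-use/land-cover class grid (byte codes)."""

    year: int
    grid: np.ndarray
    geometry: GridGeometry
    nodata: int = 0

    def __post_init__(self) -> None:
        if self.grid.shape != tuple(self.geometry.shape):
            raise GeometryError(
                f"grid shape {self.grid.shape} != geometry {self.geometry.shape}"
            )

    def validate_codes(self, legend: dict[str, int]) -> None:
        known = set(legend.values()) | {self.nodata}
        present = set(np.unique(self.grid).tolist())
        unknown = sorted(present - known)
        if unknown:
            raise ValueError(
                f"raster {self.year}: unknown class codes {unknown} "
                f"(legend has {sorted(known)})"
            )

    @property
    def valid(self) -> np.ndarray:
        return self.grid != self.nodata


@dataclass
class CarbonState:
    """Co-registered AGB/BGB/SCS grids (Mg-C ha^-1) for one year.

    Nodata pixels are NaN in all three arrays. ``tcs`` is the pixelwise
    total AGB + BGB + SCS.
    """

    year: int
    agb: np.ndarray
    bgb: np.ndarray
    scs: np.ndarray
    geometry: GridGeometry
    provenance: dict = field(default_factory=dict)

    @property
    def tcs(self) -> np.ndarray:
        return self.agb + self.bgb + self.scs

    def reservoir(self, name: str) -> np.ndarray:
        return {"AGB": self.agb, "BGB": self.bgb, "SCS100": self.scs}[name]


class ClassMapping:
    """Maps raster class codes to parameter classes per reservoir.

    Savanna (SF) and grassland (GF) formations keep distinct biomass
    parameters but share the pooled Cerrado (CDO) soil parameters; water
    and urban classes carry zero carbon by definition.
    """

    def __init__(
        self,
        legend: dict[str, int],
        reservoir_classes: dict[str, dict[str, str]],
        zero_carbon: Sequence[str] = ZERO_CARBON_CLASSES,
    ) -> None:
        self.legend = dict(legend)
        self.nodata_code = legend.get("nodata", 0)
        self.zero_carbon = tuple(zero_carbon)
        self.reservoir_classes = {k: dict(v) for k, v in reservoir_classes.items()}
        carbon_names = set(legend) - set(self.zero_carbon) - {"nodata"}
        missing = carbon_names - set(self.reservoir_classes)
        if missing:
            raise ValueError(f"class mapping incomplete, unmapped classes: {sorted(missing)}")

    @property
    def code_to_name(self) -> dict[int, str]:
        return {v: k for k, v in self.legend.items()}

    def param_class(self, class_name: str, reservoir: str) -> str:
        return self.reservoir_classes[class_name][reservoir]

    def validate_table(self, table: CarbonParamTable) -> None:
        missing = [
            (name, res)
            for name, per_res in self.reservoir_classes.items()
            for res in RESERVOIRS
            if (per_res[res], res) not in table
        ]
        if missing:
            raise ValueError(f"parameter table missing entries for {missing}")


def default_legend() -> dict[str, int]:
    """The shipped nine-class legend plus nodata (byte codes)."""
    with resources.files("wbcm.data").joinpath("legend.json").open() as f:
        return json.load(f)


def default_mapping(legend: dict[str, int] | None = None) -> ClassMapping:
    """Default mapping: each class its own biomass parameters; SF and GF
    share the CDO soil pool; FOR soil is its own pool."""
    if legend is None:
        legend = default_legend()
    rc = {}
    for name in legend:
        if name in ("nodata",) + ZERO_CARBON_CLASSES:
            continue
        soil = "CDO" if name in ("SF", "GF") else name
        rc[name] = {"AGB": name, "BGB": name, "SCS100": soil}
    return ClassMapping(legend, rc)


# ---------------------------------------------------------------------------
# Per-year random index fields (counter-based, traversal-order independent)


def _year_rng(seed: int, year: int, reservoir_idx: int) -> np.random.Generator:
    key = np.random.SeedSequence([int(seed), int(year), int(reservoir_idx)])
    return np.random.Generator(np.random.Philox(key))


def _index_field(seed: int, year: int, reservoir_idx: int,
                 shape: tuple[int, int], n_pop: int) -> np.ndarray:
    return _year_rng(seed, year, reservoir_idx).integers(0, n_pop, size=shape)


def _fill_values(
    out: np.ndarray,
    target: np.ndarray,
    lulcc: LulccRaster,
    table: CarbonParamTable,
    mapping: ClassMapping,
    reservoir: str,
    mode: str,
    seed: int,
) -> None:
    """Assign reservoir values into ``out`` where ``target`` is True."""
    res_idx = RESERVOIRS.index(reservoir)
    codes = lulcc.grid
    name_of = mapping.code_to_name
    if mode == "stochastic":
        idx = _index_field(seed, lulcc.year, res_idx, codes.shape, table.n_pop)
    present = np.unique(codes[target])
    for code in present:
        name = name_of.get(int(code))
        if name is None:
            raise ValueError(f"raster {lulcc.year}: unmapped class code {int(code)}")
        sel = target & (codes == code)
        if name in mapping.zero_carbon:
            out[sel] = 0.0
            continue
        pcls = mapping.param_class(name, reservoir)
        if mode == "expected":
            out[sel] = table.get(pcls, reservoir).avg
        else:
            pool = table.pool(pcls, reservoir, seed)
            out[sel] = pool[idx[sel]]


def initialize_state(
    lulcc_0: LulccRaster,
    table: CarbonParamTable,
    mapping: ClassMapping,
    mode: str = "stochastic",
    seed: int = 0,
) -> CarbonState:
    """Initial-year carbon maps: one independent draw per pixel and
    reservoir (or the class mean in expected mode)."""
    if mode not in ("stochastic", "expected"):
        raise ValueError(f"unknown mode {mode!r}")
    lulcc_0.validate_codes(mapping.legend)
    mapping.validate_table(table)
    valid = lulcc_0.valid
    arrays = {}
    for res in RESERVOIRS:
        arr = np.full(lulcc_0.grid.shape, np.nan)
        _fill_values(arr, valid, lulcc_0, table, mapping, res, mode, seed)
        arrays[res] = arr
    return CarbonState(
        year=lulcc_0.year,
        agb=arrays["AGB"],
        bgb=arrays["BGB"],
        scs=arrays["SCS100"],
        geometry=lulcc_0.geometry,
        provenance={"seed": seed, "mode": mode},
    )


def step(
    state_prev: CarbonState,
    lulcc_prev: LulccRaster,
    lulcc_next: LulccRaster,
    table: CarbonParamTable,
    mapping: ClassMapping,
    mode: str = "stochastic",
    seed: int = 0,
) -> CarbonState:
    """Advance one year: keep values where the class is unchanged,
    redraw all three reservoirs where it changed (memoryless)."""
    if lulcc_prev.geometry != lulcc_next.geometry or state_prev.geometry != lulcc_next.geometry:
        raise GeometryError("inputs to step are not co-registered")
    lulcc_next.validate_codes(mapping.legend)
    changed = (lulcc_prev.grid != lulcc_next.grid) & lulcc_next.valid
    nodata_next = ~lulcc_next.valid
    arrays = {}
    for res in RESERVOIRS:
        arr = state_prev.reservoir(res).copy()
        _fill_values(arr, changed, lulcc_next, table, mapping, res, mode, seed)
        arr[nodata_next] = np.nan
        arrays[res] = arr
    return CarbonState(
        year=lulcc_next.year,
        agb=arrays["AGB"],
        bgb=arrays["BGB"],
        scs=arrays["SCS100"],
        geometry=lulcc_next.geometry,
        provenance={"seed": seed, "mode": mode},
    )


def run_reconstruction(
    series: Sequence[LulccRaster],
    table: CarbonParamTable,
    mapping: ClassMapping | None = None,
    mode: str = "stochastic",
    seed: int = 0,
    on_state: Callable[[CarbonState, LulccRaster], None] | None = None,
    keep: str = "all",
) -> list[CarbonState]:
    """Run the reconstruction over an ordered raster series.

    ``on_state(state, lulcc)`` is invoked for every year, letting callers
    stream states to disk; ``keep='all'`` (default) returns every state,
    ``keep='last'`` only the final one (``on_state`` still sees all).
    """
    if not series:
        raise ValueError("empty land-cover series")
    years = [r.year for r in series]
    if any(b <= a for a, b in zip(years, years[1:])):
        raise ValueError(f"raster years must be strictly increasing, got {years}")
    if mapping is None:
        mapping = default_mapping()
    state = initialize_state(series[0], table, mapping, mode=mode, seed=seed)
    if on_state is not None:
        on_state(state, series[0])
    out = [state]
    for prev_r, next_r in zip(series, series[1:]):
        state = step(state, prev_r, next_r, table, mapping, mode=mode, seed=seed)
        if on_state is not None:
            on_state(state, next_r)
        if keep == "all":
            out.append(state)
        else:
            out = [state]
    return out
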