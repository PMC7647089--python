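"""Per-class carbon parameters and truncated-normal value pools.

Each land-cover class carries a mean and standard deviation for three
carbon reservoirs — above-ground biomass (AGB), below-ground biomass
(BGB) and the 0-100 cm soil carbon stock (SCS100), all in Mg-C ha^-1.
From these a Monte Carlo "population" (pool) of plausible per-pixel
values is built for each (class, reservoir) pair: normal draws with
out-of-bounds values rejection-resampled so the pool stays inside
[avg - k*std, avg + k*std] without atoms at the bounds.

The truncation multiplier k defaults to 0.95, which reproduces the
published min/max bounds of the reference parameter set; the classical
central-95% convention (k = 1.96) is selectable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReservoirParams",
    "CarbonParamTable",
    "RESERVOIRS",
    "truncation_bounds",
    "build_population",
]

RESERVOIRS = ("AGB", "BGB", "SCS100")

DEFAULT_K = 0.95
DEFAULT_N_POP = 100_000


def truncation_bounds(avg: float, std: float, k: float) -> tuple[float, float]:
    """Symmetric truncation bounds (avg - k*std, avg + k*std)."""
    if std < 0:
        raise ValueError(f"std must be >= 0, got {std}")
    return avg - k * std, avg + k * std


@dataclass(frozen=True)
class ReservoirParams:
    """Distribution parameters of one (class, reservoir) pair, Mg-C ha^-1."""

    lulcc_class: str
    reservoir: str
    avg: float
    std: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError(f"{self.lulcc_class}/{self.reservoir}: std < 0")
        if not (self.min <= self.avg <= self.max):
            raise ValueError(
                f"{self.lulcc_class}/{self.reservoir}: bounds "
                f"[{self.min}, {self.max}] do not bracket avg {self.avg}"
            )


def build_population(
    params: ReservoirParams, n_pop: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Pool of `n_pop` truncated-normal draws for one (class, reservoir).

    Draws outside [min, max] are replaced by redrawing (rejection), so
    the pool carries no probability atoms at the bounds. Reproducible:
    the same seed gives a bit-identical pool.
    """
    if params.min > params.max:
        raise ValueError("min > max in parameter configuration")
    rng = np.random.default_rng(seed)
    if params.std == 0:
        return np.full(n_pop, params.avg)
    pool = rng.normal(params.avg, params.std, size=n_pop)
    for _ in range(1000):
        bad = (pool < params.min) | (pool > params.max)
        n_bad = int(bad.sum())
        if n_bad == 0:
            return pool
        pool[bad] = rng.normal(params.avg, params.std, size=n_bad)
    raise RuntimeError(
        f"rejection sampling did not converge for "
        f"{params.lulcc_class}/{params.reservoir}; bounds too narrow?"
    )


def _substream(root_seed: int, lulcc_class: str, reservoir: str) -> np.random.SeedSequence:
    # Stable per-(class, reservoir) substream: adding a class never
    # perturbs the pools of existing classes.
    tag = zlib.crc32(f"{lulcc_class}/{reservoir}".encode())
    return np.random.SeedSequence([int(root_seed), tag])


class CarbonParamTable:
    """Table of per-class, per-reservoir carbon parameters with pools.

    Parameters
    ----------
    entries : mapping (class, reservoir) -> ReservoirParams
    k : float
        Truncation multiplier used where a row's min/max were not given.
    n_pop : int
        Pool size per (class, reservoir) pair.
    """

    def __init__(
        self,
        entries: dict[tuple[str, str], ReservoirParams],
        k: float = DEFAULT_K,
        n_pop: int = DEFAULT_N_POP,
    ) -> None:
        if k <= 0:
            raise ValueError(f"truncation multiplier k must be > 0, got {k}")
        if n_pop < 1000:
            raise ValueError(f"population size must be >= 1000, got {n_pop}")
        self.entries = dict(entries)
        self.k = float(k)
        self.n_pop = int(n_pop)
        self._pools: dict[tuple[str, str], np.ndarray] = {}
        self._pool_seed: int | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, k: float = DEFAULT_K, n_pop: int = DEFAULT_N_POP
    ) -> "CarbonParamTable":
        """Build from a table with columns class, reservoir, avg, std[, min, max].

        Missing min/max are filled with avg +/- k*std.
        """
        frame = frame.rename(columns={"class": "lulcc_class"})
        entries = {}
        for _, row in frame.iterrows():
            lo, hi = truncation_bounds(float(row["avg"]), float(row["std"]), k)
            if "min" in frame.columns and pd.notna(row["min"]):
                lo = float(row["min"])
            if "max" in frame.columns and pd.notna(row["max"]):
                hi = float(row["max"])
            p = ReservoirParams(
                str(row["lulcc_class"]), str(row["reservoir"]),
                float(row["avg"]), float(row["std"]), lo, hi,
            )
            entries[(p.lulcc_class, p.reservoir)] = p
        return cls(entries, k=k, n_pop=n_pop)

    @classmethod
    def from_csv(
        cls, path: str | Path, k: float = DEFAULT_K, n_pop: int = DEFAULT_N_POP
    ) -> "CarbonParamTable":
        frame = pd.read_csv(path)
        required = {"class", "reservoir", "avg", "std"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"parameter file {path} missing columns {sorted(missing)}")
        return cls.from_frame(frame, k=k, n_pop=n_pop)

    @classmethod
    def default(cls, k: float = DEFAULT_K, n_pop: int = DEFAULT_N_POP) -> "CarbonParamTable":
        """The shipped reference parameter set (literature biomass values
        and field-campaign soil stocks)."""
        with resources.as_file(
            resources.files("wbcm.data").joinpath("default_params.csv")
        ) as p:
            return cls.from_csv(p, k=k, n_pop=n_pop)

    # -- access ------------------------------------------------------------

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries

    def get(self, lulcc_class: str, reservoir: str) -> ReservoirParams:
        try:
            return self.entries[(lulcc_class, reservoir)]
        except KeyError:
            raise KeyError(
                f"no parameters for class {lulcc_class!r}, reservoir {reservoir!r}"
            ) from None

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted({c for c, _ in self.entries}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p.lulcc_class, p.reservoir, p.avg, p.std, p.min, p.max)
            for p in self.entries.values()
        ]
        return pd.DataFrame(rows, columns=["class", "reservoir", "avg", "std", "min", "max"])

    # -- pools -------------------------------------------------------------

    def pool(self, lulcc_class: str, reservoir: str, seed: int) -> np.ndarray:
        """Value pool for one (class, reservoir), built lazily and cached
        per root seed. Substreams are independent per pair."""
        if self._pool_seed != seed:
            self._pools.clear()
            self._pool_seed = seed
        key = (lulcc_class, reservoir)
        if key not in self._pools:
            p = self.get(lulcc_class, reservoir)
            self._pools[key] = build_population(
                p, self.n_pop, _substream(seed, lulcc_class, reservoir)
            )
        return self._pools[key]

    def draw_value(
        self,
        lulcc_class: str,
        reservoir: str,
        rng: np.random.Generator | None = None,
        mode: str = "stochastic",
        seed: int = 0,
    ) -> float:
        """One value for a (class, reservoir) pair.

        ``expected`` mode returns the class mean exactly (deterministic,
        seed-independent); ``stochastic`` mode samples uniformly from the
        class pool.
        """
        p = self.get(lulcc_class, reservoir)
        if mode == "expected":
            return p.avg
        if mode != "stochastic":
            raise ValueError(f"unknown mode {mode!r}")
        if rng is None:
            rng = np.random.default_rng()
        pool = self.pool(lulcc_class, reservoir, seed)
        return float(pool[rng.integers(self.n_pop)])
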