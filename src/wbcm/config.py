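"""Run configuration and the end-to-end pipeline.

``run_pipeline`` reads a land-cover raster directory, runs the
bookkeeping reconstruction, and writes the full report bundle: tidy
CSVs of regional totals, period statistics and period t-tests, class
areas, the first-to-last-year total-carbon difference map, a time-series
plot and a manifest (seed, mode, parameter-file hash, package version)
so a rerun with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gridio import read_lulcc_dir, write_ascii_grid, write_state
from .model import default_legend, default_mapping, run_reconstruction
from .params import DEFAULT_K, DEFAULT_N_POP, CarbonParamTable
from .report import (
    DEFAULT_PERIODS,
    add_rollups,
    aggregate,
    area_accounting,
    diff_map,
    period_change_tests,
    period_stats,
    plot_timeseries,
)

__all__ = ["RunConfig", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    lulcc_dir: Path
    out_dir: Path
    params_file: Path | None = None
    legend_file: Path | None = None
    mode: str = "stochastic"
    seed: int = 0
    k: float = DEFAULT_K
    n_pop: int = DEFAULT_N_POP
    ttest_variant: str = "pooled"
    periods: tuple[tuple[str, int, int], ...] = DEFAULT_PERIODS
    write_states: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "periods" in raw:
            raw["periods"] = tuple(tuple(p) for p in raw["periods"])
        for key in ("lulcc_dir", "out_dir", "params_file", "legend_file"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def validate(self) -> None:
        if not Path(self.lulcc_dir).is_dir():
            raise ConfigError(f"land-cover directory not found: {self.lulcc_dir}")
        for f in (self.params_file, self.legend_file):
            if f is not None and not Path(f).is_file():
                raise ConfigError(f"file not found: {f}")
        if self.mode not in ("stochastic", "expected"):
            raise ConfigError(f"mode must be stochastic or expected, got {self.mode!r}")
        labels = [p[0] for p in self.periods]
        spans = sorted((p[1], p[2]) for p in self.periods)
        if any(a2 < a1 for _, (a1, a2) in zip(labels, spans)):
            raise ConfigError("period ranges must be ordered (start <= end)")
        if any(b1 <= a2 for (_, a2), (b1, _) in zip(spans, spans[1:])):
            raise ConfigError("periods must be non-overlapping and ordered")


def _sha256(path: Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute reconstruction + reporting; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    legend = (
        json.loads(Path(config.legend_file).read_text())
        if config.legend_file
        else default_legend()
    )
    mapping = default_mapping(legend)
    table = (
        CarbonParamTable.from_csv(config.params_file, k=config.k, n_pop=config.n_pop)
        if config.params_file
        else CarbonParamTable.default(k=config.k, n_pop=config.n_pop)
    )

    series = read_lulcc_dir(config.lulcc_dir, legend)
    years = [r.year for r in series]

    per_year = []
    states_ends = {}

    def on_state(state, lulcc):
        per_year.append(aggregate(state, lulcc, mapping))
        if state.year in (years[0], years[-1]):
            states_ends[state.year] = state
        if config.write_states:
            write_state(out / "states", state)

    run_reconstruction(series, table, mapping, mode=config.mode,
                       seed=config.seed, on_state=on_state, keep="last")

    totals = pd.concat(per_year, ignore_index=True)
    rolled = add_rollups(totals)
    areas = area_accounting(series, legend)
    region_area = float(areas[areas["year"] == years[0]]["area_mha"].sum())

    rolled.to_csv(out / "totals.csv", index=False)
    areas.to_csv(out / "areas.csv", index=False)

    periods = [p for p in config.periods if p[1] >= years[0] and p[2] <= years[-1]]
    stats_df = tests_df = None
    if periods:
        stats_df = period_stats(totals, region_area, periods)
        stats_df.to_csv(out / "period_stats.csv", index=False)
        if len(periods) > 1:
            tests_df = pd.concat(
                [
                    period_change_tests(totals, region_area, periods[0], p,
                                        variant=config.ttest_variant)
                    for p in periods[1:]
                ],
                ignore_index=True,
            )
            tests_df.to_csv(out / "period_tests.csv", index=False)

    dmap = diff_map(states_ends[years[0]], states_ends[years[-1]])
    write_ascii_grid(out / f"tcs_diff_{years[0]}_{years[-1]}.asc", dmap,
                     series[0].geometry, -9999.0)
    plot_timeseries(totals, out / "tcs_timeseries.png")

    manifest = {
        "package_version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "k": config.k,
        "n_pop": config.n_pop,
        "ttest_variant": config.ttest_variant,
        "years": years,
        "region_area_mha": region_area,
        "params_sha256": _sha256(config.params_file),
        "n_rasters": len(series),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
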