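"""Raster and table input/output.

Rasters are stored in the plain-text ESRI ASCII grid format (``.asc``:
a six-line header — ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value — followed by whitespace-separated rows), with a JSON
sidecar (``<name>.meta.json``) carrying anything the header cannot:
year, CRS tag, seed, mode, parameter-file hash. A carbon state is three
grids (``agb_YYYY.asc`` etc.) sharing one sidecar; values round-trip
losslessly at float32 precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import CarbonState, GeometryError, GridGeometry, LulccRaster

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_lulcc",
    "read_lulcc_dir",
    "write_state",
    "read_state",
]

_YEAR_RE = re.compile(r"(\d{4})")


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    geometry: GridGeometry,
    nodata: float | int,
    fmt: str = "%.9e",
) -> None:
    path = Path(path)
    nrows, ncols = grid.shape
    a, _, x0, _, e, y0 = geometry.transform
    yll = y0 + e * nrows  # e is negative (north-up): lower-left corner
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {x0:.6f}\nyllcorner {yll:.6f}\n"
        f"cellsize {abs(a):.6f}\nNODATA_value {nodata}\n"
    )
    out = grid
    if np.issubdtype(grid.dtype, np.floating):
        out = np.where(np.isnan(grid), nodata, grid)
    with open(path, "w") as f:
        f.write(header)
        np.savetxt(f, out, fmt=fmt)


def read_ascii_grid(path: str | Path, crs: str = "EPSG:32723"):
    """Returns (array, GridGeometry, nodata). Nodata in float grids
    becomes NaN; integer grids keep the nodata code."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as f:
        for _ in range(6):
            k, v = f.readline().split()
            header[k.lower()] = float(v)
        data = np.loadtxt(f)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({nrows}, {ncols})")
    cs = header["cellsize"]
    y0 = header["yllcorner"] + cs * nrows
    geom = GridGeometry(
        shape=(nrows, ncols),
        transform=(cs, 0.0, header["xllcorner"], 0.0, -cs, y0),
        crs=crs,
    )
    return data, geom, header["nodata_value"]


def write_lulcc(path: str | Path, raster: LulccRaster, meta: dict | None = None) -> None:
    write_ascii_grid(path, raster.grid, raster.geometry, raster.nodata, fmt="%d")
    sidecar = Path(path).with_suffix("").with_suffix(".meta.json")
    payload = {"year": raster.year, "crs": raster.geometry.crs}
    if meta:
        payload.update(meta)
    sidecar.write_text(json.dumps(payload, indent=1))


def read_lulcc_dir(
    path: str | Path, legend: dict[str, int], nodata: int | None = None
) -> list[LulccRaster]:
    """Read all ``*.asc`` rasters in a directory, sorted by the 4-digit
    year in their file names; enforces shared geometry and known codes."""
    path = Path(path)
    files = sorted(path.glob("*.asc"))
    if not files:
        raise FileNotFoundError(f"no .asc rasters found in {path}")
    if nodata is None:
        nodata = legend.get("nodata", 0)
    by_year: dict[int, Path] = {}
    for f in files:
        m = _YEAR_RE.search(f.stem)
        if not m:
            raise ValueError(f"cannot parse a 4-digit year from file name {f.name}")
        year = int(m.group(1))
        if year in by_year:
            raise ValueError(f"duplicate year {year}: {by_year[year].name} and {f.name}")
        by_year[year] = f
    out: list[LulccRaster] = []
    geom0 = None
    for year in sorted(by_year):
        data, geom, _ = read_ascii_grid(by_year[year])
        if geom0 is None:
            geom0 = geom
        elif geom != geom0:
            raise GeometryError(f"{by_year[year].name}: geometry differs from first raster")
        r = LulccRaster(year=year, grid=data.astype(np.uint8), geometry=geom, nodata=nodata)
        try:
            r.validate_codes(legend)
        except ValueError as exc:
            raise ValueError(f"{by_year[year].name}: {exc}") from None
        out.append(r)
    return out


def write_state(outdir: str | Path, state: CarbonState, nodata: float = -9999.0) -> None:
    """Write one carbon state as three float grids plus a sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for res, arr in (("agb", state.agb), ("bgb", state.bgb), ("scs", state.scs)):
        write_ascii_grid(outdir / f"{res}_{state.year}.asc",
                         arr.astype(np.float32).astype(np.float64),
                         state.geometry, nodata)
    (outdir / f"state_{state.year}.meta.json").write_text(
        json.dumps({"year": state.year, "crs": state.geometry.crs,
                    **state.provenance}, indent=1)
    )


def read_state(outdir: str | Path, year: int) -> CarbonState:
    outdir = Path(outdir)
    arrays = {}
    geom = None
    for res in ("agb", "bgb", "scs"):
        f = outdir / f"{res}_{year}.asc"
        if not f.exists():
            raise FileNotFoundError(f"missing band file {f}")
        data, g, nodata = read_ascii_grid(f)
        data = np.where(data == nodata, np.nan, data)
        if geom is None:
            geom = g
        elif g != geom:
            raise GeometryError(f"{f.name}: geometry differs between state bands")
        arrays[res] = data
    meta_file = outdir / f"state_{year}.meta.json"
    prov = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    prov.pop("year", None)
    crs = prov.pop("crs", geom.crs)
    geom = GridGeometry(shape=geom.shape, transform=geom.transform, crs=crs)
    return CarbonState(year=year, agb=arrays["agb"], bgb=arrays["bgb"],
                       scs=arrays["scs"], geometry=geom, provenance=prov)
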