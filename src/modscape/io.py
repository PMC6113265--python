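"""Raster and bundle I/O.

Rasters are written as plain single-band TIFF (float32 for continuous
layers, uint8 for categorical) with a JSON sidecar (``<name>.tif.json``)
carrying the grid metadata — pixel size, origin, nodata — plus any class-code
table.  Write/read roundtrips are value-exact for the stored dtype.  All
layers of one run must share a single grid; reading a raster against an
expected grid raises :class:`~modscape.grids.AlignmentError` naming both.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .grids import CLASS_CODES, LandUseMap, RasterGrid, ZONE_CODES
from .synthetic import LandscapeBundle, SyntheticConfig


def write_raster(values: np.ndarray, grid: RasterGrid, path: str | Path,
                 categorical: bool = False, classes: dict | None = None,
                 extra: dict | None = None) -> Path:
    """Write one single-band raster and its JSON grid sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(values)
    if categorical:
        arr = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
    else:
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    sidecar = {
        "shape": list(grid.shape),
        "pixel_size": grid.pixel_size,
        "origin": list(grid.origin),
        "nodata": None if np.isnan(grid.nodata) else grid.nodata,
        "dtype": str(arr.dtype),
    }
    if classes:
        sidecar["classes"] = classes
    if extra:
        sidecar["extra"] = extra
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_raster(path: str | Path,
                expect_grid: RasterGrid | None = None) -> tuple[np.ndarray, RasterGrid]:
    """Read a raster + sidecar; optionally enforce a run grid."""
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        grid = RasterGrid(
            shape=tuple(meta["shape"]),
            pixel_size=float(meta["pixel_size"]),
            origin=tuple(meta.get("origin", (0.0, 0.0))),
            nodata=float("nan") if meta.get("nodata") is None else float(meta["nodata"]),
        )
    else:
        grid = RasterGrid(shape=arr.shape)
    if expect_grid is not None:
        expect_grid.require_match(grid, what=str(path))
    return arr, grid


def write_bundle(bundle: LandscapeBundle, out_dir: str | Path) -> Path:
    """Serialize a synthetic landscape bundle to a directory of rasters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = bundle.grid
    write_raster(bundle.landuse_t0.classes, g, out / "landuse_t0.tif",
                 categorical=True, classes=CLASS_CODES)
    write_raster(bundle.zones, g, out / "zones.tif",
                 categorical=True, classes=ZONE_CODES)
    for name in ("dem", "precipitation", "temperature", "et0"):
        write_raster(getattr(bundle, name), g, out / f"{name}.tif")
    for name, arr in bundle.soil_stack.items():
        write_raster(arr, g, out / f"soil_{name}.tif")
    for name, arr in bundle.wind_stack.items():
        write_raster(arr, g, out / f"wind_{name}.tif")
    cfg = dataclasses.asdict(bundle.config)
    (out / "config.json").write_text(json.dumps(cfg, indent=1))
    return out


def read_bundle(bundle_dir: str | Path) -> LandscapeBundle:
    """Reload a bundle written by :func:`write_bundle`."""
    d = Path(bundle_dir)
    cfg_raw = json.loads((d / "config.json").read_text())
    cfg_raw["shape"] = tuple(cfg_raw["shape"])
    cfg_raw["elevation_range"] = tuple(cfg_raw["elevation_range"])
    config = SyntheticConfig(**cfg_raw)
    lu, grid = read_raster(d / "landuse_t0.tif")
    zones, _ = read_raster(d / "zones.tif", expect_grid=grid)
    layers = {}
    for name in ("dem", "precipitation", "temperature", "et0"):
        layers[name], _ = read_raster(d / f"{name}.tif", expect_grid=grid)
    soil = {p.name[len("soil_"):-len(".tif")]: read_raster(p, expect_grid=grid)[0]
            for p in sorted(d.glob("soil_*.tif"))}
    wind = {p.name[len("wind_"):-len(".tif")]: read_raster(p, expect_grid=grid)[0]
            for p in sorted(d.glob("wind_*.tif"))}
    return LandscapeBundle(
        landuse_t0=LandUseMap(lu, grid, zones),
        dem=layers["dem"].astype(float),
        precipitation=layers["precipitation"].astype(float),
        temperature=layers["temperature"].astype(float),
        et0=layers["et0"].astype(float),
        soil_stack={k: v.astype(float) for k, v in soil.items()},
        wind_stack={k: v.astype(float) for k, v in wind.items()},
        zones=zones, grid=grid, config=config,
    )
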