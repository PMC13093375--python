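"""Raster, vector, occurrence, tree and config I/O.

Two raster formats are supported:

* single-band float32 GeoTIFF (``.tif``/``.tiff``) carrying the standard
  ``ModelPixelScale``/``ModelTiepoint``/``GDAL_NODATA`` tags. When the grid is
  metric with km units, header pixel sizes are written in metres (4.5 km cells
  become a 4500 m pixel), matching how projected GeoTIFFs are conventionally
  georeferenced. Grid metadata that TIFF tags cannot carry (variable name,
  CRS tag, units) lives in a JSON ``ImageDescription``.
* a plain-text grid dialect (``.asc``/``.grd``/``.txt``): a ``key value``
  header followed by the value matrix, one row per line. Human-readable and
  diff-able; the format used by test fixtures.

Vector polygons are read/written as GeoJSON via :mod:`shapely`; occurrences as
``species,x,y`` CSV; trees as newick; configuration as YAML.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape

from .grid import Grid, GridMismatchError, MaskLayer, OccurrenceSet, RasterLayer, require_same_grid
from .trees import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "read_raster",
    "write_raster",
    "read_occurrences",
    "write_occurrences",
    "read_tree",
    "write_tree",
    "read_geojson",
    "write_geojson",
    "rasterize_mask",
    "read_config",
    "write_config",
]

_TEXT_SUFFIXES = (".asc", ".grd", ".txt")
_TIFF_SUFFIXES = (".tif", ".tiff")

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


def _grid_scale_factor(grid: Grid) -> float:
    """Multiplier from grid units to the units stored in GeoTIFF headers."""
    return 1000.0 if grid.units == "km" else 1.0


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_raster(layer: RasterLayer, path) -> Path:
    """Write ``layer`` to ``path``; format chosen by file suffix."""
    path = Path(path)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        _write_text_grid(layer, path)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        _write_geotiff(layer, path)
    else:
        raise ValueError(f"unsupported raster suffix {path.suffix!r}")
    return path


def read_raster(path, reference_grid: Grid | None = None) -> RasterLayer:
    """Read a raster; optionally enforce geometry against ``reference_grid``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        layer = _read_text_grid(path)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        layer = _read_geotiff(path)
    else:
        raise ValueError(f"unsupported raster suffix {path.suffix!r}")
    if reference_grid is not None:
        require_same_grid(reference_grid, layer.grid, str(path))
    return layer


def _write_text_grid(layer: RasterLayer, path: Path) -> None:
    g = layer.grid
    vals = np.where(np.isnan(layer.values), g.nodata, layer.values)
    with open(path, "w") as fh:
        fh.write("PALEOREFUGIA_GRID 1\n")
        fh.write(f"variable {layer.variable or '-'}\n")
        fh.write(f"crs_tag {g.crs_tag}\n")
        fh.write(f"units {g.units}\n")
        fh.write(f"n_rows {g.n_rows}\n")
        fh.write(f"n_cols {g.n_cols}\n")
        fh.write(f"origin_x {g.origin_x!r}\n")
        fh.write(f"origin_y {g.origin_y!r}\n")
        fh.write(f"cell_size {g.cell_size!r}\n")
        fh.write(f"nodata {g.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_text_grid(path: Path) -> RasterLayer:
    with open(path) as fh:
        magic = fh.readline().split()
        if not magic or magic[0] != "PALEOREFUGIA_GRID":
            raise ValueError(f"{path} is not a paleorefugia text grid")
        header = {}
        for _ in range(9):
            key, value = fh.readline().split(None, 1)
            header[key] = value.strip()
        n_rows, n_cols = int(header["n_rows"]), int(header["n_cols"])
        grid = Grid(
            n_rows=n_rows,
            n_cols=n_cols,
            origin_x=float(header["origin_x"]),
            origin_y=float(header["origin_y"]),
            cell_size=float(header["cell_size"]),
            nodata=float(header["nodata"]),
            crs_tag=header["crs_tag"],
            units=header["units"],
        )
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: matrix shape {values.shape} != header {(n_rows, n_cols)}")
    values[values == grid.nodata] = np.nan
    variable = "" if header["variable"] == "-" else header["variable"]
    return RasterLayer(grid, values, variable)


def _write_geotiff(layer: RasterLayer, path: Path) -> None:
    import tifffile

    g = layer.grid
    scale = _grid_scale_factor(g)
    vals = np.where(np.isnan(layer.values), g.nodata, layer.values).astype(np.float32)
    description = json.dumps(
        {"variable": layer.variable, "crs_tag": g.crs_tag, "units": g.units}
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size * scale, g.cell_size * scale, 0.0)),
        (
            _MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, g.origin_x * scale, g.origin_y * scale, 0.0),
        ),
        (_GDAL_NODATA, "s", 0, str(g.nodata)),
    ]
    tifffile.imwrite(path, vals, description=description, extratags=extratags)


def _read_geotiff(path: Path) -> RasterLayer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: multi-band rasters are not supported")
        page = tif.pages[0]
        arr = page.asarray()
        if arr.ndim != 2:
            raise ValueError(f"{path}: multi-band rasters are not supported")
        tags = page.tags
        meta = {"variable": "", "crs_tag": "synthetic-cartesian", "units": "km"}
        if page.description:
            try:
                meta.update(json.loads(page.description))
            except json.JSONDecodeError:
                pass
        scale_tag = tags.get(_MODEL_PIXEL_SCALE)
        tie_tag = tags.get(_MODEL_TIEPOINT)
        nodata_tag = tags.get(_GDAL_NODATA)
        if scale_tag is None or tie_tag is None:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        scale = 1000.0 if meta["units"] == "km" else 1.0
        cell = float(scale_tag.value[0]) / scale
        origin_x = float(tie_tag.value[3]) / scale
        origin_y = float(tie_tag.value[4]) / scale
        nodata = float(nodata_tag.value) if nodata_tag is not None else -9999.0
    grid = Grid(
        n_rows=arr.shape[0],
        n_cols=arr.shape[1],
        origin_x=origin_x,
        origin_y=origin_y,
        cell_size=cell,
        nodata=nodata,
        crs_tag=meta["crs_tag"],
        units=meta["units"],
    )
    values = arr.astype(float)
    values[values == nodata] = np.nan
    return RasterLayer(grid, values, meta["variable"])


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def read_occurrences(path) -> list[OccurrenceSet]:
    """Read a ``species,x,y`` CSV into one :class:`OccurrenceSet` per species.

    Exact duplicate coordinates are collapsed; species are returned sorted by
    name so the result is order-independent.
    """
    df = pd.read_csv(path)
    missing = {"species", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    for col in ("x", "y"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"occurrence column {col!r} is not numeric")
    sets = []
    for species, sub in df.groupby("species", sort=True):
        occ = OccurrenceSet(str(species), sub[["x", "y"]].to_numpy(float))
        logger.info(
            "occurrences: species=%s unique=%d modelable=%s",
            species, occ.n_unique, occ.modelable,
        )
        sets.append(occ)
    return sets


def write_occurrences(sets: Iterable[OccurrenceSet], path) -> Path:
    frames = [
        pd.DataFrame({"species": s.species, "x": s.points[:, 0], "y": s.points[:, 1]})
        for s in sets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path) -> Phylogeny:
    return Phylogeny.read(path)


def write_tree(tree: Phylogeny, path) -> Path:
    tree.write(path)
    return Path(path)


# ---------------------------------------------------------------------------
# vector geometry
# ---------------------------------------------------------------------------

def read_geojson(path) -> list:
    """Read all geometries of a GeoJSON file (FeatureCollection or geometry)."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        return [shapely_shape(f["geometry"]) for f in obj["features"]]
    if obj.get("type") == "Feature":
        return [shapely_shape(obj["geometry"])]
    return [shapely_shape(obj)]


def write_geojson(geometries: Sequence, path) -> Path:
    features = [
        {"type": "Feature", "properties": {}, "geometry": shapely_mapping(g)}
        for g in geometries
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return Path(path)


def rasterize_mask(polygons: Sequence, grid: Grid, role: str = "study_area") -> MaskLayer:
    """Rasterize polygons with the center-point rule.

    A cell is 1 iff its center falls inside (or on the boundary of) any
    polygon. Deterministic and area-unbiased at the analysis resolution.
    """
    polygons = list(polygons)
    values = np.zeros(grid.shape, dtype=float)
    if not polygons:
        warnings.warn("rasterize_mask: empty geometry collection; all-zero mask")
        return MaskLayer(grid, values, role)
    xs, ys = grid.cell_centers()
    points = shapely.points(xs.ravel(), ys.ravel())
    covered = np.zeros(points.shape, dtype=bool)
    for poly in polygons:
        covered |= shapely.covers(poly, points)
    values = covered.reshape(grid.shape).astype(float)
    return MaskLayer(grid, values, role)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return Path(path)
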