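"""Regular lon/lat raster grids and single-band GeoTIFF I/O.

A :class:`RasterStack` holds named, coregistered 2-D float layers over a
north-up regular grid in geographic coordinates (WGS84 by default).  Nodata is
represented internally as NaN; a cell is *valid* only when every layer is
finite there, so the whole stack shares one nodata mask.

GeoTIFFs are written one single-band float32 file per layer with the standard
georeferencing tags (ModelPixelScale, ModelTiepoint, a minimal
GeoKeyDirectory carrying the EPSG code, and GDAL_NODATA), plus a JSON
manifest naming the layers, so a stack round-trips losslessly and remains
readable by GDAL-based tools.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

NODATA = -9999.0

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridGeoreference:
    """Affine georeference of a north-up regular grid.

    ``x_origin``/``y_origin`` are the coordinates of the outer corner of cell
    (0, 0); ``x_res`` is positive, ``y_res`` negative for north-up grids.
    """

    x_origin: float
    y_origin: float
    x_res: float
    y_res: float

    def cell_centers(self, rows, cols):
        lon = self.x_origin + (np.asarray(cols, dtype=float) + 0.5) * self.x_res
        lat = self.y_origin + (np.asarray(rows, dtype=float) + 0.5) * self.y_res
        return lon, lat

    def cell_index(self, lons, lats):
        """Map coordinates to (row, col); half-open cells, points exactly on
        an interior edge go to the lower-index cell."""
        fx = (np.asarray(lons, dtype=float) - self.x_origin) / self.x_res
        fy = (np.asarray(lats, dtype=float) - self.y_origin) / self.y_res
        cols = np.floor(fx).astype(np.int64)
        rows = np.floor(fy).astype(np.int64)
        cols = np.where((fx == cols) & (cols > 0), cols - 1, cols)
        rows = np.where((fy == rows) & (rows > 0), rows - 1, rows)
        return rows, cols

    def close_to(self, other: "GridGeoreference", tol: float = 1e-6) -> bool:
        return (
            abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.x_res - other.x_res) <= tol
            and abs(self.y_res - other.y_res) <= tol
        )


@dataclass
class RasterStack:
    """Named coregistered layers sharing one grid and one nodata mask."""

    names: list[str]
    data: np.ndarray  # (n_layers, n_rows, n_cols), float64, NaN = nodata
    georef: GridGeoreference
    crs: str = "EPSG:4326"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise ValueError("data must be (n_layers, rows, cols) matching names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def n_layers(self) -> int:
        return len(self.names)

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where every layer is finite."""
        return np.isfinite(self.data).all(axis=0)

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "RasterStack":
        idx = [self.names.index(n) for n in names]
        return RasterStack(list(names), self.data[idx].copy(), self.georef, self.crs)

    def table(self, names: Sequence[str] | None = None):
        """Predictor values at all valid cells.

        Returns ``(X, rows, cols)`` where X is (n_valid, n_layers) in the
        order of ``names`` (default: all layers).
        """
        names = list(names) if names is not None else self.names
        mask = self.valid_mask
        rows, cols = np.nonzero(mask)
        idx = [self.names.index(n) for n in names]
        X = self.data[idx][:, rows, cols].T
        return X, rows, cols

    def values_at(self, lons, lats, names: Sequence[str] | None = None) -> np.ndarray:
        """Sample layer values at point coordinates (nearest cell)."""
        names = list(names) if names is not None else self.names
        rows, cols = self.georef.cell_index(lons, lats)
        nr, nc = self.shape
        if np.any((rows < 0) | (rows >= nr) | (cols < 0) | (cols >= nc)):
            raise ValueError("point outside raster extent")
        idx = [self.names.index(n) for n in names]
        return self.data[idx][:, rows, cols].T

    def with_layer_data(self, data: np.ndarray) -> "RasterStack":
        return RasterStack(list(self.names), data, self.georef, self.crs)


def _geokeys(epsg: int) -> tuple[int, ...]:
    # version 1.1.0, 3 keys: model type = geographic, raster type = area, GCS
    return (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, epsg)


def write_geotiff(path, array: np.ndarray, georef: GridGeoreference,
                  crs: str = "EPSG:4326", nodata: float = NODATA,
                  dtype=np.float32) -> Path:
    """Write one single-band georeferenced TIFF; NaN cells become ``nodata``."""
    path = Path(path)
    arr = np.asarray(array, dtype=float).copy()
    arr[~np.isfinite(arr)] = nodata
    arr = arr.astype(dtype)
    epsg = int(str(crs).split(":")[-1])
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (georef.x_res, abs(georef.y_res), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, georef.x_origin, georef.y_origin, 0.0)),
        (_TAG_GEOKEYS, "H", 16, _geokeys(epsg)),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]
    tifffile.imwrite(path, arr, extratags=extratags)
    return path


def read_geotiff(path) -> tuple[np.ndarray, GridGeoreference, str]:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`.

    Nodata cells come back as NaN.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray().astype(float)
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        georef = GridGeoreference(
            x_origin=float(tie[3]) - float(tie[0]) * float(scale[0]),
            y_origin=float(tie[4]) + float(tie[1]) * float(scale[1]),
            x_res=float(scale[0]),
            y_res=-float(scale[1]),
        )
        crs = "EPSG:4326"
        if _TAG_GEOKEYS in tags:
            keys = tags[_TAG_GEOKEYS].value
            for i in range(4, len(keys) - 3, 4):
                if keys[i] == 2048:
                    crs = f"EPSG:{keys[i + 3]}"
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            try:
                nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00"))
            except ValueError:
                nodata = None
        if nodata is not None:
            arr[arr == nodata] = np.nan
    return arr, georef, crs


def write_stack(stack: RasterStack, directory) -> list[Path]:
    """Write a stack as one GeoTIFF per layer plus ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in stack.names:
        paths.append(write_geotiff(directory / f"{name}.tif", stack.layer(name),
                                   stack.georef, stack.crs))
    manifest = {
        "layers": stack.names,
        "files": [p.name for p in paths],
        "crs": stack.crs,
        "transform": [stack.georef.x_origin, stack.georef.y_origin,
                      stack.georef.x_res, stack.georef.y_res],
        "nodata": NODATA,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths


def read_stack(source) -> RasterStack:
    """Read a stack from a manifest directory or an iterable of GeoTIFF paths.

    All layers must share the grid (transform within 1e-6 and equal shapes);
    a mismatch raises with the offending layer named.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        directory = Path(source)
        manifest = json.loads((directory / "manifest.json").read_text())
        paths = [directory / f for f in manifest["files"]]
        names = list(manifest["layers"])
    else:
        paths = [Path(p) for p in source]
        names = [p.stem for p in paths]

    arrays, georef, crs = [], None, None
    for name, path in zip(names, paths):
        arr, g, c = read_geotiff(path)
        if georef is None:
            georef, crs, shape = g, c, arr.shape
        else:
            if arr.shape != shape:
                raise ValueError(f"layer '{name}' has shape {arr.shape}, expected {shape}")
            if not g.close_to(georef):
                raise ValueError(f"layer '{name}' transform does not match the stack grid")
        arrays.append(arr)
    if georef is None:
        raise ValueError("no layers to read")
    return RasterStack(names, np.stack(arrays), georef, crs)
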