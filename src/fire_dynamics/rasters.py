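"""Raster containers and TIFF I/O.

Two small in-memory containers carry the pipeline's gridded data:

* :class:`BandStack` — co-registered surface-reflectance grids for one
  epoch (blue, green, red, NIR, SWIR), each dimensionless in [0, 1],
  with a shared validity mask and a GDAL-style geotransform.
* :class:`IndexGrid` — a single derived per-pixel quantity (NDVI, NBR,
  ΔNBR, CO₂-flux index, ...) with nodata carried as NaN plus a mask.

On disk, stacks are float32 multi-page TIFFs with GeoTIFF pixel-scale /
tiepoint tags, a GDAL nodata tag, and a JSON image description holding
band order and epoch, so files open in GIS software and round-trip
losslessly through this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

NODATA = -9999.0
BAND_ORDER = ("blue", "green", "red", "nir", "swir")

# GDAL-style geotransform: (x origin, pixel width, 0, y origin, 0, -pixel height)
GeoTransform = tuple[float, float, float, float, float, float]
DEFAULT_TRANSFORM: GeoTransform = (0.0, 463.3, 0.0, 0.0, 0.0, -463.3)


def _as_grid(a) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got shape {arr.shape}")
    return arr


@dataclass
class BandStack:
    """Co-registered reflectance grids for one epoch.

    ``mask`` is True where a pixel is *invalid* (nodata); invalid cells
    are excluded from all index arithmetic downstream.
    """

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    swir: np.ndarray
    mask: np.ndarray | None = None
    transform: GeoTransform = DEFAULT_TRANSFORM
    epoch: str = ""

    def __post_init__(self) -> None:
        grids = [_as_grid(getattr(self, b)) for b in BAND_ORDER]
        shape = grids[0].shape
        for name, g in zip(BAND_ORDER, grids):
            if g.shape != shape:
                raise ValueError(f"band '{name}' shape {g.shape} != {shape}")
            setattr(self, name, g)
        if self.mask is None:
            self.mask = np.zeros(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise ValueError("mask shape does not match bands")

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape

    def band(self, name: str) -> np.ndarray:
        if name not in BAND_ORDER:
            raise KeyError(f"unknown band '{name}'")
        return getattr(self, name)


@dataclass
class IndexGrid:
    """A single per-pixel index with nodata handling.

    ``values`` holds NaN at invalid cells; ``mask`` mirrors that (True =
    invalid). ``units`` is empty for dimensionless ratio indices.
    """

    values: np.ndarray
    name: str
    mask: np.ndarray | None = None
    transform: GeoTransform = DEFAULT_TRANSFORM
    units: str = ""
    epoch: str = ""

    def __post_init__(self) -> None:
        self.values = _as_grid(self.values)
        invalid = ~np.isfinite(self.values)
        if self.mask is None:
            self.mask = invalid
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | invalid
        self.values = np.where(self.mask, np.nan, self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]


def _geotiff_extratags(transform: GeoTransform, nodata: float):
    x0, dx, _, y0, _, dy = transform
    # ModelPixelScale (33550), ModelTiepoint (33922), GDAL_NODATA (42113)
    return [
        (33550, "d", 3, (abs(dx), abs(dy), 0.0)),
        (33922, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (42113, "s", 0, str(nodata)),
    ]


def write_stack(path, stack: BandStack, nodata: float = NODATA) -> None:
    """Write a BandStack as a 5-page float32 TIFF (blue,green,red,NIR,SWIR)."""
    data = np.stack([stack.band(b) for b in BAND_ORDER]).astype(np.float32)
    data[:, stack.mask] = nodata
    meta = {
        "bands": list(BAND_ORDER),
        "transform": list(stack.transform),
        "nodata": nodata,
        "epoch": stack.epoch,
    }
    tifffile.imwrite(
        path,
        data,
        description=json.dumps(meta),
        extratags=_geotiff_extratags(stack.transform, nodata),
    )


def read_stack(path, band_order: tuple[str, ...] | None = None) -> BandStack:
    """Read a multi-band reflectance TIFF written by :func:`write_stack`.

    ``band_order`` overrides the stored (or default) band ordering for
    stacks produced elsewhere.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float64)
        meta = _read_meta(tif)
    if data.ndim == 2:
        raise ValueError(f"{path}: expected a multi-band stack, got one band")
    order = tuple(band_order or meta.get("bands", BAND_ORDER))
    if len(order) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} bands on disk, {len(order)} names given"
        )
    nodata = float(meta.get("nodata", NODATA))
    mask = np.any(data == nodata, axis=0) | ~np.all(np.isfinite(data), axis=0)
    bands = {name: data[i] for i, name in enumerate(order)}
    bands = {k: np.where(mask, np.nan, v) for k, v in bands.items()}
    return BandStack(
        mask=mask,
        transform=tuple(meta.get("transform", DEFAULT_TRANSFORM)),
        epoch=str(meta.get("epoch", "")),
        **{b: bands[b] for b in BAND_ORDER},
    )


def write_index(path, grid: IndexGrid, nodata: float = NODATA) -> None:
    """Write an IndexGrid as a single-band float32 TIFF."""
    data = np.where(grid.mask, nodata, grid.values).astype(np.float32)
    meta = {
        "index": grid.name,
        "units": grid.units,
        "transform": list(grid.transform),
        "nodata": nodata,
        "epoch": grid.epoch,
    }
    tifffile.imwrite(
        path,
        data,
        description=json.dumps(meta),
        extratags=_geotiff_extratags(grid.transform, nodata),
    )


def read_index(path) -> IndexGrid:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(np.float64)
        meta = _read_meta(tif)
    nodata = float(meta.get("nodata", NODATA))
    mask = (data == nodata) | ~np.isfinite(data)
    return IndexGrid(
        values=np.where(mask, np.nan, data),
        name=str(meta.get("index", "")),
        mask=mask,
        transform=tuple(meta.get("transform", DEFAULT_TRANSFORM)),
        units=str(meta.get("units", "")),
        epoch=str(meta.get("epoch", "")),
    )


def write_byte_grid(path, codes: np.ndarray, transform: GeoTransform,
                    legend: dict, nodata_code: int = 255) -> None:
    """Write an integer class-code grid (e.g. a severity map) as uint8 TIFF."""
    meta = {"legend": legend, "transform": list(transform), "nodata": nodata_code}
    tifffile.imwrite(
        path,
        np.asarray(codes, dtype=np.uint8),
        description=json.dumps(meta),
        extratags=_geotiff_extratags(transform, nodata_code),
    )


def read_byte_grid(path) -> tuple[np.ndarray, GeoTransform, dict]:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = _read_meta(tif)
    return (
        np.asarray(data, dtype=np.uint8),
        tuple(meta.get("transform", DEFAULT_TRANSFORM)),
        meta.get("legend", {}),
    )


def _read_meta(tif: tifffile.TiffFile) -> dict:
    desc = tif.pages[0].description
    if not desc:
        return {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return {}
    return meta if isinstance(meta, dict) else {}
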