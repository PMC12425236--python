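"""Raster readers/writers.

The golden-file dialect is the ESRI ASCII grid (plain text, 6-line header,
``NODATA_value -9999``); values are written at full precision so a write→read
round trip is bit-exact. GeoTIFF is supported for interoperability through
``tifffile`` (single band, no CRS metadata — the pipeline works on
already-aligned grids).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from ..types import Grid

__all__ = ["RasterData", "read_raster", "write_raster"]

_DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class RasterData:
    """A raster lattice plus the grid metadata needed to align it."""

    values: np.ndarray
    nodata_mask: np.ndarray  # True where the cell is NoData
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata_value: float = _DEFAULT_NODATA

    def to_grid(self) -> Grid:
        return Grid(
            n_rows=self.values.shape[0],
            n_cols=self.values.shape[1],
            cell_area=self.cellsize**2,
            valid_mask=~self.nodata_mask,
        )


def read_raster(path: str | Path, grid: Optional[Grid] = None) -> RasterData:
    """Read a GeoTIFF or ESRI ASCII grid raster.

    If *grid* is given, the raster must align with it (same shape) or an
    alignment error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt"):
        data = _read_ascii(path)
    elif suffix in (".tif", ".tiff"):
        data = _read_tiff(path)
    else:
        raise ValueError(f"unknown raster format {suffix!r} (expected .asc or .tif)")
    if grid is not None and data.values.shape != grid.shape:
        raise ValueError(
            f"raster {path.name} shape {data.values.shape} does not align "
            f"with grid {grid.shape}"
        )
    return data


def write_raster(
    path: str | Path,
    values: np.ndarray,
    nodata_mask: Optional[np.ndarray] = None,
    cellsize: float = 1.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
) -> Path:
    """Write a raster; the format is chosen by extension (.asc or .tif)."""
    path = Path(path)
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("raster values must be 2-D")
    if nodata_mask is None:
        nodata_mask = np.zeros(values.shape, dtype=bool)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt"):
        _write_ascii(path, values, nodata_mask, cellsize, xllcorner, yllcorner)
    elif suffix in (".tif", ".tiff"):
        _write_tiff(path, values, nodata_mask)
    else:
        raise ValueError(f"unknown raster format {suffix!r} (expected .asc or .tif)")
    return path


def _write_ascii(path, values, nodata_mask, cellsize, xllcorner, yllcorner):
    out = np.where(nodata_mask, _DEFAULT_NODATA, values.astype(float))
    with open(path, "w") as fh:
        fh.write(f"ncols {values.shape[1]}\n")
        fh.write(f"nrows {values.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner:.17g}\n")
        fh.write(f"yllcorner {yllcorner:.17g}\n")
        fh.write(f"cellsize {cellsize:.17g}\n")
        fh.write(f"NODATA_value {_DEFAULT_NODATA:g}\n")
        for row in out:
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


def _read_ascii(path) -> RasterData:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "cellsize",
            "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing header field {key}")
    body = "\n".join(lines[i:])
    values = np.array(body.split(), dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.size != n_rows * n_cols:
        raise ValueError(
            f"ASCII grid {path}: expected {n_rows * n_cols} values, got {values.size}"
        )
    values = values.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    return RasterData(
        values=values,
        nodata_mask=values == nodata,
        cellsize=header.get("cellsize", 1.0),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        nodata_value=nodata,
    )


def _write_tiff(path, values, nodata_mask):
    import tifffile

    if values.dtype == bool or np.issubdtype(values.dtype, np.integer):
        out = values.astype(np.uint8)
        if nodata_mask.any():
            out = np.where(nodata_mask, 255, out).astype(np.uint8)
    else:
        out = np.where(nodata_mask, np.nan, values).astype(np.float32)
    tifffile.imwrite(path, out)


def _read_tiff(path) -> RasterData:
    import tifffile

    values = np.asarray(tifffile.imread(path))
    if values.ndim != 2:
        raise ValueError(f"GeoTIFF {path} is not single-band")
    if np.issubdtype(values.dtype, np.floating):
        nodata_mask = np.isnan(values)
    else:
        nodata_mask = values == 255
    return RasterData(
        values=values.astype(float), nodata_mask=nodata_mask, nodata_value=np.nan
    )
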