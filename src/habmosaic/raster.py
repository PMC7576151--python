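"""Single-band raster grid: the carrier for covariates, suitability and masks.

A :class:`Raster` is a 2-D array on a uniform square-cell grid with an
affine-north-up transform described by the origin of the lower-left corner
and the cell size. Nodata is represented as NaN in float rasters and as a
sentinel in integer rasters. All stack operations require an identical grid.

Rasters are stored on disk as ESRI ASCII grids (plain text) with an optional
JSON sidecar carrying the CRS tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

INT_NODATA = -9999


@dataclass
class Raster:
    """A single-band grid.

    Parameters
    ----------
    values
        2-D array (row 0 = northernmost row, as in ASCII grid layout).
    x_origin, y_origin
        Coordinates (m) of the lower-left corner of the grid.
    cell_size
        Square cell edge length in metres; must be positive.
    crs_tag
        Free-form CRS label (e.g. an EPSG string); not interpreted.
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 120.0
    crs_tag: str = "local-albers"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- grid geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def require_same_grid(self, other: "Raster") -> None:
        if not self.same_grid(other):
            raise ValueError("rasters are not on the same grid/transform")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, each of shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin + (self.nrows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        row = self.nrows - 1 - np.floor((y - self.y_origin) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        if not np.all(inside):
            raise ValueError("points fall outside the raster extent")
        return row, col

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Raster values at point locations (cell containing each point)."""
        row, col = self.index_of(x, y)
        return self.values[row, col]

    # -- nodata --------------------------------------------------------
    def nodata_mask(self) -> np.ndarray:
        if np.issubdtype(self.values.dtype, np.floating):
            return np.isnan(self.values)
        return self.values == INT_NODATA

    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask()

    # -- derivation ----------------------------------------------------
    def with_values(self, values: np.ndarray) -> "Raster":
        """A new raster on this grid holding `values`."""
        if np.asarray(values).shape != self.shape:
            raise ValueError("replacement values have the wrong shape")
        return replace(self, values=np.asarray(values))

    def copy(self) -> "Raster":
        return replace(self, values=self.values.copy())

    # -- area ----------------------------------------------------------
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    # -- I/O -----------------------------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid, plus a `.json` sidecar for the CRS."""
        path = Path(path)
        is_int = np.issubdtype(self.values.dtype, np.integer)
        nodata = INT_NODATA if is_int else -9999.0
        vals = self.values.astype(float).copy()
        if not is_int:
            vals[np.isnan(vals)] = nodata
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.x_origin}\n")
            fh.write(f"yllcorner {self.y_origin}\n")
            fh.write(f"cellsize {self.cell_size}\n")
            fh.write(f"NODATA_value {nodata}\n")
            fmt = "%d" if is_int else "%.8g"
            np.savetxt(fh, vals, fmt=fmt)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"crs_tag": self.crs_tag, "integer": bool(is_int)}))

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        path = Path(path)
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        crs_tag = "local-albers"
        is_int = False
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            crs_tag = meta.get("crs_tag", crs_tag)
            is_int = meta.get("integer", False)
        nodata = header.get("nodata_value", -9999.0)
        if is_int:
            values = values.astype(int)
        else:
            values[values == nodata] = np.nan
        return cls(
            values=values,
            x_origin=header["xllcorner"],
            y_origin=header["yllcorner"],
            cell_size=header["cellsize"],
            crs_tag=crs_tag,
        )


def stack_valid_mask(rasters: list[Raster]) -> np.ndarray:
    """Cells valid in every raster of a stack."""
    if not rasters:
        raise ValueError("empty stack")
    mask = rasters[0].valid_mask()
    for r in rasters[1:]:
        rasters[0].require_same_grid(r)
        mask &= r.valid_mask()
    return mask
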