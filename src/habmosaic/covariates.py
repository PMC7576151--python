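"""Raster habitat variables: distance, density, terrain and patch metrics.

These are the standard landscape-ecology covariates fed to the suitability
models: Euclidean distance to a cover class, focal (moving-window) density,
the terrain ruggedness index (TRI), Fragstats-style patch shape index and
contiguity, plus the pairwise correlation screen that decides which
variables may enter the same model.

All operators inherit the grid/transform of their input, propagate nodata,
and are validated against brute-force oracles in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster


@dataclass
class CovariateStack:
    """Named rasters on one shared grid, with metadata and correlations."""

    rasters: dict[str, Raster]
    metadata: dict[str, str] = field(default_factory=dict)
    correlation: pd.DataFrame | None = None
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = list(self.rasters)
        if len(names) != len(set(names)):
            raise ValueError("covariate names must be unique")
        first = next(iter(self.rasters.values()))
        for r in self.rasters.values():
            first.require_same_grid(r)

    @property
    def names(self) -> list[str]:
        return list(self.rasters)

    @property
    def grid(self) -> Raster:
        return next(iter(self.rasters.values()))

    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.grid.shape, dtype=bool)
        for r in self.rasters.values():
            mask &= r.valid_mask()
        return mask

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        """(n_valid_cells, n_vars) matrix of covariate values."""
        names = names or self.names
        mask = self.valid_mask()
        return np.column_stack([self.rasters[n].values[mask] for n in names])

    def values_at(self, x: np.ndarray, y: np.ndarray,
                  names: list[str] | None = None) -> np.ndarray:
        names = names or self.names
        return np.column_stack([self.rasters[n].sample(x, y) for n in names])

    def subset(self, names: list[str]) -> "CovariateStack":
        return CovariateStack(
            rasters={n: self.rasters[n] for n in names},
            metadata={n: self.metadata.get(n, "") for n in names},
        )


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

def euclidean_distance(mask: Raster) -> Raster:
    """Center-to-center Euclidean distance (m) to the nearest true cell."""
    m = mask.values.astype(bool)
    if not m.any():
        raise ValueError("distance target mask has no true cells")
    dist = ndimage.distance_transform_edt(~m, sampling=mask.cell_size)
    return mask.with_values(dist.astype(float))


def _disc_kernel(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    di, dj = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    return (di**2 + dj**2 <= radius_cells**2).astype(float)


def focal_density(mask: Raster, radius_m: float) -> Raster:
    """Proportion of cells within ``radius_m`` of the focal center that are true.

    A cell belongs to the window when its center lies within the radius of
    the focal cell's center. Edge windows are truncated to in-extent cells,
    so the output stays a true proportion in [0, 1] everywhere.
    """
    if radius_m < mask.cell_size:
        raise ValueError("window radius must be at least one cell")
    kernel = _disc_kernel(radius_m / mask.cell_size)
    m = mask.values.astype(float)
    hits = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    norm = ndimage.convolve(np.ones_like(m), kernel, mode="constant", cval=0.0)
    return mask.with_values(hits / norm)


def tri(elevation: Raster) -> Raster:
    """Terrain ruggedness index.

    Root-mean-square elevation difference between each cell and its eight
    neighbours; boundary cells average over the neighbours that exist.
    """
    z = elevation.values.astype(float)
    nrows, ncols = z.shape
    sq_sum = np.zeros_like(z)
    count = np.zeros_like(z)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            src = z[max(0, -di):nrows - max(0, di), max(0, -dj):ncols - max(0, dj)]
            dst = z[max(0, di):nrows - max(0, -di), max(0, dj):ncols - max(0, -dj)]
            view = (slice(max(0, di), nrows - max(0, -di)),
                    slice(max(0, dj), ncols - max(0, -dj)))
            sq_sum[view] += (src - dst) ** 2
            count[view] += 1.0
    return elevation.with_values(np.sqrt(sq_sum / count))


def label_patches(class_mask: Raster) -> Raster:
    """4-connected components of a binary class raster (0 = background)."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, _ = ndimage.label(class_mask.values.astype(bool), structure=structure)
    return class_mask.with_values(labels)


def patch_perimeter_area(labels: np.ndarray) -> dict[int, tuple[int, int]]:
    """Per-patch (perimeter in cell edges, area in cells).

    Perimeter counts every cell edge shared with a different patch, the
    background, or the grid exterior: P = 4A - 2 * (same-patch rook pairs).
    """
    out: dict[int, tuple[int, int]] = {}
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    shared = {int(i): 0 for i in ids}
    same_r = (labels[:, :-1] == labels[:, 1:]) & (labels[:, :-1] > 0)
    same_d = (labels[:-1, :] == labels[1:, :]) & (labels[:-1, :] > 0)
    for arr, same in ((labels[:, :-1], same_r), (labels[:-1, :], same_d)):
        vals, cnts = np.unique(arr[same], return_counts=True)
        for v, c in zip(vals, cnts):
            shared[int(v)] += int(c)
    for i, a in zip(ids, areas):
        out[int(i)] = (4 * int(a) - 2 * shared[int(i)], int(a))
    return out


def shape_index(patches: Raster) -> tuple[dict[int, float], float]:
    """Fragstats shape index per patch, and the area-weighted mean.

    SHAPE = 0.25 P / sqrt(A) with P in cell-edge units and A in cells; a
    square patch scores exactly 1 and every grid patch scores >= 1.
    """
    labels = patches.values.astype(int)
    pa = patch_perimeter_area(labels)
    if not pa:
        raise ValueError("no patches in class")
    per_patch = {i: 0.25 * p / np.sqrt(a) for i, (p, a) in pa.items()}
    areas = np.array([pa[i][1] for i in per_patch], dtype=float)
    vals = np.array([per_patch[i] for i in per_patch])
    return per_patch, float(np.average(vals, weights=areas))


def contiguity(patches: Raster, window_area_km2: float = 0.5) -> Raster:
    """Per-cell contiguity of a patch class within a local window.

    Each patch cell gets a 3x3 template score (orthogonal neighbours weight
    2, diagonals 1, center 1, only same-class cells counted) normalized so
    an isolated cell scores 0 and a fully surrounded cell scores 1. The
    output cell value is the mean score of patch cells whose centers fall in
    a circular window of ``window_area_km2`` around the cell; windows with
    no patch cell score 0.
    """
    cell_km2 = (patches.cell_size / 1000.0) ** 2
    if window_area_km2 < cell_km2:
        raise ValueError("window smaller than one cell")
    m = patches.values.astype(bool).astype(float)
    template = np.array([[1.0, 2.0, 1.0], [2.0, 1.0, 2.0], [1.0, 2.0, 1.0]])
    # neighbour part of the template; the center contributes 1 by membership
    neigh = template.copy()
    neigh[1, 1] = 0.0
    t = ndimage.convolve(m, neigh, mode="constant", cval=0.0) + 1.0
    score = np.where(m > 0, (t - 1.0) / 12.0, 0.0)
    radius_m = np.sqrt(window_area_km2 * 1e6 / np.pi)
    radius_cells = max(1.0, radius_m / patches.cell_size)
    kernel = _disc_kernel(radius_cells)
    num = ndimage.convolve(score * m, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return patches.with_values(out)


def correlation_screen(
    stack: CovariateStack, threshold: float = 0.7
) -> list[tuple[str, str, float]]:
    """Flag variable pairs with |Pearson r| >= threshold over valid cells.

    Zero-variance variables are recorded as degenerate and excluded from
    pairing. The full correlation matrix is stored on the stack.
    """
    if len(stack.names) < 2:
        raise ValueError("need at least two variables to screen")
    mask = stack.valid_mask()
    data = {n: stack.rasters[n].values[mask] for n in stack.names}
    stack.degenerate = [n for n, v in data.items() if np.std(v) == 0]
    usable = [n for n in stack.names if n not in stack.degenerate]
    mat = np.corrcoef(np.vstack([data[n] for n in usable])) \
        if len(usable) >= 2 else np.ones((len(usable), len(usable)))
    corr = pd.DataFrame(np.eye(len(stack.names)), index=stack.names,
                        columns=stack.names)
    for i, a in enumerate(usable):
        for j, b in enumerate(usable):
            corr.loc[a, b] = mat[i, j]
    stack.correlation = corr
    flagged = []
    for a, b in combinations(usable, 2):
        r = float(corr.loc[a, b])
        if abs(r) >= threshold:
            flagged.append((a, b, r))
    stack.flagged_pairs = flagged
    return flagged


def write_correlation_csv(stack: CovariateStack, path: str | Path) -> None:
    if stack.correlation is None:
        raise ValueError("run correlation_screen first")
    stack.correlation.to_csv(path)


# ---------------------------------------------------------------------------
# Stack assembly from a synthetic landscape
# ---------------------------------------------------------------------------

def build_stack(
    landscape,
    local_radius_m: float = 500.0,
    neighborhood_radius_m: float = 1500.0,
    include_truth_covariates: bool = True,
) -> CovariateStack:
    """Engineer the model covariates from a landscape.

    Produces distance/density/terrain/shape variables from land cover and
    elevation (0.5 km local and 1.5 km neighbourhood window radii), plus the
    landscape's continuous fields.
    """
    from .synth import NATURAL, WETLAND  # local import avoids a cycle

    lc = landscape.landcover
    natural = lc.with_values((np.isin(lc.values, [NATURAL, WETLAND])).astype(int))
    wetland = lc.with_values((lc.values == WETLAND).astype(int))
    rasters: dict[str, Raster] = {}
    meta: dict[str, str] = {}
    if include_truth_covariates:
        for name, r in landscape.covariates.items():
            rasters[name] = r
            meta[name] = "field"
    rasters["dist_natural"] = euclidean_distance(natural)
    meta["dist_natural"] = "distance"
    rasters["natural_density_local"] = focal_density(natural, local_radius_m)
    meta["natural_density_local"] = "density"
    rasters["wetland_density"] = focal_density(wetland, neighborhood_radius_m)
    meta["wetland_density"] = "density"
    rasters["tri"] = tri(landscape.elevation)
    meta["tri"] = "terrain"
    rasters["elevation"] = landscape.elevation
    meta["elevation"] = "terrain"
    rasters["natural_contiguity"] = contiguity(label_patches(natural))
    meta["natural_contiguity"] = "shape"
    return CovariateStack(rasters=rasters, metadata=meta)
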