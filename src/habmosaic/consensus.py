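"""Consensus surfaces, thresholding, mosaicking and scale combination.

Per-iteration continuous suitability maps (both model families) are
averaged cellwise into one consensus surface per extent; the average of the
per-iteration max-sensitivity+specificity thresholds binarizes it. Local
(unit-scale) outputs, fitted on buffered unit extents, are trimmed to their
owning unit and mosaicked into one map; local and state binaries are then
combined into categories (none / local-only / state-only / both) with
exact cell-count area accounting, and a display binning assigns cells to
cumulative presence-frequency classes at 10% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import INT_NODATA, Raster

CATEGORY_CODES = {0: "none", 1: "local_only", 2: "state_only", 3: "both"}


@dataclass
class ConsensusOutput:
    continuous: Raster
    threshold: float
    binary: Raster
    scale: str = "state"


@dataclass
class CategoryMap:
    raster: Raster
    areas_km2: dict[str, float] = field(default_factory=dict)

    def area_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(code, name, self.areas_km2.get(name, 0.0))
             for code, name in CATEGORY_CODES.items()],
            columns=["code", "category", "area_km2"],
        )


def average_surfaces(surfaces: list[Raster]) -> Raster:
    """Cellwise arithmetic mean; nodata wherever any input is nodata."""
    if not surfaces:
        raise ValueError("no surfaces to average")
    first = surfaces[0]
    acc = np.zeros(first.shape, dtype=float)
    bad = np.zeros(first.shape, dtype=bool)
    for s in surfaces:
        first.require_same_grid(s)
        vals = s.values.astype(float)
        bad |= s.nodata_mask()
        acc += np.where(s.nodata_mask(), 0.0, vals)
    out = acc / len(surfaces)
    out[bad] = np.nan
    return first.with_values(out)


def apply_threshold(continuous: Raster, threshold: float) -> Raster:
    """Binary habitat map: 1 where value >= threshold, nodata preserved."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = continuous.values.astype(float)
    out = np.where(vals >= threshold, 1, 0)
    out[continuous.nodata_mask()] = INT_NODATA
    return continuous.with_values(out.astype(int))


def buffered_unit_mask(unit_labels: Raster, label: int,
                       buffer_km: float = 20.0) -> Raster:
    """Cells of a unit plus a buffer ring, used as local fitting context."""
    inside = unit_labels.values == label
    if not inside.any():
        raise ValueError(f"no cells carry unit label {label}")
    dist = ndimage.distance_transform_edt(~inside, sampling=unit_labels.cell_size)
    return unit_labels.with_values((dist <= buffer_km * 1000.0).astype(int))


def mosaic_units(unit_outputs: dict[int, Raster], unit_labels: Raster) -> Raster:
    """Statewide surface: each cell takes the value of its owning unit's model.

    Buffered fitting context never contributes values: outputs are trimmed
    to cells whose unit label matches at mosaic time, so the result is
    independent of unit processing order.
    """
    labels = unit_labels.values
    present = np.unique(labels)
    missing = set(present.tolist()) - set(unit_outputs)
    if missing:
        raise ValueError(f"cells contained by units without outputs: {sorted(missing)}")
    out = np.full(unit_labels.shape, np.nan)
    for label, surface in unit_outputs.items():
        unit_labels.require_same_grid(surface)
        own = labels == label
        out[own] = surface.values.astype(float)[own]
    return unit_labels.with_values(out)


def combine_scales(local_binary: Raster, state_binary: Raster) -> CategoryMap:
    """Weighted sum 1*local + 2*state: categories none/local-only/state-only/both."""
    local_binary.require_same_grid(state_binary)
    lb = local_binary.values
    sb = state_binary.values
    bad = (lb == INT_NODATA) | (sb == INT_NODATA)
    code = 1 * np.where(bad, 0, lb) + 2 * np.where(bad, 0, sb)
    code[bad] = INT_NODATA
    raster = local_binary.with_values(code.astype(int))
    cell = local_binary.cell_area_km2()
    areas = {
        name: float(np.count_nonzero(code == c)) * cell
        for c, name in CATEGORY_CODES.items()
    }
    return CategoryMap(raster=raster, areas_km2=areas)


def consensus_output(
    surfaces: list[Raster], thresholds: list[float], scale: str = "state"
) -> ConsensusOutput:
    """Average iteration surfaces and apply the mean of iteration thresholds."""
    continuous = average_surfaces(surfaces)
    t = float(np.mean(thresholds))
    return ConsensusOutput(continuous=continuous, threshold=t,
                           binary=apply_threshold(continuous, t), scale=scale)


def cumulative_frequency_bins(
    continuous: Raster, presence_points: np.ndarray, step: float = 0.10
) -> tuple[Raster, pd.DataFrame]:
    """Reclassify a consensus surface into cumulative presence-frequency bins.

    Class boundaries are the suitability quantiles (step, 2*step, ...) of
    the values at presence points, so each of the 1/step ordered bins holds
    about that share of presences (up to ties); bin index increases with
    suitability.
    """
    presence_points = np.asarray(presence_points, dtype=float)
    n_bins = int(round(1.0 / step))
    if presence_points.shape[0] < n_bins:
        raise ValueError("fewer presences than bins")
    pres = continuous.sample(presence_points[:, 0], presence_points[:, 1])
    if np.any(np.isnan(pres)):
        raise ValueError("presence points fall on nodata cells")
    qs = np.quantile(pres, np.linspace(step, 1.0 - step, n_bins - 1))
    vals = continuous.values.astype(float)
    binned = np.searchsorted(qs, vals, side="right") + 1
    binned = binned.astype(int)
    binned[continuous.nodata_mask()] = INT_NODATA
    pres_bin = np.searchsorted(qs, pres, side="right") + 1
    rows = []
    valid_cells = np.count_nonzero(~continuous.nodata_mask())
    for b in range(1, n_bins + 1):
        rows.append((
            b,
            float((pres_bin == b).mean()),
            int(np.count_nonzero(binned == b)),
            float(np.count_nonzero(binned == b)) / valid_cells,
        ))
    table = pd.DataFrame(
        rows, columns=["bin", "presence_share", "n_cells", "cell_share"])
    return continuous.with_values(binned), table
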