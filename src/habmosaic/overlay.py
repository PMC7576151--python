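"""Threat and protection overlays: area and percentage accounting.

Habitat maps (binary or categorical) are intersected with threat layers
(inundation at sea-level-rise scenarios, projected development) and with
protected lands. All areas are cell counts times the cell area in km^2, so
percentages recompute exactly from their own printed areas. Reports round
half-up to two decimals; raw values are retained in machine output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import INT_NODATA, Raster


def round_half_up(value: float, digits: int = 2) -> float:
    """Decimal half-up rounding, the convention used in printed area tables."""
    if not np.isfinite(value):
        return float("nan")
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _binary(values: np.ndarray) -> np.ndarray:
    return (values == 1) & (values != INT_NODATA)


def area_km2(habitat: Raster) -> float:
    """Area of the positive class of a binary raster."""
    return float(np.count_nonzero(_binary(habitat.values))) * habitat.cell_area_km2()


def percent_of(overlap_km2: float, total_km2: float) -> float:
    """Percentage an overlap represents of a stated total; nan if total is 0."""
    if total_km2 == 0:
        return float("nan")
    return 100.0 * overlap_km2 / total_km2


def overlay_area(habitat: Raster, mask: Raster) -> tuple[float, float]:
    """(overlap km^2, percent of habitat area) of habitat AND mask."""
    habitat.require_same_grid(mask)
    hab = _binary(habitat.values)
    both = hab & _binary(mask.values)
    cell = habitat.cell_area_km2()
    hab_area = float(np.count_nonzero(hab)) * cell
    overlap = float(np.count_nonzero(both)) * cell
    return overlap, percent_of(overlap, hab_area)


def protection_gap(habitat: Raster, protected_mask: Raster) -> tuple[float, float]:
    """(unprotected km^2, percent of habitat) — habitat AND NOT protected."""
    habitat.require_same_grid(protected_mask)
    hab = _binary(habitat.values)
    gap = hab & ~_binary(protected_mask.values)
    cell = habitat.cell_area_km2()
    hab_area = float(np.count_nonzero(hab)) * cell
    area = float(np.count_nonzero(gap)) * cell
    return area, percent_of(area, hab_area)


def compound_overlap(
    habitat: Raster, mask_a: Raster, mask_b: Raster,
    habitat_name: str = "habitat", a_name: str = "mask_a", b_name: str = "mask_b",
) -> dict[str, float]:
    """Three-way intersection with explicitly named denominators.

    Returns the intersection area plus its percentage of the habitat area,
    of habitat AND mask_a, and of habitat AND mask_b.
    """
    habitat.require_same_grid(mask_a)
    habitat.require_same_grid(mask_b)
    hab = _binary(habitat.values)
    a = _binary(mask_a.values)
    b = _binary(mask_b.values)
    cell = habitat.cell_area_km2()
    triple = float(np.count_nonzero(hab & a & b)) * cell
    hab_area = float(np.count_nonzero(hab)) * cell
    ha = float(np.count_nonzero(hab & a)) * cell
    hb = float(np.count_nonzero(hab & b)) * cell
    return {
        "area_km2": triple,
        f"pct_of_{habitat_name}": percent_of(triple, hab_area),
        f"pct_of_{habitat_name}_and_{a_name}": percent_of(triple, ha),
        f"pct_of_{habitat_name}_and_{b_name}": percent_of(triple, hb),
    }


@dataclass
class OverlayReport:
    """Rows of habitat class x threat layer overlap accounting."""

    rows: list[dict] = field(default_factory=list)

    def add(
        self, habitat_class: str, layer: str, overlap_km2: float,
        class_area_km2: float, both_scales_km2: float | None = None,
    ) -> None:
        pct = percent_of(overlap_km2, class_area_km2)
        row = {
            "habitat_class": habitat_class,
            "layer": layer,
            "overlap_km2": overlap_km2,
            "class_area_km2": class_area_km2,
            "percent_of_class": pct,
            "percent_of_class_2dp": round_half_up(pct, 2),
        }
        if both_scales_km2 is not None:
            row["percent_identified_by_both"] = round_half_up(
                percent_of(both_scales_km2, overlap_km2), 2)
        self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> None:
        self.frame().to_csv(path, index=False)


def category_masks(category_raster: Raster) -> dict[str, Raster]:
    """Binary masks per habitat class from a combined-scales category map.

    ``local`` and ``state`` include the cells identified at both scales;
    ``both`` is their intersection and ``combined`` their union.
    """
    code = category_raster.values
    make = category_raster.with_values
    return {
        "local": make(np.isin(code, [1, 3]).astype(int)),
        "state": make(np.isin(code, [2, 3]).astype(int)),
        "both": make((code == 3).astype(int)),
        "combined": make(np.isin(code, [1, 2, 3]).astype(int)),
    }


def build_overlay_report(
    category_raster: Raster, threat_masks: dict[str, Raster],
    protected_name: str = "protected",
) -> OverlayReport:
    """Table of overlaps of each habitat class with each threat layer.

    Protection enters as its complement (unprotected habitat); every other
    layer enters directly. The both-scales column reports what share of the
    combined-class overlap was identified at both scales.
    """
    masks = category_masks(category_raster)
    report = OverlayReport()
    for layer, mask in threat_masks.items():
        unprotected = layer == protected_name
        for cls_name, hab in masks.items():
            if unprotected:
                overlap, _ = protection_gap(hab, mask)
                label = "unprotected"
            else:
                overlap, _ = overlay_area(hab, mask)
                label = layer
            both_km2 = None
            if cls_name == "combined":
                if unprotected:
                    both_km2, _ = protection_gap(masks["both"], mask)
                else:
                    both_km2, _ = overlay_area(masks["both"], mask)
            report.add(cls_name, label, overlap, area_km2(hab), both_km2)
    return report
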