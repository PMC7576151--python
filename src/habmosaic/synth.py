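"""Synthetic landscapes, virtual species and telemetry.

The generator produces everything the analysis consumes, with the
statistical structure the method assumes, so the full pipeline can be
exercised and validated without any geodata downloads:

* spatially autocorrelated continuous covariates (Gaussian random fields
  with exponential covariance, synthesized spectrally via circulant
  embedding);
* categorical land cover (natural / agriculture / urban / wetland / water)
  and an elevation surface with low-lying coastal cells;
* a known ground-truth suitability surface (inverse-logit of a linear
  combination of covariates) for parameter-recovery tests;
* habitat-biased, serially autocorrelated telemetry with mixed VHF/GPS
  collars, lognormal DOP noise, capture/mortality records and juveniles;
* elevation-driven inundation masks, development near urban seeds, and
  protected natural areas;
* a k-region Voronoi partition of the extent standing in for management
  units, the local modeling extents.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit
from shapely.geometry import MultiPoint, Point, box, mapping
from shapely.ops import voronoi_diagram

from .raster import Raster
from .screening import GPS, VHF, TelemetryFix

LANDCOVER_CLASSES = {1: "natural", 2: "agriculture", 3: "urban",
                     4: "wetland", 5: "water"}
NATURAL, AGRICULTURE, URBAN, WETLAND, WATER = 1, 2, 3, 4, 5


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    The 120 m cell mirrors the analysis resolution; the fix interval and
    per-animal sample sizes are set so that tracks span several calendar
    months and the temporal subsampler has work to do.
    """

    nrows: int = 120
    ncols: int = 120
    cell_size: float = 120.0
    corr_range_m: float = 2400.0       # autocorrelation range of the fields
    n_animals: int = 30
    n_fixes: int = 2200                # ~92 days at 1-h spacing
    fix_interval_hours: float = 1.0
    vhf_fraction: float = 0.3
    # VHF collars record less often; their interval is scaled by this factor
    # (and their fix count scaled down) so track durations stay comparable.
    vhf_interval_multiplier: float = 5.0
    juvenile_fraction: float = 0.2
    dop_median: float = 2.0            # lognormal DOP: median 2, sigma 0.6
    dop_sigma: float = 0.6
    mortality_prob: float = 0.15
    bad_status_prob: float = 0.03
    step_sd_cells: float = 2.0
    n_units: int = 4
    # truth model: None -> DEFAULT_TRUTH_COEFFICIENTS / intercept -0.5
    truth_coefficients: dict | None = None
    truth_intercept: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")


@dataclass
class Landscape:
    """A synthetic study area: covariates, land cover, units and truth."""

    covariates: dict[str, Raster]
    landcover: Raster
    elevation: Raster
    unit_labels: Raster
    unit_polygons: dict[str, object]      # name -> shapely polygon
    truth_suitability: Raster | None = None
    truth_coefficients: dict[str, float] = field(default_factory=dict)
    truth_intercept: float = 0.0

    @property
    def grid(self) -> Raster:
        return self.landcover

    def extent_polygon(self):
        g = self.grid
        return box(g.x_origin, g.y_origin,
                   g.x_origin + g.ncols * g.cell_size,
                   g.y_origin + g.nrows * g.cell_size)


# ---------------------------------------------------------------------------
# Gaussian random fields
# ---------------------------------------------------------------------------

def gen_gaussian_field(
    nrows: int,
    ncols: int,
    corr_range_cells: float,
    seed: int,
    cell_size: float = 120.0,
) -> Raster:
    """Zero-mean unit-variance Gaussian field with exponential covariance.

    ``cov(d) = exp(-d / corr_range_cells)`` with d in cell units; a range of
    0 gives i.i.d. noise. Synthesis is spectral (circulant embedding on a
    doubled torus), so cost is O(N log N) and output is seed-deterministic.
    """
    if nrows <= 0 or ncols <= 0:
        raise ValueError("grid dimensions must be positive")
    if corr_range_cells < 0:
        raise ValueError("correlation range must be non-negative")
    rng = np.random.default_rng(seed)
    if corr_range_cells == 0:
        values = rng.standard_normal((nrows, ncols))
    else:
        m, n = 2 * nrows, 2 * ncols
        di = np.minimum(np.arange(m), m - np.arange(m))
        dj = np.minimum(np.arange(n), n - np.arange(n))
        dist = np.hypot(di[:, None], dj[None, :])
        cov = np.exp(-dist / corr_range_cells)
        spectrum = np.fft.fft2(cov).real
        spectrum[spectrum < 0] = 0.0      # embedding may be slightly indefinite
        white = rng.standard_normal((m, n))
        field_t = np.fft.ifft2(np.sqrt(spectrum) * np.fft.fft2(white)).real
        values = field_t[:nrows, :ncols]
    values = (values - values.mean()) / values.std()
    return Raster(values=values, cell_size=cell_size)


# ---------------------------------------------------------------------------
# Landscape assembly
# ---------------------------------------------------------------------------

def _voronoi_units(
    nrows: int, ncols: int, cell_size: float, k: int, rng: np.random.Generator
) -> tuple[Raster, dict[str, object]]:
    width, height = ncols * cell_size, nrows * cell_size
    seeds = np.column_stack([rng.uniform(0, width, k), rng.uniform(0, height, k)])
    cols = (np.arange(ncols) + 0.5) * cell_size
    rows = (nrows - np.arange(nrows) - 0.5) * cell_size
    cx, cy = np.meshgrid(cols, rows)
    d2 = ((cx[..., None] - seeds[:, 0]) ** 2 + (cy[..., None] - seeds[:, 1]) ** 2)
    labels = np.argmin(d2, axis=-1).astype(int)
    extent = box(0, 0, width, height)
    cells = voronoi_diagram(MultiPoint([Point(*s) for s in seeds]), envelope=extent)
    polys: dict[str, object] = {}
    for geom in cells.geoms:
        clipped = geom.intersection(extent)
        for i, s in enumerate(seeds):
            if clipped.contains(Point(*s)):
                polys[f"unit_{i}"] = clipped
                break
    label_raster = Raster(values=labels, cell_size=cell_size)
    return label_raster, polys


DEFAULT_TRUTH_COEFFICIENTS = {"forage": 1.8, "cover": 1.2, "human_pressure": -1.8}
DEFAULT_TRUTH_INTERCEPT = -0.5

# A sharply selective virtual species: suitable cells are rare and telemetry
# concentrates strongly in them. Used for end-to-end recovery benchmarks.
STRONG_TRUTH_COEFFICIENTS = {"forage": 5.0, "cover": 4.0, "human_pressure": -5.0}
STRONG_TRUTH_INTERCEPT = -6.0


def make_landscape(config: SimConfig | None = None) -> Landscape:
    """Build a full synthetic landscape from one configuration."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    range_cells = config.corr_range_m / config.cell_size
    sub = rng.integers(0, 2**31 - 1, size=16)

    def fld(i: int, rng_cells: float | None = None) -> Raster:
        return gen_gaussian_field(
            config.nrows, config.ncols,
            range_cells if rng_cells is None else rng_cells,
            int(sub[i]), config.cell_size,
        )

    covariates = {
        "forage": fld(0),
        "cover": fld(1),
        "human_pressure": fld(2),
        "moisture": fld(3),
        "noise_a": fld(4, 0.0),
        "noise_b": fld(5, 0.0),
    }
    g_elev = fld(6, range_cells * 1.5)
    elevation = covariates["forage"].with_values(5.0 + 5.0 * g_elev.values)

    g_agri = fld(7)
    lc = np.full((config.nrows, config.ncols), NATURAL, dtype=int)
    water = elevation.values < 0.0
    lc[water] = WATER
    urban = (covariates["human_pressure"].values > 1.3) & ~water
    lc[urban] = URBAN
    agri = (g_agri.values > 0.8) & ~water & ~urban
    lc[agri] = AGRICULTURE
    wet = (elevation.values < 1.5) & (lc == NATURAL)
    lc[wet] = WETLAND
    landcover = elevation.with_values(lc)

    unit_labels, unit_polys = _voronoi_units(
        config.nrows, config.ncols, config.cell_size, config.n_units, rng
    )
    scape = Landscape(
        covariates=covariates,
        landcover=landcover,
        elevation=elevation,
        unit_labels=unit_labels,
        unit_polygons=unit_polys,
    )
    coefs = (config.truth_coefficients if config.truth_coefficients is not None
             else DEFAULT_TRUTH_COEFFICIENTS)
    icpt = (config.truth_intercept if config.truth_intercept is not None
            else DEFAULT_TRUTH_INTERCEPT)
    gen_virtual_species(scape, coefs, intercept=icpt)
    return scape


def gen_virtual_species(
    landscape: Landscape,
    coefficients: Mapping[str, float],
    intercept: float = 0.0,
) -> Raster:
    """Define the ground-truth suitability surface.

    ``suitability(x) = inverse-logit(intercept + sum_i beta_i cov_i(x))``;
    the result is stored on the landscape and returned.
    """
    unknown = set(coefficients) - set(landscape.covariates)
    if unknown:
        raise KeyError(f"unknown covariates in truth model: {sorted(unknown)}")
    grid = landscape.grid
    lin = np.full(grid.shape, float(intercept))
    for name, beta in coefficients.items():
        lin = lin + beta * landscape.covariates[name].values
    suit = grid.with_values(expit(lin))
    landscape.truth_suitability = suit
    landscape.truth_coefficients = dict(coefficients)
    landscape.truth_intercept = float(intercept)
    return suit


# ---------------------------------------------------------------------------
# Telemetry
# ---------------------------------------------------------------------------

def simulate_telemetry(
    landscape: Landscape, config: SimConfig | None = None
) -> list[TelemetryFix]:
    """Habitat-biased correlated walks with collar and life-history metadata.

    Each animal starts in a cell drawn proportionally to truth suitability
    and proposes Gaussian steps; a proposed destination is accepted with
    probability equal to its suitability (rejection sampling), otherwise the
    animal keeps its position for that fix. The marginal distribution of
    accepted locations is therefore enriched in high-suitability cells.
    """
    config = config or SimConfig()
    if config.n_animals <= 0:
        raise ValueError("n_animals must be positive")
    if landscape.truth_suitability is None:
        raise ValueError("landscape has no truth_suitability")
    rng = np.random.default_rng(config.seed + 1)
    suit = landscape.truth_suitability.values
    grid = landscape.grid
    nrows, ncols = grid.shape
    width = ncols * grid.cell_size
    height = nrows * grid.cell_size

    flat = suit.ravel() / suit.sum()
    start_cells = rng.choice(suit.size, size=config.n_animals, p=flat)
    base_time = datetime(2015, 1, 1, tzinfo=timezone.utc)
    step_sd = config.step_sd_cells * grid.cell_size

    fixes: list[TelemetryFix] = []
    for a in range(config.n_animals):
        animal_id = f"bear_{a:03d}"
        is_vhf = rng.random() < config.vhf_fraction
        collar = VHF if is_vhf else GPS
        mult = config.vhf_interval_multiplier if is_vhf else 1.0
        interval = timedelta(hours=config.fix_interval_hours * mult)
        n_fixes_a = max(2, int(config.n_fixes / mult)) if is_vhf else config.n_fixes
        juvenile = rng.random() < config.juvenile_fraction
        age = rng.uniform(1.0, 3.9) if juvenile else rng.uniform(4.0, 12.0)
        dies = rng.random() < config.mortality_prob
        r0, c0 = np.unravel_index(start_cells[a], suit.shape)
        x = grid.x_origin + (c0 + 0.5) * grid.cell_size
        y = grid.y_origin + (nrows - r0 - 0.5) * grid.cell_size
        t = base_time + timedelta(hours=float(rng.integers(0, 24 * 30)))
        for i in range(n_fixes_a):
            if i > 0:
                for _ in range(25):
                    px = x + rng.normal(0.0, step_sd)
                    py = y + rng.normal(0.0, step_sd)
                    # reflect back into the extent
                    px = abs(px - grid.x_origin) % (2 * width)
                    px = grid.x_origin + (2 * width - px if px > width else px)
                    py = abs(py - grid.y_origin) % (2 * height)
                    py = grid.y_origin + (2 * height - py if py > height else py)
                    row = min(nrows - 1, max(0, int((grid.y_origin + height - py)
                                                    // grid.cell_size)))
                    col = min(ncols - 1, max(0, int((px - grid.x_origin)
                                                    // grid.cell_size)))
                    if rng.random() < suit[row, col]:
                        x, y = px, py
                        break
            if collar == GPS:
                dop = float(np.exp(np.log(config.dop_median)
                                   + config.dop_sigma * rng.standard_normal()))
                status = "2D" if rng.random() < config.bad_status_prob else "3D"
            else:
                dop = float("nan")
                status = "NA"
            event = "normal"
            if i == 0:
                event = "capture"
            elif dies and i == n_fixes_a - 1:
                event = "mortality"
            fixes.append(TelemetryFix(
                animal_id=animal_id, timestamp=t, x=x, y=y, collar=collar,
                dop=dop, fix_status=status, event=event, age_years=age,
            ))
            t = t + interval
    return fixes


# ---------------------------------------------------------------------------
# Threat and protection masks
# ---------------------------------------------------------------------------

def gen_threat_masks(
    landscape: Landscape,
    slr_levels_cm: Sequence[float] = (30.0, 305.0),
    dev_fraction: float = 0.1,
    protect_fraction: float = 0.3,
    seed: int = 0,
) -> dict[str, Raster]:
    """Inundation, development and protection masks on the shared grid.

    Inundation at a sea-level-rise scenario is the set of cells with
    elevation strictly below the level, so masks nest across increasing
    levels. Development covers ``dev_fraction`` of non-water cells, drawn
    without replacement with weights decaying away from urban seeds;
    protection covers ``protect_fraction`` of natural cells in smooth blobs.
    """
    if not (0.0 <= dev_fraction <= 1.0 and 0.0 <= protect_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if any(l < 0 for l in slr_levels_cm):
        raise ValueError("sea-level-rise levels must be non-negative")
    rng = np.random.default_rng(seed)
    elev = landscape.elevation.values
    lc = landscape.landcover.values
    grid = landscape.grid
    masks: dict[str, Raster] = {}
    for level in slr_levels_cm:
        m = (elev < level / 100.0).astype(int)
        masks[f"inundation_{int(level)}cm"] = grid.with_values(m)

    eligible = (lc != WATER)
    n_dev = int(round(dev_fraction * eligible.sum()))
    dist_urban = ndimage.distance_transform_edt(lc != URBAN) if (lc == URBAN).any() \
        else np.zeros_like(elev)
    weights = np.exp(-dist_urban / 10.0)
    w = np.where(eligible, weights, 0.0).ravel()
    dev = np.zeros(elev.size, dtype=int)
    if n_dev > 0:
        idx = rng.choice(elev.size, size=n_dev, replace=False, p=w / w.sum())
        dev[idx] = 1
    masks["development"] = grid.with_values(dev.reshape(elev.shape))

    natural = (lc == NATURAL) | (lc == WETLAND)
    n_prot = int(round(protect_fraction * natural.sum()))
    blob = gen_gaussian_field(grid.nrows, grid.ncols, 15.0,
                              int(rng.integers(0, 2**31 - 1)), grid.cell_size)
    wp = np.where(natural, np.exp(2.0 * blob.values), 0.0).ravel()
    prot = np.zeros(elev.size, dtype=int)
    if n_prot > 0:
        idx = rng.choice(elev.size, size=n_prot, replace=False, p=wp / wp.sum())
        prot[idx] = 1
    masks["protected"] = grid.with_values(prot.reshape(elev.shape))
    return masks


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_units_geojson(landscape: Landscape, path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"name": name},
         "geometry": mapping(poly)}
        for name, poly in landscape.unit_polygons.items()
    ]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def write_landscape(landscape: Landscape, out_dir: str | Path) -> None:
    """Write all rasters as ASCII grids and the units as GeoJSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, r in landscape.covariates.items():
        r.write_ascii(out / f"cov_{name}.asc")
    landscape.landcover.write_ascii(out / "landcover.asc")
    landscape.elevation.write_ascii(out / "elevation.asc")
    landscape.unit_labels.write_ascii(out / "unit_labels.asc")
    if landscape.truth_suitability is not None:
        landscape.truth_suitability.write_ascii(out / "truth_suitability.asc")
    write_units_geojson(landscape, out / "units.geojson")
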