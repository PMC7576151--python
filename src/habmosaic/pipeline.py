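"""End-to-end two-scale analysis driven by one configuration.

Stages: simulate (or load) inputs -> screen telemetry -> engineer the
covariate stack -> per scale {variable selection, k-fold fits of both model
families, five-measure evaluation, consensus averaging, thresholding,
mosaicking} -> combine scales into habitat categories -> threat/protection
overlays. Every stochastic stage draws its seed from the run seed, so a
rerun with the same configuration reproduces every artifact; a manifest of
SHA-256 hashes is written to make that checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import covariates as cov
from . import evaluation as ev
from . import mahalanobis as mh
from . import maxent as mx
from . import overlay as ov
from . import screening as scr
from . import synth
from .raster import Raster

log = logging.getLogger("habmosaic")


@dataclass
class ModelConfig:
    k_folds: int = 10
    n_background: int = 10000
    n_eval_background: int = 2000
    reg_multiplier: float = 1.0
    kde_level: float = 0.95
    n_knots: int = 15
    corr_threshold: float = 0.7
    contribution_floor: float = 1.0
    maha_floor: float = 0.05
    buffer_km: float = 20.0


@dataclass
class RunConfig:
    out_dir: str = "run"
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)
    screening: scr.ScreeningConfig = field(default_factory=scr.ScreeningConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    scales: tuple[str, ...] = ("state", "local")
    thresholds_override: dict[str, float] = field(default_factory=dict)
    slr_levels_cm: tuple[float, ...] = (30.0, 305.0)
    dev_fraction: float = 0.1
    protect_fraction: float = 0.3
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["screening"]["low_quality_status"] = sorted(
            self.screening.low_quality_status)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = synth.SimConfig(**d.pop("sim", {}))
        s = d.pop("screening", {})
        if "low_quality_status" in s:
            s["low_quality_status"] = frozenset(s["low_quality_status"])
        screening = scr.ScreeningConfig(**s)
        model = ModelConfig(**d.pop("model", {}))
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        if "slr_levels_cm" in d:
            d["slr_levels_cm"] = tuple(d["slr_levels_cm"])
        return cls(sim=sim, screening=screening, model=model, **d)


@dataclass
class ScaleResult:
    scale: str
    consensus: cns.ConsensusOutput
    reports: list[ev.EvaluationReport]
    maxent_thresholds: list[float]
    variables: dict[str, list[str]]


@dataclass
class RunResult:
    config: RunConfig
    landscape: synth.Landscape
    threat_masks: dict[str, Raster]
    presence_xy: np.ndarray
    stack: cov.CovariateStack
    scale_results: dict[str, ScaleResult]
    category: cns.CategoryMap | None
    overlay_report: ov.OverlayReport | None
    area_table: pd.DataFrame | None
    out_dir: Path


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _seed_stream(seed: int):
    rng = np.random.default_rng(seed)
    while True:
        yield int(rng.integers(0, 2**31 - 1))


def screen_and_subsample(
    fixes: list[scr.TelemetryFix], config: scr.ScreeningConfig
) -> tuple[list[scr.TelemetryFix], pd.DataFrame]:
    kept, rejlog = scr.screen_fixes(fixes, config)
    kept = scr.subsample_all(kept, config.subsample_hours)
    return kept, rejlog


def _fit_family_folds(
    presence_xy: np.ndarray,
    stack: cov.CovariateStack,
    mcfg: ModelConfig,
    region: Raster | mx.KdePolygon | None,
    variables_mx: list[str],
    variables_mh: list[str],
    seed: int,
    tag: str,
) -> tuple[list[Raster], list[Raster], list[ev.EvaluationReport], list[float]]:
    """k-fold Maxent and Mahalanobis surfaces + per-iteration evaluation."""
    n = presence_xy.shape[0]
    k = mcfg.k_folds if n >= max(mcfg.k_folds, 20) else (2 if n >= 10 else 1)
    reports: list[ev.EvaluationReport] = []
    mx_surfaces: list[Raster] = []
    mh_surfaces: list[Raster] = []
    thresholds: list[float] = []
    if k == 1:
        # too few presences for CV: single fit, evaluated on training data
        folds = [None]
    else:
        folds = mx.cross_validate(
            presence_xy, stack, k=k, seed=seed,
            n_background=mcfg.n_background, region=region,
            variables=variables_mx, reg_multiplier=mcfg.reg_multiplier,
            n_knots=mcfg.n_knots,
        )
    for i, fold in enumerate(folds):
        if fold is None:
            bg_xy = mx.sample_background(
                region if region is not None
                else stack.grid.with_values(stack.valid_mask().astype(int)),
                n=mcfg.n_background, seed=seed)
            P = stack.values_at(presence_xy[:, 0], presence_xy[:, 1], variables_mx)
            B = stack.values_at(bg_xy[:, 0], bg_xy[:, 1], variables_mx)
            model = mx.fit_maxent(P, B, reg_multiplier=mcfg.reg_multiplier,
                                  names=variables_mx, n_knots=mcfg.n_knots)
            train = test = presence_xy
        else:
            model, train, test, bg_xy = (fold.model, fold.train_presence_xy,
                                         fold.test_presence_xy, fold.background_xy)
        eval_bg = bg_xy[: mcfg.n_eval_background]
        surf_mx = mx.predict_maxent(model, stack.subset(variables_mx))
        rep = ev.evaluate_fold(surf_mx, test, eval_bg,
                               model_tag=f"{tag}:maxent", fold=i)
        reports.append(rep)
        thresholds.append(rep.threshold)
        mx_surfaces.append(surf_mx)

        Pm = stack.values_at(train[:, 0], train[:, 1], variables_mh)
        maha = mh.fit_mahalanobis(Pm, variables_mh)
        surf_mh = mh.predict_mahalanobis(maha, stack.subset(variables_mh))
        reports.append(ev.evaluate_fold(surf_mh, test, eval_bg,
                                        model_tag=f"{tag}:mahalanobis", fold=i))
        mh_surfaces.append(surf_mh)
    return mx_surfaces, mh_surfaces, reports, thresholds


def _select_variables(
    presence_xy: np.ndarray,
    stack: cov.CovariateStack,
    mcfg: ModelConfig,
    region,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Reverse step-wise (Maxent) and PCA-guided (Mahalanobis) selection."""
    bg_xy = mx.sample_background(
        region if region is not None
        else stack.grid.with_values(stack.valid_mask().astype(int)),
        n=mcfg.n_background, seed=seed)
    vars_mx, _ = mx.stepwise_select(
        stack, presence_xy, bg_xy,
        reg_multiplier=mcfg.reg_multiplier,
        contribution_floor=mcfg.contribution_floor,
        corr_threshold=mcfg.corr_threshold,
        seed=seed, n_knots=mcfg.n_knots,
    )
    usable = [n for n in stack.names if n not in stack.degenerate]
    Pu = stack.values_at(presence_xy[:, 0], presence_xy[:, 1], usable)
    vars_mh, _ = mh.iterative_removal(Pu, usable,
                                      contribution_floor=mcfg.maha_floor)
    return vars_mx, vars_mh


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full two-scale analysis; write artifacts and manifest."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seed_stream(config.seed)
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.time()
        log.info("stage %s", name)

    def done(name):
        timings[name] = time.time() - timings[name]
        log.info("stage %s done in %.1fs", name, timings[name])

    # -- simulate ------------------------------------------------------
    stage("simulate")
    sim = config.sim
    landscape = synth.make_landscape(sim)
    fixes = synth.simulate_telemetry(landscape, sim)
    threat_masks = synth.gen_threat_masks(
        landscape, config.slr_levels_cm, config.dev_fraction,
        config.protect_fraction, seed=next(seeds))
    synth.write_landscape(landscape, out / "landscape")
    scr.write_fixes_csv(fixes, out / "fixes_raw.csv")
    for name, m in threat_masks.items():
        m.write_ascii(out / "landscape" / f"mask_{name}.asc")
    done("simulate")

    # -- screen --------------------------------------------------------
    stage("screen")
    kept, rejlog = screen_and_subsample(fixes, config.screening)
    if not kept:
        raise RuntimeError("screening removed every fix")
    scr.write_fixes_csv(kept, out / "fixes_screened.csv")
    rejlog.to_csv(out / "rejection_log.csv", index=False)
    presence_xy = np.array([[f.x, f.y] for f in kept])
    log.info("screened %d -> %d fixes", len(fixes), len(kept))
    done("screen")

    # -- covariates ----------------------------------------------------
    stage("covariates")
    stack = cov.build_stack(landscape)
    cov.correlation_screen(stack, config.model.corr_threshold)
    cov.write_correlation_csv(stack, out / "correlation.csv")
    done("covariates")

    mcfg = config.model
    scale_results: dict[str, ScaleResult] = {}
    grid = stack.grid
    cell_km2 = grid.cell_area_km2()

    # -- state scale ----------------------------------------------------
    if "state" in config.scales:
        stage("state")
        kde = mx.kde_polygon(presence_xy, grid, level=mcfg.kde_level)
        region_mask = grid.with_values(
            (kde.mask.values.astype(bool) & stack.valid_mask()).astype(int))
        vars_mx, vars_mh = _select_variables(
            presence_xy, stack, mcfg, region_mask, next(seeds))
        log.info("state variables: maxent=%s mahalanobis=%s", vars_mx, vars_mh)
        mx_s, mh_s, reports, thresholds = _fit_family_folds(
            presence_xy, stack, mcfg, region_mask, vars_mx, vars_mh,
            next(seeds), "state")
        t_state = config.thresholds_override.get(
            "state", float(np.mean(thresholds)))
        cont_state = cns.average_surfaces(mx_s + mh_s)
        out_state = cns.ConsensusOutput(
            continuous=cont_state,
            threshold=t_state,
            binary=cns.apply_threshold(cont_state, t_state),
            scale="state")
        scale_results["state"] = ScaleResult(
            "state", out_state, reports, thresholds,
            {"maxent": vars_mx, "mahalanobis": vars_mh})
        done("state")

    # -- local scale ----------------------------------------------------
    if "local" in config.scales:
        stage("local")
        labels = landscape.unit_labels.values
        unit_ids = [int(u) for u in np.unique(labels)]
        unit_cont: dict[int, Raster] = {}
        unit_bin: dict[int, Raster] = {}
        reports_l: list[ev.EvaluationReport] = []
        thresholds_l: list[float] = []
        variables_l: dict[str, list[str]] = {}
        for uid in unit_ids:
            buf = cns.buffered_unit_mask(landscape.unit_labels, uid,
                                         mcfg.buffer_km)
            region_mask = grid.with_values(
                (buf.values.astype(bool) & stack.valid_mask()).astype(int))
            rows, cols = grid.index_of(presence_xy[:, 0], presence_xy[:, 1])
            in_unit = buf.values[rows, cols].astype(bool)
            pres_u = presence_xy[in_unit]
            if pres_u.shape[0] < 10:
                raise RuntimeError(
                    f"unit {uid} has only {pres_u.shape[0]} presences; "
                    "increase n_animals or n_fixes")
            vars_mx, vars_mh = _select_variables(
                pres_u, stack, mcfg, region_mask, next(seeds))
            variables_l[f"unit_{uid}:maxent"] = vars_mx
            variables_l[f"unit_{uid}:mahalanobis"] = vars_mh
            mx_s, mh_s, reports, thresholds = _fit_family_folds(
                pres_u, stack, mcfg, region_mask, vars_mx, vars_mh,
                next(seeds), f"unit_{uid}")
            reports_l.extend(reports)
            t_unit = config.thresholds_override.get(
                "local", float(np.mean(thresholds)))
            thresholds_l.extend(thresholds)
            cont = cns.average_surfaces(mx_s + mh_s)
            unit_cont[uid] = cont
            unit_bin[uid] = cns.apply_threshold(cont, t_unit)
        mosaic_cont = cns.mosaic_units(unit_cont, landscape.unit_labels)
        mosaic_bin = cns.mosaic_units(unit_bin, landscape.unit_labels)
        bin_vals = mosaic_bin.values.copy()
        bin_int = np.where(np.isnan(bin_vals), -9999, bin_vals).astype(int)
        out_local = cns.ConsensusOutput(
            continuous=mosaic_cont,
            threshold=config.thresholds_override.get(
                "local", float(np.mean(thresholds_l))),
            binary=mosaic_bin.with_values(bin_int),
            scale="local")
        scale_results["local"] = ScaleResult(
            "local", out_local, reports_l, thresholds_l, variables_l)
        done("local")

    # -- consensus artifacts --------------------------------------------
    stage("outputs")
    all_reports = [r for sr in scale_results.values() for r in sr.reports]
    ev.reports_to_csv(all_reports, out / "evaluation_reports.csv")
    for name, sr in scale_results.items():
        sr.consensus.continuous.write_ascii(out / f"consensus_{name}.asc")
        sr.consensus.binary.write_ascii(out / f"habitat_{name}.asc")
        binned, bin_table = cns.cumulative_frequency_bins(
            sr.consensus.continuous, presence_xy)
        binned.write_ascii(out / f"display_bins_{name}.asc")
        bin_table.to_csv(out / f"display_bins_{name}.csv", index=False)

    category = None
    overlay_report = None
    area_table = None
    if {"state", "local"} <= set(scale_results):
        category = cns.combine_scales(scale_results["local"].consensus.binary,
                                      scale_results["state"].consensus.binary)
        category.raster.write_ascii(out / "habitat_categories.asc")
        category.area_table().to_csv(out / "category_areas.csv", index=False)

        # per-unit area accounting (Table-3 analogue)
        rows = []
        labels = landscape.unit_labels.values
        for uid in sorted(np.unique(labels).tolist()):
            row = {"unit": f"unit_{int(uid)}"}
            for name, sr in scale_results.items():
                b = sr.consensus.binary.values
                row[f"{name}_km2"] = float(
                    np.count_nonzero((b == 1) & (labels == uid))) * cell_km2
            rows.append(row)
        total = {"unit": "total"}
        for name, sr in scale_results.items():
            total[f"{name}_km2"] = float(
                np.count_nonzero(sr.consensus.binary.values == 1)) * cell_km2
        rows.append(total)
        area_table = pd.DataFrame(rows)
        area_table.to_csv(out / "habitat_areas_by_unit.csv", index=False)

        overlay_report = ov.build_overlay_report(category.raster, threat_masks)
        overlay_report.to_csv(out / "overlay_report.csv")
    done("outputs")

    # -- manifest --------------------------------------------------------
    manifest = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest[str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    config.to_yaml(out / "config.yaml")
    log.info("pipeline finished in %.1fs", time.time() - t_start)

    return RunResult(
        config=config, landscape=landscape, threat_masks=threat_masks,
        presence_xy=presence_xy, stack=stack, scale_results=scale_results,
        category=category, overlay_report=overlay_report,
        area_table=area_table, out_dir=out,
    )
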