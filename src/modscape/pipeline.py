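"""End-to-end pipeline: synth -> simulate -> quantify -> interact.

The driver generates a synthetic landscape, fabricates a calibration land-use
pair by stepping the base map through a configured historical transition
matrix, estimates the transition matrix back from that pair, projects demand
under each configured scenario (with the matrix step-split so one projection
step covers ``step_years``), allocates demand with the ANN-CA, quantifies the
six ES for every projection year (climate, soil and terrain held fixed — land
use is the only driver that changes), and runs the regional and grid-scale
interaction analysis.  Every output is traceable to config + seed via the
manifest; reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .es import (
    AVScoreTable,
    CarbonDensityTable,
    CropParams,
    ESLayer,
    RWEQFactorStack,
    USLEFactorStack,
    WaterYieldInputs,
    aesthetic_value,
    carbon_sequestration,
    crop_production,
    rainfall_erosivity,
    rweq_sand_fixation,
    slope_length_steepness,
    soil_erodibility_epic,
    usle_soil_conservation,
    water_yield,
    zonal_totals,
)
from .grids import CLASS_CODES, LandUseMap, ValidationError
from .interactions import (
    ES_ORDER,
    attribute_causes,
    classify_regional_trends,
    encode_overlay,
    filter_codes_by_area,
    minmax_normalize,
    reclass_change,
)
from .io import write_bundle, write_raster
from .landuse import (
    CAParams,
    TransitionMatrix,
    apply_scenario_modifiers,
    ca_allocate,
    default_scenarios,
    estimate_transition_matrix,
    kappa,
    project_demand,
    roc_auc,
    step_split_matrix,
    train_suitability,
)
from .synthetic import SyntheticConfig, generate_driving_factors, generate_landscape

log = logging.getLogger("modscape")

#: mild historical drift used to fabricate the calibration pair when the
#: config does not supply one: oasis expansion (bare -> cropland/built-up)
#: and slight grassland degradation, the signal the scenarios then modify.
def default_calibration_matrix() -> TransitionMatrix:
    classes = tuple(CLASS_CODES)
    p = np.eye(6)
    idx = {c: i for i, c in enumerate(classes)}
    def set_(frm, to, v):
        p[idx[frm], idx[to]] = v
    set_("bare", "cropland", 0.03)
    set_("bare", "grassland", 0.02)
    set_("bare", "built-up", 0.004)
    set_("grassland", "cropland", 0.02)
    set_("grassland", "bare", 0.015)
    set_("grassland", "built-up", 0.003)
    set_("forest", "grassland", 0.01)
    set_("forest", "cropland", 0.004)
    set_("cropland", "built-up", 0.02)
    set_("cropland", "grassland", 0.01)
    set_("water", "bare", 0.01)
    for i in range(6):
        p[i, i] = 1.0 - (p[i].sum() - p[i, i])
    return TransitionMatrix(classes, p, period_years=15.0)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    scenarios: list[str] = field(default_factory=lambda: ["BAU", "ED", "EC"])
    years: list[int] = field(default_factory=lambda: [2015, 2020, 2025, 2030, 2035])
    calibration_period_years: float = 15.0
    calibration_matrix: TransitionMatrix | None = None
    n_driving_factors: int = 16
    sample_fraction: float = 0.10
    min_interaction_area_km2: float = 40.0
    unchanged_epsilon: float = 0.0
    i_zrd: float = 0.7          # uniform land-quality grade of cropland
    demand_tolerance: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValidationError("years must be strictly increasing")
        steps = {b - a for a, b in zip(self.years, self.years[1:])}
        if len(steps) > 1:
            raise ValidationError("years must be evenly spaced")

    @property
    def step_years(self) -> int:
        return self.years[1] - self.years[0]


def _markov_step_map(landuse: LandUseMap, matrix: TransitionMatrix,
                     seed: int) -> LandUseMap:
    """Advance a map one matrix period by independent per-pixel row draws."""
    rng = np.random.default_rng(seed)
    codes = np.array([CLASS_CODES[c] for c in matrix.classes], dtype=np.uint8)
    lut = np.full(codes.max() + 1, -1, dtype=np.int64)
    for i, c in enumerate(codes):
        lut[c] = i
    idx = lut[landuse.classes.ravel()]
    cum = np.cumsum(matrix.probs, axis=1)
    u = rng.random(idx.size)
    nxt = (u[:, None] > cum[idx]).sum(axis=1).clip(max=len(codes) - 1)
    return LandUseMap(codes[nxt].reshape(landuse.classes.shape),
                      landuse.grid, landuse.zones)


def _quantify_all(bundle, landuse: LandUseMap, config: PipelineConfig,
                  year: int) -> dict[str, ESLayer]:
    """All six ES layers for one land-use map on the fixed environment."""
    g = bundle.grid
    wy = water_yield(
        WaterYieldInputs(bundle.precipitation, bundle.et0), landuse, year)
    cp = crop_production(
        CropParams(i_zrd=np.full(g.shape, config.i_zrd)),
        bundle.temperature, bundle.precipitation, landuse, year)
    usle = USLEFactorStack(
        r=rainfall_erosivity(bundle.precipitation),
        k=soil_erodibility_epic(bundle.soil_stack["sand"], bundle.soil_stack["silt"],
                                bundle.soil_stack["clay"],
                                bundle.soil_stack["organic_matter"]),
        ls=slope_length_steepness(bundle.dem, g.pixel_size))
    sc = usle_soil_conservation(usle, landuse, year)
    rweq = RWEQFactorStack(wf=bundle.wind_stack["WF"], ef=bundle.wind_stack["EF"],
                           scf=bundle.wind_stack["SCF"], ka=bundle.wind_stack["Ka"])
    sf = rweq_sand_fixation(rweq, landuse, year)
    cs, _ = carbon_sequestration(CarbonDensityTable(), landuse, year)
    av = aesthetic_value(AVScoreTable(), landuse, year)
    return {"WY": wy, "CP": cp, "SC": sc, "SF": sf, "CS": cs, "AV": av}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages for every configured scenario; return the run dir.

    Raises with the failing stage's name on error; the manifest records
    config, seed, package version and a hash of every written file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_times: dict[str, float] = {}
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31 - 1))
             for name in ("calibration", "factors", "training", "allocation")}

    def _stage(name):
        log.info("stage %s", name)
        stage_times[name] = time.time()
        return name

    stage = _stage("synth")
    try:
        bundle = generate_landscape(config.synthetic)
        write_bundle(bundle, out / "bundle")
        lu_start = bundle.landuse_t0            # calibration-period start
        cal = config.calibration_matrix or default_calibration_matrix()
        lu_base = _markov_step_map(lu_start, cal, seeds["calibration"])  # base year
        write_raster(lu_base.classes, bundle.grid,
                     out / f"landuse_{config.years[0]}.tif",
                     categorical=True, classes=CLASS_CODES)

        stage = _stage("simulate")
        p_cal = estimate_transition_matrix(
            lu_start, lu_base, config.calibration_period_years)
        factors = generate_driving_factors(
            bundle, config.n_driving_factors, seeds["factors"])
        surface = train_suitability(
            factors, lu_base, config.sample_fraction, seeds["training"],
            min_class_samples=5)
        auc = roc_auc(surface, lu_base)
        px_area = bundle.grid.pixel_area_km2
        n_split = max(int(round(config.calibration_period_years / config.step_years)), 1)
        q_by_scenario = {}
        all_scen = default_scenarios()
        for name in config.scenarios:
            p_s = apply_scenario_modifiers(p_cal, all_scen[name])
            q_by_scenario[name] = step_split_matrix(p_s, n_split)

        # validation: reallocate the base year from the calibration start
        base_demand = {c: lu_base.class_counts()[CLASS_CODES[c]]
                       for c in p_cal.classes}
        ca_params = CAParams(demand_tolerance=config.demand_tolerance,
                             seed=seeds["allocation"])
        sim_base, diag0 = ca_allocate(lu_start, surface, ca_params, base_demand)
        validation = {"roc_auc": auc, "kappa": kappa(sim_base, lu_base),
                      "base_allocation": diag0}
        (out / "validation.json").write_text(json.dumps(validation, indent=1, default=str))

        results: dict[str, dict] = {}
        for name in config.scenarios:
            sdir = out / name
            sdir.mkdir(exist_ok=True)
            q = q_by_scenario[name]
            areas0 = {c: lu_base.class_counts()[CLASS_CODES[c]] * px_area
                      for c in q.classes}
            demand = project_demand(q, areas0, config.years)
            pd.DataFrame(demand.areas, index=config.years,
                         columns=demand.classes).rename_axis("year") \
                .to_csv(sdir / "demand_km2.csv")

            lu_by_year = {config.years[0]: lu_base}
            current = lu_base
            for step, year in enumerate(config.years[1:], start=1):
                target_px = {c: demand.at(year)[c] / px_area for c in q.classes}
                params = CAParams(demand_tolerance=config.demand_tolerance,
                                  seed=seeds["allocation"] + step)
                current, diag = ca_allocate(current, surface, params, target_px)
                lu_by_year[year] = current
                write_raster(current.classes, bundle.grid,
                             sdir / f"landuse_{year}.tif",
                             categorical=True, classes=CLASS_CODES)

            stage = _stage(f"quantify[{name}]")
            es_by_year = {y: _quantify_all(bundle, lu_by_year[y], config, y)
                          for y in config.years}
            y0, y1 = config.years[0], config.years[-1]
            for y in (y0, y1):
                for key, layer in es_by_year[y].items():
                    write_raster(layer.values, bundle.grid,
                                 sdir / f"es_{key}_{y}.tif")

            stage = _stage(f"interact[{name}]")
            series_rows = []
            series = {}
            for key in ES_ORDER:
                totals = np.array([
                    float(zonal_totals(es_by_year[y][key], bundle.zones)
                          .query("zone == 'all'")["total"].iloc[0])
                    for y in config.years])
                series[key] = totals
                norm = minmax_normalize(totals)
                for y, raw, nv in zip(config.years, totals, norm):
                    series_rows.append({"scenario": name, "year": y, "es": key,
                                        "raw": raw, "normalized": nv})
            pd.DataFrame(series_rows).to_csv(sdir / "flower_series.csv", index=False)
            trends = classify_regional_trends(series)
            (sdir / "trends.json").write_text(json.dumps(
                {"per_es": trends.per_es,
                 "pairs": {f"{a}|{b}": v for (a, b), v in trends.pairs.items()}},
                indent=1))

            digits = {key: reclass_change(es_by_year[y0][key], es_by_year[y1][key],
                                          config.unchanged_epsilon)
                      for key in ES_ORDER}
            codes = encode_overlay(digits, bundle.grid)
            filtered = filter_codes_by_area(codes, config.min_interaction_area_km2)
            write_raster(filtered.codes, bundle.grid, sdir / "interaction_codes.tif")
            (sdir / "interaction_legend.json").write_text(
                json.dumps(filtered.legend, indent=1))
            causes = attribute_causes(filtered, lu_by_year[y0], lu_by_year[y1])
            causes.to_csv(sdir / "causes.csv", index=False)
            results[name] = {
                "demand_final": demand.at(y1),
                "n_retained_interactions": sum(1 for e in filtered.legend
                                               if e["code"] != 0),
            }
    except Exception as err:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    from . import __version__ as pkg_version
    manifest = {
        "version": pkg_version,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "results": json.loads(json.dumps(results, default=str)),
        "files": {str(p.relative_to(out)): _sha256(p)
                  for p in sorted(out.rglob("*")) if p.is_file()},
    }
    log.info("run complete in %.1f s", time.time() - t_start)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
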