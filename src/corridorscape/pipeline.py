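"""End-to-end orchestration: simulate -> SDM -> resistance -> corridors ->
circuit -> change accounting -> validation, per time step, plus the
sensitivity scan over the resistance shape factor and corridor cutoff.

Every stage draws its randomness from named substreams of one master seed,
so a run is a pure function of (config, seed): rerunning writes byte-identical
CSV artifacts. Time steps are processed independently; the cross-step link
summary (one row per corridor, sorted by descending centrality) is assembled
at the end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from corridorscape import change as change_mod
from corridorscape import circuit as circuit_mod
from corridorscape import connectivity as conn
from corridorscape import sdm as sdm_mod
from corridorscape import synthetic as syn
from corridorscape.raster import CovariateStack, RasterGrid, collinearity_filter, write_raster

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "sensitivity_scan",
    "rasterize_geojson",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full-run settings; nested sections mirror the pipeline stages."""

    simulation: syn.SimulationConfig = field(default_factory=syn.SimulationConfig)
    n_absences: int = 1000
    replications: int = 10
    train_fraction: float = 0.75
    collinearity_threshold: float = 0.7
    fast_learners: bool = False
    jackknife: bool = True
    jackknife_replications: int = 5
    resistance_c: float = 0.25
    cutoff: float = 200.0
    pairs: list[tuple[int, int]] | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            if "time_steps" in sim:
                sim["time_steps"] = tuple(sim["time_steps"])
            if "cropland_target_fraction" in sim:
                sim["cropland_target_fraction"] = tuple(sim["cropland_target_fraction"])
            sim = syn.SimulationConfig(**sim)
        pairs = d.pop("pairs", None)
        if pairs is not None:
            pairs = [tuple(p) for p in pairs]
        return cls(simulation=sim, pairs=pairs, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["time_steps"] = list(d["simulation"]["time_steps"])
        d["simulation"]["cropland_target_fraction"] = list(
            d["simulation"]["cropland_target_fraction"]
        )
        if d["pairs"] is not None:
            d["pairs"] = [list(p) for p in d["pairs"]]
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    pa_masks: list[RasterGrid]
    pa_names: list[str]
    landcover: list[RasterGrid]
    suitability: dict[int, sdm_mod.SuitabilitySurface]
    models: dict[int, sdm_mod.EnsembleModel]
    importance: dict[int, dict[str, float]]
    links: dict[int, list[conn.CorridorLink]]
    change_table: change_mod.ChangeTable
    encroachment: pd.DataFrame
    transects: pd.DataFrame
    reports: pd.DataFrame
    activity: pd.DataFrame
    binary_accuracy: float
    links_summary: pd.DataFrame


def rasterize_geojson(collection: dict, template: RasterGrid) -> tuple[list[RasterGrid], list[str]]:
    """Burn each GeoJSON polygon feature into a binary mask on ``template``
    (cell centers inside the polygon)."""
    import shapely
    from shapely.geometry import shape

    xs, ys = template.cell_centers()
    masks, names = [], []
    for i, feat in enumerate(collection.get("features", [])):
        geom = shape(feat["geometry"])
        inside = shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(template.shape)
        masks.append(template.copy_with(inside.astype(float)))
        names.append(feat.get("properties", {}).get("name", f"PA{i + 1}"))
    return masks, names


def _step_stack(static: CovariateStack, cropland: RasterGrid) -> CovariateStack:
    """SDM covariates for one time step: distance to that step's cropland
    (listed first, so the keep-earlier collinearity rule protects the focal
    anthropogenic covariate) followed by the static layers."""
    from corridorscape.raster import euclidean_distance_surface

    stack = CovariateStack(
        names=["dist_cropland"],
        grids={"dist_cropland": euclidean_distance_surface(cropland)},
    )
    for name in syn.SDM_COVARIATES:
        stack.add(name, static[name])
    return stack


def run_pipeline(
    cfg: PipelineConfig, out_dir: str | Path | None = None, seed: int | None = None
) -> PipelineResult:
    """Execute all stages on a synthetic landscape; optionally write every
    artifact under ``out_dir``. ``seed`` overrides the simulation seed."""
    if seed is not None:
        cfg = dataclasses.replace(cfg, simulation=dataclasses.replace(cfg.simulation, seed=seed))
    sim = cfg.simulation
    t0 = time.time()

    def stage(name: str):
        logger.info("[%6.1fs] stage %s", time.time() - t0, name)

    stage("simulate")
    static = syn.simulate_covariates(sim)
    pa_masks = syn.simulate_protected_areas(sim)
    pa_names = [f"PA{i + 1}" for i in range(len(pa_masks))]
    cropland = syn.simulate_cropland_series(sim, static, pa_masks)
    landcover = syn.landcover_series(sim, static, cropland)

    suitability: dict[int, sdm_mod.SuitabilitySurface] = {}
    models: dict[int, sdm_mod.EnsembleModel] = {}
    importance: dict[int, dict[str, float]] = {}
    links: dict[int, list[conn.CorridorLink]] = {}
    presences_by_step: dict[int, pd.DataFrame] = {}
    learners = sdm_mod.default_learners(fast=cfg.fast_learners)
    truth_last = None

    for si, step in enumerate(sim.time_steps):
        stage(f"sdm {step}")
        full_stack = _step_stack(static, cropland[si])
        # ground truth uses the unfiltered stack; the filter only shapes what
        # the fitted model sees
        truth = syn.true_suitability(sim, full_stack)
        stack, dropped, _ = collinearity_filter(full_stack, cfg.collinearity_threshold)
        if dropped:
            logger.info("step %s: collinearity filter dropped %s", step, dropped)
        presences = syn.sample_presences(truth, sim.n_presence, seed=sim.seed + si)
        presences_by_step[step] = presences
        background = stack.template.copy_with(stack.joint_valid_mask().astype(float))
        absences = sdm_mod.sample_pseudo_absences(
            background, presences, cfg.n_absences, seed=np.random.default_rng((sim.seed, 20 + si))
        )
        model = sdm_mod.fit_ensemble(
            presences, absences, stack, learners, cfg.replications, cfg.train_fraction,
            seed=sim.seed + si,
        )
        surface = sdm_mod.predict_suitability(model, stack)
        # max(sens+spec) threshold from model scores at presence/absence cells
        pcells = np.concatenate([presences["row"], absences["row"]]), np.concatenate(
            [presences["col"], absences["col"]]
        )
        scores = surface.grid.values[pcells[0].astype(int), pcells[1].astype(int)]
        y = np.concatenate([np.ones(len(presences)), np.zeros(len(absences))])
        surface.threshold = sdm_mod.max_sens_spec_threshold(scores, y)
        surface = sdm_mod.classify_suitability(surface, seed=sim.seed)
        suitability[step] = surface
        models[step] = model
        if cfg.jackknife:
            stage(f"jackknife {step}")
            importance[step] = sdm_mod.jackknife_importance(
                presences, absences, stack,
                sdm_mod.default_learners(fast=True),
                replications=cfg.jackknife_replications,
                train_fraction=cfg.train_fraction, seed=sim.seed + si,
            )

        stage(f"corridors {step}")
        res = conn.suitability_to_resistance(surface, conn.ResistanceParams(c=cfg.resistance_c))
        step_links = conn.build_link_table(
            pa_masks, res, pairs=cfg.pairs, cutoff=cfg.cutoff, names=pa_names
        )
        stage(f"circuit {step}")
        circuit_mod.pinchpoint_maps(step_links, res, pa_masks, names=pa_names)
        circuit_mod.link_centrality(step_links)
        step_links.sort(key=lambda lk: (-(lk.centrality if np.isfinite(lk.centrality) else -1),
                                        lk.pa_from, lk.pa_to))
        links[step] = step_links
        if si == len(sim.time_steps) - 1:
            truth_last = truth

    stage("change")
    change_table = change_mod.compose_change_table(
        landcover, list(sim.time_steps),
        total_area_km2=landcover[0].valid_mask().sum() * sim.cellsize**2,
        class_names={v: k for k, v in syn.LANDCOVER_CODES.items()},
    )
    last = sim.time_steps[-1]
    encroachment = change_mod.corridor_encroachment(
        links[last], landcover, list(sim.time_steps), syn.LANDCOVER_CODES["cropland"]
    )

    stage("validate")
    transects, reports = syn.simulate_validation_data(truth_last, links[last], sim)
    activity = change_mod.corridor_activity(links[last], reports)
    binary_accuracy = sdm_mod.binary_map_accuracy(suitability[last].binary(), transects)

    links_summary = _links_summary(links, sim.time_steps, activity)
    result = PipelineResult(
        config=cfg, pa_masks=pa_masks, pa_names=pa_names, landcover=landcover,
        suitability=suitability, models=models, importance=importance, links=links,
        change_table=change_table, encroachment=encroachment, transects=transects,
        reports=reports, activity=activity, binary_accuracy=binary_accuracy,
        links_summary=links_summary,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    stage("done")
    return result


def _links_summary(
    links: dict[int, list[conn.CorridorLink]],
    steps: Sequence[int],
    activity: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-step link table, one row per corridor, sorted by descending
    centrality at the last step."""
    last = steps[-1]
    act = activity.set_index(["pa_from", "pa_to"]) if len(activity) else None
    rows = []
    for lk in links[last]:
        row: dict = {"pa_from": lk.pa_from, "pa_to": lk.pa_to}
        for step in steps:
            match = next(
                (l for l in links[step] if (l.pa_from, l.pa_to) == (lk.pa_from, lk.pa_to)), None
            )
            if match is None:
                continue
            row[f"cwd_eud_{step}"] = match.cwd_eud_ratio
            row[f"cwd_lcp_{step}"] = match.cwd_lcp_ratio
            row[f"centrality_{step}"] = match.centrality
        if act is not None and (lk.pa_from, lk.pa_to) in act.index:
            arow = act.loc[(lk.pa_from, lk.pa_to)]
            row["sightings_mean"] = arow["sightings_mean"]
            row["sightings_sd"] = arow["sightings_sd"]
            row["seasons"] = arow["seasons"]
            row["status"] = arow["status"]
        rows.append(row)
    df = pd.DataFrame(rows)
    if f"centrality_{last}" in df.columns:
        df = df.sort_values(f"centrality_{last}", ascending=False).reset_index(drop=True)
    return df


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    sim = result.config.simulation
    fmt = "%.6g"
    with open(out / "pas.geojson", "w") as fh:
        json.dump(syn.pa_geojson(result.pa_masks, result.pa_names), fh)
    for si, step in enumerate(sim.time_steps):
        write_raster(result.landcover[si], out / f"landcover_{step}.asc")
        write_raster(result.suitability[step].grid, out / f"suitability_{step}.asc")
        if result.suitability[step].classes is not None:
            write_raster(result.suitability[step].classes, out / f"suitability_classes_{step}.asc")
        result.models[step].auc_table.to_csv(out / f"auc_table_{step}.csv", float_format=fmt)
        if step in result.importance:
            pd.Series(result.importance[step], name="percent_contribution").rename_axis(
                "covariate"
            ).to_csv(out / f"importance_{step}.csv", float_format=fmt)
        _links_csv(result.links[step]).to_csv(out / f"links_{step}.csv", index=False,
                                              float_format=fmt)
    result.change_table.table.to_csv(out / "change_table.csv", float_format=fmt)
    result.encroachment.to_csv(out / "encroachment.csv", index=False, float_format=fmt)
    result.transects.to_csv(out / "transects.csv", index=False, float_format=fmt)
    result.reports.to_csv(out / "reports.csv", index=False, float_format=fmt)
    result.activity.to_csv(out / "corridor_status.csv", index=False, float_format=fmt)
    result.links_summary.to_csv(out / "links_summary.csv", index=False, float_format=fmt)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=True)


def _links_csv(links: list[conn.CorridorLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pa_from": lk.pa_from,
                "pa_to": lk.pa_to,
                "lcp_cost_cwkm": lk.lcp_cost,
                "lcp_length_km": lk.lcp_length,
                "euclid_dist_km": lk.euclid_dist,
                "cwd_eud": lk.cwd_eud_ratio,
                "cwd_lcp": lk.cwd_lcp_ratio,
                "centrality": lk.centrality,
                "current_mean": lk.current_mean,
                "current_max": lk.current_max,
                "reachable": lk.reachable,
            }
            for lk in links
        ]
    )


def sensitivity_scan(
    cfg: PipelineConfig,
    c_values: Sequence[float] = (2.0, 1.0, 0.5, 0.25),
    cutoffs: Sequence[float] = (200.0, 150.0, 100.0, 50.0),
    surface: sdm_mod.SuitabilitySurface | None = None,
) -> pd.DataFrame:
    """Corridor count and total corridor area for every (c, cutoff)
    combination — the evidence base for choosing the resistance shape and the
    truncation threshold.

    When ``surface`` is not given, the suitability of the last time step is
    fitted once and reused across combinations (the scan varies only the
    resistance transform and the truncation).
    """
    sim = cfg.simulation
    pa_masks = syn.simulate_protected_areas(sim)
    pa_names = [f"PA{i + 1}" for i in range(len(pa_masks))]
    if surface is None:
        static = syn.simulate_covariates(sim)
        cropland = syn.simulate_cropland_series(sim, static, pa_masks)
        full_stack = _step_stack(static, cropland[-1])
        truth = syn.true_suitability(sim, full_stack)
        stack, _, _ = collinearity_filter(full_stack, cfg.collinearity_threshold)
        presences = syn.sample_presences(truth, sim.n_presence, seed=sim.seed)
        background = stack.template.copy_with(stack.joint_valid_mask().astype(float))
        absences = sdm_mod.sample_pseudo_absences(
            background, presences, cfg.n_absences, seed=np.random.default_rng((sim.seed, 99))
        )
        model = sdm_mod.fit_ensemble(
            presences, absences, stack, sdm_mod.default_learners(fast=True),
            cfg.replications, cfg.train_fraction, seed=sim.seed,
        )
        surface = sdm_mod.predict_suitability(model, stack)

    rows = []
    for c in c_values:
        res = conn.suitability_to_resistance(surface, conn.ResistanceParams(c=c))
        links = conn.build_link_table(pa_masks, res, pairs=cfg.pairs, cutoff=max(cutoffs),
                                      names=pa_names)
        # reuse each link's corridor values by re-truncating at every cutoff
        needed = sorted({i for p in (cfg.pairs or
                         [(i, j) for i in range(len(pa_masks)) for j in range(i + 1, len(pa_masks))])
                         for i in p})
        cwd = {i: conn.cost_weighted_distance(res, pa_masks[i]) for i in needed}
        name_to_idx = {n: i for i, n in enumerate(pa_names)}
        for cutoff in cutoffs:
            n_corr = 0
            area = 0.0
            for lk in links:
                if not lk.reachable:
                    continue
                i, j = name_to_idx[lk.pa_from], name_to_idx[lk.pa_to]
                _, mask = conn.normalized_corridor(cwd[i], cwd[j], lk.lcp_cost, cutoff)
                cells = int((mask.values > 0).sum())
                if cells:
                    n_corr += 1
                    area += cells * res.grid.cellsize**2
            rows.append({"c": c, "cutoff": cutoff, "n_corridors": n_corr,
                         "corridor_area_km2": area})
    return pd.DataFrame(rows)
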