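"""Full-analysis orchestration: multi-extent niche models, connectivity,
patch prioritization, and gap analysis in one reproducible run.

The pipeline mirrors the analysis order: generate (or load) the landscape;
screen predictors for collinearity; for each focal extent, smooth the
predictors with a circular moving window, fit the suitability ensemble,
binarize with both threshold rules, and compute pattern metrics; select
the best extent by mean test AUC; transform that extent's suitability to
resistance; then for each dispersal threshold build resistant kernels,
delineate cores, rank them by dPC (area and strength attributes), and
overlay conservation areas; finally sum factorial least-cost-path
corridors.  Every artifact is written under the run directory with a
machine-readable manifest (config, versions, per-file checksums).
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

from . import __version__
from .connectivity import (
    DISPERSAL_THRESHOLDS,
    factorial_lcp,
    resistant_kernel,
    suitability_to_resistance,
)
from .grid import (
    Grid,
    OccurrenceSet,
    Stack,
    focal_mean_circular,
    morans_i,
    pearson_screen,
    read_raster,
    write_raster,
)
from .niche import (
    ModelConfig,
    apply_threshold,
    fit_ensemble,
    predict_suitability,
    resolve_threshold,
    variable_importance,
)
from .patches import correlation_length, delineate_cores, lpi, number_of_patches, pland
from .prioritize import build_patch_graph, ca_prioritization, gap_coverage, rank_patches
from .synth import (
    ConservationAreas,
    LandscapeSpec,
    TrueModel,
    generate_conservation_areas,
    generate_predictor_stack,
    simulate_occurrences,
)

__all__ = ["PipelineConfig", "run_full"]

log = logging.getLogger("landconnect")


@dataclass
class PipelineConfig:
    """Run settings; the defaults reproduce the analysis settings
    (extents 0.1/0.5/1/2/4 km, dispersal thresholds 50000..250000 cost
    units, 70th-percentile cores, 10 replicates, 10000 background
    points)."""

    # inputs: either paths ...
    stack_paths: dict[str, str] | None = None
    occurrences_path: str | None = None
    cas_path: str | None = None
    # ... or a synthetic landscape
    synthetic: LandscapeSpec | None = None
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {"env1": 2.5, "env2": -2.0, "dist_roads": -1.0}
    )
    true_intercept: float = -4.0
    n_occurrences: int = 188

    extents: tuple[float, ...] = (100.0, 500.0, 1000.0, 2000.0, 4000.0)
    dispersal_thresholds: tuple[float, ...] = DISPERSAL_THRESHOLDS
    threshold_rules: tuple[str, ...] = (
        "p10_training_presence",
        "mean_presence_suitability",
    )
    core_percentile: float = 70.0
    buffer_width: float = 200.0
    dispersal_p_med: float = 0.5
    moran_aggregation_cell: float = 1000.0
    max_lcp_sources: int = 40
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    outdir: str = "landconnect_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = LandscapeSpec(**raw["synthetic"])
        if "model" in raw and raw["model"] is not None:
            raw["model"] = ModelConfig(**raw["model"])
        for key in ("extents", "dispersal_thresholds", "threshold_rules"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        spec = config.synthetic
        stack = generate_predictor_stack(spec)
        truth = TrueModel(
            coefficients=config.true_coefficients, intercept=config.true_intercept
        )
        occ = simulate_occurrences(truth, stack, config.n_occurrences, seed=spec.seed)
        cas = generate_conservation_areas(spec)
        return stack, occ, cas
    if not (config.stack_paths and config.occurrences_path):
        raise ValueError("config needs either a synthetic spec or input paths")
    stack = Stack({n: read_raster(p) for n, p in config.stack_paths.items()})
    occ = OccurrenceSet.from_csv(config.occurrences_path)
    cas = (
        ConservationAreas.from_geojson(config.cas_path)
        if config.cas_path
        else ConservationAreas([], [])
    )
    return stack, occ, cas


def run_full(config: PipelineConfig) -> Path:
    """Run the complete analysis; returns the run directory.

    Any stage failure aborts with the stage name; everything written up to
    that point stays on disk.  Reruns with the same config and seed
    produce byte-identical artifacts (identical manifest hashes).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    manifest: dict = {
        "version": __version__,
        "config": _jsonable(config.to_dict()),
        "stages": {},
        "files": {},
    }
    stage = "inputs"
    try:
        t0 = time.time()
        stack, occ, cas = _load_inputs(config)
        occ.to_csv(outdir / "occurrences.csv")
        if cas.n:
            cas.to_geojson(outdir / "conservation_areas.geojson")
        _stage_done(manifest, stage, t0)

        stage = "screening"
        t0 = time.time()
        moran = morans_i(occ, stack.geometry, config.moran_aggregation_cell)
        log.info(
            "Moran's I on occurrences: I=%.4f z=%.3f (%s)",
            moran.I,
            moran.z_score,
            moran.status,
        )
        retained, corr = pearson_screen(stack)
        corr.to_csv(outdir / "predictor_correlations.csv")
        stack = stack.subset(retained)
        manifest["stages"]["screening_detail"] = {
            "moran_I": None if np.isnan(moran.I) else moran.I,
            "moran_z": None if np.isnan(moran.z_score) else moran.z_score,
            "retained": retained,
        }
        _stage_done(manifest, stage, t0)

        stage = "niche_models"
        t0 = time.time()
        per_extent: dict[float, dict] = {}
        metric_rows = []
        for extent in config.extents:
            smoothed = Stack(
                {n: focal_mean_circular(g, extent) for n, g in stack.items()}
            )
            mc = ModelConfig(**{**asdict(config.model), "seed": config.seed})
            ens = fit_ensemble(occ, smoothed, mc)
            hs = predict_suitability(ens, smoothed)
            write_raster(hs, outdir / f"hs_extent{int(extent)}m.asc")
            ens.coefficient_table().to_csv(
                outdir / f"coefficients_extent{int(extent)}m.csv", index=False
            )
            binaries = {}
            for rule_name in config.threshold_rules:
                rule = resolve_threshold(ens, occ, hs, rule_name)
                binary = apply_threshold(hs, rule)
                write_raster(
                    binary, outdir / f"binary_extent{int(extent)}m_{rule_name}.asc"
                )
                binaries[rule_name] = binary
                metric_rows.append(
                    {
                        "extent_m": extent,
                        "rule": rule_name,
                        "threshold": rule.value,
                        "pland": pland(binary),
                        "np": number_of_patches(binary),
                        "lpi": lpi(binary),
                        "cl_m": correlation_length(binary),
                    }
                )
            per_extent[extent] = {
                "ensemble": ens,
                "smoothed": smoothed,
                "hs": hs,
                "binaries": binaries,
                "auc": ens.mean_test_auc,
            }
            log.info("extent %.0f m: mean test AUC %.3f", extent, ens.mean_test_auc)
        pd.DataFrame(metric_rows).to_csv(outdir / "pattern_metrics.csv", index=False)
        _stage_done(manifest, stage, t0)

        stage = "extent_selection"
        # ties break toward the larger extent
        best_extent = max(config.extents, key=lambda e: (per_extent[e]["auc"], e))
        best = per_extent[best_extent]
        manifest["stages"]["extent_selection_detail"] = {
            "best_extent_m": best_extent,
            "auc_by_extent": {str(e): per_extent[e]["auc"] for e in config.extents},
        }
        log.info("best extent: %.0f m", best_extent)
        imp = variable_importance(
            best["ensemble"], occ, best["smoothed"], seed=config.seed
        )
        imp.to_csv(outdir / "variable_importance.csv")

        stage = "resistance"
        t0 = time.time()
        resistance = suitability_to_resistance(best["hs"])
        write_raster(resistance.grid, outdir / "resistance.asc")
        _stage_done(manifest, stage, t0)

        stage = "connectivity"
        t0 = time.time()
        src_cells = occ.cells(resistance.grid)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
        uniq = np.unique(src_cells, axis=0)
        if len(uniq) > config.max_lcp_sources:
            pick = rng.choice(len(uniq), size=config.max_lcp_sources, replace=False)
            lcp_sources = uniq[np.sort(pick)]
        else:
            lcp_sources = uniq
        corridors = factorial_lcp(resistance, lcp_sources, config.buffer_width)
        write_raster(corridors, outdir / "corridor_strength.asc")
        corridor_pct = (
            100.0
            * np.nansum(corridors.values > 0)
            / corridors.mask.sum()
        )
        manifest["stages"]["connectivity_detail"] = {
            "n_lcp_sources": int(len(lcp_sources)),
            "corridor_landscape_pct": corridor_pct,
        }
        _stage_done(manifest, stage, t0)

        stage = "cores_prioritization_gap"
        t0 = time.time()
        gap_rows = []
        for D in config.dispersal_thresholds:
            kern = resistant_kernel(resistance, occ, D)
            write_raster(kern.grid, outdir / f"kernel_D{int(D)}.asc")
            cores = delineate_cores(kern, config.core_percentile)
            cores.table().to_csv(outdir / f"cores_D{int(D)}.csv", index=False)
            write_raster(cores.labels, outdir / f"core_labels_D{int(D)}.asc")
            if cores.n:
                d_med = max_reach_for(D)
                for attribute in ("area", "strength"):
                    graph = build_patch_graph(
                        cores,
                        attribute=attribute,
                        dispersal=(config.dispersal_p_med, d_med),
                    )
                    rank_patches(graph).to_csv(
                        outdir / f"dpc_{attribute}_D{int(D)}.csv", index=False
                    )
                if cas.n:
                    cov = gap_coverage(cores, cas)
                    cov.insert(0, "dispersal_D", D)
                    gap_rows.append(cov)
        if gap_rows:
            pd.concat(gap_rows).to_csv(outdir / "gap_coverage.csv", index=False)
        if cas.n:
            suitable = best["binaries"][config.threshold_rules[0]]
            ca_rank = ca_prioritization(
                cas,
                suitable,
                dispersal=(config.dispersal_p_med, max_reach_for(config.dispersal_thresholds[0])),
            )
            ca_rank.to_csv(outdir / "ca_prioritization.csv", index=False)
        _stage_done(manifest, stage, t0)
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def max_reach_for(threshold: float) -> float:
    """Median-dispersal distance (meters) used for p(d) calibration: half
    the optimal-habitat reach of the cost-unit threshold."""
    return threshold / 2.0


def _stage_done(manifest: dict, stage: str, t0: float) -> None:
    manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
    log.info("stage %s done (%.1fs)", stage, time.time() - t0)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
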