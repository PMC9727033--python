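"""End-to-end pipeline: simulate -> localize -> cluster -> bursts -> report.

A single master seed expands to per-stage child seeds through
``numpy.random.SeedSequence(master).spawn``; the child index of each stage
is recorded in the run manifest. All stage outputs are schema-versioned
CSV/JSON so identical (config, seed) runs are byte-identical, except for
the manifest's wall-clock timestamp.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__, localize, pipeio, simkit, spatialcluster, tcpalm

logger = logging.getLogger(__name__)

STAGE_SEED_INDEX = {"sim": 0, "localize": 1, "cluster": 2, "bursts": 3}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    Section invariants are enforced on construction (each section's own
    dataclass validates itself) before any stage executes.
    """

    sim: simkit.SimConfig = field(default_factory=simkit.SimConfig)
    detection: localize.DetectionParams = field(default_factory=localize.DetectionParams)
    clustering: spatialcluster.ClusteringParams = field(
        default_factory=spatialcluster.ClusteringParams
    )
    camera: simkit.CameraModel = field(default_factory=simkit.CameraModel)
    max_gap_frames: int = 20
    short_lifetime_cutoff: float = 100.0
    pm_band_px: int = 2
    render_movie: bool = False  # False = fast path via the localization table
    localization_noise_sd: float = 20.0  # nm, fast path only
    seed: int = 0
    log_level: str = "INFO"

    def burst_params(self) -> tcpalm.BurstParams:
        return tcpalm.BurstParams(
            max_gap_frames=self.max_gap_frames,
            frame_rate=self.sim.frame_rate,
            short_lifetime_cutoff=self.short_lifetime_cutoff,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("sim", simkit.SimConfig),
            ("detection", localize.DetectionParams),
            ("clustering", spatialcluster.ClusteringParams),
            ("camera", simkit.CameraModel),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(pipeio.load_yaml(path))

    def to_yaml(self, path) -> None:
        pipeio.dump_yaml(self.to_dict(), path)


def stage_seeds(master_seed: int) -> dict:
    children = np.random.SeedSequence(master_seed).spawn(len(STAGE_SEED_INDEX))
    return {
        name: int(children[idx].generate_state(1)[0])
        for name, idx in STAGE_SEED_INDEX.items()
    }


def run_pipeline(config: PipelineConfig, out_dir) -> pipeio.RunManifest:
    """Execute all stages, persisting outputs under ``out_dir``.

    Any stage failure aborts the run; the manifest (written up front and
    updated per stage) records which stages completed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)

    manifest = pipeio.RunManifest(
        config_hash=pipeio.config_hash(config.to_dict()),
        seed=config.seed,
        stage_seeds=seeds,
        package_version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    config.to_yaml(out / "config.yaml")

    sim_cfg = config.sim.with_(seed=seeds["sim"])

    # --- simulate -----------------------------------------------------------
    region_labels = simkit.default_cell_geometry(sim_cfg, pm_band_px=config.pm_band_px)
    clusters_gt, traces = simkit.simulate_ground_truth(sim_cfg, region_labels=region_labels)
    pipeio.write_table(
        simkit.clusters_to_frame(clusters_gt), out / "ground_truth_clusters.csv",
        kind="ground_truth_clusters",
    )
    manifest.completed_stages.append("sim")
    manifest.write(manifest_path)

    # --- localizations ------------------------------------------------------
    if config.render_movie:
        stack = simkit.render_frames(traces, config.camera, sim_cfg)
        pipeio.write_stack(
            out / "movie.tif", stack, sim_cfg.pixel_size, sim_cfg.frame_rate
        )
        locs = localize.localize_stack(
            stack, config.detection, pixel_size=sim_cfg.pixel_size, camera=config.camera
        )
    else:
        locs = simkit.emit_localization_table(
            traces, sim_cfg, localization_noise_sd=config.localization_noise_sd
        )
    pipeio.write_table(locs, out / "localizations.csv", kind="localizations")
    manifest.completed_stages.append("localize")
    manifest.write(manifest_path)

    # --- spatial clustering -------------------------------------------------
    clusters, labels = spatialcluster.dbscan_cluster(locs, config.clustering)
    mask = spatialcluster.RegionMask(labels=region_labels, pixel_size=sim_cfg.pixel_size)
    spatialcluster.assign_regions(clusters, mask)
    locs_out = locs.copy()
    locs_out["cluster_id"] = labels
    pipeio.write_table(locs_out, out / "localizations_labeled.csv", kind="localizations")
    pipeio.write_table(
        spatialcluster.clusters_to_frame(clusters), out / "clusters.csv", kind="clusters"
    )
    manifest.completed_stages.append("cluster")
    manifest.write(manifest_path)

    # --- bursts + summary ---------------------------------------------------
    params = config.burst_params()
    bursts = tcpalm.bursts_from_clusters(
        locs, labels, clusters, params, n_frames=sim_cfg.n_frames
    )
    pipeio.write_table(
        tcpalm.bursts_to_frame(bursts, params), out / "bursts.csv", kind="bursts"
    )
    summary = summarize_run(bursts, clusters, params)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.completed_stages.append("bursts")
    manifest.write(manifest_path)
    return manifest


def summarize_run(bursts, clusters, params: tcpalm.BurstParams) -> dict:
    """JSON-ready per-region lifetime summary and cluster statistics."""
    out: dict = {"regions": {}, "n_bursts_total": len(bursts)}
    if bursts:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for region, s in tcpalm.summarize_by_region(bursts, params).items():
                out["regions"][region] = {
                    "tau_avg_short_s": _round(s.tau_avg_short),
                    "sem_tau_s": _round(s.sem_tau),
                    "fraction_long": _round(s.fraction_long),
                    "n_bursts": s.n_bursts,
                }
    if clusters:
        stats = tcpalm.cluster_stats(spatialcluster.clusters_to_frame(clusters))
        out["detections_per_cluster"] = {
            "mean": _round(stats.detections_mean),
            "min": stats.detections_min,
            "max": stats.detections_max,
        }
    return out


def _round(x: float, nd: int = 6) -> Optional[float]:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return None
    return round(float(x), nd)
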