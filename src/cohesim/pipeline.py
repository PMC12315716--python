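"""End-to-end pipeline: lattice simulation -> ChIP track / FRiP ->
polymer sampling -> contact map -> scores.

One master seed drives every stage (substreams are derived per stage /
replica), so two runs with equal configs produce equal numerical
outputs.  Each stage writes its artifact together with a sidecar hash of
the resolved config; on re-run, a stage whose artifact and hash match is
reused instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chipseq, io, layouts, scores
from .lattice import LatticeConfig, run_lattice
from .polymer import PolymerConfig, aggregate_map, sample_conformations

log = logging.getLogger("cohesim.pipeline")

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_CONFIG"]


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run.

    Every tunable of the lattice, polymer and scoring stages appears here
    with its documented default; ``seed`` controls all stages.
    """

    # Lattice
    n_sites: int = 10_000
    site_bp: int = 250
    n_replicas: int = 1
    extruder_separation: int = 1_000
    tau_E: float = 1_320.0
    leg_speed: float = 125.0
    dt_lattice: float = 0.5
    duration: float = 12_000.0
    sample_every: float = 2.0
    burn_in: float = -1.0  # -1 -> 3 * tau_E
    # Barrier layout (used when barriers_bed is empty)
    barriers_bed: str = ""
    n_barriers: int = 32
    tau_b: float = 1_350.0
    tau_u: float = 150.0
    orientation_scheme: str = "random"
    # ChIP / FRiP
    track_bin_bp: int = 250
    frip_window: int = 0
    # Polymer
    monomer_bp: int = 2_500
    bond_length: float = 1.0
    spring_k: float = 50.0
    excluded_volume_strength: float = 5.0
    dt_3d: float = 0.004
    steps_per_lattice_frame: int = 60
    equilibration_steps: int = 3_000
    capture_radius: float = 2.0
    bond_force_sat: float = 15.0
    polymer_frame_stride: int = 15
    polymer_max_frames: int = 500
    # Scoring
    map_resolution: int = 10_000
    insulation_window_bp: int = 50_000
    snippet_bp: int = 80_000
    dot_bins: int = 25
    dot_min_bp: float = 100_000.0
    dot_max_bp: float = 5_000_000.0
    dot_center_extent: int = 1
    dot_control_extent: int = 3
    voxel_size: float = 1.0
    smoothing_sigma: float = 2.0
    # Global
    seed: int = 0

    def lattice_config(self) -> LatticeConfig:
        return LatticeConfig(
            n_sites=self.n_sites,
            site_bp=self.site_bp,
            n_replicas=self.n_replicas,
            extruder_separation=self.extruder_separation,
            tau_E=self.tau_E,
            leg_speed=self.leg_speed,
            dt_lattice=self.dt_lattice,
            seed=self.seed,
        )

    def polymer_config(self) -> PolymerConfig:
        return PolymerConfig(
            monomer_bp=self.monomer_bp,
            bond_length=self.bond_length,
            spring_k=self.spring_k,
            excluded_volume_strength=self.excluded_volume_strength,
            dt_3d=self.dt_3d,
            steps_per_lattice_frame=self.steps_per_lattice_frame,
            equilibration_steps=self.equilibration_steps,
            capture_radius=self.capture_radius,
            bond_force_sat=self.bond_force_sat,
            seed=self.seed + 1,
        )

    def barriers(self):
        if self.barriers_bed:
            return io.read_barriers(self.barriers_bed, site_bp=self.site_bp)
        spec = layouts.LayoutSpec(
            region_bp=self.n_sites * self.site_bp,
            n_barriers=self.n_barriers,
            site_bp=self.site_bp,
            orientation_scheme=self.orientation_scheme,
            tau_b=self.tau_b,
            tau_u=self.tau_u,
            seed=self.seed,
        )
        return layouts.random_layout(spec)


DEFAULT_CONFIG = {k: v for k, v in vars(RunConfig()).items()}


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(vars(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_fresh(path: Path, hash_path: Path, h: str) -> bool:
    return path.exists() and hash_path.exists() and hash_path.read_text() == h


@dataclass
class PipelineResult:
    trace_path: Path
    track_path: Path
    frip_report_path: Path
    conformations_path: Path
    map_path: Path
    scores_path: Path
    frip: float
    control_frip: float
    insulation: float
    mean_dot: float
    vermicelli: float
    loaded: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig, out_dir) -> PipelineResult:
    """Execute all stages in order, reusing fresh stage outputs.

    Stages: lattice trace -> ChIP track + FRiP -> polymer conformations
    (replica 0) -> contact map -> insulation / dot / vermicelli scores.
    A failing stage aborts with its name in the raised error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = _config_hash(cfg)
    paths = {
        name: out / fname
        for name, fname in [
            ("trace", "trace.h5"),
            ("track", "track.bedGraph"),
            ("frip", "frip.tsv"),
            ("confs", "conformations.h5"),
            ("map", "map.npz"),
            ("scores", "scores.tsv"),
        ]
    }

    def run_stage(name, func):
        t0 = time.perf_counter()
        try:
            result = func()
        except Exception as exc:
            (out / f"{name}.INCOMPLETE").write_text(str(exc))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.1f s", name, time.perf_counter() - t0)
        (out / f"{name}.hash").write_text(h)
        return result

    barriers = cfg.barriers()
    io.write_barriers(barriers, out / "barriers.bed", site_bp=cfg.site_bp)

    # Stage 1: lattice
    if _stage_fresh(paths["trace"], out / "trace.hash", h):
        trace = io.read_trace(paths["trace"])
        log.info("stage trace reused")
    else:
        def _lattice():
            trace = run_lattice(
                cfg.lattice_config(), barriers, cfg.duration, cfg.sample_every,
                burn_in=None if cfg.burn_in < 0 else cfg.burn_in,
            )
            io.write_trace(trace, paths["trace"])
            return trace
        trace = run_stage("trace", _lattice)

    # Stage 2: ChIP track + FRiP
    def _chip():
        track = chipseq.accumulate_track(trace)
        io.write_track(
            chipseq.track_to_bedgraph(track, bin_bp=cfg.track_bin_bp),
            paths["track"],
        )
        barrier_sites = sorted({b.site for b in barriers})
        f = chipseq.frip(track, barrier_sites, window=cfg.frip_window)
        control = len(barrier_sites) / cfg.n_sites
        io.write_report(
            {"frip": f, "control_frip": control, "seed": cfg.seed,
             "config_hash": h}, paths["frip"],
        )
        return track, f, control

    track, frip_val, control_frip = run_stage("chip", _chip)

    # Stage 3: polymer conformations (replica 0)
    if _stage_fresh(paths["confs"], out / "confs.hash", h):
        confs = io.read_conformations(paths["confs"])
        log.info("stage confs reused")
    else:
        def _polymer():
            confs = sample_conformations(
                trace, cfg.polymer_config(), replica=0,
                frame_stride=cfg.polymer_frame_stride,
                max_frames=cfg.polymer_max_frames,
            )
            io.write_conformations(confs, paths["confs"], meta={"hash": h})
            return confs
        confs = run_stage("confs", _polymer)

    # Stage 4: contact map
    def _map():
        cmap = aggregate_map(
            confs, cfg.map_resolution, cfg.monomer_bp, cfg.capture_radius
        )
        io.write_map(cmap, paths["map"])
        return cmap

    cmap = run_stage("map", _map)

    # Stage 5: scores
    def _scores():
        w = cfg.insulation_window_bp // cfg.map_resolution
        bins = sorted(
            {
                b.site * cfg.site_bp // cfg.map_resolution
                for b in barriers
                if w <= b.site * cfg.site_bp // cfg.map_resolution < cmap.n_bins - w
            }
        )
        ins, _ = scores.insulation_score(cmap, bins, cfg.insulation_window_bp)
        pairs = scores.convergent_pairs_bp(barriers, cfg.site_bp)
        profile = scores.dot_profile(
            cmap, pairs, snippet_bp=cfg.snippet_bp, n_bins=cfg.dot_bins,
            dist_min_bp=cfg.dot_min_bp, dist_max_bp=cfg.dot_max_bp,
            center_extent=cfg.dot_center_extent,
            control_extent=cfg.dot_control_extent,
        )
        mean_dot = (
            scores.mean_dot_score(profile)
            if (profile.snippet_counts > 0).any()
            else float("nan")
        )
        verm = scores.vermicelli_score_frames(
            confs, voxel_size=cfg.voxel_size, smoothing_sigma=cfg.smoothing_sigma
        )
        io.write_report(
            {
                "insulation": ins,
                "mean_dot_score": mean_dot,
                "vermicelli": verm,
                "frip": frip_val,
                "control_frip": control_frip,
                "seed": cfg.seed,
                "config_hash": h,
            },
            paths["scores"],
        )
        return ins, mean_dot, verm

    ins, mean_dot, verm = run_stage("scores", _scores)

    return PipelineResult(
        trace_path=paths["trace"],
        track_path=paths["track"],
        frip_report_path=paths["frip"],
        conformations_path=paths["confs"],
        map_path=paths["map"],
        scores_path=paths["scores"],
        frip=frip_val,
        control_frip=control_frip,
        insulation=ins,
        mean_dot=mean_dot,
        vermicelli=verm,
    )
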