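"""Readers and writers: barrier BED, bedGraph tracks, trace/conformation
HDF5 containers, contact-map archives, TSV reports, and the flat
key-value run configuration.

Coordinates are 0-based half-open everywhere (BED convention); the
lattice <-> bp conversion is ``bp = site * site_bp`` (interval
``[site*site_bp, (site+1)*site_bp)``), applied only here and in the
layout generators.

Barrier BED dialect (tab-separated, no header):
``chrom  start  end  name  score  strand  tau_b  tau_u``
where score echoes the occupancy ``tau_b/(tau_b+tau_u)`` and strand is
``+`` (blocks rightward-moving legs) or ``-`` (blocks leftward-moving
legs).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .chipseq import OccupancyTrack
from .lattice import BarrierSite, LatticeTrace
from .polymer import Conformation, ContactMap

__all__ = [
    "read_barriers",
    "write_barriers",
    "write_track",
    "write_trace",
    "read_trace",
    "write_conformations",
    "read_conformations",
    "write_map",
    "read_map",
    "write_report",
    "load_config",
]

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "tau_b", "tau_u"]


def read_barriers(path, site_bp: int = 250) -> list[BarrierSite]:
    """Parse the barrier BED dialect into :class:`BarrierSite` records."""
    barriers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 tab-separated columns "
                    f"(chrom start end name score strand tau_b tau_u), got "
                    f"{len(fields)}"
                )
            chrom, start, end, name, score, strand, tau_b, tau_u = fields[:8]
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: strand must be '+' (blocks rightward "
                    f"legs) or '-' (blocks leftward legs), got {strand!r}"
                )
            try:
                start_i = int(start)
                tau_b_f = float(tau_b)
                tau_u_f = float(tau_u)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            barriers.append(
                BarrierSite(
                    site=start_i // site_bp,
                    orientation=strand,
                    tau_b=tau_b_f,
                    tau_u=tau_u_f,
                )
            )
    return barriers


def write_barriers(
    barriers: list[BarrierSite], path, site_bp: int = 250, chrom: str = "replica"
) -> None:
    rows = []
    for k, b in enumerate(barriers):
        start = b.site * site_bp
        rows.append(
            (chrom, start, start + site_bp, f"barrier_{k}",
             round(b.occupancy, 6), b.orientation, b.tau_b, b.tau_u)
        )
    pd.DataFrame(rows, columns=_BED_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_track(track_df: pd.DataFrame, path) -> None:
    """Write a bedGraph (0-based half-open, sorted by start)."""
    track_df.sort_values(["chrom", "start"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_trace(trace: LatticeTrace, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("times", data=trace.times)
        h5.create_dataset("leg_positions", data=trace.leg_positions,
                          compression="gzip")
        h5.create_dataset("barrier_states", data=trace.barrier_states,
                          compression="gzip")
        h5.create_dataset("barrier_sites", data=trace.barrier_sites)
        h5.create_dataset("replica_of_extruder", data=trace.replica_of_extruder)
        h5.create_dataset("replica_of_barrier", data=trace.replica_of_barrier)
        h5.attrs["n_sites"] = trace.n_sites
        h5.attrs["site_bp"] = trace.site_bp
        h5.attrs["n_replicas"] = trace.n_replicas
        h5.attrs["seed"] = trace.seed
        h5.attrs["config"] = json.dumps(trace.config)


def read_trace(path) -> LatticeTrace:
    with h5py.File(path, "r") as h5:
        return LatticeTrace(
            times=h5["times"][:],
            leg_positions=h5["leg_positions"][:],
            barrier_states=h5["barrier_states"][:],
            barrier_sites=h5["barrier_sites"][:],
            replica_of_extruder=h5["replica_of_extruder"][:],
            replica_of_barrier=h5["replica_of_barrier"][:],
            n_sites=int(h5.attrs["n_sites"]),
            site_bp=int(h5.attrs["site_bp"]),
            n_replicas=int(h5.attrs["n_replicas"]),
            seed=int(h5.attrs["seed"]),
            config=json.loads(h5.attrs["config"]),
        )


def write_conformations(confs: list[Conformation], path, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["n_frames"] = len(confs)
        h5.attrs["meta"] = json.dumps(meta or {})
        for k, conf in enumerate(confs):
            g = h5.create_group(f"frame_{k:06d}")
            g.create_dataset("coordinates", data=conf.coordinates,
                             compression="gzip")
            g.create_dataset("bonds", data=conf.bonds)
            g.attrs["frame_time"] = conf.frame_time


def read_conformations(path) -> list[Conformation]:
    out = []
    with h5py.File(path, "r") as h5:
        for k in range(int(h5.attrs["n_frames"])):
            g = h5[f"frame_{k:06d}"]
            out.append(
                Conformation(
                    coordinates=g["coordinates"][:],
                    frame_time=float(g.attrs["frame_time"]),
                    bonds=g["bonds"][:].reshape(-1, 2),
                )
            )
    return out


def write_map(cmap: ContactMap, path) -> None:
    np.savez_compressed(
        path,
        matrix=cmap.matrix,
        resolution=cmap.resolution,
        n_frames=cmap.n_frames,
        monomer_bp=cmap.monomer_bp,
    )


def read_map(path) -> ContactMap:
    with np.load(path) as z:
        return ContactMap(
            matrix=z["matrix"],
            resolution=int(z["resolution"]),
            n_frames=int(z["n_frames"]),
            monomer_bp=int(z["monomer_bp"]),
        )


def write_report(rows: dict, path) -> None:
    """Write a flat key/value TSV report (one row per key), sorted."""
    df = pd.DataFrame(sorted(rows.items()), columns=["key", "value"])
    df.to_csv(path, sep="\t", index=False)


def load_config(path, defaults: dict) -> dict:
    """Read a flat key-value (YAML mapping) config; unknown keys rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    unknown = set(data) - set(defaults)
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys: {', '.join(sorted(unknown))}"
        )
    resolved = dict(defaults)
    resolved.update(data)
    return resolved
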