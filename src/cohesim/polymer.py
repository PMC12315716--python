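"""Lightweight bead-spring polymer sampler coupled to lattice extruder traces.

Chromatin is a chain of monomers (2.5 kb each by default) in units of one
monomer diameter, evolved by overdamped Brownian dynamics (Euler-Maruyama,
kT = 1, unit friction) under three forces: harmonic backbone springs,
harmonic extruder bonds linking the coarse-grained positions of the two
legs of each extruder, and a soft excluded-volume repulsion that permits
strand passage (soft-core regime).  Extruder bonds are switched
instantaneously at each lattice frame and a configurable number of
relaxation steps follows each switch before a conformation is harvested.

This sampler targets ensemble contact statistics (contact maps and
morphology scores), not calibrated dynamics: simulated time is in units
of the monomer diffusion time and no mapping to wall-clock chromatin
dynamics is attempted.

Contacts are all monomer pairs closer than a capture radius (excluding
adjacent monomers); aggregated over frames and binned, they form the in
silico Hi-C contact map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .lattice import LatticeTrace

__all__ = [
    "PolymerConfig",
    "Conformation",
    "ContactMap",
    "ChainBreakError",
    "legs_to_bonds",
    "advance_polymer",
    "capture_contacts",
    "aggregate_map",
    "sample_conformations",
]


class ChainBreakError(RuntimeError):
    """Consecutive monomers separated by more than twice the bond rest
    length: integration instability.  Reduce ``dt_3d`` (or ``max_force``)."""


@dataclass
class PolymerConfig:
    """Parameters of the bead-spring sampler.

    Lengths are in monomer diameters (one monomer represents
    ``monomer_bp`` bp of a 50-nm chromatin fiber segment); times in units
    of the monomer diffusion time.
    """

    monomer_bp: int = 2_500
    bond_length: float = 1.0
    spring_k: float = 50.0
    excluded_volume_strength: float = 5.0
    dt_3d: float = 0.004
    steps_per_lattice_frame: int = 60
    equilibration_steps: int = 3_000
    capture_radius: float = 2.0
    bond_force_sat: float = 15.0
    max_force: float = 100.0
    neighbor_every: int = 5
    neighbor_skin: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capture_radius <= 0:
            raise ValueError("capture_radius must be positive")
        if self.bond_length <= 0 or self.dt_3d <= 0:
            raise ValueError("bond_length and dt_3d must be positive")


@dataclass
class Conformation:
    """One harvested 3D conformation.

    ``bonds`` are the extruder bonds (monomer index pairs) active in this
    frame, i.e. the coarse-grained legs of the corresponding lattice frame.
    """

    coordinates: np.ndarray
    frame_time: float
    bonds: np.ndarray  # (n_bonds, 2) int

    @property
    def n_monomers(self) -> int:
        return self.coordinates.shape[0]

    def extruder_monomers(self) -> np.ndarray:
        """Monomer indices occupied by bonded extruder legs."""
        if self.bonds.size == 0:
            return np.empty(0, dtype=np.int64)
        return self.bonds.ravel().astype(np.int64)


def legs_to_bonds(
    leg_positions: np.ndarray, site_bp: int, monomer_bp: int
) -> np.ndarray:
    """Coarse-grain extruder legs (lattice sites) to monomer bond pairs.

    Each extruder contributes one bond between
    ``floor(leg * site_bp / monomer_bp)`` monomer indices; bonds with both
    legs in the same monomer are dropped.
    """
    if monomer_bp % site_bp != 0:
        raise ValueError("monomer_bp must be an integer multiple of site_bp")
    legs = np.asarray(leg_positions, dtype=np.int64).reshape(-1, 2)
    mono = legs * site_bp // monomer_bp
    keep = mono[:, 0] != mono[:, 1]
    return mono[keep]


def _forces(
    coords: np.ndarray,
    bonds: np.ndarray,
    pairs: np.ndarray,
    config: PolymerConfig,
) -> np.ndarray:
    f = np.zeros_like(coords)
    r0 = config.bond_length
    k = config.spring_k
    # Backbone springs: harmonic near the rest length, stiffened 4x beyond
    # 1.5 r0 so that no bounded pull can stretch a link to the 2 r0
    # connectivity limit.
    d = coords[1:] - coords[:-1]
    r = np.linalg.norm(d, axis=1)
    ext = r - r0
    mag = np.where(ext <= 0.5 * r0, k * ext, k * 0.5 * r0 + 4.0 * k * (ext - 0.5 * r0))
    fb = (mag / np.maximum(r, 1e-12))[:, None] * d
    f[:-1] += fb
    f[1:] -= fb
    # Extruder bonds: saturating (pseudo-Huber) springs, so a bond switched
    # onto a distant monomer drags it at a bounded force the backbone can
    # sustain instead of yanking the chain apart.
    if bonds.size:
        i, j = bonds[:, 0], bonds[:, 1]
        d = coords[j] - coords[i]
        r = np.linalg.norm(d, axis=1)
        ext = r - r0
        w = config.bond_force_sat / k  # crossover extension
        mag = config.bond_force_sat * ext / np.sqrt(w * w + ext * ext)
        fb = (mag / np.maximum(r, 1e-12))[:, None] * d
        np.add.at(f, i, fb)
        np.add.at(f, j, -fb)
    # Soft excluded volume (linear repulsion below one diameter)
    if pairs.size and config.excluded_volume_strength > 0:
        i, j = pairs[:, 0], pairs[:, 1]
        d = coords[j] - coords[i]
        r = np.linalg.norm(d, axis=1)
        inside = r < r0
        if inside.any():
            i, j, d, r = i[inside], j[inside], d[inside], r[inside]
            mag = config.excluded_volume_strength * (1.0 - r / r0) / r0
            fr = (mag / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(f, i, -fr)
            np.add.at(f, j, fr)
    return f


def _check_chain(coords: np.ndarray, config: PolymerConfig) -> None:
    r = np.linalg.norm(coords[1:] - coords[:-1], axis=1)
    if (r >= 2.0 * config.bond_length).any():
        raise ChainBreakError(
            "chain connectivity violated (consecutive monomer distance >= "
            "2x bond rest length); reduce dt_3d"
        )


def advance_polymer(
    coords: np.ndarray,
    bonds: np.ndarray,
    config: PolymerConfig,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance the chain by ``n_steps`` of overdamped Brownian dynamics.

    Returns the updated coordinate array (modified in place).  Forces are
    capped at ``config.max_force`` per monomer so that instantaneous bond
    switches between distant monomers relax smoothly.  Raises
    :class:`ChainBreakError` if the backbone stretches beyond twice the
    rest length.
    """
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    dt = config.dt_3d
    noise_amp = np.sqrt(2.0 * dt)
    cutoff = config.bond_length + config.neighbor_skin
    pairs = np.empty((0, 2), dtype=np.int64)
    for step in range(n_steps):
        if config.excluded_volume_strength > 0 and step % config.neighbor_every == 0:
            tree = cKDTree(coords)
            pairs = tree.query_pairs(cutoff, output_type="ndarray")
        f = _forces(coords, bonds, pairs, config)
        fmag = np.linalg.norm(f, axis=1)
        over = fmag > config.max_force
        if over.any():
            f[over] *= (config.max_force / fmag[over])[:, None]
        coords += f * dt + noise_amp * rng.standard_normal(coords.shape)
    _check_chain(coords, config)
    return coords


def capture_contacts(coords: np.ndarray, capture_radius: float) -> np.ndarray:
    """All unordered monomer pairs with distance < capture radius,
    excluding the trivial |i - j| <= 1 neighbours.  Returns (n, 2) int."""
    if capture_radius <= 0:
        raise ValueError("capture_radius must be positive")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(capture_radius, output_type="ndarray")
    if pairs.size == 0:
        return pairs.reshape(0, 2)
    return pairs[np.abs(pairs[:, 0] - pairs[:, 1]) > 1]


@dataclass
class ContactMap:
    """Symmetric binned contact-count matrix."""

    matrix: np.ndarray
    resolution: int
    n_frames: int
    monomer_bp: int

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of_bp(self, pos_bp: float) -> int:
        return int(pos_bp // self.resolution)


def aggregate_map(
    conformations,
    resolution: int,
    monomer_bp: int,
    capture_radius: float,
    n_monomers: int | None = None,
) -> ContactMap:
    """Accumulate captured contacts from a conformation stream into a
    symmetric binned matrix (each contact increments both (i,j) and (j,i))."""
    conformations = list(conformations)
    if not conformations:
        raise ValueError("at least one conformation required")
    if n_monomers is None:
        n_monomers = conformations[0].n_monomers
    n_bins = -(-n_monomers * monomer_bp // resolution)
    mat = np.zeros((n_bins, n_bins), dtype=np.float64)
    for conf in conformations:
        pairs = capture_contacts(conf.coordinates, capture_radius)
        if pairs.size == 0:
            continue
        bins = pairs * monomer_bp // resolution
        np.add.at(mat, (bins[:, 0], bins[:, 1]), 1.0)
        np.add.at(mat, (bins[:, 1], bins[:, 0]), 1.0)
    return ContactMap(
        matrix=mat,
        resolution=resolution,
        n_frames=len(conformations),
        monomer_bp=monomer_bp,
    )


def _random_walk_init(n: int, step: float, rng: np.random.Generator) -> np.ndarray:
    steps = rng.standard_normal((n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    steps[0] = 0.0
    return np.cumsum(step * steps, axis=0)


def sample_conformations(
    trace: LatticeTrace,
    config: PolymerConfig,
    replica: int = 0,
    frame_stride: int = 1,
    max_frames: int | None = None,
    window_sites: tuple[int, int] | None = None,
) -> list[Conformation]:
    """Generate one 3D conformation per (strided) lattice frame.

    The chain covers one replica, or the ``window_sites = (start, stop)``
    sub-interval of it (useful when a long concatenated lattice is
    simulated and only a section is rendered in 3D; extruder bonds with a
    leg outside the window are dropped).  Extruder bonds for each frame
    are the coarse-grained leg positions of that frame; the chain is
    equilibrated under the first frame's bonds, then relaxed
    ``steps_per_lattice_frame`` steps after each bond switch before
    harvesting.  Deterministic given ``config.seed``.
    """
    if config.monomer_bp % trace.site_bp != 0:
        raise ValueError("monomer_bp must be a multiple of the lattice site_bp")
    cols = np.flatnonzero(trace.replica_of_extruder == replica)
    if cols.size == 0:
        raise ValueError(f"trace has no extruders for replica {replica}")
    frames = np.arange(0, trace.n_frames, frame_stride)
    if max_frames is not None:
        frames = frames[:max_frames]
    if frames.size == 0:
        raise ValueError("no frames selected")
    start, stop = window_sites if window_sites is not None else (0, trace.n_sites)
    if not (0 <= start < stop <= trace.n_sites):
        raise ValueError("window_sites outside the replica lattice")
    sites_per_monomer = config.monomer_bp // trace.site_bp
    if (stop - start) % sites_per_monomer != 0:
        raise ValueError("window length must be a whole number of monomers")
    n_monomers = (stop - start) * trace.site_bp // config.monomer_bp
    rng = np.random.default_rng(config.seed)
    coords = _random_walk_init(n_monomers, config.bond_length, rng)

    def frame_bonds(f: int) -> np.ndarray:
        legs = trace.leg_positions[f, cols]
        inside = (legs >= start).all(axis=1) & (legs < stop).all(axis=1)
        return legs_to_bonds(legs[inside] - start, trace.site_bp, config.monomer_bp)

    advance_polymer(
        coords, frame_bonds(frames[0]), config, config.equilibration_steps, rng
    )
    out: list[Conformation] = []
    for f in frames:
        bonds = frame_bonds(f)
        advance_polymer(coords, bonds, config, config.steps_per_lattice_frame, rng)
        out.append(
            Conformation(
                coordinates=coords.copy(),
                frame_time=float(trace.times[f]),
                bonds=bonds,
            )
        )
    return out
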