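"""Synthetic barrier layouts and conformation fixtures.

Layout generators emulate the reference setup of the simulations: 32
randomly positioned CTCF barriers per 2.5-Mb replica (mean spacing,
counting both end gaps, of 2.5 Mb / 33 ~ 75 kb), plus the simplified
two-barrier convergent layout used by the analytical loop-size model.
Morphology fixtures provide constructed 3D conformations (an axial
"vermicelli-like" chain and an equilibrium coil) as a test surface for
the vermicelli score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import BLOCKS_LEFT, BLOCKS_RIGHT, BarrierSite

__all__ = [
    "LayoutSpec",
    "random_layout",
    "convergent_pair",
    "morphology_fixtures",
]


@dataclass(frozen=True)
class LayoutSpec:
    """Specification of a random barrier layout.

    ``orientation_scheme`` is one of ``"random"`` (each barrier blocks
    rightward or leftward legs independently with probability 1/2),
    ``"alternating"``, or ``"all-convergent-pairs"`` (consecutive barriers
    paired facing inward).
    """

    region_bp: int = 2_500_000
    n_barriers: int = 32
    site_bp: int = 250
    orientation_scheme: str = "random"
    tau_b: float = 1_350.0
    tau_u: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_barriers < 0:
            raise ValueError("n_barriers must be >= 0")
        if self.orientation_scheme not in (
            "random",
            "alternating",
            "all-convergent-pairs",
        ):
            raise ValueError(
                f"unknown orientation_scheme {self.orientation_scheme!r}"
            )

    @property
    def n_sites(self) -> int:
        return self.region_bp // self.site_bp


def random_layout(spec: LayoutSpec) -> list[BarrierSite]:
    """Distinct uniform-random barrier positions; deterministic given seed."""
    n_sites = spec.n_sites
    if spec.n_barriers >= n_sites:
        raise ValueError(
            f"{spec.n_barriers} barriers do not fit on {n_sites} lattice sites"
        )
    rng = np.random.default_rng(spec.seed)
    sites = np.sort(rng.choice(n_sites, size=spec.n_barriers, replace=False))
    if spec.orientation_scheme == "random":
        orients = np.where(rng.random(spec.n_barriers) < 0.5, BLOCKS_RIGHT, BLOCKS_LEFT)
    elif spec.orientation_scheme == "alternating":
        orients = np.where(np.arange(spec.n_barriers) % 2 == 0, BLOCKS_LEFT, BLOCKS_RIGHT)
    else:  # all-convergent-pairs: (i even, i odd) pairs face inward
        orients = np.where(np.arange(spec.n_barriers) % 2 == 0, BLOCKS_LEFT, BLOCKS_RIGHT)
    return [
        BarrierSite(
            site=int(s),
            orientation=str(o),
            tau_b=spec.tau_b,
            tau_u=spec.tau_u,
        )
        for s, o in zip(sites, orients)
    ]


def layout_gaps_bp(layout: list[BarrierSite], region_bp: int, site_bp: int) -> np.ndarray:
    """Inter-barrier gaps in bp, including the two end gaps."""
    pos = np.sort(np.array([b.site for b in layout], dtype=np.int64)) * site_bp
    edges = np.concatenate([[0], pos, [region_bp]])
    return np.diff(edges)


def convergent_pair(
    delta: int,
    region_bp: int,
    site_bp: int = 250,
    tau_b: float = 1_350.0,
    tau_u: float = 150.0,
) -> list[BarrierSite]:
    """Two barriers centered in the region, ``delta`` bp apart, facing inward.

    The left barrier blocks leftward-moving legs and the right barrier
    blocks rightward-moving legs, so an extruder loaded between them is
    trapped (convergent-CTCF loop anchoring semantics).
    """
    if delta >= region_bp:
        raise ValueError("delta must be smaller than region_bp")
    if delta < 2 * site_bp:
        raise ValueError("delta must span at least 2 lattice sites")
    center = region_bp // site_bp // 2
    half = delta // site_bp // 2
    left_site = center - half
    right_site = left_site + delta // site_bp
    return [
        BarrierSite(site=left_site, orientation=BLOCKS_LEFT, tau_b=tau_b, tau_u=tau_u),
        BarrierSite(site=right_site, orientation=BLOCKS_RIGHT, tau_b=tau_b, tau_u=tau_u),
    ]


def morphology_fixtures(
    kind: str,
    n_monomers: int = 400,
    seed: int = 0,
) -> tuple[np.ndarray, list[int]]:
    """Constructed conformations for exercising the vermicelli score.

    ``"axial"``: the chain is wound as dense loops around a smooth central
    curve, with extruder monomers lying on the curve (the geometry of a
    condensed, cohesin-axis "vermicelli" chromosome).  ``"coil"``: an
    equilibrium random-walk chain with sparse random extruder monomers.
    Returns ``(coordinates, extruder_monomer_indices)``; coordinates are
    in monomer-diameter units.  Deterministic given seed.
    """
    if n_monomers < 100:
        raise ValueError("n_monomers must be >= 100")
    rng = np.random.default_rng(seed)
    if kind == "axial":
        loop_len = 20
        t = np.arange(n_monomers, dtype=float)
        axis_pos = t / loop_len  # slow drift along the axis
        phase = 2 * np.pi * (t % loop_len) / loop_len
        radius = 3.0
        coords = np.column_stack(
            [
                radius * np.cos(phase),
                radius * np.sin(phase),
                axis_pos,
            ]
        )
        # gentle curvature of the central curve
        coords[:, 0] += 2.0 * np.sin(axis_pos / 8.0)
        coords += 0.1 * rng.standard_normal(coords.shape)
        extruders = [int(i) for i in np.arange(0, n_monomers, loop_len)]
        # place extruder monomers on the axis itself
        for i in extruders:
            coords[i, 0] = 2.0 * np.sin(axis_pos[i] / 8.0)
            coords[i, 1] = 0.0
        return coords, extruders
    if kind == "coil":
        steps = rng.standard_normal((n_monomers, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.cumsum(steps, axis=0)
        extruders = sorted(
            int(i) for i in rng.choice(n_monomers, size=max(2, n_monomers // 50), replace=False)
        )
        return coords, extruders
    raise ValueError(f"unknown fixture kind {kind!r}")
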