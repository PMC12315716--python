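"""Shared runners for reference-scale simulations.

The map-level comparisons reuse one experimental procedure: a
concatenated 10-replica lattice (25 Mb, 100 extruders) carrying the
same 32-barrier layout tiled into each replica, coupled to bead-spring
polymer runs over two 2.5-Mb windows whose contact maps are pooled.
Session-scoped caching keeps each simulated condition to a single run
per test session.
"""

import warnings

import numpy as np
import pytest

import cohesim as cs

TAU_E_REF = 1_320.0
LEG_SPEED = 125.0
N_REP = 10
SITES_PER_REPLICA = 10_000
LAYOUT_SEED = 42


def occupancy_tau_u(tau_b: float, occupancy: float) -> float:
    return tau_b * (1.0 - occupancy) / occupancy


@pytest.fixture(scope="session")
def base_layout():
    """One 32-barrier random layout per 2.5-Mb replica (occupancy set per run)."""
    return cs.random_layout(
        cs.LayoutSpec(region_bp=2_500_000, n_barriers=32, site_bp=250,
                      tau_b=660.0, tau_u=occupancy_tau_u(660.0, 0.7),
                      seed=LAYOUT_SEED)
    )


def tiled_barriers(base_layout, tau_b, tau_u, bound=True):
    return [
        cs.BarrierSite(b.site + r * SITES_PER_REPLICA, b.orientation,
                       tau_b, tau_u, bound=bound)
        for r in range(N_REP)
        for b in base_layout
    ]


def run_tiled_lattice(barriers, tau_E, seed, n_frames, sample_every,
                      dt=0.5, leg_speed=LEG_SPEED):
    config = cs.LatticeConfig(
        n_sites=SITES_PER_REPLICA * N_REP, site_bp=250,
        extruder_separation=1_000, tau_E=tau_E, leg_speed=leg_speed,
        dt_lattice=dt, seed=seed,
    )
    duration = 3.0 * tau_E + sample_every * n_frames
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # coarse-dt warnings in fast-barrier runs
        return cs.run_lattice(config, barriers, duration=duration,
                              sample_every=sample_every)


def frip_of(trace, barriers):
    track = cs.accumulate_track(trace)
    return cs.frip(track, sorted({b.site for b in barriers}))


@pytest.fixture(scope="session")
def map_condition(base_layout):
    """Runner: (tau_b, tau_E, seed) -> dict of FRiP/insulation/dot scores.

    Lattice sampled every 40 s for 800 frames after a 3 tau_E burn-in;
    polymer over windows (0, 2.5 Mb) and (2.5, 5 Mb), 90 relaxation
    steps per frame, maps pooled at 10-kb resolution.  Results cached
    per parameter set for the whole session.
    """
    cache: dict = {}

    def run(tau_b: float, tau_E: float, seed: int = 7,
            occupancy: float = 0.7, n_frames: int = 800):
        key = (tau_b, tau_E, seed, occupancy, n_frames)
        if key in cache:
            return cache[key]
        tau_u = occupancy_tau_u(tau_b, occupancy)
        barriers = tiled_barriers(base_layout, tau_b, tau_u)
        trace = run_tiled_lattice(barriers, tau_E, seed, n_frames, 40.0)
        mats = []
        for wi, (a, b) in enumerate([(0, 10_000), (10_000, 20_000)]):
            pconfig = cs.PolymerConfig(
                seed=seed + 1 + wi, steps_per_lattice_frame=90,
                equilibration_steps=4_000,
            )
            confs = cs.sample_conformations(
                trace, pconfig, frame_stride=1, max_frames=n_frames,
                window_sites=(a, b),
            )
            mats.append(cs.aggregate_map(confs, 10_000, 2_500, 2.0).matrix)
        cmap = cs.ContactMap(mats[0] + mats[1], 10_000, 2 * n_frames, 2_500)
        w = 5
        bins = sorted({
            b.site * 250 // 10_000 for b in base_layout
            if w <= b.site * 250 // 10_000 < cmap.n_bins - w
        })
        insulation, _ = cs.insulation_score(cmap, bins, 50_000)
        pairs = cs.convergent_pairs_bp(base_layout, 250)
        profile = cs.dot_profile(cmap, pairs)
        result = {
            "frip": frip_of(trace, barriers),
            "insulation": insulation,
            "mean_dot": cs.mean_dot_score(profile),
            "map": cmap,
        }
        cache[key] = result
        return result

    return run
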