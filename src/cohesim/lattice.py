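"""1D lattice simulation of loop extruders with dynamic CTCF barriers.

Chromatin is a lattice of ``n_sites`` sites of ``site_bp`` bp each (250 bp
by default, fine enough to resolve CTCF exchange that is rapid relative to
the extruder lifetime).  Loop extruders are two-legged agents whose legs
translocate outward with a fixed per-update Bernoulli step probability
``leg_speed * dt / site_bp``; extruders unbind with probability
``dt / tau_E`` per update and instantly reload at a random free adjacent
site pair, keeping the extruder count fixed at
``n_sites // extruder_separation``.  CTCF barrier sites are telegraph
processes (bound dwell ``tau_b``, unbound dwell ``tau_u``) that, while
bound, block legs travelling in one direction.

Blocking semantics: a leg may step *onto* a barrier site from either side;
while the barrier is bound it cannot step *past* it in the blocked
direction, so stalled legs rest exactly on barrier sites.  When the
barrier unbinds, the stalled leg resumes on its next successful step.
Rebinding is unconditional on extruder positions (CTCF can rebind inside
an extruded loop).

Update order per timestep: (1) barrier flips, (2) extruder unbinding and
reloading, (3) leg steps in random order over legs.  Replicas are
independent lattices with impassable ends, simulated with per-replica RNG
substreams of one master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BarrierSite",
    "LatticeConfig",
    "LatticeState",
    "LatticeTrace",
    "InvalidTimestepError",
    "DensityError",
    "EmptyTraceError",
    "step_barriers",
    "step_extruders",
    "recycle_extruders",
    "run_lattice",
]

#: Orientation value for a barrier that blocks rightward-moving legs.
BLOCKS_RIGHT = "+"
#: Orientation value for a barrier that blocks leftward-moving legs.
BLOCKS_LEFT = "-"


class InvalidTimestepError(ValueError):
    """A per-update probability dt/tau exceeds 1."""


class DensityError(RuntimeError):
    """No free adjacent site pair is available to reload an extruder."""


class EmptyTraceError(ValueError):
    """Requested duration leaves no samples after the burn-in."""


@dataclass
class BarrierSite:
    """A dynamic CTCF barrier on the lattice.

    Parameters
    ----------
    site : 0-based lattice index.
    orientation : ``"+"`` blocks rightward-moving legs, ``"-"`` blocks
        leftward-moving legs (matching the BED strand convention of the
        barrier-layout files).
    tau_b : mean bound time (s), > 0.
    tau_u : mean unbound time (s), >= 0; 0 means permanently bound.
    bound : current state; evolves only via :func:`step_barriers`.
    """

    site: int
    orientation: str
    tau_b: float
    tau_u: float
    bound: bool = True

    def __post_init__(self) -> None:
        if self.orientation not in (BLOCKS_RIGHT, BLOCKS_LEFT):
            raise ValueError(
                f"orientation must be '+' (blocks rightward legs) or "
                f"'-' (blocks leftward legs), got {self.orientation!r}"
            )
        if self.tau_b <= 0:
            raise ValueError("tau_b must be positive")
        if self.tau_u < 0:
            raise ValueError("tau_u must be non-negative")

    @property
    def occupancy(self) -> float:
        return self.tau_b / (self.tau_b + self.tau_u)


@dataclass
class LatticeConfig:
    """Configuration of one lattice run (all replicas).

    ``n_sites`` is the per-replica lattice length.  ``leg_speed`` is the
    translocation rate of a single leg in bp/s, so the total loop growth
    rate is ``2 * leg_speed``.  ``dt_lattice`` should resolve the fastest
    process: a warning is issued if any of ``tau_b``, ``tau_u`` or
    ``tau_E`` is below ``10 * dt_lattice``.
    """

    n_sites: int = 10_000
    site_bp: int = 250
    n_replicas: int = 1
    extruder_separation: int = 1_000
    tau_E: float = 1_320.0
    leg_speed: float = 125.0
    dt_lattice: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.extruder_separation < 2:
            raise ValueError("extruder_separation must be >= 2")
        if self.n_sites // self.extruder_separation < 1:
            raise ValueError("extruder_separation leaves no extruders")
        if self.tau_E <= 0 or self.leg_speed <= 0 or self.dt_lattice <= 0:
            raise ValueError("tau_E, leg_speed and dt_lattice must be positive")

    @property
    def n_extruders(self) -> int:
        """Extruders per replica (count is conserved by instant reloading)."""
        return self.n_sites // self.extruder_separation

    @property
    def step_probability(self) -> float:
        return self.leg_speed * self.dt_lattice / self.site_bp

    def validate_timestep(self, barriers: list[BarrierSite]) -> None:
        """Raise on invalid per-update probabilities; warn on coarse dt."""
        dt = self.dt_lattice
        if self.step_probability > 1.0:
            raise InvalidTimestepError(
                f"leg step probability {self.step_probability:.3g} > 1; "
                "reduce dt_lattice or leg_speed"
            )
        if dt / self.tau_E > 1.0:
            raise InvalidTimestepError("dt_lattice/tau_E > 1")
        fastest = self.tau_E
        for b in barriers:
            if dt / b.tau_b > 1.0 or (b.tau_u > 0 and dt / b.tau_u > 1.0):
                raise InvalidTimestepError(
                    f"barrier at site {b.site}: dt/tau exceeds 1"
                )
            fastest = min(fastest, b.tau_b, b.tau_u if b.tau_u > 0 else np.inf)
        if dt > fastest / 10.0:
            warnings.warn(
                f"dt_lattice={dt} is coarse for the fastest timescale "
                f"{fastest:.3g} s (flip probability > 0.1 per update)",
                stacklevel=2,
            )


@dataclass
class LatticeState:
    """Mutable simulation state of a single replica (array-of-struct layout)."""

    n_sites: int
    # Barriers
    b_site: np.ndarray
    b_blocks_right: np.ndarray
    b_tau_b: np.ndarray
    b_tau_u: np.ndarray
    b_bound: np.ndarray
    # Extruders
    left: np.ndarray
    right: np.ndarray
    stalled_left: np.ndarray
    stalled_right: np.ndarray
    # Site occupancy by legs and barrier lookup
    occupied: np.ndarray
    barrier_at: np.ndarray
    # Loop sizes (in sites) recorded at each extruder unbinding event
    unbind_loop_sizes: list[int] = field(default_factory=list)

    @classmethod
    def create(
        cls,
        config: LatticeConfig,
        barriers: list[BarrierSite],
        rng: np.random.Generator,
    ) -> "LatticeState":
        n = config.n_sites
        b_site = np.array([b.site for b in barriers], dtype=np.int64)
        if b_site.size and (b_site.min() < 0 or b_site.max() >= n):
            raise ValueError("barrier site outside lattice")
        if b_site.size != np.unique(b_site).size:
            raise ValueError("barrier sites must be distinct")
        barrier_at = np.full(n, -1, dtype=np.int64)
        barrier_at[b_site] = np.arange(b_site.size)
        state = cls(
            n_sites=n,
            b_site=b_site,
            b_blocks_right=np.array(
                [b.orientation == BLOCKS_RIGHT for b in barriers], dtype=bool
            ),
            b_tau_b=np.array([b.tau_b for b in barriers], dtype=float),
            b_tau_u=np.array([b.tau_u for b in barriers], dtype=float),
            b_bound=np.array([b.bound for b in barriers], dtype=bool),
            left=np.zeros(config.n_extruders, dtype=np.int64),
            right=np.zeros(config.n_extruders, dtype=np.int64),
            stalled_left=np.zeros(config.n_extruders, dtype=bool),
            stalled_right=np.zeros(config.n_extruders, dtype=bool),
            occupied=np.zeros(n, dtype=bool),
            barrier_at=barrier_at,
        )
        for e in range(config.n_extruders):
            state._load_extruder(e, rng)
        return state

    def _load_extruder(self, e: int, rng: np.random.Generator) -> None:
        """Place extruder ``e`` on a uniformly chosen free adjacent site pair."""
        free = ~self.occupied
        pairs = np.flatnonzero(free[:-1] & free[1:])
        if pairs.size == 0:
            raise DensityError(
                "no free adjacent site pair available for extruder reloading; "
                "lattice too dense (reduce extruder count or enlarge lattice)"
            )
        s = int(pairs[rng.integers(pairs.size)])
        self.left[e] = s
        self.right[e] = s + 1
        self.occupied[s] = True
        self.occupied[s + 1] = True
        self.stalled_left[e] = False
        self.stalled_right[e] = False

    @property
    def loop_sizes(self) -> np.ndarray:
        """Current loop sizes in lattice sites (right - left)."""
        return self.right - self.left


def step_barriers(barriers, dt: float, rng: np.random.Generator):
    """Advance every barrier's telegraph state by one update of length ``dt``.

    Bound barriers unbind with probability ``dt/tau_b``; unbound barriers
    rebind with probability ``dt/tau_u`` (unconditional on extruder
    positions).  ``tau_u = 0`` barriers never unbind.  Accepts either a
    :class:`LatticeState` or a list of :class:`BarrierSite` (updated in
    place); returns the new bound-state array.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(barriers, LatticeState):
        state = barriers
        tau_b, tau_u, bound = state.b_tau_b, state.b_tau_u, state.b_bound
    else:
        state = None
        tau_b = np.array([b.tau_b for b in barriers], dtype=float)
        tau_u = np.array([b.tau_u for b in barriers], dtype=float)
        bound = np.array([b.bound for b in barriers], dtype=bool)
    if bound.size == 0:
        return bound
    p_unbind = dt / tau_b
    with np.errstate(divide="ignore"):
        p_bind = np.where(tau_u > 0, dt / np.where(tau_u > 0, tau_u, 1.0), 1.0)
    if (p_unbind > 1).any() or (p_bind > 1).any():
        raise InvalidTimestepError("dt/tau exceeds 1 for at least one barrier")
    u = rng.random(bound.size)
    flip = np.where(bound, (u < p_unbind) & (tau_u > 0), u < p_bind)
    new_bound = bound ^ flip
    if state is not None:
        state.b_bound = new_bound
    else:
        for b, nb in zip(barriers, new_bound):
            b.bound = bool(nb)
    return new_bound


def step_extruders(
    state: LatticeState, config: LatticeConfig, rng: np.random.Generator
) -> None:
    """Attempt one outward Bernoulli step per leg, in random leg order.

    A step is refused (silently; the stall flag is set) when the
    destination is outside the replica, occupied by another leg, or when
    the leg currently rests on a bound barrier oriented against its
    direction of travel.  Previously stalled legs retry automatically.
    """
    p = config.step_probability
    n_legs = 2 * state.left.size
    if n_legs == 0:
        return
    order = rng.permutation(n_legs)
    fire = rng.random(n_legs) < p
    left, right = state.left, state.right
    occupied, barrier_at = state.occupied, state.barrier_at
    b_bound, b_blocks_right = state.b_bound, state.b_blocks_right
    for k in order[fire[order]]:
        e = k >> 1
        if k & 1:  # right leg, moves +1
            x = right[e]
            y = x + 1
            if y >= state.n_sites or occupied[y]:
                state.stalled_right[e] = True
                continue
            bi = barrier_at[x]
            if bi >= 0 and b_bound[bi] and b_blocks_right[bi]:
                state.stalled_right[e] = True
                continue
            occupied[x] = False
            occupied[y] = True
            right[e] = y
            state.stalled_right[e] = False
        else:  # left leg, moves -1
            x = left[e]
            y = x - 1
            if y < 0 or occupied[y]:
                state.stalled_left[e] = True
                continue
            bi = barrier_at[x]
            if bi >= 0 and b_bound[bi] and not b_blocks_right[bi]:
                state.stalled_left[e] = True
                continue
            occupied[x] = False
            occupied[y] = True
            left[e] = y
            state.stalled_left[e] = False


def recycle_extruders(
    state: LatticeState, config: LatticeConfig, rng: np.random.Generator
) -> None:
    """Unbind each extruder with probability ``dt/tau_E`` and reload it.

    Reloading is instantaneous and uniform over all adjacent pairs of
    currently unoccupied sites, so the extruder count is conserved.  The
    loop size (in sites) at each unbinding is appended to
    ``state.unbind_loop_sizes``.
    """
    p = config.dt_lattice / config.tau_E
    dies = rng.random(state.left.size) < p
    for e in np.flatnonzero(dies):
        state.unbind_loop_sizes.append(int(state.right[e] - state.left[e]))
        state.occupied[state.left[e]] = False
        state.occupied[state.right[e]] = False
        state._load_extruder(e, rng)


@dataclass
class LatticeTrace:
    """Sampled time series of extruder leg positions and barrier states.

    ``leg_positions`` has shape ``(n_frames, n_extruders_total, 2)`` with
    replica-local lattice indices (left, right); ``barrier_states`` has
    shape ``(n_frames, n_barriers_total)``.  ``replica_of_extruder`` and
    ``replica_of_barrier`` map columns to replicas; all replicas share the
    same barrier layout (``barrier_sites`` repeats per replica).
    """

    times: np.ndarray
    leg_positions: np.ndarray
    barrier_states: np.ndarray
    barrier_sites: np.ndarray
    replica_of_extruder: np.ndarray
    replica_of_barrier: np.ndarray
    n_sites: int
    site_bp: int
    n_replicas: int
    seed: int
    config: dict

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_extruders(self) -> int:
        return self.leg_positions.shape[1]


def _run_replica(
    config: LatticeConfig,
    barriers: list[BarrierSite],
    n_burn_updates: int,
    n_frames: int,
    updates_per_sample: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, LatticeState]:
    state = LatticeState.create(config, barriers, rng)
    legs = np.empty((n_frames, state.left.size, 2), dtype=np.int32)
    bstates = np.empty((n_frames, state.b_bound.size), dtype=bool)

    def update() -> None:
        step_barriers(state, config.dt_lattice, rng)
        recycle_extruders(state, config, rng)
        step_extruders(state, config, rng)

    for _ in range(n_burn_updates):
        update()
    for f in range(n_frames):
        if f > 0:
            for _ in range(updates_per_sample):
                update()
        legs[f, :, 0] = state.left
        legs[f, :, 1] = state.right
        bstates[f] = state.b_bound
    return legs, bstates, state


def run_lattice(
    config: LatticeConfig,
    barriers: list[BarrierSite],
    duration: float,
    sample_every: float,
    burn_in: float | None = None,
) -> LatticeTrace:
    """Run the lattice simulation and return a sampled steady-state trace.

    The same barrier layout is instantiated in each of
    ``config.n_replicas`` independent replicas (reflecting ends, separate
    RNG substreams derived from ``config.seed``).  Sampling starts after
    ``burn_in`` (default ``3 * tau_E``) and records a frame every
    ``sample_every`` seconds up to ``duration``.  Deterministic given the
    seed.
    """
    if burn_in is None:
        burn_in = 3.0 * config.tau_E
    if sample_every <= 0:
        raise ValueError("sample_every must be positive")
    if duration < burn_in:
        raise EmptyTraceError(
            f"duration {duration} s is shorter than the burn-in {burn_in} s; "
            "no steady-state frames would be recorded"
        )
    config.validate_timestep(barriers)
    dt = config.dt_lattice
    n_burn = int(round(burn_in / dt))
    ups = max(1, int(round(sample_every / dt)))
    n_frames = int((duration - burn_in) / sample_every) + 1

    all_legs, all_bstates = [], []
    for r in range(config.n_replicas):
        rng = np.random.default_rng([config.seed, r])
        legs, bstates, _ = _run_replica(config, barriers, n_burn, n_frames, ups, rng)
        all_legs.append(legs)
        all_bstates.append(bstates)

    n_ext = config.n_extruders
    n_bar = len(barriers)
    times = burn_in + ups * dt * np.arange(n_frames)
    return LatticeTrace(
        times=times,
        leg_positions=np.concatenate(all_legs, axis=1),
        barrier_states=np.concatenate(all_bstates, axis=1),
        barrier_sites=np.tile(
            np.array([b.site for b in barriers], dtype=np.int64), config.n_replicas
        ),
        replica_of_extruder=np.repeat(np.arange(config.n_replicas), n_ext),
        replica_of_barrier=np.repeat(np.arange(config.n_replicas), n_bar),
        n_sites=config.n_sites,
        site_bp=config.site_bp,
        n_replicas=config.n_replicas,
        seed=config.seed,
        config=vars(config).copy(),
    )
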