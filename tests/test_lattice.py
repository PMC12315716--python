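"""Lattice extrusion dynamics: telegraph barriers, leg stepping, recycling."""

import numpy as np
import pytest

from cohesim.analytical import RegimeParams, expected_loop_size
from cohesim.lattice import (
    BarrierSite,
    EmptyTraceError,
    InvalidTimestepError,
    LatticeConfig,
    LatticeState,
    recycle_extruders,
    run_lattice,
    step_barriers,
    step_extruders,
)


def make_state(config, barriers, seed=0):
    rng = np.random.default_rng(seed)
    return LatticeState.create(config, barriers, rng), rng


class TestBarrierTelegraph:
    def test_tau_u_zero_stays_bound_forever(self):
        b = BarrierSite(site=5, orientation="+", tau_b=10.0, tau_u=0.0)
        rng = np.random.default_rng(0)
        for _ in range(2000):
            step_barriers([b], dt=1.0, rng=rng)
        assert b.bound

    def test_symmetric_rates_give_half_occupancy(self):
        # tau_b = tau_u = 4 s at dt = 0.4: the discrete two-state chain has
        # stationary bound fraction exactly 0.5; the time average over
        # 1e6 barrier-updates must match within Monte-Carlo error.
        barriers = [
            BarrierSite(site=i, orientation="+", tau_b=4.0, tau_u=4.0)
            for i in range(100)
        ]
        rng = np.random.default_rng(1)
        n_updates = 10_000
        total = 0
        for _ in range(n_updates):
            total += int(step_barriers(barriers, dt=0.4, rng=rng).sum())
        frac = total / (n_updates * len(barriers))
        # correlation time tau_c = (1/tau_b + 1/tau_u)^-1 = 2 s per barrier
        se = np.sqrt(2 * 0.25 * 2.0 / (n_updates * 0.4 * len(barriers)))
        assert abs(frac - 0.5) < 4 * se

    def test_reference_occupancy_0p9(self):
        # tau_b = 1350 s, tau_u = 150 s: stationary bound fraction 0.9.
        barriers = [
            BarrierSite(site=i, orientation="-", tau_b=1350.0, tau_u=150.0)
            for i in range(50)
        ]
        rng = np.random.default_rng(2)
        total = 0
        n_updates = 20_000
        for _ in range(n_updates):
            total += int(step_barriers(barriers, dt=5.0, rng=rng).sum())
        frac = total / (n_updates * len(barriers))
        tau_c = 1.0 / (1 / 1350.0 + 1 / 150.0)
        se = np.sqrt(2 * 0.9 * 0.1 * tau_c / (n_updates * 5.0 * len(barriers)))
        assert abs(frac - 0.9) < 4 * se

    def test_invalid_timestep_rejected(self):
        b = BarrierSite(site=0, orientation="+", tau_b=0.5, tau_u=1.0)
        with pytest.raises(InvalidTimestepError):
            step_barriers([b], dt=1.0, rng=np.random.default_rng(0))


class TestLegStepping:
    def cfg(self, **kw):
        kw.setdefault("n_sites", 100)
        kw.setdefault("extruder_separation", 100)
        kw.setdefault("site_bp", 250)
        kw.setdefault("leg_speed", 250.0)  # step probability 1 at dt=1
        kw.setdefault("dt_lattice", 1.0)
        kw.setdefault("tau_E", 1e9)
        return LatticeConfig(**kw)

    def test_unimpeded_growth_two_sites_per_update(self):
        config = self.cfg()
        state, rng = make_state(config, [])
        state.left[0], state.right[0] = 50, 51
        state.occupied[:] = False
        state.occupied[[50, 51]] = True
        for k in range(1, 11):
            step_extruders(state, config, rng)
            assert state.right[0] - state.left[0] == 1 + 2 * k

    def test_leg_rests_on_barrier_then_blocked(self):
        # A rightward leg may step ONTO a bound blocking barrier but not
        # past it while bound; it resumes when the barrier unbinds.
        config = self.cfg()
        barrier = BarrierSite(site=60, orientation="+", tau_b=1e9, tau_u=1.0)
        state, rng = make_state(config, [barrier])
        state.left[0], state.right[0] = 50, 58
        state.occupied[:] = False
        state.occupied[[50, 58]] = True
        for _ in range(5):
            step_extruders(state, config, rng)
        assert state.right[0] == 60  # resting on the barrier site
        assert state.stalled_right[0]
        state.b_bound[0] = False
        step_extruders(state, config, rng)
        assert state.right[0] == 61
        assert not state.stalled_right[0]

    def test_nonblocking_side_passes_freely(self):
        # Unidirectionality: a barrier blocking rightward legs does not
        # impede a leftward-moving leg.
        config = self.cfg()
        barrier = BarrierSite(site=40, orientation="+", tau_b=1e9, tau_u=1.0)
        state, rng = make_state(config, [barrier])
        state.left[0], state.right[0] = 45, 90
        state.occupied[:] = False
        state.occupied[[45, 90]] = True
        for _ in range(10):
            step_extruders(state, config, rng)
        assert state.left[0] == 35  # passed through site 40

    def test_facing_legs_do_not_bypass(self):
        config = self.cfg(extruder_separation=50)  # two extruders
        state, rng = make_state(config, [])
        state.left[:] = [10, 31]
        state.right[:] = [30, 60]
        state.occupied[:] = False
        state.occupied[[10, 30, 31, 60]] = True
        for _ in range(5):
            step_extruders(state, config, rng)
        # facing legs at 30/31 cannot advance; outer legs keep moving
        assert state.right[0] == 30 and state.left[1] == 31
        assert state.stalled_right[0] and state.stalled_left[1]


class TestRecycling:
    def test_count_conserved_and_loops_recorded(self):
        config = LatticeConfig(
            n_sites=1000, extruder_separation=100, tau_E=10.0,
            leg_speed=125.0, dt_lattice=0.5,
        )
        state, rng = make_state(config, [])
        for _ in range(2000):
            recycle_extruders(state, config, rng)
            step_extruders(state, config, rng)
            assert state.occupied.sum() == 2 * config.n_extruders
            assert (state.left <= state.right).all()
        assert len(state.unbind_loop_sizes) > 500

    def test_mean_realized_lifetime_matches_tau_E(self):
        # Residence time of the memoryless unbinding: mean over many
        # extruder generations approaches tau_E.
        config = LatticeConfig(
            n_sites=2000, extruder_separation=20, tau_E=50.0,
            leg_speed=0.1, dt_lattice=1.0,
        )
        state, rng = make_state(config, [])
        n_ext = config.n_extruders
        born = np.zeros(n_ext)
        durations = []
        p = config.dt_lattice / config.tau_E
        t = 0.0
        for _ in range(20_000):
            t += config.dt_lattice
            dies = rng.random(n_ext) < p
            for e in np.flatnonzero(dies):
                durations.append(t - born[e])
                born[e] = t
        mean = np.mean(durations)
        se = np.std(durations) / np.sqrt(len(durations))
        assert len(durations) > 10_000
        assert abs(mean - config.tau_E) < 4 * se + config.dt_lattice


class TestRunLattice:
    def test_deterministic_given_seed(self):
        config = LatticeConfig(
            n_sites=500, extruder_separation=100, tau_E=100.0, dt_lattice=0.5,
            seed=9,
        )
        bars = [BarrierSite(site=250, orientation="+", tau_b=100.0, tau_u=20.0)]
        t1 = run_lattice(config, bars, duration=800.0, sample_every=2.0)
        t2 = run_lattice(config, bars, duration=800.0, sample_every=2.0)
        assert np.array_equal(t1.leg_positions, t2.leg_positions)
        assert np.array_equal(t1.barrier_states, t2.barrier_states)

    def test_duration_shorter_than_burn_in_rejected(self):
        config = LatticeConfig(n_sites=500, extruder_separation=100, tau_E=100.0)
        with pytest.raises(EmptyTraceError):
            run_lattice(config, [], duration=100.0, sample_every=1.0)

    def test_legs_confined_and_count_constant(self):
        config = LatticeConfig(
            n_sites=400, extruder_separation=40, tau_E=50.0, dt_lattice=0.5,
            n_replicas=2, seed=3,
        )
        trace = run_lattice(config, [], duration=500.0, sample_every=5.0)
        assert trace.leg_positions.shape[1] == 2 * config.n_extruders
        assert trace.leg_positions.min() >= 0
        assert trace.leg_positions.max() < config.n_sites
        assert (trace.leg_positions[:, :, 0] <= trace.leg_positions[:, :, 1]).all()

    def test_no_barrier_steady_state_loop_size(self):
        # Sparse extruders: mean steady-state loop ~ 2 * leg_speed * tau_E
        # (the stationary-age mean of the exponential lifetime).
        config = LatticeConfig(
            n_sites=20_000, extruder_separation=2_000, tau_E=300.0,
            leg_speed=125.0, dt_lattice=0.5, seed=4,
        )
        trace = run_lattice(config, [], duration=30_000.0, sample_every=10.0)
        loops_bp = (
            (trace.leg_positions[:, :, 1] - trace.leg_positions[:, :, 0])
            * config.site_bp
        )
        expect = 2 * config.leg_speed * config.tau_E
        assert loops_bp.mean() == pytest.approx(expect, rel=0.12)

    def test_transient_barriers_leave_uniform_background(self):
        # tau_b << tau_E: leg accumulation at barrier sites approaches the
        # no-barrier uniform background (within 3x).
        config = LatticeConfig(
            n_sites=2_000, extruder_separation=200, tau_E=600.0,
            leg_speed=125.0, dt_lattice=0.2, seed=5,
        )
        # Transparency requires unbound windows longer than the per-site
        # stepping timescale (site_bp / leg_speed = 2 s here), so it is
        # probed at occupancy 0.5 (tau_u = tau_b = 2 s << tau_E).
        bars = [
            BarrierSite(site=s, orientation="+", tau_b=2.0, tau_u=2.0)
            for s in range(100, 2000, 200)
        ]
        trace = run_lattice(config, bars, duration=6_000.0, sample_every=2.0)
        counts = np.bincount(trace.leg_positions.ravel(), minlength=2000)
        at_barriers = counts[[b.site for b in bars]].mean()
        background = counts.mean()
        assert at_barriers < 3 * background


class TestAnalyticalEquivalence:
    def test_single_extruder_between_convergent_barriers(self):
        """Discrete-lattice loop sizes at unbinding reproduce the
        closed-form expectation for one extruder between two convergent
        dynamic barriers (midpoint loading)."""
        site_bp = 250
        tau_E, tau_b, tau_u = 120.0, 60.0, 30.0
        leg_speed, dt = 125.0, 0.5
        delta_sites = 60  # 15 kb; delta/v = 30 s < tau_E
        n_sites = 2_000
        mid = n_sites // 2
        left_site = mid - delta_sites // 2
        right_site = left_site + delta_sites
        config = LatticeConfig(
            n_sites=n_sites, extruder_separation=n_sites, tau_E=tau_E,
            leg_speed=leg_speed, dt_lattice=dt,
        )
        barriers = [
            BarrierSite(site=left_site, orientation="-", tau_b=tau_b, tau_u=tau_u),
            BarrierSite(site=right_site, orientation="+", tau_b=tau_b, tau_u=tau_u),
        ]
        rng = np.random.default_rng(17)
        loops = []
        p_die = dt / tau_E
        for _ in range(800):
            state = LatticeState.create(config, barriers, rng)
            # midpoint loading; stationary barrier states
            state.occupied[:] = False
            state.left[0], state.right[0] = mid, mid + 1
            state.occupied[[mid, mid + 1]] = True
            occ = tau_b / (tau_b + tau_u)
            state.b_bound[:] = rng.random(2) < occ  # stationary start
            while rng.random() >= p_die:
                step_barriers(state, dt, rng)
                step_extruders(state, config, rng)
            loops.append((state.right[0] - state.left[0]) * site_bp)
        params = RegimeParams(
            tau_E=tau_E, tau_b=tau_b, tau_u=tau_u,
            delta=delta_sites * site_bp, v=2 * leg_speed,
        )
        expected = expected_loop_size(params)
        mean = np.mean(loops)
        sem = np.std(loops) / np.sqrt(len(loops))
        assert abs(mean - expected) < 3 * sem + 0.05 * expected
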