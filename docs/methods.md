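# Methods

`cohesim` models interphase genome folding by cohesin loop extrusion
limited by *dynamic* CTCF barriers — barrier sites that stochastically
exchange between bound and unbound states rather than acting as fixed
walls — and computes the observables used to confront such models with
genomic and imaging data: in silico ChIP-seq and FRiP, Hi-C-style
contact maps with insulation and convergent-dot scores, and the
vermicelli morphology score.

## 1. Lattice model of extrusion with telegraph barriers

Chromatin is a 1D lattice of 250-bp sites.  Each CTCF barrier site is an
independent telegraph process: bound dwells are exponential with mean
τ_b, unbound dwells exponential with mean τ_u, giving stationary
occupancy

    o = τ_b / (τ_b + τ_u).

While bound, a barrier blocks extruder legs travelling in one direction
(its orientation); rebinding is unconditional on extruder positions.

Loop extruders are two-legged agents.  Each leg steps outward with
Bernoulli probability `leg_speed · dt / site_bp` per update; extruders
unbind with probability `dt/τ_E` per update and instantly reload on a
uniformly chosen pair of adjacent unoccupied sites, so the extruder
count is fixed at `n_sites / extruder_separation`.  A leg may step onto
a barrier site from either side but cannot step past it in the blocked
direction while the barrier is bound, so *stalled legs rest exactly on
barrier sites*; this makes the FRiP statistic parameter-free.  Legs
refuse steps onto occupied sites (no extruder–extruder bypass).  Update
order per timestep: barrier flips, extruder recycling, leg steps in
random order over legs (removing systematic left/right bias).

### Reference parameters

| parameter | default | basis |
|---|---|---|
| site size | 250 bp | fine enough to resolve rapid CTCF exchange |
| replica length | 2.5 Mb (10,000 sites) | reference region size |
| extruder separation | 250 kb (1,000 sites) | reference density |
| τ_E | 1,320 s (22 min) | cohesin FRAP residence time in mESCs |
| leg_speed | 125 bp/s per leg (v = 250 bp/s total) | see below |
| dt_lattice | 0.5 s | fastest default process ≥ 10·dt |
| barriers | 32 per 2.5 Mb, uniform random, random orientation | ~75-kb mean spacing |
| reference barrier | τ_b = 1,350 s, τ_u = 150 s (o = 0.9) | high-occupancy CTCF site |

The extrusion speed is not fixed by published point estimates, so it is
a calibrated choice: `leg_speed = 125 bp/s` gives an unimpeded
processivity v·τ_E = 330 kb, within the experimentally estimated range
for cohesin and of the same order as the extruder separation.  This
calibration also reproduces the reference phenomenology the model is
meant to exhibit — pronounced ChIP peaks and TADs for long-lived
high-occupancy barriers, their disappearance for transient barriers at
the same occupancy, and condensation into a vermicelli morphology when
the lifetime is raised sevenfold with transient barriers.

### Replica geometry

Reference runs use *consecutive* replicas: one concatenated lattice
(e.g. 10 × 2.5 Mb = 100,000 sites) carrying the same 32-barrier layout
tiled into each replica, with a single pair of impassable ends.  We
measured that small isolated lattices distort long-lifetime statistics:
with 2 reflecting ends per 20 legs, 10–17 % of legs end up parked at
the boundaries, which is enough to reverse lifetime trends in FRiP.  In
the concatenated geometry the ends hold ≲1 % of legs.  `run_lattice`
still supports independent replicas (`n_replicas > 1`) for strict
confinement studies.

Within the fixed-timestep scheme, a leg waiting at a flickering barrier
passes during an unbound window with probability ≈ 1 − exp(−ν·τ_u),
where ν = leg_speed/site_bp is the stepping rate.  When τ_u falls below
1/ν (≈2 s at the default speed), even nominally "transient" barriers
accumulate legs several-fold over background, because legs miss the
unbound windows.  This is a property of finite stepping rates, not of
the integrator; transparency of transient barriers holds when
τ_u ≫ 1/ν.

## 2. Closed-form loop size between convergent dynamic barriers

For one extruder loaded at the midpoint between two convergent barriers
δ bp apart, growing its loop at total rate v with exponential lifetime
(mean τ_E), integrating the three kinetic regimes (death before
arrival; stall at a bound barrier; bypass after the residual bound
dwell) over the lifetime distribution, the stationary barrier state at
arrival (bound with probability o) and the exponential residual bound
time (memorylessness) gives

    E[loop] = v·τ_E · [ 1 − o · exp(−δ/(v·τ_E)) · τ_b/(τ_b + τ_E) ].

Limits: o→0 gives the unimpeded mean v·τ_E; the static limit
(τ_b, τ_u → ∞ at fixed o) is linear in occupancy,
v·τ_E·(1 − o·e^{−δ/(v·τ_E)}); permanently bound barriers with
v·τ_E ≫ δ pin the loop at δ.  Note the finite-processivity correction:
at v·τ_E = 10δ the capped mean is δ·(1−e^{−0.1})/0.1 ≈ 0.952δ, i.e.
~5 % below δ; recovering the spacing to 2 % requires v·τ_E ≳ 50δ, which
is why the static-pair validation uses v·τ_E = 100δ.

The formula is validated against an *independent* event-driven oracle
(`mc_loop_oracle`) that simulates the full alternating-dwell telegraph
trajectory of each barrier — it never invokes the stationary/memoryless
shortcuts of the derivation — and against the discrete lattice
simulator with a single extruder.  Midpoint and uniform loading are
both available; the closed form assumes midpoint loading.

## 3. Bead-spring polymer sampler

The 3D stage is a self-contained overdamped Brownian-dynamics sampler
(Euler–Maruyama, kT = 1, unit friction, lengths in monomer diameters;
one monomer = 2.5 kb of a 50-nm fiber).  Forces:

* backbone springs, harmonic (k = 50) near the unit rest length and
  stiffened 4× beyond 1.5 diameters, so that no bounded pull can
  stretch a link to the 2-diameter connectivity limit;
* extruder bonds between the coarse-grained leg monomers, with a
  saturating (pseudo-Huber) force capped at 15 — a bond switched onto a
  distant monomer drags it at a force the backbone can sustain instead
  of tearing the chain;
* soft linear excluded-volume repulsion (ε = 5) below one diameter,
  permitting strand passage (soft-core regime); neighbor lists are
  rebuilt every 5 steps with a 1-diameter skin.

Bonds are switched instantaneously at each lattice frame and the chain
relaxes a configurable number of steps (default 60; 90 in scoring runs)
before harvest; the chain is equilibrated under the first frame's bonds
(3,000–4,000 steps) before harvesting begins.  A chain-connectivity
check (consecutive distance < 2 diameters) runs after every call and
raises an integration-instability error advising a smaller `dt_3d`
(default 0.004).

The sampler targets *ensemble contact statistics*, not calibrated
dynamics: no mapping from integrator time to wall-clock chromatin
diffusion is attempted, and global conformational modes (overall
compaction) decorrelate slowly compared to the total sampled time.
Loop turnover (τ_E) rejuvenates local structure, so loop-scale features
(TADs, dots) equilibrate; absolute long-range contact levels should not
be over-interpreted.

When a long concatenated lattice is simulated, the polymer renders a
2.5-Mb *window* of it; extruder bonds with a leg outside the window are
dropped (the same boundary treatment a per-replica 3D simulation of a
concatenated 1D system implies).

Contacts are all monomer pairs within a 2-diameter capture radius,
excluding |i−j| ≤ 1, accumulated into 10-kb bins (2.5-kb for display
maps); each contact increments both (i,j) and (j,i).

## 4. Observables

**ChIP track / FRiP.** The track tallies both legs of every extruder
per lattice site over all frames and replicas.  FRiP is the fraction of
leg observations exactly on barrier sites (a windowed variant exists
for sensitivity analysis); the no-barrier control level is
(number of barrier sites)/(number of lattice sites).

**Insulation.**  For each barrier bin b with window w = 50 kb: the mean
contact count over the two within-TAD triangles (pairs i<j on one side
of b with separation 2..w bins, hypotenuses on the diagonal) divided by
the mean over the between-TAD triangle (pairs strictly crossing b with
separation ≤ w).  The first diagonal is excluded everywhere, both
regions sample the same separations 2..w, and the ratio is invariant
under uniform map rescaling.  Scores are averaged over barriers;
barriers with empty between-regions are excluded with a warning.

**Convergent dot score.**  For every convergently oriented barrier pair
(the left barrier blocks leftward legs, the right blocks rightward
legs), an 80-kb snippet centered on the pair's pixel is collected;
snippets are averaged within 25 geometric distance bins spanning
100 kb – 5 Mb; the per-bin score is the center pixel over the mean of
four 3×3 *corner* control blocks, and the distance-averaged score
weights bins by snippet counts.  Corner controls cancel any smoothly
varying distance-dependent background exactly (two blocks sit at the
pair distance, one each above and below it).  Single-pixel controls are
available but are noisy at desk-scale frame counts (near-empty corner
pixels produce unbounded ratios), hence the 3×3 default.

**Vermicelli score.**  All monomer positions and the bonded extruder-leg
monomer positions are rasterized onto a common voxel grid (1-diameter
voxels, bounding box padded by 3σ), both fields are Gaussian-smoothed
(σ = 2 voxels), and the score is the Pearson correlation over voxels.
Condensed loop-array ("vermicelli") conformations concentrate extruder
anchors on an axial core threading the chromatin density and score
high; dispersed coils with scattered extruders score low.  The
morphology develops over thousands of relaxation steps, so scoring runs
harvest a longer trajectory and score its later part.

## 5. Synthetic layouts and fixtures

`random_layout` draws distinct uniform sites (32 per 2.5 Mb by default;
mean gap with ends counted = region/(n+1) ≈ 75.8 kb) with orientations
random (each direction probability ½), alternating, or paired
convergent.  `convergent_pair` builds the simplified two-barrier layout
(δ apart, centered, facing inward).  `morphology_fixtures` constructs
an axial loop-array conformation and an equilibrium coil as a test
surface for the vermicelli score.  All generators are pure functions of
(spec, seed).  The synthetic layouts emulate uniformly random barrier
placement with shared timescales; real CTCF sites cluster, have
heterogeneous dwell times and motif-strength-dependent occupancy, so
passing tests demonstrate correctness of the machinery, not genomic
realism.

## 6. Scaled problem sizes

Reference-scale analyses in the test-suite and the acceptance script
use: a concatenated 25-Mb lattice (10 tiled replicas, 100 extruders)
sampled for ≥ 10⁴ frames for FRiP statistics; 800 polymer frames over
two 2.5-Mb windows (1,000 monomers each) for map scores; and 220
harvested frames on one 2.5-Mb replica for morphology scores.  These
sizes were chosen as the smallest at which the scored features are
reproducible across seeds; the corresponding Monte-Carlo error is the
dominant uncertainty in all map-level comparisons.

## 7. Known limitations

* FRiP and insulation responses to large lifetime increases are weaker
  than, and in part opposite to, those reported for the original
  simulations: with a conserved extruder count and leg–leg exclusion,
  raising τ_E moves legs from barrier-pinned to collision-pinned states
  (frozen leg–leg interfaces away from barriers), which lowers FRiP and
  does not lower insulation at intermediate τ_b.  The behaviours
  reported for WAPL-depletion-like conditions may depend on details not
  modelled here (e.g. concomitant changes in cohesin density).
* The polymer sampler trades dynamic fidelity for tractability; only
  ratio-type map statistics and morphology scores are meaningful.
* At these system sizes the vermicelli score discriminates weakly.
  Transient-barrier high-lifetime runs do condense (radius of gyration
  ~8–10 diameters versus ~11–12 for quasi-static barriers), but a
  geometrically elongated worm cannot form from only 10–40 loops: the
  cohesin-anchor axis is itself an unstiffened random walk and the loop
  corona is as thick as the axis is long, so the voxel Pearson score
  saturates near 0.5 for both conditions instead of separating at the
  ~0.65 level that full molecular-dynamics pipelines report.  Producing
  that separation would require bottle-brush stiffening from hard-core
  excluded volume and far longer relaxation than this sampler targets.
* Telegraph barriers share one (τ_b, τ_u) pair per run by default;
  per-site heterogeneity is supported by the types but unexplored.
* The analytical model neglects extruder–extruder collisions and any
  second barrier beyond the convergent pair.
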