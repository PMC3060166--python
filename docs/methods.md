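# Methods

This note records the model as implemented, the parameter choices that
matter, and the places where the design was genuinely open and a choice
had to be made.

## Model overview and assumptions

The simulated agent is a point in a 2-D plane with a heading, moving at
a fixed speed of 10 length units per behavioural step.  All procedures
communicate through one currency: a compass angle (world-fixed frame,
counterclockwise from +x) plus a non-negative salience.  The control
network only chooses the direction of each step; speed is never
modulated.  There is no sensory noise, no odometric error, and no
learning — "learned" states (reference vectors, landmark definitions)
are set by hand in the scenario, which mirrors how the original
experiments switch memories on and off to emulate learning states.
Navigation failure modes therefore come from the architecture itself
(gating, arbitration, run-off), not from noisy inputs; searches are
provoked by scenario design (zero-vector releases, displacement) rather
than by accumulated PI error.

The architecture is deliberately decentralized: each memory element
reads only its own store.  The single point where vectors are combined
arithmetically is inside the PI subsystem (reference minus current);
stored vectors of two different elements are never subtracted, which is
what the zero-vector-release scenario is designed to expose.

## Path integration

The current vector is held in Cartesian components internally (polar
exposed), so the representation has no singularity at the origin.  It
is reset exactly and only on nest entry.  Passive displacement
(capture/transport interventions) bypasses the integrator.

The PI procedure's output is normalized to length 1; its direction is
that of `reference − current`.  Below a cutoff the direction of that
difference counts as noise-dominated and the output length is 0 (the
zero-vector state).  For the standalone function the cutoff default is
1.0 length units (a tenth of a step).  Inside the simulation loop the
cutoff is the search gain's inner breakpoint d1(t): the PI is treated
as directionless exactly where the search gain is saturated.  This
coupling matters: with a small fixed cutoff the unit-length PI output
(entering the sum at the same 0.2 weight as the fully active random
generator) pulls the searcher back so strongly from d ≈ 1 on that
excursions never exceed roughly one step length and the growing
breakpoints are unreachable; the search area then never widens.  With
the d1(t) cutoff the random walk diffuses freely in a zone that grows
with search time, and the excursion envelope grows the way the
area-concentrated-search literature describes.

## Motivation network

Eight units with activations in [0, 1], synchronous update
a(t+1) = clip₀₁(W·a(t) + drive), relaxed to an attractor once per
behavioural step (drives held constant during relaxation).  Defaults:

| parameter | value | role |
|---|---|---|
| self-excitation, stay/forage | 1.0 | bistable persistence of the top-level decision |
| self-excitation, source and direction pairs | 0.8 | persistence *conditional on* the foraging context |
| self-excitation, ACSon/ACSoff | 0.0 | these units track their graded drives |
| pair inhibition | −1.2 | winner-take-all (difference mode grows ×2 per iteration) |
| forage → child | +0.3 | keeps the active sub-decisions alive |
| child → forage | +0.1 | foraging context sustained by its children |
| gate threshold | 0.5 | "motivation active" for all gating |
| event drive | 1.5 | flips a bistable pair from any attractor (> the 0.9 hysteresis margin) |
| tie-break noise | 1e−6 | seeded, on the six decision units at event time |

The self-excitation profile is graded on purpose.  A uniform value of
1.0 makes every unit self-sustaining, so switching `stay` on could
never extinguish the source/direction decisions; at 0.8 those units
decay once `forage` stops feeding them.  The ACS pair has no
self-excitation at all because ACSon's activation *is* the length of
the random generator's output and must follow the graded gain f(d, t)
rather than saturate; their excitatory input from `forage` is realized
as a gate on their sensory drives (gain → ACSon, summed landmark
salience → ACSoff).  The tie-break noise is restricted to the six
decision units: a symmetric positive nudge on the self-excitation-free
ACS pair would place its synchronous update on a rectified two-cycle
instead of breaking a tie.

`relax` iterates to a fixed point (tolerance 1e−9, max 500 iterations)
and reports unresolved ties — an exactly symmetric pair sits on an
unstable fixed point and is flagged as non-converged rather than
silently accepted.

Habituation (the oscillation variant, enabled only in the
feeder-directed-bee scenario) multiplies each inhibitory weight by
(1 − h) with h ← h + α·a_pre·(1 − h) − β·h, α = 0.05, β = 0.02.  The
decay rate was chosen by scanning: β must let an edge recover during
its presynaptic unit's silent half-cycle, otherwise the pair flips once
and then locks into a both-active absorbing state once both edges have
habituated; β ≈ 0.4 α with symmetric drives of 0.2 sustains the
alternation (about 5 reversals per 200 steps, independent of the
starting state).  With habituation enabled the network is stepped once
per behavioural step instead of relaxed, so the alternation unfolds on
the behavioural timescale.

## Landmark memories

Route landmarks: catchment radius default 20 length units (two steps),
salience 1.0 at perception, −0.05 per step for ten steps, constant 0.5
for five more, 0 from step 16 on.  The local angle is sampled once at
the trigger and held; re-entering a catchment resets the run-off.  The
16-step support is what limits a local vector's useful length to 150
length units of travel — the mechanism behind the "local vector too
short" experiment.

Place landmarks: catchment radius default 25 units, three signposts,
stored as goal→signpost vectors at learning time.  The output is the
mean of (seen − learned) signpost vectors, renormalized to salience 1,
recomputed every step inside the catchment (continuous matching).
With full stored vectors this mean equals the goal direction exactly,
for any signpost placement — the simplest concretization consistent
with the required contract (zero correction at the goal, homing
direction elsewhere).  Degraded-salience perception (noisy input) is
not modelled.

Gating: a route element needs both its trip-direction unit and its
source unit at or above 0.5; home snapshots need `inbound` only; food
snapshots need `outbound` plus their source.

## Search and arbitration

Random turns are uniform on [−0.3, 0.7] rad (mean +0.2, a
counterclockwise bias).  The gain f(d, t) is piecewise linear in the
PI discrepancy d with breakpoints interpolating from (3.3, 20) to
(33, 200) linearly in search time, saturating at T_max = 500 steps
(the growth rate is a free parameter; 500 steps puts saturation well
inside a standard 1000-step search).  d is the length of the PI
element's input (reference − current), which for an inbound searcher
is just the current-vector length; using the PI input rather than the
raw current vector lets the same mechanism drive searches at an
expected food location.  The search timer advances while ACSon is at
or above the gate threshold, pauses otherwise, and resets on nest
entry or whenever any landmark is perceived.

Arbitration is one-shot feedforward lateral inhibition, b = −0.4,
rectified at zero, within two separate pools (all landmark elements;
PI and the random generator).  Within the landmark pool, place
elements inhibit route elements with no reverse edge.  The summed raw
landmark salience (not the post-inhibition weights) zeroes the PI
salience whenever it exceeds 1e−9, and the same sum is the ACSoff
drive.  PI and random-generator saliences are scaled by 0.2 after the
suppression and before the within-pool inhibition.  If the final
weighted vector sum is degenerate (length < 1e−9) the previous heading
is kept, so motion is always defined.

## The world engine and scenarios

Step order: interventions → event sensing → motivation relaxation
(drives: current events, previous step's landmark-salience sum, the
gain at the current PI discrepancy) → landmark updates and outputs →
PI and ACS outputs → arbitration → move 10 units → log.  The one-step
lag on the landmark sum entering the motivation net is a deliberate
decentralized-plausible choice; the PI suppression itself uses the
current step's saliences and is therefore exact at every step.  Nest
and food detection radius is 10 units (one step).  Food pickup is
instantaneous and stores the current vector as that source's reference.

The canonical scenarios re-create the published experiments in a
hand-authored geometry (the original figures print no coordinates):
nest at the origin, food A at (260, 180), food B at (300, −140),
twelve route landmarks (three per trip) and three place snapshots.
The outbound-A chain lies on the straight nest→A line; the inbound-A
landmarks lie off the return line (so the return is pure PI) while the
first outbound catchment deliberately intersects it (to demonstrate
motivational gating); the first inbound-B landmark's local vector
points at a landmark ~210 units away, beyond the 150-unit run-off.
The bee world puts the feeder at (400, 0), the release point 300 units
north of it, and a three-landmark inbound chain (spacing < 150 units)
between the home-vector zero point and the nest.  The randomized
world generator (`random_world`) samples 1–2 food sources and 0–12
route landmarks with random catchments and local angles in a
400-unit arena, for property testing.

Determinism: a single seeded RNG stream per run; checkpoints capture
world, log and RNG state and restore bit-for-bit.

## Analysis

The distance series is the per-step Euclidean distance to a reference
point; its envelope is summarized as per-window maxima (default window
100 steps).  The radial density profile pools per-step distances over
paths into bins of 10 length units (the bin width of the original
supplementary profile is unstated; one step length is the natural
resolution).  Two conventions are provided: raw step-count fractions
per bin, and counts divided by annulus area before normalization
(`per_area=True`).  Field profiles of searching ants are densities per
unit area, and only that convention is center-peaked for a search that
spends comparable time at all covered radii; the shape-based checks of
the emergent search therefore use the per-area profile.

## Scope and limitations

* Learning and acquisition of memories are outside the model; so are
  image-based view matching, 3-D flight geometry, obstacles, terrain,
  multi-agent effects and leg-level locomotion.
* PI is noise-free; search onset comes from scenario design, not from
  integrator error.
* The dependence of search-area width on the length of the preceding
  travel is intentionally not modelled.
* The motivation-network weights reproduce all required attractor,
  switching and oscillation behaviours but are this package's own
  parameterization of the described architecture, not published
  values; they are exposed in the scenario configuration.
* Test and scenario problem sizes (1000-step searches, 10-path
  profiles, 100 random initial conditions) are the package's standard
  study conditions and are what the shipped statistics refer to.
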