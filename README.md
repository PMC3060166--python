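# antnav — decentralized insect-navigation simulator

`antnav` is an agent-based simulator of a fully decentralized navigation
architecture for desert ants and honeybees.  It is aimed at researchers
in computational neuroethology and behaviour-based robotics who want to
test how far path integration plus a bank of *independent* landmark
memories — with no shared spatial representation, no "cognitive map" —
can carry an agent through the classic navigational feats: novel
shortcuts between two food sources, route following along landmark
chains, homing after experimenter displacement, and systematic search.

## The architecture

The agent walks at a fixed 10 length units per step; a network of
independent procedures competes every step to set the walking
direction only.

* **Path integration (PI).**  A current vector **c** accumulates all
  active displacements since the last nest entry.  Finding food at
  source *i* stores **c** as a long-term reference vector **m**ᵢ.  The
  PI procedure outputs the unit vector along **m**ᵢ − **c** (outbound)
  or −**c** (inbound; the "sign reversal" is realized by gating the
  reference memory to zero).  Passive transport bypasses the integrator.
* **Motivation network.**  Eight units in [0, 1], coupled in mutually
  inhibitory pairs — (stay, forage), (sourceA, sourceB), (outbound,
  inbound), (ACSon, ACSoff) — with `forage` exciting its child
  decisions.  Relaxation to an attractor leaves one winner per pair;
  every memory element is gated by the pair states (e.g. a route
  landmark learned on the outbound trip to A responds only while
  *outbound* and *sourceA* are both active).  An optional habituation
  process on the inhibitory edges turns a doubly-driven pair into an
  oscillator.
* **Landmark memories.**  Route landmarks emit a fixed compass "local
  vector" when their catchment circle is entered, at salience 1, which
  then runs off (−0.05/step for 10 steps, a 0.5 plateau for 5 steps,
  then 0).  Place landmarks (nest and food) store a three-signpost
  snapshot and continuously emit the direction that improves the match,
  at salience 1.  No element ever reads another element's store.
* **Search (ACS).**  A random-turn generator (uniform on [−0.3, 0.7]
  rad — a counterclockwise bias) proposes a new heading each step at a
  gain f(d, t) that is 1 below an inner distance breakpoint, 0 beyond
  an outer one (3.3 and 20 length units at search onset, growing
  linearly with search time to 33 and 200).  Blended with the PI pull
  back toward the goal this produces area-concentrated search without
  any explicit search program.
* **Arbitration.**  Saliences pass through one-shot feedforward lateral
  inhibition (weight b = −0.4) in two separate pools — landmarks
  vs. PI/random — with place landmarks inhibiting route landmarks
  one-way.  Any active landmark zeroes the PI salience outright, and PI
  and random-generator saliences are scaled by 0.2 so landmarks always
  dominate.  The winner-weighted unit vectors are summed; the angle of
  the sum is the heading.

## Worked example: the novel shortcut

The agent has learned vectors to two food sources but has never
travelled between them.  Source A is found empty; the motivation
network flips to source B and the path integrator — reading *only* the
stored vector B together with the current vector — steers the novel
route A→B:

```python
import math
import antnav
from antnav.scenarios import canonical

log = antnav.run(canonical("shortcut_a_to_b", seed=1), seed=1)
flip = next(r for r in log.records if "food_absent_at" in r["events"])
print("heading after flip: %.1f deg" % math.degrees(flip["heading"]))
print("bearing of B-A:     %.1f deg"
      % math.degrees(math.atan2(-140 - 180, 300 - 260)))
```

prints

```
heading after flip: -81.9 deg
bearing of B-A:     -82.9 deg
```

The run's control sequence (winning procedure per step) is

```
PI -> rLM_Aout1 -> rLM_Aout2 -> rLM_Aout3 -> fLMA -> PI -> fLMB -> PI
   -> rLM_Bin1 -> PI -> hLM
```

— out to A along the three outbound route landmarks and the food
snapshot, the PI shortcut to B after the flip (within 1° of the B−A
bearing, although no subtraction of stored vectors ever happens), and
home via one route landmark whose local vector runs off, the path
integrator, and the nest snapshot.  The run ends at the nest
(final position (2.2, −5.6)) with the current vector reset to 0.

The same machinery is scriptable from the shell:

```
antnav run --scenario shortcut_a_to_b --seed 1 --out runs/
antnav plot trajectory --log runs/shortcut_a_to_b_seed1.csv \
       --scenario shortcut_a_to_b --out shortcut.png
antnav analyze search --logs runs/zero_vector_search_seed3.csv --origin 0,0
```

Other canonical scenarios: `two_food_route_a`, `two_food_route_b`,
`bee_displacement`, `zero_vector_release` (the architecture's critical
prediction — a zero-vector agent released at empty A heads along vector
B, *not* B−A), `zero_vector_search`, `feeder_directed_bee`.  Custom
worlds are plain YAML (`antnav export-scenario <name> <file>` writes a
template).

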