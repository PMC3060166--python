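"""Procedural landmark memories: route landmarks and place snapshots.

Two kinds of landmark memory element live in the bank, and both are
strictly private — no element ever reads another element's store, and no
ordering among landmarks is represented anywhere.

*Route landmarks* associate a catchment area somewhere along a learned
route with a compass direction (the "local vector").  When the agent
enters the catchment while the element's two motivational gates (trip
direction and current goal) are open, the element emits its local angle
at full salience 1.0.  The landmark is then no longer attended: as the
walk continues the salience runs off on a fixed schedule — down by 0.05
per step for ten steps, flat at 0.5 for five more, then zero — so that a
newly recognized landmark can override the fading one.

*Place landmarks* (home and food) hold a snapshot: the vectors from the
goal to three signposts, recorded at learning time.  While the agent is
inside the catchment the element continuously compares the currently
seen signpost vectors with the stored ones; the mean mismatch points at
the goal, and walking along it improves the match until the goal is
reached.  Salience is 1 throughout (a perceived place landmark always
wins over a fading route landmark, enforced downstream by the one-way
inhibition in the arbitration stage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .geometry import EPS_LENGTH, PolarVector, Position
from .motivation import GATE_THRESHOLD, MotivationState

#: default catchment radii in length units (two / two-and-a-half steps);
#: the published figures draw them as circles without printing numbers
DEFAULT_ROUTE_RADIUS = 20.0
DEFAULT_PLACE_RADIUS = 25.0

#: route-landmark salience run-off: 1.0 at perception, -0.05 per step
#: for 10 steps, constant 0.5 for 5 more steps, then 0
DECAY_STEP = 0.05
DECAY_RAMP_STEPS = 10
DECAY_PLATEAU_STEPS = 5
DECAY_SUPPORT = DECAY_RAMP_STEPS + DECAY_PLATEAU_STEPS  # last step with salience > 0


def route_salience(steps_since_trigger: int) -> float:
    """Salience of a route-landmark element *k* steps after perception."""
    k = steps_since_trigger
    if k < 0:
        raise ValueError("steps_since_trigger must be non-negative")
    if k <= DECAY_RAMP_STEPS:
        return 1.0 - DECAY_STEP * k
    if k <= DECAY_SUPPORT:
        return 1.0 - DECAY_STEP * DECAY_RAMP_STEPS
    return 0.0


@dataclass
class Gates:
    """The two motivation units that must both be active for the element
    to respond at all: the goal (source) and the trip direction."""

    source: str | None  # "A", "B" or None (home elements: any source)
    direction: str      # "outbound" or "inbound"

    def passed(self, motivations: MotivationState) -> bool:
        if not motivations.is_active(self.direction):
            return False
        if self.source is None:
            return True
        return motivations.is_active(f"source{self.source}")


@dataclass
class RouteLandmarkElement:
    """One learned route landmark with its local vector."""

    id: str
    catchment_center: Position
    local_angle: float
    gates: Gates
    catchment_radius: float = DEFAULT_ROUTE_RADIUS
    #: steps since the landmark was last perceived; None while dormant
    steps_since_trigger: int | None = None

    def update(self, agent_pos: Position, motivations: MotivationState) -> None:
        """Per-step trigger/decay bookkeeping.

        Entering the catchment with both gates open (re)starts the
        run-off at full salience; otherwise an already running element
        simply ages by one step.  Re-entry resets the counter.
        """
        inside = agent_pos.distance_to(self.catchment_center) <= self.catchment_radius
        if inside and self.gates.passed(motivations):
            self.steps_since_trigger = 0
        elif self.steps_since_trigger is not None:
            self.steps_since_trigger += 1
            if self.steps_since_trigger > DECAY_SUPPORT:
                self.steps_since_trigger = None

    def output(self, agent_pos: Position, motivations: MotivationState) -> PolarVector:
        """(local_angle, salience) under the current gates."""
        if self.steps_since_trigger is None or not self.gates.passed(motivations):
            return PolarVector.zero()
        return PolarVector(self.local_angle,
                           route_salience(self.steps_since_trigger))

    def reset(self) -> None:
        self.steps_since_trigger = None


@dataclass
class PlaceLandmarkElement:
    """A snapshot memory defining a place (home or a food source).

    ``learned_vectors[i]`` is the vector goal -> signpost_i stored at
    learning time.  The element's output direction is the mean of the
    per-signpost corrections (seen vector minus learned vector), which
    vanishes exactly at the goal.
    """

    id: str
    goal: Position
    signposts: Sequence[Position]
    gates: Gates
    catchment_radius: float = DEFAULT_PLACE_RADIUS
    learned_vectors: Sequence[PolarVector] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.signposts) != 3:
            raise ValueError("a place landmark stores exactly three signposts")
        if not self.learned_vectors:
            self.learned_vectors = [PolarVector.between(self.goal, s)
                                    for s in self.signposts]

    def inside(self, agent_pos: Position) -> bool:
        return agent_pos.distance_to(self.goal) <= self.catchment_radius

    def snapshot_output(self, agent_pos: Position) -> PolarVector:
        """Direction that improves the snapshot match, at unit salience.

        Mean over signposts of (vector agent -> signpost) minus the
        learned (goal -> signpost) vector.  Length is set to 1; when the
        mean correction is negligible the agent is at the goal and the
        output is the zero vector.
        """
        sx = sy = 0.0
        for signpost, learned in zip(self.signposts, self.learned_vectors):
            seen = PolarVector.between(agent_pos, signpost)
            sx += seen.x - learned.x
            sy += seen.y - learned.y
        n = len(self.signposts)
        mean = PolarVector.from_xy(sx / n, sy / n)
        if mean.length < EPS_LENGTH:
            return PolarVector.zero()
        return PolarVector(mean.angle, 1.0)

    def output(self, agent_pos: Position, motivations: MotivationState) -> PolarVector:
        """Gated per-step output; recomputed continuously inside the
        catchment (the match is re-evaluated every step)."""
        if not self.inside(agent_pos) or not self.gates.passed(motivations):
            return PolarVector.zero()
        return self.snapshot_output(agent_pos)

    def reset(self) -> None:
        pass  # stateless between steps


def default_signposts(goal: Position, distance: float = 60.0) -> list[Position]:
    """Three signposts on an equilateral triangle around *goal*; used by
    scenario builders when no explicit signposts are given."""
    return [goal.displaced(math.radians(90.0 + 120.0 * k), distance)
            for k in range(3)]
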