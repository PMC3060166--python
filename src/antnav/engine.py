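"""World engine: scenarios, world state, events and the simulation loop.

A :class:`Scenario` is a declarative description of one experiment — the
nest, the food sources, the learned landmark bank, the agent's initial
state and any experimenter interventions (capture-and-release
displacement, removing a reward).  :class:`Simulation` owns the mutable
:class:`WorldState` and advances it one behavioural step at a time:

1. apply any interventions due this step;
2. sense events (nest entry, food found / found empty) using the
   agent's current motivational context;
3. feed the events plus the continuous drives (summed landmark salience
   from the previous step, the search gain f(d, t)) into the motivation
   network and let it relax;
4. update the landmark elements and collect every procedure's output;
5. arbitrate (lateral inhibition + weighted summation) to a heading;
6. walk 10 length units along that heading and pass the same
   displacement to the path integrator;
7. log the step.

The run ends when the agent, inbound, enters the nest (or after
``max_steps``).  Identical seeds give bit-identical trajectories, and a
checkpointed world can be restored mid-run with the same guarantee.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from . import acs as acs_mod
from .acs import AcsState
from .arbitration import (ACS_ID, LANDMARK_POOL, PI_ACS_POOL, PI_ID,
                          ArbitrationResult, InhibitionConfig,
                          ProcedureOutput, SalienceBundle, resolve_heading)
from .geometry import PolarVector, Position, RngStream
from .landmarks import PlaceLandmarkElement, RouteLandmarkElement
from .motivation import (GATE_THRESHOLD, HabituationParams, MotivationState,
                         MotivationWeights, apply_event, relax,
                         motivation_step)
from .path_integration import (CurrentVector, ReferenceVectorMemory,
                               pi_discrepancy, pi_output, update_current)

#: fixed forward speed (length units per step); the network controls
#: direction only
STEP_LENGTH = 10.0

#: detection radius for "at the nest" / "at a food source"
EPS_GOAL = 10.0


@dataclass
class FoodSource:
    id: str
    position: Position
    has_food: bool = True


@dataclass
class AgentInit:
    position: Position
    heading: float = 0.0
    current_vector: PolarVector = field(default_factory=PolarVector.zero)
    #: initial motivation activations by unit name
    motivations: dict[str, float] = field(default_factory=dict)


@dataclass
class Intervention:
    """An experimenter action.

    Fired either at a fixed step (``step=n``, applied before that step's
    sensing) or one step after a named event first occurs
    (``after_event="food_found"`` — e.g. capturing a bee once it has
    loaded up at the feeder).  Supported actions: ``displace`` (with
    ``position`` and ``reset_current``), ``remove_food`` / ``add_food``
    (with ``source``).
    """

    action: str
    step: int | None = None
    after_event: str | None = None
    position: Position | None = None
    reset_current: bool = False
    source: str | None = None
    fired: bool = False

    def __post_init__(self) -> None:
        if (self.step is None) == (self.after_event is None):
            raise ValueError("exactly one of step/after_event must be set")
        if self.action not in ("displace", "remove_food", "add_food"):
            raise ValueError(f"unknown intervention action {self.action!r}")


@dataclass
class Scenario:
    """Complete, self-contained description of one experiment."""

    name: str
    nest: Position
    food_sources: list[FoodSource]
    route_landmarks: list[RouteLandmarkElement] = field(default_factory=list)
    place_landmarks: list[PlaceLandmarkElement] = field(default_factory=list)
    #: preloaded nest-to-food reference vectors ("learned" states are set
    #: by hand; acquisition is not simulated)
    reference_vectors: dict[str, PolarVector] = field(default_factory=dict)
    agent: AgentInit | None = None
    interventions: list[Intervention] = field(default_factory=list)
    motivation_weights: MotivationWeights = field(default_factory=MotivationWeights)
    inhibition: InhibitionConfig = field(default_factory=InhibitionConfig)
    habituation: HabituationParams | None = None
    #: persistent drives fed to the motivation net every step (used by
    #: the feeder-directed-bee variant where both trip directions stay
    #: stimulated)
    persistent_drives: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    max_steps: int = 500
    step_length: float = STEP_LENGTH
    eps_goal: float = EPS_GOAL
    acs_t_max: float = acs_mod.T_MAX_DEFAULT
    stop_at_nest: bool = True

    def __post_init__(self) -> None:
        if self.agent is None:
            self.agent = AgentInit(position=self.nest)
        ids = [s.id for s in self.food_sources]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate food source ids")
        known = set(ids)
        for sid in self.reference_vectors:
            if sid not in known:
                raise ValueError(f"reference vector for unknown source {sid!r}")
        for lm in self.route_landmarks:
            if lm.gates.source is not None and lm.gates.source not in known:
                raise ValueError(f"landmark {lm.id} gated on unknown source")
            if lm.catchment_radius <= 0:
                raise ValueError(f"landmark {lm.id} has non-positive radius")
        for lm in self.place_landmarks:
            if lm.catchment_radius <= 0:
                raise ValueError(f"landmark {lm.id} has non-positive radius")


@dataclass
class WorldState:
    """Everything that changes while a simulation runs."""

    position: Position
    heading: float
    current: CurrentVector
    motivation: MotivationState
    references: ReferenceVectorMemory
    route_elements: list[RouteLandmarkElement]
    place_elements: list[PlaceLandmarkElement]
    acs: AcsState
    food_available: dict[str, bool]
    step_count: int = 0
    #: summed landmark salience emitted on the previous step (drives
    #: ACSoff and is all the search generator knows about landmarks)
    last_landmark_sum: float = 0.0
    events_seen: set = field(default_factory=set)
    terminal: bool = False


class TrajectoryLog:
    """Append-only per-step record of a run."""

    def __init__(self, scenario_name: str = "", seed: int | None = None):
        self.scenario_name = scenario_name
        self.seed = seed
        self.records: list[dict[str, Any]] = []

    def append(self, record: dict[str, Any]) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def positions(self) -> list[tuple[float, float]]:
        return [(r["x"], r["y"]) for r in self.records]

    def winners(self) -> list[str | None]:
        return [r["winner"] for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {k: v for k, v in r.items()
                   if k not in ("weights", "activations", "events")}
            row["events"] = ";".join(r["events"])
            row["weights"] = json.dumps(r["weights"])
            for unit, a in r["activations"].items():
                row[f"m_{unit}"] = a
            rows.append(row)
        return pd.DataFrame(rows)

    def save_csv(self, path) -> None:
        """Delimited table, one row per step, with a JSON metadata header."""
        meta = {"scenario": self.scenario_name, "seed": self.seed,
                "n_steps": len(self.records)}
        with open(path, "w") as fh:
            fh.write(f"# antnav trajectory {json.dumps(meta)}\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def load_csv(cls, path) -> "TrajectoryLog":
        with open(path) as fh:
            header = fh.readline()
            meta = json.loads(header.split("antnav trajectory", 1)[1])
            frame = pd.read_csv(fh)
        log = cls(meta.get("scenario", ""), meta.get("seed"))
        for _, row in frame.iterrows():
            rec = {k: row[k] for k in row.index
                   if not k.startswith("m_") and k not in ("weights", "events")}
            rec["weights"] = json.loads(row["weights"])
            rec["events"] = [e for e in str(row["events"]).split(";")
                             if e and e != "nan"]
            rec["activations"] = {k[2:]: row[k] for k in row.index
                                  if k.startswith("m_")}
            log.append(rec)
        return log


class Simulation:
    """Owns one world and advances it step by step."""

    def __init__(self, scenario: Scenario, seed: int | None = None):
        self.scenario = scenario
        self.seed = scenario.seed if seed is None else seed
        self.rng = RngStream(self.seed)
        self.world = self._initial_world()
        self.log = TrajectoryLog(scenario.name, self.seed)
        self._interventions = [copy.deepcopy(iv)
                               for iv in scenario.interventions]

    # -- construction -------------------------------------------------

    def _initial_world(self) -> WorldState:
        sc = self.scenario
        agent = sc.agent
        motivation = MotivationState.from_dict(agent.motivations)
        refs = ReferenceVectorMemory(
            {s.id: sc.reference_vectors.get(s.id, PolarVector.zero())
             for s in sc.food_sources})
        acs_state = AcsState(prev_heading=agent.heading)
        return WorldState(
            position=agent.position,
            heading=agent.heading,
            current=CurrentVector(agent.current_vector),
            motivation=motivation,
            references=refs,
            route_elements=[copy.deepcopy(lm) for lm in sc.route_landmarks],
            place_elements=[copy.deepcopy(lm) for lm in sc.place_landmarks],
            acs=acs_state,
            food_available={s.id: s.has_food for s in sc.food_sources},
        )

    # -- interventions ------------------------------------------------

    def displace(self, new_pos: Position, reset_current: bool = False) -> None:
        """Teleport the agent (capture and release).

        Passive transport does not pass through the path integrator, so
        the current vector is untouched unless *reset_current* asks for
        a zero-vector release.
        """
        self.world.position = new_pos
        if reset_current:
            self.world.current = CurrentVector(PolarVector.zero())

    def _apply_interventions(self) -> list[str]:
        applied = []
        for iv in self._interventions:
            if iv.fired:
                continue
            due = (iv.step is not None and self.world.step_count >= iv.step) or \
                  (iv.after_event is not None
                   and iv.after_event in self.world.events_seen)
            if not due:
                continue
            iv.fired = True
            if iv.action == "displace":
                self.displace(iv.position, iv.reset_current)
            elif iv.action == "remove_food":
                self.world.food_available[iv.source] = False
            elif iv.action == "add_food":
                self.world.food_available[iv.source] = True
            applied.append(iv.action)
        return applied

    # -- event sensing -------------------------------------------------

    def _sense_events(self) -> dict[str, object]:
        sc, w = self.scenario, self.world
        events: dict[str, object] = {}
        m = w.motivation
        if m.is_active("inbound") and \
                w.position.distance_to(sc.nest) <= sc.eps_goal:
            events["entered_nest"] = True
        source_id = m.selected_source()
        if m.is_active("outbound") and source_id is not None:
            source = next((s for s in sc.food_sources if s.id == source_id),
                          None)
            if source is not None and \
                    w.position.distance_to(source.position) <= sc.eps_goal:
                if w.food_available[source_id]:
                    events["food_found"] = True
                else:
                    events["food_absent_at"] = source_id
        return events

    # -- the step ------------------------------------------------------

    def step(self) -> dict[str, Any]:
        """Advance the world one behavioural step; returns the log record."""
        sc, w = self.scenario, self.world
        if w.terminal:
            raise RuntimeError("simulation already terminal")

        applied = self._apply_interventions()
        events = self._sense_events()
        for name in events:
            w.events_seen.add(name)

        # effects of discrete events on the world (before the walk)
        if "food_found" in events:
            w.references.store(w.motivation.selected_source(), w.current)
        if "entered_nest" in events:
            w.current = CurrentVector(PolarVector.zero())
            w.acs.reset()
            if sc.stop_at_nest:
                w.terminal = True

        # continuous drives: search gain from the PI discrepancy under
        # the current gating, landmark sum from the previous step
        gated_ref = w.references.gated_output(
            w.motivation.selected_source(), w.motivation.is_active("outbound"))
        d = pi_discrepancy(gated_ref, w.current).length
        gain = acs_mod.acs_gain(d, w.acs.timer, sc.acs_t_max)
        forage_active = w.motivation.is_active("forage") or \
            "start_foraging" in events
        drive_events: dict[str, object] = dict(events)
        drive_events["landmark_sum"] = w.last_landmark_sum
        drive_events["acs_gain"] = gain
        drives = apply_event(drive_events, forage_active,
                             rng=self.rng if events else None)
        for unit, extra in sc.persistent_drives.items():
            drives[unit] = drives.get(unit, 0.0) + extra

        if sc.habituation is not None:
            # oscillation variant: one network update per behavioural
            # step so the habituation-driven alternation unfolds in time
            w.motivation = motivation_step(w.motivation,
                                           sc.motivation_weights, drives,
                                           sc.habituation)
        else:
            w.motivation = relax(w.motivation, sc.motivation_weights,
                                 drives).state

        # procedural memory outputs under the relaxed motivation
        bundle = SalienceBundle()
        for lm in w.route_elements:
            lm.update(w.position, w.motivation)
            out = lm.output(w.position, w.motivation)
            bundle.add(ProcedureOutput(lm.id, out.angle, out.length,
                                       LANDMARK_POOL))
        for lm in w.place_elements:
            out = lm.output(w.position, w.motivation)
            bundle.add(ProcedureOutput(lm.id, out.angle, out.length,
                                       LANDMARK_POOL, is_place=True))
        lm_sum = bundle.landmark_salience_sum()

        gated_ref = w.references.gated_output(
            w.motivation.selected_source(), w.motivation.is_active("outbound"))
        # the PI direction is noise-dominated ("about zero") exactly
        # where the search gain saturates: inside d1(t)
        d1, _ = acs_mod.breakpoints(w.acs.timer, sc.acs_t_max)
        pi_vec = pi_output(gated_ref, w.current, eps=d1)
        bundle.add(ProcedureOutput(PI_ID, pi_vec.angle, pi_vec.length,
                                   PI_ACS_POOL))

        if lm_sum > sc.inhibition.suppression_eps:
            w.acs.reset()  # a perceived landmark ends the search
        acs_activation = w.motivation["ACSon"]
        w.acs.tick(searching=acs_activation >= GATE_THRESHOLD)
        acs_vec = acs_mod.acs_output(w.acs, self.rng, acs_activation)
        bundle.add(ProcedureOutput(ACS_ID, acs_vec.angle, acs_vec.length,
                                   PI_ACS_POOL))

        result = resolve_heading(bundle, sc.inhibition, w.heading)

        moving = w.motivation.is_active("forage") and not w.terminal
        if moving:
            displacement = PolarVector(result.heading, sc.step_length)
            w.position = w.position.displaced(result.heading, sc.step_length)
            w.current = update_current(w.current, displacement)
            w.heading = result.heading
            w.acs.prev_heading = result.heading

        record = {
            "step": w.step_count,
            "x": w.position.x, "y": w.position.y,
            "heading": w.heading,
            "cv_length": w.current.length,
            "cv_angle": w.current.vector.angle,
            "pi_d": d,
            "acs_gain": gain,
            "acs_timer": w.acs.timer,
            "landmark_sum": lm_sum,
            "winner": result.winner,
            "weights": result.weights,
            "activations": w.motivation.as_dict(),
            "events": sorted(events) + applied,
        }
        self.log.append(record)
        w.last_landmark_sum = lm_sum
        w.step_count += 1
        return record

    def run(self) -> TrajectoryLog:
        while not self.world.terminal and \
                self.world.step_count < self.scenario.max_steps:
            self.step()
        return self.log

    # -- checkpointing -------------------------------------------------

    def checkpoint(self) -> dict:
        """Snapshot of world + RNG; restoring reproduces the run
        bit-for-bit."""
        return {
            "world": copy.deepcopy(self.world),
            "rng_state": copy.deepcopy(self.rng.state()),
            "interventions": copy.deepcopy(self._interventions),
            "log_records": copy.deepcopy(self.log.records),
        }

    def restore(self, chk: dict) -> None:
        self.world = copy.deepcopy(chk["world"])
        self.rng.set_state(copy.deepcopy(chk["rng_state"]))
        self._interventions = copy.deepcopy(chk["interventions"])
        self.log.records = copy.deepcopy(chk["log_records"])


def run(scenario: Scenario, seed: int | None = None) -> TrajectoryLog:
    """Run *scenario* to completion and return its trajectory log."""
    return Simulation(scenario, seed).run()
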