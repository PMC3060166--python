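"""Scenario builders: the canonical experiments and randomized worlds.

The published experiments are re-created here as hand-authored worlds
(the original figures print no coordinates, so the geometry is an
acknowledged approximation chosen to reproduce the described behaviour):

* ``two_food_route_a`` — out to food A guided by three route landmarks,
  straight home by path integration, crossing (and ignoring) an
  outbound catchment on the way back.
* ``two_food_route_b`` — out to food B by pure path integration; on the
  way home a route landmark's local vector runs off short of the next
  landmark and the path integrator finishes the trip.
* ``shortcut_a_to_b`` — food A is found empty, the motivation network
  flips to source B, and the agent takes the novel shortcut A->B using
  only the stored vector B.
* ``bee_displacement`` — the agent loads up at the feeder, is carried
  north, flies off its home vector, searches, and homes along a chain
  of inbound route landmarks.
* ``zero_vector_release`` — the critical prediction: released as a
  zero-vector agent inside A's (empty) catchment, the agent heads along
  vector B, not along B - A.
* ``zero_vector_search`` — a bare world for the emergent
  area-concentrated search statistics.
* ``feeder_directed_bee`` — the oscillation variant: habituating
  inhibition with both trip directions driven.

All scenarios are plain data and can be round-tripped through YAML.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import yaml

from .arbitration import InhibitionConfig
from .engine import AgentInit, FoodSource, Intervention, Scenario
from .geometry import PolarVector, Position, angle_between
from .landmarks import (DEFAULT_PLACE_RADIUS, DEFAULT_ROUTE_RADIUS, Gates,
                        PlaceLandmarkElement, RouteLandmarkElement,
                        default_signposts)
from .motivation import HabituationParams, MotivationWeights

NEST = Position(0.0, 0.0)
FOOD_A = Position(260.0, 180.0)
FOOD_B = Position(300.0, -140.0)

_FORAGING_OUT = {"forage": 1.0, "outbound": 1.0}


def _route(id_: str, center: Position, toward: Position,
           source: str, direction: str) -> RouteLandmarkElement:
    return RouteLandmarkElement(
        id=id_, catchment_center=center,
        local_angle=angle_between(center, toward),
        gates=Gates(source=source, direction=direction))


def _place(id_: str, goal: Position, source: str | None,
           direction: str) -> PlaceLandmarkElement:
    return PlaceLandmarkElement(
        id=id_, goal=goal, signposts=default_signposts(goal),
        gates=Gates(source=source, direction=direction))


def _two_food_landmarks() -> tuple[list[RouteLandmarkElement],
                                   list[PlaceLandmarkElement]]:
    """The 12 route landmarks (three per trip) and 3 place landmarks of
    the two-food world."""
    route = [
        # outbound to A: a chain the straight line H->A runs into
        _route("rLM_Aout1", Position(90, 60), Position(150, 140), "A", "outbound"),
        _route("rLM_Aout2", Position(150, 140), Position(220, 160), "A", "outbound"),
        _route("rLM_Aout3", Position(220, 160), FOOD_A, "A", "outbound"),
        # inbound from A: learned but off the straight A->H line
        _route("rLM_Ain1", Position(200, 80), NEST, "A", "inbound"),
        _route("rLM_Ain2", Position(120, 30), NEST, "A", "inbound"),
        _route("rLM_Ain3", Position(30, 70), NEST, "A", "inbound"),
        # outbound to B: off the straight H->B line (pure PI outbound)
        _route("rLM_Bout1", Position(140, -20), FOOD_B, "B", "outbound"),
        _route("rLM_Bout2", Position(210, -135), FOOD_B, "B", "outbound"),
        _route("rLM_Bout3", Position(260, -60), FOOD_B, "B", "outbound"),
        # inbound from B: the first sits on the B->H line and points at a
        # landmark near the lower margin -- too far for its local vector
        RouteLandmarkElement(
            id="rLM_Bin1", catchment_center=Position(150, -70),
            local_angle=math.radians(-115.0),
            gates=Gates(source="B", direction="inbound")),
        _route("rLM_Bin2", Position(80, -270), NEST, "B", "inbound"),
        _route("rLM_Bin3", Position(40, -200), NEST, "B", "inbound"),
    ]
    place = [
        _place("hLM", NEST, None, "inbound"),
        _place("fLMA", FOOD_A, "A", "outbound"),
        _place("fLMB", FOOD_B, "B", "outbound"),
    ]
    return route, place


def _two_food_scenario(name: str, target: str, *,
                       a_has_food: bool = True,
                       agent: AgentInit | None = None,
                       max_steps: int = 300) -> Scenario:
    route, place = _two_food_landmarks()
    if agent is None:
        agent = AgentInit(
            position=NEST,
            heading=0.0,
            motivations={**_FORAGING_OUT, f"source{target}": 1.0})
    return Scenario(
        name=name,
        nest=NEST,
        food_sources=[FoodSource("A", FOOD_A, has_food=a_has_food),
                      FoodSource("B", FOOD_B, has_food=True)],
        route_landmarks=route,
        place_landmarks=place,
        reference_vectors={"A": PolarVector.between(NEST, FOOD_A),
                           "B": PolarVector.between(NEST, FOOD_B)},
        agent=agent,
        max_steps=max_steps,
    )


def two_food_route_a(seed: int = 0) -> Scenario:
    """Out to A along the outbound landmark chain, home by PI."""
    sc = _two_food_scenario("two_food_route_a", "A")
    sc.seed = seed
    return sc


def two_food_route_b(seed: int = 0) -> Scenario:
    """Out to B by PI; inbound local vector runs off, PI finishes."""
    sc = _two_food_scenario("two_food_route_b", "B")
    sc.seed = seed
    return sc


def shortcut_a_to_b(seed: int = 0) -> Scenario:
    """A is empty: the agent flips to source B and shortcuts A->B."""
    sc = _two_food_scenario("shortcut_a_to_b", "A", a_has_food=False,
                            max_steps=400)
    sc.seed = seed
    return sc


def zero_vector_release(seed: int = 0) -> Scenario:
    """Released at (empty) A as a zero-vector agent: the prediction is
    an initial heading along vector B, not along B - A."""
    agent = AgentInit(position=FOOD_A, heading=0.0,
                      current_vector=PolarVector.zero(),
                      motivations={**_FORAGING_OUT, "sourceA": 1.0})
    sc = _two_food_scenario("zero_vector_release", "A", a_has_food=False,
                            agent=agent, max_steps=200)
    sc.stop_at_nest = True
    sc.seed = seed
    return sc


BEE_FOOD = Position(400.0, 0.0)
BEE_RELEASE = Position(400.0, 300.0)


def bee_displacement(seed: int = 0,
                     habituation: bool = False) -> Scenario:
    """Capture at the feeder, release to the north: home-vector flight,
    search, then landmark-guided homing along an inbound chain."""
    chain = [Position(40, 250), Position(10, 160), Position(-20, 80)]
    route = [
        _route("rLM_in1", chain[0], chain[1], "A", "inbound"),
        _route("rLM_in2", chain[1], chain[2], "A", "inbound"),
        _route("rLM_in3", chain[2], NEST, "A", "inbound"),
    ]
    place = [_place("hLM", NEST, None, "inbound"),
             _place("fLMA", BEE_FOOD, "A", "outbound")]
    sc = Scenario(
        name="bee_displacement",
        nest=NEST,
        food_sources=[FoodSource("A", BEE_FOOD, has_food=True)],
        route_landmarks=route,
        place_landmarks=place,
        reference_vectors={"A": PolarVector.between(NEST, BEE_FOOD)},
        agent=AgentInit(position=NEST, heading=0.0,
                        motivations={**_FORAGING_OUT, "sourceA": 1.0}),
        interventions=[Intervention(action="displace",
                                    after_event="food_found",
                                    position=BEE_RELEASE,
                                    reset_current=False)],
        max_steps=1500,
        seed=seed,
    )
    if habituation:
        sc.habituation = HabituationParams()
        sc.persistent_drives = {"inbound": 0.2, "outbound": 0.2,
                                "forage": 0.5}
        sc.name = "feeder_directed_bee"
    return sc


def feeder_directed_bee(seed: int = 0) -> Scenario:
    """Oscillation variant of the bee experiment: habituating inhibition
    with both trip directions driven keeps the agent alternating between
    feeder-directed and home-directed behaviour."""
    return bee_displacement(seed, habituation=True)


def zero_vector_search(seed: int = 0, max_steps: int = 1000) -> Scenario:
    """A bare world for the emergent search: inbound zero-vector agent,
    no landmarks, nest far out of reach."""
    return Scenario(
        name="zero_vector_search",
        nest=Position(1e5, 0.0),
        food_sources=[],
        agent=AgentInit(position=Position(0.0, 0.0), heading=0.0,
                        current_vector=PolarVector.zero(),
                        motivations={"forage": 1.0, "inbound": 1.0}),
        max_steps=max_steps,
        seed=seed,
    )


CANONICAL = {
    "two_food_route_a": two_food_route_a,
    "two_food_route_b": two_food_route_b,
    "shortcut_a_to_b": shortcut_a_to_b,
    "bee_displacement": bee_displacement,
    "zero_vector_release": zero_vector_release,
    "zero_vector_search": zero_vector_search,
    "feeder_directed_bee": feeder_directed_bee,
}


def canonical(name: str, seed: int = 0) -> Scenario:
    """Look up a canonical scenario by name."""
    try:
        return CANONICAL[name](seed)
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"known: {sorted(CANONICAL)}") from None


def random_world(seed: int,
                 n_food_sources: int | None = None,
                 n_route_landmarks: int | None = None,
                 arena: float = 400.0) -> Scenario:
    """A randomized world in the style of the canonical experiments.

    One nest, 1-2 food sources with preloaded reference vectors, and
    0-12 route landmarks with random catchments and local vectors, plus
    place landmarks at nest and food.  Used for property testing.
    """
    rng = np.random.default_rng(seed)
    if n_food_sources is None:
        n_food_sources = int(rng.integers(1, 3))
    if n_route_landmarks is None:
        n_route_landmarks = int(rng.integers(0, 13))
    source_ids = ["A", "B"][:n_food_sources]
    sources = []
    refs = {}
    for sid in source_ids:
        pos = Position(float(rng.uniform(-arena, arena)),
                       float(rng.uniform(-arena, arena)))
        while pos.distance_to(NEST) < 100:
            pos = Position(float(rng.uniform(-arena, arena)),
                           float(rng.uniform(-arena, arena)))
        sources.append(FoodSource(sid, pos, has_food=True))
        refs[sid] = PolarVector.between(NEST, pos)
    route = []
    for k in range(n_route_landmarks):
        center = Position(float(rng.uniform(-arena, arena)),
                          float(rng.uniform(-arena, arena)))
        route.append(RouteLandmarkElement(
            id=f"rLM{k}", catchment_center=center,
            local_angle=float(rng.uniform(-math.pi, math.pi)),
            catchment_radius=float(rng.uniform(10, 30)),
            gates=Gates(source=str(rng.choice(source_ids)),
                        direction=str(rng.choice(["outbound", "inbound"])))))
    place = [_place("hLM", NEST, None, "inbound")]
    for s in sources:
        place.append(_place(f"fLM{s.id}", s.position, s.id, "outbound"))
    target = source_ids[0]
    return Scenario(
        name=f"random_world_{seed}",
        nest=NEST,
        food_sources=sources,
        route_landmarks=route,
        place_landmarks=place,
        reference_vectors=refs,
        agent=AgentInit(position=NEST,
                        motivations={**_FORAGING_OUT, f"source{target}": 1.0}),
        max_steps=600,
        seed=seed,
    )


# -- YAML serialization ------------------------------------------------

def _pos(p: Position) -> list[float]:
    return [p.x, p.y]


def scenario_to_dict(sc: Scenario) -> dict:
    return {
        "name": sc.name,
        "nest": _pos(sc.nest),
        "food_sources": [{"id": s.id, "position": _pos(s.position),
                          "has_food": s.has_food} for s in sc.food_sources],
        "route_landmarks": [{
            "id": lm.id, "center": _pos(lm.catchment_center),
            "radius": lm.catchment_radius, "local_angle": lm.local_angle,
            "source": lm.gates.source, "direction": lm.gates.direction,
        } for lm in sc.route_landmarks],
        "place_landmarks": [{
            "id": lm.id, "goal": _pos(lm.goal),
            "radius": lm.catchment_radius,
            "signposts": [_pos(s) for s in lm.signposts],
            "learned_vectors": [[v.angle, v.length]
                                for v in lm.learned_vectors],
            "source": lm.gates.source, "direction": lm.gates.direction,
        } for lm in sc.place_landmarks],
        "reference_vectors": {sid: [v.angle, v.length]
                              for sid, v in sc.reference_vectors.items()},
        "agent": {
            "position": _pos(sc.agent.position),
            "heading": sc.agent.heading,
            "current_vector": [sc.agent.current_vector.angle,
                               sc.agent.current_vector.length],
            "motivations": dict(sc.agent.motivations),
        },
        "interventions": [{
            "action": iv.action, "step": iv.step,
            "after_event": iv.after_event,
            "position": _pos(iv.position) if iv.position else None,
            "reset_current": iv.reset_current, "source": iv.source,
        } for iv in sc.interventions],
        "motivation_weights": {
            "self_excitation": dict(sc.motivation_weights.self_excitation),
            "pair_inhibition": sc.motivation_weights.pair_inhibition,
            "forage_to_child": sc.motivation_weights.forage_to_child,
            "child_to_forage": sc.motivation_weights.child_to_forage,
        },
        "inhibition": {"b": sc.inhibition.b,
                       "pi_acs_scale": sc.inhibition.pi_acs_scale,
                       "suppression_eps": sc.inhibition.suppression_eps},
        "habituation": (None if sc.habituation is None else
                        {"alpha": sc.habituation.alpha,
                         "beta": sc.habituation.beta}),
        "persistent_drives": dict(sc.persistent_drives),
        "seed": sc.seed,
        "max_steps": sc.max_steps,
        "step_length": sc.step_length,
        "eps_goal": sc.eps_goal,
        "acs_t_max": sc.acs_t_max,
        "stop_at_nest": sc.stop_at_nest,
    }


def scenario_from_dict(d: Mapping) -> Scenario:
    route = [RouteLandmarkElement(
        id=lm["id"], catchment_center=Position(*lm["center"]),
        catchment_radius=lm.get("radius", DEFAULT_ROUTE_RADIUS),
        local_angle=lm["local_angle"],
        gates=Gates(source=lm.get("source"), direction=lm["direction"]))
        for lm in d.get("route_landmarks", [])]
    place = [PlaceLandmarkElement(
        id=lm["id"], goal=Position(*lm["goal"]),
        catchment_radius=lm.get("radius", DEFAULT_PLACE_RADIUS),
        signposts=[Position(*s) for s in lm["signposts"]],
        learned_vectors=[PolarVector(a, l)
                         for a, l in lm.get("learned_vectors", [])],
        gates=Gates(source=lm.get("source"), direction=lm["direction"]))
        for lm in d.get("place_landmarks", [])]
    agent_d = d.get("agent")
    agent = None
    if agent_d is not None:
        cv = agent_d.get("current_vector", [0.0, 0.0])
        agent = AgentInit(position=Position(*agent_d["position"]),
                          heading=agent_d.get("heading", 0.0),
                          current_vector=PolarVector(*cv),
                          motivations=dict(agent_d.get("motivations", {})))
    interventions = [Intervention(
        action=iv["action"], step=iv.get("step"),
        after_event=iv.get("after_event"),
        position=(Position(*iv["position"]) if iv.get("position") else None),
        reset_current=iv.get("reset_current", False),
        source=iv.get("source")) for iv in d.get("interventions", [])]
    hab = d.get("habituation")
    return Scenario(
        name=d["name"],
        nest=Position(*d["nest"]),
        food_sources=[FoodSource(s["id"], Position(*s["position"]),
                                 s.get("has_food", True))
                      for s in d.get("food_sources", [])],
        route_landmarks=route,
        place_landmarks=place,
        reference_vectors={sid: PolarVector(a, l) for sid, (a, l)
                           in d.get("reference_vectors", {}).items()},
        agent=agent,
        interventions=interventions,
        motivation_weights=MotivationWeights.from_config(
            d.get("motivation_weights", {})),
        inhibition=InhibitionConfig.from_config(d.get("inhibition", {})),
        habituation=None if hab is None else HabituationParams(**hab),
        persistent_drives=dict(d.get("persistent_drives", {})),
        seed=d.get("seed", 0),
        max_steps=d.get("max_steps", 500),
        step_length=d.get("step_length", 10.0),
        eps_goal=d.get("eps_goal", 10.0),
        acs_t_max=d.get("acs_t_max", 500),
        stop_at_nest=d.get("stop_at_nest", True),
    )


def save_scenario(sc: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
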