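"""Recurrent motivation network: behaviour selection by mutual inhibition.

Eight motivation units, organised as four mutually inhibitory pairs,

    (stay, forage), (sourceA, sourceB), (outbound, inbound), (ACSon, ACSoff),

gate every procedural memory in the architecture.  Each unit holds an
activation in [0, 1].  Within a pair the units inhibit each other, so
after the network has relaxed to an attractor only one unit of each pair
is active — a winner-take-all decision.  ``forage`` excites its four
child units (source and direction choices) and receives weak excitation
back from them, so the foraging context keeps its sub-decisions alive
and switching ``stay`` on collapses the whole foraging branch.

The ACSon/ACSoff pair is special: ACSon must *track* the graded search
gain f(d, t) (its activation multiplies the random generator's output
length), so these two units carry no self-excitation — they follow their
drives, rectified through the mutual inhibition.  ACSoff is driven by
the summed salience of all landmark elements and shuts the search down
the moment any landmark is recognized.

An optional habituation process on the inhibitory connections weakens an
edge while its presynaptic unit stays active.  With both ``inbound`` and
``outbound`` driven at once this turns the bistable pair into an
oscillator — the mechanism invoked for bees that alternate between
heading to the feeder and heading home.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import RngStream

UNITS: tuple[str, ...] = (
    "stay", "forage", "sourceA", "sourceB",
    "outbound", "inbound", "ACSon", "ACSoff",
)
UNIT_INDEX: dict[str, int] = {name: i for i, name in enumerate(UNITS)}

PAIRS: tuple[tuple[str, str], ...] = (
    ("stay", "forage"),
    ("sourceA", "sourceB"),
    ("outbound", "inbound"),
    ("ACSon", "ACSoff"),
)

#: activation above this counts as "motivation active" for gating
GATE_THRESHOLD = 0.5

#: magnitude of the seeded tie-breaking noise added to event drives
TIE_NOISE = 1e-6


@dataclass
class MotivationWeights:
    """Connection weights of the motivation network.

    The architecture (which units pair up, which excite which) is fixed;
    the magnitudes are free parameters.  Defaults: self-excitation 1.0
    for the top-level pair, 0.8 for the source/direction pairs (so they
    need the foraging context to sustain themselves), 0.0 for the
    gain-tracking ACS pair; pair inhibition -1.2 (strong enough for
    winner-take-all against any self-coupling); forage->child +0.3 and
    child->forage +0.1.
    """

    self_excitation: Mapping[str, float] = field(default_factory=lambda: {
        "stay": 1.0, "forage": 1.0,
        "sourceA": 0.8, "sourceB": 0.8,
        "outbound": 0.8, "inbound": 0.8,
        "ACSon": 0.0, "ACSoff": 0.0,
    })
    pair_inhibition: float = -1.2
    forage_to_child: float = 0.3
    child_to_forage: float = 0.1
    #: children that exchange excitation with forage (the ACS pair is
    #: instead gated by forage on its sensory drives; see drives_from_events)
    children: Sequence[str] = ("sourceA", "sourceB", "outbound", "inbound")

    def __post_init__(self) -> None:
        if self.pair_inhibition >= 0:
            raise ValueError("pair inhibition must be negative")
        if self.forage_to_child < 0 or self.child_to_forage < 0:
            raise ValueError("excitatory weights must be positive")

    def matrix(self) -> np.ndarray:
        """Dense weight matrix W with W[post, pre]."""
        n = len(UNITS)
        W = np.zeros((n, n))
        for name, w in self.self_excitation.items():
            i = UNIT_INDEX[name]
            W[i, i] = w
        for a, b in PAIRS:
            i, j = UNIT_INDEX[a], UNIT_INDEX[b]
            W[i, j] = self.pair_inhibition
            W[j, i] = self.pair_inhibition
        f = UNIT_INDEX["forage"]
        for child in self.children:
            c = UNIT_INDEX[child]
            W[c, f] = self.forage_to_child
            W[f, c] = self.child_to_forage
        return W

    @classmethod
    def from_config(cls, cfg: Mapping) -> "MotivationWeights":
        kwargs = {}
        for key in ("self_excitation", "pair_inhibition",
                    "forage_to_child", "child_to_forage"):
            if key in cfg:
                kwargs[key] = cfg[key]
        return cls(**kwargs)


@dataclass
class HabituationParams:
    """Habituation of inhibitory edges: h -> h + alpha*a_pre*(1-h) - beta*h.

    The decay rate beta must let an edge recover during its presynaptic
    unit's silent half-cycle, or the pair locks into a both-active state
    once both edges have habituated; beta around 0.4*alpha sustains the
    alternation for symmetric drives of moderate strength.
    """

    alpha: float = 0.05
    beta: float = 0.02


@dataclass
class MotivationState:
    """Activations of the eight units plus habituation of inhibitory edges."""

    activations: np.ndarray = field(
        default_factory=lambda: np.zeros(len(UNITS)))
    #: habituation level per inhibitory edge, keyed (pre, post); only
    #: used when the oscillation variant is enabled
    habituation: dict[tuple[str, str], float] = field(default_factory=dict)

    def __getitem__(self, unit: str) -> float:
        return float(self.activations[UNIT_INDEX[unit]])

    def set(self, unit: str, value: float) -> None:
        self.activations[UNIT_INDEX[unit]] = np.clip(value, 0.0, 1.0)

    def is_active(self, unit: str, threshold: float = GATE_THRESHOLD) -> bool:
        return self[unit] >= threshold

    def selected_source(self) -> str | None:
        """Id of the food source currently above gate threshold, if any."""
        if self.is_active("sourceA"):
            return "A"
        if self.is_active("sourceB"):
            return "B"
        return None

    def copy(self) -> "MotivationState":
        return MotivationState(self.activations.copy(),
                               dict(self.habituation))

    def as_dict(self) -> dict[str, float]:
        return {u: float(self.activations[i]) for i, u in enumerate(UNITS)}

    @classmethod
    def from_dict(cls, activations: Mapping[str, float],
                  habituation: Mapping | None = None) -> "MotivationState":
        state = cls()
        for unit, value in activations.items():
            state.set(unit, value)
        if habituation:
            state.habituation = {tuple(k.split("->")) if isinstance(k, str)
                                 else tuple(k): v
                                 for k, v in habituation.items()}
        return state


def _inhibitory_edges() -> list[tuple[str, str]]:
    edges = []
    for a, b in PAIRS:
        edges.append((a, b))
        edges.append((b, a))
    return edges


def motivation_step(state: MotivationState,
                    weights: MotivationWeights,
                    drives: Mapping[str, float] | np.ndarray | None = None,
                    habituation: HabituationParams | None = None,
                    ) -> MotivationState:
    """One synchronous update of all units.

    a(t+1) = clip01( W a(t) + drive ).  With *habituation* given, every
    inhibitory weight (pre -> post) is scaled by (1 - h[pre, post]) and
    the habituation levels are advanced one step.
    """
    drive_vec = _as_drive_vector(drives)
    W = weights.matrix()
    hab = dict(state.habituation)
    if habituation is not None:
        for pre, post in _inhibitory_edges():
            h = hab.get((pre, post), 0.0)
            W[UNIT_INDEX[post], UNIT_INDEX[pre]] *= (1.0 - h)
    a = np.clip(W @ state.activations + drive_vec, 0.0, 1.0)
    if habituation is not None:
        for pre, post in _inhibitory_edges():
            h = hab.get((pre, post), 0.0)
            a_pre = float(state.activations[UNIT_INDEX[pre]])
            hab[(pre, post)] = h + habituation.alpha * a_pre * (1.0 - h) \
                - habituation.beta * h
    return MotivationState(a, hab)


@dataclass
class RelaxResult:
    state: MotivationState
    converged: bool
    iterations: int
    ties: list[tuple[str, str]] = field(default_factory=list)


def relax(state: MotivationState,
          weights: MotivationWeights,
          drives: Mapping[str, float] | np.ndarray | None = None,
          tol: float = 1e-9,
          max_iters: int = 500,
          habituation: HabituationParams | None = None) -> RelaxResult:
    """Iterate the update until the network settles into an attractor.

    Drives are held constant throughout the relaxation (they model a
    sensory stimulus present while the decision is being made).  Returns
    the final state, a convergence flag and any unresolved ties — an
    exactly symmetric pair sits on an unstable fixed point and is
    reported as non-converged.  With habituation enabled the inbound/
    outbound pair may never settle (it oscillates); callers wanting the
    oscillation should step the network once per behavioural step
    instead of relaxing it.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    current = state
    converged = False
    iterations = 0
    for iterations in range(1, max_iters + 1):
        nxt = motivation_step(current, weights, drives, habituation)
        delta = float(np.max(np.abs(nxt.activations - current.activations)))
        current = nxt
        if delta < tol:
            converged = True
            break
    ties = []
    for a, b in PAIRS:
        va, vb = current[a], current[b]
        if abs(va - vb) < 10 * tol and max(va, vb) > 10 * tol:
            ties.append((a, b))
    if ties:
        converged = False
    return RelaxResult(current, converged, iterations, ties)


#: additive drive magnitude of a discrete behavioural event; strong
#: enough to flip a bistable pair out of its current attractor
EVENT_DRIVE = 1.5


def apply_event(event: Mapping[str, object],
                forage_active: bool = True,
                rng: RngStream | None = None) -> dict[str, float]:
    """Translate discrete events and continuous signals into unit drives.

    Recognized keys: ``start_foraging``, ``left_nest``, ``food_found``,
    ``food_absent_at`` (value: source id), ``entered_nest``,
    ``landmark_sum`` (summed landmark saliences -> ACSoff),
    ``acs_gain`` (search gain f(d,t) -> ACSon),
    ``drive_outbound``/``drive_inbound`` (persistent extra drives, used
    by the habituation scenarios).  The ACS drives only pass while the
    foraging context is active.  If *rng* is given, seeded noise of
    magnitude 1e-6 is added to break exact ties.
    """
    drives: dict[str, float] = {}

    def add(unit: str, value: float) -> None:
        drives[unit] = drives.get(unit, 0.0) + value

    for key, value in event.items():
        if key == "start_foraging":
            add("forage", EVENT_DRIVE)
        elif key == "left_nest":
            add("outbound", EVENT_DRIVE)
        elif key == "food_found":
            add("inbound", EVENT_DRIVE)
        elif key == "food_absent_at":
            add(f"source{value}", -EVENT_DRIVE)
        elif key == "entered_nest":
            add("stay", EVENT_DRIVE)
        elif key == "landmark_sum":
            if forage_active:
                add("ACSoff", float(value))
        elif key == "acs_gain":
            if forage_active:
                add("ACSon", float(value))
        elif key == "drive_outbound":
            add("outbound", float(value))
        elif key == "drive_inbound":
            add("inbound", float(value))
        elif key == "select_source":
            add(f"source{value}", EVENT_DRIVE)
        else:
            raise KeyError(f"unknown event {key!r}")

    if rng is not None and drives:
        # seeded tie-break noise on every decision unit: an exactly
        # symmetric pair (an unstable fixed point) must be nudged off
        # it.  The ACS pair is exempt — it carries continuous sensory
        # signals, not a discrete decision, and without self-excitation
        # a symmetric positive nudge puts its synchronous update on a
        # rectified two-cycle.
        for unit in ("stay", "forage", "sourceA", "sourceB",
                     "outbound", "inbound"):
            drives[unit] = drives.get(unit, 0.0) + \
                rng.draw_uniform(-TIE_NOISE, TIE_NOISE)
    return drives


def _as_drive_vector(drives) -> np.ndarray:
    if drives is None:
        return np.zeros(len(UNITS))
    if isinstance(drives, np.ndarray):
        return drives
    vec = np.zeros(len(UNITS))
    for unit, value in drives.items():
        vec[UNIT_INDEX[unit]] = value
    return vec
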