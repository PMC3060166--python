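"""Arbitration: lateral inhibition over saliences and the final summation.

The procedures do not take turns by a central schedule; they compete.
Their vector lengths (saliences) pass through a one-layered feedforward
lateral inhibition network organised in two separate pools:

* the *landmark pool* — all route and place elements.  Inhibition is
  symmetric with weight b = -0.4, except that place (food/home)
  elements inhibit route elements without any influence in the opposite
  direction, so a perceived place landmark always outweighs a route
  landmark.
* the *PI/ACS pool* — the path integrator and the random generator.
  Their saliences are first scaled by 0.2 so that any active landmark
  dominates them in the final sum; within the pool the same b applies,
  and near-equal saliences survive as a mixed contribution (this is the
  blend that produces area-concentrated search).

In addition, the summed salience of all landmark elements zeroes the
path integrator's salience outright: while any landmark memory is
active the PI does not contribute at all.

The surviving weighted unit vectors are summed; the angle of the result
is the walking direction.  The network controls direction only — speed
is a fixed 10 length units per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .geometry import EPS_LENGTH, PolarVector, weighted_vector_sum

#: procedure ids reserved for the PI/ACS pool
PI_ID = "PI"
ACS_ID = "rand"

LANDMARK_POOL = "landmark_pool"
PI_ACS_POOL = "pi_acs_pool"


@dataclass
class InhibitionConfig:
    """Arbitration parameters.

    b
        Inhibitory weight of the lateral inhibition network (negative).
    pi_acs_scale
        Factor applied to the PI and random-generator saliences before
        summation, guaranteeing landmark dominance.
    suppression_eps
        Any landmark salience sum above this zeroes the PI salience.
    """

    b: float = -0.4
    pi_acs_scale: float = 0.2
    suppression_eps: float = 1e-9

    def __post_init__(self) -> None:
        if self.b >= 0:
            raise ValueError("inhibitory weight b must be negative")

    @classmethod
    def from_config(cls, cfg: Mapping) -> "InhibitionConfig":
        return cls(**{k: cfg[k] for k in ("b", "pi_acs_scale",
                                          "suppression_eps") if k in cfg})


@dataclass
class ProcedureOutput:
    """One procedure's proposal: a direction and a salience."""

    id: str
    angle: float
    salience: float
    pool: str
    is_place: bool = False  # place landmarks inhibit route landmarks one-way

    def __post_init__(self) -> None:
        if self.salience < 0:
            raise ValueError("salience must be non-negative")


@dataclass
class SalienceBundle:
    """All procedure outputs entering arbitration for one step."""

    entries: list[ProcedureOutput] = field(default_factory=list)

    def add(self, entry: ProcedureOutput) -> None:
        self.entries.append(entry)

    def pool(self, tag: str) -> list[ProcedureOutput]:
        return [e for e in self.entries if e.pool == tag]

    def landmark_salience_sum(self) -> float:
        return sum(e.salience for e in self.pool(LANDMARK_POOL))


def lateral_inhibit(entries: list[ProcedureOutput],
                    config: InhibitionConfig) -> dict[str, float]:
    """One-shot feedforward lateral inhibition within one pool.

    out_i = max(0, s_i + b * sum of s_j over competitors j with an edge
    j -> i).  Within the landmark pool, edges from route elements to
    place elements are absent (one-way dominance); all other within-pool
    edges are symmetric.  Results are rectified at zero.
    """
    weights: dict[str, float] = {}
    for e in entries:
        inhibition = 0.0
        for other in entries:
            if other.id == e.id:
                continue
            if e.is_place and not other.is_place:
                continue  # no route -> place influence
            inhibition += other.salience
        weights[e.id] = max(0.0, e.salience + config.b * inhibition)
    return weights


def suppress_pi(landmark_salience_sum: float, pi_salience: float,
                config: InhibitionConfig | None = None) -> float:
    """Zero the PI salience whenever any landmark memory is active."""
    eps = config.suppression_eps if config is not None else 1e-9
    return 0.0 if landmark_salience_sum > eps else pi_salience


@dataclass
class ArbitrationResult:
    heading: float
    weights: dict[str, float]        # post-inhibition weight per procedure
    total: PolarVector               # the summed motor vector
    winner: str | None               # procedure with the largest weight


def resolve_heading(bundle: SalienceBundle, config: InhibitionConfig,
                    prev_heading: float) -> ArbitrationResult:
    """Run one full arbitration cycle and return the walking direction.

    Pipeline: suppress PI by the landmark salience sum; scale the PI/ACS
    saliences by ``pi_acs_scale``; lateral inhibition separately within
    each pool; weighted vector summation over everything.  If the summed
    vector is degenerate the previous heading is kept (the agent walks
    on rather than stalling on an undefined direction).
    """
    lm_sum = bundle.landmark_salience_sum()

    pi_acs = []
    for e in bundle.pool(PI_ACS_POOL):
        s = e.salience
        if e.id == PI_ID:
            s = suppress_pi(lm_sum, s, config)
        pi_acs.append(ProcedureOutput(e.id, e.angle, s * config.pi_acs_scale,
                                      e.pool))
    landmark = bundle.pool(LANDMARK_POOL)

    weights = lateral_inhibit(landmark, config)
    weights.update(lateral_inhibit(pi_acs, config))

    angles = {e.id: e.angle for e in landmark + pi_acs}
    total = weighted_vector_sum((angles[pid], w) for pid, w in weights.items())
    if total.length < EPS_LENGTH:
        heading = prev_heading
    else:
        heading = total.angle
    winner = None
    if weights:
        best = max(weights, key=lambda pid: weights[pid])
        if weights[best] > 0:
            winner = best
    return ArbitrationResult(heading, weights, total, winner)
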