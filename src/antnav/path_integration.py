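"""Path integration: current vector, reference-vector memories, PI output.

The path integrator keeps a running sum of all active displacements since
the agent last entered the nest (the *current vector*).  When food is
found at a rewarding source the current vector is copied into a long-term
*reference vector* memory for that source.  The PI procedure's output is
the normalized difference ``reference - current``: the compass direction
that closes the gap to the goal.  On inbound trips the reference memories
are gated off, so the effective reference is the zero (nest) vector and
the output points home.

Passive displacement (the experimenter carrying the agent) does not pass
through the integrator, which is what makes the classic capture-and-
release experiments informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import PolarVector

#: below this remaining distance the PI direction is noise-dominated and
#: the output length drops to 0 ("zero-vector" state)
EPS_PI = 1.0


@dataclass
class CurrentVector:
    """Accumulated nest-relative displacement; reset only at nest entry."""

    vector: PolarVector = field(default_factory=PolarVector.zero)

    @property
    def length(self) -> float:
        return self.vector.length

    def copy(self) -> "CurrentVector":
        return CurrentVector(self.vector)


def update_current(current: CurrentVector, displacement: PolarVector) -> CurrentVector:
    """Add one step's active displacement onto the current vector."""
    return CurrentVector(current.vector + displacement)


def reset_current(current: CurrentVector) -> CurrentVector:
    """Zero the integrator; called exactly and only on nest entry."""
    return CurrentVector(PolarVector.zero())


@dataclass
class ReferenceVectorMemory:
    """Long-term store of nest-to-food vectors, one per known source.

    The memory bank persists across trips.  Its output is gated by the
    motivation network: only while the agent is outbound and the matching
    source motivation is active does a stored vector reach the PI stage;
    otherwise the gated output is the zero vector (which is also how the
    homeward "sign reversal" is realized — the goal becomes the nest).
    """

    vectors: dict[str, PolarVector] = field(default_factory=dict)

    def store(self, source_id: str, current: CurrentVector) -> None:
        """Copy the current vector into the memory for *source_id*.

        Triggered by a food-found event at a rewarding source; a repeat
        visit simply overwrites with the fresh value.
        """
        if source_id not in self.vectors:
            raise KeyError(f"unknown food source {source_id!r}")
        self.vectors[source_id] = current.vector

    def gated_output(self, source_id: str | None, outbound_active: bool) -> PolarVector:
        """Reference vector seen by the PI stage under the current gates.

        Zero whenever the outbound motivation is off (inbound: the goal
        is the nest) or no source is selected.
        """
        if not outbound_active or source_id is None:
            return PolarVector.zero()
        if source_id not in self.vectors:
            raise KeyError(f"unknown food source {source_id!r}")
        return self.vectors[source_id]


def pi_discrepancy(reference: PolarVector, current: CurrentVector) -> PolarVector:
    """Raw (un-normalized) PI input: ``reference - current``.

    Its length is the remaining distance to the PI goal; this is also the
    distance signal d that drives the search gain f(d, t).
    """
    return reference - current.vector


def pi_output(reference: PolarVector, current: CurrentVector,
              eps: float = EPS_PI) -> PolarVector:
    """Normalized PI procedure output.

    Unit length in the direction of ``reference - current``; length 0
    when the remaining distance is below *eps* (the zero-vector state,
    which lets the search generator take over).  The simulation loop
    passes the search gain's inner breakpoint d1(t) as *eps*: the PI
    direction counts as noise-dominated exactly while the search gain is
    saturated, so the random walk diffuses freely inside a zone that
    widens with search time — this is what makes the emergent search
    area grow the way real ants' does.
    """
    diff = pi_discrepancy(reference, current)
    if diff.length < eps:
        return PolarVector.zero()
    return PolarVector(diff.angle, 1.0)
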