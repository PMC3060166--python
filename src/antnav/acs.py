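"""Random-turn generator and search gain: emergent area-concentrated search.

No explicit search program exists in the architecture.  Instead a simple
random process proposes, every step, a new heading obtained by turning
the previous heading by an angle drawn uniformly from [-0.3, 0.7] rad —
a counterclockwise-biased turn.  The length of this proposal is the
activation of the ACSon motivation unit, which in turn tracks the gain

    f(d, t) = 1                      for d <= d1(t)
            = (d2(t) - d)/(d2(t) - d1(t))   for d1(t) < d < d2(t)
            = 0                      for d >= d2(t),

where d is the remaining distance signalled by the path integrator (the
length of its raw input, reference minus current vector; for an inbound
agent simply the current-vector length).  The breakpoints start at
d1 = 3.3 and d2 = 20 length units and grow linearly with search time to
their maxima 33 and 200, reflecting ants' widening search with time.
Blending this proposal with the path integrator's pull back toward the
zero point produces looping search centred on the expected goal.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import PolarVector, RngStream

#: uniform turn interval in radians (counterclockwise bias, mean +0.2)
TURN_LOW = -0.3
TURN_HIGH = 0.7

#: gain breakpoints at search onset and their asymptotic maxima (length units)
D1_INITIAL = 3.3
D1_MAX = 33.0
D2_INITIAL = 20.0
D2_MAX = 200.0

#: steps of search time over which the breakpoints reach their maxima
T_MAX_DEFAULT = 500


def draw_turn(rng: RngStream) -> float:
    """One random heading change in radians, uniform on [-0.3, 0.7]."""
    return rng.draw_uniform(TURN_LOW, TURN_HIGH)


def breakpoints(t: float, t_max: float = T_MAX_DEFAULT) -> tuple[float, float]:
    """Gain breakpoints (d1, d2) after *t* steps of searching; both
    interpolate linearly from their initial values to their maxima,
    saturating at t = t_max."""
    if t < 0:
        raise ValueError("search time must be non-negative")
    frac = min(t / t_max, 1.0) if t_max > 0 else 1.0
    d1 = D1_INITIAL + (D1_MAX - D1_INITIAL) * frac
    d2 = D2_INITIAL + (D2_MAX - D2_INITIAL) * frac
    return d1, d2


def acs_gain(d: float, t: float, t_max: float = T_MAX_DEFAULT) -> float:
    """Search gain in [0, 1] for PI distance *d* and search time *t*."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    d1, d2 = breakpoints(t, t_max)
    if d <= d1:
        return 1.0
    if d >= d2:
        return 0.0
    return (d2 - d) / (d2 - d1)


@dataclass
class AcsState:
    """Search bookkeeping: how long the current search has been running
    and the heading the next random turn is applied to."""

    search_timer: int | None = None  # None while no search is running
    prev_heading: float = 0.0

    @property
    def timer(self) -> float:
        return 0.0 if self.search_timer is None else float(self.search_timer)

    def tick(self, searching: bool) -> None:
        """Advance the timer while the ACSon gate passes; a pause keeps
        the accumulated time (the search resumes where it left off)."""
        if searching:
            self.search_timer = 0 if self.search_timer is None \
                else self.search_timer + 1

    def reset(self) -> None:
        """Called on nest entry or when a landmark is perceived."""
        self.search_timer = None

    def copy(self) -> "AcsState":
        return AcsState(self.search_timer, self.prev_heading)


def acs_output(state: AcsState, rng: RngStream,
               acs_on_activation: float) -> PolarVector:
    """The random generator's proposal for this step.

    A fresh turn is drawn relative to the previous heading; the vector
    length is the ACSon activation (zero activation silences the
    generator without consuming a draw, keeping runs reproducible across
    scenarios that never search).
    """
    if acs_on_activation <= 0.0:
        return PolarVector.zero()
    angle = state.prev_heading + draw_turn(rng)
    return PolarVector(angle, min(acs_on_activation, 1.0))
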