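"""Geometry primitives shared by all navigation procedures.

Every procedural memory in the architecture communicates with the motor
stage through the same currency: a compass direction plus a non-negative
vector length (the "salience").  The world frame is Cartesian internally,
with compass angles measured counter-clockwise from the +x axis ("east"
is 0, "north" is pi/2).  Angles are always normalized to (-pi, pi].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: lengths below this are treated as "no direction"
EPS_LENGTH = 1e-9


def normalize_angle(angle: float) -> float:
    """Wrap *angle* (radians) into the interval (-pi, pi]."""
    a = math.remainder(angle, 2.0 * math.pi)
    if a <= -math.pi:
        a += 2.0 * math.pi
    return a


@dataclass(frozen=True)
class Position:
    """Cartesian world coordinates in length units."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite position ({self.x}, {self.y})")

    def distance_to(self, other: "Position") -> float:
        return math.hypot(other.x - self.x, other.y - self.y)

    def displaced(self, angle: float, length: float) -> "Position":
        """Position reached by walking *length* units along compass *angle*."""
        return Position(self.x + length * math.cos(angle),
                        self.y + length * math.sin(angle))

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class PolarVector:
    """A compass direction with a non-negative length.

    Used both for spatial vectors (length in length units) and for the
    normalized outputs of procedural memories (length = salience).
    A zero-length vector has its angle reported as 0 by convention;
    callers must treat ``length < EPS_LENGTH`` as "no direction".
    """

    angle: float
    length: float

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"negative vector length {self.length}")
        object.__setattr__(self, "angle", normalize_angle(self.angle))

    @classmethod
    def zero(cls) -> "PolarVector":
        return cls(0.0, 0.0)

    @classmethod
    def from_xy(cls, x: float, y: float) -> "PolarVector":
        length = math.hypot(x, y)
        if length < EPS_LENGTH:
            return cls(0.0, 0.0)
        return cls(math.atan2(y, x), length)

    @classmethod
    def between(cls, p: Position, q: Position) -> "PolarVector":
        """Displacement vector from *p* to *q*."""
        return cls.from_xy(q.x - p.x, q.y - p.y)

    @property
    def x(self) -> float:
        return self.length * math.cos(self.angle)

    @property
    def y(self) -> float:
        return self.length * math.sin(self.angle)

    def __add__(self, other: "PolarVector") -> "PolarVector":
        return PolarVector.from_xy(self.x + other.x, self.y + other.y)

    def __sub__(self, other: "PolarVector") -> "PolarVector":
        return PolarVector.from_xy(self.x - other.x, self.y - other.y)

    def scaled(self, factor: float) -> "PolarVector":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return PolarVector(self.angle, self.length * factor)

    def normalized(self) -> "PolarVector":
        """Unit-length copy; the zero vector stays zero."""
        if self.length < EPS_LENGTH:
            return PolarVector.zero()
        return PolarVector(self.angle, 1.0)


def weighted_vector_sum(entries: Iterable[tuple[float, float]]) -> PolarVector:
    """Sum unit vectors at given angles, each scaled by its weight.

    This is the final summation of the motor output stage: every active
    procedure contributes a unit direction weighted by its post-inhibition
    salience.  An empty list (or perfect cancellation) yields the zero
    vector.

    Parameters
    ----------
    entries
        Iterable of ``(angle_radians, weight)`` with weight >= 0.
    """
    sx = 0.0
    sy = 0.0
    for angle, weight in entries:
        if weight < 0:
            raise ValueError(f"negative weight {weight}")
        sx += weight * math.cos(angle)
        sy += weight * math.sin(angle)
    return PolarVector.from_xy(sx, sy)


def angle_between(p: Position, q: Position) -> float:
    """Compass angle of the vector from *p* to *q*.

    Raises ``ValueError`` for coincident points, where the direction is
    degenerate.
    """
    dx, dy = q.x - p.x, q.y - p.y
    if math.hypot(dx, dy) < EPS_LENGTH:
        raise ValueError("degenerate direction: p == q")
    return math.atan2(dy, dx)


class RngStream:
    """Seeded random stream; one per simulation run.

    Thin wrapper over :class:`numpy.random.Generator` exposing only the
    draws the model needs, plus state (de)serialization so that a
    checkpointed world restores bit-for-bit.
    """

    def __init__(self, seed: int | None = None):
        self.seed = seed
        self._gen = np.random.default_rng(seed)

    def draw_uniform(self, a: float, b: float) -> float:
        return float(self._gen.uniform(a, b))

    def state(self) -> dict:
        return self._gen.bit_generator.state

    def set_state(self, state: dict) -> None:
        self._gen.bit_generator.state = state

    @classmethod
    def from_state(cls, seed: int | None, state: dict) -> "RngStream":
        rng = cls(seed)
        rng.set_state(state)
        return rng
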