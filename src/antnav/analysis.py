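"""Post-hoc trajectory analysis: search statistics and batch running.

The search-walk statistics mirror the standard descriptors for
area-concentrated search in ants: the distance-to-release-point time
series (whose envelope grows as the search widens) and the radial
density profile of visited positions, averaged over repeated searches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Scenario, Simulation, TrajectoryLog
from .geometry import Position

#: default radial bin width in length units (one step)
DEFAULT_BIN_WIDTH = 10.0


@dataclass
class DistanceSeries:
    """Per-step Euclidean distance to a reference point."""

    steps: np.ndarray
    distances: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": self.steps, "distance": self.distances})

    def envelope(self, window: int = 100) -> np.ndarray:
        """Maximum distance per consecutive window of *window* steps."""
        n = len(self.distances)
        return np.array([self.distances[i:i + window].max()
                         for i in range(0, n, window)])


@dataclass
class SearchProfile:
    """Normalized radial visit-density histogram, averaged over paths."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_paths: int

    def peak_bin(self) -> int:
        return int(np.argmax(self.density))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_low": self.bin_edges[:-1],
                             "bin_high": self.bin_edges[1:],
                             "density": self.density})


def distance_series(log: TrajectoryLog, origin: Position) -> DistanceSeries:
    """Distance to *origin* at every logged step."""
    if len(log) == 0:
        raise ValueError("empty trajectory log")
    steps = np.array([r["step"] for r in log.records])
    dist = np.array([math.hypot(r["x"] - origin.x, r["y"] - origin.y)
                     for r in log.records])
    return DistanceSeries(steps, dist)


def density_profile(logs: list[TrajectoryLog], origin: Position,
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    per_area: bool = False) -> SearchProfile:
    """Radial histogram of per-step distances, pooled over paths.

    With ``per_area=False`` the profile is the fraction of all logged
    steps falling in each radial bin.  With ``per_area=True`` each bin's
    count is divided by the area of its annulus before normalizing —
    the search-density-per-unit-area profile that field studies of
    searching ants report (a searcher that covered every annulus for an
    equal time would then show a falling profile, not a flat one).
    Densities are >= 0 and sum to 1 in both conventions, and the result
    is invariant to the order of the logs.
    """
    if not logs:
        raise ValueError("need at least one trajectory log")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    all_d = [distance_series(log, origin).distances for log in logs]
    dmax = max(float(d.max()) for d in all_d)
    n_bins = max(1, int(math.ceil((dmax + 1e-9) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for d in all_d:
        h, _ = np.histogram(d, bins=edges)
        counts += h
    if per_area:
        annulus = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        counts = counts / annulus
    density = counts / counts.sum()
    return SearchProfile(edges, density, n_paths=len(logs))


def batch_run(scenario: Scenario, seeds: list[int]) -> list[TrajectoryLog]:
    """Independent runs of *scenario*, one per seed."""
    if len(seeds) != len(set(seeds)):
        raise ValueError("seeds must be distinct")
    return [Simulation(scenario, seed).run() for seed in seeds]


# -- plotting (conveniences mirroring the published figure style) ------

def plot_trajectory(log: TrajectoryLog, scenario: Scenario | None = None,
                    ax=None):
    """Trajectory map with catchment circles; outbound steps red,
    inbound steps blue, as in the published figures."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    if scenario is not None:
        ax.plot(scenario.nest.x, scenario.nest.y, marker="s", color="gold",
                markersize=10, zorder=5)
        for s in scenario.food_sources:
            ax.plot(s.position.x, s.position.y, marker="*", color="green",
                    markersize=12, zorder=5)
        for lm in scenario.route_landmarks:
            color = "red" if lm.gates.direction == "outbound" else "blue"
            ax.add_patch(Circle(lm.catchment_center.as_tuple(),
                                lm.catchment_radius, fill=False,
                                edgecolor=color, alpha=0.6))
        for lm in scenario.place_landmarks:
            color = "gold" if lm.gates.source is None else "green"
            ax.add_patch(Circle(lm.goal.as_tuple(), lm.catchment_radius,
                                fill=False, edgecolor=color, alpha=0.8))
    for r in log.records:
        outbound = r["activations"].get("outbound", 0) >= 0.5
        ax.plot(r["x"], r["y"], marker="s", markersize=2.5,
                color="red" if outbound else "blue")
    ax.set_aspect("equal")
    ax.set_xlabel("x [length units]")
    ax.set_ylabel("y [length units]")
    return ax


def plot_distance_series(series: DistanceSeries, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.steps, series.distances, lw=0.8)
    ax.set_xlabel("time [steps]")
    ax.set_ylabel("distance d [length units]")
    return ax


def plot_density_profile(profile: SearchProfile, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
    width = profile.bin_edges[1] - profile.bin_edges[0]
    ax.bar(centers, profile.density, width=width * 0.9)
    ax.set_xlabel("distance from origin [length units]")
    ax.set_ylabel(f"visit density (n = {profile.n_paths} paths)")
    return ax
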