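"""Trajectory statistics discriminating the behavioural hypotheses.

These operate on departure records, chase events, trajectory tables
and behavioural-event tables — whether produced by the simulator or
read from external CSV files in the same schemas:

- departure synchrony and steepness separate independent from
  copying-driven foraging departures;
- chase onset gaps and direction correlations (in
  :mod:`leksim.intruder`) separate independent from coordinated
  territory defence;
- occupancy and aggression heatmaps with a rank-correlation
  association test the harassment-avoidance signature: females
  spending less time where male aggression concentrates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import Role, Territory, TrajectorySet
from .errors import SchemaError, UndefinedMetricError
from .foraging import DepartureRecord

#: Ethogram codes for behavioural events: resting, walking/marking,
#: display/courtship, chasing, tactile fights, parallel walks.
ETHOGRAM_CODES = ("R", "W", "D", "C", "F", "P")

#: Default aggression codes: chases and tactile fights.
AGGRESSION_CODES = frozenset({"C", "F"})

EVENT_COLUMNS = ("tick", "actor_id", "behaviour_code", "x", "y")


class HeatmapKind(str, Enum):
    OCCUPANCY_TIME = "occupancy_time"
    EVENT_COUNT = "event_count"


@dataclass
class GridSpec:
    """Geometry of a rectangular analysis grid."""

    x_min: float
    y_min: float
    cell_size: float
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid must have at least one cell per axis")

    @classmethod
    def from_territories(
        cls, territories: Sequence[Territory], n_cells: int = 20
    ) -> "GridSpec":
        """Square grid over the territory bounding box padded by one
        territory radius, ``n_cells`` cells per axis (the default
        analysis grid)."""
        C = np.array([t.centre for t in territories], dtype=float)
        pad = max(t.radius for t in territories)
        x_min, y_min = C.min(axis=0) - pad
        x_max, y_max = C.max(axis=0) + pad
        cell = max(x_max - x_min, y_max - y_min) / n_cells
        return cls(float(x_min), float(y_min), float(cell), n_cells, n_cells)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ix, iy, in_bounds) for arrays of coordinates."""
        ix = np.floor((np.asarray(x, dtype=float) - self.x_min) / self.cell_size).astype(int)
        iy = np.floor((np.asarray(y, dtype=float) - self.y_min) / self.cell_size).astype(int)
        ok = (ix >= 0) & (ix < self.n_x) & (iy >= 0) & (iy < self.n_y)
        return ix, iy, ok


@dataclass
class HeatmapGrid:
    """A dense grid of occupancy time or event counts.

    ``values[iy, ix]`` covers the cell with lower-left corner
    ``(x_min + ix*cell_size, y_min + iy*cell_size)``.  Points falling
    outside the grid are accumulated in ``overflow`` rather than
    dropped, so grid total + overflow conserves the input mass.
    """

    spec: GridSpec
    values: np.ndarray
    kind: HeatmapKind
    overflow: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_y, self.spec.n_x):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.n_y}, {self.spec.n_x})"
            )
        if (self.values < 0).any():
            raise ValueError("heatmap values must be nonnegative")

    def same_geometry(self, other: "HeatmapGrid") -> bool:
        return self.spec == other.spec

    @property
    def total(self) -> float:
        return float(self.values.sum() + self.overflow)


# ---------------------------------------------------------------------------
# departure statistics


def departure_synchrony(
    departures: Sequence[DepartureRecord], w: int
) -> Tuple[float, bool]:
    """Fraction of neighbour departure pairs within ``w`` ticks.

    A pair (i, j) counts as a neighbour pair if either was in the
    other's copying neighbourhood when it departed.  Returns
    ``(fraction, used_neighbour_pairs)``; when no neighbour pair
    exists the fraction is computed over all pairs and the flag is
    False.  Undefined with fewer than two departures.
    """
    if w < 0:
        raise ValueError("window w must be >= 0")
    deps = list(departures)
    if len(deps) < 2:
        raise UndefinedMetricError("departure_synchrony needs >= 2 departures")
    pairs = []
    for a, b in combinations(deps, 2):
        nb_a = a.neighbours_at_departure or frozenset()
        nb_b = b.neighbours_at_departure or frozenset()
        if a.agent_id in nb_b or b.agent_id in nb_a:
            pairs.append((a, b))
    used_neighbours = bool(pairs)
    if not pairs:
        pairs = list(combinations(deps, 2))
    close = sum(1 for a, b in pairs if abs(a.departure_tick - b.departure_tick) <= w)
    return close / len(pairs), used_neighbours


def departure_steepness(
    departures: Sequence[DepartureRecord], n_males: int, w: int
) -> float:
    """Peak fraction of the lek departing within any ``w``-tick window.

    max over t of |{departures in [t, t+w]}| / n_males — the height of
    the steepest rise of the forager count curve.  Zero with no
    departures.
    """
    if n_males < 1:
        raise ValueError("n_males must be >= 1")
    if w < 0:
        raise ValueError("window w must be >= 0")
    ticks = sorted(d.departure_tick for d in departures)
    if not ticks:
        return 0.0
    arr = np.asarray(ticks)
    # a maximising window can always start at a departure tick
    best = max(int(((arr >= t) & (arr <= t + w)).sum()) for t in set(ticks))
    return best / n_males


# ---------------------------------------------------------------------------
# heatmaps


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check an event table against the ethogram schema."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"event table missing columns {missing}")
    bad = ~events["behaviour_code"].isin(ETHOGRAM_CODES)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0]) + 1
        raise SchemaError(
            f"row {row}: unknown behaviour code "
            f"{events['behaviour_code'].iloc[row - 1]!r} (expected one of {ETHOGRAM_CODES})"
        )
    return events


def occupancy_heatmap(
    traj: TrajectorySet, spec: GridSpec, role: Role = Role.FEMALE
) -> HeatmapGrid:
    """Accumulate agent-ticks of one role into grid cells (Δt = 1).

    Every row of the filtered trajectory contributes one unit of
    occupancy time to the cell containing its position, or to the
    overflow bucket if outside the grid.
    """
    frame = traj.frame
    sub = frame[frame["role"] == Role(role).name]
    values = np.zeros((spec.n_y, spec.n_x))
    ix, iy, ok = spec.cell_index(sub["x"].to_numpy(), sub["y"].to_numpy())
    np.add.at(values, (iy[ok], ix[ok]), 1.0)
    return HeatmapGrid(
        spec=spec,
        values=values,
        kind=HeatmapKind.OCCUPANCY_TIME,
        overflow=float((~ok).sum()),
    )


def aggression_heatmap(
    events: pd.DataFrame, spec: GridSpec, codes: Set[str] = AGGRESSION_CODES
) -> HeatmapGrid:
    """Count behavioural events with the given codes per grid cell."""
    unknown = set(codes) - set(ETHOGRAM_CODES)
    if unknown:
        raise ValueError(f"unknown behaviour codes in filter: {sorted(unknown)}")
    validate_events(events)
    sub = events[events["behaviour_code"].isin(codes)]
    values = np.zeros((spec.n_y, spec.n_x))
    ix, iy, ok = spec.cell_index(sub["x"].to_numpy(), sub["y"].to_numpy())
    np.add.at(values, (iy[ok], ix[ok]), 1.0)
    return HeatmapGrid(
        spec=spec, values=values, kind=HeatmapKind.EVENT_COUNT, overflow=float((~ok).sum())
    )


def heatmap_association(a: HeatmapGrid, b: HeatmapGrid) -> Tuple[float, int]:
    """Spearman rank correlation between two heatmaps.

    Computed across the informative cells (a + b > 0); zero-everywhere
    cells carry no information and would dilute the rank statistic.
    A negative value on (female occupancy, male aggression) is the
    harassment-avoidance signature.  Returns (rho, n_cells_used).
    """
    if not a.same_geometry(b):
        raise ValueError("heatmap geometry mismatch")
    va = a.values.reshape(-1)
    vb = b.values.reshape(-1)
    mask = (va + vb) > 0
    n = int(mask.sum())
    if n < 3:
        raise UndefinedMetricError(
            f"only {n} informative cells; association undefined"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = stats.spearmanr(va[mask], vb[mask])
    if np.isnan(rho):
        raise UndefinedMetricError("constant ranks; association undefined")
    return float(rho), n
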