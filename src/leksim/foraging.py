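"""Foraging departures from a settled lek.

During a foraging activity window each lekking male may switch to a
foraging state, travel to the foraging site, and return.  Two switch
rules are compared:

- ``INDEPENDENT``: each lekking male switches with probability
  ``p_f`` per tick, regardless of anyone else — departure times are
  i.i.d. geometric.
- ``SOCIAL``: the per-tick switch probability is
  ``clip(p_spont + k_copy * n, 0, 1)`` where ``n`` is the number of
  foraging males within ``R_social`` at the previous tick.  Copying
  produces cascades: departures cluster in time and space.

Travelling males head straight to the foraging site (same
constant-speed, noisy-heading kinematics as the site-fidelity rule),
switch to returning on arrival, and head back to the breeding centre
with no social interactions en route.  Each male completes at most one
foraging episode per activity window.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import FrozenSet, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import (
    BehaviouralState,
    Role,
    SimulationState,
    TrajectorySet,
    frame_from_arrays,
    repulsion_velocity,
    step_towards,
)
from .params import ModelParams


class ForagingModel(str, Enum):
    INDEPENDENT = "independent"
    SOCIAL = "social"


@dataclass
class DepartureRecord:
    """One male's foraging episode within an activity window.

    ``neighbours_at_departure`` holds the ids of all residents within
    ``R_social`` of the departer one tick before it left.  Records
    read back from the departure CSV carry only the neighbour count
    (``neighbours_at_departure`` is None there).
    """

    agent_id: int
    departure_tick: int
    return_tick: Optional[int]
    neighbours_at_departure: Optional[FrozenSet[int]] = None
    n_neighbours: Optional[int] = None

    def __post_init__(self) -> None:
        if self.neighbours_at_departure is not None:
            self.neighbours_at_departure = frozenset(self.neighbours_at_departure)
            if self.n_neighbours is None:
                self.n_neighbours = len(self.neighbours_at_departure)
        if self.n_neighbours is None:
            self.n_neighbours = 0
        if self.return_tick is not None and self.return_tick <= self.departure_tick:
            raise ValueError("return_tick must exceed departure_tick")


def switch_probability(
    n_foraging_neighbours: int, model: ForagingModel, params: ModelParams
) -> float:
    """Per-tick probability that a lekking male switches to foraging."""
    if n_foraging_neighbours < 0:
        raise ValueError(
            f"n_foraging_neighbours must be >= 0, got {n_foraging_neighbours}"
        )
    model = ForagingModel(model)
    if model is ForagingModel.INDEPENDENT:
        return params.p_f
    return min(1.0, params.p_spont + params.k_copy * n_foraging_neighbours)


def foraging_step(agent, params: ModelParams, rng: np.random.Generator) -> np.ndarray:
    """Displacement of a travelling male: towards the foraging site
    while FORAGING_OUT, towards the breeding centre while RETURNING.
    Same noisy constant-speed kinematics as the attraction rule; no
    repulsion or copying en route.
    """
    if agent.behavioural_state == BehaviouralState.FORAGING_OUT:
        target = np.asarray(params.foraging_site)
    elif agent.behavioural_state == BehaviouralState.RETURNING:
        target = np.asarray(params.centre)
    else:
        raise ValueError(
            f"foraging_step applies to FORAGING_OUT/RETURNING agents, "
            f"got {BehaviouralState(agent.behavioural_state).name}"
        )
    noise = float(rng.normal(0.0, params.noise_sd)) if params.noise_sd > 0 else 0.0
    return step_towards(agent.position, target, params.speed, params.arrival_tol, noise)


def run_foraging_episode(
    lek_state: SimulationState,
    model: ForagingModel,
    params: ModelParams,
    seed: int,
    record: bool = True,
) -> Tuple[Optional[TrajectorySet], List[DepartureRecord]]:
    """Simulate one foraging activity window on a settled lek.

    Starts from ``lek_state`` (all residents LEKKING) and runs
    ``episode_steps`` ticks.  Each tick, every lekking male that has
    not yet completed an episode evaluates :func:`switch_probability`
    against the previous tick's foraging-neighbour count; switched
    males travel out and back.  Males still lekking keep following the
    fidelity+repulsion rules (with lekking males only as repulsion
    neighbours — travellers are socially invisible).

    The RNG stream consumes one switch-uniform and one heading-noise
    draw per agent per tick in ascending id order, independent of the
    rule outcomes, so runs with ``k_copy = 0`` reproduce the
    independent model draw-for-draw when ``p_spont = p_f``.

    Returns the trajectory (or None when ``record=False``) and one
    :class:`DepartureRecord` per departed male.
    """
    model = ForagingModel(model)
    if not np.all(lek_state.states == BehaviouralState.LEKKING):
        raise ValueError("run_foraging_episode requires all agents LEKKING")
    if not np.all(lek_state.roles == Role.RESIDENT_MALE):
        raise ValueError("run_foraging_episode expects resident males only")

    rng = np.random.default_rng(seed)
    n = lek_state.n
    ids = lek_state.ids.copy()
    pos = lek_state.positions.copy()
    states = np.full(n, BehaviouralState.LEKKING, dtype=np.int64)
    completed = np.zeros(n, dtype=bool)
    departed = np.zeros(n, dtype=bool)
    dep_tick = np.full(n, -1, dtype=np.int64)
    ret_tick = np.full(n, -1, dtype=np.int64)
    dep_neighbours: List[FrozenSet[int]] = [frozenset()] * n

    T = params.episode_steps
    site = np.asarray(params.foraging_site)
    centre = np.asarray(params.centre)
    if record:
        pos_hist = np.empty((T + 1, n, 2))
        state_hist = np.empty((T + 1, n), dtype=np.int64)
        pos_hist[0] = pos
        state_hist[0] = states

    LEK = BehaviouralState.LEKKING
    OUT = BehaviouralState.FORAGING_OUT
    RET = BehaviouralState.RETURNING

    for t in range(1, T + 1):
        prev_pos = pos
        prev_states = states.copy()
        D = cdist(prev_pos, prev_pos)
        np.fill_diagonal(D, np.inf)
        social_mask = D <= params.R_social

        # --- state transitions (evaluated on previous-tick world) ---
        u = rng.random(n)
        if model is ForagingModel.SOCIAL:
            n_forage_nb = (social_mask & (prev_states == OUT)[None, :]).sum(axis=1)
            p = np.clip(params.p_spont + params.k_copy * n_forage_nb, 0.0, 1.0)
        else:
            p = np.full(n, params.p_f)
        switched = (prev_states == LEK) & ~completed & ~departed & (u < p)
        for i in np.nonzero(switched)[0]:
            dep_tick[i] = t
            dep_neighbours[i] = frozenset(
                int(ids[j]) for j in np.nonzero(social_mask[i])[0]
            )
        departed |= switched
        states[switched] = OUT

        dist_site = np.hypot(prev_pos[:, 0] - site[0], prev_pos[:, 1] - site[1])
        arrived_site = (prev_states == OUT) & (dist_site <= params.arrival_tol)
        states[arrived_site] = RET
        dist_home = np.hypot(prev_pos[:, 0] - centre[0], prev_pos[:, 1] - centre[1])
        arrived_home = (prev_states == RET) & (dist_home <= params.arrival_tol)
        states[arrived_home] = LEK
        completed |= arrived_home
        ret_tick[arrived_home] = t

        # --- synchronous movement from previous-tick positions ---
        eps = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)
        disp = np.zeros((n, 2))
        lek_m = states == LEK

        def _vec_step(mask: np.ndarray, target: np.ndarray) -> None:
            if not mask.any():
                return
            dx = target[0] - prev_pos[mask, 0]
            dy = target[1] - prev_pos[mask, 1]
            dist = np.hypot(dx, dy)
            theta = np.arctan2(dy, dx) + eps[mask]
            step = params.speed * np.column_stack([np.cos(theta), np.sin(theta)])
            step[dist <= params.arrival_tol] = 0.0
            disp[mask] = step

        _vec_step(states == OUT, site)
        _vec_step(states == RET, centre)
        # lekking males: repulsion from lekking neighbours has priority
        rep_nb = (D <= params.R_r) & lek_m[None, :]
        has_rep = rep_nb.any(axis=1) & lek_m
        _vec_step(lek_m & ~has_rep, centre)
        for i in np.nonzero(has_rep)[0]:
            disp[i] = repulsion_velocity(prev_pos[i], prev_pos[rep_nb[i]], params, rng)
        pos = prev_pos + disp
        if record:
            pos_hist[t] = pos
            state_hist[t] = states

    traj = None
    if record:
        frame = frame_from_arrays(ids, lek_state.roles, pos_hist, state_hist)
        traj = TrajectorySet(frame=frame, params=params, final_state=None)

    records = [
        DepartureRecord(
            agent_id=int(ids[i]),
            departure_tick=int(dep_tick[i]),
            return_tick=int(ret_tick[i]) if ret_tick[i] >= 0 else None,
            neighbours_at_departure=dep_neighbours[i],
        )
        for i in range(n)
        if departed[i]
    ]
    return traj, records


def forager_count_series(traj: TrajectorySet) -> pd.Series:
    """Number of males off the lek (FORAGING_OUT or RETURNING) per tick."""
    frame = traj.frame
    out = frame["state"].isin([BehaviouralState.FORAGING_OUT.name, BehaviouralState.RETURNING.name])
    counts = frame[out].groupby("tick").size()
    ticks = np.arange(traj.n_ticks)
    return counts.reindex(ticks, fill_value=0).astype(int)


def matched_independent_rate(mean_departures: float, n_males: int, ticks: int) -> float:
    """Independent-model rate whose expected total departures over
    ``ticks`` equals ``mean_departures``.

    Departure times under the independent rule are geometric, so the
    expected number departed by tick T is ``n (1 - (1-p)^T)``;
    inverting gives the matched rate in closed form.
    """
    if not 0 <= mean_departures <= n_males:
        raise ValueError("mean_departures must lie in [0, n_males]")
    frac = mean_departures / n_males
    if frac >= 1.0:
        return 1.0
    return 1.0 - (1.0 - frac) ** (1.0 / ticks)
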