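"""Lek formation: agents, movement rules and the per-tick update.

The model is a self-propelled-particle system on an unbounded plane.
Each resident male moves at a constant per-step speed; its direction
is set by two rules with strict priority:

1. *Short-range repulsion* (higher priority): if any other male lies
   within the closed ball of radius ``R_r``, step directly away from
   them (centroid of all such neighbours by default), with no heading
   noise.
2. *Site fidelity*: otherwise, step towards the breeding centre with
   a wrapped-normal heading error of standard deviation ``noise_sd``.

Updates are synchronous: every displacement for tick *t+1* is computed
from the positions at tick *t*, then all positions move at once.
Iteration is in ascending agent id and a single RNG stream drives the
whole run, so a (params, seed) pair reproduces a run exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .params import ModelParams


class Role(IntEnum):
    RESIDENT_MALE = 0
    INTRUDER_MALE = 1
    FEMALE = 2


class BehaviouralState(IntEnum):
    LEKKING = 0
    FORAGING_OUT = 1
    RETURNING = 2
    CHASING = 3


#: Transitions legal for a resident male.  Females never take
#: FORAGING_OUT; self-loops are always allowed.
LEGAL_TRANSITIONS = frozenset(
    [
        (BehaviouralState.LEKKING, BehaviouralState.FORAGING_OUT),
        (BehaviouralState.FORAGING_OUT, BehaviouralState.RETURNING),
        (BehaviouralState.RETURNING, BehaviouralState.LEKKING),
        (BehaviouralState.LEKKING, BehaviouralState.CHASING),
        (BehaviouralState.CHASING, BehaviouralState.LEKKING),
    ]
)


@dataclass
class AgentState:
    """One agent at one tick."""

    id: int
    role: Role
    position: np.ndarray
    heading: float
    behavioural_state: BehaviouralState


@dataclass
class SimulationState:
    """The whole world at one tick.

    Per-agent attributes are stored as parallel arrays (ascending id
    order); :meth:`agents` materialises :class:`AgentState` views when
    object access is more convenient than array access.
    """

    tick: int
    ids: np.ndarray
    roles: np.ndarray
    positions: np.ndarray
    headings: np.ndarray
    states: np.ndarray
    rng: np.random.Generator

    @property
    def n(self) -> int:
        return len(self.ids)

    def agents(self) -> List[AgentState]:
        return [
            AgentState(
                id=int(self.ids[i]),
                role=Role(int(self.roles[i])),
                position=self.positions[i].copy(),
                heading=float(self.headings[i]),
                behavioural_state=BehaviouralState(int(self.states[i])),
            )
            for i in range(self.n)
        ]

    def copy(self) -> "SimulationState":
        g = np.random.default_rng(0)
        g.bit_generator.state = self.rng.bit_generator.state
        return SimulationState(
            tick=self.tick,
            ids=self.ids.copy(),
            roles=self.roles.copy(),
            positions=self.positions.copy(),
            headings=self.headings.copy(),
            states=self.states.copy(),
            rng=g,
        )


@dataclass
class Territory:
    """A resident male's territory, derived from the settled lek."""

    id: int
    owner_id: int
    centre: np.ndarray
    radius: float


@dataclass
class TrajectorySet:
    """Long-form trajectory record: one row per (tick, agent).

    ``frame`` columns: ``tick, agent_id, role, state, x, y`` with
    roles and states as their enum names.  ``final_state`` carries the
    world at the last tick so a later phase can pick up where a run
    ended.
    """

    frame: pd.DataFrame
    params: Optional[ModelParams] = None
    final_state: Optional[SimulationState] = None

    COLUMNS = ("tick", "agent_id", "role", "state", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"trajectory frame missing columns {missing}")

    def positions_at(self, tick: int) -> pd.DataFrame:
        return self.frame[self.frame["tick"] == tick]

    def per_agent(self, agent_id: int) -> pd.DataFrame:
        sub = self.frame[self.frame["agent_id"] == agent_id]
        return sub.sort_values("tick").reset_index(drop=True)

    @property
    def n_ticks(self) -> int:
        return int(self.frame["tick"].max()) + 1 if len(self.frame) else 0


def frame_from_arrays(
    ids: np.ndarray,
    roles: np.ndarray,
    positions: np.ndarray,
    states: np.ndarray,
    first_tick: int = 0,
) -> pd.DataFrame:
    """Build a long-form trajectory frame from dense arrays.

    ``positions`` has shape (T, n, 2) and ``states`` (T, n); roles are
    constant over a run.
    """
    T, n = states.shape
    ticks = np.repeat(np.arange(first_tick, first_tick + T), n)
    role_names = np.array([Role(r).name for r in roles])
    state_names = np.array([s.name for s in BehaviouralState])
    return pd.DataFrame(
        {
            "tick": ticks,
            "agent_id": np.tile(ids, T),
            "role": pd.Categorical(np.tile(role_names, T), categories=[r.name for r in Role]),
            "state": pd.Categorical(
                state_names[states.reshape(-1)], categories=[s.name for s in BehaviouralState]
            ),
            "x": positions[:, :, 0].reshape(-1),
            "y": positions[:, :, 1].reshape(-1),
        }
    )


# ---------------------------------------------------------------------------
# movement rules


def init_state(params: ModelParams, seed: int) -> SimulationState:
    """Place ``n_males`` resident males uniformly in the initial box.

    All start LEKKING with headings uniform on [0, 2π).  Deterministic
    given ``seed``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_males
    cx, cy = params.centre
    L = params.arena_half_width
    positions = np.column_stack(
        [rng.uniform(cx - L, cx + L, n), rng.uniform(cy - L, cy + L, n)]
    )
    headings = rng.uniform(0.0, 2.0 * math.pi, n)
    return SimulationState(
        tick=0,
        ids=np.arange(n, dtype=np.int64),
        roles=np.full(n, Role.RESIDENT_MALE, dtype=np.int64),
        positions=positions,
        headings=headings,
        states=np.full(n, BehaviouralState.LEKKING, dtype=np.int64),
        rng=rng,
    )


def step_towards(
    position: np.ndarray,
    target: np.ndarray,
    speed: float,
    arrival_tol: float,
    noise: float = 0.0,
) -> np.ndarray:
    """Constant-speed step towards ``target`` with heading error ``noise``.

    Returns the zero vector once the target is within ``arrival_tol``
    (the degenerate-bearing rule: no direction is defined at the
    target, so arrived agents hold position).
    """
    dx = float(target[0]) - float(position[0])
    dy = float(target[1]) - float(position[1])
    if math.hypot(dx, dy) <= arrival_tol:
        return np.zeros(2)
    theta = math.atan2(dy, dx) + noise
    return np.array([speed * math.cos(theta), speed * math.sin(theta)])


def attraction_velocity(
    position: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Site-fidelity step: towards the breeding centre at constant
    speed, heading perturbed by a wrapped-normal error of std. dev.
    ``noise_sd``.  Zero within ``arrival_tol`` of the centre.
    """
    noise = float(rng.normal(0.0, params.noise_sd)) if params.noise_sd > 0 else 0.0
    return step_towards(
        position, np.asarray(params.centre), params.speed, params.arrival_tol, noise
    )


def repulsion_velocity(
    position: np.ndarray,
    neighbour_positions: np.ndarray,
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Noiseless constant-speed step directly away from neighbours.

    The reference point is the centroid of the listed neighbours
    (``repulsion_mode="centroid"``) or the nearest one
    (``"nearest"``).  If the reference point coincides with the
    agent's own position the direction is drawn uniformly at random
    (tie-break; requires ``rng``).
    """
    nb = np.atleast_2d(np.asarray(neighbour_positions, dtype=float))
    if nb.shape[0] == 0:
        raise ValueError("repulsion_velocity requires at least one neighbour")
    pos = np.asarray(position, dtype=float)
    if params.repulsion_mode == "nearest":
        d2 = ((nb - pos) ** 2).sum(axis=1)
        ref = nb[int(np.argmin(d2))]
    else:
        ref = nb.mean(axis=0)
    away = pos - ref
    norm = math.hypot(away[0], away[1])
    if norm == 0.0:
        if rng is None:
            raise ValueError(
                "coincident neighbour centroid: an rng is required for the random tie-break"
            )
        theta = float(rng.uniform(0.0, 2.0 * math.pi))
        return np.array([params.speed * math.cos(theta), params.speed * math.sin(theta)])
    return params.speed * away / norm


def resolve_velocity(
    agent: AgentState,
    neighbours_within_R_r: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Priority gate between the two rules: repulsion wins outright.

    If the neighbour list is non-empty the output *is* the repulsion
    step; otherwise it is the attraction step.  The rules are never
    blended.
    """
    nb = np.atleast_2d(np.asarray(neighbours_within_R_r, dtype=float))
    if nb.size and nb.shape[0] > 0:
        return repulsion_velocity(agent.position, nb, params, rng)
    return attraction_velocity(agent.position, params, rng)


def _formation_displacements(
    positions: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Per-tick displacements for all LEKKING males, synchronous.

    One heading-noise draw is consumed per agent per tick in ascending
    id order regardless of which rule fires, so the stream layout does
    not depend on the (data-dependent) rule choices.
    """
    n = positions.shape[0]
    eps = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)
    D = cdist(positions, positions)
    np.fill_diagonal(D, np.inf)
    nb_mask = D <= params.R_r  # closed ball
    has_nb = nb_mask.any(axis=1)

    disp = np.zeros((n, 2))
    cx, cy = params.centre
    free = ~has_nb

    if params.attraction_on:
        mid_mask = (D <= params.R_attr) & free[:, None]
        has_mid = mid_mask.any(axis=1) & free
    else:
        has_mid = np.zeros(n, dtype=bool)

    pull = free & ~has_mid
    if pull.any():
        dx = cx - positions[pull, 0]
        dy = cy - positions[pull, 1]
        dist = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx) + eps[pull]
        step = params.speed * np.column_stack([np.cos(theta), np.sin(theta)])
        step[dist <= params.arrival_tol] = 0.0
        disp[pull] = step

    for i in np.nonzero(has_mid)[0]:
        ref = positions[mid_mask[i]].mean(axis=0)
        dx, dy = ref[0] - positions[i, 0], ref[1] - positions[i, 1]
        if math.hypot(dx, dy) <= params.arrival_tol:
            continue
        theta = math.atan2(dy, dx) + eps[i]
        disp[i] = (params.speed * math.cos(theta), params.speed * math.sin(theta))

    for i in np.nonzero(has_nb)[0]:
        disp[i] = repulsion_velocity(positions[i], positions[nb_mask[i]], params, rng)
    return disp


def advance(state: SimulationState, params: ModelParams) -> SimulationState:
    """One synchronous formation tick, in place.

    All displacements are computed from the positions at the current
    tick, then applied at once; headings are updated to the realised
    direction of motion; the tick counter increments.
    """
    disp = _formation_displacements(state.positions, params, state.rng)
    moved = (disp != 0).any(axis=1)
    state.headings[moved] = np.arctan2(disp[moved, 1], disp[moved, 0])
    state.positions += disp
    state.tick += 1
    return state


def run_formation(
    params: ModelParams, seed: int, record: bool = True
) -> TrajectorySet:
    """Simulate the lek-formation phase from a random start.

    Runs ``formation_steps`` ticks of the fidelity+repulsion dynamics.
    The returned :class:`TrajectorySet` covers ticks 0..formation_steps
    and carries the final world in ``final_state`` (the settled lek).
    """
    state = init_state(params, seed)
    T = params.formation_steps
    if record:
        pos_hist = np.empty((T + 1, state.n, 2))
        pos_hist[0] = state.positions
    for t in range(1, T + 1):
        advance(state, params)
        if record:
            pos_hist[t] = state.positions
    if record:
        states_hist = np.full((T + 1, state.n), BehaviouralState.LEKKING, dtype=np.int64)
        frame = frame_from_arrays(state.ids, state.roles, pos_hist, states_hist)
    else:
        frame = frame_from_arrays(
            state.ids,
            state.roles,
            state.positions[None, :, :],
            np.full((1, state.n), BehaviouralState.LEKKING, dtype=np.int64),
            first_tick=T,
        )
    return TrajectorySet(frame=frame, params=params, final_state=state)


def derive_territories(traj: TrajectorySet, window: int) -> List[Territory]:
    """Territory centres from the tail of a formation run.

    Each resident male's centre is its mean position over the final
    ``window`` ticks; every territory gets the same radius, half the
    mean nearest-neighbour distance among the centres.  This is a
    package convention for turning a settled lek into marked
    territories, not a behavioural rule.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    frame = traj.frame
    males = frame[frame["role"] == Role.RESIDENT_MALE.name]
    last_tick = int(males["tick"].max())
    first_tick = int(males["tick"].min())
    if last_tick - first_tick + 1 < window:
        raise ValueError(
            f"window={window} exceeds run length {last_tick - first_tick + 1}"
        )
    tail = males[males["tick"] > last_tick - window]
    centres = tail.groupby("agent_id", observed=True)[["x", "y"]].mean().sort_index()
    ids = centres.index.to_numpy()
    C = centres.to_numpy()
    if len(ids) < 2:
        raise ValueError("need at least two resident males to derive territories")
    D = cdist(C, C)
    np.fill_diagonal(D, np.inf)
    radius = float(D.min(axis=1).mean()) / 2.0
    return [
        Territory(id=k, owner_id=int(ids[k]), centre=C[k].copy(), radius=radius)
        for k in range(len(ids))
    ]
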