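"""Intruder males and resident chase rules.

A single non-resident male crosses the settled lek on a straight path.
Residents defend under one of two rules whose movement signatures
differ:

- ``INDEPENDENT``: a resident starts chasing only when the intruder
  enters its own territory, after a personal reaction latency drawn
  once, uniform on the integers [0, latency_max] ticks.  Chase onsets
  are staggered.
- ``COORDINATED``: additionally, a lekking resident with chasing
  neighbours within ``R_social`` joins the chase with probability
  ``min(1, k_chase * n_chasing_neighbours)`` per tick.  Onsets bunch
  together and chase trajectories align.

A chasing resident pursues the intruder's last position at constant
speed and gives up once the intruder is beyond
``stop_radius_factor × territory radius`` from its own territory
centre, then returns home.  A chased intruder flees directly away
from its nearest chaser at ``flee_speed_factor × speed``; otherwise it
continues towards its exit point.  Residents not chasing hold station
at their own territory centres for the duration of the episode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import (
    BehaviouralState,
    Role,
    SimulationState,
    Territory,
    TrajectorySet,
    frame_from_arrays,
    step_towards,
)
from .errors import UndefinedMetricError
from .params import IntruderParams, ModelParams


class ChaseMode(str, Enum):
    INDEPENDENT = "independent"
    COORDINATED = "coordinated"


@dataclass
class ChaseEvent:
    """One resident's chase bout: CHASING from onset to offset tick."""

    resident_id: int
    onset_tick: int
    offset_tick: int
    mode: ChaseMode


def spawn_intruder(
    state: SimulationState,
    entry_point: Sequence[float],
    exit_point: Sequence[float],
    params: ModelParams,
) -> SimulationState:
    """Append an intruder male at ``entry_point`` headed for ``exit_point``."""
    entry = np.asarray(entry_point, dtype=float)
    exit_ = np.asarray(exit_point, dtype=float)
    if np.allclose(entry, exit_):
        raise ValueError("entry_point and exit_point must differ (degenerate path)")
    new = state.copy()
    iid = int(new.ids.max()) + 1
    new.ids = np.append(new.ids, iid)
    new.roles = np.append(new.roles, Role.INTRUDER_MALE)
    new.positions = np.vstack([new.positions, entry[None, :]])
    new.headings = np.append(
        new.headings, math.atan2(exit_[1] - entry[1], exit_[0] - entry[0])
    )
    new.states = np.append(new.states, BehaviouralState.LEKKING)
    return new


def run_intruder_episode(
    territories: Sequence[Territory],
    entry_point: Sequence[float],
    exit_point: Sequence[float],
    mode: ChaseMode,
    params: ModelParams,
    iparams: IntruderParams,
    seed: int,
    record: bool = True,
) -> Tuple[Optional[TrajectorySet], List[ChaseEvent]]:
    """Simulate one intruder crossing and the residents' response.

    Residents start at their territory centres (the settled lek).  The
    episode ends when the intruder reaches its exit point, leaves the
    lek area entirely, or after ``max_ticks`` ticks.  Latencies and
    the coordinated-join uniforms come from a fresh stream seeded with
    ``seed``; draws are consumed in ascending resident id order.
    """
    mode = ChaseMode(mode)
    entry = np.asarray(entry_point, dtype=float)
    exit_ = np.asarray(exit_point, dtype=float)
    if np.allclose(entry, exit_):
        raise ValueError("entry_point and exit_point must differ (degenerate path)")
    rng = np.random.default_rng(seed)
    n = len(territories)
    terr = sorted(territories, key=lambda t: t.owner_id)
    ids = np.array([t.owner_id for t in terr], dtype=np.int64)
    centres = np.array([t.centre for t in terr], dtype=float)
    radius = np.array([t.radius for t in terr], dtype=float)
    stop_r = iparams.stop_radius_factor * radius

    latency = rng.integers(0, iparams.latency_max + 1, n)
    pending = np.full(n, -1, dtype=np.int64)  # tick at which a triggered chase starts
    chasing = np.zeros(n, dtype=bool)
    onset = np.full(n, -1, dtype=np.int64)
    events: List[ChaseEvent] = []

    pos = centres.copy()
    ipos = entry.copy()
    intruder_id = int(ids.max()) + 1
    lek_centroid = centres.mean(axis=0)
    escape_dist = 1.1 * max(
        np.linalg.norm(entry - lek_centroid), np.linalg.norm(exit_ - lek_centroid)
    )

    hist_pos = [np.vstack([pos, ipos[None, :]])]
    hist_state = [np.append(np.full(n, BehaviouralState.LEKKING), BehaviouralState.LEKKING)]

    t_end = iparams.max_ticks
    for t in range(1, iparams.max_ticks + 1):
        prev_pos = pos
        prev_ipos = ipos
        prev_chasing = chasing.copy()

        # --- chase-state transitions, from the previous tick's world ---
        d_to_centre = np.hypot(
            prev_ipos[0] - centres[:, 0], prev_ipos[1] - centres[:, 1]
        )
        u = rng.random(n)
        inside = d_to_centre <= radius
        # arm the latency countdown on first entry; the chase launches
        # when it expires even if the intruder has moved on (a reaction
        # delay postpones the chase, it does not call it off)
        for i in range(n):
            if prev_chasing[i]:
                continue
            if pending[i] < 0 and inside[i]:
                pending[i] = t + int(latency[i])
        start = np.zeros(n, dtype=bool)
        expired = (pending >= 0) & (pending <= t) & ~prev_chasing
        start |= expired
        pending[expired] = -1
        if mode is ChaseMode.COORDINATED and prev_chasing.any():
            Dres = cdist(prev_pos, prev_pos)
            np.fill_diagonal(Dres, np.inf)
            n_chase_nb = ((Dres <= params.R_social) & prev_chasing[None, :]).sum(axis=1)
            p_join = np.minimum(1.0, iparams.k_chase * n_chase_nb)
            # a chase is only joinable while the intruder is within the
            # joiner's own chase range, else it would stop immediately
            start |= ~prev_chasing & (u < p_join) & (d_to_centre <= stop_r)
        start &= ~prev_chasing
        chasing = prev_chasing | start
        onset[start] = t

        stop = prev_chasing & (d_to_centre > stop_r)
        for i in np.nonzero(stop)[0]:
            events.append(
                ChaseEvent(
                    resident_id=int(ids[i]),
                    onset_tick=int(onset[i]),
                    offset_tick=int(t - 1),
                    mode=mode,
                )
            )
            onset[i] = -1
        chasing &= ~stop

        # --- movement ---
        disp = np.zeros((n, 2))
        for i in range(n):
            if chasing[i]:
                disp[i] = step_towards(
                    prev_pos[i], prev_ipos, params.speed, params.arrival_tol
                )
            else:
                disp[i] = step_towards(
                    prev_pos[i], centres[i], params.speed, params.arrival_tol
                )
        pos = prev_pos + disp

        if prev_chasing.any():
            d_chasers = np.hypot(
                prev_ipos[0] - prev_pos[:, 0], prev_ipos[1] - prev_pos[:, 1]
            )
            d_chasers[~prev_chasing] = np.inf
            nearest = int(np.argmin(d_chasers))
            away = prev_ipos - prev_pos[nearest]
            norm = math.hypot(away[0], away[1])
            if norm == 0.0:
                theta = float(rng.uniform(0.0, 2.0 * math.pi))
                away = np.array([math.cos(theta), math.sin(theta)])
                norm = 1.0
            ipos = prev_ipos + iparams.flee_speed_factor * params.speed * away / norm
        else:
            ipos = prev_ipos + step_towards(
                prev_ipos, exit_, params.speed, params.arrival_tol
            )

        if record:
            hist_pos.append(np.vstack([pos, ipos[None, :]]))
            st = np.where(chasing, BehaviouralState.CHASING, BehaviouralState.LEKKING)
            hist_state.append(np.append(st, BehaviouralState.LEKKING))

        reached_exit = np.linalg.norm(ipos - exit_) <= params.arrival_tol
        escaped = (
            np.linalg.norm(ipos - lek_centroid) > escape_dist and not chasing.any()
        )
        if reached_exit or escaped:
            t_end = t
            break

    for i in np.nonzero(chasing)[0]:  # close bouts still open at episode end
        events.append(
            ChaseEvent(
                resident_id=int(ids[i]),
                onset_tick=int(onset[i]),
                offset_tick=int(t_end),
                mode=mode,
            )
        )

    traj = None
    if record:
        all_ids = np.append(ids, intruder_id)
        all_roles = np.append(
            np.full(n, Role.RESIDENT_MALE, dtype=np.int64), Role.INTRUDER_MALE
        )
        positions = np.stack(hist_pos)
        states = np.stack(hist_state).astype(np.int64)
        frame = frame_from_arrays(all_ids, all_roles, positions, states)
        traj = TrajectorySet(frame=frame, params=params, final_state=None)
    return traj, sorted(events, key=lambda e: (e.onset_tick, e.resident_id))


def chase_onset_gap(events: Sequence[ChaseEvent]) -> float:
    """Mean pairwise difference of first chase-onset ticks.

    Residents with several bouts contribute their first onset.  Zero
    when at most one resident chased.
    """
    first: dict = {}
    for e in events:
        if e.resident_id not in first or e.onset_tick < first[e.resident_id]:
            first[e.resident_id] = e.onset_tick
    onsets = sorted(first.values())
    if len(onsets) <= 1:
        return 0.0
    total = sum(abs(a - b) for a, b in combinations(onsets, 2))
    npairs = len(onsets) * (len(onsets) - 1) // 2
    return total / npairs


def _chase_displacements(agent_frame: pd.DataFrame) -> dict:
    """Map tick -> displacement vector for chase moves.

    The move from tick *t-1* to *t* is driven by the state held at
    *t* (the simulator updates states, then moves), so a tick *t*
    counts as a chase move when the agent is CHASING at *t*.
    """
    frame = agent_frame.sort_values("tick")
    ticks = frame["tick"].to_numpy()
    xy = frame[["x", "y"]].to_numpy(dtype=float)
    st = frame["state"].to_numpy()
    out = {}
    for k in range(len(ticks) - 1):
        if st[k + 1] == BehaviouralState.CHASING.name and ticks[k + 1] == ticks[k] + 1:
            out[int(ticks[k + 1])] = xy[k + 1] - xy[k]
    return out


def chase_direction_correlation(
    traj_a: pd.DataFrame, traj_b: pd.DataFrame
) -> float:
    """Directional alignment of two chase trajectories.

    Mean, over ticks where both agents are CHASING, of the cosine of
    the angle between their per-tick displacement vectors.  The
    displacement at tick *t* is the move from *t-1* to *t*, attributed
    to the state held at *t*.  Symmetric in its arguments; raises
    :class:`UndefinedMetricError` with fewer than two overlapping
    ticks.
    """
    da = _chase_displacements(traj_a)
    db = _chase_displacements(traj_b)
    common = sorted(set(da) & set(db))
    cosines = []
    for t in common:
        va, vb = da[t], db[t]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0.0 or nb == 0.0:
            continue
        cosines.append(float(np.dot(va, vb) / (na * nb)))
    if len(cosines) < 2:
        raise UndefinedMetricError(
            "chase_direction_correlation needs >= 2 overlapping chasing ticks"
        )
    return float(np.mean(cosines))


def mean_pairwise_chase_correlation(
    traj: TrajectorySet, events: Sequence[ChaseEvent]
) -> float:
    """Mean :func:`chase_direction_correlation` over all chaser pairs
    with enough overlap.  Undefined when no pair overlaps."""
    ids = sorted({e.resident_id for e in events})
    vals = []
    sub = {i: traj.per_agent(i) for i in ids}
    for a, b in combinations(ids, 2):
        try:
            vals.append(chase_direction_correlation(sub[a], sub[b]))
        except UndefinedMetricError:
            continue
    if not vals:
        raise UndefinedMetricError("no chaser pair with overlapping chase ticks")
    return float(np.mean(vals))
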