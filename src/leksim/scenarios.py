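"""Canned experiments comparing behavioural rules on fixed leks.

Each function builds its own inputs (a settled lek or a synthetic
ring of territories), runs the simulator under two contrasted rules,
and returns the discriminating statistics as plain numbers.  They are
the package's reference experiments: the formation contraction check,
independent-departure analytics against the geometric closed form,
the social-vs-independent foraging contrast, the
coordinated-vs-independent chase contrast, the four female-strategy
signatures, and the harassment-avoidance heatmap self-consistency
check.

All randomness flows from an explicit ``base_seed`` through
:func:`child_seed`, so every experiment is reproducible end to end.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    BehaviouralState,
    Role,
    SimulationState,
    Territory,
    TrajectorySet,
    run_formation,
)
from .errors import UndefinedMetricError
from .females import (
    MatingRecord,
    Strategy,
    VisitSequence,
    draw_qualities,
    mating_skew,
    revisit_count,
    simulate_females,
)
from .foraging import (
    ForagingModel,
    matched_independent_rate,
    run_foraging_episode,
)
from .intruder import (
    ChaseMode,
    chase_onset_gap,
    mean_pairwise_chase_correlation,
    run_intruder_episode,
)
from .metrics import (
    GridSpec,
    aggression_heatmap,
    departure_steepness,
    departure_synchrony,
    heatmap_association,
    occupancy_heatmap,
)
from .params import FemaleParams, IntruderParams, ModelParams


def child_seed(base_seed: int, *path: int) -> int:
    """Stable sub-seed derivation: independent streams per stage/run."""
    ss = np.random.SeedSequence([int(base_seed), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def make_ring_lek(
    n_territories: int, spacing: float = 2.0, centre: Tuple[float, float] = (0.0, 0.0)
) -> Tuple[SimulationState, List[Territory]]:
    """A synthetic settled lek: territories evenly spaced on a ring.

    Neighbouring centres sit ``spacing`` apart along the ring chord;
    each territory's radius is half that (the usual derivation rule on
    an equally spaced lek).  Residents stand at their centres, all
    LEKKING.
    """
    if n_territories < 2:
        raise ValueError("need at least two territories")
    R = spacing / (2.0 * math.sin(math.pi / n_territories))
    angles = 2.0 * math.pi * np.arange(n_territories) / n_territories
    centres = np.column_stack(
        [centre[0] + R * np.cos(angles), centre[1] + R * np.sin(angles)]
    )
    territories = [
        Territory(id=k, owner_id=k, centre=centres[k].copy(), radius=spacing / 2.0)
        for k in range(n_territories)
    ]
    state = SimulationState(
        tick=0,
        ids=np.arange(n_territories, dtype=np.int64),
        roles=np.full(n_territories, Role.RESIDENT_MALE, dtype=np.int64),
        positions=centres.copy(),
        headings=np.zeros(n_territories),
        states=np.full(n_territories, BehaviouralState.LEKKING, dtype=np.int64),
        rng=np.random.default_rng(0),
    )
    return state, territories


def settle_lek(params: ModelParams, seed: int) -> SimulationState:
    """Run the formation phase and return the settled lek state."""
    traj = run_formation(params, seed, record=False)
    return traj.final_state


# ---------------------------------------------------------------------------
# formation


def formation_contraction_experiment(
    params: ModelParams, n_seeds: int, base_seed: int
) -> Dict[str, float]:
    """Contraction and spacing of the settled lek over many seeds.

    For each seed: RMS distance to the breeding centre at tick 0 vs
    the final tick, and the final nearest-neighbour distances.
    Returns the fraction of seeds that contracted and the median final
    NN distance in units of R_r.
    """
    from scipy.spatial.distance import cdist

    from .core import init_state

    contracted = 0
    nn_all: List[float] = []
    centre = np.asarray(params.centre)
    for k in range(n_seeds):
        seed = child_seed(base_seed, 0, k)
        init = init_state(params, seed).positions
        rms0 = float(np.sqrt(((init - centre) ** 2).sum(axis=1).mean()))
        traj = run_formation(params, seed, record=False)
        final = traj.final_state.positions
        rms1 = float(np.sqrt(((final - centre) ** 2).sum(axis=1).mean()))
        if rms1 < rms0:
            contracted += 1
        D = cdist(final, final)
        np.fill_diagonal(D, np.inf)
        nn_all.extend(D.min(axis=1).tolist())
    return {
        "contraction_fraction": contracted / n_seeds,
        "median_final_nn_over_Rr": float(np.median(nn_all)) / params.R_r,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# foraging


def independent_departure_analytics(
    params: ModelParams,
    n_seeds: int,
    eval_ticks: Sequence[int],
    base_seed: int,
) -> Dict[str, object]:
    """Mean cumulative departures vs the geometric closed form.

    Under the independent rule each male's departure tick is
    geometric(p_f), so the expected number departed by tick t is
    ``n (1 - (1-p_f)^t)``.  Returns observed means, expectations,
    standard errors, and the worst |z| across the evaluation ticks.
    """
    lek, _ = make_ring_lek_grid(params.n_males, spacing=2.0 * params.R_r)
    eval_ticks = list(eval_ticks)
    counts = np.zeros((n_seeds, len(eval_ticks)))
    for k in range(n_seeds):
        _, deps = run_foraging_episode(
            lek, ForagingModel.INDEPENDENT, params, child_seed(base_seed, 1, k), record=False
        )
        ticks = np.array([d.departure_tick for d in deps])
        for j, t in enumerate(eval_ticks):
            counts[k, j] = (ticks <= t).sum()
    observed = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / math.sqrt(n_seeds)
    expected = params.n_males * (1.0 - (1.0 - params.p_f) ** np.asarray(eval_ticks))
    z = np.abs(observed - expected) / np.where(se > 0, se, np.inf)
    return {
        "eval_ticks": eval_ticks,
        "observed_mean": observed.tolist(),
        "expected": expected.tolist(),
        "standard_error": se.tolist(),
        "max_abs_z": float(z.max()),
        "n_seeds": n_seeds,
    }


def make_ring_lek_grid(
    n_males: int, spacing: float = 2.0, centre: Tuple[float, float] = (0.0, 0.0)
) -> Tuple[SimulationState, List[Territory]]:
    """A compact hexagonal-packed settled lek for larger n.

    Rings of territories around a central one, ``spacing`` apart —
    the shape a fidelity+repulsion run settles into, constructed
    directly so experiments on a *fixed* lek need no formation run.
    """
    pts = [np.array(centre, dtype=float)]
    ring = 1
    while len(pts) < n_males:
        # hexagonal ring `ring` has 6*ring points
        for k in range(6 * ring):
            ang = 2.0 * math.pi * k / (6 * ring)
            pts.append(
                np.array(
                    [
                        centre[0] + ring * spacing * math.cos(ang),
                        centre[1] + ring * spacing * math.sin(ang),
                    ]
                )
            )
            if len(pts) == n_males:
                break
        ring += 1
    centres = np.array(pts[:n_males])
    from scipy.spatial.distance import cdist

    D = cdist(centres, centres)
    np.fill_diagonal(D, np.inf)
    radius = float(D.min(axis=1).mean()) / 2.0
    territories = [
        Territory(id=k, owner_id=k, centre=centres[k].copy(), radius=radius)
        for k in range(n_males)
    ]
    state = SimulationState(
        tick=0,
        ids=np.arange(n_males, dtype=np.int64),
        roles=np.full(n_males, Role.RESIDENT_MALE, dtype=np.int64),
        positions=centres.copy(),
        headings=np.zeros(n_males),
        states=np.full(n_males, BehaviouralState.LEKKING, dtype=np.int64),
        rng=np.random.default_rng(0),
    )
    return state, territories


def calibrate_matched_rate(
    lek: SimulationState,
    params: ModelParams,
    n_calibration_seeds: int,
    base_seed: int,
) -> float:
    """Independent rate matched to the SOCIAL model's mean departures.

    Measures the social model's mean total departures over calibration
    seeds, then inverts the geometric closed form.  The per-male
    departure fraction uses a Jeffreys-style correction
    ``(k + 0.5) / (N + 1)`` so a fully saturated social run does not
    degenerate to p_f = 1.
    """
    total = 0
    for k in range(n_calibration_seeds):
        _, deps = run_foraging_episode(
            lek, ForagingModel.SOCIAL, params, child_seed(base_seed, 2, k), record=False
        )
        total += len(deps)
    N = n_calibration_seeds * lek.n
    frac = (total + 0.5) / (N + 1.0)
    return matched_independent_rate(frac * lek.n, lek.n, params.episode_steps)


def social_vs_independent_departures(
    params: ModelParams,
    n_pairs: int,
    base_seed: int,
    w: int = 5,
    n_calibration_seeds: int = 30,
) -> Dict[str, object]:
    """Paired foraging runs: copying vs rate-matched independent.

    For each pair of seeds, one SOCIAL and one INDEPENDENT episode run
    on the same fixed lek; the independent rate is calibrated so mean
    total departures agree.  Returns the synchrony values of both
    arms, the AUROC of synchrony as a classifier between them, and
    the fraction of pairs where the social run is strictly steeper.
    """
    lek, _ = make_ring_lek_grid(params.n_males, spacing=2.0 * params.R_r)
    p_matched = calibrate_matched_rate(lek, params, n_calibration_seeds, base_seed)
    params_ind = params.replace(p_f=p_matched)

    sync_soc: List[float] = []
    sync_ind: List[float] = []
    steeper = 0
    valid_pairs = 0
    for k in range(n_pairs):
        _, dep_s = run_foraging_episode(
            lek, ForagingModel.SOCIAL, params, child_seed(base_seed, 3, k), record=False
        )
        _, dep_i = run_foraging_episode(
            lek, ForagingModel.INDEPENDENT, params_ind, child_seed(base_seed, 4, k), record=False
        )
        try:
            sync_soc.append(departure_synchrony(dep_s, w)[0])
            sync_ind.append(departure_synchrony(dep_i, w)[0])
        except UndefinedMetricError:
            continue
        st_s = departure_steepness(dep_s, params.n_males, w)
        st_i = departure_steepness(dep_i, params.n_males, w)
        valid_pairs += 1
        if st_s > st_i:
            steeper += 1
    auroc = _auroc(sync_soc, sync_ind)
    return {
        "matched_p_f": p_matched,
        "synchrony_social": sync_soc,
        "synchrony_independent": sync_ind,
        "auroc": auroc,
        "steepness_social_wins": steeper,
        "n_pairs": valid_pairs,
    }


def _auroc(positives: Sequence[float], negatives: Sequence[float]) -> float:
    """AUROC via the rank-sum identity U / (n1 n2)."""
    if not positives or not negatives:
        raise UndefinedMetricError("AUROC needs both classes non-empty")
    u = stats.mannwhitneyu(positives, negatives, alternative="two-sided").statistic
    return float(u / (len(positives) * len(negatives)))


# ---------------------------------------------------------------------------
# intruder chasing


def run_chase_correlation(traj: TrajectorySet, events) -> float:
    """Run-level chase synchrony in [-1, 1].

    For each chaser pair, the sum of per-tick direction cosines over
    ticks where *both* chase, divided by the number of ticks where
    *either* chases — directional alignment discounted by
    non-simultaneity, so staggered independent chases score low even
    when both pursue the same intruder.  Averaged over pairs; NaN when
    fewer than two residents chased.
    """
    from itertools import combinations

    from .intruder import _chase_displacements

    ids = sorted({e.resident_id for e in events})
    if len(ids) < 2:
        return float("nan")
    disp = {i: _chase_displacements(traj.per_agent(i)) for i in ids}
    vals = []
    for a, b in combinations(ids, 2):
        da, db = disp[a], disp[b]
        union = set(da) | set(db)
        if not union:
            continue
        total = 0.0
        for t in set(da) & set(db):
            va, vb = da[t], db[t]
            na, nb = np.linalg.norm(va), np.linalg.norm(vb)
            if na > 0 and nb > 0:
                total += float(np.dot(va, vb) / (na * nb))
        vals.append(total / len(union))
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def chase_mode_comparison(
    params: ModelParams,
    iparams: IntruderParams,
    n_pairs: int,
    base_seed: int,
    n_territories: int = 10,
) -> Dict[str, object]:
    """Paired intruder crossings under both chase rules.

    A fixed ring lek; the intruder crosses on a chord through the
    midpoint of an adjacent territory pair, so several residents are
    triggered on each side.  For each seed pair, the mean chase-onset
    gap and a run-level chase-direction correlation are computed under
    both modes; sign tests summarise the contrast.

    The run-level correlation averages the pairwise chase-direction
    cosine over all chaser pairs, with a pair that never chased
    simultaneously contributing 0 (no synchronous chasing); it is NaN
    only when fewer than two residents chased at all.
    """
    _, territories = make_ring_lek(n_territories, spacing=2.0 * params.R_r)
    R = float(np.linalg.norm(territories[0].centre))
    # chord through the centres of the adjacent pair (0, 1): exactly
    # those two territories are entered, giving one encounter with two
    # independent chasers and a recruitable neighbourhood around them
    c0, c1 = territories[0].centre, territories[1].centre
    u = (c1 - c0) / np.linalg.norm(c1 - c0)
    m = (c0 + c1) / 2.0
    L = R + 6.0 * params.R_r
    entry = tuple(m - L * u)
    exit_ = tuple(m + L * u)

    gaps: Dict[str, List[float]] = {"independent": [], "coordinated": []}
    corrs: Dict[str, List[float]] = {"independent": [], "coordinated": []}
    for k in range(n_pairs):
        seed = child_seed(base_seed, 5, k)
        for mode in (ChaseMode.INDEPENDENT, ChaseMode.COORDINATED):
            traj, events = run_intruder_episode(
                territories, entry, exit_, mode, params, iparams, seed
            )
            gaps[mode.value].append(chase_onset_gap(events))
            corrs[mode.value].append(run_chase_correlation(traj, events))

    gap_wins = sum(
        1 for a, b in zip(gaps["coordinated"], gaps["independent"]) if a < b
    )
    corr_pairs = [
        (a, b)
        for a, b in zip(corrs["coordinated"], corrs["independent"])
        if not (math.isnan(a) or math.isnan(b))
    ]
    corr_wins = sum(1 for a, b in corr_pairs if a > b)
    gap_p = stats.binomtest(gap_wins, n_pairs, 0.5, alternative="greater").pvalue
    corr_p = (
        stats.binomtest(corr_wins, len(corr_pairs), 0.5, alternative="greater").pvalue
        if corr_pairs
        else float("nan")
    )
    return {
        "mean_gap_independent": float(np.mean(gaps["independent"])),
        "mean_gap_coordinated": float(np.mean(gaps["coordinated"])),
        "mean_corr_independent": float(np.nanmean(corrs["independent"])),
        "mean_corr_coordinated": float(np.nanmean(corrs["coordinated"])),
        "gap_wins": gap_wins,
        "corr_wins": corr_wins,
        "n_corr_pairs": len(corr_pairs),
        "gap_sign_test_p": float(gap_p),
        "corr_sign_test_p": float(corr_p),
        "n_pairs": n_pairs,
    }


# ---------------------------------------------------------------------------
# female strategies


def strategy_signature_battery(
    fparams: FemaleParams,
    n_females: int,
    base_seed: int,
    n_territories: int = 12,
    n_skew_pairs: int = 100,
    n_skew_females: int = 100,
) -> Dict[str, object]:
    """The four mate-sampling signatures on a fixed ring lek.

    - THRESHOLD: no revisits, ever.
    - BEST_OF_N: every mated female revisits, and the chosen male is
      the argmax of her sampled qualities.
    - RANDOM: visits-to-mating is geometric(p_mate) (chi-square GoF).
    - COPYING: mating skew exceeds RANDOM's in paired seeds.
    """
    _, territories = make_ring_lek(n_territories)
    qrng = np.random.default_rng(child_seed(base_seed, 6))
    qualities = draw_qualities(territories, qrng)
    qual_by_terr = {t.id: q.quality for t, q in zip(territories, qualities)}
    owner_by_terr = {t.id: t.owner_id for t in territories}

    # THRESHOLD: revisit counts
    v_thr, m_thr = simulate_females(
        n_females, Strategy.THRESHOLD, territories, qualities, fparams, child_seed(base_seed, 7)
    )
    thr_revisits = max(revisit_count(v) for v in v_thr)

    # BEST_OF_N: revisits and argmax choice
    v_bon, m_bon = simulate_females(
        n_females, Strategy.BEST_OF_N, territories, qualities, fparams, child_seed(base_seed, 8)
    )
    bon_min_revisits = min(revisit_count(v) for v in v_bon)
    bon_argmax_ok = all(
        rec.male_id
        == owner_by_terr[
            min(
                seq.territory_ids[: fparams.best_of_n],
                key=lambda t: (-qual_by_terr[t], t),
            )
        ]
        for seq, rec in zip(v_bon, m_bon)
    )

    # RANDOM: geometric goodness of fit on visits to mating
    v_rnd, m_rnd = simulate_females(
        n_females, Strategy.RANDOM, territories, qualities, fparams, child_seed(base_seed, 9)
    )
    n_visits = [len(v.visits) for v, m in zip(v_rnd, m_rnd) if m.male_id is not None]
    gof_p = geometric_gof_pvalue(n_visits, fparams.p_mate)

    # COPYING vs RANDOM: paired mating skew
    wins = 0
    for k in range(n_skew_pairs):
        seed = child_seed(base_seed, 10, k)
        _, m_c = simulate_females(
            n_skew_females, Strategy.COPYING, territories, qualities, fparams, seed
        )
        _, m_r = simulate_females(
            n_skew_females, Strategy.RANDOM, territories, qualities, fparams, seed
        )
        if mating_skew(m_c, n_territories) > mating_skew(m_r, n_territories):
            wins += 1
    return {
        "threshold_max_revisits": int(thr_revisits),
        "best_of_n_min_revisits": int(bon_min_revisits),
        "best_of_n_argmax_ok": bool(bon_argmax_ok),
        "random_geometric_gof_p": float(gof_p),
        "copying_skew_wins": wins,
        "n_skew_pairs": n_skew_pairs,
        "copying_gini_example": float(
            mating_skew(
                simulate_females(
                    n_females, Strategy.COPYING, territories, qualities, fparams,
                    child_seed(base_seed, 11),
                )[1],
                n_territories,
            )
        ),
        "random_gini_example": float(mating_skew(m_rnd, n_territories)),
        "n_females": n_females,
    }


def geometric_gof_pvalue(samples: Sequence[int], p: float) -> float:
    """Chi-square goodness of fit of positive-integer samples against
    a geometric(p) law with known p, lumping the tail so every
    expected bin count is at least 5."""
    x = np.asarray(samples, dtype=int)
    if len(x) < 10:
        raise UndefinedMetricError("too few samples for a goodness-of-fit test")
    n = len(x)
    # choose K so the lumped tail P(X >= K) keeps expected count >= 5
    K = 1
    while n * (1.0 - p) ** K >= 5.0 and K < 10_000:
        K += 1
    K = max(K, 2)
    observed = np.array(
        [(x == k).sum() for k in range(1, K)] + [(x >= K).sum()], dtype=float
    )
    expected = np.array(
        [n * p * (1.0 - p) ** (k - 1) for k in range(1, K)] + [n * (1.0 - p) ** (K - 1)]
    )
    chi2, pval = stats.chisquare(observed, expected)
    return float(pval)


# ---------------------------------------------------------------------------
# harassment-avoidance heatmaps


def harassment_avoidance_experiment(
    n_seeds: int,
    base_seed: int,
    avoidance: bool,
    n_territories: int = 12,
    n_females: int = 100,
    visits_per_female: int = 30,
    events_scale: float = 120.0,
    beta: float = 4.0,
    n_cells: int = 20,
) -> Dict[str, object]:
    """Self-consistency of the heatmap association statistic.

    Per-territory aggression rates are drawn Uniform(0,1); aggression
    events (codes C/F) fall Poisson(rate × events_scale) per
    territory, uniformly inside its disc.  With ``avoidance`` on,
    female positions fall inside territory discs with per-territory
    weights ``exp(-beta × rate)`` — harassment avoidance.  With it
    off, females wander with no discernible spatial feature: positions
    uniform over the whole analysis region (the movement null).
    Returns the Spearman association per seed.
    """
    _, territories = make_ring_lek(n_territories)
    spec = GridSpec.from_territories(territories, n_cells=n_cells)
    centres = np.array([t.centre for t in territories])
    radius = territories[0].radius
    rhos: List[float] = []
    for k in range(n_seeds):
        rng = np.random.default_rng(child_seed(base_seed, 12 if avoidance else 13, k))
        rates = rng.uniform(0.0, 1.0, n_territories)

        def disc_points(tid: int, m: int) -> np.ndarray:
            r = radius * np.sqrt(rng.uniform(0.0, 1.0, m))
            ang = rng.uniform(0.0, 2.0 * math.pi, m)
            return centres[tid] + np.column_stack([r * np.cos(ang), r * np.sin(ang)])

        ev_rows = []
        for j in range(n_territories):
            m = rng.poisson(rates[j] * events_scale)
            if m == 0:
                continue
            pts = disc_points(j, m)
            codes = np.where(rng.random(m) < 0.5, "C", "F")
            for q in range(m):
                ev_rows.append((0, j, codes[q], pts[q, 0], pts[q, 1]))
        events = pd.DataFrame(
            ev_rows, columns=["tick", "actor_id", "behaviour_code", "x", "y"]
        )

        n_visits = n_females * visits_per_female
        if avoidance:
            weights = np.exp(-beta * rates)
            weights = weights / weights.sum()
            terr_choice = rng.choice(n_territories, size=n_visits, p=weights)
            occ_pts = np.vstack(
                [disc_points(j, int((terr_choice == j).sum())) for j in range(n_territories)
                 if (terr_choice == j).any()]
            )
        else:
            x = rng.uniform(spec.x_min, spec.x_min + spec.n_x * spec.cell_size, n_visits)
            y = rng.uniform(spec.y_min, spec.y_min + spec.n_y * spec.cell_size, n_visits)
            occ_pts = np.column_stack([x, y])
        occ_frame = pd.DataFrame(
            {
                "tick": np.arange(len(occ_pts)),
                "agent_id": np.zeros(len(occ_pts), dtype=int),
                "role": Role.FEMALE.name,
                "state": BehaviouralState.LEKKING.name,
                "x": occ_pts[:, 0],
                "y": occ_pts[:, 1],
            }
        )
        occ = occupancy_heatmap(TrajectorySet(frame=occ_frame), spec, Role.FEMALE)
        agg = aggression_heatmap(events, spec)
        rho, _ = heatmap_association(occ, agg)
        rhos.append(rho)
    return {
        "rhos": rhos,
        "negative_fraction": float(np.mean([r < 0 for r in rhos])),
        "median_abs_rho": float(np.median(np.abs(rhos))),
        "n_seeds": n_seeds,
    }
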