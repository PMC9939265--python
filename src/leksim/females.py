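"""Female mate-sampling strategies on a settled lek.

Females visit territories in discrete steps (one tick per visit) and
mate according to one of four decision rules:

- ``RANDOM``: move uniformly between territories (no immediate
  repetition) and mate at each visit with probability ``p_mate`` — the
  null model.
- ``BEST_OF_N``: sample N distinct territories without replacement,
  then return to the highest-quality one sampled and mate (ties go to
  the lowest territory id).  Produces at least one revisit per mating.
- ``THRESHOLD``: visit distinct territories without replacement until
  one meets the quality threshold, mate immediately; leave unmated if
  none qualifies.  Produces no revisits.
- ``COPYING``: with probability ``p_copy`` go straight to the
  territory of the most recent prior mating and mate there (falling
  back to a random step when no mating has happened yet); otherwise
  take a random step.  Concentrates matings on early-chosen males and
  inflates mating skew.

Females are processed sequentially in id order, so each sees the
matings of all earlier females.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Territory
from .errors import ConfigurationError, UndefinedMetricError
from .params import FemaleParams


class Strategy(str, Enum):
    RANDOM = "random"
    BEST_OF_N = "best_of_n"
    THRESHOLD = "threshold"
    COPYING = "copying"


@dataclass
class MaleQuality:
    owner_id: int
    quality: float


@dataclass
class Visit:
    territory_id: int
    entry_tick: int
    exit_tick: int


@dataclass
class VisitSequence:
    female_id: int
    visits: List[Visit] = field(default_factory=list)

    @property
    def territory_ids(self) -> List[int]:
        return [v.territory_id for v in self.visits]


@dataclass
class MatingRecord:
    female_id: int
    male_id: Optional[int]
    tick: int


def draw_qualities(
    territories: Sequence[Territory], rng: np.random.Generator
) -> List[MaleQuality]:
    """Draw one Uniform(0,1) quality per resident male, once per lek."""
    return [
        MaleQuality(owner_id=t.owner_id, quality=float(rng.uniform()))
        for t in sorted(territories, key=lambda t: t.id)
    ]


def _quality_by_territory(
    territories: Sequence[Territory], qualities: Sequence[MaleQuality]
) -> Dict[int, float]:
    by_owner = {q.owner_id: q.quality for q in qualities}
    out = {}
    for t in territories:
        if t.owner_id not in by_owner:
            raise ConfigurationError(
                f"qualities: no quality for territory owner {t.owner_id}"
            )
        out[t.id] = by_owner[t.owner_id]
    return out


def simulate_female(
    strategy: Strategy,
    territories: Sequence[Territory],
    qualities: Sequence[MaleQuality],
    prior_matings: Sequence[MatingRecord],
    params: FemaleParams,
    rng: np.random.Generator,
    female_id: int = 0,
) -> Tuple[VisitSequence, MatingRecord]:
    """Run one female through the lek under the given strategy.

    ``prior_matings`` are the realised matings of earlier females
    (used only by COPYING).  Visits dwell one tick each; the mating
    tick is the exit tick of the final visit.
    """
    strategy = Strategy(strategy)
    if not territories:
        raise ValueError("need at least one territory")
    terr = sorted(territories, key=lambda t: t.id)
    tids = [t.id for t in terr]
    owner = {t.id: t.owner_id for t in terr}
    qual = _quality_by_territory(terr, qualities)

    if strategy is Strategy.BEST_OF_N and params.best_of_n > len(tids):
        raise ConfigurationError(
            f"best_of_n: N={params.best_of_n} exceeds the {len(tids)} territories"
        )

    seq = VisitSequence(female_id=female_id)

    def visit(tid: int) -> Visit:
        v = Visit(territory_id=tid, entry_tick=len(seq.visits), exit_tick=len(seq.visits) + 1)
        seq.visits.append(v)
        return v

    def random_next(current: Optional[int]) -> int:
        choices = [t for t in tids if t != current]
        return choices[int(rng.integers(len(choices)))]

    if strategy is Strategy.BEST_OF_N:
        order = [tids[k] for k in rng.permutation(len(tids))[: params.best_of_n]]
        for tid in order:
            visit(tid)
        best = min(order, key=lambda t: (-qual[t], t))  # ties -> lowest id
        v = visit(best)
        return seq, MatingRecord(female_id, owner[best], v.exit_tick)

    if strategy is Strategy.THRESHOLD:
        order = [tids[k] for k in rng.permutation(len(tids))]
        for tid in order:
            v = visit(tid)
            if qual[tid] >= params.threshold:
                return seq, MatingRecord(female_id, owner[tid], v.exit_tick)
        return seq, MatingRecord(female_id, None, seq.visits[-1].exit_tick)

    # RANDOM and COPYING share the random-step loop
    current: Optional[int] = None
    mated = [m for m in prior_matings if m.male_id is not None]
    terr_of_male = {owner[t]: t for t in tids}
    for _ in range(params.max_visits):
        # the copy-decision draw is consumed by RANDOM too, so the two
        # strategies are draw-for-draw identical when p_copy = 0
        u_copy = rng.uniform()
        if strategy is Strategy.COPYING and mated and u_copy < params.p_copy:
            target_male = mated[-1].male_id
            tid = terr_of_male.get(target_male)
            if tid is None:
                raise ConfigurationError(
                    f"prior_matings: male {target_male} holds no territory on this lek"
                )
            v = visit(tid)
            return seq, MatingRecord(female_id, owner[tid], v.exit_tick)
        tid = random_next(current)
        current = tid
        v = visit(tid)
        if rng.uniform() < params.p_mate:
            return seq, MatingRecord(female_id, owner[tid], v.exit_tick)
    warnings.warn(
        f"female {female_id} hit max_visits={params.max_visits} without mating",
        RuntimeWarning,
    )
    return seq, MatingRecord(female_id, None, seq.visits[-1].exit_tick)


def simulate_females(
    n_females: int,
    strategy: Strategy,
    territories: Sequence[Territory],
    qualities: Sequence[MaleQuality],
    params: FemaleParams,
    seed: int,
) -> Tuple[List[VisitSequence], List[MatingRecord]]:
    """Sequentially simulate ``n_females`` females (ids 0..n-1)."""
    rng = np.random.default_rng(seed)
    visits: List[VisitSequence] = []
    matings: List[MatingRecord] = []
    for f in range(n_females):
        v, m = simulate_female(
            strategy, territories, qualities, matings, params, rng, female_id=f
        )
        visits.append(v)
        matings.append(m)
    return visits, matings


def revisit_count(visits: VisitSequence) -> int:
    """Number of visit entries to a territory already seen earlier in
    the sequence (counted per entry, not per territory)."""
    seen: set = set()
    count = 0
    for tid in visits.territory_ids:
        if tid in seen:
            count += 1
        seen.add(tid)
    return count


def mating_counts(
    matings: Sequence[MatingRecord], male_ids: Sequence[int]
) -> np.ndarray:
    counts = {int(m): 0 for m in male_ids}
    for rec in matings:
        if rec.male_id is not None:
            if rec.male_id not in counts:
                raise ValueError(f"mating by unknown male {rec.male_id}")
            counts[rec.male_id] += 1
    return np.array([counts[int(m)] for m in male_ids], dtype=np.int64)


def mating_skew(matings: Sequence[MatingRecord], n_males: int) -> float:
    """Gini coefficient of per-male mating counts (zeros included).

    G = Σ_ij |m_i − m_j| / (2 n Σ_i m_i).  Males never mated still
    count in the denominator's n.  Returns 0.0 (with a RuntimeWarning)
    when no matings occurred at all.
    """
    if n_males <= 0:
        raise ValueError("n_males must be positive")
    counts = np.zeros(n_males, dtype=np.int64)
    index = {}
    for rec in matings:
        if rec.male_id is None:
            continue
        if rec.male_id not in index:
            if len(index) >= n_males:
                raise ValueError("more distinct mated males than n_males")
            index[rec.male_id] = len(index)
        counts[index[rec.male_id]] += 1
    total = counts.sum()
    if total == 0:
        warnings.warn("no matings occurred; skew undefined, returning 0", RuntimeWarning)
        return 0.0
    diffs = np.abs(counts[:, None] - counts[None, :]).sum()
    return float(diffs / (2.0 * n_males * total))


def central_preference_index(
    visit_sequences: Sequence[VisitSequence], territories: Sequence[Territory]
) -> float:
    """Ratio of visited-territory centrality to overall centrality.

    For each female, the mean distance of her visited territory
    centres (with multiplicity) to the lek centroid is divided by the
    mean distance of *all* territory centres; the index is the mean of
    that ratio over females.  Values below 1 indicate preferential use
    of central territories.
    """
    if not territories:
        raise ValueError("need at least one territory")
    centres = {t.id: np.asarray(t.centre, dtype=float) for t in territories}
    C = np.array(list(centres.values()))
    centroid = C.mean(axis=0)
    all_mean = float(np.linalg.norm(C - centroid, axis=1).mean())
    if all_mean == 0.0:
        raise UndefinedMetricError("all territories at the centroid; index undefined")
    ratios = []
    for seq in visit_sequences:
        if not seq.visits:
            continue
        d = [float(np.linalg.norm(centres[tid] - centroid)) for tid in seq.territory_ids]
        ratios.append(np.mean(d) / all_mean)
    if not ratios:
        raise UndefinedMetricError("no visits supplied")
    return float(np.mean(ratios))
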