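"""Departure statistics, heatmaps and rank association.

The fuzz tests check each statistic against an independent brute-force
reimplementation on many small random instances, exactly.
"""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from leksim.core import BehaviouralState, Role, TrajectorySet
from leksim.errors import SchemaError, UndefinedMetricError
from leksim.foraging import DepartureRecord
from leksim.metrics import (
    AGGRESSION_CODES,
    GridSpec,
    HeatmapGrid,
    HeatmapKind,
    aggression_heatmap,
    departure_steepness,
    departure_synchrony,
    heatmap_association,
    occupancy_heatmap,
)


def dep(agent_id, tick, neighbours=()):
    return DepartureRecord(agent_id, tick, None, frozenset(neighbours))


def female_traj(points):
    return TrajectorySet(
        frame=pd.DataFrame(
            {
                "tick": range(len(points)),
                "agent_id": 0,
                "role": Role.FEMALE.name,
                "state": BehaviouralState.LEKKING.name,
                "x": [p[0] for p in points],
                "y": [p[1] for p in points],
            }
        )
    )


class TestSynchrony:
    def test_simultaneous_departures_one(self):
        deps = [dep(i, 5, {j for j in range(4) if j != i}) for i in range(4)]
        frac, used_nb = departure_synchrony(deps, 2)
        assert frac == 1.0 and used_nb

    def test_wide_gaps_zero(self):
        deps = [dep(0, 0, {1}), dep(1, 50, {0})]
        assert departure_synchrony(deps, 5)[0] == 0.0

    def test_no_neighbour_pairs_falls_back_flagged(self):
        deps = [dep(0, 0), dep(1, 2), dep(2, 50)]
        frac, used_nb = departure_synchrony(deps, 5)
        assert not used_nb
        assert frac == pytest.approx(1 / 3)

    def test_single_departure_undefined(self):
        with pytest.raises(UndefinedMetricError):
            departure_synchrony([dep(0, 1)], 5)

    def test_matches_brute_force_on_fuzzed_instances(self):
        rng = np.random.default_rng(101)
        for _ in range(400):
            n = int(rng.integers(2, 12))
            ids = list(range(n))
            deps = []
            for i in ids:
                nb = {j for j in ids if j != i and rng.random() < 0.4}
                deps.append(dep(i, int(rng.integers(0, 30)), nb))
            w = int(rng.integers(0, 8))
            got, _ = departure_synchrony(deps, w)
            # oracle: direct double loop
            close = total = 0
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = deps[i], deps[j]
                    if (
                        a.agent_id in b.neighbours_at_departure
                        or b.agent_id in a.neighbours_at_departure
                    ):
                        total += 1
                        close += abs(a.departure_tick - b.departure_tick) <= w
            if total == 0:
                total = n * (n - 1) // 2
                close = sum(
                    abs(deps[i].departure_tick - deps[j].departure_tick) <= w
                    for i in range(n)
                    for j in range(i + 1, n)
                )
            assert got == close / total


class TestSteepness:
    def test_mass_departure_one(self):
        deps = [dep(i, 7) for i in range(10)]
        assert departure_steepness(deps, 10, 3) == 1.0

    def test_single_departure(self):
        assert departure_steepness([dep(0, 3)], 20, 5) == pytest.approx(1 / 20)

    def test_no_departures_zero(self):
        assert departure_steepness([], 10, 5) == 0.0

    def test_matches_exhaustive_window_scan(self):
        rng = np.random.default_rng(202)
        for _ in range(400):
            n_males = int(rng.integers(2, 20))
            k = int(rng.integers(0, n_males + 1))
            ticks = rng.integers(0, 40, k)
            deps = [dep(i, int(t)) for i, t in enumerate(ticks)]
            w = int(rng.integers(0, 10))
            got = departure_steepness(deps, n_males, w)
            best = 0
            for t in range(-10, 60):  # oracle: scan every window start
                best = max(best, int(((ticks >= t) & (ticks <= t + w)).sum()))
            assert got == best / n_males


class TestHeatmaps:
    def test_stationary_female_single_cell(self):
        spec = GridSpec(0.0, 0.0, 1.0, 5, 5)
        traj = female_traj([(2.5, 3.5)] * 10)
        grid = occupancy_heatmap(traj, spec, Role.FEMALE)
        assert grid.values[3, 2] == 10
        assert grid.values.sum() == 10
        assert grid.overflow == 0

    def test_role_filter_excludes_others(self):
        spec = GridSpec(0.0, 0.0, 1.0, 5, 5)
        traj = female_traj([(1.5, 1.5)] * 4)
        grid = occupancy_heatmap(traj, spec, Role.RESIDENT_MALE)
        assert grid.values.sum() == 0

    def test_out_of_grid_goes_to_overflow_not_dropped(self):
        spec = GridSpec(0.0, 0.0, 1.0, 3, 3)
        traj = female_traj([(1.0, 1.0), (99.0, 99.0), (-5.0, 0.0)])
        grid = occupancy_heatmap(traj, spec, Role.FEMALE)
        assert grid.values.sum() == 1
        assert grid.overflow == 2
        assert grid.total == 3

    def test_conservation_on_simulated_run(self, params):
        from leksim.core import run_formation

        traj = run_formation(params.replace(n_males=5, formation_steps=40), 8)
        spec = GridSpec(-10.0, -10.0, 2.0, 10, 10)
        grid = occupancy_heatmap(traj, spec, Role.RESIDENT_MALE)
        assert grid.total == 5 * 41  # every agent-tick lands somewhere

    def test_aggression_counts_filtered_codes(self):
        spec = GridSpec(0.0, 0.0, 1.0, 4, 4)
        events = pd.DataFrame(
            {
                "tick": [0, 1, 2, 3],
                "actor_id": [0, 0, 1, 1],
                "behaviour_code": ["C", "F", "F", "D"],
                "x": [0.5, 0.5, 0.5, 0.5],
                "y": [0.5, 0.5, 0.5, 0.5],
            }
        )
        grid = aggression_heatmap(events, spec)
        assert grid.values[0, 0] == 3  # D excluded by default codes
        zero = aggression_heatmap(events, spec, codes={"P"})
        assert zero.values.sum() == 0

    def test_unknown_filter_code_rejected(self):
        spec = GridSpec(0.0, 0.0, 1.0, 4, 4)
        events = pd.DataFrame(
            {"tick": [0], "actor_id": [0], "behaviour_code": ["C"], "x": [0.5], "y": [0.5]}
        )
        with pytest.raises(ValueError, match="unknown behaviour codes"):
            aggression_heatmap(events, spec, codes={"X"})

    def test_unknown_event_code_rejected_with_row(self):
        spec = GridSpec(0.0, 0.0, 1.0, 4, 4)
        events = pd.DataFrame(
            {
                "tick": [0, 1],
                "actor_id": [0, 0],
                "behaviour_code": ["C", "Q"],
                "x": [0.5, 0.5],
                "y": [0.5, 0.5],
            }
        )
        with pytest.raises(SchemaError, match="row 2"):
            aggression_heatmap(events, spec)

    def test_nonpositive_cell_size_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0.0, 0.0, 0.0, 4, 4)


class TestAssociation:
    def grid(self, values):
        values = np.asarray(values, dtype=float)
        spec = GridSpec(0.0, 0.0, 1.0, values.shape[1], values.shape[0])
        return HeatmapGrid(spec=spec, values=values, kind=HeatmapKind.EVENT_COUNT)

    def test_self_association_one(self, rng):
        a = self.grid(rng.integers(0, 9, (5, 5)))
        rho, n = heatmap_association(a, a)
        assert rho == pytest.approx(1.0)
        assert n == int((a.values > 0).sum())

    def test_reversed_association_minus_one(self, rng):
        vals = rng.permutation(25).reshape(5, 5).astype(float)
        a = self.grid(vals)
        b = self.grid(vals.max() - vals + 1.0)
        rho, _ = heatmap_association(a, b)
        assert rho == pytest.approx(-1.0)

    def test_geometry_mismatch_rejected(self, rng):
        a = self.grid(np.ones((4, 4)))
        b = self.grid(np.ones((5, 5)))
        with pytest.raises(ValueError, match="geometry"):
            heatmap_association(a, b)

    def test_too_few_informative_cells_undefined(self):
        a = self.grid(np.zeros((4, 4)))
        b = self.grid(np.zeros((4, 4)))
        with pytest.raises(UndefinedMetricError):
            heatmap_association(a, b)


class TestRangeProperties:
    @given(
        ticks=st.lists(st.integers(0, 100), min_size=2, max_size=30),
        w=st.integers(0, 20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_synchrony_in_unit_interval(self, ticks, w):
        deps = [dep(i, t, {j for j in range(len(ticks)) if j != i}) for i, t in enumerate(ticks)]
        frac, _ = departure_synchrony(deps, w)
        assert 0.0 <= frac <= 1.0

    @given(
        ticks=st.lists(st.integers(0, 100), min_size=0, max_size=20),
        extra=st.integers(0, 10),
        w=st.integers(0, 20),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_steepness_in_unit_interval(self, ticks, extra, w):
        n_males = len(ticks) + extra if ticks or extra else 1
        deps = [dep(i, t) for i, t in enumerate(ticks)]
        assert 0.0 <= departure_steepness(deps, max(n_males, 1), w) <= 1.0

    @given(st.lists(st.integers(0, 5), min_size=4, max_size=25))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_gini_in_unit_range(self, counts):
        from leksim.females import MatingRecord, mating_skew

        matings = [
            MatingRecord(f, m, 1) for m, c in enumerate(counts) for f in range(c)
        ]
        if not matings:
            return
        g = mating_skew(matings, len(counts))
        assert 0.0 <= g < 1.0
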