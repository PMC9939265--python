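"""Movement rules: placement, attraction, repulsion, priority, updates."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from leksim.core import (
    AgentState,
    BehaviouralState,
    Role,
    SimulationState,
    advance,
    attraction_velocity,
    derive_territories,
    init_state,
    repulsion_velocity,
    resolve_velocity,
    run_formation,
)
from leksim.errors import ConfigurationError
from leksim.params import ModelParams


def make_state(positions, params, seed=0):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return SimulationState(
        tick=0,
        ids=np.arange(n, dtype=np.int64),
        roles=np.full(n, Role.RESIDENT_MALE, dtype=np.int64),
        positions=positions.copy(),
        headings=np.zeros(n),
        states=np.full(n, BehaviouralState.LEKKING, dtype=np.int64),
        rng=np.random.default_rng(seed),
    )


class TestInitState:
    def test_deterministic_under_fixed_seed(self, params):
        a = init_state(params, 7)
        b = init_state(params, 7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.headings, b.headings)

    def test_placement_box_containment(self):
        p = ModelParams(n_males=200, arena_half_width=13.0, centre=(3.0, -2.0))
        s = init_state(p, 1)
        assert np.all(np.abs(s.positions[:, 0] - 3.0) <= 13.0)
        assert np.all(np.abs(s.positions[:, 1] + 2.0) <= 13.0)
        assert np.all(s.states == BehaviouralState.LEKKING)
        assert np.all((s.headings >= 0) & (s.headings < 2 * math.pi))

    def test_mean_position_clt(self):
        # mean of n uniforms on [-L, L] has sd L/sqrt(3 n) per axis
        L = 50.0
        p = ModelParams(n_males=10_000, arena_half_width=L)
        s = init_state(p, 5)
        bound = 3.0 * L / math.sqrt(3 * 10_000)
        assert np.all(np.abs(s.positions.mean(axis=0)) <= bound)

    def test_invalid_params_name_field(self):
        with pytest.raises(ConfigurationError, match="n_males"):
            ModelParams(n_males=1)
        with pytest.raises(ConfigurationError, match="p_f"):
            ModelParams(p_f=1.5)
        with pytest.raises(ConfigurationError, match="speed"):
            ModelParams(speed=0.0)
        with pytest.raises(ConfigurationError, match="R_attr"):
            ModelParams(attraction_on=True, R_attr=0.5, R_r=1.0)


class TestAttraction:
    def test_noiseless_pull_toward_centre(self, rng):
        p = ModelParams(noise_sd=0.0, speed=0.7)
        v = attraction_velocity(np.array([5.0, 0.0]), p, rng)
        assert np.allclose(v, [-0.7, 0.0])

    def test_constant_speed_contract(self, rng):
        p = ModelParams(speed=0.3)
        for _ in range(50):
            pos = rng.normal(0, 10, 2)
            v = attraction_velocity(pos, p, rng)
            norm = np.linalg.norm(v)
            assert norm == pytest.approx(0.3) or norm == 0.0

    def test_zero_within_arrival_tolerance(self, rng):
        p = ModelParams(arrival_tol=0.5)
        assert np.array_equal(
            attraction_velocity(np.array([0.3, 0.0]), p, rng), np.zeros(2)
        )

    def test_heading_error_circular_sd_matches_noise_sd(self):
        # the heading error law is wrapped normal, whose circular std
        # equals the underlying sd
        p = ModelParams(noise_sd=0.3, speed=1.0)
        rng = np.random.default_rng(11)
        pos = np.array([10.0, 0.0])
        errs = []
        for _ in range(100_000):
            v = attraction_velocity(pos, p, rng)
            errs.append(math.atan2(v[1], v[0]) - math.pi)
        sd = stats.circstd(np.asarray(errs))
        assert sd == pytest.approx(0.3, abs=0.01)


class TestRepulsion:
    def test_directly_away_from_lone_neighbour(self, params, rng):
        v = repulsion_velocity(np.zeros(2), np.array([[0.5, 0.0]]), params, rng)
        assert np.allclose(v, [-params.speed, 0.0])

    def test_symmetry_cancels_lateral_component(self, params, rng):
        nb = np.array([[0.3, 0.2], [0.3, -0.2]])
        v = repulsion_velocity(np.zeros(2), nb, params, rng)
        assert np.allclose(v, [-params.speed, 0.0])

    def test_nearest_mode_ignores_far_neighbour(self, rng):
        p = ModelParams(repulsion_mode="nearest")
        nb = np.array([[0.2, 0.0], [0.0, 0.9]])
        v = repulsion_velocity(np.zeros(2), nb, p, rng)
        assert np.allclose(v, [-p.speed, 0.0])

    def test_coincident_tiebreak_direction_uniform(self, params):
        # degenerate centroid: direction should be uniform on the circle
        rng = np.random.default_rng(3)
        angles = []
        for _ in range(800):
            v = repulsion_velocity(np.zeros(2), np.zeros((1, 2)), params, rng)
            assert np.linalg.norm(v) == pytest.approx(params.speed)
            angles.append(math.atan2(v[1], v[0]) % (2 * math.pi))
        counts, _ = np.histogram(angles, bins=8, range=(0, 2 * math.pi))
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_requires_neighbours(self, params, rng):
        with pytest.raises(ValueError):
            repulsion_velocity(np.zeros(2), np.empty((0, 2)), params, rng)


class TestResolve:
    def agent(self, pos):
        return AgentState(0, Role.RESIDENT_MALE, np.asarray(pos, float), 0.0,
                          BehaviouralState.LEKKING)

    def test_repulsion_wins_within_radius(self, params):
        rng = np.random.default_rng(0)
        nb = np.array([[0.9 * params.R_r, 0.0]])
        v = resolve_velocity(self.agent([0, 0]), nb, params, rng)
        expected = repulsion_velocity(np.zeros(2), nb, params, np.random.default_rng(0))
        assert np.array_equal(v, expected)

    def test_attraction_when_no_neighbour(self, params):
        v = resolve_velocity(
            self.agent([4.0, 0.0]), np.empty((0, 2)), params, np.random.default_rng(1)
        )
        expected = attraction_velocity(
            np.array([4.0, 0.0]), params, np.random.default_rng(1)
        )
        assert np.array_equal(v, expected)

    def test_boundary_distance_counts_as_within(self, params):
        # closed-ball convention, exercised through the full update
        s = make_state([[0.0, 0.0], [params.R_r, 0.0]], params.replace(noise_sd=0.0))
        advance(s, params.replace(noise_sd=0.0))
        # both agents repelled straight apart along x
        assert s.positions[0, 0] < 0.0
        assert s.positions[1, 0] > params.R_r


class TestAdvance:
    def test_single_agent_attraction_step(self):
        p = ModelParams(noise_sd=0.0, speed=0.2)
        s = make_state([[5.0, 0.0], [100.0, 100.0]], p)
        advance(s, p)
        assert np.allclose(s.positions[0], [4.8, 0.0])
        assert s.tick == 1

    def test_every_step_exact_speed_or_zero(self, params):
        s = init_state(params.replace(n_males=15, arena_half_width=3.0), 2)
        for _ in range(60):
            before = s.positions.copy()
            advance(s, params)
            d = np.linalg.norm(s.positions - before, axis=1)
            assert np.all(
                np.isclose(d, params.speed, atol=1e-12) | np.isclose(d, 0.0)
            )

    def test_priority_gating_bit_for_bit(self, params):
        # an agent with a neighbour inside R_r moves by the exact
        # repulsion output, no blending
        from leksim.core import _formation_displacements

        s = init_state(params.replace(n_males=12, arena_half_width=1.5), 9)
        pos0 = s.positions.copy()
        rng_clone = np.random.default_rng(0)
        rng_clone.bit_generator.state = s.rng.bit_generator.state
        disp = _formation_displacements(pos0, params, rng_clone)
        advance(s, params)
        assert np.array_equal(s.positions, pos0 + disp)
        D = cdist(pos0, pos0)
        np.fill_diagonal(D, np.inf)
        nb_mask = D <= params.R_r
        assert nb_mask.any(), "fixture should produce crowded agents"
        for i in range(12):
            if nb_mask[i].any():
                expected = repulsion_velocity(pos0[i], pos0[nb_mask[i]], params)
                assert np.array_equal(disp[i], expected)

    def test_reflection_symmetry_noiseless(self):
        p = ModelParams(noise_sd=0.0)
        base = np.random.default_rng(4).uniform(-10, 10, (8, 2))
        a = make_state(base, p)
        b = make_state(base * np.array([1.0, -1.0]), p)
        for _ in range(100):
            advance(a, p)
            advance(b, p)
        assert np.allclose(a.positions * np.array([1.0, -1.0]), b.positions)


class TestFormation:
    def test_noiseless_single_distance_arithmetic(self):
        # one agent reaches the centre in ceil((d - tol)/s) steps; the
        # second agent sits far away so it never interacts
        p = ModelParams(noise_sd=0.0, speed=0.2, arrival_tol=0.2)
        s = make_state([[7.0, 0.0], [1000.0, 1000.0]], p)
        d, tol, sp = 7.0, 0.2, 0.2
        k = math.ceil((d - tol) / sp)
        for step in range(1, k + 1):
            advance(s, p)
        assert np.linalg.norm(s.positions[0]) <= tol

    def test_formation_contracts_and_spaces(self):
        p = ModelParams(n_males=15, arena_half_width=30.0, formation_steps=800)
        traj = run_formation(p, 3)
        first = traj.positions_at(0)[["x", "y"]].to_numpy()
        last = traj.positions_at(800)[["x", "y"]].to_numpy()
        assert np.sqrt((last**2).sum(1).mean()) < np.sqrt((first**2).sum(1).mean())
        D = cdist(last, last)
        np.fill_diagonal(D, np.inf)
        assert np.median(D.min(axis=1)) >= 0.5 * p.R_r

    def test_identical_seed_identical_trajectory(self):
        p = ModelParams(n_males=6, formation_steps=50)
        a = run_formation(p, 5)
        b = run_formation(p, 5)
        assert a.frame.equals(b.frame)


class TestDeriveTerritories:
    def test_stationary_agents_centres_equal_positions(self, params):
        from leksim.core import frame_from_arrays, TrajectorySet

        pos = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 6.0]])
        positions = np.repeat(pos[None, :, :], 10, axis=0)
        states = np.zeros((10, 3), dtype=np.int64)
        frame = frame_from_arrays(
            np.arange(3), np.zeros(3, dtype=np.int64), positions, states
        )
        terr = derive_territories(TrajectorySet(frame=frame), window=5)
        assert len(terr) == 3
        for t, expected in zip(terr, pos):
            assert np.allclose(t.centre, expected)
        # NN distances: 4, 4, 6 -> mean 14/3, radius half that
        assert terr[0].radius == pytest.approx((4 + 4 + 6) / 3 / 2)

    def test_two_males_radius_half_separation(self, params):
        from leksim.core import frame_from_arrays, TrajectorySet

        pos = np.array([[0.0, 0.0], [2.0, 0.0]])
        positions = np.repeat(pos[None, :, :], 4, axis=0)
        states = np.zeros((4, 2), dtype=np.int64)
        frame = frame_from_arrays(
            np.arange(2), np.zeros(2, dtype=np.int64), positions, states
        )
        terr = derive_territories(TrajectorySet(frame=frame), window=4)
        assert terr[0].radius == pytest.approx(1.0)

    def test_jittering_agent_centre_is_time_average(self, rng):
        from leksim.core import frame_from_arrays, TrajectorySet

        T = 50
        jitter = rng.normal(0, 0.1, (T, 2, 2))
        base = np.array([[0.0, 0.0], [5.0, 0.0]])
        positions = base[None, :, :] + jitter
        states = np.zeros((T, 2), dtype=np.int64)
        frame = frame_from_arrays(
            np.arange(2), np.zeros(2, dtype=np.int64), positions, states
        )
        terr = derive_territories(TrajectorySet(frame=frame), window=T)
        for k in range(2):
            assert np.allclose(terr[k].centre, positions[:, k, :].mean(axis=0))

    def test_window_longer_than_run_errors(self, params):
        traj = run_formation(ModelParams(n_males=3, formation_steps=10), 1)
        with pytest.raises(ValueError, match="window"):
            derive_territories(traj, window=50)
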