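"""Model parameters and validation.

All lengths are in arena units with the male–male repulsion radius
``R_r`` as the natural scale (default 1.0); all rates are per discrete
time step (Δt = 1).  Behavioural rules live in :mod:`leksim.core`,
:mod:`leksim.foraging`, :mod:`leksim.intruder` and :mod:`leksim.females`;
this module only declares the constants they read.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Tuple

from .errors import ConfigurationError

Point = Tuple[float, float]

#: How a male resolves repulsion from several neighbours at once.
REPULSION_MODES = ("centroid", "nearest")


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{name}: {msg}")


def _check_prob(value: float, name: str) -> None:
    _check(
        isinstance(value, (int, float)) and math.isfinite(value) and 0.0 <= value <= 1.0,
        name,
        f"must be a probability in [0, 1], got {value!r}",
    )


def _check_pos(value: float, name: str) -> None:
    _check(
        isinstance(value, (int, float)) and math.isfinite(value) and value > 0,
        name,
        f"must be a positive finite number, got {value!r}",
    )


def _check_point(value, name: str) -> Tuple[float, float]:
    try:
        x, y = float(value[0]), float(value[1])
    except (TypeError, ValueError, IndexError):
        raise ConfigurationError(f"{name}: must be a 2D point, got {value!r}") from None
    _check(math.isfinite(x) and math.isfinite(y), name, "coordinates must be finite")
    return (x, y)


@dataclass
class ModelParams:
    """Constants of the lek-formation and foraging model.

    Attributes
    ----------
    n_males:
        Number of resident males placed at the start of the season.
    arena_half_width:
        Half-width of the square box, centred on ``centre``, in which
        males are placed uniformly at tick 0.  The plane itself is
        unbounded; this only bounds the initial condition.
    centre:
        Breeding-ground centre; the target of the site-fidelity
        attraction rule.  Origin by default.
    speed:
        Per-step displacement magnitude ``s``.  Every moving agent
        covers exactly this distance each tick.
    noise_sd:
        Standard deviation (radians) of the wrapped-normal heading
        error applied to the attraction rule.  Repulsion is noiseless.
    R_r:
        Short-range repulsion radius.  A male with any other male
        within this distance (closed ball) ignores attraction and
        steps directly away from them.
    R_attr, attraction_on:
        Optional mid-range male–male attraction: when enabled, a male
        with no neighbour inside ``R_r`` but at least one inside
        ``R_attr`` steps towards the centroid of those mid-range
        neighbours instead of the breeding centre.  Off by default;
        the baseline formation model uses only fidelity + repulsion.
    R_social:
        Radius of the copying neighbourhood used by the social
        foraging rule, by coordinated chasing and by the departure
        synchrony statistic.
    p_f:
        Per-step probability of an independent switch to the foraging
        state.
    p_spont, k_copy:
        Social foraging model: switch probability is
        ``clip(p_spont + k_copy * n_foraging_neighbours, 0, 1)``.
        ``p_spont`` seeds the first departures; ``k_copy`` is the
        per-neighbour copying increment.
    foraging_site:
        Location of the foraging site / water hole males travel to.
    arrival_tol:
        Distance within which a target (centre, foraging site) counts
        as reached; also the zero-displacement radius of the
        attraction rule.
    formation_steps, episode_steps:
        Tick counts of the lek-formation phase and of one foraging
        activity window.
    repulsion_mode:
        ``"centroid"`` — step away from the centroid of all
        neighbours within ``R_r``; ``"nearest"`` — away from the
        nearest neighbour only.
    seed:
        Default RNG seed for runs configured from file.
    """

    n_males: int = 20
    arena_half_width: float = 50.0
    centre: Point = (0.0, 0.0)
    speed: float = 0.2
    noise_sd: float = 0.2
    R_r: float = 1.0
    R_attr: float = 5.0
    attraction_on: bool = False
    R_social: float = 5.0
    p_f: float = 0.01
    p_spont: float = 0.002
    k_copy: float = 0.05
    foraging_site: Point = (30.0, 0.0)
    arrival_tol: float = 0.2
    formation_steps: int = 2000
    episode_steps: int = 500
    repulsion_mode: str = "centroid"
    seed: int = 0

    def __post_init__(self) -> None:
        self.centre = _check_point(self.centre, "centre")
        self.foraging_site = _check_point(self.foraging_site, "foraging_site")
        self.validate()

    def validate(self) -> None:
        _check(isinstance(self.n_males, int) and self.n_males >= 2, "n_males",
               f"must be an integer >= 2, got {self.n_males!r}")
        _check_pos(self.arena_half_width, "arena_half_width")
        _check_pos(self.speed, "speed")
        _check(isinstance(self.noise_sd, (int, float)) and math.isfinite(self.noise_sd)
               and self.noise_sd >= 0, "noise_sd",
               f"must be a nonnegative finite number, got {self.noise_sd!r}")
        _check_pos(self.R_r, "R_r")
        _check_pos(self.R_attr, "R_attr")
        _check_pos(self.R_social, "R_social")
        _check_pos(self.arrival_tol, "arrival_tol")
        if self.attraction_on:
            _check(self.R_r < self.R_attr, "R_attr",
                   f"must exceed R_r={self.R_r} when attraction_on")
        _check_prob(self.p_f, "p_f")
        _check_prob(self.p_spont, "p_spont")
        _check(isinstance(self.k_copy, (int, float)) and math.isfinite(self.k_copy)
               and self.k_copy >= 0, "k_copy",
               f"must be a nonnegative finite number, got {self.k_copy!r}")
        _check(isinstance(self.formation_steps, int) and self.formation_steps >= 1,
               "formation_steps", f"must be an integer >= 1, got {self.formation_steps!r}")
        _check(isinstance(self.episode_steps, int) and self.episode_steps >= 1,
               "episode_steps", f"must be an integer >= 1, got {self.episode_steps!r}")
        _check(self.repulsion_mode in REPULSION_MODES, "repulsion_mode",
               f"must be one of {REPULSION_MODES}, got {self.repulsion_mode!r}")
        _check(isinstance(self.seed, int) and self.seed >= 0, "seed",
               f"must be a nonnegative integer, got {self.seed!r}")

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class IntruderParams:
    """Constants of the intruder-chasing scenario.

    ``latency_max`` — each resident draws a reaction latency once,
    uniform on the integers [0, latency_max] ticks, between the
    intruder entering its territory and the chase starting.
    ``k_chase`` — coordinated mode: per-tick probability of joining a
    chase is ``min(1, k_chase * n_chasing_neighbours_within_R_social)``.
    ``flee_speed_factor`` — a chased intruder flees directly away from
    its nearest chaser at this multiple of the resident speed.
    ``stop_radius_factor`` — a resident abandons the chase once the
    intruder is beyond this multiple of its territory radius from its
    own territory centre, then returns home.
    ``max_ticks`` — hard cap on episode length.
    """

    latency_max: int = 20
    k_chase: float = 1.0
    flee_speed_factor: float = 1.2
    stop_radius_factor: float = 2.0
    max_ticks: int = 400

    def __post_init__(self) -> None:
        _check(isinstance(self.latency_max, int) and self.latency_max >= 0,
               "latency_max", f"must be a nonnegative integer, got {self.latency_max!r}")
        _check(isinstance(self.k_chase, (int, float)) and math.isfinite(self.k_chase)
               and self.k_chase >= 0, "k_chase",
               f"must be a nonnegative finite number, got {self.k_chase!r}")
        _check_pos(self.flee_speed_factor, "flee_speed_factor")
        _check(self.stop_radius_factor >= 1, "stop_radius_factor",
               f"must be >= 1, got {self.stop_radius_factor!r}")
        _check(isinstance(self.max_ticks, int) and self.max_ticks >= 1,
               "max_ticks", f"must be an integer >= 1, got {self.max_ticks!r}")

    def replace(self, **kwargs) -> "IntruderParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class FemaleParams:
    """Constants of the female mate-sampling strategies.

    ``p_mate`` — per-visit mating probability under random sampling.
    ``best_of_n`` — number of distinct territories sampled under the
    best-of-N strategy before returning to the best one.
    ``threshold`` — minimum acceptable male quality under the
    threshold strategy.
    ``p_copy`` — probability per decision that a copying female
    targets the territory of the most recent prior mating instead of
    taking a random step.
    """

    p_mate: float = 0.2
    best_of_n: int = 5
    threshold: float = 0.7
    p_copy: float = 0.8
    max_visits: int = 100_000

    def __post_init__(self) -> None:
        _check_prob(self.p_mate, "p_mate")
        _check(self.p_mate > 0, "p_mate", "must be positive (random sampling never terminates otherwise)")
        _check(isinstance(self.best_of_n, int) and self.best_of_n >= 1,
               "best_of_n", f"must be an integer >= 1, got {self.best_of_n!r}")
        _check(isinstance(self.threshold, (int, float)) and math.isfinite(self.threshold),
               "threshold", f"must be a finite number, got {self.threshold!r}")
        _check_prob(self.p_copy, "p_copy")
        _check(isinstance(self.max_visits, int) and self.max_visits >= 1,
               "max_visits", f"must be an integer >= 1, got {self.max_visits!r}")

    def replace(self, **kwargs) -> "FemaleParams":
        return dataclasses.replace(self, **kwargs)
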