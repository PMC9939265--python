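# Methods

## Model overview

`leksim` simulates a lek as a self-propelled-particle system in
continuous 2-D space and discrete time (Δt = 1; all rates are
per-step).  The plane is unbounded — no walls or habitat structure —
and the initial condition places `n_males` resident males uniformly in
a square box of half-width `arena_half_width` centred on the breeding
ground.  Updates are synchronous: all displacements for a tick are
computed from the previous tick's positions, then applied at once.
This is the standard scheme for Vicsek-class models and makes runs
bit-for-bit reproducible from a (parameters, seed) pair.  A single RNG
stream drives each run; agents are processed in ascending id order,
and per-tick random draws are consumed in a fixed layout regardless of
which rules fire, so rule outcomes never shift the stream for other
agents.

### Movement rules (lek formation)

Each lekking male applies, in strict priority order:

1. **Short-range repulsion.**  If any other male lies within the
   *closed* ball of radius `R_r`, step at speed `speed` directly away
   from the centroid of all such neighbours (or the nearest one, with
   `repulsion_mode="nearest"`).  Repulsion carries no heading noise;
   the noise term attaches to site fidelity only.
2. **Site fidelity.**  Otherwise step at `speed` towards the breeding
   centre, with a wrapped-normal heading error of standard deviation
   `noise_sd`.  Within `arrival_tol` of the target the bearing is
   undefined and the displacement is zero.

Two degenerate cases have explicit tie-breaks: an agent exactly at the
repulsion centroid moves in a uniformly random direction at full
speed, and an agent within `arrival_tol` of its target does not move.
An optional mid-range attraction rule (off by default) inserts between
the two: a male with no neighbour inside `R_r` but neighbours inside
`R_attr` steps towards their centroid instead of the centre.

Every per-tick displacement has magnitude exactly `speed` or 0.  There
is no inertia and no within-lek spatial fidelity: males returning from
a foraging trip head for the breeding centre, not their old territory.

### Territories

The paper-independent housekeeping step of turning a settled lek into
marked territories is a package convention: each male's territory
centre is its mean position over the last `window` ticks of a
formation run, and all territories share one radius — half the mean
nearest-neighbour distance among centres.  On synthetic ring or
hexagonal leks with spacing 2`R_r` this yields radius `R_r`.

### Foraging departures

Within an activity window of `episode_steps` ticks, every lekking male
that has not yet foraged evaluates a switch probability each tick:

- independent: `p_f`;
- social: `min(1, p_spont + k_copy * n)`, with `n` the number of
  FORAGING_OUT residents within `R_social` at the previous tick.

The linear social form needs two constants the hypothesis itself does
not fix: without a spontaneous term no cascade can start, so
`p_spont` seeds departures, and `k_copy` scales the per-neighbour
copying increment.  With `k_copy = 0` and `p_spont = p_f` the social
model reproduces the independent model draw-for-draw.  RETURNING males
are deliberately not counted as foraging neighbours: copying is a
response to departures, not arrivals.

A switched male travels to `foraging_site` (same noisy constant-speed
kinematics), switches to RETURNING on arrival, heads back to the
breeding centre, and resumes lekking; it is ineligible to depart again
in the same window.  Travellers are socially invisible: they neither
repel nor get counted by lekking males, and ignore repulsion
themselves.

### Intruder chasing

An intruder male enters at a configured point and moves at `speed`
towards an exit point.  Resident behaviour during an episode is
anchored to territories: non-chasing residents hold station at their
own territory centre (sending them to the breeding centre would
collapse the settled geometry mid-episode).

- **Independent rule.**  When the intruder first enters a resident's
  territory, a reaction countdown starts — a latency drawn once per
  resident, uniform on the integers [0, `latency_max`].  The chase
  launches when the countdown expires even if the intruder has moved
  on: a reaction delay postpones a chase, it does not cancel it.
- **Coordinated rule.**  Additionally, a lekking resident with `c`
  chasing neighbours within `R_social` joins with probability
  `min(1, k_chase * c)` per tick, provided the intruder is still
  within its own chase range (otherwise the recruit would stop in the
  same tick it started).

A chaser pursues the intruder's last observed position at `speed` and
abandons the chase once the intruder is beyond
`stop_radius_factor × territory radius` from its own territory centre.
A chased intruder flees directly away from its nearest chaser at
`flee_speed_factor × speed`; unchased, it resumes course to the exit.
The episode ends at the exit, on escape beyond the lek area, or after
`max_ticks`.  Latency, the flee multiplier (1.2), the stop radius
(2×) and `k_chase` are model conventions required to make the two
sketched scenarios concrete; all are configuration parameters.

### Female strategies

Qualities are drawn once per lek, Uniform(0, 1) per resident male.
Females are processed sequentially (arrival order = id), each seeing
the realised matings of earlier females; visits dwell one tick.

- RANDOM: uniform moves between territories (no immediate
  repetition), mating with `p_mate` per visit.
- BEST_OF_N: `N` distinct territories sampled uniformly without
  replacement, then a return visit to the highest-quality sampled
  territory (ties to the lowest territory id) and a certain mating.
- THRESHOLD: distinct territories without replacement until quality ≥
  θ; mates immediately; leaves unmated if the lek is exhausted.
- COPYING: with probability `p_copy` the female goes straight to the
  territory of the most recent prior mating and mates there —
  copying *is* the choice, so no further `p_mate` coin is tossed —
  otherwise she takes a RANDOM step.  Keying on past matings rather
  than currently present females is a design choice; the copy-decision
  draw is consumed by RANDOM too, making `p_copy = 0` identical to
  RANDOM under the same seed.

## Statistics

- **Departure synchrony**: the fraction of neighbour departure pairs
  (either departer was in the other's `R_social` neighbourhood at its
  departure) whose departure ticks differ by at most `w`.  A
  within-window pair fraction is used rather than a Pearson
  correlation because each agent contributes a single scalar
  timestamp, not a series.  With no neighbour pairs the statistic
  falls back to all pairs and says so; with fewer than two departures
  it is undefined (raised, never 0).
- **Departure steepness**: max over `t` of the fraction of the lek
  departing in `[t, t+w]` — the height of the steepest rise of the
  forager count curve.
- **Chase onset gap**: mean pairwise difference of first chase-onset
  ticks among residents that chased.
- **Chase direction correlation** (pair level): mean cosine between
  the two agents' per-tick displacement vectors over ticks where both
  are chasing; undefined with fewer than two overlapping ticks.  The
  displacement into tick *t* is attributed to the state held at *t*,
  matching the simulator's update order.
- **Run-level chase synchrony** (used to compare chase modes): per
  chaser pair, the summed cosine over simultaneous chase ticks divided
  by the size of the union of the two chase windows, averaged over
  pairs.  Pure overlap-conditioned cosines reward any two pursuers of
  a common target — even ones chasing at different times — so they
  barely separate the modes; normalising by the union makes staggered
  chases score near zero and simultaneous aligned chases near one.
- **Revisit count, mating skew**: revisits are entries to an
  already-visited territory; skew is the Gini coefficient
  Σ<sub>ij</sub>|m<sub>i</sub> − m<sub>j</sub>| / (2 n Σ m), zeros
  included, 0 (flagged by a warning) when no matings occurred.
- **Heatmaps**: occupancy accumulates agent-ticks of one role into
  grid cells; aggression counts events with ethogram codes C/F.
  Out-of-grid points go to an overflow bucket, so grid total +
  overflow always equals the filtered input size.  Association is a
  Spearman rank correlation over informative cells (a + b > 0);
  Spearman because event counts are heavy-tailed, and the mask because
  jointly empty cells carry no information and would dilute the
  statistic.  The default grid is 20×20 cells over the territory
  bounding box padded by one radius.

## Parameter defaults

The repulsion radius is the model's natural length unit
(`R_r` = 1).  Defaults, chosen once as a plausible operating point:

| parameter | default | note |
|---|---|---|
| `speed` | 0.2 | 0.2 R_r per step; a box of half-width 50 R_r is crossable well within 2000 formation steps |
| `noise_sd` | 0.2 rad | mild directional error; lek still condenses |
| `arena_half_width` | 50 | initial spread ≫ final lek size |
| `R_social` | 5 | a few territory spacings: a local neighbourhood |
| `arrival_tol` | 0.2 | one step length |
| `p_f` | 0.01 | mean independent waiting time 100 steps |
| `p_spont`, `k_copy` | 0.002, 0.05 | rare seeding; cascades once a few neighbours forage |
| `foraging_site` | (30, 0) | off-lek but reachable within an episode |
| `latency_max` | 20 | independent reaction latencies U[0, 20] ticks |
| `k_chase` | 1.0 | a single chasing neighbour suffices to recruit |
| `flee_speed_factor` | 1.2 | intruders escape, chases end |
| `stop_radius_factor` | 2.0 | chases stay local to the territory |
| `p_mate` | 0.2 | ~5 visits before a random-strategy mating |
| `best_of_n`, `threshold`, `p_copy` | 5, 0.7, 0.8 | moderate sampling effort; selective threshold; strong copying |

## Reference experiments

The canned experiments in `leksim.scenarios` fix the study conditions;
`scripts/acceptance.py` and the end-to-end tests run them unchanged.

- **Formation** (n = 20, box half-width 50, 2000 steps, 100 seeds):
  final RMS distance to the centre below the initial RMS, and final
  nearest-neighbour spacing (median ≥ 0.5 R_r) showing repulsion
  prevents collapse.
- **Independent analytics** (n = 100, p_f = 0.01, 500 ticks, 200
  seeds): mean cumulative departures at ticks 10/50/100 against the
  geometric closed form n(1 − (1 − p_f)^t), in standard-error units.
- **Social contrast** (n = 50, k_copy = 0.05, 100 paired runs on a
  fixed hexagonal lek): the independent arm's rate is calibrated to
  the social arm's mean total departures by inverting the geometric
  form; the measured departure fraction uses a Jeffreys-style
  correction (k + ½)/(N + 1) so a fully saturated social arm does not
  degenerate to p_f = 1.  Reported: AUROC of synchrony between arms
  and the fraction of pairs where the social run is steeper.
- **Chase contrast** (10-territory ring, 100 paired seeds): the
  intruder travels the chord through the centres of adjacent
  territories 0 and 1 — exactly those two residents are triggered
  directly, a neighbourhood around them is recruitable, and the
  scenario mirrors the canonical two-male sketch.  Reported: mean
  onset gaps, run-level chase synchrony, and paired sign tests.
- **Strategy battery** (12-territory ring, 500 females/strategy):
  threshold revisits (identically zero), best-of-N revisits and argmax
  choice, a chi-square goodness-of-fit of random-strategy
  visits-to-mating against geometric(p_mate) (tail lumped so every
  expected bin ≥ 5), and paired copying-vs-random mating skew.
- **Harassment avoidance** (12 territories, 100 seeds/arm):
  per-territory aggression rates ~ U(0, 1); C/F events fall
  Poisson(rate × 120) per territory, uniform in its disc.  In the
  avoidance arm female positions fall in territory discs with weights
  exp(−4 × rate); in the null arm females wander with no spatial
  feature — positions uniform over the whole analysis region.  A
  disc-kernel null would inherit a structural positive rank
  correlation (disc-rim cells are low in both maps) of about +0.36
  and misrepresent "no discernible feature".

## What the simulator does and does not emulate

Synthetic trajectories exercise every statistic end to end, but they
idealise real leks: space is featureless and unbounded; males are
identical point particles with constant speed and no energetics,
courtship display, or day/night forcing; females teleport between
territory visits of fixed one-tick duration; at most one intruder is
present and chases have a hard stop rule; male quality is a scalar
drawn independently of position.  Passing tests therefore demonstrate
that the statistics discriminate the implemented rule sets under these
conditions — not that real blackbuck (or other lekking species)
follow any of the rules, which is exactly the question the statistics
are meant to take to field data.

## Known limitations

- The departure CSV stores only the neighbour *count* at departure,
  so synchrony computed from re-loaded files uses the all-pairs
  fallback (and flags it); the in-memory records keep full neighbour
  sets.
- Chase-direction correlation requires trajectories recorded at every
  tick; events alone are not sufficient.
- The formation dynamics never strictly equilibrate (agents jitter at
  the noise scale), so territory centres depend mildly on the
  averaging window.
- Goodness-of-fit and sign tests in the reference experiments are
  frequentist checks at fixed scales; they are not calibrated for
  very small leks (n < 5).
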