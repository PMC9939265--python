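# leksim

Agent-based simulation of lek mating systems, with the trajectory
statistics needed to tell competing behavioural rules apart from
movement data.

Leks — aggregations of small, resource-free territories that males
defend and females visit solely to mate — pose a classic puzzle in
behavioural ecology: which local interaction rules produce the
collective patterns seen on a lek (tight territory clustering,
synchronised foraging departures, joint chasing of intruders, strongly
skewed male mating success)?  With fine-scale trajectory data now
obtainable from aerial video, competing rules can in principle be
discriminated by their movement signatures.  `leksim` provides both
halves of that programme for modellers and field ecologists:

1. a minimal spatially explicit agent-based model that generates
   trajectories under alternative rule sets, and
2. statistics that quantify the predicted signatures, applicable
   identically to simulated output or to external trajectory/event
   tables in the documented CSV schemas.

## The model

Males move on an unbounded plane in discrete time with constant
per-step speed *s*.  A lekking male with no neighbour within the
repulsion radius *R*<sub>r</sub> steps towards the breeding centre
with a wrapped-normal heading error (sd σ); if any neighbour is within
*R*<sub>r</sub>, it instead steps directly away from those neighbours
— repulsion has strict priority.  Iterating these two rules from a
random start contracts the population into a stable, evenly spaced
cluster of territories: a lek.

On the settled lek, three behavioural contrasts are implemented:

- **Foraging departures.**  Independent rule: each lekking male
  switches to a foraging state with probability *p*<sub>f</sub> per
  step (departure times geometric).  Social rule: the switch
  probability is *p*<sub>spont</sub> + *k*<sub>copy</sub>·*n*, where
  *n* counts foraging neighbours within *R*<sub>social</sub> — copying
  produces departure cascades.  Travellers go to a foraging site and
  return, one episode per male per activity window.
- **Intruder chasing.**  An intruder male crosses the lek.
  Independent rule: a resident chases only after the intruder enters
  its own territory, with a personal reaction latency ~ U[0, 20]
  ticks.  Coordinated rule: residents additionally join chases started
  by neighbours within *R*<sub>social</sub>.
- **Female mate sampling.**  Four strategies: random (mate with
  probability *p*<sub>mate</sub> per visit), best-of-*N* (sample *N*
  males, return to the best), threshold (mate at the first male with
  quality ≥ θ), and copying (with probability *p*<sub>copy</sub>, go
  mate where the last female mated).

The metrics module computes the discriminating statistics: departure
synchrony (fraction of neighbour departure pairs within a window) and
steepness (peak departing fraction per window), chase onset gaps and
chase-direction correlations, territory revisit counts, the Gini
coefficient of per-male mating counts, a central-preference index, and
female-occupancy / male-aggression heatmaps with a Spearman
association (negative association = harassment avoidance).

## Worked example

```sh
$ leksim --config example.yaml --seed 42 --out-dir demo simulate formation
formation: 20 males, 2000 ticks -> demo/formation_trajectories.csv

$ leksim --config example.yaml --seed 42 --out-dir demo simulate foraging --model social
foraging (social): 20 departures -> demo/departures.csv

$ leksim analyze departures --departures demo/departures.csv --n-males 20 --window 5
departures: 20
synchrony (w=5): 0.9947 [all-pairs fallback: no neighbour pairs]
steepness (w=5): 0.9500

$ leksim --config example.yaml --seed 42 --out-dir demo simulate females --strategy copying --n-females 200
females (copying): 200/200 mated -> demo/matings.csv

$ leksim analyze skew --matings demo/matings.csv --n-males 20
mating skew (Gini over 20 males): 0.8105
```

Under the copying departure rule, 99% of departure pairs fall within
5 ticks of each other and 95% of the lek departs inside one 5-tick
window — the cascade signature (an independent-rule run with the same
total departures gives synchrony ≈ 0.08).  The note on the synchrony
line records that neighbour identities are not stored in the departure
CSV, so all pairs were compared.  Mate-choice copying concentrates 200
matings on a few males: a Gini of 0.81 against ≈ 0.07 for random
sampling.

The same `analyze` commands accept externally produced tables in the
CSV schemas documented in `leksim/io.py`.

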