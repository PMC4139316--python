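# Methods

## Model structure

The simulator is an individual-based model of central-place nectar foraging
with social recruitment. Three kinds of state evolve: a grid world of forage
patches, a colony of scout and recruit agents, and a daily energy ledger.

**World.** A 201×201 grid of 100 m cells centred on the nest (which never
holds forage). At initialisation each non-nest cell is forage with
probability `d_patch`; patch ages start uniform on {1..`a_max`} and patch
quality is drawn from Normal(`q_mean`, `q_sd`), redrawn while ≤ 0.05 mol/l so
concentrations stay physical. Each morning patches age by a day and die past
`a_max`; empty cells give birth to new patches. Two birth modes are
implemented because the turnover rule admits two readings: the default
`stationary` mode uses the per-day birth probability
`b = d_patch / (a_max (1 − d_patch))` that balances the death flow and keeps
expected occupancy at `d_patch` (the parameter is labelled a *density*); the
`literal` mode uses `b = d_patch` per empty cell per day, which equilibrates
occupancy at `d·a/(1 + d·a)` (≈ 0.41 at defaults) and is retained only for
comparison.

**Agents.** Scouts (six states) search by Lévy flight: a uniform random
heading, a leg length `d = (1 − a)^{1/(1−µ)}` cell widths (`a ~ U[0,1)`,
minimum step one cell), straight flight at `v` until the leg is exhausted,
repeat; landing on a forage cell starts feeding for Normal(180, 60) steps
(truncated ≥ 1). Recruits (eight states) additionally wait for dances and fly
straight to a known site. Motivated foragers leave the nest with `p_exit` per
step inside the foraging window; idle waiting recruits independently start
scouting with `p_rs` per step. All in-nest steps cost `c_rest`, all airborne
or on-patch steps `9·c_rest`. Every agent dies with probability `m` per step
and is replaced in place by a naive nestmate, keeping colony size constant.
Agents are updated in a freshly shuffled order each step; deaths, state
transitions and recruitment all happen within the step an agent is visited.

**Dance decision.** During each of the `t_nest = 6` unloading steps after a
successful trip (while flying is still allowed) the forager dances with
probability `p_d × influx_factor`. `p_d` is a logistic in the net trip value
`q_t = 282.25·q − (2d/70 m) · 9c_rest − (180·9c_rest + 6·c_rest)` (load
energy minus round-trip flight at 70 m/step minus handling), so it rises with
quality and falls with distance — the curves at 0/2.5/5/10 km are ordered
sigmoids. The influx factor declines linearly from 1 to `influx_floor` as the
count of foragers returning within the trailing `influx_window` steps reaches
20, and is constant beyond: a crowded dance floor suppresses further
recruitment. Under SI a dance recruits one waiting forager with probability
`p_dance = 0.25`; the recruit learns the site vector and owes a one-off
`c_recruit = 325 J` search penalty on first arrival. Under NI a dance sends
exactly one waiting forager out to scout for itself, with no penalty —
disoriented dances act as pure activation, carrying no usable vector.

**Site fidelity.** Each morning a recruit with a known site keeps it with
probability `min(1, p_d + 0.3)` (so a site danced for 50% of the time is
revisited on 80% of mornings) and otherwise forgets it; a kept-but-vanished
site is discovered in flight and abandoned on return. Scouts never carry
sites across days. A *tenure spell* is the number of distinct consecutive
days a recruit delivered from one site; spells end by abandonment, patch
death, agent death or the end of the run, and are summarised by the Poisson
maximum-likelihood mean (the sample mean, SE = √(mean/n)). Spells are
collected for recruits only, since scout site-holding is within-day by
construction.

## Calibration constants

The profitability-to-dance relation is not pinned down by machine-readable
field data, so its two constants are free parameters, fixed once
against the medium-density baseline behaviour and then frozen:

| constant | default | meaning |
|---|---|---|
| `dance_anchor_q` | 1.4 mol/l | quality danced for 50% of the time at 1 km |
| `dance_anchor_d_m` | 1000 m | distance of that anchor |
| `dance_slope_frac` | 0.40 | logistic scale as a fraction of the midpoint |
| `influx_window` | 20 steps | span of the returning-forager count |
| `influx_floor` | 0.0 | dance multiplier at ≥ 20 recent returns |

The anchor places the dance midpoint two quality SDs above the mean, which
makes dancing genuinely selective: ordinary sites (q ≈ 1) are advertised on
roughly a fifth of unloading steps and revisited on 50–70% of mornings, while
top-tail sites are advertised often and retained for several days. That
selectivity is what gives spatial information its value in the model — SI
recruits inherit above-average sites, NI-activated scouting recruits adopt
average ones — and it reproduces the observed site persistency (≈ 1.0 days
when patches last one day, ≈ 2.8 when they last four weeks). The influx
suppression with a zero floor acts as a colony-level activity thermostat: a
busy colony stops recruiting, which caps both conditions at a similar
mobilisation and keeps the SI−NI contrast driven by *where* recruits are
sent rather than how many.

Explicit `dance_midpoint` / `dance_slope` values (joules) override the
anchor, for recalibration against other assumed dance data.

## Scheduling and replication

A run is a pure function of (parameters, schedule, seed): one numpy
generator drives world and morning randomness and a separately seeded
compiled stream drives the step loop, so identical seeds reproduce records
bitwise. Schedules start with `t_init = 3` SI acclimatization days (always
excluded from summaries) followed by 48 experimental days: constant SI or NI
(no-switch), or alternating blocks of 2, 3 or 12 days. Replicate sets run 12
runs with seeds `base_seed + i`; switching designs alternate the starting
condition so six runs begin with SI and six with NI. Within a day the order
is: patch turnover, morning keep-or-abandon decisions, then the step loop;
the stretches before the foraging window opens and after every agent has
returned are advanced in closed form (resting costs plus binomial mortality),
which is exact because only death can change state outside the window.

## Outputs

Each day yields one record: condition, net energy gain (deliveries − flight
and resting costs − recruitment penalties; the ledger identity is asserted in
tests), deliveries/costs/trips split by role, median trip distance (over that
day's completed deliveries, NaN when there were none), deaths, dances,
recruitments, first/last nest departure step, and the tenure spells that
ended. The relative SI benefit is `100 × (mean SI − mean NI)/mean NI` over
per-run mean daily gains, acclimatization excluded; switching designs use the
same contrast between SI-condition and NI-condition days of the same runs.
Per-capita efficiency divides a role's net (or optionally gross) energy by
its agent-days. `carryover_profile` averages gain by position within a
treatment block, where first-day excess relative to the block's end is the
carry-over signature; the profile flattens when `persistent_recruits=False`.

## What the generator does and does not emulate

The world reproduces the experimental conditions being modelled: stochastic
patch turnover with
bounded longevity, normal quality variation, a fixed daily foraging window,
and distances on a 20×20 km plane. It deliberately omits within-day nectar
depletion, diurnal quality cycles, competition between foragers on one patch,
weather, dance-floor spatial structure, and local search around an advertised
site. Passing tests therefore show that the *recruitment-and-persistence
dynamics* behave as described, not that absolute energy figures transfer to
real colonies; absolute gains here (hundreds of kJ per colony-day) follow
directly from the parameter table's trip energetics with all foragers making
~15 trips per day.

## Numerical choices and degenerate inputs

Quality and feeding-time normals are truncated by redraw (> 0.05 mol/l) and
rounding (≥ 1 step). Flight reflects at the world boundary (inert at default
ranges). Arrival is declared when the remaining distance is below one step's
travel. The logistic is clamped at |z| > 40. `mu_levy = 1` is rejected (the
inverse-CDF exponent diverges), so the search-exponent sensitivity preset
sweeps µ ∈ {2, 3, 4}. Empty tenure or gain vectors raise instead of
returning NaNs; a non-positive NI mean makes the relative benefit undefined
and raises. Replicate medians with zero trips propagate as NaN and are
excluded by the pandas aggregations.

## Problem sizes

Full-scale experiments (51 days × 8640 steps × 300 agents, 12 replicates per
condition) are used everywhere results are reported: the acceptance script
(~180 runs) and the comparative acceptance tests (~200 runs, shared through a
session cache). Unit and mechanics tests use a miniature configuration
(720-step days, 50 agents, 61×61 world) that exercises identical code paths.

## Known limitations

- The dance curve is a calibrated stand-in for unpublished figure data; only
  its anchors (50% dance → 80% return; monotonicity; distance ordering) are
  empirically grounded.
- Per-capita efficiencies follow directly from the per-step exit
  probability: motivated foragers re-exit almost immediately, so active
  individuals net a few kJ per day. Published per-forager field estimates
  are an order of magnitude smaller; colony-level *relative* quantities are
  the robust outputs here.
- With one-day patches the SI deficit is deep (≈ −30%): when nothing
  persists overnight, the one-recruit-per-dance NI mobilisation advantage
  dominates recruitment quality for most of each day, and no calibration of
  the dance curve moves this above roughly −25% without breaking the
  density and longevity orderings.
- Scheduling details that the model description leaves open (agent update
  order, day-end handling of airborne agents, the influx window) are fixed
  by the explicit choices documented above; behavioural equivalence, not
  code identity, is the goal.
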