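# waggle

Agent-based simulation of honeybee colony foraging with and without the
spatial information carried by waggle dances, built to study a methodological
problem in bee research: experiments that repeatedly switch a colony between
oriented dances (**SI**, spatial information) and disoriented dances (**NI**,
no vector information) can *hide* the benefit of dance communication, because
recruited foragers keep visiting a food source for several days after the
treatment changes (site fidelity / persistency), so energy collected during
NI days is partly a delayed product of SI-day recruitment.

The package is for behavioural ecologists and modellers who want to
regenerate those carry-over effects, quantify how much of the dance benefit a
given experimental design can detect, and explore how the benefit depends on
the environment (food density, patch longevity, colony size, search
behaviour).

## The model

A colony of `N = 300` agents (30 scouts, 270 recruits) forages on a 201×201
grid of 100 m cells around a central nest for 51 simulated days of 8640
ten-second steps (3 acclimatization days, always SI, then 48 experimental
days). Cells hold forage patches with quality `q ~ N(1, 0.2) mol/l` that die
after `a_max` days; empty cells are reborn so the expected patch density
stays at `d_patch`. Agents move at `v = 0.7` cell widths per step; scouts
search with a Lévy flight (`P(ℓ > d) = d^(1−µ)`, `µ = 2.4`), forage within a
daily window (06:23–17:37), pay `c_rest = 0.04861 J` per resting step and
`9·c_rest` when flying or on a patch, die with probability `m = 7·10⁻⁶` per
step (replaced by a naive nestmate), and deliver
`50 µl × q × 5 645 000 J/mol ≈ 282·q J` per trip.

A returning forager dances with probability

    p_d(q, d) = logistic((q_t − midpoint) / slope) × influx_factor,

where `q_t` is the net energetic trip value (load minus round-trip flight and
handling costs) and the influx factor falls linearly to 0 as returns in the
last 20 steps reach 20. Under SI each dance recruits one waiting forager to
the advertised site with probability `p_dance = 0.25` (paying a one-off
`c_recruit = 325 J` search penalty); under NI each dance instead sends one
waiting forager out to scout for itself. Each morning an experienced recruit
revisits its site with probability `min(1, p_d + 0.3)` — a source danced for
half the time is revisited on 80% of mornings — otherwise it abandons it.

The colony-level quantity of interest is the mean daily net energy gain, and
the *relative benefit of SI*, `100 × (mean SI gain − mean NI gain) / mean NI
gain`, measured either between constant-condition colonies or within SI/NI
switching designs (2-, 3- or 12-day cycles, half the replicates starting with
each condition).

## Worked example

```python
from waggle import Params, make_plan, replicate
from waggle.analysis import benefit_summary

params = Params(d_patch=0.01, n_runs=4, base_seed=900)   # sparse food
si = replicate(params, make_plan(None, "SI", params))
ni = replicate(params, make_plan(None, "NI", params))
print(benefit_summary(si, ni))
```

prints (seeds as above):

```
{'si_mean': 905047.58, 'si_se': 42912.61, 'ni_mean': 691144.57,
 'ni_se': 26857.61, 'relative_benefit_pct': 30.95, 'n_runs': 4}
```

i.e. colonies with oriented dances netted ~905 kJ of nectar energy per day
against ~691 kJ without vector information: a +31% benefit of spatial
information at this low food density (4 replicates; the full designs use 12,
and benefit estimates at this replication carry standard errors of several
percentage points).
The same tables feed `carryover_profile` (gain by day-within-block, exposing
first-day contamination after a switch), `per_capita_efficiency` (J per
forager-day by role) and `persistency_poisson` (mean days a recruit stays
with one site).

A CLI wraps the same machinery:

```bash
waggle run --out out/ --cycle 3 --set d_patch=0.01      # one replicate set
waggle experiment experiment2 --out out/exp2/           # preset suite
waggle summarize out/days.csv
```

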