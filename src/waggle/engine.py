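"""Simulation clock: day loop, SI/NI scheduling, replication and records.

A run covers ``t_init`` acclimatization days (always SI) followed by
``n_exp_days`` experimental days whose SI/NI condition comes from an
:class:`ExperimentPlan`.  Each day: patch turnover, the recruits' morning
keep-or-abandon decisions, then the step loop (compiled kernel) over the
foraging window; the nest-bound night portion is settled in closed form.
One day yields one record; a run yields a ``pandas.DataFrame``.

Reproducibility: a run is a pure function of (params, schedule, seed).  The
seed feeds both the numpy generator used for world/morning randomness and
the kernel's internal stream.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import _kernel as K
from .behavior import (Colony, ROLE_RECRUIT, ROLE_SCOUT, new_colony,
                       apply_mortality_batch, morning_reset)
from .communication import DanceModel
from .config import Params, validate
from .environment import daily_turnover, init_world

__all__ = ["ExperimentPlan", "condition_schedule", "make_plan",
           "run_simulation", "replicate", "SI", "NI"]

SI = "SI"
NI = "NI"

_TRIP_CAP = 200_000   # per-day delivery-distance buffer
_SPELL_CAP = 8_192    # per-day ended-tenure buffer


@dataclasses.dataclass(frozen=True)
class ExperimentPlan:
    """A condition schedule plus replication instructions."""

    schedule: tuple[str, ...]      # per-day SI/NI, length t_init + n_exp_days
    label: str = ""
    n_runs: int = 12
    base_seed: int = 0
    start_condition: str = SI      # condition of the first experimental cycle
    cycle: int | None = None       # days per cycle; None = no switching


def condition_schedule(cycle: int | None, start: str,
                       params: Params) -> tuple[str, ...]:
    """Per-day conditions: ``t_init`` SI days, then either a constant
    condition (no switching) or alternating blocks of ``cycle`` days
    beginning with ``start``."""
    if start not in (SI, NI):
        raise ValueError(f"start must be {SI!r} or {NI!r}, got {start!r}")
    days = [SI] * params.t_init
    other = NI if start == SI else SI
    for d in range(params.n_exp_days):
        if cycle is None:
            days.append(start)
        else:
            days.append(start if (d // cycle) % 2 == 0 else other)
    return tuple(days)


def make_plan(cycle: int | None, start: str, params: Params,
              label: str = "", n_runs: int | None = None,
              base_seed: int | None = None) -> ExperimentPlan:
    return ExperimentPlan(
        schedule=condition_schedule(cycle, start, params),
        label=label or (f"cycle={cycle or 'none'},start={start}"),
        n_runs=params.n_runs if n_runs is None else n_runs,
        base_seed=params.base_seed if base_seed is None else base_seed,
        start_condition=start, cycle=cycle)


def _night_batch(colony: Colony, params: Params, rng: np.random.Generator,
                 n_steps: int) -> tuple[float, float, int, list[int]]:
    """Rest costs and mortality for nest-bound steps, per role."""
    cost_s = params.n_scouts * n_steps * params.c_rest
    cost_r = params.n_recruits * n_steps * params.c_rest
    deaths, spells = apply_mortality_batch(colony, params, rng, n_steps)
    return cost_s, cost_r, deaths, spells


def run_simulation(params: Params, plan: ExperimentPlan,
                   seed: int) -> pd.DataFrame:
    """One replicate: returns a day-level table with the energy ledger,
    trip statistics and ended site tenures for each simulated day."""
    p = validate(params)
    if len(plan.schedule) != p.n_days:
        raise ValueError(
            f"schedule length {len(plan.schedule)} != t_init + n_exp_days "
            f"= {p.n_days}")
    dm = DanceModel.from_params(p)
    rng = np.random.default_rng(seed)
    K.seed_kernel(int(seed) % 2_147_483_647 + 1)

    world = init_world(p, rng)
    colony = new_colony(p)
    trip_dists = np.zeros(_TRIP_CAP)
    spells_buf = np.zeros(_SPELL_CAP, dtype=np.int64)
    acc = np.zeros(K.A_SIZE)

    records = []
    for day in range(1, p.n_days + 1):
        if day > 1:
            daily_turnover(world, p, rng)
        assert not world.is_forage[world.half_extent, world.half_extent]
        spells_today = morning_reset(colony, p, rng)
        condition = plan.schedule[day - 1]

        # pre-dawn: everyone rests in the nest
        cost_s, cost_r, deaths, sp = _night_batch(
            colony, p, rng, p.forage_open)
        spells_today.extend(sp)

        acc[:] = 0.0
        K.simulate_day(
            *colony.arrays(),
            world.is_forage, world.quality, world.half_extent,
            condition == SI,
            p.p_exit, p.p_rs, p.v, p.mu_levy,
            p.t_patch_mean, p.t_patch_sd, p.t_nest,
            p.c_rest, p.c_move, p.m,
            dm.trip_j_per_q, dm.flight_cost_per_m, dm.handling_j,
            p.c_recruit, p.n_dance, p.p_dance, dm.midpoint, dm.slope,
            p.influx_window, p.influx_floor,
            p.forage_open, p.forage_close, p.t_day, p.cell_width_m,
            acc, trip_dists, spells_buf, colony.returns_by_step,
        )
        stop = int(acc[K.A_STOP])
        cost_s += acc[K.A_COST_S]
        cost_r += acc[K.A_COST_R]
        deaths += int(acc[K.A_DEATHS])
        spells_today.extend(int(t) for t in spells_buf[:int(acc[K.A_NSPELL])])

        # night: all agents are home again
        ns, nr, d2, sp2 = _night_batch(colony, p, rng, p.t_day - stop)
        cost_s += ns
        cost_r += nr
        deaths += d2
        spells_today.extend(sp2)

        if day == p.n_days:  # run end terminates open spells
            open_spells = colony.tenure[(colony.role == ROLE_RECRUIT)
                                        & colony.has_site
                                        & (colony.tenure > 0)]
            spells_today.extend(int(t) for t in open_spells)

        deliv_s = float(acc[K.A_DELIV_S])
        deliv_r = float(acc[K.A_DELIV_R])
        penalties = float(acc[K.A_PENALTY])
        net = deliv_s + deliv_r - cost_s - cost_r - penalties
        colony.energy_store += net
        n_trips = int(acc[K.A_NDIST])
        records.append({
            "day": day,
            "condition": condition,
            "acclimatization": day <= p.t_init,
            "net_gain": net,
            "energy_store": colony.energy_store,
            "deliveries_scout": deliv_s,
            "deliveries_recruit": deliv_r,
            "costs_scout": float(cost_s),
            "costs_recruit": float(cost_r),
            "penalties": penalties,
            "trips_scout": int(acc[K.A_TRIPS_S]),
            "trips_recruit": int(acc[K.A_TRIPS_R]),
            "median_trip_distance_m": (
                float(np.median(trip_dists[:n_trips])) if n_trips else np.nan),
            "deaths": deaths,
            "dances": int(acc[K.A_DANCES]),
            "recruitments": int(acc[K.A_RECRUITED]),
            "first_exit_step": (int(acc[K.A_EXIT_MIN])
                                if np.isfinite(acc[K.A_EXIT_MIN]) else -1),
            "last_exit_step": (int(acc[K.A_EXIT_MAX])
                               if np.isfinite(acc[K.A_EXIT_MAX]) else -1),
            "tenures_ended": spells_today,
        })

    df = pd.DataFrame.from_records(records)
    df["seed"] = seed
    return df


def replicate(params: Params, plan: ExperimentPlan) -> pd.DataFrame:
    """Run ``plan.n_runs`` replicates with seeds ``base_seed + i``.

    For switching designs half the runs start with SI in the first cycle and
    half with NI (alternating by run index; with an odd run count the split
    is floored for the second start)."""
    p = validate(params)
    if plan.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    tables = []
    for r in range(plan.n_runs):
        if plan.cycle is None:
            sched_plan = plan
            start = plan.start_condition
        else:
            start = plan.start_condition if r % 2 == 0 else (
                NI if plan.start_condition == SI else SI)
            sched_plan = dataclasses.replace(
                plan, schedule=condition_schedule(plan.cycle, start, p),
                start_condition=start)
        df = run_simulation(p, sched_plan, seed=plan.base_seed + r)
        df["run_id"] = r
        df["start_condition"] = start
        tables.append(df)
    out = pd.concat(tables, ignore_index=True)
    out["label"] = plan.label
    return out
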