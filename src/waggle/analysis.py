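"""Replicate statistics and derived quantities.

All summaries exclude the acclimatization days.  The central quantity is the
relative benefit of spatial information, 100 * (mean SI gain - mean NI gain)
/ mean NI gain, computed either between no-switch SI and NI replicate sets
or, for switching designs, between the SI-condition and NI-condition days of
the same runs (the "apparent" benefit an experimenter would measure).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import ROLE_RECRUIT
from .config import Params
from .engine import ExperimentPlan, NI, SI, make_plan

__all__ = [
    "per_run_mean_gain", "relative_benefit", "apparent_benefit",
    "per_capita_efficiency", "collect_tenures", "persistency_poisson",
    "carryover_profile", "preset_experiments", "benefit_summary",
]


def _experimental(day_table: pd.DataFrame) -> pd.DataFrame:
    return day_table[~day_table["acclimatization"]]


def per_run_mean_gain(day_table: pd.DataFrame,
                      condition: str | None = None) -> np.ndarray:
    """Mean daily net energy gain per run (J/day), acclimatization excluded;
    optionally restricted to days in one condition."""
    df = _experimental(day_table)
    if condition is not None:
        df = df[df["condition"] == condition]
    if df.empty:
        raise ValueError("no experimental days selected")
    return df.groupby("run_id")["net_gain"].mean().to_numpy()


def relative_benefit(si_gains: np.ndarray, ni_gains: np.ndarray) -> float:
    """Relative SI benefit in percent: 100 * (mean(si) - mean(ni)) / mean(ni).

    Undefined (raises) when the NI mean is not positive."""
    si_gains = np.asarray(si_gains, dtype=float)
    ni_gains = np.asarray(ni_gains, dtype=float)
    if si_gains.size == 0 or ni_gains.size == 0:
        raise ValueError("empty gain vector")
    ni_mean = ni_gains.mean()
    if ni_mean <= 0:
        raise ValueError(
            f"relative benefit undefined: NI mean gain {ni_mean:.3g} <= 0")
    return float(100.0 * (si_gains.mean() - ni_mean) / ni_mean)


def apparent_benefit(switch_table: pd.DataFrame) -> float:
    """Benefit an SI/NI switch experiment would report: per-run mean gains on
    SI-condition days versus NI-condition days of the same runs."""
    return relative_benefit(per_run_mean_gain(switch_table, SI),
                            per_run_mean_gain(switch_table, NI))


def per_capita_efficiency(day_table: pd.DataFrame, role: str,
                          params: Params, gross: bool = False) -> float:
    """Net (default) or gross energy collected per forager of a role per
    day, J/day, acclimatization excluded.

    Net = (deliveries - flight/rest costs - recruitment penalties) summed
    over the role, divided by role-agent-days."""
    if role not in ("scout", "recruit"):
        raise ValueError(f"role must be 'scout' or 'recruit', got {role!r}")
    df = _experimental(day_table)
    n_role = params.n_scouts if role == "scout" else params.n_recruits
    agent_days = n_role * len(df)
    if agent_days == 0:
        raise ValueError("zero agent-days for role " + role)
    deliveries = df[f"deliveries_{role}"].sum()
    if gross:
        return float(deliveries / agent_days)
    costs = df[f"costs_{role}"].sum()
    if role == "recruit":
        costs += df["penalties"].sum()
    return float((deliveries - costs) / agent_days)


def collect_tenures(day_table: pd.DataFrame,
                    include_acclimatization: bool = False) -> np.ndarray:
    """All ended site-tenure spells (days per agent-site), pooled."""
    df = day_table if include_acclimatization else _experimental(day_table)
    out: list[int] = []
    for spells in df["tenures_ended"]:
        out.extend(spells)
    return np.asarray(out, dtype=np.int64)


def persistency_poisson(tenure_counts: np.ndarray) -> tuple[float, float]:
    """Poisson maximum-likelihood mean and its standard error for site
    persistency spells: mean = sample mean, SE = sqrt(mean / n)."""
    counts = np.asarray(tenure_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("no tenure spells supplied")
    if (counts < 1).any():
        raise ValueError("tenure spells must be >= 1 day")
    mean = float(counts.mean())
    se = float(np.sqrt(mean / counts.size))
    return mean, se


def carryover_profile(switch_table: pd.DataFrame) -> pd.DataFrame:
    """Mean net gain by (condition, day position within its block).

    Within each run, experimental days are grouped into maximal runs of a
    constant condition; position 1 is the first day after a switch.  The
    first-day excess over later positions is the carry-over signature."""
    df = _experimental(switch_table).sort_values(["run_id", "day"])
    positions = []
    for _, sub in df.groupby("run_id", sort=True):
        conds = sub["condition"].to_numpy()
        pos = np.ones(len(conds), dtype=int)
        for i in range(1, len(conds)):
            pos[i] = pos[i - 1] + 1 if conds[i] == conds[i - 1] else 1
        positions.append(pd.Series(pos, index=sub.index))
    df = df.assign(block_position=pd.concat(positions))
    out = (df.groupby(["condition", "block_position"])["net_gain"]
           .agg(["mean", "sem", "count"]).reset_index())
    return out


def benefit_summary(si_table: pd.DataFrame,
                    ni_table: pd.DataFrame) -> dict[str, float]:
    """Condition means ± SE and the relative benefit for a no-switch pair."""
    si = per_run_mean_gain(si_table)
    ni = per_run_mean_gain(ni_table)
    return {
        "si_mean": float(si.mean()),
        "si_se": float(si.std(ddof=1) / np.sqrt(si.size)),
        "ni_mean": float(ni.mean()),
        "ni_se": float(ni.std(ddof=1) / np.sqrt(ni.size)),
        "relative_benefit_pct": relative_benefit(si, ni),
        "n_runs": int(si.size),
    }


# ---- preset experiment suites ----------------------------------------------

_CYCLES: tuple[int | None, ...] = (None, 2, 3, 12)


def preset_experiments(name: str,
                       params: Params | None = None
                       ) -> list[tuple[Params, ExperimentPlan]]:
    """Parameter/plan pairs for the canned experiment suites.

    ``experiment1``: food density {0.1, 0.05, 0.01} x cycle {none, 2, 3, 12}.
    ``experiment2``: patch longevity {1, 7, 14, 28} x the same cycles at
    medium density.  ``no_cost``: certain free recruitment (p_dance=1,
    c_recruit=0) at longevities {7, 21}, no-switch and 2-day cycles.
    ``sensitivity``: one-factor sweeps around the defaults (colony size,
    Lévy exponent, exit probability, recruitment cost, persistence).

    No-switch entries use the plan's ``start_condition`` as the constant
    condition; run the returned plan once as given (SI) and once with the
    NI counterpart to measure a benefit.
    """
    base = params if params is not None else Params()
    out: list[tuple[Params, ExperimentPlan]] = []

    def add(p: Params, cycle: int | None, label: str) -> None:
        if cycle is None:
            out.append((p, make_plan(None, SI, p, label=label + ",SI")))
        else:
            out.append((p, make_plan(cycle, SI, p, label=label)))

    if name == "experiment1":
        for d in (0.1, 0.05, 0.01):
            for cyc in _CYCLES:
                add(base.replace(d_patch=d), cyc,
                    f"d_patch={d},cycle={cyc or 'none'}")
    elif name == "experiment2":
        for a in (1, 7, 14, 28):
            for cyc in _CYCLES:
                add(base.replace(a_max=a), cyc,
                    f"a_max={a},cycle={cyc or 'none'}")
    elif name == "no_cost":
        for a in (7, 21):
            p = base.replace(a_max=a, p_dance=1.0, c_recruit=0.0)
            for cyc in (None, 2):
                add(p, cyc, f"no_cost,a_max={a},cycle={cyc or 'none'}")
    elif name == "sensitivity":
        for ns, nr in ((30, 270), (60, 540), (120, 1080)):
            add(base.replace(n_scouts=ns, n_recruits=nr), base.t_switch,
                f"colony={ns + nr}")
        for mu in (2.0, 3.0, 4.0):  # mu = 1 leaves the Levy CDF undefined
            add(base.replace(mu_levy=mu), base.t_switch, f"mu_levy={mu}")
        for pe in (0.01, 0.1, 0.5, 0.8):
            add(base.replace(p_exit=pe), base.t_switch, f"p_exit={pe}")
        for cr in (0.0, 325.0):
            add(base.replace(c_recruit=cr), base.t_switch, f"c_recruit={cr}")
        for pers in (True, False):
            add(base.replace(persistent_recruits=pers), base.t_switch,
                f"persistent={pers}")
    else:
        raise ValueError(f"unknown experiment preset: {name!r}")
    return out
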