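"""Agents: roles, finite-state machines, energetics, and daily decisions.

The colony is stored as a struct-of-arrays (:class:`Colony`) so that the
per-step state machines can run inside a compiled kernel (see ``_kernel``).
Scouts cycle through six states (idle, scouting, feeding, returning full,
unloading/dancing, returning empty); recruits add waiting-for-dance and
flying-to-a-known-site, for eight.  Pure per-decision functions (Lévy leg
lengths, step costs, trip value) live here and are shared with the kernel.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .communication import DanceModel
from .config import Params

__all__ = [
    "IDLE", "SCOUTING", "FLY_TO_SITE", "FEEDING", "RETURN_FULL",
    "RETURN_EMPTY", "UNLOADING", "WAITING", "ROLE_SCOUT", "ROLE_RECRUIT",
    "Colony", "new_colony", "draw_levy_length", "step_cost", "trip_value",
    "morning_reset", "apply_mortality_batch",
]

# agent states
IDLE = 0          # in nest, motivated (scout, or recruit holding a site)
SCOUTING = 1      # Levy-flight search
FLY_TO_SITE = 2   # recruit flying straight to its known site
FEEDING = 3       # on a forage patch
RETURN_FULL = 4   # homing with a full load
RETURN_EMPTY = 5  # homing empty-handed
UNLOADING = 6     # in nest, unloading and possibly dancing
WAITING = 7       # recruit with no site, waiting for a dance

IN_NEST_STATES = (IDLE, UNLOADING, WAITING)

ROLE_SCOUT = 0
ROLE_RECRUIT = 1


@dataclasses.dataclass
class Colony:
    """Struct-of-arrays population plus the colony energy ledger."""

    role: np.ndarray            # int64, ROLE_SCOUT | ROLE_RECRUIT
    state: np.ndarray           # int64
    x: np.ndarray               # float64, cell units, nest at origin
    y: np.ndarray
    heading: np.ndarray         # float64, radians
    leg: np.ndarray             # float64, remaining Levy leg, cell units
    site_ix: np.ndarray         # int64 cell index of the known/last site
    site_iy: np.ndarray
    site_q: np.ndarray          # float64, remembered quality, mol/l
    site_d: np.ndarray          # float64, nest-site distance, metres
    has_site: np.ndarray        # bool (recruit site fidelity)
    penalty_pending: np.ndarray  # bool, c_recruit owed on first arrival
    timer: np.ndarray           # int64, feeding/unloading steps remaining
    tenure: np.ndarray          # int64, days with deliveries in current spell
    visited_today: np.ndarray   # bool, delivered from the site today
    energy_store: float = 0.0
    returns_by_step: np.ndarray | None = None  # int64 (t_day,), influx buffer

    @property
    def n(self) -> int:
        return self.role.shape[0]

    def arrays(self) -> tuple[np.ndarray, ...]:
        """Array tuple in the order the day kernel expects."""
        return (self.role, self.state, self.x, self.y, self.heading,
                self.leg, self.site_ix, self.site_iy, self.site_q,
                self.site_d, self.has_site, self.penalty_pending,
                self.timer, self.tenure, self.visited_today)


def new_colony(params: Params) -> Colony:
    """All agents idle in the nest, without foraging experience."""
    n = params.n_agents
    role = np.zeros(n, dtype=np.int64)
    role[params.n_scouts:] = ROLE_RECRUIT
    state = np.where(role == ROLE_SCOUT, IDLE, WAITING).astype(np.int64)
    z = lambda dt: np.zeros(n, dtype=dt)  # noqa: E731
    return Colony(
        role=role, state=state,
        x=z(np.float64), y=z(np.float64), heading=z(np.float64),
        leg=z(np.float64),
        site_ix=z(np.int64), site_iy=z(np.int64),
        site_q=z(np.float64), site_d=z(np.float64),
        has_site=z(np.bool_), penalty_pending=z(np.bool_),
        timer=z(np.int64), tenure=z(np.int64), visited_today=z(np.bool_),
        returns_by_step=np.zeros(params.t_day, dtype=np.int64),
    )


# ---- pure per-decision functions -------------------------------------------

@njit(cache=True)
def _levy_length(a: float, mu: float) -> float:
    return (1.0 - a) ** (1.0 / (1.0 - mu))


def draw_levy_length(rng: np.random.Generator, mu_levy: float) -> float:
    """One Levy leg length in cell widths: d = (1-a)^(1/(1-mu)), a ~ U[0,1).

    Power law with tail exponent mu_levy and minimum step 1 cell."""
    if mu_levy <= 1.0:
        raise ValueError("mu_levy must be > 1")
    return float(_levy_length(float(rng.random()), mu_levy))


def step_cost(state: int, params: Params) -> float:
    """Energy cost of one time step, J: resting rate in the nest, the flight
    rate when airborne or on a patch."""
    if state in IN_NEST_STATES:
        return params.c_rest
    return params.c_move


def trip_value(quality: float, params: Params) -> float:
    """Energy delivered by one full load of nectar at the given quality."""
    if quality < 0:
        raise ValueError("quality must be >= 0")
    return quality * params.trip_j_per_q


# ---- daily decisions -------------------------------------------------------

def morning_reset(colony: Colony, params: Params,
                  rng: np.random.Generator) -> list[int]:
    """Dawn bookkeeping: experienced recruits decide whether to keep their
    site (probability = return curve) or abandon it; scouts start the day
    siteless.  Returns the lengths of the site tenures that just ended.

    With ``persistent_recruits=False`` every recruit abandons unconditionally,
    reproducing the no-site-fidelity control."""
    dm = DanceModel.from_params(params)
    spells: list[int] = []

    scouts = colony.role == ROLE_SCOUT
    recruits = ~scouts
    colony.has_site[scouts] = False
    colony.penalty_pending[scouts] = False

    held = recruits & colony.has_site
    idx = np.nonzero(held)[0]
    if idx.size:
        if not params.persistent_recruits:
            drop = idx
        else:
            q_t = (colony.site_q[idx] * dm.trip_j_per_q
                   - 2.0 * colony.site_d[idx] * dm.flight_cost_per_m
                   - dm.handling_j)
            p_d = 1.0 / (1.0 + np.exp(-np.clip(
                (q_t - dm.midpoint) / dm.slope, -40, 40)))
            p_keep = np.minimum(1.0, p_d + dm.return_shift)
            drop = idx[rng.random(idx.size) >= p_keep]
        spells.extend(int(t) for t in colony.tenure[drop] if t > 0)
        colony.has_site[drop] = False
        colony.penalty_pending[drop] = False
        colony.tenure[drop] = 0

    colony.state[scouts] = IDLE
    colony.state[recruits & colony.has_site] = IDLE
    colony.state[recruits & ~colony.has_site] = WAITING
    colony.x[:] = 0.0
    colony.y[:] = 0.0
    colony.leg[:] = 0.0
    colony.timer[:] = 0
    colony.visited_today[:] = False
    if colony.returns_by_step is not None:
        colony.returns_by_step[:] = 0
    return spells


def _reset_agent(colony: Colony, i: int) -> None:
    colony.state[i] = IDLE if colony.role[i] == ROLE_SCOUT else WAITING
    colony.x[i] = colony.y[i] = 0.0
    colony.leg[i] = 0.0
    colony.timer[i] = 0
    colony.has_site[i] = False
    colony.penalty_pending[i] = False
    colony.tenure[i] = 0
    colony.visited_today[i] = False


def apply_mortality_batch(colony: Colony, params: Params,
                          rng: np.random.Generator,
                          n_steps: int) -> tuple[int, list[int]]:
    """Apply per-step mortality over ``n_steps`` nest-bound steps at once.

    Each death replaces the agent in place with a naive idle agent of the
    same role, keeping the population size constant.  Returns the number of
    deaths and the site-tenure spells that ended with them.  Used for the
    parts of the day when every agent is in the nest; within the foraging
    window the kernel applies mortality step by step."""
    if n_steps <= 0 or params.m <= 0.0:
        return 0, []
    p_die = -np.expm1(n_steps * np.log1p(-params.m))  # 1-(1-m)^n
    deaths = int(rng.binomial(colony.n, p_die))
    spells: list[int] = []
    if deaths:
        victims = rng.choice(colony.n, size=deaths, replace=False)
        for i in victims:
            if (colony.role[i] == ROLE_RECRUIT and colony.has_site[i]
                    and colony.tenure[i] > 0):
                spells.append(int(colony.tenure[i]))
            _reset_agent(colony, int(i))
    return deaths, spells
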