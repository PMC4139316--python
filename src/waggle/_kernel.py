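"""Compiled inner loop: one foraging day of the colony.

``simulate_day`` advances every agent through the foraging window of a
single day.  Agents are visited in a freshly shuffled order each step;
mortality is applied per agent per step.  The kernel starts at
``forage_open`` (before dawn every agent is in the nest, so those steps are
settled in closed form by the engine) and stops early once the window has
closed and every agent is back in the nest.

All randomness uses numba's internal global RNG, seeded once per run via
:func:`seed_kernel`, which makes runs reproducible from a single integer.

Accumulator layout (``acc`` float64 array): see the ``A_*`` constants.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .behavior import (IDLE, SCOUTING, FLY_TO_SITE, FEEDING, RETURN_FULL,
                       RETURN_EMPTY, UNLOADING, WAITING, ROLE_SCOUT,
                       ROLE_RECRUIT)
from .communication import (_dance_probability, _effective_value,
                            _influx_factor)

# accumulator indices
A_DELIV_S = 0    # J delivered by scouts
A_DELIV_R = 1    # J delivered by recruits
A_COST_S = 2     # J spent by scouts (rest + flight)
A_COST_R = 3     # J spent by recruits (rest + flight, excl. penalties)
A_PENALTY = 4    # J of c_recruit penalties charged
A_TRIPS_S = 5    # completed deliveries by scouts
A_TRIPS_R = 6    # completed deliveries by recruits
A_DEATHS = 7
A_DANCES = 8
A_RECRUITED = 9  # successful SI recruitments (site learned)
A_NDIST = 10     # entries used in trip_dists
A_NSPELL = 11    # entries used in spells
A_EXIT_MIN = 12  # earliest nest departure step this day
A_EXIT_MAX = 13  # latest nest departure step this day
A_STOP = 14      # step at which the kernel stopped
A_SIZE = 16


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _levy(mu):
    return (1.0 - np.random.random()) ** (1.0 / (1.0 - mu))


@njit(cache=True)
def _feed_time(mean, sd):
    t = int(round(np.random.normal(mean, sd)))
    return t if t >= 1 else 1


@njit(cache=True)
def _pick_waiting(state):
    """Uniformly random agent in WAITING, or -1 (reservoir sample)."""
    count = 0
    pick = -1
    for j in range(state.shape[0]):
        if state[j] == WAITING:
            count += 1
            if np.random.random() * count < 1.0:
                pick = j
    return pick


@njit(cache=True)
def _note_exit(acc, s):
    if s < acc[A_EXIT_MIN]:
        acc[A_EXIT_MIN] = s
    if s > acc[A_EXIT_MAX]:
        acc[A_EXIT_MAX] = s


@njit(cache=True)
def simulate_day(
    role, state, x, y, heading, leg, site_ix, site_iy, site_q, site_d,
    has_site, penalty_pending, timer, tenure, visited_today,
    is_forage, quality, half,
    condition_si,
    p_exit, p_rs, v, mu, t_patch_mean, t_patch_sd, t_nest,
    c_rest, c_move, m, trip_j_per_q, flight_cost_per_m, handling_j,
    c_recruit, n_dance, p_dance, dance_mid, dance_slope,
    influx_window, influx_floor,
    forage_open, forage_close, t_day, cell_width_m,
    acc, trip_dists, spells, returns_by_step,
):
    n = role.shape[0]
    order = np.arange(n)
    lim = half + 0.5
    acc[A_EXIT_MIN] = np.inf
    acc[A_EXIT_MAX] = -np.inf
    recent = 0  # returns within the trailing influx window
    stop = t_day

    for s in range(forage_open, t_day):
        if s > forage_close:
            all_home = True
            for i in range(n):
                st = state[i]
                if st != IDLE and st != WAITING:
                    all_home = False
                    break
            if all_home:
                stop = s
                break
        if s - influx_window >= 0:
            recent -= returns_by_step[s - influx_window]

        # fresh random update order every step
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp

        window_open = s <= forage_close  # s >= forage_open by construction

        for k in range(n):
            i = order[k]

            if m > 0.0 and np.random.random() < m:
                # death and in-place replacement by a naive nestmate
                acc[A_DEATHS] += 1.0
                if role[i] == ROLE_RECRUIT:
                    if has_site[i] and tenure[i] > 0:
                        ns = int(acc[A_NSPELL])
                        if ns < spells.shape[0]:
                            spells[ns] = tenure[i]
                            acc[A_NSPELL] += 1.0
                    state[i] = WAITING
                    acc[A_COST_R] += c_rest
                else:
                    state[i] = IDLE
                    acc[A_COST_S] += c_rest
                has_site[i] = False
                penalty_pending[i] = False
                timer[i] = 0
                tenure[i] = 0
                visited_today[i] = False
                x[i] = 0.0
                y[i] = 0.0
                leg[i] = 0.0
                continue

            st = state[i]

            if st == IDLE:
                if role[i] == ROLE_SCOUT:
                    acc[A_COST_S] += c_rest
                    if window_open and np.random.random() < p_exit:
                        state[i] = SCOUTING
                        x[i] = 0.0
                        y[i] = 0.0
                        heading[i] = 2.0 * math.pi * np.random.random()
                        leg[i] = _levy(mu)
                        _note_exit(acc, s)
                else:
                    acc[A_COST_R] += c_rest
                    if window_open and np.random.random() < p_exit:
                        state[i] = FLY_TO_SITE
                        x[i] = 0.0
                        y[i] = 0.0
                        _note_exit(acc, s)

            elif st == WAITING:
                acc[A_COST_R] += c_rest
                if window_open and np.random.random() < p_rs:
                    state[i] = SCOUTING
                    x[i] = 0.0
                    y[i] = 0.0
                    heading[i] = 2.0 * math.pi * np.random.random()
                    leg[i] = _levy(mu)
                    _note_exit(acc, s)

            elif st == SCOUTING:
                if role[i] == ROLE_SCOUT:
                    acc[A_COST_S] += c_move
                else:
                    acc[A_COST_R] += c_move
                if not window_open:
                    state[i] = RETURN_EMPTY
                else:
                    x[i] += v * math.cos(heading[i])
                    y[i] += v * math.sin(heading[i])
                    leg[i] -= v
                    # reflecting boundary
                    if x[i] > lim:
                        x[i] = 2.0 * lim - x[i]
                        heading[i] = math.pi - heading[i]
                    elif x[i] < -lim:
                        x[i] = -2.0 * lim - x[i]
                        heading[i] = math.pi - heading[i]
                    if y[i] > lim:
                        y[i] = 2.0 * lim - y[i]
                        heading[i] = -heading[i]
                    elif y[i] < -lim:
                        y[i] = -2.0 * lim - y[i]
                        heading[i] = -heading[i]
                    ix = int(math.floor(x[i] + 0.5))
                    iy = int(math.floor(y[i] + 0.5))
                    if (ix != 0 or iy != 0) and is_forage[ix + half, iy + half]:
                        state[i] = FEEDING
                        timer[i] = _feed_time(t_patch_mean, t_patch_sd)
                        site_ix[i] = ix
                        site_iy[i] = iy
                        site_q[i] = quality[ix + half, iy + half]
                        site_d[i] = math.sqrt(float(ix * ix + iy * iy)) \
                            * cell_width_m
                        if role[i] == ROLE_RECRUIT:
                            has_site[i] = True
                            tenure[i] = 0
                            visited_today[i] = False
                            penalty_pending[i] = False
                    elif leg[i] <= 0.0:
                        heading[i] = 2.0 * math.pi * np.random.random()
                        leg[i] = _levy(mu)

            elif st == FLY_TO_SITE:
                acc[A_COST_R] += c_move
                if not window_open:
                    state[i] = RETURN_EMPTY  # keep the site for tomorrow
                else:
                    tx = float(site_ix[i])
                    ty = float(site_iy[i])
                    dx = tx - x[i]
                    dy = ty - y[i]
                    dist = math.sqrt(dx * dx + dy * dy)
                    if dist <= v:
                        x[i] = tx
                        y[i] = ty
                        if penalty_pending[i]:
                            acc[A_PENALTY] += c_recruit
                            penalty_pending[i] = False
                        if is_forage[site_ix[i] + half, site_iy[i] + half]:
                            site_q[i] = quality[site_ix[i] + half,
                                                site_iy[i] + half]
                            state[i] = FEEDING
                            timer[i] = _feed_time(t_patch_mean, t_patch_sd)
                        else:
                            # site vanished overnight
                            if tenure[i] > 0:
                                ns = int(acc[A_NSPELL])
                                if ns < spells.shape[0]:
                                    spells[ns] = tenure[i]
                                    acc[A_NSPELL] += 1.0
                            has_site[i] = False
                            tenure[i] = 0
                            state[i] = RETURN_EMPTY
                    else:
                        x[i] += v * dx / dist
                        y[i] += v * dy / dist

            elif st == FEEDING:
                if role[i] == ROLE_SCOUT:
                    acc[A_COST_S] += c_move
                else:
                    acc[A_COST_R] += c_move
                if not window_open:
                    state[i] = RETURN_EMPTY
                else:
                    timer[i] -= 1
                    if timer[i] <= 0:
                        state[i] = RETURN_FULL

            elif st == RETURN_FULL or st == RETURN_EMPTY:
                if role[i] == ROLE_SCOUT:
                    acc[A_COST_S] += c_move
                else:
                    acc[A_COST_R] += c_move
                dist = math.sqrt(x[i] * x[i] + y[i] * y[i])
                if dist <= v:
                    x[i] = 0.0
                    y[i] = 0.0
                    if st == RETURN_FULL:
                        state[i] = UNLOADING
                        timer[i] = t_nest
                        val = site_q[i] * trip_j_per_q
                        if role[i] == ROLE_SCOUT:
                            acc[A_DELIV_S] += val
                            acc[A_TRIPS_S] += 1.0
                        else:
                            acc[A_DELIV_R] += val
                            acc[A_TRIPS_R] += 1.0
                        nd = int(acc[A_NDIST])
                        if nd < trip_dists.shape[0]:
                            trip_dists[nd] = site_d[i]
                            acc[A_NDIST] += 1.0
                        returns_by_step[s] += 1
                        recent += 1
                        if role[i] == ROLE_RECRUIT and has_site[i] \
                                and not visited_today[i]:
                            tenure[i] += 1
                            visited_today[i] = True
                    else:
                        if role[i] == ROLE_SCOUT:
                            state[i] = IDLE
                        elif has_site[i]:
                            state[i] = IDLE
                        else:
                            state[i] = WAITING
                else:
                    x[i] -= v * x[i] / dist
                    y[i] -= v * y[i] / dist

            elif st == UNLOADING:
                if role[i] == ROLE_SCOUT:
                    acc[A_COST_S] += c_rest
                else:
                    acc[A_COST_R] += c_rest
                if timer[i] > 0 and window_open:
                    q_t = _effective_value(site_q[i], site_d[i], trip_j_per_q,
                                           flight_cost_per_m, handling_j)
                    p_d = _dance_probability(q_t, dance_mid, dance_slope)
                    p_d *= _influx_factor(float(recent), influx_floor)
                    if np.random.random() < p_d:
                        acc[A_DANCES] += 1.0
                        for _ in range(n_dance):
                            jj = _pick_waiting(state)
                            if jj < 0:
                                continue
                            if condition_si:
                                if np.random.random() < p_dance:
                                    site_ix[jj] = site_ix[i]
                                    site_iy[jj] = site_iy[i]
                                    site_q[jj] = site_q[i]
                                    site_d[jj] = site_d[i]
                                    has_site[jj] = True
                                    penalty_pending[jj] = True
                                    tenure[jj] = 0
                                    visited_today[jj] = False
                                    state[jj] = IDLE
                                    acc[A_RECRUITED] += 1.0
                            else:
                                # disoriented dance: one follower is animated
                                # to scout for itself, no penalty, no vector
                                state[jj] = SCOUTING
                                x[jj] = 0.0
                                y[jj] = 0.0
                                heading[jj] = 2.0 * math.pi \
                                    * np.random.random()
                                leg[jj] = _levy(mu)
                                _note_exit(acc, s)
                timer[i] -= 1
                if timer[i] <= 0:
                    state[i] = IDLE

    acc[A_STOP] = stop
    return stop
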