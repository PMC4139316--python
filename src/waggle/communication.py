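"""Dance and abandonment decisions.

A returning forager advertises its food source with a probability that rises
with the net energetic value of a trip to that source (quality up, distance
down) and falls with the current influx of returning foragers.  The decision
of an experienced recruit to revisit its site the next morning follows the
same curve shifted up by ``return_shift`` (a source danced for 50% of the
time is revisited with probability 0.8).

The profitability-to-dance curve itself is a logistic in the net trip value
``q_t`` with midpoint and slope as calibration constants.  By default the
midpoint is anchored at the net value of a ``dance_anchor_q`` mol/l source at
``dance_anchor_d_m`` metres, and the slope is ``dance_slope_frac`` of the
midpoint; both can be overridden numerically (``dance_midpoint`` /
``dance_slope``).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from numba import njit

from .config import Params

__all__ = [
    "DanceModel", "effective_value", "dance_probability", "influx_factor",
    "return_probability", "record_return", "n_recent_returns",
]

INFLUX_SATURATION = 20  # returning foragers at which dancing bottoms out


# ---- scalar kernels (shared with the simulation engine) --------------------

@njit(cache=True)
def _effective_value(q, d_m, trip_j_per_q, flight_cost_per_m, handling_j):
    return q * trip_j_per_q - 2.0 * d_m * flight_cost_per_m - handling_j


@njit(cache=True)
def _dance_probability(q_t, midpoint, slope):
    z = (q_t - midpoint) / slope
    if z > 40.0:
        return 1.0
    if z < -40.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


@njit(cache=True)
def _influx_factor(n_recent, floor):
    if n_recent >= INFLUX_SATURATION:
        return floor
    return 1.0 - (1.0 - floor) * n_recent / INFLUX_SATURATION


@njit(cache=True)
def _return_probability(p_d, shift):
    p = p_d + shift
    return 1.0 if p > 1.0 else p


# ---- resolved model --------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DanceModel:
    """Dance/abandonment curves with all constants resolved to numbers."""

    trip_j_per_q: float       # J delivered per mol/l of quality
    flight_cost_per_m: float  # J per metre flown
    handling_j: float         # J spent handling (patch + unloading)
    midpoint: float           # J, net trip value at which p_d = 0.5
    slope: float              # J, logistic scale
    return_shift: float
    influx_floor: float
    influx_window: int

    @classmethod
    def from_params(cls, params: Params) -> "DanceModel":
        trip = params.trip_j_per_q
        flight = params.c_move / (params.v * params.cell_width_m)
        handling = (params.t_patch_mean * params.c_move
                    + params.t_nest * params.c_rest)
        mid = params.dance_midpoint
        if mid is None:
            mid = _effective_value(params.dance_anchor_q,
                                   params.dance_anchor_d_m,
                                   trip, flight, handling)
        if mid <= 0:
            raise ValueError(
                "dance midpoint resolves to a non-positive net trip value; "
                "adjust dance_midpoint or the anchor parameters")
        slope = params.dance_slope
        if slope is None:
            slope = params.dance_slope_frac * mid
        return cls(trip, flight, handling, float(mid), float(slope),
                   params.return_shift, params.influx_floor,
                   params.influx_window)


def effective_value(quality: float, distance_m: float, params: Params) -> float:
    """Net energetic value q_t of one trip: delivered load minus round-trip
    flight cost minus handling cost, in joules."""
    if quality < 0:
        raise ValueError("quality must be >= 0")
    if distance_m < 0:
        raise ValueError("distance must be >= 0")
    dm = DanceModel.from_params(params)
    return float(_effective_value(quality, distance_m, dm.trip_j_per_q,
                                  dm.flight_cost_per_m, dm.handling_j))


def dance_probability(quality: float, distance_m: float,
                      params: Params) -> float:
    """Probability (before influx modulation) of dancing for a source."""
    dm = DanceModel.from_params(params)
    q_t = _effective_value(quality, distance_m, dm.trip_j_per_q,
                           dm.flight_cost_per_m, dm.handling_j)
    return float(_dance_probability(q_t, dm.midpoint, dm.slope))


def influx_factor(n_recent_returns: int, params: Params) -> float:
    """Dance-probability multiplier: 1 with no recent returns, declining
    linearly to ``influx_floor`` at 20 returns, constant beyond."""
    if n_recent_returns < 0:
        raise ValueError("n_recent_returns must be >= 0")
    return float(_influx_factor(float(n_recent_returns), params.influx_floor))


def return_probability(quality: float, distance_m: float,
                       params: Params) -> float:
    """Probability that an experienced recruit revisits its site the next
    morning: the dance curve shifted up by ``return_shift``, clamped at 1."""
    p_d = dance_probability(quality, distance_m, params)
    return float(_return_probability(p_d, params.return_shift))


# ---- influx bookkeeping ----------------------------------------------------

def record_return(returns_by_step: np.ndarray, step: int) -> None:
    """Register a completed forager return at ``step`` of the day."""
    returns_by_step[step] += 1


def n_recent_returns(returns_by_step: np.ndarray, step: int,
                     params: Params) -> int:
    """Returns counted within the trailing ``influx_window`` steps
    (inclusive of ``step``)."""
    lo = max(0, step - params.influx_window + 1)
    return int(returns_by_step[lo:step + 1].sum())
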