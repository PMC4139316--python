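"""Model parameters: defaults, validation and (de)serialisation.

Every tunable of the simulation lives in :class:`Params`, including the
calibration constants of the dance curve that are not fixed by field data
(``dance_anchor_q``/``dance_anchor_d_m``/``dance_slope_frac``, or explicit
``dance_midpoint``/``dance_slope``).  A :class:`Params` is a plain frozen-ish
dataclass; :func:`validate` checks every invariant at once and is called by
the engine before any run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import yaml

__all__ = ["Params", "validate", "from_dict", "to_dict", "load", "save"]


@dataclasses.dataclass
class Params:
    """Full parameter set of the foraging model.

    Durations are in 10-second time steps unless the name says days;
    energies in joules; distances in metres where suffixed ``_m``,
    otherwise in cell widths (1 cell = ``cell_width_m`` metres).
    """

    # colony composition
    n_scouts: int = 30
    n_recruits: int = 270

    # clock
    t_day: int = 8640              # steps per day (10 s steps)
    t_init: int = 3                # acclimatization days, always SI
    n_exp_days: int = 48           # experimental days after acclimatization
    t_switch: int | None = 3       # SI/NI cycle length in days; None = no switching

    # departure probabilities (per step)
    p_exit: float = 0.815          # motivated forager leaves the nest
    p_rs: float = 0.00009          # idle recruit starts scouting on its own

    # world / patches
    d_patch: float = 0.05          # target density of forage patches
    a_max: int = 14                # patch longevity in days
    y_patch_mg: float = 50.0       # nectar load per trip
    q_mean: float = 1.0            # nectar quality, mol/l
    q_sd: float = 0.2
    grid_half_extent: int = 100    # cells from nest to edge (201x201 world)
    cell_width_m: float = 100.0
    patch_birth_mode: str = "stationary"   # or "literal"

    # trip timing
    t_patch_mean: float = 180.0    # on-patch handling time, steps
    t_patch_sd: float = 60.0
    t_nest: int = 6                # in-nest unloading steps

    # flight
    v: float = 0.7                 # speed, cell widths per step
    mu_levy: float = 2.4           # Levy-flight tail exponent

    # energetics
    c_rest: float = 0.04861        # J per resting step
    c_move_factor: float = 9.0     # flight cost multiplier on c_rest
    e_mol: float = 5_645_000.0     # J per mol sugar
    c_recruit: float = 325.0       # one-off search penalty for dance recruits
    load_volume_ul: float = 50.0   # microlitres of nectar per load

    # mortality
    m: float = 0.000007            # per-step death probability

    # recruitment
    n_dance: int = 1               # followers reached per dance
    p_dance: float = 0.25          # per-follower recruitment success (SI)

    # dance / abandonment calibration
    dance_midpoint: float | None = None   # J; computed from anchor when None
    dance_slope: float | None = None      # J; computed from anchor when None
    dance_anchor_q: float = 1.4           # mol/l at which p_d = 0.5 ...
    dance_anchor_d_m: float = 1000.0      # ... at this foraging distance
    dance_slope_frac: float = 0.40        # slope as a fraction of the midpoint
    return_shift: float = 0.30            # next-day return prob above dance prob

    # influx modulation of dancing
    influx_window: int = 20        # trailing steps over which returns count
    influx_floor: float = 0.0      # dance multiplier at >= 20 recent returns

    # recruit persistence (False reproduces the daily-switching control)
    persistent_recruits: bool = True

    # foraging window, steps of day (06:23-17:37 with 10 s steps from 06:00)
    forage_open: int = 138
    forage_close: int = 4182

    # replication
    n_runs: int = 12
    base_seed: int = 0

    # ---- derived quantities -------------------------------------------------

    @property
    def n_agents(self) -> int:
        return self.n_scouts + self.n_recruits

    @property
    def n_days(self) -> int:
        return self.t_init + self.n_exp_days

    @property
    def c_move(self) -> float:
        """Energy cost per step when airborne or on a patch, J."""
        return self.c_move_factor * self.c_rest

    @property
    def trip_j_per_q(self) -> float:
        """Delivered joules per (mol/l) of quality for one full load."""
        return self.load_volume_ul * 1e-6 * self.e_mol

    def replace(self, **changes: Any) -> "Params":
        return dataclasses.replace(self, **changes)


_PROBABILITIES = ("p_exit", "p_rs", "p_dance", "m", "d_patch",
                  "influx_floor", "return_shift")
_NONNEGATIVE = ("t_patch_sd", "q_sd", "c_rest", "e_mol", "c_recruit",
                "load_volume_ul", "y_patch_mg", "base_seed")
_POSITIVE = ("t_day", "t_patch_mean", "t_nest", "q_mean", "v", "cell_width_m",
             "c_move_factor", "n_dance", "n_runs", "a_max",
             "grid_half_extent", "dance_slope_frac", "dance_anchor_q")


def validate(params: Params) -> Params:
    """Return ``params`` unchanged or raise ``ValueError`` listing every
    violated invariant."""
    errors: list[str] = []
    for name in _PROBABILITIES:
        val = getattr(params, name)
        if not (0.0 <= val <= 1.0):
            errors.append(f"{name}={val!r} must be a probability in [0, 1]")
    for name in _NONNEGATIVE:
        if getattr(params, name) < 0:
            errors.append(f"{name}={getattr(params, name)!r} must be >= 0")
    for name in _POSITIVE:
        if getattr(params, name) <= 0:
            errors.append(f"{name}={getattr(params, name)!r} must be > 0")
    for name in ("n_scouts", "n_recruits", "t_init", "n_exp_days",
                 "influx_window"):
        if getattr(params, name) < 0:
            errors.append(f"{name}={getattr(params, name)!r} must be >= 0")
    if params.mu_levy <= 1.0:
        errors.append(
            f"mu_levy={params.mu_levy!r} must be > 1: the Levy inverse-CDF "
            "exponent 1/(1-mu) is undefined at mu = 1")
    if params.t_switch is not None and params.t_switch < 1:
        errors.append(f"t_switch={params.t_switch!r} must be None or >= 1 day")
    if not (0 <= params.forage_open < params.forage_close < params.t_day):
        errors.append(
            f"foraging window [{params.forage_open}, {params.forage_close}] "
            f"must satisfy 0 <= open < close < t_day={params.t_day}")
    if params.patch_birth_mode == "stationary" and params.d_patch >= 1.0:
        errors.append("d_patch must be < 1 in stationary patch-birth mode")
    if params.patch_birth_mode not in ("stationary", "literal"):
        errors.append(
            f"patch_birth_mode={params.patch_birth_mode!r} must be "
            "'stationary' or 'literal'")
    if params.dance_midpoint is not None and params.dance_midpoint <= 0:
        errors.append("dance_midpoint must be > 0 when given")
    if params.dance_slope is not None and params.dance_slope <= 0:
        errors.append("dance_slope must be > 0 when given")
    if not (0.0 < params.return_shift < 1.0):
        errors.append(f"return_shift={params.return_shift!r} must be in (0, 1)")
    if params.n_agents <= 0:
        errors.append("colony must contain at least one agent")
    if errors:
        raise ValueError("invalid parameters:\n  " + "\n  ".join(errors))
    return params


# ---- serialisation ---------------------------------------------------------

_FIELD_NAMES = {f.name for f in dataclasses.fields(Params)}


def to_dict(params: Params) -> dict[str, Any]:
    return dataclasses.asdict(params)


def from_dict(data: dict[str, Any]) -> Params:
    """Build a Params from a flat mapping; unknown keys are rejected."""
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    clean = dict(data)
    if isinstance(clean.get("t_switch"), str):
        if clean["t_switch"].lower() == "none":
            clean["t_switch"] = None
        else:
            clean["t_switch"] = int(clean["t_switch"])
    return Params(**clean)


def load(path: str | Path) -> Params:
    """Read a flat JSON or YAML parameter file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value document")
    return from_dict(data)


def save(params: Params, path: str | Path) -> None:
    path = Path(path)
    data = to_dict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
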