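import pytest

from waggle import Params, make_plan, replicate
from waggle.engine import SI


def small_params(**over) -> Params:
    """A miniature configuration for fast mechanics tests: short days, a
    small world and colony.  Behavioural rules are identical to defaults."""
    base = dict(
        n_scouts=10, n_recruits=40,
        t_day=720, forage_open=30, forage_close=430,
        t_init=1, n_exp_days=3,
        grid_half_extent=30,
        t_patch_mean=60.0, t_patch_sd=20.0,
        n_runs=2, base_seed=7,
    )
    base.update(over)
    return Params(**base)


@pytest.fixture
def tiny():
    return small_params()


@pytest.fixture(scope="session")
def colony_runs():
    """Memoized full-scale replicate sets shared across acceptance tests.

    ``no_switch(condition, seed, **over)`` runs 12 constant-condition
    replicates; ``switch(cycle, seed, **over)`` runs 12 switching replicates
    (6 SI-first, 6 NI-first).  Results are cached for the session so several
    tests can reuse the same experiment."""
    cache: dict = {}

    def no_switch(condition: str, seed: int, **over):
        key = ("ns", condition, seed, tuple(sorted(over.items())))
        if key not in cache:
            p = Params(n_runs=12, base_seed=seed, **over)
            cache[key] = replicate(p, make_plan(None, condition, p))
        return cache[key]

    def switch(cycle: int, seed: int, **over):
        key = ("sw", cycle, seed, tuple(sorted(over.items())))
        if key not in cache:
            p = Params(n_runs=12, base_seed=seed, **over)
            cache[key] = replicate(p, make_plan(cycle, SI, p))
        return cache[key]

    return no_switch, switch
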