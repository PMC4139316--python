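import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from waggle.analysis import (apparent_benefit, carryover_profile,
                             collect_tenures, per_capita_efficiency,
                             persistency_poisson, preset_experiments,
                             relative_benefit)
from waggle.config import Params


class TestRelativeBenefit:
    def test_arithmetic(self):
        assert relative_benefit([121.6], [100.0]) == pytest.approx(21.6)
        assert relative_benefit([84.2], [100.0]) == pytest.approx(-15.8)
        assert relative_benefit([5.0, 7.0], [5.0, 7.0]) == 0.0

    def test_undefined_for_nonpositive_reference(self):
        with pytest.raises(ValueError, match="undefined"):
            relative_benefit([10.0], [-1.0])
        with pytest.raises(ValueError):
            relative_benefit([], [1.0])


def _day_table(rows):
    base = dict(acclimatization=False, run_id=0, penalties=0.0,
                deliveries_scout=0.0, deliveries_recruit=0.0,
                costs_scout=0.0, costs_recruit=0.0, net_gain=0.0,
                condition="SI", day=1, tenures_ended=[])
    return pd.DataFrame([{**base, **r} for r in rows])


class TestPerCapitaEfficiency:
    def test_single_recruit_single_trip(self):
        """One delivery of 282.25 J against one day of resting costs."""
        p = Params(n_scouts=1, n_recruits=1)
        rest = p.t_day * p.c_rest
        df = _day_table([dict(deliveries_recruit=282.25, costs_recruit=rest)])
        value = per_capita_efficiency(df, "recruit", p)
        assert value == pytest.approx(282.25 - rest)
        assert value == pytest.approx(-137.75, abs=0.01)

    def test_no_trips_is_pure_cost(self):
        p = Params(n_scouts=2, n_recruits=1)
        rest = p.t_day * p.c_rest
        df = _day_table([dict(costs_scout=2 * rest)])
        assert per_capita_efficiency(df, "scout", p) == pytest.approx(-rest)

    def test_penalties_charged_to_recruits_only(self):
        p = Params(n_scouts=1, n_recruits=1)
        df = _day_table([dict(deliveries_recruit=500.0, penalties=325.0)])
        assert per_capita_efficiency(df, "recruit", p) \
            == pytest.approx(500.0 - 325.0)
        assert per_capita_efficiency(df, "scout", p) == 0.0

    def test_gross_option_ignores_costs(self):
        p = Params(n_scouts=1, n_recruits=1)
        df = _day_table([dict(deliveries_recruit=500.0, costs_recruit=100.0,
                              penalties=325.0)])
        assert per_capita_efficiency(df, "recruit", p, gross=True) == 500.0

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            per_capita_efficiency(_day_table([{}]), "queen", Params())


class TestPersistency:
    def test_closed_form_mle(self):
        mean, se = persistency_poisson([1, 2, 3, 2])
        assert mean == 2.0
        assert se == pytest.approx(np.sqrt(2.0 / 4.0))
        assert persistency_poisson([1, 1, 1])[0] == 1.0

    def test_against_numeric_likelihood_maximisation(self):
        """The closed-form Poisson MLE agrees with direct numeric
        maximisation of the log likelihood to 1e-6."""
        rng = np.random.default_rng(8)
        data = rng.poisson(2.7, size=400) + 1

        def nll(mu):
            return -(data * np.log(mu) - mu).sum()

        res = optimize.minimize_scalar(nll, bounds=(0.1, 30.0),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        mean, _ = persistency_poisson(data)
        assert mean == pytest.approx(res.x, abs=1e-6)

    def test_rejects_empty_or_fractional_day_spells(self):
        with pytest.raises(ValueError):
            persistency_poisson([])
        with pytest.raises(ValueError):
            persistency_poisson([0, 1])

    def test_collect_tenures_pools_spells(self):
        df = _day_table([dict(tenures_ended=[1, 2]),
                         dict(tenures_ended=[4])])
        df.loc[1, "day"] = 2
        assert sorted(collect_tenures(df)) == [1, 2, 4]


class TestCarryover:
    def test_block_positions_follow_the_schedule(self):
        rows = []
        for day, (cond, gain) in enumerate(
                [("SI", 10.0), ("SI", 11.0), ("NI", 30.0), ("NI", 5.0),
                 ("SI", 8.0), ("SI", 9.0)], start=1):
            rows.append(dict(day=day, condition=cond, net_gain=gain))
        prof = carryover_profile(_day_table(rows))
        ni1 = prof[(prof.condition == "NI") & (prof.block_position == 1)]
        assert ni1["mean"].iloc[0] == 30.0
        si1 = prof[(prof.condition == "SI") & (prof.block_position == 1)]
        assert si1["mean"].iloc[0] == 9.0  # days 1 and 5
        assert prof["block_position"].max() == 2


class TestPresets:
    @pytest.mark.parametrize("name, size", [
        ("experiment1", 12), ("experiment2", 16), ("no_cost", 4),
        ("sensitivity", 14),
    ])
    def test_suite_sizes(self, name, size):
        suite = preset_experiments(name)
        assert len(suite) == size
        for params, plan in suite:
            assert len(plan.schedule) == params.n_days

    def test_experiment_grids_cover_the_design(self):
        e1 = preset_experiments("experiment1")
        assert {p.d_patch for p, _ in e1} == {0.1, 0.05, 0.01}
        assert {pl.cycle for _, pl in e1} == {None, 2, 3, 12}
        e2 = preset_experiments("experiment2")
        assert {p.a_max for p, _ in e2} == {1, 7, 14, 28}
        nc = preset_experiments("no_cost")
        assert all(p.p_dance == 1.0 and p.c_recruit == 0.0 for p, _ in nc)
        assert {p.a_max for p, _ in nc} == {7, 21}

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            preset_experiments("bogus")


def test_apparent_benefit_uses_condition_days():
    rows = []
    for run in (0, 1):
        for day, cond in enumerate(["SI", "NI"] * 3, start=1):
            gain = 110.0 if cond == "SI" else 100.0
            rows.append(dict(day=day, condition=cond, net_gain=gain,
                             run_id=run))
    assert apparent_benefit(_day_table(rows)) == pytest.approx(10.0)
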