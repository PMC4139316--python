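import numpy as np
import pandas as pd
import pytest

from waggle import Params, condition_schedule, make_plan, replicate, \
    run_simulation
from waggle.engine import NI, SI

from conftest import small_params


class TestSchedules:
    def test_no_switch_is_constant_after_acclimatization(self):
        p = Params()
        sched = condition_schedule(None, SI, p)
        assert len(sched) == 51
        assert all(c == SI for c in sched)
        ni = condition_schedule(None, NI, p)
        assert ni[:3] == (SI, SI, SI)  # acclimatization is always SI
        assert all(c == NI for c in ni[3:])

    def test_three_day_cycles(self):
        sched = condition_schedule(3, SI, Params())
        assert sched[3:6] == (SI,) * 3
        assert sched[6:9] == (NI,) * 3
        assert sched[9:12] == (SI,) * 3

    def test_twelve_day_cycles_make_four_blocks(self):
        sched = condition_schedule(12, SI, Params())
        blocks = [sched[3 + 12 * k: 15 + 12 * k] for k in range(4)]
        assert [b[0] for b in blocks] == [SI, NI, SI, NI]
        assert all(len(set(b)) == 1 for b in blocks)

    def test_unknown_start_condition_rejected(self):
        with pytest.raises(ValueError):
            condition_schedule(3, "both", Params())


class TestRunSimulation:
    def test_record_shape_and_day_accounting(self, tiny):
        df = run_simulation(tiny, make_plan(None, SI, tiny), seed=3)
        assert len(df) == tiny.n_days
        assert df["acclimatization"].sum() == tiny.t_init
        assert (df["condition"] == SI).all()

    def test_same_seed_reproduces_identically(self, tiny):
        plan = make_plan(2, SI, tiny)
        a = run_simulation(tiny, plan, seed=99)
        b = run_simulation(tiny, plan, seed=99)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, tiny):
        plan = make_plan(None, SI, tiny)
        a = run_simulation(tiny, plan, seed=1)
        b = run_simulation(tiny, plan, seed=2)
        assert not np.allclose(a["net_gain"], b["net_gain"])

    def test_grounded_colony_pays_exactly_the_resting_cost(self):
        """With no exits at all every day's loss is the whole-colony resting
        cost, and nothing else happens."""
        p = small_params(p_exit=0.0, p_rs=0.0, m=0.0)
        df = run_simulation(p, make_plan(None, SI, p), seed=5)
        expect = -p.n_agents * p.t_day * p.c_rest
        assert np.allclose(df["net_gain"], expect, rtol=1e-12)
        assert (df["trips_scout"] == 0).all()
        assert (df[["dances", "recruitments", "deaths"]] == 0).all().all()

    def test_energy_ledger_identity_every_day(self, tiny):
        df = run_simulation(tiny, make_plan(3, SI, tiny), seed=17)
        recon = (df["deliveries_scout"] + df["deliveries_recruit"]
                 - df["costs_scout"] - df["costs_recruit"] - df["penalties"])
        assert np.allclose(df["net_gain"], recon, rtol=1e-12)
        assert np.allclose(df["energy_store"], df["net_gain"].cumsum(),
                           rtol=1e-12)

    def test_departures_stay_inside_the_foraging_window(self, tiny):
        df = run_simulation(tiny, make_plan(None, SI, tiny), seed=23)
        active = df[df["first_exit_step"] >= 0]
        assert len(active) > 0
        assert (active["first_exit_step"] >= tiny.forage_open).all()
        assert (active["last_exit_step"] <= tiny.forage_close).all()

    def test_heavy_mortality_keeps_the_simulation_coherent(self):
        p = small_params(m=0.003)
        df = run_simulation(p, make_plan(None, SI, p), seed=9)
        assert (df["deaths"] > 0).all()
        recon = (df["deliveries_scout"] + df["deliveries_recruit"]
                 - df["costs_scout"] - df["costs_recruit"] - df["penalties"])
        assert np.allclose(df["net_gain"], recon, rtol=1e-12)

    def test_schedule_length_must_match_params(self, tiny):
        plan = make_plan(None, SI, tiny)
        longer = tiny.replace(n_exp_days=tiny.n_exp_days + 1)
        with pytest.raises(ValueError, match="schedule length"):
            run_simulation(longer, plan, seed=0)


class TestReplicate:
    def test_replicate_stacks_runs_with_distinct_seeds(self, tiny):
        table = replicate(tiny, make_plan(None, SI, tiny))
        assert set(table["run_id"]) == {0, 1}
        assert len(table) == 2 * tiny.n_days
        g = table.groupby("run_id")["net_gain"].sum()
        assert g.loc[0] != g.loc[1]

    def test_switch_designs_balance_the_starting_condition(self):
        p = small_params(n_runs=4)
        table = replicate(p, make_plan(2, SI, p))
        starts = table.groupby("run_id")["start_condition"].first()
        assert sorted(starts) == [NI, NI, SI, SI]
        # NI-first runs spend their first experimental block in NI
        first_exp = table[table["day"] == p.t_init + 1]
        for _, row in first_exp.iterrows():
            assert row["condition"] == row["start_condition"]

    def test_no_switch_runs_all_share_the_condition(self):
        p = small_params(n_runs=3)
        table = replicate(p, make_plan(None, NI, p))
        exp = table[~table["acclimatization"]]
        assert (exp["condition"] == NI).all()
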