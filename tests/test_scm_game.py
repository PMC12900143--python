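"""Game-engine tests: policy maths, day stepping, conservation, KPIs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vreeg.errors import ParameterError, PolicyError, ScenarioComplete
from vreeg.scm_game import (
    ActorState,
    DemandSchedule,
    PolicyParams,
    ScenarioConfig,
    bullwhip_ratio,
    eoq,
    ledger_frame,
    new_chain_state,
    npc_order,
    reorder_point,
    run_scenario,
    safety_stock,
    step_day,
)


def params(**kw) -> PolicyParams:
    base = dict(z=1.645, mean_demand=7.0, lead_time=1, order_cost=1.0, holding_cost=1.0)
    base.update(kw)
    return PolicyParams(**base)


class TestPolicyMath:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(z=1.0, mean_demand=1.0, lead_time=1), 1.0),
            (dict(z=1.645, mean_demand=7.0, lead_time=1), 11.515),
            (dict(z=1.645, mean_demand=0.0, lead_time=3), 0.0),
        ],
    )
    def test_safety_stock(self, kw, expected):
        assert safety_stock(params(**kw)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(z=1.0, mean_demand=1.0, lead_time=1), 2.0),
            (dict(z=1.645, mean_demand=7.0, lead_time=1), 18.515),
            (dict(z=2.3, mean_demand=0.0, lead_time=4), 0.0),
        ],
    )
    def test_reorder_point(self, kw, expected):
        assert reorder_point(params(**kw)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(mean_demand=2.0, order_cost=1.0, holding_cost=1.0), 2.0),
            (dict(mean_demand=7.0, order_cost=1.0, holding_cost=1.0), math.sqrt(14.0)),
            (dict(mean_demand=8.0, order_cost=1.0, holding_cost=4.0), 2.0),
        ],
    )
    def test_eoq(self, kw, expected):
        assert eoq(params(**kw)) == pytest.approx(expected, rel=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            PolicyParams(lead_time=0)
        with pytest.raises(ParameterError):
            PolicyParams(mean_demand=-1)
        with pytest.raises(ParameterError):
            PolicyParams(holding_cost=0.0)
        with pytest.raises(ParameterError):
            PolicyParams(service_level=1.0)

    def test_monotonicity(self):
        # EOQ nondecreasing in demand and order cost, nonincreasing in h;
        # ROP nondecreasing in z, demand, lead time.
        grid = np.linspace(0.5, 20.0, 12)
        eoq_d = [eoq(params(mean_demand=d)) for d in grid]
        assert all(a <= b + 1e-12 for a, b in zip(eoq_d, eoq_d[1:]))
        eoq_h = [eoq(params(holding_cost=h)) for h in grid]
        assert all(a >= b - 1e-12 for a, b in zip(eoq_h, eoq_h[1:]))
        rop_z = [reorder_point(params(z=z)) for z in grid]
        assert all(a <= b + 1e-12 for a, b in zip(rop_z, rop_z[1:]))
        rop_l = [reorder_point(params(lead_time=lt)) for lt in (1, 2, 3, 5)]
        assert all(a <= b for a, b in zip(rop_l, rop_l[1:]))


class TestNPCOrder:
    def test_above_rop_no_order(self):
        actor = ActorState("distributor", inventory=100.0)
        assert npc_order(actor, params()) == 0

    def test_below_rop_orders_ceil_eoq(self):
        actor = ActorState("distributor", inventory=10.0)
        assert npc_order(actor, params()) == 4  # ceil(sqrt(14))

    def test_boundary_inclusive(self):
        actor = ActorState("manufacturer", inventory=reorder_point(params()))
        assert npc_order(actor, params()) == math.ceil(eoq(params()))

    def test_in_transit_counts_toward_position(self):
        actor = ActorState("distributor", inventory=10.0, in_transit=[(5, 50.0)])
        assert npc_order(actor, params()) == 0

    @pytest.mark.parametrize("name", ["customer", "farmer"])
    def test_policy_error_for_non_npc(self, name):
        with pytest.raises(PolicyError):
            npc_order(ActorState(name), params())


class TestStepDay:
    def test_retailer_fulfilment(self):
        state = new_chain_state(ScenarioConfig())
        rec = step_day(state, 0)
        retailer = rec.actors["retailer"]
        assert retailer.demand_faced == 5
        assert retailer.sales == 5
        assert retailer.lost_sales == 0
        assert retailer.end_inventory == 5

    def test_empty_stock_all_lost(self):
        config = ScenarioConfig(demand_schedule=(8,), initial_retailer_inventory=0)
        rec = step_day(new_chain_state(config), 0)
        assert rec.actors["retailer"].sales == 0
        assert rec.actors["retailer"].lost_sales == 8

    def test_day3_scripted_demand_is_12(self):
        state = new_chain_state(ScenarioConfig())
        for _ in range(2):
            step_day(state, 0)
        rec = step_day(state, 0)
        assert rec.actors["retailer"].demand_faced == 12

    def test_step_past_schedule_raises(self):
        state = new_chain_state(ScenarioConfig(demand_schedule=(1,)))
        step_day(state, 0)
        with pytest.raises(ScenarioComplete):
            step_day(state, 0)

    def test_player_order_arrives_after_lead_time(self):
        config = ScenarioConfig(demand_schedule=(0, 0, 0), initial_retailer_inventory=0)
        state = new_chain_state(config)
        step_day(state, 6)
        rec2 = step_day(state, 0)
        assert rec2.actors["retailer"].arrivals == 6
        assert rec2.actors["retailer"].end_inventory == 6


class TestRunScenario:
    def test_zero_order_policy_lost_sales(self):
        # With no replenishment only the starting stock of 10 can be sold.
        records, kpis = run_scenario(player_policy=[0] * 7)
        total_demand = sum((5, 8, 12, 8, 8, 5, 3))
        assert kpis.total_lost_sales == total_demand - 10
        assert kpis.total_revenue == 10

    def test_all_zero_schedule(self):
        config = ScenarioConfig(demand_schedule=(0,) * 5)
        records, kpis = run_scenario(config, player_policy=[0] * 5)
        assert kpis.total_revenue == 0
        assert kpis.total_lost_sales == 0

    def test_phase_only_adds_disclosure(self):
        base, kpi_a = run_scenario(ScenarioConfig(phase="no_communication"))
        comm, kpi_b = run_scenario(ScenarioConfig(phase="communication"))
        for rec_a, rec_b in zip(base, comm):
            assert rec_a.actors == rec_b.actors
            assert rec_a.disclosure is None
            assert set(rec_b.disclosure) == {"distributor", "manufacturer"}
        assert kpi_a == kpi_b

    def test_determinism_bit_identical_ledgers(self):
        frame_a = ledger_frame(run_scenario()[0])
        frame_b = ledger_frame(run_scenario()[0])
        assert frame_a.to_csv() == frame_b.to_csv()

    def test_shipment_timing_oracle(self):
        """Arrivals equal the upstream actor's sales one lead time earlier."""
        records, _ = run_scenario()
        lead = ScenarioConfig().lead_time
        links = [("retailer", "distributor"), ("distributor", "manufacturer"),
                 ("manufacturer", "farmer")]
        for i, rec in enumerate(records):
            for downstream, upstream in links:
                j = i - lead
                expected = records[j].actors[upstream].sales if j >= 0 else 0.0
                assert rec.actors[downstream].arrivals == expected


def assert_conservation(records):
    for rec in records:
        for name, actor_day in rec.actors.items():
            if not math.isfinite(actor_day.end_inventory):
                continue
            assert actor_day.end_inventory == pytest.approx(
                actor_day.start_inventory + actor_day.arrivals - actor_day.sales
            )
            assert actor_day.sales + actor_day.lost_sales == pytest.approx(
                actor_day.demand_faced
            )
            assert actor_day.sales >= 0 and actor_day.lost_sales >= 0
            assert actor_day.end_inventory >= 0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    schedule=st.lists(st.integers(0, 20), min_size=2, max_size=8),
    orders=st.lists(st.integers(0, 25), min_size=8, max_size=8),
    start=st.integers(0, 30),
)
def test_conservation_invariants_hold_for_any_scenario(schedule, orders, start):
    config = ScenarioConfig(
        demand_schedule=tuple(schedule), initial_retailer_inventory=start
    )
    records, _ = run_scenario(config, player_policy=orders[: len(schedule)])
    assert_conservation(records)


class TestBullwhip:
    def test_orders_equal_demand(self):
        demand = [5, 8, 12, 8, 8, 5, 3]
        assert bullwhip_ratio(demand, demand) == 1.0

    def test_constant_orders(self):
        assert bullwhip_ratio([4, 4, 4], [1, 5, 9]) == 0.0

    def test_zero_demand_variance_errors(self):
        with pytest.raises(ParameterError):
            bullwhip_ratio([1, 2, 3], [4, 4, 4])

    def test_kpi_report_contains_per_actor_ratios(self):
        _, kpis = run_scenario()
        assert set(kpis.bullwhip_ratio_per_actor) == {
            "retailer", "distributor", "manufacturer",
        }
        assert all(
            v >= 0 or math.isnan(v) for v in kpis.bullwhip_ratio_per_actor.values()
        )
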