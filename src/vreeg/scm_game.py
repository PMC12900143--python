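"""Deterministic multi-echelon supply-chain game engine.

Models the four-actor chain used in the VR role-play scenario —
farmer → manufacturer (processor) → distributor → retailer (player) →
customer — with scripted daily customer demand, NPC replenishment driven
by a 95% service level ((R, Q)-style reorder-point policy with an EOQ
batch), lost sales (no backorders), and player-facing KPIs: revenue,
lost sales, holding cost, and per-actor bullwhip ratios.

Policy maths
------------
The non-player actors follow three standard inventory-control quantities:

* safety stock        ``SS  = z · D̄ · L``
* reorder point       ``ROP = SS + D̄ · L``
* economic order qty  ``EOQ = sqrt(2 · D̄ · K / h)``

where ``z`` is the service-level factor (1.645 for a one-sided 95% normal
quantile), ``D̄`` the mean daily demand, ``L`` the lead time in days,
``K`` the fixed cost per order and ``h`` the holding cost per unit-day.
The safety-stock expression is used exactly in this product form; see
docs/methods.md for a note on how it relates to the textbook
``z·σ_D·√L`` variant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError, PolicyError, ScenarioComplete

__all__ = [
    "ACTOR_CHAIN",
    "DEFAULT_DEMAND_SCHEDULE",
    "PolicyParams",
    "DemandSchedule",
    "ActorState",
    "ChainState",
    "ActorDay",
    "DayRecord",
    "KPIReport",
    "ScenarioConfig",
    "safety_stock",
    "reorder_point",
    "eoq",
    "npc_order",
    "step_day",
    "run_scenario",
    "bullwhip_ratio",
    "ledger_frame",
]

#: Fixed actor order, upstream to downstream.
ACTOR_CHAIN = ("farmer", "manufacturer", "distributor", "retailer", "customer")

#: Scripted one-week customer demand (units/day) of the default scenario.
DEFAULT_DEMAND_SCHEDULE = (5, 8, 12, 8, 8, 5, 3)

#: Actors that run the reorder-point/EOQ policy.
NPC_POLICY_ACTORS = ("distributor", "manufacturer")


@dataclass(frozen=True)
class PolicyParams:
    """Parameters of the NPC replenishment policy.

    Attributes
    ----------
    service_level : float
        Target probability of not stocking out, in (0, 1).
    z : float
        Service-level factor (standard-normal quantile of
        ``service_level``); default 1.645 for the 95% level.
    mean_demand : float
        Mean daily demand D̄ in units/day.
    lead_time : int
        Replenishment lead time L in whole days, ≥ 1.
    order_cost : float
        Fixed cost K per order placed (currency/order).
    holding_cost : float
        Holding cost h per unit per day (currency/unit/day).
    """

    service_level: float = 0.95
    z: float = 1.645
    mean_demand: float = 7.0
    lead_time: int = 1
    order_cost: float = 1.0
    holding_cost: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.service_level < 1.0:
            raise ParameterError(f"service_level must be in (0,1), got {self.service_level}")
        if self.z <= 0:
            raise ParameterError(f"z must be > 0, got {self.z}")
        if self.mean_demand < 0:
            raise ParameterError(f"mean_demand must be >= 0, got {self.mean_demand}")
        if int(self.lead_time) != self.lead_time or self.lead_time < 1:
            raise ParameterError(f"lead_time must be an integer >= 1, got {self.lead_time}")
        if self.order_cost <= 0:
            raise ParameterError(f"order_cost must be > 0, got {self.order_cost}")
        if self.holding_cost <= 0:
            raise ParameterError(f"holding_cost must be > 0, got {self.holding_cost}")


@dataclass(frozen=True)
class DemandSchedule:
    """Ordered scripted customer demand, one non-negative integer per day."""

    daily_demand: tuple = DEFAULT_DEMAND_SCHEDULE

    def __post_init__(self) -> None:
        demand = tuple(int(d) for d in self.daily_demand)
        if any(d < 0 for d in demand):
            raise ParameterError("daily demand entries must be >= 0")
        if tuple(self.daily_demand) != demand:
            raise ParameterError("daily demand entries must be integers")
        object.__setattr__(self, "daily_demand", demand)

    def __len__(self) -> int:
        return len(self.daily_demand)

    def __getitem__(self, day_index: int) -> int:
        return self.daily_demand[day_index]


def safety_stock(params: PolicyParams) -> float:
    """Safety stock ``SS = z · D̄ · L`` (units)."""
    return params.z * params.mean_demand * params.lead_time


def reorder_point(params: PolicyParams) -> float:
    """Reorder point ``ROP = SS + D̄ · L`` (units)."""
    return safety_stock(params) + params.mean_demand * params.lead_time


def eoq(params: PolicyParams) -> float:
    """Economic order quantity ``sqrt(2 · D̄ · K / h)`` (units)."""
    return math.sqrt(2.0 * params.mean_demand * params.order_cost / params.holding_cost)


@dataclass
class ActorState:
    """Mutable per-actor state: stock on hand, incoming pipeline, ledger totals.

    ``inventory`` is ``math.inf`` for the farmer, who acts as an
    infinite-capacity source; the customer is a pure demand sink and
    keeps zero stock.
    """

    name: str
    inventory: float = 0.0
    in_transit: list = field(default_factory=list)  # [(arrival_day, units)]
    cumulative_sales: float = 0.0
    cumulative_lost_sales: float = 0.0
    cumulative_demand: float = 0.0

    def position(self) -> float:
        """Inventory position = on hand + shipped units still in transit."""
        return self.inventory + sum(units for _, units in self.in_transit)


def npc_order(actor: ActorState, params: PolicyParams) -> int:
    """Order quantity for a non-player actor under the (R, Q) policy.

    Returns ``ceil(EOQ)`` when the inventory position (on hand plus
    outstanding orders) is at or below the reorder point, else 0. Only the
    distributor and the manufacturer run this policy; the farmer is an
    infinite source and the customer a demand placeholder.
    """
    if actor.name not in NPC_POLICY_ACTORS:
        raise PolicyError(f"ordering policy does not apply to actor {actor.name!r}")
    if actor.position() <= reorder_point(params):
        return math.ceil(eoq(params))
    return 0


@dataclass(frozen=True)
class ActorDay:
    """One actor's ledger line for one day (all quantities in units)."""

    demand_faced: float
    sales: float
    lost_sales: float
    order_placed: float
    arrivals: float
    start_inventory: float
    end_inventory: float


@dataclass(frozen=True)
class DayRecord:
    """Ledger for a single simulated day.

    ``actors`` maps actor name to its :class:`ActorDay`. ``revenue`` and
    ``holding_cost_incurred`` are the player's (retailer's) KPIs for the
    day. ``disclosure`` is only populated in the communication phase and
    exposes upstream inventories and the order each NPC would place at its
    end-of-day position — observation only, NPC behaviour is unchanged.
    """

    day: int
    actors: dict
    revenue: float
    holding_cost_incurred: float
    disclosure: dict | None = None


@dataclass
class ChainState:
    """Full game state: day counter, phase, actor states, day ledger."""

    day: int
    phase: str
    actors: dict
    schedule: DemandSchedule
    config: "ScenarioConfig"
    day_records: list = field(default_factory=list)


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario configuration for :func:`run_scenario`.

    Defaults reproduce the scripted study scenario: one week of demand
    (5, 8, 12, 8, 8, 5, 3), retailer starting stock 10, unit ordering and
    holding costs, and a 95% service level for the NPC actors.
    """

    demand_schedule: tuple = DEFAULT_DEMAND_SCHEDULE
    initial_retailer_inventory: int = 10
    initial_distributor_inventory: int = 20
    initial_manufacturer_inventory: int = 20
    phase: str = "no_communication"
    unit_price: float = 1.0
    player_holding_cost: float = 1.0
    policy: PolicyParams = field(default_factory=PolicyParams)
    lead_time: int = 1

    def __post_init__(self) -> None:
        if self.phase not in ("no_communication", "communication"):
            raise ConfigError(f"unknown phase {self.phase!r}")
        for name in (
            "initial_retailer_inventory",
            "initial_distributor_inventory",
            "initial_manufacturer_inventory",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.unit_price < 0 or self.player_holding_cost < 0:
            raise ConfigError("prices and holding costs must be >= 0")
        if int(self.lead_time) != self.lead_time or self.lead_time < 1:
            raise ConfigError("lead_time must be an integer >= 1")
        try:
            DemandSchedule(self.demand_schedule)
        except ParameterError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ScenarioConfig":
        mapping = dict(mapping)
        if "policy" in mapping and isinstance(mapping["policy"], dict):
            mapping["policy"] = PolicyParams(**mapping["policy"])
        if "demand_schedule" in mapping:
            mapping["demand_schedule"] = tuple(mapping["demand_schedule"])
        try:
            return cls(**mapping)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def new_chain_state(config: ScenarioConfig) -> ChainState:
    """Initialise day-1 chain state from a scenario config."""
    actors = {
        "farmer": ActorState("farmer", inventory=math.inf),
        "manufacturer": ActorState(
            "manufacturer", inventory=float(config.initial_manufacturer_inventory)
        ),
        "distributor": ActorState(
            "distributor", inventory=float(config.initial_distributor_inventory)
        ),
        "retailer": ActorState("retailer", inventory=float(config.initial_retailer_inventory)),
        "customer": ActorState("customer", inventory=0.0),
    }
    return ChainState(
        day=1,
        phase=config.phase,
        actors=actors,
        schedule=DemandSchedule(config.demand_schedule),
        config=config,
    )


def _receive_arrivals(actor: ActorState, day: int) -> float:
    """Move pipeline units due today into stock; return the amount."""
    due = sum(units for when, units in actor.in_transit if when == day)
    actor.in_transit = [(when, units) for when, units in actor.in_transit if when != day]
    if math.isfinite(actor.inventory):
        actor.inventory += due
    return due


def _fulfil(actor: ActorState, demand: float) -> tuple:
    """Serve demand from stock; unmet demand is lost. Returns (sales, lost)."""
    sales = demand if not math.isfinite(actor.inventory) else min(demand, actor.inventory)
    lost = demand - sales
    if math.isfinite(actor.inventory):
        actor.inventory -= sales
    actor.cumulative_demand += demand
    actor.cumulative_sales += sales
    actor.cumulative_lost_sales += lost
    return sales, lost


def step_day(state: ChainState, player_order: int) -> DayRecord:
    """Advance the simulation by one day.

    Within-day event order for each actor, processed downstream to
    upstream (retailer, distributor, manufacturer, farmer):

    1. receive pipeline arrivals due today,
    2. fulfil demand (scripted customer demand for the retailer, the
       downstream actor's same-day order for the others); unmet demand is
       recorded as lost sales,
    3. place an order (``player_order`` for the retailer, the reorder-point
       policy for distributor and manufacturer),
    4. units shipped by the upstream actor enter the orderer's pipeline
       with arrival day ``day + lead_time``.

    Mutates ``state`` in place and returns the day's :class:`DayRecord`
    (also appended to ``state.day_records``).
    """
    day = state.day
    if day > len(state.schedule):
        raise ScenarioComplete(f"schedule has {len(state.schedule)} days; cannot step day {day}")
    if player_order < 0 or int(player_order) != player_order:
        raise ParameterError(f"player_order must be a non-negative integer, got {player_order}")

    config = state.config
    lead = config.lead_time
    demand_today = state.schedule[day - 1]
    actors = state.actors
    records: dict[str, ActorDay] = {}

    # Orders flow upstream within the day: each entry is (orderer, quantity).
    downstream_order = {"distributor": float(player_order)}

    # --- retailer -----------------------------------------------------
    retailer = actors["retailer"]
    start_inv = retailer.inventory
    arrivals = _receive_arrivals(retailer, day)
    sales, lost = _fulfil(retailer, float(demand_today))
    records["retailer"] = ActorDay(
        demand_faced=float(demand_today),
        sales=sales,
        lost_sales=lost,
        order_placed=float(player_order),
        arrivals=arrivals,
        start_inventory=start_inv,
        end_inventory=retailer.inventory,
    )

    # --- distributor, manufacturer ------------------------------------
    ship_to = {"distributor": "retailer", "manufacturer": "distributor"}
    for name in ("distributor", "manufacturer"):
        actor = actors[name]
        start_inv = actor.inventory
        arrivals = _receive_arrivals(actor, day)
        demand = downstream_order.get(name, 0.0)
        sales, lost = _fulfil(actor, demand)
        if sales > 0:
            actors[ship_to[name]].in_transit.append((day + lead, sales))
        order = float(npc_order(actor, config.policy))
        upstream = "manufacturer" if name == "distributor" else "farmer"
        downstream_order[upstream] = order
        records[name] = ActorDay(
            demand_faced=demand,
            sales=sales,
            lost_sales=lost,
            order_placed=order,
            arrivals=arrivals,
            start_inventory=start_inv,
            end_inventory=actor.inventory,
        )

    # --- farmer (infinite source, always ships) ------------------------
    farmer = actors["farmer"]
    demand = downstream_order.get("farmer", 0.0)
    sales, lost = _fulfil(farmer, demand)
    if sales > 0:
        actors["manufacturer"].in_transit.append((day + lead, sales))
    records["farmer"] = ActorDay(
        demand_faced=demand,
        sales=sales,
        lost_sales=lost,
        order_placed=0.0,
        arrivals=0.0,
        start_inventory=math.inf,
        end_inventory=math.inf,
    )

    # --- customer (demand placeholder) ---------------------------------
    records["customer"] = ActorDay(
        demand_faced=0.0,
        sales=0.0,
        lost_sales=0.0,
        order_placed=float(demand_today),
        arrivals=0.0,
        start_inventory=0.0,
        end_inventory=0.0,
    )

    disclosure = None
    if state.phase == "communication":
        disclosure = {
            name: {
                "inventory": actors[name].inventory,
                "expected_order": float(npc_order(actors[name], config.policy)),
            }
            for name in NPC_POLICY_ACTORS
        }

    record = DayRecord(
        day=day,
        actors=records,
        revenue=records["retailer"].sales * config.unit_price,
        holding_cost_incurred=records["retailer"].end_inventory * config.player_holding_cost,
        disclosure=disclosure,
    )
    state.day_records.append(record)
    state.day += 1
    return record


def bullwhip_ratio(orders: Sequence[float], demand: Sequence[float]) -> float:
    """Variance amplification ratio ``var(orders) / var(demand)``.

    Population variances; both series must have the same length ≥ 2 and
    the demand series must not be constant.
    """
    orders = np.asarray(orders, dtype=float)
    demand = np.asarray(demand, dtype=float)
    if orders.shape != demand.shape or orders.ndim != 1 or orders.size < 2:
        raise ParameterError("orders and demand must be 1-D series of equal length >= 2")
    demand_var = float(np.var(demand))
    if demand_var == 0.0:
        raise ParameterError("demand variance is zero; bullwhip ratio undefined")
    return float(np.var(orders)) / demand_var


@dataclass(frozen=True)
class KPIReport:
    """Aggregated player KPIs over a full scenario run."""

    total_revenue: float
    total_lost_sales: float
    total_holding_cost: float
    bullwhip_ratio_per_actor: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


PlayerPolicy = Callable[[int, ChainState], int]


def run_scenario(
    config: ScenarioConfig | dict | None = None,
    player_policy: PlayerPolicy | Sequence[int] | None = None,
) -> tuple[list[DayRecord], KPIReport]:
    """Run a full scenario and aggregate the KPI report.

    Parameters
    ----------
    config : ScenarioConfig or mapping, optional
        Scenario settings; defaults to the scripted study scenario.
    player_policy : callable or sequence of int, optional
        Either ``f(day, state) -> order`` or a per-day order list. The
        default player mirrors the day's scripted demand (pass-through).

    Returns
    -------
    (day_records, kpi_report)
        The per-day ledger and the aggregated KPI summary. Bullwhip ratios
        compare each ordering actor's order series against the scripted
        customer demand.
    """
    if config is None:
        config = ScenarioConfig()
    elif isinstance(config, dict):
        config = ScenarioConfig.from_mapping(config)

    schedule = DemandSchedule(config.demand_schedule)
    if player_policy is None:
        policy_fn: PlayerPolicy = lambda day, state: schedule[day - 1]
    elif callable(player_policy):
        policy_fn = player_policy
    else:
        orders = [int(o) for o in player_policy]
        if len(orders) < len(schedule):
            raise ConfigError(
                f"player order list has {len(orders)} entries for {len(schedule)} days"
            )
        policy_fn = lambda day, state: orders[day - 1]

    state = new_chain_state(config)
    records: list[DayRecord] = []
    for day in range(1, len(schedule) + 1):
        records.append(step_day(state, int(policy_fn(day, state))))

    demand = [float(d) for d in schedule.daily_demand]
    bullwhip = {}
    for name in ("retailer", "distributor", "manufacturer"):
        orders_series = [rec.actors[name].order_placed for rec in records]
        try:
            bullwhip[name] = bullwhip_ratio(orders_series, demand)
        except ParameterError:
            bullwhip[name] = float("nan")

    kpis = KPIReport(
        total_revenue=sum(rec.revenue for rec in records),
        total_lost_sales=sum(rec.actors["retailer"].lost_sales for rec in records),
        total_holding_cost=sum(rec.holding_cost_incurred for rec in records),
        bullwhip_ratio_per_actor=bullwhip,
    )
    return records, kpis


def ledger_frame(records: Iterable[DayRecord]) -> pd.DataFrame:
    """Flatten day records into a tidy frame (one row per actor-day)."""
    rows = []
    for rec in records:
        for actor, ad in rec.actors.items():
            rows.append(
                {
                    "day": rec.day,
                    "actor": actor,
                    "demand_faced": ad.demand_faced,
                    "sales": ad.sales,
                    "lost_sales": ad.lost_sales,
                    "order_placed": ad.order_placed,
                    "arrivals": ad.arrivals,
                    "start_inventory": ad.start_inventory,
                    "end_inventory": ad.end_inventory,
                    "revenue": rec.revenue if actor == "retailer" else 0.0,
                    "holding_cost": rec.holding_cost_incurred if actor == "retailer" else 0.0,
                }
            )
    return pd.DataFrame(rows)
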