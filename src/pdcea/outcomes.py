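"""Rewards, discounting and incremental cost-effectiveness results.

Costs (NT$/yr, societal perspective) and utilities are attached per
state and attained age, discounted at the configured annual rate, and
summed to per-person life years (LY), quality-adjusted life years
(QALY) and total cost. The two arms are then compared as incremental
cost-effectiveness ratios (ICER, NT$/QALY and NT$/LY), net monetary
benefit (NMB) at a willingness-to-pay threshold, and the WHO
cost-effectiveness classification against GDP per capita.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import (CohortTrace, State, Strategy, STAGE_OF, PD_STATES,
                     DEATH_STATES, N_STATES, run_cohort, default_strategies)
from .parameters import ParameterSet


def discount_factor(cycle: int, r: float) -> float:
    """Present-value factor (1+r)^(-cycle); cycle 0 undiscounted."""
    if r < 0:
        raise ValueError("negative discount rate")
    return (1.0 + r) ** (-cycle)


def state_cost(state: State, age: float, cycle: int, strategy: Strategy,
               ps: ParameterSet) -> float:
    """Annual societal cost (NT$) of occupying ``state`` at ``age``."""
    if state in DEATH_STATES:
        raise ValueError("death states accrue no cost")
    c = ps.costs
    covered = False
    if state == State.NORMAL:
        return 0.0
    if state == State.DM:
        cost = c.dm_medical.at(age) + c.dm_productivity_loss.at(age)
        covered = strategy.covers("dm")
    elif state in PD_STATES:
        key = f"hy{STAGE_OF[state]}"
        cost = c.pd_medical[key] + c.home_care[key] + c.pd_productivity_loss[key]
        covered = strategy.covers("pd")
    else:  # PD + DM
        key = f"hy{STAGE_OF[state]}"
        cost = (c.pddm_medical[key] + c.home_care[key]
                + c.pd_productivity_loss[key] + c.dm_productivity_loss.at(age))
        if ps.options.pddm_cost_adds_dm_medical:
            cost += c.dm_medical.at(age)
        covered = strategy.covers("pd_dm")
    if covered:
        cost += c.exenatide_annual
    return cost


def state_utility(state: State, age: float, cycle: int, strategy: Strategy,
                  ps: ParameterSet) -> float:
    """Utility weight in [0,1] of occupying ``state`` at ``age``.

    Diabetic states subtract the DM decrement plus an annual decline;
    the decline is approximated by model time (cycle index) because the
    cohort does not track state-entry times. Exenatide adds its utility
    increment in covered diabetic states. The result is clamped to [0,1].
    """
    if state in DEATH_STATES:
        raise ValueError("death states have utility 0 by convention")
    u = ps.utilities
    decline_years = cycle if ps.options.dm_decline_by_model_time else 0
    dm_loss = u.dm_decrement + u.dm_annual_decline * decline_years
    if state == State.NORMAL:
        value = u.normal.at(age)
    elif state == State.DM:
        value = u.normal.at(age) - dm_loss
        if strategy.covers("dm"):
            value += ps.effects.dm_utility_increment
    elif state in PD_STATES:
        value = u.pd[f"hy{STAGE_OF[state]}"]
    else:
        value = u.pd[f"hy{STAGE_OF[state]}"] - dm_loss
        if strategy.covers("pd_dm"):
            value += ps.effects.dm_utility_increment
    return min(1.0, max(0.0, value))


def reward_arrays(ps: ParameterSet, strategy: Strategy
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cycle, per-state rewards: (cost, utility, alive-indicator).

    Shapes (horizon, 13); death states carry zero everywhere.
    """
    horizon = ps.economics.horizon_cycles
    cost = np.zeros((horizon, N_STATES))
    util = np.zeros((horizon, N_STATES))
    alive = np.zeros(N_STATES)
    for s in State:
        if s in DEATH_STATES:
            continue
        alive[s] = 1.0
        for t in range(horizon):
            age = ps.economics.entry_age + t
            cost[t, s] = state_cost(s, age, t, strategy, ps)
            util[t, s] = state_utility(s, age, t, strategy, ps)
    return cost, util, alive


@dataclass
class OutcomeSummary:
    """Per-person totals over the horizon for one strategy."""

    strategy_label: str
    ly: float
    qaly: float
    cost: float
    ly_undiscounted: float
    qaly_undiscounted: float
    cost_undiscounted: float

    def as_dict(self) -> dict:
        return dict(strategy=self.strategy_label, ly=self.ly, qaly=self.qaly,
                    cost=self.cost, ly_undiscounted=self.ly_undiscounted,
                    qaly_undiscounted=self.qaly_undiscounted,
                    cost_undiscounted=self.cost_undiscounted)


def _occupancy_for_accrual(trace: CohortTrace, timing: str) -> np.ndarray:
    occ = trace.occupancy
    if timing == "start":
        return occ[:-1]
    if timing == "half_cycle":
        return 0.5 * (occ[:-1] + occ[1:])
    raise ValueError(f"unknown reward timing {timing!r}")


def accrue(trace: CohortTrace, ps: ParameterSet, strategy: Strategy,
           reference_trace: CohortTrace | None = None) -> OutcomeSummary:
    """Discounted and undiscounted per-person outcomes from a trace.

    Rewards accrue on start-of-cycle occupancy for cycles 0..horizon-1
    (or on the adjacent-boundary average under half-cycle timing), each
    cycle discounted by (1+r)^-t.

    Under ``dm_cost_accrual == 'equalized'`` the DM-state background
    cost stream (medical + productivity loss, excluding the drug) is
    taken from ``reference_trace`` — the comparator arm — so both arms
    carry identical DM background costs and differ only through drug
    cost and non-DM states.
    """
    if trace.strategy_label != strategy.label:
        raise ValueError("trace was produced under a different strategy")
    horizon = ps.economics.horizon_cycles
    if trace.occupancy.shape != (horizon + 1, N_STATES):
        raise ValueError("trace shape does not match parameter horizon")
    cost_arr, util_arr, alive = reward_arrays(ps, strategy)
    occ = _occupancy_for_accrual(trace, ps.options.reward_timing)
    disc = (1.0 + ps.economics.discount_rate) ** -np.arange(horizon)
    n = ps.economics.cohort_size

    dm_occ = occ[:, State.DM]
    if (ps.options.dm_cost_accrual == "equalized"
            and reference_trace is not None):
        ref_occ = _occupancy_for_accrual(reference_trace,
                                         ps.options.reward_timing)
        dm_occ = ref_occ[:, State.DM]
    dm_bg = np.array([ps.costs.dm_medical.at(ps.economics.entry_age + t)
                      + ps.costs.dm_productivity_loss.at(ps.economics.entry_age + t)
                      for t in range(horizon)])

    per_cycle_ly = occ @ alive
    per_cycle_qaly = np.einsum("ts,ts->t", occ, util_arr)
    # drug cost stays on own occupancy; only the DM background stream is
    # swapped under the equalized accrual mode
    per_cycle_cost = (np.einsum("ts,ts->t", occ, cost_arr)
                      + (dm_occ - occ[:, State.DM]) * dm_bg)
    return OutcomeSummary(
        strategy_label=strategy.label,
        ly=float(disc @ per_cycle_ly) / n,
        qaly=float(disc @ per_cycle_qaly) / n,
        cost=float(disc @ per_cycle_cost) / n,
        ly_undiscounted=float(per_cycle_ly.sum()) / n,
        qaly_undiscounted=float(per_cycle_qaly.sum()) / n,
        cost_undiscounted=float(per_cycle_cost.sum()) / n,
    )


@dataclass
class IncrementalResult:
    """Incremental comparison of the add-on arm against conventional."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    nmb: float
    wtp: float
    classification: str

    def as_dict(self) -> dict:
        return dict(delta_cost=self.delta_cost, delta_qaly=self.delta_qaly,
                    delta_ly=self.delta_ly, icer_per_qaly=self.icer_per_qaly,
                    icer_per_ly=self.icer_per_ly, nmb=self.nmb, wtp=self.wtp,
                    classification=self.classification)


def classify_icer(delta_cost: float, delta_qaly: float,
                  icer: float | None, gdp_per_capita: float) -> str:
    """WHO willingness-to-pay rule against GDP per capita."""
    if delta_qaly > 0 and delta_cost <= 0:
        return "dominant"
    if delta_qaly < 0 and delta_cost >= 0:
        return "dominated"
    if icer is None:
        return "undefined (no QALY difference)"
    if delta_qaly < 0:
        return "dominated" if delta_cost > 0 else "south-west (less costly, less effective)"
    if icer < gdp_per_capita:
        return "very cost-effective"
    if icer < 3.0 * gdp_per_capita:
        return "cost-effective"
    return "not cost-effective"


def incremental(conv: OutcomeSummary, exe: OutcomeSummary,
                wtp: float) -> IncrementalResult:
    """Incremental cost, effect, ICERs, NMB and WHO classification."""
    d_cost = exe.cost - conv.cost
    d_qaly = exe.qaly - conv.qaly
    d_ly = exe.ly - conv.ly
    icer_q = d_cost / d_qaly if d_qaly != 0.0 else None
    icer_l = d_cost / d_ly if d_ly != 0.0 else None
    nmb = wtp * d_qaly - d_cost
    label = classify_icer(d_cost, d_qaly, icer_q, wtp)
    return IncrementalResult(delta_cost=d_cost, delta_qaly=d_qaly,
                             delta_ly=d_ly, icer_per_qaly=icer_q,
                             icer_per_ly=icer_l, nmb=nmb, wtp=wtp,
                             classification=label)


def run_base_case(ps: ParameterSet, check: bool = True
                  ) -> tuple[OutcomeSummary, OutcomeSummary, IncrementalResult]:
    """Both arms end-to-end on one parameter set."""
    conv_s, exe_s = default_strategies(ps)
    conv_trace = run_cohort(ps, conv_s, check=check)
    exe_trace = run_cohort(ps, exe_s, check=False)
    conv = accrue(conv_trace, ps, conv_s)
    exe = accrue(exe_trace, ps, exe_s, reference_trace=conv_trace)
    inc = incremental(conv, exe, ps.economics.wtp_gdp)
    return conv, exe, inc
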