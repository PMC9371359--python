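"""Discrete-time Markov cohort engine for the 13-state PD/DM model.

State space (13 states): Normal; DM; four Parkinson's disease states by
Hoehn-Yahr (H-Y) stage 1..4+; four PD-with-comorbid-DM states by H-Y
stage; and three cause-specific absorbing death states (PD, DM, other).
Progression through H-Y stages is irreversible and DM, once acquired,
is never lost; incident PD always enters at H-Y 1.

Each annual cycle a 13x13 row-stochastic transition matrix is built for
the cohort's attained age (entry age + cycle): death is resolved first
as competing cause-specific risks, then disease onset / stage
progression among the survivors, all folded into one matrix
multiplicatively. The expected (fractional-person) cohort of 1,000 is
propagated over 50 cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .parameters import ParameterSet, TransitionRateSet, validate

N_STATES = 13


class State(IntEnum):
    """The 13 health states of the model."""

    NORMAL = 0
    DM = 1
    PD_HY1 = 2
    PD_HY2 = 3
    PD_HY3 = 4
    PD_HY4 = 5
    PDDM_HY1 = 6
    PDDM_HY2 = 7
    PDDM_HY3 = 8
    PDDM_HY4 = 9
    DEATH_PD = 10
    DEATH_DM = 11
    DEATH_OTHER = 12


PD_STATES = (State.PD_HY1, State.PD_HY2, State.PD_HY3, State.PD_HY4)
PDDM_STATES = (State.PDDM_HY1, State.PDDM_HY2, State.PDDM_HY3, State.PDDM_HY4)
DEATH_STATES = (State.DEATH_PD, State.DEATH_DM, State.DEATH_OTHER)
LIVING_STATES = tuple(s for s in State if s not in DEATH_STATES)

#: H-Y stage (1..4) of each PD/PD+DM state
STAGE_OF = {**{s: i + 1 for i, s in enumerate(PD_STATES)},
            **{s: i + 1 for i, s in enumerate(PDDM_STATES)}}

STATE_LABELS = [
    "Normal", "DM",
    "PD-HY1", "PD-HY2", "PD-HY3", "PD-HY4+",
    "PDDM-HY1", "PDDM-HY2", "PDDM-HY3", "PDDM-HY4+",
    "Death-PD", "Death-DM", "Death-Other",
]


@dataclass(frozen=True)
class Strategy:
    """A treatment arm.

    ``exenatide_coverage`` lists the living disease-state groups
    ('dm', 'pd', 'pd_dm') that receive exenatide effects and its cost;
    empty for the conventional arm.
    """

    label: str
    exenatide_coverage: frozenset = frozenset()

    def covers(self, group: str) -> bool:
        return group in self.exenatide_coverage


def conventional() -> Strategy:
    return Strategy("conventional")


def exenatide_addon(ps: ParameterSet | None = None) -> Strategy:
    """Add-on exenatide arm; coverage from model options (default: all
    DM/PD/PD+DM living disease states)."""
    cov = ps.options.exenatide_coverage if ps is not None else ("dm", "pd", "pd_dm")
    return Strategy("exenatide-add-on", frozenset(cov))


def default_strategies(ps: ParameterSet) -> tuple[Strategy, Strategy]:
    return conventional(), exenatide_addon(ps)


# ---------------------------------------------------------------------------
# Probability primitives
# ---------------------------------------------------------------------------

def rate_to_probability(rate: float, mode: str = "exponential",
                        dt: float = 1.0) -> float:
    """Annual transition probability from an annual hazard rate.

    'exponential' uses the constant-hazard conversion 1 - exp(-rate*dt);
    'identity' takes the rate itself as a probability, capped at 1.
    """
    if rate < 0:
        raise ValueError(f"negative rate: {rate}")
    if mode == "exponential":
        return 1.0 - math.exp(-rate * dt)
    if mode == "identity":
        return min(rate * dt, 1.0)
    raise ValueError(f"unknown rate conversion mode: {mode!r}")


def combine_competing_risks(cause_probs: dict) -> tuple[float, dict]:
    """Combine per-cause annual death probabilities within one cycle.

    Total death probability is 1 - prod(1 - p_k); it is allocated to
    causes proportionally to the constant-hazard weights -ln(1 - p_k).
    Any cause with p_k = 1 dominates (certain causes share the whole
    probability equally).

    Returns ``(total, {cause: allocated probability})``.
    """
    for cause, p in cause_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {cause} outside [0,1]: {p}")
    certain = [c for c, p in cause_probs.items() if p >= 1.0]
    if certain:
        share = 1.0 / len(certain)
        return 1.0, {c: (share if c in certain else 0.0)
                     for c in cause_probs}
    total = 1.0 - math.prod(1.0 - p for p in cause_probs.values())
    hazards = {c: -math.log1p(-p) for c, p in cause_probs.items()}
    hsum = sum(hazards.values())
    if hsum == 0.0:
        return 0.0, {c: 0.0 for c in cause_probs}
    return total, {c: total * h / hsum for c, h in hazards.items()}


# ---------------------------------------------------------------------------
# Transition matrix
# ---------------------------------------------------------------------------

def build_matrix(ps: ParameterSet, strategy: Strategy, cycle: int) -> np.ndarray:
    """Row-stochastic 13x13 transition matrix for one cycle.

    Within-cycle ordering: cause-specific death first, then disease
    onset / H-Y progression among survivors.
    """
    if not 0 <= cycle < ps.economics.horizon_cycles:
        raise ValueError(f"cycle {cycle} outside horizon")
    age = ps.economics.entry_age + cycle
    mode = ps.options.rate_conversion
    dt = ps.economics.cycle_length_years

    p_other = ps.mortality.other.at(age)
    p_dm_death = ps.mortality.dm.at(age)
    p_dm_death_exe = p_dm_death * ps.effects.dm_mortality_factor

    M = np.zeros((N_STATES, N_STATES))

    # Normal: other-cause death, then DM or PD onset among survivors
    i_dm = ps.incidence.dm.at(age)
    i_pd = ps.incidence.pd.at(age)
    surv = 1.0 - p_other
    M[State.NORMAL, State.DEATH_OTHER] = p_other
    M[State.NORMAL, State.DM] = surv * i_dm
    M[State.NORMAL, State.PD_HY1] = surv * i_pd
    M[State.NORMAL, State.NORMAL] = surv * (1.0 - i_dm - i_pd)

    # DM: competing DM/other death, then PD onset among survivors
    dm_covered = strategy.covers("dm")
    p_dm = p_dm_death_exe if dm_covered else p_dm_death
    total, alloc = combine_competing_risks(
        {"dm": p_dm, "other": p_other})
    i_pddm = ps.incidence.pd_given_dm.at(age)
    if dm_covered:
        i_pddm *= 1.0 - ps.effects.pd_incidence_reduction
    surv = 1.0 - total
    M[State.DM, State.DEATH_DM] = alloc["dm"]
    M[State.DM, State.DEATH_OTHER] = alloc["other"]
    M[State.DM, State.PDDM_HY1] = surv * i_pddm
    M[State.DM, State.DM] = surv * (1.0 - i_pddm)

    # PD (no DM): competing PD-stage/other death, then progression
    pd_covered = strategy.covers("pd")
    rates_pd = ps.rates_pd_treated() if pd_covered else ps.rates_pd
    _fill_pd_rows(M, PD_STATES, rates_pd,
                  extra_causes={"other": p_other},
                  ps=ps, mode=mode, dt=dt, death_state_extra=None)

    # PD + DM: PD-stage, DM and other-cause death compete
    pddm_covered = strategy.covers("pd_dm")
    rates_pddm = ps.rates_pddm_treated() if pddm_covered else ps.rates_pddm
    p_dm_in_pddm = p_dm_death_exe if pddm_covered else p_dm_death
    _fill_pd_rows(M, PDDM_STATES, rates_pddm,
                  extra_causes={"dm": p_dm_in_pddm, "other": p_other},
                  ps=ps, mode=mode, dt=dt, death_state_extra=State.DEATH_DM)

    # Absorbing death states
    for s in DEATH_STATES:
        M[s, s] = 1.0

    rowsums = M.sum(axis=1)
    if not np.allclose(rowsums, 1.0, rtol=0.0, atol=1e-12):
        bad = int(np.argmax(np.abs(rowsums - 1.0)))
        raise ValueError(f"row {STATE_LABELS[bad]} sums to {rowsums[bad]!r}")
    if (M < 0).any():
        raise ValueError("negative transition probability")
    return M


def _fill_pd_rows(M: np.ndarray, states, rates: TransitionRateSet,
                  extra_causes: dict, ps: ParameterSet, mode: str,
                  dt: float, death_state_extra) -> None:
    lams = rates.as_tuple()
    for idx, s in enumerate(states):
        stage = idx + 1
        causes = {"pd": ps.mortality.pd_stage[f"hy{stage}"], **extra_causes}
        total, alloc = combine_competing_risks(causes)
        surv = 1.0 - total
        M[s, State.DEATH_PD] = alloc["pd"]
        M[s, State.DEATH_OTHER] = alloc["other"]
        if death_state_extra is not None:
            M[s, death_state_extra] = alloc["dm"]
        if stage < 4:
            p_prog = rate_to_probability(lams[stage - 1], mode, dt)
            M[s, states[idx + 1]] = surv * p_prog
            M[s, s] = surv * (1.0 - p_prog)
        else:
            M[s, s] = surv


# ---------------------------------------------------------------------------
# Cohort propagation
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """State occupancy (persons) at each cycle boundary 0..horizon."""

    occupancy: np.ndarray       # (horizon+1, 13)
    ages: np.ndarray            # attained age at each boundary
    strategy_label: str

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATE_LABELS)
        df.insert(0, "age", self.ages)
        df.index.name = "cycle"
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def initial_cohort(ps: ParameterSet) -> np.ndarray:
    """Entry-age occupancy: cohort split between Normal and DM by the
    DM prevalence at entry; fractional persons allowed."""
    occ = np.zeros(N_STATES)
    n = ps.economics.cohort_size
    prev = ps.economics.dm_prevalence_at_entry
    occ[State.DM] = n * prev
    occ[State.NORMAL] = n * (1.0 - prev)
    return occ


def run_cohort(ps: ParameterSet, strategy: Strategy,
               check: bool = True) -> CohortTrace:
    """Propagate the expected cohort over the full horizon."""
    if check:
        problems = validate(ps)
        if problems:
            raise ValueError("invalid parameter set: " + "; ".join(problems))
    horizon = ps.economics.horizon_cycles
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0] = initial_cohort(ps)
    for t in range(horizon):
        occ[t + 1] = occ[t] @ build_matrix(ps, strategy, t)
    ages = ps.economics.entry_age + np.arange(horizon + 1)
    return CohortTrace(occupancy=occ, ages=ages, strategy_label=strategy.label)
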