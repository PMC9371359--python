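"""Test-input generators and independent oracles.

Three independent routes to the same expectations keep the cohort
engine honest:

* closed-form geometric-series outcomes for a toy constant-hazard model;
* an individual-level microsimulation that samples trajectories from
  the *same* per-cycle transition-matrix rows the cohort engine uses
  (shared probability construction, independent propagation and
  accrual);
* random valid parameter perturbations drawn uniformly from the
  published plausible ranges.

Also emits the published default parameter inventory as a config file.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from . import parameters as pm
from .markov import Strategy, build_matrix, initial_cohort
from .outcomes import OutcomeSummary, reward_arrays


def emit_default_fixture(path) -> None:
    """Write the published default parameter set as a YAML/JSON config."""
    pm.save_parameters(pm.published_defaults(), path)


def perturb_parameters(ps: pm.ParameterSet, seed: int) -> pm.ParameterSet:
    """A valid random parameter set: every ranged input drawn uniformly
    from its plausible bounds; derived quantities follow automatically.

    Deterministic given ``seed``; degenerate ranges return the base
    value unchanged.
    """
    rng = np.random.default_rng(seed)
    out, _ = draw_parameter_set(ps, rng)
    return out


def draw_parameter_set(ps: pm.ParameterSet, rng: np.random.Generator,
                       max_attempts: int = 1000
                       ) -> tuple[pm.ParameterSet, int]:
    """One uniform draw of every ranged parameter, redrawn until the
    joint set is valid (the printed H-Y utility ranges overlap, so
    independent draws can break stage monotonicity).

    Returns ``(parameter_set, number_of_redraws)``.
    """
    for attempt in range(max_attempts):
        out = ps.copy()
        for pid in sorted(out.ranges):
            r = out.ranges[pid]
            pm.set_parameter(out, pid, float(rng.uniform(r.low, r.high)))
        if not pm.validate(out):
            return out, attempt
    raise RuntimeError(f"no valid draw in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# Toy model with closed-form outcomes
# ---------------------------------------------------------------------------

@dataclass
class ToyModelSpec:
    """Two-state (alive/dead) constant-hazard toy model.

    Start-of-cycle accrual gives geometric-series closed forms, e.g.
    discounted QALY = u * sum_{t=0}^{T-1} ((1-p)/(1+r))^t.
    """

    death_prob: float
    cost: float
    utility: float
    discount_rate: float
    horizon: int

    def __post_init__(self):
        if not 0.0 <= self.death_prob <= 1.0:
            raise ValueError("death_prob outside [0, 1]")
        if not 0.0 <= self.utility <= 1.0:
            raise ValueError("utility outside [0, 1]")


def _geometric_sum(x: float, n: int) -> float:
    if x == 1.0:
        return float(n)
    return (1.0 - x ** n) / (1.0 - x)


def closed_form_outcomes(spec: ToyModelSpec) -> OutcomeSummary:
    """Exact per-person outcomes of the toy model."""
    s = 1.0 - spec.death_prob
    d = 1.0 / (1.0 + spec.discount_rate)
    ly = _geometric_sum(s * d, spec.horizon)
    ly_undisc = _geometric_sum(s, spec.horizon)
    return OutcomeSummary(
        strategy_label="toy",
        ly=ly, qaly=spec.utility * ly, cost=spec.cost * ly,
        ly_undiscounted=ly_undisc,
        qaly_undiscounted=spec.utility * ly_undisc,
        cost_undiscounted=spec.cost * ly_undisc,
    )


def toy_matrices(spec: ToyModelSpec) -> np.ndarray:
    """Per-cycle 2x2 transition matrix of the toy model (alive, dead)."""
    p = spec.death_prob
    return np.array([[1.0 - p, p], [0.0, 1.0]])


# ---------------------------------------------------------------------------
# Generic microsimulation
# ---------------------------------------------------------------------------

@dataclass
class MicrosimConfig:
    parameters: pm.ParameterSet
    strategy: Strategy
    n_individuals: int
    seed: int


@dataclass
class MicrosimResult:
    """Sample means with Monte-Carlo standard errors."""

    mean: OutcomeSummary
    se_ly: float
    se_qaly: float
    se_cost: float
    n_individuals: int


def _simulate_paths(init_probs: np.ndarray, matrices: list[np.ndarray],
                    n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample n state trajectories; returns (T+1, n) int state array."""
    n_states = init_probs.shape[0]
    states = rng.choice(n_states, size=n, p=init_probs)
    path = np.empty((len(matrices) + 1, n), dtype=np.int64)
    path[0] = states
    for t, M in enumerate(matrices):
        cum = np.cumsum(M, axis=1)
        u = rng.random(n)
        nxt = np.empty(n, dtype=np.int64)
        for s in np.unique(states):
            mask = states == s
            nxt[mask] = np.searchsorted(cum[s], u[mask], side="right")
        states = np.minimum(nxt, n_states - 1)
        path[t + 1] = states
    return path


def _accrue_paths(path: np.ndarray, cost_arr: np.ndarray,
                  util_arr: np.ndarray, alive: np.ndarray,
                  r: float, timing: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual discounted LY/QALY/cost from sampled trajectories."""
    horizon, n = path.shape[0] - 1, path.shape[1]
    disc = (1.0 + r) ** -np.arange(horizon)
    ly = np.zeros(n)
    qaly = np.zeros(n)
    cost = np.zeros(n)
    for t in range(horizon):
        if timing == "half_cycle":
            w_alive = 0.5 * (alive[path[t]] + alive[path[t + 1]])
            w_util = 0.5 * (util_arr[t][path[t]] + util_arr[t][path[t + 1]])
            w_cost = 0.5 * (cost_arr[t][path[t]] + cost_arr[t][path[t + 1]])
        else:
            w_alive = alive[path[t]]
            w_util = util_arr[t][path[t]]
            w_cost = cost_arr[t][path[t]]
        ly += disc[t] * w_alive
        qaly += disc[t] * w_util
        cost += disc[t] * w_cost
    return ly, qaly, cost


def microsimulate(cfg: MicrosimConfig) -> MicrosimResult:
    """Individual-level Monte-Carlo counterpart of the cohort engine.

    Trajectories are drawn from the rows of the same per-cycle matrices
    `build_matrix` produces and accrue the same per-state rewards, so
    sample means estimate the cohort expectations; reproducible given
    the seed.
    """
    ps = cfg.parameters
    rng = np.random.default_rng(cfg.seed)
    horizon = ps.economics.horizon_cycles
    matrices = [build_matrix(ps, cfg.strategy, t) for t in range(horizon)]
    init = initial_cohort(ps) / ps.economics.cohort_size
    path = _simulate_paths(init, matrices, cfg.n_individuals, rng)
    cost_arr, util_arr, alive = reward_arrays(ps, cfg.strategy)
    ly, qaly, cost = _accrue_paths(path, cost_arr, util_arr, alive,
                                   ps.economics.discount_rate,
                                   ps.options.reward_timing)
    n = cfg.n_individuals
    mean = OutcomeSummary(
        strategy_label=cfg.strategy.label,
        ly=float(ly.mean()), qaly=float(qaly.mean()), cost=float(cost.mean()),
        ly_undiscounted=float("nan"), qaly_undiscounted=float("nan"),
        cost_undiscounted=float("nan"),
    )
    return MicrosimResult(
        mean=mean,
        se_ly=float(ly.std(ddof=1) / np.sqrt(n)),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)),
        n_individuals=n,
    )


def microsimulate_toy(spec: ToyModelSpec, n: int, seed: int) -> MicrosimResult:
    """Microsimulation of the toy model (oracle cross-check)."""
    rng = np.random.default_rng(seed)
    M = toy_matrices(spec)
    matrices = [M] * spec.horizon
    init = np.array([1.0, 0.0])
    path = _simulate_paths(init, matrices, n, rng)
    horizon = spec.horizon
    cost_arr = np.tile(np.array([spec.cost, 0.0]), (horizon, 1))
    util_arr = np.tile(np.array([spec.utility, 0.0]), (horizon, 1))
    alive = np.array([1.0, 0.0])
    ly, qaly, cost = _accrue_paths(path, cost_arr, util_arr, alive,
                                   spec.discount_rate, "start")
    mean = OutcomeSummary(
        strategy_label="toy",
        ly=float(ly.mean()), qaly=float(qaly.mean()), cost=float(cost.mean()),
        ly_undiscounted=float("nan"), qaly_undiscounted=float("nan"),
        cost_undiscounted=float("nan"),
    )
    return MicrosimResult(mean=mean,
                          se_ly=float(ly.std(ddof=1) / np.sqrt(n)),
                          se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)),
                          se_cost=float(cost.std(ddof=1) / np.sqrt(n)),
                          n_individuals=n)


def cohort_toy_outcomes(spec: ToyModelSpec) -> OutcomeSummary:
    """Toy model pushed through matrix propagation + array accrual
    (the cohort-engine arithmetic on the 2-state chain)."""
    M = toy_matrices(spec)
    occ = np.zeros((spec.horizon + 1, 2))
    occ[0] = [1.0, 0.0]
    for t in range(spec.horizon):
        occ[t + 1] = occ[t] @ M
    disc = (1.0 + spec.discount_rate) ** -np.arange(spec.horizon)
    alive_occ = occ[:-1, 0]
    ly = float(disc @ alive_occ)
    return OutcomeSummary(
        strategy_label="toy",
        ly=ly, qaly=spec.utility * ly, cost=spec.cost * ly,
        ly_undiscounted=float(alive_occ.sum()),
        qaly_undiscounted=spec.utility * float(alive_occ.sum()),
        cost_undiscounted=spec.cost * float(alive_occ.sum()),
    )
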