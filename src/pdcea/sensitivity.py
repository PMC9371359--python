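"""One-way (tornado) and probabilistic sensitivity analysis.

The tornado sweep re-runs the full base-case pipeline with each ranged
parameter pushed to its lower and upper plausible bound, everything
else held at base, and orders parameters by the width of the induced
ICER excursion. The PSA draws every ranged parameter independently and
uniformly from its bounds (the published analysis names no
distribution), re-derives dependent quantities, and runs both arms per
iteration; its draws feed the cost-effectiveness acceptability curve
(CEAC) and the incremental cost-effectiveness plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import parameters as pm
from .outcomes import run_base_case
from .synthetic import draw_parameter_set


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float | None
    icer_at_high: float | None
    width: float


def _icer_for(ps: pm.ParameterSet) -> float | None:
    # validation (with the one-way exemption) already happened
    return run_base_case(ps, check=False)[2].icer_per_qaly


def one_way_tornado(ps: pm.ParameterSet) -> list[TornadoEntry]:
    """ICER excursions for every registered parameter range, sorted by
    width descending (ties broken alphabetically); perturbations are
    applied to copies, never to ``ps``.
    """
    entries = []
    for pid in sorted(ps.ranges):
        rng = ps.ranges[pid]
        icers = []
        for bound in (rng.low, rng.high):
            trial = ps.copy()
            pm.set_parameter(trial, pid, bound)
            # a one-way excursion to a printed bound may cross a
            # neighbouring stage's base utility; that joint-coherence
            # rule binds full parameter sets, not single excursions
            problems = [p for p in pm.validate(trial)
                        if "strictly decreasing" not in p]
            if problems:
                raise ValueError(f"excursion {pid}={bound} invalid: "
                                 + "; ".join(problems))
            icers.append(_icer_for(trial))
        lo_icer, hi_icer = icers
        if lo_icer is None or hi_icer is None:
            width = float("inf")
        else:
            width = abs(hi_icer - lo_icer)
        entries.append(TornadoEntry(pid, rng.low, rng.high,
                                    lo_icer, hi_icer, width))
    entries.sort(key=lambda e: (-e.width, e.parameter))
    return entries


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Per-iteration incremental results of the Monte-Carlo PSA."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    delta_ly: np.ndarray
    n_iterations: int
    seed: int
    sampling: str = "uniform"
    n_redrawn: int = 0

    @property
    def icer(self) -> np.ndarray:
        """Per-iteration ICER (NaN where the QALY difference is 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.delta_qaly != 0.0,
                            self.delta_cost / self.delta_qaly, np.nan)

    def nmb(self, wtp: float) -> np.ndarray:
        return wtp * self.delta_qaly - self.delta_cost

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of iterations with positive incremental NMB."""
        return float(np.mean(self.nmb(wtp) > 0.0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "icer": self.icer,
        })


def run_psa(ps: pm.ParameterSet, n: int = 1000, seed: int = 0,
            sampling: str = "uniform") -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty.

    Each iteration draws every ranged parameter independently from its
    plausible bounds ('uniform' is the default and the published mode;
    invalid joint draws are redrawn and counted), recomputes derived
    quantities, and runs both strategies. Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one iteration")
    if sampling != "uniform":
        raise ValueError(f"unsupported sampling mode {sampling!r}")
    rng = np.random.default_rng(seed)
    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    d_ly = np.empty(n)
    redrawn = 0
    for i in range(n):
        drawn, extra = draw_parameter_set(ps, rng)
        redrawn += extra
        _, _, inc = run_base_case(drawn)
        d_cost[i] = inc.delta_cost
        d_qaly[i] = inc.delta_qaly
        d_ly[i] = inc.delta_ly
    return PSAResult(delta_cost=d_cost, delta_qaly=d_qaly, delta_ly=d_ly,
                     n_iterations=n, seed=seed, sampling=sampling,
                     n_redrawn=redrawn)


@dataclass
class CEACPoint:
    wtp: float
    probability: float


def default_wtp_grid(ps: pm.ParameterSet, n_points: int = 61) -> np.ndarray:
    """0 to 3x GDP per capita (the WHO decision band)."""
    return np.linspace(0.0, 3.0 * ps.economics.wtp_gdp, n_points)


def ceac(psa: PSAResult, wtp_grid) -> list[CEACPoint]:
    """Probability of positive incremental NMB at each WTP value."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    return [CEACPoint(float(w), psa.prob_cost_effective(w)) for w in grid]


def ceac_table(points: list[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame([(p.wtp, p.probability) for p in points],
                        columns=["wtp", "probability_cost_effective"])


def icer_plane(psa: PSAResult) -> tuple[pd.DataFrame, dict[str, int]]:
    """Scatter of (dQALY, dCost) per iteration plus quadrant counts.

    NE: more effective & more costly; SE: more effective & cheaper
    (dominant); NW: less effective & more costly (dominated); SW:
    less effective & cheaper. Boundary points count toward the
    east/north side.
    """
    df = pd.DataFrame({"delta_qaly": psa.delta_qaly,
                       "delta_cost": psa.delta_cost})
    east = psa.delta_qaly >= 0
    north = psa.delta_cost >= 0
    quadrants = {
        "NE": int(np.sum(east & north)),
        "SE": int(np.sum(east & ~north)),
        "NW": int(np.sum(~east & north)),
        "SW": int(np.sum(~east & ~north)),
    }
    return df, quadrants
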