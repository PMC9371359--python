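"""Model inputs for the exenatide add-on cost-effectiveness analysis.

Holds every input of the decision model — age-banded incidences and
mortalities, Hoehn–Yahr (H-Y) stage transition rates, treatment-effect
multipliers, costs (NT$, 2020 value) and utilities — together with the
plausible ranges used by the sensitivity analyses, and reads/writes them
as strict, versioned YAML/JSON configuration files.

Conventions
-----------
* Age bands are inclusive-lower / exclusive-upper; the top band is
  open-ended (``"80+"``).
* H-Y stages are indexed 1..4, stage 4 standing for 4+ (severe/late).
* Treated (exenatide) transition rates are derived quantities:
  lambda_k * m_k, kept unrounded internally, rounded to 4 decimals for
  display only.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

SCHEMA_VERSION = 1

STAGE_KEYS = ("hy1", "hy2", "hy3", "hy4")


class ConfigError(ValueError):
    """A configuration file violates the documented schema."""


# ---------------------------------------------------------------------------
# Age-banded tables
# ---------------------------------------------------------------------------

@dataclass
class AgeBand:
    """One row of an age-banded table.

    ``upper`` is exclusive; ``None`` marks the open-ended top band.
    """

    lower: int
    upper: Optional[int]
    value: float

    def contains(self, age: float) -> bool:
        return age >= self.lower and (self.upper is None or age < self.upper)

    @property
    def key(self) -> str:
        if self.upper is None:
            return f"{self.lower}+"
        return f"{self.lower}-{self.upper - 1}"


@dataclass
class AgeTable:
    """Piecewise-constant lookup over contiguous age bands."""

    bands: list[AgeBand]

    def at(self, age: float) -> float:
        """Value of the band containing ``age`` (inclusive lower bound)."""
        for band in self.bands:
            if band.contains(age):
                return band.value
        raise KeyError(f"age {age} below the first band ({self.bands[0].lower})")

    def to_dict(self) -> dict[str, float]:
        return {b.key: b.value for b in self.bands}

    @staticmethod
    def from_dict(d: dict[str, float]) -> "AgeTable":
        bands = []
        for key, value in d.items():
            lower, upper = _parse_band_key(key)
            bands.append(AgeBand(lower, upper, float(value)))
        bands.sort(key=lambda b: b.lower)
        return AgeTable(bands)


def _parse_band_key(key: str) -> tuple[int, Optional[int]]:
    key = str(key)
    if key.endswith("+"):
        return int(key[:-1]), None
    lo, hi = key.split("-")
    return int(lo), int(hi) + 1


def lookup(table: AgeTable, age: float) -> float:
    """Band value for ``age``; inclusive-lower / exclusive-upper boundaries."""
    return table.at(age)


# ---------------------------------------------------------------------------
# Domain parameter groups
# ---------------------------------------------------------------------------

@dataclass
class IncidenceTables:
    """Annual incidence probabilities by attained age.

    ``pd_given_dm`` is the elevated PD incidence among people with
    pre-existing diabetes (age-specific hazard ratio ~2.2 below 60,
    ~1.5 above, folded into the printed values).
    """

    pd: AgeTable
    dm: AgeTable
    pd_given_dm: AgeTable


@dataclass
class MortalityTables:
    """Cause-specific annual death probabilities.

    DM mortality under exenatide is *derived*: conventional probability
    times the mortality effect (0.88), never stored independently.
    PD mortality is H-Y stage-specific rather than age-specific.
    """

    dm: AgeTable
    other: AgeTable
    pd_stage: dict[str, float]  # hy1..hy4


@dataclass
class TransitionRateSet:
    """Annual H-Y stage transition rates (lambda1: 1->2, lambda2: 2->3,
    lambda3: 3->4+)."""

    lam1: float
    lam2: float
    lam3: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lam1, self.lam2, self.lam3)


@dataclass
class ExenatideEffectSet:
    """Multiplicative treatment effects of add-on exenatide.

    m1..m3 scale the stage transition rates; dm_mortality_factor scales
    the DM death probability; dm_utility_increment is added to the
    utility of diabetic states; pd_incidence_reduction (scenario-only,
    0 in the base case) scales down PD incidence among treated DM
    occupants.
    """

    m1: float
    m2: float
    m3: float
    dm_mortality_factor: float
    dm_utility_increment: float
    pd_incidence_reduction: float = 0.0


@dataclass
class CostSchedule:
    """Societal-perspective annual costs in NT$ (2020 value, as printed)."""

    pd_medical: dict[str, float]
    pddm_medical: dict[str, float]
    home_care: dict[str, float]
    pd_productivity_loss: dict[str, float]
    dm_medical: AgeTable
    dm_productivity_loss: AgeTable
    exenatide_annual: float


@dataclass
class UtilitySchedule:
    normal: AgeTable          # 0.92 (40-64), 0.84 (65+)
    pd: dict[str, float]      # per H-Y stage
    dm_decrement: float       # utility lost with DM (stored positive)
    dm_annual_decline: float  # further annual utility loss with DM


@dataclass
class EconomicSettings:
    discount_rate: float = 0.03
    horizon_cycles: int = 50
    cycle_length_years: float = 1.0
    cohort_size: float = 1000.0
    entry_age: int = 40
    dm_prevalence_at_entry: float = 0.0605
    wtp_gdp: float = 839558.0


@dataclass
class ModelOptions:
    """Structural switches the source analysis leaves under-determined.

    ``rate_conversion``: 'exponential' (p = 1 - exp(-lambda)) or
    'identity' (p = min(lambda, 1)).
    ``reward_timing``: 'start' (start-of-cycle occupancy) or 'half_cycle'
    (average of adjacent cycle boundaries).
    ``exenatide_coverage``: which living disease-state groups receive
    exenatide effects and cost in the add-on arm.
    ``dm_cost_accrual``: 'per_arm' accrues DM background costs (medical
    + productivity loss) on each arm's own occupancy; 'equalized'
    assigns the DM background cost stream of the comparator arm to both
    arms, so the arms differ only through drug cost and non-DM states.
    """

    rate_conversion: str = "exponential"
    reward_timing: str = "start"
    exenatide_coverage: tuple[str, ...] = ("dm", "pd", "pd_dm")
    dm_cost_accrual: str = "per_arm"
    pddm_cost_adds_dm_medical: bool = False
    dm_decline_by_model_time: bool = True
    use_printed_pddm_lambda3: bool = False


@dataclass
class ParameterRange:
    """Plausible [low, high] bounds of one scalar input for SA/PSA."""

    low: float
    high: float


@dataclass
class ParameterSet:
    """The complete model input inventory plus SA ranges and options."""

    incidence: IncidenceTables
    mortality: MortalityTables
    rates_pd: TransitionRateSet
    rates_pddm: TransitionRateSet
    effects: ExenatideEffectSet
    costs: CostSchedule
    utilities: UtilitySchedule
    economics: EconomicSettings = field(default_factory=EconomicSettings)
    options: ModelOptions = field(default_factory=ModelOptions)
    ranges: dict[str, ParameterRange] = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------

    def rates_pd_treated(self) -> TransitionRateSet:
        return derive_treated_rates(self.rates_pd, self.effects)

    def rates_pddm_treated(self) -> TransitionRateSet:
        treated = derive_treated_rates(self.rates_pddm, self.effects)
        if self.options.use_printed_pddm_lambda3:
            treated = TransitionRateSet(treated.lam1, treated.lam2, 0.0210)
        return treated

    def dm_mortality_exenatide(self, age: float) -> float:
        return self.mortality.dm.at(age) * self.effects.dm_mortality_factor

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def derive_treated_rates(base: TransitionRateSet,
                         eff: ExenatideEffectSet) -> TransitionRateSet:
    """Exenatide-treated transition rates: (l1*m1, l2*m2, l3*m3), unrounded."""
    return TransitionRateSet(base.lam1 * eff.m1,
                             base.lam2 * eff.m2,
                             base.lam3 * eff.m3)


def displayed_rates(rates: TransitionRateSet) -> tuple[float, float, float]:
    """Rates rounded to 4 decimals, the precision used in reports."""
    return tuple(round(x, 4) for x in rates.as_tuple())


# ---------------------------------------------------------------------------
# Published defaults
# ---------------------------------------------------------------------------

def published_defaults() -> ParameterSet:
    """The published base-case parameter inventory.

    Every value is as printed in the source cost-effectiveness study
    (Taiwan, NT$ at 2020 value, cohort entering at age 40).
    """
    incidence = IncidenceTables(
        pd=AgeTable.from_dict({
            "40-49": 0.0,
            "50-59": 0.000211,
            "60-69": 0.000995,
            "70-79": 0.003005,
            "80+": 0.003699,
        }),
        dm=AgeTable.from_dict({
            "40-49": 0.00964,
            "50-59": 0.00964,
            "60-69": 0.01906,
            "70-79": 0.01906,
            "80+": 0.01637,
        }),
        pd_given_dm=AgeTable.from_dict({
            "40-49": 0.0,
            "50-59": 0.000464,
            "60-69": 0.001542,
            "70-79": 0.004658,
            "80+": 0.005733,
        }),
    )
    mortality = MortalityTables(
        dm=AgeTable.from_dict({
            "40-49": 0.01510,
            "50-59": 0.02195,
            "60-69": 0.03931,
            "70-74": 0.05288,
            "75+": 0.08150,
        }),
        other=AgeTable.from_dict({
            "40-49": 0.00266,
            "50-59": 0.00507,
            "60-69": 0.01028,
            "70-79": 0.02677,
            "80+": 0.05722,
        }),
        pd_stage={"hy1": 0.01, "hy2": 0.048, "hy3": 0.080, "hy4": 0.199},
    )
    rates_pd = TransitionRateSet(0.3237, 0.068, 0.3192)
    rates_pddm = TransitionRateSet(0.4369, 0.1462, 0.3192)
    # Base-case multipliers implied by the treated-rate arithmetic
    # (0.3065 = 0.3237*0.947 etc.); the independently printed nominal
    # multipliers 0.981/0.245/0.214 supply only the SA ranges below.
    effects = ExenatideEffectSet(
        m1=0.947, m2=0.239, m3=0.206,
        dm_mortality_factor=0.88,
        dm_utility_increment=0.08,
        pd_incidence_reduction=0.0,
    )
    costs = CostSchedule(
        pd_medical={"hy1": 21821.9, "hy2": 69074.2,
                    "hy3": 71969.3, "hy4": 133558.1},
        pddm_medical={"hy1": 21821.9, "hy2": 90217.1,
                      "hy3": 77079.1, "hy4": 148740.9},
        home_care={"hy1": 0.0, "hy2": 0.0, "hy3": 22220.0, "hy4": 22220.0},
        pd_productivity_loss={"hy1": 17261.2, "hy2": 52185.1,
                              "hy3": 95538.9, "hy4": 54593.7},
        dm_medical=AgeTable.from_dict({
            "40-49": 43903.6,
            "50-59": 58903.6,
            "60-69": 73903.6,
            "70-79": 88903.6,
            "80+": 103903.6,
        }),
        # productivity loss listed only for working ages; 0 from 70 on
        dm_productivity_loss=AgeTable.from_dict({
            "40-49": 635049.0,
            "50-59": 605055.6,
            "60-69": 481893.0,
            "70+": 0.0,
        }),
        exenatide_annual=33926.8,
    )
    utilities = UtilitySchedule(
        normal=AgeTable.from_dict({"40-64": 0.92, "65+": 0.84}),
        pd={"hy1": 0.708, "hy2": 0.678, "hy3": 0.622, "hy4": 0.499},
        dm_decrement=0.04,
        dm_annual_decline=0.003,
    )
    ranges = {
        "incidence.pd.50-59": ParameterRange(0.000193, 0.000229),
        "incidence.pd.60-69": ParameterRange(0.000773, 0.001218),
        "incidence.pd.70-79": ParameterRange(0.002577, 0.003435),
        "incidence.pd.80+": ParameterRange(0.003280, 0.004118),
        "incidence.dm.40-49": ParameterRange(0.00911, 0.01017),
        "incidence.dm.50-59": ParameterRange(0.00911, 0.01017),
        "incidence.dm.60-69": ParameterRange(0.01699, 0.02112),
        "incidence.dm.70-79": ParameterRange(0.01699, 0.02112),
        "incidence.dm.80+": ParameterRange(0.01419, 0.01854),
        "incidence.pd_given_dm.50-59": ParameterRange(0.000371, 0.000578),
        "incidence.pd_given_dm.60-69": ParameterRange(0.001453, 0.001711),
        "incidence.pd_given_dm.70-79": ParameterRange(0.004387, 0.005169),
        "incidence.pd_given_dm.80+": ParameterRange(0.005401, 0.006362),
        "mortality.dm.40-49": ParameterRange(0.0099, 0.0203),
        "mortality.dm.50-59": ParameterRange(0.0123, 0.0350),
        "mortality.dm.60-69": ParameterRange(0.0273, 0.0547),
        "mortality.dm.70-74": ParameterRange(0.0486, 0.0580),
        "mortality.dm.75+": ParameterRange(0.0778, 0.0863),
        "mortality.other.40-49": ParameterRange(0.0017, 0.0035),
        "mortality.other.50-59": ParameterRange(0.0038, 0.0065),
        "mortality.other.60-69": ParameterRange(0.0070, 0.0148),
        "mortality.other.70-79": ParameterRange(0.0164, 0.0393),
        "mortality.other.80+": ParameterRange(0.0432, 0.0628),
        "effects.dm_mortality_factor": ParameterRange(0.86, 0.90),
        # printed nominal range is 0.95-0.99; low extended to cover the
        # base-case multiplier implied by the treated-rate arithmetic
        "effects.m1": ParameterRange(0.947, 0.99),
        "effects.m2": ParameterRange(0.20, 0.32),
        "effects.m3": ParameterRange(0.17, 0.28),
        "costs.pd_medical.hy2": ParameterRange(17470.5, 254268.4),
        "costs.pd_medical.hy3": ParameterRange(22218.5, 152150.8),
        "costs.pd_medical.hy4": ParameterRange(50890.6, 172994.6),
        "costs.pddm_medical.hy2": ParameterRange(24685.3, 264341.0),
        "costs.pddm_medical.hy3": ParameterRange(43927.4, 123334.5),
        "costs.pd_productivity_loss.hy1": ParameterRange(5218.5, 29304.0),
        "costs.pd_productivity_loss.hy2": ParameterRange(40142.4, 64227.8),
        "costs.pd_productivity_loss.hy3": ParameterRange(83496.2, 107581.6),
        "costs.pd_productivity_loss.hy4": ParameterRange(42550.9, 66636.4),
        "costs.dm_medical.40-49": ParameterRange(39887.8, 47919.4),
        "costs.dm_medical.50-59": ParameterRange(54887.8, 62919.4),
        "costs.dm_medical.60-69": ParameterRange(69887.8, 77919.4),
        "costs.dm_medical.70-79": ParameterRange(84887.8, 92919.4),
        "costs.dm_medical.80+": ParameterRange(99887.8, 107919.4),
        "utilities.pd.hy1": ParameterRange(0.638, 0.778),
        "utilities.pd.hy2": ParameterRange(0.608, 0.748),
        "utilities.pd.hy3": ParameterRange(0.552, 0.692),
        "utilities.pd.hy4": ParameterRange(0.429, 0.569),
        "utilities.dm_decrement": ParameterRange(0.0352, 0.0448),
        "utilities.dm_annual_decline": ParameterRange(0.00214, 0.00387),
        "utilities.normal.40-64": ParameterRange(0.74, 1.00),
        "utilities.normal.65+": ParameterRange(0.39, 1.00),
        "effects.dm_utility_increment": ParameterRange(0.06, 0.10),
        "economics.discount_rate": ParameterRange(0.0, 0.05),
    }
    return ParameterSet(
        incidence=incidence,
        mortality=mortality,
        rates_pd=rates_pd,
        rates_pddm=rates_pddm,
        effects=effects,
        costs=costs,
        utilities=utilities,
        ranges=ranges,
    )


# ---------------------------------------------------------------------------
# Scalar-parameter registry (shared by tornado / PSA / perturbation)
# ---------------------------------------------------------------------------

def _band_ref(table: AgeTable, key: str) -> AgeBand:
    for band in table.bands:
        if band.key == key:
            return band
    raise KeyError(key)


def get_parameter(ps: ParameterSet, pid: str) -> float:
    """Current value of registry parameter ``pid``."""
    head, *rest = pid.split(".")
    if head == "incidence":
        group, key = rest
        return _band_ref(getattr(ps.incidence, group), key).value
    if head == "mortality":
        group, key = rest
        return _band_ref(getattr(ps.mortality, group), key).value
    if head == "effects":
        return getattr(ps.effects, rest[0])
    if head == "costs":
        group = rest[0]
        obj = getattr(ps.costs, group)
        if isinstance(obj, AgeTable):
            return _band_ref(obj, rest[1]).value
        return obj[rest[1]]
    if head == "utilities":
        group = rest[0]
        if group == "normal":
            return _band_ref(ps.utilities.normal, rest[1]).value
        if group == "pd":
            return ps.utilities.pd[rest[1]]
        return getattr(ps.utilities, group)
    if head == "economics":
        return getattr(ps.economics, rest[0])
    raise KeyError(pid)


def set_parameter(ps: ParameterSet, pid: str, value: float) -> None:
    """Set registry parameter ``pid`` in place (derived values follow)."""
    head, *rest = pid.split(".")
    if head == "incidence":
        group, key = rest
        _band_ref(getattr(ps.incidence, group), key).value = value
    elif head == "mortality":
        group, key = rest
        _band_ref(getattr(ps.mortality, group), key).value = value
    elif head == "effects":
        setattr(ps.effects, rest[0], value)
    elif head == "costs":
        group = rest[0]
        obj = getattr(ps.costs, group)
        if isinstance(obj, AgeTable):
            _band_ref(obj, rest[1]).value = value
        else:
            obj[rest[1]] = value
    elif head == "utilities":
        group = rest[0]
        if group == "normal":
            _band_ref(ps.utilities.normal, rest[1]).value = value
        elif group == "pd":
            ps.utilities.pd[rest[1]] = value
        else:
            setattr(ps.utilities, group, value)
    elif head == "economics":
        setattr(ps.economics, rest[0], value)
    else:
        raise KeyError(pid)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_bands(name: str, table: AgeTable, out: list[str],
                 lo: float = 0.0, hi: float = math.inf,
                 start_age: int = 40) -> None:
    if not table.bands:
        out.append(f"{name}: empty table")
        return
    if table.bands[0].lower != start_age:
        out.append(f"{name}: first band starts at {table.bands[0].lower}, "
                   f"expected {start_age}")
    prev_upper = table.bands[0].lower
    for band in table.bands:
        if band.lower != prev_upper:
            out.append(f"{name}.{band.key}: bands not contiguous")
        prev_upper = band.upper if band.upper is not None else None
        if not (lo <= band.value <= hi):
            out.append(f"{name}.{band.key}: value {band.value} outside "
                       f"[{lo}, {hi}]")
        if prev_upper is None:
            break
    if table.bands[-1].upper is not None:
        out.append(f"{name}: top band must be open-ended")


def validate(ps: ParameterSet) -> list[str]:
    """All invariant violations in ``ps`` (empty list means valid)."""
    v: list[str] = []
    _check_bands("incidence.pd", ps.incidence.pd, v, 0.0, 1.0)
    _check_bands("incidence.dm", ps.incidence.dm, v, 0.0, 1.0)
    _check_bands("incidence.pd_given_dm", ps.incidence.pd_given_dm, v, 0.0, 1.0)
    _check_bands("mortality.dm", ps.mortality.dm, v, 0.0, 1.0)
    _check_bands("mortality.other", ps.mortality.other, v, 0.0, 1.0)
    _check_bands("costs.dm_medical", ps.costs.dm_medical, v)
    _check_bands("costs.dm_productivity_loss", ps.costs.dm_productivity_loss, v)
    _check_bands("utilities.normal", ps.utilities.normal, v, 0.0, 1.0)

    if ps.incidence.pd.bands[0].value != 0.0:
        v.append("incidence.pd.40-49: PD incidence before age 50 must be 0")
    for band in ps.incidence.pd.bands:
        elevated = ps.incidence.pd_given_dm.at(band.lower)
        if elevated < band.value - 1e-15:
            v.append(f"incidence.pd_given_dm.{band.key}: {elevated} below "
                     f"plain PD incidence {band.value}")

    stages = [ps.mortality.pd_stage[k] for k in STAGE_KEYS]
    for k, p in zip(STAGE_KEYS, stages):
        if not 0.0 <= p <= 1.0:
            v.append(f"mortality.pd_stage.{k}: {p} outside [0, 1]")
    if any(b > a for a, b in zip(stages[1:], stages[:-1])):
        v.append("mortality.pd_stage: must be non-decreasing in stage")
    if ps.effects.dm_mortality_factor > 1.0:
        v.append("effects.dm_mortality_factor: exceeds 1, treated DM "
                 "mortality would exceed conventional")

    for name, rates in (("rates_pd", ps.rates_pd), ("rates_pddm", ps.rates_pddm)):
        for lam_name, lam in zip(("lam1", "lam2", "lam3"), rates.as_tuple()):
            if lam < 0:
                v.append(f"{name}.{lam_name}: negative rate {lam}")
    for fname in ("m1", "m2", "m3", "dm_mortality_factor"):
        if getattr(ps.effects, fname) < 0:
            v.append(f"effects.{fname}: negative factor")
    if not 0.0 <= ps.effects.pd_incidence_reduction <= 1.0:
        v.append("effects.pd_incidence_reduction: outside [0, 1]")

    for group in ("pd_medical", "pddm_medical", "home_care",
                  "pd_productivity_loss"):
        for key, amount in getattr(ps.costs, group).items():
            if amount < 0:
                v.append(f"costs.{group}.{key}: negative amount {amount}")
    if ps.costs.exenatide_annual < 0:
        v.append("costs.exenatide_annual: negative amount")

    pd_u = [ps.utilities.pd[k] for k in STAGE_KEYS]
    for k, u in zip(STAGE_KEYS, pd_u):
        if not 0.0 <= u <= 1.0:
            v.append(f"utilities.pd.{k}: {u} outside [0, 1]")
    if not all(a > b for a, b in zip(pd_u[:-1], pd_u[1:])):
        v.append("utilities.pd: must be strictly decreasing in stage")
    if ps.utilities.dm_decrement < 0 or ps.utilities.dm_annual_decline < 0:
        v.append("utilities.dm decrement/decline: must be non-negative")

    eco = ps.economics
    if eco.discount_rate < 0:
        v.append("economics.discount_rate: negative")
    if eco.horizon_cycles < 1:
        v.append("economics.horizon_cycles: must be >= 1")
    if not 0.0 <= eco.dm_prevalence_at_entry <= 1.0:
        v.append("economics.dm_prevalence_at_entry: outside [0, 1]")
    if eco.cohort_size <= 0:
        v.append("economics.cohort_size: must be positive")

    if ps.options.rate_conversion not in ("exponential", "identity"):
        v.append("options.rate_conversion: must be exponential|identity")
    if ps.options.reward_timing not in ("start", "half_cycle"):
        v.append("options.reward_timing: must be start|half_cycle")
    if ps.options.dm_cost_accrual not in ("per_arm", "equalized"):
        v.append("options.dm_cost_accrual: must be per_arm|equalized")
    for group in ps.options.exenatide_coverage:
        if group not in ("dm", "pd", "pd_dm"):
            v.append(f"options.exenatide_coverage: unknown group {group!r}")

    for pid, rng in ps.ranges.items():
        try:
            base = get_parameter(ps, pid)
        except KeyError:
            v.append(f"ranges.{pid}: unknown parameter id")
            continue
        if not rng.low <= base <= rng.high:
            v.append(f"ranges.{pid}: base {base} outside "
                     f"[{rng.low}, {rng.high}]")
    return v


# ---------------------------------------------------------------------------
# Serialisation (strict, versioned)
# ---------------------------------------------------------------------------

def to_dict(ps: ParameterSet) -> dict:
    """Plain-dict form of a ParameterSet (the on-disk schema)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "incidence": {
            "pd": ps.incidence.pd.to_dict(),
            "dm": ps.incidence.dm.to_dict(),
            "pd_given_dm": ps.incidence.pd_given_dm.to_dict(),
        },
        "mortality": {
            "dm": ps.mortality.dm.to_dict(),
            "other": ps.mortality.other.to_dict(),
            "pd_stage": dict(ps.mortality.pd_stage),
        },
        "transition_rates": {
            "pd": {"lam1": ps.rates_pd.lam1, "lam2": ps.rates_pd.lam2,
                   "lam3": ps.rates_pd.lam3},
            "pd_dm": {"lam1": ps.rates_pddm.lam1, "lam2": ps.rates_pddm.lam2,
                      "lam3": ps.rates_pddm.lam3},
        },
        "effects": asdict(ps.effects),
        "costs": {
            "pd_medical": dict(ps.costs.pd_medical),
            "pddm_medical": dict(ps.costs.pddm_medical),
            "home_care": dict(ps.costs.home_care),
            "pd_productivity_loss": dict(ps.costs.pd_productivity_loss),
            "dm_medical": ps.costs.dm_medical.to_dict(),
            "dm_productivity_loss": ps.costs.dm_productivity_loss.to_dict(),
            "exenatide_annual": ps.costs.exenatide_annual,
        },
        "utilities": {
            "normal": ps.utilities.normal.to_dict(),
            "pd": dict(ps.utilities.pd),
            "dm_decrement": ps.utilities.dm_decrement,
            "dm_annual_decline": ps.utilities.dm_annual_decline,
        },
        "economics": asdict(ps.economics),
        "options": {
            "rate_conversion": ps.options.rate_conversion,
            "reward_timing": ps.options.reward_timing,
            "exenatide_coverage": list(ps.options.exenatide_coverage),
            "dm_cost_accrual": ps.options.dm_cost_accrual,
            "pddm_cost_adds_dm_medical": ps.options.pddm_cost_adds_dm_medical,
            "dm_decline_by_model_time": ps.options.dm_decline_by_model_time,
            "use_printed_pddm_lambda3": ps.options.use_printed_pddm_lambda3,
        },
        "sa_ranges": {pid: [r.low, r.high] for pid, r in ps.ranges.items()},
    }


_TOP_KEYS = {"schema_version", "incidence", "mortality", "transition_rates",
             "effects", "costs", "utilities", "economics", "options",
             "sa_ranges"}


def _require_keys(d: dict, allowed: set[str], context: str) -> None:
    if not isinstance(d, dict):
        raise ConfigError(f"{context}: expected a mapping")
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")
    missing = allowed - set(d)
    if missing:
        raise ConfigError(f"{context}: missing key(s) {sorted(missing)}")


def _num_table(d: dict, context: str) -> dict[str, float]:
    out = {}
    for key, value in d.items():
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{context}.{key}: non-numeric value {value!r}")
        out[str(key)] = float(value)
    return out


def from_dict(data: dict) -> ParameterSet:
    """Parse the on-disk schema; unknown or missing keys are errors."""
    _require_keys(data, _TOP_KEYS, "config")
    if data["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(f"config: unsupported schema_version "
                          f"{data['schema_version']!r}")

    _require_keys(data["incidence"], {"pd", "dm", "pd_given_dm"}, "incidence")
    _require_keys(data["mortality"], {"dm", "other", "pd_stage"}, "mortality")
    _require_keys(data["transition_rates"], {"pd", "pd_dm"}, "transition_rates")
    _require_keys(data["effects"],
                  {"m1", "m2", "m3", "dm_mortality_factor",
                   "dm_utility_increment", "pd_incidence_reduction"},
                  "effects")
    _require_keys(data["costs"],
                  {"pd_medical", "pddm_medical", "home_care",
                   "pd_productivity_loss", "dm_medical",
                   "dm_productivity_loss", "exenatide_annual"}, "costs")
    _require_keys(data["utilities"],
                  {"normal", "pd", "dm_decrement", "dm_annual_decline"},
                  "utilities")
    _require_keys(data["economics"],
                  {"discount_rate", "horizon_cycles", "cycle_length_years",
                   "cohort_size", "entry_age", "dm_prevalence_at_entry",
                   "wtp_gdp"}, "economics")
    _require_keys(data["options"],
                  {"rate_conversion", "reward_timing", "exenatide_coverage",
                   "dm_cost_accrual", "pddm_cost_adds_dm_medical",
                   "dm_decline_by_model_time", "use_printed_pddm_lambda3"},
                  "options")

    def stage_map(d: dict, context: str) -> dict[str, float]:
        _require_keys(d, set(STAGE_KEYS), context)
        return _num_table(d, context)

    tr = data["transition_rates"]
    for arm in ("pd", "pd_dm"):
        _require_keys(tr[arm], {"lam1", "lam2", "lam3"},
                      f"transition_rates.{arm}")

    eff = _num_table(data["effects"], "effects")
    eco_raw = data["economics"]
    eco = _num_table(eco_raw, "economics")
    opt = data["options"]
    cov = opt["exenatide_coverage"]
    if not isinstance(cov, list) or not all(isinstance(c, str) for c in cov):
        raise ConfigError("options.exenatide_coverage: expected list of strings")
    for flag in ("pddm_cost_adds_dm_medical", "dm_decline_by_model_time",
                 "use_printed_pddm_lambda3"):
        if not isinstance(opt[flag], bool):
            raise ConfigError(f"options.{flag}: expected a boolean")

    ranges = {}
    for pid, bounds in data["sa_ranges"].items():
        if (not isinstance(bounds, list) or len(bounds) != 2
                or any(isinstance(b, bool) or not isinstance(b, (int, float))
                       for b in bounds)):
            raise ConfigError(f"sa_ranges.{pid}: expected [low, high]")
        if bounds[0] > bounds[1]:
            raise ConfigError(f"sa_ranges.{pid}: low > high")
        ranges[str(pid)] = ParameterRange(float(bounds[0]), float(bounds[1]))

    ps = ParameterSet(
        incidence=IncidenceTables(
            pd=AgeTable.from_dict(_num_table(data["incidence"]["pd"],
                                             "incidence.pd")),
            dm=AgeTable.from_dict(_num_table(data["incidence"]["dm"],
                                             "incidence.dm")),
            pd_given_dm=AgeTable.from_dict(
                _num_table(data["incidence"]["pd_given_dm"],
                           "incidence.pd_given_dm")),
        ),
        mortality=MortalityTables(
            dm=AgeTable.from_dict(_num_table(data["mortality"]["dm"],
                                             "mortality.dm")),
            other=AgeTable.from_dict(_num_table(data["mortality"]["other"],
                                                "mortality.other")),
            pd_stage=stage_map(data["mortality"]["pd_stage"],
                               "mortality.pd_stage"),
        ),
        rates_pd=TransitionRateSet(**_num_table(tr["pd"],
                                                "transition_rates.pd")),
        rates_pddm=TransitionRateSet(**_num_table(tr["pd_dm"],
                                                  "transition_rates.pd_dm")),
        effects=ExenatideEffectSet(**eff),
        costs=CostSchedule(
            pd_medical=stage_map(data["costs"]["pd_medical"],
                                 "costs.pd_medical"),
            pddm_medical=stage_map(data["costs"]["pddm_medical"],
                                   "costs.pddm_medical"),
            home_care=stage_map(data["costs"]["home_care"],
                                "costs.home_care"),
            pd_productivity_loss=stage_map(
                data["costs"]["pd_productivity_loss"],
                "costs.pd_productivity_loss"),
            dm_medical=AgeTable.from_dict(
                _num_table(data["costs"]["dm_medical"], "costs.dm_medical")),
            dm_productivity_loss=AgeTable.from_dict(
                _num_table(data["costs"]["dm_productivity_loss"],
                           "costs.dm_productivity_loss")),
            exenatide_annual=float(data["costs"]["exenatide_annual"]),
        ),
        utilities=UtilitySchedule(
            normal=AgeTable.from_dict(_num_table(data["utilities"]["normal"],
                                                 "utilities.normal")),
            pd=stage_map(data["utilities"]["pd"], "utilities.pd"),
            dm_decrement=float(data["utilities"]["dm_decrement"]),
            dm_annual_decline=float(data["utilities"]["dm_annual_decline"]),
        ),
        economics=EconomicSettings(
            discount_rate=eco["discount_rate"],
            horizon_cycles=int(eco["horizon_cycles"]),
            cycle_length_years=eco["cycle_length_years"],
            cohort_size=eco["cohort_size"],
            entry_age=int(eco["entry_age"]),
            dm_prevalence_at_entry=eco["dm_prevalence_at_entry"],
            wtp_gdp=eco["wtp_gdp"],
        ),
        options=ModelOptions(
            rate_conversion=str(opt["rate_conversion"]),
            reward_timing=str(opt["reward_timing"]),
            exenatide_coverage=tuple(cov),
            dm_cost_accrual=str(opt["dm_cost_accrual"]),
            pddm_cost_adds_dm_medical=opt["pddm_cost_adds_dm_medical"],
            dm_decline_by_model_time=opt["dm_decline_by_model_time"],
            use_printed_pddm_lambda3=opt["use_printed_pddm_lambda3"],
        ),
        ranges=ranges,
    )
    problems = validate(ps)
    if problems:
        raise ConfigError("config violates model invariants: "
                          + "; ".join(problems))
    return ps


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Write ``ps`` as YAML (.yaml/.yml) or JSON (.json)."""
    path = Path(path)
    data = to_dict(ps)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a parameter config (YAML or JSON); strict schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"parameter config not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return from_dict(data)
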