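"""Species-agnostic daily carbon-water core.

The two crop simulators in this package (rice seedling, oil palm) share one
set of primitives: a single-layer soil water bucket whose state is summarised
by FTSW (fraction of transpirable soil water), broken-stick drought response
functions, Beer-Lambert light interception, radiation-use-efficiency carbon
supply, the supply/demand index of competition Ic, and a daily carbon budget
with reserve storage and mobilization.

Conventions
-----------
* One time step = one day.  All rates are per day.
* Water is tracked as depth (mm) over whatever footprint the caller's bucket
  represents (unit ground area for a field canopy, pot footprint for a pot).
* Carbon is tracked as g CH2O per plant.
* All process rates are evaluated with the *morning* FTSW, i.e. the bucket
  state before the day's transpiration is withdrawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = [
    "ClimateDay",
    "SoilBucket",
    "CarbonBudget",
    "SoilStep",
    "NO_DEMAND",
    "thermal_time_increment",
    "compute_ftsw",
    "stress_factor",
    "intercept_fraction",
    "daily_supply",
    "index_of_competition",
    "resolve_budget",
    "step_soil",
]

#: Sentinel returned by :func:`index_of_competition` when demand is zero.
#: Downstream code treats it as "no competition", i.e. Ic >= 1 (surplus path).
NO_DEMAND = float("inf")


@dataclass(frozen=True)
class ClimateDay:
    """One day of weather forcing.

    Attributes
    ----------
    day_index : 0-based day number.
    tmean : mean air temperature, degC.
    par : photosynthetically active radiation, MJ m-2 d-1.
    etp : reference evaporative demand, mm d-1.
    water_in : rain + irrigation, mm d-1.
    """

    day_index: int
    tmean: float
    par: float
    etp: float
    water_in: float = 0.0

    def __post_init__(self) -> None:
        if self.day_index < 0:
            raise ValueError("day_index must be >= 0")
        if self.par < 0 or self.etp < 0 or self.water_in < 0:
            raise ValueError("par, etp and water_in must be non-negative")


@dataclass(frozen=True)
class SoilBucket:
    """Single-layer soil water store.

    ``swc_fc`` is the content at field capacity, ``swc_min`` the content at
    which transpiration becomes negligible; their difference is the total
    transpirable soil water (TTSW).  The bucket is immutable; stepping it
    returns a new instance.
    """

    swc: float
    swc_fc: float
    swc_min: float = 0.0

    def __post_init__(self) -> None:
        if self.swc_fc <= self.swc_min:
            raise ValueError("swc_fc must exceed swc_min")
        if not (self.swc_min - 1e-12 <= self.swc <= self.swc_fc + 1e-12):
            raise ValueError("swc outside [swc_min, swc_fc]")

    @property
    def ttsw(self) -> float:
        return self.swc_fc - self.swc_min

    @property
    def ftsw(self) -> float:
        return compute_ftsw(self)

    def refilled(self) -> tuple["SoilBucket", float]:
        """Refill to field capacity; returns (new bucket, water added in mm)."""
        added = self.swc_fc - self.swc
        return replace(self, swc=self.swc_fc), added


@dataclass(frozen=True)
class CarbonBudget:
    """Daily whole-plant carbon bookkeeping (g CH2O plant-1).

    Satisfies ``supply + mobilized == growth_realized + stored + overflow``
    up to floating-point tolerance (checked by :meth:`check_conservation`).
    ``growth_realized`` is the carbon actually spent on demand (growth plus
    maintenance); ``deficit`` is the unmet part of demand.
    """

    supply: float
    demand: float
    ic: float
    reserve: float
    mobilized: float
    stored: float
    overflow: float
    growth_realized: float
    deficit: float

    def check_conservation(self, rtol: float = 1e-9) -> None:
        lhs = self.supply + self.mobilized
        rhs = self.growth_realized + self.stored + self.overflow
        scale = max(1.0, abs(lhs), abs(rhs))
        if abs(lhs - rhs) > rtol * scale:
            raise AssertionError(
                f"carbon budget not conserved: in={lhs!r} out={rhs!r}"
            )


class SoilStep(NamedTuple):
    bucket: SoilBucket
    transpiration: float
    drainage: float


def thermal_time_increment(tmean: float, tbase: float) -> float:
    """Daily effective temperature, max(0, tmean - tbase), in degCd."""
    return max(0.0, tmean - tbase)


def compute_ftsw(bucket: SoilBucket) -> float:
    """Fraction of transpirable soil water, clamped to [0, 1].

    FTSW = (SWC - SWC_min) / (SWC_fc - SWC_min), the ratio of actual to
    total plant-available soil water.
    """
    if bucket.swc_fc <= bucket.swc_min:
        raise ValueError("swc_fc must exceed swc_min")
    f = (bucket.swc - bucket.swc_min) / (bucket.swc_fc - bucket.swc_min)
    return min(1.0, max(0.0, f))


def stress_factor(ftsw: float, threshold: float) -> float:
    """Broken-stick drought response: V/Vmax as a function of FTSW.

    Returns 1 while FTSW is above the threshold, and FTSW/threshold below it
    (linear decline to 0 at FTSW = 0).  A threshold of 0 means the process is
    insensitive to drought and the factor is identically 1.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if threshold == 0.0 or ftsw > threshold:
        return 1.0
    return max(0.0, ftsw) / threshold


def intercept_fraction(lai: float, k: float) -> float:
    """Beer-Lambert canopy light interception: 1 - exp(-k * LAI)."""
    if lai < 0:
        raise ValueError("lai must be >= 0")
    if k <= 0:
        raise ValueError("k must be > 0")
    return 1.0 - math.exp(-k * lai)


def daily_supply(
    climate: ClimateDay,
    fint: float,
    rue: float,
    transp_stress: float,
    density: float,
) -> float:
    """Daily whole-plant assimilate supply, g CH2O plant-1.

    Intercepted PAR is converted with a radiation use efficiency and the
    stand-level assimilation is partitioned among plants by cropping density.
    Assimilation scales with the same broken-stick factor as transpiration
    (stomatal closure reduces both proportionally).
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    if min(fint, rue, transp_stress) < 0:
        raise ValueError("fint, rue and transp_stress must be >= 0")
    return climate.par * fint * rue * transp_stress / density


def index_of_competition(supply: float, demand: float) -> float:
    """Ic = supply / demand; returns the NO_DEMAND sentinel when demand is 0.

    The sentinel compares >= 1, so zero-demand days follow the surplus
    (store/overflow) path downstream.
    """
    if supply < 0:
        raise ValueError("supply must be >= 0")
    if demand == 0.0:
        return NO_DEMAND
    return supply / demand


def resolve_budget(
    supply: float,
    demand: float,
    reserve: float,
    storage_fraction: float,
    mobilization_fraction: float,
    reserve_capacity: float = math.inf,
) -> CarbonBudget:
    """Resolve the daily supply/demand balance against a single reserve pool.

    Surplus days (Ic >= 1): demand is fully met, a fraction of the excess is
    stored up to the remaining reserve capacity, the rest overflows (assimilate
    neither used nor stored is discarded from the daily supply).

    Deficit days (Ic < 1): a fraction of the reserve is mobilizable; as much
    of it as needed covers the gap.  Whatever remains unmet is reported as
    ``deficit`` for the caller (growth delay / senescence rules).
    """
    if min(supply, demand, reserve, storage_fraction, mobilization_fraction) < 0:
        raise ValueError("all budget inputs must be >= 0")
    if reserve > reserve_capacity + 1e-9:
        raise ValueError("reserve exceeds reserve_capacity")

    ic = index_of_competition(supply, demand)
    if ic >= 1.0:
        excess = supply - demand
        stored = min(storage_fraction * excess, reserve_capacity - reserve)
        return CarbonBudget(
            supply=supply,
            demand=demand,
            ic=ic,
            reserve=reserve + stored,
            mobilized=0.0,
            stored=stored,
            overflow=excess - stored,
            growth_realized=demand,
            deficit=0.0,
        )
    mobilizable = mobilization_fraction * reserve
    mobilized = min(mobilizable, demand - supply)
    growth = supply + mobilized
    return CarbonBudget(
        supply=supply,
        demand=demand,
        ic=ic,
        reserve=reserve - mobilized,
        mobilized=mobilized,
        stored=0.0,
        overflow=0.0,
        growth_realized=growth,
        deficit=demand - growth,
    )


def step_soil(
    bucket: SoilBucket,
    potential_transpiration: float,
    transp_threshold: float,
    water_in: float,
) -> SoilStep:
    """Advance the bucket one day.

    Actual transpiration is the potential demand scaled by the broken-stick
    factor at the morning FTSW, clamped so the bucket never drops below
    SWC_min.  Water input is added afterwards; anything above field capacity
    drains and is lost.
    """
    if potential_transpiration < 0:
        raise ValueError("potential_transpiration must be >= 0")
    if water_in < 0:
        raise ValueError("water_in must be >= 0")
    sf = stress_factor(compute_ftsw(bucket), transp_threshold)
    actual = min(potential_transpiration * sf, bucket.swc - bucket.swc_min)
    actual = max(0.0, actual)
    raw = bucket.swc - actual + water_in
    drainage = max(0.0, raw - bucket.swc_fc)
    new = replace(bucket, swc=min(bucket.swc_fc, raw))
    return SoilStep(new, actual, drainage)
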