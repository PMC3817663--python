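"""Oil palm vegetative growth with trunk/leaf NSC reserve dynamics.

A mono-axial perennial model: new leaves appear at a thermal-time production
rate (drought-sensitive through ``leaf_appearance_th``), each leaf expands
along a normalized sigmoid of thermal age toward a potential final area set
by plant age, and each leaf carries one internode growing toward a potential
volume.  Carbon demand prices potential growth through a chemical cost and
the structural end-members (``max_sla`` for leaves, ``min_dens`` for wood).

Reserves live in two kinds of pools: the trunk (bounded by a maximal NSC
concentration) and each leaf (the mass between its ``max_sla`` structural
skeleton and the ``min_sla`` fully-loaded state).  Surplus carbon is stored
proportionally to remaining pool capacity; shortfalls mobilize reserves in
proportion to each pool's offer (a mobilizable fraction weighted by filling
status).  Growth that can be financed neither by supply nor by reserves is
*postponed*, never cancelled: organ size shows no drought plasticity, only
delay.  Leaves die of thermal age, and drought accelerates aging below a
senescence threshold.  A constant reproductive demand stands in for bunch
growth so the analysis isolates vegetative source-sink regulation.

Per-leaf state is held in parallel numpy arrays for speed (factorial sweeps
run thousands of tree-years).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import (
    NO_DEMAND,
    CarbonBudget,
    daily_supply,
    index_of_competition,
    intercept_fraction,
    step_soil,
    stress_factor,
    thermal_time_increment,
)
from .scenarios import Scenario

__all__ = [
    "PalmGenotype",
    "PalmState",
    "allocate_surplus",
    "mobilize_reserves",
    "leaf_demand",
    "internode_demand",
    "nsc_concentration",
    "sigmoid_fraction",
    "simulate_palm",
    "PalmResult",
    "monthly_aggregates",
]

# Stress factors are floored when used as an aging divisor so a bone-dry day
# accelerates senescence at most this many fold.
_MAX_AGING_ACCEL = 20.0


@dataclass(frozen=True)
class PalmGenotype:
    """Genotypic parameters of the oil palm vegetative model."""

    prod_rate: float = 0.005  # leaves per degCd of effective temperature
    active_duration: float = 9000.0  # degCd of (stress-accelerated) leaf lifespan
    max_sla: float = 250.0  # cm2 g-1; SLA of the bare structural leaf
    min_sla: float = 150.0  # cm2 g-1; SLA when the leaf is reserve-saturated
    min_dens: float = 0.2  # g cm-3; structural wood density
    reserve_ratio_storage: float = 0.6  # share of daily excess sent to reserves
    max_nsc_content: float = 0.5  # g g-1; trunk NSC concentration ceiling
    leaf_appearance_th: float = 0.4  # FTSW threshold for leaf production
    transpiration_th: float = 0.4  # FTSW threshold for transpiration & assimilation
    senescence_drought_th: float = 0.25  # FTSW threshold accelerating leaf aging
    cost: float = 1.44  # g CH2O per g structural DM (growth respiration included)
    sigmoid_t50: float = 450.0  # degCd; inflection of the expansion sigmoid
    sigmoid_scale: float = 120.0  # degCd; sigmoid steepness scale
    leaf_area_max: float = 1.0e5  # cm2; adult potential final leaf area (10 m2)
    internode_volume_max: float = 6000.0  # cm3; adult potential internode volume
    age_ramp_tt: float = 15000.0  # degCd; saturation scale of the age ramps
    k: float = 0.5
    rue: float = 1.5  # g CH2O per MJ intercepted PAR
    tbase: float = 15.0  # degC
    reproductive_demand: float = 350.0  # g CH2O d-1, constant sink (adult bunch load)
    mob_frac: float = 0.1  # mobilizable fraction of a pool per day
    m_coef: float = 0.0008  # maintenance, g CH2O per g structural biomass per day

    def __post_init__(self) -> None:
        if not 0 < self.min_sla < self.max_sla:
            raise ValueError("need 0 < min_sla < max_sla")
        if not 0 < self.max_nsc_content < 1:
            raise ValueError("max_nsc_content must be in (0, 1)")
        if self.prod_rate <= 0:
            raise ValueError("prod_rate must be > 0")
        for name in ("leaf_appearance_th", "transpiration_th",
                     "senescence_drought_th", "reserve_ratio_storage"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    # Growth window: the normalized sigmoid is cut to exactly [0, 1] here.
    @property
    def expansion_end_tt(self) -> float:
        return self.sigmoid_t50 + 8.0 * self.sigmoid_scale

    def potential_leaf_area(self, plant_age_tt: float) -> float:
        return self.leaf_area_max * (1.0 - math.exp(-plant_age_tt / self.age_ramp_tt))

    def potential_internode_volume(self, plant_age_tt: float) -> float:
        return self.internode_volume_max * (
            1.0 - math.exp(-plant_age_tt / self.age_ramp_tt)
        )

    def leaf_reserve_capacity_per_area(self) -> float:
        """g of reserve a leaf can hold per cm2 of realized area."""
        return 1.0 / self.min_sla - 1.0 / self.max_sla


def sigmoid_fraction(age_tt, t50: float, scale: float) -> np.ndarray:
    """Normalized expansion sigmoid F(age): 0 at age 0, exactly 1 at the end
    of the growth window (t50 + 8 * scale), monotone logistic in between.

    Daily potential increments ``potential * (F(age + da) - F(age))`` sum to
    exactly the potential over any aging path that crosses the window.
    """
    age = np.asarray(age_tt, dtype=float)
    t_end = t50 + 8.0 * scale
    raw = 1.0 / (1.0 + np.exp(-(np.clip(age, 0.0, t_end) - t50) / scale))
    lo = 1.0 / (1.0 + math.exp(t50 / scale))
    hi = 1.0 / (1.0 + math.exp(-(t_end - t50) / scale))
    return (raw - lo) / (hi - lo)


def leaf_demand(d_area: float, cost: float, max_sla: float) -> float:
    """Carbon to grow ``d_area`` cm2 of leaf: structural mass (area over
    max_sla) times the chemical cost, g CH2O."""
    if d_area < 0 or cost <= 0 or max_sla <= 0:
        raise ValueError("need d_area >= 0 and positive cost and max_sla")
    return d_area * cost / max_sla


def internode_demand(d_volume: float, cost: float, min_dens: float) -> float:
    """Carbon to grow ``d_volume`` cm3 of internode: structural wood mass
    (volume times minimal density) times the chemical cost, g CH2O."""
    if d_volume < 0 or cost < 0 or min_dens < 0:
        raise ValueError("inputs must be non-negative")
    return d_volume * min_dens * cost


def nsc_concentration(structural_mass: float, reserve_mass: float) -> float:
    """Organ NSC concentration: reserve over total (structural + reserve) mass."""
    total = structural_mass + reserve_mass
    if total <= 0:
        raise ValueError("organ has zero total mass")
    return reserve_mass / total


def allocate_surplus(
    excess: float,
    reserves: np.ndarray,
    capacities: np.ndarray,
    reserve_ratio_storage: float,
) -> tuple[np.ndarray, float]:
    """Store a share of the daily excess across reserve pools.

    ``reserve_ratio_storage * excess`` is storable, capped by total remaining
    capacity and split proportionally to each pool's remaining headroom.
    Returns (per-pool additions, overflow).
    """
    if excess < 0:
        raise ValueError("excess must be >= 0")
    headroom = np.maximum(0.0, capacities - reserves)
    total_headroom = headroom.sum()
    storable = min(reserve_ratio_storage * excess, total_headroom)
    if storable <= 0 or total_headroom <= 0:
        return np.zeros_like(headroom), excess
    additions = storable * headroom / total_headroom
    return additions, excess - storable


def mobilize_reserves(
    shortfall: float,
    reserves: np.ndarray,
    capacities: np.ndarray,
    mob_frac: float,
) -> tuple[np.ndarray, float]:
    """Draw carbon from reserve pools to cover a shortfall.

    Each pool offers ``mob_frac * filling_status * reserve`` where the
    filling status is reserve over capacity; the draw is proportional to
    offers and never exceeds the shortfall.  Returns (per-pool draws, total
    mobilized).
    """
    if shortfall < 0:
        raise ValueError("shortfall must be >= 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        filling = np.where(capacities > 0, reserves / capacities, 0.0)
    offers = mob_frac * filling * reserves
    total_offer = offers.sum()
    if total_offer <= 0 or shortfall <= 0:
        return np.zeros_like(offers), 0.0
    mobilized = min(total_offer, shortfall)
    draws = mobilized * offers / total_offer
    return draws, mobilized


@dataclass
class PalmState:
    """Whole-tree state: parallel per-leaf arrays plus the trunk pools."""

    genotype: PalmGenotype
    plant_age_tt: float
    leaf_age: np.ndarray  # effective thermal age (drought-accelerated), degCd
    leaf_potential: np.ndarray  # cm2
    leaf_realized: np.ndarray  # cm2
    leaf_pending: np.ndarray  # cm2 of postponed expansion
    leaf_reserve: np.ndarray  # g
    leaf_alive: np.ndarray  # bool
    inode_age: np.ndarray  # degCd (calendar thermal age)
    inode_potential: np.ndarray  # cm3
    inode_realized: np.ndarray  # cm3
    inode_pending: np.ndarray  # cm3 postponed
    trunk_struct: float
    trunk_reserve: float
    appear_acc: float = 0.0

    @classmethod
    def establish(
        cls,
        genotype: PalmGenotype,
        plant_age_years: float = 10.0,
        mean_tt_per_day: float = 11.5,
        initial_trunk_nsc: float = 0.25,
        initial_leaf_fill: float = 0.3,
    ) -> "PalmState":
        """Build an adult tree with a steady-state canopy.

        Standing leaves are spaced 1/prod_rate degCd apart in age up to the
        active duration; each is as far along its expansion sigmoid as its
        age implies.  Trunk structural mass integrates the internodes of all
        leaves ever produced; trunk reserve is set from an initial NSC
        concentration.
        """
        g = genotype
        age_tt = plant_age_years * 365.0 * mean_tt_per_day
        n = int(g.active_duration * g.prod_rate)
        ages = (np.arange(n) + 0.5) / g.prod_rate  # youngest first
        potential = np.full(n, g.potential_leaf_area(age_tt))
        frac = sigmoid_fraction(ages, g.sigmoid_t50, g.sigmoid_scale)
        realized = potential * frac
        cap = realized * g.leaf_reserve_capacity_per_area()
        n_total = age_tt * g.prod_rate
        trunk_struct = n_total * g.potential_internode_volume(age_tt) * g.min_dens
        c = initial_trunk_nsc
        inode_pot = np.full(n, g.potential_internode_volume(age_tt))
        return cls(
            genotype=g,
            plant_age_tt=age_tt,
            leaf_age=ages,
            leaf_potential=potential,
            leaf_realized=realized,
            leaf_pending=np.zeros(n),
            leaf_reserve=initial_leaf_fill * cap,
            leaf_alive=np.ones(n, dtype=bool),
            inode_age=ages.copy(),
            inode_potential=inode_pot,
            inode_realized=inode_pot * frac,
            inode_pending=np.zeros(n),
            trunk_struct=trunk_struct,
            trunk_reserve=trunk_struct * c / (1.0 - c),
        )

    # -- aggregates ---------------------------------------------------------
    def green_leaf_area_cm2(self) -> float:
        return float(self.leaf_realized[self.leaf_alive].sum())

    def leaf_structural_mass(self) -> np.ndarray:
        return self.leaf_realized / self.genotype.max_sla

    def leaf_reserve_capacity(self) -> np.ndarray:
        return self.leaf_realized * self.genotype.leaf_reserve_capacity_per_area()

    def trunk_reserve_capacity(self) -> float:
        c = self.genotype.max_nsc_content
        return self.trunk_struct * c / (1.0 - c)

    def trunk_nsc(self) -> float:
        return nsc_concentration(self.trunk_struct, self.trunk_reserve)

    def leaf_count(self) -> int:
        return int(self.leaf_alive.sum())

    def total_reserve(self) -> float:
        return float(self.trunk_reserve + self.leaf_reserve[self.leaf_alive].sum())

    def check_invariants(self) -> None:
        g = self.genotype
        cap = self.leaf_reserve_capacity()
        if np.any(self.leaf_reserve[self.leaf_alive] > cap[self.leaf_alive] + 1e-6):
            raise AssertionError("leaf reserve exceeds min_sla capacity")
        if self.trunk_reserve > self.trunk_reserve_capacity() + 1e-6:
            raise AssertionError("trunk NSC above max_nsc_content")
        if np.any(self.leaf_realized > self.leaf_potential + 1e-6):
            raise AssertionError("leaf realized area above potential")

    # -- development --------------------------------------------------------
    def senesce(self, d_tt: float, ftsw: float) -> float:
        """Age leaves (drought accelerates aging below the senescence
        threshold); kill those past the active duration.  Returns the
        carbon lost with dying leaves (their residual reserve)."""
        g = self.genotype
        sf = stress_factor(ftsw, g.senescence_drought_th)
        aging = d_tt / max(sf, 1.0 / _MAX_AGING_ACCEL)
        self.leaf_age = self.leaf_age + aging
        self.inode_age = self.inode_age + d_tt
        dying = self.leaf_alive & (self.leaf_age >= g.active_duration)
        lost_reserve = float(self.leaf_reserve[dying].sum())
        self.leaf_reserve[dying] = 0.0
        self.leaf_alive = self.leaf_alive & ~dying
        return lost_reserve

    def produce_leaves(self, d_tt: float, ftsw: float) -> int:
        """Appearance accumulator gains prod_rate * d_tt, slowed by drought
        below leaf_appearance_th; one new leaf (and internode) per unit."""
        g = self.genotype
        sf = stress_factor(ftsw, g.leaf_appearance_th)
        self.appear_acc += g.prod_rate * d_tt * sf
        n_new = int(self.appear_acc)
        if n_new == 0:
            return 0
        self.appear_acc -= n_new
        area_pot = g.potential_leaf_area(self.plant_age_tt)
        vol_pot = g.potential_internode_volume(self.plant_age_tt)
        z = np.zeros(n_new)
        self.leaf_age = np.concatenate([self.leaf_age, z])
        self.leaf_potential = np.concatenate([self.leaf_potential, z + area_pot])
        self.leaf_realized = np.concatenate([self.leaf_realized, z])
        self.leaf_pending = np.concatenate([self.leaf_pending, z])
        self.leaf_reserve = np.concatenate([self.leaf_reserve, z])
        self.leaf_alive = np.concatenate([self.leaf_alive, np.ones(n_new, dtype=bool)])
        self.inode_age = np.concatenate([self.inode_age, z])
        self.inode_potential = np.concatenate([self.inode_potential, z + vol_pot])
        self.inode_realized = np.concatenate([self.inode_realized, z])
        self.inode_pending = np.concatenate([self.inode_pending, z])
        return n_new


PALM_COLUMNS = [
    "day", "ftsw", "swc", "lai", "fint", "d_tt", "sf_transp", "sf_appear",
    "supply", "veg_demand", "repro_demand", "maintenance", "demand", "ic",
    "mobilized", "stored", "overflow", "growth_realized", "deficit",
    "leaf_area_m2", "leaf_count", "trunk_nsc_gg", "trunk_reserve_g",
    "leaf_reserve_g", "transpiration_mm", "drainage_mm", "rain_mm",
    "irrigation_mm", "senesced_reserve_g",
]


@dataclass
class PalmResult:
    frame: pd.DataFrame
    state: PalmState
    budgets: list[CarbonBudget]


def simulate_palm(
    genotype: PalmGenotype,
    scenario: Scenario,
    state: PalmState | None = None,
    check_invariants_every: int = 1,
) -> PalmResult:
    """Run the palm model over a scenario; one row per day.

    Daily order: irrigation (if any) -> FTSW -> stress factors -> senescence
    -> leaf production -> potential growth and demand -> supply -> carbon
    resolution (store surplus / mobilize and postpone under shortage) ->
    soil step.
    """
    g = genotype
    if state is None:
        state = PalmState.establish(g)
    bucket = scenario.soil.make_bucket()
    density = scenario.density
    cap_per_area = g.leaf_reserve_capacity_per_area()

    rows = []
    budgets: list[CarbonBudget] = []
    for clim in scenario.weather:
        day = clim.day_index
        irrigation = 0.0
        target = scenario.irrigation.target_fill(day)
        if target is not None:
            goal = bucket.swc_min + target * bucket.ttsw
            if goal > bucket.swc:
                irrigation = goal - bucket.swc
                bucket = replace(bucket, swc=goal)

        ftsw = bucket.ftsw
        sf_transp = stress_factor(ftsw, g.transpiration_th)
        sf_appear = stress_factor(ftsw, g.leaf_appearance_th)
        d_tt = thermal_time_increment(clim.tmean, g.tbase)
        state.plant_age_tt += d_tt

        age_before = state.leaf_age.copy()
        inode_age_before = state.inode_age.copy()
        senesced_reserve = state.senesce(d_tt, ftsw)
        state.produce_leaves(d_tt, ftsw)
        # Newly produced organs enter the *_before arrays at age 0.
        n = state.leaf_age.size
        if age_before.size < n:
            pad = n - age_before.size
            age_before = np.concatenate([age_before, np.zeros(pad)])
            inode_age_before = np.concatenate([inode_age_before, np.zeros(pad)])

        # Potential growth increments for this day (sigmoid step + postponed).
        f0 = sigmoid_fraction(age_before, g.sigmoid_t50, g.sigmoid_scale)
        f1 = sigmoid_fraction(state.leaf_age, g.sigmoid_t50, g.sigmoid_scale)
        leaf_inc = np.where(
            state.leaf_alive, state.leaf_potential * (f1 - f0) + state.leaf_pending, 0.0
        )
        v0 = sigmoid_fraction(inode_age_before, g.sigmoid_t50, g.sigmoid_scale)
        v1 = sigmoid_fraction(state.inode_age, g.sigmoid_t50, g.sigmoid_scale)
        inode_inc = state.inode_potential * (v1 - v0) + state.inode_pending

        leaf_demand = leaf_inc * g.cost / g.max_sla
        inode_demand = inode_inc * g.min_dens * g.cost
        veg_demand = float(leaf_demand.sum() + inode_demand.sum())
        maintenance = g.m_coef * (
            float(state.leaf_structural_mass()[state.leaf_alive].sum())
            + state.trunk_struct
        )
        demand = veg_demand + g.reproductive_demand + maintenance

        area_cm2 = state.green_leaf_area_cm2()
        lai = area_cm2 * 1e-4 * density
        fint = intercept_fraction(lai, g.k)
        supply = daily_supply(clim, fint, g.rue, sf_transp, density)
        ic = index_of_competition(supply, demand)

        if ic >= 1.0:
            # Full growth; store a share of the excess across all pools.
            state.leaf_realized = state.leaf_realized + leaf_inc
            state.leaf_pending = np.zeros_like(state.leaf_pending)
            state.inode_realized = state.inode_realized + inode_inc
            state.inode_pending = np.zeros_like(state.inode_pending)
            state.trunk_struct += float(inode_inc.sum()) * g.min_dens
            reserves = np.concatenate([[state.trunk_reserve], state.leaf_reserve])
            caps = np.concatenate(
                [[state.trunk_reserve_capacity()],
                 np.where(state.leaf_alive, state.leaf_realized * cap_per_area, 0.0)]
            )
            additions, overflow = allocate_surplus(
                supply - demand, reserves, caps, g.reserve_ratio_storage
            )
            state.trunk_reserve += float(additions[0])
            state.leaf_reserve = state.leaf_reserve + additions[1:]
            stored = float(additions.sum())
            mobilized = 0.0
            growth_realized = demand
            deficit = 0.0
        else:
            shortfall = demand - supply
            reserves = np.concatenate([[state.trunk_reserve], state.leaf_reserve])
            caps = np.concatenate(
                [[state.trunk_reserve_capacity()],
                 np.where(state.leaf_alive, state.leaf_realized * cap_per_area, 0.0)]
            )
            draws, mobilized = mobilize_reserves(shortfall, reserves, caps, g.mob_frac)
            state.trunk_reserve -= float(draws[0])
            state.leaf_reserve = state.leaf_reserve - draws[1:]
            available = supply + mobilized
            maintenance_met = min(available, maintenance)
            rest = available - maintenance_met
            sink_demand = veg_demand + g.reproductive_demand
            ratio = rest / sink_demand if sink_demand > 0 else 0.0
            ratio = min(1.0, ratio)
            # Realized growth; the unmet part of leaf/internode growth is
            # postponed (pending), unmet reproduction and maintenance lost.
            state.leaf_realized = state.leaf_realized + leaf_inc * ratio
            state.leaf_pending = np.where(state.leaf_alive, leaf_inc * (1 - ratio), 0.0)
            state.inode_realized = state.inode_realized + inode_inc * ratio
            state.inode_pending = inode_inc * (1 - ratio)
            state.trunk_struct += float(inode_inc.sum()) * ratio * g.min_dens
            growth_realized = maintenance_met + ratio * sink_demand
            deficit = demand - growth_realized
            stored = 0.0
            overflow = 0.0

        budget = CarbonBudget(
            supply=supply,
            demand=demand,
            ic=ic,
            reserve=state.total_reserve(),
            mobilized=mobilized,
            stored=stored,
            overflow=overflow,
            growth_realized=growth_realized,
            deficit=deficit,
        )
        budget.check_conservation()
        budgets.append(budget)
        if check_invariants_every and day % check_invariants_every == 0:
            state.check_invariants()

        pot_transp = clim.etp * fint
        bucket, transp, drain = step_soil(
            bucket, pot_transp, g.transpiration_th, clim.water_in
        )

        rows.append(
            (
                day, ftsw, bucket.swc, lai, fint, d_tt, sf_transp, sf_appear,
                supply, veg_demand, g.reproductive_demand, maintenance, demand,
                ic if ic != NO_DEMAND else np.inf,
                mobilized, stored, overflow, growth_realized, deficit,
                area_cm2 * 1e-4, state.leaf_count(), state.trunk_nsc(),
                state.trunk_reserve, float(state.leaf_reserve[state.leaf_alive].sum()),
                transp, drain, clim.water_in, irrigation,
                senesced_reserve,
            )
        )

    frame = pd.DataFrame(rows, columns=PALM_COLUMNS)
    return PalmResult(frame=frame, state=state, budgets=budgets)


def monthly_aggregates(result: PalmResult) -> pd.DataFrame:
    """30-day aggregates: supply and demand in kg CH2O per tree per month,
    mean leaf area and end-of-month trunk NSC concentration."""
    f = result.frame.copy()
    f["month"] = f["day"] // 30
    out = f.groupby("month").agg(
        supply_kg=("supply", lambda s: s.sum() / 1000.0),
        demand_kg=("demand", lambda s: s.sum() / 1000.0),
        leaf_area_m2=("leaf_area_m2", "mean"),
        trunk_nsc_gg=("trunk_nsc_gg", "last"),
        ftsw_min=("ftsw", "min"),
    )
    return out.reset_index()
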