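"""Rice seedling morphogenesis driven by the daily carbon-water engine.

A meristem-centred model of vegetative rice growth: phytomers are initiated
on each axis at a thermal-time plastochron, every new leaf is pre-dimensioned
from its predecessor plus a meristem growth capacity (MGC), leaves extend at
a rate set by their potential final length over one plastochron, and areal
growth is priced into carbon through a rank-dependent structural specific
leaf area.  Tillering is gated by the whole-plant index of competition Ic;
carbon deficit accelerates leaf senescence and, if sustained, aborts the
youngest tiller.  Drought acts through FTSW on leaf expansion (LER_th) and
on transpiration and hence assimilation (Transpiration_th), via the shared
broken-stick response.

The model covers the vegetative phase only (no internode elongation, no
reproductive development); roots are a bulk compartment whose demand is a
fixed fraction of shoot growth demand.
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
    resolve_budget,
    step_soil,
    stress_factor,
    thermal_time_increment,
)
from .scenarios import Scenario

__all__ = [
    "RiceGenotype",
    "RiceLeaf",
    "RiceAxis",
    "RicePlantState",
    "schedule_initiation",
    "predimension_leaf",
    "daily_expansion",
    "structural_sla",
    "structural_demand",
    "simulate_rice",
    "RiceResult",
]


@dataclass(frozen=True)
class RiceGenotype:
    """Genotypic parameters of the rice seedling model.

    The three developmental parameters (``plasto``, ``mgc``, ``ict``) and the
    two drought-sensitivity thresholds (``ler_th``, ``transpiration_th``) are
    the traits under study; the rest set the carbon economy.
    """

    plasto: float = 50.0  # degCd; plastochron = phyllochron = leaf expansion duration
    mgc: float = 10.0  # cm; per-rank increment of potential final leaf length
    ict: float = 1.0  # Ic threshold above which a tiller bud activates
    ler_th: float = 0.4  # FTSW threshold for leaf expansion rate
    transpiration_th: float = 0.4  # FTSW threshold for transpiration & assimilation
    k: float = 0.5  # Beer-Lambert extinction coefficient
    rue: float = 3.5  # g CH2O per MJ intercepted PAR
    tbase: float = 12.0  # degC
    width_allometry: float = 0.05  # leaf width = width_allometry * length
    shape_factor: float = 0.725  # lanceolate blade: area = shape * length * width
    first_leaf_length: float = 5.0  # cm, potential final length of leaf 1
    cost: float = 1.4  # g CH2O per g structural DM (growth respiration included)
    root_demand_coef: float = 0.55  # root demand as fraction of shoot growth demand
    storage_fraction: float = 0.9  # share of daily excess stored in the reserve
    mobilization_fraction: float = 0.9  # share of reserve mobilizable per day
    sla_ref: float = 450.0  # cm2 g-1, structural SLA at rank 1 (young leaves are thin)
    sla_p: float = 0.30  # slope of the log-rank SLA relation
    cap_coef: float = 0.3  # reserve capacity per g structural biomass
    m_coef: float = 0.015  # g CH2O per g living structural biomass per day
    senescence_accel: float = 0.1  # fraction of green area lost per unit deficit ratio
    abort_after_days: int = 3  # consecutive deficit days before tiller abortion
    tiller_first_frac: float = 0.9  # tiller's first leaf size relative to parent's newest
    initial_reserve: float = 0.02  # g CH2O, seed starch store
    death_green_area_cm2: float = 0.25  # viability floor: below this the plant is dead

    def __post_init__(self) -> None:
        if self.plasto <= 0:
            raise ValueError("plasto must be > 0")
        if self.mgc < 0 or self.first_leaf_length <= 0:
            raise ValueError("mgc must be >= 0 and first_leaf_length > 0")
        for name in ("ler_th", "transpiration_th", "storage_fraction",
                     "mobilization_fraction", "root_demand_coef"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def leaf_area_from_length(self, length: float) -> float:
        """Allometric blade area (cm2): shape * length * (width_allometry * length)."""
        return self.shape_factor * self.width_allometry * length * length


def structural_sla(rank: int, sla_ref: float, sla_p: float) -> float:
    """Rank-dependent structural SLA: sla_ref * (1 + sla_p * ln(rank)).

    With ``sla_p > 0`` later leaves are cheaper per unit area.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    sla = sla_ref * (1.0 + sla_p * math.log(rank))
    if sla <= 0:
        raise ValueError(f"non-positive structural SLA at rank {rank}")
    return sla


def structural_demand(
    area_increment: float, rank: int, sla_ref: float, sla_p: float, cost: float = 1.0
) -> float:
    """Carbon demand (g CH2O) to build ``area_increment`` cm2 at a given rank:
    the new structural mass (area over the rank's SLA) times its chemical
    cost (growth respiration included)."""
    if area_increment < 0:
        raise ValueError("area_increment must be >= 0")
    return cost * area_increment / structural_sla(rank, sla_ref, sla_p)


def predimension_leaf(prev_final_length: float, mgc: float, ic: float) -> float:
    """Potential final length of the next leaf on an axis.

    The meristem adds MGC to the previous leaf's final length; when the plant
    is carbon-limited (Ic < 1) the *increment* is scaled by Ic, so sizes stay
    monotone (never below the previous final length).
    """
    if prev_final_length < 0 or mgc < 0 or ic < 0:
        raise ValueError("inputs must be >= 0")
    return prev_final_length + mgc * min(1.0, ic)


@dataclass
class RiceLeaf:
    """One leaf blade on one axis."""

    axis_id: int
    rank: int
    potential_final_length: float
    length: float = 0.0
    structural_mass: float = 0.0
    senesced_area: float = 0.0
    status: str = "expanding"  # expanding | mature | dead

    def area(self, genotype: RiceGenotype) -> float:
        return genotype.leaf_area_from_length(self.length)

    def green_area(self, genotype: RiceGenotype) -> float:
        if self.status == "dead":
            return 0.0
        return max(0.0, self.area(genotype) - self.senesced_area)


def daily_expansion(
    leaf: RiceLeaf,
    genotype: RiceGenotype,
    d_tt: float,
    ftsw: float,
) -> tuple[float, float]:
    """Potential (length, area) increments of an expanding leaf for one day.

    LER is potential final length over one plastochron of thermal time,
    down-regulated by the broken-stick FTSW response at ``ler_th``; length
    never exceeds the pre-dimensioned potential.
    """
    if leaf.status != "expanding":
        return 0.0, 0.0
    sf = stress_factor(ftsw, genotype.ler_th)
    dl = (leaf.potential_final_length / genotype.plasto) * d_tt * sf
    dl = min(dl, leaf.potential_final_length - leaf.length)
    new_area = genotype.leaf_area_from_length(leaf.length + dl)
    return dl, new_area - leaf.area(genotype)


@dataclass
class RiceAxis:
    """Main stem or tiller: its own thermal clock and leaf sequence."""

    axis_id: int
    thermal_time: float = 0.0
    initiated: int = 0
    leaves: list[RiceLeaf] = field(default_factory=list)
    alive: bool = True
    first_leaf_length: float | None = None  # None: genotype default


def schedule_initiation(axis: RiceAxis, d_tt: float, plasto: float) -> int:
    """Advance the axis clock; return how many new phytomers it initiates.

    A phytomer appears each time cumulated thermal time crosses a multiple of
    the plastochron, so an axis at thermal time T carries floor(T / plasto)
    phytomers.
    """
    if d_tt < 0:
        raise ValueError("d_tt must be >= 0")
    before = math.floor(axis.thermal_time / plasto)
    axis.thermal_time += d_tt
    after = math.floor(axis.thermal_time / plasto)
    return after - before


@dataclass
class RicePlantState:
    """Whole plant: axes, reserve pool, bulk root mass, life flag."""

    genotype: RiceGenotype
    axes: list[RiceAxis] = field(default_factory=list)
    reserve: float = 0.0
    root_mass: float = 0.0
    alive: bool = True
    ic_prev: float = 1.0
    deficit_streak: int = 0
    _next_axis_id: int = 0

    @classmethod
    def germinate(cls, genotype: RiceGenotype) -> "RicePlantState":
        state = cls(genotype=genotype, reserve=genotype.initial_reserve)
        state._new_axis()  # main stem
        return state

    def _new_axis(self) -> RiceAxis:
        axis = RiceAxis(axis_id=self._next_axis_id)
        self._next_axis_id += 1
        self.axes.append(axis)
        return axis

    # -- aggregates ---------------------------------------------------------
    def living_leaves(self) -> list[RiceLeaf]:
        return [
            lf
            for ax in self.axes
            if ax.alive
            for lf in ax.leaves
            if lf.status != "dead"
        ]

    def green_area(self) -> float:
        g = self.genotype
        return sum(lf.green_area(g) for lf in self.living_leaves())

    def green_biomass(self) -> float:
        """Structural mass of living leaves, weighted by their green fraction."""
        g = self.genotype
        total = 0.0
        for lf in self.living_leaves():
            area = lf.area(g)
            if area > 0:
                total += lf.structural_mass * lf.green_area(g) / area
        return total

    def structural_biomass(self) -> float:
        """All shoot structural mass ever built (green + senesced + dead)."""
        return sum(lf.structural_mass for ax in self.axes for lf in ax.leaves)

    def leaf_count(self) -> int:
        return len(self.living_leaves())

    def tiller_count(self) -> int:
        return sum(1 for ax in self.axes if ax.alive and ax.axis_id != 0)

    def reserve_capacity(self) -> float:
        g = self.genotype
        return g.initial_reserve + g.cap_coef * (self.structural_biomass() + self.root_mass)

    # -- development --------------------------------------------------------
    def develop(self, d_tt: float) -> None:
        """Initiate phytomers on every axis; new phytomer events may recruit
        one tiller bud each when the previous day's Ic exceeded Ict."""
        g = self.genotype
        for axis in list(self.axes):
            if not axis.alive:
                continue
            for _ in range(schedule_initiation(axis, d_tt, g.plasto)):
                if axis.leaves:
                    prev = axis.leaves[-1].potential_final_length
                    pot = predimension_leaf(prev, g.mgc, self.ic_prev)
                else:
                    pot = (
                        axis.first_leaf_length
                        if axis.first_leaf_length is not None
                        else g.first_leaf_length
                    )
                axis.leaves.append(
                    RiceLeaf(
                        axis_id=axis.axis_id,
                        rank=len(axis.leaves) + 1,
                        potential_final_length=pot,
                    )
                )
                if self.ic_prev > g.ict:
                    tiller = self._new_axis()
                    # A tiller bud emerges with a first leaf pre-dimensioned
                    # near its parent's current leaf size.
                    tiller.first_leaf_length = max(
                        g.first_leaf_length, g.tiller_first_frac * pot
                    )

    def apply_deficit(self, deficit: float, demand: float) -> float:
        """Deficit-driven senescence and tiller abortion; returns area lost.

        Green area senesces at ``senescence_accel * (deficit / demand)`` per
        day, oldest leaves first; after ``abort_after_days`` consecutive
        deficit days the youngest tiller aborts.  The plant dies when no
        green area remains.  Senescence removes green area, not accumulated
        structural mass.
        """
        g = self.genotype
        if deficit <= 1e-12 or demand <= 0:
            self.deficit_streak = 0
            return 0.0
        self.deficit_streak += 1
        to_lose = g.senescence_accel * (deficit / demand) * self.green_area()
        lost = 0.0
        # Oldest first: axis creation order, then rank.
        for axis in self.axes:
            if not axis.alive:
                continue
            for lf in axis.leaves:
                if to_lose <= lost + 1e-15:
                    break
                green = lf.green_area(g)
                if green <= 0:
                    continue
                take = min(green, to_lose - lost)
                lf.senesced_area += take
                lost += take
                if lf.green_area(g) <= 1e-12 and lf.length > 0:
                    lf.status = "dead"
        if self.deficit_streak >= g.abort_after_days:
            tillers = [ax for ax in self.axes if ax.alive and ax.axis_id != 0]
            if tillers:
                youngest = tillers[-1]
                youngest.alive = False
                for lf in youngest.leaves:
                    lf.status = "dead"
        if self.green_area() <= g.death_green_area_cm2:
            self.alive = False
        return lost


TRAJECTORY_COLUMNS = [
    "day", "ftsw", "swc", "lai", "fint", "d_tt", "sf_ler", "sf_transp",
    "supply", "demand", "ic", "reserve", "mobilized", "stored", "overflow",
    "growth_realized", "deficit", "green_area_cm2", "green_biomass_g",
    "structural_biomass_g", "root_mass_g", "leaf_count", "tiller_count",
    "alive", "transpiration_mm", "drainage_mm", "irrigation_mm", "rain_mm",
]


@dataclass
class RiceResult:
    """Daily trajectory plus the final plant state."""

    frame: pd.DataFrame
    state: RicePlantState
    budgets: list[CarbonBudget]


def simulate_rice(genotype: RiceGenotype, scenario: Scenario) -> RiceResult:
    """Run the rice seedling model over a scenario; one row per day.

    Daily order: morning irrigation -> FTSW -> stress factors -> development
    (with yesterday's Ic) -> expansion potentials and demand -> supply -> Ic
    and carbon budget -> realized growth -> deficit response -> soil step.
    """
    g = genotype
    state = RicePlantState.germinate(g)
    bucket = scenario.soil.make_bucket()
    footprint = scenario.soil.footprint_m2
    density = scenario.density

    rows = []
    budgets: list[CarbonBudget] = []
    for clim in scenario.weather:
        day = clim.day_index
        # Morning irrigation per policy.
        irrigation = 0.0
        target = scenario.irrigation.target_fill(day)
        if target is not None:
            goal = bucket.swc_min + target * bucket.ttsw
            if goal > bucket.swc:
                irrigation = goal - bucket.swc
                bucket = replace(bucket, swc=goal)

        ftsw = bucket.ftsw
        sf_ler = stress_factor(ftsw, g.ler_th)
        sf_transp = stress_factor(ftsw, g.transpiration_th)
        d_tt = thermal_time_increment(clim.tmean, g.tbase)

        morning_area = state.green_area()  # cm2; used for fint and transpiration
        lai = morning_area * 1e-4 * density
        fint = intercept_fraction(lai, g.k)

        if state.alive:
            state.develop(d_tt)

            # Potential expansion and carbon demand.
            expanding = [lf for lf in state.living_leaves() if lf.status == "expanding"]
            increments: list[tuple[RiceLeaf, float, float]] = []
            shoot_growth_demand = 0.0
            for lf in expanding:
                dl, da = daily_expansion(lf, g, d_tt, ftsw)
                increments.append((lf, dl, da))
                shoot_growth_demand += structural_demand(da, lf.rank, g.sla_ref, g.sla_p, g.cost)
            root_growth_demand = g.root_demand_coef * shoot_growth_demand
            maintenance = g.m_coef * (state.green_biomass() + state.root_mass)
            demand = shoot_growth_demand + root_growth_demand + maintenance

            supply = daily_supply(clim, fint, g.rue, sf_transp, density)
            budget = resolve_budget(
                supply, demand, state.reserve,
                g.storage_fraction, g.mobilization_fraction,
                state.reserve_capacity(),
            )
            budget.check_conservation()
            budgets.append(budget)
            state.reserve = budget.reserve

            # Maintenance has priority; remaining realized carbon scales growth.
            maintenance_met = min(budget.growth_realized, maintenance)
            growth_carbon = budget.growth_realized - maintenance_met
            growth_demand = shoot_growth_demand + root_growth_demand
            ratio = growth_carbon / growth_demand if growth_demand > 0 else 0.0
            ratio = min(1.0, ratio)
            for lf, dl, _ in increments:
                if dl <= 0 and lf.length >= lf.potential_final_length - 1e-9:
                    lf.status = "mature"
                    continue
                old_area = lf.area(g)
                lf.length = min(lf.potential_final_length, lf.length + dl * ratio)
                lf.structural_mass += structural_demand(
                    lf.area(g) - old_area, lf.rank, g.sla_ref, g.sla_p
                )  # dry matter, not CH2O: cost excluded
                if lf.length >= lf.potential_final_length - 1e-9:
                    lf.status = "mature"
            state.root_mass += root_growth_demand * ratio / g.cost

            state.apply_deficit(budget.deficit, demand)
            state.ic_prev = min(budget.ic, 1e6)  # cap the no-demand sentinel
        else:
            supply = demand = 0.0
            budget = resolve_budget(0.0, 0.0, state.reserve, 0.0, 0.0,
                                    max(state.reserve, state.reserve_capacity()))
            budgets.append(budget)

        # Water: evaporative demand on the plant's ground share, as depth
        # over the pot footprint (canopy energy cap, not leaf-area demand).
        pot_transp = (
            clim.etp * fint / (density * footprint) if state.alive else 0.0
        )
        bucket, transp, drain = step_soil(
            bucket, pot_transp, g.transpiration_th, clim.water_in
        )

        rows.append(
            (
                day, ftsw, bucket.swc, lai, fint, d_tt, sf_ler, sf_transp,
                budget.supply, budget.demand,
                budget.ic if budget.ic != NO_DEMAND else np.inf,
                state.reserve, budget.mobilized, budget.stored, budget.overflow,
                budget.growth_realized, budget.deficit,
                state.green_area(), state.green_biomass(),
                state.structural_biomass(), state.root_mass,
                state.leaf_count(), state.tiller_count(), state.alive,
                transp, drain, irrigation, clim.water_in,
            )
        )

    frame = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return RiceResult(frame=frame, state=state, budgets=budgets)
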