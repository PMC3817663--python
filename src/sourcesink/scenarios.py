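"""Scenario factory: synthetic weather, soil and irrigation configurations.

Builds the simulation experiments the analysis needs without any external
data: a constant greenhouse climate for rice seedlings with two dry-down
variants, and a two-season tropical climate for oil palm whose January-April
dry-season water deficit (precipitation minus evaporative demand) is tunable.

All generated series are deterministic functions of their parameters and a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .engine import SoilBucket
from .weather import WeatherSeries

__all__ = [
    "IrrigationPolicy",
    "SoilConfig",
    "Scenario",
    "soil_from_config",
    "rice_constant_climate",
    "rice_drought_scenario",
    "palm_seasonal_climate",
    "palm_field_scenario",
    "RICE_PAR",
    "RICE_TMEAN",
    "RICE_ETP",
]

# Rice greenhouse forcing: averages of the glasshouse records the rice
# simulations are anchored to.
RICE_PAR = 7.6  # MJ m-2 d-1
RICE_TMEAN = 25.4  # degC
RICE_ETP = 1.85  # mm d-1

# Day-of-year (0-based) on which the palm series starts: 1 May, so that a
# two-year run spans two complete Jan-Apr dry seasons.
_PALM_START_DOY = 120
_DRY_SEASON_DAYS = 120  # Jan 1 .. Apr 30


@dataclass(frozen=True)
class IrrigationPolicy:
    """How the simulator tops up the soil bucket each morning.

    kind:
      * ``none`` - rainfed; only the weather's ``water_in`` enters the soil.
      * ``refill_until`` - refill to field capacity every morning up to (but
        not including) ``switch_day``, then stop (dry-down semantics).
      * ``maintain_fraction`` - refill to ``fraction`` of TTSW every morning
        for the whole run (greenhouse control semantics).
    """

    kind: Literal["none", "refill_until", "maintain_fraction"] = "none"
    switch_day: int | None = None
    fraction: float = 1.0

    def target_fill(self, day: int) -> float | None:
        """Morning refill target as a fraction of TTSW, or None for no refill."""
        if self.kind == "none":
            return None
        if self.kind == "refill_until":
            if self.switch_day is None:
                raise ValueError("refill_until policy needs switch_day")
            return 1.0 if day < self.switch_day else None
        return self.fraction


@dataclass(frozen=True)
class SoilConfig:
    """Bucket geometry: TTSW depth, initial fill, and the footprint the
    depth refers to (pot footprint for pot experiments; per-m2 for fields)."""

    ttsw_mm: float
    initial_fill: float = 1.0
    footprint_m2: float = 1.0

    def make_bucket(self) -> SoilBucket:
        return soil_from_config(self.ttsw_mm, self.initial_fill)


@dataclass(frozen=True)
class Scenario:
    """A complete simulation setting: forcing + soil + irrigation + stand."""

    name: str
    weather: WeatherSeries
    soil: SoilConfig
    irrigation: IrrigationPolicy
    density: float  # plants m-2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if (
            self.irrigation.kind == "refill_until"
            and self.irrigation.switch_day is not None
            and self.irrigation.switch_day > len(self.weather)
        ):
            raise ValueError("irrigation switch day beyond scenario duration")

    @property
    def duration(self) -> int:
        return len(self.weather)


def soil_from_config(ttsw_mm: float, initial_fill: float) -> SoilBucket:
    """Zero-offset bucket: swc_min = 0, swc_fc = TTSW, swc = fill * TTSW."""
    if ttsw_mm <= 0:
        raise ValueError("ttsw_mm must be > 0")
    if not 0.0 <= initial_fill <= 1.0:
        raise ValueError("initial_fill must be in [0, 1]")
    return SoilBucket(swc=initial_fill * ttsw_mm, swc_fc=ttsw_mm, swc_min=0.0)


def rice_constant_climate(
    days: int,
    par: float = RICE_PAR,
    tmean: float = RICE_TMEAN,
    etp: float = RICE_ETP,
) -> WeatherSeries:
    """Constant greenhouse climate for rice seedling runs."""
    if days <= 0:
        raise ValueError("days must be > 0")
    return WeatherSeries.build(
        tmean_c=np.full(days, tmean),
        par_mj_m2=np.full(days, par),
        etp_mm=np.full(days, etp),
        water_in_mm=np.zeros(days),
    )


def rice_drought_scenario(
    kind: Literal["short_severe", "long_moderate"],
    ttsw_mm: float = 30.0,
    pot_footprint_m2: float = 0.01,
    etp_dry: float | None = None,
) -> Scenario:
    """The two rice dry-down experiments.

    20 days well-watered (daily refill to field capacity), then watering
    stops: either an 11-day dry-down at full evaporative demand (1.85 mm,
    ``short_severe``) or a 21-day dry-down at reduced demand (0.9 mm,
    ``long_moderate``).  TTSW is depth over the pot footprint (30 mm =
    300 cm3 transpirable water in a 1-litre pot, which reproduces the
    observed dry-down pace: FTSW ~0.2 after 11 unthrottled days).
    """
    wet_days = 20
    if kind == "short_severe":
        dry_days, default_etp = 11, 1.85
    elif kind == "long_moderate":
        dry_days, default_etp = 21, 0.9
    else:
        raise ValueError(f"unknown rice drought kind: {kind!r}")
    etp_dry = default_etp if etp_dry is None else etp_dry
    n = wet_days + dry_days
    etp = np.full(n, RICE_ETP)
    etp[wet_days:] = etp_dry
    weather = WeatherSeries.build(
        tmean_c=np.full(n, RICE_TMEAN),
        par_mj_m2=np.full(n, RICE_PAR),
        etp_mm=etp,
        water_in_mm=np.zeros(n),
    )
    return Scenario(
        name=f"rice_{kind}",
        weather=weather,
        soil=SoilConfig(ttsw_mm=ttsw_mm, initial_fill=1.0, footprint_m2=pot_footprint_m2),
        irrigation=IrrigationPolicy(kind="refill_until", switch_day=wet_days),
        density=30.0,
        meta={"wet_days": wet_days, "dry_days": dry_days, "etp_dry": etp_dry},
    )


def _seasonal(doy: np.ndarray, mean: float, amplitude: float, peak_doy: float) -> np.ndarray:
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.0)


def palm_seasonal_climate(
    years: int,
    dry_season_deficit_mm: float | Sequence[float] = -179.0,
    seed: int = 0,
    start_doy: int = _PALM_START_DOY,
) -> WeatherSeries:
    """Two-season tropical climate with a calibrated Jan-Apr water deficit.

    Evaporative demand and temperature follow smooth seasonal curves peaking
    in the dry season; rainfall arrives as pulses (every 3rd day in the wet
    season, every 5th in the dry season).  Dry-season pulse amounts are
    rescaled so that sum(rain - etp) over each Jan-Apr window equals the
    requested deficit exactly; wet-season pulses give every wet month a
    positive water balance.

    ``dry_season_deficit_mm`` may be a scalar (same every year) or one value
    per dry-season window contained in the series.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    n = years * 365
    abs_day = start_doy + np.arange(n)
    doy = abs_day % 365

    etp = _seasonal(doy, mean=4.0, amplitude=0.8, peak_doy=60.0)
    tmean = _seasonal(doy, mean=26.5, amplitude=1.0, peak_doy=60.0)
    par = _seasonal(doy, mean=8.5, amplitude=1.5, peak_doy=60.0)

    dry_mask = doy < _DRY_SEASON_DAYS
    # Contiguous dry-season windows, in order of appearance.
    edges = np.flatnonzero(np.diff(np.concatenate(([0], dry_mask.view(np.int8), [0]))))
    windows = list(zip(edges[0::2], edges[1::2]))

    deficits = np.atleast_1d(np.asarray(dry_season_deficit_mm, dtype=float))
    if deficits.size == 1:
        deficits = np.repeat(deficits, len(windows))
    if deficits.size != len(windows):
        raise ValueError(
            f"need one deficit per dry season ({len(windows)}), got {deficits.size}"
        )

    rng = np.random.default_rng(seed)
    rain = np.zeros(n)

    # Wet season: a pulse every 3rd day, mean 18 mm -> ~6 mm d-1 against
    # ~3.5 mm d-1 demand, so every wet month has a positive balance.
    wet_pulse = (~dry_mask) & (abs_day % 3 == 0)
    rain[wet_pulse] = 18.0 * rng.uniform(0.7, 1.3, wet_pulse.sum())

    for (start, stop), deficit in zip(windows, deficits):
        if deficit > 0:
            raise ValueError(
                f"dry-season deficit must be <= 0 mm, got {deficit}"
            )
        idx = np.arange(start, stop)
        etp_sum = etp[idx].sum()
        target = etp_sum + deficit
        if target < 0:
            raise ValueError(
                f"infeasible deficit {deficit} mm: exceeds the window's "
                f"total evaporative demand ({etp_sum:.0f} mm)"
            )
        pulse_idx = idx[abs_day[idx] % 5 == 0]
        weights = rng.uniform(0.5, 1.5, pulse_idx.size)
        rain[pulse_idx] = target * weights / weights.sum()

    return WeatherSeries.build(
        tmean_c=tmean, par_mj_m2=par, etp_mm=etp, water_in_mm=rain
    )


def palm_field_scenario(
    dry_season_deficit_mm: float | Sequence[float] = (-179.0, -2.0),
    years: int = 2,
    seed: int = 0,
    ttsw_mm: float = 150.0,
    initial_fill: float = 1.0,
    density: float = 0.0143,
) -> Scenario:
    """Rainfed oil palm stand (143 trees ha-1) under the seasonal climate."""
    weather = palm_seasonal_climate(years, dry_season_deficit_mm, seed=seed)
    deficits = np.atleast_1d(np.asarray(dry_season_deficit_mm, dtype=float))
    return Scenario(
        name="palm_field",
        weather=weather,
        soil=SoilConfig(ttsw_mm=ttsw_mm, initial_fill=initial_fill),
        irrigation=IrrigationPolicy(kind="none"),
        density=density,
        meta={"deficits_mm": deficits.tolist(), "seed": seed},
    )


def palm_sweep_scenario(
    dry_season_deficit_mm: float = -179.0,
    seed: int = 0,
    recovery_days: int = 182,
    ttsw_mm: float = 150.0,
    density: float = 0.0143,
) -> Scenario:
    """Single dry season of chosen severity plus a recovery period.

    An 18-month run (May start): eight wet months, one Jan-Apr dry season at
    the requested deficit, then ``recovery_days`` of wet season so that
    slow after-effects of the drought (canopy loss, reserve refill) register
    in end-of-run responses.  This is the scenario the threshold sweeps use.
    """
    full = palm_seasonal_climate(2, (dry_season_deficit_mm, -100.0), seed=seed)
    n = 245 + _DRY_SEASON_DAYS + recovery_days
    weather = WeatherSeries(full.frame.iloc[:n])
    return Scenario(
        name=f"palm_sweep_{dry_season_deficit_mm:+.0f}mm",
        weather=weather,
        soil=SoilConfig(ttsw_mm=ttsw_mm, initial_fill=1.0),
        irrigation=IrrigationPolicy(kind="none"),
        density=density,
        meta={"deficit_mm": dry_season_deficit_mm, "seed": seed},
    )


def dry_season_balance(weather: WeatherSeries) -> list[float]:
    """Sum(rain - etp) over each Jan-Apr window of a palm series (for checks)."""
    frame = weather.frame
    doy = (_PALM_START_DOY + frame["day"].to_numpy()) % 365
    dry = doy < _DRY_SEASON_DAYS
    edges = np.flatnonzero(np.diff(np.concatenate(([0], dry.view(np.int8), [0]))))
    out = []
    for start, stop in zip(edges[0::2], edges[1::2]):
        block = frame.iloc[start:stop]
        out.append(float((block["water_in_mm"] - block["etp_mm"]).sum()))
    return out
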