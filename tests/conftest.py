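import numpy as np
import pytest

from sourcesink.engine import SoilBucket
from sourcesink.palm import PalmGenotype
from sourcesink.rice import RiceGenotype
from sourcesink.scenarios import (
    IrrigationPolicy,
    Scenario,
    SoilConfig,
    rice_drought_scenario,
)
from sourcesink.weather import WeatherSeries


@pytest.fixture
def rice_genotype():
    return RiceGenotype()


@pytest.fixture
def palm_genotype():
    return PalmGenotype()


@pytest.fixture
def short_severe():
    return rice_drought_scenario("short_severe")


@pytest.fixture
def long_moderate():
    return rice_drought_scenario("long_moderate")


def constant_weather(days, tmean=26.5, par=8.5, etp=4.0, rain=0.0):
    return WeatherSeries.build(
        tmean_c=np.full(days, float(tmean)),
        par_mj_m2=np.full(days, float(par)),
        etp_mm=np.full(days, float(etp)),
        water_in_mm=np.full(days, float(rain)),
    )


def irrigated_scenario(days, density, ttsw=150.0, footprint=1.0, **weather_kw):
    """Permanently well-watered: refilled to field capacity every morning."""
    return Scenario(
        name="irrigated",
        weather=constant_weather(days, **weather_kw),
        soil=SoilConfig(ttsw_mm=ttsw, initial_fill=1.0, footprint_m2=footprint),
        irrigation=IrrigationPolicy(kind="maintain_fraction", fraction=1.0),
        density=density,
    )


def rainfed_scenario(weather, density, ttsw=150.0, initial_fill=1.0, footprint=1.0):
    return Scenario(
        name="rainfed",
        weather=weather,
        soil=SoilConfig(ttsw_mm=ttsw, initial_fill=initial_fill, footprint_m2=footprint),
        irrigation=IrrigationPolicy(kind="none"),
        density=density,
    )


def bucket(swc, fc=50.0, mn=10.0):
    return SoilBucket(swc=swc, swc_fc=fc, swc_min=mn)
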