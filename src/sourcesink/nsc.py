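"""Non-structural carbohydrate (NSC) data computations.

Utilities for the greenhouse measurements that anchor the simulation study:
sugar composition shares of an organ (hexose / sucrose / starch as percent
of total NSC), stressed-vs-control relative variation, whole-plant NSC
concentration from organ dry weights, and normalized transpiration
(Tr_norm) from daily pot-weighing series.

A reference table of organ NSC concentrations at dry-down onset (rice IR64
mature and young leaves; oil palm G01 mature leaf and trunk, mg per g dry
weight) ships with the package.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUGARS",
    "load_reference_table",
    "composition_shares",
    "relative_variation",
    "whole_plant_nsc",
    "tr_norm",
]

SUGARS = ("hexose", "sucrose", "starch")


def load_reference_table() -> pd.DataFrame:
    """Organ NSC concentrations (mg g-1 DW) at dry-down onset.

    Hexose is a pooled column (glucose + fructose).  Columns: species,
    organ, treatment, hexose_mg_g, sucrose_mg_g, starch_mg_g.
    """
    with resources.files("sourcesink.data").joinpath("table1_nsc.csv").open() as fh:
        return pd.read_csv(fh)


def composition_shares(
    hexose: float, sucrose: float, starch: float, decimals: int = 1
) -> dict[str, float]:
    """Percent of total NSC contributed by each sugar, rounded to one
    decimal (round-half-even); shares sum to 100 up to rounding."""
    values = np.array([hexose, sucrose, starch], dtype=float)
    if np.any(values < 0):
        raise ValueError("concentrations must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("total NSC must be positive")
    shares = 100.0 * values / total
    return {s: round(float(v), decimals) for s, v in zip(SUGARS, shares)}


def relative_variation(stressed_value: float, control_value: float) -> float:
    """(stressed - control) / control: the relative change under stress."""
    if control_value <= 0:
        raise ValueError("control_value must be positive")
    return (stressed_value - control_value) / control_value


def whole_plant_nsc(
    organs: Iterable[tuple[float, float]], shoot_dry_weight: float
) -> float:
    """Whole-plant NSC concentration from organ (dry_weight, concentration)
    pairs: sum of organ NSC dry weights over shoot dry weight.

    Concentration units are preserved (mg g-1 in, mg g-1 out).
    """
    if shoot_dry_weight <= 0:
        raise ValueError("shoot_dry_weight must be positive")
    total = 0.0
    for dw, conc in organs:
        if dw < 0:
            raise ValueError("organ dry weights must be non-negative")
        total += dw * conc
    return total / shoot_dry_weight


def tr_norm(series: pd.DataFrame) -> pd.DataFrame:
    """Normalized transpiration from a pot-weighing series.

    ``series`` is tidy with columns ``plant_id, group, day, pot_weight_g,
    leaf_area_m2`` where group is ``control`` or ``stressed``.  Daily
    transpiration of a plant is the pot weight loss between consecutive
    days (assigned to the first day); the per-leaf-area rate is divided by
    the mean control rate of the same day.  Days where a plant gains weight
    (watering events) are flagged and excluded from that plant's series.

    Returns one row per (plant, day) with columns ``transpiration_g``,
    ``rate_g_m2``, ``tr_norm`` and ``excluded``.
    """
    required = {"plant_id", "group", "day", "pot_weight_g", "leaf_area_m2"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series missing columns: {sorted(missing)}")
    if not set(series["group"]).issubset({"control", "stressed"}):
        raise ValueError("group must be 'control' or 'stressed'")

    frames = []
    for plant_id, sub in series.sort_values("day").groupby("plant_id"):
        days = sub["day"].to_numpy()
        if len(days) < 2 or np.any(np.diff(days) != 1):
            raise ValueError(
                f"plant {plant_id!r}: need consecutive daily weighings"
            )
        loss = -np.diff(sub["pot_weight_g"].to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "plant_id": plant_id,
                    "group": sub["group"].iloc[0],
                    "day": days[:-1],
                    "transpiration_g": loss,
                    "leaf_area_m2": sub["leaf_area_m2"].to_numpy()[:-1],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["excluded"] = out["transpiration_g"] < 0
    out["rate_g_m2"] = np.where(
        out["excluded"], np.nan, out["transpiration_g"] / out["leaf_area_m2"]
    )

    control_mean = (
        out[(out["group"] == "control") & ~out["excluded"]]
        .groupby("day")["rate_g_m2"]
        .mean()
    )
    if control_mean.empty or (control_mean <= 0).any():
        raise ValueError("need at least one positive control rate per day")
    days_with_data = out["day"].unique()
    missing_ctrl = set(days_with_data) - set(control_mean.index)
    if missing_ctrl:
        raise ValueError(f"no control plant on days {sorted(missing_ctrl)}")
    out["tr_norm"] = out["rate_g_m2"] / out["day"].map(control_mean)
    return out
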