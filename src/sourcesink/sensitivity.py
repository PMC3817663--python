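"""Factorial sensitivity analysis of drought-sensitivity thresholds.

The computational experiment at the heart of the analysis: vary two FTSW
threshold parameters of a crop model on a full factorial grid (one
deterministic simulation per cell), then decompose the variance of a scalar
response into the two main effects and their interaction with a two-way
ANOVA, and locate the response optimum on the grid.

With a single replicate per cell (the simulators are deterministic) the
residual sum of squares of the two-way ANOVA is identically the interaction
sum of squares, so the decomposition is closed-form:

    SS_A  = n_b * sum_i (mean_i. - mean)^2
    SS_B  = n_a * sum_j (mean_.j - mean)^2
    SS_AB = SS_total - SS_A - SS_B
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .palm import PalmGenotype, PalmResult, simulate_palm
from .rice import RiceGenotype, RiceResult, simulate_rice
from .scenarios import Scenario

__all__ = [
    "SweepGrid",
    "VarianceDecomposition",
    "Optimum",
    "RESPONSES",
    "threshold_grid",
    "run_sweep",
    "variance_decomposition",
    "find_optimum",
    "export_heatmap",
    "read_heatmap",
]

# Named response extractors over a simulation trajectory frame.
RESPONSES: dict[str, Callable[[pd.DataFrame], float]] = {
    "final_green_biomass": lambda f: float(f["green_biomass_g"].iloc[-1]),
    "final_green_area": lambda f: float(f["green_area_cm2"].iloc[-1]),
    "cumulative_supply": lambda f: float(f["supply"].sum()),
    "cumulative_transpiration": lambda f: float(f["transpiration_mm"].sum()),
    "final_trunk_nsc": lambda f: float(f["trunk_nsc_gg"].iloc[-1]),
    "final_leaf_area": lambda f: float(f["leaf_area_m2"].iloc[-1]),
    "final_ftsw": lambda f: float(f["ftsw"].iloc[-1]),
}


@dataclass(frozen=True)
class SweepGrid:
    """Full-factorial response surface over two threshold parameters."""

    param_a: str
    param_b: str
    a_values: np.ndarray
    b_values: np.ndarray
    response: str
    values: np.ndarray  # shape (len(a_values), len(b_values))

    def __post_init__(self) -> None:
        a = np.asarray(self.a_values, dtype=float)
        b = np.asarray(self.b_values, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (a.size, b.size):
            raise ValueError("values shape does not match axes")
        if not np.isfinite(v).all():
            raise ValueError("response grid has missing/non-finite cells")
        for axis in (a, b):
            if np.any(np.diff(axis) <= 0) or axis.min() < 0 or axis.max() > 1:
                raise ValueError("axes must be strictly increasing within [0, 1]")
        object.__setattr__(self, "a_values", a)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "values", v)

    def transpose(self) -> "SweepGrid":
        return SweepGrid(
            param_a=self.param_b,
            param_b=self.param_a,
            a_values=self.b_values,
            b_values=self.a_values,
            response=self.response,
            values=self.values.T,
        )


@dataclass(frozen=True)
class VarianceDecomposition:
    """Shares of response variance explained by A, B and their interaction."""

    share_a: float
    share_b: float
    share_ab: float
    ss_total: float
    degenerate: bool = False


@dataclass(frozen=True)
class Optimum:
    a: float
    b: float
    value: float
    ties: tuple[tuple[float, float], ...]


def threshold_grid(n: int, lo: float = 0.02, hi: float = 1.0) -> np.ndarray:
    """Uniformly spaced FTSW threshold values spanning [lo, hi] inclusive."""
    if n < 2:
        raise ValueError("need at least 2 grid points")
    return np.linspace(lo, hi, n)


def _simulate(model: str, genotype, scenario: Scenario) -> pd.DataFrame:
    if model == "rice":
        res: RiceResult = simulate_rice(genotype, scenario)
    elif model == "palm":
        res_p: PalmResult = simulate_palm(genotype, scenario, check_invariants_every=0)
        return res_p.frame
    else:
        raise ValueError(f"unknown model {model!r}")
    return res.frame


def run_sweep(
    model: str,
    genotype_base,
    scenario: Scenario,
    param_a: str,
    param_b: str,
    n_a: int = 20,
    n_b: int = 20,
    responses: Sequence[str] = ("final_green_biomass",),
    lo: float = 0.02,
    hi: float = 1.0,
) -> dict[str, SweepGrid]:
    """One deterministic simulation per grid cell, several responses at once.

    Only the two named threshold parameters differ between cells.  Returns a
    mapping from response name to its :class:`SweepGrid`.  A simulation
    failure is re-raised annotated with the offending cell coordinates.
    """
    if not isinstance(genotype_base, (RiceGenotype, PalmGenotype)):
        raise TypeError("genotype_base must be a rice or palm genotype")
    for p in (param_a, param_b):
        if not p.endswith("_th") or not hasattr(genotype_base, p):
            raise ValueError(f"{p!r} is not a threshold parameter of the model")
    unknown = [r for r in responses if r not in RESPONSES]
    if unknown:
        raise ValueError(f"unknown responses: {unknown}")

    a_values = threshold_grid(n_a, lo, hi)
    b_values = threshold_grid(n_b, lo, hi)
    out = {r: np.empty((n_a, n_b)) for r in responses}
    for i, va in enumerate(a_values):
        for j, vb in enumerate(b_values):
            geno = dataclasses.replace(
                genotype_base, **{param_a: float(va), param_b: float(vb)}
            )
            try:
                frame = _simulate(model, geno, scenario)
            except Exception as exc:  # annotate with the cell and re-raise
                raise RuntimeError(
                    f"simulation failed at cell ({param_a}={va:.3f}, "
                    f"{param_b}={vb:.3f})"
                ) from exc
            for r in responses:
                out[r][i, j] = RESPONSES[r](frame)
    return {
        r: SweepGrid(
            param_a=param_a,
            param_b=param_b,
            a_values=a_values,
            b_values=b_values,
            response=r,
            values=out[r],
        )
        for r in responses
    }


def variance_decomposition(grid: SweepGrid) -> VarianceDecomposition:
    """Two-way ANOVA with interaction on a single-replicate full factorial.

    Returns the fractions of total sum of squares explained by each
    parameter and by their interaction (shares sum to 1).  A constant grid
    is flagged degenerate and reported as (0, 0, 0) with a warning.
    """
    y = grid.values
    n_a, n_b = y.shape
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total <= 0 or not np.isfinite(ss_total):
        warnings.warn(
            "response grid has zero variance; shares are undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return VarianceDecomposition(0.0, 0.0, 0.0, ss_total, degenerate=True)
    ss_a = float(n_b * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_b = float(n_a * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_ab = ss_total - ss_a - ss_b
    return VarianceDecomposition(
        share_a=ss_a / ss_total,
        share_b=ss_b / ss_total,
        share_ab=max(0.0, ss_ab) / ss_total,
        ss_total=ss_total,
    )


def find_optimum(grid: SweepGrid, objective: str = "max") -> Optimum:
    """Extremal cell of the grid; ties broken by smallest (a, b) and listed."""
    if objective not in ("max", "min"):
        raise ValueError("objective must be 'max' or 'min'")
    y = grid.values
    best = y.max() if objective == "max" else y.min()
    idx = np.argwhere(y == best)
    # Row-major argwhere order is already lexicographic in (a, b).
    ties = tuple(
        (float(grid.a_values[i]), float(grid.b_values[j])) for i, j in idx
    )
    i0, j0 = idx[0]
    return Optimum(
        a=float(grid.a_values[i0]),
        b=float(grid.b_values[j0]),
        value=float(best),
        ties=ties,
    )


def export_heatmap(grid: SweepGrid, path: str | Path) -> None:
    """Long-format CSV: one row per cell, full float precision."""
    a, b = np.meshgrid(grid.a_values, grid.b_values, indexing="ij")
    frame = pd.DataFrame(
        {
            grid.param_a: a.ravel(),
            grid.param_b: b.ravel(),
            grid.response: grid.values.ravel(),
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_heatmap(path: str | Path) -> SweepGrid:
    """Inverse of :func:`export_heatmap` (lossless round-trip)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    param_a, param_b, response = frame.columns[:3]
    pivot = frame.pivot(index=param_a, columns=param_b, values=response)
    return SweepGrid(
        param_a=param_a,
        param_b=param_b,
        a_values=pivot.index.to_numpy(dtype=float),
        b_values=pivot.columns.to_numpy(dtype=float),
        response=response,
        values=pivot.to_numpy(dtype=float),
    )
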