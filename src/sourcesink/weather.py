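"""Daily weather series container and its CSV interchange format.

The on-disk format is one row per day with columns
``day, tmean_c, par_mj_m2, etp_mm, water_in_mm`` (header required, ``day`` a
0-based integer index).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .engine import ClimateDay

__all__ = ["WeatherSeries", "COLUMNS"]

COLUMNS = ["day", "tmean_c", "par_mj_m2", "etp_mm", "water_in_mm"]


class WeatherSeries:
    """Immutable sequence of :class:`~sourcesink.engine.ClimateDay`.

    Wraps a pandas DataFrame in the standard column layout; iterating yields
    ``ClimateDay`` records in day order.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"weather frame missing columns: {missing}")
        frame = frame.loc[:, COLUMNS].sort_values("day").reset_index(drop=True)
        if not np.array_equal(frame["day"].to_numpy(), np.arange(len(frame))):
            raise ValueError("day column must be a contiguous 0-based index")
        if (frame[["par_mj_m2", "etp_mm", "water_in_mm"]] < 0).any().any():
            raise ValueError("par, etp and water_in must be non-negative")
        self._frame = frame

    @classmethod
    def build(
        cls,
        tmean_c,
        par_mj_m2,
        etp_mm,
        water_in_mm,
    ) -> "WeatherSeries":
        """Assemble a series from per-day arrays (broadcast against each other)."""
        arrays = np.broadcast_arrays(
            np.atleast_1d(np.asarray(tmean_c, dtype=float)),
            np.atleast_1d(np.asarray(par_mj_m2, dtype=float)),
            np.atleast_1d(np.asarray(etp_mm, dtype=float)),
            np.atleast_1d(np.asarray(water_in_mm, dtype=float)),
        )
        n = arrays[0].shape[0]
        return cls(
            pd.DataFrame(
                {
                    "day": np.arange(n),
                    "tmean_c": arrays[0],
                    "par_mj_m2": arrays[1],
                    "etp_mm": arrays[2],
                    "water_in_mm": arrays[3],
                }
            )
        )

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[ClimateDay]:
        for row in self._frame.itertuples(index=False):
            yield ClimateDay(
                day_index=int(row.day),
                tmean=float(row.tmean_c),
                par=float(row.par_mj_m2),
                etp=float(row.etp_mm),
                water_in=float(row.water_in_mm),
            )

    def __getitem__(self, day: int) -> ClimateDay:
        row = self._frame.iloc[day]
        return ClimateDay(
            day_index=int(row["day"]),
            tmean=float(row["tmean_c"]),
            par=float(row["par_mj_m2"]),
            etp=float(row["etp_mm"]),
            water_in=float(row["water_in_mm"]),
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, WeatherSeries) and self._frame.equals(other._frame)

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "WeatherSeries":
        return cls(pd.read_csv(path))
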