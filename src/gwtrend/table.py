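"""Observation containers.

The central data structure is :class:`ObservationTable`: a long-format table
with one row per (station, year) measurement, wrapped around a pandas
DataFrame together with a *scale state*.  The scale state records which
transformations have been applied to the value column — raw concentration
(e.g. mg/L), log10, or log10 after station-wise mean-centering — and
operations enforce the allowed transitions raw -> log10 -> log10_centered.

Duplicate (station, year) rows are deliberately legal: the trend model is
formulated for several observations per location, and monitoring programs
do occasionally sample a station twice in a season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("gwtrend")

#: canonical column order
CORE_COLUMNS = ["station_id", "x", "y", "year", "value"]
OPTIONAL_COLUMNS = ["program", "month"]


class ScaleState(str, Enum):
    """Which transformation chain the value column has been through."""

    RAW = "raw"
    LOG10 = "log10"
    LOG10_CENTERED = "log10_centered"


@dataclass(frozen=True)
class Observation:
    """A single (station, year) measurement.

    Coordinates are planar projected metres; ``value`` is on whatever scale
    the owning table declares.
    """

    station_id: object
    x: float
    y: float
    year: int
    value: float
    program: Optional[str] = None
    month: Optional[int] = None


class ObservationTable:
    """Ordered collection of observations plus its scale state.

    Parameters
    ----------
    df
        DataFrame with at least the columns ``station_id, x, y, year,
        value`` (``program`` and ``month`` optional).  Input row order is
        preserved and never re-sorted.
    scale_state
        Scale of the ``value`` column.
    validate
        Run invariant checks (finite coordinates, integral years, positive
        raw values, consistent per-station coordinates).  Internal callers
        that construct already-checked frames pass ``False``.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        scale_state: ScaleState = ScaleState.RAW,
        validate: bool = True,
    ):
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required columns: {missing}")
        cols = CORE_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
        df = df[cols].reset_index(drop=True)
        df = df.astype({"x": float, "y": float, "value": float})
        self._df = df
        self.scale_state = ScaleState(scale_state)
        if validate:
            self._check_invariants()

    # -- invariants ---------------------------------------------------------
    def _check_invariants(self) -> None:
        df = self._df
        for col in ("x", "y"):
            bad = ~np.isfinite(df[col].to_numpy())
            if bad.any():
                row = int(np.nonzero(bad)[0][0])
                raise ValidationError(f"non-finite {col} at row {row + 1}")
        if not np.isfinite(df["value"].to_numpy()).all():
            bad = ~np.isfinite(df["value"].to_numpy())
            row = int(np.nonzero(bad)[0][0])
            raise ValidationError(f"non-finite value at row {row + 1}")
        years = df["year"].to_numpy()
        if not np.all(np.asarray(years, dtype=float) == np.floor(np.asarray(years, dtype=float))):
            raise ValidationError("year column must be integer calendar years")
        self._df["year"] = df["year"].astype(int)
        if self.scale_state is ScaleState.RAW:
            nonpos = df["value"].to_numpy() <= 0
            if nonpos.any():
                row = int(np.nonzero(nonpos)[0][0])
                raise ValidationError(
                    f"non-positive raw value at row {row + 1}; raw concentrations must be > 0"
                )
        if "month" in df.columns:
            m = df["month"].dropna()
            if len(m) and not m.astype(int).between(1, 12).all():
                raise ValidationError("month values must lie in 1..12")
        # every observation of one station carries identical coordinates
        nuniq = df.groupby("station_id", sort=False)[["x", "y"]].nunique()
        offenders = nuniq[(nuniq["x"] > 1) | (nuniq["y"] > 1)]
        if len(offenders):
            raise ValidationError(
                f"station(s) with inconsistent coordinates: {list(offenders.index[:5])}"
            )

    # -- accessors ----------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        """The underlying long-format DataFrame (do not mutate)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def n_obs(self) -> int:
        return len(self._df)

    @property
    def station_ids(self) -> pd.Index:
        """Distinct station ids in order of first appearance."""
        return pd.Index(self._df["station_id"].drop_duplicates())

    @property
    def n_stations(self) -> int:
        return self._df["station_id"].nunique()

    def stations(self) -> pd.DataFrame:
        """One row per station: station_id, x, y (first-appearance order)."""
        return (
            self._df.drop_duplicates("station_id")[["station_id", "x", "y"]]
            .reset_index(drop=True)
        )

    def obs_per_station(self) -> pd.Series:
        return self._df.groupby("station_id", sort=False).size()

    def iter_observations(self) -> Iterable[Observation]:
        for row in self._df.itertuples(index=False):
            yield Observation(
                station_id=row.station_id,
                x=row.x,
                y=row.y,
                year=int(row.year),
                value=row.value,
                program=getattr(row, "program", None),
                month=getattr(row, "month", None),
            )

    # -- construction helpers ----------------------------------------------
    def with_values(self, values: np.ndarray, scale_state: ScaleState) -> "ObservationTable":
        """Return a copy with the value column replaced and a new scale state."""
        df = self._df.copy()
        df["value"] = np.asarray(values, dtype=float)
        return ObservationTable(df, scale_state, validate=False)

    def subset(self, mask: np.ndarray) -> "ObservationTable":
        """Row subset (boolean mask over rows), preserving order and scale."""
        df = self._df.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return ObservationTable(df, self.scale_state, validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ObservationTable(n_obs={self.n_obs}, n_stations={self.n_stations}, "
            f"scale={self.scale_state.value})"
        )
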