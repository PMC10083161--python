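"""Pre-processing, per-station summaries and spatial-heterogeneity diagnostics.

The pipeline mirrors standard practice for skewed water-chemistry data:

1. log10-transform concentrations (stabilises variance, damps outliers);
2. drop stations with fewer than two observations (no trend information);
3. screen for suspicious series with the log-normal coefficient of
   variation, ``CV = sqrt(exp(s_ln^2) - 1)`` with ``s_ln = s10 * ln(10)``,
   where ``s10`` is the sample SD of the log10 values — a CV above about
   0.8-1 means the spread of a series is of the order of its level;
4. station-wise mean-centering, so differing site levels cannot masquerade
   as temporal trends when stations enter the record in different years;
5. a crude per-station change-per-year statistic fed into Moran's I to ask
   whether temporal change is spatially clustered at all (if it is not, a
   geographically differentiated trend model is pointless).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import norm

from .errors import DegenerateDataError, StateError, ValidationError
from .table import ObservationTable, ScaleState

logger = logging.getLogger("gwtrend")

__all__ = [
    "log10_transform", "filter_min_observations", "cv_lognormal",
    "station_summaries", "flag_high_cv", "center_by_station",
    "remove_stations", "morans_i", "MoranResult",
]


def log10_transform(table: ObservationTable) -> ObservationTable:
    """Replace every value by its base-10 logarithm (raw -> log10)."""
    if table.scale_state is not ScaleState.RAW:
        raise StateError(f"log10_transform expects a raw-scale table, got {table.scale_state.value}")
    values = table.df["value"].to_numpy()
    if np.any(values <= 0):
        row = int(np.nonzero(values <= 0)[0][0])
        raise ValidationError(f"non-positive value at row {row + 1}; cannot log-transform")
    out = table.with_values(np.log10(values), ScaleState.LOG10)
    logger.info("log10_transform: %d rows", len(out))
    return out


def filter_min_observations(
    table: ObservationTable, min_n: int = 2
) -> Tuple[ObservationTable, int]:
    """Keep only stations observed at least ``min_n`` times.

    Returns the filtered table and the number of *observations* removed.
    The default of 2 is the minimum for any notion of temporal change.
    """
    if min_n < 1:
        raise ValidationError("min_n must be >= 1")
    counts = table.df.groupby("station_id", sort=False)["value"].transform("size")
    mask = (counts >= min_n).to_numpy()
    removed = int((~mask).sum())
    out = table.subset(mask)
    logger.info(
        "filter_min_observations(min_n=%d): %d -> %d rows (%d observations removed, %d stations kept)",
        min_n, table.n_obs, out.n_obs, removed, out.n_stations,
    )
    return out, removed


def cv_lognormal(s10: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Coefficient of variation of log-normally distributed data.

    ``CV = sqrt(exp(s_ln^2) - 1)`` with ``s_ln = s10 * ln(10)``, where
    ``s10`` is the standard deviation of the log10-transformed values.
    Dimensionless; 0 iff ``s10 == 0``; strictly increasing in ``s10``.
    """
    s10 = np.asarray(s10, dtype=float)
    if np.any(s10 < 0):
        raise ValidationError("s10 must be non-negative")
    s_ln = s10 * math.log(10.0)
    out = np.sqrt(np.expm1(s_ln ** 2))
    return float(out) if out.ndim == 0 else out


def station_summaries(table: ObservationTable) -> pd.DataFrame:
    """Per-station summary statistics of a log10-scale table.

    Returns one row per station (first-appearance order) with columns
    ``station_id, x, y, n_obs, mean_log, s10, s_ln, cv_lognormal,
    first_year, last_year, change_per_year``.

    ``s10`` is the sample SD (denominator n-1); for single-observation
    stations ``s10``/``cv_lognormal``/``change_per_year`` are NaN (flagged
    undefined).  ``change_per_year`` is the crude two-point slope
    ``(y_last - y_first) / (year_last - year_first)`` using the temporally
    first and last log10 observations; when several rows share the first
    (last) year the earlier (later) row in input order is used.
    """
    if table.scale_state is not ScaleState.LOG10:
        raise StateError("station_summaries expects a log10-scale table")
    rows = []
    df = table.df
    for sid, grp in df.groupby("station_id", sort=False):
        vals = grp["value"].to_numpy()
        years = grp["year"].to_numpy()
        n = len(grp)
        mean_log = float(vals.mean())
        if n >= 2:
            s10 = float(vals.std(ddof=1))
            cv = cv_lognormal(s10)
        else:
            s10 = np.nan
            cv = np.nan
        order = np.argsort(years, kind="stable")
        first_i, last_i = order[0], order[-1]
        fy, ly = int(years[first_i]), int(years[last_i])
        if ly > fy:
            change = (vals[last_i] - vals[first_i]) / (ly - fy)
        else:
            change = np.nan
            if n >= 2:
                logger.info("station %r: all observations share year %d; change_per_year undefined", sid, fy)
        rows.append({
            "station_id": sid,
            "x": grp["x"].iloc[0], "y": grp["y"].iloc[0],
            "n_obs": n, "mean_log": mean_log,
            "s10": s10, "s_ln": s10 * math.log(10.0), "cv_lognormal": cv,
            "first_year": fy, "last_year": ly, "change_per_year": change,
        })
    out = pd.DataFrame(rows)
    logger.info("station_summaries: %d stations", len(out))
    return out


def flag_high_cv(summaries: pd.DataFrame, threshold: float) -> Set:
    """Stations whose log-normal CV is *strictly* greater than ``threshold``."""
    if threshold <= 0:
        raise ValidationError("CV threshold must be > 0")
    if len(summaries) == 0:
        return set()
    mask = summaries["cv_lognormal"] > threshold
    flagged = set(summaries.loc[mask, "station_id"])
    logger.info("flag_high_cv(threshold=%g): %d of %d stations flagged", threshold, len(flagged), len(summaries))
    return flagged


def center_by_station(table: ObservationTable) -> ObservationTable:
    """Subtract each station's mean log10 level (log10 -> log10_centered).

    Every station's centered series sums to zero; the transform removes
    between-station level differences so that staggered entry of
    high-level or low-level stations cannot fake a temporal trend.
    """
    if table.scale_state is not ScaleState.LOG10:
        raise StateError("center_by_station expects a log10-scale table")
    means = table.df.groupby("station_id", sort=False)["value"].transform("mean")
    out = table.with_values(
        table.df["value"].to_numpy() - means.to_numpy(), ScaleState.LOG10_CENTERED
    )
    logger.info("center_by_station: %d rows, %d stations", len(out), out.n_stations)
    return out


def remove_stations(table: ObservationTable, station_ids: Iterable) -> ObservationTable:
    """Drop all observations of the given stations (sensitivity analyses)."""
    drop = set(station_ids)
    mask = ~table.df["station_id"].isin(drop).to_numpy()
    out = table.subset(mask)
    logger.info("remove_stations: removed %d stations, %d -> %d rows", len(drop), table.n_obs, out.n_obs)
    return out


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its null moments under the randomization assumption."""

    observed_i: float
    expected_i: float
    sd_i: float
    p_value: float
    n: int
    weight_scheme: str

    def to_dict(self) -> dict:
        return {
            "observed_i": self.observed_i, "expected_i": self.expected_i,
            "sd_i": self.sd_i, "p_value": self.p_value, "n": self.n,
            "weight_scheme": self.weight_scheme,
        }


def morans_i(
    values: np.ndarray,
    coords: np.ndarray,
    row_standardize: bool = False,
) -> MoranResult:
    """Global Moran's I with inverse Euclidean-distance weights.

    Parameters
    ----------
    values
        One number per station (here typically ``change_per_year``).
    coords
        (n, 2) station coordinates, metres.
    row_standardize
        Scale each weight-matrix row to sum to one before computing the
        statistic (off by default; the weight scheme used is recorded in
        the result).

    Notes
    -----
    Weights are ``w_ij = 1 / d_ij`` with a zero diagonal.  The statistic is
    the standard double-sum form ``I = n/S0 * sum_ij w_ij z_i z_j / sum_i
    z_i^2`` on the mean-centered values.  The expected value under the null
    is ``-1/(n-1)`` exactly; the variance uses the analytic randomization
    (kurtosis-corrected) formula and the p-value a two-sided normal
    approximation.  The variance formula requires n >= 4; for n == 3 the
    statistic and expectation are still returned, with NaN sd and p.
    """
    v = np.asarray(values, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = len(v)
    if n < 3:
        raise ValidationError("Moran's I needs at least 3 stations")
    if xy.shape != (n, 2):
        raise ValidationError("coords must be an (n, 2) array matching values")
    z = v - v.mean()
    if np.allclose(z, 0.0):
        raise DegenerateDataError("values have zero variance; Moran's I undefined")
    d = cdist(xy, xy)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0.0):
        raise ValidationError(
            "coincident stations (zero pairwise distance); jitter or aggregate them first"
        )
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    scheme = "inverse Euclidean distance, zero diagonal"
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
        scheme += ", row-standardized"

    s0 = w.sum()
    obs = (n / s0) * (z @ w @ z) / (z @ z)
    ei = -1.0 / (n - 1)
    if n >= 4:
        s1 = 0.5 * ((w + w.T) ** 2).sum()
        s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
        b2 = n * (z ** 4).sum() / ((z ** 2).sum() ** 2)
        var = (
            n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
            - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
        ) / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - ei * ei
        sd = math.sqrt(var)
        p = 2.0 * norm.sf(abs(obs - ei) / sd)
    else:
        sd = float("nan")
        p = float("nan")
    result = MoranResult(float(obs), ei, sd, float(p), n, scheme)
    logger.info("morans_i: I=%.6g (E=%.4g, sd=%.4g, p=%.3g, n=%d)", obs, ei, sd, p, n)
    return result
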