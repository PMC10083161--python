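"""Synthetic rotating-panel monitoring data with known trend surfaces.

Emulates the structure of a national lake survey: a few hundred to a few
thousand stations scattered over a planar domain (optionally denser toward
the south), split into revisit panels so each station is sampled only every
``n_panels`` years, with log10-scale values generated from smooth spatially
varying intercept and slope fields plus i.i.d. Gaussian noise,

    log10 value = beta0(x, y) + beta1(x, y) * (year - mid_year) + eps,

optionally with a shared nonlinear time profile and with injectable
first-observation outliers to exercise the variability screen.  Everything
is deterministic given the configuration's seed.

Defaults follow the design the estimator targets: 800 stations, 6 panels
over 2008-2021 (each station visited 2-3 times), noise SD 0.1 on the log10
scale, and slope magnitudes of order 0.015-0.02 log10 units per year.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .table import ObservationTable, ScaleState

logger = logging.getLogger("gwtrend")

__all__ = [
    "GaussianBump", "ScalarField", "TrendSurface", "two_region_surface",
    "SyntheticConfig", "generate_network", "assign_panels",
    "simulate_observations", "inject_outliers", "true_coefficients",
]


@dataclass(frozen=True)
class GaussianBump:
    """One radial Gaussian component of a scalar field."""

    cx: float
    cy: float
    width: float       # metres; SD of the radial Gaussian
    amplitude: float


@dataclass(frozen=True)
class ScalarField:
    """Constant plus a sum of Gaussian bumps; finite and deterministic."""

    constant: float = 0.0
    bumps: Tuple[GaussianBump, ...] = ()

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(np.broadcast(x, y).shape, self.constant, dtype=float)
        for b in self.bumps:
            r2 = (x - b.cx) ** 2 + (y - b.cy) ** 2
            out += b.amplitude * np.exp(-r2 / (2.0 * b.width ** 2))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class _StepEastWest:
    """Two-region step field: one value west of a split, another east."""

    x_split: float
    west: float
    east: float

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float)
        out = np.where(x < self.x_split, self.west, self.east)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class TrendSurface:
    """True spatial fields: intercept beta0 and slope beta1 (log10/year)."""

    intercept_field: Callable
    slope_field: Callable


def two_region_surface(
    bounds: Tuple[float, float, float, float],
    slope_west: float = 0.015,
    slope_east: float = -0.02,
    intercept_level: float = 1.0,
) -> TrendSurface:
    """A step slope field split down the middle of the x-range.

    The default magnitudes (+0.015 west, -0.02 east, in log10 units per
    year) are of the order seen for organic-carbon trends in boreal lakes;
    the intercept defaults to log10(10 mg/L) = 1.
    """
    x0, _, x1, _ = bounds
    split = 0.5 * (x0 + x1)
    return TrendSurface(
        intercept_field=ScalarField(constant=intercept_level),
        slope_field=_StepEastWest(split, slope_west, slope_east),
    )


@dataclass
class SyntheticConfig:
    """Design parameters of the simulated monitoring program."""

    n_stations: int = 800
    bounds: Tuple[float, float, float, float] = (0.0, 0.0, 500_000.0, 1_000_000.0)
    n_panels: int = 6
    years: Tuple[int, int] = (2008, 2021)
    observations_per_visit: int = 1
    noise_sd_log10: float = 0.1
    outlier_fraction: float = 0.0
    outlier_shift_log10: float = 0.8
    density_gradient: Optional[float] = None  # south:north density ratio (>1 denser south)
    seed: int = 0

    def __post_init__(self):
        x0, y0, x1, y1 = self.bounds
        if not (x1 > x0 and y1 > y0):
            raise ValidationError("degenerate domain bounds")
        if self.n_stations < 1:
            raise ValidationError("n_stations must be >= 1")
        if self.n_panels < 1:
            raise ValidationError("n_panels must be >= 1")
        if self.n_panels > self.years[1] - self.years[0] + 1:
            raise ValidationError("more panels than years")
        if self.noise_sd_log10 < 0:
            raise ValidationError("noise_sd_log10 must be >= 0")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValidationError("outlier_fraction must lie in [0, 1]")
        if self.observations_per_visit < 1:
            raise ValidationError("observations_per_visit must be >= 1")

    @property
    def mid_year(self) -> float:
        return 0.5 * (self.years[0] + self.years[1])


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent substreams per stage so adding outliers does not shift
    # the noise draws
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_network(config: SyntheticConfig) -> pd.DataFrame:
    """Place stations in the domain: ``station_id, x, y``.

    Uniform by default; ``density_gradient=r`` makes the point density at
    the south edge (low y) r times the density at the north edge, linearly
    interpolated — mimicking a denser network in the populated south.
    """
    rng = _rng(config, 0)
    x0, y0, x1, y1 = config.bounds
    n = config.n_stations
    xs = rng.uniform(x0, x1, size=n)
    u = rng.uniform(0.0, 1.0, size=n)
    if config.density_gradient is None or config.density_gradient == 1.0:
        v = u
    else:
        r = float(config.density_gradient)
        if r <= 0:
            raise ValidationError("density_gradient must be > 0")
        # density f(v) = r + (1-r)v on [0,1]; invert its CDF
        norm = r + (1.0 - r) / 2.0
        a = (1.0 - r) / 2.0
        v = np.where(
            a == 0.0, u,
            (-r + np.sqrt(r * r + 4.0 * a * norm * u)) / (2.0 * a),
        )
    ys = y0 + v * (y1 - y0)
    df = pd.DataFrame({
        "station_id": [f"S{i:05d}" for i in range(n)],
        "x": xs, "y": ys,
    })
    logger.info("generate_network: %d stations, seed=%d", n, config.seed)
    return df


def assign_panels(stations: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Rotating-panel visit schedule: one row per (station, year) visit.

    Stations are shuffled (seeded) and dealt round-robin into
    ``n_panels`` panels; panel p is visited in every year with
    ``(year - first_year) % n_panels == p``.  With 6 panels over
    2008-2021 every station is visited 2 or 3 times.  Returns columns
    ``station_id, panel, year``.
    """
    rng = _rng(config, 1)
    n = len(stations)
    order = rng.permutation(n)
    panel = np.empty(n, dtype=int)
    panel[order] = np.arange(n) % config.n_panels
    y0, y1 = config.years
    rows = []
    for p in range(config.n_panels):
        visit_years = [yr for yr in range(y0, y1 + 1) if (yr - y0) % config.n_panels == p]
        members = stations.index[panel == p]
        for idx in members:
            for yr in visit_years:
                rows.append((stations.at[idx, "station_id"], p, yr))
    sched = pd.DataFrame(rows, columns=["station_id", "panel", "year"])
    # stable station-major order as generated, then chronological per station
    sched = sched.sort_values(["station_id", "year"], kind="stable").reset_index(drop=True)
    logger.info("assign_panels: %d visits over %d panels", len(sched), config.n_panels)
    return sched


def true_coefficients(stations: pd.DataFrame, surface: TrendSurface) -> pd.DataFrame:
    """Evaluate the true intercept/slope fields at station locations."""
    return pd.DataFrame({
        "station_id": stations["station_id"],
        "x": stations["x"], "y": stations["y"],
        "beta0": surface.intercept_field(stations["x"].to_numpy(), stations["y"].to_numpy()),
        "beta1": surface.slope_field(stations["x"].to_numpy(), stations["y"].to_numpy()),
    })


def simulate_observations(
    schedule: pd.DataFrame,
    stations: pd.DataFrame,
    surface: TrendSurface,
    config: SyntheticConfig,
    trend_profile: Optional[Callable] = None,
    scale: str = "log10",
) -> ObservationTable:
    """Draw observations along the visit schedule.

    log10 value = beta0(s) + beta1(s) * (year - mid_year)
                  [+ trend_profile(year)] + Normal(0, noise_sd_log10).

    ``trend_profile`` is an optional spatially constant nonlinear time
    component (year -> offset in log10 units), used to simulate trend
    reversals for the moving-window analysis.  ``scale="raw"`` exports
    10**value instead (for exercising the raw-input pipeline).
    """
    rng = _rng(config, 2)
    coords = stations.set_index("station_id")[["x", "y"]]
    sched = schedule.loc[schedule.index.repeat(config.observations_per_visit)].reset_index(drop=True)
    xs = coords.loc[sched["station_id"], "x"].to_numpy()
    ys = coords.loc[sched["station_id"], "y"].to_numpy()
    years = sched["year"].to_numpy(dtype=float)
    b0 = np.asarray(surface.intercept_field(xs, ys), dtype=float)
    b1 = np.asarray(surface.slope_field(xs, ys), dtype=float)
    vals = b0 + b1 * (years - config.mid_year)
    if trend_profile is not None:
        vals = vals + np.asarray(trend_profile(years), dtype=float)
    if config.noise_sd_log10 > 0:
        vals = vals + rng.normal(0.0, config.noise_sd_log10, size=len(vals))
    df = pd.DataFrame({
        "station_id": sched["station_id"].to_numpy(),
        "x": xs, "y": ys,
        "year": sched["year"].to_numpy(),
        "value": vals,
    })
    if scale == "log10":
        table = ObservationTable(df, ScaleState.LOG10, validate=False)
    elif scale == "raw":
        df["value"] = np.power(10.0, df["value"])
        table = ObservationTable(df, ScaleState.RAW, validate=False)
    else:
        raise ValidationError("scale must be 'log10' or 'raw'")
    logger.info(
        "simulate_observations: %d observations, noise_sd=%.3g, seed=%d",
        len(table), config.noise_sd_log10, config.seed,
    )
    return table


def inject_outliers(
    table: ObservationTable, config: SyntheticConfig
) -> Tuple[ObservationTable, List]:
    """Shift the temporally first observation of a random station subset.

    ``round(outlier_fraction * n_stations)`` stations are drawn (seeded)
    and their earliest observation (earliest year; first in input order on
    ties) is shifted by ``outlier_shift_log10``.  Returns the modified
    table and the injected station ids so a screen's recall can be scored.
    """
    rng = _rng(config, 3)
    ids = table.station_ids.to_numpy()
    n_inject = int(round(config.outlier_fraction * len(ids)))
    if n_inject == 0:
        return table, []
    chosen = rng.choice(ids, size=n_inject, replace=False)
    chosen_set = set(chosen)
    values = table.df["value"].to_numpy().copy()
    for sid, grp in table.df.groupby("station_id", sort=False):
        if sid not in chosen_set:
            continue
        first_row = grp.index[np.argsort(grp["year"].to_numpy(), kind="stable")[0]]
        values[first_row] += config.outlier_shift_log10
    out = table.with_values(values, table.scale_state)
    logger.info(
        "inject_outliers: %d stations shifted by %+g log10 units",
        n_inject, config.outlier_shift_log10,
    )
    return out, list(chosen)
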