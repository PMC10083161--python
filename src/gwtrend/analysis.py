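"""Higher-level trend analyses built on the estimator.

Covers the standard workflow around a fitted surface: classifying stations
into significant up/down/no-trend at a chosen level, comparing two fits
station by station (sensitivity to removing high-variation stations, or to
the neighbourhood size), merging observation tables from several monitoring
programs, and the moving-window analysis that exposes nonlinearity by
refitting the linear model on overlapping temporal subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import StateError, ValidationError
from .gwr import BandwidthSelection, GWRResult, fit_gwr, select_bandwidth
from .preprocess import center_by_station, filter_min_observations
from .table import ObservationTable, ScaleState

logger = logging.getLogger("gwtrend")

__all__ = [
    "significance_classes", "compare_fits", "combine_programs",
    "moving_window_fit", "FitComparison", "WindowedResult",
]

FitLike = Union[GWRResult, pd.DataFrame]


def _fits_frame(fit: FitLike) -> pd.DataFrame:
    return fit.fits if isinstance(fit, GWRResult) else fit


def significance_classes(result: FitLike, alpha: float = 0.05) -> pd.Series:
    """Classify every station as ``down``, ``up`` or ``none``.

    ``down``/``up`` require ``p_slope`` strictly below ``alpha`` and the
    corresponding slope sign; everything else — including a p-value equal
    to alpha, a zero slope, or an invalid fit — is ``none``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    fits = _fits_frame(result)
    p = fits["p_slope"].to_numpy()
    slope = fits["slope"].to_numpy()
    cls = np.full(len(fits), "none", dtype=object)
    with np.errstate(invalid="ignore"):
        sig = p < alpha
        cls[sig & (slope < 0)] = "down"
        cls[sig & (slope > 0)] = "up"
    return pd.Series(cls, index=fits["station_id"].to_numpy(), name="signif_class")


@dataclass
class FitComparison:
    """Station-wise differences between two fitted surfaces (b minus a)."""

    slope_difference: pd.Series  # indexed by station_id, fit_b - fit_a
    max_abs_difference: float
    stations_changing_significance_class: set

    def summary(self) -> dict:
        return {
            "n_shared": int(len(self.slope_difference)),
            "max_abs_difference": self.max_abs_difference,
            "n_class_changes": len(self.stations_changing_significance_class),
        }


def compare_fits(fit_a: FitLike, fit_b: FitLike, alpha: float = 0.05) -> FitComparison:
    """Compare two fits on their shared stations.

    The slope difference is ``fit_b - fit_a``; a station "changes class"
    when its up/down/none label at level ``alpha`` differs between fits.
    """
    a = _fits_frame(fit_a).set_index("station_id")
    b = _fits_frame(fit_b).set_index("station_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValidationError("the two fits share no stations")
    diff = (b.loc[shared, "slope"] - a.loc[shared, "slope"]).rename("slope_difference")
    cls_a = significance_classes(_fits_frame(fit_a), alpha).loc[shared]
    cls_b = significance_classes(_fits_frame(fit_b), alpha).loc[shared]
    changed = set(shared[(cls_a != cls_b).to_numpy()])
    max_abs = float(np.nanmax(np.abs(diff.to_numpy()))) if len(diff) else 0.0
    logger.info(
        "compare_fits: %d shared stations, max |d slope|=%.4g, %d class changes",
        len(shared), max_abs, len(changed),
    )
    return FitComparison(diff, max_abs, changed)


def combine_programs(
    tables: Sequence[ObservationTable],
    month_ranges: Optional[Sequence[Optional[Tuple[int, int]]]] = None,
) -> ObservationTable:
    """Concatenate observation tables from different monitoring programs.

    All tables must share one scale state and have disjoint station ids.
    ``month_ranges`` optionally gives an inclusive (lo, hi) month filter per
    table (e.g. ``(9, 12)`` for an autumn subset); ``None`` keeps all rows.
    Downstream weighting treats rows from all programs identically — that
    is the point of combining them.
    """
    if not tables:
        raise ValidationError("no tables to combine")
    if month_ranges is not None and len(month_ranges) != len(tables):
        raise ValidationError("month_ranges must align with tables")
    scale = tables[0].scale_state
    if any(t.scale_state is not scale for t in tables):
        raise StateError("all tables must share one scale_state before combining")
    seen: set = set()
    frames = []
    for i, tbl in enumerate(tables):
        ids = set(tbl.station_ids)
        collision = seen & ids
        if collision:
            raise ValidationError(
                f"station id(s) {sorted(collision)[:5]} appear in more than one program; "
                "disambiguate ids before combining"
            )
        seen |= ids
        df = tbl.df
        if month_ranges is not None and month_ranges[i] is not None:
            lo, hi = month_ranges[i]
            if "month" not in df.columns:
                raise ValidationError(f"table {i} has no month column but a month filter was requested")
            df = df[df["month"].astype(float).between(lo, hi)]
        frames.append(df)
    out = ObservationTable(pd.concat(frames, ignore_index=True), scale, validate=False)
    logger.info("combine_programs: %d tables -> %d rows, %d stations", len(tables), out.n_obs, out.n_stations)
    return out


@dataclass
class WindowedResult:
    """One temporal window's fit (or a flagged-empty placeholder)."""

    window_start: int
    window_end: int
    selected_k: Optional[int]
    result: Optional[GWRResult]
    selection: Optional[BandwidthSelection] = None
    empty: bool = False


def moving_window_fit(
    table: ObservationTable,
    window_length: int = 10,
    step: int = 1,
    k_grid: Optional[Sequence[int]] = None,
    k: Optional[int] = None,
    kernel: str = "bisquare",
) -> List[WindowedResult]:
    """Refit the linear trend model on overlapping temporal windows.

    The input is a *log10* (uncentered) table; within each window the
    stations are re-filtered to >= 2 observations and re-centered on their
    within-window means, so that each window is a self-contained analysis.
    The neighbourhood size is re-selected by cross-validation over
    ``k_grid`` per window (pass a fixed ``k`` to skip the search).  Windows
    advance by ``step`` years from the earliest year until the window end
    reaches the latest observed year; a window left with fewer than 3
    stations is flagged empty rather than fatal.
    """
    if table.scale_state is not ScaleState.LOG10:
        raise StateError("moving_window_fit expects a log10 (uncentered) table; it re-centers per window")
    if k_grid is None and k is None:
        raise ValidationError("provide either k_grid (CV per window) or a fixed k")
    years = table.df["year"].to_numpy()
    y0, y1 = int(years.min()), int(years.max())
    if y1 - y0 + 1 < window_length:
        raise ValidationError(f"data span {y1 - y0 + 1} years < window length {window_length}")
    results: List[WindowedResult] = []
    for start in range(y0, y1 - window_length + 2, step):
        end = start + window_length - 1
        mask = (years >= start) & (years <= end)
        sub = table.subset(mask)
        sub, _ = filter_min_observations(sub, 2)
        if sub.n_stations < 3:
            logger.warning("window %d-%d: only %d station(s) after filtering; flagged empty", start, end, sub.n_stations)
            results.append(WindowedResult(start, end, None, None, empty=True))
            continue
        centered = center_by_station(sub)
        if k is not None:
            k_win, selection = int(min(k, centered.n_obs)), None
        else:
            grid = [g for g in k_grid if 3 <= g <= centered.n_obs]
            if not grid:
                grid = [min(max(3, centered.n_obs // 10), centered.n_obs)]
            selection = select_bandwidth(centered, grid, kernel=kernel)
            k_win = selection.selected_k
        res = fit_gwr(centered, k_win, kernel=kernel)
        logger.info("window %d-%d: %d stations, k=%d", start, end, sub.n_stations, k_win)
        results.append(WindowedResult(start, end, k_win, res, selection))
    return results
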