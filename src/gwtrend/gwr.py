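"""Geographically weighted regression of values on time.

At every station a weighted least squares line ``value ~ year`` is fitted,
with weights given by a compactly supported bisquare kernel

    w(d) = (1 - (d/b)^2)^2   if d < b,   else 0

whose bandwidth ``b`` is *adaptive*: the Euclidean distance from the focal
station to its k-th nearest observation.  Because the kernel is strictly
inside-open, the k-th neighbour itself receives weight zero.  k counts
observations, not stations — co-located observations each occupy a rank.

Inference follows the weighted-least-squares convention: a single global
residual variance ``sigma2 = RSS / edf`` with effective degrees of freedom
``edf = n - 2*tr(S) + tr(S'S)`` (S is the hat matrix collecting every local
fit's row at its own station), and per-station sandwich covariance
``sigma2 * (X'WX)^-1 X'W^2X (X'WX)^-1``.  P-values are two-sided t with
``edf`` degrees of freedom and deliberately unadjusted for multiplicity;
they delineate regions, they are not station-level tests.

Bandwidth selection is leave-one-out cross-validation over a user grid of
candidate k: each observation is predicted from its own station's local fit
with that observation's weight set to zero (bandwidth ranks kept from the
full data).  Leave-whole-station-out is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import t as t_dist

from .errors import ConfigurationError, DegenerateDataError, StateError, ValidationError
from .table import ObservationTable, ScaleState

logger = logging.getLogger("gwtrend")

__all__ = [
    "adaptive_bandwidth", "bisquare_weight", "local_wls", "fit_gwr",
    "cv_score", "select_bandwidth", "GWRResult", "LocalWLSFit",
    "CVScore", "BandwidthSelection",
]

# relative floor on the weighted variance of t below which a local design
# is treated as singular
_SINGULAR_TOL = 1e-10


def adaptive_bandwidth(focal: np.ndarray, obs_coords: np.ndarray, k: int) -> float:
    """Distance from ``focal`` to its k-th nearest observation.

    Co-located observations each count (the focal station's own
    observations sit at distance zero and are included).  A returned
    bandwidth of exactly 0 means at least k observations are co-located
    with the focal point; downstream weighting must treat that as
    degenerate.
    """
    obs_coords = np.atleast_2d(np.asarray(obs_coords, dtype=float))
    n = len(obs_coords)
    if not (3 <= k <= n):
        raise ConfigurationError(f"k={k} outside valid range [3, {n}]")
    d = np.hypot(*(obs_coords - np.asarray(focal, dtype=float)).T)
    d_sorted = np.sort(d, kind="stable")
    return float(d_sorted[k - 1])


def bisquare_weight(d, b):
    """Bisquare kernel ``(1 - (d/b)^2)^2`` for ``d < b``, zero otherwise.

    Strict at the boundary: ``w(d=b) = 0``.
    """
    if np.any(np.asarray(b) <= 0):
        raise ValidationError("bandwidth b must be > 0")
    d = np.asarray(d, dtype=float)
    u = d / b
    w = np.where(u < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    return float(w) if w.ndim == 0 else w


@dataclass(frozen=True)
class LocalWLSFit:
    """One local weighted least squares line fit."""

    intercept: float
    slope: float
    cov_unscaled: np.ndarray  # (X'WX)^-1 X'W^2X (X'WX)^-1, multiply by sigma2
    rss_w: float              # weighted residual sum of squares
    local_r2: float
    n_pos: int                # observations with strictly positive weight


def local_wls(t: np.ndarray, y: np.ndarray, w: np.ndarray) -> LocalWLSFit:
    """Weighted least squares of ``y`` on ``(1, t)``.

    Requires at least two strictly positive weights spanning at least two
    distinct ``t`` values.  Zero-weight observations are inert.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    pos = w > 0
    n_pos = int(pos.sum())
    if n_pos < 2:
        raise DegenerateDataError("local fit needs >= 2 observations with positive weight")
    if np.ptp(t[pos]) == 0:
        raise DegenerateDataError("all positively weighted observations share one t value")
    X = np.column_stack([np.ones_like(t), t])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    a = X.T @ (w[:, None] * X)
    b_mat = X.T @ ((w ** 2)[:, None] * X)
    a_inv = np.linalg.inv(a)
    cov_unscaled = a_inv @ b_mat @ a_inv
    resid = y - X @ beta
    rss_w = float(w @ resid ** 2)
    ybar_w = float(w @ y / w.sum())
    tss_w = float(w @ (y - ybar_w) ** 2)
    r2 = 1.0 - rss_w / tss_w if tss_w > 0 else float("nan")
    return LocalWLSFit(float(beta[0]), float(beta[1]), cov_unscaled, rss_w, r2, n_pos)


# ---------------------------------------------------------------------------
# vectorised engine


class _Workspace:
    """Precomputed arrays for one table: distances, time axis, ownership."""

    def __init__(self, table: ObservationTable):
        df = table.df
        st = df.drop_duplicates("station_id")
        self.st_ids = st["station_id"].to_numpy()
        self.st_xy = st[["x", "y"]].to_numpy(dtype=float)
        sid_to_idx = {s: i for i, s in enumerate(self.st_ids)}
        self.owner = df["station_id"].map(sid_to_idx).to_numpy()
        years = df["year"].to_numpy(dtype=float)
        self.t_ref = 0.5 * (years.min() + years.max())
        self.t = years - self.t_ref
        self.y = df["value"].to_numpy(dtype=float)
        self.n = len(df)
        self.n_st = len(self.st_ids)
        # distance from every station (rows) to every observation (cols)
        self.D = cdist(self.st_xy, self.st_xy)[:, self.owner]
        self.t_scale = max(1.0, np.ptp(self.t) ** 2)
        self.st_n_obs = np.bincount(self.owner, minlength=self.n_st)

    def bandwidths(self, k: int) -> np.ndarray:
        if not (3 <= k <= self.n):
            raise ConfigurationError(f"k={k} outside valid range [3, {self.n}]")
        return np.partition(self.D, k - 1, axis=1)[:, k - 1]

    def weights(self, k: int, kernel: str) -> tuple[np.ndarray, np.ndarray]:
        """(bandwidth per station, weight matrix stations x observations)."""
        b = self.bandwidths(k)
        degenerate = b <= 0
        b_safe = np.where(degenerate, 1.0, b)
        if kernel == "bisquare":
            u = self.D / b_safe[:, None]
            w = np.where(u < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        elif kernel == "uniform":
            # debug kernel: flat weights inside the (closed) bandwidth; with
            # k = n every local fit collapses onto the global OLS fit
            w = (self.D <= b_safe[:, None]).astype(float)
        else:
            raise ConfigurationError(f"unknown kernel {kernel!r}")
        w[degenerate] = 0.0
        if degenerate.any():
            logger.warning(
                "%d station(s) have >= k co-located observations (bandwidth 0); flagged degenerate",
                int(degenerate.sum()),
            )
        return b, w


@dataclass
class _StationSums:
    """Per-station moment sums of the weighted design."""

    S0: np.ndarray; St: np.ndarray; Stt: np.ndarray
    Sy: np.ndarray; Sty: np.ndarray; Syy: np.ndarray
    S0_2: np.ndarray; St_2: np.ndarray; Stt_2: np.ndarray
    n_pos: np.ndarray; det: np.ndarray; valid: np.ndarray


def _station_sums(ws: _Workspace, w: np.ndarray, b: np.ndarray) -> _StationSums:
    t, y = ws.t, ws.y
    S0 = w.sum(axis=1)
    St = w @ t
    Stt = w @ (t * t)
    Sy = w @ y
    Sty = w @ (t * y)
    Syy = w @ (y * y)
    w2 = w * w
    S0_2 = w2.sum(axis=1)
    St_2 = w2 @ t
    Stt_2 = w2 @ (t * t)
    n_pos = (w > 0).sum(axis=1)
    det = S0 * Stt - St ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        vt = det / np.maximum(S0 ** 2, 1e-300)
    valid = (b > 0) & (n_pos >= 2) & (vt > _SINGULAR_TOL * ws.t_scale)
    return _StationSums(S0, St, Stt, Sy, Sty, Syy, S0_2, St_2, Stt_2, n_pos, det, valid)


@dataclass
class GWRResult:
    """A fitted geographically weighted trend model.

    ``fits`` has one row per station in first-appearance order, invalid
    (singular) stations flagged via ``valid=False`` with NaN estimates.
    Intercepts are reported at the reference year ``t_ref`` (mid-span of
    the data), which leaves slopes untouched but keeps the normal
    equations well conditioned.
    """

    fits: pd.DataFrame
    k: int
    kernel: str
    t_ref: float
    sigma2_hat: float
    trace_S: float
    trace_StS: float
    effective_df: float
    rss: float
    overall_adj_r2: float
    n_obs_used: int
    sigma_mode: str = "global"

    @property
    def slopes(self) -> pd.Series:
        return self.fits.set_index("station_id")["slope"]


def fit_gwr(
    table: ObservationTable,
    k: int,
    kernel: str = "bisquare",
    allow_uncentered: bool = False,
    sigma: str = "global",
) -> GWRResult:
    """Fit the local trend model at every station.

    Parameters
    ----------
    table
        Observations in ``log10_centered`` scale (pass
        ``allow_uncentered=True`` to accept plain ``log10`` for
        comparison runs on uncentered data).  Every station must hold at
        least two observations — apply :func:`~gwtrend.preprocess.filter_min_observations` first.
    k
        Adaptive neighbourhood size, counted in observations; ``k >= 3``.
    kernel
        ``"bisquare"`` (default) or the ``"uniform"`` debug kernel.
    sigma
        ``"global"`` (default): one residual variance ``RSS/edf`` shared by
        all stations.  ``"local"``: per-station weighted residual variance
        with denominator ``n_pos - 2`` (exploratory only).
    """
    allowed = {ScaleState.LOG10_CENTERED} | ({ScaleState.LOG10} if allow_uncentered else set())
    if table.scale_state not in allowed:
        raise StateError(
            f"fit_gwr expects a log10_centered table (got {table.scale_state.value}); "
            "center_by_station first, or pass allow_uncentered=True"
        )
    if sigma not in ("global", "local"):
        raise ConfigurationError("sigma must be 'global' or 'local'")
    low = table.obs_per_station()
    if (low < 2).any():
        raise ValidationError(
            f"{int((low < 2).sum())} station(s) have fewer than 2 observations; "
            "apply filter_min_observations first"
        )

    ws = _Workspace(table)
    b, w = ws.weights(k, kernel)
    s = _station_sums(ws, w, b)
    t, y, owner = ws.t, ws.y, ws.owner

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (s.S0 * s.Sty - s.St * s.Sy) / s.det
        intercept = (s.Stt * s.Sy - s.St * s.Sty) / s.det
        # A^-1 entries
        a00 = s.Stt / s.det
        a01 = -s.St / s.det
        a11 = s.S0 / s.det
    slope = np.where(s.valid, slope, np.nan)
    intercept = np.where(s.valid, intercept, np.nan)
    if not s.valid.all():
        logger.warning(
            "fit_gwr: %d station(s) with singular local design excluded from traces",
            int((~s.valid).sum()),
        )

    # sandwich C = A^-1 B A^-1 per station (2x2, closed form)
    with np.errstate(divide="ignore", invalid="ignore"):
        c00 = a00 * (a00 * s.S0_2 + a01 * s.St_2) + a01 * (a00 * s.St_2 + a01 * s.Stt_2)
        c11 = a01 * (a01 * s.S0_2 + a11 * s.St_2) + a11 * (a01 * s.St_2 + a11 * s.Stt_2)

    # hat-matrix diagonals and row norms, evaluated at each observation's
    # own station
    obs_valid = s.valid[owner]
    w_self = w[owner, np.arange(ws.n)]
    quad_a = a00[owner] + 2.0 * a01[owner] * t + a11[owner] * t * t
    lev = w_self * quad_a
    # M = A^-1 B A^-1 entries per station
    m00 = c00
    m11 = c11
    with np.errstate(divide="ignore", invalid="ignore"):
        m01 = a00 * (a01 * s.S0_2 + a11 * s.St_2) + a01 * (a01 * s.St_2 + a11 * s.Stt_2)
    row_norm2 = m00[owner] + 2.0 * m01[owner] * t + m11[owner] * t * t

    yhat = intercept[owner] + slope[owner] * t
    resid = y - yhat
    rss = float(np.nansum(np.where(obs_valid, resid ** 2, 0.0)))
    n_used = int(obs_valid.sum())
    trace_S = float(np.nansum(np.where(obs_valid, lev, 0.0)))
    trace_StS = float(np.nansum(np.where(obs_valid, row_norm2, 0.0)))
    edf = n_used - 2.0 * trace_S + trace_StS
    if edf <= 0:
        raise DegenerateDataError(f"effective degrees of freedom non-positive ({edf:.3g})")
    sigma2 = rss / edf

    # local weighted R^2 and weighted RSS per station
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_w = (
            s.Syy - 2.0 * intercept * s.Sy - 2.0 * slope * s.Sty
            + intercept ** 2 * s.S0 + 2.0 * intercept * slope * s.St + slope ** 2 * s.Stt
        )
        tss_w = s.Syy - s.Sy ** 2 / s.S0
        local_r2 = np.where(tss_w > 0, 1.0 - rss_w / tss_w, np.nan)
    local_r2 = np.clip(local_r2, 0.0, 1.0, out=local_r2, where=np.isfinite(local_r2))

    if sigma == "local":
        with np.errstate(divide="ignore", invalid="ignore"):
            sig2_station = np.where(s.n_pos > 2, rss_w / np.maximum(s.n_pos - 2, 1), np.nan)
    else:
        sig2_station = np.full(ws.n_st, sigma2)

    with np.errstate(invalid="ignore"):
        se_int = np.sqrt(sig2_station * c00)
        se_slope = np.sqrt(sig2_station * c11)
        t_slope = slope / se_slope
    p_slope = 2.0 * t_dist.sf(np.abs(t_slope), edf)
    se_int = np.where(s.valid, se_int, np.nan)
    se_slope = np.where(s.valid, se_slope, np.nan)
    t_slope = np.where(s.valid, t_slope, np.nan)
    p_slope = np.where(s.valid, p_slope, np.nan)

    # overall adjusted R^2 about the global mean of the used observations
    y_used = y[obs_valid]
    tss = float(((y_used - y_used.mean()) ** 2).sum())
    overall_adj_r2 = 1.0 - (rss / edf) / (tss / (n_used - 1)) if tss > 0 else float("nan")

    fits = pd.DataFrame({
        "station_id": ws.st_ids,
        "x": ws.st_xy[:, 0], "y": ws.st_xy[:, 1],
        "n_obs": ws.st_n_obs,
        "intercept": intercept, "slope": slope,
        "se_intercept": se_int, "se_slope": se_slope,
        "t_slope": t_slope, "p_slope": p_slope,
        "local_r2": np.where(s.valid, local_r2, np.nan),
        "bandwidth_dist": b,
        "k": k,
        "n_positive_weight": s.n_pos,
        "valid": s.valid,
    })
    logger.info(
        "fit_gwr: k=%d kernel=%s n=%d stations=%d edf=%.1f sigma2=%.4g adjR2=%.3f",
        k, kernel, ws.n, ws.n_st, edf, sigma2, overall_adj_r2,
    )
    return GWRResult(
        fits=fits, k=k, kernel=kernel, t_ref=ws.t_ref, sigma2_hat=sigma2,
        trace_S=trace_S, trace_StS=trace_StS, effective_df=edf, rss=rss,
        overall_adj_r2=overall_adj_r2, n_obs_used=n_used, sigma_mode=sigma,
    )


@dataclass(frozen=True)
class CVScore:
    """Leave-one-out prediction error sum for one candidate k."""

    score: float
    n_excluded: int  # observations whose left-out local fit was singular


def _cv_from_workspace(ws: _Workspace, k: int, kernel: str, loo: str) -> CVScore:
    b, w = ws.weights(k, kernel)
    s = _station_sums(ws, w, b)
    t, y, owner = ws.t, ws.y, ws.owner
    n = ws.n
    w_self = w[owner, np.arange(n)]

    if loo == "obs":
        d0, d1, d2 = w_self, w_self * t, w_self * t * t
        dy, dty = w_self * y, w_self * t * y
        npos_drop = (w_self > 0).astype(int)
    elif loo == "station":
        # drop every observation of the focal observation's station at once
        def acc(vals):
            return np.bincount(owner, weights=vals, minlength=ws.n_st)[owner]
        d0 = acc(w_self)
        d1 = acc(w_self * t)
        d2 = acc(w_self * t * t)
        dy = acc(w_self * y)
        dty = acc(w_self * t * y)
        npos_drop = np.bincount(owner, weights=(w_self > 0).astype(float), minlength=ws.n_st
                                ).astype(int)[owner]
    else:
        raise ConfigurationError("loo must be 'obs' or 'station'")

    S0 = s.S0[owner] - d0
    St = s.St[owner] - d1
    Stt = s.Stt[owner] - d2
    Sy = s.Sy[owner] - dy
    Sty = s.Sty[owner] - dty
    det = S0 * Stt - St ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        vt = det / np.maximum(S0 ** 2, 1e-300)
        slope = (S0 * Sty - St * Sy) / det
        intercept = (Stt * Sy - St * Sty) / det
    valid = (
        s.valid[owner]
        & ((s.n_pos[owner] - npos_drop) >= 2)
        & (vt > _SINGULAR_TOL * ws.t_scale)
    )
    pred = intercept + slope * t
    resid = np.where(valid, y - pred, 0.0)
    n_excl = int((~valid).sum())
    if n_excl:
        logger.info("cv_score(k=%d): %d observation(s) with singular leave-out fit excluded", k, n_excl)
    return CVScore(float(resid @ resid), n_excl)


def cv_score(
    table: ObservationTable,
    k: int,
    kernel: str = "bisquare",
    loo: str = "obs",
    allow_uncentered: bool = False,
) -> CVScore:
    """Leave-one-out cross-validation score for neighbourhood size ``k``.

    Each observation is predicted from its own station's local fit with the
    observation's weight zeroed; bandwidth ranks are computed on the full
    observation set.  ``loo="station"`` zeroes all of the focal station's
    observations instead.  Singular leave-out fits are excluded from the
    sum and counted.
    """
    allowed = {ScaleState.LOG10_CENTERED} | ({ScaleState.LOG10} if allow_uncentered else set())
    if table.scale_state not in allowed:
        raise StateError("cv_score expects a log10_centered table (or allow_uncentered=True)")
    return _cv_from_workspace(_Workspace(table), k, kernel, loo)


@dataclass
class BandwidthSelection:
    """Grid of candidate neighbourhood sizes with their LOO-CV scores."""

    k_grid: list = field(default_factory=list)
    cv_scores: list = field(default_factory=list)
    n_excluded: list = field(default_factory=list)
    selected_k: int = 0

    def to_dict(self) -> dict:
        return {
            "k_grid": list(map(int, self.k_grid)),
            "cv_scores": list(map(float, self.cv_scores)),
            "n_excluded": list(map(int, self.n_excluded)),
            "selected_k": int(self.selected_k),
        }


def select_bandwidth(
    table: ObservationTable,
    k_grid: Optional[Sequence[int]] = None,
    kernel: str = "bisquare",
    loo: str = "obs",
    allow_uncentered: bool = False,
) -> BandwidthSelection:
    """Exhaustive LOO-CV search over a grid of neighbourhood sizes.

    Default grid: 10, 20, ... up to the number of observations (or just
    ``[n]`` for tiny tables).  Ties are broken toward the smaller k.
    """
    allowed = {ScaleState.LOG10_CENTERED} | ({ScaleState.LOG10} if allow_uncentered else set())
    if table.scale_state not in allowed:
        raise StateError("select_bandwidth expects a log10_centered table (or allow_uncentered=True)")
    ws = _Workspace(table)
    if k_grid is None:
        k_grid = list(range(10, ws.n + 1, 10)) or [ws.n]
    k_grid = sorted(int(k) for k in k_grid)
    if not k_grid:
        raise ConfigurationError("k_grid must be non-empty")
    scores, excl = [], []
    for k in k_grid:
        cv = _cv_from_workspace(ws, k, kernel, loo)
        scores.append(cv.score)
        excl.append(cv.n_excluded)
    best = int(np.argmin(scores))  # first minimum -> smallest k on ties
    if scores.count(min(scores)) > 1:
        logger.info("select_bandwidth: tie in CV scores, choosing smaller k=%d", k_grid[best])
    sel = BandwidthSelection(list(k_grid), scores, excl, k_grid[best])
    logger.info("select_bandwidth: grid=%s selected_k=%d", list(k_grid), sel.selected_k)
    return sel
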