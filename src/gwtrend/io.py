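"""Reading and writing long-format observation tables and result tables.

Input is CSV with a header row; column names are configurable through a
``column_map`` (logical name -> actual header).  Coordinates must be planar
projected metres: tables whose coordinates all fit inside the geographic
longitude/latitude envelope are rejected with a message instructing the user
to project first, since Euclidean distances on degrees are meaningless.

Results are written either as CSV (full float precision, round-trip safe to
better than 12 significant digits) or as RFC 7946 GeoJSON Point features.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .table import CORE_COLUMNS, OPTIONAL_COLUMNS, ObservationTable, ScaleState

logger = logging.getLogger("gwtrend")

DEFAULT_COLUMNS = {c: c for c in CORE_COLUMNS + OPTIONAL_COLUMNS}

#: columns of a written result table, in order
RESULT_COLUMNS = [
    "station_id", "x", "y", "n_obs", "intercept", "slope",
    "se_intercept", "se_slope", "t_slope", "p_slope", "signif_class",
    "local_r2", "bandwidth_dist", "k",
]

_FLOAT_FMT = "%.17g"


def _looks_geographic(x: np.ndarray, y: np.ndarray) -> bool:
    # Projected national grids are in metres; an entire table inside the
    # lon/lat envelope is almost certainly unprojected coordinates.
    return bool(
        len(x)
        and np.nanmax(np.abs(x)) <= 180.0
        and np.nanmax(np.abs(y)) <= 90.0
    )


def read_observations(
    path: str,
    column_map: Optional[Mapping[str, str]] = None,
    scale_state: ScaleState = ScaleState.RAW,
    allow_geographic: bool = False,
) -> ObservationTable:
    """Read a long-format observation CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Mapping from logical names (``station_id, x, y, year, value`` and
        optionally ``program, month``) to the actual column headers.
        Unmapped logical names default to themselves.
    scale_state
        Scale of the value column in the file (default raw concentration).
    allow_geographic
        Skip the lon/lat envelope rejection (for deliberately tiny toy
        coordinate systems).

    Returns
    -------
    ObservationTable
        In the given scale state, input row order preserved.  Duplicate
        (station, year) rows are retained: multiple observations per
        location are a feature of the method, not an error.
    """
    if not os.path.exists(path):
        raise ConfigurationError(f"input file not found: {path}")
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown logical column names: {sorted(unknown)}")
        colmap.update(column_map)

    raw = pd.read_csv(path)
    missing = [colmap[c] for c in CORE_COLUMNS if colmap[c] not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"missing required column(s) {missing} in {path}; "
            f"available: {list(raw.columns)}"
        )

    out = pd.DataFrame({"station_id": raw[colmap["station_id"]]})
    for logical in ("x", "y", "year", "value"):
        col = pd.to_numeric(raw[colmap[logical]], errors="coerce")
        bad = col.isna() & ~raw[colmap[logical]].isna() | raw[colmap[logical]].isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValidationError(
                f"column '{colmap[logical]}' fails to parse as a number at data row {row + 1}"
            )
        out[logical] = col
    for logical in OPTIONAL_COLUMNS:
        if colmap[logical] in raw.columns:
            out[logical] = raw[colmap[logical]]

    if not allow_geographic and _looks_geographic(out["x"].to_numpy(), out["y"].to_numpy()):
        raise ValidationError(
            "coordinates look like longitude/latitude degrees; project them to a "
            "planar metric system (e.g. a national grid) before analysis"
        )

    table = ObservationTable(out, scale_state=scale_state)
    logger.info(
        "read_observations: %s -> %d rows, %d stations (scale=%s)",
        path, table.n_obs, table.n_stations, table.scale_state.value,
    )
    return table


def write_observations(table: ObservationTable, path: str) -> None:
    """Write an observation table back to CSV at full float precision."""
    table.df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    logger.info("write_observations: %d rows -> %s", table.n_obs, path)


def _result_frame(result, alpha: float) -> pd.DataFrame:
    # imported lazily to avoid an import cycle with analysis
    from .analysis import significance_classes

    fits = result.fits.copy()
    fits["signif_class"] = significance_classes(result, alpha=alpha).to_numpy()
    fits["k"] = result.k
    return fits[RESULT_COLUMNS]


def write_results(result, path: str, format: str = "csv", alpha: float = 0.05) -> None:
    """Write a fitted GWR result, one row/feature per station.

    ``format="csv"`` writes the columns in :data:`RESULT_COLUMNS`;
    ``format="geojson"`` writes an RFC 7946 FeatureCollection of Points with
    the same fields as properties.  Numeric fields survive a CSV round trip
    to better than 12 significant digits.
    """
    if result is None or len(result.fits) == 0:
        raise ValidationError("cannot write an empty result")
    frame = _result_frame(result, alpha)
    if format == "csv":
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif format == "geojson":
        features = []
        for rec in frame.to_dict(orient="records"):
            geom = {"type": "Point", "coordinates": [rec["x"], rec["y"]]}
            props = {k: (None if isinstance(v, float) and np.isnan(v) else v)
                     for k, v in rec.items() if k not in ("x", "y")}
            props["x"] = rec["x"]
            props["y"] = rec["y"]
            features.append({"type": "Feature", "geometry": geom, "properties": props})
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        raise ConfigurationError(f"unknown result format: {format!r} (use 'csv' or 'geojson')")
    logger.info("write_results: %d stations -> %s (%s)", len(frame), path, format)


def read_results(path: str) -> pd.DataFrame:
    """Read back a result CSV written by :func:`write_results`."""
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"result file {path} is missing columns {missing}")
    return df
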