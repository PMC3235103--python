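"""Growth-rate and biomass estimation from optical-density time series.

The maximal growth rate is the highest slope of a loess smooth of
natural-log OD, evaluated on a dense time grid — i.e., the steepest
log-linear stretch of the curve. The local fit is cubic (tricube weights):
for derivative estimation a quadratic carries a large one-sided boundary
bias when the steepest stretch sits at the start of the record (15%
overshoot on a logistic benchmark, in our hands and in R's loess alike),
while the cubic's extra term absorbs the curvature change and keeps the
recovered rate within ~1% there and exact on log-linear input. Biomass
production is OD at 24 h minus OD at the start. Readings at or below the
instrument baseline (OD 0.04) are excluded from the log fit rather than
imputed, since growth during lag occurs below the detection limit.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import GrowthFit, ODSeries
from .synthetic_data import OD_BASELINE

__all__ = ["max_growth_rate", "biomass_production", "plate_summary"]

_GRID_STEP = 0.05  # hours; evaluation grid for the smooth
_MIN_POINTS = 12


_LOESS_DEGREE = 3


def _loess_slopes(
    t: np.ndarray, y: np.ndarray, span: float, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fitted values and first derivatives of a tricube-weighted local
    cubic regression of y on t, evaluated at ``grid``."""
    deg = _LOESS_DEGREE
    n = t.size
    k = min(max(int(np.ceil(span * n)), deg + 4), n)
    d = np.abs(t[None, :] - grid[:, None])  # (g, n)
    dmax = np.partition(d, k - 1, axis=1)[:, k - 1]
    dmax = np.where(dmax <= 0, np.finfo(float).eps, dmax)
    u = np.clip(d / dmax[:, None], 0.0, 1.0)
    w = (1.0 - u**3) ** 3
    x = t[None, :] - grid[:, None]
    X = np.stack([x**p for p in range(deg + 1)], axis=2)  # (g, n, deg+1)
    A = np.einsum("gn,gni,gnj->gij", w, X, X)
    bvec = np.einsum("gn,gni,n->gi", w, X, y)
    A = A + 1e-12 * np.eye(deg + 1)[None, :, :]
    beta = np.linalg.solve(A, bvec[:, :, None])[:, :, 0]
    return beta[:, 0], beta[:, 1]


def max_growth_rate(series: ODSeries, span: float = 0.2) -> GrowthFit:
    """Maximal per-hour slope of log OD from a loess (local cubic) smooth.

    Parameters
    ----------
    series : ODSeries
        OD readings; values at or below the 0.04 baseline are dropped.
    span : float
        Loess span as a fraction of retained points (default 0.2).

    Returns
    -------
    GrowthFit
        ``max_rate`` (per hour) and ``t_at_max`` (hours); ``biomass`` is
        left NaN (see :func:`biomass_production`).
    """
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    mask = series.od > OD_BASELINE + 1e-12
    t = series.times[mask]
    od = series.od[mask]
    if t.size < _MIN_POINTS:
        raise ValueError(
            f"only {t.size} readings above the OD {OD_BASELINE} baseline; "
            f"need >= {_MIN_POINTS} for the loess fit"
        )
    if np.any(od <= 0):
        raise ValueError("non-positive OD after baseline handling")
    y = np.log(od)
    grid = np.arange(t.min(), t.max() + 1e-12, _GRID_STEP)
    _, slope = _loess_slopes(t, y, span, grid)
    i = int(np.argmax(slope))
    return GrowthFit(max_rate=float(slope[i]), t_at_max=float(grid[i]))


def biomass_production(series: ODSeries) -> float:
    """OD at 24 h minus OD at the start (nearest readings within 0.25 h)."""
    i0 = int(np.argmin(np.abs(series.times - 0.0)))
    i24 = int(np.argmin(np.abs(series.times - 24.0)))
    if abs(series.times[i0]) > 0.25:
        raise ValueError("no reading within 0.25 h of the start")
    if abs(series.times[i24] - 24.0) > 0.25:
        raise ValueError("no reading within 0.25 h of 24 h")
    return float(series.od[i24] - series.od[i0])


def plate_summary(
    plate: Sequence[ODSeries],
    well_map: Union[pd.DataFrame, Mapping[str, Mapping]],
    span: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well growth fits joined to colony metadata, plus colony summaries.

    ``well_map`` maps ``well_id`` to at least ``colony_id`` and ``ploidy``
    (DataFrame with a ``well_id`` column, or a dict of dicts). Unmapped
    wells are excluded with a warning. Colony summaries are mean +/- SE
    over replicate wells; output ordering is by colony then well, so it is
    invariant to the input row order.
    """
    if not plate:
        raise ValueError("empty plate")
    if isinstance(well_map, pd.DataFrame):
        meta = {row["well_id"]: dict(row) for _, row in well_map.iterrows()}
    else:
        meta = {k: dict(v) for k, v in well_map.items()}

    rows = []
    for series in plate:
        if series.well_id not in meta:
            warnings.warn(f"well {series.well_id!r} not in well map; excluded", UserWarning)
            continue
        info = meta[series.well_id]
        fit = max_growth_rate(series, span=span)
        rows.append(
            {
                "well_id": series.well_id,
                "colony_id": info.get("colony_id"),
                "ploidy": info.get("ploidy"),
                "generation": info.get("generation", np.nan),
                "max_rate": fit.max_rate,
                "t_at_max": fit.t_at_max,
                "biomass": biomass_production(series),
            }
        )
    if not rows:
        raise ValueError("no mapped wells on the plate")
    wells = pd.DataFrame(rows).sort_values(["colony_id", "well_id"]).reset_index(drop=True)

    def _se(v: pd.Series) -> float:
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    colonies = (
        wells.groupby(["colony_id", "ploidy"], dropna=False)
        .agg(
            n_wells=("well_id", "count"),
            rate_mean=("max_rate", "mean"),
            rate_se=("max_rate", _se),
            biomass_mean=("biomass", "mean"),
            biomass_se=("biomass", _se),
        )
        .reset_index()
        .sort_values("colony_id")
        .reset_index(drop=True)
    )
    return wells, colonies
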