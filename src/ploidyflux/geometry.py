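"""Prolate-spheroid cell morphometrics.

Budding yeast cells are well approximated by prolate spheroids (ellipsoids
of revolution about the major axis). From a cell's full major axis L and
minor axis W (both in um, L >= W) we compute:

    volume          V    = pi * L * W^2 / 6
    eccentricity    e    = sqrt(1 - (W/L)^2)
    surface area    SA   = 2*pi*b^2 * (1 + (a/(b*e)) * asin(e)),
                           a = L/2, b = W/2   (sphere limit pi*W^2 at e -> 0)
    shape ratio     SA/V

Diploid cells are roughly twice the volume of haploids, so SA/V — the
quantity that constrains nutrient uptake per unit cytoplasm — is the shape
descriptor of biological interest when comparing ploidies.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import CellMeasurement

__all__ = [
    "volume",
    "eccentricity",
    "surface_area",
    "sa_v_ratio",
    "shape_table",
]

# below this eccentricity the closed form 2*pi*b^2*(1 + a/(b e) asin e)
# is evaluated through the asin(e)/e series to avoid 0/0
_E_SERIES_CUTOFF = 1e-6


def _check_axes(L, W) -> tuple[np.ndarray, np.ndarray]:
    L = np.asarray(L, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(L <= 0) or np.any(W <= 0):
        raise ValueError("axes must be positive")
    if np.any(W > L * (1 + 1e-12)):
        raise ValueError("minor axis W exceeds major axis L; swap-correct first")
    return L, W


def volume(L, W):
    """Prolate-spheroid volume pi*L*W^2/6 (um^3) from full axes L >= W > 0."""
    L, W = _check_axes(L, W)
    out = np.pi * L * W**2 / 6.0
    return float(out) if out.ndim == 0 else out


def eccentricity(L, W):
    """Eccentricity sqrt(1 - (W/L)^2); 0 for a sphere, -> 1 for a rod."""
    L, W = _check_axes(L, W)
    ratio = np.minimum(W / L, 1.0)
    out = np.sqrt(1.0 - ratio**2)
    return float(out) if out.ndim == 0 else out


def surface_area(L, W):
    """Prolate-spheroid surface area (um^2) from full axes L >= W > 0.

    Uses SA = 2*pi*b^2*(1 + (a/(b*e))*asin(e)) with semi-axes a = L/2,
    b = W/2; for e below 1e-6 the asin(e)/e factor is replaced by its
    Maclaurin series (1 + e^2/6 + 3e^4/40) so the sphere limit pi*W^2 is
    returned exactly rather than through a 0/0.
    """
    L, W = _check_axes(L, W)
    a = L / 2.0
    b = W / 2.0
    e = np.sqrt(np.clip(1.0 - (b / a) ** 2, 0.0, 1.0))
    # asin(e)/e, series-stabilised near the sphere
    small = e < _E_SERIES_CUTOFF
    safe_e = np.where(small, 1.0, e)
    factor = np.where(
        small,
        1.0 + e**2 / 6.0 + 3.0 * e**4 / 40.0,
        np.arcsin(np.clip(safe_e, -1.0, 1.0)) / safe_e,
    )
    out = 2.0 * np.pi * b**2 * (1.0 + (a / b) * factor)
    return float(out) if out.ndim == 0 else out


def sa_v_ratio(L, W):
    """Surface area to volume ratio (um^-1)."""
    return surface_area(L, W) / volume(L, W)


def _swap_corrected(measurements: Iterable[CellMeasurement]) -> list[CellMeasurement]:
    fixed = []
    n_swapped = 0
    for m in measurements:
        if m.W > m.L:
            n_swapped += 1
            m = CellMeasurement(m.cell_id, m.colony_id, m.ploidy, m.W, m.L)
        fixed.append(m)
    if n_swapped:
        warnings.warn(
            f"swapped major/minor axes for {n_swapped} cell(s) with W > L",
            UserWarning,
            stacklevel=3,
        )
    return fixed


def shape_table(
    measurements: Sequence[CellMeasurement],
    group_by: Sequence[str] = ("colony_id", "ploidy"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell shape descriptors plus grouped mean +/- SE summaries.

    Parameters
    ----------
    measurements : list of CellMeasurement
        Axis measurements; W > L entries are swap-corrected with a warning
        (manual ellipse drawing can transpose axes).
    group_by : sequence of str
        Columns of the per-cell table to aggregate over (subset of
        ``colony_id``, ``ploidy``).

    Returns
    -------
    (cells, summary)
        ``cells`` has one row per cell with V, SA, e and SA/V; ``summary``
        carries mean, SE (sd/sqrt(n)) and n per group and descriptor.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("shape_table needs at least one measurement")
    measurements = _swap_corrected(measurements)

    cells = pd.DataFrame(
        {
            "cell_id": [m.cell_id for m in measurements],
            "colony_id": [m.colony_id for m in measurements],
            "ploidy": [m.ploidy for m in measurements],
            "L_um": [m.L for m in measurements],
            "W_um": [m.W for m in measurements],
        }
    )
    L = cells["L_um"].to_numpy()
    W = cells["W_um"].to_numpy()
    cells["V"] = volume(L, W)
    cells["SA"] = surface_area(L, W)
    cells["e"] = eccentricity(L, W)
    cells["sa_v"] = cells["SA"] / cells["V"]

    keys = [k for k in group_by if k in ("colony_id", "ploidy")]
    if not keys:
        raise ValueError("group_by must include 'colony_id' and/or 'ploidy'")
    long = cells.melt(
        id_vars=keys, value_vars=["V", "SA", "e", "sa_v"],
        var_name="descriptor", value_name="value",
    )
    grouped = long.groupby(keys + ["descriptor"], dropna=False)["value"]
    summary = grouped.agg(
        mean="mean",
        se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n="count",
    ).reset_index()
    return cells, summary
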