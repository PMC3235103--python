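"""Ploidy calling from flow cytometry and aneuploidy screening from coverage.

Colony-level ploidy is called by clustering G1-peak fluorescence positions
with exact one-dimensional k-means (k = 2): because optimal 1-D clusters
are contiguous in sorted order, enumerating the n-1 threshold splits finds
the global within-cluster sum-of-squares optimum without any dependence on
initialisation. Population-level diploid fractions come from hydroxyurea-
arrested histograms: arrest collapses the G1/G2 ambiguity (a haploid G2
peak sits exactly on a diploid G1 peak), so a gate at 1.5x the haploid G1
position separates the ploidies up to a known arrest-escape fraction,
which is corrected analytically.

Aneuploidy screening compares each chromosome's share of mapped sequenced
sites against its share of mappable reference sites; a whole extra
chromosome shifts that ratio to ~2x in haploids and ~1.5x in diploids,
so flags are raised midway, at >= 1.4 or <= 0.6.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .datatypes import FlowSample, PloidyCallSet

__all__ = [
    "g1_peak",
    "call_ploidy",
    "diploid_fraction",
    "frequency_change",
    "coverage_ratios",
]

_MIN_EVENTS = 1000
_MODE_DENSITY_FLOOR = 0.10  # qualifying modes must reach 10% of the max density
GATE_MULTIPLIER = 1.5  # gate at 1.5x the haploid G1 peak (c/2c midpoint region)
FLAG_HIGH = 1.4
FLAG_LOW = 0.6


def g1_peak(sample: FlowSample, grid_points: int = 1024) -> float:
    """Position of the lowest-fluorescence mode of the event density.

    The density is a Gaussian KDE with Silverman's bandwidth; local maxima
    below 10% of the global density maximum are ignored (debris shoulders),
    and the lowest qualifying mode — the G1 peak — is returned.
    """
    ev = sample.events
    if ev.size < _MIN_EVENTS:
        raise ValueError(f"need >= {_MIN_EVENTS} events, got {ev.size}")
    kde = gaussian_kde(ev, bw_method="silverman")
    grid = np.linspace(ev.min(), ev.max(), grid_points)
    dens = kde(grid)
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    is_max = np.zeros_like(dens, dtype=bool)
    is_max[1:-1] = interior
    is_max[0] = dens[0] >= dens[1]
    is_max[-1] = dens[-1] >= dens[-2]
    qualifying = is_max & (dens >= _MODE_DENSITY_FLOOR * dens.max())
    if not qualifying.any():  # pragma: no cover - defensive
        raise ValueError("no qualifying density mode found")
    return float(grid[np.argmax(qualifying)])


def _best_split(sorted_vals: np.ndarray) -> tuple[int, float]:
    """Minimal two-cluster WSS over all contiguous splits of sorted values."""
    n = sorted_vals.size
    best = (1, np.inf)
    for i in range(1, n):
        left, right = sorted_vals[:i], sorted_vals[i:]
        wss = float(((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum())
        if wss < best[1]:
            best = (i, wss)
    return best


def call_ploidy(
    peaks: Mapping[str, float],
    anchors: Optional[tuple[float, float]] = None,
) -> PloidyCallSet:
    """Cluster colony G1-peak positions into haploid/diploid groups (k = 2).

    Parameters
    ----------
    peaks : mapping colony_id -> G1-peak fluorescence
    anchors : (haploid_ref, diploid_ref), optional
        Control-sample peak positions; when given they join the clustering
        and the cluster containing the haploid control is labelled 1N.
        Without anchors the lower-centroid cluster is 1N.

    The 1-D k-means optimum is found exactly by enumerating sorted splits.
    """
    ids = list(peaks)
    vals = np.array([float(peaks[i]) for i in ids])
    pts = vals.copy()
    labels = list(ids)
    if anchors is not None:
        hap_ref, dip_ref = float(anchors[0]), float(anchors[1])
        pts = np.append(pts, [hap_ref, dip_ref])
        labels += ["__hap_anchor__", "__dip_anchor__"]
    if len(pts) < 2:
        raise ValueError("need >= 2 colonies, or >= 1 colony plus anchors")
    if np.ptp(pts) == 0:
        raise ValueError("no separation: all peak positions identical")

    order = np.argsort(pts, kind="stable")
    sorted_pts = pts[order]
    split, wss_k2 = _best_split(sorted_pts)
    wss_k1 = float(((pts - pts.mean()) ** 2).sum())

    low_set = {labels[j] for j in order[:split]}
    if anchors is not None and "__hap_anchor__" not in low_set:
        # anchors force orientation; haploid control in the upper cluster
        # would mean the controls themselves are inseparable
        if "__dip_anchor__" in low_set:
            raise ValueError("anchors fall in the same cluster; cannot orient")
    assignments = {cid: (1 if cid in low_set else 2) for cid in ids}
    return PloidyCallSet(
        peaks={cid: float(peaks[cid]) for cid in ids},
        assignments=assignments,
        wss_k1=wss_k1,
        wss_k2=wss_k2,
    )


def diploid_fraction(
    sample: FlowSample,
    haploid_peak: float,
    escape_fraction: float = 0.10,
    gate_multiplier: float = GATE_MULTIPLIER,
) -> float:
    """Diploid fraction of an arrested sample, corrected for arrest escape.

    Events above the gate (``gate_multiplier`` x the haploid G1 peak,
    default 1.5x — midway between the haploid c and diploid 2c peaks) are
    counted as diploid. Under the two-peak arrest model a fraction
    ``escape_fraction`` of haploids escapes to its G2 position (2c, above
    the gate), so the raw above-gate fraction satisfies
    raw = d + (1 - d) * esc and the corrected estimate is
    (raw - esc) / (1 - esc), clipped to [0, 1]. (Escaped diploids move from
    2c to 4c and stay above the gate, so they need no correction.)
    """
    if not sample.arrested:
        raise ValueError("diploid_fraction requires an arrested sample")
    if haploid_peak <= 0:
        raise ValueError("haploid_peak must be > 0")
    if not (0.0 <= escape_fraction < 1.0):
        raise ValueError("escape_fraction must be in [0, 1)")
    gate = gate_multiplier * haploid_peak
    ev = sample.events
    if ev.size < _MIN_EVENTS:
        raise ValueError(f"need >= {_MIN_EVENTS} events, got {ev.size}")
    if gate <= 0 or gate >= 4.0 * float(np.max(ev)):
        raise ValueError("gate falls outside the plausible data range")
    raw = float(np.mean(ev > gate))
    corrected = (raw - escape_fraction) / (1.0 - escape_fraction)
    return float(np.clip(corrected, 0.0, 1.0))


def frequency_change(day0: float, day14: float) -> float:
    """Change in diploid frequency over a competition (day14 - day0)."""
    for v in (day0, day14):
        if not (0.0 <= v <= 1.0):
            raise ValueError("fractions must be in [0, 1]")
    return day14 - day0


def coverage_ratios(
    coverage: pd.DataFrame,
    flag_high: float = FLAG_HIGH,
    flag_low: float = FLAG_LOW,
) -> pd.DataFrame:
    """Per-chromosome relative coverage ratios with aneuploidy flags.

    ``coverage`` needs columns ``chromosome``, ``mapped_sites`` and
    ``ref_sites``. The ratio for chromosome c is its share of mapped sites
    divided by its share of reference sites; euploid chromosomes sit near
    1.0 while a whole-chromosome gain shifts the ratio toward 2x (haploid)
    or 1.5x (diploid), so ratios >= ``flag_high`` or <= ``flag_low`` are
    flagged.
    """
    required = {"chromosome", "mapped_sites", "ref_sites"}
    if not required.issubset(coverage.columns):
        raise ValueError(f"coverage table needs columns {sorted(required)}")
    counts = coverage["mapped_sites"].to_numpy(dtype=float)
    ref = coverage["ref_sites"].to_numpy(dtype=float)
    if np.any(counts < 0) or np.any(ref < 0):
        raise ValueError("site counts must be non-negative")
    if ref.sum() <= 0:
        raise ValueError("zero reference total")
    if counts.sum() <= 0:
        raise ValueError("zero mapped total")
    ratio = (counts / counts.sum()) / (ref / ref.sum())
    out = coverage[["chromosome"]].copy()
    out["ratio"] = ratio
    out["flag"] = (ratio >= flag_high) | (ratio <= flag_low)
    return out
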