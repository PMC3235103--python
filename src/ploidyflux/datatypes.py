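"""Shared domain types for the batch-culture ploidy toolkit.

The types mirror the objects handled in a serial-transfer evolution
experiment: strain growth parameters, the daily transfer protocol, the
within-cycle population state, and the records produced by the standard
assays (optical-density time series, cell axis measurements, competition
count tables, flow-cytometry event lists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "StrainParams",
    "TransferProtocol",
    "SimState",
    "SimConfig",
    "ODSeries",
    "CellMeasurement",
    "CompetitionAssay",
    "FlowSample",
    "GrowthFit",
    "FitResult",
    "TestResult",
    "PloidyCallSet",
    "ExtinctCultureError",
    "ConvergenceError",
    "SaturatedAssayError",
]


class ExtinctCultureError(RuntimeError):
    """Raised when a culture has no cells left to propagate."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SaturatedAssayError(ValueError):
    """Raised when competition fractions are degenerate (all 0 or all 1)."""


@dataclass(frozen=True)
class StrainParams:
    """Growth and morphology parameters for one strain.

    Attributes
    ----------
    strain_id : str
        Unique label.
    ploidy : int
        1 (haploid) or 2 (diploid).
    lag : float
        Hours of no growth after transfer into fresh medium (>= 0).
    growth_rate : float
        Maximal exponential growth rate r during log phase, per hour (> 0).
    yield_per_cell : float
        Glucose consumed per new cell produced, mg (> 0).
    fds_slope : float
        Frequency-dependence coefficient b, per generation: the strain's
        Malthusian advantage gains b * (1 - f) where f is its own frequency.
        b > 0 means an advantage when rare that declines with frequency.
    mean_volume : float
        Mean single-cell volume, um^3.
    eccentricity : float
        Target prolate-spheroid eccentricity in [0, 1).
    """

    strain_id: str
    ploidy: int
    lag: float
    growth_rate: float
    yield_per_cell: float
    fds_slope: float
    mean_volume: float
    eccentricity: float

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be > 0")
        if self.yield_per_cell <= 0:
            raise ValueError("yield_per_cell must be > 0")
        if not (0.0 <= self.eccentricity < 1.0):
            raise ValueError("eccentricity must be in [0, 1)")
        if self.mean_volume <= 0:
            raise ValueError("mean_volume must be > 0")


@dataclass(frozen=True)
class TransferProtocol:
    """Daily serial-transfer regime (default: 1:101 dilution in 10 mL every 24 h)."""

    dilution_factor: float = 101.0
    culture_volume: float = 10.0  # mL
    period: float = 24.0  # hours between transfers
    n_days: int = 1

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.culture_volume <= 0 or self.period <= 0:
            raise ValueError("culture_volume and period must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    @property
    def generations_per_transfer(self) -> float:
        """Population doublings imposed per transfer: log2(dilution_factor)."""
        return math.log2(self.dilution_factor)


@dataclass
class SimState:
    """Population state within one transfer cycle."""

    counts: dict  # strain_id -> cell count (>= 0)
    resource: float  # glucose remaining, mg (>= 0)
    time_in_cycle: float = 0.0  # hours

    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class SimConfig:
    """Full configuration for a multi-day evolution simulation."""

    seed: int
    strains: Sequence[StrainParams]
    protocol: TransferProtocol
    initial_counts: Mapping[str, float]
    od_noise_sd: float = 0.002
    count_noise: str = "binomial"  # "binomial" | "none"
    diploidization_rate: float = 0.0  # per cell per generation, 1N -> 2N

    def __post_init__(self) -> None:
        if self.count_noise not in ("binomial", "none"):
            raise ValueError("count_noise must be 'binomial' or 'none'")
        if not (0.0 <= self.diploidization_rate <= 1e-2):
            raise ValueError("diploidization_rate must be in [0, 1e-2]")
        known = {s.strain_id for s in self.strains}
        unknown = set(self.initial_counts) - known
        if unknown:
            raise ValueError(f"initial_counts for unknown strains: {sorted(unknown)}")


@dataclass
class ODSeries:
    """Optical-density time series for one plate well."""

    well_id: str
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have the same length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class CellMeasurement:
    """Major/minor axis measurement (um) for one cell."""

    cell_id: str
    colony_id: str
    ploidy: Optional[int]
    L: float  # major axis
    W: float  # minor axis


@dataclass
class CompetitionAssay:
    """Fluorescent/non-fluorescent counts over generations for one replicate."""

    replicate_id: str
    T: np.ndarray  # generations, non-decreasing
    n_nonfluor: np.ndarray
    n_fluor: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.n_nonfluor = np.asarray(self.n_nonfluor)
        self.n_fluor = np.asarray(self.n_fluor)
        if not (self.T.shape == self.n_nonfluor.shape == self.n_fluor.shape):
            raise ValueError("T, n_nonfluor, n_fluor must share one length")
        if np.any(np.diff(self.T) < 0):
            raise ValueError("T must be non-decreasing")
        tot = self.n_nonfluor + self.n_fluor
        if np.any(tot <= 0):
            raise ValueError("each observation needs n_nonfluor + n_fluor > 0")
        if np.unique(self.T).size < 2:
            raise ValueError("need >= 2 distinct generation values")

    @property
    def fractions(self) -> np.ndarray:
        """Observed non-fluorescent fraction per time point."""
        tot = (self.n_nonfluor + self.n_fluor).astype(float)
        return self.n_nonfluor / tot


@dataclass
class FlowSample:
    """Per-event fluorescence values for one flow-cytometry sample."""

    sample_id: str
    events: np.ndarray
    arrested: bool = False

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.size and np.any(self.events <= 0):
            raise ValueError("all fluorescence events must be > 0")


@dataclass
class GrowthFit:
    """Growth-curve summary: maximal log-OD slope and biomass gain."""

    max_rate: float  # per hour
    t_at_max: float  # hours
    biomass: float = float("nan")  # OD(24 h) - OD(start)
    flags: list = field(default_factory=list)


@dataclass
class FitResult:
    """Competition-model fit: initial fraction and Malthusian difference."""

    p0_hat: float
    m_hat: float  # per generation
    rss: float
    n_obs: int


@dataclass
class TestResult:
    """Outcome of a statistical test."""

    statistic: float
    df: float
    p_value: float
    tail: str  # "two" | "greater" | "less"
    estimate: float = float("nan")
    note: str = ""


@dataclass
class PloidyCallSet:
    """k-means (k=2) ploidy assignment over colony G1-peak positions."""

    peaks: dict  # colony_id -> G1 peak position
    assignments: dict  # colony_id -> 1 or 2
    wss_k1: float
    wss_k2: float
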