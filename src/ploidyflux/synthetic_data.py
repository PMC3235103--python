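"""Forward simulation of a serial-transfer batch-culture evolution experiment.

The simulated system is a haploid *S. cerevisiae* population in YPD that is
diluted 1:101 into 10 mL of fresh medium every 24 h (about 6.66 population
doublings per day). Within a cycle each strain

1. sits idle for its lag phase,
2. grows exponentially at an effective per-hour rate
       h_i = r_i * (1 + b_i * (1 - f_i) / ln 2),
   where r_i is the strain's maximal growth rate, f_i its current
   frequency, and b_i a per-generation Malthusian frequency-dependence
   coefficient (b > 0: advantage when rare, declining with own frequency;
   the factor r_i/ln2 converts a per-generation advantage into a per-hour
   rate using the strain's instantaneous doubling rate),
3. stops when the shared glucose pool is exhausted (every new cell of
   strain i consumes ``yield_per_cell_i`` mg of glucose).

No diauxic/ethanol phase is modelled: growth halts at glucose exhaustion.
Haploids may spontaneously diploidize at a small per-cell per-generation
rate, seeding the diploid invasions the assays are designed to detect.

On top of the population dynamics the module fabricates every assay input
the analysis stages consume: Bioscreen-style 48 h OD curves, arrested and
unarrested flow-cytometry samples, prolate-spheroid cell measurements,
competition count tables, and HPLC-style glucose depletion series.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .datatypes import (
    CellMeasurement,
    CompetitionAssay,
    ExtinctCultureError,
    FlowSample,
    ODSeries,
    SimConfig,
    SimState,
    StrainParams,
    TransferProtocol,
)

__all__ = [
    "GLUCOSE_INIT_PCT",
    "OD_BASELINE",
    "OD_PER_BIOVOLUME",
    "initial_resource",
    "make_initial_state",
    "autodiploid_params",
    "simulate_cycle",
    "bottleneck",
    "simulate_evolution",
    "generate_od_curve",
    "generate_flow_sample",
    "generate_cell_measurements",
    "generate_competition_counts",
    "generate_glucose_series",
]

_LN2 = math.log(2.0)

GLUCOSE_INIT_PCT = 2.0  # % w/v glucose in fresh YPD (standard recipe)
OD_BASELINE = 0.04  # Bioscreen detection floor, OD units

# OD per (um^3 of cells per mL). Calibrated so the reference ancestral
# haploid (60 um^3, 2e-7 mg glucose per new cell) saturates near OD 1.3
# in 10 mL: ~1.01e9 cells * 60 um^3 / 10 mL = 6.06e9 um^3/mL at 24 h.
OD_PER_BIOVOLUME = 1.3 / 6.06e9

_FLOW_CV = 0.08  # fluorescence peak coefficient of variation
_G2_SHARE_CYCLING = 0.35  # fraction of an unarrested population in G2


def initial_resource(culture_volume_ml: float) -> float:
    """Glucose mass (mg) in a fresh culture of the given volume at 2% w/v."""
    return GLUCOSE_INIT_PCT / 100.0 * culture_volume_ml * 1000.0


def make_initial_state(
    counts: Mapping[str, float], protocol: TransferProtocol
) -> SimState:
    """Fresh-medium state with full glucose and the given cell counts."""
    return SimState(
        counts=dict(counts),
        resource=initial_resource(protocol.culture_volume),
        time_in_cycle=0.0,
    )


def autodiploid_params(haploid: StrainParams, volume_ratio: float = 1.82) -> StrainParams:
    """Diploid derivative of a haploid strain produced by genome doubling.

    Growth kinetics are inherited; cell volume and per-cell glucose yield
    scale by the empirical diploid/haploid volume ratio (about 1.8), and
    eccentricity moves to the typical diploid value.
    """
    if haploid.ploidy != 1:
        raise ValueError("autodiploid_params expects a haploid strain")
    return replace(
        haploid,
        strain_id=haploid.strain_id + "_2N",
        ploidy=2,
        yield_per_cell=haploid.yield_per_cell * volume_ratio,
        mean_volume=haploid.mean_volume * volume_ratio,
        eccentricity=0.57,
    )


def _od_from_counts(counts: np.ndarray, volumes: np.ndarray, culture_volume: float) -> float:
    return OD_PER_BIOVOLUME * float(np.dot(counts, volumes)) / culture_volume


def simulate_cycle(
    state: SimState,
    strains: Sequence[StrainParams],
    protocol: TransferProtocol,
    record_times: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, SimState]:
    """Integrate one growth cycle (lag -> exponential -> glucose exhaustion).

    Parameters
    ----------
    state : SimState
        Starting counts and glucose; ``resource`` must be positive.
    strains : sequence of StrainParams
        Parameters for every strain appearing in ``state.counts``.
    protocol : TransferProtocol
        Supplies cycle length and culture volume.
    record_times : array, optional
        Times (h) at which to record the trajectory; defaults to an hourly
        grid over the cycle.

    Returns
    -------
    (trajectory, final_state)
        ``trajectory`` has columns ``time_h``, ``resource_mg``, ``od`` and
        one ``count_<strain_id>`` column per strain; ``final_state`` is the
        saturated pre-bottleneck state.
    """
    ids = [s.strain_id for s in strains]
    n0 = np.array([float(state.counts.get(i, 0.0)) for i in ids])
    if np.any(n0 < 0):
        raise ValueError("cell counts must be non-negative")
    if n0.sum() <= 0:
        raise ExtinctCultureError("extinct culture")
    if state.resource <= 0:
        raise ValueError("cycle must start with resource > 0")

    period = protocol.period
    if record_times is None:
        record_times = np.arange(0.0, period + 1e-9, 1.0)
    record_times = np.asarray(record_times, dtype=float)
    if record_times.size and (record_times.min() < -1e-9 or record_times.max() > period + 1e-9):
        raise ValueError("record_times must lie within the cycle period")

    alive = n0 > 0
    r = np.array([s.growth_rate for s in strains])[alive]
    b = np.array([s.fds_slope for s in strains])[alive]
    lag = np.array([s.lag for s in strains])[alive]
    yld = np.array([s.yield_per_cell for s in strains])[alive]
    volumes = np.array([s.mean_volume for s in strains])

    # piecewise integration: strain lags partition the cycle into segments
    # with a fixed set of actively growing strains
    breaks = sorted({0.0, period} | {float(x) for x in lag if 0.0 < x < period})
    x = np.log(n0[alive])
    resource = float(state.resource)
    exhausted = False
    # each segment contributes (t0, t1, evaluator(t) -> (x_alive, resource))
    segments: list[tuple[float, float, Callable]] = []

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        grow = (lag <= t0 + 1e-12) & (not exhausted)
        if not grow.any() or exhausted:
            xs, rs = x.copy(), resource

            def const_eval(t, xs=xs, rs=rs):
                return xs, rs

            segments.append((t0, t1, const_eval))
            continue

        grow_mask = grow.copy()

        def rhs(t, y, grow_mask=grow_mask):
            N = np.exp(y[:-1])
            f = N / N.sum()
            h = np.where(grow_mask, r * (1.0 + b * (1.0 - f) / _LN2), 0.0)
            dR = -float(np.dot(yld, h * N))
            return np.append(h, dR)

        def out_of_glucose(t, y):
            return y[-1]

        out_of_glucose.terminal = True
        out_of_glucose.direction = -1

        y0 = np.append(x, resource)
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y0,
            method="RK45",
            rtol=1e-10,
            atol=np.append(np.full(x.size, 1e-12), 1e-9),
            dense_output=True,
            events=out_of_glucose,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"cycle integration failed: {sol.message}")
        t_end = float(sol.t[-1])

        def ode_eval(t, sol=sol, t_end=t_end):
            tt = min(t, t_end)
            y = sol.sol(tt)
            return y[:-1], max(float(y[-1]), 0.0)

        segments.append((t0, t1, ode_eval))
        x, resource = ode_eval(t1)
        if sol.status == 1:  # glucose exhausted inside this segment
            exhausted = True
            resource = 0.0

    def eval_at(t: float) -> tuple[np.ndarray, float]:
        t = min(max(t, 0.0), period)
        for t0, t1, fn in segments:
            if t <= t1 + 1e-12:
                return fn(max(t, t0))
        return segments[-1][2](period)  # pragma: no cover

    n_rec = record_times.size
    counts_rec = np.zeros((n_rec, len(ids)))
    resource_rec = np.zeros(n_rec)
    od_rec = np.zeros(n_rec)
    for k, t in enumerate(record_times):
        xa, R = eval_at(float(t))
        full = np.zeros(len(ids))
        full[alive] = np.exp(xa)
        counts_rec[k] = full
        resource_rec[k] = R
        od_rec[k] = _od_from_counts(full, volumes, protocol.culture_volume)

    traj = pd.DataFrame({"time_h": record_times, "resource_mg": resource_rec, "od": od_rec})
    for j, sid in enumerate(ids):
        traj[f"count_{sid}"] = counts_rec[:, j]

    final_counts = np.zeros(len(ids))
    xa, R = eval_at(period)
    final_counts[alive] = np.exp(xa)
    final = SimState(
        counts={sid: float(c) for sid, c in zip(ids, final_counts)},
        resource=R,
        time_in_cycle=period,
    )
    return traj, final


def bottleneck(
    state: SimState,
    protocol: TransferProtocol,
    rng: Optional[np.random.Generator] = None,
    count_noise: str = "binomial",
) -> SimState:
    """Transfer 1/D of the culture into fresh medium.

    With ``count_noise="binomial"`` each strain's surviving count is a
    binomial draw with success probability 1/D (independent across strains;
    at ~1e9 cells this is indistinguishable from multivariate hypergeometric
    sampling). With ``"none"`` counts are divided by D and rounded. Glucose
    is reset to the fresh-medium level.
    """
    if state.total() <= 0:
        raise ExtinctCultureError("extinct culture")
    D = protocol.dilution_factor
    new_counts = {}
    for sid, c in state.counts.items():
        if c <= 0:
            new_counts[sid] = 0.0
        elif count_noise == "none":
            new_counts[sid] = float(round(c / D))
        else:
            if rng is None:
                raise ValueError("binomial bottleneck requires an rng")
            new_counts[sid] = float(rng.binomial(int(round(c)), 1.0 / D))
    return SimState(
        counts=new_counts,
        resource=initial_resource(protocol.culture_volume),
        time_in_cycle=0.0,
    )


def _apply_diploidization(
    state: SimState,
    strains: Sequence[StrainParams],
    rate: float,
    gens: float,
    rng: np.random.Generator,
    companion: Mapping[str, str],
) -> None:
    """Convert a binomial share of each haploid strain to its 2N companion."""
    if rate <= 0:
        return
    p_cycle = 1.0 - (1.0 - rate) ** gens
    for s in strains:
        if s.ploidy != 1:
            continue
        n = state.counts.get(s.strain_id, 0.0)
        if n <= 0:
            continue
        k = rng.binomial(int(round(n)), p_cycle)
        if k:
            state.counts[s.strain_id] = n - k
            cid = companion[s.strain_id]
            state.counts[cid] = state.counts.get(cid, 0.0) + k


def simulate_evolution(config: SimConfig) -> pd.DataFrame:
    """Run the full serial-transfer experiment for ``protocol.n_days`` days.

    Each day composes :func:`simulate_cycle` (growth to saturation),
    stochastic haploid-to-diploid conversion, and :func:`bottleneck`.
    Frequencies are recorded at saturation (pre-bottleneck), matching when
    the experimental samples were drawn.

    Returns a tidy table with columns ``day``, ``strain``, ``frequency``
    and ``diploid_fraction``.
    """
    rng = np.random.default_rng(config.seed)
    strains = list(config.strains)
    companion: dict[str, str] = {}
    if config.diploidization_rate > 0:
        existing = {s.strain_id for s in strains}
        for s in list(strains):
            if s.ploidy == 1:
                d = autodiploid_params(s)
                companion[s.strain_id] = d.strain_id
                if d.strain_id not in existing:
                    strains.append(d)
                    existing.add(d.strain_id)

    ploidy_of = {s.strain_id: s.ploidy for s in strains}
    state = make_initial_state(
        {s.strain_id: float(config.initial_counts.get(s.strain_id, 0.0)) for s in strains},
        config.protocol,
    )

    rows = []

    def record(day: int) -> None:
        tot = state.total()
        if tot <= 0:
            raise ExtinctCultureError("extinct culture")
        dip = sum(c for sid, c in state.counts.items() if ploidy_of[sid] == 2) / tot
        for sid in (s.strain_id for s in strains):
            rows.append(
                {
                    "day": day,
                    "strain": sid,
                    "frequency": state.counts.get(sid, 0.0) / tot,
                    "diploid_fraction": dip,
                }
            )

    record(0)
    gens = config.protocol.generations_per_transfer
    for day in range(1, config.protocol.n_days + 1):
        _, state = simulate_cycle(state, strains, config.protocol)
        _apply_diploidization(
            state, strains, config.diploidization_rate, gens, rng, companion
        )
        record(day)
        if day < config.protocol.n_days:
            state = bottleneck(state, config.protocol, rng, config.count_noise)
    return pd.DataFrame(rows)


def generate_od_curve(
    strain: StrainParams,
    protocol: TransferProtocol,
    noise_sd: float,
    rng: Optional[np.random.Generator] = None,
    duration: float = 48.0,
    interval: float = 0.25,
    well_id: str = "A1",
) -> ODSeries:
    """Bioscreen-style OD series: 15-min reads over 48 h for a monoculture.

    The deterministic curve comes from :func:`simulate_cycle` started from
    a 1/D inoculum of a saturated culture; i.i.d. Gaussian read noise is
    added and the series floored at the instrument baseline (OD 0.04).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    long_protocol = replace(protocol, period=duration)
    n0 = initial_resource(protocol.culture_volume) / (
        strain.yield_per_cell * (protocol.dilution_factor - 1.0)
    )
    state = make_initial_state({strain.strain_id: n0}, long_protocol)
    times = np.arange(0.0, duration + 1e-9, interval)
    traj, _ = simulate_cycle(state, [strain], long_protocol, record_times=times)
    det = np.maximum(traj["od"].to_numpy(), OD_BASELINE)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        od = np.maximum(det + rng.normal(0.0, noise_sd, size=det.size), OD_BASELINE)
    else:
        od = det
    return ODSeries(well_id=well_id, times=times, od=od)


def generate_flow_sample(
    n_events: int,
    diploid_fraction: float,
    arrested: bool,
    escape_fraction: float,
    rng: np.random.Generator,
    g1_haploid: float = 100.0,
    cv: float = _FLOW_CV,
    g2_share: float = _G2_SHARE_CYCLING,
    sample_id: str = "S1",
) -> FlowSample:
    """Synthesize a DNA-content histogram for a haploid/diploid mixture.

    Unarrested cells split between G1 and G2 peaks (haploid: c and 2c,
    diploid: 2c and 4c) so the haploid G2 peak coincides with the diploid
    G1 peak. Hydroxyurea arrest concentrates each ploidy at its G1 peak
    except for an ``escape_fraction`` of cells remaining at G2. Peaks are
    Gaussian with CV ~8%.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not (0.0 <= diploid_fraction <= 1.0 and 0.0 <= escape_fraction <= 1.0):
        raise ValueError("fractions must be in [0, 1]")
    is_dip = rng.random(n_events) < diploid_fraction
    base = np.where(is_dip, 2.0 * g1_haploid, g1_haploid)
    p_double = escape_fraction if arrested else g2_share
    doubled = rng.random(n_events) < p_double
    mean = base * np.where(doubled, 2.0, 1.0)
    events = rng.normal(mean, cv * mean)
    events = np.clip(events, 1e-6, None)
    return FlowSample(sample_id=sample_id, events=events, arrested=arrested)


def generate_cell_measurements(
    strain: StrainParams,
    n_cells: int,
    cv: float,
    rng: np.random.Generator,
    colony_id: Optional[str] = None,
) -> list[CellMeasurement]:
    """Draw prolate-spheroid axis measurements matching a strain's morphology.

    Major axes are log-normal with spread ``cv``; minor axes follow the
    strain's target eccentricity with independent log-normal noise of
    spread ``cv/2``. The log-normal location is chosen so the expected
    recomputed volume equals ``strain.mean_volume`` exactly.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    colony_id = colony_id or strain.strain_id
    e = strain.eccentricity
    axis_ratio = math.sqrt(1.0 - e**2)  # W/L
    L_target = (6.0 * strain.mean_volume / (math.pi * axis_ratio**2)) ** (1.0 / 3.0)
    s_l = cv
    s_w = cv / 2.0
    # E[pi/6 L^3 (W/L)^2] = mean_volume requires this log-location shift
    mu = math.log(L_target) - 1.5 * s_l**2 - (2.0 / 3.0) * s_w**2
    L = np.exp(rng.normal(mu, s_l, size=n_cells)) if cv > 0 else np.full(n_cells, math.exp(mu))
    w_noise = np.exp(rng.normal(0.0, s_w, size=n_cells)) if cv > 0 else np.ones(n_cells)
    W = np.minimum(L * axis_ratio * w_noise, L)
    return [
        CellMeasurement(
            cell_id=f"{colony_id}_c{i:04d}",
            colony_id=colony_id,
            ploidy=strain.ploidy,
            L=float(L[i]),
            W=float(W[i]),
        )
        for i in range(n_cells)
    ]


def generate_competition_counts(
    p0: float,
    m: float,
    days: Iterable[int],
    dilution: float,
    n_events: int,
    rng: np.random.Generator,
    replicate_id: str = "R1",
) -> CompetitionAssay:
    """Simulate daily flow counts for a marked-competitor assay.

    At day d the elapsed generations are T = d*log2(D); the true
    non-fluorescent fraction follows the two-type Malthusian model
    p0*e^{mT} / (p0*e^{mT} + 1 - p0) and observed counts are binomial
    samples of ``n_events`` cells.
    """
    from .competition import predicted_fraction  # local import; one-way dependency

    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    days = np.asarray(list(days), dtype=float)
    T = days * math.log2(dilution)
    frac = np.array([predicted_fraction(p0, m, t) for t in T])
    n_non = rng.binomial(n_events, frac)
    return CompetitionAssay(
        replicate_id=replicate_id,
        T=T,
        n_nonfluor=n_non,
        n_fluor=n_events - n_non,
    )


def generate_glucose_series(
    strains: Sequence[StrainParams],
    counts: Mapping[str, float],
    times: Iterable[float],
    protocol: Optional[TransferProtocol] = None,
) -> pd.DataFrame:
    """Glucose depletion curve (% w/v) for a mixed culture over 0-24 h.

    Glucose starts at 2% w/v and decreases by the yield-weighted number of
    new cells produced, so populations with equal summed consumption give
    identical curves regardless of how many (or how large) their cells are.
    """
    protocol = protocol or TransferProtocol()
    times = np.asarray(sorted(times), dtype=float)
    if times.size == 0:
        raise ValueError("need at least one time point")
    if times.min() < 0 or times.max() > 24.0:
        raise ValueError("times must lie within [0, 24] hours")
    state = make_initial_state(counts, protocol)
    r0 = state.resource
    traj, _ = simulate_cycle(state, strains, protocol, record_times=times)
    glucose = GLUCOSE_INIT_PCT * traj["resource_mg"].to_numpy() / r0
    return pd.DataFrame({"time_h": times, "glucose_pct": glucose})
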