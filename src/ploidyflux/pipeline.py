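"""End-to-end scenario runs: simulate -> assay -> analyse -> report.

Three built-in scenarios exercise the full closed loop (simulated raw
assay data analysed by the same estimators a real experiment would use):

- ``neutral``: haploids and diploids with identical kinetics at 50:50.
  Every assay and test should come out null.
- ``diploid_fds``: equal maximal growth rates, but both ploidies gain a
  linear Malthusian advantage when rare (b = 0.08/generation each), giving
  a stable interior equilibrium at frequency 0.5. Diploids seeded at 1%
  rise past 20% within two weeks while monoculture growth-rate, biomass
  and lag assays detect no diploid advantage — the central paradox this
  package exists to demonstrate: standard fitness components are blind to
  frequency-dependent advantages.
- ``late_sweeper``: a diploid lineage with the same maximal growth rate
  but a shorter lag seeded at 5%; it fixes even though the growth-rate
  assay sees nothing.

Outputs are deterministic given the seed; every table carries a config
hash in its provenance header so re-runs can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .competition import fitness_table
from .datatypes import (
    ODSeries,
    SimConfig,
    SimState,
    StrainParams,
    TransferProtocol,
)
from .geometry import shape_table
from .growthcurves import plate_summary
from .ploidy import diploid_fraction, frequency_change, g1_peak
from .stats import fisher_exact_2x2, welch_t
from .synthetic_data import (
    generate_cell_measurements,
    generate_competition_counts,
    generate_flow_sample,
    generate_od_curve,
    make_initial_state,
    simulate_cycle,
    simulate_evolution,
)
from . import io as pfio

__all__ = [
    "RunConfig",
    "RunReport",
    "build_scenario",
    "run_scenario",
    "replay_replicate_evolution",
    "paradox_trial",
    "polymorphism_span",
]

_LN2 = math.log(2.0)

SCENARIOS = ("neutral", "diploid_fds", "late_sweeper", "custom")

# Baseline strain kinetics: YPD-typical maximal rate ~0.5/h, brief lag,
# yields tuned so a saturated 10 mL culture holds ~1e9 haploid cells.
_HAPLOID_DEFAULTS = dict(
    ploidy=1, lag=1.5, growth_rate=0.5, yield_per_cell=2.0e-7,
    fds_slope=0.0, mean_volume=60.0, eccentricity=0.47,
)
# Diploid volume and per-cell glucose demand scale together (110/60), so
# the two ploidies consume glucose at the same population rate with fewer,
# larger diploid cells.
_DIPLOID_DEFAULTS = dict(
    ploidy=2, lag=1.5, growth_rate=0.5, yield_per_cell=2.0e-7 * 110.0 / 60.0,
    fds_slope=0.0, mean_volume=110.0, eccentricity=0.57,
)
_TOTAL_INOCULUM = 1.0e7  # cells transferred into 10 mL fresh medium
_FDS_B = 0.08  # per-generation rare-type advantage in the diploid_fds scenario


@dataclass
class RunConfig:
    """Configuration for a scenario run; unknown keys are rejected."""

    seed: int
    scenario: str = "neutral"
    n_days: int = 14
    n_colonies_per_ploidy: int = 5
    wells_per_colony: int = 7
    cells_per_colony: int = 15
    cell_cv: float = 0.12
    flow_events: int = 30000
    competition_events: int = 10000
    competition_replicates: int = 4
    n_tubes: int = 0
    spike_fraction: float = 0.0  # extra sweeper-diploid inoculum for replay
    loess_span: float = 0.2
    gate_multiplier: float = 1.5
    escape_fraction: float = 0.10
    dilution: float = 101.0
    od_noise_sd: float = 0.002
    strains: Optional[list] = None  # for scenario == "custom"
    initial_frequencies: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.scenario == "custom" and not self.strains:
            raise ValueError("custom scenario needs explicit strains")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Tables plus provenance for one scenario run."""

    tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = " ".join(f"{k}={v}" for k, v in self.provenance.items())
        for name, df in self.tables.items():
            pfio.write_table(df, out / f"{name}.tsv", provenance=header)


def polymorphism_span(first_diploid_gen: float, last_haploid_gen: float) -> float:
    """Generations over which haploids and diploids coexisted in a time
    series: last generation a haploid was sampled minus the first
    generation a diploid was sampled."""
    if last_haploid_gen < first_diploid_gen:
        raise ValueError("last haploid generation precedes first diploid generation")
    return last_haploid_gen - first_diploid_gen


def _haploid(strain_id: str = "hap", **over) -> StrainParams:
    return StrainParams(strain_id=strain_id, **{**_HAPLOID_DEFAULTS, **over})


def _diploid(strain_id: str = "dip", **over) -> StrainParams:
    return StrainParams(strain_id=strain_id, **{**_DIPLOID_DEFAULTS, **over})


def build_scenario(config: RunConfig) -> SimConfig:
    """Materialise the strain set and initial counts for a scenario."""
    if config.scenario == "neutral":
        strains = [_haploid(), _diploid()]
        freqs = {"hap": 0.5, "dip": 0.5}
    elif config.scenario == "diploid_fds":
        strains = [_haploid(fds_slope=_FDS_B), _diploid(fds_slope=_FDS_B)]
        freqs = {"hap": 0.99, "dip": 0.01}
    elif config.scenario == "late_sweeper":
        strains = [_haploid(), _diploid("dip_sweeper", lag=0.5)]
        freqs = {"hap": 0.95, "dip_sweeper": 0.05}
    else:  # custom
        strains = list(config.strains)
        freqs = dict(config.initial_frequencies or {})
        if not freqs:
            freqs = {s.strain_id: 1.0 / len(strains) for s in strains}
    counts = {sid: f * _TOTAL_INOCULUM for sid, f in freqs.items()}
    protocol = TransferProtocol(
        dilution_factor=config.dilution, n_days=config.n_days
    )
    return SimConfig(
        seed=config.seed,
        strains=strains,
        protocol=protocol,
        initial_counts=counts,
        od_noise_sd=config.od_noise_sd,
        count_noise="binomial",
    )


def pairwise_malthusian(
    strain: StrainParams, competitor: StrainParams, protocol: TransferProtocol
) -> float:
    """Per-generation Malthusian difference of ``strain`` vs ``competitor``.

    Measured the way the wet assay defines it: one noise-free 50:50
    co-culture cycle, logit frequency change divided by the generations
    per transfer.
    """
    if strain.strain_id == competitor.strain_id:
        return 0.0  # self-competition is neutral by definition
    state = make_initial_state(
        {strain.strain_id: _TOTAL_INOCULUM / 2, competitor.strain_id: _TOTAL_INOCULUM / 2},
        protocol,
    )
    _, final = simulate_cycle(state, [strain, competitor], protocol)
    f1 = final.counts[strain.strain_id] / final.total()
    d_logit = math.log(f1 / (1 - f1))  # started at logit 0
    return d_logit / protocol.generations_per_transfer


def _growth_plate(config: RunConfig, sim: SimConfig, rng: np.random.Generator):
    """Simulated Bioscreen plate: wells_per_colony wells for each colony."""
    plate: list[ODSeries] = []
    well_rows = []
    w = 0
    for strain in sim.strains:
        for c in range(config.n_colonies_per_ploidy):
            colony = f"{strain.strain_id}_col{c + 1}"
            for _ in range(config.wells_per_colony):
                w += 1
                well = f"W{w:03d}"
                plate.append(
                    generate_od_curve(
                        strain, sim.protocol, config.od_noise_sd, rng, well_id=well
                    )
                )
                well_rows.append(
                    {"well_id": well, "colony_id": colony, "ploidy": strain.ploidy}
                )
    return plate, pd.DataFrame(well_rows)


def _test_row(name: str, res) -> dict:
    return {
        "test": name,
        "statistic": res.statistic,
        "df": res.df,
        "p": res.p_value,
        "estimate": res.estimate,
        "tail": res.tail,
        "note": res.note,
    }


def run_scenario(config: RunConfig, out_dir=None) -> RunReport:
    """Run a full scenario: evolution, growth, geometry, competition and
    ploidy assays, plus the Welch/Fisher tests the assays call for.

    Returns a :class:`RunReport`; if ``out_dir`` is given all tables are
    also written as TSV with a provenance header.
    """
    rng = np.random.default_rng(config.seed)
    sim = build_scenario(config)
    report = RunReport(
        provenance={
            "package": "ploidyflux",
            "version": __version__,
            "seed": config.seed,
            "scenario": config.scenario,
            "config_hash": config.config_hash(),
        }
    )
    tests = []

    # --- evolution ---------------------------------------------------
    evo = simulate_evolution(sim)
    report.tables["evolution"] = evo

    # --- growth-curve assay ------------------------------------------
    plate, well_map = _growth_plate(config, sim, rng)
    wells, colonies = plate_summary(plate, well_map, span=config.loess_span)
    report.tables["growth_wells"] = wells
    report.tables["growth_colonies"] = colonies
    hap_rates = colonies.loc[colonies["ploidy"] == 1, "rate_mean"].to_numpy()
    dip_rates = colonies.loc[colonies["ploidy"] == 2, "rate_mean"].to_numpy()
    hap_bio = colonies.loc[colonies["ploidy"] == 1, "biomass_mean"].to_numpy()
    dip_bio = colonies.loc[colonies["ploidy"] == 2, "biomass_mean"].to_numpy()
    if hap_rates.size >= 2 and dip_rates.size >= 2:
        tests.append(_test_row("growth_rate_hap_vs_dip", welch_t(hap_rates, dip_rates)))
        tests.append(_test_row("biomass_hap_vs_dip", welch_t(hap_bio, dip_bio)))

    # --- cell geometry ------------------------------------------------
    cells = []
    for strain in sim.strains:
        for c in range(config.n_colonies_per_ploidy):
            cells.extend(
                generate_cell_measurements(
                    strain,
                    config.cells_per_colony,
                    config.cell_cv,
                    rng,
                    colony_id=f"{strain.strain_id}_col{c + 1}",
                )
            )
    cell_df, shape_summary = shape_table(cells)
    report.tables["shapes"] = cell_df
    report.tables["shape_summary"] = shape_summary
    hap_v = cell_df.loc[cell_df["ploidy"] == 1, "V"].to_numpy()
    dip_v = cell_df.loc[cell_df["ploidy"] == 2, "V"].to_numpy()
    if hap_v.size >= 2 and dip_v.size >= 2:
        tests.append(_test_row("volume_hap_vs_dip", welch_t(hap_v, dip_v)))

    # --- competition against a common competitor ---------------------
    competitor = _haploid("competitor")
    assays, meta = [], {}
    for strain in sim.strains:
        m_true = pairwise_malthusian(strain, competitor, sim.protocol)
        for c in range(config.n_colonies_per_ploidy):
            colony = f"{strain.strain_id}_col{c + 1}"
            for r in range(config.competition_replicates):
                rid = f"{colony}_r{r + 1}"
                assays.append(
                    generate_competition_counts(
                        0.5, m_true, [0, 1, 2, 3], config.dilution,
                        config.competition_events, rng, replicate_id=rid,
                    )
                )
                meta[rid] = {"colony_id": colony, "ploidy": strain.ploidy}
    reps, comp_colonies = fitness_table(assays, meta)
    report.tables["competition_replicates"] = reps
    report.tables["competition_colonies"] = comp_colonies
    hap_m = comp_colonies.loc[comp_colonies["ploidy"] == 1, "m_mean"].to_numpy()
    dip_m = comp_colonies.loc[comp_colonies["ploidy"] == 2, "m_mean"].to_numpy()
    if hap_m.size >= 2 and dip_m.size >= 2:
        tests.append(_test_row("competition_m_hap_vs_dip", welch_t(hap_m, dip_m)))

    # --- closed-loop ploidy dynamics ----------------------------------
    final_day = evo["day"].max()
    true0 = float(evo.loc[evo["day"] == 0, "diploid_fraction"].iloc[0])
    true1 = float(evo.loc[evo["day"] == final_day, "diploid_fraction"].iloc[0])
    cal = generate_flow_sample(
        10000, 0.0, True, config.escape_fraction, rng, sample_id="hap_control"
    )
    hap_peak = g1_peak(cal)
    s0 = generate_flow_sample(
        config.flow_events, true0, True, config.escape_fraction, rng, sample_id="day0"
    )
    s1 = generate_flow_sample(
        config.flow_events, true1, True, config.escape_fraction, rng,
        sample_id=f"day{final_day}",
    )
    est0 = diploid_fraction(s0, hap_peak, config.escape_fraction, config.gate_multiplier)
    est1 = diploid_fraction(s1, hap_peak, config.escape_fraction, config.gate_multiplier)
    gate = config.gate_multiplier * hap_peak
    n_dip0 = int(np.sum(s0.events > gate))
    n_dip1 = int(np.sum(s1.events > gate))
    report.tables["ploidy_dynamics"] = pd.DataFrame(
        [
            {
                "day_start": 0,
                "day_end": int(final_day),
                "true_start": true0,
                "true_end": true1,
                "est_start": est0,
                "est_end": est1,
                "delta_est": frequency_change(est0, est1),
            }
        ]
    )
    fisher = fisher_exact_2x2(
        [
            [n_dip0, config.flow_events - n_dip0],
            [n_dip1, config.flow_events - n_dip1],
        ]
    )
    tests.append(_test_row("diploid_freq_day0_vs_end_fisher", fisher))

    report.tables["tests"] = pd.DataFrame(tests)
    if out_dir is not None:
        report.write(out_dir)
    return report


def replay_replicate_evolution(config: RunConfig, out_dir=None) -> pd.DataFrame:
    """Replicate-tube evolution: per-tube change in diploid frequency.

    Each tube independently re-runs the scenario for ``n_days`` days; the
    start and end diploid fractions are estimated through the full closed
    loop (arrested flow samples analysed with the ploidy module against a
    haploid calibration control), not read off the simulator truth. With
    ``spike_fraction > 0`` an extra shorter-lag diploid lineage is mixed
    into the inoculum, mimicking spiking late-sweeping diploid culture
    into an earlier population sample. ``n_tubes = 0`` returns an empty
    table.
    """
    cols = ["tube", "true_start", "true_end", "est_start", "est_end", "delta_est"]
    if config.n_tubes == 0:
        return pd.DataFrame(columns=cols)
    base = build_scenario(config)
    rows = []
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_tubes)
    for tube, ss in enumerate(seeds, start=1):
        rng = np.random.default_rng(ss)
        tube_seed = int(rng.integers(0, 2**31 - 1))
        counts = dict(base.initial_counts)
        strains = list(base.strains)
        if config.spike_fraction > 0:
            sweeper = _diploid("dip_spike", lag=0.5)
            strains.append(sweeper)
            total = sum(counts.values())
            counts = {k: v * (1 - config.spike_fraction) for k, v in counts.items()}
            counts[sweeper.strain_id] = config.spike_fraction * total
        sim = SimConfig(
            seed=tube_seed,
            strains=strains,
            protocol=base.protocol,
            initial_counts=counts,
            od_noise_sd=base.od_noise_sd,
            count_noise=base.count_noise,
        )
        evo = simulate_evolution(sim)
        final_day = evo["day"].max()
        true0 = float(evo.loc[evo["day"] == 0, "diploid_fraction"].iloc[0])
        true1 = float(evo.loc[evo["day"] == final_day, "diploid_fraction"].iloc[0])
        cal = generate_flow_sample(10000, 0.0, True, config.escape_fraction, rng)
        hap_peak = g1_peak(cal)
        s0 = generate_flow_sample(config.flow_events, true0, True, config.escape_fraction, rng)
        s1 = generate_flow_sample(config.flow_events, true1, True, config.escape_fraction, rng)
        est0 = diploid_fraction(s0, hap_peak, config.escape_fraction, config.gate_multiplier)
        est1 = diploid_fraction(s1, hap_peak, config.escape_fraction, config.gate_multiplier)
        rows.append(
            {
                "tube": tube,
                "true_start": true0,
                "true_end": true1,
                "est_start": est0,
                "est_end": est1,
                "delta_est": frequency_change(est0, est1),
            }
        )
    df = pd.DataFrame(rows, columns=cols)
    if out_dir is not None:
        pfio.write_table(
            df,
            Path(out_dir) / "replay.tsv",
            provenance=f"package=ploidyflux version={__version__} "
            f"seed={config.seed} config_hash={config.config_hash()}",
        )
    return df


def paradox_trial(
    seed: int,
    n_days: int = 14,
    n_colonies: int = 5,
    wells_per_colony: int = 3,
) -> dict:
    """One replicate of the frequency-dependence paradox experiment.

    Runs the ``diploid_fds`` scenario (equal maximal growth rates, rare-
    type advantage b = 0.08/generation, diploids seeded at 1%) and asks
    two questions: does the monoculture growth/biomass assay see a diploid
    advantage (it should not), and do diploids nevertheless rise past 20%?

    Returns a dict with the final diploid frequency, the Welch p-values,
    and the combined success flag.
    """
    config = RunConfig(
        seed=seed,
        scenario="diploid_fds",
        n_days=n_days,
        n_colonies_per_ploidy=n_colonies,
        wells_per_colony=wells_per_colony,
    )
    rng = np.random.default_rng(seed)
    sim = build_scenario(config)
    evo = simulate_evolution(sim)
    f_final = float(evo.loc[evo["day"] == evo["day"].max(), "diploid_fraction"].iloc[0])

    plate, well_map = _growth_plate(config, sim, rng)
    _, colonies = plate_summary(plate, well_map, span=config.loess_span)
    hap = colonies[colonies["ploidy"] == 1]
    dip = colonies[colonies["ploidy"] == 2]
    rate_t = welch_t(dip["rate_mean"].to_numpy(), hap["rate_mean"].to_numpy())
    bio_t = welch_t(dip["biomass_mean"].to_numpy(), hap["biomass_mean"].to_numpy())

    # "detectable advantage": the diploid-minus-haploid estimate exceeds
    # 2 SE in the advantage direction (one-sided by construction: only a
    # diploid advantage could explain the rise)
    def detected(res) -> bool:
        se = abs(res.estimate / res.statistic) if res.statistic != 0 else float("inf")
        return res.estimate > 2.0 * se

    no_assay_advantage = not detected(rate_t) and not detected(bio_t)
    rose = f_final > 0.2
    return {
        "seed": seed,
        "final_diploid_fraction": f_final,
        "growth_rate_p": rate_t.p_value,
        "biomass_p": bio_t.p_value,
        "rate_advantage_estimate": rate_t.estimate,
        "biomass_advantage_estimate": bio_t.estimate,
        "no_assay_advantage": no_assay_advantage,
        "diploids_rose": rose,
        "paradox_reproduced": bool(no_assay_advantage and rose),
    }
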