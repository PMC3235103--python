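"""Simulator checks against closed forms and conservation laws."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from ploidyflux.datatypes import (
    ExtinctCultureError,
    SimConfig,
    SimState,
    StrainParams,
    TransferProtocol,
)
from ploidyflux.synthetic_data import (
    GLUCOSE_INIT_PCT,
    OD_BASELINE,
    bottleneck,
    generate_cell_measurements,
    generate_competition_counts,
    generate_flow_sample,
    generate_glucose_series,
    generate_od_curve,
    initial_resource,
    make_initial_state,
    simulate_cycle,
    simulate_evolution,
)


def strain(sid="A", r=0.5, lag=0.0, b=0.0, yld=2e-7, vol=60.0, ploidy=1, e=0.47):
    return StrainParams(sid, ploidy, lag, r, yld, b, vol, e)


PROT = TransferProtocol()


class TestSimulateCycle:
    def test_symmetry_identical_strains(self):
        s1, s2 = strain("A"), strain("B")
        state = make_initial_state({"A": 5e6, "B": 5e6}, PROT)
        _, final = simulate_cycle(state, [s1, s2], PROT)
        tot = final.total()
        assert final.counts["A"] / tot == pytest.approx(0.5, abs=1e-12)

    def test_pure_exponential_closed_form(self):
        # effectively unlimited glucose: e^{r t} growth for t = 2 h
        c = strain("C", r=0.5, yld=1e-12)
        state = make_initial_state({"C": 1000.0}, PROT)
        traj, _ = simulate_cycle(state, [c], PROT, record_times=np.array([0.0, 2.0]))
        assert traj["count_C"].iloc[1] / 1000.0 == pytest.approx(math.e, rel=1e-9)

    def test_logit_change_matches_analytic_race(self):
        # two-strain exponential race: d logit(f_A) = (r_A - r_B) * t_exp
        a, b_ = strain("A", r=0.55), strain("B", r=0.50)
        state = make_initial_state({"A": 5e6, "B": 5e6}, PROT)
        _, final = simulate_cycle(state, [a, b_], PROT)
        fA = final.counts["A"] / final.total()
        d_logit = math.log(fA / (1 - fA))
        R0 = initial_resource(PROT.culture_volume)
        t_exp = brentq(
            lambda t: 5e6 * 2e-7 * ((np.exp(0.55 * t) - 1) + (np.exp(0.5 * t) - 1)) - R0,
            1.0,
            24.0,
        )
        assert d_logit == pytest.approx(0.05 * t_exp, rel=1e-8)

    def test_lag_delays_growth(self):
        s = strain("A", lag=2.0)
        state = make_initial_state({"A": 1e6}, PROT)
        traj, _ = simulate_cycle(state, [s], PROT, record_times=np.array([0.0, 1.0, 2.0, 3.0]))
        counts = traj["count_A"].to_numpy()
        assert counts[0] == counts[1] == counts[2] == pytest.approx(1e6)
        assert counts[3] > 1e6

    def test_resource_never_increases_and_growth_stops(self):
        s = strain("A")
        state = make_initial_state({"A": 1e7}, PROT)
        traj, final = simulate_cycle(state, [s], PROT)
        res = traj["resource_mg"].to_numpy()
        assert np.all(np.diff(res) <= 1e-9)
        assert final.resource == pytest.approx(0.0, abs=1e-6)
        # counts flat after exhaustion
        counts = traj["count_A"].to_numpy()
        sat = counts[-1]
        exhausted = res <= 1e-9
        assert np.allclose(counts[exhausted], sat, rtol=1e-9)

    def test_resource_conservation(self):
        # glucose consumed equals yield-weighted new cells, exactly
        a, b_ = strain("A", r=0.55), strain("B", r=0.45, yld=3e-7)
        state = make_initial_state({"A": 4e6, "B": 6e6}, PROT)
        traj, _ = simulate_cycle(state, [a, b_], PROT)
        used = initial_resource(PROT.culture_volume) - traj["resource_mg"]
        produced = 2e-7 * (traj["count_A"] - 4e6) + 3e-7 * (traj["count_B"] - 6e6)
        # exact up to the integrator's tolerance (rtol 1e-10 on ~1e9 cells)
        assert np.allclose(used, produced, rtol=1e-7, atol=1e-5)

    def test_extinct_culture_raises(self):
        state = SimState(counts={"A": 0.0}, resource=200.0)
        with pytest.raises(ExtinctCultureError, match="extinct"):
            simulate_cycle(state, [strain("A")], PROT)


class TestBottleneck:
    def test_deterministic_division(self):
        state = SimState(counts={"A": 101000.0}, resource=0.0)
        out = bottleneck(state, PROT, count_noise="none")
        assert out.counts["A"] == 1000.0
        assert out.resource == pytest.approx(initial_resource(PROT.culture_volume))

    def test_binomial_preserves_expected_frequency(self, rng):
        state = SimState(counts={"A": 60000.0, "B": 40000.0}, resource=0.0)
        freqs = []
        for _ in range(1000):
            out = bottleneck(state, PROT, rng)
            tot = out.total()
            if tot > 0:
                freqs.append(out.counts["A"] / tot)
        mean = np.mean(freqs)
        se = np.std(freqs, ddof=1) / math.sqrt(len(freqs))
        assert abs(mean - 0.6) < 3 * se + 1e-12

    def test_loss_probability_matches_binomial_mass_at_zero(self, rng):
        # P(strain with 50 cells lost) = (1 - 1/101)^50
        p_lose = (1 - 1 / 101) ** 50
        losses = 0
        n_rep = 4000
        for _ in range(n_rep):
            out = bottleneck(SimState(counts={"A": 50.0, "B": 50.0}, resource=0.0), PROT, rng)
            losses += out.counts["A"] == 0
        se = math.sqrt(p_lose * (1 - p_lose) / n_rep)
        assert abs(losses / n_rep - p_lose) < 4 * se


class TestSimulateEvolution:
    def test_neutral_diploid_fraction_constant_without_noise(self):
        cfg = SimConfig(
            seed=1,
            strains=[strain("h"), strain("d", ploidy=2, vol=110.0, yld=2e-7 * 110 / 60)],
            protocol=TransferProtocol(n_days=4),
            initial_counts={"h": 5e6, "d": 5e6},
            count_noise="none",
        )
        df = simulate_evolution(cfg)
        assert np.allclose(df["diploid_fraction"], 0.5, atol=1e-9)

    def test_rare_type_advantage_rises_then_plateaus(self):
        # symmetric b > 0: deterministic recursion predicts equilibrium 0.5
        cfg = SimConfig(
            seed=1,
            strains=[strain("h", b=0.08), strain("d", ploidy=2, b=0.08, vol=110.0, yld=2e-7 * 110 / 60)],
            protocol=TransferProtocol(n_days=30),
            initial_counts={"h": 9.9e6, "d": 1e5},
            count_noise="none",
        )
        df = simulate_evolution(cfg)
        frac = df.groupby("day")["diploid_fraction"].first()
        assert frac.loc[0] == pytest.approx(0.01)
        assert frac.is_monotonic_increasing
        assert frac.loc[30] == pytest.approx(0.5, abs=0.02)

    def test_neutral_drift_mean_change_near_zero(self):
        deltas = []
        for seed in range(30):
            cfg = SimConfig(
                seed=seed,
                strains=[strain("h"), strain("d", ploidy=2, vol=110.0, yld=2e-7 * 110 / 60)],
                protocol=TransferProtocol(n_days=14),
                initial_counts={"h": 5e6, "d": 5e6},
            )
            df = simulate_evolution(cfg)
            frac = df.groupby("day")["diploid_fraction"].first()
            deltas.append(frac.loc[14] - frac.loc[0])
        se = np.std(deltas, ddof=1) / math.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se + 1e-12

    def test_diploidization_seeds_diploids(self):
        cfg = SimConfig(
            seed=7,
            strains=[strain("h")],
            protocol=TransferProtocol(n_days=5),
            initial_counts={"h": 1e7},
            diploidization_rate=1e-4,
        )
        df = simulate_evolution(cfg)
        assert set(df["strain"]) == {"h", "h_2N"}
        final = df[df["day"] == 5]["diploid_fraction"].iloc[0]
        assert final > 0

    def test_determinism_byte_identical(self, tmp_path):
        from ploidyflux.io import write_table

        def run():
            cfg = SimConfig(
                seed=11,
                strains=[strain("h"), strain("d", ploidy=2, vol=110.0, yld=2e-7 * 110 / 60)],
                protocol=TransferProtocol(n_days=3),
                initial_counts={"h": 5e6, "d": 5e6},
            )
            return simulate_evolution(cfg)

        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_table(run(), p1)
        write_table(run(), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestODCurve:
    def test_noiseless_is_deterministic_curve(self):
        s1 = generate_od_curve(strain("A", lag=1.5), PROT, 0.0)
        s2 = generate_od_curve(strain("A", lag=1.5), PROT, 0.0)
        assert np.array_equal(s1.od, s2.od)
        assert s1.times[1] - s1.times[0] == 0.25
        assert s1.times[-1] == 48.0
        assert np.all(s1.od >= OD_BASELINE)

    def test_saturation_tracks_yield_and_volume(self):
        # saturation OD ~ (R0/yield) * volume: halving yield doubles it
        lo = generate_od_curve(strain("A", yld=2e-7), PROT, 0.0)
        hi = generate_od_curve(strain("A", yld=1e-7), PROT, 0.0)
        assert hi.od[-1] / lo.od[-1] == pytest.approx(2.0, rel=0.02)

    def test_seeded_reproducibility(self):
        a = generate_od_curve(strain("A"), PROT, 0.002, np.random.default_rng(5))
        b = generate_od_curve(strain("A"), PROT, 0.002, np.random.default_rng(5))
        assert np.array_equal(a.od, b.od)


class TestFlowSample:
    def test_pure_haploid_arrested_single_peak(self, rng):
        fs = generate_flow_sample(5000, 0.0, True, 0.0, rng)
        assert fs.events.mean() == pytest.approx(100.0, rel=0.01)
        assert fs.events.std() / fs.events.mean() == pytest.approx(0.08, rel=0.1)

    def test_diploid_haploid_mean_ratio_two(self, rng):
        hap = generate_flow_sample(20000, 0.0, True, 0.0, rng)
        dip = generate_flow_sample(20000, 1.0, True, 0.0, rng)
        assert dip.events.mean() / hap.events.mean() == pytest.approx(2.0, rel=0.01)

    def test_escape_fraction_creates_g2_shoulder(self, rng):
        fs = generate_flow_sample(30000, 0.0, True, 0.10, rng)
        frac_high = np.mean(fs.events > 150.0)
        assert frac_high == pytest.approx(0.10, abs=0.01)


class TestCellMeasurements:
    def test_spheres_when_cv_zero_and_e_zero(self, rng):
        s = strain("A", e=0.0, vol=65.0)
        cells = generate_cell_measurements(s, 10, 0.0, rng)
        assert all(c.L == pytest.approx(c.W, rel=1e-12) for c in cells)

    def test_large_sample_mean_volume(self, rng):
        from ploidyflux.geometry import volume

        s = strain("D", ploidy=2, vol=126.0, e=0.57)
        cells = generate_cell_measurements(s, 10000, 0.12, rng)
        mean_v = np.mean([volume(c.L, c.W) for c in cells])
        assert mean_v == pytest.approx(126.0, rel=0.01)

    def test_seeded_reproducibility(self):
        s = strain("A")
        c1 = generate_cell_measurements(s, 20, 0.1, np.random.default_rng(3))
        c2 = generate_cell_measurements(s, 20, 0.1, np.random.default_rng(3))
        assert [(c.L, c.W) for c in c1] == [(c.L, c.W) for c in c2]


class TestCompetitionCounts:
    def test_neutral_expectation_flat(self, rng):
        a = generate_competition_counts(0.5, 0.0, [0, 1, 2, 3], 101, 200000, rng)
        se = math.sqrt(0.25 / 200000)
        assert np.all(np.abs(a.fractions - 0.5) < 4 * se)

    def test_logit_closed_form_day_one(self, rng):
        a = generate_competition_counts(0.5, 0.1, [0, 1], 101, 2_000_000, rng)
        expected = math.exp(0.6658) / (1 + math.exp(0.6658))  # ~0.6606
        assert a.fractions[1] == pytest.approx(expected, abs=0.001)
        assert a.T[1] == pytest.approx(math.log2(101), rel=1e-12)


class TestGlucoseSeries:
    def test_initial_condition_and_lag(self):
        s = strain("A", lag=2.0)
        df = generate_glucose_series([s], {"A": 1e7}, [0, 1, 2, 4, 8, 24])
        assert df["glucose_pct"].iloc[0] == pytest.approx(GLUCOSE_INIT_PCT)
        assert np.allclose(df[df["time_h"] <= 2.0]["glucose_pct"], GLUCOSE_INIT_PCT)
        assert df["glucose_pct"].is_monotonic_decreasing

    def test_equal_consumption_identical_curves(self):
        # same r and summed yield*count trajectory -> same glucose curve,
        # despite 'fewer individual diploid cells'
        hap = strain("h", yld=2e-7, vol=60.0)
        dip = strain("d", ploidy=2, yld=4e-7, vol=120.0)
        t = [0, 2, 4, 6, 8, 24]
        g_h = generate_glucose_series([hap], {"h": 1e7}, t)
        g_d = generate_glucose_series([dip], {"d": 5e6}, t)
        assert np.allclose(g_h["glucose_pct"], g_d["glucose_pct"], rtol=1e-8)
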