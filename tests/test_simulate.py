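"""Label-propagation simulator: closed forms, oracles, noise, starch and
protein trajectories."""

import numpy as np
import pytest
from scipy.linalg import expm

from chloroflux.kinetics import LabelSeries
from chloroflux.simulate import (add_noise, mid_table, simulate_labeling,
                                 simulate_protein_labeling, simulate_starch,
                                 synthetic_enrichment_families)


def enrich(sim, met):
    return sim.enrichment(met)


class TestLabelingDynamics:
    def test_one_pool_closed_form(self, one_pool):
        # E(t) = a (1 - exp(-k t)), a = 0.5, k = v/P = 0.1
        sim = simulate_labeling(one_pool, [0.0, 10.0, 30.0])
        expected = 0.5 * (1 - np.exp(-0.1 * np.array([0.0, 10.0, 30.0])))
        assert np.allclose(enrich(sim, "A"), expected, atol=1e-8)
        assert enrich(sim, "A")[1] == pytest.approx(0.3161, abs=1e-4)

    def test_no_label_without_enrichment(self, minimal_chain):
        net = minimal_chain.with_parameters()
        net.inputs["CO2"] = 0.0
        sim = simulate_labeling(net, [0.0, 20.0, 100.0])
        for m in sim.mids:
            assert np.allclose(sim.enrichment(m), 0.0, atol=1e-12)

    def test_two_pool_series_matches_matrix_exponential(self, two_pool):
        # independent oracle: affine linear ODE on the two m+1 fractions,
        # x' = K (x - x_inf), solved by matrix exponential
        times = np.array([0.0, 3.0, 7.5, 20.0, 60.0])
        sim = simulate_labeling(two_pool, times)
        kA, kB = 0.1, 0.05
        K = np.array([[-kA, 0.0], [kB, -kB]])
        x_inf = np.array([0.5, 0.5])
        oracle = np.array([x_inf + expm(K * t) @ (-x_inf) for t in times])
        got = np.column_stack([enrich(sim, "A"), enrich(sim, "B")])
        assert np.abs(got - oracle).max() < 1e-6

    def test_enrichment_non_decreasing_under_step_labelling(self, cbc_toy):
        sim = simulate_labeling(cbc_toy, np.linspace(0, 60, 13))
        for m in sim.mids:
            assert np.all(np.diff(sim.enrichment(m)) > -1e-9)

    def test_dilution_caps_plateau(self, one_pool):
        net = one_pool.with_parameters(dilutions={"A": 0.4})
        sim = simulate_labeling(net, [0.0, 500.0])
        # plateau = (1 - d) * a
        assert enrich(sim, "A")[-1] == pytest.approx(0.6 * 0.5, abs=1e-6)

    def test_total_13c_bounded_by_input(self, cbc_toy):
        times = np.array([0.0, 5.0, 10.0, 20.0, 40.0])
        sim = simulate_labeling(cbc_toy, times)
        a = cbc_toy.inputs["CO2"]
        cin = cbc_toy.total_input_carbon_flux()
        for i, t in enumerate(times[1:], start=1):
            total13 = sum(
                sim.enrichment(m)[i] * cbc_toy.pools[m] * cbc_toy.n_carbons(m)
                for m in sim.mids)
            assert total13 <= a * cin * t + 1e-9

    def test_negative_time_rejected(self, one_pool):
        with pytest.raises(ValueError):
            simulate_labeling(one_pool, [-1.0, 5.0])


class TestNoise:
    def test_zero_sd_is_identity(self, one_pool):
        sim = simulate_labeling(one_pool, [5.0, 10.0])
        noisy = add_noise(sim, 0.0, seed=3)
        for m in sim.mids:
            assert np.allclose(noisy.mids[m], sim.mids[m])

    def test_seed_determinism(self, one_pool):
        sim = simulate_labeling(one_pool, [5.0, 10.0])
        a = add_noise(sim, 0.01, seed=11)
        b = add_noise(sim, 0.01, seed=11)
        c = add_noise(sim, 0.01, seed=12)
        assert np.array_equal(a.mids["A"], b.mids["A"])
        assert not np.array_equal(a.mids["A"], c.mids["A"])

    def test_montecarlo_sd_near_nominal(self, two_pool):
        sim = simulate_labeling(two_pool, [10.0])
        draws = np.array([add_noise(sim, 0.01, seed=s).mids["B"][0]
                          for s in range(1000)])
        # channels away from the [0, 1] boundary keep ~the nominal sd
        # (renormalization projects out the common mode: factor sqrt(1-1/2))
        emp = draws.std(axis=0)
        assert np.all(emp > 0.004) and np.all(emp < 0.012)

    def test_rows_stay_normalized(self, cbc_toy):
        sim = simulate_labeling(cbc_toy, [5.0, 40.0])
        noisy = add_noise(sim, 0.02, seed=5)
        for m, mids in noisy.mids.items():
            assert np.allclose(mids.sum(axis=1), 1.0)
            assert np.all(mids >= 0)


class TestStarch:
    def test_balanced_turnover_keeps_total_constant(self):
        df = simulate_starch(100.0, synth=50.0, degr=50.0,
                             times=np.linspace(0, 18000, 31))
        assert np.allclose(df["total_umolC"], df["total_umolC"].iloc[0],
                           rtol=1e-9)

    def test_no_degradation_keeps_c12_constant(self):
        df = simulate_starch(100.0, synth=50.0, degr=0.0,
                             times=np.linspace(0, 18000, 31))
        assert np.allclose(df["c12_umolC"], df["c12_umolC"].iloc[0])

    def test_net_accumulation_slope(self):
        # synth 70, degr 51 nmol C/s over 300 min: net slope ~ 19 nmol C/s
        t = np.linspace(0, 300 * 60, 301)
        df = simulate_starch(150.0, synth=70.0, degr=51.0, times=t)
        slope = np.polyfit(df["time_s"], df["total_umolC"] * 1e3, 1)[0]
        assert slope == pytest.approx(19.0, rel=1e-6)

    def test_depletion_truncates_at_zero(self):
        df = simulate_starch(0.5, synth=0.0, degr=50.0,
                             times=np.linspace(0, 360000, 60))
        assert df["c12_umolC"].min() >= 0.0


class TestProteinLabeling:
    def test_zero_free_enrichment_keeps_bound_zero(self):
        df = simulate_protein_labeling(2.0, lambda t: 0.0,
                                       np.linspace(0, 10, 11))
        assert np.allclose(df["bound_enrichment"], 0.0)

    def test_constant_free_closed_form(self):
        # E_b(t) = E_f (1 - exp(-k t)), k = 0.05 / h
        df = simulate_protein_labeling(5.0, lambda t: 0.6,
                                       np.array([0.0, 10.0]))
        assert df["bound_enrichment"].iloc[-1] == pytest.approx(
            0.6 * (1 - np.exp(-0.5)), abs=1e-6)
        assert df["bound_enrichment"].iloc[-1] == pytest.approx(0.2361,
                                                                abs=2e-4)

    def test_saturating_free_matches_euler_oracle(self):
        free = lambda t: 0.5 * (1 - np.exp(-t / 0.4))
        times = np.linspace(0, 6, 13)
        df = simulate_protein_labeling(4.0, free, times)
        # independent fine-step explicit Euler
        k, dt, eb = 0.04, 1e-4, 0.0
        oracle = [0.0]
        t = 0.0
        for target in times[1:]:
            while t < target - 1e-12:
                eb += dt * k * (free(t) - eb)
                t += dt
            oracle.append(eb)
        assert np.abs(df["bound_enrichment"].to_numpy()
                      - np.array(oracle)).max() < 1e-4

    def test_invalid_psr_rejected(self):
        with pytest.raises(ValueError):
            simulate_protein_labeling(0.0, lambda t: 0.5, [0, 1])


class TestTablesAndFamilies:
    def test_mid_table_shape_and_normalization(self, cbc_toy):
        sim = simulate_labeling(cbc_toy, [5.0, 40.0])
        df = mid_table(sim)
        assert {"metabolite", "n_carbons", "time_s", "replicate"} <= \
            set(df.columns)
        mcols = [c for c in df.columns
                 if c.startswith("m") and c[1:].isdigit()]
        assert np.allclose(df[mcols].sum(axis=1), 1.0)

    def test_family_curves_labelled_and_bounded(self):
        mat = synthetic_enrichment_families(5, seed=1)
        assert mat.shape == (20, 8)
        assert mat.values.min() >= 0 and mat.values.max() <= 100
        assert mat.loc["fast_00"].iloc[-1] > mat.loc["flat_00"].iloc[-1]
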