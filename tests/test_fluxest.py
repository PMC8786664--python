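"""Flux estimators: minimum assimilation/PEPC, product synthesis, starch
turnover, protein synthesis and derived ratios."""

import numpy as np
import pytest

from chloroflux.fluxest import (FluxEstimate, PoolTable, flux_ratio,
                                gc_pool_flux_sum, lipid_synthesis_index,
                                min_assimilation_rate, min_pepc_flux,
                                pct_c12_supply_from_starch,
                                product_synthesis_rate, protein_flux,
                                psr_from_enrichment, starch_rates)
from chloroflux.kinetics import LabelSeries
from chloroflux.simulate import (simulate_labeling, simulate_protein_labeling)


def series(name, times, values, **kw):
    return LabelSeries(name, np.asarray(times, float),
                       np.asarray(values, float), **kw)


class TestMinAssimilation:
    def test_hand_example(self):
        # P=10, n=3: 13C at 5 s = 0.02*30 = 0.6 -> 0.12/s; at 10 s -> 0.09/s;
        # max 0.12, /0.5 medium, x1000 => 240 nmol C g-1 s-1
        pools = PoolTable({"X": (10.0, 3)})
        s = [series("X", [5, 10], [0.02, 0.03])]
        est = min_assimilation_rate(s, pools, medium_enrichment=0.5)
        assert est.value == pytest.approx(240.0)
        assert est.window == (5.0, 5.0)

    def test_zero_enrichment_gives_zero(self):
        pools = PoolTable({"X": (10.0, 3)})
        est = min_assimilation_rate([series("X", [5, 10], [0, 0])], pools)
        assert est.value == 0.0

    def test_linear_in_inverse_medium_enrichment(self):
        pools = PoolTable({"X": (10.0, 3)})
        s = [series("X", [5, 10], [0.02, 0.03])]
        full = min_assimilation_rate(s, pools, medium_enrichment=1.0)
        assert full.value == pytest.approx(120.0)

    def test_missing_pool_is_reported(self):
        pools = PoolTable({"X": (10.0, 3)})
        with pytest.raises(KeyError, match="Y"):
            min_assimilation_rate([series("Y", [5, 10], [0.1, 0.1])], pools)

    def test_never_exceeds_true_input_on_simulator_output(self, cbc_toy):
        sim = simulate_labeling(cbc_toy, [0, 5, 10, 20, 40])
        pools = PoolTable({m: (cbc_toy.pools[m], cbc_toy.n_carbons(m))
                           for m in sim.mids})
        allseries = [series(m, sim.times, sim.enrichment(m),
                            pool_size=cbc_toy.pools[m]) for m in sim.mids]
        est = min_assimilation_rate(allseries, pools,
                                    cbc_toy.inputs["CO2"])
        true_nmol = cbc_toy.total_input_carbon_flux() * 1e3
        assert 0 < est.value <= true_nmol


class TestMinPEPC:
    def test_zero_labelling_gives_zero(self):
        pools = PoolTable({"MAL": (6.0, 4), "ASP": (4.0, 4)})
        est = min_pepc_flux([series("MAL", [5, 10], [0, 0]),
                             series("ASP", [5, 10], [0, 0])], pools)
        assert est.value == 0.0

    def test_equals_assimilation_when_only_mal_asp_measured(self):
        pools = PoolTable({"MAL": (6.0, 4), "ASP": (4.0, 4)})
        s = [series("MAL", [5, 10], [0.01, 0.015]),
             series("ASP", [5, 10], [0.02, 0.02])]
        assert min_pepc_flux(s, pools).value == pytest.approx(
            min_assimilation_rate(s, pools).value)

    def test_bounded_by_true_pepc_carbon_flux(self, cbc_toy):
        sim = simulate_labeling(cbc_toy, [0, 5, 10, 20, 40])
        pools = PoolTable({"MAL": (cbc_toy.pools["MAL"], 4)})
        s = [series("MAL", sim.times, sim.enrichment("MAL"))]
        est = min_pepc_flux(s, pools, cbc_toy.inputs["CO2"])
        # true C flux into malate: 4 C per pepc turnover
        true_nmol = cbc_toy.fluxes["pepc"] * 4 * 1e3
        assert 0 < est.value <= true_nmol


class TestProductSynthesis:
    def test_constant_product_gives_zero(self):
        t = np.array([1800, 3600, 5400, 7200], float)
        est = product_synthesis_rate(series("suc", t, [0.2] * 4), 3.4,
                                     carbon_ratio=12)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        # E rising 0 -> 0.5 linearly over 90 min, P=3.4, ratio 12:
        # slope = 0.5*3.4/5400 umol/s -> *12*1000 = 3.778 nmol C g-1 s-1
        t = np.linspace(1800, 7200, 5)
        e = 0.5 * (t - 1800) / 5400
        est = product_synthesis_rate(series("suc", t, e), 3.4,
                                     carbon_ratio=12)
        assert est.value == pytest.approx(0.5 * 3.4 * 12 / 5400 * 1e3,
                                          rel=1e-9)
        assert est.value == pytest.approx(3.78, abs=0.01)

    def test_linear_in_pool_size(self):
        t = np.linspace(1800, 7200, 5)
        e = 0.5 * (t - 1800) / 5400
        one = product_synthesis_rate(series("g", t, e), 1.0, carbon_ratio=6)
        two = product_synthesis_rate(series("g", t, e), 2.0, carbon_ratio=6)
        assert two.value == pytest.approx(2 * one.value)

    def test_window_outside_data_rejected(self):
        t = np.array([10.0, 20.0, 30.0])
        with pytest.raises(ValueError, match="window"):
            product_synthesis_rate(series("x", t, [0, 0.1, 0.2]), 1.0)


class TestGCPoolFluxSum:
    def test_flat_series_sum_to_zero(self):
        t = np.linspace(1800, 7200, 4)
        pools = PoolTable({"pyruvate": (0.5, 3), "citrate": (3.0, 6)})
        s = [series("pyruvate", t, [0.1] * 4), series("citrate", t, [0.2] * 4)]
        with pytest.warns(UserWarning, match="missing"):
            est = gc_pool_flux_sum(s, pools)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_single_metabolite_equals_its_product_rate(self):
        t = np.linspace(1800, 7200, 4)
        e = 0.3 * (t - 1800) / 5400
        pools = PoolTable({"glutamate": (12.0, 5)})
        s = series("glutamate", t, e)
        with pytest.warns(UserWarning):
            total = gc_pool_flux_sum([s], pools)
        direct = product_synthesis_rate(s, 12.0, carbon_ratio=5)
        assert total.value == pytest.approx(direct.value)


class TestStarchRates:
    def test_identity_net_equals_difference(self):
        out = starch_rates(150.0, 9.44e-5, -2.89e-5)
        assert out["net"].value == pytest.approx(
            out["synthesis"].value - out["degradation"].value, rel=1e-12)

    def test_zero_c12_slope_means_no_degradation(self):
        out = starch_rates(150.0, 1e-4, 0.0)
        assert out["degradation"].value == 0.0
        assert out["net"].value == pytest.approx(out["synthesis"].value)

    def test_balanced_turnover_zero_net(self):
        out = starch_rates(150.0, 5e-5, -5e-5)
        assert out["net"].value == pytest.approx(0.0, abs=1e-12)

    def test_positive_c12_slope_warns(self):
        with pytest.warns(UserWarning, match="unlabelled"):
            starch_rates(150.0, 1e-5, 1e-5)

    def test_pct_c12_supply_examples(self):
        degr = FluxEstimate("d", 26.0)
        assim = FluxEstimate("a", 414.0)
        assert pct_c12_supply_from_starch(degr, assim) == pytest.approx(
            6.28, abs=0.005)
        assert pct_c12_supply_from_starch(
            FluxEstimate("d", 51.0), FluxEstimate("a", 267.0)) == \
            pytest.approx(19.10, abs=0.005)
        assert pct_c12_supply_from_starch(
            FluxEstimate("d", 0.0), assim) == 0.0
        with pytest.raises(ZeroDivisionError):
            pct_c12_supply_from_starch(degr, FluxEstimate("a", 0.0))


class TestProtein:
    def test_flux_unit_conversion(self):
        # 1.9 %/h of 248 mg/gDW at 43% C = 2.026 mg C/h = 46.9 nmol C/s
        est = protein_flux(1.9, 248.0, 0.43)
        assert est.value == pytest.approx(46.9, abs=0.05)
        assert protein_flux(0.0, 248.0).value == 0.0
        assert protein_flux(1.9, 496.0, 0.43).value == pytest.approx(
            2 * est.value)

    def test_psr_no_correction_needed(self):
        # fully labelled precursor, bound rising 0 -> 0.05 in 1 h => 5 %/h
        t_s = np.array([0.0, 1800.0, 3600.0])
        bound = series("protein", t_s, [0.0, 0.025, 0.05])
        free = series("free", t_s, [1.0, 1.0, 1.0])
        assert psr_from_enrichment(bound, free) == pytest.approx(5.0)

    def test_psr_zero_bound_slope(self):
        t_s = np.array([0.0, 1800.0, 3600.0])
        assert psr_from_enrichment(series("p", t_s, [0.1] * 3),
                                   series("f", t_s, [0.8] * 3)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_psr_unidentifiable_without_free_label(self):
        t_s = np.array([0.0, 1800.0, 3600.0])
        with pytest.raises(ValueError, match="unidentifiable"):
            psr_from_enrichment(series("p", t_s, [0, 0.01, 0.02]),
                                series("f", t_s, [0.0] * 3))

    def test_recovery_from_simulated_protein_labelling(self):
        psr_true = 4.7
        free = lambda th: 0.55 * (1 - np.exp(-th / 0.3))
        times_h = np.linspace(0.0, 2.0, 9)
        df = simulate_protein_labeling(psr_true, free, times_h)
        t_s = times_h[1:] * 3600.0
        bound = series("protein", t_s, df["bound_enrichment"].iloc[1:])
        freesr = series("free", t_s, df["free_enrichment"].iloc[1:])
        got = psr_from_enrichment(bound, freesr)
        assert abs(got - psr_true) / psr_true < 0.05


class TestRatiosAndIndexes:
    def test_lipid_index(self):
        assert lipid_synthesis_index(198.0, 0.1) == pytest.approx(19.8)
        assert lipid_synthesis_index(198.0, 0.0) == 0.0

    def test_ratio_basics(self):
        x = FluxEstimate("x", 2.0, 0.0)
        assert flux_ratio(x, x).value == pytest.approx(1.0)
        assert flux_ratio(x, FluxEstimate("y", 4.0, 0.0)).value == \
            pytest.approx(0.5)
        with pytest.raises(ZeroDivisionError):
            flux_ratio(x, FluxEstimate("z", 0.0))

    def test_sd_propagation_matches_monte_carlo(self, rng):
        num = FluxEstimate("n", 2.0, 0.2)
        den = FluxEstimate("d", 4.0, 0.4)
        est = flux_ratio(num, den)
        draws = rng.normal(2.0, 0.2, 200_000) / rng.normal(4.0, 0.4, 200_000)
        assert est.sd == pytest.approx(draws.std(), rel=0.05)

    def test_estimators_homogeneous_in_pools(self):
        pools1 = PoolTable({"X": (10.0, 3)})
        pools2 = PoolTable({"X": (20.0, 3)})
        s = [series("X", [5, 10], [0.02, 0.03])]
        assert min_assimilation_rate(s, pools2).value == pytest.approx(
            2 * min_assimilation_rate(s, pools1).value)
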