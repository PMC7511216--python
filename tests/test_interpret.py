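"""Post-fit analyses: normalization, cofactor balances, route discrimination,
subnetwork flux, physiology and reconciliation."""

import numpy as np
import pandas as pd
import pytest

from methyloflux.interpret import (
    CofactorConfig,
    ReconciliationConfig,
    cofactor_balance,
    compute_physiology,
    discriminate_arabitol_route,
    load_default_cofactor_config,
    normalize_fluxes,
    reconcile_rates,
    scalaflux_subnetwork_fit,
)
from methyloflux.fit import FitConfig
from methyloflux.model import FluxVector, load_bundled_network
from methyloflux.synthetic import (
    GeneratorSpec,
    generate_growth_series,
    generate_steady_dataset,
    reference_condition,
)


def _zero_flux(net):
    return FluxVector({r: 0.0 for r in net.reactions})


class TestNormalization:
    """Published C-mmol/C-mmol ratios from printed absolute fluxes + uptakes."""

    @pytest.mark.parametrize(
        "model,rxn,flux,uptake_C,expected",
        [
            ("methanol", "zwf", 2.3, 30.6, 0.45),
            ("mannitol", "zwf", 1.8, 36.0, 0.30),
            ("arabitol", "zwf", 0.5, 21.4, 0.14),
            ("methanol", "idh", 0.62, 30.6, 0.12),  # TCA flux up to isocitrate
            ("arabitol", "idh", 4.7, 21.4, 1.32),
        ],
    )
    def test_printed_values(self, model, rxn, flux, uptake_C, expected):
        net = load_bundled_network(model)
        fv = _zero_flux(net)
        fv.net[rxn] = flux
        assert normalize_fluxes(fv, net, uptake_C)[rxn] == pytest.approx(expected, abs=0.005)

    def test_zero_flux_stays_zero(self, mannitol_cond):
        fv = _zero_flux(mannitol_cond.net)
        assert normalize_fluxes(fv, mannitol_cond.net, 36.0)["idh"] == 0.0

    def test_uptake_normalizes_to_one(self, mannitol_cond):
        nm = normalize_fluxes(mannitol_cond.truth, mannitol_cond.net, mannitol_cond.uptake_C)
        assert nm["manupt"] == pytest.approx(1.0)

    def test_carbon_conservation(self, mannitol_cond):
        """All carbon entering as substrate leaves via exports and drains."""
        c = mannitol_cond
        nm = normalize_fluxes(c.truth, c.net, c.uptake_C)
        outflow = sum(nm[r.id] for r in c.net.reactions.values() if r.exports)
        assert outflow == pytest.approx(1.0, abs=1e-9)

    def test_positive_uptake_required(self, mannitol_cond):
        with pytest.raises(ValueError):
            normalize_fluxes(mannitol_cond.truth, mannitol_cond.net, 0.0)


class TestCofactorBalance:
    def test_all_zero_map_is_all_zero(self):
        cfg = load_default_cofactor_config()
        net = load_bundled_network("methanol")
        bal = cofactor_balance(_zero_flux(net), cfg, growth_rate=0.0)
        assert np.allclose(bal.table.to_numpy(), 0.0)

    def test_methanol_nadph_production_total(self):
        """Printed producer contributions sum to the printed 14.3 total."""
        cfg = load_default_cofactor_config()
        net = load_bundled_network("methanol")
        fv = _zero_flux(net)
        fv.net.update({"zwf": 2.3, "gnd": 2.3, "idh": 0.62, "mae": 5.1, "detox": 4.0})
        bal = cofactor_balance(fv, cfg, growth_rate=0.46)
        assert bal.table.loc["NADPH", "production"] == pytest.approx(14.3, abs=0.05)

    def test_closure_identity_on_reference_map(self, mannitol_cond):
        cfg = load_default_cofactor_config()
        bal = cofactor_balance(mannitol_cond.truth, cfg, growth_rate=mannitol_cond.growth_rate)
        assert bal.closure_residual() == pytest.approx(0.0, abs=1e-12)
        # NADH surplus fully routed to oxidative phosphorylation
        assert bal.table.loc["NADH", "unknown"] == pytest.approx(0.0, abs=1e-12)

    def test_oxphos_uses_po_ratios(self):
        cfg = CofactorConfig({"NADH": {"a": 1}, "FADH2": {"b": 1}, "ATP": {}},
                             po_nadh=1.5, po_fadh2=1.0)
        bal = cofactor_balance(FluxVector({"a": 2.0, "b": 1.0}), cfg)
        assert bal.table.loc["ATP", "transfer"] == pytest.approx(-(1.5 * 2.0 + 1.0 * 1.0))

    def test_invalid_po(self):
        with pytest.raises(ValueError):
            CofactorConfig({}, po_nadh=0.0)


class TestRouteDiscrimination:
    @pytest.mark.parametrize("true_route1, failing", [(1.0, "PTS5-only"), (0.0, "PTS1-only")])
    def test_wrong_exclusive_route_fails_chi2(self, true_route1, failing):
        spec = GeneratorSpec(condition="arabitol", route1_fraction=true_route1, seed=7,
                             nmr_enrichments=[("Rib5P", 1), ("Rib5P", 5), ("Pyr", 2), ("Pyr", 3)],
                             nmr_couplings=[("Pyr", 2)])
        ms, cond = generate_steady_dataset(spec)
        cfg = FitConfig(n_starts=4, seed=3, flux_bound=15.0)
        cons = [({"araupt1": 1.0, "araupt5": 1.0}, cond.uptake)] + cond.fit_constraints[2:]
        tbl = discriminate_arabitol_route(cond.net, ms, cond.label_input, cfg,
                                          extra_constraints=cons, exchange=cond.exchange)
        tbl = tbl.set_index("variant")
        assert not tbl.loc[failing, "passes"]
        for ok in set(tbl.index) - {failing}:
            assert tbl.loc[ok, "passes"], ok
        assert tbl.loc["both", "route1_fraction"] == pytest.approx(true_route1, abs=0.02)

    def test_uninformative_data_pass_everywhere(self):
        spec = GeneratorSpec(condition="arabitol", route1_fraction=1.0, seed=7)
        ms, cond = generate_steady_dataset(spec)
        tbl_huge_sd = ms.table.assign(sd=1e3)
        ms_blur = type(ms)(tbl_huge_sd, ms.rates)
        cfg = FitConfig(n_starts=2, seed=3, flux_bound=15.0)
        cons = [({"araupt1": 1.0, "araupt5": 1.0}, cond.uptake)] + cond.fit_constraints[2:]
        out = discriminate_arabitol_route(cond.net, ms_blur, cond.label_input, cfg,
                                          extra_constraints=cons, exchange=cond.exchange)
        assert out["passes"].all()


class TestScalaflux:
    def test_closed_form_recovery(self):
        t = np.linspace(0, 10, 40)
        pool, v = 2.0, 0.8
        res = scalaflux_subnetwork_fit(t, np.zeros_like(t), np.exp(-v * t / pool), pool,
                                       target_sd=0.01, mc_n=20, seed=3)
        assert res["v"] == pytest.approx(v, abs=1e-6)

    def test_noisy_recovery_within_mc_sd(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 10, 40)
        pool, v = 2.0, 0.8
        clean = np.exp(-v * t / pool)
        noisy = np.clip(clean + rng.normal(0, 0.01, t.shape), 0, 1)
        res = scalaflux_subnetwork_fit(t, np.zeros_like(t), noisy, pool,
                                       target_sd=0.01, mc_n=200, seed=3)
        assert abs(res["v"] - v) < 3 * res["sd"]

    def test_pool_scaling_recovers_v_given_pool(self):
        """Only v/pool shapes the curve, but v is recovered when pool is known."""
        t = np.linspace(0, 10, 30)
        for k in (1.0, 2.5):
            v, pool = 0.8 * k, 2.0 * k
            res = scalaflux_subnetwork_fit(t, np.zeros_like(t), np.exp(-v * t / pool), pool,
                                           mc_n=5, seed=0)
            assert res["v"] == pytest.approx(v, rel=1e-6)

    def test_unlabeled_precursor_flagged(self):
        t = np.linspace(0, 5, 10)
        with pytest.raises(ValueError, match="unidentifiable"):
            scalaflux_subnetwork_fit(t, np.ones_like(t), np.ones_like(t), 1.0)

    def test_nonmonotone_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            scalaflux_subnetwork_fit(np.array([0.0, 2.0, 1.0]), np.zeros(3), np.ones(3), 1.0)


class TestPhysiology:
    def test_exact_exponential_growth_rate(self):
        series = generate_growth_series(0.46, 0.389, np.linspace(0, 4, 10), uptake=6.0)
        res = compute_physiology(series["od"], series["substrate"], 0.389,
                                 substrate_molar_mass=32.04, substrate_carbons=1)
        assert res.growth_rate == pytest.approx(0.46, abs=1e-9)
        assert res.uptake == pytest.approx(6.0, rel=1e-9)

    def test_od_to_biomass_conversion(self):
        # OD 2.0 with the bioreactor conversion factor
        assert 2.0 * 0.389 == pytest.approx(0.778)
        series = generate_growth_series(0.46, 0.389, np.linspace(0, 2, 5), od0=2.0)
        X0 = 0.389 * series["od"]["od"].iloc[0]
        assert X0 == pytest.approx(0.778, rel=1e-12)

    def test_product_rate_round_trip(self):
        series = generate_growth_series(0.36, 0.22, np.linspace(0, 6, 12), uptake=6.0,
                                        product_rates={"acetate": 1.75})
        res = compute_physiology(series["od"], series["substrate"], 0.22,
                                 substrate_molar_mass=182.17, substrate_carbons=6,
                                 product_series={"acetate": series["acetate"]})
        assert res.product_rates["acetate"] == pytest.approx(1.75, rel=1e-9)

    def test_noisy_growth_rate_within_se(self):
        series = generate_growth_series(0.36, 0.22, np.linspace(0, 6, 12), od_cv=0.02, seed=9)
        res = compute_physiology(series["od"], None, 0.22)
        assert abs(res.growth_rate - 0.36) < 2 * res.growth_rate_se

    def test_nonpositive_od_rejected(self):
        df = pd.DataFrame({"time_h": [0, 1, 2], "od": [0.1, 0.0, 0.4]})
        with pytest.raises(ValueError):
            compute_physiology(df, None, 0.22)


class TestReconciliation:
    def test_consistent_rates_unchanged(self):
        rates = pd.DataFrame({"name": ["in", "out"], "value": [2.0, 2.0], "sd": [0.1, 0.1]})
        out, chi2, p, ok = reconcile_rates(rates, [[1.0, -1.0]])
        assert chi2 == pytest.approx(0.0, abs=1e-12) and ok
        np.testing.assert_allclose(out["reconciled"], out["value"])

    def test_two_variable_analytic_projection(self):
        """Single carbon balance, one perturbed rate: the correction splits
        inversely to the variances (hand-derived projection)."""
        rates = pd.DataFrame({"name": ["a", "b"], "value": [1.2, 1.0], "sd": [0.1, 0.2]})
        out, chi2, _, _ = reconcile_rates(rates, [[1.0, -1.0]])
        # r* = r - S E'(E S E')^-1 E r with E=[1,-1], S=diag(.01,.04)
        imbalance = 0.2
        denom = 0.01 + 0.04
        np.testing.assert_allclose(
            out["reconciled"], [1.2 - 0.01 * imbalance / denom, 1.0 + 0.04 * imbalance / denom]
        )
        assert chi2 == pytest.approx(imbalance**2 / denom)

    def test_acetate_yield_from_printed_rates(self):
        # acetate production over mannitol uptake in mol/mol
        acetate, uptake_C = 1.75, 36.0
        yield_mol = acetate / (uptake_C / 6)
        assert round(yield_mol, 1) == 0.3

    def test_biomass_carbon_content(self):
        cfg = ReconciliationConfig()
        # CH1.646N0.219O0.410S0.005, 6% ash -> about 40 mmol C per gDCW
        assert cfg.biomass_carbon_content() == pytest.approx(40.07, abs=0.1)

    def test_redundant_constraints_rejected(self):
        rates = pd.DataFrame({"name": ["a", "b"], "value": [1.0, 1.0], "sd": [0.1, 0.1]})
        with pytest.raises(ValueError):
            reconcile_rates(rates, [[1.0, -1.0], [2.0, -2.0]])
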