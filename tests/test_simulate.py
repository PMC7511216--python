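"""Labeling simulation: EMU path, exhaustive oracle, dynamics, projections."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methyloflux.model import FluxVector, LabelInput, apply_flux_parameters, free_flux_basis, parse_network
from methyloflux.simulate import (
    SingularLabelingError,
    cid_from_isotopomers,
    emu_decompose,
    project_measurements,
    simulate_instationary,
    simulate_isotopomers_exhaustive,
    simulate_steady_labeling,
)

import pandas as pd


def toy_flux(net, **values):
    return FluxVector({r: values.get(r, 0.0) for r in net.reactions},
                      {r.id: values.get(f"x_{r.id}", 0.0) for r in net.reactions.values() if r.reversible})


class TestDecomposition:
    def test_chain_full_molecule_single_unit(self, chain_net):
        sys_ = emu_decompose(chain_net, ["B"])
        assert sys_.n_units == 1 and sys_.sizes == [2]

    def test_chain_with_positional_targets(self, chain_net):
        sys_ = emu_decompose(chain_net, ["B", ("B", (1,)), ("B", (2,))])
        assert sys_.n_units == 3 and sys_.sizes == [1, 2]

    def test_rump_units_cover_oracle_fragments(self, rump_net):
        sys_ = emu_decompose(rump_net, ["T3"])
        units = set(sys_.entries)
        # both cleavage halves of the hexose are needed
        assert ("H6", (0, 1, 2)) in units and ("H6", (3, 4, 5)) in units

    def test_empty_targets(self, chain_net):
        assert emu_decompose(chain_net, []).n_units == 0

    def test_unreachable_target_raises(self):
        net = parse_network(
            "MET A 1 source\nMET B 1 internal\nMET O 1 internal\n"
            "RXN r1 irr 1 A[a] -> 1 B[a]\nRXN r2 irr 1 B[a] -> out\n"
            "RXN r3 irr 1 O[a] -> out"
        )
        with pytest.raises(ValueError, match="unreachable"):
            emu_decompose(net, ["O"])


class TestStationary:
    def test_label_passthrough(self, chain_net):
        fv = toy_flux(chain_net, r1=1.0, r2=1.0)
        st_ = simulate_steady_labeling(chain_net, fv, LabelInput({"A": [("10", 1.0)]}, purity=1.0))
        np.testing.assert_allclose(st_.cid("B"), [0, 1, 0], atol=1e-12)

    def test_unlabeled_input_gives_m0(self, mannitol_cond):
        inp = LabelInput({"Mntl": [("000000", 1.0)]})
        st_ = simulate_steady_labeling(mannitol_cond.net, mannitol_cond.truth, inp)
        for sp in mannitol_cond.net.internal_metabolites:
            cid = st_.cid(sp)
            assert cid[0] == pytest.approx(1.0, abs=1e-9)

    def test_cids_on_simplex(self, arabitol_cond):
        st_ = simulate_steady_labeling(arabitol_cond.net, arabitol_cond.truth, arabitol_cond.label_input)
        for sp in arabitol_cond.net.internal_metabolites:
            cid = st_.cid(sp)
            assert np.all(cid >= -1e-12)
            assert cid.sum() == pytest.approx(1.0, abs=1e-9)

    def test_flux_scaling_invariance(self, arabitol_cond):
        st1 = simulate_steady_labeling(arabitol_cond.net, arabitol_cond.truth, arabitol_cond.label_input)
        st2 = simulate_steady_labeling(
            arabitol_cond.net, arabitol_cond.truth.scaled(3.7), arabitol_cond.label_input
        )
        for sp in arabitol_cond.net.internal_metabolites:
            np.testing.assert_allclose(st1.cid(sp), st2.cid(sp), atol=1e-10)

    def test_route_labeling_signature(self, arabitol_cond):
        """[5-13C]arabitol labels Rib5P C1 via the Xyl5P route, C5 via Ribu5P."""
        from methyloflux.synthetic import reference_condition

        pts1 = reference_condition("arabitol", route1_fraction=1.0)
        pts5 = reference_condition("arabitol", route1_fraction=0.0)
        t = ["Rib5P", ("Rib5P", (1,)), ("Rib5P", (5,))]
        s1 = simulate_steady_labeling(pts1.net, pts1.truth, pts1.label_input, targets=t)
        s5 = simulate_steady_labeling(pts5.net, pts5.truth, pts5.label_input, targets=t)
        assert s1.enrichment("Rib5P", 1) > 0.5 > s1.enrichment("Rib5P", 5)
        assert s5.enrichment("Rib5P", 5) > 0.5 > s5.enrichment("Rib5P", 1)


@pytest.fixture(scope="module")
def cases():
    from conftest import oracle_case_suite

    return oracle_case_suite()


class TestAgainstExhaustiveOracle:
    """EMU path equals the full isotopomer balance on structured toys."""

    @pytest.mark.parametrize("key", ["chain", "diamond", "split_join", "reversible", "symmetric", "rump"])
    def test_cid_marginals_match(self, cases, key):
        net, fv, inp = cases[key]
        st_ = simulate_steady_labeling(net, fv, inp)
        iso = simulate_isotopomers_exhaustive(net, fv, inp)
        for m in net.internal_metabolites:
            emu_cid = st_.cid(m)
            oracle = cid_from_isotopomers(iso[m], net.n_carbons(m))
            assert np.max(np.abs(emu_cid - oracle)) < 1e-8, m

    def test_symmetric_orientation_invariance(self, cases):
        net, fv, inp = cases["symmetric"]
        iso = simulate_isotopomers_exhaustive(net, fv, inp)
        n = net.n_carbons("F")
        dist = iso["F"].reshape((2,) * n)
        np.testing.assert_allclose(dist, np.transpose(dist, tuple(range(n - 1, -1, -1))), atol=1e-10)

    def test_cap_enforced(self, mannitol_cond):
        with pytest.raises(ValueError, match="cap"):
            simulate_isotopomers_exhaustive(
                mannitol_cond.net, mannitol_cond.truth, mannitol_cond.label_input, cap=100
            )


class TestInstationary:
    def _single_pool(self):
        net = parse_network(
            "MET S 1 source\nMET P 1 internal 1000\n"
            "RXN up irr 1 S[a] -> 1 P[a]\nRXN outp irr 1 P[a] -> out"
        )
        return net, FluxVector({"up": 2.0, "outp": 2.0})

    def test_single_pool_closed_form(self):
        net, fv = self._single_pool()
        t = np.linspace(0, 2, 9)
        tc = simulate_instationary(
            net, fv, None,
            LabelInput({"S": [("0", 1.0)]}), LabelInput({"S": [("1", 1.0)]}, purity=1.0), t,
        )
        np.testing.assert_allclose(tc.cid("P")[:, 0], np.exp(-2.0 * t), atol=1e-6)

    def test_pool_doubling_dilates_time(self):
        net, fv = self._single_pool()
        t = np.linspace(0, 1, 6)
        pre = LabelInput({"S": [("0", 1.0)]})
        post = LabelInput({"S": [("1", 1.0)]}, purity=1.0)
        a = simulate_instationary(net, fv, {"P": 1000.0}, pre, post, t)
        b = simulate_instationary(net, fv, {"P": 2000.0}, pre, post, 2 * t)
        np.testing.assert_allclose(a.cid("P"), b.cid("P"), atol=1e-6)

    def test_t0_matches_preswitch_and_converges_to_stationary(self, methanol_cond):
        c = methanol_cond
        targets = ["Gnt6P", "Rib5P", "PEP"]
        # long horizon: terminal state must approach the post-switch stationary solution
        t = np.array([0.0, 5.0, 60.0]) / 60.0
        pre = LabelInput({"MeOH": [("0", 1.0)]})
        tc = simulate_instationary(c.net, c.truth, None, pre, c.label_input, t, targets=targets)
        stat = simulate_steady_labeling(c.net, c.truth, c.label_input, targets=targets)
        for sp in targets:
            assert tc.cid(sp)[0, 0] == pytest.approx(1.0, abs=1e-7)  # pre-switch state
            np.testing.assert_allclose(tc.cid(sp)[-1], stat.cid(sp), atol=0.01)

    def test_nonmonotone_times_rejected(self):
        net, fv = self._single_pool()
        with pytest.raises(ValueError, match="increasing"):
            simulate_instationary(net, fv, None, LabelInput({"S": [("0", 1.0)]}),
                                  LabelInput({"S": [("1", 1.0)]}), np.array([0.0, 0.5, 0.4]))


class TestProjection:
    def test_positional_enrichment_from_pure_isotopomer(self, chain_net):
        fv = toy_flux(chain_net, r1=1, r2=1)
        st_ = simulate_steady_labeling(
            chain_net, fv, LabelInput({"A": [("10", 1.0)]}, purity=1.0),
            targets=["B", ("B", (1,)), ("B", (2,))],
        )
        assert st_.enrichment("B", 1) == pytest.approx(1.0)
        assert st_.enrichment("B", 2) == pytest.approx(0.0)

    def test_mask_omits_entries(self, mannitol_cond):
        st_ = simulate_steady_labeling(mannitol_cond.net, mannitol_cond.truth, mannitol_cond.label_input)
        tbl = pd.DataFrame(
            [("Gnt6P", "cid", k, 0.0, 0.005, k not in (2, 3)) for k in range(7)],
            columns=["species", "kind", "index", "value", "sd", "use"],
        )
        out = project_measurements(st_, tbl)
        assert len(out) == 5
        assert set(out["index"]) == {0, 1, 4, 5, 6}

    def test_coupling_fractions_match_isotopomer_enumeration(self, reversible_net):
        """Multiplet fractions from subset-CID inversion equal direct summation
        over the exhaustive isotopomer distribution."""
        fv = toy_flux(reversible_net, r1=1, r2=1, r3=1, x_r2=0.5)
        inp = LabelInput({"A": [("100", 0.5), ("011", 0.5)]}, purity=0.95)
        frags = [("C", a) for r in range(1, 4) for a in itertools.combinations((1, 2, 3), r)]
        st_ = simulate_steady_labeling(reversible_net, fv, inp, targets=frags)
        got = st_.coupling_fractions("C", 2)

        iso = simulate_isotopomers_exhaustive(reversible_net, fv, inp)["C"].reshape((2, 2, 2))
        p_anchor = iso[:, 1, :].sum()
        expected = {
            "s": iso[0, 1, 0] / p_anchor,
            "d1": iso[1, 1, 0] / p_anchor,
            "d2": iso[0, 1, 1] / p_anchor,
            "dd": iso[1, 1, 1] / p_anchor,
        }
        for k in expected:
            assert got[k] == pytest.approx(expected[k], abs=1e-8), k

    def test_unknown_species_raises(self, chain_net):
        fv = toy_flux(chain_net, r1=1, r2=1)
        st_ = simulate_steady_labeling(chain_net, fv, LabelInput({"A": [("10", 1.0)]}))
        tbl = pd.DataFrame([("Z", "cid", 0, 0.0, 0.005, True)],
                           columns=["species", "kind", "index", "value", "sd", "use"])
        with pytest.raises(KeyError):
            project_measurements(st_, tbl)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(split=st.floats(0.0, 1.0), purity=st.floats(0.9, 1.0))
def test_diamond_cid_simplex_property(split, purity):
    """Any admissible split and purity yields simplex CIDs everywhere."""
    from conftest import diamond_truth

    net, par, fv = diamond_truth(split)
    inp = LabelInput({"S": [("10", 1.0)]}, purity=purity)
    st_ = simulate_steady_labeling(net, fv, inp)
    for sp in ("X", "P"):
        cid = st_.cid(sp)
        assert np.all(cid >= -1e-12)
        assert cid.sum() == pytest.approx(1.0, abs=1e-9)
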