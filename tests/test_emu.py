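import numpy as np
import pytest

from lemnaflux.emu import (
    SimulationError,
    brute_force_isotopomers,
    emu_decompose,
    marginal_mid,
    simulate_mids,
    substrate_distributions,
)
from lemnaflux.isotope import SubstrateLabel, natural_skeleton_mid, unlabeled
from lemnaflux.network import FluxState, steady_state_basis

LBL_1C = {"A": SubstrateLabel((("1-", 1.0, 1.0),))}  # pure [1-13C], no background


def _state(net, net_fluxes, xch=None):
    n = len(net.reactions)
    v = np.zeros(n)
    for rid, val in net_fluxes.items():
        v[net.rxn_index(rid)] = val
    x = np.zeros(n)
    for rid, val in (xch or {}).items():
        x[net.rxn_index(rid)] = val
    return FluxState(net, v, x)


class TestDecomposition:
    def test_linear_two_carbon_chain_has_two_emus(self):
        from lemnaflux.network import parse_network

        net = parse_network(
            "# metabolite A x 2 external\n"
            "# metabolite B c 2 balanced\n"
            "# metabolite C x 2 external\n"
            "v1\tA#ab\tB#ab\tirr\t0.0\tinf\n"
            "v2\tB#ab\tC#ab\tirr\t0.0\tinf\n"
        )
        system = emu_decompose(net, [("B", (0, 1))])
        assert len(system.emus) == 1  # B12 is the only unknown
        assert system.substrate_emus == {("A", (0, 1))}

    def test_condensation_toy_emu_count_matches_hand_enumeration(self, toy):
        net = toy("toy_condensation")
        system = emu_decompose(net, [("E", (0, 1, 2, 3))])
        # hand enumeration: unknown EMUs E1234, C12, D12 (exchange couples
        # C and D at size 2); substrates A12, B12
        assert sorted(system.emus) == [
            ("C", (0, 1)),
            ("D", (0, 1)),
            ("E", (0, 1, 2, 3)),
        ]

    def test_unknown_target_carbons_raise(self, toy):
        net = toy("toy_linear")
        with pytest.raises(SimulationError, match="unknown carbons"):
            emu_decompose(net, [("B", (0, 5))])

    def test_lemna_core_panel_decomposition_is_solvable(self, ins_truth, ins_fit_model):
        _, model = ins_fit_model
        # every level matrix must be nonsingular for strictly positive fluxes
        mids = model.system.simulate(ins_truth, model.dists)
        for mid in mids.values():
            assert mid.sum() == pytest.approx(1.0, abs=1e-8)


class TestSimulateMIDs:
    def test_label_conservation_along_chain(self, toy):
        net = toy("toy_linear")
        flux = _state(net, {"v1": 10, "v2": 10, "v3": 10})
        mids = simulate_mids(net, flux, LBL_1C, [("C", (0, 1)), ("B", (0, 1))])
        for mid in mids.values():
            assert mid == pytest.approx([0, 1, 0], abs=1e-12)

    def test_unlabeled_feed_gives_natural_mids(self, toy):
        net = toy("toy_midsize")
        basis = steady_state_basis(net)
        flux = basis.flux_state(np.array([2.0, 3.0]))
        mids = simulate_mids(net, flux, {}, [("P", (0, 1, 2)), ("G", (0, 1, 2, 3))])
        assert mids[("P", (0, 1, 2))] == pytest.approx(natural_skeleton_mid(3), abs=1e-7)
        assert mids[("G", (0, 1, 2, 3))] == pytest.approx(natural_skeleton_mid(4), abs=1e-7)

    def test_condensation_matches_closed_form_convolution(self, toy):
        net = toy("toy_condensation")
        labels = {
            "A": SubstrateLabel((("1-", 1.0, 1.0),)),
            "B": SubstrateLabel((("--", 1.0, 0.0),)),
        }
        # no exchange: E = A (x) B exactly
        flux = _state(net, {"v1": 7, "v2": 7, "v3": 7, "v4": 7})
        mids = simulate_mids(net, flux, labels, [("E", (0, 1, 2, 3))])
        a = np.array([0.0, 1.0, 0.0])
        b = np.array([1.0, 0.0, 0.0])
        assert mids[("E", (0, 1, 2, 3))] == pytest.approx(np.convolve(a, b), abs=1e-8)

    def test_zero_flux_subnetwork_is_diagnosed_or_clamped(self, toy):
        net = toy("toy_condensation")
        flux = _state(net, {"v1": 0, "v2": 7, "v3": 0, "v4": 0})
        # clamped fluxes keep the system solvable and normalized
        mids = simulate_mids(net, flux, {"A": LBL_1C["A"]}, [("E", (0, 1, 2, 3))])
        assert mids[("E", (0, 1, 2, 3))].sum() == pytest.approx(1.0)


class TestBruteForceOracle:
    def test_oracle_matches_emu_on_all_toys(self, toy):
        cases = [
            ("toy_linear", {"v1": 10, "v2": 10, "v3": 10}, {}, "C", 2),
            ("toy_diamond", {"v1": 10, "v2": 4, "v3": 6, "v4": 4, "v5": 6, "v6": 10}, {}, "E", 2),
            (
                "toy_condensation",
                {"v1": 5, "v2": 5, "v3": 5, "v4": 5},
                {"vx": 3.0},
                "E",
                4,
            ),
            ("toy_exchange", {"v1": 4, "v2": 6, "v3": 4, "v4": 6}, {"vx": 8.0}, "Q", 2),
        ]
        for name, netflux, xch, target, ncarb in cases:
            net = toy(name)
            labels = {
                m: SubstrateLabel((("1" + "0" * (net.metabolites[m].n_carbons - 1), 1.0, 0.99),))
                for m in net.substrate_inputs
                if net.metabolites[m].n_carbons > 1
            }
            flux = _state(net, netflux, xch)
            key = (target, tuple(range(ncarb)))
            mids = simulate_mids(net, flux, labels, [key])
            bf = brute_force_isotopomers(net, flux, labels)
            assert np.max(np.abs(mids[key] - marginal_mid(bf[target]))) < 1e-8

    def test_oracle_matches_emu_on_random_flux_states(self, toy, midsize_network):
        net = midsize_network
        basis = steady_state_basis(net)
        rng = np.random.default_rng(42)
        labels = {"A": SubstrateLabel((("1000", 0.5, 0.99), ("1111", 0.2, 0.99), ("0000", 0.3, 0.0)))}
        targets = [("P", (0, 1, 2)), ("Q", (0, 1)), ("G", (0, 1, 2, 3))]
        from lemnaflux.fitting import _feasible_center

        center = _feasible_center(basis)
        lo = np.array([r.lb for r in net.reactions])
        n_ok = 0
        worst = 0.0
        while n_ok < 20:
            q = center + rng.normal(0.0, 3.0, basis.n_free_net)
            v = basis.expand(q)
            if np.min(np.where(np.isfinite(lo), v - lo, np.inf)) < 0.2:
                continue
            xch = np.zeros(len(net.reactions))
            for rid in basis.free_exchange_ids:
                xch[net.rxn_index(rid)] = rng.uniform(0.0, 10.0)
            flux = FluxState(net, v, xch)
            mids = simulate_mids(net, flux, labels, targets)
            bf = brute_force_isotopomers(net, flux, labels)
            for met, pos in targets:
                dev = np.max(np.abs(mids[(met, pos)] - marginal_mid(bf[met], pos)))
                worst = max(worst, dev)
            n_ok += 1
        assert worst < 1e-8

    def test_convergence_independent_of_initialization(self, toy, midsize_flux):
        net = midsize_flux.network
        labels = {"A": SubstrateLabel((("1100", 1.0, 0.99),))}
        bf1 = brute_force_isotopomers(net, midsize_flux, labels)
        init = {m.id: np.full(2**m.n_carbons, 1.0 / 2**m.n_carbons)
                for m in net.metabolites.values() if m.id not in ("A", "CO2")}
        bf2 = brute_force_isotopomers(net, midsize_flux, labels, init=init)
        for met in bf1:
            assert np.max(np.abs(bf1[met] - bf2[met])) < 1e-10

    def test_size_guard_refuses_large_networks(self, ins_truth):
        with pytest.raises(SimulationError, match="exceeds"):
            brute_force_isotopomers(
                ins_truth.network, ins_truth, {}, max_states=100
            )

    def test_symmetric_scrambling_mixes_c1_c4(self, toy):
        net = toy("toy_scramble")
        labels = {"A": SubstrateLabel((("1---", 1.0, 1.0),))}
        # all flux through the scrambled branch pair
        flux = _state(net, {"v1": 10, "v2a": 5, "v2b": 5, "v3": 10, "v4": 0})
        mids = simulate_mids(net, flux, labels, [("M", (0,)), ("M", (3,))])
        # 50:50 scrambling: the C1 label appears equally on C1 and C4
        assert mids[("M", (0,))][1] == pytest.approx(0.5, abs=1e-9)
        assert mids[("M", (3,))][1] == pytest.approx(0.5, abs=1e-9)
        bf = brute_force_isotopomers(net, flux, labels)
        assert marginal_mid(bf["M"], (0,))[1] == pytest.approx(0.5, abs=1e-9)


class TestSimulationInvariants:
    def test_flux_scaling_leaves_mids_unchanged(self, toy, midsize_flux):
        net = midsize_flux.network
        labels = {"A": SubstrateLabel((("1010", 1.0, 0.99),))}
        targets = [("P", (0, 1, 2)), ("Q", (0, 1))]
        m1 = simulate_mids(net, midsize_flux, labels, targets)
        scaled = FluxState(net, midsize_flux.net * 7.3, midsize_flux.xch * 7.3)
        m2 = simulate_mids(net, scaled, labels, targets)
        for k in m1:
            assert m1[k] == pytest.approx(m2[k], abs=1e-12)

    def test_exchange_monotonically_equilibrates_pools(self, toy):
        net = toy("toy_exchange")
        labels = {"A": SubstrateLabel((("11", 1.0, 1.0),))}  # P fed labeled, Q unlabeled
        prev_gap = None
        for x in (0.0, 2.0, 10.0, 50.0, 500.0):
            flux = _state(net, {"v1": 5, "v2": 5, "v3": 5, "v4": 5}, {"vx": x})
            mids = simulate_mids(net, flux, labels, [("P", (0, 1)), ("Q", (0, 1))])
            gap = abs(mids[("P", (0, 1))][2] - mids[("Q", (0, 1))][2])
            if prev_gap is not None:
                assert gap < prev_gap
            prev_gap = gap
        assert prev_gap < 0.02  # near isotopic equilibrium at high exchange

    def test_label_carbon_balance_at_steady_state(self, toy, midsize_flux):
        # total 13C inflow equals total 13C outflow
        net = midsize_flux.network
        labels = {"A": SubstrateLabel((("1100", 1.0, 0.99),))}
        dists = substrate_distributions(net, labels)
        from lemnaflux.isotope import average_enrichment

        targets = [("POut", (0, 1, 2)), ("QOut", (0, 1)), ("CO2", (0,))]
        mids = simulate_mids(net, midsize_flux, labels, targets)
        v = midsize_flux.net
        inflow = v[net.rxn_index("v1")] * 4 * average_enrichment(dists["A"], 4)
        out = (
            v[net.rxn_index("v7")] * 3 * average_enrichment(mids[("POut", (0, 1, 2))])
            + v[net.rxn_index("v8")] * 2 * average_enrichment(mids[("QOut", (0, 1))])
            + v[net.rxn_index("v9")] * 1 * average_enrichment(mids[("CO2", (0,))])
        )
        assert out == pytest.approx(inflow, rel=1e-9)
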