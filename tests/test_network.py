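import numpy as np
import pytest

from lemnaflux.fixtures import FIXTURES, fixture_text
from lemnaflux.lemna_core import BIOMASS_SINKS, build_lemna_core
from lemnaflux.network import (
    NetworkError,
    aggregation_map,
    parse_network,
    serialize_network,
    steady_state_basis,
    validate_carbon_balance,
)


class TestParsing:
    def test_one_line_toy(self):
        net = parse_network(
            "# metabolite A x 2 external\n"
            "# metabolite B c 2 balanced\n"
            "vA\tA#ab\tB#ab\tirr\t0.0\tinf\n"
        )
        assert len(net.reactions) == 1
        assert validate_carbon_balance(net) == []

    def test_dropped_atom_is_an_error(self):
        text = (
            "# metabolite A x 2 external\n"
            "# metabolite B c 1 balanced\n"
            "vBad\tA#ab\tB#a\tirr\t0.0\tinf\n"
        )
        with pytest.raises(NetworkError, match="vBad"):
            parse_network(text)

    def test_malformed_term_names_line(self):
        text = (
            "# metabolite A x 2 external\n"
            "# metabolite B c 2 balanced\n"
            "vA\tA##ab\tB#ab\tirr\t0.0\tinf\n"
        )
        with pytest.raises(NetworkError, match="line 3"):
            parse_network(text)

    @pytest.mark.parametrize("name", FIXTURES)
    def test_fixture_reaction_count_matches_header(self, name):
        text = fixture_text(name)
        declared = int(
            next(l for l in text.splitlines() if l.startswith("# reactions")).split()[-1]
        )
        net = parse_network(text)
        assert len(net.reactions) == declared
        assert validate_carbon_balance(net) == []

    def test_serialization_round_trip(self):
        net = build_lemna_core("B", "INS")
        net2 = parse_network(serialize_network(net))
        assert net2.reaction_ids == net.reaction_ids
        assert net2.fixed_fluxes == net.fixed_fluxes
        for r1, r2 in zip(net.reactions, net2.reactions):
            assert r1 == r2


class TestCarbonBalance:
    def test_dropping_co2_without_product_is_reported(self):
        from lemnaflux.network import Metabolite, Network, Reaction, Term

        net = Network(
            "t",
            [Metabolite("A", "x", 2, False), Metabolite("B", "c", 1, True)],
            [Reaction("vLoss", (Term("A", "ab"),), (Term("B", "a"),), False)],
        )
        violations = validate_carbon_balance(net)
        assert len(violations) == 1
        assert "vLoss" in violations[0]

    def test_reversible_reaction_checked_once(self, toy):
        net = toy("toy_exchange")
        assert validate_carbon_balance(net) == []


class TestSteadyStateBasis:
    def test_linear_chain_fully_determined(self, toy):
        net = toy("toy_linear")
        basis = steady_state_basis(net)
        assert basis.n_free_net == 0
        v = basis.expand(np.zeros(0))
        assert np.allclose(v, 10.0)

    def test_diamond_has_one_free_split(self, toy):
        net = toy("toy_diamond")
        basis = steady_state_basis(net)
        assert basis.n_free_net == 1
        v = basis.expand(np.array([1.0]))
        S = net.stoichiometric_matrix()
        assert np.max(np.abs(S @ v)) < 1e-9

    def test_lemna_core_free_count_matches_rank_oracle(self, ins_preset):
        from lemnaflux.synth import _fixed_fluxes

        net = build_lemna_core("C", "INS")
        fixed = _fixed_fluxes(ins_preset)
        basis = steady_state_basis(net, extra_fixed=fixed)
        # independent oracle: numerical rank of the full constraint matrix
        n = len(net.reactions)
        S = net.stoichiometric_matrix()
        rows = [S]
        for rc in net.ratio_constraints:
            row = np.zeros((1, n))
            row[0, net.rxn_index(rc.numerator)] = 1.0
            row[0, net.rxn_index(rc.denominator)] = -rc.ratio
            rows.append(row)
        for rid in {**net.fixed_fluxes, **fixed}:
            row = np.zeros((1, n))
            row[0, net.rxn_index(rid)] = 1.0
            rows.append(row)
        rank = np.linalg.matrix_rank(np.vstack(rows))
        assert basis.n_free_net == n - rank

    def test_expanded_vectors_satisfy_steady_state_and_ratio(self):
        net = build_lemna_core("B", "ONS")
        basis = steady_state_basis(net)
        rng = np.random.default_rng(1)
        S = net.stoichiometric_matrix()
        i, j = net.rxn_index("vRBC"), net.rxn_index("vRBO")
        for _ in range(5):
            v = basis.expand(rng.normal(0, 50, basis.n_free_net))
            scale = max(1.0, np.max(np.abs(v)))
            assert np.max(np.abs(S @ v)) / scale < 1e-9
            assert v[i] / v[j] == pytest.approx(1000.0, rel=1e-6)

    def test_inconsistent_fixed_fluxes_raise(self, toy):
        net = toy("toy_linear")
        with pytest.raises(NetworkError, match="[Ii]nconsistent"):
            steady_state_basis(net, extra_fixed={"v2": 33.0})  # feed fixed at 10


class TestLemnaCoreModes:
    def test_mode_a_has_no_atmospheric_influx(self):
        net = build_lemna_core("A", "INS")
        assert "CO2_RBC" not in net.metabolites
        assert "vCO2_atm_in" not in net.reaction_ids
        rbc = net.reaction("vRBC")
        assert any(t.metabolite == "CO2_c" for t in rbc.educts)

    def test_mode_b_adds_rbc_pool_with_adjacent_transfers(self):
        a = build_lemna_core("A", "INS")
        b = build_lemna_core("B", "INS")
        extra = set(b.reaction_ids) - set(a.reaction_ids)
        assert extra == {"vCO2_atm_in", "vCO2_atm_out", "vCO2_mix"}
        assert set(b.metabolites) - set(a.metabolites) == {"CO2_RBC"}
        rbc = b.reaction("vRBC")
        assert any(t.metabolite == "CO2_RBC" for t in rbc.educts)
        # apart from the RuBisCO CO2 source, shared reactions are identical
        for rid in set(a.reaction_ids) - {"vRBC"}:
            assert a.reaction(rid) == b.reaction(rid)

    def test_ins_mode_fixes_gln_uptake_to_zero(self):
        assert build_lemna_core("B", "INS").fixed_fluxes["vGln_up"] == 0.0
        assert "vGln_up" not in build_lemna_core("B", "ONS").fixed_fluxes

    def test_mode_c_declares_uptake_measurement_slots(self):
        assert build_lemna_core("C", "ONS").measured_uptakes == [
            "vGlc_up", "vGln_up", "vCO2_up",
        ]

    def test_all_22_sinks_present(self):
        net = build_lemna_core("B", "ONS")
        assert len(BIOMASS_SINKS) == 22
        for sink in BIOMASS_SINKS:
            assert sink in net.reaction_ids


class TestAggregation:
    def test_duplicated_oppp_steps_are_summed(self):
        net = build_lemna_core("B", "ONS")
        am = aggregation_map(net)
        row = am.combination("vG6PDH")
        v = np.zeros(len(net.reactions))
        v[net.rxn_index("vG6PDH_c")] = 30.0
        v[net.rxn_index("vG6PDH_p")] = 98.1
        assert row @ v == pytest.approx(128.1)

    def test_transporters_map_to_zero_rows(self):
        net = build_lemna_core("B", "ONS")
        am = aggregation_map(net)
        for rid in ("vT_G6P", "vT_TP", "vT_PEP", "vT_PGA", "vPyr_cm"):
            assert np.all(am.combination(rid) == 0.0)

    def test_aggregated_vector_is_steady_on_merged_network(self, ins_truth):
        # merged stoichiometry applied to the aggregated flux vector
        net = ins_truth.network
        am = aggregation_map(net)
        from lemnaflux.network import _merged_met

        merged_bal = sorted(
            {_merged_met(m) for m in net.balanced_metabolites}
        )
        # group original S rows by merged metabolite, drop transporter columns
        S = net.stoichiometric_matrix()
        rowmap = {m: i for i, m in enumerate(net.balanced_metabolites)}
        for m_merged in merged_bal:
            rows = [
                S[rowmap[m]]
                for m in net.balanced_metabolites
                if _merged_met(m) == m_merged
            ]
            balance = np.sum(rows, axis=0) @ ins_truth.net
            assert abs(balance) < 1e-8
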