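import math

import numpy as np
import pytest

from lemnaflux import physiology as phys
from lemnaflux import tables


class TestGrowthRate:
    def test_published_ins_endpoint(self):
        mu = phys.growth_rate(1.1, 34.1, 240.0)
        assert mu == pytest.approx(0.0143, abs=0.0002)
        assert round(mu, 3) == 0.014

    def test_no_growth_gives_zero(self):
        assert phys.growth_rate(3.3, 3.3, 100.0) == 0.0

    def test_doubling_in_unit_time(self):
        assert phys.growth_rate(1.0, 2.0, 1.0) == pytest.approx(math.log(2))

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_nonpositive_inputs_raise(self, bad):
        with pytest.raises(ValueError):
            phys.growth_rate(*bad)


class TestDoublingTime:
    def test_published_doubling_times(self):
        assert phys.doubling_time(math.log(2) / 50.5) == pytest.approx(50.5)
        assert phys.doubling_time(math.log(2)) == pytest.approx(1.0)

    def test_inverse_of_growth_rate(self):
        assert phys.doubling_time(phys.growth_rate(1, 2, 35.7)) == pytest.approx(35.7)

    def test_nonpositive_mu_raises(self):
        with pytest.raises(ValueError):
            phys.doubling_time(0.0)


class TestUptakeRate:
    def test_no_depletion_gives_zero(self):
        assert phys.uptake_rate(100.0, 100.0, 0.001, 0.01, 0.014) == 0.0

    def test_back_solved_glucose_fixture(self):
        # inputs reconstructed from the published glucose uptake and weights
        v = phys.uptake_rate(2775.0, 2301.0, 0.0021, 0.0656, 0.0137)
        assert v == pytest.approx(102.3, rel=0.01)

    def test_linear_in_growth_rate(self):
        v1 = phys.uptake_rate(100.0, 60.0, 0.002, 0.06, 0.014)
        v2 = phys.uptake_rate(100.0, 60.0, 0.002, 0.06, 0.028)
        assert v2 == pytest.approx(2 * v1)

    def test_invariant_under_proportional_rescaling(self):
        v1 = phys.uptake_rate(100.0, 60.0, 0.002, 0.06, 0.014)
        v2 = phys.uptake_rate(200.0, 120.0, 0.004, 0.12, 0.014)
        assert v2 == pytest.approx(v1)

    def test_no_biomass_raises(self):
        with pytest.raises(ZeroDivisionError):
            phys.uptake_rate(1, 0, 0.01, 0.01, 0.014)


class TestCO2Uptake:
    def test_published_ins_value(self):
        v = phys.co2_uptake(0.211, 102.3, 0.0)
        assert v == pytest.approx(589.7, rel=0.01)

    def test_published_ons_value(self):
        v = phys.co2_uptake(0.146, 80.3, 79.6)
        assert v == pytest.approx(521.8, rel=0.01)

    def test_biomass_at_substrate_enrichment_means_no_co2(self):
        assert phys.co2_uptake(0.403, 77.0, 0.0) == pytest.approx(0.0)

    def test_infeasible_enrichment_raises(self):
        with pytest.raises(ValueError):
            phys.co2_uptake(0.010, 100.0)

    def test_forward_form_is_exact_inverse(self):
        for f in (0.08, 0.146, 0.211, 0.35):
            v = phys.co2_uptake(f, 102.3, 40.0)
            assert phys.co2_uptake_forward(v, 102.3, 40.0) == pytest.approx(
                f, abs=1e-12
            )


class TestResampling:
    MEANS = dict(f13C_BM=0.211, vGlc_up=102.3, vGln_up=0.0)
    SDS = dict(f13C_BM=0.011, vGlc_up=4.3, vGln_up=0.0)

    def test_zero_sds_degenerate(self):
        mean, sd, rejected = phys.resample_co2_uptake(
            self.MEANS, {k: 0.0 for k in self.SDS}, n=50, seed=0
        )
        assert sd == 0.0
        assert mean == pytest.approx(phys.co2_uptake(0.211, 102.3))
        assert rejected == 0

    def test_sd_has_published_order_of_magnitude(self):
        _, sd, _ = phys.resample_co2_uptake(self.MEANS, self.SDS, n=10000, seed=1)
        assert 10.0 < sd < 200.0  # published +-79.3

    def test_seeded_repeat_is_bit_identical(self):
        a = phys.resample_co2_uptake(self.MEANS, self.SDS, n=500, seed=7)
        b = phys.resample_co2_uptake(self.MEANS, self.SDS, n=500, seed=7)
        assert a == b

    def test_sd_estimate_converges(self):
        _, sd1, _ = phys.resample_co2_uptake(self.MEANS, self.SDS, n=4000, seed=3)
        _, sd4, _ = phys.resample_co2_uptake(self.MEANS, self.SDS, n=16000, seed=4)
        assert abs(sd4 - sd1) / sd4 < 3.0 / math.sqrt(4000)


class TestDepletion:
    def test_glucose_stays_below_20_percent(self):
        f_ins = phys.depletion_fraction(102.3, 0.0137, 0.0021, 0.0656, 2775.0)
        f_ons = phys.depletion_fraction(80.3, 0.0194, 0.0023, 0.0681, 2775.0)
        assert f_ins < 0.20 and f_ons < 0.20
        assert f_ins == pytest.approx(0.17, abs=0.01)

    def test_gln_near_40_percent_under_ons(self):
        f = phys.depletion_fraction(79.6, 0.0194, 0.0023, 0.0681, 685.0)
        assert f == pytest.approx(0.40, abs=0.02)

    def test_zero_uptake_zero_depletion(self):
        assert phys.depletion_fraction(0.0, 0.014, 0.002, 0.06, 100.0) == 0.0


class TestBiomassFluxes:
    def test_cell_wall_glucan_flux(self):
        comp = phys.BiomassComposition(
            {"cell_wall": (0.31, 0.0)},
            {"cell_wall": [("vHPc_out", 1.0 / 162.14)]},
        )
        fluxes = phys.biomass_fluxes(comp, 0.0137)
        assert fluxes["vHPc_out"] == pytest.approx(26.2, abs=0.2)

    def test_zero_fraction_zero_flux(self):
        comp = phys.BiomassComposition(
            {"cell_wall": (0.0, 0.0)}, {"cell_wall": [("vHPc_out", 1 / 162.14)]}
        )
        assert phys.biomass_fluxes(comp, 0.0137)["vHPc_out"] == 0.0

    def test_linear_in_mu_and_fraction(self):
        comp1 = phys.BiomassComposition(
            {"c": (0.1, 0.0)}, {"c": [("vX", 0.01)]}
        )
        comp2 = phys.BiomassComposition(
            {"c": (0.2, 0.0)}, {"c": [("vX", 0.01)]}
        )
        f = phys.biomass_fluxes
        assert f(comp1, 0.028)["vX"] == pytest.approx(2 * f(comp1, 0.014)["vX"])
        assert f(comp2, 0.014)["vX"] == pytest.approx(2 * f(comp1, 0.014)["vX"])

    def test_missing_monomer_spec_is_keyed_error(self):
        with pytest.raises(KeyError, match="lipid"):
            phys.BiomassComposition({"lipid": (0.05, 0.0)}, {})

    def test_default_composition_reconstructs_published_sinks(self):
        for cond in ("INS", "ONS"):
            comp = tables.default_composition(cond)
            mu = math.log(2) / tables.GROWTH[cond]["doubling"]
            fluxes = phys.biomass_fluxes(comp, mu)
            for sink in ("vHPc_out", "vSt_out", "vCit_out", "vFASp"):
                assert fluxes[sink] == pytest.approx(
                    tables.SINK_FLUXES[cond][sink][0], rel=1e-6
                )
            total = sum(f for f, _ in comp.fractions.values())
            assert total <= 1.0


class TestBiomassUncertainty:
    COMP = phys.BiomassComposition(
        {"cell_wall": (0.31, 0.015), "starch": (0.06, 0.006)},
        {
            "cell_wall": [("vHPc_out", 1 / 162.14)],
            "starch": [("vSt_out", 1 / 162.14)],
        },
    )

    def test_zero_sds_give_zero_flux_sds(self):
        out = phys.propagate_biomass_uncertainty(
            phys.BiomassComposition(
                {"cell_wall": (0.31, 0.0)}, {"cell_wall": [("vHPc_out", 1 / 162.14)]}
            ),
            0.0137, 0.0, n=20, seed=0,
        )
        assert out["vHPc_out"][1] == 0.0

    def test_doubling_input_sds_roughly_doubles_output_sds(self):
        big = phys.BiomassComposition(
            {k: (f, 2 * sd) for k, (f, sd) in self.COMP.fractions.items()},
            self.COMP.monomers,
        )
        a = phys.propagate_biomass_uncertainty(self.COMP, 0.0137, 0.0005, 10000, seed=5)
        b = phys.propagate_biomass_uncertainty(big, 0.0137, 0.001, 10000, seed=6)
        for sink in a:
            assert b[sink][1] / a[sink][1] == pytest.approx(2.0, rel=0.1)

    def test_seeded_reproducibility(self):
        a = phys.propagate_biomass_uncertainty(self.COMP, 0.0137, 0.001, 20, seed=9)
        b = phys.propagate_biomass_uncertainty(self.COMP, 0.0137, 0.001, 20, seed=9)
        assert a == b
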