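"""Reduced central-metabolism reference network for growing duckweed fronds.

A compact (~60 reaction) compartmentalized model of *Lemna gibba* central
carbon metabolism with textbook carbon atom maps: cytosolic and plastidic
glycolysis, oxidative pentose-phosphate pathway duplicated in both
compartments (there is no pentose-phosphate translocator), the
Calvin-Benson-Bassham cycle with RuBisCO carboxylation and oxygenation plus
lumped photorespiration, a mitochondrial TCA cycle with a merged OAA/Mal
pool and fumarate-symmetry scrambling, reversible PEP carboxylation
(PEPC/PEPCK), glutamine entry, and the 22 biomass sink fluxes.

Three CO2-pool configurations are supported:

* mode ``A`` — a single cellular CO2 pool used by all carboxylations and
  decarboxylations, with net efflux to the atmosphere only (no uptake of
  atmospheric CO2 is possible);
* mode ``B`` — adds a separate ``CO2_RBC`` pool used by RuBisCO that
  exchanges with atmospheric CO2 via independent uptake and release
  reactions and with the cellular CO2 pool via a reversible mixing
  reaction;
* mode ``C`` — topologically identical to ``B`` but declares uptake-flux
  measurement slots for ``vGlc_up``, ``vGln_up`` and ``vCO2_up`` (the
  latter maps onto the atmospheric influx ``vCO2_atm_in``).

The nitrogen mode toggles the glutamine feed: ``INS`` (inorganic nitrogen)
fixes ``vGln_up`` to zero, ``ONS`` leaves it available.

RuBisCO oxygenation is constrained to 1/1000 of carboxylation in all modes
(photorespiration suppressed under photomixotrophy); O2 itself carries no
carbon and is not tracked.
"""

from __future__ import annotations

from .network import Network, parse_network

__all__ = ["build_lemna_core", "BIOMASS_SINKS", "CO2_MODES", "NITROGEN_MODES"]

CO2_MODES = ("A", "B", "C")
NITROGEN_MODES = ("INS", "ONS")

#: the 22 biomass sink reactions (names as used in the biomass-flux table)
BIOMASS_SINKS = (
    "vAlaP", "vGluP", "vGlnP", "vSerP", "vGlyP", "vHisP", "vPheP", "vTyrP",
    "vValP", "vLeuP", "vIleP", "vThrP", "vAsxP", "vLysP", "vGlyc_out",
    "vFASp", "vGlc_out", "vCit_out", "vMal_out", "vFruc_out", "vSt_out",
    "vHPc_out",
)

_METABOLITES = """\
# metabolite Glc_x x 6 external
# metabolite Gln_x x 5 external
# metabolite CO2_x x 1 external
# metabolite G6P_c c 6 balanced
# metabolite G6P_p p 6 balanced
# metabolite F6P_c c 6 balanced
# metabolite F6P_p p 6 balanced
# metabolite TP_c c 3 balanced
# metabolite TP_p p 3 balanced
# metabolite PGA_c c 3 balanced
# metabolite PGA_p p 3 balanced
# metabolite PEP_c c 3 balanced
# metabolite PEP_p p 3 balanced
# metabolite Pyr_c c 3 balanced
# metabolite Pyr_p p 3 balanced
# metabolite Pyr_m m 3 balanced
# metabolite P5P_c c 5 balanced
# metabolite P5P_p p 5 balanced
# metabolite S7P_c c 7 balanced
# metabolite S7P_p p 7 balanced
# metabolite E4P_c c 4 balanced
# metabolite E4P_p p 4 balanced
# metabolite RuBP_p p 5 balanced
# metabolite PG2_p p 2 balanced
# metabolite AcCoA_p p 2 balanced
# metabolite AcCoA_m m 2 balanced
# metabolite Cit_m m 6 balanced
# metabolite KG_m m 5 balanced
# metabolite OAA merged 4 balanced
# metabolite Glu_c c 5 balanced
# metabolite Gln_c c 5 balanced
# metabolite CO2_c merged 1 balanced
# metabolite AlaBM x 3 external
# metabolite GluBM x 5 external
# metabolite GlnBM x 5 external
# metabolite SerBM x 3 external
# metabolite GlyBM x 2 external
# metabolite C1BM x 1 external
# metabolite HisBM x 5 external
# metabolite PheBM x 9 external
# metabolite TyrBM x 9 external
# metabolite ValBM x 5 external
# metabolite LeuBM x 6 external
# metabolite IleBM x 6 external
# metabolite ThrBM x 4 external
# metabolite AsxBM x 4 external
# metabolite LysBM x 6 external
# metabolite GlycBM x 3 external
# metabolite FASBM x 2 external
# metabolite GlcBM x 6 external
# metabolite CitBM x 6 external
# metabolite MalBM x 4 external
# metabolite FrucBM x 6 external
# metabolite StBM x 6 external
# metabolite HPcBM x 6 external
"""

# Aldolase convention: F6P abcdef splits into DHAP-derived TP (cba) and
# GAP-derived TP (def) so that a single triose pool mixes both halves.
# RuBisCO: carboxylation at C2 of RuBP, cleavage between C2/C3; the new
# (CO2-derived) carbon becomes the carboxyl of the upper PGA.
# Photorespiration lump: 2 phosphoglycolate -> glycerate + CO2 with the CO2
# released from the C1 of one glycolate (via the glycine decarboxylase step).
_REACTIONS_CORE = """\
vGlc_up\tGlc_x#abcdef\tG6P_c#abcdef\tirr\t0.0\t3000.0
vGln_up\tGln_x#abcde\tGln_c#abcde\tirr\t0.0\t3000.0
vPGI_c\tG6P_c#abcdef\tF6P_c#abcdef\trev\t-3000.0\t3000.0
vALD_c\tF6P_c#abcdef\tTP_c#cba + TP_c#def\trev\t-3000.0\t3000.0
vGAPDH_c\tTP_c#abc\tPGA_c#abc\trev\t-3000.0\t3000.0
vENO_c\tPGA_c#abc\tPEP_c#abc\trev\t-3000.0\t3000.0
vPK_c\tPEP_c#abc\tPyr_c#abc\tirr\t0.0\t3000.0
vPGI_p\tG6P_p#abcdef\tF6P_p#abcdef\trev\t-3000.0\t3000.0
vALD_p\tF6P_p#abcdef\tTP_p#cba + TP_p#def\trev\t-3000.0\t3000.0
vGAPDH_p\tTP_p#abc\tPGA_p#abc\trev\t-3000.0\t3000.0
vENO_p\tPGA_p#abc\tPEP_p#abc\trev\t-3000.0\t3000.0
vPK_p\tPEP_p#abc\tPyr_p#abc\tirr\t0.0\t3000.0
vG6PDH_c\tG6P_c#abcdef\tP5P_c#bcdef + CO2_c#a\tirr\t0.0\t3000.0
vTK1_c\tP5P_c#abcde + P5P_c#fghij\tS7P_c#abfghij + TP_c#cde\trev\t-3000.0\t3000.0
vTK2_c\tP5P_c#abcde + E4P_c#fghi\tF6P_c#abfghi + TP_c#cde\trev\t-3000.0\t3000.0
vTA_c\tS7P_c#abcdefg + TP_c#hij\tE4P_c#defg + F6P_c#abchij\trev\t-3000.0\t3000.0
vG6PDH_p\tG6P_p#abcdef\tP5P_p#bcdef + CO2_c#a\tirr\t0.0\t3000.0
vTK1_p\tP5P_p#abcde + P5P_p#fghij\tS7P_p#abfghij + TP_p#cde\trev\t-3000.0\t3000.0
vTK2_p\tP5P_p#abcde + E4P_p#fghi\tF6P_p#abfghi + TP_p#cde\trev\t-3000.0\t3000.0
vTA_p\tS7P_p#abcdefg + TP_p#hij\tE4P_p#defg + F6P_p#abchij\trev\t-3000.0\t3000.0
vT_G6P\tG6P_c#abcdef\tG6P_p#abcdef\trev\t-3000.0\t3000.0
vT_TP\tTP_c#abc\tTP_p#abc\trev\t-3000.0\t3000.0
vT_PEP\tPEP_c#abc\tPEP_p#abc\trev\t-3000.0\t3000.0
vT_PGA\tPGA_c#abc\tPGA_p#abc\trev\t-3000.0\t3000.0
vPRK\tP5P_p#abcde\tRuBP_p#abcde\tirr\t0.0\t3000.0
vRBC\tRuBP_p#abcde + {co2_rbc}#f\tPGA_p#fba + PGA_p#cde\tirr\t0.0\t3000.0
vRBO\tRuBP_p#abcde\tPG2_p#ba + PGA_p#cde\tirr\t0.0\t3000.0
vPR\tPG2_p#ab + PG2_p#cd\tPGA_p#abd + CO2_c#c\tirr\t0.0\t3000.0
vPyr_cm\tPyr_c#abc\tPyr_m#abc\trev\t-3000.0\t3000.0
vPDH_p\tPyr_p#abc\tAcCoA_p#bc + CO2_c#a\tirr\t0.0\t3000.0
vPDH_m\tPyr_m#abc\tAcCoA_m#bc + CO2_c#a\tirr\t0.0\t3000.0
vCS\tOAA#abcd + AcCoA_m#ef\tCit_m#dcbfea\tirr\t0.0\t3000.0
vIDH\tCit_m#abcdef\tKG_m#abcde + CO2_c#f\tirr\t0.0\t3000.0
vKGDH_a\tKG_m#abcde\tOAA#bcde + CO2_c#a\tirr\t0.0\t3000.0
vKGDH_b\tKG_m#abcde\tOAA#edcb + CO2_c#a\tirr\t0.0\t3000.0
vPEPC\tPEP_c#abc + CO2_c#d\tOAA#abcd\trev\t-3000.0\t3000.0
vGlnGlu\tGln_c#abcde\tGlu_c#abcde\trev\t-3000.0\t3000.0
vGluKG\tGlu_c#abcde\tKG_m#abcde\trev\t-3000.0\t3000.0
vCO2_out\tCO2_c#a\tCO2_x#a\tirr\t0.0\t3000.0
vAlaP\tPyr_c#abc\tAlaBM#abc\tirr\t0.0\t3000.0
vGluP\tGlu_c#abcde\tGluBM#abcde\tirr\t0.0\t3000.0
vGlnP\tGln_c#abcde\tGlnBM#abcde\tirr\t0.0\t3000.0
vSerP\tPGA_p#abc\tSerBM#abc\tirr\t0.0\t3000.0
vGlyP\tPGA_p#abc\tGlyBM#ab + C1BM#c\tirr\t0.0\t3000.0
vHisP\tP5P_p#abcde\tHisBM#abcde\tirr\t0.0\t3000.0
vPheP\tE4P_p#abcd + PEP_p#efg + PEP_p#hij\tPheBM#hijfgabcd + CO2_c#e\tirr\t0.0\t3000.0
vTyrP\tE4P_p#abcd + PEP_p#efg + PEP_p#hij\tTyrBM#hijfgabcd + CO2_c#e\tirr\t0.0\t3000.0
vValP\tPyr_p#abc + Pyr_p#def\tValBM#defbc + CO2_c#a\tirr\t0.0\t3000.0
vLeuP\tPyr_p#abc + Pyr_p#def + AcCoA_p#gh\tLeuBM#ghefbc + CO2_c#a + CO2_c#d\tirr\t0.0\t3000.0
vIleP\tOAA#abcd + Pyr_p#efg\tIleBM#abfgcd + CO2_c#e\tirr\t0.0\t3000.0
vThrP\tOAA#abcd\tThrBM#abcd\tirr\t0.0\t3000.0
vAsxP\tOAA#abcd\tAsxBM#abcd\tirr\t0.0\t3000.0
vLysP\tOAA#abcd + Pyr_p#efg\tLysBM#abcdfg + CO2_c#e\tirr\t0.0\t3000.0
vGlyc_out\tTP_c#abc\tGlycBM#abc\tirr\t0.0\t3000.0
vFASp\tAcCoA_p#ab\tFASBM#ab\tirr\t0.0\t3000.0
vGlc_out\tG6P_c#abcdef\tGlcBM#abcdef\tirr\t0.0\t3000.0
vCit_out\tCit_m#abcdef\tCitBM#abcdef\tirr\t0.0\t3000.0
vMal_out\tOAA#abcd\tMalBM#abcd\tirr\t0.0\t3000.0
vFruc_out\tF6P_c#abcdef\tFrucBM#abcdef\tirr\t0.0\t3000.0
vSt_out\tG6P_p#abcdef\tStBM#abcdef\tirr\t0.0\t3000.0
vHPc_out\tG6P_c#abcdef\tHPcBM#abcdef\tirr\t0.0\t3000.0
"""

_REACTIONS_RBC_POOL = """\
vCO2_atm_in\tCO2_x#a\tCO2_RBC#a\tirr\t0.0\t3000.0
vCO2_atm_out\tCO2_RBC#a\tCO2_x#a\tirr\t0.0\t3000.0
vCO2_mix\tCO2_c#a\tCO2_RBC#a\trev\t-3000.0\t3000.0
"""


def network_text(co2_mode: str = "B", nitrogen_mode: str = "ONS") -> str:
    """Network-TSV text of the requested lemna-core configuration."""
    if co2_mode not in CO2_MODES:
        raise ValueError(f"co2_mode must be one of {CO2_MODES}")
    if nitrogen_mode not in NITROGEN_MODES:
        raise ValueError(f"nitrogen_mode must be one of {NITROGEN_MODES}")
    mets = _METABOLITES
    reactions = _REACTIONS_CORE
    if co2_mode == "A":
        reactions = reactions.format(co2_rbc="CO2_c")
    else:
        mets += "# metabolite CO2_RBC merged 1 balanced\n"
        reactions = reactions.format(co2_rbc="CO2_RBC") + _REACTIONS_RBC_POOL
    n_rxn = sum(1 for ln in reactions.splitlines() if ln.strip())
    header = [
        f"# name lemna_core_{co2_mode}_{nitrogen_mode}",
        f"# reactions {n_rxn}",
        "# ratio vRBC vRBO 1000.0",
        "# ratio vKGDH_a vKGDH_b 1.0",
    ]
    if nitrogen_mode == "INS":
        header.append("# fixed vGln_up 0.0")
    return "\n".join(header) + "\n" + mets + reactions


def build_lemna_core(co2_mode: str = "B", nitrogen_mode: str = "ONS") -> Network:
    """Construct the reduced reference network in the requested CO2-pool
    configuration (A, B or C) and nitrogen mode (INS or ONS)."""
    net = parse_network(network_text(co2_mode, nitrogen_mode))
    if co2_mode == "C":
        net.measured_uptakes = ["vGlc_up", "vGln_up", "vCO2_up"]
    return net


#: reaction id the measured atmospheric-CO2 uptake rate constrains (mode C)
CO2_UPTAKE_REACTION = "vCO2_atm_in"
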