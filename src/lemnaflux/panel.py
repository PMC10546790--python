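"""Default GC-MS fragment panel: 27 fragments from 16 biomass analytes.

The measured analytes are proteinogenic amino acids (TBDMS derivatives),
glucose units of starch and cell-wall polymers, the glucosyl and fructosyl
moieties of sucrose, the lipid glycerol moiety, and the C1-C2 unit of
fatty acids.  Each fragment records the skeleton carbon positions retained
in the ion and the elemental formula of the derivative/adduct part beyond
the skeleton carbons (used for natural-isotope correction).

The exact published fragment list is not fully enumerable from the study
text; this panel is a documented synthetic stand-in with the stated counts
(27 fragments, 16 analytes) and typical derivatization chemistry, mapped
onto the biomass sink pools of the reduced reference network.
"""

from __future__ import annotations

from .isotope import FragmentSpec

__all__ = ["panel_default"]

# derivative-part formulas (everything in the ion beyond skeleton carbons)
_M57_2T = "C8H26NO2Si2"     # [M-57], 2x TBDMS amino acids
_M159_2T = "C6H16NSi"       # [M-159], 2x TBDMS amino acids
_M57_3T = "C14H40NO3Si3"    # [M-57], 3x TBDMS amino acids
_M159_3T = "C12H34NOSi2"    # [M-159], 3x TBDMS amino acids
_F302 = "C10H28NO2Si2"      # f302-type C1-C2 fragment of TBDMS amino acids

_PANEL = [
    # (id, analyte, network pool, 1-based carbons, derivative formula)
    ("Ala_M57", "Ala", "AlaBM", (1, 2, 3), _M57_2T),
    ("Ala_M159", "Ala", "AlaBM", (2, 3), _M159_2T),
    ("Gly_M57", "Gly", "GlyBM", (1, 2), _M57_2T),
    ("Gly_M159", "Gly", "GlyBM", (2,), _M159_2T),
    ("Ser_M57", "Ser", "SerBM", (1, 2, 3), _M57_3T),
    ("Ser_M159", "Ser", "SerBM", (2, 3), _M159_3T),
    ("Thr_M57", "Thr", "ThrBM", (1, 2, 3, 4), _M57_3T),
    ("Thr_M159", "Thr", "ThrBM", (2, 3, 4), _M159_3T),
    ("Asp_M57", "Asp", "AsxBM", (1, 2, 3, 4), _M57_3T),
    ("Asp_M159", "Asp", "AsxBM", (2, 3, 4), _M159_3T),
    ("Asp_f302", "Asp", "AsxBM", (1, 2), _F302),
    ("Glu_M57", "Glu", "GluBM", (1, 2, 3, 4, 5), _M57_3T),
    ("Glu_M159", "Glu", "GluBM", (2, 3, 4, 5), _M159_3T),
    ("Glu_f302", "Glu", "GluBM", (1, 2), _F302),
    ("Phe_f302", "Phe", "PheBM", (1, 2), _F302),
    ("Val_M57", "Val", "ValBM", (1, 2, 3, 4, 5), _M57_2T),
    ("Val_M159", "Val", "ValBM", (2, 3, 4, 5), _M159_2T),
    ("Ile_M159", "Ile", "IleBM", (2, 3, 4, 5, 6), _M159_2T),
    ("Lys_M159", "Lys", "LysBM", (2, 3, 4, 5, 6), _M159_2T),
    # glucose units as alditol-acetate / methyl derivatives
    ("StGlc_C16", "starch_glucose", "StBM", (1, 2, 3, 4, 5, 6), "C6H14O5"),
    ("StGlc_C15", "starch_glucose", "StBM", (1, 2, 3, 4, 5), "C4H10O4"),
    ("CWGlc_C16", "cellwall_glucose", "HPcBM", (1, 2, 3, 4, 5, 6), "C6H14O5"),
    # sucrose moieties (TMS)
    ("SucGlc_C16", "sucrose_glucosyl", "GlcBM", (1, 2, 3, 4, 5, 6), "C9H27O3Si3"),
    ("SucFru_C16", "sucrose_fructosyl", "FrucBM", (1, 2, 3, 4, 5, 6), "C9H27O3Si3"),
    # glycerol (trifluoroacetylated; correction part approximated F-free)
    ("Glyc_C13", "glycerol", "GlycBM", (1, 2, 3), "C2H5O2"),
    ("Glyc_C12", "glycerol", "GlycBM", (1, 2), "C2H5O2"),
    # fatty-acid carboxyl unit (McLafferty ion of the methyl ester)
    ("FA_C12", "fatty_acid", "FASBM", (1, 2), "CH4O2"),
]


def panel_default() -> list[FragmentSpec]:
    """The default 27-fragment / 16-analyte measurement panel."""
    return [FragmentSpec(*row) for row in _PANEL]
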