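"""Measured physiology and biomass-flux values for the two growth
conditions.

These are the published endpoint measurements for *Lemna gibba* fronds
grown photomixotrophically on glucose with either an inorganic (INS,
nitrate/ammonium) or an organic (ONS, glutamine) nitrogen source: growth
parameters, substrate uptake rates, and the 22 biomass sink fluxes.  They
serve as the fixed inputs of the flux-analysis pipeline and as the anchors
of the synthetic-data presets.
"""

from __future__ import annotations

import numpy as np

from .physiology import BiomassComposition

__all__ = [
    "GROWTH",
    "UPTAKES",
    "SINK_FLUXES",
    "MEDIUM",
    "default_composition",
    "AA_SINK_SPEC",
]

#: growth parameters (means; SDs where used downstream).  Initial dry
#: weights are not measured directly and are reconstructed as
#: A0 x (dw per area); dry weights in g, areas cm^2, times h.
GROWTH = {
    "INS": dict(
        t=240.0, A0=1.1, At=34.1, D=0.0656, dw_per_area=0.0019,
        doubling=50.5, doubling_sd=2.0, mu=0.014, mu_sd=0.001,
        f13C_BM=0.211, f13C_BM_sd=0.011,
    ),
    "ONS": dict(
        t=192.0, A0=0.9, At=27.2, D=0.0681, dw_per_area=0.0025,
        doubling=35.7, doubling_sd=1.0, mu=0.019, mu_sd=0.001,
        f13C_BM=0.146, f13C_BM_sd=0.001,
    ),
}

#: specific substrate uptake rates, umol / g dw / h (mean, SD)
UPTAKES = {
    "INS": {"vGlc_up": (102.3, 4.3), "vGln_up": (0.0, 0.0), "vCO2_up": (589.7, 79.3)},
    "ONS": {"vGlc_up": (80.3, 2.5), "vGln_up": (79.6, 2.1), "vCO2_up": (521.8, 56.4)},
}

#: medium supply per 100 mL culture: glucose 5 g/L, Gln 6.85 mM (ONS); umol
MEDIUM = {"S0_glc": 2775.0, "S0_gln": 685.0}

#: the 22 biomass sink fluxes, umol / g dw / h (mean, SD)
SINK_FLUXES = {
    "INS": {
        "vAlaP": (2.92, 0.18), "vGluP": (6.53, 0.26), "vGlnP": (3.00, 0.15),
        "vSerP": (3.04, 0.32), "vGlyP": (1.99, 0.07), "vHisP": (0.95, 0.03),
        "vPheP": (2.26, 0.06), "vTyrP": (1.76, 0.05), "vValP": (2.28, 0.07),
        "vLeuP": (2.93, 0.09), "vIleP": (1.50, 0.04), "vThrP": (2.50, 0.08),
        "vAsxP": (7.84, 0.64), "vLysP": (2.20, 0.06), "vGlyc_out": (2.87, 0.05),
        "vFASp": (48.43, 0.87), "vGlc_out": (7.17, 0.66), "vCit_out": (5.46, 0.57),
        "vMal_out": (4.45, 0.48), "vFruc_out": (1.74, 0.35), "vSt_out": (5.24, 0.61),
        "vHPc_out": (26.17, 0.50),
    },
    "ONS": {
        "vAlaP": (4.85, 0.20), "vGluP": (10.99, 0.36), "vGlnP": (5.00, 0.17),
        "vSerP": (4.49, 0.27), "vGlyP": (3.49, 0.15), "vHisP": (1.65, 0.07),
        "vPheP": (4.05, 0.18), "vTyrP": (3.15, 0.14), "vValP": (4.01, 0.16),
        "vLeuP": (5.24, 0.22), "vIleP": (2.67, 0.11), "vThrP": (4.43, 0.18),
        "vAsxP": (11.88, 0.43), "vLysP": (3.93, 0.17), "vGlyc_out": (3.36, 0.09),
        "vFASp": (56.67, 1.48), "vGlc_out": (10.90, 0.85), "vCit_out": (8.20, 0.55),
        "vMal_out": (7.18, 0.55), "vFruc_out": (2.65, 0.24), "vSt_out": (6.24, 0.60),
        "vHPc_out": (17.76, 0.86),
    },
}

# ---------------------------------------------------------------------------
# default protein amino-acid composition and monomer specifications

#: anhydroglucose residue mass in glucan polymers (cell wall, starch), g/mol
MW_ANHYDROGLUCOSE = 162.14

#: generic plant-protein amino-acid composition (g amino acid per g protein)
#: with residue molar masses (free MW - 18.02).  This is a synthetic
#: stand-in for a literature-average duckweed protein table; users supply
#: their own for real analyses.
AA_COMPOSITION = {
    # aa: (mass fraction of protein, residue MW)
    "Ala": (0.062, 71.08), "Arg": (0.058, 156.19), "Asx": (0.094, 114.60),
    "Cys": (0.010, 103.14), "Glu": (0.066, 129.12), "Gln": (0.044, 128.13),
    "Gly": (0.054, 57.05), "His": (0.022, 137.14), "Ile": (0.046, 113.16),
    "Leu": (0.086, 113.16), "Lys": (0.059, 128.17), "Met": (0.018, 131.19),
    "Phe": (0.053, 147.18), "Pro": (0.046, 97.12), "Ser": (0.047, 87.08),
    "Thr": (0.046, 101.10), "Trp": (0.015, 186.21), "Tyr": (0.039, 163.18),
    "Val": (0.058, 99.13),
}

#: amino acid -> biomass sink reaction (lumping as in the flux table:
#: Pro/Arg drain with Glu, Cys with Ser, Trp with His, Met with Thr)
AA_SINK_SPEC = {
    "Ala": "vAlaP", "Arg": "vGluP", "Asx": "vAsxP", "Cys": "vSerP",
    "Glu": "vGluP", "Gln": "vGlnP", "Gly": "vGlyP", "His": "vHisP",
    "Ile": "vIleP", "Leu": "vLeuP", "Lys": "vLysP", "Met": "vThrP",
    "Phe": "vPheP", "Pro": "vGluP", "Ser": "vSerP", "Thr": "vThrP",
    "Trp": "vHisP", "Tyr": "vTyrP", "Val": "vValP",
}


def _protein_monomers() -> list[tuple[str, float]]:
    per_sink: dict[str, float] = {}
    for aa, (w, mw) in AA_COMPOSITION.items():
        sink = AA_SINK_SPEC[aa]
        per_sink[sink] = per_sink.get(sink, 0.0) + w / mw
    return sorted(per_sink.items())


#: monomer molar masses used for the non-protein components, g/mol
_MW = {
    # hexose pools counted as glycosyl residues, acyl chains as CH2-CH2 units
    "glucose": 162.14, "fructose": 162.14, "citrate": 192.12,
    "malate": 134.09, "glycerol_moiety": 92.09 - 18.02,
    "acetyl_unit": 28.05,
}


def default_composition(condition: str) -> BiomassComposition:
    """Default biomass composition for one growth condition.

    Non-protein fractions are back-derived from the published sink fluxes
    and growth rate (a documented reconstruction — the underlying
    composition table is not reproduced here); the protein fraction is the
    least-squares match of the amino-acid sink fluxes given the default
    protein composition table.
    """
    mu = np.log(2.0) / GROWTH[condition]["doubling"]
    sinks = SINK_FLUXES[condition]
    scale = mu * 1e6

    def back(sink: str, mw: float, n_monomer: float = 1.0) -> float:
        return sinks[sink][0] * mw / n_monomer / scale

    protein_mono = _protein_monomers()
    m = np.array([mol for _, mol in protein_mono])
    f = np.array([sinks[s][0] for s, _ in protein_mono]) / scale
    protein_frac = float(m @ f / (m @ m))

    fractions = {
        "protein": protein_frac,
        "cell_wall": back("vHPc_out", MW_ANHYDROGLUCOSE),
        "starch": back("vSt_out", MW_ANHYDROGLUCOSE),
        "hexoses": back("vGlc_out", _MW["glucose"]),
        "fructose": back("vFruc_out", _MW["fructose"]),
        "citrate": back("vCit_out", _MW["citrate"]),
        "malate": back("vMal_out", _MW["malate"]),
        "lipid_glycerol": back("vGlyc_out", _MW["glycerol_moiety"]),
        "lipid_acyl": back("vFASp", _MW["acetyl_unit"]),
    }
    # The reconstruction slightly overshoots unit mass because the sink
    # fluxes also drain free-metabolite pools not part of the dry-weight
    # polymer fractions; rescale fractions to sum below one while keeping
    # the implied fluxes exact (monomer coefficients scale inversely).
    total = sum(fractions.values())
    factor = min(1.0, 0.98 / total)
    fractions = {k: v * factor for k, v in fractions.items()}

    rel_sd = 0.05  # generic relative uncertainty of composition fractions
    monomers = {
        "protein": [(s, m / factor) for s, m in protein_mono],
        "cell_wall": [("vHPc_out", 1.0 / MW_ANHYDROGLUCOSE / factor)],
        "starch": [("vSt_out", 1.0 / MW_ANHYDROGLUCOSE / factor)],
        "hexoses": [("vGlc_out", 1.0 / _MW["glucose"] / factor)],
        "fructose": [("vFruc_out", 1.0 / _MW["fructose"] / factor)],
        "citrate": [("vCit_out", 1.0 / _MW["citrate"] / factor)],
        "malate": [("vMal_out", 1.0 / _MW["malate"] / factor)],
        "lipid_glycerol": [("vGlyc_out", 1.0 / _MW["glycerol_moiety"] / factor)],
        "lipid_acyl": [("vFASp", 1.0 / _MW["acetyl_unit"] / factor)],
    }
    return BiomassComposition(
        {k: (v, rel_sd * v) for k, v in fractions.items()}, monomers
    )
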