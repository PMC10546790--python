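"""Physiological rate equations for exponentially growing duckweed cultures.

Specific growth rate from frond-area increase, doubling time, specific
substrate uptake rates from medium depletion, the atmospheric-CO2 uptake
rate inferred from whole-biomass 13C enrichment, substrate depletion
fractions, biomass-composition-derived sink fluxes, and resampling-based
error propagation for all of these.

Units: areas cm^2, dry weights g, times h, substrate amounts umol, rates
umol per g dry weight per h, growth rate 1/h, enrichments as fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "growth_rate",
    "doubling_time",
    "uptake_rate",
    "co2_uptake",
    "co2_uptake_forward",
    "resample_co2_uptake",
    "depletion_fraction",
    "BiomassComposition",
    "biomass_fluxes",
    "propagate_biomass_uncertainty",
    "GrowthRecord",
    "E_NAT",
    "E_GLC_U40",
]

#: natural-abundance fractional 13C enrichment
E_NAT = 0.011
#: average 13C enrichment of medium glucose in the 40:60 U-13C6 experiment
E_GLC_U40 = 0.403


@dataclass
class GrowthRecord:
    """Endpoint growth observation of one culture."""

    A0: float  # initial frond area, cm^2
    At: float  # final frond area, cm^2
    t: float  # culture time, h
    D0: float | None = None  # initial dry weight, g
    D: float | None = None  # final dry weight, g

    @property
    def mu(self) -> float:
        return growth_rate(self.A0, self.At, self.t)


def growth_rate(A0: float, At: float, t: float) -> float:
    """Specific growth rate mu = (ln At - ln A0) / t of an exponentially
    growing culture, from initial and final frond area."""
    if A0 <= 0 or At <= 0 or t <= 0:
        raise ValueError("areas and culture time must be positive")
    return (math.log(At) - math.log(A0)) / t


def doubling_time(mu: float) -> float:
    """Doubling time ln 2 / mu."""
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    return math.log(2.0) / mu


def uptake_rate(S0: float, S: float, D0: float, D: float, mu: float) -> float:
    """Specific substrate uptake rate v = ((S0 - S)/(D - D0)) * mu.

    ``S0``/``S`` are the substrate amounts (umol) in the vessel at the start
    and end of culture, ``D0``/``D`` the corresponding dry weights (g);
    consumption is reported positive.
    """
    if D == D0:
        raise ZeroDivisionError("no biomass was formed (D == D0)")
    return (S0 - S) / (D - D0) * mu


def co2_uptake(
    f13C_BM: float,
    vGlc_up: float,
    vGln_up: float = 0.0,
    e_glc: float = E_GLC_U40,
    e_nat: float = E_NAT,
) -> float:
    """Atmospheric-CO2 uptake rate inferred from whole-biomass 13C
    enrichment.

    Solves the carbon-molar enrichment balance for the CO2 uptake rate:
    ``vCO2 = [6 vGlc (e_glc - f) + 5 vGln (e_nat - f)] / (f - e_nat)``.
    Requires the biomass enrichment ``f13C_BM`` to exceed natural abundance.
    """
    if f13C_BM <= e_nat:
        raise ValueError(
            "biomass enrichment at or below natural abundance: no positive CO2 uptake"
        )
    return (
        6.0 * vGlc_up * (e_glc - f13C_BM) + 5.0 * vGln_up * (e_nat - f13C_BM)
    ) / (f13C_BM - e_nat)


def co2_uptake_forward(
    vCO2_up: float,
    vGlc_up: float,
    vGln_up: float = 0.0,
    e_glc: float = E_GLC_U40,
    e_nat: float = E_NAT,
) -> float:
    """Forward form: biomass 13C enrichment implied by the carbon-molar
    uptake fluxes (exact inverse of :func:`co2_uptake`)."""
    num = 6.0 * vGlc_up * e_glc + 5.0 * vGln_up * e_nat + vCO2_up * e_nat
    den = 6.0 * vGlc_up + 5.0 * vGln_up + vCO2_up
    return num / den


def resample_co2_uptake(
    means: dict[str, float],
    sds: dict[str, float],
    n: int = 10000,
    seed: int | None = None,
    e_glc: float = E_GLC_U40,
    e_nat: float = E_NAT,
) -> tuple[float, float, int]:
    """Monte-Carlo (resampling) uncertainty of the inferred CO2 uptake rate.

    ``means``/``sds`` carry keys ``f13C_BM``, ``vGlc_up``, ``vGln_up``.
    Draws with an infeasible biomass enrichment (f <= e_nat) are rejected
    and redrawn; the rejection count is returned alongside mean and sample
    SD.
    """
    if n < 2:
        raise ValueError("need at least 2 resamples")
    rng = np.random.default_rng(seed)
    keys = ("f13C_BM", "vGlc_up", "vGln_up")
    out = np.empty(n)
    rejected = 0
    for i in range(n):
        while True:
            f, vglc, vgln = (
                rng.normal(means[k], sds.get(k, 0.0)) for k in keys
            )
            if f > e_nat:
                break
            rejected += 1
        out[i] = co2_uptake(f, vglc, vgln, e_glc, e_nat)
    ddof = 1 if n > 1 else 0
    return float(out.mean()), float(out.std(ddof=ddof)), rejected


def depletion_fraction(v: float, mu: float, D0: float, D: float, S0: float) -> float:
    """Fraction of the initially supplied substrate consumed over the
    culture: ``v * (D - D0) / mu / S0``."""
    if S0 == 0:
        raise ZeroDivisionError("no substrate supplied (S0 == 0)")
    return v * (D - D0) / mu / S0


# ---------------------------------------------------------------------------
# biomass composition -> sink fluxes


@dataclass
class BiomassComposition:
    """Biomass fraction table and monomer specification.

    ``fractions`` maps component name -> (g per g dry weight, SD).
    ``monomers`` maps component name -> list of (sink flux name, mol of that
    sink's monomer per g of component).
    """

    fractions: dict[str, tuple[float, float]]
    monomers: dict[str, list[tuple[str, float]]]

    def __post_init__(self):
        for name, (f, sd) in self.fractions.items():
            if f < 0 or sd < 0:
                raise ValueError(f"negative fraction or SD for {name}")
        total = sum(f for f, _ in self.fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"fractions sum to {total} > 1")
        missing = [c for c in self.fractions if c not in self.monomers]
        if missing:
            raise KeyError(f"no monomer specification for component(s) {missing}")


def biomass_fluxes(composition: BiomassComposition, mu: float) -> dict[str, float]:
    """Biomass sink fluxes (umol / g dw / h): for each sink,
    sum over components of (g/g fraction) x (mol monomer per g component)
    x mu x 1e6."""
    fluxes: dict[str, float] = {}
    for comp, (frac, _) in composition.fractions.items():
        for sink, mol_per_g in composition.monomers[comp]:
            fluxes[sink] = fluxes.get(sink, 0.0) + frac * mol_per_g * mu * 1e6
    return fluxes


def propagate_biomass_uncertainty(
    composition: BiomassComposition,
    mu_mean: float,
    mu_sd: float,
    n: int = 20,
    seed: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Gaussian perturbation of composition fractions and growth rate,
    repeated ``n`` times; returns per-sink (mean, sample SD).  Perturbed
    fractions falling below zero are truncated at zero."""
    if n < 2:
        raise ValueError("need at least 2 repetitions")
    rng = np.random.default_rng(seed)
    names = sorted({s for mono in composition.monomers.values() for s, _ in mono})
    samples = {s: np.empty(n) for s in names}
    for i in range(n):
        mu = rng.normal(mu_mean, mu_sd)
        # perturbed fractions bypass the unit-sum check: jitter around a
        # composition near 1 g/g legitimately overshoots it
        fluxes: dict[str, float] = {}
        for c, (f, sd) in composition.fractions.items():
            frac = max(0.0, rng.normal(f, sd))
            for sink, mol_per_g in composition.monomers[c]:
                fluxes[sink] = fluxes.get(sink, 0.0) + frac * mol_per_g * mu * 1e6
        for s in names:
            samples[s][i] = fluxes.get(s, 0.0)
    return {
        s: (float(v.mean()), float(v.std(ddof=1))) for s, v in samples.items()
    }
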