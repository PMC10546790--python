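"""Synthetic labeling datasets with the experimental design of the study.

Ground-truth flux states are anchored to the measured uptake rates and the
22 biomass sink fluxes, with the remaining free fluxes set to reproduce the
published operating regime: combined oxidative-OPPP flux at 60% of RuBisCO
carboxylation, an even cytosol/plastid OPPP split, the atmospheric share of
the RuBisCO CO2 pool near 58% (INS) / 60% (ONS), and PEP carboxylation
running forward under INS but reversed (decarboxylating) under ONS.
Measurements emulate the GC-MS panel: fragment MIDs simulated at truth,
mixed with 3.3% unlabeled inoculum biomass, convolved with the natural
isotopologue distribution of the derivative side chains, and corrupted with
Gaussian noise (SD 1% fractional enrichment by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from . import tables
from .emu import FLUX_CLAMP
from .fitting import (
    RAW_MASS_WINDOW,
    FluxMeasurement,
    LabelingModel,
    MeasurementSet,
    MIDMeasurement,
)
from .isotope import (
    INOCULUM_FRACTION,
    FragmentSpec,
    SubstrateLabel,
    glucose_80_10_10,
    natural_mid,
    natural_skeleton_mid,
)
from .lemna_core import BIOMASS_SINKS, CO2_UPTAKE_REACTION, build_lemna_core
from .network import FluxState, Network, steady_state_basis
from .panel import panel_default

__all__ = ["ScenarioPreset", "preset", "truth_flux", "generate_measurements"]


@dataclass
class ScenarioPreset:
    """Study-condition preset for synthetic data generation."""

    name: str  # "INS" or "ONS"
    co2_mode: str = "C"
    uptakes: dict = field(default_factory=dict)  # reaction -> (mean, sd)
    sinks: dict = field(default_factory=dict)  # reaction -> (mean, sd)
    labels: dict = field(default_factory=dict)  # substrate -> SubstrateLabel
    noise_sd: float = 0.01
    inoculum_fraction: float = INOCULUM_FRACTION
    oppp_flux: float = 0.0  # combined oxidative OPPP target, umol/gdw/h
    oppp_rubisco_ratio: float = 0.60
    atm_fraction: float = 0.58
    pepc_net: float = 25.0
    seed: int = 0

    @property
    def condition(self) -> str:
        return self.name


def preset(name: str, co2_mode: str = "C", seed: int = 0) -> ScenarioPreset:
    """The INS-like or ONS-like scenario with the published anchors."""
    if name not in ("INS", "ONS"):
        raise ValueError("preset name must be 'INS' or 'ONS'")
    up = tables.UPTAKES[name]
    # combined OPPP flux and atmospheric fraction as published per condition
    anchors = dict(
        INS=dict(oppp=128.1, atm=0.58, pepc=25.0),
        ONS=dict(oppp=141.4, atm=0.60, pepc=-15.0),
    )[name]
    return ScenarioPreset(
        name=name,
        co2_mode=co2_mode,
        uptakes={"vGlc_up": up["vGlc_up"], "vGln_up": up["vGln_up"]},
        sinks=dict(tables.SINK_FLUXES[name]),
        labels={"Gln_x": None, "Glc_x": glucose_80_10_10()},
        oppp_flux=anchors["oppp"],
        atm_fraction=anchors["atm"],
        pepc_net=anchors["pepc"],
        seed=seed,
    )


def preset_labels(p: ScenarioPreset) -> dict[str, SubstrateLabel]:
    """Substrate labels of a preset (unlabeled feeds are implied)."""
    return {k: v for k, v in p.labels.items() if v is not None}


def _fixed_fluxes(p: ScenarioPreset) -> dict[str, float]:
    fixed = {sink: p.sinks[sink][0] for sink in BIOMASS_SINKS}
    fixed["vGlc_up"] = p.uptakes["vGlc_up"][0]
    fixed["vGln_up"] = p.uptakes["vGln_up"][0]
    return fixed


def truth_flux(p: ScenarioPreset, network: Network | None = None) -> FluxState:
    """Ground-truth flux state of a preset on the reference network.

    Uptakes and the 22 sinks are fixed to their measured values; the
    remaining free net fluxes are solved by least squares against the
    regime anchors (OPPP split and total, atmospheric CO2 influx, PEPC
    direction) with a small ridge pulling undetermined splits toward
    moderate values; exchange fluxes come from a seeded draw, with the
    CO2-pool mixing exchange set to realize the atmospheric-fraction
    anchor exactly.
    """
    network = network or build_lemna_core(p.co2_mode, p.name)
    basis = steady_state_basis(network, extra_fixed=_fixed_fluxes(p))
    n = len(network.reactions)
    vrbc = p.oppp_flux / p.oppp_rubisco_ratio
    targets = {
        "vRBC": (vrbc, 1.0),
        "vG6PDH_c": (p.oppp_flux / 2.0, 1.0),
        "vG6PDH_p": (p.oppp_flux / 2.0, 1.0),
        # soft: PEPC magnitude is largely set by the fixed sink demands;
        # only its direction is an anchor (asserted below)
        "vPEPC": (p.pepc_net, 0.05),
    }
    if p.co2_mode in ("B", "C"):
        targets[CO2_UPTAKE_REACTION] = (tables.UPTAKES[p.name]["vCO2_up"][0], 1.0)

    t_idx = np.array([network.rxn_index(r) for r in targets])
    t_val = np.array([targets[r][0] for r in targets])
    t_w = np.array([targets[r][1] for r in targets])
    N, vp = basis.nullspace, basis.particular
    lo = np.array([r.lb for r in network.reactions])
    ridge = 0.02

    def resid(q):
        v = vp + N @ q
        under = np.where(np.isfinite(lo), np.minimum(v - lo, 0.0), 0.0)
        return np.concatenate(
            [
                t_w * (v[t_idx] - t_val),
                ridge * v / 100.0,
                1e4 * under,
            ]
        )

    q0 = np.zeros(basis.n_free_net)
    sol = scipy.optimize.least_squares(resid, q0, method="trf")
    v = vp + N @ sol.x
    viol = np.min(np.where(np.isfinite(lo), v - lo, 0.0))
    if viol < -1e-6:
        raise RuntimeError(f"truth construction violates bounds by {viol}")
    hard = t_w >= 0.5
    dev = np.max(np.abs(v[t_idx][hard] - t_val[hard]) / np.maximum(1.0, np.abs(t_val[hard])))
    if dev > 0.02:
        raise RuntimeError(f"truth anchors missed by up to {dev:.1%}")
    if np.sign(v[network.rxn_index("vPEPC")]) != np.sign(p.pepc_net):
        raise RuntimeError("PEPC direction anchor not realized by this preset")
    v[np.abs(v) < FLUX_CLAMP] = 0.0

    rng = np.random.default_rng(p.seed)
    xch = np.zeros(n)
    for rid in basis.free_exchange_ids:
        xch[network.rxn_index(rid)] = rng.uniform(2.0, 25.0)
    if p.co2_mode in ("B", "C"):
        i_in = network.rxn_index(CO2_UPTAKE_REACTION)
        i_mix = network.rxn_index("vCO2_mix")
        mix_fwd = v[i_in] * (1.0 - p.atm_fraction) / p.atm_fraction
        x_mix = mix_fwd - max(v[i_mix], 0.0)
        if x_mix < 0:
            raise RuntimeError("atmospheric-fraction anchor infeasible for this truth")
        xch[i_mix] = x_mix
    state = FluxState(network, v, xch)
    if state.steady_state_residual() > 1e-9:
        raise RuntimeError("constructed truth is not at steady state")
    return state


def generate_measurements(
    truth: FluxState,
    network: Network | None = None,
    panel: list[FragmentSpec] | None = None,
    p: ScenarioPreset | None = None,
    seed: int | None = None,
    model: LabelingModel | None = None,
) -> MeasurementSet:
    """Simulate the raw (derivatized, inoculum-mixed, noisy) measurement set
    of a preset at a given truth flux state.

    With ``noise_sd = 0`` and ``inoculum_fraction = 0`` the raw MIDs equal
    the simulated fragment MIDs convolved with the derivative natural
    distribution exactly.  Fixed seed gives identical output.
    """
    p = p or preset("INS")
    network = network or truth.network
    panel = panel or panel_default()
    labels = preset_labels(p)
    model = model or LabelingModel(network, panel, labels)
    skel = model.fragment_mids(truth)
    rng = np.random.default_rng(p.seed if seed is None else seed)
    f = p.inoculum_fraction
    mids = []
    for frag in panel:
        m = skel[frag.id]
        if f > 0:
            m = (1.0 - f) * m + f * natural_skeleton_mid(frag.n_carbons)
        raw = np.convolve(m, natural_mid(frag.formula)) if frag.formula else m
        raw = raw[: frag.n_carbons + RAW_MASS_WINDOW]  # recorded mass window
        raw = raw / raw.sum()
        # per-entry SDs of renormalized additive intensity noise: the
        # normalization correlates the entries and inflates the variance of
        # dominant fractions (this is what replicate-derived empirical SDs
        # of measured fractions show)
        k = len(raw)
        sds = p.noise_sd * np.sqrt(np.clip(1.0 - 2.0 * raw + k * raw**2, 0.0, None))
        if p.noise_sd > 0:
            # additive Gaussian noise, renormalized; entries are NOT clipped
            # at zero (like real corrected MS fractions, near-zero bins may
            # go slightly negative) so that every entry stays unbiased
            raw = raw + rng.normal(0.0, p.noise_sd, size=k)
            raw = raw / raw.sum()
        mids.append(
            MIDMeasurement(
                frag, raw, sds,
                noise_sigma=p.noise_sd if p.noise_sd > 0 else None,
            )
        )
    fluxes = []
    if p.co2_mode == "C":
        fluxes.append(
            FluxMeasurement("vGlc_up", truth["vGlc_up"], p.uptakes["vGlc_up"][1])
        )
        if p.uptakes["vGln_up"][0] > 0:
            fluxes.append(
                FluxMeasurement("vGln_up", truth["vGln_up"], p.uptakes["vGln_up"][1])
            )
        fluxes.append(
            FluxMeasurement(
                CO2_UPTAKE_REACTION,
                truth[CO2_UPTAKE_REACTION],
                tables.UPTAKES[p.name]["vCO2_up"][1],
            )
        )
    return MeasurementSet(mids, fluxes)


#: small two-substrate condensation network used for statistical
#: calibration studies: every free parameter (one net flux, one exchange)
#: has direct labeling leverage on the measured fragments
CALIBRATION_TOY = """\
# name toy_calibration
# reactions 5
# metabolite A x 2 external
# metabolite B x 2 external
# metabolite C c 2 balanced
# metabolite D c 2 balanced
# metabolite E c 4 balanced
# metabolite F x 4 external
# fixed v1 10.0
v1\tA#ab\tC#ab\tirr\t0.0\t100.0
v2\tB#ab\tD#ab\tirr\t0.0\t100.0
vx\tC#ab\tD#ab\trev\t-100.0\t100.0
v3\tC#ab + D#cd\tE#abcd\tirr\t0.0\t100.0
v4\tE#abcd\tF#abcd\tirr\t0.0\t100.0
"""


def calibration_problem():
    """Calibration study setup: network, ground-truth flux state, substrate
    labels, measured fragments, and the compiled labeling model.

    The labeled feed enters pool C, the unlabeled feed pool D; the free net
    flux sets how much labeled carbon crosses into D and the free exchange
    sets how far the two pools equilibrate, and the three E fragments (full
    and both halves) observe both directly.
    """
    from .network import parse_network

    net = parse_network(CALIBRATION_TOY)
    n = len(net.reactions)
    v = np.zeros(n)
    for rid, val in [("v1", 10.0), ("v2", 6.0), ("vx", 2.0), ("v3", 8.0), ("v4", 8.0)]:
        v[net.rxn_index(rid)] = val
    x = np.zeros(n)
    x[net.rxn_index("vx")] = 10.0
    truth = FluxState(net, v, x)
    # both feeds carry label so every measured mass bin is populated: bins
    # with no signal would only contribute clipping bias to the statistic
    labels = {
        "A": SubstrateLabel((("11", 0.5, 0.90), ("00", 0.5, 0.0))),
        "B": SubstrateLabel((("11", 0.2, 0.90), ("00", 0.8, 0.0))),
    }
    frags = [
        FragmentSpec("E_full", "E", "E", (1, 2, 3, 4)),
        FragmentSpec("E_12", "E", "E", (1, 2)),
        FragmentSpec("E_34", "E", "E", (3, 4)),
    ]
    model = LabelingModel(net, frags, labels)
    return net, truth, labels, frags, model


def fitting_network(p: ScenarioPreset, co2_mode: str | None = None) -> Network:
    """Network used for fitting a preset's data: sinks and uptakes fixed to
    their measured values (the uptake rates stay free parameters when the
    CO2 mode provides them as flux measurements instead)."""
    mode = co2_mode or p.co2_mode
    net = build_lemna_core(mode, p.name)
    fixed = {sink: p.sinks[sink][0] for sink in BIOMASS_SINKS}
    if mode != "C":
        fixed["vGlc_up"] = p.uptakes["vGlc_up"][0]
        fixed["vGln_up"] = p.uptakes["vGln_up"][0]
    return net.with_fixed(fixed)
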