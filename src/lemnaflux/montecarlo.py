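"""Monte-Carlo flux uncertainty, compartment-aggregated statistics, flux
ratios, and the atmospheric share of the RuBisCO CO2 pool.

Flux confidence measures come from repeatedly corrupting the measurement
set with Gaussian noise (per the reported standard deviations, after the 1%
floor), refitting each corrupted replicate from multiple random starts, and
taking sample statistics over the replicate best fits.  Linear
combinations — in particular the sums that merge compartment-duplicated
reactions into the uncompartmentalized view — are applied to every ensemble
member, so the uncertainty of a combined flux reflects the (often strongly
negative) correlations between its poorly-resolved parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fitting import (
    FitResult,
    LabelingModel,
    MeasurementSet,
    MIDMeasurement,
    FluxMeasurement,
    apply_sd_floor,
    fit,
)
from .network import AggregationMap, FluxState, Network

__all__ = [
    "MCEnsemble",
    "monte_carlo",
    "perturb_measurements",
    "aggregate_ensemble",
    "flux_ratio",
    "atmospheric_fraction",
]


@dataclass
class MCEnsemble:
    """Best-fit flux states of noise-perturbed measurement replicates."""

    network: Network
    base: FitResult
    members: list[FluxState]
    replicate_seeds: list[int]
    flagged: list[int] = field(default_factory=list)

    @property
    def net_matrix(self) -> np.ndarray:
        return np.vstack([m.net for m in self.members])

    def stats(self) -> dict[str, tuple[float, float]]:
        """Per-reaction (mean, sample SD) of the net flux over members."""
        M = self.net_matrix
        mean = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        return {
            r.id: (float(mean[i]), float(sd[i]))
            for i, r in enumerate(self.network.reactions)
        }


def perturb_measurements(
    meas: MeasurementSet, rng: np.random.Generator
) -> MeasurementSet:
    """One noise replicate: Gaussian noise with the (floored) SDs added to
    every MID entry (clipped at zero, renormalized) and to every flux
    measurement."""
    mids = []
    for m in meas.mids:
        # unbiased corruption matching the generator's noise model:
        # additive intensity noise then renormalization (whiteners are
        # rebuilt around the perturbed values at fit time)
        sigma = m.noise_sigma if m.noise_sigma else None
        vals = m.values + rng.normal(0.0, sigma if sigma else m.sds, size=len(m.values))
        s = vals.sum()
        if s <= 0:
            vals = m.values.copy()
            s = vals.sum()
        mids.append(
            MIDMeasurement(m.fragment, vals / s, m.sds, noise_sigma=m.noise_sigma)
        )
    fluxes = [
        FluxMeasurement(f.reaction, f.value + rng.normal(0.0, f.sd), f.sd)
        for f in meas.fluxes
    ]
    return MeasurementSet(mids, fluxes)


def monte_carlo(
    network: Network,
    meas: MeasurementSet,
    labels: dict,
    n_replicates: int = 20,
    restarts_per_replicate: int = 50,
    seed: int | None = None,
    max_iter: int = 2000,
    base_fit: FitResult | None = None,
    xch_scale: float | None = None,
    model: LabelingModel | None = None,
    stop_at: float | None = None,
    sd_floor: float | None = None,
) -> MCEnsemble:
    """Monte-Carlo flux uncertainty by refitting noise-corrupted data.

    Each replicate perturbs the measurements per their SDs and refits from
    ``restarts_per_replicate`` start points (the base best fit is always
    included as a warm start).  A replicate whose fit fails is redrawn
    once, then recorded as flagged.
    """
    from .fitting import SD_FLOOR

    floor = SD_FLOOR if sd_floor is None else sd_floor
    meas = apply_sd_floor(meas, floor)
    model = model or LabelingModel(network, meas.fragments, labels)
    kw = {} if xch_scale is None else dict(xch_scale=xch_scale)
    if base_fit is None:
        base_fit = fit(
            network, meas, labels,
            n_restarts=restarts_per_replicate, max_iter=max_iter,
            seed=None if seed is None else seed + 1_000_003, model=model,
            sd_floor=floor, **kw,
        )
    rng = np.random.default_rng(seed)
    members: list[FluxState] = []
    seeds: list[int] = []
    flagged: list[int] = []
    warm = [(base_fit.q, base_fit.t)]
    for i in range(n_replicates):
        ok = False
        for attempt in range(2):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            pert = perturb_measurements(meas, np.random.default_rng(rep_seed))
            try:
                r = fit(
                    network, pert, labels,
                    n_restarts=restarts_per_replicate, max_iter=max_iter,
                    seed=rep_seed, model=model, basis=base_fit.basis,
                    extra_starts=warm, xch_scale=base_fit.xch_scale,
                    stop_at=stop_at, sd_floor=floor,
                )
            except RuntimeError as exc:
                warnings.warn(f"replicate {i} attempt {attempt}: {exc}")
                continue
            members.append(r.flux)
            seeds.append(rep_seed)
            ok = True
            break
        if not ok:
            flagged.append(i)
    if not members:
        raise RuntimeError("no Monte-Carlo replicate produced a fit")
    return MCEnsemble(network, base_fit, members, seeds, flagged)


def aggregate_ensemble(
    ens: MCEnsemble, comb_map: AggregationMap
) -> dict[str, tuple[float, float, float]]:
    """Aggregated flux table: name -> (best fit, ensemble mean, ensemble
    SD), with each linear combination applied to every ensemble member."""
    A = comb_map.matrix
    best = A @ ens.base.flux.net
    M = ens.net_matrix @ A.T
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    return {
        name: (float(best[i]), float(mean[i]), float(sd[i]))
        for i, name in enumerate(comb_map.names)
    }


def flux_ratio(
    ens: MCEnsemble,
    numerator: np.ndarray,
    denominator: np.ndarray,
) -> tuple[float, float]:
    """Mean and sample SD over the ensemble of the ratio of two linear flux
    combinations; members with a zero denominator are excluded with a
    warning."""
    num = ens.net_matrix @ np.asarray(numerator, dtype=float)
    den = ens.net_matrix @ np.asarray(denominator, dtype=float)
    ok = np.abs(den) > 1e-12
    if not np.all(ok):
        warnings.warn(f"excluded {int((~ok).sum())} member(s) with zero denominator")
    if not np.any(ok):
        raise ZeroDivisionError("denominator is zero in every ensemble member")
    r = num[ok] / den[ok]
    sd = float(r.std(ddof=1)) if len(r) > 1 else 0.0
    return float(r.mean()), sd


def atmospheric_fraction(flux: FluxState, network: Network | None = None) -> float:
    """Share of the RuBisCO CO2 pool supplied by atmospheric uptake, on the
    forward-flux formulation: atmospheric influx divided by total forward
    inflow (atmospheric influx + forward mixing inflow from cellular CO2).

    Only defined for configurations carrying the separate ``CO2_RBC``
    pool."""
    network = network or flux.network
    if "CO2_RBC" not in network.metabolites:
        raise ValueError(
            "atmospheric fraction requires the CO2_RBC pool (CO2 mode B or C)"
        )
    atm_in = flux.fwd[network.rxn_index("vCO2_atm_in")]
    mix_in = flux.fwd[network.rxn_index("vCO2_mix")]
    total = atm_in + mix_in
    if total <= 0:
        raise ZeroDivisionError("no inflow into the RuBisCO CO2 pool")
    return float(atm_in / total)
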