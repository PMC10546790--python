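"""End-to-end orchestration of the flux-analysis pipeline.

Thin composition layer over the library modules: the physiology report
(growth, uptake and biomass-flux arithmetic), scenario simulation, flux
fitting, CO2-pool model-configuration comparison, Monte-Carlo uncertainty
with compartment aggregation, and file I/O for the measurement and flux
tables.  Every entry point is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import physiology as phys
from . import tables
from .fitting import (
    FitResult,
    FluxMeasurement,
    LabelingModel,
    MeasurementSet,
    MIDMeasurement,
    apply_sd_floor,
    fit,
)
from .isotope import FragmentSpec
from .montecarlo import (
    MCEnsemble,
    aggregate_ensemble,
    atmospheric_fraction,
    flux_ratio,
    monte_carlo,
)
from .network import FluxState, aggregation_map
from .synth import (
    ScenarioPreset,
    fitting_network,
    generate_measurements,
    preset,
    preset_labels,
    truth_flux,
)

__all__ = [
    "physiology_report",
    "simulate_scenario",
    "fit_scenario",
    "compare_configs",
    "mc_scenario",
    "write_measurements",
    "read_measurements",
    "write_flux_tsv",
]


# ---------------------------------------------------------------------------
# physiology report


def physiology_report(condition: str, n_resample: int = 10000, seed: int = 0) -> dict:
    """Growth, uptake, depletion and biomass-flux arithmetic for one
    condition, mirroring the published growth/uptake/biomass tables."""
    g = tables.GROWTH[condition]
    up = tables.UPTAKES[condition]
    mu = math.log(2.0) / g["doubling"]
    mu_area = phys.growth_rate(g["A0"], g["At"], g["t"])
    D0 = g["A0"] * g["dw_per_area"]
    vglc, vgln = up["vGlc_up"][0], up["vGln_up"][0]
    co2 = phys.co2_uptake(g["f13C_BM"], vglc, vgln)
    co2_mean, co2_sd, rejected = phys.resample_co2_uptake(
        dict(f13C_BM=g["f13C_BM"], vGlc_up=vglc, vGln_up=vgln),
        dict(f13C_BM=g["f13C_BM_sd"], vGlc_up=up["vGlc_up"][1], vGln_up=up["vGln_up"][1]),
        n=n_resample,
        seed=seed,
    )
    comp = tables.default_composition(condition)
    bm = phys.biomass_fluxes(comp, mu)
    bm_sd = phys.propagate_biomass_uncertainty(comp, mu, g["mu_sd"], n=20, seed=seed)
    report = dict(
        condition=condition,
        mu=mu,
        mu_from_areas=mu_area,
        doubling_time=phys.doubling_time(mu),
        inoculum_fraction=D0 / g["D"],
        vGlc_up=vglc,
        vGln_up=vgln,
        vCO2_up=co2,
        vCO2_up_resampled=(co2_mean, co2_sd, rejected),
        glc_depletion=phys.depletion_fraction(
            vglc, mu, D0, g["D"], tables.MEDIUM["S0_glc"]
        ),
        gln_depletion=(
            phys.depletion_fraction(vgln, mu, D0, g["D"], tables.MEDIUM["S0_gln"])
            if vgln > 0
            else 0.0
        ),
        biomass_fluxes={k: (v, bm_sd[k][1]) for k, v in sorted(bm.items())},
    )
    return report


# ---------------------------------------------------------------------------
# measurement table I/O (fragment panel CSV layout)


def write_measurements(meas: MeasurementSet, mid_path, flux_path=None) -> None:
    rows = []
    for m in meas.mids:
        f = m.fragment
        row = dict(
            fragment_id=f.id,
            analyte=f.analyte,
            metabolite=f.metabolite,
            skeleton_positions=",".join(str(p) for p in f.positions),
            derivative_formula=f.formula,
        )
        for i, (v, s) in enumerate(zip(m.values, m.sds)):
            row[f"m{i}"] = v
            row[f"sd{i}"] = s
        rows.append(row)
    pd.DataFrame(rows).to_csv(mid_path, index=False)
    if flux_path is not None:
        pd.DataFrame(
            [dict(reaction=f.reaction, value=f.value, sd=f.sd) for f in meas.fluxes]
        ).to_csv(flux_path, index=False)


def read_measurements(mid_path, flux_path=None) -> MeasurementSet:
    df = pd.read_csv(mid_path)
    mids = []
    for _, row in df.iterrows():
        positions = tuple(int(x) for x in str(row["skeleton_positions"]).split(","))
        formula = row.get("derivative_formula", "")
        frag = FragmentSpec(
            row["fragment_id"],
            row["analyte"],
            row["metabolite"],
            positions,
            "" if pd.isna(formula) else str(formula),
        )
        vals, sds = [], []
        i = 0
        while f"m{i}" in row and not pd.isna(row[f"m{i}"]):
            vals.append(float(row[f"m{i}"]))
            sds.append(float(row[f"sd{i}"]))
            i += 1
        mids.append(MIDMeasurement(frag, np.array(vals), np.array(sds)))
    fluxes = []
    if flux_path is not None and Path(flux_path).exists():
        for _, row in pd.read_csv(flux_path).iterrows():
            fluxes.append(FluxMeasurement(row["reaction"], row["value"], row["sd"]))
    return MeasurementSet(mids, fluxes)


def write_flux_tsv(flux: FluxState, path) -> None:
    rows = [
        dict(reaction=r.id, net=flux.net[i], exchange=flux.xch[i])
        for i, r in enumerate(flux.network.reactions)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# scenario stages


def simulate_scenario(
    p: ScenarioPreset, outdir=None, seed: int | None = None
) -> tuple[FluxState, MeasurementSet]:
    truth = truth_flux(p)
    meas = generate_measurements(truth, p=p, seed=seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_measurements(
            meas, outdir / "measurements_mid.csv", outdir / "measurements_flux.csv"
        )
        write_flux_tsv(truth, outdir / "truth_flux.tsv")
        (outdir / "scenario.json").write_text(
            json.dumps(
                dict(
                    preset=p.name,
                    co2_mode=p.co2_mode,
                    noise_sd=p.noise_sd,
                    inoculum_fraction=p.inoculum_fraction,
                    seed=p.seed if seed is None else seed,
                ),
                indent=2,
            )
        )
    return truth, meas


def scenario_model(
    p: ScenarioPreset, meas: MeasurementSet, co2_mode: str | None = None
):
    """Fitting network plus raw-space labeling model for a preset's data."""
    net = fitting_network(p, co2_mode)
    mode = co2_mode or p.co2_mode
    # uptake-rate measurements are what configuration C adds; A and B fit
    # the labeling data alone
    if mode == "C":
        known = set(net.reaction_ids)
        flt = [f for f in meas.fluxes if f.reaction in known]
    else:
        flt = []
    meas_net = MeasurementSet(list(meas.mids), flt)
    model = LabelingModel(
        net,
        meas.fragments,
        preset_labels(p),
        derivatized=True,
        inoculum_fraction=p.inoculum_fraction,
    )
    return net, meas_net, model


def fit_scenario(
    p: ScenarioPreset,
    meas: MeasurementSet,
    n_restarts: int = 100,
    max_iter: int = 2000,
    seed: int | None = None,
    co2_mode: str | None = None,
    stop_at: float | None = None,
) -> FitResult:
    net, meas_net, model = scenario_model(p, meas, co2_mode)
    return fit(
        net,
        meas_net,
        preset_labels(p),
        n_restarts=n_restarts,
        max_iter=max_iter,
        seed=seed,
        model=model,
        stop_at=stop_at,
    )


def compare_configs(
    p: ScenarioPreset,
    meas: MeasurementSet,
    n_restarts: int = 8,
    max_iter: int = 400,
    seed: int | None = None,
    modes=("A", "B", "C"),
) -> dict[str, dict]:
    """Fit the CO2-pool configurations A/B/C on identical data; flux
    measurements that reference reactions absent from a configuration are
    dropped for that configuration."""
    out = {}
    for mode in modes:
        try:
            r = fit_scenario(
                p, meas, n_restarts=n_restarts, max_iter=max_iter, seed=seed,
                co2_mode=mode, stop_at=None,
            )
            out[mode] = dict(
                ssr=r.ssr,
                dof=r.dof,
                chi2_critical=r.chi2_critical,
                accepted=r.accepted,
            )
        except Exception as exc:  # per-mode failures recorded, not fatal
            out[mode] = dict(error=str(exc))
    return out


def full_run(
    p: ScenarioPreset,
    outdir,
    seed: int | None = None,
    n_restarts: int = 20,
    n_replicates: int = 10,
    restarts_per_replicate: int = 10,
    max_iter: int = 400,
) -> dict:
    """End-to-end scenario: simulate, fit, Monte-Carlo, aggregate, report.

    Writes the dataset, the best-fit flux table, the aggregated flux table
    with ensemble SDs, and a JSON summary into ``outdir``; returns the
    summary.  Deterministic under a fixed seed.
    """
    outdir = Path(outdir)
    truth, meas = simulate_scenario(p, outdir=outdir, seed=seed)
    ens, summary = mc_scenario(
        p, meas,
        n_replicates=n_replicates,
        restarts_per_replicate=restarts_per_replicate,
        base_restarts=n_restarts, max_iter=max_iter,
        replicate_max_iter=max_iter // 2 or None, seed=seed,
    )
    write_flux_tsv(ens.base.flux, outdir / "fit_flux.tsv")
    agg_rows = [
        dict(combination=name, best=v[0], mean=v[1], sd=v[2])
        for name, v in summary["aggregated"].items()
    ]
    pd.DataFrame(agg_rows).to_csv(outdir / "fluxes_aggregated.tsv", sep="\t", index=False)
    out = dict(
        preset=p.name,
        co2_mode=p.co2_mode,
        seed=seed,
        ssr=ens.base.ssr,
        dof=ens.base.dof,
        chi2_critical=ens.base.chi2_critical,
        accepted=ens.base.accepted,
        n_members=len(ens.members),
        oppp_rubisco_ratio=summary["oppp_rubisco_ratio"],
        atm_fraction=summary["atm_fraction"],
        net_pepc=ens.base.flux["vPEPC"],
    )
    (outdir / "summary.json").write_text(json.dumps(out, indent=2, default=float))
    return out


def mc_scenario(
    p: ScenarioPreset,
    meas: MeasurementSet,
    n_replicates: int = 20,
    restarts_per_replicate: int = 50,
    base_restarts: int = 20,
    max_iter: int = 400,
    replicate_max_iter: int | None = None,
    seed: int | None = None,
    stop_at_critical: bool = True,
) -> tuple[MCEnsemble, dict]:
    """Monte-Carlo uncertainty for a preset plus the aggregated summary:
    combined (uncompartmentalized) fluxes, the OPPP/RuBisCO decarboxylation
    ratio, and the atmospheric fraction of the RuBisCO CO2 pool."""
    net, meas_net, model = scenario_model(p, meas)
    labels = preset_labels(p)
    base = fit(
        net, meas_net, labels, n_restarts=base_restarts, max_iter=max_iter,
        seed=seed, model=model,
    )
    stop = base.chi2_critical if stop_at_critical else None
    ens = monte_carlo(
        net, meas_net, labels,
        n_replicates=n_replicates,
        restarts_per_replicate=restarts_per_replicate,
        seed=seed, max_iter=replicate_max_iter or max_iter,
        base_fit=base, model=model, stop_at=stop,
    )
    am = aggregation_map(net)
    agg = aggregate_ensemble(ens, am)
    n = len(net.reactions)
    oppp = np.zeros(n)
    oppp[net.rxn_index("vG6PDH_c")] = 1.0
    oppp[net.rxn_index("vG6PDH_p")] = 1.0
    rbc = np.zeros(n)
    rbc[net.rxn_index("vRBC")] = 1.0
    ratio, ratio_sd = flux_ratio(ens, oppp, rbc)
    atm = [atmospheric_fraction(m, net) for m in ens.members]
    summary = dict(
        aggregated=agg,
        oppp_rubisco_ratio=(ratio, ratio_sd),
        atm_fraction=(float(np.mean(atm)), float(np.std(atm, ddof=1))),
        base_ssr=base.ssr,
        base_accepted=base.accepted,
    )
    return ens, summary
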