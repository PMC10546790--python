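"""Flux estimation by variance-weighted least squares with multi-start
optimization and chi-square goodness-of-fit testing.

The objective is the sum of squared residuals (SSR) between simulated and
measured fragment MIDs plus measured net fluxes, each weighted by its
standard deviation; MID standard deviations carry a floor of 1% on the
fractional-enrichment scale.  Free net fluxes are parameterized through the
steady-state null space, exchange fluxes through a bounded 0..1 transform
(``xch = scale * t / (1 - t)``), and optimization restarts from randomized
feasible start values.  A fit is statistically accepted when its SSR does
not exceed the chi-square quantile at the 90% confidence level for the
model's degrees of freedom.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.stats import chi2

from .emu import EMUSystem, emu_decompose, substrate_distributions
from .isotope import (
    FragmentSpec,
    SubstrateLabel,
    correct_derivative,
    correct_inoculum,
    natural_mid,
    natural_skeleton_mid,
    propagate_correction_sd,
)
from .network import FluxState, FreeFluxBasis, Network, steady_state_basis

__all__ = [
    "MIDMeasurement",
    "FluxMeasurement",
    "MeasurementSet",
    "FitResult",
    "LabelingModel",
    "apply_sd_floor",
    "correct_measurement_set",
    "ssr",
    "dof",
    "chi2_critical",
    "chi2_test",
    "fit",
    "find_alternative_optima",
]

SD_FLOOR = 0.01
XCH_SCALE = 100.0
XCH01_MAX = 0.95
_PENALTY = 1e3


@dataclass(frozen=True)
class MIDMeasurement:
    fragment: FragmentSpec
    values: np.ndarray
    sds: np.ndarray
    #: intensity-noise SD behind the reported fractions; when set, residuals
    #: are whitened with the renormalization covariance (see ``whiten``)
    noise_sigma: float | None = None
    whitener: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if self.values.shape != self.sds.shape:
            raise ValueError(f"{self.fragment.id}: value/SD length mismatch")
        if np.any(self.sds < 0):
            raise ValueError(f"{self.fragment.id}: negative SD")


def _renorm_whitener(values: np.ndarray, sigma: float, floor: float) -> np.ndarray:
    """Rank-(k-1) whitening matrix for renormalized additive noise.

    Additive intensity noise of SD ``sigma`` followed by normalization has
    covariance sigma^2 J J^T with J = I - v 1^T (singular along the sum
    direction, which carries no information because measured fractions sum
    to one).  The returned (k-1) x k matrix maps a raw residual onto
    independent unit-variance coordinates; eigen-SDs are floored like
    ordinary SDs.
    """
    k = len(values)
    J = np.eye(k) - np.outer(values, np.ones(k))
    C = sigma**2 * (J @ J.T)
    w, U = np.linalg.eigh(C)
    # drop the (numerically) zero sum-direction eigenvalue
    idx = np.argsort(w)[1:]
    sd_eig = np.maximum(np.sqrt(np.clip(w[idx], 0.0, None)), floor)
    return (U[:, idx] / sd_eig).T


def whiten(meas: "MeasurementSet", floor: float = 0.01) -> "MeasurementSet":
    """Attach renormalization whiteners to every MID measurement carrying a
    ``noise_sigma``; measurements without one keep per-entry SD weighting."""
    mids = []
    for m in meas.mids:
        if m.noise_sigma is not None and m.noise_sigma > 0:
            W = _renorm_whitener(m.values, m.noise_sigma, floor)
            mids.append(
                MIDMeasurement(m.fragment, m.values, m.sds, m.noise_sigma, W)
            )
        else:
            mids.append(m)
    return MeasurementSet(mids, list(meas.fluxes))


@dataclass(frozen=True)
class FluxMeasurement:
    reaction: str
    value: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError(f"{self.reaction}: flux measurement needs SD > 0")


@dataclass
class MeasurementSet:
    """MID measurements (one group per fragment) plus measured net fluxes."""

    mids: list[MIDMeasurement]
    fluxes: list[FluxMeasurement] = field(default_factory=list)

    @property
    def n_mid_values(self) -> int:
        return sum(len(m.values) for m in self.mids)

    @property
    def n_groups(self) -> int:
        return len(self.mids)

    @property
    def fragments(self) -> list[FragmentSpec]:
        return [m.fragment for m in self.mids]


def apply_sd_floor(meas: MeasurementSet, floor: float = SD_FLOOR) -> MeasurementSet:
    """Raise every MID standard deviation to at least ``floor`` (1% on the
    fractional scale by default); whitened measurements are rebuilt with
    the floored eigen-SDs."""
    mids = []
    for m in meas.mids:
        sds = np.maximum(m.sds, floor)
        W = m.whitener
        if m.noise_sigma is not None and m.noise_sigma > 0:
            W = _renorm_whitener(m.values, m.noise_sigma, floor)
        mids.append(MIDMeasurement(m.fragment, m.values, sds, m.noise_sigma, W))
    return MeasurementSet(mids, list(meas.fluxes))


def correct_measurement_set(
    meas: MeasurementSet, inoculum_fraction: float = 0.0
) -> MeasurementSet:
    """Derivative natural-isotope correction followed by unlabeled-inoculum
    correction, fragment by fragment.  Standard deviations are propagated
    through the (linear) deconvolution — the correction amplifies raw-MID
    noise — and scaled by the inoculum factor."""
    out = []
    for m in meas.mids:
        skel = correct_derivative(m.values, m.fragment)
        sds = propagate_correction_sd(m.sds, m.fragment, inoculum_fraction)
        if inoculum_fraction > 0:
            nat = natural_skeleton_mid(m.fragment.n_carbons)
            skel = correct_inoculum(skel, inoculum_fraction, nat)
        out.append(MIDMeasurement(m.fragment, skel, sds))
    return MeasurementSet(out, list(meas.fluxes))


# ---------------------------------------------------------------------------
# simulation front-end


#: masses recorded beyond the skeleton MID in a raw (derivatized) fragment;
#: kept short — mass bins carrying no signal would only contribute
#: clipping bias under the additive-noise measurement emulation
RAW_MASS_WINDOW = 3


class LabelingModel:
    """Compiled measurement model: network + fragment panel + substrate
    labels.  ``fragment_mids`` maps a flux state to the skeleton MID of
    every fragment; with ``derivatized=True`` it instead returns the raw
    observable MIDs — skeleton MIDs mixed with the unlabeled-inoculum
    contribution and convolved with the natural isotopologue distribution
    of the derivative side chains — so that fits can compare directly
    against uncorrected measurements with independent errors."""

    def __init__(
        self,
        network: Network,
        fragments: list[FragmentSpec],
        labels: dict[str, SubstrateLabel],
        derivatized: bool = False,
        inoculum_fraction: float = 0.0,
    ):
        self.network = network
        self.fragments = list(fragments)
        self.labels = dict(labels)
        self.derivatized = derivatized
        self.inoculum_fraction = inoculum_fraction
        targets = sorted({(f.metabolite, f.positions0) for f in self.fragments})
        self.system: EMUSystem = emu_decompose(network, targets)
        self.dists = substrate_distributions(network, labels)
        self._sub_mids = self.system.substrate_emu_mids(self.dists)
        self._deriv = {
            f.id: (natural_mid(f.formula) if f.formula else np.array([1.0]))
            for f in fragments
        }
        self._nat_skel = {f.id: natural_skeleton_mid(f.n_carbons) for f in fragments}

    def _contaminate(self, frag: FragmentSpec, skel: np.ndarray) -> np.ndarray:
        f = self.inoculum_fraction
        if f > 0:
            skel = (1.0 - f) * skel + f * self._nat_skel[frag.id]
        raw = np.convolve(skel, self._deriv[frag.id])
        raw = raw[: frag.n_carbons + RAW_MASS_WINDOW]
        return raw / raw.sum()

    def fragment_mids(self, flux: FluxState) -> dict[str, np.ndarray]:
        mids = self.system.simulate(flux, self.dists, self._sub_mids)
        out = {}
        for f in self.fragments:
            skel = mids[(f.metabolite, tuple(sorted(f.positions0)))]
            out[f.id] = self._contaminate(f, skel) if self.derivatized else skel
        return out


def _residuals(flux: FluxState, meas: MeasurementSet, model: LabelingModel) -> np.ndarray:
    sim = model.fragment_mids(flux)
    parts = []
    for m in meas.mids:
        s = sim[m.fragment.id]
        k = min(len(s), len(m.values))
        if m.whitener is not None and m.whitener.shape[1] == k:
            parts.append(m.whitener @ (s[:k] - m.values[:k]))
        else:
            parts.append((s[:k] - m.values[:k]) / m.sds[:k])
    for fm in meas.fluxes:
        parts.append(np.array([(flux[fm.reaction] - fm.value) / fm.sd]))
    return np.concatenate(parts)


def ssr(
    flux: FluxState,
    meas: MeasurementSet,
    model: LabelingModel,
) -> float:
    """Variance-weighted sum of squared residuals of one flux state."""
    r = _residuals(flux, meas, model)
    return float(r @ r)


# ---------------------------------------------------------------------------
# degrees of freedom and the chi-square acceptance rule


def dof(
    n_mid_measurements: int,
    n_groups: int,
    n_flux_measurements: int,
    n_free_net: int,
    n_free_xch: int,
) -> int:
    """Degrees of freedom: MID measurements minus measurement groups, plus
    measured flux rates, minus free net and exchange fluxes."""
    d = n_mid_measurements - n_groups + n_flux_measurements - (n_free_net + n_free_xch)
    if d <= 0:
        raise ValueError(f"model is under-determined (dof = {d})")
    return d


def chi2_critical(dof_: int, alpha: float = 0.10) -> float:
    """Chi-square acceptance threshold: the (1 - alpha) quantile (the 90%
    quantile at the default confidence level)."""
    return float(chi2.ppf(1.0 - alpha, dof_))


def chi2_test(ssr_value: float, dof_: int, alpha: float = 0.10) -> bool:
    """Goodness-of-fit verdict; the boundary SSR == critical is accepted."""
    if dof_ < 1:
        raise ValueError("dof must be >= 1")
    return ssr_value <= chi2_critical(dof_, alpha)


# ---------------------------------------------------------------------------
# multi-start fitting


@dataclass
class FitResult:
    flux: FluxState
    ssr: float
    dof: int
    chi2_critical: float
    accepted: bool
    restarts: list[dict]
    basis: FreeFluxBasis
    q: np.ndarray
    t: np.ndarray
    xch_scale: float

    def summary(self) -> dict:
        return dict(
            ssr=self.ssr,
            dof=self.dof,
            chi2_critical=self.chi2_critical,
            accepted=self.accepted,
            n_restarts=len(self.restarts),
        )


def _xch_from_t(t: np.ndarray, scale: float) -> np.ndarray:
    return scale * t / (1.0 - t)


def _bound_penalties(network: Network, v: np.ndarray) -> np.ndarray:
    lo = np.array([r.lb for r in network.reactions])
    hi = np.array([r.ub for r in network.reactions])
    under = np.where(np.isfinite(lo), np.minimum(v - lo, 0.0), 0.0)
    over = np.where(np.isfinite(hi), np.minimum(hi - v, 0.0), 0.0)
    return _PENALTY * np.concatenate([under, over])


def _feasible_center(basis: FreeFluxBasis) -> np.ndarray:
    """Free-flux coordinates of a minimum-norm feasible flux vector: ridge
    pull toward small flux magnitudes with strong hinge penalties on bound
    violations.  Serves as the center for randomized restarts."""
    nq = basis.n_free_net
    if nq == 0:
        return np.zeros(0)
    N, vp = basis.nullspace, basis.particular
    lb = np.array([r.lb for r in basis.network.reactions])
    ub = np.array([r.ub for r in basis.network.reactions])

    def resid(q):
        v = vp + N @ q
        under = np.where(np.isfinite(lb), np.minimum(v - lb, 0.0), 0.0)
        over = np.where(np.isfinite(ub), np.minimum(ub - v, 0.0), 0.0)
        return np.concatenate([1e-3 * v, 1e3 * under, 1e3 * over])

    res = scipy.optimize.least_squares(resid, np.zeros(nq), method="trf")
    return res.x


def fit(
    network: Network,
    meas: MeasurementSet,
    labels: dict[str, SubstrateLabel],
    n_restarts: int = 100,
    max_iter: int = 2000,
    seed: int | None = None,
    alpha: float = 0.10,
    xch_scale: float = XCH_SCALE,
    model: LabelingModel | None = None,
    basis: FreeFluxBasis | None = None,
    extra_starts: list[tuple[np.ndarray, np.ndarray]] | None = None,
    stop_at: float | None = None,
    sd_floor: float = SD_FLOOR,
    verbose: bool = False,
) -> FitResult:
    """Estimate the flux state minimizing the variance-weighted SSR.

    Gradient-based constrained least squares (trust-region reflective) from
    ``n_restarts`` randomized feasible start values for the free fluxes;
    ``max_iter`` bounds the residual evaluations per restart.  Deterministic
    given ``seed``.  ``extra_starts`` prepends warm starts (pairs of free-
    net coordinates and xch01 values) to the random ones.
    """
    meas = apply_sd_floor(meas, sd_floor)
    model = model or LabelingModel(network, meas.fragments, labels)
    basis = basis or steady_state_basis(network)
    rng = np.random.default_rng(seed)
    nq, nx = basis.n_free_net, basis.n_free_xch
    rev_idx = np.array(
        [network.rxn_index(rid) for rid in basis.free_exchange_ids], dtype=int
    )

    def flux_of(p: np.ndarray) -> FluxState:
        v = basis.expand(p[:nq])
        x = np.zeros(len(network.reactions))
        if nx:
            x[rev_idx] = _xch_from_t(p[nq:], xch_scale)
        return FluxState(network, v, x)

    def fun(p: np.ndarray) -> np.ndarray:
        fl = flux_of(p)
        return np.concatenate(
            [_residuals(fl, meas, model), _bound_penalties(network, fl.net)]
        )

    q_c = _feasible_center(basis)
    flux_scale = max(20.0, float(np.max(np.abs(basis.expand(q_c)))) if nq else 20.0)
    lo = np.concatenate([np.full(nq, -np.inf), np.zeros(nx)])
    hi = np.concatenate([np.full(nq, np.inf), np.full(nx, XCH01_MAX)])

    starts: list[tuple[np.ndarray, np.ndarray]] = list(extra_starts or [])
    while len(starts) < n_restarts:
        sigma = float(rng.choice([0.5, 1.0, 2.0, 4.0])) * flux_scale
        q0 = q_c + rng.normal(0.0, sigma, size=nq)
        t0 = rng.uniform(0.0, 0.9, size=nx)
        starts.append((q0, t0))

    restart_log: list[dict] = []
    best = None
    for i, (q0, t0) in enumerate(starts):
        p0 = np.clip(np.concatenate([q0, t0]), lo, hi)
        t_start = time.perf_counter()
        try:
            res = scipy.optimize.least_squares(
                fun,
                p0,
                bounds=(lo, hi),
                method="trf",
                x_scale=np.concatenate([np.full(nq, flux_scale), np.full(nx, 0.1)]),
                max_nfev=max_iter,
            )
        except Exception as exc:  # pragma: no cover - defensive
            restart_log.append(dict(restart=i, ssr=np.inf, error=str(exc)))
            continue
        fl = flux_of(res.x)
        pen = _bound_penalties(network, fl.net)
        # tolerate bound violations negligible against the flux scale
        feasible = bool(np.max(np.abs(pen)) < _PENALTY * 1e-4 * max(1.0, flux_scale / 100.0))
        s = ssr(fl, meas, model)
        restart_log.append(
            dict(
                restart=i,
                ssr=float(s),
                feasible=feasible,
                nfev=int(res.nfev),
                seconds=time.perf_counter() - t_start,
            )
        )
        if verbose:
            print(f"restart {i}: ssr={s:.4g} feasible={feasible} nfev={res.nfev}")
        if feasible and (best is None or s < best[0]):
            best = (s, res.x)
        if stop_at is not None and best is not None and best[0] <= stop_at:
            break
    if best is None:
        raise RuntimeError(
            "all restarts failed to reach a feasible optimum; "
            f"log: {restart_log[:5]} ..."
        )
    s_best, p_best = best
    fl_best = flux_of(p_best)
    d = dof(meas.n_mid_values, meas.n_groups, len(meas.fluxes), nq, nx)
    crit = chi2_critical(d, alpha)
    return FitResult(
        flux=fl_best,
        ssr=float(s_best),
        dof=d,
        chi2_critical=crit,
        accepted=chi2_test(s_best, d, alpha),
        restarts=restart_log,
        basis=basis,
        q=p_best[:nq].copy(),
        t=p_best[nq:].copy(),
        xch_scale=xch_scale,
    )


def find_alternative_optima(
    network: Network,
    meas: MeasurementSet,
    labels: dict[str, SubstrateLabel],
    fitresult: FitResult,
    combination: str | np.ndarray,
    values: np.ndarray | None = None,
    n_grid: int = 9,
    span: float = 1.0,
    tolerance: float | None = None,
    restarts_per_point: int = 1,
    max_iter: int = 600,
    seed: int | None = None,
) -> dict:
    """Parameter-continuation profile of one flux (or linear combination).

    Re-optimizes with the flux of interest pinned across a grid of values
    and reports the interval over which the SSR stays within ``tolerance``
    (default: the 1-dof chi-square 90% quantile) of the best fit.
    """
    n = len(network.reactions)
    if isinstance(combination, str):
        coef = np.zeros(n)
        coef[network.rxn_index(combination)] = 1.0
    else:
        coef = np.asarray(combination, dtype=float)
    best_val = float(coef @ fitresult.flux.net)
    if values is None:
        width = span * max(1.0, abs(best_val))
        values = np.linspace(best_val - width, best_val + width, n_grid)
    tol = tolerance if tolerance is not None else float(chi2.ppf(0.90, 1))
    meas_f = apply_sd_floor(meas)
    model = LabelingModel(network, meas_f.fragments, labels)
    profile = []
    for val in values:
        try:
            b = FreeFluxBasis(network, extra_linear=[(coef, float(val))])
            warm = (b.project(fitresult.flux.net), fitresult.t)
            r = fit(
                network,
                meas_f,
                labels,
                n_restarts=restarts_per_point,
                max_iter=max_iter,
                seed=seed,
                model=model,
                basis=b,
                extra_starts=[warm],
                xch_scale=fitresult.xch_scale,
            )
            profile.append(r.ssr)
        except Exception:
            # infeasible or failed pin: outside the confidence region
            profile.append(np.inf)
    profile = np.asarray(profile)
    ok = profile <= fitresult.ssr + tol
    inside = np.asarray(values)[ok]
    return dict(
        values=np.asarray(values),
        ssr=profile,
        best_value=best_val,
        tolerance=tol,
        interval=(float(inside.min()), float(inside.max())) if ok.any() else None,
    )
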