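"""Steady-state labeling simulation via EMU decomposition.

An EMU (elementary metabolite unit) is a subset of a metabolite's carbon
atoms.  At isotopic steady state the MID of every EMU satisfies a flux
balance in which condensation reactions couple an EMU only to strictly
smaller EMUs, so the full system decomposes into one linear solve per EMU
size.  The decomposition is compiled once per (network, target set) and the
per-size systems are then assembled from a flux vector with precomputed
index arrays, which keeps a single simulation at the sub-millisecond to
few-millisecond scale even for the full reference network.

A brute-force full-isotopomer fixed-point solver is included as an
independent verification oracle for small networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .isotope import SubstrateLabel, mixture_distribution, marginalize_positional, NAT_13C
from .network import FluxState, Network

__all__ = [
    "EMUSystem",
    "emu_decompose",
    "simulate_mids",
    "brute_force_isotopomers",
    "substrate_distributions",
    "SimulationError",
]

FLUX_CLAMP = 1e-9


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# unidirectional reaction view


@dataclass(frozen=True)
class _UniReaction:
    rxn_index: int
    forward: bool
    educts: tuple
    products: tuple


def _unidirectional(network: Network) -> list[_UniReaction]:
    out = []
    for i, r in enumerate(network.reactions):
        out.append(_UniReaction(i, True, r.educts, r.products))
        if r.reversible:
            out.append(_UniReaction(i, False, r.products, r.educts))
    return out


def _uni_fluxes(network: Network, flux: FluxState, clamp: float = FLUX_CLAMP) -> np.ndarray:
    fwd, bwd = flux.fwd, flux.bwd
    vals = []
    for u in _unidirectional(network):
        vals.append(fwd[u.rxn_index] if u.forward else bwd[u.rxn_index])
    v = np.asarray(vals)
    if np.any(v < clamp):
        v = np.maximum(v, clamp)
    return v


# ---------------------------------------------------------------------------
# decomposition


def _emu_key(met: str, positions0) -> tuple:
    return (met, tuple(sorted(positions0)))


class EMUSystem:
    """Compiled EMU decomposition of a network for a fixed set of target
    EMUs.

    ``simulate(flux, substrate_dists)`` returns a dict mapping every EMU key
    ``(metabolite, positions0)`` reachable backward from the targets to its
    MID.
    """

    def __init__(self, network: Network, targets: list[tuple]):
        self.network = network
        self.uni = _unidirectional(network)
        self.substrates = set(network.substrate_inputs)
        self.targets = [_emu_key(m, p) for m, p in targets]
        self._decompose()
        self._compile()

    # -- backward tracing ------------------------------------------------
    def _producers(self, met: str):
        """(uni_index, product_term) pairs producing ``met``."""
        out = []
        for ui, u in enumerate(self.uni):
            for t in u.products:
                if t.metabolite == met:
                    out.append((ui, u, t))
        return out

    def _decompose(self):
        for met, pos in self.targets:
            n = self.network.metabolites[met].n_carbons
            if any(p < 0 or p >= n for p in pos):
                raise SimulationError(
                    f"target references unknown carbons of {met} (has {n})"
                )
        balance: dict[tuple, list] = {}
        pending = [k for k in self.targets if k[0] not in self.substrates]
        seen = set(pending)
        self.substrate_emus: set[tuple] = {
            k for k in self.targets if k[0] in self.substrates
        }
        while pending:
            key = pending.pop()
            met, pos = key
            terms = []
            producers = self._producers(met)
            if not producers:
                raise SimulationError(
                    f"metabolite {met} has no producing reaction; cannot balance EMU {key}"
                )
            for ui, u, t in producers:
                letters = {t.atoms[i] for i in pos}
                srcs = []
                for e in u.educts:
                    sub = tuple(j for j, ch in enumerate(e.atoms) if ch in letters)
                    if sub:
                        srcs.append(_emu_key(e.metabolite, sub))
                if sum(len(s[1]) for s in srcs) != len(pos):
                    raise SimulationError(
                        f"atom map of reaction {self.network.reactions[u.rxn_index].id} "
                        f"does not cover EMU {key}"
                    )
                terms.append((ui, tuple(srcs)))
                for s in srcs:
                    if s[0] in self.substrates:
                        self.substrate_emus.add(s)
                    elif s not in seen:
                        seen.add(s)
                        pending.append(s)
            balance[key] = terms
        self.balance = balance
        self.emus = sorted(balance, key=lambda k: (len(k[1]), k))
        self.sizes = sorted({len(k[1]) for k in self.emus})

    # -- compile per-size linear systems ---------------------------------
    def _compile(self):
        self.levels = []
        for size in self.sizes:
            unknowns = [k for k in self.emus if len(k[1]) == size]
            col = {k: i for i, k in enumerate(unknowns)}
            y_index: dict[tuple, int] = {}
            y_terms: list = []
            a_rows, a_cols, a_uni = [], [], []
            d_rows, d_uni = [], []
            b_rows, b_cols, b_uni = [], [], []
            for k in unknowns:
                r = col[k]
                for ui, srcs in self.balance[k]:
                    d_rows.append(r)
                    d_uni.append(ui)
                    if len(srcs) == 1 and srcs[0] in col:
                        a_rows.append(r)
                        a_cols.append(col[srcs[0]])
                        a_uni.append(ui)
                    else:
                        ykey = srcs
                        if ykey not in y_index:
                            y_index[ykey] = len(y_terms)
                            y_terms.append(srcs)
                        b_rows.append(r)
                        b_cols.append(y_index[ykey])
                        b_uni.append(ui)
            self.levels.append(
                dict(
                    size=size,
                    unknowns=unknowns,
                    a=(np.array(a_rows, int), np.array(a_cols, int), np.array(a_uni, int)),
                    d=(np.array(d_rows, int), np.array(d_uni, int)),
                    b=(np.array(b_rows, int), np.array(b_cols, int), np.array(b_uni, int)),
                    y_terms=y_terms,
                )
            )

    # -- simulation ------------------------------------------------------
    def substrate_emu_mids(
        self, substrate_dists: dict[str, np.ndarray]
    ) -> dict[tuple, np.ndarray]:
        """MIDs of all substrate EMUs the system needs (flux-independent;
        compute once per label specification)."""
        out = {}
        for met, pos in self.substrate_emus:
            if met not in substrate_dists:
                raise SimulationError(f"no label distribution given for substrate {met}")
            out[(met, pos)] = marginalize_positional(substrate_dists[met], pos)
        return out

    def simulate(
        self,
        flux: FluxState,
        substrate_dists: dict[str, np.ndarray],
        _substrate_mids: dict[tuple, np.ndarray] | None = None,
    ) -> dict[tuple, np.ndarray]:
        v = _uni_fluxes(self.network, flux)
        mids: dict[tuple, np.ndarray] = dict(
            _substrate_mids
            if _substrate_mids is not None
            else self.substrate_emu_mids(substrate_dists)
        )

        def emu_mid(key: tuple) -> np.ndarray:
            if key in mids:
                return mids[key]
            raise SimulationError(f"EMU {key} not yet solved")

        for level in self.levels:
            unknowns = level["unknowns"]
            n = len(unknowns)
            size = level["size"]
            A = np.zeros((n, n))
            ar, ac, au = level["a"]
            if len(ar):
                np.add.at(A, (ar, ac), v[au])
            dr, du = level["d"]
            diag = np.zeros(n)
            np.add.at(diag, dr, v[du])
            A[np.arange(n), np.arange(n)] -= diag
            Y = np.zeros((len(level["y_terms"]), size + 1))
            for yi, srcs in enumerate(level["y_terms"]):
                mid = emu_mid(srcs[0])
                for s in srcs[1:]:
                    mid = np.convolve(mid, emu_mid(s))
                Y[yi] = mid
            B = np.zeros((n, Y.shape[0]))
            br, bc, bu = level["b"]
            if len(br):
                np.add.at(B, (br, bc), v[bu])
            try:
                X = np.linalg.solve(A, -(B @ Y))
            except np.linalg.LinAlgError as exc:
                bad = [unknowns[i] for i in range(n) if diag[i] <= 2 * FLUX_CLAMP]
                raise SimulationError(
                    f"singular EMU system at size {size}; zero-flux EMUs: {bad[:5]}"
                ) from exc
            for i, k in enumerate(unknowns):
                mids[k] = X[i]
        for k in self.targets:
            emu_mid(k)
        return mids


def emu_decompose(network: Network, targets: list[tuple]) -> EMUSystem:
    """Compile the minimal EMU system reachable backward from ``targets``
    (list of ``(metabolite, positions0)``, 0-based carbon positions)."""
    return EMUSystem(network, targets)


def substrate_distributions(
    network: Network, labels: dict[str, SubstrateLabel]
) -> dict[str, np.ndarray]:
    """Positional label distributions for every substrate input; substrates
    without an explicit label are unlabeled at natural abundance."""
    dists = {}
    for met in network.substrate_inputs:
        n = network.metabolites[met].n_carbons
        if met in labels:
            dists[met] = mixture_distribution(labels[met], n)
        else:
            comp = np.array([1.0])
            for _ in range(n):
                comp = np.concatenate([comp * (1 - NAT_13C), comp * NAT_13C])
            dists[met] = comp
    return dists


def simulate_mids(
    network: Network,
    flux: FluxState,
    labels: dict[str, SubstrateLabel],
    targets: list[tuple],
    system: EMUSystem | None = None,
) -> dict[tuple, np.ndarray]:
    """Steady-state MIDs of the target EMUs for one flux state.

    ``targets`` are ``(metabolite, positions0)`` pairs; returns a dict keyed
    the same way.  Each MID sums to one; the result is deterministic.
    """
    system = system or emu_decompose(network, targets)
    dists = substrate_distributions(network, labels)
    mids = system.simulate(flux, dists)
    return {k: mids[k] for k in system.targets}


# ---------------------------------------------------------------------------
# brute-force full-isotopomer oracle


def brute_force_isotopomers(
    network: Network,
    flux: FluxState,
    labels: dict[str, SubstrateLabel],
    max_states: int = 2**20,
    tol: float = 1e-13,
    max_iter: int = 200000,
    init: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Fixed-point solution of the full positional-isotopomer balance.

    Returns, for every non-substrate metabolite, the probability vector over
    all 2**n positional labeling states.  Intended as a verification oracle
    for small networks; refuses instances whose total state count exceeds
    ``max_states``.
    """
    subs = set(network.substrate_inputs)
    sub_dists = substrate_distributions(network, labels)
    mets = [m for m in network.metabolites.values() if m.id not in subs]
    total = sum(2**m.n_carbons for m in mets)
    if total > max_states:
        raise SimulationError(
            f"total isotopomer state count {total} exceeds guard {max_states}"
        )
    uni = _unidirectional(network)
    v = _uni_fluxes(network, flux)

    # precompute per-unidirectional-reaction state maps
    plans = []
    inflow = {m.id: 0.0 for m in mets}
    for ui, u in enumerate(uni):
        if not u.products:
            continue
        nbits = [network.metabolites[e.metabolite].n_carbons for e in u.educts]
        offsets = np.concatenate([[0], np.cumsum(nbits)])[:-1]
        letter_bit = {}
        for e, off in zip(u.educts, offsets):
            for j, ch in enumerate(e.atoms):
                letter_bit[ch] = off + j
        s_arr = np.arange(2 ** int(sum(nbits)), dtype=np.int64)
        pmaps = []
        for t in u.products:
            if t.metabolite in subs:
                continue
            pstate = np.zeros_like(s_arr)
            for j, ch in enumerate(t.atoms):
                pstate |= ((s_arr >> letter_bit[ch]) & 1) << j
            pmaps.append((t.metabolite, pstate))
            inflow[t.metabolite] += v[ui]
        if pmaps:
            plans.append((ui, [e.metabolite for e in u.educts], pmaps))

    # initial guess: natural abundance everywhere
    dist = {}
    for m in mets:
        comp = np.array([1.0])
        for _ in range(m.n_carbons):
            comp = np.concatenate([comp * (1 - NAT_13C), comp * NAT_13C])
        dist[m.id] = comp
    if init:
        for k, d0 in init.items():
            dist[k] = np.asarray(d0, dtype=float)

    def lookup(met):
        return sub_dists[met] if met in subs else dist[met]

    produced = {m.id for m in mets if inflow[m.id] > 0}
    for it in range(max_iter):
        new = {m: np.zeros_like(d) for m, d in dist.items()}
        for ui, educt_mets, pmaps in plans:
            joint = lookup(educt_mets[0])
            for em in educt_mets[1:]:
                joint = np.outer(lookup(em), joint).ravel()
            for met, pstate in pmaps:
                new[met] += v[ui] * np.bincount(
                    pstate, weights=joint, minlength=len(new[met])
                )
        delta = 0.0
        for m in list(dist):
            if m not in produced:
                continue
            nd = new[m] / inflow[m]
            # project back onto the probability simplex: condensation terms
            # make the iteration expansive in the sum direction, so tiny
            # floating-point drift would otherwise grow exponentially
            nd /= nd.sum()
            delta = max(delta, float(np.max(np.abs(nd - dist[m]))))
            dist[m] = nd
        if delta < tol:
            break
    else:
        warnings.warn(f"isotopomer fixed point not converged (last delta {delta:.2e})")
    return dist


def marginal_mid(dist: np.ndarray, positions0: tuple[int, ...] | None = None) -> np.ndarray:
    """MID of a positional isotopomer distribution (optionally of a carbon
    subset)."""
    n = int(np.log2(len(dist)))
    if positions0 is None:
        positions0 = tuple(range(n))
    return marginalize_positional(dist, tuple(positions0))
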