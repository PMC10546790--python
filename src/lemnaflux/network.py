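"""Compartmentalized atom-transition metabolic networks.

A network is a set of metabolites (with carbon counts and compartment tags)
and reactions whose educt/product terms carry per-carbon atom maps written as
``Metab#abc`` — one letter per carbon, educt-side letters assigned
left-to-right with C1 first.  Carbon conservation means the multiset of
letters on the educt side equals the multiset on the product side; a reaction
may "drop" carbons only by routing them into an explicit unbalanced
(external) pool such as CO2 released to the atmosphere.

The module also provides the free-flux parameterization of the steady-state
flux space (null space of the stoichiometric matrix over balanced
metabolites, with fixed-flux and flux-ratio constraints applied) and the
linear-combination map that aggregates compartment-duplicated reactions into
an uncompartmentalized view.
"""

from __future__ import annotations

import io
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "Metabolite",
    "Term",
    "Reaction",
    "RatioConstraint",
    "Network",
    "NetworkError",
    "FluxState",
    "FreeFluxBasis",
    "AggregationMap",
    "parse_network",
    "serialize_network",
    "validate_carbon_balance",
    "steady_state_basis",
    "aggregation_map",
]

COMPARTMENTS = {"c", "p", "m", "x", "merged"}

INF = float("inf")


class NetworkError(ValueError):
    """Raised for malformed or inconsistent network definitions."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    n_carbons: int
    balanced: bool

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(f"unknown compartment {self.compartment!r} for {self.id}")
        if self.n_carbons < 0:
            raise NetworkError(f"negative carbon count for {self.id}")
        if self.compartment == "x" and self.balanced:
            raise NetworkError(f"external metabolite {self.id} cannot be balanced")


@dataclass(frozen=True)
class Term:
    """One educt or product occurrence: metabolite id plus its atom map."""

    metabolite: str
    atoms: str


@dataclass(frozen=True)
class Reaction:
    id: str
    educts: tuple[Term, ...]
    products: tuple[Term, ...]
    reversible: bool
    lb: float = 0.0
    ub: float = INF

    def __post_init__(self):
        if not self.reversible and self.lb < 0:
            object.__setattr__(self, "lb", 0.0)


@dataclass(frozen=True)
class RatioConstraint:
    """Fixed ratio numerator/denominator between two net fluxes."""

    numerator: str
    denominator: str
    ratio: float

    def __post_init__(self):
        if self.ratio <= 0:
            raise NetworkError("ratio must be > 0")


class Network:
    def __init__(
        self,
        name: str,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        fixed_fluxes: dict[str, float] | None = None,
        ratio_constraints: list[RatioConstraint] | None = None,
        measured_uptakes: list[str] | None = None,
    ):
        self.name = name
        self.metabolites: dict[str, Metabolite] = {m.id: m for m in metabolites}
        if len(self.metabolites) != len(metabolites):
            raise NetworkError("duplicate metabolite ids")
        self.reactions: list[Reaction] = list(reactions)
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._rxn_index) != len(self.reactions):
            raise NetworkError("duplicate reaction ids")
        self.fixed_fluxes = dict(fixed_fluxes or {})
        self.ratio_constraints = list(ratio_constraints or [])
        self.measured_uptakes = list(measured_uptakes or [])
        self._check_references()

    # -- basic accessors -------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def rxn_index(self, rid: str) -> int:
        return self._rxn_index[rid]

    @property
    def balanced_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.balanced]

    @property
    def substrate_inputs(self) -> list[str]:
        """External metabolites consumed somewhere (the feed pools)."""
        consumed = {t.metabolite for r in self.reactions for t in r.educts}
        produced_rev = {
            t.metabolite for r in self.reactions if r.reversible for t in r.products
        }
        consumed |= produced_rev
        return [
            m.id
            for m in self.metabolites.values()
            if not m.balanced and m.id in consumed and not self._is_pure_product(m.id)
        ]

    def _is_pure_product(self, mid: str) -> bool:
        as_educt = any(t.metabolite == mid for r in self.reactions for t in r.educts)
        as_product = any(t.metabolite == mid for r in self.reactions for t in r.products)
        return as_product and not as_educt

    def with_fixed(self, extra: dict[str, float]) -> "Network":
        merged = dict(self.fixed_fluxes)
        merged.update(extra)
        net = Network.__new__(Network)
        net.name = self.name
        net.metabolites = self.metabolites
        net.reactions = self.reactions
        net._rxn_index = self._rxn_index
        net.fixed_fluxes = merged
        net.ratio_constraints = self.ratio_constraints
        net.measured_uptakes = self.measured_uptakes
        return net

    # -- validation ------------------------------------------------------
    def _check_references(self):
        for r in self.reactions:
            for t in r.educts + r.products:
                if t.metabolite not in self.metabolites:
                    raise NetworkError(
                        f"reaction {r.id} references unknown metabolite {t.metabolite}"
                    )
                n = self.metabolites[t.metabolite].n_carbons
                if len(t.atoms) != n:
                    raise NetworkError(
                        f"reaction {r.id}: atom map {t.atoms!r} has {len(t.atoms)} "
                        f"letters but {t.metabolite} has {n} carbons"
                    )
        for rc in self.ratio_constraints:
            for rid in (rc.numerator, rc.denominator):
                if rid not in self._rxn_index:
                    raise NetworkError(f"ratio constraint references unknown reaction {rid}")
        for rid in list(self.fixed_fluxes) + list(self.measured_uptakes):
            if rid not in self._rxn_index:
                raise NetworkError(f"constraint references unknown reaction {rid}")

    # -- stoichiometry ---------------------------------------------------
    def stoichiometric_matrix(self, metabolite_ids: list[str] | None = None) -> np.ndarray:
        """Net stoichiometric matrix S (rows: metabolites, cols: reactions)."""
        mets = metabolite_ids if metabolite_ids is not None else self.balanced_metabolites
        row = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for t in r.educts:
                if t.metabolite in row:
                    S[row[t.metabolite], j] -= 1.0
            for t in r.products:
                if t.metabolite in row:
                    S[row[t.metabolite], j] += 1.0
        return S


# ---------------------------------------------------------------------------
# flux state


@dataclass
class FluxState:
    """Net/exchange flux values for every reaction of a network.

    ``net`` and ``xch`` are aligned with ``network.reactions``.  The
    equivalent forward/backward formulation is ``fwd = max(net, 0) + xch``
    and ``bwd = max(-net, 0) + xch``; irreversible reactions carry zero
    exchange.
    """

    network: Network
    net: np.ndarray
    xch: np.ndarray

    def __post_init__(self):
        n = len(self.network.reactions)
        self.net = np.asarray(self.net, dtype=float)
        self.xch = np.asarray(self.xch, dtype=float)
        if self.net.shape != (n,) or self.xch.shape != (n,):
            raise ValueError("flux vectors must match the network's reaction count")
        irr = np.array([not r.reversible for r in self.network.reactions])
        if np.any(self.xch[irr] != 0.0):
            raise ValueError("irreversible reactions must have zero exchange flux")
        if np.any(self.xch < 0):
            raise ValueError("exchange fluxes must be nonnegative")

    @property
    def fwd(self) -> np.ndarray:
        return np.maximum(self.net, 0.0) + self.xch

    @property
    def bwd(self) -> np.ndarray:
        return np.maximum(-self.net, 0.0) + self.xch

    def __getitem__(self, rid: str) -> float:
        return float(self.net[self.network.rxn_index(rid)])

    def xch_of(self, rid: str) -> float:
        return float(self.xch[self.network.rxn_index(rid)])

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            r.id: (float(self.net[i]), float(self.xch[i]))
            for i, r in enumerate(self.network.reactions)
        }

    def steady_state_residual(self) -> float:
        S = self.network.stoichiometric_matrix()
        r = S @ self.net
        scale = max(1.0, float(np.max(np.abs(self.net))))
        return float(np.max(np.abs(r))) / scale


# ---------------------------------------------------------------------------
# carbon balance validation


def validate_carbon_balance(network: Network) -> list[str]:
    """Return human-readable violations; empty list means every reaction
    conserves carbon atom multisets (reversible reactions are checked once)."""
    violations = []
    for r in network.reactions:
        educt_letters = Counter("".join(t.atoms for t in r.educts))
        product_letters = Counter("".join(t.atoms for t in r.products))
        for side, cnt in (("educt", educt_letters), ("product", product_letters)):
            dup = [a for a, k in cnt.items() if k > 1]
            if dup:
                violations.append(
                    f"{r.id}: duplicate atom label(s) {sorted(dup)} on {side} side"
                )
        if educt_letters != product_letters:
            missing = set(educt_letters) - set(product_letters)
            extra = set(product_letters) - set(educt_letters)
            violations.append(
                f"{r.id}: carbon not conserved "
                f"(lost {sorted(missing) or '-'}, gained {sorted(extra) or '-'})"
            )
    return violations


# ---------------------------------------------------------------------------
# network TSV format

_MET_RE = re.compile(r"^#\s*metabolite\s+(\S+)\s+(\S+)\s+(\d+)\s+(balanced|external)\s*$")
_NAME_RE = re.compile(r"^#\s*name\s+(\S+)\s*$")
_COUNT_RE = re.compile(r"^#\s*reactions\s+(\d+)\s*$")
_FIXED_RE = re.compile(r"^#\s*fixed\s+(\S+)\s+(\S+)\s*$")
_RATIO_RE = re.compile(r"^#\s*ratio\s+(\S+)\s+(\S+)\s+(\S+)\s*$")
_TERM_RE = re.compile(r"^([^#\s]+)#([A-Za-z0-9]*)$")


def _parse_side(text: str, rid: str, lineno: int) -> tuple[Term, ...]:
    text = text.strip()
    if not text:
        return ()
    terms = []
    for part in text.split("+"):
        part = part.strip()
        m = _TERM_RE.match(part)
        if not m:
            raise NetworkError(
                f"line {lineno}: reaction {rid}: malformed atom-map term {part!r}"
            )
        terms.append(Term(m.group(1), m.group(2)))
    return tuple(terms)


def parse_network(text: str) -> Network:
    """Parse the tab-delimited network format.

    Header lines (``#``-prefixed):
      ``# name <id>``, ``# reactions <count>``,
      ``# metabolite <id> <compartment> <n_carbons> <balanced|external>``,
      ``# fixed <reaction> <value>``, ``# ratio <num> <den> <value>``.
    Reaction lines:
      ``<id>\\t<educts>\\t<products>\\t<rev|irr>\\t<lb>\\t<ub>`` with terms
      ``Metab#abc`` joined by ``+``.
    """
    name = "network"
    declared_count = None
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    fixed: dict[str, float] = {}
    ratios: list[RatioConstraint] = []
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            if m := _NAME_RE.match(line):
                name = m.group(1)
            elif m := _COUNT_RE.match(line):
                declared_count = int(m.group(1))
            elif m := _MET_RE.match(line):
                metabolites.append(
                    Metabolite(m.group(1), m.group(2), int(m.group(3)), m.group(4) == "balanced")
                )
            elif m := _FIXED_RE.match(line):
                fixed[m.group(1)] = float(m.group(2))
            elif m := _RATIO_RE.match(line):
                ratios.append(RatioConstraint(m.group(1), m.group(2), float(m.group(3))))
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise NetworkError(f"line {lineno}: expected 6 tab-separated fields, got {len(parts)}")
        rid, educts, products, rev, lb, ub = parts
        if rev not in ("rev", "irr"):
            raise NetworkError(f"line {lineno}: reversibility must be 'rev' or 'irr'")
        reactions.append(
            Reaction(
                rid.strip(),
                _parse_side(educts, rid, lineno),
                _parse_side(products, rid, lineno),
                rev == "rev",
                float(lb),
                float(ub),
            )
        )
    net = Network(name, metabolites, reactions, fixed, ratios)
    if declared_count is not None and declared_count != len(reactions):
        raise NetworkError(
            f"header declares {declared_count} reactions but file contains {len(reactions)}"
        )
    violations = validate_carbon_balance(net)
    if violations:
        raise NetworkError("carbon balance violations:\n" + "\n".join(violations))
    return net


def serialize_network(network: Network) -> str:
    out = [f"# name {network.name}", f"# reactions {len(network.reactions)}"]
    for m in network.metabolites.values():
        kind = "balanced" if m.balanced else "external"
        out.append(f"# metabolite {m.id} {m.compartment} {m.n_carbons} {kind}")
    for rid, val in network.fixed_fluxes.items():
        out.append(f"# fixed {rid} {val!r}")
    for rc in network.ratio_constraints:
        out.append(f"# ratio {rc.numerator} {rc.denominator} {rc.ratio!r}")
    for r in network.reactions:
        educts = " + ".join(f"{t.metabolite}#{t.atoms}" for t in r.educts)
        products = " + ".join(f"{t.metabolite}#{t.atoms}" for t in r.products)
        rev = "rev" if r.reversible else "irr"
        out.append(f"{r.id}\t{educts}\t{products}\t{rev}\t{r.lb}\t{r.ub}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# steady-state free-flux basis


class FreeFluxBasis:
    """Affine parameterization of all net-flux vectors satisfying steady
    state, fixed-flux constraints and flux-ratio constraints.

    ``expand(q)`` maps a free-flux vector (length ``n_free_net``) to the full
    net-flux vector; any expanded vector satisfies S v = 0 on balanced
    metabolites to ~1e-9 relative and all ratio constraints exactly (to
    numerical precision).
    """

    def __init__(
        self,
        network: Network,
        extra_fixed: dict[str, float] | None = None,
        extra_linear: list[tuple[np.ndarray, float]] | None = None,
    ):
        self.network = network
        fixed = dict(network.fixed_fluxes)
        if extra_fixed:
            fixed.update(extra_fixed)
        self.fixed = fixed
        n = len(network.reactions)
        S = network.stoichiometric_matrix()
        rows = [S]
        rhs = [np.zeros(S.shape[0])]
        for coef, val in extra_linear or []:
            rows.append(np.asarray(coef, dtype=float).reshape(1, n))
            rhs.append(np.array([float(val)]))
        for rc in network.ratio_constraints:
            row = np.zeros((1, n))
            row[0, network.rxn_index(rc.numerator)] = 1.0
            row[0, network.rxn_index(rc.denominator)] = -rc.ratio
            rows.append(row)
            rhs.append(np.zeros(1))
        for rid, val in fixed.items():
            row = np.zeros((1, n))
            row[0, network.rxn_index(rid)] = 1.0
            rows.append(row)
            rhs.append(np.array([float(val)]))
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        resid = A @ sol - b
        scale = max(1.0, float(np.max(np.abs(b))) if b.size else 1.0)
        if np.max(np.abs(resid)) > 1e-6 * scale:
            raise NetworkError(
                "inconsistent fixed-flux/ratio constraints: no feasible steady state "
                f"(max residual {np.max(np.abs(resid)):.3g})"
            )
        self.A = A
        self.particular = sol
        self.nullspace = scipy.linalg.null_space(A, rcond=1e-10)
        self.n_free_net = self.nullspace.shape[1]
        xch_free = [
            r.id for r in network.reactions if r.reversible
        ]
        self.free_exchange_ids = xch_free
        self.n_free_xch = len(xch_free)

    def expand(self, q: np.ndarray) -> np.ndarray:
        q = np.atleast_1d(np.asarray(q, dtype=float))
        if q.shape != (self.n_free_net,):
            raise ValueError(f"expected {self.n_free_net} free net fluxes, got {q.shape}")
        return self.particular + self.nullspace @ q

    def project(self, v: np.ndarray) -> np.ndarray:
        """Least-squares free-flux coordinates of a full net vector."""
        return self.nullspace.T @ (np.asarray(v, dtype=float) - self.particular)

    def flux_state(self, q: np.ndarray, xch: dict[str, float] | np.ndarray | None = None) -> FluxState:
        net = self.expand(q)
        x = np.zeros_like(net)
        if xch is not None:
            if isinstance(xch, dict):
                for rid, val in xch.items():
                    x[self.network.rxn_index(rid)] = val
            else:
                x = np.asarray(xch, dtype=float)
        return FluxState(self.network, net, x)


def steady_state_basis(network: Network, extra_fixed: dict[str, float] | None = None) -> FreeFluxBasis:
    return FreeFluxBasis(network, extra_fixed)


# ---------------------------------------------------------------------------
# compartment aggregation


_SUFFIX_RE = re.compile(r"_(c|p|m)$")


def _merged_met(mid: str) -> str:
    return _SUFFIX_RE.sub("", mid)


def _merged_rid(rid: str) -> str:
    return _SUFFIX_RE.sub("", rid)


@dataclass
class AggregationMap:
    """Named linear combinations mapping a compartmentalized flux vector to
    the uncompartmentalized view (rows of ``matrix`` align with ``names``)."""

    network: Network
    names: list[str]
    matrix: np.ndarray
    members: dict[str, list[str]] = field(default_factory=dict)

    def apply(self, net: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(net, dtype=float)

    def combination(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]


def aggregation_map(network: Network) -> AggregationMap:
    """Aggregate fluxes of compartment-duplicated reactions.

    Reactions whose educt and product metabolite multisets coincide after
    dropping compartment suffixes are summed into one combined reaction;
    transporters between pools that merge become all-zero rows.
    """
    n = len(network.reactions)
    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    zero_rows: list[int] = []
    for i, r in enumerate(network.reactions):
        e = tuple(sorted(_merged_met(t.metabolite) for t in r.educts))
        p = tuple(sorted(_merged_met(t.metabolite) for t in r.products))
        if e == p:
            zero_rows.append(i)
            continue
        key = (e, p)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)

    names, rows, members = [], [], {}
    used = set()

    def _group_name(idx: list[int]) -> str:
        ids = [network.reactions[i].id for i in idx]
        stripped = {_merged_rid(x) for x in ids}
        if len(stripped) == 1:
            base = stripped.pop()
        else:
            import os

            base = os.path.commonprefix(ids).rstrip("_") or "+".join(ids)
        name = base
        k = 2
        while name in used:
            name = f"{base}.{k}"
            k += 1
        used.add(name)
        return name

    for key in order:
        idx = groups[key]
        name = _group_name(idx)
        row = np.zeros(n)
        row[idx] = 1.0
        names.append(name)
        rows.append(row)
        members[name] = [network.reactions[i].id for i in idx]
    for i in zero_rows:
        rid = network.reactions[i].id
        names.append(rid)
        rows.append(np.zeros(n))
        members[rid] = [rid]
    return AggregationMap(network, names, np.vstack(rows), members)
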