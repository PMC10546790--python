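"""Mass-isotopomer arithmetic and measurement corrections.

A MID (mass isotopomer distribution) is a nonnegative vector m0..mn summing
to one: the fractions of a fragment carrying 0..n heavy carbons.  This
module provides substrate label mixtures (positional isotopomer
distributions), average enrichment, MID convolution, isotopologue
distributions of derivative formulas from natural isotope abundances, the
natural-abundance correction for derivatized GC-MS fragments, and the
correction for unlabeled inoculum biomass carried into the harvest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import scipy.optimize

__all__ = [
    "NATURAL_ABUNDANCE",
    "NAT_13C",
    "SubstrateLabel",
    "FragmentSpec",
    "validate_mid",
    "mixture_distribution",
    "positional_to_mid",
    "marginalize_positional",
    "average_enrichment",
    "convolve",
    "natural_mid",
    "natural_skeleton_mid",
    "correct_derivative",
    "correct_inoculum",
]

#: fractional natural 13C abundance used throughout (the conventional 1.1%)
NAT_13C = 0.011

#: isotopologue mass-abundance vectors for the elements occurring in GC-MS
#: derivative formulas (index = mass shift in Da above the monoisotopic mass);
#: standard terrestrial values, with 13C fixed at the 1.1% convention above.
NATURAL_ABUNDANCE: dict[str, np.ndarray] = {
    "C": np.array([1.0 - NAT_13C, NAT_13C]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0, 0.0001]),
    "Si": np.array([0.92223, 0.04685, 0.03092]),
}


def validate_mid(mid: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    mid = np.asarray(mid, dtype=float)
    if np.any(mid < -tol):
        raise ValueError("MID has negative fractions")
    if abs(mid.sum() - 1.0) > tol:
        raise ValueError(f"MID does not sum to 1 (sum={mid.sum()!r})")
    return mid


@dataclass(frozen=True)
class SubstrateLabel:
    """A mixture of positional labeling species of one substrate.

    ``components`` is a list of ``(pattern, mole_fraction, purity)`` where
    ``pattern`` marks enriched positions with '1' ('0' positions carry
    natural abundance, '-' positions are exactly 12C) and ``purity`` is the
    per-position 13C probability of the enriched positions.
    """

    components: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        total = sum(f for _, f, _ in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1 (got {total})")
        for pat, _, purity in self.components:
            if not set(pat) <= {"0", "1", "-"}:
                raise ValueError(f"bad pattern {pat!r}")
            if not 0.0 <= purity <= 1.0:
                raise ValueError("purity must lie in [0, 1]")

    @property
    def n_carbons(self) -> int:
        return len(self.components[0][0])


def unlabeled(n_carbons: int) -> SubstrateLabel:
    return SubstrateLabel((("0" * n_carbons, 1.0, 0.0),))


def glucose_80_10_10(purity: float = 0.99) -> SubstrateLabel:
    """The labeling design of the tracer cultures: unlabeled, [1-13C] and
    [U-13C6] glucose at molar ratio 80:10:10."""
    return SubstrateLabel(
        (
            ("000000", 0.80, purity),
            ("100000", 0.10, purity),
            ("111111", 0.10, purity),
        )
    )


def glucose_u40(purity: float = 0.99) -> SubstrateLabel:
    """40:60 [U-13C6]:unlabeled glucose (the biomass-enrichment experiment)."""
    return SubstrateLabel((("111111", 0.40, purity), ("000000", 0.60, 0.0)))


def mixture_distribution(label: SubstrateLabel, n_carbons: int) -> np.ndarray:
    """Probability vector over all 2**n positional labeling states (bit i of
    the state index set means carbon i+1 is 13C); natural abundance applies
    to unenriched positions."""
    if label.n_carbons != n_carbons:
        raise ValueError(
            f"label patterns have {label.n_carbons} positions, expected {n_carbons}"
        )
    dist = np.zeros(2**n_carbons)
    for pattern, frac, purity in label.components:
        p13 = np.array(
            [purity if ch == "1" else (0.0 if ch == "-" else NAT_13C) for ch in pattern]
        )
        comp = np.array([1.0])
        for p in p13:
            comp = np.concatenate([comp * (1 - p), comp * p])
        dist += frac * comp
    return dist


def positional_to_mid(dist: np.ndarray) -> np.ndarray:
    """Collapse a 2**n positional distribution to its (n+1)-long MID."""
    n = int(np.log2(len(dist)))
    if 2**n != len(dist):
        raise ValueError("positional distribution length must be a power of 2")
    weights = np.array([bin(s).count("1") for s in range(len(dist))])
    return np.bincount(weights, weights=dist, minlength=n + 1)


def marginalize_positional(dist: np.ndarray, positions: tuple[int, ...]) -> np.ndarray:
    """MID of a carbon subset (0-based positions) of a positional
    distribution."""
    n = int(np.log2(len(dist)))
    masks = [1 << p for p in positions]
    weights = np.array(
        [sum(1 for m in masks if s & m) for s in range(len(dist))]
    )
    return np.bincount(weights, weights=dist, minlength=len(positions) + 1)


def average_enrichment(dist: np.ndarray, n_carbons: int | None = None) -> float:
    """Mean fractional 13C enrichment of a MID (length n+1) or of a
    positional distribution (length 2**n, pass ``n_carbons`` to
    disambiguate)."""
    dist = np.asarray(dist, dtype=float)
    if n_carbons is not None and len(dist) == 2**n_carbons:
        dist = positional_to_mid(dist) if n_carbons > 0 else dist
        n = n_carbons
    else:
        n = len(dist) - 1
    if n == 0:
        return 0.0
    return float(np.arange(n + 1) @ dist / n)


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """MID of the condensation of two independent fragments (Cauchy
    product)."""
    return np.convolve(np.asarray(a, dtype=float), np.asarray(b, dtype=float))


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    if isinstance(formula, dict):
        counts = dict(formula)
    else:
        counts = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
    for el, n in counts.items():
        if el not in NATURAL_ABUNDANCE:
            raise ValueError(f"no abundance data for element {el!r}")
        if n < 0:
            raise ValueError("negative element count")
    return counts


def natural_mid(formula: str | dict[str, int]) -> np.ndarray:
    """Isotopologue mass distribution of an elemental formula at natural
    terrestrial isotope abundances (C, H, N, O, S, Si)."""
    counts = parse_formula(formula)
    mid = np.array([1.0])
    for el, n in counts.items():
        for _ in range(n):
            mid = np.convolve(mid, NATURAL_ABUNDANCE[el])
    return mid


def natural_skeleton_mid(n_carbons: int) -> np.ndarray:
    """MID of an n-carbon skeleton at natural 13C abundance (binomial)."""
    return natural_mid({"C": n_carbons})


@dataclass(frozen=True)
class FragmentSpec:
    """One measured GC-MS fragment: analyte, the skeleton carbon positions
    included in the ion, the source metabolite pool of the network, and the
    elemental formula of everything in the ion beyond the skeleton carbons."""

    id: str
    analyte: str
    metabolite: str
    positions: tuple[int, ...]  # 1-based carbon positions of the analyte
    formula: str = ""

    @property
    def n_carbons(self) -> int:
        return len(self.positions)

    @property
    def positions0(self) -> tuple[int, ...]:
        return tuple(p - 1 for p in self.positions)


def derivative_correction_matrix(frag: FragmentSpec, n_raw: int) -> np.ndarray:
    """Forward convolution matrix of the derivative natural MID: maps a
    skeleton MID (length n_carbons+1) onto the raw fragment MID (length
    ``n_raw``)."""
    d = natural_mid(frag.formula) if frag.formula else np.array([1.0])
    A = np.zeros((n_raw, frag.n_carbons + 1))
    for j in range(frag.n_carbons + 1):
        seg = d[: n_raw - j]
        A[j : j + len(seg), j] = seg
    return A


def propagate_correction_sd(
    sds: np.ndarray, frag: FragmentSpec, inoculum_fraction: float = 0.0
) -> np.ndarray:
    """Standard deviations of the corrected skeleton MID implied by
    independent raw-MID errors: linear least-squares error propagation
    through the deconvolution, then scaled by the inoculum correction
    factor 1/(1-f)."""
    sds = np.asarray(sds, dtype=float)
    A = derivative_correction_matrix(frag, len(sds))
    # weighted LS covariance diag; raw errors treated as independent
    W = A / np.maximum(sds, 1e-12)[:, None]
    cov = np.linalg.pinv(W.T @ W)
    out = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return out / (1.0 - inoculum_fraction)


def correct_derivative(raw: np.ndarray, frag: FragmentSpec) -> np.ndarray:
    """Deconvolve the natural-isotope contribution of the derivative side
    chains (and any non-carbon skeleton atoms) from a measured fragment MID,
    returning the skeleton-carbon MID.

    Solved as a nonnegative least-squares deconvolution against the full
    correction matrix, renormalized; inverse of
    ``convolve(skeleton, natural_mid(formula))`` to ~1e-6 on clean data.
    """
    raw = np.asarray(raw, dtype=float)
    nskel = frag.n_carbons
    if len(raw) < nskel + 1:
        raise ValueError(
            f"fragment {frag.id}: raw MID has {len(raw)} masses, "
            f"need at least {nskel + 1}"
        )
    d = natural_mid(frag.formula) if frag.formula else np.array([1.0])
    if len(d) == 1:
        out = raw[: nskel + 1].copy()
        s = out.sum()
        return out / s if s > 0 else out
    A = np.zeros((len(raw), nskel + 1))
    for j in range(nskel + 1):
        seg = d[: len(raw) - j]
        A[j : j + len(seg), j] = seg
    x, _ = scipy.optimize.nnls(A, raw)
    s = x.sum()
    if s <= 0:
        raise ValueError(f"fragment {frag.id}: deconvolution returned empty MID")
    return x / s


def correct_inoculum(
    mid: np.ndarray, f_unlabeled: float, natural_skeleton: np.ndarray
) -> np.ndarray:
    """Remove the contribution of a fraction ``f_unlabeled`` of unlabeled
    (natural-abundance) inoculum biomass from a measured skeleton MID.

    Inverse of the forward mixture
    ``(1 - f) * mid_true + f * natural_skeleton``; the result is clipped at
    zero and renormalized.
    """
    if not 0.0 <= f_unlabeled < 1.0:
        raise ValueError("inoculum fraction must lie in [0, 1)")
    mid = np.asarray(mid, dtype=float)
    nat = np.asarray(natural_skeleton, dtype=float)
    if mid.shape != nat.shape:
        raise ValueError("MID and natural skeleton MID lengths differ")
    out = (mid - f_unlabeled * nat) / (1.0 - f_unlabeled)
    out = np.clip(out, 0.0, None)
    s = out.sum()
    if s <= 0:
        raise ValueError("inoculum correction removed all signal")
    return out / s


#: default unlabeled-inoculum biomass fraction of the harvest
INOCULUM_FRACTION = 0.033
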