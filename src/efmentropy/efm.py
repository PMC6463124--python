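"""Extreme flux modes of the stationary flux cone.

The stationary states of a network with stoichiometric matrix ν and
unidirectional transformations form the polyhedral cone
``{v ≥ 0 : νv = 0}``.  Its extreme rays — equivalently the support-minimal
stationary flux vectors — are the extreme flux modes (EFMs): the elementary
pathways out of which every stationary flux pattern is built as a
nonnegative combination v = Σ jᵢ Eᵢ.

Enumeration is by the double description method over exact Python integers,
so ν·E = 0 holds exactly and the normalization (coprime integer entries) is
canonical.  Networks here are small (≲ 30 columns); no attempt is made at
large-scale metabolic performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .network import (
    INFLOW,
    OUTFLOW,
    NetworkError,
    ReactionNetwork,
    stoichiometric_matrix,
)

INTERNAL_CLOSED = "internal_closed"
OPEN_PRODUCTIVE = "open_productive"
FLOW_THROUGH = "flow_through"


@dataclass(frozen=True)
class FluxMode:
    """One extreme ray of the stationary flux cone.

    ``coefficients`` are coprime nonnegative integers aligned with the
    network's transformation list; ``support`` uses the 1-based
    transformation indices.  ``parity_partner`` is the position (in the
    enumerated list) of the mirror-image mode; a parity singlet points at
    itself.
    """

    coefficients: tuple[int, ...]
    support: frozenset[int]
    pathway_class: str | None = None
    parity_partner: int | None = None

    def coefficient(self, index: int, network: ReactionNetwork) -> int:
        return self.coefficients[network.indices.index(index)]


# ---------------------------------------------------------------------------
# Enumeration (double description over exact integers)
# ---------------------------------------------------------------------------

def _normalize(ray: Sequence[int]) -> tuple[int, ...]:
    g = math.gcd(*[abs(int(x)) for x in ray])
    return tuple(int(x) // g for x in ray)


def _extreme_rays(rows: Iterable[Sequence[int]], n: int) -> list[tuple[int, ...]]:
    """Extreme rays of {v ≥ 0 : A v = 0}, A given by integer ``rows``.

    Starts from the unit rays of the orthant and intersects with one
    hyperplane at a time, combining adjacent positive/negative rays.
    Adjacency uses the standard combinatorial zero-set test, which is exact
    because every ray satisfies all previously processed equalities.
    """
    rays: list[tuple[int, ...]] = [
        tuple(1 if i == j else 0 for i in range(n)) for j in range(n)
    ]
    for a in rows:
        a = [int(x) for x in a]
        if all(x == 0 for x in a):
            continue
        dots = [sum(ai * ri for ai, ri in zip(a, r)) for r in rays]
        zero = [r for r, d in zip(rays, dots) if d == 0]
        pos = [(r, d) for r, d in zip(rays, dots) if d > 0]
        neg = [(r, d) for r, d in zip(rays, dots) if d < 0]
        new = list(zero)
        zerosets = [frozenset(i for i, x in enumerate(r) if x == 0) for r in rays]
        for rp, dp in pos:
            zp = frozenset(i for i, x in enumerate(rp) if x == 0)
            for rm, dm in neg:
                zm = frozenset(i for i, x in enumerate(rm) if x == 0)
                common = zp & zm
                adjacent = not any(
                    common <= z
                    for r, z in zip(rays, zerosets)
                    if r is not rp and r is not rm
                )
                if not adjacent:
                    continue
                combo = tuple(dp * m - dm * p for p, m in zip(rp, rm))
                new.append(_normalize(combo))
        # dedupe (combinations of distinct pairs can coincide)
        rays = list(dict.fromkeys(new))
    return rays


def _support_minimal(rays: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    supports = [frozenset(i for i, x in enumerate(r) if x != 0) for r in rays]
    keep = []
    for i, (r, s) in enumerate(zip(rays, supports)):
        if not s:
            continue
        if any(supports[j] < s for j in range(len(rays)) if j != i):
            continue
        keep.append(r)
    return keep


def enumerate_efms(network: ReactionNetwork) -> list[FluxMode]:
    """All extreme flux modes, classified and parity-paired.

    Deterministic order: by support size, then lexicographically by the
    sorted support (1-based transformation indices).
    """
    nu = stoichiometric_matrix(network)
    rays = _extreme_rays(nu.tolist(), network.n_transformations)
    rays = _support_minimal(rays)
    idx = network.indices

    def key(ray):
        supp = tuple(idx[i] for i, x in enumerate(ray) if x != 0)
        return (len(supp), supp)

    rays.sort(key=key)
    modes = [
        FluxMode(
            coefficients=ray,
            support=frozenset(idx[i] for i, x in enumerate(ray) if x != 0),
        )
        for ray in rays
    ]
    modes = [replace(m, pathway_class=classify_efm(m, network)) for m in modes]
    try:
        pairing = parity_pair_efms(modes, network)
        modes = [replace(m, parity_partner=pairing[i]) for i, m in enumerate(modes)]
    except NetworkError:
        pass  # network without a parity structure; leave partners unset
    return modes


def classify_efm(mode: FluxMode, network: ReactionNetwork) -> str:
    """internal_closed (no flow step), flow_through (an inflow plus its own
    outflow, nothing else), or open_productive."""
    kinds = {i: network.by_index(i).kind for i in mode.support}
    if all(k not in (INFLOW, OUTFLOW) for k in kinds.values()):
        return INTERNAL_CLOSED
    inflows = [i for i, k in kinds.items() if k == INFLOW]
    outflows = [i for i, k in kinds.items() if k == OUTFLOW]
    if len(mode.support) == 2 and len(inflows) == 1 and len(outflows) == 1:
        fed = next(iter(network.by_index(inflows[0]).net_stoich))
        drained = next(iter(network.by_index(outflows[0]).reactant_stoich))
        if fed == drained:
            return FLOW_THROUGH
    return OPEN_PRODUCTIVE


def parity_pair_efms(
    modes: Sequence[FluxMode], network: ReactionNetwork
) -> dict[int, int]:
    """Involution mapping each mode's position to that of its mirror image.

    The enantiomer swap permutes the transformation columns; applying that
    permutation to an EFM must land on another EFM of the same set.
    """
    perm = network.parity_transformation_permutation()
    idx = network.indices
    pos = {m.coefficients: i for i, m in enumerate(modes)}
    col_of = {index: j for j, index in enumerate(idx)}
    pairing: dict[int, int] = {}
    for i, m in enumerate(modes):
        swapped = [0] * len(idx)
        for j, index in enumerate(idx):
            swapped[col_of[perm[index]]] = m.coefficients[j]
        partner = pos.get(tuple(swapped))
        if partner is None:
            raise NetworkError(
                "parity permutation maps an EFM outside the enumerated set "
                "(network/parity mismatch)"
            )
        pairing[i] = partner
    return pairing


def find_mode(modes: Sequence[FluxMode], support: Iterable[int]) -> FluxMode:
    """The unique mode with the given support (1-based indices)."""
    s = frozenset(support)
    hits = [m for m in modes if m.support == s]
    if len(hits) != 1:
        raise KeyError(f"no unique mode with support {sorted(s)}")
    return hits[0]


def efm_matrix(modes: Sequence[FluxMode]) -> np.ndarray:
    """E as an integer matrix, transformations × modes."""
    return np.array([m.coefficients for m in modes], dtype=int).T


# ---------------------------------------------------------------------------
# Convex decomposition of stationary rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyDecomposition:
    """Nonnegative pathway currents j with v ≈ Σ jᵢEᵢ.

    ``residual`` is the Euclidean norm of v − Ej; ``stationary`` flags
    whether it is below the requested tolerance (a genuinely stationary
    rate vector decomposes exactly, up to rounding).
    """

    j: np.ndarray
    residual: float
    stationary: bool


def decompose_steady_rates(
    vss: Sequence[float],
    modes: Sequence[FluxMode],
    rtol: float = 1e-6,
) -> SteadyDecomposition:
    """Least-squares nonnegative expansion of a stationary rate vector in the
    extreme flux modes (v = Σ jᵢEᵢ, jᵢ ≥ 0)."""
    v = np.asarray(vss, dtype=float)
    if np.any(v < 0):
        raise ValueError("stationary rates must be nonnegative")
    E = efm_matrix(modes).astype(float)
    # scale columns to comparable magnitude for the solver, then undo
    j, res = nnls(E, v)
    scale = np.linalg.norm(v)
    stationary = res <= rtol * (scale if scale > 0 else 1.0)
    return SteadyDecomposition(j=j, residual=float(res), stationary=bool(stationary))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def efm_table(modes: Sequence[FluxMode], network: ReactionNetwork) -> pd.DataFrame:
    """The E matrix as a DataFrame (rows: transformation indices, columns:
    mode labels M1..Mn in the deterministic enumeration order)."""
    E = efm_matrix(modes)
    return pd.DataFrame(
        E,
        index=pd.Index(network.indices, name="transformation"),
        columns=[f"M{i+1}" for i in range(len(modes))],
    )


def pathway_listing(modes: Sequence[FluxMode], network: ReactionNetwork) -> str:
    """Human-readable pathway table: support, class and parity partner per mode."""
    lines = ["mode\tsupport\tclass\tparity_partner"]
    for i, m in enumerate(modes):
        partner = f"M{m.parity_partner + 1}" if m.parity_partner is not None else "-"
        supp = ",".join(str(s) for s in sorted(m.support))
        lines.append(f"M{i+1}\t{{{supp}}}\t{m.pathway_class}\t{partner}")
    return "\n".join(lines) + "\n"
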