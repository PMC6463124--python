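"""Open-flow mass-action reaction networks.

A network is an ordered set of species plus an ordered list of
*unidirectional* transformations: forward/reverse halves of reversible
reactions, zeroth-order inflows and first-order outflows of a CSTR.
Reversible chemistry is always split into its two halves so that the
stationary flux cone lives in the nonnegative orthant, which is what makes
extreme-flux-mode enumeration and the per-pathway entropy bookkeeping exact.

The bundled fixture is a two-replicator chiral hypercycle: an achiral
resource A feeds two pairs of enantiomeric replicators (1R, 2R in D and L
forms) coupled by homochiral mutual cross-catalysis inside an open-flow
reactor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("efmentropy")

#: Transformation kinds.
REACTION_FORWARD = "reaction_forward"
REACTION_REVERSE = "reaction_reverse"
INFLOW = "inflow"
OUTFLOW = "outflow"
KINDS = (REACTION_FORWARD, REACTION_REVERSE, INFLOW, OUTFLOW)

#: Species order of the hypercycle fixture (row order of its matrix).
HYPERCYCLE_SPECIES = ("A", "2RD", "1RD", "1RL", "2RL")


class NetworkError(ValueError):
    """Invalid network construction or query."""


class ParseError(NetworkError):
    """Malformed plain-text network file."""


@dataclass(frozen=True)
class SpeciesSet:
    """Ordered species labels with an optional mirror (parity) involution.

    ``chiral_partner`` maps every label to its enantiomer; achiral species
    map to themselves.
    """

    labels: tuple[str, ...]
    chiral_partner: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise NetworkError("duplicate species labels")
        partner = dict(self.chiral_partner)
        for s in self.labels:
            partner.setdefault(s, s)
        for a, b in partner.items():
            if a not in self.labels or b not in self.labels:
                raise NetworkError(f"chiral partner refers to unknown species {a!r}/{b!r}")
            if partner[b] != a:
                raise NetworkError(f"chiral_partner is not an involution at {a!r}")
        object.__setattr__(self, "chiral_partner", partner)

    @property
    def achiral(self) -> tuple[str, ...]:
        return tuple(s for s in self.labels if self.chiral_partner[s] == s)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class Transformation:
    """One unidirectional transformation (column of the stoichiometric matrix).

    ``reactant_stoich`` holds the kinetic orders α (catalysts included), so
    the mass-action monomial is ``k · Π [X]^α``; ``net_stoich`` holds the net
    production, in which catalysts cancel.  For an inflow the monomial is
    empty and ``rate_constant`` is the full constant rate f·c_in; an outflow
    is first order with rate constant f.
    """

    index: int  # 1-based, stable across variants
    kind: str
    reactant_stoich: Mapping[str, int]
    net_stoich: Mapping[str, int]
    rate_constant: float
    reverse_partner: int | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise NetworkError(f"unknown transformation kind {self.kind!r}")
        if self.rate_constant < 0:
            raise NetworkError(f"negative rate constant in transformation {self.index}")
        if self.kind == INFLOW and self.reactant_stoich:
            raise NetworkError(f"inflow {self.index} must have an empty reactant monomial")
        if self.kind == OUTFLOW and (
            len(self.reactant_stoich) != 1 or set(self.reactant_stoich.values()) != {1}
        ):
            raise NetworkError(f"outflow {self.index} must be first order in one species")
        object.__setattr__(self, "reactant_stoich", dict(self.reactant_stoich))
        object.__setattr__(
            self, "net_stoich", {s: n for s, n in self.net_stoich.items() if n != 0}
        )


@dataclass(frozen=True)
class ReactionNetwork:
    """Species + ordered transformations, with the parity structure derived."""

    species: SpeciesSet
    transformations: tuple[Transformation, ...]

    def __post_init__(self):
        object.__setattr__(self, "transformations", tuple(self.transformations))
        seen = set()
        for t in self.transformations:
            if t.index in seen:
                raise NetworkError(f"duplicate transformation index {t.index}")
            seen.add(t.index)
            for s in list(t.reactant_stoich) + list(t.net_stoich):
                if s not in self.species.labels:
                    raise NetworkError(
                        f"transformation {t.index} references unknown species {s!r}"
                    )
        for t in self.transformations:
            if t.kind in (REACTION_FORWARD, REACTION_REVERSE) and t.reverse_partner is not None:
                if t.reverse_partner not in seen:
                    raise NetworkError(
                        f"transformation {t.index} names a missing reverse partner"
                    )
                p = self.by_index(t.reverse_partner)
                net = {s: t.net_stoich.get(s, 0) + p.net_stoich.get(s, 0)
                       for s in self.species.labels}
                if any(v != 0 for v in net.values()):
                    raise NetworkError(
                        f"pair ({t.index},{p.index}) is not micro-reversible"
                    )

    # -- indexing -----------------------------------------------------------

    def by_index(self, index: int) -> Transformation:
        for t in self.transformations:
            if t.index == index:
                return t
        raise NetworkError(f"no transformation with index {index}")

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(t.index for t in self.transformations)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_transformations(self) -> int:
        return len(self.transformations)

    def reversible_pairs(self) -> tuple[tuple[int, int], ...]:
        """(forward, reverse) index pairs, in forward-index order.

        Strictly irreversible reaction steps (no partner) are not listed;
        they carry no finite affinity.
        """
        return tuple(
            (t.index, t.reverse_partner)
            for t in self.transformations
            if t.kind == REACTION_FORWARD and t.reverse_partner is not None
        )

    # -- parity -------------------------------------------------------------

    def parity_transformation_permutation(self) -> dict[int, int]:
        """Permutation of transformation indices induced by the enantiomer swap.

        Each transformation, with its species relabelled by ``chiral_partner``,
        must reappear in the network with the same kind and rate constant;
        otherwise the network is not mirror symmetric.
        """
        swap = self.species.chiral_partner
        perm: dict[int, int] = {}
        for t in self.transformations:
            react = {swap[s]: a for s, a in t.reactant_stoich.items()}
            net = {swap[s]: n for s, n in t.net_stoich.items()}
            image = None
            for u in self.transformations:
                if (
                    u.kind == t.kind
                    and u.reactant_stoich == react
                    and u.net_stoich == net
                    and u.rate_constant == t.rate_constant
                ):
                    image = u.index
                    break
            if image is None:
                raise NetworkError(
                    f"network is not parity symmetric: transformation {t.index} "
                    "has no mirror image"
                )
            perm[t.index] = image
        return perm

    # -- flow structure -----------------------------------------------------

    def flow_species(self) -> dict[str, tuple[float, float]]:
        """Map species → (f, c_in) for species carried by the open flow.

        f is the outflow rate constant; c_in the feed concentration
        (inflow constant rate / f, or 0 when the species has no inflow).
        """
        out: dict[str, tuple[float, float]] = {}
        inflow_rate = {next(iter(t.net_stoich)): t.rate_constant
                       for t in self.transformations if t.kind == INFLOW}
        for t in self.transformations:
            if t.kind == OUTFLOW:
                sp = next(iter(t.reactant_stoich))
                f = t.rate_constant
                c_in = inflow_rate.get(sp, 0.0) / f if f > 0 else 0.0
                out[sp] = (f, c_in)
        return out


# ---------------------------------------------------------------------------
# Stoichiometry and kinetics
# ---------------------------------------------------------------------------

def stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer matrix ν: one row per species (SpeciesSet order), one column
    per transformation (list order)."""
    nu = np.zeros((network.n_species, network.n_transformations), dtype=int)
    for j, t in enumerate(network.transformations):
        for s, n in t.net_stoich.items():
            nu[network.species.index(s), j] = n
    return nu


def rate_vector(network: ReactionNetwork, conc: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Mass-action rates v_j = k_j · Π_i [X_i]^α_ji (mol L⁻¹ s⁻¹).

    ``conc`` is either a mapping species → concentration or a sequence in
    species order.  Inflow rates are the stored constants.
    """
    c = _conc_array(network, conc)
    if np.any(c < 0):
        raise NetworkError("negative concentration")
    v = np.empty(network.n_transformations)
    for j, t in enumerate(network.transformations):
        if t.kind == INFLOW:
            v[j] = t.rate_constant
        else:
            m = t.rate_constant
            for s, a in t.reactant_stoich.items():
                m *= c[network.species.index(s)] ** a
            v[j] = m
    return v


def _conc_array(network: ReactionNetwork, conc) -> np.ndarray:
    if isinstance(conc, Mapping):
        return np.array([conc[s] for s in network.species.labels], dtype=float)
    c = np.asarray(conc, dtype=float)
    if c.shape != (network.n_species,):
        raise NetworkError(
            f"expected {network.n_species} concentrations, got shape {c.shape}"
        )
    return c


def conserved_moieties(network: ReactionNetwork) -> list[tuple[Fraction, ...]]:
    """Exact rational basis of the left null space of the *reaction* columns.

    These are the linear combinations of species conserved by the chemistry
    alone (the open flow breaks them).  For the hypercycle there is a single
    one, the total A-equivalent mass (1,1,1,1,1).
    """
    cols = [j for j, t in enumerate(network.transformations)
            if t.kind in (REACTION_FORWARD, REACTION_REVERSE)]
    nu = stoichiometric_matrix(network)[:, cols]
    rows = [[Fraction(int(x)) for x in nu[:, j]] for j in range(nu.shape[1])]
    return _rational_nullspace(rows, network.n_species)


def _rational_nullspace(rows: list[list[Fraction]], n: int) -> list[tuple[Fraction, ...]]:
    """Null space basis of the row system (exact Gaussian elimination)."""
    mat = [row[:] for row in rows]
    pivots: list[int] = []
    r = 0
    for col in range(n):
        piv = next((i for i in range(r, len(mat)) if mat[i][col] != 0), None)
        if piv is None:
            continue
        mat[r], mat[piv] = mat[piv], mat[r]
        mat[r] = [x / mat[r][col] for x in mat[r]]
        for i in range(len(mat)):
            if i != r and mat[i][col] != 0:
                fac = mat[i][col]
                mat[i] = [a - fac * b for a, b in zip(mat[i], mat[r])]
        pivots.append(col)
        r += 1
    basis = []
    free = [c for c in range(n) if c not in pivots]
    for fc in free:
        vec = [Fraction(0)] * n
        vec[fc] = Fraction(1)
        for pr, pc in enumerate(pivots):
            vec[pc] = -mat[pr][fc]
        basis.append(tuple(vec))
    return basis


# ---------------------------------------------------------------------------
# Hypercycle fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HypercycleParams:
    """Rate constants, flow and initial condition of the hypercycle study.

    Defaults are the reference parameter set: ka=1e4, k-a=10, kb=1e3,
    k-b=0.5 (L² mol⁻² s⁻¹ for the termolecular steps as written), volumetric
    flow q=0.2 μL/s through a V=1 L reactor (f=q/V=2e-7 s⁻¹), feed
    [A]in=1e-4 mol/L, initial replicator concentrations c0=1e-6 mol/L each,
    and a chiral seed δ=1e-23 mol/L added to 2RL.
    """

    ka: float = 1.0e4
    k_minus_a: float = 1.0e1
    kb: float = 1.0e3
    k_minus_b: float = 5.0e-1
    q: float = 2.0e-7   # L/s (0.2 μL/s)
    V: float = 1.0      # L
    A_in: float = 1.0e-4
    c0: float = 1.0e-6
    delta: float = 1.0e-23

    def __post_init__(self):
        for name in ("ka", "k_minus_a", "kb", "k_minus_b", "q", "V",
                     "A_in", "c0", "delta"):
            if getattr(self, name) < 0:
                raise NetworkError(f"parameter {name} must be nonnegative")
        if self.V <= 0:
            raise NetworkError("reactor volume V must be positive")
        logger.debug("flow parameter f = q/V = %g s^-1", self.f)

    @property
    def f(self) -> float:
        """Inverse residence time q/V (s⁻¹)."""
        return self.q / self.V

    def initial_concentrations(self) -> dict[str, float]:
        """Reactor contents at t=0: feed-level A, racemic replicators, +δ on 2RL."""
        return {
            "A": self.A_in,
            "2RD": self.c0,
            "1RD": self.c0,
            "1RL": self.c0,
            "2RL": self.c0 + self.delta,
        }


def build_hypercycle_network(params: HypercycleParams | None = None) -> ReactionNetwork:
    """The fourteen-transformation two-replicator hypercycle in a CSTR.

    Numbering: 1–4 the D-sector forward/reverse cross-catalyses, 5/6 the
    D-enantiomer outflows, 7–10 and 11/12 the mirror L-sector, 13 the inflow
    of A, 14 its outflow.  Chirality constrains the rate constants:
    k1=k7=ka, k2=k8=k-a, k3=k9=kb, k4=k10=k-b.
    """
    p = params or HypercycleParams()
    f = p.f
    species = SpeciesSet(
        HYPERCYCLE_SPECIES,
        chiral_partner={"2RD": "2RL", "2RL": "2RD", "1RD": "1RL", "1RL": "1RD"},
    )

    def catalysis(idx, resource, grown, catalyst, kf, kr):
        fwd = Transformation(
            idx, REACTION_FORWARD,
            {resource: 1, grown: 1, catalyst: 1},
            {resource: -1, grown: +1},
            kf, reverse_partner=idx + 1,
        )
        rev = Transformation(
            idx + 1, REACTION_REVERSE,
            {grown: 2, catalyst: 1},
            {resource: +1, grown: -1},
            kr, reverse_partner=idx,
        )
        return [fwd, rev]

    def outflow(idx, sp):
        return Transformation(idx, OUTFLOW, {sp: 1}, {sp: -1}, f)

    ts = []
    ts += catalysis(1, "A", "1RD", "2RD", p.ka, p.k_minus_a)
    ts += catalysis(3, "A", "2RD", "1RD", p.kb, p.k_minus_b)
    ts += [outflow(5, "1RD"), outflow(6, "2RD")]
    ts += catalysis(7, "A", "1RL", "2RL", p.ka, p.k_minus_a)
    ts += catalysis(9, "A", "2RL", "1RL", p.kb, p.k_minus_b)
    ts += [outflow(11, "1RL"), outflow(12, "2RL")]
    ts += [
        Transformation(13, INFLOW, {}, {"A": +1}, f * p.A_in),
        Transformation(14, OUTFLOW, {"A": 1}, {"A": -1}, f),
    ]
    return ReactionNetwork(species, tuple(ts))


def remove_enantiomer_outflows(network: ReactionNetwork) -> ReactionNetwork:
    """Variant in which only the achiral flow species enter and leave.

    Drops every outflow of a chiral species (transformations 5, 6, 11, 12 of
    the fixture), keeping the original indices of the survivors.  Idempotent.
    """
    keep = tuple(
        t for t in network.transformations
        if not (t.kind == OUTFLOW
                and network.species.chiral_partner[next(iter(t.reactant_stoich))]
                != next(iter(t.reactant_stoich)))
    )
    return ReactionNetwork(network.species, keep)


# ---------------------------------------------------------------------------
# Plain-text network format
# ---------------------------------------------------------------------------
#
#   # comment
#   species: A 2RD 1RD 1RL 2RL
#   chiral: 2RD=2RL 1RD=1RL
#   1; reaction_forward; A + 1RD + 2RD -> 2 1RD + 2RD; k=10000.0; reverse=2
#   13; inflow; -> A; k=2e-11
#   14; outflow; A -> ; k=2e-07
#
# Rate constants are written with repr() so a write→read round trip is
# bit-exact.

def write_network(network: ReactionNetwork, path) -> None:
    lines = ["# efmentropy network file"]
    lines.append("species: " + " ".join(network.species.labels))
    pairs = sorted(
        {tuple(sorted((a, b))) for a, b in network.species.chiral_partner.items() if a != b}
    )
    if pairs:
        lines.append("chiral: " + " ".join(f"{a}={b}" for a, b in pairs))
    for t in network.transformations:
        products = dict(t.reactant_stoich)
        for s, n in t.net_stoich.items():
            products[s] = products.get(s, 0) + n
        lhs = _side_str(t.reactant_stoich, network)
        rhs = _side_str(products, network)
        fields = [str(t.index), t.kind, f"{lhs} -> {rhs}", f"k={t.rate_constant!r}"]
        if t.reverse_partner is not None:
            fields.append(f"reverse={t.reverse_partner}")
        lines.append("; ".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _side_str(stoich: Mapping[str, int], network: ReactionNetwork) -> str:
    parts = []
    for s in network.species.labels:
        n = stoich.get(s, 0)
        if n == 0:
            continue
        parts.append(s if n == 1 else f"{n} {s}")
    return " + ".join(parts)


def _parse_side(text: str, labels, lineno: int) -> dict[str, int]:
    stoich: dict[str, int] = {}
    text = text.strip()
    if not text:
        return stoich
    for term in text.split("+"):
        toks = term.split()
        if len(toks) == 1:
            n, sp = 1, toks[0]
        elif len(toks) == 2:
            try:
                n = int(toks[0])
            except ValueError:
                raise ParseError(f"line {lineno}: bad stoichiometric count {toks[0]!r}")
            sp = toks[1]
        else:
            raise ParseError(f"line {lineno}: cannot parse term {term.strip()!r}")
        if sp not in labels:
            raise ParseError(f"line {lineno}: unknown species {sp!r}")
        stoich[sp] = stoich.get(sp, 0) + n
    return stoich


def read_network(path) -> ReactionNetwork:
    labels: tuple[str, ...] | None = None
    chiral: dict[str, str] = {}
    transformations: list[Transformation] = []
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("species:"):
                labels = tuple(line.split(":", 1)[1].split())
                continue
            if line.startswith("chiral:"):
                for pair in line.split(":", 1)[1].split():
                    a, _, b = pair.partition("=")
                    chiral[a] = b
                    chiral[b] = a
                continue
            if labels is None:
                raise ParseError(f"line {lineno}: species header must precede transformations")
            fields = [f.strip() for f in line.split(";")]
            if len(fields) < 4:
                raise ParseError(f"line {lineno}: expected 'index; kind; scheme; k=...'")
            try:
                index = int(fields[0])
            except ValueError:
                raise ParseError(f"line {lineno}: bad index {fields[0]!r}")
            if index in seen:
                raise ParseError(f"line {lineno}: duplicate index {index}")
            seen.add(index)
            kind = fields[1]
            if kind not in KINDS:
                raise ParseError(f"line {lineno}: unknown kind {kind!r}")
            if "->" not in fields[2]:
                raise ParseError(f"line {lineno}: scheme must contain '->'")
            lhs_s, rhs_s = fields[2].split("->", 1)
            lhs = _parse_side(lhs_s, labels, lineno)
            rhs = _parse_side(rhs_s, labels, lineno)
            kv: dict[str, str] = {}
            for extra in fields[3:]:
                key, _, val = extra.partition("=")
                kv[key.strip()] = val.strip()
            if "k" not in kv:
                raise ParseError(f"line {lineno}: missing rate constant k=")
            try:
                k = float(kv["k"])
            except ValueError:
                raise ParseError(f"line {lineno}: bad rate constant {kv['k']!r}")
            reverse = int(kv["reverse"]) if "reverse" in kv else None
            net = {s: rhs.get(s, 0) - lhs.get(s, 0)
                   for s in set(lhs) | set(rhs)}
            try:
                transformations.append(
                    Transformation(index, kind, lhs, net, k, reverse_partner=reverse)
                )
            except NetworkError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    if labels is None or not transformations:
        raise ParseError("no transformations")
    return ReactionNetwork(SpeciesSet(labels, chiral), tuple(transformations))
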