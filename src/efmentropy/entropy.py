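"""Entropy production, exchange and per-pathway partition.

For unidirectional mass-action rate pairs (v_f, v_r) the volumetric entropy
production is

    σ = R Σ_pairs (v_f − v_r) ln(v_f / v_r)  ≥ 0,

each pair contributing nonnegatively.  The open flow exchanges entropy with
the environment at

    σ_e = R Σ_flow_species f (c_in − c) ln(c / c_eq),

where c_eq is the detailed-balance equilibrium the reactor contents would
relax to if isolated from the flow while keeping their chemical mass.
Every transformation also carries a *partial* entropy (forward catalysis
R·v_f·ln(v_f/v_r), reverse R·v_r·ln(v_r/v_f), inflow R·f·c_in·ln(c_eq/c),
outflow R·f·c·ln(c/c_eq)), and distributing these over the extreme flux
modes — dividing the partial entropy of a transformation by the number of
modes whose support contains it — yields per-pathway entropies σ(Eᵢ) with
the exact balance

    Σᵢ σ(Eᵢ) = σ − σ_e = dS/dt,

which vanishes at any stationary state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .efm import FluxMode, SteadyDecomposition, efm_matrix
from .network import (
    INFLOW,
    OUTFLOW,
    REACTION_FORWARD,
    REACTION_REVERSE,
    NetworkError,
    ReactionNetwork,
    _conc_array,
    conserved_moieties,
    rate_vector,
)

logger = logging.getLogger("efmentropy")

#: Ideal gas constant (J K⁻¹ mol⁻¹); σ is reported per unit volume,
#: J K⁻¹ s⁻¹ L⁻¹, since concentrations are mol/L and rates mol/(L·s).
R_GAS = 8.314

#: Floor applied *inside logarithms only*; rates/concentrations themselves
#: are never clipped.
LOG_FLOOR = 1e-300

_guard_count = {"log_floor": 0}


def _xlogratio(x: float, num: float, den: float) -> float:
    """x·ln(num/den) with the conventions x=0 → 0 and num=den → 0."""
    if x == 0.0 or num == den:
        return 0.0
    if num < LOG_FLOOR or den < LOG_FLOOR:
        _guard_count["log_floor"] += 1
        num = max(num, LOG_FLOOR)
        den = max(den, LOG_FLOOR)
        if num == den:
            return 0.0
    return x * math.log(num / den)


def guard_counts() -> dict[str, int]:
    """Counts of logarithm-floor activations since import (diagnostic)."""
    return dict(_guard_count)


# ---------------------------------------------------------------------------
# Equilibrium reference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumReference:
    """Closed-system detailed-balance equilibrium of a given composition.

    ``c_eq`` is in species order; ``total_mass`` is the conserved
    moiety total (A-equivalents for the hypercycle, where every species
    counts once).  The equilibrium depends on the composition only through
    that total, so a fully chiral input has the same (racemic) reference as
    a racemic one of equal mass.
    """

    c_eq: np.ndarray
    total_mass: float
    moiety: tuple[float, ...]

    def of(self, species: str, network: ReactionNetwork) -> float:
        return float(self.c_eq[network.species.index(species)])


def equilibrium_reference(
    network: ReactionNetwork, composition: Mapping[str, float] | Sequence[float]
) -> EquilibriumReference:
    """Solve detailed balance + mass conservation for the isolated reactor.

    Detailed balance makes every forward rate equal its reverse, which is a
    *linear* system in log-concentrations; the one-parameter solution family
    is then pinned by the conserved chemical mass of ``composition``.
    Requires every reversible pair to have a nonzero reverse constant and
    the chemistry to conserve a single positive moiety.
    """
    c0 = _conc_array(network, composition)
    if np.any(c0 < 0) or c0.sum() <= 0:
        raise NetworkError("composition must be nonnegative with positive mass")

    moieties = conserved_moieties(network)
    if len(moieties) != 1:
        raise NetworkError(
            f"expected a single conserved moiety, found {len(moieties)}"
        )
    m = np.array([float(x) for x in moieties[0]])
    if np.any(m <= 0):
        m = -m
    if np.any(m <= 0):
        raise NetworkError("conserved moiety is not sign-definite")
    total = float(m @ c0)

    # detailed balance: (α_r − α_f) · ln c = ln(k_f / k_r) for each pair
    ns = network.n_species
    rows, rhs = [], []
    for fi, ri in network.reversible_pairs():
        tf, tr = network.by_index(fi), network.by_index(ri)
        if tr.rate_constant == 0 or tf.rate_constant == 0:
            raise NetworkError(
                f"pair ({fi},{ri}) has a vanishing rate constant: no finite equilibrium"
            )
        row = np.zeros(ns)
        for s, a in tr.reactant_stoich.items():
            row[network.species.index(s)] += a
        for s, a in tf.reactant_stoich.items():
            row[network.species.index(s)] -= a
        rows.append(row)
        rhs.append(math.log(tf.rate_constant / tr.rate_constant))
    A = np.array(rows)
    b = np.array(rhs)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    if not np.allclose(A @ sol, b, atol=1e-10):
        raise NetworkError("detailed-balance conditions are inconsistent")
    null = _nullspace(A)
    if null.shape[1] != 1:
        raise NetworkError(
            "equilibrium family is not one-dimensional; cannot pin by mass alone"
        )
    u = null[:, 0]

    def mass(t: float) -> float:
        return float(m @ np.exp(sol + t * u)) - total

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if mass(lo) * mass(hi) <= 0:
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise NetworkError("failed to bracket the equilibrium mass equation")
    t = brentq(mass, lo, hi, xtol=1e-15, rtol=8.9e-16)
    c_eq = np.exp(sol + t * u)
    return EquilibriumReference(c_eq=c_eq, total_mass=total, moiety=tuple(m))


def _nullspace(A: np.ndarray) -> np.ndarray:
    _, s, vh = np.linalg.svd(A)
    tol = max(A.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    rank = int((s > tol).sum())
    return vh[rank:].T


# ---------------------------------------------------------------------------
# Production and exchange
# ---------------------------------------------------------------------------

def entropy_production(
    network: ReactionNetwork,
    conc: Mapping[str, float] | Sequence[float],
    gas_constant: float = R_GAS,
) -> float:
    """σ = R Σ (v_f − v_r) ln(v_f/v_r) over reversible pairs; ≥ 0."""
    v = rate_vector(network, conc)
    col = {i: j for j, i in enumerate(network.indices)}
    total = 0.0
    for fi, ri in network.reversible_pairs():
        vf, vr = v[col[fi]], v[col[ri]]
        total += _xlogratio(vf - vr, vf, vr)
    return gas_constant * total


def ness_entropy_from_j(
    decomp: SteadyDecomposition | Sequence[float],
    modes: Sequence[FluxMode],
    network: ReactionNetwork,
    gas_constant: float = R_GAS,
) -> float:
    """Stationary entropy production from the pathway currents alone.

    At a stationary state v = Σ jᵢEᵢ, so each pair's forward (reverse) rate
    is the sum of the currents through the modes whose support contains the
    forward (reverse) column.  On the hypercycle this reduces to the
    four-term form driven solely by the open unidirectional modes, and is
    independent of the unreactive flow-through current.  A pair with zero
    reverse sum but positive forward sum has infinite affinity; math.inf is
    returned and logged in that case.
    """
    j = decomp.j if isinstance(decomp, SteadyDecomposition) else np.asarray(decomp, float)
    if np.any(np.asarray(j) < 0):
        raise ValueError("pathway currents must be nonnegative")
    total = 0.0
    for fi, ri in network.reversible_pairs():
        vf = sum(ji for ji, m in zip(j, modes) if fi in m.support)
        vr = sum(ji for ji, m in zip(j, modes) if ri in m.support)
        if (vf > 0 and vr == 0) or (vr > 0 and vf == 0):
            logger.warning("pair (%d,%d): one-sided current, infinite affinity", fi, ri)
            return math.inf
        total += _xlogratio(vf - vr, vf, vr)
    return gas_constant * total


def exchange_entropy(
    network: ReactionNetwork,
    conc: Mapping[str, float] | Sequence[float],
    ref: EquilibriumReference,
    gas_constant: float = R_GAS,
) -> float:
    """σ_e = R Σ f (c_in − c) ln(c/c_eq) over flow-carried species."""
    c = _conc_array(network, conc)
    total = 0.0
    for sp, (f, c_in) in network.flow_species().items():
        i = network.species.index(sp)
        total += f * _xlogratio(c_in - c[i], c[i], ref.c_eq[i])
    return gas_constant * total


# ---------------------------------------------------------------------------
# Partial entropies
# ---------------------------------------------------------------------------

def partial_entropy_transformation(
    network: ReactionNetwork,
    conc: Mapping[str, float] | Sequence[float],
    ref: EquilibriumReference,
    j_index: int,
    gas_constant: float = R_GAS,
) -> float:
    """Partial entropy of one transformation, by kind.

    forward: R·v_f·ln(v_f/v_r);  reverse: R·v_r·ln(v_r/v_f);
    inflow of X: R·f·c_in·ln(c_eq/c);  outflow of Y: R·f·c·ln(c/c_eq).
    The forward and reverse halves of a pair sum to that pair's production
    term, and the flow partials over all species sum to −σ_e.
    """
    t = network.by_index(j_index)
    c = _conc_array(network, conc)
    v = rate_vector(network, conc)
    col = {i: j for j, i in enumerate(network.indices)}
    if t.kind in (REACTION_FORWARD, REACTION_REVERSE):
        vj = v[col[j_index]]
        vp = v[col[t.reverse_partner]]
        return gas_constant * _xlogratio(vj, vj, vp)
    if t.kind == INFLOW:
        sp = next(iter(t.net_stoich))
        i = network.species.index(sp)
        return gas_constant * _xlogratio(t.rate_constant, ref.c_eq[i], c[i])
    if t.kind == OUTFLOW:
        sp = next(iter(t.reactant_stoich))
        i = network.species.index(sp)
        f = t.rate_constant
        return gas_constant * _xlogratio(f * c[i], c[i], ref.c_eq[i])
    raise NetworkError(f"unknown transformation kind {t.kind!r}")


def efm_weights(modes: Sequence[FluxMode], network: ReactionNetwork) -> dict[int, Fraction]:
    """weight(t) = 1 / (number of modes whose support contains t).

    Transformations on no pathway get weight 0.  Summing weight(t) over the
    modes containing t gives 1 for every covered transformation, which is
    what makes the pathway partition an exact resolution of σ − σ_e.
    """
    counts = {i: 0 for i in network.indices}
    for m in modes:
        for i in m.support:
            counts[i] += 1
    return {
        i: (Fraction(1, n) if n else Fraction(0)) for i, n in counts.items()
    }


def partial_entropy_efm(
    network: ReactionNetwork,
    conc: Mapping[str, float] | Sequence[float],
    ref: EquilibriumReference,
    modes: Sequence[FluxMode],
    gas_constant: float = R_GAS,
) -> tuple[np.ndarray, dict[int, Fraction]]:
    """σ(Eᵢ) for every mode, plus the stoichiometric weights.

    σ(Eᵢ) = Σ_{t ∈ support(Eᵢ)} weight(t) · σ(t).  Individual values may
    have either sign; only their sum is constrained (= σ − σ_e).
    """
    for m in modes:
        if not m.support <= set(network.indices):
            raise NetworkError("modes do not belong to this network")
    w = efm_weights(modes, network)
    partial = {
        i: partial_entropy_transformation(network, conc, ref, i, gas_constant)
        for i in network.indices
    }
    sigma_efm = np.array([
        sum(float(w[i]) * partial[i] for i in m.support) for m in modes
    ])
    return sigma_efm, w


# ---------------------------------------------------------------------------
# Ledger
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntropyLedger:
    """All entropy quantities of one state."""

    gas_constant: float
    sigma: float
    sigma_e: float
    per_transformation: dict[int, float]
    per_efm: np.ndarray
    weights: dict[int, Fraction]
    balance_residual: float
    j: SteadyDecomposition | None = None


def make_ledger(
    network: ReactionNetwork,
    conc: Mapping[str, float] | Sequence[float],
    ref: EquilibriumReference,
    modes: Sequence[FluxMode],
    gas_constant: float = R_GAS,
    j: SteadyDecomposition | None = None,
) -> EntropyLedger:
    sigma = entropy_production(network, conc, gas_constant)
    sigma_e = exchange_entropy(network, conc, ref, gas_constant)
    per_t = {
        i: partial_entropy_transformation(network, conc, ref, i, gas_constant)
        for i in network.indices
    }
    weights = efm_weights(modes, network)
    per_efm = np.array([
        sum(float(weights[i]) * per_t[i] for i in m.support) for m in modes
    ])
    residual = float(per_efm.sum() - (sigma - sigma_e))
    return EntropyLedger(
        gas_constant=gas_constant,
        sigma=sigma,
        sigma_e=sigma_e,
        per_transformation=per_t,
        per_efm=per_efm,
        weights=weights,
        balance_residual=residual,
        j=j,
    )


def balance_check(ledger: EntropyLedger) -> float:
    """Σσ(Eᵢ) − (σ − σ_e); an identity (≈ rounding) whenever every
    transformation lies on at least one pathway."""
    return ledger.balance_residual


def ledger_series(
    network: ReactionNetwork,
    times: Sequence[float],
    concentrations: np.ndarray,
    modes: Sequence[FluxMode],
    ref: EquilibriumReference,
    gas_constant: float = R_GAS,
) -> pd.DataFrame:
    """Entropy bookkeeping along a trajectory (rows: time points).

    Columns: time, sigma, sigma_e, sigma_M1..sigma_Mn, sum_efm,
    balance_residual — the data behind the production/partition figures.
    """
    rows = []
    for t, c in zip(times, np.asarray(concentrations, dtype=float)):
        led = make_ledger(network, c, ref, modes, gas_constant)
        row = {"time": t, "sigma": led.sigma, "sigma_e": led.sigma_e}
        for k, val in enumerate(led.per_efm):
            row[f"sigma_M{k+1}"] = val
        row["sum_efm"] = float(led.per_efm.sum())
        row["balance_residual"] = led.balance_residual
        rows.append(row)
    return pd.DataFrame(rows)
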