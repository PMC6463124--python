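"""Stiff integration of the open-flow mass-action kinetics.

The hard numerical requirement is carrying a chiral seed of δ ≈ 1e-23 mol/L
against racemic concentrations ≈ 1e-6 mol/L: the relative perturbation
(~5e-18) is below double precision if the enantiomer concentrations are
integrated directly.  The default solver therefore integrates the chiral
sum/difference coordinates

    s = [XL] + [XD],   χ = [XL] − [XD]

whose right-hand sides are expanded so the χ-equations contain no
catastrophic cancellation (they are built from products of sums and
differences, never from differences of near-equal monomials).  A raw
per-species mode exists for cross-checking at larger seeds and for
arbitrary networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .entropy import R_GAS, _xlogratio
from .network import (
    HYPERCYCLE_SPECIES,
    INFLOW,
    OUTFLOW,
    HypercycleParams,
    NetworkError,
    ReactionNetwork,
    rate_vector,
    stoichiometric_matrix,
)

logger = logging.getLogger("efmentropy")


class IntegrationError(RuntimeError):
    """Solver failure or inadmissible state; carries the failing time."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message if time is None else f"{message} (t={time:g} s)")
        self.time = time


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced output grid: t_min to t_end, plus the t=0 sample."""

    t_min: float = 1e-2
    points_per_decade: int = 400

    def times(self, t_end: float) -> np.ndarray:
        if t_end <= self.t_min:
            return np.linspace(0.0, t_end, 50)
        decades = math.log10(t_end / self.t_min)
        n = max(int(round(decades * self.points_per_decade)) + 1, 10)
        return np.concatenate([[0.0], np.logspace(math.log10(self.t_min),
                                                  math.log10(t_end), n)])


@dataclass
class Trajectory:
    """Time-gridded solution: concentrations, rates, enantiomeric excesses."""

    times: np.ndarray
    concentrations: np.ndarray   # (n_times, n_species), species order
    rates: np.ndarray            # (n_times, n_transformations)
    ee: np.ndarray               # (n_times, 2): replicators 1 and 2, signed %
    network: ReactionNetwork
    snapped_negative: int = 0    # concentrations in [-atol, 0) snapped to 0

    @property
    def final_concentrations(self) -> np.ndarray:
        return self.concentrations[-1]


@dataclass(frozen=True)
class NessState:
    """A (numerically) stationary composition and its fluxes."""

    concentrations: np.ndarray
    rates: np.ndarray
    rhs_norm: float
    time: float
    metastable_windows: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class EventTimes:
    """Landmarks of a run; absent events are None, never exceptions."""

    sigma_peak_time: float | None
    smsb_time: float | None
    plateau_window: tuple[float, float] | None


# ---------------------------------------------------------------------------
# Hypercycle structure extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _HypercycleModel:
    ka: float
    k_minus_a: float
    kb: float
    k_minus_b: float
    inflow: float      # constant rate f·A_in
    f_A: float         # outflow rate constant of A
    f_repl: float      # outflow rate constant of the replicators (0 if closed to them)


def _as_hypercycle(network: ReactionNetwork) -> _HypercycleModel | None:
    """Recognize the (possibly no-enantiomer-outflow) hypercycle topology."""
    if network.species.labels != HYPERCYCLE_SPECIES:
        return None
    idx = set(network.indices)
    if not {1, 2, 3, 4, 7, 8, 9, 10, 13, 14} <= idx:
        return None
    if idx - {1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14}:
        return None
    has_out = {5, 6, 11, 12} <= idx
    if not has_out and idx & {5, 6, 11, 12}:
        return None
    g = network.by_index
    # chirality constraint: mirror steps share rate constants
    if (g(1).rate_constant != g(7).rate_constant
            or g(2).rate_constant != g(8).rate_constant
            or g(3).rate_constant != g(9).rate_constant
            or g(4).rate_constant != g(10).rate_constant):
        return None
    return _HypercycleModel(
        ka=g(1).rate_constant,
        k_minus_a=g(2).rate_constant,
        kb=g(3).rate_constant,
        k_minus_b=g(4).rate_constant,
        inflow=g(13).rate_constant,
        f_A=g(14).rate_constant,
        f_repl=g(5).rate_constant if has_out else 0.0,
    )


def _sumdiff_rhs(model: _HypercycleModel):
    ka, kma = model.ka, model.k_minus_a
    kb, kmb = model.kb, model.k_minus_b
    r, fA, fr = model.inflow, model.f_A, model.f_repl

    def rhs(t, y):
        A, s1, x1, s2, x2 = y
        P = (s1 * s2 + x1 * x2) / 2.0          # L1L2 + D1D2
        Q = (s1 * x2 + s2 * x1) / 2.0          # L1L2 − D1D2
        Ra = (s1 * s1 * s2 + 2 * s1 * x1 * x2 + x1 * x1 * s2) / 4.0
        Sa = (s1 * s1 * x2 + 2 * s1 * s2 * x1 + x1 * x1 * x2) / 4.0
        Rb = (s2 * s2 * s1 + 2 * s2 * x1 * x2 + x2 * x2 * s1) / 4.0
        Sb = (s2 * s2 * x1 + 2 * s1 * s2 * x2 + x2 * x2 * x1) / 4.0
        return np.array([
            -(ka + kb) * A * P + kma * Ra + kmb * Rb + r - fA * A,
            ka * A * P - kma * Ra - fr * s1,
            ka * A * Q - kma * Sa - fr * x1,
            kb * A * P - kmb * Rb - fr * s2,
            kb * A * Q - kmb * Sb - fr * x2,
        ])

    def jac(t, y):
        A, s1, x1, s2, x2 = y
        P = (s1 * s2 + x1 * x2) / 2.0
        Q = (s1 * x2 + s2 * x1) / 2.0
        Ra = (s1 * s1 * s2 + 2 * s1 * x1 * x2 + x1 * x1 * s2) / 4.0
        Sa = (s1 * s1 * x2 + 2 * s1 * s2 * x1 + x1 * x1 * x2) / 4.0
        Rb = (s2 * s2 * s1 + 2 * s2 * x1 * x2 + x2 * x2 * s1) / 4.0
        Sb = (s2 * s2 * x1 + 2 * s1 * s2 * x2 + x2 * x2 * x1) / 4.0
        dP = np.array([0.0, s2 / 2, x2 / 2, s1 / 2, x1 / 2])
        dQ = np.array([0.0, x2 / 2, s2 / 2, x1 / 2, s1 / 2])
        dRa = np.array([0.0, P, Q, (s1 * s1 + x1 * x1) / 4, s1 * x1 / 2])
        dSa = np.array([0.0, Q, P, s1 * x1 / 2, (s1 * s1 + x1 * x1) / 4])
        dRb = np.array([0.0, (s2 * s2 + x2 * x2) / 4, s2 * x2 / 2, P, Q])
        dSb = np.array([0.0, s2 * x2 / 2, (s2 * s2 + x2 * x2) / 4, Q, P])
        eA = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        J = np.empty((5, 5))
        J[0] = -(ka + kb) * (P * eA + A * dP) + kma * dRa + kmb * dRb - fA * eA
        J[1] = ka * (P * eA + A * dP) - kma * dRa
        J[1, 1] -= fr
        J[2] = ka * (Q * eA + A * dQ) - kma * dSa
        J[2, 2] -= fr
        J[3] = kb * (P * eA + A * dP) - kmb * dRb
        J[3, 3] -= fr
        J[4] = kb * (Q * eA + A * dQ) - kmb * dSb
        J[4, 4] -= fr
        return J

    return rhs, jac


def mass_action_rhs(network: ReactionNetwork):
    """Generic d[X]/dt = ν·v([X]) (raw coordinates), with ν fixed."""
    nu = stoichiometric_matrix(network).astype(float)

    def rhs(t, y):
        c = np.maximum(y, 0.0)
        return nu @ rate_vector(network, c)

    return rhs


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(
    network: ReactionNetwork,
    params: HypercycleParams,
    t_end: float = 1e9,
    grid: GridSpec | None = None,
    *,
    conc0: Mapping[str, float] | None = None,
    chi0: tuple[float, float] | None = None,
    coords: str = "auto",
    rtol: float = 1e-10,
    atol_conc: float = 1e-16,
    atol_chi: float = 1e-30,
    method: str = "Radau",
) -> Trajectory:
    """Integrate the network to ``t_end`` from the reference initial state.

    ``coords='sum_diff'`` (default for the hypercycle topology) integrates
    chiral sum/difference variables; ``'raw'`` integrates the species
    concentrations directly.  ``conc0`` overrides the initial composition
    built from ``params``.

    A chiral seed far below the racemic concentrations cannot survive being
    expressed as L and D concentrations (c0 + δ rounds to c0 in double
    precision once δ/c0 < 1e-16), so in sum/difference mode the initial
    differences are set exactly: by default χ = (0, δ) from ``params``, or
    explicitly via ``chi0`` = (χ1, χ2) when ``conc0`` is overridden.
    """
    if t_end <= 0:
        raise IntegrationError("t_end must be positive")
    grid = grid or GridSpec()
    t_eval = grid.times(t_end)
    c0_map = dict(params.initial_concentrations())
    if conc0 is not None:
        c0_map.update(conc0)

    model = _as_hypercycle(network)
    if coords == "auto":
        coords = "sum_diff" if model is not None else "raw"
    if coords == "sum_diff":
        if model is None:
            raise NetworkError("sum/difference coordinates need the hypercycle topology")
        if chi0 is None:
            if conc0 is None:
                chi0 = (0.0, params.delta)
            else:
                chi0 = (c0_map["1RL"] - c0_map["1RD"], c0_map["2RL"] - c0_map["2RD"])
        traj = _simulate_sumdiff(network, model, c0_map, chi0, t_eval,
                                 rtol, atol_conc, atol_chi, method)
    elif coords == "raw":
        traj = _simulate_raw(network, c0_map, t_eval, rtol, atol_conc, method)
    else:
        raise ValueError(f"unknown coordinate mode {coords!r}")
    return traj


def _solve(rhs, jac, y0, t_eval, rtol, atol, method):
    sol = solve_ivp(
        rhs, (t_eval[0], t_eval[-1]), y0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol, jac=jac,
    )
    if not sol.success:
        raise IntegrationError(f"stiff integration failed: {sol.message}",
                               time=float(sol.t[-1]) if sol.t.size else None)
    return sol


def _finalize(network, times, conc, atol_conc, ee=None) -> Trajectory:
    worst = conc.min()
    if worst < -atol_conc:
        i, j = np.unravel_index(conc.argmin(), conc.shape)
        raise IntegrationError(
            f"negative concentration {worst:g} in {network.species.labels[j]}",
            time=float(times[i]),
        )
    snapped = int(((conc < 0).sum()))
    if snapped:
        logger.info("snapped %d tiny negative concentrations to 0", snapped)
    conc = np.maximum(conc, 0.0)
    rates = np.array([rate_vector(network, c) for c in conc])
    if ee is None:
        iD1 = network.species.index("1RD")
        iL1 = network.species.index("1RL")
        iD2 = network.species.index("2RD")
        iL2 = network.species.index("2RL")
        ee = np.stack([
            _ee_series(conc[:, iL1], conc[:, iD1]),
            _ee_series(conc[:, iL2], conc[:, iD2]),
        ], axis=1)
    return Trajectory(times=times, concentrations=conc, rates=rates, ee=ee,
                      network=network, snapped_negative=snapped)


def _ee_series(L: np.ndarray, D: np.ndarray) -> np.ndarray:
    tot = L + D
    with np.errstate(invalid="ignore", divide="ignore"):
        ee = np.where(tot > 0, 100.0 * (L - D) / np.where(tot > 0, tot, 1.0), 0.0)
    return np.clip(ee, -100.0, 100.0)


def _simulate_sumdiff(network, model, c0_map, chi0, t_eval, rtol, atol_conc,
                      atol_chi, method):
    y0 = np.array([
        c0_map["A"],
        c0_map["1RL"] + c0_map["1RD"],
        chi0[0],
        c0_map["2RL"] + c0_map["2RD"],
        chi0[1],
    ])
    rhs, jac = _sumdiff_rhs(model)
    atol = np.array([atol_conc, atol_conc, atol_chi, atol_conc, atol_chi])
    sol = _solve(rhs, jac, y0, t_eval, rtol, atol, method)
    A, s1, x1, s2, x2 = sol.y
    # species order (A, 2RD, 1RD, 1RL, 2RL)
    conc = np.stack([
        A, (s2 - x2) / 2.0, (s1 - x1) / 2.0, (s1 + x1) / 2.0, (s2 + x2) / 2.0,
    ], axis=1)
    # ee straight from the sum/difference state; the reconstructed L and D
    # concentrations cannot resolve |χ|/s below machine epsilon
    with np.errstate(invalid="ignore", divide="ignore"):
        ee = np.stack([
            np.where(s1 > 0, 100.0 * x1 / np.where(s1 > 0, s1, 1.0), 0.0),
            np.where(s2 > 0, 100.0 * x2 / np.where(s2 > 0, s2, 1.0), 0.0),
        ], axis=1)
    ee = np.clip(ee, -100.0, 100.0)
    return _finalize(network, sol.t, conc, atol_conc, ee=ee)


def _simulate_raw(network, c0_map, t_eval, rtol, atol_conc, method):
    y0 = np.array([c0_map[s] for s in network.species.labels])
    rhs = mass_action_rhs(network)
    sol = _solve(rhs, None, y0, t_eval, rtol, atol_conc, method)
    return _finalize(network, sol.t, sol.y.T, atol_conc)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def enantiomeric_excess(traj: Trajectory, replicator_id: int) -> np.ndarray:
    """Signed percent excess ee = 100·(L − D)/(L + D); 0/0 ≡ 0."""
    if replicator_id not in (1, 2):
        raise ValueError("replicator_id must be 1 or 2")
    return traj.ee[:, replicator_id - 1]


def rhs_norm_series(traj: Trajectory) -> np.ndarray:
    """max_i |(ν·v)_i| at every stored time (stationarity measure)."""
    nu = stoichiometric_matrix(traj.network).astype(float)
    return np.abs(traj.rates @ nu.T).max(axis=1)


def detect_ness(
    traj: Trajectory,
    network: ReactionNetwork | None = None,
    tol: float | None = None,
    refine: bool = True,
) -> NessState:
    """Last state whose right-hand side falls below ``tol``; optionally
    Newton-polished to the exact stationary point.

    ``tol`` defaults to 1e-7 of the peak |ν·v| along the run.  Earlier
    sub-``tol`` stretches separated from the final one (the metastable
    racemic plateau) are reported as ``metastable_windows``.
    """
    network = network or traj.network
    norms = rhs_norm_series(traj)
    peak = float(norms.max())
    if tol is None:
        tol = 1e-7 * peak if peak > 0 else math.inf
    below = norms <= tol
    if not below.any():
        raise IntegrationError("no stationary state in window: "
                               f"min |ν·v| = {norms.min():g} > tol = {tol:g}")
    i_last = int(np.nonzero(below)[0][-1])
    # contiguous sub-tol stretches; all but the final one are metastable
    windows = []
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b and start is not None:
            windows.append((start, i - 1))
            start = None
    if start is not None:
        windows.append((start, len(below) - 1))
    metastable = tuple(
        (float(traj.times[a]), float(traj.times[b]))
        for a, b in windows if b < i_last and traj.times[a] > 0
    )

    conc = traj.concentrations[i_last].copy()
    nu = stoichiometric_matrix(network).astype(float)

    def g(c):
        return nu @ rate_vector(network, np.maximum(c, 0.0))

    if refine:
        sol = root(g, conc, method="hybr", tol=1e-14)
        cand = np.maximum(sol.x, 0.0)
        if sol.success and np.abs(g(cand)).max() <= np.abs(g(conc)).max():
            conc = cand
    rates = rate_vector(network, conc)
    return NessState(
        concentrations=conc,
        rates=rates,
        rhs_norm=float(np.abs(nu @ rates).max()),
        time=float(traj.times[i_last]),
        metastable_windows=metastable,
    )


def sigma_series(traj: Trajectory, gas_constant: float = R_GAS) -> np.ndarray:
    """Entropy production σ(t) along the trajectory, from the stored rates."""
    col = {i: j for j, i in enumerate(traj.network.indices)}
    out = np.empty(len(traj.times))
    pairs = traj.network.reversible_pairs()
    for n, v in enumerate(traj.rates):
        out[n] = gas_constant * sum(
            _xlogratio(v[col[f]] - v[col[r]], v[col[f]], v[col[r]]) for f, r in pairs
        )
    return out


def event_times(
    traj: Trajectory,
    *,
    ee_threshold: float = 50.0,
    plateau_rel: float = 0.01,
    gas_constant: float = R_GAS,
) -> EventTimes:
    """Landmark times: first σ peak, mirror-symmetry-breaking crossing of the
    replicator-1 excess through ``ee_threshold`` %, and the metastable
    plateau of nearly-constant σ between peak and symmetry breaking."""
    sigma = sigma_series(traj, gas_constant)
    t = traj.times

    peak_time = None
    if sigma.max() > 0:
        peaks, _ = find_peaks(sigma, prominence=0.1 * sigma.max())
        if peaks.size:
            peak_time = float(t[peaks[0]])
        elif sigma.argmax() not in (0, len(sigma) - 1):
            peak_time = float(t[sigma.argmax()])

    smsb_time = None
    ae = np.abs(traj.ee[:, 0])
    above = np.nonzero(ae >= ee_threshold)[0]
    if above.size and above[0] > 0:
        i = above[0]
        # interpolate the crossing in log-time
        t0, t1 = t[i - 1], t[i]
        e0, e1 = ae[i - 1], ae[i]
        if t0 > 0 and e1 > e0:
            frac = (ee_threshold - e0) / (e1 - e0)
            smsb_time = float(10 ** (math.log10(t0)
                                     + frac * (math.log10(t1) - math.log10(t0))))
        else:
            smsb_time = float(t1)
    elif above.size:
        smsb_time = float(t[above[0]])

    plateau = None
    if peak_time is not None:
        lo = np.searchsorted(t, peak_time)
        hi = np.searchsorted(t, smsb_time) if smsb_time is not None else len(t)
        seg = sigma[lo:hi]
        if seg.size > 2:
            # longest window with max/min ratio ≤ 1+plateau_rel (two pointers
            # with monotonic deques for the sliding max and min)
            from collections import deque

            best = (0, 0)
            i = 0
            maxq: deque[int] = deque()
            minq: deque[int] = deque()
            for jx in range(seg.size):
                while maxq and seg[maxq[-1]] <= seg[jx]:
                    maxq.pop()
                maxq.append(jx)
                while minq and seg[minq[-1]] >= seg[jx]:
                    minq.pop()
                minq.append(jx)
                while seg[maxq[0]] > (1 + plateau_rel) * seg[minq[0]]:
                    i += 1
                    if maxq[0] < i:
                        maxq.popleft()
                    if minq[0] < i:
                        minq.popleft()
                if jx - i > best[1] - best[0]:
                    best = (i, jx)
            a, b = best
            if t[lo + b] > 1.5 * t[lo + a]:  # require a nontrivial span
                plateau = (float(t[lo + a]), float(t[lo + b]))
    return EventTimes(sigma_peak_time=peak_time, smsb_time=smsb_time,
                      plateau_window=plateau)
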