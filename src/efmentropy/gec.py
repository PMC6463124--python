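"""Chemical forces, flows, and the General Evolution Criterion (GEC).

Each reversible pair k carries a thermodynamic force (its affinity over
temperature) and a flow (its net rate):

    F_k = A_k/T = R ln(v_k,f / v_k,r),      J_k = v_k,f − v_k,r,

so that σ = Σ_k F_k J_k, each summand nonnegative.  Splitting the time
derivative of σ into the force-driven and flow-driven parts,

    dσ/dt = dFσ/dt + dJσ/dt,
    dFσ/dt = Σ_k (dF_k/dt) J_k,   dJσ/dt = Σ_k F_k (dJ_k/dt),

the GEC of nonlinear non-equilibrium thermodynamics states dFσ/dt ≤ 0,
with equality at stationary states.  In an open-flow reactor the matter
fluxes enter the force derivatives implicitly through d[X]/dt = ν·v, which
contains the flow pseudo-reactions; dF_k/dt is evaluated analytically by
the chain rule through that right-hand side, and cross-checked against
finite differences of σ(t) on the stored log-time grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dynamics import Trajectory, event_times, sigma_series
from .entropy import LOG_FLOOR, R_GAS
from .network import (
    ReactionNetwork,
    _conc_array,
    rate_vector,
    stoichiometric_matrix,
)

logger = logging.getLogger("efmentropy")


class GridTooCoarseError(RuntimeError):
    """Finite-difference cross-check disagrees with the chain rule beyond
    tolerance; refine the output grid (more points per decade)."""


@dataclass(frozen=True)
class GECPoint:
    """Forces and flows of one state, one entry per reversible pair."""

    pairs: tuple[tuple[int, int], ...]
    forces: np.ndarray   # J K⁻¹ mol⁻¹
    flows: np.ndarray    # mol L⁻¹ s⁻¹

    @property
    def sigma(self) -> float:
        return float(self.forces @ self.flows)


@dataclass(frozen=True)
class GECRecord:
    """Force/flow decomposition of dσ/dt along a trajectory."""

    times: np.ndarray
    pairs: tuple[tuple[int, int], ...]
    forces: np.ndarray          # (n_times, n_pairs)
    flows: np.ndarray           # (n_times, n_pairs)
    sigma: np.ndarray
    dF_sigma_dt: np.ndarray
    dJ_sigma_dt: np.ndarray
    dsigma_dt: np.ndarray       # analytic: dFσ/dt + dJσ/dt
    dsigma_dt_fd: np.ndarray    # finite-difference cross-check (nan at edges)
    gec_satisfied: bool


def forces_and_flows(
    network: ReactionNetwork,
    conc: Mapping[str, float] | Sequence[float],
    gas_constant: float = R_GAS,
) -> GECPoint:
    """(F_k, J_k) per reversible pair; Σ F·J reproduces σ exactly.

    A pair with both rates zero contributes (0, 0) by convention.
    """
    v = rate_vector(network, conc)
    col = {i: j for j, i in enumerate(network.indices)}
    pairs = network.reversible_pairs()
    F = np.zeros(len(pairs))
    J = np.zeros(len(pairs))
    for k, (fi, ri) in enumerate(pairs):
        vf, vr = v[col[fi]], v[col[ri]]
        if vf == 0.0 and vr == 0.0:
            logger.debug("pair (%d,%d): both rates zero, (F,J)=(0,0)", fi, ri)
            continue
        F[k] = gas_constant * math.log(max(vf, LOG_FLOOR) / max(vr, LOG_FLOOR))
        J[k] = vf - vr
    return GECPoint(pairs=pairs, forces=F, flows=J)


def _monomial_dot(t, c, cdot, network) -> float:
    """d v_j/dt by the product rule (robust at zero concentrations)."""
    if not t.reactant_stoich:
        return 0.0
    total = 0.0
    items = [(network.species.index(s), a) for s, a in t.reactant_stoich.items()]
    for i, a in items:
        term = a * (c[i] ** (a - 1)) * cdot[i]
        for l, al in items:
            if l != i:
                term *= c[l] ** al
        total += term
    return t.rate_constant * total


def gec_decomposition(
    traj: Trajectory,
    network: ReactionNetwork | None = None,
    gas_constant: float = R_GAS,
    *,
    check_grid: bool = True,
    away_rtol: float = 1e-6,
    spike_rtol: float = 1e-2,
    gec_tol_rel: float = 1e-9,
) -> GECRecord:
    """Resolve dσ/dt into force- and flow-driven parts along a trajectory.

    dF_k/dt uses the analytic log-derivative Σ_i α_ji d[X_i]/dt / [X_i] of
    each rate monomial, with d[X]/dt = ν·v; the same construction gives
    dJ_k/dt.  When ``check_grid`` is set, a fourth-order finite difference
    of σ in log-time must agree with dFσ/dt + dJσ/dt to ``away_rtol``
    (relative to the derivative's peak magnitude), relaxed to
    ``spike_rtol`` within a factor of 4 of the symmetry-breaking spike;
    disagreement raises :class:`GridTooCoarseError`.
    """
    network = network or traj.network
    nu = stoichiometric_matrix(network).astype(float)
    col = {i: j for j, i in enumerate(network.indices)}
    pairs = network.reversible_pairs()
    n = len(traj.times)

    forces = np.zeros((n, len(pairs)))
    flows = np.zeros((n, len(pairs)))
    dF = np.zeros((n, len(pairs)))
    dJ = np.zeros((n, len(pairs)))

    for ti in range(n):
        c = traj.concentrations[ti]
        v = traj.rates[ti]
        cdot = nu @ v
        for k, (fi, ri) in enumerate(pairs):
            tf, tr = network.by_index(fi), network.by_index(ri)
            vf, vr = v[col[fi]], v[col[ri]]
            if vf == 0.0 and vr == 0.0:
                continue
            forces[ti, k] = gas_constant * math.log(
                max(vf, LOG_FLOOR) / max(vr, LOG_FLOOR))
            flows[ti, k] = vf - vr
            # log-derivatives of the monomials (stable even when the rates
            # underflow, provided the reactant concentrations are positive)
            lf = _logderiv(tf, c, cdot, network)
            lr = _logderiv(tr, c, cdot, network)
            if lf is not None and lr is not None and vf > 0 and vr > 0:
                dF[ti, k] = gas_constant * (lf - lr)
                dJ[ti, k] = vf * lf - vr * lr
            else:
                dJ[ti, k] = (_monomial_dot(tf, c, cdot, network)
                             - _monomial_dot(tr, c, cdot, network))

    dF_sigma = (dF * flows).sum(axis=1)
    dJ_sigma = (forces * dJ).sum(axis=1)
    dsigma = dF_sigma + dJ_sigma
    sigma = (forces * flows).sum(axis=1)
    fd = _log_grid_derivative(traj.times, sigma)

    scale = float(np.abs(dF_sigma).max())
    gec_ok = bool((dF_sigma <= gec_tol_rel * max(scale, 1e-300)).all())

    record = GECRecord(
        times=traj.times, pairs=pairs, forces=forces, flows=flows,
        sigma=sigma, dF_sigma_dt=dF_sigma, dJ_sigma_dt=dJ_sigma,
        dsigma_dt=dsigma, dsigma_dt_fd=fd, gec_satisfied=gec_ok,
    )
    if check_grid:
        _check_fd_agreement(traj, record, away_rtol, spike_rtol)
    return record


def _logderiv(t, c, cdot, network) -> float | None:
    """Σ_i α_ji ċ_i/c_i, or None when a reactant concentration vanishes."""
    total = 0.0
    for s, a in t.reactant_stoich.items():
        i = network.species.index(s)
        if c[i] <= 0.0:
            return None
        total += a * cdot[i] / c[i]
    return total


def _log_grid_derivative(times: np.ndarray, y: np.ndarray) -> np.ndarray:
    """6th-order central differences of y w.r.t. t on a log-uniform grid.

    The high order keeps the truncation error below the tight agreement
    band even across the sharp production peak.  Entries where the grid is
    not log-uniform (the t=0 sample, edges) are nan.
    """
    out = np.full_like(y, np.nan, dtype=float)
    pos = times > 0
    t = times[pos]
    yy = y[pos]
    if t.size < 7:
        return out
    u = np.log(t)
    du = np.diff(u)
    if np.ptp(du) > 1e-6 * du.mean():
        return out  # not log-uniform; no cross-check possible
    h = du.mean()
    dydu = np.full_like(yy, np.nan)
    dydu[3:-3] = (
        -yy[:-6] + 9 * yy[1:-5] - 45 * yy[2:-4]
        + 45 * yy[4:-2] - 9 * yy[5:-1] + yy[6:]
    ) / (60 * h)
    out[pos] = dydu / t
    return out


def _check_fd_agreement(traj, record, away_rtol, spike_rtol):
    fd = record.dsigma_dt_fd
    an = record.dsigma_dt
    ok = np.isfinite(fd)
    if not ok.any():
        return
    scale = float(np.abs(an[ok]).max())
    if scale == 0.0:
        return
    err = np.abs(fd - an) / scale
    ev = event_times(traj)
    rtol = np.full_like(err, away_rtol)
    if ev.smsb_time is not None:
        near = (traj.times >= ev.smsb_time / 4) & (traj.times <= ev.smsb_time * 4)
        rtol[near] = spike_rtol
    bad = ok & (err > rtol)
    if bad.any():
        i = int(np.nanargmax(np.where(bad, err, -np.inf)))
        raise GridTooCoarseError(
            f"finite-difference check fails at t={traj.times[i]:g} s "
            f"(relative error {err[i]:.3g}); refine the output grid"
        )


@dataclass(frozen=True)
class StabilityReport:
    """Numerical stability probe of the run's final stationary state."""

    dsigma_nonpositive_after_peak: bool
    max_sigma_rise_after_peak: float  # largest re-rise of σ after its peak, / σ_peak
    flows_bounded_by_forces_near_ness: bool
    sigma_plateau: float | None
    sigma_ness: float
    entropy_drop: float | None      # σ(plateau) − σ(final NESS); None if no plateau
    minimized: bool | None
    smsb_detected: bool


def stability_probe(
    traj: Trajectory,
    network: ReactionNetwork | None = None,
    gas_constant: float = R_GAS,
    *,
    ness_window_decades: float = 0.5,
    rise_tol_rel: float = 0.01,
) -> StabilityReport:
    """Check that σ never re-rises appreciably after the production peak,
    that |dJσ/dt| ≤ |dFσ/dt| near the final stationary state, and the
    entropy-production drop from the metastable racemic plateau to the
    final state.

    The post-peak check is formulated on σ itself (largest re-rise relative
    to the peak value, tolerance ``rise_tol_rel``) rather than pointwise on
    dσ/dt: along the metastable racemic branch the production genuinely
    drifts slightly upward while the state creeps along the thermodynamic
    branch, so a pointwise sign test would flag physically meaningful
    behavior.
    """
    network = network or traj.network
    rec = gec_decomposition(traj, network, gas_constant, check_grid=False)
    ev = event_times(traj, gas_constant=gas_constant)
    t = traj.times
    sigma = rec.sigma
    scale = float(np.abs(rec.dsigma_dt).max())
    slack = 1e-6 * max(scale, 1e-300)

    after_peak = np.ones_like(t, dtype=bool)
    if ev.sigma_peak_time is not None:
        after_peak = t > ev.sigma_peak_time
    seg = sigma[after_peak]
    if seg.size and sigma.max() > 0:
        rise = float((seg - np.minimum.accumulate(seg)).max() / sigma.max())
    else:
        rise = 0.0
    mono = rise <= rise_tol_rel

    near = t >= t[-1] / 10 ** ness_window_decades
    bounded = bool(
        (np.abs(rec.dJ_sigma_dt[near]) <= np.abs(rec.dF_sigma_dt[near]) + slack).all()
    )

    sigma_ness = float(sigma[-1])
    sigma_plateau = None
    drop = None
    minimized = None
    if ev.plateau_window is not None:
        sel = (t >= ev.plateau_window[0]) & (t <= ev.plateau_window[1])
        sigma_plateau = float(np.median(sigma[sel]))
        drop = sigma_plateau - sigma_ness
        minimized = drop > 0
    return StabilityReport(
        dsigma_nonpositive_after_peak=mono,
        max_sigma_rise_after_peak=rise,
        flows_bounded_by_forces_near_ness=bounded,
        sigma_plateau=sigma_plateau,
        sigma_ness=sigma_ness,
        entropy_drop=drop,
        minimized=minimized,
        smsb_detected=ev.smsb_time is not None,
    )
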