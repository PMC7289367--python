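"""Activation criteria: cumulative shear stress and its critical threshold.

A platelet is primed for activation when a surface-grafted VWF multimer
unfolds completely.  For an arbitrary shear history ``tau(t)`` along the
platelet trajectory three statements order themselves around the simulated
ground truth:

* **necessary** (cumulative shear stress): complete unfolding requires

      CSS = integral of tau(t) dt  >  CSS_0(N),

  with the closed-form threshold
  ``CSS_0 = (3N/2)^{1/3} sqrt(7/4 + (1/4)(3N/2)^{-8/3} - 2(3N/2)^{-1/3})``,
  an increasing function of multimer size ``N``;

* **sufficient** (momentum): if the momentum at the end of the shear burst
  exceeds the separatrix momentum ``|qdot_A|`` toward unfolding, free
  motion completes the unfolding;

* **ground truth**: direct integration of the equation of motion.

For rectangular impulses of amplitude ``tau_m`` the minimal unfolding
duration ``t_F(tau_m)`` is tabulated here; it diverges at the amplitude
asymptote ``tau_hash`` (below which no finite impulse unfolds a resting
molecule) and approaches the hyperbola ``tau_m * t_F = CSS_0`` at large
amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import dynamics, model
from .dynamics import BoundarySpec, State, Trajectory
from .model import MultimerParameters
from .profiles import ShearProfile, rectangular

__all__ = [
    "ActivationReport",
    "CriticalCurve",
    "ConvergenceError",
    "NEVER",
    "cumulative_shear",
    "css0",
    "necessary_condition",
    "momentum_sufficient_condition",
    "tau_threshold",
    "critical_duration",
    "critical_curve",
    "classify",
]

#: Sentinel duration for amplitudes that can never unfold a resting molecule.
NEVER = math.inf


class ConvergenceError(RuntimeError):
    """A bracketing/bisection search failed to converge."""


@dataclass(frozen=True)
class ActivationReport:
    """Outcome of a shear history applied to an initially folded multimer."""

    css: float
    css0: float
    necessary_met: bool
    momentum_sufficient_met: bool
    fully_unfolded: bool
    residual_momentum: Optional[float]
    final_state: State
    trajectory: Optional[Trajectory] = None

    @property
    def activated(self) -> bool:
        """Alias for the simulation ground truth ``fully_unfolded``."""
        return self.fully_unfolded


@dataclass(frozen=True)
class CriticalCurve:
    """Critical impulse duration versus amplitude for one multimer size.

    ``points`` has columns ``tau_m`` and ``t_F``; rows at or below the
    asymptote ``tau_hash`` carry ``t_F = inf``.
    """

    N: int
    points: pd.DataFrame
    tau_hash: float
    css0: float


def cumulative_shear(profile: ShearProfile, t_in: Optional[float] = None,
                     t_out: Optional[float] = None) -> float:
    """Cumulative shear stress: the exact integral of the profile over
    ``[t_in, t_out]`` (full support by default; zero outside it)."""
    if t_in is not None and t_out is not None and not t_in < t_out:
        raise ValueError("require t_in < t_out")
    return profile.integral(t_in, t_out)


def css0(params: MultimerParameters) -> float:
    """Critical cumulative shear stress ``CSS_0(N)``, dimensionless.

    Closed form in ``a = 3N/2``:
    ``a^{1/3} * sqrt(7/4 + a^{-8/3}/4 - 2 a^{-1/3})``.  Identically equal
    to ``sqrt(2 (U_0(1) - U_0(q_m))) / q_m^{3/7}`` — the separatrix
    momentum divided by the maximal shear coupling factor.
    """
    a = 1.5 * params.N
    return a ** (1.0 / 3.0) * math.sqrt(
        1.75 + 0.25 * a ** (-8.0 / 3.0) - 2.0 * a ** (-1.0 / 3.0)
    )


def necessary_condition(profile: ShearProfile, params: MultimerParameters) -> bool:
    """Does the profile's total cumulative shear strictly exceed CSS_0?

    Necessary but not sufficient for complete unfolding of an initially
    folded molecule.
    """
    return cumulative_shear(profile) > css0(params)


def momentum_sufficient_condition(qdot_out: float, params: MultimerParameters) -> bool:
    """Is the end-of-burst momentum super-critical toward unfolding?

    True iff ``qdot_out < 0`` and ``|qdot_out|`` exceeds the separatrix
    momentum ``|qdot_A|``; then free motion completes the unfolding.
    """
    return qdot_out < 0 and abs(qdot_out) > model.saddle_momentum(params)


def tau_threshold(params: MultimerParameters) -> float:
    """Amplitude asymptote ``tau_hash``: the sustained shear below which a
    resting folded molecule never unfolds.

    The unique shear in ``(tau_star, tau_c)`` at which the from-rest energy
    equals the barrier energy, ``U_tau(q_m) = U_tau(q_barrier(tau))``.
    Above it the quasistatically released molecule clears the barrier in
    finite time; below it the barrier holds for any duration.
    """
    qm = params.q_m

    def residual(tau: float) -> float:
        ls = model.landscape_at(tau, params)
        return float(model.potential_energy(qm, tau)) - ls.U_barrier

    eps = 1e-12
    lo = model.tau_star(params) * (1 + 1e-9) + eps
    hi = model.TAU_C * (1 - 1e-9)
    return float(brentq(residual, lo, hi, xtol=1e-15, rtol=8.9e-16))


def _unfolds_after(tau_m: float, duration: float, params: MultimerParameters,
                   rtol: float = 1e-9, atol: float = 1e-9) -> bool:
    """Does a rectangular impulse of this amplitude and duration unfold a
    molecule initially at rest in the folded state?

    Exact within the model: if the origin is not reached during the
    impulse, the post-impulse fate is decided by the conservative
    separatrix test at switch-off.
    """
    traj = dynamics.simulate(
        rectangular(tau_m, duration), params,
        State(q=params.q_m, qdot=0.0, t=0.0),
        BoundarySpec(restitution_at_origin=0.0),
        t_end=duration, rtol=rtol, atol=atol,
    )
    if traj.fully_unfolded:
        return True
    return dynamics.separatrix_test(traj.final_state, params)


def critical_duration(tau_m: float, params: MultimerParameters,
                      rel_tol: float = 1e-6, max_iter: int = 200) -> float:
    """Minimal rectangular-impulse duration ``t_F`` that unfolds a resting
    folded molecule at amplitude ``tau_m``.

    Found by geometric bracket expansion followed by bisection on the
    duration, with the time integrator as oracle; returns :data:`NEVER`
    (infinity) for amplitudes at or below the asymptote
    :func:`tau_threshold`.
    """
    if not tau_m > 0:
        raise ValueError("tau_m must be positive")
    if tau_m <= tau_threshold(params):
        return NEVER

    lo = 0.0
    hi = 10.0 * css0(params) / tau_m
    for _ in range(200):
        if _unfolds_after(tau_m, hi, params):
            break
        lo, hi = hi, 2.0 * hi
    else:
        raise ConvergenceError(
            f"no unfolding bracket found up to duration {hi:g} at tau_m={tau_m:g}"
        )
    for _ in range(max_iter):
        if hi - lo <= rel_tol * hi:
            return hi
        mid = 0.5 * (lo + hi)
        if _unfolds_after(tau_m, mid, params):
            hi = mid
        else:
            lo = mid
    raise ConvergenceError(
        f"bisection for t_F did not reach rel_tol={rel_tol:g} in {max_iter} iterations"
    )


def critical_curve(params: MultimerParameters,
                   tau_grid: Sequence[float]) -> CriticalCurve:
    """Tabulate ``t_F`` over ``tau_grid`` and attach the asymptote and CSS_0."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    if np.any(tau_grid <= 0):
        raise ValueError("amplitudes must be positive")
    th = tau_threshold(params)
    c0 = css0(params)
    t_f = [NEVER if tm <= th else critical_duration(float(tm), params)
           for tm in tau_grid]
    points = pd.DataFrame({"tau_m": tau_grid, "t_F": t_f})
    return CriticalCurve(N=params.N, points=points, tau_hash=th, css0=c0)


def classify(profile: ShearProfile, params: MultimerParameters,
             boundary: BoundarySpec = BoundarySpec(),
             rtol: float = 1e-9, atol: float = 1e-9,
             keep_trajectory: bool = False) -> ActivationReport:
    """Full activation verdict for a shear history, from the folded state.

    Simulates from ``(q_m, 0)`` over the profile's support.  If the origin
    is not reached while shear acts, the conservative separatrix test at
    the final state decides the post-history fate exactly, and the residual
    momentum at eventual origin contact follows from energy conservation.
    """
    t0 = min(0.0, profile.support[0])
    traj = dynamics.simulate(profile, params,
                             State(q=params.q_m, qdot=0.0, t=t0), boundary,
                             t_end=profile.support[1], rtol=rtol, atol=atol)
    final = traj.final_state
    unfolded = traj.fully_unfolded
    residual: Optional[float] = None
    if unfolded:
        contact = traj.first_event(dynamics.EventKind.ORIGIN_CONTACT)
        i = int(np.searchsorted(traj.t, contact.time))
        i = min(i, traj.t.size - 1)
        residual = float(abs(traj.qdot[i]))
    elif dynamics.separatrix_test(final, params):
        unfolded = True
        # free conservative motion to q = 0 converts all energy to kinetic
        residual = math.sqrt(2.0 * max(dynamics.total_energy(final, 0.0), 0.0))

    return ActivationReport(
        css=cumulative_shear(profile),
        css0=css0(params),
        necessary_met=necessary_condition(profile, params),
        momentum_sufficient_met=momentum_sufficient_condition(final.qdot, params),
        fully_unfolded=unfolded,
        residual_momentum=residual,
        final_state=final,
        trajectory=traj if keep_trajectory else None,
    )
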