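"""Potential landscape and equilibrium analysis of shear-driven VWF unfolding.

A von Willebrand factor (VWF) multimer grafted on a platelet surface is
described by a single dimensionless conformational coordinate
``q = (2r/d)**7``, where ``r`` is the radius of the still-globular part and
``d`` the subunit size.  ``q`` runs from ``q_m = (3N/2)**(7/3)`` (fully
folded globule of ``N`` subunits) down to ``0`` (fully extended chain).
Under a dimensionless shear stress ``tau`` the coordinate obeys the
conservative equation of motion

    q'' = -tau * q**(3/7) + q**(1/7) - 1

which derives from the potential

    U_tau(q) = (7/10) * tau * q**(10/7) - (7/8) * q**(8/7) + q.

This module provides the potential, its force, the folded/unfolded order
parameter, and the bifurcation structure of the stationary states: the
shear ``tau_star`` at which a partially unfolded minimum detaches from the
folded wall, and the fold catastrophe at ``tau_c = 4/27`` where barrier and
partial minimum merge and only the fully unfolded state survives.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TAU_C",
    "Regime",
    "MultimerParameters",
    "PotentialLandscape",
    "potential_energy",
    "acceleration",
    "unfolding_degree",
    "coordinate_from_unfolding_degree",
    "landscape_at",
    "tau_star",
    "tau_c",
    "saddle_momentum",
    "bifurcation_diagram",
]

#: Fold-catastrophe shear: above it the potential is monotone downhill
#: toward q = 0.  Independent of multimer size.
TAU_C = 4.0 / 27.0

#: Location of the potential barrier at zero shear (the saddle of the
#: zero-shear phase portrait).
Q_SADDLE = 1.0


class Regime(enum.Enum):
    """Topological class of the potential ``U_tau`` on ``[0, q_m]``."""

    #: tau < tau_star: minima at q = 0 and at the folded wall q = q_m.
    FOLDED_BISTABLE = "folded_bistable"
    #: tau_star < tau < tau_c: minima at q = 0 and at an interior q_partial.
    PARTIAL_BISTABLE = "partial_bistable"
    #: tau > tau_c: single minimum at q = 0, molecule unfolds from anywhere.
    MONOSTABLE_UNFOLDED = "monostable_unfolded"


class UnsupportedMultimerError(ValueError):
    """Raised for multimer sizes outside the model's regime of validity."""


@dataclass(frozen=True)
class MultimerParameters:
    """Size of the VWF multimer and derived folded-state coordinate.

    Parameters
    ----------
    N : int
        Number of monomeric subunits.  Must be at least 3 so that the fold
        point ``q = (3/2)**7`` lies inside the physical interval
        ``(0, q_m)`` and the full three-regime structure of the potential
        exists.
    """

    N: int

    def __post_init__(self) -> None:
        if not float(self.N).is_integer():
            raise UnsupportedMultimerError(f"N must be an integer, got {self.N!r}")
        if self.N < 3:
            raise UnsupportedMultimerError(
                f"N must be >= 3 (got {self.N}); for smaller multimers the fold "
                "point leaves the physical domain and the regime structure "
                "degenerates"
            )
        object.__setattr__(self, "N", int(self.N))

    @property
    def q_m(self) -> float:
        """Folded-state coordinate ``(3N/2)**(7/3)``."""
        return (1.5 * self.N) ** (7.0 / 3.0)

    def contour_length(self, d: float) -> float:
        """Physical contour length ``L = N * d`` for subunit size ``d``."""
        if d <= 0:
            raise ValueError("subunit size d must be positive")
        return self.N * d


@dataclass(frozen=True)
class PotentialLandscape:
    """Critical points and regime class of ``U_tau`` at fixed shear.

    ``q_barrier`` is the local maximum (the generalized saddle; exactly 1 at
    zero shear), present whenever ``tau < tau_c``.  ``q_partial`` is the
    interior local minimum, present only in the partially unfolded regime
    ``tau_star < tau < tau_c``.
    """

    tau: float
    regime: Regime
    q_barrier: Optional[float]
    q_partial: Optional[float]
    U_barrier: Optional[float]
    U_qm: float


def _check_domain(q, tau) -> None:
    if np.any(np.asarray(q) < 0):
        raise ValueError("coordinate q must be nonnegative")
    if np.any(np.asarray(tau) < 0):
        raise ValueError("shear stress tau must be nonnegative")


def potential_energy(q, tau):
    """Dimensionless potential ``(7/10) tau q^{10/7} - (7/8) q^{8/7} + q``.

    Accepts scalars or arrays; both arguments must be nonnegative.
    """
    _check_domain(q, tau)
    q = np.asarray(q, dtype=float)
    out = 0.7 * tau * q ** (10.0 / 7.0) - 0.875 * q ** (8.0 / 7.0) + q
    return out if out.ndim else float(out)


def acceleration(q, tau):
    """Force term of the equation of motion, ``-tau q^{3/7} + q^{1/7} - 1``.

    Equals ``-dU/dq`` of :func:`potential_energy` at the same ``(q, tau)``.
    """
    _check_domain(q, tau)
    q = np.asarray(q, dtype=float)
    out = -tau * q ** (3.0 / 7.0) + q ** (1.0 / 7.0) - 1.0
    return out if out.ndim else float(out)


def unfolding_degree(q, params: MultimerParameters):
    """Degree of unfolding ``u = 1 - (q/q_m)**(3/7)``.

    ``u`` is the extended tail length over the contour length: 0 in the
    folded state ``q = q_m``, 1 in the fully unfolded state ``q = 0``.
    Strictly decreasing in ``q`` on ``[0, q_m]``.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > params.q_m * (1 + 1e-12)):
        raise ValueError(f"q must lie in [0, q_m={params.q_m:g}]")
    out = 1.0 - np.clip(q / params.q_m, 0.0, 1.0) ** (3.0 / 7.0)
    return out if out.ndim else float(out)


def coordinate_from_unfolding_degree(u, params: MultimerParameters):
    """Inverse of :func:`unfolding_degree`: ``q = q_m (1-u)**(7/3)``."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("u must lie in [0, 1]")
    out = params.q_m * (1.0 - u) ** (7.0 / 3.0)
    return out if out.ndim else float(out)


def tau_star(params: MultimerParameters) -> float:
    """Shear at which the interior minimum detaches from the folded wall.

    Stationarity of the potential evaluated at ``q = q_m`` gives
    ``tau_star = ((3N/2)**(1/3) - 1) / (3N/2)``; decreasing in ``N``.
    """
    a = 1.5 * params.N
    return (a ** (1.0 / 3.0) - 1.0) / a


def tau_c(params: MultimerParameters) -> float:
    """Fold-catastrophe shear ``4/27``, independent of multimer size.

    Stationary points of ``U_tau`` are roots of the cubic
    ``tau s**3 - s + 1 = 0`` in ``s = q**(1/7)``; the double root occurs at
    ``s = 3/2`` when ``tau = 4/27``, and ``q = (3/2)**7`` lies inside
    ``(0, q_m)`` for every supported ``N >= 3``.
    """
    # params validates N >= 3 on construction; touching q_m keeps the
    # contract explicit for duck-typed inputs.
    if params.N < 3:
        raise UnsupportedMultimerError("tau_c requires N >= 3")
    return TAU_C


def saddle_momentum(params: MultimerParameters) -> float:
    """Momentum ``|qdot_A|`` of the zero-shear separatrix at ``q = q_m``.

    ``|qdot_A| = sqrt(2 (U_0(1) - U_0(q_m)))``: the speed a trajectory on
    the separatrix has when it passes the folded state.  A state at
    ``(q_m, qdot)`` reaches complete unfolding under free (zero-shear)
    motion iff ``qdot < 0`` and ``|qdot| > |qdot_A|``.
    """
    qm = params.q_m
    du = potential_energy(Q_SADDLE, 0.0) - potential_energy(qm, 0.0)
    return math.sqrt(2.0 * du)


def _stationary_roots(tau: float) -> tuple[float, ...]:
    """Positive roots ``s`` of ``tau s**3 - s + 1 = 0``, ascending.

    In ``s = q**(1/7)`` stationarity of the potential reduces to this
    cubic; solving the polynomial avoids bracketing fractional powers near
    the fold.
    """
    if tau == 0.0:
        return (1.0,)
    roots = np.roots([tau, 0.0, -1.0, 1.0])
    real = roots[np.abs(roots.imag) < 1e-9 * max(1.0, np.abs(roots).max())].real
    pos = sorted(s for s in real if s > 0)
    return tuple(pos)


def landscape_at(tau: float, params: MultimerParameters) -> PotentialLandscape:
    """Classify the potential at shear ``tau`` and locate its critical points.

    Returns a :class:`PotentialLandscape` whose ``q_barrier`` (local
    maximum) exists iff ``tau < tau_c`` and whose ``q_partial`` (interior
    local minimum) exists iff the larger stationary root falls strictly
    inside ``(0, q_m)``, i.e. in the partially unfolded regime.
    """
    if tau < 0:
        raise ValueError("shear stress tau must be nonnegative")
    qm = params.q_m
    U_qm = potential_energy(qm, tau)

    if tau >= TAU_C:
        return PotentialLandscape(tau, Regime.MONOSTABLE_UNFOLDED, None, None, None, U_qm)

    if tau == 0.0:
        # Degenerate cubic (linear): the barrier is the saddle at q = 1.
        return PotentialLandscape(
            tau, Regime.FOLDED_BISTABLE, Q_SADDLE, None,
            float(potential_energy(Q_SADDLE, 0.0)), U_qm,
        )

    roots = _stationary_roots(tau)
    if len(roots) < 2:  # pragma: no cover - closed under tau < 4/27
        return PotentialLandscape(tau, Regime.MONOSTABLE_UNFOLDED, None, None, None, U_qm)

    s1, s2 = roots[0], roots[-1]
    q_barrier = s1 ** 7
    q_min = s2 ** 7
    U_barrier = float(potential_energy(q_barrier, tau))
    if q_min >= qm:
        # The would-be interior minimum sits beyond the folded wall:
        # the physical minimum is the wall itself.
        return PotentialLandscape(tau, Regime.FOLDED_BISTABLE, q_barrier, None, U_barrier, U_qm)
    return PotentialLandscape(tau, Regime.PARTIAL_BISTABLE, q_barrier, q_min, U_barrier, U_qm)


def bifurcation_diagram(
    params: MultimerParameters, tau_grid: Sequence[float]
) -> pd.DataFrame:
    """Branch table of steady states versus shear, in unfolding degree.

    For each shear value the table lists every steady state as a row
    ``(tau, branch, u, stable)``.  The fully unfolded branch ``u = 1`` is
    stable at all shear; the folded branch ``u = 0`` exists for
    ``tau < tau_star``; the partially unfolded branch for
    ``tau_star < tau < tau_c``; the barrier gives the unstable branch for
    ``tau < tau_c``.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if np.any(tau_grid < 0):
        raise ValueError("tau_grid must be nonnegative")
    if np.any(np.diff(tau_grid) < 0):
        raise ValueError("tau_grid must be sorted ascending")

    rows = []
    for tau in tau_grid:
        ls = landscape_at(float(tau), params)
        rows.append((tau, "unfolded", 1.0, True))
        if ls.regime is Regime.FOLDED_BISTABLE:
            rows.append((tau, "folded", 0.0, True))
        if ls.q_partial is not None:
            rows.append((tau, "partial", float(unfolding_degree(ls.q_partial, params)), True))
        if ls.q_barrier is not None:
            rows.append((tau, "barrier", float(unfolding_degree(ls.q_barrier, params)), False))
    return pd.DataFrame(rows, columns=["tau", "branch", "u", "stable"])
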