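"""Time integration of the unfolding equation of motion with boundary events.

The conformational coordinate moves in the potential of :mod:`sipact.model`
under a time-dependent shear profile:

    q'' = -tau(t) * q**(3/7) + q**(1/7) - 1,   0 <= q <= q_m.

The system is conservative on spans of constant shear, so the integrator is
a high-order adaptive Runge-Kutta (DOP853) with event location for the two
physical boundaries and for separatrix crossing:

* ``q = 0`` (complete unfolding): an inelastic origin (restitution 0)
  absorbs the molecule — total unfolding is irreversible adhesion; a
  partially or fully elastic origin reflects ``qdot -> -e * qdot``.
* ``q = q_m`` (folded wall): a STICKY wall zeroes the outward momentum (the
  refolded globule is held at the wall while the net force presses into
  it, i.e. while ``tau <= tau_star``); REFLECT negates it.
* separatrix crossing: the moment the zero-shear energy first exceeds the
  saddle energy ``U_0(1) = 1/8`` while moving toward unfolding — from then
  on free motion reaches ``q = 0``.

Integration is split at the shear profile's breakpoints so discontinuous
waveforms (rectangular impulses) do not degrade the adaptive error control.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import List, NamedTuple, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import model
from .model import MultimerParameters
from .profiles import ShearProfile

__all__ = [
    "State",
    "Wall",
    "BoundarySpec",
    "EventKind",
    "Event",
    "Trajectory",
    "SimulationError",
    "total_energy",
    "separatrix_test",
    "simulate",
    "simulate_verlet",
]

_SADDLE_ENERGY = 0.125  # U_0(q = 1), the zero-shear barrier energy


class SimulationError(RuntimeError):
    """Integration failed (solver breakdown or runaway boundary contacts)."""


@dataclass(frozen=True)
class State:
    """Phase-space point: coordinate ``q``, momentum ``qdot``, time ``t``."""

    q: float
    qdot: float
    t: float = 0.0


class Wall(enum.Enum):
    """Behaviour at the folded wall ``q = q_m``."""

    STICKY = "sticky"
    REFLECT = "reflect"


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary handling at both ends of the physical interval.

    ``restitution_at_origin`` is the coefficient of restitution ``e`` at
    ``q = 0``: 0 (default) is irreversible adhesion of the unfolded
    molecule, 1 a perfectly elastic bounce.
    """

    restitution_at_origin: float = 0.0
    wall_at_qm: Wall = Wall.STICKY

    def __post_init__(self) -> None:
        if not 0.0 <= self.restitution_at_origin <= 1.0:
            raise ValueError("restitution coefficient must lie in [0, 1]")


class EventKind(enum.Enum):
    SEPARATRIX_CROSS = "separatrix_cross"
    ORIGIN_CONTACT = "origin_contact"
    WALL_CONTACT = "wall_contact"


class Event(NamedTuple):
    kind: EventKind
    time: float


@dataclass
class Trajectory:
    """Sampled solution of the equation of motion plus located events."""

    t: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    events: List[Event] = field(default_factory=list)
    fully_unfolded: bool = False
    params: Optional[MultimerParameters] = None

    @property
    def final_state(self) -> State:
        return State(q=float(self.q[-1]), qdot=float(self.qdot[-1]), t=float(self.t[-1]))

    def first_event(self, kind: EventKind) -> Optional[Event]:
        for ev in self.events:
            if ev.kind is kind:
                return ev
        return None


def total_energy(state: State, tau: float) -> float:
    """Kinetic plus potential energy ``qdot**2/2 + U_tau(q)``.

    Conserved along the motion wherever the shear is constant and no
    boundary is touched.
    """
    return 0.5 * state.qdot ** 2 + float(model.potential_energy(state.q, tau))


def separatrix_test(state: State, params: MultimerParameters) -> bool:
    """Would free motion (zero shear, no dissipation) from here reach q = 0?

    True iff the state lies below the zero-shear separatrix through the
    saddle at ``q = 1``: either it is already past the saddle and moving
    toward unfolding (``q < 1`` with ``qdot < 0``), or it moves toward
    unfolding with energy above the saddle energy ``U_0(1) = 1/8``.  For
    conservative motion this energy inequality is exact — no integration
    is needed.
    """
    if state.qdot >= 0:
        return False
    if state.q < model.Q_SADDLE:
        return True
    return total_energy(state, 0.0) > _SADDLE_ENERGY


def _release_time(profile: ShearProfile, t_from: float, t_end: float,
                  tau_release: float) -> Optional[float]:
    """First time in [t_from, t_end] where the shear exceeds ``tau_release``.

    While stuck at the folded wall the net force presses inward iff
    ``tau <= tau_star``; the molecule is released when the shear first
    exceeds it.  The profile is scanned on its breakpoints plus a fine
    grid and the crossing is refined by root bracketing.
    """
    if profile(t_from) > tau_release:
        return t_from
    pts = [t_from, t_end]
    pts += [b for b in profile.breakpoints() if t_from < b < t_end]
    lo, hi = profile.support
    for b in (lo, hi):
        if t_from < b < t_end:
            pts.append(b)
    pts = np.unique(pts)
    for a, b in zip(pts[:-1], pts[1:]):
        grid = np.linspace(a, b, 257)
        above = profile(grid) > tau_release
        if not above.any():
            continue
        i = int(np.argmax(above))
        if i == 0:
            return float(grid[0])
        g = lambda t: profile(t) - tau_release
        try:
            return float(brentq(g, grid[i - 1], grid[i], xtol=1e-13, rtol=1e-14))
        except ValueError:
            return float(grid[i])
    return None


_MAX_SEGMENTS = 10_000

#: Shear excess over tau_star required to release a stuck molecule from the
#: folded wall; see the wall-handling comment in :func:`simulate`.
_RELEASE_SLACK = 1e-7


def simulate(profile: ShearProfile, params: MultimerParameters,
             initial: State, boundary: BoundarySpec = BoundarySpec(),
             t_end: float = None, rtol: float = 1e-9, atol: float = 1e-9,
             sample_dt: Optional[float] = None) -> Trajectory:
    """Integrate the equation of motion from ``initial`` until ``t_end``.

    Adaptive DOP853 with dense event location; the reported samples are the
    accepted solver steps (or a uniform grid of spacing ``sample_dt``
    evaluated from the dense interpolant), so the coordinate never exits
    ``[0, q_m]`` in them — boundaries are handled by event location, not
    clipping.

    Raises :class:`SimulationError` on solver failure or when boundary
    contacts do not terminate (e.g. an elastic molecule rattling between
    walls beyond an internal segment cap).
    """
    if t_end is None:
        t_end = profile.support[1]
    if not t_end > initial.t:
        raise ValueError("t_end must exceed the initial time")
    qm = params.q_m
    if not 0.0 <= initial.q <= qm * (1 + 1e-12):
        raise ValueError(f"initial q must lie in [0, q_m={qm:g}]")
    ts = model.tau_star(params)

    def rhs(t, y):
        q = y[0] if y[0] > 0.0 else 0.0
        tau = profile(t)
        if not np.isfinite(tau):
            raise SimulationError(f"non-finite shear stress at t={t}")
        return (y[1], -tau * q ** (3.0 / 7.0) + q ** (1.0 / 7.0) - 1.0)

    def ev_origin(t, y):
        return y[0]
    ev_origin.terminal = True
    ev_origin.direction = -1.0

    def ev_wall(t, y):
        return y[0] - qm
    ev_wall.terminal = True
    ev_wall.direction = 1.0

    def ev_sep(t, y):
        q = y[0] if y[0] > 0.0 else 0.0
        return 0.5 * y[1] ** 2 + float(model.potential_energy(q, 0.0)) - _SADDLE_ENERGY
    ev_sep.terminal = False
    ev_sep.direction = 1.0

    # integration checkpoints: profile breakpoints inside the span
    cuts = sorted({float(b) for b in profile.breakpoints()
                   if initial.t < b < t_end})

    t_samples = [initial.t]
    q_samples = [float(initial.q)]
    v_samples = [float(initial.qdot)]
    events: List[Event] = []
    fully_unfolded = False

    t = float(initial.t)
    q, v = float(initial.q), float(initial.qdot)

    def record(tt, qq, vv):
        t_samples.append(float(tt))
        q_samples.append(float(np.clip(qq, 0.0, qm)))
        v_samples.append(float(vv))

    for _ in range(_MAX_SEGMENTS):
        # --- stuck-at-wall handling -----------------------------------
        at_wall = q >= qm * (1 - 1e-13)
        if at_wall and v >= 0.0:
            if boundary.wall_at_qm is Wall.STICKY:
                v = 0.0
            elif v > 0.0:
                v = -v
        if at_wall and v == 0.0 and profile(t) <= ts + _RELEASE_SLACK:
            # Held by the wall until the shear can pull the globule off.
            # The small slack keeps the pull-off force decisively negative,
            # so the freed coordinate leaves the wall monotonically instead
            # of dithering at it (the shear missed while waiting imparts a
            # momentum error ~ slack * dwell time, far below the solver
            # tolerance).
            t_rel = _release_time(profile, t, t_end, ts + _RELEASE_SLACK)
            if t_rel is None or t_rel >= t_end:
                record(t_end, qm, 0.0)
                break
            if t_rel > t:
                record(t_rel, qm, 0.0)
                t, q, v = t_rel, qm, 0.0
        if t >= t_end:
            break

        # --- integrate up to the next profile breakpoint ---------------
        t_next = t_end
        for c in cuts:
            if c > t * (1 + 1e-15) and c > t + 1e-15:
                t_next = min(t_end, c)
                break
        sol = solve_ivp(rhs, (t, t_next), (q, v), method="DOP853",
                        rtol=rtol, atol=atol,
                        dense_output=sample_dt is not None,
                        events=(ev_origin, ev_wall, ev_sep))
        if not sol.success:
            raise SimulationError(f"integration failed at t={t:g}: {sol.message}")
        if sample_dt is not None and sol.t[-1] > sol.t[0]:
            grid = np.arange(sol.t[0] + sample_dt, sol.t[-1], sample_dt)
            dense = sol.sol(grid) if grid.size else np.empty((2, 0))
            sol.t = np.concatenate([[sol.t[0]], grid, [sol.t[-1]]])
            sol.y = np.column_stack(
                [sol.y[:, 0], dense, sol.y[:, -1]])

        for te, ye in zip(sol.t_events[2], sol.y_events[2]):
            # an energy upcrossing counts as a separatrix cross only while
            # the molecule moves toward unfolding
            if ye[1] < 0:
                events.append(Event(EventKind.SEPARATRIX_CROSS, float(te)))

        for tt, qq, vv in zip(sol.t[1:], sol.y[0][1:], sol.y[1][1:]):
            record(tt, qq, vv)

        if sol.t_events[0].size:  # origin contact
            te = float(sol.t_events[0][0])
            ve = float(sol.y_events[0][0][1])
            events.append(Event(EventKind.ORIGIN_CONTACT, te))
            fully_unfolded = True
            # the solver already recorded the event state as last sample
            t_samples[-1], q_samples[-1], v_samples[-1] = te, 0.0, ve
            e = boundary.restitution_at_origin
            if e == 0.0:
                break  # irreversible adhesion in the unfolded state
            t, q, v = te, 0.0, -e * ve
            record(t, q, v)
            continue
        if sol.t_events[1].size:  # folded-wall contact
            te = float(sol.t_events[1][0])
            ve = float(sol.y_events[1][0][1])
            events.append(Event(EventKind.WALL_CONTACT, te))
            t_samples[-1], q_samples[-1], v_samples[-1] = te, qm, ve
            if boundary.wall_at_qm is Wall.STICKY:
                t, q, v = te, qm, 0.0
            else:
                t, q, v = te, qm, -ve
            record(t, q, v)
            continue

        t, q, v = float(sol.t[-1]), float(sol.y[0][-1]), float(sol.y[1][-1])
        if t >= t_end * (1 - 1e-15):
            break
    else:
        raise SimulationError(
            f"exceeded {_MAX_SEGMENTS} integration segments (runaway contacts?)"
        )

    events.sort(key=lambda ev: ev.time)
    return Trajectory(
        t=np.asarray(t_samples), q=np.asarray(q_samples),
        qdot=np.asarray(v_samples), events=events,
        fully_unfolded=fully_unfolded, params=params,
    )


def simulate_verlet(profile: ShearProfile, params: MultimerParameters,
                    initial: State, t_end: float, dt: float) -> Trajectory:
    """Fixed-step velocity-Verlet integration (energy-drift audit mode).

    Symplectic, second order, no boundary or event handling: integration
    stops early if the coordinate leaves ``(0, q_m)``.  Intended solely for
    auditing the adaptive integrator's energy drift on contact-free spans.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    n = int(math.ceil((t_end - initial.t) / dt))
    t = initial.t + dt * np.arange(n + 1)
    q = np.empty(n + 1)
    v = np.empty(n + 1)
    q[0], v[0] = initial.q, initial.qdot
    qm = params.q_m

    def acc(qq, tt):
        qq = qq if qq > 0 else 0.0
        return -profile(tt) * qq ** (3.0 / 7.0) + qq ** (1.0 / 7.0) - 1.0

    a = acc(q[0], t[0])
    k = n
    for i in range(n):
        q[i + 1] = q[i] + v[i] * dt + 0.5 * a * dt * dt
        if not 0.0 < q[i + 1] < qm:
            k = i + 1
            q[k] = min(max(q[k], 0.0), qm)
            v[k] = v[i] + a * dt
            break
        a_new = acc(q[i + 1], t[i + 1])
        v[i + 1] = v[i] + 0.5 * (a + a_new) * dt
        a = a_new
    return Trajectory(t=t[:k + 1], q=q[:k + 1], qdot=v[:k + 1],
                      events=[], fully_unfolded=bool(q[k] <= 0.0), params=params)
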