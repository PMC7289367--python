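"""Physical <-> dimensionless conversion and the dimensional force laws.

The core modules work entirely in the dimensionless variables of the
equation of motion; this module holds the bridge to physical units.  The
nondimensionalization uses

* stress scale ``4 sigma / (k d)``: ``tau_dimensionless = k tau d / (4 sigma)``,
* time scale ``sqrt(4 m0 / (15 sigma pi))``,

where ``k`` is the dimensionless drag coefficient of the shear force on the
globule, ``d`` the monomeric subunit size, ``sigma`` the effective
surface-tension coefficient driving refolding, and ``m0`` the subunit mass.
No defaults are provided for these constants — the model itself fixes none
of them, so every physical-unit result is conditional on user-supplied
values.  As a convenience, a stress scale alone can be calibrated by
pinning the fold-catastrophe shear (``tau_c = 4/27``) to a known physical
activation threshold such as the commonly cited 80 dyn/cm^2 for sustained
shear.

The dimensional force laws behind the model are also exposed: the
unfolding force ``F_un = k pi r^2 tau`` of the shear drag on a globule of
radius ``r`` and the refolding force ``F_f = sigma pi d (1 - d/(2r))`` of
effective surface tension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .model import TAU_C

__all__ = [
    "PhysicalScale",
    "StressCalibration",
    "stress_to_dimensionless",
    "stress_from_dimensionless",
    "time_to_dimensionless",
    "time_from_dimensionless",
    "unfolding_force",
    "folding_force",
    "calibrate_stress_scale",
    "load_config",
]


@dataclass(frozen=True)
class PhysicalScale:
    """Physical constants of the nondimensionalization.

    Parameters
    ----------
    k : float
        Dimensionless drag proportionality coefficient of the unfolding
        force.
    d : float
        Monomeric subunit size (length units, e.g. cm).
    sigma : float
        Effective surface-tension coefficient (force/length).
    m0 : float
        Mass of one monomeric subunit.

    ``stress_scale`` and ``time_scale`` are derived on access, never
    stored.
    """

    k: float
    d: float
    sigma: float
    m0: float

    def __post_init__(self) -> None:
        for name in ("k", "d", "sigma", "m0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def stress_scale(self) -> float:
        """Stress that maps to dimensionless shear 1: ``4 sigma / (k d)``."""
        return 4.0 * self.sigma / (self.k * self.d)

    @property
    def time_scale(self) -> float:
        """Physical duration of one dimensionless time unit:
        ``sqrt(4 m0 / (15 sigma pi))``."""
        return math.sqrt(4.0 * self.m0 / (15.0 * self.sigma * math.pi))


@dataclass(frozen=True)
class StressCalibration:
    """A stress scale known without the individual constants k, d, sigma.

    Produced by :func:`calibrate_stress_scale`; carries no time scale.
    """

    stress_scale: float
    time_scale: Optional[float] = None


Scale = Union[PhysicalScale, StressCalibration]


def _require_scale(scale) -> float:
    if scale is None or getattr(scale, "stress_scale", None) is None:
        raise ValueError("a scale with stress_scale is required")
    return scale.stress_scale


def stress_to_dimensionless(tau_physical: float, scale: Scale) -> float:
    """Convert physical shear stress to dimensionless: ``k tau d / (4 sigma)``."""
    if tau_physical < 0:
        raise ValueError("shear stress must be nonnegative")
    return tau_physical / _require_scale(scale)


def stress_from_dimensionless(tau: float, scale: Scale) -> float:
    """Inverse of :func:`stress_to_dimensionless`."""
    if tau < 0:
        raise ValueError("shear stress must be nonnegative")
    return tau * _require_scale(scale)


def time_to_dimensionless(t_physical: float, scale: PhysicalScale) -> float:
    """Convert physical time to dimensionless using the model's time scale."""
    if t_physical < 0:
        raise ValueError("time must be nonnegative")
    if getattr(scale, "time_scale", None) is None:
        raise ValueError("a scale with time_scale is required")
    return t_physical / scale.time_scale


def time_from_dimensionless(t: float, scale: PhysicalScale) -> float:
    """Inverse of :func:`time_to_dimensionless`."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    if getattr(scale, "time_scale", None) is None:
        raise ValueError("a scale with time_scale is required")
    return t * scale.time_scale


def unfolding_force(r: float, tau_physical: float, k: float) -> float:
    """Shear drag force unfolding the globule: ``F_un = k pi r^2 tau``."""
    if not r > 0:
        raise ValueError("globule radius must be positive")
    return k * math.pi * r * r * tau_physical


def folding_force(r: float, d: float, sigma: float) -> float:
    """Effective surface-tension force refolding the molecule:
    ``F_f = sigma pi d (1 - d/(2r))``.

    Vanishes at the single-subunit radius ``r = d/2`` and saturates at
    ``sigma pi d`` for a large globule.
    """
    if r < d / 2.0:
        raise ValueError("globule radius must be at least d/2")
    return sigma * math.pi * d * (1.0 - d / (2.0 * r))


def calibrate_stress_scale(tau_physical_at_tauc: float) -> StressCalibration:
    """Pin the fold catastrophe to a known physical activation stress.

    Maps the supplied physical stress (e.g. the literature threshold of
    80 dyn/cm^2 for sustained-shear activation) to the model's fold
    catastrophe ``tau_c = 4/27``, yielding a stress scale without knowing
    ``k``, ``d``, ``sigma`` individually.  A convenience heuristic — not a
    model prediction.
    """
    if not tau_physical_at_tauc > 0:
        raise ValueError("calibration stress must be positive")
    return StressCalibration(stress_scale=tau_physical_at_tauc / TAU_C)


_CONFIG_KEYS = {
    "N": int,
    "k": float,
    "d": float,
    "sigma": float,
    "m0": float,
    "restitution": float,
    "rtol": float,
    "atol": float,
}


def load_config(path) -> dict:
    """Parse a plain-text ``key = value`` configuration file.

    Recognised keys: ``N`` (required, integer), ``k``, ``d``, ``sigma``,
    ``m0``, ``restitution``, ``rtol``, ``atol`` (floats).  Lines starting
    with ``#`` and blank lines are ignored.
    """
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            out[key] = _CONFIG_KEYS[key](value)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad value for {key!r}: {value!r}") from exc
    if "N" not in out:
        raise ValueError(f"{path}: missing required key 'N'")
    return out
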