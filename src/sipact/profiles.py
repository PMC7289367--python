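"""Shear-stress waveforms: analytic constructors and CSV ingestion.

A :class:`ShearProfile` is a nonnegative dimensionless shear stress
``tau(t)`` with finite support, evaluating to exactly 0 outside it (a clean
switch-off is what makes the post-impulse separatrix test exact).  Built-in
waveforms — rectangular, trapezoid, truncated Gaussian, half-sine — are
smooth stand-ins for the impulsive shear histories a platelet experiences
transiting a stenotic region; arbitrary histories (e.g. shear sampled along
a CFD platelet trajectory) are ingested from two-column CSV files and
interpolated piecewise-linearly.

Every profile knows its exact integral, so cumulative shear stress is
computed in closed form rather than by quadrature.
"""

from __future__ import annotations

import enum
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "ProfileKind",
    "ShearProfile",
    "ProfileError",
    "ColumnSchemaError",
    "NonMonotoneTimeError",
    "NegativeStressError",
    "MissingScaleError",
    "rectangular",
    "trapezoid",
    "gaussian_pulse",
    "half_sine",
    "sampled",
    "read_profile_csv",
    "write_profile_csv",
]

#: Truncation half-width of the Gaussian pulse, in units of its width.
GAUSSIAN_TRUNCATION = 4.0


class ProfileKind(enum.Enum):
    RECTANGULAR = "rectangular"
    TRAPEZOID = "trapezoid"
    GAUSSIAN_PULSE = "gaussian_pulse"
    HALF_SINE = "half_sine"
    SAMPLED = "sampled"


class ProfileError(ValueError):
    """Base class for malformed shear-profile inputs."""


class ColumnSchemaError(ProfileError):
    """CSV header does not consist of exactly `time,shear_stress`."""


class NonMonotoneTimeError(ProfileError):
    """CSV time column is not strictly increasing."""


class NegativeStressError(ProfileError):
    """A shear-stress value is negative."""


class MissingScaleError(ProfileError):
    """Physical-units input supplied without a conversion scale."""


class ShearProfile:
    """Nonnegative shear stress as a function of dimensionless time.

    Do not instantiate directly; use the constructor functions
    :func:`rectangular`, :func:`trapezoid`, :func:`gaussian_pulse`,
    :func:`half_sine`, :func:`sampled` or :func:`read_profile_csv`.
    """

    def __init__(self, kind: ProfileKind, support: tuple[float, float],
                 parameters: dict, breakpoints: Sequence[float]):
        self.kind = kind
        self.support = (float(support[0]), float(support[1]))
        self.parameters = dict(parameters)
        self._breakpoints = tuple(float(b) for b in breakpoints)
        if not self.support[1] > self.support[0]:
            raise ProfileError("profile support must have positive length")

    # -- evaluation -----------------------------------------------------

    def _value_inside(self, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, t):
        """Shear stress at time ``t`` (scalar or array); 0 outside support."""
        t = np.asarray(t, dtype=float)
        inside = (t >= self.support[0]) & (t <= self.support[1])
        out = np.zeros_like(t)
        if np.any(inside):
            out[inside] = self._value_inside(t[inside])
        return out if out.ndim else float(out)

    def breakpoints(self) -> tuple[float, ...]:
        """Times where the waveform is not smooth (integration is split there)."""
        return self._breakpoints

    # -- integration ----------------------------------------------------

    def _integral_inside(self, a: float, b: float) -> float:
        raise NotImplementedError

    def integral(self, t0: Optional[float] = None, t1: Optional[float] = None) -> float:
        """Exact integral of the profile over ``[t0, t1]``.

        Defaults to the full support; spans extending outside the support
        contribute zero there.
        """
        lo, hi = self.support
        a = lo if t0 is None else max(float(t0), lo)
        b = hi if t1 is None else min(float(t1), hi)
        if t0 is not None and t1 is not None and t1 < t0:
            raise ValueError("integration span must have t0 <= t1")
        if b <= a:
            return 0.0
        return self._integral_inside(a, b)


def _piecewise_linear_integral(times: np.ndarray, values: np.ndarray,
                               a: float, b: float) -> float:
    """Exact integral of a piecewise-linear function over [a, b] within its nodes."""
    grid = np.unique(np.concatenate([[a, b], times[(times > a) & (times < b)]]))
    vals = np.interp(grid, times, values)
    return float(np.trapezoid(vals, grid))


class _Rectangular(ShearProfile):
    def _value_inside(self, t):
        return np.full_like(t, self.parameters["tau_m"])

    def _integral_inside(self, a, b):
        return self.parameters["tau_m"] * (b - a)


class _PiecewiseLinear(ShearProfile):
    """Shared implementation for trapezoid and sampled profiles."""

    def __init__(self, kind, support, parameters, times, values):
        super().__init__(kind, support, parameters, breakpoints=times)
        self._times = np.asarray(times, dtype=float)
        self._values = np.asarray(values, dtype=float)

    def _value_inside(self, t):
        return np.interp(t, self._times, self._values)

    def _integral_inside(self, a, b):
        return _piecewise_linear_integral(self._times, self._values, a, b)


class _GaussianPulse(ShearProfile):
    def _value_inside(self, t):
        c, w = self.parameters["center"], self.parameters["width"]
        return self.parameters["tau_m"] * np.exp(-((t - c) ** 2) / (2.0 * w * w))

    def _integral_inside(self, a, b):
        c, w = self.parameters["center"], self.parameters["width"]
        z = 1.0 / (w * math.sqrt(2.0))
        return self.parameters["tau_m"] * w * math.sqrt(math.pi / 2.0) * float(
            erf((b - c) * z) - erf((a - c) * z)
        )


class _HalfSine(ShearProfile):
    def _value_inside(self, t):
        d = self.parameters["duration"]
        return self.parameters["tau_m"] * np.sin(np.pi * t / d)

    def _integral_inside(self, a, b):
        d = self.parameters["duration"]
        tau_m = self.parameters["tau_m"]
        return tau_m * d / math.pi * (math.cos(math.pi * a / d) - math.cos(math.pi * b / d))


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ProfileError(f"{name} must be positive, got {value!r}")


def rectangular(tau_m: float, duration: float) -> ShearProfile:
    """Rectangular impulse of amplitude ``tau_m`` on ``[0, duration]``.

    Integral is exactly ``tau_m * duration``.
    """
    _check_positive(tau_m=tau_m, duration=duration)
    return _Rectangular(ProfileKind.RECTANGULAR, (0.0, duration),
                        {"tau_m": tau_m, "duration": duration},
                        breakpoints=(0.0, duration))


def trapezoid(tau_m: float, duration: float, ramp: float) -> ShearProfile:
    """Symmetric trapezoid: linear ramps of length ``ramp`` at both ends.

    Support is ``[0, duration]`` with a flat top of length
    ``duration - 2*ramp``; ``ramp = 0`` degenerates to the rectangle.
    Integral is ``tau_m * (duration - ramp)``.
    """
    _check_positive(tau_m=tau_m, duration=duration)
    if ramp < 0 or 2 * ramp > duration:
        raise ProfileError("ramp must satisfy 0 <= 2*ramp <= duration")
    if ramp == 0:
        return rectangular(tau_m, duration)
    times = np.array([0.0, ramp, duration - ramp, duration])
    values = np.array([0.0, tau_m, tau_m, 0.0])
    # A degenerate flat top (2*ramp == duration) collapses to a triangle.
    keep = np.concatenate([[True], np.diff(times) > 0])
    return _PiecewiseLinear(ProfileKind.TRAPEZOID, (0.0, duration),
                            {"tau_m": tau_m, "duration": duration, "ramp": ramp},
                            times[keep], values[keep])


def gaussian_pulse(tau_m: float, center: float, width: float) -> ShearProfile:
    """Gaussian pulse truncated at ±4 widths around ``center``.

    Peak value ``tau_m`` at the centre; the exact truncated area is
    ``tau_m * width * sqrt(2 pi) * erf(4/sqrt(2))``.
    """
    _check_positive(tau_m=tau_m, width=width)
    half = GAUSSIAN_TRUNCATION * width
    return _GaussianPulse(ProfileKind.GAUSSIAN_PULSE,
                          (center - half, center + half),
                          {"tau_m": tau_m, "center": center, "width": width},
                          breakpoints=(center - half, center + half))


def half_sine(tau_m: float, duration: float) -> ShearProfile:
    """Half sine arch ``tau_m * sin(pi t / duration)`` on ``[0, duration]``.

    Integral is ``2 * tau_m * duration / pi``.
    """
    _check_positive(tau_m=tau_m, duration=duration)
    return _HalfSine(ProfileKind.HALF_SINE, (0.0, duration),
                     {"tau_m": tau_m, "duration": duration},
                     breakpoints=(0.0, duration))


def sampled(times: Sequence[float], values: Sequence[float]) -> ShearProfile:
    """Piecewise-linear profile through ``(times, values)`` sample points.

    Times must be strictly increasing, values nonnegative; evaluation is 0
    outside ``[times[0], times[-1]]``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.size < 2 or times.shape != values.shape:
        raise ProfileError("need two equal-length 1-D arrays with >= 2 samples")
    if np.any(np.diff(times) <= 0):
        raise NonMonotoneTimeError("sample times must be strictly increasing")
    if np.any(values < 0):
        raise NegativeStressError("shear stress samples must be nonnegative")
    return _PiecewiseLinear(ProfileKind.SAMPLED, (times[0], times[-1]),
                            {"n_samples": int(times.size)}, times, values)


_CSV_COLUMNS = ["time", "shear_stress"]


def read_profile_csv(path, units_mode: str = "dimensionless",
                     scale=None) -> ShearProfile:
    """Read a two-column ``time,shear_stress`` CSV into a sampled profile.

    ``units_mode="dimensionless"`` stores the values as-is.  With
    ``units_mode="physical"`` the stress column is divided by
    ``scale.stress_scale``; if ``scale`` also carries a ``time_scale`` (a
    full :class:`~sipact.units.PhysicalScale`), the time column is divided
    by it as well, otherwise times are taken as already dimensionless.
    """
    if units_mode not in ("dimensionless", "physical"):
        raise ProfileError(f"unknown units_mode {units_mode!r}")
    df = pd.read_csv(path)
    if list(df.columns) != _CSV_COLUMNS:
        raise ColumnSchemaError(
            f"expected exactly columns {_CSV_COLUMNS}, got {list(df.columns)}"
        )
    if len(df) < 2:
        raise ProfileError("need at least 2 samples")
    times = df["time"].to_numpy(dtype=float)
    values = df["shear_stress"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise NonMonotoneTimeError("time column must be strictly increasing")
    if np.any(values < 0):
        raise NegativeStressError("shear_stress column must be nonnegative")
    if units_mode == "physical":
        if scale is None or getattr(scale, "stress_scale", None) is None:
            raise MissingScaleError(
                "physical units_mode requires a scale with a stress_scale"
            )
        values = values / scale.stress_scale
        time_scale = getattr(scale, "time_scale", None)
        if time_scale is not None:
            times = times / time_scale
    return sampled(times, values)


def write_profile_csv(profile: ShearProfile, path, sampling_step: float) -> None:
    """Sample ``profile`` on a uniform grid over its support and write CSV.

    The grid includes both support edges; reading the file back reproduces
    the written values exactly at the sample times.
    """
    if not sampling_step > 0:
        raise ProfileError("sampling_step must be positive")
    lo, hi = profile.support
    n = int(math.floor((hi - lo) / sampling_step + 1e-12))
    grid = lo + sampling_step * np.arange(n + 1)
    if grid[-1] < hi - 1e-12 * max(1.0, abs(hi)):
        grid = np.append(grid, hi)
    pd.DataFrame({"time": grid, "shear_stress": profile(grid)}).to_csv(
        Path(path), index=False
    )
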