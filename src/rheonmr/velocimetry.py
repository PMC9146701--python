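"""Stage 1: from velocity profiles + torque to local flow curves.

A rheo-MRI experiment in a narrow-gap Couette cell yields the azimuthal
velocity v(r) across the gap together with a concurrent torque reading from
the rheometer. The local shear rate is

    gamma_dot(r) = | r * d(v/r)/dr |

(the rate-of-strain invariant for azimuthal flow; rigid-body rotation gives
exactly zero), obtained with a Savitzky-Golay first-derivative filter, and
the local stress follows from the torque balance

    sigma(r) = T / (2 pi r^2 H).

Pairing the two across the gap gives a local flow curve (LFC): many
(shear rate, stress) samples from a single snapshot in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .params import CouetteGeometry


class SchemaError(ValueError):
    """Input data violate a declared schema or invariant."""


@dataclass(frozen=True)
class VelocityProfile:
    """Tabulated azimuthal velocity across the Couette gap.

    Positions in metres (strictly ascending), velocity in m/s. At least 7
    points are required (the default Savitzky-Golay window).
    """

    r: np.ndarray
    v: np.ndarray
    time_stamp: float = 0.0
    applied_rate: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "v", v)
        if r.ndim != 1 or r.shape != v.shape:
            raise SchemaError("r and v must be 1-D arrays of equal length")
        if r.size < 7:
            raise SchemaError("velocity profile needs >= 7 points")
        if np.any(np.diff(r) <= 0.0):
            raise SchemaError("positions must be strictly ascending")
        if np.any(r <= 0.0):
            raise SchemaError("positions must be positive (inside a Couette gap)")


@dataclass(frozen=True)
class LocalFlowCurve:
    """Paired (shear rate, stress) samples across the gap at one time point."""

    gamma_dot: np.ndarray
    sigma: np.ndarray
    r: np.ndarray
    time_stamp: float = 0.0

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma_dot, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        r = np.asarray(self.r, dtype=float)
        for name, arr in (("gamma_dot", g), ("sigma", s), ("r", r)):
            object.__setattr__(self, name, arr)
        if not (g.shape == s.shape == r.shape):
            raise SchemaError("gamma_dot, sigma, r must have equal lengths")
        if np.any(g < 0.0):
            raise SchemaError("shear rates must be >= 0")

    def __len__(self) -> int:
        return self.gamma_dot.size


def stress_profile(torque: float, geometry: CouetteGeometry, r_values) -> np.ndarray:
    """Local stress sigma(r) = T / (2 pi r^2 H) from the torque balance.

    Strictly decreasing across the gap for positive torque; raises if any
    position lies outside the gap.
    """
    if torque < 0.0:
        raise ValueError("torque must be >= 0")
    r = np.asarray(r_values, dtype=float)
    lo, hi = geometry.inner_radius, geometry.outer_radius
    tol = 1e-9 * geometry.gap
    if np.any(r < lo - tol) or np.any(r > hi + tol):
        raise ValueError("positions outside the Couette gap")
    return torque / (2.0 * np.pi * r**2 * geometry.height)


def sg_derivative(
    values,
    positions,
    window: int = 7,
    poly_order: int = 1,
    edge_order: int | None = None,
) -> np.ndarray:
    """Savitzky-Golay first derivative on a uniform grid.

    Interior points use the centred least-squares local-polynomial filter.
    The first and last half-windows use one-sided polynomial fits over the
    first/last ``window`` points (no truncation of the profile), by default
    of order ``poly_order + 2``: a one-sided fit of the interior order
    carries an O(h) curvature bias at the walls — exactly where a Couette
    profile bends fastest, and where a shear-thinning fluid close to arrest
    has large higher derivatives — while two extra orders push the endpoint
    error below the smoothing error of the interior filter.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(positions, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("values and positions must be 1-D arrays of equal length")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > y.size:
        raise ValueError("window exceeds number of points")
    if not 0 <= poly_order < window:
        raise ValueError("need 0 <= poly_order < window")
    if edge_order is None:
        edge_order = min(poly_order + 2, window - 1)
    steps = np.diff(x)
    h = steps.mean()
    if np.any(np.abs(steps - h) > 1e-6 * abs(h)):
        raise ValueError(
            "positions are not uniformly spaced (relative tolerance 1e-6); "
            "resample the profile before differentiating"
        )
    deriv = savgol_filter(y, window, poly_order, deriv=1, delta=h, mode="interp")
    half = window // 2
    for sl in (slice(0, half), slice(y.size - half, y.size)):
        base = slice(0, window) if sl.start == 0 else slice(y.size - window, y.size)
        xc = x[base] - x[base].mean()  # centred for conditioning
        coeffs = np.polyfit(xc, y[base], edge_order)
        dcoeffs = np.polyder(coeffs)
        deriv[sl] = np.polyval(dcoeffs, x[sl] - x[base].mean())
    return deriv


def shear_rate_profile(
    profile: VelocityProfile, window: int = 7, poly_order: int = 1
) -> np.ndarray:
    """Local shear rate |r d(v/r)/dr| across the gap.

    v/r is formed first (exact identity), so a single Savitzky-Golay pass
    produces the derivative; rigid-body rotation maps to zero shear rate.
    """
    omega = profile.v / profile.r
    domega = sg_derivative(omega, profile.r, window=window, poly_order=poly_order)
    return np.abs(profile.r * domega)


def assemble_lfc(
    profile: VelocityProfile,
    torque: float,
    geometry: CouetteGeometry,
    *,
    torque_time: float | None = None,
    time_tolerance: float = np.inf,
    gamma_min: float = 0.05,
    window: int = 7,
    poly_order: int = 1,
) -> LocalFlowCurve:
    """Pair local shear rates with local stresses into a flow curve.

    Points with shear rate below ``gamma_min`` (s^-1, the velocimetry noise
    floor) are masked out; a fully arrested profile therefore yields an
    empty curve. If ``torque_time`` is given it must agree with the profile
    time stamp within ``time_tolerance``.
    """
    if torque_time is not None and abs(torque_time - profile.time_stamp) > time_tolerance:
        raise ValueError(
            f"torque time {torque_time} does not match profile time "
            f"{profile.time_stamp} within {time_tolerance}"
        )
    gamma = shear_rate_profile(profile, window=window, poly_order=poly_order)
    sigma = stress_profile(torque, geometry, profile.r)
    keep = gamma >= gamma_min
    return LocalFlowCurve(
        gamma_dot=gamma[keep],
        sigma=sigma[keep],
        r=profile.r[keep],
        time_stamp=profile.time_stamp,
    )
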