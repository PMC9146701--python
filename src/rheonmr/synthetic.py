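"""Forward simulation of every measurement the pipeline consumes.

Emulates the four instruments: (i) rheo-MRI velocity profiles + rheometer
torque for a Herschel-Bulkley fluid in a narrow-gap Couette cell, including
partial yielding (shear localization) when the applied rotation cannot yield
the whole gap; (ii) structural-kinetic yield-stress decay series; (iii)
Murday-Cotts PFG droplet-sizing decays; (iv) two-component D-T2 decay
surfaces. All noise is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .params import CouetteGeometry, HBParams, NoiseSpec, PGSEParams, SKMParams
from .velocimetry import VelocityProfile, stress_profile
from .restricted import (  # noqa: F401  (re-exported forward models)
    murday_cotts_attenuation,
    pfg_decay_lognormal,
    stejskal_tanner_attenuation,
)

__all__ = [
    "CouetteSolution",
    "couette_forward_solve",
    "noisy_profile",
    "skm_series",
    "stress_profile",
    "murday_cotts_attenuation",
    "pfg_decay_lognormal",
    "stejskal_tanner_attenuation",
    "dt2_signal",
]


class CouetteSolverError(RuntimeError):
    """Torque root search failed; message carries the bracket diagnostics."""


@dataclass(frozen=True)
class CouetteSolution:
    """Steady Couette flow of an HB fluid: profile, torque and yield radius.

    ``yield_radius`` is None when the whole gap is sheared; when it lies
    inside the gap the material beyond it is arrested (shear localization).
    ``at_yield_limit`` marks the degenerate zero-rotation case where the
    torque is only bounded by the yield limit 2 pi Ri^2 H tau0.
    """

    profile: VelocityProfile
    torque: float
    yield_radius: float | None
    at_yield_limit: bool = False

    def __iter__(self):
        return iter((self.profile, self.torque, self.yield_radius))


def _sheared_outer_limit(torque: float, geometry: CouetteGeometry, hb: HBParams):
    """Outer edge of the flowing band and the yield radius (None if beyond Ro)."""
    if hb.yield_stress == 0.0:
        return geometry.outer_radius, None
    ry = np.sqrt(torque / (2.0 * np.pi * geometry.height * hb.yield_stress))
    if ry >= geometry.outer_radius:
        return geometry.outer_radius, None
    return ry, ry


def _rotor_rate_for_torque(torque: float, geometry: CouetteGeometry, hb: HBParams):
    r_edge, _ = _sheared_outer_limit(torque, geometry, hb)
    if r_edge <= geometry.inner_radius:
        return 0.0

    def integrand(r: float) -> float:
        sigma = torque / (2.0 * np.pi * r**2 * geometry.height)
        return hb.shear_rate(sigma) / r

    val, _err = quad(integrand, geometry.inner_radius, r_edge, limit=200)
    return val


def couette_forward_solve(
    geometry: CouetteGeometry,
    hb: HBParams,
    rotor_rate: float,
    n_points: int = 21,
) -> CouetteSolution:
    """Steady velocity profile and torque for an HB fluid, inner wall rotating.

    Solves the inverse problem: find the torque T whose stress field
    sigma(r) = T/(2 pi r^2 H), pushed through the constitutive law
    gamma_dot(r) = ((sigma - tau0)/K)^(1/n) (zero below tau0), integrates to
    the imposed rotor rate Omega = int_{Ri}^{min(ry,Ro)} gamma_dot/r dr.
    The outer wall is fixed, so omega(r) = int_r^{edge} gamma_dot/s ds and
    v = r * omega. ``n_points`` samples span the gap uniformly (the default
    21 matches a ~50 um imaging resolution over a 1 mm gap).
    """
    if rotor_rate < 0.0:
        raise ValueError("rotor_rate must be >= 0")
    r = np.linspace(geometry.inner_radius, geometry.outer_radius, n_points)
    if rotor_rate == 0.0:
        torque = 2.0 * np.pi * geometry.inner_radius**2 * geometry.height * hb.yield_stress
        yield_radius = geometry.inner_radius if hb.yield_stress > 0.0 else None
        profile = VelocityProfile(r=r, v=np.zeros_like(r), applied_rate=0.0)
        return CouetteSolution(profile, torque, yield_radius, at_yield_limit=True)

    # Bracket the torque: below yield limit no flow; expand upward until the
    # achievable rotor rate exceeds the target.
    t_lo = 2.0 * np.pi * geometry.inner_radius**2 * geometry.height * hb.yield_stress
    gamma_guess = rotor_rate * geometry.inner_radius / geometry.gap
    sigma_guess = hb.stress(max(gamma_guess, 1e-6))
    t_hi = max(
        2.0 * np.pi * geometry.inner_radius**2 * geometry.height * float(sigma_guess),
        t_lo * 1.001 if t_lo > 0 else 1e-12,
    )
    for _ in range(200):
        if _rotor_rate_for_torque(t_hi, geometry, hb) > rotor_rate:
            break
        t_hi *= 2.0
    else:
        raise CouetteSolverError(
            f"no torque bracket found: Omega({t_hi:.3e} N m) = "
            f"{_rotor_rate_for_torque(t_hi, geometry, hb):.3e} < {rotor_rate:.3e} rad/s"
        )
    torque = brentq(
        lambda T: _rotor_rate_for_torque(T, geometry, hb) - rotor_rate,
        t_lo,
        t_hi,
        xtol=1e-18,
        rtol=1e-14,
    )
    r_edge, yield_radius = _sheared_outer_limit(torque, geometry, hb)

    def omega_at(ri: float) -> float:
        if ri >= r_edge:
            return 0.0

        def integrand(s: float) -> float:
            sigma = torque / (2.0 * np.pi * s**2 * geometry.height)
            return hb.shear_rate(sigma) / s

        val, _err = quad(integrand, ri, r_edge, limit=200)
        return val

    v = np.array([ri * omega_at(ri) for ri in r])
    applied = rotor_rate * geometry.inner_radius / geometry.gap
    profile = VelocityProfile(r=r, v=v, applied_rate=applied)
    return CouetteSolution(profile, torque, yield_radius)


def noisy_profile(profile: VelocityProfile, noise: NoiseSpec) -> VelocityProfile:
    """Seeded noise on the velocities; sigma = 0 returns the profile unchanged."""
    return VelocityProfile(
        r=profile.r.copy(),
        v=noise.apply(profile.v),
        time_stamp=profile.time_stamp,
        applied_rate=profile.applied_rate,
        metadata=dict(profile.metadata),
    )


def skm_series(
    params: SKMParams, times, noise: NoiseSpec | None = None
) -> np.ndarray:
    """Yield-stress decay tau0(t) = (tau00 - tau0e)/(ks t + 1) + tau0e, + noise."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("times must be >= 0")
    clean = params.tau0(t)
    if noise is None:
        return clean
    return noise.apply(clean)


def dt2_signal(
    components,
    pgse: PGSEParams,
    echo_times,
    noise: NoiseSpec | None = None,
):
    """Multi-exponential D-T2 decay surface S(g, t).

    ``components`` is a sequence of (amplitude, D, T2) triples; the surface
    is sum_k A_k exp(-b(g) D_k) exp(-t / T2_k), deliberately satisfying the
    exponential-kernel assumption of the 2D inverse Laplace inversion.
    Returns a :class:`rheonmr.dt2.DT2Dataset`.
    """
    from .dt2 import DT2Dataset

    t = np.asarray(echo_times, dtype=float)
    b = pgse.b_values()[:, None]
    S = np.zeros((b.size, t.size))
    for amp, D, T2 in components:
        if amp <= 0.0 or D <= 0.0 or T2 <= 0.0:
            raise ValueError("component amplitudes, D and T2 must be > 0")
        S += amp * np.exp(-b * D) * np.exp(-t[None, :] / T2)
    if noise is not None:
        S = noise.apply(S)
    return DT2Dataset(
        gradient_strengths=pgse.g,
        echo_times=t,
        signal=S,
        pgse=pgse,
    )
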