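"""Restricted diffusion inside spheres: Murday-Cotts PGSE attenuation.

The Gaussian-phase-approximation expression for the echo attenuation of
molecules diffusing inside an impermeable sphere of radius R is

    ln E = -2 gamma^2 g^2 * sum_m [ 2 delta a_m - 2 + 2 e^{-a_m delta}
                                    + 2 e^{-a_m Delta} - e^{-a_m (Delta-delta)}
                                    - e^{-a_m (Delta+delta)} ]
                                  / ( alpha_m^6 D^2 (alpha_m^2 R^2 - 2) )

with a_m = alpha_m^2 D and alpha_m R = x_m the positive roots of

    x J'_{3/2}(x) - (1/2) J_{3/2}(x) = 0,

equivalently the extrema of the spherical Bessel function j_1. Emulsion
droplet sizing integrates this kernel over a volume-weighted lognormal
diameter distribution.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq
from scipy.special import jv, jvp

from .params import PGSEParams


class TruncationError(RuntimeError):
    """Raised when the Murday-Cotts eigenmode series has not converged."""


def _boundary_condition(x: float) -> float:
    return x * jvp(1.5, x) - 0.5 * jv(1.5, x)


@lru_cache(maxsize=8)
def sphere_bessel_roots(n_roots: int = 50) -> np.ndarray:
    """First ``n_roots`` positive roots x_m of x J'_3/2(x) = J_3/2(x)/2.

    These are the extrema of j_1 (x_1 = 2.0816, x_2 = 5.9404, ...), spaced
    asymptotically by pi; located by sign-change scanning plus Brent.
    """
    roots = []
    xs = np.arange(0.5, (n_roots + 3) * np.pi, 0.05)
    f = np.array([_boundary_condition(x) for x in xs])
    sign_change = np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]
    for i in sign_change:
        roots.append(brentq(_boundary_condition, xs[i], xs[i + 1], xtol=1e-14))
        if len(roots) == n_roots:
            break
    if len(roots) < n_roots:
        raise RuntimeError(f"only found {len(roots)} of {n_roots} Bessel roots")
    return np.asarray(roots)


def murday_cotts_log_attenuation(
    radii, diffusivity: float, pgse: PGSEParams, n_roots: int = 50
) -> np.ndarray:
    """ln E for each (radius, gradient) pair; shape (n_radii, n_gradients).

    Raises :class:`TruncationError` when the estimated series tail exceeds
    2% of the sum (too few roots for the requested parameter regime). The
    terms fall off at worst like 1/x_m^2 (free-diffusion limit), so the
    tail is bounded by roughly n_roots times the last retained term.
    """
    R = np.atleast_1d(np.asarray(radii, dtype=float))[:, None]
    if np.any(R <= 0.0):
        raise ValueError("sphere radius must be > 0")
    if diffusivity <= 0.0:
        raise ValueError("diffusivity must be > 0")
    x = sphere_bessel_roots(n_roots)[None, :]
    d, Dt = pgse.gradient_duration, pgse.diffusion_time
    D = diffusivity
    alpha2 = (x / R) ** 2  # (n_radii, n_roots)
    a = alpha2 * D
    num = (
        2.0 * d * a
        - 2.0
        + 2.0 * np.exp(-a * d)
        + 2.0 * np.exp(-a * Dt)
        - np.exp(-a * (Dt - d))
        - np.exp(-a * (Dt + d))
    )
    # For a (Delta+delta) << 1 the exponentials cancel catastrophically
    # (num ~ a^3 while each term is O(1)); switch to the Taylor series.
    small = a * (Dt + d) < 0.1
    num_series = (
        a**3 * d**2 * (Dt - d / 3.0)
        - a**4 * d**2 * Dt**2 / 2.0
        + a**5 * (10.0 * Dt**3 * d**2 + 5.0 * Dt * d**4 - d**5) / 60.0
    )
    num = np.where(small, num_series, num)
    terms = num / (alpha2**3 * D**2 * (alpha2 * R**2 - 2.0))
    total = terms.sum(axis=1)
    tail = np.abs(terms[:, -1]) * n_roots
    if np.any(tail > 2e-2 * np.abs(total)):
        raise TruncationError(
            f"Murday-Cotts series not converged with {n_roots} roots; "
            "increase n_roots"
        )
    g = pgse.g[None, :]
    return -2.0 * pgse.gyromagnetic_ratio**2 * g**2 * total[:, None]


def murday_cotts_attenuation(
    radius: float, diffusivity: float, pgse: PGSEParams, n_roots: int = 50
) -> np.ndarray:
    """Echo attenuation E(g) for a single sphere radius; E(0) = 1."""
    return np.exp(murday_cotts_log_attenuation(radius, diffusivity, pgse, n_roots))[0]


def stejskal_tanner_attenuation(diffusivity: float, pgse: PGSEParams) -> np.ndarray:
    """Free (unrestricted) diffusion attenuation exp(-b D)."""
    return np.exp(-pgse.b_values() * diffusivity)


def pfg_decay_lognormal(
    d33_um: float,
    alpha: float,
    d_oil: float,
    pgse: PGSEParams,
    quadrature_nodes: int = 64,
    n_roots: int = 50,
) -> np.ndarray:
    """Volume-averaged attenuation over a lognormal droplet-diameter distribution.

    The volume-weighted distribution is lognormal in diameter with median
    ``d33_um`` (micrometres, the volume-weighted geometric mean diameter
    D_3,3) and log-domain width ``alpha`` (dimensionless). Because the NMR
    signal is proportional to droplet volume, the attenuation is the plain
    average of the single-sphere kernel against this volume-weighted density.
    Gauss-Legendre quadrature over ln(d) on +/- 4 alpha.
    """
    if d33_um <= 0.0:
        raise ValueError("d33_um must be > 0")
    if alpha < 0.0:
        raise ValueError("alpha must be >= 0")
    mu = np.log(d33_um * 1e-6)
    if alpha == 0.0:
        return murday_cotts_attenuation(0.5 * d33_um * 1e-6, d_oil, pgse, n_roots)
    nodes, weights = leggauss(quadrature_nodes)
    ln_d = mu + 4.0 * alpha * nodes
    radii = 0.5 * np.exp(ln_d)
    pdf = np.exp(-0.5 * ((ln_d - mu) / alpha) ** 2)
    w = weights * pdf
    w /= w.sum()
    E = np.exp(murday_cotts_log_attenuation(radii, d_oil, pgse, n_roots))
    return w @ E
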