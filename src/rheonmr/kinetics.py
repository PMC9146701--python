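"""Stage 3: structural-kinetic modelling of yield-stress decay.

Thixotropic breakdown under steady shear is described by second-order
structural kinetics, which integrate to

    tau0(t) = (tau0_initial - tau0_equilibrium) / (ks t + 1) + tau0_equilibrium.

``ks`` is the breakdown rate (inverse of the supplied time unit — the fit
never converts units) and the ratio tau0_initial / tau0_equilibrium
measures the extent of breakdown. When the observation window is short
relative to 1/ks the equilibrium plateau is extrapolated, not observed;
the fit flags that situation instead of pretending the parameters are
well determined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .params import SKMParams


@dataclass(frozen=True)
class SKMFit:
    """Structural-kinetics fit: parameters, uncertainties and breakdown extent."""

    params: SKMParams
    uncertainties: dict
    breakdown_ratio: float
    residual_norm: float
    flags: tuple = ()


class StructuralKinetics(BaseEstimator, RegressorMixin):
    """Bounded least-squares fit of the second-order breakdown model.

    Internally parametrised as (tau0e, delta, ks) with delta = tau00 - tau0e
    so the tau00 >= tau0e >= 0 ordering is a plain box constraint.

    Fitted attributes: ``tau00_``, ``tau0e_``, ``ks_``, ``breakdown_ratio_``,
    ``stderr_``, ``residual_norm_``, ``flags_``.
    """

    #: ks * t_max below this marks the plateau as extrapolated.
    EQUILIBRIUM_THRESHOLD = 0.1

    def __init__(self, weights=None):
        self.weights = weights

    @staticmethod
    def model(t, tau00, tau0e, ks):
        t = np.asarray(t, dtype=float)
        return (tau00 - tau0e) / (ks * t + 1.0) + tau0e

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).reshape(-1)
        tau0 = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != tau0.shape:
            raise ValueError("times and yield stresses must have equal length")
        if t.size < 4:
            raise ValueError("need >= 4 points")
        if np.any(t < 0.0) or not np.any(t > 0.0):
            raise ValueError("times must be >= 0 with at least one > 0")
        w = np.ones_like(tau0) if self.weights is None else np.asarray(self.weights, float)

        flags = []
        scale = max(abs(tau0).max(), 1.0)
        if np.ptp(tau0) <= 1e-12 * scale:
            # Flat series: ks is unidentifiable; report the constant level.
            c = float(tau0[0])
            self.tau00_, self.tau0e_, self.ks_ = c, c, 0.0
            self.residual_norm_ = 0.0
            self.stderr_ = {"tau00": 0.0, "tau0e": 0.0, "ks": np.inf}
            self.flags_ = ("flat-series",)
            return self

        def residual(p):
            tau0e, delta, ks = p
            return w * (self.model(t, tau0e + delta, tau0e, ks) - tau0)

        delta0 = max(tau0[0] - tau0[-1], 1e-6 * scale)
        x0 = [max(tau0[-1], 0.0), delta0, 1.0 / np.median(t[t > 0])]
        sol = least_squares(
            residual, x0, bounds=([0.0, 0.0, 0.0], [np.inf] * 3), xtol=1e-15,
            ftol=1e-15, gtol=1e-15,
        )
        tau0e, delta, ks = sol.x
        self.tau00_ = float(tau0e + delta)
        self.tau0e_ = float(tau0e)
        self.ks_ = float(ks)
        self.residual_norm_ = float(np.sqrt(2.0 * sol.cost))
        dof = t.size - 3
        names = ("tau0e", "delta", "ks")
        if dof > 0:
            ssr = 2.0 * sol.cost
            cov = np.linalg.pinv(sol.jac.T @ sol.jac) * ssr / dof
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            var00 = cov[0, 0] + cov[1, 1] + 2.0 * cov[0, 1]
            self.stderr_ = {
                "tau0e": float(se[0]),
                "ks": float(se[2]),
                "tau00": float(np.sqrt(max(var00, 0.0))),
            }
        else:
            self.stderr_ = {k: np.inf for k in ("tau0e", "ks", "tau00")}
        if self.ks_ * t.max() < self.EQUILIBRIUM_THRESHOLD:
            flags.append("equilibrium-unreached")
        self.flags_ = tuple(flags)
        return self

    @property
    def breakdown_ratio_(self) -> float:
        if self.tau0e_ == 0.0:
            raise ZeroDivisionError("equilibrium yield stress is zero")
        return self.tau00_ / self.tau0e_

    def predict(self, X):
        return self.model(X, self.tau00_, self.tau0e_, self.ks_)


def fit_skm(times, tau0_values, weights=None) -> SKMFit:
    """Fit the breakdown model; thin wrapper over :class:`StructuralKinetics`."""
    est = StructuralKinetics(weights=weights).fit(times, tau0_values)
    params = SKMParams(est.tau00_, est.tau0e_, est.ks_)
    ratio = est.tau00_ / est.tau0e_ if est.tau0e_ > 0.0 else np.inf
    return SKMFit(
        params=params,
        uncertainties=est.stderr_,
        breakdown_ratio=ratio,
        residual_norm=est.residual_norm_,
        flags=est.flags_,
    )


def breakdown_ratio(fit: SKMFit) -> float:
    """Extent of structural breakdown tau00 / tau0e."""
    if fit.params.tau0e == 0.0:
        raise ZeroDivisionError("equilibrium yield stress is zero")
    return fit.params.tau00 / fit.params.tau0e
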