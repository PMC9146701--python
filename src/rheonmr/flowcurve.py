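"""Stage 2: Herschel-Bulkley fits of local flow curves.

The constitutive law is sigma = tau0 + K * gamma_dot**n. For a fixed flow
index n the law is linear in (tau0, K), so both estimators profile the
nonlinearity out: the inner problem is solved exactly by non-negative
linear least squares and the outer problem is a 1-D search over n. This
makes the fit deterministic and immune to the local minima that plague
3-parameter starts, and it guarantees that the global-n fit can never do
worse than per-curve fits clamped to the shared index.

`GlobalFlowIndexHB` fits a whole shear-treatment time series jointly with
one shared flow index; the per-curve yield stresses it returns are the
input to the structural-kinetics stage. The dimensionless representation
(capillary number Ca = mu gamma_dot R / sigma_i, scaled viscous stress
tau_v R / sigma_i) collapses curves that differ only in yield stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar, nnls
from sklearn.base import BaseEstimator, RegressorMixin

from .params import EmulsionProperties, HBParams
from .velocimetry import LocalFlowCurve


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class HBFit:
    """Result of a Herschel-Bulkley fit of one local flow curve."""

    params: HBParams
    stderr: dict
    residual_norm: float
    time_stamp: float = 0.0
    shared_n: bool = False


def _curve_arrays(curve):
    if isinstance(curve, LocalFlowCurve):
        return curve.gamma_dot, curve.sigma, curve.time_stamp
    gamma, sigma = curve
    return np.asarray(gamma, dtype=float), np.asarray(sigma, dtype=float), 0.0


def _nnls_hb(gamma: np.ndarray, sigma: np.ndarray, n: float):
    """Exact bounded (tau0, K) >= 0 fit at fixed flow index n."""
    A = np.column_stack([np.ones_like(gamma), gamma**n])
    coef, resid = nnls(A, sigma)
    return coef[0], coef[1], resid


def _hb_jacobian(gamma, tau0, K, n):
    gn = gamma**n
    with np.errstate(divide="ignore", invalid="ignore"):
        dlog = np.where(gamma > 0.0, np.log(np.where(gamma > 0.0, gamma, 1.0)), 0.0)
    return np.column_stack([np.ones_like(gamma), gn, K * gn * dlog])


def _covariance_stderr(J, residuals, names):
    n_obs, n_par = J.shape
    dof = n_obs - n_par
    ssr = float(residuals @ residuals)
    if dof <= 0:
        return {k: np.inf for k in names}
    try:
        cov = np.linalg.pinv(J.T @ J) * ssr / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return {k: np.inf for k in names}
    return dict(zip(names, se.tolist()))


_N_BOUNDS = (0.02, 2.0)


def _profile_n(objective, n_grid=None):
    """Coarse grid + bounded refinement of a smooth 1-D objective in n."""
    if n_grid is None:
        n_grid = np.linspace(_N_BOUNDS[0], _N_BOUNDS[1], 45)
    vals = [objective(n) for n in n_grid]
    i = int(np.argmin(vals))
    lo = n_grid[max(i - 1, 0)]
    hi = n_grid[min(i + 1, len(n_grid) - 1)]
    if lo == hi:
        return float(n_grid[i])
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x) if res.fun <= vals[i] else float(n_grid[i])


class HerschelBulkley(BaseEstimator, RegressorMixin):
    """Herschel-Bulkley regression sigma = tau0 + K gamma_dot**n.

    Parameters
    ----------
    n_fixed : float or None
        Fit with the flow index clamped (the inner linear problem only).
    loss : {"linear"}
        Plain least squares on sigma (robust losses are not implemented for
        the profiled solver).

    Fitted attributes: ``tau0_``, ``K_``, ``n_``, ``params_``, ``stderr_``,
    ``residual_norm_``.
    """

    def __init__(self, n_fixed: float | None = None, loss: str = "linear"):
        self.n_fixed = n_fixed
        self.loss = loss

    def fit(self, X, y=None):
        gamma = np.asarray(X, dtype=float).reshape(-1)
        sigma = np.asarray(y, dtype=float).reshape(-1)
        if gamma.shape != sigma.shape:
            raise ValueError("shear rates and stresses must have equal length")
        if self.loss != "linear":
            raise ValueError("only loss='linear' is supported")
        n_distinct = np.unique(gamma).size
        need = 3 if self.n_fixed is not None else 4
        if n_distinct < need:
            raise FitError(
                f"need >= {need} distinct shear-rate points, got {n_distinct}"
            )
        if self.n_fixed is not None:
            if not _N_BOUNDS[0] <= self.n_fixed <= _N_BOUNDS[1]:
                raise ValueError(f"n_fixed outside {_N_BOUNDS}")
            n = float(self.n_fixed)
        else:
            n = _profile_n(lambda nn: _nnls_hb(gamma, sigma, nn)[2])
        tau0, K, resid = _nnls_hb(gamma, sigma, n)
        self.tau0_, self.K_, self.n_ = float(tau0), float(K), float(n)
        self.residual_norm_ = float(resid)
        r = sigma - (tau0 + K * gamma**n)
        if self.n_fixed is not None:
            J = _hb_jacobian(gamma, tau0, K, n)[:, :2]
            self.stderr_ = _covariance_stderr(J, r, ["tau0", "K"])
            self.stderr_["n"] = 0.0
        else:
            J = _hb_jacobian(gamma, tau0, K, n)
            self.stderr_ = _covariance_stderr(J, r, ["tau0", "K", "n"])
        return self

    @property
    def params_(self) -> HBParams:
        return HBParams(self.tau0_, self.K_, self.n_)

    def predict(self, X):
        gamma = np.asarray(X, dtype=float).reshape(-1)
        return self.tau0_ + self.K_ * gamma**self.n_


class GlobalFlowIndexHB(BaseEstimator):
    """Joint HB fit of several flow curves sharing a single flow index.

    Minimises the total squared stress residual over per-curve (tau0, K)
    pairs and one shared n. The per-curve yield stresses form the
    shear-treatment decay series consumed by the kinetics stage.

    Fitted attributes: ``n_``, ``tau0_``, ``K_`` (arrays over curves),
    ``fits_`` (list of :class:`HBFit`), ``residual_norm_``, ``stderr_``.
    """

    def fit(self, curves, y=None):
        data = [_curve_arrays(c) for c in curves]
        if len(data) < 1:
            raise FitError("need at least one flow curve")
        for gamma, _sigma, _t in data:
            if np.unique(gamma).size < 3:
                raise FitError("each curve needs >= 3 distinct shear-rate points")

        def total_residual(n):
            return sum(_nnls_hb(g, s, n)[2] ** 2 for g, s, _ in data)

        n = _profile_n(total_residual)
        self.n_ = float(n)
        tau0s, Ks, fits = [], [], []
        res_blocks, jac_blocks = [], []
        for gamma, sigma, tstamp in data:
            tau0, K, resid = _nnls_hb(gamma, sigma, n)
            tau0s.append(tau0)
            Ks.append(K)
            r = sigma - (tau0 + K * gamma**n)
            res_blocks.append(r)
            jac_blocks.append((gamma, tau0, K))
            fits.append(
                HBFit(
                    params=HBParams(tau0, max(K, np.finfo(float).tiny), n),
                    stderr={},
                    residual_norm=float(resid),
                    time_stamp=tstamp,
                    shared_n=True,
                )
            )
        self.tau0_ = np.asarray(tau0s)
        self.K_ = np.asarray(Ks)
        residuals = np.concatenate(res_blocks)
        self.residual_norm_ = float(np.sqrt(residuals @ residuals))
        # Joint Jacobian: block-diagonal in (tau0_t, K_t), dense in n.
        T = len(data)
        n_obs = residuals.size
        J = np.zeros((n_obs, 2 * T + 1))
        row = 0
        for t, (gamma, tau0, K) in enumerate(jac_blocks):
            Jt = _hb_jacobian(gamma, tau0, K, n)
            m = gamma.size
            J[row : row + m, 2 * t : 2 * t + 2] = Jt[:, :2]
            J[row : row + m, -1] = Jt[:, 2]
            row += m
        names = [f"{p}_{t}" for t in range(T) for p in ("tau0", "K")] + ["n"]
        self.stderr_ = _covariance_stderr(J, residuals, names)
        for t, f in enumerate(fits):
            f.stderr.update(
                tau0=self.stderr_.get(f"tau0_{t}", np.inf),
                K=self.stderr_.get(f"K_{t}", np.inf),
                n=self.stderr_.get("n", np.inf),
            )
        self.fits_ = fits
        return self


def fit_hb(lfc, n_fixed: float | None = None) -> HBFit:
    """Fit one local flow curve; thin wrapper over :class:`HerschelBulkley`."""
    gamma, sigma, tstamp = _curve_arrays(lfc)
    est = HerschelBulkley(n_fixed=n_fixed).fit(gamma, sigma)
    return HBFit(
        params=HBParams(est.tau0_, max(est.K_, np.finfo(float).tiny), est.n_),
        stderr=est.stderr_,
        residual_norm=est.residual_norm_,
        time_stamp=tstamp,
        shared_n=n_fixed is not None,
    )


def fit_hb_global_n(lfcs) -> list[HBFit]:
    """Joint fit with one shared flow index; wrapper over GlobalFlowIndexHB."""
    return GlobalFlowIndexHB().fit(lfcs).fits_


@dataclass(frozen=True)
class DimensionlessFlow:
    """Capillary-number representation of the viscous branch of a flow curve."""

    capillary_number: np.ndarray
    scaled_viscous_stress: np.ndarray


def dimensionless_viscous_stress(
    hbfit, props: EmulsionProperties, gamma_dot
) -> DimensionlessFlow:
    """Scale the viscous stress tau_v = K gamma_dot**n to droplet units.

    Ca = mu gamma_dot R / sigma_i and tau_v~ = tau_v R / sigma_i with
    sigma_i the interfacial tension and R the mean droplet radius.
    """
    params = hbfit.params if isinstance(hbfit, HBFit) else hbfit
    gamma = np.asarray(gamma_dot, dtype=float)
    tau_v = params.consistency * gamma**params.flow_index
    scale = props.droplet_radius / props.interfacial_tension
    ca = props.continuous_phase_viscosity * gamma * scale
    return DimensionlessFlow(capillary_number=ca, scaled_viscous_stress=tau_v * scale)
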