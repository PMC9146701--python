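"""Stage 5: 2D D-T2 correlation maps by regularized inverse Laplace inversion.

A stimulated-echo PGSE block (diffusion encoding, gradient strength g) is
followed by a CPMG echo train (transverse relaxation, echo time t), giving

    S(g, t) = integral integral F(D, T2) exp(-b(g) D) exp(-t / T2) dD dT2,
    b(g) = gamma^2 g^2 delta^2 (Delta - delta/3).

The map F >= 0 is recovered on a log-spaced (D, T2) grid by Tikhonov-
regularized non-negative least squares,

    min_F  || K1 F K2' - S ||_F^2 + lambda ||F||_F^2,   F >= 0,

after SVD compression of both exponential kernels (their singular values
decay fast, so a handful of components carries all the information). The
solver is FISTA projected gradient with adaptive restart; the problem is
strongly convex for lambda > 0, so the compressed solve matches a
brute-force NNLS solve of the same program.

Only the water component (highest diffusivity) is read out quantitatively:
restricted oil diffusion violates the exponential-kernel assumption and
produces spurious structure in the oil region of the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import linregress
from sklearn.base import BaseEstimator

from .params import PGSEParams


@dataclass(frozen=True)
class DT2Dataset:
    """Measured (or synthetic) decay surface S(gradient, echo time)."""

    gradient_strengths: np.ndarray
    echo_times: np.ndarray
    signal: np.ndarray
    pgse: PGSEParams
    echo_spacing: float | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.gradient_strengths, dtype=float)
        t = np.asarray(self.echo_times, dtype=float)
        S = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "gradient_strengths", g)
        object.__setattr__(self, "echo_times", t)
        object.__setattr__(self, "signal", S)
        if S.shape != (g.size, t.size):
            raise ValueError(
                f"signal shape {S.shape} does not match axes ({g.size}, {t.size})"
            )
        if self.echo_spacing is not None:
            expected = self.echo_spacing * np.arange(1, t.size + 1)
            if not np.allclose(t, expected, rtol=1e-9):
                raise ValueError("echo_times must equal echo_spacing * (1..N)")


@dataclass(frozen=True)
class Peak:
    """One connected component of the map: position of its maximum and mass."""

    D: float
    T2: float
    mass: float
    D_centroid: float
    T2_centroid: float
    T2_mean: float


@dataclass(frozen=True)
class DT2Map:
    """Non-negative amplitude density on a log-spaced (D, T2) grid."""

    D_grid: np.ndarray
    T2_grid: np.ndarray
    amplitude: np.ndarray
    regularization_weight: float
    peaks: tuple = ()
    flags: tuple = ()

    @property
    def total_mass(self) -> float:
        return float(self.amplitude.sum())


@dataclass(frozen=True)
class T2Calibration:
    """Linear T2,w vs protein-concentration calibration."""

    slope: float
    intercept: float
    r_squared: float


def default_d_grid(n: int = 64) -> np.ndarray:
    return np.logspace(-13, -8, n)


def default_t2_grid(n: int = 64) -> np.ndarray:
    return np.logspace(np.log10(1e-3), np.log10(3.0), n)


def _check_log_spaced(grid: np.ndarray, name: str) -> None:
    ratios = np.diff(np.log(grid))
    if np.any(grid <= 0) or np.any(np.abs(ratios - ratios[0]) > 1e-9 * abs(ratios[0])):
        raise ValueError(f"{name} must be positive and log-spaced")


def build_kernels(dataset: DT2Dataset, D_grid, T2_grid):
    """Exponential kernel matrices K1[i,k]=exp(-b_i D_k), K2[j,l]=exp(-t_j/T2_l)."""
    D_grid = np.asarray(D_grid, dtype=float)
    T2_grid = np.asarray(T2_grid, dtype=float)
    _check_log_spaced(D_grid, "D_grid")
    _check_log_spaced(T2_grid, "T2_grid")
    b = dataset.pgse.b_values()
    K1 = np.exp(-np.outer(b, D_grid))
    K2 = np.exp(-np.outer(dataset.echo_times, 1.0 / T2_grid))
    return K1, K2


def _fista_nonneg(K1c, K2c, Sc, lam, F0, max_iter, tol):
    """min_F ||K1c F K2c' - Sc||^2 + lam ||F||^2 s.t. F >= 0 (FISTA + restart)."""
    s1 = np.linalg.norm(K1c, 2)
    s2 = np.linalg.norm(K2c, 2)
    L = 2.0 * ((s1 * s2) ** 2 + lam)
    F = np.clip(F0, 0.0, None)
    Y = F.copy()
    t_mom = 1.0
    A1 = K1c.T @ K1c
    A2 = K2c.T @ K2c
    B = K1c.T @ Sc @ K2c
    for _ in range(max_iter):
        grad = 2.0 * (A1 @ Y @ A2 - B + lam * Y)
        F_new = np.clip(Y - grad / L, 0.0, None)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        step = F_new - F
        if np.vdot(Y - F_new, step) > 0.0:  # adaptive restart
            t_new = 1.0
            Y = F_new.copy()
        else:
            Y = F_new + ((t_mom - 1.0) / t_new) * step
        delta = np.linalg.norm(step)
        F = F_new
        t_mom = t_new
        if delta <= tol * max(np.linalg.norm(F), 1e-30):
            break
    return F


def detect_peaks(
    amplitude: np.ndarray,
    D_grid: np.ndarray,
    T2_grid: np.ndarray,
    cell_floor: float = 1e-3,
    mass_floor: float = 0.01,
) -> tuple:
    """Connected components of the map above a mass threshold.

    Cells below ``cell_floor`` of the maximum cell are discarded, remaining
    cells are grouped by 8-connectivity, and regions holding at least
    ``mass_floor`` of the total mass are reported (sorted by descending
    mass). Each peak carries the grid position of the region maximum, its
    log-domain mass centroid, and the mass-weighted linear mean T2.
    """
    total = amplitude.sum()
    if total <= 0.0:
        return ()
    mask = amplitude > cell_floor * amplitude.max()
    labels, n_regions = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    logD = np.log10(D_grid)[:, None] * np.ones_like(amplitude)
    logT2 = np.log10(T2_grid)[None, :] * np.ones_like(amplitude)
    T2_mat = T2_grid[None, :] * np.ones_like(amplitude)
    peaks = []
    for k in range(1, n_regions + 1):
        region = labels == k
        mass = float(amplitude[region].sum())
        if mass < mass_floor * total:
            continue
        masked = np.where(region, amplitude, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), amplitude.shape)
        w = amplitude[region]
        peaks.append(
            Peak(
                D=float(D_grid[i]),
                T2=float(T2_grid[j]),
                mass=mass,
                D_centroid=float(10 ** (np.sum(w * logD[region]) / mass)),
                T2_centroid=float(10 ** (np.sum(w * logT2[region]) / mass)),
                T2_mean=float(np.sum(w * T2_mat[region]) / mass),
            )
        )
    peaks.sort(key=lambda p: p.mass, reverse=True)
    return tuple(peaks)


class ILT2D(BaseEstimator):
    """Regularized non-negative 2D inverse Laplace inversion.

    Parameters
    ----------
    D_grid, T2_grid : arrays or None
        Log-spaced grids; defaults cover D in [1e-13, 1e-8] m^2/s and
        T2 in [1 ms, 3 s] with 64 points each.
    reg_weight : float or "auto"
        Tikhonov weight lambda; "auto" selects it by the discrepancy
        principle against a noise estimate from the tail of the
        highest-gradient echo train.
    sv_threshold : float
        Relative singular-value cutoff for kernel compression (0 keeps
        every component, making compression exact).

    Fitted attributes: ``F_`` (map, n_D x n_T2), ``reg_weight_``,
    ``residual_``, ``noise_sigma_``, ``peaks_``, ``flags_``.
    """

    def __init__(
        self,
        D_grid=None,
        T2_grid=None,
        reg_weight="auto",
        sv_threshold: float = 1e-8,
        max_iter: int = 20000,
        tol: float = 1e-9,
        discrepancy_factor: float = 1.0,
    ):
        self.D_grid = D_grid
        self.T2_grid = T2_grid
        self.reg_weight = reg_weight
        self.sv_threshold = sv_threshold
        self.max_iter = max_iter
        self.tol = tol
        self.discrepancy_factor = discrepancy_factor

    def _compress(self, K):
        U, s, Vt = np.linalg.svd(K, full_matrices=False)
        keep = s > self.sv_threshold * s[0]
        if not np.any(keep):
            raise RuntimeError(
                f"kernel compression collapsed: no singular value above "
                f"{self.sv_threshold} of s_max"
            )
        r = int(keep.sum())
        return U[:, :r], s[:r, None] * Vt[:r]

    @staticmethod
    def estimate_noise(dataset: DT2Dataset) -> float:
        """Noise level from the tail of the highest-gradient echo train."""
        tail = dataset.signal[-1, -max(dataset.signal.shape[1] // 4, 8):]
        return float(np.std(np.diff(tail)) / np.sqrt(2.0))

    def fit(self, dataset: DT2Dataset, y=None):
        Dg = default_d_grid() if self.D_grid is None else np.asarray(self.D_grid, float)
        Tg = default_t2_grid() if self.T2_grid is None else np.asarray(self.T2_grid, float)
        S = dataset.signal
        if not np.any(S):
            self.F_ = np.zeros((Dg.size, Tg.size))
            self.D_grid_, self.T2_grid_ = Dg, Tg
            self.reg_weight_ = 0.0
            self.residual_ = 0.0
            self.noise_sigma_ = 0.0
            self.peaks_ = ()
            self.flags_ = ("empty-signal",)
            return self
        K1, K2 = build_kernels(dataset, Dg, Tg)
        U1, K1c = self._compress(K1)
        U2, K2c = self._compress(K2)
        Sc = U1.T @ S @ U2
        self.noise_sigma_ = self.estimate_noise(dataset)
        flags = []
        b = dataset.pgse.b_values()
        b_small = b[b > 0].min() if np.any(b > 0) else 0.0
        if b_small > 0 and Dg.max() > 5.0 / b_small:
            flags.append("d-grid-exceeds-gradient-encoding")
        if Tg.max() > 10.0 * dataset.echo_times.max():
            flags.append("t2-grid-exceeds-echo-window")

        F0 = np.zeros((Dg.size, Tg.size))
        if self.reg_weight == "auto":
            lam, F = self._auto_lambda(K1c, K2c, Sc, F0)
        else:
            lam = float(self.reg_weight)
            F = _fista_nonneg(K1c, K2c, Sc, lam, F0, self.max_iter, self.tol)
        self.D_grid_, self.T2_grid_ = Dg, Tg
        self.F_ = F
        self.reg_weight_ = lam
        self.residual_ = float(np.linalg.norm(K1c @ F @ K2c.T - Sc))
        self.peaks_ = detect_peaks(F, Dg, Tg)
        self.flags_ = tuple(flags)
        return self

    def _auto_lambda(self, K1c, K2c, Sc, F0):
        """Discrepancy principle: residual ~ noise norm in the compressed space."""
        m1, m2 = Sc.shape
        target = self.discrepancy_factor * self.noise_sigma_ * np.sqrt(m1 * m2)
        smax2 = (np.linalg.norm(K1c, 2) * np.linalg.norm(K2c, 2)) ** 2
        lams = smax2 * np.logspace(-10, 0, 21)
        F = F0
        prev = None
        for lam in lams:
            F = _fista_nonneg(K1c, K2c, Sc, lam, F, self.max_iter, self.tol)
            res = np.linalg.norm(K1c @ F @ K2c.T - Sc)
            if res >= target:
                if prev is None:
                    return lam, F
                # bisect in log-lambda between the bracketing pair
                lo, hi = prev[0], lam
                for _ in range(12):
                    mid = np.sqrt(lo * hi)
                    F = _fista_nonneg(K1c, K2c, Sc, mid, F, self.max_iter, self.tol)
                    if np.linalg.norm(K1c @ F @ K2c.T - Sc) >= target:
                        hi = mid
                    else:
                        lo = mid
                F = _fista_nonneg(K1c, K2c, Sc, hi, F, self.max_iter, self.tol)
                return hi, F
            prev = (lam, F)
        return lams[-1], F

    def to_map(self) -> DT2Map:
        return DT2Map(
            D_grid=self.D_grid_,
            T2_grid=self.T2_grid_,
            amplitude=self.F_,
            regularization_weight=self.reg_weight_,
            peaks=self.peaks_,
            flags=self.flags_,
        )


def ilt2d(dataset: DT2Dataset, D_grid=None, T2_grid=None, reg_weight="auto",
          **kwargs) -> DT2Map:
    """Invert a decay surface to a D-T2 map; wrapper over :class:`ILT2D`."""
    est = ILT2D(D_grid=D_grid, T2_grid=T2_grid, reg_weight=reg_weight, **kwargs)
    return est.fit(dataset).to_map()


def extract_water_peak(dt2_map: DT2Map):
    """(D_w, T2_w, mass) of the aqueous-phase component.

    Among the detected peaks the one with the highest diffusion coefficient
    is taken as water (free-water-like mobility); equal-D ties break towards
    the larger mass. T2_w is the mass-weighted mean T2 of the region.
    """
    if not dt2_map.peaks:
        raise ValueError("no peaks above threshold in the map")
    best = max(dt2_map.peaks, key=lambda p: (p.D, p.mass))
    return best.D, best.T2_mean, best.mass


def t2_concentration_fit(concentrations, t2w_values) -> T2Calibration:
    """Ordinary least-squares line T2,w(c); needs >= 3 concentrations."""
    c = np.asarray(concentrations, dtype=float)
    t2 = np.asarray(t2w_values, dtype=float)
    if c.size < 3 or c.size != t2.size:
        raise ValueError("need >= 3 matched (concentration, T2w) points")
    res = linregress(c, t2)
    return T2Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def diffusion_length(D: float, Delta: float) -> float:
    """Root-mean-square 1D displacement sqrt(2 D Delta)."""
    if D <= 0.0 or Delta < 0.0:
        raise ValueError("need D > 0 and Delta >= 0")
    return float(np.sqrt(2.0 * D * Delta))
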