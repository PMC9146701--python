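"""Physical parameter containers shared across the pipeline.

All quantities are SI unless a field name says otherwise (droplet diameters
are carried in micrometres because that is the unit the instrument software
and the food-emulsion literature report them in).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.675221874e8


@dataclass(frozen=True)
class CouetteGeometry:
    """Concentric-cylinder (Couette) cell.

    Defaults describe a narrow-gap cell with 20/22 mm inner/outer diameter
    (1 mm gap). The cell height is a configurable instrument constant; only
    quantities that use a consistent height are physically meaningful.
    """

    inner_radius: float = 10.0e-3
    outer_radius: float = 11.0e-3
    height: float = 40.0e-3

    def __post_init__(self) -> None:
        if not 0.0 < self.inner_radius < self.outer_radius:
            raise ValueError(
                "require 0 < inner_radius < outer_radius, got "
                f"{self.inner_radius!r}, {self.outer_radius!r}"
            )
        if self.height <= 0.0:
            raise ValueError(f"height must be positive, got {self.height!r}")

    @property
    def gap(self) -> float:
        return self.outer_radius - self.inner_radius

    def rotor_rate_for_applied_shear(self, applied_rate: float) -> float:
        """Rotor angular velocity (rad/s) for a nominal applied shear rate.

        Uses the narrow-gap convention Omega = gamma_dot * gap / Ri.
        """
        return applied_rate * self.gap / self.inner_radius


@dataclass(frozen=True)
class HBParams:
    """Herschel-Bulkley constitutive law: sigma = tau0 + K * gamma_dot**n."""

    yield_stress: float
    consistency: float
    flow_index: float

    def __post_init__(self) -> None:
        if self.yield_stress < 0.0:
            raise ValueError("yield_stress must be >= 0")
        if self.consistency <= 0.0:
            raise ValueError("consistency must be > 0")
        if not 0.0 < self.flow_index <= 2.0:
            raise ValueError("flow_index must be in (0, 2]")

    def stress(self, gamma_dot):
        g = np.asarray(gamma_dot, dtype=float)
        return self.yield_stress + self.consistency * g**self.flow_index

    def shear_rate(self, sigma):
        """Invert the law; zero below the yield stress."""
        s = np.asarray(sigma, dtype=float)
        excess = np.clip(s - self.yield_stress, 0.0, None)
        return (excess / self.consistency) ** (1.0 / self.flow_index)


@dataclass(frozen=True)
class SKMParams:
    """Second-order structural-kinetic decay of the yield stress.

    tau0(t) = (tau00 - tau0e) / (ks * t + 1) + tau0e

    ``ks`` is in the inverse of whatever unit the time axis uses; the model
    never converts time units.
    """

    tau00: float
    tau0e: float
    ks: float

    def __post_init__(self) -> None:
        if not self.tau00 >= self.tau0e >= 0.0:
            raise ValueError("require tau00 >= tau0e >= 0")
        if self.ks < 0.0:
            raise ValueError("ks must be >= 0")

    def tau0(self, times):
        t = np.asarray(times, dtype=float)
        return (self.tau00 - self.tau0e) / (self.ks * t + 1.0) + self.tau0e

    @property
    def breakdown_ratio(self) -> float:
        if self.tau0e == 0.0:
            raise ZeroDivisionError("tau0e is zero; breakdown ratio undefined")
        return self.tau00 / self.tau0e


@dataclass(frozen=True)
class PGSEParams:
    """Pulsed-gradient spin-echo encoding parameters.

    gradient_strengths in T/m (non-negative, strictly increasing),
    gradient_duration delta and diffusion_time Delta in seconds.
    """

    gradient_strengths: tuple
    gradient_duration: float
    diffusion_time: float
    gyromagnetic_ratio: float = GAMMA_H

    def __post_init__(self) -> None:
        g = np.asarray(self.gradient_strengths, dtype=float)
        object.__setattr__(self, "gradient_strengths", tuple(g.tolist()))
        if self.gradient_duration <= 0.0:
            raise ValueError("gradient_duration must be > 0")
        if self.diffusion_time <= self.gradient_duration:
            raise ValueError("diffusion_time must exceed gradient_duration")
        if g.size and (np.any(g < 0.0) or np.any(np.diff(g) <= 0.0)):
            raise ValueError(
                "gradient strengths must be non-negative and strictly increasing"
            )

    @property
    def g(self) -> np.ndarray:
        return np.asarray(self.gradient_strengths, dtype=float)

    def b_values(self) -> np.ndarray:
        """Stejskal-Tanner b-factor gamma^2 g^2 delta^2 (Delta - delta/3), s/m^2."""
        gam, d, D = self.gyromagnetic_ratio, self.gradient_duration, self.diffusion_time
        return gam**2 * self.g**2 * d**2 * (D - d / 3.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded Gaussian noise.

    kind "additive-gaussian": adds sigma (absolute units of the signal).
    kind "multiplicative-gaussian": multiplies by (1 + sigma * N(0,1)),
    i.e. sigma is a fractional level.
    """

    kind: str = "additive-gaussian"
    sigma: float = 0.0
    seed: int = 0

    _KINDS = ("additive-gaussian", "multiplicative-gaussian")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.sigma < 0.0:
            raise ValueError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values, rng: np.random.Generator | None = None) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.sigma == 0.0:
            return v.copy()
        if rng is None:
            rng = self.rng()
        draw = rng.standard_normal(v.shape)
        if self.kind == "additive-gaussian":
            return v + self.sigma * draw
        return v * (1.0 + self.sigma * draw)


@dataclass(frozen=True)
class EmulsionProperties:
    """Material constants used for the dimensionless (capillary) scaling."""

    interfacial_tension: float
    continuous_phase_viscosity: float
    droplet_radius: float
    volume_fraction: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "interfacial_tension",
            "continuous_phase_viscosity",
            "droplet_radius",
            "volume_fraction",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.volume_fraction >= 1.0:
            raise ValueError("volume_fraction must be < 1")
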