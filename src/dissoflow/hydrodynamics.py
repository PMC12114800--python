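"""Channel hydrodynamics: Reynolds number, laminar profile, Blasius solution.

The flow channel is a rectangular duct; the Reynolds number uses the full
channel height H as characteristic length, Re = u_mean * H / nu, with nu
the kinematic viscosity of water at the working temperature.  Velocities
are always quoted as cross-section mean velocities.

The Blasius flat-plate similarity solution (f''' + f f''/2 = 0 with
f(0) = f'(0) = 0, f'(inf) = 1) supplies the theoretical reference for the
hydrodynamic boundary layer: its 99% thickness scales as
delta_99 = eta_99 * sqrt(nu x / U), i.e. as Re_x^-1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .substances import water_properties

__all__ = [
    "BlasiusSolution",
    "ChannelGeometry",
    "FlowState",
    "blasius_similarity",
    "poiseuille_profile",
    "reynolds_number",
    "velocity_from_reynolds",
]


@dataclass(frozen=True)
class ChannelGeometry:
    """Flow channel geometry (lengths in mm, volume in mL)."""

    full_height_mm: float = 5.0
    inlet_length_mm: float = 9.0
    tablet_length_mm: float = 8.0
    outlet_length_mm: float = 9.0
    tablet_diameter_mm: float = 8.0
    medium_volume_ml: float = 900.0

    def __post_init__(self) -> None:
        for name in ("full_height_mm", "inlet_length_mm", "tablet_length_mm",
                     "outlet_length_mm", "tablet_diameter_mm",
                     "medium_volume_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def half_height_mm(self) -> float:
        return self.full_height_mm / 2.0

    @property
    def tablet_area_m2(self) -> float:
        """Exposed circular tablet face area, m^2."""
        r_m = self.tablet_diameter_mm * 1e-3 / 2.0
        return np.pi * r_m**2


@dataclass(frozen=True)
class FlowState:
    """A flow operating point: Re, mean velocity and temperature."""

    reynolds: float
    mean_velocity: float  # m/s
    temperature_C: float

    def __post_init__(self) -> None:
        if (self.reynolds > 0) != (self.mean_velocity > 0):
            raise ValueError("Re and mean velocity must be both zero or both positive")
        if self.reynolds < 0 or self.mean_velocity < 0:
            raise ValueError("Re and mean velocity must be non-negative")

    @classmethod
    def from_reynolds(
        cls, reynolds: float, geometry: ChannelGeometry, temperature_C: float
    ) -> "FlowState":
        u = velocity_from_reynolds(reynolds, geometry, temperature_C)
        return cls(reynolds=reynolds, mean_velocity=u, temperature_C=temperature_C)

    @classmethod
    def from_velocity(
        cls, mean_velocity: float, geometry: ChannelGeometry, temperature_C: float
    ) -> "FlowState":
        re = reynolds_number(mean_velocity, geometry, temperature_C)
        return cls(reynolds=re, mean_velocity=mean_velocity,
                   temperature_C=temperature_C)


def reynolds_number(
    mean_velocity: float,
    geometry: ChannelGeometry = ChannelGeometry(),
    temperature_C: float = 37.0,
) -> float:
    """Re = u_mean * H / nu with H the full channel height."""
    if mean_velocity < 0:
        raise ValueError("mean velocity must be non-negative")
    nu = water_properties(temperature_C).kinematic_viscosity
    return mean_velocity * geometry.full_height_mm * 1e-3 / nu


def velocity_from_reynolds(
    reynolds: float,
    geometry: ChannelGeometry = ChannelGeometry(),
    temperature_C: float = 37.0,
) -> float:
    """Exact inverse of :func:`reynolds_number` (m/s)."""
    if reynolds < 0:
        raise ValueError("Re must be non-negative")
    nu = water_properties(temperature_C).kinematic_viscosity
    return reynolds * nu / (geometry.full_height_mm * 1e-3)


def poiseuille_profile(
    y: float | np.ndarray, mean_velocity: float, half_height: float
) -> float | np.ndarray:
    """Plane-Poiseuille velocity at wall distance ``y`` (same units as
    ``half_height``); u(0) = 0, u(half_height) = 1.5 u_mean (centerline).

    u(y) = 1.5 * u_mean * (2 s - s^2) with s = y / half_height; the upper
    half of the channel is the mirror image (symmetry plane at the
    centerline).
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0) or np.any(y_arr > half_height):
        raise ValueError("y must lie in [0, half_height]")
    s = y_arr / half_height
    u = 1.5 * mean_velocity * (2.0 * s - s**2)
    return float(u) if np.isscalar(y) else u


@dataclass(frozen=True)
class BlasiusSolution:
    """Blasius similarity solution on an eta grid.

    ``delta99_coefficient`` is eta_99, the similarity coordinate where
    f' = 0.99, so delta_99(x) = eta_99 * sqrt(nu x / U); the thickness
    exponent with respect to Re_x is -1/2.
    """

    eta: np.ndarray
    f: np.ndarray
    f_prime: np.ndarray
    f_double_prime: np.ndarray
    wall_shear_constant: float  # f''(0)
    delta99_coefficient: float  # eta_99
    thickness_exponent: float  # -0.5

    def delta99(self, x: float, free_stream_velocity: float, nu: float) -> float:
        """99% boundary-layer thickness at position x (m)."""
        return self.delta99_coefficient * np.sqrt(
            nu * x / free_stream_velocity
        )


def _integrate_blasius(fpp0: float, eta_max: float, rtol: float = 1e-11):
    def rhs(_eta, state):
        f, fp, fpp = state
        return [fp, fpp, -0.5 * f * fpp]

    return solve_ivp(
        rhs, (0.0, eta_max), [0.0, 0.0, fpp0],
        method="RK45", rtol=rtol, atol=1e-12, dense_output=True,
    )


def blasius_similarity(
    eta_max: float = 10.0, tol: float = 1e-8, n_grid: int = 501
) -> BlasiusSolution:
    """Solve the Blasius equation by shooting on f''(0).

    A bracketing secant iteration drives f'(eta_max) to 1 within ``tol``.
    """
    lo, hi = 0.1, 1.0

    def shoot(fpp0: float) -> float:
        sol = _integrate_blasius(fpp0, eta_max)
        return sol.y[1, -1] - 1.0

    f_lo, f_hi = shoot(lo), shoot(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"Blasius shooting bracket failed: f'({lo})-1={f_lo:.3g}, "
            f"f'({hi})-1={f_hi:.3g}"
        )
    a, b, fa, fb = lo, hi, f_lo, f_hi
    fpp0 = 0.5 * (a + b)
    for _ in range(100):
        # secant step, clipped to the bracket (falls back to bisection)
        fpp0 = b - fb * (b - a) / (fb - fa)
        if not a < fpp0 < b:
            fpp0 = 0.5 * (a + b)
        fc = shoot(fpp0)
        if abs(fc) < tol:
            break
        if fa * fc < 0:
            b, fb = fpp0, fc
        else:
            a, fa = fpp0, fc
    else:
        raise RuntimeError(
            f"Blasius shooting did not converge: residual {fc:.3g} after 100 "
            "iterations"
        )

    sol = _integrate_blasius(fpp0, eta_max)
    eta = np.linspace(0.0, eta_max, n_grid)
    f, fp, fpp = sol.sol(eta)

    # eta where f' crosses 0.99, by inverse interpolation on the dense grid
    idx = int(np.searchsorted(fp, 0.99))
    e0, e1 = eta[idx - 1], eta[idx]
    p0, p1 = fp[idx - 1], fp[idx]
    eta99 = e0 + (0.99 - p0) * (e1 - e0) / (p1 - p0)

    return BlasiusSolution(
        eta=eta, f=f, f_prime=fp, f_double_prime=fpp,
        wall_shear_constant=fpp0,
        delta99_coefficient=float(eta99),
        thickness_exponent=-0.5,
    )
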