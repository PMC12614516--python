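"""Kelvin-Voigt fractional-derivative (KVFD) forward model.

The KVFD model describes a spring (relaxed Young's modulus ``E0``) in
parallel with a fractional-order dashpot (viscosity ``eta``, order
``alpha``), yielding the complex Young's modulus

    E*(f) = E0 + eta * (j * 2*pi*f)**alpha
          = [E0 + eta*(2*pi*f)**alpha * cos(pi*alpha/2)]
            + j [eta*(2*pi*f)**alpha * sin(pi*alpha/2)]

Real and imaginary parts are the storage and loss moduli E', E''.  The
loss angle is ``delta = arctan(E''/E')``.  Under the plane shear-wave
equation the complex wavenumber is ``k = omega * sqrt(2*(1+nu)*rho / E*)``
(for an incompressible medium, nu = 0.5, the familiar factor 3 appears),
from which phase velocity ``c_s = omega / Re(k)`` and attenuation
``alpha_att = -Im(k)`` follow.  A loss-aware closed form that avoids
complex arithmetic,

    c_s = sqrt( 2*(E'^2 + E''^2) / (2*(1+nu)*rho * (|E*| + E')) ),

is used as the primary implementation; its equivalence to the complex
route is asserted in the test suite.

All quantities are SI internally (Pa, Pa*s**alpha, kg/m^3, Hz, m/s);
reporting layers convert to kPa and degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "KVFDParams",
    "ComplexModulusSample",
    "ComplexWavenumber",
    "storage_loss",
    "complex_modulus",
    "loss_angle",
    "phase_velocity",
    "attenuation",
    "wavenumber",
    "velocity_from_shear_moduli",
    "young_shear_convert",
    "inflation_factor",
]


@dataclass(frozen=True)
class KVFDParams:
    """Material parameters of the KVFD model plus medium constants.

    Parameters
    ----------
    E0 : float
        Relaxed (zero-frequency) Young's modulus, Pa.  Must be positive.
    eta : float
        Fractional viscosity, Pa*s**alpha.  Must be nonnegative.
    alpha : float
        Fractional derivative order, dimensionless, open interval (0, 1).
        The classical limits alpha = 0 (pure spring offset) and alpha = 1
        (Newtonian dashpot) are admitted only with ``allow_limit_alpha``.
    rho : float
        Mass density, kg/m^3 (default 1000, water-like soft-tissue phantom).
    nu : float
        Poisson's ratio in [0, 0.5] (default 0.5, incompressible).
    allow_limit_alpha : bool
        Permit alpha in {0, 1} as explicit limiting cases.
    """

    E0: float
    eta: float
    alpha: float
    rho: float = 1000.0
    nu: float = 0.5
    allow_limit_alpha: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.E0 > 0:
            raise ParameterError(f"E0 must be > 0 Pa, got {self.E0}")
        if self.eta < 0:
            raise ParameterError(f"eta must be >= 0 Pa*s^alpha, got {self.eta}")
        lo, hi = (0.0, 1.0)
        ok = lo < self.alpha < hi or (
            self.allow_limit_alpha and self.alpha in (lo, hi)
        )
        if not ok:
            raise ParameterError(
                f"alpha must lie in (0, 1) (limits 0/1 need allow_limit_alpha), "
                f"got {self.alpha}"
            )
        if not self.rho > 0:
            raise ParameterError(f"rho must be > 0 kg/m^3, got {self.rho}")
        if not 0.0 <= self.nu <= 0.5:
            raise ParameterError(f"nu must lie in [0, 0.5], got {self.nu}")

    def with_(self, **kwargs) -> "KVFDParams":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ComplexModulusSample:
    """Complex Young's modulus evaluated at one frequency (or an array)."""

    f: np.ndarray | float
    E_storage: np.ndarray | float
    E_loss: np.ndarray | float
    E_mag: np.ndarray | float
    delta: np.ndarray | float  # loss angle, radians


@dataclass(frozen=True)
class ComplexWavenumber:
    """Complex shear wavenumber k = beta - i*alpha_att at one frequency."""

    f: np.ndarray | float
    beta: np.ndarray | float  # rad/m
    alpha_att: np.ndarray | float  # Np/m


def _stiffness_factor(nu: float) -> float:
    # E = 2(1+nu) G; for nu = 0.5 this is the familiar 3.
    return 2.0 * (1.0 + nu)


def _check_freq(f, allow_zero: bool):
    f = np.asarray(f, dtype=float)
    if np.any(~np.isfinite(f)):
        raise ParameterError("frequencies must be finite")
    if allow_zero:
        if np.any(f < 0):
            raise ParameterError("frequencies must be >= 0 Hz")
    else:
        if np.any(f <= 0):
            raise ParameterError("frequencies must be > 0 Hz")
    return f


def storage_loss(params: KVFDParams, f) -> tuple[np.ndarray, np.ndarray]:
    """Storage and loss Young's moduli E'(f), E''(f) in Pa.

    E'(f)  = E0 + eta*(2*pi*f)**alpha * cos(pi*alpha/2)
    E''(f) = eta*(2*pi*f)**alpha * sin(pi*alpha/2)
    """
    f = _check_freq(f, allow_zero=True)
    w = 2.0 * np.pi * f
    wa = np.where(w > 0, w, 1.0) ** params.alpha
    wa = np.where(w > 0, wa, 0.0 if params.alpha > 0 else 1.0)
    half = np.pi * params.alpha / 2.0
    e_sto = params.E0 + params.eta * wa * np.cos(half)
    e_loss = params.eta * wa * np.sin(half)
    return e_sto, e_loss


def complex_modulus(params: KVFDParams, f) -> ComplexModulusSample:
    """Full complex-modulus sample: E', E'', |E*| and loss angle (radians)."""
    f = _check_freq(f, allow_zero=True)
    e_sto, e_loss = storage_loss(params, f)
    mag = np.hypot(e_sto, e_loss)
    delta = np.arctan2(e_loss, e_sto)
    return ComplexModulusSample(f=f, E_storage=e_sto, E_loss=e_loss,
                                E_mag=mag, delta=delta)


def loss_angle(params: KVFDParams, f) -> np.ndarray:
    """Loss angle delta(f) = arctan(E''/E') in radians."""
    return complex_modulus(params, f).delta


def phase_velocity(params: KVFDParams, f) -> np.ndarray:
    """Loss-aware shear phase velocity c_s(f) in m/s.

    c_s = sqrt( 2 (E'^2 + E''^2) / (2(1+nu) rho (sqrt(E'^2+E''^2) + E')) )

    Defined for propagating waves only; raises on f <= 0.
    """
    f = _check_freq(f, allow_zero=False)
    e_sto, e_loss = storage_loss(params, f)
    mag2 = e_sto * e_sto + e_loss * e_loss
    denom = _stiffness_factor(params.nu) * params.rho * (np.sqrt(mag2) + e_sto)
    return np.sqrt(2.0 * mag2 / denom)


def attenuation(params: KVFDParams, f) -> np.ndarray:
    """Shear attenuation coefficient alpha_att(f) in Np/m.

    alpha_att = omega * sqrt( 2(1+nu) rho / 2 * (|E*| - E') / |E*|^2 );
    equal to -Im(k) of :func:`wavenumber`, and zero iff eta = 0.
    """
    f = _check_freq(f, allow_zero=False)
    w = 2.0 * np.pi * f
    e_sto, e_loss = storage_loss(params, f)
    mag = np.hypot(e_sto, e_loss)
    # |E*| - E' rewritten as E''^2 / (|E*| + E') to avoid cancellation
    # in the small-loss regime
    inner = (
        _stiffness_factor(params.nu) * params.rho / 2.0
        * e_loss**2 / ((mag + e_sto) * mag**2)
    )
    return w * np.sqrt(inner)


def wavenumber(params: KVFDParams, f) -> ComplexWavenumber:
    """Complex wavenumber k(f) = beta - i*alpha_att via the complex route.

    k = omega * sqrt(2(1+nu) rho / E*(omega)), principal branch, with the
    sign fixed so that beta > 0 (outgoing wave) and alpha_att >= 0.
    """
    f = _check_freq(f, allow_zero=True)
    w = 2.0 * np.pi * f
    wa = np.where(w > 0, w, 1.0)
    e_star = params.E0 + params.eta * (1j * wa) ** params.alpha
    k = w * np.sqrt(_stiffness_factor(params.nu) * params.rho / e_star)
    k = np.where(np.real(k) < 0, -k, k)
    k = np.where(w > 0, k, 0.0 + 0.0j)
    return ComplexWavenumber(f=f, beta=np.real(k), alpha_att=-np.imag(k))


def velocity_from_shear_moduli(Gp, Gpp, rho: float) -> np.ndarray:
    """Shear-wave speed from measured storage/loss shear moduli (rheometry).

    c_s = sqrt( 2 (G'^2 + G''^2) / (rho G' (1 + sqrt(1 + (G''/G')^2))) )
    """
    Gp = np.asarray(Gp, dtype=float)
    Gpp = np.asarray(Gpp, dtype=float)
    if np.any(Gp <= 0):
        raise ParameterError("storage modulus G' must be > 0 Pa")
    if np.any(Gpp < 0):
        raise ParameterError("loss modulus G'' must be >= 0 Pa")
    if not rho > 0:
        raise ParameterError("rho must be > 0 kg/m^3")
    num = 2.0 * (Gp * Gp + Gpp * Gpp)
    den = rho * Gp * (1.0 + np.sqrt(1.0 + (Gpp / Gp) ** 2))
    return np.sqrt(num / den)


def young_shear_convert(
    value,
    nu: float,
    direction: Literal["shear_to_young", "young_to_shear"],
):
    """Convert between shear and Young's moduli via E = 2 (1 + nu) G.

    Applies componentwise, so complex moduli convert unchanged in phase.
    """
    if not 0.0 <= nu <= 0.5:
        raise ParameterError(f"nu must lie in [0, 0.5], got {nu}")
    factor = _stiffness_factor(nu)
    value = np.asarray(value)
    if direction == "shear_to_young":
        return value * factor
    if direction == "young_to_shear":
        return value / factor
    raise ParameterError(f"unknown direction {direction!r}")


def inflation_factor(delta) -> np.ndarray:
    """Phase-velocity inflation factor F = 1 / cos(delta/2), delta in radians.

    F quantifies how much the lossy phase velocity exceeds the lossless
    sqrt(E'/(3 rho)) value; percent inflation is (F - 1) * 100.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0) or np.any(delta >= np.pi):
        raise ParameterError("loss angle must lie in [0, pi) radians")
    return 1.0 / np.cos(delta / 2.0)
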