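"""Forward acoustic models for a viscoelastic film on a quartz sensor in liquid.

The quartz crystal microbalance with dissipation monitoring (QCM-D) reads out
per-overtone shifts of resonance frequency (``delta_f``, Hz) and dissipation
(``delta_d``, dimensionless) as material couples to the sensor.  Two forward
models are provided:

* the Sauerbrey relation for thin rigid films, where ``-delta_f`` is
  proportional to areal mass, and
* a single-layer Voigt (Voinova) viscoelastic model in the thin-film limit,
  which captures the frequency *underestimation* and finite dissipation of
  soft hydrated films such as supported vesicle layers (SVLs).

Shifts are referenced to the bare sensor already immersed in buffer, so the
bulk-liquid loading terms cancel and only the film contribution remains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import DegenerateLayerError, InvalidOvertoneError

#: kg·m⁻² → ng·cm⁻² conversion factor.
KG_M2_TO_NG_CM2 = 1e8


def _check_overtone(n: int) -> None:
    if not isinstance(n, (int,)) or isinstance(n, bool):
        # allow numpy integer scalars
        try:
            if int(n) != n:
                raise InvalidOvertoneError(f"overtone must be an integer, got {n!r}")
            n = int(n)
        except (TypeError, ValueError):
            raise InvalidOvertoneError(f"overtone must be an integer, got {n!r}") from None
    if n <= 0 or n % 2 == 0:
        raise InvalidOvertoneError(f"overtone must be an odd positive integer, got {n}")


@dataclass(frozen=True)
class CrystalParams:
    """Quartz sensor constants.

    Parameters
    ----------
    f0 : float
        Fundamental resonance frequency in Hz.  Default 5 MHz (standard
        AT-cut sensor).
    zq : float
        Acoustic impedance of quartz, kg·m⁻²·s⁻¹.  Default 8.8e6.
    c_sauerbrey : float, optional
        Mass sensitivity constant in ng·cm⁻²·Hz⁻¹.  When omitted it is
        derived as ``zq / (2 f0²)`` converted to ng·cm⁻², ≈17.6 for a 5 MHz
        sensor.  A supplied value more than 5% away from the derived one
        triggers a warning (cross-check, not an error).
    """

    f0: float = 5e6
    zq: float = 8.8e6
    c_sauerbrey: float = field(default=0.0)

    def __post_init__(self):
        if self.f0 <= 0 or self.zq <= 0:
            raise ValueError("f0 and zq must be strictly positive")
        derived = self.zq / (2.0 * self.f0**2) * KG_M2_TO_NG_CM2
        if self.c_sauerbrey == 0.0:
            object.__setattr__(self, "c_sauerbrey", derived)
        elif self.c_sauerbrey <= 0:
            raise ValueError("c_sauerbrey must be strictly positive")
        elif abs(self.c_sauerbrey - derived) / derived > 0.05:
            warnings.warn(
                f"c_sauerbrey={self.c_sauerbrey:.3g} deviates >5% from "
                f"zq/(2 f0^2)={derived:.3g} ng·cm⁻²·Hz⁻¹",
                stacklevel=2,
            )

    @property
    def areal_mass_quartz(self) -> float:
        """Effective quartz areal mass ρq·hq = zq/(2 f0), kg·m⁻²."""
        return self.zq / (2.0 * self.f0)


@dataclass(frozen=True)
class BulkLiquid:
    """Newtonian bulk liquid above the film (density kg·m⁻³, viscosity Pa·s)."""

    rho_b: float = 1000.0
    eta_b: float = 1e-3

    def __post_init__(self):
        if self.rho_b <= 0 or self.eta_b <= 0:
            raise ValueError("bulk density and viscosity must be strictly positive")

    def penetration_depth(self, omega: float) -> float:
        """Viscous penetration depth δ = sqrt(2 η_b / (ρ_b ω)) in metres."""
        return math.sqrt(2.0 * self.eta_b / (self.rho_b * omega))


@dataclass(frozen=True)
class ViscoelasticLayer:
    """Single uniform Voigt film: density ρ, thickness L, viscosity η, shear modulus μ.

    The robustly identifiable quantity in QCM-D inversion is the areal mass
    ρ·L; ρ and L individually suffer a well-known degeneracy.
    """

    rho: float
    thickness: float
    eta: float
    mu: float

    def __post_init__(self):
        if min(self.rho, self.thickness, self.eta, self.mu) < 0:
            raise ValueError("layer parameters must be nonnegative")

    @property
    def areal_mass(self) -> float:
        """ρ·L in kg·m⁻²."""
        return self.rho * self.thickness

    @property
    def areal_mass_ng_cm2(self) -> float:
        return self.areal_mass * KG_M2_TO_NG_CM2


@dataclass(frozen=True)
class OvertoneMeasurement:
    """One (n, Δf, ΔD) reading; ΔD stored as a pure number (not 1e-6 units)."""

    n: int
    delta_f: float
    delta_d: float

    def __post_init__(self):
        _check_overtone(self.n)


def voigt_forward(
    layer: ViscoelasticLayer,
    bulk: BulkLiquid,
    crystal: CrystalParams,
    n: int,
) -> tuple[float, float]:
    """Per-overtone (Δf, ΔD) of a thin Voigt film under bulk liquid.

    Thin-film (L ≪ δ) truncation of the Voinova solution, with shifts
    referenced to the sensor in buffer so bulk-only terms drop out:

    .. math::

        \\Delta f = -\\frac{1}{2\\pi \\rho_q h_q}\\left[ L\\rho\\omega
            - 2L\\left(\\frac{\\eta_b}{\\delta}\\right)^2
              \\frac{\\eta\\omega^2}{\\mu^2 + \\omega^2\\eta^2} \\right],
        \\qquad
        \\Delta D = \\frac{1}{\\pi n f_0 \\rho_q h_q}\\,
            2L\\left(\\frac{\\eta_b}{\\delta}\\right)^2
            \\frac{\\mu\\omega}{\\mu^2 + \\omega^2\\eta^2}

    with ω = 2π n f0 and δ the viscous penetration depth.  The rigid limit
    (μ → ∞ or η → 0 with μ large) reduces to the Sauerbrey relation.

    Returns ``(0.0, 0.0)`` exactly for a zero-thickness film.  Warns when
    L > δ/2, where the thin-film truncation degrades.
    """
    _check_overtone(n)
    if layer.thickness == 0.0:
        return 0.0, 0.0
    if layer.mu == 0.0 and layer.eta == 0.0:
        raise DegenerateLayerError(
            "film with L > 0 requires eta > 0 or mu > 0 (zero both is unphysical)"
        )
    omega = 2.0 * math.pi * n * crystal.f0
    delta = bulk.penetration_depth(omega)
    if layer.thickness > delta / 2.0:
        warnings.warn(
            f"thickness {layer.thickness:.3g} m exceeds half the penetration depth "
            f"{delta:.3g} m at n={n}; thin-film truncation may be inaccurate",
            stacklevel=2,
        )
    rhoq_hq = crystal.areal_mass_quartz
    lorentz = layer.mu**2 + omega**2 * layer.eta**2
    visc = 2.0 * layer.thickness * (bulk.eta_b / delta) ** 2
    delta_f = -(1.0 / (2.0 * math.pi * rhoq_hq)) * (
        layer.thickness * layer.rho * omega - visc * layer.eta * omega**2 / lorentz
    )
    delta_d = (1.0 / (math.pi * n * crystal.f0 * rhoq_hq)) * (
        visc * layer.mu * omega / lorentz
    )
    return delta_f, delta_d


def sauerbrey_mass(
    delta_f: float,
    n: int,
    crystal: CrystalParams,
    mode: str = "classic",
) -> float:
    """Areal mass (ng·cm⁻²) from a frequency shift via the Sauerbrey relation.

    ``classic`` uses m = -C·Δf/n (rigid thin film).  ``sqrt_n`` uses
    m = -C·Δf/√n: normalizing overtones by √n rather than n partially
    compensates the mass underestimation of the rigid model on viscous
    layers, where Δf scales more like √n than n.

    Sign convention: a negative Δf (mass added) yields a positive mass.
    """
    _check_overtone(n)
    if mode == "classic":
        return -crystal.c_sauerbrey * delta_f / n
    if mode == "sqrt_n":
        return -crystal.c_sauerbrey * delta_f / math.sqrt(n)
    raise ValueError(f"mode must be 'classic' or 'sqrt_n', got {mode!r}")


def normalize_overtone(delta_f: float, n: int, mode: str = "by_sqrt_n") -> float:
    """Δf normalized by overtone: ``by_n`` → Δf/n, ``by_sqrt_n`` → Δf/√n.

    √n normalization is the conventional display for layers dominated by
    viscous loading.
    """
    _check_overtone(n)
    if mode == "by_n":
        return delta_f / n
    if mode == "by_sqrt_n":
        return delta_f / math.sqrt(n)
    raise ValueError(f"mode must be 'by_n' or 'by_sqrt_n', got {mode!r}")


def sauerbrey_delta_f(areal_mass: float, n: int, crystal: CrystalParams) -> float:
    """Inverse Sauerbrey: Δf (Hz) of a rigid film of given areal mass (kg·m⁻²)."""
    _check_overtone(n)
    return -n * crystal.f0 * areal_mass / crystal.areal_mass_quartz
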