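"""Closed-form viscoelastic model and Stokes-law utilities.

The material model is an *extended Kelvin-Voigt* element: a spring (elastic
modulus ``E``) in parallel with a dashpot (viscosity ``eta2``), the pair in
series with a second dashpot (viscosity ``eta1``) that carries long-time
viscous flow.  Its creep compliance is

    J(t) = (1/E) * (1 - exp(-t * E / eta2)) + t / eta1

and the complex shear modulus follows from the complex compliance
``J*(w) = 1/(E + i w eta2) + 1/(i w eta1)`` via ``G*(w) = 1/J*(w)``.

Internal unit convention: lengths in micrometres, time in seconds, force in
piconewtons, moduli in pascals (1 Pa = 1 pN/um^2).  This keeps every number
within a few orders of magnitude of unity for the soft (~0.1 Pa) networks
this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ViscoelasticParams",
    "StokesContext",
    "creep_compliance",
    "complex_moduli",
    "stokes_drag",
    "stokes_velocity",
    "G0_SI",
    "KBT_ROOM",
    "kbt_at",
]

#: standard gravity, m/s^2 (effective gravity is expressed as a multiple)
G0_SI = 9.81

#: Boltzmann factor at 298 K in internal units, pN*um
KBT_ROOM = 4.11e-3

#: converts (kg/m^3 * m/s^2 * um^3) -> pN for buoyant-weight arithmetic
_WEIGHT_TO_PN = 1e-6


def kbt_at(temperature_K: float) -> float:
    """kB*T in pN*um at the given absolute temperature."""
    if temperature_K < 0:
        raise ValueError(f"temperature must be non-negative, got {temperature_K}")
    return KBT_ROOM * temperature_K / 298.0


@dataclass(frozen=True)
class ViscoelasticParams:
    """Three-parameter extended Kelvin-Voigt material description.

    Parameters
    ----------
    E : float
        Elastic modulus of the Kelvin-Voigt spring, Pa.
    eta2 : float
        Viscosity of the dashpot in parallel with the spring, Pa*s.  Sets
        the retardation time ``tau = eta2 / E``.
    eta1 : float
        Viscosity of the series dashpot, Pa*s; dominates the long-time flow.
    """

    E: float
    eta2: float
    eta1: float

    def __post_init__(self) -> None:
        for name in ("E", "eta2", "eta1"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @property
    def retardation_time(self) -> float:
        """Kelvin-Voigt retardation time eta2/E, s."""
        return self.eta2 / self.E

    def to_dict(self) -> dict:
        return {"E_Pa": self.E, "eta2_Pas": self.eta2, "eta1_Pas": self.eta1}

    @classmethod
    def from_dict(cls, d: dict) -> "ViscoelasticParams":
        return cls(E=d["E_Pa"], eta2=d["eta2_Pas"], eta1=d["eta1_Pas"])


@dataclass(frozen=True)
class StokesContext:
    """Inputs for Stokes-law settling of a dense sphere in a viscous medium.

    radius in um, delta_rho (particle minus medium density) in kg/m^3,
    g_multiple as a dimensionless multiple of standard gravity, viscosity
    in Pa*s.
    """

    radius: float
    delta_rho: float
    g_multiple: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if self.g_multiple < 0:
            raise ValueError(f"g_multiple must be >= 0, got {self.g_multiple}")


def creep_compliance(t, params: ViscoelasticParams):
    """Creep compliance J(t) of the extended Kelvin-Voigt model, 1/Pa.

    ``J(t) = (1/E)(1 - exp(-t E / eta2)) + t/eta1``.  J(0) = 0, J is strictly
    increasing, and dJ/dt decays monotonically to the terminal flow rate
    1/eta1.

    Parameters
    ----------
    t : array_like
        Time(s) since force onset, s; must be >= 0.
    params : ViscoelasticParams
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("creep compliance is defined for t >= 0 only")
    J = (1.0 - np.exp(-t * params.E / params.eta2)) / params.E + t / params.eta1
    return J if J.ndim else float(J)


def complex_moduli(omega, params: ViscoelasticParams):
    """Storage and loss moduli (G', G'') of the extended Kelvin-Voigt model.

    Closed forms obtained by inverting the complex compliance
    ``J*(w) = 1/(E + i w eta2) + 1/(i w eta1)``:

        G'(w)  = E w^2 eta1^2 / (E^2 + w^2 (eta1+eta2)^2)
        G''(w) = (w eta1 E^2 + w^3 eta1 eta2 (eta1+eta2))
                 / (E^2 + w^2 (eta1+eta2)^2)

    Parameters
    ----------
    omega : array_like
        Angular frequency, rad/s; strictly positive.

    Returns
    -------
    (G_storage, G_loss) in Pa, same shape as ``omega``.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("complex moduli require omega > 0")
    E, eta1, eta2 = params.E, params.eta1, params.eta2
    denom = E**2 + omega**2 * (eta1 + eta2) ** 2
    g_storage = E * omega**2 * eta1**2 / denom
    g_loss = (omega * eta1 * E**2 + omega**3 * eta1 * eta2 * (eta1 + eta2)) / denom
    if g_storage.ndim:
        return g_storage, g_loss
    return float(g_storage), float(g_loss)


def stokes_drag(radius: float, viscosity: float) -> float:
    """Stokes drag coefficient 6*pi*eta*R in pN*s/um.

    With viscosity in Pa*s (= pN*s/um^2) and radius in um the product is
    already in pN*s/um; no numeric conversion is needed.
    """
    if radius <= 0 or viscosity <= 0:
        raise ValueError(
            f"radius and viscosity must be positive, got {radius}, {viscosity}"
        )
    return 6.0 * np.pi * viscosity * radius


def stokes_velocity(ctx: StokesContext) -> float:
    """Terminal settling speed of a dense sphere, um/s.

    v = F / (6 pi eta R) with buoyant weight F = (4/3) pi R^3 drho g, i.e.
    v = (2/9) * drho * (g_multiple * g0) * R^2 / eta, converted to um/s.
    Linear in g_multiple and quadratic in radius.
    """
    weight_pN = (
        (4.0 / 3.0)
        * np.pi
        * ctx.radius**3
        * ctx.delta_rho
        * ctx.g_multiple
        * G0_SI
        * _WEIGHT_TO_PN
    )
    return weight_pN / stokes_drag(ctx.radius, ctx.viscosity)
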