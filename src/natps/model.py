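"""Two-state diabatic model: coupled harmonic wells with constant coupling.

All quantities are in atomic units (Hartree, bohr, electron mass, atomic
time unit; hbar = 1).  The single unit-bridging constant is the Boltzmann
constant in Hartree per kelvin.

The diabatic electronic Hamiltonian is

    H(q) = [[ eps (q - x0)^2 / x0^2,  Vc                     ],
            [ Vc,                     eps (q + x0)^2 / x0^2  ]]

i.e. two harmonic wells displaced by +-x0 with a constant off-diagonal
coupling Vc.  Its adiabatic surfaces are Vbar(q) +- Vz(q) with

    Vbar = (H11 + H22) / 2,     Vz = sqrt(((H11 - H22)/2)^2 + Vc^2)

so the gap 2 Vz is minimal (2 Vc) at the crossing seam q = 0.  The barrier
on the lower adiabat, measured from the crossing to zero (the energy of the
diabatic well bottoms), is Ea = (1 - Vc/eps) eps.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

#: Boltzmann constant in Hartree / kelvin (CODATA).
KB_HARTREE_PER_K = 3.166811563e-6


@dataclass(frozen=True)
class ModelParams:
    """Constants of the coupled-harmonic two-state model (atomic units).

    Attributes
    ----------
    epsilon : float
        Energy scale of the diabatic wells (Hartree).
    x0 : float
        Displacement of the well minima from the origin (bohr).
    Vc : float
        Constant diabatic coupling (Hartree).
    mass : float
        Nuclear mass (electron masses).
    """

    epsilon: float = 0.05
    x0: float = 1.0
    Vc: float = 0.01
    mass: float = 1836.15

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.x0 <= 0:
            raise ValueError(f"x0 must be positive, got {self.x0}")
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.Vc < 0:
            raise ValueError(f"Vc must be non-negative, got {self.Vc}")


@dataclass(frozen=True)
class AdiabaticPoint:
    """Adiabatic representation of the model at one nuclear geometry.

    ``Vbar`` is the state-averaged potential, ``Vz`` the half-gap, and
    ``nac`` the nonadiabatic coupling <psi_-|d/dq psi_+>.  The adiabatic
    surfaces are ``Vbar - Vz`` (lower) and ``Vbar + Vz`` (upper).
    """

    q: float
    Vbar: float
    Vz: float
    dVbar: float
    dVz: float
    nac: float


class TwoStateModel(ABC):
    """Abstract two-state diabatic model on a single nuclear coordinate.

    Subclasses supply the diabatic matrix elements and their derivatives;
    the adiabatic quantities, forces and the mixing angle are derived here.
    The integrator and sampling machinery depend only on this interface, so
    any 1D two-state model can be plugged in.
    """

    mass: float

    @abstractmethod
    def diabatic_elements(self, q: float) -> tuple[float, float, float]:
        """Return (H11, H22, H12) at ``q``."""

    @abstractmethod
    def diabatic_derivatives(self, q: float) -> tuple[float, float, float]:
        """Return (dH11/dq, dH22/dq, dH12/dq) at ``q``."""

    # -- derived adiabatic quantities ------------------------------------

    def diabatic_hamiltonian(self, q: float) -> np.ndarray:
        h11, h22, h12 = self.diabatic_elements(q)
        return np.array([[h11, h12], [h12, h22]])

    def adiabatize(self, q: float) -> AdiabaticPoint:
        h11, h22, h12 = self.diabatic_elements(q)
        d11, d22, d12 = self.diabatic_derivatives(q)
        vd = 0.5 * (h11 - h22)
        dvd = 0.5 * (d11 - d22)
        vz = math.hypot(vd, h12)
        if vz == 0.0:
            raise ValueError(f"adiabatic surfaces are degenerate at q={q}")
        return AdiabaticPoint(
            q=q,
            Vbar=0.5 * (h11 + h22),
            Vz=vz,
            dVbar=0.5 * (d11 + d22),
            dVz=(vd * dvd + h12 * d12) / vz,
            # nac = d(theta)/dq for mixing angle 2*theta = atan2(H12, Vd)
            nac=0.5 * (vd * d12 - h12 * dvd) / (vz * vz),
        )

    def mixing_angle(self, q: float) -> float:
        """Half the rotation angle diagonalizing H(q), smooth in q for H12 > 0.

        The lower/upper eigenvectors are (-sin t, cos t) and (cos t, sin t)
        with t = mixing_angle(q); this fixes a globally continuous gauge as
        long as (H11 - H22, H12) never passes through the origin.
        """
        h11, h22, h12 = self.diabatic_elements(q)
        return 0.5 * math.atan2(h12, 0.5 * (h11 - h22))

    def eigenvectors(self, q: float) -> np.ndarray:
        """Columns = (lower, upper) adiabatic eigenvectors in the smooth gauge."""
        t = self.mixing_angle(q)
        c, s = math.cos(t), math.sin(t)
        return np.array([[-s, c], [c, s]])

    def surface(self, q: float, sign: int) -> float:
        """Adiabatic potential Vbar + sign * Vz (sign = -1 lower, +1 upper)."""
        ap = self.adiabatize(q)
        return ap.Vbar + sign * ap.Vz

    def force(self, q: float, active_sign: int) -> float:
        """Force -d/dq [Vbar + active_sign * Vz] on the active adiabat."""
        if active_sign not in (-1, 1):
            raise ValueError(f"active_sign must be +-1, got {active_sign}")
        ap = self.adiabatize(q)
        return -(ap.dVbar + active_sign * ap.dVz)


class CoupledHarmonicModel(TwoStateModel):
    """Two coupled harmonic diabats; the concrete model used throughout."""

    def __init__(self, params: ModelParams | None = None):
        self.params = params or ModelParams()
        self.mass = self.params.mass

    def diabatic_elements(self, q: float) -> tuple[float, float, float]:
        p = self.params
        k = p.epsilon / (p.x0 * p.x0)
        return (k * (q - p.x0) ** 2, k * (q + p.x0) ** 2, p.Vc)

    def diabatic_derivatives(self, q: float) -> tuple[float, float, float]:
        p = self.params
        k = p.epsilon / (p.x0 * p.x0)
        return (2.0 * k * (q - p.x0), 2.0 * k * (q + p.x0), 0.0)

    # Analytic shortcuts used by the hot integration loop (equivalent to
    # adiabatize(), specialized to this model).

    def vbar_vz(self, q: float) -> tuple[float, float]:
        p = self.params
        k = p.epsilon / (p.x0 * p.x0)
        vd = -2.0 * p.epsilon * q / p.x0
        return (k * (q * q + p.x0 * p.x0), math.hypot(vd, p.Vc))


def diabatic_hamiltonian(q: float, params: ModelParams) -> np.ndarray:
    """2x2 symmetric diabatic potential matrix at ``q`` (Hartree)."""
    return CoupledHarmonicModel(params).diabatic_hamiltonian(q)


def adiabatize(q: float, params: ModelParams) -> AdiabaticPoint:
    """Adiabatic potentials, derivatives and coupling at ``q``."""
    return CoupledHarmonicModel(params).adiabatize(q)


def force(q: float, active_sign: int, params: ModelParams) -> float:
    """Force on the active adiabatic surface (Hartree / bohr)."""
    return CoupledHarmonicModel(params).force(q, active_sign)


def barrier_height(params: ModelParams) -> float:
    """Adiabatic lower-surface barrier Ea = (1 - Vc/eps) * eps.

    Measures the crossing-point energy of the lower adiabat relative to the
    diabatic well-bottom energy (zero).  The true well depth of the lower
    adiabat is larger by Vc^2 / (4 eps) because the coupling pushes the
    adiabatic minima slightly below zero; the relative residual
    Vc^2 / (4 eps (eps - Vc)) is ~1.3% at Vc = 0.2 eps and <1e-4 only for
    Vc <~ 0.02 eps.

    Raises
    ------
    ValueError
        If Vc > epsilon (the formula leaves its validity regime: the
        crossing is no longer a barrier).
    """
    if params.Vc > params.epsilon:
        raise ValueError(
            f"barrier formula requires Vc <= epsilon, got Vc={params.Vc} > {params.epsilon}"
        )
    return (1.0 - params.Vc / params.epsilon) * params.epsilon


def barrier_temperature(params: ModelParams) -> float:
    """Temperature at which k_B T equals the barrier height (kelvin)."""
    return barrier_height(params) / KB_HARTREE_PER_K
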