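"""Electronic subsystem: coefficient pair <-> Bloch spin vector, propagation.

The two-level electronic wavefunction |Psi> = c- |psi-> + c+ |psi+> (adiabatic
basis) is mapped onto a unit spin vector

    Sx = 2 Re(c+* c-),   Sy = 2 Im(c+* c-),   Sz = |c+|^2 - |c-|^2

so the south pole is the pure lower state and the active surface is
sign(Sz).  Coefficients are the stored representation; the spin vector is
derived on demand.

Propagation uses local diabatization: the coefficients are rotated into the
diabatic frame at the start geometry, propagated there with a fourth-order
Magnus integrator (two-point Gauss quadrature, analytic 2x2 exponential)
along a linear-in-time nuclear sub-path, and rotated back into the
adiabatic frame at the end geometry.  The scheme is unitary by construction
and exactly symmetric under time reversal (conjugate coefficients, reversed
path), because the diabatic Hamiltonian is real symmetric.

Under time reversal, q -> q, p -> -p, (Sx, Sy, Sz) -> (Sx, -Sy, Sz), which
in the coefficient picture is complex conjugation c -> c*.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from natps.integrator import PhasePoint
    from natps.model import TwoStateModel

_SQRT3 = math.sqrt(3.0)
# Gauss-Legendre nodes on [0, 1]
_G1 = 0.5 - 0.5 / _SQRT3
_G2 = 0.5 + 0.5 / _SQRT3

#: Default number of electronic substeps per nuclear step.  At the model's
#: default time step (5 a.t.u.) this keeps the one-step amplitude error of
#: the Magnus-4 propagator below 1e-10 against a brute-force integration of
#: the time-dependent Schroedinger equation.
DEFAULT_SUBSTEPS = 8

_NORM_TOL = 1e-8


def coeffs_to_spin(c) -> np.ndarray:
    """Map a normalized adiabatic coefficient pair (c-, c+) to a unit spin vector."""
    cm, cp = complex(c[0]), complex(c[1])
    norm = abs(cm) ** 2 + abs(cp) ** 2
    if abs(norm - 1.0) > _NORM_TOL:
        raise ValueError(f"coefficient pair not normalized: |c|^2 = {norm}")
    cross = cp.conjugate() * cm
    return np.array([2.0 * cross.real, 2.0 * cross.imag, abs(cp) ** 2 - abs(cm) ** 2])


def spin_to_coeffs(S) -> np.ndarray:
    """Inverse Bloch map; the global phase is fixed by c- real and >= 0.

    For the north pole (|c-| = 0) the convention degenerates and c+ is taken
    real positive instead.
    """
    sx, sy, sz = float(S[0]), float(S[1]), float(S[2])
    norm = math.sqrt(sx * sx + sy * sy + sz * sz)
    if abs(norm - 1.0) > _NORM_TOL:
        raise ValueError(f"spin vector not on the unit sphere: |S| = {norm}")
    am = math.sqrt(max(0.0, 0.5 * (1.0 - sz)))
    ap = math.sqrt(max(0.0, 0.5 * (1.0 + sz)))
    if am < 1e-12:
        return np.array([0.0 + 0.0j, 1.0 + 0.0j])
    # c+* c- = (Sx + i Sy)/2 with c- = am real
    cp = complex(sx, -sy) / (2.0 * am)
    return np.array([complex(am, 0.0), cp])


def _propagate_scalar(
    cm: complex,
    cp: complex,
    q_start: float,
    q_end: float,
    dt: float,
    model: "TwoStateModel",
    n_sub: int,
) -> tuple[complex, complex]:
    """Scalar hot-path core of :func:`propagate_electronic`."""
    if dt == 0.0:
        return cm, cp
    # adiabatic -> diabatic at q_start
    th = model.mixing_angle(q_start)
    co, si = math.cos(th), math.sin(th)
    d1 = -si * cm + co * cp
    d2 = co * cm + si * cp

    elems = model.diabatic_elements
    h = dt / n_sub
    dq = (q_end - q_start) / n_sub
    gamma_pref = _SQRT3 / 12.0 * h * h
    for k in range(n_sub):
        qa = q_start + (k + _G1) * dq
        qb = q_start + (k + _G2) * dq
        a1, e1, b1 = elems(qa)
        a2, e2, b2 = elems(qb)
        theta0 = 0.25 * h * (a1 + e1 + a2 + e2)
        nz = 0.25 * h * ((a1 - e1) + (a2 - e2))
        nx = 0.5 * h * (b1 + b2)
        # [H1, H2]_{01} = (H11-H22)_1 * H12_2 - (H11-H22)_2 * H12_1
        ny = -gamma_pref * ((a1 - e1) * b2 - (a2 - e2) * b1)
        r = math.sqrt(nx * nx + ny * ny + nz * nz)
        if r > 1e-8:
            cr = math.cos(r)
            s = math.sin(r) / r
        else:
            cr = 1.0 - 0.5 * r * r
            s = 1.0 - r * r / 6.0
        ph = complex(math.cos(theta0), -math.sin(theta0))
        m11 = ph * complex(cr, -s * nz)
        m12 = ph * complex(-s * ny, -s * nx)
        m21 = ph * complex(s * ny, -s * nx)
        m22 = ph * complex(cr, s * nz)
        d1, d2 = m11 * d1 + m12 * d2, m21 * d1 + m22 * d2

    # diabatic -> adiabatic at q_end
    th = model.mixing_angle(q_end)
    co, si = math.cos(th), math.sin(th)
    return (-si * d1 + co * d2, co * d1 + si * d2)


def propagate_electronic(
    c,
    q_start: float,
    q_end: float,
    dt: float,
    model: "TwoStateModel",
    n_sub: int = DEFAULT_SUBSTEPS,
) -> np.ndarray:
    """Propagate adiabatic coefficients over one nuclear step.

    The nuclear coordinate is taken to move linearly in time from
    ``q_start`` to ``q_end`` during ``dt``; the implied velocity carries the
    entire nonadiabatic coupling, so no explicit momentum argument is
    needed.  Returns the coefficients in the adiabatic basis at ``q_end``.
    Norm is conserved to machine precision.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be positive, got {dt}")
    cm, cp = _propagate_scalar(complex(c[0]), complex(c[1]), q_start, q_end, dt, model, n_sub)
    return np.array([cm, cp])


def time_reverse(point: "PhasePoint") -> "PhasePoint":
    """Time-reversal map: q -> q, p -> -p, c -> c* (so Sy flips sign).

    An involution; the time label and active surface are unchanged.
    """
    return replace(point, p=-point.p, c=np.conj(point.c))
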