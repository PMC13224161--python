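"""Deterministic, time-reversible MASH propagation.

One step is a velocity-Verlet update of the nuclei on the active adiabatic
surface with concurrent electronic propagation.  The active surface is
sign(Sz) (ties broken to the lower state).  When the trial step detects a
sign change of Sz, the precise crossing time is located by a bracketing
root search on the sub-propagated coupled system, the system is advanced
exactly to the crossing, the hop is performed there (velocity rescaling,
or reflection if the upward hop is frustrated), and the remainder of the
step is completed on the resulting surface.  At most one hop per step is
assumed; a second crossing inside the same step aborts with a diagnostic.

Locating the hop inside the step keeps the dynamics exactly time
reversible: the nuclei traverse the same potential pieces in both time
directions.  The end-of-step variant :func:`mash_step_naive` (kept as a
diagnostic) breaks this by several orders of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from natps.electronic import DEFAULT_SUBSTEPS, _propagate_scalar, coeffs_to_spin, time_reverse
from natps.model import TwoStateModel

#: Default time step (a.t.u.), small enough for a robust in-step root search.
DEFAULT_DT = 5.0

#: Default cap on one-sided propagation length (steps).
DEFAULT_MAX_STEPS = 4000

_ROOT_XTOL = 1e-10


@dataclass(frozen=True)
class PhasePoint:
    """One point of the extended phase space Gamma = (q, p, S).

    The electronic state is stored as the adiabatic coefficient pair
    ``c = (c-, c+)``; the spin vector is derived.  ``active`` caches
    sign(Sz) with the tie Sz = 0 resolved to the lower state (-1).
    """

    q: float
    p: float
    c: np.ndarray
    t: float = 0.0
    active: int = -1

    @property
    def spin(self) -> np.ndarray:
        return coeffs_to_spin(self.c)

    @property
    def sz(self) -> float:
        return (self.c[1].real ** 2 + self.c[1].imag ** 2) - (
            self.c[0].real ** 2 + self.c[0].imag ** 2
        )

    @staticmethod
    def make(q: float, p: float, c, t: float = 0.0) -> "PhasePoint":
        c = np.asarray(c, dtype=complex)
        sz = abs(c[1]) ** 2 - abs(c[0]) ** 2
        return PhasePoint(q=q, p=p, c=c, t=t, active=-1 if sz <= 0.0 else 1)


@dataclass(frozen=True)
class HopEvent:
    """A surface-hop record at the moment Sz = 0."""

    t: float
    q: float
    phi: float
    direction: Literal["up", "down"]
    frustrated: bool = False


class Trajectory:
    """Time-ordered sequence of phase points on a uniform grid.

    Hop events occur at sub-step times and are recorded separately; the
    stored grid is uniform with spacing ``dt``.
    """

    __slots__ = ("t", "q", "p", "c", "active", "dt", "hops", "meta")

    def __init__(self, t, q, p, c, active, dt: float, hops: Sequence[HopEvent] = (), meta=None):
        self.t = np.asarray(t, dtype=float)
        self.q = np.asarray(q, dtype=float)
        self.p = np.asarray(p, dtype=float)
        self.c = np.asarray(c, dtype=complex)
        self.active = np.asarray(active, dtype=np.int8)
        self.dt = float(dt)
        self.hops = list(hops)
        self.meta = dict(meta) if meta else {}

    @classmethod
    def from_points(cls, points: Sequence[PhasePoint], dt: float, hops=(), meta=None):
        return cls(
            t=[pt.t for pt in points],
            q=[pt.q for pt in points],
            p=[pt.p for pt in points],
            c=[pt.c for pt in points],
            active=[pt.active for pt in points],
            dt=dt,
            hops=hops,
            meta=meta,
        )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_steps(self) -> int:
        """Number of integration steps (points - 1); the path length L."""
        return len(self.t) - 1

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def sz(self) -> np.ndarray:
        return (np.abs(self.c[:, 1]) ** 2 - np.abs(self.c[:, 0]) ** 2).astype(float)

    @property
    def spin(self) -> np.ndarray:
        cross = np.conj(self.c[:, 1]) * self.c[:, 0]
        return np.column_stack([2.0 * cross.real, 2.0 * cross.imag, self.sz])

    def point(self, i: int) -> PhasePoint:
        return PhasePoint(
            q=float(self.q[i]),
            p=float(self.p[i]),
            c=self.c[i].copy(),
            t=float(self.t[i]),
            active=int(self.active[i]),
        )

    def energies(self, model: TwoStateModel) -> np.ndarray:
        out = np.empty(len(self.t))
        for i in range(len(self.t)):
            ap = model.adiabatize(float(self.q[i]))
            out[i] = self.p[i] ** 2 / (2.0 * model.mass) + ap.Vbar + int(self.active[i]) * ap.Vz
        return out

    def reversed(self) -> "Trajectory":
        """The time-reversed trajectory, re-labelled to run forward in time.

        Positions are retraced in opposite order, momenta flip sign,
        coefficients are conjugated (Sy -> -Sy).  Hop directions swap
        (up <-> down) and their coherence angles flip sign; frustrated
        events stay frustrated.
        """
        t0, t1 = self.t[0], self.t[-1]
        new_t = t0 + (t1 - self.t[::-1])
        hops = sorted(
            (
                HopEvent(
                    t=float(t0 + (t1 - h.t)),
                    q=h.q,
                    phi=-h.phi,
                    direction=(
                        h.direction
                        if h.frustrated
                        else ("down" if h.direction == "up" else "up")
                    ),
                    frustrated=h.frustrated,
                )
                for h in self.hops
            ),
            key=lambda h: h.t,
        )
        return Trajectory(
            t=new_t,
            q=self.q[::-1].copy(),
            p=-self.p[::-1],
            c=np.conj(self.c[::-1]),
            active=self.active[::-1].copy(),
            dt=self.dt,
            hops=hops,
            meta=self.meta,
        )

    def slice(self, i0: int, i1: int) -> "Trajectory":
        """Sub-trajectory over point indices [i0, i1] inclusive."""
        t_lo, t_hi = self.t[i0], self.t[i1]
        hops = [h for h in self.hops if t_lo <= h.t <= t_hi]
        return Trajectory(
            t=self.t[i0 : i1 + 1],
            q=self.q[i0 : i1 + 1],
            p=self.p[i0 : i1 + 1],
            c=self.c[i0 : i1 + 1],
            active=self.active[i0 : i1 + 1],
            dt=self.dt,
            hops=hops,
        )

    def concatenate(self, other: "Trajectory") -> "Trajectory":
        """Join two segments sharing the boundary point (this end = other start)."""
        if not math.isclose(self.t[-1], other.t[0], abs_tol=1e-9):
            raise ValueError("segments do not share a boundary time")
        return Trajectory(
            t=np.concatenate([self.t, other.t[1:]]),
            q=np.concatenate([self.q, other.q[1:]]),
            p=np.concatenate([self.p, other.p[1:]]),
            c=np.concatenate([self.c, other.c[1:]]),
            active=np.concatenate([self.active, other.active[1:]]),
            dt=self.dt,
            hops=sorted(list(self.hops) + list(other.hops), key=lambda h: h.t),
        )


def total_energy(point: PhasePoint, model: TwoStateModel) -> float:
    """E = p^2/2m + Vbar(q) + sign(Sz) Vz(q), using the cached active sign."""
    ap = model.adiabatize(point.q)
    return point.p**2 / (2.0 * model.mass) + ap.Vbar + point.active * ap.Vz


def attempt_hop(
    point: PhasePoint, direction: Literal["up", "down"], model: TwoStateModel
) -> tuple[PhasePoint, bool]:
    """Perform the surface hop at a crossing point (|Sz| ~ 0).

    Downward hops are always allowed: the momentum along the coupling
    direction (in 1D, the full momentum) is rescaled so that total energy
    is conserved, p'^2 = p^2 + 4 m Vz.  Upward hops require kinetic energy
    along the coupling of at least the gap 2 Vz; then p'^2 = p^2 - 4 m Vz
    with the sign of p preserved.  Otherwise the hop is frustrated: the
    momentum along the coupling is reversed and the surface is unchanged.

    Returns the post-event point and a flag marking frustration.
    """
    if abs(point.sz) > 1e-6:
        raise ValueError(f"attempt_hop called away from the crossing: Sz = {point.sz}")
    ap = model.adiabatize(point.q)
    m = model.mass
    p = point.p
    if direction == "down":
        p_new = math.copysign(math.sqrt(p * p + 4.0 * m * ap.Vz), p)
        return replace(point, p=p_new, active=-1), False
    if p * p >= 4.0 * m * ap.Vz:
        p_new = math.copysign(math.sqrt(p * p - 4.0 * m * ap.Vz), p)
        return replace(point, p=p_new, active=1), False
    return replace(point, p=-p), True


def _vv_elec(
    q: float,
    p: float,
    cm: complex,
    cp: complex,
    sign: int,
    tau: float,
    model: TwoStateModel,
    n_sub: int,
) -> tuple[float, float, complex, complex]:
    """Velocity-Verlet + electronic propagation over tau on a fixed surface."""
    if tau == 0.0:
        return q, p, cm, cp
    m = model.mass
    ph = p + 0.5 * tau * model.force(q, sign)
    q1 = q + tau * ph / m
    p1 = ph + 0.5 * tau * model.force(q1, sign)
    cm1, cp1 = _propagate_scalar(cm, cp, q, q1, tau, model, n_sub)
    return q1, p1, cm1, cp1


def mash_step(
    point: PhasePoint,
    dt: float,
    model: TwoStateModel,
    n_sub: int = DEFAULT_SUBSTEPS,
    root_xtol: float = _ROOT_XTOL,
) -> tuple[PhasePoint, HopEvent | None]:
    """One MASH step; returns the new point and the hop event, if any.

    The trial step runs hop-free on the active surface.  If the trial ends
    with Sz on the other hemisphere, the crossing time is bracketed on
    (0, dt) and located by Brent's method on the sub-propagated Sz, the
    hop is applied there, and the remaining time is integrated on the
    (possibly new) surface.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be positive, got {dt}")
    q0, p0 = point.q, point.p
    cm0, cp0 = complex(point.c[0]), complex(point.c[1])
    s = point.active

    q1, p1, cm1, cp1 = _vv_elec(q0, p0, cm0, cp0, s, dt, model, n_sub)
    sz1 = (cp1.real**2 + cp1.imag**2) - (cm1.real**2 + cm1.imag**2)
    s1 = -1 if sz1 <= 0.0 else 1
    if s1 == s:
        return (
            PhasePoint(q=q1, p=p1, c=np.array([cm1, cp1]), t=point.t + dt, active=s),
            None,
        )

    # Sz changed hemisphere inside the step: locate the crossing.
    def crossing(tau: float) -> float:
        _, _, a, b = _vv_elec(q0, p0, cm0, cp0, s, tau, model, n_sub)
        return (b.real**2 + b.imag**2) - (a.real**2 + a.imag**2)

    sz0 = (cp0.real**2 + cp0.imag**2) - (cm0.real**2 + cm0.imag**2)
    if sz0 == 0.0 or (sz0 > 0) == (sz1 > 0):  # pragma: no cover - defensive
        raise RuntimeError("hop detection inconsistency: endpoint signs do not bracket zero")
    try:
        tau_star = brentq(crossing, 0.0, dt, xtol=root_xtol, maxiter=200)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"hop root search failed to converge: {exc}") from exc

    qs, ps, cms, cps = _vv_elec(q0, p0, cm0, cp0, s, tau_star, model, n_sub)
    star = PhasePoint(q=qs, p=ps, c=np.array([cms, cps]), t=point.t + tau_star, active=s)
    direction: Literal["up", "down"] = "up" if s == -1 else "down"
    hopped, frustrated = attempt_hop(star, direction, model)
    cross = cps.conjugate() * cms
    event = HopEvent(
        t=point.t + tau_star,
        q=qs,
        phi=math.atan2(2.0 * cross.imag, 2.0 * cross.real),
        direction=direction,
        frustrated=frustrated,
    )

    s_new = hopped.active
    q2, p2, cm2, cp2 = _vv_elec(
        hopped.q, hopped.p, cms, cps, s_new, dt - tau_star, model, n_sub
    )
    sz2 = (cp2.real**2 + cp2.imag**2) - (cm2.real**2 + cm2.imag**2)
    s2 = -1 if sz2 <= 0.0 else 1
    if s2 != s_new:
        raise RuntimeError(
            "two Sz sign changes within one time step; reduce dt "
            f"(dt={dt}, t={point.t}, q={q0})"
        )
    return (
        PhasePoint(q=q2, p=p2, c=np.array([cm2, cp2]), t=point.t + dt, active=s_new),
        event,
    )


def mash_step_naive(
    point: PhasePoint,
    dt: float,
    model: TwoStateModel,
    n_sub: int = DEFAULT_SUBSTEPS,
) -> tuple[PhasePoint, HopEvent | None]:
    """End-of-step hop variant: a diagnostic foil for :func:`mash_step`.

    The hop is detected and performed only after the full nuclear step, as
    in conventional surface-hopping codes.  The nuclei then traverse
    different potential pieces forward and backward in time, which breaks
    time reversibility; kept to demonstrate (and test) that failure mode.
    """
    q0, p0 = point.q, point.p
    s = point.active
    q1, p1, cm1, cp1 = _vv_elec(q0, p0, complex(point.c[0]), complex(point.c[1]), s, dt, model, n_sub)
    sz1 = (cp1.real**2 + cp1.imag**2) - (cm1.real**2 + cm1.imag**2)
    s1 = -1 if sz1 <= 0.0 else 1
    end = PhasePoint(q=q1, p=p1, c=np.array([cm1, cp1]), t=point.t + dt, active=s)
    if s1 == s:
        return end, None
    direction: Literal["up", "down"] = "up" if s == -1 else "down"
    ap = model.adiabatize(q1)
    m = model.mass
    if direction == "down":
        p_new = math.copysign(math.sqrt(p1 * p1 + 4.0 * m * ap.Vz), p1)
        hopped, frustrated = replace(end, p=p_new, active=-1), False
    elif p1 * p1 >= 4.0 * m * ap.Vz:
        p_new = math.copysign(math.sqrt(p1 * p1 - 4.0 * m * ap.Vz), p1)
        hopped, frustrated = replace(end, p=p_new, active=1), False
    else:
        hopped, frustrated = replace(end, p=-p1), True
    cross = cp1.conjugate() * cm1
    event = HopEvent(
        t=point.t + dt,
        q=q1,
        phi=math.atan2(2.0 * cross.imag, 2.0 * cross.real),
        direction=direction,
        frustrated=frustrated,
    )
    return hopped, event


def propagate_until_basin(
    point: PhasePoint,
    basins,
    direction: Literal["forward", "backward"],
    max_steps: int,
    dt: float,
    model: TwoStateModel,
    n_sub: int = DEFAULT_SUBSTEPS,
) -> tuple[list[PhasePoint], list[HopEvent], str, int]:
    """Propagate until the trajectory enters one of the two basins.

    The starting point itself is not tested (and is not included in the
    returned segment): shooting points may sit inside a basin, in which
    case the segment must still leave it by propagation.  Backward
    propagation time-reverses the start, propagates forward, and returns
    the segment mapped back to physical time order (points read
    past -> ``point``).

    Returns (points, hops, status, steps_used) with status the basin name,
    ``"uncommitted"`` if ``max_steps`` was exhausted, or ``"aborted"`` on
    the rare double-crossing integrator failure (callers treat both as a
    failed shot).
    """
    basin_a, basin_b = basins
    if direction == "backward":
        pts, hops, status, n = propagate_until_basin(
            time_reverse(point), basins, "forward", max_steps, dt, model, n_sub
        )
        t0 = point.t
        out = [replace(time_reverse(pt), t=t0 - (pt.t - t0)) for pt in reversed(pts)]
        out_hops = [
            HopEvent(
                t=t0 - (h.t - t0),
                q=h.q,
                phi=-h.phi,
                direction=(
                    h.direction if h.frustrated else ("down" if h.direction == "up" else "up")
                ),
                frustrated=h.frustrated,
            )
            for h in reversed(hops)
        ]
        return out, out_hops, status, n

    pts: list[PhasePoint] = []
    hops: list[HopEvent] = []
    current = point
    for n in range(1, max_steps + 1):
        try:
            current, event = mash_step(current, dt, model, n_sub)
        except RuntimeError:
            return pts, hops, "aborted", n - 1
        pts.append(current)
        if event is not None:
            hops.append(event)
        if basin_a.contains(current.q, current.active):
            return pts, hops, basin_a.name, n
        if basin_b.contains(current.q, current.active):
            return pts, hops, basin_b.name, n
    return pts, hops, "uncommitted", max_steps
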