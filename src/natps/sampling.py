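"""Sampling the stationary MASH Boltzmann distribution; brute-force runs.

The canonical distribution of the MASH energy function factorizes into a
Maxwell-Boltzmann momentum, a joint density over position and hemisphere

    rho(q, s) ~ exp(-beta (Vbar(q) + s Vz(q))),   s = sign(Sz) = +-1,

and a spin vector uniform on the selected hemisphere (the Sz marginal is
flat within each hemisphere).  Positions are drawn by tabulated inverse-CDF
on a dense grid.  This distribution is stationary under MASH dynamics, so
unbiased NVE trajectories started from it sample the equilibrium path
ensemble; reactive segments harvested from them are the brute-force
reference for transition path sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from natps.electronic import spin_to_coeffs
from natps.integrator import DEFAULT_DT, PhasePoint, Trajectory, mash_step
from natps.model import KB_HARTREE_PER_K, TwoStateModel


@dataclass(frozen=True)
class ThermalSpec:
    """Temperature and the derived inverse energy beta = 1/(k_B T)."""

    temperature: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def beta(self) -> float:
        return 1.0 / (KB_HARTREE_PER_K * self.temperature)

    @property
    def kT(self) -> float:
        return KB_HARTREE_PER_K * self.temperature


#: Width of the sampled energy window above the lower-surface minimum, in kT.
#: exp(-30) ~ 1e-13 keeps the truncated tail mass far below the 1e-8
#: normalization requirement of the tabulated inverse CDF.
_ENERGY_WINDOW_KT = 30.0
_GRID_POINTS = 1 << 14


def _position_grid(model: TwoStateModel, thermal: ThermalSpec) -> np.ndarray:
    """Grid covering all q with lower-surface energy within the thermal window."""
    window = _ENERGY_WINDOW_KT * thermal.kT
    probe = np.linspace(-1.0, 1.0, 201)
    vmin = min(model.surface(q, -1) for q in probe)
    qmax = 1.0
    while model.surface(qmax, -1) < vmin + window:
        qmax *= 1.25
        if qmax > 1e3:  # pragma: no cover - defensive
            raise RuntimeError("unbound lower surface: cannot build sampling grid")
    qmin = -1.0
    while model.surface(qmin, -1) < vmin + window:
        qmin *= 1.25
    return np.linspace(qmin * 1.05, qmax * 1.05, _GRID_POINTS)


def boltzmann_position_density(
    model: TwoStateModel, thermal: ThermalSpec, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized joint weights w[s, i] ~ exp(-beta(Vbar +- Vz)) on the grid.

    Returns (grid, w) with w of shape (2, len(grid)); row 0 is the lower
    hemisphere (s = -1), row 1 the upper.  The common offset is removed
    before exponentiation for numerical stability.
    """
    if grid is None:
        grid = _position_grid(model, thermal)
    vbar = np.empty_like(grid)
    vz = np.empty_like(grid)
    for i, q in enumerate(grid):
        ap = model.adiabatize(float(q))
        vbar[i] = ap.Vbar
        vz[i] = ap.Vz
    beta = thermal.beta
    lower = vbar - vz
    shift = lower.min()
    w = np.vstack(
        [np.exp(-beta * (lower - shift)), np.exp(-beta * (vbar + vz - shift))]
    )
    if w[0, 0] > 1e-10 * w[0].max() or w[0, -1] > 1e-10 * w[0].max():
        raise RuntimeError("sampling grid does not cover the thermal range")
    return grid, w


class BoltzmannSampler:
    """Reusable sampler of the stationary MASH Boltzmann distribution.

    Precomputes the tabulated inverse CDF of the position marginal for each
    hemisphere once; drawing is then vectorized and cheap.
    """

    def __init__(self, model: TwoStateModel, thermal: ThermalSpec):
        self.model = model
        self.thermal = thermal
        self.grid, self.weights = boltzmann_position_density(model, thermal)
        totals = np.trapezoid(self.weights, self.grid, axis=1)
        self.p_upper = totals[1] / totals.sum()
        self._cdfs = []
        for s_idx in (0, 1):
            w = self.weights[s_idx]
            cdf = np.concatenate(
                [[0.0], np.cumsum((w[1:] + w[:-1]) * np.diff(self.grid) / 2.0)]
            )
            cdf /= cdf[-1]
            self._cdfs.append(cdf)

    def sample(self, n: int, rng: np.random.Generator) -> list[PhasePoint]:
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        upper = rng.random(n) < self.p_upper
        qs = np.empty(n)
        for s_idx, mask in ((0, ~upper), (1, upper)):
            k = int(mask.sum())
            if k:
                qs[mask] = np.interp(rng.random(k), self._cdfs[s_idx], self.grid)
        ps = rng.normal(0.0, math.sqrt(self.model.mass * self.thermal.kT), size=n)
        # uniform on the chosen hemisphere: Sz flat on its half-range, azimuth flat
        u = rng.random(n)
        sz = np.where(upper, u, -u)
        sz = np.clip(sz, -1.0 + 1e-12, 1.0 - 1e-12)
        phi = rng.uniform(-math.pi, math.pi, size=n)
        sperp = np.sqrt(1.0 - sz * sz)
        return [
            PhasePoint(
                q=float(qs[i]),
                p=float(ps[i]),
                c=spin_to_coeffs(
                    [sperp[i] * math.cos(phi[i]), sperp[i] * math.sin(phi[i]), sz[i]]
                ),
                t=0.0,
                active=1 if upper[i] else -1,
            )
            for i in range(n)
        ]


def sample_boltzmann(
    model: TwoStateModel,
    thermal: ThermalSpec,
    n: int,
    rng: np.random.Generator,
) -> list[PhasePoint]:
    """Draw ``n`` phase points from the stationary MASH Boltzmann distribution."""
    return BoltzmannSampler(model, thermal).sample(n, rng)


def _basin_labels(traj: Trajectory, basins) -> np.ndarray:
    """0 = neither, 1 = first basin, 2 = second basin, per stored point."""
    basin_a, basin_b = basins
    labels = np.zeros(len(traj), dtype=np.int8)
    for i in range(len(traj)):
        q = float(traj.q[i])
        s = int(traj.active[i])
        if basin_a.contains(q, s):
            labels[i] = 1
        elif basin_b.contains(q, s):
            labels[i] = 2
    return labels


def harvest_transitions(traj: Trajectory, basins) -> list[Trajectory]:
    """Extract all reactive segments of an unbiased trajectory.

    A segment runs from the last point inside one basin to the first point
    inside the other, with no interior point in either basin.  Segments are
    returned oriented first-basin -> second-basin; occurrences in the
    opposite direction are stored time-reversed and flagged in
    ``meta["reversed"]``.
    """
    labels = _basin_labels(traj, basins)
    segments: list[Trajectory] = []
    prev_idx = -1
    prev_label = 0
    for i, lab in enumerate(labels):
        if lab == 0:
            continue
        if prev_label != 0 and lab != prev_label:
            seg = traj.slice(prev_idx, i)
            if prev_label == 2:
                seg = seg.reversed()
                seg.meta["reversed"] = True
            else:
                seg.meta["reversed"] = False
            seg.meta["reactive"] = True
            seg.meta["source_span"] = (prev_idx, i)
            segments.append(seg)
        prev_idx, prev_label = i, lab
    return segments


def brute_force_run(
    model: TwoStateModel,
    thermal: ThermalSpec,
    basins,
    total_steps_budget: int,
    trajectory_length: int = 100_000,
    rng: np.random.Generator | None = None,
    dt: float = DEFAULT_DT,
    n_sub: int | None = None,
    min_transitions: int | None = None,
) -> tuple[list[Trajectory], int]:
    """Harvest reactive segments from unbiased NVE MASH trajectories.

    Repeatedly draws fresh initial conditions from the stationary
    distribution, integrates a fixed-length energy-conserving trajectory,
    and collects all reactive segments.  Stops when the step budget is
    exhausted (always) or, if ``min_transitions`` is given, as soon as that
    many segments have been harvested at a trajectory boundary.

    Returns (segments, steps_used); ``steps_used`` counts every integrator
    step, including trajectories that yielded no transition.
    """
    if total_steps_budget <= 0:
        raise ValueError("total_steps_budget must be positive")
    rng = rng or np.random.default_rng()
    from natps.electronic import DEFAULT_SUBSTEPS

    n_sub = n_sub or DEFAULT_SUBSTEPS
    sampler = BoltzmannSampler(model, thermal)
    segments: list[Trajectory] = []
    steps_used = 0
    traj_id = 0
    while steps_used < total_steps_budget:
        if min_transitions is not None and len(segments) >= min_transitions:
            break
        start = sampler.sample(1, rng)[0]
        n_steps = min(trajectory_length, total_steps_budget - steps_used)
        pts = [start]
        hops = []
        current = start
        done = 0
        for _ in range(n_steps):
            try:
                current, event = mash_step(current, dt, model, n_sub)
            except RuntimeError:
                # rare double-crossing at this dt: keep the partial
                # trajectory, it is still a valid piece of MASH dynamics
                break
            done += 1
            pts.append(current)
            if event is not None:
                hops.append(event)
        steps_used += done
        traj = Trajectory.from_points(pts, dt, hops)
        for seg in harvest_transitions(traj, basins):
            seg.meta["source_trajectory"] = traj_id
            segments.append(seg)
        traj_id += 1
    return segments, steps_used
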