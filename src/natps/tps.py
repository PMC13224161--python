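"""Transition path sampling in the extended nuclear-electronic phase space.

The path ensemble is the set of trajectories whose first point lies in
basin A, whose last point lies in basin B, and whose interior touches
neither basin (the indicator H_AB).  It is sampled by a shooting Markov
chain: pick a point of the current reactive path uniformly at random,
perturb its velocity with the Uhlenbeck-Ornstein move

    v' = alpha v + sqrt(1 - alpha^2) dv,   dv ~ Maxwell-Boltzmann(T),

keep position and electronic coefficients, propagate forward and backward
in time until both sides commit to a basin, and accept the assembled
candidate with the flexible-length Metropolis probability

    P_acc = h_A(first) h_B(last) min{1, L_old / L_new}.

On rejection (wrong endpoints, interior basin contact, non-commitment
within the step cap, or the length factor) the previous path is repeated
in the chain.  Because MASH dynamics is deterministic, time reversible and
volume preserving, and the velocity move satisfies detailed balance, the
chain leaves the reactive path ensemble invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from natps.electronic import DEFAULT_SUBSTEPS
from natps.integrator import (
    DEFAULT_DT,
    DEFAULT_MAX_STEPS,
    HopEvent,
    PhasePoint,
    Trajectory,
    propagate_until_basin,
)
from natps.model import TwoStateModel
from natps.sampling import ThermalSpec, harvest_transitions


@dataclass(frozen=True)
class BasinSpec:
    """A metastable basin: lower-adiabat configurations beyond a threshold."""

    name: str
    q_bound: float
    side: str  # "below" | "above"
    required_state_sign: int = -1

    def __post_init__(self) -> None:
        if self.side not in ("below", "above"):
            raise ValueError(f"side must be 'below' or 'above', got {self.side!r}")

    def contains(self, q: float, active_sign: int) -> bool:
        if active_sign != self.required_state_sign:
            return False
        return q < self.q_bound if self.side == "below" else q > self.q_bound


def default_basins() -> tuple[BasinSpec, BasinSpec]:
    """A: lower state with q < -0.8; B: lower state with q > 0.8 (bohr)."""
    return (
        BasinSpec(name="A", q_bound=-0.8, side="below"),
        BasinSpec(name="B", q_bound=0.8, side="above"),
    )


def in_basin(point: PhasePoint, basin: BasinSpec) -> bool:
    """Indicator h_basin(Gamma)."""
    return basin.contains(point.q, point.active)


@dataclass(frozen=True)
class TPSConfig:
    """Run configuration for a shooting chain."""

    temperature: float
    n_paths: int = 10_000
    alpha: float = 0.9
    dt: float = DEFAULT_DT
    max_steps_per_side: int = DEFAULT_MAX_STEPS
    burn_in_fraction: float = 0.15
    seed: int = 0
    n_sub: int = DEFAULT_SUBSTEPS
    reverse_accept: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError(f"burn_in_fraction must be in [0, 1), got {self.burn_in_fraction}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.dt <= 0 or self.n_paths < 1 or self.max_steps_per_side < 1:
            raise ValueError("dt, n_paths and max_steps_per_side must be positive")

    @property
    def thermal(self) -> ThermalSpec:
        return ThermalSpec(self.temperature)

    @property
    def burn_in(self) -> int:
        return int(self.burn_in_fraction * self.n_paths)


@dataclass
class ShotRecord:
    """Book-keeping for one shooting move."""

    shoot_index: int
    accepted: bool
    steps_generated: int
    reason: str = "accepted"


@dataclass
class PathEnsemble:
    """The Markov chain of reactive trajectories.

    ``paths`` holds each distinct accepted trajectory once (index 0 is the
    seed path); ``chain`` maps every MC step to its path index, repeating
    the previous index on rejection.  All ensemble averages weight paths by
    their chain multiplicity; ``burn_in`` marks the number of leading MC
    steps excluded from analysis.
    """

    paths: list[Trajectory]
    chain: np.ndarray
    records: list[ShotRecord]
    total_steps_generated: int
    burn_in: int
    config: TPSConfig
    meta: dict = field(default_factory=dict)

    def chain_indices(self, include_burn_in: bool = False) -> np.ndarray:
        return self.chain if include_burn_in else self.chain[self.burn_in :]

    def chain_paths(self, include_burn_in: bool = False):
        """Iterate trajectories with chain multiplicity (repeats on rejection)."""
        for idx in self.chain_indices(include_burn_in):
            yield self.paths[idx]

    def distinct_paths(self, include_burn_in: bool = False) -> list[Trajectory]:
        idx = sorted(set(int(i) for i in self.chain_indices(include_burn_in)))
        return [self.paths[i] for i in idx]

    @property
    def acceptance_rate(self) -> float:
        return sum(r.accepted for r in self.records) / max(1, len(self.records))

    def transition_times(self, include_burn_in: bool = False) -> np.ndarray:
        """Per-MC-step transition times tau = L * dt (chain-weighted series)."""
        durations = np.array([p.duration for p in self.paths])
        return durations[self.chain_indices(include_burn_in)]

    @property
    def n_samples(self) -> int:
        """Chain length after burn-in (the MC sample count)."""
        return len(self.chain) - self.burn_in


def perturb_velocity(
    v: float,
    thermal: ThermalSpec,
    alpha: float,
    rng: np.random.Generator,
    mass: float,
) -> float:
    """Uhlenbeck-Ornstein velocity move; preserves Maxwell-Boltzmann at T."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    dv = rng.normal(0.0, math.sqrt(thermal.kT / mass))
    return alpha * v + math.sqrt(1.0 - alpha * alpha) * dv


def _reactive(path: Trajectory, basins) -> bool:
    """H_AB[X] = 1: endpoints in A and B, interior in neither."""
    basin_a, basin_b = basins
    n = len(path)
    if n < 2:
        return False
    q, s = path.q, path.active
    if not (basin_a.contains(float(q[0]), int(s[0])) and basin_b.contains(float(q[-1]), int(s[-1]))):
        return False
    for i in range(1, n - 1):
        if basin_a.contains(float(q[i]), int(s[i])) or basin_b.contains(float(q[i]), int(s[i])):
            return False
    return True


def shoot(
    current_path: Trajectory,
    basins,
    config: TPSConfig,
    model: TwoStateModel,
    rng: np.random.Generator,
) -> tuple[Trajectory, bool, int, str]:
    """One two-sided shooting move.

    Returns (path, accepted, steps_generated, reason); on rejection the
    returned path is ``current_path``.  ``steps_generated`` counts every
    integration step of both sides, also for rejected and uncommitted
    shots.
    """
    basin_a, basin_b = basins
    idx = int(rng.integers(0, len(current_path)))
    pt = current_path.point(idx)
    v_new = perturb_velocity(pt.p / model.mass, config.thermal, config.alpha, rng, model.mass)
    sp = replace(pt, p=model.mass * v_new, t=0.0)

    bwd_pts, bwd_hops, bwd_status, bwd_steps = propagate_until_basin(
        sp, basins, "backward", config.max_steps_per_side, config.dt, model, config.n_sub
    )
    fwd_pts, fwd_hops, fwd_status, fwd_steps = propagate_until_basin(
        sp, basins, "forward", config.max_steps_per_side, config.dt, model, config.n_sub
    )
    steps = bwd_steps + fwd_steps
    if "aborted" in (bwd_status, fwd_status):
        return current_path, False, steps, "aborted"
    if "uncommitted" in (bwd_status, fwd_status):
        return current_path, False, steps, "uncommitted"
    if {bwd_status, fwd_status} != {basin_a.name, basin_b.name}:
        return current_path, False, steps, "same-basin"

    candidate = Trajectory.from_points(
        bwd_pts + [sp] + fwd_pts, config.dt, sorted(bwd_hops + fwd_hops, key=lambda h: h.t)
    )
    if bwd_status == basin_b.name:
        if not config.reverse_accept:
            return current_path, False, steps, "reversed-orientation"
        candidate = candidate.reversed()
    # re-anchor times at zero
    shift = float(candidate.t[0])
    candidate.t = candidate.t - shift
    candidate.hops = [replace(h, t=h.t - shift) for h in candidate.hops]

    if not _reactive(candidate, basins):
        return current_path, False, steps, "interior-basin"

    l_old = current_path.n_steps
    l_new = candidate.n_steps
    if rng.random() >= min(1.0, l_old / l_new):
        return current_path, False, steps, "length-factor"
    candidate.meta["reactive"] = True
    return candidate, True, steps, "accepted"


def run_tps(
    initial_path: Trajectory,
    basins,
    config: TPSConfig,
    model: TwoStateModel,
    rng: np.random.Generator | None = None,
) -> PathEnsemble:
    """Run a shooting chain of ``config.n_paths`` moves from a seed path.

    The first ``burn_in_fraction`` of the chain is marked as equilibration
    and excluded from analysis by default (the paths are kept).  With a
    fixed seed the chain is bit-reproducible.
    """
    if not _reactive(initial_path, basins):
        raise ValueError("initial path does not satisfy the reactive-path constraint H_AB = 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    paths = [initial_path]
    chain = np.empty(config.n_paths, dtype=np.int64)
    records: list[ShotRecord] = []
    total_steps = 0
    current_idx = 0
    for i in range(config.n_paths):
        new_path, accepted, steps, reason = shoot(paths[current_idx], basins, config, model, rng)
        total_steps += steps
        if accepted:
            paths.append(new_path)
            current_idx = len(paths) - 1
        chain[i] = current_idx
        records.append(ShotRecord(i, accepted, steps, reason))
    return PathEnsemble(
        paths=paths,
        chain=chain,
        records=records,
        total_steps_generated=total_steps,
        burn_in=config.burn_in,
        config=config,
    )


def make_initial_path(
    model: TwoStateModel,
    basins,
    config: TPSConfig,
    start_point: PhasePoint | None = None,
    max_retries: int = 50,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Generate a seed reactive path from a high-energy start.

    The default start (q = 1.0 bohr, v = -0.0087 bohr/a.t.u., spin at the
    south pole) carries enough kinetic energy to traverse the barrier.
    The point is propagated in both time directions until each side first
    touches a basin; the assembled trajectory is trimmed to its reactive
    segment.  If no reactive segment emerges, fresh Maxwell-Boltzmann
    velocities at the run temperature are tried.
    """
    from natps.electronic import time_reverse
    from natps.integrator import mash_step

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if start_point is None:
        start_point = PhasePoint.make(q=1.0, p=model.mass * (-0.0087), c=[1.0, 0.0])

    def free_segment(origin: PhasePoint) -> tuple[list[PhasePoint], list[HopEvent]]:
        pts, hops, current = [], [], origin
        for _ in range(config.max_steps_per_side):
            try:
                current, event = mash_step(current, config.dt, model, config.n_sub)
            except RuntimeError:
                break
            pts.append(current)
            if event is not None:
                hops.append(event)
        return pts, hops

    pt = start_point
    for attempt in range(max_retries):
        # propagate a fixed window in both time directions, then trim to the
        # first reactive segment it contains
        fwd_pts, fwd_hops = free_segment(pt)
        rev_pts, rev_hops = free_segment(time_reverse(pt))
        t0 = pt.t
        bwd_pts = [replace(time_reverse(b), t=t0 - (b.t - t0)) for b in reversed(rev_pts)]
        bwd_hops = [
            HopEvent(
                t=t0 - (h.t - t0),
                q=h.q,
                phi=-h.phi,
                direction=(
                    h.direction if h.frustrated else ("down" if h.direction == "up" else "up")
                ),
                frustrated=h.frustrated,
            )
            for h in reversed(rev_hops)
        ]
        traj = Trajectory.from_points(
            bwd_pts + [pt] + fwd_pts, config.dt, sorted(bwd_hops + fwd_hops, key=lambda h: h.t)
        )
        segments = harvest_transitions(traj, basins)
        if segments:
            seed = segments[0]
            shift = float(seed.t[0])
            seed.t = seed.t - shift
            seed.hops = [replace(h, t=h.t - shift) for h in seed.hops]
            seed.meta["reactive"] = True
            return seed
        # retry with a fresh thermal velocity from the current position
        v = rng.normal(0.0, math.sqrt(config.thermal.kT / model.mass))
        pt = replace(start_point, p=model.mass * v)
    raise RuntimeError(
        f"no reactive seed path found in {max_retries} attempts; "
        "try a different start point or temperature"
    )


def anneal(
    temperatures,
    config: TPSConfig,
    model: TwoStateModel,
    basins,
    pilot_paths: int = 0,
    min_paths: int = 100,
    max_paths: int | None = None,
) -> list[PathEnsemble]:
    """Path-space annealing over a descending temperature ladder.

    Sampling starts at the highest temperature from a fresh seed path; each
    subsequent chain is seeded with the final accepted path of the previous
    one (reactivity does not depend on temperature, so the inherited seed
    remains valid; it is re-checked defensively).  If ``pilot_paths`` > 0 a
    short pilot chain estimates the transition-time spread sigma_tau at
    each temperature and the ensemble size is scaled as
    N(T) ~ (sigma_tau(T) / sigma_tau(T_0))^2 * config.n_paths, keeping
    sigma_tau / sqrt(N) roughly constant across the ladder.
    """
    temperatures = list(temperatures)
    if any(b >= a for a, b in zip(temperatures, temperatures[1:])):
        raise ValueError("temperatures must be strictly descending")
    rng = np.random.default_rng(config.seed)
    ensembles: list[PathEnsemble] = []
    seed_path: Trajectory | None = None
    sigma_ref: float | None = None
    for temp in temperatures:
        cfg = replace(config, temperature=temp, seed=int(rng.integers(0, 2**31 - 1)))
        if seed_path is None or not _reactive(seed_path, basins):
            seed_path = make_initial_path(model, basins, cfg, rng=rng)
        n_paths = cfg.n_paths
        if pilot_paths > 0:
            pilot_cfg = replace(cfg, n_paths=pilot_paths, burn_in_fraction=0.0)
            pilot = run_tps(seed_path, basins, pilot_cfg, model)
            sigma = float(np.std(pilot.transition_times()))
            if sigma_ref is None:
                sigma_ref = max(sigma, 1e-12)
            scale = (sigma / sigma_ref) ** 2
            n_paths = int(np.clip(round(config.n_paths * scale), min_paths, max_paths or 10**9))
            seed_path = pilot.paths[int(pilot.chain[-1])]
        cfg = replace(cfg, n_paths=n_paths)
        ens = run_tps(seed_path, basins, cfg, model)
        ens.meta["temperature"] = temp
        ensembles.append(ens)
        seed_path = ens.paths[int(ens.chain[-1])]
    return ensembles
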