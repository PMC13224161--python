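"""Ensemble observables: transition times, chain correlation, hop statistics.

All chain-level estimators weight each trajectory by its multiplicity in
the Markov chain (a rejected move repeats the previous path), which is the
correct Monte-Carlo estimator; statistics over the set of distinct paths
are available alongside where useful.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from natps.integrator import Trajectory
from natps.tps import PathEnsemble


def transition_time(path: Trajectory, basins=None) -> float:
    """Duration tau = L * dt of a reactive path (first-in-A to first-in-B)."""
    if basins is not None:
        from natps.tps import _reactive

        if not _reactive(path, basins):
            raise ValueError("path does not satisfy the reactive-path constraint")
    return path.duration


def autocorrelation(tau: np.ndarray, n_max: int) -> np.ndarray:
    """Autocorrelation C(n) of a transition-time series over MC steps.

    C(n) = sum_{t=0}^{N-n-1} (tau_t - <tau>)(tau_{t+n} - <tau>) / ((N-n) sigma^2)

    with the population (1/N) mean and variance of the full series, so that
    C(0) = 1 exactly.  A zero-variance series returns C(0) = 1, C(n>0) = 0
    with a warning.
    """
    tau = np.asarray(tau, dtype=float)
    n_data = len(tau)
    if n_max >= n_data:
        raise ValueError(f"n_max ({n_max}) must be smaller than the series length ({n_data})")
    mean = tau.mean()
    var = tau.var()  # population convention
    if var == 0.0:
        warnings.warn("zero-variance transition-time series; autocorrelation ill-defined")
        out = np.zeros(n_max + 1)
        out[0] = 1.0
        return out
    delta = tau - mean
    out = np.empty(n_max + 1)
    for n in range(n_max + 1):
        out[n] = np.dot(delta[: n_data - n], delta[n:]) / ((n_data - n) * var)
    return out


class DecorrelationResult(NamedTuple):
    n: int
    crossed: bool


def decorrelation_length(C: np.ndarray, threshold: float = 1.0 / math.e) -> DecorrelationResult:
    """Smallest lag n with C(n) <= threshold (default 1/e).

    If the autocorrelation never crosses the threshold within the computed
    range, the largest available lag is returned with ``crossed=False``.
    """
    C = np.asarray(C, dtype=float)
    if abs(C[0] - 1.0) > 1e-9:
        raise ValueError("autocorrelation must start at C(0) = 1")
    below = np.nonzero(C <= threshold)[0]
    if len(below) == 0:
        return DecorrelationResult(len(C) - 1, False)
    return DecorrelationResult(int(below[0]), True)


def coherence_angle(S) -> float:
    """Azimuthal angle phi = atan2(Sy, Sx) of the spin vector, in (-pi, pi]."""
    sx, sy = float(S[0]), float(S[1])
    if sx == 0.0 and sy == 0.0:
        raise ValueError("coherence angle undefined at Sx = Sy = 0")
    return math.atan2(sy, sx)


@dataclass(frozen=True)
class HopStatistics:
    """Chain-weighted aggregate of hop events over a path ensemble.

    ``positions``/``phis`` collect non-frustrated hops with chain
    multiplicity; ``hops_per_path`` is the per-MC-step count of
    non-frustrated hops; frustrated events are tallied separately.
    """

    positions: np.ndarray
    phis: np.ndarray
    hops_per_path: np.ndarray
    frustrated_per_path: np.ndarray

    @property
    def mean_hop_position(self) -> float:
        return float(self.positions.mean()) if len(self.positions) else float("nan")

    def fraction_at_least(self, k: int) -> float:
        return float(np.mean(self.hops_per_path >= k))

    @property
    def mean_hops(self) -> float:
        return float(self.hops_per_path.mean())


def hop_statistics(
    ensemble: PathEnsemble, include_burn_in: bool = False, weighted: bool = True
) -> HopStatistics:
    """Aggregate hop positions, coherence angles and per-path hop counts.

    ``weighted=True`` follows the chain (repeating paths as the chain
    dictates); ``weighted=False`` uses each distinct accepted path once,
    which is the right choice for independence-assuming hypothesis tests.
    """
    per_path_counts = {}
    per_path_frustrated = {}
    per_path_pos = {}
    per_path_phi = {}
    for i, path in enumerate(ensemble.paths):
        real = [h for h in path.hops if not h.frustrated]
        per_path_counts[i] = len(real)
        per_path_frustrated[i] = sum(1 for h in path.hops if h.frustrated)
        per_path_pos[i] = [h.q for h in real]
        per_path_phi[i] = [h.phi for h in real]

    if weighted:
        indices = ensemble.chain_indices(include_burn_in)
    else:
        indices = sorted(set(int(i) for i in ensemble.chain_indices(include_burn_in)))
    positions, phis, counts, frus = [], [], [], []
    for idx in indices:
        idx = int(idx)
        positions.extend(per_path_pos[idx])
        phis.extend(per_path_phi[idx])
        counts.append(per_path_counts[idx])
        frus.append(per_path_frustrated[idx])
    return HopStatistics(
        positions=np.array(positions),
        phis=np.array(phis),
        hops_per_path=np.array(counts),
        frustrated_per_path=np.array(frus),
    )


class EfficiencyRatio(NamedTuple):
    """Steps-per-transition-path ratio; a lower bound if nothing was found."""

    value: float
    is_lower_bound: bool

    def __str__(self) -> str:
        return f"ER > {self.value:g} (no transition paths)" if self.is_lower_bound else f"ER = {self.value:g}"


def efficiency_ratio(total_steps: int, n_paths: int) -> EfficiencyRatio:
    """Average number of integration steps spent per transition path.

    With zero paths the total step count is reported as a lower bound on
    the ratio.
    """
    if n_paths < 0 or total_steps < 0:
        raise ValueError("counts must be non-negative")
    if n_paths == 0:
        return EfficiencyRatio(float(total_steps), True)
    return EfficiencyRatio(total_steps / n_paths, False)


def path_density(
    ensemble: PathEnsemble, q_grid: np.ndarray, include_burn_in: bool = False
) -> dict[str, np.ndarray]:
    """State-resolved occupancy histograms of visited positions.

    Returns bin probability masses for the lower and upper adiabat over
    ``q_grid`` bin edges, chain-weighted, normalized so that the total
    (lower + upper) occupancy sums to 1.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    lower = np.zeros(len(q_grid) - 1)
    upper = np.zeros(len(q_grid) - 1)
    multiplicity = np.bincount(
        ensemble.chain_indices(include_burn_in), minlength=len(ensemble.paths)
    )
    for i, path in enumerate(ensemble.paths):
        w = multiplicity[i]
        if w == 0:
            continue
        on_lower = path.active < 0
        lower += w * np.histogram(path.q[on_lower], bins=q_grid)[0]
        upper += w * np.histogram(path.q[~on_lower], bins=q_grid)[0]
    total = lower.sum() + upper.sum()
    if total > 0:
        lower /= total
        upper /= total
    return {"lower": lower, "upper": upper, "edges": q_grid}


def compare_distributions(sample_a, sample_b):
    """Two-sample Kolmogorov-Smirnov test (statistic, p-value)."""
    sample_a = np.asarray(sample_a, dtype=float)
    sample_b = np.asarray(sample_b, dtype=float)
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(sample_a, sample_b, method="asymp")
    return res.statistic, res.pvalue
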