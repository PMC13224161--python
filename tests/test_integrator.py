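"""Integrator contracts: conservation, reversibility, hops, volume."""

import math

import numpy as np
import pytest

from natps.electronic import spin_to_coeffs, time_reverse
from natps.integrator import (
    PhasePoint,
    Trajectory,
    attempt_hop,
    mash_step,
    mash_step_naive,
    propagate_until_basin,
    total_energy,
)


def hop_rich_start(model):
    """The high-energy seed start: crosses the coupling region repeatedly."""
    return PhasePoint.make(q=1.0, p=model.mass * -0.0087, c=[1.0, 0.0])


def run_steps(pt, n, dt, model, step=mash_step):
    hops = []
    for _ in range(n):
        pt, ev = step(pt, dt, model)
        if ev is not None:
            hops.append(ev)
    return pt, hops


class TestTotalEnergy:
    def test_by_substitution_at_the_well(self, model):
        pt = PhasePoint.make(q=1.0, p=0.0, c=[1.0, 0.0])
        expected = 0.1 - math.sqrt(0.01 + 0.0001)
        assert total_energy(pt, model) == pytest.approx(expected, abs=1e-12)

    def test_hemisphere_energy_difference_is_the_gap(self, model, rng):
        for q in rng.uniform(-2, 2, size=10):
            lo = PhasePoint.make(q=q, p=3.0, c=[1.0, 0.0])
            hi = PhasePoint.make(q=q, p=3.0, c=[0.0, 1.0])
            gap = total_energy(hi, model) - total_energy(lo, model)
            assert gap == pytest.approx(2 * model.adiabatize(q).Vz, rel=1e-12)


class TestAttemptHop:
    def make_crossing_point(self, model, ke, q=0.1):
        p = math.sqrt(2 * model.mass * ke)
        return PhasePoint.make(q=q, p=p, c=spin_to_coeffs([1.0, 0.0, 0.0]))

    def test_down_hop_gains_the_gap(self, model):
        # Vz(q*) = 0.01 requires solving; use q where Vz is known: q=0 -> Vz=Vc
        pt = self.make_crossing_point(model, ke=0.005, q=0.0)
        pt = PhasePoint(q=pt.q, p=pt.p, c=pt.c, t=0.0, active=1)
        out, frustrated = attempt_hop(pt, "down", model)
        assert not frustrated
        assert out.active == -1
        assert out.p**2 / (2 * model.mass) == pytest.approx(0.005 + 2 * 0.01, rel=1e-12)

    def test_frustrated_up_hop_reflects(self, model):
        pt = self.make_crossing_point(model, ke=0.015, q=0.0)
        out, frustrated = attempt_hop(pt, "up", model)
        assert frustrated
        assert out.p == -pt.p
        assert out.active == -1

    def test_allowed_up_hop_conserves_energy(self, model):
        pt = self.make_crossing_point(model, ke=0.025, q=0.0)
        out, frustrated = attempt_hop(pt, "up", model)
        assert not frustrated
        assert out.active == 1
        assert out.p > 0  # momentum sign preserved
        assert out.p**2 / (2 * model.mass) == pytest.approx(0.005, rel=1e-12)
        e_before = pt.p**2 / (2 * model.mass) + model.surface(pt.q, -1)
        e_after = out.p**2 / (2 * model.mass) + model.surface(pt.q, +1)
        assert e_after == pytest.approx(e_before, abs=1e-14)

    def test_rejects_points_away_from_the_crossing(self, model):
        pt = PhasePoint.make(q=0.0, p=5.0, c=[1.0, 0.0])
        with pytest.raises(ValueError):
            attempt_hop(pt, "up", model)


class TestMashStep:
    def test_no_crossing_reduces_to_velocity_verlet(self, model):
        pt = PhasePoint.make(q=1.2, p=2.0, c=[1.0, 0.0])
        dt = 5.0
        out, ev = mash_step(pt, dt, model)
        assert ev is None
        ph = pt.p + 0.5 * dt * model.force(pt.q, -1)
        q1 = pt.q + dt * ph / model.mass
        p1 = ph + 0.5 * dt * model.force(q1, -1)
        assert out.q == pytest.approx(q1, abs=1e-15)
        assert out.p == pytest.approx(p1, abs=1e-15)

    def test_hop_step_conserves_energy(self, model):
        # near-crossing start just below the equator, moving right with
        # enough kinetic energy for the upward hop; dt small enough that
        # velocity-Verlet truncation sits below the 1e-8 bound, isolating
        # the hop bookkeeping itself
        c0 = spin_to_coeffs([math.sqrt(1 - 1e-6), 0.0, -1e-3])
        pt = PhasePoint.make(q=-0.02, p=math.sqrt(2 * model.mass * 0.025), c=c0)
        out, ev = mash_step(pt, 0.25, model)
        assert ev is not None and not ev.frustrated and ev.direction == "up"
        assert abs(total_energy(out, model) - total_energy(pt, model)) < 1e-8

    def test_hop_event_is_at_the_crossing(self, model):
        c0 = spin_to_coeffs([math.sqrt(1 - 1e-6), 0.0, -1e-3])
        pt = PhasePoint.make(q=-0.02, p=math.sqrt(2 * model.mass * 0.025), c=c0)
        dt = 5.0
        out, ev = mash_step(pt, dt, model)
        assert ev is not None
        assert pt.t < ev.t < pt.t + dt
        # re-propagating the hop-free trial up to the hop time lands at Sz ~ 0
        from natps.integrator import _vv_elec

        _, _, cm, cp = _vv_elec(
            pt.q, pt.p, complex(pt.c[0]), complex(pt.c[1]), -1, ev.t - pt.t, model, 8
        )
        assert abs(abs(cp) ** 2 - abs(cm) ** 2) < 1e-8

    def test_energy_drift_stays_bounded_with_hops(self, model):
        # velocity-Verlet truncation dominates: ~1e-4 Ha at the production
        # step of 5 a.t.u., ~1e-6 at dt = 0.5 (quadratic in dt)
        for dt, n, bound in ((5.0, 2000, 2e-4), (0.5, 2000, 1e-6)):
            pt = hop_rich_start(model)
            e0 = total_energy(pt, model)
            hops = 0
            worst = 0.0
            for _ in range(n):
                pt, ev = mash_step(pt, dt, model)
                hops += ev is not None
                worst = max(worst, abs(total_energy(pt, model) - e0))
            assert worst < bound, f"dt={dt}"
            assert hops > 0

    def test_spin_norm_pinned_to_the_sphere(self, model):
        pt = hop_rich_start(model)
        worst = 0.0
        for _ in range(1500):
            pt, _ = mash_step(pt, 5.0, model)
            worst = max(worst, abs(np.linalg.norm(pt.spin) - 1.0))
        assert worst < 1e-10

    def test_round_trip_reversibility_across_hops(self, model):
        start = hop_rich_start(model)
        fwd, hops = run_steps(start, 1000, 5.0, model)
        assert len(hops) >= 1
        back, _ = run_steps(time_reverse(fwd), 1000, 5.0, model)
        rec = time_reverse(back)
        assert abs(rec.q - start.q) < 1e-8
        assert abs(rec.p - start.p) < 1e-8
        assert np.max(np.abs(rec.c - start.c)) < 1e-8

    def test_naive_end_of_step_variant_breaks_reversibility(self, model):
        start = hop_rich_start(model)
        fwd, hops = run_steps(start, 1000, 5.0, model, step=mash_step_naive)
        assert len(hops) >= 1
        back, _ = run_steps(time_reverse(fwd), 1000, 5.0, model, step=mash_step_naive)
        rec = time_reverse(back)
        err = max(abs(rec.q - start.q), abs(rec.p - start.p))
        assert err > 1e-4  # >= 4 orders of magnitude worse than the exact scheme

    def test_one_step_map_preserves_phase_space_volume(self, model):
        # Jacobian of (q, p, Sz, phi) -> one hop-free step, by central
        # differences; dSz dphi is the invariant measure on the sphere
        import math as m

        def step_coords(x):
            q, p, sz, phi = x
            r = m.sqrt(1 - sz * sz)
            c = spin_to_coeffs([r * m.cos(phi), r * m.sin(phi), sz])
            out, ev = mash_step(PhasePoint.make(q=q, p=p, c=c), 5.0, model)
            assert ev is None
            s = out.spin
            return np.array([out.q, out.p, s[2], m.atan2(s[1], s[0])])

        x0 = np.array([-0.45, 25.0, -0.5, 0.3])
        h = np.array([1e-6, 1e-5, 1e-6, 1e-6])
        jac = np.empty((4, 4))
        for j in range(4):
            dx = np.zeros(4)
            dx[j] = h[j]
            jac[:, j] = (step_coords(x0 + dx) - step_coords(x0 - dx)) / (2 * h[j])
        assert abs(np.linalg.det(jac) - 1.0) < 1e-6

    def test_double_crossing_raises_with_diagnostic(self, model):
        # a huge step across the whole coupling region forces Sz to wander
        # back and forth within one step
        c0 = spin_to_coeffs([math.sqrt(1 - 0.04), 0.0, -0.2])
        pt = PhasePoint.make(q=-0.4, p=math.sqrt(2 * model.mass * 0.05), c=c0)
        with pytest.raises(RuntimeError, match="reduce dt"):
            for _ in range(10):
                pt, _ = mash_step(pt, 120.0, model)


class TestPropagateUntilBasin:
    def test_commits_from_a_high_energy_start(self, model, basins):
        pt = hop_rich_start(model)
        pts, hops, status, steps = propagate_until_basin(pt, basins, "forward", 4000, 5.0, model)
        assert status in ("A", "B")
        assert steps == len(pts)
        assert basins[0 if status == "A" else 1].contains(pts[-1].q, pts[-1].active)

    def test_backward_equals_forward_of_the_time_reversed_point(self, model, basins):
        pt = PhasePoint.make(q=0.2, p=-30.0, c=[1.0, 0.0])
        bwd, _, status_b, _ = propagate_until_basin(pt, basins, "backward", 4000, 5.0, model)
        fwd, _, status_f, _ = propagate_until_basin(
            time_reverse(pt), basins, "forward", 4000, 5.0, model
        )
        assert status_b == status_f
        assert len(bwd) == len(fwd)
        # stored backward points are the time-reversed forward points in
        # reverse order
        for b, f in zip(bwd, reversed(fwd)):
            assert b.q == pytest.approx(f.q, abs=1e-14)
            assert b.p == pytest.approx(-f.p, abs=1e-14)

    def test_uncommitted_when_out_of_steps(self, model, basins):
        pt = PhasePoint.make(q=0.0, p=0.0, c=[1.0, 0.0])
        _, _, status, steps = propagate_until_basin(pt, basins, "forward", 10, 5.0, model)
        assert status == "uncommitted"
        assert steps == 10


class TestTrajectory:
    def test_reversal_is_involutive_and_relabels_hops(self, model):
        pt = hop_rich_start(model)
        pts, hops = [], []
        for _ in range(300):
            pt, ev = mash_step(pt, 5.0, model)
            pts.append(pt)
            if ev:
                hops.append(ev)
        traj = Trajectory.from_points(pts, 5.0, hops)
        assert len(traj.hops) > 0
        rev = traj.reversed()
        np.testing.assert_allclose(rev.q, traj.q[::-1])
        np.testing.assert_allclose(rev.p, -traj.p[::-1])
        assert rev.t[0] == traj.t[0] and np.all(np.diff(rev.t) > 0)
        back = rev.reversed()
        np.testing.assert_allclose(back.q, traj.q)
        np.testing.assert_allclose(back.c, traj.c)
        for h1, h2 in zip(back.hops, traj.hops):
            assert h1.t == pytest.approx(h2.t, abs=1e-9)
            assert h1.direction == h2.direction

    def test_energy_labels_follow_the_active_surface(self, model):
        pt = hop_rich_start(model)
        pts = []
        for _ in range(200):
            pt, _ = mash_step(pt, 5.0, model)
            pts.append(pt)
        traj = Trajectory.from_points(pts, 5.0)
        energies = traj.energies(model)
        assert np.max(np.abs(energies - energies[0])) < 5e-4
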