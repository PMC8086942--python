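"""Particle advection, plane-transection detection and outlet classification."""

import numpy as np
import pytest

from fontanmix import CrossSection, FlowConfig, Particle, Pathline, advect, classify_outlet, detect_crossings, make_duct_field, release_schedule, trace_ensemble
from fontanmix.flow import BlinkingDuctField, SeedPlan
from fontanmix.tracing import LABEL_HV, STATUS_ACTIVE, STATUS_EXITED, STATUS_OUT_OF_DOMAIN


def _stirred_field(eps=0.3, pulsatility=0.55):
    return BlinkingDuctField(
        a=1.0, L=20.0, w0=10.0, period=1.0, pulsatility=pulsatility, eps=eps, tau=0.25, phase_u=0.9, phase_v=2.3
    )


class TestAdvect:
    def test_steady_axial_transport(self, steady_field):
        # eps = 0, P = 0: dz/dt = w0 on the axis, (x, y) frozen
        p = Particle(id=0, label=LABEL_HV, x=0.0, y=0.0, z=0.0)
        (path,) = advect(steady_field, [p], dt=0.01, max_cycles=3, substeps=2)
        assert path.status == STATUS_EXITED  # w0 = 10, L = 20: the axis particle exits after 2 s
        # travel is linear in time until the outlet
        k = min(150, len(path.t) - 2)
        assert path.xyz[k, 2] == pytest.approx(steady_field.w0 * path.t[k], rel=1e-9)
        assert path.xyz[-1, 2] == pytest.approx(steady_field.L)

    def test_transverse_position_frozen_without_stirring(self, steady_field, rng):
        pts = [Particle(id=i, label=LABEL_HV, x=x, y=y, z=0.0) for i, (x, y) in enumerate(rng.uniform(-0.7, 0.7, (20, 2)))]
        paths = advect(steady_field, pts, dt=0.01, max_cycles=2, substeps=2)
        for p, pt in zip(paths, pts):
            assert np.max(np.abs(p.xyz[:, 0] - pt.x)) < 1e-9
            assert np.max(np.abs(p.xyz[:, 1] - pt.y)) < 1e-9

    def test_terminal_position_matches_tiny_step_euler(self):
        # independent oracle: forward Euler at dt/1000
        f = _stirred_field(eps=0.3)
        dt, substeps, horizon = 0.01, 10, 150
        p = Particle(id=0, label=LABEL_HV, x=0.2, y=-0.3, z=0.0)
        (path,) = advect(f, [p], dt=dt, max_cycles=2, substeps=substeps)
        t_end = path.t[horizon]
        x, y, z = 0.2, -0.3, 0.0
        h = dt / 1000.0
        n_euler = int(round(t_end / h))
        for i in range(n_euler):
            u, v, w = f.velocity(x, y, z, i * h)
            x, y, z = x + h * u, y + h * v, z + h * w
        assert abs(path.xyz[horizon, 0] - x) < 1e-3
        assert abs(path.xyz[horizon, 1] - y) < 1e-3
        assert abs(path.xyz[horizon, 2] - z) < 1e-3

    def test_out_of_domain_clamped_and_flagged(self):
        # a strong blink drives near-wall particles through the side wall
        f = _stirred_field(eps=1.5)
        pts = [Particle(id=i, label=LABEL_HV, x=0.98, y=-0.5 + 0.1 * i, z=0.0) for i in range(5)]
        paths = advect(f, pts, dt=0.01, max_cycles=1, substeps=5)
        flagged = [p for p in paths if p.status == STATUS_OUT_OF_DOMAIN]
        assert flagged
        for p in flagged:
            assert np.max(np.abs(p.xyz[-1, :2])) <= f.a + 1e-12

    def test_pathline_time_strictly_increasing(self):
        with pytest.raises(ValueError):
            Pathline(particle_id=0, label=0, t=np.array([0.0, 0.0, 0.1]), xyz=np.zeros((3, 3)))


class TestDetectCrossings:
    def _pathline(self, zs, xs=None, dt=1.0):
        n = len(zs)
        xs = xs if xs is not None else np.zeros(n)
        xyz = np.column_stack([xs, np.zeros(n), zs])
        return Pathline(particle_id=7, label=LABEL_HV, t=np.arange(1, n + 1, dtype=float) * dt, xyz=xyz)

    def test_linear_interpolation(self):
        path = self._pathline([0.4, 0.6], xs=[1.0, 2.0])
        (c,) = detect_crossings(path, CrossSection("caudal", 0.5), dt=1.0, n_steps=10)
        assert c.x == pytest.approx(1.5)
        assert c.plane_id == "caudal"

    def test_monotone_below_plane(self):
        path = self._pathline([0.1, 0.2, 0.3, 0.4])
        assert detect_crossings(path, CrossSection("caudal", 0.5), dt=1.0, n_steps=10) == []

    def test_oscillating_pathline_counts_positive_crossings_only(self):
        path = self._pathline([0.4, 0.6, 0.4, 0.6])
        crossings = detect_crossings(path, CrossSection("caudal", 0.5), dt=1.0, n_steps=10)
        assert len(crossings) == 2
        assert all(c.direction == 1 for c in crossings)

    def test_sample_on_plane_counted_once(self):
        path = self._pathline([0.3, 0.5, 0.7])
        crossings = detect_crossings(path, CrossSection("caudal", 0.5), dt=1.0, n_steps=10)
        assert len(crossings) == 1
        assert crossings[0].step == 2  # assigned to the segment ending on the plane

    def test_phase_and_cycle_bookkeeping(self):
        path = self._pathline([0.0, 0.2, 0.45, 0.8], dt=1.0)
        (c,) = detect_crossings(path, CrossSection("cranial", 0.5), dt=1.0, n_steps=3)
        assert c.step == 4
        assert c.cycle == 2
        assert c.phase == 1


class TestClassifyOutlet:
    def _exited(self, x_exit, pid=0):
        xyz = np.array([[0.0, 0.0, 19.0], [x_exit, 0.0, 20.0]])
        return Pathline(particle_id=pid, label=LABEL_HV, t=np.array([0.0, 0.1]), xyz=xyz, status=STATUS_EXITED)

    def test_left_of_threshold(self):
        assert classify_outlet(self._exited(0.5), x_split=0.0) == "LPA"
        assert classify_outlet(self._exited(-0.5), x_split=0.0) == "RPA"

    def test_active_is_unresolved(self):
        p = self._exited(0.5)
        p.status = STATUS_ACTIVE
        assert classify_outlet(p, x_split=0.0) == "unresolved"

    def test_tie_alternates_by_parity(self):
        assert classify_outlet(self._exited(0.0, pid=0), x_split=0.0) == "LPA"
        assert classify_outlet(self._exited(0.0, pid=1), x_split=0.0) == "RPA"

    def test_straight_streamlines_classified_by_seed_position(self, steady_field, rng):
        # eps = 0: outlet side is exactly the seed's side of x_split
        x = rng.uniform(-0.7, 0.7, 200)
        y = rng.uniform(-0.7, 0.7, 200)
        plan = SeedPlan(x=x, y=y, z=0.0, label=np.full(200, LABEL_HV, np.int8), subregion=np.full(200, -1, np.int16))
        res = trace_ensemble(steady_field, [(0, plan)], n_steps=100, max_cycles=12, substeps=2)
        exited = res.particles[res.particles["status"] == STATUS_EXITED]
        assert len(exited) == 200
        lpa_engine = (exited.sort_values("id")["exit_x"].to_numpy() > 0).sum()
        assert lpa_engine == (x > 0).sum()


class TestReleaseSchedule:
    def test_mixing_mode_five_cycles(self, small_config):
        events = release_schedule("mixing", small_config, n_hv=3)
        assert len(events) == 5 * small_config.n_steps
        assert [k for k, _ in events] == list(range(500))

    def test_hfd_mode_one_cycle(self, small_config):
        events = release_schedule("hfd", small_config, n_hv=3)
        assert len(events) == small_config.n_steps

    def test_hfd_horizon_between_5_and_12_cycles(self, small_config):
        field = make_duct_field(small_config)
        events = release_schedule("hfd", small_config, n_hv=5)
        res = trace_ensemble(
            field, events, n_steps=100, max_cycles=12, substeps=1, min_cycles=5, resolve_fraction=0.99
        )
        assert 5 <= res.cycles_run <= 12

    def test_unknown_mode_rejected(self, small_config):
        with pytest.raises(ValueError):
            release_schedule("both", small_config)


class TestEnsembleEngine:
    def test_particle_conservation(self, rng):
        f = _stirred_field(eps=0.4)
        plans = []
        for k in range(0, 50, 10):
            n = 40
            plans.append(
                (
                    k,
                    SeedPlan(
                        x=rng.uniform(-0.9, 0.9, n),
                        y=rng.uniform(-0.9, 0.9, n),
                        z=0.0,
                        label=np.full(n, LABEL_HV, np.int8),
                        subregion=np.full(n, -1, np.int16),
                    ),
                )
            )
        with pytest.warns(UserWarning):
            res = trace_ensemble(f, plans, n_steps=100, max_cycles=3, substeps=2)
        assert len(res.particles) == 200
        assert set(res.particles["status"]).issubset({STATUS_ACTIVE, STATUS_EXITED, STATUS_OUT_OF_DOMAIN})

    def test_matches_pathline_route(self, rng):
        # the streaming engine and the pathline+detector route must agree
        f = _stirred_field(eps=0.25)
        n = 15
        x, y = rng.uniform(-0.6, 0.6, (2, n))
        plan = SeedPlan(x=x, y=y, z=0.0, label=np.full(n, LABEL_HV, np.int8), subregion=np.full(n, -1, np.int16))
        sec = CrossSection("caudal", 2.0)
        res = trace_ensemble(f, [(0, plan)], sections=(sec,), n_steps=100, max_cycles=3, substeps=4)
        particles = [Particle(id=i, label=LABEL_HV, x=x[i], y=y[i], z=0.0) for i in range(n)]
        paths = advect(f, particles, dt=0.01, max_cycles=3, substeps=4)
        ref = []
        for p in paths:
            ref.extend(detect_crossings(p, sec, dt=0.01, n_steps=100))
        assert len(ref) == len(res.crossings)
        eng = res.crossings.sort_values("particle_id")
        ref = sorted(ref, key=lambda c: c.particle_id)
        assert np.allclose(eng["x"].to_numpy(), [c.x for c in ref], atol=1e-9)
        assert np.array_equal(eng["step"].to_numpy(), [c.step for c in ref])

    def test_step_halving_moves_crossings_below_tolerance(self, rng):
        f = _stirred_field(eps=0.3)
        n = 30
        x, y = rng.uniform(-0.6, 0.6, (2, n))

        def crossings(substeps):
            plan = SeedPlan(x=x.copy(), y=y.copy(), z=0.0, label=np.full(n, LABEL_HV, np.int8), subregion=np.full(n, -1, np.int16))
            sec = CrossSection("cranial", 18.0)
            res = trace_ensemble(f, [(0, plan)], sections=(sec,), n_steps=100, max_cycles=5, substeps=substeps)
            return res.crossings.sort_values("particle_id")[["particle_id", "x", "y"]].to_numpy()

        c1, c2 = crossings(10), crossings(20)
        assert len(c1) == len(c2)
        assert np.array_equal(c1[:, 0], c2[:, 0])
        assert np.max(np.abs(c1[:, 1:] - c2[:, 1:])) < 1e-4

    def test_fused_kernel_matches_generic_path(self, rng):
        # the numba fast path must be numerically identical to the generic
        # field-interface route
        kwargs = dict(a=1.0, L=20.0, w0=10.0, period=1.0, pulsatility=0.55, eps=0.25, tau=0.5, phase_u=0.9, phase_v=2.3)
        f_fast = BlinkingDuctField(fast_kernel=True, **kwargs)
        f_slow = BlinkingDuctField(fast_kernel=False, **kwargs)
        n = 200
        x, y = rng.uniform(-0.6, 0.6, (2, n))

        def run(field):
            plan = SeedPlan(
                x=x.copy(), y=y.copy(), z=0.0, label=np.full(n, LABEL_HV, np.int8), subregion=np.full(n, -1, np.int16)
            )
            return trace_ensemble(
                field, [(0, plan)], sections=(CrossSection("caudal", 2.0),), n_steps=100, max_cycles=2, substeps=2
            )

        r1, r2 = run(f_fast), run(f_slow)
        assert (r1.particles["status"] == r2.particles["status"]).all()
        assert np.allclose(r1.particles[["exit_x", "exit_y"]], r2.particles[["exit_x", "exit_y"]], atol=1e-12, equal_nan=True)
        assert len(r1.crossings) == len(r2.crossings)
        assert np.allclose(r1.crossings[["x", "y"]], r2.crossings[["x", "y"]], atol=1e-12)

    def test_unidirectional_flow_crosses_each_plane_once(self, rng):
        f = _stirred_field(eps=0.1)
        n = 50
        plan = SeedPlan(
            x=rng.uniform(-0.5, 0.5, n),
            y=rng.uniform(-0.5, 0.5, n),
            z=0.0,
            label=np.full(n, LABEL_HV, np.int8),
            subregion=np.full(n, -1, np.int16),
        )
        sec = CrossSection("caudal", 2.0)
        res = trace_ensemble(f, [(0, plan)], sections=(sec,), n_steps=100, max_cycles=5, substeps=2)
        assert res.crossings["particle_id"].is_unique
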