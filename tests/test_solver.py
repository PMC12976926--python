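"""Solver components: TV, costs, lambda scaling, CG image step, SGD motion step."""

import numpy as np
import pytest

from freebeat.encoding import (
    AcquisitionSet,
    CoilMaps,
    ReferenceImage,
    forward,
    synthetic_coilmaps,
)
from freebeat.motion import LowRankMotion, init_temporal, lowpass_temporal
from freebeat.solver import (
    CostTrace,
    FieldUpsampler,
    ReconConfig,
    data_cost,
    image_step,
    motion_step,
    run,
    scale_lambda,
    tv_iso,
    tv_iso_grad,
)
from freebeat.solver import _frame_motion_gradient


class TestTV:
    def test_constant_field_zero(self):
        f = np.full((3, 6, 6, 6), 2.7)
        assert tv_iso(f) == 0.0

    def test_positive_one_homogeneous(self, rng):
        f = rng.standard_normal((3, 5, 5, 5))
        assert tv_iso(2.0 * f) == pytest.approx(2.0 * tv_iso(f), rel=1e-12)
        assert tv_iso(f) >= 0.0

    def test_single_voxel_impulse_matches_exhaustive_enumeration(self):
        # one nonzero u_x at voxel (1,2,1) of a 4^3 field: brute-force the
        # nine forward-difference stencils over every voxel
        f = np.zeros((3, 4, 4, 4))
        f[0, 1, 2, 1] = 1.0
        brute = 0.0
        for x in range(4):
            for y in range(4):
                for z in range(4):
                    sq = 0.0
                    for c in range(3):
                        for a, (dx, dy, dz) in enumerate([(1, 0, 0), (0, 1, 0), (0, 0, 1)]):
                            xx, yy, zz = x + dx, y + dy, z + dz
                            if xx < 4 and yy < 4 and zz < 4:
                                sq += (f[c, xx, yy, zz] - f[c, x, y, z]) ** 2
                    brute += np.sqrt(sq)
        assert tv_iso(f) == pytest.approx(brute, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        f = rng.standard_normal((3, 5, 5, 5))
        g = tv_iso_grad(f, eps=1e-10)
        d = rng.standard_normal(f.shape)
        d /= np.linalg.norm(d)
        eps = 1e-6
        num = (tv_iso(f + eps * d) - tv_iso(f - eps * d)) / (2 * eps)
        assert num == pytest.approx(float((g * d).sum()), rel=1e-5)

    def test_nonfinite_rejected(self):
        f = np.zeros((3, 4, 4, 4))
        f[0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            tv_iso(f)


class TestDataCost:
    @pytest.fixture(scope="class")
    def problem(self, small_scene, small_acquisition):
        acq, maps = small_acquisition
        grid = tuple(small_scene.spec.grid_shape)
        model = small_scene.gt_motion_model(
            acq.binning.n_frames, acq.binning.frame_rate_hz
        )
        q = ReferenceImage(small_scene.reference_volume, small_scene.voxel_size_mm)
        return acq, maps, model, q

    def test_exact_model_gives_zero_cost(self, problem):
        acq, maps, model, q = problem
        assert data_cost(acq, q, model, maps, np.arange(8)) < 1e-25

    def test_unit_modulus_residual_normalization(self, problem, rng):
        acq, maps, model, q = problem
        # zero image against unit-modulus data: per-sample-normalized l2 is 1
        phases = rng.uniform(0, 2 * np.pi, acq.samples.shape)
        unit = AcquisitionSet(
            samples=np.exp(1j * phases), schedule=acq.schedule, binning=acq.binning
        )
        zero_q = ReferenceImage(np.zeros_like(q.data), q.voxel_size_mm)
        assert data_cost(unit, zero_q, model, maps, np.arange(4)) == pytest.approx(1.0)
        assert data_cost(
            unit, zero_q, model, maps, np.arange(4), norm="l1"
        ) == pytest.approx(1.0)

    def test_l1_l2_cauchy_schwarz_relation(self, problem):
        acq, maps, model, q = problem
        zero_q = ReferenceImage(np.zeros_like(q.data), q.voxel_size_mm)
        sub = np.arange(6)
        n = 6 * 20 * acq.n_coils * q.data.shape[0]
        l1 = data_cost(acq, zero_q, model, maps, sub, "l1")
        l2 = data_cost(acq, zero_q, model, maps, sub, "l2")
        assert l1 <= np.sqrt(l2) + 1e-12  # mean|r| <= sqrt(mean|r|^2)

    def test_empty_subset_rejected(self, problem):
        acq, maps, model, q = problem
        with pytest.raises(ValueError):
            data_cost(acq, q, model, maps, np.array([]))
        with pytest.raises(ValueError):
            data_cost(acq, q, model, maps, np.arange(3), norm="huber")


class TestScaleLambda:
    @pytest.fixture(scope="class")
    def problem(self, small_scene, small_acquisition):
        acq, maps = small_acquisition
        model = small_scene.gt_motion_model(
            acq.binning.n_frames, acq.binning.frame_rate_hz
        )
        q = ReferenceImage(small_scene.reference_volume * 0.5, small_scene.voxel_size_mm)
        return acq, maps, model, q

    def test_zero_relative_weight(self, problem):
        acq, maps, model, q = problem
        assert scale_lambda(0.0, q, model, acq, maps) == 0.0

    def test_zero_motion_init_finite(self, problem):
        acq, maps, model, q = problem
        zero = LowRankMotion(
            Phi=np.zeros_like(model.Phi), Psi=model.Psi,
            grid_shape=model.grid_shape, full_shape=model.full_shape,
            rank=model.rank, frame_rate_hz=model.frame_rate_hz,
        )
        lam = scale_lambda(0.1, q, zero, acq, maps)
        assert np.isfinite(lam) and lam > 0

    def test_homogeneity_in_data_scale(self, problem):
        # with a zero reference the residual is exactly the data, so
        # doubling k-space quadruples the l2 cost and doubles the l1 cost
        acq, maps, model, q = problem
        zero_q = ReferenceImage(np.zeros_like(q.data), q.voxel_size_mm)
        doubled = AcquisitionSet(
            samples=2 * acq.samples, schedule=acq.schedule, binning=acq.binning
        )
        sub = np.arange(5)
        base_l2 = scale_lambda(0.1, zero_q, model, acq, maps, "l2", sub)
        base_l1 = scale_lambda(0.1, zero_q, model, acq, maps, "l1", sub)
        assert scale_lambda(0.1, zero_q, model, doubled, maps, "l2", sub) \
            == pytest.approx(4 * base_l2, rel=1e-10)
        assert scale_lambda(0.1, zero_q, model, doubled, maps, "l1", sub) \
            == pytest.approx(2 * base_l1, rel=1e-10)


class TestImageStep:
    def test_fully_sampled_recovery(self, rng):
        shape = (16, 16, 16)
        truth = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        maps = CoilMaps(maps=np.ones((1,) + shape, complex))
        yy, zz = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        full = np.stack([yy.ravel(), zz.ravel()], axis=1)
        from freebeat.trajectory import FrameBinning, SamplingSchedule

        sch = SamplingSchedule(readouts=full, matrix=shape, tr_ms=1.0)
        samples = forward(truth, None, maps, full)
        acq = AcquisitionSet(
            samples=np.transpose(samples, (1, 0, 2)),
            schedule=sch,
            binning=FrameBinning(256, 1, 256.0, 1000 / 256, np.arange(256)[None, :]),
        )
        model = LowRankMotion(
            Phi=np.zeros((3 * 16**3, 1)), Psi=np.zeros((1, 1)),
            grid_shape=shape, full_shape=shape, rank=1, frame_rate_hz=4.0,
        )
        cfg = ReconConfig(rank=1, image_inner_iters=10, max_iters=1, coarse_iters=0)
        q0 = ReferenceImage(np.zeros(shape, complex))
        q = image_step(acq, model, maps, q0, cfg)
        assert np.abs(q.data - truth).max() < 1e-5

    def test_zero_data_gives_zero_image(self, small_acquisition):
        acq, maps = small_acquisition
        silent = AcquisitionSet(
            samples=np.zeros_like(acq.samples), schedule=acq.schedule, binning=acq.binning
        )
        shape = maps.shape
        model = LowRankMotion(
            Phi=np.zeros((3 * int(np.prod(shape)), 1)),
            Psi=np.zeros((acq.binning.n_frames, 1)),
            grid_shape=shape, full_shape=shape, rank=1,
            frame_rate_hz=acq.binning.frame_rate_hz,
        )
        cfg = ReconConfig(rank=1, image_inner_iters=5, max_iters=1, coarse_iters=0)
        q0 = ReferenceImage(np.zeros(shape, complex))
        q = image_step(silent, model, maps, q0, cfg, frame_subset=np.arange(8))
        assert np.abs(q.data).max() == 0.0


class TestMotionGradient:
    def test_matches_finite_differences_both_norms(self, small_scene, small_acquisition):
        acq, maps = small_acquisition
        rng = np.random.default_rng(0)
        q = small_scene.reference_volume
        u = 0.3 * rng.standard_normal((3,) + q.shape)
        t = 5
        n = 20 * maps.n_coils * q.shape[0]
        for norm in ("l2", "l1"):
            g, _ = _frame_motion_gradient(acq, q, u, maps, t, norm, n)

            def cost(uu):
                r = forward(q, uu, maps, acq.frame_lines(t)) - acq.frame_samples(t)
                return (
                    (np.abs(r) ** 2).sum() if norm == "l2" else np.abs(r).sum()
                ) / n

            d = rng.standard_normal(u.shape)
            d /= np.linalg.norm(d)
            eps = 1e-5
            num = (cost(u + eps * d) - cost(u - eps * d)) / (2 * eps)
            assert num == pytest.approx(float((g * d).sum()), rel=1e-4)

    def test_zero_data_zero_image_keeps_model_at_zero(self, small_acquisition):
        acq, maps = small_acquisition
        shape = maps.shape
        silent = AcquisitionSet(
            samples=np.zeros_like(acq.samples), schedule=acq.schedule, binning=acq.binning
        )
        M = acq.binning.n_frames
        model = LowRankMotion(
            Phi=np.zeros((3 * int(np.prod(shape)), 2)),
            Psi=init_temporal(M, 2, acq.binning.frame_rate_hz, seed=0),
            grid_shape=shape, full_shape=shape, rank=2,
            frame_rate_hz=acq.binning.frame_rate_hz,
        )
        cfg = ReconConfig(rank=2, max_iters=3, coarse_iters=0, batch_frames=8)
        q0 = ReferenceImage(np.zeros(shape, complex))
        out = motion_step(silent, q0, model, maps, cfg, 3)
        assert np.all(out.Phi == 0.0)


class TestRunOrchestration:
    def test_zero_iterations_returns_initialization(self, small_acquisition):
        acq, maps = small_acquisition
        cfg = ReconConfig(rank=2, max_iters=0, coarse_iters=0, batch_frames=8, seed=3)
        q, model, trace = run(acq, maps, cfg)
        assert len(trace) == 0
        assert np.all(model.Phi == 0.0)
        assert model.Psi.shape == (acq.binning.n_frames, 2)

    def test_seeded_runs_are_bit_identical(self, small_acquisition):
        acq, maps = small_acquisition
        cfg = ReconConfig(
            rank=2, max_iters=6, coarse_iters=0, batch_frames=8,
            pyramid_levels=1, image_every=3, image_inner_iters=2, seed=7,
        )
        q1, m1, t1 = run(acq, maps, cfg)
        q2, m2, t2 = run(acq, maps, cfg)
        assert np.array_equal(m1.Phi, m2.Phi)
        assert np.array_equal(q1.data, q2.data)
        assert t1.total == t2.total

    def test_cost_trace_decreases_overall(self, small_acquisition):
        acq, maps = small_acquisition
        cfg = ReconConfig(
            rank=4, max_iters=20, coarse_iters=0, batch_frames=16,
            pyramid_levels=1, image_every=5, image_inner_iters=3, seed=1,
        )
        _, _, trace = run(acq, maps, cfg)
        assert trace.total[-1] < trace.total[0]

    def test_trace_rejects_nonfinite(self):
        tr = CostTrace()
        with pytest.raises(FloatingPointError):
            tr.append(np.nan, 0.0, (8, 8, 8))


class TestFieldUpsampler:
    def test_adjoint_dot_test(self, rng):
        ups = FieldUpsampler((8, 8, 8), (16, 16, 16))
        x = rng.standard_normal((3, 8, 8, 8))
        y = rng.standard_normal((3, 16, 16, 16))
        lhs = float((ups.up(x) * y).sum())
        rhs = float((x * ups.down_adjoint(y)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_identity_when_same_grid(self, rng):
        ups = FieldUpsampler((8, 8, 8), (8, 8, 8))
        x = rng.standard_normal((3, 8, 8, 8))
        assert ups.up(x) is x


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            ReconConfig(norm="huber")
        with pytest.raises(ValueError):
            ReconConfig(coarse_iters=200, max_iters=100)
        with pytest.raises(ValueError):
            ReconConfig(lambda_rel=-1.0)
        with pytest.raises(ValueError):
            ReconConfig(precision="half")
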