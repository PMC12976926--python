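"""Encoding operator: warp, forward/adjoint pair, simulation, calibration."""

import numpy as np
import pytest

from freebeat.encoding import (
    AcquisitionSet,
    CoilMaps,
    ReferenceImage,
    adjoint,
    estimate_coilmaps,
    fft3c,
    forward,
    gridded_time_average,
    ifft3c,
    simulate_acquisition,
    synthetic_coilmaps,
    time_averaged_recon,
    warp_backward,
)
from freebeat.phantom import Ellipsoid, PhantomSpec, make_phantom
from freebeat.trajectory import SamplingSchedule, build_schedule

SHAPE = (16, 16, 16)


def _complex_volume(rng, shape=SHAPE):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


def _smooth_field(scale=0.5, shape=SHAPE):
    x = np.sin(np.linspace(0, 3, shape[0]))[:, None, None] * np.ones(shape)
    return scale * np.stack([x, 0.5 * x, -x])


class TestWarp:
    def test_identity_warp_is_exact(self, rng):
        v = _complex_volume(rng)
        assert np.array_equal(warp_backward(v, np.zeros((3,) + SHAPE)), v)

    def test_integer_shift_with_fill(self, rng):
        v = _complex_volume(rng)
        f = np.zeros((3,) + SHAPE)
        f[0] = 1.0
        w = warp_backward(v, f, fill=7.0)
        assert np.array_equal(w[:-1], v[1:])
        assert np.allclose(w[-1], 7.0)

    def test_half_voxel_shift_averages_neighbors(self):
        lin = np.arange(16, dtype=float)[:, None, None] * np.ones(SHAPE)
        f = np.zeros((3,) + SHAPE)
        f[0] = 0.5
        w = warp_backward(lin.astype(complex), f)
        expected = 0.5 * (lin[:-1] + lin[1:])
        assert np.abs(w[:-1].real - expected).max() < 1e-12

    def test_constant_volume_invariant_under_inbounds_field(self, rng):
        v = np.full(SHAPE, 2.5 + 1j)
        f = _smooth_field(0.9)
        w = warp_backward(v, f)
        interior = (slice(2, -2),) * 3
        assert np.abs(w[interior] - v[interior]).max() < 1e-12

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            warp_backward(_complex_volume(rng), np.zeros((3, 8, 8, 8)))


class TestForwardAdjoint:
    @pytest.fixture(scope="class")
    def operators(self):
        rng = np.random.default_rng(5)
        maps = synthetic_coilmaps(SHAPE, 4, seed=2)
        lines = np.stack([rng.integers(0, 16, 30), rng.integers(0, 16, 30)], axis=1)
        return maps, lines

    @pytest.mark.parametrize("with_field", [False, True])
    def test_adjoint_dot_test(self, operators, rng, with_field):
        maps, lines = operators
        field = _smooth_field(0.5) if with_field else None
        x = _complex_volume(rng)
        y = rng.standard_normal((4, 30, 16)) + 1j * rng.standard_normal((4, 30, 16))
        Ax = forward(x, field, maps, lines)
        Ahy = adjoint(y, field, maps, lines)
        err = abs(np.vdot(y, Ax) - np.vdot(Ahy, x))
        assert err / (np.linalg.norm(Ax) * np.linalg.norm(y)) < 1e-6

    def test_zero_image_zero_samples(self, operators):
        maps, lines = operators
        out = forward(np.zeros(SHAPE, complex), None, maps, lines)
        assert np.all(out == 0)
        back = adjoint(np.zeros((4, 30, 16), complex), None, maps, lines)
        assert np.all(back == 0)

    def test_full_sampling_uniform_coil_reduces_to_fft(self, rng):
        x = _complex_volume(rng)
        maps = CoilMaps(maps=np.ones((1,) + SHAPE, complex))
        yy, zz = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        full = np.stack([yy.ravel(), zz.ravel()], axis=1)
        s = forward(x, None, maps, full)
        k = fft3c(x)
        assert np.abs(s[0] - k[:, full[:, 0], full[:, 1]].T).max() < 1e-12
        # adjoint-of-forward is identity for a unitary operator
        xr = adjoint(s, None, maps, full)
        assert np.abs(xr - x).max() < 1e-12

    def test_parseval_on_full_sampling(self, rng):
        x = _complex_volume(rng)
        maps = CoilMaps(maps=np.ones((1,) + SHAPE, complex))
        yy, zz = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        full = np.stack([yy.ravel(), zz.ravel()], axis=1)
        s = forward(x, None, maps, full)
        assert np.linalg.norm(s) == pytest.approx(np.linalg.norm(x), rel=1e-12)

    def test_empty_frame_rejected(self, operators, rng):
        maps, _ = operators
        with pytest.raises(ValueError):
            forward(_complex_volume(rng), None, maps, np.empty((0, 2), int))

    def test_centered_fft_roundtrip(self, rng):
        x = _complex_volume(rng)
        assert np.abs(ifft3c(fft3c(x)) - x).max() < 1e-12


class TestSimulation:
    def test_static_noiseless_full_cartesian_roundtrip(self):
        spec = PhantomSpec(
            grid_shape=SHAPE, voxel_size_mm=(6, 6, 6),
            body=Ellipsoid((7.8, 7.8, 7.8), (7.0, 7.3, 7.0), 0.35),
            ventricles=(Ellipsoid((7.8, 7.8, 7.8), (3.5, 3.0, 3.0), 1.0),),
            ventricle_labels=("rv",), target_label="rv",
            myocardium_shell_thickness=0.8,
            contraction_amplitude=0.0,
        )
        scene = make_phantom(spec)
        yy, zz = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        readouts = np.stack([yy.ravel(), zz.ravel()], axis=1)
        sch = SamplingSchedule(readouts=readouts, matrix=SHAPE, tr_ms=2.4)
        maps = CoilMaps(maps=np.ones((1,) + SHAPE, complex))
        acq = simulate_acquisition(scene, maps, sch, 256, noise_sigma=0.0, seed=0)
        k = np.transpose(
            acq.samples[:, 0, :].reshape(16, 16, 16), (2, 0, 1)
        )
        recon = ifft3c(k)
        ref = scene.reference_volume
        assert np.abs(recon - ref).max() / np.abs(ref).max() < 1e-6

    def test_seed_reproducibility(self, small_scene):
        grid = tuple(small_scene.spec.grid_shape)
        sch = build_schedule(200, grid, 2.4, 20)
        maps = synthetic_coilmaps(grid, 2, seed=0)
        a = simulate_acquisition(small_scene, maps, sch, 20, 0.05, seed=9)
        b = simulate_acquisition(small_scene, maps, sch, 20, 0.05, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_noise_variance_matches_sigma(self, small_scene):
        grid = tuple(small_scene.spec.grid_shape)
        sch = build_schedule(2000, grid, 2.4, 20)
        maps = synthetic_coilmaps(grid, 4, seed=0)
        clean = simulate_acquisition(small_scene, maps, sch, 20, 0.0, seed=3)
        sigma = 0.07
        noisy = simulate_acquisition(small_scene, maps, sch, 20, sigma, seed=3)
        diff = noisy.samples - clean.samples
        assert diff.size >= 1e5
        assert np.mean(np.abs(diff) ** 2) == pytest.approx(sigma**2, rel=0.05)


class TestTimeAveragedRecon:
    def test_static_phantom_recovery(self, small_phantom_spec):
        from dataclasses import replace

        spec = replace(small_phantom_spec, contraction_amplitude=0.0)
        scene = make_phantom(spec)
        grid = tuple(spec.grid_shape)
        # denser leaflets: a 16x16 phase-encode plane needs 40 samples per
        # leaflet for the union of rings to cover nearly all cells
        sch = build_schedule(8000, grid, 2.4, 40, 1.0)
        maps = synthetic_coilmaps(grid, 4, seed=1)
        acq = simulate_acquisition(scene, maps, sch, 20, 0.0, seed=0)
        rec = time_averaged_recon(acq, maps)
        ref = scene.reference_volume
        err = np.linalg.norm(rec.data - ref) / np.linalg.norm(ref)
        assert err < 0.05

    def test_zero_samples_zero_image(self, small_acquisition):
        acq, maps = small_acquisition
        silent = AcquisitionSet(
            samples=np.zeros_like(acq.samples), schedule=acq.schedule,
            binning=acq.binning,
        )
        rec = time_averaged_recon(silent, maps)
        assert np.all(rec.data == 0)


class TestCoilMaps:
    def test_synthetic_maps_unit_rss(self):
        maps = synthetic_coilmaps((12, 12, 12), 6, seed=4)
        rss = np.sqrt((np.abs(maps.maps) ** 2).sum(axis=0))
        assert np.abs(rss - 1.0).max() < 1e-12

    def test_single_constant_coil_estimate(self):
        img = np.ones(SHAPE, complex)
        k = fft3c(img)[None]
        maps = estimate_coilmaps(k, calib_radius=6)
        support = np.abs(maps.maps[0]) > 0
        assert support.any()
        assert np.allclose(np.abs(maps.maps[0][support]), 1.0, atol=1e-9)

    def test_norm_bound_everywhere(self, small_acquisition):
        acq, _ = small_acquisition
        est = estimate_coilmaps(gridded_time_average(acq), calib_radius=5)
        norms = np.sqrt((np.abs(est.maps) ** 2).sum(axis=0))
        assert norms.max() <= 1.0 + 1e-6

    def test_recovers_smooth_ground_truth_maps(self, small_scene):
        grid = tuple(small_scene.spec.grid_shape)
        gt_maps = synthetic_coilmaps(grid, 4, seed=7)
        sch = build_schedule(6000, grid, 2.4, 20, 2.0)
        acq = simulate_acquisition(small_scene, gt_maps, sch, 20, 0.0, seed=0)
        est = estimate_coilmaps(gridded_time_average(acq), calib_radius=5)
        body = np.abs(small_scene.reference_volume) > 0.2
        support = (np.sqrt((np.abs(est.maps) ** 2).sum(axis=0)) > 0.5) & body
        # compare magnitudes (phase is only defined up to a per-voxel global)
        err = np.abs(np.abs(est.maps[:, support]) - np.abs(gt_maps.maps[:, support]))
        assert np.median(err) < 0.05

    def test_empty_calibration_rejected(self, small_acquisition):
        acq, _ = small_acquisition
        with pytest.raises(ValueError):
            estimate_coilmaps(gridded_time_average(acq), calib_radius=0)
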