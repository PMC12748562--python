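"""Unit tests for reconstruction, detection, calibration and metrics."""

import numpy as np
import pytest

from holoscat.evaluate import (calibrate_coordinates, ground_truth_image,
                               image_metrics, resample_to_object_frame)
from holoscat.medium import VirtualMedium
from holoscat.reconstruct import (ReconstructionStack, detect_sources,
                                  fwhm_measure, max_intensity_projection,
                                  reconstruct_volume)
from holoscat.retrieval import RetrievedFieldSet
from holoscat.simulate import PointSourceSet

from conftest import haar_unitary

AIRY_FWHM_UM = 1.0290 / 2.0 * 0.55 / 0.35  # analytic spot width at NA 0.35


@pytest.fixture(scope="module")
def oracle_setup(small_scene):
    """Truth fields at the layer plus the exact virtual layer for the
    reference source (the oracle every reconstruction test builds on)."""
    truth = small_scene["truth"]
    grid = small_scene["grid"]
    fields = RetrievedFieldSet(values=truth.fields_camera, grid=grid,
                               plane_z=0.0).propagate_to(30.0)
    ref = 0
    medium = VirtualMedium(phase=np.angle(truth.fields_layer[ref]),
                           grid=grid, plane_z=30.0, reference_index=ref)
    return {"fields": fields, "medium": medium, "grid": grid,
            "sources": small_scene["sources"], "ref": ref}


@pytest.fixture(scope="module")
def oracle_stack(oracle_setup):
    return reconstruct_volume(oracle_setup["fields"],
                              oracle_setup["medium"],
                              np.arange(-3.0, 3.01, 0.2))


class TestReconstructVolume:
    def test_nonnegative_and_energy_constant(self, oracle_stack):
        assert np.all(oracle_stack.values >= 0)
        energies = oracle_stack.values.sum(axis=(1, 2))
        assert np.ptp(energies) < 1e-8 * energies.mean()

    def test_empty_z_rejected(self, oracle_setup):
        with pytest.raises(ValueError, match="z_samples"):
            reconstruct_volume(oracle_setup["fields"],
                               oracle_setup["medium"], [])

    def test_oracle_medium_focuses_all_sources(self, oracle_setup,
                                               oracle_stack):
        det = detect_sources(oracle_stack, rel_threshold=0.1,
                             merge_radius=0.8)
        assert det is not None and len(det) == 3

    def test_invariant_under_unitary_mixture(self, oracle_setup):
        z = np.array([-1.0, 0.0, 1.0])
        base = reconstruct_volume(oracle_setup["fields"],
                                  oracle_setup["medium"], z)
        mixed_fields = oracle_setup["fields"].mixed_by(haar_unitary(3, 0))
        mixed = reconstruct_volume(mixed_fields, oracle_setup["medium"], z)
        assert np.allclose(mixed.values, base.values, rtol=1e-9, atol=1e-12)

    def test_invariant_under_global_phases_and_permutation(self,
                                                           oracle_setup):
        z = np.array([0.0])
        base = reconstruct_volume(oracle_setup["fields"],
                                  oracle_setup["medium"], z)
        vals = oracle_setup["fields"].values
        rotated = (vals * np.exp(1j * np.array([0.7, -2.1, 1.3]))[:, None,
                                                                  None])
        permuted = RetrievedFieldSet(values=rotated[[2, 0, 1]],
                                     grid=oracle_setup["grid"],
                                     plane_z=30.0)
        out = reconstruct_volume(permuted, oracle_setup["medium"], z)
        assert np.allclose(out.values, base.values, rtol=1e-9, atol=1e-12)

    def test_scrambled_medium_destroys_focus(self, oracle_setup,
                                             oracle_stack):
        """Permuting the virtual layer's phase removes the compensation:
        focal contrast collapses by well over 5x."""
        rng = np.random.default_rng(1)
        scrambled_phase = oracle_setup["medium"].phase.ravel().copy()
        rng.shuffle(scrambled_phase)
        scrambled = VirtualMedium(
            phase=scrambled_phase.reshape(oracle_setup["medium"].phase.shape),
            grid=oracle_setup["grid"], plane_z=30.0, reference_index=0)
        ctrl = reconstruct_volume(oracle_setup["fields"], scrambled,
                                  oracle_stack.z_values)
        contrast = oracle_stack.peak / oracle_stack.values.mean()
        ctrl_contrast = ctrl.peak / ctrl.values.mean()
        assert contrast / ctrl_contrast >= 5.0

    def test_oracle_spot_is_diffraction_limited(self, oracle_setup,
                                                oracle_stack):
        det = detect_sources(oracle_stack, rel_threshold=0.1,
                             merge_radius=0.8)
        cal = calibrate_coordinates(det, oracle_setup["sources"])
        i = int(np.argmax(det.intensity))
        w = fwhm_measure(oracle_stack, (det.x[i], det.y[i], det.z[i]),
                         axis="x", lateral_scale=abs(cal.magnification))
        assert 0.8 * AIRY_FWHM_UM <= w <= 1.25 * AIRY_FWHM_UM


class TestDetectSources:
    def test_threshold_one_gives_single_detection(self, oracle_stack):
        det = detect_sources(oracle_stack, rel_threshold=1.0)
        assert det is not None and len(det) == 1

    def test_empty_stack_gives_none(self, grid64):
        stack = ReconstructionStack(values=np.zeros((3,) + grid64.shape),
                                    z_values=np.array([-1.0, 0.0, 1.0]),
                                    grid=grid64)
        assert detect_sources(stack) is None

    def test_reference_source_lands_at_origin(self, oracle_setup,
                                              oracle_stack):
        """The reference field's own source refocuses at the centre of the
        reconstruction frame (its phase is fully cancelled)."""
        det = detect_sources(oracle_stack, rel_threshold=0.1,
                             merge_radius=0.8)
        d = np.hypot(det.x, det.y)
        assert d.min() < 0.5 * oracle_stack.grid.pitch

    def test_pairwise_distances_after_calibration(self, oracle_setup,
                                                  oracle_stack):
        det = detect_sources(oracle_stack, rel_threshold=0.1,
                             merge_radius=0.8)
        cal = calibrate_coordinates(det, oracle_setup["sources"])
        xo, yo = cal.to_object(det.x, det.y)
        src = oracle_setup["sources"]

        def _pairs(xs, ys):
            return sorted(np.hypot(xs[i] - xs[j], ys[i] - ys[j])
                          for i in range(len(xs))
                          for j in range(i + 1, len(xs)))

        got = _pairs(xo, yo)
        want = _pairs(src.x, src.y)
        assert np.allclose(got, want, atol=0.5)


class TestCalibration:
    def test_identity_calibration(self):
        pts = PointSourceSet(x=[0.0, 5.0, -3.0, 2.0],
                             y=[1.0, -2.0, 4.0, -4.0],
                             z=[10.0, 12.0, 14.0, 16.0],
                             intensity=[1.0] * 4)
        cal = calibrate_coordinates(pts, pts)
        assert cal.magnification == pytest.approx(1.0, abs=1e-9)
        assert cal.residual_rms < 1e-9
        assert cal.z_scale == pytest.approx(1.0, abs=1e-9)
        assert cal.parity == 1

    def test_doubled_z_recovers_half_scale(self):
        truth = PointSourceSet(x=[0.0, 5.0, -3.0], y=[1.0, -2.0, 4.0],
                               z=[10.0, 20.0, 30.0], intensity=[1.0] * 3)
        det = PointSourceSet(x=truth.x, y=truth.y, z=2.0 * truth.z,
                             intensity=truth.intensity)
        cal = calibrate_coordinates(det, truth)
        assert cal.z_scale == pytest.approx(0.5, abs=1e-6)

    def test_mirror_and_scale_recovered(self):
        truth = PointSourceSet(x=[0.0, 5.0, -3.0, 2.0],
                               y=[1.0, -2.0, 4.0, -4.0],
                               z=[10.0] * 4, intensity=[1.0] * 4)
        det = PointSourceSet(x=-0.4 * np.asarray(truth.x),
                             y=0.4 * np.asarray(truth.y),
                             z=truth.z, intensity=truth.intensity)
        cal = calibrate_coordinates(det, truth)
        assert cal.parity == -1
        assert abs(cal.magnification) == pytest.approx(0.4, rel=1e-6)
        xo, yo = cal.to_object(det.x, det.y)
        assert np.allclose(xo, truth.x, atol=1e-6)
        assert np.allclose(yo, truth.y, atol=1e-6)

    def test_too_few_pairs_rejected(self):
        pts = PointSourceSet(x=[0.0, 1.0], y=[0.0, 1.0], z=[1.0, 2.0],
                             intensity=[1.0, 1.0])
        with pytest.raises(ValueError, match="3"):
            calibrate_coordinates(pts, pts)


class TestImageMetrics:
    def test_identical_images(self, grid64):
        rng = np.random.default_rng(2)
        img = rng.uniform(0.0, 1.0, grid64.shape)
        psnr, ssim = image_metrics(img, img)
        assert psnr == 100.0
        assert ssim == pytest.approx(1.0, abs=1e-12)

    def test_known_noise_gives_predicted_psnr(self):
        """Uniform noise of known variance on a unit-peak image with a true
        zero background floor: PSNR = -10 log10(MSE)."""
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(3)
        # smooth reference: registration then sits at zero shift and the
        # added noise is the only difference between the images
        ref = gaussian_filter(rng.uniform(0, 1, (64, 64)), 2.0, mode="wrap")
        ref = 0.3 + 0.6 * (ref - ref.min()) / np.ptp(ref)
        ref[rng.random((64, 64)) < 0.02] = 0.0  # anchors the 1st percentile
        ref[32, 32] = 1.0  # anchors the peak
        noisy = ref.copy()
        body = (ref >= 0.3) & (ref < 1.0)
        a = 0.01
        noisy[body] += rng.uniform(-a, a, int(body.sum()))
        expected_mse = np.mean(body) * a ** 2 / 3.0
        psnr, _ = image_metrics(noisy, ref)
        assert psnr == pytest.approx(-10.0 * np.log10(expected_mse), abs=0.5)

    def test_metrics_symmetric(self, grid64):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.0, 1.0, grid64.shape)
        b = np.clip(a + rng.normal(0, 0.05, grid64.shape), 0.0, None)
        pab, sab = image_metrics(a, b)
        pba, sba = image_metrics(b, a)
        assert pab == pytest.approx(pba, abs=1e-12)
        assert sab == pytest.approx(sba, abs=1e-12)

    def test_registration_removes_translation(self, grid64):
        rng = np.random.default_rng(5)
        from scipy.ndimage import gaussian_filter

        ref = gaussian_filter(rng.uniform(0, 1, grid64.shape), 2.0)
        shifted = np.roll(ref, (3, -2), axis=(0, 1))
        psnr, ssim = image_metrics(shifted, ref)
        assert psnr > 40.0
        assert ssim > 0.99

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="size"):
            image_metrics(np.zeros((8, 8)), np.zeros((9, 9)))


class TestMIPAndFWHM:
    def test_mip_of_impulse(self, grid64):
        vol = np.zeros((5,) + grid64.shape)
        vol[2, 10, 20] = 7.0
        stack = ReconstructionStack(values=vol,
                                    z_values=np.arange(5, dtype=float),
                                    grid=grid64)
        mip = max_intensity_projection(stack, "z")
        assert mip[10, 20] == 7.0
        assert mip.sum() == 7.0

    def test_mip_max_equals_stack_max(self, oracle_stack):
        for axis in ("x", "y", "z"):
            assert max_intensity_projection(
                oracle_stack, axis).max() == oracle_stack.peak

    def test_zmip_consistent_with_3d_detections(self, oracle_stack):
        det = detect_sources(oracle_stack, rel_threshold=0.1,
                             merge_radius=0.8)
        mip = max_intensity_projection(oracle_stack, "z")
        grid = oracle_stack.grid
        for n in range(len(det)):
            ix = int(round(det.x[n] / grid.pitch + grid.n_x // 2))
            iy = int(round(det.y[n] / grid.pitch + grid.n_y // 2))
            patch = mip[max(iy - 1, 0): iy + 2, max(ix - 1, 0): ix + 2]
            assert patch.max() >= 0.1 * mip.max()

    def test_gaussian_fwhm_closed_form(self, grid64):
        sigma = 1.0  # um
        img = np.exp(-(grid64.xx ** 2 + grid64.yy ** 2) / (2 * sigma ** 2))
        stack = ReconstructionStack(values=img[None],
                                    z_values=np.array([0.0]), grid=grid64)
        w = fwhm_measure(stack, (0.0, 0.0, 0.0), axis="x")
        assert w == pytest.approx(2.3548 * sigma, rel=0.02)

    def test_fwhm_invariant_under_rescaling(self, grid64):
        img = np.exp(-(grid64.xx ** 2 + grid64.yy ** 2) / 2.0)
        a = ReconstructionStack(values=img[None], z_values=np.array([0.0]),
                                grid=grid64)
        b = ReconstructionStack(values=37.5 * img[None],
                                z_values=np.array([0.0]), grid=grid64)
        wa = fwhm_measure(a, (0.0, 0.0, 0.0), axis="y")
        wb = fwhm_measure(b, (0.0, 0.0, 0.0), axis="y")
        assert wa == pytest.approx(wb, rel=1e-9)

    def test_flat_profile_flagged(self, grid64):
        img = np.ones(grid64.shape)
        stack = ReconstructionStack(values=img[None],
                                    z_values=np.array([0.0]), grid=grid64)
        with pytest.warns(UserWarning, match="half maximum"):
            w = fwhm_measure(stack, (0.0, 0.0, 0.0), axis="x")
        assert np.isnan(w)


class TestObjectFrameResampling:
    def test_ground_truth_roundtrip(self, grid64):
        """A synthetic stack slice painted at known reconstruction
        positions maps back onto the object-frame truth image."""
        src = PointSourceSet(x=[-4.0, 3.0, 0.0], y=[2.0, -3.0, 5.0],
                             z=[30.0] * 3, intensity=[1.0] * 3)
        # magnified reconstruction: the painted spots (NA 0.35 / mag) stay
        # well sampled on the grid
        mag = 2.0
        rec = np.zeros(grid64.shape)
        from holoscat.propagation import point_source_field

        for n in range(3):
            f = point_source_field(grid64, mag * src.x[n], mag * src.y[n],
                                   na=0.35 / mag)
            rec += np.abs(f.values) ** 2
        det = PointSourceSet(x=mag * np.asarray(src.x),
                             y=mag * np.asarray(src.y),
                             z=np.zeros(3), intensity=[1.0] * 3)
        cal = calibrate_coordinates(det, src)
        obj_img = resample_to_object_frame(rec, grid64, cal)
        gt = ground_truth_image(src, grid64, 30.0, na=0.35)
        psnr, ssim = image_metrics(obj_img, gt)
        assert ssim > 0.95
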