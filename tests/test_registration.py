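"""LNCC similarity, FFD regularization, hybrid cost, affine init, warping."""

import numpy as np
import pytest

from fetatlas.config import RegWeights
from fetatlas.core import BrainMask, GestationalAge, ImageVolume, Sample, SubjectMeta
from fetatlas.phantom import PhantomSpec, make_phantom, perturb_phantom
from fetatlas.registration import (
    FFDTransform,
    apply_transform,
    fit_affine_init,
    lncc_similarity,
    register_ffd,
    registration_cost,
    regularization_energy,
)


@pytest.fixture(scope="module")
def phantom32():
    spec = PhantomSpec(
        ga=GestationalAge.from_weeks_days(26), noise_sd=8.0, seed=2,
        grid_shape=(32, 32, 32), spacing=1.4,
    )
    return make_phantom(spec)


class TestLNCC:
    def test_identity_near_one(self, phantom32):
        s = lncc_similarity(phantom32.image, phantom32.image, phantom32.mask)
        assert s >= 0.99

    def test_affine_intensity_invariance(self, phantom32):
        rescaled = ImageVolume(3.2 * phantom32.image.data + 150.0, phantom32.image.affine)
        a = lncc_similarity(phantom32.image, phantom32.image, phantom32.mask)
        b = lncc_similarity(phantom32.image, rescaled, phantom32.mask)
        assert b == pytest.approx(a, abs=1e-6)

    def test_independent_noise_near_zero(self, small_phantom):
        rng = np.random.default_rng(11)
        noise = ImageVolume(
            rng.normal(size=small_phantom.image.shape), small_phantom.image.affine
        )
        s = lncc_similarity(small_phantom.image, noise, small_phantom.mask)
        assert s < 0.2

    def test_empty_mask_rejected(self, phantom32):
        empty = BrainMask(np.zeros(phantom32.image.shape, bool), phantom32.image.affine)
        with pytest.raises(ValueError):
            lncc_similarity(phantom32.image, phantom32.image, empty)


class TestRegularization:
    def _transform(self, phantom):
        return FFDTransform.identity_like(phantom.image, ctrl_spacing_mm=6.0)

    def test_identity_is_zero(self, phantom32):
        assert regularization_energy(self._transform(phantom32)) == (0.0, 0.0)

    def test_uniform_translation_is_zero(self, phantom32):
        t = self._transform(phantom32)
        t.coeffs[..., 1] = 4.2
        be, le = regularization_energy(t)
        assert be == pytest.approx(0.0, abs=1e-12)
        assert le == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp(self, phantom32):
        t = self._transform(phantom32)
        xs = t.origin[0] + np.arange(t.lattice_shape[0]) * t.ctrl_spacing[0]
        t.coeffs[..., 0] = 0.1 * xs[:, None, None]
        be, le = regularization_energy(t)
        assert be == pytest.approx(0.0, abs=1e-10)
        # J = diag(0.1, 0, 0): mean squared symmetric Jacobian norm = 0.01
        assert le == pytest.approx(0.01, rel=1e-6)

    def test_rigid_infinitesimal_rotation_has_zero_linear_energy(self, phantom32):
        t = self._transform(phantom32)
        xs = t.origin[0] + np.arange(t.lattice_shape[0]) * t.ctrl_spacing[0]
        ys = t.origin[1] + np.arange(t.lattice_shape[1]) * t.ctrl_spacing[1]
        # u = omega x r (skew-symmetric Jacobian)
        t.coeffs[..., 0] = -0.05 * ys[None, :, None]
        t.coeffs[..., 1] = 0.05 * xs[:, None, None]
        be, le = regularization_energy(t)
        assert be == pytest.approx(0.0, abs=1e-10)
        assert le == pytest.approx(0.0, abs=1e-10)


class TestRegistrationCost:
    def test_components_at_identity_on_self(self, phantom32):
        w = RegWeights()
        t = FFDTransform.identity_like(phantom32.image, w.grid_spacing_mm)
        cost, comp = registration_cost(phantom32, phantom32, t, w, use_landmarks=True)
        assert comp["alpha_lncc"] == pytest.approx(0.5994)
        assert comp["lncc"] >= 0.99
        assert comp["landmark"] == pytest.approx(0.0, abs=1e-12)
        assert comp["bending"] == 0.0 and comp["linear"] == 0.0
        assert cost == pytest.approx(-w.alpha_lncc * comp["lncc"])

    def test_landmark_term_off(self, phantom32):
        w = RegWeights()
        t = FFDTransform.identity_like(phantom32.image, w.grid_spacing_mm)
        t.coeffs[..., 0] += 1.0  # uniform shift: landmark pairs now offset
        _, with_lm = registration_cost(phantom32, phantom32, t, w, use_landmarks=True)
        _, without = registration_cost(phantom32, phantom32, t, w, use_landmarks=False)
        assert with_lm["landmark"] > 0
        assert without["landmark"] == 0.0


class TestAffineInit:
    def test_translation_recovered(self, phantom32):
        moved, _ = perturb_phantom(phantom32, translation=(3.0, -2.0, 1.0))
        A = fit_affine_init(moved, phantom32, use_landmarks=True)
        # maps subject (moved) -> atlas (original): inverse translation
        np.testing.assert_allclose(np.diag(A)[:3], 1.0, atol=1e-6)
        np.testing.assert_allclose(A[:3, 3], [-3.0, 2.0, -1.0], atol=0.1)

    def test_identity_for_identical_inputs(self, phantom32):
        A = fit_affine_init(phantom32, phantom32, use_landmarks=True)
        np.testing.assert_allclose(A, np.eye(4), atol=1e-9)

    def test_mask_moment_mode_recovers_scale(self, phantom32):
        scaled, _ = perturb_phantom(phantom32, scale=(1.15, 1.1, 1.2))
        A = fit_affine_init(scaled, phantom32, use_landmarks=False)
        np.testing.assert_allclose(
            np.diag(A)[:3], [1 / 1.15, 1 / 1.1, 1 / 1.2], rtol=0.05
        )

    def test_no_landmarks_no_masks_rejected(self, phantom32):
        from fetatlas.core import LandmarkSet

        empty_mask = BrainMask(np.zeros(phantom32.image.shape, bool), phantom32.image.affine)
        bare = Sample(phantom32.meta, phantom32.image, empty_mask, LandmarkSet())
        with pytest.raises(ValueError):
            fit_affine_init(bare, bare, use_landmarks=True)


class TestApplyTransform:
    def test_identity_is_bitexact_on_labels(self, phantom32):
        t = FFDTransform.identity_like(phantom32.image, 6.0)
        labels = ImageVolume(
            phantom32.probmaps.data.argmax(0).astype(np.int16), phantom32.image.affine
        )
        warped = apply_transform(t, labels, "nearest")
        np.testing.assert_array_equal(warped.data, labels.data)

    def test_label_set_never_grows(self, phantom32):
        t = FFDTransform.identity_like(phantom32.image, 6.0)
        rng = np.random.default_rng(3)
        t.coeffs += rng.normal(0, 1.0, t.coeffs.shape)
        labels = ImageVolume(
            phantom32.probmaps.data.argmax(0).astype(np.int16), phantom32.image.affine
        )
        warped = apply_transform(t, labels, "nearest")
        assert set(np.unique(warped.data)) <= set(np.unique(labels.data))

    def test_pure_translation_ffd_moves_points_exactly(self, phantom32):
        t = FFDTransform.identity_like(phantom32.image, 6.0)
        t.coeffs[..., 0] = 2.5  # B-spline partition of unity
        pts = np.array([[0.0, 0.0, 0.0], [3.0, -2.0, 5.0]])
        out = apply_transform(t, pts, "forward-points")
        np.testing.assert_allclose(out, pts + np.array([2.5, 0.0, 0.0]), atol=1e-9)

    def test_probmaps_stay_normalized(self, phantom32):
        t = FFDTransform.identity_like(phantom32.image, 6.0)
        t.coeffs[..., 1] = 1.0
        warped = apply_transform(t, phantom32.probmaps, "linear")
        np.testing.assert_allclose(warped.data.sum(axis=0), 1.0, atol=1e-9)

    def test_unknown_mode_rejected(self, phantom32):
        t = FFDTransform.identity_like(phantom32.image, 6.0)
        with pytest.raises(ValueError):
            apply_transform(t, phantom32.image, "cubic")


class TestRegisterFFD:
    def test_self_registration_near_identity(self, phantom32):
        t = register_ffd(phantom32, phantom32, use_landmarks=True)
        pts = np.array([phantom32.landmarks[k] for k in phantom32.landmarks.present_ids])
        disp = np.linalg.norm(t.apply_points(pts) - pts, axis=1)
        assert disp.mean() < 0.2 * phantom32.image.spacing[0]

    def test_translation_recovery(self, phantom32):
        moved, _ = perturb_phantom(phantom32, translation=(2.8, 0.0, -1.4))
        t = register_ffd(moved, phantom32, use_landmarks=True)
        ids = moved.landmarks.present_ids
        xs = np.array([moved.landmarks[k] for k in ids])
        xa = np.array([phantom32.landmarks[k] for k in ids])
        err = np.linalg.norm(t.apply_points(xs) - xa, axis=1).mean()
        assert err < phantom32.image.spacing[0]  # < 1 voxel

    def test_cost_decreases_from_affine_init(self, phantom32):
        moved, _ = perturb_phantom(
            phantom32, scale=(1.05, 0.95, 1.0), smooth_warp_amplitude=1.5, seed=4
        )
        w = RegWeights()
        t = register_ffd(moved, phantom32, weights=w, use_landmarks=True)
        t0 = FFDTransform.identity_like(moved.image, w.grid_spacing_mm, t.affine_init)
        c_init, _ = registration_cost(moved, phantom32, t0, w, use_landmarks=True)
        c_final, _ = registration_cost(moved, phantom32, t, w, use_landmarks=True)
        assert c_final <= c_init

    def test_deterministic(self, phantom32):
        moved, _ = perturb_phantom(phantom32, translation=(1.5, 1.0, 0.0))
        t1 = register_ffd(moved, phantom32, use_landmarks=True, seed=0)
        t2 = register_ffd(moved, phantom32, use_landmarks=True, seed=0)
        np.testing.assert_array_equal(t1.coeffs, t2.coeffs)
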