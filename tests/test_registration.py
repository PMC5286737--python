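"""Optical flow, warping and the PCA motion basis."""

import numpy as np
import pytest

import cardiotherm as ct
from cardiotherm.registration import (
    MotionField,
    build_motion_basis,
    estimate_flow,
    project_motion,
    reconstruct_motion,
    warp,
    warp_phase,
)


def smooth_image(n=64, seed=None):
    """Deterministic smooth test image with gradients everywhere."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    return (
        1.0
        + 0.3 * np.sin(2 * np.pi * xx / n * 2.1) * np.cos(2 * np.pi * yy / n * 1.7)
        + 0.2 * np.sin(2 * np.pi * (xx + 2 * yy) / n * 3.0)
    )


class TestEstimateFlow:
    def test_identity_pair_gives_zero_field(self):
        img = smooth_image()
        f = estimate_flow(img, img)
        assert np.abs(f.dy).max() < 0.05
        assert np.abs(f.dx).max() < 0.05

    def test_recovers_integer_shift(self):
        img = smooth_image()
        moving = np.roll(img, 3, axis=0)  # periodic padding, shift (3, 0)
        f = estimate_flow(moving, img)
        inner = slice(10, -10)
        assert f.dy[inner, inner].mean() == pytest.approx(3.0, abs=0.5)
        assert abs(f.dx[inner, inner].mean()) < 0.5

    def test_registration_reduces_phantom_mismatch(self):
        """Warping back the respiratory shift must cut the MSE by >= 50%."""
        reductions = []
        for seed in range(10):
            cfg = ct.PhantomConfig(
                grid_size=(48, 48), n_frames=4, heat_peak_degc=0.0,
                heat_onset_frame=0, heat_duration_frames=0,
                drift_rate_rad_s=0.0, resp_amplitude_mm=5.0, snr=150.0, seed=seed,
            )
            series, _ = ct.generate_series(cfg)
            ref, mov = series.magnitude[0], series.magnitude[1]
            f = estimate_flow(mov, ref)
            mse_before = np.mean((mov - ref) ** 2)
            mse_after = np.mean((warp(mov, f) - ref) ** 2)
            reductions.append(1 - mse_after / mse_before)
        assert np.mean(reductions) >= 0.5

    def test_shift_equivariance(self):
        img = smooth_image()
        f1 = estimate_flow(np.roll(img, 2, axis=1), img)
        f2 = estimate_flow(np.roll(img, 4, axis=1), img)
        inner = slice(12, -12)
        assert f2.dx[inner, inner].mean() == pytest.approx(
            2 * f1.dx[inner, inner].mean(), abs=0.6
        )

    def test_all_zero_image_flagged(self):
        with pytest.warns(RuntimeWarning):
            f = estimate_flow(np.zeros((16, 16)), np.zeros((16, 16)))
        assert np.all(f.dy == 0) and np.all(f.dx == 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            estimate_flow(np.ones((8, 8)), np.ones((9, 9)))


class TestWarp:
    def test_zero_field_is_identity(self):
        img = smooth_image(32)
        z = MotionField(np.zeros((32, 32)), np.zeros((32, 32)))
        np.testing.assert_array_equal(warp(img, z), img)

    def test_inverse_roundtrip(self):
        img = smooth_image(64)
        d = (1.3, -2.2)
        field = MotionField(np.full((64, 64), d[0]), np.full((64, 64), d[1]))
        inv = MotionField(-field.dy, -field.dx)
        back = warp(warp(img, field), inv)
        inner = slice(8, -8)
        rmse = np.sqrt(np.mean((back[inner, inner] - img[inner, inner]) ** 2))
        assert rmse / np.sqrt(np.mean(img[inner, inner] ** 2)) < 0.02

    def test_constant_phase_invariant(self):
        rng = np.random.default_rng(0)
        field = MotionField(rng.normal(scale=2, size=(16, 16)),
                            rng.normal(scale=2, size=(16, 16)))
        phase = np.full((16, 16), 2.9)  # near the wrap
        np.testing.assert_allclose(warp_phase(phase, field), 2.9, atol=1e-9)

    def test_validity_mask_marks_out_of_bounds(self):
        img = smooth_image(16)
        field = MotionField(np.full((16, 16), 5.0), np.zeros((16, 16)))
        _, valid = warp(img, field, return_valid=True)
        assert not valid[-1, :].any() and valid[0, :].all()

    def test_non_finite_field_rejected(self):
        img = smooth_image(8)
        field = MotionField(np.full((8, 8), np.nan), np.zeros((8, 8)))
        with pytest.raises(ValueError):
            warp(img, field)

    def test_intensity_conserved_away_from_edges(self):
        img = smooth_image(64)
        field = MotionField(np.full((64, 64), 0.6), np.full((64, 64), -0.4))
        out = warp(np.roll(np.roll(img, 1, 0), 0, 1), field)
        inner = slice(8, -8)
        assert out[inner, inner].sum() == pytest.approx(
            img[inner, inner].sum(), rel=0.02
        )


class TestMotionBasis:
    def _fields(self, coeffs, mode):
        return [MotionField(c * mode[0], c * mode[1], i)
                for i, c in enumerate(coeffs)]

    def test_identical_fields(self):
        f = MotionField(np.ones((8, 8)), np.zeros((8, 8)))
        basis = build_motion_basis([f] * 5, n_components=2)
        np.testing.assert_allclose(basis.explained_variance, 0.0)
        np.testing.assert_allclose(basis.mean_field.dy, 1.0)

    def test_rank_one_construction(self):
        mode = (smooth_image(12) - 1, 0.5 * (smooth_image(12) - 1))
        fields = self._fields([0.5, -1.0, 2.0, 0.1, -0.7], mode)
        basis = build_motion_basis(fields, n_components=2)
        assert basis.explained_variance[0] == pytest.approx(1.0, abs=1e-10)
        # component proportional to the mode
        comp = basis.components[0]
        vec = MotionField(*mode).as_vector()
        cos = abs(comp @ vec) / np.linalg.norm(vec)
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(5)
        fields = [MotionField(rng.normal(size=(10, 10)), rng.normal(size=(10, 10)))
                  for _ in range(8)]
        basis = build_motion_basis(fields, n_components=3)
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-10)

    def test_phantom_sinusoidal_motion_is_rank_one(self):
        """The respiratory motion manifold is 1D: one dominant component."""
        for seed in range(5):
            cfg = ct.PhantomConfig(
                grid_size=(48, 48), n_frames=12, heat_peak_degc=0.0,
                heat_onset_frame=0, heat_duration_frames=0,
                drift_rate_rad_s=0.0, snr=150.0, seed=seed,
            )
            series, _ = ct.generate_series(cfg)
            flows = [estimate_flow(series.magnitude[i], series.magnitude[0])
                     for i in range(12)]
            basis = build_motion_basis(flows, n_components=2)
            assert basis.explained_variance[0] >= 0.95

    def test_too_few_fields(self):
        f = MotionField(np.ones((4, 4)), np.ones((4, 4)))
        with pytest.raises(ValueError):
            build_motion_basis([f, f], n_components=2)


class TestProjectMotion:
    @pytest.fixture()
    def basis(self):
        rng = np.random.default_rng(7)
        fields = [MotionField(rng.normal(size=(8, 8)), rng.normal(size=(8, 8)))
                  for _ in range(10)]
        return build_motion_basis(fields, n_components=2)

    def test_mean_field_projects_to_zero(self, basis):
        np.testing.assert_allclose(
            project_motion(basis.mean_field, basis), 0.0, atol=1e-10
        )

    def test_component_coefficients(self, basis):
        vec = basis.mean_vector + 2.0 * basis.components[0]
        f = MotionField.from_vector(vec, basis.shape)
        np.testing.assert_allclose(project_motion(f, basis), [2.0, 0.0], atol=1e-10)

    def test_roundtrip_matches_linear_algebra(self, basis):
        rng = np.random.default_rng(11)
        f = MotionField(rng.normal(size=(8, 8)), rng.normal(size=(8, 8)))
        coeffs = project_motion(f, basis)
        recon = reconstruct_motion(coeffs, basis)
        # direct rank-limited projection
        centered = f.as_vector() - basis.mean_vector
        expected = basis.mean_vector + basis.components.T @ (basis.components @ centered)
        np.testing.assert_allclose(recon.as_vector(), expected, atol=1e-10)
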