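"""Gradient fields, the trilinear orientation histogram and patch scaling."""

import numpy as np
import pytest

from oracles import brute_force_descriptor
from p300hist import (Descriptor, GradientField, Keypoint, RunConfig,
                      StandardizedSignal, default_keypoint, gradient_field,
                      hist_descriptor, normalize_descriptor,
                      patch_amplitude_coverage, patch_scale,
                      patch_time_coverage, render_plot, resolve_scale)
from p300hist.errors import EmptyPatchError


def random_field(rng, shape=(36, 36)):
    mag = rng.uniform(0.0, 10.0, size=shape)
    ang = rng.uniform(0.0, 360.0, size=shape)
    return GradientField(mag, ang)


class TestPatchScale:
    def test_horizontal_scale_from_span(self):
        s_x, _ = patch_scale(gamma=4, lambda_s=0.56, fs=16.0, delta_uV=9.0)
        assert s_x == pytest.approx(2.9867, abs=1e-3)

    def test_vertical_scale_from_amplitude(self):
        _, s_y = patch_scale(gamma=4, lambda_s=0.56, fs=16.0, delta_uV=9.0)
        assert s_y == 3.0

    def test_common_integer_scale(self):
        assert resolve_scale(*patch_scale(4, 0.56, 16.0, 9.0)) == 3

    def test_unit_case(self):
        s_x, _ = patch_scale(gamma=12, lambda_s=1.0, fs=1.0, delta_uV=1.0)
        assert s_x == 1.0

    def test_mismatched_directions_rejected(self):
        with pytest.raises(ValueError):
            resolve_scale(2.0, 3.0)

    def test_coverage_inversions(self):
        assert patch_amplitude_coverage(3, 4) == 9.0
        assert patch_time_coverage(3, 4, 16.0) == pytest.approx(0.5625)


class TestDefaultKeypoint:
    def _image(self):
        values = np.array([-2, 0, 3, 1, -1], dtype=np.int64)
        return render_plot(StandardizedSignal(values, 0.0, 1.0, 4))

    def test_printed_coordinate(self):
        kp = default_keypoint(self._image(), RunConfig())
        assert kp.x == 35  # floor(0.55 * 16 * 4)
        assert kp.s == 3

    def test_gamma_one(self):
        kp = default_keypoint(self._image(), RunConfig(gamma=1))
        assert kp.x == 8

    def test_y_is_zero_row(self):
        img = self._image()
        assert default_keypoint(img, RunConfig()).y == img.zero_row == 3


class TestGradientField:
    def test_constant_image_has_zero_magnitude(self):
        field = gradient_field(np.zeros((5, 5)))
        assert np.all(field.magnitude == 0.0)

    def test_single_white_pixel_neighbors(self):
        img = np.zeros((5, 5))
        img[2, 2] = 255.0
        field = gradient_field(img)
        # central differences: 4-neighbors see half the step
        for (r, c), angle in {(2, 1): 0.0, (1, 2): 90.0,
                              (2, 3): 180.0, (3, 2): 270.0}.items():
            assert field.magnitude[r, c] == pytest.approx(127.5)
            assert field.angle[r, c] == pytest.approx(angle)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, size=(9, 9))
        f = gradient_field(img)
        fr = gradient_field(np.rot90(img))
        H, W = img.shape
        for i in range(1, W - 1):
            for j in range(1, H - 1):
                # rot90: R[i, j] = I[j, W-1-i]; gradient rotates with it
                expect = (f.angle[j, W - 1 - i] - 90.0) % 360.0
                if fr.magnitude[i, j] > 1e-9:
                    assert fr.angle[i, j] == pytest.approx(expect, abs=1e-9)


class TestHistDescriptor:
    def test_zero_field_gives_zero_descriptor(self):
        field = GradientField(np.zeros((36, 36)), np.zeros((36, 36)))
        d = hist_descriptor(field, Keypoint(18, 18, 3))
        assert np.all(d.h == 0.0)

    def test_mass_collapses_at_block_and_bin_centers(self):
        """A gradient sitting exactly on a block centre with an angle at a
        bin centre lands entirely in that single histogram cell, scaled by
        the leading 3s factor."""
        mag = np.zeros((40, 40))
        ang = np.zeros((40, 40))
        mag[23, 23] = 2.0   # offset (3,3) from keypoint -> v = (0.5, 0.5)
        ang[23, 23] = 90.0
        d = hist_descriptor(GradientField(mag, ang), Keypoint(20, 20, 2))
        grid = d.as_grid()
        assert grid[2, 2, 2] == pytest.approx(3 * 2 * 2.0)
        assert np.count_nonzero(grid) == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            field = random_field(rng)
            d = hist_descriptor(field, Keypoint(18, 18, 3))
            want = brute_force_descriptor(field.magnitude, field.angle,
                                          18, 18, 3)
            assert np.allclose(d.h, want, rtol=1e-9, atol=1e-12)

    def test_partition_of_unity(self):
        """Weights sum to 1 for pixels with normalized offset inside
        [-3/2, 3/2]^2, so sum(h) = 3s * sum of interior magnitudes."""
        rng = np.random.default_rng(1)
        s = 2
        mag = np.zeros((40, 40))
        ang = rng.uniform(0, 360, size=(40, 40))
        interior = slice(20 - 9, 20 + 9 + 1)  # |offset| <= 4.5 s
        mag[interior, interior] = rng.uniform(0, 5, size=(19, 19))
        d = hist_descriptor(GradientField(mag, ang), Keypoint(20, 20, s))
        assert d.h.sum() == pytest.approx(3 * s * mag.sum(), rel=1e-12)

    def test_translation_covariance(self):
        rng = np.random.default_rng(2)
        field = random_field(rng, shape=(50, 50))
        field.magnitude[:, :5] = 0  # keep content clear of the borders
        field.magnitude[:, -15:] = 0
        field.magnitude[:5, :] = 0
        field.magnitude[-15:, :] = 0
        d0 = hist_descriptor(field, Keypoint(20, 20, 2))
        shifted = GradientField(np.roll(field.magnitude, (7, 9), axis=(0, 1)),
                                np.roll(field.angle, (7, 9), axis=(0, 1)))
        d1 = hist_descriptor(shifted, Keypoint(29, 27, 2))
        assert np.allclose(d0.h, d1.h, atol=1e-10)

    def test_horizontal_mirror_permutes_blocks_and_angles(self):
        """Mirroring the image maps cell (i, j, b) to (i, 3-j, (4-b) mod 8)."""
        rng = np.random.default_rng(3)
        img = (rng.uniform(0, 1, size=(31, 31)) < 0.3) * 255.0
        x = y = 15  # odd width: the centre column maps to itself
        d = hist_descriptor(gradient_field(img), Keypoint(x, y, 2)).as_grid()
        dm = hist_descriptor(gradient_field(np.fliplr(img)),
                             Keypoint(x, y, 2)).as_grid()
        mapped = d[:, ::-1, :][:, :, [(4 - b) % 8 for b in range(8)]]
        assert np.allclose(dm, mapped, atol=1e-9)

    def test_keypoint_outside_image_rejected(self):
        field = random_field(np.random.default_rng(0))
        with pytest.raises(EmptyPatchError):
            hist_descriptor(field, Keypoint(200, 18, 3))


class TestNormalize:
    def test_zero_maps_to_zero(self):
        d = normalize_descriptor(Descriptor(np.zeros(128)))
        assert np.all(d.h == 0.0)
        assert d.normalized

    def test_max_entry_becomes_one(self):
        d = normalize_descriptor(Descriptor(np.linspace(0, 7, 128)))
        assert d.h.max() == 1.0
        assert d.h.min() >= 0.0

    def test_idempotent_in_value(self):
        raw = np.abs(np.random.default_rng(0).normal(size=128))
        once = normalize_descriptor(Descriptor(raw))
        twice = normalize_descriptor(Descriptor(once.h.copy()))
        assert np.allclose(once.h, twice.h)

    def test_double_normalization_flagged(self):
        d = normalize_descriptor(Descriptor(np.ones(128)))
        with pytest.raises(ValueError):
            normalize_descriptor(d)

    def test_l2_mode(self):
        d = normalize_descriptor(Descriptor(np.ones(128)), mode="l2")
        assert np.linalg.norm(d.h) == pytest.approx(1.0)
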