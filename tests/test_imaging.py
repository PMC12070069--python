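"""Projection, line sampling and normalization against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hcrprof as hp
from hcrprof.imaging import DegenerateProfileError


def make_stack(pixels, labels=None):
    pixels = np.asarray(pixels, dtype=float)
    labels = labels or tuple(f"ch{i}" for i in range(pixels.shape[0]))
    return hp.ImageStack(pixels=pixels, channel_labels=labels)


class TestMaxProject:
    def test_takes_per_pixel_maximum_over_z(self):
        pixels = np.zeros((1, 2, 4, 4))
        pixels[0, 0, 1, 2] = 3.0
        pixels[0, 1, 1, 2] = 7.0
        proj = hp.max_project(make_stack(pixels))
        assert proj.pixels[0, 1, 2] == 7.0

    def test_single_slice_is_identity(self):
        rng = np.random.default_rng(0)
        pixels = rng.random((2, 1, 8, 9))
        proj = hp.max_project(make_stack(pixels))
        np.testing.assert_array_equal(proj.pixels, pixels[:, 0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.integers(1, 3), st.integers(1, 5), st.integers(2, 12), st.integers(2, 12),
        st.integers(0, 2**31 - 1),
    )
    def test_equals_brute_force_loop(self, n_c, n_z, h, w, seed):
        pixels = np.random.default_rng(seed).random((n_c, n_z, h, w))
        proj = hp.max_project(make_stack(pixels))
        for ci in range(n_c):
            for r in range(h):
                for c in range(w):
                    assert proj.pixels[ci, r, c] == max(
                        pixels[ci, z, r, c] for z in range(n_z)
                    )


def dense_bilinear(img, r, c):
    """Independent bilinear interpolation oracle (clamped borders)."""
    r = min(max(r, 0.0), img.shape[0] - 1.0)
    c = min(max(c, 0.0), img.shape[1] - 1.0)
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = min(r0 + 1, img.shape[0] - 1), min(c0 + 1, img.shape[1] - 1)
    fr, fc = r - r0, c - c0
    return (
        img[r0, c0] * (1 - fr) * (1 - fc)
        + img[r1, c0] * fr * (1 - fc)
        + img[r0, c1] * (1 - fr) * fc
        + img[r1, c1] * fr * fc
    )


class TestExtractProfile:
    def test_constant_field(self):
        proj = hp.Projection(np.full((1, 20, 30), 42.0), ("g",))
        prof = hp.extract_profile(proj, hp.LineSpec(start=(10, 2), end=(10, 25)))
        np.testing.assert_array_equal(prof.values[0], 42.0)
        np.testing.assert_array_equal(prof.positions, np.arange(24))

    def test_linear_ramp_sampled_exactly(self):
        img = np.tile(np.arange(30.0), (20, 1))[None]
        proj = hp.Projection(img, ("g",))
        prof = hp.extract_profile(proj, hp.LineSpec(start=(5, 3), end=(5, 27)))
        np.testing.assert_allclose(prof.values[0], np.arange(3.0, 28.0), atol=1e-12)

    def test_diagonal_line_matches_dense_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.random((40, 60))
        proj = hp.Projection(img[None], ("g",))
        line = hp.LineSpec(start=(3.0, 5.0), end=(35.0, 52.0))
        prof = hp.extract_profile(proj, line)
        length = np.hypot(32.0, 47.0)
        ur, uc = 32.0 / length, 47.0 / length
        expected = [
            dense_bilinear(img, 3.0 + k * ur, 5.0 + k * uc) for k in prof.positions
        ]
        np.testing.assert_allclose(prof.values[0], expected, atol=1e-6)

    def test_angled_scene_matches_analytic_mixture(self):
        cfg = hp.SceneConfig(
            image_height=128, image_width=128, n_z=1,
            channels=[hp.StripeSpec(channel_label="g", band_centers=[80.0],
                                    band_widths=[9.0], amplitudes=[3.0],
                                    background=0.5)],
            stripe_axis_angle=25.0, n_replicates=1, seed=0,
        )
        stacks, truth = hp.generate_scene(cfg)
        prof = hp.extract_profile(hp.max_project(stacks[0]), truth.lines[0])
        center = truth.for_replicate(0, "g").profile_centers[0]
        d = prof.positions.astype(float)
        expected = 0.5 + 3.0 * np.exp(-((d - center) ** 2) / (2 * 9.0**2))
        # bilinear sampling of the rendered pixel grid limits agreement with
        # the continuous curve to O(h^2 * curvature)
        np.testing.assert_allclose(prof.values[0], expected, atol=0.01)

    def test_channels_sampled_identically(self):
        rng = np.random.default_rng(2)
        img = rng.random((2, 30, 30))
        line = hp.LineSpec(start=(2.0, 3.0), end=(27.0, 25.0), linewidth=3)
        a = hp.extract_profile(hp.Projection(img, ("x", "y")), line)
        b = hp.extract_profile(hp.Projection(img[::-1], ("y", "x")), line)
        np.testing.assert_array_equal(a.values[0], b.values[1])
        np.testing.assert_array_equal(a.values[1], b.values[0])

    def test_medial_end_controls_orientation(self):
        img = np.tile(np.arange(30.0), (20, 1))[None]
        proj = hp.Projection(img, ("g",))
        fwd = hp.extract_profile(proj, hp.LineSpec(start=(5, 3), end=(5, 27)))
        rev = hp.extract_profile(
            proj, hp.LineSpec(start=(5, 3), end=(5, 27), medial_end="end")
        )
        np.testing.assert_allclose(rev.values[0], fwd.values[0][::-1])

    def test_endpoint_outside_image_errors(self):
        proj = hp.Projection(np.zeros((1, 10, 10)), ("g",))
        with pytest.raises(ValueError, match="outside"):
            hp.extract_profile(proj, hp.LineSpec(start=(0, 0), end=(5, 12)))


class TestNormalizeProfile:
    def make_profile(self, values):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return hp.LineProfile(
            positions=np.arange(values.shape[1]),
            values=values,
            channel_labels=tuple(f"ch{i}" for i in range(values.shape[0])),
        )

    def test_direct_formula(self):
        norm = hp.normalize_profile(self.make_profile([10.0, 30.0, 50.0]))
        np.testing.assert_allclose(norm.values[0], [0.0, 0.5, 1.0])
        assert norm.norm_params == ((10.0, 50.0),)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_range_contract_and_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        raw = rng.random((2, 12)) * 100
        norm = hp.normalize_profile(self.make_profile(raw))
        for ch in norm.values:
            assert ch.min() == 0.0 and ch.max() == 1.0
        rescaled = hp.normalize_profile(self.make_profile(scale * raw + shift))
        np.testing.assert_allclose(rescaled.values, norm.values, atol=1e-9)

    def test_idempotent_on_normalized_values(self):
        norm = hp.normalize_profile(self.make_profile([3.0, 7.0, 5.0, 11.0]))
        again = hp.normalize_profile(
            self.make_profile(norm.values[0])
        )
        np.testing.assert_allclose(again.values, norm.values, atol=1e-12)

    def test_constant_channel_raises_and_names_channel(self):
        prof = self.make_profile(np.vstack([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]))
        with pytest.raises(DegenerateProfileError, match="ch1"):
            hp.normalize_profile(prof)
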