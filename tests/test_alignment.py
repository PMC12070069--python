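"""Peak fitting, peak-centred registration and replicate averaging."""

import numpy as np
import pytest

import hcrprof as hp
from conftest import profiles_from_scene


def gaussian(x, baseline, amplitude, center, width):
    return baseline + amplitude * np.exp(-((x - center) ** 2) / (2 * width**2))


def analytic_profile(center, width=6.0, amplitude=0.8, baseline=0.1, n=100,
                     source=("img", "line"), label="ref"):
    x = np.arange(n)
    return hp.NormalizedProfile(
        positions=x,
        values=gaussian(x.astype(float), baseline, amplitude, center, width)[None],
        channel_labels=(label,),
        source=source,
    )


class TestFitPeak:
    def test_noiseless_parameters_recovered_exactly(self):
        x = np.arange(100)
        v = gaussian(x.astype(float), 0.1, 0.8, 37.0, 6.0)
        fit = hp.fit_peak(x, v)
        assert fit.converged
        assert fit.baseline == pytest.approx(0.1, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.8, abs=1e-6)
        assert fit.center == pytest.approx(37.0, abs=1e-6)
        assert fit.width == pytest.approx(6.0, abs=1e-6)

    def test_bimodal_input_keeps_center_in_sampled_range(self):
        x = np.arange(100).astype(float)
        v = gaussian(x, 0.0, 0.8, 25.0, 5.0) + gaussian(x, 0.0, 0.7, 75.0, 5.0)
        fit = hp.fit_peak(x, v)
        assert x.min() <= fit.center <= x.max()

    def test_mean_center_recovery_under_noise(self):
        rng = np.random.default_rng(42)
        x = np.arange(100).astype(float)
        truth = gaussian(x, 0.1, 0.8, 37.0, 6.0)
        centers = [
            hp.fit_peak(x, truth + rng.normal(0.0, 0.05, x.size)).center
            for _ in range(200)
        ]
        assert abs(np.mean(centers) - 37.0) < 0.5

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="5 samples"):
            hp.fit_peak(np.arange(4), np.ones(4))

    def test_lorentzian_model_recovers_its_own_curve(self):
        x = np.arange(80).astype(float)
        v = 0.05 + 0.9 / (1.0 + ((x - 33.0) / 5.0) ** 2)
        fit = hp.fit_peak(x, v, model="lorentzian")
        assert fit.converged and fit.center == pytest.approx(33.0, abs=1e-6)


class TestAlignProfiles:
    def test_single_profile_centered_on_its_peak(self):
        aligned = hp.align_profiles([analytic_profile(40.0)], "ref")
        prof = aligned.profiles[0]
        assert prof.positions[0] == -40
        assert prof.positions[np.argmax(prof.values[0])] == 0

    def test_two_images_intersection_grid(self):
        profs = [
            analytic_profile(30.0, source=("img1", "l")),
            analytic_profile(50.0, source=("img2", "l")),
        ]
        aligned = hp.align_profiles(profs, "ref")
        assert aligned.profiles[0].positions[0] == -30
        assert aligned.profiles[0].positions[-1] == 69
        assert aligned.profiles[1].positions[0] == -50
        assert aligned.profiles[1].positions[-1] == 49
        np.testing.assert_array_equal(aligned.common_grid, np.arange(-30, 50))

    def test_shift_bookkeeping_restores_original_positions(self):
        profs, _ = profiles_from_scene(hp.stage13_scene(seed=2))
        aligned = hp.align_profiles(profs, "pax3")
        for orig, shifted, shift in zip(profs, aligned.profiles, aligned.shifts):
            np.testing.assert_array_equal(shifted.positions + shift, orig.positions)

    def test_integer_grid_stays_integer(self):
        profs, _ = profiles_from_scene(hp.stage13_scene(seed=2))
        aligned = hp.align_profiles(profs, "pax3")
        for p in aligned.profiles:
            assert np.issubdtype(np.asarray(p.positions).dtype, np.integer)

    def test_synthetic_reference_peaks_land_near_zero(self):
        profs, _ = profiles_from_scene(hp.stage13_scene(seed=7))
        aligned = hp.align_profiles(profs, "pax3")
        grid = aligned.common_grid
        for p in aligned.profiles:
            sel = np.searchsorted(p.positions, grid)
            ref = p.values[p.channel_labels.index("pax3")][sel]
            # the fitted (not raw-argmax) peak is what centering controls
            assert abs(hp.fit_peak(grid, ref).center) <= 1.0

    def test_common_grid_is_brute_force_intersection(self):
        profs, _ = profiles_from_scene(hp.stage13_scene(seed=9))
        aligned = hp.align_profiles(profs, "pax3")
        expected = set(aligned.profiles[0].positions.tolist())
        for p in aligned.profiles[1:]:
            expected &= set(p.positions.tolist())
        assert sorted(expected) == aligned.common_grid.tolist()

    def test_missing_reference_channel_errors(self):
        with pytest.raises(ValueError, match="reference channel"):
            hp.align_profiles([analytic_profile(40.0)], "snai2")
        with pytest.raises(ValueError, match="no profiles"):
            hp.align_profiles([], "ref")

    def test_subpixel_mode_produces_integer_resampled_grid(self):
        profs, _ = profiles_from_scene(hp.stage13_scene(seed=3))
        aligned = hp.align_profiles(profs, "pax3", subpixel=True)
        avg = hp.average_profiles(aligned)
        assert abs(avg.grid[np.argmax(avg.channel_mean("pax3"))]) <= 1


class TestAverageProfiles:
    def build_aligned(self, value_sets):
        profs = [
            hp.NormalizedProfile(
                positions=np.arange(len(v)),
                values=np.asarray(v, dtype=float)[None],
                channel_labels=("ref",),
                source=(f"img{i}", "l"),
            )
            for i, v in enumerate(value_sets)
        ]
        grid = profs[0].positions
        return hp.AlignedProfileSet(
            reference_channel="ref",
            profiles=tuple(profs),
            shifts=tuple(0.0 for _ in profs),
            common_grid=grid,
            fits={},
        )

    def test_identical_profiles_have_zero_sem(self):
        avg = hp.average_profiles(self.build_aligned([[0.1, 0.5, 1.0]] * 3))
        np.testing.assert_allclose(avg.means[0], [0.1, 0.5, 1.0])
        np.testing.assert_allclose(avg.sems[0], 0.0, atol=1e-15)

    def test_two_point_sem_closed_form(self):
        avg = hp.average_profiles(self.build_aligned([[0.2], [0.6]]))
        assert avg.means[0][0] == pytest.approx(0.4)
        assert avg.sems[0][0] == pytest.approx(0.2)  # sd(0.2, 0.6)/sqrt(2)

    def test_matches_two_pass_loop_oracle(self):
        rng = np.random.default_rng(5)
        sets = rng.random((6, 11))
        avg = hp.average_profiles(self.build_aligned(sets))
        for gi in range(11):
            vals = [sets[pi][gi] for pi in range(6)]
            mean = sum(vals) / 6
            var = sum((v - mean) ** 2 for v in vals) / 5
            assert avg.means[0][gi] == pytest.approx(mean, abs=1e-12)
            assert avg.sems[0][gi] == pytest.approx((var**0.5) / 6**0.5, abs=1e-12)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            hp.average_profiles(self.build_aligned([[0.1, 0.2]]))
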