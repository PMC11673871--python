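import numpy as np
import pytest

import oxyflow as ox
from oxyflow.mbll import HemodynamicMaps
from oxyflow.profiles import (
    ConcentrationProfile,
    grand_average,
    normalize_at_onset,
    roi_profile,
    smooth_pixelwise,
)


def _maps_from_series(series_per_pixel: np.ndarray) -> HemodynamicMaps:
    """Build maps whose hbo carries the given (T, H, W) series; hbr constant."""
    hbo = np.asarray(series_per_pixel, dtype=float)
    hbr = np.ones_like(hbo)
    hbt = hbo + hbr
    valid = np.ones(hbo.shape, dtype=bool)
    return HemodynamicMaps(
        hbo=hbo, hbr=hbr, hbt=hbt, sto2=hbo / hbt, valid=valid,
        sto2_valid=valid, timestamps_s=np.arange(float(hbo.shape[0])),
    )


class TestSavitzkyGolay:
    def test_constant_series_unchanged(self):
        maps = _maps_from_series(np.full((30, 2, 2), 5.0))
        out = smooth_pixelwise(maps, window=11, polyorder=3)
        np.testing.assert_allclose(out.hbo, 5.0)

    def test_quadratic_reproduced_exactly(self):
        t = np.arange(40.0)
        series = (t**2)[:, None, None] * np.ones((1, 2, 2))
        out = smooth_pixelwise(_maps_from_series(series), window=11, polyorder=3)
        interior = slice(5, -5)
        np.testing.assert_allclose(out.hbo[interior], series[interior], rtol=1e-10)

    def test_noise_variance_strictly_reduced_on_ramp(self):
        rng = np.random.default_rng(7)
        t = np.arange(60.0)
        ramp = t[:, None, None] * np.ones((1, 3, 3))
        noisy = ramp + rng.normal(0, 0.5, size=ramp.shape)
        out = smooth_pixelwise(_maps_from_series(noisy), window=11, polyorder=3)
        before = np.var(noisy - ramp)
        after = np.var(out.hbo - ramp)
        assert after < before

    def test_hbt_identity_preserved_after_filtering(self, control_maps):
        out = smooth_pixelwise(control_maps)
        np.testing.assert_array_equal(out.hbt, out.hbo + out.hbr)

    @pytest.mark.parametrize("window,polyorder", [(10, 3), (5, 5), (5, 7)])
    def test_bad_filter_config_rejected(self, window, polyorder):
        maps = _maps_from_series(np.zeros((30, 1, 1)))
        with pytest.raises(ValueError):
            smooth_pixelwise(maps, window=window, polyorder=polyorder)

    def test_window_longer_than_series_rejected(self):
        maps = _maps_from_series(np.zeros((9, 1, 1)))
        with pytest.raises(ValueError, match="length"):
            smooth_pixelwise(maps, window=11, polyorder=3)

    def test_filter_commutes_with_roi_mean(self):
        """Both the filter and the ROI mean are linear, so
        filter-then-average equals average-then-filter."""
        from scipy.signal import savgol_filter

        rng = np.random.default_rng(3)
        series = rng.normal(size=(50, 4, 4))
        maps = _maps_from_series(series)
        roi = ox.make_rect_roi((0, 0), 4, (4, 4), "all")
        a = roi_profile(smooth_pixelwise(maps, 11, 3), roi, "hbo").values
        b = savgol_filter(roi_profile(maps, roi, "hbo").values, 11, 3, mode="interp")
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestRoiProfile:
    def test_identical_pixels_give_that_series(self):
        series = np.linspace(0, 1, 20)[:, None, None] * np.ones((1, 3, 3))
        maps = _maps_from_series(series)
        roi = ox.make_rect_roi((0, 0), 3, (3, 3), "r")
        prof = roi_profile(maps, roi, "hbo")
        np.testing.assert_allclose(prof.values, series[:, 0, 0])

    def test_two_pixel_mean(self):
        series = np.zeros((5, 1, 2))
        series[:, 0, 0] = 1.0
        series[:, 0, 1] = 3.0
        maps = _maps_from_series(series)
        roi = ox.make_rect_roi((0, 0), (1, 2), (1, 2), "r")
        prof = roi_profile(maps, roi, "hbo")
        np.testing.assert_allclose(prof.values, 2.0)

    def test_invalid_pixels_excluded_from_mean(self):
        series = np.zeros((5, 1, 2))
        series[:, 0, 0] = 1.0
        series[:, 0, 1] = 99.0
        maps = _maps_from_series(series)
        maps.valid[:, 0, 1] = False
        roi = ox.make_rect_roi((0, 0), (1, 2), (1, 2), "r")
        prof = roi_profile(maps, roi, "hbo")
        np.testing.assert_allclose(prof.values, 1.0)
        np.testing.assert_array_equal(prof.n_pixels_per_frame, 1)

    def test_no_valid_pixels_rejected(self):
        maps = _maps_from_series(np.zeros((5, 2, 2)))
        maps.valid[:] = False
        roi = ox.make_rect_roi((0, 0), 2, (2, 2), "r")
        with pytest.raises(ValueError, match="valid"):
            roi_profile(maps, roi, "hbo")

    def test_roi_profile_matches_sidecar_ground_truth(self, control_maps, control_bundle):
        _, _, _, masks, truth = control_bundle
        prof = roi_profile(control_maps, masks["foot"], "hbo")
        np.testing.assert_allclose(
            prof.values, truth[truth.region == "foot"].hbo_eff.to_numpy(), atol=1e-9
        )


class TestNormalizeAtOnset:
    def _profile(self, values):
        return ConcentrationProfile(
            values=np.asarray(values, float),
            timestamps_s=np.arange(float(len(values))),
            parameter="hbo",
        )

    def test_ten_percent_rise(self):
        paradigm = ox.Paradigm(rest_s=2, hold_s=1, recovery_s=2)
        prof = self._profile([10, 10, 10, 11, 11])
        out = normalize_at_onset(prof, paradigm)
        assert out.values[0] == 0.0
        assert out.values[1] == pytest.approx(10.0)
        assert out.timestamps_s[0] == 2.0

    def test_flat_series_gives_flat_zero(self):
        paradigm = ox.Paradigm(rest_s=2, hold_s=1, recovery_s=2)
        out = normalize_at_onset(self._profile([4, 4, 4, 4, 4]), paradigm)
        np.testing.assert_allclose(out.values, 0.0)

    def test_negative_onset_keeps_sign_convention(self):
        paradigm = ox.Paradigm(rest_s=1, hold_s=1, recovery_s=1)
        out = normalize_at_onset(self._profile([-10, -10, -9]), paradigm)
        assert out.values[-1] == pytest.approx(10.0)  # rise reads as positive

    def test_zero_onset_rejected(self):
        paradigm = ox.Paradigm(rest_s=1, hold_s=1, recovery_s=1)
        with pytest.raises(ValueError, match="normalize"):
            normalize_at_onset(self._profile([1, 0, 1]), paradigm)

    def test_idempotent_at_same_onset(self):
        paradigm = ox.Paradigm(rest_s=2, hold_s=1, recovery_s=2)
        once = normalize_at_onset(self._profile([10, 10, 10, 11, 12]), paradigm)
        twice = normalize_at_onset(once, paradigm)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_control_sto2_plateaus_about_two_percent_above_onset(self, paradigm):
        """The programmed recovery lands the StO2 percent change near +2 %
        around the 100th second, recovered through the full pipeline."""
        scene = ox.control_scene(shape=(48, 48), noise_sd=0.0)
        stack, cal, masks, _ = ox.render_stack(scene, seed=2)
        sm = smooth_pixelwise(ox.compute_hemodynamics(stack, cal))
        prof = normalize_at_onset(roi_profile(sm, masks["foot"], "sto2"), paradigm)
        late = prof.values[(prof.timestamps_s >= 100)]
        assert 1.0 < late.mean() < 3.0
        # plateau: late samples vary far less than the swing
        assert np.ptp(late) < 0.2


class TestGrandAverage:
    def _profile(self, values):
        return ConcentrationProfile(
            values=np.asarray(values, float),
            timestamps_s=np.arange(float(len(values))),
            parameter="sto2",
        )

    def test_identical_profiles_mean_equals_profile_se_zero(self):
        p = self._profile([1, 2, 3])
        mean, se = grand_average([p, p, p])
        np.testing.assert_allclose(mean.values, [1, 2, 3])
        np.testing.assert_allclose(se.values, 0.0)

    def test_two_constant_profiles_hand_arithmetic(self):
        # values 0 and 2: mean 1, sample sd sqrt(2), SE = sqrt(2)/sqrt(2) = 1
        mean, se = grand_average([self._profile([0, 0]), self._profile([2, 2])])
        np.testing.assert_allclose(mean.values, 1.0)
        np.testing.assert_allclose(se.values, 1.0)

    def test_mixed_parameters_rejected(self):
        a = self._profile([1, 2])
        b = ConcentrationProfile(
            values=np.array([1.0, 2.0]), timestamps_s=np.arange(2.0), parameter="hbo"
        )
        with pytest.raises(ValueError, match="mixed"):
            grand_average([a, b])

    def test_se_band_covers_truth_in_simulation(self, paradigm):
        """Nine replicate control profiles (3 'subjects' x 3 repetitions):
        the mean +/- 2 SE band should cover the noise-free response at most
        time points."""
        truth_scene = ox.control_scene(shape=(32, 32), noise_sd=0.0)
        stack0, cal0, masks0, _ = ox.render_stack(truth_scene, seed=0)
        sm0 = smooth_pixelwise(ox.compute_hemodynamics(stack0, cal0))
        truth_prof = normalize_at_onset(roi_profile(sm0, masks0["foot"], "sto2"), paradigm)

        profs = []
        for s in range(9):
            scene = ox.control_scene(shape=(32, 32), noise_sd=0.02)
            stack, cal, masks, _ = ox.render_stack(scene, seed=100 + s)
            sm = smooth_pixelwise(ox.compute_hemodynamics(stack, cal))
            profs.append(normalize_at_onset(roi_profile(sm, masks["foot"], "sto2"), paradigm))
        mean, se = grand_average(profs)
        covered = np.abs(mean.values - truth_prof.values) <= 2 * se.values + 1e-9
        assert covered.mean() >= 0.9
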