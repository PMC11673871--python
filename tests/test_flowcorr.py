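import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oxyflow as ox
from oxyflow.flowcorr import (
    build_reference,
    correlation_map,
    default_correlation_window,
    pairwise_roi_correlations,
    pearson,
)
from oxyflow.mbll import HemodynamicMaps
from oxyflow.profiles import smooth_pixelwise


def brute_force_pcc(x, y):
    """Independent two-pass oracle: explicit means, explicit sums."""
    n = len(x)
    xbar = sum(x) / n
    ybar = sum(y) / n
    num = sum((x[i] - xbar) * (y[i] - ybar) for i in range(n))
    dx = sum((x[i] - xbar) ** 2 for i in range(n))
    dy = sum((y[i] - ybar) ** 2 for i in range(n))
    return num / (dx * dy) ** 0.5


def _sto2_maps(sto2: np.ndarray) -> HemodynamicMaps:
    hbo = sto2.copy()
    hbr = 1.0 - sto2
    valid = np.ones(sto2.shape, dtype=bool)
    return HemodynamicMaps(
        hbo=hbo, hbr=hbr, hbt=hbo + hbr, sto2=sto2, valid=valid,
        sto2_valid=valid, timestamps_s=np.arange(float(sto2.shape[0])),
    )


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert pearson(x, x) == pytest.approx(1.0)

    def test_negated_series_is_minus_one(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert pearson(x, -x + 3.0) == pytest.approx(-1.0)

    def test_hand_case(self):
        # numerator 3, denominator sqrt(2 * 14/3)
        expected = 3.0 / np.sqrt(2.0 * 14.0 / 3.0)
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(expected, abs=1e-12)
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.981980506, abs=1e-9)

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n = rng.integers(3, 60)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert abs(pearson(x, y) - brute_force_pcc(list(x), list(y))) <= 1e-12

    def test_zero_variance_returns_invalid_marker(self):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="3"):
            pearson([1.0, 2.0], [1.0, 2.0])

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-10.0, 10.0),
        seed=st.integers(0, 2**16),
    )
    def test_invariant_under_positive_affine_rescaling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r = pearson(x, y)
        assert pearson(x, a * y + b) == pytest.approx(r, abs=1e-9)
        assert pearson(x, -a * y + b) == pytest.approx(-r, abs=1e-9)


class TestWindow:
    def test_default_window_is_41_to_80_seconds(self, paradigm):
        start, end = default_correlation_window(paradigm)
        assert (start, end) == (41.0, 80.0)
        n = int(end - start) + 1
        assert n == 40

    def test_window_shifts_with_the_paradigm(self):
        p = ox.Paradigm(rest_s=30, hold_s=15, recovery_s=45, sampling_hz=1)
        assert default_correlation_window(p) == (31.0, 60.0)

    def test_window_scales_with_sampling_rate(self):
        p = ox.Paradigm(rest_s=40, hold_s=20, recovery_s=60, sampling_hz=2)
        start, end = default_correlation_window(p)
        assert start == 40.5
        assert end == 80.0


class TestReference:
    def test_single_pixel_roi_reference_equals_that_series(self, paradigm):
        rng = np.random.default_rng(0)
        sto2 = rng.uniform(0.4, 0.8, size=(120, 4, 4))
        maps = _sto2_maps(sto2)
        roi = ox.make_rect_roi((1, 2), 1, (4, 4), "bg")
        ref = build_reference(maps, "roi", roi=roi, paradigm=paradigm)
        idx = np.arange(41, 81)
        np.testing.assert_allclose(ref.values, sto2[idx, 1, 2])

    def test_global_mean_of_identical_pixels_equals_common_series(self, paradigm):
        series = np.linspace(0.4, 0.8, 120)
        sto2 = series[:, None, None] * np.ones((1, 3, 3))
        maps = _sto2_maps(sto2)
        foot = ox.make_rect_roi((0, 0), 3, (3, 3), "foot")
        ref = build_reference(maps, "global_mean", foot_mask=foot, paradigm=paradigm)
        np.testing.assert_allclose(ref.values, series[41:81])

    def test_roi_mode_requires_explicit_roi(self, paradigm):
        maps = _sto2_maps(np.random.default_rng(0).uniform(0.4, 0.8, (120, 3, 3)))
        with pytest.raises(ValueError, match="ROI"):
            build_reference(maps, "roi", paradigm=paradigm)

    def test_zero_variance_reference_rejected(self, paradigm):
        maps = _sto2_maps(np.full((120, 3, 3), 0.6))
        foot = ox.make_rect_roi((0, 0), 3, (3, 3), "foot")
        with pytest.raises(ValueError, match="variance"):
            build_reference(maps, "global_mean", foot_mask=foot, paradigm=paradigm)


class TestCorrelationMap:
    def test_pixels_equal_to_reference_map_to_one(self, paradigm):
        series = np.sin(np.linspace(0, 6, 120)) + 2
        sto2 = series[:, None, None] * np.ones((1, 4, 4))
        maps = _sto2_maps(sto2)
        foot = ox.make_rect_roi((0, 0), 4, (4, 4), "foot")
        ref = build_reference(maps, "global_mean", foot_mask=foot, paradigm=paradigm)
        cm = correlation_map(maps, ref, foot)
        np.testing.assert_allclose(cm.pcc, 1.0)

    def test_own_series_as_reference_gives_one_at_that_pixel(self, paradigm):
        rng = np.random.default_rng(5)
        maps = _sto2_maps(rng.uniform(0.3, 0.9, size=(120, 4, 4)))
        roi = ox.make_rect_roi((2, 3), 1, (4, 4), "pix")
        ref = build_reference(maps, "roi", roi=roi, paradigm=paradigm)
        foot = ox.make_rect_roi((0, 0), 4, (4, 4), "foot")
        cm = correlation_map(maps, ref, foot)
        assert cm.pcc[2, 3] == pytest.approx(1.0)

    def test_exclusions_are_invalid_and_skipped(self, paradigm):
        rng = np.random.default_rng(5)
        maps = _sto2_maps(rng.uniform(0.3, 0.9, size=(120, 4, 4)))
        foot = ox.make_rect_roi((0, 0), 4, (4, 4), "foot")
        fid = ox.make_rect_roi((0, 0), 2, (4, 4), "fiducial")
        ref = build_reference(maps, "global_mean", foot_mask=foot, paradigm=paradigm)
        cm = correlation_map(maps, ref, foot, exclusions=[fid])
        assert np.isnan(cm.pcc[:2, :2]).all()
        assert np.isfinite(cm.pcc[2:, 2:]).all()

    def test_short_window_rejected(self, paradigm):
        maps = _sto2_maps(np.random.default_rng(0).uniform(size=(120, 3, 3)))
        foot = ox.make_rect_roi((0, 0), 3, (3, 3), "foot")
        ref = build_reference(maps, "global_mean", foot_mask=foot, paradigm=paradigm)
        ref.window = (41.0, 42.0)
        ref.values = ref.values[:2]
        with pytest.raises(ValueError, match="window"):
            correlation_map(maps, ref, foot)

    def test_inverted_wound_is_negative_background_positive(self, paradigm):
        scene = ox.wound_scene(
            shape=(64, 64), noise_sd=0.01, wound_inverted=True, wound_delay_s=0.0
        )
        stack, cal, masks, _ = ox.render_stack(scene, seed=9)
        sm = smooth_pixelwise(ox.compute_hemodynamics(stack, cal))
        bg_roi = ox.make_rect_roi((40, 20), 8, (64, 64), "bgref")
        bg_roi.mask &= masks["background"].mask
        ref = build_reference(sm, "roi", roi=bg_roi, paradigm=paradigm)
        cm = correlation_map(sm, ref, masks["foot"], exclusions=[masks["fiducial"]])
        assert np.nanmean(cm.pcc[masks["wound"].mask]) < 0
        assert np.nanmean(cm.pcc[masks["background"].mask]) > 0.8


class TestPairwiseRoiCorrelations:
    def test_roi_against_itself_is_one(self, paradigm):
        rng = np.random.default_rng(1)
        maps = _sto2_maps(rng.uniform(0.3, 0.9, size=(120, 6, 6)))
        a = ox.make_rect_roi((0, 0), 3, (6, 6), "A")
        b = ox.make_rect_roi((0, 0), 3, (6, 6), "A2")  # same pixels
        table = pairwise_roi_correlations(maps, [a, b], paradigm=paradigm)
        assert table.pcc.iloc[0] == pytest.approx(1.0)

    def test_identical_and_inverted_rois(self, paradigm):
        t = np.arange(120.0)
        base = np.sin(t / 9.0)
        sto2 = np.zeros((120, 1, 3))
        sto2[:, 0, 0] = base
        sto2[:, 0, 1] = base
        sto2[:, 0, 2] = -base
        maps = _sto2_maps(sto2 + 2.0)
        rois = [ox.make_rect_roi((0, i), 1, (1, 3), lab) for i, lab in enumerate("ABC")]
        table = pairwise_roi_correlations(maps, rois, paradigm=paradigm)
        got = {(r.roi_a, r.roi_b): r.pcc for r in table.itertuples()}
        assert got[("A", "B")] == pytest.approx(1.0)
        assert got[("A", "C")] == pytest.approx(-1.0)
        assert got[("B", "C")] == pytest.approx(-1.0)

    def test_delayed_wound_correlates_less_than_backgrounds(self, paradigm):
        scene = ox.wound_scene(shape=(64, 64), noise_sd=0.01, wound_delay_s=20.0)
        stack, cal, masks, _ = ox.render_stack(scene, seed=4)
        sm = smooth_pixelwise(ox.compute_hemodynamics(stack, cal))
        b1 = ox.make_rect_roi((38, 12), 8, (64, 64), "B1")
        b1.mask &= masks["background"].mask
        b2 = ox.make_rect_roi((38, 44), 8, (64, 64), "B2")
        b2.mask &= masks["background"].mask
        w = ox.RoiMask(masks["wound"].mask, "W")
        table = pairwise_roi_correlations(sm, [b1, b2, w], paradigm=paradigm)
        got = {(r.roi_a, r.roi_b): r.pcc for r in table.itertuples()}
        assert got[("B1", "B2")] > 0.9
        assert got[("B1", "W")] < got[("B1", "B2")]
        assert got[("B2", "W")] < got[("B1", "B2")]


class TestMelaninInvariance:
    @pytest.mark.parametrize("noise_sd,min_pcc", [(0.0, 0.99), (0.02, 0.9)])
    def test_identical_responses_correlate_despite_melanin(self, noise_sd, min_pcc, paradigm):
        """A static pigmentation attenuation (melanin 1.0 vs 0.4) must not
        decorrelate the recovered StO2 responses of identical tissue."""
        scene = ox.split_scene(shape=(64, 64), noise_sd=noise_sd, melanin_factors=(1.0, 0.4))
        stack, cal, masks, _ = ox.render_stack(scene, seed=21)
        sm = smooth_pixelwise(ox.compute_hemodynamics(stack, cal))
        p1 = ox.roi_profile(sm, masks["B1"], "sto2")
        p2 = ox.roi_profile(sm, masks["B2"], "sto2")
        assert pearson(p1.values, p2.values) > min_pcc
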