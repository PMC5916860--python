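"""Segmentation, shape measurement and colour-index extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafdyn.errors import (
    AchromaticError,
    DivisionByZero,
    InvariantViolation,
    NoLeafFound,
    TipAmbiguous,
    ZeroAreaError,
)
from leafdyn.imaging import (
    LeafImage,
    LeafMask,
    color_indices,
    dgci,
    etiolation_degree,
    extract_features,
    indices_from_rgb,
    mean_rgb,
    measure_area,
    measure_perimeter,
    segment_etiolation,
    segment_leaf,
    tip_third,
)
from leafdyn.synthetic import DEFAULT_PROFILES, render_leaf_image, sample_plant_parameters

WHITE = (245, 245, 242)


def _image_with_blobs(shape, blobs, bg=WHITE):
    """Rectangular coloured blobs on a near-white background."""
    img = np.empty(shape + (3,), np.uint8)
    img[:] = bg
    for (r0, r1, c0, c1), colour in blobs:
        img[r0:r1, c0:c1] = colour
    return LeafImage(pixels=img, dpi=300.0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentLeaf:
    def test_recovers_rendered_mask(self, third_leaf):
        img, truth = third_leaf
        mask = segment_leaf(img)
        n_true = truth.leaf_mask.sum()
        assert abs(mask.n_pixels - n_true) / n_true < 0.01
        # and essentially the same pixels, not just the same count
        assert (mask.data & truth.leaf_mask).sum() / n_true > 0.99

    def test_uniform_image_has_no_leaf(self):
        img = _image_with_blobs((50, 50), [])
        with pytest.raises(NoLeafFound):
            segment_leaf(img)

    def test_largest_component_wins(self):
        img = _image_with_blobs(
            (120, 200),
            [((10, 20, 10, 20), (60, 120, 40)),          # 100 px blob
             ((40, 80, 50, 150), (60, 120, 40))],        # 4000 px blob
        )
        mask = segment_leaf(img, min_area_px=50)
        assert mask.n_pixels == 4000
        assert mask.data[50, 100] and not mask.data[15, 15]

    def test_fixed_threshold_accepted(self, third_leaf):
        img, truth = third_leaf
        mask = segment_leaf(img, threshold=80.0)
        assert abs(mask.n_pixels - truth.leaf_mask.sum()) / truth.leaf_mask.sum() < 0.02


class TestShapeMeasures:
    def test_area_calibration(self):
        mask = LeafMask(np.ones((100, 100), bool))
        assert measure_area(mask, 300.0) == pytest.approx(10000 * (2.54 / 300) ** 2)
        assert measure_area(mask, 300.0) == pytest.approx(0.71685, abs=1e-5)
        one = np.zeros((5, 5), bool)
        one[2, 2] = True
        assert measure_area(LeafMask(one), 254.0) == pytest.approx(1e-4)

    def test_empty_mask_rejected(self):
        with pytest.raises(ZeroAreaError):
            measure_area(LeafMask(np.zeros((5, 5), bool)), 300.0)
        with pytest.raises(ZeroAreaError):
            measure_perimeter(LeafMask(np.zeros((5, 5), bool)), 300.0)

    def test_perimeter_square_closed_form(self):
        mask = np.zeros((120, 120), bool)
        mask[10:110, 10:110] = True
        lp = measure_perimeter(LeafMask(mask), 300.0)
        assert lp == pytest.approx(4 * 100 * 2.54 / 300, rel=0.02)

    def test_perimeter_disk_closed_form(self):
        yy, xx = np.mgrid[0:120, 0:120]
        mask = (yy - 60) ** 2 + (xx - 60) ** 2 <= 50 ** 2
        lp_px = measure_perimeter(LeafMask(mask), 300.0) * 300 / 2.54
        assert lp_px == pytest.approx(2 * np.pi * 50, rel=0.03)

    @pytest.mark.parametrize("angle", [37.0, 90.0])
    def test_rotation_invariance_on_rerender(self, noiseless_cfg, angle):
        """LA exact and LP within 1% when the same blade is re-rendered rotated."""
        params = sample_plant_parameters(DEFAULT_PROFILES["N3"], seed=2, cv=0.0)
        img0, _ = render_leaf_image(params, 30, "3rd", noiseless_cfg, angle_deg=0.0)
        img1, _ = render_leaf_image(params, 30, "3rd", noiseless_cfg, angle_deg=angle)
        m0, m1 = segment_leaf(img0), segment_leaf(img1)
        la0 = measure_area(m0, noiseless_cfg.dpi)
        la1 = measure_area(m1, noiseless_cfg.dpi)
        assert la1 == pytest.approx(la0, rel=0.005)
        lp0 = measure_perimeter(m0, noiseless_cfg.dpi)
        lp1 = measure_perimeter(m1, noiseless_cfg.dpi)
        assert lp1 == pytest.approx(lp0, rel=0.01)


# ---------------------------------------------------------------------------
# etiolation
# ---------------------------------------------------------------------------

class TestEtiolation:
    def test_degree_formula(self):
        assert etiolation_degree(25.0, 100.0) == 0.25
        assert etiolation_degree(0.0, 3.0) == 0.0
        assert etiolation_degree(3.0, 3.0) == 1.0

    def test_degree_guards(self):
        with pytest.raises(ZeroAreaError):
            etiolation_degree(0.0, 0.0)
        with pytest.raises(InvariantViolation):
            etiolation_degree(2.0, 1.0)

    def test_segmentation_tracks_truth(self, third_leaf):
        img, truth = third_leaf
        leaf = segment_leaf(img)
        et = segment_etiolation(img, leaf)
        la, ea = leaf.n_pixels, et.n_pixels
        assert abs(ea / la - truth.ed) <= 0.03

    def test_fully_green_leaf_has_no_etiolation(self):
        img = _image_with_blobs((60, 200), [((20, 40, 20, 180), (60, 120, 40))])
        leaf = segment_leaf(img)
        assert segment_etiolation(img, leaf).n_pixels == 0

    def test_zero_hue_cut_empty(self, third_leaf):
        img, _ = third_leaf
        leaf = segment_leaf(img)
        assert segment_etiolation(img, leaf, hue_cut=0.0).n_pixels == 0

    def test_subset_of_leaf(self, third_leaf):
        img, _ = third_leaf
        leaf = segment_leaf(img)
        et = segment_etiolation(img, leaf)
        assert not (et.data & ~leaf.data).any()


# ---------------------------------------------------------------------------
# tip trisection
# ---------------------------------------------------------------------------

def _rect_with_tip():
    """Horizontal 300x30 bar with a triangular tip on the right."""
    mask = np.zeros((60, 400), bool)
    mask[15:45, 20:320] = True
    for i in range(40):                       # triangle 320..360
        half = int(15 * (1 - i / 40))
        if half > 0:
            mask[30 - half:30 + half, 320 + i] = True
    return mask


class TestTipThird:
    def test_tip_is_rightmost_third(self):
        mask = _rect_with_tip()
        tt = tip_third(LeafMask(mask))
        cols = np.argwhere(tt.data)[:, 1]
        full_cols = np.argwhere(mask)[:, 1]
        divider = full_cols.max() - (full_cols.max() - full_cols.min()) / 3
        assert cols.min() >= divider - 2
        # the centroid of the selected pixels sits on the tip side
        assert cols.mean() > np.argwhere(mask)[:, 1].mean()

    def test_square_warns_ambiguous(self):
        mask = np.zeros((50, 50), bool)
        mask[10:40, 10:40] = True
        with pytest.warns(TipAmbiguous):
            tip_third(LeafMask(mask))

    @pytest.mark.parametrize("angle", [0.0, 37.0])
    def test_equivariance_on_rerender(self, noiseless_cfg, angle):
        """The extracted tip third matches the generator's distal third at
        any orientation, and the selected fraction of the blade is stable."""
        params = sample_plant_parameters(DEFAULT_PROFILES["N3"], seed=2, cv=0.0)
        img, truth = render_leaf_image(params, 30, "3rd", noiseless_cfg,
                                       angle_deg=angle)
        tt = tip_third(segment_leaf(img))
        overlap = (tt.data & truth.tip_third_mask).sum() / max(
            tt.n_pixels, truth.tip_third_mask.sum()
        )
        assert overlap > 0.90
        frac = tt.n_pixels / truth.leaf_mask.sum()
        truth_frac = truth.tip_third_mask.sum() / truth.leaf_mask.sum()
        # divider placement is pixel-quantized; ~1% of blade area at 60 dpi
        assert frac == pytest.approx(truth_frac, abs=0.02)


# ---------------------------------------------------------------------------
# colour indices
# ---------------------------------------------------------------------------

class TestColorIndices:
    def test_mean_rgb(self):
        img = _image_with_blobs((10, 20), [((0, 10, 0, 10), (0, 0, 0)),
                                           ((0, 10, 10, 20), (200, 100, 50))])
        full = LeafMask(np.ones((10, 20), bool))
        assert mean_rgb(img, full) == pytest.approx((100, 50, 25))
        uni = _image_with_blobs((5, 5), [((0, 5, 0, 5), (100, 150, 50))])
        assert mean_rgb(uni, LeafMask(np.ones((5, 5), bool))) == (100, 150, 50)
        with pytest.raises(ZeroAreaError):
            mean_rgb(img, LeafMask(np.zeros((10, 20), bool)))

    def test_reference_triple(self):
        idx = color_indices(100, 150, 50)
        assert idx["NRI"] == pytest.approx(1 / 3, abs=1e-9)
        assert idx["NGI"] == pytest.approx(0.5, abs=1e-9)
        assert idx["NBI"] == pytest.approx(1 / 6, abs=1e-9)
        assert idx["ExG"] == pytest.approx(0.5, abs=1e-9)
        assert idx["ExR"] == pytest.approx(1.4 / 3 - 0.5, abs=1e-9)
        assert idx["G"] == 150

    def test_gray_symmetry(self):
        idx = color_indices(77, 77, 77)
        assert idx["NRI"] == idx["NGI"] == idx["NBI"] == pytest.approx(1 / 3)
        assert idx["ExG"] == pytest.approx(0.0, abs=1e-12)
        assert idx["ExR"] == pytest.approx(1.4 / 3 - 1 / 3, abs=1e-9)

    def test_black_rejected(self):
        with pytest.raises(DivisionByZero):
            color_indices(0, 0, 0)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(1, 255), st.integers(0, 255), st.integers(0, 255))
    def test_normalization_identity(self, r, g, b):
        idx = color_indices(r, g, b)
        assert idx["NRI"] + idx["NGI"] + idx["NBI"] == pytest.approx(1.0, abs=1e-9)
        # given the normalization, ExG collapses to 3*NGI - 1
        assert idx["ExG"] == pytest.approx(3 * idx["NGI"] - 1, abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(30, 255), st.integers(30, 255), st.integers(30, 255),
           st.floats(0.1, 1.0))
    def test_scale_invariance(self, r, g, b, c):
        base = color_indices(r, g, b)
        scaled = color_indices(c * r, c * g, c * b)
        for key in ("NRI", "NGI", "NBI", "ExR", "ExG"):
            assert scaled[key] == pytest.approx(base[key], abs=1e-9)


class TestDGCI:
    def test_pure_green(self):
        assert dgci(0, 255, 0) == pytest.approx(1 / 3, abs=1e-9)

    def test_hue60_zero(self):
        assert dgci(255, 255, 0) == pytest.approx(0.0, abs=1e-9)

    def test_achromatic_rejected(self):
        with pytest.raises(AchromaticError):
            dgci(128, 128, 128)

    def test_negative_below_hue60_not_clamped(self):
        assert dgci(255, 128, 0) < dgci(255, 255, 0)


# ---------------------------------------------------------------------------
# composite extraction
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def test_fil_uses_whole_leaf_no_etiolation_fields(self, render_cfg):
        params = sample_plant_parameters(DEFAULT_PROFILES["N2"], seed=4, cv=0.1)
        img, _ = render_leaf_image(params, 29, "FIL", render_cfg)
        feats = extract_features(img)
        assert feats.region_tag == "whole_leaf"
        assert feats.EA is None and feats.ED is None

    def test_third_leaf_matches_truth(self, third_leaf):
        img, truth = third_leaf
        f = extract_features(img)
        assert abs(f.LA - truth.la) / truth.la <= 0.01
        assert abs(f.LP - truth.lp) / truth.lp <= 0.03
        assert abs(f.ED - truth.ed) <= 0.03
        for got, want in zip(
            (f.G,), (truth.mean_rgb_tip[1],)
        ):
            assert abs(got - want) <= 2.0

    def test_nri_identity_holds_on_extraction(self, third_leaf):
        img, _ = third_leaf
        f = extract_features(img)
        assert f.NRI + f.NGI + f.NBI == pytest.approx(1.0, abs=1e-9)
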