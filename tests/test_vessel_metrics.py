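"""Thresholding, masking, skeletonization and the vascular metrics."""

import numpy as np
import pytest

from octaq import (
    EnFaceAngiogram,
    QuantifyConfig,
    adjusted_flow_index,
    contrast_stretch,
    faz_background_binarize,
    generate_angiogram,
    large_vessel_mask,
    make_annulus,
    microcapillary_density,
    phansalkar_binarize,
    quantify_eye,
    shanbhag_binarize,
    skeletonize,
    vessel_density,
    vessel_length_density,
)
from octaq.io_roi import AnnularROI
from octaq.vessel_metrics import BinaryVesselMap, shanbhag_threshold_bin
from octaq.synthetic_data import VesselParams, _participant_images


def _img(pixels, field=3.0, scan="macula", **kw):
    return EnFaceAngiogram(np.asarray(pixels, float), field, scan, **kw)


def _full_roi(shape):
    return AnnularROI((0, 0), 0.0, 99.0, "all", np.ones(shape, dtype=bool))


# ---------------------------------------------------------------------------
# Phansalkar
# ---------------------------------------------------------------------------


def _phansalkar_oracle(img, w=15, p=2.0, q=10.0, k=0.25, r=0.5):
    """Brute-force per-pixel double loop with mirror padding."""
    pad = w // 2
    padded = np.pad(img, pad, mode="reflect")  # scipy 'mirror' == np.pad 'reflect'
    out = np.zeros_like(img, dtype=bool)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = padded[i : i + w, j : j + w]
            m, s = win.mean(), win.std()
            t = m * (1 + p * np.exp(-q * m) + k * (s / r - 1))
            out[i, j] = img[i, j] > t
    return out


def test_phansalkar_all_zero_image_is_all_background():
    mask = phansalkar_binarize(_img(np.zeros((32, 32)))).mask
    assert not mask.any()  # t = 0 and the inequality is strict


def test_phansalkar_constant_half_image_is_all_foreground():
    # zero variance: t = 0.5 (1 + 2 e^-5 - 0.25) ~ 0.3817 < 0.5
    t = 0.5 * (1 + 2 * np.exp(-5) - 0.25)
    assert t == pytest.approx(0.3817, abs=1e-4)
    mask = phansalkar_binarize(_img(np.full((32, 32), 0.5))).mask
    assert mask.all()


@pytest.mark.parametrize("seed", range(20))
def test_phansalkar_matches_bruteforce_oracle(seed):
    img = np.random.default_rng(seed).random((32, 32))
    ours = phansalkar_binarize(img).mask
    assert np.array_equal(ours, _phansalkar_oracle(img))


def test_phansalkar_even_window_rejected():
    with pytest.raises(ValueError, match="odd"):
        phansalkar_binarize(_img(np.zeros((16, 16))), window_px=14)


# ---------------------------------------------------------------------------
# Shanbhag
# ---------------------------------------------------------------------------


def _shanbhag_oracle_scan(hist):
    """Independent exhaustive scan of all candidate bins for the fuzzy
    information criterion (naive float loops, no vectorisation)."""
    norm = hist / hist.sum()
    P1 = np.cumsum(norm)
    P2 = 1.0 - P1
    occ = np.nonzero(hist)[0]
    best, best_v = None, np.inf
    for it in range(occ[0], occ[-1]):
        term_b = 0.5 / P1[it]
        eb = -sum(
            norm[ih] * np.log(1 - term_b * P1[ih - 1])
            for ih in range(1, it + 1)
            if norm[ih] > 0
        ) * term_b
        term_o = 0.5 / P2[it]
        eo = -sum(
            norm[ih] * np.log(1 - term_o * P2[ih])
            for ih in range(it + 1, len(hist))
            if norm[ih] > 0
        ) * term_o
        v = abs(eb - eo)
        if v < best_v:
            best, best_v = it, v
    return best


def test_shanbhag_separates_two_delta_histogram():
    img = np.concatenate([np.full(512, 0.2), np.full(512, 0.8)])
    rng = np.random.default_rng(0)
    rng.shuffle(img)
    result = shanbhag_binarize(_img(img.reshape(32, 32)))
    t = result.threshold_params["threshold"]
    assert 0.2 < t < 0.8
    assert result.mask.sum() == 512  # exactly the bright population


def test_shanbhag_constant_image_falls_back_to_background():
    with pytest.warns(UserWarning, match="constant"):
        result = shanbhag_binarize(_img(np.full((16, 16), 0.4)))
    assert not result.mask.any()
    assert result.threshold_params["threshold_bin"] is None


def test_shanbhag_threshold_equals_exhaustive_scan_on_bimodal_image():
    rng = np.random.default_rng(7)
    img = np.clip(
        np.where(
            rng.random((64, 64)) < 0.4,
            rng.normal(0.7, 0.08, (64, 64)),
            rng.normal(0.2, 0.06, (64, 64)),
        ),
        0,
        1,
    )
    hist, _ = np.histogram(img, bins=256, range=(0, 1))
    assert shanbhag_threshold_bin(hist) == _shanbhag_oracle_scan(hist)


# ---------------------------------------------------------------------------
# contrast stretch
# ---------------------------------------------------------------------------


def test_contrast_stretch_expands_narrow_range():
    rng = np.random.default_rng(1)
    img = _img(rng.uniform(0.4, 0.6, (64, 64)))
    out = contrast_stretch(img)
    assert out.pixels.min() == pytest.approx(0.0, abs=0.01)
    assert out.pixels.max() == pytest.approx(1.0, abs=0.01)


def test_contrast_stretch_preserves_pixel_ordering():
    rng = np.random.default_rng(2)
    img = _img(rng.random((32, 32)))
    out = contrast_stretch(img).pixels
    flat_in, flat_out = img.pixels.ravel(), out.ravel()
    order = np.argsort(flat_in)
    assert (np.diff(flat_out[order]) >= 0).all()


def test_contrast_stretch_degenerate_image_unchanged():
    img = _img(np.full((16, 16), 0.3))
    with pytest.warns(UserWarning, match="degenerate"):
        out = contrast_stretch(img)
    assert np.array_equal(out.pixels, img.pixels)


# ---------------------------------------------------------------------------
# FAZ background thresholding
# ---------------------------------------------------------------------------


def _faz_disc_image(radius_mm=0.25, size=304, field=3.0, vessel=0.5, seed=0):
    """High-signal field with a central low-noise avascular disc."""
    rng = np.random.default_rng(seed)
    img = np.full((size, size), vessel) + rng.normal(0, 0.02, (size, size))
    c = size // 2
    rr = np.hypot(*np.meshgrid(np.arange(size) - c, np.arange(size) - c, indexing="ij"))
    disc = rr * field / size <= radius_mm
    img[disc] = np.abs(rng.normal(0.05, 0.01, disc.sum()))
    return _img(np.clip(img, 0, 1))


def test_faz_area_of_constructed_disc_matches_analytic():
    img = _faz_disc_image(radius_mm=0.25)
    _, faz = faz_background_binarize(img)
    assert faz.area_mm2 == pytest.approx(np.pi * 0.25**2, rel=0.02)


def test_faz_threshold_suppresses_background_keeps_vessels(macular_scan):
    image, truth = macular_scan
    binary, _ = faz_background_binarize(image)
    vessel_recall = binary.mask[truth.vessel_mask].mean()
    bg_suppression = 1.0 - binary.mask[~truth.vessel_mask].mean()
    assert vessel_recall >= 0.99
    assert bg_suppression >= 0.97


def test_faz_zero_background_gives_zero_threshold():
    img = _faz_disc_image()
    pixels = img.pixels.copy()
    c = img.shape[0] // 2
    rr = np.hypot(*np.meshgrid(np.arange(304) - c, np.arange(304) - c, indexing="ij"))
    pixels[rr * 3.0 / 304 <= 0.25] = 0.0
    img = _img(pixels)
    binary, faz = faz_background_binarize(img)
    assert faz.threshold == 0.0
    assert np.array_equal(binary.mask, pixels > 0)


def test_faz_seed_on_vessel_rejected_with_guidance():
    img = _faz_disc_image()
    with pytest.raises(ValueError, match="high-signal"):
        faz_background_binarize(img, faz_seed_px=(10, 10))  # on the vessel field


def test_faz_requires_macular_scan(disc_scan):
    with pytest.raises(ValueError, match="macular"):
        faz_background_binarize(disc_scan[0])


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def _binary(mask):
    return BinaryVesselMap(mask=np.asarray(mask, bool), provenance="phansalkar")


def test_vessel_density_trivial_extremes():
    roi = _full_roi((20, 20))
    assert vessel_density(_binary(np.ones((20, 20))), roi) == 100.0
    assert vessel_density(_binary(np.zeros((20, 20))), roi) == 0.0


def test_vessel_density_exact_on_constructed_coverage():
    mask = np.zeros((20, 20), bool)
    mask[:8, :] = True  # exactly 40% of the pixels
    assert vessel_density(_binary(mask), _full_roi((20, 20))) == pytest.approx(40.0)


def test_vessel_density_empty_roi_rejected():
    empty = AnnularROI((0, 0), 1.0, 1.0, "all", np.zeros((20, 20), bool))
    with pytest.raises(ValueError, match="empty ROI"):
        vessel_density(_binary(np.ones((20, 20))), empty)


def test_large_vessel_mask_removes_small_components():
    # one 2-px and one 500-px component; 25-px criterion keeps only the latter
    size = 304
    img = np.full((size, size), 0.05)
    img[10, 10:12] = 0.9  # 2 px
    img[100:120, 100:125] = 0.9  # 500 px
    image = _img(img, field=4.5, scan="disc")
    result = large_vessel_mask(image)
    assert result.mask.sum() == 500
    assert not result.mask[10, 10]


def test_large_vessel_mask_empty_image_is_empty():
    with pytest.warns(UserWarning):
        result = large_vessel_mask(_img(np.zeros((64, 64)), field=4.5, scan="disc"))
    assert not result.mask.any()


def test_large_vessel_mask_is_subset_of_shanbhag_foreground(disc_scan):
    image, _ = disc_scan
    fg = shanbhag_binarize(contrast_stretch(image)).mask
    lv = large_vessel_mask(image).mask
    assert not (lv & ~fg).any()


def test_microcapillary_density_reductions():
    roi = _full_roi((20, 20))
    fg = np.zeros((20, 20), bool)
    fg[:10] = True
    none = np.zeros((20, 20), bool)
    from octaq.vessel_metrics import LargeVesselMask

    empty_large = LargeVesselMask(none, 25, 25.0)
    assert microcapillary_density(_binary(fg), empty_large, roi) == vessel_density(
        _binary(fg), roi
    )
    same_large = LargeVesselMask(fg.copy(), 25, 25.0)
    assert microcapillary_density(_binary(fg), same_large, roi) == 0.0
    full_large = LargeVesselMask(np.ones((20, 20), bool), 25, 25.0)
    with pytest.raises(ValueError, match="large-vessel"):
        microcapillary_density(_binary(fg), full_large, roi)


def test_microcapillary_density_exact_on_constructed_mesh():
    roi = _full_roi((20, 20))
    large = np.zeros((20, 20), bool)
    large[:10] = True  # non-large region = 200 px
    fg = large.copy()
    fg[10:13, :] = True  # 60 px of capillaries = 30% of non-large
    from octaq.vessel_metrics import LargeVesselMask

    value = microcapillary_density(_binary(fg), LargeVesselMask(large, 25, 25.0), roi)
    assert value == pytest.approx(30.0)


# ---------------------------------------------------------------------------
# skeleton + VLD + AFI
# ---------------------------------------------------------------------------


def test_skeletonize_bar_collapses_to_one_pixel_line():
    mask = np.zeros((40, 120), bool)
    mask[18:23, 10:110] = True  # 5 px wide, 100 px long
    sk = skeletonize(_binary(mask)).mask
    from scipy import ndimage

    assert ndimage.label(sk, structure=np.ones((3, 3)))[1] == 1  # one line
    assert (sk.sum(axis=0) <= 1).all()  # never more than 1 px per column
    assert abs(sk.sum() - 100) <= 4  # endpoint retraction of the thinning


def test_skeletonize_single_pixel_and_idempotence(macular_scan):
    single = np.zeros((9, 9), bool)
    single[4, 4] = True
    assert np.array_equal(skeletonize(_binary(single)).mask, single)
    binary, _ = faz_background_binarize(macular_scan[0])
    once = skeletonize(binary).mask
    twice = skeletonize(once).mask
    assert np.array_equal(once, twice)


def test_skeleton_is_one_pixel_wide_subset(macular_scan):
    from scipy import ndimage

    binary, _ = faz_background_binarize(macular_scan[0])
    sk = skeletonize(binary).mask
    assert not (sk & ~binary.mask).any()
    # no skeleton pixel sits inside a fully-foreground 3x3 neighborhood
    full33 = ndimage.minimum_filter(sk.astype(np.uint8), size=3).astype(bool)
    assert not full33.any()


def test_vld_counts_and_rejects_empty_roi():
    roi = AnnularROI((0, 0), 0.0, 99.0, "all", np.zeros((100, 100), bool))
    roi.pixel_mask[:50, :] = True  # 5000 px ROI
    sk = np.zeros((100, 100), bool)
    sk[10, 20:70] = True  # 50 px line
    from octaq.vessel_metrics import SkeletonMap

    assert vessel_length_density(SkeletonMap(sk), roi) == pytest.approx(1.0)
    assert vessel_length_density(SkeletonMap(np.zeros((100, 100), bool)), roi) == 0.0
    empty = AnnularROI((0, 0), 1.0, 1.0, "all", np.zeros((100, 100), bool))
    with pytest.raises(ValueError, match="empty ROI"):
        vessel_length_density(SkeletonMap(sk), empty)


@pytest.mark.parametrize("seed", range(20))
def test_vld_never_exceeds_vd_for_same_binarization(seed):
    img = np.random.default_rng(seed).random((64, 64))
    binary = phansalkar_binarize(img)
    roi = _full_roi((64, 64))
    vd = vessel_density(binary, roi)
    vld = vessel_length_density(skeletonize(binary), roi)
    assert 0.0 <= vld <= vd <= 100.0


def test_afi_constant_vessels_and_masking_property():
    img = np.full((50, 50), 0.1)
    fg = np.zeros((50, 50), bool)
    fg[10:20, 10:40] = True
    img[fg] = 0.42
    image = _img(img)
    roi = _full_roi((50, 50))
    assert adjusted_flow_index(image, _binary(fg), roi) == pytest.approx(0.42)
    # invariant to background pixels below threshold
    img2 = img.copy()
    img2[~fg] = 0.02
    assert adjusted_flow_index(_img(img2), _binary(fg), roi) == pytest.approx(0.42)


def test_afi_monte_carlo_mean_recovery():
    rng = np.random.default_rng(5)
    fg = np.zeros((150, 150), bool)
    fg[10:140, 10:90] = True  # > 10^4 vessel px
    img = np.full((150, 150), 0.05)
    img[fg] = np.clip(rng.normal(0.40, 0.05, fg.sum()), 0, 1)
    value = adjusted_flow_index(_img(img), _binary(fg), _full_roi((150, 150)))
    assert value == pytest.approx(0.40, abs=0.002)


def test_afi_empty_selection_returns_nan_with_warning():
    image = _img(np.zeros((20, 20)))
    with pytest.warns(UserWarning, match="no vessel"):
        value = adjusted_flow_index(image, _binary(np.zeros((20, 20), bool)), _full_roi((20, 20)))
    assert np.isnan(value)


# ---------------------------------------------------------------------------
# rotation invariance of the metrics
# ---------------------------------------------------------------------------


def test_metrics_invariant_under_90_degree_rotation():
    image, _ = generate_angiogram(size_px=153, layer="SCP", seed=11)
    rot = EnFaceAngiogram(np.rot90(image.pixels).copy(), 3.0, "macula", layer="SCP")
    for img in (image, rot):
        assert img.center_px == (76, 76)
    roi = make_annulus(image, 1.0, 3.0)
    roi_rot = make_annulus(rot, 1.0, 3.0)
    b = phansalkar_binarize(image)
    b_rot = phansalkar_binarize(rot)
    assert vessel_density(b, roi) == pytest.approx(vessel_density(b_rot, roi_rot))
    assert adjusted_flow_index(image, b, roi) == pytest.approx(
        adjusted_flow_index(rot, b_rot, roi_rot)
    )
    vld = vessel_length_density(skeletonize(b), roi)
    vld_rot = vessel_length_density(skeletonize(b_rot), roi_rot)
    assert vld == pytest.approx(vld_rot, abs=0.1)  # thinning is not exactly isotropic


# ---------------------------------------------------------------------------
# quantify_eye
# ---------------------------------------------------------------------------


def test_quantify_eye_populates_all_rows_and_is_deterministic():
    imgs = _participant_images(42, 152, 1.0)  # SCP macula + RPC disc
    res1 = quantify_eye(imgs)
    res2 = quantify_eye(imgs)
    assert [(r.layer, r.roi, r.metric) for r in res1] == [
        ("SCP", "parafovea", "vd"),
        ("SCP", "parafovea", "vld"),
        ("SCP", "parafovea", "afi"),
        ("SCP", "fovea", "faz_area_mm2"),
        ("RPC", "peripapillary", "vd"),
        ("RPC", "peripapillary_superior", "vd"),
        ("RPC", "peripapillary", "vld"),
        ("RPC", "peripapillary", "microcap_vd"),
    ]
    assert all(np.isfinite(r.value) for r in res1)
    assert [r.value for r in res1] == [r.value for r in res2]  # bit-identical


def test_quantify_eye_skips_quality_failing_scan():
    imgs = _participant_images(42, 152, 1.0)
    bad_scp = imgs[0].replace(quality=(5, 60))  # SQ below the >=6 gate
    res = quantify_eye([bad_scp, imgs[1]])
    assert all(r.layer != "SCP" for r in res)
    assert any(r.layer == "RPC" for r in res)
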