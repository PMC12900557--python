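"""Preprocessing and two-scale z-line segmentation."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from sarcomech.io import ChannelImage
from sarcomech.quant import find_sarcomeres, preprocess, segment_zlines


def test_constant_raster_degenerates_to_zeros():
    img = ChannelImage(np.full((64, 64), 7.0), 0.1, "structural")
    with pytest.warns(UserWarning):
        out = preprocess(img)
    assert np.all(out.data == 0.0)


def test_tophat_removes_smooth_ramp():
    x = np.arange(600) * 0.1
    X, _ = np.meshgrid(x, np.arange(280) * 0.1)
    comb = 0.5 + 0.5 * np.cos(2 * np.pi * X / 1.8)
    ramp = 5.0 * X / X.max()
    with_ramp = preprocess(ChannelImage(comb + ramp, 0.1, "structural"))
    without = preprocess(ChannelImage(comb, 0.1, "structural"))
    rms = np.sqrt(np.mean((with_ramp.data - without.data) ** 2))
    assert rms < 0.05


def test_percentile_saturation_pins_tails(clean_parts):
    *_, image = clean_parts
    out = preprocess(image)
    assert (out.data == 0.0).mean() >= 0.01
    assert (out.data == 1.0).mean() >= 0.01
    assert out.data.min() == 0.0 and out.data.max() == 1.0


def test_segmentation_recall_precision_on_noiseless_comb(clean_parts):
    _, _, template, image = clean_parts
    pre = preprocess(image)
    seg = segment_zlines(pre)
    truth = template.comb >= 0.5          # ridge half-maximum support
    dilated = ndi.binary_dilation(truth, iterations=1)
    recall = (seg & truth).sum() / truth.sum()
    precision = (seg & dilated).sum() / seg.sum()
    assert recall >= 0.9
    assert precision >= 0.9


def test_pure_noise_yields_almost_no_foreground(rng):
    img = ChannelImage(100 + 10 * rng.normal(size=(280, 600)), 0.1, "structural")
    seg = segment_zlines(preprocess(img))
    assert seg.mean() < 0.02


def test_inverted_contrast_gives_near_empty_mask(clean_parts):
    """The operator detects bright thin structures only."""
    *_, image = clean_parts
    upright = segment_zlines(preprocess(image))
    inverted = segment_zlines(
        ChannelImage(image.data.max() - image.data, 0.1, "structural"))
    assert inverted.mean() < 0.05
    assert inverted.mean() < 0.5 * upright.mean()


def test_scale_guards():
    img = ChannelImage(np.random.default_rng(0).random((64, 64)), 1.0, "structural")
    with pytest.raises(ValueError):
        segment_zlines(img, scale_small_um=0.5, scale_large_um=10.0)
    with pytest.raises(ValueError):
        segment_zlines(img, scale_small_um=10.0, scale_large_um=2.0)
    with pytest.raises(ValueError):
        preprocess(img, tophat_radius_um=0.0)


def test_find_sarcomeres_hand_checkable():
    mask = np.zeros((20, 20), dtype=bool)
    mask[5, 2:7] = True       # 5x1 bar centred at col 4
    mask[12, 10:15] = True    # 5x1 bar centred at col 12
    labels, table = find_sarcomeres(mask, pixel_size_um=1.0, min_area_um2=1.0)
    assert len(table) == 2
    got = sorted(zip(table.x_um, table.y_um))
    assert got[0] == (4.0, 5.0)
    assert got[1] == (12.0, 12.0)


def test_find_sarcomeres_area_filter_and_empty():
    mask = np.zeros((10, 10), dtype=bool)
    mask[2, 2:4] = True
    labels, table = find_sarcomeres(mask, 1.0, min_area_um2=50.0)
    assert len(table) == 0
    labels, table = find_sarcomeres(np.zeros((5, 5), bool), 1.0)
    assert len(table) == 0 and labels.max() == 0


def test_detected_count_matches_truth(clean_parts):
    _, _, template, image = clean_parts
    pre = preprocess(image)
    labels, table = find_sarcomeres(segment_zlines(pre), 0.1)
    n_true = len(template.zlines)
    assert abs(len(table) - n_true) <= 0.1 * n_true
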