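"""Cell summaries and the integrated quantification chain."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from sarcomech.io import ChannelImage
from sarcomech.quant import cell_summary, quantify_cell
from sarcomech.synth import generate_cell


def _records(**cols):
    base = dict(label=[1], x_um=[0.0], y_um=[0.0], theta_rad=[0.1],
                spacing_um=[1.6], fret_index=[50.0])
    base.update(cols)
    n = max(len(v) for v in base.values())
    return pd.DataFrame({k: (v * n if len(v) == 1 else v)
                         for k, v in base.items()})


def test_median_and_iqr_hand_computed():
    rec = _records(fret_index=[40.0, 50.0, 60.0], theta_rad=[0.1] * 3,
                   spacing_um=[1.5, 1.6, 1.7], label=[1, 2, 3],
                   x_um=[0.0] * 3, y_um=[0.0] * 3)
    s = cell_summary(rec)
    assert s.median_fret_index == 50.0
    assert s.fret_iqr == 10.0
    assert s.mean_spacing_um == pytest.approx(1.6)


def test_single_record_iqr_zero():
    s = cell_summary(_records())
    assert s.fret_iqr == 0.0
    assert s.n_sarcomeres == 1


def test_no_valid_spacing_still_summarised():
    rec = _records(spacing_um=[np.nan])
    s = cell_summary(rec)
    assert np.isnan(s.mean_spacing_um)
    assert s.median_fret_index == 50.0


def test_empty_rejected():
    with pytest.raises(ValueError):
        cell_summary(pd.DataFrame())


def test_quantified_cell_matches_ground_truth(live_cell):
    records, summ = quantify_cell(live_cell.donor, live_cell.acceptor,
                                  cell_mask=live_cell.mask.mask)
    truth = live_cell.truth_summary()
    assert abs(summ.mean_spacing_um - truth["mean_spacing_um"]) < 0.05
    assert abs(summ.median_fret_index - truth["median_fret_index"]) < 1.0
    assert summ.order_parameter > 0.9
    assert abs(len(records) - truth["n_sarcomeres"]) <= 0.1 * truth["n_sarcomeres"]


def test_rectangles_more_ordered_than_circles():
    """Image-level contrast: uniaxial rectangles vs multidomain circles."""
    S_rect = [quantify_cell(c.donor, c.acceptor, cell_mask=c.mask.mask)[1]
              .order_parameter
              for c in (generate_cell("live-contracted", s) for s in (21, 22, 23))]
    S_circ = [quantify_cell(c.donor, c.acceptor, cell_mask=c.mask.mask)[1]
              .order_parameter
              for c in (generate_cell("circle-contracted", s) for s in (21, 22, 23))]
    assert np.mean(S_rect) > np.mean(S_circ)
    assert np.mean(S_rect) > 0.85


def test_rotation_equivariance_of_pipeline(clean_parts, rect_mask):
    """Rotating the image rotates the director, leaving S unchanged."""
    preset, field, template, image = clean_parts
    from sarcomech.synth import render_fret_pair
    donor, acceptor = render_fret_pair(rect_mask, template, preset, seed=12)
    _, s0 = quantify_cell(donor, acceptor, cell_mask=rect_mask.mask)

    def rot(img):
        return ChannelImage(ndi.rotate(img.data, -30.0, reshape=True, order=1,
                                       cval=preset.background_level),
                            img.pixel_size_um, img.role)

    _, s1 = quantify_cell(rot(donor), rot(acceptor))
    d_dir = np.rad2deg((s1.director_rad - s0.director_rad) % np.pi)
    assert min(abs(d_dir - 30.0), abs(d_dir - 210.0 % 180)) <= 3.0
    assert abs(s1.order_parameter - s0.order_parameter) < 0.05


def test_spacing_window_is_hard_postcondition(live_cell):
    records, _ = quantify_cell(live_cell.donor, live_cell.acceptor,
                               cell_mask=live_cell.mask.mask)
    sp = records.spacing_um.dropna()
    assert (sp >= 1.2).all() and (sp <= 2.8).all()
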