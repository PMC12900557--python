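"""Forward rendering: striation combs, FRET channel pairs, photobleaching."""

import numpy as np
import pytest

from sarcomech.quant import fret_efficiency
from sarcomech.synth import (CellShapeSpec, build_striation_template,
                             get_preset, make_cell_mask,
                             make_orientation_field, make_photobleach_pair,
                             render_fret_pair, render_striations)


def _first_autocorr_peak_um(profile, px, min_lag_um=0.8):
    """Independent 1D autocorrelation oracle for the striation period."""
    p = profile - profile.mean()
    ac = np.correlate(p, p, mode="full")[len(p) - 1:]
    lag0 = int(round(min_lag_um / px))
    k = lag0 + np.argmax(ac[lag0:int(3.0 / px)])
    return k * px


@pytest.fixture(scope="module")
def fixed_spacing_parts():
    preset = get_preset("live-contracted").noiseless.replace(
        spacing_mean_um=1.8, spacing_sd_um=0.0, orientation_jitter_deg=0.0)
    mask = make_cell_mask(CellShapeSpec())
    field = make_orientation_field(mask, preset, seed=3)
    template = build_striation_template(mask, field, preset, seed=3)
    return preset, mask, field, template


def test_constant_spacing_comb_period(fixed_spacing_parts):
    preset, mask, field, template = fixed_spacing_parts
    img = render_striations(mask, field, preset, seed=3, template=template)
    row = img.data[img.data.shape[0] // 2]
    peak = _first_autocorr_peak_um(row, img.pixel_size_um)
    assert abs(peak - 1.8) <= img.pixel_size_um / 2 + 1e-9


def test_render_deterministic(rect_mask, clean_parts):
    preset, field, template, _ = clean_parts
    noisy = preset.replace(noise_gaussian_sd=10.0, poisson_noise=True)
    a = render_striations(rect_mask, field, noisy, seed=9)
    b = render_striations(rect_mask, field, noisy, seed=9)
    assert np.array_equal(a.data, b.data)


def test_psf_monotonically_reduces_modulation(rect_mask, clean_parts):
    preset, field, template, _ = clean_parts
    depths = []
    for sigma in [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]:
        img = render_striations(rect_mask, field,
                                preset.replace(psf_sigma_um=sigma),
                                seed=5, template=template)
        row = img.data[img.data.shape[0] // 2, 300:500]
        depths.append(row.max() - row.min())
    assert all(a > b for a, b in zip(depths, depths[1:]))


def test_negative_psf_rejected(rect_mask, clean_parts):
    _, field, template, _ = clean_parts
    with pytest.raises(ValueError):
        get_preset("live-contracted").replace(psf_sigma_um=-0.1)


def test_fret_pair_reconstructs_assigned_index(fixed_spacing_parts):
    preset, mask, field, template = fixed_spacing_parts
    vals = np.full(len(template.zlines), 50.0)
    donor, acceptor = render_fret_pair(mask, template, preset, seed=4,
                                       fret_values=vals)
    z = template.zlines[len(template.zlines) // 2]
    d = donor.data.ravel()[z.pixels] - preset.background_level
    a = acceptor.data.ravel()[z.pixels] - preset.background_level
    measured = 100.0 * a.sum() / (d.sum() + a.sum())
    assert abs(measured - 50.0) <= 0.5


def test_fret_zero_leaves_acceptor_at_background(fixed_spacing_parts):
    preset, mask, field, template = fixed_spacing_parts
    vals = np.zeros(len(template.zlines))
    _, acceptor = render_fret_pair(mask, template, preset, seed=4,
                                   fret_values=vals)
    assert np.allclose(acceptor.data, preset.background_level, atol=1e-9)


def test_invalid_fret_median_rejected():
    with pytest.raises(ValueError):
        get_preset("live-contracted").replace(fret_index_median=120.0)


def test_photobleach_pair_algebra(fixed_spacing_parts):
    preset, mask, field, template = fixed_spacing_parts
    donor, _ = render_fret_pair(mask, template, preset, seed=6)
    assert np.array_equal(make_photobleach_pair(donor, 0.0).data, donor.data)
    assert np.allclose(make_photobleach_pair(donor, 0.5).data, 2.0 * donor.data)
    with pytest.raises(ValueError):
        make_photobleach_pair(donor, 1.0)


def test_photobleach_roundtrip_recovers_efficiency(fixed_spacing_parts):
    preset, mask, field, template = fixed_spacing_parts
    donor, _ = render_fret_pair(mask, template, preset, seed=6)
    post = make_photobleach_pair(donor, 0.3)
    labels = np.zeros(template.shape, dtype=int)
    for z in template.zlines[:20]:
        labels.ravel()[z.pixels] = z.label + 1
    eff = fret_efficiency(donor, post, labels)
    assert np.all(np.abs(eff.E_FRET.dropna() - 0.3) <= 0.01)
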