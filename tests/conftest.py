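"""Shared fixtures: small synthetic cells reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from sarcomech.synth import (CellShapeSpec, build_striation_template,
                             generate_cell, get_preset, make_cell_mask,
                             make_orientation_field, render_striations)


@pytest.fixture(scope="session")
def rect_mask():
    return make_cell_mask(CellShapeSpec())


@pytest.fixture(scope="session")
def circle_mask():
    return make_cell_mask(CellShapeSpec(kind="circle"))


@pytest.fixture(scope="session")
def clean_parts(rect_mask):
    """Noiseless live-contracted rectangle: (preset, field, template, image)."""
    preset = get_preset("live-contracted").noiseless
    field = make_orientation_field(rect_mask, preset, seed=5)
    template = build_striation_template(rect_mask, field, preset, seed=5)
    image = render_striations(rect_mask, field, preset, seed=5, template=template)
    return preset, field, template, image


@pytest.fixture(scope="session")
def live_cell():
    """One noisy live-contracted rectangle with full ground truth."""
    return generate_cell("live-contracted", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
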