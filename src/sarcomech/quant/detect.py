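"""Sarcomere detection: connected components of the z-line mask."""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.measure import regionprops


def find_sarcomeres(mask: np.ndarray, pixel_size_um: float,
                    min_area_um2: float = 0.2) -> tuple[np.ndarray, pd.DataFrame]:
    """8-connected components with area >= min_area_um2.

    Returns a relabelled integer image (0 = background, labels 1..n) and
    a table of centroids in μm (x = col * px, y = row * px).  An empty
    mask yields an empty table, not an error.
    """
    if mask.dtype != bool:
        mask = mask.astype(bool)
    px = pixel_size_um
    lab = sk_label(mask, connectivity=2)
    rows, keep = [], np.zeros(lab.max() + 1, dtype=int)
    next_id = 0
    for rp in regionprops(lab):
        if rp.area * px * px < min_area_um2:
            continue
        next_id += 1
        keep[rp.label] = next_id
        cy, cx = rp.centroid
        rows.append({"label": next_id, "x_um": cx * px, "y_um": cy * px,
                     "area_um2": rp.area * px * px})
    labels = keep[lab]
    cols = ["label", "x_um", "y_um", "area_um2"]
    return labels, pd.DataFrame(rows, columns=cols)
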