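"""Ratiometric FRET index and acceptor-photobleaching FRET efficiency.

The per-sarcomere FRET index is the percent-like acceptor fraction
100 * A / (D + A) of background-subtracted channel means over the
sarcomere mask (ratio of means; more noise-robust than mean of ratios).
FRET efficiency from acceptor photobleaching is E = 1 - F_DA / F_D with
F_DA the donor fluorescence before and F_D after bleaching; values are
clamped to [0, 1] because noise can push the raw ratio past the physical
range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ..io import ChannelImage


def estimate_background(img: ChannelImage, cell_mask: np.ndarray | None = None,
                        labels: np.ndarray | None = None) -> float:
    """Median intensity outside the cell.

    Uses the provided cell mask; failing that, everything more than
    ~1 μm away from any labelled sarcomere counts as background.
    """
    if cell_mask is not None:
        outside = ~cell_mask.astype(bool)
    elif labels is not None:
        r = max(1, int(round(1.0 / img.pixel_size_um)))
        outside = ~ndi.binary_dilation(labels > 0, iterations=r)
    else:
        raise ValueError("need a cell mask or a label image for background")
    if not outside.any():
        return 0.0
    return float(np.median(img.data[outside]))


def fret_index(labels: np.ndarray, donor: ChannelImage, acceptor: ChannelImage,
               cell_mask: np.ndarray | None = None,
               method: str = "ratio-of-means") -> pd.DataFrame:
    """Per-sarcomere FRET index table (label, mean_donor, mean_acceptor, fret_index).

    Channel means are background-subtracted; a component whose total
    background-subtracted signal is <= 0 gets a NaN index.
    """
    if donor.data.shape != acceptor.data.shape or donor.data.shape != labels.shape:
        raise ValueError("donor, acceptor and labels must share a shape")
    if method not in ("ratio-of-means", "mean-of-ratios"):
        raise ValueError(f"unknown method {method!r}")
    bg_d = estimate_background(donor, cell_mask, labels)
    bg_a = estimate_background(acceptor, cell_mask, labels)
    ids = np.arange(1, labels.max() + 1)
    if len(ids) == 0:
        return pd.DataFrame(columns=["label", "mean_donor", "mean_acceptor",
                                     "fret_index"])
    mean_d = ndi.mean(donor.data, labels, ids) - bg_d
    mean_a = ndi.mean(acceptor.data, labels, ids) - bg_a
    if method == "ratio-of-means":
        total = mean_d + mean_a
        idx = np.where(total > 0, 100.0 * mean_a / np.where(total > 0, total, 1.0),
                       np.nan)
    else:
        d = donor.data - bg_d
        a = acceptor.data - bg_a
        tot = d + a
        ratio = np.where(tot > 0, 100.0 * a / np.where(tot > 0, tot, 1.0), np.nan)
        idx = ndi.mean(np.nan_to_num(ratio), labels, ids)
    return pd.DataFrame({"label": ids, "mean_donor": mean_d,
                         "mean_acceptor": mean_a, "fret_index": idx})


def fret_efficiency(f_da: ChannelImage, f_d: ChannelImage,
                    regions: np.ndarray) -> pd.DataFrame:
    """Acceptor-photobleaching efficiency E = 1 - F_DA/F_D per region.

    ``regions`` is a label image (0 = ignore).  Regions whose post-bleach
    donor mean is <= 0 get a NaN efficiency.
    """
    if f_da.data.shape != f_d.data.shape or f_da.data.shape != regions.shape:
        raise ValueError("images and regions must share a shape")
    ids = np.arange(1, regions.max() + 1)
    m_da = ndi.mean(f_da.data, regions, ids)
    m_d = ndi.mean(f_d.data, regions, ids)
    eff = np.where(m_d > 0,
                   np.clip(1.0 - m_da / np.where(m_d > 0, m_d, 1.0), 0.0, 1.0),
                   np.nan)
    return pd.DataFrame({"region": ids, "F_DA": m_da, "F_D": m_d,
                         "E_FRET": eff})
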