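"""Local sarcomere spacing and orientation by patch 2D autocorrelation.

For an image patch centred on a sarcomere, the 2D autocorrelation of the
mean-subtracted patch is scanned over directions 0..π.  Along each
direction the radial profile's first local maximum inside the physical
periodicity window [s_min, s_max] (default 1.2-2.8 μm) is located; the
myofibril-axis direction θ is the one maximising that peak, and the
spacing is the sub-pixel (parabolic-refined) peak radius along θ.
Patches without an in-window peak above a prominence floor yield None.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from ..io import ChannelImage


def autocorrelate_2d(patch: np.ndarray) -> np.ndarray:
    """Unbiased (overlap-corrected) linear FFT autocorrelation.

    Mean-subtracted, zero-padded to avoid wrap-around, divided by the
    triangular overlap window so peak positions are not dragged toward
    zero lag, and normalised to 1 at zero lag.  Returned with the input
    shape and the zero lag at ``(n0//2, n1//2)``; lags are at most half
    the patch, where the overlap factor stays >= 1/4.
    """
    p = patch - patch.mean()
    n0, n1 = p.shape
    F = np.fft.rfft2(p, s=(2 * n0, 2 * n1))
    ac = np.fft.irfft2(np.abs(F) ** 2, s=(2 * n0, 2 * n1))
    ac = np.fft.fftshift(ac)[n0 - n0 // 2:2 * n0 - n0 // 2,
                             n1 - n1 // 2:2 * n1 - n1 // 2]
    k0 = np.abs(np.arange(n0) - n0 // 2)
    k1 = np.abs(np.arange(n1) - n1 // 2)
    overlap = np.outer(1.0 - k0 / n0, 1.0 - k1 / n1)
    ac = ac / overlap
    peak = ac[n0 // 2, n1 // 2]
    return ac / peak if peak > 0 else ac


def _extract_patch(data: np.ndarray, row: int, col: int, half: int) -> np.ndarray:
    """Patch with reflection padding when it overruns the image border."""
    H, W = data.shape
    pad = ((max(0, half - row), max(0, row + half + 1 - H)),
           (max(0, half - col), max(0, col + half + 1 - W)))
    if any(p > 0 for pp in pad for p in pp):
        data = np.pad(data, pad, mode="reflect")
        row += pad[0][0]
        col += pad[1][0]
    return data[row - half:row + half + 1, col - half:col + half + 1]


def local_spacing_orientation(img: ChannelImage, centroid_um: tuple[float, float],
                              patch_um: float = 8.0, s_min: float = 1.2,
                              s_max: float = 2.8, angle_step_deg: float = 2.0,
                              prominence: float = 0.05
                              ) -> tuple[float, float] | None:
    """Return (spacing_um, theta) at a sarcomere, or None if aperiodic.

    theta is the direction of maximum periodicity (the myofibril axis,
    normal to the z-lines) in [0, π).  Emitted spacings always lie in
    [s_min, s_max].
    """
    if s_min >= s_max:
        raise ValueError("s_min must be < s_max")
    if patch_um < 2.0 * s_max:
        raise ValueError("patch must span at least twice the maximum spacing")
    px = img.pixel_size_um
    half = int(round(patch_um / 2.0 / px))
    col = int(round(centroid_um[0] / px))
    row = int(round(centroid_um[1] / px))
    patch = _extract_patch(img.data.astype(float), row, col, half)
    ac = autocorrelate_2d(patch)
    c0 = np.array(ac.shape) // 2

    # radial profiles for all directions at once
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    dr = px / 2.0
    radii = np.arange(max(dr, s_min - 0.4), min(half * px, s_max + 0.4), dr)
    cos_a, sin_a = np.cos(angles), np.sin(angles)
    rows = c0[0] + np.outer(sin_a, radii / px)
    cols = c0[1] + np.outer(cos_a, radii / px)
    profiles = map_coordinates(ac, [rows.ravel(), cols.ravel()], order=3,
                               mode="nearest").reshape(len(angles), len(radii))

    # A valid periodicity peak must rise `prominence` above its local
    # trough and explain at least 2*prominence of the zero-lag variance
    # (rejects white-noise wander in the unbiased tail).
    in_window = (radii >= s_min) & (radii <= s_max)
    candidates = []  # (radius index, angle index)
    for j in range(len(angles)):
        peaks, _ = find_peaks(profiles[j], prominence=prominence,
                              height=2.0 * prominence)
        peaks = [p for p in peaks if in_window[p]]
        if peaks:
            candidates.append((peaks[0], j))  # first in-window peak

    if not candidates:
        return None

    def _refined_radius(p: int, prof: np.ndarray) -> float:
        # parabolic sub-pixel refinement of the peak radius
        if 0 < p < len(radii) - 1:
            denom = prof[p - 1] - 2 * prof[p] + prof[p + 1]
            delta = 0.5 * (prof[p - 1] - prof[p + 1]) / denom if denom != 0 else 0.0
            return float(radii[p] + np.clip(delta, -1.0, 1.0) * dr)
        return float(radii[p])

    # The myofibril normal has the *shortest* first peak: an off-axis
    # direction sees the projected (longer) period p/cos(dtheta).  Among
    # directions whose peak falls within one sample of the minimal radius
    # bin, pick the one minimising the refined radius.
    p_min = min(p for p, _ in candidates)
    best_r, best_j = np.inf, 0
    for p, j in candidates:
        if p > p_min + 1:
            continue
        r = _refined_radius(p, profiles[j])
        if r < best_r:
            best_r, best_j = r, j
    spacing = float(np.clip(best_r, s_min, s_max))
    theta = float(angles[best_j]) % np.pi
    return spacing, theta
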