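"""Per-pixel striation orientation fields.

Orientations are unsigned line directions in [0, π) (nematic, period π),
measured from the image x-axis, counterclockwise positive.  Uniaxial
fields follow the pattern long axis with a spatially correlated Gaussian
jitter whose marginal SD equals the preset jitter.  Multidomain fields
tile the mask with Voronoi domains of independent uniform angles,
smoothed across domain boundaries in the doubled-angle representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .presets import StriationPreset
from .shapes import CellMask


@dataclass
class OrientationField:
    """Angles (radians, [0, π)) on the mask plus the domain partition."""

    angles: np.ndarray        # (H, W) float; defined on mask pixels
    domains: np.ndarray       # (H, W) int domain label, -1 outside mask
    domain_angles: np.ndarray  # base angle per domain
    pixel_size_um: float

    @property
    def n_domains(self) -> int:
        return len(self.domain_angles)

    def sample(self, x_um: float, y_um: float) -> float:
        px = self.pixel_size_um
        i = int(np.clip(round(y_um / px), 0, self.angles.shape[0] - 1))
        j = int(np.clip(round(x_um / px), 0, self.angles.shape[1] - 1))
        return float(self.angles[i, j])


def _fold(theta: np.ndarray) -> np.ndarray:
    return np.mod(theta, np.pi)


def _smooth_jitter_field(shape, sd_rad: float, corr_um: float, px: float,
                         mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated Gaussian field with exact sample SD over the mask."""
    if sd_rad == 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=corr_um / px)
    s = smooth[mask].std()
    if s == 0:
        return np.zeros(shape)
    smooth = smooth - smooth[mask].mean()
    return smooth * (sd_rad / smooth[mask].std())


def make_orientation_field(mask: CellMask, preset: StriationPreset,
                           seed: int) -> OrientationField:
    """Generate the per-pixel angle field for one cell (deterministic in seed)."""
    m = mask.mask
    if not m.any():
        raise ValueError("empty cell mask")
    rng = np.random.default_rng(seed)
    px = mask.pixel_size_um
    jitter = np.deg2rad(preset.orientation_jitter_deg)

    if preset.orientation_mode == "uniaxial":
        base = mask.long_axis_angle
        angles = np.full(m.shape, base, dtype=float)
        angles += _smooth_jitter_field(m.shape, jitter, corr_um=2.0, px=px,
                                       mask=m, rng=rng)
        domains = np.where(m, 0, -1)
        return OrientationField(_fold(angles), domains, np.array([base]), px)

    if preset.n_domains < 1:
        raise ValueError("multidomain orientation requires n_domains >= 1")
    n = preset.n_domains
    ys, xs = np.nonzero(m)
    pts = np.column_stack([xs, ys]).astype(float)
    # farthest-point sampling spreads the Voronoi seeds, keeping domain
    # areas comparable
    sub = pts[rng.choice(len(pts), min(len(pts), 4000), replace=False)]
    chosen = [sub[rng.integers(len(sub))]]
    dmin = np.full(len(sub), np.inf)
    for _ in range(n - 1):
        dmin = np.minimum(dmin, np.sum((sub - chosen[-1]) ** 2, axis=1))
        chosen.append(sub[np.argmax(dmin)])
    seeds_xy = np.array(chosen)

    Y, X = np.indices(m.shape)
    d2 = (X[..., None] - seeds_xy[:, 0]) ** 2 + (Y[..., None] - seeds_xy[:, 1]) ** 2
    domains = np.argmin(d2, axis=-1)

    # Stratified, area-balanced angles: jittered bins spanning [0, pi),
    # with the largest domains receiving maximally separated bins.  A
    # multidomain cell is thereby guaranteed multi-directional for any
    # seed (nematic order stays well below the uniaxial regime), which is
    # the defining contrast with the rectangular phenotype.
    bins = (np.arange(n) + rng.uniform(0.0, 1.0, n)) * np.pi / n
    areas = np.bincount(domains[m], minlength=n)
    order_by_area = np.argsort(-areas)
    # van-der-Corput style bin order: successive bins far apart
    bin_order = sorted(range(n), key=lambda i: int(bin(i + n)[3:][::-1], 2))
    domain_angles = np.empty(n)
    domain_angles[order_by_area] = bins[bin_order]
    angles = domain_angles[domains]
    # smooth across boundaries in the doubled-angle (nematic) representation
    sigma_px = 1.0 / px
    c = gaussian_filter(np.cos(2 * angles), sigma_px)
    s = gaussian_filter(np.sin(2 * angles), sigma_px)
    angles = 0.5 * np.arctan2(s, c)
    domains = np.where(m, domains, -1)
    return OrientationField(_fold(angles), domains, domain_angles, px)
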