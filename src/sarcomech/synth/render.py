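"""Forward model: paint z-line ridges and render fluorescence channels.

Z-disks are rendered as Gaussian-profile ridges (default FWHM 0.35 μm)
perpendicular to the local myofibril axis, with successive gaps along the
axis drawn from N(spacing_mean, spacing_sd).  The explicit per-ridge
construction is what makes the ground truth exact: every rendered
sarcomere knows its centroid, orientation, gap to the next z-line and
FRET index.

Channel model: the donor and acceptor share the structural ridge comb;
a sarcomere with FRET index f contributes fraction f/100 of its photons
to the acceptor and 1 - f/100 to the donor, so 100*A/(D+A) recovers f at
its pixels before noise.  Both channels are blurred by a Gaussian PSF,
offset by a uniform background and optionally corrupted by Poisson shot
noise plus Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ..io import ChannelImage
from .orientation import OrientationField
from .presets import StriationPreset
from .shapes import CellMask

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ZLine:
    """One rendered z-disk: ground truth for a single sarcomere."""

    label: int
    center_um: tuple[float, float]      # painted intensity centroid (x, y)
    theta: float                        # myofibril-axis direction, [0, pi)
    spacing_um: float                   # gap to the neighbouring z-line
    pixels: np.ndarray                  # flat indices into the raster
    weights: np.ndarray                 # Gaussian ridge weights at pixels
    fret_index: float = np.nan


@dataclass
class StriationTemplate:
    """Clean (pre-PSF, pre-noise) ridge comb plus per-sarcomere truth."""

    shape: tuple[int, int]
    pixel_size_um: float
    comb: np.ndarray                    # sum of ridge weights, peak ~1
    zlines: list[ZLine] = field(default_factory=list)

    @property
    def mean_spacing_um(self) -> float:
        return float(np.mean([z.spacing_um for z in self.zlines]))

    def orientations(self) -> np.ndarray:
        return np.array([z.theta for z in self.zlines])


def _nematic_mean(angles: np.ndarray) -> float:
    return float(0.5 * np.arctan2(np.mean(np.sin(2 * angles)),
                                  np.mean(np.cos(2 * angles)))) % np.pi


def build_striation_template(mask: CellMask, field_: OrientationField,
                             preset: StriationPreset, seed: int) -> StriationTemplate:
    """Place z-lines domain by domain and paint their Gaussian ridges."""
    rng = np.random.default_rng(seed)
    px = mask.pixel_size_um
    H, W = mask.mask.shape
    comb = np.zeros((H, W))
    sigma_r = preset.ridge_fwhm_um / _FWHM
    tpl = StriationTemplate((H, W), px, comb)

    label = 0
    for d in range(field_.n_domains):
        dm = (field_.domains == d) & mask.mask
        ys, xs = np.nonzero(dm)
        if len(ys) < 16:
            continue
        x_um, y_um = xs * px, ys * px
        phi = field_.domain_angles[d] if field_.n_domains > 1 else mask.long_axis_angle
        u = np.array([np.cos(phi), np.sin(phi)])
        proj = x_um * u[0] + y_um * u[1]
        pmin, pmax = proj.min(), proj.max()
        anchor = np.array([x_um.mean(), y_um.mean()])

        # draw z-line positions along the domain axis
        positions = []
        t = pmin + rng.uniform(0.0, preset.spacing_mean_um)
        while t <= pmax:
            positions.append(t)
            t += max(rng.normal(preset.spacing_mean_um, preset.spacing_sd_um),
                     preset.min_gap_um)
        if len(positions) < 2:
            continue
        gaps = np.diff(positions)

        domain_lines: list[ZLine] = []
        for k, tk in enumerate(positions):
            ck = anchor + (tk - anchor @ u) * u
            theta_k = field_.sample(*ck)
            uk = np.array([np.cos(theta_k), np.sin(theta_k)])
            dist = (x_um - ck[0]) * uk[0] + (y_um - ck[1]) * uk[1]
            sel = np.abs(dist) <= 4.0 * sigma_r
            if sel.sum() < 4:
                continue
            w = np.exp(-dist[sel] ** 2 / (2.0 * sigma_r ** 2))
            flat = ys[sel] * W + xs[sel]
            comb_flat = comb.ravel()
            np.add.at(comb_flat, flat, w)
            cx = float(np.average(x_um[sel], weights=w))
            cy = float(np.average(y_um[sel], weights=w))
            spacing = gaps[k] if k < len(gaps) else gaps[-1]
            domain_lines.append(ZLine(label, (cx, cy), theta_k % np.pi,
                                      float(spacing), flat, w))
            label += 1
        tpl.zlines.extend(domain_lines)
    if not tpl.zlines:
        raise ValueError("no z-lines could be placed on this mask/preset")
    return tpl


def _detect(clean: np.ndarray, preset: StriationPreset,
            rng: np.random.Generator, px: float) -> np.ndarray:
    """PSF blur + background + noise on a clean photon raster."""
    img = clean
    if preset.psf_sigma_um > 0:
        img = gaussian_filter(img, preset.psf_sigma_um / px)
    img = img + preset.background_level
    if preset.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if preset.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, preset.noise_gaussian_sd, img.shape)
    return np.clip(img, 0.0, None)


def render_striations(mask: CellMask, field_: OrientationField,
                      preset: StriationPreset, seed: int,
                      template: StriationTemplate | None = None) -> ChannelImage:
    """Structural-channel raster of the striated cell (deterministic in seed)."""
    if preset.psf_sigma_um < 0:
        raise ValueError("psf_sigma_um must be >= 0")
    if template is None:
        template = build_striation_template(mask, field_, preset, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    img = _detect(preset.amplitude * template.comb, preset, rng, mask.pixel_size_um)
    return ChannelImage(img, mask.pixel_size_um, "structural")


def render_fret_pair(mask: CellMask, template: StriationTemplate,
                     preset: StriationPreset, seed: int,
                     fret_values: np.ndarray | None = None
                     ) -> tuple[ChannelImage, ChannelImage]:
    """Donor/acceptor pair; assigns each z-line its true FRET index in-place.

    ``fret_values`` overrides the random per-sarcomere draws (one value
    per z-line, index units in [0, 100]).
    """
    if not 0.0 < preset.fret_index_median < 100.0:
        raise ValueError("fret_index_median must lie in (0, 100)")
    ss = np.random.SeedSequence([seed, 2])
    rng_f, rng_d, rng_a = [np.random.default_rng(s) for s in ss.spawn(3)]
    H, W = template.shape
    donor = np.zeros(H * W)
    acceptor = np.zeros(H * W)
    for k, z in enumerate(template.zlines):
        if fret_values is not None:
            f = float(fret_values[k])
        else:
            f = float(np.clip(rng_f.normal(preset.fret_index_median,
                                           preset.fret_index_spread), 0.5, 99.5))
        z.fret_index = f
        np.add.at(acceptor, z.pixels, (f / 100.0) * preset.amplitude * z.weights)
        np.add.at(donor, z.pixels, (1.0 - f / 100.0) * preset.amplitude * z.weights)
    px = template.pixel_size_um
    d_img = _detect(donor.reshape(H, W), preset, rng_d, px)
    a_img = _detect(acceptor.reshape(H, W), preset, rng_a, px)
    return (ChannelImage(d_img, px, "donor"), ChannelImage(a_img, px, "acceptor"))


def make_photobleach_pair(donor_pre: ChannelImage, e_true: float) -> ChannelImage:
    """Donor image after complete acceptor photobleaching.

    Inverts E = 1 - F_DA/F_D: the dequenched donor is F_D = F_DA/(1 - E).
    """
    if not 0.0 <= e_true < 1.0:
        raise ValueError("E_true must satisfy 0 <= E < 1")
    post = donor_pre.data / (1.0 - e_true)
    return ChannelImage(post, donor_pre.pixel_size_um, "donor")
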