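"""Striation presets emulating micropatterned hiPSC cardiomyocytes.

The published cohort statistics the presets carry:

* sarcomere spacing, live rectangular cells: contracted 1.63 ± 0.15 μm
  (mean ± SD), relaxed 1.73 ± 0.14 μm; fixed cells: contracted
  1.61 ± 0.15 μm, relaxed 1.74 ± 0.24 μm;
* per-cell median FRET index (percent-like, 100·A/(D+A)): contracted
  44.21, relaxed 51.70.

Circular cells are given multi-domain orientation fields (lower nematic
order), slightly longer spacing, and a contracted FRET median near the
relaxed value — circles do not build z-disk tension.  Day-1 ("immature")
presets qualitatively emulate early sarcomerogenesis: longer spacing,
multi-domain order even on rectangles, lower contrast, smaller FRET
spread; no published day-1 numbers are claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class StriationPreset:
    name: str
    spacing_mean_um: float
    spacing_sd_um: float
    orientation_mode: str = "uniaxial"      # "uniaxial" | "multidomain"
    orientation_jitter_deg: float = 4.0
    n_domains: int = 8                      # multidomain only
    fret_index_median: float = 50.0         # percent-like index units
    fret_index_spread: float = 5.0          # SD of per-sarcomere indices
    psf_sigma_um: float = 0.15
    ridge_fwhm_um: float = 0.35             # z-line Gaussian ridge FWHM
    amplitude: float = 1000.0               # peak signal, detector counts
    background_level: float = 100.0         # uniform offset, counts
    noise_gaussian_sd: float = 10.0         # read noise, counts
    poisson_noise: bool = True              # shot noise on the clean counts
    min_gap_um: float = 0.8                 # hard floor on drawn z-line gaps

    def __post_init__(self):
        if self.orientation_mode not in ("uniaxial", "multidomain"):
            raise ValueError(f"unknown orientation_mode {self.orientation_mode!r}")
        if not 0.0 < self.fret_index_median < 100.0:
            raise ValueError("fret_index_median must lie in (0, 100)")
        if self.spacing_sd_um < 0 or self.fret_index_spread < 0:
            raise ValueError("spreads must be >= 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")
        if self.spacing_mean_um <= 0:
            raise ValueError("spacing_mean_um must be > 0")

    def replace(self, **kw) -> "StriationPreset":
        return replace(self, **kw)

    @property
    def noiseless(self) -> "StriationPreset":
        return self.replace(noise_gaussian_sd=0.0, poisson_noise=False)


_P = StriationPreset

PRESETS: dict[str, StriationPreset] = {p.name: p for p in [
    _P("live-contracted", 1.63, 0.15, fret_index_median=44.21),
    _P("live-relaxed", 1.73, 0.14, fret_index_median=51.70),
    _P("fixed-contracted", 1.61, 0.15, fret_index_median=44.21),
    _P("fixed-relaxed", 1.74, 0.24, fret_index_median=51.70),
    _P("circle-contracted", 1.70, 0.18, orientation_mode="multidomain",
       fret_index_median=51.0),
    _P("circle-relaxed", 1.78, 0.18, orientation_mode="multidomain",
       fret_index_median=51.7),
    _P("day1-rect", 1.82, 0.20, orientation_mode="multidomain",
       fret_index_median=48.0, fret_index_spread=3.0, amplitude=600.0),
    _P("day1-circle", 1.84, 0.20, orientation_mode="multidomain",
       fret_index_median=50.0, fret_index_spread=3.0, amplitude=600.0),
]}


def get_preset(name: str) -> StriationPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None
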