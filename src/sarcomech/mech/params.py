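"""Model parameters for the chemo-mechanical feedback law.

Units: stresses and moduli in kPa; the feedback strengths ``alpha`` and
``alpha_a`` in kPa^-1; ``beta`` (motor-binding cost) occupies the same
nondimensional unit slot as ``alpha`` (see docs/methods.md for the unit
convention).  ``rho0`` is the quiescent, non-adhered contractility.

Two state presets are provided: the contracted state uses rho0 = 2 kPa,
the relaxed state rho0 = 0.01 kPa (10 Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ModelParams:
    """Constants of the feedback contractility model.

    alpha    -- feedback of contractility to stress (kPa^-1)
    alpha_a  -- feedback of contractility to stress anisotropy (kPa^-1)
    beta     -- energetic cost of motor binding (same nondimensional slot)
    rho0     -- quiescent contractility (kPa)
    K, mu    -- cytoskeleton bulk / shear moduli (kPa)
    K_alpha, mu_alpha -- alpha-actinin bulk / shear moduli (kPa); default
        equal to the cytoskeletal values.
    """

    alpha: float = 1.0
    alpha_a: float = 2.0
    beta: float = 4.0
    rho0: float = 2.0
    K: float = 3.333
    mu: float = 0.3448
    K_alpha: float = field(default=None)  # type: ignore[assignment]
    mu_alpha: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.K_alpha is None:
            object.__setattr__(self, "K_alpha", self.K)
        if self.mu_alpha is None:
            object.__setattr__(self, "mu_alpha", self.mu)
        self.validate()

    def validate(self) -> None:
        for name in ("K", "mu", "K_alpha", "mu_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"modulus {name} must be > 0")
        if self.rho0 < 0:
            raise ValueError("rho0 must be >= 0")
        if self.beta <= self.alpha:
            raise ValueError("beta must exceed alpha (feedback denominators)")
        if self.alpha_a / (self.beta - self.alpha) >= 1.0:
            raise ValueError(
                "anisotropy gain 2*rho_a_bar = alpha_a/(beta-alpha) must be < 1 "
                "for the fixed point to be a contraction"
            )

    def replace(self, **kw) -> "ModelParams":
        d = asdict(self)
        d.update(kw)
        return ModelParams(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


#: Contracted-state parameter preset (rho0 = 2 kPa).
CONTRACTED = ModelParams()

#: Relaxed-state preset (rho0 = 10 Pa); all other constants unchanged.
RELAXED = ModelParams(rho0=0.01)

STATE_PRESETS = {"contracted": CONTRACTED, "relaxed": RELAXED}
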