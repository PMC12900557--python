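"""Nematic order parameter of sarcomere orientations.

S = <(3 cos^2(theta_i - n) - 1)/2> with the director n chosen to maximise
S.  In 2D the maximising direction is the principal eigenvector of the
nematic tensor <2 u (x) u - I>; S is then evaluated by the averaging
formula against that director.  Perfect alignment gives S = 1; isotropic
2D orientations give S -> 0.25 (since <cos^2> = 1/2 in the plane).
"""

from __future__ import annotations

import numpy as np

_TIE_TOL = 1e-12


def order_parameter(orientations) -> tuple[float, float]:
    """Return (S, director) for nematic angles in radians.

    The director is reported in [0, π).  For a degenerate nematic tensor
    (no preferred axis, e.g. two equal groups at 0° and 90°) the tie is
    broken toward the smaller angle.
    """
    theta = np.atleast_1d(np.asarray(orientations, dtype=float))
    if theta.size == 0:
        raise ValueError("order_parameter requires at least one orientation")
    c, s = np.cos(theta), np.sin(theta)
    # 2x2 nematic tensor <2 u(x)u - I>
    m_xx = np.mean(2 * c * c - 1.0)
    m_xy = np.mean(2 * c * s)
    # eigenvector of [[m_xx, m_xy], [m_xy, -m_xx]] for the largest eigenvalue
    lam = np.hypot(m_xx, m_xy)
    if lam < _TIE_TOL:
        director = 0.0
    else:
        director = 0.5 * np.arctan2(m_xy, m_xx)
    director %= np.pi
    S = evaluate_order(theta, director)
    # tie-break toward the smaller angle among equivalent directors
    if lam < _TIE_TOL:
        director = 0.0
    return float(S), float(director)


def evaluate_order(orientations, director: float) -> float:
    """Evaluate S = <(3 cos^2(theta - n) - 1)/2> against a given director."""
    theta = np.asarray(orientations, dtype=float)
    return float(np.mean((3.0 * np.cos(theta - director) ** 2 - 1.0) / 2.0))
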