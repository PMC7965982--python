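"""Inverse use of the trained ensemble: velocity from observed damage.

With all other boundary conditions fixed, the ensemble probability that
the damage threshold is exceeded is swept over velocity.  The resulting
sigmoid-shaped curve saturates at a plateau probability P_f; the impact
velocity consistent with *exactly* the observed damage proportion is taken
as the first grid velocity whose probability reaches 95% of P_f (the
probability refers to *at least* the proportion being damaged, so the
plateau onset marks where that proportion is first reached).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .ml import ImpactScenario, TrainedEnsemble, extract_features, features_frame

__all__ = [
    "VelocityCurve",
    "probability_velocity_curve",
    "plateau_and_velocity",
]

#: Fraction of the upper velocity grid averaged into the plateau estimate.
PLATEAU_WINDOW_FRACTION = 0.1
#: Plateau-onset criterion: first v with P(v) >= this fraction of P_f.
PLATEAU_ONSET_FRACTION = 0.95


@dataclass(frozen=True)
class VelocityCurve:
    """Probability-velocity sweep with its plateau summary.

    ``plateau_probability`` is the mean probability over the top decile of
    the velocity grid; ``v_at_95`` the first grid velocity reaching 95% of
    it, or ``None`` when never reached (``reached`` False).
    """

    velocities: np.ndarray
    probabilities: np.ndarray
    plateau_probability: float
    v_at_95: float | None
    reached: bool


def plateau_and_velocity(velocities, probabilities,
                         window_fraction: float = PLATEAU_WINDOW_FRACTION,
                         onset_fraction: float = PLATEAU_ONSET_FRACTION,
                         smooth: bool = False):
    """Plateau probability and plateau-onset velocity of a sweep.

    P_f is the mean probability over the top *window_fraction* of the
    velocity grid (after optional isotonic smoothing, useful when member
    probabilities oscillate in the upper plateau); the onset velocity is
    the smallest grid v with ``P(v) >= onset_fraction * P_f``.  Returns
    ``(P_f, v)`` with ``v = None`` when the onset level is never reached
    (e.g. an all-zero curve).
    """
    v = np.asarray(velocities, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if v.size < 10:
        raise ValueError("need at least 10 curve samples")
    if v.size != p.size:
        raise ValueError("velocity and probability grids are misaligned")
    if np.any(np.diff(v) <= 0):
        raise ValueError("velocity grid must be strictly ascending")
    if smooth:
        p = IsotonicRegression(y_min=0.0, y_max=1.0).fit_transform(v, p)
    n_win = max(1, int(np.ceil(window_fraction * v.size)))
    p_f = float(np.mean(p[-n_win:]))
    if p_f <= 0.0:
        return 0.0, None
    hit = np.flatnonzero(p >= onset_fraction * p_f)
    if hit.size == 0:
        return p_f, None
    return p_f, float(v[hit[0]])


def probability_velocity_curve(ensemble: TrainedEnsemble,
                               base: ImpactScenario, mesh, dmn_ids,
                               v_min: float = 1.0, v_max: float = 15.0,
                               step: float = 0.1,
                               smooth: bool = False) -> VelocityCurve:
    """Sweep velocity with the other boundary conditions held fixed.

    Features are re-extracted at each velocity (the geometric features are
    constant for a fixed impact point, the velocity feature varies) and
    the ensemble probability evaluated on the grid
    ``v_min, v_min + step, ..., v_max``.
    """
    if v_min >= v_max:
        raise ValueError(f"v_min must be < v_max, got [{v_min}, {v_max}]")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((v_max - v_min) / step)) + 1
    velocities = np.linspace(v_min, v_max, n)

    class _Row:
        __slots__ = ("features",)

        def __init__(self, f):
            self.features = f

    rows = [_Row(extract_features(dataclasses.replace(base, velocity=float(v)),
                                  mesh, dmn_ids)) for v in velocities]
    probs = np.asarray(ensemble.predict_proba(features_frame(rows)), dtype=float)
    if smooth:
        probs = IsotonicRegression(y_min=0.0, y_max=1.0).fit_transform(
            velocities, probs)
    p_f, v95 = plateau_and_velocity(velocities, probs, smooth=False)
    return VelocityCurve(velocities=velocities, probabilities=probs,
                         plateau_probability=p_f, v_at_95=v95,
                         reached=v95 is not None)
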