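"""Accident-reconstruction kinematics.

Desk arithmetic used in medico-legal impact reconstruction: composing a fall
height from signed components, free-fall impact velocity, impact force from
head mass and peak acceleration, and mph/(m/s) conversion.  Each quantity
carries the rounding profile conventional in forensic reports, so the
printed numbers match the reconstruction narratives exactly (e.g. a 7.3 m
fall gives "12 m/s" at integer rounding, 10.1 m gives "14.1 m/s" at one
decimal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

__all__ = [
    "G_STANDARD",
    "MPH_TO_MS",
    "FallSpec",
    "compose_fall_height",
    "freefall_velocity",
    "impact_force",
    "mph_to_ms",
    "ms_to_mph",
]

#: Gravitational acceleration used throughout (m/s^2).
G_STANDARD = 9.81
#: Exact statute definition, 1 mph = 0.44704 m/s.
MPH_TO_MS = 0.44704


@dataclass(frozen=True)
class FallSpec:
    """A fall described by signed height components (m)."""

    components: list[float] = field(default_factory=list)
    gravity: float = G_STANDARD

    @property
    def height(self) -> float:
        return compose_fall_height(self.components)

    @property
    def velocity(self) -> float:
        return freefall_velocity(self.height, g=self.gravity)


def _round(x: float, decimals: int | None) -> float:
    """Round to *decimals* places, or to the nearest integer when None."""
    if decimals is None:
        return float(round(x))
    return float(round(x, decimals))


def compose_fall_height(components) -> float:
    """Algebraic sum of signed height components, rounded to 1 decimal (m).

    E.g. roof-gutter height + gutter + standing height − head-to-contact
    offset.  Raises ``ValueError`` when the composed height is not positive.
    """
    components = list(components)
    if not components:
        raise ValueError("at least one height component is required")
    total = float(sum(components))
    if total <= 0:
        raise ValueError(f"composed fall height {total:g} m is not positive")
    return _round(total, 1)


def freefall_velocity(h: float, g: float = G_STANDARD,
                      decimals: int | None = None) -> float:
    """Impact velocity ``sqrt(2 g h)`` of a simple fall from rest (m/s).

    No initial velocity and no arc of rotation are considered.  *decimals*
    selects the rounding profile: ``None`` (default) rounds to the nearest
    integer, an int rounds to that many decimals.
    """
    if h <= 0:
        raise ValueError(f"fall height must be positive, got {h:g} m")
    return _round(sqrt(2.0 * g * h), decimals)


def impact_force(mass: float, accel_g: float) -> float:
    """Peak impact force ``m * a`` for an acceleration in multiples of g (kN).

    Rounded to 2 decimals; e.g. a 6.82 kg adult head at 80 g gives 5.35 kN.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass:g} kg")
    return _round(mass * accel_g * G_STANDARD / 1000.0, 2)


def mph_to_ms(v_mph: float, decimals: int | None = 1) -> float:
    """Convert miles per hour to m/s (default: 1-decimal rounding)."""
    return _round(float(v_mph) * MPH_TO_MS, decimals)


def ms_to_mph(v_ms: float, decimals: int | None = 1) -> float:
    """Convert m/s to miles per hour (default: 1-decimal rounding)."""
    return _round(float(v_ms) / MPH_TO_MS, decimals)
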