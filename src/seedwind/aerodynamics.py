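"""Aerodynamic scaling relations for wind-dispersed diaspores.

Three standard relations frame the windward-area model:

* airflow thrust on the windward face, ``F = c * rho * v**2 * S`` —
  valid in the inertial regime where form drag dominates;
* terminal-velocity scaling with wing loading, ``v_ter ∝ sqrt(w / A_W)``
  (``w`` weight, ``A_W`` wing surface area) — only ratios between two
  diaspores are meaningful, the proportionality constant being unknown;
* the Reynolds number ``Re = rho * v * L / mu`` with a regime predicate
  for the 1e3–1e4 band typical of centimetre-scale falling seeds, where
  inertial forces dominate viscous ones and the thrust law applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .windward import InvalidParameterError

__all__ = [
    "AirState",
    "DiasporeMass",
    "thrust",
    "terminal_velocity_scale",
    "compare_terminal_velocity",
    "reynolds_number",
    "in_inertial_regime",
    "INERTIAL_RE_MIN",
    "INERTIAL_RE_MAX",
]

#: Reynolds-number band in which falling centimetre-scale diaspores operate.
INERTIAL_RE_MIN = 1e3
INERTIAL_RE_MAX = 1e4


@dataclass(frozen=True)
class AirState:
    """Fluid state: density rho (kg m^-3), dynamic viscosity mu (Pa s), flow speed v (m s^-1)."""

    density: float = 1.225
    dynamic_viscosity: float = 1.8e-5
    velocity: float = 1.0

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise InvalidParameterError(f"air density must be > 0, got {self.density!r}")
        if not self.dynamic_viscosity > 0:
            raise InvalidParameterError(
                f"dynamic viscosity must be > 0, got {self.dynamic_viscosity!r}"
            )
        if self.velocity < 0:
            raise InvalidParameterError(f"velocity must be >= 0, got {self.velocity!r}")


@dataclass(frozen=True)
class DiasporeMass:
    """Weight w (force units) and wing surface area A_W (area units) of one diaspore."""

    weight: float
    wing_area: float

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise InvalidParameterError(f"weight must be > 0, got {self.weight!r}")
        if not self.wing_area > 0:
            raise InvalidParameterError(f"wing area must be > 0, got {self.wing_area!r}")

    @property
    def wing_loading(self) -> float:
        """w / A_W; higher loading means faster descent."""
        return self.weight / self.wing_area


def thrust(c: float, air: AirState, windward: float) -> float:
    """Airflow thrust F = c * rho * v**2 * S on windward area S.

    Linear in the windward area and quadratic in the flow speed; ``c``
    is a free drag-type coefficient.
    """
    if not c > 0:
        raise InvalidParameterError(f"coefficient c must be > 0, got {c!r}")
    if windward < 0:
        raise InvalidParameterError(f"windward area must be >= 0, got {windward!r}")
    return c * air.density * air.velocity**2 * windward


def terminal_velocity_scale(d: DiasporeMass) -> float:
    """sqrt(w / A_W): the terminal-velocity scale set by wing loading.

    The absolute descent speed needs a drag coefficient and air density;
    this scale supports only comparisons between diaspores.
    """
    return math.sqrt(d.wing_loading)


def compare_terminal_velocity(d1: DiasporeMass, d2: DiasporeMass) -> float:
    """Ratio of terminal-velocity scales v_ter(d1) / v_ter(d2).

    Equal wing loadings give 1; the lower-loaded diaspore descends
    strictly more slowly.
    """
    return terminal_velocity_scale(d1) / terminal_velocity_scale(d2)


def reynolds_number(air: AirState, characteristic_length: float) -> float:
    """Re = rho * v * L / mu for characteristic length L in metres.

    For a falling ovule, L defaults by convention to the ovule length.
    """
    if not characteristic_length > 0:
        raise InvalidParameterError(
            f"characteristic length must be > 0, got {characteristic_length!r}"
        )
    return air.density * air.velocity * characteristic_length / air.dynamic_viscosity


def in_inertial_regime(re: float) -> bool:
    """True when Re lies in the inertia-dominated 1e3–1e4 band (inclusive)."""
    return INERTIAL_RE_MIN <= re <= INERTIAL_RE_MAX
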