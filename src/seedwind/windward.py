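"""Windward-area model for an autorotating winged diaspore.

An ovule or seed with ``n`` wings attached radially and symmetrically
around its long axis spins as it falls.  At rotation angle ``theta``
(the angle between the airflow and a reference wing, measured in the
rotation plane) the wings present a combined projected area ``S(theta)``
to the flow.  Because the body shadows the far side of the rotor, at
most two wings contribute at any instant: ``S(theta)`` is the per-wing
maximum area ``swing`` times the sum of the two largest values of
``|sin(azimuth)|`` over the ``n`` wing azimuths (for a single wing, the
one value).  This rule yields the classical per-count closed forms

* ``n = 1``:  ``S = swing * |sin(theta)|``
* ``n = 2``:  ``S = 2 * swing * |sin(theta)|``
* ``n = 3``:  ``S = sqrt(3) * swing * cos(pi/3 - theta)`` on ``[pi/6, pi/3]``
* ``n = 4``:  ``S = 2 * swing * max(|sin(theta)|, |cos(theta)|)``

and extrapolates them to any wing count.

The dispersal-relevant quantity is the windward area accumulated over
one full rotation, ``D = integral of S over [0, 2*pi]``, compared with a
non-rotating control that keeps its wings facing the wind.  Their ratio
is the relative efficiency ``Er``; the windward *stability* ``min S /
max S`` is a second figure of merit, largest for three wings.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "DiasporeRotor",
    "WindwardSeries",
    "EfficiencyResult",
    "EvaluationMethod",
    "InvalidParameterError",
    "UnsupportedClosedFormError",
    "wing_projection_angles",
    "windward_area",
    "windward_series",
    "fundamental_period",
    "accumulated_windward",
    "control_accumulated",
    "relative_efficiency",
    "windward_stability",
    "windward_range",
    "efficiency_report",
]

TWO_PI = 2.0 * math.pi


class InvalidParameterError(ValueError):
    """A model parameter violates its physical domain."""


class UnsupportedClosedFormError(ValueError):
    """No closed-form accumulated area exists for this wing count."""


class EvaluationMethod(str, enum.Enum):
    CLOSED_FORM = "closed_form"
    QUADRATURE = "quadrature"


@dataclass(frozen=True)
class DiasporeRotor:
    """An idealised rotating diaspore.

    Parameters
    ----------
    n
        Number of wings, >= 1.
    swing
        Maximum windward area of a single wing (any area unit); all
        returned areas are proportional to it.
    r
        Wing-tip-to-axis distance in mm.  Descriptive only: it appears
        in morphological accounts of the rotor but in none of the
        windward formulas, so it is stored and never used.
    """

    n: int
    swing: float = 1.0
    r: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise InvalidParameterError(f"wing count n must be an integer >= 1, got {self.n!r}")
        if not self.swing > 0:
            raise InvalidParameterError(f"swing must be > 0, got {self.swing!r}")
        if self.r is not None and not self.r > 0:
            raise InvalidParameterError(f"tip radius r must be > 0 when given, got {self.r!r}")


@dataclass(frozen=True)
class WindwardSeries:
    """Sampled windward area S(theta) for one rotor."""

    thetas: np.ndarray
    values: np.ndarray
    rotor: DiasporeRotor


@dataclass(frozen=True)
class EfficiencyResult:
    """Cycle-accumulated windward areas and relative efficiency for one rotor.

    ``d_rotating`` and ``d_control`` are in swing·radian units;
    ``er = d_rotating / d_control`` is a dimensionless fraction in (0, 1].
    """

    n: int
    d_rotating: float
    d_control: float
    er: float
    method: EvaluationMethod
    extrapolated: bool = field(default=False)

    @property
    def er_percent(self) -> float:
        return 100.0 * self.er


def wing_projection_angles(n: int, theta: float) -> list[float]:
    """Azimuths of the ``n`` radially symmetric wings at rotation angle ``theta``.

    Returns ``theta + 2*pi*k/n`` for ``k = 0..n-1``, reduced mod ``2*pi``.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InvalidParameterError(f"wing count n must be an integer >= 1, got {n!r}")
    if not math.isfinite(theta):
        raise InvalidParameterError(f"theta must be finite, got {theta!r}")
    return [(theta + TWO_PI * k / n) % TWO_PI for k in range(n)]


def _projection_sum(n: int, theta: np.ndarray) -> np.ndarray:
    """Sum of the two largest |sin| wing projections (one for n = 1)."""
    k = np.arange(n)[:, None]
    p = np.abs(np.sin(np.asarray(theta, dtype=float)[None, :] + TWO_PI * k / n))
    if n == 1:
        return p[0]
    # top-2 via partition along the wing axis
    top2 = np.partition(p, n - 2, axis=0)[n - 2 :, :]
    return top2.sum(axis=0)


def windward_area(rotor: DiasporeRotor, theta):
    """Windward area S(theta) for the rotor, in the units of ``rotor.swing``.

    Accepts a scalar or array ``theta`` (radians); angles are reduced
    internally, so any finite value is valid.
    """
    arr = np.atleast_1d(np.asarray(theta, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("theta must be finite")
    out = rotor.swing * _projection_sum(rotor.n, arr)
    return float(out[0]) if np.isscalar(theta) or np.ndim(theta) == 0 else out


def windward_series(rotor: DiasporeRotor, thetas: Sequence[float] | np.ndarray) -> WindwardSeries:
    """Evaluate S(theta) on an ordered grid of angles."""
    thetas = np.asarray(thetas, dtype=float)
    return WindwardSeries(thetas=thetas, values=windward_area(rotor, thetas), rotor=rotor)


def fundamental_period(n: int) -> float:
    """Fundamental period of S(theta): pi for n = 1, 2*pi/n for even n, pi/n for odd n.

    The absolute value in the projection halves the naive ``2*pi/n``
    rotational period for odd wing counts.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InvalidParameterError(f"wing count n must be an integer >= 1, got {n!r}")
    if n % 2 == 0:
        return TWO_PI / n
    return math.pi / n


#: Closed-form accumulated windward area over a full cycle, per unit swing.
_CLOSED_FORM_D = {
    1: 4.0,
    2: 8.0,
    3: 6.0 * math.sqrt(3.0),
    4: 8.0 * math.sqrt(2.0),
}


def _breakpoints(n: int) -> np.ndarray:
    """Kink points of S(theta) on [0, 2*pi].

    The wing-ranking switchovers and the |sin| folds all fall on integer
    multiples of pi/(2n).
    """
    return np.linspace(0.0, TWO_PI, 4 * n + 1)


def accumulated_windward(rotor: DiasporeRotor, method: EvaluationMethod | str = EvaluationMethod.CLOSED_FORM) -> float:
    """Windward area accumulated over one full rotation, D = ∫₀^{2π} S(θ) dθ.

    ``closed_form`` is exact and available for n in {1, 2, 3, 4}
    (4, 8, 6√3 and 8√2 per unit swing); ``quadrature`` integrates the
    projection rule piecewise between its kink points for any n and
    agrees with the closed forms to better than 1e-9 relative.
    """
    method = EvaluationMethod(method)
    if method is EvaluationMethod.CLOSED_FORM:
        if rotor.n not in _CLOSED_FORM_D:
            raise UnsupportedClosedFormError(
                f"no closed form for n={rotor.n}; use method='quadrature'"
            )
        return _CLOSED_FORM_D[rotor.n] * rotor.swing
    pts = _breakpoints(rotor.n)
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        val, _ = integrate.quad(
            lambda t: _projection_sum(rotor.n, np.array([t]))[0],
            a,
            b,
            epsabs=1e-12,
            epsrel=1e-12,
        )
        total += val
    return total * rotor.swing


def control_accumulated(n: int, swing: float) -> float:
    """Accumulated windward area of the non-rotating facing-wind control.

    The control presents one full wing for n = 1 and two for n >= 2
    over the whole cycle: ``2*pi*swing*min(n, 2)``.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InvalidParameterError(f"wing count n must be an integer >= 1, got {n!r}")
    if not swing > 0:
        raise InvalidParameterError(f"swing must be > 0, got {swing!r}")
    return TWO_PI * swing * min(int(n), 2)


def relative_efficiency(rotor: DiasporeRotor, method: EvaluationMethod | str = "auto") -> EfficiencyResult:
    """Relative wind-dispersal efficiency Er of the rotating diaspore.

    ``Er = D_rotating / D_control``, a fraction in (0, 1].  With
    ``method="auto"`` the closed form is used for n <= 4 and quadrature
    beyond; results for n >= 5 extrapolate the projection rule and are
    flagged as such.
    """
    if method == "auto":
        method = (
            EvaluationMethod.CLOSED_FORM if rotor.n in _CLOSED_FORM_D else EvaluationMethod.QUADRATURE
        )
    method = EvaluationMethod(method)
    d_rot = accumulated_windward(rotor, method)
    d_ctl = control_accumulated(rotor.n, rotor.swing)
    return EfficiencyResult(
        n=rotor.n,
        d_rotating=d_rot,
        d_control=d_ctl,
        er=d_rot / d_ctl,
        method=method,
        extrapolated=rotor.n > 4,
    )


def windward_range(rotor: DiasporeRotor) -> tuple[float, float]:
    """(min, max) of S(theta) over one fundamental period.

    On each smooth piece between kink points the projection sum is a
    single sinusoid, so piece extrema are located by bounded scalar
    optimisation and combined with the kink values.
    """
    n = rotor.n
    period = fundamental_period(n)
    pts = [t for t in _breakpoints(n) if t <= period + 1e-15]
    if pts[-1] < period:
        pts.append(period)
    f = lambda t: _projection_sum(n, np.array([t]))[0]
    lo = min(f(t) for t in pts)
    hi = max(f(t) for t in pts)
    for a, b in zip(pts[:-1], pts[1:]):
        res_min = optimize.minimize_scalar(f, bounds=(a, b), method="bounded", options={"xatol": 1e-10})
        res_max = optimize.minimize_scalar(lambda t: -f(t), bounds=(a, b), method="bounded", options={"xatol": 1e-10})
        lo = min(lo, float(res_min.fun))
        hi = max(hi, float(-res_max.fun))
    if lo < 1e-12:  # edge-on zeros evaluate through floating-point sin
        lo = 0.0
    return lo * rotor.swing, hi * rotor.swing


def windward_stability(rotor: DiasporeRotor) -> float:
    """Windward stability ratio min S / max S over one period, in [0, 1].

    A quantitative proxy for motion stability during autorotation: a
    rotor whose projected area never collapses (ratio near 1) spins
    steadily.  Three wings maximise it (sqrt(3)/2 ~ 0.866) ahead of four
    (sqrt(2)/2 ~ 0.707); one and two wings pass edge-on through zero.
    """
    lo, hi = windward_range(rotor)
    return lo / hi


def efficiency_report(rotor: DiasporeRotor, method: EvaluationMethod | str = "auto") -> dict:
    """JSON-ready efficiency summary for one rotor."""
    res = relative_efficiency(rotor, method)
    return {
        "n": res.n,
        "D_rotating": res.d_rotating,
        "D_control": res.d_control,
        "Er_percent": res.er_percent,
        "method": res.method.value,
        "stability": windward_stability(rotor),
    }
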