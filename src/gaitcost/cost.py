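"""Metabolic cost model of straight-bout and circle walking.

Walking steadily at speed ``v`` costs a metabolic rate (per unit body mass)

    Edot(v) = a0 + a1*v + a2*v**2        [W/kg]

with coefficients that differ between adults without amputation and adults
with a below-knee (transtibial) or above-knee (transfemoral) amputation.
A short straight bout of length ``D`` walked at speed ``v`` additionally pays
for speeding up from rest and slowing back down; that start-stop cost is
modelled as the kinetic-energy change ``v**2 / 2`` scaled by the reciprocal
muscle efficiencies for positive and negative work and by a dimensionless
factor ``a_change``.  Walking a circle of radius ``R`` at tangential speed
``v`` pays an extra turning rate ``a_turn * (v/R)**2``.

Minimising total cost over speed yields the energy-optimal speed for each
task: an implicit cubic condition for straight bouts (solved by bisection)
and a closed form for circles.  All costs are per unit body mass, so subject
mass never enters these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "CostCoefficients",
    "EfficiencyParams",
    "SpeedBand",
    "steady_rate",
    "bout_total_cost",
    "optimal_speed_straight",
    "circle_cost_per_distance",
    "optimal_speed_circle",
    "near_optimal_band",
]

#: groups the coefficient tables distinguish
GROUPS = ("above_knee", "below_knee", "none")


@dataclass(frozen=True)
class CostCoefficients:
    """The five cost-model parameters for one population group.

    Parameters
    ----------
    a0, a1, a2 :
        Steady-rate coefficients, ``Edot = a0 + a1*v + a2*v**2`` in W/kg
        with ``v`` in m/s.  ``a1`` may be negative; ``a0`` and ``a2`` must
        be positive so the cost per distance is U-shaped.
    a_change :
        Dimensionless scaling on the start-stop (changing-speed) work cost.
    a_turn :
        Turning cost coefficient, W/kg per (1/s)^2; multiplies ``(v/R)**2``.
    group_label :
        One of ``"above_knee"``, ``"below_knee"``, ``"none"``.
    """

    a0: float
    a1: float
    a2: float
    a_change: float = 0.0
    a_turn: float = 0.0
    group_label: str = "none"

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError(f"a0 must be positive, got {self.a0}")
        if self.a2 <= 0:
            raise ValueError(f"a2 must be positive, got {self.a2}")
        if self.a_change < 0:
            raise ValueError(f"a_change must be non-negative, got {self.a_change}")
        if self.a_turn < 0:
            raise ValueError(f"a_turn must be non-negative, got {self.a_turn}")
        if self.group_label not in GROUPS:
            raise ValueError(
                f"group_label must be one of {GROUPS}, got {self.group_label!r}"
            )

    @property
    def v_max(self) -> float:
        """Upper bound sqrt(a0/a2) on both optimal speeds, m/s."""
        return float(np.sqrt(self.a0 / self.a2))

    def replace(self, **changes) -> "CostCoefficients":
        return replace(self, **changes)


@dataclass(frozen=True)
class EfficiencyParams:
    """Muscle efficiencies for positive and negative mechanical work.

    ``k = 1/eta_pos + 1/eta_neg`` converts a kinetic-energy change into
    metabolic energy (accelerate with positive work, decelerate with
    negative work).
    """

    eta_pos: float = 0.25
    eta_neg: float = 1.2

    def __post_init__(self) -> None:
        if self.eta_pos <= 0 or self.eta_neg <= 0:
            raise ValueError("efficiencies must be positive")

    @property
    def k(self) -> float:
        return 1.0 / self.eta_pos + 1.0 / self.eta_neg


@dataclass(frozen=True)
class SpeedBand:
    """Interval of speeds whose cost is within ``fraction`` of the minimum."""

    v_opt: float
    v_lo: float
    v_hi: float
    fraction: float = 0.01
    open_upper: bool = False

    def __post_init__(self) -> None:
        if not (self.v_lo <= self.v_opt <= self.v_hi):
            raise ValueError("band must contain v_opt")

    def contains(self, v: float) -> bool:
        return self.v_lo <= v <= self.v_hi


def steady_rate(coeffs: CostCoefficients, v):
    """Steady-state metabolic rate at speed ``v``, W/kg.

    Accepts scalar or array ``v``; negative speeds are rejected.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("speed must be non-negative")
    out = coeffs.a0 + coeffs.a1 * v + coeffs.a2 * v**2
    return float(out) if out.ndim == 0 else out


def bout_total_cost(
    coeffs: CostCoefficients, eff: EfficiencyParams, D: float, v
):
    """Total cost of a rest-to-rest straight bout of length ``D``, J/kg.

    steady term ``Edot(v) * D / v`` plus start-stop term
    ``a_change * k * v**2 / 2``.  Diverges as v -> 0+.
    """
    if D <= 0:
        raise ValueError("distance must be positive")
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("speed must be positive (cost diverges at v = 0)")
    out = steady_rate(coeffs, v) * D / v + coeffs.a_change * eff.k * v**2 / 2.0
    return float(out) if np.ndim(out) == 0 else out


def circle_cost_per_distance(coeffs: CostCoefficients, v, R: float):
    """Cost per distance walking a circle of radius ``R`` at speed ``v``, J/kg/m.

    ``a0/v + a1 + a2*v + a_turn*v/R**2``.
    """
    if R <= 0:
        raise ValueError("radius must be positive")
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("speed must be positive")
    out = coeffs.a0 / v + coeffs.a1 + coeffs.a2 * v + coeffs.a_turn * v / R**2
    return float(out) if np.ndim(out) == 0 else out


def _vopt_straight_bisect(a0, a2, a_change, k, D, tol=1e-10, max_iter=100):
    """Vectorised bisection for the optimal straight-bout speed.

    Solves ``a_change * k * v**3 / (a0 - a2 v**2) = D`` for
    ``v in (0, sqrt(a0/a2))``; the left side is monotone increasing on that
    interval so the bracket is guaranteed.  Broadcasts over all arguments.
    Entries with ``a_change == 0`` return ``sqrt(a0/a2)`` exactly.
    """
    a0, a2, a_change, D = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (a0, a2, a_change, D))
    )
    vmax = np.sqrt(a0 / a2)
    degenerate = a_change == 0
    lo = np.full(a0.shape, 1e-9)
    hi = vmax - 1e-12
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        lhs = a_change * k * mid**3 / (a0 - a2 * mid**2)
        too_low = lhs < D
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.all(hi - lo < tol):
            break
    v = 0.5 * (lo + hi)
    return np.where(degenerate, vmax, v)


def optimal_speed_straight(
    coeffs: CostCoefficients, eff: EfficiencyParams, D
) -> float:
    """Energy-optimal speed for a rest-to-rest straight bout of length ``D``.

    Root of ``a_change * v**3 * (1/eta_pos + 1/eta_neg) / (a0 - a2 v**2) = D``
    on ``(0, sqrt(a0/a2))``, found by bisection (absolute tolerance 1e-10 on
    v).  With ``a_change = 0`` the condition degenerates and the minimiser of
    the steady cost per distance, ``sqrt(a0/a2)``, is returned analytically.
    Strictly increasing in ``D`` and bounded above by ``sqrt(a0/a2)``.
    """
    D_arr = np.asarray(D, dtype=float)
    if np.any(D_arr <= 0):
        raise ValueError("distance must be positive")
    v = _vopt_straight_bisect(coeffs.a0, coeffs.a2, coeffs.a_change, eff.k, D_arr)
    return float(v) if v.ndim == 0 else v


def optimal_speed_circle(coeffs: CostCoefficients, R) -> float:
    """Energy-optimal tangential speed on a circle of radius ``R``.

    Closed form ``sqrt(a0 / (a2 + a_turn / R**2))``: strictly increasing in
    ``R`` and approaching the straight-line optimum ``sqrt(a0/a2)`` as the
    radius grows.
    """
    R_arr = np.asarray(R, dtype=float)
    if np.any(R_arr <= 0):
        raise ValueError("radius must be positive")
    v = np.sqrt(coeffs.a0 / (coeffs.a2 + coeffs.a_turn / R_arr**2))
    return float(v) if v.ndim == 0 else v


def near_optimal_band(
    cost_curve: Callable[[float], float],
    v_opt: float,
    fraction: float = 0.01,
    v_max: float | None = None,
    tol: float = 1e-10,
) -> SpeedBand:
    """Speeds whose cost is within ``fraction`` of the minimum of a unimodal curve.

    Finds the two crossings of ``cost(v) = (1 + fraction) * cost(v_opt)`` by
    geometric bracket expansion followed by bisection (tolerance ``tol`` on
    v).  If the cost never exceeds the threshold below ``v_max`` (default
    ``10 * v_opt``), the band is reported open-ended upward with
    ``v_hi = v_max``.
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    c_opt = cost_curve(v_opt)
    if fraction == 0:
        return SpeedBand(v_opt=v_opt, v_lo=v_opt, v_hi=v_opt, fraction=0.0)
    threshold = (1.0 + fraction) * c_opt

    def excess(v):
        return cost_curve(v) - threshold

    # lower side: shrink geometrically toward 0 until above threshold
    lo = v_opt
    step = 0.5
    while excess(lo) < 0:
        lo *= step
        if lo < 1e-12:  # cost stays flat down to ~0 speed: degenerate curve
            lo = 1e-12
            break
    v_lo = _bisect_scalar(excess, lo, v_opt, tol) if excess(lo) >= 0 else lo

    # upper side: expand geometrically until above threshold or v_max
    if v_max is None:
        v_max = 10.0 * v_opt
    hi = v_opt
    open_upper = False
    while True:
        hi = min(hi * 2.0, v_max)
        if excess(hi) >= 0:
            break
        if hi >= v_max:
            open_upper = True
            break
    if open_upper:
        v_hi = v_max
    else:
        v_hi = _bisect_scalar(excess, v_opt, hi, tol)
    return SpeedBand(
        v_opt=v_opt, v_lo=v_lo, v_hi=v_hi, fraction=fraction, open_upper=open_upper
    )


def _bisect_scalar(f, a, b, tol):
    """Bisection for a sign change of f on [a, b]; f(a), f(b) opposite signs
    (one side may sit exactly on zero)."""
    fa = f(a)
    if fa == 0:
        return a
    sign_a = fa > 0
    for _ in range(200):
        mid = 0.5 * (a + b)
        fm = f(mid)
        if (fm > 0) == sign_a:
            a = mid
        else:
            b = mid
        if b - a < tol:
            break
    return 0.5 * (a + b)
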