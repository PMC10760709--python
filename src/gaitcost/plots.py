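"""Optional static figures: model-vs-data speed curves with 1% cost bands.

Requires matplotlib (``pip install gaitcost[plot]``); imported lazily so the
rest of the package has no plotting dependency.
"""

from __future__ import annotations

import numpy as np

from .cost import CostCoefficients, EfficiencyParams, bout_total_cost, \
    circle_cost_per_distance, near_optimal_band, optimal_speed_circle, \
    optimal_speed_straight


def plot_speed_vs_distance(coeffs: CostCoefficients, eff: EfficiencyParams,
                           observed=None, distances=None, ax=None):
    """Optimal speed and 1% band against bout distance; ``observed`` maps
    distance -> group-mean speed."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    D = np.asarray(distances if distances is not None
                   else np.linspace(2.0, 25.0, 60))
    v = np.array([optimal_speed_straight(coeffs, eff, d) for d in D])
    lo, hi = [], []
    for d, vo in zip(D, v):
        band = near_optimal_band(lambda s: bout_total_cost(coeffs, eff, d, s), vo)
        lo.append(band.v_lo)
        hi.append(band.v_hi)
    ax.fill_between(D, lo, hi, alpha=0.25, label="within 1% of min cost")
    ax.plot(D, v, label="optimal speed")
    if observed:
        ax.plot(list(observed), list(observed.values()), "o", label="observed")
    ax.set_xlabel("bout distance (m)")
    ax.set_ylabel("speed (m/s)")
    ax.set_title(f"straight bouts, {coeffs.group_label}")
    ax.legend()
    return ax


def plot_speed_vs_radius(coeffs: CostCoefficients, observed=None,
                         radii=None, ax=None):
    """Optimal tangential speed and 1% band against circle radius."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    R = np.asarray(radii if radii is not None else np.linspace(0.5, 4.0, 60))
    v = np.array([optimal_speed_circle(coeffs, r) for r in R])
    lo, hi = [], []
    for r, vo in zip(R, v):
        band = near_optimal_band(
            lambda s: circle_cost_per_distance(coeffs, s, r), vo)
        lo.append(band.v_lo)
        hi.append(band.v_hi)
    ax.fill_between(R, lo, hi, alpha=0.25, label="within 1% of min cost")
    ax.plot(R, v, label="optimal speed")
    if observed:
        ax.plot(list(observed), list(observed.values()), "o", label="observed")
    ax.set_xlabel("circle radius (m)")
    ax.set_ylabel("tangential speed (m/s)")
    ax.set_title(f"circle walking, {coeffs.group_label}")
    ax.legend()
    return ax
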