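"""Inverse optimization of walking cost coefficients from preferred speeds.

The observable is a table of timed trials: straight rest-to-rest bouts of
known distance and multi-lap circle trials of known radius.  Under the
energy-optimality hypothesis, a subject's preferred speed in each condition
is the minimiser of the cost model for that condition, so the model's free
coefficients can be estimated by minimising the mean squared error (MSE)
between model-optimal and observed speeds, pooled over all straight and
circle trials of one amputation group.

Two fit versions are supported.  Version 1 holds the literature steady-rate
coefficients (a0, a1, a2) fixed and estimates (a_change, a_turn).  Version 2
additionally frees a2, which shifts both task predictions.  a0 and a1 are
never fit: the optimal speeds are invariant to a1 and to rescaling all
coefficients by a common factor, so a0 merely sets the scale.

The MSE surface is minimised with Nelder-Mead simplex restarts on
log-transformed coefficients (enforcing non-negativity), and the optimum is
validated against a fine parameter grid: because a_change enters only the
straight-bout predictions and a_turn only the circle predictions, the grid
SSE separates as ``SSE(a2, a_change, a_turn) = SSE_straight(a2, a_change) +
SSE_circle(a2, a_turn)`` and the exhaustive grid minimum is computed
exactly without materialising the full 3-D product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cost import (
    CostCoefficients,
    EfficiencyParams,
    optimal_speed_circle,
    optimal_speed_straight,
    _vopt_straight_bisect,
)
from . import reference

__all__ = [
    "FitSpec",
    "IdentifiabilityError",
    "PreferredSpeedModel",
    "InverseOptResults",
    "predict_speeds",
    "mse",
    "fit",
    "grid_validate",
    "DEFAULT_GRIDS",
]

#: default validation grids per free coefficient: (min, max, fine step)
DEFAULT_GRIDS: dict[str, tuple[float, float, float]] = {
    "a_change": (0.0, 10.0, 0.01),
    "a_turn": (0.0, 20.0, 0.02),
    "a2": (0.5, 10.0, 0.01),
}

_FREE_BY_VERSION = {1: ("a_change", "a_turn"), 2: ("a2", "a_change", "a_turn")}


class IdentifiabilityError(ValueError):
    """A free coefficient has no trials that constrain it."""


@dataclass(frozen=True)
class FitSpec:
    """What to fit: version, group, fixed coefficients, starts and grids."""

    version: int
    group_label: str
    fixed_coeffs: CostCoefficients
    start_points: tuple = ()
    grids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.version not in _FREE_BY_VERSION:
            raise ValueError(f"version must be 1 or 2, got {self.version}")

    @property
    def free_names(self) -> tuple[str, ...]:
        return _FREE_BY_VERSION[self.version]

    @classmethod
    def for_group(cls, group: str, version: int = 1, **kwargs) -> "FitSpec":
        """Spec with the literature steady-rate coefficients for ``group``."""
        base = reference.coefficients(group, version=None)
        return cls(version=version, group_label=group, fixed_coeffs=base,
                   **kwargs)


def predict_speeds(
    coeffs: CostCoefficients,
    eff: EfficiencyParams,
    trials: pd.DataFrame,
) -> np.ndarray:
    """Model-optimal speed for every trial row, in input order.

    Straight rows (finite ``distance_m``) use the implicit straight-bout
    optimum; circle rows (finite ``radius_m``) use the closed-form circle
    optimum.  Rows with neither are rejected.
    """
    if len(trials) == 0:
        return np.empty(0)
    D = pd.to_numeric(trials.get("distance_m"), errors="coerce").to_numpy(float)
    R = pd.to_numeric(trials.get("radius_m"), errors="coerce").to_numpy(float)
    is_straight = np.isfinite(D)
    is_circle = np.isfinite(R) & ~is_straight
    bad = ~(is_straight | is_circle)
    if bad.any():
        raise ValueError(
            f"trial rows {list(trials.index[bad])} have neither a distance "
            "nor a radius"
        )
    out = np.empty(len(trials))
    if is_straight.any():
        # solve once per unique distance
        uD, inv = np.unique(D[is_straight], return_inverse=True)
        v = np.atleast_1d(optimal_speed_straight(coeffs, eff, uD))
        out[is_straight] = v[inv]
    if is_circle.any():
        uR, inv = np.unique(R[is_circle], return_inverse=True)
        v = np.atleast_1d(optimal_speed_circle(coeffs, uR))
        out[is_circle] = v[inv]
    return out


def mse(
    coeffs: CostCoefficients,
    eff: EfficiencyParams,
    trials: pd.DataFrame,
) -> float:
    """Mean squared error between model-optimal and observed trial speeds,
    pooled over straight and circle trials."""
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    if "speed_m_s" not in trials.columns or trials["speed_m_s"].isna().any():
        raise ValueError("every trial needs an observed speed (speed_m_s)")
    pred = predict_speeds(coeffs, eff, trials)
    obs = trials["speed_m_s"].to_numpy(float)
    return float(np.mean((pred - obs) ** 2))


# ---------------------------------------------------------------------------
# sufficient statistics: SSE against a condition prediction only needs the
# per-condition count, sum and sum of squares of observed speeds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Moments:
    values: np.ndarray  # unique condition values (distances or radii)
    n: np.ndarray
    s: np.ndarray
    q: np.ndarray

    @classmethod
    def from_trials(cls, cond: np.ndarray, obs: np.ndarray) -> "_Moments":
        u, inv = np.unique(cond, return_inverse=True)
        n = np.bincount(inv).astype(float)
        s = np.bincount(inv, weights=obs)
        q = np.bincount(inv, weights=obs**2)
        return cls(values=u, n=n, s=s, q=q)

    def sse(self, vhat: np.ndarray) -> np.ndarray:
        """Sum over conditions of SSE given predictions ``vhat`` with the
        condition axis last; broadcasts over leading grid axes.  Clamped at
        zero against floating cancellation on near-perfect fits."""
        sse = np.sum(self.n * vhat**2 - 2.0 * self.s * vhat + self.q, axis=-1)
        return np.maximum(sse, 0.0)


def _split_moments(trials: pd.DataFrame) -> tuple[_Moments | None, _Moments | None]:
    D = pd.to_numeric(trials.get("distance_m"), errors="coerce").to_numpy(float)
    R = pd.to_numeric(trials.get("radius_m"), errors="coerce").to_numpy(float)
    obs = trials["speed_m_s"].to_numpy(float)
    is_straight = np.isfinite(D)
    is_circle = np.isfinite(R) & ~is_straight
    ms = _Moments.from_trials(D[is_straight], obs[is_straight]) if is_straight.any() else None
    mc = _Moments.from_trials(R[is_circle], obs[is_circle]) if is_circle.any() else None
    return ms, mc


class PreferredSpeedModel:
    """Energy-optimality model of preferred walking speeds for one group.

    Parameters
    ----------
    trials :
        Trial table (one amputation group) with observed ``speed_m_s``.
    spec :
        :class:`FitSpec`; or use ``group``/``version`` shortcuts.
    eff :
        Muscle work efficiencies; defaults to (0.25, 1.2).

    Examples
    --------
    >>> model = PreferredSpeedModel.from_dataset(cohort, group="above_knee",
    ...                                          version=2)
    >>> res = model.fit()
    >>> res.params  # fitted a2, a_change, a_turn   # doctest: +SKIP
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        spec: FitSpec | None = None,
        group: str = "above_knee",
        version: int = 1,
        eff: EfficiencyParams | None = None,
    ) -> None:
        if spec is None:
            spec = FitSpec.for_group(group, version=version)
        self.spec = spec
        self.eff = eff or EfficiencyParams()
        self.trials = trials.reset_index(drop=True)
        if "speed_m_s" not in self.trials.columns:
            raise ValueError("trials must carry observed speed_m_s")
        self._ms, self._mc = _split_moments(self.trials)
        self._check_identifiability()

    @classmethod
    def from_dataset(cls, dataset, group: str, version: int = 1,
                     eff: EfficiencyParams | None = None,
                     spec: FitSpec | None = None) -> "PreferredSpeedModel":
        """Build from a :class:`~gaitcost.data.CohortDataset`, selecting the
        trials of subjects in ``group``."""
        trials = dataset.trials_for_group(group)
        if spec is None:
            spec = FitSpec.for_group(group, version=version)
        return cls(trials, spec=spec, eff=eff)

    # -- plumbing -----------------------------------------------------------
    def _check_identifiability(self) -> None:
        free = self.spec.free_names
        if "a_turn" in free and self._mc is None:
            raise IdentifiabilityError(
                "a_turn is free but there are no circle trials"
            )
        if "a_change" in free and self._ms is None:
            raise IdentifiabilityError(
                "a_change is free but there are no straight trials"
            )

    @property
    def nobs(self) -> int:
        return len(self.trials)

    def _coeffs_at(self, free_values: dict[str, float]) -> CostCoefficients:
        return self.spec.fixed_coeffs.replace(
            group_label=self.spec.group_label, **free_values
        )

    def _mse_at(self, free_values: dict[str, float]) -> float:
        """Fast MSE via the per-condition sufficient statistics."""
        c = self._coeffs_at(free_values)
        sse = 0.0
        if self._ms is not None:
            vhat = _vopt_straight_bisect(
                c.a0, c.a2, c.a_change, self.eff.k, self._ms.values
            )
            sse += float(self._ms.sse(vhat))
        if self._mc is not None:
            vhat = np.sqrt(c.a0 / (c.a2 + c.a_turn / self._mc.values**2))
            sse += float(self._mc.sse(vhat))
        return sse / self.nobs

    def _default_starts(self) -> list[np.ndarray]:
        """Start points spanning the validation grids (log-space fitting
        needs strictly positive starts)."""
        by_name = {
            "a2": [self.spec.fixed_coeffs.a2, 1.0, 3.0, 6.0, 9.0],
            "a_change": [0.3, 1.3, 2.7, 5.0, 9.0],
            "a_turn": [0.5, 1.1, 6.6, 12.0, 19.0],
        }
        return [np.array([by_name[n][i] for n in self.spec.free_names])
                for i in range(5)]

    # -- estimation ---------------------------------------------------------
    def fit(
        self,
        start_points=None,
        validate_grid: bool = True,
        grids: dict | None = None,
    ) -> "InverseOptResults":
        """Minimise the pooled MSE over the free coefficients.

        Runs a Nelder-Mead simplex search on log-coefficients from every
        start point and keeps the best minimum; then (by default) validates
        it against the exhaustive fine-grid minimum.
        """
        free = self.spec.free_names
        starts = list(start_points or self.spec.start_points or
                      self._default_starts())
        best = None
        start_results = []
        for x0 in starts:
            x0 = np.asarray(x0, dtype=float)
            if np.any(x0 <= 0):
                raise ValueError("start points must be strictly positive")
            res = minimize(
                lambda z: self._mse_at(dict(zip(free, np.exp(z)))),
                np.log(x0),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
            )
            start_results.append(
                {"x0": x0.tolist(), "mse": float(res.fun),
                 "converged": bool(res.success),
                 "params": dict(zip(free, np.exp(res.x)))}
            )
            if best is None or res.fun < best.fun:
                best = res
        if not any(r["converged"] for r in start_results):
            warnings.warn("no Nelder-Mead start converged; using best iterate")
        params = dict(zip(free, np.exp(best.x)))
        result = InverseOptResults(
            model=self,
            spec=self.spec,
            params=pd.Series(params, name="estimate"),
            coeffs=self._coeffs_at(params),
            mse=float(best.fun),
            n_trials=self.nobs,
            converged=any(r["converged"] for r in start_results),
            start_results=start_results,
        )
        if validate_grid:
            result = grid_validate(result, grids=grids)
        return result


@dataclass
class InverseOptResults:
    """Results of one inverse-optimization fit.

    ``params`` holds the free coefficient estimates, ``coeffs`` the full
    merged coefficient set, ``mse`` the achieved mean squared speed error in
    (m/s)^2.  After grid validation ``grid_validated`` records whether no
    point of the fine grid beat the optimizer, with the grid's best MSE and
    location attached.
    """

    model: PreferredSpeedModel
    spec: FitSpec
    params: pd.Series
    coeffs: CostCoefficients
    mse: float
    n_trials: int
    converged: bool = True
    grid_validated: bool | None = None
    grid_best_mse: float | None = None
    grid_best_params: dict | None = None
    start_results: list = field(default_factory=list)

    def predict(self, trials: pd.DataFrame | None = None) -> np.ndarray:
        """Model-optimal speeds at the fitted coefficients (defaults to the
        fitted trial table)."""
        if trials is None:
            trials = self.model.trials
        return predict_speeds(self.coeffs, self.model.eff, trials)

    def to_record(self) -> dict:
        """JSON-ready summary record."""
        return {
            "group": self.spec.group_label,
            "version": self.spec.version,
            "free": list(self.spec.free_names),
            "params": {k: float(v) for k, v in self.params.items()},
            "fixed": {"a0": self.coeffs.a0, "a1": self.coeffs.a1,
                      **({} if "a2" in self.spec.free_names
                         else {"a2": self.coeffs.a2})},
            "mse": self.mse,
            "rmse": float(np.sqrt(self.mse)),
            "n_trials": self.n_trials,
            "converged": self.converged,
            "grid_validated": self.grid_validated,
            "grid_best_mse": self.grid_best_mse,
        }

    def summary(self) -> str:
        """Plain-text summary table."""
        lines = [
            "Inverse optimization of walking cost coefficients",
            "=" * 52,
            f"group:           {self.spec.group_label}",
            f"version:         {self.spec.version} "
            f"(free: {', '.join(self.spec.free_names)})",
            f"n trials:        {self.n_trials}",
            f"MSE:             {self.mse:.6g} (m/s)^2",
            f"RMSE:            {np.sqrt(self.mse):.4g} m/s",
            f"grid validated:  {self.grid_validated}",
            "-" * 52,
            f"{'coefficient':<12}{'estimate':>12}  {'status':<8}",
        ]
        for name in ("a0", "a1", "a2", "a_change", "a_turn"):
            status = "free" if name in self.spec.free_names else "fixed"
            lines.append(f"{name:<12}{getattr(self.coeffs, name):>12.4f}  {status:<8}")
        return "\n".join(lines)


def fit(spec: FitSpec, trials: pd.DataFrame,
        eff: EfficiencyParams | None = None, **fit_kwargs) -> InverseOptResults:
    """Functional entry point: fit ``spec`` to a trial table."""
    return PreferredSpeedModel(trials, spec=spec, eff=eff).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# grid validation
# ---------------------------------------------------------------------------

def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _grid_min(model: PreferredSpeedModel, a2_axis, ach_axis, at_axis):
    """Exact minimum of the grid MSE using the separable SSE structure.

    For each a2, the straight SSE depends only on a_change and the circle
    SSE only on a_turn, so ``min over (a_change, a_turn)`` splits into two
    independent 1-D minima.
    """
    c = model.spec.fixed_coeffs
    k = model.eff.k
    n = model.nobs
    best = (np.inf, None)
    # straight SSE on (a2, a_change) grid, circle SSE on (a2, a_turn) grid
    for i, a2 in enumerate(np.atleast_1d(a2_axis)):
        if model._ms is not None and len(ach_axis):
            vhat = _vopt_straight_bisect(
                c.a0, a2, ach_axis[:, None], k, model._ms.values[None, :]
            )
            sse_s = model._ms.sse(vhat)  # (n_ach,)
            j = int(np.argmin(sse_s))
            s_part, ach_best = float(sse_s[j]), float(ach_axis[j])
        else:
            s_part, ach_best = 0.0, None
        if model._mc is not None and len(at_axis):
            vhat = np.sqrt(c.a0 / (a2 + at_axis[:, None] / model._mc.values[None, :] ** 2))
            sse_c = model._mc.sse(vhat)
            j = int(np.argmin(sse_c))
            c_part, at_best = float(sse_c[j]), float(at_axis[j])
        else:
            c_part, at_best = 0.0, None
        total = (s_part + c_part) / n
        if total < best[0]:
            best = (total, {"a2": float(a2), "a_change": ach_best,
                            "a_turn": at_best})
    return best


def grid_validate(
    result: InverseOptResults,
    grids: dict | None = None,
    refine: int = 10,
) -> InverseOptResults:
    """Check the optimizer against an exhaustive fine parameter grid.

    A coarse pass at ``refine`` times the fine step covers the whole grid;
    a second pass at the fine step covers +/- one coarse step around the
    coarse incumbent.  Sets ``grid_validated`` iff the optimizer's MSE is
    at or below the grid minimum (tolerance 1e-12).  If the fitted optimum
    lies outside the grid bounds the validation is inconclusive
    (``grid_validated = None``) with a warning.
    """
    model = result.model
    spec = result.spec
    grids = {**DEFAULT_GRIDS, **(grids or {})}

    free = spec.free_names
    for name in free:
        lo, hi, step = grids[name]
        val = float(result.params[name])
        if not (lo - step <= val <= hi + step):
            warnings.warn(
                f"fitted {name}={val:.4g} outside grid bounds [{lo}, {hi}]; "
                "grid validation inconclusive"
            )
            return replace(result, grid_validated=None)

    def axes(pass_grids):
        a2_ax = (_axis(*pass_grids["a2"]) if "a2" in free
                 else np.array([spec.fixed_coeffs.a2]))
        ach_ax = _axis(*pass_grids["a_change"]) if "a_change" in free else np.array([])
        at_ax = _axis(*pass_grids["a_turn"]) if "a_turn" in free else np.array([])
        return a2_ax, ach_ax, at_ax

    coarse = {n: (lo, hi, st * refine) for n, (lo, hi, st) in grids.items()}
    best_mse, best_at = _grid_min(model, *axes(coarse))

    # refine at the fine step around the coarse incumbent
    fine = {}
    for name in grids:
        lo, hi, st = grids[name]
        center = best_at.get(name) if best_at else None
        if center is None:
            fine[name] = (lo, hi, st)
        else:
            span = st * refine
            fine[name] = (max(lo, center - span), min(hi, center + span), st)
    mse_f, at_f = _grid_min(model, *axes(fine))
    if mse_f < best_mse:
        best_mse, best_at = mse_f, at_f

    return replace(
        result,
        grid_validated=bool(result.mse <= best_mse + 1e-12),
        grid_best_mse=float(best_mse),
        grid_best_params={k: v for k, v in (best_at or {}).items()
                          if k in free},
    )
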