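"""Derringer–Suich desirability functions and multi-response optimization.

Each predicted response y is mapped to an individual desirability
d(y) in [0, 1] by a piecewise power ramp (0 = completely undesirable,
1 = most desirable), and the responses are combined into an overall
desirability D by the (importance-weighted) geometric mean, so that any
single d = 0 vetoes the candidate.  The optimum formulation is the
factor setting maximizing D over the design cube; the search is a
deterministic dense grid scan followed by a local polish, which makes
the result exactly reproducible for a fixed grid density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .design_space import FactorSpec, decode
from .response_surface import FittedModel

__all__ = [
    "DesirabilitySpec",
    "MROResult",
    "InverseTargetResult",
    "individual_desirability",
    "overall_desirability",
    "optimize_mro",
    "inverse_target",
]


@dataclass(frozen=True)
class DesirabilitySpec:
    """Goal for one response.

    ``goal`` is "maximize", "minimize" or "target".  For maximize /
    minimize, ``bounds = (worst, best)`` in response units; for target,
    ``bounds = (low, target, high)``.  ``weight`` shapes the ramp
    (1 = linear) and ``importance`` weights this response in the
    geometric-mean aggregation.
    """

    response: str
    goal: str
    bounds: tuple[float, ...]
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in ("maximize", "minimize", "target"):
            raise ValueError(f"unknown goal {self.goal!r}")
        need = 3 if self.goal == "target" else 2
        if len(self.bounds) != need:
            raise ValueError(f"goal {self.goal!r} needs {need} bounds")
        if self.goal == "target":
            lo, t, hi = self.bounds
            if not (lo < t < hi):
                raise ValueError("target bounds must satisfy low < target < high")
        elif self.bounds[0] == self.bounds[1]:
            raise ValueError("degenerate bounds: worst equals best")
        if self.weight <= 0 or self.importance <= 0:
            raise ValueError("weight and importance must be positive")


def individual_desirability(y, spec: DesirabilitySpec) -> np.ndarray | float:
    """Ramp transform of response values into [0, 1]; vectorized over y."""
    y = np.asarray(y, dtype=float)
    w = spec.weight
    if spec.goal == "maximize":
        worst, best = spec.bounds
        d = np.clip((y - worst) / (best - worst), 0.0, 1.0) ** w
    elif spec.goal == "minimize":
        worst, best = spec.bounds
        # mirrored ramp: 1 at/below best, 0 at/above worst
        d = np.clip((worst - y) / (worst - best), 0.0, 1.0) ** w
    else:
        lo, t, hi = spec.bounds
        up = np.clip((y - lo) / (t - lo), 0.0, 1.0)
        down = np.clip((hi - y) / (hi - t), 0.0, 1.0)
        d = np.where(y <= t, up, down) ** w
    return d if d.ndim else float(d)


def overall_desirability(ds: Sequence[float] | np.ndarray,
                         importances: Sequence[float] | None = None):
    """Importance-weighted geometric mean of individual desirabilities.

    With unit importances this is (d1 * d2 * ... * dm) ** (1/m); any
    zero component forces the result to zero.  Vectorized: each element
    of ``ds`` may be an array of candidate points.
    """
    arrs = [np.asarray(d, dtype=float) for d in ds]
    if not arrs:
        raise ValueError("no desirabilities to combine")
    if importances is None:
        importances = [1.0] * len(arrs)
    if len(importances) != len(arrs):
        raise ValueError("importances must match the number of responses")
    total = float(sum(importances))
    logd = sum(w * np.log(np.maximum(a, 1e-300)) for w, a in zip(importances, arrs))
    D = np.exp(logd / total)
    D = np.where(sum((a == 0) for a in arrs) > 0, 0.0, D)
    return D if D.ndim else float(D)


@dataclass
class MROResult:
    argmax_raw: dict[str, float]
    argmax_coded: dict[str, float]
    overall_D: float
    per_response: dict[str, tuple[float, float]]  # response -> (prediction, d)
    n_evaluated: int
    all_zero: bool = False  # no candidate achieved D > 0


def _coded_grid(factor_names: Sequence[str], density: int) -> dict[str, np.ndarray]:
    axes = np.meshgrid(*[np.linspace(-1.0, 1.0, density)] * len(factor_names),
                       indexing="ij")
    return {name: ax.ravel() for name, ax in zip(factor_names, axes)}


def _evaluate_D(models: Mapping[str, FittedModel], specs: Sequence[DesirabilitySpec],
                coded_point: Mapping[str, np.ndarray]):
    ds, preds = [], {}
    for spec in specs:
        pred = models[spec.response].predict(coded_point, coding="coded")
        preds[spec.response] = pred
        ds.append(individual_desirability(pred, spec))
    D = overall_desirability(ds, [s.importance for s in specs])
    return np.atleast_1d(D), preds


def optimize_mro(models: Mapping[str, FittedModel],
                 specs: Sequence[DesirabilitySpec],
                 grid: int = 41, polish: bool = True) -> MROResult:
    """Maximize overall desirability over the coded design cube.

    Dense ``grid**k`` scan (ties broken toward the first point in the
    deterministic grid order) followed by a bounded Nelder–Mead polish
    from the best cell; the polished point is only accepted when it
    improves on the grid value, so the result never falls below the
    scan's maximum.
    """
    if not specs:
        raise ValueError("no desirability specs")
    missing = [s.response for s in specs if s.response not in models]
    if missing:
        raise KeyError(f"no fitted model for response(s) {missing}")
    factors: list[FactorSpec] = next(iter(models.values())).factors
    names = [f.name for f in factors]

    points = _coded_grid(names, grid)
    D, _ = _evaluate_D(models, specs, points)
    best = int(np.argmax(D))
    x_best = np.array([points[n][best] for n in names])
    d_best = float(D[best])
    n_eval = D.size

    if polish:
        def negD(x):
            pt = {n: np.array([v]) for n, v in zip(names, x)}
            return -float(_evaluate_D(models, specs, pt)[0][0])

        # polish from the best few grid cells (distinct basins), with one
        # restart each, so a single stalled simplex cannot cost the optimum
        top = np.argsort(D)[::-1][:5]
        starts = [np.array([points[n][i] for n in names]) for i in top]
        for x0 in starts:
            res = optimize.minimize(negD, x0, method="Nelder-Mead",
                                    bounds=[(-1.0, 1.0)] * len(names),
                                    options={"xatol": 1e-8, "fatol": 1e-12})
            res = optimize.minimize(negD, res.x, method="Nelder-Mead",
                                    bounds=[(-1.0, 1.0)] * len(names),
                                    options={"xatol": 1e-8, "fatol": 1e-12})
            n_eval += res.nfev
            if -res.fun > d_best:
                x_best, d_best = np.clip(res.x, -1.0, 1.0), float(-res.fun)

    coded = {n: float(v) for n, v in zip(names, x_best)}
    raw = decode(coded, factors)
    point = {n: np.array([v]) for n, v in coded.items()}
    _, preds = _evaluate_D(models, specs, point)
    per = {s.response: (float(preds[s.response][0]),
                        float(individual_desirability(preds[s.response][0], s)))
           for s in specs}
    return MROResult(raw, coded, d_best, per, n_eval, all_zero=d_best == 0.0)


@dataclass
class InverseTargetResult:
    settings_raw: dict[str, float]
    settings_coded: dict[str, float]
    predicted_primary: float
    predicted_secondary: float
    feasible: bool  # primary within tolerance of the target


def inverse_target(models: Mapping[str, FittedModel],
                   primary: tuple[str, float],
                   secondary: tuple[str, str],
                   grid: int = 41, rel_tol: float = 0.01) -> InverseTargetResult:
    """Hit a target value of one response while optimizing another.

    Scans the coded cube; among points whose predicted primary response
    lies within ``rel_tol`` (relative) of the target, returns the one
    with the best secondary response.  If no grid point meets the
    tolerance, the nearest-achievable point is returned with
    ``feasible=False``.
    """
    p_resp, target = primary
    s_resp, s_goal = secondary
    if s_goal not in ("minimize", "maximize"):
        raise ValueError("secondary goal must be minimize or maximize")
    factors = models[p_resp].factors
    names = [f.name for f in factors]
    points = _coded_grid(names, grid)
    pred_p = models[p_resp].predict(points, coding="coded")
    pred_s = models[s_resp].predict(points, coding="coded")
    feasible_mask = np.abs(pred_p - target) <= rel_tol * abs(target)
    if feasible_mask.any():
        idx = np.flatnonzero(feasible_mask)
        s_vals = pred_s[idx]
        best = idx[int(np.argmin(s_vals) if s_goal == "minimize"
                       else np.argmax(s_vals))]
        feasible = True
    else:
        best = int(np.argmin(np.abs(pred_p - target)))
        feasible = False
    coded = {n: float(points[n][best]) for n in names}
    raw = decode(coded, factors)
    return InverseTargetResult(raw, coded, float(pred_p[best]),
                               float(pred_s[best]), feasible)
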