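"""Fluence-map optimization with prioritized dose-volume objectives.

The decision variable is a vector of nonnegative per-beamlet fluence
weights.  The objective is a weighted sum of one-sided quadratic
penalties evaluated on ``d = s * (M @ x) + base``, where ``M`` is the
simplified-engine dose-influence matrix, ``base`` an optional fixed
base-dose grid (the mechanism behind base-dose re-optimization) and
``s`` a dose scale (1 for a stand-alone plan, 0.5 when the plan under
optimization delivers half the course on top of a half-course base).

Penalty kinds
-------------
max_dose / min_dose
    mean over the structure of ``relu(d - L)**2`` / ``relu(L - d)**2``.
max_dvh(L, V%) / min_dvh(L, V%)
    classic dose-volume penalty: only the excess voxels nearest the
    threshold are penalized, re-selected every iteration.
mean_dose
    one-sided upper bound on the structure mean.

Each term is normalized by its structure's voxel count so weights are
comparable across structures of very different size.  The solver is
projected gradient descent with backtracking (Armijo) line search and a
nonnegativity projection; it is deterministic for a given problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose import DoseInfluenceMatrix

__all__ = [
    "Objective",
    "OptimizationProblem",
    "FluenceMap",
    "evaluate_objective",
    "objective_value_and_gradient",
    "optimize",
]

_KINDS = ("max_dose", "min_dose", "max_dvh", "min_dvh", "mean_dose")


@dataclass(frozen=True)
class Objective:
    """One dose or dose-volume planning objective."""

    structure: str
    kind: str
    dose_gy: float
    volume_pct: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.dose_gy < 0:
            raise ValueError("dose level must be nonnegative")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.kind.endswith("_dvh"):
            if self.volume_pct is None or not (0.0 <= self.volume_pct <= 100.0):
                raise ValueError("dvh objectives need volume_pct in [0, 100]")


class FluenceMap:
    """Per-beam 2-D beamlet weight arrays, stored flat.

    The flat layout follows the dose-influence matrix beamlet order;
    ``per_beam()`` reshapes into (n_u, n_rows) arrays, u being the
    leaf-travel axis.
    """

    def __init__(self, values: np.ndarray, matrix: DoseInfluenceMatrix) -> None:
        values = np.asarray(values, dtype=float).ravel()
        if values.size != matrix.n_beamlets:
            raise ValueError("fluence length mismatch")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("fluence weights must be finite and nonnegative")
        self.values = values
        self.beam_id = matrix.beam_id
        self.beam_layout = list(matrix.beam_layout)

    @classmethod
    def uniform(cls, matrix: DoseInfluenceMatrix, value: float = 1.0) -> "FluenceMap":
        return cls(np.full(matrix.n_beamlets, float(value)), matrix)

    def per_beam(self) -> list[np.ndarray]:
        out = []
        start = 0
        for b, (n_u, n_z) in enumerate(self.beam_layout):
            n = n_u * n_z
            # beamlets are emitted z-major (rows), u-minor
            out.append(self.values[start : start + n].reshape(n_z, n_u).T)
            start += n
        return out

    def scaled(self, factor: float) -> "FluenceMap":
        fm = object.__new__(FluenceMap)
        fm.values = self.values * factor
        fm.beam_id = self.beam_id
        fm.beam_layout = self.beam_layout
        return fm

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class OptimizationProblem:
    """A fluence optimization problem on the simplified dose model."""

    matrix: DoseInfluenceMatrix
    structures: dict[str, np.ndarray]   # name -> flat voxel indices
    objectives: list[Objective]
    base_dose: np.ndarray | None = None  # flat, Gy
    dose_scale: float = 1.0
    max_iter: int = 500
    tol: float = 1e-5
    patience: int = 10
    initial_fluence: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_vox = self.matrix.matrix.shape[1]
        if self.base_dose is not None:
            self.base_dose = np.asarray(self.base_dose, dtype=float).ravel()
            if self.base_dose.size != n_vox:
                raise ValueError("base dose grid incongruent with voxel space")
        for obj in self.objectives:
            if obj.structure not in self.structures:
                raise ValueError(f"objective references unknown structure {obj.structure!r}")


def _term_value_and_residual(obj: Objective, d: np.ndarray):
    """Penalty value of one objective on its structure's doses, plus the
    residual vector (same length as d) entering the gradient."""
    n = d.size
    r = np.zeros(n)
    L = obj.dose_gy
    if obj.kind == "max_dose":
        r = np.maximum(d - L, 0.0)
    elif obj.kind == "min_dose":
        r = -np.maximum(L - d, 0.0)
    elif obj.kind == "mean_dose":
        excess = d.mean() - L
        if excess > 0:
            # distributed so that grad matches d/dd of (mean(d)-L)^2
            value = obj.weight * excess**2
            r[:] = excess / n
            return value, 2.0 * obj.weight * r
        return 0.0, r
    elif obj.kind == "max_dvh":
        allowed = int(np.floor(obj.volume_pct / 100.0 * n))
        over = np.flatnonzero(d > L)
        k = over.size - allowed
        if k > 0:
            # penalize the k violating voxels closest above the threshold
            sel = over[np.argsort(d[over], kind="stable")[:k]]
            r[sel] = d[sel] - L
    elif obj.kind == "min_dvh":
        required = int(np.ceil(obj.volume_pct / 100.0 * n))
        above = int((d >= L).sum())
        k = required - above
        if k > 0:
            below = np.flatnonzero(d < L)
            sel = below[np.argsort(-d[below], kind="stable")[:k]]
            r[sel] = d[sel] - L
    value = obj.weight * float(np.dot(r, r)) / n
    grad_r = 2.0 * obj.weight * r / n
    return value, grad_r


def _dose(problem: OptimizationProblem, x: np.ndarray) -> np.ndarray:
    d = problem.dose_scale * (problem.matrix.matrix.T @ x)
    if problem.base_dose is not None:
        d = d + problem.base_dose
    return d


def evaluate_objective(problem: OptimizationProblem, fluence) -> float:
    """Total penalty of a fluence map; 0 iff every objective is met."""
    x = fluence.values if isinstance(fluence, FluenceMap) else np.asarray(fluence, float)
    if np.any(x < 0):
        raise ValueError("fluence must be nonnegative")
    d = _dose(problem, x)
    total = 0.0
    for obj in problem.objectives:
        idx = problem.structures[obj.structure]
        value, _ = _term_value_and_residual(obj, d[idx])
        total += value
    return total


def objective_value_and_gradient(
    problem: OptimizationProblem, x: np.ndarray
) -> tuple[float, np.ndarray]:
    d = _dose(problem, x)
    total = 0.0
    dpen_dd = np.zeros(d.size)
    for obj in problem.objectives:
        idx = problem.structures[obj.structure]
        value, grad_r = _term_value_and_residual(obj, d[idx])
        total += value
        np.add.at(dpen_dd, idx, grad_r)
    grad = problem.dose_scale * (problem.matrix.matrix @ dpen_dd)
    return total, grad


def _default_initial_fluence(problem: OptimizationProblem) -> np.ndarray:
    """Uniform fluence at a heuristic scale: the highest-weight lower
    (min_dose / min_dvh) objective level divided by the mean unit-fluence
    dose over its structure."""
    lower = [o for o in problem.objectives if o.kind in ("min_dose", "min_dvh")]
    if not lower:
        return np.zeros(problem.matrix.n_beamlets)
    ref = max(lower, key=lambda o: o.weight)
    idx = problem.structures[ref.structure]
    ones = np.ones(problem.matrix.n_beamlets)
    d_unit = problem.dose_scale * (problem.matrix.matrix.T @ ones)
    mean_unit = float(d_unit[idx].mean())
    if mean_unit <= 0:
        return np.zeros(problem.matrix.n_beamlets)
    target = ref.dose_gy
    if problem.base_dose is not None:
        target = max(target - float(problem.base_dose[idx].mean()), 0.0)
    return np.full(problem.matrix.n_beamlets, target / mean_unit)


def optimize(problem: OptimizationProblem) -> tuple[FluenceMap, np.ndarray]:
    """Projected-gradient descent with backtracking line search.

    Returns the optimized fluence map and the convergence trace of
    accepted penalty values (monotone non-increasing).  Stops at the
    iteration cap or when the relative penalty decrease over a patience
    window falls below ``tol``.
    """
    if problem.initial_fluence is not None:
        x = np.asarray(problem.initial_fluence, dtype=float).ravel().copy()
        if np.any(x < 0):
            raise ValueError("initial fluence must be nonnegative")
    else:
        x = _default_initial_fluence(problem)

    f, g = objective_value_and_gradient(problem, x)
    if not np.isfinite(f) or not np.all(np.isfinite(g)):
        raise RuntimeError("non-finite objective or gradient at initial fluence")
    trace = [f]
    gmax = float(np.abs(g).max())
    step = (max(float(x.max()), 1.0) / gmax) if gmax > 0 else 1.0

    for _ in range(problem.max_iter):
        if f <= 0.0:
            break
        if not np.all(np.isfinite(g)):
            raise RuntimeError("non-finite gradient encountered")
        accepted = False
        t = step
        for _bt in range(40):
            x_new = np.maximum(x - t * g, 0.0)
            delta = x - x_new
            f_new, g_new = objective_value_and_gradient(problem, x_new)
            # Armijo condition on the projected step
            if f_new <= f - 1e-4 / max(t, 1e-30) * float(np.dot(delta, delta)):
                accepted = True
                break
            t *= 0.5
        if not accepted or f_new >= f:
            break  # no further decrease possible at machine precision
        x, f, g = x_new, f_new, g_new
        trace.append(f)
        step = t * 1.5

        if len(trace) > problem.patience:
            ref = trace[-1 - problem.patience]
            if ref - f <= problem.tol * max(ref, 1e-12):
                break

    return FluenceMap(x, problem.matrix), np.asarray(trace)
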