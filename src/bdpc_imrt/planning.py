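"""Planning strategies: conventional, split-target, and base-dose-plan
compensation, with a statsmodels-style model / results interface.

The three strategies share one pipeline: optimize a fluence map on the
*simplified* dose model, compute the deliverable dose on the *accurate*
model, and normalize so the prescription covers 90% of the PTV.

* **CO** (conventional optimization): one pass with the standard
  objective preset.  The engine discrepancy (optimization-convergence
  error, OCE) surfaces as cold/hot spots in the final dose.
* **STO** (split-target optimization): identical, except the PTV
  objectives are split over its soft-tissue and lung-density components
  and the lung-component dose levels are raised by 2-4 Gy, pre-paying
  the expected lung underdose.
* **BDPC** (base-dose-plan compensation): (1) the finished CO plan at
  half the fractions becomes the base dose plan (BDP), i.e. half its
  final dose grid; (2) a top dose plan (TDP) is initialized as a
  duplicate of the BDP fluence; (3) the TDP is re-optimized on the
  simplified model with the BDP final dose added, unchanged objectives,
  so the optimizer shapes the *sum* toward the full prescription —
  producing hot fluence where the base has cold spots; (4) the TDP
  final dose is computed on the accurate engine; (5) fractions are
  restored (half-course dose doubled); (6) the plan is normalized.

Typical use::

    grid, structures = generate_thorax_phantom(PhantomConfig(seed=1))
    model = TreatmentPlanModel(grid, structures)
    res = model.fit(method="bdpc")
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose import BeamGeometry, DoseInfluenceMatrix, EngineParams, compute_dose_matrix
from .evaluation import PlanMetrics, compute_dvh, compute_plan_metrics
from .objectives import PlanConstraints, check_constraints, clinical_lung_preset
from .optimize import FluenceMap, Objective, OptimizationProblem, optimize
from .phantom import DensityGrid, StructureSet

__all__ = [
    "Plan",
    "PlanningContext",
    "TreatmentPlanModel",
    "PlanResults",
    "plan_CO",
    "plan_STO",
    "plan_BDPC",
    "normalize_plan",
    "total_MU",
]


@dataclass
class Plan:
    """A finished treatment plan.

    Dose grids are full-course (all fractions).  ``optimizer_dose`` is
    what the simplified engine believes the plan delivers;
    ``final_dose`` is the accurate-engine deliverable dose.
    """

    fluence: FluenceMap
    fractions: int
    dose_per_fraction_gy: float
    optimizer_dose: np.ndarray
    final_dose: np.ndarray
    method: str
    normalization: float = 1.0
    convergence_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.normalization <= 0:
            raise ValueError("normalization factor must be positive")
        if np.any(self.final_dose < 0):
            raise ValueError("final dose grid must be nonnegative")

    @property
    def prescription_gy(self) -> float:
        return self.fractions * self.dose_per_fraction_gy

    @property
    def mu_per_fraction(self) -> float:
        return total_MU(self)


def total_MU(plan: Plan, calibration: float = 1.0,
             model: str = "sliding_window") -> float:
    """Monitor-unit proxy per fraction.

    ``sliding_window`` (default) models dynamic-MLC delivery: the MU of
    one fluence row is the sum of positive fluence increments along the
    leaf-travel axis, so a modulated profile costs more beam-on time
    than a flat profile of equal mean.  ``fluence_sum`` is the plain
    total fluence.  Both are positively homogeneous: doubling all
    fluence doubles MU; zero fluence gives zero MU.
    """
    total = 0.0
    if model == "fluence_sum":
        total = plan.fluence.total()
    elif model == "sliding_window":
        for beam in plan.fluence.per_beam():      # (n_u, n_rows)
            inc = np.diff(beam, axis=0, prepend=0.0)
            total += np.maximum(inc, 0.0).sum()
    else:
        raise ValueError("MU model must be 'sliding_window' or 'fluence_sum'")
    return calibration * total / plan.fractions


class PlanningContext:
    """Shared per-phantom planning state: both dose-influence matrices,
    structure indices, and the prescription."""

    def __init__(
        self,
        grid: DensityGrid,
        structures: StructureSet,
        geometry: BeamGeometry | None = None,
        engine_params: EngineParams | None = None,
        prescription_gy: float = 60.0,
        fractions: int = 30,
        aperture_margin_mm: float = 10.0,
        simplified: DoseInfluenceMatrix | None = None,
        accurate: DoseInfluenceMatrix | None = None,
    ) -> None:
        self.grid = grid
        self.structures = structures
        if geometry is None:
            geometry = BeamGeometry.for_laterality(structures.laterality)
        self.geometry = geometry
        self.engine_params = engine_params or EngineParams()
        self.prescription_gy = float(prescription_gy)
        self.fractions = int(fractions)
        kw = dict(
            geometry=geometry,
            params=self.engine_params,
            aperture_mask=structures["ptv"],
            aperture_margin_mm=aperture_margin_mm,
        )
        self.simplified = simplified or compute_dose_matrix(
            grid, structures["body"], engine="simplified", **kw
        )
        self.accurate = accurate or compute_dose_matrix(
            grid, structures["body"], engine="accurate", **kw
        )
        self.indices = {name: structures.indices(name) for name in structures.names}

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.prescription_gy / self.fractions


def normalize_plan(plan: Plan, coverage_pct: float = 90.0,
                   prescription_gy: float | None = None,
                   ptv_mask: np.ndarray | None = None) -> Plan:
    """Scale a plan so the prescription isodose covers ``coverage_pct``
    of the PTV on the final dose (D_coverage% becomes the prescription).

    Fluence and both dose grids scale together, so scale-invariant
    metrics (HI, CI of a fixed isodose fraction) are preserved only as
    the spec'd ratio laws allow; the normalization factor is recorded.
    """
    if ptv_mask is None:
        ptv_mask = plan.meta.get("ptv_mask")
    if ptv_mask is None:
        raise ValueError("normalize_plan needs the PTV mask")
    if prescription_gy is None:
        prescription_gy = plan.prescription_gy
    d_cov = float(np.percentile(plan.final_dose[ptv_mask], 100.0 - coverage_pct))
    if d_cov <= 0:
        raise ValueError("PTV coverage dose is zero; cannot normalize")
    factor = prescription_gy / d_cov
    plan.fluence = plan.fluence.scaled(factor)
    plan.optimizer_dose = plan.optimizer_dose * factor
    plan.final_dose = plan.final_dose * factor
    plan.normalization *= factor
    return plan


def _finish_plan(ctx: PlanningContext, fluence: FluenceMap, trace: np.ndarray,
                 method: str, meta: dict | None = None) -> Plan:
    optimizer_dose = ctx.simplified.dose(fluence.values)
    final_dose = ctx.accurate.dose(fluence.values)
    plan = Plan(
        fluence=fluence,
        fractions=ctx.fractions,
        dose_per_fraction_gy=ctx.dose_per_fraction_gy,
        optimizer_dose=optimizer_dose,
        final_dose=final_dose,
        method=method,
        convergence_trace=trace,
        meta={"ptv_mask": ctx.structures["ptv"], **(meta or {})},
    )
    return normalize_plan(plan, 90.0, ctx.prescription_gy)


def _resolve_context(phantom, geometry, context, **ctx_kw) -> PlanningContext:
    if context is not None:
        return context
    grid, structures = phantom
    return PlanningContext(grid, structures, geometry=geometry, **ctx_kw)


def plan_CO(phantom=None, geometry=None, constraints=None, objectives=None,
            *, context: PlanningContext | None = None,
            max_iter: int = 500, **opt_kw) -> Plan:
    """Conventional optimization: simplified-model fit, accurate-model
    final dose, D90% normalization."""
    ctx = _resolve_context(phantom, geometry, context)
    objectives = objectives or clinical_lung_preset(ctx.prescription_gy)
    problem = OptimizationProblem(
        matrix=ctx.simplified,
        structures=ctx.indices,
        objectives=list(objectives),
        max_iter=max_iter,
        **opt_kw,
    )
    fluence, trace = optimize(problem)
    return _finish_plan(ctx, fluence, trace, "CO")


def split_objectives_for_sto(
    objectives: list[Objective], structures: StructureSet, lung_boost_gy: float
) -> list[Objective]:
    """Split every PTV objective over the soft/lung components, raising
    the lung-component dose levels by ``lung_boost_gy``.

    Component weights are scaled by voxel fraction so that at zero boost
    the split objective is algebraically identical to the original
    (both use per-structure mean normalization)."""
    n_ptv = int(structures["ptv"].sum())
    n_soft = int(structures["ptv_soft"].sum())
    n_lung = int(structures["ptv_lung"].sum())
    out: list[Objective] = []
    for obj in objectives:
        if obj.structure != "ptv":
            out.append(obj)
            continue
        if n_soft:
            out.append(Objective("ptv_soft", obj.kind, obj.dose_gy,
                                 obj.volume_pct, obj.weight * n_soft / n_ptv))
        if n_lung:
            out.append(Objective("ptv_lung", obj.kind, obj.dose_gy + lung_boost_gy,
                                 obj.volume_pct, obj.weight * n_lung / n_ptv))
    return out


def plan_STO(phantom=None, geometry=None, constraints=None, objectives=None,
             lung_boost_gy: float = 3.0, *,
             context: PlanningContext | None = None,
             max_iter: int = 500, **opt_kw) -> Plan:
    """Split-target optimization: PTV objectives split over PTV_soft /
    PTV_lung with the lung component raised by 2-4 Gy (default 3)."""
    ctx = _resolve_context(phantom, geometry, context)
    objectives = list(objectives or clinical_lung_preset(ctx.prescription_gy))
    if not ctx.structures["ptv_lung"].any():
        warnings.warn(
            "PTV has no lung-density component; split-target optimization "
            "falls back to the conventional objectives",
            stacklevel=2,
        )
        sto_objectives = objectives
    elif lung_boost_gy == 0.0:
        # a zero boost is definitionally the conventional plan
        sto_objectives = objectives
    else:
        sto_objectives = split_objectives_for_sto(
            objectives, ctx.structures, lung_boost_gy
        )
    problem = OptimizationProblem(
        matrix=ctx.simplified,
        structures=ctx.indices,
        objectives=sto_objectives,
        max_iter=max_iter,
        **opt_kw,
    )
    fluence, trace = optimize(problem)
    return _finish_plan(ctx, fluence, trace, "STO",
                        meta={"lung_boost_gy": lung_boost_gy})


def plan_BDPC(co_plan: Plan, phantom=None, geometry=None, objectives=None,
              reopt_cap: int = 200, *,
              context: PlanningContext | None = None, **opt_kw) -> Plan:
    """Base-dose-plan compensation built on a finished CO plan.

    The CO plan at half the fractions supplies the base dose (half its
    final-dose grid); a duplicate fluence is re-optimized against that
    base with unchanged objectives so the plan *sum* meets the full
    prescription, then fractions are restored and the plan normalized.
    """
    if co_plan.final_dose is None or not np.asarray(co_plan.final_dose).size:
        raise ValueError("BDPC requires a CO plan with a computed final dose")
    ctx = _resolve_context(phantom, geometry, context)
    objectives = objectives or clinical_lung_preset(ctx.prescription_gy)

    half = ctx.fractions // 2
    base_dose = 0.5 * np.asarray(co_plan.final_dose, dtype=float).ravel()
    problem = OptimizationProblem(
        matrix=ctx.simplified,
        structures=ctx.indices,
        objectives=list(objectives),
        base_dose=base_dose,
        dose_scale=0.5,
        max_iter=reopt_cap,
        initial_fluence=co_plan.fluence.values.copy(),
        **opt_kw,
    )
    fluence, trace = optimize(problem)
    # Restoring the fraction count doubles the half-course dose: dose is
    # linear in fractions, so the full-course grids are engine(x) itself
    # when x keeps the full-course fluence scale.
    plan = _finish_plan(
        ctx, fluence, trace, "BDPC",
        meta={
            "bdp_fractions": half,
            "bdp_prescription_gy": half * ctx.dose_per_fraction_gy,
            "base_plan_method": co_plan.method,
            "base_normalization": co_plan.normalization,
        },
    )
    return plan


class TreatmentPlanModel:
    """Planning model for one phantom (statsmodels-style).

    Construct from a density grid and structure set; ``fit`` runs one of
    the three planning strategies and returns a :class:`PlanResults`.
    The dose-influence matrices are built once and shared across fits.
    """

    def __init__(
        self,
        grid: DensityGrid,
        structures: StructureSet,
        geometry: BeamGeometry | None = None,
        objectives: list[Objective] | None = None,
        constraints: PlanConstraints | None = None,
        prescription_gy: float = 60.0,
        fractions: int = 30,
        engine_params: EngineParams | None = None,
    ) -> None:
        self.grid = grid
        self.structures = structures
        self.prescription_gy = float(prescription_gy)
        self.fractions = int(fractions)
        self.objectives = objectives or clinical_lung_preset(prescription_gy)
        self.constraints = constraints or PlanConstraints(prescription_gy=prescription_gy)
        self._geometry = geometry
        self._engine_params = engine_params
        self._context: PlanningContext | None = None

    @classmethod
    def from_phantom_config(cls, config, **kw) -> "TreatmentPlanModel":
        from .phantom import generate_thorax_phantom
        grid, structures = generate_thorax_phantom(config)
        return cls(grid, structures, **kw)

    @property
    def context(self) -> PlanningContext:
        if self._context is None:
            self._context = PlanningContext(
                self.grid,
                self.structures,
                geometry=self._geometry,
                engine_params=self._engine_params,
                prescription_gy=self.prescription_gy,
                fractions=self.fractions,
            )
        return self._context

    def fit(
        self,
        method: str = "bdpc",
        lung_boost_gy: float = 3.0,
        reopt_cap: int = 200,
        max_iter: int = 500,
        base_results: "PlanResults | None" = None,
        **opt_kw,
    ) -> "PlanResults":
        method = method.lower()
        ctx = self.context
        if method == "co":
            plan = plan_CO(context=ctx, objectives=self.objectives,
                           max_iter=max_iter, **opt_kw)
        elif method == "sto":
            plan = plan_STO(context=ctx, objectives=self.objectives,
                            lung_boost_gy=lung_boost_gy, max_iter=max_iter, **opt_kw)
        elif method == "bdpc":
            if base_results is None:
                base_results = self.fit("co", max_iter=max_iter, **opt_kw)
            plan = plan_BDPC(base_results.plan, context=ctx,
                             objectives=self.objectives, reopt_cap=reopt_cap,
                             **opt_kw)
        else:
            raise ValueError("method must be 'co', 'sto' or 'bdpc'")
        return PlanResults(self, plan, base_results=base_results
                           if method == "bdpc" else None)


class PlanResults:
    """Fitted plan: dose grids, metrics, diagnostics and summary."""

    def __init__(self, model: TreatmentPlanModel, plan: Plan,
                 base_results: "PlanResults | None" = None) -> None:
        self.model = model
        self.plan = plan
        self.base_results = base_results
        self._metrics: PlanMetrics | None = None

    @property
    def method(self) -> str:
        return self.plan.method

    @property
    def metrics(self) -> PlanMetrics:
        if self._metrics is None:
            self._metrics = compute_plan_metrics(
                self.plan.final_dose,
                self.model.structures,
                self.model.prescription_gy,
                method=self.plan.method,
                mu_per_fraction=total_MU(self.plan),
            )
        return self._metrics

    def dvh(self, structure: str, on: str = "final"):
        dose = self.plan.final_dose if on == "final" else self.plan.optimizer_dose
        return compute_dvh(dose, self.model.structures[structure],
                           structure=structure)

    def constraint_table(self) -> pd.DataFrame:
        return check_constraints(self.plan.final_dose, self.model.structures,
                                 self.model.constraints)

    def plot_dvh(self, structures: list[str] | None = None, ax=None):
        """Cumulative DVH plot of the final dose (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = structures or ["ptv", "total_lung", "esophagus", "heart",
                               "spinal_cord"]
        for name in names:
            if name not in self.model.structures:
                continue
            curve = self.dvh(name)
            ax.plot(curve.edges, curve.cum_volume_pct, label=name)
        ax.set_xlabel("Dose (Gy)")
        ax.set_ylabel("Volume (%)")
        ax.set_title(f"{self.method} plan DVH")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        m = self.metrics
        c = self.constraint_table()
        lines = [
            f"Treatment plan summary [{self.method}]",
            f"  prescription      : {self.model.prescription_gy:.1f} Gy "
            f"({self.plan.fractions} x {self.plan.dose_per_fraction_gy:.1f} Gy)",
            f"  normalization     : {self.plan.normalization:.4f} (D90% -> prescription)",
            f"  PTV D2/D50/D98    : {m.d2:.2f} / {m.d50:.2f} / {m.d98:.2f} Gy",
            f"  CI (Paddick)      : {m.ci:.2f}",
            f"  HI (ICRU 83)      : {m.hi:.2f}",
            f"  MU per fraction   : {m.mu_per_fraction:.1f}",
            f"  MLD               : {m.mld_gy:.2f} Gy",
            f"  NT V107%          : {m.nt_v107_cc:.2f} cm^3",
            f"  constraints passed: {int(c['passed'].sum())}/{len(c)}",
        ]
        failed = c[~c["passed"]]
        for _, row in failed.iterrows():
            lines.append(
                f"    FLAG {row['constraint']}: {row['value']:.2f} "
                f"(limit {row['limit']:.2f})"
            )
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable per-plan report."""
        return {
            "method": self.method,
            "prescription_gy": self.model.prescription_gy,
            "fractions": self.plan.fractions,
            "normalization": self.plan.normalization,
            "metrics": self.metrics.to_dict(),
            "constraints": self.constraint_table().to_dict(orient="records"),
            "meta": {k: v for k, v in self.plan.meta.items()
                     if isinstance(v, (int, float, str))},
        }
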