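"""Planning strategies: normalization contract, fraction bookkeeping,
degenerate equalities, the compensation mechanism and MU proxies."""

import numpy as np
import pytest

from bdpc_imrt import (
    PhantomConfig,
    generate_thorax_phantom,
    normalize_plan,
    plan_BDPC,
    plan_CO,
    plan_STO,
    total_MU,
)
from bdpc_imrt.evaluation import compute_plan_metrics
from bdpc_imrt.planning import PlanningContext

PLANAR = (64, 64, 1)


class TestNormalization:
    def test_factor_from_raw_coverage(self, co_2d):
        """Re-scaling an already normalized plan is the identity, and
        the recorded factor reproduces prescription / raw D90%."""
        plan = co_2d.plan
        ptv = co_2d.model.structures["ptv"]
        d90 = np.percentile(plan.final_dose[ptv], 10.0)
        assert d90 == pytest.approx(60.0, rel=1e-9)
        raw_d90 = d90 / plan.normalization
        assert plan.normalization == pytest.approx(60.0 / raw_d90, rel=1e-9)

    def test_coverage_contract(self, co_2d, bdpc_2d, sto_2d):
        """After normalization at least 90% of the PTV receives the
        prescription, up to one DVH bin."""
        for res in (co_2d, sto_2d, bdpc_2d):
            dvh = res.dvh("ptv")
            assert dvh.v_at_dose(60.0 - 0.05) >= 90.0 - 1e-6

    def test_hi_preserved_by_scaling(self, co_2d):
        """HI is a scale-invariant ratio: doubling the dose grid and
        renormalizing leaves it unchanged (up to binning)."""
        m1 = co_2d.metrics
        scaled = 2.0 * co_2d.plan.final_dose
        m2 = compute_plan_metrics(scaled, co_2d.model.structures, 120.0)
        assert m2.hi == pytest.approx(m1.hi, abs=2e-3)

    def test_zero_coverage_raises(self, model_2d, co_2d):
        import copy

        plan = copy.copy(co_2d.plan)
        plan.final_dose = np.zeros_like(plan.final_dose)
        with pytest.raises(ValueError, match="cannot normalize"):
            normalize_plan(plan, 90.0, 60.0,
                           model_2d.structures["ptv"])


class TestPlanCO:
    def test_deterministic(self):
        """The same phantom planned twice gives bit-identical fluence."""
        plans = []
        for _ in range(2):
            grid, s = generate_thorax_phantom(PhantomConfig(seed=4, shape=PLANAR))
            plans.append(plan_CO((grid, s)))
        assert np.array_equal(plans[0].fluence.values, plans[1].fluence.values)
        assert np.array_equal(plans[0].final_dose, plans[1].final_dose)

    def test_cold_spots_at_final_calculation(self, co_2d):
        """On a lung phantom the deliverable D98% falls below what the
        optimizer's dose model promised."""
        opt_dvh = co_2d.dvh("ptv", on="optimizer")
        fin_dvh = co_2d.dvh("ptv", on="final")
        assert fin_dvh.d_at_volume(98.0) < opt_dvh.d_at_volume(98.0)

    def test_engines_agree_without_heterogeneity(self, uniform_phantom_2d):
        grid, s = uniform_phantom_2d
        plan = plan_CO((grid, s))
        scale = plan.optimizer_dose.max()
        assert np.abs(plan.final_dose - plan.optimizer_dose).max() / scale < 0.01


class TestPlanSTO:
    def test_zero_boost_equals_co(self, lung_phantom_2d):
        grid, s = lung_phantom_2d
        ctx = PlanningContext(grid, s)
        co = plan_CO(context=ctx)
        sto = plan_STO(context=ctx, lung_boost_gy=0.0)
        assert np.array_equal(co.fluence.values, sto.fluence.values)

    def test_uniform_phantom_falls_back_to_co(self, uniform_phantom_2d):
        grid, s = uniform_phantom_2d
        ctx = PlanningContext(grid, s)
        co = plan_CO(context=ctx)
        with pytest.warns(UserWarning, match="falls back"):
            sto = plan_STO(context=ctx, lung_boost_gy=3.0)
        assert np.array_equal(co.fluence.values, sto.fluence.values)
        assert sto.method == "STO"

    def test_split_objective_weights_proportional(self, lung_phantom_2d):
        from bdpc_imrt.objectives import clinical_lung_preset
        from bdpc_imrt.planning import split_objectives_for_sto

        _, s = lung_phantom_2d
        objs = split_objectives_for_sto(clinical_lung_preset(60.0), s, 3.0)
        lung = [o for o in objs if o.structure == "ptv_lung"]
        soft = [o for o in objs if o.structure == "ptv_soft"]
        assert lung and soft
        assert all(o.dose_gy in (63.0, 66.0) for o in lung)
        n_ptv = s["ptv"].sum()
        assert lung[0].weight == pytest.approx(300.0 * s["ptv_lung"].sum() / n_ptv)


class TestPlanBDPC:
    def test_fraction_bookkeeping(self, bdpc_2d):
        """The base plan runs at half the fractions; the returned plan
        restores the prescribed 30 x 2 Gy course."""
        plan = bdpc_2d.plan
        assert plan.fractions == 30
        assert plan.prescription_gy == pytest.approx(60.0)
        assert plan.meta["bdp_fractions"] == 15
        assert plan.meta["bdp_prescription_gy"] == pytest.approx(30.0)

    def test_requires_final_dose(self, model_2d, co_2d):
        import copy

        broken = copy.copy(co_2d.plan)
        broken.final_dose = np.zeros(0)
        with pytest.raises(ValueError, match="final dose"):
            plan_BDPC(broken, context=model_2d.context)

    def test_noop_when_engines_identical(self, lung_phantom_2d):
        """With the engine gap removed the compensation is a near no-op:
        BDPC and CO coincide in homogeneity."""
        grid, s = lung_phantom_2d
        ctx = PlanningContext(grid, s)
        null_ctx = PlanningContext(grid, s, simplified=ctx.simplified,
                                   accurate=ctx.simplified)
        co = plan_CO(context=null_ctx)
        bd = plan_BDPC(co, context=null_ctx)
        hi_co = compute_plan_metrics(co.final_dose, s, 60.0).hi
        hi_bd = compute_plan_metrics(bd.final_dose, s, 60.0).hi
        assert abs(hi_co - hi_bd) < 0.01

    def test_sum_compensation_mechanism(self, model_2d, co_2d, bdpc_2d):
        """At the optimizer's dose model, the compensated sum (TDP +
        BDP) is more uniform over the PTV than doubling the base plan:
        the re-optimization places heat where the base is cold."""
        ctx = model_2d.context
        ptv = model_2d.structures["ptv"]
        x_raw = bdpc_2d.plan.fluence.values / bdpc_2d.plan.normalization
        believed_sum = (0.5 * ctx.simplified.dose(x_raw)
                        + 0.5 * co_2d.plan.final_dose)
        doubled_base = co_2d.plan.final_dose

        def spread(d):
            v = d[ptv]
            return (np.percentile(v, 98) - np.percentile(v, 2)) / np.percentile(v, 50)

        assert spread(believed_sum) < spread(doubled_base)

    def test_improves_homogeneity_on_lung_phantom(self, co_2d, sto_2d, bdpc_2d):
        assert bdpc_2d.metrics.hi < sto_2d.metrics.hi < co_2d.metrics.hi


class TestMU:
    def test_zero_fluence_zero_mu(self, co_2d):
        import copy

        plan = copy.copy(co_2d.plan)
        plan.fluence = plan.fluence.scaled(0.0)
        assert total_MU(plan) == 0.0
        assert total_MU(plan, model="fluence_sum") == 0.0

    def test_doubling_fluence_doubles_mu(self, co_2d):
        import copy

        plan = copy.copy(co_2d.plan)
        mu1 = total_MU(plan)
        plan.fluence = plan.fluence.scaled(2.0)
        assert total_MU(plan) == pytest.approx(2.0 * mu1)
        assert total_MU(plan, model="fluence_sum") == pytest.approx(
            2.0 * total_MU(co_2d.plan, model="fluence_sum"))

    def test_modulation_costs_mu(self, model_2d):
        """A modulated profile requires more beam-on time than a flat
        profile with the same total fluence (sliding-window model)."""
        import copy

        from bdpc_imrt.optimize import FluenceMap

        ctx = model_2d.context
        n = ctx.simplified.n_beamlets
        flat = FluenceMap(np.full(n, 2.0), ctx.simplified)
        mod_values = np.full(n, 2.0)
        mod_values[::2] += 1.0
        mod_values[1::2] -= 1.0
        modulated = FluenceMap(mod_values, ctx.simplified)

        base = plan_CO(context=ctx)
        p1, p2 = copy.copy(base), copy.copy(base)
        p1.fluence, p2.fluence = flat, modulated
        assert total_MU(p2) > total_MU(p1)
        assert total_MU(p2, model="fluence_sum") == pytest.approx(
            total_MU(p1, model="fluence_sum"))


class TestModelInterface:
    def test_summary_contains_key_metrics(self, bdpc_2d):
        text = bdpc_2d.summary()
        assert "BDPC" in text
        assert "HI" in text and "CI" in text and "MU" in text

    def test_constraint_table_structure(self, co_2d):
        table = co_2d.constraint_table()
        assert set(table.columns) == {"constraint", "value", "limit", "passed"}
        assert len(table) == 7

    def test_invalid_method_rejected(self, model_2d):
        with pytest.raises(ValueError, match="method"):
            model_2d.fit("vmat")

    def test_report_serializable(self, bdpc_2d, tmp_path):
        import json

        report = bdpc_2d.to_report()
        path = tmp_path / "report.json"
        path.write_text(json.dumps(report))
        back = json.loads(path.read_text())
        assert back["method"] == "BDPC"
        assert back["metrics"]["hi"] == pytest.approx(bdpc_2d.metrics.hi)

    def test_plot_dvh_returns_axes(self, co_2d):
        import matplotlib

        matplotlib.use("Agg")
        ax = co_2d.plot_dvh()
        assert ax.get_xlabel() == "Dose (Gy)"
        assert len(ax.lines) >= 2
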