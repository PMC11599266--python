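"""Cost/QALY accrual, discounting, dose arithmetic, and the incremental
comparison."""

import dataclasses

import numpy as np
import pytest

from oncocea.economics import (
    AdverseEvent,
    CostInputs,
    StrategyInputs,
    StrategyOutcome,
    Utilities,
    accrue,
    body_surface_area,
    compare,
    discount_factor,
    evaluate_case,
    weighted_patient_profile,
)
from oncocea.markov_engine import CohortTrace, ModelConfig, build_trace
from oncocea.survival_models import ParametricSurvival


def make_strategy(**overrides):
    kwargs = dict(
        name="test", key="test", drug_cost_per_cycle=0.0, adverse_events=(),
        os_model=ParametricSurvival("lognormal", 2.398, 0.808),
        pfs_model=ParametricSurvival("lognormal", 1.660, 0.850),
    )
    kwargs.update(overrides)
    return StrategyInputs(**kwargs)


class TestDoseArithmetic:
    def test_bsa_of_study_average_patient(self):
        # sex-weighted (256:236) Chinese reference height/weight -> 1.79 m^2
        h = weighted_patient_profile(169.70, 158.00, 256, 236)
        w = weighted_patient_profile(69.60, 59.00, 256, 236)
        assert h == pytest.approx(164.09, abs=0.005)
        assert w == pytest.approx(64.52, abs=0.005)
        assert round(body_surface_area(h, w), 2) == 1.79

    def test_bsa_is_the_stated_linear_form(self):
        assert body_surface_area(169.70, 69.60) == pytest.approx(
            0.0061 * 169.70 + 0.0124 * 69.60 - 0.0099, rel=1e-12)
        # weight -> 0 limit isolates the height term
        assert body_surface_area(100.0, 1e-9) == pytest.approx(0.6001, abs=1e-6)

    def test_bsa_rejects_nonpositive_measurements(self):
        with pytest.raises(ValueError):
            body_surface_area(0.0, 60.0)
        with pytest.raises(ValueError):
            body_surface_area(160.0, -1.0)

    def test_weighted_profile_identity_and_errors(self):
        assert weighted_patient_profile(3.3, 3.3, 7, 5) == pytest.approx(3.3)
        with pytest.raises(ValueError):
            weighted_patient_profile(1.0, 2.0, 0, 0)


class TestDiscounting:
    def test_cycle_zero_and_zero_rate(self):
        cfg = ModelConfig()
        assert discount_factor(0, cfg) == 1.0
        cfg0 = ModelConfig(annual_discount=0.0)
        assert all(discount_factor(c, cfg0) == 1.0 for c in (1, 13, 130))

    def test_one_year_of_cycles(self):
        # 13 cycles x 28 d = 364 d, just under a year
        cfg = ModelConfig(annual_discount=0.05)
        assert discount_factor(13, cfg) == pytest.approx(1.05 ** (-364 / 365.25), rel=1e-12)

    def test_discounting_reduces_totals(self, table1_models):
        strat = make_strategy(drug_cost_per_cycle=1000.0)
        for rate in (0.03, 0.05, 0.08):
            cfg0 = ModelConfig(annual_discount=0.0)
            cfg = ModelConfig(annual_discount=rate)
            tr = build_trace(cfg, strat.os_model, strat.pfs_model)
            out0 = accrue(tr, strat, CostInputs(), Utilities(), cfg0)
            out = accrue(tr, strat, CostInputs(), Utilities(), cfg)
            assert out.discounted_cost < out0.discounted_cost
            assert out.discounted_qalys < out0.discounted_qalys


class TestAccrual:
    def test_zero_costs_give_zero_cost_and_positive_qalys(self):
        strat = make_strategy()
        costs = CostInputs(0, 0, 0, 0, 0)
        cfg = ModelConfig()
        tr = build_trace(cfg, strat.os_model, strat.pfs_model)
        out = accrue(tr, strat, costs, Utilities(), cfg)
        assert out.discounted_cost == 0.0
        assert out.discounted_qalys > 0.0

    def test_two_cycle_hand_computation(self):
        # cohort fully dead from cycle 1: cost = AE lump + cycle-0 state cost
        # + end-of-life mass discounted one cycle
        cfg = ModelConfig(horizon_years=2.5 * 28 / 365.25)  # floors to 2 cycles
        assert cfg.n_cycles == 2
        tr = CohortTrace(
            t_months=cfg.cycle_times_months(),
            pfs=np.array([1.0, 0.0]), pd=np.array([0.0, 0.0]),
            dead=np.array([0.0, 1.0]), new_deaths=np.array([0.0, 1.0]))
        strat = make_strategy(drug_cost_per_cycle=1000.0,
                              adverse_events=(AdverseEvent("ae", 0.5, 200.0),))
        costs = CostInputs(lab_per_visit=50.0, imaging_per_visit=150.0,
                           supportive_per_cycle=0.0, end_of_life_once=11_299.0,
                           subsequent_tx_per_cycle=0.0)
        out = accrue(tr, strat, costs, Utilities(u_pfs=0.84, u_pd=0.57), cfg)
        d1 = 1.05 ** (-28 / 365.25)
        assert out.discounted_cost == pytest.approx(
            0.5 * 200.0 + (1000.0 + 50.0 + 150.0) + 11_299.0 * d1, rel=1e-12)
        assert out.discounted_qalys == pytest.approx(0.84 * 28 / 365.25, rel=1e-12)

    def test_unit_utilities_give_discounted_life_years(self, table1_models):
        # u_pfs = u_pd = 1, no discount: QALYs = restricted mean survival of
        # the OS curve, to within one cycle's width (left Riemann sum)
        cfg = ModelConfig(annual_discount=0.0)
        os_m = table1_models[("combo", "OS")]
        strat = make_strategy(os_model=os_m)
        tr = build_trace(cfg, os_m, strat.pfs_model)
        out = accrue(tr, strat, CostInputs(), Utilities(1.0, 1.0), cfg)
        rmst_years = os_m.mean_truncated(cfg.n_cycles * cfg.cycle_months) / 12.0
        assert out.discounted_qalys == pytest.approx(rmst_years, abs=cfg.cycle_years)

    def test_cost_monotone_in_unit_costs_and_qalys_in_utilities(self, base_case):
        cfg = base_case.config
        strat = base_case.intervention
        tr = build_trace(cfg, strat.os_model, strat.pfs_model)
        base = accrue(tr, strat, base_case.costs, base_case.utilities, cfg)
        for fld in ("lab_per_visit", "imaging_per_visit", "supportive_per_cycle",
                    "end_of_life_once", "subsequent_tx_per_cycle"):
            bumped = dataclasses.replace(base_case.costs,
                                         **{fld: getattr(base_case.costs, fld) + 100.0})
            out = accrue(tr, strat, bumped, base_case.utilities, cfg)
            assert out.discounted_cost > base.discounted_cost, fld
        for fld in ("u_pfs", "u_pd"):
            bumped_u = dataclasses.replace(base_case.utilities,
                                           **{fld: getattr(base_case.utilities, fld) + 0.05})
            out = accrue(tr, strat, base_case.costs, bumped_u, cfg)
            assert out.discounted_qalys > base.discounted_qalys, fld

    def test_trace_config_mismatch_rejected(self, table1_models):
        cfg = ModelConfig()
        tr = build_trace(ModelConfig(horizon_years=5), table1_models[("combo", "OS")],
                         table1_models[("combo", "PFS")])
        with pytest.raises(ValueError, match="cycles"):
            accrue(tr, make_strategy(), CostInputs(), Utilities(), cfg)

    def test_half_cycle_correction_shrinks_the_gap_to_the_integral(self, table1_models):
        os_m = table1_models[("combo", "OS")]
        pfs_m = table1_models[("combo", "PFS")]
        strat = make_strategy(os_model=os_m, pfs_model=pfs_m)
        cfg_off = ModelConfig(annual_discount=0.0)
        cfg_on = ModelConfig(annual_discount=0.0, half_cycle_correction=True)
        tr = build_trace(cfg_off, os_m, pfs_m)
        rmst_years = os_m.mean_truncated(cfg_off.n_cycles * cfg_off.cycle_months) / 12.0
        ly_off = accrue(tr, strat, CostInputs(), Utilities(1, 1), cfg_off).discounted_qalys
        ly_on = accrue(tr, strat, CostInputs(), Utilities(1, 1), cfg_on).discounted_qalys
        assert abs(ly_on - rmst_years) < abs(ly_off - rmst_years)


class TestInvariantsOfInputs:
    def test_utility_ordering_enforced(self):
        with pytest.raises(ValueError):
            Utilities(u_pfs=0.84, u_pd=0.9)
        with pytest.raises(ValueError):
            Utilities(u_pfs=1.2, u_pd=0.5)

    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError):
            CostInputs(lab_per_visit=-1.0)
        with pytest.raises(ValueError):
            AdverseEvent("x", 1.5, 10.0)


class TestComparison:
    cfg = ModelConfig()

    def test_increments_from_printed_totals(self):
        # totals as published; increments follow by subtraction
        combo = StrategyOutcome("combo", 838_492.74, 2.45)
        mono = StrategyOutcome("mono", 357_396.97, 1.54)
        res = compare(combo, mono, self.cfg)
        assert res.incremental_cost == pytest.approx(481_095.77, abs=0.005)
        assert res.incremental_qalys == pytest.approx(0.91, abs=1e-12)
        assert res.icer == pytest.approx(481_095.77 / 0.91, rel=1e-12)
        assert res.verdict.startswith("not cost-effective")

    def test_equal_strategies_flagged_equivalent(self):
        a = StrategyOutcome("a", 100.0, 1.0)
        res = compare(a, StrategyOutcome("b", 100.0, 1.0), self.cfg)
        assert res.dominance == "equivalent"
        assert res.icer is None

    def test_dominant_and_dominated_skip_the_ratio(self):
        better_cheaper = compare(StrategyOutcome("a", 50.0, 2.0),
                                 StrategyOutcome("b", 100.0, 1.0), self.cfg)
        assert better_cheaper.dominance == "dominant"
        assert better_cheaper.icer is None
        worse_dearer = compare(StrategyOutcome("a", 100.0, 1.0),
                               StrategyOutcome("b", 50.0, 2.0), self.cfg)
        assert worse_dearer.dominance == "dominated"
        assert not worse_dearer.cost_effective

    def test_nmb_agrees_with_icer_rule(self, base_case):
        res = evaluate_case(base_case)
        assert res.incremental_qalys > 0
        assert (res.nmb >= 0) == (res.icer <= base_case.config.wtp)

    def test_results_table_mirrors_two_row_layout(self, base_case):
        df = evaluate_case(base_case).to_frame()
        assert list(df["group"]) == [base_case.intervention.name,
                                     base_case.comparator.name]
        assert df.loc[1, "incremental_cost"] is None or np.isnan(df.loc[1, "incremental_cost"])
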