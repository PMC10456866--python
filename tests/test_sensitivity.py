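import dataclasses
import math

import numpy as np
import pytest

from pahcea import ParameterSet, UncertainParam, run_cea
from pahcea.sensitivity import (base_monthly_selexipag_price, ceac,
                                default_wtp_grid, owsa, price_threshold, psa,
                                selexipag_price_values, tornado_frame)


@pytest.fixture(scope="module")
def psa_result(params, cohort, settings, life_table):
    return psa(params, cohort, settings, life_table, n=300, seed=11)


def icer_at(values, cohort, settings, life_table):
    result, _ = run_cea(values, cohort, settings, life_table)
    return result.icer


@pytest.fixture(scope="module")
def entries(params, cohort, settings, life_table):
    return owsa(params, cohort, settings, life_table)


class TestOwsa:
    def test_sorted_by_span_descending(self, entries):
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)

    def test_fixed_fc1_hazard_ratio_excluded(self, entries):
        assert "hr_fc1" not in {e.parameter for e in entries}

    def test_selexipag_costs_varied_jointly(self, entries):
        names = {e.parameter for e in entries}
        assert "cost_selexipag" in names
        assert "cost_selexipag_first" not in names
        assert "cost_selexipag_subsequent" not in names

    def test_discount_rate_entry_uses_zero_and_eight_percent(
            self, entries, params, cohort, settings, life_table):
        entry = next(e for e in entries if e.parameter == "discount_rate")
        lo = icer_at(params.base_values(), cohort,
                     dataclasses.replace(settings, annual_discount_rate=0.0),
                     life_table)
        hi = icer_at(params.base_values(), cohort,
                     dataclasses.replace(settings, annual_discount_rate=0.08),
                     life_table)
        assert entry.icer_low == pytest.approx(lo, rel=1e-12)
        assert entry.icer_high == pytest.approx(hi, rel=1e-12)

    def test_degenerate_range_yields_zero_span(self, params, cohort, settings,
                                               life_table, fitted):
        frozen = params.with_param(
            "u_fc4", UncertainParam("u_fc4", 0.520, 0.520, 0.520, "beta"))
        entries = owsa(frozen, cohort, settings, life_table)
        entry = next(e for e in entries if e.parameter == "u_fc4")
        assert entry.span == 0.0
        assert entry.icer_low == pytest.approx(fitted.icer, rel=1e-12)

    def test_selexipag_cost_raises_icer_monotonically(self, params, cohort,
                                                      settings, life_table):
        base = params.base_values()
        up = dict(base, cost_selexipag_subsequent=base[
            "cost_selexipag_subsequent"] * 1.2)
        assert icer_at(up, cohort, settings, life_table) > \
            icer_at(base, cohort, settings, life_table)

    def test_tornado_frame_columns(self, entries):
        df = tornado_frame(entries)
        assert list(df.columns) == ["parameter", "icer_low", "icer_high",
                                    "span"]
        assert len(df) == len(entries)


class TestPsa:
    def test_seed_reproducibility(self, params, cohort, settings, life_table):
        a = psa(params, cohort, settings, life_table, n=25, seed=5)
        b = psa(params, cohort, settings, life_table, n=25, seed=5)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qalys, b.delta_qalys)

    def test_all_fixed_parameters_degenerate_to_base_case(
            self, params, cohort, settings, life_table, fitted):
        frozen = ParameterSet(**{
            p.name: UncertainParam(p.name, p.base, p.base, p.base, "fixed")
            for p in params})
        r = psa(frozen, cohort, settings, life_table, n=5, seed=0)
        np.testing.assert_allclose(r.delta_cost, fitted.incremental_cost,
                                   rtol=1e-12)
        np.testing.assert_allclose(r.delta_qalys, fitted.incremental_qalys,
                                   rtol=1e-12)

    def test_sampled_utility_mean_recovers_anchor(self, psa_result, params):
        x = psa_result.samples["u_fc2"].to_numpy()
        se = x.std() / math.sqrt(len(x))
        assert abs(x.mean() - params.u_fc2.base) < 3 * se

    def test_fixed_hr_fc1_never_varies(self, psa_result):
        assert (psa_result.samples["hr_fc1"] == 5.180).all()

    def test_mean_incremental_qalys_near_base_case(self, psa_result, fitted):
        """Mean-anchored sampling keeps the PSA's average effect close to
        the deterministic increment (HR median-anchoring adds some drift)."""
        de = psa_result.delta_qalys
        se = de.std() / math.sqrt(len(de))
        assert abs(de.mean() - fitted.incremental_qalys) < max(
            5 * se, 0.05 * abs(fitted.incremental_qalys))


class TestCeac:
    def test_two_strategy_probabilities_sum_to_one(self, psa_result):
        curve = ceac(psa_result)
        np.testing.assert_allclose(curve["p_triple"] + curve["p_dual"], 1.0)

    def test_zero_wtp_counts_cost_savings(self, psa_result):
        curve = ceac(psa_result, [0.0])
        expected = float(np.mean(psa_result.delta_cost < 0))
        assert curve["p_triple"].iloc[0] == expected

    def test_large_wtp_counts_positive_effects(self, psa_result):
        curve = ceac(psa_result, [1e12])
        expected = float(np.mean(psa_result.delta_qalys > 0))
        assert curve["p_triple"].iloc[0] == expected

    def test_default_grid(self):
        grid = default_wtp_grid()
        assert grid[0] == 0.0
        assert grid[-1] == 600_000.0
        assert grid[1] - grid[0] == 5_000.0

    def test_empty_grid_rejected(self, psa_result):
        with pytest.raises(ValueError):
            ceac(psa_result, [])


class TestPriceThreshold:
    def test_bisection_matches_affine_closed_form(self, params, cohort,
                                                  settings, life_table):
        """Only triple-arm costs depend on the price, linearly, so the ICER
        is affine in price; the closed-form root is the oracle."""
        i0 = icer_at(selexipag_price_values(params, 0.0), cohort, settings,
                     life_table)
        i1k = icer_at(selexipag_price_values(params, 1000.0), cohort,
                      settings, life_table)
        slope = (i1k - i0) / 1000.0
        assert slope > 0
        root = (settings.wtp_per_qaly - i0) / slope
        found = price_threshold(params, cohort, settings, life_table)
        assert found == pytest.approx(root, abs=0.01)

    def test_fixed_point_at_current_price(self, params, cohort, settings,
                                          life_table, fitted):
        current = base_monthly_selexipag_price(params)
        found = price_threshold(params, cohort, settings, life_table,
                                target=fitted.icer)
        assert found == pytest.approx(current, abs=0.01)

    def test_unbracketed_target_reports_both_ends(self, params, cohort,
                                                  settings, life_table):
        with pytest.raises(ValueError, match="not bracketed"):
            price_threshold(params, cohort, settings, life_table,
                            target=10.0)

    def test_price_scaling_leaves_effects_unchanged(self, params, cohort,
                                                    settings, life_table,
                                                    fitted):
        result, _ = run_cea(selexipag_price_values(params, 100.0), cohort,
                            settings, life_table)
        assert result.incremental_qalys == pytest.approx(
            fitted.incremental_qalys, rel=1e-12)
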