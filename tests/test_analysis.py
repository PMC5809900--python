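"""Outcome arithmetic, analysis runners and the replication search."""

import dataclasses

import pytest

from vfscreen import (CohortTrace, DEFAULT_CONVENTIONS, IncrementalResult,
                      Strategy, do_screening_average, incremental,
                      population_weighted_total, replication_search,
                      run_base_case, run_strategies, run_univariate_sensitivity)
from vfscreen.analysis import DO_SCREENING_LABEL


def _trace(params, strategy, eff, cost=0.0, dose=0.0):
    return CohortTrace(strategy=strategy, params=params,
                       conventions=DEFAULT_CONVENTIONS,
                       cumulative_new_vf_incidence=eff, total_cost=cost,
                       total_dose=dose)


def _result(sex="female", strategy="xray-only", **kw):
    base = dict(strategy=strategy, sex=sex, scenario="base_case",
                effectiveness=0.0, cost=0.0, dose=0.0,
                delta_effect=0.0, delta_cost=0.0, delta_dose=0.0)
    base.update(kw)
    return IncrementalResult(**base)


class TestIncremental:
    def test_printed_operands(self, women_base):
        idx = _trace(women_base, Strategy.XRAY_ONLY, 23.3, cost=1027.0, dose=100.0)
        ref = _trace(women_base, Strategy.NO_SCREENING, 54.6, cost=60.0)
        r = incremental(idx, ref)
        assert r.delta_effect == pytest.approx(-31.3)
        assert r.delta_cost == pytest.approx(967.0)

    def test_self_difference_is_zero(self, women_base):
        ref = _trace(women_base, Strategy.NO_SCREENING, 54.6, cost=60.0)
        r = incremental(ref, ref)
        assert (r.delta_effect, r.delta_cost, r.delta_dose) == (0.0, 0.0, 0.0)

    def test_reference_must_be_no_screening(self, women_base):
        idx = _trace(women_base, Strategy.XRAY_ONLY, 20.0)
        with pytest.raises(ValueError):
            incremental(idx, idx)


class TestDoScreeningAverage:
    @pytest.mark.parametrize("effs,expected", [
        ((25.2, 25.2, 19.6), 23.3),   # women base case
        ((10.1, 10.1, 5.0), 8.4),     # men base case
    ])
    def test_printed_incidence_averages(self, effs, expected):
        results = [_result(strategy=s, effectiveness=e)
                   for s, e in zip(("xray-after-vfa", "vfa-only", "xray-only"), effs)]
        assert do_screening_average(results).effectiveness \
            == pytest.approx(expected, abs=0.05)

    def test_printed_dose_average(self):
        results = [_result(strategy=s, delta_dose=d)
                   for s, d in zip(("xray-after-vfa", "vfa-only", "xray-only"),
                                   (747.0, 141.0, 3394.0))]
        assert round(do_screening_average(results).delta_dose) == 1427

    def test_mean_of_equal_inputs_is_identity(self):
        results = [_result(strategy=s, effectiveness=12.5, delta_cost=100.0)
                   for s in ("xray-after-vfa", "vfa-only", "xray-only")]
        avg = do_screening_average(results)
        assert avg.effectiveness == 12.5 and avg.delta_cost == 100.0

    def test_requires_exactly_the_three_screening_strategies(self):
        results = [_result(strategy=s) for s in ("xray-only",) * 3]
        with pytest.raises(ValueError):
            do_screening_average(results)


class TestPopulationWeighting:
    def test_printed_combined_values(self):
        w = _result(sex="female", delta_effect=-31.3, delta_cost=967.0,
                    delta_dose=1427.0)
        m = _result(sex="male", delta_effect=-14.2, delta_cost=630.0,
                    delta_dose=1416.0)
        total = population_weighted_total(w, m)
        assert total.delta_effect == pytest.approx(-23.3, abs=0.05)
        assert total.delta_cost == pytest.approx(810.0, abs=1.0)
        assert total.delta_dose == pytest.approx(1422.0, abs=1.0)

    def test_equal_weights_reduce_to_mean(self):
        w = _result(sex="female", delta_cost=100.0)
        m = _result(sex="male", delta_cost=200.0)
        total = population_weighted_total(w, m, {"female": 1, "male": 1})
        assert total.delta_cost == 150.0


class TestRunners:
    def test_base_case_table_structure(self, women_base, men_base):
        frame = run_base_case(women_base, men_base)
        assert len(frame) == 11  # 5 rows per sex + weighted total
        women = frame[frame.sex == "female"].set_index("strategy")
        assert women.loc["xray-after-vfa", "effectiveness_pct"] == pytest.approx(
            women.loc["vfa-only", "effectiveness_pct"], abs=1e-12)
        # cost ordering of the published table: combined < radiography < VFA
        assert women.loc["xray-after-vfa", "delta_c"] \
            < women.loc["xray-only", "delta_c"] < women.loc["vfa-only", "delta_c"]

    def test_prevalence_decrease_lowers_incidence_and_cost(self, women_base):
        frame = run_univariate_sensitivity(women_base)
        sub = frame[frame.variant == "vf_prevalence"]
        assert (sub.delta_effect_vs_base < 0).all()
        assert (sub.delta_cost_vs_base < 0).all()

    def test_null_variant_produces_zero_deltas(self, men_base):
        # men's bracketed first-fracture incidence equals the base value
        frame = run_univariate_sensitivity(men_base)
        sub = frame[frame.variant == "vf_incidence"]
        assert (sub.delta_effect_vs_base.abs() < 1e-12).all()
        assert (sub.delta_cost_vs_base.abs() < 1e-12).all()

    def test_do_screening_row_is_mean_of_strategy_rows(self, women_base, men_base):
        frame = run_base_case(women_base, men_base).set_index(["sex", "strategy"])
        women = frame.loc["female"]
        arms = women.loc[["xray-after-vfa", "vfa-only", "xray-only"]]
        assert women.loc[DO_SCREENING_LABEL, "delta_c"] == pytest.approx(
            arms["delta_c"].mean())


@pytest.fixture(scope="module")
def search(women_base, men_base, women_subgroup, men_subgroup):
    return replication_search(women_base, men_base, women_subgroup, men_subgroup)


class TestReplicationSearch:
    def test_search_is_deterministic(self, search, women_base, men_base,
                                     women_subgroup, men_subgroup):
        again = replication_search(women_base, men_base, women_subgroup,
                                   men_subgroup)
        assert again.best == search.best
        assert again.score == search.score

    def test_scores_cover_full_space_with_unique_argmin(self, search):
        assert len(search.scores) == 64
        ordered = search.scores["score"].tolist()
        assert ordered[0] < ordered[1]  # argmin is strict

    def test_residuals_reported_for_every_target(self, search):
        assert len(search.residuals) == 22
        assert {"model", "printed", "residual"} <= set(search.residuals.columns)

    def test_empty_space_rejected(self, women_base, men_base, women_subgroup,
                                  men_subgroup):
        with pytest.raises(ValueError):
            replication_search(women_base, men_base, women_subgroup,
                               men_subgroup, space=[])

    def test_best_config_matches_mens_no_screening_incidence(self, search,
                                                             men_base):
        res = run_strategies(men_base, search.best)
        ns = res["incremental"]["no-screening"].effectiveness
        assert ns == pytest.approx(22.5, abs=1.0)
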