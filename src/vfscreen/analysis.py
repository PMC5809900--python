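"""Published outcome quantities and analysis drivers.

Incremental outcomes versus no screening (dE in percentage points of
cumulative new-fracture incidence, dC in euros per capita, dRE in microsievert
per capita), the averaged "do screening" comparator, population-weighted
totals, and the runners for the base case, the one-way sensitivity analysis,
alternative scenarios, and the replication-convention search.

Rounding follows the published tables (effectiveness to one decimal, euros and
microsievert to integers) and is applied only in the reporting layer; all
internal arithmetic is full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .cascade import SCREENING_STRATEGIES, Strategy
from .conventions import Conventions, DEFAULT_CONVENTIONS, convention_space
from .engine import CohortTrace, run_cohort
from .parameters import ParameterSet, univariate_variants
from .targets import POPULATION_WEIGHTS, SUBGROUP_DO_SCREENING_DELTA_E, TABLE_BASE_CASE

__all__ = [
    "IncrementalResult", "incremental", "do_screening_average",
    "population_weighted_total", "run_strategies", "run_base_case",
    "run_scenario", "run_univariate_sensitivity", "ReplicationResult",
    "replication_search",
]

DO_SCREENING_LABEL = "do-screening"


@dataclass(frozen=True)
class IncrementalResult:
    """Outcome differences of an index strategy versus no screening."""

    strategy: str
    sex: str
    scenario: str
    effectiveness: float        # cumulative new-VF incidence, per 100 persons
    cost: float                 # discounted EUR per capita
    dose: float                 # uSv per capita
    delta_effect: float         # index - no screening, percentage points
    delta_cost: float           # EUR per capita
    delta_dose: float           # uSv per capita

    def __post_init__(self) -> None:
        if self.delta_dose < 0:
            raise ValueError("screening cannot lower radiation dose below zero")


def incremental(index: CohortTrace, reference: CohortTrace) -> IncrementalResult:
    """Componentwise differences of an index trace versus the no-screening trace."""
    if reference.strategy is not Strategy.NO_SCREENING:
        raise ValueError("reference trace must be the no-screening run")
    if (index.params.sex, index.params.scenario) != (reference.params.sex,
                                                     reference.params.scenario):
        raise ValueError("index and reference traces use different parameter sets")
    return IncrementalResult(
        strategy=Strategy(index.strategy).value,
        sex=index.params.sex,
        scenario=index.params.scenario,
        effectiveness=index.cumulative_new_vf_incidence,
        cost=index.total_cost,
        dose=index.total_dose,
        delta_effect=index.cumulative_new_vf_incidence
        - reference.cumulative_new_vf_incidence,
        delta_cost=index.total_cost - reference.total_cost,
        delta_dose=index.total_dose - reference.total_dose,
    )


def _as_result(item) -> IncrementalResult:
    if isinstance(item, IncrementalResult):
        return item
    raise TypeError("expected IncrementalResult")


def do_screening_average(results) -> IncrementalResult:
    """Unweighted componentwise mean over the three screening strategies."""
    results = [_as_result(r) for r in results]
    strategies = {r.strategy for r in results}
    expected = {s.value for s in SCREENING_STRATEGIES}
    if strategies != expected:
        raise ValueError(f"need exactly the strategies {sorted(expected)}, got {sorted(strategies)}")
    if len({(r.sex, r.scenario) for r in results}) != 1:
        raise ValueError("results mix sexes or scenarios")
    n = len(results)
    mean = lambda attr: sum(getattr(r, attr) for r in results) / n
    return IncrementalResult(
        strategy=DO_SCREENING_LABEL, sex=results[0].sex, scenario=results[0].scenario,
        effectiveness=mean("effectiveness"), cost=mean("cost"), dose=mean("dose"),
        delta_effect=mean("delta_effect"), delta_cost=mean("delta_cost"),
        delta_dose=mean("delta_dose"),
    )


def population_weighted_total(women: IncrementalResult, men: IncrementalResult,
                              weights: dict = POPULATION_WEIGHTS) -> IncrementalResult:
    """Mean of the sex-specific results weighted by registration population."""
    if women.scenario != men.scenario:
        raise ValueError("scenario mismatch between sexes")
    ww, wm = float(weights["female"]), float(weights["male"])
    tot = ww + wm
    mix = lambda attr: (getattr(women, attr) * ww + getattr(men, attr) * wm) / tot
    return IncrementalResult(
        strategy=women.strategy, sex="total", scenario=women.scenario,
        effectiveness=mix("effectiveness"), cost=mix("cost"), dose=mix("dose"),
        delta_effect=mix("delta_effect"), delta_cost=mix("delta_cost"),
        delta_dose=mix("delta_dose"),
    )


def run_strategies(params: ParameterSet,
                   conventions: Conventions = DEFAULT_CONVENTIONS) -> dict:
    """All four strategy runs plus incrementals for one parameter set.

    Returns ``{"traces": {Strategy: CohortTrace}, "incremental": {token:
    IncrementalResult}, "do_screening": IncrementalResult}``.
    """
    traces = {s: run_cohort(s, params, conventions)
              for s in (Strategy.NO_SCREENING,) + SCREENING_STRATEGIES}
    ref = traces[Strategy.NO_SCREENING]
    inc = {s.value: incremental(traces[s], ref) for s in SCREENING_STRATEGIES}
    inc[Strategy.NO_SCREENING.value] = incremental(ref, ref)
    return {
        "traces": traces,
        "incremental": inc,
        "do_screening": do_screening_average(
            [inc[s.value] for s in SCREENING_STRATEGIES]),
    }


def _results_frame(per_sex: dict, include_total: bool = True) -> pd.DataFrame:
    rows = []
    totals = {}
    for sex, res in per_sex.items():
        order = [Strategy.NO_SCREENING.value, DO_SCREENING_LABEL] + [
            s.value for s in SCREENING_STRATEGIES]
        pool = dict(res["incremental"])
        pool[DO_SCREENING_LABEL] = res["do_screening"]
        for name in order:
            r = pool[name]
            rows.append({
                "sex": sex, "strategy": name,
                "effectiveness_pct": r.effectiveness,
                "delta_e": r.delta_effect,
                "cost_eur": r.cost,
                "delta_c": r.delta_cost,
                "delta_re": r.delta_dose,
            })
        totals[sex] = res["do_screening"]
    if include_total and set(totals) == {"female", "male"}:
        t = population_weighted_total(totals["female"], totals["male"])
        rows.append({"sex": "total", "strategy": DO_SCREENING_LABEL,
                     "effectiveness_pct": t.effectiveness, "delta_e": t.delta_effect,
                     "cost_eur": t.cost, "delta_c": t.delta_cost,
                     "delta_re": t.delta_dose})
    return pd.DataFrame(rows)


def run_base_case(women_params: ParameterSet, men_params: ParameterSet,
                  conventions: Conventions = DEFAULT_CONVENTIONS) -> pd.DataFrame:
    """Full base-case results table: per-sex strategy rows, do-screening rows,
    and the population-weighted total row."""
    return _results_frame({
        "female": run_strategies(women_params, conventions),
        "male": run_strategies(men_params, conventions),
    })


def run_scenario(women_params: ParameterSet, men_params: ParameterSet,
                 conventions: Conventions = DEFAULT_CONVENTIONS) -> pd.DataFrame:
    """Same output shape as :func:`run_base_case` for alternative parameters."""
    return run_base_case(women_params, men_params, conventions)


def _dense_rank(values: dict, decimals: int = 9) -> dict:
    """1-based dense ranks; values equal after rounding share a rank."""
    levels = sorted({round(v, decimals) for v in values.values()})
    return {k: levels.index(round(v, decimals)) + 1 for k, v in values.items()}


def run_univariate_sensitivity(base: ParameterSet,
                               conventions: Conventions = DEFAULT_CONVENTIONS
                               ) -> pd.DataFrame:
    """One-way sensitivity analysis for one sex.

    For every bracketed input variant and every screening strategy, reports the
    change in cumulative incidence and cost versus the base-case run of the
    same strategy, plus the strategy's effectiveness and cost rank within the
    variant (1 = most effective / cheapest).
    """
    base_res = run_strategies(base, conventions)
    rows = []
    for name, variant in univariate_variants(base):
        var_res = run_strategies(variant, conventions)
        effs = {s.value: var_res["incremental"][s.value].effectiveness
                for s in SCREENING_STRATEGIES}
        costs = {s.value: var_res["incremental"][s.value].cost
                 for s in SCREENING_STRATEGIES}
        eff_rank = _dense_rank(effs)
        cost_rank = _dense_rank(costs)
        for s in SCREENING_STRATEGIES:
            b = base_res["incremental"][s.value]
            v = var_res["incremental"][s.value]
            rows.append({
                "variant": name, "strategy": s.value,
                "effectiveness_pct": v.effectiveness,
                "cost_eur": v.cost,
                "delta_effect_vs_base": v.effectiveness - b.effectiveness,
                "delta_cost_vs_base": v.cost - b.cost,
                "effect_rank": eff_rank[s.value],
                "cost_rank": cost_rank[s.value],
            })
    return pd.DataFrame(rows)


@dataclass
class ReplicationResult:
    """Outcome of the exhaustive convention search."""

    best: Conventions
    score: float
    residuals: pd.DataFrame     # per-target model/printed/residual for the best config
    scores: pd.DataFrame        # score per convention combination

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ReplicationResult(best={self.best.label}, score={self.score:.4f}, "
                f"n_configs={len(self.scores)})")


def _target_rows(conv: Conventions, base_w: ParameterSet, base_m: ParameterSet,
                 sg_w: ParameterSet, sg_m: ParameterSet) -> list[dict]:
    rows = []
    for sex, params in (("female", base_w), ("male", base_m)):
        res = run_strategies(params, conv)
        ns = res["incremental"][Strategy.NO_SCREENING.value]
        eff_p, cost_p, _ = TABLE_BASE_CASE[(sex, Strategy.NO_SCREENING)]
        rows.append({"target": f"{sex}/no-screening/effectiveness",
                     "model": ns.effectiveness, "printed": eff_p})
        for s in SCREENING_STRATEGIES:
            r = res["incremental"][s.value]
            eff_p, cost_p, dre_p = TABLE_BASE_CASE[(sex, s)]
            ns_cost_p = TABLE_BASE_CASE[(sex, Strategy.NO_SCREENING)][1]
            rows.append({"target": f"{sex}/{s.value}/effectiveness",
                         "model": r.effectiveness, "printed": eff_p})
            rows.append({"target": f"{sex}/{s.value}/delta_cost",
                         "model": r.delta_cost, "printed": cost_p - ns_cost_p})
            rows.append({"target": f"{sex}/{s.value}/delta_dose",
                         "model": r.delta_dose, "printed": dre_p})
    for sex, params in (("female", sg_w), ("male", sg_m)):
        res = run_strategies(params, conv)
        rows.append({"target": f"{sex}/subgroup/do-screening/delta_effect",
                     "model": res["do_screening"].delta_effect,
                     "printed": SUBGROUP_DO_SCREENING_DELTA_E[sex]})
    return rows


def replication_search(base_w: ParameterSet, base_m: ParameterSet,
                       sg_w: ParameterSet, sg_m: ParameterSet,
                       space=None) -> ReplicationResult:
    """Exhaustively score every convention combination against the printed values.

    Each combination is scored by the sum of relative absolute errors
    ``|model - printed| / |printed|`` over the printed per-sex, per-strategy
    effectiveness / incremental-cost / incremental-dose values and the printed
    subgroup do-screening incidence reductions.  Ties break in the documented
    iteration order of :func:`vfscreen.conventions.convention_space`.
    Deterministic: no randomness anywhere.
    """
    space = list(convention_space()) if space is None else list(space)
    if not space:
        raise ValueError("empty convention space")
    best_conv = None
    best_score = None
    best_rows = None
    score_rows = []
    for conv in space:
        rows = _target_rows(conv, base_w, base_m, sg_w, sg_m)
        score = sum(abs(r["model"] - r["printed"]) / abs(r["printed"])
                    for r in rows if r["printed"] != 0)
        score_rows.append({"conventions": conv.label, "score": score,
                           **conv.to_dict()})
        if best_score is None or score < best_score:
            best_conv, best_score, best_rows = conv, score, rows
    residuals = pd.DataFrame(best_rows)
    residuals["residual"] = residuals["model"] - residuals["printed"]
    return ReplicationResult(best=best_conv, score=best_score, residuals=residuals,
                             scores=pd.DataFrame(score_rows).sort_values(
                                 "score", kind="stable").reset_index(drop=True))
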