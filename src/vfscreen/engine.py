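"""Deterministic cohort state-transition engine.

Runs one strategy for one parameter set over the model horizon and accrues the
three outcomes: cumulative incident ("new") vertebral fractures, discounted
cost per capita, and cumulative radiation dose per capita.

Cycle anatomy
-------------
Each cycle of ``cycle_length`` years starts with a screening event (and, under
the six-event convention, one extra event closes the horizon).  Patients who
test positive receive one year of anti-osteoporotic therapy, which multiplies
their new-fracture probability for the cycle by ``rr_treatment``; therapy has
expired by the next screen, where still-positive patients are re-treated.
Disease transitions then play out: fracture-free patients acquire a first
(prevalent) fracture with ``vf_incidence``; fracture carriers suffer an
incident new fracture with ``new_vf_incidence``.  A new fracture on therapy is
diagnosed and the patient leaves the simulation; an untreated new fracture
exits only if clinically recognised (symptomatic fraction 1/(1+2.8)) unless
the exit-all convention is active.  Survivomg asymptomatic fractures stay at
risk and remain eligible for screening.

Payoffs
-------
Screening costs are discounted at the event time; disease payoffs at the cycle
midpoint (half-cycle correction).  A patient's *first* positive test incurs the
all-in per-patient fracture treatment cost; every incident fracture incurs one
drug-year plus a physician visit (optionally plus the symptomatic-weighted
procedure cost).  Effectiveness and radiation dose are not discounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._state import COMPARTMENTS, CompartmentVector
from .cascade import Strategy, apply_screen, screen_profile
from .conventions import Conventions, DEFAULT_CONVENTIONS
from .parameters import ParameterSet, ValidationError, convert_cycle_probability

__all__ = ["CompartmentVector", "CohortTrace", "build_cycle_transition",
           "discount_factor", "treated_new_vf_probability", "run_cohort"]


def treated_new_vf_probability(params: ParameterSet,
                               conventions: Conventions = DEFAULT_CONVENTIONS) -> float:
    """Per-cycle new-fracture probability while on therapy.

    Default: the relative risk applies to the whole cycle in which therapy
    starts.  Under the pro-rated convention only the first year of a longer
    cycle is protected; the cycle probability is recomposed from annual
    hazards.
    """
    q = params.new_vf_incidence
    rr = params.rr_treatment
    cl = params.cycle_length
    if not conventions.rr_prorated or cl <= 1.0:
        out = q * rr
    else:
        q1 = convert_cycle_probability(q, cl, 1.0)
        out = 1.0 - (1.0 - q1 * rr) * (1.0 - q1) ** (cl - 1.0)
    if not 0.0 <= out <= 1.0:
        raise ValidationError(f"treated new-VF probability {out} outside [0, 1]")
    return out


def build_cycle_transition(params: ParameterSet, on_therapy: bool,
                           conventions: Conventions = DEFAULT_CONVENTIONS) -> dict:
    """Per-cycle transition probabilities over the published health states.

    Returns a nested mapping ``{from_state: {to_state: p}}``; rows sum to one.
    Movement back to ``NO_VF`` is impossible.  The engine routes new-fracture
    mass between the exit and the at-risk post-fracture stratum according to
    the active conventions; the matrix carries the total new-fracture hazard.
    """
    inc = params.vf_incidence
    q = treated_new_vf_probability(params, conventions) if on_therapy \
        else params.new_vf_incidence
    matrix = {
        "NO_VF": {"NO_VF": 1.0 - inc, "PREVALENT_VF": inc},
        "PREVALENT_VF": {"PREVALENT_VF": 1.0 - q, "NEW_VF_EXITED": q},
        "POST_VF": {"POST_VF": 1.0 - q, "NEW_VF_EXITED": q},
        "NEW_VF_EXITED": {"NEW_VF_EXITED": 1.0},
        "VFA_IMPOSSIBLE": {"VFA_IMPOSSIBLE": 1.0},
    }
    for state, row in matrix.items():
        for p in row.values():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"transition {state}: probability {p} outside [0, 1]")
        s = sum(row.values())
        if abs(s - 1.0) > 1e-12:
            raise ValidationError(f"transition row {state} sums to {s}")
    return matrix


def discount_factor(event_time_years: float, rate: float, half_cycle: bool = False,
                    cycle_length: float = 2.0) -> float:
    """Annual-compounding present-value factor, optionally at the cycle midpoint."""
    if event_time_years < 0:
        raise ValidationError("event time must be >= 0")
    if rate < 0:
        raise ValidationError("discount rate must be >= 0")
    t = event_time_years + (cycle_length / 2.0 if half_cycle else 0.0)
    return (1.0 + rate) ** (-t)


@dataclass
class CohortTrace:
    """Completed run of one strategy: per-cycle occupancy and accrued outcomes.

    ``cumulative_new_vf_incidence`` is incident fractures per 100 cohort
    members; under the event-counting convention recurrent fractures are
    included, so the figure may exceed 100 in high-risk scenarios.
    """

    strategy: Strategy
    params: ParameterSet
    conventions: Conventions
    snapshots: list = field(default_factory=list)           # CompartmentVector per cycle
    incidence_series: list = field(default_factory=list)    # cumulative, per 100
    cost_series: list = field(default_factory=list)         # cumulative discounted EUR
    dose_series: list = field(default_factory=list)         # cumulative uSv
    cumulative_new_vf_incidence: float = 0.0
    cumulative_new_vf_persons: float = 0.0
    total_cost: float = 0.0
    total_dose: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (cycle, compartment) plus summary columns."""
        rows = []
        for i, snap in enumerate(self.snapshots):
            for comp in COMPARTMENTS:
                rows.append({
                    "cycle": i,
                    "time_years": i * self.params.cycle_length,
                    "compartment": comp,
                    "occupancy": snap[comp],
                    "cum_incidence_pct": self.incidence_series[i],
                    "cum_cost_eur": self.cost_series[i],
                    "cum_dose_usv": self.dose_series[i],
                })
        return pd.DataFrame(rows)


def run_cohort(strategy: Strategy, params: ParameterSet,
               conventions: Conventions = DEFAULT_CONVENTIONS) -> CohortTrace:
    """Run the deterministic cohort model for one strategy.

    The cohort starts with ``vf_prevalence`` in the prevalent-fracture state
    and the rest fracture-free.  Screening events occur at every cycle start
    (plus one at the horizon under the six-event convention); disease
    transitions follow :func:`build_cycle_transition`; payoffs accrue as
    described in the module docstring.
    """
    strategy = Strategy(strategy)
    n_cycles = params.n_cycles
    # degenerate zero-length horizon: nothing happens, not even a screen
    n_screens = 0 if n_cycles == 0 else \
        n_cycles + (1 if conventions.six_screening_events else 0)
    cl = params.cycle_length
    rate = params.discount_rate
    sigma = params.symptomatic_fraction
    exit_all = conventions.untreated_exit_all

    q = params.new_vf_incidence
    q_rx = treated_new_vf_probability(params, conventions)
    inc = params.vf_incidence
    newvf_cost = params.cost_drug_year + params.cost_physician_visit
    if conventions.procedure_cost_added:
        newvf_cost += sigma * params.cost_procedure

    vec = CompartmentVector.initial(params.vf_prevalence)
    trace = CohortTrace(strategy=strategy, params=params, conventions=conventions)
    events = persons = cost = dose = 0.0

    for k in range(max(n_screens, n_cycles)):
        t = k * cl
        if k < n_screens and strategy is not Strategy.NO_SCREENING:
            profile = screen_profile(strategy, params, conventions, first_event=(k == 0))
            vec, ev_cost, ev_dose = apply_screen(profile, vec)
            cost += ev_cost * discount_factor(t, rate)
            dose += ev_dose
        if k >= n_cycles:
            break

        # disease transitions over [t, t + cl)
        df_mid = discount_factor(t, rate, half_cycle=True, cycle_length=cl)
        new = CompartmentVector({c: 0.0 for c in COMPARTMENTS})
        new["exited"] = vec["exited"]

        def untreated_draw(mass: float, first: bool) -> tuple[float, float]:
            """One new-fracture draw on an untreated pool.

            Returns (surviving non-fractured mass, asymptomatic survivors who
            move to the post-new-fracture stratum).  Exits and payoffs accrue
            in place.
            """
            nonlocal events, persons, cost
            ev = mass * q
            events += ev
            if first:
                persons += ev
            cost += ev * newvf_cost * df_mid
            if exit_all:
                new["exited"] += ev
                return mass - ev, 0.0
            new["exited"] += ev * sigma
            return mass - ev, ev * (1.0 - sigma)

        # fracture-free pools acquire a first (prevalent) fracture; arrivals
        # join the undiagnosed pool after this cycle's new-fracture draws
        for src, dst in (("novf_naive", "prev_undx"), ("novf_diag", "prev_undx"),
                         ("imp_novf", "imp_prev")):
            moved = vec[src] * inc
            new[src] += vec[src] - moved
            new[dst] += moved
        # untreated carriers.  A first fracture whose asymptomatic survivor
        # stays at risk is exposed to one further same-cycle draw from the
        # post-new-fracture pool (two-year cycles are long enough for
        # recurrent fractures; at most two events per cycle are modelled).
        prev_surv, chain_undx = untreated_draw(vec["prev_undx"], True)
        post_surv, chain_dx = untreated_draw(vec["post_dx"], True)
        pn_undx_surv, stay_undx = untreated_draw(vec["postnv_undx"] + chain_undx, False)
        pn_dx_surv, stay_dx = untreated_draw(vec["postnv_dx"] + chain_dx, False)
        new["prev_undx"] += prev_surv
        new["post_dx"] += post_surv
        new["postnv_undx"] += pn_undx_surv + stay_undx
        new["postnv_dx"] += pn_dx_surv + stay_dx
        # the never-screened (VFA-impossible) stratum progresses identically
        imp_surv, chain_imp = untreated_draw(vec["imp_prev"], True)
        imp_pn_surv, stay_imp = untreated_draw(vec["imp_postnv"] + chain_imp, False)
        new["imp_prev"] += imp_surv
        new["imp_postnv"] += imp_pn_surv + stay_imp
        # treated strata: a new fracture on therapy is diagnosed and exits;
        # survivors finish therapy and wait re-screening
        for src, surv_dst, first in (("prev_rx", "post_dx", True),
                                     ("post_rx", "post_dx", True),
                                     ("postnv_rx", "postnv_dx", False)):
            mass = vec[src]
            ev = mass * q_rx
            events += ev
            if first:
                persons += ev
            cost += ev * newvf_cost * df_mid
            new["exited"] += ev
            new[surv_dst] += mass - ev

        vec = new
        vec.check_conserved()
        trace.snapshots.append(vec.copy())
        counted = events if conventions.count_events else persons
        trace.incidence_series.append(counted * 100.0)
        trace.cost_series.append(cost)
        trace.dose_series.append(dose)

    trace.cumulative_new_vf_incidence = (events if conventions.count_events
                                         else persons) * 100.0
    trace.cumulative_new_vf_persons = persons * 100.0
    trace.total_cost = cost
    trace.total_dose = dose
    if strategy is Strategy.NO_SCREENING and trace.total_dose != 0.0:
        raise AssertionError("no-screening run accrued radiation dose")
    return trace
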