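"""Cohort engine: transitions, discounting, traces and structural limits."""

import dataclasses

import pytest

from vfscreen import (Conventions, Strategy, build_cycle_transition,
                      discount_factor, run_cohort)
from vfscreen.parameters import ValidationError

ALL_STRATEGIES = list(Strategy)


class TestCycleTransition:
    def test_untreated_new_fracture_probability(self, women_base):
        m = build_cycle_transition(women_base, on_therapy=False)
        assert m["PREVALENT_VF"]["NEW_VF_EXITED"] == 0.22

    def test_therapy_scales_by_relative_risk(self, women_base):
        m = build_cycle_transition(women_base, on_therapy=True)
        assert m["PREVALENT_VF"]["NEW_VF_EXITED"] == pytest.approx(0.22 * 0.58)

    @pytest.mark.parametrize("on_therapy", [False, True])
    def test_rows_are_stochastic(self, women_base, on_therapy):
        m = build_cycle_transition(women_base, on_therapy)
        for row in m.values():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_way_back_to_no_vf(self, women_base):
        m = build_cycle_transition(women_base, False)
        for state in ("PREVALENT_VF", "POST_VF", "NEW_VF_EXITED"):
            assert m[state].get("NO_VF", 0.0) == 0.0


class TestDiscounting:
    def test_present_value_at_time_zero(self):
        assert discount_factor(0.0, 0.05) == 1.0

    def test_half_cycle_midpoint(self):
        # cycle [2, 4) at 5%: midpoint t=3
        assert discount_factor(2.0, 0.05, half_cycle=True, cycle_length=2.0) \
            == pytest.approx(1.05 ** -3, abs=1e-10)

    def test_zero_rate_is_unity(self):
        assert discount_factor(7.0, 0.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(-1.0, 0.05)


class TestRunCohort:
    def test_no_events_limit_accrues_screening_costs_only(self, women_base):
        quiet = dataclasses.replace(women_base, vf_incidence=0.0,
                                    new_vf_incidence=0.0)
        tr = run_cohort(Strategy.XRAY_ONLY, quiet)
        assert tr.cumulative_new_vf_incidence == 0.0
        # screening tests plus the first-diagnosis payoff for the 22% prevalent
        assert tr.total_cost > 0
        assert tr.total_dose > 0

    def test_no_screening_has_zero_dose(self, women_base, men_base):
        for p in (women_base, men_base):
            assert run_cohort(Strategy.NO_SCREENING, p).total_dose == 0.0

    @pytest.mark.parametrize("strategy", ALL_STRATEGIES)
    def test_mass_conserved_every_cycle(self, women_base, strategy):
        tr = run_cohort(strategy, women_base)
        for snap in tr.snapshots:
            assert snap.total() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("strategy", ALL_STRATEGIES)
    def test_series_monotone_nondecreasing(self, women_base, strategy):
        tr = run_cohort(strategy, women_base)
        for series in (tr.incidence_series, tr.dose_series):
            assert all(b >= a - 1e-12 for a, b in zip(series, series[1:]))

    @pytest.mark.parametrize("strategy", [Strategy.XRAY_AFTER_VFA,
                                          Strategy.VFA_ONLY, Strategy.XRAY_ONLY])
    def test_screening_never_hurts(self, women_base, strategy):
        ns = run_cohort(Strategy.NO_SCREENING, women_base)
        assert run_cohort(strategy, women_base).cumulative_new_vf_incidence \
            <= ns.cumulative_new_vf_incidence + 1e-12

    def test_ineffective_drug_equalises_all_strategies(self, women_base):
        # screening with an inert drug changes nothing clinically: identical
        # fraction of patients ever fracturing (recurrence tallies still
        # differ because a *diagnosed* new fracture exits the simulation)
        inert = dataclasses.replace(women_base, rr_treatment=1.0)
        persons = {s: run_cohort(s, inert).cumulative_new_vf_persons
                   for s in ALL_STRATEGIES}
        ref = persons[Strategy.NO_SCREENING]
        for v in persons.values():
            assert v == pytest.approx(ref, abs=1e-9)
        # with the exit-on-every-fracture convention the event tallies agree too
        exit_all = Conventions(untreated_exit_all=True)
        events = {s: run_cohort(s, inert, exit_all).cumulative_new_vf_incidence
                  for s in ALL_STRATEGIES}
        for v in events.values():
            assert v == pytest.approx(events[Strategy.NO_SCREENING], abs=1e-9)

    def test_vfa_based_strategies_identical(self, women_base, men_base):
        for p in (women_base, men_base):
            a = run_cohort(Strategy.XRAY_AFTER_VFA, p)
            b = run_cohort(Strategy.VFA_ONLY, p)
            assert a.cumulative_new_vf_incidence == pytest.approx(
                b.cumulative_new_vf_incidence, abs=1e-12)

    def test_zero_horizon_is_inert(self, women_base):
        degenerate = dataclasses.replace(women_base, horizon=0.0)
        for s in ALL_STRATEGIES:
            tr = run_cohort(s, degenerate)
            assert (tr.cumulative_new_vf_incidence, tr.total_cost,
                    tr.total_dose) == (0.0, 0.0, 0.0)

    def test_five_event_convention_lowers_dose(self, women_base):
        six = run_cohort(Strategy.XRAY_ONLY, women_base)
        five = run_cohort(Strategy.XRAY_ONLY, women_base,
                          Conventions(six_screening_events=False))
        assert five.total_dose < six.total_dose

    def test_trace_frame_is_tidy(self, women_base):
        frame = run_cohort(Strategy.VFA_ONLY, women_base).to_frame()
        assert {"cycle", "compartment", "occupancy",
                "cum_incidence_pct"} <= set(frame.columns)
        assert frame.groupby("cycle")["occupancy"].sum().round(12).eq(1.0).all()
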