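"""Individual-level Monte-Carlo twin of the cohort engine.

Simulates patient trajectories under exactly the probabilities, payoffs and
conventions the deterministic engine uses, standing in for the claims-derived
study population and serving as an independent oracle: at large ``n`` the
microsimulation means must agree with the cohort engine within Monte-Carlo
error on all three outcomes.

Randomness: one numpy ``default_rng(seed)`` stream, consumed cycle-
synchronously in a fixed draw order over the patient vector, so identical
``(params, n, seed)`` give bit-identical output.  State-changing branches
(unreadable trait, test results, fractures, symptomatic recognition) are
drawn; per-event screening costs and doses are accrued as their conditional
expectations, which leaves every mean unchanged and tightens the oracle.
Logged costs are present values (discounted to t = 0), so summaries are plain
sums; doses are physical (undiscounted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cascade import Strategy, screen_profile
from .conventions import Conventions, DEFAULT_CONVENTIONS
from .engine import discount_factor, run_cohort, treated_new_vf_probability
from .parameters import ParameterSet

__all__ = ["PatientTrajectory", "simulate_cohort", "summarize_microsim",
           "validate_against_cohort"]

# health-state codes
_NOVF, _PREV, _POST, _POSTNV, _EXITED = 0, 1, 2, 3, 4
_STATE_NAMES = {_NOVF: "NO_VF", _PREV: "PREVALENT_VF", _POST: "POST_VF",
                _POSTNV: "POST_VF", _EXITED: "NEW_VF_EXITED"}

EVENTS = ("screen", "vfa_unreadable", "test_positive", "therapy_start",
          "therapy_end", "incident_vf", "new_vf_exit")


@dataclass
class PatientTrajectory:
    """Event log of one simulated patient.

    ``events`` is a list of ``(time_years, event, cost_eur, dose_usv)``;
    ``incident_vf`` marks a new (post-first) vertebral fracture and
    ``new_vf_exit`` the resulting exit when the fracture is diagnosed or
    symptomatic.  Costs are present values; a patient's dose is the sum of the
    logged doses.
    """

    patient_id: int
    sex: str
    initial_state: str
    events: list = field(default_factory=list)
    final_state: str = "NO_VF"

    @property
    def total_cost(self) -> float:
        return sum(e[2] for e in self.events)

    @property
    def total_dose(self) -> float:
        return sum(e[3] for e in self.events)

    @property
    def n_new_vf(self) -> int:
        return sum(1 for e in self.events if e[1] == "incident_vf")


@dataclass
class _ArrayResult:
    """Vectorised per-patient outcomes (internal)."""

    n: int
    seed: int
    strategy: Strategy
    params: ParameterSet
    conventions: Conventions
    new_vf_counts: np.ndarray   # incident new fractures per patient
    costs: np.ndarray           # discounted EUR per patient
    doses: np.ndarray           # uSv per patient
    initial_states: np.ndarray
    final_states: np.ndarray
    log: list | None            # [(ids, time, event, costs, doses)] or None


def _simulate(strategy: Strategy, params: ParameterSet, n: int, seed: int,
              conventions: Conventions, keep_log: bool) -> _ArrayResult:
    if n < 0:
        raise ValueError("n must be >= 0")
    strategy = Strategy(strategy)
    rng = np.random.default_rng(seed)
    cl = params.cycle_length
    rate = params.discount_rate
    n_cycles = params.n_cycles
    n_screens = 0 if n_cycles == 0 else \
        n_cycles + (1 if conventions.six_screening_events else 0)
    q = params.new_vf_incidence
    q_rx = treated_new_vf_probability(params, conventions)
    inc = params.vf_incidence
    sigma = params.symptomatic_fraction
    exit_all = conventions.untreated_exit_all
    newvf_cost = params.cost_drug_year + params.cost_physician_visit
    if conventions.procedure_cost_added:
        newvf_cost += sigma * params.cost_procedure

    state = np.where(rng.random(n) < params.vf_prevalence, _PREV, _NOVF).astype(np.int8)
    initial = state.copy()
    vf_diagnosed = np.zeros(n, dtype=bool)
    fp_charged = np.zeros(n, dtype=bool)
    unreadable = np.zeros(n, dtype=bool)   # absorbing VFA-impossible flag
    on_therapy = np.zeros(n, dtype=bool)
    counts = np.zeros(n, dtype=np.int64)
    costs = np.zeros(n, dtype=float)
    doses = np.zeros(n, dtype=float)
    log: list | None = [] if keep_log else None

    def record(ids, time, event, cost, dose):
        if log is not None and ids.size:
            log.append((ids.copy(), time, event,
                        np.broadcast_to(np.asarray(cost, dtype=float), ids.shape).copy(),
                        np.broadcast_to(np.asarray(dose, dtype=float), ids.shape).copy()))

    for k in range(max(n_screens, n_cycles)):
        t = k * cl
        df = discount_factor(t, rate)
        if k < n_screens and strategy is not Strategy.NO_SCREENING:
            profile = screen_profile(strategy, params, conventions, first_event=(k == 0))
            if profile.p_unreadable_exit > 0.0:
                newly = (state != _EXITED) & ~unreadable & \
                    (rng.random(n) < profile.p_unreadable_exit)
                unreadable |= newly
                record(np.flatnonzero(newly), t, "vfa_unreadable", 0.0, 0.0)
            screened = (state != _EXITED) & ~unreadable
            carrier = screened & (state != _NOVF)
            naive_vf = carrier & ~vf_diagnosed
            prior_vf = carrier & vf_diagnosed
            no_vf = screened & (state == _NOVF)
            # expected per-event payoffs
            for mask, c, d in ((naive_vf, profile.expected_cost_given_vf,
                                profile.expected_dose_given_vf),
                               (prior_vf, profile.expected_cost_prior_dx,
                                profile.expected_dose_prior_dx),
                               (no_vf, profile.expected_cost_given_novf,
                                profile.expected_dose_given_novf)):
                costs[mask] += c * df
                doses[mask] += d
                record(np.flatnonzero(mask), t, "screen", c * df, d)
            draw = rng.random(n)
            det_first = naive_vf & (draw < profile.p_treat_given_vf)
            det_re = prior_vf & (draw < profile.p_treat_prior_dx)
            fp_first = no_vf & ~fp_charged & (draw < profile.p_treat_given_novf)
            costs[det_first] += profile.cost_first_diagnosis * df
            costs[fp_first] += profile.cost_first_diagnosis * df
            vf_diagnosed |= det_first
            fp_charged |= fp_first
            on_therapy = det_first | det_re
            record(np.flatnonzero(det_first | fp_first), t, "test_positive",
                   profile.cost_first_diagnosis * df, 0.0)
            record(np.flatnonzero(det_re), t, "test_positive", 0.0, 0.0)
            record(np.flatnonzero(on_therapy), t, "therapy_start", 0.0, 0.0)
        if k >= n_cycles:
            break

        df_mid = discount_factor(t, rate, half_cycle=True, cycle_length=cl)
        draw = rng.random(n)
        # fracture-free patients may acquire a first (prevalent) fracture
        acquire = (state == _NOVF) & (draw < inc)
        state[acquire] = _PREV
        # carriers draw an incident new fracture
        at_risk = (state == _PREV) | (state == _POST) | (state == _POSTNV)
        at_risk &= ~acquire  # this cycle's acquisitions are not yet at risk
        first_type = at_risk & (state != _POSTNV)  # no new fracture so far
        p_event = np.where(on_therapy, q_rx, q)
        fracture = at_risk & (draw < p_event)
        counts[fracture] += 1
        costs[fracture] += newvf_cost * df_mid
        record(np.flatnonzero(fracture), t + cl / 2.0, "incident_vf",
               newvf_cost * df_mid, 0.0)
        # exits: diagnosed-on-therapy always; untreated per convention
        if exit_all:
            exits = fracture
        else:
            sympt = rng.random(n) < sigma
            exits = fracture & (on_therapy | sympt)
        record(np.flatnonzero(exits), t + cl / 2.0, "new_vf_exit", 0.0, 0.0)
        # fracture survivors move to the post-new-VF stratum
        stayers = fracture & ~exits
        state[stayers] = _POSTNV
        state[exits] = _EXITED
        # an asymptomatic survivor of a *first* fracture faces one further
        # same-cycle draw from the post-new-fracture pool (they are untreated
        # by construction: treated fractures always exit)
        chain = stayers & first_type
        if chain.any():
            frac2 = chain & (rng.random(n) < q)
            counts[frac2] += 1
            costs[frac2] += newvf_cost * df_mid
            record(np.flatnonzero(frac2), t + cl / 2.0, "incident_vf",
                   newvf_cost * df_mid, 0.0)
            exits2 = frac2 if exit_all else frac2 & (rng.random(n) < sigma)
            record(np.flatnonzero(exits2), t + cl / 2.0, "new_vf_exit", 0.0, 0.0)
            state[exits2] = _EXITED
        # therapy expires; treated survivors without a fracture become POST
        rx_surv = on_therapy & ~fracture
        state[rx_surv & (state == _PREV)] = _POST
        record(np.flatnonzero(on_therapy & (state != _EXITED)),
               t + min(1.0, cl), "therapy_end", 0.0, 0.0)
        on_therapy = np.zeros(n, dtype=bool)

    return _ArrayResult(n=n, seed=seed, strategy=strategy, params=params,
                        conventions=conventions, new_vf_counts=counts, costs=costs,
                        doses=doses, initial_states=initial, final_states=state,
                        log=log)


def simulate_cohort(strategy: Strategy, params: ParameterSet, n: int, seed: int,
                    conventions: Conventions = DEFAULT_CONVENTIONS
                    ) -> list[PatientTrajectory]:
    """Simulate ``n`` patient trajectories; deterministic given (params, n, seed)."""
    res = _simulate(strategy, params, n, seed, conventions, keep_log=True)
    trajs = [PatientTrajectory(patient_id=i, sex=params.sex,
                               initial_state=_STATE_NAMES[int(res.initial_states[i])],
                               final_state=_STATE_NAMES[int(res.final_states[i])])
             for i in range(n)]
    for ids, time, event, cs, ds in res.log:
        for j, pid in enumerate(ids):
            trajs[pid].events.append((time, event, float(cs[j]), float(ds[j])))
    for tr in trajs:
        tr.events.sort(key=lambda e: e[0])
    return trajs


def summarize_microsim(trajectories, count_events: bool = True) -> dict:
    """Per-capita summaries of a trajectory collection.

    ``incidence`` is new fractures per 100 patients (events, or persons with
    ``count_events=False``); cost is the mean present-value cost; dose the
    mean physical dose.  Invariant under trajectory ordering.
    """
    if isinstance(trajectories, _ArrayResult):
        res = trajectories
        n = res.n
        if n == 0:
            raise ValueError("empty collection")
        counted = res.new_vf_counts if count_events else (res.new_vf_counts > 0)
        return {"n": n,
                "incidence_pct": float(counted.mean() * 100.0),
                "mean_cost_eur": float(res.costs.mean()),
                "mean_dose_usv": float(res.doses.mean())}
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("empty collection")
    n = len(trajs)
    counts = np.array([tr.n_new_vf for tr in trajs])
    counted = counts if count_events else (counts > 0)
    return {"n": n,
            "incidence_pct": float(counted.mean() * 100.0),
            "mean_cost_eur": float(np.mean([tr.total_cost for tr in trajs])),
            "mean_dose_usv": float(np.mean([tr.total_dose for tr in trajs]))}


def validate_against_cohort(strategy: Strategy, params: ParameterSet, n: int,
                            seed: int,
                            conventions: Conventions = DEFAULT_CONVENTIONS) -> dict:
    """Compare microsimulation means to the deterministic cohort engine.

    PASS requires each outcome (incidence, discounted cost, dose) to lie
    within three Monte-Carlo standard errors of the cohort value.  The report
    carries the z-scores; with small ``n`` the standard errors are wide and a
    note flags the low power.
    """
    if n <= 0:
        raise ValueError("n must be > 0 for validation")
    res = _simulate(strategy, params, n, seed, conventions, keep_log=False)
    trace = run_cohort(strategy, params, conventions)
    counted = (res.new_vf_counts if conventions.count_events
               else (res.new_vf_counts > 0)).astype(float) * 100.0
    report = {"strategy": Strategy(strategy).value, "sex": params.sex,
              "scenario": params.scenario, "n": n, "seed": seed,
              "conventions": conventions.label, "outcomes": {}}
    for name, sample, target in (
            ("incidence_pct", counted, trace.cumulative_new_vf_incidence),
            ("mean_cost_eur", res.costs, trace.total_cost),
            ("mean_dose_usv", res.doses, trace.total_dose)):
        mean = float(sample.mean())
        sd = float(sample.std(ddof=1)) if n > 1 else float("nan")
        se = sd / np.sqrt(n) if n > 1 else float("nan")
        if se and se > 0 and np.isfinite(se):
            z = (mean - target) / se
        else:
            z = 0.0 if mean == target else float("inf")
        report["outcomes"][name] = {
            "microsim": mean, "cohort": float(target), "se": float(se),
            "z": float(z), "pass": bool(abs(z) <= 3.0),
        }
    report["pass"] = all(o["pass"] for o in report["outcomes"].values())
    if n < 1000:
        report["note"] = "small n: Monte-Carlo standard errors are wide"
    return report
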